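# Methods

`omagkit` implements the quantitative chain of an OCT-based microvascular
perfusion analysis: optical microangiography (OMAG) flow reconstruction,
eigendecomposition velocimetry of repeated A-line ensembles, vessel-density
and perfusion-rate metrics, Poiseuille hemodynamics on patterned microvessel
graphs, fluorescence-image quantification rules, and formula-level
expression screening. Everything runs on synthetic phantoms with known
ground truth, so each stage is testable without instrument data.

## Signal model and phantom generators

An A-scan ensemble is a complex block `signal[depth, repeat, position]`.
The repeat series of a voxel is modeled as

    s_k = A_s e^{i phi_s} + sum_seg A_f e^{i(2 pi f t_k + phi_f)} + n_k,

where the static term is the tissue clutter (constant phasor, random
speckle phase per voxel), each flow segment rotates at the axial Doppler
frequency `f = 2 n v_z / lambda0`, `t_k = k / rate`, and `n_k` is circular
complex Gaussian noise (i.i.d. across voxels and repeats; the standard
shot-noise-limited OCT model). Programmed velocities are validated against
the unambiguous-range limit `lambda0 * rate / (4 n)`; beyond it the
generator refuses with an aliasing error rather than silently wrapping.

Two scan presets mirror the instrument protocols: `omag` (16 B-frame
repetitions at 250 lateral positions, 280 frames/s; repeats are inter-frame)
and `omag-v` (50 repeated A-lines at 200 positions at 20,000 A-lines/s),
both over a 1.5 x 1.5 mm^2 field at a 1340 nm center wavelength. Tissue
refractive index defaults to 1.35 (the intralipid/tissue value is not
measurable from the data; it is configurable everywhere the Doppler slope is
derived).

Default amplitudes: static clutter 1.0, flow scatterers 0.3, noise sigma
0.03. The 10 dB clutter-to-flow ratio reflects that bulk tissue backscatter
dominates the intralipid signal in fixed hearts; amplitude SNR of the flow
signal is 10. Transverse-flow decorrelation is not modeled: the velocimetry
calibration is a linear frequency-velocity map, so axial encoding suffices
to exercise every estimator; this means the phantoms cannot probe
orientation-dependent biases of real vessels.

Other generators: axis-aligned cylinder volumes (per-vessel diameter and
velocity in the truth table); lumen images whose disks are rendered as the
`round(area / px^2)` pixels nearest the centroid — the most circular region
of exactly that count, which keeps rendered areas within one pixel-area of
request; constant-velocity bead movies; and gamma-Poisson (negative
binomial) count matrices with planted fold changes (default dispersion 0.1,
half the planted genes up, half down, a `frac_silent` tail of near-zero
genes so the expression filter has real work).

## OMAG reconstruction

Flow contrast is the inter-repeat complex differential:
`flow = mean_k |S_{k+1} - S_k|`, `structure = mean_k |S_k|`. A constant
phasor cancels exactly; a rotating phasor of amplitude A contributes
`2 A |sin(pi f dt)|` per pair. Magnitude-of-complex-difference was chosen
over log-intensity subtraction because it cancels static clutter exactly
and is phase-aware. Vessel masks come from Otsu or a fixed threshold on
the (MIP of the) flow volume — the thresholding rule is configuration, not
physics. Vessel density is the masked fraction of the field in percent.
Per-vessel diameters are `2 x max` of the Euclidean distance transform over
each component's medial axis (8-/26-connectivity in 2-D/3-D), accurate to
about one pixel for vessels at least ~5 px wide.

## Eigendecomposition velocimetry

Per lateral position and axial window (default 16 px), the repeat series
are pooled into `C = (1/Z) sum_z x_z x_z^H` (N_rep x N_rep, Hermitian PSD).
Eigenpairs are sorted by descending eigenvalue; the top `n_clutter`
components (default 1 — fixed hearts have a single dominant static
component; an adaptive noise-floor rule would also be reasonable but is not
the default) are the clutter subspace. The Doppler frequency of a flow
eigenvector e is the phase of its lag-one autocorrelation
`r = sum_k e_{k+1} conj(e_k)`, `f = arg(r) rate / (2 pi)`, confined to
(-rate/2, rate/2]. Velocity is the linear map `v = slope * f` with the
axial Doppler slope `lambda0/(2n)` by default; an empirically calibrated
slope can be supplied instead.

Acceptance of a flow component requires its eigenvalue to exceed
`noise_multiple` (default 3) times the noise floor — estimated as the mean
of the lower half of the nonzero eigenvalue spectrum — and its lag-one
autocorrelation to be phase-coherent (|r| above 0.5 of its maximum). The
coherence gate is what makes static phantoms produce exactly zero flow
voxels: a large noise eigenvalue alone cannot pass. Voxels are assigned the
window's velocity when their projection energy onto the leading flow
eigenvector clears the same noise multiple; with a strong static background
this slightly over-segments the window around a vessel (leakage of the
clutter residue), which inflates flow-voxel counts but not the per-vessel
velocities, which are always averaged inside an explicit vessel mask.

Known estimator bias: at very low velocities (under ~0.3 cycles across the
ensemble, i.e. ~0.1 mm/s for the 50-repeat preset) the flow phasor is
nearly collinear with the clutter vector, so clutter rejection removes part
of the flow signal and the recovered frequency is biased by several
percent. Across 0.1-3 mm/s the median relative error is well under 5%.

Per-vessel flow is `Q_i = v_i pi (d_i/2)^2` (µL/min); the field-of-view
perfusion rate is the sum, and the volumetric rate divides by the tissue
volume `FOV area x depth`. The tissue depth is not derivable from the
en-face metrics; the default 0.89 mm is the value consistent with a
24.5 µL/min field rate equalling 12.3 mL/min/mL over a 2.25 mm^2 field, and
it is configurable and logged. Diameter-gated statistics (default
20-40 µm, the small-arteriole band) are the mean ± SD over gated vessels.

## Network hemodynamics

Vessel graphs are undirected multigraphs of rigid cylindrical tubes with
Hagen-Poiseuille conductance `g = pi r^4 / (8 mu L)`. Nodal pressures solve
the weighted graph Laplacian with Dirichlet pressure conditions (and
optional imposed nodal inflows); Kirchhoff residuals on the fixtures are
below 1e-9 relative. Interface units are µm / mPa·s / Pa / µL/min, with
wall shear `tau = 4 mu Q / (pi r^3)` reported in dyne/cm^2. The fluid is
Newtonian with configurable viscosity (1 mPa·s culture medium default,
3.5 mPa·s as a blood preset). Grid builders produce the 3x3 culture and
13x13 RNA-collection patterns (125 µm lumen default) with inlet and outlet
on opposite corners; the default pressure drop can be calibrated so the
mean wall shear matches the 0.1 dyne/cm^2 time-average of gravity-driven
culture (shear is linear in the drop, so a unit solve scales exactly).
Sprouts are added as uniform 10-50 µm bridges between random nodes or
split edge midpoints; by Rayleigh monotonicity every conducting bridge can
only lower the inlet-outlet resistance, and dead-end sprouts carry no flow
by construction while remaining in the graph for geometry reports.
Pulsatile flow, compliance and solute transport are out of scope.

## Image quantification

Particle analysis labels 8-connected components of a binary mask and
excludes particles below 20 µm^2 (strict <; the cutoff is the background
exclusion used for lumen counting). Distance-to-wall is measured from the
particle centroid to the nearest wall pixel via distance transform, and
bins [0-300), [300-600), [600-900) µm are half-open with an explicit
overflow row; bin densities are counts over the in-band image area in mm^2,
so area-weighted bin densities recompose the overall density exactly.
Coverage (e.g. platelet CD41a+ area over wall area) clips the signal to the
reference region before dividing. Colocalization counts objects whose
overlap with a marker mask exceeds a configurable fraction (default: any
overlap). Bead tracking detects centroids per frame (fixed or Otsu
threshold), links nearest neighbors under an optional displacement gate,
terminates tracks on equidistant candidates instead of guessing, and
reports mean step displacement over the frame interval (the two-time-point
0.27 s protocol is the reference case). The tracker is exact on
non-crossing constant-velocity movies; crossing tracks are a stress case
and may be terminated rather than resolved.

## Expression screening

CPM is `1e6 * count / library size`. The keep-filter retains genes with
CPM strictly above 1 in at least 2 samples. The differential gate applies
Benjamini-Hochberg to supplied per-gene p values and calls a gene
differential iff |linear fold change| > 1.5 (strict) and FDR below the
threshold (0.01 default, 0.05 preset — both thresholds appear in practice
and neither is asserted as canonical). Dispersion-modeled GLM fitting is
out of scope: the gate consumes statistics from any upstream test. For
synthetic cohorts the default statistic is a variance-moderated two-sample
t-test (empirical-Bayes shrinkage of per-gene pooled variances toward a
moment-estimated scaled-inverse-chi-squared prior): with 3 replicates per
group a plain per-gene test is dominated by variance-estimation noise,
while moderation recovers planted 4-fold genes at better than 90% under the
FDR < 0.05 gate. A plain Welch option is kept for reference. Pathway
overlap uses the upper-tail hypergeometric probability (verified against
exhaustive enumeration on small universes). PCA operates on gene-centered
`log2(CPM + 1)` without variance scaling; per-gene loading magnitudes rank
"contributions" to a component.

## Pipeline and reproducibility

The demo scenario simulates two cohorts (sparse low-velocity vs dense
high-velocity vasculature, 4 samples per group by default) at a reduced
phantom size (48 px depth x 32 positions) so the full chain — phantom,
reconstruction, velocimetry, per-vessel metrics, perfusion — runs in
seconds per sample; these sizes are package defaults, chosen to keep the
examples interactive, and scale up freely. Perfused-vessel density in the
pipeline is measured on the velocimetry flow mask (noise-floor
thresholded), not on an Otsu-binarized flow image: Otsu misbehaves on
nearly-empty flow maps. Group summaries report mean ± SEM and two-tailed
Welch tests without multiple-testing correction across metrics; fold
ratios always carry an explicit rounding rule (`none`, `nearest_int`,
`one_decimal`). Every random draw descends from the config seed, and the
run manifest records config, parameters and SHA-256 hashes of all written
tables, so reruns are byte-identical.

## What the phantoms do and do not show

Passing tests demonstrate correctness of the estimators under the stated
signal model: axial-Doppler phase rotation, ideal cylinders, disk-shaped
lumens, constant-velocity beads, NB counts with common dispersion. They do
not probe transverse flow decorrelation, multiple scattering, motion
artifacts (the protocol images arrested hearts precisely to avoid them),
irregular lumen shapes, bead size dispersion, or gene-specific dispersion
trends — conclusions about real specimens require the instrument's own
calibration data.
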