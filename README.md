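# omagkit

Quantitative tools for assessing microvascular perfusion in engineered
cardiac tissue grafts: OCT-based optical microangiography (OMAG) flow
reconstruction, eigendecomposition velocimetry of repeated A-line
ensembles, perfusion-rate metrics, Poiseuille hemodynamics of patterned
microvessel networks, fluorescence-image quantification, and the
formula-level rules of a bulk RNA-seq screen. The package ships synthetic
phantom generators with exact ground truth, so the entire chain is testable
end to end without instrument data.

It is aimed at researchers who engineer perfusable microvessel constructs
and need to quantify how well a graft integrates with host coronary
vasculature: perfused-vessel density, blood velocity in small arterioles,
and volumetric perfusion rate.

## The core computations

**OMAG flow contrast.** Repeated complex A-scans S_k at each position are
differenced: `flow = mean_k |S_{k+1} − S_k|`. Static tissue (a constant
phasor) cancels exactly; moving scatterers survive.

**Eigendecomposition velocimetry.** Repeat series pooled over an axial
window form the covariance `C = (1/Z) Σ_z x_z x_zᴴ`. Its leading
eigencomponent is the static-tissue clutter; the Doppler frequency of the
leading flow eigenvector e comes from its lag-one autocorrelation,
`f = arg(Σ_k e_{k+1} e_k*) · rate / 2π`, and maps linearly to velocity with
slope λ₀/(2n). Per-vessel flow is `Q = v·π(d/2)²`; summed over the field
and divided by tissue volume it gives the volumetric perfusion rate.

**Network hemodynamics.** Vessel graphs obey Hagen–Poiseuille
(`g = πr⁴/8μL`); nodal pressures solve Kirchhoff's laws, wall shear is
`τ = 4μQ/πr³`. Adding a conducting sprout between unequal-pressure nodes
strictly increases total flow at fixed pressure drop (Rayleigh
monotonicity) — the mechanism by which angiogenic sprouting lowers network
resistance.

**Image and expression rules.** Particle analysis with a 20 µm² background
exclusion and half-open distance bins [0–300/300–600/600–900) µm; bead
tracking velocimetry; counts-per-million with the ">1 CPM in ≥2 samples"
keep-filter, the |FC|>1.5 + BH-FDR differential gate, hypergeometric
pathway overlap, and PCA of log₂ CPM.

## Worked example

Two vessels (28 µm at 0.7 mm/s, 42 µm at 2.0 mm/s) are programmed into a
velocimetry-protocol phantom, recovered, gated and summed:

```python
import numpy as np
from omagkit import phantoms, FlowSegment
from omagkit.velocimetry import (velocity_map, per_vessel_table,
                                 gated_velocity_stats, perfusion_rate)
from omagkit.pipeline import fold_ratio

spec = phantoms.preset("omag-v", n_positions=24, depth_px=48, seed=11,
                       flow_segments=[FlowSegment((4, 8), (16, 20), 0.7),
                                      FlowSegment((14, 20), (16, 24), 2.0)])
ens, truth = phantoms.make_flow_phantom(spec)
field = velocity_map(ens, depth_window=16)
vessels = per_vessel_table(field, truth.vessel_mask_true, pixel_um=7.0)
print(vessels.round(3))
g = gated_velocity_stats(vessels, (20.0, 40.0))
print(f"gated 20-40 um velocity: {g.mean_mm_s:.3f} mm/s (n={g.n_vessels})")
rate = perfusion_rate(vessels, fov_area_mm2=2.25, tissue_depth_mm=0.89)
print(f"Q_fov = {rate.q_fov_ul_min:.4f} uL/min, "
      f"Q_vol = {rate.q_volumetric_ml_min_ml:.4f} mL/min/mL")
```

prints

```
   label  diameter_um  velocity_mm_s  q_ul_min  n_flow_voxels
0      1         28.0          0.700     0.026             16
1      2         42.0          1.995     0.166             48
gated 20-40 um velocity: 0.700 mm/s (n=1)
Q_fov = 0.1916 uL/min, Q_vol = 0.0957 mL/min/mL
```

Both programmed velocities are recovered (0.700 and 1.995 mm/s), only the
28 µm vessel falls in the small-arteriole gate, and the perfusion rates
follow from the recovered diameters and velocities. Group means feed the
fold reporter with an explicit rounding rule — e.g. densities 33.8% vs
5.3% give `fold_ratio(33.8, 5.3, "nearest_int").ratio == 6`, velocities
0.72 vs 0.29 mm/s give 2.5, and volumetric rates 12.3 vs 0.5 mL/min/mL
give 24.6 (> 20).

A command-line interface covers the same ground:

```
omagkit phantom --preset omag-v --velocity 0.5 --velocity 1.5 --out ens.h5
omagkit velocimetry --input ens.h5 --depth-mm 0.89 --out out/
omagkit network --grid 13x13 --diameter 125 --sprouts 40 --seed 7
omagkit screen --counts counts.tsv --groups A,A,A,B,B,B --fdr 0.05 --out de.tsv
omagkit run --out run_dir/
```

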