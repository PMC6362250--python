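"""Poiseuille flow on microvessel graphs.

Each edge is a rigid cylindrical tube obeying the Hagen-Poiseuille law
Q = pi dP r^4 / (8 mu L); nodal pressures solve Kirchhoff's current law on
the weighted graph Laplacian.  Units at the interface: radius/length µm,
viscosity mPa.s, pressure Pa, flow µL/min, wall shear dyne/cm^2.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Hashable, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

logger = logging.getLogger(__name__)

# (µL/min) per (m^3/s)
_M3S_TO_ULMIN = 1e9 * 60.0


def edge_conductance(
    radius_um: float, length_um: float, viscosity_mpa_s: float
) -> float:
    """Hydraulic conductance g = pi r^4 / (8 mu L), in (µL/min) per Pa."""
    if radius_um <= 0 or length_um <= 0 or viscosity_mpa_s <= 0:
        raise ValueError("radius, length and viscosity must be positive")
    r = radius_um * 1e-6
    length = length_um * 1e-6
    mu = viscosity_mpa_s * 1e-3
    g_si = np.pi * r**4 / (8.0 * mu * length)  # (m^3/s)/Pa
    return g_si * _M3S_TO_ULMIN


def wall_shear(radius_um: float, viscosity_mpa_s: float, q_ul_min: float) -> float:
    """Poiseuille wall shear stress tau = 4 mu Q / (pi r^3), in dyne/cm^2."""
    r = radius_um * 1e-6
    mu = viscosity_mpa_s * 1e-3
    q_si = q_ul_min / _M3S_TO_ULMIN
    tau_pa = 4.0 * mu * q_si / (np.pi * r**3)
    return tau_pa * 10.0  # 1 Pa = 10 dyne/cm^2


@dataclass
class VesselNetwork:
    """Graph of cylindrical vessel segments with boundary conditions.

    ``graph`` is an undirected multigraph whose nodes carry a 3-D ``pos``
    (µm) and whose edges carry radius_um, length_um, viscosity_mpa_s.
    ``pressure_bc`` maps node -> fixed pressure (Pa); ``flow_bc`` maps
    node -> imposed external inflow (µL/min, positive into the network).
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    pressure_bc: Dict[Hashable, float] = field(default_factory=dict)
    flow_bc: Dict[Hashable, float] = field(default_factory=dict)
    inlet: Optional[Hashable] = None
    outlet: Optional[Hashable] = None

    def add_vessel(
        self,
        a: Hashable,
        b: Hashable,
        radius_um: float,
        length_um: Optional[float] = None,
        viscosity_mpa_s: float = 1.0,
    ) -> None:
        if radius_um <= 0 or viscosity_mpa_s <= 0:
            raise ValueError("radius and viscosity must be positive")
        if length_um is None:
            pa = np.asarray(self.graph.nodes[a]["pos"], dtype=float)
            pb = np.asarray(self.graph.nodes[b]["pos"], dtype=float)
            length_um = float(np.linalg.norm(pa - pb))
        if length_um <= 0:
            raise ValueError("length must be positive")
        if a in self.graph.nodes and b in self.graph.nodes:
            pa = np.asarray(self.graph.nodes[a]["pos"], dtype=float)
            pb = np.asarray(self.graph.nodes[b]["pos"], dtype=float)
            if length_um < np.linalg.norm(pa - pb) - 1e-9:
                raise ValueError("edge length below Euclidean node distance")
        self.graph.add_edge(
            a, b, radius_um=radius_um, length_um=length_um,
            viscosity_mpa_s=viscosity_mpa_s,
        )

    def validate(self) -> None:
        for _, _, d in self.graph.edges(data=True):
            if min(d["radius_um"], d["length_um"], d["viscosity_mpa_s"]) <= 0:
                raise ValueError("non-positive edge geometry")


@dataclass
class FlowSolution:
    """Nodal pressures, signed edge flows, totals and per-edge wall shear."""

    pressures_pa: Dict[Hashable, float]
    edges: pd.DataFrame  # node_a, node_b, key, q_ul_min, shear_dyne_cm2
    total_inlet_flow_ul_min: float
    resistance_pa_per_ul_min: float
    pressure_drop_pa: float

    def kirchhoff_residual(self, network: VesselNetwork) -> float:
        """Largest |sum of flows| over interior nodes, relative to max |Q|."""
        acc: Dict[Hashable, float] = {n: 0.0 for n in network.graph.nodes}
        for row in self.edges.itertuples():
            acc[row.node_a] -= row.q_ul_min
            acc[row.node_b] += row.q_ul_min
        for n, q in network.flow_bc.items():
            acc[n] += q
        interior = [
            n for n in network.graph.nodes if n not in network.pressure_bc
        ]
        qmax = max(1e-300, float(self.edges["q_ul_min"].abs().max() or 0.0))
        if not interior:
            return 0.0
        return max(abs(acc[n]) for n in interior) / qmax


def solve_pressures(network: VesselNetwork) -> FlowSolution:
    """Solve Kirchhoff's laws for nodal pressures and edge flows.

    At least one pressure boundary condition is required; every connected
    component containing an unknown node must reach a pressure reference.
    """
    g = network.graph
    if not network.pressure_bc:
        raise ValueError("at least one pressure boundary condition is required")
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    fixed = set(network.pressure_bc)

    # singularity check: every component must touch a pressure reference
    for comp in nx.connected_components(g):
        if not comp & fixed:
            raise ValueError(
                f"component without pressure reference: {sorted(comp, key=str)[:5]}"
            )

    n = len(nodes)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    diag = np.zeros(n)
    for a, b, d in g.edges(data=True):
        cond = edge_conductance(d["radius_um"], d["length_um"], d["viscosity_mpa_s"])
        ia, ib = index[a], index[b]
        diag[ia] += cond
        diag[ib] += cond
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [-cond, -cond]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    lap = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    for node, q in network.flow_bc.items():
        rhs[index[node]] += q

    free = [i for i, node in enumerate(nodes) if node not in fixed]
    fixed_idx = [index[node] for node in fixed]
    p = np.zeros(n)
    for node in fixed:
        p[index[node]] = network.pressure_bc[node]
    if free:
        a_ff = lap[free][:, free]
        b_f = rhs[free] - lap[free][:, fixed_idx] @ p[fixed_idx]
        p[free] = spsolve(a_ff.tocsc(), b_f)

    erows = []
    for a, b, key, d in g.edges(keys=True, data=True):
        cond = edge_conductance(d["radius_um"], d["length_um"], d["viscosity_mpa_s"])
        q = cond * (p[index[a]] - p[index[b]])  # positive a -> b
        erows.append(
            dict(
                node_a=a,
                node_b=b,
                key=key,
                q_ul_min=q,
                shear_dyne_cm2=wall_shear(d["radius_um"], d["viscosity_mpa_s"], abs(q)),
                radius_um=d["radius_um"],
                length_um=d["length_um"],
            )
        )
    edges = pd.DataFrame(
        erows,
        columns=["node_a", "node_b", "key", "q_ul_min", "shear_dyne_cm2",
                 "radius_um", "length_um"],
    )

    inlet = network.inlet
    total_in = 0.0
    dp = 0.0
    resistance = np.nan
    if inlet is not None:
        for row in edges.itertuples():
            if row.node_a == inlet:
                total_in += row.q_ul_min
            elif row.node_b == inlet:
                total_in -= row.q_ul_min
        if network.outlet is not None:
            dp = p[index[inlet]] - p[index[network.outlet]]
            if total_in != 0:
                resistance = dp / total_in

    pressures = {node: float(p[index[node]]) for node in nodes}
    return FlowSolution(
        pressures_pa=pressures,
        edges=edges,
        total_inlet_flow_ul_min=float(total_in),
        resistance_pa_per_ul_min=float(resistance),
        pressure_drop_pa=float(dp),
    )


def grid_network(
    rows: int,
    cols: int,
    lumen_diameter_um: float = 125.0,
    spacing_um: float = 500.0,
    viscosity_mpa_s: float = 1.0,
) -> VesselNetwork:
    """Rectangular vessel lattice with inlet/outlet on opposite corners.

    Edge count is rows*(cols-1) + cols*(rows-1); the 3x3 and 13x13 layouts
    are the patterned geometries used for culture and RNA collection.
    """
    if rows < 2 or cols < 2:
        raise ValueError("grid needs rows, cols >= 2")
    net = VesselNetwork()
    for i in range(rows):
        for j in range(cols):
            net.graph.add_node((i, j), pos=(j * spacing_um, i * spacing_um, 0.0))
    r = lumen_diameter_um / 2.0
    for i in range(rows):
        for j in range(cols):
            if j + 1 < cols:
                net.add_vessel((i, j), (i, j + 1), r, spacing_um, viscosity_mpa_s)
            if i + 1 < rows:
                net.add_vessel((i, j), (i + 1, j), r, spacing_um, viscosity_mpa_s)
    net.inlet = (0, 0)
    net.outlet = (rows - 1, cols - 1)
    return net


def add_sprouts(
    network: VesselNetwork,
    n_sprouts: int,
    diameter_range_um: Tuple[float, float] = (10.0, 50.0),
    attachment: str = "nodes",
    dead_end_fraction: float = 0.0,
    viscosity_mpa_s: Optional[float] = None,
    seed: int = 0,
) -> VesselNetwork:
    """Add angiogenic sprouts as new conducting edges (in place).

    Bridging sprouts connect two distinct existing nodes (``attachment =
    'nodes'``) or freshly split edge midpoints (``'midpoints'``); a
    ``dead_end_fraction`` of sprouts instead terminates in a new leaf node
    and by construction carries no flow.  Sprout diameters are drawn
    uniformly from ``diameter_range_um`` (below the patterned lumen scale).
    """
    if attachment not in ("nodes", "midpoints"):
        raise ValueError("attachment must be 'nodes' or 'midpoints'")
    rng = np.random.default_rng(seed)
    g = network.graph
    if viscosity_mpa_s is None:
        viscosity_mpa_s = next(
            (d["viscosity_mpa_s"] for _, _, d in g.edges(data=True)), 1.0
        )
    n_dead = int(round(dead_end_fraction * n_sprouts))
    for s in range(n_sprouts):
        diameter = rng.uniform(*diameter_range_um)
        if attachment == "midpoints":
            _split_random_edge(network, rng, viscosity_mpa_s)
            _split_random_edge(network, rng, viscosity_mpa_s)
        nodes = list(g.nodes)
        if s < n_dead:
            a = nodes[rng.integers(len(nodes))]
            pa = np.asarray(g.nodes[a]["pos"], dtype=float)
            tip = tuple(pa + rng.uniform(-200, 200, size=3))
            tip_name = ("sprout_tip", s)
            g.add_node(tip_name, pos=tip)
            length = max(float(np.linalg.norm(np.asarray(tip) - pa)), 1.0)
            network.add_vessel(a, tip_name, diameter / 2.0, length, viscosity_mpa_s)
            continue
        for _ in range(20):
            a, b = nodes[rng.integers(len(nodes))], nodes[rng.integers(len(nodes))]
            if a != b:
                break
        else:
            logger.warning("sprout %d: no attachment found, skipped", s)
            continue
        pa = np.asarray(g.nodes[a]["pos"], dtype=float)
        pb = np.asarray(g.nodes[b]["pos"], dtype=float)
        length = max(float(np.linalg.norm(pa - pb)), 1.0)
        network.add_vessel(a, b, diameter / 2.0, length, viscosity_mpa_s)
    return network


def _split_random_edge(network: VesselNetwork, rng, viscosity: float) -> None:
    g = network.graph
    edges = list(g.edges(keys=True, data=True))
    if not edges:
        return
    a, b, key, d = edges[rng.integers(len(edges))]
    pa = np.asarray(g.nodes[a]["pos"], dtype=float)
    pb = np.asarray(g.nodes[b]["pos"], dtype=float)
    mid = tuple((pa + pb) / 2.0)
    name = ("mid", a, b, key, int(rng.integers(1 << 30)))
    g.remove_edge(a, b, key=key)
    g.add_node(name, pos=mid)
    half = d["length_um"] / 2.0
    network.add_vessel(a, name, d["radius_um"], half, d["viscosity_mpa_s"])
    network.add_vessel(name, b, d["radius_um"], half, d["viscosity_mpa_s"])


def calibrate_inlet_pressure(
    network: VesselNetwork, target_mean_shear_dyne_cm2: float = 0.1
) -> float:
    """Inlet-outlet pressure drop giving a target mean wall shear.

    Shear is linear in the applied pressure drop, so a unit solve scales
    exactly.  Returns the pressure drop in Pa and logs it.
    """
    if network.inlet is None or network.outlet is None:
        raise ValueError("network needs an inlet and an outlet")
    trial = VesselNetwork(
        graph=network.graph,
        pressure_bc={network.inlet: 1.0, network.outlet: 0.0},
        inlet=network.inlet,
        outlet=network.outlet,
    )
    sol = solve_pressures(trial)
    mean_shear = float(sol.edges["shear_dyne_cm2"].mean())
    if mean_shear == 0:
        raise ValueError("network carries no flow under a unit pressure drop")
    dp = target_mean_shear_dyne_cm2 / mean_shear
    logger.info("calibrated pressure drop %.4g Pa for mean shear %.3g dyne/cm^2",
                dp, target_mean_shear_dyne_cm2)
    return dp
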