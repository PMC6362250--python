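"""Serialization: ensembles to HDF5, images to 16-bit TIFF, tables to CSV,
networks to CSV edge lists and GraphML."""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .containers import AScanEnsemble, FlowVolume, QuantImage
from .hemodynamics import VesselNetwork


def save_ensemble(path: str | Path, ensemble: AScanEnsemble) -> None:
    meta = dict(
        a_line_rate_hz=ensemble.a_line_rate_hz,
        pixel_um=list(ensemble.pixel_um),
        center_wavelength_nm=ensemble.center_wavelength_nm,
        refractive_index=ensemble.refractive_index,
        preset_name=ensemble.preset_name,
    )
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=ensemble.signal.astype(np.complex64))
        f.attrs["meta"] = json.dumps(meta)


def load_ensemble(path: str | Path) -> AScanEnsemble:
    with h5py.File(path, "r") as f:
        signal = f["signal"][...].astype(np.complex128)
        meta = json.loads(f.attrs["meta"])
    return AScanEnsemble(
        signal=signal,
        a_line_rate_hz=meta["a_line_rate_hz"],
        pixel_um=tuple(meta["pixel_um"]),
        center_wavelength_nm=meta["center_wavelength_nm"],
        refractive_index=meta["refractive_index"],
        preset_name=meta.get("preset_name", ""),
    )


def save_flow_volume(path: str | Path, volume: FlowVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("flow", data=volume.flow)
        f.create_dataset("structure", data=volume.structure)
        f.attrs["pixel_um"] = list(volume.pixel_um)


def load_flow_volume(path: str | Path) -> FlowVolume:
    with h5py.File(path, "r") as f:
        return FlowVolume(
            flow=f["flow"][...],
            structure=f["structure"][...],
            pixel_um=tuple(f.attrs["pixel_um"]),
        )


def save_image_tiff(path: str | Path, image: QuantImage,
                    scale_to_uint16: bool = True) -> None:
    """Write a calibrated image as TIFF; intensities scaled to 16-bit range."""
    px = image.pixels
    if scale_to_uint16:
        lo, hi = float(px.min()), float(px.max())
        span = hi - lo if hi > lo else 1.0
        px = ((px - lo) / span * 65535.0).astype(np.uint16)
    tifffile.imwrite(
        path, px,
        resolution=(1e4 / image.pixel_um, 1e4 / image.pixel_um),
        resolutionunit="CENTIMETER",
        metadata={"pixel_um": image.pixel_um, "channel": image.channel},
    )


def load_image_tiff(path: str | Path, pixel_um: Optional[float] = None) -> QuantImage:
    with tifffile.TiffFile(path) as tif:
        px = tif.asarray()
        if pixel_um is None:
            meta = tif.shaped_metadata or tif.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            pixel_um = float(meta.get("pixel_um", 1.0))
    return QuantImage(pixels=px.astype(float), pixel_um=pixel_um)


def save_network_csv(path: str | Path, network: VesselNetwork) -> None:
    rows = [
        dict(node_a=str(a), node_b=str(b), radius_um=d["radius_um"],
             length_um=d["length_um"], viscosity_mPas=d["viscosity_mpa_s"])
        for a, b, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "radius_um", "length_um",
                                "viscosity_mPas"]).to_csv(path, index=False)


def load_network_csv(path: str | Path) -> VesselNetwork:
    df = pd.read_csv(path)
    net = VesselNetwork()
    for row in df.itertuples():
        for node in (row.node_a, row.node_b):
            if node not in net.graph.nodes:
                net.graph.add_node(node, pos=(0.0, 0.0, 0.0))
        net.graph.add_edge(
            row.node_a, row.node_b,
            radius_um=float(row.radius_um), length_um=float(row.length_um),
            viscosity_mpa_s=float(row.viscosity_mPas),
        )
    return net


def save_network_graphml(path: str | Path, network: VesselNetwork) -> None:
    g = nx.MultiGraph()
    for n, d in network.graph.nodes(data=True):
        pos = d.get("pos", (0.0, 0.0, 0.0))
        g.add_node(str(n), x=float(pos[0]), y=float(pos[1]), z=float(pos[2]))
    for a, b, d in network.graph.edges(data=True):
        g.add_edge(str(a), str(b), **{k: float(v) for k, v in d.items()})
    nx.write_graphml(g, path)
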