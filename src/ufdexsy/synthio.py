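"""Synthetic DEXSY datasets, the dataset file format, and preprocessing.

Generation emulates the two study conditions end to end: the single-scan
(ultrafast) experiment — a spatial profile whose z axis encodes the first
diffusion weighting and whose CPMG echoes encode the second — and the
conventional multi-repetition (b1, b2) experiment.  Both draw their signal
from the same two-site exchange physics, add seeded Gaussian noise at a
configurable SNR, and can optionally corrupt the edge and centre rows of
the spatial profile the way imperfect sweep-pulse onset does in practice.

Datasets are serialized as UTF-8 TSV matrices with ``#`` header comments
plus a JSON sidecar (schema ``ufdexsy-dataset-v1``) carrying axes, units,
acquisition parameters, the generation seed, and — for synthetic data —
the ground-truth system.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__ as _version
from .encoding import (
    CPMGReadout,
    EncodingBlock,
    echo_time_profile,
    encoding_region,
    uf_forward_signal,
)
from .exchange import (
    ConventionalBlock,
    TwoSiteSystem,
    full_exchange_signal,
    mixing_propagator,
)
from .laplace2d import SignalGrid

__all__ = [
    "NoiseSpec",
    "DatasetBundle",
    "exchange_weights",
    "generate_uf_dataset",
    "generate_conventional_dataset",
    "echoes_to_profiles",
    "trim_and_map",
    "write_dataset",
    "read_dataset",
]

SCHEMA = "ufdexsy-dataset-v1"


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: sd = max|signal| / snr.

    ``snr = math.inf`` means noiseless; a seed is required whenever noise is
    actually drawn.
    """

    snr: float
    seed: int | None = None
    kind: str = "gaussian-additive"

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        if self.kind != "gaussian-additive":
            raise ValueError("only gaussian-additive noise is supported")
        if math.isfinite(self.snr) and self.seed is None:
            raise ValueError("a seed is required for stochastic generation")

    def apply(self, signal: np.ndarray) -> tuple[np.ndarray, float]:
        """Return (noisy signal, noise sd)."""
        if not math.isfinite(self.snr):
            return signal.copy(), 0.0
        sd = float(np.abs(signal).max()) / self.snr
        rng = np.random.default_rng(self.seed)
        return signal + rng.normal(0.0, sd, size=signal.shape), sd


@dataclass
class DatasetBundle:
    """A signal grid plus, for synthetic data, its generating ground truth."""

    signal: SignalGrid
    truth: TwoSiteSystem | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.provenance.setdefault("generator", f"ufdexsy {_version}")


def exchange_weights(system: TwoSiteSystem, mixing_time: float) -> np.ndarray:
    """Joint (D1, D2) site-occupancy weights after the mixing time.

    W[j, k] = P(site j during first encoding, site k during second)
            = [exp(-tau_M (R1 + K))]_{kj} * M_j,  site order (F, E).

    Rows index D1 (initial site), columns D2 (final site); at tau_M = 0 the
    matrix is diag(x_F, x_E).
    """
    prop = mixing_propagator(system, mixing_time)
    m = system.populations
    return (prop * m[None, :]).T  # W[j,k] = prop[k,j]*m[j]


def generate_uf_dataset(
    system: TwoSiteSystem,
    block: EncodingBlock,
    readout: CPMGReadout,
    mixing_time: float,
    noise: NoiseSpec,
    *,
    artefacts: bool = False,
    n_z: int | None = None,
    t1_prose_convention: bool = False,
) -> DatasetBundle:
    """Simulate one single-scan DEXSY acquisition as a z x echo profile grid.

    The z axis spans the spatial-encoding region with ``n_z`` rows (default:
    the number of imaging pixels falling inside the region, from the read
    gradient and dwell); each row's first diffusion weighting follows from
    t1(z), each column is one CPMG echo top.  ``artefacts=True`` multiplies
    the two outermost and the central rows by a seeded random factor in
    [0, 0.5] — a schematic stand-in for imperfect sweep-pulse onset — and
    records the corrupted row indices so preprocessing can drop them.
    """
    z_min, z_max = encoding_region(block)
    if n_z is None:
        fov = 2.0 * math.pi / (
            readout.gamma * readout.read_grad_amplitude * readout.dwell
        )
        pixel = fov / readout.points_per_echo
        n_z = max(int((z_max - z_min) / pixel), 8)
    # pixel centres strictly inside the region
    edges = np.linspace(z_min, z_max, n_z + 1)
    z_axis = 0.5 * (edges[:-1] + edges[1:])
    t1_of_z = np.array([
        echo_time_profile(block, z, t1_prose_convention=t1_prose_convention)
        for z in z_axis
    ])
    t2_axis = readout.echo_times()

    weights = exchange_weights(system, mixing_time)
    d_sites = system.diffusivities
    # t1 decreases with z; evaluate the forward model on sorted t1 and map back
    order = np.argsort(t1_of_z)
    signal_sorted = uf_forward_signal(
        block, readout, d_sites, d_sites, weights, t1_of_z[order], t2_axis
    )
    signal = np.empty_like(signal_sorted)
    signal[order] = signal_sorted

    artefact_rows: list[int] = []
    if artefacts:
        rng = np.random.default_rng(
            None if noise.seed is None else noise.seed + 1
        )
        artefact_rows = [0, n_z - 1, n_z // 2]
        for row in artefact_rows:
            signal[row] *= rng.uniform(0.0, 0.5)

    noisy, sd = noise.apply(signal)
    grid = SignalGrid(
        axis1=z_axis,
        axis2=t2_axis,
        values=noisy,
        kind1="z",
        kind2="t2",
        noise_sd=sd if sd > 0 else 0.0,
        metadata={
            "experiment": "uf-dexsy",
            "mixing_time": mixing_time,
            "artefact_rows": artefact_rows,
            "t1_prose_convention": t1_prose_convention,
        },
    )
    return DatasetBundle(
        signal=grid,
        truth=system,
        provenance={
            "seed": noise.seed,
            "snr": noise.snr,
            "mixing_time": mixing_time,
            "artefacts": artefacts,
        },
    )


def generate_conventional_dataset(
    system: TwoSiteSystem,
    block: ConventionalBlock,
    noise: NoiseSpec,
    *,
    encoding_exchange_time: float | None = None,
) -> DatasetBundle:
    """Simulate the conventional multi-repetition DEXSY (b1, b2) surface."""
    b = block.b_values()
    signal = full_exchange_signal(
        system, block, b, b, encoding_exchange_time=encoding_exchange_time
    )
    noisy, sd = noise.apply(signal)
    grid = SignalGrid(
        axis1=b,
        axis2=b,
        values=noisy,
        kind1="b1",
        kind2="b2",
        noise_sd=sd if sd > 0 else 0.0,
        metadata={
            "experiment": "conventional-dexsy",
            "mixing_time": block.mixing_time,
            "delta": block.delta,
            "big_delta": block.big_delta,
        },
    )
    return DatasetBundle(
        signal=grid,
        truth=system,
        provenance={"seed": noise.seed, "snr": noise.snr},
    )


def echoes_to_profiles(
    echoes: np.ndarray, readout: CPMGReadout
) -> SignalGrid:
    """Fourier-transform raw CPMG echoes into spatial magnitude profiles.

    ``echoes`` is (n_echoes, points_per_echo) complex; each record is
    discrete-Fourier transformed (centred) into a magnitude profile along z,
    and the profiles are stacked into a (z x echo) grid.  The z axis follows
    from the read gradient: field of view 2*pi/(gamma*G_R*dwell), pixel
    FOV/points.
    """
    echoes = np.asarray(echoes)
    if echoes.ndim != 2 or echoes.shape[1] != readout.points_per_echo:
        raise ValueError(
            f"expected (n_echoes, {readout.points_per_echo}) echo records, "
            f"got shape {echoes.shape}"
        )
    profiles = np.abs(np.fft.fftshift(np.fft.fft(echoes, axis=1), axes=1))
    n = readout.points_per_echo
    fov = 2.0 * math.pi / (
        readout.gamma * readout.read_grad_amplitude * readout.dwell
    )
    z_axis = (np.arange(n) - n // 2) * (fov / n)
    t2 = 2.0 * readout.half_echo * np.arange(1, echoes.shape[0] + 1)
    return SignalGrid(
        axis1=z_axis,
        axis2=t2,
        values=profiles.T,
        kind1="z",
        kind2="t2",
        metadata={"experiment": "uf-dexsy", "fov": fov},
    )


def trim_and_map(
    grid: SignalGrid,
    block: EncodingBlock,
    *,
    drop_rows=None,
    t1_prose_convention: bool | None = None,
) -> SignalGrid:
    """Convert a z-axis profile grid into a t1-axis signal grid.

    Drops rows flagged as artefacts (``drop_rows`` or the grid's own
    ``artefact_rows`` metadata) and rows outside the spatial-encoding
    region, maps the surviving z values to t1 through the echo-time profile,
    and reorders so the t1 axis increases.
    """
    if grid.kind1 != "z":
        raise ValueError("trim_and_map expects a z-axis grid")
    if t1_prose_convention is None:
        t1_prose_convention = bool(
            grid.metadata.get("t1_prose_convention", False)
        )
    flagged = set(drop_rows or []) | set(grid.metadata.get("artefact_rows", []))
    z_min, z_max = encoding_region(block)
    keep = [
        i
        for i, z in enumerate(grid.axis1)
        if i not in flagged and z_min <= z <= z_max
    ]
    if not keep:
        raise ValueError("all rows trimmed: no data inside the encoding region")
    z_kept = grid.axis1[keep]
    t1 = np.array([
        echo_time_profile(block, z, t1_prose_convention=t1_prose_convention)
        for z in z_kept
    ])
    order = np.argsort(t1)
    meta = dict(grid.metadata)
    meta["rows_retained"] = len(keep)
    meta.pop("artefact_rows", None)
    return SignalGrid(
        axis1=t1[order],
        axis2=grid.axis2,
        values=grid.values[np.asarray(keep)[order]],
        kind1="t1",
        kind2=grid.kind2,
        noise_sd=grid.noise_sd,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# file format


def write_dataset(bundle: DatasetBundle, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.tsv`` (matrix) and ``<stem>.json`` (sidecar)."""
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    sidecar = stem.with_suffix(".json")
    g = bundle.signal
    lines = [
        f"# {SCHEMA}",
        f"# rows: {g.kind1}, columns: {g.kind2}; axes in the JSON sidecar",
    ]
    for row in g.values:
        lines.append("\t".join(f"{v:.12e}" for v in row))
    tsv.write_text("\n".join(lines) + "\n")

    doc: dict[str, Any] = {
        "schema": SCHEMA,
        "axis1": list(map(float, g.axis1)),
        "axis2": list(map(float, g.axis2)),
        "kind1": g.kind1,
        "kind2": g.kind2,
        "noise_sd": g.noise_sd,
        "metadata": g.metadata,
        "provenance": bundle.provenance,
    }
    if bundle.truth is not None:
        doc["truth"] = asdict(bundle.truth)
    sidecar.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return tsv, sidecar


def read_dataset(stem: str | Path) -> DatasetBundle:
    """Read a dataset written by :func:`write_dataset`."""
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    sidecar = stem.with_suffix(".json")
    doc = json.loads(sidecar.read_text())
    if doc.get("schema") != SCHEMA:
        raise ValueError(f"unrecognised dataset schema {doc.get('schema')!r}")
    rows = [
        [float(v) for v in line.split("\t")]
        for line in tsv.read_text().splitlines()
        if line and not line.startswith("#")
    ]
    grid = SignalGrid(
        axis1=np.array(doc["axis1"]),
        axis2=np.array(doc["axis2"]),
        values=np.array(rows),
        kind1=doc["kind1"],
        kind2=doc["kind2"],
        noise_sd=doc.get("noise_sd"),
        metadata=doc.get("metadata", {}),
    )
    truth = None
    if "truth" in doc:
        truth = TwoSiteSystem(**doc["truth"])
    return DatasetBundle(
        signal=grid, truth=truth, provenance=doc.get("provenance", {})
    )
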