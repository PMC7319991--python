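"""Acquisition planning arithmetic for conventional versus ultrafast DEXSY.

A conventional DEXSY experiment samples an N x M grid of gradient pairs one
repetition at a time, so its duration scales as N*M*scans times the
repetition period; the ultrafast experiment acquires the whole grid per
scan.  This module does that protocol arithmetic (repetition counts,
durations, speed-up factors) and reports the geometric coupling between the
spatial-encoding region and the imaging field of view of the CPMG read-out.
No hardware is modelled: durations are pure repetition-count x period
products, with the per-repetition sequence overhead supplied by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

from .encoding import CPMGReadout, EncodingBlock, encoding_region

__all__ = [
    "AcquisitionPlan",
    "repetitions",
    "duration",
    "speedup",
    "resolution_report",
]


@dataclass(frozen=True)
class AcquisitionPlan:
    """One acquisition protocol: grid size, scans and repetition period.

    ``repetition_time`` includes the relaxation delay.  In ``conventional``
    mode every (indirect, direct) grid point needs its own repetition; in
    ``ultrafast`` mode one repetition covers the full grid.
    """

    n_indirect: int
    n_direct: int
    scans: int = 1
    repetition_time: float = 60.0
    mode: str = "conventional"

    def __post_init__(self) -> None:
        for name in ("n_indirect", "n_direct", "scans"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be > 0")
        if self.mode not in ("conventional", "ultrafast"):
            raise ValueError("mode must be 'conventional' or 'ultrafast'")


def repetitions(plan: AcquisitionPlan) -> int:
    """Total repetitions: N*M*scans conventionally, scans ultrafast."""
    if plan.mode == "conventional":
        return plan.n_indirect * plan.n_direct * plan.scans
    return plan.scans


def duration(plan: AcquisitionPlan, sequence_overhead: float = 0.0) -> float:
    """Experiment duration in seconds: repetitions x (period + overhead).

    ``sequence_overhead`` is the per-repetition sequence length beyond the
    repetition time (encoding blocks, mixing time, read-out).
    """
    if sequence_overhead < 0:
        raise ValueError("sequence_overhead must be >= 0")
    return repetitions(plan) * (plan.repetition_time + sequence_overhead)


def speedup(conventional: AcquisitionPlan, ultrafast: AcquisitionPlan) -> float:
    """Repetition-count ratio conventional/ultrafast.

    For single-scan plans on the same grid this is exactly N*M.
    """
    if (conventional.n_indirect, conventional.n_direct) != (
        ultrafast.n_indirect, ultrafast.n_direct
    ):
        raise ValueError("plans must share the same grid size")
    return repetitions(conventional) / repetitions(ultrafast)


def resolution_report(
    block: EncodingBlock, readout: CPMGReadout
) -> dict[str, Any]:
    """Spatial-encoding/read-out geometry report.

    Returns the encoding-region length, the imaging field of view
    FOV = 2*pi/(gamma*G_R*dwell), the nominal pixel size FOV/points, and
    whether the FOV covers the encoding region (it must: pixels outside the
    region carry no signal, and aliasing would fold the profile otherwise).
    The maximum resolutions of the two dimensions are coupled: lengthening
    the read gradient admits more points per echo (finer pixels) but forces
    a longer echo time, coarsening the direct (diffusion) dimension.
    """
    if readout.dwell <= 0:
        raise ValueError("dwell time must be > 0")
    z_min, z_max = encoding_region(block)
    region = z_max - z_min
    fov = 2.0 * math.pi / (
        readout.gamma * readout.read_grad_amplitude * readout.dwell
    )
    pixel = fov / readout.points_per_echo
    report: dict[str, Any] = {
        "encoding_region_m": region,
        "field_of_view_m": fov,
        "pixel_size_m": pixel,
        "points_per_echo": readout.points_per_echo,
        "points_in_region": int(region / pixel),
        "fov_covers_region": fov >= region,
        "coupling": (
            "longer read gradient -> more points per echo (finer pixels) "
            "but longer echo time (coarser direct dimension)"
        ),
    }
    if fov < region:
        report["warning"] = (
            "field of view is smaller than the spatial encoding region; "
            "the profile will alias — increase dwell or reduce G_R"
        )
    return report


def hours(seconds: float) -> float:
    """Seconds to hours, one decimal (raw seconds are kept alongside)."""
    return round(seconds / 3600.0, 1)
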