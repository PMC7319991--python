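"""Spatial-encoding mathematics of the single-scan (ultrafast) DEXSY sequence.

The indirect dimension of the experiment is encoded spatially: a frequency-swept
(chirp) pi/2 pulse applied together with a constant gradient excites successive
sample layers at successive times, so that the double-spin-echo time t1 becomes a
linear function of position z.  The direct dimension is read out with a CPMG echo
train under a read gradient, whose echo decay carries the second diffusion
weighting.  This module implements the sweep/phase/position algebra of that
encoding and the amplitude attenuation kernels of both blocks, under the
instantaneous excitation/inversion approximation (no Bloch integration).

All quantities are SI.  Site-independent geometry lives here; the two-site
physics lives in :mod:`ufdexsy.exchange`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import GAMMA_1H

__all__ = [
    "SweepPulse",
    "EncodingBlock",
    "CPMGReadout",
    "AttenuationQuery",
    "sweep_frequency",
    "sweep_phase",
    "excitation_instant",
    "encoding_region",
    "sweep_phase_at_position",
    "echo_time_profile",
    "first_block_attenuation",
    "effective_read_gradient",
    "cpmg_attenuation",
    "uf_forward_signal",
]


@dataclass(frozen=True)
class SweepPulse:
    """A linearly frequency-swept RF pulse.

    Parameters
    ----------
    duration:
        Pulse length t_F in seconds.  The sweep runs over t in
        [-t_F/2, +t_F/2].
    sweep_width:
        Full frequency sweep width (Hz); the instantaneous frequency runs
        from -sweep_width/2 to +sweep_width/2.
    flip:
        Nominal flip angle, "pi/2" or "pi".  In the ultrafast sequence the
        pi pulse is half as long as the pi/2 pulse.
    initial_phase:
        RF phase at the sweep midpoint t = 0 (radians).
    """

    duration: float
    sweep_width: float
    flip: str = "pi/2"
    initial_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"pulse duration must be > 0, got {self.duration}")
        if self.sweep_width <= 0:
            raise ValueError(f"sweep width must be > 0, got {self.sweep_width}")
        if self.flip not in ("pi/2", "pi"):
            raise ValueError(f"flip must be 'pi/2' or 'pi', got {self.flip!r}")

    def _check_t(self, t: float) -> None:
        half = self.duration / 2.0
        if not (-half <= t <= half):
            raise ValueError(
                f"time {t} s outside the pulse window [{-half}, {half}] s"
            )


@dataclass(frozen=True)
class EncodingBlock:
    """The spatial/diffusion encoding block of the ultrafast sequence.

    Holds the pi/2 sweep pulse, the encoding gradient amplitude G_SD and the
    gyromagnetic ratio.  The pi pulse is implied: same sweep width, half the
    duration of the pi/2 pulse.
    """

    sweep_half: SweepPulse
    grad_spatial_diffusion: float  # G_SD, T/m
    gamma: float = GAMMA_1H

    def __post_init__(self) -> None:
        if self.grad_spatial_diffusion <= 0:
            raise ValueError("encoding gradient G_SD must be > 0")
        if self.gamma <= 0:
            raise ValueError("gyromagnetic ratio must be > 0")

    @property
    def sweep_pi(self) -> SweepPulse:
        """The pi pulse: same sweep width, half the pi/2 duration."""
        return SweepPulse(
            duration=self.sweep_half.duration / 2.0,
            sweep_width=self.sweep_half.sweep_width,
            flip="pi",
            initial_phase=self.sweep_half.initial_phase,
        )

    def _check_z(self, z: float) -> None:
        z_min, z_max = encoding_region(self)
        if not (z_min <= z <= z_max):
            raise ValueError(
                f"position {z} m outside the encoding region "
                f"[{z_min:.6g}, {z_max:.6g}] m"
            )


@dataclass(frozen=True)
class CPMGReadout:
    """CPMG echo-train read-out with a trapezoidal read gradient.

    ``half_echo`` is the pi/2-to-pi spacing tau; the echo spacing is 2*tau and
    echo tops occur at t2 = n*2*tau.  The read gradient is characterised by its
    plateau amplitude, ramp time and total length (ramps included); its
    diffusion weighting enters through the effective gradient of equal area
    spread over tau.
    """

    half_echo: float  # tau, s
    n_echoes: int
    read_grad_amplitude: float  # G_R plateau, T/m
    read_grad_ramp: float  # s
    read_grad_total: float  # s, ramps included
    dwell: float = 5e-6
    points_per_echo: int = 128
    selective_pulse_length: float = 1e-3  # metadata only
    gamma: float = GAMMA_1H

    def __post_init__(self) -> None:
        if self.half_echo <= 0:
            raise ValueError("half-echo spacing tau must be > 0")
        if self.n_echoes < 1:
            raise ValueError("n_echoes must be >= 1")
        if self.read_grad_total <= 2 * self.read_grad_ramp:
            raise ValueError("read gradient total length must exceed 2*ramp")
        if self.dwell <= 0:
            raise ValueError("dwell time must be > 0")
        if self.points_per_echo < 1:
            raise ValueError("points_per_echo must be >= 1")

    @property
    def echo_spacing(self) -> float:
        return 2.0 * self.half_echo

    def echo_times(self) -> np.ndarray:
        """Echo-top times n*2*tau, n = 1..n_echoes."""
        return self.echo_spacing * np.arange(1, self.n_echoes + 1)


@dataclass(frozen=True)
class AttenuationQuery:
    """One diffusing component queried against an attenuation kernel.

    ``t2_relaxation`` of ``None`` means T2 relaxation is neglected (the
    strong-gradient regime in which diffusion dominates the decay).
    """

    diffusion: float  # m^2/s
    t2_relaxation: float | None = None  # s, None = infinite
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.diffusion < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.t2_relaxation is not None and self.t2_relaxation <= 0:
            raise ValueError("T2 must be > 0 when finite")

    @property
    def r2(self) -> float:
        return 0.0 if self.t2_relaxation is None else 1.0 / self.t2_relaxation


# ---------------------------------------------------------------------------
# sweep pulse algebra


def sweep_frequency(pulse: SweepPulse, t: float) -> float:
    """Instantaneous frequency of the swept pulse at time t (Hz).

    nu_F(t) = (sweep_width / duration) * t, linear and antisymmetric about the
    sweep midpoint t = 0.
    """
    pulse._check_t(t)
    return pulse.sweep_width / pulse.duration * t


def sweep_phase(pulse: SweepPulse, t: float) -> float:
    """RF phase of the swept pulse at time t (radians).

    The phase is the time integral of 2*pi*nu_F:
    phi(t) = phi0 + pi * sweep_width * t**2 / duration, even in t.
    """
    pulse._check_t(t)
    return pulse.initial_phase + math.pi * pulse.sweep_width * t**2 / pulse.duration


# ---------------------------------------------------------------------------
# position mapping


def encoding_region(block: EncodingBlock) -> tuple[float, float]:
    """(z_min, z_max) of the region excited by the sweep.

    The sweep covers Larmor frequencies +-sweep_width/2, so under gradient
    G_SD the affected region is z = +-pi*sweep_width/(gamma*G_SD), symmetric
    about the gradient isocentre z = 0.
    """
    z_max = math.pi * block.sweep_half.sweep_width / (
        block.gamma * block.grad_spatial_diffusion
    )
    return (-z_max, z_max)


def excitation_instant(block: EncodingBlock, z: float) -> float:
    """Time (s, relative to the sweep midpoint) at which spins at z are excited.

    The sweep frequency matches the local Larmor frequency
    gamma*G_SD*z/(2*pi) at t(z) = gamma*G_SD*t_F*z / (2*pi*sweep_width).
    """
    block._check_z(z)
    p = block.sweep_half
    return block.gamma * block.grad_spatial_diffusion * p.duration * z / (
        2.0 * math.pi * p.sweep_width
    )


def sweep_phase_at_position(
    block: EncodingBlock, pulse: SweepPulse, z: float
) -> float:
    """RF phase experienced by spins at position z (radians).

    phi(z) = phi0 + gamma^2 G_SD^2 t_F z^2 / (4*pi*sweep_width): quadratic and
    even in z, and independent of gradient polarity (G_SD enters squared).
    The pi/2 and pi pulses imprint different quadratic phases because their
    durations differ by a factor of two; each is cancelled by its symmetric
    partner pulse, which is why the signal model below is amplitude-only.
    """
    block._check_z(z)
    g = block.gamma * block.grad_spatial_diffusion
    return pulse.initial_phase + g**2 * pulse.duration * z**2 / (
        4.0 * math.pi * pulse.sweep_width
    )


def echo_time_profile(
    block: EncodingBlock, z: float, *, t1_prose_convention: bool = False
) -> float:
    """Total double-spin-echo time t1 as a function of position z (seconds).

    t1(z) = 2 * (1 - gamma*G_SD*z/(pi*sweep_width)) * t_F^(pi/2): affine in z,
    zero at the top of the region (z = +z_max) and maximal at the bottom.

    As written, t1 spans [0, 4*t_F^(pi/2)] across the region.  The sequence
    narrative instead describes a span of [0, 2*t_F^(pi/2)] ("zero in the top,
    2 t_F^(pi/2) in the bottom") — a factor-of-two ambiguity this package does
    not resolve.  ``t1_prose_convention=True`` selects the halved profile; the
    default keeps the explicit formula.
    """
    block._check_z(z)
    p = block.sweep_half
    t1 = 2.0 * (
        1.0
        - block.gamma * block.grad_spatial_diffusion * z
        / (math.pi * p.sweep_width)
    ) * p.duration
    if t1_prose_convention:
        t1 *= 0.5
    return t1


# ---------------------------------------------------------------------------
# attenuation kernels


def first_block_attenuation(
    block: EncodingBlock, query: AttenuationQuery, z: float, **t1_kwargs
) -> float:
    """Echo amplitude after the first (spatial/diffusion) encoding block.

    E1(z) = E0 * exp[-(1/T2 + gamma^2 G_SD^2 t1(z)^2 / 48 * D) * t1(z)].

    The /48 arises because the block is a double spin echo: two back-to-back
    echoes of duration t1/2 under a constant gradient each contribute
    gamma^2 G^2 (t1/2)^3 D / 12, summing to gamma^2 G^2 t1^3 D / 48.
    """
    t1 = echo_time_profile(block, z, **t1_kwargs)
    g = block.gamma * block.grad_spatial_diffusion
    rate = query.r2 + g**2 * t1**2 / 48.0 * query.diffusion
    return query.amplitude * math.exp(-rate * t1)


def effective_read_gradient(readout: CPMGReadout) -> float:
    """Equivalent constant gradient for the CPMG diffusion weighting (T/m).

    The trapezoidal read pulse of plateau amplitude G_R, ramp time r and total
    length L has area G_R*(L - r); G_Reff is the amplitude of a rectangular
    pulse of length tau with the same area: G_Reff = G_R*(L - r)/tau.
    """
    area = readout.read_grad_amplitude * (
        readout.read_grad_total - readout.read_grad_ramp
    )
    return area / readout.half_echo


def cpmg_attenuation(
    readout: CPMGReadout, query: AttenuationQuery, t2: float
) -> float:
    """Echo-top amplitude in the CPMG train at time t2 (seconds).

    E2(t2) = E0 * exp[-(1/T2 + gamma^2 G_Reff^2 tau^2 / 3 * D) * t2], the
    constant-gradient CPMG diffusion decay with the effective read gradient.
    """
    if t2 < 0:
        raise ValueError("t2 must be >= 0")
    g_eff = effective_read_gradient(readout)
    rate = query.r2 + (readout.gamma * g_eff) ** 2 * readout.half_echo**2 / 3.0 \
        * query.diffusion
    return query.amplitude * math.exp(-rate * t2)


# ---------------------------------------------------------------------------
# forward model


def uf_t1_kernel(
    block: EncodingBlock, t1_axis: np.ndarray, d_grid: np.ndarray
) -> np.ndarray:
    """Indirect-dimension kernel K1[i, j] = exp(-gamma^2 G_SD^2 t1_i^3 D_j / 48)."""
    t1 = np.asarray(t1_axis, dtype=float)[:, None]
    d = np.asarray(d_grid, dtype=float)[None, :]
    g = block.gamma * block.grad_spatial_diffusion
    return np.exp(-(g**2) * t1**3 * d / 48.0)


def uf_t2_kernel(
    readout: CPMGReadout, t2_axis: np.ndarray, d_grid: np.ndarray
) -> np.ndarray:
    """Direct-dimension kernel K2[i, j] = exp(-gamma^2 G_Reff^2 tau^2 D_j t2_i / 3)."""
    t2 = np.asarray(t2_axis, dtype=float)[:, None]
    d = np.asarray(d_grid, dtype=float)[None, :]
    g_eff = effective_read_gradient(readout)
    rate = (readout.gamma * g_eff) ** 2 * readout.half_echo**2 / 3.0
    return np.exp(-rate * d * t2)


def uf_forward_signal(
    block: EncodingBlock,
    readout: CPMGReadout,
    d1_values: np.ndarray,
    d2_values: np.ndarray,
    weights: np.ndarray,
    t1_axis: np.ndarray,
    t2_axis: np.ndarray,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Noiseless ultrafast DEXSY signal for a discrete P(D1, D2) distribution.

    E[t1, t2] = E0 * sum_{jk} P[j, k]
                * exp(-gamma^2 G_SD^2 t1^3 D1_j / 48)
                * exp(-gamma^2 G_Reff^2 tau^2 D2_k t2 / 3)

    The kernel is separable, so the double sum is evaluated as
    K1 @ P @ K2.T with the two 1D kernel matrices.

    Parameters
    ----------
    d1_values, d2_values:
        Diffusion coefficients labelling the rows/columns of ``weights``.
    weights:
        Non-negative P(D1, D2) matrix, shape (len(d1_values), len(d2_values)).
    t1_axis, t2_axis:
        Strictly increasing sampling axes (seconds).

    Returns
    -------
    Signal matrix of shape (len(t1_axis), len(t2_axis)).
    """
    d1 = np.asarray(d1_values, dtype=float)
    d2 = np.asarray(d2_values, dtype=float)
    p = np.asarray(weights, dtype=float)
    if p.shape != (d1.size, d2.size):
        raise ValueError(
            f"weights shape {p.shape} does not match D grids "
            f"({d1.size}, {d2.size})"
        )
    if np.any(p < 0):
        raise ValueError("weights must be non-negative")
    for name, ax in (("t1_axis", t1_axis), ("t2_axis", t2_axis)):
        ax = np.asarray(ax, dtype=float)
        if ax.size > 1 and np.any(np.diff(ax) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
    k1 = uf_t1_kernel(block, t1_axis, d1)
    k2 = uf_t2_kernel(readout, t2_axis, d2)
    return amplitude * (k1 @ p @ k2.T)
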