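"""Two-site exchange physics for DEXSY.

Water exchanging between a free pool (F, fast diffusion) and an encapsulated
pool (E, slow diffusion, e.g. inside surfactant vesicles) follows first-order
kinetics dM/dt = -K M with the 2x2 exchange matrix K, while longitudinal
relaxation during the mixing time acts through R1.  The conventional DEXSY
signal including exchange during the diffusion encodings is a product of
matrix exponentials sandwiched between the detection vector and the
equilibrium magnetization.

Site ordering everywhere in this package: index 0 = F (free), index 1 = E
(encapsulated).  Rate naming: k_EF is the E->F rate, k_FE the F->E rate;
k = k_EF + k_FE.  Detailed balance (mass conservation at equilibrium) reads
k_FE * x_F = k_EF * x_E, i.e. k_EF = k * x_F and k_FE = k * x_E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .constants import GAMMA_1H

__all__ = [
    "TwoSiteSystem",
    "ConventionalBlock",
    "b_value",
    "exchange_matrix",
    "relaxation_matrix",
    "diffusion_matrix",
    "mixing_propagator",
    "full_exchange_signal",
    "mixing_curves",
]


@dataclass(frozen=True)
class TwoSiteSystem:
    """Physical model of a two-site exchanging system.

    Parameters
    ----------
    d_free, d_enc:
        Diffusion coefficients of the free and encapsulated pools (m^2/s).
    x_free:
        Equilibrium population of the free pool; x_enc = 1 - x_free.
    k_ef, k_fe:
        First-order exchange rates E->F and F->E (s^-1).
    r1_free, r1_enc:
        Longitudinal relaxation rates (s^-1).
    t2_free, t2_enc:
        Optional transverse relaxation times (s); None = neglected.
    """

    d_free: float
    d_enc: float
    x_free: float
    k_ef: float
    k_fe: float
    r1_free: float = 0.0
    r1_enc: float = 0.0
    t2_free: float | None = None
    t2_enc: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_free <= 1.0):
            raise ValueError("x_free must lie in [0, 1]")
        for name in ("d_free", "d_enc", "k_ef", "k_fe", "r1_free", "r1_enc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("t2_free", "t2_enc"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when given")

    @property
    def x_enc(self) -> float:
        return 1.0 - self.x_free

    @property
    def k_total(self) -> float:
        return self.k_ef + self.k_fe

    @property
    def populations(self) -> np.ndarray:
        """Equilibrium magnetization vector M = (x_F, x_E)."""
        return np.array([self.x_free, self.x_enc])

    @property
    def diffusivities(self) -> np.ndarray:
        return np.array([self.d_free, self.d_enc])

    def is_mass_conserving(self, rtol: float = 1e-9) -> bool:
        """True when k_FE * x_F == k_EF * x_E (the equilibrium is a fixed point)."""
        return bool(
            np.isclose(self.k_fe * self.x_free, self.k_ef * self.x_enc, rtol=rtol,
                       atol=1e-300)
        )

    @classmethod
    def mass_conserving(
        cls,
        d_free: float,
        d_enc: float,
        x_free: float,
        k_total: float,
        r1_free: float = 0.0,
        r1_enc: float = 0.0,
        **kwargs,
    ) -> "TwoSiteSystem":
        """Build a system from the total exchange rate k = k_EF + k_FE.

        The split follows mass conservation: k_EF = k * x_free,
        k_FE = k * (1 - x_free).
        """
        return cls(
            d_free=d_free,
            d_enc=d_enc,
            x_free=x_free,
            k_ef=k_total * x_free,
            k_fe=k_total * (1.0 - x_free),
            r1_free=r1_free,
            r1_enc=r1_enc,
            **kwargs,
        )


@dataclass(frozen=True)
class ConventionalBlock:
    """Acquisition geometry of the conventional (multi-scan) DEXSY experiment.

    The diffusion weighting of each encoding is b_i = Delta * gamma^2 * G^2 *
    delta_i^2 for gradient pulses of length delta_i separated by the diffusion
    delay Delta.  ``gradients`` is the per-step amplitude list (shared by both
    dimensions unless overridden at call time).
    """

    gradients: np.ndarray  # T/m, strictly increasing
    delta: float  # gradient pulse length, s
    big_delta: float  # diffusion delay, s
    mixing_time: float = 0.0  # tau_M, s
    gamma: float = GAMMA_1H

    def __post_init__(self) -> None:
        g = np.asarray(self.gradients, dtype=float)
        object.__setattr__(self, "gradients", g)
        if g.ndim != 1 or g.size < 1:
            raise ValueError("gradients must be a 1D non-empty array")
        if np.any(np.diff(g) <= 0):
            raise ValueError("gradient list must be strictly increasing")
        if self.delta <= 0 or self.big_delta <= 0:
            raise ValueError("delta and big_delta must be > 0")
        if self.mixing_time < 0:
            raise ValueError("mixing_time must be >= 0")
        if self.big_delta < 10 * self.delta:
            warnings.warn(
                "diffusion delay is not >> gradient pulse length "
                f"(Delta={self.big_delta}, delta={self.delta}); the "
                "short-pulse b-value approximation degrades",
                stacklevel=2,
            )

    def b_values(self, *, stejskal_tanner_correction: bool = False) -> np.ndarray:
        """b for every gradient step (s/m^2)."""
        return np.array(
            [
                b_value(
                    self, g, stejskal_tanner_correction=stejskal_tanner_correction
                )
                for g in self.gradients
            ]
        )


def b_value(
    block: ConventionalBlock,
    gradient: float,
    *,
    stejskal_tanner_correction: bool = False,
) -> float:
    """Diffusion weighting b = Delta * gamma^2 * G^2 * delta^2 (s/m^2).

    The default uses the short-pulse approximation with the plain Delta
    factor; ``stejskal_tanner_correction=True`` substitutes the full
    Stejskal-Tanner factor (Delta - delta/3) for comparison.
    """
    if gradient < 0:
        raise ValueError("gradient amplitude must be >= 0")
    dt = block.big_delta - block.delta / 3.0 if stejskal_tanner_correction \
        else block.big_delta
    return dt * block.gamma**2 * gradient**2 * block.delta**2


def exchange_matrix(system: TwoSiteSystem) -> np.ndarray:
    """The 2x2 exchange matrix K in site order (F, E).

    K = [[k_FE, -k_EF], [-k_FE, k_EF]]: diagonal entries are the loss rates of
    each site, off-diagonals the gains, so columns sum to zero and exp(-tK)
    conserves total magnetization.  Under detailed balance the equilibrium
    vector (x_F, x_E) spans the null space of K.
    """
    return np.array(
        [[system.k_fe, -system.k_ef], [-system.k_fe, system.k_ef]]
    )


def relaxation_matrix(system: TwoSiteSystem) -> np.ndarray:
    """Diagonal longitudinal relaxation matrix R1 = diag(R1F, R1E)."""
    return np.diag([system.r1_free, system.r1_enc])


def diffusion_matrix(system: TwoSiteSystem) -> np.ndarray:
    """Diagonal diffusion matrix D = diag(D_F, D_E)."""
    return np.diag([system.d_free, system.d_enc])


def mixing_propagator(system: TwoSiteSystem, mixing_time: float) -> np.ndarray:
    """exp(-tau_M * (R1 + K)): evolution of site magnetization over mixing."""
    if mixing_time < 0:
        raise ValueError("mixing time must be >= 0")
    gen = relaxation_matrix(system) + exchange_matrix(system)
    return expm(-mixing_time * gen)


def full_exchange_signal(
    system: TwoSiteSystem,
    block: ConventionalBlock,
    b1,
    b2,
    *,
    encoding_exchange_time: float | None = None,
    amplitude: float = 1.0,
):
    """Conventional DEXSY signal with exchange during the encodings.

    S(b1, b2) = S0 * 1^T [ exp(-b1 D) exp(-t_enc K) exp(-tau_M (R1 + K))
                            exp(-b2 D) exp(-t_enc K) ] M

    where t_enc (``encoding_exchange_time``) is the duration over which
    exchange acts during each diffusion encoding, defaulting to the diffusion
    delay Delta; pass 0 to switch encoding exchange off entirely, in which
    case (with K also absent from the mixing generator only when k = 0) the
    signal reduces to the no-exchange two-exponential form
    S0 * sum_j M_j exp(-(b1 + b2) D_j - tau_M R1_j).

    ``b1`` and ``b2`` broadcast: passing arrays returns the full signal
    matrix of shape (len(b1), len(b2)).
    """
    b1_arr = np.atleast_1d(np.asarray(b1, dtype=float))
    b2_arr = np.atleast_1d(np.asarray(b2, dtype=float))
    if np.any(b1_arr < 0) or np.any(b2_arr < 0):
        raise ValueError("b-values must be >= 0")
    t_enc = block.big_delta if encoding_exchange_time is None \
        else encoding_exchange_time
    if t_enc < 0:
        raise ValueError("encoding_exchange_time must be >= 0")

    d = system.diffusivities
    k = exchange_matrix(system)
    enc = expm(-t_enc * k)
    mix = mixing_propagator(system, block.mixing_time)
    m = system.populations

    # exp(-b D) is diagonal; apply it as row/column scaling around the fixed
    # matrix core mix-to-detection chain.
    #   S = 1^T diag(e1) enc mix diag(e2) enc M
    right = enc @ m  # after first encoding-exchange acting on M ... order below
    # Careful with operator order: the product is read right-to-left on M:
    # first exp(-K), then exp(-b2 D), then mixing, then exp(-K), then exp(-b1 D).
    e1 = np.exp(-np.outer(b1_arr, d))  # (n1, 2)
    e2 = np.exp(-np.outer(b2_arr, d))  # (n2, 2)
    v0 = right  # exp(-t_enc K) M, shape (2,)
    mid = e2 * v0[None, :]  # (n2, 2) = exp(-b2 D) exp(-K) M per b2
    after_mix = mid @ (enc @ mix).T  # (n2, 2): exp(-K) exp(-tau_M(R1+K)) applied
    out = amplitude * (e1 @ after_mix.T)  # (n1, n2): 1^T exp(-b1 D) ...
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            "non-finite signal from matrix-exponential model; parameters: "
            f"{system}, t_enc={t_enc}, tau_M={block.mixing_time}"
        )
    if np.isscalar(b1) or np.ndim(b1) == 0:
        out = out[0]
        if np.isscalar(b2) or np.ndim(b2) == 0:
            out = out[0]
    return out


def mixing_curves(system: TwoSiteSystem, mixing_times) -> dict[str, np.ndarray]:
    """Diagonal- and cross-peak amplitudes versus mixing time.

    I_ij(tau_M) = [exp(-tau_M (R1 + K))]_{ij} * M_j, with j the site occupied
    during the first encoding and i the site during the second.  Keys follow
    the "from->to" reading: ``I_FE`` is the F-then-E cross peak (started free,
    ended encapsulated).  At tau_M = 0 the cross peaks vanish and the diagonal
    peaks equal the equilibrium populations.
    """
    tm = np.atleast_1d(np.asarray(mixing_times, dtype=float))
    if np.any(tm < 0):
        raise ValueError("mixing times must be >= 0")
    out = {"I_FF": [], "I_EE": [], "I_FE": [], "I_EF": []}
    m = system.populations
    for t in tm:
        prop = mixing_propagator(system, t)
        out["I_FF"].append(prop[0, 0] * m[0])
        out["I_EE"].append(prop[1, 1] * m[1])
        out["I_FE"].append(prop[1, 0] * m[0])  # started F (axis 1), ended E
        out["I_EF"].append(prop[0, 1] * m[1])  # started E, ended F
    return {k: np.asarray(v) for k, v in out.items()}
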