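"""Mean-field and linearized contact-network (LCN) dynamics.

The contact-network model couples two-state channels through their
lattice neighbors: a closed channel opens at rate β × (number of open
neighbors) and an open channel closes at rate δ. The first-moment
mean-field approximation gives the nonlinear ODE system

    dp̄/dt = (β diag{ū − p̄} A − δ I) p̄,

and linearizing about the all-closed state p̄ = 0 yields the LCN model

    dp̄/dt = (β A − δ I) p̄,

whose solution decomposes over the eigenmodes (λ_i, v̄_i) of A with
per-mode exponential factors e^{(βλ_i − δ)t}. The system decays to the
all-closed state iff λ₁ < δ/β, which is the spectral stability
threshold linking lattice structure to spark probability.

Conventions: time in milliseconds, rates in ms⁻¹. The mean-field
solution is an upper bound on the true open probabilities, and the LCN
solution bounds the mean-field one from above (the linearization drops
the negative −β diag{p̄}Ap̄ term).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import scipy.stats

from .cluster_lattice import AdjacencyMatrix
from .spectral import EigenDecomposition

__all__ = [
    "CNRates",
    "ModeWeights",
    "OpenExpectation",
    "StabilityResult",
    "lcn_solution",
    "expected_open_vector",
    "expected_open_total",
    "mode_weights",
    "stability_margin",
    "nonlinear_mf_solve",
    "eigenmode_correlation",
]

#: Nominal opening rate with one open neighbor (ms^-1), from the
#: diffusion-model calibration in :mod:`ryrcn.biophysics`.
NOMINAL_BETA = 0.115
#: Channel closing rate (ms^-1), constant in the model.
NOMINAL_DELTA = 0.5
#: Default evaluation time for eigenmode weights (ms).
DEFAULT_T_HAT = 8.0


@dataclass(frozen=True)
class CNRates:
    """Contact-network transition rates (per millisecond).

    ``beta`` is the opening rate contributed by one open neighbor; a
    channel with Y open neighbors opens at rate β·Y. ``delta`` is the
    closing rate of an open channel.
    """

    beta: float = NOMINAL_BETA
    delta: float = NOMINAL_DELTA

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass(frozen=True)
class ModeWeights:
    """Eigenmode weights of the LCN solution at a fixed time t̂.

    ``b[i] = e^{(βλ_i−δ)t̂} ūᵀv̄_i`` weights mode i in the per-initiator
    open-channel expectation; ``c[i] = b[i]·(ūᵀv̄_i)/n`` weights it in the
    population expectation E[N_O]; ``c_frac`` are the fractional
    contributions c_i/Σc_j (sum to 1). At t̂ = 0, Σc_i = 1 exactly since
    Σ(ūᵀv̄_i)² = n.
    """

    t_hat: float
    eigenvalues: np.ndarray
    b: np.ndarray
    c: np.ndarray
    c_frac: np.ndarray

    def top_modes(self, k: int) -> np.ndarray:
        """Mode indices of the k largest fractional contributions."""
        return np.argsort(self.c_frac)[::-1][:k]


@dataclass(frozen=True)
class OpenExpectation:
    """Expected open-channel counts in the LCN model at time t.

    ``per_channel[j]`` is E[n̄_O(t)]_j, the expected number of open
    channels given that channel j alone is open at t = 0; ``total`` is
    E[N_O(t)] for a uniformly random initiating channel, i.e. the mean of
    the per-channel entries.
    """

    t: float
    per_channel: np.ndarray
    total: float


@dataclass(frozen=True)
class StabilityResult:
    """Signed LCN stability margin βλ₁ − δ (ms⁻¹) and its classification."""

    margin: float
    classification: str  # "sub" | "threshold" | "supra"


def _mode_factors(E: EigenDecomposition, rates: CNRates, t: float) -> np.ndarray:
    return np.exp((rates.beta * E.eigenvalues - rates.delta) * t)


def lcn_solution(
    E: EigenDecomposition, rates: CNRates, p0, t: float
) -> np.ndarray:
    """Closed-form LCN open probabilities p̄(t) = Σ_i e^{(βλ_i−δ)t} v̄_i (v̄_iᵀp̄(0)).

    Entries can exceed 1 in the supra-threshold regime; this is the
    documented linearization artifact, not an error.
    """
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (E.n,):
        raise ValueError(f"p0 must have length n={E.n}, got shape {p0.shape}")
    if t < 0:
        raise ValueError("t must be >= 0")
    V = E.eigenvectors
    coef = _mode_factors(E, rates, t) * (V.T @ p0)
    return V @ coef


def expected_open_vector(
    E: EigenDecomposition, rates: CNRates, t: float
) -> np.ndarray:
    """E[n̄_O(t)] = Σ_i e^{(βλ_i−δ)t} (ūᵀv̄_i) v̄_i.

    Entry j is the expected number of open channels at time t given that
    channel j alone was open at t = 0 (equivalently, the column sums of
    the propagator e^{(βA−δI)t}). At t = 0 this is the all-one vector.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    V = E.eigenvectors
    coef = _mode_factors(E, rates, t) * E.mode_overlaps()
    return V @ coef


def expected_open_total(E: EigenDecomposition, rates: CNRates, t: float) -> float:
    """E[N_O(t)] = (1/n) Σ_i e^{(βλ_i−δ)t} (ūᵀv̄_i)² for a random initiator."""
    if t < 0:
        raise ValueError("t must be >= 0")
    overlaps = E.mode_overlaps()
    return float(_mode_factors(E, rates, t) @ overlaps**2 / E.n)


def open_expectation(
    E: EigenDecomposition, rates: CNRates, t: float
) -> OpenExpectation:
    """Bundle per-initiator and population open-channel expectations."""
    vec = expected_open_vector(E, rates, t)
    return OpenExpectation(t=t, per_channel=vec, total=float(vec.mean()))


def mode_weights(
    E: EigenDecomposition, rates: CNRates, t_hat: float = DEFAULT_T_HAT
) -> ModeWeights:
    """Per-mode weights b_i(t̂), c_i(t̂) and fractional contributions."""
    if t_hat < 0:
        raise ValueError("t_hat must be >= 0")
    overlaps = E.mode_overlaps()
    factors = _mode_factors(E, rates, t_hat)
    b = factors * overlaps
    c = b * overlaps / E.n
    total = c.sum()
    # ūᵀv̄₁ > 0 for a connected cluster, so the total cannot vanish.
    assert total > 0, "eigenmode contributions sum to zero on a connected cluster"
    return ModeWeights(
        t_hat=t_hat, eigenvalues=E.eigenvalues.copy(), b=b, c=c, c_frac=c / total
    )


def stability_margin(
    E: EigenDecomposition, rates: CNRates, tol: float = 1e-9
) -> StabilityResult:
    """Classify the LCN dynamics: decay (sub), marginal, or growth (supra).

    The margin is βλ₁ − δ in ms⁻¹; the threshold condition is λ₁ = δ/β.
    """
    margin = rates.beta * E.lambda1 - rates.delta
    if margin < -tol:
        cls = "sub"
    elif margin > tol:
        cls = "supra"
    else:
        cls = "threshold"
    return StabilityResult(margin=float(margin), classification=cls)


def nonlinear_mf_solve(
    a: AdjacencyMatrix,
    rates: CNRates,
    p0,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the nonlinear mean-field ODE dp̄/dt = β(ū−p̄)∘(Ap̄) − δp̄.

    Returns an array of shape ``(len(t_grid), n)``. The vector field
    preserves [0,1]^n, and the solver tolerances are tight enough that the
    reported trajectories stay in range without clipping.
    """
    p0 = np.asarray(p0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    m = a.entries.astype(float)
    if p0.shape != (a.n,):
        raise ValueError(f"p0 must have length n={a.n}")
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValueError("p0 entries must lie in [0, 1]")
    beta, delta = rates.beta, rates.delta

    def rhs(_t, p):
        return beta * (1.0 - p) * (m @ p) - delta * p

    sol = scipy.integrate.solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        p0,
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"mean-field ODE solver failed: {sol.message}")
    return sol.y.T


def eigenmode_correlation(
    E: EigenDecomposition,
    rates: CNRates,
    t_hat: float = DEFAULT_T_HAT,
    k: int = 1,
    method: str = "pearson",
) -> float:
    """Correlation ρ_k between E[n̄_O(t̂)] and its k-mode partial sum.

    Modes are the dominant one plus the (k−1) largest remaining
    fractional contributions c_frac (not simply the next eigenvalues:
    ūᵀv̄_i can vanish for λ₂'s vector, leaving it weightless). ρ_n = 1
    exactly since the full sum reconstructs E[n̄_O].
    """
    if not 1 <= k <= E.n:
        raise ValueError(f"k must be in 1..{E.n}")
    full = expected_open_vector(E, rates, t_hat)
    w = mode_weights(E, rates, t_hat)
    rest = [i for i in np.argsort(w.c_frac)[::-1] if i != 0]
    selected = [0] + rest[: k - 1]
    partial = E.eigenvectors[:, selected] @ w.b[selected]
    if np.std(full) < 1e-14 or np.std(partial) < 1e-14:
        raise ValueError("correlation undefined: zero variance across channels")
    if method == "pearson":
        rho = scipy.stats.pearsonr(full, partial).statistic
    elif method == "spearman":
        rho = scipy.stats.spearmanr(full, partial).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(rho)
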