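"""Exact stochastic simulation of the contact-network model.

Each channel is a two-state (closed/open) Markov channel; a closed
channel with Y open lattice neighbors opens at rate β·Y and an open
channel closes at rate δ. A trial starts with a single initiating
channel open and runs the Gillespie stochastic simulation algorithm
until either every channel has closed (failure) or the open count
reaches the spark threshold (success; 4 open channels by default, the
operational definition of a Ca²⁺ spark). The spontaneous opening rate
with no open neighbor is taken as zero, so the all-closed state is
absorbing.

For spark-probability estimation the waiting times are irrelevant:
absorption probabilities of a continuous-time Markov chain depend only
on its embedded jump chain, so the estimator samples the jump chain
directly. Full trajectories with event times are available from
:func:`simulate_trial`.

An exact absorption-probability solver over the full 2^n configuration
space (practical for n ≲ 12) serves as an independent oracle for the
Monte-Carlo estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.sparse
import scipy.sparse.linalg

from .cluster_lattice import AdjacencyMatrix
from .mean_field import CNRates

__all__ = [
    "GillespieTrajectory",
    "SparkEstimate",
    "simulate_trial",
    "estimate_spark_probability",
    "per_channel_spark_map",
    "exact_absorption_probability",
    "ensemble_mean_open",
]

DEFAULT_SPARK_THRESHOLD = 4
MAX_EVENTS = 10**6


@dataclass(frozen=True)
class GillespieTrajectory:
    """One stochastic trial of the contact-network model.

    ``times`` are event times in ms (the initiator opens at t = 0 and is
    not an event); ``channels``/``transitions`` give the channel index
    and +1 (open) / −1 (close) for each event. ``outcome`` is ``"spark"``
    if the open count reached ``spark_threshold`` (initiator included)
    and ``"failure"`` if it hit zero.
    """

    times: np.ndarray
    channels: np.ndarray
    transitions: np.ndarray
    initiator: int
    outcome: str
    spark_threshold: int
    seed: object = None

    def open_count(self) -> np.ndarray:
        """N_O after each event (N_O(0) = 1 before the first event)."""
        return 1 + np.cumsum(self.transitions)


@dataclass(frozen=True)
class SparkEstimate:
    """Binomial Monte-Carlo estimate of the spark probability p_S."""

    p_hat: float
    se: float
    n_trials: int
    n_sparks: int
    spark_threshold: int
    beta: float
    delta: float
    initiator_policy: str
    seed: object = None


def _seed_tuple(seed) -> tuple[int, ...]:
    """Canonicalize a user seed into a tuple of ints for SeedSequence."""
    if seed is None:
        return (np.random.SeedSequence().entropy,)
    if isinstance(seed, (tuple, list)):
        out: tuple[int, ...] = ()
        for x in seed:
            out += _seed_tuple(x)
        return out
    return (int(seed),)


def _trial_rng(base: tuple[int, ...], trial: int) -> np.random.Generator:
    """Deterministic per-trial substream; trial k replays in isolation."""
    return np.random.default_rng(np.random.SeedSequence(base + (trial,)))


def _run_jump_chain(
    neighbors,
    beta: float,
    delta: float,
    initiator: int,
    spark_threshold,
    rng,
    record=None,
    t_max=None,
):
    """Core Gillespie loop shared by all simulation entry points.

    ``record`` (list or None) collects (t, channel, ±1) events; times are
    drawn only when recording or when ``t_max`` is set. With
    ``spark_threshold=None`` absorption at the threshold is disabled
    (used for mean-field comparisons) and ``t_max`` bounds the run.
    Returns the outcome string.
    """
    n = len(neighbors)
    y = [0] * n            # open-neighbor counts
    is_open = [False] * n
    open_list = [initiator]
    is_open[initiator] = True
    # frontier: insertion-ordered map of closed channels with y > 0
    frontier: dict[int, None] = {}
    s = 0                  # sum of y over frontier
    for k in neighbors[initiator]:
        y[k] += 1
        frontier[k] = None
        s += 1
    t = 0.0
    timed = record is not None or t_max is not None
    rand = rng.random
    for _ in range(MAX_EVENTS):
        n_open = len(open_list)
        if n_open == 0:
            return "failure"
        if spark_threshold is not None and n_open >= spark_threshold:
            return "spark"
        total = delta * n_open + beta * s
        if timed:
            t += -np.log1p(-rand()) / total
            if t_max is not None and t > t_max:
                return "timeout"
        u = rand() * total
        if u < delta * n_open:
            # close a uniformly random open channel
            i = open_list[int(u / delta)]
            open_list.remove(i)
            is_open[i] = False
            for k in neighbors[i]:
                y[k] -= 1
                if not is_open[k]:
                    s -= 1
                    if y[k] == 0:
                        del frontier[k]
            if y[i] > 0:
                frontier[i] = None
                s += y[i]
            if record is not None:
                record.append((t, i, -1))
        else:
            # open a frontier channel with probability proportional to y
            u = (u - delta * n_open) / beta
            acc = 0.0
            j = -1
            for cand in frontier:
                acc += y[cand]
                if u < acc:
                    j = cand
                    break
            if j < 0:  # numerical edge: fall back to the last candidate
                j = cand
            s -= y[j]
            del frontier[j]
            is_open[j] = True
            open_list.append(j)
            for k in neighbors[j]:
                y[k] += 1
                if not is_open[k]:
                    s += 1
                    frontier[k] = None
            if record is not None:
                record.append((t, j, +1))
    raise RuntimeError(f"trial exceeded {MAX_EVENTS} events without absorbing")


def simulate_trial(
    a: AdjacencyMatrix,
    rates: CNRates,
    initiator: int,
    spark_threshold: int = DEFAULT_SPARK_THRESHOLD,
    rng=None,
) -> GillespieTrajectory:
    """Run one statistically exact Gillespie trial with full event record.

    The initiating channel counts toward N_O, so a threshold of 4 means
    three additional openings.
    """
    if not 0 <= initiator < a.n:
        raise IndexError(f"initiator {initiator} out of range for n={a.n}")
    if spark_threshold < 1:
        raise ValueError("spark_threshold must be >= 1")
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = rng
        rng = np.random.default_rng(rng)
    record: list = []
    outcome = _run_jump_chain(
        a.neighbor_lists(),
        rates.beta,
        rates.delta,
        initiator,
        spark_threshold,
        rng,
        record=record,
    )
    times = np.array([e[0] for e in record])
    return GillespieTrajectory(
        times=times,
        channels=np.array([e[1] for e in record], dtype=np.int64),
        transitions=np.array([e[2] for e in record], dtype=np.int64),
        initiator=initiator,
        outcome=outcome,
        spark_threshold=spark_threshold,
        seed=seed,
    )


def estimate_spark_probability(
    a: AdjacencyMatrix,
    rates: CNRates,
    n_trials: int,
    spark_threshold: int = DEFAULT_SPARK_THRESHOLD,
    initiator: int | str = "uniform",
    seed=None,
) -> SparkEstimate:
    """Monte-Carlo estimate of p_S over independent Gillespie trials.

    ``initiator`` is either ``"uniform"`` (each channel equally likely to
    open spontaneously, the resting-cluster assumption) or a fixed
    channel index.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if spark_threshold > a.n:
        raise ValueError(
            f"spark_threshold {spark_threshold} exceeds cluster size {a.n}: "
            "success is unreachable"
        )
    if spark_threshold < 1:
        raise ValueError("spark_threshold must be >= 1")
    neighbors = a.neighbor_lists()
    uniform = initiator == "uniform"
    if not uniform and not 0 <= int(initiator) < a.n:
        raise IndexError(f"initiator {initiator} out of range for n={a.n}")
    base = _seed_tuple(seed)
    n_sparks = 0
    for trial in range(n_trials):
        rng = _trial_rng(base, trial)
        init = int(rng.integers(a.n)) if uniform else int(initiator)
        outcome = _run_jump_chain(
            neighbors, rates.beta, rates.delta, init, spark_threshold, rng
        )
        n_sparks += outcome == "spark"
    p = n_sparks / n_trials
    return SparkEstimate(
        p_hat=p,
        se=float(np.sqrt(p * (1.0 - p) / n_trials)),
        n_trials=n_trials,
        n_sparks=n_sparks,
        spark_threshold=spark_threshold,
        beta=rates.beta,
        delta=rates.delta,
        initiator_policy="uniform" if uniform else f"fixed {int(initiator)}",
        seed=seed,
    )


def per_channel_spark_map(
    a: AdjacencyMatrix,
    rates: CNRates,
    n_trials_per_channel: int,
    spark_threshold: int = DEFAULT_SPARK_THRESHOLD,
    seed=None,
) -> list[SparkEstimate]:
    """Estimate p_S separately for every fixed initiating channel.

    The result maps intra-cluster spark-probability gradients: channels
    near the cluster interior recruit neighbors more readily than
    peripheral ones.
    """
    return [
        estimate_spark_probability(
            a,
            rates,
            n_trials_per_channel,
            spark_threshold=spark_threshold,
            initiator=j,
            seed=None if seed is None else (seed, j),
        )
        for j in range(a.n)
    ]


def exact_absorption_probability(
    a: AdjacencyMatrix,
    rates: CNRates,
    initiator: int,
    spark_threshold: int = DEFAULT_SPARK_THRESHOLD,
    max_n: int = 12,
) -> float:
    """Exact spark probability by solving the configuration-space CTMC.

    Enumerates every configuration with 1..threshold−1 open channels and
    solves the linear absorption system for reaching N_O = threshold
    before N_O = 0. Exponential in n; refuses n > ``max_n``.
    """
    n = a.n
    if n > max_n:
        raise ValueError(
            f"n={n} exceeds the exact-solver cap ({max_n}); use Monte Carlo"
        )
    if not 0 <= initiator < n:
        raise IndexError(f"initiator {initiator} out of range")
    if spark_threshold < 1:
        raise ValueError("spark_threshold must be >= 1")
    if spark_threshold > n:
        raise ValueError("spark_threshold exceeds cluster size")
    if spark_threshold == 1:
        return 1.0  # the initial state already counts as a spark

    neighbors = a.neighbor_lists()
    beta, delta = rates.beta, rates.delta

    # Transient states: frozen sets of open channels, 1..threshold-1 open.
    states: list[tuple[int, ...]] = []
    for k in range(1, spark_threshold):
        states.extend(combinations(range(n), k))
    index = {s: i for i, s in enumerate(states)}
    m = len(states)

    rows, cols, vals = [], [], []
    rhs = np.zeros(m)
    for i, s in enumerate(states):
        open_set = set(s)
        events = []  # (rate, next_state or "spark"/"failure")
        for ch in s:
            nxt = tuple(x for x in s if x != ch)
            events.append((delta, nxt if nxt else "failure"))
        for ch in range(n):
            if ch in open_set:
                continue
            y = sum(nb in open_set for nb in neighbors[ch])
            if y:
                nxt = tuple(sorted(open_set | {ch}))
                target = "spark" if len(nxt) >= spark_threshold else nxt
                events.append((beta * y, target))
        total = sum(r for r, _ in events)
        rows.append(i)
        cols.append(i)
        vals.append(1.0)
        for rate, target in events:
            p = rate / total
            if target == "spark":
                rhs[i] += p
            elif target != "failure":
                rows.append(i)
                cols.append(index[target])
                vals.append(-p)
    mat = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(m, m))
    x = scipy.sparse.linalg.spsolve(mat, rhs)
    return float(x[index[(initiator,)]])


def ensemble_mean_open(
    a: AdjacencyMatrix,
    rates: CNRates,
    t_grid,
    n_trials: int,
    initiator: int | str = "uniform",
    seed=None,
) -> np.ndarray:
    """Ensemble mean of N_O(t) with threshold absorption disabled.

    Trials run until all channels close or ``t_grid[-1]`` is reached;
    absorbed trials contribute N_O = 0 thereafter. Used to check that the
    mean-field solutions bound the exact process from above.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    neighbors = a.neighbor_lists()
    uniform = initiator == "uniform"
    acc = np.zeros(t_grid.size)
    base = _seed_tuple(seed)
    for trial in range(n_trials):
        rng = _trial_rng(base, trial)
        init = int(rng.integers(a.n)) if uniform else int(initiator)
        record: list = []
        _run_jump_chain(
            neighbors,
            rates.beta,
            rates.delta,
            init,
            None,
            rng,
            record=record,
            t_max=float(t_grid[-1]),
        )
        times = np.array([e[0] for e in record])
        counts = 1 + np.cumsum([e[2] for e in record])
        idx = np.searchsorted(times, t_grid, side="right") - 1
        acc += np.where(idx < 0, 1, np.concatenate(([1], counts))[idx + 1])
    return acc / n_trials
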