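"""Non-equilibrium work processing and free energy estimation.

One alchemical edge is evaluated by equilibrium sampling at both physical
end states followed by many fast driven λ-switches; the work of each switch
is the thermodynamic integral of ∂H/∂λ along the trajectory.  Given forward
(A→B) and reverse (B→A) work samples, the Crooks fluctuation theorem

    P_f(W) / P_r(−W) = exp(β (W − ΔG))

identifies ΔG, and the Bennett acceptance ratio is its maximum-likelihood
estimator.  This module provides the frame scheduler for snapshot
extraction, trapezoidal TI, the BAR/MLE solver, a Jarzynski exponential
average (kept as an independent cross-check), bootstrap errors, replica
aggregation and ΔΔG assembly.  Everything is in kcal/mol internally;
readers convert from kJ/mol.

Sign convention: reverse works are recorded as integrated along the B→A
switch (pmx-style), so for a dissipation-free process W_r = −W_f; the
estimator handles the sign internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .constants import DEFAULT_TEMPERATURE_K, KB_KCAL_PER_MOL_K, KJ_PER_KCAL
from .exceptions import InsufficientOverlapError, ParseError

__all__ = [
    "DhdlTrace",
    "WorkSet",
    "FreeEnergyEstimate",
    "EdgeResult",
    "frame_schedule",
    "integrate_work",
    "bar_estimate",
    "jarzynski_estimate",
    "bootstrap_se",
    "combine_replicas",
    "edge_ddg",
    "read_work_file",
    "read_dhdl_trace",
]


@dataclass
class DhdlTrace:
    """∂H/∂λ samples along one switching trajectory (kcal/mol).

    λ strictly increasing marks a forward (A→B) switch, strictly decreasing
    a reverse (B→A) switch.
    """

    lam: np.ndarray
    dhdl: np.ndarray

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        self.dhdl = np.asarray(self.dhdl, dtype=float)
        if self.lam.shape != self.dhdl.shape or self.lam.ndim != 1:
            raise ValueError("lam and dhdl must be 1-D arrays of equal length")
        if self.lam.size < 2:
            raise ValueError("trace needs at least 2 samples")
        d = np.diff(self.lam)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("lambda values must be strictly monotone")


@dataclass
class WorkSet:
    """Bidirectional work samples for one edge, leg and replica (kcal/mol)."""

    edge_id: str
    leg: str
    replica: int
    w_forward: np.ndarray
    w_reverse: np.ndarray  # recorded along the B→A switch

    def __post_init__(self):
        self.w_forward = np.atleast_1d(np.asarray(self.w_forward, dtype=float))
        self.w_reverse = np.atleast_1d(np.asarray(self.w_reverse, dtype=float))
        if self.w_forward.size < 1 or self.w_reverse.size < 1:
            raise ValueError("need at least one work value in each direction")
        if not (np.all(np.isfinite(self.w_forward)) and np.all(np.isfinite(self.w_reverse))):
            raise ValueError("non-finite work value")

    @property
    def n_f(self) -> int:
        return int(self.w_forward.size)

    @property
    def n_r(self) -> int:
        return int(self.w_reverse.size)


@dataclass
class FreeEnergyEstimate:
    """ΔG (kcal/mol) with bootstrap SE and provenance."""

    value: float
    se_boot: float
    estimator: str
    n_f: int
    n_r: int
    temperature: float

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("non-finite free energy value")
        if self.se_boot < 0:
            raise ValueError("negative bootstrap SE")


@dataclass
class EdgeResult:
    """Per-edge ΔΔG = ΔG_complex − ΔG_water (kcal/mol)."""

    edge_id: str
    dg_complex: float
    dg_water: float
    ddg: float
    se: float
    replicas: int = 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.ddg - (self.dg_complex - self.dg_water)) > 1e-9:
            raise ValueError("ddg inconsistent with its two legs")
        if self.se < 0:
            raise ValueError("negative edge SE")


def frame_schedule(t_total: float, t_discard: float, n_frames: int) -> np.ndarray:
    """Snapshot extraction times (ps) from an equilibrium trajectory.

    The first ``t_discard`` ps are treated as extra equilibration and
    excluded; ``n_frames`` equally spaced times cover the remainder, ending
    exactly at ``t_total`` (the discard boundary itself is not sampled).
    The production protocol (6 ns run, first 2 ns discarded, 80 frames)
    gives times 2050, 2100, …, 6000 ps at 50 ps spacing.
    """
    if not (0 <= t_discard < t_total):
        raise ValueError("require 0 <= t_discard < t_total")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    delta = (t_total - t_discard) / n_frames
    return t_discard + delta * np.arange(1, n_frames + 1)


def integrate_work(trace: DhdlTrace) -> float:
    """Work (kcal/mol) by trapezoidal thermodynamic integration over λ.

    The integral follows the traversal direction, so a reverse trace
    (λ 1→0) yields the B→A work directly.
    """
    return float(np.trapezoid(trace.dhdl, trace.lam))


def _beta(temperature: float) -> float:
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return 1.0 / (KB_KCAL_PER_MOL_K * temperature)


def _bar_terms(dg: float, w_f: np.ndarray, w_r: np.ndarray, beta: float):
    # Bennett/Shirts self-consistency: Fermi-weighted counts in the two
    # directions balance at the MLE.  expit keeps both tails stable.
    n_f, n_r = w_f.size, w_r.size
    fwd = expit(-(np.log(n_f / n_r) + beta * (w_f - dg)))
    rev = expit(-(np.log(n_r / n_f) + beta * (dg - (-w_r))))
    return fwd, rev


def _bar_objective(dg: float, w_f: np.ndarray, w_r: np.ndarray, beta: float) -> float:
    fwd, rev = _bar_terms(dg, w_f, w_r, beta)
    return float(fwd.sum() - rev.sum())


def bar_estimate(works: WorkSet, temperature: float = DEFAULT_TEMPERATURE_K) -> FreeEnergyEstimate:
    """Maximum-likelihood ΔG from bidirectional works (BAR, Crooks-consistent).

    The MLE objective is monotone in ΔG, so a bracketed root search on
    [min(W_f ∪ −W_r) − 50 k_BT, max(W_f ∪ −W_r) + 50 k_BT] is globally
    safe.  When the forward and negated-reverse work distributions are
    separated, the objective is numerically zero over the whole gap (every
    Fermi weight underflows): the root is then undetermined and the
    estimate is refused as insufficient overlap.
    """
    beta = _beta(temperature)
    w_f, w_r = works.w_forward, works.w_reverse
    kbt = 1.0 / beta
    pooled = np.concatenate([w_f, -w_r])
    lo = float(pooled.min() - 50.0 * kbt)
    hi = float(pooled.max() + 50.0 * kbt)
    f_lo = _bar_objective(lo, w_f, w_r, beta)
    f_hi = _bar_objective(hi, w_f, w_r, beta)
    if np.sign(f_lo) == np.sign(f_hi) and not (f_lo == 0.0 or f_hi == 0.0):
        raise InsufficientOverlapError(  # pragma: no cover - guarded by monotonicity
            f"insufficient overlap: no BAR root in bracket [{lo:.4f}, {hi:.4f}] kcal/mol"
        )
    dg = brentq(_bar_objective, lo, hi, args=(w_f, w_r, beta), xtol=1e-12, rtol=8.9e-16)
    fwd, rev = _bar_terms(dg, w_f, w_r, beta)
    if fwd.sum() + rev.sum() < 1e-10:
        raise InsufficientOverlapError(
            f"insufficient overlap: work distributions are separated, the MLE "
            f"root is undetermined within bracket [{lo:.4f}, {hi:.4f}] kcal/mol"
        )
    return FreeEnergyEstimate(
        value=float(dg), se_boot=0.0, estimator="bar",
        n_f=works.n_f, n_r=works.n_r, temperature=temperature,
    )


def jarzynski_estimate(
    works: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE_K,
    direction: str = "f",
) -> float:
    """Exponential-average (Jarzynski) ΔG from unidirectional works.

    Forward: ΔG = −k_BT ln⟨exp(−βW)⟩ over A→B works.  Reverse works
    (recorded along B→A) give ΔG_B→A the same way; the A→B value is its
    negation.  Computed with log-sum-exp stabilization.  Kept as an
    independent cross-check of the bidirectional estimator.
    """
    w = np.atleast_1d(np.asarray(works, dtype=float))
    if w.size < 1:
        raise ValueError("need at least one work value")
    beta = _beta(temperature)
    dg_traversal = -(logsumexp(-beta * w) - np.log(w.size)) / beta
    if direction == "f":
        return float(dg_traversal)
    if direction == "r":
        return float(-dg_traversal)
    raise ValueError(f"direction must be 'f' or 'r', got {direction!r}")


def bootstrap_se(
    works: WorkSet,
    temperature: float = DEFAULT_TEMPERATURE_K,
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Bootstrap SE of the BAR estimate (forward and reverse resampled
    independently with replacement); deterministic for a fixed seed.

    Raises if more than 10% of resamples fail to yield an estimate.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = []
    failures = 0
    for _ in range(n_boot):
        wf = rng.choice(works.w_forward, size=works.n_f, replace=True)
        wr = rng.choice(works.w_reverse, size=works.n_r, replace=True)
        try:
            est = bar_estimate(
                WorkSet(works.edge_id, works.leg, works.replica, wf, wr), temperature
            )
            values.append(est.value)
        except InsufficientOverlapError:
            failures += 1
    if failures > 0.1 * n_boot:
        raise InsufficientOverlapError(
            f"{failures}/{n_boot} bootstrap resamples had insufficient overlap"
        )
    return float(np.std(values, ddof=1))


def estimate_with_error(
    works: WorkSet,
    temperature: float = DEFAULT_TEMPERATURE_K,
    n_boot: int = 100,
    seed: int | np.random.Generator = 0,
) -> FreeEnergyEstimate:
    """BAR estimate with its bootstrap SE filled in."""
    est = bar_estimate(works, temperature)
    est.se_boot = bootstrap_se(works, temperature, n_boot, seed)
    return est


def combine_replicas(estimates: list[FreeEnergyEstimate]) -> tuple[float, float]:
    """Aggregate replica estimates of one leg.

    value = mean over replicas; the error combines the between-replica
    scatter with the propagated per-replica bootstrap uncertainty:

        se² = s²/R + (Σᵢ se_boot,ᵢ²)/R²

    with s the sample SD over R replicas.  For a single replica the
    bootstrap SE is returned unchanged.
    """
    if not estimates:
        raise ValueError("no replica estimates to combine")
    vals = np.array([e.value for e in estimates], dtype=float)
    boots = np.array([e.se_boot for e in estimates], dtype=float)
    r = vals.size
    if r == 1:
        return float(vals[0]), float(boots[0])
    s2 = float(np.var(vals, ddof=1))
    se = np.sqrt(s2 / r + float(np.sum(boots**2)) / r**2)
    return float(vals.mean()), float(se)


def edge_ddg(
    edge_id: str,
    complex_leg: tuple[float, float],
    water_leg: tuple[float, float],
    replicas: int = 1,
) -> EdgeResult:
    """Assemble ΔΔG = ΔG_complex − ΔG_water with quadrature-combined SE."""
    dg_c, se_c = complex_leg
    dg_w, se_w = water_leg
    return EdgeResult(
        edge_id=edge_id,
        dg_complex=float(dg_c),
        dg_water=float(dg_w),
        ddg=float(dg_c - dg_w),
        se=float(np.hypot(se_c, se_w)),
        replicas=replicas,
    )


def read_work_file(path) -> np.ndarray:
    """Read a two-column work file (snapshot index, work in kJ/mol).

    Lines starting with ``#`` are ignored; works return in kcal/mol, file
    order preserved.
    """
    works = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{ln}: expected two columns, got {line!r}")
            try:
                w = float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-numeric work value {parts[1]!r}") from exc
            works.append(w / KJ_PER_KCAL)
    if not works:
        raise ParseError(f"{path}: no work values")
    return np.array(works)


def read_dhdl_trace(path) -> DhdlTrace:
    """Read a dH/dλ trace: columns (λ, dH/dλ) or (time, λ, dH/dλ), kJ/mol."""
    lam, dhdl = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            if len(parts) == 2:
                l, d = parts
            elif len(parts) >= 3:
                _, l, d = parts[:3]
            else:
                raise ParseError(f"{path}:{ln}: expected 2 or 3 columns")
            try:
                lam.append(float(l))
                dhdl.append(float(d) / KJ_PER_KCAL)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-numeric entry") from exc
    return DhdlTrace(np.array(lam), np.array(dhdl))
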