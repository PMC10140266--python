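"""Cycle closure, absolute ΔG reconstruction and benchmark metrics.

Edge ΔΔG estimates carry independent noise, so sums around graph cycles do
not vanish exactly.  Projecting the edge values onto the
node-difference-consistent subspace — a weighted least squares over node
free energies — removes the inconsistency (corrected edge values close
every cycle at machine precision) and yields per-node ΔG up to an additive
gauge constant.  The gauge is fixed to mean zero here and, for comparison
with experiment, shifted so calculated and experimental means coincide over
the ligands measured.  Benchmark metrics (AUE, RMSE, Pearson ρ, Kendall
τ_b) come with percentile-bootstrap CIs and an experimental-noise null band
(the performance ceiling a calculation exactly as uncertain as the
experiment would reach).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .chemdata import AffinityTable
from .constants import EXP_SIGMA_FLOOR_KCAL, SE_FLOOR_KCAL
from .exceptions import DisconnectedMapError
from .fepmap import PerturbationMap
from .neswork import EdgeResult

__all__ = [
    "NodeEstimate",
    "MetricsReport",
    "solve_node_dgs",
    "cycle_closure_errors",
    "offset_to_experiment",
    "compute_metrics",
    "bootstrap_metric_ci",
    "experimental_null_band",
]

METRIC_NAMES = ("aue", "rmse", "pearson_rho", "kendall_tau")


@dataclass
class NodeEstimate:
    """Absolute ΔG (kcal/mol) reconstructed for one ligand."""

    id: str
    dg_calc: float
    se: float

    def __post_init__(self):
        if not np.isfinite(self.dg_calc):
            raise ValueError(f"node '{self.id}': non-finite dg_calc")
        if self.se < 0:
            raise ValueError(f"node '{self.id}': negative se")


@dataclass
class MetricsReport:
    """Benchmark metrics with optional CIs and experimental null bands."""

    aue: float
    rmse: float
    pearson_rho: float
    kendall_tau: float
    correlations_defined: bool = True
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    null_band: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "aue": self.aue,
            "rmse": self.rmse,
            "pearson_rho": self.pearson_rho,
            "kendall_tau": self.kendall_tau,
            "correlations_defined": self.correlations_defined,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "null_band": {k: list(v) for k, v in self.null_band.items()},
        }


def _edge_lookup(pmap: PerturbationMap, edges: list[EdgeResult]) -> dict[str, EdgeResult]:
    by_id = {e.edge_id: e for e in edges}
    missing = [eid for eid in pmap.edge_ids if eid not in by_id]
    if missing:
        raise ValueError(f"missing edge results for: {missing}")
    return by_id


def solve_node_dgs(
    pmap: PerturbationMap,
    edges: list[EdgeResult],
    se_floor: float = SE_FLOOR_KCAL,
) -> list[NodeEstimate]:
    """Weighted-least-squares node ΔG from edge ΔΔG (cycle closure).

    Minimizes Σ_e w_e (g_b − g_a − ΔΔG_e)² with w_e = 1/max(se_e, floor)²,
    gauge-fixed to mean(g) = 0.  Node SEs come from the diagonal of the
    pseudo-inverse of the weighted graph Laplacian.
    """
    by_id = _edge_lookup(pmap, edges)
    g = pmap.to_networkx()
    if len(pmap.nodes) > 1 and not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise DisconnectedMapError(f"graph is disconnected; components: {comps}")

    nodes = list(pmap.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n, m = len(nodes), len(pmap.edges)
    incidence = np.zeros((m, n))
    ddg = np.zeros(m)
    weights = np.zeros(m)
    for k, e in enumerate(pmap.edges):
        res = by_id[e.id]
        incidence[k, idx[e.a]] = -1.0
        incidence[k, idx[e.b]] = 1.0
        ddg[k] = res.ddg
        weights[k] = 1.0 / max(res.se, se_floor) ** 2

    lap = incidence.T @ (weights[:, None] * incidence)
    rhs = incidence.T @ (weights * ddg)
    lap_pinv = np.linalg.pinv(lap)
    sol = lap_pinv @ rhs
    sol -= sol.mean()
    node_se = np.sqrt(np.clip(np.diag(lap_pinv), 0.0, None))
    return [NodeEstimate(nodes[i], float(sol[i]), float(node_se[i])) for i in range(n)]


def cycle_closure_errors(pmap: PerturbationMap, edges: list[EdgeResult]) -> list[float]:
    """Signed ΔΔG sums (kcal/mol) around a spanning-tree cycle basis.

    All zero for a thermodynamically consistent edge set; a tree graph has
    no cycles and returns an empty list.
    """
    by_id = _edge_lookup(pmap, edges)
    ddg = {(e.a, e.b): by_id[e.id].ddg for e in pmap.edges}
    g = pmap.to_networkx()
    sums = []
    for cycle in nx.cycle_basis(g):
        total = 0.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            if (a, b) in ddg:
                total += ddg[(a, b)]
            else:
                total -= ddg[(b, a)]
        sums.append(total)
    return sums


def offset_to_experiment(
    nodes: list[NodeEstimate], exp: AffinityTable
) -> list[NodeEstimate]:
    """Shift all calculated ΔG by one constant so the calculated mean matches
    the experimental mean over the ligands with measurements.

    Pairwise differences (the actual predictions) and node SEs are
    unchanged; idempotent.
    """
    overlap = [n for n in nodes if n.id in exp]
    if not overlap:
        raise ValueError("no ligand overlaps between calculation and experiment")
    offset = float(np.mean([exp.dg(n.id) for n in overlap])) - float(
        np.mean([n.dg_calc for n in overlap])
    )
    return [NodeEstimate(n.id, n.dg_calc + offset, n.se) for n in nodes]


def _point_metrics(
    calc: np.ndarray, exp: np.ndarray, metrics: tuple[str, ...] = METRIC_NAMES
) -> dict[str, float]:
    resid = calc - exp
    out: dict[str, float] = {}
    if "aue" in metrics:
        out["aue"] = float(np.mean(np.abs(resid)))
    if "rmse" in metrics:
        out["rmse"] = float(np.sqrt(np.mean(resid**2)))
    if "pearson_rho" in metrics or "kendall_tau" in metrics:
        degenerate = np.ptp(calc) == 0 or np.ptp(exp) == 0
        if "pearson_rho" in metrics:
            out["pearson_rho"] = (
                np.nan if degenerate else float(stats.pearsonr(calc, exp).statistic)
            )
        if "kendall_tau" in metrics:
            out["kendall_tau"] = (
                np.nan
                if degenerate
                else float(stats.kendalltau(calc, exp, variant="b").statistic)
            )
    return out


def compute_metrics(calc, exp) -> MetricsReport:
    """AUE, RMSE, Pearson ρ and tie-corrected Kendall τ_b of calc vs exp.

    With zero variance in either vector the correlations are undefined
    (reported as NaN with ``correlations_defined=False``); the error
    metrics are still meaningful.
    """
    calc = np.asarray(calc, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if calc.shape != exp.shape or calc.ndim != 1 or calc.size < 2:
        raise ValueError("calc and exp must be equal-length 1-D arrays, length >= 2")
    pm = _point_metrics(calc, exp)
    return MetricsReport(
        aue=pm["aue"],
        rmse=pm["rmse"],
        pearson_rho=pm["pearson_rho"],
        kendall_tau=pm["kendall_tau"],
        correlations_defined=not (np.isnan(pm["pearson_rho"])),
    )


def bootstrap_metric_ci(
    calc,
    exp,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> dict[str, tuple[float, float]]:
    """Percentile 95% CIs by resampling (calc, exp) pairs with replacement.

    Deterministic per seed.  Resamples that collapse to a single repeated
    pair carry no ranking information and are redrawn (bounded retries).
    """
    calc = np.asarray(calc, dtype=float)
    exp = np.asarray(exp, dtype=float)
    n = calc.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a bootstrap CI")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples: dict[str, list[float]] = {m: [] for m in metrics}
    for _ in range(n_boot):
        for _attempt in range(100):
            ii = rng.integers(0, n, size=n)
            if not np.all(ii == ii[0]):
                break
        pm = _point_metrics(calc[ii], exp[ii], metrics)
        for m in metrics:
            samples[m].append(pm[m])
    out = {}
    for m in metrics:
        arr = np.array(samples[m])
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            out[m] = (np.nan, np.nan)
        else:
            out[m] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    return out


def experimental_null_band(
    exp,
    sigma_exp,
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
    floor: float = EXP_SIGMA_FLOOR_KCAL,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> dict[str, tuple[float, float]]:
    """Experimental-noise 95% band per metric — the performance ceiling.

    Each draw perturbs the experimental values twice, independently, with
    Gaussian noise of SD max(σ_exp,i, floor) and scores one synthetic
    replica against the other: the metric distribution a calculation
    exactly as uncertain as the experiment would produce.  With all σ zero
    and the floor disabled the band collapses to perfect agreement.
    """
    exp = np.asarray(exp, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma_exp, dtype=float), exp.shape)
    if exp.size < 3:
        raise ValueError("need at least 3 experimental values")
    eff = np.maximum(sigma, floor)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples: dict[str, list[float]] = {m: [] for m in metrics}
    for _ in range(n_samples):
        a = exp + rng.normal(0.0, eff)
        b = exp + rng.normal(0.0, eff)
        pm = _point_metrics(a, b, metrics)
        for m in metrics:
            samples[m].append(pm[m])
    out = {}
    for m in metrics:
        arr = np.array(samples[m])
        arr = arr[np.isfinite(arr)]
        out[m] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    return out
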