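"""Independent oracles used by the tests.

Deliberately naive implementations — dense grids, exhaustive enumeration,
O(n²) pair counts — kept separate from the package so they cannot share a
code path with what they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

KB = 0.0019872041


def bar_objective_naive(dg, w_f, w_r, temperature):
    """Plain transcription of the Crooks-MLE balance condition."""
    beta = 1.0 / (KB * temperature)
    n_f, n_r = len(w_f), len(w_r)
    with np.errstate(over="ignore"):
        fwd = np.sum(1.0 / (1.0 + (n_f / n_r) * np.exp(beta * (np.asarray(w_f) - dg))))
        rev = np.sum(
            1.0 / (1.0 + (n_r / n_f) * np.exp(-beta * (-np.asarray(w_r) - dg)))
        )
    return fwd - rev


def bar_grid_root(w_f, w_r, temperature=298.0, tol=1e-8):
    """Root of the MLE condition by dense grid scan plus bisection."""
    pooled = np.concatenate([np.asarray(w_f), -np.asarray(w_r)])
    lo, hi = pooled.min() - 40.0, pooled.max() + 40.0
    grid = np.linspace(lo, hi, 4001)
    vals = np.array([bar_objective_naive(x, w_f, w_r, temperature) for x in grid])
    sign = np.sign(vals)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        raise ValueError("no sign change on grid")
    a, b = grid[idx[0]], grid[idx[0] + 1]
    while b - a > tol:
        m = 0.5 * (a + b)
        if np.sign(bar_objective_naive(m, w_f, w_r, temperature)) == np.sign(
            bar_objective_naive(a, w_f, w_r, temperature)
        ):
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def kendall_tau_b_naive(x, y):
    """Tie-corrected Kendall tau by explicit O(n²) pair counting."""
    x, y = np.asarray(x), np.asarray(y)
    n = x.size
    concordant = discordant = tied_x = tied_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tied_x += 1
            elif dy == 0:
                tied_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    # count ties per variable for the tau-b denominator
    def tie_term(v):
        _, counts = np.unique(v, return_counts=True)
        return sum(c * (c - 1) / 2 for c in counts)

    denom = np.sqrt((n0 - tie_term(x)) * (n0 - tie_term(y)))
    return (concordant - discordant) / denom


def wls_node_solve_naive(node_ids, edge_list, se_floor=0.1):
    """Weighted LS node values by pinning the first node and solving the
    normal equations with lstsq; returns values shifted to mean zero.

    ``edge_list``: iterable of (a, b, ddg, se).
    """
    idx = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    rows, rhs = [], []
    for a, b, ddg, se in edge_list:
        w = 1.0 / max(se, se_floor)
        row = np.zeros(n)
        row[idx[a]] = -w
        row[idx[b]] = w
        rows.append(row)
        rhs.append(w * ddg)
    # pin node 0 to zero with a heavy constraint row
    pin = np.zeros(n)
    pin[0] = 1e6
    rows.append(pin)
    rhs.append(0.0)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return sol - sol.mean()


def min_spanning_tree_bruteforce(node_ids, weighted_edges):
    """Minimum spanning tree by enumerating every spanning edge subset.

    ``weighted_edges``: list of (a, b, weight).  Returns the frozenset of
    (a, b) pairs of one minimum tree (total weight compared exactly).
    """
    n = len(node_ids)
    best, best_w = None, np.inf
    for subset in combinations(weighted_edges, n - 1):
        parent = {x: x for x in node_ids}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for a, b, _ in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if not ok:
            continue
        w = sum(e[2] for e in subset)
        if w < best_w - 1e-12:
            best_w = w
            best = frozenset((a, b) for a, b, _ in subset)
    return best, best_w


def gaussian_crossing(mu1, sd1, mu2, sd2):
    """Intersection abscissa of two Gaussian densities between their means."""
    if np.isclose(sd1, sd2):
        return 0.5 * (mu1 + mu2)
    a = 1.0 / sd2**2 - 1.0 / sd1**2
    b = 2.0 * (mu1 / sd1**2 - mu2 / sd2**2)
    c = mu2**2 / sd2**2 - mu1**2 / sd1**2 + 2.0 * np.log(sd2 / sd1)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    lo, hi = min(mu1, mu2), max(mu1, mu2)
    inside = [r for r in roots if lo - 1e-9 <= r <= hi + 1e-9]
    return inside[0] if inside else roots[np.argmin(np.abs(roots - 0.5 * (mu1 + mu2)))]
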