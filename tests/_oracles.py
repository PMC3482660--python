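"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the cell-cycle oracle
simulates a discrete population of cells instead of using the closed form,
and the enrichment oracle enumerates the hypergeometric tail with exact
integer arithmetic instead of calling scipy.
"""

from __future__ import annotations

from math import comb

import numpy as np


def population_average_factor(
    amplitude: float,
    f_peak: float,
    f_ramp: float = 0.0,
    nstep: int = 1,
    n_cells: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo estimate of Ctot / Cbas from a discrete cell population.

    Cells are assigned uniformly to compartments: peak (fraction f_peak,
    expression A in basal units), nstep ramp stages (each f_ramp/nstep,
    stage k expressing A*k/nstep for k = 0..nstep-1), and basal (the rest,
    expression 1).  The mean expression over cells estimates the factor
    linking the asynchronous average to the basal level.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    fractions = [f_peak] + [f_ramp / nstep] * nstep
    levels = [amplitude] + [amplitude * k / nstep for k in range(nstep)]
    fractions.append(1.0 - f_peak - f_ramp)
    levels.append(1.0)
    edges = np.concatenate([[0.0], np.cumsum(fractions)])
    # stratified cell positions along the cycle: one cell per 1/n slice,
    # jittered within the slice, so compartment occupancies match their
    # fractions to O(1/n) while each cell is still an individual draw
    u = (np.arange(n_cells) + rng.random(n_cells)) / n_cells
    compartment = np.searchsorted(edges, u, side="right") - 1
    compartment = np.clip(compartment, 0, len(levels) - 1)
    return float(np.asarray(levels)[compartment].mean())


def hypergeom_upper_tail(k: int, n_universe: int, k_total: int, n_draw: int) -> float:
    """Exact P(X >= k) for a hypergeometric draw, by enumeration."""
    denom = comb(n_universe, n_draw)
    num = 0
    for i in range(k, min(k_total, n_draw) + 1):
        num += comb(k_total, i) * comb(n_universe - k_total, n_draw - i)
    return num / denom


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """Exact P(X >= k) for a binomial, by brute-force summation."""
    return float(sum(comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)))


def bh_stepup(pvalues) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up for cross-checking."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q
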