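"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: segment decomposition
via the Ruzzo-Tompa all-maximal-scoring-subsequences algorithm, exact test
p-values via direct enumeration, and Dirichlet entropy expectations via
numeric integration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, stats


def ruzzo_tompa_segments(scores: list[float]) -> list[tuple[int, int]]:
    """All maximal scoring subsequences (half-open index intervals)."""
    done: list[list[float | int]] = []  # stack of [Lcum, Rcum, start, end]
    cum = 0.0
    for i, s in enumerate(scores):
        left = cum
        cum += s
        if s <= 0:
            continue
        new = [left, cum, i, i + 1]
        while True:
            j = None
            for idx in range(len(done) - 1, -1, -1):
                if done[idx][0] < new[0]:
                    j = idx
                    break
            if j is None or done[j][1] >= new[1]:
                done.append(new)
                break
            new = [done[j][0], new[1], done[j][2], new[3]]
            done = done[:j]
    return [(int(seg[2]), int(seg[3])) for seg in done]


def maximal_segments_at_density(
    sites: list[tuple[int, float]], d: float
) -> list[tuple[int, int]]:
    """Maximal scoring segments of the per-bp score (v - d at sites, -d in gaps),
    reported as inclusive site-position intervals."""
    pos = [p for p, _ in sites]
    p0 = pos[0]
    length = pos[-1] - p0 + 1
    scores = [-d] * length
    for p, v in sites:
        scores[p - p0] = v - d
    segs = ruzzo_tompa_segments(scores)
    return sorted((s + p0, e - 1 + p0) for s, e in segs)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        px = stats.hypergeom.pmf(x, n, row1, col1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


def mann_whitney_exact_enumeration(x, y) -> float:
    """Two-sided exact Mann-Whitney p with mid-rank ties, by enumeration."""
    x = list(x)
    y = list(y)
    m, n = len(x), len(y)
    ranks = stats.rankdata(x + y)
    mu = m * n / 2.0
    u_obs = float(ranks[:m].sum() - m * (m + 1) / 2)
    extreme = total = 0
    for combo in itertools.combinations(range(m + n), m):
        u = float(ranks[list(combo)].sum() - m * (m + 1) / 2)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def dirichlet_entropy_expectation_k2(alpha: float = 1.0) -> float:
    """E[-p log2 p - (1-p) log2 (1-p)] for p ~ Beta(alpha, alpha), by quadrature."""

    def integrand(p: float) -> float:
        h = 0.0
        for q in (p, 1 - p):
            if q > 0:
                h -= q * math.log2(q)
        return h * stats.beta.pdf(p, alpha, alpha)

    val, _ = integrate.quad(integrand, 0, 1)
    return val


def paired_t_p(x, y) -> float:
    """Closed-form paired t-test p (reference route via scipy distribution)."""
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return float(2 * stats.t.sf(abs(t), n - 1))
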