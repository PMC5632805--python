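"""Nonparametric group comparison for per-day area distributions.

Treatments are compared at each time-point with the Kruskal–Wallis one-way
analysis of variance by ranks (tie-corrected H, chi-square p-value), and,
when warranted, pairwise with the Conover–Iman post-hoc test on rank sums
using the pooled rank variance and the t-distribution on N - k degrees of
freedom.  Pairwise outcomes are summarised as a compact letter display:
groups sharing a letter are not significantly different at the chosen
alpha.  Pearson correlation (with its regression-F significance) is
provided for validating image-derived areas against destructive
fresh-weight measurements.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "KWResult",
    "PosthocResult",
    "kruskal_wallis",
    "conover_posthoc",
    "letter_display",
    "pearson_validation",
]


@dataclass
class KWResult:
    """Tie-corrected Kruskal–Wallis H with chi-square df and p-value."""

    h: float
    df: int
    p_value: float


@dataclass
class PosthocResult:
    """Symmetric pairwise p-value matrix plus metadata for letter assignment."""

    group_labels: list[str]
    p_matrix: np.ndarray
    alpha: float
    medians: np.ndarray
    letters: dict[str, str] = field(default_factory=dict)


def _ranked(groups: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    out, i = [], 0
    for g in groups:
        out.append(ranks[i:i + len(g)])
        i += len(g)
    return ranks, out


def kruskal_wallis(groups: list) -> KWResult:
    """Kruskal–Wallis one-way analysis of variance by ranks.

    H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, divided by the standard
    tie-correction factor 1 - sum(t^3 - t)/(N^3 - N); the p-value comes from
    the chi-square distribution with k - 1 degrees of freedom.  Data that
    are entirely tied across all groups give H = 0, p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} has no observations")
    n = np.array([g.size for g in groups])
    N = int(n.sum())
    ranks, group_ranks = _ranked(groups)
    rbar = np.array([r.mean() for r in group_ranks])
    h = 12.0 / (N * (N + 1)) * float(np.sum(n * (rbar - (N + 1) / 2.0) ** 2))
    _, counts = np.unique(np.concatenate(groups), return_counts=True)
    tie = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
    if tie == 0.0:  # every observation identical
        return KWResult(h=0.0, df=len(groups) - 1, p_value=1.0)
    h /= tie
    df = len(groups) - 1
    return KWResult(h=h, df=df, p_value=float(sps.chi2.sf(h, df)))


def conover_posthoc(groups: list, kw: KWResult | None = None,
                    labels: list[str] | None = None, alpha: float = 0.05,
                    adjust: str | None = None) -> PosthocResult:
    """Conover–Iman pairwise comparisons after a Kruskal–Wallis test.

    For groups i, j the statistic is

        t_ij = (Rbar_i - Rbar_j) /
               sqrt(S^2 * (N - 1 - H)/(N - k) * (1/n_i + 1/n_j))

    with the pooled rank variance S^2 = (sum R^2 - N (N+1)^2 / 4)/(N - 1)
    and two-sided p-values from Student's t on N - k degrees of freedom.
    P-values are unadjusted by default; ``adjust='holm'`` applies the Holm
    step-down correction.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    if kw is None:
        kw = kruskal_wallis(groups)
    n = np.array([g.size for g in groups])
    N = int(n.sum())
    if N <= k:
        raise ValueError("need more observations than groups")
    ranks, group_ranks = _ranked(groups)
    rbar = np.array([r.mean() for r in group_ranks])
    s2 = (float(np.sum(ranks**2)) - N * (N + 1) ** 2 / 4.0) / (N - 1)
    factor = max((N - 1 - kw.h) / (N - k), 1e-12)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            denom = np.sqrt(s2 * factor * (1.0 / n[i] + 1.0 / n[j]))
            if denom == 0:  # all observations identical
                pij = 1.0
            else:
                t = (rbar[i] - rbar[j]) / denom
                pij = 2.0 * float(sps.t.sf(abs(t), N - k))
            p[i, j] = p[j, i] = min(pij, 1.0)
    if adjust == "holm":
        iu = np.triu_indices(k, 1)
        adj = _holm(p[iu])
        p[iu] = adj
        p.T[iu] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    medians = np.array([float(np.median(g)) for g in groups])
    res = PosthocResult(group_labels=list(labels), p_matrix=p, alpha=alpha,
                        medians=medians)
    res.letters = letter_display(res)
    return res


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def letter_display(posthoc: PosthocResult) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Starting from a single letter shared by all groups, each significant
    pair splits every letter column containing both members into two
    columns (one without each member); columns that become subsets of
    another are absorbed.  Letters are assigned in descending-median group
    order, so the group with the largest median always carries 'a'.  Two
    groups share a letter iff their pairwise p-value is >= alpha.
    """
    k = len(posthoc.group_labels)
    # process groups in descending median order so letters read a, b, ...
    order = sorted(range(k), key=lambda i: -posthoc.medians[i])
    columns: list[set[int]] = [set(range(k))]
    sig = [(i, j) for a, i in enumerate(order) for j in order[a + 1:]
           if posthoc.p_matrix[i, j] < posthoc.alpha]
    for i, j in sig:
        new_cols = []
        for col in columns:
            if i in col and j in col:
                new_cols.extend([col - {i}, col - {j}])
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another
        columns = [c for a, c in enumerate(new_cols)
                   if c and not any(c < d or (c == d and a > b)
                                    for b, d in enumerate(new_cols))]
    # order columns by the best-ranked (largest-median) member they contain
    rank_of = {g: r for r, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank_of[g] for g in c))
    alphabet = string.ascii_lowercase
    letters = {lab: "" for lab in posthoc.group_labels}
    for ci, col in enumerate(columns):
        for g in sorted(col, key=lambda g: rank_of[g]):
            letters[posthoc.group_labels[g]] += alphabet[ci % 26]
    return letters


def pearson_validation(areas, fresh_weights) -> tuple[float, float]:
    """Pearson correlation between image areas and fresh weights, with the
    regression-F significance (identical to the correlation t-test)."""
    x = np.asarray(areas, dtype=float)
    y = np.asarray(fresh_weights, dtype=float)
    if x.size != y.size:
        raise ValueError("areas and fresh weights must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
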