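"""Rank-based statistics implemented from first principles.

Small occupational studies (here n = 7 workers, 4 replicate diffusion
cells) do not support distributional assumptions, so every comparison is
rank-based: Spearman's rho with an exact permutation p-value at small n,
the tie-corrected Kruskal-Wallis H, and Dunn's z for pairwise multiple
comparisons.  Midranks, test statistics and the permutation enumeration
are computed here directly; scipy supplies only the reference
distributions (t, chi-square, normal) for p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _dist

__all__ = [
    "RankedSample",
    "TestResult",
    "midranks",
    "spearman",
    "kruskal_wallis",
    "dunns_test",
]

#: Largest n for which the Spearman permutation null is enumerated exactly
#: (9! = 362 880 permutations; the study size n = 7 needs only 5 040).
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class RankedSample:
    """Values with their midranks and the sizes of tied groups."""

    values: np.ndarray
    ranks: np.ndarray
    tie_groups: tuple[int, ...]

    @property
    def tie_correction_sum(self) -> float:
        """Sum of t^3 - t over tied groups (the usual tie penalty)."""
        return float(sum(t**3 - t for t in self.tie_groups))


@dataclass(frozen=True)
class TestResult:
    """Statistic, p-value and (for post-hoc tests) per-pair p-values."""

    statistic: float
    p_value: float
    method: str
    comparisons: dict | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def midranks(x) -> RankedSample:
    """Assign average ranks (midranks) with tie handling.

    Tied observations share the mean of the ranks they occupy, so the rank
    sum is always n(n+1)/2.
    """
    values = np.asarray(x, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("need a non-empty 1-d sample")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    ties: list[int] = []
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        # positions i..j (0-based) share midrank of ranks i+1..j+1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        if j > i:
            ties.append(j - i + 1)
        i = j + 1
    return RankedSample(values=values, ranks=ranks, tie_groups=tuple(ties))


def _rank_correlation(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two rank vectors."""
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0.0:
        raise ValueError("constant sample: rank correlation undefined")
    return float(dx @ dy) / denom


def spearman(x, y, exact_max_n: int = EXACT_PERMUTATION_MAX_N) -> TestResult:
    """Spearman rank correlation with two-sided p-value.

    rho is the Pearson correlation of midranks (equal to the classical
    1 - 6 sum(d^2) / (n(n^2-1)) when there are no ties).  For
    n <= ``exact_max_n`` the p-value is exact: every permutation of one
    rank vector is enumerated and the fraction with |rho| at least the
    observed |rho| is reported.  For larger n the usual t approximation
    with n - 2 degrees of freedom is used.
    """
    rx = midranks(x).ranks
    ry = midranks(y).ranks
    if rx.size != ry.size:
        raise ValueError("x and y must have equal length")
    n = rx.size
    if n < 3:
        raise ValueError("need n >= 3")
    rho = _rank_correlation(rx, ry)

    if n <= exact_max_n:
        # Exact permutation null: correlation is linear in the permuted
        # ranks, so precompute centred vectors once.
        dx = rx - rx.mean()
        dy = ry - ry.mean()
        denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
        target = abs(rho) - 1e-12
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            r = float(dx @ dy[list(perm)]) / denom
            total += 1
            if abs(r) >= target:
                hits += 1
        return TestResult(
            statistic=rho,
            p_value=hits / total,
            method="spearman-exact-permutation",
            extra={"n": n, "permutations": total, "as_extreme": hits},
        )

    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * float(_dist.t.sf(abs(t), df=n - 2))
    return TestResult(
        statistic=rho,
        p_value=min(1.0, p),
        method="spearman-t-approximation",
        extra={"n": n, "t": t},
    )


def _pooled_ranks(groups: list[np.ndarray]):
    pooled = np.concatenate(groups)
    ranked = midranks(pooled)
    sizes = [g.size for g in groups]
    split = np.split(ranked.ranks, np.cumsum(sizes)[:-1])
    return ranked, split


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    H = 12 / (N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t) / (N^3 - N).  All observations identical
    yields H = 0, p = 1 (not an error).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    ranked, split = _pooled_ranks(arrays)
    n_total = ranked.values.size
    if n_total < 3:
        raise ValueError("need total n >= 3")
    grand = (n_total + 1) / 2.0
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        r.size * (r.mean() - grand) ** 2 for r in split
    )
    tie = 1.0 - ranked.tie_correction_sum / (n_total**3 - n_total)
    if tie == 0.0:  # every observation identical
        return TestResult(0.0, 1.0, "kruskal-wallis", extra={"df": len(arrays) - 1})
    h /= tie
    df = len(arrays) - 1
    p = float(_dist.chi2.sf(h, df=df))
    return TestResult(h, p, "kruskal-wallis", extra={"df": df, "tie_correction": tie})


def dunns_test(groups, labels=None, adjust: str = "bonferroni", pairs=None) -> TestResult:
    """Dunn's pairwise multiple-comparison test after Kruskal-Wallis.

    For every tested pair (i, j) the standardised mean-rank difference is

        z = (Rbar_i - Rbar_j) /
            sqrt[(N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j)]

    with a two-sided normal p-value, adjusted for multiplicity by
    ``adjust`` in {"none", "bonferroni", "holm"} over the *tested* pairs.
    ``pairs`` restricts testing to a subset of label pairs (the usual
    planned-contrast usage); by default all pairs are tested.  The
    omnibus Kruskal-Wallis statistic is returned as
    ``statistic``/``p_value``; pairwise results live in ``comparisons``.
    """
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if labels is None:
        labels = list(range(len(arrays)))
    if len(labels) != len(arrays):
        raise ValueError("labels length mismatch")
    omnibus = kruskal_wallis(arrays)
    ranked, split = _pooled_ranks(arrays)
    n_total = ranked.values.size
    var_base = n_total * (n_total + 1) / 12.0 - ranked.tie_correction_sum / (
        12.0 * (n_total - 1)
    )
    index_of = {lab: k for k, lab in enumerate(labels)}
    if pairs is None:
        tested = list(itertools.combinations(range(len(arrays)), 2))
    else:
        tested = []
        for a, b in pairs:
            if a not in index_of or b not in index_of:
                raise ValueError(f"unknown labels in pair ({a!r}, {b!r})")
            tested.append((index_of[a], index_of[b]))
    raw: dict[tuple, dict] = {}
    for i, j in tested:
        se = math.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        if se == 0.0:
            z, p = 0.0, 1.0
        else:
            z = (split[i].mean() - split[j].mean()) / se
            p = 2.0 * float(_dist.norm.sf(abs(z)))
        raw[(labels[i], labels[j])] = {"z": z, "p_raw": min(1.0, p)}

    m = len(tested)
    if adjust == "bonferroni":
        for d in raw.values():
            d["p_adjusted"] = min(1.0, d["p_raw"] * m)
    elif adjust == "holm":
        ordered = sorted(raw.items(), key=lambda kv: kv[1]["p_raw"])
        running = 0.0
        for k, (key, d) in enumerate(ordered):
            running = max(running, min(1.0, (m - k) * d["p_raw"]))
            d["p_adjusted"] = running
    else:
        for d in raw.values():
            d["p_adjusted"] = d["p_raw"]

    return TestResult(
        statistic=omnibus.statistic,
        p_value=omnibus.p_value,
        method=f"dunn-{adjust}",
        comparisons=raw,
        extra=omnibus.extra,
    )
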