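"""Alpha diversity indices and univariate group comparisons.

Indices follow the conventions of the PAST software: dominance is
D = sum(p_i^2) (the complement of the Simpson index 1-D), evenness is
Buzas-Gibson e^H / S with H the Shannon entropy in nats, and Chao1 uses
the bias-corrected form S + F1(F1-1) / (2(F2+1)) so it is defined when
there are no doubletons. Rarefaction interpolation uses the exact
hypergeometric expectation of richness at a sub-depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


@dataclass(frozen=True)
class AlphaDiversityRecord:
    sobs: int
    chao1: float
    dominance: float
    evenness: float
    f1: int
    f2: int


@dataclass
class GroupTestResult:
    """Omnibus statistic plus Bonferroni-adjusted pairwise comparisons."""

    statistic: float
    df: tuple[int, ...]
    p_value: float
    pairwise: list[tuple[str, str, float, float]]  # (group_i, group_j, stat, adj p)
    degenerate: bool = False


def alpha_diversity(counts) -> AlphaDiversityRecord:
    """Observed richness, Chao1, dominance and evenness of one sample."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero sample has no diversity")
    sobs = int(x.size)
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    chao1 = sobs + f1 * (f1 - 1) / (2 * (f2 + 1))
    p = x / x.sum()
    dominance = float(np.sum(p**2))
    shannon = float(-np.sum(p * np.log(p)))
    evenness = float(np.exp(shannon) / sobs)
    return AlphaDiversityRecord(sobs, float(chao1), dominance, evenness, f1, f2)


def alpha_diversity_table(table) -> pd.DataFrame:
    """Per-sample index table for a :class:`~phylosym.community.CountTable`."""
    records = {
        sid: dataclasses_asdict(alpha_diversity(row.to_numpy()))
        for sid, row in table.data.iterrows()
    }
    return pd.DataFrame.from_dict(records, orient="index")


def dataclasses_asdict(rec: AlphaDiversityRecord) -> dict:
    return {
        "sobs": rec.sobs, "chao1": rec.chao1, "dominance": rec.dominance,
        "evenness": rec.evenness, "f1": rec.f1, "f2": rec.f2,
    }


def rarefaction_expectation(counts, depths) -> np.ndarray:
    """Expected richness E[S_m] at each sub-depth m under subsampling
    without replacement.

    E[S_m] = S_obs - sum_i C(N - N_i, m) / C(N, m), evaluated with
    log-binomial coefficients for numerical stability. Interpolation only:
    m may not exceed the sample total N.
    """
    x = np.asarray(counts, dtype=np.int64)
    x = x[x > 0]
    n_total = int(x.sum())
    m = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (m < 1).any() or (m > n_total).any():
        raise ValueError(f"sub-depths must lie in [1, {n_total}]")

    def log_binom(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.empty(m.shape, dtype=float)
    for j, mj in enumerate(m):
        valid = (n_total - x) >= mj  # taxa that can be entirely missed
        terms = np.exp(log_binom(n_total - x[valid], mj) - log_binom(n_total, mj))
        out[j] = x.size - terms.sum()
    return out


def _bonferroni(p: float, n_comparisons: int) -> float:
    return min(1.0, p * n_comparisons)


def kruskal_dunn(groups: dict[str, np.ndarray]) -> GroupTestResult:
    """Kruskal-Wallis H with tie correction, then Dunn's z post hoc.

    Dunn's pairwise z uses the pooled rank variance with the standard tie
    correction; pairwise p-values are Bonferroni-adjusted over the
    a(a-1)/2 comparisons.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    if len(values) < 2 or any(v.size == 0 for v in values):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(values)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return GroupTestResult(0.0, (len(values) - 1,), 1.0,
                               [(a, b, 0.0, 1.0) for a, b in combinations(names, 2)],
                               degenerate=True)
    h, p = stats.kruskal(*values)

    ranks = stats.rankdata(pooled)
    sizes = [v.size for v in values]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = {
        g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    pairwise = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        se = np.sqrt(
            (n * (n + 1) / 12 - tie_term / (12 * (n - 1)))
            * (1 / sizes[i] + 1 / sizes[j])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_pair = 2 * stats.norm.sf(abs(z))
        pairwise.append((a, b, float(z), _bonferroni(p_pair, n_pairs)))
    return GroupTestResult(float(h), (len(values) - 1,), float(p), pairwise)


def anova_bonferroni(groups: dict[str, np.ndarray]) -> GroupTestResult:
    """Classical one-way ANOVA with Bonferroni-adjusted pairwise t-tests."""
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    if len(values) < 2:
        raise ValueError("need >= 2 groups")
    n = sum(v.size for v in values)
    a = len(values)
    if n - a < 1:
        raise ValueError("no residual degrees of freedom")
    grand = np.concatenate(values).mean()
    ssw = sum(((v - v.mean()) ** 2).sum() for v in values)
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in values)
    degenerate = False
    if ssw == 0:
        if ssb == 0:
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
        degenerate = True
    else:
        f = (ssb / (a - 1)) / (ssw / (n - a))
        p = float(stats.f.sf(f, a - 1, n - a))
    n_pairs = a * (a - 1) // 2
    pairwise = []
    for (i, x), (j, y) in combinations(enumerate(values), 2):
        if x.size > 1 and y.size > 1 and (x.std() > 0 or y.std() > 0):
            t, p_pair = stats.ttest_ind(x, y)
        else:
            t, p_pair = (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
        pairwise.append((names[i], names[j], float(t), _bonferroni(float(p_pair), n_pairs)))
    return GroupTestResult(float(f), (a - 1, n - a), float(p), pairwise,
                           degenerate=degenerate)


def write_alpha_report(table, info, path) -> None:
    """TSV report: per-sample indices joined with sample metadata."""
    alpha = alpha_diversity_table(table)
    out = info.data.join(alpha, how="inner")
    out.index.name = "sample"
    out.to_csv(path, sep="\t")
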