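"""Bray-Curtis dissimilarity and multivariate community statistics.

ANOSIM, multi-term PERMANOVA with sequential (Type-I) sums of squares in
the vegan ``adonis`` convention, non-metric MDS, shared-OTU (Venn) set
analysis and Dufrene-Legendre indicator values. All permutation tests use
the (1 + exceedances) / (1 + permutations) p-value estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


def _align_groups(labels, groups) -> np.ndarray:
    """Accept either a mapping label -> group or a sequence aligned with
    ``labels``."""
    if isinstance(groups, (dict, pd.Series)):
        return np.asarray([groups[l] for l in labels])
    g = np.asarray(list(groups))
    if g.size != len(labels):
        raise ValueError(f"{g.size} group labels for {len(labels)} samples")
    return g


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between all sample pairs.

    d_ij = sum|x_i - x_j| / sum(x_i + x_j); rows may be counts or averaged
    (fractional) counts.
    """
    x = table.data.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    zero = x.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    pairwise: list[tuple[str, str, float, float]] = field(default_factory=list)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    # ranks/within are condensed (pair-wise) vectors; M = n(n-1)/2
    m = ranks.size
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return (r_between - r_within) / (m / 2)


def anosim(dm: DistanceMatrix, groups, n_permutations: int = 999,
           seed: int | None = None, pairwise: bool = True) -> AnosimResult:
    """Clarke's analysis of similarities on distance ranks.

    R = (mean between-group rank - mean within-group rank) / (M/2); the
    global p-value comes from label permutations, and each group pair gets
    its own ANOSIM with Bonferroni adjustment over the pairs.
    """
    groups = _align_groups(dm.labels, groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    rng = np.random.default_rng(seed)
    ranks = rankdata(dm.condensed())
    i_idx, j_idx = np.triu_indices(dm.n, k=1)

    def observed_r(g):
        within = g[i_idx] == g[j_idx]
        return _anosim_r(ranks, within)

    r_obs = observed_r(groups)
    exceed = 0
    g = groups.copy()
    for _ in range(n_permutations):
        rng.shuffle(g)
        if observed_r(g) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)

    pw = []
    if pairwise:
        ok = {l for l, c in zip(labels, counts) if c >= 2}
        small = set(labels) - ok
        if small:
            warnings.warn(f"groups of size 1 excluded from pairwise ANOSIM: {sorted(small)}",
                          stacklevel=2)
        pairs = list(combinations(sorted(ok), 2))
        for a, b in pairs:
            keep = [l for l, gr in zip(dm.labels, groups) if gr in (a, b)]
            sub = dm.submatrix(keep)
            sub_groups = [gr for gr in groups if gr in (a, b)]
            res = anosim(sub, sub_groups, n_permutations, seed=rng.integers(2**31),
                         pairwise=False)
            pw.append((a, b, res.R, min(1.0, res.p_value * len(pairs))))
    return AnosimResult(float(r_obs), float(p), n_permutations, pw)


# ---------------------------------------------------------------------------
# PERMANOVA (adonis)


@dataclass
class PermanovaResult:
    """Sequential-SS PERMANOVA table: one row per model term plus
    Residuals and Total."""

    table: pd.DataFrame  # index: term; columns: df, SumOfSqs, F_model, R2, p

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def _design_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Expand one model term (factor, covariate, or ':' interaction) into
    design columns. Factors are dummy-coded (first level dropped);
    numeric columns enter as a single centered covariate."""
    parts = term.split(":")
    mats = []
    for part in parts:
        col = design[part]
        if pd.api.types.is_numeric_dtype(col):
            mats.append(col.to_numpy(dtype=float).reshape(-1, 1) - col.mean())
        else:
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            mats.append(dummies)
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(len(out), -1)
    return out


def permanova(dm: DistanceMatrix, design: pd.DataFrame, terms: list[str],
              n_permutations: int = 999, seed: int | None = None) -> PermanovaResult:
    """Multi-term PERMANOVA on a distance matrix (vegan ``adonis``).

    The Gower-centered inner-product matrix G = -1/2 C d^2 C is partitioned
    by sequential (Type-I) projections of the model terms in the order
    given; pseudo-F per term is (SS_term/df_term)/(SS_res/df_res) and
    p-values come from permuting sample labels of the distance matrix.
    Interaction terms are written ``a:b``; numeric design columns enter as
    single-df covariates, string columns as factors.
    """
    design = design.loc[dm.labels]
    n = dm.n
    d2 = dm.d**2
    c = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * c @ d2 @ c

    ones = np.ones((n, 1))
    cum = ones
    hats, dfs, kept_terms = [], [], []
    prev_rank = 1
    h_prev = np.ones((n, n)) / n
    for term in terms:
        cum = np.hstack([cum, _design_columns(design, term)])
        rank = np.linalg.matrix_rank(cum)
        df = rank - prev_rank
        if df == 0:
            warnings.warn(f"term {term!r} is rank-deficient; absorbed", stacklevel=2)
            hats.append(h_prev)
        else:
            h = cum @ np.linalg.pinv(cum)
            hats.append(h)
            h_prev = h
        dfs.append(df)
        kept_terms.append(term)
        prev_rank = rank
    h_full = hats[-1]
    df_res = n - prev_rank
    ss_total = np.trace(g)
    ss_res = ss_total - np.trace(h_full @ g)

    def term_stats(gmat):
        # tr(HG) = sum(H o G) since both are symmetric
        traces = [(h * gmat).sum() for h in hats]
        ss = np.diff([0.0] + traces)
        ssr = np.trace(gmat) - traces[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / np.maximum(dfs, 1)) / (ssr / df_res) if df_res > 0 else \
                np.full(len(ss), np.inf)
        return ss, f

    ss_obs, f_obs = term_stats(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        _, f_perm = term_stats(g[np.ix_(perm, perm)])
        exceed += f_perm >= f_obs
    p = (1 + exceed) / (1 + n_permutations)

    rows = {
        t: {"df": dfs[i], "SumOfSqs": ss_obs[i], "F_model": f_obs[i],
            "R2": ss_obs[i] / ss_total, "p": p[i]}
        for i, t in enumerate(kept_terms)
    }
    rows["Residuals"] = {"df": df_res, "SumOfSqs": ss_res, "F_model": np.nan,
                         "R2": ss_res / ss_total, "p": np.nan}
    rows["Total"] = {"df": n - 1, "SumOfSqs": ss_total, "F_model": np.nan,
                     "R2": 1.0, "p": np.nan}
    return PermanovaResult(pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# nMDS


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool
    seed: int | None


def nmds(dm: DistanceMatrix, k: int = 2, n_starts: int = 20,
         max_iter: int = 300, seed: int | None = None) -> NmdsResult:
    """Non-metric MDS by stress majorization with monotone regression.

    Returns the best of ``n_starts`` random starts; stress is Kruskal's
    stress-1.
    """
    from sklearn.manifold import smacof

    if dm.n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} dimensions")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords, stress, n_iter = smacof(
            dm.d, metric=False, n_components=k, n_init=n_starts,
            max_iter=max_iter, random_state=seed, normalized_stress=True,
            return_n_iter=True,
        )
    converged = n_iter < max_iter
    frame = pd.DataFrame(coords, index=dm.labels,
                         columns=[f"nmds{i + 1}" for i in range(k)])
    return NmdsResult(frame, float(stress), converged, seed)


# ---------------------------------------------------------------------------
# Shared-OTU (Venn) sets


def shared_otu_sets(table, groups: dict[str, list[str]]):
    """Venn-region OTU counts and shared-set abundance over 2-4 groups.

    An OTU is present in a group when its summed count over the group's
    samples is positive. Returns a DataFrame indexed by region (a ``+``
    joined sorted group combination) with the OTU count, the share of each
    group's reads carried by that region's OTUs, and the pooled share.
    """
    if not 2 <= len(groups) <= 4:
        raise ValueError("shared_otu_sets supports 2-4 groups")
    names = sorted(groups)
    presence = {}
    group_sums = {}
    for gname in names:
        sub = table.data.loc[groups[gname]]
        sums = sub.sum(axis=0)
        presence[gname] = sums > 0
        group_sums[gname] = sums
    membership = pd.DataFrame(presence)  # index otu, columns groups
    rows = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            in_combo = membership[list(combo)].all(axis=1)
            out_combo = ~membership[[g for g in names if g not in combo]].any(axis=1) \
                if len(combo) < len(names) else pd.Series(True, index=membership.index)
            region = in_combo & out_combo
            otus = membership.index[region]
            row = {"n_otus": int(region.sum())}
            pooled_num = pooled_den = 0.0
            for gname in names:
                total = group_sums[gname].sum()
                in_region = group_sums[gname].loc[otus].sum()
                row[f"share_{gname}"] = in_region / total if total else np.nan
                pooled_num += in_region
                pooled_den += total
            row["share_pooled"] = pooled_num / pooled_den if pooled_den else np.nan
            rows["+".join(combo)] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Indicator values


@dataclass
class IndicatorResult:
    """Dufrene-Legendre indicator values per taxon."""

    table: pd.DataFrame  # index taxon; columns best_group, A, B, indval, p
    n_permutations: int


def indicator_values(table, groups, n_permutations: int = 999,
                     seed: int | None = None) -> IndicatorResult:
    """IndVal = 100 * A * B maximized over groups, permutation-tested.

    A (specificity) is a taxon's mean abundance in the group divided by the
    summed group means; B (fidelity) is the fraction of the group's samples
    containing the taxon. Taxa absent everywhere are skipped.
    """
    x = table.data.to_numpy(dtype=float)
    g = _align_groups(table.sample_ids, groups)
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    present = x.sum(axis=0) > 0
    x = x[:, present]
    taxa = [t for t, keep in zip(table.otu_ids, present) if keep]

    def indvals(grouping):
        means = np.stack([x[grouping == lab].mean(axis=0) for lab in labels])
        occs = np.stack([(x[grouping == lab] > 0).mean(axis=0) for lab in labels])
        denom = means.sum(axis=0)
        a = np.divide(means, denom, out=np.zeros_like(means), where=denom > 0)
        return 100 * a * occs, a, occs

    iv_obs, a_obs, b_obs = indvals(g)
    best = iv_obs.argmax(axis=0)
    iv_max = iv_obs.max(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(taxa))
    gp = g.copy()
    for _ in range(n_permutations):
        rng.shuffle(gp)
        iv_perm, _, _ = indvals(gp)
        exceed += iv_perm.max(axis=0) >= iv_max
    p = (1 + exceed) / (1 + n_permutations)

    cols = np.arange(len(taxa))
    frame = pd.DataFrame({
        "best_group": labels[best],
        "A": a_obs[best, cols],
        "B": b_obs[best, cols],
        "indval": iv_max,
        "p": p,
    }, index=taxa)
    return IndicatorResult(frame.sort_values("indval", ascending=False), n_permutations)


# ---------------------------------------------------------------------------
# Report writers


def write_permanova_report(result: PermanovaResult, path) -> None:
    out = result.table.copy()
    out.index.name = "term"
    out.to_csv(path, sep="\t")


def write_anosim_report(result: AnosimResult, path) -> None:
    rows = [{"comparison": "global", "R": result.R, "p": result.p_value}]
    rows += [{"comparison": f"{a} vs {b}", "R": r, "p": p}
             for a, b, r, p in result.pairwise]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_indicator_report(result: IndicatorResult, path) -> None:
    out = result.table.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")
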