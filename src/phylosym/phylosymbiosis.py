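"""Host-phylogeny vs. microbiota-dendrogram congruence testing.

The phylosymbiosis question is whether the hierarchical clustering of host
species by their microbial community composition mirrors the hosts'
phylogeny. The pipeline here: average community profiles per host species,
Bray-Curtis dissimilarities among species, a UPGMA dendrogram, and two
rooted-tree congruence metrics against the host tree —

* Robinson-Foulds (RF): the number of nontrivial clades present in exactly
  one of the two trees, normalized by its maximum 2(n-2) for rooted binary
  trees;
* Matching Cluster (MC): the minimum-total-cost perfect matching between
  the two trees' (padded) clade sets, where pairing two clades costs the
  symmetric difference of their leaf memberships. MC refines RF by charging
  near-miss clades less than complete mismatches. It is normalized by the
  maximum MC attained over the null topology set.

Significance comes from a uniform null over labeled rooted binary
topologies: exhaustive enumeration for n <= 7 leaves ((2n-3)!! trees),
Monte-Carlo sampling otherwise. The p-value is the fraction of null
topologies at least as close to the host tree as the observed dendrogram
(ties count as successes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .betastats import DistanceMatrix, bray_curtis
from .community import CountTable, SampleInfo, merge_sections

Nested = object  # nested 2-tuples of leaf labels; a bare label is a leaf

MAX_EXHAUSTIVE_LEAVES = 7


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tree plumbing


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def leaf_set(tree: dendropy.Tree) -> frozenset:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def tree_clusters(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial clades (leaf subsets of size 2..n-1) of a rooted tree."""
    leaves = leaf_set(tree)
    n = len(leaves)
    if n < 3:
        raise TreeError("need >= 3 leaves for a nontrivial cluster set")
    clusters = set()
    for node in tree.preorder_internal_node_iter():
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(clade) <= n - 1:
            clusters.add(clade)
    return clusters


def _nested_clusters(t, acc: list) -> frozenset:
    if not isinstance(t, tuple):
        return frozenset([t])
    s = _nested_clusters(t[0], acc) | _nested_clusters(t[1], acc)
    acc.append(s)
    return s


def nested_to_clusters(t) -> set[frozenset]:
    """Cluster set of a nested-tuple topology (root clade excluded)."""
    acc: list[frozenset] = []
    full = _nested_clusters(t, acc)
    return {c for c in acc if c != full}


def nested_to_newick(t) -> str:
    def render(node):
        if not isinstance(node, tuple):
            return node
        return f"({render(node[0])},{render(node[1])})"

    return render(t) + ";"


def _insertions(t, label):
    """All ways to attach a new leaf to a nested topology (each edge plus a
    new root)."""
    yield (t, label)
    if isinstance(t, tuple):
        left, right = t
        for nl in _insertions(left, label):
            yield (nl, right)
        for nr in _insertions(right, label):
            yield (left, nr)


def enumerate_nested_topologies(labels) -> list:
    """All (2n-3)!! labeled rooted binary topologies as nested tuples."""
    labels = sorted(labels)
    n = len(labels)
    if not 3 <= n <= MAX_EXHAUSTIVE_LEAVES:
        raise TreeError(
            f"exhaustive enumeration supported for 3..{MAX_EXHAUSTIVE_LEAVES} "
            f"leaves, got {n}; use the Monte-Carlo null"
        )
    trees = [labels[0]]
    for label in labels[1:]:
        trees = [t2 for t in trees for t2 in _insertions(t, label)]
    return trees


def enumerate_topologies(labels) -> list[dendropy.Tree]:
    """All labeled rooted binary topologies on ``labels`` as trees."""
    return [tree_from_newick(nested_to_newick(t))
            for t in enumerate_nested_topologies(labels)]


def random_nested_topology(labels, rng: np.random.Generator):
    """Uniform draw over labeled rooted binary topologies.

    Sequential random leaf insertion is uniform because every k-leaf tree
    offers the same number (2k-1) of insertion positions.
    """
    labels = sorted(labels)
    t = labels[0]
    for label in labels[1:]:
        options = list(_insertions(t, label))
        t = options[rng.integers(len(options))]
    return t


# ---------------------------------------------------------------------------
# UPGMA


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration into an ultrametric rooted dendrogram.

    Merge heights are half the between-cluster average distance; distance
    ties are broken by the lexicographically smallest member label so the
    output is bit-reproducible.
    """
    if np.isnan(dm.d).any():
        raise TreeError("NaN distances")
    if dm.n < 2:
        raise TreeError("need >= 2 samples")
    # cluster state: id -> (member set, size, height, newick, min label)
    clusters = {
        i: (frozenset([l]), 1, 0.0, _quote(l), l) for i, l in enumerate(dm.labels)
    }
    dist = {
        frozenset((i, j)): dm.d[i, j]
        for i in range(dm.n) for j in range(i + 1, dm.n)
    }
    next_id = dm.n
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1],) + tuple(sorted(clusters[c][4] for c in kv[0])),
        )
        (pair, d) = best
        i, j = sorted(pair, key=lambda c: clusters[c][4])
        mi, si, hi, ni, li = clusters[i]
        mj, sj, hj, nj, lj = clusters[j]
        height = d / 2
        newick = f"({ni}:{height - hi:.10g},{nj}:{height - hj:.10g})"
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (si * dik + sj * djk) / (si + sj)
        del dist[pair]
        del clusters[i], clusters[j]
        clusters[next_id] = (mi | mj, si + sj, height, newick, min(li, lj))
        next_id += 1
    (_, _, _, newick, _) = next(iter(clusters.values()))
    return tree_from_newick(newick + ";")


def _quote(label: str) -> str:
    if any(c in label for c in " ():,;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Tree distances


def _check_leaf_sets(c1_leaves: frozenset, c2_leaves: frozenset) -> None:
    if c1_leaves != c2_leaves:
        only1 = sorted(c1_leaves - c2_leaves)
        only2 = sorted(c2_leaves - c1_leaves)
        raise TreeError(f"leaf sets differ: only in first {only1}, only in second {only2}")


def rf_distance(c1: set[frozenset], c2: set[frozenset]) -> int:
    """Rooted Robinson-Foulds: size of the symmetric difference of the two
    nontrivial cluster sets."""
    return len(c1 ^ c2)


def rf_norm(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """(RF, nRF) between two rooted trees; nRF = RF / (2(n-2))."""
    l1, l2 = leaf_set(t1), leaf_set(t2)
    _check_leaf_sets(l1, l2)
    rf = rf_distance(tree_clusters(t1), tree_clusters(t2))
    return rf, rf / (2 * (len(l1) - 2))


def mc_distance(c1: set[frozenset], c2: set[frozenset]) -> int:
    """Matching Cluster distance between two cluster sets.

    The smaller set is padded with empty clusters; pairing cost is the
    symmetric difference of leaf memberships; the minimum-cost perfect
    matching is found with the Hungarian assignment solver.
    """
    a = sorted(c1, key=sorted)
    b = sorted(c2, key=sorted)
    size = max(len(a), len(b))
    if size == 0:
        return 0
    a += [frozenset()] * (size - len(a))
    b += [frozenset()] * (size - len(b))
    cost = np.array([[len(x ^ y) for y in b] for x in a])
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


def mc_norm(t1: dendropy.Tree, t2: dendropy.Tree, null_max: int) -> tuple[int, float]:
    """(MC, nMC) with the supplied null-ensemble maximum as denominator."""
    _check_leaf_sets(leaf_set(t1), leaf_set(t2))
    if null_max <= 0:
        raise TreeError("null_max must be positive")
    mc = mc_distance(tree_clusters(t1), tree_clusters(t2))
    return mc, mc / null_max


# ---------------------------------------------------------------------------
# Congruence test


@dataclass
class CongruenceResult:
    """Congruence of one microbiota dendrogram with the host phylogeny."""

    nrf: float
    nmc: float
    p_rf: float
    p_mc: float
    rf: int
    mc: int
    n_leaves: int
    rf_max: int
    mc_max: int
    null_mode: str          # "exhaustive" or "monte-carlo"
    null_size: int
    seed: int | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "nrf", "p_rf", "nmc", "p_mc", "rf", "mc", "n_leaves",
            "rf_max", "mc_max", "null_mode", "null_size", "seed")}


def congruence_test(dendrogram: dendropy.Tree, host: dendropy.Tree,
                    null_mode: str = "auto", n_random: int = 1000,
                    seed: int | None = None) -> CongruenceResult:
    """Test a dendrogram's congruence with the host tree under a uniform
    topology null.

    For each topology in the null set the RF and MC distances to the host
    tree are computed; p is the fraction of null topologies with distance
    <= the observed one (ties included, so p > 0 always). The MC
    normalization constant is the maximum MC over the null set (and the
    observed value, so nMC <= 1 in Monte-Carlo mode too).
    """
    leaves = leaf_set(host)
    _check_leaf_sets(leaf_set(dendrogram), leaves)
    n = len(leaves)
    host_clusters = tree_clusters(host)
    obs_clusters = tree_clusters(dendrogram)
    rf_obs = rf_distance(obs_clusters, host_clusters)
    mc_obs = mc_distance(obs_clusters, host_clusters)

    if null_mode == "auto":
        null_mode = "exhaustive" if n <= MAX_EXHAUSTIVE_LEAVES else "monte-carlo"
    if null_mode == "exhaustive":
        null_sets = [nested_to_clusters(t) for t in enumerate_nested_topologies(leaves)]
    elif null_mode == "monte-carlo":
        if n_random < 100:
            warnings.warn(f"only {n_random} null topologies; p resolution is coarse",
                          stacklevel=2)
        rng = np.random.default_rng(seed)
        null_sets = [nested_to_clusters(random_nested_topology(leaves, rng))
                     for _ in range(n_random)]
    else:
        raise TreeError(f"unknown null_mode {null_mode!r}")

    rf_null = np.array([rf_distance(c, host_clusters) for c in null_sets])
    mc_null = np.array([mc_distance(c, host_clusters) for c in null_sets])
    mc_max = int(max(mc_null.max(), mc_obs))
    rf_max = 2 * (n - 2)
    return CongruenceResult(
        nrf=rf_obs / rf_max,
        nmc=mc_obs / mc_max,
        p_rf=float((rf_null <= rf_obs).mean()),
        p_mc=float((mc_null <= mc_obs).mean()),
        rf=rf_obs, mc=mc_obs, n_leaves=n, rf_max=rf_max, mc_max=mc_max,
        null_mode=null_mode, null_size=len(null_sets),
        seed=seed if null_mode == "monte-carlo" else None,
    )


# ---------------------------------------------------------------------------
# End-to-end report


@dataclass
class PhylosymbiosisReport:
    """Per-dataset congruence results (all sections combined + each section)."""

    results: dict[str, CongruenceResult]
    dendrograms: dict[str, str]  # dataset -> newick

    def summary(self) -> pd.DataFrame:
        rows = {
            name: {"nRF": r.nrf, "p_RF": r.p_rf, "nMC": r.nmc, "p_MC": r.p_mc}
            for name, r in self.results.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def write_tsv(self, path) -> None:
        out = self.summary()
        out.index.name = "dataset"
        out.to_csv(path, sep="\t")

    def write_json(self, path) -> None:
        payload = {
            name: {**r.as_dict(), "dendrogram": self.dendrograms[name]}
            for name, r in self.results.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def species_mean_profiles(table: CountTable, species) -> CountTable:
    """Mean community profile per host species (rows = species).

    ``species`` maps each row label of ``table`` to its host species.
    """
    labels = pd.Series([species[s] for s in table.sample_ids], index=table.data.index)
    means = table.data.groupby(labels, sort=True).mean()
    means.index.name = None
    return CountTable(means)


def species_dendrogram(table: CountTable, species) -> dendropy.Tree:
    """UPGMA dendrogram of species-level Bray-Curtis dissimilarities."""
    profiles = species_mean_profiles(table, species)
    dm = bray_curtis(profiles)
    if dm.n >= 2 and np.allclose(dm.condensed(), 0, atol=1e-12):
        warnings.warn("all species profiles identical; dendrogram is a tie-break "
                      "artifact", stacklevel=2)
    return upgma(dm)


def phylosymbiosis_report(table: CountTable, info: SampleInfo,
                          host: dendropy.Tree, null_mode: str = "auto",
                          n_random: int = 1000, seed: int | None = None,
                          ) -> PhylosymbiosisReport:
    """Congruence of species dendrograms with the host tree, for all
    sections combined and for each intestinal section separately.

    ``table`` should already be rarefied to a common depth. The combined
    dataset averages each individual's sections first, then averages
    individuals within species; each per-section dataset averages that
    section's samples within species.
    """
    from .community import SECTIONS

    info = info.for_samples(table.sample_ids)
    host_species = leaf_set(host)
    datasets: dict[str, tuple[CountTable, dict]] = {}

    merged = merge_sections(table, info)
    ind_species = (info.data.drop_duplicates("individual")
                   .set_index("individual")["species"].to_dict())
    datasets["all_sections"] = (merged, ind_species)
    sample_species = info.data["species"].to_dict()
    for section in SECTIONS:
        keep = [s for s in info.data.index[info.data["section"] == section]
                if s in table.data.index]
        if not keep:
            continue
        present = {sample_species[s] for s in keep}
        if present < host_species:
            warnings.warn(
                f"section {section!r} lacks species {sorted(host_species - present)}; "
                "skipped", stacklevel=2)
            continue
        datasets[section] = (CountTable(table.data.loc[keep]), sample_species)

    results, dendrograms = {}, {}
    for name, (sub_table, sub_species) in datasets.items():
        tree = species_dendrogram(sub_table, sub_species)
        results[name] = congruence_test(tree, host, null_mode=null_mode,
                                        n_random=n_random, seed=seed)
        dendrograms[name] = tree.as_string(schema="newick").strip()
    return PhylosymbiosisReport(results, dendrograms)
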