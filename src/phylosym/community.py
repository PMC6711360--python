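"""Count-table data model, I/O and pre-analysis transforms.

The working unit is an OTU count table (samples x OTUs) together with a
per-sample metadata table (host species, individual, intestinal section).
The transforms implemented here mirror the standard amplicon pre-analysis
chain: drop samples below a minimum library size, rarefy every retained
sample to a common depth by subsampling reads without replacement, average
the intestinal-section samples of each individual into one profile, and
aggregate OTU columns to genus or phylum through a taxonomy table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SECTIONS = ("anterior", "middle", "posterior")


class CommunityError(ValueError):
    """Raised for malformed tables or invalid transform preconditions."""


@dataclass
class CountTable:
    """OTU abundance matrix with sample and OTU labels.

    Counts are integers straight off a count file; they may become
    fractional after :func:`merge_sections` (section averaging), which
    downstream statistics accept.
    """

    data: pd.DataFrame  # index = sample IDs, columns = OTU IDs

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CommunityError(f"duplicate sample IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise CommunityError(f"duplicate OTU IDs: {dups}")
        if (self.data.to_numpy() < 0).any():
            raise CommunityError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class SampleInfo:
    """Per-sample factors: host species, individual, intestinal section."""

    data: pd.DataFrame  # index = sample IDs; columns species, individual, section

    REQUIRED = ("species", "individual", "section")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise CommunityError(f"metadata missing columns: {missing}")
        bad = set(self.data["section"]) - set(SECTIONS)
        if bad:
            raise CommunityError(
                f"unknown intestinal sections {sorted(bad)}; expected {SECTIONS}"
            )
        if self.data.index.has_duplicates:
            raise CommunityError("duplicate sample IDs in metadata")

    def for_samples(self, sample_ids) -> "SampleInfo":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise CommunityError(f"samples missing from metadata: {missing}")
        return SampleInfo(self.data.loc[list(sample_ids)])


# ---------------------------------------------------------------------------
# I/O


def read_count_table(path, dialect: str = "tsv") -> CountTable:
    """Read a counts TSV (first column sample ID, header of OTU IDs).

    ``dialect="mothur-shared"`` accepts the mothur ``.shared`` layout whose
    leading ``label`` and ``numOtus`` bookkeeping columns are dropped and
    whose ``Group`` column supplies the sample ID.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dup_cols = sorted({c for c in header if header.count(c) > 1})
    if dup_cols:
        raise CommunityError(f"{path}: duplicate column IDs in header: {dup_cols}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if dialect == "mothur-shared":
        cols = {c.lower(): c for c in df.columns[:3]}
        for required in ("label", "group", "numotus"):
            if required not in cols:
                raise CommunityError(
                    f"{path}: mothur-shared file must start with label/Group/numOtus "
                    f"columns, got {list(df.columns[:3])}"
                )
        df = df.set_index(df.columns[1]).drop(columns=[df.columns[0], df.columns[2]])
    elif dialect == "tsv":
        df = df.set_index(df.columns[0])
    else:
        raise CommunityError(f"unknown dialect {dialect!r}")
    df.index = df.index.astype(str)
    df.index.name = None
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise CommunityError(f"{path}: ragged or missing values at sample {row!r}")
    try:
        counts = df.astype("int64")
    except ValueError as exc:
        raise CommunityError(f"{path}: non-integer counts ({exc})") from exc
    return CountTable(counts)


def write_count_table(table: CountTable, path) -> None:
    out = table.data.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_sample_info(path) -> SampleInfo:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    df.index.name = None
    return SampleInfo(df)


def write_sample_info(info: SampleInfo, path) -> None:
    out = info.data.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    """Taxonomy TSV with columns ``otu``, ``genus``, ``phylum``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"otu", "genus", "phylum"} - set(df.columns)
    if missing:
        raise CommunityError(f"taxonomy missing columns: {sorted(missing)}")
    return df.set_index("otu")


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    out = taxonomy.copy()
    out.index.name = "otu"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Transforms


def filter_min_depth(table: CountTable, threshold: int) -> CountTable:
    """Retain exactly the samples whose library size is >= ``threshold``.

    The boundary is inclusive: a sample at exactly the rarefaction depth
    can still be rarefied (it keeps all of its reads).
    """
    if threshold <= 0:
        raise CommunityError("threshold must be positive")
    keep = table.sample_sums() >= threshold
    if not keep.any():
        warnings.warn("all samples fall below the depth threshold", stacklevel=2)
    return CountTable(table.data.loc[keep])


def rarefy(table: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    A single multivariate-hypergeometric draw per sample (mothur
    ``sub.sample`` semantics), reproducible under ``seed``.
    """
    sums = table.sample_sums()
    shallow = sums.index[sums < depth].tolist()
    if shallow:
        raise CommunityError(
            f"samples shallower than depth {depth}: {shallow}; "
            "apply filter_min_depth first"
        )
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy(dtype=np.int64)
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth, method="marginals")
    return CountTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns))


def merge_sections(table: CountTable, info: SampleInfo) -> CountTable:
    """Average each individual's section samples into a single profile.

    Individuals with fewer than three sections are averaged over whatever
    sections are present. The output row labels are individual IDs and the
    values may be fractional.
    """
    info = info.for_samples(table.sample_ids)
    individuals = info.data["individual"]
    merged = table.data.groupby(individuals, sort=False).mean()
    merged.index.name = None
    return CountTable(merged)


def aggregate_rank(table: CountTable, taxonomy: pd.DataFrame, rank: str) -> CountTable:
    """Sum OTU columns within a taxonomy label at ``rank`` (genus or phylum)."""
    if rank not in ("genus", "phylum"):
        raise CommunityError(f"rank must be 'genus' or 'phylum', got {rank!r}")
    missing = [o for o in table.otu_ids if o not in taxonomy.index]
    if missing:
        raise CommunityError(f"OTUs missing from taxonomy: {missing}")
    labels = taxonomy.loc[table.otu_ids, rank]
    agg = table.data.T.groupby(labels.to_numpy(), sort=True).sum().T
    agg.columns.name = None
    return CountTable(agg)


def to_relative(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances (rows sum to 1).

    All-zero samples are dropped with a warning rather than propagating NaN.
    """
    sums = table.sample_sums()
    empty = sums.index[sums == 0].tolist()
    if empty:
        warnings.warn(f"empty samples dropped from relative abundances: {empty}",
                      stacklevel=2)
    data = table.data.loc[sums > 0]
    return data.div(data.sum(axis=1), axis=0)
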