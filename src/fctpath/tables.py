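"""Tabular containers and readers for the pipeline.

All matrices are normalized to samples-in-rows; joins across tables are by
``sample_id`` and fail loudly on mismatch.  TSV (tab-separated, UTF-8, header
row) is the interchange format throughout; trees are newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio

VISITS = ("V0", "V1", "V3", "V6")
ARMS = ("control", "test")
STRATA = ("EE", "LE")

#: Enrollment-age cutoff (days) separating the early-enrollment (EE) from the
#: late-enrollment (LE) stratum.
STRATUM_CUTOFF_DAYS = 90


class TableError(ValueError):
    """Raised on malformed or inconsistent tabular input."""


def assign_cohort(baseline_age: float) -> str:
    """Enrollment stratum from the baseline (V0) age in days.

    EE (early enrollment) iff the infant was at most 90 days old at baseline,
    LE otherwise.
    """
    if baseline_age < 0:
        raise TableError(f"baseline age must be non-negative, got {baseline_age}")
    return "EE" if baseline_age <= STRATUM_CUTOFF_DAYS else "LE"


@dataclass
class SampleTable:
    """Per-sample metadata: infant, visit, age (days), arm, stratum."""

    frame: pd.DataFrame  # columns: sample_id, infant_id, visit, age, arm, stratum

    REQUIRED = ("sample_id", "infant_id", "visit", "age", "arm", "stratum")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise TableError(f"sample table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise TableError(f"duplicated sample_id values: {dupes}")
        if (df["age"] < 0).any():
            raise TableError("negative ages in sample table")
        bad_visit = set(df["visit"]) - set(VISITS)
        if bad_visit:
            raise TableError(f"unknown visits: {sorted(bad_visit)}")
        if df.duplicated(subset=["infant_id", "visit"]).any():
            raise TableError("duplicate (infant_id, visit) pairs")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        wanted = list(sample_ids)
        sub = self.frame.set_index("sample_id").loc[wanted].reset_index()
        return SampleTable(sub)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "infant_id": str}))


@dataclass
class TaxaCountMatrix:
    """Integer count matrix, samples x taxa, with a taxonomic level tag."""

    counts: pd.DataFrame  # index: sample_id, columns: taxon_id
    level: str = "genus"

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            raise TableError("duplicated sample IDs in count matrix")
        if df.columns.duplicated().any():
            raise TableError("duplicated taxon IDs in count matrix")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0):
                r, c = np.argwhere(frac != 0)[0]
                raise TableError(
                    f"non-integer count at sample {df.index[r]!r}, taxon {df.columns[c]!r}: "
                    f"{arr[r, c]!r}"
                )
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            raise TableError("negative counts")
        self.counts = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_count_table(path: str | Path, level: str = "genus",
                     samples_in_rows: bool = True) -> TaxaCountMatrix:
    """Read a TSV count table, normalizing orientation to samples x taxa.

    Raises :class:`TableError` naming the offending cell on non-integer
    entries and on duplicated IDs.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if not samples_in_rows:
        df = df.T
    return TaxaCountMatrix(df, level=level)


@dataclass
class MetaboliteMatrix:
    """Metabolite concentrations (nmol/g), samples x metabolites; NaN allowed."""

    concentrations: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.concentrations
        if df.index.duplicated().any():
            raise TableError("duplicated sample IDs in metabolite matrix")
        vals = df.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise TableError("negative concentrations")
        self.concentrations = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    def to_tsv(self, path: str | Path) -> None:
        self.concentrations.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetaboliteMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class KOAbundanceMatrix:
    """Relative abundances of KEGG orthologues, samples x KOs."""

    abundances: pd.DataFrame

    def __post_init__(self) -> None:
        if self.abundances.index.duplicated().any():
            raise TableError("duplicated sample IDs in KO matrix")
        if (self.abundances.to_numpy(dtype=float) < 0).any():
            raise TableError("negative KO abundances")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    def to_tsv(self, path: str | Path) -> None:
        self.abundances.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KOAbundanceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def align_tables(metadata: SampleTable, *matrices) -> None:
    """Check that every matrix covers exactly the metadata's samples."""
    ref = set(metadata.sample_ids)
    for m in matrices:
        got = set(m.sample_ids)
        if got != ref:
            raise TableError(
                f"sample mismatch: {sorted(ref - got)[:5]} missing, "
                f"{sorted(got - ref)[:5]} unexpected"
            )


# -- phylogenetic tree ------------------------------------------------------

def read_newick(path_or_str: str | Path) -> skbio.TreeNode:
    """Parse a single rooted newick tree; missing branch lengths become 0."""
    src = str(path_or_str)
    try:
        if "(" in src or ";" in src:
            tree = skbio.TreeNode.read([src])
        else:
            tree = skbio.TreeNode.read(src)
    except Exception as exc:  # skbio raises several parse error types
        raise TableError(f"malformed newick: {exc}") from exc
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise TableError("duplicated leaf labels in tree")
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise TableError(f"negative branch length at {node.name!r}")
    return tree


# -- rarefaction ------------------------------------------------------------

def rarefy(counts: Sequence[int] | np.ndarray, depth: int,
           seed: int | np.random.Generator) -> np.ndarray:
    """Subsample a count vector without replacement to ``depth`` reads.

    The marginal law is multivariate hypergeometric.  ``depth`` must not
    exceed the vector's total; callers decide whether shallow samples are
    dropped (see :func:`rarefy_matrix`).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise TableError("negative counts cannot be rarefied")
    total = int(counts.sum())
    if depth > total:
        raise TableError(f"rarefaction depth {depth} exceeds library size {total}")
    if depth == total:
        return counts.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def rarefy_matrix(matrix: TaxaCountMatrix, depth: int | None = None,
                  seed: int = 0, min_depth: int | None = None) -> TaxaCountMatrix:
    """Rarefy every sample to a common depth.

    Default depth is the minimum library size across retained samples.
    Samples below ``min_depth`` (when given) are dropped with a warning
    rather than silently kept.
    """
    rng = np.random.default_rng(seed)
    totals = matrix.counts.sum(axis=1)
    keep = matrix.counts
    if min_depth is not None:
        shallow = totals[totals < min_depth]
        if len(shallow):
            warnings.warn(
                f"dropping {len(shallow)} samples below depth {min_depth}: "
                f"{list(shallow.index[:5])}"
            )
            keep = keep.loc[totals >= min_depth]
            totals = totals[totals >= min_depth]
    if depth is None:
        depth = int(totals.min())
    out = np.vstack([rarefy(row, depth, rng) for row in keep.to_numpy()])
    return TaxaCountMatrix(
        pd.DataFrame(out, index=keep.index, columns=keep.columns), level=matrix.level
    )
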