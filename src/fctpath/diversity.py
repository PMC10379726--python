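"""Ecological diversity measures: Faith's phylogenetic diversity (alpha)
and Bray-Curtis dissimilarity (beta).

Faith's PD is the total branch length of the minimal rooted subtree spanning
the taxa present in a sample, including the path to the root.  Both measures
are computed on rarefied abundances by the pipeline (presence = count > 0
after rarefaction).
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
import skbio
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .tables import SampleTable, TaxaCountMatrix


def faith_pd(presence: Iterable[str], tree: skbio.TreeNode) -> float:
    """Faith's PD of a set of present taxa on a rooted tree.

    Taxa absent from the tree are dropped with a warning; an empty set gives
    PD = 0 with a warning.
    """
    leaves = {t.name for t in tree.tips()}
    present = [p for p in set(presence)]
    known = [p for p in present if p in leaves]
    dropped = sorted(set(present) - set(known))
    if dropped:
        warnings.warn(f"taxa absent from tree dropped from PD: {dropped[:5]}")
    if not known:
        warnings.warn("empty presence set; PD = 0")
        return 0.0
    counts = np.ones(len(known))
    return float(_skbio_faith_pd(counts, known, tree))


def faith_pd_samples(matrix: TaxaCountMatrix, tree: skbio.TreeNode) -> pd.Series:
    """Per-sample Faith's PD (presence = count > 0)."""
    out = {}
    for sid, row in matrix.counts.iterrows():
        present = row.index[row.to_numpy() > 0]
        out[sid] = faith_pd(present, tree)
    return pd.Series(out, name="faith_pd")


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(a, b)) / (sum(a) + sum(b))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("abundance vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


def bray_curtis_matrix(matrix: TaxaCountMatrix) -> pd.DataFrame:
    """All-pairs Bray-Curtis dissimilarities, samples x samples."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(matrix.values.astype(float), metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)
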