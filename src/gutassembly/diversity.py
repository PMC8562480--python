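"""Alpha diversity, rarefaction, Bray-Curtis, PCoA and related summaries.

Alpha metrics: observed OTUs, bias-corrected Chao1
``S_obs + F1(F1-1) / (2(F2+1))`` (defined even when doubletons are absent),
Shannon entropy (natural log by default), and Faith's phylogenetic
diversity (branch length of the minimal subtree spanning the observed tips,
root path included).
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import DistanceMatrix, OtuTable, PhyloTree

__all__ = [
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "group_similarity_z",
    "fb_ratio",
]

logger = logging.getLogger(__name__)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped (and logged).
    Subsampling is a multivariate hypergeometric draw per sample.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if table.is_relative:
        raise ValueError("rarefaction requires a count table")
    rng = np.random.default_rng(int(seed))
    counts = np.rint(table.counts).astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    rows = []
    for i in np.flatnonzero(keep):
        if totals[i] == depth:
            rows.append(counts[i])
        else:
            rows.append(rng.multivariate_hypergeometric(counts[i], depth))
    data = pd.DataFrame(np.array(rows, dtype=int),
                        index=[s for s, k in zip(table.sample_ids, keep) if k],
                        columns=table.otu_ids)
    return OtuTable(data, is_relative=False)


def _chao1(row: np.ndarray) -> float:
    obs = int((row > 0).sum())
    f1 = int((row == 1).sum())
    f2 = int((row == 2).sum())
    return obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _shannon(row: np.ndarray, base: float | None) -> float:
    p = row[row > 0]
    p = p / p.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def alpha_diversity(table: OtuTable, tree: PhyloTree | None = None,
                    shannon_base: float | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity table.

    Columns: ``observed_otus``, ``chao1``, ``shannon`` (nats unless
    ``shannon_base`` is given) and, when a tree is supplied, ``faith_pd``.

    Raises on all-zero samples and on observed OTUs missing from the tree.
    """
    counts = table.counts
    zero = [s for s, t in zip(table.sample_ids, counts.sum(axis=1)) if t == 0]
    if zero:
        raise ValueError(f"all-zero samples: {zero}")
    if tree is not None:
        missing = sorted(set(np.array(table.otu_ids)[(counts > 0).any(axis=0)])
                         - set(tree.tip_labels))
        if missing:
            raise ValueError(f"OTUs missing from tree: {missing}")
    out = {}
    otu_ids = np.array(table.otu_ids)
    for sid, row in zip(table.sample_ids, counts):
        rec = {
            "observed_otus": int((row > 0).sum()),
            "chao1": _chao1(np.rint(row)) if not table.is_relative
            else float((row > 0).sum()),
            "shannon": _shannon(row, shannon_base),
        }
        if tree is not None:
            rec["faith_pd"] = tree.faith_pd(otu_ids[row > 0])
        out[sid] = rec
    return pd.DataFrame(out).T


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)``."""
    counts = table.counts
    zero = [s for s, t in zip(table.sample_ids, counts.sum(axis=1)) if t == 0]
    if zero:
        raise ValueError(f"zero-total samples: {zero}")
    condensed = pdist(counts, metric="braycurtis")
    return DistanceMatrix(tuple(table.sample_ids), squareform(condensed))


def pcoa(dm: DistanceMatrix, n_axes: int | None = None
         ) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Principal coordinates analysis of a distance matrix.

    Eigendecomposition of the Gower-centered ``-1/2 D^2`` matrix.  Axes are
    ordered by descending eigenvalue; only positive-eigenvalue axes carry
    coordinates.  Negative eigenvalues are returned for inspection and are
    excluded from the proportion-explained denominator.

    Returns
    -------
    coordinates : DataFrame (samples x axes, columns ``PC1``...)
    proportion_explained : Series per axis
    eigenvalues : all eigenvalues, descending
    """
    n = len(dm)
    if n_axes is None:
        n_axes = n - 1
    if n_axes > n - 1:
        raise ValueError(f"n_axes {n_axes} exceeds n_samples-1 = {n - 1}")
    d2 = dm.values ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ d2 @ centerer
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12 * max(eigval.max(), 1.0)
    n_keep = min(n_axes, int(pos.sum()))
    coords = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    axes = [f"PC{i + 1}" for i in range(n_keep)]
    denom = eigval[pos].sum()
    prop = pd.Series(eigval[:n_keep] / denom if denom > 0 else 0.0,
                     index=axes, name="proportion_explained")
    return (pd.DataFrame(coords, index=list(dm.ids), columns=axes),
            prop, eigval)


def group_similarity_z(dm: DistanceMatrix,
                       groups: Sequence[str]) -> pd.DataFrame:
    """Group x group matrix of mean pairwise similarity z-scores.

    Similarity is ``1 - d`` for every unordered sample pair (self-pairs
    excluded), z-scored over all pairs globally; cell (g, h) averages the z
    of pairs with one sample in g and one in h.  Diagonal cells for
    single-sample groups are NaN.
    """
    groups = np.asarray(groups)
    if len(groups) != len(dm):
        raise ValueError("groups length does not match distance matrix")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    iu = np.triu_indices(len(dm), k=1)
    sim = 1.0 - dm.values[iu]
    mu, sd = sim.mean(), sim.std(ddof=0)
    z = (sim - mu) / sd if sd > 0 else np.zeros_like(sim)
    gi, gj = groups[iu[0]], groups[iu[1]]
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            mask = ((gi == a) & (gj == b)) | ((gi == b) & (gj == a))
            if mask.any():
                out.loc[a, b] = z[mask].mean()
    return out


def fb_ratio(table: OtuTable,
             taxonomy: dict[str, str]) -> pd.Series:
    """Per-sample Firmicutes/Bacteroidetes abundance ratio.

    ``taxonomy`` maps OTU id to phylum name; OTUs without a mapping are
    ignored (and logged).  Samples with zero Bacteroidetes abundance get
    NaN rather than an infinite ratio.
    """
    otus = table.otu_ids
    unmapped = [o for o in otus if o not in taxonomy]
    if unmapped:
        logger.warning("fb_ratio: %d unmapped OTUs ignored", len(unmapped))
    firm = [o for o in otus if taxonomy.get(o) == "Firmicutes"]
    bact = [o for o in otus if taxonomy.get(o) == "Bacteroidetes"]
    f = table.data[firm].sum(axis=1) if firm else pd.Series(0.0, index=table.data.index)
    b = table.data[bact].sum(axis=1) if bact else pd.Series(0.0, index=table.data.index)
    ratio = f / b.replace(0, np.nan)
    ratio.name = "fb_ratio"
    return ratio
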