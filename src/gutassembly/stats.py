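"""Permutation-based multivariate statistics: PERMANOVA, Mantel, group tests.

PERMANOVA is one-way, computed from distance-based sums of squares via the
Gower identity ``SS_total = sum_{i<j} d_ij^2 / n`` (and the analogous
within-group sums); significance comes from permuting group labels.  The
Mantel test correlates the upper triangles of two aligned distance matrices
and permutes the rows/columns of one of them jointly.  Permutation p-values
use the ``(b+1)/(n+1)`` convention, one-sided for pseudo-F (large values),
two-sided via |r| for Mantel.
"""
from __future__ import annotations

import dataclasses
import itertools
import string
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import DistanceMatrix, SampleMetadata

__all__ = [
    "PermanovaResult",
    "MantelResult",
    "permanova",
    "mantel",
    "env_distance",
    "group_compare",
]


@dataclasses.dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_perm: float
    df_between: int
    df_within: int
    n_permutations: int


@dataclasses.dataclass
class MantelResult:
    r: float
    p_perm: float
    n_permutations: int
    method: str


def _permanova_f(d2: np.ndarray, group_indices: list[np.ndarray],
                 n: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and group index arrays."""
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for idx in group_indices:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    a = len(group_indices)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(dm: DistanceMatrix, groups: Sequence[str],
              permutations: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Requires >= 2 groups, each with >= 2 samples.  The pseudo-F statistic is
    invariant to sample order and to multiplying all distances by a positive
    constant.
    """
    groups = np.asarray(groups)
    n = len(dm)
    if len(groups) != n:
        raise ValueError("groups length does not match distance matrix")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    sizes = {g: int((groups == g).sum()) for g in labels}
    small = [g for g, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"groups with a single sample: {small}")

    d2 = dm.values ** 2
    idx_obs = [np.flatnonzero(groups == g) for g in labels]
    f_obs, r2 = _permanova_f(d2, idx_obs, n)

    rng = np.random.default_rng(int(seed))
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        idx_perm = [perm[idx] for idx in idx_obs]
        f_p, _ = _permanova_f(d2, idx_perm, n)
        if f_p >= f_obs:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    a = len(labels)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2), p_perm=float(p),
                           df_between=a - 1, df_within=n - a,
                           n_permutations=permutations)


def mantel(dm1: DistanceMatrix, dm2: DistanceMatrix,
           permutations: int = 999, method: str = "pearson",
           seed: int = 0) -> MantelResult:
    """Mantel correlation between two distance matrices.

    Matrices are aligned on shared ids (``dm2`` reordered to ``dm1``'s
    order); r is the Pearson (default) or Spearman correlation of the
    upper triangles; p comes from jointly permuting the rows and columns
    of ``dm2``, two-sided via |r|.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if set(dm1.ids) != set(dm2.ids):
        raise ValueError("distance matrices have different ids")
    dm2 = dm2.subset(list(dm1.ids))
    n = len(dm1)
    iu = np.triu_indices(n, k=1)
    v1 = dm1.values[iu]
    sq2 = dm2.values
    v2 = sq2[iu]
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    if method == "spearman":
        v1 = sps.rankdata(v1)

        def corr(b: np.ndarray) -> float:
            return float(np.corrcoef(v1, sps.rankdata(b))[0, 1])
    else:
        def corr(b: np.ndarray) -> float:
            return float(np.corrcoef(v1, b)[0, 1])

    r_obs = corr(v2)
    rng = np.random.default_rng(int(seed))
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        if abs(corr(sq2[np.ix_(perm, perm)][iu])) >= abs(r_obs):
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return MantelResult(r=float(r_obs), p_perm=float(p),
                        n_permutations=permutations, method=method)


def env_distance(metadata: SampleMetadata, var: str) -> DistanceMatrix:
    """Absolute-difference (1-D Euclidean) distance between samples on one
    numeric metadata variable.  Missing values are an error."""
    values = metadata.env(var) if var in metadata.env_vars \
        else metadata.data[var]
    arr = pd.to_numeric(values, errors="coerce")
    bad = arr.index[~np.isfinite(arr.to_numpy(dtype=float))].tolist()
    if bad:
        raise ValueError(f"missing values for {var!r} in samples: {bad}")
    v = arr.to_numpy(dtype=float)
    dist = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(tuple(metadata.sample_ids), dist)


# ---------------------------------------------------------------------------
# Per-group comparisons with compact letter display
# ---------------------------------------------------------------------------

def _letter_display(labels: list[str], means: dict[str, float],
                    sig_pairs: set[frozenset]) -> pd.Series:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.  Start from a
    single letter covering all groups; for each significant pair split every
    letter set containing both, then absorb redundant subsets.  Letters are
    assigned in descending order of group mean for a stable, relabeling-
    invariant display.
    """
    sets: list[set[str]] = [set(labels)]
    for pair in sorted(sig_pairs, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        new_sets = [s for s in new_sets
                    if not any(s < t for t in new_sets)]
        # deduplicate
        uniq = []
        for s in new_sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    order = sorted(labels, key=lambda g: (-means[g], g))
    sets.sort(key=lambda s: min(order.index(g) for g in s))
    letters = {g: "" for g in labels}
    alphabet = string.ascii_lowercase
    for i, s in enumerate(sets):
        for g in s:
            letters[g] += alphabet[i % len(alphabet)]
    return pd.Series({g: "".join(sorted(letters[g])) for g in labels},
                     name="letters")


def group_compare(values: Sequence[float], groups: Sequence[str],
                  alpha: float = 0.05
                  ) -> tuple[pd.DataFrame, pd.Series, float]:
    """Compare a measurement across groups.

    One-way ANOVA omnibus test, pairwise Welch t-tests with BH adjustment,
    and a compact letter display (groups sharing a letter are not
    significantly different at ``alpha``).

    Returns (pairwise table, letters per group, omnibus ANOVA p).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    by_group = {g: values[groups == g] for g in labels}
    small = [g for g, v in by_group.items() if v.size < 2]
    if small:
        raise ValueError(f"groups with < 2 samples: {small}")
    if all(np.var(v) == 0 for v in by_group.values()):
        raise ValueError("zero within-group variance in all groups: "
                         "degenerate comparison")
    anova_p = float(sps.f_oneway(*by_group.values()).pvalue)

    pairs = list(itertools.combinations(labels, 2))
    praw = []
    for a, b in pairs:
        res = sps.ttest_ind(by_group[a], by_group[b], equal_var=False)
        praw.append(float(res.pvalue) if np.isfinite(res.pvalue) else 1.0)
    padj = multipletests(praw, method="fdr_bh")[1]
    table = pd.DataFrame({
        "group_1": [a for a, _ in pairs],
        "group_2": [b for _, b in pairs],
        "p_raw": praw,
        "p_adj": padj,
        "significant": padj <= alpha,
    })
    sig_pairs = {frozenset((a, b)) for (a, b), s
                 in zip(pairs, table["significant"]) if s}
    means = {g: float(np.mean(v)) for g, v in by_group.items()}
    letters = _letter_display(labels, means, sig_pairs)
    return table, letters, anova_p
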