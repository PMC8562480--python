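"""Phylogenetic community-assembly inference.

The central question: are gut communities assembled by deterministic
habitat filtering or by stochastic processes?  The approach follows the
nearest-taxon family of null models:

* per-OTU environmental niche optima (abundance-weighted means of nutrient
  variables) and a Mantel correlogram of niche distance against phylogenetic
  distance, establishing whether short phylogenetic distances track niche
  differences — the precondition for reading ecology out of phylogeny;
* SES.MNTD, the standardized effect size of the mean nearest taxon distance
  within each sample against a tip-label-shuffling null;
* pairwise beta-MNTD between samples and its z-score beta-NTI under the same
  null; |beta-NTI| > 2 marks a sample pair as deterministically assembled
  (clustering or overdispersion beyond chance), |beta-NTI| <= 2 as
  stochastic;
* per-group deterministic/stochastic fractions over within-group pairs.

The null model shuffles tip labels of the phylogeny across the full OTU
pool observed in the table ("taxa labels" randomization), holding the
abundance matrix fixed; the same shuffle is applied to all samples and
sample pairs within one null iteration.  999 randomizations by default.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, OtuTable, PhyloTree, SampleMetadata

__all__ = [
    "NicheOptima",
    "BetaNtiResult",
    "niche_optima",
    "niche_distance",
    "mantel_correlogram",
    "ses_mntd",
    "beta_mntd",
    "beta_nti",
    "assembly_fractions",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Niche optima and phylogenetic signal
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NicheOptima:
    """Abundance-weighted environmental optima per OTU.

    ``optima`` is OTUs x env variables with
    ``o_ie = sum_k f_ik e_k / sum_k f_ik``; ``total_abundance`` holds the
    per-OTU weight sums.  Only OTUs with nonzero total abundance appear.
    """

    optima: pd.DataFrame
    total_abundance: pd.Series


def niche_optima(table: OtuTable, metadata: SampleMetadata,
                 env_vars: Sequence[str] | None = None) -> NicheOptima:
    """Compute each OTU's environmental optimum per variable.

    The optimum is the abundance-weighted mean of the variable over the
    samples the OTU occurs in.  OTUs absent from every sample are dropped
    with a warning; no sample overlap between table and metadata is an
    error.
    """
    shared = [s for s in table.sample_ids if s in metadata.data.index]
    if not shared:
        raise ValueError("no overlapping samples between table and metadata")
    if env_vars is None:
        env_vars = metadata.env_vars
    missing = [v for v in env_vars if v not in metadata.data.columns]
    if missing:
        raise KeyError(f"env variables not in metadata: {missing}")
    sub = table.select_samples(shared)
    weights = sub.counts  # (n_samples, n_otus)
    totals = weights.sum(axis=0)
    absent = totals == 0
    if absent.any():
        logger.warning("niche_optima: dropping %d OTUs absent everywhere",
                       int(absent.sum()))
    env = metadata.data.loc[shared, list(env_vars)].to_numpy(dtype=float)
    keep = ~absent
    opt = (weights[:, keep].T @ env) / totals[keep][:, None]
    otus = np.array(sub.otu_ids)[keep]
    return NicheOptima(
        optima=pd.DataFrame(opt, index=otus, columns=list(env_vars)),
        total_abundance=pd.Series(totals[keep], index=otus,
                                  name="total_abundance"),
    )


def niche_distance(optima: NicheOptima,
                   standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance between OTU optimum vectors.

    Variables are z-standardized by default so nutrients on different units
    contribute comparably; pass ``standardize=False`` for raw units.
    """
    values = optima.optima.to_numpy(dtype=float)
    if values.shape[1] < 1:
        raise ValueError("need at least one env variable")
    if np.isnan(values).any():
        raise ValueError("missing optima")
    if standardize:
        sd = values.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=0)) / sd
    diff = values[:, None, :] - values[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(tuple(optima.optima.index), dist)


def _condensed(square: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(square.shape[0], k=1)
    return square[iu]


def mantel_correlogram(niche_d: DistanceMatrix,
                       phylo_d: DistanceMatrix,
                       n_classes: int | None = None,
                       permutations: int = 999,
                       seed: int = 0,
                       test_all: bool = False,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Mantel correlogram of niche distance over phylogenetic-distance classes.

    Phylogenetic distances are binned into ``n_classes`` equal-width classes
    (Sturges' rule on the number of pairs when not given).  For each class
    the Mantel statistic is the negated Pearson correlation between the
    niche distances and the binary within-class indicator, so a positive
    value means taxa in that distance class have *similar* niches
    (phylogenetic signal).  Significance is a two-sided permutation test
    (taxa of the niche matrix shuffled jointly, ``p = (b+1)/(n+1)`` on
    ``|r|``) with progressive Holm correction across classes.  By default
    only classes up to the one containing the median distance are tested.

    Returns a DataFrame with one row per class: bounds, midpoint, n_pairs,
    mantel_r, p_perm, p_corrected, significant.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    if set(niche_d.ids) != set(phylo_d.ids):
        raise ValueError("niche and phylogenetic matrices have different ids")
    niche_d = niche_d.subset(list(phylo_d.ids))
    n = len(phylo_d)
    dp = _condensed(phylo_d.values)
    n_pairs = dp.size
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(n_pairs))) + 1
    edges = np.linspace(0.0, dp.max(), n_classes + 1)
    cls = np.clip(np.searchsorted(edges, dp, side="right") - 1, 0,
                  n_classes - 1)
    median_class = int(cls[np.argsort(dp)[n_pairs // 2]])

    indicators = [(cls == c) for c in range(n_classes)]
    counts = [int(ind.sum()) for ind in indicators]
    tested = [c for c in range(n_classes)
              if counts[c] >= 2 and (test_all or c <= median_class)]

    def _stat(dn_vec: np.ndarray, c: int) -> float:
        ind = indicators[c].astype(float)
        if ind.std() == 0 or dn_vec.std() == 0:
            return np.nan
        return float(-np.corrcoef(dn_vec, ind)[0, 1])

    dn = _condensed(niche_d.values)
    r_obs = {c: _stat(dn, c) for c in tested}

    rng = np.random.default_rng(int(seed))
    exceed = {c: 0 for c in tested}
    square = niche_d.values
    iu = np.triu_indices(n, k=1)
    for _ in range(permutations):
        perm = rng.permutation(n)
        dn_perm = square[np.ix_(perm, perm)][iu]
        for c in tested:
            if np.isnan(r_obs[c]):
                continue
            r_p = _stat(dn_perm, c)
            if not np.isnan(r_p) and abs(r_p) >= abs(r_obs[c]):
                exceed[c] += 1
    p_perm = {c: (exceed[c] + 1) / (permutations + 1)
              if not np.isnan(r_obs[c]) else np.nan for c in tested}

    rows = []
    p_sofar: list[float] = []
    for c in range(n_classes):
        rec = {
            "class_index": c + 1,
            "d_lower": edges[c],
            "d_upper": edges[c + 1],
            "d_mid": (edges[c] + edges[c + 1]) / 2.0,
            "n_pairs": counts[c],
            "mantel_r": np.nan, "p_perm": np.nan,
            "p_corrected": np.nan, "significant": False,
        }
        if c in tested and not np.isnan(r_obs[c]):
            rec["mantel_r"] = r_obs[c]
            rec["p_perm"] = p_perm[c]
            p_sofar.append(p_perm[c])
            # progressive Holm: adjust the p-values of classes 1..c jointly
            # and report the adjusted value of class c
            m = len(p_sofar)
            order = np.argsort(p_sofar)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * p_sofar[idx])
                adj[idx] = min(1.0, running)
            rec["p_corrected"] = float(adj[-1])
            rec["significant"] = bool(adj[-1] <= alpha)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shared machinery for the tip-shuffle null
# ---------------------------------------------------------------------------

def _pool_structs(table: OtuTable, tree: PhyloTree):
    """Canonical pool (sorted present OTUs), patristic submatrix, and per-
    sample index/weight arrays (weights = within-sample relative abundance).

    The pool is sorted so results are invariant to OTU column order."""
    counts = table.counts
    present_any = counts.sum(axis=0) > 0
    pool = sorted(np.array(table.otu_ids)[present_any])
    missing = sorted(set(pool) - set(tree.tip_labels))
    if missing:
        raise ValueError(f"OTUs not on tree: {missing[:10]}")
    dp = tree.patristic().subset(pool).values
    col_of = {o: j for j, o in enumerate(table.otu_ids)}
    idx_list, w_list = [], []
    for k in range(table.n_samples):
        row = counts[k]
        pres = [j for j, o in enumerate(pool) if row[col_of[o]] > 0]
        idx = np.array(pres, dtype=int)
        w = np.array([row[col_of[pool[j]]] for j in pres], dtype=float)
        total = w.sum()
        w = w / total if total > 0 else w
        idx_list.append(idx)
        w_list.append(w)
    return pool, dp, idx_list, w_list


def _mntd_one(dsub: np.ndarray, w: np.ndarray, weighted: bool) -> float:
    d = dsub.copy()
    np.fill_diagonal(d, np.inf)
    mins = d.min(axis=1)
    return float(w @ mins) if weighted else float(mins.mean())


def _beta_mntd_matrix(dp: np.ndarray, idx_list, w_list,
                      weighted: bool) -> np.ndarray:
    """beta-MNTD over all sample pairs given a pool patristic matrix."""
    n = len(idx_list)
    p = dp.shape[0]
    nearest = np.empty((n, p))  # nearest distance of every pool taxon to sample m
    for m in range(n):
        nearest[m] = dp[:, idx_list[m]].min(axis=1)
    out = np.zeros((n, n))
    for k in range(n):
        for m in range(k + 1, n):
            if weighted:
                a = nearest[m][idx_list[k]] @ w_list[k]
                b = nearest[k][idx_list[m]] @ w_list[m]
            else:
                a = nearest[m][idx_list[k]].mean()
                b = nearest[k][idx_list[m]].mean()
            out[k, m] = out[m, k] = 0.5 * (a + b)
    return out


# ---------------------------------------------------------------------------
# SES.MNTD
# ---------------------------------------------------------------------------

def ses_mntd(table: OtuTable, tree: PhyloTree, n_null: int = 999,
             weighted: bool = False, seed: int = 0) -> pd.DataFrame:
    """Standardized effect size of MNTD per sample under the tip-shuffle null.

    ``mntd_obs`` averages (or abundance-weights) each present taxon's
    patristic distance to its nearest co-occurring taxon; the null shuffles
    tip labels across the full observed pool ``n_null`` times.  Samples with
    fewer than two OTUs are skipped with a warning.  When a sample contains
    the entire pool the shuffle cannot change the (unweighted) community
    and SES is exactly 0; otherwise a zero null SD leaves SES undefined
    (NaN).
    """
    pool, dp, idx_list, w_list = _pool_structs(table, tree)
    p = len(pool)
    rng = np.random.default_rng(int(seed))
    perms = [rng.permutation(p) for _ in range(n_null)]

    usable = []
    for k, idx in enumerate(idx_list):
        if idx.size < 2:
            logger.warning("ses_mntd: sample %s has < 2 OTUs, skipped",
                           table.sample_ids[k])
        else:
            usable.append(k)

    obs = {k: _mntd_one(dp[np.ix_(idx_list[k], idx_list[k])], w_list[k],
                        weighted) for k in usable}
    nulls = {k: np.empty(n_null) for k in usable}
    for i, perm in enumerate(perms):
        dperm = dp[np.ix_(perm, perm)]
        for k in usable:
            nulls[k][i] = _mntd_one(
                dperm[np.ix_(idx_list[k], idx_list[k])], w_list[k], weighted)

    rows = {}
    for k in usable:
        mu = nulls[k].mean()
        sd = nulls[k].std(ddof=1)
        if idx_list[k].size == p and not weighted:
            ses = 0.0  # shuffle-invariant: community is the whole pool
        elif sd > 0:
            ses = (obs[k] - mu) / sd
        else:
            ses = np.nan
        rows[table.sample_ids[k]] = {
            "mntd_obs": obs[k], "null_mean": mu, "null_sd": sd,
            "ses": ses, "n_null": n_null,
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# beta-MNTD / beta-NTI
# ---------------------------------------------------------------------------

def beta_mntd(table: OtuTable, tree: PhyloTree,
              weighted: bool = True) -> DistanceMatrix:
    """Between-sample mean nearest taxon distance.

    ``betaMNTD(k, m) = 1/2 [sum_i f_ik min_{j in m} d(i,j)
    + sum_j f_jm min_{i in k} d(j,i)]`` with ``f`` the within-sample
    relative abundance (weighted) or ``1/richness`` (unweighted).  Shared
    taxa contribute distance zero, so identical taxon sets give 0.
    """
    empty = [s for s, t in zip(table.sample_ids, table.counts.sum(axis=1))
             if t == 0]
    if empty:
        raise ValueError(f"empty samples: {empty}")
    _, dp, idx_list, w_list = _pool_structs(table, tree)
    mat = _beta_mntd_matrix(dp, idx_list, w_list, weighted)
    return DistanceMatrix(tuple(table.sample_ids), mat)


@dataclasses.dataclass
class BetaNtiResult:
    """Pairwise beta-NTI with its null distribution summaries.

    Square arrays over ``sample_ids`` (diagonal zero / NaN); ``bnti`` is
    NaN where the null SD is zero.  ``classification()`` applies the strict
    ``|bnti| > threshold`` rule for "deterministic".
    """

    sample_ids: tuple[str, ...]
    beta_mntd_obs: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    bnti: np.ndarray
    threshold: float
    n_null: int

    def classification(self) -> np.ndarray:
        """Square array of labels: deterministic / stochastic / undefined."""
        n = len(self.sample_ids)
        out = np.full((n, n), "undefined", dtype=object)
        with np.errstate(invalid="ignore"):
            det = np.abs(self.bnti) > self.threshold
        out[np.isfinite(self.bnti) & det] = "deterministic"
        out[np.isfinite(self.bnti) & ~det] = "stochastic"
        np.fill_diagonal(out, "")
        return out

    def to_long(self) -> pd.DataFrame:
        """Long-format table: one row per unordered sample pair."""
        cls = self.classification()
        rows = []
        n = len(self.sample_ids)
        for k in range(n):
            for m in range(k + 1, n):
                rows.append({
                    "sample_1": self.sample_ids[k],
                    "sample_2": self.sample_ids[m],
                    "beta_mntd": self.beta_mntd_obs[k, m],
                    "null_mean": self.null_mean[k, m],
                    "null_sd": self.null_sd[k, m],
                    "bnti": self.bnti[k, m],
                    "class": cls[k, m],
                })
        return pd.DataFrame(rows)


def beta_nti(table: OtuTable, tree: PhyloTree, n_null: int = 999,
             weighted: bool = True, threshold: float = 2.0,
             seed: int = 0) -> BetaNtiResult:
    """beta-NTI: z-score of observed beta-MNTD against the tip-shuffle null.

    One shuffle of the pool's tip labels is drawn per null iteration and
    applied to every sample pair, so iteration i is identical across pairs.
    ``|bnti| > threshold`` (strict) marks a pair deterministic; pairs with
    zero null SD get NaN and are logged.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    empty = [s for s, t in zip(table.sample_ids, table.counts.sum(axis=1))
             if t == 0]
    if empty:
        raise ValueError(f"empty samples: {empty}")
    _, dp, idx_list, w_list = _pool_structs(table, tree)
    n = len(idx_list)
    p = dp.shape[0]
    obs = _beta_mntd_matrix(dp, idx_list, w_list, weighted)

    rng = np.random.default_rng(int(seed))
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    for _ in range(n_null):
        perm = rng.permutation(p)
        null = _beta_mntd_matrix(dp[np.ix_(perm, perm)], idx_list, w_list,
                                 weighted)
        acc += null
        acc2 += null ** 2
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean ** 2, 0.0) * n_null / (n_null - 1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(sd > 0, (obs - mean) / sd, np.nan)
    np.fill_diagonal(bnti, 0.0)
    undef = int(np.sum(~np.isfinite(bnti[np.triu_indices(n, k=1)])))
    if undef:
        logger.warning("beta_nti: %d pairs with zero null SD left undefined",
                       undef)
    return BetaNtiResult(tuple(table.sample_ids), obs, mean, sd, bnti,
                         float(threshold), n_null)


def assembly_fractions(result: BetaNtiResult,
                       groups: Sequence[str]) -> pd.DataFrame:
    """Deterministic vs stochastic fractions over within-group sample pairs.

    Pairs with undefined beta-NTI are excluded from the denominator;
    groups with fewer than two samples are omitted with a warning.
    The two fractions sum to one per reported group.
    """
    groups = np.asarray(groups)
    if len(groups) != len(result.sample_ids):
        raise ValueError("groups length does not match samples")
    rows = []
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 2:
            logger.warning("assembly_fractions: group %s has < 2 samples, "
                           "omitted", g)
            continue
        vals = result.bnti[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)]
        finite = vals[np.isfinite(vals)]
        n_pairs = finite.size
        if n_pairs == 0:
            frac_det = np.nan
        else:
            frac_det = float((np.abs(finite) > result.threshold).mean())
        rows.append({
            "group": g,
            "frac_deterministic": frac_det,
            "frac_stochastic": 1.0 - frac_det if n_pairs else np.nan,
            "n_pairs": n_pairs,
        })
    return pd.DataFrame(rows).set_index("group")
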