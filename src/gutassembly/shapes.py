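"""Quadratic/linear response-shape screening against the DSR gradient.

Each feature (OTU relative abundance, pathway, nutrient, metabolite or
immune measure) is fit by ordinary least squares to
``y = b0 + b1 x + b2 x^2`` with x the dietary species richness level.
Features with a significant (FDR-corrected) quadratic term whose vertex
``-b1/(2 b2)`` falls strictly inside the observed DSR range are labelled
U (b2 > 0) or inverted-U (b2 < 0); the rest are refit linearly and
labelled positive/negative on a significant slope, else none.  The
quadratic test takes precedence because bitonic responses also show
significant linear terms under asymmetry; the vertex-in-range guard keeps
"quadratic but visually monotone" fits out of the bitonic classes.

Benjamini-Hochberg q-values are computed separately for the quadratic-term
family and the linear-term family across all screened features.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .containers import SampleMetadata

__all__ = ["fit_quadratic", "fit_linear", "classify_shape", "shape_screen"]

logger = logging.getLogger(__name__)

SHAPE_LABELS = ("U", "inverted-U", "positive", "negative", "none")


def _check_design(x: np.ndarray, y: np.ndarray, min_distinct: int) -> None:
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    if len(np.unique(x)) < min_distinct:
        raise ValueError(
            f"rank-deficient design: need >= {min_distinct} distinct x values")


def fit_quadratic(y, x) -> dict[str, float]:
    """OLS fit of ``y = b0 + b1 x + b2 x^2`` with two-sided t-test p-values.

    Returns a dict with ``beta0/1/2``, ``se0/1/2``, ``p_linear_term`` (b1)
    and ``p_quadratic`` (b2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_design(x, y, 3)
    if np.ptp(y) == 0:  # constant response: intercept-only, no evidence
        return {"beta0": float(y[0]), "beta1": 0.0, "beta2": 0.0,
                "se0": 0.0, "se1": 0.0, "se2": 0.0,
                "p_linear_term": 1.0, "p_quadratic": 1.0}
    design = sm.add_constant(np.column_stack([x, x ** 2]))
    res = sm.OLS(y, design).fit()
    # a perfect fit gives 0/0 t statistics for zero coefficients: no evidence
    pvals = np.where(np.isnan(res.pvalues), 1.0, res.pvalues)
    return {
        "beta0": res.params[0], "beta1": res.params[1], "beta2": res.params[2],
        "se0": res.bse[0], "se1": res.bse[1], "se2": res.bse[2],
        "p_linear_term": pvals[1], "p_quadratic": pvals[2],
    }


def fit_linear(y, x) -> dict[str, float]:
    """OLS fit of ``y = b0 + b1 x``; returns slope, SE and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_design(x, y, 2)
    if np.ptp(y) == 0:
        return {"beta0": float(y[0]), "beta1": 0.0, "se1": 0.0,
                "p_linear": 1.0}
    design = sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    pvals = np.where(np.isnan(res.pvalues), 1.0, res.pvalues)
    return {"beta0": res.params[0], "beta1": res.params[1],
            "se1": res.bse[1], "p_linear": pvals[1]}


def classify_shape(beta1: float, beta2: float, q_quadratic: float,
                   lin_beta1: float, q_linear: float,
                   x_range: tuple[float, float],
                   alpha: float = 0.05) -> str:
    """Apply the precedence rule to one feature's fitted statistics.

    U / inverted-U require ``q_quadratic <= alpha`` and the vertex strictly
    inside ``x_range``; otherwise positive/negative on ``q_linear <= alpha``
    by the sign of the linear slope; otherwise none.
    """
    x_min, x_max = x_range
    if np.isfinite(q_quadratic) and q_quadratic <= alpha and beta2 != 0:
        vertex = -beta1 / (2.0 * beta2)
        if x_min < vertex < x_max:
            return "U" if beta2 > 0 else "inverted-U"
    if np.isfinite(q_linear) and q_linear <= alpha and lin_beta1 != 0:
        return "positive" if lin_beta1 > 0 else "negative"
    return "none"


def shape_screen(features: pd.DataFrame, metadata: SampleMetadata,
                 alpha: float = 0.05, prevalence_min: float = 0.0,
                 x_column: str = "dsr_level"
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Screen every feature column for its response shape along DSR.

    Parameters
    ----------
    features
        Samples x features numeric table (index = sample ids).
    metadata
        Supplies the x variable (default ``dsr_level``) per sample.
    alpha
        Significance level applied to BH q-values.
    prevalence_min
        Minimum fraction of samples in which a feature must be nonzero;
        features below it are excluded (logged).

    Returns
    -------
    fits : DataFrame
        One row per screened feature: coefficients, p- and q-values for the
        quadratic and linear fits, vertex, and the shape label.
    summary : Series
        Feature counts per label (all five labels always present).
    """
    shared = [s for s in features.index if s in metadata.data.index]
    if not shared:
        raise ValueError("features and metadata share no samples")
    feats = features.loc[shared]
    x = metadata.data.loc[shared, x_column].to_numpy(dtype=float)

    if prevalence_min > 0:
        prevalence = (feats != 0).mean(axis=0)
        dropped = prevalence.index[prevalence < prevalence_min].tolist()
        if dropped:
            logger.warning("shape_screen: %d features below prevalence %.2f "
                           "excluded", len(dropped), prevalence_min)
        feats = feats.drop(columns=dropped)
    if feats.shape[1] == 0:
        raise ValueError("no features left after prevalence filtering")

    rows = []
    for fid in feats.columns:
        y = feats[fid].to_numpy(dtype=float)
        quad = fit_quadratic(y, x)
        lin = fit_linear(y, x)
        vertex = (-quad["beta1"] / (2.0 * quad["beta2"])
                  if quad["beta2"] != 0 else np.nan)
        rows.append({
            "feature": fid,
            "beta0": quad["beta0"], "beta1": quad["beta1"],
            "beta2": quad["beta2"],
            "p_quadratic": quad["p_quadratic"],
            "lin_beta1": lin["beta1"], "p_linear": lin["p_linear"],
            "vertex": vertex,
        })
    fits = pd.DataFrame(rows).set_index("feature")
    # separate BH families for the quadratic and the linear term
    fits["q_quadratic"] = multipletests(fits["p_quadratic"], method="fdr_bh")[1]
    fits["q_linear"] = multipletests(fits["p_linear"], method="fdr_bh")[1]

    x_range = (float(x.min()), float(x.max()))
    fits["label"] = [
        classify_shape(r.beta1, r.beta2, r.q_quadratic, r.lin_beta1,
                       r.q_linear, x_range, alpha)
        for r in fits.itertuples()
    ]
    summary = fits["label"].value_counts().reindex(SHAPE_LABELS, fill_value=0)
    summary.name = "n_features"
    return fits, summary
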