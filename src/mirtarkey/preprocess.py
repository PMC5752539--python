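"""Expression filtering, normalization, differential expression, and
median dichotomization.

Counts are filtered on raw reads, normalized to log2 RPKM (genes, using
per-feature lengths in kb) or log2 RPM (miRNAs), tested for tumor-vs-normal
differential expression with a Welch test plus Benjamini-Hochberg
correction, and dichotomized per feature at the median across tumor
samples.  Directions are called at FDR < ``de_fdr`` and linear fold change
> ``de_fc`` (direction-symmetric: a feature is "down" when the inverse fold
change exceeds the threshold).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_low_expression",
    "normalize",
    "differential_expression",
    "dichotomize_by_median",
]


def filter_low_expression(
    counts: ExpressionMatrix, min_reads: int, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep features with >= ``min_reads`` in strictly more than
    ``min_fraction`` of all samples (tumor and normal pooled).

    The canonical thresholds are 10 reads for genes and 2 for miRNAs.
    """
    if counts.scale != "counts":
        raise ValueError("filter_low_expression expects raw counts")
    frac = (counts.values >= min_reads).mean(axis=1)
    keep = frac > min_fraction
    if not keep.any():
        logger.warning("low-expression filter removed every feature")
    return ExpressionMatrix(
        counts.values.loc[keep], counts.feature_kind, counts.condition, scale="counts"
    )


def normalize(
    counts: ExpressionMatrix,
    gene_lengths: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """log2(RPKM + pseudocount) for genes, log2(RPM + pseudocount) for miRNAs.

    RPM = count / (library size / 1e6); RPKM further divides by the feature
    length in kb.  Library size is the per-sample total over the features
    present, so RPM is invariant to rescaling a sample's counts.
    """
    if counts.scale != "counts":
        raise ValueError("normalize expects raw counts")
    values = counts.values.astype(float)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero mapped reads: {bad}")
    per_million = values.div(totals / 1e6, axis=1)
    if counts.feature_kind == "gene":
        if gene_lengths is None:
            raise ValueError("gene normalization requires gene lengths (kb)")
        lengths = gene_lengths.reindex(counts.features)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()].tolist()
            raise ValueError(f"missing length for gene(s): {missing[:5]}")
        per_million = per_million.div(lengths, axis=0)
    logged = np.log2(per_million + pseudocount)
    return ExpressionMatrix(logged, counts.feature_kind, counts.condition, scale="log2")


def differential_expression(
    expr: ExpressionMatrix, cfg: RunConfig | None = None
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression on log-normalized values.

    Welch two-sample t-test per feature, BH-adjusted across all tested
    features; ``log2fc`` is the tumor-minus-normal difference of means on
    the log2 scale.  Returns a DataFrame indexed by feature with columns
    ``log2fc``, ``p``, ``fdr``, ``direction`` (``up``/``down``/``ns``).
    """
    cfg = cfg or RunConfig()
    if expr.scale != "log2":
        raise ValueError("differential_expression expects log-normalized values")
    tumor = expr.values.loc[:, expr.condition == "tumor"]
    normal = expr.values.loc[:, expr.condition == "normal"]
    if tumor.shape[1] < 3 or normal.shape[1] < 3:
        raise ValueError(
            "need >= 3 tumor and >= 3 normal samples for the two-group test; "
            f"got {tumor.shape[1]} tumor / {normal.shape[1]} normal"
        )
    t_arr, n_arr = tumor.to_numpy(), normal.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(t_arr, n_arr, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    log2fc = t_arr.mean(axis=1) - n_arr.mean(axis=1)
    fc_linear = 2.0 ** log2fc
    log_fc_thresh = np.log2(cfg.de_fc)
    direction = np.where(
        (fdr < cfg.de_fdr) & (log2fc > log_fc_thresh),
        "up",
        np.where((fdr < cfg.de_fdr) & (log2fc < -log_fc_thresh), "down", "ns"),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "direction": direction},
        index=expr.features,
    )


def dichotomize_by_median(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature high/low state across tumor samples.

    ``True`` (high) iff the value is strictly above the feature's median
    over tumor samples; ties at the median are low, so "high" is always
    strictly above the median.
    """
    if expr.scale != "log2":
        raise ValueError("dichotomize_by_median expects log-normalized values")
    tumor = expr.values.loc[:, expr.condition == "tumor"]
    medians = tumor.median(axis=1)
    return tumor.gt(medians, axis=0)
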