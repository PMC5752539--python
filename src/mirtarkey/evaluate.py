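"""Evaluation of the combined key-interaction signature.

Patients are clustered (k-means, k=2) on the interactions x patients
matrix of miRNA:target log-ratios; the split is judged by a log-rank test
and by a multivariable Cox model for the cluster term adjusted for age and
gender.  Cross-cohort transfer re-applies a signature learned in one
cohort to another, dropping interactions whose features are absent.
Association tests for literature support and secondary clinical outcomes
use the chi-square test with Yates continuity correction and Fisher's
exact test on 2x2 tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sklearn.cluster import KMeans

from .config import RunConfig, stage_rng
from .datatypes import ClinicalTable, ExpressionMatrix
from .survival import expression_ratio, logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "PatientClustering",
    "SignatureEvaluation",
    "ratio_matrix",
    "cluster_patients",
    "evaluate_signature",
    "cross_cohort_evaluation",
    "baseline_comparison",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "secondary_outcome_tests",
]


@dataclass
class PatientClustering:
    """Two-group k-means clustering of patients on ratio columns."""

    labels: pd.Series  # 1/2 per patient
    inertia: float
    n_restarts: int
    seed: int
    n_interactions: int


@dataclass
class SignatureEvaluation:
    """Survival contrast between the two patient clusters."""

    logrank_stat: float
    logrank_p: float
    hazard_ratio: float
    hr_p: float
    cox_flagged: bool = False
    n_transferable: int | None = None
    n_requested: int | None = None


def ratio_matrix(
    interactions: pd.DataFrame,
    mirna_log: ExpressionMatrix,
    mrna_log: ExpressionMatrix,
) -> pd.DataFrame:
    """Interactions x patients matrix of log2 miRNA:target ratios.

    Interactions whose miRNA or target is absent from the cohort are
    dropped with a warning (the cross-cohort case); an all-missing
    signature is an error.
    """
    tumor_m = mirna_log.subset("tumor")
    tumor_g = mrna_log.subset("tumor")
    rows, index, dropped = [], [], 0
    for row in interactions.itertuples():
        if row.mirna not in tumor_m.features or row.target not in tumor_g.features:
            dropped += 1
            continue
        rows.append(
            expression_ratio(
                tumor_m.values.loc[row.mirna], tumor_g.values.loc[row.target]
            )
        )
        index.append(f"{row.mirna}:{row.target}")
    if dropped:
        logger.warning("%d interaction(s) dropped: features absent from cohort", dropped)
    if not rows:
        raise ValueError("no interaction is measurable in this cohort")
    return pd.DataFrame(rows, index=pd.Index(index, name="interaction"))


def cluster_patients(
    ratios: pd.DataFrame,
    cfg: RunConfig | None = None,
    seed: int | None = None,
    n_restarts: int = 25,
) -> PatientClustering:
    """k-means (k=2) on patient column-vectors of the ratio matrix.

    Rows are z-scored first (``cfg.standardize_ratios``) so high-variance
    interactions do not dominate the Euclidean metric; best of
    ``n_restarts`` seeded initializations by inertia.
    """
    cfg = cfg or RunConfig()
    if seed is None:
        seed = cfg.rng_seed
    if ratios.shape[1] < 2:
        raise ValueError("need at least 2 patients to cluster")
    x = ratios.to_numpy(float)
    if cfg.standardize_ratios:
        sd = x.std(axis=1, keepdims=True)
        if (sd == 0).any():
            logger.warning("constant ratio row(s); left unstandardized")
        x = (x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    if np.allclose(x.std(axis=1), 0):
        raise ValueError("degenerate ratio matrix: all patients identical")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed % (2**31))
    raw = km.fit_predict(x.T)
    # deterministic label orientation: cluster containing the first patient is 1
    labels = np.where(raw == raw[0], 1, 2)
    return PatientClustering(
        labels=pd.Series(labels, index=ratios.columns, name="cluster"),
        inertia=float(km.inertia_),
        n_restarts=n_restarts,
        seed=seed,
        n_interactions=ratios.shape[0],
    )


def evaluate_signature(
    clustering: PatientClustering, clinical: ClinicalTable
) -> SignatureEvaluation:
    """Log-rank between clusters plus covariate-adjusted Cox.

    The multivariable Cox model has terms cluster (indicator of the
    poor-prognosis cluster, oriented so the hazard ratio is >= 1), age
    (continuous) and gender; subjects lacking age or gender are excluded
    from the Cox fit only.  A cluster with zero events flags the Cox fit.
    """
    shared = clustering.labels.index.intersection(clinical.samples)
    labels = clustering.labels.loc[shared]
    clin = clinical.data.loc[shared]
    g1, g2 = shared[labels == 1], shared[labels == 2]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("clustering produced an empty cluster")
    stat, p = logrank_test(
        clin.loc[g1, "time"], clin.loc[g1, "event"],
        clin.loc[g2, "time"], clin.loc[g2, "event"],
    )
    # orient: risk cluster = the one with worse survival (higher event hazard)
    flagged = (clin.loc[g1, "event"].sum() == 0) or (clin.loc[g2, "event"].sum() == 0)
    df = pd.DataFrame(
        {
            "time": clin["time"],
            "event": clin["event"],
            "age": clin["age"],
            "male": (clin["gender"] == "male").astype(float),
            "risk": (labels == 2).astype(float),
        }
    ).dropna(subset=["age", "male"])
    try:
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        beta = float(cph.params_["risk"])
        hr_p = float(cph.summary.loc["risk", "p"])
        if beta < 0:  # re-orient so cluster-term HR >= 1
            df["risk"] = 1.0 - df["risk"]
            cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
            beta = float(cph.params_["risk"])
            hr_p = float(cph.summary.loc["risk", "p"])
        hr = float(np.exp(beta))
    except Exception as err:  # degenerate design (e.g. no events in a cluster)
        logger.warning("multivariable Cox failed: %s", err)
        hr, hr_p, flagged = np.nan, np.nan, True
    return SignatureEvaluation(
        logrank_stat=stat, logrank_p=p, hazard_ratio=hr, hr_p=hr_p, cox_flagged=bool(flagged)
    )


def cross_cohort_evaluation(
    interactions: pd.DataFrame,
    mirna_log_b: ExpressionMatrix,
    mrna_log_b: ExpressionMatrix,
    clinical_b: ClinicalTable,
    cfg: RunConfig | None = None,
    seed: int | None = None,
) -> SignatureEvaluation:
    """Apply a signature learned in cohort A to cohort B.

    Restricts the ratio matrix to interactions measurable in B, clusters
    B's patients and evaluates the split; reports how many interactions
    transferred.  Fewer than three transferable interactions is an error.
    """
    ratios = ratio_matrix(interactions, mirna_log_b, mrna_log_b)
    if ratios.shape[0] < 3:
        raise ValueError(
            f"only {ratios.shape[0]} interaction(s) transferable to cohort B; need >= 3"
        )
    clustering = cluster_patients(ratios, cfg, seed=seed)
    result = evaluate_signature(clustering, clinical_b)
    result.n_transferable = ratios.shape[0]
    result.n_requested = len(interactions)
    return result


def baseline_comparison(
    key_interactions: pd.DataFrame,
    all_dysregulated: pd.DataFrame,
    mirna_log: ExpressionMatrix,
    mrna_log: ExpressionMatrix,
    clinical: ClinicalTable,
    cfg: RunConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Survival separation of the key signature vs two baselines.

    (a) key-interaction ratios, (b) ratios of all dysregulated
    interactions, (c) expression of the key miRNAs alone; each clustered
    and scored by log-rank.  Returns columns baseline, n_features,
    logrank_p, neg_log10_p.
    """
    cfg = cfg or RunConfig()
    key_mirnas = sorted(key_interactions["mirna"].unique())
    tumor_m = mirna_log.subset("tumor")
    rows = []
    feature_sets = {
        "key_interactions": ratio_matrix(key_interactions, mirna_log, mrna_log),
        "all_dysregulated": ratio_matrix(all_dysregulated, mirna_log, mrna_log),
        "key_mirnas_alone": tumor_m.values.loc[
            [m for m in key_mirnas if m in tumor_m.features]
        ],
    }
    for name, matrix in feature_sets.items():
        clustering = cluster_patients(matrix, cfg, seed=seed)
        ev = evaluate_signature(clustering, clinical)
        rows.append(
            {
                "baseline": name,
                "n_features": matrix.shape[0],
                "logrank_p": ev.logrank_p,
                "neg_log10_p": -np.log10(max(ev.logrank_p, np.finfo(float).tiny)),
            }
        )
    return pd.DataFrame(rows)


def chi_square_2x2(table, continuity: bool = True) -> tuple[float, float]:
    """Chi-square test of independence on a 2x2 table (df = 1).

    Yates continuity correction is on by default.  A zero marginal is an
    error (Fisher's exact test is the appropriate tool there).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal; use fisher_exact_2x2 instead")
    stat, p, _, _ = stats.chi2_contingency(t, correction=continuity)
    return float(stat), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (hypergeometric
    enumeration of tables at most as probable as the observed one)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integer counts")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def secondary_outcome_tests(
    clustering: PatientClustering, clinical: ClinicalTable
) -> pd.DataFrame:
    """PFS log-rank and KPS / M-stage Fisher tests between clusters.

    KPS is dichotomized at < 60 (a score of exactly 60 counts as not
    impaired); M-stage as M0 vs M1.  Absent columns are reported as
    unavailable, never fabricated.  Returns columns test, available, p.
    """
    shared = clustering.labels.index.intersection(clinical.samples)
    labels = clustering.labels.loc[shared]
    clin = clinical.data.loc[shared]
    g1, g2 = shared[labels == 1], shared[labels == 2]
    rows = []

    if {"pfs_time", "pfs_event"} <= set(clinical.available_optional):
        try:
            _, p = logrank_test(
                clin.loc[g1, "pfs_time"], clin.loc[g1, "pfs_event"],
                clin.loc[g2, "pfs_time"], clin.loc[g2, "pfs_event"],
            )
        except ValueError:
            p = np.nan
        rows.append({"test": "pfs_logrank", "available": True, "p": p})
    else:
        rows.append({"test": "pfs_logrank", "available": False, "p": np.nan})

    if "kps" in clinical.available_optional:
        low = clin["kps"] < 60
        table = [
            [int((low & (labels == 1)).sum()), int((~low & (labels == 1)).sum())],
            [int((low & (labels == 2)).sum()), int((~low & (labels == 2)).sum())],
        ]
        rows.append({"test": "kps_fisher", "available": True, "p": fisher_exact_2x2(table)})
    else:
        rows.append({"test": "kps_fisher", "available": False, "p": np.nan})

    if "m_stage" in clinical.available_optional:
        m1 = clin["m_stage"] == "M1"
        table = [
            [int((m1 & (labels == 1)).sum()), int((~m1 & (labels == 1)).sum())],
            [int((m1 & (labels == 2)).sum()), int((~m1 & (labels == 2)).sum())],
        ]
        rows.append({"test": "m_stage_fisher", "available": True, "p": fisher_exact_2x2(table)})
    else:
        rows.append({"test": "m_stage_fisher", "available": False, "p": np.nan})

    return pd.DataFrame(rows, columns=["test", "available", "p"])
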