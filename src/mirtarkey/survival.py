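"""Prognosis-related key-interaction selection.

The core procedure: patients are stratified into outcome-extreme groups by
the 95% confidence interval of the Kaplan-Meier median survival time
(survivors beyond the upper bound are "good", deaths before the lower bound
are "poor"); for each screened miRNA-target pair, a univariate Cox model on
the per-patient miRNA:target log-ratio is refit on many resampled sets
drawing 80% of each outcome group; pairs with a sign-consistent coefficient
and significance frequency above threshold are then confirmed by a log-rank
test between the two reversed-expression patient patterns on the full
cohort.

The univariate Cox partial likelihood (Efron tie handling) is maximized by
an in-package vectorized Newton-Raphson: the resampling stage performs tens
of thousands of single-covariate fits, which must be fast; tests verify it
against independent reference implementations.

:class:`KeyInteractionModel` / :class:`KeyInteractionResults` wrap the
procedure in a model/results interface; the underlying steps remain
available as functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times
from scipy import stats

from .config import RunConfig, stage_rng
from .datatypes import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeGroups",
    "CoxScreenResult",
    "km_median_ci",
    "assign_outcome_groups",
    "expression_ratio",
    "cox_univariate",
    "cox_screen_passes",
    "resampled_cox_screen",
    "pattern_split",
    "logrank_test",
    "select_key_interactions",
    "KeyInteractionModel",
    "KeyInteractionResults",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier median CI and outcome-extreme groups
# ---------------------------------------------------------------------------

@dataclass
class OutcomeGroups:
    """Outcome-extreme patient strata around the KM median CI."""

    good: pd.Index
    poor: pd.Index
    median: float
    lower: float
    upper: float


def km_median_ci(times, events, alpha: float = 0.05) -> tuple[float, float, float]:
    """Kaplan-Meier median survival time with its (1 - alpha) CI.

    The CI comes from inverting the pointwise log-log (exp-Greenwood)
    confidence band of the survival curve at 0.5 — the standard
    Brookmeyer-Crowley construction.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) < 10:
        raise ValueError(f"need >= 10 subjects for a median CI, got {len(times)}")
    if events.sum() == 0:
        raise ValueError("all subjects censored; median survival undefined")
    kmf = KaplanMeierFitter(alpha=alpha).fit(times, events)
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        raise ValueError(
            "survival curve never reaches 0.5; median undefined — a larger "
            "cohort or longer follow-up is required"
        )
    ci = median_survival_times(kmf.confidence_interval_)
    lower, upper = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return median, lower, upper


def assign_outcome_groups(
    clinical: ClinicalTable, alpha: float = 0.05, min_group_size: int = 5
) -> OutcomeGroups:
    """Good/poor outcome strata outside the KM-median CI.

    Good: survival time above the upper bound (death or censoring — either
    way the patient is known to have lived past it).  Poor: observed death
    before the lower bound; a patient censored early is uninformative and
    stays unassigned, as does everyone inside the CI.
    """
    df = clinical.data
    median, lower, upper = km_median_ci(df["time"], df["event"], alpha=alpha)
    good = df.index[df["time"] > upper]
    poor = df.index[(df["event"] == 1) & (df["time"] < lower)]
    if len(good) < min_group_size or len(poor) < min_group_size:
        raise ValueError(
            f"outcome groups too small (good={len(good)}, poor={len(poor)}); "
            "resampling would be meaningless"
        )
    return OutcomeGroups(good=good, poor=poor, median=median, lower=lower, upper=upper)


def expression_ratio(mirna_log: pd.Series, target_log: pd.Series) -> pd.Series:
    """Per-patient miRNA:target expression ratio on the log2 scale
    (difference of log2 values)."""
    if not mirna_log.index.equals(target_log.index):
        raise ValueError("miRNA and target vectors cover different samples")
    return mirna_log - target_log


# ---------------------------------------------------------------------------
# Univariate Cox (Efron ties), vectorized Newton-Raphson
# ---------------------------------------------------------------------------

def _cox_sorted(x: np.ndarray, events: np.ndarray, tie_starts, tie_counts,
                max_iter: int = 100, tol: float = 1e-10):
    """Newton-Raphson on pre-sorted data. Returns (beta, se, converged).

    ``tie_starts``/``tie_counts`` delimit blocks of tied times (None when
    all times are distinct, enabling the fully vectorized path).
    """
    n = len(x)
    beta = 0.0
    info = np.nan
    for _ in range(max_iter):
        eta = beta * x
        eta -= eta.max()  # overflow guard; partial likelihood is shift-invariant
        w = np.exp(eta)
        wx = w * x
        wx2 = wx * x
        rw = np.cumsum(w[::-1])[::-1]
        rwx = np.cumsum(wx[::-1])[::-1]
        rwx2 = np.cumsum(wx2[::-1])[::-1]
        if tie_starts is None:
            ev = events.astype(bool)
            mu = rwx[ev] / rw[ev]
            score = float((x[ev] - mu).sum())
            info = float((rwx2[ev] / rw[ev] - mu**2).sum())
        else:
            score = 0.0
            info = 0.0
            for s, c in zip(tie_starts, tie_counts):
                blk = slice(s, s + c)
                ev_idx = np.nonzero(events[blk])[0] + s
                d = len(ev_idx)
                if d == 0:
                    continue
                sw, swx, swx2 = rw[s], rwx[s], rwx2[s]
                dw = w[ev_idx].sum()
                dwx = wx[ev_idx].sum()
                dwx2 = wx2[ev_idx].sum()
                score += x[ev_idx].sum()
                frac = np.arange(d) / d
                den = sw - frac * dw
                num = swx - frac * dwx
                num2 = swx2 - frac * dwx2
                score -= (num / den).sum()
                info += (num2 / den - (num / den) ** 2).sum()
        if not np.isfinite(info) or info <= 1e-12:
            return np.nan, np.nan, False
        step = score / info
        beta += step
        if abs(beta) > 50:
            return np.nan, np.nan, False
        if abs(step) < tol:
            return beta, 1.0 / np.sqrt(info), True
    return beta, 1.0 / np.sqrt(info), False


def _tie_blocks(times_sorted: np.ndarray):
    """(starts, counts) of tied-time blocks, or (None, None) if no ties."""
    if len(np.unique(times_sorted)) == len(times_sorted):
        return None, None
    starts = np.r_[0, np.nonzero(np.diff(times_sorted) != 0)[0] + 1]
    counts = np.diff(np.r_[starts, len(times_sorted)])
    return starts, counts


def cox_univariate(covariate, times, events, max_iter: int = 100):
    """Univariate Cox proportional-hazards fit.

    Maximizes the partial likelihood with Efron handling of tied event
    times by Newton-Raphson.  Returns ``(beta, se, p)`` with a Wald
    two-sided p-value; raises on a constant covariate or < 2 events, and
    returns NaNs (flagged non-convergence) if the iteration fails.
    """
    x = np.asarray(covariate, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() < 2:
        raise ValueError(f"need >= 2 events for a Cox fit, got {int(e.sum())}")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate; Cox coefficient undefined")
    order = np.argsort(t, kind="stable")
    x, t, e = x[order], t[order], e[order]
    x = x - x.mean()  # improves conditioning; beta is translation-invariant
    starts, counts = _tie_blocks(t)
    beta, se, converged = _cox_sorted(x, e, starts, counts, max_iter=max_iter)
    if not converged:
        return np.nan, np.nan, np.nan
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return beta, se, p


# ---------------------------------------------------------------------------
# Resampled Cox screen
# ---------------------------------------------------------------------------

def cox_screen_passes(sign_consistent: bool, sig_freq: float, cfg: RunConfig) -> bool:
    """Pass rule of the resampled screen: consistent coefficient sign and
    significance frequency *strictly* above the threshold."""
    return bool(sign_consistent and sig_freq > cfg.sig_freq_threshold)


@dataclass
class CoxScreenResult:
    """Per-pair summary of the resampled univariate Cox screen."""

    n_resamples: int
    n_converged: int
    n_significant: int
    median_beta: float
    sign_consistent: bool
    sig_freq: float
    passed: bool


def _draw_sample_sets(
    groups: OutcomeGroups, cfg: RunConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shared resampled patient sets: 80% of each outcome group, without
    replacement, stratified.  The same sets are reused for every pair."""
    good = np.asarray(groups.good)
    poor = np.asarray(groups.poor)
    n_good = int(np.floor(cfg.resample_fraction * len(good)))
    n_poor = int(np.floor(cfg.resample_fraction * len(poor)))
    sets = []
    for _ in range(cfg.n_resamples):
        gs = rng.choice(good, size=n_good, replace=False)
        ps = rng.choice(poor, size=n_poor, replace=False)
        sets.append(np.concatenate([gs, ps]))
    return sets


def _prepare_sample_sets(sample_sets, clinical: ClinicalTable):
    """Pre-sort each sample set by time so per-pair fits skip the sort."""
    prepared = []
    df = clinical.data
    for samples in sample_sets:
        sub = df.loc[samples]
        t = sub["time"].to_numpy(float)
        e = sub["event"].to_numpy(int)
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        starts, counts = _tie_blocks(t)
        prepared.append((pd.Index(samples)[order], t, e, starts, counts))
    return prepared


def resampled_cox_screen(
    ratio: pd.Series,
    clinical: ClinicalTable,
    groups: OutcomeGroups,
    cfg: RunConfig | None = None,
    rng: np.random.Generator | None = None,
    prepared_sets=None,
) -> CoxScreenResult:
    """Resampled univariate Cox screen for one pair.

    A pair passes iff its coefficient sign agrees across all converged
    resamples and the fraction of resamples with p < 0.05 strictly exceeds
    ``sig_freq_threshold``.  Resamples with fewer than two events are
    skipped but stay in the denominator.
    """
    cfg = cfg or RunConfig()
    if prepared_sets is None:
        if rng is None:
            rng = stage_rng(cfg.rng_seed, "resample")
        prepared_sets = _prepare_sample_sets(_draw_sample_sets(groups, cfg, rng), clinical)
    betas = []
    sig_betas = []
    n_conv = 0
    for samples, t, e, starts, counts in prepared_sets:
        if e.sum() < 2:
            continue
        x = ratio.loc[samples].to_numpy(float)
        if np.ptp(x) == 0:
            continue
        beta, se, converged = _cox_sorted(x - x.mean(), e, starts, counts)
        if not converged:
            continue
        n_conv += 1
        betas.append(beta)
        p = 2.0 * stats.norm.sf(abs(beta / se))
        if p < 0.05:
            sig_betas.append(beta)
    betas_arr = np.array(betas)
    n_sig = len(sig_betas)
    sig_freq = n_sig / cfg.n_resamples
    considered = betas_arr if cfg.strict_sign_consistency else np.array(sig_betas)
    sign_consistent = bool(
        len(considered) > 0
        and (np.all(considered > 0) or np.all(considered < 0))
    )
    passed = cox_screen_passes(sign_consistent, sig_freq, cfg)
    return CoxScreenResult(
        n_resamples=cfg.n_resamples,
        n_converged=n_conv,
        n_significant=n_sig,
        median_beta=float(np.median(betas_arr)) if len(betas_arr) else np.nan,
        sign_consistent=sign_consistent,
        sig_freq=sig_freq,
        passed=passed,
    )


# ---------------------------------------------------------------------------
# Pattern split + log-rank confirmation
# ---------------------------------------------------------------------------

def pattern_split(
    mirna: str,
    target: str,
    states_mirna: pd.DataFrame,
    states_gene: pd.DataFrame,
) -> tuple[pd.Index, pd.Index]:
    """Split tumor samples by the reversed-expression pattern.

    Group A: miRNA high and target low; group B: miRNA low and target
    high.  Patients matching neither pattern are excluded.
    """
    hi_m = states_mirna.loc[mirna]
    hi_g = states_gene.loc[target]
    a = hi_m.index[hi_m & ~hi_g]
    b = hi_m.index[~hi_m & hi_g]
    return a, b


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(times_a, times_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Full selection
# ---------------------------------------------------------------------------

def select_key_interactions(
    screened: pd.DataFrame,
    mirna_log: ExpressionMatrix,
    mrna_log: ExpressionMatrix,
    clinical: ClinicalTable,
    cfg: RunConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, OutcomeGroups]:
    """Run the resampled-Cox screen and log-rank confirmation.

    Returns ``(key_interactions, diagnostics, outcome_groups)``;
    ``diagnostics`` carries the per-pair resampling summary for every
    screened pair, ``key_interactions`` only the selected ones, sorted by
    (mirna, target).
    """
    from .preprocess import dichotomize_by_median

    cfg = cfg or RunConfig()
    if seed is None:
        seed = cfg.rng_seed
    tumor_m = mirna_log.subset("tumor")
    tumor_g = mrna_log.subset("tumor")
    shared = tumor_m.samples.intersection(clinical.samples)
    clin = ClinicalTable(clinical.data.loc[shared])
    groups = assign_outcome_groups(clin)
    rng = stage_rng(seed, "resample")
    prepared = _prepare_sample_sets(_draw_sample_sets(groups, cfg, rng), clin)

    states_m = dichotomize_by_median(tumor_m)[shared]
    states_g = dichotomize_by_median(tumor_g)[shared]

    diag_rows = []
    key_rows = []
    for row in screened.itertuples():
        ratio = expression_ratio(
            tumor_m.values.loc[row.mirna, shared], tumor_g.values.loc[row.target, shared]
        )
        res = resampled_cox_screen(ratio, clin, groups, cfg, prepared_sets=prepared)
        rec = {
            "mirna": row.mirna,
            "target": row.target,
            "mirna_dir": row.mirna_dir,
            "target_dir": row.target_dir,
            "pattern_fraction": row.pattern_fraction,
            "median_beta": res.median_beta,
            "sign_consistent": res.sign_consistent,
            "sig_freq": res.sig_freq,
            "cox_passed": res.passed,
            "logrank_stat": np.nan,
            "logrank_p": np.nan,
            "risk_group": "",
        }
        if res.passed:
            a, b = pattern_split(row.mirna, row.target, states_m, states_g)
            if len(a) == 0 or len(b) == 0:
                logger.info("pair %s:%s dropped: empty pattern group", row.mirna, row.target)
                diag_rows.append(rec)
                continue
            ca, cb = clin.data.loc[a], clin.data.loc[b]
            try:
                stat, p = logrank_test(ca["time"], ca["event"], cb["time"], cb["event"])
            except ValueError:
                diag_rows.append(rec)
                continue
            rec["logrank_stat"], rec["logrank_p"] = stat, p
            rec["risk_group"] = "high-risk" if res.median_beta > 0 else "low-risk"
            if p < cfg.logrank_alpha:
                key_rows.append(rec)
        diag_rows.append(rec)

    columns = [
        "mirna", "target", "mirna_dir", "target_dir", "pattern_fraction",
        "median_beta", "sign_consistent", "sig_freq", "cox_passed",
        "logrank_stat", "logrank_p", "risk_group",
    ]
    diagnostics = pd.DataFrame(diag_rows, columns=columns)
    key = (
        pd.DataFrame(key_rows, columns=columns)
        .sort_values(["mirna", "target"])
        .reset_index(drop=True)
    )
    return key, diagnostics, groups


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class KeyInteractionModel:
    """Resampled-Cox selection of prognosis-related miRNA-target pairs.

    Parameters
    ----------
    mirna_log, mrna_log
        Log-normalized expression (tumor samples are used; normal samples,
        if present, are ignored at this stage).
    clinical
        Survival outcomes for the tumor samples.
    screened
        Dysregulated-interaction table from :func:`screen.screen_dysregulated`
        (columns mirna, target, mirna_dir, target_dir, pattern_fraction).
    config
        Pipeline thresholds; defaults to :class:`RunConfig()`.
    """

    def __init__(
        self,
        mirna_log: ExpressionMatrix,
        mrna_log: ExpressionMatrix,
        clinical: ClinicalTable,
        screened: pd.DataFrame,
        config: RunConfig | None = None,
    ):
        self.mirna_log = mirna_log
        self.mrna_log = mrna_log
        self.clinical = clinical
        self.screened = screened.reset_index(drop=True)
        self.config = config or RunConfig()

    def fit(self, seed: int | None = None) -> "KeyInteractionResults":
        """Run selection; ``seed`` overrides ``config.rng_seed``."""
        key, diagnostics, groups = select_key_interactions(
            self.screened,
            self.mirna_log,
            self.mrna_log,
            self.clinical,
            self.config,
            seed=seed,
        )
        return KeyInteractionResults(self, key, diagnostics, groups)


@dataclass
class KeyInteractionResults:
    """Fitted results of :class:`KeyInteractionModel`."""

    model: KeyInteractionModel
    key_interactions: pd.DataFrame
    diagnostics: pd.DataFrame
    outcome_groups: OutcomeGroups

    def summary(self) -> str:
        g = self.outcome_groups
        k = self.key_interactions
        lines = [
            "Key miRNA-target interaction selection",
            "=" * 54,
            f"screened pairs:        {len(self.diagnostics)}",
            f"outcome groups:        good={len(g.good)}  poor={len(g.poor)}",
            f"KM median [95% CI]:    {g.median:.1f} [{g.lower:.1f}, {g.upper:.1f}] days",
            f"passed Cox screen:     {int(self.diagnostics['cox_passed'].sum())}",
            f"key interactions:      {len(k)}",
        ]
        if len(k):
            lines.append("-" * 54)
            lines.append(
                k[["mirna", "target", "sig_freq", "median_beta", "logrank_p", "risk_group"]]
                .to_string(index=False, float_format=lambda v: f"{v:.3g}")
            )
        return "\n".join(lines)

    def to_network(self):
        """Bipartite key-interaction network (see :mod:`topology`)."""
        from .topology import build_network

        return build_network(self.key_interactions)

    def plot_kaplan_meier(self, mirna: str, target: str, ax=None):
        """KM curves of the two reversed-expression patient groups."""
        import matplotlib.pyplot as plt
        from .preprocess import dichotomize_by_median

        states_m = dichotomize_by_median(self.model.mirna_log)
        states_g = dichotomize_by_median(self.model.mrna_log)
        a, b = pattern_split(mirna, target, states_m, states_g)
        clin = self.model.clinical.data
        a = a.intersection(clin.index)
        b = b.intersection(clin.index)
        if ax is None:
            _, ax = plt.subplots()
        for label, idx in [("miRNA high / target low", a), ("miRNA low / target high", b)]:
            kmf = KaplanMeierFitter().fit(
                clin.loc[idx, "time"], clin.loc[idx, "event"], label=label
            )
            kmf.plot_survival_function(ax=ax)
        ax.set_xlabel("days")
        ax.set_ylabel("survival probability")
        ax.set_title(f"{mirna} : {target}")
        return ax
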