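"""Discrimination evaluation: ROC/AUC with DeLong inference, paired and
unpaired AUC comparisons, covariate-adjusted odds ratios for percentile
groups, and aggressiveness classification.

The AUC is the Mann-Whitney probability that a random case outscores a
random control, ties counting one half.  Its variance comes from DeLong's
structural components: per-case placements V10 and per-control placements
V01, giving var = S10/m + S01/n; the paired test between two scores on the
same samples adds the component covariances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._util import ValidationError, as_1d_float

HIGH_GROUP = "top_decile"
MID_GROUP = "middle_20"


@dataclass
class RocResult:
    """AUC with DeLong variance and a normal-theory 95% CI."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    ci_scale: str = "auc"
    v10: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    v01: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValidationError("AUC must lie in [0,1]")
        if self.variance < 0:
            raise ValidationError("variance must be non-negative")
        if not self.ci_low - 1e-12 <= self.auc <= self.ci_high + 1e-12:
            raise ValidationError("CI must contain the AUC")


@dataclass
class OddsRatioResult:
    """Covariate-adjusted odds ratio with a 95% Wald CI."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_high: int
    n_mid: int
    covariates: list[str]

    def __post_init__(self):
        if self.odds_ratio <= 0:
            raise ValidationError("odds ratio must be positive")
        if not self.ci_low - 1e-12 <= self.odds_ratio <= self.ci_high + 1e-12:
            raise ValidationError("CI must contain the OR")


def classify_aggressive(stage, gleason, classifier: str):
    """Aggressiveness flag under one classifier.

    ``classifier="stage"``: aggressive iff stage is T4 (vs T1-T3);
    ``classifier="gleason"``: aggressive iff Gleason >= 8 (vs <= 7).  A
    missing value for the active classifier returns None (not evaluable).
    """
    if classifier not in ("stage", "gleason"):
        raise ValidationError("classifier must be 'stage' or 'gleason'")
    if classifier == "stage":
        if stage is None or (isinstance(stage, float) and np.isnan(stage)):
            return None
        if stage not in ("T1", "T2", "T3", "T4"):
            raise ValidationError(f"unknown tumor stage {stage!r}")
        return stage == "T4"
    if gleason is None or (isinstance(gleason, float) and np.isnan(gleason)):
        return None
    g = float(gleason)
    if not (2 <= g <= 10 and g == int(g)):
        raise ValidationError(f"Gleason score must be an integer in 2..10, got {gleason}")
    return g >= 8


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels, ci_scale: str = "auc") -> RocResult:
    """AUC with DeLong variance and 95% CI.

    ``labels`` is boolean (True = case).  ``ci_scale="auc"`` puts the normal
    CI directly on the AUC (clipped to [0,1]); ``"logit"`` builds it on the
    log-odds scale and back-transforms.
    """
    s = as_1d_float(scores, "scores")
    y = np.asarray(labels, dtype=bool)
    if s.size != y.size:
        raise ValidationError("scores and labels must align")
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValidationError("need both cases and controls")
    cases, ctrls = s[y], s[~y]
    all_ranks = _midrank(np.concatenate([cases, ctrls]))
    case_ranks, ctrl_ranks = _midrank(cases), _midrank(ctrls)
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - ctrl_ranks) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    if ci_scale == "logit" and 0.0 < auc < 1.0 and se > 0:
        logit = np.log(auc / (1 - auc))
        se_logit = se / (auc * (1 - auc))
        lo, hi = logit - z * se_logit, logit + z * se_logit
        ci = (1 / (1 + np.exp(-lo)), 1 / (1 + np.exp(-hi)))
    else:
        ci_scale = "auc"
        ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return RocResult(auc=auc, variance=float(var), ci_low=float(ci[0]),
                     ci_high=float(ci[1]), n_cases=m, n_controls=n,
                     ci_scale=ci_scale, v10=v10, v01=v01)


def delong_test(roc_1: RocResult, roc_2: RocResult, paired: bool) -> dict:
    """Two-sided z-test of AUC_1 = AUC_2.

    ``paired=True`` requires both ROC results to come from the same samples
    in the same order (the covariance of structural components is used);
    ``paired=False`` treats the cohorts as independent.
    """
    if paired:
        if (roc_1.n_cases != roc_2.n_cases
                or roc_1.n_controls != roc_2.n_controls):
            raise ValidationError("paired test needs identical sample sets")
        m, n = roc_1.n_cases, roc_1.n_controls
        cov10 = (np.cov(roc_1.v10, roc_2.v10, ddof=1)[0, 1] if m > 1 else 0.0)
        cov01 = (np.cov(roc_1.v01, roc_2.v01, ddof=1)[0, 1] if n > 1 else 0.0)
        var = roc_1.variance + roc_2.variance - 2.0 * (cov10 / m + cov01 / n)
    else:
        var = roc_1.variance + roc_2.variance
    diff = roc_1.auc - roc_2.auc
    var = max(var, 0.0)
    if var == 0.0:
        z = 0.0 if diff == 0.0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return {"z": float(z), "p_value": p, "auc_diff": float(diff),
            "paired": paired}


def percentile_groups(standardized_scores, high_above: float = 0.90,
                      mid_low: float = 0.40, mid_high: float = 0.60) -> np.ndarray:
    """Label samples by PRS percentile group within this cohort.

    Percentile ranks use average ranks divided by n.  ``top_decile`` is rank
    strictly above ``high_above``; ``middle_20`` is ``mid_low`` <= rank <=
    ``mid_high`` (both inclusive); everything else is None.  Raises when a
    group comes out empty (degenerate or tiny score vectors).
    """
    s = as_1d_float(standardized_scores, "standardized_scores")
    ranks = _midrank(s) / s.size
    labels = np.full(s.size, None, dtype=object)
    labels[ranks > high_above] = HIGH_GROUP
    labels[(ranks >= mid_low) & (ranks <= mid_high)] = MID_GROUP
    if not np.any(labels == HIGH_GROUP) or not np.any(labels == MID_GROUP):
        raise ValidationError(
            "degenerate percentile groups (too few distinct scores)"
        )
    return labels


def fill_missing_ages(ages) -> np.ndarray:
    """Replace missing ages with the median of the observed ages."""
    a = as_1d_float(ages, "ages")
    missing = ~np.isfinite(a)
    if missing.all():
        raise ValidationError("all ages missing")
    if missing.any():
        a = a.copy()
        a[missing] = np.median(a[~missing])
    return a


def covariate_adjusted_or(group_labels, labels, covariates=None) -> OddsRatioResult:
    """Logistic-regression OR of case status, top decile vs middle 20%.

    Fits status ~ I(top_decile) + covariates on the samples falling in
    either group; with no covariates this equals the 2x2 cross-product OR
    exactly.  ``covariates`` is a DataFrame aligned with all samples; an
    ``age`` column gets median-filled.
    """
    g = np.asarray(group_labels, dtype=object)
    y = np.asarray(labels, dtype=bool)
    in_groups = (g == HIGH_GROUP) | (g == MID_GROUP)
    if not in_groups.any():
        raise ValidationError("no samples in the percentile groups")
    yy = y[in_groups].astype(float)
    indicator = (g[in_groups] == HIGH_GROUP).astype(float)
    for grp, name in ((1.0, HIGH_GROUP), (0.0, MID_GROUP)):
        sel = indicator == grp
        if yy[sel].min(initial=1.0) == 1.0 or yy[sel].max(initial=0.0) == 0.0:
            raise ValidationError(
                f"group {name} lacks cases or controls; use exact methods"
            )
    cov_names: list[str] = []
    exog = [np.ones(in_groups.sum()), indicator]
    if covariates is not None:
        cov = covariates.loc[np.asarray(in_groups)].copy()
        if "age" in cov.columns:
            cov["age"] = fill_missing_ages(cov["age"].to_numpy())
        for col in cov.columns:
            exog.append(cov[col].to_numpy(dtype=float))
            cov_names.append(col)
    exog = np.column_stack(exog)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-degenerate fits are flagged below
            fit = sm.Logit(yy, exog).fit(disp=0)
        coef = fit.params[1]
        se = fit.bse[1]
    except Exception as exc:  # separation / singular design
        raise ValidationError(f"logistic fit failed: {exc}") from exc
    if not (np.isfinite(coef) and np.isfinite(se)):
        raise ValidationError("logistic fit produced non-finite estimates")
    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):  # huge SE -> infinite CI bound, kept
        ci_low = float(np.exp(coef - z * se))
        ci_high = float(np.exp(coef + z * se))
    return OddsRatioResult(
        odds_ratio=float(np.exp(coef)),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(fit.pvalues[1]),
        n_high=int(indicator.sum()),
        n_mid=int((1 - indicator).sum()),
        covariates=cov_names,
    )


def covariate_adjusted_auc(scores, labels, covariates: pd.DataFrame) -> dict:
    """AUC of the fitted probabilities of status ~ PRS + covariates.

    Returns both the covariate-model AUC and the PRS-only AUC (the two
    readings of "discrimination after correcting for covariates").
    """
    s = as_1d_float(scores, "scores")
    y = np.asarray(labels, dtype=bool)
    cov = covariates.copy()
    if "age" in cov.columns:
        cov["age"] = fill_missing_ages(cov["age"].to_numpy())
    exog = np.column_stack(
        [np.ones(s.size), s] + [cov[c].to_numpy(dtype=float) for c in cov.columns]
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.astype(float), exog).fit(disp=0)
    except Exception as exc:  # perfect separation and friends
        raise ValidationError(f"logistic fit failed: {exc}") from exc
    fitted = fit.predict(exog)
    return {
        "model_auc": roc_auc(fitted, y),
        "prs_only_auc": roc_auc(s, y),
        "prs_coef": float(fit.params[1]),
    }


def build_evaluation_report(cohorts: dict, classifiers=("stage", "gleason"),
                            score_name: str = "score") -> pd.DataFrame:
    """Assemble the per-(cohort, ancestry) discrimination table.

    ``cohorts`` maps a cohort label to a dict with keys:

    - ``scores``: mapping ancestry label -> standardized score vector;
    - ``status``: boolean case indicator, aligned with the scores;
    - ``covariates``: optional DataFrame (age, PCs) for OR adjustment;
    - ``metadata``: optional DataFrame with stage/gleason columns for the
      aggressiveness rows (cases only are used).

    One row per (cohort, ancestry) for case/control discrimination, plus one
    row per classifier restricted to cases.  Failures mark the row
    (``ok=False``, reason in ``note``) instead of aborting the report.
    """
    rows = []
    for cohort_name, entry in cohorts.items():
        status = np.asarray(entry["status"], dtype=bool)
        covariates = entry.get("covariates")
        meta = entry.get("metadata")
        for ancestry, scores in entry["scores"].items():
            row = {"cohort": cohort_name, "score": score_name,
                   "ancestry": ancestry, "endpoint": "case_control",
                   "ok": True, "note": ""}
            try:
                roc = roc_auc(scores, status)
                row.update(auc=roc.auc, auc_ci_low=roc.ci_low,
                           auc_ci_high=roc.ci_high, n_cases=roc.n_cases,
                           n_controls=roc.n_controls)
                groups = percentile_groups(scores)
                orr = covariate_adjusted_or(groups, status, covariates)
                row.update(odds_ratio=orr.odds_ratio, or_ci_low=orr.ci_low,
                           or_ci_high=orr.ci_high)
            except ValidationError as exc:
                row.update(ok=False, note=str(exc))
            rows.append(row)

            if meta is None:
                continue
            for classifier in classifiers:
                arow = {"cohort": cohort_name, "score": score_name,
                        "ancestry": ancestry,
                        "endpoint": f"aggressive_{classifier}",
                        "ok": True, "note": ""}
                try:
                    flags = [
                        classify_aggressive(st, gl, classifier)
                        for st, gl in zip(meta["stage"], meta["gleason"])
                    ]
                    case_mask = status & np.array(
                        [f is not None for f in flags]
                    )
                    agg = np.array(
                        [bool(f) for f, keep in zip(flags, case_mask) if keep]
                    )
                    sub_scores = np.asarray(scores)[case_mask]
                    roc = roc_auc(sub_scores, agg)
                    arow.update(auc=roc.auc, auc_ci_low=roc.ci_low,
                                auc_ci_high=roc.ci_high, n_cases=roc.n_cases,
                                n_controls=roc.n_controls)
                    groups = percentile_groups(sub_scores)
                    sub_cov = (covariates.loc[case_mask].reset_index(drop=True)
                               if covariates is not None else None)
                    orr = covariate_adjusted_or(groups, agg, sub_cov)
                    arow.update(odds_ratio=orr.odds_ratio,
                                or_ci_low=orr.ci_low, or_ci_high=orr.ci_high)
                except ValidationError as exc:
                    arow.update(ok=False, note=str(exc))
                rows.append(arow)
    return pd.DataFrame(rows)
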