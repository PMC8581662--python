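"""Per-region diagnostic evaluation with subgroup stratification.

Each candidate region is scored by its per-sample mean methylation and
evaluated as a univariate tumor-vs-control classifier:

* odds ratio with Wald 95% CI from a univariate logistic regression
  (native IRLS fit), reported per 0.1 increase in methylation fraction
  by default (``reporting_scale``);
* AUC in the Mann–Whitney formulation (ties count one half), identical
  to the trapezoidal area under the empirical ROC curve;
* the diagnostic cutoff maximising sensitivity + specificity (the
  Youden rule; ties resolved toward higher specificity, then the lower
  cutoff);
* a two-sided Wilcoxon rank-sum p-value, BH-adjusted across the marker
  panel within each stratum.

Strata split the tumors (KRAS+/KRAS-, young/old at the cohort median
age, male/female, early/late stage, colon/rectum) while every stratum
keeps the full para-tumor control set, since para-tumors carry no
tumor-level covariates.  Prediction outcomes between two subgroups are
compared with a two-sided Fisher exact test on the correct/incorrect
contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, StratumError
from .regions import MethylationRegion, bh_adjust, region_mean, wilcoxon_rank_sum

DEFAULT_REPORTING_SCALE = 0.1

STRATA = ("all", "kras_pos", "kras_neg", "age_young", "age_old",
          "male", "female", "early", "late", "colon", "rectum")


# ---------------------------------------------------------------------------
# univariate logistic regression (IRLS)

@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, standard errors, diagnostics."""

    coef: np.ndarray
    se: np.ndarray
    converged: bool
    separated: bool
    n_iter: int
    n_obs: int


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 1e-9,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares.

    ``X`` is the full design matrix (including any intercept column).
    A tiny ridge term keeps the normal equations solvable for constant
    predictors.  Complete separation is detected (all fitted
    probabilities at their labels, diverging coefficients) and flagged
    rather than raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + ridge * np.eye(p)
        beta_new = np.linalg.solve(H, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = (X.T * w) @ X + ridge * np.eye(p)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))

    fitted_at_labels = np.all(np.abs(mu - y) < 1e-6)
    separated = bool(
        (fitted_at_labels and np.max(np.abs(beta)) > 10)
        or (not converged and fitted_at_labels)
    )
    return LogisticFit(coef=beta, se=se, converged=converged,
                       separated=separated, n_iter=it, n_obs=n)


@dataclass
class UnivariateLogisticResult:
    coefficient: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    reporting_scale: float
    separated: bool
    n_used: int
    n_dropped: int
    note: str = ""


def fit_univariate_logistic(
    x,
    y,
    reporting_scale: float = DEFAULT_REPORTING_SCALE,
) -> UnivariateLogisticResult:
    """Univariate logistic fit of binary labels on one predictor.

    Samples with missing ``x`` are excluded (their count is reported).
    The odds ratio and its Wald 95% CI are reported per
    ``reporting_scale`` units of the predictor (default 0.1, i.e. per
    10-percentage-point increase in methylation).  Complete separation
    yields an infinite-OR sentinel with an explanatory note instead of
    an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    keep = np.isfinite(x)
    n_dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    classes = np.unique(y)
    if len(classes) != 2 or not set(classes) <= {0.0, 1.0}:
        raise InputError("y must contain both classes coded 0/1")

    X = np.column_stack([np.ones_like(x), x])
    fit = logistic_irls(X, y)
    b, se = fit.coef[1], fit.se[1]

    if fit.separated:
        sign = 1.0 if b >= 0 else -1.0
        return UnivariateLogisticResult(
            coefficient=sign * np.inf,
            odds_ratio=np.inf if sign > 0 else 0.0,
            ci_low=0.0, ci_high=np.inf, wald_p=np.nan,
            reporting_scale=reporting_scale, separated=True,
            n_used=fit.n_obs, n_dropped=n_dropped,
            note=("complete separation: the predictor perfectly divides the "
                  "classes; the ML odds ratio is unbounded and the Wald "
                  "interval is uninformative (a profile-likelihood or exact "
                  "method would be needed for a finite bound)"),
        )

    z = b / se if se > 0 else 0.0
    wald_p = float(2.0 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    return UnivariateLogisticResult(
        coefficient=float(b),
        odds_ratio=float(np.exp(b * reporting_scale)),
        ci_low=float(np.exp((b - half) * reporting_scale)),
        ci_high=float(np.exp((b + half) * reporting_scale)),
        wald_p=wald_p,
        reporting_scale=reporting_scale,
        separated=False,
        n_used=fit.n_obs,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# ROC / cutoff

def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(case score > control score) + half-ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.any(~np.isfinite(scores)):
        raise InputError("scores must be finite")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise InputError("auc requires both classes")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    n1, n0 = pos.size, neg.size
    return float((r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def youden_cutoff(scores, labels) -> tuple[float, float, float]:
    """Cutoff maximising sensitivity + specificity.

    A sample is called positive when its score is >= the cutoff.  Every
    distinct score is evaluated as a candidate cutoff; ties in
    sensitivity + specificity are broken toward higher specificity,
    then toward the lower cutoff.  Returns (cutoff, sens, spec).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise InputError("youden_cutoff requires both classes")

    best = None
    for t in np.unique(scores):
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        key = (sens + spec, spec, -t)
        if best is None or key > best[0]:
            best = (key, float(t), sens, spec)
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# stratified evaluation

@dataclass
class DiagnosticResult:
    """Diagnostic summary of one region in one sample stratum."""

    region: MethylationRegion
    stratum: str
    n_cases: int
    n_controls: int
    mcam: float
    mcom: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float              # Wilcoxon rank-sum, cases vs controls
    fdr: float
    wald_p: float
    cutoff: float
    sensitivity: float
    specificity: float
    auc: float
    separated: bool = False


def select_stratum(meta: pd.DataFrame, stratum: str) -> list[str]:
    """Tumor sample ids belonging to a stratum.

    The age split is at the median tumor age within the cohort (young:
    age <= median; old: age > median); stage splits early (I/II) from
    late (III/IV).
    """
    if stratum not in STRATA:
        raise StratumError(f"unknown stratum {stratum!r}; choose from {STRATA}")
    tumors = meta[meta["tissue"] == "tumor"]
    if stratum == "all":
        sel = tumors
    elif stratum == "kras_pos":
        sel = tumors[tumors["kras_status"] == "positive"]
    elif stratum == "kras_neg":
        sel = tumors[tumors["kras_status"] == "negative"]
    elif stratum in ("age_young", "age_old"):
        median = tumors["age"].median()
        sel = (tumors[tumors["age"] <= median] if stratum == "age_young"
               else tumors[tumors["age"] > median])
    elif stratum in ("male", "female"):
        sel = tumors[tumors["sex"] == stratum]
    elif stratum in ("early", "late"):
        groups = {"early": ("I", "II"), "late": ("III", "IV")}[stratum]
        sel = tumors[tumors["stage"].isin(groups)]
    else:  # colon / rectum
        sel = tumors[tumors["location"] == stratum]
    ids = list(sel["sample_id"])
    if not ids:
        raise StratumError(f"stratum {stratum!r} contains no tumor samples")
    return ids


def evaluate_marker(
    region: MethylationRegion,
    values: pd.DataFrame,
    meta: pd.DataFrame,
    stratum: str = "all",
    reporting_scale: float = DEFAULT_REPORTING_SCALE,
) -> DiagnosticResult:
    """Evaluate one region as a diagnostic marker within a stratum.

    ``values`` holds per-site per-sample methylation fractions (array
    betas or targeted ``site_fractions`` output).  The stratum selects
    tumors; all para-tumor samples serve as controls in every stratum.
    The returned ``fdr`` equals ``p_value`` until the caller adjusts it
    across a panel (see :func:`evaluate_panel`).
    """
    tumor_ids = select_stratum(meta, stratum)
    control_ids = list(meta.loc[meta["tissue"] == "para-tumor", "sample_id"])
    if not control_ids:
        raise StratumError("no para-tumor control samples in metadata")

    sample_ids = [s for s in tumor_ids + control_ids if s in values.columns]
    means = region_mean(values, region, sample_ids)
    labels = np.array([1 if s in set(tumor_ids) else 0 for s in means.index])
    keep = means.notna().to_numpy()
    x = means.to_numpy()[keep]
    y = labels[keep]
    if len(np.unique(y)) < 2:
        raise StratumError(
            f"stratum {stratum!r} lacks one class after missing-data removal")

    logit = fit_univariate_logistic(x, y, reporting_scale)
    roc_auc = auc(x, y)
    cutoff, sens, spec = youden_cutoff(x, y)
    p = wilcoxon_rank_sum(x[y == 1], x[y == 0])
    return DiagnosticResult(
        region=region, stratum=stratum,
        n_cases=int(y.sum()), n_controls=int((1 - y).sum()),
        mcam=float(x[y == 1].mean()), mcom=float(x[y == 0].mean()),
        odds_ratio=logit.odds_ratio, ci_low=logit.ci_low,
        ci_high=logit.ci_high, p_value=p, fdr=p, wald_p=logit.wald_p,
        cutoff=cutoff, sensitivity=sens, specificity=spec, auc=roc_auc,
        separated=logit.separated,
    )


def evaluate_panel(
    regions: list[MethylationRegion],
    values: pd.DataFrame,
    meta: pd.DataFrame,
    strata=("all", "kras_pos", "kras_neg"),
    reporting_scale: float = DEFAULT_REPORTING_SCALE,
) -> list[DiagnosticResult]:
    """Evaluate a marker panel in each stratum, BH-adjusting per stratum."""
    results = []
    for stratum in strata:
        block = [
            evaluate_marker(region, values, meta, stratum, reporting_scale)
            for region in regions
        ]
        fdrs = bh_adjust([r.p_value for r in block])
        for r, f in zip(block, fdrs):
            r.fdr = float(f)
        results.extend(block)
    return results


# ---------------------------------------------------------------------------
# subgroup comparison

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise InputError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.floor(table)) or np.any(table < 0):
            raise InputError("counts must be non-negative integers")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def predict_at_cutoff(scores, cutoff: float) -> np.ndarray:
    """Positive call iff score >= cutoff (matches youden_cutoff)."""
    return (np.asarray(scores, dtype=float) >= cutoff).astype(int)


def compare_subgroup_accuracy(
    predictions,
    truth,
    subgroup_labels,
) -> tuple[float, np.ndarray]:
    """Fisher exact comparison of prediction-accuracy between two subgroups.

    Builds the 2x2 table (rows: subgroups in sorted label order;
    columns: correct, incorrect predictions) and returns its two-sided
    Fisher p together with the table.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    subgroup_labels = np.asarray(subgroup_labels)
    groups = np.unique(subgroup_labels)
    if len(groups) != 2:
        raise StratumError(
            f"need exactly two subgroups, got {list(groups)}")
    correct = predictions == truth
    table = np.array([
        [int(correct[subgroup_labels == g].sum()),
         int((~correct[subgroup_labels == g]).sum())]
        for g in groups
    ])
    if (table.sum(axis=1) == 0).any():
        raise StratumError("a subgroup contains zero samples")
    return fisher_exact_2x2(table), table
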