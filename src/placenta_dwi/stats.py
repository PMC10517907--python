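"""Subject-level cohort statistics.

Group comparison of quantitative parameters and clinical covariates
(Welch t-test when both groups pass a Shapiro–Wilk normality check at
α = 0.05, Mann–Whitney U otherwise; Pearson chi-square with Yates
continuity correction for 2x2 categorical tables), multivariable
logistic risk modelling with Wald inference, empirical ROC analysis with
DeLong confidence intervals and the Youden-optimal cutoff, a closed-form
binormal AUC oracle, and gestational-age correlation.

The "adverse outcome" group is the positive class throughout.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import CohortTable

__all__ = [
    "GroupComparisonResult",
    "LogisticTerm",
    "LogisticModelResult",
    "ROCResult",
    "CorrelationResult",
    "compare_groups",
    "logistic_model",
    "backward_eliminate",
    "roc_analysis",
    "empirical_auc",
    "delong_ci",
    "binormal_auc",
    "ga_correlation",
]


@dataclasses.dataclass
class GroupComparisonResult:
    parameter: str
    mean_sd_by_group: dict      # group -> (mean, sd) or category proportions
    test: str                   # "t" | "mann_whitney" | "chi_square"
    statistic: float
    p: float
    continuity_correction: bool = False


@dataclasses.dataclass
class LogisticTerm:
    name: str
    coefficient: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclasses.dataclass
class LogisticModelResult:
    terms: list
    converged: bool
    separation_flag: bool
    llf: float = np.nan

    def term(self, name: str) -> LogisticTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclasses.dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str             # "higher_is_positive" | "lower_is_positive"
    degenerate: bool = False


@dataclasses.dataclass
class CorrelationResult:
    r: float
    p: float
    method: str
    n: int


# ---------------------------------------------------------------------------
# Group comparison


def compare_groups(cohort: CohortTable, variable: str) -> GroupComparisonResult:
    """Two-group comparison of one cohort column.

    Continuous columns: Shapiro–Wilk per group at α = 0.05; both normal
    -> Welch t-test, otherwise Mann–Whitney U (two-sided).  Categorical
    columns: Pearson chi-square, Yates-corrected for 2x2 tables.
    """
    df = cohort.df
    if variable not in df.columns:
        raise ValueError(f"variable {variable!r} not in cohort table")

    if pd.api.types.is_numeric_dtype(df[variable]):
        adv, non = cohort.split_groups(variable)
        if len(adv) < 2 or len(non) < 2:
            raise ValueError(f"each group needs >=2 observations of {variable!r}")
        normal = all(
            sps.shapiro(np.asarray(g, dtype=float)).pvalue >= 0.05
            for g in (adv, non)
        )
        summary = {
            "adverse": (float(adv.mean()), float(adv.std(ddof=1))),
            "non_adverse": (float(non.mean()), float(non.std(ddof=1))),
        }
        if normal:
            res = sps.ttest_ind(adv, non, equal_var=False)
            return GroupComparisonResult(variable, summary, "t",
                                         float(res.statistic), float(res.pvalue))
        res = sps.mannwhitneyu(adv, non, alternative="two-sided")
        return GroupComparisonResult(variable, summary, "mann_whitney",
                                     float(res.statistic), float(res.pvalue))

    table = pd.crosstab(df["group"], df[variable])
    if table.shape[0] != 2 or (table.sum(axis=1) == 0).any():
        raise ValueError(f"need both groups populated for {variable!r}")
    yates = table.shape == (2, 2)
    chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=yates)
    props = {
        g: (table.loc[g] / table.loc[g].sum()).to_dict() for g in table.index
    }
    return GroupComparisonResult(variable, props, "chi_square",
                                 float(chi2), float(p),
                                 continuity_correction=yates)


# ---------------------------------------------------------------------------
# Logistic risk model


def _outcome_vector(cohort: CohortTable) -> np.ndarray:
    return (cohort.df["group"].astype(str) == "adverse").to_numpy(dtype=float)


def logistic_model(cohort: CohortTable, covariates,
                   outcome: str = "group") -> LogisticModelResult:
    """Maximum-likelihood logistic regression of adverse outcome on
    covariates, with Wald CIs and per-term p-values.

    Complete or quasi-complete separation is detected and flagged; the
    coefficients then come from the last stable iterate rather than an
    exception.
    """
    if outcome != "group":
        raise ValueError("outcome must be the cohort group label")
    covariates = list(covariates)
    df = cohort.df
    if len(df) < 10:
        raise ValueError("need at least 10 subjects for a logistic model")
    for c in covariates:
        if c not in df.columns or not pd.api.types.is_numeric_dtype(df[c]):
            raise ValueError(f"covariate {c!r} missing or non-numeric")

    y = _outcome_vector(cohort)
    X = sm.add_constant(df[covariates].astype(float), has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            separation = True
            res = model.fit(disp=0, maxiter=35, method="bfgs")
    # quasi-separation shows up as fitted probabilities pinned to 0/1
    fitted = res.predict(X)
    if np.all((fitted < 1e-8) | (fitted > 1 - 1e-8)) or np.any(
            np.abs(res.params.to_numpy()) > 1e3):
        separation = True

    conf = res.conf_int()
    terms = []
    for name in X.columns:
        coef = float(res.params[name])
        terms.append(LogisticTerm(
            name=name,
            coefficient=coef,
            odds_ratio=float(np.exp(coef)),
            ci_low=float(np.exp(conf.loc[name, 0])),
            ci_high=float(np.exp(conf.loc[name, 1])),
            p=float(res.pvalues[name]),
        ))
    retvals = getattr(res, "mle_retvals", None)
    converged = bool(retvals.get("converged", True)) if isinstance(retvals, dict) else True
    return LogisticModelResult(terms=terms, converged=converged and not separation,
                               separation_flag=separation, llf=float(res.llf))


def backward_eliminate(cohort: CohortTable, candidates,
                       alpha: float = 0.05) -> LogisticModelResult:
    """Backward elimination on Wald p-values.

    Starts from all candidate covariates and repeatedly drops the least
    significant term (p >= alpha) until every remaining covariate is
    significant.  Returns the final fitted model.
    """
    remaining = list(candidates)
    while True:
        fit = logistic_model(cohort, remaining)
        covar_terms = [t for t in fit.terms if t.name != "const"]
        worst = max(covar_terms, key=lambda t: t.p)
        if worst.p < alpha or len(remaining) == 1:
            return fit
        remaining.remove(worst.name)


# ---------------------------------------------------------------------------
# ROC analysis


def empirical_auc(pos, neg) -> float:
    """Empirical (trapezoidal) AUC via the Mann–Whitney rank identity
    AUC = U / (n₁·n₂); ties contribute 1/2."""
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (len(pos) * len(neg))


_empirical_auc = empirical_auc


def delong_ci(scores, labels, level: float = 0.95) -> tuple:
    """DeLong variance-based confidence interval for the empirical AUC.

    Uses the placement-value (structural component) formulation; the
    interval is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    # placement values: P(neg < pos_i) and P(pos > neg_j) with tie = 1/2
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def roc_analysis(scores, labels, direction: str = "auto") -> ROCResult:
    """Empirical ROC with DeLong CI and Youden-optimal cutoff.

    ``labels`` is truthy for the positive (adverse) class.  With
    ``direction='auto'`` the orientation is flipped so the AUC is >= 0.5;
    a fixed direction is honoured as given.  The cutoff maximises
    Youden's J = sensitivity + specificity − 1; ties break toward higher
    specificity.  A positive call is score >= cutoff (higher-is-positive)
    or score <= cutoff (lower-is-positive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        return ROCResult(0.5, 0.5, 0.5, np.nan, np.nan, np.nan,
                         "higher_is_positive", degenerate=True)

    pos, neg = scores[labels], scores[~labels]
    if direction == "auto":
        direction = ("higher_is_positive"
                     if _empirical_auc(pos, neg) >= 0.5 else "lower_is_positive")
    elif direction not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")

    oriented = scores if direction == "higher_is_positive" else -scores
    auc, lo, hi = delong_ci(oriented, labels)

    # candidate cutoffs: the observed scores (oriented; call >= cutoff positive)
    cands = np.unique(oriented)
    best = None
    for c in cands:
        call = oriented >= c
        sens = float(np.mean(call[labels]))
        spec = float(np.mean(~call[~labels]))
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (
                abs(j - best[0]) <= 1e-12 and spec > best[2]):
            best = (j, sens, spec, c)
    _, sens, spec, cut = best
    cutoff = cut if direction == "higher_is_positive" else -cut
    return ROCResult(auc, lo, hi, float(cutoff), sens, spec, direction)


def binormal_auc(m_pos: float, s_pos: float, m_neg: float, s_neg: float) -> float:
    """Closed-form AUC Φ(|Δμ|/√(σ₊²+σ₋²)) for normal class scores."""
    if s_pos <= 0 or s_neg <= 0:
        raise ValueError("standard deviations must be positive")
    return float(sps.norm.cdf(abs(m_pos - m_neg) / np.hypot(s_pos, s_neg)))


# ---------------------------------------------------------------------------
# Gestational-age correlation


def ga_correlation(cohort: CohortTable, parameter: str,
                   method: str = "spearman",
                   ga_column: str = "ga_mri") -> CorrelationResult:
    """Correlation between a parameter and gestational age at MRI."""
    df = cohort.df[[parameter, ga_column]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete pairs")
    x = df[ga_column].to_numpy(dtype=float)
    y = df[parameter].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, method, len(df))
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r), float(p), method, len(df))
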