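"""Single-locus risk modeling: Firth-penalized and ML logistic regression on
risk-allele dosage, contingency summaries, stratified tests, group allele
frequencies, and multiple-testing utilities.

The Firth estimator maximizes the Jeffreys-penalized log-likelihood

    l*(b) = l(b) + 0.5 * log det I(b)

by modified-score Newton iterations with step-halving. It yields finite
estimates under the (quasi-)separation that arises when one genotype class
contains only cases — exactly the configuration of the lead-marker dosage
table, where no control is homozygous for the risk allele. Confidence
intervals and p-values come from the profile penalized likelihood, matching
the convention of the standard R implementation (logistf); Wald intervals
are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "RiskModelFit",
    "ContingencyTable",
    "PValueSet",
    "firth_logistic",
    "mle_logistic",
    "dosage_table",
    "expand_table",
    "contingency_summaries",
    "allelic_assoc",
    "cmh_test",
    "breslow_day",
    "bonferroni_threshold",
    "bh_fdr",
    "lambda_gc",
    "allele_freq_by_group",
]

_CHI2_1 = stats.chi2(1)


# ---------------------------------------------------------------------------
# Model-fit container
# ---------------------------------------------------------------------------

@dataclass
class RiskModelFit:
    """Coefficients and inference for a logistic risk model.

    ``odds_ratio == exp(beta)`` exactly; ``ci_low/ci_high`` are profile
    penalized-likelihood limits for the Firth estimator and Wald limits for
    the MLE. ``p_values`` are per-term penalized LRT (Firth) or Wald (MLE)
    p-values; ``lrt_p`` is the overall model test against intercept-only.
    """

    terms: list
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    lrt_p: float
    log_lik: float
    estimator: str
    converged: bool
    iterations: int
    separation: bool = False
    wald_ci_low: np.ndarray = None
    wald_ci_high: np.ndarray = None

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.beta)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def or_(self, term: str) -> float:
        return float(np.exp(self.beta[self.terms.index(term)]))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "se": self.se,
                "odds_ratio": np.exp(self.beta),
                "ci_low": np.exp(self.ci_low),
                "ci_high": np.exp(self.ci_high),
                "p": self.p_values,
            }
        )


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------

def _pll(X, y, w, beta):
    eta = X @ beta
    # log(1+e^eta) evaluated stably
    log1pe = np.logaddexp(0.0, eta)
    ll = float(np.sum(w * (y * eta - log1pe)))
    p = expit(eta)
    W = w * p * (1 - p)
    sign, logdet = np.linalg.slogdet((X * W[:, None]).T @ X)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_newton(X, y, w, free, beta0, tol, max_iter):
    """Maximize the penalized likelihood over the columns in ``free`` with the
    remaining coefficients held fixed at their values in ``beta0``. The
    Jeffreys penalty always uses the full design matrix."""
    beta = beta0.copy()
    converged = False
    it = 0
    cur = _pll(X, y, w, beta)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        W = w * p * (1 - p)
        XW = X * W[:, None]
        info = XW.T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (w * (y - p) + h * (0.5 - p))
        u = score[free]
        if np.max(np.abs(u)) < tol:
            converged = True
            break
        info_ff = info[np.ix_(free, free)]
        try:
            step = np.linalg.solve(info_ff, u)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        while lam > 1e-10:
            cand = beta.copy()
            cand[free] += lam * step
            new = _pll(X, y, w, cand)
            if new >= cur - 1e-12:
                beta, cur = cand, new
                break
            lam /= 2.0
        else:
            break
    return beta, cur, converged, it


def firth_logistic(
    X,
    y,
    weights=None,
    terms=None,
    tol: float = 1e-6,
    max_iter: int = 50,
    ci_level: float = 0.95,
    profile_ci: bool = True,
) -> RiskModelFit:
    """Firth-penalized logistic regression of a binary outcome on ``X``.

    Parameters
    ----------
    X
        Design matrix including an intercept column (full rank required).
    y
        Binary outcome in {0, 1}.
    weights
        Optional frequency weights (grouped/count data fits identically to
        the expanded individual-level fit).
    terms
        Column names; defaults to ``["x0", "x1", ...]`` with ``x0`` treated
        as the intercept for the overall LRT.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    n, k = X.shape
    if terms is None:
        terms = [f"x{j}" for j in range(k)]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")

    free_all = np.arange(k)
    beta, llmax, converged, iters = _firth_newton(
        X, y, w, free_all, np.zeros(k), tol, max_iter
    )

    # covariance at the optimum (inverse penalized information ~ inverse info)
    eta = X @ beta
    p = expit(eta)
    W = w * p * (1 - p)
    cov = np.linalg.inv((X * W[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))

    crit = _CHI2_1.ppf(ci_level)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    wald_lo, wald_hi = beta - z * se, beta + z * se

    def profile_pll(j, value):
        b0 = beta.copy()
        b0[j] = value
        free = np.array([i for i in range(k) if i != j])
        if len(free) == 0:
            return _pll(X, y, w, b0)
        _, ll, _, _ = _firth_newton(X, y, w, free, b0, tol, max_iter)
        return ll

    pvals = np.full(k, np.nan)
    lo = np.full(k, np.nan)
    hi = np.full(k, np.nan)
    if converged and profile_ci:
        for j in range(k):
            ll0 = profile_pll(j, 0.0)
            pvals[j] = _CHI2_1.sf(max(0.0, 2.0 * (llmax - ll0)))

            def dev(b, j=j):
                val = 2.0 * (llmax - profile_pll(j, b)) - crit
                return val if np.isfinite(val) else 1e6

            for bound, sign in ((lo, -1.0), (hi, +1.0)):
                step = max(2.0 * se[j], 0.5)
                outer = beta[j] + sign * step
                for _ in range(40):
                    if dev(outer) > 0:
                        break
                    outer += sign * step
                else:
                    bound[j] = sign * np.inf
                    continue
                a, b_ = sorted((beta[j], outer))
                bound[j] = brentq(dev, a, b_, xtol=1e-6)

    # overall penalized LRT vs intercept-only (intercept assumed in col 0)
    lrt_p = np.nan
    if converged and k > 1:
        b0 = np.zeros(k)
        _, ll_null, _, _ = _firth_newton(X, y, w, np.array([0]), b0, tol, max_iter)
        lrt_p = stats.chi2(k - 1).sf(max(0.0, 2.0 * (llmax - ll_null)))

    return RiskModelFit(
        terms=list(terms), beta=beta, se=se,
        ci_low=lo, ci_high=hi, p_values=pvals, lrt_p=float(lrt_p),
        log_lik=llmax, estimator="firth", converged=converged,
        iterations=iters, wald_ci_low=wald_lo, wald_ci_high=wald_hi,
    )


def mle_logistic(
    X, y, weights=None, terms=None, ci_level: float = 0.95
) -> RiskModelFit:
    """Maximum-likelihood logistic regression (binomial GLM) via statsmodels.

    Separation is detected (diverging coefficients / vanishing residual
    deviance) and flagged rather than silently reported.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    n, k = X.shape
    if terms is None:
        terms = [f"x{j}" for j in range(k)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
        res = model.fit(maxiter=200)
    beta = np.asarray(res.params)
    se = np.asarray(res.bse)
    separation = bool(np.any(np.abs(beta) > 15) or np.any(se > 500))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    pvals = np.asarray(res.pvalues)
    # overall LRT vs intercept-only
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = sm.GLM(
            y, X[:, :1], family=sm.families.Binomial(), freq_weights=w
        ).fit()
    lrt_p = stats.chi2(k - 1).sf(2.0 * (res.llf - null.llf)) if k > 1 else np.nan
    return RiskModelFit(
        terms=list(terms), beta=beta, se=se,
        ci_low=beta - z * se, ci_high=beta + z * se,
        p_values=pvals, lrt_p=float(lrt_p), log_lik=float(res.llf),
        estimator="mle", converged=bool(res.converged) and not separation,
        iterations=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        separation=separation,
        wald_ci_low=beta - z * se, wald_ci_high=beta + z * se,
    )


# ---------------------------------------------------------------------------
# Contingency tables and summaries
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Dosage (0/1/2) x status (case/control) counts per cohort.

    ``counts[cohort]`` is a 3x2 array with columns (case, control).
    """

    counts: dict

    def __post_init__(self):
        for name, c in self.counts.items():
            c = np.asarray(c, dtype=np.int64)
            if c.shape != (3, 2) or (c < 0).any():
                raise ValueError(f"cohort {name!r}: counts must be 3x2 non-negative")
            self.counts[name] = c

    @property
    def pooled(self) -> np.ndarray:
        if not self.counts:
            return np.zeros((3, 2), dtype=np.int64)
        return np.sum(list(self.counts.values()), axis=0)

    def cohort(self, name: str) -> np.ndarray:
        return self.counts[name]


def dosage_table(cohort, dosages) -> ContingencyTable:
    """Cross-tabulate risk-allele dosage by case/control status per cohort.

    ``dosages`` is a per-dog vector aligned with ``cohort.table`` rows.
    """
    df = cohort.table
    d = np.asarray(dosages)
    if len(d) != len(df):
        raise ValueError("dosage vector does not match cohort size")
    out = {}
    for name, sub in df.groupby("cohort_label", sort=True):
        c = np.zeros((3, 2), dtype=np.int64)
        for dose, status in zip(d[sub.index], sub.status):
            c[int(dose), 0 if status == "case" else 1] += 1
        out[name] = c
    return ContingencyTable(out)


def expand_table(table: np.ndarray | ContingencyTable, cohort_covariate=True):
    """Expand a contingency table into (X, y, weights, terms) for model fits.

    Design: intercept, additive dosage, and (for multi-cohort tables) one
    indicator per non-reference cohort in sorted name order.
    """
    if isinstance(table, ContingencyTable):
        cohorts = sorted(table.counts)
        rows, y, w = [], [], []
        for ci, name in enumerate(cohorts):
            c = table.counts[name]
            for dose in range(3):
                for si, status in enumerate((1, 0)):
                    if c[dose, si] == 0:
                        continue
                    ind = [1.0 if (cohort_covariate and ci == j + 1) else 0.0
                           for j in range(len(cohorts) - 1)]
                    rows.append([1.0, float(dose)] + ind)
                    y.append(float(status))
                    w.append(float(c[dose, si]))
        terms = ["intercept", "dosage"] + (
            [f"cohort_{c}" for c in cohorts[1:]] if cohort_covariate else []
        )
        if not cohort_covariate:
            rows = [r[:2] for r in rows]
        return np.array(rows), np.array(y), np.array(w), terms
    c = np.asarray(table, dtype=np.int64)
    rows, y, w = [], [], []
    for dose in range(3):
        for si, status in enumerate((1, 0)):
            if c[dose, si]:
                rows.append([1.0, float(dose)])
                y.append(float(status))
                w.append(float(c[dose, si]))
    return np.array(rows), np.array(y), np.array(w), ["intercept", "dosage"]


def contingency_summaries(counts: np.ndarray) -> dict:
    """Carrier fractions per status and per-dosage penetrance for a 3x2 table."""
    c = np.asarray(counts, dtype=float)
    n_case, n_ctrl = c[:, 0].sum(), c[:, 1].sum()
    if n_case + n_ctrl == 0:
        raise ValueError("empty table")
    carriers = c[1:, :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        penetrance = c[:, 0] / c.sum(axis=1)
    return {
        "case_carrier_fraction": carriers[0] / n_case if n_case else np.nan,
        "control_carrier_fraction": carriers[1] / n_ctrl if n_ctrl else np.nan,
        "penetrance_by_dosage": penetrance,
        "n_cases": int(n_case),
        "n_controls": int(n_ctrl),
    }


# ---------------------------------------------------------------------------
# Allelic and stratified association
# ---------------------------------------------------------------------------

def allelic_assoc(table2x2) -> dict:
    """Pearson chi-square and cross-product odds ratio for a 2x2 allele table.

    Rows = (case, control), columns = (risk, non-risk) allele counts. A 0.5
    continuity value is added to every cell only when some cell is zero, and
    the correction is flagged in the output.
    """
    t = np.asarray(table2x2, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum(axis=0).min() <= 0 or t.sum(axis=1).min() <= 0:
        raise ValueError("zero margin in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    corrected = bool((t == 0).any())
    tc = t + 0.5 if corrected else t
    orr = (tc[0, 0] * tc[1, 1]) / (tc[0, 1] * tc[1, 0])
    return {
        "chi2": float(chi2),
        "p": float(p),
        "odds_ratio": float(orr),
        "case_freq": float(t[0, 0] / t[0].sum()),
        "control_freq": float(t[1, 0] / t[1].sum()),
        "continuity_corrected": corrected,
    }


def _stratified(tables):
    from statsmodels.stats.contingency_tables import StratifiedTable

    arr = np.stack([np.asarray(t, dtype=float) for t in tables], axis=-1)
    return StratifiedTable(arr)


def cmh_test(tables) -> dict:
    """Cochran-Mantel-Haenszel 1-df test (no continuity correction) and the
    Mantel-Haenszel common odds ratio over stratified 2x2 allele tables."""
    st = _stratified(tables)
    res = st.test_null_odds(correction=False)
    return {
        "chi2": float(res.statistic),
        "p": float(res.pvalue),
        "common_or": float(st.oddsratio_pooled),
    }


def breslow_day(tables) -> dict:
    """Breslow-Day homogeneity-of-odds-ratios test (k-1 df chi-square)."""
    st = _stratified(tables)
    res = st.test_equal_odds(adjust=False)
    return {"chi2": float(res.statistic), "p": float(res.pvalue),
            "df": len(tables) - 1}


# ---------------------------------------------------------------------------
# Multiple testing and inflation
# ---------------------------------------------------------------------------

@dataclass
class PValueSet:
    """Raw and BH-adjusted p-values with Bonferroni significance flags."""

    marker_ids: np.ndarray
    p_raw: np.ndarray
    p_bh: np.ndarray
    bonferroni_significant: np.ndarray
    threshold: float

    @classmethod
    def from_pvalues(cls, marker_ids, p, alpha: float = 0.05,
                     m: int | None = None) -> "PValueSet":
        p = np.asarray(p, dtype=float)
        thr = bonferroni_threshold(alpha, m if m is not None else len(p))
        return cls(
            marker_ids=np.asarray(marker_ids, dtype=object),
            p_raw=p, p_bh=bh_fdr(p),
            bonferroni_significant=p < thr, threshold=thr,
        )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def lambda_gc(p) -> float:
    """Genomic inflation factor from two-sided p-values via the 1-df
    chi-square quantile transform: median(chi2)/0.45494."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = _CHI2_1.isf(p)
    return float(np.median(chi2) / _CHI2_1.ppf(0.5))


def allele_freq_by_group(dosages, groups) -> pd.DataFrame:
    """Risk-allele frequency per group as count/chromosomes.

    Returns one row per group plus a pooled ``__all__`` row; the pooled
    frequency is the chromosome-weighted mean of group frequencies.
    """
    d = np.asarray(dosages, dtype=np.int64)
    g = np.asarray(groups, dtype=object)
    rows = []
    for name in sorted(set(g.tolist())):
        sel = g == name
        chroms = 2 * int(sel.sum())
        count = int(d[sel].sum())
        rows.append((name, count, chroms, count / chroms))
    total_c, total_n = int(d.sum()), 2 * len(d)
    rows.append(("__all__", total_c, total_n, total_c / total_n))
    return pd.DataFrame(rows, columns=["group", "risk_alleles", "chromosomes",
                                       "frequency"])
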