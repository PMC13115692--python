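"""Carrier-restricted modifier analyses: onset summaries, temporality-
constrained gonadectomy exposure, a Firth logistic modifier model, the
counting-process (start-stop) construction, and time-varying Cox
regression with robust errors clustered by dog.

Exposure rule: a case counts as exposed only if gonadectomy happened before
seizure onset *and* before the landmark age (5 years primary, 2 years as a
sensitivity cutoff); a control counts as exposed if gonadectomy happened
before the landmark. Everyone else (intact, late-gonadectomized,
post-onset-gonadectomized) is unexposed. This ordering constraint guards
against reverse causation.

Counting-process rule: a dog contributes one interval from birth to its
endpoint (onset for cases, last follow-up for controls) unless it was
gonadectomized before the landmark and before the endpoint, in which case
it contributes an unexposed interval [0, gonadectomy age) followed by an
exposed interval [gonadectomy age, endpoint). No left truncation is
applied: all dogs enter at birth. Ties use the Efron approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import RiskModelFit, firth_logistic
from .io import CohortTable

__all__ = [
    "ExposureDefinition",
    "OnsetSummary",
    "SurvivalFit",
    "onset_summary",
    "classify_exposure",
    "firth_modifier_model",
    "build_counting_process",
    "cox_tv_fit",
    "ph_check",
    "carriers_subset",
]


@dataclass(frozen=True)
class ExposureDefinition:
    """Landmark age (years) for the gonadectomy-exposure rule."""

    landmark_years: float = 5.0
    rule_id: str = "pre-onset-pre-landmark"

    def __post_init__(self):
        if not self.landmark_years > 0:
            raise ValueError("landmark must be positive")


@dataclass
class OnsetSummary:
    group: str
    n: int
    median: float
    q25: float
    q75: float


@dataclass
class SurvivalFit:
    """Hazard ratios with cluster-robust inference and a PH check hook."""

    terms: list
    log_hr: np.ndarray
    hr: np.ndarray
    se: np.ndarray            # robust (cluster-by-dog) standard errors
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    n_events: int
    monotone_flag: bool
    model: object = None      # fitted lifelines CoxTimeVaryingFitter

    def hr_of(self, term: str) -> float:
        return float(self.hr[self.terms.index(term)])


def carriers_subset(cohort: CohortTable, dosages,
                    require_gonadectomy_info: bool = True) -> pd.DataFrame:
    """Risk-allele carriers (dosage >= 1), the modifier-analysis population.

    Gonadectomized dogs lacking a gonadectomy age cannot be classified and
    are dropped with a log entry (returned under the frame's ``attrs``).
    """
    df = cohort.table.copy()
    df["dosage"] = np.asarray(dosages)
    out = df[df.dosage >= 1].reset_index(drop=True)
    dropped = []
    if require_gonadectomy_info:
        bad = (out.gonadal_status == "gonadectomized") & \
            out.age_gonadectomy_years.isna()
        dropped = out.loc[bad, "dog_id"].tolist()
        out = out[~bad].reset_index(drop=True)
    out.attrs["dropped_missing_gonadectomy"] = dropped
    return out


def onset_summary(carrier_cases: pd.DataFrame) -> list:
    """Median and IQR of onset age per sex among carrier cases.

    Quantiles use the linear-interpolation convention (numpy default,
    type-7 style).
    """
    df = carrier_cases
    cases = df[(df.status == "case") & df.age_onset_years.notna()]
    if not len(cases):
        raise ValueError("no cases with onset age")
    out = []
    for sex, sub in cases.groupby("sex", sort=True):
        ages = sub.age_onset_years.to_numpy(dtype=float)
        q25, med, q75 = np.quantile(ages, [0.25, 0.5, 0.75])
        out.append(OnsetSummary(group=str(sex), n=len(ages),
                                median=float(med), q25=float(q25),
                                q75=float(q75)))
    return out


def classify_exposure(row, definition: ExposureDefinition) -> bool:
    """Apply the temporality-constrained exposure rule to one dog."""
    if row["gonadal_status"] != "gonadectomized":
        return False
    a_g = row["age_gonadectomy_years"]
    if pd.isna(a_g):
        raise ValueError(f"gonadectomized dog {row['dog_id']} lacks an age")
    if a_g >= definition.landmark_years:
        return False
    if row["status"] == "case":
        return bool(a_g < row["age_onset_years"])
    return True


def firth_modifier_model(carriers: pd.DataFrame,
                         definition: ExposureDefinition) -> RiskModelFit:
    """Firth-penalized logistic model: status ~ exposure + male sex.

    Restricted to carriers; delegates to the shared Firth estimator, so the
    fit stays finite under the sparse-cell separation typical of this
    design. ORs carry profile penalized-likelihood CIs; the overall fit is
    the penalized LRT.
    """
    df = carriers
    exposed = df.apply(lambda r: classify_exposure(r, definition), axis=1)
    y = (df.status == "case").astype(float).to_numpy()
    X = np.column_stack([
        np.ones(len(df)),
        exposed.astype(float).to_numpy(),
        (df.sex == "M").astype(float).to_numpy(),
    ])
    return firth_logistic(X, y, terms=["intercept", "exposed", "male"])


def build_counting_process(carriers: pd.DataFrame,
                           definition: ExposureDefinition) -> pd.DataFrame:
    """Start-stop rows (dog_id, start, stop, exposed, event, male).

    Rows per dog partition [0, endpoint]; exposure switches 0 -> 1 at most
    once (at the gonadectomy age). A gonadectomy age exactly at the
    endpoint would create a zero-length exposed interval and instead yields
    a single unexposed interval (recorded in ``attrs['zero_length_dropped']``).
    """
    rows = []
    zero_dropped = []
    for r in carriers.to_dict("records"):
        is_case = r["status"] == "case"
        endpoint = r["age_onset_years"] if is_case else r["age_last_followup_years"]
        if pd.isna(endpoint):
            raise ValueError(f"dog {r['dog_id']}: endpoint age missing")
        male = 1 if r["sex"] == "M" else 0
        a_g = r.get("age_gonadectomy_years", np.nan)
        qualifies = (
            r["gonadal_status"] == "gonadectomized"
            and not pd.isna(a_g)
            and a_g < definition.landmark_years
            and a_g <= endpoint
        )
        if qualifies and a_g == endpoint:
            zero_dropped.append(r["dog_id"])
        split = qualifies and a_g < endpoint
        if split:
            rows.append((r["dog_id"], 0.0, float(a_g), 0, 0, male))
            rows.append((r["dog_id"], float(a_g), float(endpoint), 1,
                         1 if is_case else 0, male))
        else:
            rows.append((r["dog_id"], 0.0, float(endpoint), 0,
                         1 if is_case else 0, male))
    cp = pd.DataFrame(rows, columns=["dog_id", "start", "stop", "exposed",
                                     "event", "male"])
    if (cp.stop <= cp.start).any():
        bad = cp.loc[cp.stop <= cp.start, "dog_id"].tolist()
        raise ValueError(f"non-positive interval for dogs {bad}")
    cp.attrs["zero_length_dropped"] = zero_dropped
    return cp


def cox_tv_fit(cp: pd.DataFrame, ci_level: float = 0.95,
               robust: bool = True) -> SurvivalFit:
    """Cox partial likelihood on start-stop data (Efron ties) with a
    time-varying exposure and male sex, sandwich variance clustered by dog.

    A monotone partial likelihood (e.g. every event in the exposed state)
    is flagged rather than hidden.
    """
    from lifelines import CoxTimeVaryingFitter
    from lifelines.exceptions import ConvergenceError

    if cp.event.sum() == 0:
        raise ValueError("no events in the counting-process table")
    monotone = False
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    # constant covariates (e.g. nobody gonadectomized) are not estimable
    covs = [c for c in ("exposed", "male") if cp[c].nunique() > 1]
    if not covs:
        raise ValueError("no varying covariates to fit")
    data = cp[["dog_id", "start", "stop", "event"] + covs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            ctv.fit(data, id_col="dog_id", event_col="event",
                    start_col="start", stop_col="stop", show_progress=False)
        except ConvergenceError:
            # monotone partial likelihood; a light ridge keeps estimates
            # finite while the flag marks them as unstable
            monotone = True
            ctv = CoxTimeVaryingFitter(penalizer=0.1)
            ctv.fit(data, id_col="dog_id", event_col="event",
                    start_col="start", stop_col="stop", show_progress=False)
    terms = list(ctv.params_.index)
    beta = ctv.params_.to_numpy()
    if robust:
        se = _cluster_robust_se(cp, terms, beta,
                                ctv.variance_matrix_.to_numpy())
    else:
        se = ctv.standard_errors_.to_numpy()
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    events_exposed = cp.loc[cp.event == 1, "exposed"]
    monotone = monotone or bool(np.any(np.abs(beta) > 15)) or (
        len(events_exposed) > 0 and events_exposed.nunique() == 1
        and cp.exposed.nunique() > 1
    )
    return SurvivalFit(
        terms=terms,
        log_hr=beta, hr=np.exp(beta), se=se,
        ci_low=np.exp(beta - z * se), ci_high=np.exp(beta + z * se),
        p_values=2.0 * stats.norm.sf(np.abs(beta / se)),
        n_events=int(cp.event.sum()), monotone_flag=monotone, model=ctv,
    )


def _cluster_robust_se(cp: pd.DataFrame, terms, beta, naive_cov):
    """Sandwich standard errors with score residuals summed within dog.

    Score residuals use the Breslow tie convention (the usual sandwich
    approximation even when the point estimates use Efron weights).
    """
    X = cp[terms].to_numpy(dtype=float)
    start = cp["start"].to_numpy(dtype=float)
    stop = cp["stop"].to_numpy(dtype=float)
    event = cp["event"].to_numpy(dtype=int)
    w = np.exp(X @ beta)
    U = np.zeros_like(X)
    for t in np.sort(np.unique(stop[event == 1])):
        in_risk = (start < t) & (stop >= t)
        s0 = w[in_risk].sum()
        xbar = (w[in_risk, None] * X[in_risk]).sum(axis=0) / s0
        d = int(((stop == t) & (event == 1)).sum())
        centered = X[in_risk] - xbar
        U[in_risk] -= d * (w[in_risk, None] / s0) * centered
        ev = (stop == t) & (event == 1)
        U[ev] += X[ev] - xbar
    G = pd.DataFrame(U).groupby(cp["dog_id"].to_numpy()).sum().to_numpy()
    meat = G.T @ G
    V = naive_cov @ meat @ naive_cov
    return np.sqrt(np.diag(V))


def _schoenfeld_residuals(cp: pd.DataFrame, terms, beta):
    """Schoenfeld residuals and summed risk-set information for start-stop
    data; one residual per event."""
    X = cp[terms].to_numpy(dtype=float)
    start = cp["start"].to_numpy(dtype=float)
    stop = cp["stop"].to_numpy(dtype=float)
    event = cp["event"].to_numpy(dtype=int)
    risk = np.exp(X @ beta)
    k = X.shape[1]
    out_t, out_r = [], []
    info = np.zeros((k, k))
    for t in np.sort(np.unique(stop[event == 1])):
        in_risk = (start < t) & (stop >= t)
        w = risk[in_risk]
        Xr = X[in_risk]
        tot = w.sum()
        xbar = (w[:, None] * Xr).sum(axis=0) / tot
        Xc = Xr - xbar
        V = (w[:, None] * Xc).T @ Xc / tot
        for i in np.flatnonzero((stop == t) & (event == 1)):
            out_t.append(t)
            out_r.append(X[i] - xbar)
            info += V
    return np.asarray(out_t), np.asarray(out_r), info


def ph_check(fit: SurvivalFit, cp: pd.DataFrame,
             transform: str = "rank") -> pd.DataFrame:
    """Proportional-hazards check from scaled Schoenfeld residuals.

    For each term, a 1-df score test of the correlation between the scaled
    residuals and a transform of event time (``rank`` or ``identity``),
    following the Grambsch-Therneau construction. Residuals exist only at
    event times.
    """
    terms = list(fit.terms)
    t, r, info = _schoenfeld_residuals(cp, terms, fit.log_hr)
    d = len(t)
    if d < 3:
        raise ValueError("too few events for a PH check")
    if transform == "rank":
        g = stats.rankdata(t)
    elif transform == "identity":
        g = t.copy()
    else:
        raise ValueError("transform must be 'rank' or 'identity'")
    g = g - g.mean()
    A = np.linalg.inv(info)  # model-based covariance from risk-set information
    proj = r @ A.T
    denom_g = float(g @ g)
    rows = []
    for j, term in enumerate(terms):
        num = float(g @ proj[:, j])
        chi2 = d * num * num / (A[j, j] * denom_g)
        rows.append((term, chi2, float(stats.chi2(1).sf(chi2))))
    return pd.DataFrame(rows, columns=["term", "chi2", "p"])
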