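"""Cumulative incidence, Cox regression and log-rank tests by stratum.

Clinical events enter as (time, status) with status 1 = event of
interest, 2 = competing event (death before the event, by default), 0 =
censored at end of follow-up.  The cumulative incidence function uses the
Aalen-Johansen estimator; a plain 1 − Kaplan-Meier variant is available
for sensitivity.  The Cox model maximizes the Breslow partial likelihood
by Newton-Raphson with step-halving and flags monotone-likelihood
(separation) instead of returning a huge finite coefficient.  Group
comparisons use the standard log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .stratify import SplitResult

EVENT, CENSORED, COMPETING = 1, 0, 2

#: supported clinical endpoints -> (flag column, day column) or aGvHD rule
OUTCOME_DEFS = {
    "agvhd_2to4": None,          # grade >= 2, onset day
    "agvhd_any": None,           # grade >= 1, onset day
    "agvhd_skin": None,          # grade >= 1 with skin involvement
    "ebv": ("ebv", "ebv_day"),
    "cmv": ("cmv", "cmv_day"),
    "adv": ("adv_gi", "adv_gi_day"),
    "adv_systemic": ("adv_systemic", "adv_systemic_day"),
    "relapse": ("relapse", "relapse_day"),
}


@dataclass
class SurvivalDataset:
    time: np.ndarray       # positive days
    status: np.ndarray     # 0 censored, 1 event, 2 competing
    group: np.ndarray | None = None      # binary group labels (any hashable)
    covariates: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if (self.time <= 0).any():
            raise ValueError("all times must be positive")
        if self.group is not None:
            self.group = np.asarray(self.group)
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, float))
            if self.covariates.shape[0] != len(self.time):
                self.covariates = self.covariates.T


@dataclass
class CIFCurve:
    """Right-continuous step function of cumulative incidence over days."""

    times: np.ndarray          # distinct event days (steps)
    cif: np.ndarray            # cumulative incidence after each step
    at_risk: np.ndarray        # subjects at risk just before each step

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.cif[idx]) if idx >= 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.times, "cumulative_incidence": self.cif,
                             "at_risk": self.at_risk})


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    ci95: tuple[float, float]
    logrank_p: float = float("nan")
    converged: bool = True
    monotone_likelihood: bool = False
    n_events: int = 0


def cumulative_incidence(dataset: SurvivalDataset,
                         method: str = "aalen-johansen") -> CIFCurve:
    """CIF of the event of interest with competing-risk handling.

    ``method``: "aalen-johansen" (default; competing events reduce the
    event probability properly) or "one-minus-km" (competing events
    treated as censoring).
    """
    t, s = dataset.time, dataset.status
    if len(t) == 0:
        raise ValueError("empty dataset")
    if method == "one-minus-km":
        s = np.where(s == COMPETING, CENSORED, s)
    order = np.lexsort((s == CENSORED, t))  # events before censorings at ties
    t, s = t[order], s[order]
    n = len(t)
    times, cifs, risks = [], [], []
    surv, cif = 1.0, 0.0
    for u in np.unique(t):
        at_risk = int((t >= u).sum())
        d_event = int(((t == u) & (s == EVENT)).sum())
        d_comp = int(((t == u) & (s == COMPETING)).sum())
        if d_event + d_comp == 0:
            continue
        cif += surv * d_event / at_risk
        surv *= 1.0 - (d_event + d_comp) / at_risk
        times.append(u)
        cifs.append(cif)
        risks.append(at_risk)
    return CIFCurve(np.asarray(times), np.asarray(cifs), np.asarray(risks))


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# ---------------------------------------------------------------------------

def _cox_loglik(beta: np.ndarray, t, d, X):
    """Breslow log partial likelihood with gradient and information."""
    eta = X @ beta
    w = np.exp(eta)
    ll, grad, info = 0.0, np.zeros(len(beta)), np.zeros((len(beta), len(beta)))
    for u in np.unique(t[d]):
        died = (t == u) & d
        at_risk = t >= u
        m = int(died.sum())
        s0 = w[at_risk].sum()
        s1 = X[at_risk].T @ w[at_risk]
        s2 = (X[at_risk].T * w[at_risk]) @ X[at_risk]
        ll += eta[died].sum() - m * np.log(s0)
        grad += X[died].sum(axis=0) - m * s1 / s0
        info += m * (s2 / s0 - np.outer(s1, s1) / s0 ** 2)
    return ll, grad, info


def cox_fit(dataset: SurvivalDataset, covariates: np.ndarray | None = None,
            tol: float = 1e-8, max_iter: int = 50) -> CoxResult:
    """Newton-Raphson Cox fit with step-halving and separation detection.

    Competing-risk status is treated as censoring for the cause-specific
    hazard.  Monotone likelihood (|beta| drifting beyond 15) is flagged
    rather than reported as a finite estimate.
    """
    X = covariates if covariates is not None else dataset.covariates
    if X is None and dataset.group is not None:
        levels = np.unique(dataset.group)
        if len(levels) != 2:
            raise ValueError("group must be binary to encode a covariate")
        X = (dataset.group == levels[1]).astype(float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(dataset.time):
        X = X.T
    t = dataset.time
    d = dataset.status == EVENT
    n_events = int(d.sum())
    if n_events == 0:
        raise ValueError("no events in dataset")
    if any(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
        raise ValueError("constant covariate")

    beta = np.zeros(X.shape[1])
    ll, grad, info = _cox_loglik(beta, t, d, X)
    converged, monotone = False, False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            monotone = True
            break
        # step-halving: never decrease the log partial likelihood
        alpha = 1.0
        for _ in range(30):
            new_beta = beta + alpha * step
            new_ll, new_grad, new_info = _cox_loglik(new_beta, t, d, X)
            if new_ll >= ll - 1e-12:
                break
            alpha /= 2.0
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.abs(beta).max() > 15.0:
            monotone = True
            break
        if np.abs(alpha * step).max() < tol:
            converged = True
            break
    if monotone:
        return CoxResult(beta=float("nan"), hr=float("nan"), se=float("nan"),
                         ci95=(float("nan"), float("nan")), converged=False,
                         monotone_likelihood=True, n_events=n_events)
    var = np.linalg.inv(info)
    b = float(beta[0])
    se = float(np.sqrt(var[0, 0]))
    return CoxResult(beta=b, hr=float(np.exp(b)), se=se,
                     ci95=(float(np.exp(b - 1.96 * se)),
                           float(np.exp(b + 1.96 * se))),
                     converged=converged, n_events=n_events)


def logrank_test(dataset: SurvivalDataset, group: np.ndarray | None = None
                 ) -> tuple[float, float]:
    """Two-group log-rank test; competing status counts as censoring.

    Hypergeometric observed-minus-expected accumulation over distinct
    event times; p from chi-square(1).
    """
    g = group if group is not None else dataset.group
    g = np.asarray(g)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError("log-rank test requires exactly two non-empty groups")
    t = dataset.time
    d = dataset.status == EVENT
    in1 = g == levels[1]
    o_minus_e, var = 0.0, 0.0
    for u in np.unique(t[d]):
        at_risk = t >= u
        n_total = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d_total = int((d & (t == u)).sum())
        d1 = int((d & (t == u) & in1).sum())
        if n_total < 2:
            continue
        o_minus_e += d1 - d_total * n1 / n_total
        var += (d_total * (n1 / n_total) * (1 - n1 / n_total)
                * (n_total - d_total) / (n_total - 1))
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# cohort-level endpoint analysis
# ---------------------------------------------------------------------------

def build_survival(cohort: Cohort, outcome: str,
                   competing_death: bool = True,
                   competing_relapse: bool = False
                   ) -> tuple[SurvivalDataset, pd.Index]:
    """(time, status) per patient for one endpoint.

    Event time = onset day; death before the event is a competing risk
    (default); censoring at end of follow-up.  Patients with a missing or
    non-positive onset day despite an event flag are excluded.  Returns
    the dataset and the patient index it covers.
    """
    if outcome not in OUTCOME_DEFS:
        raise KeyError(f"unknown outcome {outcome!r}; "
                       f"choose from {sorted(OUTCOME_DEFS)}")
    o = cohort.outcomes.set_index("patient_id")
    times, status, keep = [], [], []
    for pid, row in o.iterrows():
        fup = float(row["followup_days"])
        if outcome.startswith("agvhd"):
            grade = int(row["agvhd_grade"])
            organs = str(row["agvhd_organs"])
            if outcome == "agvhd_2to4":
                has = grade >= 2
            elif outcome == "agvhd_skin":
                has = grade >= 1 and "skin" in organs
            else:
                has = grade >= 1
            day = row["agvhd_onset_day"]
        else:
            flag, daycol = OUTCOME_DEFS[outcome]
            has = bool(row[flag])
            day = row[daycol]
        if has and (pd.isna(day) or float(day) <= 0):
            continue  # event without usable onset: excluded
        death_day = row["death_day"]
        competing_days = []
        if competing_death and bool(row["death"]) and not pd.isna(death_day):
            competing_days.append(float(death_day))
        if competing_relapse and bool(row["relapse"]) \
                and not pd.isna(row["relapse_day"]) and outcome != "relapse":
            competing_days.append(float(row["relapse_day"]))
        comp_day = min(competing_days) if competing_days else np.inf
        if has and float(day) <= comp_day:
            times.append(float(day))
            status.append(EVENT)
        elif comp_day < np.inf:
            times.append(comp_day)
            status.append(COMPETING)
        else:
            times.append(max(fup, 1.0))
            status.append(CENSORED)
        keep.append(pid)
    return SurvivalDataset(np.asarray(times), np.asarray(status)), pd.Index(keep)


@dataclass
class StratumOutcome:
    outcome: str
    subset: str
    curves: dict[str, CIFCurve]
    curves_km: dict[str, CIFCurve]       # 1-KM sensitivity variant
    logrank_chi2: float
    logrank_p: float
    cox: CoxResult

    def to_dict(self) -> dict:
        d = {"outcome": self.outcome, "subset": self.subset,
             "logrank_chi2": self.logrank_chi2, "logrank_p": self.logrank_p,
             "cox": {"beta": self.cox.beta, "hr": self.cox.hr,
                     "se": self.cox.se, "ci95": list(self.cox.ci95),
                     "converged": self.cox.converged,
                     "monotone_likelihood": self.cox.monotone_likelihood,
                     "n_events": self.cox.n_events}}
        d["final_cif"] = {g: (float(c.cif[-1]) if len(c.cif) else 0.0)
                          for g, c in self.curves.items()}
        return d


def outcome_by_stratum(cohort: Cohort, split: SplitResult, outcome: str,
                       competing_death: bool = True,
                       competing_relapse: bool = False) -> StratumOutcome:
    """CIF curves per stratum plus log-rank and Cox(high-vs-low) tests."""
    ds, pids = build_survival(cohort, outcome,
                              competing_death=competing_death,
                              competing_relapse=competing_relapse)
    labels = pd.Series({pid: split.labels.get(pid) for pid in pids})
    mask = labels.notna().to_numpy()
    ds = SurvivalDataset(ds.time[mask], ds.status[mask],
                         group=labels.dropna().to_numpy())
    curves, curves_km = {}, {}
    for lab in ("low", "high"):
        sel = ds.group == lab
        sub = SurvivalDataset(ds.time[sel], ds.status[sel])
        curves[lab] = cumulative_incidence(sub)
        curves_km[lab] = cumulative_incidence(sub, method="one-minus-km")
    chi2, p = logrank_test(ds)
    x = (ds.group == "high").astype(float)
    try:
        cox = cox_fit(ds, covariates=x)
        cox.logrank_p = p
    except ValueError:
        cox = CoxResult(beta=float("nan"), hr=float("nan"), se=float("nan"),
                        ci95=(float("nan"), float("nan")), logrank_p=p,
                        converged=False, n_events=int((ds.status == EVENT).sum()))
    return StratumOutcome(outcome=outcome, subset=split.subset, curves=curves,
                          curves_km=curves_km, logrank_chi2=chi2, logrank_p=p,
                          cox=cox)
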