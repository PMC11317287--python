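"""Univariate association screens with effect sizes and confounder flagging.

For every (cell variable, predictor) pair the appropriate nonparametric
test is run: Wilcoxon rank-sum with Cliff's delta for binary predictors,
Kruskal-Wallis for predictors with three or more levels, Spearman
correlation (with its test) for continuous ones.  p-values are
Benjamini-Hochberg corrected across one whole matrix per scope; q < 0.1
is called significant.  Each significant pair is then screened for
confounding: a Gaussian likelihood-ratio test compares
``response ~ focal`` against ``response ~ focal + c + focal:c`` for each
candidate modality variable c, and any candidate with LRT p < 0.05 flags
the pair as confounded.  Counts are ln(1+x)-transformed before linear
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, COUNT_COLS, POST_DAYS
from .reconstitution import AB_MIN

CONFOUNDER_ALPHA = 0.05
Q_SIGNIFICANT = 0.1

#: transplant-modality variables entering the confounder screen
MODALITY_VARS = ("mrd", "atg", "serotherapy", "malignant", "sex_female",
                 "donor_age", "graft_cd3_per_kg", "graft_cd34_per_kg",
                 "graft_cd45_per_kg")


@dataclass
class TestResult:
    response: str
    scope: str                 # "day15".."day240" or "timeavg"
    predictor: str
    test: str                  # rank_sum | kruskal | spearman
    statistic: float
    effect_size: float         # Cliff's delta or Spearman rho (NaN for kruskal)
    p: float
    q: float = float("nan")
    significant: bool = False
    confounded: bool = False
    confounders_triggering: list[str] = field(default_factory=list)
    n: int = 0
    note: str = ""


# ---------------------------------------------------------------------------
# primitive tests
# ---------------------------------------------------------------------------

def cliffs_delta(x, y) -> float:
    """Cliff's delta: (#{x_i > y_j} − #{x_i < y_j}) / (|x|·|y|)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("cliffs_delta requires non-empty samples")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (len(x) * len(y)))


def rank_sum_test(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midranks for ties.

    ``mode``: "exact" enumerates the null distribution, "normal" uses the
    tie-corrected normal approximation with continuity correction, "auto"
    picks exact when both samples have n <= 12 and there are no ties.
    Returns (U statistic of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "auto":
        mode = "exact" if (len(x) <= 12 and len(y) <= 12 and not ties) else "normal"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kruskal_test(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square(k-1)."""
    if len(groups) < 2:
        raise ValueError("kruskal_test requires >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_test requires non-empty groups")
    if all(len(np.unique(g)) == 1 for g in groups) and \
            len(np.unique(np.concatenate([np.asarray(g) for g in groups]))) == 1:
        return 0.0, 1.0  # all observations identical: no separation
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson on midranks) with its t-approximation test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman_assoc requires equal lengths >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman_assoc undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# confounder screen
# ---------------------------------------------------------------------------

@dataclass
class LrtCandidate:
    candidate: str
    statistic: float
    df: int
    p: float
    skipped: bool = False
    reason: str = ""


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), int(rank)


def gaussian_lrt(y: np.ndarray, X0: np.ndarray, X1: np.ndarray
                 ) -> tuple[float, int, float]:
    """LRT = n·ln(RSS0/RSS1) for nested Gaussian linear models.

    Identical to −2(ll0 − ll1) with the variance profiled out.  df is the
    effective number of added parameters (rank difference).
    """
    n = len(y)
    rss0, rank0 = _ols_rss(X0, y)
    rss1, rank1 = _ols_rss(X1, y)
    df = rank1 - rank0
    if df <= 0:
        raise np.linalg.LinAlgError("augmented model adds no rank")
    rss1 = max(rss1, 1e-300)
    stat = n * np.log(max(rss0, 1e-300) / rss1)
    p = float(stats.chi2.sf(max(stat, 0.0), df))
    return float(stat), df, p


def confounder_lrt(response, focal, candidates: dict[str, np.ndarray],
                   alpha: float = CONFOUNDER_ALPHA
                   ) -> tuple[bool, list[LrtCandidate]]:
    """Screen a focal association for confounding by each candidate.

    M0: ln(1+response) ~ focal.  M1 adds candidate and focal:candidate
    interaction.  A candidate with LRT p < alpha triggers the confounded
    flag.  Collinear candidates are skipped and reported, never fatal.
    """
    y = np.log1p(np.asarray(response, dtype=float))
    f = np.asarray(focal, dtype=float)
    n = len(y)
    if np.ptp(y) == 0:
        return False, [LrtCandidate(c, float("nan"), 0, float("nan"), True,
                                    "zero-variance response")
                       for c in candidates]
    X0 = np.column_stack([np.ones(n), f])
    results: list[LrtCandidate] = []
    confounded = False
    for name, c in candidates.items():
        c = np.asarray(c, dtype=float)
        if np.linalg.matrix_rank(np.column_stack([X0, c])) == \
                np.linalg.matrix_rank(X0):
            results.append(LrtCandidate(name, float("nan"), 0, float("nan"),
                                        True, "collinear with focal"))
            continue
        X1 = np.column_stack([X0, c, f * c])
        if n <= X1.shape[1]:
            results.append(LrtCandidate(name, float("nan"), 0, float("nan"),
                                        True, "too few observations"))
            continue
        try:
            stat, df, p = gaussian_lrt(y, X0, X1)
        except np.linalg.LinAlgError:
            results.append(LrtCandidate(name, float("nan"), 0, float("nan"),
                                        True, "collinear with focal"))
            continue
        trig = p < alpha
        confounded = confounded or trig
        results.append(LrtCandidate(name, stat, df, p))
    return confounded, results


# ---------------------------------------------------------------------------
# association matrix
# ---------------------------------------------------------------------------

def _predictor_frame(cohort: Cohort) -> pd.DataFrame:
    """Patient-level predictors: modality variables plus outcome events."""
    p = cohort.patients.set_index("patient_id")
    o = cohort.outcomes.set_index("patient_id").reindex(p.index)
    df = pd.DataFrame(index=p.index)
    df["mrd"] = (p["donor_type"] != "MUD").astype(float)          # MSD/MFD vs MUD
    df["donor_type3"] = p["donor_type"]
    df["atg"] = p["atg"].astype(float)
    df["serotherapy"] = (p["atg"] | p["alemtuzumab"]).astype(float)
    df["malignant"] = p["malignant"].astype(float)
    df["sex_female"] = (p["sex"] == "F").astype(float)
    df["donor_age"] = p["donor_age_years"].astype(float)
    for g in ("graft_cd3_per_kg", "graft_cd34_per_kg", "graft_cd45_per_kg"):
        df[g] = p[g].astype(float)
    df["agvhd_any"] = (o["agvhd_grade"].fillna(0).astype(int) > 0).astype(float)
    df["agvhd_2to4"] = (o["agvhd_grade"].fillna(0).astype(int) >= 2).astype(float)
    df["agvhd_grade"] = o["agvhd_grade"].fillna(0).astype(float)
    df["ebv"] = o["ebv"].fillna(False).astype(float)
    df["cmv"] = o["cmv"].fillna(False).astype(float)
    df["adv"] = (o["adv_systemic"].fillna(False) |
                 o["adv_gi"].fillna(False)).astype(float)
    return df


BINARY_PREDICTORS = ("mrd", "atg", "serotherapy", "malignant", "sex_female",
                     "agvhd_any", "agvhd_2to4", "ebv", "cmv", "adv")
CONTINUOUS_PREDICTORS = ("donor_age", "graft_cd3_per_kg", "graft_cd34_per_kg",
                         "graft_cd45_per_kg", "agvhd_grade")
MULTILEVEL_PREDICTORS = ("donor_type3",)


def _response_frame(cohort: Cohort, scope: str) -> pd.DataFrame:
    """Per-patient response values: one column per cell variable."""
    if scope == "timeavg":
        out = {}
        for var in COUNT_COLS:
            wide = cohort.panel_wide(var)
            vals = {}
            for pid, row in wide.iterrows():
                s = row.dropna()
                if len(s) >= 2:
                    t = s.index.to_numpy(dtype=float)
                    vals[pid] = float(np.trapezoid(s.to_numpy(), t) / (t[-1] - t[0]))
            out[var] = pd.Series(vals)
        return pd.DataFrame(out)
    day = int(scope.removeprefix("day"))
    if day not in POST_DAYS:
        raise ValueError(f"scope {scope!r} not in schedule")
    sub = cohort.panels[cohort.panels["day"] == str(day)]
    return sub.set_index("patient_id")[list(COUNT_COLS)].astype(float)


def association_matrix(cohort: Cohort, scope: str,
                       q_threshold: float = Q_SIGNIFICANT,
                       confounder_alpha: float = CONFOUNDER_ALPHA
                       ) -> pd.DataFrame:
    """Full (cell variable x predictor) screen for one scope.

    ``scope`` is "day15".."day240" (counts at that day) or "timeavg"
    (per-patient trapezoidal time-average).  Per-cell failures are
    recorded in the ``note`` column, never aborting the matrix.  BH
    correction spans the whole matrix for the scope.
    """
    resp = _response_frame(cohort, scope)
    pred = _predictor_frame(cohort)
    results: list[TestResult] = []
    for var in COUNT_COLS:
        y_all = resp[var] if var in resp else pd.Series(dtype=float)
        for name in BINARY_PREDICTORS + MULTILEVEL_PREDICTORS + CONTINUOUS_PREDICTORS:
            tr = _one_test(var, scope, name, y_all, pred)
            results.append(tr)
    testable = [t for t in results if np.isfinite(t.p)]
    if testable:
        q = bh_adjust([t.p for t in testable])
        for t, qv in zip(testable, q):
            t.q = float(qv)
            t.significant = qv < q_threshold
    # confounder screen on significant pairs, against the other modality vars
    for t in results:
        if not t.significant:
            continue
        y = resp[t.response].dropna()
        common = y.index.intersection(pred.index)
        focal = _encode(t.predictor, pred.loc[common])
        cands = {m: pred.loc[common, m].to_numpy(dtype=float)
                 for m in MODALITY_VARS if m != t.predictor}
        conf, cand_res = confounder_lrt(y.loc[common].to_numpy(), focal, cands,
                                        alpha=confounder_alpha)
        t.confounded = conf
        t.confounders_triggering = [c.candidate for c in cand_res
                                    if not c.skipped and c.p < confounder_alpha]
    rows = [{**{k: getattr(t, k) for k in
                ("response", "scope", "predictor", "test", "statistic",
                 "effect_size", "p", "q", "significant", "confounded", "n",
                 "note")},
             "confounders_triggering": ";".join(t.confounders_triggering)}
            for t in results]
    return pd.DataFrame(rows)


def _encode(predictor: str, pred: pd.DataFrame) -> np.ndarray:
    if predictor in MULTILEVEL_PREDICTORS:
        # MRD-vs-MUD encoding when the 3-level donor type itself is focal
        return (pred["donor_type3"] != "MUD").to_numpy(dtype=float)
    return pred[predictor].to_numpy(dtype=float)


def _one_test(var: str, scope: str, name: str, y_all: pd.Series,
              pred: pd.DataFrame) -> TestResult:
    t = TestResult(response=var, scope=scope, predictor=name, test="",
                   statistic=float("nan"), effect_size=float("nan"),
                   p=float("nan"))
    y = y_all.dropna()
    common = y.index.intersection(pred.index)
    y = y.loc[common]
    t.n = len(y)
    if len(y) < 3 or np.ptp(y.to_numpy()) == 0:
        t.note = "untestable: constant or too-few response values"
        return t
    try:
        if name in BINARY_PREDICTORS:
            g = pred.loc[common, name].to_numpy(dtype=float)
            x1, x0 = y.to_numpy()[g == 1], y.to_numpy()[g == 0]
            if len(x1) == 0 or len(x0) == 0:
                t.note = "untestable: one predictor level empty"
                return t
            t.test = "rank_sum"
            t.statistic, t.p = rank_sum_test(x1, x0, mode="normal")
            t.effect_size = cliffs_delta(x1, x0)
        elif name in MULTILEVEL_PREDICTORS:
            levels = pred.loc[common, name]
            groups = [y.to_numpy()[(levels == lv).to_numpy()]
                      for lv in sorted(levels.unique())]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2:
                t.note = "untestable: fewer than two donor-type levels"
                return t
            t.test = "kruskal"
            t.statistic, t.p = kruskal_test(*groups)
        else:
            x = pred.loc[common, name].to_numpy(dtype=float)
            t.test = "spearman"
            rho, p = spearman_assoc(x, y.to_numpy())
            t.statistic, t.effect_size, t.p = rho, rho, p
    except ValueError as exc:
        t.note = f"untestable: {exc}"
        t.p = float("nan")
    if np.isfinite(t.p):
        t.p = float(min(max(t.p, np.nextafter(0, 1)), 1.0))
    return t
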