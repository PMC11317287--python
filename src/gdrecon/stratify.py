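"""High/low dichotomization by an ω²-maximizing cut over ranked abundances.

Patients are ordered by their time-averaged relative abundance R of a γδ
subset.  Each patient is represented by the pair (min-max scaled R,
min-max scaled rank); pairwise dissimilarities are weighted (Ružička)
Jaccard distances, and every admissible split of the ranked sequence into
a low and a high group is scored with a PERMANOVA-style ω² effect size
computed from the distance matrix.  The split with the largest ω² defines
the cut-off; the procedure is outcome-blind.

The continuous weighted-Jaccard form and the distance-based ω²
decomposition are this package's operationalization of the construction;
both live behind single functions so the choice is isolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class SplitResult:
    """Outcome-blind high/low split of a cohort by time-averaged abundance."""

    subset: str
    cutoff_R: float
    k: int                      # size of the low group
    omega_squared: float
    labels: dict[str, str]      # patient_id -> "low" | "high"
    eligible_n: int
    degenerate: bool = False
    ineligible: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"subset": self.subset, "cutoff_R": self.cutoff_R,
                "k": self.k, "omega_squared": self.omega_squared,
                "eligible_n": self.eligible_n, "degenerate": self.degenerate,
                "labels": self.labels, "ineligible": self.ineligible}


def weighted_jaccard(u, v) -> float:
    """Weighted (Ružička) Jaccard distance 1 - Σmin/Σmax for nonneg vectors.

    Reduces to the set Jaccard distance on binary vectors; two all-zero
    vectors are at distance 0 by convention.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if (u < 0).any() or (v < 0).any():
        raise ValueError("weighted_jaccard requires nonnegative components")
    denom = np.maximum(u, v).sum()
    if denom == 0.0:
        return 0.0
    return float(1.0 - np.minimum(u, v).sum() / denom)


def _pairwise_jaccard(Z: np.ndarray) -> np.ndarray:
    """Dense weighted-Jaccard distance matrix for rows of nonnegative Z."""
    n = Z.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        mn = np.minimum(Z[i], Z[i + 1:]).sum(axis=1)
        mx = np.maximum(Z[i], Z[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(mx > 0, 1.0 - mn / mx, 0.0)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


def omega_squared(D: np.ndarray, labels: np.ndarray) -> float:
    """Distance-based ω² effect size for a binary grouping.

    PERMANOVA-style decomposition of squared pairwise distances:
    SS_total = (1/n)·Σ_{i<j} d²; SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²;
    ω² = max(0, (SS_between − MS_within)/(SS_total + MS_within)) with
    MS_within = SS_within/(n−2).  Zero-variance data give 0.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("D must be symmetric with zero diagonal")
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required, both non-empty")
    D2 = D ** 2
    iu = np.triu_indices(n, k=1)
    ss_total = D2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) == 0:
            raise ValueError("empty group")
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    ms_within = ss_within / (n - 2) if n > 2 else 0.0
    denom = ss_total + ms_within
    if denom <= 0.0:
        return 0.0
    return float(max(0.0, (ss_between - ms_within) / denom))


def default_min_group(n: int) -> int:
    """Smallest admissible group size: max(3, ceil(0.1 n))."""
    return max(3, int(np.ceil(0.1 * n)))


def _minmax01(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng == 0.0:
        return np.zeros_like(x)
    return (x - x.min()) / rng


def find_best_cutoff(abundances: dict[str, float], min_group: int | None = None,
                     subset: str = "") -> SplitResult:
    """Exhaustive ω²-maximizing split of patients ranked by R.

    Patients with non-finite R are excluded as ineligible.  Ties in R are
    broken by patient_id for the ordering; the rank feature uses midranks
    so identical R values are indistinguishable.  Ties in ω² resolve to
    the smallest low-group size k; the cut-off is the midpoint of the
    boundary R values.
    """
    items = sorted(abundances.items())
    ineligible = [pid for pid, v in items if not np.isfinite(v)]
    items = [(pid, float(v)) for pid, v in items if np.isfinite(v)]
    n = len(items)
    mg = default_min_group(n) if min_group is None else int(min_group)
    if mg < 1:
        raise ValueError("min_group must be >= 1")
    if n < 2 * mg:
        raise ValueError(
            f"need at least {2 * mg} eligible patients for min_group={mg}, "
            f"have {n}")

    order = sorted(range(n), key=lambda i: (items[i][1], items[i][0]))
    pids = [items[i][0] for i in order]
    R = np.array([items[i][1] for i in order])
    ranks = rankdata(R, method="average")
    Z = np.column_stack([_minmax01(R), _minmax01(ranks)])
    D = _pairwise_jaccard(Z)

    best_k, best_w = mg, -1.0
    for k in range(mg, n - mg + 1):
        labels = np.array(["low"] * k + ["high"] * (n - k))
        w = omega_squared(D, labels)
        if w > best_w + 1e-12:
            best_k, best_w = k, w
    cutoff = 0.5 * (R[best_k - 1] + R[best_k])
    labels = {pid: ("low" if i < best_k else "high")
              for i, pid in enumerate(pids)}
    degenerate = bool(R.max() - R.min() == 0.0 or best_w <= 0.0)
    return SplitResult(subset=subset, cutoff_R=float(cutoff), k=best_k,
                       omega_squared=float(max(best_w, 0.0)), labels=labels,
                       eligible_n=n, degenerate=degenerate,
                       ineligible=ineligible)


def stratify_cohort(cohort, subsets=("gd_t", "vd1", "vd2"),
                    min_group: int | None = None) -> dict[str, SplitResult]:
    """Compute the high/low split per subset on the full eligible cohort."""
    from .reconstitution import abundance_table
    table = abundance_table(cohort, subsets=tuple(subsets))
    out = {}
    for subset in subsets:
        sub = table[table["subset"] == subset]
        ab = dict(zip(sub["patient_id"], sub["R"]))
        out[subset] = find_best_cutoff(ab, min_group=min_group, subset=subset)
    return out
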