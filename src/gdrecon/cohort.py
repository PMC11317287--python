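"""Cohort data model: CSV readers/writers and structural validation.

A cohort bundles three tables:

* ``patients``  — one row per transplanted patient (covariates, graft, serostatus)
* ``panels``    — one row per patient x scheduled day with absolute T-cell
  subset counts in cells/µl from the flow-cytometry panel
  (CD3, CD4, CD8, TCRαβ, TCRγδ, Vδ1, Vδ2, non-Vδ1-non-Vδ2, HLA-DR+ CD4/CD8)
* ``outcomes``  — one row per patient with clinical events (aGvHD, viral
  infections, relapse, death) and onset days

Days are integers post-transplant (day 0 = graft infusion); the
pre-conditioning sample is stored with day ``"pre"``. Missing values are
empty strings in CSV. Counts are gated independently on the cytometer and
never sum exactly, so subset-sum invariants carry a 5% relative tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: scheduled sampling days; "pre" is the pre-conditioning sample
DAYS: tuple[str, ...] = ("pre", "15", "30", "60", "100", "180", "240")
#: post-transplant days used by all analyses (integers)
POST_DAYS: tuple[int, ...] = (15, 30, 60, 100, 180, 240)

#: relative tolerance for subset-sum invariants (independent gating noise)
SUM_TOL = 0.05

COUNT_COLS: tuple[str, ...] = (
    "cd3", "cd4", "cd8", "ab_t", "gd_t",
    "vd1", "vd2", "non_vd1_vd2", "cd4_hladr", "cd8_hladr",
)

PATIENT_COLS: tuple[str, ...] = (
    "patient_id", "age_years", "sex", "disease_label", "malignant",
    "donor_type", "donor_age_years", "atg", "alemtuzumab",
    "gvhd_prophylaxis", "conditioning_label", "hla_match",
    "cmv_sero_donor", "cmv_sero_patient", "ebv_sero_donor",
    "ebv_sero_patient", "graft_cd3_per_kg", "graft_cd34_per_kg",
    "graft_cd45_per_kg",
)

PANEL_COLS: tuple[str, ...] = ("patient_id", "day") + COUNT_COLS

OUTCOME_COLS: tuple[str, ...] = (
    "patient_id", "followup_days", "death", "death_day", "trm",
    "relapse", "relapse_day", "agvhd_grade", "agvhd_onset_day",
    "agvhd_organs", "ebv", "ebv_day", "cmv", "cmv_day",
    "adv_systemic", "adv_systemic_day", "adv_gi", "adv_gi_day",
)

_CATEGORICAL = {
    "sex": {"F", "M"},
    "donor_type": {"MSD", "MFD", "MUD"},
    "gvhd_prophylaxis": {"MTX", "MMF"},
    "hla_match": {"9/10", "10/10"},
    "cmv_sero_donor": {"pos", "neg"},
    "cmv_sero_patient": {"pos", "neg"},
    "ebv_sero_donor": {"pos", "neg"},
    "ebv_sero_patient": {"pos", "neg"},
}

_BOOL_PATIENT = ("malignant", "atg", "alemtuzumab")
_BOOL_OUTCOME = ("death", "trm", "relapse", "ebv", "cmv", "adv_systemic", "adv_gi")
_ORGANS = {"skin", "liver", "gut"}


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


class IntegrityError(ValueError):
    """Structural integrity of the cohort tables is broken."""


@dataclass
class Violation:
    rule: str
    patient_id: str | None
    day: str | None
    message: str

    def to_dict(self) -> dict:
        return {"rule": self.rule, "patient_id": self.patient_id,
                "day": self.day, "message": self.message}


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, rule: str, message: str, patient_id: str | None = None,
            day: str | None = None) -> None:
        self.violations.append(Violation(rule, patient_id, day, message))

    def to_json(self) -> str:
        return json.dumps([v.to_dict() for v in self.violations], indent=2)

    def __len__(self) -> int:
        return len(self.violations)


@dataclass
class Cohort:
    """Patients, longitudinal panel measurements and clinical outcomes."""

    patients: pd.DataFrame
    panels: pd.DataFrame
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        self.patients = self.patients.reset_index(drop=True)
        self.panels = self.panels.reset_index(drop=True)
        self.outcomes = self.outcomes.reset_index(drop=True)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def panel_wide(self, count: str) -> pd.DataFrame:
        """Pivot one count column to patients x post-HSCT days (float days)."""
        post = self.panels[self.panels["day"] != "pre"].copy()
        post["day_num"] = post["day"].astype(int)
        wide = post.pivot(index="patient_id", columns="day_num", values=count)
        return wide.reindex(columns=sorted(wide.columns))

    def copy(self) -> "Cohort":
        return Cohort(self.patients.copy(), self.panels.copy(), self.outcomes.copy())


def empty_cohort() -> Cohort:
    return Cohort(
        pd.DataFrame(columns=list(PATIENT_COLS)),
        pd.DataFrame(columns=list(PANEL_COLS)),
        pd.DataFrame(columns=list(OUTCOME_COLS)),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _check_header(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in cols]
    if extra:
        raise SchemaError(f"{name}: unexpected column(s) {extra}")


def _coerce(df: pd.DataFrame, name: str, float_cols=(), int_cols=(),
            bool_cols=(), opt_num_cols=()) -> pd.DataFrame:
    """Type coercion with cell-level error coordinates."""
    errors: list[str] = []
    df = df.copy()

    def _parse_float(col, allow_blank):
        out = np.full(len(df), np.nan)
        for pos, (i, raw) in enumerate(df[col].items()):
            s = str(raw).strip()
            if s in ("", "nan", "None", "<NA>"):
                if not allow_blank:
                    errors.append(f"{name} row {i + 2} col {col!r}: "
                                  f"missing value")
                continue
            try:
                out[pos] = float(s)  # correctly-rounded: lossless round trip
            except ValueError:
                errors.append(f"{name} row {i + 2} col {col!r}: "
                              f"cannot parse {raw!r} as number")
        return out

    for col in float_cols:
        df[col] = _parse_float(col, allow_blank=True)
    for col in int_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        for i in df.index[bad]:
            errors.append(f"{name} row {i + 2} col {col!r}: "
                          f"cannot parse {df.at[i, col]!r} as integer")
        df[col] = vals.fillna(0).astype(int)
    for col in bool_cols:
        s = df[col].astype(str).str.strip().str.lower()
        ok = s.isin(["true", "false"])
        for i in df.index[~ok]:
            errors.append(f"{name} row {i + 2} col {col!r}: "
                          f"cannot parse {df.at[i, col]!r} as boolean")
        df[col] = s == "true"
    for col in opt_num_cols:  # nullable day columns
        df[col] = _parse_float(col, allow_blank=True)
    if errors:
        raise SchemaError("; ".join(errors))
    return df


def read_cohort(patients_path, panels_path, outcomes_path) -> Cohort:
    """Read and type-check the three cohort CSVs.

    Raises
    ------
    SchemaError
        Missing/extra columns, unparseable cells (with row/column
        coordinates), or a ``day`` value outside the schedule.
    IntegrityError
        Duplicate (patient, day) panel rows, duplicate patients, or
        panel/outcome rows whose patient_id has no patient record.
    """
    for p in (patients_path, panels_path, outcomes_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)

    patients = pd.read_csv(patients_path, dtype=str, keep_default_na=False)
    panels = pd.read_csv(panels_path, dtype=str, keep_default_na=False)
    outcomes = pd.read_csv(outcomes_path, dtype=str, keep_default_na=False)

    _check_header(patients, PATIENT_COLS, "patients")
    _check_header(panels, PANEL_COLS, "panels")
    _check_header(outcomes, OUTCOME_COLS, "outcomes")

    patients = _coerce(
        patients, "patients",
        float_cols=("graft_cd3_per_kg", "graft_cd34_per_kg", "graft_cd45_per_kg"),
        int_cols=("age_years", "donor_age_years"),
        bool_cols=_BOOL_PATIENT,
    )
    bad_day = ~panels["day"].isin(DAYS)
    if bad_day.any():
        i = panels.index[bad_day][0]
        raise SchemaError(
            f"panels row {i + 2} col 'day': value {panels.at[i, 'day']!r} "
            f"not in schedule {list(DAYS)}")
    panels = _coerce(panels, "panels", float_cols=COUNT_COLS)
    outcomes = _coerce(
        outcomes, "outcomes",
        int_cols=("followup_days", "agvhd_grade"),
        bool_cols=_BOOL_OUTCOME,
        opt_num_cols=("death_day", "relapse_day", "agvhd_onset_day",
                      "ebv_day", "cmv_day", "adv_systemic_day", "adv_gi_day"),
    )

    dup = patients["patient_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"patients: duplicate patient_id {patients['patient_id'][dup].iloc[0]!r}")
    dup = panels.duplicated(subset=["patient_id", "day"])
    if dup.any():
        row = panels[dup].iloc[0]
        raise IntegrityError(
            f"panels: duplicate row for patient {row['patient_id']!r} "
            f"day {row['day']!r}")
    dup = outcomes["patient_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"outcomes: duplicate patient_id {outcomes['patient_id'][dup].iloc[0]!r}")

    known = set(patients["patient_id"])
    for name, df in (("panels", panels), ("outcomes", outcomes)):
        orphan = ~df["patient_id"].isin(known)
        if orphan.any():
            raise IntegrityError(
                f"{name}: patient_id {df['patient_id'][orphan].iloc[0]!r} "
                f"has no patient record")

    return Cohort(patients, panels, outcomes)


def _sorted_tables(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    day_order = {d: i for i, d in enumerate(DAYS)}
    patients = cohort.patients.sort_values("patient_id", kind="mergesort")
    panels = cohort.panels.copy()
    if len(panels):
        panels["_d"] = panels["day"].map(day_order)
        panels = panels.sort_values(["patient_id", "_d"], kind="mergesort")
        panels = panels.drop(columns="_d")
    outcomes = cohort.outcomes.sort_values("patient_id", kind="mergesort")
    return patients, panels, outcomes


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write patients.csv / panels.csv / outcomes.csv, deterministically ordered."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, panels, outcomes = _sorted_tables(cohort)
    paths = {}
    for name, df, cols in (("patients", patients, PATIENT_COLS),
                           ("panels", panels, PANEL_COLS),
                           ("outcomes", outcomes, OUTCOME_COLS)):
        path = out / f"{name}.csv"
        d = df.reindex(columns=list(cols)).copy()
        for c in d.columns:
            if d[c].dtype == bool:
                d[c] = d[c].map({True: "true", False: "false"})
        d.to_csv(path, index=False, na_rep="")  # shortest-repr floats: lossless
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _sum_viol(report, pid, day, rule, lhs_desc, lhs, rhs_desc, rhs,
              two_sided=False):
    if two_sided:
        ok = abs(lhs - rhs) <= SUM_TOL * max(rhs, 0.0) + 1e-9
    else:
        ok = lhs <= (1.0 + SUM_TOL) * rhs + 1e-9
    if not ok:
        report.add(rule, f"{lhs_desc}={lhs:g} vs {rhs_desc}={rhs:g} "
                   f"(tol {SUM_TOL:.0%})", pid, day)


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check every cohort invariant; violations are data, not exceptions.

    The report is deterministic and independent of input row order
    (violations are sorted by rule / patient / day).
    """
    rep = ValidationReport()
    pats, panels, outs = cohort.patients, cohort.panels, cohort.outcomes

    ids = pats["patient_id"]
    for pid in ids[ids.duplicated()].unique():
        rep.add("patient_id_unique", "duplicate patient_id", str(pid), None)
    known = set(ids)

    for _, r in pats.iterrows():
        pid = r["patient_id"]
        if bool(r["atg"]) and bool(r["alemtuzumab"]):
            rep.add("serotherapy_exclusive",
                    "atg and alemtuzumab both true", pid, None)
        for col, allowed in _CATEGORICAL.items():
            if r[col] not in allowed:
                rep.add("categorical_domain",
                        f"{col}={r[col]!r} not in {sorted(allowed)}", pid, None)
        for col in ("age_years", "donor_age_years"):
            if int(r[col]) < 0:
                rep.add("nonnegative", f"{col}={r[col]}", pid, None)
        for col in ("graft_cd3_per_kg", "graft_cd34_per_kg", "graft_cd45_per_kg"):
            if float(r[col]) < 0:
                rep.add("nonnegative", f"{col}={r[col]}", pid, None)

    seen = set()
    for _, r in panels.iterrows():
        pid, day = r["patient_id"], str(r["day"])
        if pid not in known:
            rep.add("panel_patient_resolves", "unknown patient_id", pid, day)
        if day not in DAYS:
            rep.add("day_in_schedule", f"day={day!r}", pid, day)
        if (pid, day) in seen:
            rep.add("panel_unique", "duplicate (patient, day)", pid, day)
        seen.add((pid, day))
        counts = {c: float(r[c]) for c in COUNT_COLS}
        for c, v in counts.items():
            if not np.isfinite(v) or v < 0:
                rep.add("count_nonnegative", f"{c}={v}", pid, day)
        if all(np.isfinite(v) and v >= 0 for v in counts.values()):
            sub = counts["vd1"] + counts["vd2"] + counts["non_vd1_vd2"]
            _sum_viol(rep, pid, day, "gd_subset_sum",
                      "vd1+vd2+non", sub, "gd_t", counts["gd_t"], two_sided=True)
            _sum_viol(rep, pid, day, "tcr_sum",
                      "ab_t+gd_t", counts["ab_t"] + counts["gd_t"],
                      "cd3", counts["cd3"])
            _sum_viol(rep, pid, day, "cd4_cd8_sum",
                      "cd4+cd8", counts["cd4"] + counts["cd8"],
                      "cd3", counts["cd3"])
            _sum_viol(rep, pid, day, "hladr_cd4",
                      "cd4_hladr", counts["cd4_hladr"], "cd4", counts["cd4"])
            _sum_viol(rep, pid, day, "hladr_cd8",
                      "cd8_hladr", counts["cd8_hladr"], "cd8", counts["cd8"])

    out_ids = outs["patient_id"]
    for pid in out_ids[out_ids.duplicated()].unique():
        rep.add("outcome_unique", "duplicate outcome row", str(pid), None)
    for pid in known - set(out_ids):
        rep.add("outcome_present", "patient has no outcome row", pid, None)

    pat_by_id = pats.set_index("patient_id") if len(pats) else None
    for _, r in outs.iterrows():
        pid = r["patient_id"]
        if pid not in known:
            rep.add("outcome_patient_resolves", "unknown patient_id", pid, None)
        fup = int(r["followup_days"])
        if fup <= 0:
            rep.add("followup_positive", f"followup_days={fup}", pid, None)
        events = [("death", "death_day"), ("relapse", "relapse_day"),
                  ("ebv", "ebv_day"), ("cmv", "cmv_day"),
                  ("adv_systemic", "adv_systemic_day"), ("adv_gi", "adv_gi_day")]
        for flag, daycol in events:
            day = r[daycol]
            if bool(r[flag]):
                if pd.isna(day):
                    rep.add("event_day_present",
                            f"{flag}=true without {daycol}", pid, None)
                elif float(day) > fup:
                    rep.add("event_within_followup",
                            f"{daycol}={day:g} > followup {fup}", pid, None)
            elif not pd.isna(day):
                rep.add("event_day_without_flag",
                        f"{daycol}={day:g} with {flag}=false", pid, None)
        grade = int(r["agvhd_grade"])
        if grade not in range(5):
            rep.add("agvhd_grade_domain", f"agvhd_grade={grade}", pid, None)
        onset = r["agvhd_onset_day"]
        if (grade > 0) != (not pd.isna(onset)):
            rep.add("agvhd_onset_iff_grade",
                    f"grade={grade}, onset={onset}", pid, None)
        if not pd.isna(onset) and float(onset) > fup:
            rep.add("event_within_followup",
                    f"agvhd_onset_day={onset:g} > followup {fup}", pid, None)
        organs = str(r["agvhd_organs"]).strip()
        if organs:
            bad = set(organs.split(";")) - _ORGANS
            if bad:
                rep.add("agvhd_organs_domain", f"unknown organs {sorted(bad)}",
                        pid, None)
        if bool(r["relapse"]) and pat_by_id is not None and pid in pat_by_id.index:
            if not bool(pat_by_id.at[pid, "malignant"]):
                rep.add("relapse_malignant_only",
                        "relapse in non-malignant patient", pid, None)

    rep.violations.sort(key=lambda v: (v.rule, v.patient_id or "", v.day or "",
                                       v.message))
    return rep
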