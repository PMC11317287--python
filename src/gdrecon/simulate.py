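"""Synthetic pediatric-HSCT cohort generator.

Emulates a 49-patient bone-marrow-graft cohort with longitudinal
flow-cytometry counts and clinical outcomes, so every downstream stage of
the pipeline is testable without patient data.  Counts are built
hierarchically to guarantee subset coherence:

* the γδ T-cell total and the αβ T-cell count are log-normal per day, with
  day-specific medians anchored to the published reconstitution table and a
  shared multiplicative patient frailty;
* the γδ total is split into (Vδ1, Vδ2, non-Vδ1-non-Vδ2) by a Dirichlet
  whose marginal medians track the published relative concentrations;
* CD3 = αβ + γδ; CD4/CD8 share a sub-pool of CD3 via Beta fractions;
  HLA-DR+ cells are Beta sub-fractions of CD4 resp. CD8.

Covariate effects (donor type on Vδ2, serotherapy on CD4, donor age on γδ)
are centred log-scale multipliers, so group contrasts carry the planted
direction while cohort medians stay on their anchors.  Infection-response
effects (EBV raises Vδ1, CMV raises CD8) are sum-preserving reallocations
inside the respective split.  Clinical events use a two-part model: a
Bernoulli indicator whose cohort mean is calibrated by bisection to the
published rate, and a truncated log-normal onset day matched to the
published onset medians.  The aGvHD-severity and EBV indicators depend on
the latent Vδ2 propensity (the standardized log time-averaged Vδ2/αβ
level), planting the protective directions reported for high-Vδ2
recoverers; a shared log-normal susceptibility couples the three viral
indicators so the any-viral rate lands below the independence value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import (Cohort, COUNT_COLS, OUTCOME_COLS, PANEL_COLS,
                     PATIENT_COLS, POST_DAYS, empty_cohort)

_DAY_IDX = {d: i for i, d in enumerate(POST_DAYS)}

#: published per-day medians (cells/µl) for the γδ total and αβ T cells
GD_MEDIANS = (1.0, 10.0, 17.0, 27.0, 58.0, 68.0)
AB_MEDIANS = (4.0, 280.0, 610.0, 459.0, 943.0, 1152.0)
#: day-level log-normal scales (on top of patient-level effects)
GD_SIGMAS = (1.8, 1.4, 1.1, 0.9, 0.6, 0.55)
AB_SIGMAS = (2.1, 1.1, 0.85, 0.75, 0.45, 0.2)
#: published per-day median subset fractions of the γδ total (vd1, vd2, non)
SPLIT_MEDIANS = (
    (0.20, 0.65, 0.05),
    (0.265, 0.605, 0.07),
    (0.41, 0.38, 0.135),
    (0.50, 0.25, 0.16),
    (0.48, 0.26, 0.14),
    (0.51, 0.265, 0.14),
)
#: CD4 share of the CD4+CD8 pool per day (from published CD4/CD3 vs CD8/CD3)
CD4_SHARE = (0.60, 0.40, 0.29, 0.305, 0.41, 0.44)
#: HLA-DR+ activated fraction per day (declining activation)
HLADR_CD4 = (0.50, 0.40, 0.35, 0.30, 0.25, 0.22)
HLADR_CD8 = (0.50, 0.45, 0.40, 0.35, 0.30, 0.25)

#: pre-conditioning sample medians (diseased children before conditioning)
PRE_GD_MEDIAN, PRE_AB_MEDIAN = 40.0, 900.0
PRE_SPLIT = (0.25, 0.60, 0.08)

_DISEASES_MAL = (("ALL", 0.725), ("AML", 0.206), ("MDS", 0.069))
_DISEASES_NONMAL = (("SCD", 0.50), ("beta-thalassemia", 0.15), ("CGD", 0.05),
                    ("SCID", 0.05), ("SAA", 0.05), ("Hb-Yokohama", 0.05),
                    ("Fanconi", 0.05), ("CAMT", 0.05), ("osteopetrosis", 0.05))
_CONDITIONING = (("VP16/TBI", 0.184), ("Flu/TT/Treo", 0.469),
                 ("Flu/TT/Mel", 0.102), ("Flu/Bu/TT", 0.020),
                 ("Flu/TT", 0.041), ("Flu/Cy", 0.041),
                 ("Flu/Bu/Cy/TT", 0.041), ("Flu/Bu", 0.041),
                 ("Bu/Cy/Mel", 0.041), ("Amsacrine/Flu/Cy/Ara-C/TBI", 0.020))
_CMV_DR = (("pos", "pos", 0.442), ("pos", "neg", 0.163),
           ("neg", "neg", 0.209), ("neg", "pos", 0.186))


@dataclass
class EffectMultipliers:
    """Planted covariate/outcome effects (all on multiplicative scales)."""

    mud_on_vd2: float = 0.06          # <1; Vδ2 counts, days +30..+180
    serotherapy_on_cd4: float = 0.45  # <1; CD4 share of pool, days +30..+100
    donor_age_slope_on_gd: float = -0.02   # <0; per-year log slope on γδ total
    vd2_propensity_on_agvhd: float = -1.4  # <0; log multiplier per SD on II-IV risk
    vd2_propensity_on_ebv: float = -0.9    # <0; log multiplier per SD on EBV risk
    atg_on_ebv: float = 2.2           # >1; EBV risk multiplier under ATG
    cmv_on_cd8: float = 1.6           # >1; CD8 share reallocation, days +60..+180
    ebv_on_vd1: float = 1.8           # >1; Vδ1 split reallocation, days >= +100


@dataclass
class OutcomeRates:
    """Published event rates and onset-day medians."""

    agvhd_any: float = 0.46
    agvhd_2to4: float = 0.16
    agvhd_onset_median_day: float = 17.0
    ebv: float = 0.51
    ebv_onset_median_day: float = 50.0
    cmv: float = 0.285
    cmv_onset_median_day: float = 28.0
    adv: float = 0.26
    adv_onset_median_day: float = 24.0
    relapse_in_malignant: float = 0.448
    relapse_median_day: float = 171.0
    death: float = 0.10


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the published cohort: covariate frequencies from the
    patient-characteristics table, count trajectories anchored to the
    reconstitution table, and event rates/onsets from the outcomes section.
    """

    n_patients: int = 49
    seed: int = 0
    covariate_freqs: dict = field(default_factory=lambda: {
        "msd": 0.531, "mud": 0.408, "mfd": 0.061,
        "atg": 0.673, "alemtuzumab": 0.061,
        "malignant": 0.592, "female": 0.469,
        "mtx": 0.735, "hla_10_10": 0.939,
        "ebv_sero_donor_pos": 0.84, "ebv_sero_patient_pos": 0.78,
    })
    donor_age_range: tuple[int, int] = (2, 52)
    frailty_sd: float = 0.5          # shared log-normal patient frailty (mean 1)
    gd_level_sd: float = 0.45        # persistent patient-level γδ niveau
    split_tilt_sd: float = 0.5       # persistent patient-level Vδ2-share tilt
    split_concentration: float = 4.0  # Dirichlet concentration of the γδ split
    viral_susceptibility_sd: float = 0.45  # shared viral-susceptibility latent
    missingness_rate: float = 0.0    # extra per-visit dropout (beyond death)
    effects: EffectMultipliers = field(default_factory=EffectMultipliers)
    rates: OutcomeRates = field(default_factory=OutcomeRates)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for k, v in self.covariate_freqs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"covariate_freqs[{k!r}]={v} outside [0,1]")
        for name in ("frailty_sd", "gd_level_sd", "split_tilt_sd",
                     "viral_susceptibility_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must be in [0,1)")
        if self.split_concentration <= 1.0:
            raise ValueError("split_concentration must exceed 1")
        e = self.effects
        for name in ("mud_on_vd2", "serotherapy_on_cd4", "atg_on_ebv",
                     "cmv_on_cd8", "ebv_on_vd1"):
            if getattr(e, name) <= 0:
                raise ValueError(f"effects.{name} must be positive")
        r = self.rates
        for name, v in asdict(r).items():
            if "median" in name:
                if v <= 0:
                    raise ValueError(f"rates.{name} must be positive")
            elif not 0.0 <= v <= 1.0:
                raise ValueError(f"rates.{name}={v} outside [0,1]")

    @classmethod
    def null(cls, **kwargs) -> "GeneratorConfig":
        """Config with every planted effect switched off (null simulations)."""
        cfg = cls(**kwargs)
        cfg.effects = EffectMultipliers(
            mud_on_vd2=1.0, serotherapy_on_cd4=1.0, donor_age_slope_on_gd=0.0,
            vd2_propensity_on_agvhd=0.0, vd2_propensity_on_ebv=0.0,
            atg_on_ebv=1.0, cmv_on_cd8=1.0, ebv_on_vd1=1.0)
        return cfg

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "effects" in d:
            d["effects"] = EffectMultipliers(**d["effects"])
        if "rates" in d:
            d["rates"] = OutcomeRates(**d["rates"])
        if "donor_age_range" in d:
            d["donor_age_range"] = tuple(d["donor_age_range"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["donor_age_range"] = list(self.donor_age_range)
        return d


def split_alphas(medians: tuple[float, float, float], concentration: float
                 ) -> np.ndarray:
    """Dirichlet alphas whose marginal Beta medians track the targets.

    Uses the Beta median approximation (a - 1/3)/(a + b - 2/3) to place the
    Vδ2 marginal median at its printed value; the remaining mass is split
    between Vδ1 and non-Vδ1-non-Vδ2 in proportion to their printed medians
    (printed relative medians are medians of ratios and do not sum to 100).
    """
    m_vd1, m_vd2, m_non = medians
    c = concentration
    a_vd2 = m_vd2 * (c - 2.0 / 3.0) + 1.0 / 3.0
    rest = max(c - a_vd2, 0.2)
    a_vd1 = rest * m_vd1 / (m_vd1 + m_non)
    a_non = rest * m_non / (m_vd1 + m_non)
    return np.array([a_vd1, a_vd2, a_non])


def _pick(u: float, items) -> str:
    acc = 0.0
    for label, p in items:
        acc += p
        if u < acc:
            return label
    return items[-1][0]


def _trunc_lognorm(u: float, median: float, sigma: float,
                   lo: float, hi: float) -> float:
    """Inverse-CDF draw from LogNormal(ln median, sigma) truncated to [lo, hi]."""
    mu = np.log(median)
    a = norm.cdf((np.log(max(lo, 1e-9)) - mu) / sigma)
    b = norm.cdf((np.log(max(hi, lo + 1e-9)) - mu) / sigma)
    uu = a + u * max(b - a, 1e-12)
    uu = min(max(uu, 1e-12), 1 - 1e-12)
    return float(np.exp(mu + sigma * norm.ppf(uu)))


def _calibrate_probs(mult: np.ndarray, target: float) -> np.ndarray:
    """p_i = min(c*mult_i, 1) with c solved so that mean(p) == target."""
    if target <= 0:
        return np.zeros_like(mult)
    if target >= 1:
        return np.ones_like(mult)
    lo, hi = 0.0, 1.0 / max(mult.min(), 1e-12)
    for _ in range(200):
        c = 0.5 * (lo + hi)
        if np.minimum(c * mult, 1.0).mean() < target:
            lo = c
        else:
            hi = c
    return np.minimum(0.5 * (lo + hi) * mult, 1.0)


def _realloc(parts: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Rescale parts by weights while preserving their sum."""
    total = parts.sum()
    w = parts * weights
    s = w.sum()
    return w * (total / s) if s > 0 else parts


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate one synthetic cohort; deterministic for fixed (config, seed).

    Each patient draws from its own counter-derived substream, so adding
    patients never perturbs existing ones.
    """
    cfg = config if config is not None else GeneratorConfig()
    cfg.validate()
    seed = cfg.seed if seed is None else int(seed)
    n = cfg.n_patients
    if n == 0:
        return empty_cohort()

    cf = cfg.covariate_freqs
    e = cfg.effects
    r = cfg.rates
    lo_age, hi_age = cfg.donor_age_range
    log_span = np.log(hi_age / lo_age)

    patients: list[dict] = []
    lat: dict[str, np.ndarray] = {k: np.zeros(n) for k in
                                  ("frailty", "gd_level", "split_tilt",
                                   "susceptibility", "mud", "sero", "atg",
                                   "donor_age", "malignant")}
    counts = {c: np.zeros((n, len(POST_DAYS))) for c in COUNT_COLS}
    pre_counts = {c: np.zeros(n) for c in COUNT_COLS}

    p_mud = cf["mud"]
    p_sero = cf["atg"] + cf["alemtuzumab"]

    for i in range(n):
        rng = np.random.default_rng([seed, i, 0])
        u = rng.uniform(size=16)
        pid = f"P{i + 1:03d}"

        donor_items = (("MSD", cf["msd"]), ("MUD", cf["mud"]), ("MFD", cf["mfd"]))
        donor_type = _pick(u[0], donor_items)
        sero_items = (("atg", cf["atg"]), ("alem", cf["alemtuzumab"]),
                      ("none", 1 - cf["atg"] - cf["alemtuzumab"]))
        sero = _pick(u[1], sero_items)
        sex = "F" if u[2] < cf["female"] else "M"
        malignant = u[3] < cf["malignant"]
        disease = _pick(u[4], _DISEASES_MAL if malignant else _DISEASES_NONMAL)
        prophylaxis = "MTX" if u[5] < cf["mtx"] else "MMF"
        hla = "10/10" if u[6] < cf["hla_10_10"] else "9/10"
        cmv_d, cmv_p = next((d, p) for d, p, q in _cum(_CMV_DR) if u[7] < q)
        ebv_d = "pos" if u[8] < cf["ebv_sero_donor_pos"] else "neg"
        ebv_p = "pos" if u[9] < cf["ebv_sero_patient_pos"] else "neg"
        conditioning = _pick(u[10], _CONDITIONING)
        age = int(19 * rng.beta(1.0, 1.5))
        donor_age = int(lo_age * np.exp(log_span * rng.beta(1.5, 1.1)))
        graft_cd3 = float(4.9e7 * np.exp(0.71 * rng.normal()))
        graft_cd34 = float(5.2e6 * np.exp(0.62 * rng.normal()))
        graft_cd45 = float(3.9e8 * np.exp(0.51 * rng.normal()))

        patients.append({
            "patient_id": pid, "age_years": age, "sex": sex,
            "disease_label": disease, "malignant": malignant,
            "donor_type": donor_type, "donor_age_years": donor_age,
            "atg": sero == "atg", "alemtuzumab": sero == "alem",
            "gvhd_prophylaxis": prophylaxis, "conditioning_label": conditioning,
            "hla_match": hla, "cmv_sero_donor": cmv_d, "cmv_sero_patient": cmv_p,
            "ebv_sero_donor": ebv_d, "ebv_sero_patient": ebv_p,
            "graft_cd3_per_kg": graft_cd3, "graft_cd34_per_kg": graft_cd34,
            "graft_cd45_per_kg": graft_cd45,
        })
        lat["mud"][i] = donor_type == "MUD"
        lat["sero"][i] = sero != "none"
        lat["atg"][i] = sero == "atg"
        lat["donor_age"][i] = donor_age
        lat["malignant"][i] = malignant
        lat["frailty"][i] = rng.normal()
        lat["gd_level"][i] = rng.normal()
        lat["split_tilt"][i] = rng.normal()
        lat["susceptibility"][i] = rng.normal()

    # donor-age slope on the γδ compartment, centred within the cohort
    age_fac = np.exp(e.donor_age_slope_on_gd
                     * (lat["donor_age"] - lat["donor_age"].mean()))

    for i in range(n):
        rng = np.random.default_rng([seed, i, 3])
        # -- counts ---------------------------------------------------------
        z_gd = rng.normal(size=len(POST_DAYS))
        z_ab = rng.normal(size=len(POST_DAYS))
        z_gd_pre, z_ab_pre = rng.normal(), rng.normal()
        splits = np.vstack([
            rng.dirichlet(_tilt_alphas(split_alphas(SPLIT_MEDIANS[j],
                                                    cfg.split_concentration),
                                       cfg.split_tilt_sd * lat["split_tilt"][i]))
            for j in range(len(POST_DAYS))])
        pre_split = rng.dirichlet(_tilt_alphas(
            split_alphas(PRE_SPLIT, cfg.split_concentration),
            cfg.split_tilt_sd * lat["split_tilt"][i]))
        pool_frac = rng.beta(0.92 * 40, 0.08 * 40, size=len(POST_DAYS) + 1)
        cd4_share = rng.beta(np.array(CD4_SHARE + (0.55,)) * 10,
                             (1 - np.array(CD4_SHARE + (0.55,))) * 10)
        h4 = rng.beta(np.array(HLADR_CD4 + (0.15,)) * 6,
                      (1 - np.array(HLADR_CD4 + (0.15,))) * 6)
        h8 = rng.beta(np.array(HLADR_CD8 + (0.18,)) * 6,
                      (1 - np.array(HLADR_CD8 + (0.18,))) * 6)

        # mean-1 log-normal frailty times the +sd^2/2 baseline compensation
        # collapses to exp(sd * N): patient-level median exactly 1
        frail = cfg.frailty_sd * lat["frailty"][i]
        gdlvl = cfg.gd_level_sd * lat["gd_level"][i]

        gd_tot = age_fac[i] * np.exp(np.log(GD_MEDIANS) + frail + gdlvl
                                     + np.asarray(GD_SIGMAS) * z_gd)
        ab = np.exp(np.log(AB_MEDIANS) + frail
                    + np.asarray(AB_SIGMAS) * z_ab)
        parts = splits * gd_tot[:, None]  # columns: vd1, vd2, non

        gd_pre = float(age_fac[i] * np.exp(np.log(PRE_GD_MEDIAN) + frail + gdlvl
                                           + 0.9 * z_gd_pre))
        ab_pre = float(np.exp(np.log(PRE_AB_MEDIAN) + frail + 0.7 * z_ab_pre))

        # planted covariate effects, centred on the log scale
        vd2_fac = e.mud_on_vd2 ** (float(lat["mud"][i]) - p_mud)
        for d in (30, 60, 100, 180):
            parts[_DAY_IDX[d], 1] *= vd2_fac
        gd_tot = parts.sum(axis=1)

        cd3 = ab + gd_tot
        pool = cd3 * pool_frac[:-1]
        share = cd4_share[:-1].copy()
        sero_x = float(lat["sero"][i]) - p_sero
        for d in (30, 60, 100):
            j = _DAY_IDX[d]
            w = e.serotherapy_on_cd4 ** sero_x
            share[j] = share[j] * w / (share[j] * w + (1 - share[j]))
        cd4 = pool * share
        cd8 = pool * (1 - share)

        counts["gd_t"][i] = gd_tot
        counts["ab_t"][i] = ab
        counts["cd3"][i] = cd3
        counts["vd1"][i], counts["vd2"][i], counts["non_vd1_vd2"][i] = parts.T
        counts["cd4"][i] = cd4
        counts["cd8"][i] = cd8
        counts["cd4_hladr"][i] = cd4 * h4[:-1]
        counts["cd8_hladr"][i] = cd8 * h8[:-1]

        pre_parts = pre_split * gd_pre
        pre_cd3 = ab_pre + gd_pre
        pre_pool = pre_cd3 * pool_frac[-1]
        pre_counts["gd_t"][i] = gd_pre
        pre_counts["ab_t"][i] = ab_pre
        pre_counts["cd3"][i] = pre_cd3
        pre_counts["vd1"][i], pre_counts["vd2"][i], pre_counts["non_vd1_vd2"][i] = pre_parts
        pre_counts["cd4"][i] = pre_pool * cd4_share[-1]
        pre_counts["cd8"][i] = pre_pool * (1 - cd4_share[-1])
        pre_counts["cd4_hladr"][i] = pre_counts["cd4"][i] * h4[-1]
        pre_counts["cd8_hladr"][i] = pre_counts["cd8"][i] * h8[-1]

    # latent Vδ2 propensity: standardized log time-averaged Vδ2/αβ level
    log_r = np.zeros(n)
    for i in range(n):
        ratio = counts["vd2"][i] / counts["ab_t"][i]
        t = np.asarray(POST_DAYS, dtype=float)
        log_r[i] = np.log(np.trapezoid(ratio, t) / (t[-1] - t[0]))
    z = (log_r - log_r.mean()) / max(log_r.std(), 1e-12)

    # -- clinical events ----------------------------------------------------
    suscept = np.exp(cfg.viral_susceptibility_sd * lat["susceptibility"])
    p_agvhd = _calibrate_probs(np.ones(n), r.agvhd_any)
    sev_target = min(r.agvhd_2to4 / max(r.agvhd_any, 1e-9), 1.0)
    p_sev = _calibrate_probs(np.exp(e.vd2_propensity_on_agvhd * z), sev_target)
    p_ebv = _calibrate_probs(
        (e.atg_on_ebv ** lat["atg"]) * np.exp(e.vd2_propensity_on_ebv * z)
        * suscept, r.ebv)
    p_cmv = _calibrate_probs(suscept, r.cmv)
    p_adv = _calibrate_probs(suscept, r.adv)

    outcome_rows: list[dict] = []
    panel_drop: dict[int, float] = {}
    for i in range(n):
        rng = np.random.default_rng([seed, i, 1])
        u = rng.uniform(size=24)
        fup = int(np.clip(np.exp(np.log(737.0) + 0.45 * norm.ppf(u[0])),
                          280, 3000))
        death = u[1] < r.death
        death_day = None
        if death:
            death_day = int(round(_trunc_lognorm(u[2], 250.0, 0.6, 30, fup)))
            fup = death_day
        limit = fup

        agvhd = u[3] < p_agvhd[i]
        severe = agvhd and (u[4] < p_sev[i])
        grade, onset, organs = 0, None, ""
        if agvhd:
            grade = (_pick(u[5], (("2", 0.60), ("3", 0.275), ("4", 0.125)))
                     if severe else "1")
            grade = int(grade)
            onset = max(1, int(round(_trunc_lognorm(
                u[6], r.agvhd_onset_median_day, 0.54, 1, limit))))
            org = []
            if u[7] < 0.85:
                org.append("skin")
            if u[8] < (0.60 if severe else 0.20):
                org.append("gut")
            if u[9] < (0.30 if severe else 0.10):
                org.append("liver")
            organs = ";".join(org) if org else "skin"

        ebv = u[10] < p_ebv[i]
        ebv_day = (max(1, int(round(_trunc_lognorm(
            u[11], r.ebv_onset_median_day, 0.70, 1, limit)))) if ebv else None)
        cmv = u[12] < p_cmv[i]
        cmv_day = (max(1, int(round(_trunc_lognorm(
            u[13], r.cmv_onset_median_day, 1.11, 1, limit)))) if cmv else None)
        adv = u[14] < p_adv[i]
        adv_sys = adv and (u[15] < 0.615)
        adv_day = (max(1, int(round(_trunc_lognorm(
            u[16], r.adv_onset_median_day, 0.73, 1, limit)))) if adv else None)

        malignant = bool(lat["malignant"][i])
        relapse = malignant and (u[17] < r.relapse_in_malignant)
        relapse_day = (max(1, int(round(_trunc_lognorm(
            u[18], r.relapse_median_day, 0.6, 1, limit)))) if relapse else None)

        trm = death and not (relapse and relapse_day is not None
                             and relapse_day <= death_day)

        outcome_rows.append({
            "patient_id": f"P{i + 1:03d}", "followup_days": fup,
            "death": death, "death_day": death_day, "trm": trm,
            "relapse": relapse, "relapse_day": relapse_day,
            "agvhd_grade": grade, "agvhd_onset_day": onset,
            "agvhd_organs": organs,
            "ebv": ebv, "ebv_day": ebv_day, "cmv": cmv, "cmv_day": cmv_day,
            "adv_systemic": adv_sys,
            "adv_systemic_day": adv_day if adv_sys else None,
            "adv_gi": adv, "adv_gi_day": adv_day,
        })
        panel_drop[i] = death_day if death else np.inf

        # infection-response reallocations (sum-preserving)
        if ebv:
            for d in (100, 180, 240):
                j = _DAY_IDX[d]
                parts = np.array([counts["vd1"][i, j], counts["vd2"][i, j],
                                  counts["non_vd1_vd2"][i, j]])
                parts = _realloc(parts, np.array([e.ebv_on_vd1, 1.0, 1.0]))
                (counts["vd1"][i, j], counts["vd2"][i, j],
                 counts["non_vd1_vd2"][i, j]) = parts
        if cmv:
            for d in (60, 100, 180):
                j = _DAY_IDX[d]
                pair = np.array([counts["cd4"][i, j], counts["cd8"][i, j]])
                h4f = counts["cd4_hladr"][i, j] / max(pair[0], 1e-12)
                h8f = counts["cd8_hladr"][i, j] / max(pair[1], 1e-12)
                pair = _realloc(pair, np.array([1.0, e.cmv_on_cd8]))
                counts["cd4"][i, j], counts["cd8"][i, j] = pair
                counts["cd4_hladr"][i, j] = pair[0] * h4f
                counts["cd8_hladr"][i, j] = pair[1] * h8f

    # -- assemble tables ----------------------------------------------------
    panel_rows: list[dict] = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng([seed, i, 2])
        miss = rng.uniform(size=len(POST_DAYS)) < cfg.missingness_rate
        row = {"patient_id": pid, "day": "pre"}
        row.update({c: round(float(pre_counts[c][i]), 4) for c in COUNT_COLS})
        panel_rows.append(row)
        for j, d in enumerate(POST_DAYS):
            if d > panel_drop[i] or miss[j]:
                continue
            row = {"patient_id": pid, "day": str(d)}
            row.update({c: round(float(counts[c][i, j]), 4) for c in COUNT_COLS})
            panel_rows.append(row)

    return Cohort(
        pd.DataFrame(patients, columns=list(PATIENT_COLS)),
        pd.DataFrame(panel_rows, columns=list(PANEL_COLS)),
        pd.DataFrame(outcome_rows, columns=list(OUTCOME_COLS)),
    )


def _tilt_alphas(alphas: np.ndarray, log_tilt: float) -> np.ndarray:
    """Per-patient persistent Vδ2-share tilt on the Dirichlet weights."""
    a = alphas.copy()
    a[1] *= np.exp(log_tilt)
    return a


def _cum(items):
    acc = 0.0
    for row in items:
        acc += row[-1]
        yield (*row[:-1], acc)
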