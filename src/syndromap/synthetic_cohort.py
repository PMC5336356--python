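"""Synthetic TBI cohorts with the statistical structure the analysis assumes.

A single latent severity score per patient drives a CT-positive class and,
within it, correlated binary CT findings (logistic link, marginal rates
calibrated by root-finding) and the ordinal Marshall/Rotterdam severity
scores.  Six-month psychological and cognitive outcomes are drawn with
marginal means/SDs matching the study's descriptive table, correlated with
severity; GOS-E at 3 and 6 months arises from a thresholded latent recovery
process that improves over time.

A *planted* subgroup of CT-negative patients emulates the poor-recovery
mild-TBI phenotype the mapping stage is meant to find: forced PTSD
diagnosis (with the checklist score elevated through the PTSD mixture),
decremented cognition, a GOS-E drop at 6 months, and a heterozygote-enriched
genotype for one SNP.  Marginal rates are compensated so that planting does
not move the configured column marginals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .cde_io import (
    SNP_VARIABLES,
    CohortTable,
    default_specs,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# Marginal rates of the binary CT findings and the 6-month PTSD diagnosis
# (study descriptive table; CT brain pathology itself is the latent class).
DEFAULT_BINARY_RATES: dict[str, float] = {
    "skull_fracture": 0.22,
    "skull_base_fracture": 0.11,
    "facial_fracture": 0.17,
    "epidural_hematoma": 0.05,
    "subdural_hematoma": 0.26,
    "subarachnoid_hemorrhage": 0.26,
    "contusion": 0.24,
    "midline_shift": 0.07,
    "cisternal_compression": 0.12,
    "ptsd_dx_6m": 0.24,
}

DEFAULT_OUTCOME_MEANS_SDS: dict[str, tuple[float, float]] = {
    "pcl_6m": (32.98, 14.80),
    "wais_psi_6m": (99.20, 15.96),
    "cvlt_sdc_6m": (-0.08, 1.14),
    "cvlt_ldc_6m": (-0.19, 1.17),
}

# Missingness concentrated in the 6-month follow-up (counts / 586).
DEFAULT_MISSING_RATES: dict[str, float] = {
    "ptsd_dx_6m": 248 / 586,
    "pcl_6m": 248 / 586,
    "wais_psi_6m": 281 / 586,
    "cvlt_sdc_6m": 290 / 586,
    "cvlt_ldc_6m": 291 / 586,
}

# 3-category genotype frequencies (homozygote-1, heterozygote, homozygote-2).
# PARP1 from the study's genotyped-cohort column; the remaining SNPs use
# Hardy-Weinberg-consistent frequencies typical of the published literature.
DEFAULT_GENOTYPE_FREQS: dict[str, tuple[float, float, float]] = {
    "PARP1_rs3219119": (0.225, 0.389, 0.386),
    "ANKK1_rs1800497": (0.45, 0.44, 0.11),
    "ANKK1_rs4938016": (0.36, 0.48, 0.16),
    "ANKK1_rs11604671": (0.30, 0.49, 0.21),
    "COMT_rs4680": (0.25, 0.50, 0.25),
    "DRD2_rs6277": (0.30, 0.49, 0.21),
}


@dataclass(frozen=True)
class PlantedSubgroup:
    """Poor-recovery mild-TBI phenotype planted among CT-negative patients.

    ``fraction`` is the share of CT-negative patients planted (default
    matches the study's selected subgroup: 37 of 154 CT-negative genotyped
    patients).  ``gose6_decrement`` is subtracted from the 6-month latent
    recovery score (points on the GOS-E scale before discretization).
    ``het_odds_ratio`` multiplies the heterozygote odds of ``snp`` for
    planted members.
    """

    fraction: float = 37 / 154
    gose6_decrement: float = 3.0
    ptsd_probability: float = 1.0
    het_odds_ratio: float = 4.0
    snp: str = "PARP1_rs3219119"
    cognitive_decrement_sd: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 586
    seed: int = 0
    severity_prevalence: float = 0.44
    binary_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_RATES)
    )
    outcome_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_MEANS_SDS)
    )
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    genotype_freqs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_FREQS)
    )
    planted: PlantedSubgroup = field(default_factory=PlantedSubgroup)
    # ordinal CT severity targets (overall mean, CT-negative floor value)
    marshall_mean: float = 1.76
    rotterdam_mean: float = 2.45
    # GOS-E latent recovery process
    gose3_ctneg_mean: float = 6.5
    gose_ct_penalty: float = 1.6
    gose_noise_sd: float = 1.1
    gose_improvement: float = 0.5
    gose_change_noise_sd: float = 0.6
    # correlation of 6-month cognition with latent severity
    severity_loading: float = 0.3
    pcl_ptsd_separation: float = 20.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        if not 0 <= self.severity_prevalence <= 1:
            raise ConfigError("severity_prevalence must be a probability")
        for name, p in self.binary_rates.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"rate for {name} outside [0, 1]")
        for name, p in self.missing_rates.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"missing rate for {name} outside [0, 1]")
        for name, freqs in self.genotype_freqs.items():
            if len(freqs) != 3 or abs(sum(freqs) - 1.0) > 1e-8:
                raise ConfigError(f"genotype frequencies for {name} must sum to 1")
        if not 0 <= self.planted.fraction <= 1:
            raise ConfigError(
                "planted fraction is the share of CT-negative patients and "
                "must lie in [0, 1]"
            )
        if self.planted.het_odds_ratio <= 0:
            raise ConfigError("heterozygote odds ratio must be positive")
        if self.planted.snp not in self.genotype_freqs:
            raise ConfigError(f"planted SNP {self.planted.snp!r} has no frequencies")
        # planting forces PTSD; the background rate is compensated and must
        # remain a valid probability
        f_all = self.planted.fraction * (1 - self.severity_prevalence)
        p_t = self.binary_rates.get("ptsd_dx_6m", 0.0)
        if f_all * self.planted.ptsd_probability > p_t + 1e-12 and f_all < 1:
            raise ConfigError(
                "planted subgroup alone exceeds the configured PTSD rate; "
                "lower the planted fraction or raise the PTSD rate"
            )


def _calibrate_logistic_intercept(
    target: float, slope: float, z_grid: np.ndarray
) -> float:
    """Intercept a such that mean(expit(a + slope*z)) over the grid = target."""
    def gap(a: float) -> float:
        return float(np.mean(expit(a + slope * z_grid))) - target

    return optimize.brentq(gap, -30, 30)


def _enriched_freqs(
    freqs: tuple[float, float, float], het_or: float
) -> np.ndarray:
    """Multiply the heterozygote odds by ``het_or``; split the remaining
    mass between the homozygotes in their background proportions."""
    p_het = freqs[1]
    odds = het_or * p_het / (1 - p_het)
    p_het_new = odds / (1 + odds)
    rest = (1 - p_het_new) / (freqs[0] + freqs[2])
    return np.array([freqs[0] * rest, p_het_new, freqs[2] * rest])


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw one synthetic cohort; identical config and seed give identical
    tables (and byte-identical CSV exports)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    prev = config.severity_prevalence
    planted_cfg = config.planted

    # latent severity and CT-positive class -----------------------------
    z = rng.standard_normal(n)
    thr = stats.norm.ppf(1 - prev) if 0 < prev < 1 else np.inf
    ct = z >= thr if prev > 0 else np.zeros(n, bool)
    if prev >= 1:
        ct = np.ones(n, bool)

    ctneg_idx = np.flatnonzero(~ct)
    k_planted = int(round(planted_cfg.fraction * len(ctneg_idx)))
    planted = np.zeros(n, bool)
    if k_planted:
        planted[rng.choice(ctneg_idx, size=k_planted, replace=False)] = True
    f_all = planted.sum() / n

    data: dict[str, np.ndarray] = {}
    data["ct_brain_pathology"] = ct.astype(float)

    # binary CT findings: logistic link to severity within the CT+ class,
    # intercepts calibrated so the cohort marginal hits the configured rate
    slope = 1.5
    if prev > 0:
        u = (np.arange(4001) + 0.5) / 4001
        z_plus_grid = stats.norm.ppf((1 - prev) + u * prev)
        mu_plus = z_plus_grid.mean()
        for name, rate in config.binary_rates.items():
            if name == "ptsd_dx_6m":
                continue
            cond = rate / prev
            if cond > 1:
                raise ConfigError(
                    f"rate {rate} for {name} unreachable at prevalence {prev}"
                )
            x = np.zeros(n)
            if 0 < cond < 1:
                a = _calibrate_logistic_intercept(cond, slope, z_plus_grid - mu_plus)
                p_i = expit(a + slope * (z - mu_plus))
                x[ct] = (rng.random(ct.sum()) < p_i[ct]).astype(float)
            elif cond == 1:
                x[ct] = 1.0
            data[name] = x
    else:
        for name in config.binary_rates:
            if name != "ptsd_dx_6m":
                data[name] = np.zeros(n)

    # ordinal CT severity: floor value when CT-negative, severity-linked
    # discretized latent otherwise (targets the overall mean approximately)
    if prev > 0 and ct.any():
        tn = stats.truncnorm((thr - 0) / 1, np.inf, loc=0, scale=1)
        mu_p, sd_p = tn.mean(), tn.std()
        z_std = np.where(ct, (z - mu_p) / sd_p, 0.0)
        m_plus = (config.marshall_mean - (1 - prev) * 1.0) / prev
        r_plus = (config.rotterdam_mean - (1 - prev) * 2.0) / prev
        marshall = np.ones(n)
        rotterdam = np.full(n, 2.0)
        marshall[ct] = np.clip(
            np.rint(m_plus + 0.9 * z_std[ct] + 0.5 * rng.standard_normal(ct.sum())),
            1, 6,
        )
        rotterdam[ct] = np.clip(
            np.rint(r_plus + 0.7 * z_std[ct] + 0.4 * rng.standard_normal(ct.sum())),
            1, 6,
        )
    else:
        marshall = np.ones(n)
        rotterdam = np.full(n, 2.0)
    data["marshall_ct"] = marshall
    data["rotterdam_ct"] = rotterdam

    # PTSD diagnosis: planted members forced positive; the background rate
    # is lowered so the cohort marginal stays at the configured rate
    p_t = config.binary_rates.get("ptsd_dx_6m", 0.24)
    p_bg = (p_t - f_all * planted_cfg.ptsd_probability) / (1 - f_all) if f_all < 1 else p_t
    p_bg = float(np.clip(p_bg, 0, 1))
    ptsd = (rng.random(n) < p_bg).astype(float)
    if k_planted:
        ptsd[planted] = (rng.random(k_planted) < planted_cfg.ptsd_probability).astype(
            float
        )
    data["ptsd_dx_6m"] = ptsd

    # PCL: gamma mixture above the scale floor, conditional on PTSD status,
    # with component moments solved from the configured marginal mean/SD
    m_pcl, s_pcl = config.outcome_means_sds["pcl_6m"]
    delta = config.pcl_ptsd_separation
    floor = 17.0
    v_comp = s_pcl**2 - p_t * (1 - p_t) * delta**2
    if v_comp <= 0:
        raise ConfigError("PCL separation too large for the configured SD")
    m0 = m_pcl - p_t * delta - floor
    m1 = m0 + delta
    if m0 <= 0:
        raise ConfigError("PCL mixture mean below the scale floor")
    pcl = np.empty(n)
    for level, mean_c in ((0.0, m0), (1.0, m1)):
        mask = ptsd == level
        shape = mean_c**2 / v_comp
        scale = v_comp / mean_c
        pcl[mask] = floor + rng.gamma(shape, scale, size=int(mask.sum()))
    data["pcl_6m"] = np.clip(pcl, 17, 85)

    # cognition: unit-variance latent mixing severity, a shared verbal-
    # learning factor, and noise; planted decrement is mean-compensated
    rho = config.severity_loading
    shared = rng.standard_normal(n)
    plant_dev = (planted.astype(float) - f_all) * planted_cfg.cognitive_decrement_sd
    for name, extra_shared in (
        ("wais_psi_6m", 0.0),
        ("cvlt_sdc_6m", 0.6),
        ("cvlt_ldc_6m", 0.6),
    ):
        m_c, s_c = config.outcome_means_sds[name]
        resid = max(1.0 - rho**2 - extra_shared**2, 0.0) ** 0.5
        latent = -rho * z + extra_shared * shared + resid * rng.standard_normal(n)
        vals = m_c + s_c * (latent - plant_dev)
        lo, hi = {"wais_psi_6m": (50, 150), "cvlt_sdc_6m": (-4.0, 2.5),
                  "cvlt_ldc_6m": (-3.5, 2.5)}[name]
        data[name] = np.clip(vals, lo, hi)

    # GOS-E: latent recovery, improvement from 3 to 6 months, planted drop
    r3 = (
        config.gose3_ctneg_mean
        - config.gose_ct_penalty * ct
        - 0.3 * np.where(ct, np.maximum(z - thr, 0), 0)
        + config.gose_noise_sd * rng.standard_normal(n)
    )
    r6 = (
        r3
        + config.gose_improvement
        + config.gose_change_noise_sd * rng.standard_normal(n)
        - planted_cfg.gose6_decrement * planted
    )
    data["gose_3m"] = np.clip(np.rint(r3), 1, 8)
    data["gose_6m"] = np.clip(np.rint(r6), 1, 8)

    # genotypes: independent across SNPs; heterozygote-enriched for planted
    for name in SNP_VARIABLES:
        freqs = np.asarray(config.genotype_freqs[name], dtype=float)
        codes = 1.0 + rng.choice(3, size=n, p=freqs)
        if k_planted and name == planted_cfg.snp:
            enr = _enriched_freqs(tuple(freqs), planted_cfg.het_odds_ratio)
            codes[planted] = 1.0 + rng.choice(3, size=k_planted, p=enr)
        data[name] = codes

    # missingness: missing completely at random per variable, by default
    # only in the 6-month follow-up variables
    for name, rate in config.missing_rates.items():
        if name in data and rate > 0:
            mask = rng.random(n) < rate
            data[name][mask] = np.nan

    ids = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")
    ordered = (
        ["ct_brain_pathology"]
        + [c for c in DEFAULT_BINARY_RATES if c != "ptsd_dx_6m"]
        + ["marshall_ct", "rotterdam_ct", "ptsd_dx_6m", "pcl_6m", "wais_psi_6m",
           "cvlt_sdc_6m", "cvlt_ldc_6m", "gose_3m", "gose_6m"]
        + list(SNP_VARIABLES)
    )
    frame = pd.DataFrame({c: data[c] for c in ordered}, index=ids)
    truth = pd.DataFrame(
        {"ct_latent": ct, "planted_member": planted, "severity": z}, index=ids
    )
    return CohortTable(frame, default_specs(), truth=truth)


def truth_labels(cohort: CohortTable) -> pd.DataFrame:
    """Generating labels (CT latent class, planted membership, severity).

    Only available for cohorts produced by :func:`generate_cohort`.
    """
    if cohort.truth is None:
        raise ValueError("cohort carries no generating labels (not synthetic)")
    return cohort.truth
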