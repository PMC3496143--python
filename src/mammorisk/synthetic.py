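"""Synthetic case-control cohorts and hazard tables with the
statistical structure the risk model assumes.

The generator emulates a population-based case-control study of
postmenopausal women aged 50-74: genotypes at 18 independent loci in
Hardy-Weinberg proportions, percent mammographic density and BMI drawn
from a Gaussian copula with negative dependence and discretised to the
published category grids, clinical factors drawn independently, case
status assigned by rejection sampling proportional to each woman's
multiplicative relative risk, and controls frequency-matched to the
realised case age distribution.

Every subject row carries her generative true relative risk so that
parameter-recovery tests can compare estimates against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import effects as eff
from .evaluation import ReclassificationTable, RiskCutoffs
from .hazards import HazardSchedule

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_hazard_table",
    "table3_fixture",
]

# category grids matching the packaged effect-size table; upper caps for
# the open-ended top categories are generator choices
_PD_EDGES = (0.0, 0.0, 10.0, 25.0, 50.0, 75.0, 100.0)
_BMI_EDGES = (16.0, 21.79, 23.30, 25.02, 27.64, 42.0)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic case-control generator.

    Defaults mirror the emulated study: 1,017 cases and 856 controls
    (the complete-data subset size), ages 50-74, published per-locus
    odds ratios, a negative PD-BMI copula correlation, and a
    population disease probability over the ascertainment window of 3%.
    """

    n_cases: int = 1017
    n_controls: int = 856
    snp_effects: list = None
    pd_probs: tuple = eff.DEFAULT_PD_PROBS
    bmi_probs: tuple = eff.DEFAULT_BMI_PROBS
    pd_bmi_rho: float = eff.DEFAULT_PD_BMI_RHO
    menarche_probs: tuple = eff.DEFAULT_MENARCHE_PROBS
    first_birth_probs: tuple = eff.DEFAULT_FIRST_BIRTH_PROBS
    bbd_prev: float = eff.DEFAULT_BBD_PREV
    fh_prev: float = eff.DEFAULT_FH_PREV
    population_rate: float = 0.03
    age_low: int = 50
    age_high: int = 74
    model_spec: str = "full"
    seed: int | None = None

    def __post_init__(self):
        if self.snp_effects is None:
            self.snp_effects = eff.load_reference_effects().snp_effects
        for s in self.snp_effects:
            if not 0 < s.allele_freq < 1:
                raise ValueError(f"allele frequency at {s.rsid} outside (0, 1)")
        if not -1 < self.pd_bmi_rho <= 0:
            raise ValueError("pd_bmi_rho must be in (-1, 0]")
        if not 0 < self.population_rate < 1:
            raise ValueError("population_rate must be in (0, 1)")

    def effect_table(self) -> eff.EffectSizeTable:
        base = eff.load_reference_effects()
        return eff.EffectSizeTable(
            snp_effects=list(self.snp_effects),
            pd_effects=base.pd_effects,
            bmi_effects=base.bmi_effects,
            clinical_effects=base.clinical_effects,
        )

    def reference(self) -> eff.ReferenceDistribution:
        return eff.ReferenceDistribution(
            pd_probs=self.pd_probs,
            bmi_probs=self.bmi_probs,
            menarche_probs=self.menarche_probs,
            first_birth_probs=self.first_birth_probs,
            bbd_prev=self.bbd_prev,
            fh_prev=self.fh_prev,
            pd_bmi_rho=self.pd_bmi_rho,
        )

    def max_relative_risk(self) -> float:
        """Largest combined relative risk any profile can attain."""
        table = self.effect_table()
        ref = self.reference()
        rr = 1.0
        ce = table.clinical_effects
        rr *= (
            ce["menarche"] ** 2 * ce["first_birth"] ** 2 * ce["bbd"] * ce["fh"]
        ) / eff.component_mean_rr(table, "clinical", ref)
        rr *= (
            max(r for _, r in table.pd_effects) * max(r for _, r in table.bmi_effects)
        ) / eff.component_mean_rr(table, "pd_bmi", ref)
        raw = 1.0
        for s in self.snp_effects:
            raw *= s.odds_ratio**2
        rr *= raw / eff.snp_mean_relative_risk(self.snp_effects)
        return rr


@dataclass
class SyntheticCohort:
    """Generated case-control data with per-subject generative truth."""

    data: pd.DataFrame
    config: GeneratorConfig

    @property
    def cases(self) -> pd.DataFrame:
        return self.data[self.data.status == 1]

    @property
    def controls(self) -> pd.DataFrame:
        return self.data[self.data.status == 0]


def _draw_profiles(cfg: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n risk-factor profiles from the population distribution."""
    out = {}
    out["age"] = rng.integers(cfg.age_low, cfg.age_high + 1, size=n)
    out["menarche_level"] = rng.choice(3, size=n, p=cfg.menarche_probs)
    out["first_birth_level"] = rng.choice(3, size=n, p=cfg.first_birth_probs)
    out["bbd"] = (rng.random(n) < cfg.bbd_prev).astype(int)
    out["fh"] = (rng.random(n) < cfg.fh_prev).astype(int)

    # PD and BMI via a Gaussian copula with negative dependence
    rho = cfg.pd_bmi_rho
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    u_pd, u_bmi = norm.cdf(z1), norm.cdf(z2)

    pd_cum = np.concatenate([[0.0], np.cumsum(cfg.pd_probs)])
    cat = np.clip(np.searchsorted(pd_cum[1:-1], u_pd, side="right"), 0, 5)
    frac = (u_pd - pd_cum[cat]) / np.maximum(pd_cum[cat + 1] - pd_cum[cat], 1e-12)
    lo = np.asarray(_PD_EDGES)[cat]
    hi = np.asarray(_PD_EDGES)[cat + 1]
    pd_val = lo + frac * (hi - lo)
    out["pd_percent"] = np.where(cat == 0, 0.0, np.maximum(pd_val, 1e-6))

    bmi_cum = np.concatenate([[0.0], np.cumsum(cfg.bmi_probs)])
    cat_b = np.clip(np.searchsorted(bmi_cum[1:-1], u_bmi, side="right"), 0, 4)
    frac_b = (u_bmi - bmi_cum[cat_b]) / np.maximum(bmi_cum[cat_b + 1] - bmi_cum[cat_b], 1e-12)
    lo_b = np.asarray(_BMI_EDGES)[cat_b]
    hi_b = np.asarray(_BMI_EDGES)[cat_b + 1]
    out["bmi"] = lo_b + frac_b * (hi_b - lo_b)

    for s in cfg.snp_effects:
        p = s.allele_freq
        out[s.rsid] = rng.binomial(2, p, size=n)
    return pd.DataFrame(out)


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a frequency-matched case-control cohort.

    Case status is assigned by rejection sampling on the odds scale: a
    candidate profile with combined relative risk r becomes a case with
    probability c·r / (1 + c·r), where c is the baseline disease odds
    implied by ``population_rate``.  The disease odds are thus exactly
    proportional to r, which is the generative model under which the
    published odds ratios are the true logistic coefficients (so
    refitting recovers them without the odds/risk discrepancy).
    Control candidates are retained with the complementary
    probability; control ages are then re-drawn from the realised case
    age distribution (frequency matching).  Deterministic under
    ``seed``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    # a case-control emulation needs a minority disease: baseline odds
    # at or above 1 make the odds ∝ RR scheme degenerate
    if config.population_rate >= 0.5:
        raise ValueError(
            "infeasible config: population_rate "
            f"{config.population_rate} implies baseline disease odds >= 1"
        )
    table = config.effect_table()
    ref = config.reference()

    def accumulate(n_target: int, want_case: bool) -> pd.DataFrame:
        chunks, got = [], 0
        while got < n_target:
            n_draw = max(int((n_target - got) * (4 if want_case else 1.3)), 200)
            cand = _draw_profiles(config, n_draw, rng)
            rr = eff.score_cohort(cand, table, config.model_spec, ref)
            odds = config.population_rate / (1 - config.population_rate) * rr
            p_case = odds / (1 + odds)
            u = rng.random(len(cand))
            keep = (u < p_case) if want_case else (u >= p_case)
            sel = cand[keep].copy()
            sel["true_rr"] = rr[keep]
            chunks.append(sel)
            got += len(sel)
        return pd.concat(chunks, ignore_index=True).iloc[:n_target].copy()

    cases = accumulate(config.n_cases, want_case=True)
    cases["status"] = 1
    controls = accumulate(config.n_controls, want_case=False)
    controls["status"] = 0
    # frequency-match control ages to the realised case age distribution
    controls["age"] = rng.choice(cases["age"].to_numpy(), size=len(controls))
    data = pd.concat([cases, controls], ignore_index=True)
    cols = ["status", "age", "true_rr"] + [
        c for c in data.columns if c not in ("status", "age", "true_rr")
    ]
    return SyntheticCohort(data=data[cols], config=config)


def generate_hazard_table(
    age_start: int = 40,
    age_end: int = 85,
    band_width: int = 5,
    incidence_at_40: float = 120.0,
    incidence_slope: float = 9.0,
    mortality_at_40: float = 180.0,
    mortality_log_slope: float = 0.085,
    jitter_sd: float = 0.0,
    monotone: bool = True,
    zero_mortality: bool = False,
    seed: int | None = None,
) -> HazardSchedule:
    """A smooth Western-female-like hazard table on 5-year bands.

    Composite incidence rises roughly linearly from ~120 to ~500 per
    100,000 person-years between ages 40 and 85; competing mortality
    rises exponentially.  ``jitter_sd`` adds seeded log-normal noise
    (deterministic under ``seed``); ``monotone`` enforces strictly
    increasing incidence across bands.
    """
    if (age_end - age_start) % band_width:
        raise ValueError("band width must divide the age span")
    breaks = np.arange(age_start, age_end + 1, band_width, dtype=float)
    mids = (breaks[:-1] + breaks[1:]) / 2
    inc = incidence_at_40 + incidence_slope * (mids - 42.5)
    mort = mortality_at_40 * np.exp(mortality_log_slope * (mids - 42.5))
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        inc = inc * np.exp(rng.normal(0, jitter_sd, size=inc.shape))
        mort = mort * np.exp(rng.normal(0, jitter_sd, size=mort.shape))
    if monotone:
        inc = np.maximum.accumulate(inc + np.arange(len(inc)) * 1e-9)
    if zero_mortality:
        mort = np.zeros_like(mort)
    return HazardSchedule(age_breaks=breaks, h1_star=inc / 1e5, h2=mort / 1e5)


def table3_fixture() -> ReclassificationTable:
    """The published 3×3 five-year-risk reclassification counts for the
    clinical (Swe-Gail) model versus the full model, at cutoffs 2.41%
    and 4.11% (first/third quartiles of clinical-model risk)."""
    return ReclassificationTable(
        case_counts=np.array([[155, 53, 17], [161, 225, 103], [14, 97, 192]]),
        control_counts=np.array([[170, 20, 10], [236, 182, 62], [20, 65, 91]]),
        cutoffs=RiskCutoffs(0.0241, 0.0411),
    )
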