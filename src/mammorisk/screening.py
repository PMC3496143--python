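"""Analytical evaluation of risk-stratified screening strategies.

A screening-age population (ages 40-75) is simulated by resampling
risk-factor profiles from study controls within 5-year age bands
(women under 50 borrow the age-50 band's distribution, the youngest
band observed in a postmenopausal study).  Each woman's 10-year
absolute risk is computed under one or more risk models; a screening
strategy is a model plus a risk cutoff, and strategies are compared at
equal resources (equal fraction of the population eligible) on the
share of expected cases arising in the eligible group.  Expected-case
capture is analytic — each woman contributes her absolute risk as her
expected case count — so the comparison is free of label-sampling
noise; a Bernoulli label-sampling mode exists for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import effects as eff
from .absolute_risk import absolute_risk_vector
from .hazards import HazardSchedule

__all__ = [
    "ScreeningCohort",
    "ScreeningResult",
    "build_cohort",
    "attach_risks",
    "evaluate_strategy",
    "age_only_strategy",
    "match_resources",
    "stratified_report",
    "variance_sensitivity",
    "sampled_capture",
]

_PROFILE_COLS = ("menarche_level", "first_birth_level", "bbd", "fh", "pd_percent", "bmi")


@dataclass
class ScreeningCohort:
    """Simulated screening-age population with per-model risks."""

    data: pd.DataFrame
    age_weights: np.ndarray
    rel_risks: dict[str, np.ndarray] = field(default_factory=dict)
    risks: dict[str, np.ndarray] = field(default_factory=dict)
    horizon: float = 10.0

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ages(self) -> np.ndarray:
        return self.data["age"].to_numpy(float)


@dataclass
class ScreeningResult:
    """Eligibility and expected-case capture of one strategy."""

    strategy: str
    cutoff: float | None
    percent_eligible: float
    percent_cases_captured: float
    mean_risk_all: float
    sd_risk_all: float
    mean_risk_eligible: float
    sd_risk_eligible: float
    by_band: pd.DataFrame | None = field(default=None, repr=False)


def _pool_bands(pool_ages: np.ndarray) -> np.ndarray:
    return (np.clip(pool_ages, 50, None) // 5 * 5).astype(int)


def build_cohort(
    n: int,
    age_distribution,
    control_pool: pd.DataFrame,
    seed: int | None = None,
    joint_genotypes: bool = True,
    snp_effects=None,
    ages=None,
) -> ScreeningCohort:
    """Simulate a screening-age population by age-conditional resampling.

    ``age_distribution`` gives weights over integer ages 40-75 (array of
    length 36, or None for uniform).  Each woman's risk-factor profile
    is drawn with replacement from control-pool members of her 5-year
    age band; women under 50 draw from the 50-54 band and women beyond
    the pool's oldest band draw from that oldest band.  With
    ``joint_genotypes`` the genotype columns travel with the non-genetic
    factors (preserving any dependence in the pool); otherwise
    genotypes are redrawn independently under Hardy-Weinberg from
    ``snp_effects``.
    """
    rng = np.random.default_rng(seed)
    if ages is None:
        ages = np.arange(40, 76)
    ages = np.asarray(ages)
    if age_distribution is None:
        w = np.ones(len(ages))
    else:
        w = np.asarray(age_distribution, dtype=float)
        if len(w) != len(ages):
            raise ValueError("age_distribution length must match the age grid")
    w = w / w.sum()
    drawn_ages = rng.choice(ages, size=n, p=w)

    pool = control_pool.reset_index(drop=True)
    if "age" not in pool:
        raise ValueError("control pool must have an 'age' column")
    pool_band = _pool_bands(pool["age"].to_numpy(float))
    available = np.unique(pool_band)
    if 50 not in available:
        raise ValueError("control pool has no women in the 50-54 age band")

    # under-50s borrow the 50-54 band; ages beyond the study's oldest
    # band (70-74) borrow that band
    lookup_band = _pool_bands(drawn_ages.astype(float))
    lookup_band = np.minimum(lookup_band, 70)
    idx = np.empty(n, dtype=int)
    for band in np.unique(lookup_band):
        members = np.flatnonzero(pool_band == band)
        if len(members) == 0:
            raise ValueError(f"control pool has no women in the {band}-{band + 4} band")
        sel = lookup_band == band
        idx[sel] = rng.choice(members, size=int(sel.sum()))

    keep = [c for c in pool.columns if c not in ("status", "age", "true_rr")]
    data = pool.loc[idx, keep].reset_index(drop=True)
    data.insert(0, "age", drawn_ages)

    if not joint_genotypes:
        if snp_effects is None:
            raise ValueError("snp_effects required when joint_genotypes=False")
        for s in snp_effects:
            data[s.rsid] = rng.binomial(2, s.allele_freq, size=n)
    return ScreeningCohort(data=data, age_weights=w)


def attach_risks(
    cohort: ScreeningCohort,
    table: eff.EffectSizeTable,
    schedule: HazardSchedule,
    models: dict | list | tuple,
    ref: eff.ReferenceDistribution | None = None,
    delta: float = 10.0,
) -> ScreeningCohort:
    """Compute per-woman relative and 10-year absolute risks per model.

    ``models`` maps a strategy name to a model spec (or is a list of
    specs used as names).  The name ``"age_only"`` denotes the baseline
    model with relative risk 1 for every woman.
    """
    if isinstance(models, (list, tuple)):
        models = {m: m for m in models}
    cohort.horizon = delta
    ages = cohort.ages
    for name, spec in models.items():
        if name == "age_only" or spec == "age_only":
            rr = np.ones(cohort.n)
        else:
            rr = eff.score_cohort(cohort.data, table, spec, ref)
        cohort.rel_risks[name] = rr
        cohort.risks[name] = absolute_risk_vector(ages, rr, schedule, delta)
    return cohort


def _capture(case_weight: np.ndarray, eligible: np.ndarray) -> float:
    total = case_weight.sum()
    return float(case_weight[eligible].sum() / total) if total > 0 else 0.0


def evaluate_strategy(
    cohort: ScreeningCohort,
    model: str,
    cutoff: float,
    case_model: str | None = None,
) -> ScreeningResult:
    """Eligibility and expected-case capture at a risk cutoff.

    Eligible women are those with model risk strictly greater than the
    cutoff.  Expected-case weights come from ``case_model`` (default:
    the same model), so strategies can be compared against a common
    reference risk distribution.
    """
    if not 0 <= cutoff < 1:
        raise ValueError("cutoff must lie in [0, 1)")
    risks = cohort.risks[model]
    case_w = cohort.risks[case_model or model]
    eligible = risks > cutoff
    sel = risks[eligible]
    return ScreeningResult(
        strategy=model,
        cutoff=cutoff,
        percent_eligible=100.0 * eligible.mean(),
        percent_cases_captured=100.0 * _capture(case_w, eligible),
        mean_risk_all=float(risks.mean()),
        sd_risk_all=float(risks.std(ddof=1)),
        mean_risk_eligible=float(sel.mean()) if len(sel) else float("nan"),
        sd_risk_eligible=float(sel.std(ddof=1)) if len(sel) > 1 else float("nan"),
        by_band=stratified_report(cohort, model, cutoff, case_model=case_model),
    )


def age_only_strategy(
    cohort: ScreeningCohort,
    eligible_fraction: float,
    case_model: str | None = None,
    baseline_model: str = "age_only",
) -> ScreeningResult:
    """The most efficient age-only programme at a given resource level.

    Whole ages are admitted in descending order of age-specific
    expected risk until the eligible fraction is met; the marginal age
    year is included fractionally so the target is hit exactly.
    """
    if not 0 < eligible_fraction <= 1:
        raise ValueError("eligible_fraction must lie in (0, 1]")
    base = cohort.risks[baseline_model]
    case_w = cohort.risks[case_model] if case_model else base
    ages = cohort.ages
    n = cohort.n
    per_age = (
        pd.DataFrame({"age": ages, "risk": base, "w": case_w})
        .groupby("age")
        .agg(n=("risk", "size"), mean_risk=("risk", "mean"), cases=("w", "sum"))
        .sort_values("mean_risk", ascending=False)
    )
    target = eligible_fraction * n
    total_cases = case_w.sum()
    got, captured = 0.0, 0.0
    included: dict[float, float] = {}
    for age_val, row in per_age.iterrows():
        if got >= target:
            break
        frac = min(1.0, (target - got) / row["n"])
        included[age_val] = frac
        got += frac * row["n"]
        captured += frac * row["cases"]
    by_band = _age_only_band_table(cohort, included, case_w)
    eligible_pct = 100.0 * got / n
    return ScreeningResult(
        strategy="age_only",
        cutoff=None,
        percent_eligible=eligible_pct,
        percent_cases_captured=100.0 * captured / total_cases,
        mean_risk_all=float(base.mean()),
        sd_risk_all=float(base.std(ddof=1)),
        mean_risk_eligible=float("nan"),
        sd_risk_eligible=float("nan"),
        by_band=by_band,
    )


def _age_only_band_table(cohort, included: dict, case_w: np.ndarray) -> pd.DataFrame:
    ages = cohort.ages
    frac = np.array([included.get(a, 0.0) for a in ages])
    rows = []
    for lo in range(40, 80, 5):
        m = (ages >= lo) & (ages < lo + 5)
        if not m.any():
            continue
        rows.append(
            {
                "age_band": f"{lo}-{lo + 4}",
                "n": int(m.sum()),
                "percent_eligible": 100.0 * frac[m].mean(),
                "percent_cases_captured": 100.0
                * (case_w[m] * frac[m]).sum()
                / max(case_w[m].sum(), 1e-300),
            }
        )
    return pd.DataFrame(rows)


def match_resources(
    cohort: ScreeningCohort, model: str, target_eligible_fraction: float
) -> float:
    """Risk cutoff whose strict-inequality eligibility equals the target
    fraction, to within one cohort member."""
    if not 0 < target_eligible_fraction <= 1:
        raise ValueError("target fraction must lie in (0, 1]")
    risks = np.sort(cohort.risks[model])
    n = len(risks)
    m = int(round(target_eligible_fraction * n))
    if m >= n:
        return float(risks[0] * 0.5)
    # achievable eligible counts under strict inequality are limited to
    # the gaps between tied blocks; pick the candidate closest to target
    vals = np.unique(risks)
    counts_gt = n - np.searchsorted(risks, vals, side="right")
    best = int(np.argmin(np.abs(counts_gt - m)))
    return float(vals[best])


def stratified_report(
    cohort: ScreeningCohort,
    model: str,
    cutoff: float,
    case_model: str | None = None,
    band_width: int = 5,
) -> pd.DataFrame:
    """Eligibility and capture recomputed within 5-year age bands."""
    risks = cohort.risks[model]
    case_w = cohort.risks[case_model or model]
    ages = cohort.ages
    eligible = risks > cutoff
    rows = []
    start = int(ages.min() // band_width * band_width)
    for lo in range(start, int(ages.max()) + 1, band_width):
        m = (ages >= lo) & (ages < lo + band_width)
        if not m.any():
            continue
        rows.append(
            {
                "age_band": f"{lo}-{lo + band_width - 1}",
                "n": int(m.sum()),
                "percent_eligible": 100.0 * eligible[m].mean(),
                "percent_cases_captured": 100.0 * _capture(case_w[m], eligible[m]),
                "mean_risk": float(risks[m].mean()),
            }
        )
    return pd.DataFrame(rows)


def sampled_capture(
    cohort: ScreeningCohort,
    model: str,
    cutoff: float,
    rng: np.random.Generator,
    case_model: str | None = None,
) -> float:
    """Capture with actual case labels drawn Bernoulli(risk) — the
    label-sampling validation counterpart of the analytic weighting."""
    risks = cohort.risks[model]
    p = cohort.risks[case_model or model]
    labels = rng.random(cohort.n) < p
    eligible = risks > cutoff
    n_cases = labels.sum()
    return float((labels & eligible).sum() / n_cases) if n_cases else float("nan")


def variance_sensitivity(
    cohort: ScreeningCohort,
    inflation_factor: float,
    models: list[str],
    schedule: HazardSchedule,
    cutoffs: dict[str, float],
    case_model: str | None = None,
    age_threshold: float = 50.0,
) -> pd.DataFrame:
    """Sensitivity of screening results to under-50 risk-score spread.

    For women below ``age_threshold`` the log relative risks of each
    model are rescaled about their mean so that their variance grows by
    ``inflation_factor`` (1.10 = a 10% variance increase); absolute
    risks are recomputed and each strategy re-evaluated at its cutoff.
    """
    if inflation_factor <= 0:
        raise ValueError("inflation factor must be positive")
    young = cohort.ages < age_threshold
    scale = np.sqrt(inflation_factor)
    rows = []
    inflated = ScreeningCohort(
        data=cohort.data, age_weights=cohort.age_weights, horizon=cohort.horizon
    )
    for name in set(models) | ({case_model} if case_model else set()):
        lr = np.log(cohort.rel_risks[name])
        lr_new = lr.copy()
        if young.any():
            mu = lr[young].mean()
            lr_new[young] = mu + scale * (lr[young] - mu)
        inflated.rel_risks[name] = np.exp(lr_new)
        inflated.risks[name] = absolute_risk_vector(
            cohort.ages, inflated.rel_risks[name], schedule, cohort.horizon
        )
    for name in models:
        before = evaluate_strategy(cohort, name, cutoffs[name], case_model=case_model)
        after = evaluate_strategy(inflated, name, cutoffs[name], case_model=case_model)
        rows.append(
            {
                "model": name,
                "cutoff": cutoffs[name],
                "eligible_before": before.percent_eligible,
                "eligible_after": after.percent_eligible,
                "captured_before": before.percent_cases_captured,
                "captured_after": after.percent_cases_captured,
                "delta_eligible": after.percent_eligible - before.percent_eligible,
                "delta_captured": after.percent_cases_captured
                - before.percent_cases_captured,
            }
        )
    return pd.DataFrame(rows)
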