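"""Relative-risk model assembly from published per-factor effect sizes.

The multiplicative relative-risk model combines four components:

* ``clinical`` — the Gail-type factors: age at menarche and age at first
  live birth (log-linear per ordinal level), benign breast disease and
  first-degree family history (binary).
* ``pd_bmi``  — percent mammographic density (six categories) and body
  mass index (five categories), jointly, since the two are negatively
  correlated and their published effects are mutually adjusted.
* ``snp18`` / ``snp7`` — a multiplicative polygenic profile over 18
  (or the earlier subset of 7) susceptibility loci, per-allele odds
  ratios coded so the low-risk homozygote is the baseline.

Each component is normalised so that its population-average relative
risk equals 1 under a configured reference distribution; the combined
relative risk of an average woman is then 1, which makes the Bruzzi
attributable-risk conversion of composite incidence to a baseline
hazard internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SnpEffect",
    "EffectSizeTable",
    "RiskProfile",
    "PooledEstimate",
    "ProxyEffects",
    "ReferenceDistribution",
    "EstimationError",
    "load_reference_effects",
    "pool_odds_ratios",
    "recode_to_risk_allele",
    "snp_relative_risk",
    "snp_mean_relative_risk",
    "categorize_pd",
    "categorize_bmi",
    "combined_relative_risk",
    "score_cohort",
    "component_mean_rr",
    "estimate_proxy_effects",
    "SNP7_RSIDS",
]

#: The seven loci from the first generation of breast-cancer GWAS hits
#: (FGFR2, TOX3/TNRC9, MAP3K1, 8q24, LSP1, CASP8, 2q35).
SNP7_RSIDS = (
    "rs2981582",
    "rs3803662",
    "rs889312",
    "rs13281615",
    "rs3817198",
    "rs1045485",
    "rs13387042",
)

_MODEL_ALIASES = {
    "gail": ("clinical",),
    "clinical": ("clinical",),
    "pd_bmi": ("pd_bmi",),
    "snp7": ("snp7",),
    "snp18": ("snp18",),
    "gail+pd": ("clinical", "pd_bmi"),
    "gail+snp7": ("clinical", "snp7"),
    "gail+snp18": ("clinical", "snp18"),
    "gail+pd+snp7": ("clinical", "pd_bmi", "snp7"),
    "full": ("clinical", "pd_bmi", "snp18"),
}

_VALID_COMPONENTS = frozenset({"clinical", "pd_bmi", "snp7", "snp18"})


class EstimationError(RuntimeError):
    """A maximum-likelihood fit failed (e.g. complete separation)."""


def _resolve_components(model_spec) -> tuple[str, ...]:
    """Turn a model name or an iterable of component names into components."""
    if isinstance(model_spec, str):
        key = model_spec.lower()
        if key in _MODEL_ALIASES:
            return _MODEL_ALIASES[key]
        model_spec = [model_spec]
    comps = tuple(dict.fromkeys(str(c).lower() for c in model_spec))
    bad = [c for c in comps if c not in _VALID_COMPONENTS]
    if bad:
        raise ValueError(
            f"unknown model components {bad!r}; valid: {sorted(_VALID_COMPONENTS)}"
        )
    if "snp7" in comps and "snp18" in comps:
        raise ValueError("model cannot contain both snp7 and snp18")
    return comps


@dataclass(frozen=True)
class SnpEffect:
    """Per-allele odds ratio for one locus, risk-allele coded (OR >= 1)."""

    rsid: str
    odds_ratio: float
    allele_freq: float

    def __post_init__(self):
        if not self.odds_ratio > 0:
            raise ValueError(f"{self.rsid}: odds ratio must be positive")
        if not 0 < self.allele_freq < 1:
            raise ValueError(f"{self.rsid}: allele frequency must be in (0, 1)")


@dataclass
class EffectSizeTable:
    """Published per-factor relative risks defining the risk model.

    Parameters
    ----------
    snp_effects
        18 loci, each a :class:`SnpEffect`.
    pd_effects
        Six ``(lower_bound, relative_risk)`` pairs for percent density,
        reference category risk 1.00.  The first category is "exactly
        0 %"; subsequent bounds are lower-inclusive.
    bmi_effects
        Five ``(lower_bound, relative_risk)`` pairs for BMI (kg/m²),
        lower-inclusive, reference risk 1.00.
    clinical_effects
        Mapping with keys ``menarche``, ``first_birth`` (per-level
        trend odds ratios over 3 ordinal levels) and ``bbd``, ``fh``
        (binary odds ratios).
    """

    snp_effects: list[SnpEffect]
    pd_effects: list[tuple[float, float]]
    bmi_effects: list[tuple[float, float]]
    clinical_effects: dict[str, float]

    def __post_init__(self):
        if len(self.snp_effects) != 18:
            raise ValueError(f"expected 18 SNP effects, got {len(self.snp_effects)}")
        rsids = [s.rsid for s in self.snp_effects]
        if len(set(rsids)) != 18:
            raise ValueError("SNP locus ids must be unique")
        if len(self.pd_effects) != 6:
            raise ValueError("pd_effects must have exactly 6 categories")
        if len(self.bmi_effects) != 5:
            raise ValueError("bmi_effects must have exactly 5 categories")
        for name, cats in (("pd", self.pd_effects), ("bmi", self.bmi_effects)):
            if cats[0][1] != 1.0:
                raise ValueError(f"{name} reference category must have risk 1.00")
            if any(rr <= 0 for _, rr in cats):
                raise ValueError(f"{name} relative risks must be positive")
        for key in ("menarche", "first_birth", "bbd", "fh"):
            if key not in self.clinical_effects:
                raise ValueError(f"clinical_effects missing {key!r}")
            if self.clinical_effects[key] <= 0:
                raise ValueError(f"clinical effect {key!r} must be positive")

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snp_effects]

    def snp_subset(self, which: str) -> list[SnpEffect]:
        if which == "snp18":
            return list(self.snp_effects)
        if which == "snp7":
            return [s for s in self.snp_effects if s.rsid in SNP7_RSIDS]
        raise ValueError(f"unknown SNP subset {which!r}")

    @classmethod
    def from_tsv(cls, path) -> "EffectSizeTable":
        df = pd.read_csv(path, sep="\t", dtype={"level_label": str})
        snp = df[df.component == "snp"]
        pdrows = df[df.component == "pd"]
        bmirows = df[df.component == "bmi"]
        clin = df[df.component == "clinical"]
        return cls(
            snp_effects=[
                SnpEffect(r.level_label, float(r.relative_risk), float(r.allele_freq))
                for r in snp.itertuples()
            ],
            pd_effects=[
                (float(r.lower_bound), float(r.relative_risk))
                for r in pdrows.itertuples()
            ],
            bmi_effects=[
                (float(r.lower_bound), float(r.relative_risk))
                for r in bmirows.itertuples()
            ],
            clinical_effects={
                r.level_label: float(r.relative_risk) for r in clin.itertuples()
            },
        )

    def to_tsv(self, path) -> None:
        rows = []
        for s in self.snp_effects:
            rows.append(("snp", s.rsid, "", s.odds_ratio, s.allele_freq))
        for low, rr in self.pd_effects:
            rows.append(("pd", f"{low:g}", low, rr, ""))
        for low, rr in self.bmi_effects:
            rows.append(("bmi", f"{low:g}", low, rr, ""))
        for key, rr in self.clinical_effects.items():
            rows.append(("clinical", key, "", rr, ""))
        pd.DataFrame(
            rows,
            columns=["component", "level_label", "lower_bound", "relative_risk", "allele_freq"],
        ).to_csv(path, sep="\t", index=False)


def load_reference_effects() -> EffectSizeTable:
    """Load the packaged published effect-size table (18 loci, PD, BMI, clinical)."""
    with resources.as_file(
        resources.files("mammorisk.data").joinpath("effect_sizes_table1.tsv")
    ) as p:
        return EffectSizeTable.from_tsv(p)


@dataclass
class RiskProfile:
    """One woman's risk-factor profile.

    ``dosages`` maps rsid to a risk-allele count in {0, 1, 2}; missing
    loci may be omitted or set to None.  ``pd_percent`` and ``bmi`` may
    be None (missing).
    """

    age: float
    menarche_level: int = 0
    first_birth_level: int = 0
    bbd: int = 0
    fh: int = 0
    pd_percent: float | None = None
    bmi: float | None = None
    dosages: Mapping[str, int | None] | None = None

    def __post_init__(self):
        if self.pd_percent is not None and not 0 <= self.pd_percent <= 100:
            raise ValueError("pd_percent must be in [0, 100]")
        if self.dosages is not None:
            for rsid, d in self.dosages.items():
                if d is not None and d not in (0, 1, 2):
                    raise ValueError(f"dosage at {rsid} must be in {{0,1,2}}, got {d}")


@dataclass(frozen=True)
class PooledEstimate:
    """Fixed-effect inverse-variance pooled odds ratio with 95% CI."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    n_sources: int

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must contain the point estimate")


_Z975 = stats.norm.ppf(0.975)


def pool_odds_ratios(
    estimates: Sequence[tuple[float, tuple[float, float]]],
) -> PooledEstimate:
    """Fixed-effect inverse-variance pooling of odds ratios on the log scale.

    Each element is ``(odds_ratio, (ci_low, ci_high))`` with a 95% CI
    assumed symmetric on the log scale; the per-study variance is
    recovered from the CI width.
    """
    if len(estimates) == 0:
        raise ValueError("at least one estimate is required")
    log_ors, weights = [], []
    for i, (or_, (lo, hi)) in enumerate(estimates):
        if not (0 < lo <= or_ <= hi):
            raise ValueError(f"estimate {i}: CI ({lo}, {hi}) must contain OR {or_}")
        if hi == lo:
            raise ValueError(
                f"estimate {i} (OR={or_}) has a degenerate zero-width CI"
            )
        se = (np.log(hi) - np.log(lo)) / (2 * _Z975)
        log_ors.append(np.log(or_))
        weights.append(1.0 / se**2)
    log_ors = np.asarray(log_ors)
    weights = np.asarray(weights)
    pooled = float(np.sum(weights * log_ors) / np.sum(weights))
    se_pooled = float(1.0 / np.sqrt(np.sum(weights)))
    return PooledEstimate(
        odds_ratio=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - _Z975 * se_pooled)),
        ci_high=float(np.exp(pooled + _Z975 * se_pooled)),
        n_sources=len(estimates),
    )


def recode_to_risk_allele(odds_ratio: float, dosage: int) -> tuple[float, int]:
    """Recode so the low-risk homozygote is baseline: OR < 1 flips allele."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if dosage not in (0, 1, 2):
        raise ValueError("dosage must be in {0, 1, 2}")
    if odds_ratio >= 1:
        return odds_ratio, dosage
    return 1.0 / odds_ratio, 2 - dosage


def snp_mean_relative_risk(snp_effects: Iterable[SnpEffect]) -> float:
    """Population-mean multiplicative relative risk under Hardy-Weinberg.

    For each locus with risk-allele frequency ``p`` and per-allele odds
    ratio ``OR`` the genotype mean is ``p² OR² + 2p(1−p) OR + (1−p)²``;
    loci are independent so the means multiply.
    """
    mean = 1.0
    for s in snp_effects:
        p = s.allele_freq
        mean *= p**2 * s.odds_ratio**2 + 2 * p * (1 - p) * s.odds_ratio + (1 - p) ** 2
    return mean


def snp_relative_risk(
    dosages: Mapping[str, int | None],
    snp_effects: Sequence[SnpEffect],
    normalize: bool = True,
) -> float:
    """Multiplicative SNP relative risk, product over loci of OR^dosage.

    Missing dosages contribute a factor of 1 (neutral on the normalised
    scale).  With ``normalize`` the product is divided by the
    Hardy-Weinberg population mean so the population-average risk is 1.
    """
    rr = 1.0
    for s in snp_effects:
        d = dosages.get(s.rsid) if dosages is not None else None
        if d is None:
            continue
        if d not in (0, 1, 2):
            raise ValueError(f"dosage at {s.rsid} must be in {{0,1,2}}, got {d}")
        rr *= s.odds_ratio**d
    if normalize:
        rr /= snp_mean_relative_risk(snp_effects)
    return rr


def _categorize(value: float, cats: Sequence[tuple[float, float]], zero_cat: bool) -> float:
    bounds = [low for low, _ in cats]
    if zero_cat:
        # first category is "exactly zero"; second spans (0, bounds[2])
        if value == 0:
            return cats[0][1]
        idx = int(np.searchsorted(bounds[2:], value, side="right"))
        return cats[1 + idx][1]
    idx = int(np.searchsorted(bounds[1:], value, side="right"))
    return cats[idx][1]


def categorize_pd(pd_percent: float, pd_effects: Sequence[tuple[float, float]] | None = None) -> float:
    """Relative risk of the percent-density category containing ``pd_percent``.

    Category "0" means exactly 0%; the remaining bounds are
    lower-inclusive half-open intervals.
    """
    if pd_effects is None:
        pd_effects = load_reference_effects().pd_effects
    if not 0 <= pd_percent <= 100:
        raise ValueError(f"pd_percent {pd_percent} outside [0, 100]")
    return _categorize(pd_percent, pd_effects, zero_cat=True)


def categorize_bmi(bmi: float, bmi_effects: Sequence[tuple[float, float]] | None = None) -> float:
    """Relative risk of the BMI category containing ``bmi`` (lower-inclusive)."""
    if bmi_effects is None:
        bmi_effects = load_reference_effects().bmi_effects
    if not bmi > 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    return _categorize(bmi, bmi_effects, zero_cat=False)


# ---------------------------------------------------------------------------
# Reference population for per-component normalisation

#: Default marginal category prevalences; these are the synthetic
#: generator's study conditions and double as the normalising reference.
DEFAULT_PD_PROBS = (0.08, 0.12, 0.25, 0.30, 0.18, 0.07)
DEFAULT_BMI_PROBS = (0.20, 0.20, 0.20, 0.20, 0.20)
DEFAULT_MENARCHE_PROBS = (0.30, 0.45, 0.25)
DEFAULT_FIRST_BIRTH_PROBS = (0.35, 0.40, 0.25)
DEFAULT_BBD_PREV = 0.10
DEFAULT_FH_PREV = 0.12
DEFAULT_PD_BMI_RHO = -0.40


def _gaussian_copula_joint(
    row_probs: Sequence[float], col_probs: Sequence[float], rho: float
) -> np.ndarray:
    """Cell probabilities of two categorical margins coupled by a Gaussian copula."""
    from scipy.stats import multivariate_normal, norm

    rb = norm.ppf(np.concatenate([[0.0], np.cumsum(row_probs)]).clip(0, 1))
    cb = norm.ppf(np.concatenate([[0.0], np.cumsum(col_probs)]).clip(0, 1))
    mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

    def F(x, y):
        if x == -np.inf or y == -np.inf:
            return 0.0
        return float(mvn.cdf([min(x, 8.0), min(y, 8.0)]))

    out = np.empty((len(row_probs), len(col_probs)))
    for i in range(len(row_probs)):
        for j in range(len(col_probs)):
            out[i, j] = (
                F(rb[i + 1], cb[j + 1])
                - F(rb[i], cb[j + 1])
                - F(rb[i + 1], cb[j])
                + F(rb[i], cb[j])
            )
    out = np.clip(out, 0, None)
    return out / out.sum()


@dataclass
class ReferenceDistribution:
    """Population category distribution used to normalise each component.

    ``pd_bmi_joint`` is a 6×5 matrix of joint PD×BMI category
    probabilities; by default it is the Gaussian-copula coupling of the
    marginals with the configured negative correlation.
    """

    pd_probs: tuple = DEFAULT_PD_PROBS
    bmi_probs: tuple = DEFAULT_BMI_PROBS
    menarche_probs: tuple = DEFAULT_MENARCHE_PROBS
    first_birth_probs: tuple = DEFAULT_FIRST_BIRTH_PROBS
    bbd_prev: float = DEFAULT_BBD_PREV
    fh_prev: float = DEFAULT_FH_PREV
    pd_bmi_rho: float = DEFAULT_PD_BMI_RHO
    pd_bmi_joint: np.ndarray | None = None

    def __post_init__(self):
        for name, p in (
            ("pd_probs", self.pd_probs),
            ("bmi_probs", self.bmi_probs),
            ("menarche_probs", self.menarche_probs),
            ("first_birth_probs", self.first_birth_probs),
        ):
            arr = np.asarray(p, dtype=float)
            if np.any(arr < 0) or abs(arr.sum() - 1) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if not -1 < self.pd_bmi_rho <= 0:
            raise ValueError("pd_bmi_rho must be in (-1, 0]")
        if self.pd_bmi_joint is None:
            if self.pd_bmi_rho == 0:
                self.pd_bmi_joint = np.outer(self.pd_probs, self.bmi_probs)
            else:
                self.pd_bmi_joint = _gaussian_copula_joint(
                    self.pd_probs, self.bmi_probs, self.pd_bmi_rho
                )

    @classmethod
    def default(cls) -> "ReferenceDistribution":
        return cls()


def component_mean_rr(
    table: EffectSizeTable, component: str, ref: ReferenceDistribution
) -> float:
    """Population-mean relative risk of one model component under ``ref``."""
    component = component.lower()
    if component == "clinical":
        m = sum(
            p * table.clinical_effects["menarche"] ** k
            for k, p in enumerate(ref.menarche_probs)
        )
        f = sum(
            p * table.clinical_effects["first_birth"] ** k
            for k, p in enumerate(ref.first_birth_probs)
        )
        b = 1 - ref.bbd_prev + ref.bbd_prev * table.clinical_effects["bbd"]
        h = 1 - ref.fh_prev + ref.fh_prev * table.clinical_effects["fh"]
        return float(m * f * b * h)
    if component == "pd_bmi":
        pd_rr = np.array([rr for _, rr in table.pd_effects])
        bmi_rr = np.array([rr for _, rr in table.bmi_effects])
        return float(np.sum(ref.pd_bmi_joint * np.outer(pd_rr, bmi_rr)))
    if component in ("snp7", "snp18"):
        return snp_mean_relative_risk(table.snp_subset(component))
    raise ValueError(f"unknown component {component!r}")


def _require(profile: RiskProfile, fieldname: str, model: str):
    v = getattr(profile, fieldname)
    if v is None:
        raise ValueError(f"profile field {fieldname!r} is required for model {model!r}")
    return v


def combined_relative_risk(
    profile: RiskProfile,
    table: EffectSizeTable,
    model_spec,
    ref: ReferenceDistribution | None = None,
) -> float:
    """Multiplicative relative risk for one profile under a model.

    ``model_spec`` is either a model alias (``"gail"``, ``"full"``,
    ``"gail+pd"``, ``"gail+snp18"``, ...) or an iterable of component
    names from {clinical, pd_bmi, snp7, snp18}.  Each component is
    normalised to population mean 1 under ``ref``.
    """
    if ref is None:
        ref = ReferenceDistribution.default()
    comps = _resolve_components(model_spec)
    rr = 1.0
    for comp in comps:
        if comp == "clinical":
            raw = (
                table.clinical_effects["menarche"] ** profile.menarche_level
                * table.clinical_effects["first_birth"] ** profile.first_birth_level
                * table.clinical_effects["bbd"] ** profile.bbd
                * table.clinical_effects["fh"] ** profile.fh
            )
        elif comp == "pd_bmi":
            pd_percent = _require(profile, "pd_percent", comp)
            bmi = _require(profile, "bmi", comp)
            raw = categorize_pd(pd_percent, table.pd_effects) * categorize_bmi(
                bmi, table.bmi_effects
            )
        else:
            dosages = profile.dosages if profile.dosages is not None else {}
            raw = snp_relative_risk(dosages, table.snp_subset(comp), normalize=False)
        rr *= raw / component_mean_rr(table, comp, ref)
    return rr


def score_cohort(
    df: pd.DataFrame,
    table: EffectSizeTable,
    model_spec,
    ref: ReferenceDistribution | None = None,
) -> np.ndarray:
    """Vectorised :func:`combined_relative_risk` over a cohort DataFrame.

    Expected columns: ``menarche_level``, ``first_birth_level``,
    ``bbd``, ``fh`` for the clinical component; ``pd_percent``, ``bmi``
    for the density component; one dosage column per rsid for the SNP
    components (NaN = missing, contributing factor 1).
    """
    if ref is None:
        ref = ReferenceDistribution.default()
    comps = _resolve_components(model_spec)
    n = len(df)
    rr = np.ones(n)
    for comp in comps:
        if comp == "clinical":
            for col, key in (
                ("menarche_level", "menarche"),
                ("first_birth_level", "first_birth"),
                ("bbd", "bbd"),
                ("fh", "fh"),
            ):
                if col not in df:
                    raise ValueError(f"column {col!r} required for model {comp!r}")
                rr = rr * table.clinical_effects[key] ** df[col].to_numpy(float)
        elif comp == "pd_bmi":
            for col in ("pd_percent", "bmi"):
                if col not in df or df[col].isna().any():
                    raise ValueError(f"column {col!r} required for model {comp!r}")
            pdv = df["pd_percent"].to_numpy(float)
            if np.any((pdv < 0) | (pdv > 100)):
                raise ValueError("pd_percent outside [0, 100]")
            pd_bounds = np.array([low for low, _ in table.pd_effects[2:]])
            pd_rrs = np.array([r for _, r in table.pd_effects])
            idx = np.where(pdv == 0, 0, 1 + np.searchsorted(pd_bounds, pdv, side="right"))
            rr = rr * pd_rrs[idx]
            bmiv = df["bmi"].to_numpy(float)
            if np.any(bmiv <= 0):
                raise ValueError("bmi must be positive")
            bmi_bounds = np.array([low for low, _ in table.bmi_effects[1:]])
            bmi_rrs = np.array([r for _, r in table.bmi_effects])
            rr = rr * bmi_rrs[np.searchsorted(bmi_bounds, bmiv, side="right")]
        else:
            for s in table.snp_subset(comp):
                if s.rsid not in df:
                    continue
                d = df[s.rsid].to_numpy(float)
                ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
                if not ok.all():
                    raise ValueError(f"dosages at {s.rsid} outside {{0,1,2}}")
                rr = rr * s.odds_ratio ** np.nan_to_num(d)
        rr = rr / component_mean_rr(table, comp, ref)
    return rr


@dataclass(frozen=True)
class ProxyEffects:
    """Internally estimated odds ratios for the two proxy Gail variables."""

    or_bbd: float
    or_fh: float
    se_log_bbd: float
    se_log_fh: float


def estimate_proxy_effects(
    data: pd.DataFrame, table: EffectSizeTable | None = None
) -> ProxyEffects:
    """Estimate benign-breast-disease and family-history odds ratios.

    Fits a logistic model of case status on the two binary proxies with
    the combined age-at-menarche + age-at-first-birth log relative risk
    (published per-level effects) entered as a fixed offset, exactly as
    the proxy variables' effects were obtained in the source analysis.

    ``data`` needs columns ``status``, ``bbd``, ``fh``,
    ``menarche_level`` and ``first_birth_level``.
    """
    if table is None:
        table = load_reference_effects()
    for col in ("status", "bbd", "fh", "menarche_level", "first_birth_level"):
        if col not in data:
            raise ValueError(f"column {col!r} required")
    offset = data["menarche_level"].to_numpy(float) * np.log(
        table.clinical_effects["menarche"]
    ) + data["first_birth_level"].to_numpy(float) * np.log(
        table.clinical_effects["first_birth"]
    )
    exog = sm.add_constant(data[["bbd", "fh"]].to_numpy(float))
    model = sm.GLM(
        data["status"].to_numpy(float), exog, family=sm.families.Binomial(), offset=offset
    )
    try:
        res = model.fit()
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise EstimationError(f"logistic fit failed: {exc}") from exc
    se = np.asarray(res.bse)
    if not np.all(np.isfinite(se)) or np.any(se[1:] > 10):
        raise EstimationError(
            "proxy-effect logistic fit is unstable (likely complete separation)"
        )
    return ProxyEffects(
        or_bbd=float(np.exp(res.params[1])),
        or_fh=float(np.exp(res.params[2])),
        se_log_bbd=float(se[1]),
        se_log_fh=float(se[2]),
    )
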