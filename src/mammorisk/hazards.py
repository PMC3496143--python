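"""Piecewise-constant hazard schedules and the Bruzzi attributable-risk
conversion of composite incidence to a baseline hazard.

Composite (population-average) breast-cancer incidence h1*(t) mixes
women at all risk levels.  Absolute-risk projection needs the baseline
hazard h1(t) for a woman at the reference level of every risk factor;
it is obtained band-wise as h1 = h1* × (1 − AR), where AR is the
population attributable risk of the modelled factors in the Bruzzi
case-based form AR = 1 − Σ_j ρ_j / r_j (ρ_j the proportion of cases in
risk stratum j, r_j the stratum relative risk).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HazardSchedule",
    "AttributableRisk",
    "bruzzi_attributable_risk",
    "case_distribution_from_population",
    "convert_to_baseline",
    "population_attributable_risk",
]

_PROP_TOL = 1e-9


@dataclass
class HazardSchedule:
    """Age-band hazard table: composite incidence, competing mortality,
    and (after conversion) the baseline breast-cancer hazard.

    Rates are per person-year.  ``age_breaks`` has one more entry than
    the rate arrays; bands are lower-inclusive ``[lo, hi)``.
    """

    age_breaks: np.ndarray
    h1_star: np.ndarray
    h2: np.ndarray
    h1: np.ndarray | None = None

    def __post_init__(self):
        self.age_breaks = np.asarray(self.age_breaks, dtype=float)
        self.h1_star = np.asarray(self.h1_star, dtype=float)
        self.h2 = np.asarray(self.h2, dtype=float)
        if self.h1 is not None:
            self.h1 = np.asarray(self.h1, dtype=float)
        n = len(self.h1_star)
        if len(self.age_breaks) != n + 1 or len(self.h2) != n:
            raise ValueError("age_breaks must have len(h1_star) + 1 entries")
        if np.any(np.diff(self.age_breaks) <= 0):
            raise ValueError("age bands must be contiguous and ascending")
        for name, arr in (("h1_star", self.h1_star), ("h2", self.h2)):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} rates must be finite and non-negative")

    @property
    def n_bands(self) -> int:
        return len(self.h1_star)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.age_breaks[0]), float(self.age_breaks[-1])

    def band_index(self, age: float) -> int:
        """Index of the band containing ``age`` (lower-inclusive)."""
        lo, hi = self.support
        if not lo <= age < hi:
            raise ValueError(f"age {age} outside schedule support [{lo}, {hi})")
        return int(np.searchsorted(self.age_breaks, age, side="right") - 1)

    def baseline(self) -> np.ndarray:
        """The baseline hazard, falling back to composite incidence if
        no attributable-risk conversion has been applied."""
        return self.h1 if self.h1 is not None else self.h1_star

    @classmethod
    def from_tsv(cls, path) -> "HazardSchedule":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("age_low").reset_index(drop=True)
        if not np.allclose(df["age_high"].to_numpy()[:-1], df["age_low"].to_numpy()[1:]):
            raise ValueError("hazard table bands are not contiguous")
        breaks = np.concatenate([df["age_low"].to_numpy(float), [float(df["age_high"].iloc[-1])]])
        return cls(
            age_breaks=breaks,
            h1_star=df["incidence_per_100k"].to_numpy(float) / 1e5,
            h2=df["mortality_per_100k"].to_numpy(float) / 1e5,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "age_low": self.age_breaks[:-1],
                "age_high": self.age_breaks[1:],
                "incidence_per_100k": self.h1_star * 1e5,
                "mortality_per_100k": self.h2 * 1e5,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AttributableRisk:
    """Bruzzi population attributable risk with its case strata."""

    ar: float
    strata: tuple

    def __post_init__(self):
        if not 0 <= self.ar < 1:
            raise ValueError("attributable risk must be in [0, 1)")


def bruzzi_attributable_risk(
    strata: Sequence[tuple[float, float]],
) -> AttributableRisk:
    """AR = 1 − Σ_j ρ_j / r_j over case strata (ρ_j case proportion,
    r_j stratum relative risk)."""
    rho = np.array([s[0] for s in strata], dtype=float)
    rr = np.array([s[1] for s in strata], dtype=float)
    if abs(rho.sum() - 1.0) > _PROP_TOL:
        raise ValueError(f"case proportions sum to {rho.sum()}, not 1")
    if np.any(rho < 0):
        raise ValueError("case proportions must be non-negative")
    if np.any(rr <= 0):
        raise ValueError("relative risks must be positive")
    ar = 1.0 - float(np.sum(rho / rr))
    return AttributableRisk(ar=ar, strata=tuple((float(p), float(r)) for p, r in strata))


def case_distribution_from_population(
    population_probs: Sequence[float], relative_risks: Sequence[float]
) -> np.ndarray:
    """Case stratum proportions implied by population frequencies:
    ρ_j = p_j r_j / Σ_k p_k r_k."""
    p = np.asarray(population_probs, dtype=float)
    r = np.asarray(relative_risks, dtype=float)
    if p.shape != r.shape:
        raise ValueError("population probabilities and relative risks differ in length")
    if abs(p.sum() - 1.0) > _PROP_TOL:
        raise ValueError(f"population proportions sum to {p.sum()}, not 1")
    if np.any(p < 0):
        raise ValueError("population proportions must be non-negative")
    if np.any(r <= 0):
        raise ValueError("relative risks must be positive")
    w = p * r
    return w / w.sum()


def convert_to_baseline(schedule: HazardSchedule, ar) -> HazardSchedule:
    """Band-wise baseline hazard h1 = h1* × (1 − AR).

    ``ar`` may be a scalar (age-constant, the default reading) or an
    :class:`AttributableRisk`, or an array with one value per band.
    """
    if isinstance(ar, AttributableRisk):
        ar = ar.ar
    ar_arr = np.broadcast_to(np.asarray(ar, dtype=float), schedule.h1_star.shape)
    if np.any(ar_arr < 0) or np.any(ar_arr >= 1):
        raise ValueError("attributable risk must be in [0, 1)")
    return replace(schedule, h1=schedule.h1_star * (1.0 - ar_arr))


def population_attributable_risk(
    table, model_spec, ref=None, normalized: bool = True
) -> AttributableRisk:
    """AR of a model's risk factors under the configured reference
    population, via the identity AR = 1 − 1/E[r] (the Bruzzi sum with
    case proportions induced by the population distribution).

    With ``normalized`` (the package's scoring convention) every
    component already has population mean 1, so E[r] = 1 and AR = 0:
    the composite incidence IS the baseline hazard on the normalised
    relative-risk scale.  With ``normalized=False`` the raw published
    relative risks are used and E[r] is the product of per-component
    population means (components are independent in the reference).
    """
    from . import effects as _eff

    if ref is None:
        ref = _eff.ReferenceDistribution.default()
    comps = _eff._resolve_components(model_spec)
    mean_r = 1.0
    if not normalized:
        for comp in comps:
            mean_r *= _eff.component_mean_rr(table, comp, ref)
    ar = 1.0 - 1.0 / mean_r
    return AttributableRisk(ar=max(ar, 0.0), strata=())
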