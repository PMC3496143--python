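"""Discrimination, calibration and reclassification statistics for
comparing risk-prediction models on labelled (case-control) data.

Implements the Mann-Whitney AUC with DeLong variance and the paired
DeLong test, three-category reclassification tables with the Pencina
net reclassification improvement (NRI) and integrated discrimination
improvement (IDI), the Hosmer-Lemeshow calibration test with a
location-recalibration step for case-control sampling, the Brier
score, and predictiveness / case-capture curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "RiskCutoffs",
    "ReclassificationTable",
    "HosmerLemeshowResult",
    "ComparisonResult",
    "auc",
    "delong_paired_test",
    "reclassification",
    "nri_from_table",
    "nri",
    "idi",
    "hosmer_lemeshow",
    "brier",
    "case_capture_curve",
    "compare_models",
    "round_half_up",
]


def round_half_up(x, decimals: int = 0):
    """Round half away from zero, matching hand-rounded published tables."""
    factor = 10.0**decimals
    return np.floor(np.abs(x) * factor + 0.5) * np.sign(x) / factor


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both cases and controls are required")
    return y.astype(int)


# ---------------------------------------------------------------------------
# AUC and the DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Per-model AUCs and the DeLong covariance matrix.

    ``scores`` has shape (k_models, n_subjects).
    """
    pos = scores[:, labels == 1]
    neg = scores[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    aucs = np.empty(k)
    v_pos = np.empty((k, m))
    v_neg = np.empty((k, n))
    for i in range(k):
        all_ranks = _midrank(np.concatenate([pos[i], neg[i]]))
        pos_ranks = _midrank(pos[i])
        neg_ranks = _midrank(neg[i])
        aucs[i] = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
        # structural components: V10 over cases, V01 over controls
        v_pos[i] = (all_ranks[:m] - pos_ranks) / n
        v_neg[i] = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s_pos = np.atleast_2d(np.cov(v_pos)) if m > 1 else np.zeros((k, k))
    s_neg = np.atleast_2d(np.cov(v_neg)) if n > 1 else np.zeros((k, k))
    cov = s_pos / m + s_neg / n
    return aucs, cov


def auc(scores, labels) -> tuple[float, float, float]:
    """Mann-Whitney AUC (ties counted ½) with DeLong 95% Wald CI.

    Returns ``(auc, ci_low, ci_high)``, the CI clipped to [0, 1].
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)[None, :]
    aucs, cov = _delong_components(s, y)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = stats.norm.ppf(0.975)
    return (
        float(aucs[0]),
        float(np.clip(aucs[0] - z * se, 0, 1)),
        float(np.clip(aucs[0] + z * se, 0, 1)),
    )


def delong_paired_test(scores_old, scores_new, labels) -> tuple[float, float]:
    """Paired DeLong test for the difference of correlated AUCs.

    Returns ``(delta_auc, two_sided_p)`` with delta = AUC_new − AUC_old.
    """
    old = np.asarray(scores_old, dtype=float)
    new = np.asarray(scores_new, dtype=float)
    if old.shape != new.shape:
        raise ValueError("score vectors must have equal length (same subjects)")
    y = _check_binary(labels)
    if len(y) != len(old):
        raise ValueError("labels and scores differ in length")
    aucs, cov = _delong_components(np.vstack([old, new]), y)
    delta = float(aucs[1] - aucs[0])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0:
        return delta, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return delta, float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Reclassification, NRI, IDI


@dataclass(frozen=True)
class RiskCutoffs:
    """Two cutoffs splitting (0,1) into low (0,ε1], intermediate
    (ε1,ε2], and high (ε2,1) risk categories."""

    eps1: float
    eps2: float

    def __post_init__(self):
        if not 0 < self.eps1 < self.eps2 < 1:
            raise ValueError("cutoffs must satisfy 0 < eps1 < eps2 < 1")

    def assign(self, risks) -> np.ndarray:
        """Category indices 0/1/2; a risk exactly at a cutoff goes to
        the lower category."""
        r = np.asarray(risks, dtype=float)
        if np.any((r <= 0) | (r >= 1)):
            raise ValueError("risks must lie strictly inside (0, 1)")
        return np.digitize(r, [self.eps1, self.eps2], right=True)


@dataclass
class ReclassificationTable:
    """3×3 old-category × new-category counts, separately for cases and
    controls.  The total-sample table is their element-wise sum."""

    case_counts: np.ndarray
    control_counts: np.ndarray
    cutoffs: RiskCutoffs | None = None

    def __post_init__(self):
        self.case_counts = np.asarray(self.case_counts, dtype=int)
        self.control_counts = np.asarray(self.control_counts, dtype=int)
        for name, c in (("case", self.case_counts), ("control", self.control_counts)):
            if c.shape != (3, 3):
                raise ValueError(f"{name} counts must be 3x3")
            if np.any(c < 0):
                raise ValueError(f"{name} counts must be non-negative")

    @property
    def total_counts(self) -> np.ndarray:
        return self.case_counts + self.control_counts

    @property
    def n_cases(self) -> int:
        return int(self.case_counts.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_counts.sum())

    def _group(self, group: str) -> np.ndarray:
        return {
            "cases": self.case_counts,
            "controls": self.control_counts,
            "total": self.total_counts,
        }[group]

    def percent_reclassified(self, group: str) -> np.ndarray:
        """Per-row percent moved off the diagonal, rounded half-up to
        integers as in published reclassification tables."""
        c = self._group(group)
        row_tot = c.sum(axis=1)
        off = row_tot - np.diag(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(row_tot > 0, 100.0 * off / row_tot, 0.0)
        return round_half_up(pct).astype(int)

    def total_percent_reclassified(self) -> int:
        c = self.total_counts
        return int(round_half_up(100.0 * (c.sum() - np.trace(c)) / c.sum()))


def reclassification(old_risks, new_risks, labels, cutoffs: RiskCutoffs) -> ReclassificationTable:
    """Cross-classify subjects by old-model and new-model risk category."""
    y = _check_binary(labels)
    old_cat = cutoffs.assign(old_risks)
    new_cat = cutoffs.assign(new_risks)
    if len(old_cat) != len(new_cat) or len(old_cat) != len(y):
        raise ValueError("risk vectors and labels must have equal length")
    tables = []
    for g in (1, 0):
        m = y == g
        counts = np.zeros((3, 3), dtype=int)
        np.add.at(counts, (old_cat[m], new_cat[m]), 1)
        tables.append(counts)
    return ReclassificationTable(
        case_counts=tables[0], control_counts=tables[1], cutoffs=cutoffs
    )


def _move_probs(counts: np.ndarray) -> tuple[float, float, int]:
    n = counts.sum()
    up = np.triu(counts, k=1).sum()
    down = np.tril(counts, k=-1).sum()
    return up / n, down / n, int(n)


def nri_from_table(table: ReclassificationTable) -> tuple[float, float, float]:
    """Net reclassification improvement from a 3×3 table pair.

    NRI = [P(up|case) − P(down|case)] − [P(up|control) − P(down|control)];
    Z from the Pencina asymptotic variance (with the squared-net-move
    correction); two-sided p.
    """
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("both cases and controls are required")
    up_ca, down_ca, n_ca = _move_probs(table.case_counts)
    up_co, down_co, n_co = _move_probs(table.control_counts)
    nri_val = (up_ca - down_ca) - (up_co - down_co)
    var = (up_ca + down_ca - (up_ca - down_ca) ** 2) / n_ca + (
        up_co + down_co - (up_co - down_co) ** 2
    ) / n_co
    if var <= 0:
        return float(nri_val), 0.0, 1.0
    z = nri_val / np.sqrt(var)
    return float(nri_val), float(z), float(2 * stats.norm.sf(abs(z)))


def nri(old_risks, new_risks, labels, cutoffs: RiskCutoffs) -> tuple[float, float, float]:
    """Categorical NRI straight from paired risk vectors."""
    return nri_from_table(reclassification(old_risks, new_risks, labels, cutoffs))


def idi(old_risks, new_risks, labels) -> tuple[float, float, float]:
    """Integrated discrimination improvement.

    IDI = (mean Δrisk | cases) − (mean Δrisk | controls) where
    Δrisk = new − old; Z from the two groups' paired-difference
    standard errors.
    """
    y = _check_binary(labels)
    d = np.asarray(new_risks, dtype=float) - np.asarray(old_risks, dtype=float)
    if len(d) != len(y):
        raise ValueError("risk vectors and labels must have equal length")
    d_ca, d_co = d[y == 1], d[y == 0]
    idi_val = float(d_ca.mean() - d_co.mean())
    se = np.sqrt(
        d_ca.var(ddof=1) / len(d_ca) + d_co.var(ddof=1) / len(d_co)
    )
    if se == 0:
        return idi_val, 0.0, 1.0
    z = idi_val / se
    return idi_val, float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class HosmerLemeshowResult:
    chi2: float
    p: float
    df: int
    table: pd.DataFrame
    recalibration_intercept: float | None = None


def hosmer_lemeshow(
    risks, labels, n_groups: int = 10, recalibrate: bool = True
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow chi-square over deciles of predicted risk.

    With ``recalibrate`` (appropriate for case-control samples), an
    intercept-only logistic model with logit(risk) as a fixed offset is
    fitted first; its intercept shifts every risk on the logit scale
    before grouping, absorbing the case-control sampling fraction.

    The statistic is Σ_g (O_g − E_g)² / (E_g (1 − E_g/n_g)) on
    ``n_groups − 2`` degrees of freedom; groups emptied by heavy ties
    are merged (qcut with duplicate bin edges dropped).
    """
    y = _check_binary(labels)
    r = np.asarray(risks, dtype=float)
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("risks must lie strictly inside (0, 1)")
    alpha = None
    if recalibrate:
        res = sm.GLM(
            y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=logit(r)
        ).fit()
        alpha = float(res.params[0])
        r = expit(logit(r) + alpha)
    try:
        groups = np.asarray(pd.qcut(r, n_groups, labels=False, duplicates="drop"), dtype=float)
        groups[np.isnan(groups)] = 0  # fully tied values collapse into one group
        groups = groups.astype(int)
    except ValueError:  # all risks identical
        groups = np.zeros(len(r), dtype=int)
    rows = []
    for g in np.unique(groups):
        m = groups == g
        n_g = int(m.sum())
        obs = float(y[m].sum())
        exp = float(r[m].sum())
        rows.append((n_g, obs, exp, float(r[m].mean())))
    tab = pd.DataFrame(rows, columns=["n", "observed", "expected", "mean_risk"])
    denom = tab.expected * (1 - tab.expected / tab.n)
    terms = np.where(denom > 0, (tab.observed - tab.expected) ** 2 / denom, 0.0)
    chi2 = float(np.sum(terms))
    df = max(len(tab) - 2, 1)
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return HosmerLemeshowResult(
        chi2=chi2, p=p, df=df, table=tab, recalibration_intercept=alpha
    )


def brier(risks, labels) -> float:
    """Mean squared difference between predicted risk and outcome."""
    r = np.asarray(risks, dtype=float)
    y = np.asarray(labels, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("risks must lie in [0, 1]")
    if len(r) != len(y):
        raise ValueError("risks and labels must have equal length")
    return float(np.mean((r - y) ** 2))


# ---------------------------------------------------------------------------
# Predictiveness / case capture


def case_capture_curve(risks, labels=None, weights=None):
    """Share of cases captured by the top-q fraction of the risk
    distribution.

    Returns a vectorised function ``capture(q)``.  Case weight is the
    0/1 label when ``labels`` is given, otherwise each woman's own
    risk (expected cases, the analytical predictiveness weighting);
    ``weights`` overrides both.  Ties in risk are averaged over the
    tied block, so the curve is piecewise linear and well defined.
    """
    r = np.asarray(risks, dtype=float)
    if len(r) == 0:
        raise ValueError("empty input")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    elif labels is not None:
        w = np.asarray(labels, dtype=float)
    else:
        w = r.copy()
    if len(w) != len(r):
        raise ValueError("weights/labels and risks must have equal length")
    order = np.argsort(-r, kind="stable")
    r_sorted = r[order]
    w_sorted = w[order].astype(float)
    # average weights within blocks of tied risk
    start = 0
    n = len(r)
    for end in range(1, n + 1):
        if end == n or r_sorted[end] != r_sorted[start]:
            w_sorted[start:end] = w_sorted[start:end].mean()
            start = end
    total = w_sorted.sum()
    if total == 0:
        raise ValueError("no cases (zero total case weight)")
    cum = np.concatenate([[0.0], np.cumsum(w_sorted) / total])
    grid = np.arange(n + 1) / n

    def capture(q):
        q_arr = np.asarray(q, dtype=float)
        if np.any((q_arr < 0) | (q_arr > 1)):
            raise ValueError("q must lie in [0, 1]")
        out = np.interp(q_arr, grid, cum)
        return float(out) if np.isscalar(q) else out

    return capture


# ---------------------------------------------------------------------------
# One-call model comparison


@dataclass
class ComparisonResult:
    """Head-to-head summary of an old and a new risk model."""

    auc_old: tuple[float, float, float]
    auc_new: tuple[float, float, float]
    delta_auc: float
    p_delta_auc: float
    nri: float
    nri_z: float
    nri_p: float
    idi: float
    idi_z: float
    idi_p: float
    hl_old: HosmerLemeshowResult
    hl_new: HosmerLemeshowResult
    brier_old: float
    brier_new: float
    table: ReclassificationTable = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "auc_old": self.auc_old,
            "auc_new": self.auc_new,
            "delta_auc": self.delta_auc,
            "p_delta_auc": self.p_delta_auc,
            "nri": self.nri,
            "nri_z": self.nri_z,
            "nri_p": self.nri_p,
            "idi": self.idi,
            "idi_z": self.idi_z,
            "idi_p": self.idi_p,
            "hl_chi2_old": self.hl_old.chi2,
            "hl_p_old": self.hl_old.p,
            "hl_chi2_new": self.hl_new.chi2,
            "hl_p_new": self.hl_new.p,
            "brier_old": self.brier_old,
            "brier_new": self.brier_new,
            "case_table": self.table.case_counts.tolist(),
            "control_table": self.table.control_counts.tolist(),
        }


def compare_models(
    old_risks, new_risks, labels, cutoffs: RiskCutoffs
) -> ComparisonResult:
    """All pairwise evaluation statistics for two risk models at once."""
    tab = reclassification(old_risks, new_risks, labels, cutoffs)
    nri_val, nri_z, nri_p = nri_from_table(tab)
    idi_val, idi_z, idi_p = idi(old_risks, new_risks, labels)
    delta, p_delta = delong_paired_test(old_risks, new_risks, labels)
    return ComparisonResult(
        auc_old=auc(old_risks, labels),
        auc_new=auc(new_risks, labels),
        delta_auc=delta,
        p_delta_auc=p_delta,
        nri=nri_val,
        nri_z=nri_z,
        nri_p=nri_p,
        idi=idi_val,
        idi_z=idi_z,
        idi_p=idi_p,
        hl_old=hosmer_lemeshow(old_risks, labels),
        hl_new=hosmer_lemeshow(new_risks, labels),
        brier_old=brier(old_risks, labels),
        brier_new=brier(new_risks, labels),
        table=tab,
    )
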