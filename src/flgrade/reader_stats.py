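"""Reader-study statistics: agreement, ROC/AUC, and MRMC modality comparison.

The reader study behind this package is fully crossed: every reader scores
every case (0-100 confidence that the case is high grade) once unaided and
once after seeing the computer's HPF classification map.  This module
provides the statistical layer for such a design:

* score dichotomization at 50 and percent agreement with the case truth;
* the trapezoidal (Mann-Whitney) AUC with two 95% confidence interval
  constructions — an exact binomial (Clopper-Pearson) interval that treats
  the AUC as a binomial proportion over case pairs, and a U-statistic
  (DeLong-type) variance combined with the logit transform;
* the Obuchowski-Rockett (OR) multi-reader multi-case comparison of the two
  modalities with Hillis denominator degrees of freedom, applicable to both
  AUC and agreement accuracy indices (error covariances estimated by
  delete-one-case jackknife in either case);
* empirical ROC curves and the nonparametric average of reader ROC curves
  taken along the direction of the (0,1)-(1,0) diagonal of ROC space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .errors import StatsError

UNAIDED = "UNAIDED"
AIDED = "AIDED"
HIGH = "HIGH"
LOW = "LOW"


@dataclass(frozen=True)
class ScoreRecord:
    """One reader confidence observation (0-100) for one case/modality."""

    reader_id: str
    case_id: str
    modality: str
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 100:
            raise ValueError("score must lie in [0, 100]")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth risk category for one case."""

    case_id: str
    grade: str


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    ci_low: float
    ci_high: float
    method: str  # EXACT_BINOMIAL or LOGIT_USTAT


@dataclass(frozen=True)
class OrComparison:
    """Obuchowski-Rockett modality comparison with Hillis degrees of freedom."""

    index: str  # AUC or AGREEMENT
    mean_unaided: float
    mean_aided: float
    difference: float  # aided minus unaided
    ci_low: float
    ci_high: float
    f_stat: float
    ddf: float
    p_value: float


@dataclass
class RocCurve:
    """An empirical ROC polyline from (0,0) to (1,1), both axes monotone."""

    points: np.ndarray  # (n, 2) of (fpr, tpr)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if not (np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])):
            raise ValueError("curve must run from (0,0) to (1,1)")
        if np.any(np.diff(pts, axis=0) < -1e-12):
            raise ValueError("coordinates must be non-decreasing")
        self.points = pts

    def auc(self) -> float:
        return float(np.trapezoid(self.points[:, 1], self.points[:, 0]))


# ---------------------------------------------------------------------------
# input normalization


def scores_frame(scores: "pd.DataFrame | Iterable[ScoreRecord]") -> pd.DataFrame:
    if isinstance(scores, pd.DataFrame):
        df = scores.copy()
    else:
        df = pd.DataFrame([vars(s) for s in scores])
    missing = {"reader_id", "case_id", "modality", "score"} - set(df.columns)
    if missing:
        raise StatsError(f"score table missing columns {sorted(missing)}")
    return df


def truth_series(truth: "pd.DataFrame | Iterable[TruthRecord] | dict") -> pd.Series:
    if isinstance(truth, dict):
        ser = pd.Series(truth)
    elif isinstance(truth, pd.DataFrame):
        if truth["case_id"].duplicated().any():
            raise StatsError("duplicate truth records")
        ser = truth.set_index("case_id")["grade"]
    else:
        recs = list(truth)
        ser = pd.Series({r.case_id: r.grade for r in recs})
        if len(ser) != len(recs):
            raise StatsError("duplicate truth records")
    return ser


# ---------------------------------------------------------------------------
# dichotomization and agreement


def dichotomize(score: float, threshold: float = 50.0) -> str:
    """HIGH iff the confidence score reaches the threshold (default 50)."""
    return HIGH if score >= threshold else LOW


def percent_agreement(
    scores: "pd.DataFrame | Iterable[ScoreRecord]",
    truth: "pd.DataFrame | Iterable[TruthRecord] | dict",
    threshold: float = 50.0,
) -> tuple[int, int, float]:
    """Readings whose dichotomized score matches the case truth.

    Returns ``(n_agree, n_total, percent)``.
    """
    df = scores_frame(scores)
    ts = truth_series(truth)
    unmatched = set(df["case_id"]) - set(ts.index)
    if unmatched:
        raise StatsError(f"cases without truth: {sorted(unmatched)!r}", code="unmatched_case")
    calls = np.where(df["score"].to_numpy(dtype=float) >= threshold, HIGH, LOW)
    agree = int(np.sum(calls == ts.reindex(df["case_id"]).to_numpy()))
    total = len(df)
    return agree, total, 100.0 * agree / total


# ---------------------------------------------------------------------------
# AUC and confidence intervals


def _pos_neg(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if truth.dtype.kind in "USO":
        is_pos = truth == HIGH
    else:
        is_pos = truth.astype(bool)
    pos, neg = scores[is_pos], scores[~is_pos]
    if len(pos) == 0 or len(neg) == 0:
        raise StatsError("need both classes in the truth", code="degenerate_truth")
    return pos, neg


def trapezoidal_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Empirical (trapezoidal-rule) AUC = Mann-Whitney statistic.

    Over all HIGH/LOW case pairs, the fraction with the HIGH case scored
    above the LOW case, ties counted half.
    """
    pos, neg = _pos_neg(scores, truth)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    m = len(pos)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * len(neg)))


def auc_ci_exact_binomial(auc: float, n_pos: int, n_neg: int,
                          level: float = 0.95) -> AucEstimate:
    """Clopper-Pearson interval treating the AUC as a binomial proportion.

    The number of trials is the number of HIGH/LOW case pairs
    ``N = n_pos * n_neg``; successes are ``round(auc * N)``.
    """
    if n_pos < 1 or n_neg < 1:
        raise StatsError("need at least one case per class")
    n = n_pos * n_neg
    s = int(round(auc * n))
    alpha = 1.0 - level
    lo = 0.0 if s == 0 else float(stats.beta.ppf(alpha / 2, s, n - s + 1))
    hi = 1.0 if s == n else float(stats.beta.ppf(1 - alpha / 2, s + 1, n - s))
    return AucEstimate(auc=auc, ci_low=min(lo, auc), ci_high=max(hi, auc),
                       method="EXACT_BINOMIAL")


def auc_ustat_variance(scores: np.ndarray, truth: np.ndarray) -> float:
    """U-statistic (DeLong-type) variance of the empirical AUC."""
    pos, neg = _pos_neg(scores, truth)
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise StatsError("need at least two cases per class")
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)  # placement of each HIGH case among the LOWs
    v01 = psi.mean(axis=0)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def auc_ci_logit_ustat(scores: np.ndarray, truth: np.ndarray,
                       level: float = 0.95) -> AucEstimate:
    """Normal interval for logit(AUC) with U-statistic variance, mapped back.

    The delta method converts the AUC variance to the logit scale; the
    resulting symmetric interval is inverse-logit transformed, which keeps
    the endpoints inside (0, 1) and preserves their order.
    """
    auc = trapezoidal_auc(scores, truth)
    if auc <= 0.0 or auc >= 1.0:
        raise StatsError("logit undefined at AUC of 0 or 1", code="logit_undefined")
    var = auc_ustat_variance(scores, truth)
    z = stats.norm.ppf(0.5 + level / 2)
    se_logit = np.sqrt(var) / (auc * (1 - auc))
    lo, hi = expit(logit(auc) + np.array([-1, 1]) * z * se_logit)
    return AucEstimate(auc=auc, ci_low=float(lo), ci_high=float(hi), method="LOGIT_USTAT")


# ---------------------------------------------------------------------------
# ROC curves


def empirical_roc(scores: np.ndarray, truth: np.ndarray) -> RocCurve:
    """Empirical ROC from sweeping the decision threshold over the scores."""
    from sklearn.metrics import roc_curve as _sk_roc

    pos, neg = _pos_neg(scores, truth)  # validates both classes present
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    s = np.concatenate([pos, neg])
    fpr, tpr, _ = _sk_roc(y, s, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[-1], [1, 1]):
        pts = np.vstack([pts, [1.0, 1.0]])
    return RocCurve(points=pts)


def average_roc_diagonal(curves: Sequence[RocCurve], grid_points: int = 101) -> RocCurve:
    """Nonparametric average of ROC curves along the anti-diagonal direction.

    ROC space is rotated 45 degrees so that the chance line becomes the
    abscissa; each curve is then a single-valued function of position along
    that axis (its offset measured along the (0,1)-(1,0) diagonal
    direction).  Offsets are linearly interpolated on a common grid,
    averaged, and rotated back; the result is clipped to the unit square and
    made monotone by a cumulative maximum.
    """
    curves = list(curves)
    if not curves:
        raise StatsError("no curves to average", code="no_curves")
    s2 = np.sqrt(2.0)
    grid = np.linspace(0.0, s2, grid_points)
    offsets = np.empty((len(curves), grid_points))
    for i, curve in enumerate(curves):
        x, y = curve.points[:, 0], curve.points[:, 1]
        u = (x + y) / s2
        v = (y - x) / s2
        offsets[i] = np.interp(grid, u, v)
    vbar = offsets.mean(axis=0)
    x = np.clip((grid - vbar) / s2, 0.0, 1.0)
    y = np.clip((grid + vbar) / s2, 0.0, 1.0)
    x = np.maximum.accumulate(x)
    y = np.maximum.accumulate(y)
    x[0], y[0], x[-1], y[-1] = 0.0, 0.0, 1.0, 1.0
    return RocCurve(points=np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# Obuchowski-Rockett / Hillis MRMC comparison


def _index_and_jackknife(scores: np.ndarray, is_pos: np.ndarray, index: str,
                         threshold: float) -> tuple[float, np.ndarray]:
    """An accuracy index and its delete-one-case jackknife values.

    ``scores`` is the per-case vector for one reader-modality unit; returns
    ``(theta_hat, theta_jk)`` with one jackknife value per deleted case.
    """
    n_cases = len(scores)
    if index == "AGREEMENT":
        calls = scores >= threshold
        agree = (calls == is_pos).astype(float)
        total = agree.sum()
        theta = total / n_cases
        jk = (total - agree) / (n_cases - 1)
        return float(theta), jk
    pos, neg = scores[is_pos], scores[~is_pos]
    m, n = len(pos), len(neg)
    if m < 1 or n < 1:
        raise StatsError("need both classes in the truth", code="degenerate_truth")
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    total = psi.sum()
    theta = total / (m * n)
    jk = np.empty(n_cases)
    jk[is_pos] = (total - psi.sum(axis=1)) / ((m - 1) * n)
    jk[~is_pos] = (total - psi.sum(axis=0)) / (m * (n - 1))
    return float(theta), jk


def or_hillis_compare(
    scores: "pd.DataFrame | Iterable[ScoreRecord]",
    truth: "pd.DataFrame | Iterable[TruthRecord] | dict",
    index: str = "AUC",
    threshold: float = 50.0,
    level: float = 0.95,
    modalities: tuple[str, str] = (UNAIDED, AIDED),
) -> OrComparison:
    """Compare the two modalities' mean accuracy index across readers.

    Fits the Obuchowski-Rockett model: fixed modality effect, random
    readers, and correlated errors whose covariances (Cov1: same reader /
    different modality; Cov2: different reader / same modality; Cov3:
    different reader and modality) are estimated by delete-one-case
    jackknife of the per-unit index.  The modality F test uses the Hillis
    denominator degrees of freedom, and the confidence interval for the mean
    difference uses the same degrees of freedom.
    """
    if index not in ("AUC", "AGREEMENT"):
        raise StatsError(f"unknown index {index!r}")
    df = scores_frame(scores)
    ts = truth_series(truth)
    readers = sorted(df["reader_id"].unique())
    if len(readers) < 2:
        raise StatsError("need at least two readers", code="insufficient_readers")
    cases = sorted(ts.index)
    n_cases = len(cases)
    is_pos = ts.reindex(cases).to_numpy() == HIGH

    t = 2
    r = len(readers)
    theta = np.empty((r, t))
    theta_jk = np.empty((r, t, n_cases))
    piv = df.pivot_table(index="case_id", columns=["reader_id", "modality"],
                         values="score", aggfunc="first")
    for i, reader in enumerate(readers):
        for j, mod in enumerate(modalities):
            if (reader, mod) not in piv.columns:
                raise StatsError("every reader must score every case in both "
                                 "modalities", code="design_not_crossed")
            col = piv[(reader, mod)].reindex(cases)
            if col.isna().any():
                raise StatsError("every reader must score every case in both "
                                 "modalities", code="design_not_crossed")
            theta[i, j], theta_jk[i, j] = _index_and_jackknife(
                col.to_numpy(dtype=float), is_pos, index, threshold)

    # jackknife covariance matrix across the r*t reader-modality units
    flat = theta_jk.reshape(r * t, n_cases)
    dev = flat - flat.mean(axis=1, keepdims=True)
    cov = (n_cases - 1) / n_cases * (dev @ dev.T)

    same_reader = np.equal.outer(np.repeat(np.arange(r), t), np.repeat(np.arange(r), t))
    same_mod = np.equal.outer(np.tile(np.arange(t), r), np.tile(np.arange(t), r))
    diag = np.eye(r * t, dtype=bool)
    cov1 = cov[same_reader & ~same_mod].mean()
    cov2 = cov[~same_reader & same_mod].mean()
    cov3 = cov[~same_reader & ~same_mod].mean()

    grand = theta.mean()
    ms_t = r * np.sum((theta.mean(axis=0) - grand) ** 2) / (t - 1)
    resid = theta - theta.mean(axis=0) - theta.mean(axis=1, keepdims=True) + grand
    ms_tr = np.sum(resid ** 2) / ((t - 1) * (r - 1))

    denom = ms_tr + r * max(cov2 - cov3, 0.0)
    if denom <= 0:
        f_stat, ddf, p = 0.0, float("inf"), 1.0
    else:
        f_stat = float(ms_t / denom)
        ddf = float((t - 1) * (r - 1) * denom ** 2 / ms_tr ** 2) if ms_tr > 0 \
            else float("inf")
        p = float(stats.f.sf(f_stat, t - 1, ddf)) if np.isfinite(ddf) \
            else float(stats.chi2.sf(f_stat, t - 1))

    diff = float(theta[:, 1].mean() - theta[:, 0].mean())
    se_diff = float(np.sqrt(max(2.0 / r * denom, 0.0)))
    if se_diff > 0 and np.isfinite(ddf):
        tcrit = float(stats.t.ppf(0.5 + level / 2, ddf))
    else:
        tcrit = float(stats.norm.ppf(0.5 + level / 2))
    scale = 100.0 if index == "AGREEMENT" else 1.0
    return OrComparison(
        index=index,
        mean_unaided=float(theta[:, 0].mean()) * scale,
        mean_aided=float(theta[:, 1].mean()) * scale,
        difference=diff * scale,
        ci_low=(diff - tcrit * se_diff) * scale,
        ci_high=(diff + tcrit * se_diff) * scale,
        f_stat=f_stat, ddf=ddf, p_value=p)


def reader_aucs(scores: "pd.DataFrame | Iterable[ScoreRecord]",
                truth: "pd.DataFrame | Iterable[TruthRecord] | dict") -> pd.DataFrame:
    """Per-reader, per-modality trapezoidal AUCs as a tidy frame."""
    df = scores_frame(scores)
    ts = truth_series(truth)
    rows = []
    for (reader, mod), grp in df.groupby(["reader_id", "modality"]):
        auc = trapezoidal_auc(grp["score"].to_numpy(dtype=float),
                              ts.reindex(grp["case_id"]).to_numpy())
        rows.append({"reader_id": reader, "modality": mod, "auc": auc})
    return pd.DataFrame(rows)


def plot_roc_panel(curves: dict[str, RocCurve], average: RocCurve | None,
                   path: str) -> None:
    """Render per-reader ROC curves (thin) and their average (bold) to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in curves.items():
        ax.plot(curve.points[:, 0], curve.points[:, 1], lw=0.8, alpha=0.6, label=name)
    if average is not None:
        ax.plot(average.points[:, 0], average.points[:, 1], lw=2.5, color="k",
                label="average")
    ax.plot([0, 1], [0, 1], ls=":", color="gray", lw=0.8)
    ax.set_xlabel("False positive fraction")
    ax.set_ylabel("True positive fraction")
    if len(curves) <= 12:
        ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
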