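"""Accuracy and reliability statistics.

Errors are label-aligned Euclidean distances in cast-frame millimetres
(never nearest-match). Accuracy is summarized per landmark as mean ± SD
with success detection rates (SDR: percentage of predictions within
0.5 / 1 / 1.5 / 2 mm, inclusive) plus a pooled overall row and per-axis
mean absolute errors. Reliability across repeat annotation sessions is
summarized by per-landmark repeat distances and the two-way
absolute-agreement single-measures intraclass correlation ICC(A,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    FDI_LABELS,
    LandmarkSet,
    PalatemarkError,
    UndefinedStatisticError,
)

__all__ = [
    "DEFAULT_SDR_THRESHOLDS",
    "euclidean_errors",
    "axis_mae",
    "sdr",
    "summarize",
    "EvaluationReport",
    "repeat_distances",
    "RepeatabilityReport",
    "repeatability_report",
    "icc_single",
    "icc",
    "plot_error_boxplot",
]

DEFAULT_SDR_THRESHOLDS = (0.5, 1.0, 1.5, 2.0)


def _check_pair(pred: LandmarkSet, truth: LandmarkSet) -> None:
    if pred.labels != truth.labels:
        raise PalatemarkError("label mismatch between prediction and ground truth")


def euclidean_errors(pred: LandmarkSet, truth: LandmarkSet) -> np.ndarray:
    """Per-label straight-line distances (mm), in canonical FDI order."""
    _check_pair(pred, truth)
    return np.linalg.norm(pred.points - truth.points, axis=1)


def axis_mae(
    preds: list[LandmarkSet], truths: list[LandmarkSet]
) -> pd.DataFrame:
    """|dx|, |dy|, |dz| pooled over casts x landmarks: mean and SD per axis."""
    if len(preds) != len(truths) or not preds:
        raise PalatemarkError("need equal-length, non-empty paired lists")
    deltas = []
    for p, t in zip(preds, truths):
        _check_pair(p, t)
        deltas.append(np.abs(p.points - t.points))
    flat = np.concatenate(deltas)  # (n_casts * 12, 3)
    return pd.DataFrame(
        {"axis": ["x", "y", "z"], "mae": flat.mean(axis=0), "sd": flat.std(axis=0)}
    )


def sdr(errors, thresholds=DEFAULT_SDR_THRESHOLDS) -> np.ndarray:
    """Success detection rate: 100 * P(error <= t), inclusive, per threshold."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise UndefinedStatisticError("SDR undefined for an empty error list")
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds <= 0).any() or (np.diff(thresholds) <= 0).any():
        raise PalatemarkError("thresholds must be positive and ascending")
    return 100.0 * (errors[:, None] <= thresholds[None, :]).mean(axis=0)


@dataclass
class EvaluationReport:
    """Per-landmark accuracy table plus pooled overall row and outliers."""

    table: pd.DataFrame  # rows: 12 landmarks + "Overall"
    axis_table: pd.DataFrame
    n_casts: int
    outliers: pd.DataFrame  # cast_id, label, error_mm
    thresholds: tuple = DEFAULT_SDR_THRESHOLDS

    @property
    def overall_mean(self) -> float:
        return float(self.table.loc[self.table["label"] == "Overall", "mean"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")


def summarize(
    errors_by_cast: dict[str, np.ndarray],
    preds: list[LandmarkSet] | None = None,
    truths: list[LandmarkSet] | None = None,
    thresholds=DEFAULT_SDR_THRESHOLDS,
    outlier_rule: str = "3sd",
) -> EvaluationReport:
    """Build the accuracy report from per-cast, per-landmark errors.

    ``errors_by_cast`` maps cast_id -> 12 label-ordered errors (mm).
    Outliers are flagged per landmark at > mean + 3 SD (default) or, with
    ``outlier_rule="iqr"``, beyond Q3 + 1.5 IQR (the boxplot convention).
    """
    if not errors_by_cast:
        raise PalatemarkError("no casts to summarize")
    if outlier_rule not in ("3sd", "iqr"):
        raise PalatemarkError(f"unknown outlier rule {outlier_rule!r}")
    cast_ids = list(errors_by_cast)
    E = np.vstack([errors_by_cast[c] for c in cast_ids])  # (n_casts, 12)
    rows = []
    outlier_rows = []
    for j, label in enumerate(FDI_LABELS):
        e = E[:, j]
        rates = sdr(e, thresholds)
        rows.append([label, e.mean(), e.std(), *rates])
        if outlier_rule == "3sd":
            cut = e.mean() + 3.0 * e.std()
        else:
            q1, q3 = np.percentile(e, [25, 75])
            cut = q3 + 1.5 * (q3 - q1)
        for i in np.flatnonzero(e > cut):
            outlier_rows.append([cast_ids[i], label, e[i]])
    flat = E.ravel()
    rows.append(["Overall", flat.mean(), flat.std(), *sdr(flat, thresholds)])
    cols = ["label", "mean", "sd"] + [f"sdr_{t:g}mm" for t in thresholds]
    table = pd.DataFrame(rows, columns=cols)
    if preds is not None and truths is not None:
        axis_table = axis_mae(preds, truths)
    else:
        axis_table = pd.DataFrame(columns=["axis", "mae", "sd"])
    outliers = pd.DataFrame(outlier_rows, columns=["cast_id", "label", "error_mm"])
    return EvaluationReport(table, axis_table, len(cast_ids), outliers, tuple(thresholds))


# ---------------------------------------------------------------------------
# repeatability / reliability
# ---------------------------------------------------------------------------


def repeat_distances(rep1: LandmarkSet, rep2: LandmarkSet) -> np.ndarray:
    """Per-label distances between two annotation sessions (mm)."""
    return euclidean_errors(rep1, rep2)


@dataclass
class RepeatabilityReport:
    per_landmark: pd.DataFrame  # label, mean repeat distance
    overall_mean: float
    overall_sd: float
    icc_table: pd.DataFrame  # per landmark x axis ICC(A,1)

    @property
    def icc_min(self) -> float:
        return float(self.icc_table[["x", "y", "z"]].to_numpy().min())


def icc_single(x1, x2, form: str = "agreement") -> float:
    """Intraclass correlation for two sessions, single measures, k = 2.

    ``form="agreement"`` gives ICC(A,1) — two-way, absolute agreement —
    from the mean squares of the subjects x sessions table:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    ``form="consistency"`` gives ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE),
    which ignores systematic between-session shifts.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise PalatemarkError("sessions must be equal-length vectors")
    n = len(x1)
    if n < 3:
        raise UndefinedStatisticError("need at least 3 subjects for ICC")
    data = np.stack([x1, x2], axis=1)  # (n, k)
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if form == "agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise PalatemarkError(f"unknown ICC form {form!r}")
    if abs(denom) < 1e-30:
        raise UndefinedStatisticError("zero total variance; ICC undefined")
    return float((msr - mse) / denom)


def icc(
    session1: list[LandmarkSet], session2: list[LandmarkSet]
) -> pd.DataFrame:
    """ICC(A,1) per landmark and coordinate axis across repeat sessions."""
    if len(session1) != len(session2) or len(session1) < 3:
        raise UndefinedStatisticError("need >= 3 paired casts for ICC")
    A = np.stack([s.points for s in session1])  # (n, 12, 3)
    B = np.stack([s.points for s in session2])
    rows = []
    for j, label in enumerate(FDI_LABELS):
        vals = [icc_single(A[:, j, ax], B[:, j, ax]) for ax in range(3)]
        rows.append([label, *vals])
    return pd.DataFrame(rows, columns=["label", "x", "y", "z"])


def plot_error_boxplot(errors_by_cast: dict[str, np.ndarray], path) -> None:
    """Box plot of localization error per landmark, saved as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    E = np.vstack(list(errors_by_cast.values()))
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.boxplot([E[:, j] for j in range(12)], tick_labels=list(FDI_LABELS))
    ax.scatter(range(1, 13), E.mean(axis=0), marker="*", color="tab:red",
               zorder=3, label="mean")
    ax.set_xlabel("landmark (FDI)")
    ax.set_ylabel("error (mm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def repeatability_report(
    sessions: list[tuple[LandmarkSet, LandmarkSet]]
) -> RepeatabilityReport:
    """Repeat distances and coordinate ICCs over paired annotation sessions."""
    if not sessions:
        raise PalatemarkError("no sessions given")
    D = np.vstack([repeat_distances(a, b) for a, b in sessions])  # (n, 12)
    per_lm = pd.DataFrame({"label": FDI_LABELS, "mean_mm": D.mean(axis=0)})
    icc_table = icc([a for a, _ in sessions], [b for _, b in sessions])
    return RepeatabilityReport(
        per_landmark=per_lm,
        overall_mean=float(D.mean()),
        overall_sd=float(D.mean(axis=0).std()),
        icc_table=icc_table,
    )
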