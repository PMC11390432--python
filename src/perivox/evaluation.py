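"""Segmentation evaluation: Dice, sensitivity, positive predictive value.

Per subject, predicted and reference binary masks are reduced to voxel
confusion counts and the three standard overlap metrics::

    DSC = 2 TP / (2 TP + FP + FN)
    SEN = TP / (TP + FN)
    PPV = TP / (TP + FP)

DSC summarises overall overlap, SEN the fraction of true PVS voxels
detected, PPV the fraction of predicted voxels that are real.  When both
masks are empty the 0/0 forms are scored 1.0 (agreement on absence) and
the record is flagged degenerate so aggregation can exclude it on
request.

A reference comparison table of per-subject scores for five published
models (IAANet, TriSegNet, U-Net, nnU-Net, MfNS_De) on a 20-patient
cohort ships with the package for report formatting and regression
checks; see :func:`load_reference_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "confusion",
    "metrics",
    "evaluate_masks",
    "aggregate",
    "comparison_table",
    "load_reference_table",
]

METRIC_NAMES = ("DSC", "SEN", "PPV")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")


@dataclass
class MetricsRecord:
    subject_id: str
    model_name: str
    dsc: float
    sen: float
    ppv: float
    degenerate: bool = False


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Voxel confusion counts between aligned binary masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, fp, fn)


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, bool]:
    """(DSC, SEN, PPV, degenerate_flag) from confusion counts.

    Degenerate 0/0 denominators score 1.0 with the flag set: an empty
    prediction of an empty reference is perfect agreement.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    degenerate = False

    def ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 1.0
        return num / den

    dsc = ratio(2 * tp, 2 * tp + fp + fn)
    sen = ratio(tp, tp + fn)
    ppv = ratio(tp, tp + fp)
    return dsc, sen, ppv, degenerate


def evaluate_masks(
    pred: np.ndarray, truth: np.ndarray, subject_id: str = "", model_name: str = ""
) -> MetricsRecord:
    dsc, sen, ppv, deg = metrics(confusion(pred, truth))
    return MetricsRecord(subject_id, model_name, dsc, sen, ppv, degenerate=deg)


def records_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "model": [r.model_name for r in records],
            "DSC": [r.dsc for r in records],
            "SEN": [r.sen for r in records],
            "PPV": [r.ppv for r in records],
            "degenerate": [r.degenerate for r in records],
        }
    )


def aggregate(
    records: list[MetricsRecord] | pd.DataFrame, exclude_degenerate: bool = False
) -> pd.DataFrame:
    """Mean and population Std (divisor N) per metric per model.

    Population standard deviation is the convention under which the
    bundled reference table's printed Std row is reproduced exactly.
    Returns a frame indexed by (model, row) with row in {Mean, Std}.
    """
    df = records_frame(records) if not isinstance(records, pd.DataFrame) else records
    if df.empty:
        raise ValueError("no records to aggregate")
    if exclude_degenerate and "degenerate" in df:
        df = df[~df["degenerate"]]
    rows = []
    for model, grp in df.groupby("model", sort=False):
        vals = grp[list(METRIC_NAMES)]
        rows.append((model, "Mean", *vals.mean().tolist()))
        rows.append((model, "Std", *vals.std(ddof=0).tolist()))
    return pd.DataFrame(rows, columns=["model", "row", *METRIC_NAMES]).set_index(
        ["model", "row"]
    )


def comparison_table(records: list[MetricsRecord] | pd.DataFrame) -> pd.DataFrame:
    """Long-form comparison table with best-score flags.

    One row per (subject, model, metric); ``best`` is True for the
    maximal value of that metric on that subject across models (ties: all
    tied models flagged).  Mean/Std rows are appended per model with the
    same best-flag rule applied to the Mean row.
    """
    df = records_frame(records) if not isinstance(records, pd.DataFrame) else records
    long = df.melt(
        id_vars=["subject_id", "model"],
        value_vars=list(METRIC_NAMES),
        var_name="metric",
        value_name="value",
    )
    best = long.groupby(["subject_id", "metric"])["value"].transform("max")
    long["best"] = long["value"] == best
    agg = aggregate(df).reset_index()
    extra = []
    for row_name in ("Mean", "Std"):
        sub = agg[agg["row"] == row_name]
        m = sub.melt(
            id_vars=["model"],
            value_vars=list(METRIC_NAMES),
            var_name="metric",
            value_name="value",
        )
        m.insert(0, "subject_id", row_name)
        if row_name == "Mean":
            mbest = m.groupby("metric")["value"].transform("max")
            m["best"] = m["value"] == mbest
        else:
            m["best"] = False
        extra.append(m)
    return pd.concat([long, *extra], ignore_index=True)


def load_reference_table() -> pd.DataFrame:
    """Per-subject DSC/SEN/PPV for the five reference models (long form)."""
    with resources.files("perivox.data").joinpath("reference_scores.csv").open() as fh:
        wide = pd.read_csv(fh, comment="#")
    long = wide.melt(id_vars=["subject_id"], var_name="key", value_name="value")
    long[["metric", "model"]] = long["key"].str.split(":", expand=True)
    pivot = long.pivot_table(
        index=["subject_id", "model"], columns="metric", values="value"
    ).reset_index()
    pivot.columns.name = None
    return pivot.rename(columns={"subject_id": "subject_id", "model": "model"})[
        ["subject_id", "model", "DSC", "SEN", "PPV"]
    ]
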