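"""Evaluation statistics and uncertainty diagnostics.

MAE and RMSE over prediction records, normalised MAE (NMAE) per abundance
subgroup (c < 25, 25 <= c < 50, 50 <= c < 150, c >= 150, plus a "Noise"
subgroup that takes precedence for images carrying a substantial noise
box), and the Pearson correlation between predicted log noise variance and
absolute count error with a one-tailed p-value (H1: r > 0) — the diagnostic
that the learned uncertainty is informative about when the counter errs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotatedImage, PredictionRecord

__all__ = [
    "SUBGROUPS",
    "EvalReport",
    "mae",
    "rmse",
    "assign_subgroup",
    "nmae_by_subgroup",
    "uncertainty_error_correlation",
    "build_report",
]

SUBGROUPS = ("c<25", "25<=c<50", "50<=c<150", "c>=150", "Noise")

NOISE_AREA_FRACTION = 0.02  # a box covering >= 2% of the frame marks a noisy sample


def _errors(records: list[PredictionRecord]) -> np.ndarray:
    if not records:
        raise ValueError("need at least one prediction record")
    return np.array([r.count_true - r.count_pred for r in records], dtype=float)


def mae(records: list[PredictionRecord]) -> float:
    """Mean absolute count error."""
    return float(np.abs(_errors(records)).mean())


def rmse(records: list[PredictionRecord]) -> float:
    """Root mean squared count error (always >= MAE)."""
    return float(np.sqrt((_errors(records) ** 2).mean()))


def assign_subgroup(
    count_true: int,
    image: AnnotatedImage | None = None,
    noise_area_fraction: float = NOISE_AREA_FRACTION,
) -> str:
    """Subgroup label; "Noise" takes precedence over the count bins."""
    if image is not None and image.noise_boxes.shape[0]:
        h, w = image.shape
        areas = (image.noise_boxes[:, 2] - image.noise_boxes[:, 0]) * (
            image.noise_boxes[:, 3] - image.noise_boxes[:, 1]
        )
        if (areas >= noise_area_fraction * h * w).any():
            return "Noise"
    if count_true < 25:
        return "c<25"
    if count_true < 50:
        return "25<=c<50"
    if count_true < 150:
        return "50<=c<150"
    return "c>=150"


def nmae_by_subgroup(records: list[PredictionRecord]) -> dict[str, float | None]:
    """Per-subgroup sum|error| / sum(true count); None where undefined.

    Normalising by the group's total true count makes errors comparable
    between sparse and dense strata; a group whose counts sum to zero has
    no defined value and is reported as missing.
    """
    out: dict[str, float | None] = {}
    for group in SUBGROUPS:
        members = [r for r in records if r.subgroup == group]
        if not members:
            continue
        total_count = sum(r.count_true for r in members)
        if total_count <= 0:
            out[group] = None
            continue
        total_err = sum(abs(r.count_true - r.count_pred) for r in members)
        out[group] = float(total_err / total_count)
    return out


def uncertainty_error_correlation(
    records: list[PredictionRecord],
) -> tuple[float | None, float | None]:
    """Pearson r between log sigma^2 and |error|, with one-tailed p (r > 0).

    The p-value uses the t-transform of r with N - 2 degrees of freedom.
    Returns (None, None) when either axis is constant or N < 3.
    """
    if len(records) < 3:
        return None, None
    s = np.array([r.log_sigma2 for r in records], dtype=float)
    err = np.abs(_errors(records))
    if np.ptp(s) == 0 or np.ptp(err) == 0:
        return None, None
    result = stats.pearsonr(s, err, alternative="greater")
    return float(result.statistic), float(result.pvalue)


@dataclass
class EvalReport:
    mae: float
    rmse: float
    nmae: dict[str, float | None] = field(default_factory=dict)
    pearson_r: float | None = None
    one_tailed_p: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "MAE": self.mae,
            "RMSE": self.rmse,
            "NMAE": self.nmae,
            "pearson_r": self.pearson_r,
            "one_tailed_p": self.one_tailed_p,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_report(records: list[PredictionRecord]) -> EvalReport:
    """All statistics for one record set; enforces RMSE >= MAE."""
    m, r = mae(records), rmse(records)
    assert r >= m - 1e-12, "power-mean inequality violated (internal error)"
    pearson, p = uncertainty_error_correlation(records)
    return EvalReport(
        mae=m,
        rmse=r,
        nmae=nmae_by_subgroup(records),
        pearson_r=pearson,
        one_tailed_p=p,
        n=len(records),
    )


def summary_table(trial_records: dict[str, list[PredictionRecord]]) -> pd.DataFrame:
    """Per-trial MAE/RMSE columns plus their arithmetic mean.

    ``trial_records`` maps a trial label (e.g. "seed0") to its records;
    layout mirrors a per-method ablation results row.
    """
    rows = {}
    for label, records in trial_records.items():
        rows[label] = {"MAE": mae(records), "RMSE": rmse(records)}
    frame = pd.DataFrame(rows)
    frame["mean"] = frame.mean(axis=1)
    return frame
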