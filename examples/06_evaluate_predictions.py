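"""Evaluation statistics from a predictions table.

Builds a small set of prediction records by hand, computes MAE, RMSE and
the per-subgroup normalised MAE, and shows the round trip through the
predictions CSV format.
"""

import tempfile
from pathlib import Path

from sonarcount.annotations import PredictionRecord
from sonarcount.evaluate import build_report
from sonarcount.io import read_predictions, write_predictions

records = [
    PredictionRecord("f0", 10, 12.0, 0.1, "c<25"),
    PredictionRecord("f1", 30, 36.0, 0.5, "25<=c<50"),
    PredictionRecord("f2", 80, 71.0, 0.9, "50<=c<150"),
    PredictionRecord("f3", 200, 188.0, 1.4, "c>=150"),
    PredictionRecord("f4", 5, 9.0, 1.1, "Noise"),
]

path = Path(tempfile.mkdtemp()) / "predictions.csv"
write_predictions(records, path)
records = read_predictions(path)  # identical after the round trip

report = build_report(records)
print(f"MAE  {report.mae:.2f}")
print(f"RMSE {report.rmse:.2f}   (always >= MAE)")
for group, value in report.nmae.items():
    print(f"NMAE[{group}] = {value:.3f}")
# NMAE divides each group's error by its total true count, so sparse and
# dense strata become comparable on one scale.
print(f"uncertainty-error r = {report.pearson_r:.2f} (p = {report.one_tailed_p:.2f})")
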