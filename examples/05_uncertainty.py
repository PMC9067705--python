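"""Learned aleatoric uncertainty under heteroscedastic noise.

Generates the benchmark in its clutter regime (speckle noise proportional
to the fish count, so dense frames are genuinely harder), trains the
AU model (uni-task warm start, then the uncertainty-weighted loss), and
correlates the predicted log noise variance with the absolute count error
on the test split. Takes a couple of minutes on one CPU.
"""

from sonarcount.evaluate import mae, uncertainty_error_correlation
from sonarcount.train import (
    make_desk_benchmark,
    predict_records,
    train_uncertainty_model,
)

data = make_desk_benchmark(seed=1, clutter=True)
network, _ = train_uncertainty_model(data, seed=1, epochs=30)

records = predict_records(network, data.test)
r, p = uncertainty_error_correlation(records)
print(f"test MAE {mae(records):.2f}")
print(f"Pearson r(log sigma^2, |error|) = {r:.3f}  (one-tailed p = {p:.2g})")
worst = max(records, key=lambda q: q.log_sigma2)
best = min(records, key=lambda q: q.log_sigma2)
print(f"most uncertain frame: true {worst.count_true}, pred {worst.count_pred:.1f}, "
      f"log sigma^2 {worst.log_sigma2:.2f}")
print(f"least uncertain frame: true {best.count_true}, pred {best.count_pred:.1f}, "
      f"log sigma^2 {best.log_sigma2:.2f}")
# A positive r means the model flags its own hard frames: predictions with
# a high uncertainty score deserve a manual check.
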