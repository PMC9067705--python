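"""The standard desk-scale synthetic benchmark.

A fixed, CPU-affordable experimental setup used by the test suite, the
acceptance script and the examples: 300 training / 60 validation / 60 test
frames of 64x112 synthetic sonar imagery with counts in [0, 80], the tiny
backbone, and 30 training epochs. Three study protocols are provided:

* ``uni_task_benchmark`` — train the plain L1 counting model across seeds
  and compare its test MAE against the predict-the-training-mean baseline.
* ``uncertainty_benchmark`` — under the heteroscedastic-clutter generator
  regime, train the AU model (uni-task warm start, AU continuation) and
  measure the Pearson correlation between predicted log noise variance and
  absolute count error on the test split.
* ``ablation_smoke`` — run every one of the nine ablation configurations
  end-to-end for a couple of epochs (dependency chaining included) to
  verify each composition trains.
"""

from __future__ import annotations

import numpy as np

from .evaluate import mae as eval_mae, uncertainty_error_correlation
from .train import (
    desk_scale_train_config,
    make_desk_benchmark,
    mean_baseline_records,
    predict_records,
    run_ablation_suite,
    train_model,
    train_uncertainty_model,
)

__all__ = [
    "uni_task_benchmark",
    "uncertainty_benchmark",
    "ablation_smoke",
    "ALL_ABLATIONS",
]

ALL_ABLATIONS = ["i", "ii", "iii", "iv", "v", "vi", "vii", "viii", "ix"]


def uni_task_benchmark(seeds=(0, 1, 2), epochs: int = 30) -> dict:
    """Per-seed test MAE of the trained UT model vs the mean baseline."""
    test_maes, baseline_maes = [], []
    for seed in seeds:
        data = make_desk_benchmark(seed=seed, clutter=False)
        config = desk_scale_train_config("i", epochs=epochs)
        network, _ = train_model(config, data, seed=seed)
        test_maes.append(eval_mae(predict_records(network, data.test)))
        baseline_maes.append(eval_mae(mean_baseline_records(data.train, data.test)))
    return {
        "seeds": list(seeds),
        "test_mae": test_maes,
        "baseline_mae": baseline_maes,
        "median_test_mae": float(np.median(test_maes)),
        "median_baseline_mae": float(np.median(baseline_maes)),
    }


def uncertainty_benchmark(seeds=(0, 1, 2), epochs: int = 30) -> dict:
    """Uncertainty-error correlation of the AU model under clutter."""
    rs, maes = [], []
    for seed in seeds:
        data = make_desk_benchmark(seed=seed, clutter=True)
        network, _ = train_uncertainty_model(data, seed=seed, epochs=epochs)
        records = predict_records(network, data.test)
        r, _ = uncertainty_error_correlation(records)
        rs.append(r if r is not None else float("nan"))
        maes.append(eval_mae(records))
    return {
        "seeds": list(seeds),
        "pearson_r": rs,
        "test_mae": maes,
        "median_r": float(np.median(rs)),
    }


def ablation_smoke(seed: int = 0, epochs: int = 2):
    """All nine ablation configurations run end-to-end (short budget)."""
    data = make_desk_benchmark(seed=seed, clutter=False)
    table = run_ablation_suite(
        ALL_ABLATIONS,
        data,
        seeds=(seed,),
        base_config=desk_scale_train_config(epochs=epochs),
    )
    return table
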