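"""Named ablation experiments run as controlled comparisons.

Each experiment varies one architectural switch while every arm shares the
same data split, seed and training protocol:

* ``sliding_window``: the shifted masked attention layer versus a second
  unshifted, unmasked one (arms "No SW" / "With SW");
* ``downsampling_depth``: one, two or three stride-2 encoder stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import split_dataset
from .estimator import SWUNetSegmenter
from .losses_metrics import full_report

ABLATIONS = {
    "sliding_window": [("No SW", {"use_sliding_window": False}),
                       ("With SW", {"use_sliding_window": True})],
    "downsampling_depth": [("1", {"encoder_depth": 1}),
                           ("2", {"encoder_depth": 2}),
                           ("3", {"encoder_depth": 3})],
}


def run_ablation(name: str, X, y, base_params: dict | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Train one model per arm and report test Dice and H95 per arm.

    The train/val/test split is computed once from ``seed`` and reused by
    every arm.  Returns a DataFrame with columns ``arm, Dice, H95``.
    """
    if name not in ABLATIONS:
        raise ValueError(f"unknown ablation {name!r}; choose from {sorted(ABLATIONS)}")
    X = np.asarray(X)
    y = np.asarray(y)
    plan = split_dataset(list(range(len(X))), seed=seed)
    tr, te = plan.train_ids, plan.test_ids or plan.val_ids

    rows = []
    for arm, overrides in ABLATIONS[name]:
        params = dict(base_params or {})
        params.update(overrides)
        params.setdefault("seed", seed)
        est = SWUNetSegmenter(**params)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        reports = [
            full_report(p, t, classes=list(range(1, est.n_classes)))
            for p, t in zip(pred, y[te])
        ]
        dice = float(np.mean([r.aggregate()["Dice"] for r in reports]))
        h95s = [r.aggregate()["H95"] for r in reports if r.aggregate()["H95"] is not None]
        rows.append({
            "arm": arm,
            "Dice": dice,
            "H95": float(np.mean(h95s)) if h95s else None,
            "seed": seed,
            "n_train": len(tr),
            "n_test": len(te),
        })
    return pd.DataFrame(rows)
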