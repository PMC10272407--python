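"""Ablation grid on synthetic phantoms.

Trains the classifier under the M (manual threshold) / O (Otsu) /
R (radiomics branch) variants on a shared train/test split and reports
micro/macro AUC and accuracy per variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import FusionNoduleClassifier
from .phantoms import generate_dataset
from .pipeline import prepare_samples
from .train_eval import run_ablation

__all__ = ["ablation_table"]


def ablation_table(n: int = 60, epochs: int = 10, seed: int = 0,
                   input_side: int = 32, width_multiplier: float = 0.25,
                   test_fraction: float = 0.3) -> pd.DataFrame:
    """Run the three-variant grid on one seeded phantom cohort."""
    samples = generate_dataset(n, 0.5, seed=seed)
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * n))
    order = rng.permutation(n)
    test_ids = set(order[:n_test].tolist())

    prepared = {}

    def prepare(mode: str):
        if mode not in prepared:
            cubes, feats, labels, _ = prepare_samples(samples, threshold_mode=mode,
                                                      input_side=input_side)
            prepared[mode] = (cubes, feats, labels)
        cubes, feats, labels = prepared[mode]
        te = np.array(sorted(test_ids))
        tr = np.array(sorted(set(range(n)) - test_ids))
        return ((cubes[tr], feats[tr]), labels[tr], (cubes[te], feats[te]), labels[te])

    def train_and_score(train_x, train_y, test_x, use_radiomics: bool):
        est = FusionNoduleClassifier(
            input_side=input_side, width_multiplier=width_multiplier,
            radiomics_dim=train_x[1].shape[1], epochs=epochs,
            use_radiomics=use_radiomics, random_state=seed,
        )
        est.fit(train_x, train_y)
        return est.decision_function(test_x)

    return run_ablation(prepare, train_and_score)
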