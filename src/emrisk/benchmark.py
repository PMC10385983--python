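"""Seeded end-to-end benchmark runs at desk scale.

Convenience wrappers that chain simulation, cohort construction, encoding,
model training and attribution with one call, for calibration studies and
reproducibility checks.  Model sizes here are deliberately small (the
benchmark cohorts have vocabularies of under a hundred codes, so a 32-unit
single-layer network is already past the data's capacity ceiling).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import attribution, encoding, models
from .cohort import CohortConfig, build_samples, split_samples
from .simulate import SimConfig, generate_cohort

BENCH_MODEL = dict(embed_dim=32, hidden_size=32, n_layers=1, dropout=0.2,
                   learning_rate=0.005, batch_size=64, max_epochs=30,
                   patience=5)


def build_packed_cohort(sim_config: SimConfig,
                        cohort_config: CohortConfig | None = None):
    """Simulate, build samples, split, build the vocabulary, pack.

    Returns a dict with the vocabulary, per-fold packed arrays, the pooled
    sample set and its patient ids.
    """
    cohort_config = cohort_config or CohortConfig(seed=sim_config.seed + 1)
    records = generate_cohort(sim_config)
    samples = build_samples(records, cohort_config)
    folds = split_samples(samples, cohort_config)
    vocab = encoding.build_vocabulary(folds[0])

    def pack(fold):
        X, y = [], []
        for s in fold:
            try:
                X.append(encoding.pack_sample(s, vocab))
            except ValueError:
                continue
            y.append(s.y)
        return X, np.asarray(y)

    packed = [pack(f) for f in folds]
    X_all, y_all, pids = [], [], []
    for fold in folds:
        for s in fold:
            try:
                X_all.append(encoding.pack_sample(s, vocab))
            except ValueError:
                continue
            y_all.append(s.y)
            pids.append(s.patient_id)
    return {
        "vocab": vocab,
        "train": packed[0], "validation": packed[1], "test": packed[2],
        "X": X_all, "y": np.asarray(y_all), "patient_ids": pids,
    }


def make_bench_lstm(vocab_size: int, seed: int,
                    **overrides) -> models.LSTMRiskClassifier:
    kw = dict(BENCH_MODEL)
    kw.update(overrides)
    return models.LSTMRiskClassifier(vocab_size=vocab_size, seed=seed, **kw)


def attribution_benchmark(sim_config: SimConfig,
                          cohort_config: CohortConfig | None = None,
                          method: str = "benjamini_hochberg",
                          **model_overrides) -> pd.DataFrame:
    """Cross-fitted RC table for one synthetic cohort."""
    data = build_packed_cohort(sim_config, cohort_config)
    vocab = data["vocab"]
    cm = attribution.crossfit_contribution_matrix(
        lambda s: make_bench_lstm(vocab.n_tokens, s, **model_overrides),
        data["X"], data["y"], data["patient_ids"], vocab,
        seed=sim_config.seed)
    table = attribution.rc_table(cm, method=method)
    prevalence = cm.prevalence()
    return table.join(prevalence.rename("prevalence"))


def auc_benchmark(sim_config: SimConfig,
                  cohort_config: CohortConfig | None = None,
                  n_repeats: int = 10, base_seed: int = 0,
                  **model_overrides):
    """Repeat-evaluated AUROC of the recurrent model and the bag-of-codes
    logistic baseline on fixed folds of one synthetic cohort."""
    data = build_packed_cohort(sim_config, cohort_config)
    vocab = data["vocab"]
    folds = (data["train"], data["validation"], data["test"])
    lstm = models.repeat_evaluate(
        lambda s: make_bench_lstm(vocab.n_tokens, s, **model_overrides),
        folds, n_repeats=n_repeats, base_seed=base_seed)
    lr = models.repeat_evaluate(
        lambda s: models.BagOfCodesLogisticClassifier(
            vocab_size=vocab.n_tokens, seed=s),
        folds, n_repeats=n_repeats, base_seed=base_seed)
    return lstm, lr
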