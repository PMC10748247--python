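"""Shared fixtures: seeded synthetic data and one trained classifier.

The expensive experiment (corpus generation + CNN-LSTM training) runs once
per session and is shared by the model tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import scratchkit as sk

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")
from scratchkit.windowing import stack_actions

EXPERIMENT_SEED = 42
N_REPS = 20
HOLDOUT_REPS = 4


@pytest.fixture(scope="session")
def synth_cfg() -> sk.SynthConfig:
    return sk.SynthConfig(seed=EXPERIMENT_SEED)


def _windows_for(rec, lab):
    pc = sk.process_recording(rec)
    pc_c, lab_c = sk.extract_center(pc, lab)
    return sk.make_windows(pc_c, lab_c)


@pytest.fixture(scope="session")
def experiment(synth_cfg):
    """Corpus -> windows -> trained model -> held-out predictions.

    Catalog of 12 action specs (9 action types, intensive variants for the
    scratch/rub classes), 20 repetitions each; the last 4 repetitions of
    every action are held out from training.
    """
    catalog = sk.default_catalog()
    corpus = sk.generate_training_corpus(catalog, N_REPS, synth_cfg)
    sets = [_windows_for(rec, lab) for rec, lab in corpus]
    train_sets, hold_sets = [], []
    for i, ws in enumerate(sets):
        rep = i % N_REPS
        (hold_sets if rep >= N_REPS - HOLDOUT_REPS else train_sets).append(ws)
    train_set = stack_actions(train_sets)
    hold_set = stack_actions(hold_sets)

    mcfg = sk.ModelConfig(seed=7, epochs=30)
    trained = sk.train(sk.build_model(mcfg), train_set, mcfg)
    pred = sk.predict(trained, hold_set)
    return {
        "catalog": catalog,
        "train_set": train_set,
        "holdout_set": hold_set,
        "model": trained,
        "holdout_pred": pred,
    }


@pytest.fixture(scope="session")
def session_30min(synth_cfg):
    rec, lab = sk.session_preset_30min(synth_cfg)
    return rec, lab


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
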