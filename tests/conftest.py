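"""Shared fixtures: small synthetic datasets and pipeline helpers.

Everything is generated programmatically at test time; problem sizes are
deliberately small (2 subjects, a handful of trials, 1-layer autoencoder)
so the suite runs on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import eegdaae as E
from eegdaae.daae import DaaeConfig


@pytest.fixture(scope="session")
def layout():
    return E.project_montage()


@pytest.fixture(scope="session")
def two_profiles_separated():
    """Two subjects with strong spectral separation and mild session drift."""
    return E.make_profiles(2, seed=11, separation=1.5, session_drift=0.05)


@pytest.fixture(scope="session")
def one_trial(two_profiles_separated):
    return E.simulate_trial(two_profiles_separated[0], 1, "resting", 0, seed=3)


def run_identification(separation: float, seed: int, n_trials: int = 6,
                       epochs: int = 4, scheme: str = "softmin",
                       classifiers: tuple[str, ...] = ("svm",),
                       session_drift: float = 0.05) -> dict:
    """Scaled-down end-to-end run: 2 subjects -> pairwise accuracy + AUC.

    Returns {"auc": {kind: auc}, "accuracy": {kind: cube-level accuracy}}
    for a 2-subject longitudinal identification task.
    """
    from sklearn.metrics import accuracy_score

    from eegdaae.identify import make_classifier, feature_columns

    profiles = E.make_profiles(2, seed=seed, separation=separation,
                               session_drift=session_drift)
    trials = E.simulate_dataset(profiles, seed=seed,
                                trials_per_session={"auditory": n_trials})
    cfg = E.ExperimentConfig(
        scheme=scheme, stimulus="auditory", band="Alpha",
        daae=DaaeConfig(epochs=epochs, batch_size=8, learning_rate=3e-3),
        classifiers=classifiers, seed=seed,
    )
    table = E.build_feature_table(trials, cfg)
    train, test = E.longitudinal_split(table)
    out = {"auc": {}, "accuracy": {}}
    for kind in classifiers:
        out["auc"][kind] = E.fit_and_score(train, test, kind, seed=seed)
        clf = make_classifier(kind, seed=seed)
        cols = feature_columns(train)
        clf.fit(train[cols].to_numpy(), train["subject"].to_numpy())
        pred = clf.predict(test[cols].to_numpy())
        out["accuracy"][kind] = float(accuracy_score(test["subject"], pred))
    return out


def gaussian_feature_table(n_subjects: int = 3, n_trials: int = 6,
                           n_segments: int = 3, n_features: int = 8,
                           separation: float = 3.0, drift: float = 0.0,
                           seed: int = 0) -> pd.DataFrame:
    """Feature table with Gaussian class clusters (no pipeline run needed).

    Subject means are drawn N(0, separation^2 I); rows are unit-variance
    around the mean; session 2 means are shifted by ``drift`` in a random
    direction (the cross-session degradation mechanism).
    """
    rng = np.random.default_rng(seed)
    means = separation * rng.standard_normal((n_subjects, n_features))
    shift = rng.standard_normal((n_subjects, n_features))
    shift *= drift / (np.linalg.norm(shift, axis=1, keepdims=True) + 1e-12)
    rows = []
    for s in range(n_subjects):
        for session in (1, 2):
            mu = means[s] + (shift[s] if session == 2 else 0.0)
            for trial in range(n_trials):
                for seg in range(n_segments):
                    vec = mu + rng.standard_normal(n_features)
                    rows.append({
                        "subject": f"sb{s + 1:02d}", "session": session,
                        "stimulus": "resting", "band": "Alpha",
                        "scheme": "uniform", "trial": trial, "segment": seg,
                        **{f"f{k}": float(v) for k, v in enumerate(vec)},
                    })
    return pd.DataFrame(rows)
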