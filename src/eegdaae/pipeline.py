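"""End-to-end experiment orchestration.

One experiment configuration fixes a (scheme, stimulus, band) cell of the
full factorial design — 2 weighting schemes x 3 stimuli x 8 bands = 48
configurations, one autoencoder each — plus the autoencoder
hyperparameters, the softmin sensitivity beta, and the classifier
families to evaluate. ``run_experiment`` executes the whole chain

    preprocess -> target-domain generation -> data cubes ->
    autoencoder training (session 1 only) -> latent features ->
    longitudinal identification

and emits an evaluation report. A single global seed is fanned out to
stages through a stable hash of the stage name, so any stage can be
re-run independently with the same stream.
"""

from __future__ import annotations

import itertools
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .daae import DaaeConfig, build_daae, encode, aggregate_features, train_daae
from .domaingen import DEFAULT_BETA, TrialSet, make_targets
from .identify import (CLASSIFIER_KINDS, fit_and_score, identifiability,
                       longitudinal_split, pairwise_matrix, write_report)
from .preprocess import canonical_bands, preprocess_trial
from .synthdata import RawTrial, STIMULI
from .topocube import build_stream, partition_cubes, project_montage

__all__ = [
    "ExperimentConfig",
    "enumerate_configs",
    "stage_seed",
    "build_feature_table",
    "run_experiment",
]

logger = logging.getLogger("eegdaae")

SCHEMES = ("uniform", "softmin")
BAND_NAMES = tuple(b.name for b in canonical_bands())


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the factorial design plus model/evaluation settings."""

    scheme: str = "uniform"
    stimulus: str = "resting"
    band: str = "Alpha"
    beta: float = DEFAULT_BETA
    daae: DaaeConfig = field(default_factory=DaaeConfig)
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    classifier_params: dict = field(default_factory=dict)
    seed: int = 0
    pairwise: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.stimulus not in STIMULI:
            raise ValueError(f"stimulus must be one of {STIMULI}, got {self.stimulus!r}")
        if self.band not in BAND_NAMES:
            raise ValueError(f"band must be one of {BAND_NAMES}, got {self.band!r}")
        for kind in self.classifiers:
            if kind not in CLASSIFIER_KINDS:
                raise ValueError(f"unknown classifier kind {kind!r}")


def enumerate_configs(schemes=SCHEMES, stimuli=STIMULI, bands=BAND_NAMES,
                      **overrides) -> list[ExperimentConfig]:
    """Cartesian product in deterministic (scheme, stimulus, band) order."""
    schemes, stimuli, bands = tuple(schemes), tuple(stimuli), tuple(bands)
    if not (schemes and stimuli and bands):
        raise ValueError("schemes, stimuli and bands must all be nonempty")
    return [
        ExperimentConfig(scheme=s, stimulus=st, band=b, **overrides)
        for s, st, b in itertools.product(schemes, stimuli, bands)
    ]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed (stable stage-name hash)."""
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


def _group_trials(trials: list[RawTrial]) -> dict[tuple[str, int], list[RawTrial]]:
    groups: dict[tuple[str, int], list[RawTrial]] = {}
    for tr in trials:
        groups.setdefault((tr.subject_id, tr.session), []).append(tr)
    return {k: sorted(v, key=lambda t: t.trial_index) for k, v in sorted(groups.items())}


def build_feature_table(trials: list[RawTrial], cfg: ExperimentConfig) -> pd.DataFrame:
    """Run preprocessing through latent-feature extraction for one config.

    The autoencoder is trained exclusively on session-1 (source, target)
    cube pairs; features are then extracted for every cube of both
    sessions. Pairing rule: with the uniform scheme, the source cube of
    trial i, segment j pairs with the shared target's segment j; with
    softmin, source cube (i, j) pairs with target cube (i, j).
    """
    stim_trials = [t for t in trials if t.stimulus == cfg.stimulus]
    if not stim_trials:
        raise ValueError(f"no trials with stimulus {cfg.stimulus!r}")
    layout = project_montage()
    bands = [b for b in canonical_bands() if b.name == cfg.band]

    logger.info("stage=preprocess band=%s n_trials=%d", cfg.band, len(stim_trials))
    groups = _group_trials(stim_trials)

    rows = []
    train_sources, train_targets = [], []
    all_cubes: list[tuple[dict, np.ndarray]] = []
    for (subject, session), group in groups.items():
        band_trials = [preprocess_trial(t, bands)[cfg.band] for t in group]
        ts = TrialSet.from_trials(band_trials, subject_id=subject, session=session,
                                  stimulus=cfg.stimulus, band=cfg.band)
        targets = make_targets(ts, cfg.scheme, cfg.beta)

        target_cube_sets = []
        for tgt in targets.targets:  # (C, T) target signals
            stream = build_stream(tgt, layout)
            target_cube_sets.append([c.voxels for c in partition_cubes(stream)])

        for i, trial in enumerate(group):
            src_stream = build_stream(ts.trials[i], layout, provenance={
                "subject": subject, "session": session,
                "stimulus": cfg.stimulus, "trial": trial.trial_index,
            })
            src_cubes = partition_cubes(src_stream)
            tgt_cubes = target_cube_sets[0] if targets.scheme == "uniform" \
                else target_cube_sets[i]
            for j, cube in enumerate(src_cubes):
                meta = {"subject": subject, "session": session,
                        "stimulus": cfg.stimulus, "band": cfg.band,
                        "scheme": cfg.scheme, "trial": trial.trial_index,
                        "segment": j}
                all_cubes.append((meta, cube.voxels))
                if session == 1:
                    train_sources.append(cube.voxels)
                    train_targets.append(tgt_cubes[j])

    logger.info("stage=daae train_pairs=%d", len(train_sources))
    daae_cfg = replace(cfg.daae, seed=stage_seed(cfg.seed, "daae"))
    model = build_daae(daae_cfg)
    trained = train_daae(model, np.stack(train_sources), np.stack(train_targets), daae_cfg)

    logger.info("stage=features n_cubes=%d", len(all_cubes))
    cubes = np.stack([c for _, c in all_cubes])
    feats = aggregate_features(encode(trained, cubes))
    for (meta, _), vec in zip(all_cubes, feats):
        rows.append({**meta, **{f"f{k}": float(v) for k, v in enumerate(vec)}})
    table = pd.DataFrame(rows)
    table.attrs["loss_history"] = trained.loss_history
    table.attrs["initial_loss"] = trained.initial_loss
    return table


def run_experiment(cfg: ExperimentConfig, trials: list[RawTrial],
                   outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline for one configuration and report results."""
    sessions = {t.session for t in trials if t.stimulus == cfg.stimulus}
    if not {1, 2} <= sessions:
        raise ValueError(
            f"stage identify requires both sessions; got {sorted(sessions)}"
        )
    table = build_feature_table(trials, cfg)
    train, test = longitudinal_split(table)

    logger.info("stage=identify classifiers=%s", ",".join(cfg.classifiers))
    auc = {}
    for kind in cfg.classifiers:
        params = cfg.classifier_params.get(kind)
        auc[kind] = fit_and_score(train, test, kind, params,
                                  seed=stage_seed(cfg.seed, f"clf-{kind}"))

    report: dict = {
        "config": {**asdict(cfg), "daae": asdict(cfg.daae)},
        "version": __version__,
        "seed": cfg.seed,
        "n_train_rows": int(len(train)),
        "n_test_rows": int(len(test)),
        "daae_initial_loss": table.attrs["initial_loss"],
        "daae_loss_history": table.attrs["loss_history"],
        "auc": auc,
    }
    matrices = {}
    if cfg.pairwise and table["subject"].nunique() >= 2:
        kind = cfg.classifiers[0]
        mat = pairwise_matrix(table, kind, cfg.classifier_params.get(kind),
                              seed=stage_seed(cfg.seed, "pairwise"))
        scores, ranked = identifiability(mat)
        matrices["pairwise"] = mat
        report["identifiability"] = {s: float(scores[s]) for s in scores.index}
        report["least_identifiable"] = ranked[:2]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "features.csv", index=False)
        write_report(report, outdir, matrices=matrices)
    return report
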