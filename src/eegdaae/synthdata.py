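"""Synthetic multi-subject, multi-session EEG generation.

The generator emulates the geometry of a two-session biometric EEG study:
7 subjects, 24 channels (10-20 layout) sampled at 1 kHz, 3 s trials,
35 resting / 10 auditory / 10 cognitive trials per subject per session.
Each subject carries a distinct spectral signature (per-band oscillation
amplitudes and peak frequencies); session 2 perturbs amplitudes and
frequencies by a configurable drift fraction so that cross-session
evaluation faces a genuine domain shift.

The signal model is a sum of

* pink (1/f) background noise,
* per-band sinusoids at the subject's peak frequencies with random phase
  per trial and channel,
* a Gaussian-windowed evoked burst at t = 0.5 s for auditory/cognitive
  stimuli (stimulus-locked, so trial-weighted referencing has a real
  evoked component to emphasize), and
* 60 Hz line interference plus harmonics at 120/180/240 Hz,

so every preprocessing stage downstream has something real to remove.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "CHANNELS_24",
    "STIMULI",
    "TRIALS_PER_SESSION",
    "SubjectProfile",
    "RawTrial",
    "make_profiles",
    "simulate_trial",
    "simulate_dataset",
    "save_dataset",
    "load_dataset",
    "save_dataset_csv",
]

#: Fixed 24-electrode subset of the 10-20 / 10-10 nomenclature used throughout.
CHANNELS_24: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4",
)

STIMULI: tuple[str, ...] = ("resting", "auditory", "cognitive")

#: Study geometry: trials per subject per session for each stimulus.
TRIALS_PER_SESSION: dict[str, int] = {"resting": 35, "auditory": 10, "cognitive": 10}

FS_HZ = 1000.0
N_SAMPLES = 3000

# Rhythm bands the profiles are parameterized over (generation-side only;
# the analysis band bank lives in eegdaae.preprocess).
_PROFILE_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 32.0),
    "gamma": (32.0, 80.0),
}

_BASE_POWER = {"delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 4.0, "gamma": 2.0}

LINE_FREQ_HZ = 60.0
LINE_AMPLITUDE_UV = 5.0
EVOKED_LATENCY_S = 0.5
EVOKED_WIDTH_S = 0.08
EVOKED_AMPLITUDE_UV = 12.0


@dataclass(frozen=True)
class SubjectProfile:
    """Spectral signature of one synthetic subject.

    Parameters
    ----------
    subject_id
        Unique label, e.g. ``"sb01"``.
    band_power
        Band name -> per-channel oscillation amplitude (uV), shape (24,).
    peak_freqs
        Band name -> oscillation peak frequency (Hz), inside the band.
    noise_scale
        Std of the pink background noise (uV).
    session_drift
        Fractional amplitude/frequency perturbation applied in session 2,
        in [0, 1).
    """

    subject_id: str
    band_power: dict[str, np.ndarray]
    peak_freqs: dict[str, float]
    noise_scale: float = 3.0
    session_drift: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.session_drift < 1:
            raise ValueError(f"session_drift must be in [0, 1), got {self.session_drift}")
        for band, power in self.band_power.items():
            if np.any(np.asarray(power) < 0):
                raise ValueError(f"negative band_power for band {band!r}")
        for band, f in self.peak_freqs.items():
            lo, hi = _PROFILE_BANDS[band]
            if not lo <= f <= hi:
                raise ValueError(f"peak_freqs[{band!r}]={f} outside [{lo}, {hi}] Hz")


@dataclass(frozen=True)
class RawTrial:
    """One 3-second, 24-channel EEG trial at 1 kHz."""

    subject_id: str
    session: int
    stimulus: str
    trial_index: int
    data: np.ndarray = field(repr=False)  # (24, 3000) uV
    fs: float = FS_HZ
    channel_names: tuple[str, ...] = CHANNELS_24

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.channel_names), N_SAMPLES):
            raise ValueError(
                f"trial data must be {(len(self.channel_names), N_SAMPLES)}, "
                f"got {self.data.shape}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")


def make_profiles(
    n_subjects: int,
    seed: int,
    separation: float = 1.0,
    noise_scale: float = 3.0,
    session_drift: float = 0.05,
) -> list[SubjectProfile]:
    """Draw ``n_subjects`` subject profiles with distinct spectral signatures.

    ``separation`` scales the inter-subject spread of band amplitudes and
    peak frequencies around the population means; 0 makes all subjects
    spectrally identical (useful as a chance-level control). Subjects
    occupy evenly spaced slots of the spread (randomly permuted per band),
    so nonzero separation guarantees pairwise-distinct signatures in every
    band rather than merely making them likely.
    """
    if n_subjects < 2:
        raise ValueError(f"n_subjects must be >= 2, got {n_subjects}")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    n_ch = len(CHANNELS_24)
    gain_slots = np.linspace(-0.5, 0.5, n_subjects)
    # frequency offsets saturate at +-0.6 of the half-bandwidth so peaks stay
    # strictly inside the band (filter-edge rolloff would otherwise dominate)
    freq_slots = np.linspace(-0.6, 0.6, n_subjects) * min(separation, 1.0)
    gain_perm = {b: rng.permutation(n_subjects) for b in _PROFILE_BANDS}
    freq_perm = {b: rng.permutation(n_subjects) for b in _PROFILE_BANDS}
    profiles = []
    for k in range(n_subjects):
        band_power: dict[str, np.ndarray] = {}
        peak_freqs: dict[str, float] = {}
        for band, (lo, hi) in _PROFILE_BANDS.items():
            base = _BASE_POWER[band]
            # slotted subject factor plus a random channel topography
            subject_gain = 1.0 + separation * gain_slots[gain_perm[band][k]]
            topography = 1.0 + separation * 0.4 * rng.standard_normal(n_ch)
            band_power[band] = np.clip(base * subject_gain * topography, 0.0, None)
            center, half = (lo + hi) / 2, (hi - lo) / 2
            peak_freqs[band] = float(center + freq_slots[freq_perm[band][k]] * half)
        profiles.append(
            SubjectProfile(
                subject_id=f"sb{k + 1:02d}",
                band_power=band_power,
                peak_freqs=peak_freqs,
                noise_scale=noise_scale,
                session_drift=session_drift,
            )
        )
    return profiles


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, scale: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit-std per channel before scaling."""
    if scale == 0:
        return np.zeros((n_ch, n_samp))
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / FS_HZ)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    pink = np.fft.irfft(spec * shaping, n=n_samp, axis=1)
    pink /= pink.std(axis=1, keepdims=True) + 1e-12
    return scale * pink


def simulate_trial(
    profile: SubjectProfile,
    session: int,
    stimulus: str,
    trial_index: int,
    seed: int,
    line_amplitude: float = LINE_AMPLITUDE_UV,
) -> RawTrial:
    """Simulate one trial for ``profile`` under the stated signal model.

    Deterministic given all arguments: the per-trial RNG stream is derived
    from ``(seed, subject, session, stimulus, trial_index)``.
    """
    if session not in (1, 2):
        raise ValueError(f"session must be 1 or 2, got {session}")
    if stimulus not in STIMULI:
        raise ValueError(f"unknown stimulus {stimulus!r}; expected one of {STIMULI}")

    subject_key = zlib.crc32(profile.subject_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(
        [seed, subject_key, session, STIMULI.index(stimulus), trial_index]
    )
    n_ch = len(CHANNELS_24)
    t = np.arange(N_SAMPLES) / FS_HZ

    drift = profile.session_drift if session == 2 else 0.0
    amp_gain = 1.0 + drift
    freq_gain = 1.0 + 0.5 * drift

    data = _pink_noise(rng, n_ch, N_SAMPLES, profile.noise_scale)

    for band, power in profile.band_power.items():
        f = profile.peak_freqs[band] * freq_gain
        phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
        data += (amp_gain * power)[:, None] * np.sin(2 * np.pi * f * t[None, :] + phase)

    if stimulus in ("auditory", "cognitive"):
        # stimulus-locked evoked burst: fixed latency, subject-independent
        # carrier, amplitude modulated by the subject's alpha topography
        carrier_hz = 7.0 if stimulus == "cognitive" else 10.0
        window = np.exp(-0.5 * ((t - EVOKED_LATENCY_S) / EVOKED_WIDTH_S) ** 2)
        topo = 0.5 + 0.5 * profile.band_power["alpha"] / (
            profile.band_power["alpha"].max() + 1e-12
        )
        data += EVOKED_AMPLITUDE_UV * topo[:, None] * (
            window * np.sin(2 * np.pi * carrier_hz * (t - EVOKED_LATENCY_S))
        )[None, :]

    if line_amplitude > 0:
        for k, harm in enumerate((1, 2, 3, 4)):
            data += (line_amplitude / (k + 1)) * np.sin(
                2 * np.pi * LINE_FREQ_HZ * harm * t
            )[None, :]

    return RawTrial(
        subject_id=profile.subject_id,
        session=session,
        stimulus=stimulus,
        trial_index=trial_index,
        data=data,
    )


def simulate_dataset(
    profiles: Iterable[SubjectProfile],
    seed: int,
    trials_per_session: dict[str, int] | None = None,
) -> list[RawTrial]:
    """Simulate the full study: both sessions, all stimuli, for each profile.

    Defaults reproduce the study geometry: 35 resting + 10 auditory +
    10 cognitive trials per subject per session (so 7 subjects give
    7 x 2 x 55 = 770 trials).
    """
    counts = dict(TRIALS_PER_SESSION if trials_per_session is None else trials_per_session)
    trials: list[RawTrial] = []
    for profile in profiles:
        for session in (1, 2):
            for stimulus, n in counts.items():
                for idx in range(n):
                    trials.append(simulate_trial(profile, session, stimulus, idx, seed))
    return trials


# ---------------------------------------------------------------------------
# Trial archive: HDF5 container plus a delimited-text fallback for inspection.
# ---------------------------------------------------------------------------

def save_dataset(trials: Iterable[RawTrial], path: str | Path) -> None:
    """Write trials to one HDF5 file, groups /<subject>/s<session>/<stimulus>."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["fs"] = FS_HZ
        f.attrs["channel_names"] = list(CHANNELS_24)
        for tr in trials:
            grp = f.require_group(f"{tr.subject_id}/s{tr.session}/{tr.stimulus}")
            grp.create_dataset(f"trial{tr.trial_index:03d}", data=tr.data)


def load_dataset(path: str | Path) -> list[RawTrial]:
    import h5py

    trials: list[RawTrial] = []
    with h5py.File(path, "r") as f:
        for subject_id in sorted(f.keys()):
            for sess_key in sorted(f[subject_id].keys()):
                session = int(sess_key[1:])
                for stimulus in sorted(f[subject_id][sess_key].keys()):
                    grp = f[subject_id][sess_key][stimulus]
                    for name in sorted(grp.keys()):
                        trials.append(
                            RawTrial(
                                subject_id=subject_id,
                                session=session,
                                stimulus=stimulus,
                                trial_index=int(name[5:]),
                                data=grp[name][()],
                            )
                        )
    return trials


def save_dataset_csv(trials: Iterable[RawTrial], outdir: str | Path) -> None:
    """Plain-text fallback: one CSV per trial, channels as columns."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tr in trials:
        name = f"{tr.subject_id}_s{tr.session}_{tr.stimulus}_{tr.trial_index:03d}.csv"
        with open(outdir / name, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(tr.channel_names)
            writer.writerows(tr.data.T)
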