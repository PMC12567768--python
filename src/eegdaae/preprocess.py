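"""Line-noise removal, drift removal, and the eight-band filter bank.

All filters are zero-phase (forward-backward, :func:`scipy.signal.sosfiltfilt`)
and applied per channel independently:

* notch at 60 Hz and harmonics (120/180/240 Hz), IIR notch of quality
  factor 30 as second-order sections;
* 0.5 Hz high-pass, 4th-order Butterworth;
* band bank: Delta 1-4, Theta 4-8, Alpha 8-13, Beta 13-32, De2Be 1-32,
  Th2Be 4-32, Gamma 32-125, and All (>1 Hz high-pass only), 4th-order
  Butterworth band-passes.

Filter family and orders are engineering choices (standard EEG practice,
stable at fs = 1 kHz); the band edges are part of the analysis design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy import signal

from .synthdata import RawTrial

__all__ = [
    "BandDefinition",
    "canonical_bands",
    "load_bands",
    "notch_filter",
    "highpass_filter",
    "band_filter_bank",
    "preprocess_trial",
]

DEFAULT_NOTCH_FREQS = (60.0, 120.0, 180.0, 240.0)
NOTCH_Q = 30.0
BUTTER_ORDER = 4


@dataclass(frozen=True)
class BandDefinition:
    """One analysis band; ``high=None`` means high-pass only."""

    name: str
    low: float | None
    high: float | None

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and not self.low < self.high:
            raise ValueError(f"band {self.name!r}: low must be < high")


def load_bands(path: str | Path | None = None) -> list[BandDefinition]:
    """Load a band table from YAML (the shipped canonical table by default)."""
    if path is None:
        text = resources.files("eegdaae.data").joinpath("bands.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return [BandDefinition(b["name"], b["low"], b["high"]) for b in raw["bands"]]


def canonical_bands() -> list[BandDefinition]:
    """The eight canonical analysis bands."""
    return load_bands()


def _apply_sos(trial: RawTrial, sos: np.ndarray) -> RawTrial:
    filtered = signal.sosfiltfilt(sos, trial.data, axis=1)
    return replace(trial, data=np.ascontiguousarray(filtered))


def notch_filter(trial: RawTrial, freqs=DEFAULT_NOTCH_FREQS, q: float = NOTCH_Q) -> RawTrial:
    """Zero-phase IIR notch at each frequency in ``freqs``."""
    nyq = trial.fs / 2
    out = trial
    for f0 in freqs:
        if not 0 < f0 < nyq:
            raise ValueError(f"notch frequency {f0} Hz not below Nyquist ({nyq} Hz)")
        b, a = signal.iirnotch(f0, q, fs=trial.fs)
        sos = signal.tf2sos(b, a)
        out = _apply_sos(out, sos)
    return out


def highpass_filter(trial: RawTrial, cutoff: float = 0.5) -> RawTrial:
    """Zero-phase Butterworth high-pass (drift/DC removal)."""
    if not 0 < cutoff < trial.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist)")
    sos = signal.butter(BUTTER_ORDER, cutoff, btype="highpass", fs=trial.fs, output="sos")
    return _apply_sos(trial, sos)


def _band_sos(band: BandDefinition, fs: float) -> np.ndarray:
    nyq = fs / 2
    if band.high is not None and band.high >= nyq:
        raise ValueError(f"band {band.name!r}: high edge {band.high} Hz >= Nyquist")
    if band.low is None:
        raise ValueError(f"band {band.name!r}: low edge required")
    if band.high is None:
        return signal.butter(BUTTER_ORDER, band.low, btype="highpass", fs=fs, output="sos")
    return signal.butter(
        BUTTER_ORDER, [band.low, band.high], btype="bandpass", fs=fs, output="sos"
    )


def band_filter_bank(
    trial: RawTrial, bands: list[BandDefinition] | None = None
) -> dict[str, RawTrial]:
    """Split one trial into band-limited copies, one per band definition."""
    if bands is None:
        bands = canonical_bands()
    if not bands:
        raise ValueError("band list must be nonempty")
    return {band.name: _apply_sos(trial, _band_sos(band, trial.fs)) for band in bands}


def preprocess_trial(
    trial: RawTrial,
    bands: list[BandDefinition] | None = None,
    notch_freqs=DEFAULT_NOTCH_FREQS,
    hp_cutoff: float = 0.5,
) -> dict[str, RawTrial]:
    """Full chain: notch -> 0.5 Hz high-pass -> band bank."""
    return band_filter_bank(highpass_filter(notch_filter(trial, notch_freqs), hp_cutoff), bands)
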