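"""Resampling, band-pass filtering, transient trimming and epoching.

The pipeline mirrors a conventional resting-state EEG preparation:

1. polyphase resampling to a common rate (rational ratio, Kaiser-window
   anti-aliasing FIR with cutoff and transition width given as
   fractions of the output Nyquist frequency);
2. causal FIR band-pass (0.5-45 Hz by default) whose order equals the
   number of samples in a 3 s window, followed by removal of the first
   3 s so the filter transient never reaches the features;
3. segmentation into contiguous, non-overlapping fixed-length epochs.

An ``artifact_hook`` slot accepts any callable Recording -> Recording
(e.g. an ICA-based cleaner); the default is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

import numpy as np
from scipy import signal

from .recording import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocConfig",
    "EpochTensor",
    "resample_polyphase",
    "bandpass_trim",
    "epoch",
    "preprocess",
]


class TooShortError(ValueError):
    """Recording too short for the requested trim/epoching."""


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing parameters (times in seconds, frequencies in Hz)."""

    target_fs: float = 200.0
    band: tuple[float, float] = (0.5, 45.0)
    fir_order_window: float = 3.0  # FIR order = this window's sample count
    transient_trim: float = 3.0
    epoch_len: float = 3.0
    kaiser_fc_frac: float = 0.9  # anti-aliasing cutoff, fraction of Nyquist
    kaiser_df_frac: float = 0.2  # transition width, fraction of Nyquist
    kaiser_atten_db: float = 60.0
    artifact_hook: Callable[[Recording], Recording] | None = None

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.target_fs / 2):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        if self.epoch_len <= 0:
            raise ValueError("epoch length must be positive")


@dataclass
class EpochTensor:
    """Per-subject stack of fixed-length epochs (epoch x channel x sample)."""

    subject_id: str
    group: str
    dataset_id: str
    fs: float
    channel_names: list[str]
    epochs: np.ndarray

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be epoch x channel x sample")
        if self.epochs.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def resample_ratio(fs_in: float, fs_out: float, max_denominator: int = 1000):
    """Reduced (p, q) with fs_out/fs_in ~= p/q.

    Exact for rational rate pairs (all the clinical rates of interest);
    otherwise the best rational approximation with denominator <= 1000
    is used and logged.
    """
    exact = Fraction(fs_out) / Fraction(fs_in)
    frac = exact.limit_denominator(max_denominator)
    if frac != exact:
        logger.warning(
            "resampling ratio %s/%s approximated as %s", fs_out, fs_in, frac
        )
    return frac.numerator, frac.denominator


def resample_polyphase(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling with a Kaiser anti-aliasing filter.

    Cutoff 0.9 and transition width 0.2 of the limiting Nyquist
    frequency (min of input/output rates), 60 dB stopband.
    """
    cfg = PreprocConfig(target_fs=target_fs)
    p, q = resample_ratio(rec.fs, target_fs)
    if p == q:
        return rec.with_data(rec.data.copy())
    fs_up = rec.fs * p
    f_nyq = min(rec.fs, target_fs) / 2.0
    cutoff = cfg.kaiser_fc_frac * f_nyq
    width = cfg.kaiser_df_frac * f_nyq
    numtaps, beta = signal.kaiserord(cfg.kaiser_atten_db, 2.0 * width / fs_up)
    numtaps |= 1  # odd length: symmetric type-I low-pass
    # resample_poly scales an array window by p itself, so pass unit-gain taps
    h = signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs_up)
    out = signal.resample_poly(rec.data, p, q, axis=1, window=h)
    return rec.with_data(out, fs=float(target_fs))


def bandpass_trim(rec: Recording, cfg: PreprocConfig = PreprocConfig()) -> Recording:
    """Causal FIR band-pass, then drop the leading transient.

    The filter order is the sample count of ``cfg.fir_order_window``
    seconds (Hamming windowed-sinc design); the first
    ``cfg.transient_trim`` seconds of the output are discarded.
    """
    if rec.fs != cfg.target_fs:
        raise ValueError(
            f"recording at {rec.fs} Hz; resample to {cfg.target_fs} Hz first"
        )
    n_trim = int(round(cfg.transient_trim * rec.fs))
    n_epoch = int(round(cfg.epoch_len * rec.fs))
    if rec.n_samples < n_trim + n_epoch:
        raise TooShortError(
            f"{rec.duration:.2f} s recording cannot yield one "
            f"{cfg.epoch_len} s epoch after a {cfg.transient_trim} s trim"
        )
    order = int(round(cfg.fir_order_window * rec.fs))
    taps = signal.firwin(
        order + 1, list(cfg.band), pass_zero=False, window="hamming", fs=rec.fs
    )
    filtered = signal.lfilter(taps, [1.0], rec.data, axis=1)
    return rec.with_data(filtered[:, n_trim:])


def epoch(rec: Recording, epoch_len: float = 3.0) -> EpochTensor:
    """Split into floor(duration / epoch_len) contiguous epochs."""
    n_per = int(round(epoch_len * rec.fs))
    n_ep = rec.n_samples // n_per
    if n_ep < 1:
        raise TooShortError(
            f"{rec.duration:.2f} s recording shorter than one "
            f"{epoch_len} s epoch"
        )
    data = rec.data[:, : n_ep * n_per]  # remainder discarded from the end
    tensor = data.reshape(rec.n_channels, n_ep, n_per).transpose(1, 0, 2)
    return EpochTensor(
        subject_id=rec.subject_id,
        group=rec.group,
        dataset_id=rec.dataset_id,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        epochs=tensor.copy(),
    )


def preprocess(rec: Recording, cfg: PreprocConfig = PreprocConfig()) -> Recording:
    """Artifact hook, resampling and band-pass/trim (no epoching).

    Epoching is deliberately separate because amplitude transforms are
    fitted on the continuous post-filter recording.
    """
    if cfg.artifact_hook is not None:
        rec = cfg.artifact_hook(rec)
    if rec.fs != cfg.target_fs:
        rec = resample_polyphase(rec, cfg.target_fs)
    return bandpass_trim(rec, cfg)
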