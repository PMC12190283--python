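"""Seeded synthetic EEG-like cohorts with a multi-site amplitude confound.

The generator emulates the statistical structure a two-group,
two-site resting-state EEG complexity study assumes, without any claim
of physiological realism:

* healthy subjects (HS): a fast AR(1) process (band-limited noise);
* Alzheimer's patients (AD): the same fast process plus a slow AR(1)
  component (stronger low-frequency power), which survives
  coarse-graining and therefore raises long-scale multiscale fuzzy
  entropy relative to HS;
* a shared across-channel component so channels are correlated;
* multiplicative gains — per dataset (site), per subject (log-normal)
  and per channel — applied identically regardless of group label, so
  amplitude heterogeneity is a pure confound.

All randomness flows from one integer seed through per-subject
``SeedSequence`` streams, so a cohort is reproducible and extensible
without reshuffling existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import GROUP_AD, GROUP_HS, MONTAGE_10_20, Recording

__all__ = ["GroupDynamics", "SynthConfig", "generate_cohort", "generate_recording"]


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class GroupDynamics:
    """Stochastic-process parameters for one group.

    ``ar_coef`` is the lag-1 coefficient of the fast component;
    ``slow_weight`` scales an added slow AR(1) component with
    coefficient ``slow_ar_coef`` (zero weight for a pure fast process);
    ``common_weight`` mixes in a channel-shared component with the same
    dynamics to induce inter-channel correlation.
    """

    ar_coef: float = 0.7
    slow_weight: float = 0.0
    slow_ar_coef: float = 0.95
    common_weight: float = 0.5


def _default_dynamics() -> dict:
    return {
        GROUP_HS: GroupDynamics(),
        GROUP_AD: GroupDynamics(slow_weight=1.0),
    }


def _default_dataset_gains() -> dict:
    return {"A": 1.0, "B": 3.0}


@dataclass
class SynthConfig:
    """Configuration of a synthetic two-group, multi-site cohort."""

    n_subjects_per_group: int = 52
    n_channels: int = 19
    fs: float = 200.0
    duration: float = 51.0
    group_dynamics: dict = field(default_factory=_default_dynamics)
    channel_gain_profile: dict | None = None  # group -> per-channel gains
    subject_gain_sigma: float = 0.5
    dataset_gains: dict = field(default_factory=_default_dataset_gains)
    dataset_a_fraction: float = 35 / 52  # share of each group from the first site
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ConfigError("need at least one subject per group")
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigError("sampling rate and duration must be positive")
        n_samp = self.fs * self.duration
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ConfigError("duration x fs must be an integer sample count")
        if len(self.group_dynamics) != 2:
            raise ConfigError("exactly two group labels are required")
        if len(self.dataset_gains) < 2:
            raise ConfigError("at least two dataset ids are required")
        if any(g <= 0 for g in self.dataset_gains.values()):
            raise ConfigError("dataset gains must be positive")
        if self.subject_gain_sigma < 0:
            raise ConfigError("subject gain sigma must be >= 0")
        if self.channel_gain_profile is not None:
            for grp, prof in self.channel_gain_profile.items():
                prof = np.asarray(prof, dtype=float)
                if prof.shape != (self.n_channels,) or (prof <= 0).any():
                    raise ConfigError(
                        f"channel gain profile for {grp!r} must be "
                        f"{self.n_channels} positive values"
                    )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def channel_names(self) -> list[str]:
        if self.n_channels == len(MONTAGE_10_20):
            return list(MONTAGE_10_20)
        return [f"CH{i + 1}" for i in range(self.n_channels)]


def _ar1(rng: np.random.Generator, phi: float, n: int) -> np.ndarray:
    """Stationary unit-variance AR(1) series (exact stationary start)."""
    from scipy.signal import lfilter

    innov = rng.standard_normal(n) * np.sqrt(1.0 - phi**2)
    x0 = rng.standard_normal()  # stationary initial state, unit variance
    out, _ = lfilter([1.0], [1.0, -phi], innov, zi=np.array([phi * x0]))
    return out


def _subject_process(
    rng: np.random.Generator, dyn: GroupDynamics, n_channels: int, n: int,
    noise_sd: float,
) -> np.ndarray:
    """Channels x samples array of the group process, unit-SD per channel."""
    common = _ar1(rng, dyn.ar_coef, n)
    if dyn.slow_weight > 0:
        common = common + dyn.slow_weight * _ar1(rng, dyn.slow_ar_coef, n)
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        x = _ar1(rng, dyn.ar_coef, n)
        if dyn.slow_weight > 0:
            x = x + dyn.slow_weight * _ar1(rng, dyn.slow_ar_coef, n)
        x = x + dyn.common_weight * common
        x = x + noise_sd * rng.standard_normal(n)
        out[c] = x / x.std()
    return out


def generate_recording(
    config: SynthConfig, group: str, subject_index: int, dataset_id: str
) -> Recording:
    """One subject's recording from its dedicated RNG stream.

    The stream is derived from ``(seed, group, subject_index)`` so
    adding subjects or reordering the cohort loop cannot change an
    existing subject's signal.
    """
    groups = sorted(config.group_dynamics)
    if group not in groups:
        raise ConfigError(f"unknown group {group!r}")
    seq = np.random.SeedSequence(
        [config.seed, groups.index(group), subject_index]
    )
    proc_seq, gain_seq = seq.spawn(2)
    dyn = config.group_dynamics[group]
    proc = _subject_process(
        np.random.default_rng(proc_seq),
        dyn, config.n_channels, config.n_samples, config.noise_sd,
    )
    # gains come from their own child stream so they are identical no
    # matter which dynamics the group uses: a pure, label-blind confound
    subj_gain = (
        float(np.exp(np.random.default_rng(gain_seq).normal(0.0, config.subject_gain_sigma)))
        if config.subject_gain_sigma > 0
        else 1.0
    )
    if config.channel_gain_profile is not None:
        ch_gain = np.asarray(config.channel_gain_profile[group], dtype=float)
    else:
        ch_gain = np.ones(config.n_channels)
    gain = config.dataset_gains[dataset_id] * subj_gain * ch_gain[:, None]
    return Recording(
        subject_id=f"{group}{subject_index:03d}",
        group=group,
        dataset_id=dataset_id,
        fs=config.fs,
        channel_names=config.channel_names(),
        data=gain * proc,
    )


def generate_cohort(config: SynthConfig) -> list[Recording]:
    """Generate the full two-group cohort, deterministically per seed.

    Within each group the first ``dataset_a_fraction`` of subjects are
    assigned to the first dataset id (sorted order), the rest to the
    second — the label-independent site confound.
    """
    dataset_ids = sorted(config.dataset_gains)
    n_a = int(round(config.dataset_a_fraction * config.n_subjects_per_group))
    recs = []
    for group in sorted(config.group_dynamics):
        for i in range(config.n_subjects_per_group):
            ds = dataset_ids[0] if i < n_a else dataset_ids[1]
            recs.append(generate_recording(config, group, i, ds))
    return recs
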