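"""The five amplitude conditions applied before entropy extraction.

* ``reference`` — no transformation (preserves acquisition amplitudes);
* ``single_norm`` / ``global_norm`` — min-max normalization to a fixed
  output range [a_min, a_max] (default -5..+5), where x_min and x_max
  are the medians of per-window minima and maxima over 3 s windows,
  fitted per channel (single) or over all channels jointly (global);
* ``single_stand`` / ``global_stand`` — standardization to zero mean
  and unit SD, with moments per channel (single) or pooled (global).

All four transforms are per-subject affine maps with positive slope, so
inter-channel Pearson correlations are untouched; the global variants
additionally preserve cross-channel amplitude ratios, the single ones
equalize per-channel ranges/SDs. Out-of-range samples are NOT clipped:
the map stays purely affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import Recording

CONDITIONS = (
    "reference",
    "single_norm",
    "global_norm",
    "single_stand",
    "global_stand",
)

__all__ = [
    "CONDITIONS",
    "TransformSpec",
    "TransformParams",
    "fit_minmax",
    "apply_minmax",
    "fit_apply_stand",
    "apply_condition",
    "DegenerateAmplitudeError",
]


class DegenerateAmplitudeError(ValueError):
    """Constant signal: min == max or zero standard deviation."""


@dataclass(frozen=True)
class TransformSpec:
    """Which amplitude condition to apply and its constants."""

    condition: str = "reference"
    a_min: float = -5.0
    a_max: float = 5.0
    window_len: float = 3.0  # extreme-estimation window, seconds
    window_stride: float | None = None  # None -> non-overlapping
    sd_ddof: int = 1  # sample SD for standardization

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.a_min >= self.a_max:
            raise ValueError("a_min must be < a_max")


@dataclass
class TransformParams:
    """Fitted per-subject constants of one amplitude condition.

    For normalization, ``x_min``/``x_max`` are arrays of one value per
    channel (single) or length-1 arrays (global); likewise
    ``mean``/``sd`` for standardization.
    """

    condition: str
    subject_id: str
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    a_min: float = -5.0
    a_max: float = 5.0

    def __post_init__(self) -> None:
        if self.x_min is not None and np.any(self.x_min >= self.x_max):
            raise DegenerateAmplitudeError("fitted x_min >= x_max")
        if self.sd is not None and np.any(self.sd <= 0):
            raise DegenerateAmplitudeError("fitted sd <= 0")

    def to_dict(self) -> dict:
        out = {"condition": self.condition, "subject_id": self.subject_id,
               "a_min": self.a_min, "a_max": self.a_max}
        for k in ("x_min", "x_max", "mean", "sd"):
            v = getattr(self, k)
            out[k] = None if v is None else np.asarray(v).tolist()
        return out


def _window_extremes(rec: Recording, spec: TransformSpec):
    """Per-window minima and maxima, shape windows x channels."""
    n_win_samp = int(round(spec.window_len * rec.fs))
    stride = (
        n_win_samp
        if spec.window_stride is None
        else int(round(spec.window_stride * rec.fs))
    )
    starts = range(0, rec.n_samples - n_win_samp + 1, stride)
    if not len(starts):
        raise ValueError("recording shorter than one extreme-estimation window")
    mins = np.array([rec.data[:, s : s + n_win_samp].min(axis=1) for s in starts])
    maxs = np.array([rec.data[:, s : s + n_win_samp].max(axis=1) for s in starts])
    return mins, maxs


def fit_minmax(rec: Recording, spec: TransformSpec) -> TransformParams:
    """Fit windowed-median extremes for min-max normalization.

    x_max (x_min) is the median over 3 s windows of the window maxima
    (minima) — per channel for ``single_norm``, over the values of all
    channels jointly for ``global_norm``.
    """
    if spec.condition not in ("single_norm", "global_norm"):
        raise ValueError(f"fit_minmax does not handle {spec.condition!r}")
    mins, maxs = _window_extremes(rec, spec)
    if spec.condition == "single_norm":
        x_min = np.median(mins, axis=0)
        x_max = np.median(maxs, axis=0)
    else:
        # one window extreme across all channels jointly, then the median
        x_min = np.atleast_1d(np.median(mins.min(axis=1)))
        x_max = np.atleast_1d(np.median(maxs.max(axis=1)))
    return TransformParams(
        condition=spec.condition,
        subject_id=rec.subject_id,
        x_min=np.asarray(x_min, dtype=float),
        x_max=np.asarray(x_max, dtype=float),
        a_min=spec.a_min,
        a_max=spec.a_max,
    )


def apply_minmax(rec: Recording, params: TransformParams) -> Recording:
    """Affine min-max map to [a_min, a_max]; no clipping of outliers."""
    if params.condition == "single_norm":
        if len(params.x_min) != rec.n_channels:
            raise ValueError(
                f"params fitted for {len(params.x_min)} channels, "
                f"recording has {rec.n_channels}"
            )
        x_min = params.x_min[:, None]
        x_max = params.x_max[:, None]
    elif params.condition == "global_norm":
        x_min = params.x_min[0]
        x_max = params.x_max[0]
    else:
        raise ValueError(f"apply_minmax does not handle {params.condition!r}")
    span = params.a_max - params.a_min
    # divide before scaling so a sample equal to x_max (ratio exactly 1.0
    # in IEEE arithmetic) lands exactly on a_max, and x_min on a_min
    out = span * ((rec.data - x_min) / (x_max - x_min)) + params.a_min
    return rec.with_data(out)


def fit_apply_stand(rec: Recording, spec: TransformSpec):
    """Standardize to zero mean / unit SD; returns (recording, params).

    ``single_stand`` uses each channel's own moments; ``global_stand``
    pools the moments over all channels, preserving between-channel SD
    ratios. Sample SD (N-1) by default via ``spec.sd_ddof``.
    """
    if spec.condition == "single_stand":
        mean = rec.data.mean(axis=1)
        sd = rec.data.std(axis=1, ddof=spec.sd_ddof)
        if np.any(sd <= 0):
            raise DegenerateAmplitudeError("constant channel under single_stand")
        out = (rec.data - mean[:, None]) / sd[:, None]
    elif spec.condition == "global_stand":
        mean = np.atleast_1d(rec.data.mean())
        sd = np.atleast_1d(rec.data.std(ddof=spec.sd_ddof))
        if sd[0] <= 0:
            raise DegenerateAmplitudeError("constant recording under global_stand")
        out = (rec.data - mean[0]) / sd[0]
    else:
        raise ValueError(f"fit_apply_stand does not handle {spec.condition!r}")
    params = TransformParams(
        condition=spec.condition,
        subject_id=rec.subject_id,
        mean=np.asarray(mean, dtype=float),
        sd=np.asarray(sd, dtype=float),
    )
    return rec.with_data(out), params


def apply_condition(rec: Recording, spec: TransformSpec):
    """Dispatch one amplitude condition; returns (recording, params).

    ``reference`` returns the input unchanged with empty params.
    """
    if spec.condition == "reference":
        return rec, TransformParams(condition="reference", subject_id=rec.subject_id)
    if spec.condition in ("single_norm", "global_norm"):
        params = fit_minmax(rec, spec)
        return apply_minmax(rec, params), params
    if spec.condition in ("single_stand", "global_stand"):
        return fit_apply_stand(rec, spec)
    raise ValueError(f"unknown condition {spec.condition!r}")
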