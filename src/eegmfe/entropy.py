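"""Multiscale fuzzy entropy (MFE) and long-scale feature extraction.

Fuzzy entropy measures the regularity of a time series by comparing
template vectors of length ``m`` and ``m + 1`` under a continuous
(fuzzy) membership of their Chebyshev distances instead of a hard
threshold:

    FuzzEn = ln(phi_m) - ln(phi_{m+1})

where ``phi_d`` is the mean pairwise membership ``mu = exp(-d**n / r)``
over all ordered template pairs. Templates have their own mean
subtracted before distances are taken, and ``N - m`` templates are
formed for both dimensions (Chen's convention).

The multiscale curve recomputes the entropy on coarse-grained copies of
the signal: at scale ``tau`` consecutive non-overlapping blocks of
``tau`` samples are replaced by their mean, so long scales probe slow
dynamics. The tolerance is ``r = r_coef * SD``; by default the SD is
taken once from the scale-1 series and reused at every scale (the
standard multiscale convention), which makes the measure sensitive to
the amplitude of the signal — the property the amplitude-transform
study exploits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

logger = logging.getLogger(__name__)

__all__ = [
    "MFEParams",
    "MFEMatrix",
    "coarse_grain",
    "fuzzy_entropy",
    "mfe_curve",
    "mfe_matrix",
    "extract_features",
]


class DegenerateToleranceError(ValueError):
    """Raised when the fuzzy-entropy tolerance is not strictly positive."""


@dataclass(frozen=True)
class MFEParams:
    """Parameters of the multiscale fuzzy entropy computation.

    Attributes
    ----------
    m : embedding dimension (template length).
    n : fuzziness exponent of the membership function.
    r_coef : tolerance coefficient; the tolerance is ``r_coef * SD``.
    scales : scale factors at which entropy is computed.
    feature_scales : scales averaged into the per-channel feature.
    r_convention : ``"fixed_from_scale1"`` computes the SD once from the
        unscaled series and reuses it at every scale; ``"per_scale"``
        recomputes the SD from each coarse-grained series.
    membership : ``"exp_dn_over_r"`` is ``exp(-d**n / r)``;
        ``"exp_d_over_r_n"`` is the amplitude-invariant alternative
        ``exp(-(d / r)**n)``.
    """

    m: int = 2
    n: float = 2.0
    r_coef: float = 0.2
    scales: tuple[int, ...] = tuple(range(1, 21))
    feature_scales: tuple[int, ...] = (17, 18, 19, 20)
    r_convention: str = "fixed_from_scale1"
    membership: str = "exp_dn_over_r"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.n <= 0:
            raise ValueError("fuzziness exponent n must be > 0")
        if self.r_coef <= 0:
            raise ValueError("tolerance coefficient must be > 0")
        if self.r_convention not in ("fixed_from_scale1", "per_scale"):
            raise ValueError(f"unknown r_convention {self.r_convention!r}")
        if self.membership not in ("exp_dn_over_r", "exp_d_over_r_n"):
            raise ValueError(f"unknown membership {self.membership!r}")
        if not set(self.feature_scales) <= set(self.scales):
            raise ValueError("feature_scales must be a subset of scales")


@dataclass
class MFEMatrix:
    """Entropy values for one subject, indexed (epoch, channel, scale)."""

    subject_id: str
    group: str
    dataset_id: str
    channel_names: list[str]
    values: np.ndarray  # epoch x channel x scale
    params: MFEParams

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("values must be epoch x channel x scale")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.values.shape[2] != len(self.params.scales):
            raise ValueError("scale axis does not match params.scales")
        valid = self.values[np.isfinite(self.values)]
        if valid.size and valid.min() < -1e-12:
            raise ValueError("negative entropy beyond numerical noise")


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Average consecutive non-overlapping blocks of ``tau`` samples.

    Returns a series of length ``floor(len(x) / tau)``; trailing samples
    that do not fill a block are discarded.
    """
    if tau < 1:
        raise ValueError("scale factor tau must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    if len(x) < tau:
        raise ValueError("series shorter than one coarse-graining block")
    n_blocks = len(x) // tau
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


@njit(cache=True)
def _phi_pair(x, m, n):  # pragma: no cover - numba kernel
    """Return (phi_m, phi_{m+1}) summands scaled by r=1 exponent terms.

    Computes, for the N-m baselined templates of lengths m and m+1, the
    mean membership over ordered pairs i != j, with the distance raised
    to n but the division by r applied by the caller (via pre-scaling).
    """
    N = x.shape[0]
    nt = N - m
    # baselined templates: subtract each template's own mean
    tm = np.empty((nt, m))
    tm1 = np.empty((nt, m + 1))
    for i in range(nt):
        s = 0.0
        for k in range(m):
            s += x[i + k]
        mu = s / m
        for k in range(m):
            tm[i, k] = x[i + k] - mu
        s += x[i + m]
        mu1 = s / (m + 1)
        for k in range(m + 1):
            tm1[i, k] = x[i + k] - mu1
    sum_m = 0.0
    sum_m1 = 0.0
    for i in range(nt):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                t = abs(tm[i, k] - tm[j, k])
                if t > d:
                    d = t
            sum_m += math.exp(-(d ** n))
            d = 0.0
            for k in range(m + 1):
                t = abs(tm1[i, k] - tm1[j, k])
                if t > d:
                    d = t
            sum_m1 += math.exp(-(d ** n))
    npairs = nt * (nt - 1) / 2.0
    return sum_m / npairs, sum_m1 / npairs


def fuzzy_entropy(
    x: np.ndarray,
    m: int = 2,
    n: float = 2.0,
    r: float | None = None,
    membership: str = "exp_dn_over_r",
) -> float:
    """Fuzzy entropy of a series, in nats.

    The membership of a template pair at Chebyshev distance ``d`` is
    ``exp(-d**n / r)`` (default) or ``exp(-(d/r)**n)``. Returns NaN with
    a logged reason if the dimension-(m+1) mean membership underflows.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(x) < m + 2:
        raise ValueError("series too short for the embedding dimension")
    if r is None or r <= 0:
        raise DegenerateToleranceError(
            f"tolerance r must be > 0, got {r!r} (constant series upstream?)"
        )
    # fold r into the sample scale so the kernel runs with r = 1:
    # exp(-d^n/r) == exp(-(d/r^(1/n))^n); exp(-(d/r)^n) likewise with d/r.
    if membership == "exp_dn_over_r":
        xs = x / r ** (1.0 / n)
    elif membership == "exp_d_over_r_n":
        xs = x / r
    else:
        raise ValueError(f"unknown membership {membership!r}")
    phi_m, phi_m1 = _phi_pair(xs, m, float(n))
    if phi_m1 <= 0.0 or phi_m <= 0.0:
        logger.warning("fuzzy_entropy: membership mean underflowed; returning NaN")
        return float("nan")
    return math.log(phi_m) - math.log(phi_m1)


def mfe_curve(x: np.ndarray, params: MFEParams = MFEParams()) -> np.ndarray:
    """Entropy at each scale factor for one epoch of one channel."""
    x = np.asarray(x, dtype=np.float64)
    max_scale = max(params.scales)
    if len(x) < max_scale * (params.m + 2):
        raise ValueError("series too short for the largest scale factor")
    sd1 = float(np.std(x))
    out = np.empty(len(params.scales))
    for s_idx, tau in enumerate(params.scales):
        y = coarse_grain(x, tau)
        sd = sd1 if params.r_convention == "fixed_from_scale1" else float(np.std(y))
        if sd <= 0:
            raise DegenerateToleranceError("constant series gives zero tolerance")
        out[s_idx] = fuzzy_entropy(
            y, params.m, params.n, params.r_coef * sd, params.membership
        )
    return out


def mfe_matrix(epochs, params: MFEParams = MFEParams()) -> "MFEMatrix":
    """Compute the full (epoch, channel, scale) entropy array for a subject.

    ``epochs`` is an EpochTensor-like object with attributes ``epochs``
    (epoch x channel x sample), ``subject_id``, ``group``, ``dataset_id``
    and ``channel_names``.
    """
    data = np.asarray(epochs.epochs, dtype=np.float64)
    n_ep, n_ch, _ = data.shape
    values = np.empty((n_ep, n_ch, len(params.scales)))
    for e in range(n_ep):
        for c in range(n_ch):
            values[e, c] = mfe_curve(data[e, c], params)
    return MFEMatrix(
        subject_id=epochs.subject_id,
        group=epochs.group,
        dataset_id=epochs.dataset_id,
        channel_names=list(epochs.channel_names),
        values=values,
        params=params,
    )


def extract_features(matrices: list[MFEMatrix]) -> pd.DataFrame:
    """Mean long-scale entropy per channel: one row per epoch.

    Returns a DataFrame with metadata columns ``subject_id``, ``epoch``,
    ``group``, ``dataset_id`` followed by one feature column per channel.
    Observations with a NaN feature are kept but flagged in the boolean
    column ``valid`` (downstream classification drops them with a log).
    """
    if not matrices:
        raise ValueError("no MFE matrices given")
    rows = []
    channel_names = matrices[0].channel_names
    for mat in matrices:
        if mat.channel_names != channel_names:
            raise ValueError("inconsistent channel names across subjects")
        idx = [mat.params.scales.index(s) for s in mat.params.feature_scales]
        feats = mat.values[:, :, idx].mean(axis=2)  # epoch x channel
        for e in range(feats.shape[0]):
            row = {
                "subject_id": mat.subject_id,
                "epoch": e,
                "group": mat.group,
                "dataset_id": mat.dataset_id,
                "valid": bool(np.all(np.isfinite(feats[e]))),
            }
            row.update(dict(zip(channel_names, feats[e])))
            rows.append(row)
    df = pd.DataFrame(rows)
    meta = ["subject_id", "epoch", "group", "dataset_id", "valid"]
    return df[meta + channel_names]
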