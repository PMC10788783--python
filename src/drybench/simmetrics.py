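"""Similarity metrics: RMS, rank correlation, Welch power, coherence.

Spectral conventions follow the common EEG benchmarking recipe: Hamming
windows of one second (1 Hz resolution), 50% overlap, 2-35 Hz range, power
in 10*log10(µV²/Hz).  Magnitude-squared coherence supports two aggregation
modes:

* ``"epoch"`` (default): MSC formed within each 2 s epoch (3 segments) and
  then averaged across epochs.  This mirrors the within-epoch-then-average
  recipe but inherits the well-known small-sample bias of few-segment
  coherence estimates, which does not vanish with more epochs.
* ``"pooled"``: auto- and cross-spectra averaged across all epochs before
  forming the ratio; consistent (converges to true coherence) as the number
  of epochs grows.  Use this mode for quantitative recovery of ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .ioformats import ValidationError
from .preprocess import EpochSet

__all__ = [
    "SpectralParams",
    "UndefinedMetricError",
    "rms_amplitude",
    "band_correlation",
    "welch_psd",
    "msc",
    "split_half_stability",
    "grand_average",
]


class UndefinedMetricError(ValidationError):
    """Metric undefined on this input (e.g. no epochs)."""


class SpectralParams:
    """Welch parameters: Hamming window, 50% overlap, 2-35 Hz at 1 Hz resolution."""

    def __init__(
        self,
        window: str = "hamming",
        overlap: float = 0.5,
        f_range: tuple[float, float] = (2.0, 35.0),
        resolution_hz: float = 1.0,
    ) -> None:
        if not (0 <= overlap < 1):
            raise ValidationError("overlap must be in [0, 1)")
        if resolution_hz <= 0:
            raise ValidationError("resolution must be positive")
        if not (0 <= f_range[0] < f_range[1]):
            raise ValidationError("need 0 <= f_lo < f_hi")
        self.window = window
        self.overlap = overlap
        self.f_range = f_range
        self.resolution_hz = resolution_hz

    def nperseg(self, fs: float) -> int:
        n = int(round(fs / self.resolution_hz))
        if n < 2:
            raise ValidationError("segment length below 2 samples")
        return n

    def noverlap(self, fs: float) -> int:
        return int(self.nperseg(fs) * self.overlap)

    def n_segments(self, fs: float, n_times: int) -> int:
        nper = self.nperseg(fs)
        step = nper - self.noverlap(fs)
        if n_times < nper:
            return 0
        return 1 + (n_times - nper) // step

    def validate(self, fs: float, n_times: int, need_multiple: bool = False) -> None:
        if self.f_range[1] > fs / 2:
            raise ValidationError(
                f"frequency range up to {self.f_range[1]} Hz exceeds Nyquist {fs / 2} Hz"
            )
        nseg = self.n_segments(fs, n_times)
        if nseg == 0:
            raise ValidationError("epoch shorter than one Welch segment")
        if need_multiple and nseg < 2:
            raise ValidationError(
                "single-segment epochs make coherence identically 1; "
                "shorten the segment or lengthen the epoch"
            )

    def band_mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.f_range[0] - 1e-9) & (freqs <= self.f_range[1] + 1e-9)


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------


def rms_amplitude(epochs: EpochSet, channel: str) -> tuple[np.ndarray, float]:
    """Per-epoch RMS (µV) and the across-epoch mean."""
    if epochs.n_epochs == 0:
        raise UndefinedMetricError("RMS undefined on an empty epoch set")
    x = epochs.channel(channel)
    per_epoch = np.sqrt(np.mean(x**2, axis=1))
    return per_epoch, float(per_epoch.mean())


def band_correlation(
    x: np.ndarray, y: np.ndarray, method: str = "spearman"
) -> float:
    """Rank (or Pearson) correlation of two retained, unepoched series.

    Constant input makes the correlation undefined; returned as NaN
    (missing), never coerced to zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("band_correlation needs two equal-length 1-D series")
    if len(x) < 100:
        raise ValidationError(f"need at least 100 samples, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "spearman":
        rho = stats.spearmanr(x, y).statistic
    elif method == "pearson":
        rho = stats.pearsonr(x, y).statistic
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(rho)


# ---------------------------------------------------------------------------
# Spectral metrics
# ---------------------------------------------------------------------------


def _welch_kwargs(params: SpectralParams, fs: float) -> dict:
    return dict(
        fs=fs,
        window=params.window,
        nperseg=params.nperseg(fs),
        noverlap=params.noverlap(fs),
        detrend="constant",
        scaling="density",
    )


def welch_psd(
    epochs: EpochSet, channel: str, params: SpectralParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch power per epoch in dB (10*log10 µV²/Hz).

    Returns ``(freqs, per_epoch_db, mean_db)`` restricted to the configured
    frequency range; the participant-level value is the across-epoch mean of
    the per-epoch dB spectra.
    """
    params = params or SpectralParams()
    if epochs.n_epochs == 0:
        raise UndefinedMetricError("PSD undefined on an empty epoch set")
    params.validate(epochs.fs, epochs.n_times)
    x = epochs.channel(channel)
    freqs, pxx = sps.welch(x, axis=-1, **_welch_kwargs(params, epochs.fs))
    keep = params.band_mask(freqs)
    per_epoch_db = 10 * np.log10(np.maximum(pxx[:, keep], 1e-300))
    return freqs[keep], per_epoch_db, per_epoch_db.mean(axis=0)


def msc(
    epochs: EpochSet,
    pair: tuple[str, str],
    params: SpectralParams | None = None,
    mode: str = "epoch",
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence per frequency bin for one channel pair.

    ``mode="epoch"`` averages per-epoch MSC values; ``mode="pooled"``
    averages spectra across epochs first (consistent estimator).  Values lie
    in [0, 1] and are invariant to per-channel linear rescaling.
    """
    params = params or SpectralParams()
    if epochs.n_epochs == 0:
        raise UndefinedMetricError("MSC undefined on an empty epoch set")
    if mode not in ("epoch", "pooled"):
        raise ValidationError(f"unknown MSC mode {mode!r}")
    params.validate(epochs.fs, epochs.n_times, need_multiple=True)
    x = epochs.channel(pair[0])
    y = epochs.channel(pair[1])
    kw = _welch_kwargs(params, epochs.fs)
    freqs, pxy = sps.csd(x, y, axis=-1, **kw)
    _, pxx = sps.welch(x, axis=-1, **kw)
    _, pyy = sps.welch(y, axis=-1, **kw)
    keep = params.band_mask(freqs)
    pxy, pxx, pyy = pxy[:, keep], pxx[:, keep], pyy[:, keep]
    # bins with zero power in an epoch have undefined coherence -> NaN
    # (missing, never coerced to a number)
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "epoch":
            values = (np.abs(pxy) ** 2 / (pxx * pyy)).mean(axis=0)
        else:
            values = np.abs(pxy.mean(axis=0)) ** 2 / (pxx.mean(axis=0) * pyy.mean(axis=0))
    return freqs[keep], np.clip(values.real, 0.0, 1.0)


def split_half_stability(
    epochs: EpochSet,
    pair: tuple[str, str],
    params: SpectralParams | None = None,
    metric: str = "msc",
    mode: str = "epoch",
) -> float:
    """Spearman correlation across frequency bins of a spectral metric
    computed on the first vs second half of the epoch sequence."""
    if epochs.n_epochs < 4:
        return float("nan")
    half = epochs.n_epochs // 2
    first, second = epochs.subset(slice(0, half)), epochs.subset(slice(half, None))
    if metric == "msc":
        _, a = msc(first, pair, params, mode)
        _, b = msc(second, pair, params, mode)
    elif metric == "psd":
        _, _, a = welch_psd(first, pair[0], params)
        _, _, b = welch_psd(second, pair[0], params)
    else:
        raise ValidationError(f"unknown stability metric {metric!r}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def grand_average(participant_frame: pd.DataFrame) -> pd.DataFrame:
    """Grand-average participant-level tidy rows.

    Expects columns ``participant, pair, band, value`` (``band`` may hold a
    frequency bin); returns rows with ``level="grand"``, the across-
    participant mean and the across-participant variance.
    """
    required = {"participant", "pair", "band", "value"}
    missing = required - set(participant_frame.columns)
    if missing:
        raise ValidationError(f"participant frame missing columns {sorted(missing)}")
    grouped = (
        participant_frame.groupby(["pair", "band"], sort=False)["value"]
        .agg(["mean", "var", "count"])
        .reset_index()
    )
    grouped = grouped.rename(columns={"mean": "value", "var": "variance", "count": "n"})
    grouped["level"] = "grand"
    return grouped[["pair", "band", "level", "value", "variance", "n"]]
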