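"""Event-related potentials and the epoch-permutation decomposition.

The permutation analysis asks how much of the similarity between two
simultaneously recorded channels during cued epochs comes from the average
event-locked response (which survives epoch shuffling) versus instantaneous
shared activity (which does not).  Cross-channel permutations are uniform
random; self-pair permutations are derangements (no fixed points), so a
trivially perfect self-match never contaminates the null.

Coherence for matched epoch pairs pools cross- and auto-spectra across the
matched pairs before forming the ratio: cued epochs (1.2 s) hold only one
1 s Welch segment each, so a within-epoch coherence would be identically 1;
pooling across epochs is the standard multi-trial coherence estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .ioformats import ValidationError
from .preprocess import EpochSet
from .simmetrics import SpectralParams, UndefinedMetricError

__all__ = [
    "Erp",
    "PermutationResult",
    "compute_erp",
    "erp_correlation",
    "detect_components",
    "permute_and_score",
]


@dataclass
class Erp:
    """Mean cue-locked waveform (µV) for one channel over cued epochs."""

    waveform: np.ndarray
    times_s: np.ndarray  # relative to the cue
    n_epochs: int
    channel: str

    def __post_init__(self) -> None:
        if self.waveform.shape != self.times_s.shape:
            raise ValidationError("waveform and time axis must have equal length")


def compute_erp(epochs: EpochSet, channel: str) -> Erp:
    """Arithmetic mean across cued epochs per time point."""
    if epochs.n_epochs == 0:
        raise UndefinedMetricError("ERP undefined with zero epochs")
    wave = epochs.channel(channel).mean(axis=0)
    return Erp(wave, epochs.times(), epochs.n_epochs, channel)


def erp_correlation(a: Erp, b: Erp, method: str = "spearman") -> float:
    """Rank correlation of two ERPs over the full epoch window (NaN if constant)."""
    if a.waveform.shape != b.waveform.shape:
        raise ValidationError("ERPs must share the epoch window and sampling rate")
    if np.ptp(a.waveform) == 0 or np.ptp(b.waveform) == 0:
        return float("nan")
    if method == "spearman":
        return float(stats.spearmanr(a.waveform, b.waveform).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a.waveform, b.waveform).statistic)
    raise ValidationError(f"unknown correlation method {method!r}")


#: Default component search windows (s): positive peak near 200 ms, negative
#: trough near 400 ms.
DEFAULT_COMPONENT_WINDOWS = {
    "P200": (0.150, 0.250, +1),
    "N400": (0.350, 0.450, -1),
}


def detect_components(
    erp: Erp, windows: dict | None = None
) -> dict[str, tuple[float, float]]:
    """Extremum search per component window.

    ``windows`` maps name -> (t_lo, t_hi, polarity); polarity +1 takes the
    maximum, -1 the minimum.  Returns name -> (latency_s, amplitude_uv).  On
    a flat ERP the extremum degenerates to the window start with amplitude 0.
    """
    windows = windows or DEFAULT_COMPONENT_WINDOWS
    out: dict[str, tuple[float, float]] = {}
    for name, (lo, hi, polarity) in windows.items():
        sel = (erp.times_s >= lo - 1e-9) & (erp.times_s <= hi + 1e-9)
        if not np.any(sel):
            raise ValidationError(f"component window {name} [{lo}, {hi}] s outside the epoch")
        seg = erp.waveform[sel]
        t_seg = erp.times_s[sel]
        idx = int(np.argmax(polarity * seg))
        out[name] = (float(t_seg[idx]), float(seg[idx]))
    return out


# ---------------------------------------------------------------------------
# Permutation decomposition
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Per-permutation Pearson correlations and pooled MSC for the three pairs."""

    seed: int
    n_permutations: int
    freqs: np.ndarray
    unshuffled_r: float
    unshuffled_msc: np.ndarray  # (n_bins,)
    perm_r: dict  # pair name -> (B,) array
    perm_msc: dict  # pair name -> (B, n_bins) array
    pair_labels: dict  # pair name -> (label_a, label_b)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "pair": "unshuffled",
                "metric": "pearson_r",
                "mean": self.unshuffled_r,
                "sd": 0.0,
            }
        ]
        for name, r in self.perm_r.items():
            rows.append(
                {"pair": name, "metric": "pearson_r", "mean": float(r.mean()), "sd": float(r.std(ddof=1))}
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for name, r in self.perm_r.items():
            frames.append(
                pd.DataFrame(
                    {"permutation": np.arange(len(r)), "pair": name, "metric": "pearson_r", "value": r}
                )
            )
        return pd.concat(frames, ignore_index=True)


def _segment_ffts(x: np.ndarray, fs: float, params: SpectralParams) -> np.ndarray:
    """Hamming-windowed, constant-detrended segment rFFTs: (n_ep, n_seg, n_bins)."""
    nper = params.nperseg(fs)
    step = nper - params.noverlap(fs)
    n_ep, n_t = x.shape
    n_seg = 1 + (n_t - nper) // step if n_t >= nper else 0
    if n_seg == 0:
        raise ValidationError("epoch shorter than one Welch segment")
    win = sps.get_window(params.window, nper)
    segs = np.stack([x[:, i * step : i * step + nper] for i in range(n_seg)], axis=1)
    segs = segs - segs.mean(axis=2, keepdims=True)
    return np.fft.rfft(segs * win[None, None, :], axis=2)


def _pooled_msc(za: np.ndarray, zb: np.ndarray, order: np.ndarray) -> np.ndarray:
    """MSC from spectra pooled over matched epoch pairs (i, order[i])."""
    cross = (za * np.conj(zb[order])).mean(axis=(0, 1))
    pxx = (np.abs(za) ** 2).mean(axis=(0, 1))
    pyy = (np.abs(zb[order]) ** 2).mean(axis=(0, 1))
    return np.clip((np.abs(cross) ** 2 / (pxx * pyy)).real, 0.0, 1.0)


def _concat_pearson(a: np.ndarray, b: np.ndarray, order: np.ndarray) -> float:
    x = a.ravel()
    y = b[order].ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    return float(np.sum(xc * yc) / denom) if denom > 0 else float("nan")


def score_matched(
    epochs: EpochSet,
    channels: tuple[str, str],
    order: np.ndarray,
    params: SpectralParams | None = None,
) -> tuple[float, np.ndarray]:
    """Score one explicit epoch matching: (concatenated Pearson r, pooled MSC).

    Epoch ``i`` of ``channels[0]`` is matched with epoch ``order[i]`` of
    ``channels[1]``; the identity order reproduces the unshuffled values of
    :func:`permute_and_score` exactly.
    """
    params = params or SpectralParams()
    order = np.asarray(order, dtype=np.intp)
    if sorted(order.tolist()) != list(range(epochs.n_epochs)):
        raise ValidationError("order must be a permutation of the epoch indices")
    a = epochs.channel(channels[0])
    b = epochs.channel(channels[1])
    za = _segment_ffts(a, epochs.fs, params)
    zb = _segment_ffts(b, epochs.fs, params)
    freqs = np.fft.rfftfreq(params.nperseg(epochs.fs), 1.0 / epochs.fs)
    keep = params.band_mask(freqs)
    return _concat_pearson(a, b, order), _pooled_msc(za[:, :, keep], zb[:, :, keep], order)


def _derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    while True:  # expected ~e rejections
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def permute_and_score(
    epochs: EpochSet,
    channels: tuple[str, str],
    n_permutations: int = 1000,
    seed: int = 0,
    params: SpectralParams | None = None,
) -> PermutationResult:
    """Epoch-permutation decomposition for channels (A, B) — canonically
    the primary gelled electrode and the nearest dry channel.

    For each permutation, epoch ``i`` of the first channel is matched with
    epoch ``perm[i]`` of the second.  Pearson correlation is computed over
    the concatenation of matched epochs; coherence pools spectra over the
    matched pairs.  Pairs scored: A:B (uniform permutations) and the two
    self-pairs A:A, B:B (derangements).  Fully deterministic under ``seed``.
    """
    params = params or SpectralParams()
    if n_permutations < 1:
        raise ValidationError("need at least one permutation")
    if epochs.n_epochs < 3:
        raise ValidationError("need at least 3 cued epochs")
    a = epochs.channel(channels[0])
    b = epochs.channel(channels[1])
    za = _segment_ffts(a, epochs.fs, params)
    zb = _segment_ffts(b, epochs.fs, params)
    freqs_all = np.fft.rfftfreq(params.nperseg(epochs.fs), 1.0 / epochs.fs)
    keep = params.band_mask(freqs_all)
    za, zb = za[:, :, keep], zb[:, :, keep]
    freqs = freqs_all[keep]

    n = epochs.n_epochs
    identity = np.arange(n)
    unshuffled_r = _concat_pearson(a, b, identity)
    unshuffled_msc = _pooled_msc(za, zb, identity)

    rng = np.random.default_rng(seed)
    name_ab = f"{channels[0]}:{channels[1]}(perm)"
    name_aa = f"{channels[0]}:{channels[0]}(perm)"
    name_bb = f"{channels[1]}:{channels[1]}(perm)"
    spec = {
        name_ab: (a, b, za, zb, False),
        name_aa: (a, a, za, za, True),
        name_bb: (b, b, zb, zb, True),
    }
    perm_r = {k: np.empty(n_permutations) for k in spec}
    perm_msc = {k: np.empty((n_permutations, len(freqs))) for k in spec}
    for bidx in range(n_permutations):
        for name, (xa, xb, fa, fb, self_pair) in spec.items():
            order = _derangement(rng, n) if self_pair else rng.permutation(n)
            perm_r[name][bidx] = _concat_pearson(xa, xb, order)
            perm_msc[name][bidx] = _pooled_msc(fa, fb, order)

    return PermutationResult(
        seed=seed,
        n_permutations=n_permutations,
        freqs=freqs,
        unshuffled_r=unshuffled_r,
        unshuffled_msc=unshuffled_msc,
        perm_r=perm_r,
        perm_msc=perm_msc,
        pair_labels={
            name_ab: channels,
            name_aa: (channels[0], channels[0]),
            name_bb: (channels[1], channels[1]),
        },
    )
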