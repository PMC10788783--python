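"""Filtering, rejection and epoching.

Mirrors the conventional EEG benchmarking pipeline: a zero-phase Hamming
windowed-sinc band-pass (transition bandwidth 1 Hz, so the broadband 1-35 Hz
band has -6 dB cutoffs at 0.5 and 35.5 Hz), an iterative correlation-based
rejection of dry channels, robust-amplitude artifact masking on 1 s windows,
propagation of those decisions to every band-filtered copy, and extraction of
regular (2 s, non-overlapping) and cue-locked (-200..1000 ms, baselined
-200..0 ms) epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .ioformats import DRY, EventList, Recording, ValidationError

__all__ = [
    "FilterSpec",
    "BandSet",
    "EpochSet",
    "design_filter",
    "apply_filter",
    "make_band_variants",
    "reject_channels_iterative",
    "reject_artifact_windows",
    "propagate_rejections",
    "extract_regular_epochs",
    "extract_cued_epochs",
    "DEFAULT_BANDS",
]

#: Named band-pass edges (Hz). Every narrowband lies within Broadband.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "Broadband": (1.0, 35.0),
    "Delta": (1.0, 4.0),
    "Theta": (5.0, 7.0),
    "Alpha": (8.0, 12.0),
    "Beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class BandSet:
    bands: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", dict(self.bands or DEFAULT_BANDS))
        if not self.bands:
            raise ValidationError("band set must be non-empty")
        lo, hi = self.bands.get("Broadband", (1.0, 35.0))
        for name, (f1, f2) in self.bands.items():
            if not (0 < f1 < f2):
                raise ValidationError(f"band {name!r}: need 0 < f_lo < f_hi")
            if name != "Broadband" and not (lo <= f1 and f2 <= hi):
                raise ValidationError(f"band {name!r} exceeds Broadband [{lo}, {hi}] Hz")


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase windowed-sinc band-pass.

    The -6 dB cutoffs sit half a transition bandwidth outside the pass-band
    edges; the (odd-length, symmetric) kernel is applied in a single pass
    with reflection padding, so the filter is exactly zero-phase.
    """

    f_lo: float
    f_hi: float
    transition_bw: float
    fs: float
    taps: np.ndarray

    @property
    def cutoffs(self) -> tuple[float, float]:
        return (self.f_lo - self.transition_bw / 2, self.f_hi + self.transition_bw / 2)

    def response_db(self, freqs_hz: np.ndarray | float) -> np.ndarray:
        freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
        _, h = sps.freqz(self.taps, worN=2 * np.pi * freqs / self.fs)
        return 20 * np.log10(np.maximum(np.abs(h), 1e-300))


def design_filter(
    f_lo: float, f_hi: float, fs: float, transition_bw: float = 1.0
) -> FilterSpec:
    """Hamming windowed-sinc band-pass with -6 dB points at edges -/+ bw/2."""
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValidationError("need 0 < f_lo < f_hi < fs/2")
    if f_hi - f_lo <= transition_bw:
        raise ValidationError(
            f"band [{f_lo}, {f_hi}] Hz too narrow for a {transition_bw} Hz transition band"
        )
    cut_lo = f_lo - transition_bw / 2
    cut_hi = f_hi + transition_bw / 2
    if cut_lo <= 0 or cut_hi >= fs / 2:
        raise ValidationError("transition band extends beyond (0, fs/2)")
    # Hamming-window design rule: order = 3.3 / (normalized transition bw),
    # rounded to even so the kernel has odd length and integer group delay.
    order = int(np.ceil(3.3 * fs / transition_bw / 2) * 2)
    taps = sps.firwin(
        order + 1, [cut_lo, cut_hi], window="hamming", pass_zero=False, fs=fs
    )
    # null the DC gain exactly: DC sits at the stop-band edge where the
    # window's attenuation alone leaves ~-46 dB of leakage; removing the
    # kernel mean zeroes it while perturbing the pass-band by < 0.01 dB
    taps = taps - taps.mean()
    return FilterSpec(f_lo, f_hi, transition_bw, fs, taps)


def apply_filter(recording: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase filtering of every channel (reflection-padded, single pass)."""
    if abs(recording.fs - spec.fs) > 1e-9:
        raise ValidationError(
            f"filter designed for fs={spec.fs} applied to fs={recording.fs}"
        )
    out = recording.copy()
    half = (len(spec.taps) - 1) // 2
    n_t = recording.n_times
    pad = min(half, n_t - 1)
    x = recording.samples
    padded = np.concatenate(
        [x[:, 1 : pad + 1][:, ::-1], x, x[:, -pad - 1 : -1][:, ::-1]], axis=1
    )
    full = sps.fftconvolve(padded, spec.taps[None, :], mode="same")
    out.samples = full[:, pad : pad + n_t]
    return out


def make_band_variants(
    recording: Recording, bandset: BandSet | None = None, transition_bw: float = 1.0
) -> dict[str, Recording]:
    """Band-filtered copies of a recording, one per named band."""
    bandset = bandset or BandSet()
    out = {}
    for name, (f1, f2) in bandset.bands.items():
        out[name] = apply_filter(
            recording, design_filter(f1, f2, recording.fs, transition_bw)
        )
    return out


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------


def reject_channels_iterative(
    recording: Recording,
    eligible: list[str] | None = None,
    window_s: float = 5.0,
    corr_threshold: float = 0.8,
    bad_fraction: float = 0.5,
    n_neighbors: int = 4,
) -> set[str]:
    """Iterative correlation-based rejection of dry channels.

    A channel is flagged when, in more than ``bad_fraction`` of ``window_s``
    windows, its correlation with the pointwise median of its ``n_neighbors``
    nearest retained dry channels falls below ``corr_threshold``.  Flagging
    repeats until a fixed point.  Gelled channels are never eligible: the
    benchmark's own similarity analyses depend on them, and the criterion is
    itself correlation-based.
    """
    dry_labels = [ch.label for ch in recording.channels if ch.kind == DRY]
    if eligible is None:
        eligible = dry_labels
    else:
        extra = set(eligible) - set(dry_labels)
        if extra:
            raise ValidationError(f"eligible channels must be dry; offending: {sorted(extra)}")
    if len(eligible) < 3:
        warnings.warn(
            "fewer than 3 eligible channels; neighbor-correlation criterion "
            "undefined, skipping channel rejection",
            stacklevel=2,
        )
        return set()

    n_win = int(recording.n_times // int(round(window_s * recording.fs)))
    if n_win == 0:
        warnings.warn("recording shorter than one rejection window; skipping", stacklevel=2)
        return set()
    wlen = int(round(window_s * recording.fs))

    pos = {ch.label: ch.position for ch in recording.channels}
    sig = {lab: recording.get(lab) for lab in eligible}
    rejected: set[str] = set()
    for _ in range(len(eligible)):  # monotone growth → terminates
        retained = [lab for lab in eligible if lab not in rejected]
        if len(retained) < 3:
            break
        newly: set[str] = set()
        for lab in retained:
            others = sorted(
                (o for o in retained if o != lab),
                key=lambda o: (float(np.linalg.norm(pos[lab] - pos[o])), o),
            )[:n_neighbors]
            ref = np.median(np.stack([sig[o] for o in others]), axis=0)
            x = sig[lab]
            bad = 0
            for w in range(n_win):
                sl = slice(w * wlen, (w + 1) * wlen)
                xs, rs = x[sl], ref[sl]
                xc = xs - xs.mean()
                rc = rs - rs.mean()
                denom = np.sqrt(np.sum(xc**2) * np.sum(rc**2))
                corr = np.sum(xc * rc) / denom if denom > 0 else 0.0
                if corr < corr_threshold:
                    bad += 1
            if bad > bad_fraction * n_win:
                newly.add(lab)
        if not newly:
            break
        rejected |= newly
    return rejected


def reject_artifact_windows(
    recording: Recording,
    window_s: float = 1.0,
    z_threshold: float = 20.0,
) -> np.ndarray:
    """Robust-amplitude artifact mask.

    Each channel is z-scored with median/MAD over its retained samples; any
    1 s window in which any retained channel exceeds ``z_threshold`` is
    masked out.  Returns (and stores on the recording) the retained-sample
    mask.
    """
    retained = [recording.channel_index(lab) for lab in recording.retained_channels()]
    if not retained:
        raise ValidationError("artifact rejection requires at least one retained channel")
    mask = np.ones(recording.n_times, dtype=bool)
    if not np.isfinite(z_threshold):
        recording.mask = mask
        return mask
    wlen = int(round(window_s * recording.fs))
    x = recording.samples[retained]
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True) * 1.4826
    mad = np.maximum(mad, 1e-12)
    z = np.abs(x - med) / mad
    exceed = np.any(z > z_threshold, axis=0)
    n_win = int(np.ceil(recording.n_times / wlen))
    for w in range(n_win):
        sl = slice(w * wlen, min((w + 1) * wlen, recording.n_times))
        if np.any(exceed[sl]):
            mask[sl] = False
    recording.mask = mask
    return mask


def propagate_rejections(base: Recording, variants: list[Recording]) -> list[Recording]:
    """Copy the base recording's channel statuses and sample mask onto variants."""
    for v in variants:
        if v.n_times != base.n_times or v.n_channels != base.n_channels:
            raise ValidationError(
                f"variant shape {v.samples.shape} not aligned with base {base.samples.shape}"
            )
        if v.labels != base.labels:
            raise ValidationError("variant channel labels differ from base")
        v.mask = base.mask.copy()
        for i, ch in enumerate(base.channels):
            v.channels[i] = replace(v.channels[i], status=ch.status)
    return variants


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------


@dataclass
class EpochSet:
    """Epoch-sliced data: (n_epochs, n_channels, n_times) in µV.

    ``kind`` records provenance: "regular" (tiled, not baselined) or "cued"
    (event-locked, baseline-corrected when a baseline window is set).
    ``window_s`` is relative to the epoch anchor (tile start or cue).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    kind: str  # "regular" | "cued"
    window_s: tuple[float, float]
    baseline_s: tuple[float, float] | None
    starts: np.ndarray  # absolute start sample of each epoch

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be (epochs, channels, time)")
        if self.data.shape[1] != len(self.labels):
            raise ValidationError("labels must match the channel axis")
        if self.kind not in ("regular", "cued"):
            raise ValidationError("kind must be 'regular' or 'cued'")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[:, self.labels.index(label), :]
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None

    def times(self) -> np.ndarray:
        return self.window_s[0] + np.arange(self.n_times) / self.fs

    def subset(self, sl: slice) -> "EpochSet":
        return EpochSet(
            self.data[sl], self.fs, list(self.labels), self.kind,
            self.window_s, self.baseline_s, self.starts[sl],
        )


def extract_regular_epochs(recording: Recording, length_s: float = 2.0) -> EpochSet:
    """Greedy left-to-right tiling of non-overlapping clean epochs.

    Tiling restarts at the first retained sample after each masked region;
    epochs overlapping any masked sample are skipped.
    """
    wlen = int(round(length_s * recording.fs))
    starts: list[int] = []
    mask = recording.mask
    n_t = recording.n_times
    if wlen > n_t:
        warnings.warn("recording shorter than one epoch; empty epoch set", stacklevel=2)
    pos = 0
    while pos + wlen <= n_t:
        seg = mask[pos : pos + wlen]
        if seg.all():
            starts.append(pos)
            pos += wlen
        else:
            # jump past the last masked sample inside this window
            pos += int(np.nonzero(~seg)[0][-1]) + 1
    idx = np.asarray(starts, dtype=np.int64)
    data = (
        np.stack([recording.samples[:, s : s + wlen] for s in starts])
        if starts
        else np.empty((0, recording.n_channels, wlen))
    )
    return EpochSet(
        data=data,
        fs=recording.fs,
        labels=recording.labels,
        kind="regular",
        window_s=(0.0, length_s),
        baseline_s=None,
        starts=idx,
    )


def extract_cued_epochs(
    recording: Recording,
    events: EventList,
    window_s: tuple[float, float] = (-0.2, 1.0),
    baseline_s: tuple[float, float] | None = (-0.2, 0.0),
) -> EpochSet:
    """Event-locked epochs with per-epoch, per-channel baseline subtraction.

    Epochs overlapping the recording edges or any masked sample are skipped
    (counted in the returned set's bookkeeping via the surviving ``starts``).
    """
    events.validate_against(recording.n_times)
    lo = int(round(window_s[0] * recording.fs))
    hi = int(round(window_s[1] * recording.fs))
    wlen = hi - lo
    starts: list[int] = []
    chunks: list[np.ndarray] = []
    n_skipped = 0
    for s in events.sample_indices:
        a, b = s + lo, s + lo + wlen
        if a < 0 or b > recording.n_times or not recording.mask[a:b].all():
            n_skipped += 1
            continue
        starts.append(a)
        chunks.append(recording.samples[:, a:b])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} cued epochs (edge or artifact overlap)", stacklevel=2)
    data = np.stack(chunks) if chunks else np.empty((0, recording.n_channels, wlen))
    if baseline_s is not None and data.size:
        b0 = int(round((baseline_s[0] - window_s[0]) * recording.fs))
        b1 = int(round((baseline_s[1] - window_s[0]) * recording.fs))
        if not (0 <= b0 < b1 <= wlen):
            raise ValidationError("baseline window must lie inside the epoch window")
        data = data - data[:, :, b0:b1].mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        fs=recording.fs,
        labels=recording.labels,
        kind="cued",
        window_s=window_s,
        baseline_s=baseline_s,
        starts=np.asarray(starts, dtype=np.int64),
    )
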