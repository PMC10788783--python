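"""Synthetic spatio-temporal EEG generator with ground truth.

The generator emulates the statistical structure that scalp EEG benchmarking
analyses rest on, without any biophysical head model:

* each frequency band is a band-limited Gaussian random field over the scalp
  patch, with pairwise correlation given by a Gaussian spatial kernel
  ``K(d) = exp(-(d/lambda)^2)`` whose correlation length ``lambda`` shrinks
  with band frequency (low-frequency topographies are spatially smoother);
* each electrode integrates the field over its contact disc (a fixed 37-point
  hexagonal stencil), so large gelled contacts spatially low-pass the field
  relative to small dry pillars;
* the alpha band is multiplied by a shared two-state (on/off) burst envelope,
  producing the joint power-and-coherence alpha peak seen in real recordings;
* a stereotyped cue-locked potential (positive peak near 200 ms, negative
  near 400 ms) is added at every scheduled vigilance-task probe;
* per-channel sensor noise has variance ``floor^2 + kappa * impedance`` plus
  an independent 1/f stream, with impedances drawn from log-normal models
  whose medians differ by electrode type.

Everything is driven by one integer seed; identical config + seed gives a
bit-identical recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ioformats import (
    DRY,
    GELLED,
    ChannelMeta,
    ElectrodeLayout,
    EventList,
    Recording,
    ValidationError,
)

__all__ = [
    "BandSpec",
    "BurstSpec",
    "ErpComponent",
    "ErpTemplateSpec",
    "NoiseSpec",
    "TrialSpec",
    "ImpedanceModel",
    "GeneratorConfig",
    "SyntheticRecording",
    "DegenerateGeometryError",
    "gen_layout",
    "gen_trial_schedule",
    "gen_recording",
    "gen_impedance",
    "erp_template_waveform",
    "disc_stencil",
    "default_config",
]


class DegenerateGeometryError(RuntimeError):
    """Spatial covariance not factorizable even after jitter."""


@dataclass(frozen=True)
class BandSpec:
    """One spectral band of the background field.

    ``spatial_scale_mm`` is the correlation length lambda of the Gaussian
    kernel K(d) = exp(-(d/lambda)^2); ``source_rms_uv`` is the RMS of the
    band-limited source process before disc integration.
    """

    name: str
    f_lo: float
    f_hi: float
    source_rms_uv: float
    spatial_scale_mm: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(f"band {self.name!r}: need 0 < f_lo < f_hi")
        if self.spatial_scale_mm <= 0:
            raise ValidationError(f"band {self.name!r}: spatial scale must be > 0")
        if self.source_rms_uv < 0:
            raise ValidationError(f"band {self.name!r}: source RMS must be >= 0")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    def kernel(self, d_mm: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-((np.asarray(d_mm, dtype=float) / self.spatial_scale_mm) ** 2))


@dataclass(frozen=True)
class BurstSpec:
    """Two-state Markov on/off amplitude modulation of one band."""

    band: str = "Alpha"
    on_rate_hz: float = 0.5  # rate of leaving the off state
    off_rate_hz: float = 0.5  # rate of leaving the on state
    gain: float = 3.0
    smooth_s: float = 0.1

    def __post_init__(self) -> None:
        if self.gain < 1:
            raise ValidationError("burst gain must be >= 1")
        if self.on_rate_hz <= 0 or self.off_rate_hz <= 0:
            raise ValidationError("burst transition rates must be > 0")


@dataclass(frozen=True)
class ErpComponent:
    latency_ms: float
    width_ms: float  # Gaussian standard deviation
    amplitude_uv: float  # signed


@dataclass(frozen=True)
class ErpTemplateSpec:
    """Cue-locked template: sum of Gaussian bumps (positive ~200 ms, negative ~400 ms)."""

    components: tuple[ErpComponent, ...] = (
        ErpComponent(200.0, 30.0, 4.0),
        ErpComponent(400.0, 50.0, -3.0),
    )
    support_s: float = 0.8  # template extent after the cue


@dataclass(frozen=True)
class NoiseSpec:
    """Per-channel independent sensor noise.

    White-noise variance is ``floor_uv**2 + kappa * impedance`` with the
    impedance in kOhm*cm^2 and kappa in µV² per kOhm*cm²; a separate 1/f
    stream of RMS ``pink_rms_uv`` with exponent ``pink_exponent`` is added.
    """

    floor_uv: float = 1.0
    pink_exponent: float = 1.0
    pink_rms_uv: float = 1.5
    kappa: float = 0.25

    def __post_init__(self) -> None:
        for name in ("floor_uv", "pink_exponent", "pink_rms_uv", "kappa"):
            if getattr(self, name) < 0:
                raise ValidationError(f"noise parameter {name} must be non-negative")


@dataclass(frozen=True)
class TrialSpec:
    """Vigilance-task schedule: variable fixation delay then a probe cue."""

    delay_lo_s: float = 2.0
    delay_hi_s: float = 11.0
    block_s: float = 600.0
    overhead_s: float = 0.5  # response + inter-trial turnaround

    def __post_init__(self) -> None:
        if not (0 < self.delay_lo_s < self.delay_hi_s):
            raise ValidationError("need 0 < delay_lo < delay_hi")
        if self.overhead_s < 0:
            raise ValidationError("overhead must be non-negative")


@dataclass(frozen=True)
class ImpedanceModel:
    """Log-normal area-normalized impedance (kOhm*cm^2) per electrode type."""

    gelled_median: float = 1.107
    gelled_sigma: float = 0.6488  # log-scale; reproduces IQR 1.000 at this median
    dry_median: float = 3.948
    dry_sigma: float = 1.0835  # reproduces IQR 6.298

    def __post_init__(self) -> None:
        if self.gelled_median <= 0 or self.dry_median <= 0:
            raise ValidationError("impedance medians must be positive")
        if self.gelled_sigma < 0 or self.dry_sigma < 0:
            raise ValidationError("impedance dispersions must be non-negative")

    def params(self, kind: str) -> tuple[float, float]:
        if kind == GELLED:
            return self.gelled_median, self.gelled_sigma
        if kind == DRY:
            return self.dry_median, self.dry_sigma
        raise ValidationError(f"unknown electrode type {kind!r}")


def _default_bands() -> tuple[BandSpec, ...]:
    # Source RMS ~ 1/f_center (1/f background); correlation length shrinks
    # with frequency (higher bands carry higher spatial frequencies).
    return (
        BandSpec("Delta", 1.0, 4.0, 5.0, 60.0),
        BandSpec("Theta", 5.0, 7.0, 2.5, 45.0),
        BandSpec("Alpha", 8.0, 12.0, 2.0, 35.0),
        BandSpec("Beta", 13.0, 30.0, 1.0, 20.0),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    fs: float = 2000.0
    duration_s: float = 600.0
    bands: tuple[BandSpec, ...] = field(default_factory=_default_bands)
    burst: BurstSpec | None = field(default_factory=BurstSpec)
    erp: ErpTemplateSpec | None = field(default_factory=ErpTemplateSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    trial: TrialSpec = field(default_factory=TrialSpec)
    impedance: ImpedanceModel = field(default_factory=ImpedanceModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration must be positive")
        if not self.bands:
            raise ValidationError("at least one band is required")
        top = max(b.f_hi for b in self.bands)
        if self.fs <= 2 * top:
            raise ValidationError(
                f"sampling rate {self.fs} Hz must exceed twice the highest band edge ({top} Hz)"
            )
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValidationError("band names must be unique")
        if self.burst is not None and self.burst.band not in names:
            raise ValidationError(f"burst band {self.burst.band!r} not among bands {names}")


def default_config(**overrides) -> GeneratorConfig:
    """The study's default generation conditions (2 kHz, 600 s block)."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


@dataclass
class SyntheticRecording:
    """A generated Recording plus the ground truth used to make it."""

    recording: Recording
    events: EventList
    erp_template: np.ndarray  # (n_times_template,), µV, added on every channel
    erp_times: np.ndarray  # seconds relative to cue, same length
    kernels: dict  # band name -> (n_ch, n_ch) center-to-center K(d)
    effective_corr: dict  # band name -> disc-integrated channel correlation
    noise_variance_uv2: np.ndarray  # per channel (white part)
    impedances_kohm_cm2: np.ndarray  # per channel
    burst_envelope: np.ndarray | None  # shared envelope, or None
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------


def gen_layout(
    pitch_mm: float = 6.0,
    rows: int = 4,
    cols: int = 4,
    reference_offsets_mm: list[tuple[float, float]] | None = None,
    dry_diameter_mm: float = 3.0,
    gelled_diameter_mm: float = 10.0,
) -> ElectrodeLayout:
    """Regular dry grid (row-major from the bottom-left origin) plus gelled references.

    Defaults mirror the benchmark hardware: a 4 x 4 grid of 3 mm dry pillars
    at 6 mm pitch with two 10 mm gelled cups placed ~2 cm outside the array.
    """
    if pitch_mm <= 0:
        raise ValidationError("pitch must be positive")
    if rows < 1 or cols < 1:
        raise ValidationError("rows and cols must be >= 1")
    if reference_offsets_mm is None:
        reference_offsets_mm = [(-20.0, 0.0), (-20.0, 20.0)]
    channels: list[ChannelMeta] = []
    idx = 1
    for r in range(rows):
        for c in range(cols):
            channels.append(
                ChannelMeta(
                    label=f"MX{idx:02d}",
                    kind=DRY,
                    x_mm=c * pitch_mm,
                    y_mm=r * pitch_mm,
                    diameter_mm=dry_diameter_mm,
                )
            )
            idx += 1
    for i, (x, y) in enumerate(reference_offsets_mm, start=1):
        channels.append(
            ChannelMeta(
                label=f"AG{i}",
                kind=GELLED,
                x_mm=float(x),
                y_mm=float(y),
                diameter_mm=gelled_diameter_mm,
            )
        )
    return ElectrodeLayout(channels)


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------


def gen_trial_schedule(
    trial: TrialSpec,
    fs: float,
    seed: int,
    epoch_window_s: tuple[float, float] = (-0.2, 1.0),
    code: str = "cue",
) -> EventList:
    """Cue (probe-onset) times for one task block.

    Inter-cue gaps are ``overhead + U(delay_lo, delay_hi)``; no cue is placed
    closer to either recording edge than the cued-epoch window requires.
    """
    lo, hi = epoch_window_s
    min_trial = trial.delay_lo_s + trial.overhead_s
    if trial.block_s <= min_trial:
        raise ValidationError("block shorter than a single minimal trial")
    if hi - lo >= trial.block_s:
        raise ValidationError("cued-epoch window longer than the block")
    rng = np.random.default_rng(seed)
    times: list[float] = []
    t = max(0.0, -lo)  # leave room for the pre-cue window
    while True:
        t += trial.overhead_s + rng.uniform(trial.delay_lo_s, trial.delay_hi_s)
        if t + hi >= trial.block_s:
            break
        times.append(t)
    idx = np.round(np.asarray(times) * fs).astype(np.int64)
    return EventList(idx, [code] * len(idx))


# ---------------------------------------------------------------------------
# Spatial machinery
# ---------------------------------------------------------------------------


def disc_stencil(diameter_mm: float) -> np.ndarray:
    """37-point hexagonal stencil covering the contact disc (or a single point).

    Rings of 6k points at radii k/3 * R for k = 0..3; deterministic and
    resolution-independent, so disc integration does not depend on any mesh.
    """
    if diameter_mm <= 0:
        return np.zeros((1, 2))
    radius = diameter_mm / 2.0
    pts = [(0.0, 0.0)]
    for k in (1, 2, 3):
        r = radius * k / 3.0
        ang = 2 * np.pi * np.arange(6 * k) / (6 * k)
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    return np.asarray(pts)


def _channel_covariance(layout: ElectrodeLayout, band: BandSpec, point_contacts: bool) -> np.ndarray:
    """Disc-integrated channel covariance: C_ij = mean over stencil pairs of K."""
    stencils = []
    for ch in layout.channels:
        base = disc_stencil(0.0 if point_contacts else ch.diameter_mm)
        stencils.append(base + ch.position[None, :])
    n = len(stencils)
    cov = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            d = np.linalg.norm(stencils[i][:, None, :] - stencils[j][None, :, :], axis=-1)
            cov[i, j] = cov[j, i] = float(np.mean(band.kernel(d)))
    return cov


def _factorize(cov: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(
            "channel covariance is not positive definite even after jitter; "
            "check for coincident electrodes"
        ) from exc


def _bandlimited_noise(rng: np.random.Generator, n_ch: int, n_t: int, fs: float,
                       f_lo: float, f_hi: float) -> np.ndarray:
    """Independent unit-RMS Gaussian series, band-limited to [f_lo, f_hi]."""
    z = rng.standard_normal((n_ch, n_t))
    spec = np.fft.rfft(z, axis=1)
    freqs = np.fft.rfftfreq(n_t, 1.0 / fs)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    spec[:, ~keep] = 0.0
    # analytic power fraction retained by the brick-wall mask
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if n_t % 2 == 0:
        w[-1] = 1.0
    frac = float(np.sum(w[keep]) / np.sum(w))
    if frac <= 0:
        raise ValidationError(f"band [{f_lo}, {f_hi}] Hz contains no DFT bins at this length")
    return np.fft.irfft(spec, n=n_t, axis=1) / np.sqrt(frac)


def _pink_noise(rng: np.random.Generator, n_ch: int, n_t: int, fs: float,
                exponent: float, rms: float, f_floor: float = 0.5) -> np.ndarray:
    """1/f^exponent amplitude-shaped noise, flattened below f_floor, scaled to `rms`."""
    if rms == 0:
        return np.zeros((n_ch, n_t))
    z = rng.standard_normal((n_ch, n_t))
    spec = np.fft.rfft(z, axis=1)
    freqs = np.fft.rfftfreq(n_t, 1.0 / fs)
    shape = 1.0 / np.maximum(freqs, f_floor) ** (exponent / 2.0)
    shape[0] = 0.0  # no DC
    spec *= shape[None, :]
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if n_t % 2 == 0:
        w[-1] = 1.0
    power = float(np.sum(w * shape**2) / np.sum(w))
    return np.fft.irfft(spec, n=n_t, axis=1) * (rms / np.sqrt(power))


def _burst_envelope(rng: np.random.Generator, burst: BurstSpec, n_t: int, fs: float) -> np.ndarray:
    """Shared two-state on/off envelope, smoothed with a moving average."""
    # alternate exponential dwell times; start state drawn from stationary law
    p_on = burst.on_rate_hz / (burst.on_rate_hz + burst.off_rate_hz)
    state = rng.random() < p_on
    env = np.empty(n_t)
    t = 0.0
    pos = 0
    while pos < n_t:
        rate = burst.off_rate_hz if state else burst.on_rate_hz
        dwell = rng.exponential(1.0 / rate)
        # a sub-sample dwell still claims at least one sample so every
        # position is written exactly once
        end = max(min(n_t, int(round((t + dwell) * fs))), pos + 1)
        env[pos:end] = burst.gain if state else 1.0
        pos = end
        t += dwell
        state = not state
    width = max(1, int(round(burst.smooth_s * fs)))
    kernel = np.ones(width) / width
    padded = np.concatenate([env[:1].repeat(width), env, env[-1:].repeat(width)])
    return np.convolve(padded, kernel, mode="same")[width:width + n_t]


def erp_template_waveform(spec: ErpTemplateSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Template samples and their times (s, from cue onset to the support end)."""
    n = int(round(spec.support_s * fs)) + 1
    t = np.arange(n) / fs
    wave = np.zeros(n)
    for comp in spec.components:
        mu = comp.latency_ms / 1000.0
        sig = comp.width_ms / 1000.0
        wave += comp.amplitude_uv * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return wave, t


# ---------------------------------------------------------------------------
# Recording generation
# ---------------------------------------------------------------------------


def gen_impedance(
    model: ImpedanceModel, n: int, kind: str, seed: int | np.random.Generator
) -> np.ndarray:
    """Log-normal area-normalized impedance draws (kOhm*cm^2) for one type."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    median, sigma = model.params(kind)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return median * np.exp(sigma * rng.standard_normal(n))


def gen_recording(
    config: GeneratorConfig,
    layout: ElectrodeLayout,
    events: EventList | None = None,
    point_contacts: bool = False,
) -> SyntheticRecording:
    """Generate a synthetic multichannel recording with full ground truth.

    ``point_contacts=True`` ignores contact diameters (samples the field at
    electrode centers), which makes the pairwise correlation exactly K(d).
    """
    fs = config.fs
    n_t = int(round(config.duration_s * fs))
    n_ch = len(layout.channels)
    rng = np.random.default_rng(config.seed)

    if events is None and config.erp is not None:
        sched = replace(config.trial, block_s=min(config.trial.block_s, config.duration_s))
        events = gen_trial_schedule(
            sched, fs, seed=int(rng.integers(2**31)), epoch_window_s=(-0.2, 1.0)
        )
    elif events is None:
        events = EventList(np.empty(0, dtype=np.int64), [])
    events.validate_against(n_t)

    kernels: dict[str, np.ndarray] = {}
    eff_corr: dict[str, np.ndarray] = {}
    positions = layout.positions()
    dists = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)

    data = np.zeros((n_ch, n_t))
    envelope = None
    for band in config.bands:
        cov = _channel_covariance(layout, band, point_contacts)
        chol = _factorize(cov)
        z = _bandlimited_noise(rng, n_ch, n_t, fs, band.f_lo, band.f_hi)
        comp = band.source_rms_uv * (chol @ z)
        if config.burst is not None and config.burst.band == band.name:
            envelope = _burst_envelope(rng, config.burst, n_t, fs)
            comp = comp * envelope[None, :]
        data += comp
        kernels[band.name] = band.kernel(dists)
        denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        eff_corr[band.name] = cov / denom

    # ERP added identically on every channel (the array spans ~2 cm)
    if config.erp is not None:
        template, t_template = erp_template_waveform(config.erp, fs)
        for s in events.sample_indices:
            end = min(n_t, s + len(template))
            data[:, s:end] += template[None, : end - s]
    else:
        template = np.zeros(0)
        t_template = np.zeros(0)

    impedances = np.empty(n_ch)
    for i, ch in enumerate(layout.channels):
        impedances[i] = gen_impedance(config.impedance, 1, ch.kind, rng)[0]

    noise_var = config.noise.floor_uv**2 + config.noise.kappa * impedances
    white = rng.standard_normal((n_ch, n_t)) * np.sqrt(noise_var)[:, None]
    pink = _pink_noise(
        rng, n_ch, n_t, fs, config.noise.pink_exponent, config.noise.pink_rms_uv
    )
    data += white + pink

    channels = [
        replace(ch, impedance_kohm=float(impedances[i]))
        for i, ch in enumerate(layout.channels)
    ]
    rec = Recording(samples=data, fs=fs, channels=channels)
    return SyntheticRecording(
        recording=rec,
        events=events,
        erp_template=template,
        erp_times=t_template,
        kernels=kernels,
        effective_corr=eff_corr,
        noise_variance_uv2=noise_var,
        impedances_kohm_cm2=impedances,
        burst_envelope=envelope,
        config=config,
    )
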