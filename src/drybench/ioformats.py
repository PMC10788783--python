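"""Core data model and file formats.

Signals travel as EDF (16-bit, physical units µV), events as a two-column
TSV sidecar (``sample_index\\tcode``, 0-based), electrode layouts as JSON,
and impedance measurements as CSV.  All readers validate and fail loudly;
``write_edf`` followed by ``read_edf`` reproduces the samples up to the
16-bit quantization of the declared physical range.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ChannelMeta",
    "Recording",
    "EventList",
    "ElectrodeLayout",
    "read_edf",
    "write_edf",
    "read_events",
    "write_events",
    "read_layout",
    "write_layout",
    "read_impedance",
    "write_impedance",
    "attach_layout",
]

DRY = "dry"
GELLED = "gelled"

#: Default EDF physical range (µV); symmetric, so quantization error is
#: bounded by range/2**15.
DEFAULT_PHYSICAL_RANGE_UV = 1000.0


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Structurally well-formed input violating a domain invariant."""


@dataclass
class ChannelMeta:
    """Per-channel metadata: identity, geometry and bookkeeping."""

    label: str
    kind: str = DRY  # "dry" | "gelled"
    x_mm: float = 0.0
    y_mm: float = 0.0
    diameter_mm: float = 3.0
    impedance_kohm: float | None = None
    status: str = "retained"  # "retained" | "rejected"

    def __post_init__(self) -> None:
        if self.kind not in (DRY, GELLED):
            raise ValidationError(
                f"channel {self.label!r}: kind must be 'dry' or 'gelled', got {self.kind!r}"
            )
        if self.diameter_mm <= 0:
            raise ValidationError(f"channel {self.label!r}: diameter must be > 0")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm], dtype=float)


@dataclass
class Recording:
    """Multichannel EEG: channels × time matrix in µV plus a retained-sample mask.

    The mask starts all-True and is narrowed by artifact rejection; it always
    has one entry per time sample.
    """

    samples: np.ndarray  # (n_channels, n_times), µV
    fs: float
    channels: list[ChannelMeta]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channels × time array")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel metadata entries for "
                f"{self.samples.shape[0]} signal rows"
            )
        if self.mask is None:
            self.mask = np.ones(self.samples.shape[1], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.samples.shape[1],):
                raise ValidationError("mask length must equal the number of samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    @property
    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None

    def get(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def retained_channels(self) -> list[str]:
        return [ch.label for ch in self.channels if ch.status == "retained"]

    def copy(self) -> "Recording":
        return Recording(
            samples=self.samples.copy(),
            fs=self.fs,
            channels=[replace(ch) for ch in self.channels],
            mask=self.mask.copy(),
        )


@dataclass
class EventList:
    """Ordered (sample_index, code) records; indices 0-based and strictly increasing."""

    sample_indices: np.ndarray
    codes: list[str]

    def __post_init__(self) -> None:
        self.sample_indices = np.asarray(self.sample_indices, dtype=np.int64)
        if self.sample_indices.ndim != 1:
            raise ValidationError("sample_indices must be 1-D")
        if len(self.codes) != len(self.sample_indices):
            raise ValidationError("codes and sample_indices must have equal length")
        if len(self.sample_indices) and np.any(self.sample_indices < 0):
            bad = int(self.sample_indices[self.sample_indices < 0][0])
            raise ValidationError(f"negative sample index {bad}")
        if len(self.sample_indices) > 1:
            diffs = np.diff(self.sample_indices)
            if np.any(diffs <= 0):
                at = int(np.argmax(diffs <= 0))
                raise ValidationError(
                    "events must be strictly increasing; record "
                    f"{at + 1} (sample {int(self.sample_indices[at + 1])}) is not "
                    f"after record {at} (sample {int(self.sample_indices[at])})"
                )

    def __len__(self) -> int:
        return len(self.sample_indices)

    def validate_against(self, n_times: int) -> None:
        if len(self) and self.sample_indices[-1] >= n_times:
            raise ValidationError(
                f"event at sample {int(self.sample_indices[-1])} is outside the "
                f"recording ({n_times} samples)"
            )

    def select(self, code: str) -> "EventList":
        keep = [i for i, c in enumerate(self.codes) if c == code]
        return EventList(self.sample_indices[keep], [self.codes[i] for i in keep])


@dataclass
class ElectrodeLayout:
    """Planar electrode geometry: positions (mm), type and contact diameter."""

    channels: list[ChannelMeta]

    def __post_init__(self) -> None:
        labels = [ch.label for ch in self.channels]
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise ValidationError(f"duplicate channel label {lab!r}")
            seen.add(lab)

    @property
    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]

    def __getitem__(self, label: str) -> ChannelMeta:
        for ch in self.channels:
            if ch.label == label:
                return ch
        raise KeyError(f"no channel labelled {label!r}")

    def of_kind(self, kind: str) -> list[ChannelMeta]:
        return [ch for ch in self.channels if ch.kind == kind]

    def positions(self) -> np.ndarray:
        return np.array([[ch.x_mm, ch.y_mm] for ch in self.channels], dtype=float)

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self[a].position - self[b].position))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_ACCEPTED_UNITS = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6}

# EDF stores an integer number of fixed-duration data records; the writer pads
# the last record with zeros and stashes the true sample count in the
# recording-id header field so reads can truncate exactly.
_NSAMP_TAG = "NSAMP="


def _fixed(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width)


def write_edf(
    recording: Recording,
    path: str | Path,
    physical_range_uv: float = DEFAULT_PHYSICAL_RANGE_UV,
) -> None:
    """Write a Recording to a plain 16-bit EDF file (physical units µV).

    Raises :class:`FormatError` if any sample exceeds ``physical_range_uv``
    (the data would be clipped, which we refuse to do silently).
    """
    path = Path(path)
    if physical_range_uv <= 0:
        raise ValueError("physical_range_uv must be positive")
    peak = float(np.max(np.abs(recording.samples))) if recording.samples.size else 0.0
    if peak > physical_range_uv:
        raise FormatError(
            f"sample amplitude {peak:.1f} µV exceeds the physical range "
            f"±{physical_range_uv} µV; raise physical_range_uv"
        )
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs_i = int(round(fs))
    n_ch, n_times = recording.samples.shape
    spr = fs_i  # one-second records
    n_records = max(1, -(-n_times // spr))

    dig_min, dig_max = -32768, 32767
    phys_min, phys_max = -physical_range_uv, physical_range_uv
    gain = (dig_max - dig_min) / (phys_max - phys_min)

    padded = np.zeros((n_ch, n_records * spr), dtype=np.float64)
    padded[:, :n_times] = recording.samples
    digital = np.round((padded - phys_min) * gain + dig_min).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_fixed("0", 8))
        fh.write(_fixed("X X X X", 80))  # patient id (anonymous)
        fh.write(_fixed(f"Startdate X {_NSAMP_TAG}{n_times}", 80))
        fh.write(_fixed("01.01.00", 8))
        fh.write(_fixed("00.00.00", 8))
        fh.write(_fixed(str(256 * (n_ch + 1)), 8))
        fh.write(_fixed("", 44))
        fh.write(_fixed(str(n_records), 8))
        fh.write(_fixed("1", 8))  # record duration, seconds
        fh.write(_fixed(str(n_ch), 4))
        for ch in recording.channels:
            fh.write(_fixed(ch.label, 16))
        for _ in range(n_ch):
            fh.write(_fixed("", 80))  # transducer
        for _ in range(n_ch):
            fh.write(_fixed("uV", 8))
        for _ in range(n_ch):
            fh.write(_fixed(f"{phys_min:.0f}", 8))
        for _ in range(n_ch):
            fh.write(_fixed(f"{phys_max:.0f}", 8))
        for _ in range(n_ch):
            fh.write(_fixed(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_fixed(str(dig_max), 8))
        for _ in range(n_ch):
            fh.write(_fixed("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_fixed(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_fixed("", 32))
        for rec in range(n_records):
            sl = slice(rec * spr, (rec + 1) * spr)
            fh.write(digital[:, sl].tobytes())


def _read_edf_header_units(path: Path) -> tuple[list[str], int | None]:
    """Return per-signal physical dimensions and the stashed true sample count."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        recording_id = head[88:168].decode("ascii", errors="replace")
        try:
            n_ch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: unreadable channel count") from exc
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise FormatError(f"{path}: truncated EDF signal headers")
    units = [
        sig[16 * n_ch + 80 * n_ch + 8 * i : 16 * n_ch + 80 * n_ch + 8 * (i + 1)]
        .decode("ascii", errors="replace")
        .strip()
        for i in range(n_ch)
    ]
    n_true: int | None = None
    if _NSAMP_TAG in recording_id:
        tail = recording_id.split(_NSAMP_TAG, 1)[1].strip()
        token = tail.split()[0] if tail.split() else ""
        if token.isdigit():
            n_true = int(token)
    return units, n_true


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (samples converted to µV).

    Channel kind/position metadata is not carried by EDF; use
    :func:`attach_layout` to merge a layout afterwards.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    units, n_true = _read_edf_header_units(path)
    for lab_i, unit in enumerate(units):
        if unit not in _ACCEPTED_UNITS:
            raise FormatError(
                f"{path}: signal {lab_i} has physical dimension {unit!r}; "
                f"expected one of {sorted(_ACCEPTED_UNITS)}"
            )
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne uses volts internally
    if n_true is not None:
        if n_true > data_uv.shape[1]:
            raise FormatError(f"{path}: declared sample count exceeds stored data")
        data_uv = data_uv[:, :n_true]
    channels = [ChannelMeta(label=lab) for lab in raw.ch_names]
    return Recording(samples=data_uv, fs=float(raw.info["sfreq"]), channels=channels)


def attach_layout(recording: Recording, layout: ElectrodeLayout) -> Recording:
    """Merge geometry/type metadata from a layout into a recording (by label)."""
    out = recording.copy()
    for i, ch in enumerate(out.channels):
        meta = layout[ch.label]  # KeyError names the missing label
        out.channels[i] = replace(
            ch,
            kind=meta.kind,
            x_mm=meta.x_mm,
            y_mm=meta.y_mm,
            diameter_mm=meta.diameter_mm,
            impedance_kohm=meta.impedance_kohm,
        )
    return out


# ---------------------------------------------------------------------------
# Events TSV
# ---------------------------------------------------------------------------


def read_events(path: str | Path) -> EventList:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={"sample_index": np.int64, "code": str})
    except pd.errors.EmptyDataError:
        return EventList(np.empty(0, dtype=np.int64), [])
    for col in ("sample_index", "code"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(table) == 0:
        return EventList(np.empty(0, dtype=np.int64), [])
    try:
        return EventList(table["sample_index"].to_numpy(), table["code"].astype(str).tolist())
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_events(events: EventList, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_index": events.sample_indices, "code": events.codes}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Layout JSON
# ---------------------------------------------------------------------------


def read_layout(path: str | Path) -> ElectrodeLayout:
    path = Path(path)
    with open(path) as fh:
        try:
            entries = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(entries, list):
        raise FormatError(f"{path}: expected a JSON list of channel objects")
    channels = []
    for i, entry in enumerate(entries):
        missing = {"label", "type", "x_mm", "y_mm", "diameter_mm"} - set(entry)
        if missing:
            raise FormatError(f"{path}: entry {i} missing fields {sorted(missing)}")
        channels.append(
            ChannelMeta(
                label=str(entry["label"]),
                kind=str(entry["type"]),
                x_mm=float(entry["x_mm"]),
                y_mm=float(entry["y_mm"]),
                diameter_mm=float(entry["diameter_mm"]),
                impedance_kohm=(
                    float(entry["impedance_kohm"]) if entry.get("impedance_kohm") is not None else None
                ),
            )
        )
    try:
        return ElectrodeLayout(channels)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    entries = []
    for ch in layout.channels:
        entry = {
            "label": ch.label,
            "type": ch.kind,
            "x_mm": ch.x_mm,
            "y_mm": ch.y_mm,
            "diameter_mm": ch.diameter_mm,
        }
        if ch.impedance_kohm is not None:
            entry["impedance_kohm"] = ch.impedance_kohm
        entries.append(entry)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)


# ---------------------------------------------------------------------------
# Impedance CSV
# ---------------------------------------------------------------------------


def read_impedance(path: str | Path) -> pd.DataFrame:
    """Read an impedance table CSV with columns label, kohm[, timepoint]."""
    path = Path(path)
    table = pd.read_csv(path)
    for col in ("label", "kohm"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if "timepoint" not in table.columns:
        table["timepoint"] = "t0"
    if (table["kohm"] <= 0).any():
        bad = table.loc[table["kohm"] <= 0, "label"].iloc[0]
        raise ValidationError(f"{path}: non-positive impedance on channel {bad!r}")
    return table[["label", "kohm", "timepoint"]]


def write_impedance(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
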