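"""Waveform I/O: the canonical ECG record model, CSV interchange, and a
minimal MFER-subset binary format.

The canonical in-memory object is :class:`WaveformRecord`: a mapping of
standard 12-lead names to equal-length amplitude arrays in millivolts,
plus sampling rate, patient id and an optional binary outcome label.
Full-length records carry 5000 samples per lead (10 s at 500 Hz).

Two on-disk representations are supported:

* CSV — UTF-8, header row of lead names, one row per sample, amplitudes in
  millivolts. This is the canonical interchange format.
* MFER subset — a small, fully documented tag-length-value binary format
  (see ``docs/mfer_subset.md``) with its own writer, so binary-format code
  paths are exercisable without hospital exports.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import (
    CapacityError,
    EmptyInputError,
    ParseError,
    TruncationError,
    UnsupportedFormatError,
)

#: The standard 12-lead vocabulary.
LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

#: Outcome labels: 0 = survivor, 1 = non-survivor (death during CCU stay).
SURVIVOR = 0
NON_SURVIVOR = 1

#: Canonical record length: 10 s at 500 Hz.
CANONICAL_SAMPLES = 5000
CANONICAL_RATE_HZ = 500.0


@dataclass
class WaveformRecord:
    """One patient's multi-lead ECG.

    Parameters
    ----------
    patient_id
        Opaque identifier; never interpreted.
    leads
        Mapping lead name -> 1-D float array of amplitudes in millivolts.
        All leads must have equal length and names must come from the
        12-lead vocabulary.
    sampling_rate_hz
        Sampling rate in Hz (default 500).
    label
        Optional binary outcome: 0 survivor, 1 non-survivor, or None.
    """

    patient_id: str
    leads: Mapping[str, np.ndarray]
    sampling_rate_hz: float = CANONICAL_RATE_HZ
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.leads:
            raise EmptyInputError(f"record {self.patient_id!r} has no leads")
        clean: dict[str, np.ndarray] = {}
        lengths = set()
        for name, samples in self.leads.items():
            if name not in LEAD_NAMES:
                raise ParseError(
                    f"unknown lead name {name!r}; expected one of {LEAD_NAMES}")
            arr = np.asarray(samples, dtype=np.float64)
            if arr.ndim != 1:
                raise ParseError(f"lead {name!r} is not a 1-D sequence")
            clean[name] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise ParseError(
                f"record {self.patient_id!r} has ragged leads: lengths {sorted(lengths)}")
        if self.sampling_rate_hz <= 0:
            raise ParseError("sampling_rate_hz must be positive")
        if self.label is not None and self.label not in (SURVIVOR, NON_SURVIVOR):
            raise ParseError(f"label must be 0, 1 or None, got {self.label!r}")
        object.__setattr__(self, "leads", clean)

    @property
    def n_samples(self) -> int:
        return next(iter(self.leads.values())).shape[0]

    @property
    def lead_names(self) -> tuple[str, ...]:
        return tuple(self.leads.keys())

    def equals(self, other: "WaveformRecord", atol_mv: float = 1e-6) -> bool:
        """Amplitude-wise equality within ``atol_mv`` millivolts."""
        if (self.patient_id != other.patient_id
                or set(self.lead_names) != set(other.lead_names)
                or self.label != other.label
                or not np.isclose(self.sampling_rate_hz, other.sampling_rate_hz)):
            return False
        return all(
            self.leads[k].shape == other.leads[k].shape
            and np.allclose(self.leads[k], other.leads[k], atol=atol_mv, rtol=0.0)
            for k in self.lead_names)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_csv_waveform(path: str | Path, patient_id: str,
                      sampling_rate_hz: float = CANONICAL_RATE_HZ,
                      label: int | None = None) -> WaveformRecord:
    """Read a lead-per-column CSV waveform file.

    The header row names the leads; each subsequent row is one sample
    instant, amplitudes in millivolts.

    Raises
    ------
    EmptyInputError
        If the file is empty or has a header but no samples.
    ParseError
        On a ragged or non-numeric row; the message names the offending
        1-based row number.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise EmptyInputError(f"{path} is empty")
    header = [h.strip() for h in lines[0].split(",")]
    if len(lines) == 1:
        raise EmptyInputError(f"{path} has a header but no samples")
    n_cols = len(header)
    columns: list[list[float]] = [[] for _ in header]
    for row_no, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != n_cols:
            raise ParseError(
                f"{path}: row {row_no} has {len(cells)} cells, expected {n_cols}")
        for col, cell in zip(columns, cells):
            try:
                col.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: row {row_no} has non-numeric cell {cell.strip()!r}") from None
    leads = {name: np.array(col) for name, col in zip(header, columns)}
    return WaveformRecord(patient_id=patient_id, leads=leads,
                          sampling_rate_hz=sampling_rate_hz, label=label)


def write_csv_waveform(record: WaveformRecord, path: str | Path) -> None:
    """Write ``record`` as a lead-per-column CSV (header = lead names)."""
    path = Path(path)
    names = record.lead_names
    data = np.column_stack([record.leads[n] for n in names])
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(names) + "\n")
        for row in data:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# MFER subset (tag-length-value binary; layout in docs/mfer_subset.md)
# ---------------------------------------------------------------------------

MFER_PREAMBLE = b"MFER-SUBSET/1.0"

TAG_PREAMBLE = 0x40
TAG_CHANNELS = 0x04
TAG_DATA_TYPE = 0x05
TAG_SAMPLING_INTERVAL = 0x0B
TAG_RESOLUTION = 0x0C
TAG_PATIENT_ID = 0x12
TAG_LABEL = 0x16
TAG_LEAD_NAME = 0x09
TAG_WAVEFORM = 0x1E

_MANDATORY_TAGS = {TAG_PREAMBLE, TAG_CHANNELS, TAG_DATA_TYPE,
                   TAG_SAMPLING_INTERVAL, TAG_RESOLUTION, TAG_PATIENT_ID,
                   TAG_LEAD_NAME, TAG_WAVEFORM, TAG_LABEL}

DATA_TYPE_INT16 = 0
DATA_TYPE_INT32 = 1
_SAMPLE_DTYPES = {DATA_TYPE_INT16: "<i2", DATA_TYPE_INT32: "<i4"}
_SAMPLE_LIMITS = {DATA_TYPE_INT16: 2 ** 15 - 1, DATA_TYPE_INT32: 2 ** 31 - 1}

#: Writer default: 1e-6 mV per least-significant bit, stored as int32.
DEFAULT_RESOLUTION_MV = 1e-6
_MAX_BLOCK_BYTES = 2 ** 32 - 1


def _tlv(tag: int, value: bytes) -> bytes:
    if len(value) > _MAX_BLOCK_BYTES:
        raise CapacityError(
            f"value for tag 0x{tag:02X} exceeds the 32-bit length field")
    return struct.pack("<BI", tag, len(value)) + value


def write_mfer_fixture(record: WaveformRecord, path: str | Path,
                       resolution_mv: float = DEFAULT_RESOLUTION_MV,
                       data_type: int = DATA_TYPE_INT32) -> None:
    """Serialize ``record`` to the documented MFER subset.

    Amplitudes are quantized to integer multiples of ``resolution_mv``
    (little-endian int32 by default, so the default 1e-6 mV resolution
    round-trips within quantization error). Deterministic: the same record
    always yields the same bytes.

    Raises
    ------
    CapacityError
        If an amplitude does not fit the integer sample type at the chosen
        resolution, or a lead exceeds the 32-bit block length.
    """
    if data_type not in _SAMPLE_DTYPES:
        raise UnsupportedFormatError(f"unknown data type code {data_type}")
    if record.n_samples == 0:
        raise EmptyInputError(
            f"record {record.patient_id!r} has zero-length leads")
    limit = _SAMPLE_LIMITS[data_type]
    dtype = _SAMPLE_DTYPES[data_type]

    buf = io.BytesIO()
    buf.write(_tlv(TAG_PREAMBLE, MFER_PREAMBLE))
    buf.write(_tlv(TAG_CHANNELS, struct.pack("<H", len(record.lead_names))))
    buf.write(_tlv(TAG_DATA_TYPE, struct.pack("<B", data_type)))
    buf.write(_tlv(TAG_SAMPLING_INTERVAL,
                   struct.pack("<d", 1.0 / record.sampling_rate_hz)))
    buf.write(_tlv(TAG_RESOLUTION, struct.pack("<d", resolution_mv)))
    buf.write(_tlv(TAG_PATIENT_ID, record.patient_id.encode("utf-8")))
    if record.label is not None:
        buf.write(_tlv(TAG_LABEL, struct.pack("<B", record.label)))
    for name in record.lead_names:
        samples = record.leads[name]
        quantized = np.round(samples / resolution_mv)
        if np.any(np.abs(quantized) > limit):
            raise CapacityError(
                f"lead {name!r} amplitude exceeds sample type at "
                f"resolution {resolution_mv} mV/LSB")
        buf.write(_tlv(TAG_LEAD_NAME, name.encode("utf-8")))
        buf.write(_tlv(TAG_WAVEFORM, quantized.astype(dtype).tobytes()))
    Path(path).write_bytes(buf.getvalue())


def read_mfer_subset(path: str | Path) -> WaveformRecord:
    """Decode a file written in the documented MFER subset.

    Raises
    ------
    UnsupportedFormatError
        If the file does not start with the subset preamble, or an
        unrecognized mandatory tag (high bit clear) is encountered.
    TruncationError
        If a declared value runs past end-of-file or fewer waveform blocks
        than declared channels are present.
    EmptyInputError
        If the file declares zero channels.
    """
    raw = Path(path).read_bytes()
    pos = 0
    n_channels: int | None = None
    data_type: int | None = None
    interval_s: float | None = None
    resolution_mv: float | None = None
    patient_id: str | None = None
    label: int | None = None
    pending_lead: str | None = None
    leads: dict[str, np.ndarray] = {}
    saw_preamble = False

    def take(n: int, what: str) -> bytes:
        nonlocal pos
        if pos + n > len(raw):
            raise TruncationError(f"{path}: truncated while reading {what}")
        chunk = raw[pos:pos + n]
        pos += n
        return chunk

    first = True
    while pos < len(raw):
        tag, length = struct.unpack("<BI", take(5, "tag header"))
        value = take(length, f"value of tag 0x{tag:02X}")
        if first:
            if tag != TAG_PREAMBLE or value != MFER_PREAMBLE:
                raise UnsupportedFormatError(
                    f"{path}: missing MFER-subset preamble")
            saw_preamble = True
            first = False
            continue
        if tag == TAG_CHANNELS:
            (n_channels,) = struct.unpack("<H", value)
        elif tag == TAG_DATA_TYPE:
            (data_type,) = struct.unpack("<B", value)
            if data_type not in _SAMPLE_DTYPES:
                raise UnsupportedFormatError(
                    f"{path}: unknown data type code {data_type}")
        elif tag == TAG_SAMPLING_INTERVAL:
            (interval_s,) = struct.unpack("<d", value)
        elif tag == TAG_RESOLUTION:
            (resolution_mv,) = struct.unpack("<d", value)
        elif tag == TAG_PATIENT_ID:
            patient_id = value.decode("utf-8")
        elif tag == TAG_LABEL:
            (label,) = struct.unpack("<B", value)
        elif tag == TAG_LEAD_NAME:
            pending_lead = value.decode("utf-8")
        elif tag == TAG_WAVEFORM:
            if pending_lead is None:
                raise UnsupportedFormatError(
                    f"{path}: waveform block without a preceding lead name")
            if data_type is None or resolution_mv is None:
                raise UnsupportedFormatError(
                    f"{path}: waveform block before data-type/resolution tags")
            ints = np.frombuffer(value, dtype=_SAMPLE_DTYPES[data_type])
            leads[pending_lead] = ints.astype(np.float64) * resolution_mv
            pending_lead = None
        elif tag & 0x80:
            continue  # optional/private tag range: skip
        else:
            raise UnsupportedFormatError(
                f"{path}: unknown mandatory tag 0x{tag:02X}")

    if not saw_preamble:
        raise UnsupportedFormatError(f"{path}: empty or preamble-less file")
    for name, val in (("channel count", n_channels), ("sampling interval", interval_s),
                      ("resolution", resolution_mv), ("patient id", patient_id)):
        if val is None:
            raise UnsupportedFormatError(f"{path}: missing {name} tag")
    if n_channels == 0:
        raise EmptyInputError(f"{path}: declares zero channels")
    if len(leads) < n_channels:
        raise TruncationError(
            f"{path}: declared {n_channels} channels but found {len(leads)} "
            "waveform blocks")
    return WaveformRecord(patient_id=patient_id, leads=leads,
                          sampling_rate_hz=1.0 / interval_s, label=label)
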