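"""Beat input/output: WFDB records, segmentation, label schemes, text fixtures.

Real recordings arrive as WFDB record triples (``.hea`` header, ``.dat``
signal, ``.atr`` beat annotations) — e.g. the MIT-BIH Arrhythmia Database
records sampled at 360 Hz.  A beat is a fixed window around an annotated
R peak: 90 samples before the peak, the peak, and 144 after it (235 total
by default); annotations whose window would cross a signal boundary are
dropped rather than padded.

This module ships its own small WFDB reader covering the subset the
pipeline needs: single-segment records, signal formats 212 (packed 12-bit
pairs, the MIT-BIH format) and 16 (little-endian int16), and MIT-format
annotation files restricted to beat annotations.  A matching writer exists
so synthetic fixtures can be produced and round-tripped.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeatRecord",
    "SegmentationConfig",
    "BEAT_SYMBOLS",
    "AAMI_GROUPS",
    "read_wfdb_record",
    "write_wfdb_record",
    "segment_beats",
    "map_to_aami",
    "load_fixture",
    "save_fixture",
]

#: The 16 beat-type symbols (single-letter denotations; W is the
#: ventricular flutter wave, WFDB symbol '!', P the paced beat, WFDB '/').
BEAT_SYMBOLS = ("N", "L", "R", "A", "V", "a", "J", "S", "F", "W", "e", "j", "E", "P", "f", "Q")

# MIT annotation code <-> beat symbol, for the codes that are beats.
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "P", 13: "Q", 31: "W", 34: "e", 38: "f",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}

#: AAMI EC57 five-class grouping of the 15 covered beat types.
AAMI_GROUPS = {
    "NonEctopic": ("N", "L", "R", "e", "j"),
    "SupraVentricularEctopic": ("a", "A", "S", "J"),
    "VentricularEctopic": ("E", "V"),
    "Fusion": ("F",),
    "Unknown": ("Q", "P", "f"),
}
_SYMBOL_TO_AAMI = {s: g for g, symbols in AAMI_GROUPS.items() for s in symbols}


@dataclass
class BeatRecord:
    """One fixed-length beat waveform with its class label and provenance."""

    samples: np.ndarray
    label: str
    record_id: str | None = None
    r_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass(frozen=True)
class SegmentationConfig:
    """Window around the annotated R peak: ``[r - pre, r + post]`` inclusive."""

    pre: int = 90
    post: int = 144

    def __post_init__(self) -> None:
        if self.pre < 0 or self.post < 0:
            raise ValueError("pre and post must be >= 0")

    @property
    def length(self) -> int:
        return self.pre + 1 + self.post


# ---------------------------------------------------------------------------
# Minimal WFDB reader / writer
# ---------------------------------------------------------------------------

def _parse_header(hea_path: str):
    with open(hea_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty WFDB header: {hea_path}")
    rec_tokens = lines[0].split()
    name = rec_tokens[0].split("/")[0]
    n_sig = int(rec_tokens[1])
    fs = float(rec_tokens[2]) if len(rec_tokens) > 2 else 250.0
    n_samp = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        fname = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, None
        if len(tok) > 2:
            gspec = tok[2].split("/")[0]
            if "(" in gspec:
                gpart, bpart = gspec.split("(")
                gain = float(gpart) if gpart else 200.0
                baseline = int(bpart.rstrip(")"))
            else:
                gain = float(gspec) if gspec else 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        if gain == 0:
            gain = 200.0
        signals.append({"file": fname, "fmt": fmt, "gain": gain, "baseline": baseline})
    return {"name": name, "n_sig": n_sig, "fs": fs, "n_samp": n_samp, "signals": signals}


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    """Unpack format 212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = len(b) // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
    second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
    out = np.empty(2 * n_pairs, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096
    return out[:n_values]


def _encode_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if len(v) % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v).astype(np.uint32)
    first, second = v[0::2], v[1::2]
    out = np.empty((len(first), 3), dtype=np.uint8)
    out[:, 0] = first & 0xFF
    out[:, 1] = ((first >> 8) & 0x0F) | (((second >> 8) & 0x0F) << 4)
    out[:, 2] = second & 0xFF
    return out.tobytes()


def _read_annotations(atr_path: str) -> list[tuple[int, str]]:
    """MIT-format annotation stream -> [(sample_index, beat_symbol), ...]."""
    with open(atr_path, "rb") as fh:
        raw = fh.read()
    words = np.frombuffer(raw[: len(raw) // 2 * 2], dtype="<u2")
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i < len(words):
        word = int(words[i])
        code, value = word >> 10, word & 0x3FF
        i += 1
        if word == 0:
            break
        if code == 59:  # SKIP: 4-byte interval, high word first
            if i + 1 >= len(words):
                raise ValueError(f"truncated SKIP in annotation file {atr_path}")
            interval = (int(words[i]) << 16) | int(words[i + 1])
            if interval >= 1 << 31:
                interval -= 1 << 32
            t += interval
            i += 2
        elif code == 63:  # AUX: `value` bytes of text, padded to even
            i += (value + 1) // 2
        elif code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        else:
            t += value
            if code in _CODE_TO_SYMBOL:
                out.append((t, _CODE_TO_SYMBOL[code]))
    return out


def _write_annotations(atr_path: str, annotations: list[tuple[int, str]]) -> None:
    words = bytearray()
    t_prev = 0
    for index, symbol in annotations:
        if symbol not in _SYMBOL_TO_CODE:
            raise ValueError(f"unknown beat symbol {symbol!r}")
        dt = index - t_prev
        if dt < 0:
            raise ValueError("annotation indices must be non-decreasing")
        if dt > 1023:
            words += struct.pack("<H", 59 << 10)
            words += struct.pack("<HH", (dt >> 16) & 0xFFFF, dt & 0xFFFF)
            dt = 0
        words += struct.pack("<H", (_SYMBOL_TO_CODE[symbol] << 10) | dt)
        t_prev = index
    words += struct.pack("<H", 0)
    with open(atr_path, "wb") as fh:
        fh.write(bytes(words))


def read_wfdb_record(path: str, channel: int = 0):
    """Read one channel and the beat annotations of a WFDB record.

    ``path`` is the record path without extension (``.hea``, ``.dat`` and
    ``.atr`` files must sit beside it).  Returns ``(signal, annotations)``
    where ``signal`` is the channel in physical units and ``annotations``
    is a list of ``(r_index, symbol)`` beat annotations in non-decreasing
    index order.  Channel 0 corresponds to the first signal (lead MLII in
    most MIT-BIH records), channel 1 to the second (usually V1).
    """
    header = _parse_header(path + ".hea")
    if not 0 <= channel < header["n_sig"]:
        raise ValueError(
            f"channel {channel} out of range for record with {header['n_sig']} signal(s)"
        )
    atr_path = path + ".atr"
    if not os.path.exists(atr_path):
        raise FileNotFoundError(f"missing annotation file: {atr_path}")

    sig_dir = os.path.dirname(path)
    n_sig = header["n_sig"]
    # All signals of the supported records share one .dat file.
    dat_path = os.path.join(sig_dir, header["signals"][0]["file"])
    fmt = header["signals"][0]["fmt"]
    with open(dat_path, "rb") as fh:
        raw = fh.read()
    if fmt == 212:
        flat = _decode_212(raw, n_values=(len(raw) // 3) * 2)
    elif fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt} (supported: 212, 16)")
    n_samp = header["n_samp"] or len(flat) // n_sig
    adc = flat[: n_samp * n_sig].reshape(n_samp, n_sig)[:, channel]
    spec = header["signals"][channel]
    signal = (adc - spec["baseline"]) / spec["gain"]
    annotations = _read_annotations(atr_path)
    return signal, annotations


def write_wfdb_record(
    path: str,
    signals: np.ndarray,
    annotations: list[tuple[int, str]],
    fs: float = 360.0,
    fmt: int = 16,
    gain: float = 200.0,
) -> None:
    """Write a small WFDB record (fixture/synthetic use).

    ``signals`` is (n_samples, n_channels) in physical units; samples are
    quantized with ``gain`` ADC units per physical unit.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] < signals.shape[1]:
        signals = signals.T
    n_samp, n_sig = signals.shape
    name = os.path.basename(path)
    adc = np.rint(signals * gain).astype(np.int32)
    with open(path + ".hea", "w") as fh:
        fh.write(f"{name} {n_sig} {fs:g} {n_samp}\n")
        for ch in range(n_sig):
            fh.write(f"{name}.dat {fmt} {gain:g}(0) 12 0 {adc[0, ch]} 0 0 ch{ch}\n")
    flat = adc.reshape(-1)  # sample-interleaved
    if fmt == 16:
        data = flat.astype("<i2").tobytes()
    elif fmt == 212:
        data = _encode_212(flat)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt} (supported: 212, 16)")
    with open(path + ".dat", "wb") as fh:
        fh.write(data)
    _write_annotations(path + ".atr", annotations)


# ---------------------------------------------------------------------------
# Segmentation and label schemes
# ---------------------------------------------------------------------------

def segment_beats(
    signal: np.ndarray,
    annotations: list[tuple[int, str]],
    config: SegmentationConfig = SegmentationConfig(),
    record_id: str | None = None,
) -> list[BeatRecord]:
    """Cut one beat window per annotation, dropping boundary violators.

    A beat is emitted only when the full window fits inside the signal:
    ``r_index >= pre`` and ``r_index + post < len(signal)``.  Dropping is
    the contract (beats with inadequate samples before the first or after
    the last annotated complex are neglected), not an error.
    """
    signal = np.asarray(signal, dtype=float)
    out = []
    for r_index, symbol in annotations:
        if r_index >= config.pre and r_index + config.post < len(signal):
            window = signal[r_index - config.pre : r_index + config.post + 1]
            out.append(
                BeatRecord(
                    samples=window.copy(),
                    label=symbol,
                    record_id=record_id,
                    r_index=int(r_index),
                )
            )
    return out


def map_to_aami(symbol: str) -> str:
    """Map a beat symbol to its AAMI EC57 five-class group.

    The flutter-wave symbol W is outside the 15 types the AAMI grouping
    covers and raises, as does any unknown symbol.
    """
    try:
        return _SYMBOL_TO_AAMI[symbol]
    except KeyError:
        valid = sorted(_SYMBOL_TO_AAMI)
        raise ValueError(
            f"symbol {symbol!r} has no AAMI group; valid symbols: {valid}"
        ) from None


# ---------------------------------------------------------------------------
# Delimited-text fixtures
# ---------------------------------------------------------------------------

def save_fixture(records: list[BeatRecord], path: str) -> None:
    """Write beats as delimited text: one row per beat, label first."""
    with open(path, "w") as fh:
        for rec in records:
            values = ",".join(f"{v:.17g}" for v in rec.samples)
            fh.write(f"{rec.label},{values}\n")


def load_fixture(path: str, expected_length: int | None = None) -> list[BeatRecord]:
    """Read beats from delimited text (label first, then samples).

    Rows must all have the same sample count (the first row sets it unless
    ``expected_length`` is given); a ragged row raises with its 1-based row
    number.  An empty file yields an empty list.
    """
    records: list[BeatRecord] = []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            label, values = fields[0], fields[1:]
            if expected_length is None:
                expected_length = len(values)
            if len(values) != expected_length:
                raise ValueError(
                    f"row {row_no}: expected {expected_length} samples, got {len(values)}"
                )
            records.append(
                BeatRecord(samples=np.array([float(v) for v in values]), label=label)
            )
    return records
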