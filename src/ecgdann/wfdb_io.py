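"""Minimal reader/writer for WFDB-format ECG records.

Supports the subset of the MIT signal/annotation formats this package
produces and consumes: format-16 (little-endian 16-bit) signal files,
plain-text ``.hea`` headers, and MIT-format annotation files holding
beat locations and symbols.  Physical units are recovered as
``(adc - baseline) / gain``.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass

import numpy as np

# MIT annotation type codes <-> display symbols (beat annotations only).
_CODE_TO_SYMBOL = {
    1: "N",   # normal
    2: "L",   # left bundle branch block
    3: "R",   # right bundle branch block
    4: "a",   # aberrated atrial premature
    5: "V",   # premature ventricular contraction
    6: "F",   # fusion of ventricular and normal
    7: "J",   # nodal (junctional) premature
    8: "A",   # atrial premature
    9: "S",   # supraventricular premature
    10: "E",  # ventricular escape
    11: "j",  # nodal (junctional) escape
    12: "/",  # paced
    13: "Q",  # unclassifiable
    34: "e",  # atrial escape
    38: "f",  # fusion of paced and normal
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP = 59   # long time-interval escape
_NUM = 60
_SUB = 61
_CHN = 62
_AUX = 63


class WfdbFormatError(ValueError):
    """Raised when a header, signal or annotation file cannot be parsed."""


@dataclass
class SignalInfo:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    description: str


def _header_path(prefix: str) -> str:
    return prefix + ".hea"


def read_header(prefix: str) -> tuple[str, int, float, int, list[SignalInfo]]:
    """Parse a ``.hea`` file -> (record name, n_sig, fs, n_samples, signals)."""
    path = _header_path(prefix)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise WfdbFormatError(f"empty header: {path}")
    head = lines[0].split()
    if len(head) < 4:
        raise WfdbFormatError(f"malformed record line: {lines[0]!r}")
    name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    signals: list[SignalInfo] = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise WfdbFormatError(f"malformed signal line: {ln!r}")
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, 0, "mV"
        if len(tok) > 2:
            gfield = tok[2]
            if "/" in gfield:
                gfield, units = gfield.split("/", 1)
            if "(" in gfield:
                gpart, bpart = gfield.split("(")
                gain = float(gpart)
                baseline = int(bpart.rstrip(")"))
            else:
                gain = float(gfield)
        if gain == 0:
            gain = 200.0  # WFDB convention: 0 means default
        description = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(SignalInfo(tok[0], fmt, gain, baseline, units, description))
    return name, n_sig, fs, n_samples, signals


def read_record(prefix: str) -> dict:
    """Read a WFDB record -> dict with physical ``signal`` (n, n_sig), ``fs``,
    ``sig_names`` and ``n_samples``."""
    name, n_sig, fs, n_samples, signals = read_header(prefix)
    fmts = {s.fmt for s in signals}
    if fmts != {16}:
        raise WfdbFormatError(f"unsupported signal format(s) {fmts}; only 16 supported")
    dat_path = os.path.join(os.path.dirname(prefix), signals[0].file_name)
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size < n_samples * n_sig:
        raise WfdbFormatError(
            f"{dat_path}: expected {n_samples * n_sig} samples, found {raw.size}"
        )
    digital = raw[: n_samples * n_sig].reshape(n_samples, n_sig)
    physical = np.empty((n_samples, n_sig), dtype=np.float64)
    for j, s in enumerate(signals):
        physical[:, j] = (digital[:, j].astype(np.float64) - s.baseline) / s.gain
    return {
        "record_name": name,
        "fs": fs,
        "n_samples": n_samples,
        "sig_names": [s.description for s in signals],
        "signal": physical,
    }


def write_record(
    prefix: str,
    signal: np.ndarray,
    fs: float,
    sig_names: list[str] | None = None,
    gain: float = 200.0,
) -> None:
    """Write physical ``signal`` (n,) or (n, n_sig) as a format-16 record."""
    sig = np.asarray(signal, dtype=np.float64)
    if sig.ndim == 1:
        sig = sig[:, None]
    n, n_sig = sig.shape
    if sig_names is None:
        sig_names = [f"sig{j}" for j in range(n_sig)]
    if len(sig_names) != n_sig:
        raise ValueError("sig_names length mismatch")
    digital = np.clip(np.rint(sig * gain), -32768, 32767).astype("<i2")
    name = os.path.basename(prefix)
    dat_name = name + ".dat"
    digital.reshape(-1).tofile(os.path.join(os.path.dirname(prefix) or ".", dat_name))
    with open(_header_path(prefix), "w") as fh:
        fh.write(f"{name} {n_sig} {fs:g} {n}\n")
        for j in range(n_sig):
            checksum = int(np.sum(digital[:, j].astype(np.int64)) % 65536)
            if checksum >= 32768:
                checksum -= 65536
            fh.write(
                f"{dat_name} 16 {gain:g}(0)/mV 16 0 "
                f"{int(digital[0, j])} {checksum} 0 {sig_names[j]}\n"
            )


def read_annotations(prefix: str, ext: str = "atr") -> tuple[np.ndarray, list[str]]:
    """Read an MIT-format annotation file -> (sample indices, symbols)."""
    path = f"{prefix}.{ext}"
    data = np.fromfile(path, dtype="<u2")
    samples: list[int] = []
    symbols: list[str] = []
    t = 0
    i = 0
    while i < data.size:
        word = int(data[i])
        code = word >> 10
        delta = word & 0x3FF
        i += 1
        if word == 0:
            break
        if code == _SKIP:
            if i + 1 >= data.size:
                raise WfdbFormatError(f"{path}: truncated SKIP")
            interval = (int(data[i]) << 16) | int(data[i + 1])
            if interval >= 1 << 31:
                interval -= 1 << 32
            i += 2
            t += interval
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += (delta + 1) // 2  # skip aux string bytes
            continue
        t += delta
        samples.append(t)
        symbols.append(_CODE_TO_SYMBOL.get(code, "Q"))
    return np.asarray(samples, dtype=np.int64), symbols


def write_annotations(
    prefix: str, samples: np.ndarray, symbols: list[str], ext: str = "atr"
) -> None:
    """Write beat annotations in MIT format; unknown symbols stored as 'Q'."""
    samples = np.asarray(samples, dtype=np.int64)
    if samples.size != len(symbols):
        raise ValueError("samples/symbols length mismatch")
    if samples.size and np.any(np.diff(samples) < 0):
        raise ValueError("annotation samples must be non-decreasing")
    out = bytearray()
    t = 0
    for s, sym in zip(samples, symbols):
        delta = int(s) - t
        if delta > 1023 or delta < 0:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        code = _SYMBOL_TO_CODE.get(sym, _SYMBOL_TO_CODE["Q"])
        out += struct.pack("<H", (code << 10) | delta)
        t = int(s)
    out += struct.pack("<H", 0)
    with open(f"{prefix}.{ext}", "wb") as fh:
        fh.write(out)
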