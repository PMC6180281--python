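"""Minimal self-contained EDF (European Data Format) reader.

Supports the plain EDF variant: ASCII fixed-width headers and 16-bit
little-endian samples, all channels at a common sampling rate.  Annotation
channels and variable per-channel rates are rejected as unsupported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .types import Recording

__all__ = ["read_edf", "EDFFormatError"]


class EDFFormatError(ValueError):
    """Malformed or unsupported EDF content."""


def _ascii_field(raw: bytes, what: str) -> str:
    try:
        return raw.decode("ascii").strip()
    except UnicodeDecodeError as exc:
        raise EDFFormatError(f"non-ASCII bytes in EDF header field {what}") from exc


def _float_field(raw: bytes, what: str) -> float:
    text = _ascii_field(raw, what)
    try:
        return float(text)
    except ValueError as exc:
        raise EDFFormatError(f"EDF header field {what} is not numeric: {text!r}") from exc


def read_edf(
    path: str | Path,
    subject_id: str = "",
    session_id: str = "",
    group: str = "HC",
) -> Recording:
    """Read an EDF file into a Recording, applying the physical calibration
    from the per-signal headers."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise EDFFormatError("file shorter than the 256-byte EDF header")
    header = raw[:256]
    header_bytes = int(_float_field(header[184:192], "header size"))
    n_records = int(_float_field(header[236:244], "number of records"))
    record_duration = _float_field(header[244:252], "record duration")
    ns = int(_float_field(header[252:256], "signal count"))
    if ns < 1:
        raise EDFFormatError("EDF header declares no signals")
    if header_bytes != 256 + ns * 256:
        raise EDFFormatError(
            f"inconsistent header size {header_bytes} for {ns} signals"
        )
    if len(raw) < header_bytes:
        raise EDFFormatError("truncated EDF: signal headers incomplete")

    sig = raw[256:header_bytes]

    def field(offset: int, width: int, i: int) -> bytes:
        start = offset * ns + width * i
        return sig[start : start + width]

    labels = [_ascii_field(field(0, 16, i), "label") for i in range(ns)]
    if any("EDF Annotations" in lab for lab in labels):
        raise EDFFormatError("EDF+ annotation channels are unsupported")
    phys_min = [_float_field(field(104, 8, i), "physical min") for i in range(ns)]
    phys_max = [_float_field(field(112, 8, i), "physical max") for i in range(ns)]
    dig_min = [_float_field(field(120, 8, i), "digital min") for i in range(ns)]
    dig_max = [_float_field(field(128, 8, i), "digital max") for i in range(ns)]
    spr = [int(_float_field(field(216, 8, i), "samples per record")) for i in range(ns)]

    if len(set(spr)) != 1:
        raise EDFFormatError(
            f"mismatched per-channel sampling rates (samples per record {sorted(set(spr))})"
        )
    nspr = spr[0]
    if record_duration <= 0:
        raise EDFFormatError("non-positive record duration")
    fs = nspr / record_duration

    expected = header_bytes + n_records * ns * nspr * 2
    if n_records < 0:  # -1 means "unknown": infer from file size
        body = len(raw) - header_bytes
        if body % (ns * nspr * 2):
            raise EDFFormatError("truncated EDF: partial data record")
        n_records = body // (ns * nspr * 2)
    elif len(raw) < expected:
        raise EDFFormatError(
            f"truncated EDF: expected {expected} bytes, file has {len(raw)}"
        )

    samples = np.frombuffer(
        raw, dtype="<i2", count=n_records * ns * nspr, offset=header_bytes
    )
    # records x signals x samples-per-record -> signals x time
    digital = samples.reshape(n_records, ns, nspr).transpose(1, 0, 2).reshape(ns, -1)
    data = np.empty(digital.shape)
    for i in range(ns):
        d_span = dig_max[i] - dig_min[i]
        if d_span == 0:
            raise EDFFormatError(f"signal {labels[i]!r}: zero digital span")
        gain = (phys_max[i] - phys_min[i]) / d_span
        data[i] = (digital[i] - dig_min[i]) * gain + phys_min[i]
    return Recording(
        subject_id=subject_id,
        session_id=session_id,
        group=group,
        fs=fs,
        channels=tuple(labels),
        data=data,
    )
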