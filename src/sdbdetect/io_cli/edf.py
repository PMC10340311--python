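"""Minimal EDF (European Data Format) writer/reader.

Supports what the pipeline needs: multiple channels with integer sampling
rates, 1-second data records, int16 samples with physical scaling.  No
EDF+ annotations.  Implemented here because no EDF library is available in
the execution environment.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from ..core import SampledSignal

_HDR = 256
_SIG_HDR = 256


def _field(value: object, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ascii characters")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, channels: dict[str, SampledSignal], patient_id: str = "X") -> None:
    """Write named channels to an EDF file (record duration 1 s).

    Each channel's sampling rate must be a positive integer.
    """
    labels = list(channels)
    sigs = [channels[k] for k in labels]
    rates = []
    for lab, s in zip(labels, sigs):
        if abs(s.fs - round(s.fs)) > 1e-9 or s.fs < 1:
            raise ValueError(f"channel {lab!r}: EDF writer needs an integer sampling rate")
        rates.append(int(round(s.fs)))
    n_records = max(int(math.ceil(s.values.size / r)) for s, r in zip(sigs, rates))
    ns = len(labels)

    def phys_str(v: float, up: bool) -> tuple[str, float]:
        # the header field is 8 ascii chars; round *outward* until it fits
        # and scale with the value the reader will actually parse back
        sign = 1.0 if up else -1.0
        for fmt in (".6g", ".5g", ".4g", ".3g", ".2g", ".1e"):
            txt = format(v, fmt)
            if len(txt) > 8:
                continue
            parsed = float(txt)
            if parsed == v or (parsed > v) == up:
                return txt, parsed
            delta = max(abs(parsed - v), abs(v) * 1e-9, 1e-300)
            for _ in range(60):  # grow past one ulp of this representation
                txt = format(v + sign * delta, fmt)
                if len(txt) <= 8:
                    parsed = float(txt)
                    if parsed == v or (parsed > v) == up:
                        return txt, parsed
                delta *= 2.0
        raise ValueError(f"cannot encode physical bound {v}")

    digital = []
    phys = []
    for s in sigs:
        lo, hi = float(np.min(s.values)), float(np.max(s.values))
        if hi <= lo:
            hi = lo + 1.0
        span = hi - lo
        smin, pmin = phys_str(lo - 1e-4 * span, up=False)
        smax, pmax = phys_str(hi + 1e-4 * span, up=True)
        if pmax <= pmin:
            raise ValueError(
                "physical range collapsed in the 8-char EDF header fields; "
                "rescale the channel before writing"
            )
        scale = 65535.0 / (pmax - pmin)
        d = np.round((s.values - pmin) * scale - 32768.0).astype(np.int16)
        digital.append(d)
        phys.append((smin, smax))

    with open(path, "wb") as f:
        f.write(_field("0", 8))
        f.write(_field(patient_id, 80))
        f.write(_field("synthetic recording", 80))
        f.write(_field("01.01.00", 8))
        f.write(_field("00.00.00", 8))
        f.write(_field(_HDR + ns * _SIG_HDR, 8))
        f.write(_field("", 44))
        f.write(_field(n_records, 8))
        f.write(_field(1, 8))
        f.write(_field(ns, 4))
        for lab in labels:
            f.write(_field(lab, 16))
        for _ in labels:
            f.write(_field("", 80))
        for _ in labels:
            f.write(_field("au", 8))
        for smin, _ in phys:
            f.write(_field(smin, 8))
        for _, smax in phys:
            f.write(_field(smax, 8))
        for _ in labels:
            f.write(_field(-32768, 8))
        for _ in labels:
            f.write(_field(32767, 8))
        for _ in labels:
            f.write(_field("", 80))
        for r in rates:
            f.write(_field(r, 8))
        for _ in labels:
            f.write(_field("", 32))
        for rec in range(n_records):
            for d, r in zip(digital, rates):
                chunk = d[rec * r : (rec + 1) * r]
                if chunk.size < r:
                    pad = np.full(r - chunk.size, chunk[-1] if chunk.size else 0, dtype=np.int16)
                    chunk = np.concatenate([chunk, pad])
                f.write(chunk.astype("<i2").tobytes())


def read_edf(path: str | Path) -> dict[str, SampledSignal]:
    """Read every channel of an EDF file written by :func:`write_edf`."""
    with open(path, "rb") as f:
        hdr = f.read(_HDR)
        if len(hdr) < _HDR:
            raise ValueError("truncated EDF header")
        n_records = int(hdr[236:244].decode("ascii").strip())
        record_dur = float(hdr[244:252].decode("ascii").strip())
        ns = int(hdr[252:256].decode("ascii").strip())
        sig_hdr = f.read(ns * _SIG_HDR)

        def fields(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig_hdr[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        pmins = [float(v) for v in fields(16 + 80 + 8, 8)]
        pmaxs = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dmins = [float(v) for v in fields(16 + 80 + 8 + 16, 8)]
        dmaxs = [float(v) for v in fields(16 + 80 + 8 + 24, 8)]
        nsamp = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]

        raw = [np.empty(n_records * k, dtype=np.int16) for k in nsamp]
        for rec in range(n_records):
            for j, k in enumerate(nsamp):
                buf = np.frombuffer(f.read(2 * k), dtype="<i2")
                raw[j][rec * k : (rec + 1) * k] = buf

    out = {}
    for j, lab in enumerate(labels):
        gain = (pmaxs[j] - pmins[j]) / (dmaxs[j] - dmins[j])
        vals = (raw[j].astype(float) - dmins[j]) * gain + pmins[j]
        out[lab] = SampledSignal(vals, nsamp[j] / record_dur)
    return out
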