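"""Touchstone v1 two-port (.s2p) reader and writer.

Reads RI, MA and DB data formats with any of the standard frequency units;
writes RI at full float precision so that write∘read is the identity.
Only 2-port S-parameter files are supported (the prescreen's data model);
anything else is rejected with a parse error naming the offending line.

Touchstone v1 two-port column order is ``f S11 S21 S12 S22`` (note 21
before 12), two numbers per parameter.
"""

from __future__ import annotations

import os
from typing import List, Tuple

import numpy as np

from .birdcage import TwoPortSpectrum

__all__ = ["TouchstoneError", "read_touchstone", "write_touchstone"]

_FREQ_UNITS = {"HZ": 1.0, "KHZ": 1e3, "MHZ": 1e6, "GHZ": 1e9}


class TouchstoneError(ValueError):
    """Malformed Touchstone file; message carries the path and line number."""

    def __init__(self, path: str, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = path
        self.line_no = line_no


def _parse_option_line(path: str, line_no: int, tokens: List[str]) -> Tuple[float, str, float]:
    """Return (frequency multiplier, data format, reference impedance)."""
    unit_scale = 1e9  # Touchstone defaults: GHz S MA R 50
    fmt = "MA"
    z0 = 50.0
    i = 0
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok in _FREQ_UNITS:
            unit_scale = _FREQ_UNITS[tok]
        elif tok in ("RI", "MA", "DB"):
            fmt = tok
        elif tok == "S":
            pass
        elif tok in ("Y", "Z", "G", "H"):
            raise TouchstoneError(path, line_no, f"only S-parameter files are supported, got '{tok}'")
        elif tok == "R":
            if i + 1 >= len(tokens):
                raise TouchstoneError(path, line_no, "option line ends after 'R' without a value")
            try:
                z0 = float(tokens[i + 1])
            except ValueError:
                raise TouchstoneError(
                    path, line_no, f"invalid reference impedance {tokens[i + 1]!r}"
                ) from None
            i += 1
        else:
            raise TouchstoneError(path, line_no, f"unrecognized option token {tokens[i]!r}")
        i += 1
    if not z0 > 0.0:
        raise TouchstoneError(path, line_no, f"reference impedance must be positive, got {z0}")
    return unit_scale, fmt, z0


def _to_complex(fmt: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if fmt == "RI":
        return x + 1j * y
    if fmt == "MA":
        return x * np.exp(1j * np.radians(y))
    # DB: 20 log10 magnitude, angle in degrees
    return 10.0 ** (x / 20.0) * np.exp(1j * np.radians(y))


def read_touchstone(path: str | os.PathLike) -> TwoPortSpectrum:
    """Read a Touchstone v1 two-port file into a :class:`TwoPortSpectrum`."""
    path = os.fspath(path)
    unit_scale = None
    fmt = "MA"
    z0 = 50.0
    # token stream with line provenance; v1 allows records wrapped over lines
    values: List[float] = []
    value_lines: List[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if line.startswith("#"):
                if unit_scale is not None:
                    raise TouchstoneError(path, line_no, "duplicate option line")
                unit_scale, fmt, z0 = _parse_option_line(path, line_no, line[1:].split())
                continue
            if line.startswith("["):
                raise TouchstoneError(
                    path, line_no, "Touchstone v2 keyword found; only v1 files are supported"
                )
            for tok in line.split():
                try:
                    values.append(float(tok))
                except ValueError:
                    raise TouchstoneError(path, line_no, f"non-numeric token {tok!r}") from None
                value_lines.append(line_no)
    if unit_scale is None:
        unit_scale = _FREQ_UNITS["GHZ"]
    if not values:
        raise TouchstoneError(path, 0, "file contains no data")
    if len(values) % 9 != 0:
        bad_line = value_lines[9 * (len(values) // 9)] if len(values) > 9 * (len(values) // 9) else value_lines[-1]
        raise TouchstoneError(
            path,
            bad_line,
            f"expected 9 numbers per two-port record (f + 4 parameter pairs), "
            f"got {len(values)} values total — not a 2-port file?",
        )
    data = np.asarray(values, dtype=float).reshape(-1, 9)
    freqs = data[:, 0] * unit_scale
    steps = np.diff(freqs)
    if np.any(steps <= 0.0):
        idx = int(np.argmax(steps <= 0.0)) + 1
        raise TouchstoneError(
            path, value_lines[9 * idx], f"frequencies are not strictly increasing at record {idx + 1}"
        )
    if freqs.size < 2:
        raise TouchstoneError(path, value_lines[-1], "need at least two frequency records")
    s = np.empty((freqs.size, 2, 2), dtype=complex)
    # v1 two-port column order: S11 S21 S12 S22
    s[:, 0, 0] = _to_complex(fmt, data[:, 1], data[:, 2])
    s[:, 1, 0] = _to_complex(fmt, data[:, 3], data[:, 4])
    s[:, 0, 1] = _to_complex(fmt, data[:, 5], data[:, 6])
    s[:, 1, 1] = _to_complex(fmt, data[:, 7], data[:, 8])
    return TwoPortSpectrum(frequencies=freqs, s=s, reference_impedance=z0)


def write_touchstone(spectrum: TwoPortSpectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as Touchstone v1, Hz / S / RI, at full precision."""
    path = os.fspath(path)
    s = spectrum.s
    cols = np.column_stack(
        [
            spectrum.frequencies,
            s[:, 0, 0].real, s[:, 0, 0].imag,
            s[:, 1, 0].real, s[:, 1, 0].imag,
            s[:, 0, 1].real, s[:, 0, 1].imag,
            s[:, 1, 1].real, s[:, 1, 1].imag,
        ]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("! two-port scattering spectrum written by rfscreen\n")
        fh.write(f"# HZ S RI R {spectrum.reference_impedance:.17g}\n")
        for row in cols:
            fh.write(" ".join(f"{v:.17e}" for v in row) + "\n")
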