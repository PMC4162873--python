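"""Lumped-element model of two inductively coupled series-RLC loops.

The driven loop stands for one port of an MRI volume coil (already matched,
so its series resistance is on the order of the system impedance); the
passive loop stands for a conductive implant close to its resonant length.
Coupling the two splits the shared resonance into a pair of normal modes,
which is the spectral signature the prescreen looks for.

Conventions
-----------
* Time dependence ``e^{+jωt}``; an inductor has impedance ``+jωL``.
* Phases are reported in degrees on ``(−180°, +180°]``.
* The source is a unit-voltage ideal generator, so loop currents carry
  units of A/V and drive power never enters the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "Resonator",
    "CoupledPair",
    "FrequencyGrid",
    "LoopCurrents",
    "DegenerateFrequencyError",
    "series_impedance",
    "loop_currents",
    "mode_frequencies",
    "input_impedance",
    "reflection_coefficient",
    "phase_deg",
]

TWO_PI = 2.0 * np.pi


class DegenerateFrequencyError(ValueError):
    """Mesh system is singular at a specific evaluation frequency.

    Only possible at ω = 0 or for a lossless pair probed exactly at one of
    its normal-mode frequencies; raised rather than returning infinities so
    that downstream band integrals are never silently corrupted.
    """

    def __init__(self, frequency_hz: float):
        self.frequency_hz = float(frequency_hz)
        super().__init__(
            f"mesh system is singular at f = {frequency_hz:.6g} Hz "
            "(lossless pair evaluated exactly on a normal mode, or f = 0)"
        )


@dataclass(frozen=True)
class Resonator:
    """One series-resonant RLC loop.

    Parameters
    ----------
    inductance : float
        Series inductance in henries, > 0.
    capacitance : float
        Series capacitance in farads, > 0.
    resistance : float
        Series loss resistance in ohms, >= 0.
    """

    inductance: float
    capacitance: float
    resistance: float = 0.0

    def __post_init__(self) -> None:
        if not (self.inductance > 0.0 and np.isfinite(self.inductance)):
            raise ValueError(f"inductance must be positive and finite, got {self.inductance}")
        if not (self.capacitance > 0.0 and np.isfinite(self.capacitance)):
            raise ValueError(f"capacitance must be positive and finite, got {self.capacitance}")
        if not (self.resistance >= 0.0 and np.isfinite(self.resistance)):
            raise ValueError(f"resistance must be non-negative and finite, got {self.resistance}")

    @property
    def omega0(self) -> float:
        """Resonant angular frequency 1/sqrt(LC) in rad/s."""
        return 1.0 / np.sqrt(self.inductance * self.capacitance)

    @property
    def f0(self) -> float:
        """Resonant frequency in Hz."""
        return self.omega0 / TWO_PI

    @property
    def quality_factor(self) -> float:
        """Q = ω0 L / R (inf for a lossless loop)."""
        if self.resistance == 0.0:
            return np.inf
        return self.omega0 * self.inductance / self.resistance


@dataclass(frozen=True)
class CoupledPair:
    """Two series-RLC loops linked by a mutual inductance.

    ``mutual`` may be negative (orientation of the flux linkage); the
    coupling coefficient ``k = M / sqrt(L_coil L_wire)`` must satisfy
    ``|k| < 1`` for a physical transformer.
    """

    coil: Resonator
    wire: Resonator
    mutual: float
    source_impedance: float = 50.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mutual):
            raise ValueError("mutual inductance must be finite")
        if abs(self.coupling_coefficient) >= 1.0:
            raise ValueError(
                f"|k| = {abs(self.coupling_coefficient):.4g} >= 1: "
                "mutual exceeds sqrt(L_coil * L_wire)"
            )
        if not (self.source_impedance > 0.0):
            raise ValueError("source impedance must be positive")

    @property
    def coupling_coefficient(self) -> float:
        return self.mutual / np.sqrt(self.coil.inductance * self.wire.inductance)


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform (linear) frequency grid in Hz."""

    start: float
    stop: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0.0 < self.start < self.stop):
            raise ValueError(f"require 0 < start < stop, got [{self.start}, {self.stop}]")
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def frequencies(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)

    @classmethod
    def from_frequencies(cls, freqs: np.ndarray) -> "FrequencyGrid":
        freqs = np.asarray(freqs, dtype=float)
        return cls(float(freqs[0]), float(freqs[-1]), int(freqs.size))


@dataclass
class LoopCurrents:
    """Complex loop currents (A per volt of drive) on a frequency grid."""

    grid: FrequencyGrid
    coil_current: np.ndarray = field(repr=False)
    wire_current: np.ndarray = field(repr=False)


def series_impedance(res: Resonator, omega: np.ndarray) -> np.ndarray:
    """Z(ω) = R + jωL + 1/(jωC) of a series loop (ω > 0)."""
    omega = np.asarray(omega, dtype=float)
    return res.resistance + 1j * omega * res.inductance + 1.0 / (1j * omega * res.capacitance)


def _check_nonsingular(det: np.ndarray, freqs: np.ndarray, scale: np.ndarray) -> None:
    bad = np.abs(det) <= 1e-300 + 1e-14 * scale
    if np.any(bad):
        raise DegenerateFrequencyError(float(np.asarray(freqs)[bad][0]))


def loop_currents(pair: CoupledPair, grid: FrequencyGrid, drive_volts: float = 1.0) -> LoopCurrents:
    """Solve the two-loop mesh system at every grid frequency.

    The mesh equations are ``[Z_coil, jωM; jωM, Z_wire] · [I_c, I_w] = [V, 0]``
    with ``Z = R + jωL + 1/(jωC)``; the closed-form solution of the 2×2
    system is used (Cramer), identical to a direct linear solve.
    """
    if not drive_volts > 0.0:
        raise ValueError("drive_volts must be positive")
    freqs = grid.frequencies
    omega = TWO_PI * freqs
    zc = series_impedance(pair.coil, omega)
    zw = series_impedance(pair.wire, omega)
    zm = 1j * omega * pair.mutual
    det = zc * zw - zm * zm
    _check_nonsingular(det, freqs, np.abs(zc * zw) + np.abs(zm) ** 2)
    coil_i = drive_volts * zw / det
    wire_i = -drive_volts * zm / det
    return LoopCurrents(grid=grid, coil_current=coil_i, wire_current=wire_i)


def mode_frequencies(pair: CoupledPair, rtol: float = 1e-9) -> Tuple[float, float]:
    """Closed-form normal-mode frequencies of the identical-resonator pair.

    For two identical series loops coupled by M the characteristic equation
    factorizes exactly and the modes sit at::

        f± = 1 / (2π sqrt((L ∓ |M|) C))

    i.e. ``f0/sqrt(1 ± k)``: the splitting grows with |k| and both modes
    collapse to f0 as M → 0.  Returns ``(lower, upper)``.

    Only valid for the identical-resonator regime; non-identical loops must
    go through the numerical route (``metrics.detect_splitting`` on a
    synthesized spectrum).
    """
    c, w = pair.coil, pair.wire
    same = (
        np.isclose(c.inductance, w.inductance, rtol=rtol)
        and np.isclose(c.capacitance, w.capacitance, rtol=rtol)
        and np.isclose(c.resistance, w.resistance, rtol=rtol, atol=1e-30)
    )
    if not same:
        raise ValueError(
            "closed-form mode frequencies require identical coil and wire "
            "resonators; use the numerical split-peak route "
            "(rfscreen.metrics.detect_splitting) for asymmetric pairs"
        )
    l, cap, m = c.inductance, c.capacitance, abs(pair.mutual)
    f_lower = 1.0 / (TWO_PI * np.sqrt((l + m) * cap))
    f_upper = 1.0 / (TWO_PI * np.sqrt((l - m) * cap))
    return float(f_lower), float(f_upper)


def input_impedance(pair: CoupledPair, grid: FrequencyGrid) -> np.ndarray:
    """Drive-point impedance Z_in = Z_coil + (ωM)² / Z_wire per frequency.

    The reflected-load form is algebraically identical to the drive-point
    impedance of the mesh system (V / I_coil); at M = 0 it reduces to
    Z_coil exactly.
    """
    freqs = grid.frequencies
    omega = TWO_PI * freqs
    zc = series_impedance(pair.coil, omega)
    if pair.mutual == 0.0:
        return zc
    zw = series_impedance(pair.wire, omega)
    _check_nonsingular(zw, freqs, np.abs(1j * omega * pair.wire.inductance))
    return zc + (omega * pair.mutual) ** 2 / zw


def reflection_coefficient(z: np.ndarray, z0: float) -> np.ndarray:
    """Γ = (Z − Z0) / (Z + Z0) against a real reference impedance Z0 > 0."""
    if not z0 > 0.0:
        raise ValueError("reference impedance must be positive")
    z = np.asarray(z, dtype=complex)
    denom = z + z0
    if np.any(np.abs(denom) == 0.0):
        raise ValueError("Z = -Z0 is nonphysical (reflection coefficient undefined)")
    return (z - z0) / denom


def phase_deg(values: np.ndarray) -> np.ndarray:
    """Phase in degrees mapped onto (−180°, +180°]."""
    deg = np.degrees(np.angle(values))
    deg = np.where(deg <= -180.0, deg + 360.0, deg)
    return deg
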