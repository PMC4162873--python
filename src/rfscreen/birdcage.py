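"""Two-drive-port birdcage model with azimuth-dependent implant coupling.

Each drive port of the birdcage is modelled as one series resonator.  The
axial electric field of a linearly driven first-order mode varies over the
coil cross-section as ``E_z ∝ (r/a) cos(θ − φ0)``, where φ0 is the azimuth
of maximal rung current for that port, so the mutual inductance between a
long z-oriented wire and port *j* follows the same cosine law and reverses
sign across the port's E = 0 plane.  All inter-port transmission is
implant-mediated by default (the two ports share no direct mutual), which
is how the measured S21 of a well-isolated coil is interpreted.

Port polarity convention
------------------------
The reference polarity of port 2 is flipped relative to its Faraday dot
(a free choice for a coil port, equivalent to the half-turn measurement-
plane offset real cabling introduces).  Under this convention the
implant-mediated transmission through a load that is purely resistive at
the probe frequency has phase 180° when the two geometric couplings have
the same sign — the phase a network analyzer shows for a nonresonant
load.  Concretely, a model built from geometric couplings (m1, m2) uses
*effective* couplings ``(c1, c2) = (m1, −m2)`` everywhere: in the mesh,
in the scattering matrices, and in the drive-superposition law
``I_wire ∝ c1·a1 + c2·a2``.  All quantities in this module live in that
single coordinate system, so drives, S-parameters and null modes are
mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .circuit import (
    TWO_PI,
    DegenerateFrequencyError,
    FrequencyGrid,
    Resonator,
    series_impedance,
)

__all__ = [
    "PortGeometry",
    "DEFAULT_GEOMETRY",
    "WirePlacement",
    "LoadLoop",
    "BirdcageModel",
    "TwoPortSpectrum",
    "DriveVector",
    "port_couplings",
    "build_birdcage",
    "two_port_scattering",
    "synthesize_spectrum",
    "port_currents_under_drive",
    "wire_current_under_drive",
    "reflected_power",
]


@dataclass(frozen=True)
class PortGeometry:
    """Azimuth (degrees) of maximal rung current for one port's linear mode."""

    azimuth_phi0_deg: float = 0.0


DEFAULT_GEOMETRY = (PortGeometry(0.0), PortGeometry(90.0))


@dataclass(frozen=True)
class WirePlacement:
    """Placement of a long z-oriented wire in the coil cross-section.

    ``peak_mutual`` is the mutual inductance (henries) the wire would have
    with a port whose E-field maximum it sits on at full radius; the
    actual per-port coupling is scaled by ``radius_fraction`` (r/a) and
    the cosine of the azimuth offset.
    """

    azimuth_theta_deg: float
    radius_fraction: float = 1.0
    peak_mutual: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.radius_fraction <= 1.0):
            raise ValueError("radius_fraction must lie in [0, 1]")


def port_couplings(
    geometry: Sequence[PortGeometry], wire: WirePlacement
) -> Tuple[float, float]:
    """Geometric per-port mutual inductances of the wire (signed).

    ``m_j = peak_mutual · (r/a) · cos(θ − φ0_j)``: the coupling vanishes in
    port *j*'s E = 0 plane and reverses sign across it.
    """
    theta = np.radians(wire.azimuth_theta_deg)
    scale = wire.peak_mutual * wire.radius_fraction
    m = tuple(
        float(scale * np.cos(theta - np.radians(g.azimuth_phi0_deg))) for g in geometry
    )
    return m  # type: ignore[return-value]


@dataclass(frozen=True)
class LoadLoop:
    """A passive loop inductively coupled to the two ports.

    ``couplings`` are the *effective* (polarity-convention) mutual
    inductances to ports 1 and 2; complex values are allowed to express
    phase-shifted coupling paths.
    """

    resonator: Resonator
    couplings: Tuple[complex, complex]


@dataclass(frozen=True)
class BirdcageModel:
    """Two port resonators plus any number of inductively coupled loads.

    The first load, when present, is the implant wire; further loads model
    parasitics (e.g. a detuned structure on one port).  ``port_port_mutual``
    is zero for an ideally isolated coil and may be set small and nonzero
    to emulate imperfect isolation.
    """

    ports: Tuple[Resonator, Resonator]
    loads: Tuple[LoadLoop, ...] = ()
    z0: float = 50.0
    port_port_mutual: float = 0.0

    def __post_init__(self) -> None:
        if not self.z0 > 0.0:
            raise ValueError("reference impedance must be positive")

    @property
    def wire_couplings(self) -> Tuple[complex, complex]:
        """Effective couplings (c1, c2) of the implant loop, (0, 0) if none."""
        if not self.loads:
            return (0.0 + 0.0j, 0.0 + 0.0j)
        return self.loads[0].couplings


def build_birdcage(
    ports: Tuple[Resonator, Resonator],
    geometry: Sequence[PortGeometry],
    wire: WirePlacement,
    wire_resonator: Resonator,
    z0: float = 50.0,
    port_port_mutual: float = 0.0,
    extra_loads: Sequence[LoadLoop] = (),
) -> BirdcageModel:
    """Assemble a model from geometric placement.

    Applies the cosine azimuthal law and the port-2 polarity convention
    (effective couplings ``(m1, −m2)``).
    """
    m1, m2 = port_couplings(geometry, wire)
    loads = [LoadLoop(wire_resonator, (m1, -m2))]
    loads.extend(extra_loads)
    return BirdcageModel(
        ports=tuple(ports),
        loads=tuple(loads),
        z0=z0,
        port_port_mutual=port_port_mutual,
    )


def _port_impedance_matrix(model: BirdcageModel, freqs: np.ndarray) -> np.ndarray:
    """Exact 2×2 port impedance matrix per frequency (loads eliminated).

    Loads couple to the ports but not to each other, so the Schur
    complement of the load block is a sum of rank-one reflected terms:
    ``Z'_jk = Z_j δ_jk + jωM12 (1−δ_jk) + Σ_l ω² c_lj c_lk / Z_l``.
    """
    freqs = np.asarray(freqs, dtype=float)
    omega = TWO_PI * freqs
    n = freqs.size
    z = np.zeros((n, 2, 2), dtype=complex)
    z[:, 0, 0] = series_impedance(model.ports[0], omega)
    z[:, 1, 1] = series_impedance(model.ports[1], omega)
    if model.port_port_mutual != 0.0:
        zm = 1j * omega * model.port_port_mutual
        z[:, 0, 1] += zm
        z[:, 1, 0] += zm
    for load in model.loads:
        zl = series_impedance(load.resonator, omega)
        bad = np.abs(zl) <= 1e-300
        if np.any(bad):
            raise DegenerateFrequencyError(float(freqs[bad][0]))
        c1, c2 = load.couplings
        w2 = omega**2 / zl
        z[:, 0, 0] += w2 * c1 * c1
        z[:, 0, 1] += w2 * c1 * c2
        z[:, 1, 0] += w2 * c2 * c1
        z[:, 1, 1] += w2 * c2 * c2
    return z


def two_port_scattering(model: BirdcageModel, freqs: np.ndarray) -> np.ndarray:
    """S(f) = (Z − Z0 I)(Z + Z0 I)^{-1} per frequency, shape (n, 2, 2).

    Z is symmetric (the mesh contains only reciprocal elements) and
    commutes with Z ± Z0·I, so S is exactly symmetric: S12 = S21.
    """
    freqs = np.asarray(freqs, dtype=float)
    z = _port_impedance_matrix(model, freqs)
    eye = np.eye(2)
    a = z + model.z0 * eye
    b = z - model.z0 * eye
    dets = np.linalg.det(a)
    bad = ~np.isfinite(dets) | (np.abs(dets) <= 1e-300)
    if np.any(bad):
        raise DegenerateFrequencyError(float(freqs[bad][0]))
    return np.linalg.solve(a, b)


@dataclass
class TwoPortSpectrum:
    """Complex 2×2 scattering matrix over a frequency grid.

    ``s[i]`` is the scattering matrix at ``frequencies[i]`` with the usual
    indexing ``s[i, j-1, k-1] = S_jk``.
    """

    frequencies: np.ndarray = field(repr=False)
    s: np.ndarray = field(repr=False)
    reference_impedance: float = 50.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.s = np.asarray(self.s, dtype=complex)
        if self.frequencies.ndim != 1 or self.frequencies.size < 2:
            raise ValueError("spectrum needs a 1-D grid of at least 2 frequencies")
        if np.any(np.diff(self.frequencies) <= 0.0):
            raise ValueError("frequencies must be strictly increasing")
        if self.s.shape != (self.frequencies.size, 2, 2):
            raise ValueError(f"s must have shape (n, 2, 2), got {self.s.shape}")
        if not self.reference_impedance > 0.0:
            raise ValueError("reference impedance must be positive")

    @property
    def grid(self) -> FrequencyGrid:
        return FrequencyGrid.from_frequencies(self.frequencies)

    def s_param(self, j: int, k: int) -> np.ndarray:
        """S_jk trace (1-based port indices)."""
        return self.s[:, j - 1, k - 1]

    def magnitude(self, j: int, k: int) -> np.ndarray:
        return np.abs(self.s_param(j, k))

    def sample(self, frequency: float) -> np.ndarray:
        """Linearly interpolated 2×2 scattering matrix at one frequency."""
        f = float(frequency)
        if not (self.frequencies[0] <= f <= self.frequencies[-1]):
            raise ValueError(
                f"{f:.6g} Hz lies outside the spectrum grid "
                f"[{self.frequencies[0]:.6g}, {self.frequencies[-1]:.6g}]"
            )
        out = np.empty((2, 2), dtype=complex)
        for j in range(2):
            for k in range(2):
                out[j, k] = np.interp(f, self.frequencies, self.s[:, j, k].real) + 1j * np.interp(
                    f, self.frequencies, self.s[:, j, k].imag
                )
        return out

    def same_grid(self, other: "TwoPortSpectrum", rtol: float = 1e-12) -> bool:
        return self.frequencies.shape == other.frequencies.shape and np.allclose(
            self.frequencies, other.frequencies, rtol=rtol, atol=0.0
        )


def synthesize_spectrum(model: BirdcageModel, grid: FrequencyGrid) -> TwoPortSpectrum:
    """Synthesize the full two-port scattering spectrum of the model."""
    freqs = grid.frequencies
    return TwoPortSpectrum(
        frequencies=freqs,
        s=two_port_scattering(model, freqs),
        reference_impedance=model.z0,
    )


@dataclass(frozen=True)
class DriveVector:
    """Two complex incident-wave amplitudes in sqrt-watts."""

    a1: complex
    a2: complex

    @property
    def total_power(self) -> float:
        return abs(self.a1) ** 2 + abs(self.a2) ** 2

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2], dtype=complex)

    @classmethod
    def from_split(cls, total_power: float, port2_fraction: float, phase_deg: float) -> "DriveVector":
        """Power-conserving split: (1−u) of the power on port 1, u on port 2,
        with relative phase ``phase_deg`` on port 2."""
        if not 0.0 <= port2_fraction <= 1.0:
            raise ValueError("port2_fraction must lie in [0, 1]")
        a1 = np.sqrt(total_power * (1.0 - port2_fraction))
        a2 = np.sqrt(total_power * port2_fraction) * np.exp(1j * np.radians(phase_deg))
        return cls(complex(a1), complex(a2))


def port_currents_under_drive(
    model: BirdcageModel, drive: DriveVector, frequency: float
) -> np.ndarray:
    """Port loop currents (amperes) for incident waves ``drive`` at one frequency.

    From the wave/terminal relations ``a = (V + Z0 I) / (2 sqrt(Z0))`` and
    the port impedance matrix ``V = Z' I``:  ``I = 2 sqrt(Z0) (Z' + Z0)^{-1} a``.
    """
    freqs = np.array([float(frequency)])
    zp = _port_impedance_matrix(model, freqs)[0]
    return 2.0 * np.sqrt(model.z0) * np.linalg.solve(zp + model.z0 * np.eye(2), drive.as_array())


def wire_current_under_drive(
    model: BirdcageModel, drive: DriveVector, frequency: float, load_index: int = 0
) -> complex:
    """Complex current in a load loop under an arbitrary two-channel drive.

    Linear in (a1, a2); for weakly coupled identical ports it reduces to
    the superposition law ``I_wire ∝ c1 a1 + c2 a2`` in the effective
    couplings, and it vanishes exactly for the null drive of
    ``nullmode.solve_null`` when the two ports are identical.
    """
    if not model.loads:
        return 0.0 + 0.0j
    load = model.loads[load_index]
    omega = TWO_PI * float(frequency)
    zl = complex(series_impedance(load.resonator, np.array([omega]))[0])
    i_ports = port_currents_under_drive(model, drive, frequency)
    c = np.array(load.couplings, dtype=complex)
    return complex(-1j * omega * np.dot(c, i_ports) / zl)


def reflected_power(model: BirdcageModel, drive: DriveVector, frequency: float) -> float:
    """Total reflected power |b1|² + |b2|² (watts) with b = S·a."""
    s = two_port_scattering(model, np.array([float(frequency)]))[0]
    b = s @ drive.as_array()
    return float(np.sum(np.abs(b) ** 2))
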