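"""Detection and monitoring metrics for the impedance-spectrum prescreen.

Four computations:

* the *distortion parameter* — per-port band integral of the absolute
  deviation of the reflection magnitude from a reference-load spectrum,
  the scalar that tracks implant coupling strength;
* split-peak detection — the unambiguous "red flag" of resonant coupling,
  found as multiple absorption dips of |S_jj| where the reference has one;
* monitoring-frequency planning — pick per-port frequencies where the
  S-parameter responds *monotonically* to coupling strength (at the dip
  center it grows, far out on the wings it shrinks; in between the
  derivative can change sign and a probe there is rejected);
* the Pearson correlation between induced wire current and ΔS magnitude
  across an ensemble of configurations, per frequency and port.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .birdcage import TwoPortSpectrum

__all__ = [
    "DistortionReport",
    "SplitFlag",
    "MonitoringChoice",
    "MonitoringPlan",
    "PlanningError",
    "distortion_parameter",
    "detect_splitting",
    "plan_monitoring",
    "classify_monitoring_frequency",
    "current_sparam_correlation",
    "half_width_half_min",
    "DEFAULT_BAND",
]

#: Integration band used throughout, spanning the significant part of the
#: reference resonance of the bench configuration (Hz).
DEFAULT_BAND: Tuple[float, float] = (60.5e6, 63.5e6)


# --------------------------------------------------------------------------
# distortion parameter
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DistortionReport:
    """Integrated |ΔS| over the band, per port and total (units |S|·Hz)."""

    per_port: Tuple[float, float]
    band: Tuple[float, float]

    @property
    def total(self) -> float:
        return float(sum(self.per_port))


def _band_integrand_grid(
    freqs: np.ndarray, values: np.ndarray, band: Tuple[float, float]
) -> Tuple[np.ndarray, np.ndarray]:
    """Restrict (freqs, values) to the band, linearly interpolating the two
    band endpoints onto the native grid (no resampling inside)."""
    lo, hi = band
    if not (lo < hi):
        raise ValueError(f"band must satisfy lo < hi, got {band}")
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(
            f"band {band} extends outside the spectrum grid "
            f"[{freqs[0]:.6g}, {freqs[-1]:.6g}]"
        )
    inside = (freqs > lo) & (freqs < hi)
    f_sub = np.concatenate(([lo], freqs[inside], [hi]))
    v_sub = np.concatenate(
        ([np.interp(lo, freqs, values)], values[inside], [np.interp(hi, freqs, values)])
    )
    return f_sub, v_sub


def distortion_parameter(
    dut: TwoPortSpectrum,
    reference: TwoPortSpectrum,
    band: Tuple[float, float] = DEFAULT_BAND,
    complex_difference: bool = False,
) -> DistortionReport:
    """Per-port distortion D_j = ∫_band | |S_jj| − |S0_jj| | df.

    Trapezoidal quadrature on the native grid (measured spectra arrive on
    fixed grids; resampling would manufacture precision).  Both spectra
    must share the grid exactly — mismatched grids are an error, never
    silently resampled.  With ``complex_difference`` the integrand is
    |S_jj − S0_jj| instead (sensitivity-study mode).
    """
    if not dut.same_grid(reference):
        raise ValueError("dut and reference spectra are on different frequency grids")
    per_port = []
    for j in (1, 2):
        if complex_difference:
            integrand = np.abs(dut.s_param(j, j) - reference.s_param(j, j))
        else:
            integrand = np.abs(dut.magnitude(j, j) - reference.magnitude(j, j))
        f_sub, v_sub = _band_integrand_grid(dut.frequencies, integrand, band)
        per_port.append(float(np.trapezoid(v_sub, f_sub)))
    return DistortionReport(per_port=(per_port[0], per_port[1]), band=band)


# --------------------------------------------------------------------------
# split-peak detection
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitFlag:
    """Outcome of split-peak detection on one or both ports."""

    flagged: bool
    n_peaks: int
    peak_frequencies: Tuple[float, ...]
    prominence_ratio: float
    low_confidence: bool = False
    annotation: str = ""
    per_port: Dict[int, "SplitFlag"] = field(default_factory=dict, compare=False)


def _band_mask(freqs: np.ndarray, band: Tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(f"band {band} extends outside the spectrum grid")
    return (freqs >= lo) & (freqs <= hi)


def _estimate_trace_noise(mag: np.ndarray) -> float:
    """Robust noise-sigma estimate of a magnitude trace.

    Second differences remove the locally linear part of the line shape, so
    the smooth dip slope does not masquerade as noise; the median absolute
    second difference of white noise of variance σ² is 0.6745·√6·σ."""
    d2 = np.diff(mag, n=2)
    if d2.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0))


def _find_dips(
    freqs: np.ndarray, mag: np.ndarray, prominence: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local minima of |S| with at least the given prominence.

    Returns (dip frequencies, prominences, widths in Hz)."""
    idx, props = find_peaks(-mag, prominence=prominence)
    if idx.size == 0:
        return np.array([]), np.array([]), np.array([])
    widths = peak_widths(-mag, idx, rel_height=0.5)[0] * (freqs[1] - freqs[0])
    return freqs[idx], props["prominences"], widths


def _detect_port(
    dut: TwoPortSpectrum,
    reference: TwoPortSpectrum,
    band: Tuple[float, float],
    port: int,
    noise_floor: float,
    prominence_factor: float,
    min_prominence: float,
) -> SplitFlag:
    mask = _band_mask(dut.frequencies, band)
    f = dut.frequencies[mask]
    mag = dut.magnitude(port, port)[mask]
    ref_mag = reference.magnitude(port, port)[mask]
    threshold = max(prominence_factor * noise_floor, min_prominence)

    est_noise = _estimate_trace_noise(mag)
    if noise_floor > 0.0 and est_noise > 2.0 * noise_floor:
        return SplitFlag(
            flagged=False,
            n_peaks=0,
            peak_frequencies=(),
            prominence_ratio=0.0,
            low_confidence=True,
            annotation=(
                f"trace noise ~{est_noise:.3g} exceeds the configured floor "
                f"{noise_floor:.3g}; flag withheld"
            ),
        )

    dip_f, prom, widths = _find_dips(f, mag, threshold)
    ref_f, _, ref_widths = _find_dips(f, ref_mag, threshold)
    n_ref = int(ref_f.size)
    n = int(dip_f.size)
    ratio = float(np.sort(prom)[-2] / threshold) if n >= 2 else (
        float(prom[0] / threshold) if n == 1 else 0.0
    )

    if n >= max(2, n_ref + 1):
        return SplitFlag(True, n, tuple(map(float, dip_f)), ratio)
    # merged-split tie-break: one dip, but much broader than the reference's
    if n == 1 and n_ref >= 1 and ref_widths.size and widths[0] > 2.0 * float(np.max(ref_widths)):
        return SplitFlag(
            True, 1, (float(dip_f[0]),), ratio, low_confidence=True,
            annotation="single broadened dip consistent with merged split peaks",
        )
    return SplitFlag(False, n, tuple(map(float, dip_f)), ratio)


def detect_splitting(
    dut: TwoPortSpectrum,
    reference: TwoPortSpectrum,
    band: Tuple[float, float] = DEFAULT_BAND,
    noise_floor: float = 0.0,
    prominence_factor: float = 3.0,
    min_prominence: float = 1e-3,
    port: Optional[int] = None,
) -> SplitFlag:
    """Flag resonant mode splitting on the reflection dips of |S_jj|.

    A port is flagged when it shows at least one more prominent absorption
    dip in the band than the reference does (prominence threshold
    ``max(prominence_factor · noise_floor, min_prominence)``).  With
    ``port=None`` both ports are examined and the overall flag is their OR;
    per-port results are kept in ``per_port``.
    """
    if not dut.same_grid(reference):
        raise ValueError("dut and reference spectra are on different frequency grids")
    ports = (1, 2) if port is None else (port,)
    results = {
        p: _detect_port(dut, reference, band, p, noise_floor, prominence_factor, min_prominence)
        for p in ports
    }
    worst = max(results.values(), key=lambda r: (r.flagged, r.n_peaks, r.prominence_ratio))
    return SplitFlag(
        flagged=worst.flagged,
        n_peaks=worst.n_peaks,
        peak_frequencies=worst.peak_frequencies,
        prominence_ratio=worst.prominence_ratio,
        low_confidence=worst.low_confidence,
        annotation=worst.annotation,
        per_port=results,
    )


# --------------------------------------------------------------------------
# monitoring-frequency planning
# --------------------------------------------------------------------------


class PlanningError(RuntimeError):
    """No monitoring frequency with a single-signed response was found."""


@dataclass(frozen=True)
class MonitoringChoice:
    port: int
    regime: str  # "center" or "wing"
    frequency_hz: float
    expected_sign: int  # +1: |S| grows with coupling, −1: it shrinks


@dataclass(frozen=True)
class MonitoringPlan:
    choices: Tuple[MonitoringChoice, ...]
    coupling_range: Tuple[float, float]
    hwhm_hz: Dict[int, float]

    def choice(self, port: int, regime: str) -> MonitoringChoice:
        for c in self.choices:
            if c.port == port and c.regime == regime:
                return c
        raise KeyError(f"no monitoring choice for port {port}, regime {regime!r}")


def half_width_half_min(
    spectrum: TwoPortSpectrum, port: int, band: Optional[Tuple[float, float]] = None
) -> Tuple[float, float]:
    """(dip-center frequency, HWHM) of the |S_jj| absorption dip.

    The half level is midway between the in-band baseline (maximum) and the
    dip minimum; crossings are linearly interpolated on both sides.
    """
    freqs = spectrum.frequencies
    mag = spectrum.magnitude(port, port)
    if band is not None:
        mask = _band_mask(freqs, band)
        freqs, mag = freqs[mask], mag[mask]
    i_min = int(np.argmin(mag))
    level = 0.5 * (float(np.max(mag)) + float(mag[i_min]))
    f_center = float(freqs[i_min])

    def _crossing(side: int) -> float:
        idx = np.arange(i_min, -1, -1) if side < 0 else np.arange(i_min, freqs.size)
        vals = mag[idx]
        above = np.nonzero(vals >= level)[0]
        if above.size == 0:
            return float(freqs[idx[-1]])
        j = above[0]
        i1, i0 = idx[j], idx[j - 1]
        frac = (level - mag[i0]) / (mag[i1] - mag[i0])
        return float(freqs[i0] + frac * (freqs[i1] - freqs[i0]))

    hwhm = 0.5 * (_crossing(+1) - _crossing(-1))
    return f_center, float(hwhm)


def _response_matrix(
    family: Callable[[float], TwoPortSpectrum],
    couplings: np.ndarray,
    port: int,
) -> Tuple[np.ndarray, np.ndarray]:
    spectra = [family(float(k)) for k in couplings]
    freqs = spectra[0].frequencies
    for s in spectra[1:]:
        if not s.same_grid(spectra[0]):
            raise ValueError("model family must return spectra on a common grid")
    mags = np.stack([s.magnitude(port, port) for s in spectra], axis=0)
    return freqs, mags


def _classify(mags_vs_k: np.ndarray, tol: float) -> int:
    """+1 monotone increasing, −1 monotone decreasing, 0 ambiguous."""
    d = np.diff(mags_vs_k)
    span = float(np.max(mags_vs_k) - np.min(mags_vs_k))
    slack = tol * max(span, 1e-12)
    if np.all(d >= -slack) and span > 0:
        return +1
    if np.all(d <= slack) and span > 0:
        return -1
    return 0


def classify_monitoring_frequency(
    family: Callable[[float], TwoPortSpectrum],
    frequency: float,
    port: int,
    coupling_range: Tuple[float, float],
    n_coupling: int = 25,
    tol: float = 1e-3,
) -> int:
    """Sign of d|S_jj|/d(coupling) at one probe frequency over the range.

    Returns +1 (monotone increasing), −1 (monotone decreasing) or
    0 (derivative changes sign — reject this frequency for monitoring).
    """
    ks = np.linspace(coupling_range[0], coupling_range[1], n_coupling)
    vals = np.empty(n_coupling)
    for i, k in enumerate(ks):
        spec = family(float(k))
        vals[i] = float(np.interp(frequency, spec.frequencies, spec.magnitude(port, port)))
    return _classify(vals, tol)


def plan_monitoring(
    reference: TwoPortSpectrum,
    family: Callable[[float], TwoPortSpectrum],
    coupling_range: Tuple[float, float],
    ports: Sequence[int] = (1, 2),
    n_coupling: int = 15,
    wing_offset_hwhm: float = 5.0,
    tol: float = 1e-3,
) -> MonitoringPlan:
    """Choose per-port monitoring frequencies with single-signed response.

    ``family(k)`` must synthesize the spectrum of the model at coupling
    strength ``k`` on the reference grid.  For each port the plan returns

    * a *center* choice at the reference dip minimum, certified monotone
      increasing over the whole coupling range (sign +1), and
    * a *wing* choice at least ``wing_offset_hwhm`` reference half-widths
      from the dip center, certified monotone decreasing (sign −1).

    Frequencies whose response changes sign across the range are never
    returned; if a regime has no certified frequency the plan fails
    loudly with :class:`PlanningError`.
    """
    ks = np.linspace(coupling_range[0], coupling_range[1], n_coupling)
    choices: List[MonitoringChoice] = []
    hwhms: Dict[int, float] = {}
    for port in ports:
        freqs, mags = _response_matrix(family, ks, port)
        f_center, hwhm = half_width_half_min(reference, port)
        hwhms[port] = hwhm
        i_center = int(np.argmin(np.abs(freqs - f_center)))
        if _classify(mags[:, i_center], tol) != +1:
            raise PlanningError(
                f"port {port}: |S| at the dip center is not monotone increasing "
                "over the coupling range"
            )
        choices.append(MonitoringChoice(port, "center", float(freqs[i_center]), +1))

        dist = np.abs(freqs - f_center)
        far = np.nonzero(dist >= wing_offset_hwhm * hwhm)[0]
        wing_idx = None
        for i in far[np.argsort(dist[far])]:  # nearest certified wing point
            if _classify(mags[:, i], tol) == -1:
                wing_idx = int(i)
                break
        if wing_idx is None:
            raise PlanningError(
                f"port {port}: no monotone-decreasing frequency found beyond "
                f"{wing_offset_hwhm} HWHM from the dip center"
            )
        choices.append(MonitoringChoice(port, "wing", float(freqs[wing_idx]), -1))
    return MonitoringPlan(tuple(choices), tuple(coupling_range), hwhms)


# --------------------------------------------------------------------------
# current / ΔS correlation
# --------------------------------------------------------------------------


def current_sparam_correlation(
    currents: Sequence[float],
    spectra: Sequence[TwoPortSpectrum],
    reference: TwoPortSpectrum,
) -> Dict[int, np.ndarray]:
    """Pearson R between |I_wire| and Δ|S_jj|(f) across an ensemble.

    Returns, per port, an array of R values over the reference grid.
    Sample (n−1) normalization.  Frequencies where either variable has
    zero variance are reported as NaN (missing), never as zero.
    """
    currents = np.asarray(currents, dtype=float)
    n = currents.size
    if n < 3:
        raise ValueError("ensemble must contain at least 3 members")
    if len(spectra) != n:
        raise ValueError("need one spectrum per current value")
    for s in spectra:
        if not s.same_grid(reference):
            raise ValueError("ensemble spectra must share the reference grid")
    if np.var(currents) == 0.0:
        raise ValueError("wire-current ensemble has zero variance")
    out: Dict[int, np.ndarray] = {}
    ic = currents - currents.mean()
    sc = float(np.sqrt(np.sum(ic**2) / (n - 1)))
    for port in (1, 2):
        delta = np.stack(
            [s.magnitude(port, port) - reference.magnitude(port, port) for s in spectra],
            axis=0,
        )
        dc = delta - delta.mean(axis=0, keepdims=True)
        sd = np.sqrt(np.sum(dc**2, axis=0) / (n - 1))
        cov = np.sum(dc * ic[:, None], axis=0) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / (sd * sc)
        r[sd == 0.0] = np.nan
        out[port] = r
    return out
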