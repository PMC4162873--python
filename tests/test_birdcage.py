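"""Two-port birdcage synthesis: cosine coupling law, mesh reduction, drives."""

import numpy as np
import pytest

from rfscreen.birdcage import (
    DEFAULT_GEOMETRY,
    BirdcageModel,
    DriveVector,
    LoadLoop,
    PortGeometry,
    WirePlacement,
    build_birdcage,
    port_couplings,
    port_currents_under_drive,
    reflected_power,
    synthesize_spectrum,
    two_port_scattering,
    wire_current_under_drive,
)
from rfscreen.circuit import FrequencyGrid, Resonator, reflection_coefficient, series_impedance
from rfscreen.fixtures import (
    nominal_reference,
    nominal_wire_model,
    peak_mutual_for_k,
    port_resonator,
    wire_resonator,
)
from rfscreen.metrics import detect_splitting

from conftest import rf_grid


def wave_domain_oracle(model: BirdcageModel, freqs: np.ndarray) -> np.ndarray:
    """Independent S-matrix route: solve the *full* 3-(or more-)loop mesh in
    the wave domain per frequency and per excitation, with no Schur
    reduction.  Ports see the wave constraint a = (V + Z0 I)/(2 sqrt(Z0));
    loads are short-circuited loops."""
    z0 = model.z0
    n_loops = 2 + len(model.loads)
    out = np.empty((freqs.size, 2, 2), dtype=complex)
    for i, f in enumerate(freqs):
        omega = 2 * np.pi * f
        z = np.zeros((n_loops, n_loops), dtype=complex)
        z[0, 0] = series_impedance(model.ports[0], omega)
        z[1, 1] = series_impedance(model.ports[1], omega)
        z[0, 1] = z[1, 0] = 1j * omega * model.port_port_mutual
        for li, load in enumerate(model.loads):
            j = 2 + li
            z[j, j] = series_impedance(load.resonator, omega)
            z[0, j] = z[j, 0] = 1j * omega * load.couplings[0]
            z[1, j] = z[j, 1] = 1j * omega * load.couplings[1]
        term = np.zeros(n_loops)
        term[:2] = z0
        for col in range(2):
            a = np.zeros(n_loops)
            a[col] = 1.0
            currents = np.linalg.solve(z + np.diag(term), 2 * np.sqrt(z0) * a)
            b = a[:2] - np.sqrt(z0) * currents[:2]
            out[i, :, col] = b
    return out


class TestPortCouplings:
    def test_wire_on_port1_axis(self):
        wire = WirePlacement(0.0, 0.8, 2e-8)
        m1, m2 = port_couplings(DEFAULT_GEOMETRY, wire)
        assert m1 == pytest.approx(2e-8 * 0.8, rel=1e-12)
        assert m2 == pytest.approx(0.0, abs=1e-22)

    def test_diagonal_placement_symmetric(self):
        m1, m2 = port_couplings(DEFAULT_GEOMETRY, WirePlacement(45.0, 1.0, 1e-8))
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_quadrature_sum_invariant(self):
        """With orthogonal ports, m1^2 + m2^2 is independent of azimuth."""
        totals = [
            sum(m**2 for m in port_couplings(DEFAULT_GEOMETRY, WirePlacement(t, 1.0, 1e-8)))
            for t in range(0, 360, 10)
        ]
        np.testing.assert_allclose(totals, totals[0], rtol=1e-12)

    def test_sign_reverses_across_null_plane(self):
        m_lo = port_couplings(DEFAULT_GEOMETRY, WirePlacement(80.0, 1.0, 1e-8))[0]
        m_hi = port_couplings(DEFAULT_GEOMETRY, WirePlacement(100.0, 1.0, 1e-8))[0]
        assert m_lo > 0 > m_hi


class TestSynthesizeSpectrum:
    def test_decoupled_ports_reduce_to_single_loop(self):
        model = nominal_wire_model(0.0, 0.0)
        grid = rf_grid(201)
        spec = synthesize_spectrum(model, grid)
        assert np.all(spec.s_param(2, 1) == 0.0)
        from rfscreen.circuit import CoupledPair, input_impedance

        pair = CoupledPair(model.ports[0], wire_resonator(), 0.0)
        gamma = reflection_coefficient(input_impedance(pair, grid), model.z0)
        np.testing.assert_allclose(spec.s_param(1, 1), gamma, rtol=1e-12)

    def test_nonresonant_load_transmission_phase(self):
        """Through a load that is purely resistive at the probe frequency,
        with same-sign geometric couplings, the implant-mediated S21 has
        phase 180 deg (the expectation for a nonresonant load).  The ports
        are tuned at the probe frequency so their own impedances are real
        there and contribute no phase."""
        model = nominal_wire_model(30.0, 0.02, reference_kind="empty")
        f_probe = model.loads[0].resonator.f0  # load impedance = R here
        s = two_port_scattering(model, np.array([f_probe]))[0]
        phase = abs(np.degrees(np.angle(s[1, 0])))
        assert phase == pytest.approx(180.0, abs=1e-6)

    def test_matches_wave_domain_mesh_oracle(self):
        """Schur-reduced synthesis equals the brute-force full-mesh solve."""
        rng = np.random.default_rng(19)
        for trial in range(4):
            ports = (
                port_resonator(rng.uniform(30, 90), 62e6 + rng.uniform(-1e6, 1e6)),
                port_resonator(rng.uniform(30, 90), 62e6 + rng.uniform(-1e6, 1e6)),
            )
            wire = WirePlacement(rng.uniform(0, 360), rng.uniform(0.3, 1.0), peak_mutual_for_k(0.02))
            extra = ()
            if trial % 2:
                extra = (LoadLoop(wire_resonator(64e6, 80.0), (1e-8, -2e-8)),)
            model = build_birdcage(
                ports, DEFAULT_GEOMETRY, wire, wire_resonator(),
                port_port_mutual=rng.uniform(0, 5e-9), extra_loads=extra,
            )
            freqs = np.linspace(56e6, 74e6, 41)
            s_fast = two_port_scattering(model, freqs)
            s_oracle = wave_domain_oracle(model, freqs)
            np.testing.assert_allclose(s_fast, s_oracle, rtol=0, atol=1e-10)

    def test_reciprocity_everywhere(self):
        model = nominal_wire_model(72.0, 0.025)
        spec = synthesize_spectrum(model, rf_grid(301))
        np.testing.assert_allclose(spec.s_param(1, 2), spec.s_param(2, 1), rtol=0, atol=1e-14)

    def test_azimuthal_period_and_reflection_symmetry(self):
        grid = rf_grid(101)
        ref = nominal_reference("dielectric", grid)
        s_a = synthesize_spectrum(nominal_wire_model(33.0, 0.02), grid)
        s_b = synthesize_spectrum(nominal_wire_model(33.0 + 360.0, 0.02), grid)
        np.testing.assert_allclose(s_a.s, s_b.s, rtol=1e-12)
        # |S_jj| deviation from reference is invariant under theta -> -theta
        s_c = synthesize_spectrum(nominal_wire_model(-33.0, 0.02), grid)
        for j in (1, 2):
            dev_a = np.abs(s_a.magnitude(j, j) - ref.magnitude(j, j))
            dev_c = np.abs(s_c.magnitude(j, j) - ref.magnitude(j, j))
            np.testing.assert_allclose(dev_a, dev_c, rtol=0, atol=1e-12)

    @pytest.mark.parametrize("null_port,split_port", [(1, 2), (2, 1)])
    def test_null_plane_asymmetry(self, null_port, split_port):
        """A wire in one port's E = 0 plane leaves that port's spectrum
        exactly at the wire-free reference while the other port splits."""
        grid = rf_grid(1001)
        theta = 90.0 if null_port == 1 else 0.0
        dut = synthesize_spectrum(nominal_wire_model(theta, 0.03), grid)
        ref = nominal_reference("dielectric", grid)
        np.testing.assert_allclose(
            dut.s_param(null_port, null_port), ref.s_param(null_port, null_port), atol=1e-12
        )
        flag = detect_splitting(dut, ref)
        assert flag.per_port[split_port].flagged
        assert not flag.per_port[null_port].flagged


class TestDrives:
    def test_zero_paths_give_zero_current(self):
        # wire exactly decoupled from port 1, driven only through port 1
        model = BirdcageModel(
            ports=(port_resonator(75.0), port_resonator(75.0)),
            loads=(LoadLoop(wire_resonator(), (0.0, -1e-8)),),
        )
        current = wire_current_under_drive(model, DriveVector(1.0, 0.0), 62e6)
        assert current == 0.0

    def test_global_phase_invariance(self):
        model = nominal_wire_model(25.0, 0.02)
        d = DriveVector(0.6 + 0.1j, -0.3 + 0.7j)
        flipped = DriveVector(-d.a1, -d.a2)
        i1 = wire_current_under_drive(model, d, 61.9e6)
        i2 = wire_current_under_drive(model, flipped, 61.9e6)
        assert abs(i1) == pytest.approx(abs(i2), rel=1e-12)

    def test_linear_in_drive(self):
        model = nominal_wire_model(25.0, 0.02)
        f = 62.1e6
        ia = wire_current_under_drive(model, DriveVector(1.0, 0.0), f)
        ib = wire_current_under_drive(model, DriveVector(0.0, 1.0), f)
        iab = wire_current_under_drive(model, DriveVector(0.3 - 0.2j, 0.8j), f)
        assert iab == pytest.approx((0.3 - 0.2j) * ia + 0.8j * ib, rel=1e-12)

    def test_wire_current_matches_driven_mesh_oracle(self):
        """Reduced-system current equals a direct solve of the driven
        3x3 wave-domain mesh."""
        rng = np.random.default_rng(5)
        model = nominal_wire_model(130.0, 0.025)
        f = 61.7e6
        drive = DriveVector(complex(rng.normal(), rng.normal()), complex(rng.normal(), rng.normal()))
        omega = 2 * np.pi * f
        z = np.zeros((3, 3), dtype=complex)
        z[0, 0] = series_impedance(model.ports[0], omega)
        z[1, 1] = series_impedance(model.ports[1], omega)
        z[2, 2] = series_impedance(model.loads[0].resonator, omega)
        c1, c2 = model.loads[0].couplings
        z[0, 2] = z[2, 0] = 1j * omega * c1
        z[1, 2] = z[2, 1] = 1j * omega * c2
        term = np.diag([model.z0, model.z0, 0.0])
        rhs = 2 * np.sqrt(model.z0) * np.array([drive.a1, drive.a2, 0.0])
        i_oracle = np.linalg.solve(z + term, rhs)[2]
        i_fast = wire_current_under_drive(model, drive, f)
        assert i_fast == pytest.approx(i_oracle, rel=1e-10)

    def test_reflected_power_definition(self):
        model = nominal_wire_model(40.0, 0.02)
        f = 62.2e6
        # single-port drive: |S11|^2 * P
        s = two_port_scattering(model, np.array([f]))[0]
        p = reflected_power(model, DriveVector(np.sqrt(2.0), 0.0), f)
        assert p == pytest.approx(2.0 * (abs(s[0, 0]) ** 2 + abs(s[1, 0]) ** 2), rel=1e-12)
        # arbitrary drive equals |S a|^2
        d = DriveVector(0.5 + 0.5j, -0.7 + 0.1j)
        assert reflected_power(model, d, f) == pytest.approx(
            float(np.sum(np.abs(s @ d.as_array()) ** 2)), rel=1e-12
        )
        # passivity: never exceeds incident power
        assert reflected_power(model, d, f) <= d.total_power

    def test_drive_vector_power_split(self):
        d = DriveVector.from_split(0.1, 0.3, 120.0)
        assert d.total_power == pytest.approx(0.1, rel=1e-12)
        assert abs(d.a2) ** 2 == pytest.approx(0.03, rel=1e-12)
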