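# Methods

This note records the model, its assumptions, the numerical and design
choices, and what the synthetic fixtures do and do not emulate.

## Circuit model

Every resonant structure — a coil drive port, the wire implant's dominant
current mode, a parasitic — is a series-RLC loop. Loops interact only
through mutual inductances; the mesh impedance matrix has `Z = R + jωL +
1/(jωC)` on the diagonal and `jωM` off it. Time convention is `e^{+jωt}`
(inductive reactance `+jωL`); phases are reported in degrees on
(−180°, 180°]. Losses are frequency-independent series resistances — the
simplest model that reproduces the observed line shapes; radiation
resistance, dielectric top-load shifts of the wire resonance, and
transmission-line standing-wave structure on the wire are all outside the
model. The drive is a unit ideal voltage source, so loop currents carry
A/V and drive power never enters the core model.

For two *identical* loops the characteristic equation factorizes exactly
and the closed-form normal modes are `f± = 1/(2π√((L∓M)C))`. This closed
form is only offered in the identical-resonator regime; asymmetric pairs
must go through numerical dip detection on a synthesized spectrum, and the
closed form is continuously guarded in the test suite by a dense-grid
peak-search oracle on the simulated coil current (10⁵ points, agreement
required to 0.1% of the splitting).

Degenerate evaluations — a lossless pair probed exactly on a normal mode,
or f = 0 — raise `DegenerateFrequencyError` naming the frequency rather
than returning infinities, because silent infinities would corrupt the
band integrals downstream.

## Two-port birdcage model

The first-order mode of a linearly driven birdcage has axial electric
field `E_z ∝ (r/a)·cos(θ − φ0)`, zero on the plane 90° from the drive
azimuth and opposite in sign across it. A long z-oriented wire therefore
couples to port *j* with mutual `m_j = M_peak·(r/a)·cos(θ − φ0_j)`; the
two ports sit 90° apart by default. The two ports share **no direct
mutual** by default, so all inter-port transmission is implant-mediated —
the interpretation under which S21 carries implant information; a config
knob (`port_port_mutual`) reintroduces imperfect isolation when wanted.

Loads couple to ports but not to each other, so the exact two-port
reduction is a sum of rank-one reflected terms,
`Z'_jk = Z_j δ_jk + Σ_l ω² c_lj c_lk / Z_l`, and the scattering matrix is
`S = (Z' − Z0 I)(Z' + Z0 I)⁻¹` (the two factors commute, so S is exactly
symmetric — reciprocity holds to machine precision by construction).

**Port polarity convention.** The reference polarity of port 2 is flipped
relative to its Faraday dot. This is a free choice for a coil port —
physically it is the half-turn offset a measurement plane acquires through
cabling and matching — and it is fixed once, package-wide, so that the
implant-mediated S21 through a load that is purely resistive at the probe
frequency has phase **180°** when the two geometric couplings share a
sign, which is the phase a network analyzer shows for a nonresonant load.
Concretely the model works in *effective couplings* `(c1, c2) =
(m1, −m2)`; drives, S-matrices, induced currents and null modes all live
consistently in this one coordinate system (`I_wire ∝ c1·a1 + c2·a2`).

## Detection metrics

The distortion parameter is `D_j = ∫_band ||S_jj(f)| − |S0,jj(f)|| df`,
integrated by the trapezoid rule on the native measurement grid (band
endpoints linearly interpolated). Magnitude difference — not complex
difference — is the default integrand, matching how the deviation is
integrated in practice; a `complex_difference` flag enables the complex
mode for sensitivity studies. The integral is deliberately unnormalized
(units |S|·Hz) with the band recorded in the report, since any bandwidth
normalization would be an arbitrary constant shared by all comparisons.
No resampling ever happens silently: mismatched grids are an error.

Split detection counts absorption dips of |S_jj| (scipy `find_peaks` on
the negated magnitude) with prominence above `max(3 × noise_floor,
min_prominence)`; a port is flagged when it shows at least one more dip
than the reference. The trace noise is estimated from robust second
differences (removing the locally linear line shape); if it exceeds the
configured floor the flag is withheld with a low-confidence annotation
rather than guessed. A single dip more than twice the reference width is
reported as a merged split with `n_peaks = 1` and low confidence.

Monitoring planning sweeps the model family over the coupling range
(default 15 points) and certifies a frequency only if |S_jj| is
single-signed monotone across the *entire* range: the dip-center choice
must be monotone increasing, the wing choice (≥ 5 reference HWHM from the
center, HWHM measured on the reference dip between its in-band baseline
and minimum) monotone decreasing. Everything else — notably the 1–2 HWHM
region that the split dip sweeps through — is rejected. Pearson
correlations use the sample (n−1) normalization; zero-variance frequencies
propagate as NaN (missing), never as zero.

## Localization

`θ̂ = arctan((ΔS22/ΔS11)^p)` with a configurable compensation exponent
*p*. At the dip center the deviation follows the reflected impedance
`(ωm)²/Z_wire`, i.e. it is quadratic in the coupling, so the matched
exponent there is ½; *p* = 1 is the default for regimes where the
deviation is linear in the coupling, and the test suite exercises both.
Magnitudes give four candidates; the S21 phase parity (≈180° ⇔ m1·m2 > 0
under the package convention) retains one orthogonal plane. A single
global offset — circular least squares mod 180°, implemented as the
circular mean of doubled residuals — absorbs the unknown effective drive
points over a sweep; there is deliberately no per-point freedom. Wire
shapes with complex (phase-shifted) coupling are out of scope for the
per-point path.

## Null modes

With `I_wire ∝ c1 a1 + c2 a2`, the null drive is `(c2, −c1)` normalized
to the requested power. For identical port resonators this is exact to
machine precision (the coupling correction to `Z' + Z0` is rank-one along
the coupling vector and annihilates the null direction);
`solve_null_exact` additionally pre-multiplies by `(Z' + Z0)` to stay
exact when the two ports differ. Suppression is quoted in dB against the
equal-power worst case — the conjugate-aligned drive — which makes the
figure well-defined; an exact numerical null is reported capped at 300 dB.

The sweep pulse ramps the port-2 power fraction u linearly 0 → 1 while
the relative phase spins through ≥ 10 full turns (defaults: 50 ms, 2000
samples, 25 turns, 100 mW — the published waveform constrains only the
sub-50-ms timescale and ~100 mW power, so the rates are fixture choices).
Power is conserved exactly at every sample. The sweep's argmin drive
converges to the analytic null at the rate of the phase step (for its
phase) and of the ramp-per-turn (for its amplitude ratio); the reflected
power `‖S·a‖²` correlates positively with |I_wire| when monitoring between
the split peaks and negatively on the wings, and the small phase lag
between current minima and reflected-power extrema is reported but not
thresholded (no quantitative value exists to compare against).

## Synthetic fixtures

Nominal constants: coil ports resonate at 62.0 MHz (the center of the
60.5–63.5 MHz analysis band, mirroring a bench resonance that sits below
the nominal imaging frequency) with L = 12 µH and a 50 Ω match when
empty — a loaded dip HWHM of ≈0.6 MHz, a realistic loaded linewidth that
also places the strong-coupling mode shift at 1–2 half-widths so the full
monitoring phenomenology appears in-band. The wire mode is a 1 µH loop at
62.0 MHz with Q = 150. Dielectric loading adds 25 Ω mean series
resistance and −150 kHz mean shift per port.

Subject-to-subject scatter draws one loading factor per seed
(σ = 10% of the added resistance, shared by both ports) plus independent
per-port frequency jitter (σ = 16.1 kHz). These two constants were set
jointly, once, by measuring the distortion-parameter sensitivity of the
model numerically, so that the dielectric-only ensemble has ≈5% relative
standard deviation in D against the empty coil — the calibration the
generator is specified to have. Wire shapes are represented as
coupling-strength presets (straight/resonant k = 0.03, coiled k = 0.008,
parasitic on port 2 at 63 MHz), not geometric simulations: the analysis
sees any wire only through its effective couplings. Trace noise is
i.i.d. circular complex Gaussian per frequency point.

What the fixtures do **not** emulate: end-ring flux pickup by coiled
leads (visible in practice as anomalous S21 phase), z-dependence of the
birdcage field, drift or 1/f structure in analyzer noise, and any
absolute current/temperature scale. Passing tests therefore demonstrate
the internal consistency and the qualitative phenomenology of the method,
not calibrated safety margins on real hardware.

## Problem sizes

Default spectra use 2001 points over 55–75 MHz. The peak-search oracle
uses 10⁵ points; the localization Monte Carlo runs 24 azimuths × 100
noise draws; the fixture-calibration ensemble uses 100 seeds; sweep
convergence is checked at 10³–1.6·10⁴ samples. These sizes keep every
check comfortably deterministic and fast while leaving the statistics
(RSD, RMS error) stable to well within the asserted margins.

## Known limitations

* Single dominant wire current mode; no multi-mode or traveling-wave wire
  physics.
* Two transmit channels only; larger arrays would generalize the null
  space but are not implemented.
* The distortion parameter is a *relative* coupling monitor; the slope of
  D versus induced current varies with configuration, so no absolute
  current estimate is attempted.
* The localization path assumes real (in-phase) couplings; strongly
  reactive coupling paths break the per-point parity argument.
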