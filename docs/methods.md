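# Methods

This note records the models behind each pipeline stage, the parameters that
matter, and the numerical and design choices made where the design was open.

## Ring array model

Each micro-ring is a symmetric Lorentzian transmission dip in amplitude
transmission: T(f) = 1 − d / (1 + ((f − c)/γ)²), with γ = FWHM/2 and
FWHM = f_optical/Q at the 1550-nm carrier (c = 299 792 458 m/s exactly for all
frequency↔wavelength conversions). No under/over-coupling asymmetry or Fano
line shape is modelled, matching the Lorentzian model used for dip fitting.
Rings on one bus combine multiplicatively (independent resonators); optical
crosstalk beyond spectral overlap is out of scope.

Defaults: Q = 6×10⁵ (middle of the 5–7×10⁵ fabrication range), dip depth 0.9
(deep but not total extinction), adjacent-ring spacing 1.66 GHz. Fifteen rings
centred in the ±20-GHz band span 23.24 GHz centre-to-centre.

`assign_resonances` budgets one spacing-slot per ring (capacity ⌊band/spacing⌋,
consistent with `max_rings_by_spacing`) plus an edge margin of half a FWHM per
side, guarding the demodulation edge effect. The 24.9-GHz "occupied span"
number quoted for 15 rings at 1.66 GHz includes such margins; the module
exposes both the centre-to-centre span and the margin and does not attempt to
reconcile them.

**Pressure sensitivity** (Hz of resonance shift per Pa) is not a published
device number. It is fixed at 10⁵ Hz/Pa as the package's calibration point;
all pressure-referred outputs scale trivially with it.

## Comb synthesis

One OFDM frame of N = 1536 complex baseband samples at 60 GS/s; occupied bins
are all DFT bins with |k·Δf| ≤ 20 GHz (1024 teeth), each with unit magnitude;
the DC bin is zeroed for carrier suppression (modulator biased at its null).
The modulator, amplifiers and optical filter are abstracted into a single
gain-plus-noise stage at the receiver. Subcarrier phases default to the
deterministic Newman quadratic schedule, which keeps the frame's peak-to-
average power ratio at 2.1 (seeded pseudo-random schedules measured 6–9 and
are available as an option; phases never affect tooth powers). No cyclic
prefix or guard interval is used — the channel is static within a frame.

## Interrogation chain

Quasi-static frames: pressure is held constant over each 25.6-ns frame. This
is exact for band-limited drives below the per-ring Nyquist rate Δf/2 ≈
19.5 MHz, where less than half an acoustic period elapses per frame. The
received frame is ifft(X·T) plus circular complex white Gaussian noise; the
per-sample noise std is `receiver_noise_density · sqrt(dac_rate)`.

Demodulation is a per-frame DFT normalised by the analytic no-array reference
(hardware would measure this calibration frame); magnitude transmission is
used for fitting by default.

**Dip tracking** fits, per ring and frame, the teeth within ± spacing/2 of the
tuned centre to a Lorentzian *plus a linear baseline*; the linear term absorbs
the tails of neighbouring dips inside the window. Without it the windowed fit
shows ~1% cross-ring bias; with it, cross-talk on undriven rings is ~0.7% of
the driven-ring RMS and the unbounded Levenberg–Marquardt fit is several times
faster than a bounded one. Fits warm-start from the previous frame's centre;
non-converged frames are interpolated from neighbours and counted; a centre
leaving the window raises a tracking error naming the ring. Recovered-shift
accuracy stays within Δf/10 (≈3.9 MHz): step shifts of 100 MHz are recovered
with ~0.25% bias and an 80-MHz-amplitude tone with ~2% amplitude compression.

**Noise calibration.** The receiver noise density default (4.9×10⁻⁹ /√Hz)
was set once by `calibrate_noise_density` so that the noise-only recovered
pressure floor of the default 15-ring, full-comb configuration integrates to
the parallel-mode noise-equivalent-pressure scale of ≈36 Pa over the ~20-MHz
detection band; re-measuring across seeds gives 35–36 Pa. Crosstalk is always
quantified on a noiseless run, because with noise on, an undriven ring's RMS
is the NEP floor — noise, not leakage.

**Single-ring wideband readout** (`direct_interrogate`) models CW edge
detection: output = (dT/df at the bias) · sensitivity · pressure + noise. For
a Lorentzian the slope magnitude peaks at (FWHM/2)/√3 from the centre, where
the dip has fallen to 3/4 of its depth — not at the half-depth point — and
`optimal_bias_offset` returns that extremum (verified by a dense sweep test).

## Acoustic forward model

Sources and sensors are coplanar; propagation keeps 3-D spherical spreading
(1/r). Synthesis runs in the frequency domain so time-of-flight delays are
exact. Point absorbers carry a Gaussian-derivative (bipolar) signature whose
width follows the excitation pulse (default σ = 1.1 ns, the ns-scale
characterization pulse); finite-radius absorbers add the analytic N-wave of a
uniformly heated sphere (duration 2R/v). Optional power-law amplitude
attenuation (dB·cm⁻¹·MHz⁻ᵉ) is off by default.

**Receive band**: a truncated-Gaussian magnitude exp(−(f−f_pk)²/2σ²) on f ≥ 0
with f_pk ≤ 0, solved in closed form so the contiguous −3 dB and −6 dB widths
equal the configured 115 and 175 MHz (this requires bw₆ ≥ √2·bw₃). The shape
peaks near DC and its −6 dB-band centroid is ≈78 MHz; the nominal 60-MHz
centre frequency enters only the closed-form resolution estimates.

**Angular response**: |sinc(a·f·sinθ/v)|-type spatial-aperture model, clamped
to zero beyond the first null so the gain is monotone nonincreasing in |θ| at
every frequency, with the coefficient pinned so the gain is exactly −3 dB at
±30° for 25 MHz. A consequence worth stating: the usable half-angle shrinks
as 1/f, so NA(f)·f is constant at sin(30°)·25 MHz, and the lateral
point-spread envelope FWHM of a scanned-aperture image is
0.71·v/(sin30°·25 MHz) ≈ 85 μm *independent of scan length*. The simulated
fiber cross-section reproduces this closed form within 3%. Real devices
measured several tens of μm narrower, implying an angular response that
narrows more slowly than 1/f; refining the frequency scaling of the aperture
model is a known limitation.

## Reconstruction

Universal back-projection with b = 2p − 2t ∂p/∂t (central differences for the
derivative), linear interpolation for fractional delays, uniform detector
weights (per element for linear arrays, per angle for rotational scans),
coherent summation across rotation angles in the sample frame, and
normalisation by detector count. Pixels whose time of flight leaves the record
window contribute zero and are counted. Default grid 25-μm pixels; signed
images are stored, with the axial Hilbert envelope applied only for metrics
and display. `profile_fwhm` applies the envelope automatically only when the
profile oscillates (significant negative excursion), so smooth nonnegative
profiles keep their exact width.

## Characterization

Time gating uses a rectangular window with optional raised-cosine tapers.
Frequency responses are magnitude spectra of the gated record normalised to
peak; the analyzer can deconvolve the known excitation spectrum (bins below
10⁻³ of the source peak are zeroed, not amplified), and the characterization
workflow does so — the raw point-source record is source × band, and the
bipolar source signature would otherwise tilt the measured band. Bandwidths
are contiguous widths around the global spectral peak with interpolated
crossings; secondary lobes are ignored. The acceptance-angle map normalises
each frequency row by its on-axis value after compensating 1/r spreading, so
source and band factors cancel exactly. Noise densities use Welch averaging
with Hann segments (4096-sample segments by default). The closed-form
resolution estimates are 0.71·v/(NA·f₀) = 35.5 μm and 0.88·v/Δf = 11.5 μm at
the default parameters.

## Array-vs-single-element contrast gain

The √15 CNR enhancement is checked as a Monte-Carlo property: a fixed
noiseless record set of a low-frequency point target (20-ns excitation, so
every element's acceptance cone covers it — the analogue of the extended
low-frequency biological structures this comparison is made on) receives
fresh iid per-sensor white noise each trial; full-array and central-element
reconstructions are compared. The CNR ratio's expectation is √N because the
aligned signal sums coherently while iid noise grows as √N; the gain is
reported as 10·log₁₀(CNR ratio) ≈ 5.88 dB for N = 15, the scale on which such
array gains are quoted. The background region sits on the far side of the
target ("away from the centre"); near-side regions under-estimate the
single-element background spread because back-projection arcs leave few
independent samples there. Measured: 5.50 ± 0.04 dB over 50 trials.

## Synthetic data: what it does and does not emulate

Phantoms (figure-of-eight hot spot, drifting microsphere, crossed hairs,
branching leaf skeleton) are deterministic per seed and qualitative stand-ins
for the imaging targets; the exact trajectories and vein geometries of the
real experiments are not published. The forward model is linear, homogeneous
and 2-D in-plane: no full-wave propagation, heterogeneous sound speed, shear
waves, optical fluence, polarization, laser drift, modulator nonlinearity or
fiber dispersion. Passing tests therefore demonstrate the correctness and
self-consistency of the interrogation and reconstruction chain under these
idealised conditions, not the performance of any physical device; the
hardware-measured sensor numbers (NEP density, measured resolutions) serve
only as calibration anchors.

## Problem sizes

Defaults used by the test suite and the reproduction script, chosen as
desk-scale versions of the experiments: 2048 interrogation frames (52 μs of
signal) for round trips; 3° rotation steps over 360° for full-view imaging;
0.4-mm linear-scan steps over ±8 mm for planar imaging; 8 frames at 20 Hz for
the moving microsphere; 50 Monte-Carlo trials for the CNR gain; 0.1-mm sweep
steps over ±4 mm for the acceptance-angle map; 14–28-μm scan steps over
2.8 mm for the fiber point-spread (the hardware used 0.7 μm). The fiber
standoff defaults to 2.4 mm so the 2.8-mm scan subtends the full ±30°
acceptance cone, the regime the lateral-resolution formula assumes; at a 5-mm
standoff the scan itself would cap the NA at 0.27.
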