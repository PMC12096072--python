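# Methods

This note documents the models implemented in `triplexion`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Triplex target-site scanning

A triplex target site is modeled as a contiguous tract on one strand of
an annotated promoter satisfying, with defaults:

* length ≥ 15 nt (`min_length`) — the minimum at which short RNA third
  strands form stable Hoogsteen triplexes in vitro;
* pyrimidine interruptions ≤ 10 % of tract length
  (`max_pyrimidine_fraction`) and never two in a row
  (`max_consecutive_interruptions = 1`), mirroring common
  triplex-search practice;
* tract boundaries are purines — an interruption at an edge is simply a
  shorter tract, so admitting it would double-count candidates;
* the tract must overlap the promoter-proximal window
  `[−35 start − margin, +1 + margin]` with `margin = 20 nt`. "Close to
  the consensus" has no canonical quantification; ±20 nt covers the
  footprint of the σ⁷⁰ holoenzyme with slack and is configurable.

Coordinates are 0-based half-open on the sense strand throughout;
template-strand tracts are found by scanning the reverse complement and
mapped back, with `purine_sequence` reported 5′→3′ on the template
strand. Overlapping maximal tracts on one strand are merged into their
union when the union still qualifies (one site per promoter region is
the biologically expected situation); otherwise the longer tract wins.
The scan is exhaustive over substrings (promoters are ≤ a few hundred
nt), which keeps it trivially equivalent to the brute-force oracle used
in the tests.

TFO design maps the purine strand positionwise: pyrimidine motif A→U,
G→C, read parallel; purine motif A→A, G→G, then reversed so the
returned 5′→3′ RNA runs antiparallel. Interruptions receive the
Hoogsteen partner of the complementary purine and are recorded as
mismatches in the TFO's own coordinate frame. Tracts whose dominant
base exceeds 80 % are flagged low-complexity: homopolymeric
(A-rich) tracts fail to form stable triplexes in practice, and the flag
propagates that caveat.

Transcription-unit geometries follow the fixed mapping A: downstream +
template-strand purine, B: downstream + sense, C: within-consensus +
template, D: within-consensus + sense. The shipped direction rule table
(downstream → enhancement, within-consensus → inhibition) is
placement-level only; per-geometry exceptions exist experimentally, so
the prediction is used for consistency reporting and never modifies a
measurement.

## Dissociation constants

**Melt route.** Fluorescence-vs-temperature curves are smoothed with a
Savitzky–Golay filter (window 9 samples, polynomial order 2 — the
smallest window that suppresses instrument-grade noise without shifting
a transition midpoint by more than the 0.5 °C grid step), differentiated
by central differences and negated; half a window is trimmed at each
end. Peaks are local maxima of −dF/dT with prominence ≥ 5 % of the
profile maximum. The hottest peak is the duplex transition (a warning
is recorded if its Tm leaves 45–60 °C); the most prominent cooler peak
is the triplex. Replicate curves are averaged per concentration before
differentiation.

The triplex/duplex peak-height *ratio* (heights, not areas — the
derivative peak intensity is what the titration figures report; areas
are available by flag) is fitted against TFO concentration with a
four-parameter logistic in log₁₀ c. The zero-TFO point cannot sit on a
log axis; it anchors the plateau the response starts from (bottom for
the rising ratio, top for falling duplex-band depletion), leaving top,
log EC₅₀ and Hill slope free. K_d = 10^(log EC₅₀), reported in µM with
a delta-method standard error from the fit covariance. A fitted
transition amplitude below 3× the residual standard deviation — or a
flat series, or curves that never show a second peak — raises a
**"no stable triplex"** signal instead of returning a number, the same
call made for sites that fail to form triplexes experimentally.

**EMSA route.** Duplex band intensities are normalized to the zero-TFO
lane (the per-lane-total alternative is ambiguous when the stain binds
RNA) and fitted with the falling logistic; K_d is the concentration at
half-depletion. Because gel separation and stain affinity distort the
apparent isotherm, this route systematically underestimates K_d; the
generator reproduces this with a `staining_bias ≥ 1` term that divides
the apparent K_d, and the package treats melt-route values as the
reference. The free-TFO band is carried through I/O but ignored in
estimation.

## Kinetic rates and modulation

Reporter fluorescence rates are OLS slopes over fixed windows:
transcription 60–180 min (the reaction reaches steady linearity about
an hour after start; "about 1 h" is hardened to exactly 60 min and is
configurable), coupled transcription–translation 120–240 min (the same
2-h span shifted one hour for ribosomal accumulation lag; lag is
handled purely by the window shift, with no explicit lag-model fit).
Modulation is `(mean_sample − mean_ref)/mean_ref × 100` over ≥ 3
replicate slopes; its spread is first-order ratio propagation of the
replicate slope standard deviations (sd, not sem — the replicate
scatter is the quantity the ± columns of the experimental tables
carry). Significance is a two-sample, two-sided, pooled-variance t-test
(Welch by flag) with the usual 0.05/0.01/0.001 star thresholds; the
direction (enhancement/inhibition) is only asserted when significant.
Blot quantification divides sample replicate intensities by the paired
reference replicate (falling back to the reference mean when counts
differ) and tests the ratios against 1.0 with a one-sample t-test.

## Triplex geometry and the strain optimum

From a three-chain structural model the package extracts, using the C1′
glycosidic anchor as the representative atom (configurable to any atom
name; the reference measurements were made interactively in a viewer
without a stated atom, and C1′ is the standard nucleotide reference
point):

* **L₁, L₂** — mean of the three unordered pairwise distances among the
  terminal-triad representative points at the 5′ and 3′ ends of the
  polypurine strand (a duplex-pair-only variant is available by flag,
  since "distance between nucleotide pairs in the same plane" admits
  both readings);
* **|L₁−L₂|** — end-to-end asymmetry, the duplex-strain proxy;
* **L₃** — distance between the two triad centroids, i.e. helix length
  (consistent with ~14 steps × ~3.4 Å rise for 15-mers).

Chain roles (Watson–Crick purine / pyrimidine / RNA third strand) are
inferred when absent: the chain with O2′ atoms is the RNA; of the DNA
chains the purine-richer is the purine strand; ties demand an explicit
role map. Terminal triads are matched by proximity to the purine-strand
termini, so parallel and antiparallel chain layouts need no annotation.
All metrics are rigid-body invariant by construction (tested to
10⁻⁹ Å).

The strain–modulation relation is fitted with a biphasic sigmoid — the
product of a rising and a falling logistic plus baseline,
`f(d) = b + A·σ((d−d₁)/w₁)·σ(−(d−d₂)/w₂)` — by bounded least squares
from a deterministic grid of ≥ 8 initializations (staggered midpoint
pairs × two width scales); the lowest residual sum of squares wins, and
the peak is read off a 0.001 Å grid over the data range. A maximum on
the range boundary means the data are monotone and a "no peak" signal
is raised. With six data points and six parameters the model can nearly
interpolate; width lower bounds (10⁻³ of the data span) and the
deterministic multistart keep the fit reproducible, and the residual
sum of squares is reported so that degenerate fits are visible.

Which distance metric pairs with which modulation series was an open
choice; the package fits all four metrics side by side against the
downstream-geometry (A) modulation values and reports the best fit by
residual sum of squares. On the shipped reference tables the 3′-plane
distance L₂ wins decisively and places the enhancement optimum at
10.35 Å, with tighter and wider geometries losing enhancement — the
strain-optimum picture the analysis was built to test.

## Synthetic data: what it does and does not emulate

All generators are pure functions of (parameter block, seed); identical
inputs give byte-identical outputs.

* **Melt curves** — two independent logistic transitions (duplex at
  50 °C, triplex at 42 °C, width 0.8 °C, equal amplitudes) on a
  25→95 °C, 0.5 °C ramp; the triplex amplitude scales with the
  single-site bound fraction c/(c + K_d) (no TFO depletion: the duplex
  target is far below K_d, as in the emulated titrations);
  multiplicative Gaussian noise (default 2 %), 3 replicates. Unless
  given explicitly, the seven nonzero concentrations are log-spaced
  over K_d × 10^±1.1 — a titration designed to bracket its transition,
  as the emulated experiments were. This is *not* a coupled
  partition-function melting model: transition coupling, baseline
  slopes and hysteresis are absent, so passing recovery tests shows the
  derivative-ratio statistics work, not that any real curve shape is
  reproduced.
* **Gel lanes** — duplex ∝ 1 − f, triplex ∝ f with the apparent
  isotherm computed from K_d / staining_bias; no migration physics.
* **Kinetics** — baseline + rate·max(0, t − lag), plateau-capped,
  5-min sampling over 8 h; additive trace noise (sd 2 a.u.) and 5 %
  replicate-level rate jitter, matching the replicate scatter of the
  emulated rate tables. No plate-reader drift or evaporation effects.
* **Helix** — three C1′ strands on ideal helical paths (radius 6.1 Å,
  phases 0/120/240°, twist 32.7°, rise 3.4 Å), the pyrimidine strand
  antiparallel, the RNA chain carrying O2′ pseudo-atoms; a linear
  radius taper injects controllable end-to-end strain with
  |L₁−L₂| = √3·taper. These are geometric scaffolds, not force-field
  models.
* **Promoter** — consensus hexamers at configured positions in a
  random background that forces a pyrimidine every 4th position on each
  strand, with the embedded tract flanked by double interruptions on
  its purine strand, so the tract is provably the unique discoverable
  site.
* **Strain points** — distances sampled over a range with modulation
  from the same biphasic model (rescaled so the injected amplitude is
  attained at the peak) plus additive noise.

Calibration results under these conditions (computed by the test
suite): noiseless K_d recovery is exact to < 0.1 % across 0.5–19 µM; at
2 % noise with 3 replicates, ≥ 95 of 100 seeded runs land within a
factor 1.5; injected rate multipliers 0.6–1.5 are recovered as percent
modulation within ± 2 points on average over 100 seeds; the noiseless
strain-peak round trip is exact to ± 0.005 Å.

## Degenerate inputs and tie-breaks

Zero-variance replicate groups skip the t-test (ns unless the means
differ with zero spread). Profiles with no peak above threshold yield
an empty call list and a zero titration response. Equal purine
fractions in the two DNA chains, missing representative atoms, chain
count ≠ 3, unequal residue counts, empty joins and duplicate join ids
are all hard errors with descriptive messages. Proximity-window margins
extending beyond the sequence are clamped, not errors.

## Known limitations

* The biphasic peak fit on six points is close to saturated; the
  reported optimum should be read together with its residual sum of
  squares, and the per-metric fits are all exposed.
* Melt-shape thermodynamics (ΔH/ΔS), Mg²⁺/pH dependence, gel
  densitometry from images, mechanistic polymerase ON/OFF kinetics and
  force-field-quality structure generation are out of scope.
* The direction rule table encodes placement-level behavior only; it
  does not reproduce per-geometry exceptions.
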