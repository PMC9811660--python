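# Methods

## The relaxation model

A nitroxide spin label contributes a paramagnetic transverse relaxation rate
to a nearby ¹H nucleus

Γ₂(r) = (K / r⁶) · (4 τc + 3 τc / (1 + ω_H² τc²))

where r is the electron–nucleus distance (Å), τc the rotational correlation
time of the complex, ω_H the ¹H Larmor angular frequency, and
K = 1.23×10¹⁶ Å⁶ s⁻² (= 1.23×10⁻³² cm⁶ s⁻²) the dipolar interaction constant
for a nitroxide S = 1/2 electron and a proton; the electron-spin quantities
(S, g, γ, β) are absorbed into K.  This is the standard
Solomon–Bloembergen transverse spectral-density combination; at the default
field and correlation time (ω_H τc)² ≈ 4×10⁴, so the dispersive term
contributes < 0.01% and Γ₂ is effectively K·4τc/r⁶ (this limit is checked in
the test suite).

The observable is the oxidized/reduced peak-intensity ratio, modelled as

I_ox / I_red = [R₂ / (R₂ + Γ₂)] · exp(−Γ₂ t_evol)

combining the steady-state amplitude loss from line broadening with the
exponential loss over the transverse evolution period of the pulse sequence.
R₂ (diamagnetic) is taken as π × linewidth-at-half-height, the Lorentzian
convention.

### Fast exchange

For a weak complex exchanging fast on the relaxation timescale the observed
rate is the population-weighted bound-state rate, Γ₂_obs = p·Γ₂_bound.  All
population inference assumes this regime.  It is self-consistent here: the
inferred K_D values are ≥ millimolar, for which dissociation rates are far
faster than the ~10³ s⁻¹ relaxation rates involved.  Intermediate or slow
exchange, cross-correlated relaxation, and solvent PREs are out of scope.

### Parameters

| parameter | default | units | provenance |
|---|---|---|---|
| τc | 4.0×10⁻⁸ | s | stated correlation time of the ~100 kDa assembly |
| ¹H frequency | 8.0×10⁸ | Hz | spectrometer used for the PRE spectra |
| linewidth (dia) | 25.0 | Hz | estimated from cross-peaks |
| t_evol | 9.0×10⁻³ | s | calibrated; see below |
| K | 1.23×10¹⁶ | Å⁶ s⁻² | standard nitroxide–¹H constant |
| labeled_total | 2.0×10⁻⁵ | M | observed-domain concentration |
| partner_total | 1.1×10⁻⁴ | M | spin-labeled partner at the endpoint |

**t_evol calibration.** The transverse evolution time of the experiment is
not a published number, and the exact ratio expression used in the original
analysis (whether it contains an exponential factor and over which period)
is not reproducible from the text.  We adopt the amplitude×exponential form
above and set t_evol = 9 ms, the value at which the model reproduces both
published full-occupancy predictions simultaneously (ratio ≈ 3×10⁻⁶ at 11 Å
and ≈ 2×10⁻⁷ at 10.6 Å) as well as the worked population inversions (0.7%
and 0.9%) and the ≤ 19 Å strong-PRE threshold.  The parameter is exposed on
`SpinSystemParams`; conclusions in the weak-attenuation regime (ratios
0.7–1.0) are only mildly sensitive to it because the amplitude term
dominates there.

### Inversions

- ratio → Γ₂: bracketed Brent root-finding on the forward model
  (round-trips to 10⁻⁹ relative).  Observed ratios ≥ 1 — common, since
  baseline noise scatters ratios up to ~1.2 — clip to Γ₂ = 0 (no binding
  information) rather than being rejected.  Ratios ≤ 0 are rejected: a peak
  broadened beyond detection carries only a lower bound on Γ₂.
- ratio + distance → population: p = Γ₂_obs/Γ₂_bound(r), clipped to [0, 1].
- population ↔ K_D: 1:1 mass action at the stated totals; the p→K_D
  direction is closed-form, the K_D→p direction solves the binding quadratic
  via the numerically stable root (no cancellation at large K_D).
- target ratio + population → distance: closed form
  r = (p·K·j(τc)/Γ₂_target)^(1/6), exact because Γ₂ ∝ r⁻⁶; cross-checked in
  tests against generic root-finding.

## Structure-derived distances

Crystal structures carry no spin label, so a pseudo-atom stands in for the
nitroxide: `cbeta` uses the Cβ coordinate of the mutated residue
(conservative, underestimates reach), `cbeta_extended` (default, 7.0 Å)
pushes along the Cα→Cβ direction to approximate the nitroxide midpoint of
the MTSL linker.  No rotamer-ensemble averaging or ⟨r⁻⁶⟩ weighting is
attempted; published per-residue distances can instead be supplied directly
via `DistanceTable.from_pairs`, which decouples the population/K_D
arithmetic from the probe model entirely.

Amide distances are measured to the backbone nitrogen by default because
X-ray structures usually lack hydrogens; this carries a systematic ~1 Å
uncertainty relative to the NH proton, negligible beside the probe-position
uncertainty.  Residue renumbering between construct and crystal is explicit
configuration (`chain_map`); no sequence alignment is attempted.  Distance
tables are invariant under rigid-body motion of the structure (tested with
random rotations/translations) and report unmeasurable residues in a
`missing` list instead of dropping them.

For methyl-bearing residues (`atom_role="methyl_C"`), the nearest methyl
carbon per residue is used so that tables keep one row per residue and the
footprint logic is conservative (the closest methyl dominates the r⁻⁶
average anyway).

## Peak tables and profiles

PRE per replicate is I_ox/I_red; profiles report the replicate mean and the
sample (n−1) standard deviation, matching duplicate-experiment error bars.
An alternative profile divides summed intensities across replicates (the
added-spectra convention); the two agree exactly when per-replicate ratios
agree.  Records with non-positive reduced intensity are flagged invalid and
counted, never silently dropped.

Classification bins are half-open [lo, hi), exhaustive over [0, ∞):
strong [0, 0.4), intermediate [0.4, 0.6), moderate [0.6, 0.8),
baseline [0.8, 1.2), elevated [1.2, ∞).  The half-open convention is chosen
for exhaustiveness; it only affects values exactly at a boundary.  Region
annotation (primary / polybasic / tripartite surfaces of the C₂B domain)
ships as an editable mapping seeded with the exemplar residues the source
structures highlight, not an exhaustive list.

The perturbation analysis for non-PRE titrations divides bound-sample by
free-sample intensities at the free-form peak positions, normalizes by the
arithmetic mean over all assigned residues (cancelling concentration and
gain differences between samples — the analysis is exactly invariant to
global scaling of either spectrum), and flags residues below a 0.75
threshold.

## Mode assessment

For each candidate binding mode the distance table fixes, per residue, the
ratio expected at full occupancy and the population implied by the observed
ratio.  The summary compares the expected strong-PRE footprint (residues
closer than the distance at which the full-occupancy ratio crosses the
strong threshold, default 0.4) with the observed strong set; a mode with no
overlap is reported unsupported — the argument structure for rejecting a
binding mode.  Each residue's observed ratio caps the population and hence
bounds K_D from below; the summary reports the largest of these lower bounds
with its residue, the most constraining single observation.  Exposed
side-chain peaks can show sporadic close contacts with the probe without
specific binding, so side-chain assignments participate only when present in
both tables and are interpreted with that caveat.

Point estimates only: the underlying probe-position and exchange-regime
assumptions dominate the error budget and are not quantified here, so no
per-residue error bars are attached to populations or K_D values.

## Synthetic experiments

The generator emulates the titration endpoint: a residue set with known
probe distances, a true bound population, duplicate spectra, and
multiplicative log-normal noise on every intensity (mean exactly 1,
CV configurable).  Log-normal noise keeps intensities positive;
the 3% default CV approximates the observed width of the experimental
baseline band (ratios 0.8–1.2) and is an assumption, not a reproduction —
the true intensity-noise magnitude of the source experiments is unknown.
A titration-ladder constant (20/50/80/110 µM partner) mirrors the published
concentration series for users simulating full titrations.

What the generator does *not* emulate: chemical-shift changes and peak
overlap, H/D-exchange intensity loss, residue-to-residue linewidth
variation, or correlated noise between the oxidized and reduced
measurements.  Passing recovery tests therefore demonstrate the correctness
and conditioning of the inversion pipeline under the model's own
assumptions, not robustness to every artifact of real spectra.

With zero noise the pipeline is an exact identity: simulate → profile →
invert returns the true population at every informative residue to 10⁻⁹
relative tolerance (the primary end-to-end test).  The Monte-Carlo recovery
study (200 trials per condition, one close-contact residue at 10.6 Å,
CV 2%) recovers a 1% true population with median error well inside ±30%;
trial seeds are spawned deterministically from a single study seed.  These
problem sizes run in seconds and are the defaults used by the test suite
and examples.

## Numerical choices and degenerate inputs

- Root-finding: Brent's method with relative tolerance 10⁻¹³; brackets grown
  geometrically from [0, 1] s⁻¹.
- Ratios ≥ 1 → p = 0 (flagged "no binding information" in assessments, None
  for K_D); p = 0 → K_D reported as an explicit error (infinite), never a
  number; p·labeled_total ≥ partner_total → infeasibility error.
- Glycine probe sites fall back from Cβ to Cα with a warning.
- Predicted ratios below ~10⁻¹² underflow the inversion's meaningful range
  and are excluded from round-trip guarantees (the peak is long gone at that
  point).

## Known limitations

- Single-mode interpretation: each assessment attributes observed
  attenuation to one binding mode at a time; no mixture deconvolution.
- The probe pseudo-atom is a fixed point, not an ensemble; distances nearer
  than ~6 Å to the label are dominated by label flexibility the model does
  not capture.
- No fitting of τc from data — it is an input.
- The K_D arithmetic assumes a single 1:1 equilibrium; competing binding
  modes at other surfaces bias inferred populations toward zero at the
  probed surface.
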