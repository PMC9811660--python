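# spinpre

Spin-label PRE analysis for weak, sparsely populated protein–protein
complexes.

Nitroxide spin labels (MTSL) attached to engineered cysteines broaden NMR
cross-peaks of nuclei that come close to the unpaired electron, with an
r⁻⁶ distance dependence.  Because the effect is enormous at close range, the
ratio of peak intensities measured before (oxidized, paramagnetic) and after
(reduced, diamagnetic) quenching of the label reports on complexes populated
at well below 1% — which makes the *absence* of expected attenuation a
quantitative upper bound on how populated a candidate binding mode can be.
`spinpre` implements this entire inference chain for the kind of question it
was built around: does the Synaptotagmin-1 C₂B domain bind the
SNARE–complexin-1 bundle through a proposed "tripartite" interface in
solution, and if not, how weak must that interaction be?

## Model

The observable for each residue is the intensity ratio

```
I_ox / I_red = [R₂ / (R₂ + Γ₂)] · exp(−Γ₂ t)
```

with diamagnetic rate R₂ = π·Δν (Lorentzian linewidth Δν at half height),
transverse evolution time t, and paramagnetic rate

```
Γ₂(r) = (K / r⁶) · (4 τc + 3 τc / (1 + ω_H² τc²))
```

for electron–nucleus distance r, rotational correlation time τc, ¹H Larmor
frequency ω_H, and the nitroxide–¹H interaction constant
K = 1.23×10¹⁶ Å⁶ s⁻².  For a weak complex in fast exchange the observed rate
is p·Γ₂ for bound fraction p, so an observed ratio at a structure-predicted
distance inverts to a population, and 1:1 mass action at the known total
concentrations converts p to a dissociation constant K_D.

Defaults describe the titration endpoint of the target experiments:
τc = 40 ns, 800 MHz, 25 Hz linewidth, t = 9 ms, 20 µM observed domain
against 110 µM spin-labeled partner.

## Worked example

```python
from spinpre import (SpinSystemParams, BindingContext,
                     population_from_ratio, kd_from_population)

params = SpinSystemParams()   # 40 ns, 800 MHz, 25 Hz, 9 ms
ctx = BindingContext()        # 20 uM observed / 110 uM partner

for residue, ratio, distance in [(350, 0.89, 11.6), (354, 0.77, 10.6)]:
    p = population_from_ratio(ratio, distance, params)
    kd = kd_from_population(p, ctx)
    print(f"residue {residue}: ratio {ratio:.2f} at {distance:.1f} A -> "
          f"population {100*p:.1f}%  K_D {1e3*kd:.0f} mM")
```

prints

```
residue 350: ratio 0.89 at 11.6 A -> population 0.7%  K_D 16 mM
residue 354: ratio 0.77 at 10.6 A -> population 0.9%  K_D 12 mM
```

i.e. even attributing the faint attenuation at these two amides entirely to
the candidate binding mode, that mode is under 1% populated and its affinity
is in the tens-of-millimolar range — no substantial binding in solution.
The `examples/` directory has one short script per capability: ratio
inversion, sensitivity curves and detection limits, peak-table profiling and
perturbation analysis, structure-derived strong-PRE footprints with a mode
verdict, and Monte-Carlo recovery of known populations from simulated noisy
spectra.

## Package layout

- `spinpre.model` — forward model, inversions (ratio ↔ Γ₂, p ↔ K_D),
  distance solving
- `spinpre.geometry` — PDB/mmCIF loading (gemmi), spin-label pseudo-atom
  placement, per-residue distance tables, strong-PRE footprints
- `spinpre.tables` — peak-table parsing, replicate PRE profiles with
  classification and region annotation, normalized-ratio perturbation
  analysis
- `spinpre.assess` — observed-vs-predicted joins per binding mode,
  theoretical curves, detection limits, K_D lower bounds
- `spinpre.simulate` — synthetic oxidized/reduced peak tables, recovery
  studies, fixture structures
- `spinpre.config` — YAML/JSON parameter loading

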