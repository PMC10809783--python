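# monosurf

Quantitative analysis of pulmonary-surfactant film biophysics: iso-cycle
metrics from surfactometry traces and structural metrics from molecular
monolayer coordinate frames, with ground-truth synthetic data generators for
validating every stage.

Pulmonary surfactant is the lipid–protein film lining the alveolar
air–liquid interface; its job is to drive surface tension toward zero on
compression (exhalation) and respread on expansion. Two instrument classes
probe this function: a Langmuir–Blodgett trough (LBT) records
surface-pressure/area (Π–A) isotherms under quasi-static barrier cycling,
and a constrained sessile drop (CSD) surfactometer records
surface-tension/area (γ–A) iso-cycles at physiological rates.
Atomistic simulations of the same films produce coordinate frames whose
lateral organization (liquid-condensed vs liquid-expanded phase, chain
tilt, interfacial partitioning of dissolved chemicals) explains the
functional readouts. `monosurf` implements both analysis arms for anyone
studying how inhaled chemicals — e.g. flavoring aldehydes and their acetal
byproducts in vaping aerosols — perturb surfactant films.

## What it computes

**Trace metrics** (`monosurf.trace_io`, `monosurf.surface_metrics`)

- Surface pressure ↔ tension conversion, Π = γ₀ − γ with γ₀ = 72.8 mN/m for
  clean water at 20 °C.
- Segmentation of A(t) into compression/expansion iso-cycles (median
  smoothing + amplitude-filtered turning points).
- Per-cycle extrema Π_max / γ_min and the areas where they occur.
- Compressibility modulus κ = −A (∂Π/∂A), the reciprocal of the
  compressibility C, computed pointwise along a branch with Savitzky–Golay
  smoothing (9-point default), plus the endpoint "global compressibility"
  |Δγ/ΔA| for sparsely sampled drop cycles.
- Hysteresis ΔA: the area gap between compression and expansion branches at
  half the cycle's maximum surface measure.
- γ_min decay kinetics across cycles: mono/biexponential fits parameterized
  directly by half-lives, y(t) = plateau + Σ aᵢ·2^(−t/t½ᵢ), with
  extra-sum-of-squares F-test model selection.

**Monolayer structure** (`monosurf.monolayer`)

- PDB/GRO frame loading (multi-model supported), leaflet assignment, area
  per lipid.
- L_c packing fraction: DBSCAN clustering (cutoff 0.71 nm, 6 neighbors) of
  the 10th acyl carbons and cholesterol C14 atoms in the membrane plane
  under periodic minimum-image distances.
- Acyl-chain tilt: angle between the C1→C16 chain vector and the monolayer
  normal, folded to [0°, 90°].
- Number-density profiles along z, phosphate-centered and max-normalized.
- Heavy-atom contact counts within 0.6 nm, normalized by the number of
  possible partner pairs; contacts-vs-area series and two-replica
  mean/half-difference aggregation.

**Synthetic data** (`monosurf.synthetic`) generates all of the above inputs
with exact attached ground truth: protocol-default LBT/CSD traces riding a
constant-κ₀ isotherm with controllable hysteresis and kinks, decay series,
and two-leaflet monolayer frames with hexagonally packed L_c patches,
disordered regions, tilted chains, cholesterol, interfacial chemical
particles, and protein inclusions.

## Worked example

```python
import numpy as np
from monosurf import synthetic, trace_io, surface_metrics as sm, monolayer as ml

# A ten-cycle trough run (215 -> 56 cm^2 at 150 cm^2/min) on a film of
# constant modulus 100 mN/m with 3 cm^2 of constructed hysteresis.
tr, truth = synthetic.generate_trace(
    synthetic.TraceSpec(seed=7, kappa0=100.0, hysteresis_shift=3.0))
cycles = trace_io.segment_cycles(tr)
print(f"cycles: {cycles.n_cycles} ({cycles.n_complete} complete)")

c0, c1 = cycles.cycles[0].compression
curve = sm.modulus_curve(tr.area[c0:c1+1][::-1], tr.surface_value[c0:c1+1][::-1])
mask = (curve.pressure_grid > 5) & (curve.pressure_grid < 60)
print(f"kappa (5-60 mN/m): {curve.kappa_raw[mask].mean():.2f} mN/m")
h = [x for x in sm.cycle_hysteresis(tr, cycles) if x is not None]
print(f"hysteresis at half-max: {np.mean(h):.3f} cm^2")

# A fully condensed 149-lipid leaflet at 55 A^2 per lipid, chains tilted 25 deg.
frame, ft = synthetic.build_monolayer_frame(synthetic.MonolayerSpec(
    n_lipids_per_leaflet=149, apl=55.0, lc_patch_fraction=1.0, tilt_deg=25.0, seed=7))
print(f"L_c fraction: {ml.packing_fraction(frame).lc_fraction:.3f}")
print(f"mean tilt: {ml.chain_tilt(frame).mean_tilt:.2f} deg")
print(f"APL: {ml.area_per_lipid(frame):.1f} A^2")
```

Output:

```
cycles: 10 (10 complete)
kappa (5-60 mN/m): 100.00 mN/m
hysteresis at half-max: 3.000 cm^2
L_c fraction: 1.000
mean tilt: 25.00 deg
APL: 55.0 A^2
```

The segmentation finds exactly the ten generated cycles; the pointwise
modulus recovers the generating κ₀; the half-maximum area gap returns the
constructed 3 cm² shift; and the structural analyses recover the
constructed packing, tilt and area per lipid of the frame.

A `monosurf` command-line interface wraps the same stages
(`monosurf trace segment`, `monosurf metrics`, `monosurf mono analyze`,
`monosurf simulate ...`, `monosurf validate`, `monosurf run --config
run.yaml`); see `monosurf --help`.

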