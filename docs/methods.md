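# Methods

## Scope and data model

`monosurf` analyzes two kinds of input. A *surfactometry trace* is a
timestamped series of interfacial area and a surface measure in mN/m —
surface pressure Π for Langmuir–Blodgett trough (LBT) exports (area in
cm²), surface tension γ for constrained sessile drop (CSD) exports (area in
mm² of drop surface). The two measures are related through the clean-water
reference, Π = γ₀ − γ, with γ₀ = 72.8 mN/m at 20 °C. A *monolayer frame* is
a labeled set of atom coordinates (nm) for a two-leaflet system: lipid
monolayers at the two water–vacuum interfaces of a thin water slab,
periodic in x and y, optionally containing a protein inclusion and
interfacial "chemical" particles.

## Trace segmentation

The area series is smoothed with a centered moving median (default window
5 samples) — robust against single-point jitter without displacing
monotone ramps — and turning points are found with a zigzag filter that
ignores reversals smaller than `min_amplitude_fraction` (default 0.02) of
the global area range. Because median smoothing flattens sharp reversals,
each detected turn is snapped to the raw-area extremum within half a
smoothing window, so noiseless triangle vertices are recovered exactly. A
cycle is a compression branch (area non-increasing) plus its expansion;
trailing incomplete cycles (CSD runs stop at a fixed 120 s, usually
mid-cycle) are retained but flagged, and window summaries skip them.

## Iso-cycle metrics

*Extrema.* Π_max (pressure traces) or γ_min (tension traces) is the raw
sample extremum of each cycle; no interpolation, since instrument sampling
is dense relative to the extremum's flatness.

*Compressibility modulus.* κ = −A (∂Π/∂A) = 1/C, with C the area
compressibility. The derivative uses centered finite differences on the
(possibly non-uniform) area grid, one-sided at the ends; consecutive
duplicate areas are collapsed by averaging first, and a non-monotone branch
is an error naming the first violation. The smoothed curve applies a
Savitzky–Golay filter to the raw pointwise modulus — default window 9,
polynomial order 3 (the order is a package choice; 3 preserves the
curvature of the biphasic κ(Π) shape). Note that pointwise derivatives of
a noisy isotherm are noise-dominated: at 0.2 mN/m Gaussian noise and
~200 samples per branch the raw modulus scatters by tens of percent and a
9-point filter reduces, but does not remove, that scatter. The smoothed
curve is unbiased around the true modulus; for quantitative κ values from
noisy data, average over a pressure window. κ is best computed on the
first-cycle compression branch, where the film is still complete.

*Global compressibility.* For drop cycles with few samples, the endpoint
slope (γ_max − γ_min)/(A@γ_max − A@γ_min) on the compression branch,
reported as a positive magnitude with the signed slope retained.

*Hysteresis.* The level is half the whole-cycle maximum of the surface
measure; each branch's area at that level comes from linear interpolation
at its first crossing, and ΔA = A_compression − A_expansion (positive when
the expansion branch lies inside, the usual loss/refinement signature).
Using the whole-cycle maximum rather than the compression-branch maximum is
immaterial for well-formed cycles, where the two coincide.

*Decay kinetics.* γ_min across cycles is fitted with
y(t) = plateau + Σ aᵢ·2^(−t/t½ᵢ), aᵢ ≥ 0, t½ᵢ > 0 — the half-life
parameterization makes printed half-lives the parameters themselves
(helpers convert to e-folding rates). Fitting is deterministic: a fixed
log-spaced half-life grid spanning [min Δt, 10·T] provides candidate
half-lives, non-negative linear least squares (NNLS) gives amplitudes and
plateau at each candidate, and the best grid point seeds a bounded
trust-region refinement. The biexponential is never reported with a worse
residual than the monoexponential (the mono optimum is a boundary point of
the bi model; if refinement lands worse, the embedded mono solution is
substituted). `model="auto"` selects bi over mono by the
extra-sum-of-squares F test at α = 0.05, the convention of the commercial
fitting packages used for such curves; corrected AIC is available as an
option. Degenerate constant series resolve to a flat monoexponential with
zero amplitude.

## Monolayer structure

*Loading.* PDB and GRO files are read through MDAnalysis (positions
converted Å → nm). Multi-model PDBs are supported; because some readers
drop CRYST1 boxes on multi-model files, the loader falls back to parsing
the CRYST1 records directly, accepting the GROMACS convention of one
CRYST1 per MODEL (which is also what the package's own series writer
emits, since a compression series needs a per-frame box). Residue names
resolve to a closed species vocabulary (DPPC/POPC/POPG/CHOL/PROTEIN/
CHEMICAL/WATER/ION) through a mapping that covers CHARMM-style and builder
names and can be extended via YAML; unknown residues are a hard error
listing the names.

*Leaflets.* A lipid belongs to the upper leaflet when its headgroup marker
(phosphate P, else the molecule centroid) lies above the water-slab mean z
(or an explicit midplane); ties go upper with a warning.

*Area per lipid.* box_x·box_y / N_lipids(leaflet), reported in Å² (the
field's unit) while coordinates stay in nm; one conversion point.

*L_c packing fraction.* The 10th acyl carbon of every phospholipid chain
and the C14 atom of every cholesterol are clustered in (x, y) by DBSCAN
with eps = 0.71 nm under periodic minimum-image distances. "Six neighbors
within the cutoff" is read as six *other* points (a `count_self` flag
exposes the alternative); border points attached to a cluster count as
condensed, since they are part of a tightly packed cluster — an
`include_border` flag exposes the stricter core-only convention. The L_c
fraction is the clustered share of entities; a per-frame wrapper reports
the time mean and standard deviation. The implementation (scikit-learn
DBSCAN on a precomputed periodic distance matrix) is tested for exact
label agreement against an independent brute-force O(N²) DBSCAN.

*Chain tilt.* Per chain, the angle between the C1→C16 vector and z, folded
to [0°, 90°] so leaflet orientation and chain direction conventions cannot
flip signs; averaged over chains (two per phospholipid), cholesterol
excluded.

*Density profiles.* Per-species number densities along z, re-centered every
frame at the leaflet's mean phosphate z (removing interface drift) with the
positive axis pointing away from water, accumulated over frames, then each
species divided by its maximum (absent species yield a flagged all-zero
profile). Default bin width 0.1 nm.

*Contacts.* Heavy-atom pairs (hydrogens excluded by atom name) between two
disjoint groups within 0.6 nm under 3D periodicity, counted with a
periodic k-d tree and normalized by N_A·N_B, the number of possible
interaction partners. Contacts-vs-area bins per-frame normalized contacts
by APL; empty bins are omitted (flagged) to keep the grid strictly
increasing. Two replicas aggregate to per-bin mean and half absolute
difference — the error convention for duplicate simulations.

## Synthetic data: what it emulates, and what it does not

The generators produce inputs whose ground truth is exact by construction,
so every analysis stage can be validated as a round trip.

*Traces.* LBT: a triangle-wave area schedule, ten cycles between 215 and
56 cm² at 150 cm²/min; the sampling interval is snapped so barrier
reversals land on samples, making expansion samples exact mirrors of
compression samples. CSD: a sinusoidal schedule with ≤ 20% area reduction
at 20 cycles/min, 5 frames/s for 120 s (600 samples; the final cycle ends
mid-stroke and is flagged, as in real runs). The surface measure follows
the constant-modulus isotherm Π(A) = κ₀ ln(A_max/A) capped at
`pi_max_target`, with optional kink plateaus. Defaults: κ₀ = 100 mN/m
(LBT) and 300 mN/m (CSD) — the drop sweeps γ from ~72 to single digits
over only ~20% of area, so the effective film is stiffer. Hysteresis is
constructed by recording the expansion branch at areas rigidly shifted
inward by `hysteresis_shift` while the surface values follow the unshifted
schedule; the expansion branch is then an exact displaced copy of the
compression branch, interpolation errors cancel, and the half-maximum gap
recovers the shift to float precision.

*Decay series.* Direct evaluation of the half-life model plus seeded
Gaussian noise. Test conditions use the published half-life magnitudes
(44.52 s and 253.2 s); noisy-recovery checks use 600 samples over 1200 s
(≈ 4.7 slow-phase half-lives — a record must span several half-lives to
pin down the slow phase) at noise 5% of the phase amplitude.

*Monolayer frames.* Lipids are marker-bearing rods, not chemically
realistic molecules: every analysis consumes only the marker atoms (C1,
C10, C16 per chain; cholesterol C14; phosphate P) and heavy-atom
positions, so realism beyond the markers would add cost without
information. Composition is apportioned by largest remainder (default
68:20:10:2 DPPC:POPC:POPG:CHOL; 60:20:10:10 for compression series), and
the box is sized so the area per lipid matches the requested value exactly. A chosen
fraction of chain/cholesterol entities sits on a hexagonal lattice
(spacing 0.48 nm, typical condensed-phase chain packing) built as complete
x-periodic rows: interior-row sites are DBSCAN cores, edge-row sites are
borders within one spacing of a core, and leftover entities are placed as
close satellites of interior sites — so the constructed L_c membership is
exact, including odd counts. The disordered remainder sits on a jittered
sparse hexagonal lattice with guaranteed minimum periodic separation
0.717 nm > eps, the densest arrangement that keeps non-L_c membership
unambiguous (plain random placement with such an exclusion cannot reach
the required density at physiological APL). This coupling implies
physically sensible spec choices: fully condensed frames want small APL
(~55 Å²), fully disordered ones large APL (≳ 105 Å²); infeasible
combinations raise a geometry error instead of silently degrading the
ground truth. All chains share the polar tilt angle (lattice chains with a
common azimuth, disordered chains with random azimuths), so the mean tilt
equals the spec tilt exactly. Chemical particles sit exactly at the
requested z offset from the phosphate plane; the optional protein is a
compact geometric blob of 60 heavy atoms, with no structural claim.

*Compression series.* Frames with linearly decreasing APL (default 110 →
54.5 Å²) produced by affine in-plane rescaling (z preserved). The
protein/chemical placement in these series is contact-calibration
geometry: a sparse 9-atom protein grid with spacing ≥ 2× the contact
cutoff, and a linearly growing number of chemicals docked 0.3 nm from
distinct protein atoms (the rest held far away in z), so the normalized
contact count has an exactly known closed form per frame.

What passing these round trips does *not* show: the generators have no
energetics, no thermal disorder in the condensed patch, no squeeze-out or
collapse, no realistic chemical partitioning kinetics, and the trace
isotherm has a single constant modulus rather than the biphasic behavior
of real films. Recovery of constructed ground truth validates the
*measurement machinery*, not any biological claim.

## Numerical choices and degenerate inputs

- Seeds: every stochastic generator takes an explicit integer seed
  (`numpy.random.default_rng`); identical seeds give byte-identical
  output. The CLI derives all stage seeds from one top-level seed.
- Pressure/tension conversion applies the same subtraction both ways, so a
  double conversion is an involution up to one IEEE rounding step.
- Constant-area traces segment to zero cycles with a warning, not an
  error; traces beginning mid-expansion skip the partial leading branch.
- A cycle whose surface extremes coincide has zero global compressibility;
  zero area separation with distinct extremes is a degenerate-cycle error.
- DBSCAN on fewer than min_neighbors + 1 entities returns L_c fraction 0
  with a warning.
- Decay fits require at least 3 points per free parameter; the constant
  series resolves to amplitude 0 at the data mean.
- GRO output quantizes coordinates to 0.001 nm; the builder keeps all
  constructed separations > 1.4 pm away from the 0.71 nm decision
  boundary, so packing ground truth survives a write/read cycle.

## Known limitations

- Triclinic boxes and z-periodic systems are out of scope; x/y periodicity
  is assumed for clustering and 3D periodicity for contacts.
- The packing distance matrix is dense (O(N²) memory); fine up to the few
  thousand entities of monolayer systems, not for bulk bilayer stacks.
- Instrument dialects are header-driven conventions, not vendor parsers;
  exports from other software need the generic dialect with appropriate
  headers.
- The CSD area unit (mm², drop surface area) is a convention of this
  package; instruments reporting projected area need rescaling upstream.
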