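"""Ground-truth-labeled synthetic inputs for every analysis stage.

The generators emulate the two data streams the analysis modules consume:

* surfactometry traces -- triangle-wave LBT barrier schedules
  (ten cycles, 215 -> 56 cm^2 at 150 cm^2/min by default) and sinusoidal CSD
  drop oscillations (<= 20% area reduction, 20 cycles/min, 5 Hz sampling,
  120 s), with the surface measure following an exponential isotherm of
  constant compressibility modulus kappa0, optional kink plateaus, a rigid
  expansion-branch area shift of known hysteresis, and Gaussian noise;
* gamma_min decay series with known plateau, amplitudes and half-lives;
* monolayer coordinate frames -- two leaflets of marker-bearing rod lipids
  around a thin water slab, with a hexagonally packed (L_c-like) patch of
  known size, a guaranteed-sparse disordered remainder, uniform known chain tilt,
  cholesterol, phosphate markers, interfacial chemical particles at a known
  z offset, an optional protein blob, and compression series with
  constructed protein-chemical contact counts.

Every generator attaches a :class:`GroundTruth` record carrying the
construction parameters, so recovery tests never need to re-derive them.
Lipids are deliberately coarse: every analysis consumes only the marker
atoms (C1/C10/C16 per chain, cholesterol C14, phosphate P) and heavy-atom
positions, so chemically realistic molecules would add nothing but cost.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .monolayer import MonolayerFrame
from .trace_io import GAMMA0_WATER_20C, SurfactometryTrace

__all__ = [
    "TraceSpec",
    "MonolayerSpec",
    "GroundTruth",
    "GeometryError",
    "apportion_composition",
    "waters_per_lipid",
    "generate_trace",
    "generate_decay_series",
    "build_monolayer_frame",
    "simulate_compression_series",
    "write_frame",
    "write_frames",
]

#: Static-simulation composition, DPPC:POPC:POPG:CHOL molar ratios.
STATIC_COMPOSITION = (68, 20, 10, 2)
#: Dynamic-simulation composition used for compression series.
DYNAMIC_COMPOSITION = (60, 20, 10, 10)

_SPECIES_ORDER = ("DPPC", "POPC", "POPG", "CHOL")
_CHAIN_SEG = 0.125  # nm between consecutive chain beads
_HEAD_OFFSET = 1.0  # nm from water midplane to phosphate plane
_BOX_Z = 8.0  # nm


class GeometryError(ValueError):
    """Monolayer spec geometry is infeasible (lattice vs box area)."""


@dataclass
class GroundTruth:
    """Construction parameters attached to every generated artifact."""

    true_kappa0: float | None = None
    true_hysteresis: float | None = None
    true_pi_max: float | None = None
    n_cycles: int | None = None
    device: str | None = None
    gamma0: float | None = None
    true_plateau: float | None = None
    true_amplitudes: tuple | None = None
    true_half_lives: tuple | None = None
    true_lc_fraction: float | None = None
    true_tilt_deg: float | None = None
    true_apl: float | None = None
    species_counts: dict | None = None
    n_entities_per_leaflet: int | None = None
    n_chemical: int | None = None
    chemical_z_offset: float | None = None
    apl_sequence: tuple | None = None
    true_contacts: tuple | None = None
    contact_pair: tuple | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            k: v for k, v in dataclasses.asdict(self).items() if v not in (None, {})
        }
        text = json.dumps(payload, indent=2, default=list)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def apportion_composition(total: int, ratios) -> tuple[int, ...]:
    """Largest-remainder apportionment of ``total`` molecules among species.

    Counts sum exactly to ``total``; ties in the fractional remainders are
    broken by species order (earlier species first), so the result is
    deterministic.
    """
    ratios = np.asarray(ratios, dtype=float)
    if total < 1:
        raise ValueError(f"total must be >= 1, got {total}")
    if np.any(ratios < 0) or ratios.sum() == 0:
        raise ValueError("ratios must be non-negative and not all zero")
    quota = total * ratios / ratios.sum()
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    # Stable sort keeps species order on remainder ties.
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return tuple(int(c) for c in base)


def waters_per_lipid(n_waters: int, n_lipids_total: int) -> tuple[float, int]:
    """Hydration level of a two-leaflet system: exact ratio and rounded value."""
    if n_lipids_total <= 0:
        raise ZeroDivisionError("n_lipids_total must be positive")
    ratio = n_waters / n_lipids_total
    return ratio, int(round(ratio))


# ---------------------------------------------------------------------------
# Surfactometry traces
# ---------------------------------------------------------------------------


@dataclass
class TraceSpec:
    """Parameters of a synthetic surfactometry run.

    LBT defaults follow the trough protocol (ten cycles between 215 and
    56 cm^2 at 150 cm^2/min); CSD defaults follow the drop protocol (20%
    area reduction, 20 cycles per minute, 120 s at 5 frames per second).
    ``kappa0`` sets the isotherm stiffness, ``pi_max_target`` the plateau
    cap, ``hysteresis_shift`` the rigid inward shift of the expansion branch
    in area units, and ``kink_positions`` optional plateau features at the
    given surface pressures.
    """

    device: str = "LBT"
    n_cycles: int | None = None
    area_range: tuple[float, float] | None = None  # (min, max), cm^2 or mm^2
    rate: float | None = None  # cm^2/min (LBT) or cycles/min (CSD)
    kappa0: float | None = None  # 100 (LBT) / 300 (CSD) when unset
    pi_max_target: float = 70.0
    hysteresis_shift: float = 0.0
    kink_positions: tuple[float, ...] = ()
    kink_width: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0
    sampling_hz: float | None = None
    duration_s: float | None = None  # CSD only
    csd_amplitude: float = 0.2  # fractional area reduction, <= 0.2 by protocol
    gamma0: float = GAMMA0_WATER_20C

    def __post_init__(self) -> None:
        if self.device not in ("LBT", "CSD"):
            raise ValueError(f"unknown device {self.device!r}")
        if self.device == "LBT":
            self.kappa0 = 100.0 if self.kappa0 is None else self.kappa0
            self.n_cycles = 10 if self.n_cycles is None else self.n_cycles
            self.area_range = self.area_range or (56.0, 215.0)
            self.rate = 150.0 if self.rate is None else self.rate
            self.sampling_hz = 2.0 if self.sampling_hz is None else self.sampling_hz
        else:
            # A drop cycle spans only ~20% of the area but sweeps gamma from
            # ~72 down to single digits, so the effective film is much
            # stiffer than on the trough.
            self.kappa0 = 300.0 if self.kappa0 is None else self.kappa0
            self.rate = 20.0 if self.rate is None else self.rate
            self.sampling_hz = 5.0 if self.sampling_hz is None else self.sampling_hz
            self.duration_s = 120.0 if self.duration_s is None else self.duration_s
            self.area_range = self.area_range or (
                30.0 * (1.0 - self.csd_amplitude),
                30.0,
            )
            if self.csd_amplitude > 0.2 + 1e-12:
                raise ValueError("CSD area reduction exceeds the 20% protocol bound")
        lo, hi = self.area_range
        if not (0 < lo < hi):
            raise ValueError(f"area_range must be positive and ordered, got {self.area_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pi_max_target > self.gamma0:
            raise ValueError(
                f"pi_max_target {self.pi_max_target} exceeds gamma0 {self.gamma0}"
            )


def _apply_kinks(pi: np.ndarray, kinks, width: float) -> np.ndarray:
    """Insert flat plateaus of the given width at each kink pressure."""
    out = pi.copy()
    for k in sorted(kinks):
        above = out > k
        out = np.where(above, np.maximum(k, out - width), out)
    return out


def generate_trace(spec: TraceSpec) -> tuple[SurfactometryTrace, GroundTruth]:
    """Generate a surfactometry trace with known isotherm and hysteresis.

    The area follows the device schedule (constant-rate triangle for LBT,
    sinusoid for CSD).  The surface measure follows the constant-modulus
    isotherm ``Pi(A) = kappa0 * ln(A_max / A)`` capped at ``pi_max_target``,
    with optional kink plateaus.  The expansion branch is recorded at areas
    rigidly shifted inward by ``hysteresis_shift``, so the half-maximum area
    gap equals the shift exactly in the noiseless case.
    """
    rng = np.random.default_rng(spec.seed)
    a_min, a_max = spec.area_range
    dt = 1.0 / spec.sampling_hz

    if spec.device == "LBT":
        t_half = (a_max - a_min) / spec.rate * 60.0
        # Snap the sampling interval so barrier reversals land on samples:
        # expansion samples are then exact mirror images of compression
        # samples and interpolated branch crossings cancel rigid shifts.
        n_half = max(2, int(round(t_half * spec.sampling_hz)))
        dt = t_half / n_half
        t = np.arange(2 * n_half * spec.n_cycles + 1) * dt
        phase = (t / t_half) % 2.0
        frac = np.where(phase < 1.0, phase, 2.0 - phase)
        schedule = a_max - frac * (a_max - a_min)
        expanding = phase >= 1.0
        n_cycles = spec.n_cycles
    else:
        t = np.arange(0.0, spec.duration_s, dt)
        f = spec.rate / 60.0
        phase = 2.0 * math.pi * f * t
        schedule = a_max - 0.5 * (a_max - a_min) * (1.0 - np.cos(phase))
        expanding = np.sin(phase) < 0.0
        n_cycles = int(f * spec.duration_s)

    # The surface measure follows the isotherm on the unshifted schedule; the
    # recorded expansion area is shifted inward.  The expansion branch is then
    # an exact rigid copy of the compression branch displaced in area, so the
    # half-maximum crossing recovers the shift to float precision.
    area = np.where(expanding, schedule - spec.hysteresis_shift, schedule)
    if np.any(area <= 0):
        raise ValueError("hysteresis_shift drives the recorded area non-positive")

    pi = spec.kappa0 * np.log(a_max / schedule)
    pi = np.clip(pi, 0.0, None)
    if spec.kink_positions:
        pi = _apply_kinks(pi, spec.kink_positions, spec.kink_width)
    pi = np.minimum(pi, spec.pi_max_target)
    if spec.noise_sd > 0:
        pi = pi + rng.normal(0.0, spec.noise_sd, size=pi.size)

    if spec.device == "CSD":
        surface = spec.gamma0 - pi
        kind = "tension"
    else:
        surface = pi
        kind = "pressure"

    trace = SurfactometryTrace(
        time=t,
        area=area,
        surface_value=surface,
        measure_kind=kind,
        device=spec.device,
        temperature_c=25.0,
        metadata={"generator": "monosurf.synthetic", "seed": str(spec.seed)},
    )
    pi_reachable = min(
        spec.pi_max_target,
        spec.kappa0 * math.log(a_max / a_min)
        - spec.kink_width * len(spec.kink_positions),
    )
    truth = GroundTruth(
        true_kappa0=spec.kappa0,
        true_hysteresis=spec.hysteresis_shift,
        true_pi_max=pi_reachable,
        n_cycles=n_cycles,
        device=spec.device,
        gamma0=spec.gamma0,
    )
    return trace, truth


def generate_decay_series(
    plateau: float,
    amplitudes,
    half_lives,
    duration: float = 120.0,
    rate: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """gamma_min(t) = plateau + sum_i a_i * 2**(-t/thalf_i) + noise."""
    amplitudes = tuple(float(a) for a in np.atleast_1d(amplitudes))
    half_lives = tuple(float(h) for h in np.atleast_1d(half_lives))
    if any(a < 0 for a in amplitudes):
        raise ValueError("amplitudes must be non-negative")
    if any(h <= 0 for h in half_lives) or duration <= 0:
        raise ValueError("half_lives and duration must be positive")
    t = np.arange(0.0, duration, 1.0 / rate)
    y = np.full_like(t, plateau)
    for a, h in zip(amplitudes, half_lives):
        y = y + a * np.exp2(-t / h)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    truth = GroundTruth(
        true_plateau=plateau, true_amplitudes=amplitudes, true_half_lives=half_lives
    )
    return t, y, truth


# ---------------------------------------------------------------------------
# Monolayer frames
# ---------------------------------------------------------------------------


@dataclass
class MonolayerSpec:
    """Parameters of a synthetic two-leaflet monolayer frame.

    Defaults mirror the protein-free static systems: 149 lipids per leaflet
    at DPPC:POPC:POPG:CHOL = 68:20:10:2, APL in the physiological band.
    ``lc_patch_fraction`` of the chain/cholesterol entities sit on a
    hexagonal lattice (default spacing 0.48 nm, typical of condensed-phase
    chain packing) with uniform tilt; the remainder is placed with a
    guaranteed minimum spacing above the 0.71 nm clustering cutoff so its
    L_c membership is unambiguously negative.  Disordered chains keep the
    same polar tilt with randomized azimuths, so the mean tilt is exactly
    ``tilt_deg`` by construction.  Dense, fully condensed states therefore
    want a small APL (around 55 A^2) and fully disordered states a large one
    (above about 105 A^2); infeasible combinations raise
    :class:`GeometryError` rather than silently breaking the ground truth.
    """

    n_lipids_per_leaflet: int = 149
    composition_ratio: tuple[float, float, float, float] = STATIC_COMPOSITION
    apl: float = 100.0  # Angstrom^2
    lc_patch_fraction: float = 0.0
    lattice_spacing: float = 0.48  # nm
    tilt_deg: float = 0.0
    n_chemical: int = 0
    chemical_z_offset: float = 0.8  # nm above the phosphate plane
    include_protein: bool = False
    n_waters: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (40.0 <= self.apl <= 120.0):
            raise ValueError(f"apl must lie in [40, 120] A^2, got {self.apl}")
        if not (0.0 <= self.lc_patch_fraction <= 1.0):
            raise ValueError("lc_patch_fraction must lie in [0, 1]")
        if not (0.0 <= self.tilt_deg <= 90.0):
            raise ValueError("tilt_deg must lie in [0, 90]")
        ratios = np.asarray(self.composition_ratio, dtype=float)
        if ratios.min() < 0 or ratios.sum() == 0:
            raise ValueError("composition ratios must be non-negative, not all zero")


def _hex_patch_sites(box_l: float, spacing: float, k: int) -> np.ndarray:
    """k lattice sites: complete x-periodic hexagonal rows plus paired extras.

    Rows span the full box width with the spacing nudged to the nearest
    commensurate value, so every row wraps periodically in x.  Complete rows
    guarantee that each lattice site is either a DBSCAN core point or within
    one lattice spacing of one, making the constructed L_c membership exact.
    The ``k mod n_cols`` leftover entities are placed as close satellites of
    interior sites.
    """
    if k == 0:
        return np.empty((0, 2))
    n_cols = max(3, int(round(box_l / spacing)))
    sx = box_l / n_cols
    if abs(sx - spacing) > 0.25 * spacing:
        raise GeometryError(
            f"lattice spacing {spacing} nm incompatible with box width {box_l:.2f} nm"
        )
    dy = spacing * math.sqrt(3.0) / 2.0
    n_rows = k // n_cols
    r = k % n_cols
    if n_rows < 3:
        raise GeometryError(
            f"patch of {k} entities spans fewer than 3 rows of {n_cols}; "
            "increase lc_patch_fraction or the system size"
        )
    if (n_rows - 1) * dy > box_l - dy:
        raise GeometryError("lattice patch does not fit the box (overfull lattice)")
    rows = np.repeat(np.arange(n_rows), n_cols)
    cols = np.tile(np.arange(n_cols), n_rows)
    x = (cols + 0.5 * (rows % 2)) * sx
    y = rows * dy
    sites = np.column_stack([x % box_l, y])
    if r:
        # Satellites next to interior sites inherit >= 6 in-cutoff neighbors.
        hosts = sites[n_cols : n_cols + r]
        sites = np.vstack([sites, hosts + np.array([0.08, 0.04])])
    return sites


def _sparse_sites(
    rng: np.random.Generator,
    n: int,
    box_l: float,
    y_lo: float,
    y_hi: float,
    wrap_y: bool,
) -> np.ndarray:
    """Disordered-entity sites with a guaranteed minimum separation > eps.

    A jittered sparse hexagonal lattice: spacing is chosen from the available
    area (never below 0.74 nm), rows span the full box width commensurately,
    and a +/-0.008 nm uniform jitter is added, so the minimum periodic
    separation stays above 0.717 nm -- strictly outside the 0.71 nm
    clustering cutoff, making non-L_c membership unambiguous.  At
    physiological areas per lipid this is the densest arrangement that keeps
    that guarantee, which is why plain dart-throwing is not used.
    """
    if n == 0:
        return np.empty((0, 2))
    jitter = 0.008
    d_min = 0.74
    height = (box_l if wrap_y else y_hi - y_lo)
    area = box_l * height
    if area <= 0:
        raise GeometryError("no room left for disordered entities")
    d = math.sqrt(2.0 * area / (math.sqrt(3.0) * n))
    d = min(max(d, d_min), 1.2)
    while True:
        n_cols = max(1, int(box_l // d))
        sx = box_l / n_cols
        dy = d * math.sqrt(3.0) / 2.0
        if wrap_y:
            n_rows = max(1, int(box_l // dy))
            dy = box_l / n_rows
            ys = y_lo + np.arange(n_rows) * dy
        else:
            ys = y_lo + np.arange(max(1, int(height // dy) + 1)) * dy
            ys = ys[ys <= y_hi + 1e-12]
        if n_cols * ys.size >= n:
            break
        if d <= d_min:
            raise GeometryError(
                "disordered region too dense to keep entities farther apart "
                "than the clustering cutoff; increase apl or lc_patch_fraction"
            )
        d = max(d * 0.97, d_min)
    rows = np.repeat(np.arange(ys.size), n_cols)[:n]
    cols = np.tile(np.arange(n_cols), ys.size)[:n]
    x = (cols + 0.5 * (rows % 2)) * sx
    sites = np.column_stack([x, ys[rows]])
    sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)
    sites[:, 0] %= box_l
    return sites


def _species_sequence(counts: dict[str, int]) -> list[str]:
    seq: list[str] = []
    for sp in _SPECIES_ORDER:
        seq.extend([sp] * counts[sp])
    return seq


class _FrameBuilder:
    """Accumulates atoms molecule by molecule."""

    def __init__(self) -> None:
        self.coords: list[np.ndarray] = []
        self.names: list[str] = []
        self.species: list[str] = []
        self.resnames: list[str] = []
        self.mol_ids: list[int] = []
        self._next_mol = 0

    def add_molecule(self, species: str, resname: str, atoms: list[tuple[str, np.ndarray]]) -> int:
        mid = self._next_mol
        self._next_mol += 1
        for name, xyz in atoms:
            self.coords.append(np.asarray(xyz, dtype=float))
            self.names.append(name)
            self.species.append(species)
            self.resnames.append(resname)
            self.mol_ids.append(mid)
        return mid

    def build(self, box: np.ndarray) -> MonolayerFrame:
        return MonolayerFrame(
            coords=np.vstack(self.coords),
            names=np.array(self.names),
            species=np.array(self.species),
            resnames=np.array(self.resnames),
            mol_ids=np.array(self.mol_ids, dtype=int),
            box=np.asarray(box, dtype=float),
        )


def _chain_atoms(
    suffix: str, site_xy: np.ndarray, z_c1: float, direction: np.ndarray
) -> list[tuple[str, np.ndarray]]:
    """Marker beads C1/C10/C16 of one acyl chain; C10 sits at the site xy."""
    c1_xy = site_xy - 9.0 * _CHAIN_SEG * direction[:2]
    c1 = np.array([c1_xy[0], c1_xy[1], z_c1])
    c10 = c1 + 9.0 * _CHAIN_SEG * direction
    c16 = c1 + 15.0 * _CHAIN_SEG * direction
    return [(f"C1{suffix}", c1), (f"C10{suffix}", c10), (f"C16{suffix}", c16)]


def _build_leaflet(
    builder: _FrameBuilder,
    spec: MonolayerSpec,
    counts: dict[str, int],
    box_l: float,
    z_mid: float,
    sign: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Place one leaflet; returns (n_entities, n_lc_entities)."""
    species_seq = _species_sequence(counts)
    n_entities = sum(2 if sp != "CHOL" else 1 for sp in species_seq)
    k_target = int(round(spec.lc_patch_fraction * n_entities))

    # Whole molecules go to the patch; cholesterol (1 entity) fixes parity.
    in_patch = {}
    remaining = k_target
    for i, sp in enumerate(species_seq):
        need = 1 if sp == "CHOL" else 2
        if remaining >= need:
            in_patch[i] = True
            remaining -= need
        else:
            in_patch[i] = False
    if remaining == 1:
        for i, sp in enumerate(species_seq):
            if sp == "CHOL" and not in_patch[i]:
                in_patch[i] = True
                remaining = 0
                break
    k_actual = k_target - remaining

    sites = _hex_patch_sites(box_l, spec.lattice_spacing, k_actual)
    patch_top = sites[:, 1].max() if k_actual else 0.0
    n_sparse = n_entities - k_actual
    if k_actual:
        sparse = _sparse_sites(
            rng, n_sparse, box_l, patch_top + 0.74, box_l - 0.74, wrap_y=False
        )
    else:
        sparse = _sparse_sites(rng, n_sparse, box_l, 0.0, box_l, wrap_y=True)

    z_head = z_mid + sign * _HEAD_OFFSET
    z_c1 = z_head + sign * 0.15
    tilt = math.radians(spec.tilt_deg)
    next_site = 0
    next_sparse = 0
    n_lc = 0
    for i, sp in enumerate(species_seq):
        n_ent = 1 if sp == "CHOL" else 2
        if in_patch[i]:
            xy = sites[next_site : next_site + n_ent]
            next_site += n_ent
            azimuths = np.zeros(n_ent)
            n_lc += n_ent
        else:
            xy = sparse[next_sparse : next_sparse + n_ent]
            next_sparse += n_ent
            azimuths = rng.uniform(0.0, 2.0 * math.pi, size=n_ent)
        if sp == "CHOL":
            atoms = [
                ("O3", np.array([xy[0, 0], xy[0, 1], z_head])),
                ("C14", np.array([xy[0, 0], xy[0, 1], z_head + sign * 0.6])),
            ]
            builder.add_molecule("CHOL", "CHOL", atoms)
        else:
            atoms = [("P", np.array([xy[0, 0], xy[0, 1], z_head]))]
            for j, suffix in enumerate(("A", "B")):
                phi = azimuths[j]
                direction = np.array(
                    [
                        math.sin(tilt) * math.cos(phi),
                        math.sin(tilt) * math.sin(phi),
                        sign * math.cos(tilt),
                    ]
                )
                atoms.extend(_chain_atoms(suffix, xy[j], z_c1, direction))
            builder.add_molecule(sp, sp, atoms)
    return n_entities, n_lc


def build_monolayer_frame(spec: MonolayerSpec) -> tuple[MonolayerFrame, GroundTruth]:
    """Build a two-leaflet monolayer frame with exact ground truth.

    The box is sized so that the area per lipid matches ``spec.apl``
    exactly.  Chain C10 markers sit on the lattice/disordered sites, so the
    packing analysis sees exactly the constructed geometry; the C1->C16
    vectors make exactly ``tilt_deg`` with the normal; chemicals sit exactly
    ``chemical_z_offset`` above the phosphate plane of the upper leaflet.
    """
    rng = np.random.default_rng(spec.seed)
    c_dppc, c_popc, c_popg, c_chol = apportion_composition(
        spec.n_lipids_per_leaflet, spec.composition_ratio
    )
    counts = {"DPPC": c_dppc, "POPC": c_popc, "POPG": c_popg, "CHOL": c_chol}
    box_l = math.sqrt(spec.n_lipids_per_leaflet * spec.apl) / 10.0  # nm
    z_mid = _BOX_Z / 2.0

    builder = _FrameBuilder()
    n_up, lc_up = _build_leaflet(builder, spec, counts, box_l, z_mid, +1.0, rng)
    n_lo, lc_lo = _build_leaflet(builder, spec, counts, box_l, z_mid, -1.0, rng)

    if spec.include_protein:
        # A compact geometric blob of heavy atoms in the upper leaflet.
        center = np.array([box_l / 2.0, box_l / 2.0, z_mid + 1.4])
        n_blob = 60
        pts = rng.normal(0.0, 0.35, size=(n_blob, 3)) + center
        builder.add_molecule(
            "PROTEIN", "PROT", [(f"B{i+1}", p) for i, p in enumerate(pts)]
        )

    if spec.n_chemical:
        z_chem = z_mid + _HEAD_OFFSET + spec.chemical_z_offset
        xy = rng.uniform(0.0, box_l, size=(spec.n_chemical, 2))
        for i in range(spec.n_chemical):
            builder.add_molecule(
                "CHEMICAL", "CHEM", [("CX", np.array([xy[i, 0], xy[i, 1], z_chem]))]
            )

    n_side = int(math.ceil(math.sqrt(spec.n_waters)))
    w_xy = (np.stack(np.meshgrid(np.arange(n_side), np.arange(n_side)), -1).reshape(-1, 2) + 0.5) * (
        box_l / n_side
    )
    for i in range(spec.n_waters):
        builder.add_molecule(
            "WATER", "SOL", [("OW", np.array([w_xy[i, 0], w_xy[i, 1], z_mid]))]
        )

    frame = builder.build(np.array([box_l, box_l, _BOX_Z]))
    truth = GroundTruth(
        true_lc_fraction=lc_up / n_up,
        true_tilt_deg=spec.tilt_deg,
        true_apl=spec.apl,
        species_counts=counts,
        n_entities_per_leaflet=n_up,
        n_chemical=spec.n_chemical,
        chemical_z_offset=spec.chemical_z_offset if spec.n_chemical else None,
        extras={"lc_fraction_lower": lc_lo / n_lo, "box_nm": float(box_l)},
    )
    return frame, truth


def simulate_compression_series(
    spec: MonolayerSpec | None = None,
    apl_start: float = 110.0,
    apl_end: float = 54.5,
    n_frames: int = 11,
    n_contact_max: int | None = None,
) -> tuple[list[MonolayerFrame], GroundTruth]:
    """Monolayer compression series with constructed contact ground truth.

    Frames carry linearly decreasing APL (the default 110 -> 54.5 Angstrom^2
    matches a physiologically relevant compression span); in-plane
    coordinates are affinely rescaled between frames while z is preserved.
    A sparse 9-atom protein grid and ``n_chemical`` chemical particles are
    placed per frame so that the number of protein-chemical contacts is an
    exactly known, linearly increasing function of compression: contact
    calibration geometry, not an attempt at realistic insertion.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not (apl_start > apl_end > 0):
        raise ValueError("need apl_start > apl_end > 0")
    if spec is None:
        spec = MonolayerSpec(
            n_lipids_per_leaflet=100,
            composition_ratio=DYNAMIC_COMPOSITION,
            apl=apl_start,
            n_chemical=20,
            seed=0,
        )
    base_spec = replace(spec, apl=apl_start, include_protein=False, n_chemical=0)
    base, _ = build_monolayer_frame(base_spec)
    n_chem = spec.n_chemical or 20
    n_prot = 9
    if n_contact_max is None:
        n_contact_max = min(n_prot, n_chem)
    if n_contact_max > min(n_prot, n_chem):
        raise ValueError("n_contact_max exceeds the available partner count")

    apls = np.linspace(apl_start, apl_end, n_frames)
    z_mid = _BOX_Z / 2.0
    rng = np.random.default_rng(spec.seed + 1)
    frames: list[MonolayerFrame] = []
    contacts: list[float] = []
    for i, apl in enumerate(apls):
        s = math.sqrt(apl / apl_start)
        box_l = base.box[0] * s
        builder = _FrameBuilder()
        # Affine in-plane rescale of the lipid/water system; z preserved.
        mids = np.unique(base.mol_ids)
        for mid in mids:
            idx = np.nonzero(base.mol_ids == mid)[0]
            xyz = base.coords[idx].copy()
            xyz[:, :2] *= s
            builder.add_molecule(
                str(base.species[idx[0]]),
                str(base.resnames[idx[0]]),
                list(zip(base.names[idx], xyz)),
            )
        # Sparse protein grid: spacing >= 2x the contact cutoff, so each
        # docked chemical touches exactly one protein atom.
        prot_xy = (np.stack(np.meshgrid(np.arange(3), np.arange(3)), -1).reshape(-1, 2) + 0.5) * (
            box_l / 3.0
        )
        builder.add_molecule(
            "PROTEIN",
            "PROT",
            [(f"B{j+1}", np.array([p[0], p[1], z_mid + 1.3])) for j, p in enumerate(prot_xy)],
        )
        progress = (apl_start - apl) / (apl_start - apl_end)
        c_i = int(round(n_contact_max * progress))
        for j in range(n_chem):
            if j < c_i:
                pos = np.array(
                    [(prot_xy[j, 0] + 0.3) % box_l, prot_xy[j, 1], z_mid + 1.3]
                )
            else:
                pos = np.array(
                    [rng.uniform(0, box_l), rng.uniform(0, box_l), z_mid + 3.5]
                )
            builder.add_molecule("CHEMICAL", "CHEM", [("CX", pos)])
        frame = builder.build(np.array([box_l, box_l, _BOX_Z]))
        frame.frame_time = float(i)
        frames.append(frame)
        contacts.append(c_i / (n_prot * n_chem))

    truth = GroundTruth(
        apl_sequence=tuple(float(a) for a in apls),
        true_contacts=tuple(contacts),
        contact_pair=("PROTEIN", "CHEMICAL"),
        species_counts={"n_protein_atoms": n_prot, "n_chemical": n_chem},
    )
    return frames, truth


# ---------------------------------------------------------------------------
# Coordinate writers
# ---------------------------------------------------------------------------


def _to_universe(frame: MonolayerFrame):
    import MDAnalysis as mda

    mids, inv = np.unique(frame.mol_ids, return_inverse=True)
    u = mda.Universe.empty(
        frame.n_atoms, n_residues=mids.size, atom_resindex=inv, trajectory=True
    )
    u.add_TopologyAttr("names", list(frame.names))
    res_names = [str(frame.resnames[np.nonzero(frame.mol_ids == m)[0][0]]) for m in mids]
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", list(range(1, mids.size + 1)))
    u.atoms.positions = frame.coords * 10.0  # nm -> A
    u.dimensions = np.array(
        [frame.box[0] * 10.0, frame.box[1] * 10.0, frame.box[2] * 10.0, 90.0, 90.0, 90.0]
    )
    return u


def write_frame(frame: MonolayerFrame, path) -> str:
    """Write a single frame to GRO or PDB (by file extension)."""
    u = _to_universe(frame)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return str(path)


def write_frames(frames, path) -> str:
    """Write a multi-frame series to a multi-model PDB file.

    A CRYST1 record is emitted before every MODEL (as GROMACS does), so
    series with frame-dependent boxes -- compression runs -- survive the
    round trip.
    """
    import os
    import tempfile

    path = str(path)
    if not path.lower().endswith(".pdb"):
        raise ValueError("multi-frame output requires a .pdb path")
    fd, tmp = tempfile.mkstemp(suffix=".pdb")
    os.close(fd)
    try:
        with open(path, "w", encoding="utf-8") as out:
            for i, frame in enumerate(frames, start=1):
                write_frame(frame, tmp)
                with open(tmp, "r", encoding="utf-8") as fh:
                    lines = fh.read().splitlines()
                cryst = next(ln for ln in lines if ln.startswith("CRYST1"))
                atoms = [
                    ln for ln in lines if ln.startswith(("ATOM", "HETATM", "TER"))
                ]
                out.write(cryst + "\n")
                out.write(f"MODEL     {i:>4d}\n")
                out.write("\n".join(atoms) + "\n")
                out.write("ENDMDL\n")
            out.write("END\n")
    finally:
        os.unlink(tmp)
    return path
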