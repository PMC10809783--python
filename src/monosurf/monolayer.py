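"""Structural analysis of lipid-monolayer coordinate frames.

A monolayer system here is two leaflets of lipids (DPPC/POPC/POPG-like
phospholipids plus cholesterol) at the two water-vacuum interfaces of a thin
water slab, optionally with a protein inclusion and interfacial "chemical"
particles.  The analyses mirror standard monolayer trajectory work:

* leaflet assignment from headgroup position relative to the water midplane;
* area per lipid (APL) from the in-plane box area;
* liquid-condensed (L_c) packing fraction: DBSCAN clustering of mid-chain
  carbon markers (10th acyl carbon of each phospholipid chain, the C14 atom
  of cholesterol) in the membrane plane with periodic minimum-image
  distances, cutoff 0.71 nm and 6 required neighbors -- any chain or
  cholesterol belonging to a cluster counts as L_c;
* acyl-chain tilt: angle between the C1->C16 chain vector and the monolayer
  normal (z), folded to [0, 90] degrees;
* number-density profiles along z, centered at the phosphate plane and
  normalized to a maximum of 1 per species;
* heavy-atom contact counts between two groups within a 0.6 nm cutoff,
  normalized by the number of possible partner pairs, including
  contacts-versus-area series and two-replica aggregation.

Coordinates are handled in nm internally; APL is reported in Angstrom^2.
Boxes must be orthorhombic; x and y are treated as periodic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

__all__ = [
    "MonolayerFrame",
    "PackingResult",
    "TiltResult",
    "DensityProfile",
    "ContactResult",
    "ContactSeries",
    "SpeciesMap",
    "MappingError",
    "BoxError",
    "MidplaneError",
    "MarkerError",
    "SelectionError",
    "AlignmentError",
    "load_frames",
    "assign_leaflets",
    "area_per_lipid",
    "packing_fraction",
    "packing_fraction_series",
    "chain_tilt",
    "density_profile",
    "contact_count",
    "contacts_vs_area",
    "replica_aggregate",
]

SPECIES_VOCABULARY = frozenset(
    {"DPPC", "POPC", "POPG", "CHOL", "PROTEIN", "CHEMICAL", "WATER", "ION"}
)
PHOSPHOLIPID_SPECIES = frozenset({"DPPC", "POPC", "POPG"})
LIPID_SPECIES = PHOSPHOLIPID_SPECIES | {"CHOL"}

#: Residue-name -> species defaults covering CHARMM-style and builder names.
DEFAULT_RESIDUE_MAP: dict[str, str] = {
    "DPPC": "DPPC",
    "POPC": "POPC",
    "POPG": "POPG",
    "CHL1": "CHOL",
    "CHOL": "CHOL",
    "CHL": "CHOL",
    "PROT": "PROTEIN",
    "CHEM": "CHEMICAL",
    "SOL": "WATER",
    "TIP3": "WATER",
    "OPC": "WATER",
    "HOH": "WATER",
    "WAT": "WATER",
    "SOD": "ION",
    "CLA": "ION",
    "POT": "ION",
    "NA": "ION",
    "CL": "ION",
}

#: Atom-name triples (C1, C10, C16) of each acyl chain; CHARMM sn-1 chains
#: are C3x, sn-2 chains C2x; the synthetic builder uses A/B suffixes.
DEFAULT_CHAIN_MARKERS: tuple[dict[str, str], ...] = (
    {"c1": "C1A", "c10": "C10A", "c16": "C16A"},
    {"c1": "C1B", "c10": "C10B", "c16": "C16B"},
    {"c1": "C21", "c10": "C210", "c16": "C216"},
    {"c1": "C31", "c10": "C310", "c16": "C316"},
)
DEFAULT_CHOL_MARKERS: tuple[str, ...] = ("C14",)
DEFAULT_PHOSPHATE_NAMES: tuple[str, ...] = ("P", "P8")


class MappingError(ValueError):
    """Residue names could not be resolved to the species vocabulary."""


class BoxError(ValueError):
    """Missing or non-orthorhombic box dimensions."""


class MidplaneError(ValueError):
    """No water and no explicit midplane to reference leaflets against."""


class MarkerError(ValueError):
    """Required marker atoms are missing for a species."""


class SelectionError(ValueError):
    """Invalid atom group selection (empty or overlapping groups)."""


class AlignmentError(ValueError):
    """Replica contact series do not share a grid or group pair."""


@dataclass
class SpeciesMap:
    """Resolution of residue names to species and atom names to marker roles."""

    residues: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RESIDUE_MAP))
    chain_markers: tuple[dict[str, str], ...] = DEFAULT_CHAIN_MARKERS
    chol_markers: tuple[str, ...] = DEFAULT_CHOL_MARKERS
    phosphate_names: tuple[str, ...] = DEFAULT_PHOSPHATE_NAMES

    @classmethod
    def from_yaml(cls, path) -> "SpeciesMap":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        base = cls()
        residues = dict(base.residues)
        residues.update({str(k).upper(): str(v).upper() for k, v in (cfg.get("residues") or {}).items()})
        chains = cfg.get("chain_markers")
        chain_markers = (
            tuple({k: str(v) for k, v in c.items()} for c in chains)
            if chains
            else base.chain_markers
        )
        return cls(
            residues=residues,
            chain_markers=chain_markers,
            chol_markers=tuple(cfg.get("chol_markers", base.chol_markers)),
            phosphate_names=tuple(cfg.get("phosphate_names", base.phosphate_names)),
        )


@dataclass
class MonolayerFrame:
    """Labeled atom coordinates of a two-leaflet monolayer system.

    ``coords`` are nm; ``box`` is the orthorhombic (x, y, z) box in nm with
    x and y periodic.  ``mol_ids`` group atoms into molecules and ``species``
    holds one vocabulary label per atom.
    """

    coords: np.ndarray  # (N, 3) nm
    names: np.ndarray  # (N,) atom names
    species: np.ndarray  # (N,) vocabulary labels
    resnames: np.ndarray  # (N,) original residue names
    mol_ids: np.ndarray  # (N,) int molecule index
    box: np.ndarray  # (3,) nm
    frame_time: float | None = None  # ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise BoxError(f"box must be 3 positive lengths, got {self.box}")
        unknown = set(np.unique(self.species)) - SPECIES_VOCABULARY
        if unknown:
            raise MappingError(f"species outside vocabulary: {sorted(unknown)}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def atom_indices(self, species=None, names=None, mol_ids=None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if species is not None:
            wanted = {species} if isinstance(species, str) else set(species)
            mask &= np.isin(self.species, sorted(wanted))
        if names is not None:
            wanted_n = {names} if isinstance(names, str) else set(names)
            mask &= np.isin(self.names, sorted(wanted_n))
        if mol_ids is not None:
            mask &= np.isin(self.mol_ids, np.asarray(mol_ids))
        return np.nonzero(mask)[0]

    def molecules(self, species=None) -> dict[int, np.ndarray]:
        """Mapping molecule id -> atom indices, optionally filtered by species.

        Species labels are per-molecule (residue) in all supported inputs, so
        grouping the filtered atoms by molecule id returns whole molecules.
        """
        idx = self.atom_indices(species=species)
        order = np.argsort(self.mol_ids[idx], kind="stable")
        sorted_idx = idx[order]
        ids = self.mol_ids[sorted_idx]
        if ids.size == 0:
            return {}
        splits = np.nonzero(np.diff(ids))[0] + 1
        groups = np.split(sorted_idx, splits)
        return {int(self.mol_ids[g[0]]): g for g in groups}

    def heavy_mask(self) -> np.ndarray:
        """Non-hydrogen atoms, judged from the atom name (leading digits ignored)."""
        stripped = np.char.lstrip(self.names.astype(str), "0123456789")
        return ~np.char.startswith(stripped, "H")


def _pdb_cryst_boxes(path) -> list[np.ndarray]:
    """CRYST1 records of a PDB file, in order (GROMACS writes one per model)."""
    boxes: list[np.ndarray] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                boxes.append(
                    np.array(
                        [
                            float(line[6:15]),
                            float(line[15:24]),
                            float(line[24:33]),
                            float(line[33:40]),
                            float(line[40:47]),
                            float(line[47:54]),
                        ]
                    )
                )
    return boxes


def load_frames(paths, species_map: SpeciesMap | None = None) -> list[MonolayerFrame]:
    """Load monolayer frames from PDB/GRO coordinate or trajectory files.

    Multi-model PDB and multi-frame trajectories yield one
    :class:`MonolayerFrame` per frame, in file order.  Positions are
    converted from Angstrom to nm.  Residue names are resolved through the
    species map; unresolvable names raise :class:`MappingError` listing them.
    """
    import MDAnalysis as mda

    species_map = species_map or SpeciesMap()
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    frames: list[MonolayerFrame] = []
    for path in paths:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        resnames = np.array([r.strip().upper() for r in u.atoms.resnames])
        unknown = sorted(set(resnames) - set(species_map.residues))
        if unknown:
            raise MappingError(
                f"{path}: residue names without a species mapping: {unknown}"
            )
        species = np.array([species_map.residues[r] for r in resnames])
        names = np.array([n.strip() for n in u.atoms.names])
        mol_ids = u.atoms.resindices.astype(int)
        cryst: list[np.ndarray] | None = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in u.trajectory:
                dims = ts.dimensions
                if dims is None and str(path).lower().endswith(".pdb"):
                    # Multi-model PDB readers can drop CRYST1; recover the
                    # per-model (GROMACS-style) or global record directly.
                    if cryst is None:
                        cryst = _pdb_cryst_boxes(path)
                    if len(cryst) > ts.frame:
                        dims = cryst[ts.frame]
                    elif len(cryst) == 1:
                        dims = cryst[0]
                if dims is None or not np.all(np.asarray(dims)[:3] > 0):
                    raise BoxError(f"{path}: frame {ts.frame} has no box dimensions")
                dims = np.asarray(dims, dtype=float)
                if not np.allclose(dims[3:6], 90.0, atol=0.1):
                    raise BoxError(f"{path}: only orthorhombic boxes are supported")
                frames.append(
                    MonolayerFrame(
                        coords=ts.positions.astype(float) / 10.0,
                        names=names.copy(),
                        species=species.copy(),
                        resnames=resnames.copy(),
                        mol_ids=mol_ids.copy(),
                        box=dims[:3] / 10.0,
                        frame_time=float(ts.time) / 1000.0 if ts.time is not None else None,
                    )
                )
    return frames


def _phosphate_z(frame: MonolayerFrame, mol_atoms: np.ndarray, species_map: SpeciesMap) -> float | None:
    names = frame.names[mol_atoms]
    for pname in species_map.phosphate_names:
        hit = mol_atoms[names == pname]
        if hit.size:
            return float(frame.coords[hit[0], 2])
    return None


def assign_leaflets(
    frame: MonolayerFrame,
    midplane: float | None = None,
    species_map: SpeciesMap | None = None,
) -> dict[int, str]:
    """Assign every lipid molecule to the upper or lower leaflet.

    The reference midplane defaults to the mean z of the water slab; lipids
    whose headgroup marker (phosphate, else molecule centroid) sits above it
    are ``"upper"``, below are ``"lower"``.  A lipid exactly at the midplane
    is assigned upper (tie-break) with a warning.
    """
    species_map = species_map or SpeciesMap()
    if midplane is None:
        water = frame.atom_indices(species="WATER")
        if water.size == 0:
            raise MidplaneError(
                "frame contains no water and no explicit midplane was given"
            )
        midplane = float(np.mean(frame.coords[water, 2]))
    labels: dict[int, str] = {}
    for mid, atoms in frame.molecules(species=LIPID_SPECIES).items():
        z = _phosphate_z(frame, atoms, species_map)
        if z is None:
            z = float(np.mean(frame.coords[atoms, 2]))
        if z == midplane:
            warnings.warn(f"lipid molecule {mid} exactly at midplane; assigned upper")
        labels[mid] = "upper" if z >= midplane else "lower"
    return labels


def area_per_lipid(
    frame: MonolayerFrame,
    leaflet: str = "upper",
    assignment: dict[int, str] | None = None,
) -> float:
    """In-plane box area divided by the leaflet's lipid count, in Angstrom^2."""
    assignment = assignment if assignment is not None else assign_leaflets(frame)
    n = sum(1 for lab in assignment.values() if lab == leaflet)
    if n == 0:
        raise ZeroDivisionError(f"no lipids assigned to the {leaflet!r} leaflet")
    return float(frame.box[0] * frame.box[1] * 100.0 / n)  # nm^2 -> A^2


def _min_image_dists_2d(points: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    delta = points[:, None, :] - points[None, :, :]
    delta -= box_xy * np.round(delta / box_xy)
    return np.sqrt((delta**2).sum(axis=-1))


@dataclass
class PackingResult:
    """L_c assignment of chain/cholesterol entities in one leaflet."""

    lc_fraction: float
    cluster_labels: np.ndarray  # per entity; -1 = not in any cluster
    entity_positions: np.ndarray  # (n, 2) marker xy, nm
    entity_mol_ids: np.ndarray
    n_entities: int
    warnings: list[str] = field(default_factory=list)


def _collect_packing_entities(
    frame: MonolayerFrame,
    leaflet: str,
    assignment: dict[int, str],
    species_map: SpeciesMap,
) -> tuple[np.ndarray, np.ndarray]:
    """Marker xy of every acyl chain (10th carbon) and cholesterol (C14)."""
    positions: list[np.ndarray] = []
    mol_of: list[int] = []
    missing: set[str] = set()
    for mid, atoms in frame.molecules(species=LIPID_SPECIES).items():
        if assignment.get(mid) != leaflet:
            continue
        names = frame.names[atoms]
        sp = frame.species[atoms[0]]
        if sp == "CHOL":
            found = False
            for marker in species_map.chol_markers:
                hit = atoms[names == marker]
                if hit.size:
                    positions.append(frame.coords[hit[0], :2])
                    mol_of.append(mid)
                    found = True
                    break
            if not found:
                missing.add(sp)
        else:
            any_chain = False
            for chain in species_map.chain_markers:
                hit = atoms[names == chain["c10"]]
                if hit.size:
                    positions.append(frame.coords[hit[0], :2])
                    mol_of.append(mid)
                    any_chain = True
            if not any_chain:
                missing.add(str(sp))
    if missing:
        raise MarkerError(
            f"could not resolve packing marker atoms for species: {sorted(missing)}"
        )
    if not positions:
        return np.empty((0, 2)), np.empty(0, dtype=int)
    return np.vstack(positions), np.asarray(mol_of, dtype=int)


def packing_fraction(
    frame: MonolayerFrame,
    leaflet: str = "upper",
    assignment: dict[int, str] | None = None,
    eps: float = 0.71,
    min_neighbors: int = 6,
    include_border: bool = True,
    count_self: bool = False,
    species_map: SpeciesMap | None = None,
) -> PackingResult:
    """Fraction of chains/cholesterol in tightly packed (L_c-like) clusters.

    The 10th acyl carbon of each phospholipid chain and the C14 atom of each
    cholesterol are clustered in the membrane plane by DBSCAN under periodic
    minimum-image distances.  A core entity needs ``min_neighbors`` *other*
    entities within ``eps`` (set ``count_self=True`` for the convention that
    counts the point itself); entities joined to a cluster as border points
    count as L_c by default, since they are part of a tightly packed cluster.
    """
    species_map = species_map or SpeciesMap()
    assignment = assignment if assignment is not None else assign_leaflets(frame, species_map=species_map)
    pos, mol_of = _collect_packing_entities(frame, leaflet, assignment, species_map)
    n = pos.shape[0]
    if n == 0:
        raise SelectionError(f"no packing entities in the {leaflet!r} leaflet")
    if n < min_neighbors + 1:
        return PackingResult(
            0.0, np.full(n, -1), pos, mol_of, n,
            warnings=[f"only {n} entities; fewer than min_neighbors+1"],
        )
    dists = _min_image_dists_2d(pos, frame.box[:2])
    min_samples = min_neighbors + (1 if not count_self else 0)
    db = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(dists)
    labels = db.labels_.copy()
    if not include_border:
        core = np.zeros(n, dtype=bool)
        core[db.core_sample_indices_] = True
        labels = np.where(core, labels, -1)
    lc = float(np.count_nonzero(labels >= 0)) / n
    return PackingResult(lc, labels, pos, mol_of, n)


def packing_fraction_series(frames, **kwargs) -> tuple[float, float, list[PackingResult]]:
    """Time average of the L_c fraction over frames: (mean, std, per-frame)."""
    results = [packing_fraction(f, **kwargs) for f in frames]
    fracs = np.array([r.lc_fraction for r in results])
    return float(fracs.mean()), float(fracs.std()), results


@dataclass
class TiltResult:
    """Acyl-chain tilt relative to the monolayer normal."""

    mean_tilt: float  # degrees
    per_chain_tilt: np.ndarray  # degrees, one per chain
    n_chains: int


def chain_tilt(
    frame: MonolayerFrame,
    leaflet: str = "upper",
    assignment: dict[int, str] | None = None,
    species_map: SpeciesMap | None = None,
) -> TiltResult:
    """Mean tilt of phospholipid acyl chains in a leaflet.

    For each chain the vector from the first to the 16th carbon is compared
    with the z axis; the angle is folded to [0, 90] degrees so that leaflet
    orientation and chain direction conventions cannot flip signs.
    Cholesterol is excluded.  Averaging is over chains (two per
    phospholipid).
    """
    species_map = species_map or SpeciesMap()
    assignment = assignment if assignment is not None else assign_leaflets(frame, species_map=species_map)
    tilts: list[float] = []
    missing: set[str] = set()
    for mid, atoms in frame.molecules(species=PHOSPHOLIPID_SPECIES).items():
        if assignment.get(mid) != leaflet:
            continue
        names = frame.names[atoms]
        resolved = 0
        for chain in species_map.chain_markers:
            hit1 = atoms[names == chain["c1"]]
            hit16 = atoms[names == chain["c16"]]
            if hit1.size and hit16.size:
                v = frame.coords[hit16[0]] - frame.coords[hit1[0]]
                norm = np.linalg.norm(v)
                if norm == 0:
                    continue
                cos = abs(v[2]) / norm
                tilts.append(float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))))
                resolved += 1
            elif hit1.size != hit16.size:
                missing.add(str(frame.species[atoms[0]]))
        if resolved == 0:
            missing.add(str(frame.species[atoms[0]]))
    if missing:
        raise MarkerError(f"missing C1/C16 chain markers for species: {sorted(missing)}")
    arr = np.asarray(tilts)
    if arr.size == 0:
        raise SelectionError(f"no phospholipid chains in the {leaflet!r} leaflet")
    return TiltResult(float(arr.mean()), arr, int(arr.size))


@dataclass
class DensityProfile:
    """Per-species number density along z, phosphate-centered, max-normalized."""

    z_grid: np.ndarray  # bin centers, nm, 0 = phosphate plane
    density_per_species: dict[str, np.ndarray]
    raw_counts: dict[str, np.ndarray]
    bin_width: float
    empty_species: list[str] = field(default_factory=list)


def density_profile(
    frames,
    species_groups: dict[str, object],
    leaflet: str = "upper",
    bin_width: float = 0.1,
    z_range: tuple[float, float] = (-4.0, 4.0),
    species_map: SpeciesMap | None = None,
) -> DensityProfile:
    """Number-density profiles along the monolayer normal.

    ``species_groups`` maps an output label to a species name (or list of
    species).  For every frame the z origin is shifted to the mean phosphate
    position of the chosen leaflet before histogramming, removing interface
    drift; counts accumulate over frames and each species curve is then
    divided by its maximum.  Species absent from all frames yield an all-zero
    profile and are flagged rather than raising.
    """
    species_map = species_map or SpeciesMap()
    if not frames:
        raise ValueError("need at least one frame")
    edges = np.arange(z_range[0], z_range[1] + bin_width * 0.5, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = {label: np.zeros(centers.size) for label in species_groups}
    for frame in frames:
        assignment = assign_leaflets(frame, species_map=species_map)
        p_z: list[float] = []
        for mid, atoms in frame.molecules(species=PHOSPHOLIPID_SPECIES).items():
            if assignment.get(mid) != leaflet:
                continue
            z = _phosphate_z(frame, atoms, species_map)
            if z is not None:
                p_z.append(z)
        if not p_z:
            raise MarkerError("no phosphate markers found for profile centering")
        z0 = float(np.mean(p_z))
        sign = 1.0 if leaflet == "upper" else -1.0
        for label, sel in species_groups.items():
            idx = frame.atom_indices(species=sel)
            if idx.size == 0:
                continue
            # Positive profile coordinate points away from water for either
            # leaflet, so upper/lower profiles are comparable.
            z_rel = sign * (frame.coords[idx, 2] - z0)
            h, _ = np.histogram(z_rel, bins=edges)
            counts[label] += h
    density: dict[str, np.ndarray] = {}
    empty: list[str] = []
    for label, c in counts.items():
        peak = c.max()
        if peak == 0:
            density[label] = c.copy()
            empty.append(label)
        else:
            density[label] = c / peak
    return DensityProfile(centers, density, counts, bin_width, empty)


@dataclass(frozen=True)
class ContactResult:
    """Normalized heavy-atom contact count between two groups."""

    normalized: float
    raw_pairs: int
    n_a: int
    n_b: int

    def __float__(self) -> float:
        return self.normalized


def _resolve_group(frame: MonolayerFrame, group) -> np.ndarray:
    if isinstance(group, str) or (
        isinstance(group, (list, tuple, set)) and all(isinstance(g, str) for g in group)
    ):
        idx = frame.atom_indices(species=group)
    else:
        idx = np.asarray(group, dtype=int)
    heavy = frame.heavy_mask()
    idx = idx[heavy[idx]]
    return idx


def contact_count(
    frame: MonolayerFrame,
    group_a,
    group_b,
    cutoff: float = 0.6,
) -> ContactResult:
    """Heavy-atom contacts between two disjoint groups under 3D periodicity.

    Counts pairs (a in A, b in B) whose minimum-image distance is at most
    ``cutoff`` and divides by ``N_A * N_B``, the number of possible
    interaction partners.  Groups are species labels or explicit atom index
    arrays; hydrogens are excluded before counting.
    """
    idx_a = _resolve_group(frame, group_a)
    idx_b = _resolve_group(frame, group_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise SelectionError("contact groups must be non-empty after hydrogen exclusion")
    if np.intersect1d(idx_a, idx_b).size:
        raise SelectionError("contact groups must be disjoint")
    box = frame.box
    pa = np.mod(frame.coords[idx_a], box)
    pb = np.mod(frame.coords[idx_b], box)
    # cKDTree requires strictly in-box coordinates when boxsize is set.
    pa = np.where(pa >= box, 0.0, pa)
    pb = np.where(pb >= box, 0.0, pb)
    tree_a = cKDTree(pa, boxsize=box)
    tree_b = cKDTree(pb, boxsize=box)
    pairs = int(tree_a.count_neighbors(tree_b, cutoff))
    return ContactResult(pairs / (idx_a.size * idx_b.size), pairs, idx_a.size, idx_b.size)


@dataclass
class ContactSeries:
    """Normalized contacts of one group pair binned by area per lipid."""

    apl_grid: np.ndarray  # bin centers, A^2, strictly increasing
    normalized_contacts: np.ndarray
    error: np.ndarray | None
    group_pair: tuple[str, str]
    flags: list[str] = field(default_factory=list)


def contacts_vs_area(
    frames,
    group_a,
    group_b,
    apl_bins,
    cutoff: float = 0.6,
    leaflet: str = "upper",
    species_map: SpeciesMap | None = None,
) -> ContactSeries:
    """Per-frame normalized contacts averaged within area-per-lipid bins.

    Frames whose APL falls outside the bin edges are skipped and flagged;
    empty bins are omitted from the output grid (and flagged), keeping the
    APL grid strictly increasing.
    """
    apl_bins = np.asarray(apl_bins, dtype=float)
    if apl_bins.size < 2 or np.any(np.diff(apl_bins) <= 0):
        raise ValueError("apl_bins must be increasing edges with >= 2 entries")
    sums = np.zeros(apl_bins.size - 1)
    counts = np.zeros(apl_bins.size - 1, dtype=int)
    flags: list[str] = []
    n_out = 0
    for frame in frames:
        assignment = assign_leaflets(frame, species_map=species_map)
        apl = area_per_lipid(frame, leaflet, assignment)
        j = int(np.searchsorted(apl_bins, apl, side="right")) - 1
        if j < 0 or j >= counts.size:
            n_out += 1
            continue
        value = contact_count(frame, group_a, group_b, cutoff).normalized
        sums[j] += value
        counts[j] += 1
    if n_out:
        flags.append(f"{n_out} frame(s) outside the APL bin range")
    filled = counts > 0
    if not filled.all():
        flags.append(f"{int((~filled).sum())} empty APL bin(s) omitted")
    centers = 0.5 * (apl_bins[:-1] + apl_bins[1:])
    pair = (
        group_a if isinstance(group_a, str) else "group_a",
        group_b if isinstance(group_b, str) else "group_b",
    )
    return ContactSeries(
        centers[filled], sums[filled] / counts[filled], None, pair, flags
    )


def replica_aggregate(series_1: ContactSeries, series_2: ContactSeries) -> ContactSeries:
    """Combine two replica contact series into mean and half-difference error.

    Duplicate simulations are summarized by their per-bin mean, with the
    half absolute difference between replicas as the error estimate.
    """
    if series_1.group_pair != series_2.group_pair:
        raise AlignmentError(
            f"group pairs differ: {series_1.group_pair} vs {series_2.group_pair}"
        )
    if series_1.apl_grid.size != series_2.apl_grid.size or not np.allclose(
        series_1.apl_grid, series_2.apl_grid
    ):
        raise AlignmentError("replica APL grids do not match")
    mean = 0.5 * (series_1.normalized_contacts + series_2.normalized_contacts)
    err = 0.5 * np.abs(series_1.normalized_contacts - series_2.normalized_contacts)
    return ContactSeries(
        series_1.apl_grid.copy(), mean, err, series_1.group_pair,
        sorted(set(series_1.flags) | set(series_2.flags)),
    )
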