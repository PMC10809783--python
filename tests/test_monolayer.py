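"""Monolayer structure: leaflets, APL, packing, tilt, densities, contacts."""

import numpy as np
import pytest

import oracles
from monosurf import monolayer as ml
from monosurf import synthetic
from monosurf.monolayer import MonolayerFrame


def _hex_lattice(n_cols, n_rows, spacing):
    rows = np.repeat(np.arange(n_rows), n_cols)
    cols = np.tile(np.arange(n_cols), n_rows)
    x = (cols + 0.5 * (rows % 2)) * spacing
    y = rows * spacing * np.sqrt(3) / 2.0
    return np.column_stack([x, y])


class TestLoadFrames:
    def test_two_molecule_gro_fixture(self, tmp_path, marker_frame_factory):
        frame = marker_frame_factory(np.array([[1.0, 1.0], [3.0, 3.0]]), box_l=6.0)
        path = synthetic.write_frame(frame, tmp_path / "two.gro")
        loaded = ml.load_frames(path)[0]
        assert loaded.n_atoms == frame.n_atoms
        assert len(loaded.molecules(species="DPPC")) == 2

    def test_unknown_residue_raises_mapping_error(self, tmp_path):
        frame = MonolayerFrame(
            coords=np.array([[1.0, 1, 1], [2, 2, 2]]),
            names=np.array(["C1", "C2"]),
            species=np.array(["CHEMICAL", "CHEMICAL"]),
            resnames=np.array(["XYZ", "XYZ"]),
            mol_ids=np.array([0, 0]),
            box=np.array([5.0, 5.0, 5.0]),
        )
        path = synthetic.write_frame(frame, tmp_path / "bad.pdb")
        with pytest.raises(ml.MappingError, match="XYZ"):
            ml.load_frames(path)

    def test_multiframe_pdb_order_preserved(self, tmp_path):
        frames, truth = synthetic.simulate_compression_series(n_frames=3)
        path = synthetic.write_frames(frames, tmp_path / "series.pdb")
        loaded = ml.load_frames(path)
        assert len(loaded) == 3
        apls = [ml.area_per_lipid(f) for f in loaded]
        np.testing.assert_allclose(apls, truth.apl_sequence, rtol=1e-3)


class TestAssignLeaflets:
    def test_labels_match_construction(self):
        frame, _ = synthetic.build_monolayer_frame(
            synthetic.MonolayerSpec(n_lipids_per_leaflet=36, apl=100.0, seed=0)
        )
        labels = ml.assign_leaflets(frame)
        upper = [m for m, l in labels.items() if l == "upper"]
        lower = [m for m, l in labels.items() if l == "lower"]
        assert len(upper) == len(lower) == 36
        for mid in upper:
            atoms = frame.atom_indices(mol_ids=[mid])
            assert frame.coords[atoms, 2].mean() > 4.0

    def test_explicit_midplane_single_leaflet(self, marker_frame_factory):
        frame = marker_frame_factory(np.array([[1.0, 1.0], [2.0, 2.0]]), box_l=5.0)
        labels = ml.assign_leaflets(frame, midplane=0.0)
        assert set(labels.values()) == {"upper"}

    def test_no_water_no_midplane_raises(self, marker_frame_factory):
        frame = marker_frame_factory(np.array([[1.0, 1.0]]), box_l=5.0)
        frame = MonolayerFrame(
            coords=frame.coords[:4],
            names=frame.names[:4],
            species=frame.species[:4],
            resnames=frame.resnames[:4],
            mol_ids=frame.mol_ids[:4],
            box=frame.box,
        )
        with pytest.raises(ml.MidplaneError):
            ml.assign_leaflets(frame)

    def test_lipid_at_midplane_goes_upper_with_warning(self, marker_frame_factory):
        frame = marker_frame_factory(np.array([[1.0, 1.0]]), box_l=5.0, z_head=5.0)
        with pytest.warns(UserWarning, match="midplane"):
            labels = ml.assign_leaflets(frame, midplane=5.0)
        assert labels[0] == "upper"


class TestAreaPerLipid:
    def test_physiological_scale_arithmetic(self, marker_frame_factory):
        # 9.05 x 9.05 nm holding 149 lipids is ~55 A^2 per lipid.
        pts = np.random.default_rng(0).uniform(0, 9.05, size=(149, 2))
        frame = marker_frame_factory(pts, box_l=9.05)
        apl = ml.area_per_lipid(frame, "upper", {i: "upper" for i in range(149)})
        assert apl == pytest.approx(54.97, abs=0.01)

    def test_simple_division(self, marker_frame_factory):
        pts = np.random.default_rng(1).uniform(0, 10, size=(100, 2))
        frame = marker_frame_factory(pts, box_l=10.0)
        apl = ml.area_per_lipid(frame, "upper", {i: "upper" for i in range(100)})
        assert apl == pytest.approx(100.0)

    def test_scales_linearly_with_box_x(self, marker_frame_factory):
        pts = np.random.default_rng(2).uniform(0, 8, size=(50, 2))
        frame = marker_frame_factory(pts, box_l=8.0)
        assignment = {i: "upper" for i in range(50)}
        doubled = MonolayerFrame(
            coords=frame.coords,
            names=frame.names,
            species=frame.species,
            resnames=frame.resnames,
            mol_ids=frame.mol_ids,
            box=frame.box * np.array([2.0, 1.0, 1.0]),
        )
        assert ml.area_per_lipid(doubled, "upper", assignment) == pytest.approx(
            2 * ml.area_per_lipid(frame, "upper", assignment)
        )

    def test_empty_leaflet_raises(self, marker_frame_factory):
        frame = marker_frame_factory(np.array([[1.0, 1.0]]), box_l=5.0)
        with pytest.raises(ZeroDivisionError):
            ml.area_per_lipid(frame, "lower", {0: "upper"})


class TestPackingFraction:
    def test_periodic_hexagonal_lattice_is_fully_condensed(self, marker_frame_factory):
        # 20 columns wrap exactly; every site has 6 neighbors within eps.
        spacing = 0.48
        pts = _hex_lattice(20, 10, spacing)
        frame = marker_frame_factory(pts, box_l=20 * spacing)
        res = ml.packing_fraction(frame, "upper", {i: "upper" for i in range(len(pts))})
        assert res.lc_fraction == 1.0

    def test_sparse_gas_is_fully_disordered(self, marker_frame_factory):
        pts = _hex_lattice(8, 8, 0.9)  # min spacing 0.9 > eps
        frame = marker_frame_factory(pts, box_l=8 * 0.9)
        res = ml.packing_fraction(frame, "upper", {i: "upper" for i in range(len(pts))})
        assert res.lc_fraction == 0.0
        assert np.all(res.cluster_labels == -1)

    def test_matches_brute_force_oracle_on_mixed_frame(self, marker_frame_factory):
        rng = np.random.default_rng(5)
        lattice = _hex_lattice(10, 10, 0.48) + 0.2
        gas = rng.uniform(0, 12.0, size=(100, 2))
        pts = np.vstack([lattice, gas])
        frame = marker_frame_factory(pts, box_l=12.0)
        assignment = {i: "upper" for i in range(len(pts))}
        res = ml.packing_fraction(frame, "upper", assignment)
        labels, core = oracles.brute_dbscan(
            res.entity_positions, frame.box[:2], eps=0.71, min_neighbors=6
        )
        np.testing.assert_array_equal(res.cluster_labels >= 0, labels >= 0)
        assert oracles.same_partition(res.cluster_labels, labels, core)
        assert abs(res.lc_fraction - np.mean(labels >= 0)) < 1e-12

    def test_invariant_under_rigid_translation(self, marker_frame_factory):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 6, size=(80, 2))
        assignment = {i: "upper" for i in range(80)}
        a = ml.packing_fraction(
            marker_frame_factory(pts, box_l=6.0), "upper", assignment
        )
        b = ml.packing_fraction(
            marker_frame_factory((pts + 2.345) % 6.0, box_l=6.0), "upper", assignment
        )
        assert a.lc_fraction == b.lc_fraction

    def test_too_few_entities_warns_zero(self, marker_frame_factory):
        frame = marker_frame_factory(np.array([[1.0, 1.0], [1.2, 1.2]]), box_l=5.0)
        res = ml.packing_fraction(frame, "upper", {0: "upper", 1: "upper"})
        assert res.lc_fraction == 0.0
        assert res.warnings


class TestChainTilt:
    def test_vertical_chains_have_zero_tilt(self):
        frame, _ = synthetic.build_monolayer_frame(
            synthetic.MonolayerSpec(n_lipids_per_leaflet=36, apl=100.0, tilt_deg=0.0, seed=1)
        )
        res = ml.chain_tilt(frame)
        assert res.mean_tilt == pytest.approx(0.0, abs=1e-9)

    def test_uniform_25_degree_tilt(self):
        frame, _ = synthetic.build_monolayer_frame(
            synthetic.MonolayerSpec(
                n_lipids_per_leaflet=64, apl=55.0, lc_patch_fraction=1.0,
                tilt_deg=25.0, seed=2,
            )
        )
        res = ml.chain_tilt(frame)
        assert res.mean_tilt == pytest.approx(25.0, abs=1e-9)
        assert res.mean_tilt == pytest.approx(np.mean(res.per_chain_tilt))

    def test_lower_leaflet_matches_upper_by_fold(self):
        frame, _ = synthetic.build_monolayer_frame(
            synthetic.MonolayerSpec(
                n_lipids_per_leaflet=64, apl=55.0, lc_patch_fraction=1.0,
                tilt_deg=25.0, seed=2,
            )
        )
        lower = ml.chain_tilt(frame, leaflet="lower")
        assert lower.mean_tilt == pytest.approx(25.0, abs=1e-9)

    def test_invariant_under_rotation_about_z(self):
        frame, _ = synthetic.build_monolayer_frame(
            synthetic.MonolayerSpec(n_lipids_per_leaflet=36, apl=100.0, tilt_deg=20.0, seed=3)
        )
        before = ml.chain_tilt(frame).mean_tilt
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = MonolayerFrame(
            coords=frame.coords @ rot.T,
            names=frame.names,
            species=frame.species,
            resnames=frame.resnames,
            mol_ids=frame.mol_ids,
            box=frame.box,
        )
        assert ml.chain_tilt(rotated).mean_tilt == pytest.approx(before, abs=1e-9)

    def test_missing_c16_marker_raises(self, marker_frame_factory):
        frame = marker_frame_factory(np.array([[1.0, 1.0]]), box_l=5.0)
        keep = frame.names != "C16A"
        broken = MonolayerFrame(
            coords=frame.coords[keep],
            names=frame.names[keep],
            species=frame.species[keep],
            resnames=frame.resnames[keep],
            mol_ids=frame.mol_ids[keep],
            box=frame.box,
        )
        with pytest.raises(ml.MarkerError):
            ml.chain_tilt(broken, "upper", {0: "upper"})


class TestDensityProfile:
    def test_point_mass_gives_unit_peak_in_right_bin(self):
        frame, _ = synthetic.build_monolayer_frame(
            synthetic.MonolayerSpec(
                n_lipids_per_leaflet=36, apl=100.0, n_chemical=40,
                chemical_z_offset=1.0, seed=4,
            )
        )
        prof = ml.density_profile([frame], {"chem": "CHEMICAL"})
        peak_z = prof.z_grid[np.argmax(prof.density_per_species["chem"])]
        assert abs(peak_z - 1.0) <= prof.bin_width
        assert prof.density_per_species["chem"].max() == 1.0

    def test_gaussian_cloud_matches_histogram_oracle(self):
        rng = np.random.default_rng(9)
        frame, _ = synthetic.build_monolayer_frame(
            synthetic.MonolayerSpec(n_lipids_per_leaflet=36, apl=100.0, seed=5)
        )
        z_draws = rng.normal(0.8, 0.2, size=500)
        chem_coords = np.column_stack(
            [
                rng.uniform(0, frame.box[0], 500),
                rng.uniform(0, frame.box[1], 500),
                5.0 + z_draws,  # phosphate plane of the upper leaflet is z=5
            ]
        )
        n0 = frame.n_atoms
        frame = MonolayerFrame(
            coords=np.vstack([frame.coords, chem_coords]),
            names=np.concatenate([frame.names, ["CX"] * 500]),
            species=np.concatenate([frame.species, ["CHEMICAL"] * 500]),
            resnames=np.concatenate([frame.resnames, ["CHEM"] * 500]),
            mol_ids=np.concatenate(
                [frame.mol_ids, frame.mol_ids.max() + 1 + np.arange(500)]
            ),
            box=frame.box,
        )
        prof = ml.density_profile([frame], {"chem": "CHEMICAL"})
        edges = np.arange(-4.0, 4.0 + 0.05, 0.1)
        expected, _ = np.histogram(z_draws, bins=edges)
        np.testing.assert_array_equal(prof.raw_counts["chem"], expected)
        peak_z = prof.z_grid[np.argmax(prof.density_per_species["chem"])]
        assert abs(peak_z - 0.8) <= 0.1 + 1e-9
        assert prof.density_per_species["chem"].max() == 1.0
        # Conservation: all particles land somewhere in the range.
        assert prof.raw_counts["chem"].sum() == 500

    def test_absent_species_flagged_not_error(self):
        frame, _ = synthetic.build_monolayer_frame(
            synthetic.MonolayerSpec(n_lipids_per_leaflet=36, apl=100.0, seed=6)
        )
        prof = ml.density_profile([frame], {"chem": "CHEMICAL"})
        assert "chem" in prof.empty_species
        assert not prof.density_per_species["chem"].any()


class TestContactCount:
    def _two_particle_frame(self, dist):
        coords = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0 + dist]])
        return MonolayerFrame(
            coords=coords,
            names=np.array(["B1", "CX"]),
            species=np.array(["PROTEIN", "CHEMICAL"]),
            resnames=np.array(["PROT", "CHEM"]),
            mol_ids=np.array([0, 1]),
            box=np.array([5.0, 5.0, 5.0]),
        )

    def test_pair_inside_cutoff(self):
        res = ml.contact_count(self._two_particle_frame(0.5), "PROTEIN", "CHEMICAL")
        assert res.normalized == 1.0

    def test_pair_outside_cutoff(self):
        res = ml.contact_count(self._two_particle_frame(0.7), "PROTEIN", "CHEMICAL")
        assert res.normalized == 0.0

    def test_matches_brute_force_with_periodic_images(self):
        rng = np.random.default_rng(12)
        box = np.array([4.0, 4.0, 4.0])
        pa = rng.uniform(0, 4, size=(300, 3))
        pb = rng.uniform(0, 4, size=(300, 3))
        frame = MonolayerFrame(
            coords=np.vstack([pa, pb]),
            names=np.array(["B1"] * 300 + ["CX"] * 300),
            species=np.array(["PROTEIN"] * 300 + ["CHEMICAL"] * 300),
            resnames=np.array(["PROT"] * 300 + ["CHEM"] * 300),
            mol_ids=np.concatenate([np.zeros(300, int), np.arange(1, 301)]),
            box=box,
        )
        res = ml.contact_count(frame, "PROTEIN", "CHEMICAL")
        expected = oracles.brute_contact_pairs(pa, pb, box, 0.6)
        assert res.raw_pairs == expected
        assert res.normalized == expected / (300 * 300)

    def test_symmetric_and_monotone_in_cutoff(self):
        frame = self._two_particle_frame(0.55)
        ab = ml.contact_count(frame, "PROTEIN", "CHEMICAL")
        ba = ml.contact_count(frame, "CHEMICAL", "PROTEIN")
        assert ab.normalized == ba.normalized
        narrow = ml.contact_count(frame, "PROTEIN", "CHEMICAL", cutoff=0.3)
        wide = ml.contact_count(frame, "PROTEIN", "CHEMICAL", cutoff=1.0)
        assert narrow.normalized <= ab.normalized <= wide.normalized

    def test_hydrogens_excluded(self):
        frame = self._two_particle_frame(0.5)
        frame.names[1] = "H1"
        with pytest.raises(ml.SelectionError):
            ml.contact_count(frame, "PROTEIN", "CHEMICAL")

    def test_overlapping_groups_raise(self):
        frame = self._two_particle_frame(0.5)
        with pytest.raises(ml.SelectionError):
            ml.contact_count(frame, [0, 1], [1])


class TestContactsVsArea:
    def test_constructed_series_recovered_exactly(self):
        frames, truth = synthetic.simulate_compression_series(n_frames=6)
        series = ml.contacts_vs_area(
            frames, "PROTEIN", "CHEMICAL", apl_bins=np.arange(50, 116, 5)
        )
        for apl, expected in zip(truth.apl_sequence, truth.true_contacts):
            j = np.argmin(np.abs(series.apl_grid - apl))
            assert series.normalized_contacts[j] == pytest.approx(expected)

    def test_bins_not_covering_data_flagged(self):
        frames, _ = synthetic.simulate_compression_series(n_frames=3)
        series = ml.contacts_vs_area(
            frames, "PROTEIN", "CHEMICAL", apl_bins=np.array([200.0, 210.0])
        )
        assert any("outside" in f for f in series.flags)
        assert series.apl_grid.size == 0


class TestReplicaAggregate:
    def _series(self, values):
        return ml.ContactSeries(
            apl_grid=np.array([60.0, 70.0]),
            normalized_contacts=np.asarray(values, float),
            error=None,
            group_pair=("PROTEIN", "CHEMICAL"),
        )

    def test_identical_replicas_zero_error(self):
        agg = ml.replica_aggregate(self._series([0.1, 0.2]), self._series([0.1, 0.2]))
        np.testing.assert_array_equal(agg.error, [0.0, 0.0])

    def test_mean_and_half_difference(self):
        agg = ml.replica_aggregate(self._series([1.0, 1.0]), self._series([3.0, 3.0]))
        np.testing.assert_allclose(agg.normalized_contacts, [2.0, 2.0])
        np.testing.assert_allclose(agg.error, [1.0, 1.0])

    def test_mismatched_grids_raise(self):
        other = ml.ContactSeries(
            apl_grid=np.array([60.0]),
            normalized_contacts=np.array([0.1]),
            error=None,
            group_pair=("PROTEIN", "CHEMICAL"),
        )
        with pytest.raises(ml.AlignmentError):
            ml.replica_aggregate(self._series([0.1, 0.2]), other)


class TestSpeciesMap:
    def test_yaml_override_extends_defaults(self, tmp_path):
        cfg = tmp_path / "map.yaml"
        cfg.write_text("residues:\n  DMPC: DPPC\n  BNZ: CHEMICAL\n")
        smap = ml.SpeciesMap.from_yaml(cfg)
        assert smap.residues["DMPC"] == "DPPC"
        assert smap.residues["BNZ"] == "CHEMICAL"
        assert smap.residues["POPG"] == "POPG"  # defaults retained

    def test_custom_residue_resolves_on_load(self, tmp_path, marker_frame_factory):
        frame = marker_frame_factory(np.array([[1.0, 1.0]]), box_l=5.0)
        frame.resnames = np.where(frame.resnames == "DPPC", "DMPC", frame.resnames)
        path = synthetic.write_frame(frame, tmp_path / "f.gro")
        cfg = tmp_path / "map.yaml"
        cfg.write_text("residues:\n  DMPC: DPPC\n")
        loaded = ml.load_frames(path, species_map=ml.SpeciesMap.from_yaml(cfg))[0]
        assert set(loaded.species) == {"DPPC", "WATER"}
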