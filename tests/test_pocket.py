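import numpy as np
import pytest

from ck1switch import (
    build_grid,
    contour_map,
    ensemble_frequency_map,
    frame_free_volume,
    read_grid_map,
    write_grid_map,
)
from ck1switch.gridio import GridMap
from ck1switch.pocket import BONDI_RADII, PocketSpec, SphereRegion, default_pocket_spec
from ck1switch.structures import Ensemble, Structure
from ck1switch import synthetic as syn

from .oracles import mc_union_volume

SPHERE_V = lambda r: 4.0 / 3.0 * np.pi * r**3  # noqa: E731


class TestBuildGrid:
    def test_single_sphere_volume(self):
        spec = PocketSpec(spheres=[SphereRegion((0, 0, 0), 8.0)], grid_spacing=1.0)
        grid = build_grid(spec)
        volume = grid.mask.sum() * spec.grid_spacing**3
        assert volume == pytest.approx(SPHERE_V(8.0), rel=0.03)

    def test_disjoint_spheres_additive(self):
        spec = PocketSpec(
            spheres=[SphereRegion((0, 0, 0), 5.0), SphereRegion((30, 0, 0), 5.0)],
            grid_spacing=1.0,
        )
        both = build_grid(spec).mask.sum()
        single = build_grid(
            PocketSpec(spheres=[SphereRegion((0, 0, 0), 5.0)], grid_spacing=1.0)
        ).mask.sum()
        assert both == pytest.approx(2 * single, rel=0.01)

    def test_overlapping_union_matches_monte_carlo(self, rng):
        centers = np.array([[0, 0, 0], [8, 2, 0], [4, 1, 6.0]])
        radii = np.array([8.0, 8.0, 8.0])
        spec = PocketSpec(
            spheres=[SphereRegion(tuple(c), r) for c, r in zip(centers, radii)],
            grid_spacing=0.5,
        )
        grid_volume = build_grid(spec).mask.sum() * 0.5**3
        mc = mc_union_volume(centers, radii, n_samples=10**6, rng=rng)
        assert grid_volume == pytest.approx(mc, rel=0.02)

    def test_empty_region_error(self):
        # sphere smaller than the spacing can miss every lattice point
        spec = PocketSpec(
            spheres=[SphereRegion((0.45, 0.5, 0.5), 0.05)], grid_spacing=1.0
        )
        with pytest.raises(ValueError, match="no grid points"):
            build_grid(spec)


class TestFrameVolume:
    def test_no_atoms_full_volume(self):
        scene, spec, expected = syn.make_pocket_scene(occlusion="none")
        grid = build_grid(spec)
        volume, open_mask = frame_free_volume(np.zeros((0, 3)), scene, spec, grid)
        assert open_mask.all()
        assert volume == pytest.approx(grid.mask.sum() * spec.grid_spacing**3)
        assert volume == pytest.approx(expected, rel=0.03)

    def test_center_atom_removes_vdw_sphere(self):
        spec = PocketSpec(
            spheres=[SphereRegion((0.0, 0.0, 0.0), 8.0)], grid_spacing=0.5
        )
        scene, spec, expected = syn.make_pocket_scene(spec, occlusion="center_atom")
        grid = build_grid(spec)
        volume, _ = frame_free_volume(scene.coords, scene, spec, grid)
        full = grid.mask.sum() * spec.grid_spacing**3
        deficit = full - volume
        assert deficit == pytest.approx(SPHERE_V(BONDI_RADII["C"]), rel=0.08)

    def test_half_slab_analytic(self):
        spec = PocketSpec(
            spheres=[SphereRegion((0.0, 0.0, 0.0), 8.0)], grid_spacing=0.5
        )
        scene, spec, expected = syn.make_pocket_scene(spec, occlusion="half_slab")
        grid = build_grid(spec)
        volume, _ = frame_free_volume(scene.coords, scene, spec, grid)
        assert volume == pytest.approx(expected, rel=0.02)
        # and the cap is close to half the sphere
        assert volume == pytest.approx(SPHERE_V(8.0) / 2, rel=0.06)

    def test_unknown_element_is_configuration_error(self, toy_up):
        spec = PocketSpec(
            spheres=[SphereRegion((0, 0, 0), 8.0)],
            radii_table={"N": 1.55},  # C and O deliberately missing
        )
        grid = build_grid(spec)
        with pytest.raises(KeyError, match="'C'"):
            frame_free_volume(toy_up.coords, toy_up, spec, grid)

    def test_adding_atoms_is_monotone(self, rng):
        scene, spec, _ = syn.make_pocket_scene(occlusion="none")
        grid = build_grid(spec)
        atoms = rng.uniform(-6, 6, size=(20, 3))
        toy = syn.make_pocket_scene(occlusion="center_atom")[0]
        carbon = toy.atoms[0]
        from dataclasses import replace

        prev = np.inf
        for k in (0, 5, 10, 20):
            struct = Structure(
                id="s",
                atoms=[replace(carbon, serial=i + 1, xyz=tuple(atoms[i])) for i in range(k)],
            )
            volume, _ = frame_free_volume(struct.coords, struct, spec, grid)
            assert volume <= prev + 1e-9
            prev = volume

    def test_refinement_reduces_error(self):
        analytic = SPHERE_V(8.0)
        errors = []
        for spacing in (2.0, 1.0, 0.5):
            spec = PocketSpec(
                spheres=[SphereRegion((0, 0, 0), 8.0)], grid_spacing=spacing
            )
            grid = build_grid(spec)
            errors.append(abs(grid.mask.sum() * spacing**3 - analytic))
        assert errors[2] < errors[1] < errors[0]


class TestFrequencyMap:
    def _lid_ensemble(self):
        """10 frames alternating an open and a closed 'lid' over the sphere top."""
        spec = PocketSpec(spheres=[SphereRegion((0.0, 0.0, 0.0), 6.0)], grid_spacing=1.0)
        closed_scene, _, _ = syn.make_pocket_scene(
            PocketSpec(spheres=[SphereRegion((0.0, 0.0, 0.0), 6.0)], grid_spacing=1.0),
            occlusion="half_slab",
        )
        open_coords = closed_scene.coords + np.array([0.0, 0.0, -100.0])  # lid far away
        frames = [closed_scene.coords if i % 2 == 0 else open_coords for i in range(10)]
        return Ensemble(topology=closed_scene, frames=frames), spec

    def test_alternating_lid_gives_half_occupancy(self):
        ens, spec = self._lid_ensemble()
        with pytest.warns(UserWarning):  # the lid moves the centroid a lot
            freq, series = ensemble_frequency_map(ens, spec)
        vals = freq.masked_values()
        lid_points = np.isclose(vals, 0.5)
        open_points = np.isclose(vals, 1.0)
        assert lid_points.sum() > 0 and open_points.sum() > 0
        assert np.all(lid_points | open_points)

    def test_identical_frames_give_binary_map(self, toy_up):
        spec = PocketSpec(spheres=[SphereRegion((20.0, 20.0, 20.0), 8.0)])
        ens = Ensemble(topology=toy_up, frames=[toy_up.coords] * 3)
        freq, _ = ensemble_frequency_map(ens, spec)
        vals = freq.masked_values()
        assert np.all(np.isclose(vals, 0.0) | np.isclose(vals, 1.0))

    def test_map_equals_mean_of_frame_indicators(self):
        ens, spec = self._lid_ensemble()
        grid = build_grid(spec)
        with pytest.warns(UserWarning):
            freq, series = ensemble_frequency_map(ens, spec, grid=grid)
        indicators = []
        for frame in ens.frames:
            _, open_mask = frame_free_volume(frame, ens.topology, spec, grid)
            indicators.append(open_mask)
        np.testing.assert_allclose(
            freq.values[freq.mask], np.mean(indicators, axis=0)
        )

    def test_mean_volume_consistency(self):
        ens, spec = self._lid_ensemble()
        with pytest.warns(UserWarning):
            freq, series = ensemble_frequency_map(ens, spec)
        assert series.mean == pytest.approx(
            spec.grid_spacing**3 * freq.values[freq.mask].sum()
        )

    def test_stride_subsamples_frames(self):
        ens, spec = self._lid_ensemble()
        spec.frame_stride = 2
        with pytest.warns(UserWarning):
            _, series = ensemble_frequency_map(ens, spec)
        assert len(series.volumes) == 5
        np.testing.assert_array_equal(series.frame_indices, [0, 2, 4, 6, 8])


class TestContour:
    def test_constant_maps(self):
        grid = GridMap(
            origin=np.zeros(3), spacing=1.0, dims=(5, 5, 5),
            values=np.full((5, 5, 5), 0.5), mask=np.ones((5, 5, 5), bool),
        )
        assert contour_map(grid, 0.1).mask.sum() == 125
        low = GridMap(
            origin=np.zeros(3), spacing=1.0, dims=(5, 5, 5),
            values=np.full((5, 5, 5), 0.05), mask=np.ones((5, 5, 5), bool),
        )
        assert contour_map(low, 0.1).mask.sum() == 0

    def test_monotone_in_level(self, rng):
        values = rng.uniform(0, 1, size=(6, 6, 6))
        grid = GridMap(origin=np.zeros(3), spacing=1.0, dims=(6, 6, 6),
                       values=values, mask=np.ones((6, 6, 6), bool))
        counts = [contour_map(grid, lv).mask.sum() for lv in (0.1, 0.3, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)
        # retained-point count matches a direct count
        assert counts[0] == (values >= 0.1).sum()

    def test_invalid_level(self, rng):
        grid = GridMap(origin=np.zeros(3), spacing=1.0, dims=(2, 2, 2),
                       values=np.zeros((2, 2, 2)))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                contour_map(grid, bad)


class TestGridIO:
    def test_round_trip(self, tmp_path, rng):
        values = rng.uniform(0, 1, size=(7, 6, 5))
        grid = GridMap(origin=np.array([1.0, -2.0, 3.5]), spacing=0.5,
                       dims=(7, 6, 5), values=values)
        path = tmp_path / "map.dx"
        write_grid_map(grid, path)
        back = read_grid_map(path)
        assert back.dims == grid.dims
        assert back.spacing == pytest.approx(0.5)
        np.testing.assert_allclose(back.origin, grid.origin)
        np.testing.assert_allclose(back.values, grid.values, atol=1e-6)

    def test_empty_sphere_map_round_trip(self, tmp_path):
        scene, spec, _ = syn.make_pocket_scene(occlusion="none")
        grid = build_grid(spec)
        ens = Ensemble(topology=scene, frames=[np.zeros((0, 3))])
        freq, _ = ensemble_frequency_map(ens, spec, grid=grid)
        path = tmp_path / "empty.dx"
        write_grid_map(freq, path)
        back = read_grid_map(path)
        dense = np.where(freq.mask, freq.values, 0.0)
        np.testing.assert_allclose(back.values, dense, atol=1e-6)

    def test_out_of_range_values_rejected(self, tmp_path):
        grid = GridMap(origin=np.zeros(3), spacing=1.0, dims=(2, 2, 2),
                       values=np.full((2, 2, 2), 1.5))
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            write_grid_map(grid, tmp_path / "bad.dx")


class TestDefaultSpec:
    def test_spheres_anchored_on_anion_site_residues(self, toy_up):
        spec = default_pocket_spec(toy_up)
        assert len(spec.spheres) == 3
        c1 = np.array(spec.spheres[0].center)
        c2 = np.array(spec.spheres[1].center)
        c3 = np.array(spec.spheres[2].center)
        np.testing.assert_allclose(c3, (c1 + c2) / 2)
        assert all(s.radius == 8.0 for s in spec.spheres)
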