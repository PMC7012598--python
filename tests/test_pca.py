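import numpy as np
import pytest

from ck1switch import (
    fit_pc_model,
    histogram_projections,
    mode_endpoints,
    project,
)
from ck1switch.structures import (
    AtomSelection,
    BACKBONE_ATOMS,
    Ensemble,
    StructureError,
    select_atoms,
)
from ck1switch import synthetic as syn


def _backbone_mode(structure, rng):
    """Unit 3N-vector over backbone atoms only (zero on side-chain atoms)."""
    idx = select_atoms(structure, AtomSelection(atom_names=BACKBONE_ATOMS))
    v = np.zeros(structure.coords.size)
    comps = np.repeat(np.array(idx) * 3, 3) + np.tile([0, 1, 2], len(idx))
    v[comps] = rng.normal(size=len(comps))
    return v / np.linalg.norm(v)


def _restrict_to_backbone(vec, structure):
    idx = select_atoms(structure, AtomSelection(atom_names=BACKBONE_ATOMS))
    comps = np.repeat(np.array(idx) * 3, 3) + np.tile([0, 1, 2], len(idx))
    out = vec[comps]
    return out / np.linalg.norm(out)


class TestFit:
    def test_identical_frames_zero_variance(self, toy_up):
        ens = Ensemble(topology=toy_up, frames=[toy_up.coords] * 5)
        model = fit_pc_model([ens], toy_up)
        assert np.all(model.eigenvalues < 1e-18)

    def test_rank_one_displacement(self, toy_up, rng):
        v = _backbone_mode(toy_up, rng)
        amplitude = 3.0
        frames = [
            (toy_up.coords.ravel() + a * v).reshape(-1, 3)
            for a in (-amplitude, amplitude)
        ]
        ens = Ensemble(topology=toy_up, frames=frames)
        # frames are constructed in a common frame; an extra Kabsch fit
        # would absorb the mode's rigid-body component
        model = fit_pc_model([ens], toy_up, superpose=False)
        assert model.eigenvalues[0] == pytest.approx(amplitude**2, rel=1e-6)
        if model.n_modes > 1:
            assert model.eigenvalues[1] < 1e-10 * model.eigenvalues[0]
        cos = abs(model.eigenvectors[0] @ _restrict_to_backbone(v, toy_up))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_two_mode_generator_recovery(self, toy_up, rng):
        v1 = _backbone_mode(toy_up, rng)
        v2 = _backbone_mode(toy_up, rng)
        ens, truth = syn.make_mode_trajectory(
            toy_up, [(v1, 9.0), (v2, 4.0)], n_frames=2000, noise_sigma=0.1, seed=21
        )
        model = fit_pc_model([ens], toy_up)
        assert model.eigenvalues[0] == pytest.approx(9.0, rel=0.10)
        assert model.eigenvalues[1] == pytest.approx(4.0, rel=0.10)
        cos = abs(
            model.eigenvectors[0] @ _restrict_to_backbone(truth["modes"][0], toy_up)
        )
        assert cos > 0.99

    def test_single_frame_rejected(self, toy_up):
        ens = Ensemble(topology=toy_up, frames=[toy_up.coords])
        with pytest.raises(StructureError):
            fit_pc_model([ens], toy_up)

    def test_eigenvectors_orthonormal_eigenvalues_descending(self, toy_up, rng):
        ens, _ = syn.make_mode_trajectory(
            toy_up,
            [(_backbone_mode(toy_up, rng), 5.0), (_backbone_mode(toy_up, rng), 2.0)],
            n_frames=100, noise_sigma=0.2, seed=6,
        )
        model = fit_pc_model([ens], toy_up)
        gram = model.eigenvectors @ model.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(model.n_modes), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert np.all(model.eigenvalues >= 0)

    def test_agrees_with_svd_oracle_on_small_instance(self, toy_up, rng):
        """Eigenvalues match direct diagonalization of the covariance matrix."""
        ens, _ = syn.make_mode_trajectory(
            toy_up, [(_backbone_mode(toy_up, rng), 4.0)],
            n_frames=50, noise_sigma=0.3, seed=13,
        )
        model = fit_pc_model([ens], toy_up)
        # independent route: explicit covariance + eigh on superposed frames
        from ck1switch.pca import _reduce_backbone, _superposed_flat

        red, _ = _reduce_backbone(ens)
        x = _superposed_flat(red.frames, model.reference_coords)
        cov = np.cov(x.T, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        k = model.n_modes
        np.testing.assert_allclose(model.eigenvalues, eig[:k], rtol=1e-8, atol=1e-12)

    def test_rigid_motion_invariance(self, toy_up, rng):
        ens, _ = syn.make_mode_trajectory(
            toy_up, [(_backbone_mode(toy_up, rng), 4.0)],
            n_frames=60, noise_sigma=0.1, seed=5,
        )
        theta = 1.1
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        rotated = Ensemble(
            topology=ens.topology,
            frames=[f @ rot.T + np.array([3.0, -2.0, 7.0]) for f in ens.frames],
        )
        m1 = fit_pc_model([ens], toy_up)
        m2 = fit_pc_model([rotated], toy_up)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, rtol=1e-6, atol=1e-9)


class TestProjection:
    @pytest.fixture
    def fitted(self, toy_up, rng):
        ens, truth = syn.make_mode_trajectory(
            toy_up, [(_backbone_mode(toy_up, rng), 9.0), (_backbone_mode(toy_up, rng), 4.0)],
            n_frames=500, noise_sigma=0.05, seed=33,
        )
        return ens, fit_pc_model([ens], toy_up)

    def test_mean_structure_projects_to_zero(self, fitted):
        ens, model = fitted
        mean_struct = model.topology.with_coords(model.mean_coords)
        series = project(
            Ensemble(topology=model.topology, frames=[model.mean_coords]),
            model, 0, backbone_only=False, superpose=False,
        )
        assert series.values[0] == pytest.approx(0.0, abs=1e-8)

    def test_mean_plus_mode_projects_to_amplitude(self, fitted):
        _, model = fitted
        a = 7.5
        shifted = model.mean_coords + a * model.eigenvectors[0].reshape(-1, 3)
        series = project(
            Ensemble(topology=model.topology, frames=[shifted]),
            model, 0, backbone_only=False, superpose=False,
        )
        assert series.values[0] == pytest.approx(a, abs=1e-8)

    def test_projection_variance_equals_eigenvalue(self, fitted):
        ens, model = fitted
        series = project(ens, model, 0)
        assert np.var(series.values) == pytest.approx(model.eigenvalues[0], rel=1e-6)

    def test_projections_uncorrelated(self, fitted):
        ens, model = fitted
        p1 = project(ens, model, 0).values
        p2 = project(ens, model, 1).values
        cov = np.mean((p1 - p1.mean()) * (p2 - p2.mean()))
        assert abs(cov) < 1e-6 * model.eigenvalues[0]

    def test_component_out_of_range(self, fitted):
        ens, model = fitted
        with pytest.raises(IndexError):
            project(ens, model, model.n_modes + 5)


class TestHistogram:
    def test_all_zero_values_single_bin(self):
        from ck1switch.pca import ProjectionSeries

        series = ProjectionSeries(system="s", component=0, values=np.zeros(10))
        out = histogram_projections(series, bin_width=1.0)
        assert out.counts.sum() == 10
        assert out.counts.max() == 10

    def test_symmetric_two_bins(self):
        from ck1switch.pca import ProjectionSeries

        values = np.array([-1.0] * 5 + [1.0] * 5)
        out = histogram_projections(
            ProjectionSeries(system="s", component=0, values=values), bin_width=1.0
        )
        assert out.counts.sum() == 10
        nonzero = out.counts[out.counts > 0]
        np.testing.assert_array_equal(nonzero, [5, 5])

    def test_gaussian_sd_recovered_from_binned_data(self, rng):
        from ck1switch.pca import ProjectionSeries

        sigma = 12.0
        values = rng.normal(0, sigma, size=5000)
        out = histogram_projections(
            ProjectionSeries(system="s", component=0, values=values), bin_width=2.0
        )
        centers = (out.bin_edges[:-1] + out.bin_edges[1:]) / 2
        mean = np.average(centers, weights=out.counts)
        sd = np.sqrt(np.average((centers - mean) ** 2, weights=out.counts))
        assert sd == pytest.approx(sigma, rel=0.10)

    def test_bad_bin_width(self):
        from ck1switch.pca import ProjectionSeries

        series = ProjectionSeries(system="s", component=0, values=np.ones(3))
        with pytest.raises(ValueError):
            histogram_projections(series, bin_width=0.0)


class TestEndpoints:
    @pytest.fixture
    def model(self, toy_up, rng):
        ens, _ = syn.make_mode_trajectory(
            toy_up, [(_backbone_mode(toy_up, rng), 9.0), (_backbone_mode(toy_up, rng), 4.0)],
            n_frames=200, noise_sigma=0.05, seed=44,
        )
        return fit_pc_model([ens], toy_up)

    def test_zero_amplitude_is_mean(self, model):
        plus, minus = mode_endpoints(model, 0, 0.0)
        np.testing.assert_allclose(plus.coords, model.mean_coords)
        np.testing.assert_allclose(minus.coords, model.mean_coords)

    def test_endpoints_project_to_amplitude(self, model):
        plus, minus = mode_endpoints(model, 0, 80.0)
        ens = Ensemble(topology=model.topology, frames=[plus.coords, minus.coords])
        series = project(ens, model, 0, backbone_only=False, superpose=False)
        np.testing.assert_allclose(series.values, [80.0, -80.0], atol=1e-8)

    def test_endpoints_orthogonal_to_other_components(self, model):
        plus, minus = mode_endpoints(model, 0, 80.0)
        ens = Ensemble(topology=model.topology, frames=[plus.coords, minus.coords])
        series = project(ens, model, 1, backbone_only=False, superpose=False)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-8)

    def test_midpoint_is_mean(self, model):
        plus, minus = mode_endpoints(model, 1, 60.0)
        np.testing.assert_allclose(
            (plus.coords + minus.coords) / 2, model.mean_coords, atol=1e-12
        )
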