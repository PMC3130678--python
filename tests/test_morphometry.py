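"""Procrustes superimposition, sliding, shape PCA and parallel analysis."""

import numpy as np
import pandas as pd
import pytest

import peakshift as pk
from peakshift.errors import (
    CurveDefinitionError,
    DegenerateShapeError,
    ShapeMismatchError,
)
from peakshift.morphometry import _center_scale, read_tps, write_tps

SQUARE = np.array([[1.0, 1.0], [-1.0, 1.0], [-1.0, -1.0], [1.0, -1.0]])
TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])


def _config(points, roles=None, species="sp", specimen="sp_1"):
    roles = np.zeros(len(points), int) if roles is None else np.asarray(roles)
    return pk.LandmarkConfiguration(points, roles, specimen_id=specimen, species_id=species)


def _rot(phi):
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, s], [-s, c]])


class TestCentroidSize:
    def test_unit_square(self):
        assert pk.centroid_size(_config(SQUARE)) == pytest.approx(2 * np.sqrt(2))

    def test_scaling_linearity(self):
        assert pk.centroid_size(_config(TRIANGLE * 3)) == pytest.approx(
            3 * pk.centroid_size(_config(TRIANGLE))
        )

    def test_translation_invariance(self):
        shifted = TRIANGLE + np.array([5.0, -7.0])
        assert pk.centroid_size(_config(shifted)) == pytest.approx(
            pk.centroid_size(_config(TRIANGLE))
        )

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateShapeError):
            pk.LandmarkConfiguration(
                np.zeros((4, 2)), np.zeros(4, int)
            )


class TestGPA:
    def test_identical_rotated_triangles_align(self):
        configs = [
            _config(TRIANGLE, species="a", specimen="a_1"),
            _config(TRIANGLE @ _rot(np.pi / 2), species="b", specimen="b_1"),
        ]
        aligned = pk.gpa(configs)
        d = np.sqrt(((aligned.shapes[0] - aligned.shapes[1]) ** 2).sum())
        assert d == pytest.approx(0.0, abs=1e-10)

    def test_consensus_normalized(self, rng):
        configs = [
            _config(rng.standard_normal((6, 2)), species=f"s{i}", specimen=f"s{i}_1")
            for i in range(8)
        ]
        aligned = pk.gpa(configs)
        assert np.allclose(aligned.consensus.mean(axis=0), 0, atol=1e-10)
        assert np.sqrt((aligned.consensus**2).sum()) == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_similarity_transforms(self, rng):
        base = [rng.standard_normal((7, 2)) for _ in range(6)]
        configs = [_config(b, species=f"s{i}", specimen=f"s{i}_1") for i, b in enumerate(base)]
        jittered = [
            _config(
                3.0 * (b @ _rot(rng.uniform(0, 2 * np.pi))) + rng.uniform(-9, 9, 2),
                species=f"s{i}", specimen=f"s{i}_1",
            )
            for i, b in enumerate(base)
        ]
        a1 = pk.gpa(configs).coordinates.to_numpy()
        a2 = pk.gpa(jittered).coordinates.to_numpy()
        assert np.abs(a1 - a2).max() < 1e-8

    def test_mixed_point_counts_raise(self):
        with pytest.raises(ShapeMismatchError):
            pk.gpa([_config(TRIANGLE), _config(SQUARE)])

    def test_species_averaging(self, rng):
        # two specimens per species scattered around distinct means
        means = {"a": TRIANGLE, "b": SQUARE[:3] * 1.5}
        configs = []
        for sp, m in means.items():
            for j in range(5):
                configs.append(
                    _config(m + rng.normal(0, 0.01, m.shape), species=sp,
                            specimen=f"{sp}_{j}")
                )
        aligned = pk.gpa(configs)
        assert list(aligned.coordinates.index) == ["a", "b"]
        assert aligned.centroid_sizes["b"] > aligned.centroid_sizes["a"]


class TestProcrustesDistance:
    def test_similarity_copy_is_zero(self, rng):
        shape = rng.standard_normal((5, 2))
        copy = 2.5 * (shape @ _rot(1.1)) + np.array([3.0, -1.0])
        assert pk.procrustes_distance(shape, copy) == pytest.approx(0.0, abs=1e-10)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = rng.standard_normal((2, 6, 2))
            assert pk.procrustes_distance(a, b) == pytest.approx(
                pk.procrustes_distance(b, a), abs=1e-12
            )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_rotation_scale_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal((2, 3, 2))
        d = pk.procrustes_distance(a, b)
        A, B = _center_scale(a), _center_scale(b)
        best = np.inf
        for phi in np.linspace(0, 2 * np.pi, 5000):
            Br = B @ _rot(phi)
            beta = (A * Br).sum()  # optimal scale given the rotation
            best = min(best, ((A - beta * Br) ** 2).sum())
        assert d == pytest.approx(np.sqrt(max(best, 0.0)), abs=1e-4)

    def test_mismatch_raises(self):
        with pytest.raises(ShapeMismatchError):
            pk.procrustes_distance(TRIANGLE, SQUARE)


class TestSliding:
    @staticmethod
    def _curve_configs(rng, n=6, k=9, noise=0.02):
        s = np.linspace(0, np.pi, k)
        base = np.column_stack([np.cos(s), np.sin(s)])
        roles = np.array([0] + [1] * (k - 2) + [0])
        return [
            pk.LandmarkConfiguration(
                base + rng.normal(0, noise, base.shape), roles,
                specimen_id=f"s{i}_1", species_id=f"s{i}",
            )
            for i in range(n)
        ], roles

    def test_fixed_point_on_identical_configurations(self):
        # every configuration equals the consensus, so each semilandmark
        # already minimizes its distance to the consensus: sliding is exact
        s = np.linspace(0, np.pi, 9)
        base = np.column_stack([np.cos(s), np.sin(s)])
        roles = np.array([0] + [1] * 7 + [0])
        configs = [
            pk.LandmarkConfiguration(base, roles, specimen_id=f"u{i}_1", species_id=f"u{i}")
            for i in range(5)
        ]
        aligned = pk.gpa(configs)
        slid = pk.slide_semilandmarks(aligned)
        assert np.abs(
            slid.coordinates.to_numpy() - aligned.coordinates.to_numpy()
        ).max() < 1e-12

    def test_single_pass_removes_tangent_displacement(self):
        # one point displaced purely along its neighbour chord, consensus
        # held fixed: the projection pass restores it exactly
        from peakshift.morphometry import _slide_pass

        s = np.linspace(0, np.pi, 9)
        base = np.column_stack([np.cos(s), np.sin(s)])
        tangent = base[5] - base[3]
        tangent /= np.linalg.norm(tangent)
        displaced = base.copy()
        displaced[4] += 0.05 * tangent
        shapes = displaced[None].copy()
        _slide_pass(shapes, base, np.array([4]))
        assert np.abs(shapes[0] - base).max() < 1e-12

    def test_pipeline_shrinks_tangent_displacement(self):
        # against a consensus dominated by undisplaced copies, the full
        # slide-and-resuperimpose loop removes nearly all the displacement
        s = np.linspace(0, np.pi, 9)
        base = np.column_stack([np.cos(s), np.sin(s)])
        roles = np.array([0] + [1] * 7 + [0])
        tangent = base[5] - base[3]
        tangent /= np.linalg.norm(tangent)
        displaced = base.copy()
        displaced[4] += 0.05 * tangent
        configs = [
            pk.LandmarkConfiguration(base, roles, specimen_id=f"u{i}_1", species_id=f"u{i}")
            for i in range(30)
        ] + [pk.LandmarkConfiguration(displaced, roles, specimen_id="d_1", species_id="d")]
        before = pk.gpa(configs)
        resid_before = np.sqrt(((before.shapes[-1] - before.consensus) ** 2).sum())
        slid = pk.gpa(configs, slide=True)
        resid_after = np.sqrt(((slid.shapes[-1] - slid.consensus) ** 2).sum())
        assert resid_after < resid_before / 50

    @pytest.mark.parametrize("seed", range(20))
    def test_never_increases_procrustes_ss(self, seed):
        rng = np.random.default_rng(seed)
        configs, _ = self._curve_configs(rng, n=5, noise=0.05)
        aligned = pk.gpa(configs)
        ss_before = float(((aligned.shapes - aligned.consensus) ** 2).sum())
        slid = pk.slide_semilandmarks(aligned)
        ss_after = float(((slid.shapes - slid.consensus) ** 2).sum())
        assert ss_after <= ss_before + 1e-12

    def test_boundary_semilandmark_raises(self, rng):
        roles = np.array([1, 0, 0, 0])
        cfg = [_config(rng.standard_normal((4, 2)), roles=roles)]
        aligned = pk.gpa(cfg)
        with pytest.raises(CurveDefinitionError):
            pk.slide_semilandmarks(aligned)


class TestShapePCA:
    def test_two_species_single_axis(self, rng):
        coords = pd.DataFrame(rng.standard_normal((2, 8)), index=["a", "b"])
        pcm = pk.shape_pca(coords)
        assert (pcm.eigenvalues > 1e-12).sum() == 1

    def test_eigenvalue_conservation(self, rng):
        coords = pd.DataFrame(rng.standard_normal((20, 10)))
        pcm = pk.shape_pca(coords)
        assert pcm.eigenvalues.sum() == pytest.approx(
            coords.var(axis=0, ddof=1).sum(), abs=1e-10
        )

    def test_reconstruction_identity(self, rng):
        coords = pd.DataFrame(rng.standard_normal((49, 12)))
        pcm = pk.shape_pca(coords)
        rebuilt = pcm.scores.to_numpy() @ pcm.eigenvectors.T + pcm.mean
        assert np.abs(rebuilt - coords.to_numpy()).max() < 1e-8


class TestParallelAnalysis:
    def test_null_data_retains_none(self):
        zero = 0
        for rep in range(20):
            r = np.random.default_rng(300 + rep)
            n = pk.parallel_analysis(
                r.standard_normal((100, 12)), n_reps=200, seed=400 + rep
            )
            zero += n == 0
        assert zero >= 18  # >= 90% of runs

    def test_two_planted_factors_recovered(self):
        two = 0
        for rep in range(20):
            r = np.random.default_rng(500 + rep)
            F = r.standard_normal((200, 2)) * 10
            L = r.standard_normal((2, 12))
            X = F @ L + r.standard_normal((200, 12))
            two += pk.parallel_analysis(X, n_reps=200, seed=600 + rep) == 2
        assert two >= 19  # >= 95% of runs

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((50, 8))
        a = pk.parallel_analysis(X, n_reps=150, seed=7)
        b = pk.parallel_analysis(X, n_reps=150, seed=7)
        assert a == b

    def test_bad_percentile_raises(self, rng):
        with pytest.raises(ValueError):
            pk.parallel_analysis(rng.standard_normal((20, 4)), percentile=1.5, seed=0)


class TestTPS:
    def test_roundtrip(self, tmp_path, rng):
        configs = [
            _config(rng.standard_normal((5, 2)), species="Artibeus",
                    specimen=f"Artibeus_{i}")
            for i in range(3)
        ]
        path = tmp_path / "shapes.tps"
        write_tps(configs, path)
        back = read_tps(path)
        assert len(back) == 3
        assert back[0].species_id == "Artibeus"
        assert np.allclose(back[1].points, configs[1].points, atol=1e-7)
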