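"""Spatial ICA, consensus clustering and component screening."""

import numpy as np
import pytest
from sklearn.decomposition import FastICA

from mfnc import decompose


def _skewed_maps(rng, n_comp, n_loc):
    """Sparse one-signed spatial patterns (super-Gaussian across locations)."""
    maps = np.zeros((n_comp, n_loc))
    block = n_loc // n_comp
    for i in range(n_comp):
        maps[i, i * block : i * block + block // 3] = 1.0 + rng.random(block // 3)
    return maps


@pytest.fixture()
def rank2_data():
    rng = np.random.default_rng(0)
    maps = _skewed_maps(rng, 2, 300)
    tcs = rng.standard_normal((2, 400)) ** 3  # independent super-Gaussian
    return maps, tcs, maps.T @ tcs


class TestSpatialICA:
    def test_rank1_identity(self):
        rng = np.random.default_rng(1)
        pattern = np.abs(rng.standard_normal(120)) ** 2
        tc = rng.standard_normal(200)
        data = np.outer(pattern, tc)
        cs = decompose.spatial_ica(data, seed=0)
        assert cs.n_components == 1
        got = cs.spatial_maps[0]
        # whitening centers across locations, so compare mean-free patterns
        pc = pattern - pattern.mean()
        c = abs(np.dot(got - got.mean(), pc)) / (
            np.linalg.norm(got - got.mean()) * np.linalg.norm(pc)
        )
        assert c > 0.999

    def test_two_orthogonal_patterns_recovered(self, rank2_data):
        maps, tcs, data = rank2_data
        cs = decompose.spatial_ica(data, mode="symmetric", seed=0)
        M = cs.spatial_maps - cs.spatial_maps.mean(axis=1, keepdims=True)
        M /= np.linalg.norm(M, axis=1, keepdims=True)
        T = maps - maps.mean(axis=1, keepdims=True)
        T /= np.linalg.norm(T, axis=1, keepdims=True)
        C = np.abs(M @ T.T)
        assert C.max(axis=0).min() > 0.99

    def test_matches_sklearn_fastica_components(self):
        # dual route: on symmetric heavy-tailed spatial sources (where the
        # logcosh contrast is appropriate for both implementations) the
        # recovered maps must agree with sklearn's FastICA
        rng = np.random.default_rng(5)
        maps = rng.standard_t(df=3, size=(2, 400))
        tcs = rng.standard_normal((2, 500))
        data = maps.T @ tcs
        ours = decompose.spatial_ica(
            data, mode="symmetric", seed=0, fun="logcosh"
        ).spatial_maps
        ours = ours - ours.mean(axis=1, keepdims=True)
        ours /= np.linalg.norm(ours, axis=1, keepdims=True)
        sk = FastICA(n_components=2, random_state=0, whiten="unit-variance", max_iter=2000)
        theirs = sk.fit_transform(data).T  # (2, n_loc) spatial sources
        theirs = theirs - theirs.mean(axis=1, keepdims=True)
        theirs /= np.linalg.norm(theirs, axis=1, keepdims=True)
        C = np.abs(ours @ theirs.T)
        assert C.max(axis=0).min() > 0.98

    def test_maps_unit_norm_and_sign_convention(self, rank2_data):
        _, _, data = rank2_data
        cs = decompose.spatial_ica(data, mode="symmetric", seed=0)
        norms = np.linalg.norm(cs.spatial_maps, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)
        for row in cs.spatial_maps:
            assert row[np.argmax(np.abs(row))] > 0

    def test_reconstruction_of_noiseless_low_rank_data(self, rank2_data):
        _, _, data = rank2_data
        cs = decompose.spatial_ica(data, mode="symmetric", seed=0)
        # maps are mean-free across locations; evaluate on centered data
        dc = data - data.mean(axis=0, keepdims=True)
        recon = cs.spatial_maps.T @ decompose._fit_time_courses(cs.spatial_maps, dc)
        explained = 1 - np.linalg.norm(dc - recon) ** 2 / np.linalg.norm(dc) ** 2
        assert explained > 0.99

    def test_nonfinite_data_rejected(self):
        with pytest.raises(ValueError):
            decompose.spatial_ica(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestConsensus:
    def test_identical_runs_reproduce_components(self, rank2_data):
        _, _, data = rank2_data
        run = decompose.spatial_ica(data, mode="symmetric", seed=0)
        cons = decompose.consensus_components([run] * 20, data=data)
        assert cons.n_components == run.n_components
        C = np.abs(cons.spatial_maps @ run.spatial_maps.T)
        assert C.max(axis=0).min() > 0.999

    def test_permutation_and_sign_invariance(self, rank2_data):
        _, _, data = rank2_data
        runs = [decompose.spatial_ica(data, mode="symmetric", seed=s) for s in range(6)]
        cons_a = decompose.consensus_components(runs, data=data)
        rng = np.random.default_rng(3)
        shuffled = []
        for r in runs[::-1]:
            perm = rng.permutation(r.n_components)
            signs = rng.choice([-1.0, 1.0], r.n_components)
            shuffled.append(
                decompose.ComponentSet(
                    spatial_maps=decompose._canonicalize(signs[:, None] * r.spatial_maps[perm]),
                    time_courses=r.time_courses[perm],
                )
            )
        cons_b = decompose.consensus_components(shuffled, data=data)
        assert cons_a.n_components == cons_b.n_components
        C = np.abs(cons_a.spatial_maps @ cons_b.spatial_maps.T)
        assert C.max(axis=0).min() > 0.999

    def test_min_occurrence_filters_rare_components(self, rank2_data):
        _, _, data = rank2_data
        runs = [decompose.spatial_ica(data, mode="symmetric", seed=s) for s in range(4)]
        # adulterate one run with a junk component
        junk = np.zeros(data.shape[0])
        junk[::7] = 1.0
        r0 = runs[0]
        runs[0] = decompose.ComponentSet(
            spatial_maps=decompose._canonicalize(np.vstack([r0.spatial_maps, junk])),
            time_courses=np.vstack([r0.time_courses, np.zeros(data.shape[1])]),
        )
        cons = decompose.consensus_components(runs, min_occurrence=0.5, data=data)
        assert cons.n_components == 2

    def test_requires_two_runs(self, rank2_data):
        _, _, data = rank2_data
        run = decompose.spatial_ica(data, mode="symmetric", seed=0)
        with pytest.raises(ValueError):
            decompose.consensus_components([run])


class TestScreening:
    def test_empty_exclusion_is_identity(self, rank2_data):
        _, _, data = rank2_data
        cs = decompose.spatial_ica(data, mode="symmetric", seed=0)
        out = decompose.screen_components(cs, [])
        np.testing.assert_array_equal(out.spatial_maps, cs.spatial_maps)

    def test_exclusion_count(self, rank2_data):
        _, _, data = rank2_data
        cs = decompose.spatial_ica(data, mode="symmetric", seed=0)
        out = decompose.screen_components(cs, [0])
        assert out.n_components == cs.n_components - 1

    def test_out_of_range_index(self, rank2_data):
        _, _, data = rank2_data
        cs = decompose.spatial_ica(data, mode="symmetric", seed=0)
        with pytest.raises(IndexError):
            decompose.screen_components(cs, [99])


class TestActivationMap:
    def test_z_threshold_masks_background(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal(1000)
        m[:10] += 30.0
        z = decompose.activation_zmap(m, z_threshold=3.0)
        assert np.all(z[:10] != 0)
        assert np.count_nonzero(z[10:]) == 0
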