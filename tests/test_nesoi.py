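"""Empirical-Bayes source inversion and cross-modal network matching."""

import numpy as np
import pytest

from conftest import assert_free_energy_monotone
from mfnc import decompose, nesoi


@pytest.fixture(scope="module")
def true_priors(geometry):
    """Priors built from the ground-truth fMRI-visible maps (S1, S3, S4)."""
    disc, _, _ = geometry
    prof = disc.source_profiles()
    comp = decompose.ComponentSet(prof[[0, 2, 3]], np.zeros((3, 1)), modality="fmri")
    return nesoi.build_prior_components(comp, disc, 3.0)


class TestPriorConstruction:
    def test_fmri_supports_match_truth_patches(self, geometry, true_priors):
        disc, _, _ = geometry
        fmri = [p for p in true_priors if p.label != nesoi.MSP_LABEL]
        sizes = sorted(p.coverage.size for p in fmri)
        assert sizes == [32, 90, 100]
        for p, src in zip(fmri, (0, 2, 3)):
            assert set(p.coverage) == set(disc.per_source_masks[src])

    def test_msp_patches_cover_complement_only(self, geometry, true_priors):
        disc, _, _ = geometry
        covered = set()
        for p in true_priors:
            if p.label != nesoi.MSP_LABEL:
                covered |= set(p.coverage.tolist())
        centres = [int(np.argmax(p.factor[:, 0])) for p in true_priors if p.label == nesoi.MSP_LABEL]
        assert centres and not (set(centres) & covered)

    def test_constant_map_dropped(self, geometry):
        disc, _, _ = geometry
        maps = np.zeros((1, disc.n_dipoles))
        comp = decompose.ComponentSet(maps, np.zeros((1, 1)))
        priors = nesoi.build_prior_components(comp, disc, 3.0)
        assert all(p.label == nesoi.MSP_LABEL for p in priors)

    def test_grid_mismatch_rejected(self, geometry):
        disc, _, _ = geometry
        comp = decompose.ComponentSet(np.ones((1, 10)), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            nesoi.build_prior_components(comp, disc)


class TestReML:
    def test_zero_topography_gives_zero_posterior(self, geometry, true_priors):
        _, _, lf = geometry
        r = nesoi.reml_invert(np.zeros(62), lf, true_priors)
        assert np.all(r.posterior_mean == 0)
        assert np.all(r.gamma == 0)

    @pytest.mark.parametrize("src,label_size", [(0, 90), (2, 32)])
    def test_single_prior_self_consistency(self, geometry, true_priors, src, label_size):
        """A topography generated from one prior's covariance must load on it."""
        disc, _, lf = geometry
        prof = disc.source_profiles()
        Y = lf.gain @ prof[src]
        r = nesoi.reml_invert(Y, lf, true_priors)
        assert_free_energy_monotone(r)
        labs, con = r.contributions_by_label()
        winner = labs[int(np.argmax(con))]
        expected = {0: "fMRI-0", 2: "fMRI-1"}[src]
        assert winner == expected
        assert con.max() > 0.9

    def test_eeg_only_pattern_goes_to_msp(self, geometry, true_priors):
        disc, _, lf = geometry
        prof = disc.source_profiles()
        Y = lf.gain @ prof[1]  # S2 has no fMRI prior
        r = nesoi.reml_invert(Y, lf, true_priors)
        assert_free_energy_monotone(r)
        labs, con = r.contributions_by_label()
        assert labs[int(np.argmax(con))] == nesoi.MSP_LABEL

    def test_scale_equivariance(self, geometry, true_priors):
        disc, _, lf = geometry
        prof = disc.source_profiles()
        Y = lf.gain @ prof[0]
        r1 = nesoi.reml_invert(Y, lf, true_priors)
        r2 = nesoi.reml_invert(5.0 * Y, lf, true_priors)
        scale = np.abs(r1.posterior_mean).max()
        np.testing.assert_allclose(
            r2.posterior_mean, 5.0 * r1.posterior_mean, atol=1e-6 * scale
        )
        # hyperparameters rescale consistently: the normalized contribution
        # profile is scale-free
        np.testing.assert_allclose(
            r2.normalized_contributions(), r1.normalized_contributions(), atol=0.05
        )

    def test_dimension_mismatch_rejected(self, geometry, true_priors):
        _, _, lf = geometry
        with pytest.raises(ValueError):
            nesoi.reml_invert(np.ones(10), lf, true_priors)

    def test_posterior_support_within_true_patch(self, geometry, true_priors):
        disc, _, lf = geometry
        prof = disc.source_profiles()
        Y = lf.gain @ prof[0]
        r = nesoi.reml_invert(Y, lf, true_priors)
        _, support = nesoi.source_map(r, quantile=0.01)
        assert set(support).issubset(set(disc.per_source_masks[0]))


class TestSourceMap:
    def test_quantile_keeps_ceil_fraction(self):
        r = nesoi.ReMLResult(
            gamma=np.ones(1), gamma_sensor=1.0, free_energy_trace=np.zeros(1),
            posterior_mean=np.arange(100.0), converged=True,
        )
        _, support = nesoi.source_map(r, quantile=0.01)
        assert support.size == 1 and support[0] == 99

    def test_uniform_magnitudes_resolved_by_index_order(self):
        r = nesoi.ReMLResult(
            gamma=np.ones(1), gamma_sensor=1.0, free_energy_trace=np.zeros(1),
            posterior_mean=np.ones(200), converged=True,
        )
        _, support = nesoi.source_map(r, quantile=0.01)
        np.testing.assert_array_equal(support, [0, 1])

    def test_full_quantile_returns_everything(self):
        r = nesoi.ReMLResult(
            gamma=np.ones(1), gamma_sensor=1.0, free_energy_trace=np.zeros(1),
            posterior_mean=np.arange(10.0), converged=True,
        )
        values, support = nesoi.source_map(r, quantile=1.0)
        assert support.size == 10


class TestMatching:
    def _result(self, labels, rho):
        return nesoi.ReMLResult(
            gamma=np.asarray(rho, dtype=float), gamma_sensor=0.1,
            free_energy_trace=np.zeros(1), posterior_mean=np.zeros(4),
            converged=True, prior_labels=labels,
            sensor_traces=np.ones(len(labels)),
        )

    def test_argmax_matching(self):
        labels = ["fMRI-0", "fMRI-1", "MSP"]
        priors = [nesoi.PriorComponent(l, "diag", np.arange(1), np.ones(1)) for l in labels]
        table = nesoi.match_networks([self._result(labels, [0.8, 0.1, 0.1])], priors)
        assert table.match == ["fMRI-0"]
        assert table.common == [(0, 0)]
        assert table.fmri_specific == [1]

    def test_exact_tie_breaks_to_msp(self):
        labels = ["fMRI-0", "MSP"]
        priors = [nesoi.PriorComponent(l, "diag", np.arange(1), np.ones(1)) for l in labels]
        table = nesoi.match_networks([self._result(labels, [0.5, 0.5])], priors)
        assert table.match == ["MSP"]
        assert table.eeg_specific == [0]

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            nesoi.match_networks([], [])
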