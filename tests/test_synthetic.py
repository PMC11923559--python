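"""Tests for the synthetic cohort generator."""

import numpy as np
import pytest
from scipy import stats

from cpmnet.connectome import edge_index, edge_pairs
from cpmnet.exceptions import InfeasibleSpecError
from cpmnet.parcellation import default_parcellation
from cpmnet.synthetic import (
    CohortSpec,
    baseline_matrix,
    generate_cohort,
    nearest_correlation,
    random_edge_sets,
    target_correlation_matrix,
    truth_mask,
)


class TestCohortSpec:
    def test_overlapping_planted_edges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            CohortSpec(n_subjects=8, n_nodes=10,
                       positive_edges=[(0, 1)], negative_edges=[(0, 1)])

    @pytest.mark.parametrize("edge", [(1, 0), (0, 10), (3, 3)])
    def test_invalid_edge_ordering_rejected(self, edge):
        with pytest.raises(ValueError, match="i < j"):
            CohortSpec(n_subjects=8, n_nodes=10, positive_edges=[edge])

    def test_effect_envelope_enforced(self):
        with pytest.raises(ValueError, match="below 1"):
            CohortSpec(n_subjects=8, n_nodes=10,
                       baseline_correlation=0.3, effect_size=0.4)


class TestGenerateCohort:
    def test_shape_contract(self):
        spec = CohortSpec(n_subjects=8, n_nodes=10, n_runs=2,
                          frames_per_run=120, dummy_frames=4)
        cohort = generate_cohort(spec)
        assert len(cohort.subjects) == 8
        assert len(cohort.phenotypes) == 8
        for subj in cohort.subjects:
            assert len(subj.runs) == 2
            for sig, fd in zip(subj.runs, subj.fd):
                assert sig.shape == (120, 10)
                assert fd.shape == (120,)

    def test_deterministic_from_seed(self):
        spec = CohortSpec(n_subjects=4, n_nodes=12, frames_per_run=40, seed=99)
        a, b = generate_cohort(spec), generate_cohort(spec)
        for sa, sb in zip(a.subjects, b.subjects):
            for ra, rb in zip(sa.runs, sb.runs):
                np.testing.assert_array_equal(ra, rb)
            for fa, fb in zip(sa.fd, sb.fd):
                np.testing.assert_array_equal(fa, fb)
        assert a.phenotypes == b.phenotypes

    def test_fd_baseline_below_threshold_with_spikes_above(self):
        spec = CohortSpec(n_subjects=3, n_nodes=10, frames_per_run=200,
                          fd_spike_rate=0.1, fd_spike_magnitude_mm=0.6, seed=2)
        cohort = generate_cohort(spec)
        fd = np.concatenate([f for s in cohort.subjects for f in s.fd])
        spikes = fd > 0.2
        assert spikes.any()
        np.testing.assert_allclose(fd[spikes], 0.6)
        assert fd[~spikes].max() < 0.2

    def test_empirical_correlation_converges_to_target(self):
        """Sampled frames reproduce the subject's target matrix as frames grow."""
        spec = CohortSpec(n_subjects=1, n_nodes=15, n_runs=1,
                          frames_per_run=2004, dummy_frames=4,
                          fd_spike_rate=0.0, seed=5,
                          positive_edges=[(0, 5), (2, 9)], effect_size=0.2)
        cohort = generate_cohort(spec)
        subj = cohort.subjects[0]
        emp = np.corrcoef(subj.runs[0][4:], rowvar=False)
        target = cohort.target_matrix(subj.subject_id)
        assert np.abs(emp - target).max() < 0.1  # ~4.5 SE at 2000 frames

    def test_null_effect_gives_null_edge_phenotype_association(self):
        """With effect_size=0 the per-edge Spearman p-values are uniform.

        ~200 edges at n=64: the fraction with p<0.05 must sit inside the
        binomial 95% CI around 0.05 (edges within a cohort are not fully
        independent, so the fraction is averaged over cohorts).
        """
        fracs = []
        for seed in range(5):
            spec = CohortSpec(n_subjects=64, n_nodes=21, n_runs=1,
                              frames_per_run=104, effect_size=0.0, seed=seed)
            cohort = generate_cohort(spec)
            y = cohort.phenotype_vector()
            fc = np.stack([
                np.corrcoef(s.runs[0][4:], rowvar=False)[edge_pairs(21)]
                for s in cohort.subjects
            ])
            pvals = np.array([stats.spearmanr(fc[:, e], y).pvalue
                              for e in range(fc.shape[1])])
            fracs.append((pvals < 0.05).mean())
        n_edges = 21 * 20 // 2
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_edges)
        assert abs(np.mean(fracs) - 0.05) < half_width

    def test_planted_positive_edges_track_phenotype_quartiles(self):
        """Top-quartile-phenotype subjects show higher planted-edge FC."""
        parc = default_parcellation(30)
        pos, _ = random_edge_sets(30, 30, 0, seed=3, parcellation=parc)
        spec = CohortSpec(n_subjects=64, n_nodes=30, n_runs=1,
                          frames_per_run=404, positive_edges=pos,
                          effect_size=0.3, fd_spike_rate=0.0, seed=3)
        cohort = generate_cohort(spec, parc)
        y = cohort.phenotype_vector()
        iu, ju = zip(*pos)
        fc = np.array([
            np.corrcoef(s.runs[0][4:], rowvar=False)[list(iu), list(ju)].mean()
            for s in cohort.subjects
        ])
        top = fc[y >= np.quantile(y, 0.75)].mean()
        bottom = fc[y <= np.quantile(y, 0.25)].mean()
        assert top > bottom


class TestTargetMatrix:
    def test_infeasible_triangle_signalled(self):
        """A +,+,− triangle of large planted correlations has no PSD realisation."""
        spec = CohortSpec(n_subjects=4, n_nodes=3, baseline_correlation=0.0,
                          positive_edges=[(0, 1), (0, 2)],
                          negative_edges=[(1, 2)], effect_size=0.45)
        base = baseline_matrix(spec, default_parcellation(3))
        with pytest.raises(InfeasibleSpecError):
            target_correlation_matrix(spec, 1.5, base)

    def test_projection_matches_reference_implementation(self):
        """Our Higham projection agrees with statsmodels' corr_nearest."""
        from statsmodels.stats.correlation_tools import corr_nearest

        rng = np.random.default_rng(0)
        a = rng.uniform(-0.9, 0.9, (8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        ours = nearest_correlation(a)
        ref = corr_nearest(a, threshold=1e-8, n_fact=200)
        assert np.linalg.eigvalsh(ours)[0] > -1e-12
        np.testing.assert_allclose(np.diag(ours), 1.0, atol=1e-12)
        assert np.abs(ours - ref).max() < 1e-3


class TestTruthMask:
    def test_single_edge_canonical_index(self):
        spec = CohortSpec(n_subjects=4, n_nodes=3, positive_edges=[(0, 1)])
        pos, neg = truth_mask(spec)
        np.testing.assert_array_equal(pos.indices, [edge_index(0, 1, 3)])
        assert len(neg) == 0

    def test_empty_planted_sets(self):
        spec = CohortSpec(n_subjects=4, n_nodes=5)
        pos, neg = truth_mask(spec)
        assert len(pos) == 0 and len(neg) == 0

    def test_cardinalities_match_planted_sets(self, small_parcellation):
        pos_e, neg_e = random_edge_sets(20, 4, 6, seed=0,
                                        parcellation=small_parcellation)
        spec = CohortSpec(n_subjects=4, n_nodes=20,
                          positive_edges=pos_e, negative_edges=neg_e)
        pos, neg = truth_mask(spec)
        assert len(pos) == 4 and len(neg) == 6


class TestRandomEdgeSets:
    def test_disjoint_and_degree_capped(self, small_parcellation):
        pos, neg = random_edge_sets(20, 8, 8, seed=5,
                                    parcellation=small_parcellation)
        assert not set(pos) & set(neg)
        degree = np.zeros(20, dtype=int)
        for i, j in pos + neg:
            degree[i] += 1
            degree[j] += 1
        assert degree.max() <= 4  # cap 2 with gentle relaxation

    def test_across_network_only_with_parcellation(self, small_parcellation):
        nets = small_parcellation["network"].to_numpy()
        pos, neg = random_edge_sets(20, 5, 5, seed=8,
                                    parcellation=small_parcellation)
        for i, j in pos + neg:
            assert nets[i] != nets[j]
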