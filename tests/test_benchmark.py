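import numpy as np
import pytest

from sigassign import (
    ActivityVector,
    SimulationConfig,
    score_assignments,
    simulate_catalog,
    synthetic_signatures,
)


def _small_cfg(**kw):
    base = dict(
        n_groups=2,
        samples_per_group=5,
        n_ground_truth=6,
        signatures_per_group=3,
        seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSyntheticSignatures:
    def test_columns_are_pmfs(self, sbs96):
        sigs = synthetic_signatures(10, sbs96, seed=3)
        assert np.all(sigs.probs >= 0)
        np.testing.assert_allclose(sigs.probs.sum(axis=0), 1.0, atol=1e-9)

    def test_separation_constraint_holds(self, sigs20_separated):
        P = sigs20_separated.probs
        norms = np.linalg.norm(P, axis=0)
        G = (P / norms).T @ (P / norms)
        np.fill_diagonal(G, 0.0)
        assert G.max() <= 0.3 + 1e-12


class TestSimulateCatalog:
    def test_total_conservation_at_zero_noise(self, sigs6):
        cfg = _small_cfg(n_ground_truth=4, signatures_per_group=1,
                         activity_bounds=(1000.0, 1000.0))
        cat, truths = simulate_catalog(sigs6, cfg)
        for j, t in enumerate(truths):
            assert cat.counts[:, j].sum() == t.total()
            assert t.total() == 1000

    def test_same_seed_reproduces_catalog(self, sigs6):
        cfg = _small_cfg()
        cat1, tr1 = simulate_catalog(sigs6, cfg)
        cat2, tr2 = simulate_catalog(sigs6, cfg)
        np.testing.assert_array_equal(cat1.counts, cat2.counts)
        for a, b in zip(tr1, tr2):
            assert a.as_dict() == b.as_dict()

    def test_noise_bounds_validated(self, sigs6):
        with pytest.raises(ValueError, match="noise"):
            SimulationConfig(noise_level=1.0)
        with pytest.raises(ValueError, match="noise"):
            SimulationConfig(noise_level=-0.1)

    def test_channel_means_proportional_to_signature(self, sbs96):
        """Multinomial law of large numbers: averaged over many replicates,
        per-channel counts of a single-signature sample track the signature's
        probabilities within 3 standard errors."""
        sigs = synthetic_signatures(2, sbs96, seed=5, concentration=0.5)
        n_rep, activity = 500, 400
        cfg = SimulationConfig(
            n_groups=1, samples_per_group=n_rep, n_ground_truth=1,
            signatures_per_group=1, activity_bounds=(activity, activity), seed=9,
        )
        cat, truths = simulate_catalog(sigs, cfg)
        sig_id = truths[0].signature_ids[0]
        p = sigs.column(sig_id)
        mean = cat.counts.mean(axis=1)
        se = np.sqrt(activity * p * (1 - p) / n_rep)
        ok = np.abs(mean - activity * p) <= 3 * np.maximum(se, 1e-9) + 1e-9
        # a few of 96 channels may exceed 3 SE by chance
        assert ok.mean() > 0.95

    def test_noise_perturbs_within_bounds(self, sigs6):
        cfg0 = _small_cfg(noise_level=0.0)
        cfgn = _small_cfg(noise_level=0.10)
        cat0, _ = simulate_catalog(sigs6, cfg0)
        catn, _ = simulate_catalog(sigs6, cfgn)
        # same seed: same pre-noise counts, so each channel moves by at most
        # 10% plus rounding
        diff = np.abs(catn.counts - cat0.counts)
        assert np.all(diff <= 0.10 * cat0.counts + 0.5 + 1e-9)


class TestScoring:
    def test_scoring_ground_truth_against_itself_is_perfect(self, sigs6):
        cfg = _small_cfg()
        cat, truths = simulate_catalog(sigs6, cfg)
        res = score_assignments(truths, truths, sigs6.signature_ids, cat.sample_ids)
        assert res.mean_precision == 1.0
        assert res.mean_sensitivity == 1.0
        assert res.mean_f1 == 1.0

    def test_shuffled_labels_score_near_chance(self, sigs20_separated, rng):
        """Permuting which signatures are called 'truth' should collapse the
        score to the hypergeometric chance level."""
        sigs = sigs20_separated
        cfg = SimulationConfig(
            n_groups=4, samples_per_group=25, n_ground_truth=20,
            signatures_per_group=3, seed=13,
        )
        cat, truths = simulate_catalog(sigs, cfg)
        ids = list(sigs.signature_ids)
        shuffled = []
        for t in truths:
            pick = rng.choice(len(ids), size=len(t.signature_ids), replace=False)
            shuffled.append(
                ActivityVector(tuple(ids[i] for i in pick), t.activities)
            )
        res = score_assignments(shuffled, truths, sigs.signature_ids, cat.sample_ids)
        # permutation oracle: E[TP] for 3 draws from 20 with 3 truly active
        k, n, K = 3, 20, 3
        expected_tp = k * K / n
        expected_precision = expected_tp / k
        assert res.mean_precision == pytest.approx(expected_precision, abs=0.08)
        assert res.mean_sensitivity == pytest.approx(expected_tp / K, abs=0.08)


class TestEngineOnSimulatedCohorts:
    def test_fit_error_envelope_at_zero_noise(self, sigs20_separated):
        """Noise-free samples with activities >= 100 from signatures present
        in the reference fit with relative error at most the addition
        threshold (no 0.05-sized component can remain unexplained)."""
        from sigassign import assign_cohort

        cfg = SimulationConfig(
            n_groups=3, samples_per_group=10, n_ground_truth=9,
            signatures_per_group=3, activity_bounds=(100.0, 5000.0), seed=19,
        )
        cat, _ = simulate_catalog(sigs20_separated, cfg)
        results = assign_cohort(cat, sigs20_separated)
        assert max(r.relative_error for r in results) <= 0.05 + 1e-9

    def test_mean_f1_does_not_improve_with_noise(self, sbs96):
        """Statistical trend on matched seeds over 100 samples: adding 10%
        channel noise must not raise mean F1 (small stochastic slack)."""
        from sigassign import run_benchmark

        sigs = synthetic_signatures(30, sbs96, seed=23)
        f1 = {}
        for noise in (0.0, 0.10):
            cfg = SimulationConfig(
                n_groups=5, samples_per_group=20, n_ground_truth=12,
                signatures_per_group=3, noise_level=noise, seed=29,
            )
            cat, truths = simulate_catalog(sigs, cfg)
            f1[noise] = run_benchmark(sigs, cat, truths).mean_f1
        assert f1[0.10] <= f1[0.0] + 0.02
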