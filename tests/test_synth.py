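import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import metadfc as m
from metadfc.atlas import link_index
from metadfc.mc import compute_dfc_stream, compute_mc, partition_mc, static_fc
from metadfc.states import fit_states, run_lengths, standardize_and_concatenate
from metadfc.synth import (
    GRADED_AGREEMENT,
    GRADED_SHAPES,
    BoldSession,
    StateGenConfig,
    _renewal_gate,
)
from metadfc.temporal import burstiness, interval_decomposition


class TestTwoZoneModel:
    def test_default_has_four_states(self, two_zone_cfg):
        assert two_zone_cfg.n_states == 4
        assert two_zone_cfg.n_regions == 16
        assert np.allclose(two_zone_cfg.transition_matrix.sum(axis=1), 1.0)

    def test_equal_sync_levels_degenerate(self):
        cfg = m.make_default_two_zone_model(sync_high=0.3, sync_low=0.3)
        for k in range(1, 4):
            assert np.allclose(cfg.covariances[0], cfg.covariances[k])

    def test_high_sync_states_have_denser_zone1_block(self):
        cfg = m.make_default_two_zone_model(sync_high=0.6, sync_low=0.2)
        z1 = cfg.atlas.zone_indices("I")
        off = ~np.eye(len(z1), dtype=bool)

        def z1_mean(k):
            return cfg.covariances[k][np.ix_(z1, z1)][off].mean()

        # states 1 and 4 are the high-synchronization states
        assert min(z1_mean(0), z1_mean(3)) > max(z1_mean(1), z1_mean(2))

    def test_invalid_sync_raises(self):
        with pytest.raises(ValueError):
            m.make_default_two_zone_model(sync_high=0.2, sync_low=0.4)

    def test_non_psd_covariance_names_state(self):
        cfg = m.make_default_two_zone_model()
        bad = cfg.covariances.copy()
        bad[2] = np.full_like(bad[2], 0.9)
        np.fill_diagonal(bad[2], 0.1)
        with pytest.raises(ValueError, match="state 3"):
            StateGenConfig(cfg.centroids, bad, cfg.transition_matrix, 3.0, cfg.atlas)


class TestStateSequence:
    def test_identity_transition_matrix_freezes_state(self, two_zone_cfg):
        cfg = StateGenConfig(
            two_zone_cfg.centroids,
            two_zone_cfg.covariances,
            np.eye(4),
            1e9,
            two_zone_cfg.atlas,
        )
        labels = m.generate_state_sequence(cfg, 500, seed=0)
        assert np.unique(labels).size == 1

    def test_mean_dwell_matches_chain_expectation(self, two_zone_cfg):
        labels = m.generate_state_sequence(two_zone_cfg, 100_000, seed=1)
        _, lens = run_lengths(labels)
        assert abs(lens.mean() - two_zone_cfg.dwell_mean) / two_zone_cfg.dwell_mean < 0.02

    def test_seed_reproducibility(self, two_zone_cfg):
        a = m.generate_state_sequence(two_zone_cfg, 1000, seed=5)
        b = m.generate_state_sequence(two_zone_cfg, 1000, seed=5)
        assert np.array_equal(a, b)

    def test_invalid_transition_matrix_rejected(self, two_zone_cfg):
        bad = np.full((4, 4), 0.5)
        with pytest.raises(ValueError):
            StateGenConfig(
                two_zone_cfg.centroids, two_zone_cfg.covariances, bad, 3.0,
                two_zone_cfg.atlas,
            )


class TestBoldCohort:
    def test_cluster_recovery_on_default_model(self, default_cohort, fitted_state_model):
        _, truths = default_cohort
        _, model = fitted_state_model
        ari = adjusted_rand_score(
            np.concatenate(truths), np.concatenate(model.labels)
        )
        assert ari > 0.9

    def test_zero_covariance_gives_exact_recovery(self, two_zone_cfg):
        cfg = StateGenConfig(
            two_zone_cfg.centroids,
            np.zeros_like(two_zone_cfg.covariances),
            two_zone_cfg.transition_matrix,
            3.0,
            two_zone_cfg.atlas,
        )
        sessions, truths = m.generate_bold_cohort(cfg, 2, 200, seed=0)
        # noiseless frames: each frame equals its state's centroid exactly
        frames = np.hstack([s.data for s in sessions]).T
        dists = np.linalg.norm(frames[:, None, :] - cfg.centroids[None], axis=2)
        recovered = dists.argmin(axis=1) + 1
        assert np.array_equal(recovered, np.concatenate(truths))

    def test_per_state_fc_converges_to_implied_correlation(self, two_zone_cfg):
        sessions, truths = m.generate_bold_cohort(two_zone_cfg, 1, 60_000, seed=4)
        x = sessions[0].data.T
        labels = truths[0]
        for k in range(4):
            emp = np.corrcoef(x[labels == k + 1].T)
            implied = two_zone_cfg.covariances[k]  # unit-variance construction
            assert np.abs(emp - implied).max() < 0.05

    def test_reproducible_under_seed(self, two_zone_cfg):
        a, _ = m.generate_bold_cohort(two_zone_cfg, 2, 50, seed=9)
        b, _ = m.generate_bold_cohort(two_zone_cfg, 2, 50, seed=9)
        assert np.array_equal(a[0].data, b[0].data)

    def test_session_validation(self):
        with pytest.raises(ValueError):
            BoldSession("s", "SYN", 2.0, np.array([[1.0, np.nan], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            BoldSession("s", "BAD", 2.0, np.zeros((2, 5)))


class TestBinaryTrains:
    def test_periodic_train_is_antiperiodic_burstiness(self):
        train = m.generate_binary_train(
            "periodic", 200, {"mean_duration": 4, "mean_gap": 4}, seed=0
        )
        epochs, gaps = interval_decomposition(train)
        assert set(epochs[:-1]) == {4}
        assert burstiness(epochs) == -1.0

    def test_poisson_epochs_near_zero_burstiness(self):
        # measured on the duration law itself at large n
        rng = np.random.default_rng(0)
        durations = np.maximum(1, np.rint(rng.exponential(10, 100_000)))
        assert abs(burstiness(durations)) < 0.02

    def test_bursty_exceeds_poisson_at_matched_mean(self):
        deltas = []
        for seed in range(20):
            b = m.generate_binary_train(
                "bursty", 5000, {"mean_duration": 6, "mean_gap": 6}, seed=seed
            )
            p = m.generate_binary_train(
                "poisson", 5000, {"mean_duration": 6, "mean_gap": 6}, seed=seed
            )
            deltas.append(
                burstiness(interval_decomposition(b)[0])
                - burstiness(interval_decomposition(p)[0])
            )
        assert np.median(deltas) > 0

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            m.generate_binary_train("periodic", 10, {"mean_duration": 20})
        with pytest.raises(ValueError):
            m.generate_binary_train("periodic", 1, {})
        with pytest.raises(ValueError):
            m.generate_binary_train("weird", 100, {})


class TestEntangled:
    def test_shared_modulator_entangles_root_sharing_dimers(self, atlas):
        cfg = m.make_default_entangled_model(
            n_modulators=1, leaves_per_root=2, depth=0.65
        )
        sessions, truth = m.generate_entangled_bold(cfg, 1, 2000, seed=3)
        mc = compute_mc(compute_dfc_stream(sessions[0], omega=5), atlas)
        fc = static_fc(sessions[0])
        lidx = link_index(16)
        ((r, a, b),) = truth["genuine_trimers"]
        la = lidx[tuple(sorted((r, a)))]
        lb = lidx[tuple(sorted((r, b)))]
        assert mc.mc[la, lb] > 0.3
        assert abs(fc[a, b]) < 0.1

    def test_zero_depth_modulation_gives_null_mc(self, atlas):
        cfg = m.make_default_entangled_model(depth=0.0)
        sessions, _ = m.generate_entangled_bold(cfg, 1, 2000, seed=4)
        mc = compute_mc(compute_dfc_stream(sessions[0], omega=5), atlas)
        off = np.abs(mc.mc[np.triu_indices(120, 1)])
        assert np.percentile(off, 95) < 0.15

    def test_two_modulator_groups_recovered_by_louvain(self, atlas):
        cfg = m.make_default_entangled_model(n_modulators=2)
        sessions, truth = m.generate_entangled_bold(cfg, 10, 2000, seed=3)
        streams = [compute_dfc_stream(s, omega=5) for s in sessions]
        mc = compute_mc(streams, atlas, pooling="group-average")
        part = partition_mc(mc, gamma=1.4, seed=0)
        links = sorted(truth["modules"])
        ari = adjusted_rand_score(
            [truth["modules"][l] for l in links], [part.labels[l] for l in links]
        )
        assert ari > 0.9

    def test_requires_a_modulator(self, atlas):
        with pytest.raises(ValueError):
            m.CouplingGenConfig(tuple(), np.eye(16), atlas)


class TestGradedCohorts:
    def test_gate_duration_irregularity_increases_across_groups(self):
        rng_seeds = range(5)
        cvs = []
        for shape in GRADED_SHAPES:
            vals = []
            for s in rng_seeds:
                gate = _renewal_gate(20_000, shape, 10.0, np.random.default_rng(s))
                ep, _ = interval_decomposition(gate)
                vals.append(ep.std() / ep.mean())
            cvs.append(np.median(vals))
        assert all(a < b for a, b in zip(cvs, cvs[1:]))

    def test_agreement_fractions_decrease(self):
        assert all(a > b for a, b in zip(GRADED_AGREEMENT, GRADED_AGREEMENT[1:]))

    def test_groups_and_determinism(self):
        s1, t1 = m.generate_graded_cohorts(2, 200, seed=1)
        s2, _ = m.generate_graded_cohorts(2, 200, seed=1)
        assert [s.group for s in s1[::2]] == ["SNC", "NC", "aMCI", "AD"]
        assert np.array_equal(s1[0].data, s2[0].data)


class TestCohortIO:
    def test_roundtrip(self, tmp_path, two_zone_cfg):
        sessions, truths = m.generate_bold_cohort(two_zone_cfg, 3, 50, seed=0)
        manifest = m.write_cohort(
            sessions, two_zone_cfg.atlas, tmp_path,
            ground_truth={"state_labels": {s.subject_id: t for s, t in zip(sessions, truths)}},
        )
        back, atlas2 = m.read_cohort(manifest)
        assert atlas2.region_names == two_zone_cfg.atlas.region_names
        assert len(back) == 3
        assert np.allclose(back[0].data, sessions[0].data, atol=1e-5)

    def test_missing_subject_file_raises(self, tmp_path, two_zone_cfg):
        sessions, _ = m.generate_bold_cohort(two_zone_cfg, 2, 30, seed=0)
        manifest = m.write_cohort(sessions, two_zone_cfg.atlas, tmp_path)
        (tmp_path / f"{sessions[1].subject_id}.tsv").unlink()
        with pytest.raises(FileNotFoundError, match=sessions[1].subject_id):
            m.read_cohort(manifest)
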