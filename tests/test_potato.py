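import numpy as np
import pytest

from conftest import random_spd
from oracles import geodesic_midpoint
from eegpotato.io import Recording
from eegpotato.potato import (
    PotatoModel,
    SPDMatrix,
    apply_potato,
    epoch_covariance,
    fit_potato,
    partition_record,
    riemann_distance,
    riemann_mean,
)
from eegpotato.synth import SynthConfig, generate_recording, inject_artifacts


class TestEpochCovariance:
    def test_duplicated_channels_spd_with_shrinkage(self, rng):
        x = rng.standard_normal((1, 512))
        data = np.vstack([x, x])  # rank deficient
        c = epoch_covariance(data, shrinkage=0.01)
        assert np.linalg.eigvalsh(c.values)[0] > 0

    def test_independent_unit_variance_channels(self, rng):
        data = rng.standard_normal((4, 512))
        c = epoch_covariance(data, shrinkage=0.0)
        assert np.abs(np.diag(c.values) - 1.0).max() < 0.2

    def test_full_shrinkage_gives_scaled_identity(self, rng):
        data = rng.standard_normal((3, 100))
        c = epoch_covariance(data, shrinkage=1.0)
        xc = data - data.mean(axis=1, keepdims=True)
        tr = np.trace(xc @ xc.T / 100)
        np.testing.assert_allclose(c.values, (tr / 3) * np.eye(3), atol=1e-12)

    def test_underdetermined_without_shrinkage_rejected(self, rng):
        with pytest.raises(ValueError):
            epoch_covariance(rng.standard_normal((10, 5)), shrinkage=0.0)


class TestRiemannDistance:
    def test_self_distance_zero(self, rng):
        a = SPDMatrix(random_spd(rng, 5))
        assert riemann_distance(a, a) == pytest.approx(0.0, abs=1e-7)

    def test_closed_form_example(self):
        a = SPDMatrix(np.eye(2))
        b = SPDMatrix(np.diag([np.e ** 2, 1.0]))
        assert riemann_distance(a, b) == pytest.approx(2.0, abs=1e-10)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 6))
            a, b, c = (SPDMatrix(random_spd(rng, n)) for _ in range(3))
            dab, dba = riemann_distance(a, b), riemann_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-8)
            assert dab >= 0
            assert riemann_distance(a, c) <= dab + riemann_distance(b, c) + 1e-8

    def test_congruence_invariance(self, rng):
        a, b = SPDMatrix(random_spd(rng, 4)), SPDMatrix(random_spd(rng, 4))
        w = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        aw = SPDMatrix(w.T @ a.values @ w)
        bw = SPDMatrix(w.T @ b.values @ w)
        assert riemann_distance(aw, bw) == pytest.approx(
            riemann_distance(a, b), abs=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            riemann_distance(SPDMatrix(np.eye(2)), SPDMatrix(np.eye(3)))

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError):
            SPDMatrix(np.diag([1.0, -1.0]))


class TestRiemannMean:
    def test_single_matrix_is_its_own_mean(self, rng):
        a = random_spd(rng, 4)
        m = riemann_mean([SPDMatrix(a)])
        np.testing.assert_allclose(m.values, a, atol=1e-8)

    def test_scalar_matrices_geometric_mean(self):
        m = riemann_mean([SPDMatrix([[4.0]]), SPDMatrix([[9.0]])])
        assert m.values[0, 0] == pytest.approx(6.0, abs=1e-8)

    def test_two_point_mean_is_geodesic_midpoint(self, rng):
        a, b = random_spd(rng, 4), random_spd(rng, 4)
        m = riemann_mean([SPDMatrix(a), SPDMatrix(b)])
        np.testing.assert_allclose(m.values, geodesic_midpoint(a, b), atol=1e-7)

    def test_diagonal_matrices_elementwise_geometric_mean(self, rng):
        diags = np.exp(rng.standard_normal((5, 3)))
        mats = [SPDMatrix(np.diag(d)) for d in diags]
        m = riemann_mean(mats)
        expected = np.exp(np.log(diags).mean(axis=0))
        np.testing.assert_allclose(np.diag(m.values), expected, atol=1e-8)
        np.testing.assert_allclose(m.values, np.diag(np.diag(m.values)),
                                   atol=1e-8)

    def test_congruence_equivariance(self, rng):
        mats = [random_spd(rng, 3) for _ in range(4)]
        w = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        m1 = riemann_mean([SPDMatrix(w.T @ c @ w) for c in mats])
        m0 = riemann_mean([SPDMatrix(c) for c in mats])
        np.testing.assert_allclose(m1.values, w.T @ m0.values @ w, atol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            riemann_mean([])


class TestFitApplyPotato:
    def test_identical_covariances_flag_nothing(self, rng):
        c = random_spd(rng, 3)
        model = fit_potato([SPDMatrix(c.copy()) for _ in range(50)])
        assert model.sigma_logd == pytest.approx(0.0, abs=1e-10)
        for _ in range(5):
            z, label = apply_potato(model, SPDMatrix(c.copy()))
            assert label == "normal"

    def test_constructed_outlier_is_the_only_flag(self, rng):
        covs = [SPDMatrix(np.eye(4) + 0.05 * random_spd(rng, 4))
                for _ in range(49)]
        covs.append(SPDMatrix(100.0 * np.eye(4)))
        model = fit_potato(covs, z_threshold=2.5)
        flags = [apply_potato(model, c)[1] for c in covs]
        assert flags[-1] == "abnormal"
        assert flags[:-1] == ["normal"] * 49
        # brute-force ranking: the outlier is farthest from the reference
        dists = [riemann_distance(model.reference, c) for c in covs]
        assert int(np.argmax(dists)) == 49

    def test_flag_count_non_increasing_in_threshold(self, rng):
        covs = [SPDMatrix(random_spd(rng, 3)) for _ in range(40)]
        counts = []
        for z in (1.0, 1.5, 2.0, 2.5, 3.0):
            model = fit_potato(covs, z_threshold=z)
            counts.append(sum(apply_potato(model, c)[1] == "abnormal"
                              for c in covs))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_reference_itself_scores_z_floor(self, rng):
        covs = [SPDMatrix(random_spd(rng, 3)) for _ in range(20)]
        model = fit_potato(covs)
        z, label = apply_potato(model, model.reference)
        assert z == pytest.approx(-10.0)
        assert label == "normal"

    def test_boundary_z_is_normal(self):
        # distance from reference [1] to [e] is exactly 1, log d = 0;
        # with mu = -2.5, sigma = 1 the z-score is exactly the threshold
        model = PotatoModel(reference=SPDMatrix([[1.0]]), mu_logd=-2.5,
                            sigma_logd=1.0, z_threshold=2.5, n_fit=10)
        z, label = apply_potato(model, SPDMatrix([[np.e]]))
        assert z == pytest.approx(2.5, abs=1e-12)
        assert label == "normal"

    def test_too_few_epochs_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_potato([SPDMatrix(random_spd(rng, 3)) for _ in range(5)])


class TestPartitionRecord:
    def test_artifact_free_record_mostly_normal(self):
        rec, _ = generate_recording(
            SynthConfig(duration=300.0, artifact_rate=0.0, seed=2))
        labels, _, _ = partition_record(rec)
        frac_normal = labels.count("normal") / len(labels)
        assert frac_normal >= 0.95

    def test_repeated_identical_epochs_all_normal(self, rng):
        epoch = rng.standard_normal((4, 512))
        data = np.tile(epoch, (1, 20))
        rec = Recording(data=data, fs=256.0,
                        channel_names=["A", "B", "C", "D"], record_id="rep")
        labels, _, _ = partition_record(rec)
        assert labels == ["normal"] * 20

    def test_labels_partition_all_epochs(self, artifact_fixture):
        _, rec, truth = artifact_fixture
        labels, zs, _ = partition_record(rec)
        assert len(labels) == truth.n_epochs == len(zs)
        assert set(labels) <= {"normal", "abnormal"}

    def test_recovers_injected_artifacts(self):
        rec, _ = generate_recording(
            SynthConfig(duration=200.0, artifact_rate=0.0, seed=6))
        hit = [3, 17, 42, 77]
        contaminated = inject_artifacts(rec, hit, gain=20.0, seed=1)
        labels, _, _ = partition_record(contaminated)
        flagged = {i for i, l in enumerate(labels) if l == "abnormal"}
        assert set(hit) <= flagged
        assert len(flagged - set(hit)) <= 5  # few false alarms on 100 epochs
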