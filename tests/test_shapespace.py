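"""Shape PCA, functional size/shape and respiratory vectors."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from cwmorph import (CohortSpec, centroid_size, gpa, pca, functional_metrics,
                     functional_shape, functional_size, respiratory_vectors,
                     shape_at_scores, simulate_endpoint_configs)
from cwmorph.errors import InvalidParameterError
from cwmorph.shapespace import ShapePCA


def clean_endpoint_cohort(seed=31, n_subjects=4, **kw):
    spec = CohortSpec(n_subjects=n_subjects, noise_sd=0.0, dropout_prob=0.0,
                      subject_shape_sd=4.0, duration_s=16, seed=seed, **kw)
    return simulate_endpoint_configs(spec), spec


class TestShapePCA:
    def test_rank_one_data_has_single_component(self, rng):
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(size=(10, 3)) * 0.2
        data = np.stack([a] * 4 + [b] * 4)
        est = ShapePCA().fit(data)
        assert est.variance_fraction_[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(est.eigenvalues_[1:] < 1e-12 * est.eigenvalues_[0])

    def test_matches_dense_covariance_eigen_oracle(self, rng):
        data = rng.normal(size=(12, 7, 3))
        est = ShapePCA().fit(data)
        flat = data.reshape(12, -1)
        cov = np.cov(flat, rowvar=False, ddof=1)
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(est.eigenvalues_, w[: len(est.eigenvalues_)],
                                   atol=1e-9)
        scores = est.transform(data)
        oracle_scores = (flat - flat.mean(axis=0)) @ v[:, : scores.shape[1]]
        # components defined up to sign; compare magnitudes column-wise
        np.testing.assert_allclose(np.abs(scores), np.abs(oracle_scores), atol=1e-9)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        data = rng.normal(size=(15, 6, 3))
        est = ShapePCA().fit(data)
        assert est.eigenvalues_.sum() == pytest.approx(est.total_variance_, rel=1e-10)
        assert est.variance_fraction_.sum() == pytest.approx(1.0, abs=1e-10)

    def test_mean_shape_scores_are_zero(self, rng):
        est = ShapePCA().fit(rng.normal(size=(8, 5, 3)))
        np.testing.assert_allclose(est.transform(est.mean_shape_), 0.0, atol=1e-12)

    def test_loadings_orthonormal_with_deterministic_sign(self, rng):
        est = ShapePCA().fit(rng.normal(size=(10, 6, 3)))
        gram = est.components_ @ est.components_.T
        np.testing.assert_allclose(gram, np.eye(len(est.components_)), atol=1e-10)
        for row in est.components_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_own_scores_reconstruct_aligned_coordinates(self, rng):
        res = gpa(rng.normal(size=(9, 8, 3)))
        p = pca(res)
        scores = p.scores[p.score_columns()].to_numpy()
        recon = p.estimator.inverse_transform(scores)
        np.testing.assert_allclose(recon, res.aligned, atol=1e-9)

    def test_excess_score_dimension_rejected(self, rng):
        res = gpa(rng.normal(size=(4, 8, 3)))
        p = pca(res)
        with pytest.raises(InvalidParameterError):
            shape_at_scores(p, np.zeros(50))

    def test_too_few_configurations_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            ShapePCA().fit(rng.normal(size=(2, 8, 3)))


class TestFunctionalSize:
    def test_zero_when_in_equals_ex(self):
        (configs, truth), _ = clean_endpoint_cohort()
        frozen = [dataclasses.replace(c, coords=truth.ex_configs[
            (c.subject_id, c.condition)].coords) for c in configs]
        res = gpa(frozen)
        fs = functional_size(res)
        assert np.allclose(fs["FS"], 0.0, atol=1e-9)

    def test_noise_free_cohort_recovers_generator_truth(self):
        (configs, truth), _ = clean_endpoint_cohort()
        res = gpa(configs)
        fs = functional_size(res).set_index(["subject_id", "condition"])["FS"]
        for key in truth.keys():
            assert fs.loc[key] == pytest.approx(truth.true_fs[key], abs=1e-6)

    def test_fs_strictly_increases_with_amplitude(self):
        (_, g1), spec = clean_endpoint_cohort()
        spec2 = dataclasses.replace(
            spec,
            amp_thoracic_QB=2 * spec.amp_thoracic_QB,
            amp_abdominal_QB=2 * spec.amp_abdominal_QB,
            amp_thoracic_REC=2 * spec.amp_thoracic_REC,
            amp_abdominal_REC=2 * spec.amp_abdominal_REC,
        )
        _, g2 = simulate_endpoint_configs(spec2)
        for key in g1.keys():
            assert g2.true_fs[key] > g1.true_fs[key]

    def test_fs_identical_before_and_after_gpa(self):
        # GPA stores pre-scaling CS, so FS does not depend on superimposition
        (configs, _), _ = clean_endpoint_cohort()
        res = gpa(configs)
        fs_gpa = functional_size(res).set_index(["subject_id", "condition"])["FS"]
        df = pd.DataFrame({
            "subject_id": [c.subject_id for c in configs],
            "condition": [c.condition for c in configs],
            "instant": [c.instant for c in configs],
            "cs": [centroid_size(c) for c in configs],
        })
        wide = df.groupby(["subject_id", "condition", "instant"])["cs"].mean().unstack()
        direct = wide["IN"] - wide["EX"]
        for key in fs_gpa.index:
            assert fs_gpa.loc[key] == direct.loc[key]


class TestFunctionalShape:
    def test_zero_when_shapes_identical(self):
        (configs, truth), _ = clean_endpoint_cohort()
        frozen = [dataclasses.replace(c, coords=truth.ex_configs[
            (c.subject_id, c.condition)].coords) for c in configs]
        fsh = functional_shape(gpa(frozen))
        assert np.allclose(fsh["FSh"], 0.0, atol=1e-9)

    def test_noise_free_cohort_recovers_generator_truth(self):
        (configs, truth), _ = clean_endpoint_cohort()
        fsh = functional_shape(gpa(configs)).set_index(
            ["subject_id", "condition"])["FSh"]
        for key in truth.keys():
            assert fsh.loc[key] == pytest.approx(truth.true_fsh[key], abs=1e-8)

    def test_rank_order_matches_truth(self):
        (configs, truth), _ = clean_endpoint_cohort(n_subjects=6)
        fsh = functional_shape(gpa(configs)).set_index(
            ["subject_id", "condition"])["FSh"]
        keys = truth.keys()
        est_rank = np.argsort([fsh.loc[k] for k in keys])
        true_rank = np.argsort([truth.true_fsh[k] for k in keys])
        np.testing.assert_array_equal(est_rank, true_rank)

    def test_invariant_to_uniform_scaling(self):
        (configs, _), _ = clean_endpoint_cohort()
        scaled = [dataclasses.replace(c, coords=c.coords * 3.7) for c in configs]
        a = functional_shape(gpa(configs))["FSh"].to_numpy()
        b = functional_shape(gpa(scaled))["FSh"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestRespiratoryVectors:
    def test_zero_vector_when_in_equals_ex(self):
        (configs, truth), _ = clean_endpoint_cohort()
        frozen = [dataclasses.replace(c, coords=truth.ex_configs[
            (c.subject_id, c.condition)].coords
            + 0.01 * np.random.default_rng(hash(c.subject_id) % 2**31).normal(
                size=(89, 3)))
            for c in configs]
        # IN and EX coords coincide per subject x condition x cycle
        p = pca(gpa(frozen))
        vecs = respiratory_vectors(p).set_index("condition")
        assert vecs["module"].max() < 1e-9

    def test_rec_vector_longer_than_qb(self):
        (configs, _), _ = clean_endpoint_cohort(n_subjects=5)
        vecs = respiratory_vectors(pca(gpa(configs))).set_index("condition")
        assert vecs.loc["REC", "module"] > vecs.loc["QB", "module"]

    def test_matches_direct_summation_oracle(self):
        (configs, _), _ = clean_endpoint_cohort()
        p = pca(gpa(configs))
        vecs = respiratory_vectors(p, n_pcs=2).set_index("condition")
        df = p.scores
        for cond in ("QB", "REC"):
            sub = df[df["condition"] == cond]
            subjects = sorted(sub["subject_id"].unique())
            manual = np.zeros(2)
            for s in subjects:
                rows = sub[sub["subject_id"] == s]
                for i, pc in enumerate(("PC1", "PC2")):
                    manual[i] += (rows[rows["instant"] == "IN"][pc].mean()
                                  - rows[rows["instant"] == "EX"][pc].mean())
            manual /= len(subjects)
            np.testing.assert_allclose(
                vecs.loc[cond, ["PC1", "PC2"]].to_numpy(dtype=float), manual,
                atol=1e-10)

    def test_combined_metrics_table_shape(self):
        (configs, _), _ = clean_endpoint_cohort()
        m = functional_metrics(gpa(configs))
        assert set(m.columns) == {"subject_id", "condition", "FS", "FSh"}
        assert len(m) == 8  # 4 subjects x 2 conditions


class TestShapeAtScores:
    def test_zero_scores_give_mean_shape(self, rng):
        p = pca(gpa(rng.normal(size=(6, 8, 3))))
        np.testing.assert_allclose(shape_at_scores(p, np.zeros(2)), p.mean_shape,
                                   atol=1e-12)

    def test_pc1_excursion_aligns_with_breathing_mode(self):
        # single-posture cohort without subject variation: the dominant shape
        # mode is the EX -> IN breathing deformation itself
        spec = CohortSpec(n_subjects=3, noise_sd=0.0, dropout_prob=0.0,
                          subject_shape_sd=0.0, duration_s=16, seed=41)
        configs, _ = simulate_endpoint_configs(spec)
        res = gpa(configs)
        p = pca(res)
        sd = np.sqrt(p.eigenvalues[0])
        excursion = (shape_at_scores(p, [2 * sd]) - shape_at_scores(p, [-2 * sd]))
        meta = p.scores
        sel_in = (meta["instant"] == "IN").to_numpy()
        sel_ex = (meta["instant"] == "EX").to_numpy()
        mode = res.aligned[sel_in].mean(axis=0) - res.aligned[sel_ex].mean(axis=0)
        cos = np.dot(excursion.ravel(), mode.ravel()) / (
            np.linalg.norm(excursion) * np.linalg.norm(mode))
        assert abs(cos) > 0.9
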