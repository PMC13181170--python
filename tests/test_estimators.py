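"""Coverage filtering, exceed-fraction estimators, Spearman harness."""

import numpy as np
import pandas as pd
import pytest

from tasselect.affinity import AffinityMatrix, AffinityRecord
from tasselect.estimators import (
    EstimateFrame,
    EstimatorError,
    correlation_test,
    estimate_from_matrix,
    exceed_fraction_estimate,
    filter_min_measurements,
    orient_as_selectivity,
    spearman_rho,
    threshold_agnostic_consistency,
)


def rec(lig, prot, pki):
    return AffinityRecord(lig, "CC", prot, pki=pki)


class TestFilterMinMeasurements:
    def test_boundary_count_is_inclusive(self):
        records = [rec("L1", f"P{j}", 7.0) for j in range(10)]
        ligands, proteins = filter_min_measurements(records, 10)
        assert ligands == {"L1"} and len(proteins) == 10

    def test_duplicates_count_distinct_proteins(self):
        # 12 records against only 8 distinct proteins -> dropped at min 10
        records = [rec("L1", f"P{j % 8}", 7.0) for j in range(12)]
        ligands, _ = filter_min_measurements(records, 10)
        assert ligands == set()

    def test_matches_groupby_oracle(self, rng):
        records = [
            rec(f"L{rng.integers(15)}", f"P{rng.integers(20)}", 7.0)
            for _ in range(300)
        ]
        ligands, _ = filter_min_measurements(records, 5)
        df = pd.DataFrame(
            [(r.ligand_id, r.protein_id) for r in records],
            columns=["ligand", "protein"],
        )
        oracle = set(
            df.groupby("ligand")["protein"].nunique().loc[lambda s: s >= 5].index
        )
        assert ligands == oracle

    def test_raising_min_count_never_grows_the_set(self, rng):
        records = [
            rec(f"L{rng.integers(10)}", f"P{rng.integers(12)}", 7.0)
            for _ in range(200)
        ]
        prev = None
        for m in (1, 3, 5, 8, 12):
            cur, _ = filter_min_measurements(records, m)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_invalid_min_count(self):
        with pytest.raises(EstimatorError):
            filter_min_measurements([], 0)


def matrix_from(values):
    values = np.asarray(values, dtype=float)
    return AffinityMatrix(
        [f"L{i}" for i in range(values.shape[0])],
        [f"P{j}" for j in range(values.shape[1])],
        values,
        {},
    )


class TestExceedFraction:
    def test_simple_fraction(self):
        vals = np.concatenate([np.full(3, 9.0), np.full(7, 5.0)])[None, :]
        frac = exceed_fraction_estimate(matrix_from(vals), 7.0)
        assert frac.iloc[0] == pytest.approx(0.3)

    def test_nothing_exceeds(self):
        frac = exceed_fraction_estimate(matrix_from(np.full((4, 6), 5.0)), 7.0)
        assert (frac == 0.0).all()

    def test_matches_loop_oracle_both_denominators(self, rng):
        vals = rng.uniform(4, 11, size=(20, 15))
        m = matrix_from(vals)
        for denom in ("all_proteins", "measured_proteins"):
            frac = exceed_fraction_estimate(m, 7.5, denom)
            for i in range(20):
                expected = sum(v > 7.5 for v in vals[i]) / 15
                assert frac.iloc[i] == pytest.approx(expected)

    def test_sparse_measured_denominator_and_exclusion(self):
        vals = np.array([[9.0, np.nan, 5.0], [np.nan, np.nan, np.nan]])
        frac = exceed_fraction_estimate(matrix_from(vals), 7.0, "measured_proteins")
        assert list(frac.index) == ["L0"]  # L1 has no measurements
        assert frac.iloc[0] == pytest.approx(0.5)

    def test_all_proteins_requires_dense(self):
        vals = np.array([[7.0, np.nan]])
        with pytest.raises(EstimatorError, match="fully observed"):
            exceed_fraction_estimate(matrix_from(vals), 6.0, "all_proteins")

    def test_dense_equivalence_of_the_two_denominators(self, rng):
        """On a fully observed matrix the experimental-style estimator equals
        the cross-prediction-style one ligand by ligand."""
        m = matrix_from(rng.uniform(4, 11, size=(30, 12)))
        a = exceed_fraction_estimate(m, 8.0, "all_proteins")
        b = exceed_fraction_estimate(m, 8.0, "measured_proteins")
        pd.testing.assert_series_equal(a, b)


class TestOrientation:
    def test_modes(self):
        f = pd.Series([0.0, 0.25, 1.0])
        assert orient_as_selectivity(f, "raw_fraction").tolist() == [0.0, 0.25, 1.0]
        assert orient_as_selectivity(f, "one_minus_fraction").tolist() == [1.0, 0.75, 0.0]
        np.testing.assert_array_equal(
            orient_as_selectivity(f, "negated_rank"), [-0.0, -0.25, -1.0]
        )

    def test_orientation_flips_spearman_sign(self, rng):
        f = pd.Series(rng.random(50))
        cov = np.sort(rng.random(50))
        raw = spearman_rho(orient_as_selectivity(f, "raw_fraction"), cov)
        flipped = spearman_rho(orient_as_selectivity(f, "one_minus_fraction"), cov)
        assert raw == pytest.approx(-flipped)


class TestSpearman:
    def test_identity_and_reversal(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_tied_data_matches_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 3.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0, 5.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2  # average of 1-based ranks
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]  # Pearson on average ranks
        assert spearman_rho(x, y) == pytest.approx(oracle)

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(40)
        y = rng.random(40)
        assert spearman_rho(np.exp(3 * x), y) == pytest.approx(spearman_rho(x, y))

    def test_pairwise_complete_and_degenerate(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        assert spearman_rho(x, y) == pytest.approx(1.0)
        assert np.isnan(spearman_rho(np.ones(5), np.arange(5.0)))
        assert np.isnan(spearman_rho(np.arange(2.0), np.arange(2.0)))


def frame_from(values, taus, method="model_tas"):
    df = pd.DataFrame(
        values, columns=[f"est_{t}" for t in taus],
        index=pd.Index([f"L{i}" for i in range(len(values))], name="ligand_id"),
    )
    return EstimateFrame(method, df, taus)


class TestCorrelationTest:
    taus = (7.0, 8.0)

    def test_self_comparison_unit_diagonal_and_symmetry(self, rng):
        v = rng.random((30, 2))
        frames = {
            "model_tas": frame_from(v, self.taus),
            "cross_prediction": frame_from(rng.random((30, 2)), self.taus, "cross_prediction"),
            "experimental": frame_from(rng.random((30, 2)), self.taus, "experimental"),
        }
        report = correlation_test(frames, self.taus)
        for tau, mat in report.per_threshold.items():
            np.testing.assert_allclose(np.diag(mat.to_numpy()), 1.0)
            np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
        assert report.n_ligands["intersection"] == 30

    def test_identical_methods_correlate_perfectly(self, rng):
        v = rng.random((25, 2))
        frames = {
            "model_tas": frame_from(v, self.taus),
            "cross_prediction": frame_from(v, self.taus, "cross_prediction"),
        }
        report = correlation_test(frames, self.taus)
        assert report.per_threshold[7.0].loc["model_tas", "cross_prediction"] == pytest.approx(1.0)

    def test_agreement_decreases_with_noise(self):
        rng = np.random.default_rng(3)
        latent = rng.random(400)
        rhos = []
        for noise in (0.05, 0.3, 1.0):
            frames = {
                "model_tas": frame_from(
                    np.column_stack([latent + rng.normal(0, noise, 400)] * 2), self.taus
                ),
                "experimental": frame_from(
                    np.column_stack([latent + rng.normal(0, noise, 400)] * 2),
                    self.taus, "experimental",
                ),
            }
            report = correlation_test(frames, self.taus)
            rhos.append(report.per_threshold[7.0].loc["model_tas", "experimental"])
        assert rhos[0] > rhos[1] > rhos[2] > 0

    def test_empty_intersection_errors(self, rng):
        f1 = frame_from(rng.random((5, 2)), self.taus)
        f2 = frame_from(rng.random((5, 2)), self.taus, "experimental")
        f2.estimates.index = pd.Index([f"X{i}" for i in range(5)], name="ligand_id")
        with pytest.raises(EstimatorError, match="common ligands"):
            correlation_test({"model_tas": f1, "experimental": f2}, self.taus)


class TestThresholdAgnosticConsistency:
    def test_single_head_gives_unit_rho(self, rng):
        scores = pd.DataFrame({"score_7.0": rng.random(20)})
        rhos = threshold_agnostic_consistency(scores)
        assert rhos["score_7.0"] == pytest.approx(1.0)

    def test_identical_heads_all_unit(self, rng):
        col = rng.random(20)
        scores = pd.DataFrame({f"score_{t}": col for t in (7.0, 7.5, 8.0, 8.5)})
        np.testing.assert_allclose(threshold_agnostic_consistency(scores), 1.0)

    def test_rho_decreases_with_head_noise(self):
        # noise kept below the latent scale so the aggregated mean stays
        # anchored to the shared signal rather than the noisiest head
        rng = np.random.default_rng(5)
        latent = rng.random(1000)  # sd ~ 0.29
        scores = pd.DataFrame(
            {
                f"h{k}": latent + rng.normal(0, sd, 1000)
                for k, sd in enumerate((0.02, 0.06, 0.12, 0.25))
            }
        )
        rhos = threshold_agnostic_consistency(scores)
        assert rhos["h0"] > rhos["h1"] > rhos["h2"] > rhos["h3"]
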