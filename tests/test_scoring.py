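"""Signature scoring: normalization invariants, oracle equivalence, symmetries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from raspdx import (
    ContractError,
    ExpressionMatrix,
    GeneSignature,
    ValidationError,
    map_signature,
    score_pipeline,
    score_samples,
    zscore_normalize,
)


def brute_force_scores(values, genes, samples, up, down):
    """Independent loop-based reimplementation of the whole scoring pipeline.

    Explicit Python arithmetic, no vectorization: per-gene mean and sample
    sd across samples, z-scores, then mean(up) - mean(down) per sample.
    """
    z = {}
    for gi, g in enumerate(genes):
        row = [values[gi][sj] for sj in range(len(samples))]
        mean = sum(row) / len(row)
        var = sum((v - mean) ** 2 for v in row) / (len(row) - 1)
        z[g] = [(v - mean) / math.sqrt(var) for v in row]
    scores = []
    for sj in range(len(samples)):
        up_mean = sum(z[g][sj] for g in up) / len(up)
        down_mean = sum(z[g][sj] for g in down) / len(down)
        scores.append(up_mean - down_mean)
    return scores


class TestZscoreNormalize:
    def test_symmetric_three_point_row(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["G"], columns=["a", "b", "c"])
        )
        z = zscore_normalize(m)
        np.testing.assert_allclose(z.values.loc["G"], [-1.0, 0.0, 1.0])
        assert z.scale_tag == "zscored"

    def test_constant_row_dropped_not_nan(self, caplog):
        m = ExpressionMatrix(
            pd.DataFrame(
                [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["G1", "G2"], columns=list("abc")
            )
        )
        with caplog.at_level("WARNING"):
            z = zscore_normalize(m)
        assert list(z.gene_ids) == ["G1"]
        assert "zero-variance" in caplog.text

    def test_random_matrix_rows_standardized(self, rng):
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(5, 2, size=(50, 20)),
                index=[f"G{i}" for i in range(50)],
                columns=[f"s{j}" for j in range(20)],
            )
        )
        z = zscore_normalize(m)
        means = z.values.mean(axis=1).to_numpy()
        sds = z.values.std(axis=1, ddof=1).to_numpy()
        assert np.abs(means).max() < 1e-10
        assert np.abs(sds - 1).max() < 1e-10

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0]], index=["G"], columns=["a"]))
        with pytest.raises(ValidationError, match="2 samples"):
            zscore_normalize(m)


class TestMapSignature:
    def test_partial_coverage_counts(self):
        sig = GeneSignature(
            "RAS", up=tuple(f"U{i}" for i in range(105)), down=tuple(f"D{i}" for i in range(42))
        )
        genes = [f"U{i}" for i in range(97)] + [f"D{i}" for i in range(32)]
        m = ExpressionMatrix(
            pd.DataFrame(np.zeros((len(genes), 2)), index=genes, columns=["a", "b"])
        )
        mapped = map_signature(sig, m)
        rep = mapped.report
        assert (rep.n_up_requested, rep.n_up_mapped) == (105, 97)
        assert (rep.n_down_requested, rep.n_down_mapped) == (42, 32)
        assert len(rep.unmapped_up) == 8 and len(rep.unmapped_down) == 10

    def test_full_coverage_has_empty_unmapped(self, tiny_matrix, tiny_signature):
        rep = map_signature(tiny_signature, tiny_matrix).report
        assert rep.unmapped_up == () and rep.unmapped_down == ()

    def test_no_down_genes_is_scoring_impossible(self, tiny_matrix):
        sig = GeneSignature("S", up=("UPA",), down=("MISSING",))
        with pytest.raises(ValidationError, match="cannot be scored"):
            map_signature(sig, tiny_matrix)


class TestScoreSamples:
    def test_identical_up_down_rows_cancel(self):
        vals = pd.DataFrame(
            [[-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]], index=["U", "D"], columns=list("abc")
        )
        m = ExpressionMatrix(vals, scale_tag="zscored")
        sig = GeneSignature("S", up=("U",), down=("D",))
        scores = score_samples(m, map_signature(sig, m))
        np.testing.assert_allclose(scores.scores, 0.0, atol=1e-15)

    def test_unnormalized_matrix_is_contract_error(self, tiny_matrix, tiny_signature):
        mapped = map_signature(tiny_signature, tiny_matrix)
        with pytest.raises(ContractError, match="z-scored"):
            score_samples(tiny_matrix, mapped)

    def test_monotone_bump_of_one_up_gene(self):
        vals = pd.DataFrame(
            [[-1.0, 0.0, 1.0], [0.5, -1.0, 0.5], [-1.0, 1.0, 0.0]],
            index=["U1", "U2", "D1"],
            columns=list("abc"),
        )
        m = ExpressionMatrix(vals, scale_tag="zscored")
        sig = GeneSignature("S", up=("U1", "U2"), down=("D1",))
        mapped = map_signature(sig, m)
        base = score_samples(m, mapped).scores
        bumped_vals = vals.copy()
        bumped_vals.loc["U1", "b"] += 0.7
        bumped = score_samples(ExpressionMatrix(bumped_vals, scale_tag="zscored"), mapped).scores
        assert bumped["b"] - base["b"] == pytest.approx(0.7 / 2, abs=1e-12)
        assert bumped[["a", "c"]].equals(base[["a", "c"]])


class TestScorePipeline:
    def test_hand_worked_three_by_three(self, tiny_matrix, tiny_signature):
        scores, report = score_pipeline(tiny_matrix, tiny_signature)
        expected = brute_force_scores(
            tiny_matrix.values.to_numpy().tolist(),
            list(tiny_matrix.gene_ids),
            list(tiny_matrix.sample_ids),
            tiny_signature.up,
            tiny_signature.down,
        )
        np.testing.assert_allclose(scores.scores.to_numpy(), expected, atol=1e-12)
        assert (scores.n_up_used, scores.n_down_used) == (2, 1)

    def test_matches_brute_force_oracle_on_small_matrices(self, rng):
        for _ in range(25):
            n_genes = rng.integers(3, 7)
            n_samples = rng.integers(3, 6)
            n_up = rng.integers(1, n_genes)
            genes = [f"G{i}" for i in range(n_genes)]
            m = ExpressionMatrix(
                pd.DataFrame(
                    rng.normal(size=(n_genes, n_samples)),
                    index=genes,
                    columns=[f"s{j}" for j in range(n_samples)],
                )
            )
            sig = GeneSignature("S", up=tuple(genes[:n_up]), down=tuple(genes[n_up:]))
            scores, _ = score_pipeline(m, sig)
            expected = brute_force_scores(
                m.values.to_numpy().tolist(), genes, list(m.sample_ids), sig.up, sig.down
            )
            np.testing.assert_allclose(scores.scores.to_numpy(), expected, atol=1e-12)

    def test_cohort_mean_of_scores_is_zero(self, rng):
        genes = [f"G{i}" for i in range(30)]
        m = ExpressionMatrix(
            pd.DataFrame(
                rng.normal(size=(30, 12)), index=genes, columns=[f"s{j}" for j in range(12)]
            )
        )
        sig = GeneSignature("S", up=tuple(genes[:20]), down=tuple(genes[20:]))
        scores, _ = score_pipeline(m, sig)
        assert abs(scores.scores.mean()) < 1e-10

    def test_sample_permutation_equivariance(self, tiny_matrix, tiny_signature):
        scores, _ = score_pipeline(tiny_matrix, tiny_signature)
        permuted = ExpressionMatrix(
            tiny_matrix.values[["s3", "s1", "s2"]], scale_tag=tiny_matrix.scale_tag
        )
        scores_p, _ = score_pipeline(permuted, tiny_signature)
        np.testing.assert_allclose(
            scores_p.scores[["s1", "s2", "s3"]], scores.scores[["s1", "s2", "s3"]], atol=1e-12
        )

    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_affine_rescaling_of_a_gene_row_is_absorbed(self, a, b):
        vals = pd.DataFrame(
            [[1.0, 2.0, 4.0], [3.0, 1.0, 2.0], [0.0, 5.0, 1.0]],
            index=["U1", "U2", "D1"],
            columns=list("xyz"),
        )
        sig = GeneSignature("S", up=("U1", "U2"), down=("D1",))
        base, _ = score_pipeline(ExpressionMatrix(vals), sig)
        scaled = vals.copy()
        scaled.loc["U1"] = a * scaled.loc["U1"] + b
        rescored, _ = score_pipeline(ExpressionMatrix(scaled), sig)
        np.testing.assert_allclose(rescored.scores, base.scores, atol=1e-9)

    def test_rejects_already_zscored_input(self, tiny_matrix, tiny_signature):
        z = zscore_normalize(tiny_matrix)
        with pytest.raises(ContractError):
            score_pipeline(z, tiny_signature)

    def test_scores_track_latent_activation(self):
        from raspdx import CohortSpec, generate_cohort
        from scipy.stats import spearmanr

        cohort = generate_cohort(CohortSpec(seed=42, beta=2.0, noise_sd=0.5))
        scores, _ = score_pipeline(cohort.expression, cohort.signature)
        rho = spearmanr(
            scores.scores.reindex(cohort.truth["model_id"]).to_numpy(),
            cohort.truth["latent_activation"],
        ).statistic
        assert rho > 0.9
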