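"""Replicability, consistency, representativity and pruning diagnostics."""

import subprocess

import numpy as np
import pytest

import gsascore as gs
from gsascore.diagnostics import _categorize
from tests.conftest import random_expression


def score_matrix(values, set_ids=None):
    values = np.asarray(values, dtype=float)
    set_ids = set_ids or tuple(f"S{j + 1}" for j in range(values.shape[1]))
    return gs.ScoreMatrix(values, tuple(f"s{i}" for i in range(values.shape[0])), set_ids)


class TestReplicability:
    def test_identical_runs_give_one(self):
        run = score_matrix(np.random.default_rng(0).normal(size=(50, 3)))
        report = gs.replicability([run, run, run])
        assert (report.per_set == 1.0).all()
        assert report.n_initializations == 3

    def test_sign_flip_gives_one(self):
        vals = np.random.default_rng(1).normal(size=(50, 3))
        report = gs.replicability([score_matrix(vals), score_matrix(-vals)])
        assert report.per_set.to_numpy() == pytest.approx(1.0)

    def test_independent_noise_scores_low(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(200, 4))
        noisy = vals.copy()
        noisy[:, 0] = rng.normal(size=200)  # replace one set's scores by noise
        report = gs.replicability([score_matrix(vals), score_matrix(noisy)])
        assert report.per_set["S1"] < 0.25
        np.testing.assert_allclose(report.per_set[["S2", "S3", "S4"]], 1.0, atol=1e-12)

    def test_replicability_is_min_over_pairs(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(100, 1))
        runs = [score_matrix(a), score_matrix(a), score_matrix(rng.normal(size=(100, 1)))]
        report = gs.replicability(runs)
        pair = report.pairwise["S1"]
        assert report.per_set["S1"] == pytest.approx(pair[np.triu_indices(3, k=1)].min())
        assert np.allclose(pair, pair.T) and np.allclose(np.diag(pair), 1.0)

    def test_monotone_transform_invariance(self):
        vals = np.random.default_rng(4).normal(size=(80, 2))
        report = gs.replicability([score_matrix(vals), score_matrix(np.exp(vals))])
        assert report.per_set.to_numpy() == pytest.approx(1.0)

    def test_constant_scores_map_to_zero(self):
        vals = np.random.default_rng(5).normal(size=(30, 2))
        flat = vals.copy()
        flat[:, 0] = 7.0
        report = gs.replicability([score_matrix(vals), score_matrix(flat)])
        assert report.per_set["S1"] == 0.0

    def test_mismatched_samples_rejected(self):
        a = score_matrix(np.zeros((5, 1)))
        b = gs.ScoreMatrix(np.zeros((4, 1)), tuple(f"t{i}" for i in range(4)), ("S1",))
        with pytest.raises(ValueError, match="sample"):
            gs.replicability([a, b])


class TestDefinitionConsistency:
    @pytest.fixture
    def setup(self, small_data, small_model, small_scores):
        x, col, _ = small_data
        model, _ = small_model
        return x, col, model, small_scores

    def test_identical_datasets_are_fully_consistent(self, setup):
        x, col, model, scores = setup
        report = gs.definition_consistency(x, scores, x, scores, col)
        assert report.table["definition_consistency"].to_numpy() == pytest.approx(1.0)
        assert (report.table["category"] == "equivalent").all()
        assert report.table["score_replicability"].to_numpy() == pytest.approx(1.0)

    def test_negated_scores_are_opposite(self, setup):
        x, col, model, scores = setup
        neg = gs.ScoreMatrix(-scores.values, scores.sample_ids, scores.set_ids)
        report = gs.definition_consistency(x, scores, x, neg, col)
        assert report.table["definition_consistency"].to_numpy() == pytest.approx(-1.0)
        assert (report.table["category"] == "opposite").all()

    def test_two_draws_from_same_process_are_consistent(self, small_model):
        """One model scoring two cohorts that share loadings but not samples."""
        model, _ = small_model
        reports = []
        for resample in (101, 102):
            cfg = gs.GeneratorConfig(
                n_samples=120, n_sets=4, genes_per_set=10, n_background_genes=10,
                snr=5.0, seed=42, resample_seed=resample,
            )
            x, col, _ = gs.generate(cfg)
            reports.append((x, gs.compute_gsas(model, x), col))
        (xa, sa, col), (xb, sb, _) = reports
        table = gs.definition_consistency(xa, sa, xb, sb, col).table
        assert (table["definition_consistency"] > 0.7).all()
        assert set(table["category"]) <= {"equivalent", "high"}

    def test_small_shared_gene_sets_flagged_uncomputable(self, setup):
        x, col, model, scores = setup
        tiny = gs.GeneSetCollection(
            tuple(gs.GeneSet(s.id, "", s.genes[:2]) for s in col.sets)
        )
        report = gs.definition_consistency(x, scores, x, scores, tiny)
        assert (report.table["category"] == "uncomputable").all()

    def test_category_thresholds(self):
        assert _categorize(0.95) == "equivalent"
        assert _categorize(0.8) == "high"
        assert _categorize(0.3) == "low_inter"
        assert _categorize(-0.2) == "opposite"
        assert _categorize(float("nan")) == "uncomputable"


class TestRepresentativity:
    def brute_force(self, x, s):
        xc = x.values - x.values.mean(axis=0)
        sc = s.values - s.values.mean(axis=0)
        fitted = np.empty_like(xc)
        for j in range(xc.shape[1]):
            coef, *_ = np.linalg.lstsq(sc, xc[:, j], rcond=None)
            fitted[:, j] = sc @ coef
        return float(np.sum(fitted**2) / np.sum(xc**2))

    def test_matches_per_gene_least_squares_oracle(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = random_expression(50, [f"g{i}" for i in range(30)], seed=seed, standardized=True)
            s = score_matrix(rng.normal(size=(50, 5)))
            got = gs.representativity(x, s)
            assert got == pytest.approx(self.brute_force(x, s), abs=1e-10)
            assert 0.0 <= got <= 1.0 + 1e-12

    def test_monotone_under_column_addition(self):
        rng = np.random.default_rng(7)
        x = random_expression(40, [f"g{i}" for i in range(20)], seed=7, standardized=True)
        prev = 0.0
        for p in (1, 2, 4, 8):
            s = score_matrix(rng.normal(size=(40, p)), tuple(f"S{j}" for j in range(p)))
            cur = gs.representativity(x, s)
            assert cur >= prev - 1e-12
            prev = cur

    def test_full_sample_rank_scores_explain_everything(self):
        rng = np.random.default_rng(8)
        x = random_expression(10, [f"g{i}" for i in range(6)], seed=8, standardized=True)
        s = score_matrix(rng.normal(size=(10, 12)), tuple(f"S{j}" for j in range(12)))
        assert gs.representativity(x, s) == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_explains_expected_share(self):
        # under independence, per-gene R^2 ~ p/(n-1)
        rng = np.random.default_rng(9)
        n, p = 400, 5
        x = random_expression(n, [f"g{i}" for i in range(40)], seed=9, standardized=True)
        s = score_matrix(rng.normal(size=(n, p)), tuple(f"S{j}" for j in range(p)))
        got = gs.representativity(x, s)
        assert got == pytest.approx(p / (n - 1), rel=0.5)

    def test_collinear_scores_handled_by_rank_revealing_solve(self):
        x = random_expression(30, [f"g{i}" for i in range(10)], seed=10, standardized=True)
        base = np.random.default_rng(11).normal(size=(30, 2))
        dup = np.hstack([base, base[:, [0]]])  # exactly collinear third column
        s = score_matrix(dup, ("S1", "S2", "S3"))
        s2 = score_matrix(base, ("S1", "S2"))
        assert gs.representativity(x, s) == pytest.approx(gs.representativity(x, s2), abs=1e-10)

    def test_agrees_with_vegan_rda(self, tmp_path):
        """Independent oracle: redundancy analysis from the vegan R package."""
        rng = np.random.default_rng(12)
        x = random_expression(30, [f"g{i}" for i in range(12)], seed=12, standardized=True)
        s = score_matrix(rng.normal(size=(30, 4)), ("a", "b", "c", "d"))
        np.savetxt(tmp_path / "x.tsv", x.values, delimiter="\t")
        np.savetxt(tmp_path / "s.tsv", s.values, delimiter="\t")
        rcode = (
            'suppressMessages(library(vegan));'
            f'x <- as.matrix(read.table("{tmp_path}/x.tsv"));'
            f's <- as.data.frame(as.matrix(read.table("{tmp_path}/s.tsv")));'
            'r <- rda(x ~ ., data=s);'
            'cat(sprintf("%.12f", r$CCA$tot.chi / r$tot.chi))'
        )
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        assert gs.representativity(x, s) == pytest.approx(float(out.stdout), abs=1e-9)


class TestPCAgreement:
    def test_scores_equal_expression_give_perfect_agreement(self):
        x = random_expression(30, [f"g{i}" for i in range(8)], seed=13, standardized=True)
        s = gs.ScoreMatrix(x.values, x.sample_ids, tuple(f"S{j}" for j in range(8)))
        agree = gs.pc_agreement(x, s, k=4)
        np.testing.assert_allclose(agree.max_per_pc, 1.0, atol=1e-8)

    def test_dominant_factor_is_shared(self):
        """One gene set dwarfs the others, so PC1 of genes and of scores coincide."""
        cfg = gs.GeneratorConfig(
            n_samples=150, n_sets=3, genes_per_set=(30, 5, 5), n_background_genes=5,
            snr=5.0, seed=31,
        )
        x, col, _ = gs.generate(cfg)
        tcfg = gs.TrainingConfig(step1_epochs=60, step2_epochs=40, step3_epochs=60,
                                 batch_size=32, seed=1)
        model, _ = gs.train_full(col, x, None, tcfg)
        scores = gs.compute_gsas(model, x)
        # score scales are arbitrary (tanh regime), so the dominant factor can
        # sit in any score PC: look across all of them, as the diagnostic does
        agree = gs.pc_agreement(x, scores, k=3)
        assert agree.max_per_pc[0] >= 0.95

    def test_column_permutation_invariance(self):
        x = random_expression(25, [f"g{i}" for i in range(6)], seed=14, standardized=True)
        vals = np.random.default_rng(15).normal(size=(25, 5))
        s1 = score_matrix(vals)
        s2 = score_matrix(vals[:, ::-1], tuple(f"S{j}" for j in range(5)))
        a1 = gs.pc_agreement(x, s1, k=3)
        a2 = gs.pc_agreement(x, s2, k=3)
        np.testing.assert_allclose(a1.matrix, a2.matrix, atol=1e-8)

    def test_oversized_k_rejected(self):
        x = random_expression(10, ["g1", "g2"], seed=16, standardized=True)
        s = score_matrix(np.random.default_rng(17).normal(size=(10, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            gs.pc_agreement(x, s, k=5)


class TestPruning:
    def test_threshold_zero_is_single_round_passthrough(self, small_data):
        x, col, _ = small_data
        cfg = gs.TrainingConfig(step1_epochs=5, step2_epochs=3, step3_epochs=5, seed=0)
        pruned, history = gs.prune_by_replicability(col, x, None, cfg, n_seeds=2, threshold=0.0)
        assert pruned.ids == col.ids
        assert len(history) == 1 and history[0]["dropped"] == []

    def test_history_has_one_entry_per_round(self, small_data):
        x, col, _ = small_data
        cfg = gs.TrainingConfig(step1_epochs=5, step2_epochs=3, step3_epochs=5, seed=0)
        _, history = gs.prune_by_replicability(
            col, x, None, cfg, n_seeds=2, threshold=0.0, max_rounds=3
        )
        assert [h["round"] for h in history] == [1]  # converged in round 1

    def test_requires_two_seeds(self, small_data):
        x, col, _ = small_data
        with pytest.raises(ValueError, match="n_seeds"):
            gs.prune_by_replicability(col, x, n_seeds=1)

    def test_independent_high_snr_sets_survive(self, small_data):
        x, col, _ = small_data
        cfg = gs.TrainingConfig(step1_epochs=30, step2_epochs=15, step3_epochs=30, seed=1)
        pruned, history = gs.prune_by_replicability(col, x, None, cfg, n_seeds=3, threshold=0.7)
        assert pruned.ids == col.ids
        assert (history[0]["replicability"] >= 0.7).all()
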