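import filecmp

import numpy as np
import pytest

from mrexsurv import (
    PipelineConfig,
    SimConfig,
    make_fixture,
    run_pipeline,
    simulate_expression,
    simulate_methylation,
    simulate_survival,
)


def _offdiag_corr(block):
    c = np.corrcoef(block.T)
    return c[np.triu_indices_from(c, k=1)]


class TestSimulateMethylation:
    def test_independent_cpgs(self):
        cfg = SimConfig(n=500, genes=1, p_per_gene=20, cpg_corr=0.0, seed=1)
        m, genes, cpgs = simulate_methylation(cfg)
        assert np.abs(_offdiag_corr(m.values)).mean() < 0.05

    def test_exchangeable_correlation(self):
        cfg = SimConfig(n=1000, genes=1, p_per_gene=20, cpg_corr=0.5, seed=2)
        m, _, _ = simulate_methylation(cfg)
        assert _offdiag_corr(m.values).mean() == pytest.approx(0.5, abs=0.05)

    def test_determinism(self):
        cfg = SimConfig(n=50, genes=3, p_per_gene=10, seed=9)
        a, _, _ = simulate_methylation(cfg)
        b, _, _ = simulate_methylation(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            SimConfig(cpg_corr=1.0)

    def test_annotation_layout_reconstructs_blocks(self):
        from mrexsurv import assemble_gene_block, OmicsMatrix

        cfg = SimConfig(n=30, genes=3, p_per_gene=8, seed=3)
        m, genes, cpgs = simulate_methylation(cfg)
        expr = OmicsMatrix(m.sample_ids, [g.feature_id for g in genes],
                           np.zeros((30, 3)) + np.arange(3) + np.random.default_rng(0).standard_normal((30, 3)))
        for gi, gene in enumerate(genes):
            blk = assemble_gene_block(gene, cpgs, m, expr, promoter_ext=2000)
            assert blk.cpg_ids == [f"cg{gi:04d}_{j:03d}" for j in range(8)]


class TestSimulateExpression:
    def test_pve_zero_pure_noise(self, rng):
        M = rng.standard_normal((50, 10))
        G, w = simulate_expression(M, "polygenic", 0.0, rng)
        assert np.all(w == 0)

    def test_realized_pve(self):
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            M = rng.standard_normal((2000, 30))
            M = (M - M.mean(0)) / M.std(0, ddof=1)
            G, w = simulate_expression(M, "polygenic", 0.4, rng)
            ratios.append((M @ w).var(ddof=1) / G.var(ddof=1))
        assert np.mean(ratios) == pytest.approx(0.4, abs=0.05)

    def test_sparse_support_size(self, rng):
        M = rng.standard_normal((100, 50))
        _, w = simulate_expression(M, "sparse", 0.3, rng, k_causal=2)
        assert np.count_nonzero(w) == 2

    def test_pve_one_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_expression(rng.standard_normal((10, 2)), "sparse", 1.0, rng)


class TestSimulateSurvival:
    def test_exponential_median(self):
        rng = np.random.default_rng(0)
        surv = simulate_survival(None, np.zeros(10_000), None, b=1.0,
                                 baseline=("exponential", 0.1),
                                 censor_target=0.0, rng=rng)
        assert np.median(surv.time) == pytest.approx(np.log(2) / 0.1, abs=0.2)
        assert surv.event.all()

    def test_hazard_ratio_halves_median(self):
        rng = np.random.default_rng(1)
        g = np.repeat([0.0, 1.0], 10_000)
        surv = simulate_survival(None, g, None, b=np.log(2),
                                 baseline=("exponential", 0.1),
                                 censor_target=0.0, rng=rng)
        med0 = np.median(surv.time[:10_000])
        med1 = np.median(surv.time[10_000:])
        assert med0 / med1 == pytest.approx(2.0, abs=0.15)

    def test_censoring_calibration(self):
        rng = np.random.default_rng(2)
        surv = simulate_survival(None, rng.standard_normal(5000), None, b=0.5,
                                 baseline=("weibull", 1.5, 30.0),
                                 censor_target=0.3, rng=rng)
        assert 1.0 - surv.event.mean() == pytest.approx(0.3, abs=0.03)

    def test_invalid_censor_target(self, rng):
        with pytest.raises(ValueError):
            simulate_survival(None, np.zeros(5), None, censor_target=1.0, rng=rng)


class TestMakeFixture:
    def test_smoke_end_to_end(self, small_fixture_dir, tmp_path):
        cfg, paths, truth = small_fixture_dir
        pc = PipelineConfig(
            methylation=str(paths["methylation"]), expression=str(paths["expression"]),
            survival=str(paths["survival"]), genes_bed=str(paths["genes_bed"]),
            cpgs_bed=str(paths["cpgs_bed"]), outdir=str(tmp_path / "out"),
            models=("lmm",), seed=0,
        )
        results = run_pipeline(pc)
        assert len(results) == cfg.genes  # all generated genes pass default QC

    def test_regeneration_bit_identical(self, tmp_path):
        cfg = SimConfig(n=40, genes=2, p_per_gene=11, b=0.5, n_signal_genes=1, seed=5)
        p1, _ = make_fixture(cfg, tmp_path / "a")
        p2, _ = make_fixture(cfg, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_overwrite_guard(self, tmp_path):
        cfg = SimConfig(n=30, genes=1, p_per_gene=10, seed=5)
        make_fixture(cfg, tmp_path / "fx")
        with pytest.raises(FileExistsError):
            make_fixture(cfg, tmp_path / "fx")
        make_fixture(cfg, tmp_path / "fx", overwrite=True)

    def test_truth_records_signal_genes(self, small_fixture_dir):
        cfg, paths, truth = small_fixture_dir
        signal = [g for g, b in truth.b.items() if b != 0]
        assert len(signal) == cfg.n_signal_genes
        assert all(len(truth.w[g]) == cfg.p_per_gene for g in truth.w)
        assert 0 <= truth.realized_censoring < 1


class TestNullFdrControl:
    def test_null_fixture_rarely_calls_genes(self, tmp_path):
        # reduced-scale FDR-control check: no true effects anywhere
        false_calls = 0
        for seed in range(4):
            cfg = SimConfig(n=150, genes=60, p_per_gene=12, pve=0.3, b=0.0,
                            censor_target=0.3, seed=100 + seed)
            paths, _ = make_fixture(cfg, tmp_path / f"null{seed}")
            pc = PipelineConfig(
                methylation=str(paths["methylation"]), expression=str(paths["expression"]),
                survival=str(paths["survival"]), genes_bed=str(paths["genes_bed"]),
                cpgs_bed=str(paths["cpgs_bed"]), outdir=str(tmp_path / f"out{seed}"),
                models=("lmm",), seed=seed,
            )
            false_calls += int(run_pipeline(pc)["called"].sum())
        assert false_calls <= 1

    def test_signal_fixture_recovers_genes(self, tmp_path):
        # power: 5 true-signal genes with a strong effect are mostly recovered
        cfg = SimConfig(n=400, genes=20, p_per_gene=15, pve=0.5, b=0.8,
                        n_signal_genes=5, censor_target=0.3, seed=77)
        paths, truth = make_fixture(cfg, tmp_path / "sig")
        pc = PipelineConfig(
            methylation=str(paths["methylation"]), expression=str(paths["expression"]),
            survival=str(paths["survival"]), genes_bed=str(paths["genes_bed"]),
            cpgs_bed=str(paths["cpgs_bed"]), outdir=str(tmp_path / "sigout"),
            models=("lmm", "lasso"), seed=0,
        )
        results = run_pipeline(pc)
        called = set(results.loc[results["called"], "gene_id"])
        signal = {g for g, b in truth.b.items() if b != 0}
        assert len(called & signal) >= 3
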