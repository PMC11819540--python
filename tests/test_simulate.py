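import numpy as np
import pytest

from neomer.library_model import CapacityError, split_modules
from neomer.module_counting import count_modules
from neomer.enrichment import (
    fold_values,
    outer_frequency,
    replicate_stats,
    stats_from_tables,
    top_k,
    zscore,
)
from neomer.simulate import (
    PlantedBinder,
    SimulationConfig,
    TruthManifest,
    apply_selection,
    count_sample,
    recovery_report,
    reduce_template,
    render_reads,
    run_simulation,
    simulate_naive,
    write_fastq,
)


class TestReduceTemplate:
    def test_widths_and_anchors(self, paper_template):
        reduced = reduce_template(paper_template, 4, 4)
        mod_a, mod_b = split_modules(reduced)
        assert (mod_a.width, mod_b.width) == (4, 4)
        assert reduced.length == paper_template.length
        # frozen positions become A, fixed scaffold untouched
        for i, (orig, new) in enumerate(
            zip(paper_template.template, reduced.template)
        ):
            if orig != "N":
                assert new == orig
            else:
                assert new in "NA"

    def test_cannot_widen(self, paper_template):
        with pytest.raises(ValueError):
            reduce_template(paper_template, 9, 8)


class TestSimulateNaive:
    def test_shape_and_normalization(self, rng):
        cfg = SimulationConfig(w_a=3, w_b=3, replicates=4)
        draws = simulate_naive(cfg, rng)
        assert draws.shape == (4, 4**6)
        assert np.allclose(draws.sum(axis=1), 1.0)

    def test_high_concentration_approaches_uniform(self, rng):
        cfg = SimulationConfig(w_a=2, w_b=2, replicates=1, concentration=1e9)
        draws = simulate_naive(cfg, rng)
        assert np.allclose(draws, 1 / 256, rtol=1e-2)

    def test_seeded_determinism(self):
        cfg = SimulationConfig(w_a=2, w_b=2, replicates=3)
        a = simulate_naive(cfg, np.random.default_rng(5))
        b = simulate_naive(cfg, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_mean_abundance_matches_closed_form(self):
        # E[p_i] = 1/space for a symmetric Dirichlet; Monte-Carlo check
        cfg = SimulationConfig(w_a=2, w_b=2, replicates=400, concentration=50)
        draws = simulate_naive(cfg, np.random.default_rng(0))
        space = 256
        mean = draws[:, 0].mean()
        # var of one coordinate: p(1-p)/(a0+1), a0 = 50*256
        sd = np.sqrt((1 / space) * (1 - 1 / space) / (50 * space + 1) / 400)
        assert abs(mean - 1 / space) < 3 * sd

    def test_capacity_guard(self):
        cfg = SimulationConfig(w_a=8, w_b=8)
        with pytest.raises(CapacityError):
            simulate_naive(cfg, np.random.default_rng(0))


class TestApplySelection:
    def test_no_binders_is_identity(self, rng):
        cfg = SimulationConfig(w_a=2, w_b=2)
        p = simulate_naive(cfg, rng)
        assert np.array_equal(apply_selection(p, (), cfg), p)

    def test_single_binder_closed_form(self):
        cfg = SimulationConfig(
            w_a=2, w_b=2, binders=(PlantedBinder("AA", "AA", 50.0),)
        )
        space = 256
        p = np.full(space, 1 / space)
        post = apply_selection(p, cfg.binders, cfg)
        f, base = 50.0, 1 / space
        expected = f * base / (1 + (f - 1) * base)
        assert post[0] == pytest.approx(expected)
        assert post.sum() == pytest.approx(1.0)

    def test_two_binders_match_hand_renormalization(self):
        binders = (
            PlantedBinder("AC", "GT", 10.0),
            PlantedBinder("TT", "CC", 4.0),
        )
        cfg = SimulationConfig(w_a=2, w_b=2, binders=binders)
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(256))
        post = apply_selection(p, binders, cfg)
        manual = p.copy()
        manual[cfg.binder_index(binders[0])] *= 10.0
        manual[cfg.binder_index(binders[1])] *= 4.0
        manual /= manual.sum()
        assert np.allclose(post, manual)

    def test_counter_binder_untouched_in_target_condition(self):
        binders = (PlantedBinder("AA", "AA", 50.0, binds="resin"),)
        cfg = SimulationConfig(w_a=2, w_b=2, binders=binders)
        p = np.full(256, 1 / 256)
        assert np.array_equal(apply_selection(p, binders, cfg, "target"), p)
        assert apply_selection(p, binders, cfg, "resin")[0] > 1 / 256

    def test_binder_outside_space_is_config_error(self):
        cfg = SimulationConfig(w_a=2, w_b=2)
        with pytest.raises(ValueError):
            apply_selection(
                np.full(256, 1 / 256), (PlantedBinder("AAA", "AA", 2.0),), cfg
            )


class TestRenderReads:
    def test_depth_conservation_and_zero_error_round_trip(self):
        cfg = SimulationConfig(w_a=3, w_b=3, replicates=1,
                               reads_per_sample=20_000, error_rate=0.0)
        rng = np.random.default_rng(11)
        p = simulate_naive(cfg, rng)[0]
        sample = render_reads(p, cfg, rng)
        assert len(sample.reads_a) == len(sample.reads_b) == 20_000
        assert sample.joint_counts.sum() == 20_000
        table_a, table_b = count_sample(sample, cfg)
        nB = 4**cfg.w_b
        joint = sample.joint_counts.reshape(4**cfg.w_a, nB)
        assert np.array_equal(table_a.counts, joint.sum(axis=1))
        assert np.array_equal(table_b.counts, joint.sum(axis=0))
        assert table_a.n_rejected == table_b.n_rejected == 0

    def test_one_hot_abundance_renders_identical_reads(self):
        cfg = SimulationConfig(w_a=2, w_b=2, reads_per_sample=500,
                               error_rate=0.0)
        p = np.zeros(256)
        p[37] = 1.0
        sample = render_reads(p, cfg, np.random.default_rng(0))
        assert len(set(sample.reads_a)) == 1 and len(set(sample.reads_b)) == 1

    def test_error_rate_rejection_matches_binomial(self):
        # 8 fixed anchor bases, per-base error 0.01, mismatch budget 1:
        # P(reject) = P(Binom(8, 0.01) >= 2); strand rescue is negligible
        from neomer.library_model import ModuleSpec

        module = ModuleSpec(module_id="A", sequence="ACGTNNNNTGCA",
                            random_offsets=(4, 5, 6, 7))
        n = 120_000
        rng = np.random.default_rng(2)
        from neomer.simulate import _render_module_reads

        counts = np.zeros(256, dtype=np.int64)
        counts[0] = n
        reads = _render_module_reads(counts, module, 0.01, rng)
        table = count_modules(reads, module, max_mismatch=1)
        q = 0.01
        p_reject = 1 - (1 - q) ** 8 - 8 * q * (1 - q) ** 7
        expected = n * p_reject
        sd = np.sqrt(n * p_reject * (1 - p_reject))
        assert abs(table.n_rejected - expected) < 4 * sd

    def test_write_fastq(self, tmp_path):
        path = tmp_path / "x.fastq"
        write_fastq(["ACGT", "GGGG"], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "@read0" and lines[1] == "ACGT"
        assert lines[3] == "IIII" and len(lines) == 8


class TestTruthManifest:
    def test_expected_outer_fold_reflects_module_dilution(self):
        cfg = SimulationConfig(
            w_a=4, w_b=4, binders=(PlantedBinder("AAAA", "CCCC", 50.0),)
        )
        truth = TruthManifest(seed=0, config=cfg)
        fold = truth.expected_fold(cfg.binders[0])
        # marginal counting dilutes a 50x joint enrichment to ~1.4x
        assert 1.0 < fold < 50.0
        surface = truth.expected_outer_frequency("target")
        assert surface.sum() == pytest.approx(1.0, abs=1e-9)

    def test_json_round_trip(self, tmp_path, small_sim):
        _cfg, _reads, truth = small_sim
        path = tmp_path / "truth.json"
        truth.to_json(path)
        loaded = TruthManifest.from_json(path)
        assert loaded.seed == truth.seed
        assert loaded.config.binders == truth.config.binders
        assert loaded.realized_pre == truth.realized_pre

    def test_infinite_depth_single_binder_ranks_first(self):
        """Noise-free limit: the planted binder tops the z ranking.

        Frequencies are injected directly (no sampling);  replicates are
        identical so the z denominator sits at the eps floor and ordering
        is by reconstructed frequency difference alone.  With a single
        binder every other sequence shares at most one enriched module,
        so the binder is strictly first.
        """
        binder = PlantedBinder("AATT", "GGCC", 25.0)
        cfg = SimulationConfig(w_a=4, w_b=4, binders=(binder,))
        space = cfg.space
        pre = np.full(space, 1 / space)
        post = apply_selection(pre, cfg.binders, cfg)
        nB = 4**cfg.w_b
        post_m = post.reshape(4**cfg.w_a, nB)
        pre_m = pre.reshape(4**cfg.w_a, nB)
        target = replicate_stats(
            [outer_frequency(post_m.sum(axis=1), post_m.sum(axis=0))] * 3
        )
        control = replicate_stats(
            [outer_frequency(pre_m.sum(axis=1), pre_m.sum(axis=0))] * 3
        )
        (best,) = top_k(zscore(target, control, eps=1e-9), 1)
        assert (best.fill_a, best.fill_b) == ("AATT", "GGCC")


class TestEndToEndRecovery:
    def test_planted_binders_recovered(self, small_sim, small_sim_tables):
        cfg, _reads, truth = small_sim
        tables = small_sim_tables
        stats = {c: stats_from_tables(*tables[c]) for c in tables}
        all_tables = [t for pair in tables.values() for ts in pair for t in ts]
        from neomer.enrichment import default_eps

        eps = default_eps(all_tables)
        ranked = top_k(zscore(stats["target"], stats["naive"], eps), cfg.space)
        folds = {"naive": fold_values(stats["target"], stats["naive"], 0.5 * eps)}
        from neomer.enrichment import counter_screen

        with_folds, _ = counter_screen(ranked, folds, {})
        report = recovery_report(with_folds, truth, top=100)
        assert report["n_binders"] == 5
        assert report["fraction_in_top"] == 1.0
        for err in report["fold_relative_errors"].values():
            assert err < 0.5  # loose at this small depth; tight case elsewhere

    def test_counter_binders_fold_below_one(self, small_sim, small_sim_tables):
        cfg, _reads, truth = small_sim
        tables = small_sim_tables
        stats = {c: stats_from_tables(*tables[c]) for c in tables}
        fold = fold_values(stats["target"], stats["resin"], pseudo=1e-9)
        for b in cfg.binders:
            if b.binds != "resin":
                continue
            from neomer.library_model import fill_to_index

            a, bb = fill_to_index(b.fill_a), fill_to_index(b.fill_b)
            assert fold(a, bb) < 1.0

    def test_no_binders_flagged(self):
        cfg = SimulationConfig(w_a=2, w_b=2)
        truth = TruthManifest(seed=0, config=cfg)
        report = recovery_report([], truth)
        assert report["n_binders"] == 0 and report["fraction_in_top"] is None
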