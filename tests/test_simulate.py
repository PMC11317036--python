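"""Amplification simulators: efficiency model, DePCR/standard dynamics, errors, emission."""

import math

import numpy as np
import pytest

from depcrsim.design import MismatchProfile, PoolSpec, make_pool
from depcrsim.errors import ModelError, SimulationError
from depcrsim.simulate import (
    EfficiencyModel,
    QualityModel,
    RunConfig,
    annealing_efficiency,
    apply_errors,
    depcr_event_probabilities,
    emit_reads,
    paired_reads,
    simulate_depcr,
    simulate_standard_pcr,
    synthesize_reads,
)


@pytest.fixture(scope="module")
def model():
    return EfficiencyModel.default()


class TestEfficiencyModel:
    def test_perfect_match_is_one(self, model):
        assert annealing_efficiency(MismatchProfile(), 45.0, model) == 1.0

    def test_calibrated_single_mismatch_anchors(self, design, model):
        profiles = design.space.profiles
        assert model.efficiency(profiles[("V7", "ST0")], 55.0) == pytest.approx(0.01)
        assert model.efficiency(profiles[("V1", "ST0")], 45.0) == pytest.approx(0.65)
        # middle-position C-A pairing is overridden below the positional default
        assert model.efficiency(profiles[("V5", "ST0")], 45.0) == pytest.approx(0.36)
        assert model.efficiency(profiles[("V4", "ST0")], 45.0) == pytest.approx(0.54)

    def test_multiplicative_composition(self, design, model):
        t0 = design.space.template_by_id["ST0"]
        worst = next(
            p for p in design.primers
            if all(a != b for a, b in zip(p.variant_triple, t0.variant_triple))
        )
        prof = design.space.profiles[(worst.primer_id, "ST0")]
        expected = 1.0
        for e in prof.entries:
            expected *= model.penalty(e.position_label, 45.0, e.pairing)
        assert model.efficiency(prof, 45.0) == pytest.approx(expected)

    def test_unknown_temperature_raises(self, design, model):
        prof = design.space.profiles[("V7", "ST0")]
        with pytest.raises(ModelError):
            model.efficiency(prof, 50.0)

    def test_penalties_outside_unit_interval_rejected(self):
        with pytest.raises(ModelError):
            EfficiencyModel({("3'", 45.0): 0.0}, {})


class TestDePCR:
    def test_single_perfect_pair_gets_all_events(self, design, pools):
        cfg = RunConfig(reads_per_replicate=500, n_replicates=2, seed=1)
        res = simulate_depcr(pools["A"], pools["1"], 45.0, cfg, design.space)
        assert (res.counts[("V0", "ST0")] == 500).all()

    def test_head_to_head_fraction_matches_closed_form(self, design, pools):
        # equimolar V0 + V7 on ST0: mismatch fraction p/(1+p) with p the 3' penalty
        pool = PoolSpec.from_mapping("hh", {"V0": 1.0, "V7": 1.0})
        p = 0.01
        model = EfficiencyModel({("3'", 55.0): p}, {})
        n = 100_000
        cfg = RunConfig(reads_per_replicate=n, n_replicates=1, seed=11)
        res = simulate_depcr(pools["A"], pool, 55.0, cfg, design.space, model)
        expected = p / (1 + p)
        # brute-force enumeration of the two event probabilities
        assert res.probabilities[("V7", "ST0")] == pytest.approx(expected)
        frac = res.counts.iloc[0][("V7", "ST0")] / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 4 * se

    def test_event_probabilities_match_brute_force(self, design, pools, model):
        # independent oracle: explicit product template_prop x primer_prop x eff
        probs = depcr_event_probabilities(
            pools["D"], pools["10"], 45.0, design.space, model
        )
        tprop = pools["D"].proportions
        pprop = pools["10"].proportions
        raw = {}
        for pid in pools["10"].members:
            for tid in pools["D"].members:
                eff = model.efficiency(design.space.profiles[(pid, tid)], 45.0)
                raw[(pid, tid)] = tprop[tid] * pprop[pid] * eff
        total = sum(raw.values())
        for pair, value in raw.items():
            assert probs[pair] == pytest.approx(value / total)

    def test_a10_mismatch_ratio_equals_sum_of_penalties(self, design, pools, model):
        # equimolar primers on one template: ratio = sum of the nine efficiencies
        expected = sum(
            model.efficiency(design.space.profiles[(f"V{i}", "ST0")], 45.0)
            for i in range(1, 10)
        )
        n = 100_000
        cfg = RunConfig(reads_per_replicate=n, n_replicates=1, seed=5)
        res = simulate_depcr(pools["A"], pools["10"], 45.0, cfg, design.space, model)
        row = res.counts.iloc[0]
        match = row[("V0", "ST0")]
        ratio = (n - match) / match
        f = expected / (1 + expected)  # mismatch fraction
        se_f = math.sqrt(f * (1 - f) / n)
        se_ratio = se_f / (1 - f) ** 2  # delta method
        assert abs(ratio - expected) < 3 * se_ratio

    @pytest.mark.parametrize("p", [0.01, 0.1, 0.65])
    def test_penalty_recovery_from_head_to_head_counts(self, design, pools, p):
        # the measurement design: estimate p as mismatch/match in equimolar
        # head-to-head at 1e5 events; must land within 3 binomial SEs
        pool = PoolSpec.from_mapping("hh", {"V0": 1.0, "V7": 1.0})
        model = EfficiencyModel({("3'", 45.0): p}, {})
        n = 100_000
        cfg = RunConfig(reads_per_replicate=n, n_replicates=1, seed=23)
        res = simulate_depcr(pools["A"], pool, 45.0, cfg, design.space, model)
        row = res.counts.iloc[0]
        p_hat = row[("V7", "ST0")] / row[("V0", "ST0")]
        f = p / (1 + p)
        se_p = math.sqrt(f * (1 - f) / n) / (1 - f) ** 2
        assert abs(p_hat - p) < 3 * se_p


class TestStandardPCR:
    def test_single_primer_reports_only_that_primer(self, design, pools):
        cfg = RunConfig(method="standard", reads_per_replicate=400, n_replicates=1, seed=2)
        res = simulate_standard_pcr(pools["B"], pools["1"], 45.0, cfg, design.space)
        by_primer = res.counts.iloc[0].groupby(level="primer_id").sum()
        assert by_primer["V0"] == 400

    def test_two_equimolar_primers_converge_to_half_usage(self, design, pools):
        pool = PoolSpec.from_mapping("two", {"V0": 1.0, "V7": 1.0})
        cfg = RunConfig(method="standard", reads_per_replicate=50_000, n_replicates=1, seed=3)
        res = simulate_standard_pcr(pools["A"], pool, 45.0, cfg, design.space)
        usage = res.counts.iloc[0].groupby(level="primer_id").sum()
        frac = usage["V0"] / usage.sum()
        assert abs(frac - 0.5) < 0.02

    def test_neutral_scrambling_tv_nonincreasing_and_small_at_28_cycles(
        self, design, pools
    ):
        cfg = RunConfig(method="standard", reads_per_replicate=100, n_replicates=1, seed=0)
        res = simulate_standard_pcr(pools["A"], pools["10"], 45.0, cfg, design.space)
        tv = res.tv_trajectory
        assert len(tv) == 28
        assert all(a >= b - 1e-12 for a, b in zip(tv, tv[1:]))
        assert tv[-1] < 0.02

    def test_reads_conserved_per_replicate(self, design, pools):
        cfg = RunConfig(method="standard", reads_per_replicate=1234, n_replicates=3, seed=9)
        res = simulate_standard_pcr(pools["B"], pools["10"], 55.0, cfg, design.space)
        assert (res.counts.sum(axis=1) == 1234).all()
        assert (res.counts.to_numpy() >= 0).all()


class TestErrorInjection:
    def test_zero_rate_is_identity(self):
        seq = "ACGTACGTACGT"
        assert apply_errors(seq, 0.0, 1) == seq

    def test_rate_one_changes_every_base(self):
        seq = "ACGT" * 50
        mutated = apply_errors(seq, 1.0, 1)
        assert all(a != b for a, b in zip(seq, mutated))

    def test_substitution_count_matches_binomial(self):
        rng = np.random.default_rng(7)
        seq = "ACGT" * 25_000  # 1e5 bases
        mutated = apply_errors(seq, 0.01, rng)
        n_sub = sum(a != b for a, b in zip(seq, mutated))
        mean, sd = 1000, math.sqrt(100_000 * 0.01 * 0.99)
        assert abs(n_sub - mean) < 4 * sd

    def test_deterministic_per_seed(self):
        seq = "ACGT" * 100
        assert apply_errors(seq, 0.1, 42) == apply_errors(seq, 0.1, 42)

    def test_invalid_rate_rejected(self):
        with pytest.raises(SimulationError):
            apply_errors("ACGT", 1.5, 0)


class TestReadEmission:
    def test_error_free_depcr_read_layout(self, design, pools):
        cfg = RunConfig(reads_per_replicate=50, n_replicates=1, seed=4)
        res = simulate_depcr(pools["A"], pools["1"], 45.0, cfg, design.space)
        reads = emit_reads(res, design.space)["rep1"]
        t0 = design.space.template_by_id["ST0"]
        v0 = design.space.primer_by_id["V0"]
        for r in reads:
            assert r.sequence[:20] == v0.core
            assert r.sequence[t0.recognition_slice] == t0.recognition_seq
            assert len(r.sequence) == len(t0.sequence)

    def test_standard_primer_region_exact_even_at_high_error(self, design, pools):
        cfg = RunConfig(
            method="standard", reads_per_replicate=300, n_replicates=1,
            per_base_error_rate=0.2, seed=6,
        )
        res = simulate_standard_pcr(pools["A"], pools["10"], 45.0, cfg, design.space)
        reads = emit_reads(res, design.space)["rep1"]
        cores = {p.core for p in design.primers}
        assert all(r.sequence[:20] in cores for r in reads)

    def test_depcr_errors_can_hit_primer_region(self, design, pools):
        cfg = RunConfig(
            reads_per_replicate=300, n_replicates=1, per_base_error_rate=0.2, seed=6
        )
        res = simulate_depcr(pools["A"], pools["1"], 45.0, cfg, design.space)
        reads = emit_reads(res, design.space)["rep1"]
        v0 = design.space.primer_by_id["V0"]
        assert any(r.sequence[:20] != v0.core for r in reads)

    def test_replicate_read_counts_match_config(self, design, pools, tmp_path):
        cfg = RunConfig(reads_per_replicate=120, n_replicates=2, seed=8)
        res = simulate_depcr(pools["A"], pools["10"], 55.0, cfg, design.space)
        paths = emit_reads(res, design.space, out_dir=tmp_path)
        from depcrsim.reads import read_fastq

        for rep, files in paths.items():
            assert len(list(read_fastq(files[0]))) == 120

    def test_paired_emission_overlaps_and_rejects_short_amplicons(self, design, pools):
        cfg = RunConfig(reads_per_replicate=5, n_replicates=1, seed=8)
        res = simulate_depcr(pools["A"], pools["1"], 45.0, cfg, design.space)
        merged = emit_reads(res, design.space)["rep1"][0]
        r1, r2 = paired_reads(merged, read_length=153)
        assert len(r1) == len(r2) == 153
        rc2 = r2.reverse_complement()
        assert merged.sequence.startswith(r1.sequence)
        assert merged.sequence.endswith(rc2.sequence)
        with pytest.raises(SimulationError):
            paired_reads(merged, read_length=1000)

    def test_debug_truth_encodes_source_pair(self, design, pools):
        cfg = RunConfig(reads_per_replicate=10, n_replicates=1, seed=8)
        res = simulate_depcr(pools["A"], pools["1"], 45.0, cfg, design.space)
        reads = emit_reads(res, design.space, debug_truth=True)["rep1"]
        assert all(r.description == "truth=V0:ST0" for r in reads)

    def test_quality_model_two_tiers(self):
        q = QualityModel(q_head=38, q_tail=28, tail_start=5).qualities(8)
        assert q == (38, 38, 38, 38, 28, 28, 28, 28)


class TestRunConfig:
    def test_default_cycles_by_method(self):
        assert RunConfig(method="depcr").effective_cycles == 2
        assert RunConfig(method="standard").effective_cycles == 28

    def test_validation(self):
        with pytest.raises(SimulationError):
            RunConfig(method="nested")
        with pytest.raises(SimulationError):
            RunConfig(per_base_error_rate=-0.1)
        with pytest.raises(SimulationError):
            RunConfig(cycles=0)
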