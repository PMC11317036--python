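"""Read classification: merging, filtering, exact-match assignment, matrices, rarefaction."""

import numpy as np
import pytest

from depcrsim.classify import (
    Assignment,
    InteractionMatrix,
    MappingIndex,
    ReadRecord,
    build_interaction_matrix,
    classify_read,
    classify_reads,
    merge_pairs,
    quality_filter,
    rarefy,
    split_matrix,
    trim_linker,
)
from depcrsim.design import CS1_LINKER
from depcrsim.errors import InputError, PipelineError
from depcrsim.simulate import RunConfig, emit_reads, paired_reads, simulate_depcr


def _read(seq, q=38, read_id="r1", rep="rep1"):
    return ReadRecord(read_id, seq, (q,) * len(seq), rep)


class TestMergePairs:
    def test_error_free_pair_merges_to_amplicon_length(self, design, pools):
        cfg = RunConfig(reads_per_replicate=20, n_replicates=1, seed=1)
        res = simulate_depcr(pools["A"], pools["1"], 45.0, cfg, design.space)
        full = emit_reads(res, design.space)["rep1"]
        pairs = [paired_reads(r) for r in full]
        merged, stats = merge_pairs([a for a, _ in pairs], [b for _, b in pairs])
        assert stats["merged"] == 20
        assert all(m.sequence == f.sequence for m, f in zip(merged, full))

    def test_non_overlapping_pair_dropped_and_counted(self):
        r1 = _read("A" * 30)
        r2 = _read("C" * 30).reverse_complement()
        merged, stats = merge_pairs([r1], [r2], min_overlap=12)
        assert merged == []
        assert stats["unmerged_no_overlap"] == 1

    def test_disagreement_resolved_toward_higher_quality(self):
        # 20-base overlap with one disagreement: R1 calls G at Q10, R2 calls T at Q40
        left = "ACGTACGTAC"
        overlap_r1 = "AAAAAAAAAAGAAAAAAAAA"
        overlap_true = "AAAAAAAAAATAAAAAAAAA"
        right = "TTGGCCAATT"
        r1 = ReadRecord("x", left + overlap_r1,
                        (40,) * 10 + (40,) * 10 + (10,) + (40,) * 9, "rep1")
        from depcrsim.design import reverse_complement
        r2_seq = reverse_complement(overlap_true + right)
        r2 = ReadRecord("x", r2_seq, (40,) * len(r2_seq), "rep1")
        merged, _ = merge_pairs([r1], [r2], min_overlap=12)
        assert merged[0].sequence == left + overlap_true + right

    def test_id_mismatch_raises(self):
        with pytest.raises(InputError):
            merge_pairs([_read("A" * 30, read_id="a")], [_read("T" * 30, read_id="b")])


class TestQualityFilter:
    def test_high_quality_retained_low_dropped(self):
        kept, stats = quality_filter([_read("ACGT", q=40), _read("ACGT", q=10)])
        assert len(kept) == 1 and stats["filtered_quality"] == 1

    def test_mean_exactly_at_threshold_is_retained(self):
        r = ReadRecord("r", "ACGT", (10, 20, 20, 30), "rep1")  # mean exactly 20
        kept, _ = quality_filter([r], min_mean_quality=20.0)
        assert kept == [r]


class TestClassifyRead:
    def test_error_free_read_assigned_to_true_pair(self, design):
        t0 = design.space.template_by_id["ST0"]
        read = _read(design.space.primer_by_id["V0"].core + t0.sequence[20:])
        a = classify_read(read, design.space)
        assert (a.status, a.primer_id, a.template_id) == ("assigned", "V0", "ST0")

    def test_nonvariant_substitution_distinguishes_modes(self, design):
        t0 = design.space.template_by_id["ST0"]
        seq = design.space.primer_by_id["V0"].core + t0.sequence[20:]
        # substitute a primer base that is NOT a variant position (index 0)
        mutated = ("C" if seq[0] != "C" else "G") + seq[1:]
        read = _read(mutated)
        assert classify_read(read, design.space, "full_primer").status == "unassigned_primer"
        a = classify_read(read, design.space, "variant_positions")
        assert (a.status, a.primer_id) == ("assigned", "V0")

    def test_unknown_recognition_window_unassigned(self, design):
        t0 = design.space.template_by_id["ST0"]
        seq = design.space.primer_by_id["V0"].core + t0.sequence[20:]
        sl = t0.recognition_slice
        bad = seq[:sl.start] + "A" * 12 + seq[sl.stop:]
        if bad[sl] in design.space.template_by_recognition:
            bad = seq[:sl.start] + "AACCGGTTAACC" + seq[sl.stop:]
        assert classify_read(_read(bad), design.space).status == "unassigned_recognition"

    def test_short_read_unassigned_recognition(self, design):
        assert (
            classify_read(_read("ACGT" * 10), design.space).status
            == "unassigned_recognition"
        )

    def test_out_of_design_pair_excluded(self, design):
        t1 = design.space.template_by_id["ST1"]
        read = _read(design.space.primer_by_id["V0"].core + t1.sequence[20:])
        a = classify_read(read, design.space, allowed_templates={"ST0"})
        assert a.status == "excluded_not_in_design"

    def test_assigned_requires_both_ids(self):
        with pytest.raises(InputError):
            Assignment("r", "assigned", primer_id="V0", template_id=None)

    def test_indexed_classifier_equals_brute_force_scan(self, design):
        # oracle: literal scan over all 640 mapping-file combinations
        mapping = design.space.to_mapping_frame()
        rec_sl = design.space.templates[0].recognition_slice
        rng = np.random.default_rng(0)
        cores = [p.core for p in design.primers]
        temps = list(design.templates)
        reads = []
        for i in range(2000):
            t = temps[rng.integers(len(temps))]
            seq = cores[rng.integers(len(cores))] + t.sequence[20:]
            arr = list(seq)
            for _ in range(rng.integers(0, 3)):
                arr[rng.integers(len(arr))] = "ACGT"[rng.integers(4)]
            reads.append(_read("".join(arr), read_id=f"r{i}"))

        def brute_force(read):
            for row in mapping.itertuples():
                if (
                    read.sequence[:20] == row.primer_core
                    and read.sequence[rec_sl] == row.recognition_seq
                ):
                    return (row.primer_id, row.template_id)
            return None

        for read in reads:
            a = classify_read(read, design.space, "full_primer")
            expected = brute_force(read)
            got = (a.primer_id, a.template_id) if a.status == "assigned" else None
            assert got == expected

    def test_mapping_tsv_index_classifies_identically(self, design, tmp_path):
        path = tmp_path / "mapping.tsv"
        design.space.to_mapping_tsv(path)
        index = MappingIndex.from_mapping_tsv(path)
        rng = np.random.default_rng(1)
        reads = []
        for i in range(300):
            t = design.templates[rng.integers(10)]
            p = design.primers[rng.integers(64)]
            reads.append(_read(p.core + t.sequence[20:], read_id=f"r{i}"))
        for mode in ("full_primer", "variant_positions"):
            a1 = classify_reads(reads, design.space, mode)
            a2 = classify_reads(reads, index, mode)
            assert a1 == a2


class TestInteractionMatrix:
    def test_single_pair_single_cell(self, design):
        t0 = design.space.template_by_id["ST0"]
        reads = [
            _read(design.space.primer_by_id["V0"].core + t0.sequence[20:], read_id=f"r{i}")
            for i in range(100)
        ]
        m = build_interaction_matrix(classify_reads(reads, design.space), design.space)
        assert m.counts.loc["rep1", ("V0", "ST0")] == 100
        assert m.row_sums()["rep1"] == 100

    def test_status_conservation(self, design):
        t0 = design.space.template_by_id["ST0"]
        good = _read(design.space.primer_by_id["V0"].core + t0.sequence[20:], read_id="g")
        short = _read("ACGT", read_id="s")
        bad_primer = _read("A" * 20 + t0.sequence[20:], read_id="b")
        if "A" * 20 in design.space.primer_by_core:
            bad_primer = good
        m = build_interaction_matrix(
            classify_reads([good, short, bad_primer], design.space), design.space
        )
        assert int(m.status_counts.sum().sum()) == 3
        assert int(m.counts.to_numpy().sum()) + int(
            m.status_counts[["unassigned_primer", "unassigned_recognition",
                             "excluded_not_in_design", "filtered_quality"]].sum().sum()
        ) == 3

    def test_simulator_round_trip_at_zero_error(self, design, pools):
        cfg = RunConfig(reads_per_replicate=1500, n_replicates=2, seed=13)
        res = simulate_depcr(pools["B"], pools["10"], 45.0, cfg, design.space)
        assignments = []
        for rep, reads in emit_reads(res, design.space).items():
            assignments.extend(
                classify_reads(reads, design.space,
                               allowed_primers=pools["10"].members,
                               allowed_templates=pools["B"].members)
            )
        m = build_interaction_matrix(
            assignments, design.space, template_pool=pools["B"], primer_pool=pools["10"]
        )
        assert (m.counts == res.counts.reindex(columns=m.counts.columns)
                .loc[m.counts.index]).all().all()

    def test_tsv_round_trip(self, design, pools, tmp_path):
        cfg = RunConfig(reads_per_replicate=200, n_replicates=2, seed=13)
        res = simulate_depcr(pools["B"], pools["10"], 45.0, cfg, design.space)
        m = InteractionMatrix(res.counts, {"method": "depcr"})
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        m2 = InteractionMatrix.from_tsv(path)
        assert (m2.counts == m.counts).all().all()

    def test_biom_json_shape(self, design, pools, tmp_path):
        import json

        cfg = RunConfig(reads_per_replicate=50, n_replicates=2, seed=13)
        res = simulate_depcr(pools["A"], pools["1"], 45.0, cfg, design.space)
        m = InteractionMatrix(res.counts)
        path = tmp_path / "m.biom.json"
        m.to_biom_json(path)
        doc = json.loads(path.read_text())
        assert doc["shape"] == [m.counts.shape[1], m.counts.shape[0]]
        assert sum(sum(r) for r in doc["data"]) == int(m.counts.to_numpy().sum())

    def test_negative_values_rejected(self, design, pools):
        cfg = RunConfig(reads_per_replicate=10, n_replicates=1, seed=0)
        res = simulate_depcr(pools["A"], pools["1"], 45.0, cfg, design.space)
        bad = res.counts.copy()
        bad.iloc[0, 0] = -1
        with pytest.raises(InputError):
            InteractionMatrix(bad)


class TestRarefaction:
    @pytest.fixture()
    def matrix(self, design, pools):
        cfg = RunConfig(reads_per_replicate=14_000, n_replicates=2, seed=21)
        res = simulate_depcr(pools["B"], pools["10"], 45.0, cfg, design.space)
        return InteractionMatrix(res.counts)

    def test_row_sums_exactly_depth_and_elementwise_bounded(self, matrix):
        r = rarefy(matrix, 7000, seed=1)
        assert (r.row_sums() == 7000).all()
        assert (r.counts.to_numpy() <= matrix.counts.to_numpy()).all()
        assert r.metadata["rarefaction_depth"] == 7000

    def test_row_at_exact_depth_returned_unchanged(self, matrix):
        total = int(matrix.row_sums().iloc[0])
        r = rarefy(matrix, total, seed=1)
        assert (r.counts.loc["rep1"] == matrix.counts.loc["rep1"]).all()

    def test_deterministic_per_seed(self, matrix):
        a = rarefy(matrix, 7000, seed=5)
        b = rarefy(matrix, 7000, seed=5)
        assert (a.counts == b.counts).all().all()

    def test_shallow_rows_dropped_with_record(self, matrix):
        shallow = matrix.counts.copy()
        shallow.loc["rep2"] = 0
        shallow.loc["rep2", ("V0", "ST0")] = 10
        r = rarefy(InteractionMatrix(shallow), 7000, seed=1)
        assert list(r.counts.index) == ["rep1"]
        assert r.metadata["rarefaction_dropped"] == ["rep2"]
        with pytest.raises(PipelineError):
            rarefy(InteractionMatrix(shallow.loc[["rep2"]]), 7000, seed=1)

    def test_hypergeometric_expectation(self):
        # row (8000, 4000, 2000) rarefied to 7000: E[cell_0] = 4000
        import pandas as pd

        cols = pd.MultiIndex.from_tuples(
            [("V0", "ST0"), ("V1", "ST1"), ("V2", "ST2")],
            names=["primer_id", "template_id"],
        )
        m = InteractionMatrix(pd.DataFrame([[8000, 4000, 2000]], index=["rep1"], columns=cols))
        vals = [rarefy(m, 7000, seed=s).counts.iloc[0, 0] for s in range(100)]
        mean = float(np.mean(vals))
        var_one = 7000 * (8000 / 14000) * (6000 / 14000) * (14000 - 7000) / (14000 - 1)
        se_mean = (var_one / 100) ** 0.5
        assert abs(mean - 4000) < 4 * se_mean


class TestMargins:
    def test_full_design_margins(self, design, pools):
        cfg = RunConfig(reads_per_replicate=3000, n_replicates=2, seed=2)
        res = simulate_depcr(pools["B"], pools["64"], 45.0, cfg, design.space)
        m = InteractionMatrix(res.counts)
        tm, pm = split_matrix(m)
        assert tm.shape[1] == 10 and pm.shape[1] == 64
        assert (tm.sum(axis=1) == m.row_sums()).all()
        assert (pm.sum(axis=1) == m.row_sums()).all()

    def test_single_cell_margins(self):
        import pandas as pd

        cols = pd.MultiIndex.from_tuples([("V0", "ST0")], names=["primer_id", "template_id"])
        m = InteractionMatrix(pd.DataFrame([[7]], index=["rep1"], columns=cols))
        tm, pm = split_matrix(m)
        assert tm.iloc[0, 0] == 7 and pm.iloc[0, 0] == 7


class TestLinkerTrim:
    def test_literal_prefix_removed(self):
        r = _read(CS1_LINKER + "ACGTACGT")
        t = trim_linker(r, CS1_LINKER)
        assert t.sequence == "ACGTACGT"
        assert trim_linker(t, CS1_LINKER).sequence == "ACGTACGT"
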