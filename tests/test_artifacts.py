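from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pb10x.artifacts import (
    CONCATEMER_LITERALS,
    EXTRACTION_LITERAL,
    METHOD_CONFIGS,
    AlignedReadRecord,
    MethodConfig,
    dedup_5p_reads,
    detect_concatemers,
    extract_5p_umi_reads,
    extract_upstream_context,
    flag_strand_invasion,
    invasion_pattern,
    records_from_tags,
    revcomp,
    strand_invasion_report,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)
PB = METHOD_CONFIGS["pb10x"]


def rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDetectConcatemers:
    def test_motif_flagged(self):
        flags, frac = detect_concatemers(["G" * 40 + "ATATGGGCTAC" + "G" * 39])
        assert flags == [True] and frac == 1.0

    def test_homopolymer_not_flagged(self):
        flags, frac = detect_concatemers(["A" * 90])
        assert flags == [False] and frac == 0.0

    def test_literal_k_mismatch(self):
        with pytest.raises(ValueError):
            detect_concatemers(["ACGT"], literals=("ATATGGGCTAC",), k=10)

    def test_read_and_revcomp_flag_identically(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            read = rand_dna(rng, 40) + "ATATGGGCTAC" + rand_dna(rng, 39)
            fwd, _ = detect_concatemers([read])
            rev, _ = detect_concatemers([revcomp(read)])
            assert fwd == rev  # both orientations are in the literal list

    def test_rate_recovery_on_simulation(self, artifact_sim):
        seqs = [s for _, s in artifact_sim.r2_records["pool1"]]
        _, frac = detect_concatemers(seqs)
        truth_frac = (artifact_sim.truth["artifact_class"] == "concatemer").mean()
        n = len(seqs)
        se = np.sqrt(0.10 * 0.90 / n)
        assert abs(frac - truth_frac) < 3 * se
        assert abs(frac - 0.10) < 3 * se


def brute_force_contains(seq, literal, hdist):
    L = len(literal)
    return any(
        sum(a != b for a, b in zip(seq[i : i + L], literal)) <= hdist
        for i in range(len(seq) - L + 1)
    )


class TestExtract5pUmiReads:
    def test_exact_literal_kept(self):
        recs = [("r1", "AAAA" + EXTRACTION_LITERAL + "AAAA")]
        assert extract_5p_umi_reads(recs) == recs

    def test_one_substitution_kept(self):
        lit = list(EXTRACTION_LITERAL)
        lit[4] = "A" if lit[4] != "A" else "C"
        recs = [("r1", "GG" + "".join(lit) + "GG")]
        assert extract_5p_umi_reads(recs, hdist=1) == recs
        assert extract_5p_umi_reads(recs, hdist=0) == []

    def test_agreement_with_brute_force(self):
        rng = np.random.default_rng(17)
        recs = []
        for i in range(1000):
            seq = rand_dna(rng, 26)
            if i % 5 == 0:  # spike in near-matches
                pos = int(rng.integers(0, 26 - 11))
                seq = seq[:pos] + EXTRACTION_LITERAL + seq[pos + 11 :]
                if i % 10 == 0:
                    j = pos + int(rng.integers(11))
                    seq = seq[:j] + "ACGT"[int(rng.integers(4))] + seq[j + 1 :]
            recs.append((f"r{i}", seq))
        kept = {rid for rid, _ in extract_5p_umi_reads(recs, hdist=1)}
        expected = {
            rid for rid, seq in recs if brute_force_contains(seq, EXTRACTION_LITERAL, 1)
        }
        assert kept == expected


class TestDedup:
    @staticmethod
    def rec(cell="c1", umi="A" * 9, ref="g1", start=0, strand="+"):
        return AlignedReadRecord(cell, umi, ref, start, strand)

    def test_identical_keys_collapse(self):
        assert len(dedup_5p_reads([self.rec(), self.rec()])) == 1

    def test_distinct_starts_kept(self):
        assert len(dedup_5p_reads([self.rec(start=0), self.rec(start=5)])) == 2

    def test_first_occurrence_wins(self):
        a, b = self.rec(), self.rec()
        a.upstream_context = "X"
        assert dedup_5p_reads([a, b])[0] is a

    def test_size_matches_set_oracle(self):
        rng = np.random.default_rng(3)
        recs = [
            self.rec(
                cell=f"c{rng.integers(3)}",
                umi=rand_dna(rng, 4),
                ref=f"g{rng.integers(3)}",
                start=int(rng.integers(4)),
                strand="+-"[int(rng.integers(2))],
            )
            for _ in range(500)
        ]
        keys = {(r.cell_id, r.umi, r.reference, r.start, r.strand) for r in recs}
        assert len(dedup_5p_reads(recs)) == len(keys)


class TestInvasionPattern:
    def test_pb10x(self):
        rec = AlignedReadRecord("c", "ACGTACGTA", "g", 50)
        pat = invasion_pattern(rec, PB)
        assert pat == "ACGTACGTA" + "TTTCTTATAT" + "GGG"
        assert len(pat) == 22

    def test_tenx_length_23(self):
        rec = AlignedReadRecord("c", "ACGTACGTAC", "g", 50)
        assert len(invasion_pattern(rec, METHOD_CONFIGS["tenx"])) == 23

    def test_ss3x_ww_split(self):
        rec = AlignedReadRecord("c", "ACGTACGTTA", "g", 50)
        assert invasion_pattern(rec, METHOD_CONFIGS["ss3x"]) == "ACGTACGT" + "TA" + "GGG"

    def test_umi_length_mismatch(self):
        with pytest.raises(ValueError):
            invasion_pattern(AlignedReadRecord("c", "ACGT", "g", 0), PB)


def brute_force_flag(window, pattern, max_mismatch):
    """Exhaustive anchored-offset x substitution enumeration."""
    L = len(pattern)
    if len(window) < L:
        return False, None
    best = min(
        sum(a != b for a, b in zip(window[off : off + L], pattern))
        for off in range(len(window) - L + 1)
    )
    return (best <= max_mismatch), (best if best <= max_mismatch else None)


def mk_record(umi, context):
    rec = AlignedReadRecord("c", umi, "g", 100)
    rec.upstream_context = context
    return rec


class TestFlagStrandInvasion:
    def test_exact_pattern_in_padded_window(self):
        umi = "ACGTACGTA"
        pattern = umi + "TTTCTTATAT" + "GGG"
        rec = mk_record(umi, "A" + pattern)  # 23-nt window, pattern at offset 1
        flagged, best = flag_strand_invasion(rec, PB)
        assert flagged and best == 0

    def test_three_vs_four_mismatches(self):
        umi = "ACGTACGTA"
        pattern = umi + "TTTCTTATAT" + "GGG"

        def mutate(p, k):
            out = list(p)
            for i in range(k):
                out[2 * i] = "A" if out[2 * i] != "A" else "C"
            return "".join(out)

        # exactly-3-mismatch window, with a non-compensating pad base
        rec3 = mk_record(umi, "T" + mutate(pattern, 3))
        flagged, best = flag_strand_invasion(rec3, PB)
        assert flagged and best == 3
        rec4 = mk_record(umi, "T" + mutate(pattern, 4))
        flagged4, _ = flag_strand_invasion(rec4, PB)
        # guard: ensure offset 0 can't compensate in this construction
        assert not flagged4

    def test_contig_start_empty_window(self):
        rec = mk_record("ACGTACGTA", "")
        assert flag_strand_invasion(rec, PB) == (False, None)

    def test_window_shorter_than_pattern(self):
        rec = mk_record("ACGTACGTA", "ACGT" * 5)  # 20 < 22
        assert flag_strand_invasion(rec, PB) == (False, None)

    @given(st.text(alphabet="ACGT", min_size=0, max_size=26), st.integers(0, 5))
    @settings(max_examples=300)
    def test_matches_brute_force_oracle(self, window, max_mm):
        umi = "ACGTACGTA"
        config = MethodConfig(name="PB10X_5p", umi_len=9, spacer="TTTCTTATAT",
                              max_mismatch=max_mm)
        rec = mk_record(umi, window)
        pattern = umi + "TTTCTTATAT" + "GGG"
        assert flag_strand_invasion(rec, config) == brute_force_flag(
            window[-config.window :], pattern, max_mm
        )

    def test_edit_semantics_tolerates_indel(self):
        umi = "ACGTACGTA"
        pattern = umi + "TTTCTTATAT" + "GGG"
        # delete one base from the pattern inside the window
        window = "TT" + pattern[:10] + pattern[11:]
        rec = mk_record(umi, window)
        assert not flag_strand_invasion(rec, PB, semantics="hamming")[0]
        flagged, best = flag_strand_invasion(rec, PB, semantics="edit")
        assert flagged and best == 1

    def test_monotonic_in_max_mismatch_and_window(self):
        rng = np.random.default_rng(8)
        umi = "ACGTACGTA"
        pattern = umi + "TTTCTTATAT" + "GGG"
        windows = []
        for _ in range(200):
            w = list(rand_dna(rng, 23))
            if rng.random() < 0.5:  # plant a mutated pattern
                k = int(rng.integers(0, 6))
                p = list(pattern)
                for i in rng.choice(22, size=k, replace=False):
                    p[i] = "ACGT"[int(rng.integers(4))]
                w[1:] = p
            windows.append("".join(w))

        def pct(max_mm, window_len):
            cfg = MethodConfig(name="PB10X_5p", umi_len=9, spacer="TTTCTTATAT",
                               window=window_len, max_mismatch=max_mm)
            recs = [mk_record(umi, w[-window_len:]) for w in windows]
            return sum(flag_strand_invasion(r, cfg)[0] for r in recs)

        assert pct(0, 23) <= pct(1, 23) <= pct(2, 23) <= pct(3, 23) <= pct(4, 23)
        assert pct(3, 22) <= pct(3, 23)


class TestUpstreamContext:
    REF = {"g1": "ACGTACGTAA" * 30}

    def test_plus_strand_window_23(self):
        ctx = extract_upstream_context(self.REF, "g1", 100, "+")
        assert len(ctx) == 23
        assert ctx == self.REF["g1"][77:100]

    def test_truncated_at_contig_start(self):
        assert extract_upstream_context(self.REF, "g1", 5, "+") == self.REF["g1"][:5]
        assert extract_upstream_context(self.REF, "g1", 0, "+") == ""

    def test_minus_strand_reverse_complemented(self):
        ctx = extract_upstream_context(self.REF, "g1", 100, "-")
        assert ctx == revcomp(self.REF["g1"][100:123])


class TestInvasionReport:
    def test_all_invasion_zero_mutation(self, layout24, barcodes24):
        from pb10x.simulate import make_transcriptome, simulate_expression, simulate_reads

        tx = make_transcriptome(60, seed=2)
        expr = simulate_expression(layout24, tx, seed=3)
        sim = simulate_reads(
            expr, layout24, depth_per_cell=20, invasion_rate=1.0, seed=5,
            transcriptome=tx,
        )
        report = strand_invasion_report(
            records_from_tags(sim.tags), sim.reference, PB
        )
        assert report.percent_flagged == 100.0
        assert report.mismatch_histogram[0] == report.n_flagged

    def test_injected_mismatches_land_in_histogram(self, layout24):
        from pb10x.simulate import make_transcriptome, simulate_expression, simulate_reads

        tx = make_transcriptome(60, seed=2)
        expr = simulate_expression(layout24, tx, seed=3)
        sim = simulate_reads(
            expr, layout24, depth_per_cell=20, invasion_rate=1.0, seed=5,
            transcriptome=tx, invasion_mismatches=2,
        )
        report = strand_invasion_report(records_from_tags(sim.tags), sim.reference, PB)
        assert report.percent_flagged == 100.0
        assert report.mismatch_histogram[2] == report.n_flagged

    def test_false_positive_floor_near_zero(self):
        rng = np.random.default_rng(21)
        recs = []
        for i in range(2000):
            rec = AlignedReadRecord(f"c{i}", rand_dna(rng, 9), "g", 100)
            rec.upstream_context = rand_dna(rng, 23)
            recs.append(rec)
        report = strand_invasion_report(recs, None, PB)
        assert report.percent_flagged < 1.0  # floor reported, not asserted at 0

    def test_rate_recovery(self, artifact_sim):
        records = records_from_tags(artifact_sim.tags)
        report = strand_invasion_report(records, artifact_sim.reference, PB)
        dedup = dedup_5p_reads(records)
        truth = artifact_sim.truth.set_index("read_id")
        tag_truth = truth.loc[artifact_sim.tags["read_id"]]
        expected_pct = 100.0 * (tag_truth["artifact_class"] == "strand_invasion").mean()
        n = report.n_dedup_reads
        se_pct = 100 * np.sqrt(0.2 * 0.8 / n)
        assert abs(report.percent_flagged - expected_pct) < 3 * se_pct

    def test_histogram_sums_to_flagged(self, artifact_sim):
        report = strand_invasion_report(
            records_from_tags(artifact_sim.tags), artifact_sim.reference, PB
        )
        assert sum(report.mismatch_histogram.values()) == report.n_flagged
        assert 0 <= report.percent_flagged <= 100

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            strand_invasion_report([], None, PB)


def test_method_configs_match_protocols():
    assert METHOD_CONFIGS["ss3x"].umi_len == 10
    assert METHOD_CONFIGS["pb10x"].umi_len == 9
    assert METHOD_CONFIGS["tenx"].umi_len == 10
    for cfg in METHOD_CONFIGS.values():
        assert cfg.window == 23
        assert cfg.max_mismatch == 3
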