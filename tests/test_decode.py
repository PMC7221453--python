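import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from covselect._bases import seq_to_ascii, umi_int_to_seq
from covselect.decode import (
    ReadAssignment,
    assign_member,
    collapse_umi,
    decode_fastq,
    decode_read_matrix,
    decode_reads,
    estimate_molecules,
    parse_read,
)
from covselect.library import assemble_tag
from covselect.simulate import (
    resin_condition,
    sample_read_matrix,
    simulate_selection,
    write_fastq,
)


def _tag(design, member_idx, umi):
    return assemble_tag(
        design.members[member_idx], umi, design.schema, design.codon_books
    )


class TestParseRead:
    def test_error_free_round_trip(self, tiny_design):
        seq = _tag(tiny_design, 4, "ACGTAC")
        p = parse_read(seq, tiny_design.schema)
        assert p.ok and p.codons == ("CCCC", "CGCG") and p.umi == "ACGTAC"

    def test_three_upstream_errors_rejected(self, tiny_design):
        seq = _tag(tiny_design, 0, "ACGTAC")
        bad = "TTT" + seq[3:]  # upstream ACGTACGT -> TTTTACGT: 3 mismatches
        assert sum(a != b for a, b in zip(bad[:8], "ACGTACGT")) == 3
        p = parse_read(bad, tiny_design.schema)
        assert not p.ok and p.reason == "constant_mismatch"

    def test_two_constant_errors_tolerated(self, tiny_design):
        seq = _tag(tiny_design, 0, "ACGTAC")
        bad = "TT" + seq[2:]
        assert parse_read(bad, tiny_design.schema).ok

    def test_short_read_truncated(self, tiny_design):
        p = parse_read("ACGT", tiny_design.schema)
        assert not p.ok and p.reason == "truncated"


class TestAssignMember:
    def test_exact_codons(self, tiny_design):
        status, mid, ncorr, reason = assign_member(("CCCC", "CGCG"), tiny_design)
        assert status == "assigned" and mid == 4 and ncorr == 0

    def test_single_substitution_corrected(self, tiny_design):
        status, mid, ncorr, _ = assign_member(("CCCA", "CGCG"), tiny_design)
        assert status == "assigned" and mid == 4 and ncorr == 1

    def test_double_substitution_unassigned(self, tiny_design):
        # brute force: distance >= 2 to every codon in the cycle-0 book
        status, mid, _, reason = assign_member(("CCAA", "CGCG"), tiny_design)
        assert status == "unassigned" and reason == "bad_codon"

    def test_valid_codons_nonexistent_combination(self, tiny_design):
        # (GGGG, GTGT) = indices (2, 2), deliberately absent from the library
        status, mid, _, reason = assign_member(("GGGG", "GTGT"), tiny_design)
        assert status == "unassigned" and reason == "no_member"


class TestCollapseUmi:
    def test_identical_n12_counted_as_single_event(self):
        reads = [
            ReadAssignment(0, "assigned", member_id=1, umi="AAAAAA"),
            ReadAssignment(1, "assigned", member_id=1, umi="AAAAAA"),
            ReadAssignment(2, "assigned", member_id=1, umi="CCCCCC"),
        ]
        table = collapse_umi(reads, umi_space=4 ** 6)
        row = table.counts.iloc[0]
        assert row["raw_reads"] == 3 and row["unique_events"] == 2

    def test_pcr_duplicates_collapse_to_one(self):
        reads = [
            ReadAssignment(i, "assigned", member_id=7, umi="ACGTAC") for i in range(1000)
        ]
        table = collapse_umi(reads, umi_space=4 ** 6)
        assert table.counts.iloc[0]["unique_events"] == 1
        assert table.counts.iloc[0]["raw_reads"] == 1000

    def test_matches_brute_force_pair_oracle(self, rng):
        """Randomised stream equals an independent set-of-pairs oracle exactly."""
        n = 10_000
        members = rng.integers(0, 50, n)
        umis = rng.integers(0, 200, n)
        df = pd.DataFrame(
            {
                "status": pd.Categorical(
                    ["assigned"] * n, categories=["assigned", "unassigned", "ambiguous"]
                ),
                "member_id": members,
                "umi": [umi_int_to_seq(int(u), 6).encode() for u in umis],
            }
        )
        table = collapse_umi(df, umi_space=4 ** 6)
        oracle: dict[int, set] = {}
        raw: dict[int, int] = {}
        for m, u in zip(members, umis):
            oracle.setdefault(int(m), set()).add(int(u))
            raw[int(m)] = raw.get(int(m), 0) + 1
        got = table.counts.set_index("member_id")
        assert len(got) == len(oracle)
        for m, s in oracle.items():
            assert got.loc[m, "unique_events"] == len(s)
            assert got.loc[m, "raw_reads"] == raw[m]

    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 15)), min_size=0, max_size=200
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_property_against_set_oracle(self, pairs):
        reads = [
            ReadAssignment(i, "assigned", member_id=m, umi=umi_int_to_seq(u, 3))
            for i, (m, u) in enumerate(pairs)
        ]
        table = collapse_umi(reads, umi_space=4 ** 3)
        expect = len({(m, u) for m, u in pairs})
        assert table.counts["unique_events"].sum() == expect
        assert table.counts["raw_reads"].sum() == len(pairs)

    def test_empty_stream(self):
        table = collapse_umi([], umi_space=4 ** 6)
        assert table.counts.empty and table.total_assigned == 0


class TestEstimateMolecules:
    def test_zero(self):
        assert estimate_molecules(0, 4 ** 12) == 0.0

    def test_taylor_limit(self):
        s = 4 ** 12
        assert estimate_molecules(100, s) / 100 == pytest.approx(1.0, rel=1e-5)

    def test_n12_occupancy_formula(self):
        # 1e6 distinct UMIs of the 16.8M space -> about 1.031e6 molecules
        got = estimate_molecules(1_000_000, 16_777_216)
        assert got == pytest.approx(-16_777_216 * math.log1p(-1_000_000 / 16_777_216))
        assert got == pytest.approx(1.0305e6, rel=1e-3)

    def test_monte_carlo_inversion(self, rng):
        """Throw n balls into S bins, count occupied, invert: ≤1% relative
        error up to occupancy S/10."""
        S = 4 ** 6  # 4096
        for n in (50, 200, 400):
            occupied = np.empty(200)
            for i in range(200):
                occupied[i] = len(np.unique(rng.integers(0, S, n)))
            est = estimate_molecules(float(occupied.mean()), S)
            assert est == pytest.approx(n, rel=0.01)

    def test_saturated_space_fails(self):
        with pytest.raises(ValueError, match="saturated"):
            estimate_molecules(4 ** 6, 4 ** 6)


class TestDecodeEndToEnd:
    def test_error_free_round_trip_recovers_truth(self, small_design):
        """With no sequencing errors and deep coverage, decoding recovers the
        ground-truth distinct (member, UMI) pairs exactly."""
        design = small_design
        cond = resin_condition(2.0, seed=21, n_reads=60_000, seq_error_rate=0.0)
        pool = simulate_selection(design, cond)
        reads, _ = sample_read_matrix(
            pool, np.ones(pool.n_molecules), design, 60_000, 0.0, seed=22
        )
        frame, stats = decode_reads(reads, design)
        assert stats.assigned == stats.total_reads  # 100% assigned
        table = collapse_umi(frame, umi_space=design.schema.umi_space)
        truth = pool.distinct_umis_per_member()
        truth.index = [design.members[i].member_id for i in truth.index]
        got = table.counts.set_index("member_id")["unique_events"]
        # deep coverage: every molecule seen at least once
        assert got.sort_index().equals(truth.sort_index().astype(got.dtype))
        # collision inversion stays within 1% of retained molecules
        est = table.counts["estimated_molecules"].sum()
        assert est == pytest.approx(pool.n_molecules, rel=0.01)

    def test_errors_never_misassign_across_members(self, small_design):
        """min-Hamming-3 books: errors lose reads but never relabel them."""
        design = small_design
        cond = resin_condition(2.0, seed=23)
        pool = simulate_selection(design, cond)
        n_reads, rate = 30_000, 0.005
        rng = np.random.default_rng(24)
        reads, mol_idx = sample_read_matrix(
            pool, np.ones(pool.n_molecules), design, n_reads, rate, rng=rng
        )
        frame, stats = decode_reads(reads, design)
        L = design.schema.layout_length
        assert stats.assigned < stats.total_reads
        assert stats.assigned > n_reads * (1 - L * rate)
        true_members = np.array(
            [design.members[pool.molecule_member[m]].member_id for m in mol_idx]
        )
        assigned = frame["status"].to_numpy() == "assigned"
        assert (frame.loc[assigned, "member_id"].to_numpy() == true_members[assigned]).all()

    def test_phantom_umi_events_bias_upward(self, small_design):
        design = small_design
        cond = resin_condition(2.0, seed=25)
        pool = simulate_selection(design, cond)
        rng = np.random.default_rng(26)
        reads, _ = sample_read_matrix(
            pool, np.ones(pool.n_molecules) * 20, design, 50_000, 0.01, rng=rng
        )
        frame, _ = decode_reads(reads, design)
        table = collapse_umi(frame, umi_space=design.schema.umi_space)
        assert table.counts["unique_events"].sum() > pool.distinct_umis_per_member().sum()

    def test_read_order_invariance(self, small_design, rng):
        design = small_design
        cond = resin_condition(2.0, seed=27, n_reads=5_000, seq_error_rate=0.005)
        pool = simulate_selection(design, cond)
        reads, _ = sample_read_matrix(
            pool, np.ones(pool.n_molecules), design, 5_000, 0.005, seed=28
        )
        t1 = collapse_umi(decode_reads(reads, design)[0], umi_space=4 ** 12)
        perm = rng.permutation(5_000)
        t2 = collapse_umi(decode_reads(reads[perm], design)[0], umi_space=4 ** 12)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_vectorised_path_matches_scalar_reference(self, tiny_design, rng):
        """The matrix decoder and the per-read parse/assign path agree."""
        design = tiny_design
        schema = design.schema
        seqs = []
        for _ in range(300):
            m = int(rng.integers(0, len(design.members)))
            umi = umi_int_to_seq(int(rng.integers(0, 4 ** 6)), 6)
            s = np.frombuffer(_tag(design, m, umi).encode(), np.uint8).copy()
            nerr = int(rng.integers(0, 4))
            pos = rng.integers(0, schema.layout_length, nerr)
            s[pos] = np.frombuffer(b"ACGT", np.uint8)[rng.integers(0, 4, nerr)]
            seqs.append(s.tobytes().decode())
        frame, _ = decode_reads(seqs, design)
        for i, s in enumerate(seqs):
            p = parse_read(s, schema)
            if not p.ok:
                assert frame.loc[i, "status"] != "assigned"
                continue
            status, mid, ncorr, _ = assign_member(p.codons, design)
            assert frame.loc[i, "status"] == status
            if status == "assigned":
                assert frame.loc[i, "member_id"] == mid
                assert frame.loc[i, "n_corrected"] == ncorr

    def test_conservation_partition(self, small_design):
        design = small_design
        cond = resin_condition(2.0, seed=29)
        pool = simulate_selection(design, cond)
        reads, _ = sample_read_matrix(
            pool, np.ones(pool.n_molecules), design, 10_000, 0.02, seed=30
        )
        _, stats = decode_reads(reads, design)
        assert stats.assigned + stats.unassigned + stats.ambiguous == 10_000

    def test_decode_fastq_round_trip(self, small_design, tmp_path):
        design = small_design
        cond = resin_condition(2.0, seed=31, n_reads=2_000, seq_error_rate=0.0)
        pool = simulate_selection(design, cond)
        reads, mol_idx = sample_read_matrix(
            pool, np.ones(pool.n_molecules), design, 2_000, 0.0, seed=32
        )
        path = tmp_path / "r.fastq"
        write_fastq(reads, path, mol_idx)
        table, stats = decode_fastq(path, design)
        assert stats.total_reads == 2_000 and stats.assigned == 2_000
        direct = collapse_umi(decode_reads(reads, design)[0], umi_space=4 ** 12)
        pd.testing.assert_frame_equal(table.counts, direct.counts)

    def test_decode_fastq_empty(self, small_design, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        table, stats = decode_fastq(path, small_design)
        assert stats.total_reads == 0 and table.counts.empty

    def test_decode_fastq_malformed(self, small_design, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\nMISSING_PLUS\nIIII\n")
        with pytest.raises(ValueError, match="malformed FASTQ"):
            decode_fastq(path, small_design)

    def test_truncated_reads_reported(self, small_design):
        design = small_design
        seqs = ["ACGT", _tag(design, 0, "ACGTACGTACGT")]
        frame, stats = decode_reads(seqs, design)
        assert frame.loc[0, "reason"] == "truncated"
        assert stats.assigned == 1 and stats.unassigned == 1
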