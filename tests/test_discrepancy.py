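import numpy as np
import pytest

from alnbench.align_io import Alignment
from alnbench.blocks import Subfamily
from alnbench.discrepancy import (
    Discrepancy,
    detect_deleted_segments,
    detect_inserted_segments,
    detect_outlier_segments,
    detect_terminal_errors,
    core_blocks_of,
    filter_reliable,
    scan,
    ReliabilityReport,
)
from alnbench.synthetic import BlockSpec, FamilySpec, generate, plant_discrepancy

from conftest import random_alignment


def _aln_with_starts(starts, length=120):
    """One residue run per sequence beginning at the given 1-based column."""
    ids, seqs = [], []
    for i, s in enumerate(starts):
        ids.append(f"s{i}")
        seqs.append("-" * (s - 1) + "A" * (length - s + 1))
    return Alignment(tuple(ids), tuple(seqs))


class TestTerminalErrors:
    def test_quartile_window_flags_the_straggler(self):
        # N-terminal columns 1,1,1,2,100: Q1=1, Q3=2, open window (-9, 12)
        aln = _aln_with_starts([1, 1, 1, 2, 100])
        flags = detect_terminal_errors(aln, Subfamily("S1", aln.ids))
        n_flags = [d for d in flags if d.terminal_side == "N"]
        assert [d.seq_id for d in n_flags] == ["s4"]

    def test_uniform_starts_give_no_flags(self):
        aln = _aln_with_starts([1, 1, 1, 1, 1])
        flags = detect_terminal_errors(aln, Subfamily("S1", aln.ids))
        assert [d for d in flags if d.terminal_side == "N"] == []

    def test_terminal_exactly_on_window_edge_is_flagged(self):
        # starts all 1 -> Q1 = Q3 = 1 (0-based 0); edge = Q3 + 10
        starts = [1, 1, 1, 1, 11]  # 0-based terminal 10 == Q3 + 10 exactly
        aln = _aln_with_starts(starts)
        flags = detect_terminal_errors(aln, Subfamily("S1", aln.ids))
        assert any(d.seq_id == "s4" and d.terminal_side == "N" for d in flags)

    def test_small_subfamily_yields_no_flags(self):
        aln = _aln_with_starts([1, 1, 100])
        assert detect_terminal_errors(aln, Subfamily("S1", aln.ids)) == []


class TestOutlierSegments:
    def test_planted_shuffle_is_flagged_and_nothing_else(self, model):
        hits = 0
        for seed in range(10):
            spec = FamilySpec(
                subfamily_sizes=(8,), seed=seed,
                blocks=tuple(BlockSpec(24, (0,), 0.9) for _ in range(3)),
                linker_length=12, linker_jitter=2,
            )
            t = generate(spec)
            target = t.alignment.ids[0]
            t = plant_discrepancy(
                t, "outlier_segment", 0, seed=seed, target_id=target,
                block_id=t.blocks[1].block_id,
            )
            sf = t.subfamilies[0]
            cores = core_blocks_of(t.alignment, sf, model=model)
            flags = detect_outlier_segments(t.alignment, sf, cores, model=model)
            assert {d.seq_id for d in flags} <= {target}
            if any(d.seq_id == target for d in flags):
                hits += 1
        assert hits >= 9

    def test_clean_family_has_no_flags(self, small_truth, model):
        sf = small_truth.subfamilies[0]
        cores = core_blocks_of(small_truth.alignment, sf, model=model)
        assert detect_outlier_segments(
            small_truth.alignment, sf, cores, model=model
        ) == []

    def test_singleton_subfamily_degenerate(self, small_truth, model):
        sf = Subfamily("S1", small_truth.alignment.ids[:1])
        assert detect_outlier_segments(
            small_truth.alignment, sf, [], model=model
        ) == []

    def test_identical_members_never_flagged(self, model):
        aln = Alignment(
            tuple(f"s{i}" for i in range(6)), ("ACDEFGHIKLMNPQRS",) * 6
        )
        sf = Subfamily("S1", aln.ids)
        cores = core_blocks_of(aln, sf, model=model)
        assert cores  # fully conserved -> one core block
        assert detect_outlier_segments(aln, sf, cores, model=model) == []


def _insertion_alignment(n_members=5, gap_len=11):
    """Full columns flanking a run occupied by s0 alone."""
    left = "ACDEFGHIKL"
    right = "MNPQRSTVWY"
    ins = "W" * gap_len
    rows = [left + ins + right]
    rows += [left + "-" * gap_len + right for _ in range(n_members - 1)]
    return Alignment(tuple(f"s{i}" for i in range(n_members)), tuple(rows))


class TestInsertedSegments:
    def test_long_single_sequence_run_is_flagged(self):
        aln = _insertion_alignment(gap_len=11)  # j - i = 12
        sf = Subfamily("S1", aln.ids)
        (d,) = detect_inserted_segments(aln, sf)
        assert d.seq_id == "s0"
        assert (d.start, d.stop) == (10, 21)

    def test_short_run_is_below_rule_threshold(self):
        aln = _insertion_alignment(gap_len=7)  # j - i = 8 < 10
        assert detect_inserted_segments(aln, Subfamily("S1", aln.ids)) == []

    def test_interleaved_residues_break_the_single_sequence_condition(self):
        left, right = "ACDEFGHIKL", "MNPQRSTVWY"
        run0 = "WWWWW-WWWWW"
        run1 = "-----W-----"
        rows = [left + run0 + right, left + run1 + right]
        rows += [left + "-" * 11 + right for _ in range(3)]
        aln = Alignment(tuple(f"s{i}" for i in range(5)), tuple(rows))
        assert detect_inserted_segments(aln, Subfamily("S1", aln.ids)) == []

    def test_excluded_fragments_leave_the_occupancy_counts(self):
        aln = _insertion_alignment(gap_len=11)
        # excluding the inserted sequence removes the intervening run
        sf = Subfamily("S1", aln.ids)
        assert detect_inserted_segments(aln, sf, excluded={"s0"}) == []


def _deletion_alignment(n_members=6, gap_len=15):
    core = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRS"[: gap_len + 10]
    left, right = "ACDEF", "VWYAC"
    mid = core[: gap_len]
    rows = [left + "-" * gap_len + right]
    rows += [left + mid + right for _ in range(n_members - 1)]
    return Alignment(tuple(f"s{i}" for i in range(n_members)), tuple(rows))


class TestDeletedSegments:
    def test_long_all_gap_run_is_flagged(self):
        aln = _deletion_alignment(gap_len=15)
        (d,) = detect_deleted_segments(aln, Subfamily("S1", aln.ids))
        assert d.seq_id == "s0"
        assert (d.start, d.stop) == (5, 20)

    def test_second_gapped_member_breaks_occupancy_condition(self):
        aln = _deletion_alignment(gap_len=15)
        rows = list(aln.seqs)
        rows[1] = rows[1][:10] + "-" + rows[1][11:]  # second gap inside run
        aln2 = Alignment(aln.ids, tuple(rows))
        assert detect_deleted_segments(aln2, Subfamily("S1", aln2.ids)) == []

    def test_edge_deletion_is_out_of_rule_scope(self):
        # missing stretch at the alignment edge: no full boundary column on
        # the left, so the terminal rule (not this one) governs
        rows = ["-" * 15 + "ACDEFGHIKL"]
        rows += ["WYACDEFGHIKLMNP"[:15] + "ACDEFGHIKL" for _ in range(5)]
        aln = Alignment(tuple(f"s{i}" for i in range(6)), tuple(rows))
        assert detect_deleted_segments(aln, Subfamily("S1", aln.ids)) == []


class TestBruteForceEquivalence:
    """Rules 3-4 are pure set logic: they must agree with a literal scan
    over all column pairs (i, j)."""

    @staticmethod
    def _brute_force(aln, members, kind, min_span=10):
        n = len(members)
        rows = {s: aln.row(s) for s in members}
        occ = [
            sum(1 for s in members if rows[s][c] != "-")
            for c in range(aln.n_cols)
        ]
        found = set()
        for i in range(aln.n_cols):
            for j in range(i + min_span, aln.n_cols):
                if occ[i] != n or occ[j] != n:
                    continue
                between = range(i + 1, j)
                if kind == "inserted":
                    if not all(occ[k] == 1 for k in between):
                        continue
                    owners = {
                        s for k in between for s in members if rows[s][k] != "-"
                    }
                    if len(owners) == 1:
                        found.add((owners.pop(), i + 1, j))
                else:
                    if not all(occ[k] == n - 1 for k in between):
                        continue
                    absent = {
                        s for s in members
                        if all(rows[s][k] == "-" for k in between)
                    }
                    present_gaps = {
                        s for k in between for s in members if rows[s][k] == "-"
                    }
                    if len(absent) == 1 and present_gaps == absent:
                        found.add((absent.pop(), i + 1, j))
        # keep only maximal reports: drop pairs strictly inside another
        maximal = {
            f for f in found
            if not any(
                g != f and g[0] == f[0] and g[1] <= f[1] and g[2] >= f[2]
                for g in found
            )
        }
        return maximal

    def test_detectors_match_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(3, 7))
            m = int(rng.integers(20, 60))
            aln = random_alignment(rng, n, m, gap_frac=0.35)
            sf = Subfamily("S1", aln.ids)
            got_ins = {
                (d.seq_id, d.start, d.stop)
                for d in detect_inserted_segments(aln, sf)
            }
            got_del = {
                (d.seq_id, d.start, d.stop)
                for d in detect_deleted_segments(aln, sf)
            }
            assert got_ins == self._brute_force(aln, list(aln.ids), "inserted")
            assert got_del == self._brute_force(aln, list(aln.ids), "deleted")


class TestScan:
    def test_one_plant_of_each_kind_gives_exactly_four_flags(self, model):
        for seed in range(5):
            spec = FamilySpec(
                subfamily_sizes=(8,), seed=seed,
                blocks=tuple(BlockSpec(24, (0,), 0.9) for _ in range(4)),
                linker_length=12, linker_jitter=2,
            )
            t = generate(spec)
            hosts = [b.block_id for b in t.blocks]
            ids = t.alignment.ids
            t = plant_discrepancy(t, "outlier_segment", 0, seed=seed * 10 + 1,
                                  target_id=ids[0], block_id=hosts[0])
            t = plant_discrepancy(t, "inserted_segment", 12, seed=seed * 10 + 2,
                                  target_id=ids[1], block_id=hosts[1])
            t = plant_discrepancy(t, "deleted_segment", 12, seed=seed * 10 + 3,
                                  target_id=ids[2], block_id=hosts[2])
            t = plant_discrepancy(t, "terminal_error", 25, seed=seed * 10 + 4,
                                  target_id=ids[3])
            rep = scan(t.alignment, subfamilies=t.subfamilies, model=model)
            got = {(d.seq_id, d.kind) for d in rep.discrepancies}
            want = {(d.seq_id, d.kind) for d in t.discrepancies}
            assert got == want
            assert len(rep.discrepancies) == 4

    def test_clean_family_is_fully_reliable(self, small_truth, model):
        rep = scan(
            small_truth.alignment, subfamilies=small_truth.subfamilies,
            model=model,
        )
        assert rep.reliable_ids == list(small_truth.alignment.ids)
        assert rep.flagged_ids == set()

    def test_determinism(self, small_truth, model):
        r1 = scan(small_truth.alignment, model=model)
        r2 = scan(small_truth.alignment, model=model)
        assert r1.discrepancies == r2.discrepancies

    def test_report_partitions_the_ids(self, model):
        spec = FamilySpec(
            subfamily_sizes=(8,), seed=3,
            blocks=tuple(BlockSpec(24, (0,), 0.9) for _ in range(3)),
            linker_length=12, linker_jitter=2,
        )
        t = generate(spec)
        t = plant_discrepancy(t, "terminal_error", 25, seed=5,
                              target_id=t.alignment.ids[0])
        rep = scan(t.alignment, subfamilies=t.subfamilies, model=model)
        assert set(rep.reliable_ids) | rep.flagged_ids == set(t.alignment.ids)
        assert set(rep.reliable_ids) & rep.flagged_ids == set()


class TestFilterReliable:
    def test_no_flags_is_identity(self, small_truth):
        rep = ReliabilityReport(ids=small_truth.alignment.ids)
        filtered, blocks = filter_reliable(
            small_truth.alignment, rep, small_truth.blocks
        )
        assert filtered == small_truth.alignment
        assert blocks == small_truth.blocks

    def test_empty_reliable_set_is_an_error(self):
        aln = Alignment(("a",), ("ACD",))
        rep = ReliabilityReport(
            ids=aln.ids,
            discrepancies=[
                Discrepancy("a", "terminal_error", 0, 1, terminal_side="N")
            ],
        )
        with pytest.raises(ValueError):
            filter_reliable(aln, rep)

    def test_surviving_residue_pairings_preserved(self, small_truth):
        aln = small_truth.alignment
        flagged = aln.ids[2]
        rep = ReliabilityReport(
            ids=aln.ids,
            discrepancies=[
                Discrepancy(flagged, "terminal_error", 0, 1, terminal_side="N")
            ],
        )
        filtered, _ = filter_reliable(aln, rep, small_truth.blocks)
        assert list(filtered.ids) == [i for i in aln.ids if i != flagged]

        def pairings(a, sids):
            out = set()
            for x in sids:
                for y in sids:
                    if x >= y:
                        continue
                    rx, ry = a.row(x), a.row(y)
                    kx = ky = 0
                    for c in range(a.n_cols):
                        cx, cy = rx[c] != "-", ry[c] != "-"
                        if cx and cy:
                            out.add((x, y, kx, ky))
                        kx += cx
                        ky += cy
            return out

        survivors = list(filtered.ids)
        assert pairings(aln, survivors) == pairings(filtered, survivors)
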