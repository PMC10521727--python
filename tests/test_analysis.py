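from dataclasses import replace

import numpy as np
import pytest

from gdpanedit import (NanobodyConstruct, RegionMap, SequenceRecord,
                       align_to_reference, analyze_pool, call_mutations,
                       exclude_artifacts, get_condition, net_ledger,
                       simulate_pool, summarize)
from gdpanedit.analysis import AlignmentRejected, MutationCall

from conftest import random_dna


def _construct_of_length(rng, L):
    seq = random_dna(rng, L)
    rmap = RegionMap((("CDR1", 30, 51), ("CDR2", 90, 111),
                      ("CDR3", 150, 171)), orf_offset=0)
    return NanobodyConstruct(SequenceRecord("ref", seq), rmap)


class TestAlign:
    def test_identity(self, reference):
        aln = align_to_reference(reference.record, reference)
        assert aln.blocks == []
        assert aln.identity == 1.0

    def test_deletion_left_aligned_among_equal_placements(self, reference):
        """A 9-nt deletion must land at the leftmost equal-score placement."""
        mutant_seq = reference.seq[:100] + reference.seq[109:]
        aln = align_to_reference(SequenceRecord("d", mutant_seq), reference)
        blocks = [b for b in aln.blocks if b[0] == "del"]
        assert len(blocks) == 1
        _, start, end, _ = blocks[0]
        assert end - start == 9
        # oracle: every start whose deletion reproduces the same string
        equal = [s for s in range(len(reference) - 9 + 1)
                 if reference.seq[:s] + reference.seq[s + 9:] == mutant_seq]
        assert start == min(equal)

    def test_unrelated_sequence_rejected(self, reference, rng):
        junk = SequenceRecord("junk", random_dna(rng, len(reference)))
        with pytest.raises(AlignmentRejected):
            align_to_reference(junk, reference)


class TestCalls:
    def test_single_substitution(self, reference):
        seq = list(reference.seq)
        pos = 42
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        aln = align_to_reference(SequenceRecord("m", "".join(seq)), reference)
        calls, n_ins = call_mutations(aln, reference, "m")
        assert n_ins == 0
        assert len(calls) == 1
        c = calls[0]
        assert (c.pos0, c.ref) == (pos, reference.seq[pos])
        assert c.region == "FR1"

    def test_deletion_called_per_position(self, reference):
        s, _ = reference.map.interval("CDR2")
        mutant = SequenceRecord("d9", reference.seq[:s] + reference.seq[s + 9:])
        aln = align_to_reference(mutant, reference)
        calls, _ = call_mutations(aln, reference, "d9")
        dels = [c for c in calls if c.is_deletion]
        assert len(dels) == 9
        assert [c.pos0 for c in dels] == sorted(c.pos0 for c in dels)

    def test_insertion_flagged_not_called(self, reference):
        mutant = SequenceRecord("ins", reference.seq[:60] + "TTT"
                                + reference.seq[60:])
        aln = align_to_reference(mutant, reference)
        calls, n_ins = call_mutations(aln, reference, "ins")
        assert n_ins == 1
        assert calls == []


class TestExclusion:
    def _calls(self, cell, positions, deletion=False):
        return [MutationCall(p, "A", "-" if deletion else "G", "FR1", cell)
                for p in positions]

    def test_nothing_excluded_without_deletions(self):
        kept, log = exclude_artifacts({"a": self._calls("a", [1, 5, 9])})
        assert set(kept) == {"a"} and log == []

    def test_long_deletion_run_excluded(self):
        calls = {"a": self._calls("a", range(100, 145), deletion=True),
                 "b": self._calls("b", [3]),
                 "c": self._calls("c", range(10, 30), deletion=True)}
        kept, log = exclude_artifacts(calls, max_deletion_len=30)
        assert set(kept) == {"b", "c"}
        assert log[0][0] == "a"

    def test_exclusion_fraction_tracks_configured_rate(self):
        """Sequences lost to long deletions ~ Binomial(rounds x rate)."""
        cond = get_condition("aidmut1_conventional")
        rep, pool, ledger, cfg = __import__("gdpanedit").run_condition(
            "aidmut1_conventional", rng_seed=31, pool_size=400)
        rate = cond.profile.long_deletion_rate_per_round
        p_excl = 1 - (1 - rate) ** cfg.rounds
        n, k = 400, rep.n_excluded
        se = (p_excl * (1 - p_excl) / n) ** 0.5
        assert abs(k / n - p_excl) <= 4 * se


class TestSummarize:
    def test_rate_arithmetic_single_sequence(self, rng):
        cons = _construct_of_length(rng, 1000)
        calls = [MutationCall(i, cons.seq[i], "A" if cons.seq[i] != "A" else "C",
                              "FR1", "s") for i in (3, 100, 200, 600, 900)]
        rep = summarize({"s": calls}, cons)
        assert rep.overall_rate_per_kb == pytest.approx(5.0)
        assert rep.mean_sites_per_seq == pytest.approx(5.0)

    def test_rate_matches_reported_mean_sites(self, rng):
        """37 calls over 10 x 360 bp: 10.28/kb and 3.7 sites/sequence."""
        cons = _construct_of_length(rng, 360)
        per_seq = [4, 4, 4, 4, 4, 4, 4, 3, 3, 3]
        assert sum(per_seq) == 37
        calls_by_seq = {}
        for i, k in enumerate(per_seq):
            calls_by_seq[f"s{i}"] = [
                MutationCall(10 + j, cons.seq[10 + j],
                             "A" if cons.seq[10 + j] != "A" else "C",
                             "FR1", f"s{i}") for j in range(k)]
        rep = summarize(calls_by_seq, cons)
        assert rep.overall_rate_per_kb == pytest.approx(37 / 3600 * 1000)
        assert rep.overall_rate_per_kb == pytest.approx(10.28, abs=0.01)
        assert rep.mean_sites_per_seq == pytest.approx(3.7)

    def test_all_cdr_calls_give_100_percent(self, rng):
        cons = _construct_of_length(rng, 1000)
        calls = [MutationCall(31, cons.seq[31],
                              "A" if cons.seq[31] != "A" else "C",
                              "CDR1", "s")]
        rep = summarize({"s": calls}, cons)
        assert rep.cdr_rate_percent == 100.0

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError):
            summarize({}, _construct_of_length(rng, 300))

    def test_single_event_deletion_convention_switch(self, rng):
        cons = _construct_of_length(rng, 1000)
        calls = [MutationCall(p, cons.seq[p], "-", "FR1", "s")
                 for p in range(50, 59)]
        per_base = summarize({"s": calls}, cons)
        per_event = summarize({"s": calls}, cons,
                              count_deletions_per_base=False)
        assert per_base.mean_sites_per_seq == 9
        assert per_event.mean_sites_per_seq == 1


class TestRoundTrip:
    def test_calls_recover_ledger_without_deletions(self):
        cond = get_condition("aidmut1_conventional")
        prof = replace(cond.profile, long_deletion_rate_per_round=0.0)
        cfg = cond.config(60, 37)
        cfg.profile = prof
        pool, ledger = simulate_pool(cfg)
        net = net_ledger(ledger)
        for rec in pool:
            aln = align_to_reference(rec, cfg.construct)
            calls, _ = call_mutations(aln, cfg.construct, rec.id)
            mine = net[net.cell_id == rec.id]
            assert set((c.pos0, c.ref, c.alt) for c in calls) == \
                set(zip(mine.pos0, mine.ref, mine.alt))

    def test_calls_recover_ledger_with_sparse_deletions(self):
        """In-frame deletions at physiological density round-trip too."""
        cond = get_condition("aidmut2_conventional")
        prof = replace(cond.profile, long_deletion_rate_per_round=0.0,
                       deletion_rate_per_round=0.05)
        cfg = cond.config(80, 41)
        cfg.profile = prof
        pool, ledger = simulate_pool(cfg)
        net = net_ledger(ledger)
        for rec in pool:
            aln = align_to_reference(rec, cfg.construct)
            calls, _ = call_mutations(aln, cfg.construct, rec.id)
            mine = net[net.cell_id == rec.id]
            assert set((c.pos0, c.ref, c.alt) for c in calls) == \
                set(zip(mine.pos0, mine.ref, mine.alt)), rec.id


class TestMassBalance:
    def test_composition_after_equals_mutant_composition(self):
        rep, pool, ledger, cfg = __import__("gdpanedit").run_condition(
            "aidmut1_conventional", rng_seed=43, pool_size=80)
        kept = set(rep.sites_per_sequence)
        counts = np.zeros(4)
        for rec in pool:
            if rec.id in kept:
                for i, b in enumerate("ACGT"):
                    counts[i] += rec.seq.count(b)
        assert np.allclose(rep.base_composition_after, counts / counts.sum(),
                           atol=1e-9)
        assert rep.base_composition_before.sum() == pytest.approx(1.0, abs=1e-9)
        assert rep.base_composition_after.sum() == pytest.approx(1.0, abs=1e-9)
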