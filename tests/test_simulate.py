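from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from gdpanedit import (EditorProfile, SimulationConfig, analyze_pool,
                       get_condition, net_ledger, sample_sequenced_reads,
                       simulate_pool)
from gdpanedit.simulate import SimulationError, _SimPlan


def _flat_profile(**kw):
    base = dict(name="test", class_probs={"C>T": 0.5, "G>A": 0.3, "A>G": 0.1,
                                          "T>C": 0.1},
                per_base_edit_prob_per_round=0.02)
    base.update(kw)
    return EditorProfile(**base)


class TestProfileValidation:
    def test_class_probs_must_sum_to_one(self):
        with pytest.raises(SimulationError):
            _flat_profile(class_probs={"C>T": 0.5})

    def test_window_bounds(self):
        with pytest.raises(SimulationError):
            _flat_profile(window=(-60, -10))
        with pytest.raises(SimulationError):
            _flat_profile(window=(-10, -50))

    def test_spectrum_rows_are_distributions(self):
        prof = _flat_profile()
        spec = prof.spectrum
        assert np.allclose(spec.sum(axis=1), 1.0)
        assert np.allclose(np.diag(spec), 0.0)

    def test_long_deletions_are_long(self):
        with pytest.raises(SimulationError):
            _flat_profile(long_deletion_length=10)


class TestNullAndConservation:
    def test_null_process(self, reference, guides):
        prof = _flat_profile(per_base_edit_prob_per_round=0.0)
        cfg = SimulationConfig(reference, prof, guides, "conventional",
                               pool_size=5, rng_seed=1, sample_size=5)
        pool, ledger = simulate_pool(cfg)
        assert all(rec.seq == reference.seq for rec in pool)
        assert ledger.empty

    def test_deletions_off_preserves_length(self, reference, guides):
        cfg = SimulationConfig(reference, _flat_profile(), guides,
                               "conventional", pool_size=20, rng_seed=2,
                               sample_size=20)
        pool, _ = simulate_pool(cfg)
        assert all(len(rec.seq) == len(reference) for rec in pool)

    def test_edits_confined_to_windows(self, reference, guides):
        cfg = SimulationConfig(reference, _flat_profile(), guides,
                               "conventional", pool_size=30, rng_seed=3,
                               sample_size=30)
        pool, _ = simulate_pool(cfg)
        allowed = set()
        for g in guides:
            a, b = g.window_span(len(reference))
            allowed.update(range(a, b))
        for rec in pool:
            diffs = {i for i, (x, y) in enumerate(zip(reference.seq, rec.seq))
                     if x != y}
            assert diffs <= allowed

    def test_g4_mode_confined_to_cdrs_when_no_off_rate(self, g4_reference):
        prof = _flat_profile(edited_strand="template",
                             per_base_edit_prob_per_round=0.05,
                             off_window_fraction=0.0)
        cfg = SimulationConfig(g4_reference, prof, [], "g4_spontaneous",
                               pool_size=20, rng_seed=4, sample_size=20)
        pool, _ = simulate_pool(cfg)
        cdr = set()
        for _, s, e in g4_reference.map.cdr_intervals():
            cdr.update(range(s, e))
        for rec in pool:
            diffs = {i for i, (x, y) in enumerate(zip(g4_reference.seq, rec.seq))
                     if x != y}
            assert diffs <= cdr


class TestDeterminism:
    def test_same_seed_same_pool(self, reference, guides):
        cfg = SimulationConfig(reference, _flat_profile(), guides,
                               "conventional", pool_size=10, rng_seed=7,
                               sample_size=10)
        p1, l1 = simulate_pool(cfg)
        p2, l2 = simulate_pool(cfg)
        assert [r.seq for r in p1] == [r.seq for r in p2]
        assert l1.equals(l2)

    def test_counter_mode_pool_growth_stable(self, reference, guides):
        """Enlarging the pool must not reshuffle earlier cells."""
        prof = _flat_profile()
        small = SimulationConfig(reference, prof, guides, "conventional",
                                 pool_size=5, rng_seed=7, sample_size=5)
        big = SimulationConfig(reference, prof, guides, "conventional",
                               pool_size=25, rng_seed=7, sample_size=5)
        ps, _ = simulate_pool(small)
        pb, _ = simulate_pool(big)
        assert [r.seq for r in ps] == [r.seq for r in pb[:5]]

    def test_sampling_deterministic_and_bounded(self, reference, guides):
        cfg = SimulationConfig(reference, _flat_profile(), guides,
                               "conventional", pool_size=20, rng_seed=1,
                               sample_size=20)
        pool, _ = simulate_pool(cfg)
        s1 = sample_sequenced_reads(pool, 8, 3)
        s2 = sample_sequenced_reads(pool, 8, 3)
        s3 = sample_sequenced_reads(pool, 8, 4)
        assert [r.id for r in s1] == [r.id for r in s2]
        assert [r.id for r in s1] != [r.id for r in s3]
        assert [r.id for r in sample_sequenced_reads(pool, 20, 0)] == \
            [r.id for r in pool]
        with pytest.raises(SimulationError):
            sample_sequenced_reads(pool, 21, 0)


class TestLedger:
    def test_net_ledger_equals_sequence_diff(self, reference, guides):
        cfg = SimulationConfig(reference,
                               _flat_profile(per_base_edit_prob_per_round=0.05),
                               guides, "conventional", pool_size=40,
                               rng_seed=11, sample_size=40)
        pool, ledger = simulate_pool(cfg)
        net = net_ledger(ledger)
        for rec in pool:
            diffs = {(i, x, y) for i, (x, y)
                     in enumerate(zip(reference.seq, rec.seq)) if x != y}
            mine = net[net.cell_id == rec.id]
            assert diffs == set(zip(mine.pos0, mine.ref, mine.alt))

    def test_ledger_records_deletions_per_position(self, g4_reference):
        prof = _flat_profile(edited_strand="template",
                             per_base_edit_prob_per_round=0.0,
                             deletion_rate_per_round=1.0,
                             deletion_lengths=(9,))
        cfg = SimulationConfig(g4_reference, prof, [], "g4_spontaneous",
                               pool_size=3, rng_seed=5, rounds=1,
                               sample_size=3)
        pool, ledger = simulate_pool(cfg)
        assert (ledger.event_type == "deletion").all()
        assert all(len(rec.seq) == len(g4_reference) - 9 for rec in pool)
        for cid, grp in ledger.groupby("cell_id"):
            pos = sorted(grp.pos0)
            assert pos == list(range(pos[0], pos[0] + 9))


class TestSpectrumAndStrand:
    def test_spectrum_recovery_within_3se(self, reference, guides):
        """First edits at each position follow the configured spectrum."""
        prof = _flat_profile(per_base_edit_prob_per_round=0.05)
        cfg = SimulationConfig(reference, prof, guides, "conventional",
                               pool_size=800, rng_seed=13, sample_size=800)
        _, ledger = simulate_pool(cfg)
        first = ledger.groupby(["cell_id", "pos0"], as_index=False).head(1)
        assert len(first) > 8000
        spec = prof.spectrum
        for ref_base in "ACGT":
            sub = first[first.ref == ref_base]
            n = len(sub)
            if n < 300:
                continue
            for alt_base in "ACGT":
                if alt_base == ref_base:
                    continue
                p = spec["ACGT".index(ref_base), "ACGT".index(alt_base)]
                phat = (sub.alt == alt_base).mean()
                se = max((p * (1 - p) / n) ** 0.5, 1e-9)
                assert abs(phat - p) <= 3 * se + 1e-12, (ref_base, alt_base)

    def test_template_strand_profile_reads_as_g_to_a(self):
        """A template-strand cytidine editor must show coding G>A calls."""
        rep, *_ = __import__("gdpanedit").run_condition(
            "aidmut2_conventional", rng_seed=17, pool_size=100)
        cls, share = rep.modal_substitution()
        assert cls == "G>A"
        assert share > 0.4


def _report_of(cfg):
    pool, _ = simulate_pool(cfg)
    return analyze_pool(pool, cfg.construct)


class TestGuidanceDynamics:
    def test_conventional_activity_decays_across_rounds(self, reference):
        """Round-3 new substitutions fall below round-1 under fixed spacers."""
        cond = get_condition("aidmut1_conventional")
        prof = replace(cond.profile, target_rate_per_kb=None,
                       per_base_edit_prob_per_round=0.08,
                       long_deletion_rate_per_round=0.0)
        cfg = cond.config(300, 19)
        cfg.profile = prof
        _, ledger = simulate_pool(cfg)
        by_round = ledger.groupby("round").size()
        assert by_round[3] < by_round[1]

    def test_self_assembling_rate_constant_across_rounds(self):
        cond = get_condition("aidmut1_delta")
        prof = replace(cond.profile, target_rate_per_kb=None,
                       per_base_edit_prob_per_round=0.08)
        cfg = cond.config(300, 19)
        cfg.profile = prof
        _, ledger = simulate_pool(cfg)
        by_round = ledger.groupby("round").size()
        # constant in expectation: rounds agree within Monte-Carlo noise
        lo, hi = by_round.min(), by_round.max()
        assert (hi - lo) / hi < 0.15

    def test_seed_mutations_suppress_conventional_editing(self, reference):
        """Same editor, same per-base probability: a target carrying 2 seed
        mismatches per protospacer is edited far less."""
        from gdpanedit import run_condition, seed_mutated_reference
        from gdpanedit.simulate import resolve_per_base_prob
        cond = get_condition("aidmut1_conventional")
        p = resolve_per_base_prob(cond.config(1, 0))
        frozen = replace(cond.profile, target_rate_per_kb=None,
                         per_base_edit_prob_per_round=p,
                         long_deletion_rate_per_round=0.0)
        cfg = cond.config(100, 23)
        cfg.profile = frozen
        rep_clean = _report_of(cfg)
        cfg_mut = cond.config(100, 23)
        cfg_mut.profile = frozen
        cfg_mut.construct = seed_mutated_reference(reference)
        rep_mut = _report_of(cfg_mut)
        assert rep_mut.overall_rate_per_kb < rep_clean.overall_rate_per_kb / 5


class TestCalibration:
    def test_markov_expectation_matches_monte_carlo(self, reference, guides):
        prof = _flat_profile(per_base_edit_prob_per_round=0.05)
        cfg = SimulationConfig(reference, prof, guides, "conventional",
                               pool_size=400, rng_seed=29, sample_size=400)
        plan = _SimPlan(cfg)
        expected = plan._expected_sites(plan.p)
        pool, ledger = simulate_pool(cfg)
        net = net_ledger(ledger)
        got = len(net) / cfg.pool_size
        se = (got / cfg.pool_size) ** 0.5  # Poisson-scale error bound
        assert abs(got - expected) < 4 * se

    def test_unreachable_rate_raises(self, reference, guides):
        prof = _flat_profile(per_base_edit_prob_per_round=None,
                             target_rate_per_kb=2000.0)
        cfg = SimulationConfig(reference, prof, guides, "conventional",
                               pool_size=1, rng_seed=1, sample_size=1)
        with pytest.raises(SimulationError):
            _SimPlan(cfg)
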