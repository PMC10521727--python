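"""Stochastic simulation of base-editor mutagenesis on a cell pool.

Each cell carries one copy of the nanobody gene and evolves independently
over synchronous transfection rounds. Per round and per guide, every
position of the editing window (-10..-50 from the PAM, PAM = +1..+3) is
edited with probability

    per_base_edit_prob x base_preference x guide_activity x extension_mult

where the base preference re-weights the flat per-base probability by the
editor's substitution-class distribution (a cytidine deaminase hits C far
more often than A), guide activity follows the seed-mismatch model of
:mod:`gdpanedit.guides`, and the extension multiplier encodes the relative
efficiency of 5'-extended truncated guides. Conventional guides keep their
spacer fixed, so accumulating protospacer mutations throttles later rounds;
self-assembling guides re-derive their spacer from each cell's current
transcript every round and never lose activity while their framework anchor
is intact. A third mode emulates the guide-free, G-quadruplex-driven
spontaneous editing concentrated in (grafted) CDRs.

Editor profiles state a target overall mutation rate (per 1000 bp after
three rounds); the per-base probability that realizes it on a given
construct/guide geometry is solved at setup by bisection on an exact
per-position Markov-chain expectation (see ``docs/methods.md``). Deletions
are injected as left-aligned in-frame events; rare long-range deletions are
emitted so that downstream exclusion rules are exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .construct import NanobodyConstruct, SequenceRecord
from .guides import ConventionalGuide, TruncatedGuide, SPACER_LEN, PAIRING_LEN

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
EDIT_MODES = ("conventional", "self_assembling", "g4_spontaneous")
ALPHA = 0.2  # per-mismatch activity retention (two mismatches -> 4%)


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


class SimulationError(ValueError):
    pass


@dataclass
class EditorProfile:
    """One editor/guide condition: window, spectrum, rates, deletion model.

    ``class_probs`` is the distribution of substitution classes on the
    *edited* strand (e.g. ``{"C>T": 0.6, ...}``); the conditional 4x4
    spectrum and the per-base editability preference are derived from it.
    Exactly one of ``per_base_edit_prob_per_round`` and ``target_rate_per_kb``
    must be set; in the latter case the per-base probability is calibrated
    against the actual construct/guide geometry at simulation setup.
    """

    name: str
    class_probs: dict[str, float]
    edited_strand: str = "coding"
    window: tuple[int, int] = (-50, -10)
    per_base_edit_prob_per_round: float | None = None
    target_rate_per_kb: float | None = None
    target_cdr_share: float | None = None
    deletion_rate_per_round: float = 0.0
    deletion_lengths: tuple[int, ...] = (9, 18)
    long_deletion_rate_per_round: float = 0.0
    long_deletion_length: int = 60
    extension_multiplier: dict[int, float] = field(
        default_factory=lambda: {0: 1.0, 15: 1.0, 21: 1.0})
    off_window_fraction: float = 0.0  # g4 mode: editability outside the CDRs

    def __post_init__(self):
        if self.edited_strand not in ("coding", "template"):
            raise SimulationError("edited_strand must be 'coding' or 'template'")
        lo, hi = self.window
        if not (-50 <= lo < hi <= -10):
            raise SimulationError("window must satisfy -50 <= lo < hi <= -10")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-6:
            raise SimulationError(f"class_probs sum to {total}, expected 1")
        for cls, prob in self.class_probs.items():
            ref, _, alt = cls.partition(">")
            if ref not in BASES or alt not in BASES or ref == alt:
                raise SimulationError(f"bad substitution class {cls!r}")
            if not 0.0 <= prob <= 1.0:
                raise SimulationError(f"probability of {cls} outside [0,1]")
        for p in (self.per_base_edit_prob_per_round, self.deletion_rate_per_round,
                  self.long_deletion_rate_per_round):
            if p is not None and not 0.0 <= p <= 1.0:
                raise SimulationError("probabilities must lie in [0,1]")
        if self.long_deletion_length < 30:
            raise SimulationError("long deletions are >= 30 nt by definition")

    @property
    def class_matrix(self) -> np.ndarray:
        """4x4 joint class matrix on the edited strand (rows = ref base)."""
        m = np.zeros((4, 4))
        for cls, prob in self.class_probs.items():
            m[_CODE[cls[0]], _CODE[cls[2]]] = prob
        return m

    @property
    def base_mass(self) -> np.ndarray:
        return self.class_matrix.sum(axis=1)

    @property
    def spectrum(self) -> np.ndarray:
        """Conditional substitution spectrum: rows sum to 1 over the 3 alts."""
        m = self.class_matrix
        mass = m.sum(axis=1)
        spec = np.zeros((4, 4))
        for b in range(4):
            if mass[b] > 0:
                spec[b] = m[b] / mass[b]
            else:  # base never edited; keep a proper distribution anyway
                spec[b] = np.full(4, 1 / 3)
                spec[b, b] = 0.0
        return spec


@dataclass
class SimulationConfig:
    construct: NanobodyConstruct
    profile: EditorProfile
    guides: Sequence[ConventionalGuide | TruncatedGuide]
    mode: str = "conventional"
    rounds: int = 3
    pool_size: int = 10
    rng_seed: int = 0
    sample_size: int = 10
    extension_len: int = 0

    def __post_init__(self):
        if self.mode not in EDIT_MODES:
            raise SimulationError(f"mode must be one of {EDIT_MODES}")
        if self.rounds < 1:
            raise SimulationError("rounds >= 1")
        if self.sample_size > self.pool_size:
            raise SimulationError("sample_size exceeds pool_size")
        if self.mode == "conventional":
            if not all(isinstance(g, ConventionalGuide) for g in self.guides):
                raise SimulationError("conventional mode needs ConventionalGuides")
        elif self.mode == "self_assembling":
            if not all(isinstance(g, TruncatedGuide) for g in self.guides):
                raise SimulationError("self_assembling mode needs TruncatedGuides")


class _SimPlan:
    """Precomputed geometry, weights and calibrated probabilities."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        prof, cons = cfg.profile, cfg.construct
        L = len(cons)
        self.L = L
        self.ref = _encode(cons.seq)
        self.coding = prof.edited_strand == "coding"
        self.esb_ref = self.ref if self.coding else 3 - self.ref

        self.ext_mult = prof.extension_multiplier.get(cfg.extension_len, 1.0)

        in_cdr = np.zeros(L, dtype=bool)
        for _, s, e in cons.map.cdr_intervals():
            in_cdr[s:e] = True
        self.in_cdr = in_cdr

        # per-pass editable positions and raw window weights
        self.passes: list[np.ndarray] = []     # absolute positions
        self.pass_w: list[np.ndarray] = []     # window weight per position
        if cfg.mode == "g4_spontaneous":
            if prof.off_window_fraction > 0:
                idx = np.arange(L)
                w = np.where(in_cdr, 1.0, prof.off_window_fraction)
            else:
                idx = np.flatnonzero(in_cdr)
                w = np.ones(len(idx))
            keep = w > 0
            self.passes.append(idx[keep])
            self.pass_w.append(w[keep])
        else:
            for g in cfg.guides:
                a, b = g.window_span(L, prof.window)
                idx = np.arange(a, b)
                self.passes.append(idx)
                self.pass_w.append(np.ones(len(idx)))

        # base preference: class mass divided by window base composition
        mass = prof.base_mass
        comp = np.zeros(4)
        tot = 0.0
        for idx, w in zip(self.passes, self.pass_w):
            for b in range(4):
                comp[b] += w[self.esb_ref[idx] == b].sum()
            tot += w.sum()
        if tot == 0:
            raise SimulationError("no editable positions")
        comp /= tot
        self.pref = np.array([mass[b] / comp[b] if comp[b] > 0 else 0.0
                              for b in range(4)])

        # CDR-share bias multiplier
        share = prof.target_cdr_share
        if share is None or cfg.mode == "g4_spontaneous":
            bias = 1.0
        else:
            sc = sf = 0.0
            for idx, w in zip(self.passes, self.pass_w):
                u = w * self.pref[self.esb_ref[idx]]
                sc += u[in_cdr[idx]].sum()
                sf += u[~in_cdr[idx]].sum()
            if share <= 0:
                bias = 0.0
            elif sc == 0 or share >= 1:
                raise SimulationError("CDR share target unreachable: no "
                                      "editable CDR positions")
            else:
                bias = (share / (1 - share)) * (sf / sc)
        self.pass_w = [w * np.where(in_cdr[idx], bias, 1.0)
                       for idx, w in zip(self.passes, self.pass_w)]

        # spacer geometry + initial activity inputs per guide
        self.spacer_idx: list[np.ndarray] = []
        self.spacer_codes: list[np.ndarray] = []
        self.anchor_idx: list[np.ndarray] = []
        if cfg.mode == "conventional":
            for g in cfg.guides:
                s, e = g.spacer_span()
                self.spacer_idx.append(np.arange(s, e))
                self.spacer_codes.append(_encode(g.spacer))
        elif cfg.mode == "self_assembling":
            for g in cfg.guides:
                a, b = g.anchor_span
                self.anchor_idx.append(np.arange(a, b))
                # pairing sequence as plus-strand codes at the anchor
                from .construct import reverse_complement
                self.spacer_codes.append(_encode(reverse_complement(g.pairing_seq)))

        # spectrum machinery (edited-strand space)
        spec = prof.spectrum
        self.alt_codes = np.array([[a for a in range(4) if a != b]
                                   for b in range(4)])
        cond3 = np.array([[spec[b, a] for a in range(4) if a != b]
                          for b in range(4)])
        cond3 = cond3 / cond3.sum(axis=1, keepdims=True)
        self.cond3 = cond3
        self.cum3 = np.cumsum(cond3, axis=1)

        # deletion geometry
        if cfg.mode == "g4_spontaneous":
            s, e = cons.map.interval("CDR2")
            self.del_region = (s, e)
        else:
            spans = [(idx[0], idx[-1] + 1) for idx in self.passes if len(idx)]
            self.del_region = (min(s for s, _ in spans),
                               max(e for _, e in spans)) if spans else (0, L)

        # resolve the per-base probability
        if prof.per_base_edit_prob_per_round is not None:
            self.p = prof.per_base_edit_prob_per_round
        elif prof.target_rate_per_kb is not None:
            target_sites = prof.target_rate_per_kb / 1000.0 * L
            self.p = self._calibrate(target_sites)
        else:
            raise SimulationError(
                "profile needs per_base_edit_prob_per_round or target_rate_per_kb")

    # -- calibration -------------------------------------------------------

    def _initial_activity(self) -> list[float]:
        cfg = self.cfg
        acts = []
        if cfg.mode == "conventional":
            for sp_idx, sp_codes in zip(self.spacer_idx, self.spacer_codes):
                m0 = int((self.ref[sp_idx] != sp_codes).sum())
                acts.append(ALPHA ** m0 * self.ext_mult)
        elif cfg.mode == "self_assembling":
            for an_idx, an_codes in zip(self.anchor_idx, self.spacer_codes):
                ok = bool((self.ref[an_idx] == an_codes).all())
                acts.append(self.ext_mult if ok else 0.0)
        else:
            acts = [1.0]
        return acts

    def _expected_sites(self, p: float) -> float:
        """Exact per-position Markov expectation of mutated positions.

        Guide-activity decay in conventional mode is folded in through a
        Poisson approximation of accumulated spacer mismatches.
        """
        cfg = self.cfg
        n_guides = len(self.passes)
        a0 = self._initial_activity()
        # per-round activity schedule
        A = np.zeros((cfg.rounds + 1, n_guides))
        A[1] = a0
        P = np.zeros((self.L, 4))
        P[np.arange(self.L), self.esb_ref] = 1.0
        lam_cum = np.zeros(n_guides)
        for r in range(1, cfg.rounds + 1):
            if cfg.mode == "conventional":
                A[r] = np.array(a0) * np.exp(-(1 - ALPHA) * lam_cum)
            else:
                A[r] = a0
            for gi, (idx, w) in enumerate(zip(self.passes, self.pass_w)):
                q_pos = np.minimum(p * w * A[r, gi], 1.0)
                qb = np.minimum(q_pos[:, None] * self.pref[None, :], 1.0)
                sub = P[idx]
                inflow = np.einsum("ib,ib,ba->ia", sub, qb, self.spectrum4)
                P[idx] = sub * (1 - qb) + inflow
            if cfg.mode == "conventional":
                lam_r = np.zeros(n_guides)
                for gi, sp_idx in enumerate(self.spacer_idx):
                    for hj, (idx, w) in enumerate(zip(self.passes, self.pass_w)):
                        sel = np.isin(idx, sp_idx)
                        if sel.any():
                            lam_r[gi] += p * A[r, hj] * (
                                w[sel] * self.pref[self.esb_ref[idx[sel]]]).sum()
                lam_cum += lam_r
        p_mut = 1.0 - P[np.arange(self.L), self.esb_ref]
        prof = cfg.profile
        if prof.deletion_rate_per_round:
            # per-position per-round deletion coverage; a deleted position is
            # mutated regardless of prior substitution
            delta = self._deletion_coverage()
            p_del = 1.0 - (1.0 - delta) ** cfg.rounds
            p_mut = p_del + (1.0 - p_del) * p_mut
        return float(p_mut.sum())

    def _deletion_coverage(self) -> np.ndarray:
        """P(a given position is covered by a deletion event in one round)."""
        prof = self.cfg.profile
        cov = np.zeros(self.L)
        lo, hi = self.del_region
        for length in prof.deletion_lengths:
            starts = np.arange(lo, min(hi, self.L - length) + 1)
            if len(starts) == 0:
                continue
            per_start = prof.deletion_rate_per_round / \
                (len(prof.deletion_lengths) * len(starts))
            for s in starts:
                cov[s:s + length] += per_start
        return cov

    @property
    def spectrum4(self) -> np.ndarray:
        return self.cfg.profile.spectrum

    def _calibrate(self, target_sites: float) -> float:
        if target_sites <= 0:
            return 0.0
        hi = 1e-5
        while self._expected_sites(hi) < target_sites:
            hi *= 2
            if hi > 64.0:
                raise SimulationError("target mutation rate unreachable on "
                                      "this construct/guide geometry")
        lo = 0.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if self._expected_sites(mid) < target_sites:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # -- simulation --------------------------------------------------------

    def _left_align(self, state: np.ndarray, alive: np.ndarray,
                    s: int, length: int) -> int:
        ref = self.ref
        e = s + length
        while (s > 0 and alive[s - 1]
               and state[s - 1] == ref[s - 1] and state[e - 1] == ref[e - 1]
               and ref[s - 1] == ref[e - 1]):
            s -= 1
            e -= 1
        return s

    def _inject_deletion(self, rng, state, alive, length, region, events,
                         cell_id, rnd, event_type):
        lo, hi = region
        starts = [s for s in range(lo, min(hi, self.L - length) + 1)
                  if s + length <= self.L and alive[s:s + length].all()]
        if not starts:
            return
        s = starts[rng.integers(len(starts))]
        s = self._left_align(state, alive, s, length)
        alive[s:s + length] = False
        for pos in range(s, s + length):
            events.append((cell_id, rnd, pos, BASES[self.ref[pos]], "-",
                           event_type))

    def _evolve_cell(self, cell_idx: int) -> tuple[str, str, list]:
        cfg = self.cfg
        prof = cfg.profile
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.rng_seed,
                                   spawn_key=(cell_idx,)))
        state = self.ref.copy()
        alive = np.ones(self.L, dtype=bool)
        cell_id = f"cell{cell_idx:05d}"
        events: list[tuple] = []
        for rnd in range(1, cfg.rounds + 1):
            for gi, (idx, w) in enumerate(zip(self.passes, self.pass_w)):
                # current guidance activity
                if cfg.mode == "conventional":
                    sp_idx = self.spacer_idx[gi]
                    mism = (state[sp_idx] != self.spacer_codes[gi]) | ~alive[sp_idx]
                    act = ALPHA ** int(mism.sum()) * self.ext_mult
                elif cfg.mode == "self_assembling":
                    an_idx = self.anchor_idx[gi]
                    ok = alive[an_idx].all() and \
                        (state[an_idx] == self.spacer_codes[gi]).all()
                    # an intact anchor re-assembles on the cell's own
                    # transcript: the spacer matches its protospacer exactly
                    act = self.ext_mult if ok else 0.0
                else:
                    act = 1.0
                if act <= 0.0:
                    continue
                cur = state[idx]
                esb = cur if self.coding else 3 - cur
                q = np.minimum(self.p * w * self.pref[esb] * act, 1.0)
                q[~alive[idx]] = 0.0
                hit = rng.random(len(idx)) < q
                k = int(hit.sum())
                if k == 0:
                    continue
                rows = esb[hit]
                choice = (rng.random(k)[:, None] >= self.cum3[rows][:, :2]).sum(1)
                alt_esb = self.alt_codes[rows, choice]
                alt_cod = alt_esb if self.coding else 3 - alt_esb
                positions = idx[hit]
                state[positions] = alt_cod
                for pos, alt in zip(positions, alt_cod):
                    events.append((cell_id, rnd, int(pos),
                                   BASES[self.ref[pos]], BASES[alt],
                                   "substitution"))
            if prof.deletion_rate_per_round and \
                    rng.random() < prof.deletion_rate_per_round:
                length = int(prof.deletion_lengths[
                    rng.integers(len(prof.deletion_lengths))])
                self._inject_deletion(rng, state, alive, length,
                                      self.del_region, events, cell_id, rnd,
                                      "deletion")
            if prof.long_deletion_rate_per_round and \
                    rng.random() < prof.long_deletion_rate_per_round:
                self._inject_deletion(rng, state, alive,
                                      prof.long_deletion_length, (0, self.L),
                                      events, cell_id, rnd, "long_deletion")
        seq = "".join(BASES[b] for b in state[alive])
        return cell_id, seq, events


def simulate_pool(config: SimulationConfig
                  ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Evolve a pool of cells; returns (mutant records, event ledger).

    The ledger holds one row per injected event (cell_id, round, pos0, ref,
    alt, event_type); deletions contribute one row per deleted reference
    position, at their left-aligned placement. Cells use counter-mode RNG
    substreams, so enlarging the pool never reshuffles earlier cells.
    """
    plan = _SimPlan(config)
    pool: list[SequenceRecord] = []
    rows: list[tuple] = []
    for i in range(config.pool_size):
        cell_id, seq, events = plan._evolve_cell(i)
        pool.append(SequenceRecord(cell_id, seq))
        rows.extend(events)
    ledger = pd.DataFrame(rows, columns=["cell_id", "round", "pos0", "ref",
                                         "alt", "event_type"])
    return pool, ledger


def net_ledger(ledger: pd.DataFrame) -> pd.DataFrame:
    """Collapse the raw event ledger to net per-position outcomes.

    The last event at a position wins; substitutions whose final base equals
    the reference (reversions) drop out. The result is exactly what diffing
    the output sequence against the reference recovers.
    """
    if ledger.empty:
        return ledger.copy()
    last = ledger.groupby(["cell_id", "pos0"], as_index=False).tail(1)
    keep = ~((last["event_type"] == "substitution") &
             (last["alt"] == last["ref"]))
    return last[keep].reset_index(drop=True)


def resolve_per_base_prob(config: SimulationConfig) -> float:
    """The per-base edit probability a configuration will simulate with.

    Either the profile's explicit value or the probability calibrated
    against this construct/guide geometry. Freezing this value lets the same
    editor be replayed on a different target (e.g. a seed-mutated one)
    without re-calibration.
    """
    return _SimPlan(config).p


def editing_weights(config: SimulationConfig
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position editing weights of a configured simulation.

    Returns (positions, relative selection weights, per-position alternative
    distributions over the 3 non-reference bases) — the inputs the weighted
    diversity estimator needs to honor the generator's biases.
    """
    plan = _SimPlan(config)
    acc: dict[int, float] = {}
    for idx, w in zip(plan.passes, plan.pass_w):
        u = w * plan.pref[plan.esb_ref[idx]]
        for pos, ui in zip(idx, u):
            acc[int(pos)] = acc.get(int(pos), 0.0) + float(ui)
    positions = np.array(sorted(acc))
    weights = np.array([acc[p] for p in positions])
    alt_probs = plan.cond3[plan.esb_ref[positions]]
    return positions, weights, alt_probs


def sample_sequenced_reads(pool: Sequence[SequenceRecord], sample_size: int,
                           rng_seed: int) -> list[SequenceRecord]:
    """Uniform sample without replacement (the 'pick >= 10 clones' step)."""
    if sample_size > len(pool):
        raise SimulationError("cannot sample more sequences than the pool holds")
    rng = np.random.default_rng(rng_seed)
    idx = np.sort(rng.choice(len(pool), size=sample_size, replace=False))
    return [pool[i] for i in idx]


def write_ledger(ledger: pd.DataFrame, path) -> None:
    ledger.to_csv(path, sep="\t", index=False)
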