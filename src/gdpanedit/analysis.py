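"""Mutation-spectrum analysis of mutant clone pools.

Pipeline: globally align each sequenced clone to the reference construct,
call substitutions and per-position deletions, exclude clones carrying
long-range fragment deletions (an artifact, not a base-editor signature),
and aggregate the spectrum statistics: overall rate per 1000 bp, the share
of calls falling inside CDRs, per-position enrichment, the substitution-type
matrix and the base-composition shift.

Conventions: the rate denominator is n_sequences x reference length, and a
multi-nucleotide deletion counts one call per deleted reference position
(both switchable); insertions are called but excluded from rate statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._pairwise import PairwiseAlignment, global_align
from .construct import (CDR_NAMES, NanobodyConstruct, SequenceRecord,
                        annotate_regions, translate_and_check)

BASES = "ACGT"


class AlignmentRejected(ValueError):
    """Sequence identity to the reference fell below the acceptance floor."""


@dataclass(frozen=True)
class MutationCall:
    pos0: int
    ref: str
    alt: str  # base, or "-" for a deleted reference position
    region: str
    cell_id: str

    @property
    def type(self) -> str:
        return f"{self.ref}>{self.alt}"

    @property
    def is_deletion(self) -> bool:
        return self.alt == "-"


@dataclass
class MutationReport:
    overall_rate_per_kb: float
    cdr_rate_percent: float
    mean_sites_per_seq: float
    per_position_counts: np.ndarray
    type_counts: dict[str, int]
    base_composition_before: np.ndarray
    base_composition_after: np.ndarray
    n_sequences_analyzed: int
    n_excluded: int
    stop_codon_flags: dict[str, bool] = field(default_factory=dict)
    frameshift_flags: dict[str, bool] = field(default_factory=dict)
    n_insertions: int = 0
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)
    sites_per_sequence: dict[str, int] = field(default_factory=dict)

    def substitution_shares(self) -> dict[str, float]:
        """Each substitution class as a fraction of all substitution calls."""
        subs = {t: c for t, c in self.type_counts.items() if not t.endswith("-")}
        total = sum(subs.values())
        return {t: c / total for t, c in subs.items()} if total else {}

    def modal_substitution(self) -> tuple[str, float]:
        shares = self.substitution_shares()
        if not shares:
            return "", 0.0
        cls = max(shares, key=shares.get)
        return cls, shares[cls]

    def to_dict(self) -> dict:
        return {
            "overall_rate_per_kb": self.overall_rate_per_kb,
            "cdr_rate_percent": self.cdr_rate_percent,
            "mean_sites_per_seq": self.mean_sites_per_seq,
            "n_sequences_analyzed": self.n_sequences_analyzed,
            "n_excluded": self.n_excluded,
            "n_insertions": self.n_insertions,
            "type_counts": dict(self.type_counts),
            "base_composition_before": self.base_composition_before.tolist(),
            "base_composition_after": self.base_composition_after.tolist(),
            "per_position_counts": self.per_position_counts.tolist(),
        }


def align_to_reference(mutant: SequenceRecord, construct: NanobodyConstruct,
                       identity_floor: float = 0.70) -> PairwiseAlignment:
    """Global affine alignment; deletions left-aligned; rejects junk."""
    aln = global_align(construct.seq, mutant.seq)
    if aln.identity < identity_floor:
        raise AlignmentRejected(
            f"{mutant.id}: identity {aln.identity:.3f} < {identity_floor}")
    return aln


def call_mutations(aln: PairwiseAlignment, construct: NanobodyConstruct,
                   cell_id: str = "") -> tuple[list[MutationCall], int]:
    """Per-position calls from an accepted alignment.

    Returns (calls, n_insertions): one call per substituted position and per
    deleted reference position; insertion events are counted but not called.
    """
    calls: list[MutationCall] = []
    n_ins = 0
    for kind, rs, re_, payload in aln.blocks:
        if kind == "sub":
            calls.append(MutationCall(rs, construct.seq[rs], payload,
                                      annotate_regions(construct, rs), cell_id))
        elif kind == "del":
            for pos in range(rs, re_):
                calls.append(MutationCall(pos, construct.seq[pos], "-",
                                          annotate_regions(construct, pos),
                                          cell_id))
        else:
            n_ins += 1
    return calls, n_ins


def exclude_artifacts(calls_by_sequence: dict[str, list[MutationCall]],
                      max_deletion_len: int = 30
                      ) -> tuple[dict[str, list[MutationCall]],
                                 list[tuple[str, str]]]:
    """Drop whole sequences carrying a deletion run >= max_deletion_len."""
    kept: dict[str, list[MutationCall]] = {}
    log: list[tuple[str, str]] = []
    for cell_id, calls in calls_by_sequence.items():
        del_pos = sorted(c.pos0 for c in calls if c.is_deletion)
        run = longest = 0
        prev = None
        for p in del_pos:
            run = run + 1 if prev is not None and p == prev + 1 else 1
            longest = max(longest, run)
            prev = p
        if longest >= max_deletion_len:
            log.append((cell_id,
                        f"long-range deletion ({longest} nt) — excluded"))
        else:
            kept[cell_id] = calls
    return kept, log


def summarize(calls_by_sequence: dict[str, list[MutationCall]],
              construct: NanobodyConstruct,
              n_excluded: int = 0,
              count_deletions_per_base: bool = True) -> MutationReport:
    """Aggregate spectrum statistics over the accepted sequences.

    overall_rate_per_kb = 1000 x mutated reference positions /
    (n_sequences x reference length); cdr_rate_percent is the share of calls
    inside CDR intervals. The base-composition-after vector applies the
    type counts to the reference composition (substitutions move mass
    between bases; deletions remove it), which is exactly the composition of
    the accepted mutant sequences when insertions are absent.
    """
    n_seq = len(calls_by_sequence)
    if n_seq == 0:
        raise ValueError("no sequences to summarize")
    L = len(construct)
    per_pos = np.zeros(L, dtype=int)
    type_counts: dict[str, int] = {}
    sites_per_seq: dict[str, int] = {}
    n_calls = 0
    n_cdr = 0
    for cell_id, calls in calls_by_sequence.items():
        sites_per_seq[cell_id] = len(calls)
        for c in calls:
            per_pos[c.pos0] += 1
            type_counts[c.type] = type_counts.get(c.type, 0) + 1
            n_calls += 1
            if c.region in CDR_NAMES:
                n_cdr += 1
    if not count_deletions_per_base:
        # collapse each deletion run to one event for the rate statistics
        n_calls = 0
        n_cdr = 0
        for calls in calls_by_sequence.values():
            prev_del = None
            for c in sorted(calls, key=lambda c: c.pos0):
                if c.is_deletion and prev_del == c.pos0 - 1:
                    prev_del = c.pos0
                    continue
                prev_del = c.pos0 if c.is_deletion else None
                n_calls += 1
                if c.region in CDR_NAMES:
                    n_cdr += 1

    before_counts = np.zeros(4)
    for i, b in enumerate(BASES):
        before_counts[i] = construct.seq.count(b) * n_seq
    after_counts = before_counts.copy()
    for t, cnt in type_counts.items():
        ref, alt = t[0], t[2]
        after_counts[BASES.index(ref)] -= cnt
        if alt != "-":
            after_counts[BASES.index(alt)] += cnt

    return MutationReport(
        overall_rate_per_kb=1000.0 * n_calls / (n_seq * L),
        cdr_rate_percent=100.0 * n_cdr / n_calls if n_calls else 0.0,
        mean_sites_per_seq=n_calls / n_seq,
        per_position_counts=per_pos,
        type_counts=type_counts,
        base_composition_before=before_counts / before_counts.sum(),
        base_composition_after=after_counts / after_counts.sum(),
        n_sequences_analyzed=n_seq,
        n_excluded=n_excluded,
        sites_per_sequence=sites_per_seq,
    )


def analyze_pool(mutants: list[SequenceRecord], construct: NanobodyConstruct,
                 identity_floor: float = 0.70, max_deletion_len: int = 30,
                 frame_checks: bool = False) -> MutationReport:
    """align -> call -> exclude -> summarize, end to end."""
    calls_by_seq: dict[str, list[MutationCall]] = {}
    n_ins = 0
    n_rejected = 0
    reject_log: list[tuple[str, str]] = []
    for rec in mutants:
        try:
            aln = align_to_reference(rec, construct, identity_floor)
        except AlignmentRejected as exc:
            n_rejected += 1
            reject_log.append((rec.id, str(exc)))
            continue
        calls, ins = call_mutations(aln, construct, rec.id)
        calls_by_seq[rec.id] = calls
        n_ins += ins
    kept, excl_log = exclude_artifacts(calls_by_seq, max_deletion_len)
    report = summarize(kept, construct, n_excluded=len(excl_log) + n_rejected)
    report.n_insertions = n_ins
    report.exclusion_log = reject_log + excl_log
    if frame_checks:
        by_id = {r.id: r for r in mutants}
        for cell_id in kept:
            fr = translate_and_check(construct, by_id[cell_id])
            report.stop_codon_flags[cell_id] = fr.has_internal_stop
            report.frameshift_flags[cell_id] = fr.frameshift
    return report


def calls_to_frame(calls_by_sequence: dict[str, list[MutationCall]]
                   ) -> pd.DataFrame:
    rows = [(c.cell_id, c.pos0, c.ref, c.alt, c.region)
            for calls in calls_by_sequence.values() for c in calls]
    return pd.DataFrame(rows, columns=["cell_id", "pos0", "ref", "alt",
                                       "region"])
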