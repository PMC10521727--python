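"""G-quadruplex motif detection and G4-grafted CDR construct design.

A G-quadruplex-forming sequence is four G-tracts of at least ``min_tract``
guanines joined by loops of 1-7 arbitrary bases (G2+ N1-7 G2+ N1-7 G2+ N1-7
G2+). The complementary strand of a folded quadruplex stays single-stranded,
which is what makes these motifs editable windows; scanning therefore
defaults to both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

from .construct import (CDR_NAMES, ConstructError, NanobodyConstruct,
                        RegionMap, SequenceRecord, reverse_complement)


@dataclass(frozen=True)
class G4Motif:
    start: int
    end: int
    strand: str
    tract_spans: tuple[tuple[int, int], ...]
    loop_lengths: tuple[int, int, int]
    seq: str

    def __post_init__(self):
        if len(self.tract_spans) != 4:
            raise ValueError("a quadruplex needs exactly 4 G-tracts")
        if not all(1 <= l <= 7 for l in self.loop_lengths):
            raise ValueError("loop lengths must be in [1, 7]")

    @property
    def signature(self) -> str:
        t = "/".join(str(e - s) for s, e in self.tract_spans)
        l = "/".join(str(x) for x in self.loop_lengths)
        return f"G{t}_L{l}"


def _longest_motif_at(seq: str, i: int, min_tract: int,
                      loop_min: int, loop_max: int):
    """Longest tract/loop decomposition of a motif starting exactly at i.

    Returns (end, tract_starts_and_lens, loop_lens) or None. Ties in end
    position resolve to longer earlier tracts (G-runs are absorbed into the
    tract rather than split into tract + loop).
    """
    n = len(seq)

    # length of the G-run starting at each position
    run = [0] * (n + 1)
    for j in range(n - 1, -1, -1):
        run[j] = run[j + 1] + 1 if seq[j] == "G" else 0

    @lru_cache(maxsize=None)
    def best(pos: int, tracts_left: int):
        if run[pos] < min_tract:
            return None
        if tracts_left == 1:
            tl = run[pos]  # absorb the whole terminal run
            return (pos + tl, ((pos, tl),), ())
        out = None
        for tl in range(run[pos], min_tract - 1, -1):
            for ll in range(loop_max, loop_min - 1, -1):
                nxt = pos + tl + ll
                if nxt >= n:
                    continue
                sub = best(nxt, tracts_left - 1)
                if sub is None:
                    continue
                end, tr, lo = sub
                if out is None or end > out[0]:
                    out = (end, ((pos, tl),) + tr, (ll,) + lo)
        return out

    res = best(i, 4)
    best.cache_clear()
    return res


def _scan_one_strand(seq: str, min_tract: int, loop_min: int, loop_max: int):
    """All (start, end, tracts, loops) longest-matches per start position."""
    out = []
    for i in range(len(seq)):
        if seq[i] != "G":
            continue
        if i > 0 and seq[i - 1] == "G":
            continue  # a motif never starts mid-run: the longer run wins
        res = _longest_motif_at(seq, i, min_tract, loop_min, loop_max)
        if res is not None:
            end, tracts, loops = res
            out.append((i, end, tuple((s, s + l) for s, l in tracts), loops))
    return out


def find_motifs(seq: str, min_tract: int = 2, loop_min: int = 1,
                loop_max: int = 7, both_strands: bool = True,
                all_matches: bool = False) -> list[G4Motif]:
    """Scan for quadruplex motifs.

    By default returns maximal, mutually non-overlapping motifs chosen
    greedily left to right (longest match wins at each leftmost start;
    '+' beats '-' on exact ties). With ``all_matches`` every admissible
    start position is reported, overlaps included.
    """
    if min_tract < 2:
        raise ValueError("min_tract must be >= 2")
    if loop_min < 1 or loop_min > loop_max:
        raise ValueError("need 1 <= loop_min <= loop_max")
    seq = seq.upper()
    n = len(seq)

    candidates: list[G4Motif] = []
    for s_, e_, tr, lo in _scan_one_strand(seq, min_tract, loop_min, loop_max):
        candidates.append(G4Motif(s_, e_, "+", tr, lo, seq[s_:e_]))
    if both_strands:
        rc = reverse_complement(seq)
        for s_, e_, tr, lo in _scan_one_strand(rc, min_tract, loop_min, loop_max):
            tr_m = tuple(sorted((n - te, n - ts) for ts, te in tr))
            candidates.append(
                G4Motif(n - e_, n - s_, "-", tr_m, lo[::-1], rc[s_:e_]))

    candidates.sort(key=lambda m: (m.start, -(m.end - m.start), m.strand))
    if all_matches:
        return candidates
    chosen: list[G4Motif] = []
    cursor = 0
    for m in candidates:
        if m.start >= cursor:
            chosen.append(m)
            cursor = m.end
    return chosen


def graft_g4_into_cdrs(construct: NanobodyConstruct,
                       fragments: dict[str, str],
                       stop_is_error: bool = False) -> NanobodyConstruct:
    """Replace CDR intervals with quadruplex-forming fragments.

    Each fragment must itself scan positive for a G4 motif on at least one
    strand and must preserve the reading frame (net length change a multiple
    of 3). Framework sequence and translation are untouched; the region map
    is re-indexed around the new CDR lengths.
    """
    for name in fragments:
        if name not in CDR_NAMES:
            raise ConstructError(f"{name!r} is not a CDR")
    seq = construct.seq
    rmap = construct.map
    for name in CDR_NAMES:  # left to right so shifts stay consistent
        if name not in fragments:
            continue
        frag = fragments[name].upper()
        if not find_motifs(frag, both_strands=True):
            raise ConstructError(f"{name} fragment carries no quadruplex motif")
        start, end = rmap.interval(name)
        delta = len(frag) - (end - start)
        if delta % 3 != 0:
            raise ConstructError(
                f"{name} fragment breaks frame (net change {delta} nt)")
        seq = seq[:start] + frag + seq[end:]
        rmap = RegionMap(
            tuple((n,
                   s if s <= start else s + delta,
                   e if e < end else e + delta)
                  for n, s, e in rmap.regions),
            rmap.orf_offset)
    out = NanobodyConstruct(
        SequenceRecord(construct.record.id + "/G4", seq),
        rmap, construct.strand_of_record)
    prot = out.protein()
    if "*" in prot[:-1]:
        msg = f"grafted ORF of {out.record.id} contains an internal stop codon"
        if stop_is_error:
            raise ConstructError(msg)
        warnings.warn(msg)
    return out
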