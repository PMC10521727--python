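"""Global affine-gap alignment of near-identical mutant clones to a
reference, with VCF-style left-normalization of gaps.

Scoring is pinned at match +1, mismatch -2, gap open -8, gap extend -2.
Gap penalties are deliberately stiff: with a gap of length k costing
8 + 2k, a spurious deletion+insertion pair can never outscore a run of k
substitutions (that would need 3k > 2(8 + 2k), impossible), so dense
substitution clusters — e.g. quadruplex-driven hypermutation at two thirds
of CDR positions — stay substitutions, while true deletions are still
forced by the length difference in a global alignment. Among equal-score
placements, gaps are shifted maximally 5'-ward by rotating flanking matched
bases (the standard variant-normalization rule).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class PairwiseAlignment:
    """A normalized global alignment as two equal-length gapped strings."""

    ref: str
    mut: str
    gapped_ref: str
    gapped_mut: str
    score: float

    @property
    def identity(self) -> float:
        n = sum(a == b for a, b in zip(self.gapped_ref, self.gapped_mut))
        return n / len(self.gapped_ref)

    @property
    def blocks(self) -> list[tuple[str, int, int, str]]:
        """Difference blocks as (kind, ref_start, ref_end, payload).

        kind in {"sub", "del", "ins"}; for insertions ref_start == the
        insertion point and ref_end = ref_start + inserted length (payload
        holds the inserted bases).
        """
        out: list[tuple[str, int, int, str]] = []
        rpos = 0
        i = 0
        cols = list(zip(self.gapped_ref, self.gapped_mut))
        while i < len(cols):
            r, m = cols[i]
            if r != "-" and m != "-":
                if r != m:
                    out.append(("sub", rpos, rpos + 1, m))
                rpos += 1
                i += 1
            elif m == "-":  # deletion run
                start = rpos
                while i < len(cols) and cols[i][1] == "-":
                    rpos += 1
                    i += 1
                out.append(("del", start, rpos, ""))
            else:  # insertion run
                ins = []
                while i < len(cols) and cols[i][0] == "-":
                    ins.append(cols[i][1])
                    i += 1
                out.append(("ins", rpos, rpos + len(ins), "".join(ins)))
        return out

    def ref_to_mut(self, ref_pos: int) -> int:
        """Mutant coordinate of a reference coordinate (gap-skipping)."""
        rpos = mpos = 0
        for r, m in zip(self.gapped_ref, self.gapped_mut):
            if rpos == ref_pos and r != "-":
                return mpos
            if r != "-":
                rpos += 1
            if m != "-":
                mpos += 1
        return mpos


def _left_normalize(gr: list[str], gm: list[str]) -> None:
    """Shift gap runs maximally 5'-ward by rotating equal flanking bases."""
    for gapped, other in ((gm, gr), (gr, gm)):
        i = len(gapped) - 1
        while i >= 0:
            if gapped[i] != "-":
                i -= 1
                continue
            end = i + 1
            while i >= 0 and gapped[i] == "-":
                i -= 1
            start = i + 1
            # rotate left while the flanking aligned pair is a match whose
            # base equals the last base of the run on the other string
            while (start > 0 and gapped[start - 1] != "-"
                   and other[start - 1] != "-"
                   and gapped[start - 1] == other[start - 1]
                   and other[start - 1] == other[end - 1]):
                other[start - 1], other[end - 1] = other[end - 1], other[start - 1]
                gapped[start - 1], gapped[end - 1] = gapped[end - 1], gapped[start - 1]
                start -= 1
                end -= 1
            i = start - 1


def global_align(ref: str, mut: str) -> PairwiseAlignment:
    aln = next(iter(_ALIGNER.align(ref, mut)))
    gr, gm = list(str(aln[0])), list(str(aln[1]))
    _left_normalize(gr, gm)
    return PairwiseAlignment(ref, mut, "".join(gr), "".join(gm), float(aln.score))
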