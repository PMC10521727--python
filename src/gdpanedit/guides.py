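"""Guide RNA design: conventional CDR-targeting spacers with PTG assembly,
truncated self-assembling guides, and the seed-mismatch activity model.

Conventional guides are 20-nt spacers 5' of an NGG PAM; the deaminase-
accessible window of the tethered base editor spans positions -10..-50
counting the PAM as +1..+3. Truncated guides drop the crRNA part entirely:
a re-programmed 14-nt tracrRNA 5' end pairs with the framework ("constant")
region of the nanobody transcript immediately 3' of a CDR, so the cell's own
— possibly already mutated — mRNA supplies the spacer. The spacer of such a
self-assembled guide therefore always matches the latest target sequence,
which is what makes the mutagenesis iterative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .construct import (ConstructError, NanobodyConstruct, SequenceRecord,
                        reverse_complement)

SPACER_LEN = 20
PAIRING_LEN = 14
# base-editing window relative to the PAM (PAM = +1..+3); inclusive bounds
WINDOW_REL = (-50, -10)
EXTENSION_LENGTHS = (0, 15, 21)

# canonical S. pyogenes sgRNA scaffold (DNA representation)
SGRNA_SCAFFOLD = ("GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCA"
                  "ACTTGAAAAAGTGGCACCGAGTCGGTGC")
# synthetic stand-in for the glycine tRNA spacer unit of PTG constructs
GLY_TRNA = ("GCATTGGTGGTTCAGTGGTAGAATTCTCGCCTGCCACGCGGGAGGCCCGGGTTC"
            "GATTCCCGGCCAATGCA")
POLIII_TERMINATOR = "TTTTTTT"


class AssemblyFailed(RuntimeError):
    """Self-assembling guide could not pair: the anchor window is mutated."""


@dataclass(frozen=True)
class ConventionalGuide:
    """A 20-nt spacer + NGG PAM site, stored in coding(+)-strand coordinates.

    ``spacer`` is the plus-strand sequence of the protospacer footprint;
    reverse-complementation to the RNA sense happens at serialization
    (``oriented_spacer``).
    """

    spacer: str
    pam_start: int  # plus-strand start of the PAM trinucleotide
    strand: str
    target_region: str

    def __post_init__(self):
        if len(self.spacer) != SPACER_LEN:
            raise ConstructError("spacer must be exactly 20 nt")
        if self.strand not in "+-":
            raise ConstructError("strand must be '+' or '-'")

    @property
    def oriented_spacer(self) -> str:
        return self.spacer if self.strand == "+" else reverse_complement(self.spacer)

    def spacer_span(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.pam_start - SPACER_LEN, self.pam_start
        return self.pam_start + 3, self.pam_start + 3 + SPACER_LEN

    def window_span(self, seq_len: int,
                    window: tuple[int, int] = WINDOW_REL) -> tuple[int, int]:
        """Editing-window footprint in plus-strand coordinates, clipped."""
        lo, hi = window
        if self.strand == "+":
            a, b = self.pam_start + lo, self.pam_start + hi + 1
        else:
            a, b = self.pam_start + 2 - hi, self.pam_start + 3 - lo
        return max(0, a), min(seq_len, max(0, b))


@dataclass(frozen=True)
class TruncatedGuide:
    """Self-assembling guide: 14-nt pairing anchor in the framework 3' of a CDR."""

    pairing_seq: str
    extension_len: int
    anchor_pos: int  # transcript position where pairing begins (== CDR end)
    target_region: str

    def __post_init__(self):
        if len(self.pairing_seq) != PAIRING_LEN:
            raise ConstructError("pairing_seq must be exactly 14 nt")
        if self.extension_len not in EXTENSION_LENGTHS:
            raise ConstructError(f"extension_len must be one of {EXTENSION_LENGTHS}")

    @property
    def anchor_span(self) -> tuple[int, int]:
        return self.anchor_pos, self.anchor_pos + PAIRING_LEN

    def spacer_span(self) -> tuple[int, int]:
        return self.anchor_pos - SPACER_LEN, self.anchor_pos

    def window_span(self, seq_len: int,
                    window: tuple[int, int] = WINDOW_REL) -> tuple[int, int]:
        # the hijacked mRNA segment sits where a spacer would: treat the
        # anchor start as the +1 position of a virtual PAM
        lo, hi = window
        return (max(0, self.anchor_pos + lo),
                min(seq_len, max(0, self.anchor_pos + hi + 1)))


@dataclass(frozen=True)
class PTGConstruct:
    """Polycistronic tRNA-gRNA construct: three guides released by tRNA processing."""

    elements: tuple[tuple[str, str], ...]
    promoter: str = "U6"

    def __post_init__(self):
        n_grna = sum(1 for kind, _ in self.elements if kind == "gRNA")
        if n_grna != 3:
            raise ConstructError("a PTG construct carries exactly 3 gRNA units")

    @property
    def dna(self) -> str:
        return "".join(seq for _, seq in self.elements)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def design_conventional(construct: NanobodyConstruct,
                        region: str) -> list[ConventionalGuide]:
    """All guides (either strand) whose editing window overlaps ``region``.

    Sorted by window/region overlap descending, then PAM position, then
    strand. Empty (with a warning) when no PAM serves the region.
    """
    seq = construct.seq
    n = len(seq)
    r_start, r_end = construct.map.interval(region)
    out = []
    for p in range(n - 2):
        if seq[p + 1:p + 3] == "GG" and p >= SPACER_LEN:
            g = ConventionalGuide(seq[p - SPACER_LEN:p], p, "+", region)
            out.append(g)
        if seq[p:p + 2] == "CC" and p + 3 + SPACER_LEN <= n:
            g = ConventionalGuide(seq[p + 3:p + 3 + SPACER_LEN], p, "-", region)
            out.append(g)

    def overlap(g: ConventionalGuide) -> int:
        a, b = g.window_span(n)
        return max(0, min(b, r_end) - max(a, r_start))

    out = [g for g in out if overlap(g) > 0]
    out.sort(key=lambda g: (-overlap(g), g.pam_start, g.strand))
    if not out:
        warnings.warn(f"no candidate guide for {region}")
    return out


def assemble_ptg(guides: list[ConventionalGuide],
                 tRNA_seq: str = GLY_TRNA,
                 scaffold_seq: str = SGRNA_SCAFFOLD,
                 terminator: str = POLIII_TERMINATOR,
                 promoter: str = "U6") -> PTGConstruct:
    """Serialize three guides into one tRNA-flanked polycistron."""
    if len(guides) != 3:
        raise ConstructError("PTG assembly requires exactly 3 guides")
    spacers = [g.oriented_spacer for g in guides]
    if len(set(spacers)) < 3:
        warnings.warn("duplicate spacers in PTG construct")
    elements: list[tuple[str, str]] = [("tRNA", tRNA_seq)]
    for sp in spacers:
        elements.append(("gRNA", sp + scaffold_seq))
        elements.append(("tRNA", tRNA_seq))
    elements.append(("terminator", terminator))
    return PTGConstruct(tuple(elements), promoter)


def parse_ptg(dna: str,
              tRNA_seq: str = GLY_TRNA,
              scaffold_seq: str = SGRNA_SCAFFOLD,
              terminator: str = POLIII_TERMINATOR) -> list[str]:
    """Recover the three spacers from a serialized PTG construct."""
    unit = len(tRNA_seq)
    if not dna.startswith(tRNA_seq):
        raise ConstructError("malformed PTG: missing leading tRNA")
    pos = unit
    spacers = []
    for _ in range(3):
        sp = dna[pos:pos + SPACER_LEN]
        pos += SPACER_LEN
        if dna[pos:pos + len(scaffold_seq)] != scaffold_seq:
            raise ConstructError("malformed PTG: scaffold not found after spacer")
        pos += len(scaffold_seq)
        if dna[pos:pos + unit] != tRNA_seq:
            raise ConstructError("malformed PTG: missing inter-unit tRNA")
        pos += unit
        spacers.append(sp)
    if dna[pos:] != terminator:
        raise ConstructError("malformed PTG: bad terminator")
    return spacers


def design_truncated(construct: NanobodyConstruct, region: str,
                     extension_len: int = 0) -> TruncatedGuide:
    """Truncated guide anchored to the 14-nt framework window 3' of a CDR.

    The anchor sits in constant (framework) sequence by construction, so it
    survives CDR-confined mutagenesis and the guide keeps re-assembling on
    the mutated transcript round after round.
    """
    from .construct import annotate_regions, CDR_NAMES

    if region not in CDR_NAMES:
        raise ConstructError(f"{region!r} is not a CDR")
    _, cdr_end = construct.map.interval(region)
    if cdr_end + PAIRING_LEN > len(construct):
        raise ConstructError(
            f"{region} ends too close to the transcript 3' end for a 14-nt anchor")
    for pos in range(cdr_end, cdr_end + PAIRING_LEN):
        if annotate_regions(construct, pos) in CDR_NAMES:
            raise ConstructError("anchor window overlaps a CDR; anchoring must "
                                 "be in constant framework sequence")
    window = construct.seq[cdr_end:cdr_end + PAIRING_LEN]
    return TruncatedGuide(reverse_complement(window), extension_len,
                          cdr_end, region)


def derive_self_assembled_spacer(guide: TruncatedGuide,
                                 current_transcript: SequenceRecord | str) -> str:
    """Spacer the guide acquires from the *current* transcript.

    The 14-nt anchor must match exactly; the returned 20-mer is whatever now
    sits immediately 5' of the anchor, mutations included. Raises
    ``AssemblyFailed`` when the anchor window itself is mutated or too
    little upstream sequence remains.
    """
    seq = current_transcript if isinstance(current_transcript, str) \
        else current_transcript.seq
    anchor = reverse_complement(guide.pairing_seq)
    pos = seq.find(anchor)
    if pos == -1:
        raise AssemblyFailed("anchor window not found on current transcript")
    if pos < SPACER_LEN:
        raise AssemblyFailed("fewer than 20 nt upstream of the anchor")
    return seq[pos - SPACER_LEN:pos]


def guide_activity(spacer: str, protospacer_on_target: str,
                   alpha: float = 0.2) -> float:
    """Guidance activity as a function of spacer/protospacer mismatches.

    activity = alpha**m for m mismatches; alpha = 0.2 so that two seed
    mismatches cost 96% of guidance function. Monotone non-increasing in m
    and bounded in [0, 1].
    """
    if len(spacer) != SPACER_LEN or len(protospacer_on_target) != SPACER_LEN:
        raise ConstructError("spacer and protospacer must both be 20 nt")
    m = sum(a != b for a, b in zip(spacer.upper(),
                                   protospacer_on_target.upper()))
    return alpha ** m
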