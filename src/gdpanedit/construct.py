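"""Nanobody construct model: sequences, CDR/framework region maps, frame
checks and the in-silico nested-PCR utility.

Coordinates are 0-based, half-open everywhere. A nanobody construct couples a
DNA sequence with a region map partitioning it into the canonical
FR1-CDR1-FR2-CDR2-FR3-CDR3-FR4 layout of a VHH domain plus the reading-frame
offset of the ORF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = set("ACGT")
REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
CDR_NAMES = ("CDR1", "CDR2", "CDR3")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


class ConstructError(ValueError):
    """Invalid construct, region map or primer input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A labelled uppercase DNA sequence over {A,C,G,T} (N on explicit flag)."""

    id: str
    seq: str
    allow_n: bool = False

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ConstructError(f"{self.id}: empty sequence")
        allowed = DNA_ALPHABET | ({"N"} if self.allow_n else set())
        bad = set(self.seq) - allowed
        if bad:
            raise ConstructError(f"{self.id}: non-DNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RegionMap:
    """Ordered, non-overlapping (name, start, end) intervals plus ORF offset.

    Exactly three CDR entries are required and the full ORF span must be a
    multiple of 3 so that downstream frame checks are meaningful.
    """

    regions: tuple[tuple[str, int, int], ...]
    orf_offset: int = 0

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(
            (str(n), int(s), int(e)) for n, s, e in self.regions))
        prev_end = None
        for name, start, end in self.regions:
            if name not in REGION_NAMES:
                raise ConstructError(f"unknown region name {name!r}")
            if not 0 <= start < end:
                raise ConstructError(f"{name}: bad interval [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ConstructError(f"{name}: overlapping / unsorted intervals")
            prev_end = end
        n_cdr = sum(1 for n, _, _ in self.regions if n in CDR_NAMES)
        if n_cdr != 3:
            raise ConstructError(f"expected exactly 3 CDR intervals, got {n_cdr}")
        span = self.orf_end - self.orf_offset
        if span % 3 != 0:
            raise ConstructError(f"ORF span {span} is not a multiple of 3")

    @property
    def orf_end(self) -> int:
        return max(e for _, _, e in self.regions)

    def cdr_intervals(self) -> list[tuple[str, int, int]]:
        return [(n, s, e) for n, s, e in self.regions if n in CDR_NAMES]

    def interval(self, name: str) -> tuple[int, int]:
        for n, s, e in self.regions:
            if n == name:
                return s, e
        raise KeyError(name)

    def shifted(self, at: int, delta: int) -> "RegionMap":
        """Shift every boundary at/after ``at`` by ``delta`` (graft re-indexing)."""
        new = []
        for n, s, e in self.regions:
            new.append((n,
                        s + delta if s >= at else s,
                        e + delta if e > at else e))
        return RegionMap(tuple(new), self.orf_offset)


@dataclass(frozen=True)
class NanobodyConstruct:
    """Reference sequence plus region annotation for one nanobody gene."""

    record: SequenceRecord
    map: RegionMap
    strand_of_record: str = "coding"

    def __post_init__(self):
        if self.strand_of_record not in ("coding", "template"):
            raise ConstructError("strand_of_record must be 'coding' or 'template'")
        if self.map.orf_end > len(self.record):
            raise ConstructError("region map extends beyond sequence")

    def __len__(self) -> int:
        return len(self.record)

    @property
    def seq(self) -> str:
        return self.record.seq

    def orf(self) -> str:
        return self.seq[self.map.orf_offset:self.map.orf_end]

    def protein(self) -> str:
        return str(Seq(self.orf()).translate())

    def check_reference_frame(self) -> None:
        prot = self.protein()
        if "*" in prot[:-1]:
            raise ConstructError(
                f"{self.record.id}: internal stop codon in reference ORF")


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse PCR primers (5'→3') with a required exact 3' seed."""

    fwd: str
    rev: str
    three_prime_seed: int = 15

    def __post_init__(self):
        object.__setattr__(self, "fwd", self.fwd.upper())
        object.__setattr__(self, "rev", self.rev.upper())
        if min(len(self.fwd), len(self.rev)) < 15:
            raise ConstructError("primers must be >= 15 nt")
        if self.three_prime_seed < 10:
            raise ConstructError("three_prime_seed must be >= 10")


@dataclass(frozen=True)
class FrameReport:
    protein: str
    has_internal_stop: bool
    frameshift: bool


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def annotate_regions(construct: NanobodyConstruct, position: int) -> str:
    """Region name containing ``position``; unlisted positions are
    'framework-other'."""
    if not 0 <= position < len(construct):
        raise IndexError(f"position {position} outside [0, {len(construct)})")
    for name, start, end in construct.map.regions:
        if start <= position < end:
            return name
    return "framework-other"


def translate_and_check(construct: NanobodyConstruct,
                        mutant: SequenceRecord,
                        identity_floor: float = 0.70) -> FrameReport:
    """Translate an (aligned) mutant and report frame integrity.

    ``frameshift`` is true iff the net indel length inside the ORF is not a
    multiple of 3; ``has_internal_stop`` iff a stop codon precedes the ORF
    end in the mutant's own frame.
    """
    from ._pairwise import global_align  # local import avoids a cycle

    aln = global_align(construct.seq, mutant.seq)
    if aln.identity < identity_floor:
        raise ConstructError(
            f"{mutant.id}: identity {aln.identity:.2f} below floor {identity_floor}")
    o, oe = construct.map.orf_offset, construct.map.orf_end
    net = 0
    for kind, rs, re_, _ in aln.blocks:
        lo, hi = max(rs, o), min(re_, oe)
        if kind == "del" and hi > lo:
            net -= hi - lo
        elif kind == "ins" and o <= rs < oe:
            net += re_ - rs  # re_ encodes inserted length span in mutant
    frameshift = net % 3 != 0
    # translate the mutant segment corresponding to the ORF
    mut_o = aln.ref_to_mut(o)
    mut_oe = aln.ref_to_mut(oe)
    orf_seq = mutant.seq[mut_o:mut_oe]
    orf_seq = orf_seq[: len(orf_seq) - len(orf_seq) % 3]
    prot = str(Seq(orf_seq).translate()) if orf_seq else ""
    has_stop = "*" in prot[:-1] if prot else False
    return FrameReport(prot, has_stop, frameshift)


def _footprint_plus(template: str, primer: str, seed: int) -> list[tuple[int, int]]:
    """Plus-strand primer binding footprints.

    The 3'-terminal ``seed`` nucleotides must match exactly; the 5' part is
    extended only as far as it keeps matching (cloning tails may overhang).
    Returns (start, end) of the matched footprint on the template.
    """
    out = []
    core = primer[-seed:]
    start = template.find(core)
    while start != -1:
        fp_start = start
        k = len(primer) - seed  # unmatched 5' portion remaining
        while k > 0 and fp_start > 0 and template[fp_start - 1] == primer[k - 1]:
            fp_start -= 1
            k -= 1
        out.append((fp_start, start + seed))
        start = template.find(core, start + 1)
    return out


def in_silico_pcr(template: SequenceRecord,
                  primers: PrimerPair) -> list[tuple[int, int, int]]:
    """Predict amplicons of a primer pair on a template.

    fwd binds the plus strand, rev binds the minus strand downstream; the
    amplicon spans both primer footprints. Returns (start, end, length)
    tuples; empty when no site pair exists.
    """
    seq = template.seq
    seed = primers.three_prime_seed
    if len(seq) < seed:
        return []
    fwd_sites = _footprint_plus(seq, primers.fwd, seed)
    # rev binds minus strand: its footprint appears as revcomp(rev) on plus
    rc = reverse_complement(seq)
    rev_sites_rc = _footprint_plus(rc, primers.rev, seed)
    n = len(seq)
    rev_sites = [(n - e, n - s) for s, e in rev_sites_rc]
    amplicons = []
    for fs, fe in fwd_sites:
        for rs, re_ in rev_sites:
            if rs >= fe:  # rev footprint strictly downstream of fwd 3' end
                amplicons.append((fs, re_, re_ - fs))
    amplicons.sort()
    return amplicons


# Nested primer pairs used for nanobody locus amplification.
NEST1 = PrimerPair("AGCTCGTTTAGTGAACCGTC", "CACAGCAGGCCGTTGAACTTG", 15)
NEST2 = PrimerPair("TCCACGCTGTTTTGACCTCC", "CACCTGTAGAAGGGGTTCTC", 15)
NEST3 = PrimerPair("ATATTCTAGATGGCCCTGCTGCTGCAC", "ATATGAATTCCTCGCAGGTGCCCTGGTT", 15)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, allow_n: bool = False) -> list[SequenceRecord]:
    return [SequenceRecord(rec.id, str(rec.seq), allow_n=allow_n)
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def write_region_map(rmap: RegionMap, seq_id: str, path: str | Path) -> None:
    """BED-like 3+1 column region file (start, end, name) with headers."""
    with open(path, "w") as fh:
        fh.write(f"#sequence={seq_id}\n#orf_offset={rmap.orf_offset}\n")
        for name, start, end in rmap.regions:
            fh.write(f"{start}\t{end}\t{name}\n")


def read_region_map(path: str | Path) -> tuple[str, RegionMap]:
    """Read the BED-like region file; a JSON alternative is accepted."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        rmap = RegionMap(tuple((r["name"], r["start"], r["end"])
                               for r in data["regions"]),
                         int(data.get("orf_offset", 0)))
        return data.get("sequence", ""), rmap
    seq_id, orf_offset, rows = "", 0, []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            if key == "sequence":
                seq_id = val
            elif key == "orf_offset":
                orf_offset = int(val)
            continue
        start, end, name = line.split("\t")[:3]
        rows.append((name, int(start), int(end)))
    return seq_id, RegionMap(tuple(rows), orf_offset)
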