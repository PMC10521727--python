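"""Packaged study fixtures: the synthetic nanobody reference, literature
G-quadruplex fragments, editor profiles and the named editing conditions.

The anti-GFP nanobody scaffold itself is not redistributable from the study
that motivated this package, so the packaged reference is a SYNTHETIC
VHH-style construct: a 357-nt ORF with the canonical
FR1-CDR1-FR2-CDR2-FR3-CDR3-FR4 layout, an NGG PAM placed immediately 3' of
each CDR (the first framework codon after every CDR is GGG) and no internal
stop codon. Each named condition couples an editor profile to a guidance
mode; profile rates are the overall per-1000-bp mutation rates those
conditions produced after three transfection rounds, and the simulator
calibrates its per-base probability against them at setup.
"""

from __future__ import annotations

from dataclasses import dataclass

from .analysis import analyze_pool, MutationReport
from .construct import (NanobodyConstruct, RegionMap, SequenceRecord,
                        ConstructError)
from .g4 import graft_g4_into_cdrs
from .guides import (ConventionalGuide, TruncatedGuide, design_conventional,
                     design_truncated)
from .simulate import (EditorProfile, SimulationConfig, sample_sequenced_reads,
                       simulate_pool)

# ---------------------------------------------------------------------------
# Synthetic reference construct
# ---------------------------------------------------------------------------

_SEGMENTS = (
    ("FR1", "QVQLVESGGGLVQAGGSLRLSCAAS"),
    ("CDR1", "GRTFSSYA"),
    ("FR2", "GISWFRQAPGKEREFVA"),
    ("CDR2", "INSGGGST"),
    ("FR3", "GYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYC"),
    ("CDR3", "AADPSTYYSGSY"),
    ("FR4", "GWGQGTQVTVS"),
)

_CODONS = {
    "A": ("GCT", "GCC", "GCA"), "R": ("CGT", "AGA", "CGC"),
    "N": ("AAT", "AAC"), "D": ("GAT", "GAC"), "C": ("TGT", "TGC"),
    "Q": ("CAA", "CAG"), "E": ("GAA", "GAG"),
    "G": ("GGT", "GGC", "GGA"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC"), "L": ("CTG", "CTT", "CTC"),
    "K": ("AAA", "AAG"), "M": ("ATG",), "F": ("TTT", "TTC"),
    "P": ("CCT", "CCA", "CCC"), "S": ("TCT", "AGC", "TCA", "TCC"),
    "T": ("ACT", "ACC", "ACA"), "W": ("TGG",), "Y": ("TAT", "TAC"),
    "V": ("GTT", "GTG", "GTC"),
}


def synthetic_reference() -> NanobodyConstruct:
    """The packaged synthetic VHH-style reference construct (357 nt)."""
    counters: dict[str, int] = {}
    seq_parts: list[str] = []
    regions: list[tuple[str, int, int]] = []
    pos = 0
    for name, aa_seq in _SEGMENTS:
        codons = []
        for j, aa in enumerate(aa_seq):
            if j == 0 and name in ("FR2", "FR3", "FR4"):
                # PAM engineering: the codon right after each CDR is GGG, so
                # an NGG PAM sits at the CDR 3' boundary on the plus strand
                codons.append("GGG")
                continue
            i = counters.get(aa, 0)
            counters[aa] = i + 1
            codons.append(_CODONS[aa][i % len(_CODONS[aa])])
        part = "".join(codons)
        regions.append((name, pos, pos + len(part)))
        seq_parts.append(part)
        pos += len(part)
    construct = NanobodyConstruct(
        SequenceRecord("VHH-syn", "".join(seq_parts)),
        RegionMap(tuple(regions), orf_offset=0))
    construct.check_reference_frame()
    return construct


# literature promoter G-quadruplex sequences, trimmed to frame-preserving
# lengths and free of in-frame stop codons at the packaged CDR boundaries
G4_FRAGMENTS = {
    "CDR1": "GGGGCGGGCCGGGGGCGGGGT",                     # VEGF promoter
    "CDR2": "TTGAGGGTGGGTAGGGTGGGTAAA",                  # c-myc (Pu) region
    "CDR3": "AGGGGCGGGCGCGGGAGGAAGGGGGCGGGAGCGGGGCTG",   # BCL-2 P1 promoter
}


def synthetic_g4_reference() -> NanobodyConstruct:
    """Reference with all three CDRs replaced by quadruplex fragments."""
    out = graft_g4_into_cdrs(synthetic_reference(), G4_FRAGMENTS,
                             stop_is_error=True)
    return out


def default_guides(construct: NanobodyConstruct) -> list[ConventionalGuide]:
    """One conventional guide per CDR, at the engineered CDR-boundary PAM."""
    guides = []
    for cdr in ("CDR1", "CDR2", "CDR3"):
        _, cdr_end = construct.map.interval(cdr)
        cands = design_conventional(construct, cdr)
        at_boundary = [g for g in cands
                       if g.pam_start == cdr_end and g.strand == "+"]
        guides.append(at_boundary[0] if at_boundary else cands[0])
    return guides


def truncated_guides(construct: NanobodyConstruct,
                     extension_len: int) -> list[TruncatedGuide]:
    return [design_truncated(construct, cdr, extension_len)
            for cdr in ("CDR1", "CDR2", "CDR3")]


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def seed_mutated_reference(construct: NanobodyConstruct | None = None,
                           n_per_spacer: int = 2) -> NanobodyConstruct:
    """Reference with pre-existing mutations in each 20-nt seed recognition
    site (the protospacer 5' of each CDR-boundary PAM).

    Offsets from the CDR end are chosen deterministically so that the
    transitions introduce no internal stop codon; all pre-mutations land
    inside CDRs, so framework anchors of truncated guides stay intact.
    """
    cons = construct or synthetic_reference()
    for offsets in ((5, 12), (6, 13), (4, 11), (7, 14), (5, 11)):
        seq = list(cons.seq)
        for cdr in ("CDR1", "CDR2", "CDR3"):
            _, cdr_end = cons.map.interval(cdr)
            for off in offsets[:n_per_spacer]:
                pos = cdr_end - off
                seq[pos] = _TRANSITION[seq[pos]]
        candidate = NanobodyConstruct(
            SequenceRecord(cons.record.id + "/seedmut", "".join(seq)),
            cons.map, cons.strand_of_record)
        if "*" not in candidate.protein()[:-1]:
            return candidate
    raise ConstructError("could not place seed mutations without a stop codon")


# ---------------------------------------------------------------------------
# Editor profiles and named conditions
# ---------------------------------------------------------------------------

_BE3_CLASSES = {"C>T": 0.60, "G>A": 0.10, "C>G": 0.06, "C>A": 0.06,
                "A>G": 0.08, "T>C": 0.08, "A>C": 0.01, "T>G": 0.01}
_AIDMUT1_CLASSES = {"C>T": 0.5581, "G>A": 0.2019, "C>G": 0.07, "C>A": 0.05,
                    "A>G": 0.06, "T>C": 0.06}
# AIDmut2 deaminates the template strand: its template C>T signature reads
# as G>A on the coding strand the analyzer reports
_AIDMUT2_CLASSES = {"C>T": 0.5526, "G>A": 0.18, "C>G": 0.08, "C>A": 0.06,
                    "A>G": 0.06, "T>C": 0.0674}
_G4_CLASSES = {"C>T": 0.45, "C>A": 0.15, "C>G": 0.10, "G>A": 0.15,
               "A>G": 0.08, "T>C": 0.07}

# relative efficiency of truncated-guide 5' extensions, as the ratio of the
# observed overall rates to the same editor under conventional guidance
_AIDMUT1_EXT = {0: 6.82 / 10.2, 15: 9.71 / 10.2, 21: 9.97 / 10.2}
_AIDMUT2_EXT = {0: 2.36 / 6.23, 15: 7.87 / 6.23, 21: 10.7 / 6.23}


@dataclass(frozen=True)
class Condition:
    """One editor x guidance study condition, ready to simulate."""

    name: str
    profile: EditorProfile
    mode: str
    extension_len: int
    construct: NanobodyConstruct
    guides: tuple

    def config(self, pool_size: int, rng_seed: int, rounds: int = 3,
               sample_size: int | None = None) -> SimulationConfig:
        return SimulationConfig(
            construct=self.construct, profile=self.profile,
            guides=list(self.guides), mode=self.mode, rounds=rounds,
            pool_size=pool_size, rng_seed=rng_seed,
            sample_size=sample_size if sample_size is not None else pool_size,
            extension_len=self.extension_len)


def _profile(name, classes, strand, rate, *, share=None, ext=None,
             del_rate=0.0, del_lens=(9, 18), long_rate=0.0,
             off_frac=0.0) -> EditorProfile:
    return EditorProfile(
        name=name, class_probs=classes, edited_strand=strand,
        target_rate_per_kb=rate, target_cdr_share=share,
        deletion_rate_per_round=del_rate, deletion_lengths=del_lens,
        long_deletion_rate_per_round=long_rate,
        extension_multiplier=ext or {0: 1.0, 15: 1.0, 21: 1.0},
        off_window_fraction=off_frac)


# name -> (classes, strand, mode, ext_len, rate/kb, CDR share, deletion model)
_TABLE = {
    "g4_spontaneous":
        dict(classes=_G4_CLASSES, strand="template", mode="g4_spontaneous",
             ext_len=0, rate=161.0, share=None, del_rate=0.06,
             del_lens=(9, 18), long_rate=0.0, off_frac=0.02, target="g4"),
    "be3_conventional":
        dict(classes=_BE3_CLASSES, strand="coding", mode="conventional",
             ext_len=0, rate=2.92, share=None, del_rate=0.01, del_lens=(3,),
             long_rate=0.0, target="clean"),
    "aidmut1_conventional":
        dict(classes=_AIDMUT1_CLASSES, strand="coding", mode="conventional",
             ext_len=0, rate=10.2, share=None, del_rate=0.0,
             long_rate=0.01, target="clean"),
    "aidmut2_conventional":
        dict(classes=_AIDMUT2_CLASSES, strand="template", mode="conventional",
             ext_len=0, rate=6.23, share=None, del_rate=0.01, del_lens=(3,),
             long_rate=0.01, target="clean"),
    "aidmut1_delta":
        dict(classes=_AIDMUT1_CLASSES, strand="coding", mode="self_assembling",
             ext_len=0, rate=6.82, share=None, ext=_AIDMUT1_EXT, target="clean"),
    "aidmut2_delta":
        dict(classes=_AIDMUT2_CLASSES, strand="template", mode="self_assembling",
             ext_len=0, rate=2.36, share=None, ext=_AIDMUT2_EXT, target="clean"),
    "aidmut1_delta21":
        dict(classes=_AIDMUT1_CLASSES, strand="coding", mode="self_assembling",
             ext_len=21, rate=9.97, share=None, ext=_AIDMUT1_EXT, target="clean"),
    "aidmut2_delta21":
        dict(classes=_AIDMUT2_CLASSES, strand="template", mode="self_assembling",
             ext_len=21, rate=10.7, share=0.6222, ext=_AIDMUT2_EXT, target="clean"),
    "aidmut1_conv_seedmut":
        dict(classes=_AIDMUT1_CLASSES, strand="coding", mode="conventional",
             ext_len=0, rate=1.31, share=0.0, target="seedmut"),
    "aidmut2_conv_seedmut":
        dict(classes=_AIDMUT2_CLASSES, strand="template", mode="conventional",
             ext_len=0, rate=1.67, share=0.1429, target="seedmut"),
    "aidmut1_delta15":
        dict(classes=_AIDMUT1_CLASSES, strand="coding", mode="self_assembling",
             ext_len=15, rate=9.71, share=0.4054, ext=_AIDMUT1_EXT,
             target="seedmut"),
    "aidmut2_delta15":
        dict(classes=_AIDMUT2_CLASSES, strand="template", mode="self_assembling",
             ext_len=15, rate=7.87, share=0.3939, ext=_AIDMUT2_EXT,
             target="seedmut"),
}

CONDITION_NAMES = tuple(_TABLE)


def get_condition(name: str) -> Condition:
    """Build a named study condition (construct, guides, calibrated profile)."""
    if name not in _TABLE:
        raise KeyError(f"unknown condition {name!r}; "
                       f"choose from {CONDITION_NAMES}")
    spec = _TABLE[name]
    clean = synthetic_reference()
    if spec["target"] == "g4":
        construct = synthetic_g4_reference()
    elif spec["target"] == "seedmut":
        construct = seed_mutated_reference(clean)
    else:
        construct = clean
    mode = spec["mode"]
    if mode == "conventional":
        guides = tuple(default_guides(clean))  # spacers from the clean design
    elif mode == "self_assembling":
        guides = tuple(truncated_guides(clean, spec["ext_len"]))
    else:
        guides = ()
    profile = _profile(name, spec["classes"], spec["strand"], spec["rate"],
                       share=spec["share"], ext=spec.get("ext"),
                       del_rate=spec.get("del_rate", 0.0),
                       del_lens=spec.get("del_lens", (9, 18)),
                       long_rate=spec.get("long_rate", 0.0),
                       off_frac=spec.get("off_frac", 0.0))
    return Condition(name, profile, mode, spec["ext_len"], construct, guides)


def run_condition(name: str, rng_seed: int, pool_size: int = 200,
                  rounds: int = 3, sample_size: int | None = None,
                  construct_override: NanobodyConstruct | None = None
                  ) -> tuple[MutationReport, list, "object", SimulationConfig]:
    """Simulate a named condition and analyze the sequenced sample.

    Returns (report, pool, ledger, config). The analysis reference is the
    condition's own starting construct (pre-existing seed mutations are not
    counted as mutations, as in the source experiments).
    """
    cond = get_condition(name)
    cfg = cond.config(pool_size, rng_seed, rounds, sample_size)
    if construct_override is not None:
        cfg = SimulationConfig(
            construct=construct_override, profile=cfg.profile,
            guides=cfg.guides, mode=cfg.mode, rounds=cfg.rounds,
            pool_size=cfg.pool_size, rng_seed=cfg.rng_seed,
            sample_size=cfg.sample_size, extension_len=cfg.extension_len)
    pool, ledger = simulate_pool(cfg)
    sample = sample_sequenced_reads(pool, cfg.sample_size,
                                    (cfg.rng_seed + 10007) % (2 ** 31))
    report = analyze_pool(sample, cfg.construct)
    return report, pool, ledger, cfg
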