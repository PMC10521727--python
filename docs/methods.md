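# Methods

`gdpanedit` models gene designated-region pan-editing (GDP): CRISPR
base-editor mutagenesis confined to the complementarity-determining regions
(CDRs) of a nanobody gene, used to build synthetic antibody libraries
without animal immunization. The package covers the computational side of
that workflow — construct and guide design, a stochastic simulator that
stands in for the (undeposited) Sanger-sequencing data, the
mutation-spectrum analysis that such experiments report, and an occupancy
model of effective library size.

## The editing model

A pool of cells each carries one integrated copy of the nanobody gene.
Transfection rounds are synchronous global steps (3 by default); no cell
division, selection or transfection-efficiency heterogeneity is modeled.
Per round and per guide, each position of the deaminase-accessible window is
substituted with probability

    p_base x pref(base) x activity(guide) x ext(extension)

* **Window.** Positions −10…−50 relative to the PAM, with the PAM occupying
  +1…+3 on the guide's strand. This window is far wider than canonical
  cytidine-base-editor windows; it is treated as a per-guide footprint (the
  alternative — an aggregate footprint over the three co-expressed guides —
  is not modeled). Internally all arithmetic is 0-based half-open on the
  plus strand; PAM-relative numbering is a presentation layer.
* **Base preference and spectrum.** A profile is specified as a distribution
  over substitution classes on the edited strand (e.g. C>T 0.60 for a
  coding-strand cytidine editor). At setup the per-base preference is
  derived as `pref(b) = class_mass(b) / composition(b)` over the editable
  window, so that the realized class shares reproduce the configured
  distribution on any reference; the conditional 4x4 spectrum (rows
  normalized over the three alternatives) is derived from the same table.
  Editors that deaminate the template strand (profile flag) produce coding
  G>A calls from template C>T events; the simulator works in edited-strand
  space and complements on write.
* **Guide activity.** Activity decays geometrically with spacer/protospacer
  mismatches, `activity = 0.2^m`, calibrated to the single published
  anchor point that two seed mismatches cost 96% of guidance function.
  Mismatch position is ignored — every spacer position weighs equally —
  because only the 2-mismatch case is quantified; position weighting is a
  natural extension hook. Conventional guides keep their designed spacer, so
  each cell's activity is re-evaluated every round against its current
  sequence (deleted positions count as mismatches). Self-assembling
  (truncated) guides re-derive their spacer from the cell's own transcript:
  if the 14-nt framework anchor immediately 3' of the CDR is intact, the
  acquired spacer matches its protospacer by construction and activity is
  the extension multiplier; if the anchor is mutated, assembly fails and the
  guide is silent that round.
* **Extension multiplier.** gRNAΔ, gRNAΔ15 and gRNAΔ21 differ mechanically
  only in a 5' extension; functionally the profile supplies a relative
  efficiency per extension length (the observed rate ratios to conventional
  guidance). The mechanism behind Δ21 > Δ0 is not modeled.
* **Quadruplex mode.** The guide-free G4 condition edits CDR positions (the
  grafted quadruplex fragments) at full weight and all other positions at a
  small fraction (0.02), with the template strand edited — the G-rich coding
  strand folds, exposing its complement.
* **Deletions.** In-frame deletions (9/18 nt in the G4 condition, emulating
  the observed 3/6-amino-acid CDR2 deletions; 3 nt at low rate for editors
  with reported deletion classes) are injected at most once per round,
  left-aligned against the reference. Rare long-range deletions (≥30 nt,
  rate 0.01/round for the AID-variant conventional conditions) are emitted
  specifically so the analyzer's exclusion rule is exercised.
* **RNG.** One seed per simulation; each cell draws from a substream keyed
  by its index (`SeedSequence(seed, spawn_key=(cell,))`), so growing the
  pool never reshuffles earlier cells.

## Calibration

Profiles state a target overall mutation rate (per 1000 bp after the full
run) rather than a per-base probability, because the published quantities
are rates. A first-order inversion
(`p = rate/1000 x L / (rounds x editable_positions)`) is inadequate at the
extremes this package must reproduce: at 161/1000 bp two thirds of CDR
positions are hit (saturation and back-mutation), and conventional guides
lose activity round over round as their protospacers mutate. The simulator
therefore solves for `p` by bisection on an exact expectation: each
position evolves as a 4-state Markov chain under the per-round, per-guide
edit probabilities, with conventional-guide activity decay folded in through
a Poisson approximation of accumulated spacer mismatches, and deletion
coverage added per position. This expectation matches Monte-Carlo means to
within sampling error (it is exact for the guide-free mode).

Conditions with a published CDR share of mutations additionally carry a
CDR-bias multiplier applied to window positions inside CDRs, solved in
closed form from the target share and the pref-weighted window composition.
Conditions without a published share use bias 1; their CDR share is then an
emergent property of window/CDR geometry.

## Analysis pipeline

Mutant clones are globally aligned to the reference (match +1, mismatch −2,
gap open −8, gap extend −2). The gap penalties are deliberately stiff: a
gap run of length k costs 8 + 2k, so a spurious deletion+insertion pair can
never outscore a run of substitutions (that would require 3k > 2(8 + 2k)),
which keeps hypermutated CDR clusters called as substitutions; true
deletions are still forced by the length deficit of a global alignment.
Gaps are shifted maximally 5'-ward among equal-score placements by rotating
flanking matched bases (VCF-style normalization), and the simulator records
its deletions at the same normalized placement. Sequences below 70% global
identity are rejected; sequences containing a deletion run ≥30 nt are
excluded whole, mirroring the exclusion of long-range deletion artifacts
from the source analyses.

Rates use the convention `1000 x mutated reference positions /
(n_sequences x reference_length)`, with multi-nucleotide deletions counted
per deleted position; both choices are switches (`count_deletions_per_base`)
since the original counting convention is not stated. Insertions are called
and counted but excluded from rate statistics. The base-composition-after
vector applies the called events to the reference composition; when no
insertions are flagged this equals the composition of the analyzed mutant
sequences exactly (a mass-balance identity asserted in the tests). With
dense mutation adjacent to a true deletion the maximum-score alignment is
occasionally a genuinely different parsimony interpretation than the
injected events (e.g. the gap placed over a substituted run, or a longer
deletion plus an insertion); totals are essentially unaffected and the
round-trip tests therefore pin exactness on deletion-free pools and
physiological deletion densities.

## Synthetic reference and fixtures

The nanobody sequences behind the motivating experiments are not deposited,
so the packaged reference is a synthetic VHH-style construct: a 357-nt ORF,
FR1(75) CDR1(24) FR2(51) CDR2(24) FR3(114) CDR3(36) FR4(33), built from a
plausible nanobody protein sequence with cycling codon choice, no internal
stop, and the first framework codon after each CDR fixed to GGG so that an
NGG PAM sits at each CDR 3' boundary. Consequences of that geometry: the
conventional spacer for each CDR is the 20 nt at the CDR 3' end, the
truncated-guide anchor (the 14 nt after the CDR) contains the PAM and never
overlaps the spacer, and the editing window covers the CDR 3' portion plus
upstream framework. The G4-grafted variant replaces the CDRs with literature
promoter quadruplexes (VEGF, c-myc, BCL-2), trimmed to frame-preserving
lengths that scan positive under the G2+N1-7 motif rule and introduce no
stop codon. The seed-mutated target used for the iterativity comparison
carries two transition substitutions inside each of the three protospacers
(offsets chosen deterministically to avoid stop codons); the published
description mutates "the" 20-bp seed recognition site, but only suppression
of all three guides is consistent with the reported global rate collapse,
so all three spacers are pre-mutated.

Each packaged condition couples an editor class distribution to a guidance
mode and its published overall rate (and CDR share where printed):
G4-spontaneous 161/1000; BE3, AIDmut1, AIDmut2 conventional 2.92, 10.2,
6.23; AIDmut1/2 with gRNAΔ 6.82, 2.36; with gRNAΔ21 9.97, 10.7 (62.22% CDR
for AIDmut2); on the seed-mutated target, conventional 1.31 (0% CDR) and
1.67 (14.29% CDR), gRNAΔ15 9.71 (40.54%) and 7.87 (39.39%). Class
distributions fix the published modal shares (C>T 60% BE3, 55.81% AIDmut1;
template C>T = coding G>A 55.26% AIDmut2) and spread the remainder over
minor classes in roughly the proportions such editors produce; the G4
distribution is a choice (G>A-dominant on the coding strand) since no
breakdown is printed.

## What the simulator does and does not emulate

It reproduces: pools of ≥10 near-identical ~360-nt sequences; substitutions
concentrated in editing windows around the CDRs with strand-biased C>T/G>A
spectra; occasional in-frame deletions and rare long-range deletions; the
iterativity contrast between fixed-spacer and self-assembled guidance; and
the printed aggregate statistics as calibrated expectations. It does not
emulate: Sanger chromatogram noise or basecalling error, PCR/cloning bias,
chromatin or sequence-context effects on deaminase activity (beyond the
base-preference weights), RNase processing of the gRNAΔ:mRNA duplex
(modeled only as the exact-anchor rule), cell fitness effects, or
transfection heterogeneity. Passing round-trip tests therefore demonstrates
internal consistency of simulator and analyzer under the stated model, not
fidelity to any particular wet-lab dataset.

## Diversity estimation

Effective library size is the expected number of distinct variant sequences
in a pool of P cells. With variant classes indexed by mutation count k
(class size `N_k = C(E,k) * 3^k` over E editable positions) and within-class
uniformity, `E[distinct] = sum_k N_k (1 - (1 - w_k/N_k)^P)`, evaluated in
the log domain (N_k overflows doubles long before nanobody scale). Real
editors concentrate mass on preferred positions, making the uniform formula
an upper bound on occupancy evenness; a weighted path uses the generator's
own position/alternative weights — exact enumeration for k ≤ 2 (which hold
all collision mass at desk scale) and a second-order birthday correction
with elementary-symmetric-polynomial sums for k ≥ 3. Desk-scale validation
(10^4-cell pools) uses the weighted path; the 10^8-cell projection under a
Poisson(4) mutation load uses the uniform formula and clears 10^7 distinct
variants comfortably.

## Problem sizes and numerical choices

Tests and the acceptance script run pools of 60–1000 cells (10^4 for the
diversity check) on the 357-nt construct — sizes at which every calibrated
rate is resolved to ~3 standard errors in seconds. Calibration bisects 60
iterations; probabilities are clipped to [0,1]; spectrum rows with zero
class mass fall back to uniform over the three alternatives so they remain
distributions; greedy motif selection breaks ties left-to-right, longest
match first, '+' strand before '−'; deletion placement resamples only among
fully intact (undeleted) start positions and skips the event if none exist.
Degenerate inputs (template shorter than a primer, CDR too close to the
transcript end for an anchor, empty pools) raise typed errors or return
empty results as documented per function.

## Known limitations

* The seed-mismatch activity model is a single-parameter geometric decay
  anchored at one published point; real mismatch tolerance is
  position-dependent.
* Class-share calibration is first-order: under heavy saturation (the G4
  condition) realized shares drift a few points from the configured
  distribution as preferred bases are consumed.
* The weighted diversity estimator assumes product-form variant
  probabilities (independent position picks conditioned on k), ignoring the
  mild negative correlation that guide-activity decay induces between early
  and late edits.
* The exclusion rule keys on deletion run length only; a biological ≥30-nt
  deletion would be excluded like an artifact, as in the source analyses.
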