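# Methods

This note records the models, rules and numerical choices behind `setfam`,
and what the synthetic-data tests do and do not demonstrate about real data.

## The classification model

A protein is summarised by its **architecture**: the N→C ordered list of
canonical domain names derived from a domain-hit table (1-based inclusive
coordinates; any CD-search/PFAM-style scan can produce it). Classification
is catalog-driven and total — every SET-carrying protein receives exactly
one hierarchical label:

1. **Canonicalisation.** Domain names pass through a case-insensitive
   synonym map (`Post-SET` → `PostSET`, `zf-C2H2` → `ZnF_C2H2`,
   `SAD_SRA` → `SRA`, …). Unknown names pass through unchanged and are
   treated as extras; the tables' "extra domains" columns contain many
   one-off names and erroring on them would be wrong.
2. **Hit resolution.** Hits overlapping reciprocally by >50% are competing
   calls for one region: higher score wins, then longer hit, then smaller
   start.
3. **Signature extraction.** The signature vocabulary is the union of the
   domains of all exactly-matchable catalog backbones; everything outside
   it is an extra and is stripped before matching. Repeat counts are
   significant (`PHD-AWS-SET` ≠ `PHD-PHD-PHD-AWS-SET`).
4. **Exact match.** The stripped signature is compared to catalog backbones
   as a whole list, so extensions can never fall back onto a prefix entry
   (`AWS-SET-PostSET` is II-1B, never II-1A).
5. **Class V rules.** Failing an exact match: a Rubisco-LSMT
   substrate-binding domain makes a SETD; TPR repeats with no other
   signature domain make a TPR protein. These are marker rules, not
   backbone comparisons, because the published architectures of this class
   are heterogeneous.
6. **Nearest-family Orphans.** A signature with no backbone match but a
   family-diagnostic bigram — `AWS-SET` adjacency (Ash); `PreSET-SET`
   adjacency without SRA (Su(var)); PWWP or PHD anywhere upstream of SET
   (Trx) — is assigned that family's Orphan subgroup (`match_kind:
   fallback_bigram`). Checked in that order; exact matching already
   resolves the one printed architecture (`PWWP-AWS-SET`, Trx III-2D) that
   would otherwise trip the Ash rule.
7. **Homology fallback.** Bare or interrupted SET domains carry no
   architectural signal. Their SET substring is globally aligned to
   reference SET domains; the best-identity reference with ≥0.8 coverage
   assigns its family's Orphan subgroup if identity ≥0.3, else the protein
   is a Class V Orphan. The 30%/80% defaults are conventional
   remote-homology thresholds; the underlying survey never quantified
   "significantly low homology". E(z) has no printed Orphan subgroup, so
   an E(z)-nearest bare SET also lands in Class V Orphan.

### Duplicate backbones

The published tables print the same backbone under two families:
`PHD-PreSET-SET` appears as Trx III-3D (in Mp) and Su(var) IV-2B (in Sm),
and the bare `SET` backbone is the Orphan row of all three family tables.
The catalog therefore enforces backbone uniqueness only *within* a family.
A cross-family exact-match tie is resolved by SET-domain homology to the
candidate families' references (the survey itself combined domain
organisation with sequence alignment); without sequences the earlier
catalog entry wins deterministically.

### The E(z) catalog block

Class I has no published table; its seven variants are transcribed from a
schematic figure and prose constraints (PreSET in rice and *Selaginella*;
a vanadium-binding domain in *Physcomitrella* and *Marchantia*; CSR and
MSL *Ostreococcus*-specific; SANT rice-only; no E(z) in *Cyanophora* or
*Volvox*). The ids I-1…I-7 and their phyletic profiles are this package's
own reconstruction and are marked as such in the catalog file.

## Identification

* **ORF extraction** scans all six frames; an ORF runs from an ATG
  (`require_atg=False` switches to stop-to-stop) to the first in-frame
  stop or the sequence end. Ties break by frame order (+1, +2, +3, −1, −2,
  −3), then 5′-most start. Default minimum 100 aa.
* **Candidate filter**: ≥1 SET hit with score ≥ `min_score` (default 0 —
  precomputed hit tables are trusted; the threshold exists for noisy
  scans). The 200–3500 aa window is the observed length range of SET
  proteins and is enforced as a warning, not a drop (strict mode
  available): it was reported as a result, not used as a criterion. The
  hit-table integrity check (unknown protein ids → error) is restricted to
  SET hits so that re-filtering a filtered set is a no-op.
* **Interrupted SET domains**: two SET hits separated by ≥10 aa whose
  union spans ≤400 aa *and whose combined length is ≤170 aa* (about one
  130–150 aa SET domain) merge into one hit flagged `interrupted`. The
  combined-length cap is this package's refinement: without it the rule
  collapses the genuine tandem SET domains of type IV-1C
  (`SRA-PreSET-SET-SET`).
* **Redundancy removal**: per (species, locus) the longest sequence
  survives (ties: lexicographically smallest id); then per species,
  proteins with byte-identical SET substrings collapse to the longest
  carrier. Within-species comparison is an assumption — the survey did not
  state the scope of its redundancy removal.

## Alignment and nomenclature

Global Needleman–Wunsch via Biopython's `PairwiseAligner` with BLOSUM62,
gap open 10, extend 0.5 (affine). Identity = matches / aligned columns
with terminal-gap columns excluded; coverage = aligned fraction of the
shorter sequence. A progressive multiple alignment is deliberately not
built: all-pairs global alignment is fully specifiable, testable against a
brute-force enumerator, and feeds the distance phylogeny directly.

Names are *CapitalizedHomolog* + lowercase species code (`SDG8cr`). When a
base name recurs within a species the whole group gains `-a`, `-b`, …
suffixes in assignment order (the first assignee is renamed
retroactively); hyphens avoid ambiguity with homolog names ending in
letters. Past `-z` the scheme extends to `-aa`, `-ab`, ….

The bundled reference FASTA
(`data/reference_set_domains_synthetic.fasta`) contains **synthetic**
surrogate SET-domain sequences carrying familiar Arabidopsis/rice gene
names (CLF, SDG8, ATX1, SUVH4, …), two per family, with pairwise identity
<0.35 enforced at generation. Real curated SET domains can be substituted
via `ReferenceSet.from_fasta` without touching any other component.

## Phylogeny

* **Distances**: p-distance, d(i,j) = 1 − identity, in [0, 1].
* **NJ**: classic Saitou–Nei agglomeration. Q-criterion ties (tolerance
  1e-12) break on the lexicographically smallest joined label pair, making
  the tree deterministic under label permutation. Negative branch-length
  estimates are clamped to 0 and logged. Exact on additive matrices —
  verified against the generating trees and an exhaustive topology search
  at 4–5 taxa, and against scikit-bio's independent NJ on perturbed
  matrices.
* **Bootstrap**: no MSA exists, so columns are taken from a
  reference-anchored pseudo-alignment — each position of the longest
  sequence holds the residue every other sequence aligns to it (gap if
  none). Columns are resampled with replacement; support = % of replicate
  trees containing each internal bipartition of the point-estimate tree.
  This is a documented approximation: anchor-invisible insertions are
  ignored, so supports on real, indel-rich families would be optimistic.
* **Clade purity**: per family, the maximum Jaccard overlap between the
  family's leaf set and either side of any edge's bipartition (the
  degenerate whole-tree side included, so a single-family input scores 1).
  Purity 1.0 means one edge splits the family off exactly.

## The synthetic generator

The generator emulates the survey's inputs at desk scale. Defaults are the
study conditions: one protein per `+` cell of the transcribed phyletic
matrices for all five classes (Class V, which has no published matrix,
uses species lists mirroring the prose: SETD from chlorophyta onward, TPR
from *Chlamydomonas* onward, Orphans in every species), 2 SET-free decoys
per species, 15% redundant truncated isoforms, 10% of proteins emitted
only as transcripts, and 5% per-site block mutation. That yields ~180
ground-truth proteins per run — a deliberate scale-down of the published
506-protein inventory that keeps every architecture type and phyletic
pattern intact while the full suite runs in well under a minute.

Mechanics worth knowing:

* Every domain name maps to one fixed random 60–150 aa block per run; SET
  blocks are the bundled family reference sequences (mutated per protein),
  so homology fallback and phylogeny behave as on real families. Class V
  proteins use a divergent random SET block.
* `mutation_rate` defaults to 0.05 rather than 0 because the redundancy
  rule (correctly) collapses byte-identical SET substrings: at rate 0 all
  same-species paralogs of a family would merge. Architectures are exact
  at any rate, since hits are emitted from the construction.
* Transcript UTRs are drawn from {C, G, T} only, so they can neither start
  nor extend an ORF; each transcript is verified to decode back to its
  protein before emission.
* Everything derives from the single config seed; identical configs give
  byte-identical files.

What passing these tests shows: the rule catalog, the pipeline plumbing
and the tree machinery are internally correct and deterministic. What they
do not show: robustness to real domain-scan noise (miscalled boundaries,
missing hits), real amino-acid composition, indels, or domain gain/loss
along a phylogeny — the generator simulates none of these, and the
published full-scale inventory (506 proteins from 16 public proteomes, and
the maximum-likelihood tree) is out of scope by design.

## Degenerate inputs and edge cases

Empty hit lists give empty architectures; architectures with neither SET
nor TPR raise a typed error (`NotSetPathwayError`); an empty catalog file
loads as an empty catalog with a warning; fewer than 3 phylogeny-eligible
proteins skips the tree stage; `n_reps=1` bootstrap yields supports in
{0, 100}; a protein whose every reference alignment falls below coverage
0.8 keeps the provisional Class V Orphan label.
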