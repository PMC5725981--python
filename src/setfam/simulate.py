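"""Ground-truth-labeled synthetic proteomes, transcriptomes and hit tables.

The generator emulates the study's inputs at desk scale: for every "+" cell
of the per-family phyletic matrices it plants a protein whose sequence embeds
the entry's domain backbone as concatenated domain blocks joined by random
linkers, with a matching domain-hit table.  Each domain name maps to one
fixed random block per run; SET blocks are derived from the bundled family
reference surrogates so that homology fallback and phylogeny behave as they
would on real families.  Decoy proteins (no SET), redundant isoforms sharing
a locus, and transcripts whose longest ORF encodes the protein provide the
noise the identification stage must remove.

Everything is reproducible from the config seed alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (Catalog, CatalogEntry, DomainHit, FAMILIES,
                      PRESENCE_COLUMN_ORDER, load_catalog)
from .homology import ReferenceSet
from .identification import ProteinRecord, Transcript, extract_longest_orf

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: default species lists for the class V groups, mirroring the reported
#: pattern: SETD from chlorophyta onward, TPR first in Chlamydomonas with
#: peak abundance in pteridophytes, Orphans in every species.
DEFAULT_CLASSV_SPECIES = {
    "V-SETD": ("Cv", "Cr", "Vc", "Sm", "Os", "At"),
    "V-TPR": ("Cr", "Sm", "Pa", "Os", "At"),
    "V-Orphan": PRESENCE_COLUMN_ORDER,
}

_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table
        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic proteome.

    Defaults plant one protein per "+" cell of the transcribed phyletic
    matrices (all five classes), add two SET-free decoys per species, give
    15% of proteins a redundant truncated isoform and emit 10% of proteins
    only as transcripts.  ``mutation_rate`` perturbs every domain block per
    protein; the default 0.05 approximates within-family SET divergence and
    keeps SET substrings distinct between paralogs (identical substrings
    are, by design, collapsed by redundancy removal).  Architectures are
    exact at any rate - hits are emitted from the construction.
    """

    seed: int
    proteins_per_cell: int = 1
    decoys_per_species: int = 2
    isoform_rate: float = 0.15
    transcript_fraction: float = 0.10
    mutation_rate: float = 0.05
    extra_domain_prob: float = 0.3
    include_families: tuple[str, ...] = FAMILIES
    classv_species: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v)
                                 for k, v in DEFAULT_CLASSV_SPECIES.items()})
    #: family -> boolean DataFrame (catalog labels x species) replacing the
    #: transcribed phyletic matrix for that family
    presence_overrides: dict[str, pd.DataFrame] | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("isoform_rate", "transcript_fraction", "mutation_rate",
                     "extra_domain_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.proteins_per_cell < 1:
            raise ValueError("proteins_per_cell must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    label: str
    architecture: str          # full N->C architecture incl. planted extras
    species: str
    locus: str


@dataclass
class SyntheticTruth:
    records: dict[str, TruthRecord]
    expected_counts: pd.DataFrame               # species x family
    expected_presence: dict[str, pd.DataFrame]  # family -> type x species
    decoy_ids: list[str]
    isoform_ids: list[str]
    transcript_ids: list[str]

    def to_json(self) -> str:
        return json.dumps({
            "records": {pid: vars(r) for pid, r in sorted(self.records.items())},
            "expected_counts": self.expected_counts.to_dict(),
            "expected_presence": {f: m.to_dict()
                                  for f, m in self.expected_presence.items()},
            "decoy_ids": sorted(self.decoy_ids),
            "isoform_ids": sorted(self.isoform_ids),
            "transcript_ids": sorted(self.transcript_ids),
        }, indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    proteins: list[ProteinRecord]
    transcripts: list[Transcript]
    hits: list[DomainHit]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteins.fasta",
            "transcripts": outdir / "transcripts.fasta",
            "hits": outdir / "hits.tsv",
            "truth": outdir / "truth.json",
        }
        with open(paths["proteins"], "w") as fh:
            for p in self.proteins:
                fh.write(f">{p.protein_id} species={p.species}"
                         f" locus={p.locus_id or '-'}\n")
                for i in range(0, len(p.sequence), 60):
                    fh.write(p.sequence[i:i + 60] + "\n")
        with open(paths["transcripts"], "w") as fh:
            for t in self.transcripts:
                fh.write(f">{t.transcript_id} species={t.species}\n")
                for i in range(0, len(t.sequence), 60):
                    fh.write(t.sequence[i:i + 60] + "\n")
        pd.DataFrame(
            [(h.protein_id, h.domain, h.start, h.end, h.score)
             for h in self.hits],
            columns=["protein_id", "domain", "start", "end", "score"],
        ).to_csv(paths["hits"], sep="\t", index=False)
        paths["truth"].write_text(self.truth.to_json())
        return paths


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA, size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        choices = AA[AA != chars[i]]
        chars[i] = rng.choice(choices)
    return "".join(chars)


class _BlockLibrary:
    """Fixed per-run domain blocks; SET blocks are family-specific."""

    def __init__(self, rng: np.random.Generator, references: ReferenceSet):
        self._rng = rng
        self._blocks: dict[str, str] = {}
        for fam in FAMILIES[:4]:
            refs = references.for_family(fam)
            if refs:
                self._blocks[f"SET::{fam}"] = refs[0].sequence
        # a divergent SET for class V proteins
        self._blocks["SET::ClassV"] = _random_seq(rng, 136)

    def get(self, domain: str, family: str | None = None) -> str:
        key = f"SET::{family}" if domain == "SET" and family else domain
        if key not in self._blocks:
            self._blocks[key] = _random_seq(
                self._rng, int(self._rng.integers(60, 151)))
        return self._blocks[key]


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    table = _codon_table()
    return "".join(rng.choice(table[aa]) for aa in protein)


def _as_transcript(p: ProteinRecord, rng: np.random.Generator,
                   max_tries: int = 8) -> Transcript:
    """Embed a protein as the longest ORF of a synthetic transcript.

    UTRs are drawn from {C, G, T} only, so they can neither start an
    upstream ORF nor extend the coding one; the construction is verified by
    re-running the ORF extractor and re-drawn in the (rare) event a longer
    ORF arises in another frame.
    """
    tid = f"{p.protein_id}_t"
    for _ in range(max_tries):
        utr5 = "".join(rng.choice(list("CGT"), size=int(rng.integers(12, 37))))
        utr3 = "".join(rng.choice(list("CGT"), size=int(rng.integers(12, 37))))
        nt = utr5 + _reverse_translate(p.sequence, rng) + "TAA" + utr3
        t = Transcript(tid, p.species, nt)
        orf = extract_longest_orf(t, min_aa=min(100, len(p.sequence)))
        if orf is not None and orf.sequence == p.sequence:
            return t
    raise RuntimeError(f"could not embed {p.protein_id} as longest ORF")


# ---------------------------------------------------------------------------
# proteome generation

def _plant_protein(pid: str, species: str, entry: CatalogEntry,
                   blocks: _BlockLibrary, rng: np.random.Generator,
                   cfg: GeneratorConfig) -> tuple[ProteinRecord, list[DomainHit], str]:
    family = entry.label.family
    domains = list(entry.backbone)
    if entry.label.class_code == "V" and entry.label.classv_kind == "TPR":
        domains = ["TPR", "TPR", "TPR", "SET"]
    if cfg.extra_domain_prob > 0 and entry.known_extras:
        if rng.random() < cfg.extra_domain_prob:
            extra = sorted(entry.known_extras)[
                int(rng.integers(0, len(entry.known_extras)))]
            domains = domains + [extra]
    parts = ["M" + _random_seq(rng, int(rng.integers(30, 61)))]
    hits: list[DomainHit] = []
    pos = len(parts[0])
    for dom in domains:
        block = mutate(blocks.get(dom, family), cfg.mutation_rate, rng)
        start = pos + 1
        parts.append(block)
        pos += len(block)
        hits.append(DomainHit(pid, dom, start, pos,
                              score=round(float(rng.uniform(60, 180)), 1)))
        linker = _random_seq(rng, int(rng.integers(10, 31)))
        parts.append(linker)
        pos += len(linker)
    # C-terminal tail keeps even bare-SET proteins inside the observed
    # 200-3500 aa length range
    tail = _random_seq(rng, int(rng.integers(40, 91)))
    parts.append(tail)
    seq = "".join(parts)
    locus = f"{pid}_loc"
    protein = ProteinRecord(pid, species, seq, locus_id=locus)
    return protein, hits, "-".join(domains)


def _split_set_hit(hits: list[DomainHit], rng: np.random.Generator) -> list[DomainHit]:
    """Split a SET hit into two sub-hits with a >=10 aa gap (interrupted SET)."""
    out = []
    for h in hits:
        if h.domain == "SET" and h.length > 80:
            third = h.length // 3
            gap = int(rng.integers(10, 21))
            out.append(DomainHit(h.protein_id, "SET", h.start,
                                 h.start + third - 1, h.score))
            out.append(DomainHit(h.protein_id, "SET",
                                 h.start + third + gap, h.end, h.score))
        else:
            out.append(h)
    return out


def generate_proteome(cfg: GeneratorConfig,
                      catalog: Catalog | None = None,
                      references: ReferenceSet | None = None) -> SyntheticBundle:
    """Emit a labeled synthetic proteome/transcriptome/hit-table bundle."""
    catalog = catalog or load_catalog()
    references = references or ReferenceSet.load_default()
    rng = np.random.default_rng(cfg.seed)
    blocks = _BlockLibrary(rng, references)

    proteins: list[ProteinRecord] = []
    transcripts: list[Transcript] = []
    hits: list[DomainHit] = []
    records: dict[str, TruthRecord] = {}
    decoy_ids, isoform_ids, transcript_ids = [], [], []

    planted: list[tuple[str, CatalogEntry]] = []
    for entry in catalog:
        fam = entry.label.family
        if fam in cfg.include_families and fam != "ClassV":
            override = (cfg.presence_overrides or {}).get(fam)
            for sp in PRESENCE_COLUMN_ORDER:
                if override is not None:
                    present = (str(entry.label) in override.index
                               and bool(override.loc[str(entry.label), sp]))
                else:
                    present = bool(entry.species_presence.get(sp))
                if present:
                    planted.extend((sp, entry) for _ in range(cfg.proteins_per_cell))
        elif fam == "ClassV" and "ClassV" in cfg.include_families:
            for sp in cfg.classv_species.get(str(entry.label), ()):
                planted.extend((sp, entry) for _ in range(cfg.proteins_per_cell))

    if not planted and cfg.transcript_fraction > 0:
        raise ValueError("transcript_fraction > 0 but no proteins are planted")

    counter: dict[tuple[str, str], int] = {}
    for sp, entry in planted:
        key = (sp, str(entry.label))
        counter[key] = counter.get(key, 0) + 1
        pid = f"{sp}_{str(entry.label)}_{counter[key]}"
        protein, phits, arch = _plant_protein(pid, sp, entry, blocks, rng, cfg)
        if (entry.label.class_code == "V"
                and entry.label.classv_kind == "Orphan" and rng.random() < 0.5):
            phits = _split_set_hit(phits, rng)
        as_transcript = rng.random() < cfg.transcript_fraction
        if as_transcript:
            final_pid = f"{pid}_t_orf"
            phits = [DomainHit(final_pid, h.domain, h.start, h.end, h.score)
                     for h in phits]
            transcripts.append(_as_transcript(protein, rng))
            transcript_ids.append(f"{pid}_t")
            locus = ""
        else:
            final_pid = pid
            proteins.append(protein)
            locus = protein.locus_id
            if rng.random() < cfg.isoform_rate:
                iso_id = f"{pid}_iso"
                iso_seq = protein.sequence[: max(60, int(0.6 * len(protein)))]
                proteins.append(ProteinRecord(iso_id, sp, iso_seq,
                                              locus_id=protein.locus_id))
                hits.extend(DomainHit(iso_id, h.domain, h.start, h.end, h.score)
                            for h in phits if h.end <= len(iso_seq))
                isoform_ids.append(iso_id)
        hits.extend(phits)
        records[final_pid] = TruthRecord(str(entry.label), arch, sp, locus)

    for sp in PRESENCE_COLUMN_ORDER:
        for k in range(cfg.decoys_per_species):
            pid = f"{sp}_decoy_{k + 1}"
            seq = "M" + _random_seq(rng, int(rng.integers(150, 401)))
            proteins.append(ProteinRecord(pid, sp, seq))
            if rng.random() < 0.5:
                start = int(rng.integers(10, 40))
                hits.append(DomainHit(pid, "PHD", start, start + 49,
                                      score=round(float(rng.uniform(40, 90)), 1)))
            decoy_ids.append(pid)

    truth = SyntheticTruth(
        records=records,
        expected_counts=_expected_counts(records),
        expected_presence=_expected_presence(records, catalog, cfg),
        decoy_ids=decoy_ids,
        isoform_ids=isoform_ids,
        transcript_ids=transcript_ids,
    )
    return SyntheticBundle(proteins, transcripts, hits, truth)


def _expected_counts(records: dict[str, TruthRecord]) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=list(PRESENCE_COLUMN_ORDER),
                          columns=list(FAMILIES))
    for rec in records.values():
        code = rec.label.split("-")[0]
        fam = {"I": "E(z)", "II": "Ash", "III": "Trx",
               "IV": "Su(var)", "V": "ClassV"}[code]
        counts.loc[rec.species, fam] += 1
    return counts


def _expected_presence(records: dict[str, TruthRecord], catalog: Catalog,
                       cfg: GeneratorConfig) -> dict[str, pd.DataFrame]:
    out = {}
    for fam in cfg.include_families:
        if fam == "ClassV":
            continue
        entries = catalog.family_entries(fam)
        mat = pd.DataFrame(False, index=[str(e.label) for e in entries],
                           columns=list(PRESENCE_COLUMN_ORDER))
        for rec in records.values():
            if rec.label in mat.index:
                mat.loc[rec.label, rec.species] = True
        out[fam] = mat
    return out


# ---------------------------------------------------------------------------
# family sequence sets for phylogeny tests

def generate_family_sequences(seed: int,
                              families: tuple[str, ...] = FAMILIES[:4],
                              n_per_family: int = 10,
                              mutation_rate: float = 0.05,
                              length: int = 130,
                              max_ancestor_identity: float = 0.4,
                              ) -> tuple[dict[str, str], dict[str, str]]:
    """Labeled SET-domain sequences from divergent per-family ancestors.

    One random ancestor is drawn per family (pairwise global-alignment
    identity below *max_ancestor_identity*, enforced by rejection), then
    descendants arise by point substitution at *mutation_rate* per site.
    Returns (id -> sequence, id -> family).
    """
    from .homology import global_align
    if len(families) < 1:
        raise ValueError("need at least one family")
    rng = np.random.default_rng(seed)
    ancestors: dict[str, str] = {}
    for fam in families:
        for _ in range(200):
            cand = _random_seq(rng, length)
            if all(global_align(cand, a).identity < max_ancestor_identity
                   for a in ancestors.values()):
                ancestors[fam] = cand
                break
        else:  # pragma: no cover - rejection virtually never exhausts
            raise RuntimeError("could not draw divergent ancestors")
    seqs, labels = {}, {}
    for fam, anc in ancestors.items():
        tag = fam.replace("(", "").replace(")", "").replace("/", "")
        for k in range(n_per_family):
            sid = f"{tag}_{k + 1}"
            seqs[sid] = mutate(anc, mutation_rate, rng)
            labels[sid] = fam
    return seqs, labels
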