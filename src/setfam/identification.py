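"""Building the non-redundant SET-candidate protein set.

Inputs are proteome FASTA records and/or transcriptome sequences; transcripts
are reduced to their longest open reading frame before domain screening.
Candidates are proteins with at least one SET domain hit in the accompanying
hit table; redundancy is removed per locus (longest isoform wins) and per
species (identical SET-domain substrings collapse to the longest carrier).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from Bio.Seq import Seq

from .catalog import DomainHit, SynonymMap

log = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
NT_ALPHABET = frozenset("ACGTUN")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    species: str
    sequence: str
    locus_id: str = ""
    source: str = "proteome"     # proteome | transdecoded

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id}")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id}: non-amino-acid characters {sorted(bad)}")

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    species: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.transcript_id}")
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"{self.transcript_id}: non-nucleotide characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass
class FilterConfig:
    """Candidate-filter settings.

    The 200-3500 aa window is the length range observed for SET proteins;
    by default out-of-range candidates are kept with a warning rather than
    dropped, since the range is an observation, not a selection criterion.
    """

    min_score: float = 0.0
    min_len: int = 200
    max_len: int = 3500
    strict_length: bool = False


# ---------------------------------------------------------------------------
# ORF extraction ("transdecoding")

_FRAMES = ((+1, 0), (+1, 1), (+1, 2), (-1, 0), (-1, 1), (-1, 2))


def _frame_orfs(aa: str, require_atg: bool) -> list[tuple[int, str]]:
    """(start_codon_index, peptide) for every ORF in one translated frame."""
    orfs = []
    if require_atg:
        seen_stop_after: int | None = None
        for i, res in enumerate(aa):
            if res != "M":
                continue
            stop = aa.find("*", i)
            pep = aa[i:stop] if stop != -1 else aa[i:]
            if pep:
                orfs.append((i, pep))
    else:
        pos = 0
        for chunk in aa.split("*"):
            if chunk:
                orfs.append((pos, chunk))
            pos += len(chunk) + 1
    return orfs


def extract_longest_orf(transcript: Transcript, min_aa: int = 100,
                        require_atg: bool = True) -> ProteinRecord | None:
    """Translate the longest ORF over all six reading frames.

    An ORF runs from an ATG (or from the frame start when ``require_atg`` is
    False) to the first in-frame stop or the sequence end.  Ties are broken
    by frame order (+1, +2, +3, -1, -2, -3), then by 5'-most start within
    the frame.  Returns ``None`` when the best ORF is shorter than *min_aa*.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = transcript.sequence
    best: tuple[int, int, int, str] | None = None  # (-len, frame_idx, start, pep)
    for frame_idx, (strand, offset) in enumerate(_FRAMES):
        nt = seq if strand == 1 else str(Seq(seq).reverse_complement())
        sub = nt[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate())
        for start, pep in _frame_orfs(aa, require_atg):
            key = (-len(pep), frame_idx, start, pep)
            if best is None or key < best:
                best = key
    if best is None or -best[0] < min_aa:
        return None
    return ProteinRecord(
        protein_id=f"{transcript.transcript_id}_orf",
        species=transcript.species,
        sequence=best[3],
        source="transdecoded",
    )


# ---------------------------------------------------------------------------
# SET-hit handling

def is_set_hit(hit: DomainHit, synonyms: SynonymMap | None = None) -> bool:
    name = synonyms.normalize(hit.domain) if synonyms else hit.domain
    return name == "SET"


def merge_interrupted_set_hits(hits: list[DomainHit],
                               min_gap: int = 10,
                               max_span: int = 400,
                               max_combined: int = 170) -> list[DomainHit]:
    """Merge split SET hits on one protein into an 'interrupted' SET hit.

    Two SET hits separated by a gap of at least *min_gap* residues are taken
    to be one interrupted domain - a hallmark of Orphan-type proteins - when
    their union spans at most *max_span* residues and their combined length
    stays within *max_combined* (roughly one 130-150 aa SET domain), so two
    genuine tandem SET domains are never collapsed.  Hits with smaller gaps
    merge silently (one fragmented prediction).
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out: list[DomainHit] = []
    for pid, phits in by_protein.items():
        sets = sorted((h for h in phits if h.domain == "SET"),
                      key=lambda h: (h.start, h.end))
        others = [h for h in phits if h.domain != "SET"]
        merged: list[DomainHit] = []
        for h in sets:
            if merged:
                prev = merged[-1]
                gap = h.start - prev.end - 1
                span = max(h.end, prev.end) - prev.start + 1
                combined = prev.length + h.length
                if span <= max_span and combined <= max_combined:
                    merged[-1] = replace(
                        prev,
                        end=max(h.end, prev.end),
                        score=max(h.score, prev.score),
                        interrupted=prev.interrupted or gap >= min_gap,
                    )
                    continue
            merged.append(h)
        out.extend(others)
        out.extend(merged)
    return sorted(out, key=lambda h: (h.protein_id, h.start, h.end))


def find_set_candidates(proteins: list[ProteinRecord], hits: list[DomainHit],
                        cfg: FilterConfig | None = None,
                        synonyms: SynonymMap | None = None) -> list[ProteinRecord]:
    """Keep proteins with at least one SET domain hit scoring >= min_score.

    Input order is preserved; the operation is idempotent.  SET hits
    referencing unknown protein ids are an error (they indicate id
    mismatches between the hit table and the sequence set); stray non-SET
    hits are ignored, so re-filtering an already filtered set is a no-op.
    """
    cfg = cfg or FilterConfig()
    known = {p.protein_id for p in proteins}
    set_hits = [h for h in hits if is_set_hit(h, synonyms)]
    unknown = sorted({h.protein_id for h in set_hits} - known)
    if unknown:
        raise ValueError(
            f"hit table references unknown proteins: {', '.join(unknown)}")
    with_set = {h.protein_id for h in set_hits if h.score >= cfg.min_score}
    out = []
    for p in proteins:
        if p.protein_id not in with_set:
            continue
        if not (cfg.min_len <= len(p) <= cfg.max_len):
            if cfg.strict_length:
                log.info("dropping %s: length %d outside [%d, %d]",
                         p.protein_id, len(p), cfg.min_len, cfg.max_len)
                continue
            log.warning("%s: length %d outside the expected range [%d, %d]",
                        p.protein_id, len(p), cfg.min_len, cfg.max_len)
        out.append(p)
    return out


def _set_substring(protein: ProteinRecord, hits_by_pid: dict[str, list[DomainHit]],
                   synonyms: SynonymMap | None) -> str | None:
    phits = [h for h in hits_by_pid.get(protein.protein_id, ())
             if is_set_hit(h, synonyms)]
    if not phits:
        return None
    h = max(phits, key=lambda h: (h.length, -h.start))
    return protein.sequence[h.start - 1: h.end]


def deduplicate(candidates: list[ProteinRecord], hits: list[DomainHit],
                synonyms: SynonymMap | None = None) -> list[ProteinRecord]:
    """Two-stage redundancy removal.

    1. Within each (species, locus) group the longest sequence survives
       (ties: lexicographically smallest protein id).
    2. Within each species, proteins whose SET-domain substrings are
       identical collapse to the longest protein (same tie-break).

    Deterministic and idempotent; never increases the protein count.
    """
    best_per_locus: dict[tuple[str, str], ProteinRecord] = {}
    no_locus: list[ProteinRecord] = []
    for p in candidates:
        if not p.locus_id:
            no_locus.append(p)
            continue
        key = (p.species, p.locus_id)
        cur = best_per_locus.get(key)
        # longer wins; on equal length the smaller id wins
        if cur is None or len(p) > len(cur) or (
                len(p) == len(cur) and p.protein_id < cur.protein_id):
            best_per_locus[key] = p
    no_locus_ids = {id(p) for p in no_locus}
    survivors = [p for p in candidates
                 if id(p) in no_locus_ids
                 or best_per_locus.get((p.species, p.locus_id)) is p]

    hits_by_pid: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_pid.setdefault(h.protein_id, []).append(h)
    best_per_set: dict[tuple[str, str], ProteinRecord] = {}
    keep_always: list[ProteinRecord] = []
    for p in survivors:
        sub = _set_substring(p, hits_by_pid, synonyms)
        if sub is None:
            keep_always.append(p)
            continue
        key = (p.species, sub)
        cur = best_per_set.get(key)
        if cur is None or len(p) > len(cur) or (
                len(p) == len(cur) and p.protein_id < cur.protein_id):
            best_per_set[key] = p
    chosen = {id(p) for p in best_per_set.values()} | {id(p) for p in keep_always}
    return [p for p in survivors if id(p) in chosen]
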