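"""Readers and writers for the pipeline's plain-text formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .catalog import DomainHit
from .classify import ClassifiedProtein
from .identification import ProteinRecord, Transcript

HIT_COLUMNS = ["protein_id", "domain", "start", "end", "score"]


def _header_tags(description: str) -> dict[str, str]:
    return dict(t.split("=", 1) for t in description.split() if "=" in t)


def read_protein_fasta(path: str | Path, species: str | None = None,
                       source: str = "proteome") -> list[ProteinRecord]:
    """Protein FASTA; ``species=`` and ``locus=`` header tags are honoured."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = _header_tags(rec.description)
        locus = tags.get("locus", "")
        out.append(ProteinRecord(
            protein_id=rec.id,
            species=tags.get("species", species or "?"),
            sequence=str(rec.seq).rstrip("*"),
            locus_id="" if locus == "-" else locus,
            source=source,
        ))
    return out


def read_transcript_fasta(path: str | Path,
                          species: str | None = None) -> list[Transcript]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = _header_tags(rec.description)
        out.append(Transcript(
            transcript_id=rec.id,
            species=tags.get("species", species or "?"),
            sequence=str(rec.seq),
        ))
    return out


def read_hits_tsv(path: str | Path) -> list[DomainHit]:
    """Domain-hit table: protein_id, domain, start, end, score (1-based)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: hit table lacks columns {missing}")
    return [DomainHit(str(r.protein_id), str(r.domain), int(r.start),
                      int(r.end), float(r.score))
            for r in df.itertuples(index=False)]


def write_hits_tsv(hits: list[DomainHit], path: str | Path) -> None:
    pd.DataFrame([(h.protein_id, h.domain, h.start, h.end, h.score)
                  for h in hits],
                 columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_protein_fasta(proteins: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id} species={p.species}"
                     f" locus={p.locus_id or '-'}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")


def classified_frame(classified: list[ClassifiedProtein],
                     names: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for cp in classified:
        rows.append({
            "protein_id": cp.protein.protein_id,
            "species": cp.protein.species,
            "name": (names or {}).get(cp.protein.protein_id, ""),
            "architecture": str(cp.architecture),
            "signature": str(cp.signature_architecture),
            "label": str(cp.label),
            "family": cp.label.family,
            "match_kind": cp.match_kind,
            "extras": ",".join(cp.extras),
            "nearest_reference": cp.nearest_reference or "",
            "reference_identity": (
                "" if cp.reference_identity is None
                else f"{cp.reference_identity:.3f}"),
        })
    return pd.DataFrame(rows)
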