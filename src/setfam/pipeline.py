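"""End-to-end orchestration: transdecode -> identify -> dedupe -> classify
-> name -> summarise -> filter -> phylogeny, with a reproducible manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as sio
from .catalog import Catalog, FAMILIES, load_catalog
from .classify import ClassifiedProtein, classify_all
from .homology import (AlignParams, NameRegistry, ReferenceSet,
                       assign_family_by_homology, make_base_name)
from .identification import (DomainHit, FilterConfig, ProteinRecord,
                             Transcript, deduplicate, extract_longest_orf,
                             find_set_candidates, is_set_hit,
                             merge_interrupted_set_hits)
from .phylogeny import (bootstrap_support, class_purity, nj_tree,
                        pdistance_matrix, write_newick, write_phylip)
from .summaries import (count_by_class_species, first_appearance_report,
                        phylogeny_input_filter, presence_matrix)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    proteome_fastas: list[Path] = field(default_factory=list)
    transcript_fastas: list[Path] = field(default_factory=list)
    hits_tsvs: list[Path] = field(default_factory=list)
    reference_fasta: Path | None = None       # default: bundled surrogates
    catalog_path: Path | None = None          # default: bundled catalog
    min_orf_aa: int = 100
    filter: FilterConfig = field(default_factory=FilterConfig)
    homology_threshold: float = 0.3
    homology_min_coverage: float = 0.8
    bootstrap_reps: int = 0                   # 0 = plain NJ tree, no supports
    include_family_orphans_in_tree: bool = False

    def validate(self) -> None:
        for p in (*self.proteome_fastas, *self.transcript_fastas,
                  *self.hits_tsvs):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _nearest_reference_names(classified: list[ClassifiedProtein],
                             hits_by_pid: dict[str, list[DomainHit]],
                             references: ReferenceSet, catalog: Catalog,
                             params: AlignParams | None = None) -> dict[str, str]:
    """Closest family reference per classified class I-IV protein."""
    nearest = {}
    for cp in classified:
        if cp.label.class_code == "V":
            continue
        if cp.nearest_reference:
            nearest[cp.protein.protein_id] = cp.nearest_reference
            continue
        phits = [h for h in hits_by_pid.get(cp.protein.protein_id, ())
                 if is_set_hit(h, catalog.synonyms)]
        if not phits:
            continue
        h = max(phits, key=lambda h: (h.length, -h.start))
        sub = ReferenceSet(references.for_family(cp.label.family)) \
            if references.for_family(cp.label.family) else references
        asg = assign_family_by_homology(
            cp.protein.sequence[h.start - 1:h.end], sub,
            threshold=0.0, min_coverage=0.0, params=params)
        if asg.nearest:
            nearest[cp.protein.protein_id] = asg.nearest
    return nearest


def run_pipeline(cfg: RunConfig,
                 proteins: list[ProteinRecord] | None = None,
                 transcripts: list[Transcript] | None = None,
                 hits: list[DomainHit] | None = None) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    Inputs may be given as files through *cfg* or directly in memory; the
    run is deterministic for fixed inputs and seed.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = load_catalog(cfg.catalog_path)
    references = (ReferenceSet.from_fasta(cfg.reference_fasta)
                  if cfg.reference_fasta else ReferenceSet.load_default())

    proteins = list(proteins or [])
    transcripts = list(transcripts or [])
    hits = list(hits or [])
    for p in cfg.proteome_fastas:
        proteins.extend(sio.read_protein_fasta(p))
    for p in cfg.transcript_fastas:
        transcripts.extend(sio.read_transcript_fasta(p))
    for p in cfg.hits_tsvs:
        hits.extend(sio.read_hits_tsv(p))

    manifest: dict = {"seed": cfg.seed, "stages": {}}
    stages = manifest["stages"]
    stages["input"] = {"proteins": len(proteins),
                       "transcripts": len(transcripts), "hits": len(hits)}

    # 1. transdecode
    transdecoded = []
    for t in transcripts:
        orf = extract_longest_orf(t, min_aa=cfg.min_orf_aa)
        if orf is not None:
            transdecoded.append(orf)
    all_proteins = proteins + transdecoded
    stages["transdecode"] = {"orfs": len(transdecoded)}

    # 2. identify SET candidates (merging split SET hits first)
    hits = merge_interrupted_set_hits(
        [DomainHit(h.protein_id, catalog.synonyms.normalize(h.domain),
                   h.start, h.end, h.score) for h in hits])
    try:
        candidates = find_set_candidates(all_proteins, hits, cfg.filter,
                                         catalog.synonyms)
    except ValueError as err:
        raise RuntimeError(f"identify stage failed: {err}") from err
    stages["identify"] = {"candidates": len(candidates)}

    # 3. dedupe
    unique = deduplicate(candidates, hits, catalog.synonyms)
    stages["dedupe"] = {"unique": len(unique)}
    sio.write_protein_fasta(unique, outdir / "candidates.fasta")

    # 4. classify
    classified = classify_all(unique, hits, catalog, references,
                              threshold=cfg.homology_threshold,
                              min_coverage=cfg.homology_min_coverage)
    by_family = {f: sum(cp.label.family == f for cp in classified)
                 for f in FAMILIES}
    stages["classify"] = {"classified": len(classified), "families": by_family}

    # 5. name
    hits_by_pid: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_pid.setdefault(h.protein_id, []).append(h)
    nearest = _nearest_reference_names(classified, hits_by_pid, references,
                                       catalog)
    registry = NameRegistry()
    for cp in classified:
        pid = cp.protein.protein_id
        if pid in nearest:
            registry.assign(pid, cp.protein.species,
                            make_base_name(nearest[pid], cp.protein.species))
    names = registry.names()
    stages["name"] = {"named": len(names)}
    sio.classified_frame(classified, names).to_csv(
        outdir / "classified.tsv", sep="\t", index=False)

    # 6. summarise
    counts = count_by_class_species(classified, catalog.panel)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    for family, fname in (("Ash", "ash"), ("Trx", "trx"),
                          ("Su(var)", "suvar"), ("E(z)", "ez")):
        mat = presence_matrix(classified, family, catalog)
        mat.replace({True: "+", False: "-"}).to_csv(
            outdir / f"presence_{fname}.tsv", sep="\t")
    first_appearance_report(catalog, catalog.panel).to_csv(
        outdir / "first_appearance.tsv", sep="\t", index=False)
    stages["summarise"] = {"total": int(counts.values.sum())}

    # 7. phylogeny of classifiable (non-Orphan, non-class-V) SET domains
    tree_input = phylogeny_input_filter(
        classified, include_family_orphans=cfg.include_family_orphans_in_tree)
    stages["phylogeny_input"] = {"proteins": len(tree_input)}
    if len(tree_input) >= 3:
        seqs = {}
        fam_labels = {}
        for cp in tree_input:
            phits = [h for h in hits_by_pid.get(cp.protein.protein_id, ())
                     if is_set_hit(h, catalog.synonyms)]
            if not phits:
                continue
            h = max(phits, key=lambda h: (h.length, -h.start))
            seqs[cp.protein.protein_id] = \
                cp.protein.sequence[h.start - 1:h.end]
            fam_labels[cp.protein.protein_id] = cp.label.family
        dm = pdistance_matrix(seqs)
        (outdir / "distances.phy").write_text(write_phylip(dm))
        if cfg.bootstrap_reps > 0:
            tree = bootstrap_support(seqs, n_reps=cfg.bootstrap_reps,
                                     seed=cfg.seed)
        else:
            tree = nj_tree(dm)
        (outdir / "tree.nwk").write_text(write_newick(tree))
        purity = class_purity(tree, fam_labels)
        stages["phylogeny"] = {
            "leaves": len(seqs),
            "class_purity": {k: round(v, 4) for k, v in purity.items()},
        }
    else:
        log.info("fewer than 3 phylogeny-eligible proteins; skipping tree")
        stages["phylogeny"] = {"leaves": 0}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
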