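"""Comparative summaries: class counts, phyletic profiles, first appearances.

These reproduce the study-style outputs: a species-by-family count table,
per-family presence/absence matrices over the architecture types, and the
earliest lineage in which a domain appears within a family context.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import (Catalog, CatalogEntry, FAMILIES, PRESENCE_COLUMN_ORDER,
                      SpeciesPanel)
from .classify import ClassifiedProtein


def count_by_class_species(classified: list[ClassifiedProtein],
                           panel: SpeciesPanel | None = None,
                           species_order: tuple[str, ...] = PRESENCE_COLUMN_ORDER,
                           ) -> pd.DataFrame:
    """Species x family count matrix (rows sum to per-species totals)."""
    panel = panel or SpeciesPanel.load()
    counts = pd.DataFrame(0, index=list(species_order), columns=list(FAMILIES))
    for cp in classified:
        sp = cp.protein.species
        if sp not in counts.index:
            raise ValueError(f"{cp.protein.protein_id}: unknown species {sp!r}")
        counts.loc[sp, cp.label.family] += 1
    return counts


def presence_matrix(classified: list[ClassifiedProtein], family: str,
                    catalog: Catalog,
                    species_order: tuple[str, ...] = PRESENCE_COLUMN_ORDER,
                    ) -> pd.DataFrame:
    """Architecture-type x species boolean matrix for one family.

    Rows are the family's catalog entries in catalog order; a cell is True
    iff at least one protein of that species carries exactly that label.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    rows = [e for e in catalog.family_entries(family)]
    mat = pd.DataFrame(False, index=[str(e.label) for e in rows],
                       columns=list(species_order))
    for cp in classified:
        key = str(cp.label)
        if cp.label.family == family and key in mat.index:
            mat.loc[key, cp.protein.species] = True
    return mat


@dataclass(frozen=True)
class FirstAppearance:
    domain: str
    context_class: str       # family name or "any"
    species: str
    lineage: str
    lineage_rank: int


def earliest_appearance(data, domain: str, context_class: str = "any",
                        panel: SpeciesPanel | None = None,
                        catalog: Catalog | None = None) -> FirstAppearance | None:
    """Earliest-diverging species in which *domain* occurs in *context_class*.

    *data* may be a list of classified proteins (occurrence = the domain in
    a protein's architecture) or a list of catalog entries (occurrence =
    the domain in an entry's backbone, weighted by its phyletic profile).
    Returns None when the domain occurs nowhere.
    """
    panel = panel or SpeciesPanel.load()
    present: set[str] = set()
    for item in data:
        if isinstance(item, ClassifiedProtein):
            if context_class not in ("any", item.label.family):
                continue
            if domain in item.architecture or domain in item.extras:
                present.add(item.protein.species)
        elif isinstance(item, CatalogEntry):
            if context_class not in ("any", item.label.family):
                continue
            if domain in item.backbone:
                present.update(
                    c for c, v in item.species_presence.items() if v)
        else:
            raise TypeError(f"cannot scan {type(item).__name__}")
    if not present:
        return None
    first = min((panel[c] for c in present), key=lambda s: s.lineage_rank)
    return FirstAppearance(domain=domain, context_class=context_class,
                           species=first.code, lineage=first.lineage,
                           lineage_rank=first.lineage_rank)


def first_appearance_report(catalog: Catalog,
                            panel: SpeciesPanel | None = None) -> pd.DataFrame:
    """Earliest lineage of every signature domain within every family."""
    panel = panel or SpeciesPanel.load()
    rows = []
    for family in FAMILIES[:4]:
        entries = catalog.family_entries(family)
        domains = sorted({d for e in entries for d in e.backbone})
        for dom in domains:
            fa = earliest_appearance(entries, dom, family, panel=panel)
            if fa is not None:
                rows.append({"family": family, "domain": dom,
                             "first_species": fa.species,
                             "first_lineage": fa.lineage,
                             "lineage_rank": fa.lineage_rank})
    return pd.DataFrame(rows)


def phylogeny_input_filter(classified: list[ClassifiedProtein],
                           include_family_orphans: bool = False,
                           ) -> list[ClassifiedProtein]:
    """Select the proteins eligible for SET-domain phylogeny.

    Class V (Orphan, SETD, TPR) proteins are excluded for their weak
    sequence similarity; family Orphans (bare SET domains placed by
    homology) are excluded by default for the same reason.
    """
    out = []
    for cp in classified:
        if cp.label.class_code == "V":
            continue
        if cp.label.family_orphan and not include_family_orphans:
            continue
        if cp.match_kind in ("fallback_homology", "fallback_bigram") \
                and not include_family_orphans:
            continue
        out.append(cp)
    return out
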