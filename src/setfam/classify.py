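"""Architecture-driven classification of SET-pathway proteins.

The classifier is catalog-driven and total: every protein carrying a SET
domain (or TPR repeats) receives exactly one hierarchical label.

Decision order per protein:

1. Strip extras: keep only domains from the signature vocabulary (the union
   of all matchable catalog backbones).  Repeat counts are significant
   (PHD-AWS-SET and PHD-PHD-PHD-AWS-SET are different types).
2. Exact backbone match -> the catalog entry's label.  When one backbone is
   printed under two families (PHD-PreSET-SET appears under both Trx and
   Su(var)), the SET-domain sequence decides by homology to family
   references; without sequences the earlier catalog entry wins.
3. Class V markers: a Rubisco-LSMT substrate-binding domain makes a SETD;
   TPR repeats without any canonical family domain make a TPR protein.
4. A family-diagnostic bigram (AWS-SET -> Ash; PreSET-SET without SRA ->
   Su(var); PWWP/PHD upstream of SET -> Trx) yields that family's Orphan.
5. Otherwise the SET domain goes to the homology fallback, landing in a
   family Orphan group (II/III/IV-Orphan) or, failing that, Class V Orphan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .catalog import (Architecture, Catalog, CatalogEntry, ClassLabel,
                      DomainHit, FAMILY_BY_CLASS)
from .homology import AlignParams, ReferenceSet, assign_family_by_homology
from .identification import ProteinRecord, is_set_hit

log = logging.getLogger(__name__)

#: class code keyed by family, for building family-Orphan labels
_CLASS_BY_FAMILY = {fam: code for code, fam in FAMILY_BY_CLASS.items()}

V_ORPHAN = ClassLabel("ClassV", "V", classv_kind="Orphan")
V_SETD = ClassLabel("ClassV", "V", classv_kind="SETD")
V_TPR = ClassLabel("ClassV", "V", classv_kind="TPR")


class NotSetPathwayError(ValueError):
    """Raised for architectures with neither a SET domain nor TPR repeats."""


def family_orphan_label(family: str) -> ClassLabel:
    code = _CLASS_BY_FAMILY[family]
    if code in ("II", "III", "IV"):
        return ClassLabel(family, code, family_orphan=True)
    # E(z) has no printed Orphan subgroup; such proteins fall to Class V
    return V_ORPHAN


# ---------------------------------------------------------------------------
# architecture construction from domain hits

def _reciprocal_overlap(a: DomainHit, b: DomainHit) -> bool:
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return False
    return ov / a.length > 0.5 and ov / b.length > 0.5


def build_architecture(hits: list[DomainHit],
                       catalog: Catalog | None = None) -> Architecture:
    """N->C architecture from a protein's domain hits.

    Hits overlapping reciprocally by more than 50% are competing calls for
    the same region: the higher score wins, then the longer hit, then the
    smaller start.  Names are canonicalized through the synonym map when a
    catalog is supplied.
    """
    if not hits:
        return Architecture(())
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    ranked = sorted(hits, key=lambda h: (-h.score, -h.length, h.start))
    kept: list[DomainHit] = []
    for h in ranked:
        if not any(_reciprocal_overlap(h, k) for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end))
    synonyms = catalog.synonyms if catalog is not None else None
    names = [synonyms.normalize(h.domain) if synonyms else h.domain for h in kept]
    return Architecture(names)


# ---------------------------------------------------------------------------
# classification

@dataclass(frozen=True)
class ClassificationResult:
    label: ClassLabel
    match_kind: str                       # exact | fallback_bigram | fallback_homology | classv
    signature: Architecture
    extras: tuple[str, ...]
    candidates: tuple[CatalogEntry, ...] = ()   # >1 on cross-family backbone ties


def split_signature(arch: Architecture, catalog: Catalog) -> tuple[list[str], list[str]]:
    """Partition an architecture into signature domains and extras."""
    sig, extras = [], []
    for name in arch:
        canon = catalog.synonyms.normalize(name)
        (sig if canon in catalog.signature_vocab else extras).append(canon)
    return sig, extras


def _bigram_family(sig: list[str]) -> str | None:
    for i in range(len(sig) - 1):
        if sig[i] == "AWS" and sig[i + 1] == "SET":
            return "Ash"
    if "SRA" not in sig:
        for i in range(len(sig) - 1):
            if sig[i] == "PreSET" and sig[i + 1] == "SET":
                return "Su(var)"
    if "SET" in sig:
        set_at = sig.index("SET")
        if any(d in ("PWWP", "PHD") for d in sig[:set_at]):
            return "Trx"
    return None


def classify_architecture(arch: Architecture, catalog: Catalog) -> ClassificationResult:
    """Map one ordered domain architecture to a class label.

    Proteins needing sequence evidence (bare SET domains, cross-family
    backbone ties) receive a provisional label with a non-exact
    ``match_kind``; :func:`classify_all` refines them by homology.
    """
    normalized = [catalog.synonyms.normalize(d) for d in arch]
    sig, extras = split_signature(Architecture(normalized), catalog)
    sig_arch = Architecture(sig)
    extras_t = tuple(extras)
    if "SET" not in sig and "TPR" not in normalized:
        raise NotSetPathwayError(
            f"not a SET-pathway protein: architecture {arch} has neither "
            "a SET domain nor TPR repeats")

    matches = catalog.exact_matches(sig)
    if matches:
        return ClassificationResult(matches[0].label, "exact", sig_arch,
                                    extras_t, tuple(matches))
    if "Rubis_subs_bind" in normalized:
        return ClassificationResult(V_SETD, "classv", sig_arch, extras_t)
    if "TPR" in normalized and set(sig) <= {"SET"}:
        return ClassificationResult(V_TPR, "classv", sig_arch, extras_t)
    if set(sig) <= {"SET"}:
        # bare or interrupted SET: decided by homology downstream
        return ClassificationResult(V_ORPHAN, "fallback_homology",
                                    sig_arch, extras_t)
    fam = _bigram_family(sig)
    if fam is not None:
        return ClassificationResult(family_orphan_label(fam), "fallback_bigram",
                                    sig_arch, extras_t)
    return ClassificationResult(V_ORPHAN, "fallback_homology", sig_arch, extras_t)


@dataclass(frozen=True)
class ClassifiedProtein:
    protein: ProteinRecord
    architecture: Architecture
    signature_architecture: Architecture
    label: ClassLabel
    extras: tuple[str, ...]
    match_kind: str
    ambiguous: bool = False          # exact match shared across families
    nearest_reference: str | None = None
    reference_identity: float | None = None


def _set_domain_sequence(protein: ProteinRecord, phits: list[DomainHit],
                         catalog: Catalog) -> str | None:
    sets = [h for h in phits if is_set_hit(h, catalog.synonyms)]
    if not sets:
        return None
    h = max(sets, key=lambda h: (h.length, -h.start))
    return protein.sequence[h.start - 1: h.end]


def classify_all(proteins: list[ProteinRecord], hits: list[DomainHit],
                 catalog: Catalog, references: ReferenceSet | None = None,
                 threshold: float = 0.3, min_coverage: float = 0.8,
                 params: AlignParams | None = None) -> list[ClassifiedProtein]:
    """Classify every protein; sequence evidence resolves the fallbacks.

    Every input protein appears exactly once in the output, in input order.
    """
    hits_by_pid: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_pid.setdefault(h.protein_id, []).append(h)

    out: list[ClassifiedProtein] = []
    for p in proteins:
        phits = hits_by_pid.get(p.protein_id, [])
        arch = build_architecture(phits, catalog)
        res = classify_architecture(arch, catalog)
        label, kind, ambiguous = res.label, res.match_kind, len(res.candidates) > 1
        nearest, ident = None, None

        set_seq = _set_domain_sequence(p, phits, catalog)
        if ambiguous and references is not None and set_seq:
            # same backbone under several families: best family identity wins
            fams = [e.label.family for e in res.candidates]
            sub = ReferenceSet([r for r in references if r.family in fams])
            if len(sub):
                asg = assign_family_by_homology(set_seq, sub, threshold=0.0,
                                                min_coverage=0.0, params=params)
                nearest, ident = asg.nearest, asg.identity
                for e in res.candidates:
                    if e.label.family == asg.family:
                        label = e.label
                        break
        elif kind == "fallback_homology" and references is not None and set_seq:
            asg = assign_family_by_homology(set_seq, references,
                                            threshold=threshold,
                                            min_coverage=min_coverage,
                                            params=params)
            nearest, ident = asg.nearest, asg.identity
            label = (family_orphan_label(asg.family)
                     if asg.family is not None else V_ORPHAN)
        elif kind == "fallback_homology":
            log.debug("%s: no references or SET sequence; keeping %s",
                      p.protein_id, label)

        out.append(ClassifiedProtein(
            protein=p, architecture=arch,
            signature_architecture=res.signature, label=label,
            extras=res.extras, match_kind=kind, ambiguous=ambiguous,
            nearest_reference=nearest, reference_identity=ident))
    return out
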