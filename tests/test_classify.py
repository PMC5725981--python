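"""Architecture construction and catalog-driven classification."""

import pytest

from setfam.catalog import Architecture, DomainHit
from setfam.classify import (NotSetPathwayError, build_architecture,
                             classify_all, classify_architecture)
from setfam.homology import ReferenceSet
from setfam.simulate import GeneratorConfig, generate_proteome, mutate
import numpy as np

# --------------------------------------------------------------------------
# build_architecture

def _h(dom, start, end, score=50.0, pid="p"):
    return DomainHit(pid, dom, start, end, score)


def test_hits_ordered_n_to_c():
    arch = build_architecture([_h("SET", 500, 640), _h("AWS", 430, 490)])
    assert list(arch) == ["AWS", "SET"]


def test_overlapping_hits_resolved_by_score():
    arch = build_architecture([_h("PHD", 100, 160, 30.0),
                               _h("PHD", 105, 165, 50.0)])
    assert list(arch) == ["PHD"]


def test_overlap_resolution_matches_reference_rule():
    rng = np.random.default_rng(42)
    for _ in range(25):
        hits = []
        for i in range(int(rng.integers(2, 6))):
            start = int(rng.integers(1, 200))
            length = int(rng.integers(30, 120))
            hits.append(_h(rng.choice(["PHD", "AWS", "SET"]), start,
                           start + length - 1, float(rng.integers(10, 90))))
        got = build_architecture(hits)
        greedy = []
        for h in sorted(hits, key=lambda h: (-h.score, -h.length, h.start)):
            ov = lambda a, b: min(a.end, b.end) - max(a.start, b.start) + 1
            if not any(ov(h, k) > 0 and ov(h, k) / h.length > 0.5
                       and ov(h, k) / k.length > 0.5 for k in greedy):
                greedy.append(h)
        greedy.sort(key=lambda h: (h.start, h.end))
        assert list(got) == [h.domain for h in greedy]


def test_empty_hits_give_empty_architecture():
    assert list(build_architecture([])) == []


def test_hits_from_multiple_proteins_rejected():
    with pytest.raises(ValueError):
        build_architecture([_h("SET", 1, 100, pid="a"),
                            _h("AWS", 1, 50, pid="b")])


# --------------------------------------------------------------------------
# classify_architecture

@pytest.mark.parametrize("domains,label,kind", [
    (["AWS", "SET"], "II-1A", "exact"),
    (["AWS", "SET", "PostSET"], "II-1B", "exact"),
    (["PWWP", "FYR", "PHD", "PHD", "SET"], "III-1A", "exact"),
    (["SRA", "PreSET", "SET", "SET"], "IV-1C", "exact"),
    (["ZnF_C2H2", "AWS", "SET", "ZnF_C2H2", "ZnF_C2H2"], "II-3C", "exact"),
    (["TCR", "PreSET", "SET"], "I-3", "exact"),
    (["SET"], "V-Orphan", "fallback_homology"),
    (["Rubis_subs_bind", "SET"], "V-SETD", "classv"),
    (["TPR", "TPR", "TPR", "SET"], "V-TPR", "classv"),
    # nearest-family Orphans via diagnostic bigrams
    (["SANT", "AWS", "SET"], "II-Orphan", "fallback_bigram"),
    (["SAND", "PreSET", "SET"], "IV-Orphan", "fallback_bigram"),
    (["PHD", "PHD", "PHD", "PHD", "SET"], "III-Orphan", "fallback_bigram"),
])
def test_classification_examples(catalog, domains, label, kind):
    res = classify_architecture(Architecture(domains), catalog)
    assert str(res.label) == label
    assert res.match_kind == kind


def test_catalog_roundtrip_every_backbone(catalog):
    """Classifying each matchable backbone returns that entry's label."""
    for entry in catalog:
        if not entry.matchable:
            continue
        res = classify_architecture(entry.backbone, catalog)
        assert res.match_kind == "exact"
        assert entry.label in {e.label for e in res.candidates}
        if len(res.candidates) == 1:
            assert res.label == entry.label


def test_prefix_safety(catalog):
    """Extended backbones never classify to their prefix entry."""
    by_backbone = {tuple(e.backbone): e for e in catalog if e.matchable}
    for bb, entry in by_backbone.items():
        for other in by_backbone:
            if len(other) > len(bb) and other[:len(bb)] == bb:
                res = classify_architecture(Architecture(other), catalog)
                assert str(res.label) != str(entry.label)


def test_extras_do_not_change_label(catalog):
    for extra in ("TUDOR", "PLN03081", "LIM", "FRILLYDOMAIN"):
        res = classify_architecture(
            Architecture(["AWS", "SET", extra]), catalog)
        assert str(res.label) == "II-1A"
        assert extra in res.extras
    res = classify_architecture(Architecture(["TUDOR", "AWS", "SET"]), catalog)
    assert str(res.label) == "II-1A"


def test_no_set_no_tpr_is_an_error(catalog):
    with pytest.raises(NotSetPathwayError):
        classify_architecture(Architecture(["PHD", "PWWP"]), catalog)


def test_synonyms_normalized_before_matching(catalog):
    res = classify_architecture(Architecture(["aws", "Set", "Post-SET"]),
                                catalog)
    assert str(res.label) == "II-1B"


# --------------------------------------------------------------------------
# classify_all with homology fallback

def _bare_set_protein(pid, species, seq):
    from setfam.identification import ProteinRecord
    pad = "M" + "G" * 60
    prot = ProteinRecord(pid, species, pad + seq + "A" * 60)
    hit = DomainHit(pid, "SET", len(pad) + 1, len(pad) + len(seq), 80.0)
    return prot, hit


def test_bare_set_near_ash_reference_becomes_family_orphan(catalog, references):
    rng = np.random.default_rng(0)
    ash = references.for_family("Ash")[0].sequence
    prot, hit = _bare_set_protein("q1", "Cr", mutate(ash, 0.04, rng))
    [cp] = classify_all([prot], [hit], catalog, references)
    assert str(cp.label) == "II-Orphan"
    assert cp.match_kind == "fallback_homology"
    assert cp.nearest_reference == references.for_family("Ash")[0].name


def test_bare_set_far_from_all_references_stays_class_v(catalog, references):
    rng = np.random.default_rng(1)
    random_set = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=130))
    prot, hit = _bare_set_protein("q2", "Cr", random_set)
    [cp] = classify_all([prot], [hit], catalog, references)
    assert str(cp.label) == "V-Orphan"


def test_exact_match_short_circuits_references(catalog, references):
    from setfam.identification import ProteinRecord
    prot = ProteinRecord("q3", "At", "M" + "A" * 400)
    hits = [DomainHit("q3", "AWS", 50, 110, 60.0),
            DomainHit("q3", "SET", 130, 260, 90.0)]
    [with_refs] = classify_all([prot], hits, catalog, references)
    [without] = classify_all([prot], hits, catalog, None)
    assert str(with_refs.label) == str(without.label) == "II-1A"


def test_cross_family_tie_resolved_by_set_homology(catalog, references):
    """PHD-PreSET-SET is printed under both Trx and Su(var); the SET
    sequence decides."""
    from setfam.identification import ProteinRecord
    rng = np.random.default_rng(2)
    for fam, want in (("Trx", "III-3D"), ("Su(var)", "IV-2B")):
        ref = references.for_family(fam)[0].sequence
        set_seq = mutate(ref, 0.05, rng)
        pad = "M" + "G" * 40
        seq = pad + "W" * 60 + "L" * 10 + "C" * 90 + "V" * 10 + set_seq + "A" * 40
        pid = f"tie_{fam}"
        prot = ProteinRecord(pid, "Sm", seq)
        s0 = len(pad) + 1
        hits = [DomainHit(pid, "PHD", s0, s0 + 59, 50.0),
                DomainHit(pid, "PreSET", s0 + 70, s0 + 159, 50.0),
                DomainHit(pid, "SET", s0 + 170, s0 + 170 + len(set_seq) - 1,
                          90.0)]
        [cp] = classify_all([prot], hits, catalog, references)
        assert cp.ambiguous
        assert str(cp.label) == want


def test_totality_on_synthetic_proteome(catalog, references, bundle,
                                        all_proteins):
    from setfam.identification import find_set_candidates
    cands = find_set_candidates(all_proteins, bundle.hits,
                                synonyms=catalog.synonyms)
    classified = classify_all(cands, bundle.hits, catalog, references)
    assert len(classified) == len(cands)
    assert all(cp.label is not None for cp in classified)
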