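"""Domain vocabulary, species panel and the architecture rule catalog.

The classification scheme used throughout this package maps a protein's
ordered (N->C) domain architecture onto a hierarchy of five classes of
SET-domain proteins:

* Class I   -- E(z), the catalytic PRC2 subunit family (H3K27 methylation)
* Class II  -- Ash, marked by the AWS domain directly N-terminal of SET
* Class III -- Trx, rich in PHD / PWWP / FYR reader domains
* Class IV  -- Su(var), marked by PreSET and, in one branch, the SRA domain
* Class V   -- Orphan / SETD (Rubisco-LSMT) / TPR proteins with weakly
  conserved SET domains and few associated domains

The catalog is a plain-text table bundled with the package: one record per
architecture type, holding the label (e.g. ``II-2A`` = class II, subclass 2,
subdivision A), the signature backbone, tolerated extra domains and a
16-character phyletic +/- profile over the species panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

#: families keyed by roman class code
FAMILY_BY_CLASS = {
    "I": "E(z)",
    "II": "Ash",
    "III": "Trx",
    "IV": "Su(var)",
    "V": "ClassV",
}
FAMILIES = ("E(z)", "Ash", "Trx", "Su(var)", "ClassV")

#: column order used by the phyletic presence strings of the catalog file
PRESENCE_COLUMN_ORDER = (
    "At", "Os", "Pa", "Sm", "Pp", "Mp", "Nm", "Kf",
    "Mr", "Mpu", "Ot", "Ol", "Cv", "Cr", "Vc", "Cp",
)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("setfam").joinpath("data", name)))


# ---------------------------------------------------------------------------
# species panel

@dataclass(frozen=True)
class SpeciesCode:
    """One member of the 16-species Archaeplastida panel."""

    code: str
    lineage_rank: int          # 1 = earliest-diverging lineage
    lineage: str               # e.g. "chlorophyta"
    name: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


class SpeciesPanel:
    """The ordered species panel read from a lineage-order config."""

    def __init__(self, species: Sequence[SpeciesCode]):
        if len(species) != 16:
            raise ValueError(f"expected 16 species, got {len(species)}")
        codes = [s.code for s in species]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate species codes in lineage config")
        ranks = sorted(s.lineage_rank for s in species)
        if ranks != list(range(1, 17)):
            raise ValueError("lineage_rank must be a permutation of 1..16")
        self._by_code = {s.code: s for s in species}
        #: species ordered by lineage_rank (evolutionary order)
        self.lineage_order = tuple(sorted(species, key=lambda s: s.lineage_rank))

    @classmethod
    def load(cls, path: str | Path | None = None) -> "SpeciesPanel":
        path = _data_path("lineage.tsv") if path is None else Path(path)
        species = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("code\t"):
                continue
            code, rank, lineage, name = line.split("\t")
            species.append(SpeciesCode(code, int(rank), lineage, name))
        return cls(species)

    def __getitem__(self, code: str) -> SpeciesCode:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"unknown species code {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __iter__(self):
        return iter(self.lineage_order)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(s.code for s in self.lineage_order)


# ---------------------------------------------------------------------------
# domain-name normalization

class SynonymMap:
    """Case-insensitive alias -> canonical domain-name map (total function)."""

    def __init__(self, aliases: dict[str, str], canonical: Iterable[str]):
        self._canon = {c.lower(): c for c in canonical}
        self._alias = {a.lower(): c for a, c in aliases.items()}

    @classmethod
    def load(cls, path: str | Path | None = None,
             canonical: Iterable[str] = ()) -> "SynonymMap":
        path = _data_path("synonyms.tsv") if path is None else Path(path)
        aliases = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("alias\t"):
                continue
            alias, canon = line.split("\t")
            aliases[alias] = canon
        return cls(aliases, canonical)

    def register_canonical(self, names: Iterable[str]) -> None:
        for n in names:
            self._canon.setdefault(n.lower(), n)

    def normalize(self, raw: str) -> str:
        """Canonical name for *raw*; unknown names pass through unchanged."""
        if not raw:
            raise ValueError("empty domain name")
        key = raw.strip().lower()
        if key in self._alias:
            return self._alias[key]
        if key in self._canon:
            return self._canon[key]
        return raw.strip()

    def is_known(self, name: str) -> bool:
        key = name.strip().lower()
        return key in self._alias or key in self._canon


# ---------------------------------------------------------------------------
# architectures and labels

@dataclass(frozen=True)
class DomainHit:
    """A named domain interval on a protein (1-based inclusive coordinates)."""

    protein_id: str
    domain: str
    start: int
    end: int
    score: float = 0.0
    interrupted: bool = False

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"bad hit coordinates {self.start}..{self.end} on {self.protein_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Architecture:
    """Ordered N->C list of canonical domain names."""

    domains: tuple[str, ...]

    def __init__(self, domains: Iterable[str]):
        object.__setattr__(self, "domains", tuple(domains))

    def __str__(self) -> str:
        return "-".join(self.domains)

    def __iter__(self):
        return iter(self.domains)

    def __len__(self):
        return len(self.domains)

    def __contains__(self, name: str) -> bool:
        return name in self.domains

    @classmethod
    def parse(cls, text: str, synonyms: SynonymMap | None = None) -> "Architecture":
        names = [t for t in text.strip().split("-") if t]
        if synonyms is not None:
            names = [synonyms.normalize(n) for n in names]
        return cls(names)


@dataclass(frozen=True)
class ClassLabel:
    """Hierarchical family assignment, e.g. II-2C or V-SETD."""

    family: str                 # E(z) | Ash | Trx | Su(var) | ClassV
    class_code: str             # I..V
    subclass: str = ""          # e.g. "II-2"
    subdivision: str = ""       # e.g. "II-2C"
    classv_kind: str = ""       # Orphan | SETD | TPR (class V only)
    family_orphan: bool = False  # the per-family Orphan subgroups (II/III/IV)

    def __post_init__(self):
        if self.subdivision and not self.subclass:
            raise ValueError("subdivision implies subclass")
        if (self.class_code == "V") != bool(self.classv_kind):
            raise ValueError("classv_kind must be set iff class_code is V")
        if self.family_orphan and self.class_code not in ("II", "III", "IV"):
            raise ValueError("family_orphan only applies to classes II-IV")

    def __str__(self) -> str:
        if self.class_code == "V":
            return f"V-{self.classv_kind}"
        if self.family_orphan:
            return f"{self.class_code}-Orphan"
        return self.subdivision or self.subclass or self.class_code

    @classmethod
    def parse(cls, text: str) -> "ClassLabel":
        """Parse label strings like ``II-2C``, ``I-3``, ``IV-Orphan``, ``V-SETD``."""
        text = text.strip()
        code, _, rest = text.partition("-")
        if code not in FAMILY_BY_CLASS:
            raise ValueError(f"bad class code in label {text!r}")
        family = FAMILY_BY_CLASS[code]
        if code == "V":
            if rest not in ("Orphan", "SETD", "TPR"):
                raise ValueError(f"bad class V kind in {text!r}")
            return cls(family, code, classv_kind=rest)
        if rest == "Orphan":
            return cls(family, code, family_orphan=True)
        if code == "I":
            # E(z) variants carry a bare numeric id (I-1 .. I-7)
            return cls(family, code, subclass=text)
        # e.g. II-2C -> subclass II-2, subdivision II-2C
        num = rest.rstrip("ABCDEFGH")
        sub = f"{code}-{num}"
        return cls(family, code, subclass=sub,
                   subdivision=text if rest != num else "")


# ---------------------------------------------------------------------------
# catalog

@dataclass
class CatalogEntry:
    """One architecture type of the classification catalog."""

    label: ClassLabel
    backbone: Architecture
    known_extras: frozenset[str] = frozenset()
    species_presence: dict[str, bool] = field(default_factory=dict)

    @property
    def matchable(self) -> bool:
        """Whether exact backbone matching applies to this entry.

        Bare-SET Orphan rows and the class V rule rows are matched by
        homology fallback / marker domains instead, because a lone SET
        domain carries no architectural signal.
        """
        if self.label.class_code == "V":
            return False
        return tuple(self.backbone) != ("SET",)

    def presence_string(self, order: Sequence[str] = PRESENCE_COLUMN_ORDER) -> str:
        return "".join("+" if self.species_presence[c] else "-" for c in order)


class CatalogError(ValueError):
    pass


class Catalog:
    """The loaded rule catalog plus derived lookup structures."""

    def __init__(self, entries: Sequence[CatalogEntry], panel: SpeciesPanel,
                 synonyms: SynonymMap):
        self.entries = list(entries)
        self.panel = panel
        self.synonyms = synonyms
        self._validate()
        #: signature vocabulary: domains appearing in matchable backbones
        self.signature_vocab = frozenset(
            d for e in self.entries if e.matchable for d in e.backbone)
        self._by_backbone: dict[tuple[str, ...], list[CatalogEntry]] = {}
        for e in self.entries:
            if e.matchable:
                self._by_backbone.setdefault(tuple(e.backbone), []).append(e)
        self._by_label = {str(e.label): e for e in self.entries}
        all_names = (set(self.signature_vocab)
                     | {d for e in self.entries for d in e.backbone}
                     | {d for e in self.entries for d in e.known_extras})
        self.synonyms.register_canonical(sorted(all_names))

    def _validate(self) -> None:
        seen: dict[tuple[str, tuple[str, ...]], CatalogEntry] = {}
        for e in self.entries:
            for code in e.species_presence:
                if code not in self.panel:
                    raise CatalogError(
                        f"entry {e.label}: unknown species code {code!r}")
            if len(e.species_presence) != 16:
                raise CatalogError(
                    f"entry {e.label}: presence vector has "
                    f"{len(e.species_presence)} species, expected 16")
            if e.label.class_code != "V" and "SET" not in e.backbone:
                raise CatalogError(f"entry {e.label}: backbone lacks SET")
            if not e.matchable:
                continue
            key = (e.label.family, tuple(e.backbone))
            if key in seen:
                raise CatalogError(
                    f"duplicate backbone {e.backbone} in entries "
                    f"{seen[key].label} and {e.label}")
            seen[key] = e

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def by_label(self, label: str) -> CatalogEntry:
        return self._by_label[label]

    def exact_matches(self, signature: Sequence[str]) -> list[CatalogEntry]:
        """Entries whose backbone equals *signature*, in catalog order.

        The same backbone may legitimately label more than one entry across
        families (the tables print PHD-PreSET-SET under both Trx and
        Su(var)); callers disambiguate by SET-domain homology.
        """
        return list(self._by_backbone.get(tuple(signature), ()))

    def family_entries(self, family: str) -> list[CatalogEntry]:
        return [e for e in self.entries if e.label.family == family]


def load_catalog(path: str | Path | None = None,
                 panel: SpeciesPanel | None = None,
                 synonyms: SynonymMap | None = None) -> Catalog:
    """Load the architecture rule catalog (the bundled one by default)."""
    path = _data_path("catalog.tsv") if path is None else Path(path)
    panel = panel or SpeciesPanel.load()
    synonyms = synonyms or SynonymMap.load()
    entries = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#") or line.startswith("label\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise CatalogError(f"{path}:{lineno}: expected 4 columns")
        label_s, backbone_s, extras_s, presence_s = parts
        label = ClassLabel.parse(label_s)
        backbone = Architecture.parse(backbone_s, synonyms)
        extras = frozenset() if extras_s.strip() in ("-", "") else frozenset(
            x.strip() for x in extras_s.split(","))
        if len(presence_s) != 16:
            raise CatalogError(
                f"{path}:{lineno}: presence string must have 16 characters")
        presence = {code: ch == "+"
                    for code, ch in zip(PRESENCE_COLUMN_ORDER, presence_s)}
        entries.append(CatalogEntry(label, backbone, extras, presence))
    if not entries:
        log.warning("catalog file %s contains no entries", path)
    return Catalog(entries, panel, synonyms)


def normalize_domain_name(raw: str, synonyms: SynonymMap | None = None) -> str:
    """Normalize a raw domain name through the bundled synonym map."""
    synonyms = synonyms or SynonymMap.load()
    return synonyms.normalize(raw)
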