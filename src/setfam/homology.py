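"""Pairwise global alignment of SET domains and homology-based fallbacks.

Proteins whose architecture is a bare (or interrupted) SET domain carry no
architectural signal, so their family is decided by aligning the SET-domain
substring against reference SET domains from Arabidopsis and rice: the best
identity reference with sufficient coverage wins, provided identity clears a
threshold.  The same machinery names proteins after their closest reference
homolog.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

_VALID_AA = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")


@dataclass(frozen=True)
class AlignParams:
    """Needleman-Wunsch parameters (affine gaps).

    Defaults (BLOSUM62, open 10, extend 0.5) are the classic protein-protein
    global-alignment settings.  A linear gap model is obtained by setting
    ``gap_extend == gap_open``.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity: float     # matches / aligned columns, terminal gaps excluded
    coverage: float     # aligned residues of the shorter sequence / its length

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity and coverage must lie in [0, 1]")


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global")
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(a: str, b: str, params: AlignParams | None = None) -> AlignmentResult:
    """Global (Needleman-Wunsch) alignment of two amino-acid sequences.

    Identity counts matches over aligned columns with terminal gap columns
    excluded; coverage is the fraction of the shorter sequence lying in
    columns where both sequences have a residue.  Deterministic given
    parameters (the highest-scoring alignment reported by the dynamic
    program is used).
    """
    params = params or AlignParams()
    a, b = a.upper().rstrip("*"), b.upper().rstrip("*")
    for name, s in (("a", a), ("b", b)):
        if not s:
            raise ValueError(f"sequence {name} is empty")
        if not _VALID_AA.match(s):
            raise ValueError(f"sequence {name} contains non-amino-acid characters")
    aln = _aligner(params).align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    # core = columns between the first and last position where both rows
    # carry residues (terminal overhangs excluded)
    both = [i for i in range(len(ra)) if ra[i] != "-" and rb[i] != "-"]
    if not both:
        return AlignmentResult(score=float(aln.score), identity=0.0, coverage=0.0)
    lo, hi = both[0], both[-1] + 1
    matches = sum(1 for i in range(lo, hi) if ra[i] == rb[i] and ra[i] != "-")
    identity = matches / (hi - lo)
    shorter = min(len(a), len(b))
    coverage = len(both) / shorter
    return AlignmentResult(score=float(aln.score), identity=identity,
                           coverage=min(coverage, 1.0))


# ---------------------------------------------------------------------------
# reference set

@dataclass(frozen=True)
class ReferenceEntry:
    name: str
    family: str
    species: str        # At or Os
    sequence: str


@dataclass
class ReferenceSet:
    """Reference SET-domain sequences (Arabidopsis / rice surrogates)."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate reference names")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def families(self) -> list[str]:
        seen = []
        for e in self.entries:
            if e.family not in seen:
                seen.append(e.family)
        return seen

    def for_family(self, family: str) -> list[ReferenceEntry]:
        return [e for e in self.entries if e.family == family]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        """Read references from FASTA with ``family=`` / ``species=`` header tags."""
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            tags = dict(t.split("=", 1) for t in rec.description.split()
                        if "=" in t)
            entries.append(ReferenceEntry(
                name=rec.id, family=tags.get("family", "?"),
                species=tags.get("species", "?"), sequence=str(rec.seq)))
        return cls(entries)

    @classmethod
    def load_default(cls) -> "ReferenceSet":
        path = resources.files("setfam").joinpath(
            "data", "reference_set_domains_synthetic.fasta")
        return cls.from_fasta(str(path))


@dataclass(frozen=True)
class FamilyAssignment:
    family: str | None
    nearest: str | None = None      # reference name
    identity: float = 0.0
    score: float = 0.0


def assign_family_by_homology(query_set_domain: str, refs: ReferenceSet,
                              threshold: float = 0.3,
                              min_coverage: float = 0.8,
                              params: AlignParams | None = None) -> FamilyAssignment:
    """Family of the best-identity reference, or None below threshold.

    Only alignments covering at least *min_coverage* of the shorter sequence
    are considered; ties on identity break by score, then by reference name.
    """
    if not len(refs):
        raise ValueError("reference set is empty")
    best: tuple[float, float, str, ReferenceEntry] | None = None
    for ref in refs:
        res = global_align(query_set_domain, ref.sequence, params)
        if res.coverage < min_coverage:
            continue
        if (best is None
                or (res.identity, res.score) > (best[0], best[1])
                or ((res.identity, res.score) == (best[0], best[1])
                    and ref.name < best[2])):
            best = (res.identity, res.score, ref.name, ref)
    if best is None:
        return FamilyAssignment(None)
    identity, score, name, ref = best
    if identity < threshold:
        return FamilyAssignment(None, nearest=name, identity=identity, score=score)
    return FamilyAssignment(ref.family, nearest=name, identity=identity, score=score)


# ---------------------------------------------------------------------------
# nomenclature

def _suffix(i: int) -> str:
    """0 -> a, 1 -> b, ... 25 -> z, 26 -> aa, 27 -> ab, ..."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


class NameRegistry:
    """Per-run name assignment with deterministic collision suffixes.

    Names follow the convention *capitalized homolog name* + *lowercase
    species code* (e.g. the Chlamydomonas protein nearest SDG8 becomes
    ``SDG8cr``).  When a base name recurs within a species the whole group
    is suffixed ``-a``, ``-b``, ... in assignment order, the first assignee
    being renamed retroactively.
    """

    def __init__(self):
        self._groups: dict[tuple[str, str], list[str]] = {}  # base -> protein ids

    def assign(self, protein_id: str, species: str, base: str) -> str:
        key = (species, base)
        group = self._groups.setdefault(key, [])
        group.append(protein_id)
        if len(group) == 1:
            return base
        return f"{base}-{_suffix(len(group) - 1)}"

    def names(self) -> dict[str, str]:
        """Final protein-id -> name map, with retroactive suffixes applied."""
        out = {}
        for (species, base), group in self._groups.items():
            if len(group) == 1:
                out[group[0]] = base
            else:
                for i, pid in enumerate(group):
                    out[pid] = f"{base}-{_suffix(i)}"
        return out


def make_base_name(nearest_ref_name: str, species: str) -> str:
    ref = nearest_ref_name[:1].upper() + nearest_ref_name[1:]
    return f"{ref}{species.lower()}"


def name_protein(protein_id: str, species: str, nearest_ref_name: str,
                 registry: NameRegistry) -> str:
    """Assign a name from the nearest reference homolog; see NameRegistry."""
    return registry.assign(protein_id, species,
                           make_base_name(nearest_ref_name, species))
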