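"""Distance-based phylogeny of SET domains: p-distances, NJ, bootstrap, purity.

The tree method is classic Saitou-Nei neighbor joining on p-distances
(1 - global-alignment identity).  NJ is exact on additive matrices, which
makes it fully testable; branch supports come from bootstrapping columns of
a reference-anchored pseudo-alignment, and a clade-purity statistic scores
how cleanly the four canonical families separate on the tree.
"""

from __future__ import annotations

import logging
from io import StringIO

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from .homology import AlignParams, global_align

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances

def pdistance_matrix(seqs: dict[str, str],
                     params: AlignParams | None = None) -> DistanceMatrix:
    """All-pairs p-distances, d(i,j) = 1 - identity of the global alignment."""
    ids = list(seqs)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(seqs[ids[i]], seqs[ids[j]], params)
            d[i, j] = d[j, i] = 1.0 - res.identity
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q-criterion ties break on the lexicographically smallest joined label
    pair, making the construction deterministic.  Negative branch-length
    estimates are clamped to zero (logged).  The returned tree is unrooted,
    represented with a trifurcating root.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = {(a, b): dm[a, b] for a in dm.ids for b in dm.ids}
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in dm.ids}
    active = list(dm.ids)
    clamped = 0
    join_count = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((i, j)))
                if best_q is None or q < best_q - 1e-12 or (
                        abs(q - best_q) <= 1e-12 and pair < best):
                    best_q, best = q, pair
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        u = f"__nj{join_count}"
        join_count += 1
        parent = TreeNode()
        ci, cj = nodes.pop(i), nodes.pop(j)
        ci.length, cj.length = _clamp(li), _clamp(lj)
        parent.extend([ci, cj])
        nodes[u] = parent
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[u, k] = d[k, u] = duk
        d[u, u] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    root = TreeNode()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = _clamp(lk)
        root.append(nodes[k])
    if clamped:
        log.warning("clamped %d negative NJ branch length(s) to 0", clamped)
    return root


def write_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def write_phylip(dm: DistanceMatrix) -> str:
    """PHYLIP square distance-matrix format."""
    lines = [f"{dm.shape[0]:5d}"]
    for i in dm.ids:
        row = " ".join(f"{dm[i, j]:.6f}" for j in dm.ids)
        lines.append(f"{i:<10s} {row}")
    return "\n".join(lines) + "\n"


def read_phylip(text: str) -> DistanceMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n = int(lines[0])
    ids, rows = [], []
    for ln in lines[1:n + 1]:
        parts = ln.split()
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(np.array(rows), ids)


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, purity

def _bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Internal-edge bipartitions, keyed by the canonical (child-side) leaf set.

    The side not containing the alphabetically first leaf is the canonical
    representative, making the keys invariant to rooting and leaf order.
    """
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    out = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            canon = side if anchor not in side else leaves - side
            out[canon] = node
    return out


def _pseudo_alignment(seqs: dict[str, str],
                      params: AlignParams | None = None) -> tuple[list[str], np.ndarray]:
    """Anchor every sequence to the longest one, column by column.

    No multiple alignment is built; instead each position of the longest
    sequence indexes one column, holding the residue each other sequence
    aligns to that position (gap where none does).
    """
    ids = list(seqs)
    anchor = max(ids, key=lambda i: (len(seqs[i]), i))
    cols = len(seqs[anchor])
    mat = np.full((len(ids), cols), "-", dtype="<U1")
    params = params or AlignParams()
    aligner = Align.PairwiseAligner(mode="global")
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    for row, sid in enumerate(ids):
        if sid == anchor:
            mat[row] = list(seqs[anchor])
            continue
        aln = aligner.align(seqs[anchor], seqs[sid])[0]
        ra, rb = str(aln[0]), str(aln[1])
        apos = 0
        for ca, cb in zip(ra, rb):
            if ca != "-":
                mat[row, apos] = cb
                apos += 1
    return ids, mat


def _distances_from_columns(ids: list[str], mat: np.ndarray) -> DistanceMatrix:
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            comp = (a != "-") & (b != "-")
            ncomp = int(comp.sum())
            d[i, j] = d[j, i] = (
                float((a[comp] != b[comp]).mean()) if ncomp else 1.0)
    return DistanceMatrix(d, ids)


def bootstrap_support(seqs: dict[str, str], n_reps: int = 100,
                      seed: int = 0,
                      params: AlignParams | None = None) -> TreeNode:
    """NJ tree with bootstrap supports on internal edges.

    Columns of the reference-anchored pseudo-alignment are resampled with
    replacement; support is the percentage of replicate trees containing
    each internal bipartition of the point-estimate tree.  Reproducible
    given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids, mat = _pseudo_alignment(seqs, params)
    tree = nj_tree(_distances_from_columns(ids, mat))
    target = _bipartitions(tree)
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    ncols = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep_tree = nj_tree(_distances_from_columns(ids, mat[:, cols]))
        rep_bps = set(_bipartitions(rep_tree))
        for bp in hits:
            if bp in rep_bps:
                hits[bp] += 1
    for bp, node in target.items():
        support = 100.0 * hits[bp] / n_reps
        node.support = support
        node.name = f"{support:.0f}"
    return tree


def class_purity(tree: TreeNode, labels: dict[str, str]) -> dict[str, float]:
    """Per-family clade purity plus the mean, each in [0, 1].

    For each family the score is the maximum, over all tree edges, of the
    Jaccard overlap between either side of the edge's bipartition and the
    family's leaf set; 1.0 means some edge splits the family off exactly.
    The degenerate whole-tree side counts, so a single-family input scores 1.
    """
    leaves = [t.name for t in tree.tips()]
    missing = [l for l in leaves if l not in labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing}")
    universe = frozenset(leaves)
    sides = {frozenset([l]) for l in leaves} | {universe}
    for node in tree.non_tips(include_self=False):
        sides.add(frozenset(t.name for t in node.tips()))
    sides |= {universe - s for s in sides}
    fams = sorted(set(labels[l] for l in leaves))
    out = {}
    for fam in fams:
        fset = frozenset(l for l in leaves if labels[l] == fam)
        out[fam] = max(len(s & fset) / len(s | fset) for s in sides if s)
    out["mean"] = sum(out[f] for f in fams) / len(fams)
    return out
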