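"""Global alignment of multi-domain architectures.

Two proteins' MDAs are aligned with the Needleman–Wunsch dynamic
programme, run over domain tokens instead of residues.  The substitution
function is hierarchical: an aligned pair of domains scores highest when
the two are the same FunFam, less when they are different FunFams of one
superfamily (graded by their proximity in that superfamily's FunFam tree),
less again for a bare superfamily match, and least for a shared fold.
Unrelated pairs score the mismatch penalty −1.0 and each gapped domain
costs −0.01; with these published penalties the optimum prefers two gaps
(−0.02) over a mismatch column, but the mismatch entry remains part of the
substitution function and is exposed directly.

Scores are reported raw and normalised by the larger self-alignment score
of the two inputs, so 1.0 means identical architectures and normalisation
penalises length differences.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy

from .model import MDA, AlignParams, DomainToken, FamilyHierarchy, GenomeSet, Level

__all__ = [
    "MatchLevel",
    "AlignmentColumn",
    "MDAAlignment",
    "substitution_score",
    "tree_similarity",
    "align",
    "rank_neighbours",
]


class MatchLevel(str, enum.Enum):
    """Relationship at which an aligned pair of domains matched."""

    FUNFAM = "funfam"
    TREE = "tree"
    SUPERFAMILY = "superfamily"
    FOLD = "fold"
    MISMATCH = "mismatch"


#: One-letter codes for alignment column strings (CIGAR-like).
_LEVEL_CODE = {
    MatchLevel.FUNFAM: "M",
    MatchLevel.TREE: "T",
    MatchLevel.SUPERFAMILY: "S",
    MatchLevel.FOLD: "F",
    MatchLevel.MISMATCH: "X",
}


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of an MDA alignment.

    kind is ``"match"`` (both tokens present), ``"gap_a"`` (token of B
    against a gap in A) or ``"gap_b"`` (token of A against a gap in B).
    """

    kind: str
    token_a: Optional[DomainToken]
    token_b: Optional[DomainToken]
    level: Optional[MatchLevel]
    score: float

    @property
    def code(self) -> str:
        if self.kind == "match":
            return _LEVEL_CODE[self.level]
        return "I" if self.kind == "gap_a" else "D"


@dataclass(frozen=True)
class MDAAlignment:
    """Optimal global alignment of two MDAs."""

    mda_a: MDA
    mda_b: MDA
    columns: tuple[AlignmentColumn, ...]
    raw_score: float
    normalized_score: float

    @property
    def cigar(self) -> str:
        """Column string: M/T/S/F/X for match levels, I/D for gaps."""
        return "".join(c.code for c in self.columns)


def _tree_depths(tree: dendropy.Tree) -> dict:
    """Per-node edge depth from the root, cached on the tree object."""
    cached = getattr(tree, "_domarch_depths", None)
    if cached is not None:
        return cached
    depths: dict = {}
    for node in tree.preorder_node_iter():
        depths[node] = 0 if node.parent_node is None else depths[node.parent_node] + 1
    leaf_map = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter() if leaf.taxon
    }
    tree._domarch_depths = depths
    tree._domarch_leaves = leaf_map
    return depths


def tree_similarity(ff_a: str, ff_b: str, tree: dendropy.Tree) -> float:
    """Similarity of two FunFams within one superfamily's FunFam tree.

    Defined as depth(LCA) / max(depth(a), depth(b)) with depth counted in
    edges from the root on the unweighted topology: 1 for identical leaves,
    0 when the lowest common ancestor is the root, strictly decreasing as
    the LCA moves rootward.  Branch lengths are ignored.
    """
    depths = _tree_depths(tree)
    leaves = tree._domarch_leaves
    try:
        node_a, node_b = leaves[ff_a], leaves[ff_b]
    except KeyError as exc:
        raise KeyError(f"FunFam {exc.args[0]!r} is not a leaf of the tree") from None
    if ff_a == ff_b:
        return 1.0
    # Walk the deeper node up until the two meet: the LCA.
    a, b = node_a, node_b
    while depths[a] > depths[b]:
        a = a.parent_node
    while depths[b] > depths[a]:
        b = b.parent_node
    while a is not b:
        a, b = a.parent_node, b.parent_node
    return depths[a] / max(depths[node_a], depths[node_b])


def substitution_score(
    a: DomainToken,
    b: DomainToken,
    hierarchy: FamilyHierarchy,
    p: AlignParams = AlignParams(),
) -> tuple[float, MatchLevel]:
    """Hierarchical substitution score for an aligned pair of domains.

    Falls through identical FunFam -> FunFam tree -> same superfamily ->
    same fold -> mismatch.  Unintegrated families (no hierarchy mapping)
    are their own singleton family at every level: they match only an
    identical family id, at full FunFam score.
    """
    if a.level == Level.UNINTEGRATED or b.level == Level.UNINTEGRATED:
        if a.family_id == b.family_id:
            return p.s_funfam, MatchLevel.FUNFAM
        return p.s_mismatch, MatchLevel.MISMATCH

    if a.family_id == b.family_id:
        if a.level == Level.FUNFAM:
            return p.s_funfam, MatchLevel.FUNFAM
        if a.level == Level.SUPERFAMILY:
            return p.s_superfamily, MatchLevel.SUPERFAMILY
        return p.s_fold, MatchLevel.FOLD

    sf_a = hierarchy.superfamily_of(a.family_id)
    sf_b = hierarchy.superfamily_of(b.family_id)
    if sf_a is not None and sf_a == sf_b:
        if a.level == Level.FUNFAM and b.level == Level.FUNFAM:
            tree = hierarchy.tree_for(sf_a)
            if tree is not None:
                try:
                    sim = tree_similarity(a.family_id, b.family_id, tree)
                except KeyError:
                    sim = None
                if sim is not None:
                    score = p.s_superfamily + (p.s_tree_max - p.s_superfamily) * sim
                    return score, MatchLevel.TREE
        return p.s_superfamily, MatchLevel.SUPERFAMILY

    fold_a = hierarchy.fold_of(a.family_id)
    fold_b = hierarchy.fold_of(b.family_id)
    if fold_a is not None and fold_a == fold_b:
        return p.s_fold, MatchLevel.FOLD

    return p.s_mismatch, MatchLevel.MISMATCH


def align(
    mda_a: MDA,
    mda_b: MDA,
    hierarchy: FamilyHierarchy,
    p: AlignParams = AlignParams(),
) -> MDAAlignment:
    """Needleman–Wunsch global alignment of two domain strings.

    Linear gap cost (``p.s_gap`` per gapped domain).  Traceback ties are
    broken match > gap-in-B > gap-in-A, making the reported alignment
    deterministic; the optimal score is unaffected by the tie-break.

    The normalised score is raw_score / max(self-score(A), self-score(B))
    where self-score(X) = |X| * s_funfam; two empty MDAs normalise to 1.
    """
    ta, tb = mda_a.tokens, mda_b.tokens
    n, m = len(ta), len(tb)
    gap = p.s_gap

    sub = [
        [substitution_score(ta[i], tb[j], hierarchy, p) for j in range(m)]
        for i in range(n)
    ]

    # F[i][j] = best score aligning ta[:i] with tb[:j].
    F = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        F[i][0] = i * gap
    for j in range(1, m + 1):
        F[0][j] = j * gap
    for i in range(1, n + 1):
        row, prev = F[i], F[i - 1]
        for j in range(1, m + 1):
            row[j] = max(prev[j - 1] + sub[i - 1][j - 1][0], prev[j] + gap, row[j - 1] + gap)

    # Traceback, preferring match, then gap in B (consume A), then gap in A.
    cols: list[AlignmentColumn] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s, level = sub[i - 1][j - 1]
            if F[i][j] == F[i - 1][j - 1] + s:
                cols.append(AlignmentColumn("match", ta[i - 1], tb[j - 1], level, s))
                i, j = i - 1, j - 1
                continue
        if i > 0 and F[i][j] == F[i - 1][j] + gap:
            cols.append(AlignmentColumn("gap_b", ta[i - 1], None, None, gap))
            i -= 1
            continue
        cols.append(AlignmentColumn("gap_a", None, tb[j - 1], None, gap))
        j -= 1
    cols.reverse()

    raw = F[n][m]
    denom = max(n, m) * p.s_funfam
    normalized = 1.0 if denom == 0 else raw / denom
    return MDAAlignment(
        mda_a=mda_a,
        mda_b=mda_b,
        columns=tuple(cols),
        raw_score=raw,
        normalized_score=normalized,
    )


def rank_neighbours(
    query: MDA,
    targets: GenomeSet,
    hierarchy: FamilyHierarchy,
    p: AlignParams = AlignParams(),
) -> list[tuple[str, float]]:
    """Rank a genome's proteins by normalised MDA similarity to a query.

    Descending by score; ties broken by protein id.
    """
    scored = [
        (pid, align(query, mda, hierarchy, p).normalized_score)
        for pid, mda in targets.proteins.items()
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored
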