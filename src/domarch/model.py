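"""Core data types for multi-domain architecture (MDA) analysis.

A protein's MDA is the ordered, non-overlapping string of domain-family
assignments along its sequence.  Domain families live in a three-level
hierarchy borrowed from CATH: functional families (FunFams) nest inside
homologous superfamilies, which nest inside folds (the T/topology level).
Families from resources without a structural hierarchy (Pfam-A/B) are
carried as *unintegrated* tokens: they match only themselves.

Coordinates are 1-based and inclusive throughout, the convention of HMMER
domain tables and of the assignment files this package mirrors.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

__all__ = [
    "Resource",
    "Level",
    "DomainHit",
    "DomainToken",
    "MDA",
    "FamilyHierarchy",
    "AlignParams",
    "GenomeSet",
    "token_from_hit",
    "select_longest_transcript",
]


class Resource(str, enum.Enum):
    """Annotation resource a domain hit came from."""

    CATH = "cath"
    FUNFAM = "funfam"
    PFAM_A = "pfam_a"
    PFAM_B = "pfam_b"
    SUPERFAMILY = "superfamily"


#: Resources whose family identifiers must resolve against the hierarchy.
HIERARCHICAL_RESOURCES = frozenset({Resource.CATH, Resource.FUNFAM})


class Level(str, enum.Enum):
    """Deepest hierarchy level at which a family identifier is defined."""

    FUNFAM = "funfam"
    SUPERFAMILY = "superfamily"
    FOLD = "fold"
    UNINTEGRATED = "unintegrated"


@dataclass(frozen=True)
class DomainHit:
    """A single family match on a protein, with residue range and E-value."""

    protein_id: str
    family_id: str
    resource: Resource
    start: int
    end: int
    evalue: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "resource", Resource(self.resource))
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid residue range [{self.start}, {self.end}] for "
                f"{self.protein_id}/{self.family_id}: need 1 <= start <= end"
            )
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue} for {self.protein_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainToken:
    """One domain in an MDA string: a family id, its level, and its range."""

    family_id: str
    level: Level
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "level", Level(self.level))
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid token range [{self.start}, {self.end}] for {self.family_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MDA:
    """Ordered, non-overlapping domain string of one protein."""

    protein_id: str
    tokens: tuple[DomainToken, ...]
    protein_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if self.protein_length <= 0:
            raise ValueError(f"non-positive protein length for {self.protein_id}")
        prev_end = 0
        for tok in self.tokens:
            if tok.start <= prev_end:
                raise ValueError(
                    f"tokens of {self.protein_id} are unsorted or overlapping "
                    f"at {tok.family_id}[{tok.start}-{tok.end}]"
                )
            if tok.end > self.protein_length:
                raise ValueError(
                    f"token {tok.family_id}[{tok.start}-{tok.end}] exceeds protein "
                    f"length {self.protein_length} of {self.protein_id}"
                )
            prev_end = tok.end

    def __len__(self) -> int:
        return len(self.tokens)

    def family_string(self) -> tuple[str, ...]:
        """Ordered family identifiers — the 'domain grammar' of the protein."""
        return tuple(t.family_id for t in self.tokens)


class FamilyHierarchy:
    """FunFam -> superfamily -> fold maps, plus optional per-superfamily trees.

    Parameters
    ----------
    funfam_to_superfamily
        Map from FunFam id (e.g. ``"3.40.50.300/FF/1234"``) to its
        superfamily id (``"3.40.50.300"``).
    superfamily_to_fold
        Map from superfamily id to fold id (``"3.40.50"``).
    trees
        Optional map from superfamily id to a rooted dendropy tree whose
        leaves are labelled with FunFam ids of that superfamily.
    """

    def __init__(
        self,
        funfam_to_superfamily: Mapping[str, str],
        superfamily_to_fold: Mapping[str, str],
        trees: Optional[Mapping[str, dendropy.Tree]] = None,
    ) -> None:
        self.funfam_to_superfamily = dict(funfam_to_superfamily)
        self.superfamily_to_fold = dict(superfamily_to_fold)
        self.trees = dict(trees or {})
        for ff, sf in self.funfam_to_superfamily.items():
            if sf not in self.superfamily_to_fold:
                raise ValueError(
                    f"FunFam {ff} maps to undeclared superfamily {sf}"
                )
        self._folds = frozenset(self.superfamily_to_fold.values())
        for sf, tree in self.trees.items():
            if sf not in self.superfamily_to_fold:
                raise ValueError(f"tree attached to undeclared superfamily {sf}")
            for leaf in tree.leaf_node_iter():
                label = leaf.taxon.label if leaf.taxon else None
                if self.funfam_to_superfamily.get(label) != sf:
                    raise ValueError(
                        f"tree of superfamily {sf} has leaf {label!r} that is "
                        f"not one of its FunFams"
                    )

    def level_of(self, family_id: str) -> Optional[Level]:
        """Deepest level at which ``family_id`` is defined, or None."""
        if family_id in self.funfam_to_superfamily:
            return Level.FUNFAM
        if family_id in self.superfamily_to_fold:
            return Level.SUPERFAMILY
        if family_id in self._folds:
            return Level.FOLD
        return None

    def superfamily_of(self, family_id: str) -> Optional[str]:
        if family_id in self.funfam_to_superfamily:
            return self.funfam_to_superfamily[family_id]
        if family_id in self.superfamily_to_fold:
            return family_id
        return None

    def fold_of(self, family_id: str) -> Optional[str]:
        sf = self.superfamily_of(family_id)
        if sf is not None:
            return self.superfamily_to_fold[sf]
        if family_id in self._folds:
            return family_id
        return None

    def tree_for(self, superfamily_id: str) -> Optional[dendropy.Tree]:
        return self.trees.get(superfamily_id)

    @property
    def funfams(self) -> tuple[str, ...]:
        return tuple(self.funfam_to_superfamily)

    @property
    def superfamilies(self) -> tuple[str, ...]:
        return tuple(self.superfamily_to_fold)

    @property
    def folds(self) -> frozenset[str]:
        return self._folds


@dataclass(frozen=True)
class AlignParams:
    """Scoring constants of the MDA aligner.

    Positive match scores must increase with specificity:
    ``s_fold <= s_superfamily <= s_tree_max <= s_funfam``.  Mismatch and
    per-gap penalties are negative; the defaults −1.0 and −0.01 are the
    published constants, the positive scores are configurable choices.
    """

    s_funfam: float = 1.0
    s_tree_max: float = 0.9
    s_superfamily: float = 0.6
    s_fold: float = 0.3
    s_mismatch: float = -1.0
    s_gap: float = -0.01

    def __post_init__(self) -> None:
        if not (0 < self.s_fold <= self.s_superfamily <= self.s_tree_max <= self.s_funfam):
            raise ValueError(
                "match scores must satisfy 0 < s_fold <= s_superfamily "
                "<= s_tree_max <= s_funfam (increasing specificity); got "
                f"fold={self.s_fold}, superfamily={self.s_superfamily}, "
                f"tree_max={self.s_tree_max}, funfam={self.s_funfam}"
            )
        if self.s_mismatch >= 0:
            raise ValueError(f"mismatch score must be negative, got {self.s_mismatch}")
        if self.s_gap >= 0:
            raise ValueError(f"gap penalty must be negative, got {self.s_gap}")


@dataclass
class GenomeSet:
    """A named collection of proteins with resolved MDAs."""

    name: str
    proteins: dict[str, MDA] = field(default_factory=dict)
    gene_map: Optional[dict[str, set[str]]] = None
    taxon_lineage: Optional[list[tuple[str, str]]] = None  # (rank, name), root first

    def __post_init__(self) -> None:
        for pid, mda in self.proteins.items():
            if mda.protein_id != pid:
                raise ValueError(
                    f"genome {self.name}: key {pid!r} does not match MDA "
                    f"protein_id {mda.protein_id!r}"
                )

    def __len__(self) -> int:
        return len(self.proteins)

    def lineage_at(self, rank: str) -> Optional[str]:
        if self.taxon_lineage is None:
            return None
        for r, name in self.taxon_lineage:
            if r == rank:
                return name
        return None


def token_from_hit(hit: DomainHit, hierarchy: FamilyHierarchy) -> DomainToken:
    """Convert a domain hit into an MDA token, assigning its hierarchy level.

    The level is the deepest one at which the hit's family id is defined.
    Hits from non-hierarchical resources (Pfam-A/B) become *unintegrated*
    tokens.  A cath/funfam hit whose id is unknown to the hierarchy is an
    error rather than silently unintegrated.
    """
    level = hierarchy.level_of(hit.family_id)
    if level is None:
        if hit.resource in HIERARCHICAL_RESOURCES:
            raise KeyError(
                f"family {hit.family_id!r} ({hit.resource.value} hit on "
                f"{hit.protein_id}) is not resolvable in the hierarchy"
            )
        level = Level.UNINTEGRATED
    return DomainToken(
        family_id=hit.family_id, level=level, start=hit.start, end=hit.end
    )


def select_longest_transcript(genome: GenomeSet) -> GenomeSet:
    """Collapse each gene to its single longest transcript.

    Per gene, the protein with maximal ``protein_length`` is retained;
    length ties are broken by lexicographically smallest protein id so the
    result is deterministic.  Proteins absent from the gene map are kept
    unchanged (treated as single-transcript genes).
    """
    if genome.gene_map is None:
        raise ValueError(f"genome {genome.name} has no gene map")
    mapped: set[str] = set()
    kept: dict[str, MDA] = {}
    for gene_id in sorted(genome.gene_map):
        transcripts = genome.gene_map[gene_id]
        present = sorted(t for t in transcripts if t in genome.proteins)
        mapped.update(present)
        if not present:
            warnings.warn(
                f"gene {gene_id} of genome {genome.name} has no transcripts "
                f"with an MDA; skipped",
                stacklevel=2,
            )
            continue
        best = max(present, key=lambda pid: (genome.proteins[pid].protein_length, ))
        # max() keeps the first of equals; `present` is sorted, so ties go to
        # the lexicographically smallest id.
        kept[best] = genome.proteins[best]
    for pid, mda in genome.proteins.items():
        if pid not in mapped:
            kept[pid] = mda
    return GenomeSet(
        name=genome.name,
        proteins=kept,
        gene_map={g: set(t) for g, t in genome.gene_map.items()},
        taxon_lineage=list(genome.taxon_lineage) if genome.taxon_lineage else None,
    )
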