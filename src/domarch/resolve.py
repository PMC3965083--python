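"""Overlap resolution: pick an optimal non-overlapping subset of domain hits.

Domain assignment integrates several resources (CATH/FunFam HMMs, Pfam,
SUPERFAMILY), which routinely produce overlapping hits on the same
stretch of sequence.  The composite MDA keeps a single, non-overlapping
combination of acceptably-scoring hits chosen to maximise the number of
residues covered.  Maximum coverage over non-overlapping intervals is the
weighted-interval-scheduling problem; the chain dynamic programme below
solves it exactly, with deterministic tie-breaking at equal coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .model import MDA, DomainHit, FamilyHierarchy, Resource, token_from_hit

__all__ = ["ResolutionConfig", "filter_acceptable", "resolve", "compose_mda"]

DEFAULT_PRIORITY = (
    Resource.CATH,
    Resource.FUNFAM,
    Resource.SUPERFAMILY,
    Resource.PFAM_A,
    Resource.PFAM_B,
)


@dataclass(frozen=True)
class ResolutionConfig:
    """Knobs of the overlap resolver.

    max_evalue
        Acceptability threshold; hits with larger E-values are discarded
        before optimisation.
    resource_priority
        Order used to break coverage ties and to decide which of two
        tolerably-overlapping hits gets trimmed.
    overlap_tolerance
        Residues two selected hits may share; the shared stretch is trimmed
        from the lower-priority hit.  Default 0: fully non-overlapping.
    """

    max_evalue: float = 1e-3
    resource_priority: tuple[Resource, ...] = DEFAULT_PRIORITY
    overlap_tolerance: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "resource_priority", tuple(Resource(r) for r in self.resource_priority)
        )
        if self.overlap_tolerance < 0:
            raise ValueError("overlap_tolerance must be >= 0")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")

    def priority_index(self, resource: Resource) -> int:
        try:
            return self.resource_priority.index(resource)
        except ValueError:
            return len(self.resource_priority)


def filter_acceptable(
    hits: Sequence[DomainHit], cfg: ResolutionConfig = ResolutionConfig()
) -> list[DomainHit]:
    """Keep hits with E-value <= cfg.max_evalue, preserving input order."""
    return [h for h in hits if h.evalue <= cfg.max_evalue]


@dataclass
class _Chain:
    hits: list[DomainHit] = field(default_factory=list)
    coverage: int = 0
    evalue_rank_sum: int = 0
    priority_sum: int = 0

    def key(self) -> tuple:
        # Minimised lexicographically: maximal coverage first, then fewer
        # domains, then more significant hits (smaller summed E-value rank),
        # then higher-priority resources, then lexicographic family ids.
        return (
            -self.coverage,
            len(self.hits),
            self.evalue_rank_sum,
            self.priority_sum,
            tuple(sorted(h.family_id for h in self.hits)),
        )


def resolve(
    hits: Sequence[DomainHit], cfg: ResolutionConfig = ResolutionConfig()
) -> list[DomainHit]:
    """Select the maximum-coverage non-overlapping subset of acceptable hits.

    All hits must be on the same protein.  Two selected hits may share up to
    ``cfg.overlap_tolerance`` residues; any shared residues are trimmed from
    the lower-priority hit so the returned list is strictly non-overlapping.
    Ties at equal coverage are broken by (1) fewer domains, (2) smaller
    summed E-value rank, (3) resource priority, (4) lexicographic family id,
    which also makes the result independent of input order.

    Returns the selected hits sorted by start position.
    """
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(
            f"resolve() expects hits of a single protein, got {sorted(protein_ids)}"
        )
    acc = filter_acceptable(hits, cfg)
    if not acc:
        return []

    # Rank by E-value significance (0 = most significant) for tie-breaking.
    by_evalue = sorted(
        acc, key=lambda h: (h.evalue, h.start, h.end, h.family_id, h.resource.value)
    )
    ev_rank = {id(h): i for i, h in enumerate(by_evalue)}

    # Canonical order: makes the DP (and hence tie-breaking) independent of
    # the caller's ordering.
    order = sorted(
        acc,
        key=lambda h: (
            h.end,
            h.start,
            cfg.priority_index(h.resource),
            h.family_id,
            h.evalue,
        ),
    )

    tol = cfg.overlap_tolerance
    n = len(order)
    # best[i] = best chain ending with hit i (hits sorted by end).
    best: list[_Chain] = []
    for i, hit in enumerate(order):
        base = _Chain(
            hits=[hit],
            coverage=hit.length,
            evalue_rank_sum=ev_rank[id(hit)],
            priority_sum=cfg.priority_index(hit.resource),
        )
        cand = base
        for j in range(i):
            prev = order[j]
            overlap = prev.end - hit.start + 1
            if overlap > tol:
                continue
            trimmed = max(overlap, 0)  # residues double-covered, trimmed later
            ext = _Chain(
                hits=best[j].hits + [hit],
                coverage=best[j].coverage + hit.length - trimmed,
                evalue_rank_sum=best[j].evalue_rank_sum + ev_rank[id(hit)],
                priority_sum=best[j].priority_sum + cfg.priority_index(hit.resource),
            )
            if ext.key() < cand.key():
                cand = ext
        best.append(cand)

    winner = min(best, key=_Chain.key)
    selected = sorted(winner.hits, key=lambda h: (h.start, h.end))
    return _trim_overlaps(selected, cfg) if tol > 0 else selected


def _trim_overlaps(selected: list[DomainHit], cfg: ResolutionConfig) -> list[DomainHit]:
    """Trim tolerated overlaps from the lower-priority member of each pair."""
    out = list(selected)
    for i in range(1, len(out)):
        prev, cur = out[i - 1], out[i]
        overlap = prev.end - cur.start + 1
        if overlap <= 0:
            continue
        pp = (cfg.priority_index(prev.resource), prev.evalue)
        cp = (cfg.priority_index(cur.resource), cur.evalue)
        if cp >= pp:  # current is lower priority (or tie): trim its start
            out[i] = replace(cur, start=prev.end + 1)
        else:
            out[i - 1] = replace(prev, end=cur.start - 1)
    return [h for h in out if h.start <= h.end]


def compose_mda(
    resolved: Sequence[DomainHit],
    hierarchy: FamilyHierarchy,
    protein_length: int,
    protein_id: Optional[str] = None,
) -> MDA:
    """Assemble the composite MDA from a non-overlapping set of hits."""
    if protein_id is None:
        ids = {h.protein_id for h in resolved}
        if len(ids) > 1:
            raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
        protein_id = ids.pop() if ids else ""
    ordered = sorted(resolved, key=lambda h: (h.start, h.end))
    tokens = [token_from_hit(h, hierarchy) for h in ordered]
    for tok in tokens:
        if tok.end > protein_length:
            raise ValueError(
                f"token {tok.family_id}[{tok.start}-{tok.end}] outside protein "
                f"{protein_id} of length {protein_length}"
            )
    return MDA(protein_id=protein_id, tokens=tuple(tokens), protein_length=protein_length)
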