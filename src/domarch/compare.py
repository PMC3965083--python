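"""Genome-scale analyses built on MDA alignment.

All-vs-all similarity matrices, distinctive architectures (proteins whose
best alignment against comparison genomes is poor, candidate carriers of
lineage-specific function), unique domain compositions, Fisher's-exact
domain-family enrichment with Benjamini–Hochberg correction, MDA-length
distributions and taxonomic grouping.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import align
from .model import MDA, AlignParams, FamilyHierarchy, GenomeSet, select_longest_transcript

__all__ = [
    "EnrichmentResult",
    "DistinctivenessRecord",
    "fisher_test",
    "all_vs_all",
    "distinctive_mdas",
    "unique_compositions",
    "fisher_enrichment",
    "mda_length_distribution",
    "group_by_taxon",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher's-exact enrichment of one domain family in a foreground genome."""

    family_id: str
    count_fg: int
    total_fg: int
    count_bg: int
    total_bg: int
    odds_ratio: float
    p_value: float
    q_value: float


@dataclass(frozen=True)
class DistinctivenessRecord:
    """Best cross-genome similarity of one protein's architecture."""

    protein_id: str
    best_match_protein_id: Optional[str]
    max_normalized_score: float
    distinctive: bool


def all_vs_all(
    genome_a: GenomeSet,
    genome_b: GenomeSet,
    hierarchy: FamilyHierarchy,
    p: AlignParams = AlignParams(),
) -> pd.DataFrame:
    """Matrix of normalised MDA alignment scores between two genomes.

    Proteins with identical domain strings are deduplicated before
    alignment and the matrix re-expanded afterwards, so the cost scales
    with the number of distinct architectures, not proteins.
    """
    ids_a, ids_b = list(genome_a.proteins), list(genome_b.proteins)
    mat = np.empty((len(ids_a), len(ids_b)))
    if mat.size == 0:
        return pd.DataFrame(mat, index=ids_a, columns=ids_b)

    def _groups(genome: GenomeSet) -> dict[tuple[str, ...], list[str]]:
        groups: dict[tuple[str, ...], list[str]] = {}
        for pid, mda in genome.proteins.items():
            groups.setdefault(mda.family_string(), []).append(pid)
        return groups

    ga, gb = _groups(genome_a), _groups(genome_b)
    pos_a = {pid: i for i, pid in enumerate(ids_a)}
    pos_b = {pid: j for j, pid in enumerate(ids_b)}
    for key_a, members_a in ga.items():
        rep_a = genome_a.proteins[members_a[0]]
        for key_b, members_b in gb.items():
            rep_b = genome_b.proteins[members_b[0]]
            score = align(rep_a, rep_b, hierarchy, p).normalized_score
            for pa in members_a:
                for pb in members_b:
                    mat[pos_a[pa], pos_b[pb]] = score
    return pd.DataFrame(mat, index=ids_a, columns=ids_b)


def distinctive_mdas(
    genome: GenomeSet,
    comparison: Sequence[GenomeSet],
    hierarchy: FamilyHierarchy,
    p: AlignParams = AlignParams(),
    threshold: float = 0.5,
) -> list[DistinctivenessRecord]:
    """Flag proteins whose architecture has no good match in other genomes.

    A protein is distinctive when its maximum normalised alignment score
    against every protein of every comparison genome falls below the
    threshold.  With an empty comparison set the maximum is −inf and all
    proteins are distinctive.  Records are sorted ascending by the maximum
    score (most distinctive first), ties by protein id.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    matrices = [
        all_vs_all(genome, other, hierarchy, p)
        for other in comparison
        if other.proteins
    ]
    records = []
    for pid in sorted(genome.proteins):
        best_score = -math.inf
        best_id: Optional[str] = None
        for scores in matrices:
            row = scores.loc[pid]
            top = row.idxmax()
            if row[top] > best_score:
                best_score, best_id = float(row[top]), str(top)
        records.append(
            DistinctivenessRecord(
                protein_id=pid,
                best_match_protein_id=best_id,
                max_normalized_score=best_score,
                distinctive=best_score < threshold,
            )
        )
    records.sort(key=lambda r: (r.max_normalized_score, r.protein_id))
    return records


def _composition(mda: MDA) -> frozenset[tuple[str, int]]:
    return frozenset(Counter(mda.family_string()).items())


def unique_compositions(genome_a: GenomeSet, genome_b: GenomeSet) -> set[str]:
    """Proteins of A whose domain composition occurs nowhere in B.

    A composition is the order-insensitive multiset of family ids, so a
    permuted architecture present in B does not count as unique.
    """
    seen_b = {_composition(mda) for mda in genome_b.proteins.values()}
    return {
        pid for pid, mda in genome_a.proteins.items() if _composition(mda) not in seen_b
    }


def fisher_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (sample odds ratio, p-value); the route used by
    :func:`fisher_enrichment` for every family table.
    """
    odds, pval = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(pval)


def fisher_enrichment(
    fg: GenomeSet,
    bg: Sequence[GenomeSet],
    mode: str = "presence",
) -> list[EnrichmentResult]:
    """Domain-family enrichment of a foreground genome against backgrounds.

    For each family a 2x2 table is tested with the two-sided Fisher's exact
    test; q-values are Benjamini–Hochberg over all tested families.  In
    ``"presence"`` mode (default) the unit is proteins containing the
    family at least once — robust to tandem repeats; ``"counts"`` mode
    tests domain counts against total domain counts instead.  Backgrounds
    are pooled.  Results are sorted by q-value, then descending odds ratio,
    then family id.
    """
    if not fg.proteins:
        raise ValueError(f"foreground genome {fg.name} is empty")
    if mode not in ("presence", "counts"):
        raise ValueError(f"mode must be 'presence' or 'counts', got {mode!r}")

    def tally(genomes: Iterable[GenomeSet]) -> tuple[Counter, int]:
        counts: Counter = Counter()
        total = 0
        for g in genomes:
            for mda in g.proteins.values():
                fams = mda.family_string()
                if mode == "presence":
                    counts.update(set(fams))
                    total += 1
                else:
                    counts.update(fams)
                    total += len(fams)
        return counts, total

    fg_counts, total_fg = tally([fg])
    bg_counts, total_bg = tally(bg)
    families = sorted(set(fg_counts) | set(bg_counts))
    if not families:
        return []

    rows = []
    for fam in families:
        a = fg_counts.get(fam, 0)
        c = bg_counts.get(fam, 0)
        odds, pval = fisher_test(a, total_fg - a, c, total_bg - c)
        rows.append((fam, a, c, odds, pval))

    _, qvals, _, _ = multipletests([r[4] for r in rows], method="fdr_bh")
    results = [
        EnrichmentResult(
            family_id=fam,
            count_fg=a,
            total_fg=total_fg,
            count_bg=c,
            total_bg=total_bg,
            odds_ratio=odds,
            p_value=pval,
            q_value=float(q),
        )
        for (fam, a, c, odds, pval), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, -r.odds_ratio, r.family_id))
    return results


def mda_length_distribution(
    genomes: Union[GenomeSet, Sequence[GenomeSet]],
) -> Counter:
    """Histogram of domains per protein (MDA length).

    When a genome carries a gene map, the longest transcript per gene is
    selected first so multi-transcript genes are counted once.
    """
    if isinstance(genomes, GenomeSet):
        genomes = [genomes]
    hist: Counter = Counter()
    for g in genomes:
        if g.gene_map is not None:
            g = select_longest_transcript(g)
        hist.update(len(mda) for mda in g.proteins.values())
    return hist


def group_by_taxon(
    genomes: Sequence[GenomeSet], level: str
) -> dict[str, list[GenomeSet]]:
    """Partition genomes by their lineage entry at a named taxonomic rank.

    Genomes without a lineage, or whose lineage lacks the rank, fall into
    the ``"unclassified"`` group.  The partition is exhaustive and
    disjoint.
    """
    groups: dict[str, list[GenomeSet]] = {}
    for g in genomes:
        name = g.lineage_at(level)
        groups.setdefault(name if name is not None else "unclassified", []).append(g)
    return groups
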