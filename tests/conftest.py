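"""Shared fixtures: a small hand-built hierarchy and independent oracles.

The oracles are deliberately naive (exhaustive enumeration) and share no
code with the implementation paths they check.
"""

from __future__ import annotations

from math import comb, inf

import dendropy
import pytest

from domarch import (
    MDA,
    DomainHit,
    DomainToken,
    FamilyHierarchy,
    Level,
    Resource,
)

# --------------------------------------------------------------------------
# Hand-built hierarchy: 2 folds, 3 superfamilies, 8 FunFams.
# Superfamily 1.10.8.10 carries a balanced depth-2 FunFam tree; 1.10.8.20
# has FunFams but no tree; 2.60.40.10 has two FunFams and no tree.


@pytest.fixture(scope="session")
def hierarchy() -> FamilyHierarchy:
    ff_to_sf = {
        "1.10.8.10/FF/1": "1.10.8.10",
        "1.10.8.10/FF/2": "1.10.8.10",
        "1.10.8.10/FF/3": "1.10.8.10",
        "1.10.8.10/FF/4": "1.10.8.10",
        "1.10.8.20/FF/1": "1.10.8.20",
        "1.10.8.20/FF/2": "1.10.8.20",
        "2.60.40.10/FF/1": "2.60.40.10",
        "2.60.40.10/FF/2": "2.60.40.10",
    }
    sf_to_fold = {
        "1.10.8.10": "1.10.8",
        "1.10.8.20": "1.10.8",
        "2.60.40.10": "2.60.40",
    }
    tree = dendropy.Tree.get(
        data="(('1.10.8.10/FF/1','1.10.8.10/FF/2'),"
        "('1.10.8.10/FF/3','1.10.8.10/FF/4'));",
        schema="newick",
    )
    return FamilyHierarchy(ff_to_sf, sf_to_fold, {"1.10.8.10": tree})


def make_token(family_id: str, hierarchy: FamilyHierarchy, start: int, end: int) -> DomainToken:
    level = hierarchy.level_of(family_id) or Level.UNINTEGRATED
    return DomainToken(family_id=family_id, level=level, start=start, end=end)


def make_mda(protein_id: str, families, hierarchy: FamilyHierarchy) -> MDA:
    """MDA from a family-id list, tokens laid out 100 residues apart."""
    tokens = []
    pos = 1
    for fam in families:
        tokens.append(make_token(fam, hierarchy, pos, pos + 79))
        pos += 100
    return MDA(protein_id=protein_id, tokens=tuple(tokens),
               protein_length=max(pos, 2))


def make_hit(pid="p1", fam="1.10.8.10/FF/1", resource=Resource.FUNFAM,
             start=1, end=100, evalue=1e-10) -> DomainHit:
    return DomainHit(protein_id=pid, family_id=fam, resource=resource,
                     start=start, end=end, evalue=evalue)


# --------------------------------------------------------------------------
# Oracles


def brute_force_align_score(sub, n, m, gap):
    """Maximum score over ALL global alignments, by explicit enumeration.

    ``sub[i][j]`` is the substitution score for pairing token i of A with
    token j of B.  Every alignment is a monotone path of match /
    gap-in-B / gap-in-A moves; all are enumerated recursively.
    """
    best = -inf

    def walk(i, j, score):
        nonlocal best
        if i == n and j == m:
            best = max(best, score)
            return
        if i < n and j < m:
            walk(i + 1, j + 1, score + sub[i][j])
        if i < n:
            walk(i + 1, j, score + gap)
        if j < m:
            walk(i, j + 1, score + gap)

    walk(0, 0, 0.0)
    return best


def brute_force_max_coverage(hits):
    """Max residue coverage over all 2^n pairwise non-overlapping subsets."""
    n = len(hits)
    best = 0
    for mask in range(1 << n):
        chosen = [hits[i] for i in range(n) if mask >> i & 1]
        ok = all(
            a.end < b.start or b.end < a.start
            for k, a in enumerate(chosen)
            for b in chosen[k + 1:]
        )
        if ok:
            best = max(best, sum(h.length for h in chosen))
    return best


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by direct enumeration of tables with fixed margins.

    Integer hypergeometric weights keep the tie comparison exact; the
    p-value is the total weight of tables no more probable than the
    observed one, over the total weight.
    """
    N = a + b + c + d
    if N == 0:
        return 1.0
    K, n1 = a + c, a + b
    weights = {
        k: comb(K, k) * comb(N - K, n1 - k)
        for k in range(max(0, n1 - (N - K)), min(K, n1) + 1)
    }
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / comb(N, n1)
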