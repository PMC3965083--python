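"""Synthetic fixtures with planted ground truth.

Generates a balanced three-level family hierarchy with random FunFam
trees, genomes of proteins whose MDAs are drawn from a configurable
length distribution, and noisy hit tables in which decoy hits overlap the
planted (true) hits with strictly worse E-values.  Because every decoy is
nested strictly inside a true hit and shorter than it, the
maximum-coverage resolver provably recovers the planted architecture when
the true/decoy E-value ranges are disjoint — the basis of the end-to-end
recovery tests.

All generators are driven by a single integer seed and are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .model import (
    MDA,
    DomainHit,
    DomainToken,
    FamilyHierarchy,
    GenomeSet,
    Level,
    Resource,
    token_from_hit,
)

__all__ = ["SimConfig", "simulate_hierarchy", "simulate_genome", "mutate_mda"]

#: Default MDA length distribution: mostly 1–3 domains, a tail to 5,
#: mimicking the short-MDA dominance of real proteomes.
DEFAULT_LENGTH_DIST = {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.10, 5: 0.05}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic generator.

    E-value ranges are (low, high) bounds for log-uniform sampling; the
    defaults keep true and decoy ranges disjoint (true hits are always
    more significant) and both below the usual 1e-3 acceptability
    threshold, so decoys survive filtering and must be rejected by the
    coverage optimisation itself.
    """

    n_folds: int = 3
    n_superfamilies_per_fold: int = 2
    n_funfams_per_superfamily: int = 4
    n_proteins: int = 50
    mda_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    hit_noise: float = 0.2
    true_evalue_range: tuple[float, float] = (1e-50, 1e-10)
    decoy_evalue_range: tuple[float, float] = (1e-8, 1e-4)
    domain_length_range: tuple[int, int] = (40, 300)
    max_linker: int = 50
    p_superfamily_hit: float = 0.0
    p_unintegrated_hit: float = 0.0
    n_pfam_families: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_folds", "n_superfamilies_per_fold",
                     "n_funfams_per_superfamily", "n_proteins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        probs = np.array(list(self.mda_length_distribution.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("mda_length_distribution probabilities must sum to 1")
        if any(k < 1 for k in self.mda_length_distribution):
            raise ValueError("MDA lengths must be >= 1")
        if not 0.0 <= self.hit_noise <= 1.0:
            raise ValueError("hit_noise must be in [0, 1]")
        if not 0.0 <= self.p_superfamily_hit + self.p_unintegrated_hit <= 1.0:
            raise ValueError("resource-mix probabilities must sum to <= 1")


def _balanced_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random balanced binary tree over shuffled labels, as Newick."""
    labels = list(labels)
    rng.shuffle(labels)

    def build(sub: list[str]) -> str:
        if len(sub) == 1:
            return sub[0]
        mid = len(sub) // 2
        return f"({build(sub[:mid])},{build(sub[mid:])})"

    return build(labels) + ";"


def simulate_hierarchy(cfg: SimConfig) -> tuple[FamilyHierarchy, dict[str, dendropy.Tree]]:
    """Balanced random hierarchy: folds x superfamilies x FunFams, with trees.

    Family ids follow the CATH dotted-code grammar: fold ``1.10.F``,
    superfamily ``1.10.F.S0``, FunFam ``1.10.F.S0/FF/K``.  Each
    superfamily gets a random balanced FunFam tree; every FunFam appears
    in exactly one tree.
    """
    rng = np.random.default_rng(cfg.seed)
    ff_to_sf: dict[str, str] = {}
    sf_to_fold: dict[str, str] = {}
    trees: dict[str, dendropy.Tree] = {}
    for f in range(cfg.n_folds):
        fold = f"1.10.{f + 1}"
        for s in range(cfg.n_superfamilies_per_fold):
            sf = f"{fold}.{(s + 1) * 10}"
            sf_to_fold[sf] = fold
            funfams = [
                f"{sf}/FF/{k + 1}" for k in range(cfg.n_funfams_per_superfamily)
            ]
            for ff in funfams:
                ff_to_sf[ff] = sf
            newick = _balanced_newick(funfams, rng)
            trees[sf] = dendropy.Tree.get(data=newick, schema="newick")
    return FamilyHierarchy(ff_to_sf, sf_to_fold, trees), trees


def simulate_genome(
    cfg: SimConfig,
    hierarchy: FamilyHierarchy,
    name: str = "sim",
    seed: Optional[int] = None,
) -> tuple[GenomeSet, list[DomainHit]]:
    """Genome with planted MDAs plus a noisy hit table.

    Each protein draws an MDA length from the configured distribution and
    lays non-overlapping true hits separated by random linkers.  True hits
    are FunFam assignments by default; ``p_superfamily_hit`` and
    ``p_unintegrated_hit`` optionally downgrade a fraction to
    bare-superfamily (cath) or unintegrated (pfam_a) assignments — note a
    bare-superfamily domain self-aligns at the superfamily score, so only
    pure-FunFam genomes reach normalised self-similarity 1.  Decoy
    hits — ``hit_noise`` of all hits in expectation — are strictly nested
    inside a random true hit, carry a different family and a worse
    E-value.  The returned genome holds the planted (ground-truth) MDAs;
    the hit table holds true and decoy hits shuffled together.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    funfams = list(hierarchy.funfams)
    superfams = list(hierarchy.superfamilies)
    pfams = [f"PF{i + 1:05d}" for i in range(cfg.n_pfam_families)]
    lengths = np.array(sorted(cfg.mda_length_distribution), dtype=int)
    probs = np.array([cfg.mda_length_distribution[int(k)] for k in lengths])

    def log_uniform(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    proteins: dict[str, MDA] = {}
    hits: list[DomainHit] = []
    width = len(str(cfg.n_proteins))
    for i in range(cfg.n_proteins):
        pid = f"{name}_p{i + 1:0{width}d}"
        k = int(rng.choice(lengths, p=probs))
        true_hits: list[DomainHit] = []
        pos = 0
        for _ in range(k):
            pos += int(rng.integers(0, cfg.max_linker + 1)) + 1
            dlen = int(rng.integers(*cfg.domain_length_range, endpoint=True))
            start, end = pos, pos + dlen - 1
            pos = end
            u = rng.uniform()
            if u < cfg.p_superfamily_hit:
                fam, resource = str(rng.choice(superfams)), Resource.CATH
            elif u < cfg.p_superfamily_hit + cfg.p_unintegrated_hit:
                fam, resource = str(rng.choice(pfams)), Resource.PFAM_A
            else:
                fam, resource = str(rng.choice(funfams)), Resource.FUNFAM
            true_hits.append(
                DomainHit(
                    protein_id=pid,
                    family_id=fam,
                    resource=resource,
                    start=start,
                    end=end,
                    evalue=log_uniform(*cfg.true_evalue_range),
                )
            )
        protein_length = pos + int(rng.integers(0, cfg.max_linker + 1))
        tokens = tuple(token_from_hit(h, hierarchy) for h in true_hits)
        proteins[pid] = MDA(protein_id=pid, tokens=tokens, protein_length=protein_length)

        n_decoys = int(round(len(true_hits) * cfg.hit_noise / (1.0 - cfg.hit_noise))) \
            if cfg.hit_noise < 1.0 else len(true_hits)
        decoys = []
        for _ in range(n_decoys):
            host = true_hits[int(rng.integers(len(true_hits)))]
            # Strictly nested and strictly shorter: never coverage-optimal.
            lo = host.start + int(rng.integers(1, 6))
            hi = host.end - int(rng.integers(1, 6))
            if lo > hi:
                lo, hi = host.start + 1, host.end - 1
            fam = str(rng.choice(funfams))
            while fam == host.family_id:
                fam = str(rng.choice(funfams))
            decoys.append(
                DomainHit(
                    protein_id=pid,
                    family_id=fam,
                    resource=Resource.FUNFAM,
                    start=lo,
                    end=hi,
                    evalue=log_uniform(*cfg.decoy_evalue_range),
                )
            )
        combined = true_hits + decoys
        order = rng.permutation(len(combined))
        hits.extend(combined[j] for j in order)

    return GenomeSet(name=name, proteins=proteins), hits


_MUTATION_OPS = ("delete", "swap", "substitute-within-superfamily", "substitute-random")


def mutate_mda(
    mda: MDA,
    op: str,
    hierarchy: FamilyHierarchy,
    seed: int = 0,
) -> MDA:
    """Apply a single architecture edit, preserving MDA invariants.

    Operations: ``delete`` a random domain; ``swap`` two adjacent domains
    (families exchanged, range slots kept); ``substitute-within-superfamily``
    replaces one FunFam domain by a different FunFam of its superfamily;
    ``substitute-random`` replaces one domain by a FunFam from a different
    fold.  Impossible edits (e.g. swap on a single-domain MDA) raise.
    """
    if op not in _MUTATION_OPS:
        raise ValueError(f"unknown op {op!r}; expected one of {_MUTATION_OPS}")
    if len(mda) == 0:
        raise ValueError("cannot mutate an empty MDA")
    rng = np.random.default_rng(seed)
    tokens = list(mda.tokens)

    if op == "delete":
        del tokens[int(rng.integers(len(tokens)))]
    elif op == "swap":
        if len(tokens) < 2:
            raise ValueError("swap requires at least two domains")
        i = int(rng.integers(len(tokens) - 1))
        a, b = tokens[i], tokens[i + 1]
        tokens[i] = DomainToken(b.family_id, b.level, a.start, a.end)
        tokens[i + 1] = DomainToken(a.family_id, a.level, b.start, b.end)
    elif op == "substitute-within-superfamily":
        candidates = []
        for i, tok in enumerate(tokens):
            if tok.level != Level.FUNFAM:
                continue
            sf = hierarchy.funfam_to_superfamily[tok.family_id]
            siblings = [
                ff for ff, s in hierarchy.funfam_to_superfamily.items()
                if s == sf and ff != tok.family_id
            ]
            if siblings:
                candidates.append((i, sorted(siblings)))
        if not candidates:
            raise ValueError(
                "no FunFam domain with a sibling FunFam in its superfamily"
            )
        i, siblings = candidates[int(rng.integers(len(candidates)))]
        new_fam = siblings[int(rng.integers(len(siblings)))]
        tokens[i] = DomainToken(new_fam, Level.FUNFAM, tokens[i].start, tokens[i].end)
    else:  # substitute-random
        i = int(rng.integers(len(tokens)))
        old_fold = hierarchy.fold_of(tokens[i].family_id)
        pool = sorted(
            ff for ff in hierarchy.funfams if hierarchy.fold_of(ff) != old_fold
        )
        if not pool:
            raise ValueError("no FunFam outside the domain's fold to substitute")
        new_fam = pool[int(rng.integers(len(pool)))]
        tokens[i] = DomainToken(new_fam, Level.FUNFAM, tokens[i].start, tokens[i].end)

    return MDA(protein_id=mda.protein_id, tokens=tuple(tokens),
               protein_length=mda.protein_length)
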