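"""Readers and writers for the on-disk formats.

All tables are plain TSV with a header row; writers prepend a
format-version comment line and readers skip ``#`` comments.  Readers
validate every field at load time and reject malformed rows with the file
name and line number rather than coercing silently.

Formats
-------
hits table        protein_id, family_id, resource, start, end, evalue
hierarchy table   family_id, superfamily_id, fold_id (CATH-style dotted
                  codes; the fold is the first three numbers of the
                  superfamily code).  A row whose family_id equals its
                  superfamily_id declares a superfamily with no FunFams.
MDA table         one row per protein: pipe-separated family ids, levels
                  and residue ranges (family ids never contain ``|``).
trees             Newick, one tree per superfamily, leaves = FunFam ids.
FASTA             protein lengths only; sequences are never used.
lineage table     genome_id, lineage as ``rank=name`` entries joined by
                  ``;`` (root first).
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Sequence, Union

import dendropy
from Bio import SeqIO

from .model import (
    MDA,
    DomainHit,
    DomainToken,
    FamilyHierarchy,
    GenomeSet,
    Level,
    Resource,
)

__all__ = [
    "read_hits",
    "write_hits",
    "read_hierarchy",
    "write_hierarchy",
    "read_trees",
    "write_trees",
    "read_fasta_lengths",
    "read_lineage",
    "read_mdas",
    "write_mdas",
]

_HITS_VERSION = "# domarch hits v1"
_MDA_VERSION = "# domarch mdas v1"

_SFAM_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
_FOLD_RE = re.compile(r"^\d+\.\d+\.\d+$")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """A malformed row, reported with file and line number."""

    def __init__(self, path: PathLike, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")


def _rows(path: PathLike, expected_header: Sequence[str]):
    """Yield (lineno, row-dict) from a TSV, checking the header."""
    with open(path, newline="") as fh:
        lineno = 0
        header = None
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != list(expected_header):
                    raise FormatError(
                        path, lineno,
                        f"expected header {list(expected_header)}, got {header}",
                    )
                continue
            if len(fields) != len(header):
                raise FormatError(
                    path, lineno,
                    f"expected {len(header)} fields, got {len(fields)}",
                )
            yield lineno, dict(zip(header, fields))
    if header is None:
        raise FormatError(path, 0, "empty file: missing header")


def read_hits(path: PathLike) -> list[DomainHit]:
    """Load a domain-hit table."""
    hits = []
    for lineno, row in _rows(
        path, ["protein_id", "family_id", "resource", "start", "end", "evalue"]
    ):
        try:
            resource = Resource(row["resource"])
        except ValueError:
            raise FormatError(
                path, lineno,
                f"unknown resource {row['resource']!r} "
                f"(expected one of {[r.value for r in Resource]})",
            ) from None
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError:
            raise FormatError(
                path, lineno, f"non-integer residue range {row['start']}-{row['end']}"
            ) from None
        try:
            evalue = float(row["evalue"])
        except ValueError:
            raise FormatError(path, lineno, f"non-numeric evalue {row['evalue']!r}") from None
        try:
            hits.append(
                DomainHit(
                    protein_id=row["protein_id"],
                    family_id=row["family_id"],
                    resource=resource,
                    start=start,
                    end=end,
                    evalue=evalue,
                )
            )
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from None
    return hits


def write_hits(hits: Iterable[DomainHit], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_HITS_VERSION + "\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "family_id", "resource", "start", "end", "evalue"])
        for h in hits:
            writer.writerow(
                [h.protein_id, h.family_id, h.resource.value, h.start, h.end, repr(h.evalue)]
            )


def read_hierarchy(path: PathLike) -> FamilyHierarchy:
    """Load the family hierarchy (without trees; see :func:`read_trees`)."""
    ff_to_sf: dict[str, str] = {}
    sf_to_fold: dict[str, str] = {}
    for lineno, row in _rows(path, ["family_id", "superfamily_id", "fold_id"]):
        fam, sf, fold = row["family_id"], row["superfamily_id"], row["fold_id"]
        if not _SFAM_RE.match(sf):
            raise FormatError(
                path, lineno, f"superfamily id {sf!r} is not a 4-number dotted code"
            )
        if not _FOLD_RE.match(fold):
            raise FormatError(
                path, lineno, f"fold id {fold!r} is not a 3-number dotted code"
            )
        if not sf.startswith(fold + "."):
            raise FormatError(
                path, lineno,
                f"fold {fold!r} is not the 3-number prefix of superfamily {sf!r}",
            )
        if sf in sf_to_fold and sf_to_fold[sf] != fold:
            raise FormatError(
                path, lineno, f"superfamily {sf} remapped from {sf_to_fold[sf]} to {fold}"
            )
        sf_to_fold[sf] = fold
        if fam != sf:
            if fam in ff_to_sf and ff_to_sf[fam] != sf:
                raise FormatError(
                    path, lineno, f"FunFam {fam} remapped from {ff_to_sf[fam]} to {sf}"
                )
            ff_to_sf[fam] = sf
    return FamilyHierarchy(ff_to_sf, sf_to_fold)


def write_hierarchy(hierarchy: FamilyHierarchy, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# domarch hierarchy v1\n")
        fh.write("family_id\tsuperfamily_id\tfold_id\n")
        for sf in hierarchy.superfamilies:
            fh.write(f"{sf}\t{sf}\t{hierarchy.superfamily_to_fold[sf]}\n")
        for ff in hierarchy.funfams:
            sf = hierarchy.funfam_to_superfamily[ff]
            fh.write(f"{ff}\t{sf}\t{hierarchy.superfamily_to_fold[sf]}\n")


def read_trees(path: PathLike, hierarchy: FamilyHierarchy) -> dict[str, dendropy.Tree]:
    """Load FunFam trees (Newick, one per superfamily).

    Each tree is assigned to the superfamily of its leaves; every leaf must
    be a FunFam of the hierarchy and all leaves of a tree must belong to
    one superfamily.
    """
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    out: dict[str, dendropy.Tree] = {}
    for idx, tree in enumerate(trees):
        superfams = set()
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else None
            sf = hierarchy.funfam_to_superfamily.get(label)
            if sf is None:
                raise ValueError(
                    f"{path}: tree {idx + 1} leaf {label!r} is not a FunFam "
                    f"of the hierarchy"
                )
            superfams.add(sf)
        if len(superfams) != 1:
            raise ValueError(
                f"{path}: tree {idx + 1} mixes superfamilies {sorted(superfams)}"
            )
        sf = superfams.pop()
        if sf in out:
            raise ValueError(f"{path}: duplicate tree for superfamily {sf}")
        out[sf] = tree
    return out


def write_trees(trees: dict[str, dendropy.Tree], path: PathLike) -> None:
    with open(path, "w") as fh:
        for sf in sorted(trees):
            fh.write(
                trees[sf].as_string(schema="newick", suppress_rooting=True).strip()
                + "\n"
            )


def read_fasta_lengths(path: PathLike) -> dict[str, int]:
    """Protein lengths from a FASTA file; duplicate ids are an error."""
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise ValueError(f"{path}: duplicate protein id {record.id!r}")
        lengths[record.id] = len(record.seq)
    return lengths


def read_lineage(path: PathLike) -> dict[str, list[tuple[str, str]]]:
    """genome_id -> ordered (rank, name) lineage, root first."""
    out: dict[str, list[tuple[str, str]]] = {}
    for lineno, row in _rows(path, ["genome_id", "lineage"]):
        gid = row["genome_id"]
        if gid in out:
            raise FormatError(path, lineno, f"duplicate genome id {gid!r}")
        lineage = []
        for entry in row["lineage"].split(";"):
            entry = entry.strip()
            if not entry:
                continue
            if "=" not in entry:
                raise FormatError(
                    path, lineno, f"lineage entry {entry!r} is not 'rank=name'"
                )
            rank, name = entry.split("=", 1)
            lineage.append((rank, name))
        out[gid] = lineage
    return out


def write_mdas(mdas: Iterable[MDA], path: PathLike) -> None:
    """Serialise MDAs: one row per protein with pipe-joined token fields."""
    with open(path, "w", newline="") as fh:
        fh.write(_MDA_VERSION + "\n")
        fh.write("protein_id\tprotein_length\tfamilies\tlevels\tranges\n")
        for mda in mdas:
            fams = "|".join(t.family_id for t in mda.tokens)
            levels = "|".join(t.level.value for t in mda.tokens)
            ranges = "|".join(f"{t.start}-{t.end}" for t in mda.tokens)
            fh.write(f"{mda.protein_id}\t{mda.protein_length}\t{fams}\t{levels}\t{ranges}\n")


def read_mdas(path: PathLike) -> list[MDA]:
    """Load an MDA table written by :func:`write_mdas`."""
    mdas = []
    for lineno, row in _rows(
        path, ["protein_id", "protein_length", "families", "levels", "ranges"]
    ):
        try:
            plen = int(row["protein_length"])
        except ValueError:
            raise FormatError(
                path, lineno, f"non-integer protein length {row['protein_length']!r}"
            ) from None
        fams = row["families"].split("|") if row["families"] else []
        levels = row["levels"].split("|") if row["levels"] else []
        ranges = row["ranges"].split("|") if row["ranges"] else []
        if not (len(fams) == len(levels) == len(ranges)):
            raise FormatError(
                path, lineno,
                f"token field counts differ: {len(fams)} families, "
                f"{len(levels)} levels, {len(ranges)} ranges",
            )
        tokens = []
        for fam, level, rng in zip(fams, levels, ranges):
            m = re.match(r"^(\d+)-(\d+)$", rng)
            if not m:
                raise FormatError(path, lineno, f"malformed range {rng!r}")
            try:
                tokens.append(
                    DomainToken(
                        family_id=fam,
                        level=Level(level),
                        start=int(m.group(1)),
                        end=int(m.group(2)),
                    )
                )
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc)) from None
        try:
            mdas.append(
                MDA(protein_id=row["protein_id"], tokens=tuple(tokens), protein_length=plen)
            )
        except ValueError as exc:
            raise FormatError(path, lineno, str(exc)) from None
    return mdas
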