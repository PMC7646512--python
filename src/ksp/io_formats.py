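"""Readers, writers and preprocessing for kinase-substrate tables, PPI edge
lists and substrate FASTA files.

Phosphosites are represented as 15-mer windows: the modified residue plus
seven flanking residues on each side, padded with ``_`` where the protein
ends.  Two tab-separated dialects are supported for kinase-substrate tables:

``psp``
    Columns ``KINASE``, ``SUB_ACC_ID``, ``MOD_RSD`` (e.g. ``S15``) and
    ``SITE_+/-7_AA``; the modified residue may be lowercase.
``plain``
    ``kinase<TAB>substrate<TAB>position<TAB>peptide``.

All readers transparently accept gzip-compressed input.
"""

from __future__ import annotations

import gzip
import logging
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

from Bio import SeqIO

logger = logging.getLogger(__name__)

PAD = "_"
WINDOW_FLANK = 7
WINDOW_LENGTH = 2 * WINDOW_FLANK + 1
CENTER_INDEX = WINDOW_FLANK  # 0-based index of the modified residue
AA20 = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO_RESIDUES = frozenset("STY")

DIALECTS = ("psp", "plain")

_PSP_COLUMNS = ("KINASE", "SUB_ACC_ID", "MOD_RSD", "SITE_+/-7_AA")


class MalformedSiteError(ValueError):
    """A phosphosite record violates the 15-mer window contract."""


def _validate_peptide(peptide: str) -> str:
    if len(peptide) != WINDOW_LENGTH:
        raise MalformedSiteError(
            f"peptide {peptide!r} has length {len(peptide)}, expected {WINDOW_LENGTH}"
        )
    core = peptide.strip(PAD)
    if PAD in core:
        raise MalformedSiteError(
            f"peptide {peptide!r} has interior padding; padding may only "
            "appear as a contiguous prefix and/or suffix"
        )
    if peptide[CENTER_INDEX] not in PHOSPHO_RESIDUES:
        raise MalformedSiteError(
            f"peptide {peptide!r} center residue {peptide[CENTER_INDEX]!r} "
            "is not one of S/T/Y"
        )
    return peptide


@dataclass(frozen=True, order=True)
class PhosphoSite:
    """One experimentally observed phosphosite with its ±7 window."""

    substrate_id: str
    position: int
    residue: str
    peptide: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MalformedSiteError(f"position must be >= 1, got {self.position}")
        if self.residue not in PHOSPHO_RESIDUES:
            raise MalformedSiteError(f"residue {self.residue!r} is not one of S/T/Y")
        _validate_peptide(self.peptide)
        if self.peptide[CENTER_INDEX] != self.residue:
            raise MalformedSiteError(
                f"peptide center {self.peptide[CENTER_INDEX]!r} does not match "
                f"declared residue {self.residue!r}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.substrate_id, self.position)


@dataclass(frozen=True, order=True)
class KinaseSubstratePair:
    """A (kinase, phosphosite) relationship."""

    kinase_id: str
    site: PhosphoSite

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.kinase_id, self.site.substrate_id, self.site.position)


@dataclass(frozen=True, order=True)
class PPIEdge:
    """Undirected protein-protein interaction, stored with endpoints sorted."""

    protein_a: str
    protein_b: str

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-loop on {self.protein_a!r}")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)


@dataclass
class ReadStats:
    """Per-file bookkeeping for a table read."""

    n_rows: int = 0
    n_skipped: int = 0
    n_duplicates: int = 0
    errors: list[str] = field(default_factory=list)


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _site_from_fields(
    substrate: str, position: int, peptide: str
) -> PhosphoSite:
    # PhosphoSitePlus marks the modified residue in lowercase; record the
    # center residue, then normalise the whole window to uppercase.
    peptide = peptide.strip()
    if len(peptide) != WINDOW_LENGTH:
        raise MalformedSiteError(
            f"peptide {peptide!r} has length {len(peptide)}, expected {WINDOW_LENGTH}"
        )
    residue = peptide[CENTER_INDEX].upper()
    if residue not in PHOSPHO_RESIDUES:
        raise MalformedSiteError(
            f"center residue {peptide[CENTER_INDEX]!r} is not one of S/T/Y"
        )
    return PhosphoSite(
        substrate_id=substrate,
        position=position,
        residue=residue,
        peptide=peptide.upper(),
    )


def _parse_mod_rsd(mod_rsd: str) -> tuple[str, int]:
    mod_rsd = mod_rsd.strip().split("-")[0]  # drop "-p" style suffixes
    residue, pos = mod_rsd[0].upper(), mod_rsd[1:]
    if residue not in PHOSPHO_RESIDUES or not pos.isdigit():
        raise MalformedSiteError(f"cannot parse MOD_RSD field {mod_rsd!r}")
    return residue, int(pos)


def read_kinase_substrate_table(
    path: str | Path,
    dialect: str = "psp",
    *,
    return_stats: bool = False,
) -> list[KinaseSubstratePair] | tuple[list[KinaseSubstratePair], ReadStats]:
    """Read a kinase-substrate pair table.

    Malformed rows are logged and skipped; exact duplicate
    (kinase, substrate, position) triples are removed.  Raises
    ``ValueError`` if no valid pair survives.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    stats = ReadStats()
    pairs: list[KinaseSubstratePair] = []
    seen: set[tuple[str, str, int]] = set()
    with _open_text(path) as fh:
        header_done = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_done:
                header_done = True
                if _looks_like_header(fields, dialect):
                    continue
            stats.n_rows += 1
            try:
                pair = _parse_pair_row(fields, dialect)
            except (MalformedSiteError, ValueError, IndexError) as exc:
                stats.n_skipped += 1
                msg = f"{path}:{lineno}: skipped row: {exc}"
                stats.errors.append(msg)
                logger.warning(msg)
                continue
            if pair.key in seen:
                stats.n_duplicates += 1
                continue
            seen.add(pair.key)
            pairs.append(pair)
    if not pairs:
        raise ValueError(f"no valid kinase-substrate pairs read from {path}")
    if stats.n_skipped:
        logger.info("%s: skipped %d malformed rows", path, stats.n_skipped)
    if return_stats:
        return pairs, stats
    return pairs


def _looks_like_header(fields: Sequence[str], dialect: str) -> bool:
    upper = [f.strip().upper() for f in fields]
    if dialect == "psp":
        return any(col in upper for col in _PSP_COLUMNS)
    # plain dialect: a header row has a non-integer position column
    if len(fields) >= 3 and not fields[2].strip().lstrip("-").isdigit():
        return True
    return upper[:2] == ["KINASE", "SUBSTRATE"]


def _parse_pair_row(fields: Sequence[str], dialect: str) -> KinaseSubstratePair:
    if dialect == "psp":
        kinase, substrate, mod_rsd, peptide = (fields[i].strip() for i in range(4))
        if not (kinase and substrate and mod_rsd and peptide):
            raise MalformedSiteError("missing field")
        residue, position = _parse_mod_rsd(mod_rsd)
        site = _site_from_fields(substrate, position, peptide)
        if site.residue != residue:
            raise MalformedSiteError(
                f"MOD_RSD residue {residue} disagrees with peptide center "
                f"{site.residue}"
            )
    else:
        kinase, substrate, position, peptide = (fields[i].strip() for i in range(4))
        if not (kinase and substrate and position and peptide):
            raise MalformedSiteError("missing field")
        site = _site_from_fields(substrate, int(position), peptide)
    return KinaseSubstratePair(kinase_id=kinase, site=site)


def write_kinase_substrate_table(
    pairs: Iterable[KinaseSubstratePair],
    path: str | Path,
    dialect: str = "plain",
) -> None:
    """Write pairs in the given dialect (round-trips with the reader)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "wt") as fh:
        if dialect == "psp":
            fh.write("\t".join(_PSP_COLUMNS) + "\n")
            for p in pairs:
                fh.write(
                    f"{p.kinase_id}\t{p.site.substrate_id}\t"
                    f"{p.site.residue}{p.site.position}\t{p.site.peptide}\n"
                )
        else:
            fh.write("kinase\tsubstrate\tposition\tpeptide\n")
            for p in pairs:
                fh.write(
                    f"{p.kinase_id}\t{p.site.substrate_id}\t"
                    f"{p.site.position}\t{p.site.peptide}\n"
                )


def read_ppi_table(
    path: str | Path,
    *,
    return_stats: bool = False,
) -> list[PPIEdge] | tuple[list[PPIEdge], ReadStats]:
    """Read a two-column PPI edge list (optional header, optional extras).

    Self-loops and duplicate edges (in either orientation) are dropped.
    """
    stats = ReadStats()
    edges: list[PPIEdge] = []
    seen: set[tuple[str, str]] = set()
    with _open_text(path) as fh:
        header_done = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if not header_done:
                header_done = True
                lowered = [f.lower() for f in fields[:2]]
                if any(tok in f for f in lowered for tok in ("protein", "interactor", "gene")):
                    continue
            stats.n_rows += 1
            if len(fields) < 2 or not fields[0] or not fields[1]:
                stats.n_skipped += 1
                logger.warning("%s:%d: skipped malformed PPI row", path, lineno)
                continue
            a, b = fields[0], fields[1]
            if a == b:
                stats.n_skipped += 1
                continue
            key = (min(a, b), max(a, b))
            if key in seen:
                stats.n_duplicates += 1
                continue
            seen.add(key)
            edges.append(PPIEdge(a, b))
    if not edges:
        raise ValueError(f"no valid PPI edges read from {path}")
    if return_stats:
        return edges, stats
    return edges


def write_ppi_table(edges: Iterable[PPIEdge], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("protein_a\tprotein_b\n")
        for e in edges:
            fh.write(f"{e.protein_a}\t{e.protein_b}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence mapping."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def extract_window(sequence: str, position: int) -> str:
    """Return the 15-mer window around a 1-based position, padded with '_'.

    The window is the closed interval [position - 7, position + 7]; flanks
    that run past either end of the sequence are padded.
    """
    if not 1 <= position <= len(sequence):
        raise IndexError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    center = sequence[position - 1].upper()
    if center not in PHOSPHO_RESIDUES:
        raise MalformedSiteError(
            f"residue {center!r} at position {position} is not one of S/T/Y"
        )
    start = position - 1 - WINDOW_FLANK
    stop = position - 1 + WINDOW_FLANK + 1
    left_pad = max(0, -start)
    right_pad = max(0, stop - len(sequence))
    window = sequence[max(0, start) : min(len(sequence), stop)].upper()
    return PAD * left_pad + window + PAD * right_pad


def site_from_sequence(substrate_id: str, sequence: str, position: int) -> PhosphoSite:
    """Build a :class:`PhosphoSite` from a protein sequence and position."""
    peptide = extract_window(sequence, position)
    return PhosphoSite(
        substrate_id=substrate_id,
        position=position,
        residue=peptide[CENTER_INDEX],
        peptide=peptide,
    )


def filter_trainable_kinases(
    pairs: Iterable[KinaseSubstratePair],
    min_sites: int = 15,
    *,
    dedup: Callable[[list[str]], list[str]] | None = None,
) -> dict[str, list[PhosphoSite]]:
    """Group sites per kinase, deduplicate peptides, keep trainable kinases.

    A kinase is retained only if it has *strictly more than* ``min_sites``
    distinct site peptides.  ``dedup`` is an optional hook replacing the
    default exact-identity peptide deduplication (e.g. a similarity-threshold
    collapse); it receives the kinase's peptides in input order and returns
    the peptides to keep.
    """
    by_kinase: dict[str, list[PhosphoSite]] = {}
    for pair in pairs:
        by_kinase.setdefault(pair.kinase_id, []).append(pair.site)
    result: dict[str, list[PhosphoSite]] = {}
    for kinase, sites in by_kinase.items():
        if dedup is not None:
            keep = set(dedup([s.peptide for s in sites]))
            chosen: list[PhosphoSite] = []
            used: set[str] = set()
            for s in sites:
                if s.peptide in keep and s.peptide not in used:
                    used.add(s.peptide)
                    chosen.append(s)
        else:
            chosen = []
            used = set()
            for s in sites:
                if s.peptide not in used:
                    used.add(s.peptide)
                    chosen.append(s)
        if len(chosen) > min_sites:
            result[kinase] = chosen
    return result
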