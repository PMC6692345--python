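"""Chain coordinate I/O and the genome data model.

Chromosome models are plain bead chains: one bead per ~100 kb, coordinates in
nanometres.  Two on-disk dialects are supported: a minimal PDB dialect (one
bead per ATOM/HETATM record, chains distinguished by the chain-identifier
column) and a whitespace ``chain x y z`` XYZ/TSV dialect.  Coordinates are
taken verbatim; nothing is rescaled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Polyline",
    "Chromosome",
    "GenomeModel",
    "LinkRecord",
    "ParseError",
    "read_genome",
    "write_genome",
    "write_report",
    "read_report",
]

#: two beads closer than this (nm) are considered coincident
_MIN_SEPARATION = 1e-9


class ParseError(ValueError):
    """Malformed coordinate file; message names the offending line."""


@dataclass
class Polyline:
    """An ordered open or closed chain of 3D points (nm).

    For ``closed`` chains the last->first segment is implicit; the first
    vertex is never duplicated at the end.
    """

    vertices: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {v.shape}")
        if len(v) < 2:
            raise ValueError("a polyline needs at least 2 vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite coordinates")
        steps = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(steps <= _MIN_SEPARATION):
            raise ValueError("consecutive vertices coincide")
        if self.closed and np.linalg.norm(v[0] - v[-1]) <= _MIN_SEPARATION:
            raise ValueError("closed polyline must not duplicate its endpoint")
        self.vertices = v

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_segments(self) -> int:
        return len(self.vertices) if self.closed else len(self.vertices) - 1

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment start and end points, including the closing segment."""
        v = self.vertices
        if self.closed:
            return v, np.roll(v, -1, axis=0)
        return v[:-1], v[1:]

    def reversed(self) -> "Polyline":
        return Polyline(self.vertices[::-1].copy(), closed=self.closed)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Polyline":
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return Polyline(v, closed=self.closed)


@dataclass
class Chromosome:
    """A named chromosome chain; ``bp_per_bead`` records the model resolution."""

    name: str
    chain: Polyline
    bp_per_bead: int = 100_000

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chromosome name must be non-empty")
        if self.bp_per_bead <= 0:
            raise ValueError("bp_per_bead must be positive")


@dataclass
class GenomeModel:
    """One 3D model of one cell: an ordered set of named chromosomes."""

    cell_id: str
    model_id: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in model")

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]


@dataclass
class LinkRecord:
    """Survey result for one chromosome pair.

    ``localization`` intervals are 0-based half-open bead ranges, one per
    chain of the pair.
    """

    pair: tuple[str, str]
    gln: float
    linked: bool
    consensus: dict[str, float] | None = None
    dominant: str | None = None
    localization: tuple[tuple[int, int], tuple[int, int]] | None = None


# ---------------------------------------------------------------------------
# reading


def _collapse_duplicates(rows: list[np.ndarray], chain: str) -> np.ndarray:
    coords = np.asarray(rows, dtype=float)
    keep = np.ones(len(coords), dtype=bool)
    for i in range(1, len(coords)):
        prev = coords[np.flatnonzero(keep[:i])[-1]]
        if np.linalg.norm(coords[i] - prev) <= _MIN_SEPARATION:
            keep[i] = False
    if not keep.all():
        warnings.warn(
            f"chain {chain!r}: collapsed {int((~keep).sum())} duplicate "
            "consecutive beads",
            stacklevel=3,
        )
    return coords[keep]


def _parse_pdb(lines: Iterable[str]) -> dict[str, list[np.ndarray]]:
    chains: dict[str, list[np.ndarray]] = {}
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            chain = line[21].strip() or line[72:76].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"line {lineno}: malformed PDB record: {exc}") from exc
        if not chain:
            raise ParseError(f"line {lineno}: missing chain identifier")
        chains.setdefault(chain, []).append(np.array([x, y, z]))
    return chains


def _parse_xyz(lines: Iterable[str]) -> dict[str, list[np.ndarray]]:
    chains: dict[str, list[np.ndarray]] = {}
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 4:
            raise ParseError(
                f"line {lineno}: expected 'chain x y z', got {len(parts)} fields"
            )
        try:
            xyz = np.array([float(p) for p in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad coordinate: {exc}") from exc
        chains.setdefault(parts[0], []).append(xyz)
    return chains


def read_genome(path: str | Path, format: str | None = None,
                cell_id: str = "", model_id: str = "",
                bp_per_bead: int = 100_000) -> GenomeModel:
    """Read a genome model from a PDB- or XYZ-dialect coordinate file.

    ``format`` is ``"pdb"`` or ``"xyz"``; when omitted it is guessed from the
    file extension (``.pdb`` -> pdb, anything else -> xyz).  Chains are split
    by identifier; bead order is record order and is never re-sorted.
    """
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz"
    if format not in ("pdb", "xyz"):
        raise ValueError(f"unknown format {format!r}")
    with open(path) as fh:
        lines = fh.readlines()
    chains = _parse_pdb(lines) if format == "pdb" else _parse_xyz(lines)
    if not chains:
        raise ParseError(f"{path}: no coordinate records found")
    chromosomes = []
    for name, rows in chains.items():  # insertion order = record order
        coords = _collapse_duplicates(rows, name)
        if len(coords) < 2:
            raise ParseError(f"chain {name!r} has fewer than 2 beads")
        chromosomes.append(
            Chromosome(name=name, chain=Polyline(coords), bp_per_bead=bp_per_bead)
        )
    return GenomeModel(cell_id=cell_id or path.stem, model_id=model_id or "1",
                       chromosomes=chromosomes)


def write_genome(model: GenomeModel, path: str | Path,
                 format: str | None = None) -> None:
    """Write a genome model; inverse of :func:`read_genome`."""
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz"
    with open(path, "w") as fh:
        if format == "pdb":
            serial = 1
            for chrom in model.chromosomes:
                for x, y, z in chrom.chain.vertices:
                    fh.write(
                        f"ATOM  {serial % 100000:5d}  CA  BEA {chrom.name[0]}"
                        f"{serial % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"  1.00  0.00\n"
                    )
                    serial += 1
                fh.write("TER\n")
        elif format == "xyz":
            for chrom in model.chromosomes:
                for x, y, z in chrom.chain.vertices:
                    fh.write(f"{chrom.name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
        else:
            raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# survey reports

_TSV_COLUMNS = ["chain1", "chain2", "gln", "linked", "dominant",
                "consensus", "loc1_start", "loc1_end", "loc2_start", "loc2_end"]


def _record_to_row(r: LinkRecord) -> list:
    cons = ""
    if r.consensus:
        cons = ",".join(f"{k}:{v:.6g}" for k, v in sorted(r.consensus.items()))
    loc = r.localization or ((None, None), (None, None))
    return [r.pair[0], r.pair[1], f"{r.gln:.6f}", str(int(r.linked)),
            r.dominant or "", cons,
            *("" if x is None else str(x) for x in (*loc[0], *loc[1]))]


def write_report(records: Sequence[LinkRecord], path: str | Path,
                 format: str | None = None) -> None:
    """Write link-survey records as TSV (documented header) or JSON."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("# chromolink link survey; consensus = name:freq pairs; "
                     "intervals 0-based half-open bead ranges\n")
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for r in records:
                fh.write("\t".join(_record_to_row(r)) + "\n")
    elif format == "json":
        payload = []
        for r in records:
            payload.append({
                "pair": list(r.pair),
                "gln": r.gln,
                "linked": r.linked,
                "dominant": r.dominant,
                "consensus": r.consensus,
                "localization": (
                    [list(r.localization[0]), list(r.localization[1])]
                    if r.localization else None
                ),
            })
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> list[LinkRecord]:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        payload = json.load(fh)
    records = []
    for obj in payload:
        loc = obj.get("localization")
        records.append(LinkRecord(
            pair=tuple(obj["pair"]),
            gln=float(obj["gln"]),
            linked=bool(obj["linked"]),
            consensus=obj.get("consensus"),
            dominant=obj.get("dominant"),
            localization=(tuple(map(tuple, loc)) if loc else None),
        ))
    return records
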