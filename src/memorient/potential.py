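"""Depth-sliced knowledge-based membrane potential.

The membrane is an infinite slab 48 A thick, split into 32 slices of
1.5 A along z with z = 0 at the bilayer centre and the cytoplasm towards
negative z.  Training counts the scoring centre of each residue type per
slice over a set of pre-oriented structures; the pseudo-energy of type
``a`` in slice ``s`` is the log-odds

    E_a(s) = -ln( f_a(s) / f(s) )

where ``f_a`` is the depth distribution of type ``a`` (normalised over
slices) and ``f`` the depth distribution of all residues.  Cells with
zero observations receive a pseudocount of one so every energy is
finite.  Residues outside the slab contribute zero to the orientation
energy; thickness estimation uses the per-type core / extra-membranous
averages instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import IDENTITY, Transform, apply_transform
from .structure_io import (
    Structure,
    ScoringCentre,
    read_structure,
    scoring_centres,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AA_ORDER",
    "OUTSIDE",
    "SliceGrid",
    "PotentialTable",
    "ManifestEntry",
    "TrainingManifest",
    "TrainingError",
    "slice_index",
    "slice_indices",
    "train_potential",
    "train_from_structures",
    "count_structure",
    "residue_energy",
    "structure_energy",
    "centre_arrays",
    "save_potential",
    "load_potential",
    "cross_validation_exclusions",
]

#: Amino acids in alphabetical one-letter order; row order of all tables.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Sentinel returned by :func:`slice_index` for depths outside the slab.
OUTSIDE = -1

# Band boundaries (|z| in Angstroms) used for the per-type averages that
# back the thickness scan: hydrophobic core inside 10, head groups
# 10..20, extra-membranous 20 and beyond.
CORE_LIMIT = 10.0
EXTRAMEM_LIMIT = 20.0


class TrainingError(ValueError):
    """Raised when no usable training data remains after filtering."""


@dataclass(frozen=True)
class SliceGrid:
    half_thickness: float = 24.0
    n_slices: int = 32
    slice_width: float = 1.5

    def __post_init__(self) -> None:
        if not math.isclose(self.n_slices * self.slice_width, 2 * self.half_thickness):
            raise ValueError("n_slices * slice_width must equal 2 * half_thickness")
        if self.n_slices < 2 or self.slice_width <= 0:
            raise ValueError("invalid slice grid")

    def centres(self) -> np.ndarray:
        return -self.half_thickness + (np.arange(self.n_slices) + 0.5) * self.slice_width


DEFAULT_GRID = SliceGrid()


def slice_index(z: float, grid: SliceGrid = DEFAULT_GRID) -> int:
    """Slice index for depth ``z``; ``OUTSIDE`` if |z| beyond the slab.

    Slices are half-open ``[lo, lo + width)`` starting at
    ``-half_thickness``, so z = -24 maps to slice 0 and z = +24 is
    outside.
    """
    if not np.isfinite(z):
        raise ValueError("depth must be finite")
    if z < -grid.half_thickness or z >= grid.half_thickness:
        return OUTSIDE
    return int(np.floor((z + grid.half_thickness) / grid.slice_width))


def slice_indices(z: np.ndarray, grid: SliceGrid = DEFAULT_GRID) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`slice_index`: (indices, inside-slab mask)."""
    z = np.asarray(z, dtype=float)
    idx = np.floor((z + grid.half_thickness) / grid.slice_width).astype(np.int64)
    inside = (idx >= 0) & (idx < grid.n_slices)
    return idx, inside


@dataclass
class PotentialTable:
    """20 x n_slices pseudo-energies plus the counts that generated them."""

    grid: SliceGrid
    counts: np.ndarray  # (20, n_slices) post-pseudocount integer counts
    energy: np.ndarray  # (20, n_slices) -ln(f_a/f)
    core_avg: np.ndarray  # (20,) mean energy over |z| < 10 slices
    extramem_avg: np.ndarray  # (20,) mean energy over 20 <= |z| < 24 slices
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_counts(cls, raw_counts: np.ndarray, grid: SliceGrid = DEFAULT_GRID,
                    meta: dict | None = None, pseudocount_all: bool = False) -> "PotentialTable":
        raw = np.asarray(raw_counts)
        if raw.shape != (len(AA_ORDER), grid.n_slices):
            raise ValueError(f"counts must have shape (20, {grid.n_slices})")
        if np.any(raw < 0):
            raise ValueError("counts must be non-negative")
        if pseudocount_all:
            counts = raw.astype(np.int64) + 1
        else:
            counts = raw.astype(np.int64) + (raw == 0)
        energy = _energy_from_counts(counts)
        core_mask, extra_mask = _band_masks(grid)
        core_avg = energy[:, core_mask].mean(axis=1)
        extramem_avg = energy[:, extra_mask].mean(axis=1)
        return cls(grid=grid, counts=counts, energy=energy,
                   core_avg=core_avg, extramem_avg=extramem_avg,
                   meta=dict(meta or {}))


def _energy_from_counts(counts: np.ndarray) -> np.ndarray:
    counts = counts.astype(float)
    f_a = counts / counts.sum(axis=1, keepdims=True)
    f = counts.sum(axis=0) / counts.sum()
    return -np.log(f_a / f[None, :])


def _band_masks(grid: SliceGrid) -> tuple[np.ndarray, np.ndarray]:
    zc = np.abs(grid.centres())
    core = zc < CORE_LIMIT
    extra = zc >= EXTRAMEM_LIMIT
    return core, extra


# ---------------------------------------------------------------------------
# Training manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    entry_id: str
    path: str
    chains: tuple[str, ...]  # empty tuple = all chains
    kind: str  # "alpha" or "beta"
    resolution: float
    superfamily: str
    partners: frozenset[str] = frozenset()  # entry ids with >25% identity

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not self.superfamily:
            raise ValueError("superfamily label must be non-empty")


@dataclass
class TrainingManifest:
    entries: list[ManifestEntry]

    def by_id(self, entry_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)


MANIFEST_COLUMNS = ["id", "path", "chains", "kind", "resolution", "superfamily", "partners"]


def read_manifest(text: str) -> TrainingManifest:
    """Parse a TSV manifest: id, path, chains, kind, resolution, superfamily, partners.

    ``chains`` and ``partners`` are comma-separated; ``-`` means
    none/all.  Lines beginning with ``#`` are comments.
    """
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[:2] == ["id", "path"]:
            continue  # header row
        if len(fields) < 6:
            raise ValueError(f"manifest line needs >= 6 columns: {line!r}")
        chains = tuple(c for c in fields[2].split(",") if c and c != "-")
        partners = frozenset()
        if len(fields) >= 7 and fields[6] and fields[6] != "-":
            partners = frozenset(p for p in fields[6].split(",") if p)
        entries.append(ManifestEntry(
            entry_id=fields[0], path=fields[1], chains=chains, kind=fields[3],
            resolution=float(fields[4]), superfamily=fields[5], partners=partners))
    return TrainingManifest(entries)


def write_manifest(manifest: TrainingManifest) -> str:
    lines = ["\t".join(MANIFEST_COLUMNS)]
    for e in manifest.entries:
        lines.append("\t".join([
            e.entry_id, e.path, ",".join(e.chains) or "-", e.kind,
            f"{e.resolution:g}", e.superfamily, ",".join(sorted(e.partners)) or "-",
        ]))
    return "\n".join(lines) + "\n"


def cross_validation_exclusions(manifest: TrainingManifest, target_id: str) -> set[str]:
    """Entry ids to drop when the target is ``target_id``.

    Excludes the target itself, anything sharing its superfamily label,
    and anything listed (in either direction) as a >25% identity
    partner.
    """
    target = manifest.by_id(target_id)
    excluded = {target_id}
    for e in manifest.entries:
        if e.entry_id == target_id:
            continue
        if e.superfamily == target.superfamily:
            excluded.add(e.entry_id)
        elif e.entry_id in target.partners or target_id in e.partners:
            excluded.add(e.entry_id)
    return excluded


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def count_structure(s: Structure, grid: SliceGrid = DEFAULT_GRID,
                    chains: Sequence[str] | None = None) -> np.ndarray:
    """Raw (20, n_slices) slice-occupancy counts for one pre-oriented structure."""
    counts = np.zeros((len(AA_ORDER), grid.n_slices), dtype=np.int64)
    for centre in scoring_centres(s, chains=chains):
        idx = slice_index(float(centre.position[2]), grid)
        if idx != OUTSIDE:
            counts[AA_INDEX[centre.aa], idx] += 1
    return counts


def train_from_structures(structures: Iterable[Structure | tuple[Structure, Sequence[str] | None]],
                          grid: SliceGrid = DEFAULT_GRID, meta: dict | None = None,
                          pseudocount_all: bool = False) -> PotentialTable:
    """Train directly from in-memory pre-oriented structures."""
    counts = np.zeros((len(AA_ORDER), grid.n_slices), dtype=np.int64)
    n = 0
    for item in structures:
        if isinstance(item, tuple):
            s, chains = item
        else:
            s, chains = item, None
        counts += count_structure(s, grid, chains)
        n += 1
    if n == 0:
        raise TrainingError("empty training set")
    meta = dict(meta or {})
    meta.setdefault("n_structures", n)
    return PotentialTable.from_counts(counts, grid, meta, pseudocount_all)


def train_potential(manifest: TrainingManifest, exclusions: Iterable[str] = (),
                    grid: SliceGrid = DEFAULT_GRID, kind: str | None = None,
                    max_resolution: float = 3.5, pseudocount_all: bool = False,
                    base_dir: str | Path | None = None) -> PotentialTable:
    """Train the potential from a manifest of pre-oriented PDB files.

    Entries in ``exclusions``, of the wrong ``kind`` or above the
    resolution cutoff are dropped; unreadable files are skipped with a
    warning.
    """
    excluded = set(exclusions)
    base = Path(base_dir) if base_dir else None
    counts = np.zeros((len(AA_ORDER), grid.n_slices), dtype=np.int64)
    used: list[str] = []
    for entry in manifest.entries:
        if entry.entry_id in excluded:
            continue
        if kind is not None and entry.kind != kind:
            continue
        if entry.resolution > max_resolution:
            continue
        path = Path(entry.path)
        if base and not path.is_absolute():
            path = base / path
        try:
            s = read_structure(path.read_text(), structure_id=entry.entry_id)
            counts += count_structure(s, grid, entry.chains or None)
        except (OSError, ValueError) as exc:
            logger.warning("skipping training entry %s: %s", entry.entry_id, exc)
            continue
        used.append(entry.entry_id)
    if not used:
        raise TrainingError("empty training set after filtering")
    meta = {"kind": kind or "alpha", "resolution": max_resolution,
            "n_structures": len(used), "entries": used}
    return PotentialTable.from_counts(counts, grid, meta, pseudocount_all)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def residue_energy(p: PotentialTable, aa: str, z: float) -> float:
    """Pseudo-energy of residue type ``aa`` at depth ``z`` (0 outside the slab)."""
    if aa not in AA_INDEX:
        raise ValueError(f"unknown amino acid code {aa!r}")
    idx = slice_index(z, p.grid)
    if idx == OUTSIDE:
        return 0.0
    return float(p.energy[AA_INDEX[aa], idx])


def centre_arrays(centres: Sequence[ScoringCentre]) -> tuple[np.ndarray, np.ndarray]:
    """(aa index vector, (N, 3) coordinate array) for fast scoring."""
    if not centres:
        raise ValueError("need at least one scoring centre")
    aa_idx = np.array([AA_INDEX[c.aa] for c in centres], dtype=np.int64)
    coords = np.array([c.position for c in centres], dtype=float)
    return aa_idx, coords


def structure_energy(p: PotentialTable, centres: Sequence[ScoringCentre],
                     t: Transform = IDENTITY) -> float:
    """Sum of per-residue pseudo-energies under pose ``t``."""
    aa_idx, coords = centre_arrays(centres)
    z = apply_transform(coords, t)[:, 2]
    idx, inside = slice_indices(z, p.grid)
    e = p.energy[aa_idx, np.where(inside, idx, 0)]
    return float(np.where(inside, e, 0.0).sum())


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def save_potential(p: PotentialTable) -> str:
    """Plain-text serialisation: header lines, counts block, energies block."""
    lines = [
        f"#kind {p.meta.get('kind', 'alpha')}",
        f"#grid {p.grid.n_slices} {p.grid.slice_width:g}",
        f"#resolution {p.meta.get('resolution', 3.5):g}",
        f"#structures {p.meta.get('n_structures', 0)}",
        "#counts",
    ]
    for row in p.counts:
        lines.append(" ".join(str(int(v)) for v in row))
    lines.append("#energies")
    for row in p.energy:
        lines.append(" ".join(f"{v:.12e}" for v in row))
    return "\n".join(lines) + "\n"


def load_potential(text: str) -> PotentialTable:
    """Inverse of :func:`save_potential`.

    Energies are recomputed from the stored counts and checked against
    the stored energy block; a mismatch (edited counts, truncation)
    raises ``ValueError``.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    meta: dict = {}
    grid = DEFAULT_GRID
    i = 0
    while i < len(lines) and lines[i].startswith("#") and lines[i] != "#counts":
        key, _, value = lines[i][1:].partition(" ")
        if key == "kind":
            meta["kind"] = value.strip()
        elif key == "grid":
            n_slices, width = value.split()
            n_slices, width = int(n_slices), float(width)
            grid = SliceGrid(half_thickness=n_slices * width / 2.0,
                             n_slices=n_slices, slice_width=width)
        elif key == "resolution":
            meta["resolution"] = float(value)
        elif key == "structures":
            meta["n_structures"] = int(value)
        i += 1
    if i >= len(lines) or lines[i] != "#counts":
        raise ValueError("potential file missing #counts block")
    i += 1
    count_rows = lines[i:i + len(AA_ORDER)]
    if len(count_rows) < len(AA_ORDER):
        raise ValueError("potential file truncated in counts block")
    try:
        counts = np.array([[int(v) for v in row.split()] for row in count_rows])
    except ValueError as exc:
        raise ValueError(f"bad counts block: {exc}") from exc
    if counts.shape != (len(AA_ORDER), grid.n_slices):
        raise ValueError("counts block has wrong shape")
    i += len(AA_ORDER)
    if i >= len(lines) or lines[i] != "#energies":
        raise ValueError("potential file missing #energies block")
    i += 1
    energy_rows = lines[i:i + len(AA_ORDER)]
    if len(energy_rows) < len(AA_ORDER):
        raise ValueError("potential file truncated in energies block")
    stored = np.array([[float(v) for v in row.split()] for row in energy_rows])
    if stored.shape != (len(AA_ORDER), grid.n_slices):
        raise ValueError("energies block has wrong shape")
    table = PotentialTable.from_counts(counts, grid, meta)
    if not np.allclose(table.energy, stored, atol=1e-9, rtol=0):
        raise ValueError("stored energies do not match energies recomputed from counts")
    return table
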