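"""Orientation evaluation: tilt angles, z-shifts, naive baselines,
reference comparisons and lipid-vector checks."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .geometry import Transform
from .structure_io import Structure, scoring_centres

logger = logging.getLogger(__name__)

__all__ = [
    "TopologySegment",
    "TopologyAnnotation",
    "OrientationComparison",
    "DegenerateAxisError",
    "parse_topology",
    "format_topology",
    "longitudinal_axis",
    "tilt_angle",
    "mean_segment_tilt",
    "z_shift",
    "naive_orient",
    "compare_orientations",
    "lipid_vector_tilt",
]

SENSE_IN_OUT = "in-out"
SENSE_OUT_IN = "out-in"


class DegenerateAxisError(ValueError):
    """Raised when transmembrane segment vectors average to ~zero."""


@dataclass(frozen=True)
class TopologySegment:
    chain_id: str
    start: int
    end: int
    sense: str  # SENSE_IN_OUT or SENSE_OUT_IN

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must precede end")
        if self.sense not in (SENSE_IN_OUT, SENSE_OUT_IN):
            raise ValueError(f"unknown sense {self.sense!r}")


@dataclass
class TopologyAnnotation:
    segments: list[TopologySegment]

    def __post_init__(self) -> None:
        per_chain: dict[str, list[TopologySegment]] = {}
        for seg in self.segments:
            per_chain.setdefault(seg.chain_id, []).append(seg)
        for segs in per_chain.values():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError("segments overlap within a chain")


def parse_topology(text: str) -> TopologyAnnotation:
    """Parse a TSV topology file: ``chain  start  end  [sense]``.

    When the sense column is absent, segments alternate starting in-out
    within each chain.
    """
    rows: list[tuple[str, int, int, str | None]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"topology line needs >= 3 columns: {line!r}")
        sense = fields[3].lower() if len(fields) > 3 else None
        if sense is not None and sense not in (SENSE_IN_OUT, SENSE_OUT_IN):
            raise ValueError(f"unknown sense {sense!r}")
        rows.append((fields[0], int(fields[1]), int(fields[2]), sense))

    per_chain_count: dict[str, int] = {}
    segments = []
    for chain, start, end, sense in rows:
        if sense is None:
            k = per_chain_count.get(chain, 0)
            sense = SENSE_IN_OUT if k % 2 == 0 else SENSE_OUT_IN
            logger.info("topology sense missing for %s %d-%d; assuming %s",
                        chain, start, end, sense)
        per_chain_count[chain] = per_chain_count.get(chain, 0) + 1
        segments.append(TopologySegment(chain, start, end, sense))
    return TopologyAnnotation(segments)


def format_topology(topo: TopologyAnnotation) -> str:
    lines = ["#chain\tstart\tend\tsense"]
    for seg in topo.segments:
        lines.append(f"{seg.chain_id}\t{seg.start}\t{seg.end}\t{seg.sense}")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class OrientationComparison:
    tilt_delta: float  # degrees, in [0, 90]
    z_delta: float  # Angstroms, >= 0
    within_error: bool


def _centre_map(s: Structure) -> dict[tuple[str, int], np.ndarray]:
    return {(c.chain_id, c.res_seq): c.position for c in scoring_centres(s)}


def _segment_vectors(s: Structure, topo: TopologyAnnotation,
                     apply_sense: bool) -> list[np.ndarray]:
    centres = _centre_map(s)
    vectors = []
    for seg in topo.segments:
        start = centres.get((seg.chain_id, seg.start))
        end = centres.get((seg.chain_id, seg.end))
        if start is None or end is None:
            logger.warning("segment %s %d-%d missing boundary residue; skipped",
                           seg.chain_id, seg.start, seg.end)
            continue
        v = end - start
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            continue
        v = v / norm
        if apply_sense and seg.sense == SENSE_OUT_IN:
            v = -v
        vectors.append(v)
    if not vectors:
        raise ValueError("no usable transmembrane segments")
    return vectors


def longitudinal_axis(s: Structure, topo: TopologyAnnotation) -> np.ndarray:
    """Unit vector average of all transmembrane segment vectors, each
    flipped so it points in the in -> out (+z, in the reference frame)
    direction."""
    mean = np.mean(_segment_vectors(s, topo, apply_sense=True), axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-9:
        raise DegenerateAxisError("segment vectors cancel; degenerate axis")
    return mean / norm


def tilt_angle(axis: np.ndarray) -> float:
    """Angle between ``axis`` and the membrane normal, folded to [0, 90] degrees."""
    axis = np.asarray(axis, dtype=float)
    cos = abs(axis[2]) / np.linalg.norm(axis)
    return math.degrees(math.acos(min(1.0, max(-1.0, cos))))


def mean_segment_tilt(s: Structure, topo: TopologyAnnotation) -> float:
    """Mean absolute tilt over individual transmembrane segments."""
    vectors = _segment_vectors(s, topo, apply_sense=False)
    return float(np.mean([tilt_angle(v) for v in vectors]))


def z_shift(s: Structure, topo: TopologyAnnotation) -> float:
    """Mean z of the scoring centres of all segment boundary residues."""
    centres = _centre_map(s)
    zs = []
    for seg in topo.segments:
        for res in (seg.start, seg.end):
            pos = centres.get((seg.chain_id, res))
            if pos is None:
                logger.warning("boundary residue %s%d missing; skipped", seg.chain_id, res)
                continue
            zs.append(float(pos[2]))
    if not zs:
        raise ValueError("no usable boundary residues")
    return float(np.mean(zs))


def naive_orient(s: Structure, topo: TopologyAnnotation) -> Transform:
    """Rotation mapping the longitudinal axis onto +z, then a translation
    putting the mean boundary z at zero."""
    ax, ay, az = longitudinal_axis(s, topo)
    r = math.hypot(ay, az)
    rot_x = math.degrees(math.atan2(ay, az)) if r > 1e-12 else 0.0
    rot_y = math.degrees(math.atan2(-ax, r))
    rotation = Transform(rot_x, rot_y, 0.0)
    from .structure_io import transform_structure

    rotated = transform_structure(s, rotation)
    return Transform(rot_x, rot_y, -z_shift(rotated, topo))


def compare_orientations(test: Structure, ref: Structure, topo: TopologyAnnotation,
                         ref_error: tuple[float, float]) -> OrientationComparison:
    """Tilt and z deltas between a test and reference orientation of the
    same structure, with a within-published-error verdict."""
    key = lambda s: sorted((r.chain_id, r.res_seq, r.res_name) for r in s.residues())
    if key(test) != key(ref):
        raise ValueError("test and reference structures have different residue content")
    a = longitudinal_axis(test, topo)
    b = longitudinal_axis(ref, topo)
    cos = abs(float(np.dot(a, b)))
    tilt_delta = math.degrees(math.acos(min(1.0, cos)))
    z_delta = abs(z_shift(test, topo) - z_shift(ref, topo))
    tilt_err, z_err = ref_error
    return OrientationComparison(tilt_delta=tilt_delta, z_delta=z_delta,
                                 within_error=(tilt_delta <= tilt_err and z_delta <= z_err))


def _is_carbon(atom) -> bool:
    if atom.element:
        return atom.element.upper() == "C"
    name = atom.name.strip()
    return bool(name) and name[0] == "C" and not name.startswith("CL")


def lipid_vector_tilt(s: Structure, leaflet: str = "lower") -> float:
    """Tilt of the average lipid vector in a leaflet.

    Each hetero lipid molecule with at least two carbons contributes the
    unit vector from its first to its last carbon atom in record order;
    the leaflet is assigned from the molecule's mean z (< 0 = lower).
    """
    if leaflet not in ("upper", "lower"):
        raise ValueError("leaflet must be 'upper' or 'lower'")
    vectors = []
    for mol in s.het_molecules:
        if mol.res_name in ("HOH", "WAT"):
            continue
        mean_z = float(np.mean([a.z for a in mol.atoms]))
        if (leaflet == "lower") != (mean_z < 0):
            continue
        carbons = [a for a in mol.atoms if _is_carbon(a)]
        if len(carbons) < 2:
            continue
        v = carbons[-1].position - carbons[0].position
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            continue
        vectors.append(v / norm)
    if not vectors:
        raise ValueError(f"no lipid molecules with >= 2 carbons in {leaflet} leaflet")
    mean = np.mean(vectors, axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-9:
        raise DegenerateAxisError("lipid vectors cancel")
    return tilt_angle(mean / norm)
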