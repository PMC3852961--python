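"""Hydrophobic thickness estimation via a split head-group potential.

The two head-group windows of the potential (10 <= |z| <= 20 at rest)
are translated independently along z.  Residues inside a shifted window
are scored with the depth potential at the back-shifted depth, residues
between the windows receive their type's core average and residues
beyond them the extra-membranous average.  The offset pair minimising
the total energy yields the thickness estimate: the standard 30 A
(window midpoints at +/-15) plus the two outward offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .potential import PotentialTable, centre_arrays, slice_indices
from .structure_io import ScoringCentre, Structure, scoring_centres

__all__ = ["ThicknessResult", "split_energy", "estimate_thickness",
           "STANDARD_THICKNESS", "HEADGROUP_INNER", "HEADGROUP_OUTER"]

STANDARD_THICKNESS = 30.0
HEADGROUP_INNER = 10.0
HEADGROUP_OUTER = 20.0


@dataclass(frozen=True)
class ThicknessResult:
    thickness: float
    offset_upper: float  # signed; positive = outward (+z)
    offset_lower: float  # signed; positive = outward (-z)
    energy: float

    def __post_init__(self) -> None:
        expected = STANDARD_THICKNESS + self.offset_upper + self.offset_lower
        if abs(self.thickness - expected) > 1e-9 or self.thickness <= 0:
            raise ValueError("thickness must equal 30 + offset_upper + offset_lower and be positive")


def _split_energy_arrays(table: PotentialTable, aa_idx: np.ndarray, z: np.ndarray,
                         offset_upper: float, offset_lower: float) -> float:
    up_lo, up_hi = HEADGROUP_INNER + offset_upper, HEADGROUP_OUTER + offset_upper
    lo_hi, lo_lo = -HEADGROUP_INNER - offset_lower, -HEADGROUP_OUTER - offset_lower
    in_upper = (z >= up_lo) & (z <= up_hi)
    in_lower = (z >= lo_lo) & (z <= lo_hi)
    between = (~in_upper) & (~in_lower) & (z > lo_hi) & (z < up_lo)

    total = 0.0
    if np.any(in_upper):
        zi = z[in_upper] - offset_upper
        idx, inside = slice_indices(zi, table.grid)
        e = table.energy[aa_idx[in_upper], np.where(inside, idx, 0)]
        total += float(np.where(inside, e, 0.0).sum())
    if np.any(in_lower):
        zi = z[in_lower] + offset_lower
        idx, inside = slice_indices(zi, table.grid)
        e = table.energy[aa_idx[in_lower], np.where(inside, idx, 0)]
        total += float(np.where(inside, e, 0.0).sum())
    total += float(table.core_avg[aa_idx[between]].sum())
    outside = (~in_upper) & (~in_lower) & (~between)
    total += float(table.extramem_avg[aa_idx[outside]].sum())
    return total


def split_energy(table: PotentialTable, centres: Sequence[ScoringCentre],
                 offset_upper: float, offset_lower: float,
                 max_offset: float = 8.0) -> float:
    """Total pseudo-energy with the head-group windows shifted outward by
    ``offset_upper`` (+z leaflet) and ``offset_lower`` (-z leaflet)."""
    if abs(offset_upper) > max_offset or abs(offset_lower) > max_offset:
        raise ValueError(f"offsets must lie within +/-{max_offset} A")
    aa_idx, coords = centre_arrays(centres)
    return _split_energy_arrays(table, aa_idx, coords[:, 2], offset_upper, offset_lower)


def estimate_thickness(table: PotentialTable,
                       structure: Structure | Sequence[ScoringCentre],
                       step: float = 0.25, scan_range: float = 8.0) -> ThicknessResult:
    """Exhaustive scan of leaflet offsets on a ``step`` grid over
    ``+/-scan_range``; ties prefer the smallest total |offset|, then
    lexicographic (offset_upper, offset_lower) order."""
    if isinstance(structure, Structure):
        centres = scoring_centres(structure)
    else:
        centres = list(structure)
    aa_idx, coords = centre_arrays(centres)
    z = coords[:, 2]

    n = int(round(scan_range / step))
    offsets = np.arange(-n, n + 1) * step

    best: tuple[float, float, float, float] | None = None  # (e, |sum|, ou, ol)
    for ou in offsets:
        for ol in offsets:
            e = _split_energy_arrays(table, aa_idx, z, float(ou), float(ol))
            key = (e, abs(ou) + abs(ol), ou, ol)
            if best is None or key < best:
                best = key
    assert best is not None
    e, _, ou, ol = best
    return ThicknessResult(thickness=STANDARD_THICKNESS + ou + ol,
                           offset_upper=float(ou), offset_lower=float(ol),
                           energy=float(e))
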