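"""Idealised pre-oriented transmembrane fixtures.

Generates helix bundles whose residue identities are drawn from a
controlled depth distribution, so training, orientation, thickness and
decoy workflows can be exercised end to end without any external data.
Geometry is deliberately schematic: a C-alpha trace with the canonical
1.5 A rise per residue, C-beta placed radially at the same z as its
C-alpha, and the per-residue twist snapped so that a helix's two ends
are exactly in phase (which makes segment vectors exactly axial and
tilt/z-shift recovery checks exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import SENSE_IN_OUT, SENSE_OUT_IN, TopologyAnnotation, TopologySegment
from .geometry import Transform
from .potential import (
    AA_INDEX,
    AA_ORDER,
    DEFAULT_GRID,
    ManifestEntry,
    SliceGrid,
    TrainingManifest,
)
from .structure_io import (
    AA_1TO3,
    AtomRecord,
    Residue,
    Structure,
    scoring_centres,
    transform_structure,
    write_structure,
)

__all__ = [
    "HELIX_RISE",
    "STRAND_RISE",
    "DepthDistributionSpec",
    "SyntheticBundleSpec",
    "build_ideal_helix",
    "build_bundle",
    "sample_structures",
    "sample_training_set",
    "make_decoy_ensemble",
]

HELIX_RISE = 1.5  # A per residue along the helix axis
STRAND_RISE = 3.5  # A per residue for beta strands
HELIX_RADIUS = 2.3
CB_RADIAL_OFFSET = 1.2
BASE_TWIST = 100.0  # degrees per residue before phase snapping

HYDROPHOBIC = "AFILMV"
AROMATIC_INTERFACE = "WY"
POSITIVE = "KR"
NEGATIVE = "DE"


@dataclass
class DepthDistributionSpec:
    """Per-type enrichment over the depth slices used to sample residue
    identities (and, transitively, what a trained potential encodes)."""

    profile: np.ndarray  # (20, n_slices), positive enrichment factors
    background: np.ndarray  # (20,) composition
    noise: float = 0.0  # blend fraction of depth-independent background
    grid: SliceGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.profile.shape != (len(AA_ORDER), self.grid.n_slices):
            raise ValueError("profile must be (20, n_slices)")
        if np.any(self.profile <= 0) or np.any(self.background <= 0):
            raise ValueError("profile and background must be positive")
        if not (0.0 <= self.noise < 1.0):
            raise ValueError("noise must be in [0, 1)")

    def type_probabilities(self, slice_idx: int) -> np.ndarray:
        """P(type | slice), the distribution residues are sampled from."""
        w = self.background * self.profile[:, slice_idx]
        p = w / w.sum()
        if self.noise:
            bg = self.background / self.background.sum()
            p = (1.0 - self.noise) * p + self.noise * bg
        return p

    @classmethod
    def default_alpha(cls, core_half_width: float = 15.0,
                      grid: SliceGrid = DEFAULT_GRID, noise: float = 0.0
                      ) -> "DepthDistributionSpec":
        """Qualitative alpha-helical biology: hydrophobic core, interfacial
        aromatics, charged/polar outside, and a positive-inside bias that
        makes the potential z-asymmetric.

        ``core_half_width`` is half the hydrophobic belt width; the
        head-group bands sit within 5 A either side of it (so the default
        15 A reproduces the standard 30 A core with heads at 10-20 A).
        """
        zc = grid.centres()
        core = np.abs(zc) < core_half_width - 5.0
        head = (np.abs(zc) >= core_half_width - 5.0) & (np.abs(zc) < core_half_width + 5.0)
        outer = np.abs(zc) >= core_half_width + 5.0
        lower = zc < 0

        profile = np.ones((len(AA_ORDER), grid.n_slices))
        for aa in HYDROPHOBIC:
            profile[AA_INDEX[aa]] = np.select([core, head, outer], [25.0, 3.0, 0.2])
        for aa in AROMATIC_INTERFACE:
            profile[AA_INDEX[aa]] = np.select([core, head, outer], [1.0, 15.0, 0.5])
        for aa in NEGATIVE:
            profile[AA_INDEX[aa]] = np.select([core, head, outer], [0.05, 1.0, 12.0])
        # Positive-inside asymmetry lives in the head-group band only: the
        # extra-membranous zone stays z-symmetric so that the per-type
        # extramembranous average (taken over both leaflets) is unbiased.
        for aa in POSITIVE:
            profile[AA_INDEX[aa]] = np.select(
                [core, head & lower, head & ~lower, outer],
                [0.05, 15.0, 1.0, 2.0])
        for aa in "NQSTHCGP":
            profile[AA_INDEX[aa]] = np.select([core, head, outer], [0.2, 1.0, 6.0])

        background = np.full(len(AA_ORDER), 1.0 / len(AA_ORDER))
        return cls(profile=profile, background=background, noise=noise, grid=grid)


@dataclass(frozen=True)
class SyntheticBundleSpec:
    n_helices: int = 5
    residues_per_helix: int = 33
    rise: float = HELIX_RISE
    bundle_radius: float = 8.0
    tilt: float = 0.0  # degrees from the membrane normal
    z_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.residues_per_helix < 5:
            raise ValueError("need >= 1 helix of >= 5 residues")
        if self.rise <= 0:
            raise ValueError("rise must be positive")


def _snapped_twist(n_residues: int) -> float:
    turns = max(1, round(BASE_TWIST * (n_residues - 1) / 360.0))
    return 360.0 * turns / (n_residues - 1)


def _helix_trace(n: int, rise: float) -> tuple[np.ndarray, np.ndarray]:
    """(CA, CB) coordinate arrays for an axis-aligned helix centred at the
    origin, built so the first and last residues share a helical phase
    at x = 0."""
    twist = np.deg2rad(_snapped_twist(n))
    phase = np.pi / 2.0 + twist * np.arange(n)
    z = (np.arange(n) - (n - 1) / 2.0) * rise
    ca = np.stack([HELIX_RADIUS * np.cos(phase), HELIX_RADIUS * np.sin(phase), z], axis=1)
    r_cb = HELIX_RADIUS + CB_RADIAL_OFFSET
    cb = np.stack([r_cb * np.cos(phase), r_cb * np.sin(phase), z], axis=1)
    return ca, cb


def _make_residue(chain_id: str, res_seq: int, aa: str, ca: np.ndarray,
                  cb: np.ndarray, serial: int) -> Residue:
    res_name = AA_1TO3[aa]
    atoms = [AtomRecord(serial, "CA", " ", res_name, chain_id, res_seq, " ",
                        float(ca[0]), float(ca[1]), float(ca[2]), "C")]
    if aa != "G":
        atoms.append(AtomRecord(serial + 1, "CB", " ", res_name, chain_id, res_seq, " ",
                                float(cb[0]), float(cb[1]), float(cb[2]), "C"))
    return Residue(chain_id, res_seq, " ", res_name, atoms)


def build_ideal_helix(sequence: str, tilt: float = 0.0, z_offset: float = 0.0,
                      chain_id: str = "A", rise: float = HELIX_RISE,
                      structure_id: str = "helix") -> tuple[Structure, TopologyAnnotation]:
    """Single ideal transmembrane helix tilted by ``tilt`` degrees from z
    and shifted by ``z_offset``; topology is one in->out segment."""
    n = len(sequence)
    if n < 5:
        raise ValueError("sequence must have >= 5 residues")
    for aa in sequence:
        if aa not in AA_1TO3:
            raise ValueError(f"unknown amino acid {aa!r}")
    ca, cb = _helix_trace(n, rise)
    residues = []
    serial = 1
    for i, aa in enumerate(sequence):
        residues.append(_make_residue(chain_id, i + 1, aa, ca[i], cb[i], serial))
        serial += 2
    structure = Structure(id=structure_id, chains=[residues])
    structure = transform_structure(structure, Transform(0.0, tilt, z_offset))
    topo = TopologyAnnotation([TopologySegment(chain_id, 1, n, SENSE_IN_OUT)])
    return structure, topo


def build_bundle(spec: SyntheticBundleSpec, sequence_source=None,
                 structure_id: str = "bundle") -> tuple[Structure, TopologyAnnotation]:
    """Antiparallel helix bundle on a circle of ``bundle_radius``.

    ``sequence_source`` is a callable mapping an (n_residues,) array of
    scoring-centre depths to a sequence string; defaults to poly-leucine.
    Helices alternate direction, so segment senses alternate in->out /
    out->in.
    """
    n = spec.residues_per_helix
    ca0, cb0 = _helix_trace(n, spec.rise)
    chains = []
    segments = []
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if spec.n_helices > len(chain_ids):
        raise ValueError("too many helices")
    # Deterministic zero-mean z stagger per helix (golden-ratio sequence):
    # spreads residue depths continuously over the slice period instead of
    # leaving them all on multiples of the rise, which would quantise the
    # energy landscape.  Zero mean keeps the bundle z-shift exact.
    stagger = spec.rise * ((np.arange(spec.n_helices) * 0.618033988749895) % 1.0)
    stagger -= stagger.mean()
    for h in range(spec.n_helices):
        angle = 2.0 * np.pi * h / spec.n_helices
        offset = np.array([spec.bundle_radius * np.cos(angle),
                           spec.bundle_radius * np.sin(angle), stagger[h]])
        flip = h % 2 == 1
        ca, cb = ca0.copy(), cb0.copy()
        if flip:  # rotate 180 deg about x: antiparallel helix
            ca[:, 1:] *= -1.0
            cb[:, 1:] *= -1.0
        ca += offset
        cb += offset
        depths = cb[:, 2]
        seq = ("L" * n) if sequence_source is None else sequence_source(depths)
        cid = chain_ids[h]
        residues = [
            _make_residue(cid, i + 1, seq[i], ca[i], cb[i], 1 + 2 * (h * n + i))
            for i in range(n)
        ]
        chains.append(residues)
        segments.append(TopologySegment(cid, 1, n, SENSE_OUT_IN if flip else SENSE_IN_OUT))
    structure = Structure(id=structure_id, chains=chains)
    structure = transform_structure(structure, Transform(0.0, spec.tilt, spec.z_offset))
    return structure, TopologyAnnotation(segments)


def _depth_sampler(dist: DepthDistributionSpec, rng: np.random.Generator):
    aa = np.array(list(AA_ORDER))

    def sample(depths: np.ndarray) -> str:
        idx = np.floor((depths + dist.grid.half_thickness) / dist.grid.slice_width)
        idx = np.clip(idx, 0, dist.grid.n_slices - 1).astype(int)
        out = []
        for s in idx:
            out.append(rng.choice(aa, p=dist.type_probabilities(int(s))))
        return "".join(out)

    return sample


def sample_structures(dist: DepthDistributionSpec, n_structures: int, seed: int,
                      n_helices: int = 5, residues_per_helix: int = 33,
                      bundle_radius: float = 8.0, tilt: float = 0.0,
                      z_offset: float = 0.0
                      ) -> list[tuple[Structure, TopologyAnnotation]]:
    """Pre-oriented bundles with residue types sampled from ``dist`` at
    each residue's actual scoring-centre depth.

    Residue types are assigned in the *final* (tilted/shifted) frame, so
    a bundle built at tilt theta has its energy optimum at that pose.
    """
    if n_structures < 1:
        raise ValueError("need >= 1 structure")
    root = np.random.SeedSequence(seed)
    out = []
    for k, child in enumerate(root.spawn(n_structures)):
        rng = np.random.default_rng(child)
        spec = SyntheticBundleSpec(n_helices=n_helices,
                                   residues_per_helix=residues_per_helix,
                                   bundle_radius=bundle_radius, tilt=tilt,
                                   z_offset=z_offset)
        # build geometry first, then type residues by final depth
        structure, topo = build_bundle(spec, sequence_source=None,
                                       structure_id=f"syn_{k:03d}")
        sampler = _depth_sampler(dist, rng)
        structure = _retype(structure, sampler)
        out.append((structure, topo))
    return out


def _retype(structure: Structure, sampler) -> Structure:
    centres = scoring_centres(structure)
    depths = np.array([c.position[2] for c in centres])
    seq = sampler(depths)
    return _rename_residues(structure, {(c.chain_id, c.res_seq): aa
                                        for c, aa in zip(centres, seq)})


def _rename_residues(structure: Structure, names: dict[tuple[str, int], str]) -> Structure:
    chains = []
    for chain in structure.chains:
        new_chain = []
        for res in chain:
            aa = names.get((res.chain_id, res.res_seq))
            if aa is None:
                new_chain.append(res)
                continue
            res_name = AA_1TO3[aa]
            atoms = [a for a in res.atoms if not (aa == "G" and a.name == "CB")]
            new_chain.append(Residue(res.chain_id, res.res_seq, res.i_code, res_name, atoms))
        chains.append(new_chain)
    return Structure(id=structure.id, chains=chains,
                     het_molecules=structure.het_molecules)


def sample_training_set(dist: DepthDistributionSpec, n_structures: int, seed: int,
                        out_dir: str | Path, kind: str = "alpha",
                        **bundle_kwargs) -> TrainingManifest:
    """Write a reproducible set of pre-oriented bundles plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for structure, _ in sample_structures(dist, n_structures, seed, **bundle_kwargs):
        path = out / f"{structure.id}.pdb"
        path.write_text(write_structure(structure))
        entries.append(ManifestEntry(
            entry_id=structure.id, path=str(path), chains=(), kind=kind,
            resolution=2.0, superfamily=f"SYN_{structure.id}"))
    return TrainingManifest(entries)


def make_decoy_ensemble(dist: DepthDistributionSpec, n_decoys: int,
                        scramble_fractions, seed: int,
                        n_helices: int = 4, residues_per_helix: int = 33,
                        bundle_radius: float = 8.0
                        ) -> list[tuple[str, Structure, float]]:
    """Native bundle plus depth-scrambled decoys.

    Decoy ``i`` has a fraction ``scramble_fractions[i % len]`` of its
    residue identities permuted across positions, destroying the
    depth/type correlation while leaving geometry untouched; its quality
    pseudo-score is ``1 - fraction``.
    """
    if n_decoys < 2:
        raise ValueError("need >= 2 decoys")
    fractions = list(np.atleast_1d(np.asarray(scramble_fractions, dtype=float)))
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("scramble fractions must be in [0, 1]")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_decoys + 1)
    rng_native = np.random.default_rng(children[0])
    spec = SyntheticBundleSpec(n_helices=n_helices,
                               residues_per_helix=residues_per_helix,
                               bundle_radius=bundle_radius)
    native, _ = build_bundle(spec, structure_id="native")
    native = _retype(native, _depth_sampler(dist, rng_native))

    centres = scoring_centres(native)
    keys = [(c.chain_id, c.res_seq) for c in centres]
    aas = [c.aa for c in centres]

    ensemble = [("native", native, 1.0)]
    for i in range(n_decoys):
        rng = np.random.default_rng(children[i + 1])
        f = fractions[i % len(fractions)]
        m = int(round(f * len(keys)))
        names = dict(zip(keys, aas))
        if m >= 2:
            chosen = rng.choice(len(keys), size=m, replace=False)
            perm = rng.permutation(chosen)
            for src, dst in zip(chosen, perm):
                names[keys[dst]] = aas[src]
        decoy = _rename_residues(native, names)
        decoy.id = f"decoy_{i:03d}"
        ensemble.append((decoy.id, decoy, 1.0 - f))
    return ensemble


def write_decoy_ensemble(ensemble, out_dir: str | Path) -> Path:
    """Write ensemble PDBs and a ``model_path  e_contact  tm_score`` manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = []
    for model_id, structure, tm in ensemble:
        path = out / f"{model_id}.pdb"
        path.write_text(write_structure(structure))
        lines.append(f"{path}\t-\t{tm:.4f}")
    manifest = out / "decoys.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
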