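"""Synthetic structures, PAE matrices and PTM tables for desk-scale analysis.

The generator emulates the geometry classes that matter for exposure and
disorder statistics, not protein physics:

* ``helix`` — ideal alpha-helix CA trace (2.3 A radius, 1.5 A rise and
  100 deg twist per residue, consecutive CA-CA about 3.8 A);
* ``coil``  — extended quasi-linear chain, exact 3.8 A steps with direction
  jitter, emulating a disordered linker;
* ``globule`` — compact arrangement: CA positions on a jittered 3.8 A-step
  space-filling (boustrophedon) grid curve inside a sphere sized to the
  chain's volume, giving folded-core neighbor counts without simulation.

Segments are laid out consecutively along +x with a 3.8 A gap so they never
overlap in space.  Each segment carries its own pLDDT level and PAE: the
block PAE matrix is ``intra_pae`` within a segment and the larger of the two
segments' ``inter_pae`` across segments, mirroring how AlphaFold assigns low
PAE inside folded domains and high PAE across flexibly linked ones.  N and C
backbone atoms are synthesized along the chain direction and CB atoms placed
by ideal tetrahedral geometry (glycines get no CB), which is all the
downstream exposure metric needs.

Sequences are drawn uniformly from the 20 canonical residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exposure import PPSEProfile, pseudo_cb
from .io import PAEMatrix, StructureRecord, write_pae, write_pdb

__all__ = [
    "SegmentSpec",
    "PTMSimSpec",
    "make_chimera",
    "standard_chimera",
    "simulate_ptm_sites",
    "write_fixture",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_CA_STEP = 3.8
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST_DEG = 100.0


@dataclass(frozen=True)
class SegmentSpec:
    """One structural segment of a synthetic chimera."""

    kind: str  # helix | coil | globule
    length: int
    plddt_level: float = 90.0
    intra_pae: float = 2.0
    inter_pae: float = 25.0

    def __post_init__(self) -> None:
        if self.kind not in ("helix", "coil", "globule"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if self.intra_pae > self.inter_pae:
            raise ValueError("intra_pae must be <= inter_pae")
        if not (0.0 <= self.plddt_level <= 100.0):
            raise ValueError("plddt_level must be in [0, 100]")


@dataclass(frozen=True)
class PTMSimSpec:
    """Exposure-dependent PTM placement, optionally with a 3D hotspot."""

    ptm_type: str = "p"
    acceptor_residues: frozenset[str] = frozenset({"S", "T", "Y"})
    p_modify_exposed: float = 0.5
    p_modify_buried: float = 0.1
    cluster_center: int | None = None  # 1-based residue position
    cluster_radius: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_modify_exposed, self.p_modify_buried):
            if not (0.0 <= p <= 1.0):
                raise ValueError("modification probabilities must be in [0, 1]")


def _helix_trace(length: int) -> np.ndarray:
    k = np.arange(length)
    theta = np.deg2rad(_HELIX_TWIST_DEG) * k
    return np.column_stack(
        [_HELIX_RISE * k, _HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta)]
    )


def _coil_trace(length: int, rng: np.random.Generator) -> np.ndarray:
    # unit steps mostly along +x with Gaussian transverse jitter
    steps = np.column_stack(
        [np.ones(length - 1), rng.normal(0.0, 0.15, length - 1),
         rng.normal(0.0, 0.15, length - 1)]
    ) if length > 1 else np.zeros((0, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True) if length > 1 else 1.0
    pts = np.vstack([[0.0, 0.0, 0.0], np.cumsum(_CA_STEP * steps, axis=0)])
    return pts


def _globule_trace(length: int, rng: np.random.Generator) -> np.ndarray:
    # snake through a 3.8 A grid restricted to a sphere holding >= length points
    s = _CA_STEP
    radius = s * max(1.0, (3.0 * length / (4.0 * np.pi)) ** (1.0 / 3.0))
    while True:
        m = int(np.ceil(radius / s))
        pts = []
        for iz, z in enumerate(range(-m, m + 1)):
            ys = range(-m, m + 1) if iz % 2 == 0 else range(m, -m - 1, -1)
            for iy, y in enumerate(ys):
                xs = range(-m, m + 1) if (iz + iy) % 2 == 0 else range(m, -m - 1, -1)
                for x in xs:
                    p = np.array([x, y, z], dtype=float) * s
                    if np.linalg.norm(p) <= radius:
                        pts.append(p)
        if len(pts) >= length:
            break
        radius *= 1.15
    pts = np.asarray(pts[:length])
    return pts + rng.normal(0.0, 0.25, pts.shape)


def _backbone_from_ca(ca: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize N and C atoms along the chain direction at each CA."""
    n_res = len(ca)
    if n_res == 1:
        prev_dir = np.array([[-1.0, 0.0, 0.0]])
        next_dir = np.array([[1.0, 0.0, 0.0]])
    else:
        diff = ca[1:] - ca[:-1]
        diff /= np.linalg.norm(diff, axis=1, keepdims=True)
        prev_dir = np.vstack([-diff[:1], -diff])  # toward previous residue
        next_dir = np.vstack([diff, diff[-1:]])  # toward next residue
    # tiny transverse perturbation keeps N-CA-C from being exactly collinear
    wob = rng.normal(0.0, 0.05, (n_res, 3))
    n_xyz = ca + 1.46 * (prev_dir + wob) / np.linalg.norm(prev_dir + wob, axis=1, keepdims=True)
    c_xyz = ca + 1.52 * (next_dir - wob) / np.linalg.norm(next_dir - wob, axis=1, keepdims=True)
    return n_xyz, c_xyz


def make_chimera(
    segments: Sequence[SegmentSpec],
    seed: int = 0,
    protein_id: str = "CHIMERA",
) -> tuple[StructureRecord, PAEMatrix]:
    """Build a multi-segment synthetic protein and its block PAE matrix.

    Deterministic for a fixed seed: one private RNG stream drives sequence,
    geometry jitter and backbone wobble.
    """
    if len(segments) == 0:
        raise ValueError("at least one segment is required")
    rng = np.random.default_rng(seed)
    traces = []
    offset_x = 0.0
    for seg in segments:
        if seg.kind == "helix":
            local = _helix_trace(seg.length)
        elif seg.kind == "coil":
            local = _coil_trace(seg.length, rng)
        else:
            local = _globule_trace(seg.length, rng)
        local = local - local.min(axis=0) * np.array([1.0, 0.0, 0.0])  # shift min x to 0
        local[:, 0] += offset_x
        offset_x = local[:, 0].max() + _CA_STEP
        traces.append(local)
    ca = np.vstack(traces)
    n_total = len(ca)
    sequence = "".join(rng.choice(AMINO_ACIDS, n_total))
    n_xyz, c_xyz = _backbone_from_ca(ca, rng)
    cb = pseudo_cb(n_xyz, ca, c_xyz)
    cb[np.array(list(sequence)) == "G"] = np.nan
    plddt = np.concatenate([np.full(s.length, s.plddt_level) for s in segments])

    seg_idx = np.concatenate([np.full(s.length, k) for k, s in enumerate(segments)])
    intra = np.array([s.intra_pae for s in segments])
    inter = np.array([s.inter_pae for s in segments])
    same = seg_idx[:, None] == seg_idx[None, :]
    pae = np.where(
        same,
        intra[seg_idx][:, None],
        np.maximum(inter[seg_idx][:, None], inter[seg_idx][None, :]),
    ).astype(float)
    np.fill_diagonal(pae, 0.0)

    structure = StructureRecord(
        protein_id=protein_id,
        sequence=sequence,
        n_xyz=n_xyz,
        ca_xyz=ca,
        c_xyz=c_xyz,
        cb_xyz=cb,
        plddt=plddt,
    )
    return structure, PAEMatrix(pae)


def standard_chimera(seed: int = 0, protein_id: str = "CHIMERA") -> tuple[StructureRecord, PAEMatrix]:
    """Two 100-residue folded domains linked by a 15-residue disordered coil.

    The coil carries high internal PAE (15 A), as AlphaFold assigns to
    disordered linkers; cross-segment PAE is 25 A, domain-internal PAE 2 A.
    """
    segments = [
        SegmentSpec("globule", 100, plddt_level=92.0, intra_pae=2.0, inter_pae=25.0),
        SegmentSpec("coil", 15, plddt_level=45.0, intra_pae=15.0, inter_pae=25.0),
        SegmentSpec("globule", 100, plddt_level=92.0, intra_pae=2.0, inter_pae=25.0),
    ]
    return make_chimera(segments, seed=seed, protein_id=protein_id)


def simulate_ptm_sites(
    structure: StructureRecord,
    ppse: PPSEProfile,
    spec: PTMSimSpec,
    exposure_cutoff: int = 5,
) -> pd.DataFrame:
    """Place modifications on acceptor residues with exposure-dependent rates.

    Each acceptor residue is modified independently with ``p_modify_exposed``
    when its raw pPSE is <= ``exposure_cutoff`` and ``p_modify_buried``
    otherwise.  When ``cluster_center`` is set, acceptors within
    ``cluster_radius`` (CA-CA) of the center get ``p_modify_exposed``
    regardless of exposure, emulating a 3D modification hotspot.
    """
    if len(ppse.raw) != len(structure):
        raise ValueError("pPSE profile length does not match structure")
    seq = np.array(list(structure.sequence))
    is_acceptor = np.isin(seq, list(spec.acceptor_residues))
    p = np.where(ppse.raw <= exposure_cutoff, spec.p_modify_exposed, spec.p_modify_buried)
    if spec.cluster_center is not None:
        center_idx = spec.cluster_center - 1
        if not (0 <= center_idx < len(structure)) or not is_acceptor[center_idx]:
            raise ValueError(
                f"cluster_center {spec.cluster_center} is not an acceptor residue "
                f"of {sorted(spec.acceptor_residues)}"
            )
        d = np.linalg.norm(structure.ca_xyz - structure.ca_xyz[center_idx], axis=1)
        p = np.where(d <= spec.cluster_radius, spec.p_modify_exposed, p)
    rng = np.random.default_rng(spec.seed)
    modified = (rng.random(len(structure)) < p) & is_acceptor
    pos = np.flatnonzero(modified) + 1
    return pd.DataFrame(
        {
            "protein_id": structure.protein_id,
            "position": pos,
            "aa": seq[pos - 1],
            "ptm_type": spec.ptm_type,
            "regulatory": False,
        }
    )


def write_fixture(
    out_dir: str | Path,
    structure: StructureRecord,
    pae: PAEMatrix,
    ptm_table: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a fixture through the public file interfaces (PDB, PAE JSON, TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "structure": out_dir / f"{structure.protein_id}.pdb",
        "pae": out_dir / f"{structure.protein_id}.json",
    }
    write_pdb(structure, paths["structure"])
    write_pae(pae, paths["pae"])
    if ptm_table is not None:
        paths["ptm"] = out_dir / f"{structure.protein_id}_ptm.tsv"
        ptm_table.to_csv(paths["ptm"], sep="\t", index=False)
    return paths
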