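"""Prediction-aware part-sphere exposure (pPSE), IDR calling and exposure classes.

The pPSE generalizes half-sphere exposure: for residue i with side-chain
direction u_i = (CB_i - CA_i)/|CB_i - CA_i| (an ideal pseudo-CB for glycine),
residue j is a neighbor iff

    |CA_j - CA_i| + PAE_sym(i, j) <= radius      (PAE term optional)
    angle(u_i, CA_j - CA_i)       <= angle

with PAE_sym(i, j) = max(PAE[i, j], PAE[j, i]).  Adding the pairwise
predicted aligned error to each distance means residues whose relative
placement is uncertain are never counted as packing neighbors, so disordered
regions score low even when the predicted coordinates happen to collapse
them onto the folded core.  An angle of 180 deg is the full sphere and makes
the count independent of side-chain orientation.

Two standard configurations are used downstream:

* side-chain exposure: radius 12 A, angle 70 deg; residues with a raw pPSE
  <= 5 are classed as highly exposed;
* IDR calling: radius 24 A, full sphere, sequence-smoothed with a +/-10
  half-window; smoothed pPSE <= 34.27 flags a residue as disordered.

Short IDRs are disordered runs of at most 20 residues sandwiched between
structured runs of at least 80 residues; the "extended" region widens each
short IDR by 5 residues on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import PAEMatrix, StructureRecord

__all__ = [
    "PPSEConfig",
    "IDRConfig",
    "ShortIDRConfig",
    "PPSEProfile",
    "RegionAnnotation",
    "pseudo_cb",
    "compute_ppse",
    "smooth_profile",
    "idr_flags_from_smoothed",
    "call_idr",
    "find_short_idrs",
    "classify_exposure",
    "residue_table",
    "regions_to_bed",
]

# Ideal CB placement from the local backbone frame (b = CA-N, c = C-CA,
# a = b x c); standard construction used when no side chain is present.
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


@dataclass(frozen=True)
class PPSEConfig:
    """Neighbor-counting configuration: cone radius (A), opening angle (deg),
    and whether distances are inflated by the pairwise PAE."""

    radius: float = 12.0
    angle: float = 70.0
    use_pae: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 < self.angle <= 180.0):
            raise ValueError("angle must be in (0, 180] degrees")


@dataclass(frozen=True)
class IDRConfig:
    """IDR calling: full-sphere pPSE at 24 A, smoothed, thresholded at 34.27."""

    radius: float = 24.0
    angle: float = 180.0
    half_window: int = 10
    threshold: float = 34.27
    use_pae: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.half_window < 1:
            raise ValueError("half_window must be >= 1")


@dataclass(frozen=True)
class ShortIDRConfig:
    max_idr_len: int = 20
    min_flank_len: int = 80
    extension: int = 5

    def __post_init__(self) -> None:
        if min(self.max_idr_len, self.min_flank_len, self.extension) <= 0:
            raise ValueError("all ShortIDRConfig fields must be positive")


@dataclass
class PPSEProfile:
    """Per-residue neighbor counts; ``smoothed`` present iff ``half_window`` is."""

    protein_id: str
    config: PPSEConfig
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    half_window: int | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if (self.smoothed is None) != (self.half_window is None):
            raise ValueError("smoothed and half_window must be set together")


@dataclass
class RegionAnnotation:
    """IDR flags plus short-IDR intervals (1-based, inclusive) for one protein."""

    protein_id: str
    idr_flags: np.ndarray
    short_idr_regions: list[tuple[int, int]]
    extended_short_idr_regions: list[tuple[int, int]]

    def short_idr_mask(self) -> np.ndarray:
        return _regions_to_mask(self.short_idr_regions, len(self.idr_flags))

    def extended_mask(self) -> np.ndarray:
        return _regions_to_mask(self.extended_short_idr_regions, len(self.idr_flags))


def _regions_to_mask(regions: Sequence[tuple[int, int]], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for start, end in regions:
        mask[start - 1 : end] = True
    return mask


def pseudo_cb(n_xyz: np.ndarray, ca_xyz: np.ndarray, c_xyz: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral CB position built from the N, CA, C backbone atoms."""
    b = np.atleast_2d(ca_xyz) - np.atleast_2d(n_xyz)
    c = np.atleast_2d(c_xyz) - np.atleast_2d(ca_xyz)
    a = np.cross(b, c)
    ca2 = np.atleast_2d(ca_xyz)
    cb = ca2 + _CB_COEFF[0] * a + _CB_COEFF[1] * b + _CB_COEFF[2] * c
    return cb.reshape(np.shape(ca_xyz))


def side_chain_directions(structure: StructureRecord) -> np.ndarray:
    """Unit vectors CA->CB, substituting the ideal pseudo-CB where CB is absent."""
    cb = structure.cb_xyz.copy()
    missing = np.isnan(cb).any(axis=1)
    if missing.any():
        cb[missing] = pseudo_cb(
            structure.n_xyz[missing], structure.ca_xyz[missing], structure.c_xyz[missing]
        )
    v = cb - structure.ca_xyz
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm


def compute_ppse(
    structure: StructureRecord,
    pae: PAEMatrix | None = None,
    config: PPSEConfig = PPSEConfig(),
) -> PPSEProfile:
    """Count, for every residue, the CA atoms inside its part-sphere cone.

    With ``config.use_pae`` the CA-CA distance of each candidate pair is
    inflated by max(PAE[i, j], PAE[j, i]) before the radius test, so a PAE
    matrix is required.  Both the radius and the angle boundary are inclusive.
    """
    if config.use_pae and pae is None:
        raise ValueError(
            "compute_ppse: use_pae=True requires a PAE matrix (pass use_pae=False "
            "to count neighbors from coordinates alone)"
        )
    n = len(structure)
    ca = structure.ca_xyz
    dist = cdist(ca, ca)
    if config.use_pae:
        if len(pae) != n:
            raise ValueError(
                f"PAE matrix size {len(pae)} does not match structure length {n}"
            )
        eff = dist + pae.symmetrized()
    else:
        eff = dist
    within = eff <= config.radius
    np.fill_diagonal(within, False)
    if config.angle < 180.0:
        u = side_chain_directions(structure)
        # cos(angle between u_i and CA_j - CA_i), guarded against zero distance
        diff = ca[None, :, :] - ca[:, None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ijk,ik->ij", diff, u) / dist
        cos_thresh = np.cos(np.deg2rad(config.angle))
        within &= cosang >= cos_thresh
    raw = within.sum(axis=1).astype(np.int64)
    return PPSEProfile(protein_id=structure.protein_id, config=config, raw=raw)


def smooth_profile(profile: PPSEProfile, half_window: int) -> PPSEProfile:
    """Sliding mean over +/-half_window residues, truncated at the termini."""
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    sm = (
        pd.Series(profile.raw.astype(float))
        .rolling(window=2 * half_window + 1, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return PPSEProfile(
        protein_id=profile.protein_id,
        config=profile.config,
        raw=profile.raw,
        smoothed=sm,
        half_window=half_window,
    )


def idr_flags_from_smoothed(smoothed: np.ndarray, threshold: float) -> np.ndarray:
    """Disorder flag per residue: smoothed full-sphere pPSE <= threshold (inclusive)."""
    return np.asarray(smoothed, dtype=float) <= threshold


def call_idr(
    structure: StructureRecord,
    pae: PAEMatrix | None = None,
    config: IDRConfig = IDRConfig(),
) -> np.ndarray:
    """Per-residue IDR flags from the smoothed full-sphere pPSE."""
    prof = compute_ppse(
        structure,
        pae,
        PPSEConfig(radius=config.radius, angle=config.angle, use_pae=config.use_pae),
    )
    prof = smooth_profile(prof, config.half_window)
    return idr_flags_from_smoothed(prof.smoothed, config.threshold)


def _runs(flags: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs as (start, end, value), 1-based inclusive."""
    flags = np.asarray(flags, dtype=bool)
    out = []
    start = 0
    for i in range(1, len(flags) + 1):
        if i == len(flags) or flags[i] != flags[start]:
            out.append((start + 1, i, bool(flags[start])))
            start = i
    return out


def find_short_idrs(
    idr_flags: np.ndarray,
    config: ShortIDRConfig = ShortIDRConfig(),
    protein_id: str = "",
) -> RegionAnnotation:
    """Short IDRs: disordered runs of length <= max_idr_len whose neighboring
    structured runs on *both* sides span >= min_flank_len residues.

    A disordered run touching either terminus has no flank on that side and
    can never qualify.  Extended regions widen each short IDR by ``extension``
    residues per side, clipped to the sequence bounds.
    """
    idr_flags = np.asarray(idr_flags, dtype=bool)
    if len(idr_flags) == 0:
        raise ValueError("idr_flags must be nonempty")
    runs = _runs(idr_flags)
    n = len(idr_flags)
    short: list[tuple[int, int]] = []
    for k, (start, end, is_idr) in enumerate(runs):
        if not is_idr or (end - start + 1) > config.max_idr_len:
            continue
        if k == 0 or k == len(runs) - 1:
            continue  # terminal run: missing flank
        ls, le, _ = runs[k - 1]
        rs, re, _ = runs[k + 1]
        if (le - ls + 1) >= config.min_flank_len and (re - rs + 1) >= config.min_flank_len:
            short.append((start, end))
    extended = [
        (max(1, s - config.extension), min(n, e + config.extension)) for s, e in short
    ]
    return RegionAnnotation(
        protein_id=protein_id,
        idr_flags=idr_flags,
        short_idr_regions=short,
        extended_short_idr_regions=extended,
    )


def classify_exposure(profile: PPSEProfile, cutoff: int = 5) -> np.ndarray:
    """Label residues 'high' (raw pPSE <= cutoff) or 'low' exposure."""
    return np.where(profile.raw <= cutoff, "high", "low")


def annotate_structure(
    structure: StructureRecord,
    pae: PAEMatrix | None,
    exposure_config: PPSEConfig = PPSEConfig(),
    idr_config: IDRConfig = IDRConfig(),
    short_config: ShortIDRConfig = ShortIDRConfig(),
    exposure_cutoff: int = 5,
) -> tuple[PPSEProfile, RegionAnnotation, pd.DataFrame]:
    """Run the full per-residue pipeline for one protein.

    Returns the exposure profile (12 A / 70 deg by default), the region
    annotation from IDR calling, and the per-residue table.
    """
    expo = compute_ppse(structure, pae, exposure_config)
    idr_prof = compute_ppse(
        structure,
        pae,
        PPSEConfig(radius=idr_config.radius, angle=idr_config.angle,
                   use_pae=idr_config.use_pae),
    )
    idr_prof = smooth_profile(idr_prof, idr_config.half_window)
    flags = idr_flags_from_smoothed(idr_prof.smoothed, idr_config.threshold)
    regions = find_short_idrs(flags, short_config, protein_id=structure.protein_id)
    table = pd.DataFrame(
        {
            "protein_id": structure.protein_id,
            "position": structure.positions,
            "aa": list(structure.sequence),
            "plddt": structure.plddt,
            "ppse_exposure": expo.raw,
            "ppse_sphere": idr_prof.raw,
            "ppse_sphere_smooth": idr_prof.smoothed,
            "idr_flag": flags,
            "short_idr_flag": regions.short_idr_mask(),
            "extended_short_idr_flag": regions.extended_mask(),
            "exposure_class": classify_exposure(expo, cutoff=exposure_cutoff),
        }
    )
    return expo, regions, table


def residue_table(
    structures: dict[str, StructureRecord],
    paes: dict[str, PAEMatrix],
    **kwargs,
) -> pd.DataFrame:
    """Concatenated per-residue annotation table for a set of proteins."""
    parts = []
    for pid in sorted(structures):
        _, _, tab = annotate_structure(structures[pid], paes.get(pid), **kwargs)
        parts.append(tab)
    return pd.concat(parts, ignore_index=True)


def regions_to_bed(regions: dict[str, RegionAnnotation], extended: bool = False) -> pd.DataFrame:
    """Short-IDR intervals as BED-like rows (0-based half-open)."""
    rows = []
    for pid in sorted(regions):
        ann = regions[pid]
        ivals = ann.extended_short_idr_regions if extended else ann.short_idr_regions
        for start, end in ivals:
            rows.append({"protein_id": pid, "start": start - 1, "end": end})
    return pd.DataFrame(rows, columns=["protein_id", "start", "end"])
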