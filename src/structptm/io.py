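"""Reading and writing AlphaFold-style single-chain structures and PAE matrices.

Structure files (PDB or mmCIF, optionally gzipped) are expected to follow the
AlphaFold DB layout: one polypeptide chain, complete backbone (N, CA, C per
residue), and the per-residue prediction confidence (pLDDT, 0-100) stored in
the B-factor column.  The predicted aligned error (PAE) comes as the matching
AlphaFold DB JSON, in either the dense ``predicted_aligned_error`` dialect or
the older ``residue1``/``residue2``/``distance`` triplet dialect.

Internally residues are always re-based to positions 1..n in author order;
the original author numbering is retained as metadata so sites reported in
UniProt coordinates can be cross-checked.
"""

from __future__ import annotations

import gzip
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as bst
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_get_structure

logger = logging.getLogger(__name__)

__all__ = [
    "StructureError",
    "PAEError",
    "ResidueRecord",
    "StructureRecord",
    "PAEMatrix",
    "parse_structure",
    "parse_pae",
    "write_pdb",
    "write_pae",
]


class StructureError(ValueError):
    """Raised when a structure file violates the single-chain AlphaFold layout."""


class PAEError(ValueError):
    """Raised when a PAE matrix is malformed or inconsistent with its structure."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: identity, backbone anchors, optional CB, and pLDDT."""

    position: int  # 1-based, contiguous
    aa: str  # one-letter code ('X' for unknown)
    n_xyz: np.ndarray
    ca_xyz: np.ndarray
    c_xyz: np.ndarray
    cb_xyz: np.ndarray | None  # None for glycine / missing side chain
    plddt: float


@dataclass
class StructureRecord:
    """Per-residue representation of one predicted protein chain.

    Coordinate arrays are (n, 3) float64 in Angstrom.  ``cb_xyz`` rows are NaN
    where no CB atom exists (glycine).  ``author_positions`` preserves the
    residue numbering of the input file; internal positions are always 1..n.
    """

    protein_id: str
    sequence: str
    n_xyz: np.ndarray
    ca_xyz: np.ndarray
    c_xyz: np.ndarray
    cb_xyz: np.ndarray
    plddt: np.ndarray
    author_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("n_xyz", "ca_xyz", "c_xyz", "cb_xyz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise StructureError(
                    f"{self.protein_id}: {name} has shape {arr.shape}, expected {(n, 3)}"
                )
            setattr(self, name, arr)
        self.plddt = np.asarray(self.plddt, dtype=float)
        if self.plddt.shape != (n,):
            raise StructureError(f"{self.protein_id}: pLDDT length mismatch")
        if np.any(self.plddt < 0.0) or np.any(self.plddt > 100.0):
            bad = int(np.flatnonzero((self.plddt < 0) | (self.plddt > 100))[0]) + 1
            raise StructureError(
                f"{self.protein_id}: pLDDT out of range [0, 100] at position {bad} "
                f"(value {self.plddt[bad - 1]:g})"
            )
        has_cb = ~np.isnan(self.cb_xyz).any(axis=1)
        if has_cb.any():
            d = np.linalg.norm(self.ca_xyz[has_cb] - self.cb_xyz[has_cb], axis=1)
            if np.any(d >= 4.0):
                pos = int(np.flatnonzero(has_cb)[np.argmax(d)]) + 1
                raise StructureError(
                    f"{self.protein_id}: CA-CB distance {d.max():.2f} A >= 4 A at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self) + 1)

    @property
    def residues(self) -> list[ResidueRecord]:
        out = []
        for i, aa in enumerate(self.sequence):
            cb = None if np.isnan(self.cb_xyz[i]).any() else self.cb_xyz[i]
            out.append(
                ResidueRecord(
                    position=i + 1,
                    aa=aa,
                    n_xyz=self.n_xyz[i],
                    ca_xyz=self.ca_xyz[i],
                    c_xyz=self.c_xyz[i],
                    cb_xyz=cb,
                    plddt=float(self.plddt[i]),
                )
            )
        return out


@dataclass
class PAEMatrix:
    """Predicted aligned error in Angstrom; stored as parsed (possibly asymmetric)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise PAEError(f"PAE matrix must be square, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise PAEError("PAE matrix contains non-finite entries")
        if (v < 0).any():
            raise PAEError("PAE matrix contains negative entries")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]

    def symmetrized(self) -> np.ndarray:
        """max(PAE[i,j], PAE[j,i]) — the conservative pairwise uncertainty."""
        return np.maximum(self.values, self.values.T)


def _open_text(path: str | Path) -> _io.TextIOWrapper:
    path = Path(path)
    raw = path.open("rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return _io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    raw.seek(0)
    return _io.TextIOWrapper(raw)


def _three_to_one(res_name: str) -> str:
    try:
        one = ProteinSequence.convert_letter_3to1(res_name)
    except KeyError:
        logger.warning("unknown residue name %r mapped to 'X'", res_name)
        return "X"
    return one if one in ProteinSequence.alphabet else "X"


def parse_structure(path: str | Path, protein_id: str | None = None) -> StructureRecord:
    """Parse a single-chain PDB or mmCIF file into a :class:`StructureRecord`.

    The format is chosen from the file suffix (``.cif``/``.mmcif`` vs PDB,
    ``.gz`` handled transparently); pLDDT is taken from the CA B-factor.
    """
    path = Path(path)
    suffixes = [s.lower() for s in path.suffixes]
    is_cif = ".cif" in suffixes or ".mmcif" in suffixes
    with _open_text(path) as fh:
        if is_cif:
            cif = CIFFile.read(fh)
            atoms = _cif_get_structure(cif, model=1, extra_fields=["b_factor"])
        else:
            pdb = PDBFile.read(fh)
            atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
    # keep canonical amino acids plus unknown polymer residues (ATOM records);
    # heteroatoms such as ligands or waters are discarded
    atoms = atoms[bst.filter_amino_acids(atoms) | ~atoms.hetero]
    if atoms.array_length() == 0:
        raise StructureError(f"{path}: no amino-acid atoms found")
    chains = np.unique(atoms.chain_id)
    if len(chains) != 1:
        raise StructureError(
            f"{path}: expected exactly one chain, found {len(chains)}: {list(chains)}"
        )
    if protein_id is None:
        protein_id = path.name.split(".")[0]

    res_starts = bst.get_residue_starts(atoms)
    n = len(res_starts)
    seq = []
    coords = {k: np.full((n, 3), np.nan) for k in ("N", "CA", "C", "CB")}
    plddt = np.zeros(n)
    author = np.zeros(n, dtype=int)
    bounds = list(res_starts) + [atoms.array_length()]
    for i in range(n):
        sub = atoms[bounds[i] : bounds[i + 1]]
        res_name = sub.res_name[0]
        author[i] = int(sub.res_id[0])
        seq.append(_three_to_one(res_name))
        names = list(sub.atom_name)
        for key in ("N", "CA", "C", "CB"):
            if key in names:
                coords[key][i] = sub.coord[names.index(key)]
        if "CA" not in names:
            raise StructureError(
                f"{protein_id}: residue {res_name} {author[i]} is missing its CA atom"
            )
        for key in ("N", "C"):
            if key in names:
                continue
            raise StructureError(
                f"{protein_id}: residue {res_name} {author[i]} is missing backbone atom {key}"
            )
        plddt[i] = float(sub.b_factor[names.index("CA")])
    return StructureRecord(
        protein_id=protein_id,
        sequence="".join(seq),
        n_xyz=coords["N"],
        ca_xyz=coords["CA"],
        c_xyz=coords["C"],
        cb_xyz=coords["CB"],
        plddt=plddt,
        author_positions=author,
    )


def write_pdb(structure: StructureRecord, path: str | Path) -> None:
    """Write a StructureRecord as a single-chain PDB file (pLDDT in B-factor)."""
    n = len(structure)
    has_cb = ~np.isnan(structure.cb_xyz).any(axis=1)
    n_atoms = 3 * n + int(has_cb.sum())
    arr = bst.AtomArray(n_atoms)
    coord = np.zeros((n_atoms, 3))
    res_id = np.zeros(n_atoms, dtype=int)
    res_name = np.empty(n_atoms, dtype="U3")
    atom_name = np.empty(n_atoms, dtype="U4")
    element = np.empty(n_atoms, dtype="U2")
    b_factor = np.zeros(n_atoms)
    k = 0
    for i, aa in enumerate(structure.sequence):
        three = ProteinSequence.convert_letter_1to3(aa if aa != "X" else "X")
        names = [("N", structure.n_xyz[i], "N"), ("CA", structure.ca_xyz[i], "C"),
                 ("C", structure.c_xyz[i], "C")]
        if has_cb[i]:
            names.append(("CB", structure.cb_xyz[i], "C"))
        for nm, xyz, el in names:
            coord[k] = xyz
            res_id[k] = i + 1
            res_name[k] = three
            atom_name[k] = nm
            element[k] = el
            b_factor[k] = structure.plddt[i]
            k += 1
    arr.coord = coord
    arr.chain_id = np.full(n_atoms, "A")
    arr.res_id = res_id
    arr.res_name = res_name
    arr.atom_name = atom_name
    arr.element = element
    arr.set_annotation("b_factor", b_factor)
    pdb = PDBFile()
    pdb.set_structure(arr)
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            pdb.write(fh)
    else:
        with path.open("w") as fh:
            pdb.write(fh)


def parse_pae(path: str | Path, n_expected: int | None = None) -> PAEMatrix:
    """Parse an AlphaFold DB PAE JSON file (dense or triplet dialect).

    The triplet dialect (``residue1``/``residue2``/``distance``) is densified;
    diagonal entries are clamped to zero.  When ``n_expected`` is given the
    matrix size must match the paired structure length.
    """
    with _open_text(path) as fh:
        obj = json.load(fh)
    if isinstance(obj, list):
        if len(obj) != 1:
            raise PAEError(f"{path}: expected a single PAE object, found {len(obj)}")
        obj = obj[0]
    if not isinstance(obj, dict):
        raise PAEError(f"{path}: unrecognized PAE JSON layout")
    if "predicted_aligned_error" in obj:
        values = np.asarray(obj["predicted_aligned_error"], dtype=float)
    elif "pae" in obj:
        values = np.asarray(obj["pae"], dtype=float)
    elif {"residue1", "residue2", "distance"} <= obj.keys():
        r1 = np.asarray(obj["residue1"], dtype=int)
        r2 = np.asarray(obj["residue2"], dtype=int)
        d = np.asarray(obj["distance"], dtype=float)
        if not (len(r1) == len(r2) == len(d)):
            raise PAEError(f"{path}: triplet arrays have unequal lengths")
        n = int(max(r1.max(), r2.max()))
        if len(d) != n * n:
            raise PAEError(f"{path}: triplet list has {len(d)} entries, expected {n * n}")
        values = np.zeros((n, n))
        values[r1 - 1, r2 - 1] = d
    else:
        raise PAEError(f"{path}: no recognized PAE keys in JSON")
    mat = PAEMatrix(values)
    if n_expected is not None and len(mat) != n_expected:
        raise PAEError(
            f"{path}: PAE matrix is {len(mat)}x{len(mat)} but the structure has "
            f"{n_expected} residues"
        )
    return mat


def write_pae(pae: PAEMatrix, path: str | Path) -> None:
    """Write a PAE matrix in the dense AlphaFold DB JSON dialect."""
    payload = [{"predicted_aligned_error": pae.values.tolist(),
                "max_predicted_aligned_error": float(pae.values.max(initial=0.0))}]
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        json.dump(payload, fh)


def load_proteome(
    structure_dir: str | Path, pae_dir: str | Path | None = None
) -> tuple[dict[str, StructureRecord], dict[str, PAEMatrix]]:
    """Load every structure (and matching PAE, when a directory is given).

    Structures are matched to PAE files by shared stem.  Returns two dicts
    keyed by protein id; the PAE dict is empty when ``pae_dir`` is None.
    """
    structure_dir = Path(structure_dir)
    structures: dict[str, StructureRecord] = {}
    for path in sorted(structure_dir.iterdir()):
        suff = [s.lower() for s in path.suffixes]
        if not ({".pdb", ".ent", ".cif", ".mmcif"} & set(suff)):
            continue
        rec = parse_structure(path)
        structures[rec.protein_id] = rec
    paes: dict[str, PAEMatrix] = {}
    if pae_dir is not None:
        pae_dir = Path(pae_dir)
        for pid, rec in structures.items():
            for cand in (f"{pid}.json", f"{pid}.json.gz", f"{pid}_pae.json"):
                p = pae_dir / cand
                if p.exists():
                    paes[pid] = parse_pae(p, n_expected=len(rec))
                    break
    return structures, paes
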