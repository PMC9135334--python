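"""PTM site tables, structural joins, sequence windows, motifs and PSSMs.

PTM tables are TSV/CSV with columns ``protein_id``, ``position`` (1-based),
``aa`` (one-letter acceptor), ``ptm_type`` and optionally ``regulatory``.
Loading applies the catalog conventions: sites are kept only on the common
acceptor residues of their type (p: S/T/Y; ub/sm/ac: K; m: K/R with all
methylation subtypes grouped under ``m``; ga/gl: S/T), duplicates on
(protein, position, type) are merged, and regulatory sites missing from the
dedicated per-type list are added to it.

The structural join attaches, per site, the side-chain exposure (pPSE at
12 A / 70 deg), the exposure class, IDR / short-IDR membership, and an
``eligible_for_proximity`` flag that excludes residues inside IDRs longer
than the short-IDR cutoff (long disordered tails would otherwise dominate
3D proximity statistics with meaningless predicted coordinates).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import PPSEProfile, RegionAnnotation
from .io import StructureRecord

__all__ = [
    "DEFAULT_ACCEPTORS",
    "MotifPattern",
    "PSSM",
    "load_ptm_table",
    "filter_ptm_table",
    "annotate_sites",
    "extract_window",
    "match_motifs",
    "load_motifs",
    "build_pssm",
    "split_by_exposure",
]

#: Acceptor residues per PTM type: phosphorylation, ubiquitination,
#: sumoylation, acetylation, methylation, O-GalNAc, O-GlcNAc.
DEFAULT_ACCEPTORS: dict[str, frozenset[str]] = {
    "p": frozenset("STY"),
    "ub": frozenset("K"),
    "sm": frozenset("K"),
    "ac": frozenset("K"),
    "m": frozenset("KR"),
    "ga": frozenset("ST"),
    "gl": frozenset("ST"),
}

#: Methylation subtype labels collapsed into the single type ``m``.
METHYL_ALIASES = frozenset({"m", "m1", "m2", "m3", "me", "me1", "me2", "me3"})

_PTM_COLUMNS = ["protein_id", "position", "aa", "ptm_type", "regulatory"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    name = path.name.removesuffix(".gz")
    sep = "\t" if name.endswith(".tsv") else "," if name.endswith(".csv") else None
    return pd.read_csv(path, sep=sep, engine=None if sep else "python")


def filter_ptm_table(
    df: pd.DataFrame,
    acceptor_map: Mapping[str, frozenset[str]] | None = None,
    regulatory: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply acceptor filtering, type grouping, dedup and the regulatory union.

    Returns the cleaned table (sorted by protein, position, type) and a
    filter report counting rejected / merged rows per category.
    """
    acceptor_map = dict(DEFAULT_ACCEPTORS if acceptor_map is None else acceptor_map)
    report: dict[str, int] = {}

    def clean(d: pd.DataFrame, label: str) -> pd.DataFrame:
        d = d.copy()
        missing = [c for c in ("protein_id", "position", "aa", "ptm_type") if c not in d.columns]
        if missing:
            raise ValueError(f"{label}: missing required columns {missing}")
        pos = pd.to_numeric(d["position"], errors="coerce")
        bad = pos.isna() | (pos != pos.round()) | (pos <= 0)
        if bad.any():
            rows = d.index[bad].tolist()[:20]
            raise ValueError(f"{label}: malformed positions at input rows {rows}")
        d["position"] = pos.astype(int)
        d["aa"] = d["aa"].astype(str).str.upper()
        d["ptm_type"] = d["ptm_type"].astype(str)
        d.loc[d["ptm_type"].isin(METHYL_ALIASES), "ptm_type"] = "m"
        known = d["ptm_type"].isin(acceptor_map)
        report[f"{label}_unknown_type"] = int((~known).sum())
        d = d[known]
        ok = np.array(
            [aa in acceptor_map[t] for aa, t in zip(d["aa"], d["ptm_type"])], dtype=bool
        )
        for t in sorted(acceptor_map):
            report[f"{label}_{t}_rejected"] = int(((d["ptm_type"] == t) & ~ok).sum())
        if "regulatory" not in d.columns:
            d = d.assign(regulatory=False)
        d["regulatory"] = d["regulatory"].astype(bool)
        return d[ok][_PTM_COLUMNS]

    out = clean(df, "sites")
    if regulatory is not None:
        reg = clean(regulatory, "regulatory")
        reg = reg.assign(regulatory=True)
        n_before = len(out)
        out = pd.concat([out, reg], ignore_index=True)
        report["regulatory_rows"] = len(reg)
    # merge duplicates: regulatory is the union over duplicate reports
    n_raw = len(out)
    out = (
        out.sort_values(_PTM_COLUMNS)
        .groupby(["protein_id", "position", "ptm_type"], as_index=False)
        .agg(aa=("aa", "first"), regulatory=("regulatory", "any"))
    )[_PTM_COLUMNS]
    report["duplicates_merged"] = n_raw - len(out)
    out = out.sort_values(["protein_id", "position", "ptm_type"]).reset_index(drop=True)
    return out, report


def load_ptm_table(
    path: str | Path,
    acceptor_map: Mapping[str, frozenset[str]] | None = None,
    regulatory_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Load a PTM site table (and optional regulatory-site table) from disk."""
    df = _read_table(path)
    reg = _read_table(regulatory_path) if regulatory_path is not None else None
    return filter_ptm_table(df, acceptor_map=acceptor_map, regulatory=reg)


def annotate_sites(
    ptm: pd.DataFrame,
    structures: Mapping[str, StructureRecord],
    profiles: Mapping[str, PPSEProfile],
    regions: Mapping[str, RegionAnnotation],
    strict: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join PTM sites to their structural context.

    Rows referencing unknown proteins are dropped with a warning (or raise
    with ``strict=True``); rows whose position exceeds the protein length or
    whose acceptor letter disagrees with the structure sequence are dropped
    and counted in the report.  ``eligible_for_proximity`` is true for sites
    outside IDRs or inside short IDRs.
    """
    report = {"unknown_protein": 0, "position_out_of_bounds": 0, "sequence_mismatch": 0}
    parts = []
    for pid, grp in ptm.groupby("protein_id", sort=True):
        if pid not in structures:
            if strict:
                raise KeyError(f"no structure for protein {pid!r}")
            report["unknown_protein"] += len(grp)
            warnings.warn(f"dropping {len(grp)} sites of unknown protein {pid!r}")
            continue
        struct = structures[pid]
        prof = profiles[pid]
        ann = regions[pid]
        n = len(struct)
        pos = grp["position"].to_numpy()
        in_bounds = pos <= n
        report["position_out_of_bounds"] += int((~in_bounds).sum())
        grp = grp[in_bounds]
        pos = pos[in_bounds]
        seq = np.array(list(struct.sequence))
        match = seq[pos - 1] == grp["aa"].to_numpy()
        report["sequence_mismatch"] += int((~match).sum())
        grp = grp[match].copy()
        pos = pos[match]
        idx = pos - 1
        short_mask = ann.short_idr_mask()
        ext_mask = ann.extended_mask()
        grp["ppse_exposure"] = prof.raw[idx]
        grp["exposure_class"] = np.where(prof.raw[idx] <= 5, "high", "low")
        grp["idr_flag"] = ann.idr_flags[idx]
        grp["short_idr_flag"] = short_mask[idx]
        grp["extended_short_idr_flag"] = ext_mask[idx]
        grp["eligible_for_proximity"] = ~ann.idr_flags[idx] | short_mask[idx]
        parts.append(grp)
    if parts:
        out = pd.concat(parts, ignore_index=True)
    else:
        out = pd.DataFrame(
            columns=_PTM_COLUMNS
            + [
                "ppse_exposure",
                "exposure_class",
                "idr_flag",
                "short_idr_flag",
                "extended_short_idr_flag",
                "eligible_for_proximity",
            ]
        )
    return out, report


def extract_window(
    sequence: str, position: int, k: int = 6, require_center: str | None = None
) -> str | None:
    """Sequence window of +/-k residues around ``position``, '_'-padded at termini.

    With ``require_center`` (e.g. ``"STY"``) the window is only returned when
    the central residue is one of the given letters; otherwise None, so
    mis-annotated acceptor sites drop out of motif analyses.
    """
    n = len(sequence)
    if not (1 <= position <= n):
        raise ValueError(f"position {position} outside sequence of length {n}")
    center = sequence[position - 1]
    if require_center is not None and center not in require_center:
        return None
    lo = position - 1 - k
    hi = position - 1 + k + 1
    left = "_" * max(0, -lo)
    right = "_" * max(0, hi - n)
    return left + sequence[max(0, lo) : min(n, hi)] + right


@dataclass(frozen=True)
class MotifPattern:
    """Anchored motif: a restricted regular expression over amino-acid letters
    with exactly one capturing group marking the central acceptor position."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        try:
            rx = re.compile(self.pattern)
        except re.error as exc:
            raise ValueError(f"motif {self.name!r}: invalid pattern: {exc}") from exc
        if rx.groups != 1:
            raise ValueError(
                f"motif {self.name!r}: pattern must contain exactly one capturing "
                f"group marking the central acceptor (found {rx.groups})"
            )

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern)


def load_motifs(path: str | Path) -> list[MotifPattern]:
    """Read a motif TSV (columns: name, pattern)."""
    df = pd.read_csv(path, sep="\t")
    return [MotifPattern(str(r["name"]), str(r["pattern"])) for _, r in df.iterrows()]


def match_motifs(
    sequences: Mapping[str, str] | str,
    patterns: Sequence[MotifPattern],
    protein_id: str = "",
) -> pd.DataFrame:
    """All (overlapping) motif occurrences; one row per matched center position.

    Every start offset is probed independently so overlapping matches are all
    reported; the reported position is the 1-based center (capturing group).
    """
    if isinstance(sequences, str):
        sequences = {protein_id: sequences}
    rows = []
    for pid in sorted(sequences):
        seq = sequences[pid]
        for motif in patterns:
            rx = motif.regex
            for start in range(len(seq)):
                m = rx.match(seq, start)
                if m is None:
                    continue
                if len(m.group(1)) != 1:
                    raise ValueError(
                        f"motif {motif.name!r}: central group must match exactly one residue"
                    )
                rows.append(
                    {"protein_id": pid, "position": m.start(1) + 1, "motif": motif.name}
                )
    return pd.DataFrame(rows, columns=["protein_id", "position", "motif"])


_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PSSM:
    """Log-odds position-specific scoring matrix (bits), columns -k..+k."""

    matrix: np.ndarray  # (20, 2k+1)
    k: int
    pseudocount: float
    background: np.ndarray  # (20,)
    alphabet: str = _AA_ORDER

    def score(self, aa: str, offset: int) -> float:
        return float(self.matrix[self.alphabet.index(aa), offset + self.k])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=list(self.alphabet),
            columns=[str(o) for o in range(-self.k, self.k + 1)],
        )


def build_pssm(
    windows: Sequence[str],
    background: Mapping[str, float] | np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> PSSM:
    """Log-odds PSSM from aligned fixed-length windows.

    score(a, pos) = log2( (count(a,pos) + pc*bg[a]) / (N_pos + pc) / bg[a] )

    '_' padding is excluded from the counts and from the per-column total
    N_pos; a column containing only padding scores zero everywhere (no
    evidence).  The background must sum to 1 within 1e-9.
    """
    if len(windows) == 0:
        raise ValueError("at least one window is required")
    width = len(windows[0])
    if width % 2 != 1:
        raise ValueError("window width must be odd (2k+1)")
    if any(len(w) != width for w in windows):
        raise ValueError("all windows must have equal length")
    if background is None:
        bg = np.full(20, 1.0 / 20.0)
    elif isinstance(background, Mapping):
        bg = np.array([background[a] for a in _AA_ORDER], dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    if bg.shape != (20,) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 20 frequencies summing to 1 (+/-1e-9)")
    k = width // 2
    arr = np.array([list(w) for w in windows])
    matrix = np.zeros((20, width))
    aa_index = {a: i for i, a in enumerate(_AA_ORDER)}
    for col in range(width):
        letters = arr[:, col]
        letters = letters[letters != "_"]
        n_col = len(letters)
        if n_col == 0:
            continue
        counts = np.zeros(20)
        for a in letters:
            if a in aa_index:
                counts[aa_index[a]] += 1
            else:
                n_col -= 1  # non-standard letters carry no evidence
        matrix[:, col] = np.log2(
            (counts + pseudocount * bg) / (n_col + pseudocount) / bg
        )
    return PSSM(matrix=matrix, k=k, pseudocount=pseudocount, background=bg)


def split_by_exposure(
    annotated: pd.DataFrame, cutoff: int = 5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition annotated sites into high/low exposure plus a size-matched
    random subset of the high set (|subset| = |low|, seeded)."""
    high = annotated[annotated["ppse_exposure"] <= cutoff]
    low = annotated[annotated["ppse_exposure"] > cutoff]
    rng = np.random.default_rng(seed)
    if len(high) < len(low):
        warnings.warn(
            f"high-exposure set ({len(high)}) smaller than low-exposure set "
            f"({len(low)}); matched subset is the entire high set"
        )
        matched = high.copy()
    else:
        idx = rng.choice(len(high), size=len(low), replace=False)
        matched = high.iloc[np.sort(idx)]
    return high, low, matched
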