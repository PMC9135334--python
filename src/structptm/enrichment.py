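"""2x2 enrichment statistics for PTM structural context.

Every enrichment design reduces to the same contingency table over a
universe of acceptor residues:

                    modified    unmodified
    in category        a            b
    out of category    c            d

scored with a two-sided Fisher exact test (hypergeometric enumeration over
the support, same-margin tables with probability <= the observed table's,
with the conventional (1 + 1e-7) tolerance on the probability comparison)
and the sample odds ratio (a*d)/(b*c).  Families of tests — all PTM types of
one design, or all proteins of a per-protein scan — are corrected with
Benjamini-Hochberg.

Designs:

* ``idr``                         acceptors anywhere; category = in IDR
* ``short_idr_vs_all_idr``        acceptors in IDRs; category = in short IDR
* ``exposure_high_in_structured`` acceptors outside IDRs; category = high exposure
* ``motif``                       acceptors anywhere; category = motif center
* ``motif_in_idr``                acceptor motif centers; category = in IDR
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotate import DEFAULT_ACCEPTORS
from .exposure import PPSEProfile, RegionAnnotation
from .io import StructureRecord

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "fisher_two_sided",
    "bh_adjust",
    "enrich_in_region",
    "enrich_by_type",
    "enrich_per_protein",
    "DESIGNS",
]

DESIGNS = ("idr", "short_idr_vs_all_idr", "exposure_high_in_structured",
           "motif", "motif_in_idr")

# probability-comparison tolerance of the two-sided rule
_REL_TOL_NUM = 10**7 + 1
_REL_TOL_DEN = 10**7
# above this table total, switch from exact integer enumeration to log-space
_EXACT_LIMIT = 1000


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # in-category, modified
    b: int  # in-category, unmodified
    c: int  # out-category, modified
    d: int  # out-category, unmodified

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError(f"negative cell in contingency table: {self}")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("contingency table is empty")


@dataclass
class EnrichmentResult:
    design: str
    ptm_type: str
    odds_ratio: float
    p_value: float
    adj_p_value: float
    n_sites: int
    table: ContingencyTable
    protein_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "ptm_type": self.ptm_type,
            "protein_id": self.protein_id,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "adj_p_value": self.adj_p_value,
            "n_sites": self.n_sites,
            "a": self.table.a,
            "b": self.table.b,
            "c": self.table.c,
            "d": self.table.d,
        }


def _sample_odds_ratio(t: ContingencyTable) -> float:
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def fisher_two_sided(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    Small tables (total <= 1000) are enumerated in exact integer arithmetic;
    larger tables use log-space hypergeometric weights over the same support.
    Returns (sample odds ratio, p-value).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    oddsr = _sample_odds_ratio(table)
    if n <= _EXACT_LIMIT:
        weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
        w_obs = weights[a - lo]
        included = sum(w for w in weights if w * _REL_TOL_DEN <= w_obs * _REL_TOL_NUM)
        p = float(Fraction(included, math.comb(n, c1)))
    else:
        x = np.arange(lo, hi + 1)
        logw = hypergeom.logpmf(x, n, c1, r1)
        l_obs = logw[a - lo]
        sel = logw <= l_obs + math.log1p(1.0 / _REL_TOL_DEN)
        p = float(np.exp(logsumexp(logw[sel])))
    return oddsr, min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tabulate(category: np.ndarray, modified: np.ndarray) -> ContingencyTable:
    category = np.asarray(category, dtype=bool)
    modified = np.asarray(modified, dtype=bool)
    return ContingencyTable(
        a=int((category & modified).sum()),
        b=int((category & ~modified).sum()),
        c=int((~category & modified).sum()),
        d=int((~category & ~modified).sum()),
    )


def _design_masks(
    structure: StructureRecord,
    profile: PPSEProfile,
    ann: RegionAnnotation,
    ptm_type: str,
    design: str,
    acceptor_map: Mapping[str, frozenset[str]],
    motif_centers: np.ndarray | None,
    exposure_cutoff: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (universe, category) boolean masks for one protein."""
    seq = np.array(list(structure.sequence))
    acceptor = np.isin(seq, list(acceptor_map[ptm_type]))
    idr = ann.idr_flags
    if design == "idr":
        return acceptor, idr
    if design == "short_idr_vs_all_idr":
        return acceptor & idr, ann.short_idr_mask()
    if design == "exposure_high_in_structured":
        return acceptor & ~idr, profile.raw <= exposure_cutoff
    if design in ("motif", "motif_in_idr"):
        if motif_centers is None:
            raise ValueError(f"design {design!r} requires motif occurrences")
        centers = np.zeros(len(structure), dtype=bool)
        centers[np.asarray(motif_centers, dtype=int) - 1] = True
        if design == "motif":
            return acceptor, centers
        return acceptor & centers, idr
    raise ValueError(f"unknown design {design!r}; choose one of {DESIGNS}")


def _modified_mask(
    annotated: pd.DataFrame, pid: str, ptm_type: str, n: int,
    restrict: pd.Series | None,
) -> np.ndarray:
    rows = annotated[(annotated["protein_id"] == pid) & (annotated["ptm_type"] == ptm_type)]
    if restrict is not None:
        rows = rows[restrict.reindex(rows.index, fill_value=False)]
    mask = np.zeros(n, dtype=bool)
    if len(rows):
        mask[rows["position"].to_numpy(dtype=int) - 1] = True
    return mask


def enrich_in_region(
    annotated: pd.DataFrame,
    structures: Mapping[str, StructureRecord],
    profiles: Mapping[str, PPSEProfile],
    regions: Mapping[str, RegionAnnotation],
    ptm_type: str,
    design: str = "idr",
    acceptor_map: Mapping[str, frozenset[str]] | None = None,
    restrict: pd.Series | None = None,
    motif_occurrences: pd.DataFrame | None = None,
    exposure_cutoff: int = 5,
) -> EnrichmentResult:
    """Pooled enrichment of one PTM type in one structural category.

    The universe is every acceptor residue of ``ptm_type`` across the supplied
    proteins, restricted per design (structured-only, IDR-only, motif
    centers); ``restrict`` optionally filters the modified rows (e.g.
    regulatory sites only).  ``adj_p_value`` equals the raw p here; family
    correction happens in :func:`enrich_by_type` / :func:`enrich_per_protein`.
    """
    acceptor_map = dict(DEFAULT_ACCEPTORS if acceptor_map is None else acceptor_map)
    cats, mods = [], []
    for pid in sorted(structures):
        struct = structures[pid]
        centers = None
        if motif_occurrences is not None:
            centers = motif_occurrences.loc[
                motif_occurrences["protein_id"] == pid, "position"
            ].to_numpy()
        universe, category = _design_masks(
            struct, profiles[pid], regions[pid], ptm_type, design,
            acceptor_map, centers, exposure_cutoff,
        )
        modified = _modified_mask(annotated, pid, ptm_type, len(struct), restrict)
        cats.append(category[universe])
        mods.append(modified[universe])
    category = np.concatenate(cats) if cats else np.array([], dtype=bool)
    modified = np.concatenate(mods) if mods else np.array([], dtype=bool)
    if category.size == 0:
        raise ValueError(f"empty universe for design {design!r} / PTM type {ptm_type!r}")
    table = _tabulate(category, modified)
    oddsr, p = fisher_two_sided(table)
    return EnrichmentResult(
        design=design,
        ptm_type=ptm_type,
        odds_ratio=oddsr,
        p_value=p,
        adj_p_value=p,
        n_sites=table.a + table.c,
        table=table,
    )


def enrich_by_type(
    annotated: pd.DataFrame,
    structures: Mapping[str, StructureRecord],
    profiles: Mapping[str, PPSEProfile],
    regions: Mapping[str, RegionAnnotation],
    ptm_types: Sequence[str],
    design: str = "idr",
    **kwargs,
) -> list[EnrichmentResult]:
    """One test per PTM type, BH-adjusted across the family."""
    results = [
        enrich_in_region(annotated, structures, profiles, regions, t, design, **kwargs)
        for t in ptm_types
    ]
    adj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.adj_p_value = float(q)
    return results


def enrich_per_protein(
    annotated: pd.DataFrame,
    structures: Mapping[str, StructureRecord],
    profiles: Mapping[str, PPSEProfile],
    regions: Mapping[str, RegionAnnotation],
    ptm_type: str,
    design: str = "idr",
    acceptor_map: Mapping[str, frozenset[str]] | None = None,
    exposure_cutoff: int = 5,
) -> tuple[list[EnrichmentResult], int]:
    """Per-protein enrichment scan, BH-adjusted across all tested proteins.

    Proteins without any modified acceptor in the design universe are skipped;
    the count of skipped proteins is returned alongside the results.
    """
    acceptor_map = dict(DEFAULT_ACCEPTORS if acceptor_map is None else acceptor_map)
    results: list[EnrichmentResult] = []
    skipped = 0
    for pid in sorted(structures):
        struct = structures[pid]
        universe, category = _design_masks(
            struct, profiles[pid], regions[pid], ptm_type, design,
            acceptor_map, None, exposure_cutoff,
        )
        modified = _modified_mask(annotated, pid, ptm_type, len(struct), None)
        if universe.sum() == 0 or not (modified & universe).any():
            skipped += 1
            continue
        table = _tabulate(category[universe], modified[universe])
        oddsr, p = fisher_two_sided(table)
        results.append(
            EnrichmentResult(
                design=design,
                ptm_type=ptm_type,
                odds_ratio=oddsr,
                p_value=p,
                adj_p_value=p,
                n_sites=table.a + table.c,
                table=table,
                protein_id=pid,
            )
        )
    if results:
        adj = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adj):
            r.adj_p_value = float(q)
    return results, skipped


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
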