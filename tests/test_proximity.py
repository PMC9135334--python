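"""PAE-inflated distances, global proximity profiles, cluster permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from conftest import annotated_proteome, two_residue_structure, uniform_pae
from structptm.annotate import annotate_sites
from structptm.exposure import annotate_structure
from structptm.fixtures import PTMSimSpec, SegmentSpec, make_chimera, simulate_ptm_sites
from structptm.io import PAEMatrix
from structptm.proximity import (
    ProximityConfig,
    cluster_test,
    cluster_tests,
    global_proximity,
    pae_distance,
    pae_distance_matrix,
)


def _globule(seed, n=200, pid=None):
    s, p = make_chimera(
        [SegmentSpec("globule", n, intra_pae=2.0)], seed=seed,
        protein_id=pid or f"G{seed}",
    )
    prof, reg, _ = annotate_structure(s, p)
    return s, p, prof, reg


def _pocket_sites(structure, radius=8.0, k=5, acceptors="STY"):
    """The k closest acceptors around the acceptor with the densest pocket."""
    seq = np.array(list(structure.sequence))
    acc = np.flatnonzero(np.isin(seq, list(acceptors))) + 1
    best_center, best_n = None, -1
    for c in acc:
        d = np.linalg.norm(structure.ca_xyz[acc - 1] - structure.ca_xyz[c - 1], axis=1)
        if (d <= radius).sum() > best_n:
            best_center, best_n = c, (d <= radius).sum()
    d = np.linalg.norm(structure.ca_xyz[acc - 1] - structure.ca_xyz[best_center - 1], axis=1)
    return acc[np.argsort(d)][:k]


def _site_frame(structure, positions, ptm_type="p"):
    seq = np.array(list(structure.sequence))
    return pd.DataFrame({
        "protein_id": structure.protein_id, "position": positions,
        "aa": seq[np.asarray(positions) - 1], "ptm_type": ptm_type,
        "regulatory": False,
    })


class TestPaeDistance:
    def test_zero_pae_is_plain_ca_distance(self):
        s = two_residue_structure(ca_distance=3.0)
        assert pae_distance(s, uniform_pae(2, 0.0), 1, 2) == pytest.approx(3.0)

    def test_max_of_asymmetric_pae(self):
        s = two_residue_structure(ca_distance=3.0)
        vals = np.array([[0.0, 2.0], [4.0, 0.0]])
        assert pae_distance(s, PAEMatrix(vals), 1, 2) == pytest.approx(7.0)
        assert pae_distance(s, PAEMatrix(vals), 2, 1) == pytest.approx(7.0)

    def test_self_distance_is_hard_error(self):
        s = two_residue_structure()
        with pytest.raises(ValueError):
            pae_distance(s, uniform_pae(2, 0.0), 1, 1)

    def test_never_below_euclidean(self):
        s, p, _, _ = _globule(0, n=60)
        d_pae = pae_distance_matrix(s, p)
        d_eu = cdist(s.ca_xyz, s.ca_xyz)
        assert (d_pae >= d_eu - 1e-12).all()

    def test_matrix_reduces_to_euclidean_at_zero_pae(self):
        s, _, _, _ = _globule(1, n=50)
        zero = uniform_pae(50, 0.0)
        np.testing.assert_array_equal(
            pae_distance_matrix(s, zero), cdist(s.ca_xyz, s.ca_xyz)
        )


class TestGlobalProximity:
    def test_two_sites_forced_binning(self):
        """Two phosphosites at inflated distance 3 -> self bin (1,5] fraction 1."""
        s = two_residue_structure(ca_distance=3.0)
        s = s.__class__(
            protein_id="TWO", sequence="SS", n_xyz=s.n_xyz, ca_xyz=s.ca_xyz,
            c_xyz=s.c_xyz, cb_xyz=s.cb_xyz, plddt=s.plddt,
        )
        pae = uniform_pae(2, 0.0)
        prof, reg, _ = annotate_structure(s, pae)
        ann, _ = annotate_sites(
            _site_frame(s, [1, 2]), {"TWO": s}, {"TWO": prof}, {"TWO": reg}
        )
        profile = global_proximity(
            ann, {"TWO": s}, {"TWO": pae}, {"TWO": reg}, "p", "p",
            ProximityConfig(seed=0, eligible_only=False),
        )
        row = profile[(profile.bin_lo == 1.0)].iloc[0]
        assert row.n_acceptors == 2 and row.fraction_observed == 1.0

    def test_clustered_sites_flag_low_distance_bins(self):
        """Pocket-modified proteome: low-distance bins beat the random mean."""
        structures, paes, frames = {}, {}, []
        profiles, regions = {}, {}
        for i in range(8):
            s, p, prof, reg = _globule(300 + i, n=150)
            pid = s.protein_id
            structures[pid], paes[pid] = s, p
            profiles[pid], regions[pid] = prof, reg
            center = int(_pocket_sites(s, k=1)[0])
            frames.append(simulate_ptm_sites(
                s, prof,
                PTMSimSpec(p_modify_exposed=0.9, p_modify_buried=0.02,
                           cluster_center=center, cluster_radius=8.0, seed=i),
            ))
        ann, _ = annotate_sites(pd.concat(frames, ignore_index=True),
                                structures, profiles, regions)
        profile = global_proximity(
            ann, structures, paes, regions, "p", "p",
            ProximityConfig(n_randomizations=50, seed=1),
        )
        low = profile[(profile.bin_hi <= 10.0) & (profile.n_acceptors > 0)]
        assert ((low.fraction_observed > low.mean_random + 1.96 * low.sd_random)).any()

    def test_null_z_scores_mostly_small(self):
        rng = np.random.default_rng(2)
        n_tot, n_within = 0, 0
        for rep in range(10):
            structures, paes, frames = {}, {}, []
            profiles, regions = {}, {}
            for i in range(3):
                s, p, prof, reg = _globule(500 + rep * 10 + i, n=120)
                pid = s.protein_id
                structures[pid], paes[pid] = s, p
                profiles[pid], regions[pid] = prof, reg
                seq = np.array(list(s.sequence))
                acc = np.flatnonzero(np.isin(seq, list("STY"))) + 1
                sel = acc[rng.random(len(acc)) < 0.35]
                if len(sel):
                    frames.append(_site_frame(s, sel))
            ann, _ = annotate_sites(pd.concat(frames, ignore_index=True),
                                    structures, profiles, regions)
            profile = global_proximity(
                ann, structures, paes, regions, "p", "p",
                ProximityConfig(n_randomizations=50, seed=rep),
            )
            z = profile.z_score.to_numpy()
            z = z[np.isfinite(z)]
            n_tot += len(z)
            n_within += int((np.abs(z) < 3).sum())
        assert n_within / n_tot >= 0.95

    def test_seed_determinism(self):
        s, p, prof, reg = _globule(7, n=100)
        sites = _pocket_sites(s, k=4)
        ann, _ = annotate_sites(_site_frame(s, sites),
                                {s.protein_id: s}, {s.protein_id: prof},
                                {s.protein_id: reg})
        cfg = ProximityConfig(seed=99)
        p1 = global_proximity(ann, {s.protein_id: s}, {s.protein_id: p},
                              {s.protein_id: reg}, "p", "p", cfg)
        p2 = global_proximity(ann, {s.protein_id: s}, {s.protein_id: p},
                              {s.protein_id: reg}, "p", "p", cfg)
        pd.testing.assert_frame_equal(p1, p2)

    def test_no_sources_warns_and_returns_empty(self):
        s, p, prof, reg = _globule(8, n=60)
        ann = pd.DataFrame(columns=["protein_id", "position", "aa", "ptm_type",
                                    "regulatory"])
        with pytest.warns(UserWarning, match="no modified"):
            profile = global_proximity(ann, {s.protein_id: s}, {s.protein_id: p},
                                       {s.protein_id: reg}, "p", "p")
        assert profile.empty

    def test_colocalization_zero_bin_captures_shared_residue(self):
        """ub and ac on the same lysine compete in the leading 0 A bin."""
        s, p, prof, reg = _globule(9, n=120)
        seq = np.array(list(s.sequence))
        lys = np.flatnonzero(seq == "K") + 1
        assert len(lys) >= 2
        shared = lys[:2]
        ann, _ = annotate_sites(
            pd.concat([_site_frame(s, shared, "ub"), _site_frame(s, shared, "ac")],
                      ignore_index=True),
            {s.protein_id: s}, {s.protein_id: prof}, {s.protein_id: reg},
        )
        profile = global_proximity(ann, {s.protein_id: s}, {s.protein_id: p},
                                   {s.protein_id: reg}, "ub", "ac",
                                   ProximityConfig(seed=0))
        zero_bin = profile.iloc[0]
        assert zero_bin.bin_lo == 0.0
        assert zero_bin.n_modified == 2  # each ub site sees its own ac at 0 A


class TestClusterTest:
    def test_all_modified_degenerate_null_gives_p_one(self):
        s, p, prof, reg = _globule(10, n=80)
        seq = np.array(list(s.sequence))
        elig = np.flatnonzero(np.isin(seq, list("STY")) &
                              (~reg.idr_flags | reg.short_idr_mask())) + 1
        ann, _ = annotate_sites(_site_frame(s, elig), {s.protein_id: s},
                                {s.protein_id: prof}, {s.protein_id: reg})
        res = cluster_test(ann, s, p, reg, "p", n_permutations=200, seed=0)
        assert res.empirical_p == 1.0

    def test_pocket_detected(self):
        s, p, prof, reg = _globule(11, n=200)
        sites = _pocket_sites(s, radius=8.0, k=5)
        ann, _ = annotate_sites(_site_frame(s, sites), {s.protein_id: s},
                                {s.protein_id: prof}, {s.protein_id: reg})
        res = cluster_test(ann, s, p, reg, "p", n_permutations=10000, seed=0)
        assert res.n_sites == 5
        assert res.empirical_p <= 0.01

    def test_below_min_sites_skipped(self):
        s, p, prof, reg = _globule(12, n=100)
        sites = _pocket_sites(s, k=2)
        ann, _ = annotate_sites(_site_frame(s, sites), {s.protein_id: s},
                                {s.protein_id: prof}, {s.protein_id: reg})
        assert cluster_test(ann, s, p, reg, "p", min_sites=3, seed=0) is None
        frame, skipped = cluster_tests(ann, {s.protein_id: s}, {s.protein_id: p},
                                       {s.protein_id: reg}, "p", min_sites=3, seed=0)
        assert frame.empty and skipped == 1

    def test_empirical_p_never_zero_and_seed_stable(self):
        s, p, prof, reg = _globule(13, n=150)
        sites = _pocket_sites(s, k=4)
        ann, _ = annotate_sites(_site_frame(s, sites), {s.protein_id: s},
                                {s.protein_id: prof}, {s.protein_id: reg})
        r1 = cluster_test(ann, s, p, reg, "p", n_permutations=1000, seed=5)
        r2 = cluster_test(ann, s, p, reg, "p", n_permutations=1000, seed=5)
        assert r1.empirical_p == r2.empirical_p
        assert r1.empirical_p >= 1 / 1001

    def test_p_decreases_as_cluster_tightens(self):
        """Tighter simulated pockets give monotonically smaller p."""
        s, p, prof, reg = _globule(14, n=200)
        ps = []
        for radius in (20.0, 12.0, 6.0):
            seq = np.array(list(s.sequence))
            acc = np.flatnonzero(np.isin(seq, list("STY"))) + 1
            center = _pocket_sites(s, radius=radius, k=1)[0]
            d = np.linalg.norm(s.ca_xyz[acc - 1] - s.ca_xyz[center - 1], axis=1)
            sites = acc[np.argsort(d)][:5]
            ann, _ = annotate_sites(_site_frame(s, sites), {s.protein_id: s},
                                    {s.protein_id: prof}, {s.protein_id: reg})
            res = cluster_test(ann, s, p, reg, "p", n_permutations=5000, seed=3)
            ps.append(res.empirical_p)
        assert ps[0] >= ps[1] >= ps[2]

    def test_bh_across_proteins(self):
        structures, paes, frames = {}, {}, []
        profiles, regions = {}, {}
        for i in range(4):
            s, p, prof, reg = _globule(600 + i, n=120)
            pid = s.protein_id
            structures[pid], paes[pid] = s, p
            profiles[pid], regions[pid] = prof, reg
            frames.append(_site_frame(s, _pocket_sites(s, k=4)))
        ann, _ = annotate_sites(pd.concat(frames, ignore_index=True),
                                structures, profiles, regions)
        frame, skipped = cluster_tests(ann, structures, paes, regions, "p",
                                       n_permutations=1000, seed=0)
        assert len(frame) == 4
        assert (frame.adj_p >= frame.empirical_p - 1e-15).all()


def test_permutation_preserves_modification_counts():
    """Randomized backgrounds keep each protein's modification count."""
    s, p, prof, reg = _globule(15, n=100)
    seq = np.array(list(s.sequence))
    acc = np.flatnonzero(np.isin(seq, list("STY"))) + 1
    k = 6
    rng = np.random.default_rng(0)
    sel = rng.choice(acc, size=k, replace=False)
    # the background draw used by the profile: same count, eligible acceptors
    elig = acc[(~reg.idr_flags | reg.short_idr_mask())[acc - 1]]
    for _ in range(20):
        draw = rng.choice(elig, size=min(k, len(elig)), replace=False)
        assert len(np.unique(draw)) == min(k, len(elig))
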