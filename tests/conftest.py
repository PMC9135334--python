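import numpy as np
import pandas as pd
import pytest

from structptm.annotate import annotate_sites
from structptm.exposure import annotate_structure
from structptm.fixtures import SegmentSpec, make_chimera, standard_chimera
from structptm.io import PAEMatrix, StructureRecord


@pytest.fixture(scope="session")
def chimera():
    """Standard two-domain chimera with a 15-residue disordered linker."""
    return standard_chimera(seed=0)


@pytest.fixture(scope="session")
def globule200():
    return make_chimera(
        [SegmentSpec("globule", 200, intra_pae=2.0)], seed=5, protein_id="G200"
    )


@pytest.fixture(scope="session")
def helix30():
    return make_chimera([SegmentSpec("helix", 30)], seed=1, protein_id="H30")


def two_residue_structure(ca_distance: float = 10.0) -> StructureRecord:
    """Minimal hand-built structure: two residues along x."""
    ca = np.array([[0.0, 0.0, 0.0], [ca_distance, 0.0, 0.0]])
    n = ca + np.array([-1.0, 0.8, 0.0])
    c = ca + np.array([1.0, 0.8, 0.0])
    cb = ca + np.array([0.0, -1.2, 0.8])
    return StructureRecord(
        protein_id="TWO",
        sequence="AS",
        n_xyz=n,
        ca_xyz=ca,
        c_xyz=c,
        cb_xyz=cb,
        plddt=np.array([90.0, 90.0]),
    )


def uniform_pae(n: int, value: float) -> PAEMatrix:
    m = np.full((n, n), float(value))
    np.fill_diagonal(m, 0.0)
    return PAEMatrix(m)


def random_fixture(seed: int, max_len: int = 200):
    """Random multi-segment structure with a random asymmetric PAE matrix."""
    rng = np.random.default_rng(seed)
    kinds = ["helix", "coil", "globule"]
    n_seg = int(rng.integers(1, 4))
    lengths = rng.integers(8, max(9, max_len // n_seg), n_seg)
    total = int(lengths.sum())
    if total > max_len:
        lengths = np.maximum(8, (lengths * max_len / total).astype(int))
    segs = [
        SegmentSpec(kinds[int(rng.integers(3))], int(l), intra_pae=2.0, inter_pae=25.0)
        for l in lengths
    ]
    structure, _ = make_chimera(segs, seed=seed, protein_id=f"R{seed}")
    n = len(structure)
    pae_vals = rng.uniform(0.0, 20.0, (n, n))
    np.fill_diagonal(pae_vals, 0.0)
    return structure, PAEMatrix(pae_vals)


def annotated_proteome(structures, paes, ptm_frames):
    """Run the annotation pipeline on in-memory objects; returns the pieces
    the enrichment/proximity layers consume."""
    profiles, regions = {}, {}
    for pid in structures:
        prof, reg, _ = annotate_structure(structures[pid], paes.get(pid))
        profiles[pid] = prof
        regions[pid] = reg
    ptm = pd.concat(ptm_frames, ignore_index=True)
    ann, _ = annotate_sites(ptm, structures, profiles, regions)
    return ann, profiles, regions
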