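import numpy as np
import pytest

from ppikit.afm_io import ComplexModel, ScoreBundle


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_bundle(pae, ptm=0.8, iptm=0.7, plddt=None, pair_id="p", rank=1):
    pae = np.asarray(pae, dtype=float)
    if plddt is None:
        plddt = np.full(pae.shape[0], 80.0)
    return ScoreBundle(pair_id=pair_id, rank=rank, pae=pae, ptm=ptm, iptm=iptm, plddt=plddt)


def make_model(coords_a, coords_b, plddt=None, pair_id="p", rank=1):
    """ComplexModel straight from representative coordinates (all-ALA)."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    n = len(coords_a) + len(coords_b)
    if plddt is None:
        plddt = np.full(n, 80.0)
    return ComplexModel(
        pair_id=pair_id,
        rank=rank,
        chains=[("A", "A" * len(coords_a)), ("B", "A" * len(coords_b))],
        residue_coords=np.vstack([coords_a, coords_b]),
        plddt=np.asarray(plddt, dtype=float),
    )


@pytest.fixture
def random_inter_chain_case(rng):
    """Random 30-residue (18+12) PAE matrix plus a random contact map."""

    def _make(seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        n_a, n_b = 18, 12
        pae = r.uniform(0.0, 25.0, size=(30, 30))
        contacts = r.random((n_a, n_b)) < 0.3
        return make_bundle(pae), contacts, (0, n_a)

    return _make
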