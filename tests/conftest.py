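import numpy as np
import pytest

from ppikit.fixtures import FixtureSpec, make_toy_complex, make_toy_msa_pair
from ppikit.structure import ComplexStructure, Residue, read_complex


@pytest.fixture
def toy_spec():
    return FixtureSpec(seed=7, n_res_a=10, n_res_b=10, planted_contacts=5)


@pytest.fixture
def toy_native_path(tmp_path, toy_spec):
    path = tmp_path / "native.pdb"
    path.write_text(make_toy_complex(toy_spec))
    return path


@pytest.fixture
def toy_native(toy_native_path):
    return read_complex(toy_native_path)


@pytest.fixture
def toy_msa_paths(tmp_path):
    pair = make_toy_msa_pair(
        [9606, 10090, 7227, 562], [9606, 7227, 562, 4932], seed=11
    )
    pa, pb = tmp_path / "a.a3m", tmp_path / "b.a3m"
    pa.write_text(pair.a3m_a)
    pb.write_text(pair.a3m_b)
    return pa, pb, pair.expected_pairs


def _random_chain(rng, chain_id, n, spread):
    return [
        Residue(
            chain_id=chain_id,
            res_seq=i + 1,
            res_name="ALA",
            cb_coord=rng.uniform(-spread, spread, 3),
            plddt=float(rng.uniform(40.0, 98.0)),
        )
        for i in range(n)
    ]


@pytest.fixture
def random_complex_factory():
    """Random point-cloud complexes for brute-force oracle comparisons."""

    def make(seed, n_a=8, n_b=8, spread=12.0):
        rng = np.random.default_rng(seed)
        return ComplexStructure(
            _random_chain(rng, "A", n_a, spread),
            _random_chain(rng, "B", n_b, spread),
            source=f"random-{seed}",
        )

    return make


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    tran = rng.uniform(-30.0, 30.0, 3)
    return rot, tran


def transform_complex(cs: ComplexStructure, rot, tran) -> ComplexStructure:
    """Apply one rigid-body transform jointly to both chains."""

    def move(res: Residue) -> Residue:
        return Residue(
            chain_id=res.chain_id,
            res_seq=res.res_seq,
            res_name=res.res_name,
            cb_coord=res.cb_coord @ rot + tran,
            plddt=res.plddt,
            icode=res.icode,
            backbone_coords={
                k: v @ rot + tran for k, v in res.backbone_coords.items()
            },
            cb_source=res.cb_source,
        )

    return ComplexStructure(
        [move(r) for r in cs.chain_a],
        [move(r) for r in cs.chain_b],
        source=cs.source,
    )
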