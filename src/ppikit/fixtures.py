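"""Seeded generators for every input the toolkit consumes.

Everything here is synthetic and deterministic: toy two-chain PDB
complexes whose interface contact count is known by construction, decoy
series with a rigidly displaced ligand, per-chain a3m pairs with
controlled organism overlap, and (x, DockQ) samples drawn from the
pDockQ sigmoid.  The point is provability, not realism — chains are
laid out on a lattice so that an all-pairs 8 Å Cβ scan yields exactly
the planted number of contacts, and planted quantities are recovered
exactly by the corresponding analysis operation in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pdockq import PDockQParams, sigmoid

__all__ = [
    "FixtureSpec",
    "ToyMSAPair",
    "make_toy_complex",
    "make_decoy_series",
    "make_toy_msa_pair",
    "make_sigmoid_dataset",
]

_AA3 = "ALA"
_SPACING = 4.0  # Å between residues along a chain
_CONTACT_GAP = 7.5  # Å between paired Cβs across the interface (< 8)
_FAR_OFFSET = 10  # lattice steps separating non-contact residues

# One-letter amino-acid alphabet for toy sequences.
_AA1 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one toy complex; identical specs give identical bytes."""

    seed: int = 0
    n_res_a: int = 10
    n_res_b: int = 10
    planted_contacts: int = 5
    plddt_a: tuple[float, float] = (90.0, 0.0)  # mean, sd
    plddt_b: tuple[float, float] = (90.0, 0.0)
    displacement: float = 0.0  # extra Å pushed onto chain B

    def __post_init__(self) -> None:
        if self.planted_contacts > min(self.n_res_a, self.n_res_b):
            raise ValueError(
                "lattice geometry plants at most one contact per chain-B "
                f"residue: planted_contacts <= {min(self.n_res_a, self.n_res_b)}"
            )
        if self.planted_contacts < 0 or self.n_res_a < 1 or self.n_res_b < 1:
            raise ValueError("residue and contact counts must be non-negative")


@dataclass(frozen=True)
class ToyMSAPair:
    """Two a3m texts plus the pairing count they are built to produce."""

    a3m_a: str
    a3m_b: str
    expected_pairs: int


def _pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    res_seq: int,
    xyz: np.ndarray,
    bfactor: float,
) -> str:
    padded = f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {padded}{'':1s}{resname:>3s} {chain}"
        f"{res_seq:4d}{'':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{bfactor:6.2f}          {name[0]:>2s}"
    )


def _residue_lines(
    serial: int,
    chain: str,
    res_seq: int,
    ca: np.ndarray,
    bfactor: float,
    n_offset: np.ndarray,
) -> tuple[list[str], int]:
    # Backbone offsets keep N, CA, C, CB non-collinear; Cβ carries a
    # uniform offset so inter-chain Cβ distances equal lattice distances.
    atoms = {
        "N": ca + n_offset,
        "CA": ca,
        "C": ca + np.array([1.0, -0.8, -0.3]),
        "CB": ca + np.array([0.0, 1.0, 0.0]),
    }
    lines = []
    for name in ("N", "CA", "C", "CB"):
        lines.append(
            _pdb_atom_line(serial, name, _AA3, chain, res_seq, atoms[name], bfactor)
        )
        serial += 1
    return lines, serial


def make_toy_complex(spec: FixtureSpec) -> str:
    """Generate a two-chain PDB text with a planted interface.

    Chain A lies along x with 4 Å spacing.  The first
    ``planted_contacts`` residues of chain B sit 7.5 Å above their
    chain-A partners (one Cβ contact each: the diagonal neighbours are
    8.5 Å away); remaining B residues are shifted far along x so they
    contact nothing.  Chain B backbone N atoms dip toward chain A so
    that each planted residue pair also has one atom pair within 5 Å
    (a native contact under the stricter DockQ definition), again with
    no neighbour crosstalk.  B-factors are drawn per residue from the
    plDDT profiles, clipped to [0, 100].
    """
    rng = np.random.default_rng(spec.seed)
    plddts_a = np.clip(
        rng.normal(spec.plddt_a[0], spec.plddt_a[1], spec.n_res_a), 0, 100
    )
    plddts_b = np.clip(
        rng.normal(spec.plddt_b[0], spec.plddt_b[1], spec.n_res_b), 0, 100
    )
    lines: list[str] = []
    serial = 1
    n_off_a = np.array([-1.0, -0.8, 0.3])
    n_off_b = np.array([-1.0, -0.8, -3.0])  # dips to ~4.7 Å from partner CA
    for i in range(spec.n_res_a):
        ca = np.array([i * _SPACING, 0.0, 0.0])
        res_lines, serial = _residue_lines(
            serial, "A", i + 1, ca, plddts_a[i], n_off_a
        )
        lines.extend(res_lines)
    lines.append("TER")
    z_b = _CONTACT_GAP + spec.displacement
    for j in range(spec.n_res_b):
        if j < spec.planted_contacts:
            x = j * _SPACING
        else:
            x = (spec.n_res_a + _FAR_OFFSET + j) * _SPACING
        ca = np.array([x, 0.0, z_b])
        res_lines, serial = _residue_lines(
            serial, "B", j + 1, ca, plddts_b[j], n_off_b
        )
        lines.extend(res_lines)
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_decoy_series(
    native: str, offsets: Sequence[float], seed: int = 0, chain_b_id: str = "B"
) -> list[str]:
    """Decoys with the ligand chain rigidly translated along +z.

    ``offsets`` must be non-negative and ascending; offset 0 returns
    the native text unchanged.  Model quality against the native is
    non-increasing along the series.
    """
    if any(o < 0 for o in offsets) or list(offsets) != sorted(offsets):
        raise ValueError("offsets must be non-negative and ascending")
    decoys = []
    for offset in offsets:
        if offset == 0:
            decoys.append(native)
            continue
        out_lines = []
        for line in native.splitlines():
            if line.startswith(("ATOM", "HETATM")) and line[21] == chain_b_id:
                z = float(line[46:54]) + offset
                line = f"{line[:46]}{z:8.3f}{line[54:]}"
            out_lines.append(line)
        decoys.append("\n".join(out_lines) + "\n")
    return decoys


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(_AA1[rng.integers(len(_AA1))])
        else:
            out.append(ch)
    return "".join(out)


def make_toy_msa_pair(
    organisms_a: Sequence[int],
    organisms_b: Sequence[int],
    lengths: tuple[int, int] = (30, 25),
    seed: int = 0,
    mutation_rate: float = 0.15,
    gap_rate: float = 0.05,
) -> ToyMSAPair:
    """Two per-chain a3m texts with ``OX=`` headers from the given lists.

    Row 0 of each alignment is a random query; each organism in the
    list contributes one hit (a mutated, lightly gapped copy of the
    query).  ``expected_pairs`` is the number of organisms present in
    both lists, i.e. the number of non-query rows an organism pairing
    of the two alignments must produce.
    """
    if min(lengths) < 1:
        raise ValueError("chain lengths must be >= 1")
    rng = np.random.default_rng(seed)

    def build(tag: str, organisms: Sequence[int], length: int) -> str:
        query = "".join(_AA1[rng.integers(len(_AA1))] for _ in range(length))
        lines = [f">query_{tag}", query]
        for i, org in enumerate(organisms, start=1):
            hit = _mutate(rng, query, mutation_rate)
            hit = "".join(
                "-" if rng.random() < gap_rate else ch for ch in hit
            )
            lines.append(f">hit_{tag}{i} OX={org} toy")
            lines.append(hit)
        return "\n".join(lines) + "\n"

    return ToyMSAPair(
        a3m_a=build("a", organisms_a, lengths[0]),
        a3m_b=build("b", organisms_b, lengths[1]),
        expected_pairs=len(set(organisms_a) & set(organisms_b)),
    )


def make_sigmoid_dataset(
    params: PDockQParams,
    n: int,
    noise_sd: float,
    x_range: tuple[float, float] = (50.0, 250.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (x, DockQ) points from the pDockQ sigmoid plus noise.

    x is uniform on ``x_range``; DockQ is the sigmoid value plus
    Gaussian noise of the given sd, truncated to [0, 1] by clipping
    (DockQ is a bounded score; noisy values saturate at the bounds).
    """
    if n < 8:
        raise ValueError("need at least 8 points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    xs = rng.uniform(x_range[0], x_range[1], n)
    ys = sigmoid(xs, params.L, params.x0, params.k, params.b)
    if noise_sd > 0:
        ys = ys + rng.normal(0.0, noise_sd, n)
    return xs, np.clip(ys, 0.0, 1.0)
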