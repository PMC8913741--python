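"""Two-chain complex structures and interface metrics.

Predicted complex models store per-residue confidence (plDDT, 0-100) in
the PDB B-factor column.  The interface between the two chains is
defined on beta carbons: residue pairs from different chains whose
Cβ atoms lie within 8 Å are interface contacts, and every residue
participating in at least one contact is an interface residue.  From
these the module derives the confidence summaries used for model
ranking: the mean interface plDDT (IF_plDDT), the contact and residue
counts (IF_contacts, IF_residues), the whole-complex mean plDDT and the
minimum per-chain mean plDDT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

__all__ = [
    "Residue",
    "ComplexStructure",
    "InterfaceMetrics",
    "read_complex",
    "interface_contacts",
    "interface_metrics",
    "virtual_cbeta",
]

# Ideal-geometry reconstruction of Cβ from backbone N, CA, C.
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Place a virtual Cβ from backbone coordinates (ideal geometry)."""
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    ka, kb, kc = _CB_COEFF
    return ka * a + kb * b + kc * cvec + ca


@dataclass
class Residue:
    """One residue with its Cβ position and confidence.

    ``cb_source`` records where the Cβ came from: a deposited ``CB``
    atom, an ideal-geometry virtual atom built from N/CA/C (glycine and
    Cβ-less residues), or the CA position as a last resort.
    """

    chain_id: str
    res_seq: int
    res_name: str
    cb_coord: np.ndarray
    plddt: float
    icode: str = ""
    backbone_coords: dict[str, np.ndarray] = field(default_factory=dict)
    cb_source: Literal["atom", "virtual", "ca"] = "atom"

    @property
    def key(self) -> tuple[int, str]:
        """Residue identity within its chain (number + insertion code)."""
        return (self.res_seq, self.icode)


@dataclass
class ComplexStructure:
    """Two ordered chains of residues from one complex model or native."""

    chain_a: list[Residue]
    chain_b: list[Residue]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.chain_a or not self.chain_b:
            raise ValueError("both chains must contain at least one residue")
        if self.chain_a[0].chain_id == self.chain_b[0].chain_id:
            raise ValueError("chain IDs must be distinct")


@dataclass(frozen=True)
class InterfaceMetrics:
    """Interface counts and confidence averages for one complex model."""

    n_if_contacts: int
    n_if_residues: int
    if_plddt: float
    min_chain_plddt: float
    avg_plddt: float
    empty_interface: bool

    def as_dict(self) -> dict:
        return {
            "n_if_contacts": self.n_if_contacts,
            "n_if_residues": self.n_if_residues,
            "if_plddt": self.if_plddt,
            "min_chain_plddt": self.min_chain_plddt,
            "avg_plddt": self.avg_plddt,
            "empty_interface": self.empty_interface,
        }


def _extract_chain(chain, chain_id: str, strict: bool) -> list[Residue]:
    residues: list[Residue] = []
    for res in chain:
        hetflag, res_seq, icode = res.id
        if hetflag.strip():
            continue  # skip waters / heteroatoms
        backbone = {
            name: res[name].coord.astype(float)
            for name in ("N", "CA", "C")
            if name in res
        }
        has_cb = "CB" in res
        if strict and not has_cb:
            continue
        if has_cb:
            cb = res["CB"].coord.astype(float)
            source = "atom"
            plddt_atom = res["CB"]
        elif len(backbone) == 3:
            cb = virtual_cbeta(backbone["N"], backbone["CA"], backbone["C"])
            source = "virtual"
            plddt_atom = res["CA"]
        elif "CA" in res:
            cb = backbone["CA"].copy()
            source = "ca"
            plddt_atom = res["CA"]
        else:
            warnings.warn(
                f"chain {chain_id} residue {res_seq}{icode.strip()} has "
                "neither CB nor backbone atoms; skipped"
            )
            continue
        residues.append(
            Residue(
                chain_id=chain_id,
                res_seq=res_seq,
                res_name=res.get_resname(),
                cb_coord=cb,
                plddt=float(plddt_atom.bfactor),
                icode=icode.strip(),
                backbone_coords=backbone,
                cb_source=source,
            )
        )
    return residues


def read_complex(
    path: str | Path,
    chain_a_id: str = "A",
    chain_b_id: str = "B",
    strict: bool = False,
) -> ComplexStructure:
    """Read a two-chain complex from a PDB file.

    plDDT is taken from the B-factor column.  Glycines (and any residue
    lacking a deposited Cβ) get a virtual Cβ from ideal backbone
    geometry, falling back to the CA position; with ``strict=True``
    Cβ-less residues are excluded instead.  Only the first MODEL is
    read, and Bio.PDB resolves alternate locations to the
    highest-occupancy conformer.  A numbering gap between or within
    chains is tolerated.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(iter(structure))  # first MODEL only
    available = [c.id for c in model]
    for cid in (chain_a_id, chain_b_id):
        if cid not in available:
            raise ValueError(
                f"{path}: chain {cid!r} not found; available chains: "
                f"{available}"
            )
    chain_a = _extract_chain(model[chain_a_id], chain_a_id, strict)
    chain_b = _extract_chain(model[chain_b_id], chain_b_id, strict)
    return ComplexStructure(chain_a, chain_b, source=str(path))


def _cb_matrix(residues: list[Residue]) -> np.ndarray:
    return np.asarray([r.cb_coord for r in residues], dtype=float)


def interface_contacts(
    cs: ComplexStructure, cutoff: float = 8.0
) -> list[tuple[Residue, Residue, float]]:
    """All inter-chain residue pairs with Cβ-Cβ distance <= cutoff (Å).

    Each unordered pair appears once, ordered by (chain A index,
    chain B index).
    """
    dists = cdist(_cb_matrix(cs.chain_a), _cb_matrix(cs.chain_b))
    contacts = []
    for i, j in np.argwhere(dists <= cutoff):
        contacts.append((cs.chain_a[i], cs.chain_b[j], float(dists[i, j])))
    return contacts


def interface_metrics(
    cs: ComplexStructure, cutoff: float = 8.0
) -> InterfaceMetrics:
    """Summarise the inter-chain interface of one complex model.

    When the chains share no contacts the confidence average over the
    (empty) interface is undefined; it is carried as 0.0 with
    ``empty_interface`` set.
    """
    contacts = interface_contacts(cs, cutoff)
    if_res_a = {id(a): a for a, _, _ in contacts}
    if_res_b = {id(b): b for _, b, _ in contacts}
    n_if_residues = len(if_res_a) + len(if_res_b)

    plddt_a = np.array([r.plddt for r in cs.chain_a])
    plddt_b = np.array([r.plddt for r in cs.chain_b])
    avg_plddt = float(np.concatenate([plddt_a, plddt_b]).mean())
    min_chain_plddt = float(min(plddt_a.mean(), plddt_b.mean()))

    if contacts:
        if_vals = [r.plddt for r in if_res_a.values()]
        if_vals += [r.plddt for r in if_res_b.values()]
        if_plddt = float(np.mean(if_vals))
        empty = False
    else:
        if_plddt = 0.0
        empty = True
    return InterfaceMetrics(
        n_if_contacts=len(contacts),
        n_if_residues=n_if_residues,
        if_plddt=if_plddt,
        min_chain_plddt=min_chain_plddt,
        avg_plddt=avg_plddt,
        empty_interface=empty,
    )
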