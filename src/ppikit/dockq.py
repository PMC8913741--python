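"""Self-contained DockQ scoring of complex models against natives.

DockQ condenses the three CAPRI quality measures into one continuous
score in [0, 1]:

    DockQ = ( Fnat + 1/(1 + (iRMS/1.5)^2) + 1/(1 + (LRMS/8.5)^2) ) / 3

where Fnat is the fraction of native inter-chain contacts reproduced by
the model, iRMS is the backbone RMSD over native interface residues
after superposing on that interface, and LRMS is the ligand backbone
RMSD after superposing on the receptor.  A model with DockQ >= 0.23 is
"acceptable" in CAPRI terms.

Contacts are evaluated over the supplied atoms — backbone N, CA, C plus
Cβ — at 5 Å (native interface residues for iRMS at 10 Å), since
end-to-end predictors emit backbone-only structures.  This is a
documented approximation to the all-heavy-atom contact definition of
the reference implementation.  The receptor is the longer chain, the
ligand the shorter (ties: chain A is the receptor).

Model and native must share chain correspondence and residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial.distance import cdist

from .structure import ComplexStructure, Residue

__all__ = [
    "DockQResult",
    "DockQError",
    "combine_dockq",
    "superpose",
    "dockq_score",
    "FNAT_CUTOFF",
    "INTERFACE_CUTOFF",
    "ACCEPTABLE_THRESHOLD",
]

FNAT_CUTOFF = 5.0  # Å, contact definition for Fnat
INTERFACE_CUTOFF = 10.0  # Å, native interface definition for iRMS
ACCEPTABLE_THRESHOLD = 0.23
_IRMS_SCALE = 1.5  # Å
_LRMS_SCALE = 8.5  # Å
_BACKBONE = ("N", "CA", "C")


class DockQError(ValueError):
    """Raised for unmatched residue sets or a contact-free native."""


@dataclass(frozen=True)
class DockQResult:
    fnat: float
    lrms: float
    irms: float
    dockq: float
    acceptable: bool


def combine_dockq(fnat: float, irms: float, lrms: float) -> float:
    """Combine the three CAPRI components into the DockQ score."""
    return (
        fnat
        + 1.0 / (1.0 + (irms / _IRMS_SCALE) ** 2)
        + 1.0 / (1.0 + (lrms / _LRMS_SCALE) ** 2)
    ) / 3.0


def superpose(
    coords_fixed: np.ndarray, coords_moving: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of two point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_moving @ rotation + translation`` best fits
    ``coords_fixed``; the rotation is proper (det = +1).  Requires at
    least 3 non-collinear points in each set.
    """
    fixed = np.asarray(coords_fixed, dtype=float)
    moving = np.asarray(coords_moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3) with equal n")
    if len(fixed) < 3:
        raise ValueError("superposition requires at least 3 points")
    for pts in (fixed, moving):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError("degenerate (collinear) point set")
    sup = SVDSuperimposer()
    sup.set(fixed, moving)
    sup.run()
    rot, tran = sup.get_rotran()
    return rot, tran, float(sup.get_rms())


def _contact_atoms(res: Residue) -> np.ndarray:
    coords = [res.backbone_coords[a] for a in _BACKBONE if a in res.backbone_coords]
    coords.append(res.cb_coord)
    return np.asarray(coords, dtype=float)


def _residue_contacts(
    chain_a: list[Residue], chain_b: list[Residue], cutoff: float
) -> set[tuple[tuple, tuple]]:
    """Residue-pair keys with any supplied-atom distance <= cutoff."""
    atoms_a = [_contact_atoms(r) for r in chain_a]
    atoms_b = [_contact_atoms(r) for r in chain_b]
    flat_a = np.concatenate(atoms_a)
    flat_b = np.concatenate(atoms_b)
    idx_a = np.repeat(np.arange(len(chain_a)), [len(a) for a in atoms_a])
    idx_b = np.repeat(np.arange(len(chain_b)), [len(b) for b in atoms_b])
    close = cdist(flat_a, flat_b) <= cutoff
    pairs = set()
    ai_idx, bi_idx = np.nonzero(close)
    for ai, bi in zip(idx_a[ai_idx], idx_b[bi_idx]):
        pairs.add((chain_a[ai].key, chain_b[bi].key))
    return pairs


def _residue_map(chain: list[Residue]) -> dict[tuple, Residue]:
    return {r.key: r for r in chain}


def _check_matched(model: dict, native: dict, chain_label: str) -> None:
    missing = sorted(set(native) - set(model))
    extra = sorted(set(model) - set(native))
    if missing or extra:
        raise DockQError(
            f"chain {chain_label}: model/native residue sets differ; "
            f"missing from model: {missing[:10]}, extra in model: {extra[:10]}"
        )


def _backbone_pairs(
    model: dict[tuple, Residue], native: dict[tuple, Residue], keys
) -> tuple[np.ndarray, np.ndarray]:
    """Matched backbone coordinates (model, native) over given residues."""
    mc, nc = [], []
    for key in keys:
        rm, rn = model[key], native[key]
        for atom in _BACKBONE:
            if atom in rm.backbone_coords and atom in rn.backbone_coords:
                mc.append(rm.backbone_coords[atom])
                nc.append(rn.backbone_coords[atom])
    return np.asarray(mc, dtype=float), np.asarray(nc, dtype=float)


def dockq_score(
    model: ComplexStructure, native: ComplexStructure
) -> DockQResult:
    """Score a two-chain model against its native structure.

    Raises :class:`DockQError` if the residue numbering does not match
    between model and native, or if the native has no inter-chain
    contacts (there is no interface to score).
    """
    model_a, model_b = _residue_map(model.chain_a), _residue_map(model.chain_b)
    native_a, native_b = _residue_map(native.chain_a), _residue_map(native.chain_b)
    _check_matched(model_a, native_a, "A")
    _check_matched(model_b, native_b, "B")

    native_contacts = _residue_contacts(
        native.chain_a, native.chain_b, FNAT_CUTOFF
    )
    if not native_contacts:
        raise DockQError("native structure has no inter-chain contacts")
    model_contacts = _residue_contacts(
        model.chain_a, model.chain_b, FNAT_CUTOFF
    )
    fnat = len(native_contacts & model_contacts) / len(native_contacts)

    # iRMS: backbone RMSD over the native interface (10 Å definition)
    interface_pairs = _residue_contacts(
        native.chain_a, native.chain_b, INTERFACE_CUTOFF
    )
    if_keys_a = sorted({ka for ka, _ in interface_pairs})
    if_keys_b = sorted({kb for _, kb in interface_pairs})
    mc_a, nc_a = _backbone_pairs(model_a, native_a, if_keys_a)
    mc_b, nc_b = _backbone_pairs(model_b, native_b, if_keys_b)
    mc = np.concatenate([mc_a, mc_b])
    nc = np.concatenate([nc_a, nc_b])
    _, _, irms = superpose(nc, mc)

    # LRMS: superpose on the receptor, measure the ligand
    if len(native.chain_a) >= len(native.chain_b):
        rec_model, rec_native = model_a, native_a
        lig_model, lig_native = model_b, native_b
    else:
        rec_model, rec_native = model_b, native_b
        lig_model, lig_native = model_a, native_a
    rm, rn = _backbone_pairs(rec_model, rec_native, sorted(rec_native))
    rot, tran, _ = superpose(rn, rm)
    lm, ln = _backbone_pairs(lig_model, lig_native, sorted(lig_native))
    lm_fit = lm @ rot + tran
    lrms = float(np.sqrt(np.mean(np.sum((lm_fit - ln) ** 2, axis=1))))

    dockq = combine_dockq(fnat, irms, lrms)
    return DockQResult(
        fnat=fnat,
        lrms=lrms,
        irms=irms,
        dockq=dockq,
        acceptable=dockq >= ACCEPTABLE_THRESHOLD,
    )
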