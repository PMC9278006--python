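"""CAPRI-criteria assessment of docking models: fnat, I-RMSD, L-RMSD and class.

A model is compared to the experimentally determined (native) complex through a
residue mapping and graded into one of four accuracy classes — high, medium,
acceptable, incorrect — by the standard CAPRI decision table over three
structural-similarity metrics:

* fnat      — fraction of native cross-interface residue contacts (heavy-atom
              distance ≤ 5 Å) reproduced by the model;
* I-RMSD    — backbone RMSD over native interface residues (any heavy atom
              within 10 Å of the other partner) after superposing those residues;
* L-RMSD    — backbone RMSD over the ligand after superposing on the receptor.

Backbone means {N, CA, C, O}; all contacts use heavy atoms only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structures import (
    BACKBONE_ATOMS,
    ComplexStructure,
    ResidueKey,
    ResidueMapping,
    StructureError,
)

logger = logging.getLogger("complexqa")

FNAT_CONTACT_CUTOFF = 5.0      # Å, heavy-atom residue contact defining the interface
IRMSD_INTERFACE_CUTOFF = 10.0  # Å, native-interface residue selection for I-RMSD

CAPRI_CLASSES = ("high", "medium", "acceptable", "incorrect")
#: accuracy rank, higher is better
CLASS_RANK = {"incorrect": 0, "acceptable": 1, "medium": 2, "high": 3}


@dataclass
class ContactMap:
    pairs: frozenset[tuple[ResidueKey, ResidueKey]]
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CapriResult:
    fnat: float
    irmsd: float
    lrmsd: float
    capri_class: str
    n_native_contacts: int
    n_interface_residues: int

    def to_dict(self) -> dict:
        return {
            "fnat": self.fnat,
            "irmsd": self.irmsd,
            "lrmsd": self.lrmsd,
            "capri_class": self.capri_class,
            "n_native_contacts": self.n_native_contacts,
            "n_interface_residues": self.n_interface_residues,
        }


def _partner_atoms(complex_: ComplexStructure, partner: str) -> tuple[np.ndarray, list[ResidueKey]]:
    """Flat heavy-atom coordinate array with per-atom residue keys."""
    coords, keys = [], []
    for res in complex_.partner_residues(partner):
        for a in res.atoms:
            coords.append(a.position)
            keys.append(res.key)
    return np.asarray(coords, dtype=float), keys


def residue_contacts(complex_: ComplexStructure, cutoff: float = FNAT_CONTACT_CUTOFF) -> ContactMap:
    """All cross-partner residue pairs with any heavy-atom distance ≤ cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    r_xyz, r_keys = _partner_atoms(complex_, "receptor")
    l_xyz, l_keys = _partner_atoms(complex_, "ligand")
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    if len(r_xyz) and len(l_xyz):
        tree = cKDTree(l_xyz)
        for ri, lis in enumerate(tree.query_ball_point(r_xyz, cutoff)):
            for li in lis:
                pairs.add((r_keys[ri], l_keys[li]))
    return ContactMap(pairs=frozenset(pairs), cutoff=cutoff)


def fnat(
    model: ComplexStructure,
    native: ComplexStructure,
    mapping: ResidueMapping,
    cutoff: float = FNAT_CONTACT_CUTOFF,
) -> float:
    """Fraction of native residue contacts (at ``cutoff``) present in the model.

    Contacts are compared through the mapping, so model renumbering is
    irrelevant. Non-native contacts in the model do not count against it.
    """
    native_contacts = residue_contacts(native, cutoff)
    if not native_contacts.pairs:
        raise StructureError("no native interface: zero contacts at cutoff")
    n2m = mapping.native_to_model()
    model_contacts = residue_contacts(model, cutoff).pairs
    reproduced = sum(
        1
        for rk, lk in native_contacts.pairs
        if rk in n2m and lk in n2m and (n2m[rk], n2m[lk]) in model_contacts
    )
    return reproduced / len(native_contacts.pairs)


def kabsch_rmsd(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``moving @ rotation.T + translation`` best fits ``fixed`` with a proper
    rotation (det = +1), by the SVD formulation of the Kabsch algorithm.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if moving.shape[0] < 3:
        raise ValueError("at least 3 points are required")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    moved = moving @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return rot, trans, rmsd


def _native_interface_keys(native: ComplexStructure, cutoff: float) -> set[ResidueKey]:
    contacts = residue_contacts(native, cutoff)
    keys: set[ResidueKey] = set()
    for rk, lk in contacts.pairs:
        keys.add(rk)
        keys.add(lk)
    return keys


def _paired_backbone(
    model: ComplexStructure,
    native: ComplexStructure,
    mapping: ResidueMapping,
    native_keys: set[ResidueKey] | None = None,
    partner: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched backbone coordinates (model, native) over mapped residue pairs,
    optionally restricted to a native-key subset and/or one partner."""
    m_index = model.residue_index()
    n_index = native.residue_index()
    m_xyz, n_xyz = [], []
    for mk, nk in mapping.pairs:
        if native_keys is not None and nk not in native_keys:
            continue
        nr = n_index[nk]
        if partner is not None and native.partner_of(nr.chain_id) != partner:
            continue
        mr = m_index[mk]
        for name in BACKBONE_ATOMS:
            ma, na = mr.atom(name), nr.atom(name)
            if ma is not None and na is not None:
                m_xyz.append(ma.position)
                n_xyz.append(na.position)
    return np.asarray(m_xyz, dtype=float), np.asarray(n_xyz, dtype=float)


def irmsd(
    model: ComplexStructure,
    native: ComplexStructure,
    mapping: ResidueMapping,
    interface_cutoff: float = IRMSD_INTERFACE_CUTOFF,
) -> float:
    """Backbone RMSD over native interface residues after superposing them.

    The interface set is defined on the native only: residues of either
    partner with any heavy atom within ``interface_cutoff`` of the other
    partner.
    """
    keys = _native_interface_keys(native, interface_cutoff)
    m_xyz, n_xyz = _paired_backbone(model, native, mapping, native_keys=keys)
    if len(m_xyz) < 3:
        raise StructureError("fewer than 3 backbone atoms in the interface set")
    _, _, rmsd = kabsch_rmsd(m_xyz, n_xyz)
    return rmsd


def lrmsd(model: ComplexStructure, native: ComplexStructure, mapping: ResidueMapping) -> float:
    """Backbone RMSD over the ligand after superposing on the receptor backbone."""
    rec_m, rec_n = _paired_backbone(model, native, mapping, partner="receptor")
    if len(rec_m) < 3:
        raise StructureError("fewer than 3 receptor backbone atoms")
    rot, trans, _ = kabsch_rmsd(rec_m, rec_n)
    lig_m, lig_n = _paired_backbone(model, native, mapping, partner="ligand")
    if len(lig_m) == 0:
        raise StructureError("no ligand backbone atoms")
    moved = lig_m @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - lig_n) ** 2, axis=1))))


def classify_capri(fnat_value: float, lrmsd_value: float, irmsd_value: float) -> str:
    """CAPRI decision table, evaluated top-down (high, medium, acceptable)."""
    if not 0.0 <= fnat_value <= 1.0:
        raise ValueError(f"fnat {fnat_value} outside [0, 1]")
    if lrmsd_value < 0 or irmsd_value < 0:
        raise ValueError("RMSD values must be non-negative")
    if fnat_value >= 0.5 and (lrmsd_value <= 1.0 or irmsd_value <= 1.0):
        return "high"
    if fnat_value >= 0.3 and (lrmsd_value <= 5.0 or irmsd_value <= 2.0):
        return "medium"
    if fnat_value >= 0.1 and (lrmsd_value <= 10.0 or irmsd_value <= 4.0):
        return "acceptable"
    return "incorrect"


def assess(
    model: ComplexStructure,
    native: ComplexStructure,
    mapping: ResidueMapping,
    contact_cutoff: float = FNAT_CONTACT_CUTOFF,
    interface_cutoff: float = IRMSD_INTERFACE_CUTOFF,
) -> CapriResult:
    """Full CAPRI assessment of one model against one native complex."""
    native_contacts = residue_contacts(native, contact_cutoff)
    fn = fnat(model, native, mapping, contact_cutoff)
    ir = irmsd(model, native, mapping, interface_cutoff)
    lr = lrmsd(model, native, mapping)
    n_iface = len(_native_interface_keys(native, interface_cutoff))
    return CapriResult(
        fnat=fn,
        irmsd=ir,
        lrmsd=lr,
        capri_class=classify_capri(fn, lr, ir),
        n_native_contacts=len(native_contacts),
        n_interface_residues=n_iface,
    )
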