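"""Interface-restricted and global confidence metrics from predictor outputs.

Structure predictors emit a per-residue pLDDT (0–100, local accuracy), a pairwise
PAE matrix (predicted aligned error in Å; entry (i, j) is the expected error of
residue j when the model is aligned on residue i), and pTM/ipTM scalars. The
interface metrics restrict these to residues or residue pairs in atomic contact
across the receptor/ligand interface:

* interface pLDDT — mean per-residue pLDDT over interface residues; a model with
  no interface contacts at the cutoff scores 0.
* interface PAE — mean symmetrized PAE over contacting cross-partner residue
  pairs; a model with no contacts scores 35.

The contact cutoff defaults to 4 Å (heavy atoms), with 4–10 Å supported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structures import ComplexStructure, ResidueKey, ResidueMapping

logger = logging.getLogger("complexqa")

DEFAULT_INTERFACE_CUTOFF = 4.0
NO_CONTACT_PLDDT = 0.0
NO_CONTACT_PAE = 35.0

# key aliases covering common predictor JSON dialects
_PLDDT_KEYS = ("plddt", "pLDDT", "confidenceScore", "lddt")
_PAE_KEYS = ("pae", "predicted_aligned_error", "distance")
_PTM_KEYS = ("ptm", "pTM")
_IPTM_KEYS = ("iptm", "ipTM")


class ConfidenceError(ValueError):
    pass


@dataclass
class ConfidenceData:
    """Per-model confidence: pLDDT vector, PAE matrix, pTM/ipTM scalars."""

    plddt: np.ndarray | None = None
    pae: np.ndarray | None = None
    ptm: float | None = None
    iptm: float | None = None

    def __post_init__(self) -> None:
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if self.plddt.size and self.plddt.max() <= 1.0:
                logger.warning("pLDDT looks 0-1 scaled; rescaling to 0-100")
                self.plddt = self.plddt * 100.0
            if np.any(self.plddt < 0) or np.any(self.plddt > 100):
                raise ConfidenceError("pLDDT values outside [0, 100]")
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=float)
            if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
                raise ConfidenceError("PAE must be a square matrix")
            if np.any(self.pae < 0):
                raise ConfidenceError("PAE entries must be non-negative")
        for name, v in (("ptm", self.ptm), ("iptm", self.iptm)):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ConfidenceError(f"{name} {v} outside [0, 1]")


@dataclass
class InterfaceMetricResult:
    interface_plddt: float
    interface_pae: float
    cutoff: float
    n_interface_residues: int
    n_contact_pairs: int


def _first_key(obj: dict, keys: tuple[str, ...]):
    for k in keys:
        if k in obj:
            return obj[k]
    return None


def load_confidence(path: str | Path | None, model: ComplexStructure) -> ConfidenceData:
    """Load confidence data for ``model`` from a predictor JSON file.

    When ``path`` is None, the pLDDT is taken from the model's B-factor column
    (per-residue mean), the convention of predictor-written PDB files; PAE and
    pTM are then absent. JSON PAE may be nested lists or a flat row-major list.
    Vectors and the matrix must match the model's residue count and follow its
    residue order.
    """
    n = model.n_residues()
    if path is None:
        plddt = np.array([np.mean([a.bfactor for a in r.atoms]) for r in model.residues])
        return ConfidenceData(plddt=plddt)
    obj = json.loads(Path(path).read_text())
    if isinstance(obj, list):  # some dialects wrap the object in a 1-element list
        obj = obj[0]
    plddt = _first_key(obj, _PLDDT_KEYS)
    pae = _first_key(obj, _PAE_KEYS)
    ptm = _first_key(obj, _PTM_KEYS)
    iptm = _first_key(obj, _IPTM_KEYS)
    if plddt is not None:
        plddt = np.asarray(plddt, dtype=float)
        if plddt.shape != (n,):
            raise ConfidenceError(f"pLDDT length {plddt.shape} != residue count {n}")
    if pae is not None:
        pae = np.asarray(pae, dtype=float)
        if pae.ndim == 1:
            if pae.size != n * n:
                raise ConfidenceError(f"flat PAE size {pae.size} != {n}x{n}")
            pae = pae.reshape(n, n)
        if pae.shape != (n, n):
            raise ConfidenceError(f"PAE shape {pae.shape} != ({n}, {n})")
    return ConfidenceData(plddt=plddt, pae=pae,
                          ptm=None if ptm is None else float(ptm),
                          iptm=None if iptm is None else float(iptm))


def interface_residues(model: ComplexStructure, cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> set[ResidueKey]:
    """Residues of either partner with any cross-partner heavy-atom contact ≤ cutoff."""
    if not 4.0 <= cutoff <= 10.0:
        logger.warning("interface cutoff %.1f outside the usual 4-10 A range", cutoff)
    r_xyz, r_keys, l_xyz, l_keys = _partner_atom_arrays(model)
    out: set[ResidueKey] = set()
    if len(r_xyz) and len(l_xyz):
        tree = cKDTree(l_xyz)
        for ri, lis in enumerate(tree.query_ball_point(r_xyz, cutoff)):
            if lis:
                out.add(r_keys[ri])
                out.update(l_keys[li] for li in lis)
    return out


def _partner_atom_arrays(model: ComplexStructure):
    r_xyz, r_keys, l_xyz, l_keys = [], [], [], []
    for res in model.residues:
        part = model.partner_of(res.chain_id)
        for a in res.atoms:
            if part == "receptor":
                r_xyz.append(a.position)
                r_keys.append(res.key)
            else:
                l_xyz.append(a.position)
                l_keys.append(res.key)
    return (np.asarray(r_xyz, dtype=float), r_keys,
            np.asarray(l_xyz, dtype=float), l_keys)


def _contact_pairs(model: ComplexStructure, cutoff: float) -> set[tuple[ResidueKey, ResidueKey]]:
    r_xyz, r_keys, l_xyz, l_keys = _partner_atom_arrays(model)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    if len(r_xyz) and len(l_xyz):
        tree = cKDTree(l_xyz)
        for ri, lis in enumerate(tree.query_ball_point(r_xyz, cutoff)):
            for li in lis:
                pairs.add((r_keys[ri], l_keys[li]))
    return pairs


def interface_plddt(model: ComplexStructure, conf: ConfidenceData,
                    cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> float:
    """Mean pLDDT over interface residues; 0 when there are no contacts."""
    if conf.plddt is None:
        raise ConfidenceError("pLDDT not available")
    keys = interface_residues(model, cutoff)
    if not keys:
        return NO_CONTACT_PLDDT
    idx = {r.key: i for i, r in enumerate(model.residues)}
    return float(np.mean([conf.plddt[idx[k]] for k in keys]))


def interface_pae(model: ComplexStructure, conf: ConfidenceData,
                  cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> float:
    """Mean symmetrized PAE over contacting cross-partner residue pairs; 35 with no contacts.

    The PAE matrix is asymmetric; each contacting pair (i, j) contributes
    (pae[i, j] + pae[j, i]) / 2, making the metric independent of which partner
    is called receptor.
    """
    if conf.pae is None:
        raise ConfidenceError("PAE not available")
    pairs = _contact_pairs(model, cutoff)
    if not pairs:
        return NO_CONTACT_PAE
    idx = {r.key: i for i, r in enumerate(model.residues)}
    vals = [(conf.pae[idx[a], idx[b]] + conf.pae[idx[b], idx[a]]) / 2.0 for a, b in pairs]
    return float(np.mean(vals))


def interface_metrics(model: ComplexStructure, conf: ConfidenceData,
                      cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> InterfaceMetricResult:
    keys = interface_residues(model, cutoff)
    pairs = _contact_pairs(model, cutoff)
    return InterfaceMetricResult(
        interface_plddt=interface_plddt(model, conf, cutoff) if conf.plddt is not None else float("nan"),
        interface_pae=interface_pae(model, conf, cutoff) if conf.pae is not None else float("nan"),
        cutoff=cutoff,
        n_interface_residues=len(keys),
        n_contact_pairs=len(pairs),
    )


def average_plddt(conf: ConfidenceData) -> float:
    """Mean pLDDT over all residues."""
    if conf.plddt is None or conf.plddt.size == 0:
        raise ConfidenceError("pLDDT not available")
    return float(np.mean(conf.plddt))


def average_resolved_plddt(conf: ConfidenceData, model: ComplexStructure,
                           mapping: ResidueMapping) -> float:
    """Mean pLDDT over residues resolved in the native (i.e. paired in the mapping)."""
    if conf.plddt is None:
        raise ConfidenceError("pLDDT not available")
    mapped = {mk for mk, _ in mapping.pairs}
    idx = [i for i, r in enumerate(model.residues) if r.key in mapped]
    if not idx:
        raise ConfidenceError("no resolved residues in the mapping")
    return float(np.mean(conf.plddt[idx]))


def case_features(model: ComplexStructure,
                  cutoff: float = DEFAULT_INTERFACE_CUTOFF) -> tuple[int, int, float]:
    """(total residues, interface residues, percent of residues at the interface)."""
    total = model.n_residues()
    n_iface = len(interface_residues(model, cutoff))
    pct = 100.0 * n_iface / total if total else 0.0
    return total, n_iface, pct
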