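"""Parsing, representation and residue-level correspondence of binary protein complexes.

A complex is split into two partners (receptor and ligand chain sets). Model and
native structures are put into residue correspondence by per-chain global sequence
alignment — never by author numbering, which pipelines routinely shift (e.g. the
200-residue chain-break offset used when feeding two chains to a single-chain
predictor) — and pruned to the residues and atoms they share before any metric is
computed. Residues unresolved in the experimental structure are thereby removed
from the model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import Align

logger = logging.getLogger("complexqa")

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Three-letter -> one-letter, standard amino acids plus common modified residues
# that substitute a parent amino acid in crystal structures.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # parent-mapped non-standard residues
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K",
}

#: residue key: (chain_id, seq_number, insertion_code)
ResidueKey = tuple[str, int, str]


class StructureError(ValueError):
    """Raised for unusable or inconsistent structure input."""


@dataclass
class AtomRecord:
    """One heavy atom: name, element, position (Å), occupancy, B-factor, altloc.

    The B-factor column doubles as the per-residue pLDDT (0–100) in files written
    by structure predictors.
    """

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def backbone(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.name in BACKBONE_ATOMS]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class ComplexStructure:
    """A two-partner complex: receptor chains, ligand chains, ordered residues."""

    receptor_chains: tuple[str, ...]
    ligand_chains: tuple[str, ...]
    residues: list[Residue]
    label: str = ""

    def __post_init__(self) -> None:
        self.receptor_chains = tuple(self.receptor_chains)
        self.ligand_chains = tuple(self.ligand_chains)
        overlap = set(self.receptor_chains) & set(self.ligand_chains)
        if overlap:
            raise StructureError(f"chains {sorted(overlap)} assigned to both partners")
        known = set(self.receptor_chains) | set(self.ligand_chains)
        stray = {r.chain_id for r in self.residues} - known
        if stray:
            raise StructureError(f"residues from unassigned chains {sorted(stray)}")
        for part, chains in (("receptor", self.receptor_chains), ("ligand", self.ligand_chains)):
            if not any(r.chain_id in chains and r.backbone() for r in self.residues):
                raise StructureError(f"{part} partner has no residue with backbone atoms")

    def partner_of(self, chain_id: str) -> str:
        return "receptor" if chain_id in self.receptor_chains else "ligand"

    def partner_residues(self, partner: str) -> list[Residue]:
        chains = self.receptor_chains if partner == "receptor" else self.ligand_chains
        return [r for r in self.residues if r.chain_id in chains]

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain_residues(chain_id))

    def residue_index(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.residues}

    def n_residues(self) -> int:
        return len(self.residues)


@dataclass
class ResidueMapping:
    """One-to-one residue correspondence between a model and a native complex."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    model_only: list[ResidueKey]
    native_only: list[ResidueKey]
    chain_pairing: dict[str, str]

    def __post_init__(self) -> None:
        m_keys = [p[0] for p in self.pairs]
        n_keys = [p[1] for p in self.pairs]
        if len(set(m_keys)) != len(m_keys) or len(set(n_keys)) != len(n_keys):
            raise StructureError("residue mapping is not one-to-one")

    def model_to_native(self) -> dict[ResidueKey, ResidueKey]:
        return dict(self.pairs)

    def native_to_model(self) -> dict[ResidueKey, ResidueKey]:
        return {n: m for m, n in self.pairs}


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def read_pdb(
    path: str | Path,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
    label: str | None = None,
) -> ComplexStructure:
    """Read a PDB file into a two-partner :class:`ComplexStructure`.

    Only ATOM records of amino-acid residues in the named chains are kept
    (plus parent-mapped modified residues such as MSE, which some files write
    as HETATM). Hydrogens and waters are dropped. Alternate locations are
    resolved per atom name to the highest-occupancy conformer, ties broken by
    file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    wanted = set(receptor_chains) | set(ligand_chains)
    residues: list[Residue] = []
    seen_chains: set[str] = set()
    model = st[0]
    for chain in model:
        if chain.name not in wanted:
            continue
        seen_chains.add(chain.name)
        for res in chain:
            if res.name == "HOH" or res.name not in THREE_TO_ONE:
                continue
            # resolve altlocs: best occupancy per atom name, file order on ties
            best: dict[str, AtomRecord] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                rec = AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    bfactor=atom.b_iso,
                    altloc=atom.altloc if atom.altloc != "\0" else "",
                )
                prev = best.get(atom.name)
                if prev is None or rec.occupancy > prev.occupancy:
                    best[atom.name] = rec
            if not best:
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    res_name=res.name,
                    atoms=list(best.values()),
                )
            )
    missing = wanted - seen_chains
    if missing:
        raise StructureError(f"chains {sorted(missing)} not found in {path.name}")
    if not residues:
        raise StructureError(f"zero residues after filtering in {path.name}")
    return ComplexStructure(
        receptor_chains=tuple(receptor_chains),
        ligand_chains=tuple(ligand_chains),
        residues=residues,
        label=label if label is not None else path.stem,
    )


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write ATOM records (3-decimal coordinates, PDB fixed columns)."""
    lines = []
    serial = 0
    for res in structure.residues:
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {name}{a.altloc or ' '}{res.res_name:>3s} "
                f"{res.chain_id[:1]}{res.seq_number:>4d}{res.insertion_code or ' '}   "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{a.occupancy:6.2f}{a.bfactor:6.2f}          "
                f"{a.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Residue correspondence
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    # identity scoring with affine gaps
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def _align_chains(
    model_res: list[Residue], native_res: list[Residue]
) -> tuple[float, float, list[tuple[ResidueKey, ResidueKey]], set[ResidueKey], set[ResidueKey]]:
    """Globally align two chains' sequences; return (score, identity, pairs, m_only, n_only)."""
    seq_m = "".join(r.one_letter for r in model_res)
    seq_n = "".join(r.one_letter for r in native_res)
    aln = _aligner().align(seq_m, seq_n)[0]
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    m_paired: set[int] = set()
    n_paired: set[int] = set()
    n_ident = 0
    n_alncols = 0
    for (ms, me), (ns, ne) in zip(*aln.aligned):
        for mi, ni in zip(range(ms, me), range(ns, ne)):
            n_alncols += 1
            if seq_m[mi] == seq_n[ni] and seq_m[mi] != "X":
                n_ident += 1
                pairs.append((model_res[mi].key, native_res[ni].key))
                m_paired.add(mi)
                n_paired.add(ni)
    identity = n_ident / n_alncols if n_alncols else 0.0
    m_only = {r.key for i, r in enumerate(model_res) if i not in m_paired}
    n_only = {r.key for i, r in enumerate(native_res) if i not in n_paired}
    return aln.score, identity, pairs, m_only, n_only


def map_residues(model: ComplexStructure, native: ComplexStructure) -> ResidueMapping:
    """Assign model chains to native chains per partner and pair identical aligned residues.

    Chain assignment maximizes the summed global-alignment score over the
    (small) set of possible pairings within each partner. Aligned positions
    with identical amino-acid identity become pairs; everything else goes to
    the only-sets. A best pairing below 30% identity over aligned columns
    means the chains do not correspond.
    """
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    model_only: list[ResidueKey] = []
    native_only: list[ResidueKey] = []
    chain_pairing: dict[str, str] = {}

    for partner in ("receptor", "ligand"):
        m_chains = [c for c in (model.receptor_chains if partner == "receptor" else model.ligand_chains)
                    if model.chain_residues(c)]
        n_chains = [c for c in (native.receptor_chains if partner == "receptor" else native.ligand_chains)
                    if native.chain_residues(c)]
        if not m_chains or not n_chains:
            raise StructureError(f"{partner} partner is empty in one structure")
        # cache per chain-pair alignments
        cache = {
            (mc, nc): _align_chains(model.chain_residues(mc), native.chain_residues(nc))
            for mc in m_chains for nc in n_chains
        }
        k = min(len(m_chains), len(n_chains))
        best_assign = None
        best_score = -np.inf
        for m_sub in itertools.permutations(m_chains, k):
            for n_sub in itertools.combinations(n_chains, k):
                score = sum(cache[(mc, nc)][0] for mc, nc in zip(m_sub, n_sub))
                if score > best_score:
                    best_score = score
                    best_assign = list(zip(m_sub, n_sub))
        assert best_assign is not None
        assigned_m = {mc for mc, _ in best_assign}
        assigned_n = {nc for _, nc in best_assign}
        for mc, nc in best_assign:
            _, identity, ch_pairs, m_only, n_only = cache[(mc, nc)]
            if identity < 0.30:
                raise StructureError(
                    f"chain correspondence failed for {partner}: "
                    f"{mc}->{nc} identity {identity:.0%} < 30%"
                )
            chain_pairing[mc] = nc
            pairs.extend(ch_pairs)
            model_only.extend(sorted(m_only))
            native_only.extend(sorted(n_only))
        for mc in m_chains:
            if mc not in assigned_m:
                model_only.extend(r.key for r in model.chain_residues(mc))
        for nc in n_chains:
            if nc not in assigned_n:
                native_only.extend(r.key for r in native.chain_residues(nc))
    return ResidueMapping(pairs=pairs, model_only=model_only,
                          native_only=native_only, chain_pairing=chain_pairing)


def prune_to_common(
    model: ComplexStructure, native: ComplexStructure, mapping: ResidueMapping
) -> tuple[ComplexStructure, ComplexStructure]:
    """Restrict both structures to mapped residue pairs and, within each pair,
    to the intersection of atom names, in a consistent order."""
    m_index = model.residue_index()
    n_index = native.residue_index()
    new_m: list[Residue] = []
    new_n: list[Residue] = []
    for mk, nk in mapping.pairs:
        mr, nr = m_index[mk], n_index[nk]
        m_names = [a.name for a in mr.atoms]
        n_names = {a.name for a in nr.atoms}
        common = [nm for nm in m_names if nm in n_names]
        if not common:
            continue
        new_m.append(Residue(mr.chain_id, mr.seq_number, mr.insertion_code, mr.res_name,
                             [mr.atom(nm) for nm in common]))
        new_n.append(Residue(nr.chain_id, nr.seq_number, nr.insertion_code, nr.res_name,
                             [nr.atom(nm) for nm in common]))
    for part in ("receptor", "ligand"):
        m_chains = model.receptor_chains if part == "receptor" else model.ligand_chains
        if not any(r.chain_id in m_chains for r in new_m):
            raise StructureError(f"no common residues for {part} partner")
    pruned_model = ComplexStructure(model.receptor_chains, model.ligand_chains, new_m, model.label)
    pruned_native = ComplexStructure(native.receptor_chains, native.ligand_chains, new_n, native.label)
    return pruned_model, pruned_native
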