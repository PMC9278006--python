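"""Self-contained synthetic fixtures: toy complexes, decoy series, confidence maps.

The generator produces a two-chain native complex of idealized poly-alanine
α-helices (backbone N, CA, C, O built from literature-standard bond lengths,
bond angles and helical φ/ψ torsions), a graded series of rigid-body-perturbed
decoys with analytically known ligand RMSD (a pure translation of magnitude t
gives L-RMSD = t exactly), and fabricated confidence maps in which interface
pLDDT decreases and interface PAE increases with the model's true interface
RMSD, with a tunable noise level.

Perturbation magnitudes are mapped to CAPRI class bands empirically during
generation — the assessment itself is the arbiter — rather than assumed from
the class thresholds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import capri, confidence as conf_mod
from .structures import AtomRecord, ComplexStructure, Residue, ResidueMapping, map_residues, write_pdb

logger = logging.getLogger("complexqa")

# standard backbone geometry (Engh & Huber values) and α-helical torsions
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
PHI_HELIX = -57.0
PSI_HELIX = -47.0
OMEGA_TRANS = 180.0

# noiseless confidence model: anchors tied to true interface RMSD
PLDDT_CEILING = 95.0          # interface pLDDT of a perfect model
PLDDT_SLOPE = 5.0             # pLDDT lost per Å of interface RMSD
PLDDT_FLOOR = 20.0
PLDDT_BASELINE = 92.0         # non-interface residues
PAE_FLOOR = 0.25
PAE_SLOPE = 3.0               # Å of cross-chain PAE gained per Å of interface RMSD
PAE_CEILING = 32.0
PAE_INTRA = 1.5


@dataclass
class PerturbationSpec:
    """Rigid-body perturbation of the ligand: rotation about an axis through
    its centroid (degrees), then a translation (Å). A zero spec leaves the
    model identical to the native."""

    rotation_angle: float = 0.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0


@dataclass
class SyntheticCase:
    native: ComplexStructure
    models: list[tuple[ComplexStructure, PerturbationSpec, conf_mod.ConfidenceData]]
    truth: list[dict] = field(default_factory=list)  # expected lrmsd + class per model


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        return np.eye(3)
    x, y, z = axis / n
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension position of atom D from A-B-C internal coordinates."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_helix(n_res: int) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O) of an ideal poly-alanine α-helix."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = res[-1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"],
                             BOND_C_N, ANGLE_CA_C_N, PSI_HELIX)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next,
                              BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c_next = _place_atom(prev["C"], n_next, ca_next,
                             BOND_CA_C, ANGLE_N_CA_C, PHI_HELIX)
        # carbonyl O: anti to the next amide N across the peptide plane
        prev["O"] = _place_atom(prev["N"], prev["CA"], prev["C"],
                                BOND_C_O, ANGLE_CA_C_O, PSI_HELIX + 180.0)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    # final residue's O, with the helical psi continued
    res[-1]["O"] = _place_atom(res[-1]["N"], res[-1]["CA"], res[-1]["C"],
                               BOND_C_O, ANGLE_CA_C_O, PSI_HELIX + 180.0)
    return res


def _helix_coords(helix: list[dict[str, np.ndarray]]) -> np.ndarray:
    return np.array([xyz for r in helix for xyz in r.values()])


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _to_residues(helix: list[dict[str, np.ndarray]], chain_id: str,
                 bfactor: float = 90.0) -> list[Residue]:
    out = []
    for i, atoms in enumerate(helix, start=1):
        out.append(Residue(
            chain_id=chain_id, seq_number=i, insertion_code="", res_name="ALA",
            atoms=[AtomRecord(name=n, element=n[0], position=p, occupancy=1.0,
                              bfactor=bfactor) for n, p in atoms.items()],
        ))
    return out


def make_toy_complex(n_res_receptor: int = 16, n_res_ligand: int = 12,
                     gap: float = 3.4, seed: int = 0) -> ComplexStructure:
    """Two side-by-side ideal α-helices with the stated inter-chain gap.

    Chain A (receptor) and chain B (ligand) are parallel helices; chain B is
    rotated about its own axis by a seed-determined phase and shifted
    perpendicular to the helix axis until the minimum inter-chain heavy-atom
    distance is ≈ gap (within 0.05 Å). Deterministic under the seed.
    """
    if n_res_receptor < 5 or n_res_ligand < 5:
        raise ValueError("each chain needs at least 5 residues")
    rng = np.random.default_rng(seed)
    hel_a = _build_helix(n_res_receptor)
    hel_b = _build_helix(n_res_ligand)
    a_xyz = _helix_coords(hel_a)
    b_xyz = _helix_coords(hel_b)
    axis_a = _principal_axis(a_xyz)
    # spin B about its own axis by a random phase, then align its axis with A's
    axis_b = _principal_axis(b_xyz)
    spin = _rotation_matrix(axis_b, float(rng.uniform(0.0, 360.0)))
    b_center = b_xyz.mean(axis=0)
    b_xyz = (b_xyz - b_center) @ spin.T
    v = np.cross(axis_b, axis_a)
    s = np.linalg.norm(v)
    if s > 1e-12:
        angle = np.rad2deg(np.arctan2(s, float(np.dot(axis_b, axis_a))))
        b_xyz = b_xyz @ _rotation_matrix(v, angle).T
    # offset perpendicular to the shared axis, then relax to the target gap
    perp = np.cross(axis_a, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis_a, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    b_xyz = b_xyz + a_xyz.mean(axis=0) + perp * 10.0
    for _ in range(50):
        d = np.sqrt(((a_xyz[:, None, :] - b_xyz[None, :, :]) ** 2).sum(-1)).min()
        if abs(d - gap) < 0.05:
            break
        b_xyz = b_xyz + perp * (gap - d)
    # write back per-atom coordinates
    flat = iter(b_xyz)
    hel_b = [{n: next(flat) for n in r} for r in hel_b]
    residues = _to_residues(hel_a, "A") + _to_residues(hel_b, "B")
    return ComplexStructure(receptor_chains=("A",), ligand_chains=("B",),
                            residues=residues, label=f"toy_s{seed}")


def perturb(native: ComplexStructure, spec: PerturbationSpec) -> ComplexStructure:
    """Apply the rigid-body perturbation to the ligand; receptor untouched."""
    lig = native.partner_residues("ligand")
    centroid = np.mean([a.position for r in lig for a in r.atoms], axis=0)
    rot = _rotation_matrix(np.asarray(spec.axis, dtype=float), spec.rotation_angle)
    trans = np.asarray(spec.translation, dtype=float)
    new_res = []
    for res in native.residues:
        atoms = []
        for a in res.atoms:
            pos = a.position
            if native.partner_of(res.chain_id) == "ligand":
                pos = rot @ (pos - centroid) + centroid + trans
            atoms.append(AtomRecord(a.name, a.element, pos.copy(), a.occupancy,
                                    a.bfactor, a.altloc))
        new_res.append(Residue(res.chain_id, res.seq_number, res.insertion_code,
                               res.res_name, atoms))
    return ComplexStructure(native.receptor_chains, native.ligand_chains,
                            new_res, label=native.label + "_pert")


def fabricate_confidence(model: ComplexStructure, true_irmsd: float,
                         noise_sd: float = 0.0, seed: int = 0) -> conf_mod.ConfidenceData:
    """Confidence maps whose interface signal tracks the model's true accuracy.

    Interface-residue pLDDT is drawn around a linearly decreasing function of
    the true interface RMSD (ceiling 95, floor 20); cross-chain PAE around an
    increasing function (floor 0.25); non-interface pLDDT and intra-chain PAE
    sit at high-confidence baselines. ``noise_sd`` is the Gaussian SD added to
    pLDDT values (and, scaled by 0.3, to PAE entries); 0 gives the noiseless
    anchors exactly. pTM/ipTM are decreasing functions of the same RMSD.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = model.n_residues()
    iface = conf_mod.interface_residues(model, conf_mod.DEFAULT_INTERFACE_CUTOFF)
    base_iface = float(np.clip(PLDDT_CEILING - PLDDT_SLOPE * true_irmsd,
                               PLDDT_FLOOR, PLDDT_CEILING))
    plddt = np.full(n, PLDDT_BASELINE)
    for i, r in enumerate(model.residues):
        if r.key in iface:
            plddt[i] = base_iface
    plddt = np.clip(plddt + rng.normal(0.0, noise_sd, n) if noise_sd else plddt, 0.0, 100.0)

    base_cross = float(np.clip(PAE_FLOOR + PAE_SLOPE * true_irmsd, PAE_FLOOR, PAE_CEILING))
    chain_of = np.array([model.partner_of(r.chain_id) == "ligand" for r in model.residues])
    cross = chain_of[:, None] != chain_of[None, :]
    pae = np.where(cross, base_cross, PAE_INTRA)
    if noise_sd:
        pae = pae + rng.normal(0.0, 0.3 * noise_sd, (n, n))
    pae = np.clip(pae, PAE_FLOOR, 35.0)

    ptm = float(np.clip(0.92 - 0.04 * true_irmsd + (rng.normal(0.0, 0.005 * noise_sd) if noise_sd else 0.0), 0.05, 0.99))
    iptm = float(np.clip(0.90 - 0.06 * true_irmsd + (rng.normal(0.0, 0.005 * noise_sd) if noise_sd else 0.0), 0.02, 0.99))
    return conf_mod.ConfidenceData(plddt=plddt, pae=pae, ptm=ptm, iptm=iptm)


def _candidate_specs(rng: np.random.Generator, axis: np.ndarray) -> list[PerturbationSpec]:
    """Slides along the helix axis (graded degradation) plus a far separation."""
    specs = []
    for t in np.concatenate([np.arange(0.0, 10.01, 0.5), [12.0, 15.0, 20.0]]):
        specs.append(PerturbationSpec(translation=tuple(axis * t)))
    specs.append(PerturbationSpec(translation=tuple(axis * 30.0),
                                  rotation_angle=90.0))
    return specs


def generate_case(seed: int, models_per_case: int = 5, noise_sd: float = 0.0,
                  case_id: str = "case") -> tuple[SyntheticCase, ResidueMapping]:
    """One native plus a decoy set spanning the CAPRI classes where possible."""
    rng = np.random.default_rng(seed)
    native = make_toy_complex(seed=seed)
    native.label = case_id
    mapping = map_residues(native, native)  # identical sequences: identity mapping
    axis = _principal_axis(np.array([a.position for r in native.partner_residues("ligand")
                                     for a in r.atoms]))
    # assess the candidate grid; the assessment arbitrates class membership
    buckets: dict[str, list[tuple[PerturbationSpec, capri.CapriResult]]] = {
        c: [] for c in capri.CAPRI_CLASSES}
    for spec in _candidate_specs(rng, axis):
        model = perturb(native, spec)
        result = capri.assess(model, native, mapping)
        # incorrect decoys are kept clearly wrong (I-RMSD > 4 Å) and
        # better-than-incorrect decoys must retain a 4 Å interface, mirroring
        # real decoy sets where roughly-docked models genuinely touch;
        # borderline grid artifacts would blur the noiseless confidence signal
        if result.capri_class == "incorrect":
            if result.irmsd <= 4.0:
                continue
        elif not conf_mod.interface_residues(model, conf_mod.DEFAULT_INTERFACE_CUTOFF):
            continue
        buckets[result.capri_class].append((spec, result))
    chosen: list[tuple[PerturbationSpec, capri.CapriResult]] = []
    for c in capri.CAPRI_CLASSES:
        if buckets[c]:
            pick = buckets[c][rng.integers(len(buckets[c]))]
            chosen.append(pick)
    pool = [sc for b in buckets.values() for sc in b]
    while len(chosen) < models_per_case:
        chosen.append(pool[rng.integers(len(pool))])
    chosen = chosen[:models_per_case]

    models, truth = [], []
    for i, (spec, result) in enumerate(chosen):
        model = perturb(native, spec)
        model.label = f"{case_id}_m{i}"
        conf = fabricate_confidence(model, result.irmsd, noise_sd,
                                    seed=int(rng.integers(2**31)))
        models.append((model, spec, conf))
        truth.append({
            "expected_lrmsd": float(np.linalg.norm(spec.translation))
            if spec.rotation_angle == 0.0 else result.lrmsd,
            "expected_class": result.capri_class,
        })
    return SyntheticCase(native=native, models=models, truth=truth), mapping


def generate_benchmark(n_cases: int = 20, models_per_case: int = 5,
                       noise_sd: float = 0.0, seed: int = 0):
    """Full synthetic benchmark: cases plus the assembled per-model score table.

    Runs the CAPRI assessment and the confidence metrics end-to-end on every
    generated model, then ranks models within each case by pTM (rank 1 best).
    Returns ``(cases, ScoreTable)``.
    """
    from .discrimination import ScoreTable  # local import to avoid a cycle

    master = np.random.default_rng(seed)
    cases: list[SyntheticCase] = []
    rows = []
    for ci in range(n_cases):
        case_seed = int(master.integers(2**31))
        case, mapping = generate_case(case_seed, models_per_case, noise_sd,
                                      case_id=f"case{ci:03d}")
        cases.append(case)
        scored = []
        for model, spec, conf in case.models:
            result = capri.assess(model, native=case.native, mapping=mapping)
            scored.append({
                "case": case.native.label,
                "capri_class": result.capri_class,
                "fnat": result.fnat,
                "irmsd": result.irmsd,
                "lrmsd": result.lrmsd,
                "ptm": conf.ptm,
                "iptm": conf.iptm,
                "interface_plddt": conf_mod.interface_plddt(model, conf),
                "interface_pae": conf_mod.interface_pae(model, conf),
                "average_plddt": conf_mod.average_plddt(conf),
            })
        scored.sort(key=lambda r: -r["ptm"])
        for rank, row in enumerate(scored, start=1):
            row["rank"] = rank
            rows.append(row)
    frame = pd.DataFrame(rows)
    cols = ["case", "rank", "capri_class"] + [c for c in frame.columns
                                              if c not in ("case", "rank", "capri_class")]
    return cases, ScoreTable(frame[cols])


def write_fixture_dir(out_dir: str | Path, n_cases: int = 20,
                      models_per_case: int = 5, noise_sd: float = 0.0,
                      seed: int = 0) -> Path:
    """Emit PDB natives/models, confidence JSONs, score TSV and metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases, table = generate_benchmark(n_cases, models_per_case, noise_sd, seed)
    for case in cases:
        write_pdb(case.native, out / f"{case.native.label}_native.pdb")
        for model, spec, conf in case.models:
            write_pdb(model, out / f"{model.label}.pdb")
            payload = {
                "plddt": conf.plddt.tolist(),
                "pae": conf.pae.tolist(),
                "ptm": conf.ptm,
                "iptm": conf.iptm,
                "perturbation": asdict(spec),
            }
            (out / f"{model.label}_confidence.json").write_text(json.dumps(payload))
    table.to_tsv(out / "scores.tsv")
    (out / "metadata.json").write_text(json.dumps({
        "n_cases": n_cases, "models_per_case": models_per_case,
        "noise_sd": noise_sd, "seed": seed,
    }, indent=2))
    return out
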