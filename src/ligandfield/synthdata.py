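"""Seeded generators for every input class the pipeline consumes.

Real inputs to this kind of study — an aligned congeneric inhibitor series
with measured activities, crystal complexes of the target, conformer
libraries with known actives — are replaced by constructions with *planted
ground truth*:

* :func:`make_qsar_series` plants a linear activity model in lattice-field
  space: a rigid shared scaffold, variable substituents at fixed sites, and
  activities that are an exact linear function of similarity-field values
  at chosen hot-spot lattice points plus Gaussian noise;
* :func:`make_actives_decoys` builds conformers that match (actives) or
  violate (decoys) a given pharmacophore model;
* :func:`make_toy_complex` builds a pocket of pseudo-residues around a
  small ligand with a planted hydrogen bond and a buried apolar ring;
* :func:`make_toy_waterbox` / :func:`make_swap_system` build particle boxes
  for the swap free-energy simulator.

Every generator is a pure function of its arguments (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .chemio import AtomRecord, ComplexStructure, MoleculeRecord, assign_typing
from .fieldgen import GridSpec, ProbeSpec, assemble_field_matrix, build_grid
from .pharmacophore import Feature, PharmacophoreModel
from .waterswap import SwapState, ToyBox, select_identity_cluster

__all__ = [
    "SynthSpec",
    "make_qsar_series",
    "make_actives_decoys",
    "make_toy_complex",
    "make_toy_waterbox",
    "make_swap_system",
]

DEFAULT_SEED = 20210921

#: water-like single-site particle parameters shared by the toy boxes
WATER_LJ_RADIUS = 1.6
WATER_LJ_EPSILON = 0.155


@dataclass
class SynthSpec:
    """Recipe for a planted-truth congeneric series.

    ``effects`` maps hot spots to activity: each entry is (site index,
    field kind, weight in pIC50 per unit field value); the hot-spot lattice
    column is the grid point nearest the corresponding substituent site.
    """

    seed: int = DEFAULT_SEED
    n_molecules: int = 40
    noise_sigma: float = 0.2
    baseline: float = 7.0
    effects: tuple = ((0, "S", 3.0), (1, "E", -2.5), (2, "H", 2.0))

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


# scaffold: a rigid 6-ring in the xy plane; substituent sites stick out
_SCAFFOLD_RING_RADIUS = 1.4
_SITE_OFFSETS = (
    np.array([3.2, 0.0, 0.0]),
    np.array([-1.6, 2.8, 0.0]),
    np.array([-1.6, -2.8, 0.0]),
)

# substituent variants: (element, partial charge); hydrophobicity follows
# the typing table (apolar carbon vs charged heteroatom)
_VARIANTS = (
    ("C", 0.0),
    ("C", 0.0),       # doubled weight for the apolar variant
    ("O", -0.4),
    ("N", 0.35),
    ("S", -0.05),
)


def _scaffold_atoms() -> list[AtomRecord]:
    atoms = []
    for k in range(6):
        ang = np.pi / 3 * k
        xyz = _SCAFFOLD_RING_RADIUS * np.array([np.cos(ang), np.sin(ang), 0.0])
        atoms.append(AtomRecord("C", xyz, 0.0))
    return atoms


def make_qsar_series(spec: SynthSpec | None = None,
                     probe: ProbeSpec | None = None
                     ) -> tuple[list[MoleculeRecord], dict]:
    """Aligned congeneric series with activities linear in field values.

    Returns (molecules, truth).  ``truth`` records the lattice grid, the
    hot-spot column index, field kind and weight of every planted effect,
    and the noise-free activities, so recovery tests can check both fit
    quality and coefficient signs.
    """
    spec = spec or SynthSpec()
    if spec.n_molecules < 10:
        raise ValueError("need at least 10 molecules")
    rng = np.random.default_rng(spec.seed)
    probe = probe or ProbeSpec()

    mols: list[MoleculeRecord] = []
    for i in range(spec.n_molecules):
        atoms = _scaffold_atoms()
        for site, offset in enumerate(_SITE_OFFSETS):
            if rng.random() < 0.25:     # substituent absent
                continue
            elem, q = _VARIANTS[rng.integers(0, len(_VARIANTS))]
            atoms.append(AtomRecord(elem, offset, q))
            # small apolar decoration so hydrophobic sites form clusters
            if elem == "C" and rng.random() < 0.5:
                atoms.append(AtomRecord("C", offset + np.array([0.0, 0.0, 1.5]), 0.0))
        mol = MoleculeRecord(f"syn{i:03d}", atoms)
        assign_typing(mol)
        mols.append(mol)

    grid = build_grid(mols, spacing=2.0, margin=4.0)
    pts = grid.points()
    fm = assemble_field_matrix(mols, grid, probe, method="comsia", scale=False)

    effects = []
    y_true = np.full(spec.n_molecules, float(spec.baseline))
    for site, kind, weight in spec.effects:
        center = _SITE_OFFSETS[site]
        col = int(np.argmin(np.linalg.norm(pts - center, axis=1)))
        if not (np.linalg.norm(pts[col] - center) <= grid.spacing * np.sqrt(3)):
            raise ValueError("effect region lies outside the generated grid")
        x = fm.blocks[kind][:, col]
        y_true += weight * x
        effects.append({"site": site, "field": kind, "column": col,
                        "weight": float(weight)})
    noise = rng.normal(0.0, spec.noise_sigma, size=spec.n_molecules)
    for mol, y0, e in zip(mols, y_true, noise):
        mol.activity = float(y0 + e)
    truth = {
        "grid": grid,
        "effects": effects,
        "y_true": y_true,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    return mols, truth


# ---------------------------------------------------------------------------
# pharmacophore validation sets


def _feature_atoms(feature: Feature, center: np.ndarray,
                   rng: np.random.Generator) -> list[AtomRecord]:
    """Atoms realising one feature at ``center`` in a conformer."""
    if feature.kind == "HBD":
        # donor nitrogen plus its hydrogen
        h_dir = rng.normal(size=3)
        h_dir /= np.linalg.norm(h_dir)
        return [AtomRecord("N", center, 0.3),
                AtomRecord("H", center + 0.95 * h_dir, 0.15)]
    if feature.kind == "HBA":
        return [AtomRecord("O", center, -0.4)]
    if feature.kind == "HY":
        # triangle of apolar carbons whose centroid is the feature point
        out = []
        for k in range(3):
            ang = 2 * np.pi * k / 3
            out.append(AtomRecord(
                "C", center + 0.87 * np.array([np.cos(ang), np.sin(ang), 0.0]), 0.0))
        return out
    raise ValueError(feature.kind)


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-20, 20, size=3)
    return R, t


def make_actives_decoys(model: PharmacophoreModel, n_act: int, n_dec: int,
                        seed: int = 0, jitter: float | None = None,
                        n_conformers: int = 2
                        ) -> tuple[list[MoleculeRecord], dict[str, int]]:
    """Labelled conformer library for screening validation.

    Actives place one candidate point per core feature within
    ``jitter`` (< tolerance/2) of its center; every decoy displaces one
    feature far outside tolerance, and some additionally park an extra atom
    inside an exclusion volume.  All conformers receive a random rigid
    transform.  Returns (conformers, labels) with labels 1 = active,
    0 = decoy.
    """
    core = model.core_features
    if len(core) < 3:
        raise ValueError("model must carry at least 3 core features")
    rng = np.random.default_rng(seed)
    min_tol = min(f.tolerance for f in core)
    if jitter is None:
        jitter = 0.25 * min_tol
    if not jitter < min_tol / 2:
        raise ValueError("jitter must stay below tolerance/2")

    conformers: list[MoleculeRecord] = []
    labels: dict[str, int] = {}

    def build(mol_id: str, displace: int | None, poison_xvol: bool) -> None:
        for c in range(n_conformers):
            atoms: list[AtomRecord] = []
            for k, f in enumerate(core):
                center = f.center + rng.normal(0, jitter / 3, size=3)
                if displace is not None and k == displace:
                    # displace away from the nearest other feature so the
                    # pairwise distance grows by the full 4x tolerance: a
                    # rigid fit preserves candidate distances, so two
                    # features would have to absorb the discrepancy against
                    # a combined 2x tolerance budget (a random direction
                    # can land on a near-congruent mirror image instead)
                    others = [g.center for j, g in enumerate(core) if j != k]
                    nearest = min(others,
                                  key=lambda c: np.linalg.norm(f.center - c))
                    direction = f.center - nearest
                    direction = direction / np.linalg.norm(direction)
                    center = f.center + 4.0 * f.tolerance * direction
                atoms.extend(_feature_atoms(f, center, rng))
            if poison_xvol and model.exclusion_volumes:
                xv = model.exclusion_volumes[rng.integers(0, len(model.exclusion_volumes))]
                atoms.append(AtomRecord("C", xv.center, 0.0))
            R, t = _random_rigid(rng)
            for a in atoms:
                a.coords = a.coords @ R.T + t
            mol = MoleculeRecord(mol_id, atoms)
            assign_typing(mol)
            conformers.append(mol)

    for i in range(n_act):
        mol_id = f"act{i:03d}"
        build(mol_id, displace=None, poison_xvol=False)
        labels[mol_id] = 1
    for i in range(n_dec):
        mol_id = f"dec{i:03d}"
        # the displaced feature is what guarantees failure: an alignment may
        # legally twist by up to the feature tolerance (1.5), which exceeds
        # the exclusion radius (1.2), so a planted clash atom alone cannot.
        # Some decoys additionally carry an atom inside an exclusion volume
        # to keep that code path exercised on realistic poses.
        poison = bool(model.exclusion_volumes) and rng.random() < 0.3
        build(mol_id, displace=int(rng.integers(0, len(core))),
              poison_xvol=poison)
        labels[mol_id] = 0
    return conformers, labels


# ---------------------------------------------------------------------------
# toy complexes


@dataclass
class PocketResidue:
    res_name: str = "ALA"
    charge: float = 0.0
    hydrophobic: bool = True


DEFAULT_POCKET = tuple(
    PocketResidue("LEU" if k % 3 else "GLU", -0.4 if k % 3 == 0 else 0.0,
                  k % 3 != 0)
    for k in range(8)
)


def make_toy_complex(seed: int = 0,
                     pocket: Sequence[PocketResidue] = DEFAULT_POCKET,
                     n_frames: int = 0, frame_jitter: float = 0.0,
                     hbond_distance: float = 2.9,
                     hbond_angle_deg: float = 170.0) -> ComplexStructure:
    """Pocket of pseudo-residues around a ligand with planted interactions.

    The ligand is an apolar six-ring (one hydrophobic centroid) with an
    exocyclic N-H donor and an exocyclic carbonyl-like O acceptor; the
    first pocket residue carries the acceptor oxygen placed at
    ``hbond_distance`` with the requested D-H...A angle, and an N-H donor
    group points at the ligand oxygen.
    Residues are rings of carbon pseudo-atoms; a buried carbon below the
    ring keeps the hydrophobic centroid in protein contact.  Optional
    frames add Gaussian coordinate jitter (sigma = ``frame_jitter``).
    """
    rng = np.random.default_rng(seed)
    # ligand
    lig_atoms = _scaffold_atoms()
    n_pos = np.array([3.2, 0.0, 0.0])
    lig_atoms.append(AtomRecord("N", n_pos, -0.3))
    h_pos = n_pos + np.array([0.95, 0.0, 0.0])
    lig_atoms.append(AtomRecord("H", h_pos, 0.3))
    o_lig = np.array([-1.6, 2.8, 0.0])
    lig_atoms.append(AtomRecord("O", o_lig, -0.4))
    ligand = MoleculeRecord("TLG", lig_atoms)
    assign_typing(ligand)

    # acceptor position from the planted geometry: angle at H between N and O
    theta = np.deg2rad(180.0 - hbond_angle_deg)
    # distance is donor-heavy (N) to acceptor (O)
    # place O in the xz plane at the requested N-O distance and N-H...O angle
    d_ho = None
    # solve |N O| = hbond_distance with O = H + r*(cos t, 0, sin t)
    nh = float(np.linalg.norm(h_pos - n_pos))
    a = 1.0
    b = -2.0 * nh * np.cos(np.pi - theta)
    c = nh ** 2 - hbond_distance ** 2
    d_ho = (-b + np.sqrt(b * b - 4 * a * c)) / 2
    o_pos = h_pos + d_ho * np.array([np.cos(theta), 0.0, np.sin(theta)])

    protein: list[AtomRecord] = []

    def add_atom(elem, xyz, q, name, resnum, resname):
        protein.append(AtomRecord(elem, np.asarray(xyz, dtype=float), q,
                                  name=name, chain="A", res_name=resname,
                                  res_number=resnum))

    for r, res in enumerate(pocket, start=1):
        if r == 1:
            # acceptor residue: backbone carbon + acceptor oxygen
            add_atom("C", o_pos + np.array([1.4, 0.0, 0.6]), 0.2, "CA", r, res.res_name)
            add_atom("O", o_pos, res.charge or -0.4, "O", r, res.res_name)
            continue
        ang = 2 * np.pi * (r - 1) / len(pocket)
        base = 6.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
        add_atom("C", base, res.charge if not res.hydrophobic else 0.0, "CA",
                 r, res.res_name)
        add_atom("C", base * 1.12, 0.0, "CB", r, res.res_name)
    # buried carbon keeping the apolar ring in protein contact
    add_atom("C", [0.0, 0.0, -4.0], 0.0, "CG", len(pocket) + 1, "LEU")
    # protein donor N-H pointing straight at the ligand acceptor oxygen
    dn_pos = o_lig + np.array([0.0, 2.9, 0.0])
    add_atom("N", dn_pos, -0.3, "ND", len(pocket) + 2, "ASN")
    add_atom("H", dn_pos - np.array([0.0, 0.95, 0.0]), 0.3, "HD",
             len(pocket) + 2, "ASN")

    cx = ComplexStructure(protein, ligand)
    if n_frames:
        ref = cx.frame_coords(None)
        frames = [ref + rng.normal(0.0, frame_jitter, size=ref.shape)
                  for _ in range(n_frames)]
        cx = ComplexStructure(protein, ligand, frames)
    return cx


# ---------------------------------------------------------------------------
# swap-system boxes


def make_toy_waterbox(seed: int, n_waters: int,
                      box: tuple[float, float, float] = (18.0, 18.0, 18.0),
                      min_separation: float = 2.6,
                      charge: float = 0.0) -> ToyBox:
    """Non-overlapping single-site waters in a periodic box."""
    rng = np.random.default_rng(seed)
    L = np.asarray(box, dtype=float)
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < n_waters:
        attempts += 1
        if attempts > 200 * max(n_waters, 1):
            raise ValueError("box too full for the requested water count")
        trial = rng.uniform(0, 1, size=3) * L
        ok = True
        for c in coords:
            d = trial - c
            d -= np.round(d / L) * L
            if np.linalg.norm(d) < min_separation:
                ok = False
                break
        if ok:
            coords.append(trial)
    n = len(coords)
    coords = np.asarray(coords) if n else np.empty((0, 3))
    return ToyBox(coords, np.full(n, WATER_LJ_RADIUS),
                  np.full(n, WATER_LJ_EPSILON), np.full(n, charge),
                  np.full(n, "water", dtype=object), tuple(L), periodic=True)


def make_swap_system(seed: int = 0, n_waters: int = 12,
                     symmetric: bool = False,
                     box: tuple[float, float, float] = (18.0, 18.0, 18.0)
                     ) -> SwapState:
    """A small two-box swap system with the cluster already selected.

    With ``symmetric=True`` the 'ligand' is a single water-like particle, so
    swapping it against its one-water cluster is a null transformation with
    zero free-energy change by construction.
    """
    wb = make_toy_waterbox(seed + 1, n_waters + 1, box)
    pb_solvent = make_toy_waterbox(seed + 2, n_waters, box)
    L = np.asarray(box)
    center = L / 2.0
    if symmetric:
        lig_coords = np.array([center])
        lig_rad = [WATER_LJ_RADIUS]
        lig_eps = [WATER_LJ_EPSILON]
        lig_q = [0.0]
    else:
        lig_coords = center + np.array([[0.0, 0.0, 0.0], [1.6, 0.0, 0.0]])
        lig_rad = [1.7, 1.7]
        lig_eps = [0.107, 0.107]
        lig_q = [0.25, -0.25]
    # drop solvent overlapping the ligand
    keep = np.array([
        all(np.linalg.norm(((c - lc) - np.round((c - lc) / L) * L)) > 2.6
            for lc in lig_coords)
        for c in pb_solvent.coords])
    sol = pb_solvent.coords[keep] if keep.size else np.empty((0, 3))
    n_sol = sol.shape[0]
    n_lig = lig_coords.shape[0]
    pb = ToyBox(
        np.vstack([lig_coords, sol]),
        np.concatenate([lig_rad, np.full(n_sol, WATER_LJ_RADIUS)]),
        np.concatenate([lig_eps, np.full(n_sol, WATER_LJ_EPSILON)]),
        np.concatenate([lig_q, np.zeros(n_sol)]),
        np.array(["ligand"] * n_lig + ["water"] * n_sol, dtype=object),
        tuple(L), periodic=True)
    state = SwapState(pb, wb, np.empty(0, dtype=int), 0.0)
    state.cluster_ids = select_identity_cluster(state)
    return state
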