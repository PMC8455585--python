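"""Structure-based pharmacophore perception, merging and screening.

A pharmacophore model is a set of typed 3D features — hydrophobic (HY),
hydrogen-bond donor (HBD), hydrogen-bond acceptor (HBA) — plus exclusion
volumes (XVOL) marking protein bulk.  Features are perceived directly from a
protein-ligand complex with conventional geometric gates (H-bond heavy-atom
distance <= 3.5 A and D-H...A angle >= 130 degrees; hydrophobic centroids of
>= 3 connected apolar carbons within 4.5 A of protein carbons).  Models from
several complexes of one target can be merged into a shared model; the
shared model screens conformer libraries by least-squares superposition of
candidate feature points onto the model, with an exclusion-volume clash
check and a fit score of ``10 * n_matched - sum(d / tolerance)``.

Screening quality is quantified by the rank-sum ROC AUC, enrichment factors
and per-dataset hit rates.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import json
import numpy as np

from .chemio import (ComplexStructure, MoleculeRecord, assign_typing,
                     infer_bonds)

logger = logging.getLogger(__name__)

__all__ = [
    "Feature",
    "PharmacophoreModel",
    "ScreenHit",
    "perceive_features",
    "merge_models",
    "match_conformer",
    "screen_library",
    "roc_auc",
    "enrichment",
    "hit_rate",
]

# geometric gates and tolerances (conventional defaults, configurable)
HBOND_DISTANCE_MAX = 3.5        # donor-heavy to acceptor, Angstrom
HBOND_ANGLE_MIN = 130.0         # D-H...A, degrees
HYDROPHOBIC_CONTACT_MAX = 4.5   # centroid to protein carbon
HYDROPHOBIC_MIN_CLUSTER = 3     # connected apolar carbons per centroid
XVOL_CONTACT_MAX = 5.0          # protein heavy atom near any ligand atom
XVOL_FEATURE_CLEARANCE = 2.0    # minimum distance from non-XVOL centers
XVOL_RADIUS = 1.2
FEATURE_TOLERANCE = 1.5
MATCH_SCORE_PER_FEATURE = 10.0


@dataclass
class Feature:
    kind: str                       # HY | HBD | HBA | XVOL
    center: np.ndarray
    tolerance: float = FEATURE_TOLERANCE
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("HY", "HBD", "HBA", "XVOL"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.center = np.asarray(self.center, dtype=float)
        if self.tolerance <= 0:
            raise ValueError("feature tolerance must be positive")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = np.linalg.norm(d)
            self.direction = d / n if n > 0 else None


@dataclass
class PharmacophoreModel:
    features: list[Feature]
    source_complex_ids: list[str] = dc_field(default_factory=list)
    name: str = "pharmacophore"

    @property
    def core_features(self) -> list[Feature]:
        return [f for f in self.features if f.kind != "XVOL"]

    @property
    def exclusion_volumes(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "XVOL"]

    @property
    def screenable(self) -> bool:
        return len(self.core_features) >= 3

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "source_complex_ids": self.source_complex_ids,
            "features": [{
                "kind": f.kind,
                "center": f.center.tolist(),
                "tolerance": f.tolerance,
                "direction": None if f.direction is None else f.direction.tolist(),
            } for f in self.features],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreModel":
        d = json.loads(text)
        feats = [Feature(f["kind"], f["center"], f["tolerance"], f.get("direction"))
                 for f in d["features"]]
        return cls(feats, d.get("source_complex_ids", []), d.get("name", "pharmacophore"))


@dataclass
class ScreenHit:
    molecule_id: str
    conformer_index: int
    fit_score: float
    matched_feature_ids: list[int]
    alignment_rmsd: float


# ---------------------------------------------------------------------------
# geometry helpers


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) minimizing ||R P + t - Q|| over rows."""
    Pc = P.mean(axis=0)
    Qc = Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    return R, t


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _hydrophobic_centroids(mol: MoleculeRecord) -> list[np.ndarray]:
    """Centroids of connected clusters of >= 3 apolar carbons."""
    idx = [i for i, a in enumerate(mol.atoms)
           if a.element == "C" and a.hydrophobic_weight >= 1.0]
    if len(idx) < HYDROPHOBIC_MIN_CLUSTER:
        return []
    bonds = infer_bonds(mol)
    adj: dict[int, set[int]] = {i: set() for i in idx}
    idx_set = set(idx)
    for i, j in bonds:
        if i in idx_set and j in idx_set:
            adj[i].add(j)
            adj[j].add(i)
    seen: set[int] = set()
    centroids = []
    for start in idx:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(comp) >= HYDROPHOBIC_MIN_CLUSTER:
            centroids.append(np.mean([mol.atoms[i].coords for i in comp], axis=0))
    return centroids


def _attached_hydrogens(mol: MoleculeRecord) -> dict[int, list[int]]:
    bonds = infer_bonds(mol)
    out: dict[int, list[int]] = {}
    for i, j in bonds:
        for a, b in ((i, j), (j, i)):
            if mol.atoms[b].element == "H":
                out.setdefault(a, []).append(b)
    return out


# ---------------------------------------------------------------------------
# perception


def perceive_features(cx: ComplexStructure) -> PharmacophoreModel:
    """Perceive pharmacophore features from one protein-ligand complex.

    HBD features sit on ligand donor heavy atoms that make a geometric
    hydrogen bond to a protein acceptor; HBA features on ligand acceptors
    hydrogen-bonded to protein donors; HY features at apolar-carbon cluster
    centroids buried against protein carbons; XVOL spheres on protein heavy
    atoms lining the pocket but clear of all feature centers.
    """
    lig = cx.ligand
    prot = cx.protein_atoms
    feats: list[Feature] = []
    lig_h = _attached_hydrogens(lig)

    prot_heavy = [a for a in prot if a.element != "H"]
    prot_donor_pairs = []  # (heavy atom, hydrogen coords)
    prot_acceptors: list = []
    prot_mol = MoleculeRecord("prot", list(prot)) if prot else None
    if prot_mol is not None:
        # typing flags are not guaranteed on protein atoms (PDB input has
        # none); assign them here — the rules are deterministic/idempotent
        assign_typing(prot_mol)
        ph = _attached_hydrogens(prot_mol)
        prot_acceptors = [a for a in prot if a.is_acceptor]
        for i, a in enumerate(prot):
            if a.is_donor_h_parent:
                for hidx in ph.get(i, []):
                    prot_donor_pairs.append((a, prot[hidx].coords))

    # donors on the ligand side
    for i, a in enumerate(lig.atoms):
        if not a.is_donor_h_parent:
            continue
        for acc in prot_acceptors:
            d = float(np.linalg.norm(a.coords - acc.coords))
            if d > HBOND_DISTANCE_MAX:
                continue
            ok = any(_angle(a.coords, lig.atoms[h].coords, acc.coords) >= HBOND_ANGLE_MIN
                     for h in lig_h.get(i, []))
            if ok:
                direction = acc.coords - a.coords
                feats.append(Feature("HBD", a.coords, FEATURE_TOLERANCE, direction))
                break

    # acceptors on the ligand side
    for a in lig.atoms:
        if not a.is_acceptor:
            continue
        for donor, hxyz in prot_donor_pairs:
            d = float(np.linalg.norm(donor.coords - a.coords))
            if d > HBOND_DISTANCE_MAX:
                continue
            if _angle(donor.coords, hxyz, a.coords) >= HBOND_ANGLE_MIN:
                feats.append(Feature("HBA", a.coords, FEATURE_TOLERANCE,
                                     donor.coords - a.coords))
                break

    # hydrophobic centroids buried against protein carbons
    prot_carbons = np.array([a.coords for a in prot if a.element == "C"])
    for c in _hydrophobic_centroids(lig):
        if prot_carbons.size and (np.linalg.norm(prot_carbons - c, axis=1)
                                  <= HYDROPHOBIC_CONTACT_MAX).any():
            feats.append(Feature("HY", c))

    # exclusion volumes on pocket-lining protein heavy atoms
    lig_xyz = lig.coords
    centers = np.array([f.center for f in feats]) if feats else np.empty((0, 3))
    for a in prot_heavy:
        near_lig = (np.linalg.norm(lig_xyz - a.coords, axis=1) <= XVOL_CONTACT_MAX).any()
        if not near_lig:
            continue
        if centers.size and (np.linalg.norm(centers - a.coords, axis=1)
                             <= XVOL_FEATURE_CLEARANCE).any():
            continue
        feats.append(Feature("XVOL", a.coords, XVOL_RADIUS))

    if not any(f.kind != "XVOL" for f in feats):
        logger.warning("no pharmacophore features perceived")
        feats = [f for f in feats if f.kind != "XVOL"]
    return PharmacophoreModel(feats, [lig.id])


# ---------------------------------------------------------------------------
# merging


def merge_models(models: Sequence[PharmacophoreModel], tol: float = 1.5
                 ) -> PharmacophoreModel:
    """Shared model across complexes (pre-superposed into one frame).

    A core feature survives when a feature of the same kind from at least
    one other source model lies within ``tol`` of it; surviving groups are
    merged (mean center, max tolerance).  Exclusion volumes are unioned and
    de-duplicated at ``tol``.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to merge")
    shared: list[Feature] = []
    for kind in ("HY", "HBD", "HBA"):
        entries = [(mi, f) for mi, m in enumerate(models)
                   for f in m.features if f.kind == kind]
        used = [False] * len(entries)
        for i, (mi, f) in enumerate(entries):
            if used[i]:
                continue
            group = [(mi, f)]
            used[i] = True
            for j in range(i + 1, len(entries)):
                mj, g = entries[j]
                if used[j]:
                    continue
                if np.linalg.norm(f.center - g.center) <= tol:
                    group.append((mj, g))
                    used[j] = True
            if len({mi for mi, _ in group}) >= 2:
                center = np.mean([g.center for _, g in group], axis=0)
                tolerance = max(g.tolerance for _, g in group)
                dirs = [g.direction for _, g in group if g.direction is not None]
                direction = np.mean(dirs, axis=0) if dirs else None
                shared.append(Feature(kind, center, tolerance, direction))
    if not shared:
        logger.warning("merged model has no shared core features")
    xvols: list[Feature] = []
    for m in models:
        for f in m.exclusion_volumes:
            if all(np.linalg.norm(f.center - g.center) > tol for g in xvols):
                xvols.append(Feature("XVOL", f.center, f.tolerance))
    sources = [s for m in models for s in m.source_complex_ids]
    return PharmacophoreModel(shared + xvols, sources, "shared")


# ---------------------------------------------------------------------------
# matching and screening


def _candidate_points(conformer: MoleculeRecord) -> dict[str, list[np.ndarray]]:
    pts: dict[str, list[np.ndarray]] = {"HBD": [], "HBA": [], "HY": []}
    for a in conformer.atoms:
        if a.is_donor_h_parent:
            pts["HBD"].append(a.coords)
        if a.is_acceptor:
            pts["HBA"].append(a.coords)
    pts["HY"] = _hydrophobic_centroids(conformer)
    return pts


def match_conformer(model: PharmacophoreModel, conformer: MoleculeRecord,
                    require_all: bool = True) -> ScreenHit | None:
    """Try to fit one conformer onto the model.

    Candidate donor/acceptor atoms and hydrophobic centroids are assigned to
    features of matching kind; every assignment is scored after a
    least-squares rigid superposition.  A hit requires every matched pair
    within its feature tolerance and no heavy atom inside an exclusion
    volume.  With ``require_all`` (default) all core features must match.
    """
    core = model.core_features
    if not core:
        return None
    cand = _candidate_points(conformer)
    pools = [cand[f.kind] for f in core]
    if require_all and any(not p for p in pools):
        return None
    index_pools = [range(len(p)) for p in pools]
    heavy = np.array([a.coords for a in conformer.heavy_atoms()])
    best: ScreenHit | None = None
    for combo in itertools.product(*index_pools):
        # injective within a kind: two features of one kind must use
        # different candidate points
        seen: dict[str, set[int]] = {}
        ok = True
        for f, ci in zip(core, combo):
            s = seen.setdefault(f.kind, set())
            if ci in s:
                ok = False
                break
            s.add(ci)
        if not ok:
            continue
        P = np.array([pools[k][ci] for k, ci in enumerate(combo)])
        Q = np.array([f.center for f in core])
        R, t = _kabsch(P, Q)
        P_fit = P @ R.T + t
        d = np.linalg.norm(P_fit - Q, axis=1)
        if (d > np.array([f.tolerance for f in core])).any():
            continue
        heavy_fit = heavy @ R.T + t
        clash = False
        for xv in model.exclusion_volumes:
            if (np.linalg.norm(heavy_fit - xv.center, axis=1) < xv.tolerance).any():
                clash = True
                break
        if clash:
            continue
        score = MATCH_SCORE_PER_FEATURE * len(core) - float(
            (d / np.array([f.tolerance for f in core])).sum())
        rmsd = float(np.sqrt((d ** 2).mean()))
        hit = ScreenHit(conformer.id, 0, score, list(range(len(core))), rmsd)
        if best is None or hit.fit_score > best.fit_score:
            best = hit
    return best


def screen_library(model: PharmacophoreModel,
                   conformers: Iterable[MoleculeRecord],
                   require_all: bool = True) -> list[ScreenHit]:
    """Screen a conformer library; one best-scoring hit per molecule id.

    Conformers of the same molecule share an id; the returned list is
    sorted by fit score descending, ties broken by molecule id.
    """
    best: dict[str, ScreenHit] = {}
    counters: dict[str, int] = {}
    for conf in conformers:
        k = counters.get(conf.id, 0)
        counters[conf.id] = k + 1
        hit = match_conformer(model, conf, require_all)
        if hit is None:
            continue
        hit.conformer_index = k
        cur = best.get(conf.id)
        if cur is None or hit.fit_score > cur.fit_score:
            best[conf.id] = hit
    return sorted(best.values(), key=lambda h: (-h.fit_score, h.molecule_id))


# ---------------------------------------------------------------------------
# screening validation


def roc_auc(scores_actives: Sequence[float], scores_decoys: Sequence[float]
            ) -> float:
    """ROC AUC by the rank-sum identity, ties getting half credit."""
    a = np.asarray(scores_actives, dtype=float)
    d = np.asarray(scores_decoys, dtype=float)
    if a.size == 0 or d.size == 0:
        raise ValueError("both score lists must be nonempty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([a, d]))
    ra = ranks[:a.size].sum()
    u = ra - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * d.size))


def enrichment(ranked_labels: Sequence[int], fraction: float) -> float:
    """Enrichment factor in the top ``fraction`` of a ranked list.

    EF(f) = (actives in top ceil(f*N) / ceil(f*N)) / (actives / N).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    labels = np.asarray(ranked_labels, dtype=int)
    n = labels.size
    if n == 0 or labels.sum() == 0:
        return 0.0
    top = int(math.ceil(fraction * n))
    return float((labels[:top].sum() / top) / (labels.sum() / n))


def hit_rate(model: PharmacophoreModel,
             conformers: Iterable[MoleculeRecord],
             require_all: bool = True) -> float:
    """Fraction of molecules with at least one matching conformer."""
    by_id: dict[str, bool] = {}
    for conf in conformers:
        matched = by_id.get(conf.id, False)
        if not matched:
            matched = match_conformer(model, conf, require_all) is not None
        by_id[conf.id] = matched
    if not by_id:
        raise ValueError("empty dataset")
    return sum(by_id.values()) / len(by_id)
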