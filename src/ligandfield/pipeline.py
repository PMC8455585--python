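"""The virtual-screening funnel: filter, dedupe, screen, predict, rank.

Stages run in a fixed order — descriptor filters (drug-like / lead-like),
duplicate removal by connectivity hash, pharmacophore screening, activity
prediction with a saved field-PLS model — with monotonically non-increasing
compound counts and a JSON run manifest.  Docking is not part of the
funnel; an optional CSV of externally computed pose scores can be joined
into the final ranking instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemio import MoleculeRecord, infer_bonds, read_structures
from .fieldgen import ProbeSpec, assemble_field_matrix
from .pharmacophore import PharmacophoreModel, screen_library
from .qsar import load_model, predict_with_payload

logger = logging.getLogger(__name__)

__all__ = [
    "FunnelConfig",
    "FunnelReport",
    "molecular_descriptors",
    "druglike_filter",
    "leadlike_filter",
    "dedupe",
    "run_funnel",
]

_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    "W": 18.015, "X": 12.011,
}


@dataclass
class FunnelConfig:
    library_path: str | None = None
    pharmacophore_path: str | None = None
    qsar_model_path: str | None = None
    drug_like: bool = True
    lead_like: bool = False
    remove_duplicates: bool = True
    external_scores_path: str | None = None
    output_dir: str | None = None
    seed: int = 0


@dataclass
class FunnelReport:
    counts: dict[str, int]
    ranked: pd.DataFrame
    seed: int = 0

    def __post_init__(self) -> None:
        vals = list(self.counts.values())
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("stage counts must be non-increasing")

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "counts": self.counts,
            "ranked": self.ranked.to_dict(orient="records"),
        }, indent=1)


# ---------------------------------------------------------------------------
# descriptor filters


def molecular_descriptors(mol: MoleculeRecord) -> dict[str, float]:
    """MW, logP estimate, H-bond donor/acceptor counts, rotatable bonds.

    When the record carries a sanitizable RDKit molecule the Crippen logP
    and the strict rotatable-bond count are used; otherwise a crude
    hydrophobic-fraction logP surrogate and a heavy-atom chain count stand
    in (documented limitation for pseudo-atom inputs).
    """
    try:
        mw = sum(_ATOMIC_MASS[a.element] for a in mol.atoms)
    except KeyError as exc:
        raise ValueError(f"descriptor failure: unknown element {exc}") from exc
    hbd = sum(a.is_donor_h_parent for a in mol.atoms)
    hba = sum(a.is_acceptor for a in mol.atoms)
    logp = None
    rot = None
    rdmol = getattr(mol, "rdmol", None)
    if rdmol is not None:
        try:
            from rdkit import Chem
            from rdkit.Chem import Crippen, rdMolDescriptors

            m = Chem.Mol(rdmol)
            Chem.SanitizeMol(m)
            logp = float(Crippen.MolLogP(m))
            rot = int(rdMolDescriptors.CalcNumRotatableBonds(m))
        except Exception:
            logp = None
    if logp is None:
        heavy = [a for a in mol.atoms if a.element != "H"]
        frac = (sum(a.hydrophobic_weight for a in heavy) / len(heavy)) if heavy else 0.0
        logp = 6.0 * frac - 1.5 * (hbd + hba) / max(len(heavy), 1) * len(heavy) / 10
    if rot is None:
        # chain bonds between heavy atoms of degree > 1, minus ring bonds
        bonds = infer_bonds(mol)
        deg: dict[int, int] = {}
        for i, j in bonds:
            deg[i] = deg.get(i, 0) + 1
            deg[j] = deg.get(j, 0) + 1
        rot = sum(1 for i, j in bonds
                  if mol.atoms[i].element != "H" and mol.atoms[j].element != "H"
                  and deg.get(i, 0) > 1 and deg.get(j, 0) > 1)
    return {"mw": mw, "logp": logp, "hbd": hbd, "hba": hba,
            "rotatable_bonds": rot}


def druglike_filter(mol: MoleculeRecord) -> tuple[bool, list[str]]:
    """Rule-of-five: MW <= 500, logP <= 5, HBD <= 5, HBA <= 10; at most one
    violation is tolerated.  Boundary values pass (<= convention)."""
    try:
        d = molecular_descriptors(mol)
    except ValueError as exc:
        return False, [str(exc)]
    reasons = []
    if d["mw"] > 500:
        reasons.append(f"MW {d['mw']:.1f} > 500")
    if d["logp"] > 5:
        reasons.append(f"logP {d['logp']:.2f} > 5")
    if d["hbd"] > 5:
        reasons.append(f"HBD {d['hbd']} > 5")
    if d["hba"] > 10:
        reasons.append(f"HBA {d['hba']} > 10")
    return len(reasons) <= 1, reasons


def leadlike_filter(mol: MoleculeRecord) -> tuple[bool, list[str]]:
    """Lead-like: MW <= 350, logP <= 3.5, rotatable bonds <= 7."""
    try:
        d = molecular_descriptors(mol)
    except ValueError as exc:
        return False, [str(exc)]
    reasons = []
    if d["mw"] > 350:
        reasons.append(f"MW {d['mw']:.1f} > 350")
    if d["logp"] > 3.5:
        reasons.append(f"logP {d['logp']:.2f} > 3.5")
    if d["rotatable_bonds"] > 7:
        reasons.append(f"rotatable bonds {d['rotatable_bonds']} > 7")
    return not reasons, reasons


# ---------------------------------------------------------------------------
# duplicate removal


def _connectivity_hash(mol: MoleculeRecord) -> str:
    """Canonical connectivity hash: element multiset, bond multiset and a
    canonicalised adjacency (stereo-blind by construction)."""
    rdmol = getattr(mol, "rdmol", None)
    if rdmol is not None:
        try:
            from rdkit import Chem

            m = Chem.Mol(rdmol)
            Chem.SanitizeMol(m, catchErrors=True)
            smi = Chem.MolToSmiles(m, isomericSmiles=False)
            if smi:
                return "smi:" + smi
        except Exception:
            pass
    elems = sorted(a.element for a in mol.atoms)
    bonds = infer_bonds(mol)
    bond_kinds = sorted(
        tuple(sorted((mol.atoms[i].element, mol.atoms[j].element)))
        for i, j in bonds)
    # Morgan-style degree refinement for a canonical adjacency signature
    labels = [a.element for a in mol.atoms]
    adj: dict[int, list[int]] = {i: [] for i in range(len(mol.atoms))}
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    for _ in range(3):
        labels = [labels[i] + "(" + ",".join(sorted(labels[j] for j in adj[i])) + ")"
                  for i in range(len(labels))]
    payload = json.dumps([elems, bond_kinds, sorted(labels)])
    return "adj:" + hashlib.sha256(payload.encode()).hexdigest()


def dedupe(mols: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Keep the first occurrence of each connectivity-distinct molecule."""
    seen: set[str] = set()
    out = []
    for m in mols:
        h = _connectivity_hash(m)
        if h in seen:
            continue
        seen.add(h)
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# funnel


def run_funnel(config: FunnelConfig,
               library: Iterable[MoleculeRecord] | None = None,
               pharmacophore: PharmacophoreModel | None = None,
               qsar_payload: dict | None = None) -> FunnelReport:
    """Execute the screening funnel and return the staged report.

    Inputs may be passed in memory or as paths on the config; missing model
    files fail before any compute.  Conformers of one molecule share an id;
    counts are per unique molecule id.
    """
    if library is None:
        if not config.library_path:
            raise ValueError("no library given")
        library = read_structures(config.library_path)
    library = list(library)
    if pharmacophore is None:
        if not config.pharmacophore_path:
            raise ValueError("no pharmacophore model given")
        p = Path(config.pharmacophore_path)
        if not p.exists():
            raise FileNotFoundError(p)
        pharmacophore = PharmacophoreModel.from_json(p.read_text())
    if qsar_payload is None and config.qsar_model_path:
        p = Path(config.qsar_model_path)
        if not p.exists():
            raise FileNotFoundError(p)
        qsar_payload = load_model(p)

    def n_ids(mols: Iterable[MoleculeRecord]) -> int:
        return len({m.id for m in mols})

    counts = {"input": n_ids(library)}
    stage = library
    if config.drug_like:
        stage = [m for m in stage if druglike_filter(m)[0]]
    if config.lead_like:
        stage = [m for m in stage if leadlike_filter(m)[0]]
    counts["post_filter"] = n_ids(stage)
    if config.remove_duplicates:
        # dedupe across molecule ids: conformers of one id are not duplicates
        by_id: dict[str, list[MoleculeRecord]] = {}
        for m in stage:
            by_id.setdefault(m.id, []).append(m)
        reps = dedupe([v[0] for v in by_id.values()])
        keep = {m.id for m in reps}
        stage = [m for m in stage if m.id in keep]
    counts["post_dedup"] = n_ids(stage)

    hits = screen_library(pharmacophore, stage)
    counts["pharmacophore_hits"] = len(hits)

    rows = []
    hit_ids = [h.molecule_id for h in hits]
    predictions: dict[str, float] = {}
    if qsar_payload is not None and hits:
        by_id = {}
        for m in stage:
            by_id.setdefault(m.id, []).append(m)
        best_conf = [by_id[h.molecule_id][h.conformer_index] for h in hits]
        fm = assemble_field_matrix(best_conf, grid=qsar_payload.get("grid"),
                                   probe=ProbeSpec(),
                                   method="comfa" if qsar_payload["field_names"] == ["S", "E"]
                                   else "comsia")
        yhat = predict_with_payload(qsar_payload, fm)
        predictions = dict(zip(hit_ids, yhat))
    external = {}
    if config.external_scores_path:
        df = pd.read_csv(config.external_scores_path)
        external = dict(zip(df["id"].astype(str), df["score"].astype(float)))
    for h in hits:
        rows.append({
            "id": h.molecule_id,
            "conformer": h.conformer_index,
            "fit_score": h.fit_score,
            "alignment_rmsd": h.alignment_rmsd,
            "predicted_pic50": predictions.get(h.molecule_id, np.nan),
            "external_score": external.get(h.molecule_id, np.nan),
        })
    ranked = pd.DataFrame(rows, columns=["id", "conformer", "fit_score",
                                         "alignment_rmsd", "predicted_pic50",
                                         "external_score"])
    if not ranked.empty:
        ranked = ranked.sort_values(
            ["fit_score", "predicted_pic50"], ascending=[False, False],
            kind="mergesort").reset_index(drop=True)
    counts["qsar_ranked"] = int(ranked.shape[0])
    report = FunnelReport(counts, ranked, seed=config.seed)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "funnel_report.json").write_text(report.to_json())
        ranked.to_csv(out / "ranked_hits.csv", index=False)
    return report
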