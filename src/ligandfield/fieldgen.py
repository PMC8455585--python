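"""Molecular interaction fields on a regular lattice.

Two descriptor families are produced for a set of pre-aligned molecules:

* **CoMFA-style potential fields** — Lennard-Jones 6-12 steric energies and
  distance-dependent-dielectric Coulomb electrostatics of an sp3-carbon probe
  (charge +1 e) at every lattice point, with the steric contribution capped
  at +30 kcal/mol and electrostatics at sterically capped points replaced by
  the molecule's mean uncapped value.
* **CoMSIA-style similarity fields** — Gaussian-attenuated similarity
  indices ``A_k(j) = -sum_i w_probe * w_ik * exp(-alpha * r_iq^2)`` for five
  physicochemical properties: steric (vdw radius cubed), electrostatic
  (partial charge), hydrophobic, H-bond donor and H-bond acceptor.

Both families share the same lattice (default spacing 2.0 A) and are
assembled into a molecules x points :class:`FieldMatrix` with per-block
standard scaling, ready for latent-variable regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import constants
from .chemio import MoleculeRecord

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "FieldMatrix",
    "build_grid",
    "comfa_steric",
    "comfa_electrostatic",
    "comsia_field",
    "assemble_field_matrix",
    "export_dx",
]

COMSIA_KINDS = ("S", "E", "H", "HBD", "HBA")


@dataclass(frozen=True)
class GridSpec:
    """Regular lattice: origin corner, spacing and point counts per axis."""

    origin: tuple[float, float, float]
    spacing: float = 2.0
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1 per axis")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, flattened x-fastest: idx = ix + nx*(iy + ny*iz)."""
        nx, ny, nz = self.dims
        ix = np.arange(nx)
        iy = np.arange(ny)
        iz = np.arange(nz)
        # order points so that x varies fastest
        gz, gy, gx = np.meshgrid(iz, iy, ix, indexing="ij")
        idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        return np.asarray(self.origin) + idx * self.spacing

    def shifted(self, shift: Sequence[float]) -> "GridSpec":
        o = tuple(np.asarray(self.origin, dtype=float) + np.asarray(shift, dtype=float))
        return GridSpec(o, self.spacing, self.dims)


@dataclass
class ProbeSpec:
    """Probe atom parameters shared by both field families.

    The potential-field probe is an sp3 carbon carrying +1 e (Tripos
    convention); the similarity-field probe has unit property weights and
    Gaussian attenuation ``alpha`` (default 0.3 1/A^2).
    """

    charge: float = constants.PROBE_CHARGE
    lj_epsilon: float = constants.PROBE_LJ_EPSILON
    lj_radius: float = constants.PROBE_LJ_RADIUS
    comsia_weights: dict = dc_field(
        default_factory=lambda: {k: 1.0 for k in COMSIA_KINDS})
    attenuation_alpha: float = constants.COMSIA_ALPHA

    def __post_init__(self) -> None:
        if self.lj_radius <= 0 or self.attenuation_alpha <= 0:
            raise ValueError("probe lj_radius and attenuation_alpha must be positive")


@dataclass
class FieldMatrix:
    """Molecules x grid-points descriptor blocks, one block per field type.

    CoMFA blocks are in kcal/mol before scaling, CoMSIA blocks are unitless
    similarity indices.  ``block_scale`` records the pooled standard
    deviation each block was divided by.
    """

    molecule_ids: list[str]
    grid: GridSpec
    blocks: dict[str, np.ndarray]
    block_scale: dict[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.blocks.values()}
        if len(shapes) > 1:
            raise ValueError("all blocks must share one shape")
        for name, b in self.blocks.items():
            if b.shape != (len(self.molecule_ids), self.grid.n_points):
                raise ValueError(f"block {name}: shape {b.shape} does not match "
                                 f"({len(self.molecule_ids)}, {self.grid.n_points})")

    @property
    def field_names(self) -> list[str]:
        return list(self.blocks)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenate blocks column-wise; returns (X, column block labels)."""
        X = np.hstack([self.blocks[k] for k in self.blocks])
        labels = np.concatenate(
            [np.full(self.grid.n_points, k, dtype=object) for k in self.blocks])
        return X, labels

    def to_dataframe(self) -> pd.DataFrame:
        X, labels = self.stacked()
        cols = [f"{lab}:{i % self.grid.n_points}" for i, lab in enumerate(labels)]
        return pd.DataFrame(X, index=self.molecule_ids, columns=cols)


def build_grid(molecules: Sequence[MoleculeRecord], spacing: float = 2.0,
               margin: float = 4.0) -> GridSpec:
    """Lattice enclosing every molecule plus ``margin``, snapped to spacing.

    Per axis the atom bounding box is extended by the margin and then grown
    outward to an integer number of spacings; dims = floor(span/spacing)+1.
    """
    if not molecules:
        raise ValueError("need at least one molecule to build a grid")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xyz = np.vstack([m.coords for m in molecules])
    lo = xyz.min(axis=0) - margin
    hi = xyz.max(axis=0) + margin
    span = hi - lo
    dims = tuple(int(np.floor(s / spacing + 1e-9)) + 1 for s in span)
    return GridSpec(tuple(float(v) for v in lo), spacing, dims)


def _distances(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """(n_points, n_atoms) pairwise distances."""
    diff = points[:, None, :] - coords[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def comfa_steric(mol: MoleculeRecord, grid: GridSpec,
                 probe: ProbeSpec | None = None) -> np.ndarray:
    """Lennard-Jones 6-12 probe energy per lattice point, capped at +30.

    Pair parameters use arithmetic-mean radii (Rmin = r_atom + r_probe) and
    geometric-mean well depths.  Values above the cap are trimmed; there is
    no negative cap.
    """
    probe = probe or ProbeSpec()
    pts = grid.points()
    r = _distances(pts, mol.coords)
    rmin = np.array([a.vdw_radius for a in mol.atoms]) + probe.lj_radius
    eps = np.sqrt(np.array([constants.lj_epsilon(a.element) for a in mol.atoms])
                  * probe.lj_epsilon)
    with np.errstate(divide="ignore", over="ignore"):
        sr6 = (rmin[None, :] / np.maximum(r, 1e-12)) ** 6
        e = eps[None, :] * (sr6 * sr6 - 2.0 * sr6)
    total = e.sum(axis=1)
    total[~np.isfinite(total)] = constants.STERIC_CAP
    return np.minimum(total, constants.STERIC_CAP)


def comfa_electrostatic(mol: MoleculeRecord, grid: GridSpec,
                        probe: ProbeSpec | None = None,
                        steric: np.ndarray | None = None) -> np.ndarray:
    """Coulomb probe energy with distance-dependent dielectric eps(r) = r.

    Energy per point is ``332.0637 * q_probe * q_i / r^2`` summed over atoms.
    At points where the steric field is capped (probe inside the molecule)
    the value is replaced by the mean of that molecule's uncapped values;
    zero interatomic distance counts as capped.
    """
    probe = probe or ProbeSpec()
    if steric is None:
        steric = comfa_steric(mol, grid, probe)
    pts = grid.points()
    r = _distances(pts, mol.coords)
    q = mol.charges
    overlap = (r < 1e-6).any(axis=1)
    with np.errstate(divide="ignore"):
        e = constants.COULOMB_CONSTANT * probe.charge * q[None, :] / np.maximum(r, 1e-12) ** 2
    total = e.sum(axis=1)
    capped = (steric >= constants.STERIC_CAP - 1e-12) | overlap
    if capped.all():
        total[:] = 0.0
        return total
    mean_uncapped = total[~capped].mean()
    total[capped] = mean_uncapped
    return total


_COMSIA_WEIGHT_FUNCS = {
    "S": lambda a: a.vdw_radius ** 3,
    "E": lambda a: a.partial_charge,
    "H": lambda a: a.hydrophobic_weight,
    "HBD": lambda a: float(a.is_donor_h_parent),
    "HBA": lambda a: float(a.is_acceptor),
}


def comsia_field(mol: MoleculeRecord, grid: GridSpec,
                 probe: ProbeSpec | None = None, kind: str = "S") -> np.ndarray:
    """Gaussian similarity index per lattice point for one property field."""
    probe = probe or ProbeSpec()
    if kind not in _COMSIA_WEIGHT_FUNCS:
        raise ValueError(f"unknown similarity field kind {kind!r}; "
                         f"expected one of {COMSIA_KINDS}")
    w = np.array([_COMSIA_WEIGHT_FUNCS[kind](a) for a in mol.atoms])
    pts = grid.points()
    r = _distances(pts, mol.coords)
    wp = probe.comsia_weights.get(kind, 1.0)
    return -(wp * w[None, :] * np.exp(-probe.attenuation_alpha * r ** 2)).sum(axis=1)


def assemble_field_matrix(molecules: Sequence[MoleculeRecord],
                          grid: GridSpec | None = None,
                          probe: ProbeSpec | None = None,
                          method: str = "comfa",
                          scale: bool = True) -> FieldMatrix:
    """Compute all field blocks for a series and apply block standard scaling.

    ``method='comfa'`` yields {S, E} potential blocks; ``'comsia'`` yields
    the five similarity blocks {S, E, H, HBD, HBA}.  Each block is divided
    by its pooled (all molecules x all points) standard deviation so that
    no single field dominates the regression; the scale factors are recorded.
    """
    if not molecules:
        raise ValueError("empty molecule list")
    probe = probe or ProbeSpec()
    grid = grid or build_grid(molecules)
    blocks: dict[str, np.ndarray] = {}
    if method == "comfa":
        steric = np.vstack([comfa_steric(m, grid, probe) for m in molecules])
        elec = np.vstack([
            comfa_electrostatic(m, grid, probe, steric=s)
            for m, s in zip(molecules, steric)])
        blocks["S"] = steric
        blocks["E"] = elec
    elif method == "comsia":
        for kind in COMSIA_KINDS:
            blocks[kind] = np.vstack(
                [comsia_field(m, grid, probe, kind) for m in molecules])
    else:
        raise ValueError(f"unknown method {method!r}")
    scales: dict[str, float] = {}
    for name, b in blocks.items():
        sd = float(b.std())
        scales[name] = sd if (scale and sd > 0) else 1.0
        blocks[name] = b / scales[name]
    return FieldMatrix([m.id for m in molecules], grid, blocks, scales)


def export_dx(values: np.ndarray, grid: GridSpec, path) -> None:
    """Write one scalar field as an OpenDX grid file."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_points,):
        raise ValueError("values length must equal grid point count")
    nx, ny, nz = grid.dims
    # OpenDX expects z-fastest ordering; our flat order is x-fastest
    v = values.reshape(nz, ny, nx).transpose(2, 1, 0).ravel()
    ox, oy, oz = grid.origin
    d = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {d:.6f} 0 0",
        f"delta 0 {d:.6f} 0",
        f"delta 0 0 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {grid.n_points} data follows",
    ]
    for i in range(0, len(v), 3):
        lines.append(" ".join(f"{x:.6e}" for x in v[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "field" class field')
    Path(path).write_text("\n".join(lines) + "\n")
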