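"""Coordinate featurization: gate distances, superposition, interaction energies.

Turns reference structures or multi-model trajectories into the occlusion
observables (centre-of-mass gate distances across the outer vestibule,
ligand-residue nonbonded interaction energies) and classifies frames by
occlusion degree and interaction strength. Internal units: nm and kJ/mol;
PDB coordinates are converted from Angstrom at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "Atom", "StructureModel", "SelectionSpec", "GateReference",
    "NonbondedParams", "OcclusionLabelSeries", "SuperpositionResult",
    "read_structure", "com_distance", "superpose_kabsch",
    "nonbonded_energy", "label_occlusion", "split_by_interaction",
    "COULOMB_PREFACTOR", "ATOMIC_MASSES",
]

COULOMB_PREFACTOR = 138.935485  # kJ mol^-1 nm e^-2

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "SE": 78.971,
}


class PDBParseError(ValueError):
    """Malformed fixed-column PDB record; message carries the line number."""


@dataclass(frozen=True)
class Atom:
    name: str
    res_name: str
    res_number: int     # 1-based, human SERT numbering when applicable
    chain: str
    element: str
    position: tuple[float, float, float]  # nm

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.011)


@dataclass
class StructureModel:
    """One structural frame: atom metadata plus positions in nm."""

    atoms: list[Atom]
    source: str = ""

    def __post_init__(self):
        if any(a.res_number <= 0 for a in self.atoms):
            raise ValueError("residue numbers must be positive")
        if not np.isfinite(self.positions()).all():
            raise ValueError("non-finite atom positions")

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def with_positions(self, xyz: np.ndarray) -> "StructureModel":
        xyz = np.asarray(xyz, dtype=float)
        atoms = [Atom(a.name, a.res_name, a.res_number, a.chain, a.element,
                      tuple(p)) for a, p in zip(self.atoms, xyz)]
        return StructureModel(atoms, self.source)


@dataclass(frozen=True)
class SelectionSpec:
    """Inclusive residue-range selection with an atom filter.

    ``atoms`` is 'CA', 'heavy', 'all', or an explicit sequence of atom
    names. Residue numbering is 1-based.
    """

    chain: str | None = None
    first: int = 1
    last: int = 10 ** 9
    atoms: str | Sequence[str] = "all"

    def __post_init__(self):
        if self.first > self.last:
            raise ValueError(f"first ({self.first}) > last ({self.last})")

    def indices(self, model: StructureModel) -> np.ndarray:
        sel = []
        for i, a in enumerate(model.atoms):
            if self.chain is not None and a.chain != self.chain:
                continue
            if not (self.first <= a.res_number <= self.last):
                continue
            if self.atoms == "CA":
                if a.name != "CA":
                    continue
            elif self.atoms == "heavy":
                if a.element.upper() == "H":
                    continue
            elif self.atoms != "all" and a.name not in self.atoms:
                continue
            sel.append(i)
        return np.asarray(sel, dtype=int)


# Helix segments used throughout (1-based human SERT numbering).
SEGMENTS = {
    "TM1b": (99, 111),
    "TM5a": (274, 287),
    "TM5b": (288, 301),
    "TM6a": (324, 337),
    "TM9up": (475, 477),
}


@dataclass(frozen=True)
class GateReference:
    """Per-gate reference distances (nm) from known conformations."""

    oo: float
    oc: float
    io: float | None = None
    provenance: str = "configured"

    def __post_init__(self):
        if not self.oo > self.oc:
            raise ValueError(f"outer-gate reference requires OO > OC, "
                             f"got OO={self.oo}, OC={self.oc}")


@dataclass(frozen=True)
class NonbondedParams:
    """Per-atom nonbonded parameters aligned with an atom array."""

    charges: np.ndarray        # e
    sigma: np.ndarray          # nm
    epsilon: np.ndarray        # kJ/mol
    cutoff: float = 0.9        # nm

    def __post_init__(self):
        object.__setattr__(self, "charges", np.asarray(self.charges, float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        object.__setattr__(self, "epsilon", np.asarray(self.epsilon, float))
        if (self.sigma < 0).any() or (self.epsilon < 0).any():
            raise ValueError("sigma and epsilon must be >= 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class OcclusionLabelSeries:
    """Per-frame occlusion degree: 'none', 'partial' or 'full'."""

    labels: np.ndarray
    full_below: float
    none_above: float
    margin: float

    def counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        out = {"none": 0, "partial": 0, "full": 0}
        out.update(dict(zip(vals.tolist(), counts.tolist())))
        return out


# ---------------------------------------------------------------------------
# PDB parsing

def read_structure(pdb_text: str, source: str = "") -> list[StructureModel]:
    """Parse ATOM/HETATM records into an ordered list of frames.

    Coordinates are converted Angstrom -> nm. Alternate locations keep the
    highest occupancy (ties resolved toward altLoc 'A'). Multi-model files
    yield one StructureModel per MODEL block.
    """
    frames: list[list[Atom]] = []
    current: list[Atom] = []
    # altLoc bookkeeping per frame: key -> (occupancy, altloc, index in current)
    best: dict[tuple, tuple] = {}
    seen_any = False

    def flush():
        nonlocal current, best
        if current:
            frames.append(current)
        current, best = [], {}

    for ln, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            flush()
        elif rec == "ENDMDL":
            flush()
        elif rec in ("ATOM", "HETATM"):
            seen_any = True
            try:
                name = line[12:16].strip()
                altloc = line[16:17].strip()
                res_name = line[17:20].strip()
                chain = line[21:22].strip()
                res_number = int(line[22:26])
                x = float(line[30:38]) * 0.1
                y = float(line[38:46]) * 0.1
                z = float(line[46:54]) * 0.1
                occ_str = line[54:60].strip()
                occupancy = float(occ_str) if occ_str else 1.0
                element = line[76:78].strip() or _element_from_name(name)
            except (ValueError, IndexError) as exc:
                raise PDBParseError(f"malformed record at line {ln}: {line!r}") from exc
            atom = Atom(name, res_name, res_number, chain, element, (x, y, z))
            if altloc:
                key = (chain, res_number, res_name, name)
                prev = best.get(key)
                if prev is None:
                    best[key] = (occupancy, altloc, len(current))
                    current.append(atom)
                else:
                    p_occ, p_alt, p_idx = prev
                    better = occupancy > p_occ or (occupancy == p_occ and altloc < p_alt)
                    if better:
                        current[p_idx] = atom
                        best[key] = (occupancy, altloc, p_idx)
            else:
                current.append(atom)
    flush()
    if not seen_any:
        raise PDBParseError("no ATOM/HETATM records found")
    n0 = len(frames[0])
    for i, fr in enumerate(frames[1:], start=2):
        if len(fr) != n0:
            warnings.warn(f"model {i} has {len(fr)} atoms, model 1 has {n0}")
    return [StructureModel(fr, source) for fr in frames]


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ATOMIC_MASSES:
        return stripped[:2]
    return stripped[:1]


# ---------------------------------------------------------------------------
# geometry

def _centroid(model: StructureModel, sel: SelectionSpec, mass_weighted: bool,
              label: str) -> np.ndarray:
    idx = sel.indices(model)
    if len(idx) == 0:
        raise ValueError(f"selection {label} ({sel}) matches no atoms")
    xyz = model.positions()[idx]
    if mass_weighted:
        m = model.masses()[idx]
        return (xyz * m[:, None]).sum(axis=0) / m.sum()
    return xyz.mean(axis=0)


def com_distance(frame: StructureModel, a: SelectionSpec, b: SelectionSpec,
                 mass_weighted: bool = True) -> float:
    """Euclidean distance (nm) between (mass-weighted) selection centroids."""
    ca = _centroid(frame, a, mass_weighted, "a")
    cb = _centroid(frame, b, mass_weighted, "b")
    return float(np.linalg.norm(ca - cb))


@dataclass
class SuperpositionResult:
    frame: StructureModel
    rotation: np.ndarray   # 3x3, det = +1
    translation: np.ndarray
    rmsd: float            # nm, on the fit selection


def superpose_kabsch(frame: StructureModel, reference: StructureModel,
                     fit_selection: SelectionSpec | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``frame`` onto ``reference``.

    The optimal rotation is proper (determinant +1; reflections excluded by
    sign-correcting the smallest singular direction). RMSD is computed on
    the fit selection after the transform is applied to all atoms.
    """
    fit_selection = fit_selection or SelectionSpec()
    idx_f = fit_selection.indices(frame)
    idx_r = fit_selection.indices(reference)
    if len(idx_f) != len(idx_r):
        raise ValueError(f"fit selection maps {len(idx_f)} atoms in frame vs "
                         f"{len(idx_r)} in reference")
    if len(idx_f) < 3:
        raise ValueError("need >= 3 atoms in the fit selection")
    X = frame.positions()[idx_f]
    Y = reference.positions()[idx_r]
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    all_new = frame.positions() @ R.T + t
    moved = frame.with_positions(all_new)
    diff = moved.positions()[idx_f] - Y
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return SuperpositionResult(moved, R, t, rmsd)


# ---------------------------------------------------------------------------
# interaction energy

def nonbonded_energy(coords_a: np.ndarray, params_a: NonbondedParams,
                     coords_b: np.ndarray, params_b: NonbondedParams,
                     cutoff: float | None = None) -> float:
    """Pairwise Coulomb + Lennard-Jones energy between two atom groups.

    E = sum over pairs with r <= cutoff of
        f q_i q_j / r + 4 eps_ij [ (sig_ij/r)^12 - (sig_ij/r)^6 ]
    with Lorentz-Berthelot combination (arithmetic sigma, geometric eps)
    and plain truncation at the cutoff (default 0.9 nm). kJ/mol.
    """
    A = np.asarray(coords_a, float).reshape(-1, 3)
    B = np.asarray(coords_b, float).reshape(-1, 3)
    if len(A) != len(params_a.charges) or len(B) != len(params_b.charges):
        raise ValueError("coordinate/parameter length mismatch")
    rc = cutoff if cutoff is not None else min(params_a.cutoff, params_b.cutoff)
    r = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    if (r < 0.05).any():
        warnings.warn(f"atomic clash: minimum pair distance {r.min():.4f} nm < 0.05 nm")
    within = r <= rc
    r_safe = np.where(r > 0, r, np.inf)
    qq = np.outer(params_a.charges, params_b.charges)
    sig = 0.5 * (params_a.sigma[:, None] + params_b.sigma[None, :])
    eps = np.sqrt(np.outer(params_a.epsilon, params_b.epsilon))
    sr6 = (sig / r_safe) ** 6
    e = COULOMB_PREFACTOR * qq / r_safe + 4.0 * eps * (sr6 ** 2 - sr6)
    return float(e[within].sum())


# ---------------------------------------------------------------------------
# classification

def label_occlusion(series, ref: GateReference, margin: float = 0.05) -> OcclusionLabelSeries:
    """Classify each frame: full (d <= OC+margin), none (d >= OO-margin), else partial."""
    if margin >= (ref.oo - ref.oc) / 2:
        raise ValueError(f"margin {margin} >= (OO-OC)/2 = {(ref.oo - ref.oc) / 2}: "
                         "bands overlap")
    d = np.asarray(series, dtype=float)
    labels = np.full(d.shape, "partial", dtype=object)
    labels[d <= ref.oc + margin] = "full"
    labels[d >= ref.oo - margin] = "none"
    return OcclusionLabelSeries(labels, ref.oc + margin, ref.oo - margin, margin)


def split_by_interaction(tables: Iterable[pd.DataFrame], energy_column: str,
                         threshold: float = -20.0,
                         distance_column: str = "tm6a_tm9up_nm",
                         bins: int = 40) -> dict:
    """Split frames by interaction strength at ``threshold`` (kJ/mol).

    Strong = E < threshold, weak = E >= threshold (frames exactly at the
    threshold go to the weak set). Distance histograms for the two sets
    share bin edges. Returns strong/weak frame tables, histograms, edges.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no feature tables given")
    for i, t in enumerate(tables):
        if energy_column not in t.columns:
            raise KeyError(f"column {energy_column!r} missing from table {i}")
    pooled = pd.concat(tables, ignore_index=True)
    strong = pooled[pooled[energy_column] < threshold]
    weak = pooled[pooled[energy_column] >= threshold]
    edges = np.histogram_bin_edges(pooled[distance_column], bins=bins)
    h_strong, _ = np.histogram(strong[distance_column], bins=edges)
    h_weak, _ = np.histogram(weak[distance_column], bins=edges)
    return {
        "strong": strong.reset_index(drop=True),
        "weak": weak.reset_index(drop=True),
        "edges": edges,
        "hist_strong": h_strong,
        "hist_weak": h_weak,
        "threshold": threshold,
    }
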