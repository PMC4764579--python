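"""Ensemble geometry analytics.

Superposition (Kabsch), RMSD of an ensemble to its converged mean,
greedy RMSD-neighborhood (Daura/GROMOS) clustering with representative
selection, Shrake-Rupley solvent-accessible surface area, buried
interface area, per-residue delta-SASA between bound and free states,
and residue surface-chemistry classification.

SASA uses a deterministic Fibonacci-lattice point set (no RNG), so
areas are bit-reproducible, and a fixed Bondi-like van der Waals radius
table; hydrogens are ignored throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import Atom, Selection, Structure

logger = logging.getLogger(__name__)

#: Van der Waals radii (Angstrom) used for SASA.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

DEFAULT_PROBE = 1.4
DEFAULT_SASA_POINTS = 960

HYDROPHOBIC = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"})
BASIC = frozenset({"LYS", "ARG", "HIS"})
ACIDIC = frozenset({"ASP", "GLU"})
STANDARD_RESIDUES = HYDROPHOBIC | BASIC | ACIDIC | frozenset(
    {"GLY", "SER", "THR", "CYS", "TYR", "ASN", "GLN"})


# ---------------------------------------------------------------------------
# Superposition and RMSD

@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation and the residual RMSD."""

    rotation: np.ndarray      # 3x3, det = +1
    translation: np.ndarray   # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Solves for the proper rotation (no reflections) and translation
    minimizing the (optionally weighted) RMSD between the point sets.
    Degenerate (collinear or fewer than 3) point sets raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3) with equal n")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cm = (w[:, None] * mobile).sum(axis=0)
    cr = (w[:, None] * reference).sum(axis=0)
    pm = mobile - cm
    pr = reference - cr
    h = (w[:, None] * pm).T @ pr
    u, sing, vt = np.linalg.svd(h)
    if sing[1] < 1e-10:  # rank < 2: collinear points, rotation ill-defined
        raise ValueError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = pm @ rot.T
    rmsd = math.sqrt(float((w * np.sum((moved - pr) ** 2, axis=1)).sum()))
    return SuperpositionResult(rotation=rot, translation=cr - rot @ cm, rmsd=rmsd)


def _selection_coords(structure: Structure, selection: Selection) -> np.ndarray:
    """Stacked (n_models, n_sel, 3) coordinates; roster checked across models."""
    per_model = []
    roster_ref = None
    for mid, atoms in structure.iter_models():
        sel = selection.apply(atoms)
        roster = [(a.serial, a.name, a.res_seq, a.chain_id) for a in sel]
        if roster_ref is None:
            roster_ref = roster
        elif roster != roster_ref:
            raise ValueError("selection resolves differently across models")
        per_model.append(np.array([a.coords for a in sel]))
    if not per_model or per_model[0].shape[0] == 0:
        raise ValueError("selection is empty")
    return np.stack(per_model)


def rmsd_to_mean(structure: Structure, selection: Selection | None = None,
                 method: str = "iterative_mean", tol: float = 1e-6,
                 max_iter: int = 100) -> float:
    """Ensemble spread: average model RMSD to the converged mean structure.

    ``iterative_mean`` (default) superposes every model on the current
    mean over the selection, recomputes the mean, and iterates until the
    mean shifts by less than ``tol`` A; it returns the average over
    models of each model's RMSD to that mean.  ``pairwise_mean``
    returns the average of all pairwise superposed RMSDs instead.
    """
    selection = selection or Selection()
    coords = _selection_coords(structure, selection)
    n_models = coords.shape[0]
    if n_models < 2:
        raise ValueError("need >= 2 models")
    if method == "pairwise_mean":
        vals = [kabsch_superpose(coords[i], coords[j]).rmsd
                for i in range(n_models) for j in range(i + 1, n_models)]
        return float(np.mean(vals))
    if method != "iterative_mean":
        raise ValueError(f"unknown method {method!r}")
    mean = coords[0].copy()
    aligned = coords.copy()
    for _ in range(max_iter):
        for i in range(n_models):
            sup = kabsch_superpose(coords[i], mean)
            aligned[i] = sup.apply(coords[i])
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    else:
        raise RuntimeError(f"mean superposition did not converge in {max_iter} iterations")
    rmsds = [math.sqrt(float(np.mean(np.sum((aligned[i] - mean) ** 2, axis=1))))
             for i in range(n_models)]
    return float(np.mean(rmsds))


# ---------------------------------------------------------------------------
# Daura / GROMOS clustering

@dataclass
class ClusterResult:
    """Greedy RMSD-neighborhood clustering of an ensemble."""

    labels: np.ndarray        # cluster id per model (0-based, by extraction order)
    representatives: list[int]  # model index of each cluster center
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    @property
    def most_representative(self) -> int:
        """Center of the largest cluster (ties: first extracted)."""
        sizes = [int(np.sum(self.labels == c)) for c in range(self.n_clusters)]
        return self.representatives[int(np.argmax(sizes))]


def pairwise_rmsd_matrix(structure: Structure,
                         selection: Selection | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs between models."""
    coords = _selection_coords(structure, selection or Selection())
    n = coords.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_superpose(coords[i], coords[j]).rmsd
    return mat


def daura_cluster_from_matrix(rmsd_matrix: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy neighbor-count clustering on a precomputed RMSD matrix.

    Repeatedly pick the unassigned model with the most unassigned
    neighbors within ``cutoff`` (ties: lowest index), form a cluster of
    it and those neighbors, remove them, and repeat.  The picked model
    is the cluster's representative ("central structure").
    """
    mat = np.asarray(rmsd_matrix, dtype=float)
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValueError("rmsd_matrix must be square")
    labels = np.full(n, -1, dtype=int)
    reps: list[int] = []
    remaining = set(range(n))
    cluster_id = 0
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if j != i and mat[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = {best} | {j for j in remaining
                            if j != best and mat[best, j] <= cutoff}
        for j in members:
            labels[j] = cluster_id
        reps.append(best)
        remaining -= members
        cluster_id += 1
    return ClusterResult(labels=labels, representatives=reps, cutoff=cutoff)


def daura_cluster(structure: Structure, selection: Selection | None = None,
                  cutoff: float = 1.0) -> ClusterResult:
    """Cluster ensemble models by pairwise superposed RMSD (greedy)."""
    return daura_cluster_from_matrix(
        pairwise_rmsd_matrix(structure, selection), cutoff)


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaReport:
    """Per-atom and per-residue solvent-accessible surface areas."""

    atom_areas: pd.DataFrame   # columns serial, chain, res_seq, res_name, area
    probe: float

    def per_residue(self) -> pd.Series:
        return self.atom_areas.groupby(
            ["chain", "res_seq", "res_name"], sort=True)["area"].sum()

    @property
    def total(self) -> float:
        return float(self.atom_areas["area"].sum())


def sasa(structure: Structure, probe: float = DEFAULT_PROBE,
         n_points: int = DEFAULT_SASA_POINTS, model_id: int | None = None,
         atoms: list[Atom] | None = None) -> SasaReport:
    """Shrake-Rupley solvent-accessible surface area, heavy atoms only.

    Each atom's area is ``4 pi (r_vdw + probe)^2`` times the fraction of
    a deterministic Fibonacci-lattice point set on its expanded sphere
    not buried inside any neighbor's expanded sphere.
    """
    if atoms is None:
        if model_id is None:
            if structure.n_models != 1:
                raise ValueError("multi-model structure: pass model_id")
            model_id = structure.model_ids[0]
        atoms = structure.model(model_id)
    heavy = [a for a in atoms if not a.is_hydrogen]
    if not heavy:
        raise ValueError("no heavy atoms")
    radii = np.empty(len(heavy))
    for i, a in enumerate(heavy):
        try:
            radii[i] = VDW_RADII[a.element.upper()]
        except KeyError:
            raise KeyError(f"no van der Waals radius for element {a.element!r}")
    radii = radii + probe
    pts = np.array([a.coords for a in heavy])
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(pts)
    areas = np.empty(len(heavy))
    rmax = radii.max()
    for i in range(len(heavy)):
        test = pts[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(pts[i], radii[i] + rmax):
            if j == i:
                continue
            d2 = np.sum((test - pts[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    df = pd.DataFrame({
        "serial": [a.serial for a in heavy],
        "chain": [a.chain_id for a in heavy],
        "res_seq": [a.res_seq for a in heavy],
        "res_name": [a.res_name for a in heavy],
        "area": areas,
    })
    return SasaReport(atom_areas=df, probe=probe)


def buried_interface_area(complex_structure: Structure, part_a: Selection,
                          part_b: Selection, probe: float = DEFAULT_PROBE,
                          n_points: int = DEFAULT_SASA_POINTS) -> float:
    """Buried surface per complex: (SASA_A + SASA_B - SASA_AB) / 2."""
    mid = complex_structure.model_ids[0]
    atoms = complex_structure.model(mid)
    aa = part_a.apply(atoms)
    bb = part_b.apply(atoms)
    if {id(a) for a in aa} & {id(b) for b in bb}:
        raise ValueError("part selections overlap")
    s_a = sasa(complex_structure, probe, n_points, atoms=aa).total
    s_b = sasa(complex_structure, probe, n_points, atoms=bb).total
    s_ab = sasa(complex_structure, probe, n_points, atoms=aa + bb).total
    return 0.5 * (s_a + s_b - s_ab)


def delta_sasa(bound: Structure, free: Structure,
               selection: Selection | None = None, probe: float = DEFAULT_PROBE,
               n_points: int = DEFAULT_SASA_POINTS) -> pd.Series:
    """Per-residue SASA change on binding: SASA_free - SASA_bound.

    Positive values mark residues buried by the interaction.  The
    selection must resolve to the same residues in both structures.
    """
    selection = selection or Selection()
    out = {}
    for label, structure in (("bound", bound), ("free", free)):
        mid = structure.model_ids[0]
        atoms = structure.model(mid)
        rep = sasa(structure, probe, n_points,
                   atoms=atoms)  # full-context areas
        per_res = rep.per_residue()
        sel_atoms = selection.apply(atoms)
        keys = sorted({(a.chain_id, a.res_seq, a.res_name) for a in sel_atoms})
        out[label] = per_res.loc[keys] if keys else per_res
    if list(out["bound"].index) != list(out["free"].index):
        raise ValueError("selection resolves to different residues in the two states")
    ds = out["free"] - out["bound"]
    ds.name = "delta_sasa"
    return ds


def classify_residues(structure: Structure) -> pd.Series:
    """Surface-chemistry class per residue: hydrophobic / basic / acidic / other."""
    classes = {}
    for a in structure.model(structure.model_ids[0]):
        key = (a.chain_id, a.res_seq, a.res_name)
        if key in classes:
            continue
        rn = a.res_name.upper()
        if rn not in STANDARD_RESIDUES:
            logger.warning("nonstandard residue %s classified as 'other'", rn)
            classes[key] = "other"
        elif rn in HYDROPHOBIC:
            classes[key] = "hydrophobic"
        elif rn in BASIC:
            classes[key] = "basic"
        elif rn in ACIDIC:
            classes[key] = "acidic"
        else:
            classes[key] = "other"
    keys = sorted(classes)
    return pd.Series([classes[k] for k in keys], index=keys, name="class")
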