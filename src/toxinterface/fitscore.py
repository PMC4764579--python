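"""Density-map scoring, restraint-violation statistics and pose ranking.

* Map-model agreement is a Pearson correlation over voxels.
* Per-atom positional confidence in a density map is scored as
  ``-m_a * rho(x_a, y_a, z_a)`` — atom mass times the map value at the
  atom position, negated, with the map normalized to unit maximum.  The
  best (most negative) fraction of scores marks atoms sitting in the
  strongest density, i.e. the best-resolved ones.
* Distance-restraint violations are counted against upper bounds, with
  an RMS of the excess over violated restraints only.
* Pose ranking renders each candidate pose as a Gaussian-atom map on
  the experimental grid and orders poses by map correlation, breaking
  ties by restraint-violation count, then violation RMS, then input
  order.  This is the logic used to discriminate mirror-image (e.g.
  clockwise vs counter-clockwise) lobe assignments.

Two small NMR utilities round out the module: the 3J(HN-Ha) coupling to
backbone-phi restraint rule, and the combined amide/alpha chemical-shift
difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .core_io import DensityMap, RestraintSet, Structure

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Map-model correlation

def map_model_correlation(map_a: DensityMap, map_b: DensityMap,
                          mask_threshold: float | None = None) -> float:
    """Pearson correlation between two density maps on a common grid.

    Maps must share shape, voxel and origin (resampling is the caller's
    job).  With ``mask_threshold``, only voxels where either map exceeds
    the threshold enter the sum.  Invariant under affine rescaling of
    either map.
    """
    if map_a.grid.shape != map_b.grid.shape or not map_a.same_grid_as(map_b):
        raise ValueError("maps are not on the same grid (shape/voxel/origin)")
    a = map_a.grid.ravel()
    b = map_b.grid.ravel()
    if mask_threshold is not None:
        mask = (a > mask_threshold) | (b > mask_threshold)
        a, b = a[mask], b[mask]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance map; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Per-atom confidence

@dataclass
class AtomConfidence:
    """Per-atom density-confidence scores and the selected top fraction."""

    serials: np.ndarray
    scores: np.ndarray        # -m_a * rho_a, lower (more negative) = better
    selected: np.ndarray      # boolean mask, aligned with serials
    fraction: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"serial": self.serials, "score": self.scores,
                             "selected": self.selected})


def _interpolate_density(density: DensityMap, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of map values at Cartesian points.

    Points outside the grid bounding box read as 0 (refinement
    intermediates may poke out of the box)."""
    frac = (points - density.origin) / density.voxel
    lo_ok = np.all(frac >= 0, axis=1)
    hi_ok = np.all(frac <= np.array(density.grid.shape) - 1, axis=1)
    outside = ~(lo_ok & hi_ok)
    if np.any(outside):
        logger.warning("%d atom(s) outside the map bounding box; rho = 0",
                       int(outside.sum()))
    return map_coordinates(density.grid, frac.T, order=1, mode="constant",
                           cval=0.0)


def atom_confidence(structure: Structure, density: DensityMap,
                    fraction: float = 0.20,
                    normalization: str = "unit-max") -> AtomConfidence:
    """Rank atoms by how confidently the map supports their position.

    The map is normalized (``unit-max`` scales the positive peak to 1;
    ``zscore`` standardizes the voxel values) and each atom scored
    ``-m_a * rho`` at its position via trilinear interpolation.  The
    ``round(fraction * N)`` most negative scores are flagged selected;
    ties break toward the lower atom serial.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if normalization == "unit-max":
        dens = density.normalized()
    elif normalization == "zscore":
        g = density.grid
        dens = DensityMap((g - g.mean()) / g.std(), density.voxel,
                          density.origin, normalized_flag=True)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    atoms = structure.model(structure.model_ids[0])
    pts = np.array([a.coords for a in atoms])
    rho = _interpolate_density(dens, pts)
    masses = np.array([a.mass for a in atoms])
    serials = np.array([a.serial for a in atoms])
    scores = -masses * rho
    n_sel = int(round(fraction * len(atoms)))
    order = np.lexsort((serials, scores))  # score ascending, then serial
    selected = np.zeros(len(atoms), dtype=bool)
    selected[order[:n_sel]] = True
    return AtomConfidence(serials=serials, scores=scores, selected=selected,
                          fraction=fraction)


# ---------------------------------------------------------------------------
# Restraint violations

@dataclass
class ViolationReport:
    """Distance-restraint violation statistics for one model."""

    n_restraints: int
    n_violated: int
    violation_rmsd: float     # RMS of (distance - upper) over violated only
    excesses: list[float]
    n_unresolved: int = 0

    def __post_init__(self):
        assert 0 <= self.n_violated <= self.n_restraints


def noe_violations(structure: Structure, restraints: RestraintSet,
                   model_id: int = 1) -> ViolationReport:
    """Count upper-bound distance-restraint violations in one model.

    A restraint is violated when the model distance exceeds its upper
    bound; the report's RMSD is the root-mean-square excess over the
    violated restraints only (0 when none are violated).  Restraints
    whose selectors do not resolve to exactly one atom are excluded and
    counted separately.
    """
    atoms = structure.model(model_id)
    index: dict[tuple[str, int, str], list] = {}
    for a in atoms:
        index.setdefault((a.chain_id, a.res_seq, a.name), []).append(a)
    excesses: list[float] = []
    n_resolved = 0
    n_unresolved = 0
    n_violated = 0
    for r in restraints:
        hits_a = index.get(r.selector_a, [])
        hits_b = index.get(r.selector_b, [])
        if len(hits_a) != 1 or len(hits_b) != 1:
            n_unresolved += 1
            continue
        n_resolved += 1
        d = float(np.linalg.norm(hits_a[0].coords - hits_b[0].coords))
        if d > r.upper_bound:
            n_violated += 1
            excesses.append(d - r.upper_bound)
    rmsd = math.sqrt(np.mean(np.square(excesses))) if excesses else 0.0
    return ViolationReport(n_restraints=n_resolved, n_violated=n_violated,
                           violation_rmsd=rmsd, excesses=excesses,
                           n_unresolved=n_unresolved)


# ---------------------------------------------------------------------------
# Pose ranking

@dataclass
class PoseScore:
    pose_index: int
    correlation: float
    violations: ViolationReport


@dataclass
class PoseRanking:
    """Poses ordered best-first by (correlation, violations, RMS, input order)."""

    scores: list[PoseScore]   # in input order
    order: list[int]          # pose indices, best first

    @property
    def best(self) -> int:
        return self.order[0]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"pose": s.pose_index, "correlation": s.correlation,
                 "n_violated": s.violations.n_violated,
                 "violation_rmsd": s.violations.violation_rmsd,
                 "rank": self.order.index(s.pose_index) + 1}
                for s in self.scores]
        return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)


def rank_poses(poses: list[Structure], density: DensityMap,
               restraints: RestraintSet, sigma: float = 1.5,
               voxel: float | None = None) -> PoseRanking:
    """Rank candidate poses against an experimental map and restraints.

    Each pose is rendered as a Gaussian-atom model map on the
    experimental grid, scored by Pearson correlation with the map and
    by its restraint-violation report, then ordered by higher
    correlation, fewer violations, lower violation RMS, input order.
    All poses must share an atom roster.
    """
    from .synth import synthesize_map
    if len(poses) < 2:
        raise ValueError("need >= 2 poses to rank")
    roster0 = [(a.serial, a.name, a.res_seq, a.chain_id)
               for a in poses[0].model(poses[0].model_ids[0])]
    scores: list[PoseScore] = []
    for i, pose in enumerate(poses):
        roster = [(a.serial, a.name, a.res_seq, a.chain_id)
                  for a in pose.model(pose.model_ids[0])]
        if roster != roster0:
            raise ValueError(f"pose {i} has a different atom roster")
        model_map = synthesize_map(pose, sigma=sigma, like=density)
        corr = map_model_correlation(model_map, density)
        viol = noe_violations(pose, restraints, model_id=pose.model_ids[0])
        scores.append(PoseScore(pose_index=i, correlation=corr, violations=viol))
    order = sorted(range(len(poses)),
                   key=lambda i: (-scores[i].correlation,
                                  scores[i].violations.n_violated,
                                  scores[i].violations.violation_rmsd, i))
    return PoseRanking(scores=scores, order=order)


# ---------------------------------------------------------------------------
# NMR utilities

@dataclass(frozen=True)
class PhiRestraint:
    """Backbone-phi dihedral restraint: center +/- half_width, degrees."""

    center: float
    half_width: float
    res_seq: int | None = None

    def __post_init__(self):
        if not (-180 < self.center <= 180):
            raise ValueError("phi center must be in (-180, 180]")


def coupling_to_phi(j: float, res_seq: int | None = None) -> PhiRestraint | None:
    """Convert a 3J(HN-Ha) scalar coupling (Hz) to a phi restraint.

    Small couplings (< 5.5 Hz) indicate helical phi (-65 +/- 25 deg);
    large couplings (> 8.0 Hz) extended phi (-120 +/- 40 deg);
    intermediate values give no restraint.
    """
    if j < 0:
        raise ValueError("coupling constant must be >= 0")
    if j < 5.5:
        return PhiRestraint(center=-65.0, half_width=25.0, res_seq=res_seq)
    if j > 8.0:
        return PhiRestraint(center=-120.0, half_width=40.0, res_seq=res_seq)
    return None


@dataclass(frozen=True)
class ShiftDelta:
    """Combined Ha/HN chemical-shift difference (ppm)."""

    d_ha: float
    d_hn: float
    dcs: float


def chemical_shift_difference(d_ha: float, d_hn: float) -> ShiftDelta:
    """Combined shift difference: sqrt(d_Ha^2 + d_HN^2)."""
    if not (math.isfinite(d_ha) and math.isfinite(d_hn)):
        raise ValueError("shift differences must be finite")
    return ShiftDelta(d_ha=d_ha, d_hn=d_hn, dcs=math.hypot(d_ha, d_hn))
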