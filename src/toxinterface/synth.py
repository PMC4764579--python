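"""Synthetic input generators for every pipeline stage.

Generates toy multi-chain complexes with planted inter-chain contacts, a
labeled membrane slab, Gaussian-atom density maps, fluorescence
titrations, Hill dose-responses and perturbed coordinate ensembles.
Every generator is a pure function of its arguments and an explicit
seed: identical inputs give bit-identical outputs, and zero noise
collapses each simulator onto its closed-form model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import Atom, DensityMap, Structure, element_mass
from . import thermo

logger = logging.getLogger(__name__)

# Geometry constants for the toy builder (Angstrom).
_RES_SPACING = 12.0       # along-chain spacing; keeps non-planted pairs > 8 A
_CHAIN_SPACING = 50.0     # between-chain offset
_PLANT_OFFSET = 3.5       # planted-pair base offset; guarantees a pair < 4.5 A

# Local atom offsets of the 4-heavy-atom pseudo-residue (N, CA, C, CB) + 1 H.
_RES_TEMPLATE = {
    "N": np.array([-1.3, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.3, 0.0, 0.0]),
    "CB": np.array([0.0, 1.0, 0.5]),
    "HA": np.array([0.0, -0.8, 0.6]),
}
_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "CB": "C", "HA": "H"}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Specification for a planted-contact toy complex."""

    n_res_per_chain: int
    chains: tuple[str, ...]
    planted_contacts: tuple[tuple[str, int, str, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "chains", tuple(self.chains))
        object.__setattr__(self, "planted_contacts",
                           tuple(tuple(p) for p in self.planted_contacts))
        for ca, ra, cb, rb in self.planted_contacts:
            for c, r in ((ca, ra), (cb, rb)):
                if c not in self.chains or not (1 <= r <= self.n_res_per_chain):
                    raise ValueError(f"planted contact references missing residue {c}{r}")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the curve simulators."""

    kind: str = "multiplicative-gaussian"  # or "additive-gaussian"
    sd: float = 0.0

    def __post_init__(self):
        if self.kind not in ("multiplicative-gaussian", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.asarray(values, dtype=float).copy()
        eps = rng.normal(0.0, self.sd, size=np.shape(values))
        if self.kind == "multiplicative-gaussian":
            return values * (1.0 + eps)
        return values + eps


@dataclass
class TitrationData:
    """Replicated F/F0 measurements on a total-lipid concentration grid."""

    lipid_total: np.ndarray                # molar, shape (n_points,)
    f_over_f0: np.ndarray                  # shape (n_replicates, n_points)
    accessible_fraction: float = 0.6
    water_molarity: float = thermo.WATER_MOLARITY

    def __post_init__(self):
        self.lipid_total = np.asarray(self.lipid_total, dtype=float)
        self.f_over_f0 = np.atleast_2d(np.asarray(self.f_over_f0, dtype=float))
        if np.any(self.lipid_total < 0):
            raise ValueError("lipid concentrations must be >= 0")
        if self.f_over_f0.shape[1] != self.lipid_total.size:
            raise ValueError("replicates not aligned to the concentration grid")
        if np.any(self.f_over_f0 <= 0):
            raise ValueError("F/F0 must be positive")
        if not (0 < self.accessible_fraction <= 1):
            raise ValueError("accessible_fraction must be in (0, 1]")


@dataclass
class DoseResponseData:
    """Normalized-current responses on a toxin concentration grid."""

    concentrations: np.ndarray             # molar
    response: np.ndarray                   # same length

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if self.response.shape != self.concentrations.shape:
            raise ValueError("response not aligned to the concentration grid")


# ---------------------------------------------------------------------------
# Structures

def _make_residue(chain: str, res_seq: int, base: np.ndarray, serial0: int,
                  jitter: np.ndarray, model_id: int = 1) -> list[Atom]:
    atoms = []
    for i, (name, off) in enumerate(_RES_TEMPLATE.items()):
        elem = _ELEMENT_OF[name]
        atoms.append(Atom(serial=serial0 + i, name=name, element=elem,
                          mass=element_mass(elem), res_name="ALA",
                          res_seq=res_seq, chain_id=chain,
                          coords=base + off + jitter[i], model_id=model_id))
    return atoms


def build_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, list[tuple[str, int, str, int]]]:
    """Build a multi-chain toy complex with planted inter-chain contacts.

    Each residue is a compact 4-heavy-atom pseudo-residue (N, CA, C, CB)
    plus one hydrogen.  Chains are laid out on well-separated rails;
    each planted contact relocates the partner residue next to its
    target so that at least one heavy-atom pair falls within 4.5 A,
    while every non-planted inter-chain residue pair stays beyond 8 A.
    The construction is verified before returning and raises if the
    requested contact density is geometrically infeasible.
    """
    if len(spec.chains) < 2:
        raise ValueError("need at least 2 chains")
    rng = np.random.default_rng(spec.seed)
    # placement: chain k along x at y = k * _CHAIN_SPACING
    bases: dict[tuple[str, int], np.ndarray] = {}
    for k, chain in enumerate(spec.chains):
        for r in range(1, spec.n_res_per_chain + 1):
            bases[(chain, r)] = np.array([(r - 1) * _RES_SPACING,
                                          k * _CHAIN_SPACING, 0.0])
    # relocate the second residue of each planted pair next to the first
    for ca, ra, cb, rb in spec.planted_contacts:
        bases[(cb, rb)] = bases[(ca, ra)] + np.array([0.0, 0.0, _PLANT_OFFSET])
    atoms: list[Atom] = []
    serial = 1
    for chain in spec.chains:
        for r in range(1, spec.n_res_per_chain + 1):
            jitter = rng.normal(0.0, 0.1, size=(len(_RES_TEMPLATE), 3))
            atoms.extend(_make_residue(chain, r, bases[(chain, r)], serial, jitter))
            serial += len(_RES_TEMPLATE)
    structure = Structure(atoms=atoms, title="synthetic planted-contact complex")
    truth = [tuple(p) for p in spec.planted_contacts]
    _verify_toy_complex(structure, truth)
    return structure, truth


def _verify_toy_complex(structure: Structure, truth) -> None:
    planted = {frozenset([(ca, ra), (cb, rb)]) for ca, ra, cb, rb in truth}
    heavy = [a for a in structure.atoms if not a.is_hydrogen]
    by_res: dict[tuple[str, int], list[np.ndarray]] = {}
    for a in heavy:
        by_res.setdefault((a.chain_id, a.res_seq), []).append(a.coords)
    keys = sorted(by_res)
    for i, ki in enumerate(keys):
        for kj in keys[i + 1:]:
            if ki[0] == kj[0]:
                continue  # intra-chain pairs are unconstrained
            dmin = min(np.linalg.norm(p - q)
                       for p in by_res[ki] for q in by_res[kj])
            pair = frozenset([ki, kj])
            if pair in planted and dmin > 4.5:
                raise ValueError(
                    f"planted contact {ki}-{kj} not realized (min dist {dmin:.2f} A); "
                    "try fewer planted contacts")
            if pair not in planted and dmin <= 8.0:
                raise ValueError(
                    f"spurious proximity {ki}-{kj} ({dmin:.2f} A); "
                    "try fewer planted contacts")


def build_membrane_slab(n_lipids: int, seed: int = 0) -> Structure:
    """Build a planar two-leaflet lipid slab with labeled head/tail atoms.

    Each lipid contributes a head-group residue (res_name ``HEA``: P,
    O1, O2 atoms) and a tail residue (``TAI``: three carbons), with head
    atoms at higher |z| than every tail atom of the same leaflet.
    """
    if n_lipids < 1:
        raise ValueError("n_lipids must be >= 1")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 1
    res_seq = 1
    grid = int(np.ceil(np.sqrt(max(1, (n_lipids + 1) // 2))))
    for i in range(n_lipids):
        leaflet = 1 if i < (n_lipids + 1) // 2 else -1
        idx = i if leaflet == 1 else i - (n_lipids + 1) // 2
        x = (idx % grid) * 8.0 + rng.uniform(-0.5, 0.5)
        y = (idx // grid) * 8.0 + rng.uniform(-0.5, 0.5)
        head_z = leaflet * 20.0
        head_atoms = [("P", "P", 0.0), ("O1", "O", -0.8), ("O2", "O", -1.6)]
        for name, elem, dz in head_atoms:
            atoms.append(Atom(serial=serial, name=name, element=elem,
                              mass=element_mass(elem), res_name="HEA",
                              res_seq=res_seq, chain_id="L",
                              coords=np.array([x, y, head_z + leaflet * dz]),
                              model_id=1))
            serial += 1
        for j in range(3):
            z = leaflet * (14.0 - 4.0 * j)
            atoms.append(Atom(serial=serial, name=f"C{j+1}", element="C",
                              mass=element_mass("C"), res_name="TAI",
                              res_seq=res_seq + 1, chain_id="L",
                              coords=np.array([x, y, z]), model_id=1))
            serial += 1
        res_seq += 2
    return Structure(atoms=atoms, title="synthetic lipid slab")


def synthesize_map(structure: Structure, sigma: float = 1.5, voxel: float = 1.0,
                   padding: float = 5.0, like: DensityMap | None = None) -> DensityMap:
    """Render a structure as a sum of mass-weighted atomic Gaussians.

    The density is ``sum_a m_a * exp(-|x - x_a|^2 / (2 sigma^2))`` over
    heavy atoms, sampled at voxel centers.  With ``like`` given, the map
    is sampled on that map's grid (shape, voxel, origin) instead of a
    bounding box + padding — used when scoring poses against an
    experimental map.
    """
    if sigma <= 0 or voxel <= 0:
        raise ValueError("sigma and voxel must be positive")
    heavy = [a for a in structure.model(structure.model_ids[0])
             if not a.is_hydrogen] if structure.atoms else []
    if like is not None:
        shape = like.grid.shape
        vox = like.voxel.copy()
        origin = like.origin.copy()
    else:
        if voxel > 2 * sigma:
            logger.warning("voxel %.2f A > 2*sigma %.2f A: map is undersampled",
                           voxel, 2 * sigma)
        if heavy:
            pts = np.array([a.coords for a in heavy])
            lo = pts.min(axis=0) - padding
            hi = pts.max(axis=0) + padding
        else:
            lo, hi = np.zeros(3), np.full(3, voxel * 3)
        vox = np.full(3, float(voxel))
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel)) + 1 for i in range(3))
        shape = tuple(max(2, s) for s in shape)
        origin = lo
    grid = np.zeros(shape)
    if not heavy:
        return DensityMap(grid=grid, voxel=vox, origin=origin)
    cut = 4.0 * sigma
    axes = [origin[d] + vox[d] * np.arange(shape[d]) for d in range(3)]
    for a in heavy:
        sl, axlocal = [], []
        for d in range(3):
            i0 = int(np.searchsorted(axes[d], a.coords[d] - cut))
            i1 = int(np.searchsorted(axes[d], a.coords[d] + cut, side="right"))
            i0, i1 = max(0, i0), min(shape[d], i1)
            if i0 >= i1:
                break
            sl.append(slice(i0, i1))
            axlocal.append(axes[d][i0:i1] - a.coords[d])
        else:
            dx2 = (axlocal[0][:, None, None] ** 2 + axlocal[1][None, :, None] ** 2
                   + axlocal[2][None, None, :] ** 2)
            grid[tuple(sl)] += a.mass * np.exp(-dx2 / (2.0 * sigma ** 2))
    return DensityMap(grid=grid, voxel=vox, origin=origin)


# ---------------------------------------------------------------------------
# Curve simulators

#: Default total-lipid grid (molar): 9 points, 0 to 1.6 mM, mirroring the
#: experimental titration range.
DEFAULT_LIPID_TOTALS = tuple(np.linspace(0.0, 1.6e-3, 9))


def simulate_titration(k_x: float, f_max: float,
                       lipid_totals=DEFAULT_LIPID_TOTALS,
                       accessible_fraction: float = 0.6,
                       noise: NoiseModel = NoiseModel(sd=0.0),
                       replicates: int = 1, seed: int = 0) -> TitrationData:
    """Draw replicated F/F0 titration curves from the partition model.

    Noise is applied per replicate point; the default multiplicative
    Gaussian reflects intensity-proportional fluorescence error.
    """
    if k_x <= 0:
        raise ValueError("k_x must be positive")
    if f_max < 1:
        raise ValueError("f_max must be >= 1")
    lipid_totals = np.asarray(lipid_totals, dtype=float)
    if np.any(lipid_totals < 0):
        raise ValueError("lipid concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    model = thermo.partition_model(lipid_totals, k_x, f_max,
                                   accessible_fraction=accessible_fraction)
    reps = np.stack([noise.apply(model, rng) for _ in range(replicates)])
    return TitrationData(lipid_total=lipid_totals, f_over_f0=reps,
                         accessible_fraction=accessible_fraction)


def simulate_dose_response(k_d: float, s: float, i_min: float, i_max: float,
                           concentrations, noise: NoiseModel = NoiseModel(
                               kind="additive-gaussian", sd=0.0),
                           seed: int = 0) -> DoseResponseData:
    """Draw a Hill dose-response curve with additive measurement noise."""
    if k_d <= 0 or s <= 0:
        raise ValueError("k_d and s must be positive")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    model = thermo.hill_model(concentrations, k_d, s, i_min, i_max)
    return DoseResponseData(concentrations=concentrations,
                            response=noise.apply(model, rng))


def perturb_ensemble(structure: Structure, n_models: int, amplitude: float,
                     seed: int = 0) -> Structure:
    """Expand a single-model structure into a Gaussian-perturbed ensemble.

    Heavy atoms get independent isotropic Gaussian displacements of
    standard deviation ``amplitude`` per coordinate; each hydrogen
    rigidly follows the nearest heavy atom of its residue.
    """
    if structure.n_models != 1:
        raise ValueError("perturb_ensemble expects a single-model input")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    base = structure.model(structure.model_ids[0])
    heavy_idx = [i for i, a in enumerate(base) if not a.is_hydrogen]
    # hydrogen -> parent heavy atom (nearest heavy atom in same residue)
    parent: dict[int, int] = {}
    for i, a in enumerate(base):
        if a.is_hydrogen:
            candidates = [j for j in heavy_idx
                          if base[j].residue_key() == a.residue_key()]
            if not candidates:
                candidates = heavy_idx
            parent[i] = min(candidates,
                            key=lambda j: np.linalg.norm(base[j].coords - a.coords))
    out: list[Atom] = []
    for m in range(1, n_models + 1):
        disp = np.zeros((len(base), 3))
        d_heavy = rng.normal(0.0, amplitude, size=(len(heavy_idx), 3)) \
            if amplitude > 0 else np.zeros((len(heavy_idx), 3))
        for k, i in enumerate(heavy_idx):
            disp[i] = d_heavy[k]
        for i, j in parent.items():
            disp[i] = disp[j]
        for i, a in enumerate(base):
            out.append(Atom(serial=a.serial, name=a.name, element=a.element,
                            mass=a.mass, res_name=a.res_name, res_seq=a.res_seq,
                            chain_id=a.chain_id, coords=a.coords + disp[i],
                            model_id=m))
    return Structure(atoms=out, title=structure.title)
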