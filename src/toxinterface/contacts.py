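"""Contacting-atom-pair (N_p) statistics.

N_p between two atom groups is the number of unordered heavy-atom pairs
(one atom from each group) whose Euclidean distance is within a first
interaction shell, 6 A by default; the cutoff is inclusive.  This equals
integrating the non-normalized pair-distance distribution over the first
shell, and scales with group size by design.  Over a multi-model
structure (trajectory frames, ensemble members), values are averaged
with equal frame weights.

Inputs are assumed whole/unwrapped; there is no periodic-boundary
minimum-image handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import Atom, Selection, Structure

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 6.0
#: Backbone atom names excluded by the sidechain-only filter (CB kept).
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


def _heavy(atoms) -> list[Atom]:
    return [a for a in atoms if not a.is_hydrogen]


def np_pairs(atoms_a, atoms_b, cutoff: float = DEFAULT_CUTOFF) -> int:
    """Count heavy-atom pairs across two disjoint groups within ``cutoff``.

    The groups must not share atoms.  Hydrogens are ignored.  Distance
    exactly at the cutoff counts (the interaction-shell integral is
    closed at its upper bound).
    """
    ids_a = {id(a) for a in atoms_a}
    if any(id(b) in ids_a for b in atoms_b):
        raise ValueError("atom groups overlap; np_pairs requires disjoint groups")
    ha, hb = _heavy(atoms_a), _heavy(atoms_b)
    if not ha or not hb:
        logger.warning("np_pairs: empty heavy-atom group, returning 0")
        return 0
    ta = cKDTree(np.array([a.coords for a in ha]))
    tb = cKDTree(np.array([b.coords for b in hb]))
    return int(ta.count_neighbors(tb, cutoff))


@dataclass
class ContactMatrix:
    """Mean per-residue-pair N_p over frames, with residue labels."""

    rows: list[str]
    cols: list[str]
    values: np.ndarray  # shape (len(rows), len(cols))
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.cols)

    def row_totals(self) -> pd.Series:
        return self.to_dataframe().sum(axis=1)

    def col_totals(self) -> pd.Series:
        return self.to_dataframe().sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.values.sum())


def _group_by_residue(atoms) -> dict[tuple[str, int, str], list[Atom]]:
    groups: dict[tuple[str, int, str], list[Atom]] = {}
    for a in atoms:
        groups.setdefault(a.residue_key(), []).append(a)
    return groups


def _res_label(key: tuple[str, int, str]) -> str:
    chain, seq, name = key
    return f"{chain}{seq}{name}"


def _cross_counts(atoms_a, atoms_b, cutoff: float) -> dict[tuple, int]:
    """Heavy-atom pair counts aggregated by (residue_a, residue_b)."""
    ha, hb = _heavy(atoms_a), _heavy(atoms_b)
    counts: dict[tuple, int] = {}
    if not ha or not hb:
        return counts
    pa = np.array([a.coords for a in ha])
    pb = np.array([b.coords for b in hb])
    keys_a = [a.residue_key() for a in ha]
    keys_b = [b.residue_key() for b in hb]
    tree_b = cKDTree(pb)
    for i, neigh in enumerate(cKDTree(pa).query_ball_tree(tree_b, cutoff)):
        ka = keys_a[i]
        for j in neigh:
            key = (ka, keys_b[j])
            counts[key] = counts.get(key, 0) + 1
    return counts


def residue_contact_matrix(frames: Structure, sel_a: Selection, sel_b: Selection,
                           cutoff: float = DEFAULT_CUTOFF,
                           sidechain_only: bool = False) -> ContactMatrix:
    """Per-residue-pair mean N_p between two selections, over all frames.

    With ``sidechain_only`` the backbone atoms N, CA, C, O are excluded
    from both selections (CB is kept).  The two selections must not
    share atoms, and must resolve to the same residue rosters in every
    frame.
    """
    model_ids = frames.model_ids
    rows_ref = cols_ref = None
    per_frame: list[dict[tuple, int]] = []
    for mid in model_ids:
        atoms = frames.model(mid)
        aa = sel_a.apply(atoms)
        bb = sel_b.apply(atoms)
        if sidechain_only:
            aa = [a for a in aa if a.name not in BACKBONE_NAMES]
            bb = [b for b in bb if b.name not in BACKBONE_NAMES]
        if not aa or not bb:
            raise ValueError(f"selection empty in frame {mid}")
        shared = {id(a) for a in aa} & {id(b) for b in bb}
        if shared:
            raise ValueError("selections overlap; groups must be disjoint")
        rows = sorted(_group_by_residue(_heavy(aa)))
        cols = sorted(_group_by_residue(_heavy(bb)))
        if rows_ref is None:
            rows_ref, cols_ref = rows, cols
        elif rows != rows_ref or cols != cols_ref:
            raise ValueError("selection resolves to different residues across frames")
        per_frame.append(_cross_counts(aa, bb, cutoff))
    values = np.zeros((len(rows_ref), len(cols_ref)))
    row_idx = {k: i for i, k in enumerate(rows_ref)}
    col_idx = {k: j for j, k in enumerate(cols_ref)}
    for counts in per_frame:
        for (ka, kb), n in counts.items():
            values[row_idx[ka], col_idx[kb]] += n
    values /= len(model_ids)
    return ContactMatrix(rows=[_res_label(k) for k in rows_ref],
                         cols=[_res_label(k) for k in cols_ref],
                         values=values, n_frames=len(model_ids))


def lipid_contact_profile(frames: Structure, protein_sel: Selection,
                          head_res: set[str], tail_res: set[str],
                          cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Mean N_p of each protein residue with lipid head and tail atoms.

    Returns a DataFrame indexed by residue label with columns
    ``np_head`` and ``np_tail``.  The head/tail residue-name sets must
    be disjoint.
    """
    head_res, tail_res = set(head_res), set(tail_res)
    both = head_res & tail_res
    if both:
        raise ValueError(f"residue names in both head and tail sets: {sorted(both)}")
    model_ids = frames.model_ids
    keys_ref = None
    acc_head: dict[tuple, float] = {}
    acc_tail: dict[tuple, float] = {}
    for mid in model_ids:
        atoms = frames.model(mid)
        prot = protein_sel.apply(atoms)
        heads = [a for a in atoms if a.res_name in head_res]
        tails = [a for a in atoms if a.res_name in tail_res]
        keys = sorted(_group_by_residue(_heavy(prot)))
        if keys_ref is None:
            keys_ref = keys
            for k in keys:
                acc_head[k] = acc_tail[k] = 0.0
        elif keys != keys_ref:
            raise ValueError("protein selection differs across frames")
        for target, acc in ((heads, acc_head), (tails, acc_tail)):
            for (ka, _kb), n in _cross_counts(prot, target, cutoff).items():
                acc[ka] += n
    nf = len(model_ids)
    return pd.DataFrame(
        {"np_head": [acc_head[k] / nf for k in keys_ref],
         "np_tail": [acc_tail[k] / nf for k in keys_ref]},
        index=[_res_label(k) for k in keys_ref])


@dataclass
class CompactnessProfile:
    """Per-member mean side-chain N_p with all other cluster members."""

    residues: list[str]
    values: np.ndarray
    n_frames: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.residues, name="np_sidechain")


def cluster_compactness(frames: Structure, members: list[tuple[str, int]],
                        cutoff: float = DEFAULT_CUTOFF) -> CompactnessProfile:
    """Compactness of a side-chain cluster via mutual contact counts.

    For each member residue, the mean (over frames) N_p between its
    side-chain heavy atoms and the union of all other members'
    side-chain heavy atoms.  Fewer contacts mean a looser, more
    solvent-exposed arrangement.  Members without side-chain heavy atoms
    (glycine) score 0.
    """
    if len(members) < 2:
        raise ValueError("need >= 2 cluster members")
    members = [tuple(m) for m in members]
    model_ids = frames.model_ids
    totals = np.zeros(len(members))
    for mid in model_ids:
        atoms = frames.model(mid)
        side: dict[tuple[str, int], list[Atom]] = {m: [] for m in members}
        for a in atoms:
            key = (a.chain_id, a.res_seq)
            if key in side and not a.is_hydrogen and a.name not in BACKBONE_NAMES:
                side[key].append(a)
        for i, m in enumerate(members):
            if not side[m]:
                logger.info("member %s has no side-chain heavy atoms; N_p = 0", m)
                continue
            others = [a for mm in members if mm != m for a in side[mm]]
            if others:
                totals[i] += np_pairs(side[m], others, cutoff)
    values = totals / len(model_ids)
    labels = [f"{c}{r}" for c, r in members]
    return CompactnessProfile(residues=labels, values=values,
                              n_frames=len(model_ids))


def neighbor_residue_count(frames: Structure, query_res: tuple[str, int],
                           partner_sel: Selection,
                           cutoff: float = DEFAULT_CUTOFF) -> float:
    """Mean number of partner residues near a query residue.

    A partner residue counts in a frame when at least one of its heavy
    atoms is within ``cutoff`` of at least one heavy atom of the query
    residue; the count is averaged over frames.
    """
    chain, res_seq = query_res
    model_ids = frames.model_ids
    total = 0.0
    for mid in model_ids:
        atoms = frames.model(mid)
        query = [a for a in atoms
                 if a.chain_id == chain and a.res_seq == res_seq
                 and not a.is_hydrogen]
        if not query:
            raise ValueError(f"query residue {chain}{res_seq} absent in frame {mid}")
        partners = _heavy(partner_sel.apply(atoms))
        partners = [p for p in partners
                    if (p.chain_id, p.res_seq) != (chain, res_seq)]
        if not partners:
            logger.warning("neighbor_residue_count: empty partner selection")
            continue
        qtree = cKDTree(np.array([a.coords for a in query]))
        touched = set()
        for p, neigh in zip(partners, qtree.query_ball_point(
                np.array([p.coords for p in partners]), cutoff)):
            if neigh:
                touched.add((p.chain_id, p.res_seq))
        total += len(touched)
    return total / len(model_ids)
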