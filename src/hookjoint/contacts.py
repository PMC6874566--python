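"""Inter-subunit contacts along the −5/6/11-start lattice directions.

Subunit 0's neighbors along the three major helical directions are the
subunits 5, 6 and 11 steps up the 1-start helix.  Because each of the 11
protofilaments carries its own subunit conformation, every lattice
direction offers 11 distinct "contexts" for the same residue-residue
interface.  Interfaces present at the cutoff in all 11 contexts are
classified *constant*; present in some and absent in others, *switching* —
the operational version of interactions that survive, or are made and
broken by, protofilament compression and extension.

Per-residue variability is the standard deviation, across the 11 contexts,
of the Cα–Cα distance from each residue to the corresponding residue of
the directional neighbor: small where an interface acts as a pivot, large
where domains slide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InsufficientDataError
from .lattice import NEIGHBOR_OFFSETS, HelicalLattice
from .structure_io import DomainDefinition, SubunitModel, assign_domains

logger = logging.getLogger("hookjoint.contacts")

__all__ = [
    "ContactTable",
    "ResidueVariability",
    "find_contacts",
    "residue_variability",
    "d1_triangle_gap",
    "DEFAULT_CONTACT_CUTOFF",
]

#: Heavy-atom distance (Å) below which two residues count as interacting.
DEFAULT_CONTACT_CUTOFF = 4.0


# --------------------------------------------------------------------------
# Context selection
# --------------------------------------------------------------------------

def _representative_pairs(lattice: HelicalLattice, direction: int
                          ) -> dict[int, tuple[int, int]]:
    """One (k, k+direction) pair per protofilament context, chosen nearest
    the segment's axial middle to minimize end effects."""
    if direction not in NEIGHBOR_OFFSETS:
        raise ValueError(f"direction must be one of {NEIGHBOR_OFFSETS}, "
                         f"got {direction}")
    pair_map = lattice.neighbor_maps.get(direction, {})
    if not pair_map:
        raise InsufficientDataError(f"no +{direction} pairs in the lattice")
    s = lattice.axial_position
    s_mid = float(np.median(list(s.values())))
    chosen: dict[int, tuple[int, int]] = {}
    for k, k2 in pair_map.items():
        p = lattice.protofilament[k]
        mid = 0.5 * (s[k] + s[k2])
        if p not in chosen or abs(mid - s_mid) < abs(
                0.5 * (s[chosen[p][0]] + s[chosen[p][1]]) - s_mid):
            chosen[p] = (k, k2)
    return chosen


# --------------------------------------------------------------------------
# Contact tables
# --------------------------------------------------------------------------

@dataclass
class ContactTable:
    """Residue-pair interface distances across the protofilament contexts.

    ``table`` has one row per (residue_0, residue_neighbor) pair observed
    in contact in at least one context, with per-context minimal
    heavy-atom distances, mean, SD, presence mask and class
    (constant/switching).
    """

    direction: int
    cutoff: float
    table: pd.DataFrame
    contexts: dict[int, tuple[int, int]]

    def of_class(self, cls: str) -> pd.DataFrame:
        return self.table[self.table["class"] == cls]

    @property
    def n_constant(self) -> int:
        return int((self.table["class"] == "constant").sum())

    @property
    def n_switching(self) -> int:
        return int((self.table["class"] == "switching").sum())


def _min_residue_distances(sub_a: SubunitModel, sub_b: SubunitModel,
                           pairs: set[tuple[int, int]]) -> dict[tuple[int, int], float]:
    """Min heavy-atom distance for the requested residue pairs."""
    atoms_a = {int(n): np.array(list(r.values()))
               for n, r in zip(sub_a.residue_numbers, sub_a.atoms)}
    atoms_b = {int(n): np.array(list(r.values()))
               for n, r in zip(sub_b.residue_numbers, sub_b.atoms)}
    out = {}
    for ra, rb in pairs:
        if ra in atoms_a and rb in atoms_b:
            d = np.linalg.norm(atoms_a[ra][:, None, :] - atoms_b[rb][None, :, :],
                               axis=-1)
            out[(ra, rb)] = float(d.min())
        else:
            out[(ra, rb)] = np.nan
    return out


def find_contacts(subunits: Sequence[SubunitModel], lattice: HelicalLattice,
                  direction: int,
                  cutoff: float = DEFAULT_CONTACT_CUTOFF) -> ContactTable:
    """Enumerate residue-level interfaces along one lattice direction.

    A residue pair is *in contact* in a context when its minimal
    heavy-atom distance is ≤ ``cutoff``.  The union of in-contact pairs
    over all contexts is then measured in every context, and each pair is
    classified constant (present everywhere) or switching.
    """
    contexts = _representative_pairs(lattice, direction)
    by_chain = {s.chain_id: s for s in subunits}
    chain_of_k = lattice.chain_of_k

    union: set[tuple[int, int]] = set()
    for p, (k, k2) in contexts.items():
        sub_a, sub_b = by_chain[chain_of_k[k]], by_chain[chain_of_k[k2]]
        ca, ra = sub_a.heavy_coords()
        cb, rb = sub_b.heavy_coords()
        if cutoff > 0:
            tree_a, tree_b = cKDTree(ca), cKDTree(cb)
            for ia, ib_list in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
                for ib in ib_list:
                    union.add((int(ra[ia]), int(rb[ib])))
    columns = {f"context_{p}": [] for p in sorted(contexts)}
    records = []
    pairs = sorted(union)
    per_context = {}
    for p, (k, k2) in sorted(contexts.items()):
        per_context[p] = _min_residue_distances(by_chain[chain_of_k[k]],
                                                by_chain[chain_of_k[k2]],
                                                union)
    for ra, rb in pairs:
        dists = np.array([per_context[p][(ra, rb)] for p in sorted(contexts)])
        present = dists <= cutoff
        n_present = int(np.nansum(present))
        cls = ("constant" if n_present == len(contexts)
               else "switching" if n_present >= 1 else "absent")
        rec = {"residue_0": ra, "residue_neighbor": rb,
               "mean": float(np.nanmean(dists)), "sd": float(np.nanstd(dists)),
               "n_present": n_present, "class": cls}
        rec.update({f"context_{p}": float(d)
                    for p, d in zip(sorted(contexts), dists)})
        rec.update({f"present_{p}": bool(pr)
                    for p, pr in zip(sorted(contexts), present)})
        records.append(rec)
    base_cols = (["residue_0", "residue_neighbor", "mean", "sd",
                  "n_present", "class"]
                 + [f"context_{p}" for p in sorted(contexts)]
                 + [f"present_{p}" for p in sorted(contexts)])
    table = pd.DataFrame(records, columns=base_cols)
    logger.info("direction +%d: %d interfaces (%d constant, %d switching)",
                direction, len(table),
                int((table["class"] == "constant").sum()) if len(table) else 0,
                int((table["class"] == "switching").sum()) if len(table) else 0)
    return ContactTable(direction=direction, cutoff=cutoff, table=table,
                        contexts=contexts)


# --------------------------------------------------------------------------
# Residue variability
# --------------------------------------------------------------------------

@dataclass
class ResidueVariability:
    """Per-residue Cα neighbor-distance SD across protofilament contexts."""

    direction: int
    distances: pd.DataFrame    # index residue, one column per context
    sd: pd.Series              # per-residue SD (NaN where contexts missing)
    complete: bool

    def min_sd_residue(self) -> int:
        return int(self.sd.idxmin())

    def max_sd_residue(self) -> int:
        return int(self.sd.idxmax())

    def domain_summary(self, defs: Sequence[DomainDefinition],
                       subunit: SubunitModel) -> pd.DataFrame:
        """Mean/min/max SD per domain, plus which domain holds the global
        extremes."""
        assigned = assign_domains(subunit, defs)
        rows = []
        for d in defs:
            members = [r for r in self.sd.index if r in set(assigned[d.name])]
            if not members:
                continue
            sub_sd = self.sd.loc[members].dropna()
            rows.append({"domain": d.name, "mean_sd": float(sub_sd.mean()),
                         "min_sd": float(sub_sd.min()),
                         "max_sd": float(sub_sd.max())})
        return pd.DataFrame(rows).set_index("domain")


def residue_variability(subunits: Sequence[SubunitModel],
                        lattice: HelicalLattice,
                        direction: int) -> ResidueVariability:
    """SD, across the protofilament contexts, of each residue's Cα distance
    to the corresponding residue of the +direction neighbor.

    Residues missing from any context are reported with NaN SD and the
    result flagged incomplete (with a warning) rather than failing.
    """
    contexts = _representative_pairs(lattice, direction)
    by_chain = {s.chain_id: s for s in subunits}
    chain_of_k = lattice.chain_of_k
    cols = {}
    for p, (k, k2) in sorted(contexts.items()):
        sub_a, sub_b = by_chain[chain_of_k[k]], by_chain[chain_of_k[k2]]
        common = np.intersect1d(sub_a.residue_numbers, sub_b.residue_numbers)
        d = np.linalg.norm(sub_a.ca_of(common) - sub_b.ca_of(common), axis=1)
        cols[p] = pd.Series(d, index=common.astype(int))
    frame = pd.DataFrame(cols)
    complete_rows = frame.dropna()
    complete = len(complete_rows) == len(frame)
    if not complete:
        logger.warning("direction +%d: %d residues missing from some contexts",
                       direction, len(frame) - len(complete_rows))
    sd = frame.std(axis=1, ddof=0).where(frame.notna().all(axis=1))
    expected = lattice.start_number
    if len(contexts) < expected:
        logger.warning("direction +%d: only %d of %d contexts represented",
                       direction, len(contexts), expected)
    return ResidueVariability(direction=direction, distances=frame, sd=sd,
                              complete=complete and len(contexts) == expected)


# --------------------------------------------------------------------------
# D1 triangle gap
# --------------------------------------------------------------------------

def d1_triangle_gap(subunits: Sequence[SubunitModel], lattice: HelicalLattice,
                    context: int, defs: Sequence[DomainDefinition],
                    domain: str = "D1") -> dict:
    """Gap metrics of the triangle formed by the D1 domains of subunits
    0, +6 and +11 in one protofilament context.

    Returns the three pairwise minimal heavy-atom distances between the
    domains and the area (Å²) of the triangle of domain centroids.  The
    gap between these three domains shrinks on the compressed side of the
    bend and widens on the extended side.
    """
    pairs6 = _representative_pairs(lattice, 6)
    if context not in pairs6:
        raise InsufficientDataError(f"no +6 pair for protofilament {context}")
    k0 = pairs6[context][0]
    trio = {0: k0, 6: k0 + 6, 11: k0 + 11}
    chain_of_k = lattice.chain_of_k
    by_chain = {s.chain_id: s for s in subunits}
    missing = [off for off, k in trio.items() if k not in chain_of_k]
    if missing:
        raise InsufficientDataError(
            f"context {context}: neighbors {missing} absent from the segment")

    coords = {}
    for off, k in trio.items():
        sub = by_chain[chain_of_k[k]]
        members = assign_domains(sub, defs)[domain]
        if members.size == 0:
            raise InsufficientDataError(f"domain {domain!r} empty in context")
        mask = np.isin(sub.residue_numbers, members)
        pts, resnums = sub.heavy_coords()
        coords[off] = pts[np.isin(resnums, members)]
    mins = {}
    for a, b in [(0, 6), (6, 11), (0, 11)]:
        d = cKDTree(coords[a]).query(coords[b])[0]
        mins[f"min_dist_{a}_{b}"] = float(d.min())
    cents = {off: c.mean(axis=0) for off, c in coords.items()}
    v1, v2 = cents[6] - cents[0], cents[11] - cents[0]
    area = 0.5 * float(np.linalg.norm(np.cross(v1, v2)))
    return {"context": context, **mins, "centroid_triangle_area": area}
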