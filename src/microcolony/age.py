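"""Cellular-age test via replicative pole-age bookkeeping.

In a rod-shaped bacterium each division creates two new poles at the septum;
each daughter keeps one pre-existing pole.  A cell's replicative age is the
number of divisions its older pole has persisted through.  Which daughter
inherits the parent's older pole is decided geometrically: the daughter whose
first centroid lies farther from the parent's own birth site keeps the old
pole (growth elongates away from the inherited pole), the other daughter
receives the parent's younger pole and is "rejuvenated" to age 1.

Age is then compared between the HIGH- and LOW-ATP classes with a two-sided
Mann-Whitney rank-sum test: a heavy right age-tail in the HIGH class would
implicate an age-partitioning mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .lineage import HIGH, LOW, BinaryClassification, LineageTree

__all__ = ["PoleAgeAssignment", "assign_pole_ages", "compare_age_classes"]


@dataclass
class PoleAgeAssignment:
    cell_id: str
    old_pole_age: int   # divisions the inherited (older) pole has witnessed
    new_pole_age: int   # always 0 at birth
    tie_broken: bool = False

    @property
    def cell_age(self) -> int:
        return self.old_pole_age


class AgeAssignmentError(ValueError):
    pass


def _first_centroid(tree: LineageTree, cell_id: str) -> np.ndarray:
    for o in tree.cells[cell_id].observations:
        if not o.placeholder:
            return np.array([o.x_um, o.y_um])
    raise AgeAssignmentError(
        f"cell {cell_id} has no non-placeholder centroid at its first frames"
    )


def assign_pole_ages(tree: LineageTree) -> list[PoleAgeAssignment]:
    """Propagate pole ages down the tree; founder poles start at age 0.

    At each division the parent's two poles both gain one witnessed
    division: the daughter farther from the parent's birth centroid inherits
    the older pole (age ``parent_old + 1``); her sister inherits the pole
    created at the parent's birth, now age 1.  Equidistant daughters are
    broken deterministically toward the lower cell id and flagged.
    """
    ages: dict[str, int] = {}
    flags: dict[str, bool] = {}
    order: list[str] = []
    queue = sorted(tree.founders)
    for f in queue:
        ages[f] = 0
        flags[f] = False
    while queue:
        cid = queue.pop(0)
        order.append(cid)
        kids = tree.children_of(cid)
        if not kids:
            continue
        if len(kids) != 2:
            raise AgeAssignmentError(f"cell {cid} has {len(kids)} children")
        ref = _first_centroid(tree, cid)
        c0, c1 = (_first_centroid(tree, k) for k in kids)
        d0 = float(np.hypot(*(c0 - ref)))
        d1 = float(np.hypot(*(c1 - ref)))
        tie = math.isclose(d0, d1, rel_tol=0.0, abs_tol=1e-12)
        if tie:
            old_kid, new_kid = kids[0], kids[1]  # kids sorted by cell_id
        elif d0 > d1:
            old_kid, new_kid = kids[0], kids[1]
        else:
            old_kid, new_kid = kids[1], kids[0]
        ages[old_kid] = ages[cid] + 1
        ages[new_kid] = 1
        flags[old_kid] = flags[new_kid] = tie
        queue.extend(kids)
    return [
        PoleAgeAssignment(cell_id=cid, old_pole_age=ages[cid], new_pole_age=0,
                          tie_broken=flags[cid])
        for cid in order
    ]


def compare_age_classes(
    assignments: list[PoleAgeAssignment],
    classification: BinaryClassification,
) -> dict:
    """Two-sided tie-corrected Mann-Whitney on cell age by ATP class."""
    groups = {HIGH: [], LOW: []}
    for a in assignments:
        cls = classification.per_cell_class.get(a.cell_id)
        if cls in groups:
            groups[cls].append(a.cell_age)
    if min(len(groups[HIGH]), len(groups[LOW])) < 3:
        raise ValueError("need at least 3 cells per class")
    hi = np.array(groups[HIGH], dtype=float)
    lo = np.array(groups[LOW], dtype=float)
    if np.ptp(np.concatenate([hi, lo])) == 0:
        u, p = hi.size * lo.size / 2.0, 1.0
    else:
        u, p = mannwhitneyu(hi, lo, alternative="two-sided")
    return {
        "U": float(u),
        "p": float(p),
        "median_high": float(np.median(hi)),
        "median_low": float(np.median(lo)),
        "n_high": int(hi.size),
        "n_low": int(lo.size),
    }
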