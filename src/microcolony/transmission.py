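"""Intercellular-transmission test: spatial localization and factor decomposition.

Two complementary analyses on a single colony snapshot (by default the final
movie frame, the largest colony):

* **Spatial localization** — the fraction of cells whose nearest spatial
  neighbour shares their HIGH/LOW class, compared against a permutation null
  that shuffles class labels over the fixed cell positions.

* **Space-vs-lineage factor decomposition** — per focal cell, four absolute
  phenotype differences: to the nearest neighbour (dNB), to that neighbour's
  sister (dER), to the closest relative by lineage-path distance (dCR), and
  to the cell spatially equidistant with the closest relative (dED).  The
  per-cell ratio dER/dNB measures how much of phenotypic similarity is
  carried by sheer spatial proximity; dED/dCR measures how much is carried
  by lineage.  Mean ratios get 95% t-intervals on the log scale; an interval
  excluding 1 rejects the corresponding null.  The transmission signature is
  dER/dNB > 1 with dED/dCR ~ 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import t as t_dist

from .lineage import HIGH, LOW, BinaryClassification, LineageTree

__all__ = [
    "SpatialSnapshot",
    "SpatialFactorResult",
    "final_snapshot",
    "spatial_localization_test",
    "compute_spatial_factors",
    "ratio_interval",
]


@dataclass
class SpatialSnapshot:
    """Cells of one frame: positions, phenotype values, and binary classes."""

    frame_time: float
    cell_ids: list[str]
    xy: np.ndarray          # (n, 2) in um
    phenotype: np.ndarray   # (n,) in mM (lifetime-mean ATP)
    classes: list[str]      # HIGH/LOW per cell

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids in snapshot")


@dataclass
class RatioSummary:
    mean: float
    lower: float
    upper: float
    reject_h0: bool
    n: int
    n_excluded: int = 0


@dataclass
class SpatialFactorResult:
    per_cell: dict = field(default_factory=dict)  # cell_id -> {dNB,dER,dCR,dED}
    ratio_spatial: RatioSummary | None = None     # dER/dNB
    ratio_lineage: RatioSummary | None = None     # dED/dCR
    localization_p: float | None = None
    n_used: int = 0
    n_excluded: int = 0
    no_variation: bool = False


def final_snapshot(
    tree: LineageTree, classification: BinaryClassification
) -> SpatialSnapshot:
    """Snapshot of the last movie frame.

    The HIGH/LOW label of each cell is its class *at that frame* (the frame
    being analysed is the frame whose spatial pattern is tested); the
    continuous phenotype used for the d-differences is the noise-reduced
    lifetime-mean ATP.
    """
    last_frame = max(
        o.frame for c in tree.cells.values() for o in c.observations
        if not o.placeholder
    )
    ids, xy, ph, cls = [], [], [], []
    for cid in sorted(tree.cells):
        cell = tree.cells[cid]
        for o in cell.observations:
            if o.frame == last_frame and not o.placeholder:
                ids.append(cid)
                xy.append((o.x_um, o.y_um))
                ph.append(cell.mean_atp())
                cls.append(classification.per_observation_class[(cid, last_frame)])
                break
    return SpatialSnapshot(
        frame_time=max(o.time_h for c in tree.cells.values() for o in c.observations),
        cell_ids=ids, xy=np.array(xy), phenotype=np.array(ph), classes=cls,
    )


def _nn_indices(xy: np.ndarray) -> np.ndarray:
    d = cdist(xy, xy)
    np.fill_diagonal(d, np.inf)
    return d.argmin(axis=1)


def spatial_localization_test(
    snapshot: SpatialSnapshot, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Permutation p-value for same-class nearest-neighbour clustering.

    Statistic: fraction of cells whose nearest neighbour has the same class.
    Null: class labels permuted uniformly over the fixed positions; p is the
    fraction of permutations with a statistic >= the observed one.
    """
    n = len(snapshot.cell_ids)
    if n < 8:
        raise ValueError("need at least 8 cells")
    labels = np.array([1 if c == HIGH else 0 for c in snapshot.classes])
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    nn = _nn_indices(snapshot.xy)
    observed = float(np.mean(labels == labels[nn]))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if np.mean(perm == perm[nn]) >= observed:
            count += 1
    return count / n_perm


def _lineage_distances(tree: LineageTree, ids: list[str]) -> np.ndarray:
    """Pairwise path length (edges) between cells in the lineage forest.

    Cells in different trees of the forest get an infinite distance.
    """
    depth_paths = {cid: tree.path_to_root(cid) for cid in ids}
    n = len(ids)
    D = np.full((n, n), np.inf)
    for i in range(n):
        pi = depth_paths[ids[i]]
        pos_i = {c: k for k, c in enumerate(pi)}
        for j in range(i, n):
            if i == j:
                D[i, j] = 0.0
                continue
            for k, c in enumerate(depth_paths[ids[j]]):
                if c in pos_i:  # lowest common ancestor
                    D[i, j] = D[j, i] = pos_i[c] + k
                    break
    return D


def ratio_interval(values, alpha: float = 0.05) -> RatioSummary:
    """Mean ratio with a 95% t-interval computed on the log scale.

    Ratios are positive quantities, so the interval is symmetric in
    log-space and back-transformed; non-positive values cannot be logged and
    are excluded (counted).  H0 (ratio = 1) is rejected when the interval
    excludes 1.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    pos = v[v > 0]
    n_excluded = int(v.size - pos.size)
    if pos.size < 3:
        raise ValueError("need at least 3 positive finite ratios")
    logs = np.log(pos)
    m = logs.mean()
    se = logs.std(ddof=1) / math.sqrt(pos.size)
    tcrit = t_dist.ppf(1 - alpha / 2, pos.size - 1)
    lo, hi = math.exp(m - tcrit * se), math.exp(m + tcrit * se)
    return RatioSummary(
        mean=math.exp(m), lower=lo, upper=hi,
        reject_h0=not (lo <= 1.0 <= hi), n=int(pos.size), n_excluded=n_excluded,
    )


def compute_spatial_factors(
    snapshot: SpatialSnapshot, tree: LineageTree, alpha: float = 0.05
) -> SpatialFactorResult:
    """Per-cell dNB/dER/dCR/dED and the two ratio statistics.

    Per focal cell: dNB to the nearest spatial neighbour; dER to that
    neighbour's sister (skipped when the sister is the focal cell or absent
    from the snapshot); dCR to the cell with minimal lineage-path distance
    (spatial proximity breaks ties); dED to the cell, excluding the closest
    relative, whose spatial distance to the focal cell best matches the
    focal-to-closest-relative distance.  Ratios are averaged per cell with
    95% t-intervals on the log scale; cells with zero denominators are
    excluded and counted.
    """
    ids = snapshot.cell_ids
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 cells for factor analysis")
    for cid in ids:
        if cid not in tree.cells:
            raise ValueError(f"snapshot cell {cid} missing from tree")
    ph = snapshot.phenotype
    D = cdist(snapshot.xy, snapshot.xy)
    np.fill_diagonal(D, np.inf)
    L = _lineage_distances(tree, ids)
    np.fill_diagonal(L, np.inf)

    result = SpatialFactorResult()
    if np.ptp(ph) == 0:
        result.no_variation = True
        result.n_used = 0
        result.n_excluded = n
        for i, cid in enumerate(ids):
            result.per_cell[cid] = dict(dNB=0.0, dER=None, dCR=0.0, dED=0.0)
        return result

    idx_of = {cid: i for i, cid in enumerate(ids)}
    r_spatial, r_lineage = [], []
    n_excl_sp = n_excl_lin = 0
    for i, cid in enumerate(ids):
        rec: dict = {}
        nb = int(D[i].argmin())
        rec["dNB"] = abs(ph[i] - ph[nb])
        # the neighbour's sister cell; when the sister is the focal cell
        # itself or absent from the snapshot, fall back to the neighbour's
        # next-closest relative (cousin/niece) so the comparison cell is
        # still drawn from the neighbour's sister lineage
        er = None
        sister = tree.sister_of(ids[nb])
        if sister is not None and sister in idx_of and sister != cid:
            er = idx_of[sister]
        else:
            lnb = L[nb].copy()
            lnb[[i, nb]] = np.inf
            if np.isfinite(lnb).any():
                cand_er = np.flatnonzero(lnb == lnb.min())
                er = int(cand_er[np.argmin(D[nb, cand_er])])
        rec["dER"] = abs(ph[i] - ph[er]) if er is not None else None
        # closest relative by lineage distance, ties -> spatially closer
        lmin = L[i].min()
        cand = np.flatnonzero(L[i] == lmin)
        cr = int(cand[np.argmin(D[i, cand])])
        rec["dCR"] = abs(ph[i] - ph[cr])
        # equidistant cell: |d(i,j) - d(i,cr)| minimal, j not in {i, cr}
        target = D[i, cr]
        gap = np.abs(D[i] - target)
        gap[cr] = np.inf
        ed = int(gap.argmin())
        rec["dED"] = abs(ph[i] - ph[ed])
        result.per_cell[cid] = rec

        if rec["dER"] is not None:
            if rec["dNB"] > 0:
                r_spatial.append(rec["dER"] / rec["dNB"])
            else:
                n_excl_sp += 1
        if rec["dCR"] > 0:
            r_lineage.append(rec["dED"] / rec["dCR"])
        else:
            n_excl_lin += 1

    result.ratio_spatial = ratio_interval(r_spatial, alpha=alpha)
    result.ratio_spatial.n_excluded += n_excl_sp
    result.ratio_lineage = ratio_interval(r_lineage, alpha=alpha)
    result.ratio_lineage.n_excluded += n_excl_lin
    result.n_used = n - max(n_excl_sp, n_excl_lin)
    result.n_excluded = max(n_excl_sp, n_excl_lin)
    return result
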