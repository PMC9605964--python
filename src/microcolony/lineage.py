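"""Lineage-tree data model, table I/O, validation, and high/low ATP classification.

A microcolony movie is represented as a forest of :class:`CellRecord` objects.
Each cell carries an ordered list of per-frame :class:`Observation` values
(time in hours, centroid in micrometres, and either a pre-computed ATP
concentration in mM or a pair of raw fluorescence intensities from 405-nm and
488-nm excitation).  Frames for which segmentation failed upstream are kept in
the table as *placeholders*: they preserve tree continuity but are excluded
from every statistic.

The global high/low classification follows the two-component Gaussian-mixture
convention: a single threshold is placed at the equal-posterior point between
the two fitted component means, and every observation (and every cell, via its
lifetime-mean ATP) is labelled HIGH or LOW against that one threshold.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

__all__ = [
    "Observation",
    "CellRecord",
    "LineageTree",
    "BinaryClassification",
    "HIGH",
    "LOW",
    "TABLE_COLUMNS",
    "read_lineage_table",
    "write_lineage_table",
    "validate_tree",
    "fit_gmm_threshold",
    "classify",
]

HIGH = "HIGH"
LOW = "LOW"

#: canonical long-format schema: one row per (cell, frame)
TABLE_COLUMNS = [
    "cell_id",
    "parent_id",
    "frame",
    "time_h",
    "x_um",
    "y_um",
    "fluor_405",
    "fluor_488",
    "atp_mM",
    "placeholder",
]


class LineageError(ValueError):
    """Malformed lineage table or broken tree structure."""


@dataclass
class Observation:
    """One cell at one movie frame."""

    frame: int
    time_h: float
    x_um: float
    y_um: float
    fluor_405: float | None = None
    fluor_488: float | None = None
    atp_mM: float | None = None
    placeholder: bool = False

    def has_signal(self) -> bool:
        """True if the observation carries ATP directly or both raw channels."""
        return self.atp_mM is not None or (
            self.fluor_405 is not None and self.fluor_488 is not None
        )


@dataclass
class CellRecord:
    """A single tracked cell from birth to division (or movie end)."""

    cell_id: str
    parent_id: str | None = None
    observations: list[Observation] = field(default_factory=list)

    @property
    def birth_time(self) -> float:
        return self.observations[0].time_h

    @property
    def end_time(self) -> float:
        return self.observations[-1].time_h

    def valid_observations(self) -> list[Observation]:
        """Observations usable in statistics (placeholders excluded)."""
        return [o for o in self.observations if not o.placeholder]

    def atp_trace(self) -> np.ndarray:
        """Non-placeholder ATP values in frame order."""
        return np.array(
            [o.atp_mM for o in self.valid_observations() if o.atp_mM is not None],
            dtype=float,
        )

    def mean_atp(self) -> float:
        """Lifetime-mean ATP over non-placeholder frames (NaN if none)."""
        trace = self.atp_trace()
        return float(trace.mean()) if trace.size else math.nan


@dataclass
class LineageTree:
    """Forest of cells with parent/child links (strict binary fission)."""

    cells: dict[str, CellRecord] = field(default_factory=dict)

    @property
    def founders(self) -> list[str]:
        return [cid for cid, c in self.cells.items() if c.parent_id is None]

    def children_of(self, cell_id: str) -> list[str]:
        return sorted(
            cid for cid, c in self.cells.items() if c.parent_id == cell_id
        )

    def sister_of(self, cell_id: str) -> str | None:
        """The sibling sharing this cell's parent, if any."""
        parent = self.cells[cell_id].parent_id
        if parent is None:
            return None
        sibs = [c for c in self.children_of(parent) if c != cell_id]
        return sibs[0] if sibs else None

    def leaves(self) -> list[str]:
        return [cid for cid in sorted(self.cells) if not self.children_of(cid)]

    def root_of(self, cell_id: str) -> str:
        cid = cell_id
        while self.cells[cid].parent_id is not None:
            cid = self.cells[cid].parent_id
        return cid

    def path_to_root(self, cell_id: str) -> list[str]:
        """cell_id, parent, grandparent, ..., founder."""
        path = [cell_id]
        while self.cells[path[-1]].parent_id is not None:
            path.append(self.cells[path[-1]].parent_id)
        return path

    def root_to_leaf_paths(self) -> list[list[str]]:
        return [list(reversed(self.path_to_root(leaf))) for leaf in self.leaves()]


@dataclass
class BinaryClassification:
    """Global GMM threshold plus HIGH/LOW labels per observation and per cell."""

    threshold: float
    gmm_params: list[tuple[float, float, float]]  # (weight, mean, sd) x 2
    per_observation_class: dict[tuple[str, int], str] = field(default_factory=dict)
    per_cell_class: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Table I/O


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_lineage_table(path) -> LineageTree:
    """Read a long-format lineage table (CSV) into a validated LineageTree.

    Parameters
    ----------
    path : str or file-like
        UTF-8 comma-delimited text with header ``cell_id,parent_id,frame,
        time_h,x_um,y_um,fluor_405,fluor_488,atp_mM,placeholder``.  Empty
        ``parent_id`` marks a founder; ``placeholder`` is 0/1.

    Raises
    ------
    LineageError
        On a malformed row (naming its line), a missing column, an orphan
        parent reference, or any violated tree invariant.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str}, comment="#")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise LineageError(f"lineage table missing columns: {missing}")

    tree = LineageTree()
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cid = str(row.cell_id)
            pid = row.parent_id
            pid = None if (pid is None or (isinstance(pid, float) and math.isnan(pid)) or str(pid) == "") else str(pid)
            obs = Observation(
                frame=int(row.frame),
                time_h=float(row.time_h),
                x_um=float(row.x_um),
                y_um=float(row.y_um),
                fluor_405=_parse_optional_float(row.fluor_405),
                fluor_488=_parse_optional_float(row.fluor_488),
                atp_mM=_parse_optional_float(row.atp_mM),
                placeholder=bool(int(row.placeholder)),
            )
        except (TypeError, ValueError) as exc:
            raise LineageError(f"malformed row at line {line_no}: {exc}") from exc
        if obs.time_h < 0:
            raise LineageError(f"negative time at line {line_no}")
        if not obs.placeholder and not obs.has_signal():
            raise LineageError(
                f"line {line_no}: non-placeholder observation has neither ATP "
                "nor both fluorescence channels"
            )
        cell = tree.cells.setdefault(cid, CellRecord(cell_id=cid, parent_id=pid))
        if cell.parent_id != pid:
            raise LineageError(f"cell {cid!r} listed with conflicting parent ids")
        cell.observations.append(obs)

    for cell in tree.cells.values():
        cell.observations.sort(key=lambda o: o.frame)
        if cell.parent_id is not None and cell.parent_id not in tree.cells:
            raise LineageError(
                f"cell {cell.cell_id!r} references missing parent {cell.parent_id!r}"
            )

    violations = validate_tree(tree)
    if violations:
        raise LineageError("invalid lineage tree: " + "; ".join(violations))
    return tree


def write_lineage_table(tree: LineageTree, path) -> None:
    """Write a LineageTree back to the canonical long-format CSV."""
    rows = []
    for cid in sorted(tree.cells):
        cell = tree.cells[cid]
        for o in cell.observations:
            rows.append(
                {
                    "cell_id": cid,
                    "parent_id": cell.parent_id if cell.parent_id is not None else "",
                    "frame": o.frame,
                    "time_h": o.time_h,
                    "x_um": o.x_um,
                    "y_um": o.y_um,
                    "fluor_405": "" if o.fluor_405 is None else repr(o.fluor_405),
                    "fluor_488": "" if o.fluor_488 is None else repr(o.fluor_488),
                    "atp_mM": "" if o.atp_mM is None else repr(o.atp_mM),
                    "placeholder": int(o.placeholder),
                }
            )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df.to_csv(path, index=False)


def tree_to_frame(tree: LineageTree) -> pd.DataFrame:
    """Long-format DataFrame view of a tree (round-trips through CSV)."""
    buf = io.StringIO()
    write_lineage_table(tree, buf)
    buf.seek(0)
    return pd.read_csv(buf, dtype={"cell_id": str, "parent_id": str})


# ---------------------------------------------------------------------------
# Validation


def validate_tree(tree: LineageTree) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    Violations are data, not exceptions: an empty list means the tree is
    valid.  Checked: observation-time ordering, birth<=end, parent existence,
    strictly binary division, parent end before daughter birth, acyclicity.
    """
    violations: list[str] = []
    for cid in sorted(tree.cells):
        cell = tree.cells[cid]
        if not cell.observations:
            violations.append(f"{cid}: no observations")
            continue
        times = [o.time_h for o in cell.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            violations.append(f"{cid}: time ordering (observation times not strictly increasing)")
        if cell.parent_id is not None:
            parent = tree.cells.get(cell.parent_id)
            if parent is None:
                violations.append(f"{cid}: missing parent {cell.parent_id}")
            elif parent.observations and parent.end_time > cell.birth_time:
                violations.append(f"{cid}: time ordering (born before parent {cell.parent_id} ended)")
        kids = tree.children_of(cid)
        if len(kids) not in (0, 2):
            violations.append(f"{cid}: non-binary division ({len(kids)} children)")
    # cycle check: walking to the root must terminate
    for cid in sorted(tree.cells):
        seen = set()
        cur = cid
        while cur is not None:
            if cur in seen:
                violations.append(f"{cid}: ancestry cycle through {cur}")
                break
            seen.add(cur)
            cur = tree.cells[cur].parent_id if cur in tree.cells else None
    return violations


# ---------------------------------------------------------------------------
# GMM threshold and classification


def _equal_posterior_threshold(w, mu, sd) -> float:
    """Root of w1*N(x|mu1,sd1) = w2*N(x|mu2,sd2) strictly between the means."""

    def diff(x):
        return (
            math.log(w[0]) + norm.logpdf(x, mu[0], sd[0])
            - math.log(w[1]) - norm.logpdf(x, mu[1], sd[1])
        )

    lo, hi = mu[0], mu[1]
    eps = (hi - lo) * 1e-9
    a, b = lo + eps, hi - eps
    if diff(a) * diff(b) < 0:
        return float(brentq(diff, a, b, xtol=1e-12))
    # heavily overlapping components (near-unimodal data): no exact
    # equal-posterior crossing exists between the means, so place the
    # threshold where the posteriors are closest to equal
    grid = np.linspace(a, b, 512)
    vals = np.array([abs(diff(g)) for g in grid])
    return float(grid[int(vals.argmin())])


def fit_gmm_threshold(values, seed: int = 0, n_restarts: int = 50) -> BinaryClassification:
    """Fit a 2-component Gaussian mixture and place the high/low threshold.

    The mixture is fitted by EM (``n_restarts`` k-means-initialised restarts,
    best total log-likelihood kept; tolerance 1e-8).  The threshold is the
    equal-posterior point between the two component means — the decision
    boundary at which an ATP value is equally likely to come from either
    component.

    Parameters
    ----------
    values : array-like of float
        ATP concentrations in mM; at least 10 finite non-negative values.
    seed : int
        Seeds the restart stream deterministically.

    Returns
    -------
    BinaryClassification
        With ``threshold`` and ``gmm_params`` filled (labels empty).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite values to fit the mixture")
    if np.any(x < 0):
        raise ValueError("ATP concentrations must be non-negative")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: values have zero variance")

    # strict tolerance first; near-unimodal data can leave EM wandering on
    # the unbounded 1-D mixture likelihood ridge, so the tolerance is
    # relaxed once, and a plateaued best fit is accepted with a warning
    fits = []
    for tol in (1e-8, 1e-5):
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            tol=tol,
            n_init=n_restarts,
            init_params="kmeans",
            random_state=int(seed) % (2**31),
            max_iter=500,
        )
        gm.fit(x.reshape(-1, 1))
        fits.append(gm)
        if gm.converged_:
            if tol > 1e-8:
                warnings.warn(
                    f"EM converged only at relaxed tolerance {tol:g}", stacklevel=2
                )
            break
    gm = fits[-1]
    if not gm.converged_:
        plateau = abs(fits[1].lower_bound_ - fits[0].lower_bound_) < 1e-6 * max(
            1.0, abs(fits[0].lower_bound_)
        )
        if plateau and np.isfinite(gm.lower_bound_):
            warnings.warn(
                "EM log-likelihood plateaued without meeting tolerance; "
                "using the best fit", stacklevel=2,
            )
        else:
            raise RuntimeError("EM failed to converge across all restarts")

    order = np.argsort(gm.means_.ravel())
    w = gm.weights_.ravel()[order]
    mu = gm.means_.ravel()[order]
    sd = np.sqrt(gm.covariances_.reshape(-1)[order])
    threshold = _equal_posterior_threshold(w, mu, sd)
    params = [(float(w[i]), float(mu[i]), float(sd[i])) for i in range(2)]
    return BinaryClassification(threshold=threshold, gmm_params=params)


def classify(tree: LineageTree, threshold: float) -> BinaryClassification:
    """Label every observation and every cell HIGH/LOW against one threshold.

    Per-observation: HIGH iff that frame's ATP exceeds the threshold.
    Per-cell: HIGH iff the cell's lifetime-mean ATP (over non-placeholder
    frames) exceeds the threshold.
    """
    result = BinaryClassification(threshold=float(threshold), gmm_params=[])
    for cid in sorted(tree.cells):
        cell = tree.cells[cid]
        for o in cell.observations:
            if o.placeholder:
                continue
            if o.atp_mM is None:
                raise LineageError(
                    f"cell {cid} frame {o.frame}: missing ATP on non-placeholder observation"
                )
            result.per_observation_class[(cid, o.frame)] = (
                HIGH if o.atp_mM > threshold else LOW
            )
        mean = cell.mean_atp()
        if not math.isnan(mean):
            result.per_cell_class[cid] = HIGH if mean > threshold else LOW
    return result
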