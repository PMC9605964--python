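"""Generative microcolony simulator with one regime per heterogeneity mechanism.

The simulator emulates the observation design of the time-lapse experiments:
a binary-fission microcolony grown on a plane and imaged hourly for tens of
hours, with per-cell ATP trajectories on the 0-10 mM biosensor scale.  Each
``regime`` implants one mechanism of phenotypic heterogeneity:

* ``control`` — every cell's ATP is stationary AR(1) noise around a single
  mean; no mechanism, near-normal final-frame distribution.
* ``switching`` — a two-state telegraph process (low/high ATP mean) with
  exponential switching rates; state inherited at division.
* ``oscillation`` — sinusoidal ATP with random phase; the two generation-1
  branches carry distinct oscillator parameters (period, amplitude, level),
  linking oscillation features to the high/low classes.
* ``age_biased`` — mean ATP increases linearly with replicative pole age.
* ``transmission`` — a random subset of cells are high-ATP "producers"
  (chosen independently of lineage); non-producers relax toward a level set
  by their summed proximity-kernel exposure to producers, creating spatially
  localized high-ATP cells and a long right tail.

Geometry is point-cell: daughters are placed beside the mother along the
axis pointing away from the mother's own birth site (so the old-pole
daughter is the farther one) and pairwise overlap relaxation keeps centroid
spacing realistic.  Only centroid distances feed the analyses, so rod-shaped
mechanics are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .calibration import StandardCurve
from .lineage import CellRecord, LineageTree, Observation

__all__ = ["SimulationConfig", "simulate_colony", "emit_fluorescence"]

REGIMES = ("control", "switching", "oscillation", "age_biased", "transmission")

ATP_MIN, ATP_MAX = 0.0, 10.0  # observable biosensor range, mM


@dataclass
class SimulationConfig:
    """All knobs of the generative model, with hourly-movie defaults."""

    regime: str = "control"
    n_generations: int = 7
    n_founders: int = 3
    frame_interval: float = 1.0      # h
    tau_mean: float = 2.5            # h, mean interdivision time
    tau_cv: float = 0.15             # lognormal CV of interdivision times
    atp_low_mean: float = 1.0        # mM
    atp_high_mean: float = 4.5       # mM
    atp_noise_sd: float = 0.15       # mM
    ar_coeff: float = 0.6            # AR(1) persistence of frame-to-frame noise
    # switching regime
    switch_rate_up: float = 0.15     # per h, LOW -> HIGH
    switch_rate_down: float = 0.15   # per h, HIGH -> LOW
    # oscillation regime
    osc_period: float = 6.0          # h (fast branch)
    osc_amplitude: float = 2.0       # mM (fast branch)
    osc_period_slow: float = 12.0    # h (slow branch)
    osc_amplitude_slow: float = 0.8  # mM (slow branch)
    osc_phase_jitter: float = 0.5    # rad, per-cell phase jitter at birth
    # age regime
    age_slope: float = 0.8           # mM per pole-age division
    # transmission regime
    producer_fraction: float = 0.10
    transmission_radius: float = 1.2  # um, short-range relative to colony size
    coupling_strength: float = 4.0    # mM of exposure-driven elevation
    # geometry
    cell_spacing: float = 1.0        # um, target centroid separation
    leaf_frames: int = 3             # frames the last generation is observed
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0 <= self.producer_fraction <= 1:
            raise ValueError("producer_fraction must be in [0, 1]")
        if self.frame_interval <= 0 or self.tau_mean <= 0:
            raise ValueError("frame_interval and tau_mean must be positive")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k} = {v}\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        kwargs = {}
        fields_ = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                k, _, v = line.partition("=")
                k, v = k.strip(), v.strip()
                if k not in fields_:
                    raise ValueError(f"unknown config key {k!r}")
                if k == "regime":
                    kwargs[k] = v
                elif k in ("n_generations", "n_founders", "leaf_frames", "seed"):
                    kwargs[k] = int(v)
                else:
                    kwargs[k] = float(v)
        return cls(**kwargs)


@dataclass
class _SimCell:
    """Internal bookkeeping during simulation."""

    cell_id: str
    parent_id: str | None
    birth: float
    division: float | None     # None for leaves (movie-end cells)
    generation: int
    pole_age: int              # ground-truth replicative age
    birth_pos: np.ndarray      # position at birth (before relaxation drift)
    pos: np.ndarray = field(default=None)
    # regime state
    tele_state: int = 0
    osc_branch: int = 0
    osc_phase: float = 0.0
    producer: bool = False
    ar_value: float = 0.0


def _lognormal_tau(rng, mean, cv, size=None):
    if cv <= 0:
        return np.full(size if size else (), mean)
    s2 = np.log1p(cv**2)
    mu = np.log(mean) - s2 / 2
    return rng.lognormal(mu, np.sqrt(s2), size=size)


def _build_tree_structure(cfg: SimulationConfig, rng) -> dict[str, _SimCell]:
    """Division schedule and lineage topology (no positions/ATP yet)."""
    cells: dict[str, _SimCell] = {}
    dt = cfg.frame_interval
    queue: list[_SimCell] = []
    for f in range(cfg.n_founders):
        fid = f"c{f:02d}"
        cell = _SimCell(
            cell_id=fid, parent_id=None, birth=0.0, division=None,
            generation=0, pole_age=0,
            birth_pos=np.array([25.0 * f, 0.0]),
        )
        cells[fid] = cell
        queue.append(cell)
    while queue:
        cell = queue.pop(0)
        if cell.generation >= cfg.n_generations:
            continue
        tau = float(_lognormal_tau(rng, cfg.tau_mean, cfg.tau_cv))
        tau = max(tau, 1.01 * dt)  # every cell spans at least one frame
        cell.division = cell.birth + tau
        for d in (0, 1):
            kid = _SimCell(
                cell_id=f"{cell.cell_id}{d}",
                parent_id=cell.cell_id,
                birth=cell.division,
                division=None,
                generation=cell.generation + 1,
                # daughter 0 inherits the older pole, daughter 1 the newer
                pole_age=cell.pole_age + 1 if d == 0 else 1,
                birth_pos=np.zeros(2),
            )
            cells[kid.cell_id] = kid
            queue.append(kid)
    return cells


def _relax_positions(pos: np.ndarray, spacing: float, n_sweeps: int = 25):
    """Push overlapping centroids apart to a minimum pairwise spacing."""
    n = pos.shape[0]
    if n < 2:
        return pos
    for _ in range(n_sweeps):
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        close = dist < spacing
        if not close.any():
            break
        finite = np.where(np.isfinite(dist), dist, spacing)
        overlap = np.where(close, (spacing - finite) / np.maximum(finite, 1e-9), 0.0)
        pos = pos + 0.5 * (diff * overlap[..., None]).sum(axis=1)
    return pos


def simulate_colony(cfg: SimulationConfig) -> LineageTree:
    """Simulate one microcolony movie under the configured regime.

    Returns a fully populated :class:`LineageTree` (hourly observations with
    2D centroids and ATP in mM, clipped to the 0-10 mM biosensor range).
    Deterministic for a fixed config+seed.

    Raises
    ------
    ValueError
        If the configuration would produce more than 1e5 cells.
    """
    n_cells_expected = cfg.n_founders * (2 ** (cfg.n_generations + 1) - 1)
    if n_cells_expected > 1e5:
        raise ValueError(f"configuration would produce {n_cells_expected} cells")
    rng = np.random.default_rng(cfg.seed)
    cells = _build_tree_structure(cfg, rng)
    dt = cfg.frame_interval

    max_leaf_birth = max(c.birth for c in cells.values() if c.division is None)
    movie_end = max_leaf_birth + cfg.leaf_frames * dt
    frames = np.arange(0.0, movie_end + 1e-9, dt)

    # --- per-cell regime attributes (drawn in sorted order for determinism)
    mid = 0.5 * (cfg.atp_low_mean + cfg.atp_high_mean)
    for cid in sorted(cells):
        cell = cells[cid]
        parent = cells[cell.parent_id] if cell.parent_id else None
        if cfg.regime == "switching":
            if parent is None:
                cell.tele_state = int(rng.random() < 0.5)
            else:
                cell.tele_state = parent.tele_state  # inherited at division
        elif cfg.regime == "oscillation":
            if parent is None:
                cell.osc_branch = 0
                cell.osc_phase = rng.uniform(0, 2 * np.pi)
            elif parent.parent_id is None:
                # generation-1 split: the two branches get distinct oscillators
                cell.osc_branch = int(cell.cell_id[-1])
                cell.osc_phase = parent.osc_phase + rng.normal(0, cfg.osc_phase_jitter)
            else:
                cell.osc_branch = parent.osc_branch
                cell.osc_phase = parent.osc_phase + rng.normal(0, cfg.osc_phase_jitter)
        elif cfg.regime == "transmission":
            cell.producer = bool(rng.random() < cfg.producer_fraction)

    # --- frame loop: positions by overlap relaxation, ATP by regime
    sd_frame = cfg.atp_noise_sd * np.sqrt(max(1.0 - cfg.ar_coeff**2, 1e-12))
    obs: dict[str, list[Observation]] = {cid: [] for cid in cells}
    for fi, t in enumerate(frames):
        alive = [
            cid for cid, c in sorted(cells.items())
            if c.birth <= t and (c.division is None or t < c.division)
        ]
        if not alive:
            continue
        # place newborns beside the mother, old-pole daughter farther from
        # the mother's own birth site
        for cid in alive:
            cell = cells[cid]
            if cell.pos is None:
                if cell.parent_id is None:
                    cell.pos = cell.birth_pos.copy()
                else:
                    parent = cells[cell.parent_id]
                    axis = parent.pos - parent.birth_pos
                    norm = np.hypot(*axis)
                    if norm < 1e-9:
                        ang = rng.uniform(0, 2 * np.pi)
                        axis = np.array([np.cos(ang), np.sin(ang)])
                    else:
                        axis = axis / norm
                    sign = +1.0 if cid.endswith("0") else -1.0
                    jig = rng.normal(0, 0.05, size=2)
                    cell.pos = parent.pos + sign * 0.55 * cfg.cell_spacing * axis + jig
                cell.birth_pos = cell.pos.copy()
        pos = np.array([cells[cid].pos for cid in alive])
        pos = _relax_positions(pos, cfg.cell_spacing)
        for k, cid in enumerate(alive):
            cells[cid].pos = pos[k]

        atp = _atp_at_frame(cfg, cells, alive, t, fi, rng, mid, sd_frame, pos)
        for k, cid in enumerate(alive):
            obs[cid].append(
                Observation(
                    frame=fi, time_h=float(t),
                    x_um=float(pos[k, 0]), y_um=float(pos[k, 1]),
                    atp_mM=float(np.clip(atp[k], ATP_MIN, ATP_MAX)),
                )
            )

    tree = LineageTree()
    for cid in sorted(cells):
        if not obs[cid]:
            continue
        tree.cells[cid] = CellRecord(
            cell_id=cid, parent_id=cells[cid].parent_id, observations=obs[cid]
        )
    # drop dangling parent references for cells that never hit a frame
    for cell in tree.cells.values():
        if cell.parent_id is not None and cell.parent_id not in tree.cells:
            cell.parent_id = None
    return tree


def _atp_at_frame(cfg, cells, alive, t, fi, rng, mid, sd_frame, pos):
    """ATP value per alive cell at one frame, by regime."""
    phi = cfg.ar_coeff
    vals = np.empty(len(alive))
    if cfg.regime == "transmission":
        producers = np.array([cells[cid].producer for cid in alive])
        exposure = np.zeros(len(alive))
        if producers.any():
            d2 = ((pos[:, None, :] - pos[None, producers, :]) ** 2).sum(-1)
            # Gaussian proximity kernel summed over producers: a smooth
            # exposure field with steep hills around isolated producers
            kern = np.exp(-d2 / (2 * cfg.transmission_radius**2))
            exposure = kern.sum(axis=1)
    for k, cid in enumerate(alive):
        cell = cells[cid]
        # first frame this cell is observed at
        is_first = (fi == 0) or (cell.birth > t - cfg.frame_interval + 1e-9)
        eps = rng.normal()
        if cfg.regime == "control":
            # fresh stationary draw at birth; no inheritance across division
            if is_first:
                cell.ar_value = cfg.atp_high_mean + cfg.atp_noise_sd * rng.normal()
            else:
                cell.ar_value = (
                    cfg.atp_high_mean
                    + phi * (cell.ar_value - cfg.atp_high_mean)
                    + sd_frame * eps
                )
            vals[k] = cell.ar_value
        elif cfg.regime == "switching":
            # telegraph transition over one frame interval
            if not is_first:
                rate = cfg.switch_rate_down if cell.tele_state else cfg.switch_rate_up
                if rng.random() < 1.0 - np.exp(-rate * cfg.frame_interval):
                    cell.tele_state = 1 - cell.tele_state
            level = cfg.atp_high_mean if cell.tele_state else cfg.atp_low_mean
            vals[k] = level + cfg.atp_noise_sd * eps
        elif cfg.regime == "oscillation":
            if cell.osc_branch == 0:
                amp, period, level = cfg.osc_amplitude, cfg.osc_period, cfg.atp_high_mean
            else:
                amp, period, level = (
                    cfg.osc_amplitude_slow, cfg.osc_period_slow, cfg.atp_low_mean,
                )
            vals[k] = (
                level
                + amp * np.sin(2 * np.pi * t / period + cell.osc_phase)
                + cfg.atp_noise_sd * eps
            )
        elif cfg.regime == "age_biased":
            vals[k] = (
                cfg.atp_low_mean + cfg.age_slope * cell.pole_age
                + cfg.atp_noise_sd * eps
            )
        else:  # transmission
            if cell.producer:
                vals[k] = cfg.atp_high_mean + cfg.atp_noise_sd * eps
            else:
                target = cfg.atp_low_mean + cfg.coupling_strength * exposure[k]
                if is_first:
                    cell.ar_value = target + cfg.atp_noise_sd * rng.normal()
                else:
                    cell.ar_value = cell.ar_value + 0.5 * (target - cell.ar_value)
                vals[k] = cell.ar_value + cfg.atp_noise_sd * eps
    return vals


def emit_fluorescence(
    tree: LineageTree, curve: StandardCurve, noise_cv: float = 0.0, seed: int = 0
) -> LineageTree:
    """Fill fluor_405/fluor_488 from ATP by inverting the standard curve.

    The 488-nm channel intensity is drawn log-normally per observation; the
    405-nm channel is ratio x fluor_488 x (1 + multiplicative noise), so
    that ``fluor_405/fluor_488`` recovers the calibration ratio up to the
    noise.  ATP outside the curve range is clamped (with a warning from the
    curve).  Modifies the tree in place and returns it.
    """
    rng = np.random.default_rng(seed)
    for cid in sorted(tree.cells):
        for o in tree.cells[cid].observations:
            if o.atp_mM is None:
                raise ValueError(f"cell {cid} frame {o.frame}: no ATP to convert")
            ratio = curve.atp_to_ratio(o.atp_mM)
            f488 = float(rng.lognormal(np.log(1000.0), 0.25))
            noise = 1.0 + noise_cv * rng.normal() if noise_cv > 0 else 1.0
            o.fluor_488 = f488
            o.fluor_405 = float(ratio * f488 * noise)
    return tree
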