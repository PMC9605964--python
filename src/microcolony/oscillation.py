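"""Periodic-oscillation test.

Each lineage's ATP trajectory is smoothed by Gaussian-process regression
with a power-exponential correlation (power 1.95) whose roughness
hyperparameter is reported as ``beta = log10(theta)``.  A fit that drives
``beta`` above 4 corresponds to a correlation length far below the frame
interval — the regression has latched onto noise rather than a smooth
trend — and that lineage is excluded from the oscillation analysis.

From each converged fit, the dominant spectral component of the
mean-detrended posterior mean gives the lineage's principal frequency
(cycles/h) and amplitude (mM); the two ATP classes are then compared by
two-sided Mann-Whitney rank-sum tests on each feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import mannwhitneyu

from .lineage import HIGH, LOW, BinaryClassification, LineageTree

__all__ = [
    "GPFitOutcome",
    "OscillationFeatures",
    "gp_regress",
    "extract_principal",
    "compare_classes",
    "analyze_oscillation",
]

POWER = 1.95  # power-exponential correlation exponent
BETA_MAX_CONVERGED = 4.0
GRID_POINTS = 256


@dataclass
class GPFitOutcome:
    lineage_id: str
    beta: np.ndarray            # log10(theta) per correlation hyperparameter
    converged: bool             # all beta <= 4
    grid_times: np.ndarray      # dense grid over the observation window (h)
    posterior_mean: np.ndarray  # mM on grid_times
    iterations: int
    log_likelihood: float


@dataclass
class OscillationFeatures:
    lineage_id: str
    principal_frequency: float  # cycles per hour (NaN if no oscillation)
    principal_amplitude: float  # mM
    cell_class: str | None = None


class InsufficientDataError(ValueError):
    pass


def _neg_profile_loglik(beta, u, y, jitter):
    """Negative profile log-likelihood at beta (mean and variance profiled)."""
    theta = 10.0 ** beta[0]
    d = np.abs(u[:, None] - u[None, :]) ** POWER
    R = np.exp(-theta * d)
    n = u.size
    R[np.diag_indices(n)] += jitter
    try:
        cf = cho_factor(R, lower=True)
    except np.linalg.LinAlgError:
        return 1e300
    one = np.ones(n)
    Ri1 = cho_solve(cf, one)
    Riy = cho_solve(cf, y)
    mu = (one @ Riy) / (one @ Ri1)
    r = y - mu
    s2 = (r @ cho_solve(cf, r)) / n
    if s2 <= 0:
        return 1e300
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return 0.5 * n * math.log(s2) + 0.5 * logdet


def gp_regress(
    times,
    values,
    max_iter: int = 10_000,
    seed: int = 0,
    lineage_id: str = "",
    beta_bounds: tuple[float, float] = (-6.0, 8.0),
    jitter: float = 1e-10,
) -> GPFitOutcome:
    """Fit the profile-likelihood GP to one ATP trajectory.

    The single correlation hyperparameter is optimized by multi-start
    L-BFGS-B on ``beta`` within ``beta_bounds`` (inputs rescaled to [0, 1]);
    the fit is flagged non-converged when the optimum exceeds beta = 4, and
    such lineages must be excluded downstream.

    Raises
    ------
    InsufficientDataError
        For fewer than 4 observations.
    ValueError
        For non-increasing times.
    RuntimeError
        If the correlation matrix stays singular after jitter escalation.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise InsufficientDataError("need at least 4 observations")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    u = (t - t[0]) / (t[-1] - t[0])

    rng = np.random.default_rng(seed)
    starts = [-4.0, -2.0, 0.0, 1.5, 3.0, 5.0]
    starts += list(rng.uniform(beta_bounds[0], beta_bounds[1], size=4))
    per_start = max(10, max_iter // len(starts))

    best = None
    total_iter = 0
    jit = jitter
    for _ in range(6):  # jitter escalation
        try:
            for b0 in starts:
                res = minimize(
                    _neg_profile_loglik,
                    x0=[b0],
                    args=(u, y, jit),
                    method="L-BFGS-B",
                    bounds=[beta_bounds],
                    options={"maxiter": per_start},
                )
                total_iter += int(res.nit)
                if best is None or res.fun < best.fun:
                    best = res
            break
        except np.linalg.LinAlgError:
            jit *= 100.0
    if best is None or best.fun >= 1e299:
        raise RuntimeError("correlation matrix singular; GP fit failed")

    beta_hat = np.atleast_1d(best.x)
    theta = 10.0 ** beta_hat[0]
    d = np.abs(u[:, None] - u[None, :]) ** POWER
    R = np.exp(-theta * d)
    R[np.diag_indices(u.size)] += jit
    cf = cho_factor(R, lower=True)
    one = np.ones(u.size)
    mu = (one @ cho_solve(cf, y)) / (one @ cho_solve(cf, one))
    w = cho_solve(cf, y - mu)

    grid = np.linspace(t[0], t[-1], GRID_POINTS)
    ug = (grid - t[0]) / (t[-1] - t[0])
    rx = np.exp(-theta * np.abs(ug[:, None] - u[None, :]) ** POWER)
    post = mu + rx @ w
    return GPFitOutcome(
        lineage_id=lineage_id,
        beta=beta_hat,
        converged=bool(np.max(beta_hat) <= BETA_MAX_CONVERGED),
        grid_times=grid,
        posterior_mean=post,
        iterations=total_iter,
        log_likelihood=-float(best.fun),
    )


def extract_principal(outcome: GPFitOutcome) -> OscillationFeatures:
    """Dominant periodogram component of the detrended posterior mean.

    The posterior mean is evaluated on its uniform grid, mean-detrended, and
    Fourier-transformed; the positive frequency with the largest magnitude
    is the principal frequency and ``2|X_k|/N`` its amplitude.  A constant
    posterior mean has amplitude 0 and an undefined (NaN) frequency.
    """
    if not outcome.converged:
        raise ValueError("non-converged GP fit (beta > 4): lineage must be excluded")
    y = outcome.posterior_mean
    n = y.size
    span = outcome.grid_times[-1] - outcome.grid_times[0]
    yd = y - y.mean()
    if np.ptp(yd) == 0:
        return OscillationFeatures(outcome.lineage_id, math.nan, 0.0)
    coef = np.fft.rfft(yd)
    mags = np.abs(coef[1:])  # positive frequencies only
    k = int(np.argmax(mags)) + 1
    freq = k / span * (n - 1) / n  # grid spans [0, span] inclusive
    amplitude = 2.0 * np.abs(coef[k]) / n
    return OscillationFeatures(outcome.lineage_id, float(freq), float(amplitude))


def compare_classes(features: list[OscillationFeatures]) -> dict:
    """Two-sided Mann-Whitney comparison of frequency and amplitude by class.

    Requires at least 3 lineages per class.  When every value is tied across
    both classes the p-value is reported as 1 (no evidence of a shift).
    """
    groups = {HIGH: [], LOW: []}
    for f in features:
        if f.cell_class in groups:
            groups[f.cell_class].append(f)
    if min(len(groups[HIGH]), len(groups[LOW])) < 3:
        raise ValueError("need at least 3 lineages per class")

    report = {}
    for name, getter in (
        ("frequency", lambda f: f.principal_frequency),
        ("amplitude", lambda f: f.principal_amplitude),
    ):
        hi = np.array([getter(f) for f in groups[HIGH]], dtype=float)
        lo = np.array([getter(f) for f in groups[LOW]], dtype=float)
        hi = hi[np.isfinite(hi)]
        lo = lo[np.isfinite(lo)]
        if hi.size < 3 or lo.size < 3:
            report[name] = {"U": math.nan, "p": math.nan,
                            "median_high": math.nan, "median_low": math.nan}
            continue
        if np.ptp(np.concatenate([hi, lo])) == 0:
            u, p = hi.size * lo.size / 2.0, 1.0
        else:
            u, p = mannwhitneyu(hi, lo, alternative="two-sided")
        report[name] = {
            "U": float(u),
            "p": float(p),
            "median_high": float(np.median(hi)),
            "median_low": float(np.median(lo)),
        }
    return report


def lineage_trajectories(tree: LineageTree) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(lineage_id, times, atp) per root-to-leaf path, placeholders skipped."""
    out = []
    for path in tree.root_to_leaf_paths():
        ts, ys = [], []
        for cid in path:
            for o in tree.cells[cid].observations:
                if o.placeholder or o.atp_mM is None:
                    continue
                ts.append(o.time_h)
                ys.append(o.atp_mM)
        out.append((path[-1], np.array(ts), np.array(ys)))
    return out


def analyze_oscillation(
    tree: LineageTree,
    classification: BinaryClassification,
    max_iter: int = 10_000,
    seed: int = 0,
) -> tuple[list[OscillationFeatures], list[GPFitOutcome], list[str]]:
    """Full oscillation stage over a tree.

    Fits the GP to every root-to-leaf trajectory, applies the beta > 4
    exclusion rule, extracts principal frequency/amplitude from converged
    fits, and attaches each leaf's HIGH/LOW class.  Returns (features,
    fit outcomes, excluded lineage ids).
    """
    feats: list[OscillationFeatures] = []
    fits: list[GPFitOutcome] = []
    excluded: list[str] = []
    rng = np.random.default_rng(seed)
    for lid, ts, ys in lineage_trajectories(tree):
        if ts.size < 4:
            excluded.append(lid)
            continue
        fit = gp_regress(ts, ys, max_iter=max_iter,
                         seed=int(rng.integers(2**31)), lineage_id=lid)
        fits.append(fit)
        if not fit.converged:
            excluded.append(lid)
            continue
        f = extract_principal(fit)
        f.cell_class = classification.per_cell_class.get(lid)
        feats.append(f)
    return feats, fits, excluded
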