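"""Ratiometric biosensor calibration: 405/488 fluorescence ratio to ATP (mM).

The ratiometric ATP sensor shifts its excitation spectrum on ATP binding, so
the ratio of emission under 405-nm excitation to that under 488-nm excitation
maps monotonically to intracellular ATP concentration.  The in-vitro standard
curve is supplied as a short table of (ratio, ATP) calibration points and
interpolated with a shape-preserving monotone cubic (PCHIP), which is exact at
the calibration nodes and invertible over the calibrated range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = ["StandardCurve", "CalibrationError", "read_standard_curve"]


class CalibrationError(ValueError):
    """Non-monotone or otherwise unusable calibration table."""


@dataclass
class StandardCurve:
    """Monotone interpolation through (ratio, atp_mM) calibration points."""

    ratios: np.ndarray
    atp: np.ndarray

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.atp = np.asarray(self.atp, dtype=float)
        if self.ratios.size < 2:
            raise CalibrationError("need at least 2 calibration points")
        order = np.argsort(self.ratios)
        self.ratios = self.ratios[order]
        self.atp = self.atp[order]
        d = np.diff(self.atp)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise CalibrationError("calibration points are not strictly monotone")
        self._fwd = PchipInterpolator(self.ratios, self.atp)

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.ratios[0]), float(self.ratios[-1])

    def ratio_to_atp(self, ratio) -> np.ndarray | float:
        """Map a 405/488 intensity ratio to ATP in mM.

        Ratios outside the calibrated range are clamped to the nearest
        endpoint with a warning (the sensor saturates outside its dynamic
        range, so extrapolation is not meaningful).
        """
        r = np.asarray(ratio, dtype=float)
        lo, hi = self.valid_range
        if np.any(r < lo) or np.any(r > hi):
            warnings.warn(
                "ratio outside calibrated range; clamped to curve endpoint",
                stacklevel=2,
            )
            r = np.clip(r, lo, hi)
        out = self._fwd(r)
        return float(out) if np.isscalar(ratio) else out

    def atp_to_ratio(self, atp) -> np.ndarray | float:
        """Inverse map, ATP in mM to 405/488 ratio (clamped to curve range).

        Solved on the forward interpolant itself (unique root for a
        monotone curve), so ``ratio_to_atp(atp_to_ratio(x)) == x`` to
        numerical precision over the whole calibrated range.
        """
        a = np.asarray(atp, dtype=float)
        lo, hi = sorted((self.atp[0], self.atp[-1]))
        if np.any(a < lo) or np.any(a > hi):
            warnings.warn(
                "ATP outside calibrated range; clamped to curve endpoint",
                stacklevel=2,
            )
            a = np.clip(a, lo, hi)
        rlo, rhi = self.valid_range

        def solve_one(v):
            roots = self._fwd.solve(v, extrapolate=False)
            roots = roots[(roots >= rlo - 1e-12) & (roots <= rhi + 1e-12)]
            return float(np.clip(roots[0], rlo, rhi))

        out = np.array([solve_one(v) for v in np.atleast_1d(a)])
        return float(out[0]) if np.isscalar(atp) else out.reshape(a.shape)


def read_standard_curve(path) -> StandardCurve:
    """Read a 2-column (ratio, atp_mM) delimited text file; ``#`` comments."""
    df = pd.read_csv(path, comment="#", header=None, names=["ratio", "atp_mM"],
                     skip_blank_lines=True)
    return StandardCurve(df["ratio"].to_numpy(), df["atp_mM"].to_numpy())
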