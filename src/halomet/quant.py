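"""Calibration, recovery correction, fresh-weight conversion, LOD/LOQ.

Quantification follows internal-standard practice for pesticide residue
analysis: a linear working-standard curve (0.8–800 ng/mL), per-sample
recovery of the deuterated internal standard used as a matrix-loss
correction factor (100% / recovery%), concentrations expressed per gram
of fresh tissue, and a spiked-replicate limit of detection
LOD = t_alpha * S_s with LOQ = 3.3 * LOD, where t_alpha is the one-tailed
99th-percentile Student t at n-1 degrees of freedom (3.143 for seven
injections).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "RecoveryRecord",
    "LodResult",
    "fit_calibration",
    "correct_concentration",
    "compute_lod",
    "concentration_fw",
]


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float
    intercept: float
    r_squared: float
    levels: Tuple[Tuple[float, float], ...]
    fit_range: Tuple[float, float] = (0.8, 800.0)
    weighting: Optional[str] = None

    def predict_concentration(self, response: float) -> Tuple[float, bool]:
        """Inverse prediction; the flag marks values outside the fitted
        range."""
        conc = (response - self.intercept) / self.slope
        in_range = self.fit_range[0] <= conc <= self.fit_range[1]
        return conc, not in_range

    def response(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class RecoveryRecord:
    """Per-sample internal-standard recovery.

    Nominal spikes follow the study design: 120 ng/g fw for leaves and
    flowers, 4 ng/g fw for fruits.
    """

    sample_id: str
    is_nominal: float
    is_measured: float

    def __post_init__(self) -> None:
        if self.is_nominal <= 0 or self.is_measured <= 0:
            raise ValueError("nominal and measured spikes must be positive")

    @property
    def recovery_pct(self) -> float:
        return 100.0 * self.is_measured / self.is_nominal


@dataclass(frozen=True)
class LodResult:
    matrix: str
    n_injections: int
    t_critical: float
    s_s: float
    lod: float
    loq: float


def fit_calibration(
    levels: Sequence[Tuple[float, float]],
    fit_range: Tuple[float, float] = (0.8, 800.0),
    weighting: Optional[str] = None,
) -> CalibrationCurve:
    """Least-squares line of response vs nominal concentration.

    Requires >= 5 levels with monotone mean responses.  ``weighting`` may
    be ``"1/x"`` for inverse-concentration weights; the default is the
    unweighted ordinary fit.
    """
    if len(levels) < 5:
        raise ValueError("calibration requires at least 5 levels")
    x = np.asarray([l[0] for l in levels], dtype=float)
    y = np.asarray([l[1] for l in levels], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("calibration levels are rank deficient")
    order = np.argsort(x)
    if not np.all(np.diff(y[order]) > 0):
        raise ValueError("calibration responses must increase with concentration")
    if weighting is None:
        res = stats.linregress(x, y)
        slope, intercept, r = res.slope, res.intercept, res.rvalue
        r2 = r * r
    elif weighting == "1/x":
        w = 1.0 / x
        W = np.sum(w)
        xb = np.sum(w * x) / W
        yb = np.sum(w * y) / W
        slope = np.sum(w * (x - xb) * (y - yb)) / np.sum(w * (x - xb) ** 2)
        intercept = yb - slope * xb
        resid = y - (slope * x + intercept)
        ss_res = np.sum(w * resid**2)
        ss_tot = np.sum(w * (y - yb) ** 2)
        r2 = 1.0 - ss_res / ss_tot
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        levels=tuple((float(a), float(b)) for a, b in levels),
        fit_range=fit_range,
        weighting=weighting,
    )


def correct_concentration(measured: float, recovery_pct: float) -> float:
    """Recovery-correct a measured concentration: measured * 100 / recovery%.

    Applied per sample, so each extract is corrected by its own
    internal-standard recovery rather than a batch mean.
    """
    if recovery_pct <= 0:
        raise ValueError("recovery must be positive")
    return measured * 100.0 / recovery_pct


def compute_lod(
    spiked_results: Sequence[float],
    alpha: float = 0.01,
    matrix: str = "",
) -> LodResult:
    """Spiked-replicate LOD: t_alpha * sd(replicates); LOQ = 3.3 * LOD.

    ``t_alpha`` is the one-tailed (1 - alpha) Student t quantile at n-1
    degrees of freedom, computed (not table-looked-up); at n = 7 and
    alpha = 0.01 it equals 3.143 to three decimals.
    """
    n = len(spiked_results)
    if n < 3:
        raise ValueError("at least 3 spiked replicates required")
    t_crit = float(stats.t.ppf(1.0 - alpha, n - 1))
    s_s = float(np.std(spiked_results, ddof=1))
    if s_s == 0.0:
        warnings.warn("zero variance among spiked replicates; LOD is 0")
    lod = t_crit * s_s
    return LodResult(
        matrix=matrix, n_injections=n, t_critical=t_crit, s_s=s_s, lod=lod, loq=3.3 * lod
    )


def concentration_fw(
    extract_conc: float,
    sample_mass: float,
    extract_volume: float,
    concentration_factor: float = 1.0,
) -> float:
    """Convert an extract concentration (ng/mL) to a fresh-weight tissue
    concentration (ng/g fw).

    ``concentration_factor`` accounts for post-extraction concentration
    steps (e.g. the 5x nitrogen blow-down used for flower extracts).
    """
    if sample_mass <= 0 or extract_volume <= 0:
        raise ValueError("sample mass and extract volume must be positive")
    if concentration_factor <= 0:
        raise ValueError("concentration factor must be positive")
    return extract_conc * extract_volume / (sample_mass * concentration_factor)
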