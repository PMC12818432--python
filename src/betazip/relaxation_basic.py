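"""Basic 15N backbone relaxation: R1/R2 decays, hetNOE, R2/R1 flagging.

The R2/R1 cutoff (mean + 1 SD over the supplied residues) marks residues
with exchange broadening from microsecond-millisecond motions; it is the
screening step that precedes the CEST/CPMG analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import lmfit
import numpy as np


@dataclass
class DecaySeries:
    """Intensity-versus-delay series for one residue."""

    residue_id: str
    delays: np.ndarray
    intensities: np.ndarray
    sigma: np.ndarray | float

    def __post_init__(self):
        self.delays = np.asarray(self.delays, float)
        self.intensities = np.asarray(self.intensities, float)
        self.sigma = np.broadcast_to(
            np.asarray(self.sigma, float), self.intensities.shape).copy()
        if self.delays.size < 3:
            raise ValueError("at least 3 delay points required")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        if np.unique(self.delays).size != self.delays.size:
            raise ValueError("delays must be distinct")


@dataclass
class RateFit:
    rate: float
    rate_stderr: float | None
    i0: float
    flagged: bool = False


def fit_exponential_rate(series: DecaySeries) -> RateFit:
    """Weighted fit of I(t) = I0 exp(-R t).

    A non-decaying series yields a rate whose 1-sigma interval spans zero
    and is flagged.
    """
    if np.any(series.intensities <= 0.0):
        raise ValueError("intensities must be positive")
    t, y, s = series.delays, series.intensities, series.sigma
    # log-linear initial guess
    slope = np.polyfit(t, np.log(y), 1)[0]
    params = lmfit.Parameters()
    params.add("i0", value=float(np.max(y)), min=1e-12)
    params.add("rate", value=max(-slope, 1e-6), min=0.0)

    def residual(p):
        return (y - p["i0"].value * np.exp(-p["rate"].value * t)) / s

    res = lmfit.minimize(residual, params, method="leastsq")
    rate = float(res.params["rate"].value)
    i0 = float(res.params["i0"].value)
    stderr = res.params["rate"].stderr
    stderr = None if stderr is None else float(stderr)
    # undetectable decay: 1-sigma interval reaches zero, or the total decay
    # over the sampled delays is below the relative noise floor
    noise_rel = float(np.median(s)) / i0
    flagged = (stderr is None or rate - stderr <= 0.0
               or rate * float(np.max(t)) <= noise_rel)
    return RateFit(rate=rate, rate_stderr=stderr,
                   i0=i0, flagged=flagged)


@dataclass
class HetNoe:
    value: float
    sigma: float | None = None


def het_noe(sat_intensity: float, ref_intensity: float,
            sigma_sat: float | None = None,
            sigma_ref: float | None = None) -> HetNoe:
    """Steady-state heteronuclear NOE ratio I_sat / I_ref.

    Negative values are valid (highly flexible sites).  The uncertainty is
    first-order propagated from the two intensity errors when given.
    """
    if ref_intensity == 0.0:
        raise ValueError("reference intensity must be non-zero")
    ratio = sat_intensity / ref_intensity
    sigma = None
    if sigma_sat is not None and sigma_ref is not None:
        sigma = abs(ratio) * np.sqrt(
            (sigma_sat / sat_intensity) ** 2 + (sigma_ref / ref_intensity) ** 2
        ) if sat_intensity != 0.0 else abs(sigma_sat / ref_intensity)
    return HetNoe(value=float(ratio), sigma=sigma)


@dataclass
class R2R1Flags:
    threshold: float
    mean: float
    sd: float
    flagged: frozenset


def flag_elevated_r2_over_r1(ratios: Mapping) -> R2R1Flags:
    """Flag residues with R2/R1 above mean + 1 SD (sample SD, n - 1).

    Elevated R2/R1 indicates exchange broadening from microsecond to
    millisecond motions.  The mean and SD are computed in a single pass
    over all supplied residues (no outlier exclusion).
    """
    if len(ratios) < 5:
        raise ValueError("at least 5 residues required for the cutoff")
    vals = np.array([float(v) for v in ratios.values()])
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    threshold = mean + sd
    flagged = frozenset(
        rid for rid, v in ratios.items() if float(v) > threshold)
    return R2R1Flags(threshold=threshold, mean=mean, sd=sd, flagged=flagged)
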