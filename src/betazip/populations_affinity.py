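"""Conformational populations, binding affinities and activation curves.

Covers the quantitation steps around the exchange analysis: open/closed
populations from duplicated-peak volumes and the corresponding free-energy
difference, fast-exchange K_D fitting of chemical-shift-perturbation
titrations with explicit ligand depletion, slow/intermediate/fast exchange
classification, and hyperbolic Michaelis/activation fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import lmfit
import numpy as np

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.987e-3

#: 15N weighting in the combined 1H/15N shift perturbation
CSP_ALPHA = 0.154


# ---------------------------------------------------------------------------
# populations and free energy


@dataclass(frozen=True)
class PeakVolumePair:
    """Volumes of the duplicated (open/closed) peaks of one reporter."""

    residue_id: str
    v_open: float
    v_closed: float
    sigma_open: float = 0.0
    sigma_closed: float = 0.0

    def __post_init__(self):
        if self.v_open <= 0.0 or self.v_closed <= 0.0:
            raise ValueError("peak volumes must be positive")

    @property
    def p_open(self) -> float:
        return self.v_open / (self.v_open + self.v_closed)


@dataclass
class PopulationEstimate:
    mean_pct: float
    sd_pct: float | None
    per_residue_pct: dict
    flagged: bool = False


def open_population_from_volumes(pairs: Sequence[PeakVolumePair]
                                 ) -> PopulationEstimate:
    """Mean +/- SD open population (percent) across reporter residues.

    With a single reporter the mean is returned, the SD is undefined and
    the estimate flagged.
    """
    if len(pairs) < 1:
        raise ValueError("at least one reporter residue required")
    per = {p.residue_id: 100.0 * p.p_open for p in pairs}
    vals = np.array(list(per.values()))
    if vals.size == 1:
        return PopulationEstimate(float(vals[0]), None, per, flagged=True)
    return PopulationEstimate(float(vals.mean()),
                              float(vals.std(ddof=1)), per)


def delta_delta_g(ratio_or_populations, temperature: float = 298.0) -> float:
    """Free-energy difference -R T ln(r) in kcal/mol.

    `ratio_or_populations` is either a population ratio r > 0 or a pair
    (p1, p2), in which case r = p2/p1.  A twofold population increase at
    298 K gives -0.41 kcal/mol.
    """
    if temperature <= 0.0:
        raise ValueError("temperature must be positive")
    if np.ndim(ratio_or_populations) > 0:
        p1, p2 = (float(v) for v in ratio_or_populations)
        if p1 <= 0.0 or p2 <= 0.0:
            raise ValueError("populations must be positive")
        r = p2 / p1
    else:
        r = float(ratio_or_populations)
    if r <= 0.0:
        raise ValueError("population ratio must be positive")
    return -R_KCAL * temperature * np.log(r)


# ---------------------------------------------------------------------------
# chemical-shift perturbations and K_D


def combined_csp(delta_h_ppm, delta_n_ppm, alpha: float = CSP_ALPHA):
    """Combined 1H/15N shift perturbation sqrt(dH^2 + (alpha dN)^2) (ppm)."""
    dh = np.asarray(delta_h_ppm, float)
    dn = np.asarray(delta_n_ppm, float)
    out = np.sqrt(dh**2 + (alpha * dn) ** 2)
    return out if out.ndim else float(out)


def bound_fraction(protein_total, ligand_total, kd):
    """Fraction of protein bound under single-site binding with depletion.

    [PL]/P from the quadratic isotherm
    ((P + L + K_D) - sqrt((P + L + K_D)^2 - 4 P L)) / (2 P).
    """
    p = np.asarray(protein_total, float)
    l = np.asarray(ligand_total, float)
    s = p + l + kd
    with np.errstate(invalid="ignore", divide="ignore"):
        pl = (s - np.sqrt(np.maximum(s * s - 4.0 * p * l, 0.0))) / 2.0
        out = np.where(p > 0, pl / np.where(p > 0, p, 1.0), 0.0)
    return out if out.ndim else float(out)


@dataclass
class TitrationSeries:
    """Total-concentration series with per-residue shift changes."""

    protein_total: np.ndarray
    ligand_total: np.ndarray
    shifts: Mapping  # residue_id -> (dH array, dN array), ppm
    sigma: float = 0.01

    def __post_init__(self):
        self.protein_total = np.asarray(self.protein_total, float)
        self.ligand_total = np.asarray(self.ligand_total, float)
        if self.protein_total.size != self.ligand_total.size:
            raise ValueError("protein and ligand schedules differ in length")
        if self.protein_total.size < 5:
            raise ValueError("at least 5 titration points required")
        if np.any(self.protein_total < 0) or np.any(self.ligand_total < 0):
            raise ValueError("concentrations must be non-negative")

    def csp(self, residue_id) -> np.ndarray:
        dh, dn = self.shifts[residue_id]
        return combined_csp(dh, dn)


@dataclass
class KdFit:
    kd: float
    kd_stderr: float | None
    ddmax: dict
    flagged: bool = False
    lower_bound_only: bool = False
    chi2: float = np.nan


def fit_kd_fast_exchange(series: TitrationSeries) -> KdFit:
    """Shared-K_D fit of fast-exchange CSP titration curves.

    CSP(P, L) = ddmax * [PL]/P with the depletion isotherm; K_D is shared
    across all residues of the titration (one binding site, many probes)
    while each residue has its own ddmax.  When the data show no curvature
    (K_D far above the largest ligand concentration) the estimate is
    flagged as a lower bound only; when no residue shifts at all K_D is
    undetermined and flagged.
    """
    rids = list(series.shifts)
    max_l = float(np.max(series.ligand_total))
    csps = {rid: series.csp(rid) for rid in rids}
    if all(np.max(c) < 3.0 * series.sigma for c in csps.values()):
        return KdFit(np.nan, None, {rid: 0.0 for rid in rids}, flagged=True)

    params = lmfit.Parameters()
    params.add("kd", value=max_l / 10.0, min=1e-9, max=max(10.0, 100 * max_l))
    for i, rid in enumerate(rids):
        params.add(f"ddmax_{i}", value=float(np.max(csps[rid])), min=0.0,
                   max=5.0)

    def residual(p):
        fb = bound_fraction(series.protein_total, series.ligand_total,
                            p["kd"].value)
        out = []
        for i, rid in enumerate(rids):
            out.append((csps[rid] - p[f"ddmax_{i}"].value * fb) / series.sigma)
        return np.concatenate(out)

    best = None
    for kd0 in np.geomspace(max(max_l * 1e-3, 1e-8), max_l * 10.0, 6):
        trial = params.copy()
        trial["kd"].set(value=kd0)
        res = lmfit.minimize(residual, trial, method="leastsq")
        if best is None or res.chisqr < best.chisqr:
            best = res
    kd = float(best.params["kd"].value)
    stderr = best.params["kd"].stderr
    stderr = None if stderr is None else float(stderr)
    lower_only = kd > max_l and (stderr is None or stderr > 0.5 * kd)
    return KdFit(
        kd=kd, kd_stderr=stderr,
        ddmax={rid: float(best.params[f"ddmax_{i}"].value)
               for i, rid in enumerate(rids)},
        flagged=lower_only or stderr is None,
        lower_bound_only=lower_only,
        chi2=float(best.chisqr),
    )


def classify_exchange_regime(kex: float, delta_omega_rads: float) -> str:
    """Slow/intermediate/fast exchange relative to the shift difference.

    Slow exchange (kex << |dw|) duplicates peaks; fast exchange
    (kex >> |dw|) moves a single population-averaged peak.  Factor-5
    separations delimit the intermediate regime.
    """
    if kex < 0.0:
        raise ValueError("kex must be non-negative")
    dw = abs(delta_omega_rads)
    if kex < dw / 5.0:
        return "slow"
    if kex > 5.0 * dw:
        return "fast"
    return "intermediate"


# ---------------------------------------------------------------------------
# hyperbolic saturation fits


@dataclass
class SaturationCurve:
    """Rate versus substrate/activator concentration."""

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray | float = 1.0

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.sigma = np.broadcast_to(
            np.asarray(self.sigma, float), self.y.shape).copy()
        if self.x.size < 5:
            raise ValueError("at least 5 points required")
        if np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")
        if np.min(self.x) > 0.05 * np.max(self.x):
            raise ValueError("curve must include an x = 0 or near-zero point")


@dataclass
class HyperbolicFit:
    ymax: float
    k_half: float
    ymax_stderr: float | None
    k_stderr: float | None
    flagged_k: bool = False
    chi2: float = np.nan


def fit_hyperbolic_saturation(curve: SaturationCurve) -> HyperbolicFit:
    """Weighted fit of y = Ymax x / (K + x).

    K is flagged when the data do not constrain it: non-saturating curves
    leave K lower-bounded only, constant curves drive K to zero.
    """
    xmax = float(np.max(curve.x))
    params = lmfit.Parameters()
    params.add("ymax", value=float(np.max(curve.y)), min=0.0)
    params.add("k", value=xmax / 5.0, min=1e-12, max=1e3 * xmax)

    def residual(p):
        model = p["ymax"].value * curve.x / (p["k"].value + curve.x)
        return (curve.y - model) / curve.sigma

    best = None
    for k0 in np.geomspace(xmax / 100.0, xmax * 10.0, 5):
        trial = params.copy()
        trial["k"].set(value=k0)
        res = lmfit.minimize(residual, trial, method="leastsq")
        if best is None or res.chisqr < best.chisqr:
            best = res
    k = float(best.params["k"].value)
    k_stderr = best.params["k"].stderr
    k_stderr = None if k_stderr is None else float(k_stderr)
    flagged = (
        k_stderr is None
        or k < 1e-6 * xmax                        # constant data, K -> 0
        or (k > xmax and k_stderr > 0.5 * k)      # non-saturating
    )
    ymax_stderr = best.params["ymax"].stderr
    return HyperbolicFit(
        ymax=float(best.params["ymax"].value), k_half=k,
        ymax_stderr=None if ymax_stderr is None else float(ymax_stderr),
        k_stderr=k_stderr, flagged_k=flagged, chi2=float(best.chisqr),
    )


def k_ratio(fit_a: HyperbolicFit, fit_b: HyperbolicFit) -> float:
    """Fold change between two saturation fits as the ratio of K values."""
    return fit_a.k_half / fit_b.k_half
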