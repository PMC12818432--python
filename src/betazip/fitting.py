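"""Global least-squares fitting of CEST and CPMG exchange data.

Per-residue and grouped fits share the exchange rate and minor-state
population across residues while each residue keeps its own shift
difference(s) and relaxation baseline.  Three-state CPMG fits constrain the
slow A<->B process to CEST-derived values and extract the fast A<->C rate.
Model selection uses AIC plus the low-frequency residual pattern; residues
are partitioned into rate groups by 1-D clustering of log10(kex).

Multimodality of the objectives in kex is handled with multi-start: a
log-spaced kex grid crossed with a few minor-population starts is screened
by chi-square and the best candidates are polished with Levenberg-Marquardt.
Parameter uncertainties are 1-sigma values from the fit covariance; a
parameter is flagged underdetermined when its covariance-based 1-sigma
interval spans more than half of its allowed range, when it sits at a
bound, or when no covariance is available.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np

from .exchange_core import (
    CestExperiment,
    CpmgExperiment,
    ExchangeModel,
    ppm_to_rads,
    r2eff_from_intensities,
    simulate_cest_profile,
    simulate_cpmg_numeric,
)

#: 15N chemical shifts (ppm) for the four beta-sheet zipper probe residues
#: of the SHP2 N-SH2 domain bound to its activating phosphopeptide:
#: CEST-derived minor-state shift in the wild type versus the directly
#: observed shift in the fully zipped T42A mutant.
ZIP_PROBE_SHIFTS_15N = {
    "F41": (116.5, 116.4),
    "I56": (122.1, 122.4),
    "D40": (119.0, 118.8),
    "Q57": (128.8, 128.7),
}


# ---------------------------------------------------------------------------
# data containers


@dataclass
class CestProfile:
    """Measured or simulated CEST intensities for one residue."""

    offsets_hz: np.ndarray
    intensity: np.ndarray
    intensity_ref: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.offsets_hz = np.asarray(self.offsets_hz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.intensity_ref = np.broadcast_to(
            np.asarray(self.intensity_ref, dtype=float), self.intensity.shape
        ).copy()
        self.sigma = np.broadcast_to(
            np.asarray(self.sigma, dtype=float), self.intensity.shape
        ).copy()
        if np.any(self.sigma <= 0.0):
            raise ValueError("sigma must be positive everywhere")

    @property
    def ratio(self) -> np.ndarray:
        return self.intensity / self.intensity_ref

    @property
    def sigma_ratio(self) -> np.ndarray:
        return self.sigma / self.intensity_ref


@dataclass
class CpmgDispersion:
    """CPMG intensities for one residue; the n_cyc = 0 row is the reference."""

    ncyc: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.ncyc = np.asarray(self.ncyc, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.broadcast_to(
            np.asarray(self.sigma, dtype=float), self.intensity.shape
        ).copy()
        if np.any(self.sigma <= 0.0):
            raise ValueError("sigma must be positive everywhere")
        if not np.any(self.ncyc == 0):
            raise ValueError("a reference row with n_cyc = 0 is required")

    @property
    def reference_intensity(self) -> float:
        return float(np.mean(self.intensity[self.ncyc == 0]))

    @property
    def ncyc_nonzero(self) -> np.ndarray:
        return self.ncyc[self.ncyc > 0]

    def nu_cpmg(self, t_cpmg_s: float) -> np.ndarray:
        return self.ncyc_nonzero / t_cpmg_s

    def r2eff(self, t_cpmg_s: float) -> np.ndarray:
        mask = self.ncyc > 0
        return r2eff_from_intensities(
            self.intensity[mask], self.reference_intensity, t_cpmg_s
        )

    def sigma_r2eff(self, t_cpmg_s: float) -> np.ndarray:
        mask = self.ncyc > 0
        return self.sigma[mask] / (self.intensity[mask] * t_cpmg_s)


@dataclass
class ResidueDataset:
    """Per-residue observables entering a (group) fit."""

    residue_id: str
    cest: CestProfile | None = None
    cpmg: CpmgDispersion | None = None

    def __post_init__(self):
        if self.cest is None and self.cpmg is None:
            raise ValueError(
                f"residue {self.residue_id}: at least one observable required"
            )


@dataclass
class FitParameter:
    value: float
    stderr: float | None = None
    flagged: bool = False


@dataclass
class GroupFitResult:
    """Outcome of a grouped exchange fit.

    ``shared`` holds parameters common to the group (kex, pB, ...);
    ``per_residue`` maps residue id -> parameter dict.  ``residuals`` are
    weighted (data - model)/sigma arrays aligned with ``x_values`` (carrier
    offsets in Hz for CEST, nu_CPMG in Hz for CPMG, both ascending).
    """

    kind: str
    shared: dict = field(default_factory=dict)
    per_residue: dict = field(default_factory=dict)
    chi2: float = np.nan
    ndata: int = 0
    nvarys: int = 0
    aic: float = np.nan
    exchange_detected: bool = True
    message: str = ""
    residuals: dict = field(default_factory=dict)
    x_values: dict = field(default_factory=dict)

    @property
    def residue_ids(self):
        return tuple(self.per_residue)

    def parameter_table(self):
        """Long-format table of all parameters (name, value, sigma, flag)."""
        import pandas as pd

        rows = []
        for name, p in self.shared.items():
            rows.append(("shared", name, p.value, p.stderr, p.flagged))
        for rid, pars in self.per_residue.items():
            for name, p in pars.items():
                rows.append((rid, name, p.value, p.stderr, p.flagged))
        return pd.DataFrame(
            rows, columns=["residue_id", "name", "value", "sigma", "flag"]
        )

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "shared": {
                k: {"value": p.value, "stderr": p.stderr, "flagged": p.flagged}
                for k, p in self.shared.items()
            },
            "chi2": self.chi2,
            "ndata": self.ndata,
            "nvarys": self.nvarys,
            "aic": self.aic,
            "exchange_detected": self.exchange_detected,
            "message": self.message,
        }


# ---------------------------------------------------------------------------
# helpers


def aic_score(chi2: float, ndata: int, nvarys: int) -> float:
    """AIC surrogate N ln(chi2/N) + 2k used for exchange-model selection."""
    return ndata * np.log(max(chi2, 1e-300) / ndata) + 2 * nvarys


def _flagged(par: lmfit.Parameter, frac: float = 0.5) -> bool:
    lo, hi = par.min, par.max
    span = hi - lo
    if not np.isfinite(span) or span <= 0:
        span = max(abs(par.value), 1.0)
        lo, hi = par.value - span, par.value + span
    if par.stderr is None or not np.isfinite(par.stderr):
        return True
    if 2.0 * par.stderr > frac * span:
        return True
    # pinned at a bound by the optimizer (within numerical tolerance)
    if min(par.value - lo, hi - par.value) < 1e-8 * span + 1e-12:
        return True
    return False


def _fit_parameter(par: lmfit.Parameter, force_flag: bool = False) -> FitParameter:
    return FitParameter(
        value=float(par.value),
        stderr=None if par.stderr is None else float(par.stderr),
        flagged=force_flag or _flagged(par),
    )


def detect_minor_dip(offsets_hz, ratio, freq_15n_mhz: float,
                     exclude_hz: float = 45.0, sigma=None,
                     min_depth_sigma: float = 4.0):
    """Locate a secondary CEST dip away from the major-state resonance.

    On a symmetric offset grid the dip is found from the mirror asymmetry
    ratio(-offset) - ratio(+offset): direct saturation of the major state
    is symmetric about the carrier, so any asymmetry above the noise floor
    marks the minor resonance even when it sits on the main-dip shoulder.
    On an asymmetric grid a fallback searches for the deepest point outside
    an exclusion window around state A.  Returns the signed shift
    difference in ppm, or None when nothing rises above the noise.
    """
    offsets_hz = np.asarray(offsets_hz, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    noise = float(np.median(np.asarray(sigma))) if sigma is not None else 0.0
    symmetric = np.allclose(offsets_hz, -offsets_hz[::-1], atol=1e-6)
    if symmetric:
        asym = ratio[::-1] - ratio  # > 0 where the dip sits at +offset
        mask = np.abs(offsets_hz) > exclude_hz
        if not np.any(mask):
            return None
        cand = np.where(mask, np.abs(asym), -np.inf)
        i = int(np.argmax(cand))
        # mirror-difference noise is sqrt(2) sigma
        if np.abs(asym[i]) < max(min_depth_sigma * np.sqrt(2.0) * noise,
                                 1e-6):
            return None
        off = offsets_hz[i] if asym[i] > 0 else -offsets_hz[i]
        return float(off / freq_15n_mhz)
    mask = np.abs(offsets_hz) > exclude_hz
    if not np.any(mask):
        return None
    sub_off = offsets_hz[mask]
    sub = ratio[mask]
    i = int(np.argmin(sub))
    baseline = float(np.median(sub))
    depth = baseline - sub[i]
    if depth < max(min_depth_sigma * noise, 1e-6):
        return None
    return float(sub_off[i] / freq_15n_mhz)


def _multistart(params: lmfit.Parameters, residual, starts,
                n_full: int = 2) -> lmfit.minimizer.MinimizerResult:
    """Screen starts by chi-square, polish the best few with leastsq."""
    scored = []
    for start in starts:
        trial = params.copy()
        for name, value in start.items():
            trial[name].set(value=value)
        chi2 = float(np.sum(residual(trial) ** 2))
        scored.append((chi2, start))
    scored.sort(key=lambda t: t[0])
    best = None
    for _, start in scored[:n_full]:
        trial = params.copy()
        for name, value in start.items():
            trial[name].set(value=value)
        try:
            res = lmfit.minimize(residual, trial, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("optimizer failed to converge from every start")
    return best


# ---------------------------------------------------------------------------
# CEST fits


def fit_cest_two_state(group: Sequence[ResidueDataset],
                       experiment: CestExperiment,
                       kex_starts=None,
                       pb_starts=(0.05, 0.15, 0.3),
                       n_full_starts: int = 2) -> GroupFitResult:
    """Global two-state fit of CEST profiles with shared kex and pB.

    Each residue keeps its own signed dw (initialized from the position of
    its secondary dip), R1 and R2.  Residues without a CEST profile are
    ignored; if no residue shows a detectable minor dip the fit proceeds but
    pB is flagged underdetermined.
    """
    group = [g for g in group if g.cest is not None]
    if not group:
        raise ValueError("no CEST profiles in group")
    if kex_starts is None:
        kex_starts = np.geomspace(10.0, 1e4, 7)

    params = lmfit.Parameters()
    params.add("kex", value=100.0, min=1.0, max=1e5)
    params.add("pb", value=0.1, min=1e-4, max=0.5)
    experiments = []
    any_dip = False
    for i, g in enumerate(group):
        dw0 = detect_minor_dip(
            g.cest.offsets_hz, g.cest.ratio, experiment.freq_15n_mhz,
            sigma=g.cest.sigma_ratio,
        )
        if dw0 is not None:
            any_dip = True
        params.add(f"dw_{i}", value=dw0 if dw0 is not None else 2.0,
                   min=-12.0, max=12.0)
        params.add(f"r1_{i}", value=1.5, min=0.02, max=10.0)
        params.add(f"r2_{i}", value=10.0, min=0.5, max=200.0)
        experiments.append(dataclasses.replace(
            experiment, offsets_hz=tuple(g.cest.offsets_hz)))

    def residual(p):
        out = []
        for i, g in enumerate(group):
            model = ExchangeModel(
                (1.0 - p["pb"].value, p["pb"].value),
                kex_ab=p["kex"].value, dw_ab_ppm=p[f"dw_{i}"].value,
                r1=p[f"r1_{i}"].value, r2=p[f"r2_{i}"].value,
            )
            sim = simulate_cest_profile(model, experiments[i])
            out.append((g.cest.ratio - sim) / g.cest.sigma_ratio)
        return np.concatenate(out)

    starts = [{"kex": k, "pb": b} for k in kex_starts for b in pb_starts]
    res = _multistart(params, residual, starts, n_full=n_full_starts)

    result = GroupFitResult(
        kind="cest-2state",
        chi2=float(res.chisqr), ndata=int(res.ndata),
        nvarys=int(res.nvarys),
        aic=aic_score(res.chisqr, res.ndata, res.nvarys),
        message="" if any_dip else "no minor dip detected; pB underdetermined",
    )
    result.shared = {
        "kex": _fit_parameter(res.params["kex"]),
        "pb": _fit_parameter(res.params["pb"], force_flag=not any_dip),
    }
    for i, g in enumerate(group):
        result.per_residue[g.residue_id] = {
            "dw": _fit_parameter(res.params[f"dw_{i}"]),
            "r1": _fit_parameter(res.params[f"r1_{i}"]),
            "r2": _fit_parameter(res.params[f"r2_{i}"]),
        }
        model = ExchangeModel(
            (1.0 - res.params["pb"].value, res.params["pb"].value),
            kex_ab=res.params["kex"].value,
            dw_ab_ppm=res.params[f"dw_{i}"].value,
            r1=res.params[f"r1_{i}"].value, r2=res.params[f"r2_{i}"].value,
        )
        sim = simulate_cest_profile(model, experiments[i])
        result.residuals[g.residue_id] = (g.cest.ratio - sim) / g.cest.sigma_ratio
        result.x_values[g.residue_id] = np.asarray(g.cest.offsets_hz, float)
    return result


# ---------------------------------------------------------------------------
# CPMG fits


def _cpmg_data(group, experiment):
    data = []
    for g in group:
        if g.cpmg is None:
            continue
        r2eff = g.cpmg.r2eff(experiment.t_cpmg_s)
        sig = g.cpmg.sigma_r2eff(experiment.t_cpmg_s)
        nu = g.cpmg.nu_cpmg(experiment.t_cpmg_s)
        order = np.argsort(nu)
        data.append((g.residue_id, nu[order], r2eff[order], sig[order],
                     g.cpmg.ncyc_nonzero[order]))
    return data


def _rex_amplitude(nu, r2eff):
    lo = np.mean(r2eff[:2]) if r2eff.size > 3 else r2eff[0]
    hi = np.mean(r2eff[-2:]) if r2eff.size > 3 else r2eff[-1]
    return lo - hi


def fit_cpmg_two_state(group: Sequence[ResidueDataset],
                       experiment: CpmgExperiment,
                       kex_starts=None,
                       pb_starts=(0.02, 0.1, 0.3),
                       rex_threshold: float = 1.0,
                       n_full_starts: int = 2) -> GroupFitResult:
    """Global two-state fit of CPMG dispersions with shared kex.

    Residues whose dispersion amplitude Rex is below `rex_threshold`
    (default 1 s^-1) are excluded; when every residue is flat the function
    returns a "no exchange detected" result rather than raising.  In the
    fast-exchange regime pB and dw are individually undetermined and are
    reported flagged; their product phi = pA pB dw^2 (rad^2 s^-2) is
    attached per residue.
    """
    data = _cpmg_data(group, experiment)
    if not data:
        raise ValueError("no CPMG dispersions in group")
    keep = [d for d in data if _rex_amplitude(d[1], d[2]) > rex_threshold]
    if not keep:
        result = GroupFitResult(
            kind="cpmg-2state", exchange_detected=False,
            message="no exchange detected (all dispersions flat)",
        )
        chi2 = 0.0
        n = 0
        for rid, nu, r2eff, sig, _ in data:
            base = np.average(r2eff, weights=1.0 / sig**2)
            result.per_residue[rid] = {
                "r20": FitParameter(float(base)),
                "dw": FitParameter(0.0, flagged=True),
            }
            result.residuals[rid] = (r2eff - base) / sig
            result.x_values[rid] = nu
            chi2 += float(np.sum(((r2eff - base) / sig) ** 2))
            n += nu.size
        result.chi2 = chi2
        result.ndata = n
        result.nvarys = len(data)
        result.aic = aic_score(chi2, n, len(data))
        result.shared = {
            "kex": FitParameter(np.nan, flagged=True),
            "pb": FitParameter(np.nan, flagged=True),
        }
        return result

    if kex_starts is None:
        kex_starts = np.geomspace(100.0, 2e4, 6)
    params = lmfit.Parameters()
    params.add("kex", value=1000.0, min=10.0, max=1e5)
    params.add("pb", value=0.05, min=1e-4, max=0.5)
    for i, (rid, nu, r2eff, sig, ncyc) in enumerate(keep):
        params.add(f"dw_{i}", value=1.5, min=0.02, max=12.0)
        params.add(f"r20_{i}", value=float(np.min(r2eff)), min=0.1, max=200.0)

    exps = [dataclasses.replace(experiment, ncyc_values=tuple(d[4]))
            for d in keep]

    def residual(p):
        out = []
        for i, (rid, nu, r2eff, sig, ncyc) in enumerate(keep):
            model = ExchangeModel(
                (1.0 - p["pb"].value, p["pb"].value),
                kex_ab=p["kex"].value, dw_ab_ppm=p[f"dw_{i}"].value,
                r1=1.0, r2=p[f"r20_{i}"].value,
            )
            sim = simulate_cpmg_numeric(model, exps[i])
            out.append((r2eff - sim) / sig)
        return np.concatenate(out)

    starts = [{"kex": k, "pb": b} for k in kex_starts for b in pb_starts]
    res = _multistart(params, residual, starts, n_full=n_full_starts)

    result = GroupFitResult(
        kind="cpmg-2state",
        chi2=float(res.chisqr), ndata=int(res.ndata), nvarys=int(res.nvarys),
        aic=aic_score(res.chisqr, res.ndata, res.nvarys),
    )
    result.shared = {
        "kex": _fit_parameter(res.params["kex"]),
        "pb": _fit_parameter(res.params["pb"]),
    }
    pb = res.params["pb"].value
    for i, (rid, nu, r2eff, sig, ncyc) in enumerate(keep):
        dw = res.params[f"dw_{i}"].value
        dw_rad = float(ppm_to_rads(dw, experiment.freq_15n_mhz))
        result.per_residue[rid] = {
            "dw": _fit_parameter(res.params[f"dw_{i}"]),
            "r20": _fit_parameter(res.params[f"r20_{i}"]),
            "phi": FitParameter((1.0 - pb) * pb * dw_rad**2),
        }
        model = ExchangeModel(
            (1.0 - pb, pb), kex_ab=res.params["kex"].value, dw_ab_ppm=dw,
            r1=1.0, r2=res.params[f"r20_{i}"].value,
        )
        sim = simulate_cpmg_numeric(model, exps[i])
        result.residuals[rid] = (r2eff - sim) / sig
        result.x_values[rid] = nu
    return result


@dataclass(frozen=True)
class FixedSlowProcess:
    """A<->B parameters carried over from a CEST fit into a 3-state CPMG fit."""

    kex_ab: float
    dw_ab_ppm: Mapping
    p_b: float | None = None

    def __post_init__(self):
        if self.kex_ab <= 0.0:
            raise ValueError("fixed kex_ab must be positive")
        if self.p_b is not None and not (0.0 < self.p_b <= 0.5):
            raise ValueError("fixed pB must lie in (0, 0.5]")


def fit_cpmg_three_state_constrained(group: Sequence[ResidueDataset],
                                     fixed_ab: FixedSlowProcess,
                                     experiment: CpmgExperiment,
                                     kex_ac_starts=None,
                                     n_full_starts: int = 2) -> GroupFitResult:
    """Linear three-state (B <-> A <-> C) CPMG fit with A<->B fixed.

    The slow-process parameters come from a prior CEST fit and are held
    constant; the free parameters are the shared fast rate kex_AC, the
    per-residue |dw_AC| and R2 baseline, and the (shared, underdetermined)
    populations pB/pC.  pB is fixed when `fixed_ab.p_b` is given.
    """
    if fixed_ab is None:
        raise ValueError("fixed_ab (CEST-derived A<->B parameters) is required")
    group = [g for g in group if g.cpmg is not None]
    data = _cpmg_data(group, experiment)
    if not data:
        raise ValueError("no CPMG dispersions in group")
    for rid, *_ in data:
        if rid not in fixed_ab.dw_ab_ppm:
            raise ValueError(f"fixed_ab.dw_ab_ppm missing residue {rid!r}")
    if kex_ac_starts is None:
        kex_ac_starts = np.geomspace(300.0, 2e4, 5)

    params = lmfit.Parameters()
    params.add("kex_ac", value=2000.0, min=100.0, max=5e4)
    pb_fixed = fixed_ab.p_b is not None
    params.add("pb", value=fixed_ab.p_b if pb_fixed else 0.1,
               min=1e-3, max=0.45, vary=not pb_fixed)
    params.add("pc", value=0.05, min=1e-3, max=0.3)
    for i, (rid, nu, r2eff, sig, ncyc) in enumerate(data):
        params.add(f"dw_{i}", value=2.0, min=0.02, max=12.0)
        params.add(f"r20_{i}", value=float(np.min(r2eff)), min=0.1, max=200.0)
    exps = [dataclasses.replace(experiment, ncyc_values=tuple(d[4]))
            for d in data]

    def residual(p):
        out = []
        pb, pc = p["pb"].value, p["pc"].value
        for i, (rid, nu, r2eff, sig, ncyc) in enumerate(data):
            model = ExchangeModel(
                (1.0 - pb - pc, pb, pc),
                kex_ab=fixed_ab.kex_ab,
                dw_ab_ppm=float(fixed_ab.dw_ab_ppm[rid]),
                kex_ac=p["kex_ac"].value, dw_ac_ppm=p[f"dw_{i}"].value,
                r1=1.0, r2=p[f"r20_{i}"].value,
            )
            sim = simulate_cpmg_numeric(model, exps[i])
            out.append((r2eff - sim) / sig)
        return np.concatenate(out)

    starts = [{"kex_ac": k} for k in kex_ac_starts]
    res = _multistart(params, residual, starts, n_full=n_full_starts)

    result = GroupFitResult(
        kind="cpmg-3state",
        chi2=float(res.chisqr), ndata=int(res.ndata), nvarys=int(res.nvarys),
        aic=aic_score(res.chisqr, res.ndata, res.nvarys),
        message="A<->B fixed from CEST; populations underdetermined",
    )
    result.shared = {
        "kex_ac": _fit_parameter(res.params["kex_ac"]),
        "pb": FitParameter(float(res.params["pb"].value), flagged=True)
        if pb_fixed else _fit_parameter(res.params["pb"], force_flag=True),
        "pc": _fit_parameter(res.params["pc"], force_flag=True),
        "kex_ab": FitParameter(fixed_ab.kex_ab, flagged=False),
    }
    pb, pc = res.params["pb"].value, res.params["pc"].value
    for i, (rid, nu, r2eff, sig, ncyc) in enumerate(data):
        result.per_residue[rid] = {
            "dw_ac": _fit_parameter(res.params[f"dw_{i}"]),
            "r20": _fit_parameter(res.params[f"r20_{i}"]),
            "dw_ab": FitParameter(float(fixed_ab.dw_ab_ppm[rid])),
        }
        model = ExchangeModel(
            (1.0 - pb - pc, pb, pc), kex_ab=fixed_ab.kex_ab,
            dw_ab_ppm=float(fixed_ab.dw_ab_ppm[rid]),
            kex_ac=res.params["kex_ac"].value,
            dw_ac_ppm=res.params[f"dw_{i}"].value,
            r1=1.0, r2=res.params[f"r20_{i}"].value,
        )
        sim = simulate_cpmg_numeric(model, exps[i])
        result.residuals[rid] = (r2eff - sim) / sig
        result.x_values[rid] = nu
    return result


# ---------------------------------------------------------------------------
# model selection, grouping, minor shifts


@dataclass
class ModelSelection:
    chosen: str
    delta_aic: float
    low_freq_bias: dict


def _low_freq_bias(result: GroupFitResult, n_low: int = 3) -> float:
    """Mean signed weighted residual over the n_low lowest frequencies."""
    vals = []
    for rid, resid in result.residuals.items():
        x = result.x_values[rid]
        order = np.argsort(x)
        vals.extend(resid[order][:n_low])
    return float(np.mean(vals)) if vals else np.nan


def select_exchange_model(two_state: GroupFitResult,
                          three_state: GroupFitResult,
                          n_low: int = 3) -> ModelSelection:
    """Pick between two- and three-state fits of the same data by AIC.

    Also reports the mean signed residual over the lowest `n_low` CPMG
    frequencies for each model: a systematic sign there is the qualitative
    signature of an unmodeled slow process.
    """
    if two_state.ndata != three_state.ndata or \
            set(two_state.residue_ids) != set(three_state.residue_ids):
        raise ValueError("model selection requires fits of identical data")
    bias = {
        "two_state": _low_freq_bias(two_state, n_low),
        "three_state": _low_freq_bias(three_state, n_low),
    }
    delta = two_state.aic - three_state.aic
    if abs(delta) < 1e-9:
        chosen = "tie"
    else:
        chosen = "three_state" if delta > 0 else "two_state"
    return ModelSelection(chosen=chosen, delta_aic=float(delta),
                          low_freq_bias=bias)


@dataclass
class RateGroup:
    members: tuple
    kex_center: float

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def group_residues_by_rate(per_residue_fits,
                           threshold_log10: float = 0.3):
    """Partition residues into exchange-rate groups.

    Accepts a mapping residue_id -> kex or a list of single-residue
    GroupFitResults.  Residues are sorted by kex and merged greedily into a
    group while within `threshold_log10` of the running group center (mean
    log10 kex); the groups are intended to be refitted globally afterwards.
    Singleton groups mark residues that do not fit any group.
    """
    if isinstance(per_residue_fits, Mapping):
        items = [(rid, float(k)) for rid, k in per_residue_fits.items()]
    else:
        items = []
        for fit in per_residue_fits:
            rids = fit.residue_ids
            if len(rids) != 1:
                raise ValueError("per-residue fits must each hold one residue")
            items.append((rids[0], float(fit.shared["kex"].value)))
    items = [(rid, k) for rid, k in items if np.isfinite(k) and k > 0]
    items.sort(key=lambda t: t[1])
    groups = []
    for rid, k in items:
        logk = np.log10(k)
        if groups:
            logs, members = groups[-1]
            if logk - np.mean(logs) <= threshold_log10:
                logs.append(logk)
                members.append(rid)
                continue
        groups.append(([logk], [rid]))
    return [RateGroup(members=tuple(m), kex_center=float(10 ** np.mean(l)))
            for l, m in groups]


def reconstruct_minor_shifts(major_shift_ppm, delta_omega_ppm):
    """Minor-state shift = major-state shift + signed dw (ppm)."""
    out = np.asarray(major_shift_ppm, float) + np.asarray(delta_omega_ppm, float)
    return out if out.ndim else float(out)


def compare_minor_shifts(pairs):
    """Absolute differences |reconstructed - reference| per probe.

    `pairs` may be a mapping residue -> (reconstructed, reference) ppm, in
    which case a mapping of absolute differences is returned, or a sequence
    of pairs, returning an array.
    """
    if isinstance(pairs, Mapping):
        return {rid: abs(float(a) - float(b)) for rid, (a, b) in pairs.items()}
    arr = np.asarray(list(pairs), dtype=float)
    return np.abs(arr[:, 0] - arr[:, 1])
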