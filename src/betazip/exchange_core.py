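"""Bloch-McConnell forward models for slow-to-fast chemical exchange.

Simulates ``15N`` CEST profiles and CPMG relaxation-dispersion curves for
two-state (A <-> B) and strictly linear three-state (B <-> A <-> C) exchange
between protein conformations, in the ideal-pulse, in-phase single-spin
approximation.  The Carver-Richards closed form is provided as an independent
cross-check of the numerical propagator.

Conventions
-----------
* State A is the major state and defines the zero of the offset axis; minor
  states resonate at the signed chemical-shift differences ``dw`` (ppm,
  positive = downfield of A).
* ppm -> Hz uses the 15N spectrometer frequency in MHz (60.83 MHz at a
  600 MHz 1H field); ppm -> rad/s carries an extra factor of 2*pi.
* nu_CPMG = n_cyc / T_CPMG with 2*n_cyc ideal 180-degree pulses and echo
  delays tau = T_CPMG / (4 * n_cyc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

TWO_PI = 2.0 * np.pi

#: default 15N Larmor frequency (MHz) at a 600 MHz 1H spectrometer
DEFAULT_FREQ_15N_MHZ = 60.83

#: the 14 CPMG cycle counts used with a 40 ms constant-time relaxation period
DEFAULT_NCYC = (1, 2, 3, 4, 6, 8, 10, 14, 18, 24, 30, 40, 50, 60)


def ppm_to_hz(ppm, freq_mhz: float):
    """Chemical-shift difference in ppm -> Hz at the given Larmor frequency."""
    return np.asarray(ppm, dtype=float) * freq_mhz


def ppm_to_rads(ppm, freq_mhz: float):
    """Chemical-shift difference in ppm -> angular frequency (rad/s)."""
    return np.asarray(ppm, dtype=float) * freq_mhz * TWO_PI


def _per_state(value, n: int) -> tuple[float, ...]:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return tuple(float(arr[0]) for _ in range(n))
    if arr.size != n:
        raise ValueError(
            f"expected a scalar or {n} per-state values, got {arr.size}"
        )
    return tuple(float(v) for v in arr)


@dataclass(frozen=True)
class ExchangeModel:
    """Populations, rates and offsets for 2- or 3-state chemical exchange.

    The exchange topology for three states is strictly linear, B <-> A <-> C
    (no direct B <-> C flux).  Microscopic rate constants are derived from
    the total exchange rates and populations under detailed balance:
    ``k_AB = kex_ab * pB / (pA + pB)`` and ``pA * k_AB = pB * k_BA``.

    Parameters
    ----------
    populations : tuple
        ``(pA, pB)`` or ``(pA, pB, pC)``; must sum to 1 within 1e-12.
    kex_ab : float
        Total A<->B exchange rate ``k_AB + k_BA`` (s^-1).
    dw_ab_ppm : float
        Signed 15N shift of state B relative to A (ppm).
    r1, r2 : float or sequence
        Longitudinal / transverse relaxation rates (s^-1), scalar
        (shared by all states) or one value per state.
    kex_ac, dw_ac_ppm : float
        A<->C parameters; must be zero for a two-state model.
    """

    populations: tuple
    kex_ab: float
    dw_ab_ppm: float
    r1: object = 1.2
    r2: object = 10.0
    kex_ac: float = 0.0
    dw_ac_ppm: float = 0.0

    def __post_init__(self):
        pops = np.asarray(self.populations, dtype=float)
        if pops.size not in (2, 3):
            raise ValueError("ExchangeModel supports 2 or 3 states, got "
                             f"{pops.size} populations")
        if abs(pops.sum() - 1.0) > 1e-12:
            raise ValueError(f"populations must sum to 1, got {pops.sum()!r}")
        if np.any(pops < 0.0) or np.any(pops > 1.0):
            raise ValueError(f"populations must lie in [0, 1], got {pops!r}")
        if self.kex_ab < 0.0 or self.kex_ac < 0.0:
            raise ValueError("exchange rates must be non-negative")
        if pops.size == 2 and (self.kex_ac != 0.0 or self.dw_ac_ppm != 0.0):
            raise ValueError("two-state model cannot carry A<->C parameters")
        object.__setattr__(self, "populations", tuple(float(p) for p in pops))
        # validate per-state shapes eagerly
        _per_state(self.r1, pops.size)
        _per_state(self.r2, pops.size)

    # -- derived quantities -------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.populations)

    @property
    def p_a(self) -> float:
        return self.populations[0]

    @property
    def p_b(self) -> float:
        return self.populations[1]

    @property
    def p_c(self) -> float:
        return self.populations[2] if self.n_states == 3 else 0.0

    @property
    def r1_per_state(self) -> np.ndarray:
        return np.array(_per_state(self.r1, self.n_states))

    @property
    def r2_per_state(self) -> np.ndarray:
        return np.array(_per_state(self.r2, self.n_states))

    @property
    def dw_ppm(self) -> np.ndarray:
        """Signed per-state offsets relative to A (A first, always 0)."""
        if self.n_states == 2:
            return np.array([0.0, self.dw_ab_ppm])
        return np.array([0.0, self.dw_ab_ppm, self.dw_ac_ppm])

    @staticmethod
    def _pair_rates(kex: float, p_major: float, p_minor: float):
        tot = p_major + p_minor
        if tot <= 0.0:
            return 0.0, 0.0
        k_fwd = kex * p_minor / tot   # major -> minor
        k_rev = kex * p_major / tot   # minor -> major
        return k_fwd, k_rev

    @property
    def k_ab(self) -> float:
        return self._pair_rates(self.kex_ab, self.p_a, self.p_b)[0]

    @property
    def k_ba(self) -> float:
        return self._pair_rates(self.kex_ab, self.p_a, self.p_b)[1]

    @property
    def k_ac(self) -> float:
        return self._pair_rates(self.kex_ac, self.p_a, self.p_c)[0]

    @property
    def k_ca(self) -> float:
        return self._pair_rates(self.kex_ac, self.p_a, self.p_c)[1]

    def exchange_matrix(self) -> np.ndarray:
        """First-order rate matrix K with dM/dt = K M; columns sum to zero."""
        n = self.n_states
        K = np.zeros((n, n))
        k_ab, k_ba = self.k_ab, self.k_ba
        K[0, 0] -= k_ab
        K[1, 0] += k_ab
        K[1, 1] -= k_ba
        K[0, 1] += k_ba
        if n == 3:
            k_ac, k_ca = self.k_ac, self.k_ca
            K[0, 0] -= k_ac
            K[2, 0] += k_ac
            K[2, 2] -= k_ca
            K[0, 2] += k_ca
        return K


@dataclass(frozen=True)
class CestExperiment:
    """CEST acquisition settings: weak-B1 saturation scanned over offsets."""

    b1_hz: float
    t_relax_s: float
    offsets_hz: tuple
    freq_15n_mhz: float = DEFAULT_FREQ_15N_MHZ

    def __post_init__(self):
        if self.b1_hz <= 0.0:
            raise ValueError("b1_hz must be positive")
        if self.t_relax_s <= 0.0:
            raise ValueError("t_relax_s must be positive")
        off = np.asarray(self.offsets_hz, dtype=float)
        if off.size < 2 or np.any(np.diff(off) <= 0.0):
            raise ValueError("offsets_hz must be strictly increasing")
        object.__setattr__(self, "offsets_hz", tuple(float(o) for o in off))

    @classmethod
    def default_grid(cls, b1_hz: float = 10.0, t_relax_s: float = 0.5,
                     span_ppm: float = 6.0, step_hz: float = 20.0,
                     freq_15n_mhz: float = DEFAULT_FREQ_15N_MHZ):
        """Offset grid every `step_hz` over +/- `span_ppm` around state A."""
        half = span_ppm * freq_15n_mhz
        n = int(np.floor(half / step_hz))
        offsets = np.arange(-n, n + 1) * step_hz
        return cls(b1_hz=b1_hz, t_relax_s=t_relax_s,
                   offsets_hz=tuple(offsets), freq_15n_mhz=freq_15n_mhz)


@dataclass(frozen=True)
class CpmgExperiment:
    """Constant-time CPMG settings; nu_CPMG = n_cyc / T_CPMG."""

    t_cpmg_s: float = 0.04
    ncyc_values: tuple = DEFAULT_NCYC
    freq_15n_mhz: float = DEFAULT_FREQ_15N_MHZ

    def __post_init__(self):
        if self.t_cpmg_s <= 0.0:
            raise ValueError("t_cpmg_s must be positive")
        ncyc = tuple(int(n) for n in self.ncyc_values)
        if any(n <= 0 for n in ncyc):
            raise ValueError("n_cyc values must be positive integers")
        object.__setattr__(self, "ncyc_values", ncyc)

    @property
    def nu_cpmg(self) -> np.ndarray:
        return np.asarray(self.ncyc_values, dtype=float) / self.t_cpmg_s


# ---------------------------------------------------------------------------
# generators and propagation


def _batched_expm(a: np.ndarray) -> np.ndarray:
    """exp(a) over the leading axis of stacked square matrices.

    Uses eigendecomposition (the generators here are almost always
    diagonalizable); stacks whose eigenvector basis is ill-conditioned fall
    back to scipy's scaling-and-squaring expm.
    """
    w, v = np.linalg.eig(a)
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(v)
        out = (v * np.exp(w)[..., None, :]) @ np.linalg.inv(v)
    bad = ~np.isfinite(cond) | (cond > 1e10) | ~np.isfinite(out).all(axis=(-2, -1))
    if np.any(bad):
        flat = out.reshape(-1, a.shape[-1], a.shape[-1])
        aflat = a.reshape(-1, a.shape[-1], a.shape[-1])
        for i in np.nonzero(np.atleast_1d(bad).ravel())[0]:
            flat[i] = expm(aflat[i])
        out = flat.reshape(a.shape)
    if np.isrealobj(a):
        out = out.real
    return out


def _cest_generators(model: ExchangeModel, experiment: CestExperiment,
                     carriers_hz: np.ndarray) -> np.ndarray:
    """Stack of Bloch-McConnell evolution matrices, one per carrier offset.

    Each state contributes a 3x3 block over (x, y, z) magnetization carrying
    its resonance offset relative to the carrier, R2, R1 and the B1 nutation
    coupling y <-> z; exchange couples identical components across states.
    """
    n = model.n_states
    w1 = TWO_PI * experiment.b1_hz
    nu_state = ppm_to_hz(model.dw_ppm, experiment.freq_15n_mhz)
    r1 = model.r1_per_state
    r2 = model.r2_per_state
    K = model.exchange_matrix()
    m = carriers_hz.size
    L = np.zeros((m, 3 * n, 3 * n))
    L += np.kron(K, np.eye(3))[None, :, :]
    for i in range(n):
        om = TWO_PI * (nu_state[i] - carriers_hz)
        s = 3 * i
        L[:, s, s] += -r2[i]
        L[:, s, s + 1] += -om
        L[:, s + 1, s] += om
        L[:, s + 1, s + 1] += -r2[i]
        L[:, s + 1, s + 2] += w1
        L[:, s + 2, s + 1] += -w1
        L[:, s + 2, s + 2] += -r1[i]
    return L


def build_cest_generator(model: ExchangeModel, carrier_offset_hz: float,
                         experiment: CestExperiment) -> np.ndarray:
    """Bloch-McConnell evolution matrix (3*n_states square) at one carrier."""
    return _cest_generators(model, experiment,
                            np.array([float(carrier_offset_hz)]))[0]


def simulate_cest_profile(model: ExchangeModel,
                          experiment: CestExperiment) -> np.ndarray:
    """Normalized CEST intensity ratio I/I0 at each carrier offset.

    Equilibrium z magnetization (populations) evolves for ``t_relax`` under
    the full generator; the reference omits the saturation field, so the
    common R1 decay (and exchange of z magnetization) cancels in the ratio.
    """
    carriers = np.asarray(experiment.offsets_hz, dtype=float)
    L = _cest_generators(model, experiment, carriers)
    try:
        P = _batched_expm(L * experiment.t_relax_s)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        cond = float(np.max(np.linalg.cond(L)))
        raise RuntimeError(
            f"matrix exponential failed (generator condition ~{cond:.2e})"
        ) from err
    n = model.n_states
    m0 = np.zeros(3 * n)
    m0[2::3] = model.populations
    sat = (P @ m0)[:, 2]
    # no-saturation reference: the z sector decouples from x/y when B1 = 0
    Kz = model.exchange_matrix() - np.diag(model.r1_per_state)
    ref = (expm(Kz * experiment.t_relax_s) @ np.asarray(model.populations))[0]
    if ref <= 0.0:
        raise RuntimeError("reference intensity is non-positive")
    return sat / ref


def simulate_cpmg_numeric(model: ExchangeModel,
                          experiment: CpmgExperiment) -> np.ndarray:
    """R2,eff at each nu_CPMG from numerical evolution with ideal pulses.

    Complex transverse magnetization (one component per state, initialized
    to the populations) evolves under ``dM/dt = (i*Omega - R2 - K) M`` for
    echo delays tau = T/(4 n_cyc); each 180-degree pulse acts as complex
    conjugation, 2 n_cyc pulses in total.  ``R2,eff = -ln(I/I0)/T`` with I
    the recovered state-A magnitude and I0 the no-CPMG reference (= pA).
    """
    omega = ppm_to_rads(model.dw_ppm, experiment.freq_15n_mhz)
    A = model.exchange_matrix().astype(complex)
    A += np.diag(1j * omega - model.r2_per_state)
    p = np.asarray(model.populations, dtype=complex)
    T = experiment.t_cpmg_s
    out = np.empty(len(experiment.ncyc_values))
    for j, ncyc in enumerate(experiment.ncyc_values):
        tau = T / (4.0 * ncyc)
        Q = expm(A * tau)
        R = expm(A * 2.0 * tau)
        # one echo unit tau-180-2tau-180-tau collapses to the linear map
        # Q conj(R) Q because conjugation distributes over the product
        E = Q @ np.conj(R) @ Q
        M = np.linalg.matrix_power(E, ncyc) @ p
        intensity = float(np.abs(M[0]))
        out[j] = -np.log(intensity / model.p_a) / T
    return out


def carver_richards_r2eff(two_state_model: ExchangeModel, nu_cpmg,
                          freq_15n_mhz: float = DEFAULT_FREQ_15N_MHZ):
    """Closed-form Carver-Richards R2,eff for two-state exchange.

    Davis generalization (unequal per-state R2 retained).  In the
    fast-exchange limit the exchange contribution at low nu_CPMG tends to
    ``pA pB dw^2 / kex``.

    Raises ``ValueError`` for three-state models (no closed form here).
    """
    m = two_state_model
    if m.n_states != 2:
        raise ValueError("Carver-Richards closed form requires a two-state model")
    nu = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    if np.any(nu <= 0.0):
        raise ValueError("nu_cpmg must be positive")
    pa, pb = m.p_a, m.p_b
    kex = m.kex_ab
    dw = float(ppm_to_rads(m.dw_ab_ppm, freq_15n_mhz))
    r2a, r2b = m.r2_per_state
    if pb == 0.0 or kex == 0.0 or dw == 0.0:
        out = np.full(nu.shape, r2a)
        return out if np.ndim(nu_cpmg) else float(out[0])
    k_ab = kex * pb
    k_ba = kex * pa
    d = r2a - r2b + k_ab - k_ba
    psi = d * d - dw * dw + 4.0 * k_ab * k_ba
    zeta = 2.0 * dw * d
    root = np.hypot(psi, zeta)
    eta_p = np.sqrt(np.maximum(root + psi, 0.0)) / (nu * 2.0 * np.sqrt(2.0))
    eta_m = np.sqrt(np.maximum(root - psi, 0.0)) / (nu * 2.0 * np.sqrt(2.0))
    d_p = 0.5 * (1.0 + (psi + 2.0 * dw * dw) / root)
    d_m = 0.5 * (-1.0 + (psi + 2.0 * dw * dw) / root)
    arg = d_p * np.cosh(eta_p) - d_m * np.cos(eta_m)
    out = 0.5 * (r2a + r2b + kex) - nu * np.arccosh(np.maximum(arg, 1.0))
    return out if np.ndim(nu_cpmg) else float(out[0])


def asymptotic_r2eff(model: ExchangeModel, nu_cpmg,
                     freq_15n_mhz: float = DEFAULT_FREQ_15N_MHZ):
    """Dominant-eigenvalue decay rate of the CPMG cycle propagator.

    The slowest-decaying mode of one echo unit gives the asymptotic
    (long-T_CPMG) R2,eff, free of the minor-state amplitude contribution
    that the finite-time intensity measurement carries.  This is the
    quantity the Carver-Richards closed form approximates.
    """
    omega = ppm_to_rads(model.dw_ppm, freq_15n_mhz)
    A = model.exchange_matrix().astype(complex)
    A += np.diag(1j * omega - model.r2_per_state)
    nu = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    out = np.empty(nu.shape)
    for j, v in enumerate(nu):
        tau = 1.0 / (4.0 * v)
        Q = expm(A * tau)
        R = expm(A * 2.0 * tau)
        lam = np.max(np.abs(np.linalg.eigvals(Q @ np.conj(R) @ Q)))
        out[j] = -np.log(lam) / (4.0 * tau)
    return out if np.ndim(nu_cpmg) else float(out[0])


def r2eff_from_intensities(intensity, reference_intensity, t_cpmg_s: float):
    """R2,eff = -ln(I/I0)/T_CPMG; inverse of the simulated intensity model."""
    i = np.asarray(intensity, dtype=float)
    i0 = np.asarray(reference_intensity, dtype=float)
    if t_cpmg_s <= 0.0:
        raise ValueError("t_cpmg_s must be positive")
    if np.any(i <= 0.0) or np.any(i0 <= 0.0):
        raise ValueError("intensities must be positive")
    out = -np.log(i / i0) / t_cpmg_s
    return out if out.ndim else float(out)
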