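"""Event-based short-term synaptic plasticity (STP) model and map responses.

Each presynaptic spike evokes an EPSP shaped by a bi-exponential kernel

    V(t) = A_e * (exp(-t/tau1) - exp(-t/tau2)),   tau1 = 3.0 ms, tau2 = 0.4 ms

whose amplitude A_e is modulated by spike history through one depressing
and two facilitating (fast + slow) exponential processes.  For spike j
with preceding spikes i at lags dt_i:

    A_td = max(1 - sum_i A_d exp(-dt_i / tau_d), 0)          (depression)
    A_tf = min(1 + sum_i [A_f exp(-dt_i / tau_f)
                          + A_s exp(-dt_i / tau_s)], 3.3)    (facilitation)
    amplitude(j) = A_tf * A_td,   amplitude(first spike) = 1

so the facilitatory multiplier saturates at 3.3 times the unit response
and the depressing multiplier is floored at zero.  Amplitudes are
normalized to the first response.

Parameters vary across a spatial synapse grid by scaling with normalized
marker-size profiles: the depression amplitude/time constant follow the
tangential/radial PSD95 size factors, the fast-facilitation pair follows
the SAP102 factors, and the slow component is spatially constant.

Three printed parameter sets are bundled as presets (control and the two
knockout phenotypes); fitting uses Nelder-Mead least squares on the
normalized amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.interpolate import make_interp_spline
from scipy.optimize import minimize

__all__ = [
    "STPParams",
    "PRESETS",
    "SpikePattern",
    "pattern",
    "stp_amplitudes",
    "epsp_peak_time",
    "epsp_trace",
    "ScalingField",
    "synapse_field",
    "ResponseMap",
    "map_response",
    "fit_stp",
    "theta_burst_indices",
    "cohort_compare",
]

TAU1_MS = 3.0
TAU2_MS = 0.4
FACILITATION_CAP = 3.3


@dataclass(frozen=True)
class STPParams:
    """The six plasticity parameters (amplitudes a.u., time constants ms)."""

    A_d0: float
    tau_d0: float
    A_f0: float
    tau_f0: float
    A_s0: float
    tau_s0: float
    tau1: float = TAU1_MS
    tau2: float = TAU2_MS
    cap: float = FACILITATION_CAP

    def __post_init__(self) -> None:
        if min(self.tau_d0, self.tau_f0, self.tau_s0, self.tau1, self.tau2) <= 0:
            raise ValueError("time constants must be positive")
        if min(self.A_d0, self.A_f0, self.A_s0) < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.cap <= 1 or self.tau1 <= self.tau2:
            raise ValueError("cap must exceed 1 and tau1 must exceed tau2")


#: Fitted parameter sets: control plus the two scaffold-knockout phenotypes.
PRESETS: dict[str, STPParams] = {
    "control": STPParams(0.25, 130.0, 4.9, 13.0, 0.458, 60.0),
    "psd95": STPParams(0.022, 140.0, 7.3, 13.0, 0.458, 60.0),
    "psd93": STPParams(0.1, 440.0, 4.4, 13.0, 0.458, 60.0),
}


@dataclass(frozen=True)
class SpikePattern:
    name: str
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, float)
        if t.ndim != 1 or len(t) < 1:
            raise ValueError("pattern needs at least one spike")
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times_ms", t)


def pattern(name: str, n_pulses: int = 8, ibi_mode: str = "gap") -> SpikePattern:
    """Standard stimulation patterns.

    theta_burst: 4-pulse bursts, intra-burst IPI 25 ms, IBI 125 ms;
    theta: IPI 200 ms; gamma: IPI 25 ms; gamma_doublets: 2-pulse doublets,
    IPI 13 ms, IBI 300 ms; mixed: the fixed times 25, 50, 120, 145, 205,
    270, 310 ms.

    ``ibi_mode='gap'`` reads the interburst interval as the gap from a
    burst's last pulse to the next burst's first pulse (theta-burst onset
    period 200 ms, i.e. bursts at 5 Hz); ``'onset'`` as onset-to-onset.
    """
    if name == "mixed":
        return SpikePattern(name, np.array([25.0, 50, 120, 145, 205, 270, 310]))
    if name == "theta":
        return SpikePattern(name, 200.0 * np.arange(n_pulses))
    if name == "gamma":
        return SpikePattern(name, 25.0 * np.arange(n_pulses))
    if name in ("theta_burst", "gamma_doublets"):
        per_burst, ipi, ibi = ((4, 25.0, 125.0) if name == "theta_burst"
                               else (2, 13.0, 300.0))
        period = ibi + (per_burst - 1) * ipi if ibi_mode == "gap" else ibi
        times = []
        b = 0
        while len(times) < n_pulses:
            onset = b * period
            for p in range(per_burst):
                if len(times) < n_pulses:
                    times.append(onset + p * ipi)
            b += 1
        return SpikePattern(name, np.array(times))
    raise ValueError(f"unknown pattern {name!r}")


def stp_amplitudes(spike_times, params: STPParams,
                   return_factors: bool = False):
    """Normalized per-spike response amplitudes for a spike train.

    Returns the amplitudes (first spike = 1); with ``return_factors`` also
    the per-spike facilitation and depression multipliers.
    """
    t = np.asarray(spike_times, float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("need at least one spike")
    if len(t) > 1 and not (np.diff(t) > 0).all():
        raise ValueError("spike times must be strictly increasing")
    n = len(t)
    lag = t[:, None] - t[None, :]          # lag[j, i] = t_j - t_i
    prev = lag > 0
    with np.errstate(over="ignore"):
        dep = np.where(prev, params.A_d0 * np.exp(-lag / params.tau_d0), 0.0)
        fac = np.where(prev, params.A_f0 * np.exp(-lag / params.tau_f0)
                       + params.A_s0 * np.exp(-lag / params.tau_s0), 0.0)
    a_td = np.maximum(1.0 - dep.sum(axis=1), 0.0)
    a_tf = np.minimum(1.0 + fac.sum(axis=1), params.cap)
    amps = a_tf * a_td
    if return_factors:
        return amps, a_tf, a_td
    return amps


def epsp_peak_time(tau1: float = TAU1_MS, tau2: float = TAU2_MS) -> float:
    """Analytic peak time of the bi-exponential kernel."""
    return tau1 * tau2 / (tau1 - tau2) * np.log(tau1 / tau2)


def _kernel_peak(tau1: float, tau2: float) -> float:
    tp = epsp_peak_time(tau1, tau2)
    return np.exp(-tp / tau1) - np.exp(-tp / tau2)


def epsp_trace(spike_times, amplitudes, dt: float = 1.0,
               t_max: float | None = None,
               tau1: float = TAU1_MS, tau2: float = TAU2_MS
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Superposed EPSP voltage trace on a regular time grid.

    Returns ``(t, v, peaks)``: the grid, the trace (zero before the first
    spike, linear in the amplitudes) and the analytic per-spike peak
    values ``A_j * (exp(-tp/tau1) - exp(-tp/tau2))`` at
    ``tp = tau1 tau2/(tau1 - tau2) ln(tau1/tau2)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    st = np.asarray(spike_times, float)
    amps = np.asarray(amplitudes, float)
    if st.shape != amps.shape:
        raise ValueError("amplitudes must align with spikes")
    if t_max is None:
        t_max = st.max() + 8 * tau1
    t = np.arange(0.0, t_max + dt / 2, dt)
    rel = t[None, :] - st[:, None]
    v = np.where(rel >= 0,
                 amps[:, None] * (np.exp(-np.maximum(rel, 0) / tau1)
                                  - np.exp(-np.maximum(rel, 0) / tau2)),
                 0.0).sum(axis=0)
    peaks = amps * _kernel_peak(tau1, tau2)
    return t, v, peaks


# ----------------------------------------------------------- spatial field

SCALE_FLOOR = 0.05  # keeps scaled amplitudes/time constants away from zero


@dataclass
class ScalingField:
    """Per-synapse STP parameter scaling factors on a spatial grid.

    S_Ad / S_Td scale the depression amplitude / time constant (tangential
    and radial PSD95 size factors); S_Af / S_Tf scale fast facilitation
    (tangential and radial SAP102 size factors).  All values are clamped to
    [SCALE_FLOOR, 1].  The slow component is spatially constant.
    """

    tangential_idx: np.ndarray
    radial_idx: np.ndarray
    S_Ad: np.ndarray
    S_Td: np.ndarray
    S_Af: np.ndarray
    S_Tf: np.ndarray
    base: STPParams = field(default_factory=lambda: PRESETS["control"])

    def __len__(self) -> int:
        return len(self.S_Ad)

    def params_at(self, i: int) -> STPParams:
        return replace(self.base,
                       A_d0=self.base.A_d0 * self.S_Ad[i],
                       tau_d0=self.base.tau_d0 * self.S_Td[i],
                       A_f0=self.base.A_f0 * self.S_Af[i],
                       tau_f0=self.base.tau_f0 * self.S_Tf[i])


def _interp_profile(profile, n: int) -> np.ndarray:
    p = np.asarray(profile, float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("profiles must be normalized to [0, 1]")
    if len(p) == 1 or n == 1:
        out = np.full(n, p[0] if len(p) == 1 else p[0])
        if len(p) > 1 and n == 1:
            out = np.array([p[0]])
        return np.clip(out, SCALE_FLOOR, 1.0)
    x = np.linspace(0, 1, len(p))
    k = min(3, len(p) - 1)
    spl = make_interp_spline(x, p, k=k)   # cubic B-spline when possible
    vals = spl(np.linspace(0, 1, n))
    return np.clip(vals, SCALE_FLOOR, 1.0)


def synapse_field(tangential_psd95, radial_psd95, tangential_sap102,
                  radial_sap102, n_tangential: int = 101,
                  n_radial: int | None = None,
                  base: STPParams | None = None) -> ScalingField:
    """Interpolate normalized size profiles to a synapse grid.

    Profiles are 1D samples of normalized size factors in [0, 1],
    interpolated with cubic B-splines.  In 1D mode (``n_radial=None``,
    default 101 synapses along the tangential axis) the radial factors are
    evaluated at the profile midpoint; in 2D mode (e.g. 11 x 11) the grid
    is the outer product of the tangential and radial axes.
    """
    base = base or PRESETS["control"]
    s_ad_t = _interp_profile(tangential_psd95, n_tangential)
    s_af_t = _interp_profile(tangential_sap102, n_tangential)
    if n_radial is None:
        mid = _interp_profile(radial_psd95, 3)[1], _interp_profile(radial_sap102, 3)[1]
        ti = np.arange(n_tangential)
        return ScalingField(tangential_idx=ti, radial_idx=np.zeros_like(ti),
                            S_Ad=s_ad_t, S_Td=np.full(n_tangential, mid[0]),
                            S_Af=s_af_t, S_Tf=np.full(n_tangential, mid[1]),
                            base=base)
    s_td_r = _interp_profile(radial_psd95, n_radial)
    s_tf_r = _interp_profile(radial_sap102, n_radial)
    ti, ri = np.meshgrid(np.arange(n_tangential), np.arange(n_radial),
                         indexing="ij")
    ti, ri = ti.ravel(), ri.ravel()
    return ScalingField(tangential_idx=ti, radial_idx=ri,
                        S_Ad=s_ad_t[ti], S_Td=s_td_r[ri],
                        S_Af=s_af_t[ti], S_Tf=s_tf_r[ri], base=base)


@dataclass
class ResponseMap:
    """Per-synapse summed peak EPSP amplitudes for one stimulation pattern."""

    responses: np.ndarray
    normalized: np.ndarray
    tangential_idx: np.ndarray
    radial_idx: np.ndarray
    pattern_name: str

    @property
    def max_min_ratio(self) -> float:
        return float(self.responses.max() / self.responses.min())


def map_response(fld: ScalingField, pat: SpikePattern,
                 shared_max: float | None = None) -> ResponseMap:
    """Run the STP model at every synapse of the field.

    The synaptic response is the sum of per-spike peak EPSP amplitudes;
    the normalized variant divides by the map maximum (or ``shared_max``
    when several patterns share one normalization group), so the maximum
    is exactly 1 within a normalization group.
    """
    kp = _kernel_peak(fld.base.tau1, fld.base.tau2)
    resp = np.empty(len(fld))
    for i in range(len(fld)):
        amps = stp_amplitudes(pat.times_ms, fld.params_at(i))
        resp[i] = amps.sum() * kp
    denom = shared_max if shared_max is not None else resp.max()
    return ResponseMap(responses=resp, normalized=resp / denom,
                       tangential_idx=fld.tangential_idx,
                       radial_idx=fld.radial_idx, pattern_name=pat.name)


# ------------------------------------------------------------------ fitting

FREE_ALL = ("A_d0", "tau_d0", "A_f0", "tau_f0", "A_s0", "tau_s0")
FREE_KNOCKOUT = ("A_d0", "tau_d0", "A_f0")  # knockout refits free only these


def theta_burst_indices(bursts=(1, 2, 8, 10), per_burst: int = 4) -> np.ndarray:
    """Pulse indices of the given (1-based) bursts in a theta-burst train."""
    return np.concatenate([
        np.arange((b - 1) * per_burst, b * per_burst) for b in bursts])


def fit_stp(target_amplitudes, pat: SpikePattern,
            free: tuple[str, ...] = FREE_ALL,
            init: STPParams | None = None,
            base: STPParams | None = None,
            select_idx: np.ndarray | None = None,
            maxiter: int = 4000) -> tuple[STPParams, float, bool]:
    """Nelder-Mead least-squares fit of the STP parameters.

    ``free`` lists the parameters allowed to change (all six for a control
    fit, the knockout mode frees only A_d0, tau_d0 and A_f0); the rest stay
    at ``base``.  ``select_idx`` restricts the residual to a subset of
    spikes (e.g. the pulses of bursts 1, 2, 8 and 10 of a 10-burst
    protocol).  Optimization runs on log-parameters, so positivity is
    structural.  Returns (params, residual_sse, converged).
    """
    base = base or PRESETS["control"]
    init = init or base
    target = np.asarray(target_amplitudes, float)
    idx = np.arange(len(pat.times_ms)) if select_idx is None else np.asarray(select_idx)
    if len(target) != len(idx):
        raise ValueError("target amplitudes must align with the selected spikes")

    def build(theta_log):
        # clip keeps exp() away from under/overflow during simplex expansion
        kw = {name: float(np.exp(np.clip(v, -30.0, 30.0)))
              for name, v in zip(free, theta_log)}
        return replace(base, **kw)

    def objective(theta_log):
        amps = stp_amplitudes(pat.times_ms, build(theta_log))
        return float(((amps[idx] - target) ** 2).sum())

    x0 = np.log([getattr(init, name) for name in free])
    opts = {"maxiter": maxiter, "xatol": 1e-10, "fatol": 1e-14}

    def polished(x_start):
        res = minimize(objective, x_start, method="Nelder-Mead", options=opts)
        for _ in range(2):  # re-inflating the simplex escapes premature stalls
            res2 = minimize(objective, res.x, method="Nelder-Mead", options=opts)
            if res2.fun < res.fun:
                res = res2
        return res

    # cap/floor saturation creates flat objective regions; seeded jittered
    # restarts around the init recover from starts trapped there
    best = polished(x0)
    rng = np.random.default_rng(0)
    for _ in range(8):
        if best.fun < 1e-18:
            break
        res = polished(x0 + rng.normal(0, 0.5, len(x0)))
        if res.fun < best.fun:
            best = res
    return build(best.x), float(best.fun), bool(best.success or best.fun < 1e-10)


def cohort_compare(responses_a, responses_b, alpha: float = 0.05) -> dict:
    """Two-sample KS and t tests plus the max/min response ratio per cohort."""
    a = np.asarray(responses_a, float)
    b = np.asarray(responses_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least three synapses per cohort")
    ks = stats.ks_2samp(a, b)
    tt = stats.ttest_ind(a, b)
    return {
        "ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue),
        "t_statistic": float(tt.statistic), "t_p": float(tt.pvalue),
        "ratio_a": float(a.max() / a.min()), "ratio_b": float(b.max() / b.min()),
        "alpha": alpha,
        "significant": bool(ks.pvalue < alpha and tt.pvalue < alpha),
    }
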