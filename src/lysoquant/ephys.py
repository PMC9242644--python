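"""Whole-cell voltage-clamp simulation and kinetics fitting.

The generator is a minimal phenomenology of a slowly gating outward
rectifier (ClC-7-like transport current): Boltzmann steady-state activation
p_inf(V) = 1/(1 + exp(-(V - v_half)/k_slope)) with mono-exponential
relaxation, tau_act(V) = tau0 * exp(-V / v_tau).  Pipette dialysis of an
inhibitory lipid after break-in scales the conductance by

    s(c, t) = 1 - f_max(c) * (1 - exp(-t / tau_wash)),
    f_max(c) = f_ceiling * c^n / (c^n + ec50^n),

so inhibition develops over minutes and saturates dose-dependently.  Tail
currents on repolarization decay mono-exponentially; under inhibition the
deactivation is faster (``deact_speedup``) and the tail onset amplitude may
be inhibited more strongly than the steady-state current
(``f_ceiling_tail``), emulating a gating-state-dependent block.

Fitters: single-exponential activation/decay fits (time constants, tail
amplitudes extrapolated to repolarization onset), late/early break-in
inhibition ratios, and the Hill dose-response EC50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GatingParams",
    "InhibitionModel",
    "VoltageProtocol",
    "SweepFamily",
    "KineticsFit",
    "FamilyMetrics",
    "DoseResponseFit",
    "simulate_family",
    "fit_exponential",
    "family_metrics",
    "inhibition_ratio",
    "fit_dose_response",
]


@dataclass(frozen=True)
class GatingParams:
    """Conductance and gating of the simulated rectifier.

    Units: g_max nS, voltages mV, times s.  Currents come out in pA
    (nS x mV).  ``i_inst_frac`` is the instantaneous fraction of the pulse
    current (the part that does not relax slowly).
    """

    g_max: float = 10.0
    v_rev: float = 0.0
    v_half: float = 40.0
    k_slope: float = 25.0
    tau0: float = 0.4
    v_tau: float = 200.0
    tau_deact: float = 0.05
    i_inst_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.g_max < 0 or self.k_slope <= 0:
            raise ValueError("g_max >= 0 and k_slope > 0 required")
        if self.tau0 <= 0 or self.v_tau <= 0 or self.tau_deact <= 0:
            raise ValueError("time constants must be positive")
        if not (0.0 <= self.i_inst_frac <= 1.0):
            raise ValueError("i_inst_frac in [0, 1]")

    def p_inf(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp(-(v - self.v_half) / self.k_slope))

    def tau_act(self, v: float) -> float:
        return self.tau0 * math.exp(-v / self.v_tau)


@dataclass(frozen=True)
class InhibitionModel:
    """Time- and dose-dependent conductance inhibition after break-in.

    Defaults are chosen so that at 100 uM the simulated 3 min / 30 s current
    ratios are ~0.61 (steady-state) and ~0.34 (tail onset), i.e. ~39% and
    ~66% inhibition.  ``f_ceiling_tail`` (>= f_ceiling, <= 1) applies to the
    tail onset amplitude only; None means equal to ``f_ceiling``.
    """

    f_ceiling: float = 0.64
    ec50_um: float = 30.0
    hill_n: float = 1.5
    tau_wash_s: float = 60.0
    deact_speedup: float = 0.6
    f_ceiling_tail: float | None = 0.94

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_ceiling <= 1.0):
            raise ValueError("f_ceiling in [0, 1]")
        if self.f_ceiling_tail is not None and not (0.0 <= self.f_ceiling_tail <= 1.0):
            raise ValueError("f_ceiling_tail in [0, 1]")
        if self.ec50_um <= 0 or self.hill_n <= 0 or self.tau_wash_s <= 0:
            raise ValueError("ec50, hill_n, tau_wash must be positive")
        if not (0.0 < self.deact_speedup <= 1.0):
            raise ValueError("deact_speedup in (0, 1]")

    def hill_fraction(self, conc_um: float) -> float:
        if conc_um == 0:
            return 0.0
        cn = conc_um**self.hill_n
        return cn / (cn + self.ec50_um**self.hill_n)

    def scale(self, conc_um: float, t_s: float) -> float:
        """s(c, t): conductance scale at time t after break-in; in (0, 1]."""
        f = self.f_ceiling * self.hill_fraction(conc_um)
        return 1.0 - f * (1.0 - math.exp(-t_s / self.tau_wash_s))

    def scale_tail(self, conc_um: float, t_s: float) -> float:
        ceil = self.f_ceiling if self.f_ceiling_tail is None else self.f_ceiling_tail
        f = ceil * self.hill_fraction(conc_um)
        return 1.0 - f * (1.0 - math.exp(-t_s / self.tau_wash_s))


@dataclass(frozen=True)
class VoltageProtocol:
    """Step protocol: hold, depolarizing pulse, repolarizing tail."""

    holding_v: float = -60.0
    step_voltages: tuple[float, ...] = tuple(float(v) for v in range(-80, 141, 20))
    pre_s: float = 0.1
    pulse_s: float = 2.0
    tail_s: float = 0.5
    dt: float = 0.001

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if min(self.pre_s, self.pulse_s, self.tail_s) <= 10 * self.dt:
            raise ValueError("segment durations must exceed 10*dt")
        if not self.step_voltages:
            raise ValueError("need at least one step voltage")

    @property
    def n_pre(self) -> int:
        return int(round(self.pre_s / self.dt))

    @property
    def n_pulse(self) -> int:
        return int(round(self.pulse_s / self.dt))

    @property
    def n_tail(self) -> int:
        return int(round(self.tail_s / self.dt))


@dataclass(frozen=True)
class SweepFamily:
    """Current traces (pA), one sweep per step voltage, with segment markers."""

    protocol: VoltageProtocol
    sweeps: np.ndarray        # (n_steps, n_samples)
    t_breakin_s: float
    conc_um: float
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.protocol.n_pre + self.protocol.n_pulse + self.protocol.n_tail
        if self.sweeps.shape != (len(self.protocol.step_voltages), n):
            raise ValueError("sweep array inconsistent with protocol")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) * self.protocol.dt

    def _index(self, v: float) -> int:
        try:
            return self.protocol.step_voltages.index(float(v))
        except ValueError:
            raise ValueError(f"voltage {v} mV not in protocol steps") from None

    def pulse_segment(self, v: float) -> tuple[np.ndarray, np.ndarray]:
        """(t since pulse onset, current) for the depolarizing pulse."""
        p = self.protocol
        y = self.sweeps[self._index(v), p.n_pre : p.n_pre + p.n_pulse]
        return np.arange(y.size) * p.dt, y

    def tail_segment(self, v: float) -> tuple[np.ndarray, np.ndarray]:
        """(t since repolarization onset, current) for the tail."""
        p = self.protocol
        y = self.sweeps[self._index(v), p.n_pre + p.n_pulse :]
        return np.arange(y.size) * p.dt, y


def simulate_family(
    gating: GatingParams,
    inhibition: InhibitionModel,
    conc_um: float,
    t_breakin_s: float,
    protocol: VoltageProtocol = VoltageProtocol(),
    noise_sd_pa: float = 0.0,
    seed: int = 0,
) -> SweepFamily:
    """Simulate one pulse family recorded ``t_breakin_s`` after break-in.

    The inhibition scale is frozen at the family's break-in time (families
    are short relative to the dialysis time constant).  Additive Gaussian
    current noise; deterministic per seed.
    """
    if conc_um < 0:
        raise ValueError("conc_um must be >= 0")
    if t_breakin_s < 0:
        raise ValueError("t_breakin_s must be >= 0")
    g = gating
    p = protocol
    s = inhibition.scale(conc_um, t_breakin_s)
    s_tail = inhibition.scale_tail(conc_um, t_breakin_s)
    tau_d = g.tau_deact * (inhibition.deact_speedup if conc_um > 0 else 1.0)

    hold_i = s * g.g_max * g.p_inf(p.holding_v) * (p.holding_v - g.v_rev)
    t_pulse = np.arange(p.n_pulse) * p.dt
    t_tail = np.arange(p.n_tail) * p.dt
    sweeps = np.empty((len(p.step_voltages), p.n_pre + p.n_pulse + p.n_tail))
    for k, v in enumerate(p.step_voltages):
        tau_a = g.tau_act(v)
        act = g.i_inst_frac + (1.0 - g.i_inst_frac) * (1.0 - np.exp(-t_pulse / tau_a))
        pulse = s * g.g_max * g.p_inf(v) * (v - g.v_rev) * act
        p_end = g.p_inf(v) * (
            g.i_inst_frac + (1.0 - g.i_inst_frac) * (1.0 - math.exp(-p.pulse_s / tau_a))
        )
        tail_onset = s_tail * g.g_max * p_end * (p.holding_v - g.v_rev)
        tail = hold_i + (tail_onset - hold_i) * np.exp(-t_tail / tau_d)
        sweeps[k, : p.n_pre] = hold_i
        sweeps[k, p.n_pre : p.n_pre + p.n_pulse] = pulse
        sweeps[k, p.n_pre + p.n_pulse :] = tail
    if noise_sd_pa > 0:
        rng = np.random.default_rng(seed)
        sweeps = sweeps + rng.normal(0.0, noise_sd_pa, sweeps.shape)
    return SweepFamily(protocol=p, sweeps=sweeps, t_breakin_s=float(t_breakin_s),
                       conc_um=float(conc_um), seed=int(seed))


@dataclass(frozen=True)
class KineticsFit:
    amplitude: float
    tau: float
    offset: float
    rmse: float
    converged: bool


def _exp_decay(t, offset, amplitude, tau):
    return offset + amplitude * np.exp(-t / tau)


def _exp_activation(t, offset, amplitude, tau):
    return offset + amplitude * (1.0 - np.exp(-t / tau))


def fit_exponential(t: np.ndarray, y: np.ndarray, kind: str) -> KineticsFit:
    """Single-exponential least squares.

    ``kind='activation'`` fits y = offset + A*(1 - exp(-t/tau));
    ``kind='decay'`` fits y = offset + A*exp(-t/tau).  Initial values come
    from a log-linear regression on the detrended signal.  Degenerate or
    non-converging inputs return converged=False rather than raising.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind not in ("activation", "decay"):
        raise ValueError("kind must be 'activation' or 'decay'")
    if t.size < 20:
        raise ValueError("need >= 20 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    span = float(np.ptp(y))
    if span == 0.0 or span < 1e-9 * max(1.0, float(np.max(np.abs(y)))):
        return KineticsFit(amplitude=0.0, tau=float("nan"), offset=float(y[0]),
                           rmse=0.0, converged=False)

    ts = t - t[0]
    if kind == "decay":
        offset0 = float(y[-1])
        z = y - offset0
        a_sign = 1.0 if z[0] >= 0 else -1.0
    else:
        offset0 = float(y[0])
        z = y[-1] - y  # decays from (y_end - y_0) toward 0
        a_sign = 1.0 if (y[-1] - y[0]) >= 0 else -1.0
    zmax = float(np.max(np.abs(z)))
    sel = np.abs(z) > 0.05 * zmax
    tau0 = float(ts[-1] / 3.0) if ts[-1] > 0 else 1.0
    if sel.sum() >= 2:
        slope = np.polyfit(ts[sel], np.log(np.abs(z[sel]) + 1e-300), 1)[0]
        if slope < 0:
            tau0 = float(-1.0 / slope)
    if kind == "decay":
        amp0 = a_sign * zmax * math.exp(min(t[0] / tau0, 50.0))
    else:
        amp0 = float(y[-1] - y[0])
    model = _exp_decay if kind == "decay" else _exp_activation
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[offset0, amp0, tau0],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return KineticsFit(amplitude=float(amp0), tau=float(tau0),
                           offset=offset0, rmse=float("inf"), converged=False)
    offset, amplitude, tau = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    converged = bool(np.isfinite(tau) and tau > 0)
    return KineticsFit(amplitude=amplitude, tau=tau, offset=offset,
                       rmse=rmse, converged=converged)


#: Blanking window after repolarization (capacitance transient), seconds.
TAIL_BLANK_S = 0.005


@dataclass(frozen=True)
class FamilyMetrics:
    i_max_pa: float
    i_tail_pa: float
    tau_act_s: float
    tau_deact_s: float
    activation_fit: KineticsFit
    tail_fit: KineticsFit


def family_metrics(fam: SweepFamily, v_ref: float = 140.0) -> FamilyMetrics:
    """Headline metrics of a pulse family at the reference voltage.

    i_max: mean of the last 5% of pulse samples (steady-state reading, robust
    to noise).  i_tail: the fitted tail exponential extrapolated to the
    moment of repolarization (first 5 ms blanked).  Time constants from the
    single-exponential fits of the pulse and tail segments.
    """
    t_pulse, y_pulse = fam.pulse_segment(v_ref)
    k = max(1, int(round(0.05 * y_pulse.size)))
    i_max = float(np.mean(y_pulse[-k:]))
    act_fit = fit_exponential(t_pulse, y_pulse, kind="activation")

    t_tail, y_tail = fam.tail_segment(v_ref)
    keep = t_tail >= TAIL_BLANK_S
    tail_fit = fit_exponential(t_tail[keep], y_tail[keep], kind="decay")
    # value of the fitted exponential at t = 0 (repolarization onset)
    i_tail = tail_fit.offset + tail_fit.amplitude if tail_fit.converged else float("nan")
    return FamilyMetrics(
        i_max_pa=i_max,
        i_tail_pa=float(i_tail),
        tau_act_s=act_fit.tau if act_fit.converged else float("nan"),
        tau_deact_s=tail_fit.tau if tail_fit.converged else float("nan"),
        activation_fit=act_fit,
        tail_fit=tail_fit,
    )


def inhibition_ratio(
    fam_late: SweepFamily,
    fam_early: SweepFamily,
    v_ref: float = 140.0,
) -> tuple[float, float]:
    """Late/early ratios of i_max and i_tail for one cell's two recordings.

    The early family is the within-cell baseline (shortly after break-in);
    the late family reflects developed inhibition.
    """
    if fam_late.protocol != fam_early.protocol:
        raise ValueError("families must share a protocol")
    if not fam_late.t_breakin_s > fam_early.t_breakin_s:
        raise ValueError("late family must come after the early one")
    m_late = family_metrics(fam_late, v_ref)
    m_early = family_metrics(fam_early, v_ref)
    if m_early.i_max_pa == 0 or m_early.i_tail_pa == 0:
        raise ValueError("zero early current: ratio undefined")
    return (m_late.i_max_pa / m_early.i_max_pa, m_late.i_tail_pa / m_early.i_tail_pa)


@dataclass(frozen=True)
class DoseResponseFit:
    ec50: float
    hill_n: float
    floor: float
    ceiling: float
    rmse: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.ceiling < self.floor:
            raise ValueError("ceiling must be >= floor")

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        cn = np.where(conc > 0, conc, np.nan) ** self.hill_n
        out = np.where(
            conc > 0,
            self.floor + (self.ceiling - self.floor) * cn / (cn + self.ec50**self.hill_n),
            self.floor,
        )
        return float(out) if out.ndim == 0 else out


def _hill(c, floor, ceiling, ec50, n):
    c = np.asarray(c, dtype=float)
    cn = np.where(c > 0, c, 1e-300) ** n
    return floor + (ceiling - floor) * cn / (cn + ec50**n)


def fit_dose_response(
    conc_um: Sequence[float],
    inhibition_fraction: Sequence[float],
) -> DoseResponseFit:
    """Least-squares Hill fit of fractional inhibition vs concentration.

    Requires >= 4 distinct concentrations whose responses bracket the
    apparent half-maximal response (the concentration closest to half-max
    must not be the design's extreme).
    """
    c = np.asarray(conc_um, dtype=float)
    y = np.asarray(inhibition_fraction, dtype=float)
    if c.shape != y.shape:
        raise ValueError("conc and response must have the same length")
    distinct = np.unique(c)
    if distinct.size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    # bracketing: the concentration nearest half-max must be interior
    group_means = np.array([y[c == d].mean() for d in distinct])
    half = 0.5 * (group_means.min() + group_means.max())
    i_mid = int(np.argmin(np.abs(group_means - half)))
    if i_mid == 0 or i_mid == distinct.size - 1:
        raise ValueError(
            "non-bracketing design: need concentrations below and above the apparent midpoint"
        )
    pos = distinct[distinct > 0]
    ec50_0 = float(distinct[i_mid]) if distinct[i_mid] > 0 else float(pos.min())
    p0 = [float(group_means.min()), float(group_means.max()), ec50_0, 1.0]
    lower = [-np.inf, -np.inf, 1e-6, 0.2]
    upper = [np.inf, np.inf, 1e6, 10.0]
    popt, _ = curve_fit(_hill, c, y, p0=p0, bounds=(lower, upper),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000)
    floor, ceiling, ec50, n = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((_hill(c, *popt) - y) ** 2)))
    if ceiling < floor:  # re-express with increasing branch
        floor, ceiling = ceiling, floor
    if not (pos.min() < ec50 < c.max()):
        raise ValueError(
            "non-bracketing design: fitted EC50 falls outside the tested "
            "concentration range; add concentrations below and above the midpoint"
        )
    return DoseResponseFit(ec50=ec50, hill_n=n, floor=floor, ceiling=ceiling, rmse=rmse)
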