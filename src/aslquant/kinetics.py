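"""Forward kinetic models for ASL label-control difference signals.

The tissue model is the general kinetic model: a box-car arterial input
function (AIF) decaying at the blood T1 rate, convolved with a well-mixed
single-compartment residue function with venous outflow, which decays at the
apparent rate 1/T1app = 1/T1_tissue + f/lambda. Closed forms are provided for
both pseudo-continuous (pcasl) and pulsed (pasl) labelling; a trapezium-rule
numerical convolution serves as a model-agnostic alternative (and as the
oracle for the analytic forms).

Signal units: perfusion ``f`` is expressed in signal units per second (it
absorbs the arterial-blood equilibrium magnetisation until calibration), so
the predicted difference signal is in the same arbitrary units as the data.

Time convention: model time t is measured from the start of labelling, so the
measurement time of a pcasl volume is ``tau + PLD`` and of a pasl volume is
the inversion time TI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ._exceptions import ConfigurationError
from .data import ASLTimingSpec

__all__ = [
    "TissueKineticParams",
    "MacrovascularParams",
    "ModelConfig",
    "tissue_signal",
    "macrovascular_signal",
    "numeric_convolve",
    "full_model",
    "measurement_times",
    "white_paper_perfusion",
]

#: default labelling efficiencies (consensus-paper values)
DEFAULT_ALPHA = {"pcasl": 0.85, "pasl": 0.98}


@dataclass
class TissueKineticParams:
    """Physiological parameters of the tissue compartment.

    ``f`` is perfusion in signal units per second (relative until calibrated);
    ``att`` the arterial transit time (s); ``tau`` the label duration (s);
    ``lambda_`` the blood-tissue water partition coefficient; ``alpha`` the
    labelling efficiency.
    """

    f: float
    att: float
    tau: float
    t1_tissue: float = 1.3
    t1_blood: float = 1.65
    lambda_: float = 0.9
    alpha: float = 0.85
    #: perfusion (s^-1) for the outflow term when f is in signal units;
    #: None means f itself is physiological and is used directly
    f_outflow: Optional[float] = None

    def __post_init__(self):
        if self.f < 0:
            raise ConfigurationError("perfusion f must be non-negative")
        if self.att < 0:
            raise ConfigurationError("att must be non-negative")
        if self.tau <= 0:
            raise ConfigurationError("label duration tau must be positive")
        for name in ("t1_tissue", "t1_blood"):
            v = getattr(self, name)
            if not 0 < v < 10:
                raise ConfigurationError(f"{name} must be in (0, 10) s")
        if not 0 < self.lambda_ <= 1.2:
            raise ConfigurationError("lambda_ must be in (0, 1.2]")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must be in (0, 1]")


@dataclass
class MacrovascularParams:
    """Arterial (macrovascular) component: blood volume fraction and arrival."""

    acbv: float
    bat: float

    def __post_init__(self):
        if self.acbv < 0 or self.bat < 0:
            raise ConfigurationError("acbv and bat must be non-negative")


@dataclass
class ModelConfig:
    """Model evaluation options.

    ``white_paper_mode`` reduces the model to the consensus-paper assumptions:
    transit time fixed at zero and the residue decaying at exactly the blood
    T1 rate (no outflow term), so inverting the single-PLD model reproduces
    the consensus quantification formula.
    """

    labelling: str = "pcasl"
    include_macrovascular: bool = False
    convolution: str = "analytic"
    numeric_dt: float = 0.1
    white_paper_mode: bool = False

    def __post_init__(self):
        if self.labelling not in ("pcasl", "pasl"):
            raise ConfigurationError(f"unknown labelling {self.labelling!r}")
        if self.convolution not in ("analytic", "numeric"):
            raise ConfigurationError(f"unknown convolution {self.convolution!r}")
        if self.numeric_dt <= 0:
            raise ConfigurationError("numeric_dt must be positive")


#: nominal physiological perfusion (s^-1, ~60 ml/100 g/min) used for the
#: venous-outflow term when the fitted amplitude is in raw signal units
NOMINAL_PHYS_PERFUSION = 0.01


def _app_rate(f, t1_tissue, t1_blood, lambda_, white_paper: bool,
              f_outflow=None):
    """Apparent relaxation rate of the tissue compartment.

    1/T1app = 1/T1_tissue + f/lambda. ``f_outflow`` supplies the perfusion
    value (s^-1) for the outflow term when ``f`` itself is in signal units;
    when None, ``f`` is assumed physiological and used directly.
    """
    if white_paper:
        return 1.0 / t1_blood
    if f_outflow is None:
        f_outflow = f
    return 1.0 / t1_tissue + f_outflow / lambda_


def tissue_curve(
    times: np.ndarray,
    f,
    att,
    tau,
    t1_tissue=1.3,
    t1_blood=1.65,
    lambda_=0.9,
    alpha=0.85,
    labelling: str = "pcasl",
    white_paper: bool = False,
    f_outflow=None,
) -> np.ndarray:
    """Vectorised analytic tissue difference signal (functional core).

    ``tau`` may be a scalar or an array matching ``times`` (per-volume label
    durations, as produced by Hadamard decoding). ``f_outflow`` optionally
    decouples the outflow term of the apparent rate from the amplitude ``f``
    (needed when ``f`` is in raw signal units); the signal is then exactly
    linear in ``f``.
    """
    t = np.asarray(times, dtype=float)
    tau = np.broadcast_to(np.asarray(tau, dtype=float), t.shape).copy()
    if np.any(tau <= 0):
        raise ConfigurationError("label duration tau must be positive")
    if white_paper:
        att = 0.0
    r = _app_rate(f, t1_tissue, t1_blood, lambda_, white_paper, f_outflow)
    during = (t >= att) & (t < att + tau)
    after = t >= att + tau
    sig = np.zeros_like(t)
    amp = 2.0 * alpha * f
    if labelling == "pcasl":
        # AIF amplitude constant at exp(-att/T1b) inside the bolus window
        pre = amp * np.exp(-att / t1_blood) / r
        sig[during] = pre * (1.0 - np.exp(-(t[during] - att) * r))
        sig[after] = (
            pre
            * (1.0 - np.exp(-tau[after] * r))
            * np.exp(-(t[after] - att - tau[after]) * r)
        )
    else:  # pasl: AIF decays as exp(-t/T1b) throughout the bolus
        k = 1.0 / t1_blood - r
        def integral(a, b):
            # int_a^b exp(-s k) ds, stable as k -> 0
            if abs(k) < 1e-12:
                return b - a
            return (np.exp(-a * k) - np.exp(-b * k)) / k
        sig[during] = amp * np.exp(-t[during] * r) * integral(att, t[during])
        end = att + tau[after]
        sig[after] = amp * np.exp(-t[after] * r) * integral(att, end)
    return sig


def tissue_signal(
    params: TissueKineticParams,
    times: Sequence[float],
    config: ModelConfig,
    taus=None,
) -> np.ndarray:
    """Expected tissue difference signal at each measurement time."""
    tau = params.tau if taus is None else taus
    if config.convolution == "numeric":
        return _tissue_numeric(params, np.asarray(times, float), config, tau)
    return tissue_curve(
        times,
        params.f,
        params.att,
        tau,
        params.t1_tissue,
        params.t1_blood,
        params.lambda_,
        params.alpha,
        labelling=config.labelling,
        white_paper=config.white_paper_mode,
        f_outflow=params.f_outflow,
    )


def arterial_curve(
    times: np.ndarray,
    acbv,
    bat,
    tau,
    t1_blood=1.65,
    alpha=0.85,
    labelling: str = "pcasl",
    edge_width: float = 0.0,
) -> np.ndarray:
    """Macrovascular difference signal: the AIF itself scaled by aCBV.

    ``edge_width`` > 0 replaces the hard box-car edges with logistic ramps of
    that width (seconds). The default is the exact box-car; inference uses a
    small smoothing so the signal is differentiable in ``bat``, which
    gradient-based fitting requires (a hard edge makes the linearised update
    unstable whenever a measurement time sits on the bolus boundary).
    """
    t = np.asarray(times, dtype=float)
    tau = np.broadcast_to(np.asarray(tau, dtype=float), t.shape)
    if edge_width > 0:
        window = _logistic((t - bat) / edge_width) * _logistic(
            (bat + tau - t) / edge_width
        )
    else:
        window = ((t >= bat) & (t <= bat + tau)).astype(float)
    if labelling == "pcasl":
        decay = np.exp(-bat / t1_blood)
    else:
        decay = np.exp(-t / t1_blood)
    return 2.0 * alpha * acbv * decay * window


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def macrovascular_signal(
    params: MacrovascularParams,
    kinetics: TissueKineticParams,
    times: Sequence[float],
    config: ModelConfig,
    taus=None,
) -> np.ndarray:
    """Expected arterial difference signal at each measurement time."""
    tau = kinetics.tau if taus is None else taus
    return arterial_curve(
        times,
        params.acbv,
        params.bat,
        tau,
        kinetics.t1_blood,
        kinetics.alpha,
        labelling=config.labelling,
    )


def numeric_convolve(
    aif: Callable[[np.ndarray], np.ndarray],
    residue: Callable[[np.ndarray], np.ndarray],
    times: Sequence[float],
    dt: float,
    breakpoints: Sequence[float] = (),
) -> np.ndarray:
    """Trapezium-rule convolution of an AIF with a residue function.

    Evaluates ``int_0^t aif(s) residue(t - s) ds`` for each requested time.
    ``breakpoints`` may list times at which the AIF is discontinuous (box-car
    edges); the integration grid is split there so each panel is smooth,
    preserving the trapezium rule's second-order accuracy.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    bps = sorted(b for b in breakpoints if b > 0)
    for i, t in enumerate(times):
        if t <= 0:
            continue
        edges = [0.0] + [b for b in bps if b < t] + [t]
        total = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            n = max(2, int(np.ceil((b - a) / dt)) + 1)
            s = np.linspace(a, b, n)
            # evaluate endpoints just inside the panel so a discontinuity at
            # a breakpoint takes its one-sided value
            s_eval = s.copy()
            nudge = 1e-9 * max(b - a, dt)
            s_eval[0] += nudge
            s_eval[-1] -= nudge
            total += np.trapezoid(aif(s_eval) * residue(t - s_eval), s)
        out[i] = total
    return out


def _tissue_numeric(params, times, config, tau):
    """Tissue signal via numerical convolution (single scalar tau only)."""
    tau = float(np.asarray(tau).reshape(-1)[0]) if np.ndim(tau) else float(tau)
    att = 0.0 if config.white_paper_mode else params.att
    r = _app_rate(
        params.f, params.t1_tissue, params.t1_blood, params.lambda_,
        config.white_paper_mode, params.f_outflow,
    )
    if config.labelling == "pcasl":
        def aif(s):
            return np.where(
                (s >= att) & (s <= att + tau), np.exp(-att / params.t1_blood), 0.0
            )
    else:
        def aif(s):
            return np.where(
                (s >= att) & (s <= att + tau), np.exp(-s / params.t1_blood), 0.0
            )
    def residue(u):
        return np.exp(-u * r)
    conv = numeric_convolve(aif, residue, times, config.numeric_dt,
                            breakpoints=(att, att + tau))
    return 2.0 * params.alpha * params.f * conv


def measurement_times(timing: ASLTimingSpec, series_kind: str = "differenced",
                      eff_pld=None, eff_ld=None):
    """Measurement times (from label onset) and per-volume label durations.

    Returns ``(times, taus)`` arrays, one entry per differenced/decoded
    volume in canonical delay-major order.
    """
    if series_kind == "decoded":
        pld = np.asarray(eff_pld, dtype=float)
        taus = np.asarray(eff_ld, dtype=float)
        times = taus + pld  # time-encoded labelling is pcasl-like
        return times, taus
    delays = np.repeat(np.asarray(timing.delays), timing.repeats_per_delay)
    taus = np.full_like(delays, timing.label_duration)
    if timing.labelling == "pcasl":
        times = taus + delays
    else:
        times = delays  # TI is measured from label onset already
    return times, taus


def full_model(
    tissue: TissueKineticParams,
    arterial: Optional[MacrovascularParams],
    timing: ASLTimingSpec,
    config: ModelConfig,
) -> np.ndarray:
    """Predicted differenced series (one value per differenced volume)."""
    times, taus = measurement_times(timing)
    sig = tissue_signal(tissue, times, config, taus=taus)
    if config.include_macrovascular:
        if arterial is None:
            raise ConfigurationError(
                "include_macrovascular requires MacrovascularParams"
            )
        sig = sig + macrovascular_signal(arterial, tissue, times, config, taus=taus)
    return sig


def white_paper_perfusion(mean_diff, pld, tau, t1_blood=1.65, alpha=0.85):
    """Consensus-formula perfusion (relative units) from a mean difference.

    f = dM * exp(PLD/T1b) / (2 * alpha * T1b * (1 - exp(-tau/T1b))), the
    single-PLD quantification formula under zero transit time and pure blood
    T1 decay. Calibration (division by M0a and the 6000 * lambda factor) is
    applied separately.
    """
    return (
        np.asarray(mean_diff, dtype=float)
        * np.exp(pld / t1_blood)
        / (2.0 * alpha * t1_blood * (1.0 - np.exp(-tau / t1_blood)))
    )
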