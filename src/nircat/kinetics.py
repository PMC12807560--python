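"""Rise-decay kinetic fits of evoked dF/F0 transients.

The transient model is the product of an exponential rise and decay,

    dFF(t) = A (1 - e^{-t/tau_on}) e^{-t/tau_off} + B,

with t in seconds from the stimulation frame.  Fits are nonlinear least
squares with tau_on and tau_off parameterized in log space (positivity
without hard bounds) and data-driven starting values.  Following the
field-of-view decay behaviour, fits whose decay constant exceeds 10 s are
flagged ``excluded`` and contribute no tau_off to slice-level metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .synthetic import transient

__all__ = ["KineticsFit", "fit_kinetics", "peak_time_and_value", "TAU_OFF_MAX_S"]

#: Decay constants above this (seconds) are excluded from slice metrics.
TAU_OFF_MAX_S = 10.0


@dataclass
class KineticsFit:
    A: float
    B: float
    tau_on_s: float
    tau_off_s: float
    rss: float
    converged: bool
    excluded: bool
    exclusion_reason: str = ""
    degenerate: bool = False
    n_points: int = 0

    def model(self, t_s: np.ndarray) -> np.ndarray:
        return transient(np.asarray(t_s, float), self.A, self.tau_on_s, self.tau_off_s, self.B)


def _initial_guess(t: np.ndarray, y: np.ndarray, baseline_tail: float) -> np.ndarray:
    """Data-driven starts: B from the late-baseline dF/F0, A from the peak,
    tau_off from the 1/e post-peak fall time, tau_on from the half-rise time."""
    b0 = baseline_tail
    i_pk = int(np.argmax(y))
    a0 = max(float(y[i_pk] - b0), 1e-6)
    # decay start: first post-peak time where y falls below b0 + a0/e
    target = b0 + a0 / math.e
    post = np.nonzero(y[i_pk:] < target)[0]
    if post.size:
        tau_off0 = max(float(t[i_pk + post[0]] - t[i_pk]), 1e-3)
    else:
        tau_off0 = max(float(t[-1] - t[i_pk]), 1e-3)
    # rise: first time reaching half of the peak
    half = b0 + a0 / 2.0
    pre = np.nonzero(y[: i_pk + 1] >= half)[0]
    tau_on0 = max(float(t[pre[0]]), 1e-3) if pre.size else max(float(t[min(1, len(t) - 1)]), 1e-3)
    return np.array([a0, b0, math.log(tau_on0), math.log(tau_off0)])


def fit_kinetics(
    dff_trace: np.ndarray,
    stim_frame: int,
    frame_rate: float,
    tau_off_max_s: float = TAU_OFF_MAX_S,
    max_iter: int = 500,
) -> KineticsFit:
    """Fit the transient model to one dF/F0 trace.

    Only frames at/after stimulation enter the fit (t = 0 at the stimulation
    frame).  Non-convergence is reported via ``converged=False`` rather than
    raised; an (almost) all-zero trace is flagged ``degenerate``.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    dff_trace = np.asarray(dff_trace, dtype=float)
    y = dff_trace[stim_frame:]
    if y.size < 20:
        raise ValueError(f"need >= 20 post-stimulation frames, got {y.size}")
    t = np.arange(y.size) / frame_rate

    if np.allclose(y, 0.0, atol=1e-12) or np.ptp(y) < 1e-12:
        return KineticsFit(
            A=0.0, B=float(y.mean()) if y.size else 0.0, tau_on_s=float("nan"),
            tau_off_s=float("nan"), rss=0.0, converged=False, excluded=False,
            exclusion_reason="", degenerate=True, n_points=int(y.size),
        )

    baseline_tail = float(dff_trace[max(0, stim_frame - 5) : stim_frame].mean()) if stim_frame > 0 else 0.0
    x0 = _initial_guess(t, y, baseline_tail)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, lton, ltoff = theta
        return transient(t, a, math.exp(lton), math.exp(ltoff), b) - y

    def jac(theta: np.ndarray) -> np.ndarray:
        a, b, lton, ltoff = theta
        tau_on, tau_off = math.exp(lton), math.exp(ltoff)
        rise = 1.0 - np.exp(-t / tau_on)
        decay = np.exp(-t / tau_off)
        J = np.empty((t.size, 4))
        J[:, 0] = rise * decay
        J[:, 1] = 1.0
        # derivatives w.r.t. log tau: chain rule multiplies by tau
        J[:, 2] = -a * (t / tau_on) * np.exp(-t / tau_on) * decay
        J[:, 3] = a * rise * decay * (t / tau_off)
        return J

    try:
        sol = least_squares(
            residuals, x0, jac=jac, method="trf",
            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=max_iter * 5,
        )
        converged = bool(sol.success)
        a, b, lton, ltoff = sol.x
        rss = float(2.0 * sol.cost)
    except Exception:  # pragma: no cover - optimizer failure path
        a, b, lton, ltoff = x0
        rss = float(np.sum(residuals(x0) ** 2))
        converged = False

    tau_on = math.exp(lton)
    tau_off = math.exp(ltoff)
    excluded = tau_off > tau_off_max_s
    return KineticsFit(
        A=float(a),
        B=float(b),
        tau_on_s=float(tau_on),
        tau_off_s=float(tau_off),
        rss=rss,
        converged=converged,
        excluded=bool(excluded),
        exclusion_reason=f"tau_off {tau_off:.3f} s > {tau_off_max_s} s" if excluded else "",
        degenerate=False,
        n_points=int(y.size),
    )


def peak_time_and_value(fit: KineticsFit) -> tuple[float, float]:
    """Analytic peak of the fitted transient.

    The model's maximum over t >= 0 is at t* = tau_on ln(1 + tau_off/tau_on);
    the value is the model evaluated there.
    """
    if not fit.converged:
        raise ValueError("peak is only defined for converged fits")
    t_star = fit.tau_on_s * math.log(1.0 + fit.tau_off_s / fit.tau_on_s)
    value = float(fit.model(np.array([t_star]))[0])
    return t_star, value


def fit_traces(
    traces: Sequence, stim_frame: int, frame_rate: float, tau_off_max_s: float = TAU_OFF_MAX_S
) -> dict[int, KineticsFit]:
    """Fit every trace in a sequence of RoiTrace; keyed by roi_index."""
    return {
        tr.roi_index: fit_kinetics(tr.dff, stim_frame, frame_rate, tau_off_max_s) for tr in traces
    }
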