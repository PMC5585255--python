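"""Binding and electrophysiology assay processing.

Covers four measurement types:

* **Microscale thermophoresis (MST)** — fluorescence time traces are reduced
  to F_norm = ⟨F⟩_hot / ⟨F⟩_cold, differenced against the lowest-ligand
  condition to give ΔF_norm, and the titration fitted with a 1:1 binding
  isotherm.  The default model is exact mass action (quadratic form) with
  total protein fixed (20 nM by default); the simple hyperbola
  ΔF = baseline + amplitude·c/(Kd + c) is retained for comparison — at
  protein ≪ Kd the two agree.
* **Ratiometric calcium imaging** — response size as the trapezoidal area
  under the baseline-subtracted normalized fura-2 ratio.
* **Voltage-ramp whole-cell recording** — current density (pA/pF) at a
  reference voltage (+100 mV by default), interpolated on the ramp.
* **Gap-free single-channel recording** — NPo (number of channels × open
  probability) by half-amplitude threshold idealization around the
  modal (closed) current level.

A titration whose amplitude is statistically indistinguishable from zero is
flagged unidentifiable and no Kd is reported — a flat curve is never
force-fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import (
    ConfigurationError,
    FitError,
    IdealizationError,
    WindowingError,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MSTTrace:
    """One thermophoresis time trace at a single ligand concentration."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    ir_on_s: float
    ir_off_s: float
    concentration_uM: float
    replicate: int = 0

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("trace time must be strictly increasing")
        if not self.ir_on_s < self.ir_off_s:
            raise ConfigurationError("ir_on_s must precede ir_off_s")


@dataclass(frozen=True)
class TitrationCurve:
    """ΔF_norm versus ligand concentration (µM), with replicate labels."""

    concentration_uM: np.ndarray
    delta_fnorm: np.ndarray
    replicate: np.ndarray
    protein_conc_nM: float = 20.0

    def __post_init__(self):
        c = np.asarray(self.concentration_uM, dtype=float)
        if np.any(c <= 0):
            raise ConfigurationError("concentrations must be positive")


@dataclass(frozen=True)
class BindingFit:
    """Result of a 1:1 isotherm fit; ``kd_uM`` is None when unidentifiable."""

    model: str
    kd_uM: float | None
    amplitude: float
    baseline: float
    kd_se_uM: float | None
    amplitude_se: float | None
    baseline_se: float | None
    converged: bool
    identifiable: bool
    message: str = ""


@dataclass(frozen=True)
class CalciumTrace:
    """Normalized fura-2 340/380 ratio (baseline ≈ 1 before stimulation)."""

    time_s: np.ndarray
    ratio: np.ndarray
    stimulus_window: tuple[float, float]


@dataclass(frozen=True)
class RampRecording:
    voltage_mV: np.ndarray
    current_pA: np.ndarray
    capacitance_pF: float


@dataclass(frozen=True)
class GapFreeRecording:
    time_s: np.ndarray
    current_pA: np.ndarray
    single_channel_pA: float


# ---------------------------------------------------------------------------
# MST processing
# ---------------------------------------------------------------------------

def normalize_thermophoresis(
    trace: MSTTrace,
    cold_window: tuple[float, float] | None = None,
    hot_window: tuple[float, float] | None = None,
) -> float:
    """F_norm = mean fluorescence in the hot window / mean in the cold window.

    Defaults: cold = 5 s immediately before IR-on, hot = last 5 s before
    IR-off.
    """
    if cold_window is None:
        cold_window = (trace.ir_on_s - 5.0, trace.ir_on_s)
    if hot_window is None:
        hot_window = (trace.ir_off_s - 5.0, trace.ir_off_s)
    if cold_window[0] >= cold_window[1] or hot_window[0] >= hot_window[1]:
        raise WindowingError("windows must have positive width")
    if cold_window[1] > trace.ir_on_s + 1e-12:
        raise WindowingError("cold window must end at or before IR-on")
    if hot_window[0] < trace.ir_on_s - 1e-12 or hot_window[1] > trace.ir_off_s + 1e-12:
        raise WindowingError("hot window must lie inside the IR-on interval")
    t = np.asarray(trace.time_s, dtype=float)
    f = np.asarray(trace.fluorescence, dtype=float)
    cold = f[(t >= cold_window[0]) & (t < cold_window[1])]
    hot = f[(t >= hot_window[0]) & (t < hot_window[1])]
    if cold.size == 0 or hot.size == 0:
        raise WindowingError("a normalization window contains no samples")
    cold_mean = cold.mean()
    if cold_mean == 0:
        raise WindowingError("cold-window mean fluorescence is zero")
    return float(hot.mean() / cold_mean)


def build_titration_curve(
    traces,
    cold_window: tuple[float, float] | None = None,
    hot_window: tuple[float, float] | None = None,
    protein_conc_nM: float = 20.0,
) -> TitrationCurve:
    """ΔF_norm per concentration, referenced to each replicate's lowest
    concentration and averaged across replicates."""
    seen: set[tuple[float, int]] = set()
    by_rep: dict[int, list[tuple[float, float]]] = {}
    for tr in traces:
        key = (tr.concentration_uM, tr.replicate)
        if key in seen:
            raise ConfigurationError(
                f"duplicate concentration {tr.concentration_uM} µM in replicate {tr.replicate}"
            )
        seen.add(key)
        fnorm = normalize_thermophoresis(tr, cold_window, hot_window)
        by_rep.setdefault(tr.replicate, []).append((tr.concentration_uM, fnorm))

    per_conc: dict[float, list[float]] = {}
    for rep, points in by_rep.items():
        points.sort()
        ref = points[0][1]  # F_norm at the lowest concentration
        for c, fn in points:
            per_conc.setdefault(c, []).append(fn - ref)
    concs = np.array(sorted(per_conc))
    if concs.size < 4:
        raise ConfigurationError("a titration needs at least 4 distinct concentrations")
    dfn = np.array([np.mean(per_conc[c]) for c in concs])
    return TitrationCurve(concs, dfn, np.zeros(concs.size, dtype=int), protein_conc_nM)


# ---------------------------------------------------------------------------
# Binding isotherm fitting
# ---------------------------------------------------------------------------

def mass_action_bound_fraction(conc_uM, kd_uM: float, protein_uM: float) -> np.ndarray:
    """Fraction of protein bound under exact 1:1 mass action.

    Solves the quadratic for the complex with total ligand L, total protein P:
    bound = (P + L + Kd − sqrt((P + L + Kd)² − 4·P·L)) / (2P).
    """
    L = np.asarray(conc_uM, dtype=float)
    P = float(protein_uM)
    s = P + L + kd_uM
    disc = np.maximum(s * s - 4.0 * P * L, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * P)


def _model_response(conc, log_kd, amplitude, baseline, model, protein_uM):
    kd = math.exp(log_kd)
    if model == "mass_action":
        fb = mass_action_bound_fraction(conc, kd, protein_uM)
    else:  # hyperbola
        fb = conc / (kd + conc)
    return baseline + amplitude * fb


def fit_binding_isotherm(curve: TitrationCurve, model: str = "mass_action") -> BindingFit:
    """Nonlinear least-squares 1:1 isotherm fit with multi-start Kd grid.

    Parameters are (Kd, amplitude, baseline); Kd is searched in log space
    from a grid spanning [min(c)/10, max(c)×10].  Standard errors come from
    the Gauss–Newton covariance at the optimum.  If the amplitude's 95% CI
    spans zero (or the response is flat to machine precision) the fit is
    flagged unidentifiable and no Kd is reported.
    """
    if model not in ("mass_action", "hyperbola"):
        raise ConfigurationError(f"unknown model {model!r}")
    conc = np.asarray(curve.concentration_uM, dtype=float)
    y = np.asarray(curve.delta_fnorm, dtype=float)
    if np.unique(conc).size < 4:
        raise ConfigurationError("need ≥ 4 distinct concentrations to fit")
    protein_uM = curve.protein_conc_nM / 1000.0

    span = float(y.max() - y.min())
    scale = max(np.abs(y).max(), 1.0)
    if span <= 1e-12 * scale:
        return BindingFit(model, None, 0.0, float(y.mean()), None, None, None,
                          True, False, "flat response: Kd unidentifiable")

    def residuals(p):
        return _model_response(conc, p[0], p[1], p[2], model, protein_uM) - y

    amp0 = y[np.argmax(conc)] - y[np.argmin(conc)]
    best = None
    for kd0 in np.geomspace(conc.min() / 10.0, conc.max() * 10.0, 7):
        try:
            res = optimize.least_squares(
                residuals,
                x0=[math.log(kd0), amp0 if amp0 != 0 else span, y[np.argmin(conc)]],
                method="lm",
                max_nfev=2000,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost - 1e-15):
            best = res
    if best is None:
        raise FitError("isotherm fit did not converge from any start")

    log_kd, amplitude, baseline = best.x
    kd = math.exp(log_kd)
    n, p = conc.size, 3
    dof = max(n - p, 1)
    s2 = 2.0 * best.cost / dof
    JtJ = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(JtJ) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        kd_se = kd * se[0]  # delta method from log Kd
        amp_se, base_se = se[1], se[2]
    except np.linalg.LinAlgError:
        kd_se = amp_se = base_se = None

    identifiable = True
    message = ""
    if amp_se is not None and abs(amplitude) <= 1.96 * amp_se:
        identifiable = False
        message = "amplitude 95% CI spans zero: Kd unidentifiable"
    elif abs(amplitude) < 3.0 * math.sqrt(s2):
        # a genuine binding amplitude must clear the residual noise floor
        identifiable = False
        message = "amplitude within the residual noise floor: Kd unidentifiable"
    if kd > conc.max() * 10.0 * 0.999:
        identifiable = False
        message = "Kd at the search boundary: outside the tested concentration range"
    if not identifiable:
        return BindingFit(model, None, float(amplitude), float(baseline),
                          None, amp_se, base_se, True, False, message)
    return BindingFit(model, float(kd), float(amplitude), float(baseline),
                      kd_se, amp_se, base_se, True, True, message)


# ---------------------------------------------------------------------------
# Calcium imaging
# ---------------------------------------------------------------------------

def calcium_response_auc(
    trace: CalciumTrace,
    baseline_window: tuple[float, float] | None = None,
    response_window: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal area (ratio·s) above the mean baseline over the response
    window.  Defaults: baseline = everything before stimulus onset, response
    = the stimulus window.  May be negative."""
    t = np.asarray(trace.time_s, dtype=float)
    r = np.asarray(trace.ratio, dtype=float)
    if baseline_window is None:
        baseline_window = (float(t[0]), trace.stimulus_window[0])
    if response_window is None:
        response_window = trace.stimulus_window
    if baseline_window[1] > response_window[0] + 1e-12:
        raise WindowingError("baseline window must precede the response window")
    base_mask = (t >= baseline_window[0]) & (t < baseline_window[1])
    resp_mask = (t >= response_window[0]) & (t <= response_window[1])
    if not base_mask.any() or not resp_mask.any():
        raise WindowingError("a window contains no samples")
    baseline = r[base_mask].mean()
    return float(np.trapezoid(r[resp_mask] - baseline, t[resp_mask]))


# ---------------------------------------------------------------------------
# Patch clamp
# ---------------------------------------------------------------------------

def ramp_current_density(rec: RampRecording, at_voltage_mV: float = 100.0) -> float:
    """Current density (pA/pF) at a voltage on the ramp, by linear
    interpolation."""
    if rec.capacitance_pF <= 0:
        raise ConfigurationError("capacitance must be > 0")
    v = np.asarray(rec.voltage_mV, dtype=float)
    i = np.asarray(rec.current_pA, dtype=float)
    if not (v.min() - 1e-9 <= at_voltage_mV <= v.max() + 1e-9):
        raise ConfigurationError(f"{at_voltage_mV} mV is outside the ramp span")
    current = float(np.interp(at_voltage_mV, v, i))
    return current / rec.capacitance_pF


def estimate_npo(rec: GapFreeRecording, min_baseline_fraction: float = 0.05) -> float:
    """NPo = Σ_k k · (dwell fraction at level k).

    The closed baseline is the most-closed dominant mode of the all-points
    current histogram (the lowest-current bin holding at least
    ``min_baseline_fraction`` of the samples, refined to the local sample
    mean); samples are then idealized to integer levels by half-amplitude
    thresholds at (k − ½)·i_single above baseline.  For an ideal trace this
    reduces to mean(baseline-subtracted current)/i_single.
    """
    i = np.asarray(rec.current_pA, dtype=float)
    amp = abs(rec.single_channel_pA)
    if amp == 0:
        raise ConfigurationError("single_channel_pA must be nonzero")
    sign = 1.0 if rec.single_channel_pA > 0 else -1.0
    x = i * sign  # open levels are now above baseline
    bin_w = amp / 4.0
    edges = np.arange(x.min() - bin_w, x.max() + 2 * bin_w, bin_w)
    hist, _ = np.histogram(x, bins=edges)
    dominant = np.flatnonzero(hist >= min_baseline_fraction * x.size)
    if dominant.size == 0:
        raise IdealizationError("no dominant closed-level mode in the histogram")
    b = int(dominant[0])  # most-closed dominant bin
    center = 0.5 * (edges[b] + edges[b + 1])
    near = np.abs(x - center) <= 0.5 * bin_w + 1e-12
    baseline = x[near].mean()
    levels = np.maximum(np.round((x - baseline) / amp), 0.0)
    return float(levels.mean())
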