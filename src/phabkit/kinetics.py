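"""1:1 Langmuir binding kinetics for biolayer interferometry, plus ELISA
standard-curve and dose-response utilities.

The 1:1 model: during association at analyte concentration C,

    R(t) = Req * (1 - exp(-(ka*C + kd) * t)),   Req = Rmax * C / (C + KD)

and during dissociation starting from response R0,

    R(t) = R0 * exp(-kd * (t - t0)),

with KD = kd/ka.  Fitting is global nonlinear least squares over all phases
and traces sharing (ka, kd, Rmax), initialized from a log-linear regression
of the dissociation tail (kd) and a kobs regression across concentrations
(ka), with deterministic perturbation restarts.

Bivalent formats (IgG) give avidity-inflated apparent affinities; this
module fits the monovalent 1:1 model only and reports what the data show.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class Sensorgram:
    """One BLI trace: association then dissociation at one analyte concentration."""

    time: np.ndarray          # s, strictly increasing
    response: np.ndarray      # nm shift
    concentration: float      # M
    t_assoc_end: float        # s, phase boundary

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        if t.shape != r.shape:
            raise ValueError("time and response must have the same shape")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")

    @property
    def association_mask(self) -> np.ndarray:
        return self.time <= self.t_assoc_end

    @property
    def dissociation_mask(self) -> np.ndarray:
        return self.time > self.t_assoc_end


@dataclass(frozen=True)
class KineticFit:
    """Fitted 1:1 parameters; KD is kd/ka by construction."""

    ka: float          # 1/(M s)
    kd: float          # 1/s
    rmax: float        # response units
    residual_rms: float
    n_points: int

    def __post_init__(self):
        if min(self.ka, self.kd, self.rmax) <= 0:
            raise ValueError("ka, kd and Rmax must be positive")

    @property
    def KD(self) -> float:
        return self.kd / self.ka


def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant KD = kd / ka (M)."""
    if ka <= 0 or kd <= 0:
        raise ValueError("rate constants must be positive")
    return kd / ka


def fold_improvement(kd_reference: float, kd_variant: float) -> float:
    """Affinity fold improvement of a variant over a reference: KD_ref / KD_var."""
    if kd_reference <= 0 or kd_variant <= 0:
        raise ValueError("KD values must be positive")
    return kd_reference / kd_variant


def model_response(
    t: np.ndarray, ka: float, kd: float, rmax: float, conc: float, t_assoc_end: float
) -> np.ndarray:
    """Noiseless 1:1 response over a time grid spanning both phases."""
    t = np.asarray(t, dtype=float)
    kobs = ka * conc + kd
    req = rmax * conc / (conc + kd / ka)
    r = np.where(
        t <= t_assoc_end,
        req * (1.0 - np.exp(-kobs * t)),
        req * (1.0 - math.exp(-kobs * t_assoc_end)) * np.exp(-kd * (t - t_assoc_end)),
    )
    return r


def simulate_sensorgram(
    ka: float,
    kd: float,
    concentration: float,
    rmax: float = 1.0,
    t_assoc: float = 300.0,
    t_dissoc: float = 600.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    sampling_hz: float = 2.0,
) -> Sensorgram:
    """Simulate one 1:1 sensorgram with optional seeded Gaussian noise."""
    if min(ka, kd, concentration, rmax, t_assoc, t_dissoc) <= 0:
        raise ValueError("all kinetic parameters must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_a = int(round(t_assoc * sampling_hz))
    n_d = int(round(t_dissoc * sampling_hz))
    t = np.concatenate(
        [np.linspace(0.0, t_assoc, n_a + 1),
         t_assoc + np.linspace(0.0, t_dissoc, n_d + 1)[1:]]
    )
    r = model_response(t, ka, kd, rmax, concentration, t_assoc)
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(time=t, response=r, concentration=concentration, t_assoc_end=t_assoc)


def _initial_guess(traces: list[Sensorgram]) -> tuple[float, float, float]:
    """kd from the log-linear dissociation tail, ka from a kobs regression."""
    kds, kobs_pairs, rmax0 = [], [], 0.0
    for tr in traces:
        rmax0 = max(rmax0, float(np.max(np.abs(tr.response))))
        dm = tr.dissociation_mask
        td, rd = tr.time[dm], tr.response[dm]
        pos = rd > 1e-9 * max(1.0, rmax0)
        if pos.sum() >= 3:
            slope, _, _, _, _ = stats.linregress(td[pos], np.log(rd[pos]))
            if slope < 0:
                kds.append(-slope)
        am = tr.association_mask
        ta, ra = tr.time[am], tr.response[am]
        req = float(np.max(ra)) if len(ra) else 0.0
        resid = req - ra
        ok = resid > 1e-6 * max(req, 1e-12)
        if ok.sum() >= 3 and req > 0:
            slope, _, _, _, _ = stats.linregress(ta[ok], np.log(resid[ok]))
            if slope < 0:
                kobs_pairs.append((tr.concentration, -slope))
    kd0 = float(np.median(kds)) if kds else 1e-3
    if len(kobs_pairs) >= 2:
        conc = np.array([c for c, _ in kobs_pairs])
        kobs = np.array([k for _, k in kobs_pairs])
        ka0 = float(max(np.polyfit(conc, kobs, 1)[0], 1.0))
    elif kobs_pairs:
        c, k = kobs_pairs[0]
        ka0 = max((k - kd0) / c, 1.0)
    else:
        ka0 = 1e5
    return ka0, kd0, max(rmax0, 1e-6)


def fit_kinetics(
    traces: list[Sensorgram] | Sensorgram, n_restarts: int = 3
) -> KineticFit:
    """Global 1:1 fit of (ka, kd, Rmax) shared across traces.

    Deterministic restarts perturb the initial guess by factors of 10 in
    alternating directions; non-convergence after all restarts raises with
    the best-so-far parameters attached to the exception.
    """
    if isinstance(traces, Sensorgram):
        traces = [traces]
    if not traces:
        raise ValueError("at least one trace is required")
    all_r = np.concatenate([tr.response for tr in traces])
    n_points = all_r.size
    if float(np.max(np.abs(all_r))) < 1e-12:
        raise ValueError("no signal: traces are identically zero")

    def residuals(logp: np.ndarray) -> np.ndarray:
        # clip keeps the optimizer's exploratory steps finite
        ka, kd, rmax = np.exp(np.clip(logp, -45.0, 45.0))
        out = []
        with np.errstate(over="ignore", invalid="ignore"):
            for tr in traces:
                out.append(
                    tr.response
                    - model_response(tr.time, ka, kd, rmax, tr.concentration, tr.t_assoc_end)
                )
        return np.nan_to_num(np.concatenate(out), nan=1e6, posinf=1e6, neginf=-1e6)

    ka0, kd0, rmax0 = _initial_guess(traces)
    best = None
    perturbations = [1.0, 10.0, 0.1, 100.0][: n_restarts + 1]
    for fac in perturbations:
        x0 = np.log([ka0 * fac, kd0, rmax0])
        try:
            sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("kinetic fit failed to converge")
    ka, kd, rmax = np.exp(best.x)
    rms = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return KineticFit(ka=float(ka), kd=float(kd), rmax=float(rmax),
                      residual_rms=rms, n_points=n_points)


# ---------------------------------------------------------------------------
# ELISA utilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """Linear-range standard curve: absorbance = slope * concentration + intercept."""

    concentrations: np.ndarray
    absorbances: np.ndarray
    linear_range: tuple[int, int]   # inclusive index range into the point list
    slope: float
    intercept: float
    r_squared: float

    @property
    def absorbance_range(self) -> tuple[float, float]:
        lo, hi = self.linear_range
        vals = self.absorbances[lo: hi + 1]
        return float(np.min(vals)), float(np.max(vals))


def fit_standard_curve(points, min_r2: float = 0.98) -> StandardCurve:
    """Select the longest contiguous linear range (>= 3 points, R^2 >= min_r2).

    Points are (concentration, absorbance) pairs sorted by concentration.
    Ties in length are broken toward the higher R^2.
    """
    pts = sorted((float(c), float(a)) for c, a in points)
    if len(pts) < 4:
        raise ValueError("at least 4 standards are required")
    conc = np.array([c for c, _ in pts])
    absb = np.array([a for _, a in pts])
    best = None
    for lo in range(len(pts)):
        for hi in range(lo + 2, len(pts)):
            x, y = conc[lo: hi + 1], absb[lo: hi + 1]
            res = stats.linregress(x, y)
            r2 = res.rvalue**2
            if r2 >= min_r2:
                key = (hi - lo + 1, r2)
                if best is None or key > best[0]:
                    best = (key, lo, hi, res)
    if best is None:
        raise ValueError(f"no contiguous run of >= 3 standards reaches R^2 >= {min_r2}")
    _, lo, hi, res = best
    return StandardCurve(
        concentrations=conc, absorbances=absb, linear_range=(lo, hi),
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


@dataclass(frozen=True)
class ConcentrationEstimate:
    concentration: float | None   # None when out of the linear range
    in_range: bool
    absorbance: float
    dilution_factor: float


def estimate_concentration(
    curve: StandardCurve, absorbance: float, dilution_factor: float = 1.0
) -> ConcentrationEstimate:
    """Interpolate an unknown on the linear range, scaled back to the undiluted sample.

    Unknowns whose absorbance falls outside the linear detection range are
    flagged rather than extrapolated.
    """
    lo, hi = curve.absorbance_range
    if not (lo <= absorbance <= hi):
        return ConcentrationEstimate(None, False, absorbance, dilution_factor)
    conc = (absorbance - curve.intercept) / curve.slope
    return ConcentrationEstimate(conc * dilution_factor, True, absorbance, dilution_factor)


def sensorgrams_to_frame(traces: list[Sensorgram]):
    """Long-format table (trace, time, response, phase, concentration)."""
    import pandas as pd

    rows = []
    for k, tr in enumerate(traces):
        phases = np.where(tr.association_mask, "association", "dissociation")
        rows.append(
            pd.DataFrame(
                {
                    "trace": k,
                    "time": tr.time,
                    "response": tr.response,
                    "phase": phases,
                    "concentration": tr.concentration,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_sensorgrams(df) -> list[Sensorgram]:
    """Inverse of :func:`sensorgrams_to_frame` (groups by trace id)."""
    traces = []
    key = "trace" if "trace" in df.columns else "concentration"
    for _, grp in df.groupby(key, sort=True):
        grp = grp.sort_values("time")
        assoc = grp[grp["phase"] == "association"]
        if assoc.empty:
            raise ValueError("trace has no association phase")
        traces.append(
            Sensorgram(
                time=grp["time"].to_numpy(float),
                response=grp["response"].to_numpy(float),
                concentration=float(grp["concentration"].iloc[0]),
                t_assoc_end=float(assoc["time"].max()),
            )
        )
    return traces


def four_pl(x: np.ndarray, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    """4-parameter logistic dose response."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / np.maximum(x, 1e-300)) ** hill)


def fit_4pl(doses, responses) -> dict:
    """Least-squares 4PL fit; EC50 is returned on the concentration scale."""
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) < 5:
        raise ValueError("at least 5 doses are required")
    if np.ptp(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        raise ValueError("no dose-response transition: response is constant")
    bottom0, top0 = float(np.min(y)), float(np.max(y))
    half = bottom0 + 0.5 * (top0 - bottom0)
    ec50_0 = float(x[np.argmin(np.abs(y - half))])

    def model(x, bottom, top, log_ec50, hill):
        return four_pl(x, bottom, top, np.exp(log_ec50), hill)

    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=[bottom0, top0, np.log(ec50_0), 1.0], maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(f"4PL fit failed to converge: {exc}") from exc
    bottom, top, log_ec50, hill = popt
    pred = model(x, *popt)
    rms = float(np.sqrt(np.mean((y - pred) ** 2)))
    return {
        "bottom": float(bottom), "top": float(top),
        "ec50": float(np.exp(log_ec50)), "hill": float(hill),
        "residual_rms": rms,
    }
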