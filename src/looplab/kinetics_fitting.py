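"""Kinetic model fits for correlation curves.

Two-state model
---------------
Assuming an all-or-none transition between the fluorescent (open) and
quenched (closed) states, the normalised autocorrelation is

    G(tau) = 1 + (1/K) exp(-tau / tau_r),

where K = [open]/[closed] is the equilibrium constant and tau_r the mean
relaxation time.  Mean closing and opening times follow from

    tau_c = tau_r (1 + K),      tau_o = tau_r (1 + K) / K,

so that 1/tau_r = 1/tau_c + 1/tau_o and the open-state population is
fraction_open = K/(1+K) = tau_c/(tau_c+tau_o).  The reciprocal convention
K = [closed]/[open] is available via ``k_convention="closed_over_open"``.

Multi-exponential model
-----------------------
Beyond a short-time window (default 3 ps) curves are fitted with

    f(t) = baseline + A1 exp[-(t/tau1)^beta] + sum_i Ai exp(-t/tau_i),

a stretched-exponential picosecond component plus one or two nanosecond
exponentials; ``auto`` mode chooses 1 vs 2 by small-sample corrected AIC.
Fits with correlation coefficient <= 0.95 are flagged, not rejected.

Scaling law
-----------
Loop-closure rates of random-coil chains follow k ~ n^gamma in the number
of peptide bonds n, with gamma between -1.5 and -2.1 for Gaussian chains;
``fit_powerlaw`` estimates gamma by OLS of ln k on ln n.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .correlation import CorrelationCurve
from .errors import FitError, InputError, NoRelaxationError, ParameterError
from .state_signal import StateSeries

__all__ = [
    "TwoStateFit",
    "MultiExpFit",
    "ExpComponent",
    "StretchedComponent",
    "HBondLifetimeFit",
    "ScalingFit",
    "derive_times",
    "invert_times",
    "fit_two_state",
    "fit_multiexp",
    "fit_hbond_lifetime",
    "fit_powerlaw",
    "split_half_errors",
    "load_labelled_time_constants",
]

#: default two-state fit window in ns (the experimentally resolvable range)
TWO_STATE_WINDOW = (6.0, 300.0)
#: default start of the multi-exponential window, ns (= 3 ps)
MULTIEXP_WINDOW_START = 0.003
#: quality gate on the fit correlation coefficient
R_QUALITY_GATE = 0.95


# ---------------------------------------------------------------------------
# two-state algebra
# ---------------------------------------------------------------------------

def derive_times(K: float, tau_r: float) -> tuple[float, float, float]:
    """(tau_c, tau_o, fraction_open) from the equilibrium constant and tau_r."""
    if K <= 0 or tau_r <= 0:
        raise ParameterError("K and tau_r must be positive")
    tau_c = tau_r * (1.0 + K)
    tau_o = tau_r * (1.0 + K) / K
    return tau_c, tau_o, K / (1.0 + K)


def invert_times(tau_c: float, tau_o: float) -> tuple[float, float]:
    """(K, tau_r) from the closing and opening times; inverse of derive_times."""
    if tau_c <= 0 or tau_o <= 0:
        raise ParameterError("times must be positive")
    K = tau_c / tau_o
    tau_r = 1.0 / (1.0 / tau_c + 1.0 / tau_o)
    return K, tau_r


@dataclass
class TwoStateFit:
    K: float
    tau_r: float  # ns
    tau_c: float  # ns
    tau_o: float  # ns
    fraction_open: float
    window: tuple[float, float]
    r_correlation: float
    errors: dict[str, float] = field(default_factory=dict)
    method: str = "least_squares"

    def as_dict(self) -> dict:
        return {
            "model": "two_state",
            "K": self.K, "tau_r_ns": self.tau_r,
            "tau_c_ns": self.tau_c, "tau_o_ns": self.tau_o,
            "fraction_open": self.fraction_open,
            "window_ns": list(self.window),
            "r_correlation": self.r_correlation,
            "errors": self.errors, "method": self.method,
        }


def _pearson(y: np.ndarray, yfit: np.ndarray) -> float:
    if np.ptp(yfit) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(y, yfit)[0, 1])


def fit_two_state(
    curve: CorrelationCurve,
    window: tuple[float, float] = TWO_STATE_WINDOW,
    k_convention: str = "open_over_closed",
    series: StateSeries | None = None,
) -> TwoStateFit:
    """Least-squares fit of G(tau) = 1 + (1/K) exp(-tau/tau_r) inside ``window``.

    Raises :class:`NoRelaxationError` when the amplitude is statistically
    indistinguishable from zero (no detectable process in the window).  When
    the generating ``series`` is supplied, split-half errors on tau_c/tau_o
    are added to the covariance-based ones.
    """
    if k_convention not in ("open_over_closed", "closed_over_open"):
        raise ParameterError(f"unknown K convention {k_convention!r}")
    sub = curve.restrict(*window)
    if sub.n < 6:
        raise InputError(f"need >= 6 lag points inside the window, have {sub.n}")
    t, y = sub.lags, sub.values
    amp0 = float(y[0] - 1.0)
    span = float(np.ptp(y))
    if amp0 <= 0 or span < 1e-12:
        raise NoRelaxationError("no positive-amplitude decay in the fit window")

    # initial tau from the lag at which the excess correlation halves
    excess = y - 1.0
    below = np.flatnonzero(excess <= amp0 / 2.0)
    tau0 = float(t[below[0]]) if below.size else float(t[-1] / 2.0)
    tau0 = max(tau0, float(t[0]))

    model = lmfit.Model(lambda tau, amp, tau_r: 1.0 + amp * np.exp(-tau / tau_r))
    params = model.make_params(amp=max(amp0, 1e-6), tau_r=tau0)
    params["amp"].min = 0.0
    params["tau_r"].min = t[0] * 1e-3
    try:
        res = model.fit(y, params, tau=t)
    except Exception as exc:
        raise FitError(f"two-state fit failed: {exc}") from exc
    amp = float(res.params["amp"].value)
    tau_r = float(res.params["tau_r"].value)
    amp_err = res.params["amp"].stderr
    if amp <= 0 or (amp_err is not None and amp < 2.0 * amp_err):
        raise NoRelaxationError(
            "fitted amplitude indistinguishable from zero in the window")
    K = 1.0 / amp if k_convention == "open_over_closed" else amp
    K_open = 1.0 / amp  # algebra below always uses the open/closed convention
    tau_c, tau_o, frac = derive_times(K_open, tau_r)
    errors: dict[str, float] = {}
    if amp_err is not None and res.params["tau_r"].stderr is not None:
        errors["K"] = float(amp_err / amp**2)
        errors["tau_r"] = float(res.params["tau_r"].stderr)
    if series is not None:
        def half_analysis(s: StateSeries) -> dict:
            from .correlation import fluorescence_autocorrelation
            c = fluorescence_autocorrelation(
                s, max_lag=min(window[1] * 2, s.duration / 3))
            f = fit_two_state(c, window=window, k_convention=k_convention)
            return {"tau_c_split": f.tau_c, "tau_o_split": f.tau_o}
        try:
            errors.update(split_half_errors(series, half_analysis))
        except (NoRelaxationError, InputError, FitError):
            pass  # halves too short to resolve the process
    return TwoStateFit(
        K=K, tau_r=tau_r, tau_c=tau_c, tau_o=tau_o, fraction_open=frac,
        window=tuple(window), r_correlation=_pearson(y, res.best_fit),
        errors=errors,
    )


# ---------------------------------------------------------------------------
# multi-exponential (stretched + 1-2 exponentials)
# ---------------------------------------------------------------------------

@dataclass
class ExpComponent:
    amplitude: float
    tau: float  # ns
    relative_pct: float = float("nan")


@dataclass
class StretchedComponent:
    amplitude: float
    tau_1: float  # ns (picosecond regime in practice)
    beta: float
    relative_pct: float = float("nan")


@dataclass
class MultiExpFit:
    baseline: float
    stretched: StretchedComponent
    exponentials: list[ExpComponent]
    window_start: float  # ns
    r_correlation: float
    chi2: float
    aicc: float
    quality_flag: bool  # True when r <= 0.95 (flagged, not rejected)
    errors: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "model": "stretched_plus_exponentials",
            "baseline": self.baseline,
            "stretched": vars(self.stretched),
            "exponentials": [vars(e) for e in self.exponentials],
            "window_start_ns": self.window_start,
            "r_correlation": self.r_correlation,
            "chi2": self.chi2, "aicc": self.aicc,
            "quality_flag": self.quality_flag,
            "errors": self.errors,
        }


def _multiexp_model(t: np.ndarray, p: np.ndarray, n_exp: int) -> np.ndarray:
    base, a_s, tau_s, beta = p[0], p[1], p[2], p[3]
    y = base + a_s * np.exp(-np.power(t / tau_s, beta))
    for i in range(n_exp):
        y = y + p[4 + 2 * i] * np.exp(-t / p[5 + 2 * i])
    return y


def _aicc(chi2: float, n: int, k: int) -> float:
    # Gaussian-likelihood AIC with small-sample correction
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(chi2, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _fit_multiexp_n(t: np.ndarray, y: np.ndarray, n_exp: int) -> tuple | None:
    """Best multistart fit with n_exp nanosecond exponentials, or None."""
    span = float(y[0] - y[-1])
    base0 = float(y[-1])
    lo, hi = float(t[0]), float(t[-1])
    best = None
    # tau initialisations log-spaced over the window; beta starts at 0.7
    tau_grid = np.exp(np.linspace(np.log(lo), np.log(hi), 4 + n_exp))
    starts = []
    for i in range(len(tau_grid) - n_exp):
        taus = tau_grid[i + 1: i + 1 + n_exp]
        starts.append((tau_grid[0], taus))
    for tau_s0, taus0 in starts:
        params = lmfit.Parameters()
        params.add("base", value=base0, min=min(0.0, base0 - abs(span)),
                   max=base0 + abs(span) + 1.0)
        params.add("a_s", value=max(span / (n_exp + 1), 1e-6), min=0.0)
        params.add("tau_s", value=tau_s0, min=lo * 1e-2, max=hi)
        params.add("beta", value=0.7, min=0.05, max=1.0)
        for i, tv in enumerate(taus0):
            params.add(f"a{i}", value=max(span / (n_exp + 1), 1e-6), min=0.0)
            params.add(f"tau{i}", value=tv, min=lo * 1e-2, max=hi * 1e2)

        def resid(pars):
            v = pars.valuesdict()
            p = [v["base"], v["a_s"], v["tau_s"], v["beta"]]
            for i in range(n_exp):
                p += [v[f"a{i}"], v[f"tau{i}"]]
            return _multiexp_model(t, np.array(p, dtype=float), n_exp) - y

        try:
            out = lmfit.minimize(resid, params, method="least_squares")
        except Exception:
            continue
        chi2 = float(np.sum(out.residual**2))
        if best is None or chi2 < best[0]:
            best = (chi2, out)
    return best


def fit_multiexp(
    curve: CorrelationCurve,
    n_ns_exponentials: int | str = "auto",
    window_start: float = MULTIEXP_WINDOW_START,
    g0: float | None = None,
) -> MultiExpFit:
    """Fit baseline + stretched exponential + 1-2 exponentials beyond 3 ps.

    ``auto`` selects the number of nanosecond exponentials (1 or 2) by
    corrected AIC.  Relative amplitudes are reported as percentages of
    G(0) - 1 (``g0`` overrides the curve's own zero-lag value).
    """
    m = curve.lags >= window_start - 1e-12
    t, y = curve.lags[m], curve.values[m]
    t = np.where(t <= 0, curve.dt * 1e-3, t)  # guard a zero lag in the window
    if t.size < 10:
        raise InputError("too few lag points beyond the window start")
    if np.log10(curve.lags[curve.lags > 0].max() / curve.lags[curve.lags > 0].min()) < 1.0:
        raise InputError("curve should span a wide lag range for this model")
    if np.ptp(y) < 1e-12:
        raise NoRelaxationError("flat curve: nothing to fit")

    choices = [1, 2] if n_ns_exponentials == "auto" else [int(n_ns_exponentials)]
    fits = {}
    for n_exp in choices:
        got = _fit_multiexp_n(t, y, n_exp)
        if got is not None:
            chi2, out = got
            k = 4 + 2 * n_exp
            fits[n_exp] = (_aicc(chi2, t.size, k), chi2, out)
    if not fits:
        raise FitError("multi-exponential fit did not converge for any start")
    n_exp = min(fits, key=lambda n: fits[n][0])
    aicc, chi2, out = fits[n_exp]
    pars = out.params
    comps = [ExpComponent(float(pars[f"a{i}"].value), float(pars[f"tau{i}"].value))
             for i in range(n_exp)]
    comps.sort(key=lambda c: c.tau)
    stretched = StretchedComponent(float(pars["a_s"].value),
                                   float(pars["tau_s"].value),
                                   float(pars["beta"].value))
    if g0 is None:
        g0 = float(curve.values[0]) if curve.lags[0] == 0 else (
            1.0 / curve.mean_signal if curve.kind == "fluorescence_G"
            and curve.mean_signal > 0 else float(curve.values[0]))
    total = g0 - 1.0
    if total > 0:
        stretched.relative_pct = 100.0 * stretched.amplitude / total
        for c in comps:
            c.relative_pct = 100.0 * c.amplitude / total
    yfit = y - out.residual
    r = _pearson(y, yfit)
    errors = {name: float(pars[name].stderr)
              for name in pars if pars[name].stderr is not None}
    return MultiExpFit(
        baseline=float(pars["base"].value), stretched=stretched,
        exponentials=comps, window_start=window_start,
        r_correlation=r, chi2=chi2, aicc=aicc,
        quality_flag=r <= R_QUALITY_GATE, errors=errors,
    )


@dataclass
class HBondLifetimeFit:
    """Stretched picosecond flicker + single nanosecond exponential.

    ``lifetime_ns`` (the nanosecond relaxation time) is taken as the average
    hydrogen-bond lifetime.
    """

    baseline: float
    stretched: StretchedComponent
    exponential: ExpComponent
    lifetime_ns: float
    r_correlation: float
    errors: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "model": "hbond_lifetime",
            "baseline": self.baseline,
            "stretched": vars(self.stretched),
            "exponential": vars(self.exponential),
            "lifetime_ns": self.lifetime_ns,
            "r_correlation": self.r_correlation,
            "errors": self.errors,
        }


def fit_hbond_lifetime(curve: CorrelationCurve,
                       window_start: float = 0.0) -> HBondLifetimeFit:
    """Fit C(t) with baseline + stretched ps component + one ns exponential.

    For a Markov on/off bond the plateau is the stationary intact fraction
    and the exponential relaxation time is 1/(k_break + k_reform).
    """
    sub = curve if window_start == 0 else curve.restrict(window_start, np.inf)
    if np.ptp(sub.values) < 1e-9:
        raise NoRelaxationError("C(t) is flat (always-intact bonds?)")
    fit = fit_multiexp(sub, n_ns_exponentials=1,
                       window_start=max(window_start, sub.lags[sub.lags > 0][0]),
                       g0=float(sub.values[0]) + 1.0)
    exp = fit.exponentials[0]
    # the stretched term and the exponential form a degenerate family when
    # beta ~ 1; keep only components whose amplitude is resolvable (CI away
    # from zero) and take the dominant exponential-like one as the lifetime
    total = fit.stretched.amplitude + exp.amplitude

    def significant(amp: float, err_key: str) -> bool:
        err = fit.errors.get(err_key)
        floor = 0.02 * total
        return amp > floor and (err is None or amp > 2.0 * err)

    candidates: list[ExpComponent] = []
    if significant(exp.amplitude, "a0"):
        candidates.append(exp)
    if fit.stretched.beta > 0.9 and significant(fit.stretched.amplitude, "a_s"):
        candidates.append(ExpComponent(fit.stretched.amplitude,
                                       fit.stretched.tau_1))
    if not candidates:
        raise NoRelaxationError("no resolvable nanosecond component")
    exp = max(candidates, key=lambda c: c.amplitude)
    lifetime = exp.tau
    return HBondLifetimeFit(
        baseline=fit.baseline, stretched=fit.stretched, exponential=exp,
        lifetime_ns=lifetime, r_correlation=fit.r_correlation,
        errors=fit.errors,
    )


# ---------------------------------------------------------------------------
# power-law scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingFit:
    exponent: float
    prefactor: float
    n_values: list[float]
    n_min: float
    stderr_exponent: float
    weighted: bool

    def as_dict(self) -> dict:
        return {
            "model": "power_law",
            "exponent": self.exponent, "prefactor": self.prefactor,
            "n_values": self.n_values, "n_min": self.n_min,
            "stderr_exponent": self.stderr_exponent, "weighted": self.weighted,
        }


def fit_powerlaw(
    rates: Sequence[tuple[float, float]],
    n_min: float = 0.0,
    rate_errors: Sequence[float] | None = None,
    weighted: bool = False,
) -> ScalingFit:
    """OLS of ln k on ln n over points with n >= n_min: k = prefactor * n^gamma.

    With ``weighted=True`` and ``rate_errors`` supplied, points are weighted
    by 1/sigma^2 of ln k (sigma_lnk = sigma_k / k).
    """
    pts = [(float(n), float(k)) for n, k in rates]
    if rate_errors is not None and len(rate_errors) != len(pts):
        raise InputError("one rate error per point required")
    keep = [i for i, (n, k) in enumerate(pts) if n >= n_min]
    if len(keep) < 3:
        raise InputError(f"need >= 3 points with n >= {n_min}, have {len(keep)}")
    n = np.array([pts[i][0] for i in keep])
    k = np.array([pts[i][1] for i in keep])
    if np.any(n <= 0) or np.any(k <= 0):
        raise InputError("all n and rates must be positive")
    x, y = np.log(n), np.log(k)
    if weighted and rate_errors is not None:
        sig = np.array([rate_errors[i] for i in keep]) / k
        w = 1.0 / sig**2
        W = np.sum(w)
        xb, yb = np.sum(w * x) / W, np.sum(w * y) / W
        sxx = np.sum(w * (x - xb) ** 2)
        slope = np.sum(w * (x - xb) * (y - yb)) / sxx
        intercept = yb - slope * xb
        resid = y - (intercept + slope * x)
        dof = max(len(keep) - 2, 1)
        stderr = float(np.sqrt(np.sum(w * resid**2) / dof / sxx))
    else:
        res = stats.linregress(x, y)
        slope, intercept, stderr = float(res.slope), float(res.intercept), float(res.stderr)
    return ScalingFit(
        exponent=float(slope), prefactor=float(np.exp(intercept)),
        n_values=list(map(float, n)), n_min=float(n_min),
        stderr_exponent=stderr, weighted=bool(weighted and rate_errors is not None),
    )


# ---------------------------------------------------------------------------
# split-half errors
# ---------------------------------------------------------------------------

def split_half_errors(series, analysis: Callable) -> dict[str, float]:
    """One-sigma errors from applying ``analysis`` to the two record halves.

    The two half-results a, b give the n=2 sample standard deviation
    |a - b| / sqrt(2).  ``analysis`` may return a float or a dict of floats.
    """
    if isinstance(series, StateSeries):
        half = series.n // 2
        if half < 2:
            raise InputError("series too short to split")
        parts = [StateSeries(series.dt, series.states[:half],
                             series.cutoff_nm, series.group_spec),
                 StateSeries(series.dt, series.states[half:2 * half],
                             series.cutoff_nm, series.group_spec)]
    else:
        arr = np.asarray(series)
        half = arr.shape[0] // 2
        if half < 2:
            raise InputError("series too short to split")
        parts = [arr[:half], arr[half:2 * half]]
    try:
        a, b = analysis(parts[0]), analysis(parts[1])
    except Exception as exc:
        raise type(exc)(f"analysis failed on a half-record: {exc}") from exc
    if isinstance(a, dict):
        return {key: abs(a[key] - b[key]) / np.sqrt(2.0) for key in a}
    return {"sigma": abs(float(a) - float(b)) / np.sqrt(2.0)}


# ---------------------------------------------------------------------------
# packaged reference table
# ---------------------------------------------------------------------------

def load_labelled_time_constants() -> pd.DataFrame:
    """Closing/opening time constants (ns) of the dye-labelled GS peptides.

    Columns: n_gs, n_peptide_bonds, tau_c_sim_ns, tau_c_exp_ns,
    tau_c_exp_err_ns, tau_o_sim_ns, tau_o_exp_ns, tau_o_exp_err_ns.
    Simulation values exist only for the five shorter peptides.
    """
    ref = importlib.resources.files("looplab").joinpath("data/labelled_time_constants.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def experimental_closing_rates(n_min: float = 0.0) -> list[tuple[float, float]]:
    """(n_peptide_bonds, 1/tau_c_exp) pairs from the packaged table."""
    df = load_labelled_time_constants()
    return [(float(n), 1.0 / float(tc))
            for n, tc in zip(df["n_peptide_bonds"], df["tau_c_exp_ns"])
            if n >= n_min]
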