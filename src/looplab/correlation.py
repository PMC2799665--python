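"""Fluorescence autocorrelation G(tau) and H-bond existence autocorrelation C(t).

The second-order autocorrelation of the binary fluorescence signal I(t) is

    G(tau) = <I(t) I(t+tau)> / <I>^2,

with the angle brackets averaging over all starting times t for which both
samples lie inside the finite record (no periodic wrap-around).  With this
normalisation a mixing stationary signal decays to 1 at long lag, which is
the convention the two-state fit G = 1 + (1/K) exp(-tau/tau_r) requires.
A mean-subtracted (covariance) variant is available via ``normalization``.

The hydrogen-bond existence autocorrelation is

    C(t) = sum_bonds sum_t0 h(t0) h(t0+t)  /  sum_bonds sum_t0 h(t0),

the probability that a bond intact at a start time is (intermittent mode)
again intact, or (continuous mode) has stayed intact throughout, a time t
later.  Intermittent is the default: it tolerates transient breaking, which
is the convention behind nanosecond H-bond lifetimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError, InputError, LagError
from .state_signal import StateSeries

__all__ = [
    "CorrelationCurve",
    "log_lag_grid",
    "fluorescence_autocorrelation",
    "HBondExistenceMatrix",
    "hbond_existence_autocorrelation",
]


@dataclass
class CorrelationCurve:
    """Lag grid (ns, increasing from 0) plus correlation values."""

    lags: np.ndarray  # ns
    values: np.ndarray
    kind: str  # "fluorescence_G" | "hbond_C"
    mean_signal: float
    n_pairs_per_lag: np.ndarray
    source_length: float  # ns
    dt: float  # ns; sampling step of the source signal

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs_per_lag = np.asarray(self.n_pairs_per_lag, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise InputError("lags must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.lags.size)

    def restrict(self, lo: float, hi: float) -> "CorrelationCurve":
        """Sub-curve with lo <= lag <= hi (ns)."""
        m = (self.lags >= lo) & (self.lags <= hi)
        return CorrelationCurve(self.lags[m], self.values[m], self.kind,
                                self.mean_signal, self.n_pairs_per_lag[m],
                                self.source_length, self.dt)


def log_lag_grid(dt: float, max_lag: float, points_per_decade: int = 30,
                 include_zero: bool = True) -> np.ndarray:
    """Logarithmic lag grid snapped onto the dt sampling grid.

    About ``points_per_decade`` points from dt up to ``max_lag``; duplicate
    grid points created by the snapping are dropped.  Non-grid lags are
    snapped *down* to the nearest multiple of dt.
    """
    if max_lag < dt:
        raise LagError("max_lag below one sampling step")
    n_dec = np.log10(max_lag / dt)
    raw = dt * np.logspace(0, n_dec, max(2, int(np.ceil(n_dec * points_per_decade))))
    ks = np.unique(np.floor(raw / dt).astype(np.int64))
    ks = ks[ks >= 1]
    lags = ks * dt
    if include_zero:
        lags = np.concatenate(([0.0], lags))
    return lags


def _snap_lags(lags: np.ndarray, dt: float, n: int) -> np.ndarray:
    """Convert lag times to integer step counts, snapping down off-grid lags."""
    lags = np.asarray(lags, dtype=float)
    ks = np.floor(lags / dt + 1e-9).astype(np.int64)
    off = np.abs(ks * dt - lags) > 1e-9 * max(dt, 1.0)
    if np.any(off):
        warnings.warn("lags not on the dt grid were snapped down", stacklevel=3)
    if np.any(ks >= n):
        raise LagError(f"lag {lags.max():g} ns >= series length {n * dt:g} ns")
    if np.any(ks < 0):
        raise LagError("negative lag")
    return np.unique(ks)


def fluorescence_autocorrelation(
    signal: StateSeries,
    lags: np.ndarray | None = None,
    max_lag: float | None = None,
    normalization: str = "mean_squared",
) -> CorrelationCurve:
    """Second-order autocorrelation of a binary (or real) signal.

    Parameters
    ----------
    signal:
        The state series I(t); its mean must be positive.
    lags:
        Lag times in ns.  Default: logarithmic grid from dt to
        ``max_lag`` (default source_length/10), ~30 points per decade.
    normalization:
        ``"mean_squared"`` (default): <I(t)I(t+tau)> / <I>^2, decays to 1.
        ``"covariance"``: <dI(t) dI(t+tau)> / var(I), decays to 0.
    """
    x = signal.states.astype(np.float64)
    n = x.size
    mean = x.mean()
    if mean <= 0:
        raise DegenerateSignalError("all-zero signal: G(tau) undefined")
    if normalization not in ("mean_squared", "covariance"):
        raise InputError(f"unknown normalization {normalization!r}")
    if lags is None:
        mx = max_lag if max_lag is not None else signal.duration / 10.0
        mx = min(mx, (n - 1) * signal.dt)
        lags = log_lag_grid(signal.dt, mx)
    ks = _snap_lags(np.asarray(lags), signal.dt, n)

    if normalization == "covariance":
        var = x.var()
        if var == 0:
            raise DegenerateSignalError("constant signal has zero variance")
        xc = x - mean
        values = np.empty(ks.size)
        for i, k in enumerate(ks):
            if k == 0:
                values[i] = 1.0
            else:
                values[i] = float(np.dot(xc[:-k], xc[k:]) / (n - k)) / var
    else:
        values = np.empty(ks.size)
        denom = mean * mean
        for i, k in enumerate(ks):
            if k == 0:
                values[i] = float(np.dot(x, x) / n) / denom
            else:
                values[i] = float(np.dot(x[:-k], x[k:]) / (n - k)) / denom
    return CorrelationCurve(
        lags=ks * signal.dt,
        values=values,
        kind="fluorescence_G",
        mean_signal=float(mean),
        n_pairs_per_lag=n - ks,
        source_length=signal.duration,
        dt=signal.dt,
    )


@dataclass
class HBondExistenceMatrix:
    """Per-frame existence of a set of hydrogen bonds.

    ``existence`` is (n_frames, n_bonds) binary; ``labels`` carries one
    caller-meaningful tag per bond (e.g. ``"in_beta"`` / ``"not_in_beta"``).
    """

    dt: float  # ns
    existence: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.existence = np.asarray(self.existence)
        if self.existence.ndim != 2 or self.existence.shape[1] < 1:
            raise InputError("existence matrix must be (n_frames, n_bonds)")
        if not np.all(np.isin(np.unique(self.existence), (0, 1))):
            raise InputError("existence must be binary")
        self.existence = self.existence.astype(np.int8)
        if self.dt <= 0:
            raise InputError("dt must be positive")
        if self.labels is not None and len(self.labels) != self.n_bonds:
            raise InputError("one label per bond required")

    @property
    def n_frames(self) -> int:
        return int(self.existence.shape[0])

    @property
    def n_bonds(self) -> int:
        return int(self.existence.shape[1])

    def select(self, label: str) -> "HBondExistenceMatrix":
        if self.labels is None:
            raise InputError("matrix has no labels")
        cols = [j for j, lab in enumerate(self.labels) if lab == label]
        if not cols:
            raise InputError(f"no bonds labelled {label!r}")
        return HBondExistenceMatrix(self.dt, self.existence[:, cols],
                                    [label] * len(cols))


def _continuous_pair_counts(h: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """Number of (t0, t0+k) pairs with h intact throughout, per lag k.

    Computed from run lengths: a run of L intact frames contributes
    max(0, L-k) fully-intact pairs at lag k.
    """
    padded = np.concatenate(([0], h, [0]))
    change = np.diff(padded)
    starts = np.flatnonzero(change == 1)
    ends = np.flatnonzero(change == -1)
    run_lengths = ends - starts
    counts = np.empty(ks.size, dtype=np.int64)
    for i, k in enumerate(ks):
        counts[i] = int(np.maximum(run_lengths - k, 0).sum())
    return counts


def hbond_existence_autocorrelation(
    matrix: HBondExistenceMatrix,
    mode: str = "intermittent",
    lags: np.ndarray | None = None,
    max_lag: float | None = None,
    per_bond: bool = False,
):
    """Existence autocorrelation C(t), averaged over bonds.

    Returns a :class:`CorrelationCurve`; with ``per_bond=True`` returns
    ``(averaged_curve, list_of_per_bond_curves)`` instead, so curves can be
    group-averaged by caller-supplied labels before fitting.
    """
    if mode not in ("intermittent", "continuous"):
        raise InputError(f"unknown mode {mode!r}")
    H = matrix.existence
    n = matrix.n_frames
    if n < 2:
        raise InputError("need >= 2 frames")
    if not np.any(H):
        raise InputError("no bond is ever intact")
    if lags is None:
        mx = max_lag if max_lag is not None else n * matrix.dt / 10.0
        mx = min(mx, (n - 1) * matrix.dt)
        lags = log_lag_grid(matrix.dt, mx)
    ks = _snap_lags(np.asarray(lags), matrix.dt, n)

    def one_bond(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = h.astype(np.float64)
        num = np.empty(ks.size)
        den = np.empty(ks.size)
        if mode == "continuous":
            cont = _continuous_pair_counts(h.astype(np.int8), ks)
        for i, k in enumerate(ks):
            d = h[: n - k].sum()
            den[i] = d
            if mode == "intermittent":
                num[i] = float(np.dot(h[: n - k], h[k:])) if k else float(np.dot(h, h))
            else:
                num[i] = float(cont[i])
        return num, den

    nums = np.zeros(ks.size)
    dens = np.zeros(ks.size)
    per_curves: list[CorrelationCurve] = []
    for j in range(matrix.n_bonds):
        num, den = one_bond(H[:, j])
        nums += num
        dens += den
        if per_bond:
            with np.errstate(invalid="ignore", divide="ignore"):
                v = np.where(den > 0, num / np.maximum(den, 1), np.nan)
            per_curves.append(CorrelationCurve(
                ks * matrix.dt, v, "hbond_C", float(H[:, j].mean()),
                (n - ks), n * matrix.dt, matrix.dt))
    if np.any(dens == 0):
        raise InputError("a lag window contains no intact start frames")
    curve = CorrelationCurve(
        lags=ks * matrix.dt,
        values=nums / dens,
        kind="hbond_C",
        mean_signal=float(H.mean()),
        n_pairs_per_lag=matrix.n_bonds * (n - ks),
        source_length=n * matrix.dt,
        dt=matrix.dt,
    )
    if per_bond:
        return curve, per_curves
    return curve
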