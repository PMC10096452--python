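"""TCSPC decay analysis: IRF reconvolution, multi-exponential fits,
average lifetimes, and static-vs-dynamic quenching discrimination.

A measured decay is the true multi-exponential impulse response convolved
with the instrument response function (IRF).  Fits minimise the
Poisson-weighted chi-square (variance = max(counts, 1), standard TCSPC
practice) with amplitudes solved by non-negative linear least squares for
each trial lifetime set (variable projection) and the lifetimes optimised
by bounded nonlinear least squares from multiple log-spaced starts.

Static quenching leaves all decay components unchanged while the
steady-state intensity drops; dynamic (collisional) quenching shortens the
lifetime in proportion to the steady-state Stern-Volmer ratio,
tau0/tau = 1 + k_q tau0 [Q].  ``assess_lifetime_invariance`` implements
this discrimination.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .io import DecayHistogram, QuenchKitError, ValidationError

logger = logging.getLogger("quenchkit")

__all__ = [
    "DecayModel",
    "DecayFit",
    "gaussian_irf",
    "convolve_with_irf",
    "MultiExponentialDecay",
    "fit_multiexponential",
    "average_lifetimes",
    "select_n_exp",
    "InvarianceResult",
    "assess_lifetime_invariance",
    "FitError",
]


class FitError(QuenchKitError):
    """Decay fit failed to converge after multi-start."""


@dataclass(frozen=True)
class DecayModel:
    """Sum-of-exponentials decay model: I(t) = sum_i a_i exp(-t / tau_i).

    Lifetimes in ns, sorted ascending; amplitudes >= 0 in arbitrary units.
    ``shift`` is an IRF colour-shift in ns; ``background`` is a constant
    counts-per-channel offset.
    """

    amplitudes: tuple
    lifetimes: tuple
    shift: float = 0.0
    background: float = 0.0

    def __post_init__(self):
        a = tuple(float(x) for x in self.amplitudes)
        tau = tuple(float(x) for x in self.lifetimes)
        if len(a) != len(tau):
            raise ValidationError("amplitudes and lifetimes must have equal length")
        if not 1 <= len(tau) <= 3:
            raise ValidationError("1 to 3 exponential components supported")
        if any(t <= 0 for t in tau):
            raise ValidationError("lifetimes must be > 0")
        if any(x < 0 for x in a):
            raise ValidationError("amplitudes must be >= 0")
        if sum(a) <= 0:
            raise ValidationError("at least one amplitude must be > 0")
        order = np.argsort(tau)
        object.__setattr__(self, "amplitudes", tuple(a[i] for i in order))
        object.__setattr__(self, "lifetimes", tuple(tau[i] for i in order))
        if self.background < 0:
            raise ValidationError("background must be >= 0")

    @property
    def n_exp(self) -> int:
        return len(self.lifetimes)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, tau in zip(self.amplitudes, self.lifetimes):
            out += a * np.exp(-t / tau)
        return out


def average_lifetimes(model: DecayModel) -> Tuple[float, float]:
    """Amplitude- and intensity-weighted average lifetimes (ns).

    tau_amp = sum(a_i tau_i) / sum(a_i); tau_int = sum(a_i tau_i^2) /
    sum(a_i tau_i).  By Cauchy-Schwarz tau_int >= tau_amp, with equality
    only for a single lifetime.
    """
    a = np.array(model.amplitudes)
    tau = np.array(model.lifetimes)
    s0 = a.sum()
    if s0 <= 0:
        raise ValidationError("sum of amplitudes must be > 0")
    if tau.size == 1:  # degenerate sums are exactly tau
        return float(tau[0]), float(tau[0])
    s1 = float(a @ tau)
    s2 = float(a @ tau**2)
    return s1 / s0, s2 / s1


def gaussian_irf(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Gaussian IRF on the channel grid, unnormalised."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def _normalise_irf(irf: np.ndarray) -> np.ndarray:
    irf = np.asarray(irf, dtype=float)
    total = irf.sum()
    if total <= 0:
        raise ValidationError("IRF must have positive total intensity")
    return irf / total


def convolve_with_irf(
    model: DecayModel,
    irf: Optional[np.ndarray],
    grid: np.ndarray,
) -> np.ndarray:
    """Expected counts: (model ⊛ unit-area IRF) on the grid, plus background.

    ``irf=None`` means a delta IRF at t = grid[0] (the convolution identity).
    A nonzero model shift displaces the IRF by linear interpolation.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValidationError("grid must be 1-D with >= 2 channels")
    decay = model.evaluate(grid - grid[0])
    if irf is None:
        return decay + model.background
    kernel = _normalise_irf(irf)
    if kernel.size != grid.size:
        raise ValidationError("IRF must share the decay grid")
    if model.shift != 0.0:
        kernel = np.interp(grid - model.shift, grid, kernel, left=0.0, right=0.0)
        s = kernel.sum()
        if s > 0:
            kernel = kernel / s
    conv = np.convolve(kernel, decay)[: grid.size]
    return conv + model.background


@dataclass(frozen=True)
class DecayFit:
    """A fitted decay model with goodness-of-fit and average lifetimes."""

    model: DecayModel
    reduced_chi_square: float
    tau_amp: float
    tau_int: float
    covariance: np.ndarray  # over (a_1..a_n, tau_1..tau_n)
    n_channels_fit: int

    def stderr(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


class MultiExponentialDecay(BaseEstimator):
    """Reconvolution fit of a TCSPC histogram with 1-3 exponentials.

    Parameters
    ----------
    n_exp : int, default 1
        Number of exponential components.
    irf : None | "delta" | ("gaussian", center_ns, fwhm_ns) | ndarray
        Instrument response.  ``None`` uses the measured IRF passed to
        ``fit`` when available, else a delta.
    n_starts : int, default 5
        Multi-start count; initial lifetimes are log-spaced over
        [channel width, 10 x record length] with per-start offsets, to
        escape local minima from closely spaced lifetimes.
    fit_start : int or None
        First channel of the fit window (default: the peak channel of the
        IRF if measured, else of the decay).
    fit_background : bool, default False
        Fit a constant background (otherwise fixed at 0).

    Attributes
    ----------
    model_ : DecayModel
    reduced_chi_square_ : float
    tau_amp_, tau_int_ : float
    covariance_ : ndarray over (amplitudes, lifetimes)
    """

    def __init__(
        self,
        n_exp: int = 1,
        irf: Union[None, str, tuple, np.ndarray] = None,
        n_starts: int = 5,
        fit_start: Optional[int] = None,
        fit_stop: Optional[int] = None,
        fit_background: bool = False,
    ):
        self.n_exp = n_exp
        self.irf = irf
        self.n_starts = n_starts
        self.fit_start = fit_start
        self.fit_stop = fit_stop
        self.fit_background = fit_background

    # -- internals ---------------------------------------------------------

    def _resolve_irf(self, grid, measured) -> Optional[np.ndarray]:
        irf = self.irf
        if irf is None:
            irf = measured  # may be None -> delta
        if irf is None or (isinstance(irf, str) and irf == "delta"):
            return None
        if isinstance(irf, tuple) and irf[0] == "gaussian":
            _, center, fwhm = irf
            return gaussian_irf(grid, center, fwhm)
        return np.asarray(irf, dtype=float)

    def fit(self, X, y=None):
        """Fit a DecayHistogram, or (t, counts) arrays via X=(t, counts)."""
        if isinstance(X, DecayHistogram):
            t, counts, measured = X.channel_time, X.counts, X.irf_counts
        else:
            t, counts = X
            t = np.asarray(t, dtype=float)
            counts = np.asarray(counts, dtype=float)
            measured = None
        if counts.sum() < 1000:
            raise ValidationError("decay fit needs >= 1000 total counts")
        n_par = 2 * self.n_exp + (1 if self.fit_background else 0)
        if n_par >= t.size / 10:
            raise ValidationError("too many parameters for the channel count")

        irf = self._resolve_irf(t, measured)
        peak_src = irf if irf is not None else counts
        start = self.fit_start if self.fit_start is not None else int(np.argmax(peak_src))
        stop = self.fit_stop if self.fit_stop is not None else t.size
        sl = slice(start, stop)
        y_obs = counts[sl].astype(float)
        w = 1.0 / np.sqrt(np.maximum(y_obs, 1.0))

        dt = float(np.mean(np.diff(t)))
        record = t[-1] - t[0]

        def design(taus):
            """Weighted design matrix of unit-amplitude convolved exponentials."""
            cols = []
            for tau in taus:
                m = DecayModel(amplitudes=(1.0,), lifetimes=(tau,))
                cols.append(convolve_with_irf(m, irf, t)[sl])
            M = np.column_stack(cols)
            if self.fit_background:
                M = np.column_stack([M, np.ones(y_obs.size)])
            return M

        def amplitudes_for(taus):
            M = design(taus)
            coef, _ = optimize.nnls(M * w[:, None], y_obs * w)
            return coef, M

        def residuals(log_taus):
            taus = np.exp(log_taus)
            coef, M = amplitudes_for(taus)
            return (M @ coef - y_obs) * w

        lo, hi = np.log(dt), np.log(10.0 * record)
        best = None
        centers = np.linspace(lo + 0.25 * (hi - lo), lo + 0.75 * (hi - lo), self.n_starts)
        for c in centers:
            if self.n_exp == 1:
                x0 = np.array([c])
            else:
                half_span = 0.35 * (hi - lo)
                x0 = np.linspace(c - half_span, c + half_span, self.n_exp)
            x0 = np.clip(x0, lo, hi)
            try:
                res = optimize.least_squares(
                    residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12
                )
            except Exception:  # singular trial start
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise FitError("decay fit did not converge from any start")

        taus = np.sort(np.exp(best.x))
        coef, M = amplitudes_for(taus)
        amps = coef[: self.n_exp]
        bg = float(coef[self.n_exp]) if self.fit_background else 0.0
        if amps.sum() <= 0:
            raise FitError("all amplitudes collapsed to zero")
        if self.n_exp > 1:
            rel = np.diff(taus) / taus[:-1]
            if np.any(rel < 0.01):
                warnings.warn(
                    "lifetimes collapsed within 1%; reduce n_exp", stacklevel=2
                )
            tiny = amps < 0.02 * amps.sum()
            if np.any(tiny):
                warnings.warn(
                    "component amplitude < 2% of total; model may be overfit",
                    stacklevel=2,
                )
        # amplitudes of zero break DecayModel validation; floor them
        amps = np.maximum(amps, 1e-12 * max(amps.max(), 1.0))
        model = DecayModel(
            amplitudes=tuple(amps), lifetimes=tuple(taus), background=bg
        )

        fitted = M @ coef
        dof = max(y_obs.size - n_par, 1)
        chi2 = float(np.sum(((fitted - y_obs) * w) ** 2))
        self.reduced_chi_square_ = chi2 / dof

        self.covariance_ = self._covariance(model, irf, t, sl, y_obs, w)
        self.model_ = model
        self.tau_amp_, self.tau_int_ = average_lifetimes(model)
        self.n_channels_fit_ = int(y_obs.size)
        return self

    def _covariance(self, model, irf, t, sl, y_obs, w):
        """Gauss-Newton covariance over (amplitudes, lifetimes)."""
        p0 = np.array(list(model.amplitudes) + list(model.lifetimes))

        def predict(p):
            amps, taus = p[: self.n_exp], p[self.n_exp :]
            out = np.zeros(y_obs.size)
            for a, tau in zip(amps, taus):
                m = DecayModel(amplitudes=(1.0,), lifetimes=(abs(tau),))
                out += a * convolve_with_irf(m, irf, t)[sl]
            return out + model.background

        J = np.empty((y_obs.size, p0.size))
        for j in range(p0.size):
            h = max(abs(p0[j]) * 1e-6, 1e-12)
            pp, pm = p0.copy(), p0.copy()
            pp[j] += h
            pm[j] -= h
            J[:, j] = (predict(pp) - predict(pm)) / (2 * h)
        Jw = J * w[:, None]
        try:
            return np.linalg.inv(Jw.T @ Jw)
        except np.linalg.LinAlgError:
            return np.full((p0.size, p0.size), np.nan)


def fit_multiexponential(
    hist: DecayHistogram,
    n_exp: int = 1,
    irf_mode: Union[None, str, tuple, np.ndarray] = None,
    **kwargs,
) -> DecayFit:
    """Reconvolution fit of a decay histogram; see MultiExponentialDecay."""
    est = MultiExponentialDecay(n_exp=n_exp, irf=irf_mode, **kwargs)
    est.fit(hist)
    return DecayFit(
        model=est.model_,
        reduced_chi_square=est.reduced_chi_square_,
        tau_amp=est.tau_amp_,
        tau_int=est.tau_int_,
        covariance=est.covariance_,
        n_channels_fit=est.n_channels_fit_,
    )


def select_n_exp(
    hist: DecayHistogram,
    max_n: int = 3,
    alpha: float = 0.05,
    irf_mode=None,
    **kwargs,
) -> Tuple[int, list]:
    """Nested F-test model-order helper: smallest n whose increment to n+1
    is not significant at ``alpha``.  Returns (chosen n, fits by order)."""
    fits = []
    for n in range(1, max_n + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits.append(fit_multiexponential(hist, n_exp=n, irf_mode=irf_mode, **kwargs))
    chosen = max_n
    for n in range(1, max_n):
        f_lo, f_hi = fits[n - 1], fits[n]
        nch = f_lo.n_channels_fit
        p_lo, p_hi = 2 * n, 2 * (n + 1)
        rss_lo = f_lo.reduced_chi_square * (nch - p_lo)
        rss_hi = f_hi.reduced_chi_square * (nch - p_hi)
        if rss_hi <= 0 or rss_lo <= rss_hi:
            chosen = n
            break
        fstat = (rss_lo - rss_hi) / (p_hi - p_lo) / (rss_hi / (nch - p_hi))
        if stats.f.sf(fstat, p_hi - p_lo, nch - p_hi) >= alpha:
            chosen = n
            break
    return chosen, fits


@dataclass(frozen=True)
class InvarianceResult:
    """Outcome of the lifetime-invariance test across quencher levels."""

    verdict: str  # invariant | dynamic | inconclusive
    sv_slope: float  # k_q * tau0 (M^-1) from tau0/tau vs [Q]; NaN if untested
    sv_slope_stderr: float
    details: dict = field(default_factory=dict)


def assess_lifetime_invariance(
    fits: Sequence[Tuple[float, DecayFit]],
    k_sigma: float = 3.0,
    alpha: float = 0.05,
) -> InvarianceResult:
    """Discriminate static from dynamic quenching from decay fits.

    ``fits`` pairs each quencher concentration (mol/L) with its DecayFit;
    a zero-quencher reference is mandatory.  The verdict is

    - ``invariant`` when every lifetime and amplitude fraction lies within
      ``k_sigma`` standard errors of the reference fit (static quenching,
      or no quenching at all: the ground-state complex does not emit, so
      surviving fluorophores decay unchanged);
    - ``dynamic`` when tau0/tau versus [Q] has a significantly positive
      slope (the lifetime Stern-Volmer law of collisional quenching), with
      the recovered slope k_q·tau0 reported;
    - ``inconclusive`` otherwise.
    """
    fits = sorted(fits, key=lambda qf: qf[0])
    qs = np.array([q for q, _ in fits])
    if qs.size < 2 or qs[0] != 0.0:
        raise ValidationError("need >= 2 quencher levels including a zero reference")
    ref = fits[0][1]
    n = ref.model.n_exp
    ref_se = ref.stderr()
    ref_amps = np.array(ref.model.amplitudes)
    ref_fracs = ref_amps / ref_amps.sum()

    all_within = True
    for _, f in fits[1:]:
        if f.model.n_exp != n:
            all_within = False
            break
        amps = np.array(f.model.amplitudes)
        fracs = amps / amps.sum()
        taus = np.array(f.model.lifetimes)
        se = f.stderr()
        tau_tol = k_sigma * np.hypot(se[n:], ref_se[n:])
        tau_tol = np.maximum(tau_tol, 1e-3 * np.array(ref.model.lifetimes))
        if np.any(np.abs(taus - np.array(ref.model.lifetimes)) > tau_tol):
            all_within = False
            break
        # amplitude fractions: propagate a crude stderr via total-amplitude scale
        amp_se = np.hypot(se[:n], ref_se[:n]) / amps.sum()
        amp_tol = np.maximum(k_sigma * amp_se, 0.02)
        if np.any(np.abs(fracs - ref_fracs) > amp_tol):
            all_within = False
            break

    # lifetime Stern-Volmer regression through the origin on tau0/tau - 1
    tau0 = ref.tau_int
    y = np.array([tau0 / f.tau_int - 1.0 for _, f in fits])
    sxx = float(qs @ qs)
    slope = float(qs @ y) / sxx if sxx > 0 else float("nan")
    resid = y - slope * qs
    dof = max(qs.size - 1, 1)
    slope_se = float(np.sqrt((resid @ resid) / dof / sxx)) if sxx > 0 else float("nan")
    if slope_se > 0:
        tstat = slope / slope_se
        p_dyn = float(stats.t.sf(tstat, dof))
    else:
        p_dyn = 0.0 if slope > 0 else 1.0

    if all_within:
        verdict = "invariant"
    elif slope > 0 and p_dyn < alpha:
        verdict = "dynamic"
    else:
        verdict = "inconclusive"
    return InvarianceResult(
        verdict=verdict,
        sv_slope=slope,
        sv_slope_stderr=slope_se,
        details={"dynamic_slope_pvalue": p_dyn, "n_levels": int(qs.size)},
    )
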