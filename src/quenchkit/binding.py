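"""Association-constant estimation for 1:1 host-guest systems.

Covers the mass-action speciation solver, Stern-Volmer fits of corrected or
uncorrected fluorescence intensities, a global (multi-wavelength) fit of
absorbance titrations, and a coarse classification of association strength.

For 1:1 static quenching with a non-emissive complex the Stern-Volmer slope
of F0/F versus quencher concentration equals the association constant K.
When the quencher absorbs at the excitation wavelength, fitting uncorrected
intensities systematically inflates K: the inner-filter attenuation mimics
extra quenching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .io import Geometry, QuenchKitError, Spectrum, TitrationSeries, ValidationError
from .ife import corrected_intensities

logger = logging.getLogger("quenchkit")

__all__ = [
    "EquilibriumState",
    "SternVolmerResult",
    "BindingFitResult",
    "solve_equilibrium_1to1",
    "SternVolmer",
    "stern_volmer_fit",
    "GlobalAbsorbanceFit",
    "global_absorbance_fit",
    "classify_association",
    "InsufficientDataError",
]


class InsufficientDataError(QuenchKitError):
    """Fewer titration points than the fit requires."""


@dataclass(frozen=True)
class EquilibriumState:
    """Speciation of a 1:1 host-guest equilibrium (all mol/L)."""

    free_host: float
    free_guest: float
    complex: float


def solve_equilibrium_1to1(
    K: float, host_total: float, guest_total: float
) -> EquilibriumState:
    """Solve the 1:1 mass-action equilibrium H + G <-> HG.

    [HG] is the physically admissible (smaller) root of

        K x^2 - (K (Ht + Gt) + 1) x + K Ht Gt = 0,

    evaluated in the cancellation-free form 2c / (-b + sqrt(b^2 - 4ac)) so
    mass balance holds to ~1e-12 relative across K from 0 to 1e8 M^-1.
    """
    if K < 0:
        raise ValidationError("association constant K must be >= 0")
    if host_total < 0 or guest_total < 0:
        raise ValidationError("total concentrations must be >= 0")
    if K == 0.0 or host_total == 0.0 or guest_total == 0.0:
        return EquilibriumState(host_total, guest_total, 0.0)
    b = K * (host_total + guest_total) + 1.0
    disc = b * b - 4.0 * K * K * host_total * guest_total
    hg = 2.0 * K * host_total * guest_total / (b + np.sqrt(disc))
    hg = min(hg, host_total, guest_total)  # guard rounding at the K->inf limit
    return EquilibriumState(host_total - hg, guest_total - hg, hg)


@dataclass(frozen=True)
class SternVolmerResult:
    """Result of a Stern-Volmer fit F0/F = intercept + K [Q]."""

    K: float
    K_stderr: float
    intercept: float
    r_squared: float
    corrected: bool
    points_used: int
    curvature_flag: bool
    curvature_pvalue: float
    residual_sd: float = float("nan")  # scatter of F0/F about the fitted line


class SternVolmer(BaseEstimator, RegressorMixin):
    """Least-squares Stern-Volmer regression of F0/F on quencher concentration.

    Parameters
    ----------
    fix_intercept : bool, default True
        Constrain the intercept to 1 (the ratio at zero quencher is 1 by
        construction).  With a free intercept, its deviation from 1 is a
        systematic-error diagnostic.
    curvature_alpha : float, default 0.05
        Significance level of the F-test comparing the linear model against
        one with an added quadratic term; a significant quadratic term sets
        ``curvature_flag_`` (upward curvature is the signature of an
        uncorrected inner filter effect at high quencher).
    shared_reference : bool, default True
        Every ratio F0/F shares the single measured F0, so the errors are
        positively correlated and part of the F0 error aliases into the
        slope.  When set, ``K_stderr_`` includes this shared-reference
        variance term (estimated from the residual scatter) on top of the
        ordinary least-squares term; disable for responses that are not
        ratios to a common reference.

    Attributes
    ----------
    K_ : float
        Fitted slope, the association constant in M^-1 for 1:1 static
        quenching with a non-emissive complex.
    K_stderr_ : float
    intercept_ : float
    r_squared_ : float
        NaN when the response carries no variance (flat data, K = 0).
    curvature_flag_ : bool
    curvature_pvalue_ : float
    points_used_ : int
    """

    def __init__(
        self,
        fix_intercept: bool = True,
        curvature_alpha: float = 0.05,
        shared_reference: bool = True,
    ):
        self.fix_intercept = fix_intercept
        self.curvature_alpha = curvature_alpha
        self.shared_reference = shared_reference

    def fit(self, X, y):
        Q = np.asarray(X, dtype=float).reshape(-1)
        ratio = np.asarray(y, dtype=float).reshape(-1)
        if Q.size != ratio.size:
            raise ValidationError("X and y must have the same length")
        if np.count_nonzero(Q > 0) < 3:
            raise InsufficientDataError(
                "Stern-Volmer fit needs at least 3 nonzero-quencher points"
            )
        if self.fix_intercept:
            # slope of (ratio - 1) on Q through the origin
            sxx = float(Q @ Q)
            K = float(Q @ (ratio - 1.0)) / sxx
            resid = ratio - (1.0 + K * Q)
            dof = Q.size - 1
            sigma2 = float(resid @ resid) / max(dof, 1)
            K_se = np.sqrt(sigma2 / sxx)
            intercept = 1.0
        else:
            A = np.column_stack([np.ones_like(Q), Q])
            coef, rss, *_ = np.linalg.lstsq(A, ratio, rcond=None)
            intercept, K = float(coef[0]), float(coef[1])
            resid = ratio - A @ coef
            dof = Q.size - 2
            sigma2 = float(resid @ resid) / max(dof, 1)
            cov = sigma2 * np.linalg.inv(A.T @ A)
            K_se = float(np.sqrt(cov[1, 1]))
        if self.shared_reference and Q.size > 1:
            # a relative error e0 in F0 scales every ratio: the component of
            # e0 * ratio along Q aliases into the slope as e0 * (Q.ratio)/Sxx
            sigma_rel2 = sigma2 / float(np.mean(ratio**2))
            sxx_ = float(Q @ Q)
            K_se = float(
                np.sqrt(K_se**2 + sigma_rel2 * (float(Q @ ratio) / sxx_) ** 2)
            )
        ss_tot = float(np.sum((ratio - ratio.mean()) ** 2))
        ss_res = float(resid @ resid)
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 1e-30 else float("nan")
        self.residual_sd_ = float(np.sqrt(sigma2))
        self.K_ = K
        self.K_stderr_ = float(K_se)
        self.intercept_ = intercept
        self.points_used_ = int(Q.size)
        self._fit_curvature(Q, ratio, ss_res)
        return self

    def _fit_curvature(self, Q, ratio, rss_linear):
        """F-test of an added quadratic term against the linear model."""
        if self.fix_intercept:
            A2 = np.column_stack([Q, Q**2])
            y2 = ratio - 1.0
            p_lin, p_quad = 1, 2
        else:
            A2 = np.column_stack([np.ones_like(Q), Q, Q**2])
            y2 = ratio
            p_lin, p_quad = 2, 3
        dof2 = Q.size - p_quad
        if dof2 < 1:
            self.curvature_flag_, self.curvature_pvalue_ = False, float("nan")
            return
        coef2, *_ = np.linalg.lstsq(A2, y2, rcond=None)
        rss2 = float(np.sum((y2 - A2 @ coef2) ** 2))
        if rss2 <= 1e-300 or rss_linear <= rss2:
            self.curvature_flag_, self.curvature_pvalue_ = False, 1.0
            return
        fstat = (rss_linear - rss2) / (p_quad - p_lin) / (rss2 / dof2)
        pval = float(stats.f.sf(fstat, p_quad - p_lin, dof2))
        self.curvature_flag_ = pval < self.curvature_alpha
        self.curvature_pvalue_ = pval

    def predict(self, X):
        Q = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.K_ * Q


def stern_volmer_fit(
    series: TitrationSeries,
    use_corrected: bool,
    geometry: Optional[Geometry] = None,
    fix_intercept: bool = True,
    use_free_guest: bool = False,
    max_points: Optional[int] = None,
    curvature_alpha: float = 0.05,
) -> SternVolmerResult:
    """Stern-Volmer fit of a titration series.

    ``use_corrected`` selects the inner-filter-corrected intensities (the
    excitation-side 10^(ΔA·d) factor); the x-axis is the added (total)
    quencher concentration by default, or the iterated free-guest
    concentration when ``use_free_guest`` is set.  ``max_points`` truncates
    to the first points, never silently (a warning is logged).
    """
    geometry = geometry or series.geometry
    F = (
        corrected_intensities(series, geometry=geometry)
        if use_corrected
        else series.intensities
    )
    if np.any(F <= 0):
        raise ValidationError("Stern-Volmer fit requires strictly positive intensities")
    Q = series.guest_totals
    host = series.host_totals
    if max_points is not None and max_points < Q.size:
        logger.warning(
            "Stern-Volmer fit truncated to first %d of %d points", max_points, Q.size
        )
        Q, F, host = Q[:max_points], F[:max_points], host[:max_points]
    ref = np.where(Q == 0.0)[0]
    F0 = float(F[ref[0]])
    ratio = F0 / F

    est = SternVolmer(fix_intercept=fix_intercept, curvature_alpha=curvature_alpha)
    est.fit(Q, ratio)
    if use_free_guest:
        K = max(est.K_, 0.0)
        for _ in range(100):
            Q_free = np.array(
                [
                    solve_equilibrium_1to1(K, h, g).free_guest
                    for h, g in zip(host, Q)
                ]
            )
            est.fit(Q_free, ratio)
            K_new = max(est.K_, 0.0)
            if abs(K_new - K) <= 1e-12 * max(K, 1.0):
                break
            K = K_new
    return SternVolmerResult(
        K=est.K_,
        K_stderr=est.K_stderr_,
        intercept=est.intercept_,
        r_squared=est.r_squared_,
        corrected=use_corrected,
        points_used=est.points_used_,
        curvature_flag=est.curvature_flag_,
        curvature_pvalue=est.curvature_pvalue_,
        residual_sd=est.residual_sd_,
    )


@dataclass(frozen=True)
class BindingFitResult:
    """Result of the global absorbance fit."""

    K: float
    K_stderr: float
    eps_complex: Spectrum
    residual_rms: float
    identifiable: bool


class GlobalAbsorbanceFit(BaseEstimator):
    """Global fit of a multi-wavelength absorbance titration to a 1:1 model.

    The model is mass action plus Beer-Lambert additivity:

        A(λ, i) = ε_H(λ) [H]_i + ε_G(λ) [G]_i + ε_HG(λ) [HG]_i,

    with speciation from the quadratic 1:1 solver.  The fit is separable:
    for fixed K the complex spectrum ε_HG(λ) ≥ 0 is a clipped linear
    least-squares solve per wavelength, so the outer optimisation is a
    bounded 1-D search over log10 K.  K ≥ 0 is enforced by parameterisation.

    The binding constant is flagged non-identifiable when the best-fit
    binding signal max|A_pred(K̂) − A_pred(0)| is below 3× the residual
    noise estimate — e.g. when ε_HG ≈ ε_H + ε_G, so complexation leaves
    the spectra unchanged.
    """

    def __init__(
        self,
        log10K_bounds: tuple = (-4.0, 8.0),
        identifiability_factor: float = 3.0,
    ):
        self.log10K_bounds = log10K_bounds
        self.identifiability_factor = identifiability_factor

    def fit(self, X, y=None, *, host_totals, guest_totals, eps_host, eps_guest):
        """Fit to an absorbance matrix X of shape (n_points, n_wavelengths).

        ``eps_host`` / ``eps_guest`` are molar absorptivity vectors (M^-1
        cm^-1) on the same wavelength grid, from pure-component spectra.
        """
        A = np.asarray(X, dtype=float)
        if A.ndim != 2:
            raise ValidationError("absorbance matrix must be 2-D (points x wavelengths)")
        n_pts, n_wl = A.shape
        if n_pts < 4:
            raise InsufficientDataError("global absorbance fit needs >= 4 points")
        host = np.asarray(host_totals, dtype=float)
        guest = np.asarray(guest_totals, dtype=float)
        eH = np.asarray(eps_host, dtype=float)
        eG = np.asarray(eps_guest, dtype=float)
        if host.size != n_pts or guest.size != n_pts:
            raise ValidationError("totals must match the number of titration points")
        if eH.size != n_wl or eG.size != n_wl:
            raise ValidationError("epsilon vectors must match the wavelength grid")

        def speciation(K):
            states = [
                solve_equilibrium_1to1(K, h, g) for h, g in zip(host, guest)
            ]
            fh = np.array([s.free_host for s in states])
            fg = np.array([s.free_guest for s in states])
            hg = np.array([s.complex for s in states])
            return fh, fg, hg

        def solve_eps_hg(K):
            fh, fg, hg = speciation(K)
            R = A - np.outer(fh, eH) - np.outer(fg, eG)
            s2 = float(hg @ hg)
            if s2 <= 0:
                return np.zeros(n_wl), R, hg
            eHG = np.clip(R.T @ hg / s2, 0.0, None)
            return eHG, R, hg

        def rss(log10K):
            K = 10.0**log10K
            eHG, R, hg = solve_eps_hg(K)
            resid = R - np.outer(hg, eHG)
            return float(np.sum(resid**2))

        lo, hi = self.log10K_bounds
        res = optimize.minimize_scalar(
            rss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
        )
        if not res.success:
            raise QuenchKitError(
                f"global absorbance fit did not converge (last log10K={res.x:.4g})"
            )
        K_hat = float(10.0**res.x)
        eHG, R, hg = solve_eps_hg(K_hat)
        resid = R - np.outer(hg, eHG)
        dof = max(n_pts * n_wl - (1 + n_wl), 1)
        sigma2 = float(np.sum(resid**2)) / dof
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))

        # stderr from the curvature of RSS(K) at the optimum
        dK = max(K_hat * 1e-3, 1e-12)
        f0 = rss(np.log10(K_hat))
        fp = rss(np.log10(K_hat + dK))
        fm = rss(np.log10(max(K_hat - dK, 1e-300)))
        d2 = (fp - 2 * f0 + fm) / dK**2
        self.K_stderr_ = float(np.sqrt(2 * sigma2 / d2)) if d2 > 0 else float("inf")

        # identifiability: does the fitted K produce a binding signal above noise?
        eHG0 = eH + eG  # no-binding prediction uses additivity of free species
        _, _, hg_hat = speciation(K_hat)
        A_hat = (
            np.outer(speciation(K_hat)[0], eH)
            + np.outer(speciation(K_hat)[1], eG)
            + np.outer(hg_hat, eHG)
        )
        A_null = np.outer(host, eH) + np.outer(guest, eG)
        signal = float(np.max(np.abs(A_hat - A_null)))
        noise = np.sqrt(sigma2)
        self.identifiable_ = bool(signal > self.identifiability_factor * noise)

        self.K_ = K_hat
        self.eps_complex_ = eHG
        return self


def global_absorbance_fit(
    spectra: Sequence[Spectrum],
    host_totals: Sequence[float],
    guest_totals: Sequence[float],
    eps_host: Spectrum,
    eps_guest: Spectrum,
    wavelength_window: Optional[tuple] = None,
) -> BindingFitResult:
    """Fit per-point absorbance spectra of a titration to the 1:1 model.

    All spectra must share the wavelength grid of ``eps_host``;
    ``wavelength_window`` restricts the fit to [lo, hi] nm.
    """
    wl = eps_host.wavelengths
    for s in list(spectra) + [eps_guest]:
        if s.wavelengths.size != wl.size or not np.allclose(s.wavelengths, wl):
            raise ValidationError("all spectra must share one wavelength grid")
    mask = np.ones(wl.size, dtype=bool)
    if wavelength_window is not None:
        mask = (wl >= wavelength_window[0]) & (wl <= wavelength_window[1])
    A = np.array([s.values for s in spectra])[:, mask]
    est = GlobalAbsorbanceFit()
    est.fit(
        A,
        host_totals=host_totals,
        guest_totals=guest_totals,
        eps_host=eps_host.values[mask],
        eps_guest=eps_guest.values[mask],
    )
    return BindingFitResult(
        K=est.K_,
        K_stderr=est.K_stderr_,
        eps_complex=Spectrum(wl[mask], est.eps_complex_, kind="absorbance")
        if np.all(est.eps_complex_ >= -0.01)
        else Spectrum(wl[mask], np.clip(est.eps_complex_, 0, None), kind="absorbance"),
        residual_rms=est.residual_rms_,
        identifiable=est.identifiable_,
    )


def classify_association(
    K: float,
    K_stderr: float,
    thresholds: tuple = (1.0, 100.0),
) -> str:
    """Classify an association constant as statistical, weak, or stable.

    ``statistical`` complexes exist only at the level expected from random
    proximity: K below ``thresholds[0]`` (default 1 M^-1) or not
    significantly above zero (K < 2 stderr).  ``stable`` requires K at or
    above ``thresholds[1]`` (default 100 M^-1) and significance.
    """
    if not (np.isfinite(K) and np.isfinite(K_stderr)):
        raise ValidationError("K and K_stderr must be finite")
    statistical_bound, stable_bound = thresholds
    significant = K >= 2.0 * K_stderr
    if K < statistical_bound or not significant:
        return "statistical"
    if K >= stable_bound:
        return "stable"
    return "weak"
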