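"""Inner filter effect (IFE) quantification and correction.

When a titrant absorbs at the excitation wavelength, the measured
fluorescence drops even without any excited-state interaction: part of the
excitation beam is absorbed before reaching the emitting volume sampled by
the detector.  For emission collected from the centre of a 1 cm cell the
correction follows directly from Beer's law,

    F_corr = F · 10^(ΔA · d_eff),

where ΔA = A − A0 is the absorbance change at the excitation wavelength
(1 cm basis) relative to the titrant-free reference and d_eff is the
effective excitation pathlength (default 0.5 cm, giving the familiar
10^(ΔA/2) factor).  An analogous factor with the absorbance at the emission
wavelength corrects the emission-side IFE; it is off by default.

The correction factor depends on the emitting area sampled by the detector:
the default geometry assumes centre-of-cell detection and should be checked
against the actual fluorimeter before use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Geometry, QuenchKitError, Spectrum, TitrationSeries, ValidationError

logger = logging.getLogger("quenchkit")

__all__ = [
    "IfeAssessment",
    "delta_absorbance",
    "correct_excitation_ife",
    "correct_emission_ife",
    "corrected_intensities",
    "screen_inner_filter",
    "InnerFilterCorrection",
    "MissingAbsorbanceError",
]


class MissingAbsorbanceError(QuenchKitError):
    """Absorbance data needed for the IFE correction are absent."""


def delta_absorbance(
    series: TitrationSeries,
    wavelength: str = "lambda_ex",
    spectra: Optional[Sequence[Spectrum]] = None,
) -> np.ndarray:
    """Per-point absorbance change ΔA = A − A0 at λex or λem (1 cm basis).

    Uses the per-point A_ex / A_em columns, or, when ``spectra`` (one
    absorption spectrum per titration point, in point order) is given,
    linear interpolation of each spectrum at the requested wavelength.
    The zero-guest reference point maps to ΔA = 0 exactly.
    """
    if wavelength not in ("lambda_ex", "lambda_em"):
        raise ValidationError("wavelength must be 'lambda_ex' or 'lambda_em'")
    lam = getattr(series, wavelength)
    if spectra is not None:
        if len(spectra) != len(series.points):
            raise ValidationError("need one spectrum per titration point")
        A = np.array([s.at(lam) for s in spectra])
    else:
        col = "A_ex" if wavelength == "lambda_ex" else "A_em"
        A = series.absorbances(col)
        if A is None:
            raise MissingAbsorbanceError(
                f"no {col} data on this series; supply a UV-Vis titration "
                "(per-point absorbances or spectra) to assess the inner filter effect"
            )
    ref_idx = int(np.where(series.guest_totals == 0.0)[0][0])
    dA = A - A[ref_idx]
    dA[ref_idx] = 0.0
    return dA


def correct_excitation_ife(F, delta_A_ex, geometry: Optional[Geometry] = None):
    """Remove the excitation inner filter effect from measured intensities.

    Returns F · 10^(ΔA_ex · d_ex / 1 cm) with d_ex the effective excitation
    pathlength; the default geometry (0.5 cm) gives the 10^(ΔA/2) factor.
    Negative ΔA (titrant bleaching absorbance at λex) is allowed and gives
    factors < 1, with a logged warning.
    """
    geometry = geometry or Geometry()
    F = np.asarray(F, dtype=float)
    dA = np.asarray(delta_A_ex, dtype=float)
    if np.any(F < 0):
        raise ValidationError("fluorescence intensities must be >= 0")
    if np.any(dA < 0):
        logger.warning(
            "negative ΔA at the excitation wavelength: correction factor < 1"
        )
    factor = 10.0 ** (dA * geometry.eff_excitation_path_cm)
    out = F * factor
    return out if out.ndim else float(out)


def correct_emission_ife(F, delta_A_em, geometry: Optional[Geometry] = None):
    """Symmetric emission-side factor 10^(ΔA_em · d_em); off by default upstream."""
    geometry = geometry or Geometry()
    F = np.asarray(F, dtype=float)
    dA = np.asarray(delta_A_em, dtype=float)
    if np.any(F < 0):
        raise ValidationError("fluorescence intensities must be >= 0")
    out = F * 10.0 ** (dA * geometry.eff_emission_path_cm)
    return out if out.ndim else float(out)


def corrected_intensities(
    series: TitrationSeries,
    geometry: Optional[Geometry] = None,
    emission_correction: bool = False,
    spectra: Optional[Sequence[Spectrum]] = None,
) -> np.ndarray:
    """Inner-filter-corrected intensities for every point of a titration."""
    geometry = geometry or series.geometry
    dA_ex = delta_absorbance(series, "lambda_ex", spectra=spectra)
    F = correct_excitation_ife(series.intensities, dA_ex, geometry)
    if emission_correction:
        dA_em = delta_absorbance(series, "lambda_em", spectra=spectra)
        F = correct_emission_ife(F, dA_em, geometry)
    return F


@dataclass(frozen=True)
class IfeAssessment:
    """Screening verdict on inner-filter severity for a titration."""

    max_delta_A_ex: float
    max_delta_A_em: Optional[float]
    verdict: str  # negligible | correct_required | redesign_suggested
    per_point_factors: np.ndarray
    emission_warning: bool


def screen_inner_filter(
    series: TitrationSeries,
    thresholds: tuple = (0.01, 1.0),
    geometry: Optional[Geometry] = None,
    spectra: Optional[Sequence[Spectrum]] = None,
) -> IfeAssessment:
    """Screen a titration for inner-filter risk before any binding analysis.

    Verdicts on max ΔA at the excitation wavelength:
    below ``thresholds[0]`` (default 0.01 AU) → ``negligible``;
    above ``thresholds[1]`` (default 1.0 AU, correction factor > ~3 at the
    default geometry) → ``redesign_suggested`` (change the excitation
    wavelength or use a shorter-path cell); otherwise ``correct_required``.
    Emission-side ΔA above the negligible bound only raises a warning flag;
    with no absorbance data at λem the emission side is not assessed.
    """
    negligible_AU, redesign_AU = thresholds
    geometry = geometry or series.geometry
    dA_ex = delta_absorbance(series, "lambda_ex", spectra=spectra)
    max_ex = float(np.max(dA_ex))
    if max_ex < negligible_AU:
        verdict = "negligible"
    elif max_ex > redesign_AU:
        verdict = "redesign_suggested"
    else:
        verdict = "correct_required"
    try:
        dA_em = delta_absorbance(series, "lambda_em", spectra=spectra)
        max_em: Optional[float] = float(np.max(dA_em))
        emission_warning = max_em >= negligible_AU
    except MissingAbsorbanceError:
        max_em, emission_warning = None, False
    factors = 10.0 ** (dA_ex * geometry.eff_excitation_path_cm)
    return IfeAssessment(
        max_delta_A_ex=max_ex,
        max_delta_A_em=max_em,
        verdict=verdict,
        per_point_factors=factors,
        emission_warning=emission_warning,
    )


class InnerFilterCorrection(BaseEstimator, TransformerMixin):
    """Stateless transformer applying the inner-filter correction to arrays.

    Expects X with columns (F, ΔA_ex) or (F, ΔA_ex, ΔA_em); transform
    returns a copy with the intensity column corrected.  Composes with
    sklearn pipelines ahead of a Stern-Volmer regression.
    """

    def __init__(
        self,
        eff_excitation_path_cm: float = 0.5,
        eff_emission_path_cm: float = 0.5,
        emission_correction: bool = False,
    ):
        self.eff_excitation_path_cm = eff_excitation_path_cm
        self.eff_emission_path_cm = eff_emission_path_cm
        self.emission_correction = emission_correction

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValidationError("X must have columns (F, dA_ex[, dA_em])")
        geom = Geometry(
            cell_path_cm=max(
                1.0, self.eff_excitation_path_cm, self.eff_emission_path_cm
            ),
            eff_excitation_path_cm=self.eff_excitation_path_cm,
            eff_emission_path_cm=self.eff_emission_path_cm,
        )
        out = X.copy()
        out[:, 0] = correct_excitation_ife(X[:, 0], X[:, 1], geom)
        if self.emission_correction:
            if X.shape[1] < 3:
                raise ValidationError("emission correction needs a dA_em column")
            out[:, 0] = correct_emission_ife(out[:, 0], X[:, 2], geom)
        return out
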