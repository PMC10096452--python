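"""Synthetic titrations and TCSPC decays with known ground truth.

The generators emulate the cell-by-cell titration design used in host-guest
quenching studies: a fixed receptor concentration (10-20 μM), titrant up to
~30 equivalents (< 200-300 μM), 1:1 static quenching with a non-emissive
complex, and a titrant that absorbs at the excitation wavelength.  The
fluorescence simulator *applies* the excitation inner-filter attenuation
10^(−ΔA·d_eff) that the correction removes, so the overestimation of K from
uncorrected data — and its removal by the correction — are reproducible
with known ground truth.

Noise model: multiplicative Gaussian on intensities (default 1% relative)
and additive Gaussian on absorbances (default 0.2% of the value), typical
photometric precision.  Every generator is deterministic given its seed;
replicate suites derive per-replicate seeds as seed + replicate index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .binding import solve_equilibrium_1to1
from .io import (
    DecayHistogram,
    Geometry,
    Spectrum,
    TitrationPoint,
    TitrationSeries,
    ValidationError,
)
from .lifetime import DecayModel, convolve_with_irf, gaussian_irf

__all__ = [
    "SimulationScenario",
    "DecayScenario",
    "simulate_fluorescence_titration",
    "simulate_absorbance_titration",
    "simulate_decay",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Ground truth for a 1:1 titration simulation.

    ``eps_*`` are molar absorptivities at the excitation wavelength
    (M^-1 cm^-1); optional per-wavelength spectra drive the absorbance
    simulator.  ``complex_emissive_fraction`` = 0 means a fully quenched
    (non-emissive) complex, the standard static-quenching picture.
    """

    K_true: float
    host_total: float
    guest_grid: tuple
    eps_host: float = 0.0
    eps_guest: float = 0.0
    eps_complex: float = 0.0
    eps_host_spectrum: Optional[Spectrum] = None
    eps_guest_spectrum: Optional[Spectrum] = None
    eps_complex_spectrum: Optional[Spectrum] = None
    complex_emissive_fraction: float = 0.0
    F0: float = 1000.0
    noise_rel_F: float = 0.01
    noise_rel_A: float = 0.002
    lambda_ex: float = 300.0
    lambda_em: float = 375.0
    geometry: Geometry = field(default_factory=Geometry)
    complexation_changes_absorbance: bool = False
    eps_guest_em: float = 0.0
    emission_ife: bool = False
    seed: int = 0

    def __post_init__(self):
        grid = tuple(float(g) for g in self.guest_grid)
        object.__setattr__(self, "guest_grid", grid)
        if self.K_true < 0:
            raise ValidationError("K_true must be >= 0")
        if self.host_total < 0:
            raise ValidationError("host_total must be >= 0")
        if 0.0 not in grid:
            raise ValidationError("guest_grid must contain the zero reference")
        if any(g < 0 for g in grid):
            raise ValidationError("guest concentrations must be >= 0")
        for name in ("eps_host", "eps_guest", "eps_complex", "eps_guest_em"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0")
        if not 0.0 <= self.complex_emissive_fraction <= 1.0:
            raise ValidationError("complex_emissive_fraction must be in [0, 1]")


def _speciation(scn: SimulationScenario):
    guests = np.sort(np.array(scn.guest_grid))
    states = [solve_equilibrium_1to1(scn.K_true, scn.host_total, g) for g in guests]
    return guests, states


def simulate_fluorescence_titration(scn: SimulationScenario) -> TitrationSeries:
    """Simulate a cell-by-cell fluorescence titration with excitation IFE.

    The true emitted intensity is proportional to the emissive host
    population, [H]_free + f_em·[HG]; the observed intensity is attenuated
    by 10^(−ΔA_ex · d_ex) where ΔA_ex is the absorbance gain at the
    excitation wavelength relative to the zero-guest reference (dominated
    by the titrant: ΔA_ex = ε_G · [G]_total for the default scenario).
    The A_ex column is populated so the correction is applicable downstream.
    """
    rng = np.random.default_rng(scn.seed)
    guests, states = _speciation(scn)
    d_ex = scn.geometry.eff_excitation_path_cm
    d_em = scn.geometry.eff_emission_path_cm

    host_ref = scn.host_total
    A0_ex = scn.eps_host * host_ref
    points = []
    for g, st in zip(guests, states):
        emissive = st.free_host + scn.complex_emissive_fraction * st.complex
        F_true = scn.F0 * (emissive / host_ref if host_ref > 0 else 0.0)
        if scn.complexation_changes_absorbance:
            A_ex = (
                scn.eps_host * st.free_host
                + scn.eps_guest * st.free_guest
                + scn.eps_complex * st.complex
            )
        else:
            A_ex = scn.eps_host * host_ref + scn.eps_guest * g
        dA_ex = A_ex - A0_ex
        F_obs = F_true * 10.0 ** (-dA_ex * d_ex)
        A_em = None
        if scn.emission_ife:
            dA_em = scn.eps_guest_em * g
            F_obs *= 10.0 ** (-dA_em * d_em)
            A_em = dA_em  # host assumed transparent at its own emission maximum
        if scn.noise_rel_F > 0:
            F_obs *= 1.0 + scn.noise_rel_F * rng.standard_normal()
        if scn.noise_rel_A > 0:
            A_ex += scn.noise_rel_A * abs(A_ex) * rng.standard_normal()
            if A_em is not None:
                A_em += scn.noise_rel_A * abs(A_em) * rng.standard_normal()
        points.append(
            TitrationPoint(
                host_total=host_ref,
                guest_total=float(g),
                F=max(float(F_obs), 0.0),
                A_ex=float(A_ex),
                A_em=None if A_em is None else float(A_em),
            )
        )
    return TitrationSeries(
        points=tuple(points),
        lambda_ex=scn.lambda_ex,
        lambda_em=scn.lambda_em,
        geometry=scn.geometry,
        mode="cell_by_cell",
        label=f"synthetic fluorescence titration (K_true={scn.K_true:g} M^-1)",
    )


def _default_flat_spectrum(scn: SimulationScenario, value: float) -> Spectrum:
    lo = max(220.0, scn.lambda_ex - 60.0)
    wl = np.linspace(lo, scn.lambda_ex + 60.0, 25)
    return Spectrum(wl, np.full(wl.size, value), kind="absorbance")


def simulate_absorbance_titration(
    scn: SimulationScenario,
) -> Tuple[TitrationSeries, list]:
    """Simulate a UV-Vis absorption titration: per-point spectra plus series.

    Each spectrum is the Beer-Lambert sum ε_H(λ)[H] + ε_G(λ)[G] +
    ε_HG(λ)[HG] on a 1 cm path, with speciation from the 1:1 solver and
    additive Gaussian noise.  Scalar ε values stand in as flat spectra when
    per-wavelength spectra are not supplied.  Returns (series, spectra);
    the series' A_ex column is the (noisy) spectrum read at λex and its F
    column is zero (no emission is simulated here).
    """
    rng = np.random.default_rng(scn.seed)
    eH = scn.eps_host_spectrum or _default_flat_spectrum(scn, scn.eps_host)
    eG = scn.eps_guest_spectrum or _default_flat_spectrum(scn, scn.eps_guest)
    eHG = scn.eps_complex_spectrum or _default_flat_spectrum(scn, scn.eps_complex)
    wl = eH.wavelengths
    for s in (eG, eHG):
        if s.wavelengths.size != wl.size or not np.allclose(s.wavelengths, wl):
            raise ValidationError("epsilon spectra must share one wavelength grid")

    guests, states = _speciation(scn)
    spectra, points = [], []
    for g, st in zip(guests, states):
        A = (
            eH.values * st.free_host
            + eG.values * st.free_guest
            + eHG.values * st.complex
        )
        if scn.noise_rel_A > 0:
            A = A + scn.noise_rel_A * np.abs(A) * rng.standard_normal(A.size)
        spec = Spectrum(wl, np.clip(A, -0.01, None), kind="absorbance")
        spectra.append(spec)
        points.append(
            TitrationPoint(
                host_total=scn.host_total,
                guest_total=float(g),
                F=0.0,
                A_ex=spec.at(scn.lambda_ex) if wl[0] <= scn.lambda_ex <= wl[-1] else None,
            )
        )
    series = TitrationSeries(
        points=tuple(points),
        lambda_ex=scn.lambda_ex,
        lambda_em=scn.lambda_em,
        geometry=scn.geometry,
        mode="cell_by_cell",
        label=f"synthetic absorbance titration (K_true={scn.K_true:g} M^-1)",
    )
    return series, spectra


@dataclass(frozen=True)
class DecayScenario:
    """Ground truth for a TCSPC decay simulation.

    ``irf``: "delta", ("gaussian", center_ns, fwhm_ns), or a measured
    histogram array on the channel grid.  ``poisson=False`` returns the
    noise-free expected counts (rounded) for exactness checks.
    """

    model: DecayModel
    irf: Union[str, tuple, np.ndarray] = "delta"
    peak_counts: float = 1e4
    channels: int = 1024
    channel_width: float = 0.05
    background: float = 0.0
    poisson: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.peak_counts <= 0 or self.channels < 2 or self.channel_width <= 0:
            raise ValidationError("invalid decay scenario dimensions")
        if self.background < 0:
            raise ValidationError("background must be >= 0")


def _irf_array(scn: DecayScenario, grid: np.ndarray) -> Optional[np.ndarray]:
    if isinstance(scn.irf, str):
        if scn.irf == "delta":
            return None
        raise ValidationError(f"unknown IRF spec {scn.irf!r}")
    if isinstance(scn.irf, tuple) and scn.irf[0] == "gaussian":
        _, center, fwhm = scn.irf
        return gaussian_irf(grid, center, fwhm)
    arr = np.asarray(scn.irf, dtype=float)
    if arr.size != grid.size:
        raise ValidationError("measured IRF must share the channel grid")
    return arr


def simulate_decay(scn: DecayScenario) -> DecayHistogram:
    """Simulate a TCSPC histogram: (model ⊛ IRF), scaled, Poisson-sampled.

    Expected counts are the model reconvolved with the unit-area IRF,
    scaled so the maximum equals ``peak_counts``, plus the constant
    background; observed counts are independent Poisson variates
    (deterministic given the seed), or the rounded expectation when
    ``poisson=False``.
    """
    grid = np.arange(scn.channels) * scn.channel_width
    irf = _irf_array(scn, grid)
    base = DecayModel(
        amplitudes=scn.model.amplitudes,
        lifetimes=scn.model.lifetimes,
        shift=scn.model.shift,
        background=0.0,
    )
    expected = convolve_with_irf(base, irf, grid)
    peak = expected.max()
    if peak <= 0:
        raise ValidationError("decay model produced no signal on the grid")
    expected = expected * (scn.peak_counts / peak) + scn.background
    if scn.poisson:
        rng = np.random.default_rng(scn.seed)
        counts = rng.poisson(expected)
    else:
        counts = np.round(expected)
    irf_counts = None
    if irf is not None:
        irf_counts = np.round(irf * (scn.peak_counts / irf.max()))
    return DecayHistogram(channel_time=grid, counts=counts, irf_counts=irf_counts)
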