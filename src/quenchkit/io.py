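"""Data model and delimited-text readers for titrations, spectra and decays.

Internal unit conventions: concentrations are mol/L, wavelengths nm,
absorbances AU normalised to a 1 cm path, times ns.  Readers accept a
units declaration in the schema map and convert on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("quenchkit")

__all__ = [
    "QuenchKitError",
    "SchemaError",
    "ValidationError",
    "ReferencePointError",
    "GridError",
    "CountError",
    "Spectrum",
    "Geometry",
    "TitrationPoint",
    "TitrationSeries",
    "DecayHistogram",
    "read_titration_series",
    "write_titration_series",
    "read_decay_histogram",
    "write_decay_histogram",
]


class QuenchKitError(ValueError):
    """Base class for all validation and fitting errors raised here."""


class SchemaError(QuenchKitError):
    """A required column is missing or a units declaration is invalid."""


class ValidationError(QuenchKitError):
    """A value violates a physical invariant (negative concentration, ...)."""


class ReferencePointError(QuenchKitError):
    """The mandatory zero-titrant reference point is absent or duplicated."""


class GridError(QuenchKitError):
    """A time or wavelength grid is non-uniform or non-monotonic."""


class CountError(QuenchKitError):
    """Photon counts are fractional or negative."""


_CONCENTRATION_UNITS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "nM": 1e-9,
}


@dataclass(frozen=True)
class Spectrum:
    """A wavelength grid with absorbance or emission values.

    Absorbance values are per 1 cm path.  A small negative baseline
    (≥ −0.01 AU) is tolerated, as produced by baseline subtraction.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "absorbance"  # "absorbance" | "emission"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValidationError("wavelengths and values must be 1-D and equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise GridError("spectrum wavelengths must be strictly increasing")
        if self.kind not in ("absorbance", "emission"):
            raise ValidationError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "absorbance" and np.any(vals < -0.01):
            raise ValidationError("absorbance below -0.01 AU baseline tolerance")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("spectrum values must be finite")

    def at(self, wavelength: float) -> float:
        """Value at `wavelength` by linear interpolation between bracketing points."""
        wl = self.wavelengths
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise ValidationError(
                f"wavelength {wavelength} nm outside spectrum range [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength, wl, self.values))


@dataclass(frozen=True)
class Geometry:
    """Optical geometry of the fluorescence cell.

    ``eff_excitation_path_cm`` is the effective pathlength travelled by the
    excitation beam before the emitting volume sampled by the detector; the
    default 0.5 cm (centre of a 1 cm cell) reproduces the standard
    F_corr = 10^(ΔA/2) · F excitation inner-filter correction.
    """

    cell_path_cm: float = 1.0
    eff_excitation_path_cm: float = 0.5
    eff_emission_path_cm: float = 0.5

    def __post_init__(self):
        if self.cell_path_cm <= 0:
            raise ValidationError("cell_path_cm must be > 0")
        for name in ("eff_excitation_path_cm", "eff_emission_path_cm"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0")
            if v > self.cell_path_cm:
                raise ValidationError(f"{name} exceeds cell_path_cm")


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: total concentrations, absorbances, intensity.

    ``A_ex`` / ``A_em`` are absorbances at the excitation / emission
    wavelengths, per 1 cm path.  The zero-guest point carries F0 and A0.
    """

    host_total: float
    guest_total: float
    F: float
    A_ex: Optional[float] = None
    A_em: Optional[float] = None

    def __post_init__(self):
        if self.host_total < 0 or self.guest_total < 0:
            raise ValidationError("total concentrations must be >= 0")
        if not np.isfinite(self.F) or self.F < 0:
            raise ValidationError("fluorescence intensity must be finite and >= 0")
        for name in ("A_ex", "A_em"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValidationError(f"{name} must be finite")


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered cell-by-cell (or cumulative) titration at fixed host.

    Exactly one point must have ``guest_total == 0``: it is the reference
    defining F0 and A0 for the inner-filter correction.  In ``cell_by_cell``
    mode the host total must be constant across points.
    """

    points: tuple
    lambda_ex: float
    lambda_em: float
    geometry: Geometry = field(default_factory=Geometry)
    mode: str = "cell_by_cell"
    label: str = ""

    def __post_init__(self):
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        if self.mode not in ("cell_by_cell", "cumulative_addition"):
            raise ValidationError(f"unknown titration mode {self.mode!r}")
        guests = np.array([p.guest_total for p in pts])
        if not np.all(np.diff(guests) >= 0):
            raise ValidationError("points must be sorted by ascending guest_total")
        n_ref = int(np.sum(guests == 0.0))
        if n_ref != 1:
            raise ReferencePointError(
                f"exactly one zero-guest reference point required, found {n_ref}"
            )
        if self.mode == "cell_by_cell" and len(pts) > 1:
            hosts = np.array([p.host_total for p in pts])
            scale = max(hosts.max(), 1e-300)
            if (hosts.max() - hosts.min()) / scale > 1e-9:
                raise ValidationError(
                    "host_total must be constant across points in cell_by_cell mode"
                )

    @property
    def reference(self) -> TitrationPoint:
        return next(p for p in self.points if p.guest_total == 0.0)

    @property
    def guest_totals(self) -> np.ndarray:
        return np.array([p.guest_total for p in self.points])

    @property
    def host_totals(self) -> np.ndarray:
        return np.array([p.host_total for p in self.points])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.F for p in self.points])

    def absorbances(self, which: str = "A_ex") -> Optional[np.ndarray]:
        vals = [getattr(p, which) for p in self.points]
        if any(v is None for v in vals):
            return None
        return np.array(vals, dtype=float)


@dataclass(frozen=True)
class DecayHistogram:
    """A TCSPC decay: counts per uniformly spaced time channel.

    ``irf_counts``, when present, is the measured instrument response on the
    same grid; without it, reconvolution fits must use an analytic IRF.
    """

    channel_time: np.ndarray
    counts: np.ndarray
    irf_counts: Optional[np.ndarray] = None

    def __post_init__(self):
        t = np.asarray(self.channel_time, dtype=float)
        c = np.asarray(self.counts)
        object.__setattr__(self, "channel_time", t)
        if t.ndim != 1 or t.size < 2:
            raise GridError("channel_time must be 1-D with at least 2 channels")
        dt = np.diff(t)
        if np.any(dt <= 0) or (dt.max() - dt.min()) / dt.mean() > 1e-6:
            raise GridError("channel spacing must be uniform (1e-6 relative)")
        c_float = np.asarray(c, dtype=float)
        if np.any(c_float < 0):
            raise CountError("counts must be >= 0")
        if np.any(np.abs(c_float - np.round(c_float)) > 1e-9):
            raise CountError("counts must be integral")
        object.__setattr__(self, "counts", np.round(c_float).astype(np.int64))
        if self.irf_counts is not None:
            irf = np.asarray(self.irf_counts, dtype=float)
            if irf.size != t.size:
                raise GridError("IRF must share the decay time grid")
            if np.any(irf < 0) or np.any(np.abs(irf - np.round(irf)) > 1e-9):
                raise CountError("IRF counts must be integral and >= 0")
            object.__setattr__(self, "irf_counts", np.round(irf).astype(np.int64))

    @property
    def channel_width(self) -> float:
        return float(np.mean(np.diff(self.channel_time)))


_DEFAULT_SCHEMA = {
    "host_total": "host_total",
    "guest_total": "guest_total",
    "F": "F",
    "A_ex": "A_ex",
    "A_em": "A_em",
    "concentration_unit": "M",
}


def _read_table(path) -> pd.DataFrame:
    # sep=None + python engine sniffs comma/tab/semicolon
    return pd.read_csv(path, sep=None, engine="python")


def read_titration_series(
    path,
    schema: Optional[dict] = None,
    geometry: Optional[Geometry] = None,
    lambda_ex: float = 300.0,
    lambda_em: float = 375.0,
    mode: str = "cell_by_cell",
    label: str = "",
) -> TitrationSeries:
    """Read a titration table from delimited text.

    The schema map renames columns and declares the concentration unit
    (``M``, ``mM``, ``uM``/``μM``, ``nM``); concentrations are converted to
    mol/L on read.  Rows are sorted by ascending guest concentration (with a
    logged warning if the file was out of order) and exactly one zero-guest
    reference row must be present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sch = dict(_DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    unit = sch["concentration_unit"]
    if unit not in _CONCENTRATION_UNITS:
        raise SchemaError(f"unknown concentration unit {unit!r}")
    conv = _CONCENTRATION_UNITS[unit]

    df = _read_table(path)
    for req in ("host_total", "guest_total", "F"):
        if sch[req] not in df.columns:
            raise SchemaError(f"required column {sch[req]!r} missing from {path.name}")

    host = df[sch["host_total"]].to_numpy(dtype=float) * conv
    guest = df[sch["guest_total"]].to_numpy(dtype=float) * conv
    F = df[sch["F"]].to_numpy(dtype=float)
    for arr, name in ((host, "host_total"), (guest, "guest_total")):
        bad = np.where(arr < 0)[0]
        if bad.size:
            raise ValidationError(
                f"negative {name} in row(s) {bad.tolist()} of {path.name}"
            )
    bad = np.where(~(np.isfinite(F) & (F >= 0)))[0]
    if bad.size:
        raise ValidationError(f"invalid F in row(s) {bad.tolist()} of {path.name}")

    def _opt(col):
        if sch[col] in df.columns:
            return df[sch[col]].to_numpy(dtype=float)
        return None

    A_ex, A_em = _opt("A_ex"), _opt("A_em")

    order = np.argsort(guest, kind="stable")
    if not np.array_equal(order, np.arange(len(guest))):
        logger.warning("titration rows in %s were not sorted; reordering", path.name)

    points = []
    for i in order:
        points.append(
            TitrationPoint(
                host_total=host[i],
                guest_total=guest[i],
                F=F[i],
                A_ex=None if A_ex is None else float(A_ex[i]),
                A_em=None if A_em is None else float(A_em[i]),
            )
        )
    return TitrationSeries(
        points=tuple(points),
        lambda_ex=lambda_ex,
        lambda_em=lambda_em,
        geometry=geometry or Geometry(),
        mode=mode,
        label=label or path.stem,
    )


def write_titration_series(series: TitrationSeries, path) -> None:
    """Write a titration table (concentrations in mol/L) as CSV."""
    rows = {
        "host_total": series.host_totals,
        "guest_total": series.guest_totals,
        "F": series.intensities,
    }
    for col in ("A_ex", "A_em"):
        vals = series.absorbances(col)
        if vals is not None:
            rows[col] = vals
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decay_histogram(path) -> DecayHistogram:
    """Read a decay histogram: columns (time_ns, counts[, irf_counts])."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    if df.shape[1] < 2 or df.shape[1] > 3:
        raise SchemaError(
            f"decay file {path.name} must have 2 or 3 columns, found {df.shape[1]}"
        )
    cols = [df.iloc[:, i].to_numpy(dtype=float) for i in range(df.shape[1])]
    irf = cols[2] if len(cols) == 3 else None
    return DecayHistogram(channel_time=cols[0], counts=cols[1], irf_counts=irf)


def write_decay_histogram(hist: DecayHistogram, path) -> None:
    cols = {"time_ns": hist.channel_time, "counts": hist.counts}
    if hist.irf_counts is not None:
        cols["irf_counts"] = hist.irf_counts
    pd.DataFrame(cols).to_csv(path, index=False)
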