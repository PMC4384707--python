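"""MIRD-formalism organ dosimetry for alpha-emitting radionuclides.

The mean absorbed dose to an organ is

.. math::

    \\bar{D}_\\mathrm{organ}
        = \\frac{\\tilde{A}_\\mathrm{organ} \\sum_i n_i E_i \\Phi_i}
               {m_\\mathrm{organ}},

where :math:`\\tilde{A}` is the cumulated activity (total decays in the
organ over the integration window), :math:`n_i` the yield of radiation
:math:`i` per decay, :math:`E_i` its energy, :math:`\\Phi_i` the absorbed
fraction and :math:`m` the organ mass.  For short-range alpha particles
the absorbed fraction is 1 and only alpha lines contribute, which is the
regime this module targets (211At and its 211Po daughter).

Cumulated activity is obtained by trapezoidal integration of the
per-organ time-activity curve; curves ending before the dose window can
be extended under the assumption of an invariant biodistribution, i.e.
the decay-corrected organ content is held at its last observed level and
only physical decay continues.

Units: time in hours, activity in Bq (whole organ), energy in MeV, mass
in kg, dose in mGy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: CODATA: joules per MeV.
MEV_TO_J = 1.602176634e-13

#: Seconds per hour, converting Bq*h to decays.
BQ_H_TO_DECAYS = 3600.0

#: Physical half-life of 211At in hours (standard decay data).
AT211_HALF_LIFE_H = 7.214

#: Alpha spectrum of 211At in transient equilibrium with its 211Po
#: daughter: the direct alpha branch (41.8%, 5.87 MeV) and the
#: EC -> 211Po branch whose prompt alpha carries 7.45 MeV (58.2%).
#: Branching ratios are external constants from standard decay data and
#: can be overridden via a user nuclide file.
AT211_LINES: tuple[tuple[float, float], ...] = ((0.418, 5.87), (0.582, 7.45))


class DosimetryError(ValueError):
    """Raised for unusable nuclide, curve, or geometry definitions."""


@dataclass(frozen=True)
class NuclideAlphaSpectrum:
    """Alpha emission lines of a nuclide (including daughter branches).

    Parameters
    ----------
    lines
        Sequence of ``(yield, energy_mev)`` pairs; yields are per decay
        of the parent and dimensionless in (0, 1], energies in MeV.
    half_life_h
        Physical half-life in hours.
    """

    lines: tuple[tuple[float, float], ...]
    half_life_h: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lines", tuple((float(n), float(e)) for n, e in self.lines))
        for n, e in self.lines:
            if not 0.0 < n <= 1.0:
                raise DosimetryError(f"line yield {n} outside (0, 1]")
            if e <= 0.0:
                raise DosimetryError(f"line energy {e} MeV must be positive")
        if self.half_life_h <= 0.0:
            raise DosimetryError("half-life must be positive")

    @property
    def decay_constant(self) -> float:
        """Physical decay constant lambda = ln2 / T_1/2, in 1/h."""
        return math.log(2.0) / self.half_life_h


#: Default nuclide: 211At (+ 211Po daughter alpha).
AT211_SPECTRUM = NuclideAlphaSpectrum(lines=AT211_LINES, half_life_h=AT211_HALF_LIFE_H)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-organ activity versus time, the integrand of cumulated activity.

    ``decay_corrected=True`` means physical decay has been divided out of
    the stored activities (common for literature biodistribution data);
    conversion back to physical activity then needs the nuclide
    half-life.
    """

    organ: str
    times_h: np.ndarray
    activities_bq: np.ndarray
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.activities_bq, dtype=float)
        if t.ndim != 1 or t.size == 0 or a.shape != t.shape:
            raise DosimetryError("curve needs >=1 (time, activity) sample")
        if np.any(np.diff(t) <= 0):
            raise DosimetryError(f"times for organ {self.organ!r} must be strictly increasing")
        if np.any(a < 0):
            raise DosimetryError(f"negative activity in curve for organ {self.organ!r}")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "activities_bq", a)

    def to_physical(self, half_life_h: float) -> "TimeActivityCurve":
        """Multiply decay-corrected activities by exp(-lambda*t)."""
        if not self.decay_corrected:
            return self
        lam = math.log(2.0) / half_life_h
        return replace(
            self,
            activities_bq=self.activities_bq * np.exp(-lam * self.times_h),
            decay_corrected=False,
        )

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return replace(self, activities_bq=self.activities_bq * factor)


@dataclass(frozen=True)
class OrganGeometry:
    """Mass and absorbed fraction of a source(=target) organ.

    The absorbed fraction defaults to 1, appropriate for alpha particles
    whose range (tens of micrometres) is far below organ dimensions.
    """

    organ: str
    mass_kg: float
    absorbed_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mass_kg <= 0.0:
            raise DosimetryError(f"organ {self.organ!r}: mass must be positive")
        if not 0.0 < self.absorbed_fraction <= 1.0:
            raise DosimetryError(f"organ {self.organ!r}: absorbed fraction outside (0, 1]")


@dataclass(frozen=True)
class OrganDose:
    """One dosimetry result: organ, window, cumulated activity, dose."""

    organ: str
    window_h: tuple[float, float]
    cumulated_activity: float  # decays
    mean_dose_mgy: float

    def __post_init__(self) -> None:
        t0, t1 = self.window_h
        if t1 <= t0:
            raise DosimetryError("window end must exceed window start")
        if self.mean_dose_mgy < 0.0:
            raise DosimetryError("mean dose cannot be negative")


def mean_alpha_energy_per_decay(spectrum: NuclideAlphaSpectrum) -> float:
    """Energy emitted as alpha particles per decay, sum(n_i * E_i), in MeV.

    Independent of line ordering; raises for an empty spectrum.
    """
    if not spectrum.lines:
        raise DosimetryError("empty alpha spectrum: nuclide definition unusable")
    return float(sum(n * e for n, e in spectrum.lines))


def extend_curve(
    curve: TimeActivityCurve,
    horizon_h: float,
    half_life_h: float,
    grid_step_h: float | None = None,
) -> TimeActivityCurve:
    """Extend a curve beyond its last sample assuming invariant biodistribution.

    The decay-corrected organ content is held at its last observed level;
    the physical activity therefore continues as a pure exponential with
    the physical decay constant.  For a decay-corrected curve this means
    appending a constant level; for a physical curve the last value is
    propagated as ``A_last * exp(-lambda * (t - t_last))``.

    ``horizon_h <= last sample time`` is a documented no-op returning the
    input unchanged.  The appended grid step defaults to
    ``half_life_h / 16``, small enough that trapezoidal integration of
    the exponential tail is accurate to well under 0.1%.
    """
    t_last = float(curve.times_h[-1])
    if horizon_h <= t_last:
        return curve
    if grid_step_h is None:
        grid_step_h = half_life_h / 16.0
    n = max(1, int(math.ceil((horizon_h - t_last) / grid_step_h)))
    new_t = np.linspace(t_last, horizon_h, n + 1)[1:]
    a_last = float(curve.activities_bq[-1])
    if curve.decay_corrected:
        new_a = np.full_like(new_t, a_last)
    else:
        lam = math.log(2.0) / half_life_h
        new_a = a_last * np.exp(-lam * (new_t - t_last))
    return replace(
        curve,
        times_h=np.concatenate([curve.times_h, new_t]),
        activities_bq=np.concatenate([curve.activities_bq, new_a]),
    )


def cumulated_activity(
    curve: TimeActivityCurve,
    t_start_h: float,
    t_end_h: float,
    half_life_h: float | None = None,
) -> float:
    """Cumulated activity over a window: trapezoidal integral in decays.

    The physical activity is integrated with the trapezoidal rule over
    ``[t_start_h, t_end_h]`` and converted from Bq*h to decays (x3600).
    Window endpoints that fall between samples are linearly interpolated.
    A decay-corrected curve requires ``half_life_h`` for conversion to
    physical activity.
    """
    if t_end_h <= t_start_h:
        raise DosimetryError("t_end must exceed t_start")
    if curve.decay_corrected:
        if half_life_h is None:
            raise DosimetryError("decay-corrected curve needs half_life_h to integrate")
        curve = curve.to_physical(half_life_h)
    t, a = curve.times_h, curve.activities_bq
    if t_start_h < t[0] - 1e-12 or t_end_h > t[-1] + 1e-12:
        raise DosimetryError(
            f"window [{t_start_h}, {t_end_h}] h outside curve support "
            f"[{t[0]}, {t[-1]}] h for organ {curve.organ!r}"
        )
    inside = (t > t_start_h) & (t < t_end_h)
    tt = np.concatenate([[t_start_h], t[inside], [t_end_h]])
    aa = np.interp(tt, t, a)
    return float(np.trapezoid(aa, tt)) * BQ_H_TO_DECAYS


def organ_dose(
    cum_act: float,
    spectrum: NuclideAlphaSpectrum,
    geometry: OrganGeometry,
) -> float:
    """Mean absorbed dose in mGy from cumulated activity (decays).

    D = A_cum * sum(n_i E_i) * Phi / m, with MeV -> J conversion; the
    absorbed fraction is taken uniform across alpha lines.
    """
    if cum_act < 0.0:
        raise DosimetryError("cumulated activity cannot be negative")
    energy_j = mean_alpha_energy_per_decay(spectrum) * MEV_TO_J
    dose_gy = cum_act * energy_j * geometry.absorbed_fraction / geometry.mass_kg
    return dose_gy * 1e3


def scale_dose_with_activity(
    dose_ref_mgy: float,
    activity_ref_kbq: float,
    activity_new_kbq: float,
) -> float:
    """Rescale a dose to a different injected activity.

    Valid because cumulated activity is linear in injected activity for a
    fixed per-unit-activity biodistribution.  Returns the unrounded
    value; see :func:`round_sig` for report formatting.
    """
    if activity_ref_kbq <= 0.0:
        raise DosimetryError("reference activity must be positive")
    return dose_ref_mgy * activity_new_kbq / activity_ref_kbq


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, banker's (half-even) rounding."""
    if x == 0.0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, ndigits)


def dose_table(
    curves: Iterable[TimeActivityCurve],
    geometries: Iterable[OrganGeometry],
    spectrum: NuclideAlphaSpectrum,
    windows: Sequence[tuple[float, float]],
    reference_activity_kbq: float = 1.7,
    t_start_h: float = 0.0,
) -> pd.DataFrame:
    """Mean absorbed dose per organ and (activity, killing-time) window.

    ``curves`` are the biodistribution at the reference injected
    activity; doses for other activities are obtained by linear scaling
    of the reference cumulated activity.  Curves are extended with
    invariant biodistribution as needed to cover the longest window.

    Returns a long-format DataFrame with columns ``organ``,
    ``activity_kbq``, ``t_end_h``, ``cumulated_activity_decays``,
    ``dose_mgy`` and ``dose_mgy_2sf``.
    """
    geo = {g.organ: g for g in geometries}
    curve_map = {c.organ: c for c in curves}
    missing = sorted(set(curve_map) - set(geo)) + sorted(set(geo) - set(curve_map))
    if missing:
        raise DosimetryError(f"organs missing a curve or geometry: {missing}")
    t_max = max(t for _, t in windows)
    rows = []
    for organ in curve_map:
        curve = extend_curve(curve_map[organ], t_max, spectrum.half_life_h)
        for activity_kbq, t_end in windows:
            cum_ref = cumulated_activity(curve, t_start_h, t_end, spectrum.half_life_h)
            scale = activity_kbq / reference_activity_kbq
            dose = organ_dose(cum_ref * scale, spectrum, geo[organ])
            rows.append(
                {
                    "organ": organ,
                    "activity_kbq": activity_kbq,
                    "t_end_h": t_end,
                    "cumulated_activity_decays": cum_ref * scale,
                    "dose_mgy": dose,
                    "dose_mgy_2sf": round_sig(dose, 2),
                }
            )
    return pd.DataFrame(rows)
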