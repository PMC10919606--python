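"""Absolute quantification: Richards fits, Cy0, standard curves, Eq-style
mass-to-copies conversion.

The quantification cycle Cy0 is threshold-free: fit the raw fluorescence
to the 5-parameter Richards function

    F(x) = Fb + Fmax / (1 + exp((c - x)/b))**d

and take the x-intercept of the tangent at the inflection point, drawn
on the baseline-subtracted curve.  The inflection sits at
``x* = c + b ln d`` and the closed-form intercept is

    Cy0 = c + b ln d - b (1 + 1/d),

which for the symmetric logistic (d = 1) reduces to ``c - 2b``.  Cy0
values regressed against log10 template copies over a standard dilution
series give the linear calibration used to quantify unknowns.

Mass-to-copy conversion for a double-stranded standard of length L bp at
m ng uses copies = m * N_A / (L * 660 g/mol * 1e9 ng/g) with
N_A = 6.022e23/mol and 660 g/mol per base pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .qpcr_synth import AmplificationCurve

__all__ = [
    "AVOGADRO",
    "BP_GRAMS_PER_MOLE",
    "RichardsFit",
    "StandardCurve",
    "QuantResult",
    "copies_from_mass",
    "richards",
    "fit_richards",
    "compute_cy0",
    "build_standard_curve",
    "standard_curve_from_series",
    "quantify_sample",
    "fits_frame",
]

AVOGADRO = 6.022e23  # molecules per mole
BP_GRAMS_PER_MOLE = 660.0  # average mass of one double-stranded base pair


def copies_from_mass(mass_ng: float, length_bp: int = 390) -> float:
    """Template copies in ``mass_ng`` nanograms of an ``length_bp`` dsDNA."""
    if mass_ng < 0:
        raise ValueError("mass must be >= 0")
    if length_bp <= 0:
        raise ValueError("length must be positive")
    return mass_ng * AVOGADRO / (length_bp * BP_GRAMS_PER_MOLE * 1e9)


def richards(x, fb, fmax, b, c, d):
    """5-parameter Richards curve F(x) = Fb + Fmax/(1+exp((c-x)/b))^d."""
    return fb + fmax / (1.0 + np.exp((c - x) / b)) ** d


@dataclass(frozen=True)
class RichardsFit:
    fb: float
    fmax: float
    b: float
    c: float
    d: float
    rss: float
    converged: bool
    cy0: float = float("nan")

    def predict(self, x) -> np.ndarray:
        return richards(np.asarray(x, dtype=float), self.fb, self.fmax, self.b, self.c, self.d)


NO_FIT = RichardsFit(
    fb=float("nan"), fmax=float("nan"), b=float("nan"), c=float("nan"),
    d=float("nan"), rss=float("nan"), converged=False,
)


def compute_cy0(fit: "RichardsFit | Sequence[float]") -> float:
    """Closed-form tangent-at-inflection x-intercept of a Richards fit.

    The tangent is drawn on the baseline-subtracted signal (F - Fb), so
    the intercept is where the tangent line crosses the Fb level.
    Independent of Fmax; equivariant under translating c.
    """
    if isinstance(fit, RichardsFit):
        b, c, d = fit.b, fit.c, fit.d
    else:
        b, c, d = fit
    if d <= 0 or b <= 0:
        raise ValueError("Cy0 requires b > 0 and d > 0")
    x_star = c + b * math.log(d)
    return x_star - b * (1.0 + 1.0 / d)


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    fb0 = float(np.median(y[: max(3, len(y) // 7)]))
    fmax0 = max(float(y.max() - fb0), 1e-6)
    dy = np.diff(y)
    i = int(np.argmax(dy))
    c0 = float(x[i])
    max_slope = max(float(dy[i]), 1e-9)
    # logistic max slope = Fmax/(4b)
    b0 = float(np.clip(fmax0 / (4.0 * max_slope), 0.3, 5.0))
    return fb0, fmax0, b0, c0, 1.0


def fit_richards(
    curve: AmplificationCurve,
    *,
    amplitude_floor: float | None = None,
    max_nfev: int = 10_000,
    restarts: int = 5,
    seed: int = 0,
) -> RichardsFit:
    """Bounded least-squares Richards fit of one amplification curve.

    Curves whose amplitude never rises above the noise floor (flat or
    non-amplifying wells) are reported as a no-fit result rather than an
    error.  Failed optimizations are retried with seeded, jittered
    starting values.
    """
    x = np.asarray(curve.cycles, dtype=float)
    y = np.asarray(curve.fluorescence, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 cycles to fit 5 parameters")

    early = y[: max(3, len(y) // 7)]
    noise = max(float(np.std(early)), 1e-9)
    floor = amplitude_floor if amplitude_floor is not None else 10.0 * noise
    amplitude = float(y.max() - np.median(early))
    if amplitude < max(floor, 1e-6):
        return NO_FIT

    p0 = np.array(_initial_guess(x, y))
    lower = [-np.inf, 1e-9, 1e-3, float(x.min()) - len(x), 1e-3]
    upper = [np.inf, np.inf, 50.0, float(x.max()) + 2 * len(x), 50.0]
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(restarts + 1):
        start = p0 if attempt == 0 else p0 * rng.uniform(0.7, 1.3, size=5)
        start = np.clip(start, lower, upper)
        try:
            popt, _ = optimize.curve_fit(
                richards, x, y, p0=start, bounds=(lower, upper),
                maxfev=max_nfev, xtol=1e-10, ftol=1e-10,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((richards(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
        if attempt == 0 and best is not None:
            break  # first attempt converged; accept it
    if best is None:
        return NO_FIT
    (fb, fmax, b, c, d), rss = best
    fit = RichardsFit(fb=fb, fmax=fmax, b=b, c=c, d=d, rss=rss, converged=True)
    return RichardsFit(**{**fit.__dict__, "cy0": compute_cy0(fit)})


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration of Cy0 against log10 template copies."""

    slope: float  # cycles per log10(copies); negative for a valid assay
    intercept: float
    r_squared: float
    level_range: tuple[float, float]
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")

    def predicted_cy0(self, copies: float) -> float:
        return self.intercept + self.slope * math.log10(copies)


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    cy0: float
    estimated_copies_per_ul: float
    in_calibration_range: bool


def build_standard_curve(
    cy0s: Sequence[float],
    copies_levels: Sequence[float],
    detection_limit: float | None = None,
) -> StandardCurve:
    """OLS of Cy0 on log10(copies) over paired observations."""
    cy0s = np.asarray(cy0s, dtype=float)
    copies = np.asarray(copies_levels, dtype=float)
    if len(cy0s) != len(copies):
        raise ValueError("cy0s and copies_levels must be paired")
    if len(np.unique(copies)) < 3:
        raise ValueError("need at least 3 distinct levels")
    res = stats.linregress(np.log10(copies), cy0s)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        level_range=(float(copies.min()), float(copies.max())),
        detection_limit=detection_limit,
    )


def standard_curve_from_series(
    curves: Sequence[AmplificationCurve],
) -> tuple[StandardCurve, pd.DataFrame]:
    """Fit every dilution-series curve and calibrate Cy0 vs log10 copies.

    The detection limit is the lowest level at which every replicate
    yields a converged fit and the mean Cy0 ordering across levels stays
    monotone (more copies -> earlier Cy0).  Wells failing to fit are
    excluded from the regression.
    """
    rows = []
    for c in curves:
        fit = fit_richards(c)
        rows.append(
            {
                "copies_per_ul": c.metadata["copies_per_ul"],
                "replicate": c.metadata.get("replicate", 0),
                "cy0": fit.cy0,
                "converged": fit.converged,
                "rss": fit.rss,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    by_level = ok.groupby("copies_per_ul")["cy0"].mean().sort_index()
    n_reps = table.groupby("copies_per_ul")["converged"].agg(["sum", "size"])

    detection_limit = None
    for level in sorted(n_reps.index):
        all_fit = n_reps.loc[level, "sum"] == n_reps.loc[level, "size"]
        usable = by_level[by_level.index >= level]
        monotone = bool(np.all(np.diff(usable.to_numpy()) < 0))
        if all_fit and monotone:
            detection_limit = float(level)
            break

    sc = build_standard_curve(
        ok["cy0"].to_numpy(), ok["copies_per_ul"].to_numpy(), detection_limit
    )
    return sc, table


def quantify_sample(cy0: float, sc: StandardCurve, sample_id: str = "") -> QuantResult:
    """Invert the calibration: copies = 10**((cy0 - intercept)/slope)."""
    if sc.slope >= 0:
        raise ValueError("invalid calibration: slope must be negative")
    copies = 10.0 ** ((cy0 - sc.intercept) / sc.slope)
    lo, hi = sc.level_range
    in_range = (
        sc.predicted_cy0(hi) <= cy0 <= sc.predicted_cy0(lo)
    )  # slope < 0: high copies -> low Cy0
    return QuantResult(
        sample_id=sample_id,
        cy0=cy0,
        estimated_copies_per_ul=copies,
        in_calibration_range=bool(in_range),
    )


def fits_frame(fits: Sequence[RichardsFit]) -> pd.DataFrame:
    """Per-well fit report table."""
    return pd.DataFrame(
        {
            "fb": f.fb, "fmax": f.fmax, "b": f.b, "c": f.c, "d": f.d,
            "rss": f.rss, "cy0": f.cy0, "converged": f.converged,
        }
        for f in fits
    )
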