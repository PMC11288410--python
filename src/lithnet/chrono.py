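"""Radiocarbon calibration and probability-mass time binning.

A conventional radiocarbon age ``c14_age +/- sigma`` (years BP) is mapped
onto the calendar axis through a calibration curve mu(t) with its own
error sigma_curve(t).  On a 1-year calendar grid the posterior over
calendar age t is

    p(t)  proportional to  N(c14_age | mu(t), sigma^2 + sigma_curve(t)^2)

normalised to sum to one (flat prior).  The "two sigma" calendar set is
the 95.4% highest-posterior-density (HPD) set, built by accumulating
grid years in descending probability order.

Contexts are then assigned to contiguous 200-year calendar bins: a
context joins every bin that captures at least a threshold fraction
(default 35%) of the two-sigma-restricted, renormalised posterior mass
of any one of its dates.  The threshold keeps bin membership compact
(one or two consecutive bins for almost all contexts) while not
discarding dates whose posterior straddles a bin edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationCurve",
    "RadiocarbonDate",
    "CalibratedDensity",
    "TimeBin",
    "DatedContext",
    "MATERIAL_CLASSES",
    "read_curve",
    "identity_curve",
    "filter_dates",
    "calibrate",
    "make_bins",
    "bin_masses",
    "assign_bins",
]

logger = logging.getLogger(__name__)

MATERIAL_CLASSES = frozenset({"short_lived", "long_lived", "aggregate", "unknown"})

#: Coverage of the "two sigma" highest-posterior-density set.
TWO_SIGMA = 0.954


@dataclass
class CalibrationCurve:
    """A calibration curve on an ascending calendar grid (cal BP)."""

    cal_bp: np.ndarray
    c14_bp: np.ndarray
    sigma_curve: np.ndarray

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_bp = np.asarray(self.c14_bp, dtype=float)
        self.sigma_curve = np.asarray(self.sigma_curve, dtype=float)
        if self.cal_bp[0] > self.cal_bp[-1]:  # stored descending: flip
            self.cal_bp = self.cal_bp[::-1]
            self.c14_bp = self.c14_bp[::-1]
            self.sigma_curve = self.sigma_curve[::-1]
        if np.any(np.diff(self.cal_bp) <= 0):
            raise ValueError("calibration curve cal BP grid is not strictly monotone")
        if np.any(self.sigma_curve <= 0):
            raise ValueError("calibration curve has non-positive errors")

    @property
    def n_knots(self) -> int:
        return len(self.cal_bp)

    def interpolate(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolate curve mean and error onto ``grid``."""
        mu = np.interp(grid, self.cal_bp, self.c14_bp)
        sig = np.interp(grid, self.cal_bp, self.sigma_curve)
        return mu, sig


def read_curve(path) -> CalibrationCurve:
    """Read a 3-column calibration curve file (cal BP, 14C BP, error).

    The standard ``.14c`` dialect: ``#`` comment lines, comma or
    whitespace separated numeric rows, calendar column in either
    direction (normalised to ascending).  Malformed rows raise with
    their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2])


def identity_curve(
    cal_start: float = 0.0, cal_end: float = 15000.0, sigma: float = 1.0, step: float = 5.0
) -> CalibrationCurve:
    """A synthetic curve with ``c14 == cal`` and constant error.

    Under this curve, calibrating ``age +/- s`` recovers (to grid
    resolution) a Gaussian centred on ``age`` — useful for tests and for
    synthetic data, with no external curve file needed.
    """
    grid = np.arange(cal_start, cal_end + step, step, dtype=float)
    return CalibrationCurve(grid, grid.copy(), np.full_like(grid, float(sigma)))


@dataclass(frozen=True)
class RadiocarbonDate:
    """One radiocarbon determination linked to a site/level context."""

    lab_code: str
    site_id: str
    level_id: str
    c14_age: float
    sigma: float
    material_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"{self.lab_code}: sigma must be positive")
        if self.c14_age <= 0:
            raise ValueError(f"{self.lab_code}: 14C age must be positive")
        if self.material_class not in MATERIAL_CLASSES:
            raise ValueError(
                f"{self.lab_code}: unknown material class {self.material_class!r}"
            )

    @property
    def context(self) -> tuple[str, str]:
        return (self.site_id, self.level_id)


def filter_dates(
    dates, sd_cutoff: float = 100.0, drop_aggregate: bool = True
) -> list[RadiocarbonDate]:
    """Apply the date-quality filters.

    Drops determinations with a 1-sigma error strictly greater than
    ``sd_cutoff`` (default 100 yr) and, by default, aggregate samples
    (bulk material mixing several events).  Each drop is logged with the
    rule applied.  The cutoff is strict: ``sigma == sd_cutoff`` is kept.
    """
    kept = []
    for d in dates:
        if d.sigma > sd_cutoff:
            logger.info("dropped %s: sigma %.0f > %.0f", d.lab_code, d.sigma, sd_cutoff)
        elif drop_aggregate and d.material_class == "aggregate":
            logger.info("dropped %s: aggregate sample", d.lab_code)
        else:
            kept.append(d)
    return kept


@dataclass
class CalibratedDensity:
    """Posterior over calendar age for one date, on a 1-year grid."""

    grid: np.ndarray  # ascending cal BP, 1-year steps
    prob: np.ndarray  # sums to 1
    two_sigma: np.ndarray  # boolean HPD-set mask over grid

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.prob))])

    @property
    def median(self) -> float:
        cum = np.cumsum(self.prob)
        return float(self.grid[int(np.searchsorted(cum, 0.5))])

    @property
    def two_sigma_mass(self) -> float:
        return float(self.prob[self.two_sigma].sum())

    @property
    def two_sigma_range(self) -> tuple[float, float]:
        years = self.grid[self.two_sigma]
        return float(years.min()), float(years.max())


def calibrate(
    date: RadiocarbonDate, curve: CalibrationCurve, level: float = TWO_SIGMA
) -> CalibratedDensity:
    """Calibrate one date against a curve on a 1-year calendar grid.

    The grid spans the curve's calendar range; the posterior is the
    normalised Gaussian likelihood of the measured age given the
    interpolated curve, with variances added.  The HPD set accumulates
    grid years in descending probability order until it holds at least
    ``level`` of the mass (so its mass is >= level, within one grid
    year's probability of it).
    """
    lo, hi = float(curve.cal_bp[0]), float(curve.cal_bp[-1])
    grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    mu, sig_c = curve.interpolate(grid)
    if not (curve.c14_bp.min() <= date.c14_age <= curve.c14_bp.max()):
        raise ValueError(
            f"{date.lab_code}: 14C age {date.c14_age} outside curve support"
        )
    var = date.sigma**2 + sig_c**2
    log_like = -0.5 * (date.c14_age - mu) ** 2 / var - 0.5 * np.log(var)
    log_like -= log_like.max()
    prob = np.exp(log_like)
    prob /= prob.sum()

    order = np.argsort(prob)[::-1]
    cum = np.cumsum(prob[order])
    k = int(np.searchsorted(cum, level)) + 1
    mask = np.zeros(len(grid), dtype=bool)
    mask[order[:k]] = True
    return CalibratedDensity(grid=grid, prob=prob, two_sigma=mask)


@dataclass(frozen=True, order=True)
class TimeBin:
    """A closed calendar-year interval [end, start] in cal BP.

    ``start`` is the older (larger) bound, ``end`` the younger; the
    label prints older-first, e.g. ``8600-8401``.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start <= self.end:
            raise ValueError("bin start (older bound) must exceed end")

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"

    @property
    def width(self) -> int:
        return self.start - self.end + 1

    def contains(self, cal_bp: float) -> bool:
        return self.end <= cal_bp <= self.start


def make_bins(oldest: int = 8600, youngest: int = 6801, width: int = 200) -> list[TimeBin]:
    """Tile [youngest, oldest] cal BP with contiguous fixed-width bins.

    Default: nine 200-year bins 8600-8401, 8400-8201, ..., 7000-6801,
    ordered oldest first.  Bins share no calendar years.
    """
    if (oldest - youngest + 1) % width:
        raise ValueError("bin range is not a whole number of bins")
    return [TimeBin(s, s - width + 1) for s in range(oldest, youngest, -width)]


def bin_masses(
    density: CalibratedDensity, bins: list[TimeBin], restrict_two_sigma: bool = True
) -> np.ndarray:
    """Fraction of a date's posterior mass falling in each bin.

    With ``restrict_two_sigma`` (the default) the posterior is first
    restricted to its two-sigma HPD set and renormalised, so the
    fractions answer "where does the credible calendar range sit",
    insulated from far tails.
    """
    prob = density.prob.copy()
    if restrict_two_sigma:
        prob = np.where(density.two_sigma, prob, 0.0)
        total = prob.sum()
        if total > 0:
            prob = prob / total
    out = np.empty(len(bins))
    for i, b in enumerate(bins):
        sel = (density.grid >= b.end) & (density.grid <= b.start)
        out[i] = prob[sel].sum()
    return out


@dataclass
class DatedContext:
    """A site/level with its surviving dates and bin memberships."""

    site_id: str
    level_id: str
    dates: list[RadiocarbonDate]
    bin_memberships: list[str] = field(default_factory=list)  # bin labels, oldest first

    @property
    def context(self) -> tuple[str, str]:
        return (self.site_id, self.level_id)


def assign_bins(
    context: tuple[str, str],
    dates_and_densities: list[tuple[RadiocarbonDate, CalibratedDensity]],
    bins: list[TimeBin],
    threshold: float = 0.35,
    restrict_two_sigma: bool = True,
    combine: str = "any",
) -> DatedContext:
    """Assign a dated context to every bin reaching the mass threshold.

    A bin qualifies when the fraction of (two-sigma-restricted,
    renormalised) posterior mass inside it is >= ``threshold`` for ANY
    of the context's dates (``combine='any'``, the default — this is
    what lets a context with two discordant dates legitimately span
    three consecutive bins) or for ALL dates (``combine='all'``).

    A date that puts no bin over the threshold is logged; a context
    ending with no bins is returned with an empty membership list and
    excluded downstream.  Raising the threshold can only shrink the
    membership set.
    """
    if combine not in ("any", "all"):
        raise ValueError("combine must be 'any' or 'all'")
    if not dates_and_densities:
        raise ValueError(f"context {context}: no calibrated dates")
    per_date = []
    for date, dens in dates_and_densities:
        masses = bin_masses(dens, bins, restrict_two_sigma=restrict_two_sigma)
        hits = masses >= threshold
        if not hits.any():
            logger.warning(
                "context %s: date %s reaches no bin at threshold %.2f",
                context, date.lab_code, threshold,
            )
        per_date.append(hits)
    stacked = np.vstack(per_date)
    member = stacked.any(axis=0) if combine == "any" else stacked.all(axis=0)
    labels = [b.label for b, m in zip(bins, member) if m]
    if not labels:
        logger.warning("context %s: no bin assignment; excluded", context)
    else:
        idx = [i for i, m in enumerate(member) if m]
        if idx != list(range(idx[0], idx[-1] + 1)):
            logger.warning("context %s: non-consecutive bin memberships %s", context, labels)
    return DatedContext(context[0], context[1], [d for d, _ in dates_and_densities], labels)
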