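"""Pointwise linear regression (PLR) progression analysis.

Each of the 52 analyzed locations gets an ordinary-least-squares regression
of sensitivity — expressed in percent of age-matched mean normal, so the
three modalities share one scale — on follow-up time in years.  Locations
are flagged when the slope passes a cut-off (steeper for high-variability
edge locations) at p < 0.05, and eyes are classified under three criteria of
increasing stringency:

* liberal: any 2 flagged locations, at least 1 nonedge;
* moderate: any 3 flagged locations, at least 1 nonedge;
* conservative: a cluster of >=3 adjacent flagged locations in the same
  hemifield, at least 1 of them nonedge.

Improvement is flagged with the mirror-image cut-offs and serves as a proxy
for the specificity of the progression criteria.  An eye meeting both
directions at a given stringency is *indeterminate*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fields_io import LongitudinalSeries
from .grid import Grid, find_clusters
from .normative import NormativeModel
from .scales import MODALITIES

__all__ = [
    "CRITERIA",
    "PLRResult",
    "EyeClassification",
    "pointwise_slopes",
    "flag_locations",
    "classify_eye",
    "percent_series",
    "cohort_plr",
]

log = logging.getLogger(__name__)

CRITERIA = ("conservative", "moderate", "liberal")
DIRECTIONS = ("progression", "improvement")

#: slope cut-offs in percent of mean normal per year (inclusive)
NONEDGE_CUTOFF = 5.0
EDGE_CUTOFF = 10.0
ALPHA = 0.05

MIN_POINTS = 5


@dataclass
class PLRResult:
    """Per-location slopes, p-values and change flags for one eye/modality."""

    slopes: np.ndarray  # (54,) percent of mean normal per year; NaN at blind spots
    p_values: np.ndarray  # (54,) two-sided
    flags: np.ndarray = field(default=None)  # (54,) of {progression, improvement, none}

    def flagged(self, direction: str) -> set[int]:
        if self.flags is None:
            raise ValueError("flags not computed; call flag_locations first")
        return set(np.flatnonzero(self.flags == direction))


@dataclass(frozen=True)
class EyeClassification:
    """Per-criterion eye status: progressing / improving / indeterminate / stable."""

    status: dict[str, str]  # criterion -> status

    def __getitem__(self, criterion: str) -> str:
        return self.status[criterion]


def pointwise_slopes(times: np.ndarray, values: np.ndarray) -> PLRResult:
    """OLS slope and two-sided p-value of percent-of-normal on time, per location.

    Parameters
    ----------
    times:
        Visit times in years, strictly increasing, length >= 5 (short series
        make the t test on n-2 df the only defensible inference).
    values:
        (n_visits, 54) percent-of-mean-normal values; NaN columns (blind
        spots) propagate to NaN slopes.

    A perfect fit (zero residual variance) yields p = 0 for a nonzero slope
    and p = 1 for a zero slope, so noise-free data behave sensibly.
    """
    t = np.asarray(times, dtype=float)
    Y = np.asarray(values, dtype=float)
    if t.ndim != 1 or Y.shape[0] != t.size:
        raise ValueError("times and values have inconsistent shapes")
    if t.size < MIN_POINTS:
        raise ValueError(f"PLR needs >= {MIN_POINTS} visits, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    n = t.size
    tc = t - t.mean()
    sxx = (tc**2).sum()
    yc = Y - Y.mean(axis=0)
    slope = (tc[:, None] * yc).sum(axis=0) / sxx
    resid = yc - np.outer(tc, slope)
    ss_res = (resid**2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss_res / (n - 2) / sxx)
        tstat = slope / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)

    # degenerate perfect fits
    exact = np.isclose(ss_res, 0.0, atol=1e-10 * max(1.0, np.nanmax(np.abs(Y))))
    p = np.where(exact & (slope != 0), 0.0, p)
    p = np.where(exact & (slope == 0), 1.0, p)
    p = np.where(np.isnan(slope), np.nan, p)
    if np.any(exact & ~np.isnan(slope)):
        log.debug("zero-residual PLR fit at %d locations", int((exact & ~np.isnan(slope)).sum()))
    return PLRResult(slopes=slope, p_values=p)


def flag_locations(
    result: PLRResult,
    grid: Grid,
    *,
    nonedge_cutoff: float = NONEDGE_CUTOFF,
    edge_cutoff: float = EDGE_CUTOFF,
    alpha: float = ALPHA,
) -> PLRResult:
    """Fill change flags: slope cut-offs are inclusive, significance strict."""
    flags = np.full(len(result.slopes), "none", dtype=object)
    for loc in grid.analyzed_indices:
        s, p = result.slopes[loc], result.p_values[loc]
        if np.isnan(s) or not (p < alpha):
            continue
        cut = edge_cutoff if grid.locations[loc].is_edge else nonedge_cutoff
        if s <= -cut:
            flags[loc] = "progression"
        elif s >= cut:
            flags[loc] = "improvement"
    result.flags = flags
    return result


def _direction_met(flagged: set[int], grid: Grid, criterion: str) -> bool:
    if not flagged:
        return False
    nonedge = {i for i in flagged if not grid.locations[i].is_edge}
    if criterion == "liberal":
        return len(flagged) >= 2 and bool(nonedge)
    if criterion == "moderate":
        return len(flagged) >= 3 and bool(nonedge)
    if criterion == "conservative":
        # the nonedge requirement applies per qualifying cluster
        for cluster in find_clusters(grid, flagged, require_same_hemifield=True):
            if len(cluster) >= 3 and any(not grid.locations[i].is_edge for i in cluster):
                return True
        return False
    raise ValueError(f"unknown criterion {criterion!r}")


def classify_eye(result: PLRResult, grid: Grid) -> EyeClassification:
    """Eye status under each criterion from the per-location flags."""
    prog = result.flagged("progression")
    imp = result.flagged("improvement")
    status = {}
    for c in CRITERIA:
        p = _direction_met(prog, grid, c)
        i = _direction_met(imp, grid, c)
        if p and i:
            status[c] = "indeterminate"
        elif p:
            status[c] = "progressing"
        elif i:
            status[c] = "improving"
        else:
            status[c] = "stable"
    return EyeClassification(status=status)


def percent_series(
    series: LongitudinalSeries, modality: str, model: NormativeModel
) -> tuple[np.ndarray, np.ndarray]:
    """Times (years since this modality's own baseline test) and
    percent-of-normal values for one eye and modality.

    The normal denominator uses the subject's age at each visit, so normal
    aging decline does not register as progression.
    """
    fields = series.fields(modality)
    dates = [f.test_date for f in fields]
    t0 = dates[0]
    times = np.array([(d - t0).days / 365.25 for d in dates])
    values = np.stack([model.percent_of_normal(f) for f in fields])
    return times, values


def cohort_plr(
    cohort: list[LongitudinalSeries],
    grid: Grid,
    model: NormativeModel,
    **flag_kwargs,
) -> tuple[pd.DataFrame, dict[tuple[str, str], np.ndarray]]:
    """Run PLR over a paired cohort.

    Returns
    -------
    classifications:
        DataFrame with columns subject_id, eye, eye_id, modality and one
        column per criterion holding the eye status.
    location_counts:
        ``(modality, direction) -> (54,)`` arrays counting flagged eyes per
        location (blind spots stay 0), the per-location change maps used by
        the Friedman/Wilcoxon comparisons.
    """
    rows = []
    counts = {
        (m, d): np.zeros(grid.n_locations, dtype=int)
        for m in MODALITIES
        for d in DIRECTIONS
    }
    for series in cohort:
        for modality in MODALITIES:
            times, values = percent_series(series, modality, model)
            result = flag_locations(pointwise_slopes(times, values), grid, **flag_kwargs)
            cls = classify_eye(result, grid)
            for d in DIRECTIONS:
                for loc in result.flagged(d):
                    counts[(modality, d)][loc] += 1
            rows.append(
                {
                    "subject_id": series.subject_id,
                    "eye": series.eye,
                    "eye_id": series.eye_id,
                    "modality": modality,
                    **cls.status,
                }
            )
    return pd.DataFrame(rows), counts
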