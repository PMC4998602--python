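"""Per-location, per-modality normative aging model.

Normal perimetric sensitivity declines roughly linearly with age.  The model
here is an ordinary-least-squares fit of sensitivity (dB) on age, one
regression per test location per modality, estimated from a cross-sectional
cohort of healthy eyes (one eye per subject).  Alongside the regression
coefficients the model stores the empirical machinery needed for abnormality
probability flags:

* total deviation (TD): observed dB minus age-predicted normal dB;
* general height (GH): the 85th percentile of TD over the 52 analyzed
  locations (about the 7th-best point), the standard proxy for diffuse,
  non-glaucomatous sensitivity shifts;
* pattern deviation (PD): TD minus GH, invariant to uniform dB shifts;
* pattern standard deviation (PSD): RMS of TD about GH over the 52 analyzed
  locations;
* per-location empirical 5th / 1st percentiles of TD and PD, and the 95th
  percentile of PSD, over the normative cohort — used instead of parametric
  limits because deviation distributions are skewed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .fields_io import N_LOCATIONS, VisualField
from .grid import Grid, build_grid
from .scales import MODALITIES

__all__ = ["NormativeModel", "fit_normative"]

log = logging.getLogger(__name__)

GENERAL_HEIGHT_PERCENTILE = 85.0


@dataclass
class _ModalityFit:
    intercept: np.ndarray  # (54,) dB at age 0
    age_slope: np.ndarray  # (54,) dB per year
    residual_sd: np.ndarray  # (54,) dB
    n: int
    age_range: tuple[float, float]
    td_percentiles: dict[float, np.ndarray]  # level -> (54,)
    pd_percentiles: dict[float, np.ndarray]
    psd_p95: float


@dataclass
class NormativeModel:
    """Fitted normative model; construct via :func:`fit_normative` or
    :meth:`from_json`."""

    grid: Grid = field(default_factory=lambda: build_grid("OD"))
    fits: dict[str, _ModalityFit] = field(default_factory=dict)

    # -- access ------------------------------------------------------------

    def _fit(self, modality: str) -> _ModalityFit:
        if modality not in self.fits:
            raise ValueError(
                f"normative model has no fit for modality {modality!r}; "
                "call fit_normative first"
            )
        return self.fits[modality]

    def predict_normal(self, modality: str, age: float, location: int | None = None):
        """Mean normal sensitivity (dB) at ``age``; all 54 locations, or one.

        Linear in age with no clamping; extrapolation beyond the cohort age
        range is permitted with a logged warning.
        """
        f = self._fit(modality)
        lo, hi = f.age_range
        if not (lo <= age <= hi):
            # warn once per modality; repeats at debug level only
            key = f"_warned_extrapolation_{modality}"
            log.log(
                logging.DEBUG if getattr(self, key, False) else logging.WARNING,
                "age %.1f outside normative cohort range [%.1f, %.1f] for %s; "
                "extrapolating", age, lo, hi, modality,
            )
            object.__setattr__(self, key, True)
        pred = f.intercept + f.age_slope * age
        return pred if location is None else float(pred[location])

    def deviations(self, field: VisualField) -> tuple[np.ndarray, np.ndarray]:
        """Total and pattern deviation (dB) for one field; NaN at blind spots."""
        td = field.sens_db - self.predict_normal(field.modality, field.age)
        td = td.copy()
        td[list(self.grid.blind_spot_indices)] = np.nan
        analyzed = list(self.grid.analyzed_indices)
        gh = np.percentile(td[analyzed], GENERAL_HEIGHT_PERCENTILE)
        return td, td - gh

    def psd(self, field: VisualField) -> float:
        """Pattern standard deviation: RMS of TD about the general height."""
        _, pdev = self.deviations(field)
        analyzed = list(self.grid.analyzed_indices)
        return float(np.sqrt(np.mean(pdev[analyzed] ** 2)))

    def psd_limit(self, modality: str) -> float:
        """95th percentile of normative PSD (PSD above it is abnormal)."""
        return self._fit(modality).psd_p95

    def td_percentile(self, modality: str, level: float) -> np.ndarray:
        return self._fit(modality).td_percentiles[level]

    def pd_percentile(self, modality: str, level: float) -> np.ndarray:
        return self._fit(modality).pd_percentiles[level]

    def percent_of_normal(self, field: VisualField) -> np.ndarray:
        """Per-location sensitivity in percent of the age-matched mean normal."""
        from .scales import percent_of_normal as _pon

        normal = self.predict_normal(field.modality, field.age)
        out = _pon(field.sens_db, normal, field.modality)
        out[list(self.grid.blind_spot_indices)] = np.nan
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {"grid": json.loads(self.grid.to_json()), "fits": {}}
        for m, f in self.fits.items():
            payload["fits"][m] = {
                "intercept": f.intercept.tolist(),
                "age_slope": f.age_slope.tolist(),
                "residual_sd": f.residual_sd.tolist(),
                "n": f.n,
                "age_range": list(f.age_range),
                "td_percentiles": {str(k): v.tolist() for k, v in f.td_percentiles.items()},
                "pd_percentiles": {str(k): v.tolist() for k, v in f.pd_percentiles.items()},
                "psd_p95": f.psd_p95,
            }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "NormativeModel":
        payload = json.loads(text)
        grid = Grid.from_json(json.dumps(payload["grid"]))
        fits = {}
        for m, d in payload["fits"].items():
            fits[m] = _ModalityFit(
                intercept=np.asarray(d["intercept"], dtype=float),
                age_slope=np.asarray(d["age_slope"], dtype=float),
                residual_sd=np.asarray(d["residual_sd"], dtype=float),
                n=int(d["n"]),
                age_range=tuple(d["age_range"]),
                td_percentiles={float(k): np.asarray(v, dtype=float)
                                for k, v in d["td_percentiles"].items()},
                pd_percentiles={float(k): np.asarray(v, dtype=float)
                                for k, v in d["pd_percentiles"].items()},
                psd_p95=float(d["psd_p95"]),
            )
        return cls(grid=grid, fits=fits)


def fit_normative(
    cohort: list[VisualField],
    *,
    grid: Grid | None = None,
    percentile_levels: tuple[float, ...] = (5.0, 1.0),
) -> NormativeModel:
    """Fit the per-location aging model on a healthy cohort.

    ``cohort`` holds one field per subject per modality.  Requires at least
    two distinct ages per modality (the design matrix is singular otherwise).
    """
    grid = grid or build_grid("OD")
    model = NormativeModel(grid=grid)
    analyzed = list(grid.analyzed_indices)

    by_mod: dict[str, list[VisualField]] = {}
    for f in cohort:
        by_mod.setdefault(f.modality, []).append(f)

    for modality, fields in by_mod.items():
        ages = np.array([f.age for f in fields])
        if len(np.unique(ages)) < 2:
            raise ValueError(
                f"normative fit for {modality} needs >=2 distinct ages "
                f"(got {len(np.unique(ages))})"
            )
        Y = np.stack([f.sens_db for f in fields])  # (n, 54)
        X = np.column_stack([np.ones_like(ages), ages])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)  # (2, 54)
        resid = Y - X @ beta
        dof = max(len(fields) - 2, 1)
        resid_sd = np.sqrt((resid**2).sum(axis=0) / dof)

        fit = _ModalityFit(
            intercept=beta[0],
            age_slope=beta[1],
            residual_sd=resid_sd,
            n=len(fields),
            age_range=(float(ages.min()), float(ages.max())),
            td_percentiles={},
            pd_percentiles={},
            psd_p95=np.nan,
        )
        model.fits[modality] = fit

        # empirical deviation percentiles from the cohort's own deviations
        tds, pds, psds = [], [], []
        for f in fields:
            td, pdev = model.deviations(f)
            tds.append(td)
            pds.append(pdev)
            psds.append(np.sqrt(np.nanmean(pdev[analyzed] ** 2)))
        td_mat = np.stack(tds)
        pd_mat = np.stack(pds)
        for level in percentile_levels:
            td_p = np.full(td_mat.shape[1], np.nan)
            pd_p = np.full(pd_mat.shape[1], np.nan)
            td_p[analyzed] = np.percentile(td_mat[:, analyzed], level, axis=0)
            pd_p[analyzed] = np.percentile(pd_mat[:, analyzed], level, axis=0)
            fit.td_percentiles[level] = td_p
            fit.pd_percentiles[level] = pd_p
        fit.psd_p95 = float(np.percentile(psds, 95.0))

    return model
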