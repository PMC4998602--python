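"""Global/sectoral mean sensitivity, Bland-Altman agreement, and the linear
mixed model of mean sensitivity over time.

Mean sensitivity (MS) is computed strictly in linear contrast-sensitivity
units — dB values are converted first and averaged after, because averaging
logarithms understates the contribution of damaged locations — and expressed
in percent of the age-matched normal MS computed the same way over the same
locations.

The longitudinal model is ``MS ~ time * modality`` (SAP the reference
modality) with a random intercept and slope per subject and a random
intercept per eye nested within subject, fitted by REML; fixed effects are
reported with Wald standard errors, 95% confidence limits and p-values.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .fields_io import LongitudinalSeries, VisualField
from .grid import Grid
from .normative import NormativeModel
from .scales import MODALITIES, db_to_cs

__all__ = [
    "mean_sensitivity",
    "ms_table",
    "bland_altman",
    "BlandAltman",
    "LMMFit",
    "fit_lmm",
]

log = logging.getLogger(__name__)

SECTORS = ("global", "ST", "IT")


def mean_sensitivity(
    field: VisualField,
    model: NormativeModel,
    grid: Grid,
    locations: str = "global",
) -> float:
    """MS in percent of mean normal over a location set (global, ST or IT).

    ``100 * mean(CS_observed) / mean(CS_normal at the subject's age)``, the
    mean taken in linear units over the same locations for both numerator
    and denominator.  Blind spots are excluded by the location sets.
    """
    locs = list(grid.sector_indices(locations))
    if not locs:
        raise ValueError(f"empty location set {locations!r}")
    cs_obs = db_to_cs(field.sens_db[locs], field.modality)
    normal_db = model.predict_normal(field.modality, field.age)
    cs_norm = db_to_cs(normal_db[locs], field.modality)
    return float(100.0 * cs_obs.mean() / cs_norm.mean())


def ms_table(
    cohort: list[LongitudinalSeries], model: NormativeModel, grid: Grid
) -> pd.DataFrame:
    """Long table of MS records: one row per eye x modality x visit.

    ``time`` is years since that modality's own baseline test for the eye.
    """
    rows = []
    for series in cohort:
        for modality in MODALITIES:
            fields = series.fields(modality)
            t0 = fields[0].test_date
            for f in fields:
                rows.append(
                    {
                        "subject_id": series.subject_id,
                        "eye": series.eye,
                        "eye_id": series.eye_id,
                        "modality": modality,
                        "time": (f.test_date - t0).days / 365.25,
                        "ms_global": mean_sensitivity(f, model, grid, "global"),
                        "ms_ST": mean_sensitivity(f, model, grid, "ST"),
                        "ms_IT": mean_sensitivity(f, model, grid, "IT"),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    loa_low: float
    loa_high: float
    means: np.ndarray  # per-pair averages, for plotting
    differences: np.ndarray


def bland_altman(a, b) -> BlandAltman:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 SD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("bland_altman needs >= 3 paired values")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(md, md - 1.96 * sd, md + 1.96 * sd, (a + b) / 2.0, d)


@dataclass
class LMMFit:
    """Fixed effects and variance components of the longitudinal MS model."""

    outcome: str
    fixed_effects: pd.DataFrame  # index=term; estimate, se, ci_low, ci_high, p
    variance_components: dict[str, float]
    converged: bool
    n_obs: int
    n_subjects: int
    n_eyes: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "outcome": self.outcome,
                "reference_modality": "SAP",
                "fixed_effects": {
                    term: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                    for term, row in self.fixed_effects.iterrows()
                },
                "variance_components": self.variance_components,
                "converged": self.converged,
                "n_obs": self.n_obs,
                "n_subjects": self.n_subjects,
                "n_eyes": self.n_eyes,
            },
            indent=1,
        )


# readable aliases for the patsy-generated term names
_TERM_ALIASES = {
    "Intercept": "intercept",
    "time": "time",
    "C(modality, Treatment('SAP'))[T.SWAP]": "SWAP",
    "C(modality, Treatment('SAP'))[T.FDT]": "FDT",
    "time:C(modality, Treatment('SAP'))[T.SWAP]": "time:SWAP",
    "time:C(modality, Treatment('SAP'))[T.FDT]": "time:FDT",
}


def fit_lmm(records: pd.DataFrame, outcome: str = "global") -> LMMFit:
    """Fit ``MS ~ time * modality`` with subject random intercept+slope and
    eye-within-subject random intercept, by REML.

    ``records`` is the output of :func:`ms_table` (or any frame with columns
    subject_id, eye_id, modality, time and ms_<outcome>).  Non-convergence is
    reported in the returned fit (and logged), never silent.
    """
    col = f"ms_{outcome}" if f"ms_{outcome}" in records.columns else outcome
    if col not in records.columns:
        raise ValueError(f"outcome column {col!r} not found")
    if "SAP" not in set(records["modality"]):
        raise ValueError("modality factor must include the reference level SAP")

    df = records.rename(columns={col: "ms"}).copy()
    single_eyed = df.groupby("subject_id")["eye_id"].nunique().max() == 1
    vc = None if single_eyed else {"eye": "0 + C(eye_id)"}
    model = smf.mixedlm(
        "ms ~ time * C(modality, Treatment('SAP'))",
        data=df,
        groups="subject_id",
        re_formula="~time",
        vc_formula=vc,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        except Exception:
            res = model.fit(reml=True)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        log.warning("mixed model for %s did not converge: %s", outcome,
                    getattr(res, "mle_retvals", "no diagnostics"))

    ci = res.conf_int(alpha=0.05)
    fe_terms = list(res.fe_params.index)
    fe = pd.DataFrame(
        {
            "estimate": res.fe_params,
            "se": res.bse.loc[fe_terms],
            "ci_low": ci.loc[fe_terms, 0],
            "ci_high": ci.loc[fe_terms, 1],
            "p": res.pvalues.loc[fe_terms],
        }
    )
    fe.index = [_TERM_ALIASES.get(t, t) for t in fe.index]

    cov_re = np.asarray(res.cov_re)
    vcomp = {
        "subject_intercept_var": float(cov_re[0, 0]),
        "subject_slope_var": float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0,
        "subject_int_slope_cov": float(cov_re[0, 1]) if cov_re.shape[0] > 1 else 0.0,
        "eye_intercept_var": float(res.vcomp[0]) if len(res.vcomp) else 0.0,
        "residual_var": float(res.scale),
    }
    return LMMFit(
        outcome=outcome,
        fixed_effects=fe,
        variance_components=vcomp,
        converged=converged,
        n_obs=len(df),
        n_subjects=df["subject_id"].nunique(),
        n_eyes=df["eye_id"].nunique(),
    )
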