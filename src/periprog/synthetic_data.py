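"""Synthetic normative and patient cohorts with the statistical structure the
analysis assumes.

The generator emulates the study conditions the pipeline is built for: a
cross-sectional normative cohort (one healthy eye per subject, all three
modalities within 30 days, sensitivity declining linearly with age at every
location) and a longitudinal glaucoma cohort (5-7 visits at roughly annual
intervals, paired SAP/SWAP/FDT tests, baseline arcuate defects deep enough
to satisfy the abnormality gate, and linear dB-per-year progression injected
into a chosen adjacent location cluster of a chosen fraction of eyes).

Modality-specific measurement properties that matter downstream are built
in: SAP/SWAP test-retest variability grows with defect depth while FDT
variability is constant; SAP/SWAP thresholds step in 1 dB while the Matrix
FDT reports one of only 15 discrete levels.  Defects and progression rates
are specified in SAP dB and converted to equivalent *fractional* loss for
the other modalities (FDT, on a 20 log10 scale, gets twice the dB).

Everything is driven by a single ``numpy`` Generator, so a given config and
seed reproduce the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .fields_io import LongitudinalSeries, Visit, VisualField
from .grid import Grid, build_grid
from .scales import MODALITIES, get_scale

__all__ = [
    "SimulationConfig",
    "true_normative_params",
    "simulate_normative_cohort",
    "simulate_patient_cohort",
    "simulate_ms_records",
    "quantize_fdt",
]

_EPOCH = date(2008, 1, 6)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters; defaults are the emulated cohort's."""

    seed: int = 0
    # normative cohort
    n_normative_subjects: int = 207
    normative_noise_sd: float = 1.0  # dB, per-location test-retest
    normative_subject_sd: float = 0.5  # dB, shared within an eye
    # patient cohort
    n_patients: int = 84
    n_eyes: int = 113
    visits_range: tuple[int, int] = (5, 7)  # inclusive
    visit_interval_months: float = 12.0
    visit_interval_sd_months: float = 3.3
    min_gap_months: float = 3.5
    pairing_jitter_days: int = 20  # SWAP/FDT offset from the SAP date (<= 30)
    age_mean: float = 60.2
    age_sd: float = 9.1
    subject_sd: float = 1.0  # dB, shared across a subject's eyes and visits
    # modality noise: SAP/SWAP sd = a + b * defect depth; FDT constant
    sap_noise_a: float = 1.5
    sap_noise_b: float = 0.15
    fdt_noise_sd: float = 2.5
    fdt_levels: int = 15
    fdt_range_db: tuple[float, float] = (0.0, 38.0)
    quantize: bool = True  # 1 dB steps for SAP/SWAP, level grid for FDT
    # baseline glaucomatous defect (SAP dB)
    defect_cluster_size: tuple[int, int] = (4, 8)  # inclusive range
    defect_depth_db: tuple[float, float] = (5.0, 15.0)
    diffuse_loss_db: tuple[float, float] = (0.0, 1.5)
    # injected progression (SAP dB per year)
    progression_fraction: float = 0.2
    progression_cluster_size: int = 3
    progression_rate_db_per_year: float = 1.5


#: per-modality aging model generating the "true" normal sensitivities:
#: intercept (dB at age 0) falls off with eccentricity, slope is dB/year.
_TRUE_PARAMS = {
    "SAP": {"center": 35.5, "ecc": 0.10, "slope": -0.07},
    "SWAP": {"center": 31.0, "ecc": 0.12, "slope": -0.09},
    "FDT": {"center": 32.0, "ecc": 0.05, "slope": -0.045},
}

#: dB multiplier giving equal fractional (percent-of-normal) loss per modality
_DB_FACTOR = {m: get_scale(m).db_per_log10 / 10.0 for m in MODALITIES}


def true_normative_params(modality: str, grid: Grid | None = None):
    """Generating intercepts (54,) and the common aging slope for a modality."""
    grid = grid or build_grid("OD")
    p = _TRUE_PARAMS[modality]
    ecc = np.array([np.hypot(l.x, l.y) for l in grid.locations])
    return p["center"] - p["ecc"] * ecc, p["slope"]


def quantize_fdt(
    db, levels: int = 15, range_db: tuple[float, float] = (0.0, 38.0)
):
    """Snap to the nearest of ``levels`` evenly spaced dB levels.

    Ties round toward the lower level; out-of-range input clamps to the
    grid ends.
    """
    lo, hi = range_db
    step = (hi - lo) / (levels - 1)
    idx = np.ceil((np.asarray(db, dtype=float) - lo) / step - 0.5)
    idx = np.clip(idx, 0, levels - 1)
    return lo + idx * step


#: default generating fixed effects for the longitudinal MS model, in percent
#: of mean normal: SAP baseline level and yearly change, SWAP/FDT baseline
#: offsets and change-rate interactions relative to SAP.
DEFAULT_MS_FIXED = {
    "intercept": 71.10,
    "time": -1.69,
    "SWAP": -21.59,
    "FDT": -3.52,
    "time:SWAP": 1.02,
    "time:FDT": 2.00,
}

#: default generating variance components (percent-of-normal scale)
DEFAULT_MS_VARIANCE = {
    "subject_intercept_sd": 12.0,
    "subject_slope_sd": 1.2,
    "eye_intercept_sd": 6.0,
    "residual_sd": 5.0,
}


def simulate_ms_records(
    fixed: dict | None = None,
    variance: dict | None = None,
    *,
    n_subjects: int = 84,
    n_eyes: int = 113,
    visits_range: tuple[int, int] = (5, 7),
    visit_interval_years: float = 1.0,
    visit_interval_sd_years: float = 3.3 / 12.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate mean-sensitivity records directly from the mixed-model
    structure: ``MS = Xb + subject intercept + subject slope * time +
    eye intercept + noise``, with two eyes nested in bilateral subjects and
    all three modalities sharing each visit time.

    Used for parameter-recovery checks of :func:`periprog.fit_lmm`: the
    returned frame has exactly the columns ``fit_lmm`` consumes.
    """
    fixed = {**DEFAULT_MS_FIXED, **(fixed or {})}
    var = {**DEFAULT_MS_VARIANCE, **(variance or {})}
    rng = np.random.default_rng(seed)
    n_bilateral = n_eyes - n_subjects
    if not 0 <= n_bilateral <= n_subjects:
        raise ValueError("n_eyes must lie in [n_subjects, 2*n_subjects]")

    rows = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        b0 = rng.normal(0.0, var["subject_intercept_sd"])
        b1 = rng.normal(0.0, var["subject_slope_sd"])
        n_side = 2 if i < n_bilateral else 1
        for side in ("OD", "OS")[:n_side]:
            e0 = rng.normal(0.0, var["eye_intercept_sd"])
            n_visits = int(rng.integers(visits_range[0], visits_range[1] + 1))
            gaps = np.maximum(
                rng.normal(visit_interval_years, visit_interval_sd_years,
                           size=n_visits - 1),
                0.25,
            )
            times = np.concatenate([[0.0], np.cumsum(gaps)])
            for t in times:
                for modality in MODALITIES:
                    mu = fixed["intercept"] + fixed["time"] * t
                    if modality != "SAP":
                        mu += fixed[modality] + fixed[f"time:{modality}"] * t
                    ms = mu + b0 + b1 * t + e0 + rng.normal(0.0, var["residual_sd"])
                    rows.append(
                        {
                            "subject_id": sid,
                            "eye": side,
                            "eye_id": f"{sid}:{side}",
                            "modality": modality,
                            "time": t,
                            "ms_global": ms,
                        }
                    )
    return pd.DataFrame(rows)


def _check(config: SimulationConfig) -> None:
    if config.n_normative_subjects < 2 or config.n_patients < 1:
        raise ValueError("cohort sizes must be positive (>=2 normative subjects)")
    if not (0.0 <= config.progression_fraction <= 1.0):
        raise ValueError("progression_fraction must be in [0, 1]")
    if config.n_eyes < config.n_patients or config.n_eyes > 2 * config.n_patients:
        raise ValueError("n_eyes must lie in [n_patients, 2*n_patients]")
    if config.pairing_jitter_days > 30:
        raise ValueError("pairing jitter must keep tests within the 30-day window")


def _observe(
    true_db: np.ndarray,
    modality: str,
    td_true: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add modality-specific noise and discretization to true sensitivities."""
    if modality == "FDT":
        sd = np.full_like(true_db, config.fdt_noise_sd)
    else:
        sd = config.sap_noise_a + config.sap_noise_b * np.maximum(0.0, -td_true)
    obs = true_db + rng.normal(0.0, 1.0, size=true_db.shape) * sd
    obs = np.clip(obs, 0.0, 50.0)
    if config.quantize:
        if modality == "FDT":
            obs = quantize_fdt(obs, config.fdt_levels, config.fdt_range_db)
        else:
            obs = np.round(obs)
    return obs


def _reliability(rng: np.random.Generator) -> dict:
    return {
        "fixation_loss": round(float(rng.uniform(0.0, 0.25)), 2),
        "false_neg": round(float(rng.uniform(0.0, 0.2)), 2),
        "false_pos": round(float(rng.uniform(0.0, 0.15)), 2),
    }


def simulate_normative_cohort(
    config: SimulationConfig | None = None, *, seed: int | None = None
) -> list[VisualField]:
    """One healthy eye per subject, all three modalities within 30 days."""
    config = config or SimulationConfig()
    _check(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = build_grid("OD")
    fields = []
    for i in range(config.n_normative_subjects):
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 35.0, 85.0))
        base_date = _EPOCH + timedelta(days=int(rng.integers(0, 3 * 365)))
        for modality in MODALITIES:
            intercept, slope = true_normative_params(modality, grid)
            subj = rng.normal(0.0, config.normative_subject_sd)
            true_db = intercept + slope * age + subj
            noisy = true_db + rng.normal(
                0.0, config.normative_noise_sd, size=true_db.shape
            )
            noisy = np.clip(noisy, 0.0, 50.0)
            if config.quantize:
                noisy = (
                    quantize_fdt(noisy, config.fdt_levels, config.fdt_range_db)
                    if modality == "FDT"
                    else np.round(noisy)
                )
            offset = 0 if modality == "SAP" else int(rng.integers(0, config.pairing_jitter_days + 1))
            fields.append(
                VisualField(
                    subject_id=f"N{i:03d}",
                    eye="OD",
                    modality=modality,
                    test_date=base_date + timedelta(days=offset),
                    age=age,
                    sens_db=noisy,
                    **_reliability(rng),
                )
            )
    return fields


def _grow_cluster(
    grid: Grid,
    rng: np.random.Generator,
    size: int,
    *,
    same_hemifield: bool,
    nonedge_seed: bool = True,
    exclude: set[int] | None = None,
) -> list[int]:
    """Random connected cluster of analyzed locations, grown from a seed."""
    hemi = {l.index: l.hemifield for l in grid.locations}
    exclude = exclude or set()
    candidates = [
        l.index
        for l in grid.locations
        if not l.is_blind_spot
        and l.index not in exclude
        and (not nonedge_seed or not l.is_edge)
    ]
    if not candidates:
        raise ValueError("no candidate locations left for cluster seed")
    seed_loc = int(rng.choice(candidates))
    cluster = [seed_loc]
    while len(cluster) < size:
        frontier = sorted(
            {
                b
                for a in cluster
                for b in grid.adjacency[a]
                if b not in cluster
                and b not in exclude
                and (not same_hemifield or hemi[b] == hemi[seed_loc])
            }
        )
        if not frontier:
            break
        cluster.append(int(rng.choice(frontier)))
    return cluster


def simulate_patient_cohort(
    config: SimulationConfig | None = None, *, seed: int | None = None
) -> tuple[list[LongitudinalSeries], pd.DataFrame]:
    """Longitudinal glaucoma cohort with ground-truth change labels.

    Returns paired series (visits assembled by construction) and a truth
    table with one row per eye: whether progression was injected, at which
    locations, and at what SAP-dB rate.  The flattened fields of each series
    round-trip through the CSV schema via ``fields_io.write_fields``.
    """
    config = config or SimulationConfig()
    _check(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = build_grid("OD")

    n_bilateral = config.n_eyes - config.n_patients
    eyes = []
    for i in range(config.n_patients):
        eyes.append((f"P{i:03d}", "OD"))
        if i < n_bilateral:
            eyes.append((f"P{i:03d}", "OS"))

    subj_age = {
        f"P{i:03d}": float(np.clip(rng.normal(config.age_mean, config.age_sd), 35.0, 85.0))
        for i in range(config.n_patients)
    }
    subj_effect = {
        s: float(rng.normal(0.0, config.subject_sd)) for s in subj_age
    }
    n_prog = int(round(config.progression_fraction * len(eyes)))
    prog_eyes = set(rng.choice(len(eyes), size=n_prog, replace=False).tolist())

    series_list, truth_rows = [], []
    for e_idx, (subject_id, eye) in enumerate(eyes):
        base_age = subj_age[subject_id]
        base_date = _EPOCH + timedelta(days=int(rng.integers(0, 2 * 365)))

        lo, hi = config.defect_cluster_size
        defect_locs = _grow_cluster(
            grid, rng, int(rng.integers(lo, hi + 1)), same_hemifield=False
        )
        defect_db = np.zeros(grid.n_locations)
        dlo, dhi = config.defect_depth_db
        defect_db[defect_locs] = rng.uniform(dlo, dhi, size=len(defect_locs))
        defect_db += rng.uniform(*config.diffuse_loss_db)

        progressing = e_idx in prog_eyes
        prog_locs: list[int] = []
        rate = np.zeros(grid.n_locations)
        if progressing:
            # grown clear of the baseline defect: at locations already deep in
            # the defect the percent-of-normal floor makes a fixed dB/yr loss
            # arbitrarily small in percent terms, so injected change there
            # would be unmeasurable by construction rather than by noise
            prog_locs = _grow_cluster(
                grid,
                rng,
                config.progression_cluster_size,
                same_hemifield=True,
                exclude=set(defect_locs),
            )
            rate[prog_locs] = config.progression_rate_db_per_year

        n_visits = int(rng.integers(config.visits_range[0], config.visits_range[1] + 1))
        offsets_months = np.maximum(
            rng.normal(config.visit_interval_months, config.visit_interval_sd_months,
                       size=n_visits - 1),
            config.min_gap_months,
        )
        visit_days = np.concatenate([[0.0], np.cumsum(offsets_months) * 365.25 / 12.0])

        visits = []
        for d in visit_days:
            t_years = d / 365.25
            sap_date = base_date + timedelta(days=int(round(d)))
            fields = {}
            for modality in MODALITIES:
                fac = _DB_FACTOR[modality]
                intercept, slope = true_normative_params(modality, grid)
                age = base_age + t_years
                normal_db = intercept + slope * age
                td_true = -fac * (defect_db + rate * t_years)
                true_db = normal_db + td_true + subj_effect[subject_id]
                obs = _observe(true_db, modality, td_true, config, rng)
                offset = 0 if modality == "SAP" else int(
                    rng.integers(0, config.pairing_jitter_days + 1)
                )
                fields[modality] = VisualField(
                    subject_id=subject_id,
                    eye=eye,
                    modality=modality,
                    test_date=sap_date + timedelta(days=offset),
                    age=age,
                    sens_db=obs,
                    **_reliability(rng),
                )
            visits.append(Visit(fields=fields))
        series_list.append(
            LongitudinalSeries(subject_id=subject_id, eye=eye, visits=visits)
        )
        truth_rows.append(
            {
                "subject_id": subject_id,
                "eye": eye,
                "eye_id": f"{subject_id}:{eye}",
                "progressing": progressing,
                "progression_locations": ";".join(map(str, sorted(prog_locs))),
                "rate_db_per_year": config.progression_rate_db_per_year if progressing else 0.0,
                "n_visits": n_visits,
            }
        )
    return series_list, pd.DataFrame(truth_rows)
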