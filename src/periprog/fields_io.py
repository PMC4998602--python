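"""Visual-field records, long-format CSV I/O, reliability and visit pairing.

The on-disk schema is a long-format CSV with one row per test location per
test, plus per-test metadata repeated on each row::

    subject_id, eye, modality, test_date, age, loc_index, sens_db,
    fl, fn, fp [, md, psd, ght]

``test_date`` is ISO-8601; ``loc_index`` runs 0-53 in 24-2 row-major order
(right-eye format after mirroring); ``fl``/``fn``/``fp`` are fixation-loss,
false-negative and false-positive fractions in [0, 1]; ``ght`` is an
optional externally supplied Glaucoma Hemifield Test token
(within / borderline / outside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace
from datetime import date

import numpy as np
import pandas as pd

from .grid import Grid, build_grid, find_clusters
from .scales import MODALITIES

__all__ = [
    "VisualField",
    "Visit",
    "LongitudinalSeries",
    "read_fields",
    "write_fields",
    "is_reliable",
    "is_abnormal",
    "pair_visits",
    "N_LOCATIONS",
]

log = logging.getLogger(__name__)

N_LOCATIONS = 54

RELIABILITY_LIMIT = 0.33  # inclusive: <=33% FL, FN and FP

_GHT_TOKENS = ("within", "borderline", "outside")

_REQUIRED_COLUMNS = (
    "subject_id",
    "eye",
    "modality",
    "test_date",
    "age",
    "loc_index",
    "sens_db",
    "fl",
    "fn",
    "fp",
)


@dataclass(frozen=True)
class VisualField:
    """One perimetric test: 54 sensitivities plus metadata.

    ``sens_db`` is in grid order (blind-spot entries present but never
    analyzed).  Stored in right-eye format; OS fields are mirrored on read.
    """

    subject_id: str
    eye: str  # "OD" | "OS" (original laterality; data already mirrored)
    modality: str
    test_date: date
    age: float  # years at test
    sens_db: np.ndarray  # shape (54,)
    fixation_loss: float
    false_neg: float
    false_pos: float
    md: float | None = None
    psd: float | None = None
    ght: str | None = None

    def __post_init__(self):
        arr = np.asarray(self.sens_db, dtype=float)
        if arr.shape != (N_LOCATIONS,):
            raise ValueError(f"sens_db must have {N_LOCATIONS} entries, got {arr.shape}")
        object.__setattr__(self, "sens_db", arr)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        for name in ("fixation_loss", "false_neg", "false_pos"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.ght is not None and self.ght not in _GHT_TOKENS:
            raise ValueError(f"ght must be one of {_GHT_TOKENS}, got {self.ght!r}")


@dataclass(frozen=True)
class Visit:
    """One study visit: one field per modality, test dates within the window."""

    fields: dict[str, VisualField]  # keyed by modality

    @property
    def anchor_date(self) -> date:
        return self.fields["SAP"].test_date


@dataclass
class LongitudinalSeries:
    """Paired follow-up of one eye: ordered visits with all three modalities."""

    subject_id: str
    eye: str
    visits: list[Visit] = dc_field(default_factory=list)

    @property
    def eye_id(self) -> str:
        return f"{self.subject_id}:{self.eye}"

    def fields(self, modality: str) -> list[VisualField]:
        return [v.fields[modality] for v in self.visits]


# ---------------------------------------------------------------------------
# CSV I/O


def _mirror_permutation(grid_od: Grid) -> np.ndarray:
    """Index permutation between native-OS and right-eye row-major order.

    ``loc_index`` in the CSV is row-major in the eye's *native* orientation
    (x increasing, as devices print).  Because each 24-2 row's x-list is the
    negated reverse of the mirrored row, the mirror map is a reversal of each
    row segment — its own inverse, so the same permutation converts both ways.
    """
    rows: dict[int, list[int]] = {}
    for l in grid_od.locations:
        rows.setdefault(l.y, []).append(l.index)
    perm = np.empty(len(grid_od.locations), dtype=int)
    for indices in rows.values():
        ordered = sorted(indices, key=lambda i: grid_od.locations[i].x)
        for a, b in zip(ordered, reversed(ordered)):
            perm[a] = b
    return perm


def _mirror_sens(sens: np.ndarray, grid_od: Grid) -> np.ndarray:
    """Reorder an OS field's 54 values into right-eye format (x -> -x)."""
    return sens[_mirror_permutation(grid_od)]


def read_fields(path, *, mirror_os: bool = True) -> list[VisualField]:
    """Read long-format CSV into validated :class:`VisualField` records.

    OS fields are mirrored to right-eye format (set ``mirror_os=False`` for
    data already in right-eye format).  Malformed rows raise ``ValueError``
    naming the offending test.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    grid_od = build_grid("OD")
    fields = []
    keys = ["subject_id", "eye", "modality", "test_date"]
    for key, g in df.groupby(keys, sort=True):
        subject_id, eye, modality, test_date = key
        label = f"test {key}"
        if eye not in ("OD", "OS"):
            raise ValueError(f"{label}: eye must be OD or OS, got {eye!r}")
        if len(g) != N_LOCATIONS or set(g["loc_index"]) != set(range(N_LOCATIONS)):
            raise ValueError(f"{label}: expected loc_index 0..53 exactly once")
        g = g.sort_values("loc_index")
        for col in ("fl", "fn", "fp"):
            bad = g[(g[col] < 0) | (g[col] > 1)]
            if len(bad):
                rows = (bad.index + 2).tolist()  # 1-based incl. header
                raise ValueError(f"{label}: {col} out of [0,1] at csv line(s) {rows}")
        sens = g["sens_db"].to_numpy(dtype=float)
        if mirror_os and eye == "OS":
            sens = _mirror_sens(sens, grid_od)
        first = g.iloc[0]
        ght = first.get("ght")
        md = first.get("md")
        psd = first.get("psd")
        fields.append(
            VisualField(
                subject_id=str(subject_id),
                eye=eye,
                modality=modality,
                test_date=pd.Timestamp(test_date).date(),
                age=float(first["age"]),
                sens_db=sens,
                fixation_loss=float(first["fl"]),
                false_neg=float(first["fn"]),
                false_pos=float(first["fp"]),
                md=None if pd.isna(md) else float(md),
                psd=None if pd.isna(psd) else float(psd),
                ght=None if (ght is None or pd.isna(ght)) else str(ght),
            )
        )
    return fields


def write_fields(fields: list[VisualField], path, *, mirror_os: bool = True) -> None:
    """Write records back to the long-format CSV schema.

    In-memory fields are right-eye format; with ``mirror_os`` (the default,
    matching :func:`read_fields`) OS fields are written back in their native
    orientation so read/write round-trips are the identity.
    """
    grid_od = build_grid("OD")
    perm = _mirror_permutation(grid_od)
    rows = []
    for f in fields:
        sens = f.sens_db[perm] if (mirror_os and f.eye == "OS") else f.sens_db
        for i, s in enumerate(sens):
            rows.append(
                {
                    "subject_id": f.subject_id,
                    "eye": f.eye,
                    "modality": f.modality,
                    "test_date": f.test_date.isoformat(),
                    "age": f.age,
                    "loc_index": i,
                    "sens_db": s,
                    "fl": f.fixation_loss,
                    "fn": f.false_neg,
                    "fp": f.false_pos,
                    "md": f.md,
                    "psd": f.psd,
                    "ght": f.ght,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reliability and abnormality


def is_reliable(field: VisualField) -> bool:
    """True iff fixation losses, false negatives and false positives are all
    at or below 33% (inclusive boundary)."""
    indices = (field.fixation_loss, field.false_neg, field.false_pos)
    if any(v is None for v in indices):
        log.warning("missing reliability index for %s; treated as unreliable",
                    field.subject_id)
        return False
    return all(v <= RELIABILITY_LIMIT for v in indices)


def is_abnormal(field: VisualField, model, grid: Grid) -> bool:
    """Glaucomatous abnormality: PSD worse than the normative 5% level, OR an
    externally supplied GHT "outside" flag, OR a cluster of >=3 nonedge points
    with pattern deviation below the empirical 5% level of which >=1 is below
    the 1% level.

    ``model`` is a fitted :class:`~periprog.normative.NormativeModel`.
    """
    if field.ght == "outside":
        return True
    _, pd_dev = model.deviations(field)
    psd = model.psd(field)
    if psd > model.psd_limit(field.modality):
        return True
    p5 = model.pd_percentile(field.modality, 5.0)
    p1 = model.pd_percentile(field.modality, 1.0)
    nonedge = [
        i for i in grid.analyzed_indices
        if not grid.locations[i].is_edge and pd_dev[i] < p5[i]
    ]
    if len(nonedge) < 3:
        return False
    for cluster in find_clusters(grid, nonedge):
        if len(cluster) >= 3 and any(pd_dev[i] < p1[i] for i in cluster):
            return True
    return False


# ---------------------------------------------------------------------------
# Visit pairing


def _years_between(a: date, b: date) -> float:
    return (b - a).days / 365.25


def pair_visits(
    fields: list[VisualField],
    *,
    window_days: int = 30,
    min_gap_months: float = 3.0,
    min_visits: int = 5,
) -> LongitudinalSeries | None:
    """Assemble one eye's tests into paired visits.

    Greedy chronological matching with SAP as the anchor modality: for each
    reliable SAP test in date order, the nearest-in-time reliable SWAP and FDT
    within +/- ``window_days`` are attached, each test used at most once.
    Candidate visits closer than ``min_gap_months`` to the previously accepted
    visit are dropped.  Returns ``None`` (with a log entry) when fewer than
    ``min_visits`` complete visits survive.

    Idempotent: running the pairing on an already-paired series reproduces it.
    """
    if not fields:
        return None
    ids = {(f.subject_id, f.eye) for f in fields}
    if len(ids) > 1:
        raise ValueError(f"pair_visits expects a single eye, got {sorted(ids)}")
    subject_id, eye = next(iter(ids))

    by_mod: dict[str, list[VisualField]] = {m: [] for m in MODALITIES}
    for f in fields:
        if is_reliable(f):
            by_mod[f.modality].append(f)
        else:
            log.info("dropping unreliable %s test on %s (%s)", f.modality,
                     f.subject_id, f.test_date)
    for m in by_mod:
        by_mod[m].sort(key=lambda f: f.test_date)

    used: dict[str, set[date]] = {m: set() for m in ("SWAP", "FDT")}
    visits: list[Visit] = []
    min_gap_days = min_gap_months * 365.25 / 12.0
    for sap in by_mod["SAP"]:
        partners = {"SAP": sap}
        for m in ("SWAP", "FDT"):
            candidates = [
                f for f in by_mod[m]
                if f.test_date not in used[m]
                and abs((f.test_date - sap.test_date).days) <= window_days
            ]
            if not candidates:
                partners = None
                break
            partners[m] = min(
                candidates, key=lambda f: abs((f.test_date - sap.test_date).days)
            )
        if partners is None:
            log.info("incomplete visit around %s for %s:%s dropped",
                     sap.test_date, subject_id, eye)
            continue
        if visits and (sap.test_date - visits[-1].anchor_date).days < min_gap_days:
            log.info("visit %s for %s:%s violates %.1f-month spacing; dropped",
                     sap.test_date, subject_id, eye, min_gap_months)
            continue
        for m in ("SWAP", "FDT"):
            used[m].add(partners[m].test_date)
        visits.append(Visit(fields=partners))

    if len(visits) < min_visits:
        log.info("eye %s:%s has %d complete visits (< %d); excluded",
                 subject_id, eye, len(visits), min_visits)
        return None
    return LongitudinalSeries(subject_id=subject_id, eye=eye, visits=visits)
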