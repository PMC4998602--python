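"""End-to-end orchestration: pair visits, fit/load the normative model,
convert to percent of mean normal, run PLR and the eye criteria, compute MS
summaries, mixed models and the agreement battery, and write a report bundle.

Outputs are plain CSV/JSON so runs are diffable and reproducible; the full
configuration (every threshold used) and the seed are echoed into the
report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .agreement import agreement_report
from .fields_io import VisualField, pair_visits, read_fields
from .grid import build_grid
from .normative import NormativeModel, fit_normative
from .plr import CRITERIA, DIRECTIONS, cohort_plr
from .scales import MODALITIES
from .summaries_mixed import SECTORS, bland_altman, fit_lmm, ms_table

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults are the study's)."""

    patient_csv: str = ""
    normative_csv: str = ""  # either this or normative_model_json
    normative_model_json: str = ""
    out_dir: str = "periprog_out"
    window_days: int = 30
    min_gap_months: float = 3.0
    min_visits: int = 5
    nonedge_cutoff: float = 5.0
    edge_cutoff: float = 10.0
    alpha: float = 0.05
    criteria: tuple[str, ...] = CRITERIA
    baseline_abnormality_gate: bool = False
    n_permutations: int = 10_000
    seed: int = 1
    edge_indices: list[int] | None = None
    st_indices: list[int] | None = None
    it_indices: list[int] | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.nonedge_cutoff <= 0 or self.edge_cutoff <= 0:
            raise ValueError("slope cut-offs must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _load_normative(config: RunConfig, grid) -> NormativeModel:
    if config.normative_model_json:
        return NormativeModel.from_json(Path(config.normative_model_json).read_text())
    if not config.normative_csv:
        raise ValueError("config needs normative_csv or normative_model_json")
    cohort = read_fields(config.normative_csv)
    return fit_normative(cohort, grid=grid)


def run_pipeline(
    config: RunConfig,
    *,
    patient_fields: list[VisualField] | None = None,
    normative_model: NormativeModel | None = None,
) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    ``patient_fields`` / ``normative_model`` may be passed in-memory (e.g.
    straight from the synthetic generator); otherwise they are read from the
    paths in ``config``.  Returns the report dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = build_grid(
        "OD",
        edge_indices=config.edge_indices,
        st_indices=config.st_indices,
        it_indices=config.it_indices,
    )
    model = normative_model or _load_normative(config, grid)
    if patient_fields is None:
        patient_fields = read_fields(config.patient_csv)

    # pair visits per eye
    by_eye: dict[tuple[str, str], list[VisualField]] = {}
    for f in patient_fields:
        by_eye.setdefault((f.subject_id, f.eye), []).append(f)
    cohort = []
    for key, fields in sorted(by_eye.items()):
        series = pair_visits(
            fields,
            window_days=config.window_days,
            min_gap_months=config.min_gap_months,
            min_visits=config.min_visits,
        )
        if series is None:
            log.info("eye %s excluded at pairing", key)
            continue
        cohort.append(series)
    if not cohort:
        raise ValueError("no eye survived visit pairing")

    if config.baseline_abnormality_gate:
        from .fields_io import is_abnormal

        kept = []
        for s in cohort:
            if any(is_abnormal(f, model, grid) for f in s.visits[0].fields.values()):
                kept.append(s)
            else:
                log.info("eye %s excluded: baseline not abnormal", s.eye_id)
        cohort = kept

    # PLR + eye classification
    classifications, location_counts = cohort_plr(
        cohort,
        grid,
        model,
        nonedge_cutoff=config.nonedge_cutoff,
        edge_cutoff=config.edge_cutoff,
        alpha=config.alpha,
    )
    classifications.to_csv(out / "classifications.csv", index=False)
    flag_rows = [
        {"modality": m, "direction": d, "loc_index": i, "n_eyes": int(c)}
        for (m, d), counts in sorted(location_counts.items())
        for i, c in enumerate(counts)
    ]
    pd.DataFrame(flag_rows).to_csv(out / "location_flags.csv", index=False)

    # MS table, Bland-Altman at baseline, mixed models
    ms = ms_table(cohort, model, grid)
    ms.to_csv(out / "ms.csv", index=False)
    baseline = ms[ms["time"] == 0.0].pivot(
        index="eye_id", columns="modality", values="ms_global"
    )
    ba = {}
    for a, b in (("SAP", "SWAP"), ("SAP", "FDT"), ("SWAP", "FDT")):
        r = bland_altman(baseline[a], baseline[b])
        ba[f"{a}-{b}"] = {
            "mean_difference": r.mean_difference,
            "loa": [r.loa_low, r.loa_high],
        }
    lmm = {}
    for sector in SECTORS:
        fitres = fit_lmm(ms, outcome=sector)
        lmm[sector] = json.loads(fitres.to_json())
    (out / "lmm.json").write_text(json.dumps(lmm, indent=1))

    # agreement battery per criterion/direction
    agreement = {}
    for criterion in config.criteria:
        agreement[criterion] = {}
        for direction in DIRECTIONS:
            rep = agreement_report(
                classifications,
                criterion,
                direction,
                location_counts=location_counts,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            agreement[criterion][direction] = json.loads(rep.to_json())
    (out / "agreement.json").write_text(json.dumps(agreement, indent=1))

    counts_table = {
        c: {
            m: {
                s: int(
                    (
                        (classifications["modality"] == m)
                        & (classifications[c] == s)
                    ).sum()
                )
                for s in ("progressing", "improving", "indeterminate", "stable")
            }
            for m in MODALITIES
        }
        for c in config.criteria
    }

    report = {
        "periprog_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_eyes": len(cohort),
        "n_subjects": len({s.subject_id for s in cohort}),
        "eye_counts": counts_table,
        "bland_altman_baseline": ba,
        "outputs": [
            "classifications.csv",
            "location_flags.csv",
            "ms.csv",
            "lmm.json",
            "agreement.json",
        ],
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    _write_report_md(out / "report.md", report)
    return report


def _write_report_md(path: Path, report: dict) -> None:
    lines = [
        "# periprog run report",
        "",
        f"periprog {report['periprog_version']}; seed {report['config']['seed']}",
        f"{report['n_eyes']} eyes of {report['n_subjects']} subjects analyzed.",
        "",
        "## Eye classification counts",
        "",
    ]
    for criterion, by_mod in report["eye_counts"].items():
        lines.append(f"### {criterion}")
        lines.append("")
        lines.append("| modality | progressing | improving | indeterminate | stable |")
        lines.append("|---|---|---|---|---|")
        for m, c in by_mod.items():
            lines.append(
                f"| {m} | {c['progressing']} | {c['improving']} "
                f"| {c['indeterminate']} | {c['stable']} |"
            )
        lines.append("")
    lines.append("## Baseline Bland-Altman (global MS, % of mean normal)")
    lines.append("")
    for pair, d in report["bland_altman_baseline"].items():
        lines.append(
            f"- {pair}: mean difference {d['mean_difference']:.2f}, "
            f"95% LoA [{d['loa'][0]:.2f}, {d['loa'][1]:.2f}]"
        )
    lines.append("")
    lines.append("Full statistics: agreement.json, lmm.json, ms.csv.")
    path.write_text("\n".join(lines) + "\n")
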