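"""Cross-modality agreement battery for eye-level progression calls.

The three perimetric modalities act as three raters giving each eye a binary
label (progressing, or improving) per criterion.  This module wraps the
comparison battery: Cochran Q (omnibus proportion comparison) with pairwise
McNemar follow-ups, Fleiss kappa with a Monte-Carlo permutation p-value,
ICC(2,1), Friedman and pairwise Wilcoxon signed-rank tests on the
per-location flag-count maps, and Venn-style intersection summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa as _sm_fleiss

from .scales import MODALITIES

__all__ = [
    "classification_matrix",
    "cochran_q",
    "mcnemar",
    "fleiss_kappa",
    "icc21",
    "location_count_tests",
    "venn_summary",
    "AgreementReport",
    "agreement_report",
]

log = logging.getLogger(__name__)


def classification_matrix(
    classifications: pd.DataFrame, criterion: str, direction: str
) -> pd.DataFrame:
    """Eyes x modalities binary indicator matrix for one direction/criterion.

    Indeterminate eyes (for any modality at this criterion) are excluded
    from the direction being tested, with a log entry; the alternative of
    counting them as stable is available via downstream recoding.
    """
    target = "progressing" if direction == "progression" else "improving"
    wide = classifications.pivot(index="eye_id", columns="modality", values=criterion)
    wide = wide[list(MODALITIES)]
    indet = wide.apply(lambda r: (r == "indeterminate").any(), axis=1)
    if indet.any():
        log.info("excluding %d indeterminate eye(s) from %s/%s matrix",
                 int(indet.sum()), direction, criterion)
    return (wide[~indet] == target).astype(int)


def cochran_q(matrix) -> tuple[float, float]:
    """Cochran Q over k matched binary columns; chi-square p on k-1 df.

    Rows with all-equal entries contribute nothing; a fully degenerate
    matrix gives Q = 0, p = 1.
    """
    X = np.asarray(matrix, dtype=int)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 1:
        raise ValueError("cochran_q needs an eyes x >=2 modalities matrix")
    if np.all(X.min(axis=1) == X.max(axis=1)):
        return 0.0, 1.0
    res = _sm_cochrans_q(X, return_object=True)
    return float(res.statistic), float(res.pvalue)


def mcnemar(x, y, *, exact: bool = True) -> float:
    """Paired McNemar p-value between two binary vectors.

    Default is the exact binomial test on the discordant counts (b, c):
    ``p = min(1, 2 P(Bin(b+c, 1/2) <= min(b, c)))`` — discordant counts are
    small at these cohort sizes.  ``exact=False`` gives the (uncorrected)
    chi-square variant.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    if b + c == 0:
        return 1.0
    table = [[int(np.sum((x == 1) & (y == 1))), b], [c, int(np.sum((x == 0) & (y == 0)))]]
    res = _sm_mcnemar(table, exact=exact, correction=False)
    return float(min(1.0, res.pvalue))


def fleiss_kappa(
    matrix, *, n_permutations: int = 10_000, seed: int | None = None
) -> tuple[float, float, tuple[float, float]]:
    """Fleiss kappa across raters with a Monte-Carlo permutation p-value.

    Each permutation shuffles every rater's labels independently across eyes
    (marginals preserved); ``p = (1 + #{kappa_perm >= kappa_obs}) / (1 + B)``.
    Also returns the (min, max) range of pairwise kappas, matching the
    convention of reporting kappa with a range.

    Returns NaN kappa (with p = NaN) when every rater assigns a single
    category to every eye — agreement is then undefined.
    """
    X = np.asarray(matrix, dtype=int)
    n, k = X.shape
    if k < 2:
        raise ValueError("fleiss_kappa needs >= 2 raters")

    def _kappa(m: np.ndarray) -> float:
        table, _ = aggregate_raters(m, n_cat=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            return float(_sm_fleiss(table, method="fleiss"))

    if X.min() == X.max():
        log.warning("fleiss_kappa undefined: single category throughout")
        return float("nan"), float("nan"), (float("nan"), float("nan"))

    kappa = _kappa(X)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = np.column_stack([rng.permutation(X[:, j]) for j in range(k)])
        kp = _kappa(perm)
        if not np.isnan(kp) and kp >= kappa:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)

    pair_ks = [
        _kappa(X[:, [i, j]])
        for i, j in combinations(range(k), 2)
        if X[:, [i, j]].min() != X[:, [i, j]].max()
    ]
    rng_pair = (min(pair_ks), max(pair_ks)) if pair_ks else (kappa, kappa)
    return kappa, p, rng_pair


def icc21(matrix) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Returns the overall ICC over all raters and the (min, max) range of
    pairwise ICCs.  NaN when there is no variance to apportion.
    """
    X = np.asarray(matrix, dtype=float)
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("icc21 needs >= 2 targets and >= 2 raters")

    def _icc(m: np.ndarray) -> float:
        if np.allclose(m, m.flat[0]):
            return float("nan")
        nn, kk = m.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(nn), kk),
                "raters": np.tile(np.arange(kk), nn),
                "score": m.ravel(),
            }
        )
        tab = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="score"
        )
        # ICC(A,1) in McGraw-Wong naming = ICC(2,1): two-way random,
        # absolute agreement, single measures
        return float(tab.set_index("Type").loc["ICC(A,1)", "ICC"])

    overall = _icc(X)
    pairs = [
        v
        for i, j in combinations(range(k), 2)
        if not np.isnan(v := _icc(X[:, [i, j]]))
    ]
    rng = (min(pairs), max(pairs)) if pairs else (overall, overall)
    return overall, rng


def location_count_tests(counts) -> dict:
    """Friedman omnibus plus pairwise Wilcoxon signed-rank on per-location
    flag counts (52 locations as blocks, one column per modality).

    Wilcoxon uses the exact null distribution when there are <= 25 nonzero
    untied differences and the tie-corrected normal approximation otherwise.
    """
    df = pd.DataFrame(counts)
    cols = list(df.columns)
    X = df.to_numpy(dtype=float)
    if np.all(X == 0) or np.all(X.min(axis=1) == X.max(axis=1)):
        friedman = {"statistic": 0.0, "p": 1.0}
    else:
        st, p = stats.friedmanchisquare(*[X[:, j] for j in range(X.shape[1])])
        friedman = {"statistic": float(st), "p": float(p)}

    pairwise = {}
    for i, j in combinations(range(len(cols)), 2):
        d = X[:, i] - X[:, j]
        nz = d[d != 0]
        if nz.size == 0:
            pairwise[f"{cols[i]}-{cols[j]}"] = 1.0
            continue
        ties = len(np.unique(np.abs(nz))) < nz.size
        method = "exact" if (nz.size <= 25 and not ties) else "approx"
        res = stats.wilcoxon(X[:, i], X[:, j], method=method, correction=False)
        pairwise[f"{cols[i]}-{cols[j]}"] = float(res.pvalue)
    return {"friedman": friedman, "wilcoxon_pairwise": pairwise}


def venn_summary(matrix, baseline_md=None) -> dict:
    """Counts of the 7 intersection regions of three raters' flag sets,
    plus the median baseline (SAP) mean deviation per rater's flagged set.

    Region keys are modality-name combinations like ``"SAP"``,
    ``"SAP&SWAP"``, ``"SAP&SWAP&FDT"`` — each eye counted in exactly the
    region matching its flag pattern.
    """
    M = pd.DataFrame(matrix)
    if M.shape[1] != 3:
        raise ValueError("venn_summary expects 3 modalities")
    names = list(M.columns)
    regions = {}
    for pattern in range(1, 8):
        members = [names[j] for j in range(3) if pattern >> j & 1]
        mask = np.ones(len(M), dtype=bool)
        for j in range(3):
            want = bool(pattern >> j & 1)
            mask &= (M.iloc[:, j] == 1).to_numpy() == want
        regions["&".join(members)] = int(mask.sum())
    out = {"regions": regions}
    if baseline_md is not None:
        md = np.asarray(baseline_md, dtype=float)
        out["median_baseline_md"] = {
            name: (float(np.median(md[(M[name] == 1).to_numpy()]))
                   if (M[name] == 1).any() else None)
            for name in names
        }
    return out


@dataclass
class AgreementReport:
    """The full agreement battery for one direction/criterion."""

    direction: str
    criterion: str
    n_eyes: int
    counts: dict[str, int]
    cochran_q: dict
    mcnemar_pairwise: dict[str, float] | None
    fleiss: dict
    icc: dict
    location_tests: dict | None = None
    venn: dict | None = None

    def to_json(self) -> str:
        def _clean(o):
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, float) and np.isnan(o):
                return None
            return o

        return json.dumps(
            _clean(
                {
                    "direction": self.direction,
                    "criterion": self.criterion,
                    "n_eyes": self.n_eyes,
                    "counts": self.counts,
                    "cochran_q": self.cochran_q,
                    "mcnemar_pairwise": self.mcnemar_pairwise,
                    "fleiss_kappa": self.fleiss,
                    "icc": self.icc,
                    "icc_range_meaning": "pairwise",
                    "location_tests": self.location_tests,
                    "venn": self.venn,
                }
            ),
            indent=1,
        )


def agreement_report(
    classifications: pd.DataFrame,
    criterion: str,
    direction: str = "progression",
    *,
    location_counts: dict | None = None,
    baseline_md: pd.Series | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> AgreementReport:
    """Assemble the battery.  Pairwise follow-up tests run only when the
    omnibus test is significant at ``alpha`` (uncorrected), mirroring the
    stepwise testing procedure."""
    M = classification_matrix(classifications, criterion, direction)
    q, qp = cochran_q(M)
    pairwise = None
    if qp < alpha:
        pairwise = {
            f"{a}-{b}": mcnemar(M[a], M[b])
            for a, b in combinations(MODALITIES, 2)
        }
    kappa, kp, krange = fleiss_kappa(M, n_permutations=n_permutations, seed=seed)
    icc, icc_range = icc21(M)

    loc = None
    if location_counts is not None:
        loc = location_count_tests(
            {m: location_counts[(m, direction)] for m in MODALITIES}
        )
    md = None
    if baseline_md is not None:
        md = baseline_md.reindex(M.index).to_numpy()
    return AgreementReport(
        direction=direction,
        criterion=criterion,
        n_eyes=len(M),
        counts={m: int(M[m].sum()) for m in MODALITIES},
        cochran_q={"statistic": q, "p": qp},
        mcnemar_pairwise=pairwise,
        fleiss={"kappa": kappa, "monte_carlo_p": kp,
                "pairwise_range": list(krange)},
        icc={"icc": icc, "pairwise_range": list(icc_range)},
        location_tests=loc,
        venn=venn_summary(M, baseline_md=md),
    )
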