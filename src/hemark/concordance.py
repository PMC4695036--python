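"""Boundary-agreement statistics for manual vs automated annotations.

Four per-slide measures compare an automated tumor mask A with the manual
reference M on the tissue T, all at pixel level:

* inclusion rate  = 100·|A∩M|/|M| — how much annotated tumor is captured;
* exclusion rate  = 100·|(T∖M)∖A|/|T∖M| — how much excluded tissue is
  avoided;
* concordance index = Dice 2|A∩M|/(|A|+|M|) (Jaccard available);
* FDR = |A∖M|/|A| — the automated-region fraction that is not tumor.

A slide-level ROC treats each slide as the point
(1 − exclusion/100, inclusion/100); the weighted FDR acceptance threshold
w_non/(w_mal + w_non) encodes how much more a missed malignant cell costs
than an included benign one (2:1 → 1/3).  Undefined rates (empty
denominators, e.g. whole-tissue manual annotations) are returned as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _as_masks(*arrays: np.ndarray) -> list[np.ndarray]:
    out = [np.asarray(a, dtype=bool) for a in arrays]
    shapes = {a.shape for a in out}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {sorted(shapes)}")
    return out


def inclusion_rate(manual: np.ndarray, auto: np.ndarray) -> float:
    """Percent of the manual tumor area the automated boundary includes.

    NaN when the manual mask is empty (no reference tumor on the slide).
    """
    m, a = _as_masks(manual, auto)
    denom = np.count_nonzero(m)
    if denom == 0:
        return float("nan")
    return 100.0 * np.count_nonzero(a & m) / denom


def exclusion_rate(manual: np.ndarray, auto: np.ndarray, tissue: np.ndarray) -> float:
    """Percent of manually-excluded tissue the automated boundary excludes.

    NaN when the manual annotation covers all tissue (nothing to exclude),
    mirroring slides taken forward whole without macrodissection.
    """
    m, a, t = _as_masks(manual, auto, tissue)
    excluded = t & ~m
    denom = np.count_nonzero(excluded)
    if denom == 0:
        return float("nan")
    return 100.0 * np.count_nonzero(excluded & ~a) / denom


def concordance_index(manual: np.ndarray, auto: np.ndarray, method: str = "dice") -> float:
    """Region-overlap concordance (Dice by default, Jaccard optional).

    Two empty masks agree vacuously: returns 1.0.
    """
    m, a = _as_masks(manual, auto)
    inter = np.count_nonzero(a & m)
    na, nm = np.count_nonzero(a), np.count_nonzero(m)
    if na + nm == 0:
        return 1.0
    if method == "dice":
        return 2.0 * inter / (na + nm)
    if method == "jaccard":
        union = na + nm - inter
        return inter / union
    raise ValueError(f"unknown concordance method {method!r}")


def area_fdr(manual: np.ndarray, auto: np.ndarray) -> float:
    """Fraction of the automated region outside the reference tumor.

    NaN when the automated region is empty.
    """
    m, a = _as_masks(manual, auto)
    na = np.count_nonzero(a)
    if na == 0:
        return float("nan")
    return np.count_nonzero(a & ~m) / na


def count_fdr(manual: np.ndarray, auto: np.ndarray, nuclear: np.ndarray) -> float:
    """Nuclei-pixel-weighted FDR variant: non-tumor nuclear content of A."""
    m, a, n = _as_masks(manual, auto, nuclear)
    na = np.count_nonzero(a & n)
    if na == 0:
        return float("nan")
    return np.count_nonzero(a & n & ~m) / na


def fdr_acceptance_threshold(weight_malignant: float, weight_nonmalignant: float) -> float:
    """Weighted FDR acceptance threshold w_non/(w_mal + w_non).

    Weighting correct malignant identification twice as heavily as
    non-malignant gives 1/3 ≈ 0.33.
    """
    if weight_malignant <= 0 or weight_nonmalignant <= 0:
        raise ValueError("weights must be positive")
    return weight_nonmalignant / (weight_malignant + weight_nonmalignant)


def slide_roc(
    rates: list[tuple[float, float]]
) -> tuple[np.ndarray, float]:
    """Slide-level ROC from (inclusion %, exclusion %) pairs.

    Each slide maps to (FPR, TPR) = (1 − exclusion/100, inclusion/100);
    points are anchored at (0, 0) and (1, 1) and the AUC is the
    trapezoidal area.  Needs at least two slides with both rates defined.
    """
    pts = [
        (1.0 - ex / 100.0, inc / 100.0)
        for inc, ex in rates
        if np.isfinite(inc) and np.isfinite(ex)
    ]
    if len(pts) < 2:
        raise ValueError("need at least 2 slides with defined inclusion and exclusion")
    pts += [(0.0, 0.0), (1.0, 1.0)]
    curve = np.array(sorted(pts))
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    return curve, auc


def compare_percent_tumor(
    estimates: np.ndarray, truths: np.ndarray
) -> tuple[float, float, pd.DataFrame]:
    """Pearson r, max |deviation| and a per-case table for paired percents.

    r is NaN (flagged) when either list has zero variance; requires equal
    lengths and n >= 3 for the correlation.
    """
    est = np.asarray(estimates, float)
    tru = np.asarray(truths, float)
    if est.shape != tru.shape:
        raise ValueError("estimate/truth lists differ in length")
    if est.size < 3:
        raise ValueError("need at least 3 paired cases for a correlation")
    table = pd.DataFrame(
        {"truth": tru, "estimate": est, "deviation": est - tru}
    ).sort_values("truth", ignore_index=True)
    max_dev = float(np.max(np.abs(est - tru)))
    if est.std() == 0 or tru.std() == 0:
        return float("nan"), max_dev, table
    r, p = stats.pearsonr(est, tru)
    table.attrs["pearson_p"] = float(p)
    return float(r), max_dev, table


@dataclass
class ConcordanceReport:
    """Per-slide concordance table plus cohort aggregates."""

    per_slide: pd.DataFrame
    auc: float | None
    fdr_threshold: float

    @property
    def aggregate(self) -> dict:
        agg = {}
        for col in ("inclusion", "exclusion", "ci", "fdr"):
            v = self.per_slide[col].dropna()
            agg[f"median_{col}"] = float(v.median()) if len(v) else float("nan")
            agg[f"mean_{col}"] = float(v.mean()) if len(v) else float("nan")
        agg["auc"] = self.auc
        agg["fdr_threshold"] = self.fdr_threshold
        agg["n_accepted"] = int(self.per_slide["accepted"].sum())
        agg["n_slides"] = int(len(self.per_slide))
        return agg


def evaluate_slides(
    pairs: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    fdr_weights: tuple[float, float] = (2.0, 1.0),
    ci_method: str = "dice",
) -> ConcordanceReport:
    """Concordance report for (manual, auto, tissue) mask triples."""
    thr = fdr_acceptance_threshold(*fdr_weights)
    rows = []
    for k, (m, a, t) in enumerate(pairs):
        inc = inclusion_rate(m, a)
        exc = exclusion_rate(m, a, t)
        fdr = area_fdr(m, a)
        rows.append(
            {
                "slide": k,
                "inclusion": inc,
                "exclusion": exc,
                "ci": concordance_index(m, a, ci_method),
                "fdr": fdr,
                "accepted": bool(np.isfinite(fdr) and fdr <= thr),
            }
        )
    df = pd.DataFrame(rows)
    try:
        _, auc = slide_roc(list(zip(df["inclusion"], df["exclusion"])))
    except ValueError:
        auc = None
    return ConcordanceReport(per_slide=df, auc=auc, fdr_threshold=thr)
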