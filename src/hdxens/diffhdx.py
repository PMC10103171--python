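"""Hybrid significance testing for differential HDX between two states.

A (peptide, exposure) cell is called significant only when both
criteria hold:

1. |mean uptake difference| exceeds a global confidence-interval
   threshold computed from pooled replicate variances,

       threshold = t_crit(alpha, df_pooled) * sqrt(s_A^2/n_A + s_B^2/n_B),

   with per-state variances pooled over all testable cells (or per
   exposure when ``pooling='per_exposure'``); and
2. a per-cell Welch's t-test (unequal variances, Welch-Satterthwaite
   degrees of freedom) gives p < alpha.

The conjunction makes the test conservative relative to either
criterion alone.  Cells with fewer than two replicates in either state
are reported untestable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .types import PeptideSegment, UptakeTable


@dataclass
class HybridTestResult:
    """Per-(peptide, exposure) outcome of the hybrid test."""

    peptide_id: str
    exposure_s: float
    delta_uptake: float  # state B mean - state A mean
    global_threshold: float
    welch_p: float
    significant: bool
    testable: bool = True


def _cells(table: UptakeTable) -> pd.core.groupby.DataFrameGroupBy:
    return table.data.groupby(["peptide_id", "exposure_s"], sort=False)["uptake"]


def hybrid_test(
    a: UptakeTable,
    b: UptakeTable,
    alpha: float = 0.01,
    pooling: str = "global",
) -> list[HybridTestResult]:
    """Run the hybrid significance test on two states' uptake tables.

    ``delta_uptake`` is state B minus state A.  ``alpha`` defaults to
    0.01 (a 99% confidence threshold).  No multiple-testing correction
    is applied beyond the two-criterion conjunction.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if pooling not in ("global", "per_exposure"):
        raise ValidationError(f"unknown pooling mode {pooling!r}")
    if a.is_normalized != b.is_normalized:
        raise ValidationError("states must share units (both raw or both normalized)")

    cells_a = {k: v.to_numpy(float) for k, v in _cells(a)}
    cells_b = {k: v.to_numpy(float) for k, v in _cells(b)}
    shared = [k for k in cells_a if k in cells_b]
    if not shared:
        raise ValidationError("no shared (peptide, exposure) cells between states")

    def pooled_threshold(keys) -> float:
        va, vb, na, nb, df = [], [], [], [], 0
        for k in keys:
            xa, xb = cells_a[k], cells_b[k]
            if len(xa) < 2 or len(xb) < 2:
                continue
            va.append(np.var(xa, ddof=1))
            vb.append(np.var(xb, ddof=1))
            na.append(len(xa))
            nb.append(len(xb))
            df += (len(xa) - 1) + (len(xb) - 1)
        if not va:
            return np.nan
        s2a, s2b = np.mean(va), np.mean(vb)
        n_a, n_b = np.mean(na), np.mean(nb)
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(t_crit * np.sqrt(s2a / n_a + s2b / n_b))

    if pooling == "global":
        thr_global = pooled_threshold(shared)
        thresholds = {k: thr_global for k in shared}
    else:
        by_exp: dict[float, list] = {}
        for k in shared:
            by_exp.setdefault(k[1], []).append(k)
        per_exp = {t: pooled_threshold(keys) for t, keys in by_exp.items()}
        thresholds = {k: per_exp[k[1]] for k in shared}

    results = []
    for k in shared:
        xa, xb = cells_a[k], cells_b[k]
        delta = float(np.mean(xb) - np.mean(xa))
        thr = thresholds[k]
        if len(xa) < 2 or len(xb) < 2 or not np.isfinite(thr):
            results.append(
                HybridTestResult(k[0], float(k[1]), delta, np.nan, np.nan,
                                 significant=False, testable=False)
            )
            continue
        welch = stats.ttest_ind(xb, xa, equal_var=False)
        sig = bool(abs(delta) > thr and welch.pvalue < alpha)
        results.append(
            HybridTestResult(k[0], float(k[1]), delta, thr, float(welch.pvalue), sig)
        )
    return results


def results_frame(results: list[HybridTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide_id": [r.peptide_id for r in results],
            "exposure_s": [r.exposure_s for r in results],
            "delta": [r.delta_uptake for r in results],
            "threshold": [r.global_threshold for r in results],
            "welch_p": [r.welch_p for r in results],
            "significant": [r.significant for r in results],
            "testable": [r.testable for r in results],
        }
    )


def woods_summary(
    results: list[HybridTestResult],
    peptides: list[PeptideSegment],
    max_residue: Optional[int] = None,
) -> pd.DataFrame:
    """Classify residues from significant peptides (Woods-plot style).

    A peptide is significant when any exposure passes the hybrid test;
    its direction is the sign of the largest-magnitude significant
    delta (negative = protected, positive = deprotected).  Each residue
    is classified by majority vote over covering significant peptides;
    ties give 'nonsignificant', residues covered by no peptide at all
    give 'no-coverage'.
    """
    by_pep: dict[str, list[HybridTestResult]] = {}
    for r in results:
        by_pep.setdefault(r.peptide_id, []).append(r)

    direction: dict[str, int] = {}
    for pid, rs in by_pep.items():
        sig = [r for r in rs if r.significant]
        if sig:
            best = max(sig, key=lambda r: abs(r.delta_uptake))
            direction[pid] = 1 if best.delta_uptake > 0 else -1
        else:
            direction[pid] = 0

    if max_residue is None:
        max_residue = max(p.end for p in peptides)
    rows = []
    for res in range(1, max_residue + 1):
        covering = [p for p in peptides if p.start <= res <= p.end and p.peptide_id in direction]
        if not covering:
            rows.append((res, "no-coverage"))
            continue
        votes = [direction[p.peptide_id] for p in covering]
        n_prot = sum(1 for v in votes if v < 0)
        n_deprot = sum(1 for v in votes if v > 0)
        if n_prot > n_deprot:
            rows.append((res, "protected"))
        elif n_deprot > n_prot:
            rows.append((res, "deprotected"))
        else:
            rows.append((res, "nonsignificant"))
    return pd.DataFrame(rows, columns=["residue", "classification"])
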