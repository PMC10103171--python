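"""Re-optimization of the protection-factor scaling parameters.

The contact and hydrogen-bond scalings (beta_C, beta_H) of the
phenomenological ln PF model were calibrated on short simulations of
soluble proteins; for other systems (or much longer sampling) they can
be re-fit against an experimental dataset.  With frame weights held
fixed, the mean squared deviation between predicted and target peptide
deuteration is minimized over (beta_C, beta_H) within bounds, using a
coarse grid pre-scan to escape local minima followed by Nelder-Mead
refinement.  The procedure is deterministic given the grid and start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .forward import EnsemblePredictor, target_matrix
from .rates import IntrinsicRateSet
from .types import BetaParams, PeptideSegment, UptakeTable, _check_simplex

log = logging.getLogger(__name__)


@dataclass
class BetaFitResult:
    betas: BetaParams
    objective_value: float
    trace: pd.DataFrame  # beta_C, beta_H, objective
    non_identifiable: tuple[str, ...] = ()
    at_boundary: bool = False

    def __post_init__(self):
        if self.objective_value < 0:
            raise ValidationError("objective must be non-negative")


class BetaOptimizer(BaseEstimator):
    """Estimator fitting (beta_C, beta_H) at fixed frame weights.

    Parameters
    ----------
    init : BetaParams
        Starting point for local refinement.
    bounds : ((lo_C, hi_C), (lo_H, hi_H))
        Box constraints; defaults to [0, 2] x [0, 10].
    grid_points : int
        Points per axis of the coarse pre-scan (21 x 21 by default).
    first_residue_skip : int
        Peptide N-terminal residues excluded from exchange.

    Attributes (after ``fit``)
    --------------------------
    betas_ : BetaParams
    objective_ : float
    trace_ : DataFrame
    result_ : BetaFitResult
    """

    def __init__(
        self,
        init: BetaParams = BetaParams(0.35, 2.0),
        bounds: tuple = ((0.0, 2.0), (0.0, 10.0)),
        grid_points: int = 21,
        first_residue_skip: int = 1,
    ):
        self.init = init
        self.bounds = bounds
        self.grid_points = grid_points
        self.first_residue_skip = first_residue_skip

    def fit(
        self,
        features: pd.DataFrame,
        target: UptakeTable,
        rates: IntrinsicRateSet,
        peptides: Optional[list[PeptideSegment]] = None,
        w=None,
    ):
        (lo_c, hi_c), (lo_h, hi_h) = self.bounds
        if not (lo_c <= self.init.beta_C <= hi_c and lo_h <= self.init.beta_H <= hi_h):
            raise ValidationError("init betas outside bounds")
        if peptides is None:
            peptides = target.peptides
        predictor = EnsemblePredictor(
            features, rates, self.init, peptides, target.exposures,
            first_residue_skip=self.first_residue_skip,
        )
        n = predictor.n_frames
        w = np.full(n, 1.0 / n) if w is None else _check_simplex(np.asarray(w, float))
        tgt = target_matrix(target, predictor.peptide_ids, predictor.exposures)
        mask = np.isfinite(tgt)
        tgt0 = np.where(mask, tgt, 0.0)

        # flat directions: a feature that is constant across frames and
        # residues cannot constrain its beta
        flat = []
        if np.ptp(predictor._n_c) == 0 and predictor._n_c.max() == 0:
            flat.append("beta_C")
        if np.ptp(predictor._n_h) == 0 and predictor._n_h.max() == 0:
            flat.append("beta_H")

        trace_rows = []

        def objective(b):
            bc, bh = b
            if not (lo_c <= bc <= hi_c and lo_h <= bh <= hi_h):
                return np.inf
            predictor.set_betas(BetaParams(bc, bh))
            diff = np.where(mask, predictor.predict(w) - tgt0, 0.0)
            val = float(np.sum(diff * diff) / mask.sum())
            trace_rows.append((bc, bh, val))
            return val

        # coarse grid pre-scan
        grid_c = np.linspace(lo_c, hi_c, self.grid_points)
        grid_h = np.linspace(lo_h, hi_h, self.grid_points)
        best_val, best_b = np.inf, (self.init.beta_C, self.init.beta_H)
        for bc in grid_c:
            for bh in grid_h:
                v = objective((bc, bh))
                if v < best_val:
                    best_val, best_b = v, (bc, bh)

        # Nelder-Mead refinement from the better of grid optimum and init
        starts = [best_b, (self.init.beta_C, self.init.beta_H)]
        best = None
        for s in starts:
            res = minimize(
                objective, np.asarray(s, float), method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": 1e-15, "maxiter": 5000},
            )
            if best is None or res.fun < best.fun:
                best = res
        bc, bh = float(np.clip(best.x[0], lo_c, hi_c)), float(np.clip(best.x[1], lo_h, hi_h))
        obj = objective((bc, bh))
        if not np.isfinite(obj):
            raise ValidationError("beta objective is non-finite at the optimum")

        eps = 1e-9
        at_boundary = (
            min(bc - lo_c, hi_c - bc) < eps or min(bh - lo_h, hi_h - bh) < eps
        )
        if at_boundary:
            log.warning("beta optimum at a bound: (%.4g, %.4g)", bc, bh)
        if flat:
            log.warning("non-identifiable parameters (flat objective): %s", flat)

        self.betas_ = BetaParams(bc, bh)
        self.objective_ = obj
        self.trace_ = pd.DataFrame(
            trace_rows, columns=["beta_C", "beta_H", "objective"]
        )
        self.result_ = BetaFitResult(
            betas=self.betas_,
            objective_value=obj,
            trace=self.trace_,
            non_identifiable=tuple(flat),
            at_boundary=at_boundary,
        )
        return self


def fit_betas(
    features: pd.DataFrame,
    rates: IntrinsicRateSet,
    target: UptakeTable,
    peptides: Optional[list[PeptideSegment]] = None,
    w=None,
    init: BetaParams = BetaParams(0.35, 2.0),
    bounds: tuple = ((0.0, 2.0), (0.0, 10.0)),
    **kwargs,
) -> BetaFitResult:
    """Functional wrapper around :class:`BetaOptimizer`."""
    est = BetaOptimizer(init=init, bounds=bounds, **kwargs)
    est.fit(features, target, rates, peptides=peptides, w=w)
    return est.result_
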