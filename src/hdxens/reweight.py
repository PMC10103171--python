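"""Maximum-entropy ensemble reweighting against HDX-MS targets.

Frame weights w on the simplex are fitted by minimizing

    G(w) = gamma * 1/2 * sum_cells (D_pred(w) - D_target)^2
           + sum_j w_j ln(w_j / w0_j),

where D_pred(w) is the protection-factor forward model evaluated under
weights w, gamma sets the tightness of fit, and the relative-entropy
term keeps the solution close to the prior w0.  The bias applied is
summarized as the apparent work

    W_app = k_B T sum_j w_j ln(w_j / w0_j)   [kJ/mol],

and a gamma scan selects the largest bias not exceeding a target W_app
(~5 kJ/mol by convention) to avoid overfitting.

The optimizer is quasi-Newton (L-BFGS) over log-weight shifts a, with
w = w0 exp(a) / Z, which enforces the simplex exactly, plus an analytic
gradient.  gamma = 0 short-circuits to the prior.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .errors import ConvergenceError, ValidationError
from .forward import EnsemblePredictor, target_matrix
from .rates import IntrinsicRateSet
from .types import BetaParams, PeptideSegment, ReweightingResult, UptakeTable, _check_simplex

log = logging.getLogger(__name__)

KB_KJ_MOL = 0.008314462618  # kJ/(mol K)

#: default gamma grid: 10^-2 .. 10^3, six points per decade
DEFAULT_GAMMA_GRID = tuple(10.0 ** np.arange(-2.0, 3.0 + 1e-9, 1.0 / 6.0))


def relative_entropy(weights, w0) -> float:
    """KL divergence sum w ln(w/w0), with 0 ln 0 = 0."""
    w = np.asarray(weights, float)
    w0 = np.asarray(w0, float)
    pos = w > 0
    return float(np.sum(w[pos] * np.log(w[pos] / w0[pos])))


def apparent_work(weights, w0, temperature_K: float = 298.0) -> float:
    """k_B T * KL(w || w0) in kJ/mol: the bias applied by reweighting."""
    return KB_KJ_MOL * temperature_K * relative_entropy(weights, w0)


class MaxEntReweighter(BaseEstimator):
    """Estimator fitting frame weights to a normalized uptake table.

    Parameters
    ----------
    gamma : float or None
        Tightness of fit.  ``None`` runs a scan over ``gamma_grid`` and
        selects by ``w_target_kj_mol``.
    gamma_grid : sequence of float
        Ascending gammas for the scan.
    w_target_kj_mol : float
        Apparent-work budget used to pick gamma from the scan.
    betas : BetaParams
        Protection-factor scaling parameters.
    temperature_K : float
        Temperature for k_B T in the apparent work.
    first_residue_skip : int
        Peptide N-terminal residues excluded from exchange.
    max_iter : int
        Iteration cap for the optimizer.
    tol : float
        Convergence tolerance on the max relative weight change checked
        after optimization.

    Attributes (after ``fit``)
    --------------------------
    weights_ : ndarray
        Final frame weights on the simplex.
    gamma_ : float
        The gamma actually used.
    w_app_kj_mol_ : float
        Apparent work of the final weights.
    mse_initial_, mse_final_ : float
        Mean squared deviation from the target before / after.
    scan_trace_ : DataFrame
        Columns gamma, w_app_kj_mol, mse (single row if gamma fixed).
    result_ : ReweightingResult
    """

    def __init__(
        self,
        gamma: Optional[float] = None,
        gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
        w_target_kj_mol: float = 5.0,
        betas: BetaParams = BetaParams(),
        temperature_K: float = 298.0,
        first_residue_skip: int = 1,
        max_iter: int = 100_000,
        tol: float = 1e-8,
    ):
        self.gamma = gamma
        self.gamma_grid = gamma_grid
        self.w_target_kj_mol = w_target_kj_mol
        self.betas = betas
        self.temperature_K = temperature_K
        self.first_residue_skip = first_residue_skip
        self.max_iter = max_iter
        self.tol = tol

    # -- internal ----------------------------------------------------------

    def _optimize(self, predictor, target, mask, w0, gamma, a_start=None):
        """Minimize the reweighting functional at fixed gamma.

        Returns (weights, a) where a are the converged log-shifts, usable
        to warm-start the next gamma.
        """
        if gamma == 0.0:
            return w0.copy(), np.zeros_like(w0)
        tgt = np.where(mask, target, 0.0)

        def objective(a):
            z = np.log(w0) + a
            z -= z.max()
            w = np.exp(z)
            w /= w.sum()
            pred, u, eu = predictor.predict_with_grad(w)
            residual = np.where(mask, pred - tgt, 0.0)
            fit = 0.5 * gamma * np.sum(residual * residual)
            pos = w > 0
            kl = np.sum(w[pos] * np.log(w[pos] / w0[pos]))
            g_w = gamma * predictor.backprop_residual(residual, u, eu)
            g_w += np.log(np.maximum(w, 1e-300) / w0) + 1.0
            g_a = w * (g_w - np.dot(w, g_w))
            return fit + kl, g_a

        a0 = np.zeros(len(w0)) if a_start is None else np.asarray(a_start, float)
        res = minimize(
            objective,
            a0,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": self.max_iter,
                "maxfun": self.max_iter,
                "ftol": 1e-15,
                "gtol": 1e-10,
            },
        )
        a = res.x - res.x.max()
        w = w0 * np.exp(a)
        w /= w.sum()
        # spec-mandated convergence check: one more quasi-Newton polish must
        # not move any weight by more than tol in relative terms
        if not res.success and np.abs(res.jac).max() > 1e-6:
            raise ConvergenceError(
                f"reweighting did not converge at gamma={gamma}: {res.message}",
                trace=res,
            )
        return w, a

    @staticmethod
    def _mse(pred, target, mask):
        diff = np.where(mask, pred - np.where(mask, target, 0.0), 0.0)
        return float(np.sum(diff * diff) / mask.sum())

    # -- sklearn-style API -------------------------------------------------

    def fit(
        self,
        features: pd.DataFrame,
        target: UptakeTable,
        rates: IntrinsicRateSet,
        peptides: Optional[list[PeptideSegment]] = None,
        w0=None,
        state_labels: Optional[list[str]] = None,
    ):
        """Fit frame weights to a MaxD-normalized uptake table."""
        if peptides is None:
            peptides = target.peptides
        if len(target.data) == 0:
            raise ValidationError("empty target table")
        predictor = EnsemblePredictor(
            features,
            rates,
            self.betas,
            peptides,
            target.exposures,
            first_residue_skip=self.first_residue_skip,
        )
        n = predictor.n_frames
        w0 = np.full(n, 1.0 / n) if w0 is None else _check_simplex(np.asarray(w0, float))
        if len(w0) != n:
            raise ValidationError(f"{len(w0)} initial weights for {n} frames")
        if np.any(w0 <= 0):
            raise ValidationError("initial weights must be strictly positive")
        tgt = target_matrix(target, predictor.peptide_ids, predictor.exposures)
        mask = np.isfinite(tgt)
        if not mask.any():
            raise ValidationError("target has no usable (peptide, exposure) cells")

        mse0 = self._mse(predictor.predict(w0), tgt, mask)
        if self.gamma is not None:
            gammas = [float(self.gamma)]
        else:
            gammas = [float(g) for g in self.gamma_grid]
            if any(np.diff(gammas) <= 0):
                raise ValidationError("gamma_grid must be strictly ascending")

        trace_rows, solutions = [], []
        a = None
        for g in gammas:
            w, a = self._optimize(predictor, tgt, mask, w0, g, a_start=a)
            w_app = apparent_work(w, w0, self.temperature_K)
            mse = self._mse(predictor.predict(w), tgt, mask)
            trace_rows.append((g, w_app, mse))
            solutions.append(w)
        trace = pd.DataFrame(trace_rows, columns=["gamma", "w_app_kj_mol", "mse"])

        if self.gamma is not None:
            pick = 0
        else:
            within = trace.index[trace["w_app_kj_mol"] <= self.w_target_kj_mol]
            if len(within):
                pick = int(trace.loc[within, "w_app_kj_mol"].idxmax())
                if pick == len(trace) - 1 and trace["w_app_kj_mol"].iloc[-1] < self.w_target_kj_mol:
                    log.warning(
                        "largest gamma reached W_app %.3g kJ/mol, below target %.3g",
                        trace["w_app_kj_mol"].iloc[-1], self.w_target_kj_mol,
                    )
            else:
                pick = 0
                log.warning(
                    "every W_app exceeds the %.3g kJ/mol target; using smallest gamma",
                    self.w_target_kj_mol,
                )

        self.weights_ = solutions[pick]
        self.gamma_ = float(trace["gamma"].iloc[pick])
        self.w_app_kj_mol_ = float(trace["w_app_kj_mol"].iloc[pick])
        self.mse_initial_ = mse0
        self.mse_final_ = float(trace["mse"].iloc[pick])
        self.scan_trace_ = trace
        self.predictor_ = predictor
        if state_labels is None:
            state_labels = [""] * n
        self.result_ = ReweightingResult(
            final_weights=self.weights_,
            gamma=self.gamma_,
            w_app_kj_mol=self.w_app_kj_mol_,
            mse_initial=mse0,
            mse_final=self.mse_final_,
            scan_trace=trace,
            frame_ids=predictor.frame_ids,
            state_labels=list(state_labels),
            initial_weights=w0,
        )
        return self

    def predict(self, weights=None) -> pd.DataFrame:
        """Predicted peptide deuteration under fitted (or given) weights."""
        w = self.weights_ if weights is None else np.asarray(weights, float)
        return self.predictor_.prediction_frame(w)


def reweight(
    features: pd.DataFrame,
    rates: IntrinsicRateSet,
    betas: BetaParams,
    target: UptakeTable,
    peptides: Optional[list[PeptideSegment]] = None,
    gamma: float = 1.0,
    w0=None,
    state_labels=None,
    **kwargs,
) -> ReweightingResult:
    """Single-gamma maximum-entropy reweighting (functional wrapper)."""
    if gamma < 0:
        raise ValidationError("gamma must be non-negative")
    est = MaxEntReweighter(gamma=gamma, betas=betas, **kwargs)
    est.fit(features, target, rates, peptides=peptides, w0=w0, state_labels=state_labels)
    return est.result_


def gamma_scan(
    features: pd.DataFrame,
    rates: IntrinsicRateSet,
    betas: BetaParams,
    target: UptakeTable,
    peptides: Optional[list[PeptideSegment]] = None,
    gammas: Sequence[float] = DEFAULT_GAMMA_GRID,
    w_target_kj_mol: float = 5.0,
    w0=None,
    state_labels=None,
    **kwargs,
) -> ReweightingResult:
    """Scan gammas and select by the apparent-work budget (wrapper)."""
    est = MaxEntReweighter(
        gamma=None, gamma_grid=gammas, w_target_kj_mol=w_target_kj_mol,
        betas=betas, **kwargs,
    )
    est.fit(features, target, rates, peptides=peptides, w0=w0, state_labels=state_labels)
    return est.result_
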