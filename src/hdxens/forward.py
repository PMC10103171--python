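"""Forward model: from ensemble features to peptide-level deuterated fractions.

The protection factor of residue i under frame weights w is modelled as

    ln PF_i = sum_j w_j * (beta_C * N_C(i,j) + beta_H * N_H(i,j)),

i.e. the ensemble average of a linear combination of heavy-atom contacts
and amide hydrogen bonds (the Best-Vendruscolo phenomenological model).
Under EX2 kinetics the deuterated fraction of residue i after exposure t is

    D_i(t) = 1 - exp(-k_int,i * t / PF_i),

and a peptide's deuterated fraction is the unweighted mean of D_i(t)
over its exchange-competent residues (skipping the peptide's first
residue and prolines).  Predictions are compared directly with
MaxD-normalized experimental fractions; no separate back-exchange
correction is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DimensionError, ValidationError
from .rates import IntrinsicRateSet
from .types import (
    BetaParams,
    PeptideSegment,
    ProtectionFactorSet,
    UptakeTable,
    _check_simplex,
)

log = logging.getLogger(__name__)


def _feature_matrices(features: pd.DataFrame):
    """Pivot the long feature table into (n_frames, n_residues) matrices.

    Frame order follows first appearance in the table; residue order is
    ascending.  Every frame must cover every residue.
    """
    frame_ids = list(dict.fromkeys(features["frame_id"]))
    piv_c = features.pivot(index="frame_id", columns="residue", values="N_C")
    piv_h = features.pivot(index="frame_id", columns="residue", values="N_H")
    if piv_c.isna().any().any() or piv_h.isna().any().any():
        raise DimensionError("feature table does not cover every (frame, residue)")
    piv_c = piv_c.loc[frame_ids]
    piv_h = piv_h.loc[frame_ids]
    residues = piv_c.columns.to_numpy(dtype=int)
    return frame_ids, residues, piv_c.to_numpy(float), piv_h.to_numpy(float)


def protection_factors(
    features: pd.DataFrame, weights, betas: BetaParams = BetaParams()
) -> ProtectionFactorSet:
    """Weighted ensemble-average ln PF per residue."""
    frame_ids, residues, n_c, n_h = _feature_matrices(features)
    w = _check_simplex(np.asarray(weights, dtype=float))
    if w.shape[0] != len(frame_ids):
        raise DimensionError(
            f"{w.shape[0]} weights for {len(frame_ids)} frames in feature table"
        )
    per_frame = betas.beta_C * n_c + betas.beta_H * n_h
    return ProtectionFactorSet(residues=residues, ln_pf=w @ per_frame, weights=w)


def residue_deuteration(
    pf: ProtectionFactorSet, rates: IntrinsicRateSet, exposures
) -> pd.DataFrame:
    """D_i(t) = 1 - exp(-k_int,i t / PF_i) for each residue and exposure.

    Exposures in seconds; rates are per minute internally.
    """
    exposures = np.asarray(exposures, dtype=float)
    if (exposures < 0).any():
        raise ValidationError("negative exposure time")
    missing = [r for r in pf.residues if r not in rates]
    if missing:
        raise ValidationError(f"no intrinsic rate for residues {missing}")
    k_per_s = rates.as_per_second(pf.residues)
    pf_vals = np.exp(pf.ln_pf)
    d = 1.0 - np.exp(-np.outer(k_per_s / pf_vals, exposures))
    return pd.DataFrame(d, index=pf.residues, columns=exposures)


def peptide_deuteration(
    residue_d: pd.DataFrame,
    peptides: list[PeptideSegment],
    first_residue_skip: int = 1,
) -> pd.DataFrame:
    """Peptide-level deuterated fractions: mean over competent residues.

    Returns a (peptide_id x exposure) frame.  Peptides with no
    exchange-competent residue covered by ``residue_d`` are dropped with
    a warning.
    """
    rows = {}
    available = set(residue_d.index)
    for pep in peptides:
        competent = [
            r
            for r in pep.exchange_competent_residues(first_residue_skip)
            if r in available
        ]
        if not competent:
            log.warning("peptide %s has no exchange-competent residues; excluded",
                        pep.peptide_id)
            continue
        rows[pep.peptide_id] = residue_d.loc[competent].mean(axis=0)
    return pd.DataFrame(rows).T


def normalize_to_maxd(raw: UptakeTable, maxd: UptakeTable) -> UptakeTable:
    """Divide raw uptake (Da) by the per-peptide mean MaxD uptake.

    The maximally deuterated control sets the experimentally attainable
    ceiling per peptide, so the ratio is an absolute deuterated fraction
    with back-exchange cancelled.  Values outside [0, 1] produced by
    noise are preserved (the peptide filter deals with negatives).
    """
    if raw.is_normalized:
        raise ValidationError("raw table is already normalized")
    maxd_mean = maxd.data.groupby("peptide_id")["uptake"].mean()
    out = raw.data.copy()
    keep = np.ones(len(out), dtype=bool)
    denominators = np.empty(len(out))
    for i, pid in enumerate(out["peptide_id"]):
        if pid not in maxd_mean.index or maxd_mean[pid] <= 0:
            keep[i] = False
        else:
            denominators[i] = maxd_mean[pid]
    dropped = set(out.loc[~keep, "peptide_id"])
    for pid in sorted(dropped):
        reason = "absent from MaxD" if pid not in maxd_mean.index else "MaxD mean <= 0"
        log.warning("peptide %s dropped during normalization: %s", pid, reason)
    out = out.loc[keep].copy()
    out["uptake"] = out["uptake"].to_numpy() / denominators[keep]
    return UptakeTable(out, is_normalized=True)


def filter_peptides(
    table: UptakeTable, structure_span: tuple[int, int]
) -> UptakeTable:
    """Remove peptides unusable for reweighting.

    A peptide is excluded when (a) it overlaps residues outside
    ``structure_span`` (unresolved in the candidate structures), or
    (b) its replicate-mean normalized deuteration is negative at any
    exposure (experimental noise).  Every exclusion is logged with its
    reason.
    """
    lo, hi = structure_span
    means = table.mean_uptake()
    keep_ids = []
    for pep in table.peptides:
        if pep.start < lo or pep.end > hi:
            log.warning(
                "peptide %s (%d-%d) excluded: outside structure span %d-%d",
                pep.peptide_id, pep.start, pep.end, lo, hi,
            )
            continue
        pep_means = means.loc[means["peptide_id"] == pep.peptide_id, "uptake"]
        if (pep_means < 0).any():
            log.warning(
                "peptide %s excluded: negative mean deuteration", pep.peptide_id
            )
            continue
        keep_ids.append(pep.peptide_id)
    if not keep_ids:
        log.warning("peptide filter removed every peptide")
    return table.subset_peptides(keep_ids)


class EnsemblePredictor:
    """Precomputed forward model for fast repeated evaluation.

    Caches the per-frame ln PF contribution matrix, the intrinsic-rate /
    exposure grid and the peptide averaging operator so that predictions
    and their gradient with respect to frame weights cost a few matrix
    products.  Used by the reweighting optimizer and the beta fit.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        rates: IntrinsicRateSet,
        betas: BetaParams,
        peptides: list[PeptideSegment],
        exposures,
        first_residue_skip: int = 1,
    ):
        self.frame_ids, residues, self._n_c, self._n_h = _feature_matrices(features)
        self.exposures = np.asarray(exposures, dtype=float)
        if (self.exposures <= 0).any():
            raise ValidationError("exposures must be positive")

        # residues usable: featurized AND having an intrinsic rate
        usable = np.array([r in rates for r in residues])
        residues = residues[usable]
        self._n_c = self._n_c[:, usable]
        self._n_h = self._n_h[:, usable]
        self.residues = residues

        res_pos = {r: i for i, r in enumerate(residues)}
        avg_rows, self.peptide_ids = [], []
        for pep in peptides:
            competent = [
                res_pos[r]
                for r in pep.exchange_competent_residues(first_residue_skip)
                if r in res_pos
            ]
            if not competent:
                log.warning(
                    "peptide %s has no usable residues; excluded from predictor",
                    pep.peptide_id,
                )
                continue
            row = np.zeros(len(residues))
            row[competent] = 1.0 / len(competent)
            avg_rows.append(row)
            self.peptide_ids.append(pep.peptide_id)
        if not avg_rows:
            raise ValidationError("no peptide has usable residues")
        self._avg = np.array(avg_rows)  # (n_pep, n_res), rows sum to 1
        self._kt = np.outer(
            rates.as_per_second(residues), self.exposures
        )  # (n_res, n_t)
        self.set_betas(betas)

    def set_betas(self, betas: BetaParams) -> None:
        self.betas = betas
        self._p = betas.beta_C * self._n_c + betas.beta_H * self._n_h

    @property
    def n_frames(self) -> int:
        return len(self.frame_ids)

    def ln_pf(self, weights: np.ndarray) -> np.ndarray:
        return np.asarray(weights, float) @ self._p

    def predict(self, weights: np.ndarray) -> np.ndarray:
        """(n_peptides, n_exposures) deuterated fractions under ``weights``."""
        u = self._kt * np.exp(-self.ln_pf(weights))[:, None]
        return self._avg @ (1.0 - np.exp(-u))

    def predict_with_grad(self, weights: np.ndarray):
        """Prediction plus dD_cell/dw_j as a (n_pep, n_t, n_frames) tensor
        contraction helper: returns (pred, u, exp(-u)) for the optimizer."""
        u = self._kt * np.exp(-self.ln_pf(weights))[:, None]
        eu = np.exp(-u)
        return self._avg @ (1.0 - eu), u, eu

    def backprop_residual(self, residual: np.ndarray, u, eu) -> np.ndarray:
        """Gradient of 0.5*sum(residual^2) w.r.t. weights, given residual
        = pred - target on the (n_pep, n_t) grid (zeros where masked)."""
        s = self._avg.T @ residual  # (n_res, n_t)
        c = np.sum(s * (-u * eu), axis=1)  # d fit / d lnPF_i
        return self._p @ c

    def prediction_frame(self, weights: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            self.predict(weights), index=self.peptide_ids, columns=self.exposures
        )


def target_matrix(
    table: UptakeTable, peptide_ids: list[str], exposures
) -> np.ndarray:
    """Replicate-mean target fractions aligned to a predictor's grid.

    Missing (peptide, exposure) cells are NaN and must be masked by the
    caller.
    """
    if not table.is_normalized:
        raise ValidationError("target table must be MaxD-normalized")
    means = table.mean_uptake().set_index(["peptide_id", "exposure_s"])["uptake"]
    exposures = np.asarray(exposures, dtype=float)
    out = np.full((len(peptide_ids), len(exposures)), np.nan)
    for i, pid in enumerate(peptide_ids):
        for j, t in enumerate(exposures):
            key = (pid, t)
            if key in means.index:
                out[i, j] = means[key]
    return out
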