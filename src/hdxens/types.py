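"""Core value types shared across the pipeline.

Conventions used throughout the package:

* residue numbering is 1-based and ranges are inclusive, matching the
  "peptide 31-40" style used in the HDX-MS literature;
* uptake tables are either in daltons (raw) or dimensionless fractional
  uptake (after MaxD normalization), recorded by ``is_normalized``;
* frame weights live on the probability simplex (non-negative, summing
  to one within 1e-9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DimensionError, ValidationError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Columns every uptake table carries, in canonical order.
UPTAKE_COLUMNS = [
    "peptide_id",
    "state",
    "start",
    "end",
    "sequence",
    "exposure_s",
    "replicate",
    "uptake",
]

WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class PeptideSegment:
    """A proteolytic peptide: residues ``start``..``end`` inclusive."""

    peptide_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if self.start < 1:
            raise ValidationError(
                f"peptide {self.peptide_id}: start must be >= 1, got {self.start}"
            )
        if self.end < self.start:
            raise ValidationError(
                f"peptide {self.peptide_id}: end {self.end} < start {self.start}"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"peptide {self.peptide_id}: sequence length {len(self.sequence)} "
                f"does not match span {self.start}-{self.end}"
            )
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"peptide {self.peptide_id}: non-canonical residue codes {sorted(bad)}"
            )

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def exchange_competent_residues(self, first_residue_skip: int = 1) -> list[int]:
        """Residues of this peptide that can report exchange.

        Skips the first ``first_residue_skip`` residues (rapid back-exchange
        at the peptide N-terminus) and every proline (no backbone amide H).
        """
        out = []
        for offset, res in enumerate(self.residues):
            if offset < first_residue_skip:
                continue
            if self.sequence[offset] == "P":
                continue
            out.append(res)
        return out


@dataclass
class UptakeTable:
    """Replicate deuterium-uptake measurements, raw (Da) or normalized.

    ``data`` has the columns of :data:`UPTAKE_COLUMNS`.  Normalized values
    may legitimately fall outside [0, 1] because of replicate noise; the
    downstream peptide filter removes peptides with negative means.
    """

    data: pd.DataFrame
    is_normalized: bool = False

    def __post_init__(self):
        missing = [c for c in UPTAKE_COLUMNS if c not in self.data.columns]
        if missing:
            from .errors import FormatError

            raise FormatError(f"uptake table missing columns: {missing}")
        if (self.data["exposure_s"] <= 0).any():
            bad = self.data.loc[self.data["exposure_s"] <= 0].index[0]
            raise ValidationError(f"non-positive exposure_s at row {bad}")
        dup = self.data.duplicated(
            subset=["peptide_id", "state", "exposure_s", "replicate"]
        )
        if dup.any():
            raise ValidationError(
                f"duplicate (peptide,state,exposure,replicate) rows: "
                f"{self.data.loc[dup, 'peptide_id'].tolist()}"
            )
        self.data = self.data[UPTAKE_COLUMNS].reset_index(drop=True)

    @property
    def peptides(self) -> list[PeptideSegment]:
        """The implied peptide-segment list, in first-appearance order."""
        segs = []
        seen = set()
        for _, row in self.data.iterrows():
            if row["peptide_id"] in seen:
                continue
            seen.add(row["peptide_id"])
            segs.append(
                PeptideSegment(
                    str(row["peptide_id"]),
                    int(row["start"]),
                    int(row["end"]),
                    str(row["sequence"]),
                )
            )
        return segs

    @property
    def exposures(self) -> np.ndarray:
        return np.sort(self.data["exposure_s"].unique())

    def mean_uptake(self) -> pd.DataFrame:
        """Replicate-mean uptake per (peptide_id, exposure_s)."""
        return (
            self.data.groupby(["peptide_id", "exposure_s"], sort=False)["uptake"]
            .mean()
            .reset_index()
        )

    def subset_peptides(self, keep_ids) -> "UptakeTable":
        keep = self.data["peptide_id"].isin(set(keep_ids))
        return UptakeTable(self.data.loc[keep].copy(), is_normalized=self.is_normalized)


def _check_simplex(weights: np.ndarray, name: str = "weights") -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1:
        raise DimensionError(f"{name} must be 1-D, got shape {w.shape}")
    if w.size == 0:  # empty results are legal (header-only files)
        return w
    if (w < -WEIGHT_TOL).any():
        raise ValidationError(f"{name} contain negative entries")
    if abs(w.sum() - 1.0) > WEIGHT_TOL:
        raise ValidationError(f"{name} sum to {w.sum()!r}, expected 1 within {WEIGHT_TOL}")
    return w


@dataclass
class StructuralEnsemble:
    """An ordered set of frames with per-frame state labels and weights.

    A frame carries either atomic coordinates (``coords`` plus the atom
    annotation table) or precomputed per-residue features (``features``
    with columns frame_id, residue, N_C, N_H).  Weights default to the
    uniform prior.
    """

    frame_ids: list[str]
    state_labels: list[str]
    coords: Optional[np.ndarray] = None  # (n_frames, n_atoms, 3), angstrom
    atoms: Optional[pd.DataFrame] = None  # atom_name, res_id, res_name, element
    features: Optional[pd.DataFrame] = None  # frame_id, residue, N_C, N_H
    initial_weights: Optional[np.ndarray] = None

    def __post_init__(self):
        n = len(self.frame_ids)
        if len(self.state_labels) != n:
            raise DimensionError("state_labels length must match frame_ids")
        if self.initial_weights is None:
            self.initial_weights = np.full(n, 1.0 / n)
        self.initial_weights = _check_simplex(self.initial_weights, "initial_weights")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape[0] != n:
                raise DimensionError(
                    f"coords has {self.coords.shape[0]} frames, expected {n}"
                )
        if self.coords is None and self.features is None:
            raise ValidationError("ensemble needs coordinates or precomputed features")

    @property
    def n_frames(self) -> int:
        return len(self.frame_ids)

    @property
    def has_features(self) -> bool:
        return self.features is not None

    def subset(self, idx) -> "StructuralEnsemble":
        """Sub-ensemble at frame indices ``idx``; weights renormalized."""
        idx = np.asarray(idx, dtype=int)
        w = self.initial_weights[idx]
        feats = None
        if self.features is not None:
            keep = [self.frame_ids[i] for i in idx]
            feats = self.features[self.features["frame_id"].isin(keep)].copy()
        return StructuralEnsemble(
            frame_ids=[self.frame_ids[i] for i in idx],
            state_labels=[self.state_labels[i] for i in idx],
            coords=None if self.coords is None else self.coords[idx],
            atoms=self.atoms,
            features=feats,
            initial_weights=w / w.sum(),
        )


@dataclass(frozen=True)
class BetaParams:
    """Scaling of contacts (beta_C) and hydrogen bonds (beta_H) in ln PF."""

    beta_C: float = 0.35
    beta_H: float = 2.0

    def __post_init__(self):
        if self.beta_C < 0 or self.beta_H < 0:
            raise ValidationError("beta parameters must be non-negative")


@dataclass
class ProtectionFactorSet:
    """Ensemble-averaged ln PF per exchange-competent residue."""

    residues: np.ndarray  # int, 1-based
    ln_pf: np.ndarray  # dimensionless
    weights: np.ndarray  # the frame weights used

    def __post_init__(self):
        self.residues = np.asarray(self.residues, dtype=int)
        self.ln_pf = np.asarray(self.ln_pf, dtype=float)
        if self.residues.shape != self.ln_pf.shape:
            raise DimensionError("residues and ln_pf must align")
        if not np.isfinite(self.ln_pf).all():
            raise ValidationError("ln PF contains non-finite values")

    def as_series(self) -> pd.Series:
        return pd.Series(self.ln_pf, index=self.residues, name="ln_pf")

    def delta_g_open_kj_mol(self, temperature_K: float = 298.0) -> pd.Series:
        """Apparent opening free energy R*T*lnPF per residue (kJ/mol).

        A convenience transform for reports; not validated against
        thermodynamic measurements.
        """
        r_kj = 0.008314462618
        return pd.Series(
            r_kj * temperature_K * self.ln_pf, index=self.residues,
            name="delta_g_open_kj_mol",
        )


@dataclass
class ReweightingResult:
    """Outcome of one maximum-entropy reweighting run."""

    final_weights: np.ndarray
    gamma: float
    w_app_kj_mol: float
    mse_initial: float
    mse_final: float
    scan_trace: pd.DataFrame  # columns gamma, w_app_kj_mol, mse
    frame_ids: list[str]
    state_labels: list[str]
    initial_weights: np.ndarray

    def __post_init__(self):
        self.final_weights = _check_simplex(self.final_weights, "final_weights")
        if self.w_app_kj_mol < -1e-12:
            raise ValidationError("apparent work must be non-negative")


@dataclass
class PopulationEstimate:
    """Fractional state populations with optional subsampling SD."""

    fractions: dict  # state label -> fraction in [0, 1]
    sd: Optional[dict] = None  # state label -> SD over subsamples
    n_subsamples: int = 0

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"populations sum to {total}, expected 1")
        if self.sd is not None and any(v < 0 for v in self.sd.values()):
            raise ValidationError("population SDs must be non-negative")
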