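"""Self-contained synthetic data with the statistical structure the
pipeline assumes.

Emulates a two-state transporter-like system: an outward-facing (OF)
and an inward-facing (IF) conformational state that protect
complementary halves of the sequence.  Per frame and residue, contact
counts are Poisson and hydrogen-bond counts are small binomials, with
state-specific profiles, so the two states are HDX-distinguishable.
Experimental tables are emulated with a per-peptide multiplicative
back-exchange loss (cancelled exactly by MaxD normalization) and
Gaussian replicate noise on the normalized scale.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .forward import peptide_deuteration, protection_factors, residue_deuteration
from .rates import IntrinsicRateSet, intrinsic_rates
from .types import (
    BetaParams,
    PeptideSegment,
    StructuralEnsemble,
    UPTAKE_COLUMNS,
    UptakeTable,
)

_NON_PROLINE = "ACDEFGHIKLMNQRSTVWY"


@dataclass(frozen=True)
class StateProfile:
    """Per-residue feature statistics of one conformational state."""

    label: str
    lambda_c: np.ndarray  # Poisson mean of N_C per residue
    p_h: np.ndarray  # per-trial H-bond probability per residue

    def __post_init__(self):
        if (np.asarray(self.lambda_c) < 0).any():
            raise ValidationError("lambda_c must be non-negative")
        p = np.asarray(self.p_h)
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("p_h must lie in [0, 1]")


def default_two_state_profiles(
    n_residues: int,
    lambda_base: float = 14.0,
    lambda_protected: float = 22.0,
    p_base: float = 0.2,
    p_protected: float = 0.8,
) -> list[StateProfile]:
    """OF protects the first half of the chain, IF the second half,
    mimicking the alternating-access exposure pattern."""
    half = n_residues // 2
    lam_of = np.full(n_residues, lambda_base)
    lam_if = np.full(n_residues, lambda_base)
    p_of = np.full(n_residues, p_base)
    p_if = np.full(n_residues, p_base)
    lam_of[:half] = lambda_protected
    p_of[:half] = p_protected
    lam_if[half:] = lambda_protected
    p_if[half:] = p_protected
    return [StateProfile("OF", lam_of, p_of), StateProfile("IF", lam_if, p_if)]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic two-state benchmark."""

    n_residues: int = 60
    peptide_length: tuple[int, int] = (6, 12)
    peptide_step: int = 3
    states: list[StateProfile] | None = None
    n_frames_per_state: int = 100
    true_mixture: dict[str, float] = field(default_factory=lambda: {"OF": 0.8, "IF": 0.2})
    n_hbond_trials: int = 2
    noise_sd: float = 0.01
    n_replicates: int = 3
    exposures: tuple[float, ...] = (30.0, 300.0, 3600.0)
    pD: float = 7.4
    temperature_K: float = 298.0
    seed: int = 17

    def __post_init__(self):
        if self.states is None:
            self.states = default_two_state_profiles(self.n_residues)
        if abs(sum(self.true_mixture.values()) - 1.0) > 1e-9:
            raise ValidationError("true_mixture must sum to 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        for s in self.states:
            if len(s.lambda_c) != self.n_residues or len(s.p_h) != self.n_residues:
                raise ValidationError(
                    f"state {s.label}: profile length != n_residues"
                )


def spec_sequence(spec: SyntheticSpec) -> str:
    """Deterministic pseudo-random sequence with a couple of prolines."""
    rng = np.random.default_rng(spec.seed + 1_000_003)
    seq = list(rng.choice(list(_NON_PROLINE), size=spec.n_residues))
    if spec.n_residues >= 20:  # sprinkle prolines away from the termini
        for pos in (spec.n_residues // 3, 2 * spec.n_residues // 3):
            seq[pos] = "P"
    return "".join(seq)


def make_peptide_map(spec: SyntheticSpec) -> list[PeptideSegment]:
    """Overlapping peptides tiling the chain (deterministic under seed)."""
    rng = np.random.default_rng(spec.seed + 2_000_003)
    seq = spec_sequence(spec)
    lo, hi = spec.peptide_length
    peptides = []
    start = 1
    i = 0
    while start <= spec.n_residues - lo + 1:
        length = int(rng.integers(lo, hi + 1))
        end = min(start + length - 1, spec.n_residues)
        peptides.append(
            PeptideSegment(f"pep{i:02d}", start, end, seq[start - 1 : end])
        )
        start += spec.peptide_step
        i += 1
    return peptides


def spec_rates(spec: SyntheticSpec) -> IntrinsicRateSet:
    return intrinsic_rates(
        spec_sequence(spec), pD=spec.pD, temperature_K=spec.temperature_K
    )


def make_feature_ensemble(spec: SyntheticSpec) -> StructuralEnsemble:
    """Feature-bearing ensemble: N_C ~ Poisson, N_H ~ Binomial per state.

    Residue 1 and prolines are excluded from the feature table, matching
    what geometric featurization of coordinates would produce.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec_sequence(spec)
    competent = [
        r for r in range(2, spec.n_residues + 1) if seq[r - 1] != "P"
    ]
    rows = []
    frame_ids, labels = [], []
    for state in spec.states:
        for f in range(spec.n_frames_per_state):
            fid = f"{state.label}_{f}"
            frame_ids.append(fid)
            labels.append(state.label)
            lam = state.lambda_c[np.array(competent) - 1]
            p = state.p_h[np.array(competent) - 1]
            n_c = rng.poisson(lam)
            n_h = rng.binomial(spec.n_hbond_trials, p)
            for r, c, h in zip(competent, n_c, n_h):
                rows.append((fid, r, int(c), int(h)))
    features = pd.DataFrame(rows, columns=["frame_id", "residue", "N_C", "N_H"])
    return StructuralEnsemble(
        frame_ids=frame_ids, state_labels=labels, features=features
    )


def true_weights(spec: SyntheticSpec, ensemble: StructuralEnsemble) -> np.ndarray:
    """Frame weights realizing the spec's true state mixture (uniform
    within each state)."""
    labels = np.array(ensemble.state_labels)
    w = np.empty(len(labels))
    for s, frac in spec.true_mixture.items():
        sel = labels == s
        w[sel] = frac / sel.sum()
    return w


def make_target_uptake(
    spec: SyntheticSpec,
    betas: BetaParams = BetaParams(),
    rates: IntrinsicRateSet | None = None,
):
    """Emulated experimental tables plus the known ground truth.

    Returns (raw_table_Da, maxd_table_Da, truth) where truth holds the
    mixture fractions, the noiseless normalized fractions and the drawn
    back-exchange factors.  Noiseless peptide deuteration is computed
    through the forward model under the true mixture, scaled to daltons
    by n_amides x back-exchange (uniform 0.6-0.9 per peptide, drawn
    once), and replicate Gaussian noise of sd ``noise_sd`` (normalized
    scale) is added to both the deuterated samples and the MaxD control.
    """
    rng = np.random.default_rng(spec.seed + 3_000_003)
    ensemble = make_feature_ensemble(spec)
    peptides = make_peptide_map(spec)
    rates = rates or spec_rates(spec)
    w_true = true_weights(spec, ensemble)

    pf = protection_factors(ensemble.features, w_true, betas)
    res_d = residue_deuteration(pf, rates, spec.exposures)
    pep_d = peptide_deuteration(res_d, peptides)  # (peptide x exposure)

    backex = {p.peptide_id: rng.uniform(0.6, 0.9) for p in peptides}
    n_amides = {
        p.peptide_id: len(p.exchange_competent_residues()) for p in peptides
    }
    seg = {p.peptide_id: p for p in peptides}

    raw_rows, maxd_rows = [], []
    for pid in pep_d.index:
        p = seg[pid]
        ceiling = n_amides[pid] * backex[pid]  # Da at full deuteration
        for t in spec.exposures:
            frac = float(pep_d.loc[pid, t])
            for rep in range(1, spec.n_replicates + 1):
                eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
                raw_rows.append(
                    (pid, "sample", p.start, p.end, p.sequence, t, rep,
                     (frac + eps) * ceiling)
                )
        for rep in range(1, spec.n_replicates + 1):
            eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
            maxd_rows.append(
                (pid, "maxd", p.start, p.end, p.sequence, float(spec.exposures[-1]),
                 rep, (1.0 + eps) * ceiling)
            )

    raw = UptakeTable(pd.DataFrame(raw_rows, columns=UPTAKE_COLUMNS))
    maxd = UptakeTable(pd.DataFrame(maxd_rows, columns=UPTAKE_COLUMNS))
    truth = {
        "mixture": dict(spec.true_mixture),
        "noiseless_fractions": pep_d,
        "back_exchange": backex,
        "weights": w_true,
    }
    return raw, maxd, truth


# ---------------------------------------------------------------------------
# toy coordinates

_BB = {  # ideal backbone geometry: bond lengths (A) and angles (deg)
    "N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231, "N_H": 1.01,
    "ang_N_CA_C": 111.2, "ang_CA_C_N": 116.2, "ang_C_N_CA": 121.7,
    "ang_CA_C_O": 120.8,
}

_DIHEDRALS = {"helix": (-57.0, -47.0), "extended": (-139.0, 135.0)}


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """Position a new atom bonded to c with given internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_chain(n_residues: int, phi: float, psi: float):
    """Ideal-geometry poly-alanine backbone (N, H, CA, C, O per residue)."""
    g = _BB
    coords: dict[tuple[int, str], np.ndarray] = {}
    coords[(1, "N")] = np.zeros(3)
    coords[(1, "CA")] = np.array([g["N_CA"], 0.0, 0.0])
    ang = np.deg2rad(180.0 - g["ang_N_CA_C"])
    coords[(1, "C")] = coords[(1, "CA")] + g["CA_C"] * np.array(
        [np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(2, n_residues + 1):
        coords[(i, "N")] = _place(
            coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")],
            g["C_N"], g["ang_CA_C_N"], psi,
        )
        coords[(i, "CA")] = _place(
            coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
            g["N_CA"], g["ang_C_N_CA"], 180.0,
        )
        coords[(i, "C")] = _place(
            coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
            g["CA_C"], g["ang_N_CA_C"], phi,
        )
    for i in range(1, n_residues + 1):
        coords[(i, "O")] = _place(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            g["C_O"], g["ang_CA_C_O"], psi + 180.0,
        )
        if i > 1:  # amide H on the bisector, trans geometry
            n = coords[(i, "N")]
            u1 = coords[(i, "CA")] - n
            u2 = coords[(i - 1, "C")] - n
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            d = -(u1 + u2)
            coords[(i, "H")] = n + g["N_H"] * d / np.linalg.norm(d)
    return coords


def make_toy_pdb(n_residues: int = 12, conformers=("helix", "extended")) -> str:
    """Multi-model PDB text of ideal poly-alanine conformers.

    The helical conformer forms i -> i-4 amide H ... carbonyl O hydrogen
    bonds by construction; the extended chain forms none.  Hydrogens are
    included so featurization needs no reconstruction.
    """
    if not 2 <= n_residues <= 50:
        raise ValidationError("toy chains support 2-50 residues")
    atom_order = ["N", "H", "CA", "C", "O"]
    lines = []
    for m, conf in enumerate(conformers, start=1):
        phi, psi = _DIHEDRALS[conf]
        coords = _build_chain(n_residues, phi, psi)
        lines.append(f"MODEL     {m:>4}")
        serial = 1
        for i in range(1, n_residues + 1):
            for name in atom_order:
                if (i, name) not in coords:
                    continue
                x, y, z = coords[(i, name)]
                element = name[0]
                lines.append(
                    f"ATOM  {serial:>5} {name:^4} ALA A{i:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
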