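"""Intrinsic (unprotected) amide H/D exchange rate constants.

Implements the standard poly-DL-alanine reference-rate model of Bai,
Milne, Mayne & Englander (1993) for exchange into D2O: for residue i,

    k_int(i) = k_A * F_A * 10^(-pD)  +  k_B * F_B * 10^(pD - pK_D)  +  k_W * F_B

where k_A, k_B, k_W are the acid-, base- and water-catalyzed reference
rates and F_A, F_B are neighbor-dependent correction factors that
multiply in the side-chain contributions of residue i ("left" factor)
and residue i-1 ("right" factor), plus terminal-group factors.  Rates
are Arrhenius-corrected from the 293 K reference to the requested
temperature.

Conventions and fixed choices:

* pD is the corrected pH-meter reading (pH_read + 0.4);
* Asp and Glu are treated as charged, His as neutral, appropriate near
  the default pD 7.4;
* residue 1 and prolines have no exchangeable backbone amide and are
  omitted from the returned set.

Rates from any external calculator can be substituted through
:func:`load_rates_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: log10 reference rates, poly-DL-alanine in D2O at 293 K.
#: acid in 1/(M min); base in 1/(M min); water in 1/min.
LOG_KA_REF = 2.04
LOG_KB_REF = 10.36
LOG_KW_REF = -1.5

#: activation energies, kcal/mol (acid, base, water catalysis)
EA_ACID = 14.0
EA_BASE = 17.0
EA_WATER = 19.0

R_KCAL = 1.987204e-3  # kcal/(mol K)
T_REF = 293.0  # K
PKD = 15.05  # ion product of D2O, -log10

#: log10 side-chain correction factors:
#: (acid_left, acid_right, base_left, base_right).  "Left" applies to the
#: residue's own amide; "right" applies to the following residue's amide.
#: Asp/Glu charged, His neutral.
SIDECHAIN_FACTORS: dict[str, tuple[float, float, float, float]] = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "D": (0.90, 0.58, 0.10, -0.18),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "E": (-0.90, 0.31, -0.11, -0.15),
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "H": (0.00, 0.00, -0.10, 0.14),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "P": (0.00, -0.19, 0.00, -0.24),  # trans proline: right factors only
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
    "V": (-0.74, -0.30, -0.70, -0.14),
}

#: terminal-group log10 factors: the free N-terminal amine acts as the
#: "right" neighbor of residue 2; the C-terminal carboxyl adds to the
#: last residue's "left" factor.
NTERM_ACID_RIGHT = -1.32
NTERM_BASE_RIGHT = 1.62
CTERM_ACID_LEFT = 0.96
CTERM_BASE_LEFT = -1.80


@dataclass
class IntrinsicRateSet:
    """Residue -> intrinsic exchange rate (per minute) with its conditions."""

    rates_per_min: dict[int, float]
    pD: float = float("nan")
    temperature_K: float = float("nan")

    def __post_init__(self):
        for res, k in self.rates_per_min.items():
            if not (k > 0 and np.isfinite(k)):
                raise ValidationError(f"residue {res}: k_int must be positive, got {k}")

    def __getitem__(self, residue: int) -> float:
        return self.rates_per_min[residue]

    def __contains__(self, residue: int) -> bool:
        return residue in self.rates_per_min

    @property
    def residues(self) -> list[int]:
        return sorted(self.rates_per_min)

    def as_per_second(self, residues) -> np.ndarray:
        return np.array([self.rates_per_min[r] / 60.0 for r in residues])


def _arrhenius(log_k_ref: float, ea_kcal: float, temperature_K: float) -> float:
    k_ref = 10.0 ** log_k_ref
    return k_ref * np.exp(-(ea_kcal / R_KCAL) * (1.0 / temperature_K - 1.0 / T_REF))


#: supported reference-table versions
RATE_TABLE_VERSIONS = ("bai1993",)


def intrinsic_rates(
    sequence: str,
    pD: float = 7.4,
    temperature_K: float = 298.0,
    first_residue: int = 1,
    table_version: str = "bai1993",
) -> IntrinsicRateSet:
    """Intrinsic exchange rates (per minute) for every amide of ``sequence``.

    ``sequence`` is the full protein sequence in one-letter codes;
    ``first_residue`` is the residue number of its first position, so the
    returned keys line up with structure numbering.  Residue 1 of the
    chain and all prolines are omitted.
    """
    if table_version not in RATE_TABLE_VERSIONS:
        raise ValidationError(
            f"unknown rate table {table_version!r}; available: {RATE_TABLE_VERSIONS}"
        )
    sequence = sequence.upper()
    if not (0.0 < pD < 14.0 + 2.0):
        raise ValidationError(f"pD {pD} outside supported range")
    if temperature_K <= 0:
        raise ValidationError("temperature_K must be positive")
    for aa in sequence:
        if aa not in SIDECHAIN_FACTORS:
            raise ValidationError(f"unknown residue code {aa!r}")

    k_a = _arrhenius(LOG_KA_REF, EA_ACID, temperature_K)
    k_b = _arrhenius(LOG_KB_REF, EA_BASE, temperature_K)
    k_w = _arrhenius(LOG_KW_REF, EA_WATER, temperature_K)
    conc_d = 10.0 ** (-pD)
    conc_od = 10.0 ** (pD - PKD)

    rates = {}
    n = len(sequence)
    for i in range(1, n):  # position 0 is the N-terminal residue: skipped
        aa = sequence[i]
        if aa == "P":
            continue
        prev = sequence[i - 1]
        acid_log = SIDECHAIN_FACTORS[aa][0] + SIDECHAIN_FACTORS[prev][1]
        base_log = SIDECHAIN_FACTORS[aa][2] + SIDECHAIN_FACTORS[prev][3]
        if i == 1:
            acid_log += NTERM_ACID_RIGHT
            base_log += NTERM_BASE_RIGHT
        if i == n - 1:
            acid_log += CTERM_ACID_LEFT
            base_log += CTERM_BASE_LEFT
        f_acid = 10.0 ** acid_log
        f_base = 10.0 ** base_log
        k = k_a * f_acid * conc_d + k_b * f_base * conc_od + k_w * f_base
        rates[first_residue + i] = float(k)
    return IntrinsicRateSet(rates, pD=pD, temperature_K=temperature_K)


def load_rates_csv(path) -> IntrinsicRateSet:
    """Load residue,k_int_per_min rates produced by any external tool."""
    df = pd.read_csv(path)
    required = ["residue", "k_int_per_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        from .errors import FormatError

        raise FormatError(f"{path}: missing columns {missing}")
    if (df["k_int_per_min"] <= 0).any():
        raise ValidationError(f"{path}: non-positive k_int")
    return IntrinsicRateSet(
        {int(r.residue): float(r.k_int_per_min) for r in df.itertuples(index=False)}
    )


def write_rates_csv(rates: IntrinsicRateSet, path) -> None:
    pd.DataFrame(
        {
            "residue": rates.residues,
            "k_int_per_min": [rates[r] for r in rates.residues],
        }
    ).to_csv(path, index=False, float_format="%.17g")
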