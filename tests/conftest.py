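import numpy as np
import pandas as pd
import pytest

from hdxens.rates import IntrinsicRateSet
from hdxens.synthetic import SyntheticSpec, make_feature_ensemble, spec_rates
from hdxens.types import BetaParams, PeptideSegment, UPTAKE_COLUMNS, UptakeTable


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale two-state spec used by most integration-style tests."""
    return SyntheticSpec(
        n_residues=24, n_frames_per_state=6, noise_sd=0.0, peptide_step=4, seed=7
    )


@pytest.fixture(scope="session")
def small_ensemble(small_spec):
    return make_feature_ensemble(small_spec)


@pytest.fixture(scope="session")
def small_rates(small_spec):
    return spec_rates(small_spec)


@pytest.fixture()
def tiny_fixture():
    """Hand-sized 5-frame, 10-residue feature set with explicit rates.

    Residue 5 is 'proline-like': simply absent from the feature table
    and peptide sequences include a P there to exercise exclusions.
    """
    rng = np.random.default_rng(42)
    frames = [f"f{i}" for i in range(5)]
    residues = [2, 3, 4, 6, 7, 8, 9, 10]
    rows = []
    for f in frames:
        for r in residues:
            rows.append((f, r, int(rng.integers(0, 12)), int(rng.integers(0, 3))))
    features = pd.DataFrame(rows, columns=["frame_id", "residue", "N_C", "N_H"])
    rates = IntrinsicRateSet({r: 10.0 * (1 + 0.3 * r) for r in residues})
    peptides = [
        PeptideSegment("p1", 2, 6, "AACKP"[:5]),
        PeptideSegment("p2", 4, 10, "KPLMNQS"),
        PeptideSegment("p3", 7, 10, "MNQS"),
    ]
    return features, rates, peptides, frames


def make_uptake_table(records, is_normalized=True):
    """records: (peptide_id, start, end, sequence, exposure, replicate, uptake)."""
    rows = [
        (pid, "s", start, end, seq, t, rep, u)
        for pid, start, end, seq, t, rep, u in records
    ]
    return UptakeTable(
        pd.DataFrame(rows, columns=UPTAKE_COLUMNS), is_normalized=is_normalized
    )


@pytest.fixture()
def betas():
    return BetaParams(0.35, 2.0)
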