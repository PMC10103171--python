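import numpy as np
import pandas as pd
import pytest

from hdxens.errors import ValidationError
from hdxens.forward import (
    EnsemblePredictor,
    filter_peptides,
    normalize_to_maxd,
    peptide_deuteration,
    protection_factors,
    residue_deuteration,
    target_matrix,
)
from hdxens.rates import IntrinsicRateSet
from hdxens.types import BetaParams, PeptideSegment, UPTAKE_COLUMNS, UptakeTable

from conftest import make_uptake_table


def _features(rows):
    return pd.DataFrame(rows, columns=["frame_id", "residue", "N_C", "N_H"])


class TestProtectionFactors:
    def test_zero_features_give_unit_pf(self):
        f = _features([("f0", 2, 0, 0), ("f0", 3, 0, 0)])
        pf = protection_factors(f, [1.0], BetaParams(0.35, 2.0))
        np.testing.assert_array_equal(pf.ln_pf, [0.0, 0.0])

    def test_single_frame_hand_value(self):
        # ln PF = 0.35*10 + 2.0*2 = 7.5
        f = _features([("f0", 5, 10, 2)])
        pf = protection_factors(f, [1.0], BetaParams(0.35, 2.0))
        assert pf.ln_pf[0] == pytest.approx(7.5, abs=1e-15)

    def test_equal_weights_average_exponent(self):
        f = _features([("f0", 2, 0, 1), ("f1", 2, 0, 2)])  # lnPF 2 and 4
        pf = protection_factors(f, [0.5, 0.5], BetaParams(0.0, 2.0))
        assert pf.ln_pf[0] == pytest.approx(3.0)

    def test_linear_in_betas(self):
        rng = np.random.default_rng(0)
        f = _features(
            [(f"f{j}", r, rng.integers(0, 9), rng.integers(0, 3))
             for j in range(3) for r in (2, 3, 4)]
        )
        w = [0.2, 0.3, 0.5]
        one = protection_factors(f, w, BetaParams(0.35, 2.0)).ln_pf
        two = protection_factors(f, w, BetaParams(0.70, 4.0)).ln_pf
        np.testing.assert_allclose(two, 2.0 * one, rtol=1e-14)

    def test_frame_permutation_invariance(self):
        f = _features([("a", 2, 1, 0), ("b", 2, 5, 1), ("c", 2, 9, 2)])
        w = np.array([0.5, 0.2, 0.3])
        fp = _features([("c", 2, 9, 2), ("a", 2, 1, 0), ("b", 2, 5, 1)])
        wp = np.array([0.3, 0.5, 0.2])
        assert protection_factors(f, w).ln_pf == pytest.approx(
            protection_factors(fp, wp).ln_pf
        )


class TestResidueDeuteration:
    def _pf(self, ln_pf):
        from hdxens.types import ProtectionFactorSet

        return ProtectionFactorSet(
            residues=np.arange(2, 2 + len(ln_pf)), ln_pf=np.array(ln_pf),
            weights=np.array([1.0]),
        )

    def test_half_life_identity(self):
        # choose t so that k_int * t / PF = ln 2  ->  D = 1/2
        pf = self._pf([1.0])
        k_per_min = 60.0
        rates = IntrinsicRateSet({2: k_per_min})
        t = np.log(2.0) * np.e / (k_per_min / 60.0)
        d = residue_deuteration(pf, rates, [t])
        assert d.iloc[0, 0] == pytest.approx(0.5, rel=1e-12)

    def test_zero_time_zero_deuteration(self):
        d = residue_deuteration(self._pf([0.5, 2.0]), IntrinsicRateSet({2: 5, 3: 9}), [0.0])
        np.testing.assert_array_equal(d.to_numpy(), 0.0)

    def test_infinite_protection_limit(self):
        d = residue_deuteration(self._pf([600.0]), IntrinsicRateSet({2: 1e6}), [1e6])
        assert d.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_bounded_and_monotone_in_time(self):
        pf = self._pf([0.0, 3.0, 8.0])
        rates = IntrinsicRateSet({2: 100.0, 3: 10.0, 4: 1.0})
        d = residue_deuteration(pf, rates, [10, 100, 1000, 10000]).to_numpy()
        assert ((d >= 0) & (d <= 1)).all()
        assert (np.diff(d, axis=1) >= 0).all()

    def test_negative_exposure_rejected(self):
        with pytest.raises(ValidationError):
            residue_deuteration(self._pf([1.0]), IntrinsicRateSet({2: 1.0}), [-1.0])


class TestPeptideDeuteration:
    def test_mean_skips_first_residue(self):
        d = pd.DataFrame(
            {100.0: [0.9, 0.2, 0.4, 0.6]}, index=[10, 11, 12, 13]
        )
        pep = PeptideSegment("p", 10, 13, "ALKV")
        out = peptide_deuteration(d, [pep])
        assert out.loc["p", 100.0] == pytest.approx((0.2 + 0.4 + 0.6) / 3)

    def test_prolines_skipped(self):
        d = pd.DataFrame({60.0: [0.5, 0.3, 0.1]}, index=[5, 6, 7])
        pep = PeptideSegment("p", 4, 7, "APPK")  # competent: only residue 7
        out = peptide_deuteration(d, [pep])
        assert out.loc["p", 60.0] == pytest.approx(0.1)

    def test_all_proline_interior_excluded_with_warning(self, caplog):
        d = pd.DataFrame({60.0: [0.5]}, index=[9])
        pep = PeptideSegment("p", 5, 7, "APP")
        with caplog.at_level("WARNING"):
            out = peptide_deuteration(d, [pep])
        assert out.empty
        assert "no exchange-competent" in caplog.text


class TestEndToEndOracle:
    def test_matches_bruteforce_loops(self, tiny_fixture, betas):
        """Pipeline prediction equals explicit frame/residue/time loops."""
        features, rates, peptides, frames = tiny_fixture
        w = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        exposures = [30.0, 300.0, 3600.0]
        pred = EnsemblePredictor(
            features, rates, betas, peptides, exposures
        ).prediction_frame(w)

        feat = {
            (r.frame_id, r.residue): (r.N_C, r.N_H)
            for r in features.itertuples(index=False)
        }
        for pep in peptides:
            competent = pep.exchange_competent_residues()
            competent = [r for r in competent if r in rates]
            for t in exposures:
                acc = 0.0
                for res in competent:
                    ln_pf = 0.0
                    for wj, f in zip(w, frames):
                        n_c, n_h = feat[(f, res)]
                        ln_pf += wj * (betas.beta_C * n_c + betas.beta_H * n_h)
                    k = rates[res] / 60.0
                    acc += 1.0 - np.exp(-k * t / np.exp(ln_pf))
                expected = acc / len(competent)
                assert pred.loc[pep.peptide_id, t] == pytest.approx(
                    expected, abs=1e-12
                )


class TestMaxdNormalization:
    def _raw(self, uptakes):
        return make_uptake_table(
            [("p1", 2, 5, "ACDE", 30.0, i + 1, u) for i, u in enumerate(uptakes)],
            is_normalized=False,
        )

    def _maxd(self, uptakes):
        return make_uptake_table(
            [("p1", 2, 5, "ACDE", 3600.0, i + 1, u) for i, u in enumerate(uptakes)],
            is_normalized=False,
        )

    def test_simple_ratio(self):
        out = normalize_to_maxd(self._raw([2.0]), self._maxd([4.0]))
        assert out.is_normalized
        assert out.data["uptake"].iloc[0] == pytest.approx(0.5)

    def test_self_normalization_is_one(self):
        maxd = self._maxd([3.0, 5.0])
        out = normalize_to_maxd(maxd, maxd)
        np.testing.assert_allclose(out.data["uptake"], [0.75, 1.25])
        assert out.data["uptake"].mean() == pytest.approx(1.0)

    def test_negative_values_preserved(self):
        out = normalize_to_maxd(self._raw([-0.1]), self._maxd([4.0]))
        assert out.data["uptake"].iloc[0] == pytest.approx(-0.025)

    def test_peptide_missing_from_maxd_dropped(self, caplog):
        raw = make_uptake_table(
            [
                ("p1", 2, 5, "ACDE", 30.0, 1, 2.0),
                ("p2", 6, 9, "FGHI", 30.0, 1, 2.0),
            ],
            is_normalized=False,
        )
        with caplog.at_level("WARNING"):
            out = normalize_to_maxd(raw, self._maxd([4.0]))
        assert set(out.data["peptide_id"]) == {"p1"}
        assert "p2" in caplog.text


class TestPeptideFilter:
    def test_filter_conformance(self):
        """Out-of-span and negative-mean peptides are removed, others kept."""
        records = []
        for pid, start, end, seq, base in [
            ("edge", 1, 5, "MACDE", 0.5),       # overlaps residue 1-5: out of span
            ("neg", 100, 110, "ACDEFGHIKLM", 0.5),  # one negative mean
            ("good", 100, 110, "ACDEFGHIKLM", 0.5),
        ]:
            for t in (30.0, 300.0):
                for rep in (1, 2):
                    u = base
                    if pid == "neg" and t == 30.0:
                        u = -0.02
                    records.append((pid, start, end, seq, t, rep, u))
        table = make_uptake_table(records)
        out = filter_peptides(table, (6, 478))
        assert {p.peptide_id for p in out.peptides} == {"good"}

    def test_fully_inside_span_retained(self):
        table = make_uptake_table(
            [("p", 100, 110, "ACDEFGHIKLM", 30.0, 1, 0.4)]
        )
        out = filter_peptides(table, (6, 478))
        assert len(out.peptides) == 1


def test_target_matrix_aligns_replicate_means(tiny_fixture):
    features, rates, peptides, _ = tiny_fixture
    records = []
    for pep in peptides[:2]:
        for t in (30.0, 300.0):
            for rep, u in ((1, 0.3), (2, 0.5)):
                records.append(
                    (pep.peptide_id, pep.start, pep.end, pep.sequence, t, rep, u)
                )
    table = make_uptake_table(records)
    tgt = target_matrix(table, [p.peptide_id for p in peptides], [30.0, 300.0])
    np.testing.assert_allclose(tgt[:2], 0.4)
    assert np.isnan(tgt[2]).all()  # p3 absent from the table
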