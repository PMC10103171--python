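import numpy as np
import pandas as pd
import pytest

from hdxens.errors import ValidationError
from hdxens.forward import EnsemblePredictor, target_matrix
from hdxens.rates import IntrinsicRateSet
from hdxens.reweight import (
    KB_KJ_MOL,
    MaxEntReweighter,
    apparent_work,
    gamma_scan,
    relative_entropy,
    reweight,
)
from hdxens.types import BetaParams, PeptideSegment

from conftest import make_uptake_table


def _problem(n_frames, seed=0, n_res=4):
    """Small reweighting problem with an explicit target."""
    rng = np.random.default_rng(seed)
    residues = list(range(2, 2 + n_res))
    rows = []
    for j in range(n_frames):
        for r in residues:
            rows.append((f"f{j}", r, int(rng.integers(0, 10)), int(rng.integers(0, 3))))
    features = pd.DataFrame(rows, columns=["frame_id", "residue", "N_C", "N_H"])
    rates = IntrinsicRateSet({r: 30.0 + 10.0 * r for r in residues})
    seq = "ACDEFGHIKL"[: n_res + 1]
    peptides = [PeptideSegment("p1", 1, 1 + n_res, seq)]
    return features, rates, peptides


def _target_for(features, rates, peptides, weights, betas, exposures=(30.0, 300.0)):
    pred = EnsemblePredictor(
        features, rates, betas, peptides, exposures
    ).prediction_frame(np.asarray(weights))
    records = []
    for pid in pred.index:
        pep = next(p for p in peptides if p.peptide_id == pid)
        for t in exposures:
            records.append(
                (pid, pep.start, pep.end, pep.sequence, t, 1, float(pred.loc[pid, t]))
            )
    return make_uptake_table(records)


def grid_search_weights(features, rates, peptides, target, betas, gamma,
                        n_frames, resolution=1e-3):
    """Exhaustive oracle: minimize the reweighting functional over a
    simplex grid (vectorized enumeration, independent of the optimizer)."""
    predictor = EnsemblePredictor(features, rates, betas, peptides, target.exposures)
    tgt = target_matrix(target, predictor.peptide_ids, predictor.exposures)
    steps = int(round(1.0 / resolution))
    if n_frames == 2:
        w1 = np.linspace(0.0, 1.0, steps + 1)
        grid = np.column_stack([w1, 1.0 - w1])
    elif n_frames == 3:
        w1 = np.linspace(0.0, 1.0, steps + 1)
        a, b = np.meshgrid(w1, w1, indexing="ij")
        keep = a + b <= 1.0 + 1e-12
        grid = np.column_stack([a[keep], b[keep], 1.0 - a[keep] - b[keep]])
    else:
        raise ValueError("oracle supports 2 or 3 frames")
    w0 = np.full(n_frames, 1.0 / n_frames)
    # direct evaluation of the objective over the whole grid
    ln_pf = grid @ predictor._p  # (n_grid, n_res)
    kt = predictor._kt  # (n_res, n_t)
    d = 1.0 - np.exp(-np.exp(-ln_pf)[:, :, None] * kt[None, :, :])
    pred = np.einsum("pr,grt->gpt", predictor._avg, d)
    fit = 0.5 * gamma * ((pred - tgt[None]) ** 2).sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(grid > 0, np.log(np.maximum(grid, 1e-300) / w0), 0.0)
    kl = (grid * lg).sum(axis=1)
    return grid[np.argmin(fit + kl)]


class TestNoBiasLimit:
    def test_gamma_zero_returns_prior_exactly(self):
        features, rates, peptides = _problem(4, seed=1)
        target = _target_for(features, rates, peptides, [0.7, 0.1, 0.1, 0.1],
                             BetaParams())
        w0 = np.array([0.4, 0.3, 0.2, 0.1])
        res = reweight(features, rates, BetaParams(), target, peptides,
                       gamma=0.0, w0=w0)
        np.testing.assert_array_equal(res.final_weights, w0)
        assert res.w_app_kj_mol < 1e-9

    def test_self_consistent_target_keeps_uniform_weights(self):
        features, rates, peptides = _problem(3, seed=2)
        w0 = np.full(3, 1 / 3)
        target = _target_for(features, rates, peptides, w0, BetaParams())
        for gamma in (0.1, 10.0, 1000.0):
            res = reweight(features, rates, BetaParams(), target, peptides,
                           gamma=gamma, w0=w0)
            np.testing.assert_allclose(res.final_weights, w0, atol=1e-6)


class TestGridSearchOracle:
    @pytest.mark.parametrize("n_frames", [2, 3])
    def test_optimizer_matches_exhaustive_simplex_grid(self, n_frames):
        features, rates, peptides = _problem(n_frames, seed=3)
        betas = BetaParams()
        truth = np.zeros(n_frames)
        truth[0] = 0.9
        truth[1:] = 0.1 / (n_frames - 1)
        target = _target_for(features, rates, peptides, truth, betas)
        for gamma in (0.5, 2.0, 10.0, 100.0, 1000.0):
            res = reweight(features, rates, betas, target, peptides, gamma=gamma)
            w_grid = grid_search_weights(
                features, rates, peptides, target, betas, gamma, n_frames
            )
            np.testing.assert_allclose(res.final_weights, w_grid, atol=1.5e-3)

    def test_perfect_single_frame_target_concentrates_weight(self):
        features, rates, peptides = _problem(2, seed=4)
        betas = BetaParams()
        target = _target_for(features, rates, peptides, [1.0, 0.0], betas)
        res = reweight(features, rates, betas, target, peptides, gamma=1e5)
        assert res.final_weights[0] > 0.99


class TestApparentWork:
    def test_prior_gives_zero(self):
        w0 = np.array([0.3, 0.7])
        assert apparent_work(w0, w0) == 0.0

    def test_two_point_closed_form(self):
        # forcing (1, 0) from (1/2, 1/2): W_app = kT ln 2 ~ 1.717 kJ/mol
        w_app = apparent_work([1.0, 0.0], [0.5, 0.5], temperature_K=298.0)
        assert w_app == pytest.approx(KB_KJ_MOL * 298.0 * np.log(2.0), abs=1e-12)
        assert w_app == pytest.approx(1.717, abs=1e-3)

    def test_kl_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = rng.dirichlet(np.ones(5))
            w0 = rng.dirichlet(np.ones(5))
            assert relative_entropy(w, w0) >= -1e-12


class TestGammaScan:
    def test_trace_monotone(self, small_ensemble, small_rates, small_spec, betas):
        from hdxens.forward import normalize_to_maxd
        from hdxens.synthetic import make_target_uptake

        raw, maxd, _ = make_target_uptake(small_spec, betas, small_rates)
        target = normalize_to_maxd(raw, maxd)
        res = gamma_scan(
            small_ensemble.features, small_rates, betas, target,
            w0=small_ensemble.initial_weights,
            state_labels=small_ensemble.state_labels,
        )
        trace = res.scan_trace
        assert (np.diff(trace["w_app_kj_mol"]) >= -1e-10).all()
        assert (np.diff(trace["mse"]) <= 1e-10).all()
        assert res.mse_final <= res.mse_initial + 1e-15

    def test_selection_rule_picks_closest_below_budget(self):
        features, rates, peptides = _problem(3, seed=5)
        betas = BetaParams()
        target = _target_for(features, rates, peptides, [0.8, 0.1, 0.1], betas)
        est = MaxEntReweighter(gamma=None, w_target_kj_mol=1e9, betas=betas)
        est.fit(features, target, rates, peptides=peptides)
        full = est.scan_trace_
        # pick a budget between two achieved W_app values
        budget = full["w_app_kj_mol"].iloc[len(full) // 2] * 1.0001
        est2 = MaxEntReweighter(gamma=None, w_target_kj_mol=budget, betas=betas)
        est2.fit(features, target, rates, peptides=peptides)
        below = full.loc[full["w_app_kj_mol"] <= budget, "w_app_kj_mol"]
        assert est2.w_app_kj_mol_ == pytest.approx(below.max(), rel=1e-6)

    def test_unreachable_budget_warns_and_returns_last(self, caplog):
        features, rates, peptides = _problem(3, seed=6)
        betas = BetaParams()
        target = _target_for(features, rates, peptides, [0.5, 0.3, 0.2], betas)
        with caplog.at_level("WARNING"):
            res = gamma_scan(features, rates, betas, target, peptides,
                             gammas=[0.01, 0.1], w_target_kj_mol=50.0)
        assert "below target" in caplog.text
        assert res.gamma == pytest.approx(0.1)


class TestInvariances:
    def test_frame_duplication_preserves_state_population(self):
        features, rates, peptides = _problem(3, seed=7)
        betas = BetaParams()
        target = _target_for(features, rates, peptides, [0.6, 0.3, 0.1], betas)
        res = reweight(features, rates, betas, target, peptides, gamma=50.0)

        # duplicate frame 0, splitting its prior weight
        dup = features[features["frame_id"] == "f0"].copy()
        dup["frame_id"] = "f0b"
        features2 = pd.concat([features, dup], ignore_index=True)
        w0 = np.array([1 / 6, 1 / 3, 1 / 3, 1 / 6])
        res2 = reweight(features2, rates, betas, target, peptides,
                        gamma=50.0, w0=w0)
        merged = res2.final_weights[0] + res2.final_weights[3]
        assert merged == pytest.approx(res.final_weights[0], abs=1e-6)
        np.testing.assert_allclose(
            res2.final_weights[1:3], res.final_weights[1:3], atol=1e-6
        )

    def test_empty_target_rejected(self):
        features, rates, peptides = _problem(2, seed=8)
        target = _target_for(features, rates, peptides, [0.5, 0.5], BetaParams())
        empty = target.subset_peptides([])
        with pytest.raises(ValidationError):
            reweight(features, rates, BetaParams(), empty, peptides, gamma=1.0)

    def test_negative_gamma_rejected(self):
        features, rates, peptides = _problem(2, seed=9)
        target = _target_for(features, rates, peptides, [0.5, 0.5], BetaParams())
        with pytest.raises(ValidationError):
            reweight(features, rates, BetaParams(), target, peptides, gamma=-1.0)
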