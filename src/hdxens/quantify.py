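"""Population quantification, subsampling uncertainty and robustness checks.

The fractional population of a conformational state is the summed final
weight of the frames carrying its label.  Uncertainty is estimated by
systematic subsampling: frames are partitioned into k interleaved
subsets (stride k, offsets 0..k-1), each subset is reweighted
independently with identical settings, and the spread of the recovered
populations over the k runs is reported (k = 3 by convention).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .reweight import MaxEntReweighter
from .types import (
    PopulationEstimate,
    StructuralEnsemble,
    UptakeTable,
    _check_simplex,
)

log = logging.getLogger(__name__)


def populations(weights, labels: Sequence[str]) -> PopulationEstimate:
    """Per-state fractional populations: fraction(s) = sum of w_j over
    frames labelled s."""
    w = _check_simplex(np.asarray(weights, float))
    if len(labels) != len(w):
        raise ValidationError(f"{len(labels)} labels for {len(w)} weights")
    fractions: dict[str, float] = {}
    for wi, lab in zip(w, labels):
        fractions[lab] = fractions.get(lab, 0.0) + float(wi)
    total = sum(fractions.values())
    fractions = {k: v / total for k, v in fractions.items()}
    return PopulationEstimate(fractions=fractions)


def _partition_indices(n: int, k: int, mode: str, rng) -> list[np.ndarray]:
    if mode == "systematic":
        return [np.arange(offset, n, k) for offset in range(k)]
    if mode == "random":
        perm = rng.permutation(n)
        return [np.sort(perm[offset::k]) for offset in range(k)]
    raise ValidationError(f"unknown subsampling mode {mode!r}")


def subsample_uncertainty(
    ensemble: StructuralEnsemble,
    target: UptakeTable,
    rates,
    betas,
    k: int = 3,
    mode: str = "systematic",
    seed: Optional[int] = None,
    reweighter: Optional[MaxEntReweighter] = None,
    **fit_kwargs,
) -> PopulationEstimate:
    """Population mean and SD over k independent subsample reweightings.

    ``mode='systematic'`` (default) uses deterministic interleaved
    stride-k partitions; ``mode='random'`` uses a seeded random
    partition.  Subsets missing a state entirely are skipped with a
    warning.
    """
    if k < 2:
        raise ValidationError("need k >= 2 subsamples")
    if not ensemble.has_features:
        raise ValidationError("ensemble must carry features (run featurize first)")
    rng = np.random.default_rng(seed)
    proto = reweighter or MaxEntReweighter(betas=betas)
    all_states = set(ensemble.state_labels)

    fractions_per_run = []
    for idx in _partition_indices(ensemble.n_frames, k, mode, rng):
        sub = ensemble.subset(idx)
        if set(sub.state_labels) != all_states:
            log.warning("subsample missing a state; skipped")
            continue
        est = MaxEntReweighter(**proto.get_params())
        est.fit(
            sub.features, target, rates,
            w0=sub.initial_weights, state_labels=sub.state_labels, **fit_kwargs,
        )
        fractions_per_run.append(
            populations(est.weights_, sub.state_labels).fractions
        )
    if len(fractions_per_run) < 2:
        raise ValidationError("fewer than two usable subsamples")

    states = sorted(all_states)
    arr = np.array([[f.get(s, 0.0) for s in states] for f in fractions_per_run])
    mean = arr.mean(axis=0)
    mean = mean / mean.sum()
    sd = arr.std(axis=0, ddof=1)
    return PopulationEstimate(
        fractions=dict(zip(states, mean.tolist())),
        sd=dict(zip(states, sd.tolist())),
        n_subsamples=len(fractions_per_run),
    )


def reweighted_distribution(observable, weights, bins) -> pd.DataFrame:
    """Weighted histogram of a per-frame scalar (e.g. an interdomain
    distance in angstrom); bin masses are summed weights and sum to 1."""
    x = np.asarray(observable, float)
    w = _check_simplex(np.asarray(weights, float))
    if x.shape != w.shape:
        raise ValidationError("observable and weights must align")
    bins = np.asarray(bins, float)
    if x.min() < bins[0] or x.max() > bins[-1]:
        raise ValidationError(
            f"bins [{bins[0]}, {bins[-1]}] do not cover data range "
            f"[{x.min()}, {x.max()}]"
        )
    mass, edges = np.histogram(x, bins=bins, weights=w)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "mass": mass}
    )


def peptide_rmse(
    pred_before: pd.DataFrame, pred_after: pd.DataFrame, target: pd.DataFrame
) -> pd.DataFrame:
    """Per-peptide RMSE over exposures before and after reweighting,
    sorted descending by the after-RMSE to surface error-prone peptides.

    All three inputs are (peptide x exposure) frames on an identical
    grid.
    """
    for other, name in ((pred_after, "pred_after"), (target, "target")):
        if not pred_before.index.equals(other.index) or not pred_before.columns.equals(
            other.columns
        ):
            raise ValidationError(f"{name} grid does not match pred_before")
    rmse_before = np.sqrt(((pred_before - target) ** 2).mean(axis=1))
    rmse_after = np.sqrt(((pred_after - target) ** 2).mean(axis=1))
    out = pd.DataFrame(
        {"rmse_before": rmse_before, "rmse_after": rmse_after}
    ).rename_axis("peptide_id")
    return out.sort_values("rmse_after", ascending=False)


def exclusion_robustness(
    ensemble: StructuralEnsemble,
    target: UptakeTable,
    rates,
    betas,
    exclude: Sequence[str],
    reweighter: Optional[MaxEntReweighter] = None,
    **fit_kwargs,
) -> dict[str, PopulationEstimate]:
    """Rerun reweighting with the listed peptides removed from the target.

    Returns {'original': ..., 'excluded': ...} populations side by side,
    the basis of the robustness heatmaps comparing fits with and without
    suspect peptides.
    """
    present = {p.peptide_id for p in target.peptides}
    missing = set(exclude) - present
    if missing:
        raise ValidationError(f"peptides not in target: {sorted(missing)}")
    keep = [pid for pid in present if pid not in set(exclude)]
    if not keep:
        raise ValidationError("exclusion would empty the target")
    if len(keep) == 1:
        log.warning("only one peptide left after exclusion: fragile fit")
    reduced = target.subset_peptides(keep)

    proto = reweighter or MaxEntReweighter(betas=betas)
    out = {}
    for name, tbl in (("original", target), ("excluded", reduced)):
        est = MaxEntReweighter(**proto.get_params())
        est.fit(
            ensemble.features, tbl, rates,
            w0=ensemble.initial_weights, state_labels=ensemble.state_labels,
            **fit_kwargs,
        )
        out[name] = populations(est.weights_, ensemble.state_labels)
    return out
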