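"""End-to-end orchestration: featurize -> rates -> normalize/filter ->
reweight (gamma scan) -> populations + subsampling -> RMSE.

A run is driven by a JSON-serializable config and leaves a manifest
recording the config hash, seed, package version and a sha256 checksum
per artifact, so identical configs reproduce identical outputs for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .forward import filter_peptides, normalize_to_maxd
from .io import (
    read_ensemble_pdb,
    read_features_csv,
    read_peptide_map,
    read_uptake_csv,
    write_features_csv,
    write_uptake_csv,
    write_weights,
)
from .quantify import peptide_rmse, populations, subsample_uncertainty
from .rates import intrinsic_rates, load_rates_csv, write_rates_csv
from .reweight import DEFAULT_GAMMA_GRID, MaxEntReweighter
from .types import BetaParams, UptakeTable

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and settings of one pipeline run.

    Exactly one input route is used: ``synthetic=True`` generates the
    built-in two-state benchmark; otherwise file paths must be given.
    """

    output_dir: str = "hdxens_run"
    seed: int = 17
    synthetic: bool = True
    # file-input route
    ensemble_pdbs: dict = field(default_factory=dict)  # state label -> pdb path
    features_csv: str | None = None
    raw_uptake_csv: str | None = None
    maxd_uptake_csv: str | None = None
    peptide_map_csv: str | None = None
    rates_csv: str | None = None
    sequence: str | None = None
    # model settings
    beta_C: float = 0.35
    beta_H: float = 2.0
    pD: float = 7.4
    temperature_K: float = 298.0
    structure_span: tuple[int, int] | None = None
    w_target_kj_mol: float = 5.0
    subsample_k: int = 3
    first_residue_skip: int = 1

    def validate_paths(self):
        if self.synthetic:
            return
        needed = {
            "raw_uptake_csv": self.raw_uptake_csv,
            "maxd_uptake_csv": self.maxd_uptake_csv,
        }
        if self.features_csv is None and not self.ensemble_pdbs:
            raise ValidationError("need features_csv or ensemble_pdbs")
        if self.features_csv:
            needed["features_csv"] = self.features_csv
        needed.update({f"pdb[{k}]": v for k, v in self.ensemble_pdbs.items()})
        if self.peptide_map_csv:
            needed["peptide_map_csv"] = self.peptide_map_csv
        for name, p in needed.items():
            if p is None:
                raise ValidationError(f"config missing {name}")
            if not Path(p).exists():
                raise ValidationError(f"{name}: no such file {p}")
        if self.rates_csv is None and self.sequence is None:
            raise ValidationError("need rates_csv or sequence for intrinsic rates")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dict."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    betas = BetaParams(config.beta_C, config.beta_H)
    stages = []
    artifacts: dict[str, Path] = {}

    def done(stage: str, **files):
        stages.append(stage)
        artifacts.update({k: Path(v) for k, v in files.items()})
        log.info("stage complete: %s", stage)

    # 1. features -----------------------------------------------------------
    if config.synthetic:
        from .synthetic import (
            SyntheticSpec,
            make_feature_ensemble,
            make_peptide_map,
            make_target_uptake,
            spec_rates,
            spec_sequence,
        )

        spec = SyntheticSpec(seed=config.seed)
        ensemble = make_feature_ensemble(spec)
        peptides = make_peptide_map(spec)
        rates = spec_rates(spec)
        raw, maxd, _truth = make_target_uptake(spec, betas=betas, rates=rates)
        span = config.structure_span or (1, spec.n_residues)
        features = ensemble.features
        state_labels = ensemble.state_labels
        w0 = ensemble.initial_weights
        sub_ensemble = ensemble
    else:
        if config.features_csv:
            features = read_features_csv(config.features_csv)
            frame_ids = list(dict.fromkeys(features["frame_id"]))
            state_labels = [str(f).rsplit("_", 1)[0] for f in frame_ids]
            from .types import StructuralEnsemble

            sub_ensemble = StructuralEnsemble(
                frame_ids=frame_ids, state_labels=state_labels, features=features
            )
        else:
            from .features import featurize_ensemble
            from .types import StructuralEnsemble

            parts = [
                read_ensemble_pdb(path, label)
                for label, path in config.ensemble_pdbs.items()
            ]
            frames, labels, feats = [], [], []
            for ens in parts:
                f = featurize_ensemble(ens)
                frames += ens.frame_ids
                labels += ens.state_labels
                feats.append(f)
            features = pd.concat(feats, ignore_index=True)
            state_labels = labels
            sub_ensemble = StructuralEnsemble(
                frame_ids=frames, state_labels=labels, features=features
            )
        w0 = sub_ensemble.initial_weights
        raw = read_uptake_csv(config.raw_uptake_csv)
        maxd = read_uptake_csv(config.maxd_uptake_csv)
        peptides = (
            read_peptide_map(config.peptide_map_csv)
            if config.peptide_map_csv
            else raw.peptides
        )
        if config.rates_csv:
            rates = load_rates_csv(config.rates_csv)
        else:
            rates = intrinsic_rates(
                config.sequence, pD=config.pD, temperature_K=config.temperature_K
            )
        span = config.structure_span or (
            int(features["residue"].min()) - 1,
            int(features["residue"].max()),
        )
    write_features_csv(features, out / "features.csv")
    done("featurize", features=out / "features.csv")

    # 2. rates --------------------------------------------------------------
    write_rates_csv(rates, out / "rates.csv")
    done("rates", rates=out / "rates.csv")

    # 3. normalize + filter -------------------------------------------------
    normalized = normalize_to_maxd(raw, maxd)
    filtered = filter_peptides(normalized, span)
    if len(filtered.data) == 0:
        raise ValidationError("peptide filter removed every peptide")
    write_uptake_csv(normalized, out / "normalized.csv")
    write_uptake_csv(filtered, out / "filtered.csv")
    done("normalize_filter", normalized=out / "normalized.csv",
         filtered=out / "filtered.csv")

    # 4. reweight (gamma scan) ----------------------------------------------
    kept = {p.peptide_id for p in filtered.peptides}
    peptides = [p for p in peptides if p.peptide_id in kept]
    est = MaxEntReweighter(
        gamma=None,
        gamma_grid=DEFAULT_GAMMA_GRID,
        w_target_kj_mol=config.w_target_kj_mol,
        betas=betas,
        temperature_K=config.temperature_K,
        first_residue_skip=config.first_residue_skip,
    )
    est.fit(features, filtered, rates, peptides=peptides, w0=w0,
            state_labels=state_labels)
    write_weights(est.result_, out / "weights.csv")
    est.scan_trace_.to_csv(out / "scan_trace.csv", index=False)
    done("reweight", weights=out / "weights.csv", scan_trace=out / "scan_trace.csv")

    # 5. populations + subsampling ------------------------------------------
    pops = populations(est.weights_, state_labels)
    sub = subsample_uncertainty(
        sub_ensemble, filtered, rates, betas,
        k=config.subsample_k, reweighter=est,
    )
    pop_df = pd.DataFrame(
        {
            "state": sorted(pops.fractions),
            "fraction": [pops.fractions[s] for s in sorted(pops.fractions)],
            "subsample_mean": [sub.fractions[s] for s in sorted(pops.fractions)],
            "subsample_sd": [sub.sd[s] for s in sorted(pops.fractions)],
        }
    )
    pop_df.to_csv(out / "populations.csv", index=False)
    done("populations", populations=out / "populations.csv")

    # 6. per-peptide RMSE ----------------------------------------------------
    from .forward import target_matrix

    tgt = target_matrix(filtered, est.predictor_.peptide_ids, est.predictor_.exposures)
    tgt_df = pd.DataFrame(tgt, index=est.predictor_.peptide_ids,
                          columns=est.predictor_.exposures)
    rmse = peptide_rmse(est.predict(w0), est.predict(), tgt_df)
    rmse.to_csv(out / "rmse.csv")
    done("rmse", rmse=out / "rmse.csv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": stages,
        "gamma": est.gamma_,
        "w_app_kj_mol": est.w_app_kj_mol_,
        "mse_initial": est.mse_initial_,
        "mse_final": est.mse_final_,
        "populations": pops.fractions,
        "subsample_sd": sub.sd,
        "artifacts": {k: _sha256(v) for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
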