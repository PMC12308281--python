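"""End-to-end pipeline orchestration.

Stages (synth -> features -> plsc -> inference -> validation -> prediction
-> mediation) communicate only through declared files inside the run
directory, so any stage can be re-run in isolation.  A single top-level
seed fans out to per-stage seeds through fixed offsets, and a manifest
records config, seeds and stage timings.  Rerunning an identical config
reproduces every statistical output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import synthetic as synth
from .inference import bootstrap_loadings, permutation_test
from .mediation import dual_mediation
from .plsc import LatentModel, composite_scores, fit_plsc, loadings
from .prediction import DEFAULT_ALPHA_GRID, loocv_predict
from .validation import loocv_plsc, project_cohort, salience_similarity, split_half

__all__ = ["RunConfig", "run_pipeline"]

STAGE_DIRS = ("cohort", "features", "plsc", "inference", "validation",
              "prediction", "mediation")

# per-stage seed offsets from the top-level seed
_SEEDS = {"synth": 0, "replication": 101, "perm": 202, "boot": 303,
          "validate": 404, "mediate": 505}


@dataclass
class RunConfig:
    """One pipeline run: input mode, resampling sizes, seeds, policies."""

    input_mode: str = "synthetic"          # "synthetic" | "directory"
    input_dir: str | None = None           # cohort dir when input_mode=directory
    out_dir: str = "run"
    seed: int = 0
    n_perm: int = 1000
    n_boot: int = 1000
    n_boot_mediation: int = 10000
    loocv_n_perm: int = 200
    n_components_report: int = 5
    fdr_level: float = 0.05
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    exclusion_threshold: float = 50.0
    projection_standardize: str = "self"
    synthetic: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    write_volumes: bool = True

    def validate(self) -> None:
        if self.input_mode not in ("synthetic", "directory"):
            raise ValueError("input_mode must be 'synthetic' or 'directory'")
        if self.input_mode == "directory" and not self.input_dir:
            raise ValueError("directory mode needs input_dir")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", {})
        if "grid_dims" in syn:
            syn["grid_dims"] = tuple(syn["grid_dims"])
        if "lesion_radius_range" in syn:
            syn["lesion_radius_range"] = tuple(syn["lesion_radius_range"])
        if "alpha_grid" in raw:
            raw["alpha_grid"] = tuple(float(a) for a in raw["alpha_grid"])
        cfg = cls(**raw, synthetic=synth.SyntheticConfig(**syn))
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alpha_grid"] = list(self.alpha_grid)
        d["synthetic"]["grid_dims"] = list(self.synthetic.grid_dims)
        d["synthetic"]["lesion_radius_range"] = list(self.synthetic.lesion_radius_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_synth(config: RunConfig, run_dir: Path) -> Path:
    """Materialize the input cohort directory (generate or verify)."""
    cohort_dir = run_dir / "cohort"
    if config.input_mode == "synthetic":
        scfg = dataclasses.replace(config.synthetic,
                                   seed=config.synthetic.seed + config.seed + _SEEDS["synth"])
        cohort = synth.generate_cohort(scfg)
        synth.write_cohort(cohort, cohort_dir, write_volumes=config.write_volumes)
    else:
        src = Path(config.input_dir)
        synth.read_cohort(src)  # raises naming any missing file
        cohort_dir = src
    return cohort_dir


def stage_features(cohort_dir: Path, out_dir: Path,
                   exclusion_threshold: float = 50.0) -> None:
    """Lesion-derived features: damage, exclusions, SDC edges, imputation."""
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = synth.read_cohort(cohort_dir)
    scheme = cohort.scheme
    n = cohort.n_participants
    pid = [f"sub{str(i + 1).zfill(3)}" for i in range(n)]
    edge_names = cohort.edge_names

    beh = feat.impute_behaviour(cohort.behaviour)
    bt = beh.copy()
    bt.insert(0, "participant_id", pid)
    _write_tsv(bt, out_dir / "behaviour_imputed.tsv")

    if cohort.lesions:
        dmg = np.vstack([feat.damage_vector(l, scheme) for l in cohort.lesions])
        sdc_vecs = []
        fc_vecs = []
        excl_rows = []
        for i, lesion in enumerate(cohort.lesions):
            excl = feat.excluded_parcels(dmg[i], exclusion_threshold)
            excl_rows.append(sorted(excl))
            sdc = feat.sdc_matrix(lesion, cohort.atlas, scheme)
            sdc_vecs.append(feat.vectorize_upper(sdc))
            fc_miss = np.zeros(scheme.n_edges, dtype=bool)
            if excl:
                ii, jj = feat.edge_index(scheme.n_parcels)
                bad = np.isin(ii + 1, sorted(excl)) | np.isin(jj + 1, sorted(excl))
                fc_miss |= bad
            fc_vecs.append(feat.EdgeVector(values=np.asarray(cohort.fc_edges)[i],
                                           missing_mask=fc_miss))
        sdc_mat, sdc_kept, _ = feat.assemble_group_matrix(sdc_vecs)
        fc_mat, fc_kept, fc_dropped = feat.assemble_group_matrix(fc_vecs)

        d = pd.DataFrame(dmg, columns=[f"p{str(k + 1).zfill(3)}" for k in range(scheme.n_parcels)])
        d.insert(0, "participant_id", pid)
        _write_tsv(d, out_dir / "damage.tsv")

        s = pd.DataFrame(sdc_mat, columns=[edge_names[k] for k in sdc_kept])
        s.insert(0, "participant_id", pid)
        _write_tsv(s, out_dir / "sdc_edges.tsv")

        f = pd.DataFrame(fc_mat, columns=[edge_names[k] for k in fc_kept])
        f.insert(0, "participant_id", pid)
        _write_tsv(f, out_dir / "fc_group.tsv")

        with open(out_dir / "exclusions.json", "w") as fh:
            json.dump({"threshold_percent": exclusion_threshold,
                       "excluded_parcels": excl_rows,
                       "edges_dropped_everywhere": [int(k) for k in fc_dropped]}, fh)
    else:
        f = pd.DataFrame(np.asarray(cohort.fc_edges), columns=edge_names)
        f.insert(0, "participant_id", pid)
        _write_tsv(f, out_dir / "fc_group.tsv")


def _load_xy(features_dir: Path) -> tuple[np.ndarray, list, np.ndarray, list]:
    fc = pd.read_csv(features_dir / "fc_group.tsv", sep="\t").drop(columns=["participant_id"])
    beh = pd.read_csv(features_dir / "behaviour_imputed.tsv", sep="\t").drop(columns=["participant_id"])
    return fc.to_numpy(), list(fc.columns), beh.to_numpy(), list(beh.columns)


def stage_plsc(features_dir: Path, out_dir: Path, n_components: int = 5) -> None:
    """Fit FC-behaviour and SDC-behaviour PLSC models; export loadings/scores."""
    out_dir.mkdir(parents=True, exist_ok=True)
    X, xnames, Y, ynames = _load_xy(features_dir)

    def _one(tag: str, data: np.ndarray, names: list) -> None:
        model = fit_plsc(data, Y, feature_names=names, measure_names=ynames)
        model.to_json(out_dir / f"model_{tag}.json")
        scores = composite_scores(model, data, Y)
        k = min(n_components, model.n_components)
        sc = pd.DataFrame({"participant": np.arange(1, data.shape[0] + 1)})
        for c in range(k):
            sc[f"x_score_lc{c + 1}"] = scores.x_scores[:, c]
            sc[f"y_score_lc{c + 1}"] = scores.y_scores[:, c]
        _write_tsv(sc, out_dir / f"composite_scores_{tag}.tsv")
        load = loadings(scores, data, Y)
        xl = pd.DataFrame(load.x_loadings[:, :k],
                          columns=[f"lc{c + 1}" for c in range(k)])
        xl.insert(0, "feature", names)
        _write_tsv(xl, out_dir / f"x_loadings_{tag}.tsv")
        yl = pd.DataFrame(load.y_loadings[:, :k],
                          columns=[f"lc{c + 1}" for c in range(k)])
        yl.insert(0, "measure", ynames)
        _write_tsv(yl, out_dir / f"y_loadings_{tag}.tsv")
        summary = pd.DataFrame({
            "component": np.arange(1, model.n_components + 1),
            "singular_value": model.singular_values,
            "explained_covariance": model.explained_covariance,
        })
        _write_tsv(summary, out_dir / f"components_{tag}.tsv")

    _one("fc", X, xnames)
    sdc_path = features_dir / "sdc_edges.tsv"
    if sdc_path.exists():
        sdc = pd.read_csv(sdc_path, sep="\t").drop(columns=["participant_id"])
        keep = sdc.std(axis=0) > 0
        sdc = sdc.loc[:, keep]
        _one("sdc", sdc.to_numpy(), list(sdc.columns))


def stage_inference(features_dir: Path, out_dir: Path, cohort_dir: Path,
                    n_perm: int, n_boot: int, seed: int) -> None:
    """Permutation significance and bootstrap loading stability for FC model."""
    out_dir.mkdir(parents=True, exist_ok=True)
    X, xnames, Y, _ = _load_xy(features_dir)
    cohort = synth.read_cohort(cohort_dir)
    model = fit_plsc(X, Y)
    perm = permutation_test(X, Y, n_perm=n_perm, seed=seed + _SEEDS["perm"], model=model)
    comp = pd.DataFrame({
        "component": np.arange(1, model.n_components + 1),
        "singular_value": model.singular_values,
        "p": perm.p_values,
        "q": perm.q_values,
    })
    _write_tsv(comp, out_dir / "permutation.tsv")

    # block-level bootstrap needs the full canonical edge space; fall back to
    # edge-level when exclusions dropped columns
    scheme = cohort.scheme if X.shape[1] == cohort.scheme.n_edges else None
    boot = bootstrap_loadings(X, Y, n_boot=n_boot, seed=seed + _SEEDS["boot"],
                              scheme=scheme, model=model)
    bl = pd.DataFrame({
        "unit": boot.x_labels,
        "mean_loading_lc1": boot.x_mean_loading[:, 0],
        "sd_lc1": boot.x_loading_sd[:, 0],
        "z_lc1": boot.x_z[:, 0],
        "p_lc1": boot.x_p[:, 0],
        "q_lc1": boot.x_q[:, 0],
    })
    _write_tsv(bl, out_dir / "bootstrap_x.tsv")
    with open(out_dir / "inference_manifest.json", "w") as fh:
        json.dump({"n_perm": n_perm, "n_boot": n_boot,
                   "seed_perm": seed + _SEEDS["perm"],
                   "seed_boot": seed + _SEEDS["boot"],
                   "bootstrap_mode": "block" if scheme is not None else "edge",
                   "bootstrap_redrawn": boot.n_redrawn,
                   "loading_policy": "recomputed within each bootstrap sample after alignment"},
                  fh)


def stage_validation(features_dir: Path, out_dir: Path, config: RunConfig,
                     run_dir: Path) -> None:
    """Split-half stability, LOOCV generalization, replication projection."""
    out_dir.mkdir(parents=True, exist_ok=True)
    X, xnames, Y, ynames = _load_xy(features_dir)
    seed = config.seed + _SEEDS["validate"]
    _, _, sim = split_half(X, Y, seed=seed)
    loo = loocv_plsc(X, Y, n_perm=config.loocv_n_perm, seed=seed)
    rows = [
        {"analysis": "split_half", "statistic": "x_salience_r", "value": sim.x_salience_correlation},
        {"analysis": "split_half", "statistic": "y_salience_r", "value": sim.y_salience_correlation},
        {"analysis": "loocv_plsc", "statistic": "pooled_r", "value": loo.pooled_correlation},
        {"analysis": "loocv_plsc", "statistic": "permutation_p", "value": loo.permutation_p},
    ]

    if config.input_mode == "synthetic":
        # replication cohort from the same ground truth, projected onto the model
        cohort_dir = run_dir / "cohort"
        cohort = synth.read_cohort(cohort_dir)
        scfg = cohort.config
        rep = synth.generate_cohort(scfg, truth=cohort.truth,
                                    participant_seed=scfg.seed + _SEEDS["replication"])
        model = fit_plsc(X, Y, feature_names=xnames, measure_names=ynames)
        rep_beh = feat.impute_behaviour(rep.behaviour)
        proj = project_cohort(model, np.asarray(rep.fc_edges), rep_beh.to_numpy(),
                              standardize=config.projection_standardize,
                              n_perm=config.n_perm, seed=seed + 1)
        rep_model = fit_plsc(np.asarray(rep.fc_edges), rep_beh.to_numpy())
        rep_sim = salience_similarity(model, rep_model)
        rows += [
            {"analysis": "replication", "statistic": "projection_lc1_r",
             "value": proj.score_correlation[0]},
            {"analysis": "replication", "statistic": "projection_p",
             "value": proj.permutation_p},
            {"analysis": "replication", "statistic": "y_salience_r",
             "value": rep_sim.y_salience_correlation},
            {"analysis": "replication", "statistic": "x_salience_r",
             "value": rep_sim.x_salience_correlation},
        ]
    _write_tsv(pd.DataFrame(rows), out_dir / "validation.tsv")


def stage_prediction(features_dir: Path, plsc_dir: Path, out_dir: Path,
                     alpha_grid) -> None:
    """Ridge LOOCV: lesion features -> FC-model composite scores."""
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(plsc_dir / "composite_scores_fc.tsv", sep="\t")
    y_beh = scores["y_score_lc1"].to_numpy()
    y_fc = scores["x_score_lc1"].to_numpy()
    rows = []
    preds = {}
    for tag, fname in (("sdc", "sdc_edges.tsv"), ("damage", "damage.tsv")):
        path = features_dir / fname
        if not path.exists():
            continue
        feats = pd.read_csv(path, sep="\t").drop(columns=["participant_id"]).to_numpy()
        for target_name, target in (("behaviour_composite", y_beh),
                                    ("fc_composite", y_fc)):
            rep = loocv_predict(feats, target, alpha_grid=alpha_grid)
            rows.append({"features": tag, "target": target_name,
                         "r": rep.r, "r2": rep.r2, "mae": rep.mae,
                         "median_alpha": float(np.median(rep.per_fold_alpha))})
            preds[f"{tag}_{target_name}"] = rep.predictions
    _write_tsv(pd.DataFrame(rows), out_dir / "prediction.tsv")
    if preds:
        pf = pd.DataFrame(preds)
        pf.insert(0, "participant", np.arange(1, len(pf) + 1))
        _write_tsv(pf, out_dir / "predictions.tsv")


def stage_mediation(plsc_dir: Path, out_dir: Path, n_boot: int, seed: int) -> None:
    """Dual mediation on SDC/FC/behaviour composite scores."""
    out_dir.mkdir(parents=True, exist_ok=True)
    fc_scores = pd.read_csv(plsc_dir / "composite_scores_fc.tsv", sep="\t")
    sdc_path = plsc_dir / "composite_scores_sdc.tsv"
    if not sdc_path.exists():
        return
    sdc_scores = pd.read_csv(sdc_path, sep="\t")
    reports = dual_mediation(sdc_scores["x_score_lc1"].to_numpy(),
                             fc_scores["x_score_lc1"].to_numpy(),
                             fc_scores["y_score_lc1"].to_numpy(),
                             n_boot=n_boot, seed=seed + _SEEDS["mediate"])
    rows = []
    for name, rep in reports.items():
        rows.append({"model": name, "a": rep.a, "b": rep.b, "c": rep.c,
                     "c_prime": rep.c_prime, "ab": rep.ab,
                     "ci_low": rep.ci_low, "ci_high": rep.ci_high,
                     "proportion_mediated": rep.proportion_mediated,
                     "significant": rep.significant})
    _write_tsv(pd.DataFrame(rows), out_dir / "mediation.tsv")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write a manifest; returns the run directory."""
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    timings = {}

    def _timed(name, fn, *args, **kw):
        t0 = time.perf_counter()
        out = fn(*args, **kw)
        timings[name] = round(time.perf_counter() - t0, 3)
        return out

    cohort_dir = _timed("synth", stage_synth, config, run_dir)
    _timed("features", stage_features, cohort_dir, run_dir / "features",
           config.exclusion_threshold)
    _timed("plsc", stage_plsc, run_dir / "features", run_dir / "plsc",
           config.n_components_report)
    _timed("inference", stage_inference, run_dir / "features",
           run_dir / "inference", cohort_dir, config.n_perm, config.n_boot,
           config.seed)
    _timed("validation", stage_validation, run_dir / "features",
           run_dir / "validation", config, run_dir)
    _timed("prediction", stage_prediction, run_dir / "features",
           run_dir / "plsc", run_dir / "prediction", config.alpha_grid)
    _timed("mediation", stage_mediation, run_dir / "plsc",
           run_dir / "mediation", config.n_boot_mediation, config.seed)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": {k: config.seed + v for k, v in _SEEDS.items()},
        "stage_timings_s": timings,
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return run_dir
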