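"""End-to-end orchestration: stage sequencing, configuration, manifests.

The pipeline chains the stages

    hill-fit -> simulate -> features -> train -> evaluate -> explain

over a drug registry.  Two execution profiles exist: ``desk`` (reduced
sample counts, 50-beat pacing, small grid, bounded runtime) and ``paper``
(2,000 Hill samples, 1,000 beats, 10,000 bootstrap iterations - cluster
scale).  Every stage derives its RNG stream from the run seed, every
artifact is checksummed into a JSON manifest, and re-running with the same
configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import drug_block as db
from . import myocyte as myo
from .classifier import RiskANNClassifier, grid_search
from .evaluation import bootstrap_protocol
from .explain import ExactShapleyExplainer, rank_features
from .registry import load_registry


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


_PROFILES = {
    "desk": dict(n_samples=20, n_beats=50, last_n=25, n_iter=500,
                 epochs=30, grid=None),
    "paper": dict(n_samples=2000, n_beats=1000, last_n=250, n_iter=10000,
                  epochs=200, grid="full"),
}


@dataclass
class PipelineConfig:
    """Flat, diffable run configuration (see :func:`parse_config`)."""

    out_dir: str = "tdp_run"
    seed: int = 0
    profile: str = "desk"
    registry: str = "builtin"
    dose_response: str | None = None   # CSV; None -> synthetic from registry
    multipliers: tuple = (1.0, 2.0, 3.0, 4.0)
    bcl: float = 2000.0
    stages: tuple = ("hill-fit", "simulate", "features", "train", "evaluate", "explain")
    n_samples: int | None = None       # override profile
    n_beats: int | None = None
    n_iter: int | None = None
    epochs: int | None = None

    def resolved(self):
        base = dict(_PROFILES[self.profile])
        for k in ("n_samples", "n_beats", "n_iter", "epochs"):
            if getattr(self, k) is not None:
                base[k] = getattr(self, k)
        return base


def parse_config(path) -> PipelineConfig:
    """Parse the flat ``key = value`` configuration format."""
    kw = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in PipelineConfig.__dataclass_fields__:
            raise KeyError(f"{path}:{lineno}: unknown config key {key!r}")
        kw[key] = _coerce(key, val)
    return PipelineConfig(**kw)


def _coerce(key, val):
    if key in ("seed", "n_samples", "n_beats", "n_iter", "epochs"):
        return int(val)
    if key == "bcl":
        return float(val)
    if key == "multipliers":
        return tuple(float(x) for x in val.split(","))
    if key == "stages":
        return tuple(s.strip() for s in val.split(","))
    if key == "dose_response" and val.lower() in ("", "none"):
        return None
    return val


def write_config(cfg: PipelineConfig, path) -> None:
    lines = []
    for k, v in asdict(cfg).items():
        if v is None:
            continue
        if isinstance(v, tuple):
            v = ",".join(str(x) for x in v)
        lines.append(f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def _sha256(path):
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _log(lines, stage, seed, msg):
    entry = f"[{stage}] seed={seed} {msg}"
    lines.append(entry)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prof = config.resolved()
    seeds = {stage: config.seed + i for i, stage in enumerate(
        ("hill-fit", "simulate", "features", "train", "evaluate", "explain"))}
    log: list = []
    manifest = {"config": asdict(config), "profile": prof, "seeds": seeds,
                "artifacts": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    registry = load_registry(config.registry)
    reg_path = out / "registry.csv"
    registry.to_csv(reg_path, index=False)
    manifest["artifacts"]["registry"] = _sha256(reg_path)

    def need(path, stage):
        if not Path(path).exists():
            raise DependencyError(f"stage {stage!r} requires missing artifact {path}")
        return path

    hill_path = out / "hill_samples.csv"
    if "hill-fit" in config.stages:
        if config.dose_response:
            points = db.read_dose_response(config.dose_response)
        else:
            from .synthetic import gen_drug_specs, gen_dose_response
            specs = gen_drug_specs(registry, seed=seeds["hill-fit"])
            points = pd.concat(
                [gen_dose_response(s, seed=seeds["hill-fit"] + i)
                 for i, s in enumerate(specs)], ignore_index=True)
        sampler = db.HillCurveSampler(
            n_samples=prof["n_samples"], n_iter=2000 if config.profile == "desk" else 10000,
            seed=seeds["hill-fit"])
        sampler.fit(points)
        db.write_hill_samples(sampler.samples_, hill_path)
        manifest["artifacts"]["hill_samples"] = _sha256(hill_path)
        _log(log, "hill-fit", seeds["hill-fit"],
             f"{len(sampler.samples_)} samples, {len(sampler.diagnostics_)} warnings")

    features_path = out / "features.csv"
    if "simulate" in config.stages or "features" in config.stages:
        need(hill_path, "simulate")
        table = db.read_hill_samples(hill_path)
        protocol = myo.PacingProtocol(bcl=config.bcl, n_beats=prof["n_beats"])
        rows = compute_features(
            table, registry, protocol, multipliers=config.multipliers,
            last_n=min(prof["last_n"], prof["n_beats"]), log=log,
            seed=seeds["simulate"])
        rows.to_csv(features_path, index=False, float_format="%.10g")
        manifest["artifacts"]["features"] = _sha256(features_path)
        _log(log, "features", seeds["features"], f"{len(rows)} feature rows")

    model_path = out / "model.json"
    if "train" in config.stages:
        need(features_path, "train")
        feat = bm.validate_features(pd.read_csv(features_path))
        train = feat[feat["drug"].map(
            registry.set_index("name")["split"]) == "train"]
        X = train[bm.FEATURE_NAMES].to_numpy(float)
        y = train["risk"].to_numpy()
        clf = RiskANNClassifier(epochs=prof["epochs"], seed=seeds["train"])
        clf.fit(X, y)
        clf.save(model_path)
        manifest["artifacts"]["model"] = _sha256(model_path)
        _log(log, "train", seeds["train"], f"{len(train)} training rows")

    if "evaluate" in config.stages:
        need(model_path, "evaluate")
        need(features_path, "evaluate")
        clf = RiskANNClassifier.load(model_path)
        feat = bm.validate_features(pd.read_csv(features_path))
        test = feat[feat["drug"].map(
            registry.set_index("name")["split"]) == "test"].reset_index(drop=True)
        summary = bootstrap_protocol(clf, test, n_iter=prof["n_iter"],
                                     seed=seeds["evaluate"])
        report_path = out / "evaluation.csv"
        summary.to_frame().to_csv(report_path, index=False, float_format="%.10g")
        iters_path = out / "evaluation_iterations.csv"
        summary.per_iteration.to_csv(iters_path, index=False, float_format="%.10g")
        manifest["artifacts"]["evaluation"] = _sha256(report_path)
        manifest["artifacts"]["evaluation_iterations"] = _sha256(iters_path)
        _log(log, "evaluate", seeds["evaluate"],
             f"mean error {summary.mean_classification_error:.4f}")

    if "explain" in config.stages:
        need(model_path, "explain")
        need(features_path, "explain")
        clf = RiskANNClassifier.load(model_path)
        feat = bm.validate_features(pd.read_csv(features_path))
        train = feat[feat["drug"].map(
            registry.set_index("name")["split"]) == "train"].reset_index(drop=True)
        rng = np.random.default_rng(seeds["explain"])
        bg_idx = rng.choice(len(train), size=min(100, len(train)), replace=False)
        background = train.iloc[np.sort(bg_idx)][bm.FEATURE_NAMES].to_numpy(float)
        ex_idx = rng.choice(len(train), size=min(50, len(train)), replace=False)
        rows = train.iloc[np.sort(ex_idx)][bm.FEATURE_NAMES].to_numpy(float)
        result = ExactShapleyExplainer(clf, background).explain(rows)
        ranking = rank_features(result)
        shap_path = out / "shap_values.csv"
        result.to_long_frame().to_csv(shap_path, index=False, float_format="%.10g")
        rank_path = out / "feature_ranking.csv"
        ranking.per_class.assign(aggregate=ranking.aggregate).loc[ranking.order] \
            .to_csv(rank_path, float_format="%.10g")
        manifest["artifacts"]["shap_values"] = _sha256(shap_path)
        manifest["artifacts"]["feature_ranking"] = _sha256(rank_path)
        _log(log, "explain", seeds["explain"], f"top feature {ranking.order[0]}")

    manifest["log"] = log
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def compute_features(hill_table: pd.DataFrame, registry: pd.DataFrame,
                     protocol: myo.PacingProtocol,
                     multipliers=(1.0, 2.0, 3.0, 4.0), last_n: int = 250,
                     model: myo.CellModel | None = None, log=None,
                     seed: int = 0) -> pd.DataFrame:
    """Simulate every (drug, Hill sample, concentration), extract biomarkers,
    average over concentrations, and return the tidy feature table.

    The zero-block control run (for qInward) is shared across all samples of
    a model/protocol.  Flagged (no-repolarisation) rows are dropped with a
    logged count.
    """
    model = model or myo.surrogate_model()
    g_control = model.control_conductances()
    control_trace = myo.simulate_paced(model, g_control, protocol)
    control_beat = myo.select_representative_beat(control_trace, last_n)
    reg = registry.set_index("name")
    out_rows = []
    n_flagged = 0
    for drug in sorted(hill_table["drug"].unique()):
        if drug not in reg.index:
            raise KeyError(f"drug {drug!r} absent from registry")
        exposure = db.DrugExposure(drug, float(reg.loc[drug, "cmax"]),
                                   tuple(multipliers), reg.loc[drug, "risk"])
        for sample in db.samples_from_table(hill_table, drug):
            vecs = []
            for mult in multipliers:
                profile = db.block_profile(sample, exposure, mult)
                g = db.scale_conductances(g_control, profile)
                trace = myo.simulate_paced(model, g, protocol)
                beat = myo.select_representative_beat(trace, last_n)
                vecs.append(bm.extract_biomarkers(beat, control_beat))
            avg = bm.average_over_concentrations(vecs)
            if avg.flagged:
                n_flagged += 1
                continue
            out_rows.append({"drug": drug, "sample": sample.sample_index,
                             **avg.as_dict(), "risk": reg.loc[drug, "risk"]})
    if log is not None and n_flagged:
        _log(log, "features", seed, f"dropped {n_flagged} flagged samples")
    return pd.DataFrame(out_rows, columns=bm.FEATURE_CSV_COLUMNS)
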