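"""End-to-end orchestration: data -> surrogate -> attribution -> retrieval
-> explanation -> evaluation, under one seeded configuration.

A single master seed is fanned out deterministically to per-stage seeds
(holdout split, SHAP background subsample, LIME sampling, generation runs),
so a rerun of the same config with the mock backend reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import attribution, evaluation, explanation, retrieval, surrogate
from .data import FeatureCatalog, MoleculeTable, load_table, write_exclusion_report

logger = logging.getLogger(__name__)

BACKENDS = {"mock": explanation.MockBackend}


@dataclass
class RunConfig:
    input: str
    corpus: str
    out_dir: str
    label_column: str = "label"
    smiles_column: Optional[str] = None
    task_override: Optional[str] = None
    property_name: Optional[str] = None
    xai_method: str = "shap"          # shap | lime | both
    k: int = 3
    backend: str = "mock"
    n_runs: int = 5
    master_seed: int = 0

    def validate(self) -> None:
        if self.xai_method not in ("shap", "lime", "both"):
            raise ValueError(f"unknown xai method {self.xai_method!r}")
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}; available: {sorted(BACKENDS)}")
        if not Path(self.input).exists():
            raise ValueError(f"input file {self.input} does not exist")
        if not self.corpus or not Path(self.corpus).is_dir():
            raise ValueError(f"corpus directory {self.corpus!r} does not exist")
        if self.n_runs < 1 or self.k < 1:
            raise ValueError("n_runs and k must be >= 1")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Flat key-value (TOML) config file; explicit overrides win."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    artifacts: dict = field(default_factory=dict)   # name -> {path, sha256}
    stage_seconds: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    hyperparameters: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    versions: dict = field(default_factory=dict)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _fan_out_seeds(master_seed: int) -> dict:
    state = np.random.SeedSequence(master_seed).generate_state(5)
    names = ["split", "shap", "lime", "generation", "aux"]
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                logger.error("stage %s failed: %s", name, exc)
            else:
                logger.info("stage %s: done (%.2fs)", name, manifest.stage_seconds[name])
            return False

    return _Timer()


def _pick_catalog(table: MoleculeTable) -> FeatureCatalog:
    if all(n.startswith("maccs_") for n in table.feature_names):
        return FeatureCatalog.maccs_standard()
    return FeatureCatalog.passthrough()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; any stage error aborts with the stage name and a
    partial manifest attached to the raised exception."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _fan_out_seeds(config.master_seed)
    manifest = RunManifest(config=dataclasses.asdict(config), seeds=seeds)
    import sklearn
    import xgboost

    manifest.versions = {
        "chemxplain": _version(),
        "xgboost": xgboost.__version__,
        "sklearn": sklearn.__version__,
        "numpy": np.__version__,
    }

    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("chemxplain")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)

    def _register(name, path):
        manifest.artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        (out / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=2))
        _register("config", out / "config.json")

        with _stage(manifest, "data"):
            table = load_table(
                config.input,
                label_column=config.label_column,
                smiles_column=config.smiles_column,
                task_override=config.task_override,
            )
            table.write_csv(out / "validated.csv", label_column=config.label_column)
            write_exclusion_report(table, out / "exclusions.jsonl")
            _register("validated_table", out / "validated.csv")
            _register("exclusions", out / "exclusions.jsonl")

        with _stage(manifest, "surrogate"):
            model, eval_report = surrogate.fit_surrogate(table, split_seed=seeds["split"])
            manifest.hyperparameters = model.hyperparameters_
            surrogate.save_model(model, out / "model.json")
            surrogate.export_eval_plot(eval_report, out / "eval_plot.png")
            _register("model", out / "model.json")
            _register("eval_plot", out / "eval_plot.png")

        with _stage(manifest, "attribution"):
            catalog = _pick_catalog(table)
            importances = {}
            if config.xai_method in ("shap", "both"):
                importances["tree_shap"] = attribution.global_importance(
                    model, table, method="tree_shap", seed=seeds["shap"]
                )
            if config.xai_method in ("lime", "both"):
                importances["lime"] = attribution.global_importance(
                    model, table, method="lime", seed=seeds["lime"]
                )
            primary = importances.get("tree_shap") or importances["lime"]
            features = attribution.top_k(primary, catalog, k=min(config.k, table.d))
            for tag, gi in importances.items():
                _write_importance_csv(gi, out / f"importances_{tag}.csv")
                attribution.export_importance_plot(gi, out / f"importances_{tag}.png")
                _register(f"importances_{tag}", out / f"importances_{tag}.csv")
                _register(f"importances_{tag}_plot", out / f"importances_{tag}.png")
            if len(importances) == 2:
                from scipy.stats import spearmanr

                rho = float(
                    spearmanr(
                        importances["tree_shap"].ranks, importances["lime"].ranks
                    ).statistic
                )
                manifest.warnings.append(f"shap/lime rank agreement (spearman): {rho:.3f}")
                logger.info("shap/lime rank agreement (spearman rho): %.3f", rho)

        with _stage(manifest, "retrieval"):
            index = retrieval.CorpusIndex.from_directory(config.corpus)
            index.save(out / "corpus.idx")
            _register("corpus_index", out / "corpus.idx")
            property_name = config.property_name or config.label_column
            retrievals = {
                rec["feature"]: retrieval.retrieve_for_feature(rec, index, property_name)
                for rec in features.records
            }

        with _stage(manifest, "explanation"):
            bundle = explanation.assemble_prompt(features, retrievals, property_name)
            backend = BACKENDS[config.backend]()
            runs = explanation.generate_explanations(
                backend, bundle, features, n_runs=config.n_runs, base_seed=seeds["generation"]
            )
            runs = [explanation.attach_citations(e, index) for e in runs]
            (out / "explanations.json").write_text(
                json.dumps(
                    [
                        {
                            "run_id": e.run_id,
                            "seed": e.seed,
                            "failed": e.failed,
                            "text": e.text,
                            "hypotheses": e.hypotheses,
                            "citations": [dataclasses.asdict(c) for c in e.citations],
                            "unresolved": e.unresolved,
                        }
                        for e in runs
                    ],
                    indent=2,
                )
            )
            _register("explanations", out / "explanations.json")

        with _stage(manifest, "evaluation"):
            tally = evaluation.tally_hypotheses(runs)
            prec = evaluation.precision(tally)
            rouge = evaluation.rouge_variability(runs) if config.n_runs >= 2 else None
            audit = evaluation.audit_citations(runs, index, catalog)
            eval_payload = {
                "tally": tally.counts,
                "n_features": tally.n_features,
                "n_runs": tally.n_runs,
                "precision": prec.precision,
                "per_feature_contribution": prec.per_feature,
                "rouge_l": None
                if rouge is None
                else {"mean_f": rouge.mean_f, "sd_f": rouge.sd_f, "pairs": rouge.pairs},
                "citation_audit": {
                    "correct": audit.correct,
                    "total": audit.total,
                    "mean_normalized": audit.mean_normalized,
                    "per_explanation": audit.per_explanation,
                    "unresolved_markers": sum(e.unresolved for e in runs),
                },
            }
            (out / "eval.json").write_text(json.dumps(eval_payload, indent=2))
            _register("evaluation", out / "eval.json")

        with _stage(manifest, "report"):
            explanation.render_report(runs, primary, eval_report, index, out / "report.md")
            _register("report", out / "report.md")
    except Exception as exc:
        manifest.warnings.append(f"aborted: {exc}")
        (out / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()

    (out / "manifest.json").write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    return manifest


def _write_importance_csv(gi, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "feature": gi.feature_names,
            "score": gi.scores,
            "z": gi.z if gi.z is not None else [float("nan")] * len(gi.feature_names),
            "direction": gi.directions,
            "rank": gi.ranks,
        }
    ).sort_values("rank")
    df.to_csv(path, index=False)


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("chemxplain")
    except Exception:
        return "unknown"
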