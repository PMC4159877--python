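"""End-to-end orchestration: energies -> descriptors -> screening ->
neuro-fuzzy model -> bootstrap validation -> report.

A run is described by a :class:`RunConfig` (loadable from YAML).  Three
input modes are supported:

* **energy mode** — a registry file plus a per-form molecular-energy
  table; descriptors are derived, screened and fed to the model;
* **synthetic mode** — a :class:`~anthoqsar.synthetic_data.SyntheticSpec`
  generates the feature matrix and activity in place of input files;
* **skip-training mode** — an externally supplied prediction column is
  validated directly, which reproduces published headline metrics
  independently of any training-hyperparameter uncertainty.

Every artifact is stamped with a hash of the configuration and the
seed, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import click
import numpy as np
import pandas as pd
import yaml

from . import anfis, descriptors, feature_selection, synthetic_data, validation
from .chem_model import load_registry

__all__ = ["RunConfig", "PipelineError", "run", "report", "cli"]

logger = logging.getLogger("anthoqsar")

#: Default independent variables: electron affinity and electronegativity
#: of the flavylium cation, ionization potential of the 7-quinoidal base,
#: and the core hydroxyl count.
DEFAULT_FEATURES = list(descriptors.DEFAULT_FEATURES)


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    output_dir: str = "anthoqsar_run"
    method: str = "PM6"
    registry_path: Optional[str] = None
    energy_table_path: Optional[str] = None
    activity_path: Optional[str] = None
    predictions_path: Optional[str] = None       # enables skip-training mode
    synthetic: Optional[synthetic_data.SyntheticSpec] = None
    selected_features: list = field(default_factory=lambda: list(DEFAULT_FEATURES))
    anfis: anfis.TrainingConfig = field(default_factory=anfis.TrainingConfig)
    mfs_per_input: int = 2
    n_boot: int = 1000
    seed: int = 0
    retrain_bootstrap: bool = False
    collinearity_r2: float = 1.0

    def __post_init__(self):
        if self.method not in ("PM6", "PM7"):
            raise ValueError(f"unknown method {self.method!r}; expected PM6 or PM7")
        if isinstance(self.anfis, dict):
            self.anfis = anfis.TrainingConfig(**self.anfis)
        if isinstance(self.synthetic, dict):
            self.synthetic = synthetic_data.SyntheticSpec(**self.synthetic)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_activities(config: RunConfig) -> pd.DataFrame:
    df = pd.read_csv(config.activity_path, sep=None, engine="python")
    if "compound" not in df.columns or "activity" not in df.columns:
        raise PipelineError(
            "activities: file must have columns 'compound' and 'activity'"
        )
    return df


def _stage(name: str):
    """Wrap stage failures with the stage name and log timing."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                if not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name}: {exc}") from exc
                return False
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run(config: RunConfig) -> validation.ValidationReport:
    """Execute all stages and write artifacts into ``config.output_dir``.

    Artifacts: ``correlation_report.txt``, ``model.json``,
    ``error_trace.csv``, ``predictions.csv``, ``validation.txt`` and
    ``run.json`` (config hash, seed, stage list).  Returns the
    validation report.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed,
             "config": config.to_dict(), "stages": []}
    names: Sequence[str]

    if config.predictions_path is not None:
        # -- skip-training mode: validate supplied predictions directly
        with _stage("inject-predictions"):
            df = pd.read_csv(config.predictions_path, sep=None, engine="python")
            required = {"compound", "experimental", "predicted"}
            if not required <= set(df.columns):
                raise ValueError(
                    f"predictions file needs columns {sorted(required)}"
                )
            pairs = validation.PredictionPairs(
                y_obs=df["experimental"].to_numpy(),
                y_pred=df["predicted"].to_numpy(),
                labels=tuple(df["compound"]),
            )
            predictions = df
            stamp["stages"].append("inject-predictions")
    else:
        if config.synthetic is not None:
            with _stage("simulate"):
                features, activity, truth = synthetic_data.generate(config.synthetic)
                names = list(features.index.astype(str))
                (out / "ground_truth.json").write_text(
                    json.dumps(truth, indent=2) + "\n"
                )
                stamp["stages"].append("simulate")
        else:
            with _stage("describe"):
                if not (config.registry_path and config.energy_table_path
                        and config.activity_path):
                    raise ValueError(
                        "energy mode needs registry_path, energy_table_path "
                        "and activity_path"
                    )
                registry = load_registry(config.registry_path)
                energies = descriptors.load_energy_table(config.energy_table_path)
                features = descriptors.build_feature_table(
                    registry, energies, method=config.method,
                    features=config.selected_features,
                )
                act = _load_activities(config).set_index("compound")
                missing = [n for n in features.index if n not in act.index]
                if missing:
                    raise ValueError(f"no activity for compounds: {missing}")
                activity = act.loc[features.index, "activity"].to_numpy(dtype=float)
                stamp["stages"].append("describe")

        with _stage("screen"):
            results = feature_selection.screen_descriptors(features, activity)
            ranked = [
                r.descriptor_id
                for r in sorted(results, key=lambda r: -abs(r.r) if not r.failed else 1.0)
            ]
            kept = feature_selection.eliminate_collinear(
                ranked, features, r2_threshold=config.collinearity_r2
            )
            (out / "correlation_report.txt").write_text(
                feature_selection.correlation_report(results)
                + f"\n\nretained after collinearity elimination: {kept}\n"
            )
            features = features[[c for c in features.columns if c in kept]]
            stamp["stages"].append("screen")

        with _stage("train"):
            model, trace = anfis.fit_anfis(
                features, activity, cfg=config.anfis,
                mfs_per_input=config.mfs_per_input,
            )
            model.save(out / "model.json")
            pd.DataFrame(
                {"epoch": np.arange(1, trace.size + 1), "mse": trace}
            ).to_csv(out / "error_trace.csv", index=False)
            y_pred = model.predict(features)
            stamp["stages"].append("train")

        labels = tuple(str(i) for i in features.index)
        pairs = validation.PredictionPairs(
            y_obs=activity, y_pred=y_pred, labels=labels
        )
        predictions = pd.DataFrame(
            {"compound": labels, "experimental": activity, "predicted": y_pred}
        )

    with _stage("validate"):
        predictions.to_csv(out / "predictions.csv", index=False)
        rep = validation.bootstrap_validate(
            pairs, n_boot=config.n_boot, seed=config.seed
        )
        (out / "validation.txt").write_text(
            rep.to_text() + f"\nconfig_hash: {config.config_hash()}\n"
        )
        stamp["stages"].append("validate")

    (out / "run.json").write_text(json.dumps(stamp, indent=2, default=str) + "\n")
    return rep


def report(output_dir: Union[str, Path]) -> str:
    """One-page text summary of a completed run's artifacts."""
    out = Path(output_dir)
    if not out.is_dir():
        raise FileNotFoundError(f"run directory {out} does not exist")
    needed = ["validation.txt", "predictions.csv", "run.json"]
    for fname in needed:
        if not (out / fname).exists():
            raise FileNotFoundError(f"missing artifact {fname} in {out}")
    stamp = json.loads((out / "run.json").read_text())
    preds = pd.read_csv(out / "predictions.csv")
    lines = [
        "=== run summary ===",
        f"compounds: {len(preds)}",
        f"seed: {stamp['seed']}   config_hash: {stamp['config_hash']}",
        f"stages: {', '.join(stamp['stages'])}",
        "",
        (out / "validation.txt").read_text().rstrip(),
    ]
    corr = out / "correlation_report.txt"
    if corr.exists():
        lines += ["", "--- descriptor screening ---", corr.read_text().rstrip()]
    trace = out / "error_trace.csv"
    if trace.exists():
        tr = pd.read_csv(trace)
        lines.append(
            f"\ntraining: {len(tr)} epochs, final MSE {tr['mse'].iloc[-1]:.4g}"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Command-line interface (thin wrappers over the library)

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log stage progress.")
def cli(verbose: bool):
    """QSAR modelling of anthocyanin radical scavenging activity."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command("describe")
@click.option("--registry", required=True, type=click.Path(exists=True))
@click.option("--energies", required=True, type=click.Path(exists=True))
@click.option("--method", default="PM6", type=click.Choice(["PM6", "PM7"]))
@click.option("--features", default=",".join(DEFAULT_FEATURES), show_default=True)
@click.option("--out", required=True, type=click.Path())
def cli_describe(registry, energies, method, features, out):
    """Derive the descriptor feature table from molecular energies."""
    reg = load_registry(registry)
    recs = descriptors.load_energy_table(energies)
    table = descriptors.build_feature_table(
        reg, recs, method=method, features=features.split(",")
    )
    table.to_csv(out, index_label="compound")
    click.echo(f"wrote {table.shape[0]} x {table.shape[1]} feature table to {out}")


@cli.command("screen")
@click.option("--features", "features_path", required=True, type=click.Path(exists=True))
@click.option("--activity", "activity_path", required=True, type=click.Path(exists=True))
@click.option("--alpha-strict", default=0.01, show_default=True)
@click.option("--alpha-loose", default=0.05, show_default=True)
@click.option("--out", type=click.Path(), default=None)
def cli_screen(features_path, activity_path, alpha_strict, alpha_loose, out):
    """Pearson-screen descriptor columns against activity."""
    feats = pd.read_csv(features_path, index_col=0)
    act = pd.read_csv(activity_path, sep=None, engine="python")
    y = act[act.columns[-1]].to_numpy(dtype=float)
    results = feature_selection.screen_descriptors(
        feats, y, alpha_strict=alpha_strict, alpha_loose=alpha_loose
    )
    text = feature_selection.correlation_report(results)
    if out:
        Path(out).write_text(text + "\n")
    click.echo(text)


@cli.command("train")
@click.option("--features", "features_path", required=True, type=click.Path(exists=True))
@click.option("--activity", "activity_path", required=True, type=click.Path(exists=True))
@click.option("--epochs", default=100, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path(), help="Model JSON path.")
@click.option("--trace-out", type=click.Path(), default=None)
def cli_train(features_path, activity_path, epochs, seed, out, trace_out):
    """Train the neuro-fuzzy model on a feature table."""
    feats = pd.read_csv(features_path, index_col=0)
    act = pd.read_csv(activity_path, sep=None, engine="python")
    y = act[act.columns[-1]].to_numpy(dtype=float)
    cfg = anfis.TrainingConfig(epochs=epochs, seed=seed)
    model, trace = anfis.fit_anfis(feats, y, cfg=cfg)
    model.save(out)
    if trace_out:
        pd.DataFrame(
            {"epoch": np.arange(1, trace.size + 1), "mse": trace}
        ).to_csv(trace_out, index=False)
    click.echo(f"trained {len(model.rules)}-rule model; final MSE {trace[-1]:.4g}")


@cli.command("validate")
@click.option("--pairs", "pairs_path", required=True, type=click.Path(exists=True),
              help="CSV with columns compound, experimental, predicted.")
@click.option("--n-boot", default=1000, show_default=True)
@click.option("--seed", default=0, show_default=True)
def cli_validate(pairs_path, n_boot, seed):
    """Bootstrap-validate an (experimental, predicted) pair table."""
    df = pd.read_csv(pairs_path, sep=None, engine="python")
    pairs = validation.PredictionPairs(
        y_obs=df["experimental"].to_numpy(),
        y_pred=df["predicted"].to_numpy(),
        labels=tuple(df["compound"]),
    )
    rep = validation.bootstrap_validate(pairs, n_boot=n_boot, seed=seed)
    click.echo(rep.to_text())


@cli.command("simulate")
@click.option("--n", default=21, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out-features", required=True, type=click.Path())
@click.option("--out-activity", required=True, type=click.Path())
def cli_simulate(n, seed, out_features, out_activity):
    """Generate a synthetic descriptor/activity dataset."""
    spec = synthetic_data.SyntheticSpec(n_compounds=n, seed=seed)
    feats, activity, _ = synthetic_data.generate(spec)
    feats.to_csv(out_features, index_label="row")
    pd.DataFrame({"row": feats.index, "activity": activity}).to_csv(
        out_activity, index=False
    )
    click.echo(f"wrote {n} synthetic compounds")


@cli.command("run")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--seed", type=int, default=None, help="Override the config seed.")
def cli_run(config_path, seed):
    """Execute an end-to-end run from a YAML configuration."""
    config = RunConfig.from_yaml(config_path)
    if seed is not None:
        config.seed = seed
    rep = run(config)
    click.echo(report(config.output_dir))
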