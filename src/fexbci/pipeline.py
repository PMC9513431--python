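"""Configuration-driven orchestration: simulate -> preprocess -> optimize ->
evaluate -> compare, with a reproducibility manifest.

An experiment is described by an :class:`ExperimentConfig` (loadable from
YAML).  Two presets bracket the scale: ``full`` (240 epochs at
1 kHz, GA population 20 x 20 generations, 100 training epochs — the
faithful protocol, hours of CPU) and ``smoke`` (a minutes-long reduced run
for development).  All stages are seeded from the single global seed;
every stage writes its outputs under the run directory, and the manifest
records resolved configuration, seeds, versions, timings and the file
inventory.  Completed stages are skipped on resume when the manifest shows
the same configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import fexbci
from fexbci.cnn import FIXED_COMPARISON_GENOME, HyperparamGenome, TrainConfig
from fexbci.decoder import FacialExpressionDecoder
from fexbci.ga import GAConfig
from fexbci.preprocess import FilterSpec, RejectionRule, SampEnParams, bandpass_filter, clean_epochs
from fexbci.ga import default_layout
from fexbci.synthdata import (ArtifactSpec, EpochSet, default_signatures,
                              generate_epochs, inject_artifacts, read_epochs,
                              write_epochs)

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "optimize", "evaluate")


@dataclass
class ExperimentConfig:
    # synthetic data
    n_per_class: int = 60
    fs: float = 1000.0
    signature_family: str = "boost"      # boost | coupling
    signature_gain: float = 4.0          # band-power gain (boost family)
    coupling_strength: float = 8.0       # shared-source power (coupling family)
    background_band: tuple[float, float] = (1.0, 45.0)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    # preprocessing
    filter: FilterSpec = field(default_factory=FilterSpec)
    sampen: SampEnParams = field(default_factory=SampEnParams)
    rejection: RejectionRule = field(default_factory=RejectionRule)
    run_cleaning: bool = True
    n_directions: int = 64
    # model + search
    genome: str | tuple = "ga"
    train: TrainConfig = field(default_factory=TrainConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    # evaluation
    k_folds: int = 5
    repeats: int = 2
    include_baseline: bool = True
    # global
    seed: int = 0
    out_dir: str = "fexbci_run"
    scale: str = "full"

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.scale not in ("full", "smoke"):
            raise ValueError(f"scale must be full|smoke, got {self.scale}")
        if self.signature_family not in ("boost", "coupling"):
            raise ValueError("signature_family must be boost|coupling")
        if self.k_folds < 2 or self.repeats < 1:
            raise ValueError("need k_folds >= 2 and repeats >= 1")
        if self.genome != "ga":
            self.genome = HyperparamGenome(*self.genome)  # validates ranges

    @classmethod
    def smoke(cls, seed: int = 0, out_dir: str = "fexbci_smoke") -> "ExperimentConfig":
        """Minutes-scale preset: fewer/shorter epochs, tiny GA, fast fitness."""
        return cls(
            n_per_class=10, fs=40.0, signature_family="coupling",
            background_band=(1.0, 19.0), run_cleaning=False,
            filter=FilterSpec(order=5, band=(0.5, 18.0)),
            train=TrainConfig(epochs=20, seed=seed),
            ga=GAConfig(population_size=6, generations=3, seed=seed,
                        fitness_mode="fast"),
            k_folds=5, repeats=1, seed=seed, out_dir=out_dir, scale="smoke",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        nested = {"artifacts": ArtifactSpec, "filter": FilterSpec,
                  "sampen": SampEnParams, "rejection": RejectionRule,
                  "train": TrainConfig, "ga": GAConfig}
        kwargs = {}
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                try:
                    kwargs[key] = nested[key](**{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in value.items()})
                except TypeError as exc:
                    raise ValueError(f"invalid config section '{key}': {exc}") from exc
            elif key == "genome" and isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ValueError(f"invalid config field: {exc}") from exc

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "as_tuple"):
                return o.as_tuple()
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    completed: list = field(default_factory=list)
    failed_stage: str | None = None

    def write(self, path: Path):
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=1))
        tmp.replace(path)  # atomic on POSIX

    @classmethod
    def read(cls, path: Path) -> "RunManifest":
        return cls(**json.loads(path.read_text()))


def _stage_done(manifest: RunManifest | None, cfg_hash: str, stage: str) -> bool:
    return (manifest is not None and manifest.config_hash == cfg_hash
            and stage in manifest.completed)


def run_experiment(config: ExperimentConfig) -> RunManifest:
    """Execute all stages in order, resuming past completed ones.

    Raises on the first failing stage after writing a manifest that marks
    the failure point; partial outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    manifest_path = out / "manifest.json"
    previous = RunManifest.read(manifest_path) if manifest_path.exists() else None
    manifest = RunManifest(
        config_hash=cfg_hash, seed=config.seed,
        versions={"fexbci": fexbci.__version__, "numpy": np.__version__,
                  "python": platform.python_version()},
    )
    if previous is not None and previous.config_hash == cfg_hash:
        manifest.completed = list(previous.completed)
        manifest.timings = dict(previous.timings)
        manifest.outputs = dict(previous.outputs)

    (out / "config.yaml").write_text(yaml.safe_dump(
        json.loads(json.dumps(asdict(config), default=str))))

    def record(stage, t0, **outputs):
        manifest.timings[stage] = round(time.perf_counter() - t0, 3)
        manifest.outputs[stage] = {k: str(v) for k, v in outputs.items()}
        if stage not in manifest.completed:
            manifest.completed.append(stage)
        manifest.write(manifest_path)

    try:
        # --- simulate -----------------------------------------------------
        raw_dir = out / "epochs_raw"
        if not _stage_done(previous, cfg_hash, "simulate"):
            t0 = time.perf_counter()
            logger.info("simulate: %d epochs/class at fs=%g (seed %d)",
                        config.n_per_class, config.fs, config.seed)
            if config.signature_family == "coupling":
                from fexbci.synthdata import coupling_signatures
                sigs = coupling_signatures(config.coupling_strength)
            else:
                sigs = default_signatures(config.signature_gain)
            epochs = generate_epochs(
                config.n_per_class, sigs, fs=config.fs, seed=config.seed,
                background_band=config.background_band)
            epochs = inject_artifacts(epochs, config.artifacts,
                                      seed=config.seed + 1)
            write_epochs(epochs, raw_dir)
            record("simulate", t0, epochs=raw_dir)

        # --- preprocess ---------------------------------------------------
        clean_dir = out / "epochs_clean"
        if not _stage_done(previous, cfg_hash, "preprocess"):
            t0 = time.perf_counter()
            epochs = read_epochs(raw_dir)
            logger.info("preprocess: band-pass %s order %d%s",
                        config.filter.band, config.filter.order,
                        ", NA-MEMD cleaning" if config.run_cleaning else "")
            epochs = bandpass_filter(epochs, config.filter)
            if config.run_cleaning:
                epochs = clean_epochs(epochs, config.rejection, config.sampen,
                                      n_directions=config.n_directions,
                                      seed=config.seed + 2)
            write_epochs(epochs, clean_dir)
            record("preprocess", t0, epochs=clean_dir)

        # --- optimize + evaluate (decoder fit) ----------------------------
        if not _stage_done(previous, cfg_hash, "evaluate"):
            t0 = time.perf_counter()
            epochs = read_epochs(clean_dir)
            decoder = FacialExpressionDecoder(
                epochs, genome=config.genome, train_config=config.train,
                ga_config=config.ga, include_baseline=config.include_baseline)
            results = decoder.fit(k=config.k_folds, repeats=config.repeats,
                                  seed=config.seed)
            report_dir = out / "report"
            report_dir.mkdir(exist_ok=True)
            (report_dir / "best_genome.json").write_text(json.dumps(
                {"genome": list(results.genome.as_tuple())}))
            if results.ga_history is not None:
                results.ga_history.to_dataframe(layout=default_layout()).to_csv(
                    report_dir / "ga_history.tsv", sep="\t", index=False)
            metrics = {name: rep.to_dict() for name, rep in results.reports.items()}
            (report_dir / "metrics.json").write_text(json.dumps(metrics, indent=1))
            for name, rep in results.reports.items():
                np.savetxt(report_dir / f"confusion_{name}.tsv", rep.confusion,
                           fmt="%d", delimiter="\t")
            if results.comparison is not None:
                results.comparison.to_csv(report_dir / "comparison.tsv",
                                          sep="\t", index=False)
            (report_dir / "summary.txt").write_text(results.summary() + "\n")
            record("optimize", t0)
            record("evaluate", t0, report=report_dir)
    except Exception:
        manifest.failed_stage = next(
            (s for s in STAGES if s not in manifest.completed), "unknown")
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest
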