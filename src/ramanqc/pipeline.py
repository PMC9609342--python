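"""End-to-end orchestration: simulate -> preprocess -> screen -> split ->
select -> train -> evaluate -> predict, from one validated config.

Every stage writes its artifact into the run directory; a manifest ties
each output file's content hash to the config and seed, so a rerun with the
same config is bit-identical (the CNN trains single-threaded from a fixed
seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .calibrate import CalibrationModel, fit_engine
from .cnn import CnnSpec, receptive_field
from .errors import ConfigurationError, DataError, LookupError_
from .evaluate import EvaluationReport, cross_validate, evaluate_predictions
from .preprocess import preprocess
from .screen import screen
from .select import (CarsConfig, cars_select, sipls_select, spa_select,
                     uve_select)
from .spectra import ReferenceTable, SpectraMatrix, read_spectra_csv, write_spectra_csv
from .split import kennard_stone_split

log = logging.getLogger("ramanqc.pipeline")

SELECTOR_NAMES = ("cars", "uve", "spa", "sipls")
ENGINE_NAMES = ("plsr", "svr", "cnn")


@dataclass
class SimulateConfig:
    """Desk-scaled defaults for the end-to-end study.

    The instrument axis is 6x coarser than the 2.83 cm^-1 hardware grid and
    channel noise / batch interference are turned up so that band selection
    has something to remove; the stand-alone generator defaults
    (synth.GeneratorConfig) keep the full-resolution, clean-signal
    configuration used for screening-type analyses.
    """

    n_batches: int = 7
    replicates: int = 3
    drop_last: bool = True
    outlier_count: int = 5
    axis_resolution: float = 6 * synth.AXIS_RESOLUTION
    noise_sd: float = 0.35
    baseline_scale: float = 0.1
    interferent_scale: float = 1.2
    interferent_peaks: int = 20


@dataclass
class PreprocessConfig:
    window: int = 5     # scaled to the coarse default axis; 11 at 2.83 cm^-1
    polyorder: int = 3
    replicate_key: str = "replicate_of"


@dataclass
class ScreenConfig:
    rule: str = "mean3sd"
    k: float = 3.0
    n_scores: str | int = "auto"


@dataclass
class SelectConfig:
    cars_runs: int = 50
    cars_mc_rate: float = 0.8
    folds: int = 5
    sipls_intervals: int = 20
    spa_max_vars: int = 20


@dataclass
class CnnConfig:
    # 100 epochs is the desk-scaled training budget for the default study;
    # the stand-alone engine default (CnnSpec) keeps the full 200/40 protocol
    max_epochs: int = 100
    patience: int = 40
    batch_size: int = 50
    learning_rate: float = 1e-4


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    spectra_path: str | None = None        # used when simulate is None
    references_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    split_ratio: str = "4:1"
    select: SelectConfig = field(default_factory=SelectConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    engines: tuple[str, ...] = ("spa-svr", "cars-plsr", "cnn", "cars-cnn")
    attributes: tuple[str, ...] = synth.ATTRIBUTES
    eval_folds: int = 3   # desk-scaled; the module-level default is 5

    def validate(self) -> None:
        if not self.engines:
            raise ConfigurationError("engines list is empty")
        for label in self.engines:
            parse_engine_label(label)
        if not self.attributes:
            raise ConfigurationError("attributes list is empty")
        if self.simulate is None and not (self.spectra_path and self.references_path):
            raise ConfigurationError(
                "need either a simulate block or spectra/references paths")
        if self.eval_folds < 2:
            raise ConfigurationError("eval_folds must be >= 2")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)

        def build(klass, key):
            block = raw.pop(key, None)
            if block is None:
                return None if key == "simulate" and "spectra_path" in raw else klass()
            if not isinstance(block, dict):
                raise ConfigurationError(f"config block {key!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(klass)}
            unknown = set(block) - valid
            if unknown:
                raise ConfigurationError(f"unknown keys in {key!r}: {sorted(unknown)}")
            return klass(**block)

        sim = build(SimulateConfig, "simulate")
        pre = build(PreprocessConfig, "preprocess")
        scr = build(ScreenConfig, "screen")
        sel = build(SelectConfig, "select")
        cnn = build(CnnConfig, "cnn")
        for key in ("engines", "attributes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(simulate=sim, preprocess=pre or PreprocessConfig(),
                  screen=scr or ScreenConfig(), select=sel or SelectConfig(),
                  cnn=cnn or CnnConfig(),
                  **{k: v for k, v in raw.items()
                     if k not in ("simulate", "preprocess", "screen", "select", "cnn")})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def parse_engine_label(label: str) -> tuple[str | None, str]:
    """'cars-cnn' -> ('cars', 'cnn'); 'cnn' -> (None, 'cnn')."""
    parts = label.lower().split("-")
    if len(parts) == 1 and parts[0] in ENGINE_NAMES:
        return None, parts[0]
    if len(parts) == 2 and parts[0] in SELECTOR_NAMES and parts[1] in ENGINE_NAMES:
        return parts[0], parts[1]
    raise ConfigurationError(
        f"bad engine label {label!r}: expected '<engine>' or "
        f"'<selector>-<engine>' with selector in {SELECTOR_NAMES} and engine "
        f"in {ENGINE_NAMES}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    artifacts: dict[str, Path] = {}
    stage_log: list[dict] = []

    def record(stage: str, **info):
        stage_log.append({"stage": stage, **info})
        log.info("stage %s: %s", stage, info)

    # -- simulate / load ----------------------------------------------------
    truth_outliers: list[str] = []
    if config.simulate is not None:
        sim = config.simulate
        gen_cfg = synth.GeneratorConfig(
            n_batches=sim.n_batches, replicates=sim.replicates,
            drop_last=sim.drop_last,
            outliers=synth.OutlierSpec(count=sim.outlier_count),
            axis_resolution=sim.axis_resolution, noise_sd=sim.noise_sd,
            baseline_scale=sim.baseline_scale,
            interferent_scale=sim.interferent_scale,
            interferent_peaks=sim.interferent_peaks)
        dataset = synth.generate_dataset(gen_cfg, seed=seed)
        paths = synth.write_dataset(dataset, outdir / "simulated")
        artifacts.update({k: Path(v) for k, v in paths.items()})
        spectra, references = dataset.spectra, dataset.references
        truth_outliers = dataset.outlier_ids
        record("simulate", n_raw=spectra.n_samples,
               n_channels=spectra.n_channels, outliers=dataset.outlier_ids)
        replicate_key = "replicate_of"
    else:
        spectra = read_spectra_csv(config.spectra_path)
        references = ReferenceTable.from_csv(config.references_path)
        replicate_key = config.preprocess.replicate_key
        record("load", spectra=config.spectra_path)

    # -- preprocess ---------------------------------------------------------
    pp = preprocess(spectra,
                    replicate_key=(replicate_key if replicate_key else None),
                    window=config.preprocess.window,
                    polyorder=config.preprocess.polyorder)
    write_spectra_csv(pp, outdir / "preprocessed.csv")
    artifacts["preprocessed"] = outdir / "preprocessed.csv"
    record("preprocess", window=config.preprocess.window,
           polyorder=config.preprocess.polyorder, n_samples=pp.n_samples)

    # -- screen -------------------------------------------------------------
    screening = screen(pp, n_scores=config.screen.n_scores,
                       rule=config.screen.rule, k=config.screen.k)
    (outdir / "screening.json").write_text(
        json.dumps(screening.to_report(), indent=1, sort_keys=True))
    artifacts["screening"] = outdir / "screening.json"
    retained = screening.retained
    record("screen", rule=config.screen.rule, threshold=screening.threshold,
           flagged=screening.flagged_ids, retained=retained.n_samples)

    # -- split --------------------------------------------------------------
    split = kennard_stone_split(retained, config.split_ratio)
    (outdir / "split.json").write_text(json.dumps(split.to_dict(), indent=1))
    artifacts["split"] = outdir / "split.json"
    record("split", ratio=config.split_ratio,
           calibration=len(split.calibration_ids),
           validation=len(split.validation_ids))

    X_cal = retained.select_samples(split.calibration_ids).intensities
    X_val = retained.select_samples(split.validation_ids).intensities

    # -- select (cached per selector x attribute) ---------------------------
    selections: dict[tuple[str, str], np.ndarray] = {}

    def get_selection(selector: str, attribute: str, min_size: int = 1) -> np.ndarray:
        key = (selector, attribute)
        if key not in selections:
            y = references.values_for(attribute, list(split.calibration_ids))
            if selector == "cars":
                res = cars_select(X_cal, y,
                                  CarsConfig(n_runs=config.select.cars_runs,
                                             mc_rate=config.select.cars_mc_rate,
                                             cv_folds=config.select.folds),
                                  seed=seed)
            elif selector == "uve":
                res = uve_select(X_cal, y, seed=seed)
            elif selector == "spa":
                res = spa_select(X_cal, y, max_vars=config.select.spa_max_vars,
                                 folds=config.select.folds, seed=seed)
            elif selector == "sipls":
                res = sipls_select(X_cal, y,
                                   n_intervals=config.select.sipls_intervals,
                                   folds=config.select.folds, seed=seed)
            else:
                raise ConfigurationError(f"unknown selector {selector!r}")
            path = outdir / f"selection_{selector}_{attribute}.json"
            path.write_text(json.dumps(res.to_dict(), indent=1))
            artifacts[f"selection_{selector}_{attribute}"] = path
            selections[key] = res
            record("select", selector=selector, attribute=attribute,
                   n_selected=int(res.selected_indices.size))
        res = selections[key]
        if min_size > 1 and res.selected_indices.size < min_size:
            return res.subset_of_at_least(min_size)
        return res.selected_indices

    # -- train + evaluate ---------------------------------------------------
    report = EvaluationReport(provenance={
        "seed": seed, "split_ratio": config.split_ratio,
        "eval_folds": config.eval_folds, "engines": list(config.engines),
        "config": config.to_dict()})
    models: dict[tuple[str, str], CalibrationModel] = {}

    for label in config.engines:
        selector, engine = parse_engine_label(label)
        for attribute in config.attributes:
            y_cal = references.values_for(attribute, list(split.calibration_ids))
            y_val = references.values_for(attribute, list(split.validation_ids))
            kwargs = {}
            min_size = 1
            if engine == "cnn":
                spec = CnnSpec.for_attribute(
                    attribute, max_epochs=config.cnn.max_epochs,
                    patience=config.cnn.patience,
                    batch_size=config.cnn.batch_size,
                    learning_rate=config.cnn.learning_rate)
                kwargs["spec"] = spec
                min_size = receptive_field(spec)
            idx = (get_selection(selector, attribute, min_size)
                   if selector else None)
            try:
                model = fit_engine(engine, X_cal, y_cal, attribute=attribute,
                                   selected_indices=idx, seed=seed, **kwargs)

                def refit(Xtr, ytr, _engine=engine, _idx=idx, _kw=dict(kwargs)):
                    return fit_engine(_engine, Xtr, ytr, attribute=attribute,
                                      selected_indices=_idx, seed=seed, **_kw)

                rcv2, rmsecv, oof = cross_validate(refit, X_cal, y_cal,
                                                   config.eval_folds, seed)
                metrics = evaluate_predictions(
                    y_cal, model.predict(X_cal), y_val, model.predict(X_val),
                    rcv2, rmsecv)
                preds = {"calibration": model.predict(X_cal),
                         "validation": model.predict(X_val), "oof": oof}
                report.add(label, attribute, metrics, preds)
                model.fingerprint = _fingerprint(config)
                models[(label, attribute)] = model
                bundle = outdir / "models" / f"{label}_{attribute}"
                bundle.parent.mkdir(exist_ok=True)
                model.save(bundle)
                record("train", engine=label, attribute=attribute,
                       **{k: round(v, 6) for k, v in metrics.items()})
            except Exception as exc:  # report completeness: mark failed cells
                log.exception("engine %s failed on %s", label, attribute)
                report.add(label, attribute,
                           {"failed": f"{type(exc).__name__}: {exc}"})
                raise

    report.to_csv(outdir / "report.csv")
    report.to_json(outdir / "report.json")
    artifacts["report"] = outdir / "report.csv"
    artifacts["report_json"] = outdir / "report.json"

    # -- manifest -----------------------------------------------------------
    manifest = {
        "seed": seed,
        "config": config.to_dict(),
        "stages": stage_log,
        "planted_outliers": truth_outliers,
        "artifacts": {name: {"path": str(p.relative_to(outdir)),
                             "sha256": _sha256(p)}
                      for name, p in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest


def _fingerprint(config: PipelineConfig) -> dict:
    return {"window": config.preprocess.window,
            "polyorder": config.preprocess.polyorder,
            "minmax": True, "seed": config.seed}


def predict_unknown(models: dict[tuple[str, str], CalibrationModel] | str | Path,
                    spectra: SpectraMatrix, engine_label: str | None = None,
                    replicate_key: str | None = "replicate_of",
                    window: int = 11, polyorder: int = 3) -> pd.DataFrame:
    """Predict every attribute for unknown-batch spectra.

    ``models`` is either the dict returned by training or a run directory's
    ``models/`` folder; raw spectra are preprocessed with the same settings
    as training.  Returns a tidy (batch, sample_id, attribute, predicted)
    table.
    """
    if spectra.n_samples == 0:
        raise DataError("empty spectra input")
    if not isinstance(models, dict):
        models = load_models(models)
    if engine_label is not None:
        models = {k: v for k, v in models.items() if k[0] == engine_label}
        if not models:
            raise LookupError_(f"no models for engine {engine_label!r}")
    pp = preprocess(spectra, replicate_key=replicate_key,
                    window=window, polyorder=polyorder)
    rows = []
    for (label, attribute), model in sorted(models.items()):
        pred = model.predict(pp.intensities)
        for sid, value in zip(pp.sample_ids, pred):
            batch = sid.split("-")[0]
            rows.append({"engine": label, "batch": batch, "sample_id": sid,
                         "attribute": attribute, "predicted": float(value)})
    return pd.DataFrame(rows)


def load_models(directory: str | Path) -> dict[tuple[str, str], CalibrationModel]:
    directory = Path(directory)
    if directory.name != "models" and (directory / "models").is_dir():
        directory = directory / "models"
    models = {}
    for pkl in sorted(directory.glob("*.pkl")):
        model = CalibrationModel.load(pkl.with_suffix(""))
        desc = json.loads(pkl.with_suffix(".json").read_text())
        label = pkl.stem.rsplit("_" + model.attribute, 1)[0]
        models[(label, model.attribute)] = model
    return models
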