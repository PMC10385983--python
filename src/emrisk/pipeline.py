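"""Stage orchestration: simulate -> cohort -> train -> attribute -> report.

Each stage reads its predecessor's plain CSV/JSON artifacts from the run
directory and writes its own next to a manifest (config hash, seed, package
version, input/output checksums), so every intermediate is inspectable and a
fixed global seed reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, attribution, cohort, encoding, models, simulate

log = logging.getLogger(__name__)

STAGES = ("simulate", "cohort", "train", "attribute", "report")


@dataclass(frozen=True)
class ModelConfig:
    embed_dim: int = 128
    hidden_size: int = 128
    n_layers: int = 2
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 3
    vocab_cap: int = encoding.DEFAULT_MAX_VOCAB
    top_k_labs: int = encoding.DEFAULT_TOP_LABS
    n_repeats: int = 10
    seed: int = 0


@dataclass(frozen=True)
class AttributionConfig:
    multiple_testing: str = "benjamini_hochberg"
    anchor_code: str = "DX:G30"
    prevalence_threshold: float = 0.10
    q_threshold: float = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    cohort: cohort.CohortConfig = field(default_factory=cohort.CohortConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Propagate one global seed into every stage."""
        return PipelineConfig(
            sim=dataclasses.replace(self.sim, seed=seed),
            cohort=dataclasses.replace(self.cohort, seed=seed + 1),
            model=dataclasses.replace(self.model, seed=seed + 2),
            attribution=self.attribution,
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        sim_kw = obj.get("sim", {})
        if "planted_effects" in sim_kw:
            sim_kw["planted_effects"] = {
                k: float(v) for k, v in sim_kw["planted_effects"].items()}
        if "ad_onset_uniform_range" in sim_kw:
            sim_kw["ad_onset_uniform_range"] = tuple(sim_kw["ad_onset_uniform_range"])
        coh_kw = obj.get("cohort", {})
        if "split_ratios" in coh_kw:
            coh_kw["split_ratios"] = tuple(coh_kw["split_ratios"])
        return cls(
            sim=simulate.SimConfig(**sim_kw),
            cohort=cohort.CohortConfig(**coh_kw),
            model=ModelConfig(**obj.get("model", {})),
            attribution=AttributionConfig(**obj.get("attribution", {})),
            seed=int(obj.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if math.isinf(d["sim"]["recency_halflife_days"]):
            d["sim"]["recency_halflife_days"] = "inf"
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig,
                    inputs: list[Path], outputs: list[Path]) -> None:
    cfg = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
        "version": __version__,
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires missing artifact {path}; run its "
            f"predecessor first")
    return path


def run_simulate(config: PipelineConfig, outdir: Path) -> list[Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    records = simulate.generate_cohort(config.sim)
    events = simulate.to_event_table(records)
    patients = simulate.patients_table(records)
    ev_path, pt_path = outdir / "events.csv", outdir / "patients.csv"
    events.to_csv(ev_path, index=False)
    patients.to_csv(pt_path, index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    _write_manifest(outdir, "simulate", config, [], [ev_path, pt_path])
    log.info("simulated %d patients, %d events", len(records), len(events))
    return [ev_path, pt_path]


def run_cohort(config: PipelineConfig, outdir: Path,
               tables: encoding.MappingTables | None = None) -> list[Path]:
    events = pd.read_csv(_require(outdir / "events.csv", "cohort"), dtype=str)
    records = simulate.from_event_table(
        events, ad_code=config.sim.ad_code,
        psychosis_code=config.sim.psychosis_code,
        delirium_code=config.sim.delirium_code)
    samples = cohort.build_samples(records, config.cohort, tables)
    folds = cohort.split_samples(samples, config.cohort)
    fold_of = {}
    pos = {id(s): i for i, s in enumerate(samples)}
    for name, fold in zip(("train", "validation", "test"), folds):
        for s in fold:
            fold_of[pos[id(s)]] = name
    jl_path, csv_path = outdir / "samples.jsonl", outdir / "samples.csv"
    cohort.samples_to_jsonl(samples, jl_path, fold_of)
    cohort.samples_to_frame(samples, fold_of).to_csv(csv_path, index=False)
    _write_manifest(outdir, "cohort", config, [outdir / "events.csv"],
                    [jl_path, csv_path])
    log.info("built %d samples (%d cases)", len(samples),
             sum(s.y for s in samples))
    return [jl_path, csv_path]


def _load_folds(outdir: Path, stage: str):
    samples, folds = cohort.samples_from_jsonl(
        _require(outdir / "samples.jsonl", stage))
    out = {"train": [], "validation": [], "test": []}
    for s, f in zip(samples, folds):
        out[f].append(s)
    return out


def _packable(sample, vocab) -> bool:
    return any(t in vocab.token_of for _, toks in sample.visits for t in toks)


def _pack_fold(fold, vocab):
    X, y = [], []
    for s in fold:
        try:
            X.append(encoding.pack_sample(s, vocab))
        except ValueError:
            continue
        y.append(s.y)
    return X, np.asarray(y)


def run_train(config: PipelineConfig, outdir: Path) -> list[Path]:
    folds = _load_folds(outdir, "train")
    mc = config.model
    vocab = encoding.build_vocabulary(folds["train"], max_size=mc.vocab_cap,
                                      top_k_labs=mc.top_k_labs)
    vocab_path = outdir / "vocabulary.json"
    vocab.to_json(vocab_path)
    packed = {k: _pack_fold(v, vocab) for k, v in folds.items()}
    fold_tuple = (packed["train"], packed["validation"], packed["test"])

    def make_lstm(seed):
        return models.LSTMRiskClassifier(
            embed_dim=mc.embed_dim, hidden_size=mc.hidden_size,
            n_layers=mc.n_layers, dropout=mc.dropout,
            learning_rate=mc.learning_rate, batch_size=mc.batch_size,
            max_epochs=mc.max_epochs, patience=mc.patience,
            vocab_size=vocab.n_tokens, seed=seed)

    def make_lr(seed):
        return models.BagOfCodesLogisticClassifier(vocab_size=vocab.n_tokens,
                                                   seed=seed)

    results = {
        "LSTM": models.repeat_evaluate(make_lstm, fold_tuple,
                                       n_repeats=mc.n_repeats,
                                       base_seed=mc.seed),
        "LR": models.repeat_evaluate(make_lr, fold_tuple,
                                     n_repeats=mc.n_repeats,
                                     base_seed=mc.seed),
    }
    metrics_path = outdir / "metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump({k: v.as_dict() for k, v in results.items()}, fh,
                  indent=2, sort_keys=True)
    auc_csv = outdir / "auc_report.csv"
    pd.DataFrame(
        [(k, r.val_mean, r.test_mean, r.val_std, r.test_std)
         for k, r in results.items()],
        columns=["model", "validation_auc", "test_auc",
                 "validation_auc_std", "test_auc_std"],
    ).to_csv(auc_csv, index=False)

    # final model for attribution: one training run at the base seed
    final = make_lstm(mc.seed).fit(packed["train"][0], packed["train"][1],
                                   X_val=packed["validation"][0],
                                   y_val=packed["validation"][1])
    model_path = outdir / "model.npz"
    np.savez(model_path, **final.net_.get_weights(),
             _meta=np.array(json.dumps({
                 "embed_dim": mc.embed_dim, "hidden_size": mc.hidden_size,
                 "n_layers": mc.n_layers, "dropout": mc.dropout,
                 "vocab_size": vocab.n_tokens, "seed": mc.seed})))
    _write_manifest(outdir, "train", config, [outdir / "samples.jsonl"],
                    [vocab_path, metrics_path, auc_csv])
    return [vocab_path, metrics_path, auc_csv, model_path]


def _load_model(outdir: Path, stage: str) -> models.LSTMRiskClassifier:
    from .recurrent import LSTMNet

    path = _require(outdir / "model.npz", stage)
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["_meta"]))
    net = LSTMNet(meta["vocab_size"], meta["embed_dim"], meta["hidden_size"],
                  meta["n_layers"], meta["dropout"], seed=meta["seed"])
    net.set_weights({k: data[k] for k in net.params})
    clf = models.LSTMRiskClassifier(
        embed_dim=meta["embed_dim"], hidden_size=meta["hidden_size"],
        n_layers=meta["n_layers"], dropout=meta["dropout"],
        vocab_size=meta["vocab_size"], seed=meta["seed"])
    clf.net_ = net
    clf.classes_ = np.array([0, 1])
    return clf


def run_attribute(config: PipelineConfig, outdir: Path) -> list[Path]:
    _load_model(outdir, "attribute")  # contract: attribute requires a completed train stage
    vocab = encoding.Vocabulary.from_json(
        _require(outdir / "vocabulary.json", "attribute"))
    folds = _load_folds(outdir, "attribute")
    mc = config.model
    allsamp = folds["train"] + folds["validation"] + folds["test"]
    X, y = _pack_fold(allsamp, vocab)
    pids = [s.patient_id for s in allsamp
            if _packable(s, vocab)]

    def make_lstm(seed):
        return models.LSTMRiskClassifier(
            embed_dim=mc.embed_dim, hidden_size=mc.hidden_size,
            n_layers=mc.n_layers, dropout=mc.dropout,
            learning_rate=mc.learning_rate, batch_size=mc.batch_size,
            max_epochs=mc.max_epochs, patience=mc.patience,
            vocab_size=vocab.n_tokens, seed=seed)

    cm = attribution.crossfit_contribution_matrix(
        make_lstm, X, y, pids, vocab, seed=mc.seed)
    table = attribution.rc_table(cm, method=config.attribution.multiple_testing)
    scaled = attribution.scale_to_anchor(table, config.attribution.anchor_code)
    scaled = scaled.join(cm.prevalence().rename("prevalence"))
    rc_path = outdir / "rc_full.csv"
    scaled.to_csv(rc_path)
    _write_manifest(outdir, "attribute", config,
                    [outdir / "samples.jsonl", outdir / "vocabulary.json"],
                    [rc_path])
    return [rc_path]


def run_report(config: PipelineConfig, outdir: Path) -> list[Path]:
    table = pd.read_csv(_require(outdir / "rc_full.csv", "report"),
                        index_col="feature")
    prevalence = table["prevalence"]
    report = attribution.report_significant(
        table.drop(columns=["prevalence"]), prevalence,
        q_threshold=config.attribution.q_threshold,
        dx_prevalence_min=config.attribution.prevalence_threshold)
    # the anchor's RC is 1 by construction; it is the calibration, not a finding
    report = report[report.index != config.attribution.anchor_code]
    report_out = report.reset_index()[
        ["feature", "feature_type", "rc", "ci_high", "ci_low", "p", "q",
         "n_event", "n_nonevent", "prevalence"]
    ].rename(columns={"rc": "RC", "ci_high": "CI95up", "ci_low": "CI95down",
                      "p": "P", "q": "Q"})
    rep_path = outdir / "report.csv"
    report_out.to_csv(rep_path, index=False)
    _write_manifest(outdir, "report", config, [outdir / "rc_full.csv"],
                    [rep_path])
    return [rep_path]


def run(stage: str, config: PipelineConfig, outdir) -> list[Path]:
    outdir = Path(outdir)
    if stage == "all":
        paths = []
        for s in STAGES:
            paths += run(s, config, outdir)
        return paths
    runner = {"simulate": run_simulate, "cohort": run_cohort,
              "train": run_train, "attribute": run_attribute,
              "report": run_report}.get(stage)
    if runner is None:
        raise ValueError(f"unknown stage {stage!r}")
    return runner(config, outdir)
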