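"""End-to-end workflow orchestration.

Stages: synth-data → build-vocab → pretrain → finetune → generate →
evaluate → qsar-train → qsar-score.  Each stage reads its inputs from the
run directory, writes its artifacts there with content hashes, and appends
JSON-lines log records.  Re-running an unchanged stage with the same seed
reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .codec import TokenVocabulary, build_vocabulary, write_molecules
from .config import RunConfig, write_resolved
from .metrics import evaluate_generation, property_profile
from .nn.model import ConditionalDecoder, ModelConfig, load_checkpoint, save_checkpoint
from .qsar import predict_and_rank, train_qsar
from .sampling import GenerationConfig, generate
from .synthetic import default_profiles, generate_corpus, generate_target_sets
from .training import FinetuneConfig, finetune, pretrain

__all__ = ["STAGES", "PipelineError", "run_pipeline"]

STAGES = ("synth-data", "build-vocab", "pretrain", "finetune",
          "generate", "evaluate", "qsar-train", "qsar-score")


class PipelineError(RuntimeError):
    """A stage cannot run; the message names the stage to run first."""


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Run:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.dir = Path(cfg.outdir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.log_path = self.dir / "log.jsonl"

    def log(self, record: dict) -> None:
        record = {"time": round(time.time(), 2), **record}
        with self.log_path.open("a") as fh:
            fh.write(json.dumps(record) + "\n")

    def path(self, name: str) -> Path:
        return self.dir / name

    def require(self, name: str, produced_by: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise PipelineError(
                f"missing artifact {name!r}: run stage {produced_by!r} first")
        return p

    def provenance(self, stage: str, artifacts: list[Path]) -> None:
        meta = {
            "stage": stage,
            "seed": self.cfg.seed,
            "artifacts": {p.name: _hash_file(p) for p in artifacts if p.exists()},
        }
        self.log({"event": "stage-complete", **meta})


def _stage_synth_data(run: _Run) -> None:
    d = run.cfg.data
    corpus = generate_corpus(
        n=d.corpus_size, length_range=(d.length_min, d.length_max),
        seed=d.corpus_seed)
    targets = generate_target_sets(default_profiles(),
                                   seed=run.cfg.seed, noise_sd=d.noise_sd)
    write_molecules(corpus.records, run.path("corpus.csv"))
    write_molecules(targets.records, run.path("targets.csv"))
    run.provenance("synth-data", [run.path("corpus.csv"), run.path("targets.csv")])


def _stage_build_vocab(run: _Run) -> None:
    corpus = pd.read_csv(run.require("corpus.csv", "synth-data"))
    targets = pd.read_csv(run.require("targets.csv", "synth-data"))
    vocab = build_vocabulary(list(corpus["selfies"]) + list(targets["selfies"]))
    vocab.to_json(run.path("vocab.json"))
    run.provenance("build-vocab", [run.path("vocab.json")])


def _model_config(run: _Run, vocab: TokenVocabulary) -> ModelConfig:
    return ModelConfig(vocab_size=len(vocab), **run.cfg.model)


def _stage_pretrain(run: _Run) -> None:
    vocab = TokenVocabulary.from_json(run.require("vocab.json", "build-vocab"))
    corpus = pd.read_csv(run.require("corpus.csv", "synth-data"))
    model = ConditionalDecoder(_model_config(run, vocab), seed=run.cfg.seed)
    train_df = corpus[corpus["split"] == "train"]
    pretrain(model, train_df, vocab, run.cfg.pretrain,
             seed=run.cfg.seed, log=run.log)
    save_checkpoint(model, run.path("pretrained.npz"), vocab_hash=vocab.hash)
    run.provenance("pretrain", [run.path("pretrained.npz")])


def _stage_finetune(run: _Run) -> None:
    vocab = TokenVocabulary.from_json(run.require("vocab.json", "build-vocab"))
    targets = pd.read_csv(run.require("targets.csv", "synth-data"))
    model, _ = load_checkpoint(run.require("pretrained.npz", "pretrain"),
                               expect_vocab_hash=vocab.hash)
    cfg: FinetuneConfig = run.cfg.finetune
    finetune(model, targets[targets["split"] == "train"],
             targets[targets["split"] == "valid"], vocab, cfg,
             seed=run.cfg.seed, log=run.log)
    save_checkpoint(model, run.path("finetuned.npz"), vocab_hash=vocab.hash)
    run.provenance("finetune", [run.path("finetuned.npz")])


def _stage_generate(run: _Run) -> None:
    vocab = TokenVocabulary.from_json(run.require("vocab.json", "build-vocab"))
    ckpt = run.path("finetuned.npz")
    if not ckpt.exists():
        ckpt = run.require("pretrained.npz", "pretrain")
    model, _ = load_checkpoint(ckpt, expect_vocab_hash=vocab.hash)
    frames = []
    target_ids = [0] if not model.adapter_blocks else [0, 1, 2, 3]
    for tid in target_ids:
        gcfg = GenerationConfig(target_id=tid, seed=run.cfg.seed + tid,
                                **run.cfg.generate)
        frames.append(generate(model, vocab, gcfg))
    out = pd.concat(frames, ignore_index=True)
    write_molecules(out, run.path("generated.csv"))
    run.provenance("generate", [run.path("generated.csv")])


def _stage_evaluate(run: _Run) -> None:
    gen = pd.read_csv(run.require("generated.csv", "generate"))
    corpus = pd.read_csv(run.require("corpus.csv", "synth-data"))
    train = list(corpus[corpus["split"] == "train"]["smiles"].fillna(""))
    test = [s for s in corpus[corpus["split"] == "valid"]["smiles"].fillna("") if s]
    reference = {
        prop: [getattr(property_profile(s), prop) for s in test[:500]]
        for prop in ("MW", "LogP", "QED", "TPSA")
    }
    gen_smiles = list(gen["smiles"].fillna(""))
    n_unique = 1000 if len(gen_smiles) >= 1000 else max(1, len(gen_smiles) // 2)
    report = evaluate_generation(gen_smiles, train, reference=reference,
                                 unique_sizes=(n_unique,), seed=run.cfg.seed)
    run.path("report.json").write_text(json.dumps(report, indent=1))
    run.provenance("evaluate", [run.path("report.json")])


def _stage_qsar_train(run: _Run) -> None:
    targets = pd.read_csv(run.require("targets.csv", "synth-data"))
    import pickle
    targets = targets[targets["smiles"].notna() & (targets["smiles"] != "")]
    models = {}
    for tid, df in targets.groupby("target"):
        models[int(tid)] = train_qsar(df[df["split"] == "train"], int(tid),
                                      seed=run.cfg.qsar.seed)
    with run.path("qsar_models.pkl").open("wb") as fh:
        pickle.dump(models, fh)
    run.provenance("qsar-train", [run.path("qsar_models.pkl")])


def _stage_qsar_score(run: _Run) -> None:
    import pickle
    gen = pd.read_csv(run.require("generated.csv", "generate"))
    with run.require("qsar_models.pkl", "qsar-train").open("rb") as fh:
        models = pickle.load(fh)
    frames = []
    for tid, model in models.items():
        subset = gen[gen["target"] == tid]
        pool = subset if len(subset) else gen
        smiles = [s for s in pool["smiles"].fillna("") if s]
        ranked = predict_and_rank(model, smiles, top=run.cfg.qsar.top)
        ranked.insert(0, "target", tid)
        frames.append(ranked)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(run.path("scored.csv"), index=False)
    run.provenance("qsar-score", [run.path("scored.csv")])


_STAGE_FUNCS = {
    "synth-data": _stage_synth_data,
    "build-vocab": _stage_build_vocab,
    "pretrain": _stage_pretrain,
    "finetune": _stage_finetune,
    "generate": _stage_generate,
    "evaluate": _stage_evaluate,
    "qsar-train": _stage_qsar_train,
    "qsar-score": _stage_qsar_score,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in canonical order; returns the run dir."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    run = _Run(cfg)
    write_resolved(cfg, run.path("resolved_config.json"))
    for stage in STAGES:
        if stage in stages:
            run.log({"event": "stage-start", "stage": stage})
            _STAGE_FUNCS[stage](run)
    return run.dir
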