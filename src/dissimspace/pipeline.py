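"""End-to-end orchestration: train -> prototypes -> project -> SVM -> fuse -> evaluate.

One ensemble member is produced per (architecture, kc, representation)
triple: a Siamese scorer trained on the training fold, per-class k-means
prototypes, dissimilarity design matrices, and a one-vs-all linear SVM.
Member test-score matrices are fused by sum rule (optionally z-normalized
against the member's training scores) and the fused matrix is evaluated.

All randomness funnels through one root seed from which per-stage seeds
are derived, so a run is reproducible from its RunConfig alone.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from dissimspace.classify import (ScoreMatrix, sum_rule, train_ova_svm, znorm)
from dissimspace.data import LabeledImage, labels_of, load_image_folder
from dissimspace.dissim import build_design_matrix, save_design_matrix
from dissimspace.evaluation import EvalReport, evaluate
from dissimspace.hasc import hasc_image
from dissimspace.prototypes import select_prototypes
from dissimspace.siamese import get_architecture, scale_architecture
from dissimspace.synthetic import GeneratorConfig, make_dataset, make_split
from dissimspace.training import TrainOptions, train_snn


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (YAML-mappable)."""

    dataset: str = ""                    # image folder; empty = synthetic
    representation: str = "original"     # "original" or "hasc"
    architectures: tuple[int, ...] = (3,)
    kc_grid: tuple[int, ...] = (3,)
    input_size: int = 64                 # Siamese input layer side
    width_factor: float = 0.25           # channel shrink for scaled runs
    embedding_dim: int = 64
    cluster_side: int = 32
    train_fraction: float = 0.75
    iterations: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    svm_c: float = 1.0
    znorm_members: bool = False          # z-normalize before the plain sum rule
    seed: int = 0
    output_dir: str = ""
    synthetic: dict = field(default_factory=dict)  # GeneratorConfig overrides

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("architectures", "kc_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_or_generate(config: RunConfig) -> list[LabeledImage]:
    if config.dataset:
        return load_image_folder(config.dataset)
    gen = GeneratorConfig(**{"seed": config.seed, **config.synthetic})
    return make_dataset(gen)


def _apply_representation(images: list[LabeledImage], representation: str,
                          out_size: int) -> list[LabeledImage]:
    if representation == "original":
        return images
    if representation == "hasc":
        return [hasc_image(im, out_size=out_size) for im in images]
    raise ValueError(f"unknown representation {representation!r}")


def _member_seeds(root: int, n: int) -> list[int]:
    state = np.random.SeedSequence([root, 101]).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


@dataclass
class MemberResult:
    arch_id: int
    kc: int
    representation: str
    test_scores: ScoreMatrix
    train_scores: ScoreMatrix
    accuracy: float


def run_pipeline(config: RunConfig) -> tuple[EvalReport, list[MemberResult]]:
    """Execute every stage for each (architecture, kc) member and fuse.

    Returns the fused evaluation report and the per-member results.  If
    ``config.output_dir`` is set, reports, score CSVs, prototype CSVs and
    model checkpoints are persisted there.
    """
    dataset = _load_or_generate(config)
    dataset = _apply_representation(dataset, config.representation,
                                    config.input_size)
    train, test = make_split(dataset, config.train_fraction, seed=config.seed)
    truth = labels_of(test)
    classes = np.unique(labels_of(dataset))

    members: list[MemberResult] = []
    pairs = [(a, kc) for a in config.architectures for kc in config.kc_grid]
    seeds = _member_seeds(config.seed, len(pairs))
    out = config.output_dir
    if out:
        os.makedirs(out, exist_ok=True)

    for (arch_id, kc), seed in zip(pairs, seeds):
        stage = f"member arch={arch_id} kc={kc}"
        try:
            arch = get_architecture(arch_id)
            if config.input_size != arch.input_size or config.width_factor != 1.0:
                arch = scale_architecture(arch, config.input_size,
                                          config.width_factor,
                                          config.embedding_dim)
            options = TrainOptions(learning_rate=config.learning_rate,
                                   iterations=config.iterations,
                                   batch_size=config.batch_size, seed=seed)
            model = train_snn(arch, train, options)
            protos = select_prototypes(train, kc, seed=seed,
                                       side=config.cluster_side,
                                       representation=config.representation)
            design_tr, labels_tr = build_design_matrix(train, protos, model)
            design_te, _ = build_design_matrix(test, protos, model)
            svm = train_ova_svm(design_tr, labels_tr, C=config.svm_c)
            tag = f"nn{arch_id}_kc{kc}_{config.representation}"
            sc_tr = svm.score_matrix(design_tr, source_id=tag + "_train")
            sc_te = svm.score_matrix(design_te, source_id=tag)
            member_acc = evaluate(sc_te, truth, classes).accuracy
            members.append(MemberResult(arch_id, kc, config.representation,
                                        sc_te, sc_tr, member_acc))
            if out:
                protos.save(os.path.join(out, f"prototypes_{tag}.csv"))
                save_design_matrix(os.path.join(out, f"design_{tag}.csv"),
                                   design_te, truth, protos)
                sc_te.save(os.path.join(out, f"scores_{tag}.csv"))
                model.save(os.path.join(out, f"model_{tag}.npz"))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at {stage}: {exc}") from exc

    if config.znorm_members:
        fused = sum_rule([znorm(m.test_scores, m.train_scores) for m in members])
    else:
        fused = sum_rule([m.test_scores for m in members])
    report = evaluate(fused, truth, classes)

    if out:
        with open(os.path.join(out, "report.json"), "w") as fh:
            fh.write(report.to_json())
        log = {"config": asdict(config),
               "member_seeds": seeds,
               "member_accuracies": {f"nn{m.arch_id}_kc{m.kc}": m.accuracy
                                     for m in members}}
        with open(os.path.join(out, "run_log.json"), "w") as fh:
            json.dump(log, fh, indent=2, default=str)
    return report, members
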