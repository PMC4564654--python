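"""Multi-run training studies with run exclusion and reporting.

A study trains ``n_runs`` independently initialized networks on the same
(or per-run regenerated) transposition-augmented corpus, evaluates every
checkpoint on the three test conditions and on the training corpus, and
excludes runs that failed to train: a run is retained only if its final
training agreement reaches ``max(2 x chance, exclusion_threshold)``, where
chance is 1/24. Trajectory summaries average over retained runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .corpus import Corpus, CorpusSpec, augment_by_transposition, generate_corpus
from .encoding import N_KEYS
from .evaluation import (
    TestCondition,
    agreement_trajectory,
    build_test_sets,
    evaluate_trajectory,
    records_to_frame,
)
from .network import TrainingConfig, init_network, train
from .stats import AnovaReport

CHANCE_RATE = 1.0 / N_KEYS


class ExperimentFailureError(RuntimeError):
    """Every run of an experiment was excluded."""


@dataclass(eq=False)
class ExperimentConfig:
    """Configuration of a multi-run study.

    Run ``i`` uses network seed ``base_seed + i`` and an independent shuffle
    stream; with ``shared_corpus`` (default) all runs see the same corpus
    realization, mirroring training on a single fixed set of melodies.
    """

    training: TrainingConfig = field(default_factory=TrainingConfig)
    corpus_spec: CorpusSpec = field(default_factory=CorpusSpec)
    n_runs: int = 10
    base_seed: int = 0
    exclusion_threshold: float = 0.10
    shared_corpus: bool = True
    init_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.exclusion_threshold < 0:
            raise ValueError("exclusion_threshold must be non-negative")


@dataclass(eq=False)
class ExperimentResult:
    """Raw and aggregated outcomes of a study."""

    config: ExperimentConfig
    trajectories: pd.DataFrame  # run_id, epoch, condition, percent_correct, activation
    agreement: pd.DataFrame  # run_id, epoch, agreement
    retained_runs: list[int]
    excluded_runs: list[int]
    final_agreement: dict[int, float]  # per run, percent

    @property
    def retained_trajectories(self) -> pd.DataFrame:
        return self.trajectories[self.trajectories["run_id"].isin(self.retained_runs)]

    def condition_means(self) -> pd.DataFrame:
        """Mean percent correct and activation per condition x epoch over
        retained runs (the quantities plotted as learning curves)."""
        return (
            self.retained_trajectories.groupby(["condition", "epoch"], as_index=False)
            .agg(
                percent_correct=("percent_correct", "mean"),
                percent_correct_sd=("percent_correct", "std"),
                activation=("mean_correct_key_activation", "mean"),
                activation_sd=("mean_correct_key_activation", "std"),
            )
            .sort_values(["condition", "epoch"], ignore_index=True)
        )

    def mean_agreement(self) -> pd.DataFrame:
        kept = self.agreement[self.agreement["run_id"].isin(self.retained_runs)]
        return kept.groupby("epoch", as_index=False).agg(agreement=("agreement", "mean"))


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run, evaluate and filter a multi-run study."""
    test_sets = build_test_sets()
    shared: Corpus | None = None
    if cfg.shared_corpus:
        shared = augment_by_transposition(generate_corpus(cfg.corpus_spec))

    records = []
    agreement_rows = []
    final_agreement: dict[int, float] = {}
    for run in range(cfg.n_runs):
        if shared is not None:
            corpus = shared
        else:
            spec = CorpusSpec(
                **{**_spec_kwargs(cfg.corpus_spec), "seed": cfg.corpus_spec.seed + run}
            )
            corpus = augment_by_transposition(generate_corpus(spec))
        seed = cfg.base_seed + run
        state = init_network(seed, init_scale=cfg.init_scale)
        run_cfg = TrainingConfig(
            n_epochs=cfg.training.n_epochs,
            learning_rate=cfg.training.learning_rate,
            checkpoint_interval=cfg.training.checkpoint_interval,
            shuffle=cfg.training.shuffle,
            seed=cfg.training.seed + run,
            loss=cfg.training.loss,
            target_coding=cfg.training.target_coding,
            include_baseline=cfg.training.include_baseline,
        )
        checkpoints = train(state, corpus, run_cfg)
        records.extend(evaluate_trajectory(checkpoints, test_sets, run_id=run))
        agreement = agreement_trajectory(checkpoints, corpus)
        agreement_rows.extend(
            {"run_id": run, "epoch": e, "agreement": a} for e, a in agreement.items()
        )
        final_agreement[run] = agreement[max(agreement)]

    floor = max(2 * CHANCE_RATE, cfg.exclusion_threshold) * 100.0
    retained = [r for r, a in final_agreement.items() if a >= floor]
    excluded = [r for r in final_agreement if r not in retained]
    if not retained:
        raise ExperimentFailureError(
            f"all {cfg.n_runs} runs fell below the retention floor of {floor:.1f}% "
            f"final training agreement (per-run: {final_agreement})"
        )

    return ExperimentResult(
        config=cfg,
        trajectories=records_to_frame(records),
        agreement=pd.DataFrame(agreement_rows),
        retained_runs=retained,
        excluded_runs=excluded,
        final_agreement=final_agreement,
    )


def _spec_kwargs(spec: CorpusSpec) -> dict:
    return {
        "n_major": spec.n_major,
        "n_minor": spec.n_minor,
        "length_min": spec.length_min,
        "length_max": spec.length_max,
        "profile_major": spec.profile_major,
        "profile_minor": spec.profile_minor,
        "out_of_scale_rate": spec.out_of_scale_rate,
        "seed": spec.seed,
    }


def small_study_config(base_seed: int = 0) -> ExperimentConfig:
    """The package's reduced-scale study: 120 base melodies (106 major + 14
    minor, preserving the 315:41 mode ratio) transposed to 1,440 training
    items, 5 runs of 3,000 epochs with checkpoints every 300 epochs.

    The learning rate is lowered to 1e-4 so that, with roughly a third of
    the items and a seventeenth of the epochs of the full-scale study, the
    learning dynamics still unfold across the 10 checkpoints instead of
    finishing before the first one. Runs on one CPU in a few minutes while
    preserving the qualitative structure of the full-scale study (the
    :class:`ExperimentConfig` defaults: 356 base melodies, 10 runs of
    50,000 epochs).
    """
    return ExperimentConfig(
        training=TrainingConfig(
            n_epochs=3_000,
            learning_rate=1e-4,
            checkpoint_interval=300,
            shuffle=True,
            seed=base_seed,
        ),
        corpus_spec=CorpusSpec(n_major=106, n_minor=14, seed=base_seed),
        n_runs=5,
        base_seed=base_seed,
        exclusion_threshold=0.10,
    )


def report(
    result: ExperimentResult,
    anova_reports: Iterable[AnovaReport],
    outdir: str | Path,
) -> None:
    """Write tidy CSV tables, learning-curve figures and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    result.trajectories.to_csv(outdir / "trajectories.csv", index=False)
    result.agreement.to_csv(outdir / "agreement.csv", index=False)
    result.condition_means().to_csv(outdir / "condition_means.csv", index=False)
    result.mean_agreement().to_csv(outdir / "mean_agreement.csv", index=False)
    for rep in anova_reports:
        rep.anova.to_csv(outdir / f"anova_{rep.dv}.csv", index=False)
        rep.simple_main_effects.to_csv(
            outdir / f"simple_main_effects_{rep.dv}.csv", index=False
        )
        rep.pairwise.to_csv(outdir / f"pairwise_{rep.dv}.csv", index=False)

    _plot_curves(result, outdir)

    manifest = {
        "n_runs": result.config.n_runs,
        "base_seed": result.config.base_seed,
        "corpus_seed": result.config.corpus_spec.seed,
        "n_epochs": result.config.training.n_epochs,
        "checkpoint_interval": result.config.training.checkpoint_interval,
        "learning_rate": result.config.training.learning_rate,
        "exclusion_threshold": result.config.exclusion_threshold,
        "retained_runs": result.retained_runs,
        "excluded_runs": result.excluded_runs,
        "final_agreement": result.final_agreement,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _plot_curves(result: ExperimentResult, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = result.condition_means()
    labels = {
        TestCondition.IN_SCALE_REGULAR.value: "in-scale / regular harmony",
        TestCondition.IN_SCALE_IRREGULAR.value: "in-scale / irregular harmony",
        TestCondition.OUT_OF_SCALE_IRREGULAR.value: "out-of-scale / irregular harmony",
    }

    for column, ylabel, fname in (
        ("percent_correct", "correct key identification (%)", "percent_correct.png"),
        ("activation", "normalized C-major activation", "activation.png"),
    ):
        fig, ax = plt.subplots(figsize=(6, 4))
        for cond, label in labels.items():
            sub = means[means["condition"] == cond]
            ax.plot(sub["epoch"], sub[column], marker="o", label=label)
        ax.set_xlabel("training epoch")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / fname, dpi=150)
        plt.close(fig)

    agg = result.mean_agreement()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(agg["epoch"], agg["agreement"], marker="o", color="k")
    ax.set_xlabel("training epoch")
    ax.set_ylabel("training agreement (%)")
    fig.tight_layout()
    fig.savefig(outdir / "agreement.png", dpi=150)
    plt.close(fig)
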