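"""End-to-end pipeline driver and figure/table generation.

``run_pipeline`` ties the stages together on one cohort: ROC screen of
candidate predictors, likelihood-ratio table, sequential-model fitting,
evaluation of every non-empty combination of assessment groups,
per-case probability trajectories, trajectory plots split by outcome,
and a run log (seed, package versions, exclusions).  All tabular output
is CSV (full precision plus rounded display columns), model and
evaluation objects are JSON, and a fixed seed makes repeated runs
byte-identical.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bayes import BayesModel, CaseTrajectory
from .evaluation import bootstrap_sens_at_spec, evaluate_model
from .metrics import PredictorSpec
from .model import BayesChainClassifier, candidate_specs_from_cohort_spec
from .synthetic import Cohort, CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "plot_trajectories"]

logger = logging.getLogger("uhrbayes")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one cohort source must be given: a CSV path
    (``cohort_csv``) or a synthetic generating spec (``cohort_spec``).
    """

    output_dir: str
    cohort_csv: str | None = None
    cohort_spec: CohortSpec | None = None
    candidate_specs: list[PredictorSpec] | None = None
    grouping: list[tuple[str, list[str]]] | None = None
    alpha: float = 0.05
    pretest_probability: float | None = None
    bootstrap_iterations: int = 1000
    fixed_specificity: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.cohort_spec is None):
            raise ValueError("exactly one cohort source (cohort_csv or cohort_spec) is required")


def plot_trajectories(
    trajectories: list[CaseTrajectory],
    outcome,
    model_threshold: float | None = None,
    path=None,
):
    """Stepwise probability-of-transition plot, one panel per outcome class.

    x axis: assessment stage; y axis: probability of transition; the
    model's probability threshold, when given, is a horizontal line.
    Excluded cases are omitted.
    """
    kept = [(t, y) for t, y in zip(trajectories, outcome) if not t.excluded]
    if not kept:
        raise ValueError("no non-excluded trajectories to plot")
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    titles = {0: "Not transitioned", 1: "Transitioned"}
    stages = [s for s, _ in kept[0][0].probabilities]
    for ax, cls in zip(axes, (0, 1)):
        for traj, y in kept:
            if y != cls:
                continue
            labels, probs = zip(*traj.probabilities)
            ax.plot(range(len(probs)), probs, marker="o", alpha=0.6, lw=1)
        if model_threshold is not None:
            ax.axhline(model_threshold, color="k", ls="--", lw=1, label="model threshold")
            ax.legend(loc="upper left", fontsize=8)
        ax.set_xticks(range(len(stages)))
        ax.set_xticklabels(stages, rotation=20)
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(titles[cls])
        ax.set_xlabel("assessment stage")
    axes[0].set_ylabel("probability of transition")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def _group_subset_posteriors(model: BayesModel, clf: BayesChainClassifier, frame: pd.DataFrame, groups):
    """Posteriors from the sub-model restricted to ``groups``, on cases
    complete for that subset's predictors."""
    grouping = [(g, names) for g, names in model.grouping if g in groups]
    names = [n for _, ns in grouping for n in ns]
    sub = BayesModel(
        pretest_probability=model.pretest_probability,
        lr_table={n: model.lr_table[n] for n in names},
        grouping=grouping,
        predictor_specs=[s for s in model.predictor_specs if s.name in names],
    )
    complete = ~frame[names].isna().any(axis=1)
    idx = np.flatnonzero(complete.to_numpy())
    posts = []
    for i in idx:
        calls = clf._calls_row(frame.iloc[i])
        posts.append(sub.posterior({n: calls[n] for n in names}))
    return np.array(posts), idx


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full staged-model pipeline; returns {artifact: path}."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    stderr = logging.StreamHandler(sys.stderr)
    logger.setLevel(config.log_level.upper())
    logger.addHandler(handler)
    logger.addHandler(stderr)
    paths: dict[str, Path] = {"run_log": log_path}
    try:
        import uhrbayes

        logger.info("uhrbayes %s | numpy %s | pandas %s | seed %d",
                    uhrbayes.__version__, np.__version__, pd.__version__, config.seed)

        # --- cohort ---------------------------------------------------
        if config.cohort_csv is not None:
            cohort = Cohort.from_csv(config.cohort_csv)
            logger.info("loaded cohort from %s (n=%d)", config.cohort_csv, cohort.n_subjects)
        else:
            spec = config.cohort_spec
            if spec.seed != config.seed:
                import dataclasses as _dc

                spec = _dc.replace(spec, seed=config.seed)
            cohort = generate_cohort(spec)
            logger.info("generated synthetic cohort (n=%d, prevalence=%.3f)",
                        spec.n_subjects, spec.prevalence)
            cohort_path = outdir / "cohort.csv"
            cohort.to_csv(cohort_path)
            paths["cohort"] = cohort_path

        candidates = config.candidate_specs
        if candidates is None and cohort.spec is not None:
            candidates = candidate_specs_from_cohort_spec(cohort.spec)

        # --- whole-case exclusions (all predictors missing) ------------
        frame = cohort.values.copy()
        frame.index = pd.Index(cohort.subject_ids, name="subject_id")

        # --- fit -------------------------------------------------------
        clf = BayesChainClassifier(
            candidate_specs=candidates,
            grouping=config.grouping,
            alpha=config.alpha,
            pretest_probability=config.pretest_probability,
        )
        clf.fit(cohort.values, cohort.outcome)
        model = clf.model_
        logger.info("retained %d of %d candidate predictors at alpha=%g",
                    len(model.predictor_names), len(clf.screen_), config.alpha)

        screen_path = outdir / "roc_screen.csv"
        clf.screen_.to_csv(screen_path, index=False)
        paths["roc_screen"] = screen_path

        # --- likelihood-ratio table -------------------------------------
        lr_rows = []
        for spec_ in clf.specs_:
            perf = clf.performance_[spec_.name]
            lr_rows.append(
                {
                    "group": spec_.group,
                    "predictor": spec_.name,
                    "sensitivity_pct": 100.0 * perf.sensitivity,
                    "specificity_pct": 100.0 * perf.specificity,
                    "lr_pos": perf.lr_pos,
                    "lr_neg": perf.lr_neg,
                    "lr_pos_display": round(perf.lr_pos, 2),
                    "lr_neg_display": round(perf.lr_neg, 2),
                }
            )
        lr_path = outdir / "likelihood_ratios.csv"
        pd.DataFrame(lr_rows).to_csv(lr_path, index=False)
        paths["likelihood_ratios"] = lr_path

        # --- trajectories and exclusions --------------------------------
        trajectories = clf.trajectories(frame)
        traj_rows, excluded = [], []
        for traj, y in zip(trajectories, cohort.outcome):
            if traj.excluded:
                excluded.append({"subject_id": traj.subject_id, "reason": traj.exclusion_reason})
                continue
            for stage, prob in traj.probabilities:
                traj_rows.append(
                    {
                        "subject_id": traj.subject_id,
                        "stage": stage,
                        "probability": prob,
                        "transition": int(y),
                    }
                )
        traj_path = outdir / "trajectories.csv"
        pd.DataFrame(traj_rows).to_csv(traj_path, index=False)
        paths["trajectories"] = traj_path
        excl_path = outdir / "exclusions.csv"
        pd.DataFrame(excluded, columns=["subject_id", "reason"]).to_csv(excl_path, index=False)
        paths["exclusions"] = excl_path
        for row in excluded:
            logger.info("excluded %s (%s)", row["subject_id"], row["reason"])
        logger.info("analyzed n=%d of %d subjects", cohort.n_subjects - len(excluded),
                    cohort.n_subjects)

        # --- model serialization ----------------------------------------
        model_path = outdir / "model.json"
        model.to_json(model_path)
        paths["model"] = model_path

        # --- evaluation: every non-empty group combination --------------
        group_names = [g for g, _ in model.grouping]
        eval_rows, eval_payload = [], {}
        full_eval = None
        for r in range(1, len(group_names) + 1):
            for combo in itertools.combinations(group_names, r):
                posts, idx = _group_subset_posteriors(model, clf, frame, combo)
                ev = evaluate_model(posts, cohort.outcome[idx],
                                    prevalence=model.pretest_probability)
                label = "+".join(combo)
                row = {"model": label, "n": len(idx), **ev.to_dict()}
                eval_rows.append(row)
                eval_payload[label] = row
                if len(combo) == len(group_names):
                    full_eval = (ev, posts, idx)
        eval_csv = outdir / "model_evaluation.csv"
        pd.DataFrame(eval_rows).to_csv(eval_csv, index=False)
        paths["model_evaluation"] = eval_csv

        # --- bootstrap internal validation of the full model -------------
        ev, posts, idx = full_eval
        fixed_spec = (
            config.fixed_specificity if config.fixed_specificity is not None else ev.specificity
        )
        ci = bootstrap_sens_at_spec(
            posts, cohort.outcome[idx], fixed_spec,
            n_iterations=config.bootstrap_iterations, seed=config.seed,
        )
        eval_payload["bootstrap"] = {
            "statistic": ci.statistic,
            "point": ci.point,
            "lower": ci.lower,
            "upper": ci.upper,
            "n_iterations": ci.n_iterations,
            "method": ci.method,
            "seed": ci.seed,
        }
        eval_json = outdir / "evaluation.json"
        with open(eval_json, "w") as fh:
            json.dump(eval_payload, fh, indent=2)
        paths["evaluation_json"] = eval_json

        # --- figures ------------------------------------------------------
        fig_path = outdir / "trajectories.png"
        plot_trajectories(trajectories, cohort.outcome,
                          model_threshold=ev.threshold_probability, path=fig_path)
        paths["trajectory_plot"] = fig_path
        logger.info("full model: AUROC=%.3f sens=%.1f%% spec=%.1f%% threshold=%.4f",
                    ev.roc.auroc, 100 * ev.sensitivity, 100 * ev.specificity,
                    ev.threshold_probability)
    finally:
        logger.removeHandler(handler)
        logger.removeHandler(stderr)
        handler.close()
    return {k: str(v) for k, v in paths.items()}
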