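"""The four-step transfer procedure and its experiment harness.

Given a labeled source cohort and an unlabeled target cohort the
procedure is: (1) embed the indicator matrices (PCA, shared or separate
spaces), (2) train a linear model h* on the source embedding, (3) solve
unbalanced entropic OT from the target embedding onto the source
embedding and barycentric-project the target points, (4) apply h* to the
transported points to obtain projected target outcomes.  The plan's rows
always index target points; masses are uniform per cohort.

The harness repeats the experiment on independent subsamples (default:
120 source admissions for training, 100 target admissions for testing,
100 repeats, k = 50 embedding dimensions), refitting the embedding and
model each repeat, and also evaluates a no-transfer baseline (h* applied
to the un-transported target embedding) in the shared-space scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .embedding import (
    Cohort,
    EmbeddingMap,
    align_vocabulary,
    apply_embedding,
    fit_embedding,
    plan_spaces,
)
from .ot import (
    DiscreteMeasure,
    OTConfig,
    TransportPlan,
    barycentric_projection,
    build_cost_matrix,
    solve_ugw,
    solve_unbalanced_ot,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LinearModel",
    "ExperimentConfig",
    "TransferResult",
    "train_source_model",
    "run_ottehr",
    "evaluate",
    "run_repeated_experiment",
    "shift_test",
]


@dataclass
class LinearModel:
    """A linear predictor with an extractable Lipschitz constant.

    For regression the prediction is the affine score w.x + b.  For
    binary classification the score is passed through a logistic link
    and thresholded at probability 0.5 (equivalently, score at 0).
    """

    weights: np.ndarray
    intercept: float
    task: str = "regression"

    def decision(self, Z: np.ndarray) -> np.ndarray:
        """Raw affine score w.x + b."""
        return np.asarray(Z, dtype=float) @ self.weights + self.intercept

    def predict(self, Z: np.ndarray) -> np.ndarray:
        score = self.decision(Z)
        if self.task == "binary_classification":
            return (score >= 0).astype(float)
        return score


@dataclass
class ExperimentConfig:
    """Sampling protocol and OT hyperparameters for repeated experiments."""

    n_source_train: int = 120
    n_target_test: int = 100
    n_repeats: int = 100
    k_override: int | None = 50
    variance_target: float = 0.75
    task: str = "regression"
    ot: OTConfig = field(default_factory=OTConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_source_train", "n_target_test", "n_repeats"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TransferResult:
    """Projected target outcomes plus everything needed for the bound."""

    predicted: np.ndarray
    observed: np.ndarray
    mae: float
    rmse: float
    skipped_zero_mass: int
    plan: TransportPlan
    model: LinearModel
    source_embedding: np.ndarray
    target_embedding: np.ndarray
    transported: np.ndarray
    target_mass: np.ndarray
    source_mass: np.ndarray
    valid_rows: np.ndarray
    scenario: str


def train_source_model(
    Z_S: np.ndarray, Y_S: np.ndarray, task: str = "regression"
) -> LinearModel:
    """Fit h* on the source embedding: OLS for regression, logistic otherwise.

    Rank-deficient designs fall back to the minimum-norm least-squares
    solution with a logged warning; the fit is deterministic.
    """
    Z_S = np.atleast_2d(np.asarray(Z_S, dtype=float))
    Y_S = np.asarray(Y_S, dtype=float).ravel()
    if Z_S.shape[0] != Y_S.shape[0]:
        raise ValueError("row counts of Z_S and Y_S differ")
    if task == "regression":
        design = np.column_stack([Z_S, np.ones(Z_S.shape[0])])
        coef, _, rank, _ = np.linalg.lstsq(design, Y_S, rcond=None)
        if rank < design.shape[1]:
            logger.warning(
                "rank-deficient design (rank %d < %d); minimum-norm solution used",
                rank, design.shape[1],
            )
        return LinearModel(weights=coef[:-1], intercept=float(coef[-1]), task=task)
    if task == "binary_classification":
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        clf.fit(Z_S, Y_S.astype(int))
        return LinearModel(
            weights=clf.coef_.ravel(), intercept=float(clf.intercept_[0]), task=task
        )
    raise ValueError(f"unknown task: {task!r}")


def _identity_embedding(q: int, group: str) -> EmbeddingMap:
    # degenerate fallback: PCA is undefined on a single admission
    return EmbeddingMap(
        components=np.eye(q),
        center=np.zeros(q),
        explained_variance_ratio=np.full(q, 1.0 / q),
        k=q,
        fitted_on=group,
    )


def run_ottehr(
    source: Cohort, target: Cohort, config: ExperimentConfig
) -> TransferResult:
    """Run the four-step procedure once on full cohorts.

    The transported side is the target (plan rows index target points);
    barycentric projection maps target embeddings into the source
    embedding domain and the source model predicts there.
    """
    scenario = plan_spaces(source, target)
    if scenario == "shared" and target.code_vocabulary != source.code_vocabulary:
        target = align_vocabulary(target, source.code_vocabulary)

    if source.n_admissions < 2:
        logger.warning("single-admission source: identity embedding used")
        g_s = _identity_embedding(source.n_codes, source.group)
    else:
        k_eff = config.k_override
        if k_eff is not None:
            k_eff = min(k_eff, source.n_admissions, source.n_codes)
        g_s = fit_embedding(source, config.variance_target, k_eff)
    z_s = apply_embedding(g_s, source)

    if scenario == "shared":
        z_t = apply_embedding(g_s, target)
    else:
        if target.n_admissions < 2:
            raise ValueError("separate-space scenario needs >= 2 target admissions")
        k_eff_t = config.k_override
        if k_eff_t is not None:
            k_eff_t = min(k_eff_t, target.n_admissions, target.n_codes)
        g_t = fit_embedding(target, config.variance_target, k_eff_t)
        z_t = apply_embedding(g_t, target)

    model = train_source_model(z_s, source.outcomes, config.task)

    mu_t = DiscreteMeasure.uniform(z_t)     # transported side (plan rows)
    mu_s = DiscreteMeasure.uniform(z_s)
    if scenario == "shared":
        cost = build_cost_matrix(mu_t, mu_s, config.ot)
        plan = solve_unbalanced_ot(mu_t, mu_s, cost, config.ot)
    else:
        plan = solve_ugw(mu_t, mu_s, config.ot)

    transported = barycentric_projection(plan, mu_s)
    valid = ~np.isnan(transported).any(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.warning("%d target points skipped (zero transported mass)", n_skipped)
    if not valid.any():
        raise ValueError("empty transported set")

    predicted = model.predict(transported[valid])
    observed = target.outcomes[valid]
    mae, rmse = evaluate(predicted, observed)
    return TransferResult(
        predicted=predicted,
        observed=observed,
        mae=mae,
        rmse=rmse,
        skipped_zero_mass=n_skipped,
        plan=plan,
        model=model,
        source_embedding=z_s,
        target_embedding=z_t,
        transported=transported,
        target_mass=mu_t.mass,
        source_mass=mu_s.mass,
        valid_rows=valid,
        scenario=scenario,
    )


def evaluate(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """Mean absolute error and root mean squared error."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed lengths differ")
    if predicted.size == 0:
        raise ValueError("cannot evaluate empty vectors")
    diff = predicted - observed
    return float(np.mean(np.abs(diff))), float(np.sqrt(np.mean(diff**2)))


def run_repeated_experiment(
    source: Cohort,
    target: Cohort,
    config: ExperimentConfig,
    truth=None,
) -> pd.DataFrame:
    """Repeat the subsampled experiment; one row of metrics per repeat.

    Repeat r draws independent subsamples with seed ``config.seed + r``,
    refits the embedding and model, runs the transfer and the
    generalization-bound computation, and (shared scenario) the
    no-transfer baseline.  ``truth`` may supply exact labeling functions
    (synthetic mode); otherwise f_S is taken to be h* itself and f_T is
    refit on target labels (estimate mode).
    """
    from .bound import compute_bound

    if config.n_source_train > source.n_admissions:
        raise ValueError(
            f"n_source_train={config.n_source_train} exceeds source size "
            f"{source.n_admissions}"
        )
    if config.n_target_test > target.n_admissions:
        raise ValueError(
            f"n_target_test={config.n_target_test} exceeds target size "
            f"{target.n_admissions}"
        )

    rows = []
    for r in range(config.n_repeats):
        seed_r = config.seed + r
        rng = np.random.default_rng(seed_r)
        src_sub, _ = source.subsample(config.n_source_train, rng)
        tgt_sub, _ = target.subsample(config.n_target_test, rng)
        result = run_ottehr(src_sub, tgt_sub, config)

        if truth is not None:
            f_s_vals = truth.f_source(tgt_sub.features)
            f_t_vals = truth.f_target(tgt_sub.features)
        else:
            f_s_vals = result.model.predict(result.target_embedding)
            f_t_model = train_source_model(
                result.target_embedding, tgt_sub.outcomes, config.task
            )
            f_t_vals = f_t_model.predict(result.target_embedding)
        report = compute_bound(result, f_s_vals, f_t_vals)

        row = {
            "repeat": r,
            "seed": seed_r,
            "scenario": result.scenario,
            "k": result.source_embedding.shape[1],
            "mae": result.mae,
            "rmse": result.rmse,
            "log_mae": float(np.log(result.mae)) if result.mae > 0 else -np.inf,
            "log_rmse": float(np.log(result.rmse)) if result.rmse > 0 else -np.inf,
            "skipped_zero_mass": result.skipped_zero_mass,
            "converged": result.plan.converged,
        }
        if result.scenario == "shared":
            base_pred = result.model.predict(result.target_embedding)
            base_mae, base_rmse = evaluate(base_pred, tgt_sub.outcomes)
            row["baseline_mae"] = base_mae
            row["baseline_rmse"] = base_rmse
        row.update(report.as_dict())
        rows.append(row)
        logger.info(
            "repeat=%d seed=%d k=%d converged=%s skipped=%d mae=%.4g rmse=%.4g",
            r, seed_r, row["k"], row["converged"],
            row["skipped_zero_mass"], result.mae, result.rmse,
        )
    return pd.DataFrame(rows)


def shift_test(
    source: Cohort, target: Cohort, k_override: int | None = None
) -> np.ndarray:
    """Per-dimension two-sided Mann-Whitney U tests on shared embeddings.

    Validates the presence of covariate shift between the groups: small
    p-values (conventionally < .05) on a dimension indicate a
    significant distributional difference there.  Dimensions constant on
    both sides get p = 1.
    """
    if plan_spaces(source, target) != "shared":
        raise ValueError("shift_test requires the shared-space scenario")
    if source.n_admissions < 3 or target.n_admissions < 3:
        raise ValueError("shift_test needs at least 3 admissions per side")
    if target.code_vocabulary != source.code_vocabulary:
        target = align_vocabulary(target, source.code_vocabulary)
    g_s = fit_embedding(source, k_override=k_override)
    z_s = apply_embedding(g_s, source)
    z_t = apply_embedding(g_s, target)
    pvals = np.ones(z_s.shape[1])
    for d in range(z_s.shape[1]):
        a, b = z_s[:, d], z_t[:, d]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            continue
        pvals[d] = mannwhitneyu(a, b, alternative="two-sided").pvalue
    return pvals
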