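"""End-to-end hyperparameter campaigns and the printed-table reproduction.

Two campaign styles are offered over the same dataset and split plan:

* :func:`run_rsm_campaign` — the design-of-experiments route: build a
  face-centered CCD over (neurons, learning rate, momentum, epochs) crossed
  with the training algorithm, score every design row by cross-validated MSE,
  fit the coded quadratic surface to ln(MSECV), run the ANOVA, locate the
  surface optimum, and retrain/test the selected configuration. 60 evaluated
  configurations for the reference factor space.
* :func:`run_conventional_campaign` — the one-variable-at-a-time baseline:
  sweep neurons with the other settings at grid midpoints, fix the best, then
  sweep learning rate, momentum and epochs in turn. 60 evaluations per
  algorithm.

:func:`fit_reference_tables` reruns the surface fit on the packaged 60-run
reference design (factor levels with measured cross-validation responses) and
reports reproduced coefficients, ANOVA statistics and per-run predictions
side by side with the published values.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doe import DesignMatrix, DesignSpec, FactorSpec, build_ccd, read_design
from .neural_net import (
    TrainConfig,
    corr_coeff,
    fit_normalization,
    forward,
    init_network,
    mse,
    normalize,
    train,
)
from .rsm import SurfaceModel, AnovaTable, TransformSpec, anova, find_optimum, fit_quadratic, predict
from .synthetic_smbr import FiltrationDataset
from .validation import SplitPlan, evaluate_config, make_split

__all__ = [
    "CampaignReport",
    "SweepSpec",
    "reference_design_spec",
    "load_reference_design",
    "run_rsm_campaign",
    "run_conventional_campaign",
    "compare_methods",
    "fit_reference_tables",
]

REFERENCE_DESIGN_RESOURCE = "ccd_flux_60run.csv"
REFERENCE_VALUES_RESOURCE = "reference_values.json"
REFERENCE_DESIGN_SHA256 = "e6bda0883395d812143267eba95fcf4b6353a2418d5494c1efd16034e1439e0c"

ALGORITHM_LEVELS = ("trainlm", "traingdm")
_LEVEL_TO_ALG = {"trainlm": "lm", "traingdm": "gdm"}


def reference_design_spec() -> DesignSpec:
    """The study factor space: four numeric training parameters plus the
    two-level training-function factor, face-centered (alpha=1), six center
    replicates per algorithm."""
    return DesignSpec(
        numeric_factors=(
            FactorSpec("neurons", low=1, high=31, integer=True),
            FactorSpec("learning_rate", low=0.01, high=0.31),
            FactorSpec("momentum", low=0.6, high=0.9),
            FactorSpec("epochs", low=700, high=1000, integer=True),
        ),
        categorical_factors=(
            FactorSpec("train_function", kind="categorical", levels=ALGORITHM_LEVELS),
        ),
        alpha=1.0,
        n_center=6,
    )


def _data_path(resource: str):
    return importlib.resources.files("rsmtune").joinpath("data", resource)


def load_reference_design(verify_checksum: bool = True) -> DesignMatrix:
    """Load the packaged 60-run reference design with its measured responses."""
    path = _data_path(REFERENCE_DESIGN_RESOURCE)
    raw = path.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != REFERENCE_DESIGN_SHA256:
            raise ValueError(
                f"reference design fixture checksum mismatch: {digest}"
            )
    import io

    return read_design(io.BytesIO(raw), reference_design_spec(), response_column="msecv")


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()[:16]


@dataclass
class CampaignReport:
    """Everything one campaign produced: the evaluation log, the selection,
    and the final train/test metrics, all recomputable from the echoed seeds."""

    method: str
    seed: int
    dataset_fingerprint: str
    cv_log: pd.DataFrame           # one row per evaluated configuration
    selected: TrainConfig
    train_mse: float
    train_r: float
    test_mse: float
    test_r: float
    wall_time_s: float
    n_evaluations: int
    epoch_scale: float = 1.0
    design: DesignMatrix | None = None
    surface: SurfaceModel | None = None
    anova_table: AnovaTable | None = None
    optimum: dict | None = None

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "seed": self.seed,
            "dataset_fingerprint": self.dataset_fingerprint,
            "n_evaluations": self.n_evaluations,
            "epoch_scale": self.epoch_scale,
            "selected": {
                "n_hidden": self.selected.n_hidden,
                "learning_rate": self.selected.learning_rate,
                "momentum": self.selected.momentum,
                "epochs": self.selected.epochs,
                "algorithm": self.selected.algorithm,
            },
            "train_mse": self.train_mse,
            "train_r": self.train_r,
            "test_mse": self.test_mse,
            "test_r": self.test_r,
            "wall_time_s": self.wall_time_s,
            "cv_log": self.cv_log.to_dict(orient="records"),
        }
        if self.optimum is not None:
            payload["optimum"] = self.optimum
        if self.anova_table is not None:
            payload["anova"] = json.loads(self.anova_table.to_json())
        return json.dumps(payload, default=float)


def _config_from_row(row: pd.Series, seed: int) -> TrainConfig:
    # each design row gets its own training seed so replicate center runs
    # carry genuine run-to-run variation (the source of pure error)
    return TrainConfig(
        n_hidden=int(round(row["neurons"])),
        learning_rate=float(row["learning_rate"]),
        momentum=float(row["momentum"]),
        epochs=int(round(row["epochs"])),
        algorithm=_LEVEL_TO_ALG[row["train_function"]],
        seed=(seed * 100003 + int(row["run"])) % (2 ** 31),
    )


def _final_fit(config: TrainConfig, X, y, plan: SplitPlan, epoch_scale: float):
    """Retrain the selected configuration on the full training split and score
    it on both splits (normalized scale)."""
    tr, te = plan.train_indices, plan.test_indices
    xn = fit_normalization(X[tr])
    yn = fit_normalization(y[tr])
    Xtr, ytr = normalize(X[tr], xn), normalize(y[tr], yn)
    Xte, yte = normalize(X[te], xn), normalize(y[te], yn)
    scaled = TrainConfig(
        n_hidden=config.n_hidden,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        epochs=max(1, int(round(config.epochs * epoch_scale))),
        algorithm=config.algorithm,
        seed=config.seed,
    )
    net = init_network(X.shape[1], scaled)
    trained, _ = train(net, Xtr, ytr, scaled)
    yhat_tr = forward(trained, Xtr)
    yhat_te = forward(trained, Xte)
    return (
        mse(ytr, yhat_tr),
        corr_coeff(ytr, yhat_tr),
        mse(yte, yhat_te),
        corr_coeff(yte, yhat_te),
        trained,
    )


def run_rsm_campaign(
    data: FiltrationDataset,
    spec: DesignSpec | None = None,
    seed: int = 0,
    plan: SplitPlan | None = None,
    transform: TransformSpec = TransformSpec(0.0),
    epoch_scale: float = 1.0,
    response_ceiling: float = 1e3,
) -> CampaignReport:
    """Execute the full design-of-experiments campaign on a filtration dataset.

    Steps: split the data, build the CCD, score each design row by 3-fold
    cross-validated MSE, fit the coded quadratic to the transformed response,
    run the ANOVA, minimize the fitted surface, and retrain/test the decoded
    optimum. ``epoch_scale`` proportionally reduces every configured epoch
    budget so a whole campaign can run at small computational scale.

    Gradient-descent runs can blow up at aggressive learning-rate/momentum
    corners of the design; their cross-validated MSE is then astronomically
    large (or infinite) on the normalized scale, which would let a handful of
    runs dominate the log-scale fit. Responses are therefore capped at
    ``response_ceiling`` — far above any converged normalized MSE — and capped
    rows are flagged in the evaluation log.
    """
    t0 = _time.perf_counter()
    spec = spec or reference_design_spec()
    X, y = data.inputs, data.flux
    plan = plan or make_split(len(y), 0.6, 3, seed)
    design = build_ccd(spec)

    log_rows = []
    responses = []
    for _, row in design.table.iterrows():
        config = _config_from_row(row, seed)
        result = evaluate_config(config, X, y, plan, epoch_scale=epoch_scale)
        responses.append(result.mean_mse)
        log_rows.append(
            {
                "run": int(row["run"]),
                "space_type": row["space_type"],
                "neurons": config.n_hidden,
                "learning_rate": config.learning_rate,
                "momentum": config.momentum,
                "epochs": config.epochs,
                "train_function": row["train_function"],
                **{f"fold{i+1}_mse": m for i, m in enumerate(result.fold_mse)},
                "mean_msecv": result.mean_mse,
            }
        )
    cv_log = pd.DataFrame(log_rows)

    responses = np.asarray(responses)
    capped = ~(responses < response_ceiling)  # catches inf and NaN too
    if capped.any():
        cv_log["capped"] = capped
        responses = np.where(capped, response_ceiling, responses)

    fitted_design = design.with_responses(responses)
    surface = fit_quadratic(fitted_design, transform)
    table = anova(surface, fitted_design)
    best, per_level = find_optimum(surface, goal="minimize")

    selected = TrainConfig(
        n_hidden=int(round(best["actual"]["neurons"])),
        learning_rate=float(best["actual"]["learning_rate"]),
        momentum=float(best["actual"]["momentum"]),
        epochs=int(round(best["actual"]["epochs"])),
        algorithm=_LEVEL_TO_ALG[best["categorical"]["train_function"]],
        seed=seed,
    )
    tr_mse, tr_r, te_mse, te_r, _net = _final_fit(selected, X, y, plan, epoch_scale)

    return CampaignReport(
        method="rsm",
        seed=seed,
        dataset_fingerprint=_fingerprint(X, y),
        cv_log=cv_log,
        selected=selected,
        train_mse=tr_mse,
        train_r=tr_r,
        test_mse=te_mse,
        test_r=te_r,
        wall_time_s=_time.perf_counter() - t0,
        n_evaluations=len(cv_log),
        epoch_scale=epoch_scale,
        design=fitted_design,
        surface=surface,
        anova_table=table,
        optimum={"best": best, "per_level": per_level},
    )


@dataclass(frozen=True)
class SweepSpec:
    """One-variable-at-a-time sweep grids and the stage defaults.

    Stages run in order neurons -> learning rate -> momentum -> epochs; each
    stage holds the not-yet-swept parameters at the listed defaults and the
    already-swept ones at their selected values. The momentum grid stops at
    0.95 because a unit momentum makes the update non-contractive.
    """

    neurons: tuple[int, ...] = tuple(range(1, 31))
    learning_rates: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))
    momenta: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10)) + (0.95,)
    epoch_grid: tuple[int, ...] = tuple(range(100, 1001, 100))
    default_learning_rate: float = 0.5
    default_momentum: float = 0.5
    default_epochs: int = 500

    @property
    def n_evaluations(self) -> int:
        return (
            len(self.neurons) + len(self.learning_rates) + len(self.momenta) + len(self.epoch_grid)
        )


def run_conventional_campaign(
    data: FiltrationDataset,
    algorithm: str,
    sweep: SweepSpec | None = None,
    seed: int = 0,
    plan: SplitPlan | None = None,
    epoch_scale: float = 1.0,
) -> CampaignReport:
    """One-variable-at-a-time baseline for a single training algorithm.

    Each stage selects the grid value with the minimum mean cross-validated
    MSE (ties break to the earlier grid point) and fixes it for later stages.
    """
    if algorithm not in ("lm", "gdm"):
        raise ValueError("algorithm must be 'lm' or 'gdm'")
    t0 = _time.perf_counter()
    sweep = sweep or SweepSpec()
    X, y = data.inputs, data.flux
    plan = plan or make_split(len(y), 0.6, 3, seed)

    current = {
        "n_hidden": None,
        "learning_rate": sweep.default_learning_rate,
        "momentum": sweep.default_momentum,
        "epochs": sweep.default_epochs,
    }
    stages = [
        ("neurons", "n_hidden", sweep.neurons),
        ("learning_rate", "learning_rate", sweep.learning_rates),
        ("momentum", "momentum", sweep.momenta),
        ("epochs", "epochs", sweep.epoch_grid),
    ]
    log_rows = []
    for stage_name, key, grid in stages:
        best_val, best_mse = None, np.inf
        for value in grid:
            settings = dict(current)
            settings[key] = value
            if settings["n_hidden"] is None:
                settings["n_hidden"] = value if key == "n_hidden" else sweep.neurons[0]
            config = TrainConfig(
                n_hidden=int(settings["n_hidden"]),
                learning_rate=float(settings["learning_rate"]),
                momentum=float(settings["momentum"]),
                epochs=int(settings["epochs"]),
                algorithm=algorithm,
                seed=seed,
            )
            result = evaluate_config(config, X, y, plan, epoch_scale=epoch_scale)
            log_rows.append(
                {
                    "stage": stage_name,
                    "value": value,
                    "neurons": config.n_hidden,
                    "learning_rate": config.learning_rate,
                    "momentum": config.momentum,
                    "epochs": config.epochs,
                    **{f"fold{i+1}_mse": m for i, m in enumerate(result.fold_mse)},
                    "mean_msecv": result.mean_mse,
                }
            )
            if result.mean_mse < best_mse:
                best_val, best_mse = value, result.mean_mse
        current[key] = best_val
    cv_log = pd.DataFrame(log_rows)

    selected = TrainConfig(
        n_hidden=int(current["n_hidden"]),
        learning_rate=float(current["learning_rate"]),
        momentum=float(current["momentum"]),
        epochs=int(current["epochs"]),
        algorithm=algorithm,
        seed=seed,
    )
    tr_mse, tr_r, te_mse, te_r, _net = _final_fit(selected, X, y, plan, epoch_scale)
    return CampaignReport(
        method=f"conventional-{algorithm}",
        seed=seed,
        dataset_fingerprint=_fingerprint(X, y),
        cv_log=cv_log,
        selected=selected,
        train_mse=tr_mse,
        train_r=tr_r,
        test_mse=te_mse,
        test_r=te_r,
        wall_time_s=_time.perf_counter() - t0,
        n_evaluations=len(cv_log),
        epoch_scale=epoch_scale,
    )


def compare_methods(*reports: CampaignReport) -> dict:
    """Side-by-side comparison of campaign reports on the same dataset.

    Returns a dict with a per-method metric table and, when both an RSM and
    conventional campaigns are present, the repetition-reduction fraction
    (conventional total − RSM total) / conventional total.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    fps = {r.dataset_fingerprint for r in reports}
    if len(fps) > 1:
        raise ValueError("reports were produced on different datasets")
    table = pd.DataFrame(
        [
            {
                "method": r.method,
                "n_evaluations": r.n_evaluations,
                "train_mse": r.train_mse,
                "train_r": r.train_r,
                "test_mse": r.test_mse,
                "test_r": r.test_r,
                "wall_time_s": r.wall_time_s,
            }
            for r in reports
        ]
    )
    out = {"table": table}
    rsm_total = sum(r.n_evaluations for r in reports if r.method == "rsm")
    conv_total = sum(r.n_evaluations for r in reports if r.method.startswith("conventional"))
    if rsm_total and conv_total:
        out["rsm_evaluations"] = rsm_total
        out["conventional_evaluations"] = conv_total
        out["repetition_reduction"] = (conv_total - rsm_total) / conv_total
    return out


def fit_reference_tables(
    design: DesignMatrix | None = None, prediction_tolerance: float = 0.02
) -> dict:
    """Reproduce the published surface fit on the packaged 60-run design.

    Fits the coded quadratic to ln(response), runs the ANOVA, predicts every
    run, and lays the reproduced values alongside the published coefficients,
    ANOVA statistics and per-run predictions. Runs whose reproduced
    prediction differs from the published one by more than
    ``prediction_tolerance`` are listed as anomalies.
    """
    if design is None:
        design = load_reference_design()
    ref = json.loads(_data_path(REFERENCE_VALUES_RESOURCE).read_text())

    transform = TransformSpec(0.0)
    surface = fit_quadratic(design, transform)
    table = anova(surface, design)

    coef_rows = []
    for label, printed in ref["coefficients"].items():
        fitted = dict(zip(surface.term_labels(), surface.coefficients))[label]
        coef_rows.append(
            {
                "term": label,
                "reproduced": float(fitted),
                "published": printed,
                "abs_diff": abs(float(fitted) - printed),
            }
        )
    coef_table = pd.DataFrame(coef_rows)

    stats_map = {
        "model_f": table.model.f,
        "r2": table.r2,
        "adjusted_r2": table.adjusted_r2,
        "predicted_r2": table.predicted_r2,
        "adequate_precision": table.adequate_precision,
        "lack_of_fit_f": table.lack_of_fit.f,
        "model_df": table.model.df,
        "residual_df": table.residual.df,
        "lack_of_fit_df": table.lack_of_fit.df,
        "pure_error_df": table.pure_error.df,
        "total_df": table.cor_total.df,
    }
    stat_rows = [
        {
            "statistic": name,
            "reproduced": float(stats_map[name]),
            "published": printed,
            "abs_diff": abs(float(stats_map[name]) - printed),
        }
        for name, printed in ref["anova_statistics"].items()
    ]
    stats_table = pd.DataFrame(stat_rows)

    from .rsm import apply_transform  # local to avoid a cycle at import time

    z = apply_transform(design.responses, transform)
    points = []
    for i in range(len(design)):
        point = {f.name: design.coded[f.name].iloc[i] for f in design.spec.numeric_factors}
        point["train_function"] = design.table["train_function"].iloc[i]
        points.append(predict(surface, point))
    pred_table = pd.DataFrame(
        {
            "run": design.table["run"],
            "actual_ln": z,
            "reproduced_ln": points,
            "published_predicted_ln": ref["predicted_ln"],
        }
    )
    pred_table["abs_diff"] = (
        pred_table["reproduced_ln"] - pred_table["published_predicted_ln"]
    ).abs()
    anomalies = pred_table.loc[pred_table["abs_diff"] > prediction_tolerance, "run"].tolist()

    return {
        "surface": surface,
        "anova": table,
        "coefficients": coef_table,
        "statistics": stats_table,
        "predictions": pred_table,
        "anomalous_runs": anomalies,
        "prediction_tolerance": prediction_tolerance,
    }
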