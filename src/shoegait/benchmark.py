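"""Benchmark experiments: sensor ablation, segmentation and PC sweeps.

Three experiment drivers orchestrate the full pipeline over a cohort of
recordings:

* :func:`run_sensor_ablation` — all seven sensor combinations (P, A, G,
  PA, PG, AG, PAG) x the requested classifiers, LOOCV each;
* :func:`run_segmentation_sweep` — one combination and classifier across
  the seven gait-cycle schemes, stride through double limb support;
* :func:`run_pc_sweep` — fixed component counts instead of the 99%
  explained-variance rule.

Fold-wise metrics are compared with a classical paired one-tailed t-test
(pairing unit: participant), and :func:`render_report` writes every grid
and stored confusion matrix to CSV, including column error-rate rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (ClassifierSpec, ConfusionMatrix,
                       GaitClassificationModel, GaitClassificationResults,
                       ReductionConfig, column_error_rates)
from .features import (DISCARDED, build_feature_table, correlation_pairs,
                       select_sensor_columns)
from .layout import DEFAULT_LAYOUT, SENSOR_TYPES, SensorLayout
from .segmentation import SCHEMES, segment_cohort
from .selection import apply_discard_rule
from .simulate import Recording

_COMBO_ORDER = (
    ("pressure",),
    ("accelerometer",),
    ("gyroscope",),
    ("pressure", "accelerometer"),
    ("pressure", "gyroscope"),
    ("accelerometer", "gyroscope"),
    ("pressure", "accelerometer", "gyroscope"),
)

_ABBREV = {"pressure": "Pre", "accelerometer": "Acc", "gyroscope": "Gyro"}


@dataclass(frozen=True)
class SensorCombo:
    """A nonempty subset of the three sensor types."""

    sensors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sensors:
            raise ValueError("sensor combination must be nonempty")
        for s in self.sensors:
            if s not in SENSOR_TYPES:
                raise ValueError(f"unknown sensor type {s!r}")

    @property
    def name(self) -> str:
        return "+".join(_ABBREV[s] for s in SENSOR_TYPES if s in self.sensors)

    def retained_feature_count(self, layout: SensorLayout = DEFAULT_LAYOUT) -> int:
        """Feature count after the family discard rule, from first principles:
        correlation pairs + retained per-channel statistics x channels."""
        n = 0
        for s in self.sensors:
            n_chan = len(layout.channels((s,)))
            n += len(correlation_pairs(layout, s))
            n += (10 - len(DISCARDED[s])) * n_chan
        return n


def all_sensor_combos() -> list[SensorCombo]:
    return [SensorCombo(c) for c in _COMBO_ORDER]


@dataclass
class BenchmarkResult:
    """Grid of evaluations plus every per-fold confusion matrix."""

    grid: pd.DataFrame  # one row per (condition, classifier)
    results: dict[tuple[str, str], GaitClassificationResults]
    config: dict = field(default_factory=dict)


def _grid_row(condition: str, algorithm: str,
              res: GaitClassificationResults) -> dict:
    acc_m, acc_s = res.mean_sd("accuracy")
    pre_m, pre_s = res.mean_sd("weighted_precision")
    rec_m, rec_s = res.mean_sd("weighted_recall")
    return dict(
        condition=condition, classifier=algorithm,
        accuracy_pct=100 * acc_m, accuracy_sd=100 * acc_s,
        precision_pct=100 * pre_m, precision_sd=100 * pre_s,
        recall_pct=100 * rec_m, recall_sd=100 * rec_s,
        mean_n_pcs=res.mean_n_pcs, n_features=res.model.n_features,
    )


def run_sensor_ablation(
    recordings: list[Recording],
    classifiers: dict[str, ClassifierSpec] | None = None,
    scheme: str = "stride",
    reduction: ReductionConfig = ReductionConfig(),
    rng_seed: int = 0,
) -> BenchmarkResult:
    """LOOCV of every sensor combination x classifier on one scheme."""
    if classifiers is None:
        from .classify import classifier_specs
        classifiers = classifier_specs(rng_seed)
    layout = recordings[0].layout
    segments = segment_cohort(recordings, scheme)
    full = build_feature_table(segments, recordings, layout)
    retained = apply_discard_rule(full, layout)

    rows, results = [], {}
    for combo in all_sensor_combos():
        table = select_sensor_columns(retained, combo.sensors, layout)
        for name, spec in classifiers.items():
            res = GaitClassificationModel(table, spec, reduction).fit()
            rows.append(_grid_row(combo.name, name, res))
            results[(combo.name, name)] = res
    grid = pd.DataFrame(rows)
    return BenchmarkResult(grid, results, config=dict(
        experiment="sensor_ablation", scheme=scheme, rng_seed=rng_seed,
    ))


def run_segmentation_sweep(
    recordings: list[Recording],
    combo: SensorCombo = SensorCombo(("accelerometer", "gyroscope")),
    classifier: ClassifierSpec | None = None,
    reduction: ReductionConfig = ReductionConfig(),
) -> BenchmarkResult:
    """One combo and classifier across all seven segmentation schemes."""
    spec = classifier if classifier is not None else ClassifierSpec.svm()
    layout = recordings[0].layout
    rows, results = [], {}
    for scheme in SCHEMES:
        segments = segment_cohort(recordings, scheme)
        if not segments:
            continue  # reported as missing, not fatal
        full = build_feature_table(segments, recordings, layout)
        table = select_sensor_columns(
            apply_discard_rule(full, layout), combo.sensors, layout
        )
        res = GaitClassificationModel(table, spec, reduction).fit()
        rows.append(_grid_row(scheme, spec.algorithm, res))
        results[(scheme, spec.algorithm)] = res
    grid = pd.DataFrame(rows)
    return BenchmarkResult(grid, results, config=dict(
        experiment="segmentation_sweep", combo=combo.name,
    ))


def run_pc_sweep(
    recordings: list[Recording],
    combo: SensorCombo = SensorCombo(("accelerometer", "gyroscope")),
    classifier: ClassifierSpec | None = None,
    pc_grid: tuple[int, ...] = (10, 30, 50),
    scheme: str = "stride",
) -> BenchmarkResult:
    """Fixed-k evaluations, overriding the explained-variance rule."""
    spec = classifier if classifier is not None else ClassifierSpec.svm()
    layout = recordings[0].layout
    d_max = combo.retained_feature_count(layout)
    for k in pc_grid:
        if k > d_max:
            raise ValueError(
                f"n_pcs={k} exceeds the {d_max} retained features of "
                f"{combo.name}"
            )
    segments = segment_cohort(recordings, scheme)
    full = build_feature_table(segments, recordings, layout)
    table = select_sensor_columns(
        apply_discard_rule(full, layout), combo.sensors, layout
    )
    rows, results = [], {}
    for k in pc_grid:
        res = GaitClassificationModel(
            table, spec, ReductionConfig(n_pcs=int(k))
        ).fit()
        rows.append(_grid_row(f"n_pcs={k}", spec.algorithm, res))
        results[(f"n_pcs={k}", spec.algorithm)] = res
    grid = pd.DataFrame(rows)
    return BenchmarkResult(grid, results, config=dict(
        experiment="pc_sweep", combo=combo.name, scheme=scheme,
        pc_grid=list(pc_grid),
    ))


def default_config() -> dict:
    """Every pipeline default as one plain mapping (YAML-serializable)."""
    return {
        "cohort": {
            "n_participants": 18, "seed": 0, "sampling_rate": 100.0,
            "noise_scale": 1.0,
            "durations_per_class": {
                "normal": 180.0, "unstable_left": 60.0,
                "unstable_right": 60.0, "supination": 60.0,
                "pronation": 60.0,
            },
        },
        "segmentation": {"scheme": "stride", "threshold": 40.0,
                         "min_phase_duration": 0.05, "anchor": "right"},
        "reduction": {"variance_threshold": 0.99, "n_pcs": None},
        "classifiers": ["random_forest", "knn", "logistic_regression", "svm"],
        "rng_seed": 0,
    }


def run_from_config(config: dict, out_dir: str | Path) -> BenchmarkResult:
    """Simulate a cohort per the config, run the sensor ablation and
    write the report; returns the ablation result."""
    from .classify import classifier_specs
    from .simulate import simulate_cohort

    cfg = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    cohort = simulate_cohort(**cfg["cohort"])
    specs = {name: spec
             for name, spec in classifier_specs(cfg["rng_seed"]).items()
             if name in cfg["classifiers"]}
    reduction = ReductionConfig(**cfg["reduction"])
    result = run_sensor_ablation(
        cohort, specs, scheme=cfg["segmentation"]["scheme"],
        reduction=reduction, rng_seed=cfg["rng_seed"],
    )
    result.config = cfg
    render_report(result, out_dir)
    return result


@dataclass(frozen=True)
class PairedTTest:
    t: float
    p_one_tailed: float
    degenerate: bool = False

    @property
    def marker(self) -> str:
        """Significance marker: ** p<0.01, * p<0.05, '' otherwise."""
        if self.p_one_tailed < 0.01:
            return "**"
        if self.p_one_tailed < 0.05:
            return "*"
        return ""


def paired_t_test(a, b, alternative: str = "greater") -> PairedTTest:
    """Classical paired one-tailed t-test on participant-paired scores.

    ``alternative='greater'`` tests mean(a − b) > 0.  Zero-variance
    differences: p = 0.5 if the mean difference is 0, otherwise the test
    is degenerate (p 0 or 1 by sign).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples, n >= 2")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return PairedTTest(0.0, 0.5, degenerate=True)
        wins = (d[0] > 0) == (alternative == "greater")
        return PairedTTest(np.inf if d[0] > 0 else -np.inf,
                           0.0 if wins else 1.0, degenerate=True)
    res = stats.ttest_rel(a, b, alternative=alternative)
    return PairedTTest(float(res.statistic), float(res.pvalue))


def t_test_table(
    results: dict[str, GaitClassificationResults],
    reference: str,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Reference-vs-others paired t-tests on fold-wise metrics."""
    ref = results[reference]
    rows = []
    for name, other in results.items():
        if name == reference:
            continue
        row = {"comparison": f"{reference} vs {name}"}
        for metric in ("accuracy", "weighted_precision", "weighted_recall"):
            tt = paired_t_test(ref.per_fold(metric), other.per_fold(metric),
                               alternative)
            row[f"{metric}_p"] = tt.p_one_tailed
            row[f"{metric}_marker"] = tt.marker
        rows.append(row)
    return pd.DataFrame(rows)


def _confusion_frame(cm: ConfusionMatrix) -> pd.DataFrame:
    frame = pd.DataFrame(cm.counts, index=cm.labels,
                         columns=list(cm.labels))
    rates, avg = column_error_rates(cm)
    frame.loc["error_rate_pct"] = np.round(rates, 1)
    frame.attrs["average_error_rate_pct"] = round(avg, 1)
    return frame


def render_report(result: BenchmarkResult, out_dir: str | Path) -> list[Path]:
    """Write the grid, per-fold matrices with error-rate rows, and
    explained-variance-style summaries to CSV files under ``out_dir``."""
    if result.grid.empty:
        raise ValueError("empty benchmark result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    grid_path = out / "benchmark_grid.csv"
    result.grid.to_csv(grid_path, index=False)
    written.append(grid_path)
    for (condition, algo), res in result.results.items():
        safe = condition.replace("+", "_").replace("=", "")
        for pid, cm in res.fold_matrices.items():
            frame = _confusion_frame(cm)
            path = out / f"confusion_{safe}_{algo}_p{pid:02d}.csv"
            frame.to_csv(path, index_label="true_class")
            written.append(path)
        folds = pd.DataFrame({
            "participant_id": res.participants,
            "accuracy": res.per_fold("accuracy"),
            "weighted_precision": res.per_fold("weighted_precision"),
            "weighted_recall": res.per_fold("weighted_recall"),
            "n_pcs": [res.fold_n_pcs[p] for p in res.participants],
        })
        path = out / f"folds_{safe}_{algo}.csv"
        folds.to_csv(path, index=False)
        written.append(path)
    return written
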