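"""Experiment orchestration: the three split protocols, ELM training,
optional feature selection, baseline comparison, and report writing.

The canonical protocol trains a binary seizure-vs-rest ELM at three
training fractions (80/70/60%), with the 80/20 holdout halved into
validation and test.  Hidden-layer size defaults to the one-tenth heuristic
L = round(0.1 * n_train) (9200 -> 920, 8050 -> 805, 6900 -> 690); a
validation sweep is available instead.  Reports follow a fixed column
schema, one Training and one Testing row per protocol per model, and are
byte-identical under a fixed seed (wall-clock timings go to the run
manifest, not the report).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_io import (
    BinaryDataset,
    LabeledDataset,
    Rescaler,
    SplitSpec,
    apply_rescaler,
    balance_training,
    fit_rescaler,
    read_dataset,
    relabel_binary,
    split,
)
from .elm import (
    ELMConfig,
    decision_scores,
    default_hidden_neurons,
    derive_seed,
    fit,
    init_hidden,
    predict,
    sweep_hidden_neurons,
)
from .evaluation import confusion, metrics, roc_auc
from .feature_selection import run_feature_selection
from .synthetic import SynthConfig, generate_bonn_like

__all__ = [
    "ExperimentConfig",
    "REPORT_COLUMNS",
    "CANONICAL_SPLITS",
    "run_experiment",
    "compare_baselines",
    "write_report",
    "BASELINES",
]

#: fixed report schema: Accuracy as a percentage, everything else a fraction.
REPORT_COLUMNS = (
    "Model",
    "Phase",
    "Accuracy %",
    "Dataset Division %",
    "Samples",
    "Prevalence",
    "Precision",
    "Recall",
    "F1-Score",
    "Specificity",
    "Sensitivity",
    "AUC",
)


def CANONICAL_SPLITS(seed: int = 0) -> tuple[SplitSpec, ...]:
    """80/20 (holdout halved into validation+test), 70/30, 60/40."""
    return (
        SplitSpec(0.8, halve_holdout=True, stratified=True, seed=derive_seed(seed, 80)),
        SplitSpec(0.7, halve_holdout=False, stratified=True, seed=derive_seed(seed, 70)),
        SplitSpec(0.6, halve_holdout=False, stratified=True, seed=derive_seed(seed, 60)),
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a run needs; all randomness derives from ``seed``."""

    source: str | Path | SynthConfig | LabeledDataset | BinaryDataset
    split_specs: tuple[SplitSpec, ...]
    n_hidden: int | None = None          # None -> round(0.1 * n_train)
    sweep_grid: tuple[int, ...] | None = None
    feature_selection: bool = False
    fs_policy: str = "threshold-mean"
    fs_top_k: int | None = None
    balance_train: bool = False
    threshold: float = 0.5
    baselines: tuple[str, ...] = ()
    outdir: str | Path | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.split_specs:
            raise ValueError("at least one split spec is required")


def _load_binary(cfg: ExperimentConfig) -> BinaryDataset:
    src = cfg.source
    if isinstance(src, BinaryDataset):
        return src
    if isinstance(src, LabeledDataset):
        return relabel_binary(src)
    if isinstance(src, SynthConfig):
        return relabel_binary(generate_bonn_like(src))
    return relabel_binary(read_dataset(src))


@dataclass
class _Prepared:
    """One prepared protocol: rescaled partitions + bookkeeping."""

    spec: SplitSpec
    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray | None
    y_val: np.ndarray | None
    X_test: np.ndarray
    y_test: np.ndarray
    rescaler: Rescaler
    selected: tuple[int, ...] | None = None


def _prepare(ds: BinaryDataset, spec: SplitSpec, cfg: ExperimentConfig) -> _Prepared:
    parts = split(ds, spec)
    train = parts.train
    if cfg.balance_train:
        train = balance_training(train, seed=derive_seed(cfg.seed, 7, int(spec.train_frac * 100)))
    resc = fit_rescaler(train.features)
    Xtr = apply_rescaler(resc, train.features)
    Xte = apply_rescaler(resc, parts.test.features)
    Xva = apply_rescaler(resc, parts.validation.features) if parts.validation else None
    yva = parts.validation.labels if parts.validation else None
    return _Prepared(
        spec=spec,
        X_train=Xtr, y_train=train.labels,
        X_val=Xva, y_val=yva,
        X_test=Xte, y_test=parts.test.labels,
        rescaler=resc,
    )


def _choose_L(prep: _Prepared, cfg: ExperimentConfig, ratio_tag: int) -> int:
    if cfg.sweep_grid is not None:
        Xv = prep.X_val if prep.X_val is not None else prep.X_test
        yv = prep.y_val if prep.y_val is not None else prep.y_test
        res = sweep_hidden_neurons(
            prep.X_train, prep.y_train, Xv, yv,
            cfg.sweep_grid, seed=derive_seed(cfg.seed, 5, ratio_tag),
        )
        return res.best_L
    if cfg.n_hidden is not None:
        return cfg.n_hidden
    return default_hidden_neurons(len(prep.y_train))


def _panel_row(model_name: str, phase: str, division_pct: float,
               y_true, y_pred, scores) -> dict:
    cm = confusion(y_true, y_pred)
    try:
        _, auc = roc_auc(y_true, scores)
    except ValueError:
        auc = float("nan")
    rep = metrics(cm, auc=auc)
    return {
        "Model": model_name,
        "Phase": phase,
        "Accuracy %": round(100 * rep.accuracy, 4),
        "Dataset Division %": round(division_pct, 4),
        "Samples": rep.n_samples,
        "Prevalence": round(rep.prevalence, 6),
        "Precision": round(rep.precision, 6),
        "Recall": round(rep.recall, 6),
        "F1-Score": round(rep.f1, 6),
        "Specificity": round(rep.specificity, 6),
        "Sensitivity": round(rep.sensitivity, 6),
        "AUC": round(rep.auc, 6) if np.isfinite(rep.auc) else "",
    }


def _elm_rows(prep: _Prepared, cfg: ExperimentConfig, timings: dict) -> list[dict]:
    ratio_tag = int(round(prep.spec.train_frac * 100))
    Xtr, Xte = prep.X_train, prep.X_test
    if cfg.feature_selection:
        # rank features with a pilot ELM on all columns, then retrain reduced
        pilot_cfg = ELMConfig(
            n_hidden=min(default_hidden_neurons(len(prep.y_train)), 200),
            seed=derive_seed(cfg.seed, 3, ratio_tag),
        )
        pilot = fit(init_hidden(pilot_cfg, Xtr.shape[1]), Xtr, prep.y_train)
        fs = run_feature_selection(pilot, policy=cfg.fs_policy, k=cfg.fs_top_k)
        prep.selected = fs.selected
        keep = np.array(sorted(fs.selected))
        Xtr, Xte = Xtr[:, keep], Xte[:, keep]
    L = _choose_L(prep, cfg, ratio_tag)
    ecfg = ELMConfig(n_hidden=L, seed=derive_seed(cfg.seed, 1, ratio_tag))
    t0 = time.perf_counter()
    model = fit(init_hidden(ecfg, Xtr.shape[1]), Xtr, prep.y_train)
    t_train = time.perf_counter() - t0
    t0 = time.perf_counter()
    s_test = decision_scores(model, Xte)[:, 0]
    t_test = time.perf_counter() - t0
    s_train = decision_scores(model, Xtr)[:, 0]
    p_train = (s_train >= cfg.threshold).astype(int)
    p_test = (s_test >= cfg.threshold).astype(int)
    timings[f"ELM_{ratio_tag}"] = {"train_s": t_train, "test_s": t_test, "n_hidden": L}
    return [
        _panel_row("ELM", "Training", 100 * prep.spec.train_frac,
                   prep.y_train, p_train, s_train),
        _panel_row("ELM", "Testing", 100 * len(prep.y_test) / (len(prep.y_train) + len(prep.y_test) + (0 if prep.y_val is None else len(prep.y_val))),
                   prep.y_test, p_test, s_test),
    ]


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run every split protocol: prepare -> (select features) -> train ELM ->
    evaluate on train and test.  Returns the report table (2 rows per
    protocol) and, when ``outdir`` is set, writes report.csv + manifest.json."""
    ds = _load_binary(cfg)
    rows: list[dict] = []
    timings: dict = {}
    selected: dict = {}
    for spec in cfg.split_specs:
        prep = _prepare(ds, spec, cfg)
        rows.extend(_elm_rows(prep, cfg, timings))
        if prep.selected is not None:
            selected[str(int(spec.train_frac * 100))] = list(prep.selected)
    report = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.csv")
        _write_manifest(cfg, out / "manifest.json", timings, selected)
    return report


#: baseline registry: thin adapters around established implementations.
BASELINES = ("knn", "nb", "lr", "rf", "dt", "sgdc", "gb", "ann", "lstm")


def _make_baseline(name: str, seed: int):
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression, SGDClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.tree import DecisionTreeClassifier

    table = {
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "nb": lambda: GaussianNB(),
        "lr": lambda: LogisticRegression(max_iter=2000),
        "rf": lambda: RandomForestClassifier(n_estimators=100, random_state=seed),
        "dt": lambda: DecisionTreeClassifier(random_state=seed),
        "sgdc": lambda: SGDClassifier(loss="log_loss", random_state=seed),
        "gb": lambda: GradientBoostingClassifier(random_state=seed),
        "ann": lambda: MLPClassifier(hidden_layer_sizes=(100,), max_iter=300,
                                     random_state=seed),
    }
    if name not in table:
        raise KeyError(name)
    return table[name]()


def _baseline_scores(clf, X) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def compare_baselines(cfg: ExperimentConfig) -> pd.DataFrame:
    """ELM rows plus one Training/Testing row pair per requested baseline,
    fitted on the identical partitions.  Unavailable baselines (e.g. an LSTM
    with no deep-learning runtime installed) are skipped with a warning."""
    ds = _load_binary(cfg)
    rows: list[dict] = []
    timings: dict = {}
    for spec in cfg.split_specs:
        prep = _prepare(ds, spec, cfg)
        rows.extend(_elm_rows(prep, cfg, timings))
        ratio_tag = int(round(spec.train_frac * 100))
        test_pct = 100 * len(prep.y_test) / ds.n_rows
        for name in cfg.baselines:
            try:
                clf = _make_baseline(name, derive_seed(cfg.seed, 2, ratio_tag))
            except KeyError:
                warnings.warn(f"baseline {name!r} unavailable; skipped", UserWarning)
                continue
            t0 = time.perf_counter()
            clf.fit(prep.X_train, prep.y_train)
            timings[f"{name.upper()}_{ratio_tag}"] = {"train_s": time.perf_counter() - t0}
            rows.append(_panel_row(name.upper(), "Training", 100 * spec.train_frac,
                                   prep.y_train, clf.predict(prep.X_train),
                                   _baseline_scores(clf, prep.X_train)))
            rows.append(_panel_row(name.upper(), "Testing", test_pct,
                                   prep.y_test, clf.predict(prep.X_test),
                                   _baseline_scores(clf, prep.X_test)))
    report = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.csv")
        _write_manifest(cfg, out / "manifest.json", timings, {})
    return report


def write_report(report: pd.DataFrame, path) -> None:
    """Write the report CSV in the fixed column order (deterministic bytes)."""
    if len(report) == 0:
        raise ValueError("report has no rows")
    report.loc[:, list(REPORT_COLUMNS)].to_csv(path, index=False, lineterminator="\n")


def _jsonable(obj):
    if isinstance(obj, (str, Path)):
        return str(obj)
    if isinstance(obj, SynthConfig):
        return {k: v for k, v in asdict(obj).items()}
    if isinstance(obj, (LabeledDataset, BinaryDataset)):
        return f"<in-memory dataset, {obj.n_rows}x{obj.n_features}>"
    return obj


def _write_manifest(cfg: ExperimentConfig, path, timings: dict, selected: dict) -> None:
    doc = {
        "elmseizure_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "source": _jsonable(cfg.source),
        "split_specs": [asdict(s) for s in cfg.split_specs],
        "n_hidden": cfg.n_hidden,
        "sweep_grid": list(cfg.sweep_grid) if cfg.sweep_grid else None,
        "feature_selection": cfg.feature_selection,
        "fs_policy": cfg.fs_policy,
        "balance_train": cfg.balance_train,
        "threshold": cfg.threshold,
        "baselines": list(cfg.baselines),
        "selected_features": selected,
        "timings_s": timings,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
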