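"""Model comparison: six regressors × feature-group fusions, with holdout metrics.

The comparison grid crosses six regression algorithms (random forest,
partial least squares, multiple/simple linear, ridge, lasso) with every
non-empty subset of the five feature groups {VIs, Texture, CC, GDD, GPR}.
Data are split once into 2/3 train and 1/3 test, stratified by growth
stage, and every model is scored with R^2, RMSE, MAE and rRMSE (RMSE over
the mean observed value) on both partitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV, LinearRegression, RidgeCV
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "MODEL_KINDS",
    "FEATURE_GROUPS",
    "ModelSpec",
    "FusionCombo",
    "EvalResult",
    "split_train_test",
    "enumerate_fusions",
    "metrics",
    "fit_predict",
    "run_comparison",
]

MODEL_KINDS = ("RF", "PLSR", "MLR", "SLR", "Ridge", "Lasso")

#: feature groups addressable in fusion combos, mapped to column selectors
FEATURE_GROUPS = ("VIs", "Texture", "GDD", "CC", "GPR")
_GROUP_PREFIX = {"VIs": "vi.", "Texture": "tex."}
_GROUP_COLUMN = {"CC": "cc", "GDD": "gdd", "GPR": "gpr"}


@dataclass(frozen=True)
class ModelSpec:
    """One of the six regression algorithms plus its hyperparameters."""

    kind: str
    seed: int = 0
    n_trees: int = 500
    max_pls_components: int = 10
    cv_folds: int = 5

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; one of {MODEL_KINDS}")


@dataclass(frozen=True)
class FusionCombo:
    """A subset of feature groups fused into one predictor set."""

    groups: tuple[str, ...]
    baseline: bool = False  # single-group combos mirror the single-feature tables

    def __post_init__(self):
        if not self.groups:
            raise ValueError("fusion combo must contain at least one group")
        unknown = set(self.groups) - set(FEATURE_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")

    @property
    def label(self) -> str:
        return " + ".join(self.groups)


@dataclass
class EvalResult:
    """Train and test metrics of one model on one fusion combo."""

    model_kind: str
    combo: FusionCombo
    split_seed: int
    n_train: int
    n_test: int
    train_metrics: dict[str, float] = field(default_factory=dict)
    test_metrics: dict[str, float] = field(default_factory=dict)
    features: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "model": self.model_kind,
            "combo": self.combo.label,
            "split_seed": self.split_seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_features": len(self.features),
        }
        row.update({f"train_{k}": v for k, v in self.train_metrics.items()})
        row.update({f"test_{k}": v for k, v in self.test_metrics.items()})
        return row


def metrics(y_obs, y_pred) -> dict[str, float]:
    """R^2, RMSE, MAE and rRMSE of predictions against observations.

    rRMSE = RMSE / mean(y_obs); it is NaN (flagged undefined) when the
    observed mean is zero.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size == 0:
        raise ValueError(
            f"need equal non-empty vectors, got {y_obs.shape} and {y_pred.shape}"
        )
    resid = y_obs - y_pred
    sse = float((resid**2).sum())
    sst = float(((y_obs - y_obs.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(sse / y_obs.size))
    mae = float(np.abs(resid).mean())
    ybar = float(y_obs.mean())
    rrmse = rmse / ybar if ybar != 0 else float("nan")
    return {"r2": r2, "rmse": rmse, "mae": mae, "rrmse": rrmse}


def split_train_test(
    table: pd.DataFrame,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    stratify_by: str | None = "stage",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single random holdout split, stratified by growth stage by default."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie strictly in (0, 1), got {fraction}")
    if table.empty:
        raise ValueError("cannot split an empty table")
    strat = None
    if stratify_by is not None:
        counts = table[stratify_by].value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"strata with fewer than 2 rows: {small}")
        strat = table[stratify_by]
    train, test = train_test_split(
        table, train_size=fraction, random_state=seed, stratify=strat
    )
    return train, test


def enumerate_fusions(groups: tuple[str, ...] = FEATURE_GROUPS) -> list[FusionCombo]:
    """All non-empty subsets of the feature groups, singles flagged as baselines."""
    if not groups:
        raise ValueError("need at least one feature group")
    combos = []
    for r in range(1, len(groups) + 1):
        for sub in itertools.combinations(groups, r):
            combos.append(FusionCombo(groups=sub, baseline=(r == 1)))
    return combos


def combo_columns(
    combo: FusionCombo,
    table: pd.DataFrame,
    selection=None,
) -> list[str]:
    """Feature columns of a fusion combo, honouring a selection result.

    When a :class:`SelectionResult` is given, the VIs and Texture groups are
    narrowed to its confirmed members; CC/GDD/GPR are single columns.
    """
    cols: list[str] = []
    for grp in combo.groups:
        if grp in _GROUP_PREFIX:
            prefix = _GROUP_PREFIX[grp]
            pool = [c for c in table.columns if c.startswith(prefix)]
            if selection is not None:
                kept = [c for c in selection.confirmed if c.startswith(prefix)]
                pool = kept or pool
            cols.extend(pool)
        else:
            cols.append(_GROUP_COLUMN[grp])
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"feature columns absent from table: {missing}")
    return cols


def _make_estimator(spec: ModelSpec, n_features: int, n_train: int):
    if spec.kind == "RF":
        return RandomForestRegressor(
            n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
        )
    if spec.kind == "PLSR":
        k_max = max(1, min(spec.max_pls_components, n_features, n_train - 1))
        pipe = Pipeline(
            [("scale", StandardScaler()), ("pls", PLSRegression(n_components=1))]
        )
        if k_max == 1:
            return pipe
        return GridSearchCV(
            pipe,
            {"pls__n_components": list(range(1, k_max + 1))},
            cv=spec.cv_folds,
            scoring="neg_root_mean_squared_error",
        )
    if spec.kind in ("MLR", "SLR"):
        return LinearRegression()
    if spec.kind == "Ridge":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("ridge", RidgeCV(alphas=np.logspace(-3, 3, 25))),
            ]
        )
    if spec.kind == "Lasso":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("lasso", LassoCV(alphas=50, cv=spec.cv_folds,
                                  random_state=spec.seed, max_iter=5000)),
            ]
        )
    raise ValueError(f"unknown model kind {spec.kind!r}")


def _top_r_feature(train: pd.DataFrame, cols: list[str], target: str) -> str:
    y = train[target].to_numpy(dtype=float)
    best, best_r = None, -1.0
    for c in sorted(cols):
        x = train[c].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        r = abs(float(np.corrcoef(x, y)[0, 1]))
        if r > best_r:
            best, best_r = c, r
    if best is None:
        raise ValueError("all candidate predictors are constant")
    return best


def fit_predict(
    spec: ModelSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    combo: FusionCombo,
    target: str = "true_agb",
    selection=None,
) -> EvalResult:
    """Fit one model on the train partition and score both partitions.

    Rows with missing feature values are dropped listwise.  Simple linear
    regression uses the single train-set feature with the highest |r|
    against the target; multiple linear regression rejects a singular
    design.  Standardization for PLSR/Ridge/Lasso is fit on the train
    partition only (inside the pipeline).
    """
    cols = combo_columns(combo, train, selection)
    tr = train.dropna(subset=cols + [target])
    te = test.dropna(subset=cols + [target])
    if tr.empty or te.empty:
        raise ValueError("no complete rows left after listwise deletion")
    if spec.kind == "SLR":
        cols = [_top_r_feature(tr, cols, target)]
    Xtr = tr[cols].to_numpy(dtype=float)
    Xte = te[cols].to_numpy(dtype=float)
    ytr = tr[target].to_numpy(dtype=float)
    yte = te[target].to_numpy(dtype=float)
    if spec.kind == "MLR":
        design = np.column_stack([np.ones(len(Xtr)), Xtr])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                f"singular design for MLR on combo {combo.label!r}: "
                "collinear or constant predictors"
            )
    est = _make_estimator(spec, Xtr.shape[1], len(Xtr))
    est.fit(Xtr, ytr)
    pred_tr = np.asarray(est.predict(Xtr)).ravel()
    pred_te = np.asarray(est.predict(Xte)).ravel()
    return EvalResult(
        model_kind=spec.kind,
        combo=combo,
        split_seed=spec.seed,
        n_train=len(tr),
        n_test=len(te),
        train_metrics=metrics(ytr, pred_tr),
        test_metrics=metrics(yte, pred_te),
        features=cols,
    )


def run_comparison(
    table: pd.DataFrame,
    selection=None,
    models: tuple[str, ...] = MODEL_KINDS,
    combos: list[FusionCombo] | None = None,
    target: str = "true_agb",
    seed: int = 0,
    fraction: float = 2.0 / 3.0,
    stratify_by: str | None = "stage",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every model on every fusion combo over one holdout split.

    Returns ``(results, best)``: one row per model × combo, and the best
    combo per model ranked by test R^2 with ties broken by lower test
    rRMSE.  Individual model failures are recorded (``error`` column) and
    the grid continues.
    """
    if combos is None:
        combos = enumerate_fusions()
    train, test = split_train_test(table, fraction, seed, stratify_by)
    rows = []
    for kind in models:
        spec = ModelSpec(kind=kind, seed=seed)
        for combo in combos:
            try:
                res = fit_predict(spec, train, test, combo, target, selection)
                rows.append(res.to_row())
            except Exception as exc:  # grid continues past model failures
                rows.append(
                    {
                        "model": kind,
                        "combo": combo.label,
                        "split_seed": seed,
                        "error": str(exc),
                    }
                )
    results = pd.DataFrame(rows)
    ok = results[results.get("error").isna()] if "error" in results else results
    best = (
        ok.sort_values(
            ["model", "test_r2", "test_rrmse"], ascending=[True, False, True]
        )
        .groupby("model", as_index=False)
        .head(1)
        .reset_index(drop=True)
    )
    return results, best
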