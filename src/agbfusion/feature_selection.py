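"""Feature selection: Boruta shadow-feature wrapper, VIF screen, Pearson top-k.

Two routes are provided.  The wrapper route runs Boruta — each iteration
appends a column-permuted "shadow" copy of every candidate, fits a random
forest on real + shadow features and counts a hit whenever a real feature's
importance beats the best shadow; hit counts are then tested against a
binomial null — followed by a variance-inflation-factor screen that drops
collinear survivors.  The filter route ranks candidates by absolute Pearson
correlation with the target and keeps the top-k vegetation indices and
texture features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "SelectionResult",
    "VIFReport",
    "pearson_rank",
    "vif_screen",
    "boruta_select",
]


@dataclass
class SelectionResult:
    """Outcome of a selection run: a partition of the candidate set."""

    method: str
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    scores: dict[str, float]  # importance or |r| per candidate
    iterations: int = 0
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "confirmed": self.confirmed,
            "rejected": self.rejected,
            "tentative": self.tentative,
            "scores": self.scores,
            "iterations": self.iterations,
            "params": self.params,
        }


@dataclass(frozen=True)
class VIFReport:
    """Variance inflation factor of one candidate and whether it survived."""

    feature: str
    vif: float
    retained: bool


def _group_of(name: str) -> str:
    return name.split(".", 1)[0] if "." in name else name


def pearson_rank(
    table: pd.DataFrame,
    target: str = "true_agb",
    k_vi: int = 5,
    k_tex: int = 3,
) -> SelectionResult:
    """Select the top-|r| vegetation indices and texture features.

    Correlations are computed on pooled rows (all cultivars and dates
    together); per-cultivar correlations are diagnostics, not the selection
    input.  Ties at the k-th rank break by feature name so the result is
    deterministic.  Constant features have undefined correlation and are
    auto-rejected with a warning.
    """
    candidates = [c for c in table.columns if c.startswith(("vi.", "tex."))]
    if len(table.dropna(subset=candidates + [target])) < 3:
        raise ValueError("need at least 3 complete rows for correlation ranking")
    y = table[target].to_numpy(dtype=float)
    if np.nanstd(y) == 0:
        raise ValueError("target has zero variance")

    scores: dict[str, float] = {}
    rejected: list[str] = []
    for c in candidates:
        x = table[c].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            warnings.warn(f"feature {c} is constant or empty; rejected", stacklevel=2)
            rejected.append(c)
            scores[c] = float("nan")
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        scores[c] = abs(r)

    confirmed: list[str] = []
    for prefix, k in (("vi.", k_vi), ("tex.", k_tex)):
        pool = [c for c in candidates if c.startswith(prefix) and c not in rejected]
        # sort by descending |r|, name-lexicographic tie-break
        ranked = sorted(pool, key=lambda c: (-scores[c], c))
        confirmed.extend(ranked[:k])
    rejected.extend(c for c in candidates if c not in confirmed and c not in rejected)
    return SelectionResult(
        method="pearson",
        confirmed=confirmed,
        rejected=rejected,
        tentative=[],
        scores=scores,
        iterations=1,
        params={"k_vi": k_vi, "k_tex": k_tex, "target": target},
    )


def vif_screen(
    table: pd.DataFrame,
    candidates: list[str],
    threshold: float = 10.0,
) -> list[VIFReport]:
    """Iteratively drop the highest-VIF candidate until all VIFs <= threshold.

    VIF of a feature is 1/(1 - R^2) from an ordinary least-squares regression
    of that feature on all remaining candidates (with intercept), computed
    through statsmodels.  Exactly collinear features get VIF = inf and are
    dropped first; ties break by dropping the lexicographically later name.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    work = table[candidates].dropna()
    if len(work) < len(candidates) + 2:
        raise ValueError(
            f"need at least {len(candidates) + 2} complete rows for VIF, "
            f"have {len(work)}"
        )
    remaining = sorted(candidates)
    dropped: dict[str, float] = {}

    def current_vifs(cols: list[str]) -> dict[str, float]:
        if len(cols) == 1:
            return {cols[0]: 1.0}
        X = sm.add_constant(work[cols].to_numpy(dtype=float), has_constant="add")
        out = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for pos, c in enumerate(cols):
                v = variance_inflation_factor(X, pos + 1)
                out[c] = float(v) if np.isfinite(v) else float("inf")
        return out

    vifs = current_vifs(remaining)
    while remaining and max(vifs.values()) > threshold:
        worst = max(vifs.items(), key=lambda kv: (kv[1], kv[0]))[0]
        dropped[worst] = vifs[worst]
        remaining.remove(worst)
        vifs = current_vifs(remaining)

    reports = [VIFReport(c, vifs[c], True) for c in remaining]
    reports += [VIFReport(c, v, False) for c, v in dropped.items()]
    return sorted(reports, key=lambda r: r.feature)


def boruta_select(
    table: pd.DataFrame,
    target: str = "true_agb",
    candidates: list[str] | None = None,
    max_iter: int = 100,
    alpha: float = 0.05,
    n_trees: int = 200,
    seed: int = 0,
    *,
    resolve_tentative: bool = True,
) -> SelectionResult:
    """Boruta all-relevant selection with a random-forest learner.

    Per iteration the candidate matrix is duplicated into freshly permuted
    shadow columns, a random forest is fit on real + shadow features, and a
    real feature scores a "hit" when its importance exceeds the maximum
    shadow importance.  After ``max_iter`` iterations a two-sided binomial
    test of the hit count against p = 0.5, Bonferroni-corrected at ``alpha``,
    classifies features as confirmed (significantly above half) or rejected
    (significantly below); the rest are tentative and, when
    ``resolve_tentative`` is set, resolved by comparing their median
    importance to the median of the per-iteration shadow maxima.
    """
    if candidates is None:
        candidates = [
            c for c in table.columns
            if c.startswith(("vi.", "tex.")) or c in ("cc", "gdd", "gpr")
        ]
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate features")
    work = table[candidates + [target]].dropna()
    if len(work) < 20:
        raise ValueError(f"need at least 20 complete rows, have {len(work)}")
    y = work[target].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("target has zero variance")
    X = work[candidates].to_numpy(dtype=float)
    n, p = X.shape

    rng = np.random.default_rng(seed)
    hits = np.zeros(p, dtype=int)
    imp_history: list[np.ndarray] = []
    shadow_max_history: list[float] = []
    for it in range(max_iter):
        shadow = np.column_stack(
            [rng.permutation(X[:, jcol]) for jcol in range(p)]
        )
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(np.hstack([X, shadow]), y)
        imp = forest.feature_importances_
        real_imp, shadow_imp = imp[:p], imp[p:]
        smax = float(shadow_imp.max())
        hits += (real_imp > smax).astype(int)
        imp_history.append(real_imp)
        shadow_max_history.append(smax)

    confirmed, rejected, tentative = [], [], []
    if max_iter == 0:
        tentative = list(candidates)
        scores = {c: float("nan") for c in candidates}
    else:
        med_imp = np.median(np.vstack(imp_history), axis=0)
        med_shadow = float(np.median(shadow_max_history))
        scores = {c: float(med_imp[jcol]) for jcol, c in enumerate(candidates)}
        for jcol, c in enumerate(candidates):
            pval = stats.binomtest(int(hits[jcol]), max_iter, 0.5).pvalue
            significant = pval * p < alpha  # Bonferroni over candidates
            if significant and hits[jcol] > max_iter / 2:
                confirmed.append(c)
            elif significant and hits[jcol] < max_iter / 2:
                rejected.append(c)
            elif resolve_tentative:
                (confirmed if med_imp[jcol] > med_shadow else rejected).append(c)
            else:
                tentative.append(c)

    return SelectionResult(
        method="boruta",
        confirmed=confirmed,
        rejected=rejected,
        tentative=tentative,
        scores=scores,
        iterations=max_iter,
        params={
            "alpha": alpha,
            "n_trees": n_trees,
            "seed": seed,
            "resolve_tentative": resolve_tentative,
            "hits": {c: int(hits[jcol]) for jcol, c in enumerate(candidates)},
        },
    )
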