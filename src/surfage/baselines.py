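"""Non-topological comparators and the rewired-graph ablation.

Random forest and ridge-penalized linear regression ("GLM") consume the same
flattened scans x (vertices * features) matrices and byte-identical fold
assignments as the GCN; the ablation harness trains one GCN on the true mesh
hierarchy and one on a degree-preserving random rewiring of the same mesh, so
any performance gap isolates the value of the true topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge

from surfage.evaluation import CVOutcome, FoldPlan, make_folds, run_nested_cv
from surfage.gcn_model import ArchConfig, TrainConfig, build_model, train_model
from surfage.graphops import coarsen_graph, rewire_random


def _flatten(x: np.ndarray) -> np.ndarray:
    return x.reshape(x.shape[0], -1) if x.ndim == 3 else x


class RandomForestBaseline:
    """Regression forest on flattened vertex features."""

    def __init__(self, n_trees: int = 500, seed: int = 0):
        self.model = RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )

    def fit(self, train_x, train_y, val_x=None, val_y=None):
        x = _flatten(train_x)
        if x.shape[0] < 5:
            raise ValueError("need at least 5 training scans")
        self.model.fit(x, train_y)
        return self

    def predict(self, x):
        return self.model.predict(_flatten(x))


class RidgeBaseline:
    """Ridge-penalized linear regression; the penalty is chosen on the
    validation set (unpenalized least squares is rank deficient when the
    flattened feature count exceeds the scan count)."""

    def __init__(self, alphas: np.ndarray | None = None):
        self.alphas = (
            np.logspace(-2, 6, 17) if alphas is None else np.asarray(alphas, float)
        )
        self.model: Ridge | None = None
        self.alpha_: float | None = None

    def fit(self, train_x, train_y, val_x=None, val_y=None):
        x = _flatten(train_x)
        if x.shape[0] < 5:
            raise ValueError("need at least 5 training scans")
        self._mean = x.mean(axis=0)
        self._sd = np.where(x.std(axis=0) < 1e-12, 1.0, x.std(axis=0))
        xs = (x - self._mean) / self._sd
        if val_x is None:
            best_alpha = float(np.median(self.alphas))
        else:
            xv = (_flatten(val_x) - self._mean) / self._sd
            best_alpha, best_mae = None, np.inf
            for a in self.alphas:
                m = Ridge(alpha=a).fit(xs, train_y)
                mae = float(np.mean(np.abs(m.predict(xv) - val_y)))
                if mae < best_mae:
                    best_alpha, best_mae = float(a), mae
        self.alpha_ = best_alpha
        self.model = Ridge(alpha=best_alpha).fit(xs, train_y)
        return self

    def predict(self, x):
        xs = (_flatten(x) - self._mean) / self._sd
        return self.model.predict(xs)


class GCNPredictor:
    """Adapter giving the spectral GCN the fit/predict interface the CV
    harness expects."""

    def __init__(self, hierarchy, arch: ArchConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.hierarchy = hierarchy
        self.arch = arch or ArchConfig()
        self.train_config = train_config or TrainConfig()
        self.model = None
        self.history = None

    def fit(self, train_x, train_y, val_x, val_y):
        self.model = build_model(self.hierarchy, self.arch)
        self.history = train_model(
            self.model, train_x, train_y, val_x, val_y, self.train_config
        )
        return self

    def predict(self, x):
        return self.model.predict(x)


def fit_baseline(kind: str, train_x, train_y, val_x=None, val_y=None, config=None):
    """Fit a comparator of the given kind ('rf' or 'glm') and return it."""
    if kind == "rf":
        predictor = RandomForestBaseline(**(config or {}))
    elif kind == "glm":
        predictor = RidgeBaseline(**(config or {}))
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return predictor.fit(train_x, train_y, val_x, val_y)


@dataclass
class AblationResult:
    true_mesh: dict[str, float]
    rewired: dict[str, float]
    seed: int
    details: dict = field(default_factory=dict)


def run_ablation(
    features: np.ndarray,
    meta: pd.DataFrame,
    adjacency,
    seed: int,
    levels: int = 3,
    arch: ArchConfig | None = None,
    train_config: TrainConfig | None = None,
    plan: FoldPlan | None = None,
    folds_subset: list[int] | None = None,
    rewired_adjacency=None,
) -> AblationResult:
    """Paired GCN metrics on the true mesh vs a degree-preserving rewiring.

    Both arms share the fold plan, architecture, training configuration and
    seeds; only the graph differs.  ``rewired_adjacency`` overrides the
    rewiring (e.g. passing the true adjacency gives the identical-arms
    control of the harness).
    """
    arch = arch or ArchConfig(seed=seed)
    train_config = train_config or TrainConfig(seed=seed)
    if plan is None:
        plan = make_folds(meta, seed=seed)
    hier_true = coarsen_graph(adjacency, levels)
    if rewired_adjacency is None:
        rewired_adjacency = rewire_random(adjacency, seed)
    hier_rand = coarsen_graph(rewired_adjacency, levels)

    out = {}
    for name, hier in (("true_mesh", hier_true), ("rewired", hier_rand)):
        cv = run_nested_cv(
            features, meta,
            lambda f: GCNPredictor(hier, arch, train_config),
            plan=plan, folds_subset=folds_subset,
        )
        out[name] = cv.scores
    return AblationResult(out["true_mesh"], out["rewired"], seed)


def benchmark_models(
    features: np.ndarray,
    meta: pd.DataFrame,
    hierarchy,
    models: tuple[str, ...] = ("gcn", "rf", "glm"),
    seed: int = 0,
    arch: ArchConfig | None = None,
    train_config: TrainConfig | None = None,
    rf_trees: int = 500,
    plan: FoldPlan | None = None,
    folds_subset: list[int] | None = None,
) -> dict[str, CVOutcome]:
    """Run the requested predictors under byte-identical fold assignments."""
    if plan is None:
        plan = make_folds(meta, seed=seed)
    factories = {
        "gcn": lambda f: GCNPredictor(
            hierarchy, arch or ArchConfig(seed=seed),
            train_config or TrainConfig(seed=seed),
        ),
        "rf": lambda f: RandomForestBaseline(n_trees=rf_trees, seed=seed),
        "glm": lambda f: RidgeBaseline(),
    }
    results = {}
    for name in models:
        results[name] = run_nested_cv(
            features, meta, factories[name], plan=plan, folds_subset=folds_subset
        )
    return results
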