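"""Convolutional efficiency regressor with a binding-energy branch, and
gradient-boosted feature-importance analysis.

The regressor reads the one-hot encoded 30mer through parallel
convolutions of widths 3, 5 and 7 acting directly on the sequence, the
convolutions are flattened and passed through two fully connected layers
to a single linear output trained with mean squared error on the 0-100
efficiency scale.  The binding energy dGB enters in one of two ways:

* ``direct``        — concatenated with the flattened convolutions;
* ``after-collect`` — the convolutions are first collected in a separate
  fully connected layer, and dGB is concatenated with that layer's
  output (the default, which performed best in the ablation).

Training follows a k-fold cross-validation over similarity-closed
partitions: for each fold the network is trained on the remaining
partitions with Adam (minibatches of ``batch_size``), stopping when the
validation MSE has not improved for ``patience`` consecutive epochs and
restoring the best-epoch weights; training is repeated ``seed_repeats``
times and the best run per fold is kept.  The ensemble prediction is the
arithmetic mean over the per-fold best models.  dGB is z-scored with
training-fold statistics before entering the network.

The whole network is implemented in NumPy (im2col convolutions, manual
backprop); the architecture sizes are configuration, not contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _stats
from sklearn.ensemble import GradientBoostingRegressor

logger = logging.getLogger(__name__)

CONV_WIDTHS = (3, 5, 7)
PLACEMENTS = ("direct", "after-collect")


class ConfigError(ValueError):
    pass


class LeakageError(RuntimeError):
    """A holdout record appeared in a training or validation set."""


@dataclass(frozen=True)
class ModelConfig:
    filters_per_width: int = 100
    fc_collect_units: int = 80
    fc1_units: int = 80
    fc2_units: int = 60
    dropout: float = 0.3
    use_dGB: bool = True
    dGB_placement: str = "after-collect"
    learning_rate: float = 0.0001
    batch_size: int = 500
    patience: int = 100
    max_epochs: int = 2000
    seed_repeats: int = 10

    def __post_init__(self):
        if self.dGB_placement not in PLACEMENTS:
            raise ConfigError(f"dGB_placement must be one of {PLACEMENTS}")
        if self.batch_size < 1 or self.patience < 1:
            raise ConfigError("batch_size and patience must be >= 1")


def _relu(x):
    return np.maximum(x, 0.0)


def _patches(X: np.ndarray, w: int) -> np.ndarray:
    """im2col: (N, 30, 4) -> (N, 30-w+1, 4*w)."""
    N, L, C = X.shape
    Lw = L - w + 1
    out = np.empty((N, Lw, C * w), dtype=np.float64)
    for o in range(w):
        out[:, :, o * C:(o + 1) * C] = X[:, o:o + Lw, :]
    return out


class ConvRegressor:
    """One trained network (a single cross-validation fold member)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        F = config.filters_per_width
        self.flat_dim = sum(F * (30 - w + 1) for w in CONV_WIDTHS)
        self.params: dict[str, np.ndarray] = {}

        def he(name, shape, fan_in):
            self.params[name] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        for w in CONV_WIDTHS:
            he(f"Wc{w}", (4 * w, F), 4 * w)
            self.params[f"bc{w}"] = np.zeros(F)
        if config.dGB_placement == "after-collect":
            he("Wcol", (self.flat_dim, config.fc_collect_units), self.flat_dim)
            self.params["bcol"] = np.zeros(config.fc_collect_units)
            z_dim = config.fc_collect_units
        else:
            z_dim = self.flat_dim
        if config.use_dGB:
            z_dim += 1
        he("W1", (z_dim, config.fc1_units), z_dim)
        self.params["b1"] = np.zeros(config.fc1_units)
        he("W2", (config.fc1_units, config.fc2_units), config.fc1_units)
        self.params["b2"] = np.zeros(config.fc2_units)
        he("W3", (config.fc2_units, 1), config.fc2_units)
        self.params["b3"] = np.zeros(1)
        self.dgb_mean = 0.0
        self.dgb_std = 1.0

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward ---------------------------------------------------------
    def _forward(self, P: dict[int, np.ndarray], g: np.ndarray | None,
                 drop_rng: np.random.Generator | None = None):
        cfg = self.config
        cache = {}
        convs = []
        for w in CONV_WIDTHS:
            pre = P[w] @ self.params[f"Wc{w}"] + self.params[f"bc{w}"]
            act = _relu(pre)
            cache[f"pre{w}"] = pre
            convs.append(act.reshape(act.shape[0], -1))
        H0 = np.concatenate(convs, axis=1)
        cache["H0"] = H0
        if cfg.dGB_placement == "after-collect":
            pre_col = H0 @ self.params["Wcol"] + self.params["bcol"]
            Hc = _relu(pre_col)
            cache["pre_col"], cache["Hc"] = pre_col, Hc
            Z = Hc
        else:
            Z = H0
        if cfg.use_dGB:
            Z = np.concatenate([Z, g[:, None]], axis=1)
        cache["Z"] = Z

        def drop(a, key):
            if drop_rng is None or cfg.dropout <= 0:
                return a
            mask = (drop_rng.random(a.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            cache[key] = mask
            return a * mask

        pre1 = Z @ self.params["W1"] + self.params["b1"]
        A1 = drop(_relu(pre1), "m1")
        pre2 = A1 @ self.params["W2"] + self.params["b2"]
        A2 = drop(_relu(pre2), "m2")
        y = (A2 @ self.params["W3"] + self.params["b3"]).ravel()
        cache.update(pre1=pre1, A1=A1, pre2=pre2, A2=A2)
        return y, cache

    def predict(self, X: np.ndarray, dgb: np.ndarray | None = None) -> np.ndarray:
        """Raw predictions for one-hot input (N, 30, 4) and raw-scale dGB."""
        if self.config.use_dGB:
            if dgb is None:
                raise ValueError("model was built with use_dGB=True; dGB values required")
            g = (np.asarray(dgb, dtype=float) - self.dgb_mean) / self.dgb_std
        else:
            g = None
        P = {w: _patches(np.asarray(X, dtype=np.float64), w) for w in CONV_WIDTHS}
        y, _ = self._forward(P, g)
        return y

    # -- backward --------------------------------------------------------
    def _grads(self, P, g, y_true, drop_rng):
        cfg = self.config
        y, c = self._forward(P, g, drop_rng=drop_rng)
        n = y.size
        grads = {}
        dy = (2.0 / n) * (y - y_true)[:, None]
        grads["W3"] = c["A2"].T @ dy
        grads["b3"] = dy.sum(axis=0)
        dA2 = dy @ self.params["W3"].T
        if "m2" in c:
            dA2 = dA2 * c["m2"]
        d2 = dA2 * (c["pre2"] > 0)
        grads["W2"] = c["A1"].T @ d2
        grads["b2"] = d2.sum(axis=0)
        dA1 = d2 @ self.params["W2"].T
        if "m1" in c:
            dA1 = dA1 * c["m1"]
        d1 = dA1 * (c["pre1"] > 0)
        grads["W1"] = c["Z"].T @ d1
        grads["b1"] = d1.sum(axis=0)
        dZ = d1 @ self.params["W1"].T
        if cfg.use_dGB:
            dZ = dZ[:, :-1]
        if cfg.dGB_placement == "after-collect":
            dcol = dZ * (c["pre_col"] > 0)
            grads["Wcol"] = c["H0"].T @ dcol
            grads["bcol"] = dcol.sum(axis=0)
            dH0 = dcol @ self.params["Wcol"].T
        else:
            dH0 = dZ
        F = cfg.filters_per_width
        off = 0
        for w in CONV_WIDTHS:
            Lw = 30 - w + 1
            dAct = dH0[:, off:off + F * Lw].reshape(-1, Lw, F)
            off += F * Lw
            dPre = dAct * (c[f"pre{w}"] > 0)
            grads[f"Wc{w}"] = np.einsum("nlp,nlf->pf", P[w], dPre)
            grads[f"bc{w}"] = dPre.sum(axis=(0, 1))
        mse = float(np.mean((y - y_true) ** 2))
        return mse, grads

    # -- training --------------------------------------------------------
    def fit(self, X_train, g_train, y_train, X_val, g_val, y_val):
        """Adam training with early stopping on validation MSE.

        Returns the per-epoch validation MSE trace; the weights of the
        best epoch are restored before returning.
        """
        cfg = self.config
        rng = np.random.default_rng(self.seed)
        if cfg.use_dGB:
            self.dgb_mean = float(np.mean(g_train))
            self.dgb_std = float(np.std(g_train)) or 1.0
            gt = (np.asarray(g_train, float) - self.dgb_mean) / self.dgb_std
            gv = (np.asarray(g_val, float) - self.dgb_mean) / self.dgb_std
        else:
            gt = gv = None
        Pt = {w: _patches(np.asarray(X_train, np.float64), w) for w in CONV_WIDTHS}
        Pv = {w: _patches(np.asarray(X_val, np.float64), w) for w in CONV_WIDTHS}
        y_train = np.asarray(y_train, float)
        y_val = np.asarray(y_val, float)

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(p) for k, p in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = y_train.size
        best_mse = np.inf
        best_params = {k: p.copy() for k, p in self.params.items()}
        trace = []
        stall = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                Pb = {w: Pt[w][idx] for w in CONV_WIDTHS}
                gb = gt[idx] if gt is not None else None
                _, grads = self._grads(Pb, gb, y_train[idx], drop_rng=rng)
                t += 1
                for k, gr in grads.items():
                    m[k] = b1 * m[k] + (1 - b1) * gr
                    v[k] = b2 * v[k] + (1 - b2) * gr * gr
                    mhat = m[k] / (1 - b1 ** t)
                    vhat = v[k] / (1 - b2 ** t)
                    self.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            val_pred, _ = self._forward(Pv, gv)
            val_mse = float(np.mean((val_pred - y_val) ** 2))
            trace.append(val_mse)
            if val_mse < best_mse - 1e-12:
                best_mse = val_mse
                best_params = {k: p.copy() for k, p in self.params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        self.params = best_params
        self.val_mse = best_mse
        self.val_trace = trace
        return trace


def build_model(config: ModelConfig, seed: int = 0) -> ConvRegressor:
    """Construct an untrained network for the given configuration."""
    return ConvRegressor(config, seed=seed)


@dataclass
class EnsembleModel:
    """Best model per cross-validation fold; predicts by averaging."""

    fold_models: list
    folds: list[int]
    config: ModelConfig
    report: dict = field(default_factory=dict)

    def predict(self, X, dgb=None, clip: bool = False) -> np.ndarray:
        preds = np.stack([m.predict(X, dgb) for m in self.fold_models])
        out = preds.mean(axis=0)
        return np.clip(out, 0.0, 100.0) if clip else out


def train_cv(X, dgb, y, assignment, config: ModelConfig,
             holdout_partition: int | None = None, base_seed: int = 0) -> EnsembleModel:
    """Cross-validated ensemble training over similarity-closed partitions.

    Each partition in turn (excluding ``holdout_partition``, which is
    never touched) is the validation fold while the others train; each
    fold is repeated ``config.seed_repeats`` times with different seeds
    and the run with the lowest validation MSE is kept.
    """
    X = np.asarray(X, np.float64)
    y = np.asarray(y, float)
    dgb = np.asarray(dgb, float) if dgb is not None else None
    parts = sorted(set(int(p) for p in assignment.partition))
    folds = [p for p in parts if p != holdout_partition]
    if len(folds) < 2:
        raise ValueError("need at least 2 partitions besides the holdout")
    if holdout_partition in folds:
        raise LeakageError("holdout partition among training folds")
    holdout_idx = set() if holdout_partition is None else set(assignment.indices(holdout_partition).tolist())

    fold_models = []
    report = {"folds": {}, "holdout_partition": holdout_partition}
    for fold in folds:
        val_idx = assignment.indices(fold)
        train_idx = np.array([i for i in range(y.size)
                              if assignment.partition[i] != fold and i not in holdout_idx])
        if holdout_idx & set(val_idx.tolist()):
            raise LeakageError("holdout records leaked into a validation fold")
        best = None
        seeds = [base_seed * 10_000 + fold * 100 + r for r in range(config.seed_repeats)]
        for s in seeds:
            net = ConvRegressor(config, seed=s)
            net.fit(X[train_idx], None if dgb is None else dgb[train_idx], y[train_idx],
                    X[val_idx], None if dgb is None else dgb[val_idx], y[val_idx])
            if best is None or net.val_mse < best.val_mse:
                best = net
        fold_models.append(best)
        report["folds"][fold] = {"val_mse": best.val_mse, "seed": best.seed,
                                 "epochs": len(best.val_trace), "trace": best.val_trace}
        logger.info("fold %d: val MSE %.3f (seed %d, %d epochs)",
                    fold, best.val_mse, best.seed, len(best.val_trace))
    return EnsembleModel(fold_models, folds, config, report)


# ---------------------------------------------------------------------------
# GBRT feature importance

GBRT_GRID = {
    "learning_rate": (0.08, 0.09, 0.1),
    "max_depth": (3, 5, 7),
    "min_samples_split": (5, 10, 15, 20),
    "min_samples_leaf": (5, 10, 15, 20),
    "n_estimators": (400, 600, 800, 1000),
}


@dataclass(frozen=True)
class GBRTConfig:
    learning_rate: float = 0.1
    max_depth: int = 3
    min_samples_split: int = 5
    min_samples_leaf: int = 5
    n_estimators: int = 400
    seeds_per_fold: int = 5
    allow_off_grid: bool = False

    def __post_init__(self):
        if not self.allow_off_grid:
            for name, grid in GBRT_GRID.items():
                if getattr(self, name) not in grid:
                    raise ConfigError(f"{name}={getattr(self, name)} outside the screen grid "
                                      f"{grid}; pass allow_off_grid=True to override")


def gbrt_importance(features: np.ndarray, y: np.ndarray, assignment,
                    config: GBRTConfig = GBRTConfig(),
                    feature_names: list[str] | None = None,
                    holdout_partition: int | None = None, base_seed: int = 0):
    """Cross-validated GBRT training with normalized Gini importances.

    Per fold, the regressor is fit ``seeds_per_fold`` times and the seed
    with the lowest validation MSE is kept; impurity-based (Gini)
    importances are averaged across the per-fold best models and
    renormalized to sum to 1.  Returns ``(importance, models, report)``;
    ``importance`` is a pandas Series when names are given.
    """
    import pandas as pd

    features = np.asarray(features, float)
    y = np.asarray(y, float)
    parts = sorted(set(int(p) for p in assignment.partition))
    folds = [p for p in parts if p != holdout_partition]
    models, imps = [], []
    report = {}
    for fold in folds:
        val_idx = assignment.indices(fold)
        train_mask = (assignment.partition != fold)
        if holdout_partition is not None:
            train_mask &= (assignment.partition != holdout_partition)
        train_idx = np.nonzero(train_mask)[0]
        best, best_mse = None, np.inf
        for r in range(config.seeds_per_fold):
            gb = GradientBoostingRegressor(
                learning_rate=config.learning_rate, max_depth=config.max_depth,
                min_samples_split=config.min_samples_split,
                min_samples_leaf=config.min_samples_leaf,
                n_estimators=config.n_estimators, loss="squared_error",
                subsample=0.9, random_state=base_seed * 1000 + fold * 10 + r)
            gb.fit(features[train_idx], y[train_idx])
            mse = float(np.mean((gb.predict(features[val_idx]) - y[val_idx]) ** 2))
            if mse < best_mse:
                best, best_mse = gb, mse
        models.append(best)
        imps.append(best.feature_importances_)
        report[fold] = {"val_mse": best_mse}
    mean_imp = np.mean(imps, axis=0)
    mean_imp = mean_imp / mean_imp.sum()
    if feature_names is not None:
        mean_imp = pd.Series(mean_imp, index=feature_names).sort_values(ascending=False)
    return mean_imp, models, report


def spearman(a, b) -> float:
    return float(_stats.spearmanr(a, b)[0])
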