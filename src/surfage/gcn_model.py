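"""Chebyshev spectral graph-convolutional age regressor.

Three Chebyshev-convolution + max-pooling blocks on a coarsened mesh
hierarchy, followed by a dense head mapping the pooled per-vertex channels to
one scalar: the predicted brain age in weeks.  Implemented directly in NumPy
(forward and backward passes, Adam) — the model is small enough at the
1,284-vertex working resolution that no deep-learning framework is needed,
and pure-NumPy arithmetic keeps training bit-reproducible on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from surfage.graphops import GraphHierarchy
from surfage.synthetic_cortex import FeatureMap

_NEG = -1e30  # -inf sentinel for fake vertices in max-pooling


@dataclass
class ArchConfig:
    cheb_order: int = 3
    channels: tuple[int, ...] = (16, 32, 64)
    hidden: int = 64
    n_input_channels: int = 3
    seed: int = 0


@dataclass
class TrainConfig:
    lr: float = 2e-3
    lr_decay: float = 0.5
    lr_decay_every: int = 60
    batch_size: int = 128
    max_epochs: int = 150
    patience: int = 20
    weight_decay: float = 1e-5
    seed: int = 0


@dataclass
class AgeModel:
    """Spectral GCN with learned Chebyshev filter coefficients.

    ``params`` holds, per conv layer i, W{i} of shape (K*C_in, C_out) and
    b{i}; then head weights Wh/bh and output weights Wo/bo.  Feature
    standardization statistics (per vertex and channel, from the training
    set) are part of the model state so that predictions are self-contained.
    """

    hierarchy: GraphHierarchy
    arch: ArchConfig
    params: dict[str, np.ndarray]
    feat_mean: np.ndarray | None = None
    feat_sd: np.ndarray | None = None
    alpha: float | None = None  # bias-correction slope (set by evaluation)
    beta: float | None = None  # bias-correction intercept
    train_echo: dict = field(default_factory=dict)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ---------------- forward/backward ----------------

    def _lt(self, lvl: int, dtype) -> sp.csr_matrix:
        """Rescaled Laplacian 2L/lambda_max - I, cached per level and dtype."""
        cache = self.__dict__.setdefault("_lt_cache", {})
        key = (lvl, np.dtype(dtype).str)
        if key not in cache:
            lap = self.hierarchy.laplacians[lvl]
            lt = (2.0 / self.hierarchy.lambda_max[lvl]) * lap - sp.eye(
                lap.shape[0], format="csr"
            )
            cache[key] = sp.csr_matrix(lt, dtype=dtype)
        return cache[key]

    def _cheb_stack(self, x: np.ndarray, lvl: int) -> np.ndarray:
        """(B, V, Cin) -> (B, V, K*Cin) stack of T_k(Lt) X, k-major."""
        k = self.arch.cheb_order
        lt = self._lt(lvl, x.dtype)
        bsz, v, cin = x.shape
        out = np.empty((bsz, v, k, cin), dtype=x.dtype)
        out[:, :, 0, :] = x
        if k > 1:
            prev = np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(v, bsz * cin)
            curr = lt @ prev
            out[:, :, 1, :] = curr.reshape(v, bsz, cin).transpose(1, 0, 2)
            for i in range(2, k):
                nxt = 2.0 * (lt @ curr) - prev
                out[:, :, i, :] = nxt.reshape(v, bsz, cin).transpose(1, 0, 2)
                prev, curr = curr, nxt
        return out.reshape(bsz, v, k * cin)

    def input_basis(self, x_std: np.ndarray) -> np.ndarray:
        """Precompute the first layer's Chebyshev stack for standardized
        features; it depends only on the inputs, not on the parameters, so
        it can be shared across all training epochs."""
        z = self.hierarchy.permute_features(x_std)
        return self._cheb_stack(z, 0)

    def _conv(self, x: np.ndarray, lvl: int, w: np.ndarray, b: np.ndarray):
        xhat = self._cheb_stack(x, lvl)
        return xhat @ w + b, xhat

    def _conv_backward(self, d_y, xhat, w, lvl, cin, need_dx=True):
        k = self.arch.cheb_order
        bsz, v, cout = d_y.shape
        dw = xhat.reshape(-1, k * cin).T @ d_y.reshape(-1, cout)
        db = d_y.sum(axis=(0, 1))
        if not need_dx:
            return dw, db, None
        dxhat = (d_y @ w.T).reshape(bsz, v, k, cin)
        d_stack = np.moveaxis(dxhat, 2, 0)  # (K, B, V, Cin)
        # adjoint: dX = sum_k T_k(Lt) dXhat_k (T_k symmetric); run the
        # recursion jointly on all K slices and pick slice k of T_k
        lt = self._lt(lvl, d_y.dtype)

        def matvec(t):
            flat = np.moveaxis(t, 2, 0).reshape(v, -1)
            return np.moveaxis((lt @ flat).reshape(v, k, bsz, cin), 0, 2)

        acc = d_stack[0].copy()
        if k > 1:
            t_prev, t_curr = d_stack, matvec(d_stack)
            acc += t_curr[1]
            for i in range(2, k):
                t_next = 2.0 * matvec(t_curr) - t_prev
                acc += t_next[i]
                t_prev, t_curr = t_curr, t_next
        return dw, db, acc

    def forward(
        self,
        x: np.ndarray | None,
        cache: dict | None = None,
        input_basis: np.ndarray | None = None,
    ) -> np.ndarray:
        """x: (batch, n_real_vertices, 3) standardized features -> (batch,) ages.

        ``input_basis`` may carry a precomputed first-layer Chebyshev stack
        (see :meth:`input_basis`), in which case ``x`` is ignored.
        """
        h = self.hierarchy
        z = h.permute_features(x) if input_basis is None else None
        if cache is not None:
            cache["inputs"] = []
        n_in = self.arch.n_input_channels
        for i in range(len(self.arch.channels)):
            w, b = self.params[f"W{i}"], self.params[f"b{i}"]
            if i == 0 and input_basis is not None:
                xhat = input_basis
                y = xhat @ w + b
                cin = n_in
            else:
                cin = z.shape[2]
                y, xhat = self._conv(z, i, w, b)
            relu_mask = y > 0
            y = y * relu_mask
            # masked stride-2 max-pool; fake vertices can never win
            mask = h.real_mask[i]
            ym = np.where(mask[None, :, None], y, _NEG)
            a0, a1 = ym[:, 0::2, :], ym[:, 1::2, :]
            take1 = a1 > a0
            pooled = np.where(take1, a1, a0)
            fake_parent = ~h.real_mask[i + 1]
            pooled[:, fake_parent, :] = 0.0
            if cache is not None:
                cache["inputs"].append(
                    dict(cin=cin, xhat=xhat, relu=relu_mask, take1=take1,
                         fake_parent=fake_parent)
                )
            z = pooled
        bsz = z.shape[0]
        flat = z.reshape(bsz, -1)
        hpre = flat @ self.params["Wh"] + self.params["bh"]
        hmask = hpre > 0
        hact = hpre * hmask
        out = hact @ self.params["Wo"] + self.params["bo"]
        if cache is not None:
            cache.update(flat=flat, hmask=hmask, hact=hact, z_shape=z.shape)
        return out[:, 0]

    def backward(self, x, d_out, cache) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        d = d_out[:, None]  # (B, 1)
        grads["Wo"] = cache["hact"].T @ d
        grads["bo"] = d.sum(axis=0)
        dh = (d @ self.params["Wo"].T) * cache["hmask"]
        grads["Wh"] = cache["flat"].T @ dh
        grads["bh"] = dh.sum(axis=0)
        dz = (dh @ self.params["Wh"].T).reshape(cache["z_shape"])
        for i in range(len(self.arch.channels) - 1, -1, -1):
            info = cache["inputs"][i]
            dz[:, info["fake_parent"], :] = 0.0
            take1 = info["take1"]
            bsz, vc, c = dz.shape
            dy = np.zeros((bsz, vc * 2, c), dtype=dz.dtype)
            dy[:, 0::2, :] = np.where(take1, 0.0, dz)
            dy[:, 1::2, :] = np.where(take1, dz, 0.0)
            dy *= info["relu"]
            dw, db, dz = self._conv_backward(
                dy, info["xhat"], self.params[f"W{i}"], i, info["cin"],
                need_dx=(i > 0),
            )
            grads[f"W{i}"] = dw
            grads[f"b{i}"] = db
        return grads

    # ---------------- standardization & prediction ----------------

    def standardize(self, x: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            raise RuntimeError("model has no feature statistics; train it first")
        return ((x - self.feat_mean) / self.feat_sd).astype(np.float32)

    def predict(self, features: np.ndarray | list[FeatureMap]) -> np.ndarray:
        """Raw predicted brain age (weeks), one per scan; order preserved."""
        if isinstance(features, list):
            features = np.stack([fm.values for fm in features])
        if features.ndim == 2:
            features = features[None]
        if features.shape[1] != self.hierarchy.n_real:
            raise ValueError(
                f"expected {self.hierarchy.n_real} vertices, got {features.shape[1]}"
            )
        out = []
        for start in range(0, features.shape[0], 256):
            out.append(self.forward(self.standardize(features[start : start + 256])))
        return np.concatenate(out)

    # ---------------- persistence ----------------

    def save(self, path: str) -> None:
        arrays = dict(self.params)
        if self.feat_mean is not None:
            arrays["_feat_mean"] = self.feat_mean
            arrays["_feat_sd"] = self.feat_sd
        h = self.hierarchy
        arrays["_perm"] = h.perm
        arrays["_lambda_max"] = np.asarray(h.lambda_max)
        for i, lap in enumerate(h.laplacians):
            arrays[f"_lap{i}_data"] = lap.data
            arrays[f"_lap{i}_indices"] = lap.indices
            arrays[f"_lap{i}_indptr"] = lap.indptr
            arrays[f"_lap{i}_shape"] = np.asarray(lap.shape)
            arrays[f"_mask{i}"] = h.real_mask[i]
        header = dict(
            arch=dict(
                cheb_order=self.arch.cheb_order,
                channels=list(self.arch.channels),
                hidden=self.arch.hidden,
                n_input_channels=self.arch.n_input_channels,
                seed=self.arch.seed,
            ),
            n_levels=len(h.laplacians),
            n_real=h.n_real,
            alpha=self.alpha,
            beta=self.beta,
            train_echo=self.train_echo,
        )
        arrays["_header"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "AgeModel":
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        header = json.loads(bytes(data["_header"]).decode())
        laps, masks = [], []
        for i in range(header["n_levels"]):
            laps.append(
                sp.csr_matrix(
                    (data[f"_lap{i}_data"], data[f"_lap{i}_indices"],
                     data[f"_lap{i}_indptr"]),
                    shape=tuple(data[f"_lap{i}_shape"]),
                )
            )
            masks.append(data[f"_mask{i}"].astype(bool))
        hier = GraphHierarchy(
            laps, data["_perm"], masks, list(data["_lambda_max"]), header["n_real"]
        )
        a = header["arch"]
        arch = ArchConfig(a["cheb_order"], tuple(a["channels"]), a["hidden"],
                          a["n_input_channels"], a["seed"])
        params = {k: data[k] for k in data.files if not k.startswith("_")}
        model = cls(hier, arch, params,
                    feat_mean=data.get("_feat_mean"), feat_sd=data.get("_feat_sd"),
                    alpha=header["alpha"], beta=header["beta"],
                    train_echo=header["train_echo"])
        return model


def build_model(hierarchy: GraphHierarchy, arch: ArchConfig | None = None) -> AgeModel:
    """Initialize an untrained model (Glorot-uniform, seeded)."""
    arch = arch or ArchConfig()
    n_pool = len(arch.channels)
    if hierarchy.depth < n_pool:
        raise ValueError(
            f"hierarchy depth {hierarchy.depth} < {n_pool} pooling layers"
        )
    rng = np.random.default_rng(arch.seed)
    params: dict[str, np.ndarray] = {}

    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        # float32 throughout: memory-bandwidth-bound on CPU
        return rng.uniform(-lim, lim, size=shape).astype(np.float32)

    cin = arch.n_input_channels
    for i, cout in enumerate(arch.channels):
        params[f"W{i}"] = glorot((arch.cheb_order * cin, cout))
        params[f"b{i}"] = np.zeros(cout, dtype=np.float32)
        cin = cout
    v_final = hierarchy.laplacians[n_pool].shape[0]
    params["Wh"] = glorot((v_final * arch.channels[-1], arch.hidden))
    params["bh"] = np.zeros(arch.hidden, dtype=np.float32)
    params["Wo"] = glorot((arch.hidden, 1))
    params["bo"] = np.zeros(1, dtype=np.float32)
    return AgeModel(hierarchy, arch, params)


def expected_parameter_count(hierarchy: GraphHierarchy, arch: ArchConfig) -> int:
    """Closed-form parameter count: K*C_in*C_out + C_out per conv layer,
    plus the dense head."""
    total, cin = 0, arch.n_input_channels
    for cout in arch.channels:
        total += arch.cheb_order * cin * cout + cout
        cin = cout
    v_final = hierarchy.laplacians[len(arch.channels)].shape[0]
    total += v_final * arch.channels[-1] * arch.hidden + arch.hidden
    total += arch.hidden + 1
    return total


def train_model(
    model: AgeModel,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig | None = None,
) -> dict:
    """Train by MSE with Adam and early stopping on validation MAE.

    Feature standardization statistics are computed from the training set
    only and stored on the model.  Returns the per-epoch history; the model
    is left at the best-validation parameters.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    train_y = np.asarray(train_y, dtype=float)
    val_y = np.asarray(val_y, dtype=float)

    mean = train_x.mean(axis=0)
    sd = train_x.std(axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    model.feat_mean, model.feat_sd = mean, sd
    xs = ((train_x - mean) / sd).astype(np.float32)
    vs = ((val_x - mean) / sd).astype(np.float32)
    # first-layer Chebyshev stacks are parameter-free; compute them once
    xs_basis = model.input_basis(xs)
    vs_basis = model.input_basis(vs)
    model.params["bo"] = (model.params["bo"] + train_y.mean()).astype(np.float32)
    train_y32 = train_y.astype(np.float32)

    mom = {k: np.zeros_like(v) for k, v in model.params.items()}
    vel = {k: np.zeros_like(v) for k, v in model.params.items()}
    t = 0
    best = {"val_mae": np.inf, "params": None, "epoch": -1}
    history = {"train_loss": [], "val_mae": []}
    n = xs.shape[0]

    for epoch in range(cfg.max_epochs):
        lr = cfg.lr * cfg.lr_decay ** (epoch // cfg.lr_decay_every)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = xs_basis[idx], train_y32[idx]
            cache: dict = {}
            pred = model.forward(None, cache, input_basis=xb)
            resid = pred - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN/inf training loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            grads = model.backward(None, 2.0 * resid / len(idx), cache)
            t += 1
            for k, g in grads.items():
                if cfg.weight_decay and k.startswith("W"):
                    g = g + cfg.weight_decay * model.params[k]
                mom[k] = 0.9 * mom[k] + 0.1 * g
                vel[k] = 0.999 * vel[k] + 0.001 * g * g
                mhat = mom[k] / (1 - 0.9**t)
                vhat = vel[k] / (1 - 0.999**t)
                model.params[k] = model.params[k] - lr * mhat / (np.sqrt(vhat) + 1e-8)
        val_pred = model.forward(None, input_basis=vs_basis)
        val_mae = float(np.mean(np.abs(val_pred - val_y)))
        history["train_loss"].append(epoch_loss / n)
        history["val_mae"].append(val_mae)
        if val_mae < best["val_mae"] - 1e-6:
            best = {
                "val_mae": val_mae,
                "params": {k: v.copy() for k, v in model.params.items()},
                "epoch": epoch,
            }
        elif epoch - best["epoch"] >= cfg.patience:
            break
    if best["params"] is not None:
        model.params = best["params"]
    model.train_echo = dict(
        loss="mse", optimizer="adam", lr=cfg.lr, batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs, patience=cfg.patience, seed=cfg.seed,
        stopped_epoch=len(history["val_mae"]), best_epoch=best["epoch"],
        best_val_mae=best["val_mae"],
    )
    return history


def predict_age(model: AgeModel, features: np.ndarray | list[FeatureMap]) -> np.ndarray:
    """Raw predicted brain age (PBA, weeks) per scan."""
    return model.predict(features)
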