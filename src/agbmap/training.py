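"""Spatially blocked 8-fold cross-validation with early stopping.

Protocol: in iteration k, fold k is the test zone, fold (k+1) mod n the
validation zone, and the remaining six folds train the network. Training
monitors the validation loss — stopping when it has not improved for 35
epochs (500 epochs at most, weights restored to the best epoch) and
multiplying the learning rate by 0.2 whenever a 25-epoch plateau is seen.
The loss is the masked mean absolute error; the optimizer is Adam with the
customary defaults.

Inputs are standardized per band with statistics computed on the training
folds only, and the target is standardized the same way (inverted at
prediction time), so the monitored loss lives on a unit scale regardless of
the biomass range. Test metrics — MAE and RMSE in Mg/ha, R² — are computed
pixel-wise, over valid pixels only, in physical units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import UNet, UNetConfig, masked_mae, masked_mae_grad
from .nnops import Adam
from .patching import FoldAssignment, PatchSet

__all__ = ["TrainingPolicy", "EpochController", "Standardizer",
           "TrainedFold", "MetricsReport", "train_fold", "cross_validate",
           "compute_metrics"]


@dataclass
class TrainingPolicy:
    """The training schedule; defaults follow the experimental protocol."""

    max_epochs: int = 500
    early_stop_patience: int = 35
    lr_plateau_patience: int = 25
    lr_factor: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32

    def __post_init__(self):
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_plateau_patience >= self.early_stop_patience:
            raise ValueError(
                "plateau patience must be shorter than early-stop patience "
                "so a reduction can fire before stopping")


class EpochController:
    """Early-stopping and plateau bookkeeping, one `update` per epoch.

    'Improvement' means a strictly lower validation loss than the best seen
    so far (no minimum delta). After a learning-rate reduction the plateau
    counter resets; the early-stop counter does not.
    """

    def __init__(self, policy: TrainingPolicy):
        self.policy = policy
        self.best_loss = math.inf
        self.best_epoch = 0
        self._es_count = 0
        self._plateau_count = 0

    def update(self, epoch: int, val_loss: float):
        """Returns (improved, reduce_lr, stop) for this epoch (1-based)."""
        improved = val_loss < self.best_loss
        if improved:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self._es_count = 0
            self._plateau_count = 0
        else:
            self._es_count += 1
            self._plateau_count += 1
        reduce_lr = False
        if self._plateau_count >= self.policy.lr_plateau_patience:
            reduce_lr = True
            self._plateau_count = 0
        stop = (self._es_count >= self.policy.early_stop_patience
                or epoch >= self.policy.max_epochs)
        return improved, reduce_lr, stop


@dataclass
class Standardizer:
    """Per-band input and target standardization from training folds only."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float

    @classmethod
    def fit(cls, X, Y, M) -> "Standardizer":
        m3 = M[:, :, :, None]
        n = M.sum()
        if n == 0:
            raise ValueError("no valid pixels to fit the standardizer")
        x_mean = (X * m3).sum(axis=(0, 1, 2)) / n
        x_var = (((X - x_mean) * m3) ** 2).sum(axis=(0, 1, 2)) / n
        x_std = np.sqrt(np.maximum(x_var, 1e-12))
        yv = Y[M]
        y_std = float(max(yv.std(), 1e-12))
        return cls(x_mean=x_mean, x_std=x_std,
                   y_mean=float(yv.mean()), y_std=y_std)

    def transform_x(self, X, M):
        Xs = (X - self.x_mean) / self.x_std
        return np.where(M[:, :, :, None], Xs, 0.0)

    def transform_y(self, Y):
        return (Y - self.y_mean) / self.y_std

    def inverse_y(self, Ys):
        return Ys * self.y_std + self.y_mean


@dataclass
class TrainedFold:
    """A fitted network plus the statistics needed to apply it."""

    model: UNet
    scaler: Standardizer
    log: pd.DataFrame

    def predict(self, X, M) -> np.ndarray:
        """(N, P, P, C) patches -> (N, P, P) AGB predictions in Mg/ha."""
        Xs = self.scaler.transform_x(X, M)
        return self.scaler.inverse_y(self.model.predict(Xs))

    def save(self, weights_path, config_path) -> None:
        """Checkpoint: weights + scaler in one npz, JSON config sidecar."""
        self.model.save(weights_path, config_path)
        with np.load(weights_path) as data:
            arrays = dict(data)
        arrays.update(sc_xm=self.scaler.x_mean, sc_xs=self.scaler.x_std,
                      sc_ym=np.float64(self.scaler.y_mean),
                      sc_ys=np.float64(self.scaler.y_std))
        np.savez(weights_path, **arrays)

    @classmethod
    def load(cls, weights_path, config_path) -> "TrainedFold":
        model = UNet.load(weights_path, config_path)
        with np.load(weights_path) as data:
            scaler = Standardizer(
                x_mean=data["sc_xm"], x_std=data["sc_xs"],
                y_mean=float(data["sc_ym"]), y_std=float(data["sc_ys"]))
        return cls(model=model, scaler=scaler, log=pd.DataFrame())


def train_fold(model: UNet, train_patches, val_patches,
               policy: TrainingPolicy = None, seed: int = 0) -> TrainedFold:
    """Fit one fold: mini-batch Adam on masked MAE with the stated schedule.

    ``train_patches`` / ``val_patches`` are (X, Y, M) triples of
    (N, P, P, C), (N, P, P) and boolean (N, P, P) arrays. The returned
    model carries the weights of the best-validation epoch.
    """
    policy = policy or TrainingPolicy()
    Xtr, Ytr, Mtr = train_patches
    Xva, Yva, Mva = val_patches
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("empty training or validation set")
    scaler = Standardizer.fit(Xtr, Ytr, Mtr)
    Xtr_s = np.moveaxis(scaler.transform_x(Xtr, Mtr), 3, 1)
    Ytr_s = scaler.transform_y(Ytr)
    Xva_s = np.moveaxis(scaler.transform_x(Xva, Mva), 3, 1)
    Yva_s = scaler.transform_y(Yva)

    opt = Adam(model.parameters(), model.grads(), lr=policy.learning_rate)
    ctrl = EpochController(policy)
    rng = np.random.default_rng(seed)
    best_state = model.get_state()
    rows = []
    n = len(Xtr_s)
    for epoch in range(1, policy.max_epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        for s in range(0, n, policy.batch_size):
            idx = order[s:s + policy.batch_size]
            xb, yb, mb = Xtr_s[idx], Ytr_s[idx], Mtr[idx]
            if not mb.any():
                continue
            pred = model.forward(xb, training=True)[:, 0]
            batch_losses.append(masked_mae(pred, yb, mb))
            dpred = masked_mae_grad(pred, yb, mb)
            model.backward(dpred[:, None])
            opt.step()
        val_pred = model.forward(Xva_s, training=False)[:, 0]
        val_loss = masked_mae(val_pred, Yva_s, Mva)
        improved, reduce_lr, stop = ctrl.update(epoch, val_loss)
        rows.append({"epoch": epoch,
                     "train_loss": float(np.mean(batch_losses)),
                     "val_loss": val_loss, "lr": opt.lr})
        if improved:
            best_state = model.get_state()
        if reduce_lr:
            opt.lr *= policy.lr_factor
        if stop:
            break
    model.set_state(best_state)
    log = pd.DataFrame(rows)
    log.attrs["best_epoch"] = ctrl.best_epoch
    log.attrs["best_val_loss"] = ctrl.best_loss
    return TrainedFold(model=model, scaler=scaler, log=log)


def compute_metrics(pred, target):
    """Pixel-wise MAE, RMSE and R² = 1 − Σe²/Σ(t − t̄)².

    R² is ``None`` when the target has zero variance (undefined).
    """
    pred = np.asarray(pred, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    if pred.shape != target.shape:
        raise ValueError("pred/target length mismatch")
    if len(pred) < 2:
        raise ValueError("need at least 2 values")
    e = pred - target
    mae = float(np.abs(e).mean())
    rmse = float(np.sqrt((e ** 2).mean()))
    ss_tot = float(((target - target.mean()) ** 2).sum())
    r2 = None if ss_tot == 0 else float(1.0 - (e ** 2).sum() / ss_tot)
    return mae, rmse, r2


@dataclass
class MetricsReport:
    """Per-fold test metrics and their mean ± SD aggregate."""

    model_name: str
    per_fold: pd.DataFrame          # columns: fold, mae, rmse, r2

    @property
    def aggregate(self) -> pd.DataFrame:
        agg = self.per_fold[["mae", "rmse", "r2"]].agg(["mean", "std"])
        return agg

    def summary(self) -> str:
        a = self.aggregate
        lines = [f"{self.model_name}: 8-fold spatial cross-validation"
                 if len(self.per_fold) == 8 else
                 f"{self.model_name}: {len(self.per_fold)}-fold "
                 "spatial cross-validation"]
        for m, unit in (("mae", "Mg/ha"), ("rmse", "Mg/ha"), ("r2", "")):
            lines.append(
                f"  {m.upper():5s} {a.loc['mean', m]:8.2f} ± "
                f"{a.loc['std', m]:.2f} {unit}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        df = self.per_fold.copy()
        agg = self.aggregate
        df.loc[len(df)] = {"fold": "mean", "mae": agg.loc["mean", "mae"],
                           "rmse": agg.loc["mean", "rmse"],
                           "r2": agg.loc["mean", "r2"]}
        df.to_csv(path, index=False)


def _fold_patches(patchset: PatchSet, idx):
    return patchset.X[idx], patchset.Y[idx], patchset.valid_mask[idx]


def cross_validate(patchset: PatchSet, folds: FoldAssignment,
                   policy: TrainingPolicy = None,
                   config: UNetConfig = None, seed: int = 0,
                   model_name: str = "unet-raw-bands",
                   test_folds=None) -> MetricsReport:
    """Run the rotated 6/1/1 protocol over all folds.

    Iteration k: test = fold k, validation = fold (k+1) mod n, training =
    the rest. The three sets are asserted disjoint before any fitting.
    ``test_folds`` restricts which iterations run (all by default) without
    changing the rotation itself.
    """
    policy = policy or TrainingPolicy()
    n_folds = folds.n_folds
    if config is None:
        config = UNetConfig(in_channels=patchset.n_channels,
                            patch_size=patchset.patch_size)
    for f in range(n_folds):
        if len(folds.members(f)) == 0:
            raise ValueError(f"fold {f} is empty")
    iterations = range(n_folds) if test_folds is None else test_folds
    rows = []
    trained = {}
    for k in iterations:
        test_idx = folds.members(k)
        val_idx = folds.members((k + 1) % n_folds)
        train_idx = np.concatenate(
            [folds.members(f) for f in range(n_folds)
             if f not in (k, (k + 1) % n_folds)])
        assert not (set(test_idx) & set(train_idx)), "train/test leakage"
        assert not (set(test_idx) & set(val_idx)), "val/test leakage"
        assert not (set(val_idx) & set(train_idx)), "train/val leakage"
        model = UNet(config, seed=seed * 1009 + k)
        fitted = train_fold(model, _fold_patches(patchset, train_idx),
                            _fold_patches(patchset, val_idx),
                            policy, seed=seed * 2003 + k)
        Xt, Yt, Mt = _fold_patches(patchset, test_idx)
        pred = fitted.predict(Xt, Mt)
        mae, rmse, r2 = compute_metrics(pred[Mt], Yt[Mt])
        rows.append({"fold": k, "mae": mae, "rmse": rmse, "r2": r2})
        trained[k] = fitted
    report = MetricsReport(model_name=model_name,
                           per_fold=pd.DataFrame(rows))
    report.trained_folds = trained
    return report
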