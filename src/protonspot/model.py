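"""Planned-to-delivered spot mapping: a small feedforward regression network.

The mapping from planning parameters (target x, target y, target MU,
gantry angle, snout extension, nominal energy) to the delivered spot
(x, y, MU) is learned by a single-hidden-layer network with five tanh
units and a linear output layer — 53 free parameters for the 6-5-3
architecture.  Inputs and outputs are standardized on the training split;
training minimizes the least-squares objective with a Levenberg-Marquardt
step (the natural choice at this parameter count, where the full
Gauss-Newton system is a 53x53 solve), with a quasi-Newton fallback.
The data are split 70/15/15 into train/validation/test; the validation
split drives early stopping and the test split alone feeds the reported
fit metrics.

The estimator follows the scikit-learn contract (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
composes with sklearn model selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .logfile import FEATURE_COLUMNS, TARGET_COLUMNS, LogFile, LogHeader, SpotRecord
from .logfile import aggregate_pulses_to_spots, extract_plan_features, spot_records_to_frame
from .plan import TreatmentPlan


@dataclass
class TrainConfig:
    hidden_neurons: int = 5
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    max_iter: int = 200
    patience: int = 20
    seed: int = 0
    solver: str = "levenberg_marquardt"  # or "quasi_newton"

    def __post_init__(self) -> None:
        if self.hidden_neurons < 1:
            raise ValueError("hidden_neurons must be >= 1")
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class FitMetrics:
    """Held-out test-split metrics of a trained model."""

    mse_standardized: float          # MSE on standardized targets
    r2_standardized: float           # overall R^2 on standardized targets
    r2_raw: float                    # overall R^2 on raw-unit targets
    per_output_r2_raw: dict[str, float]
    n_train: int
    n_val: int
    n_test: int


def split_dataset(features, targets, train_frac: float = 0.70, val_frac: float = 0.15,
                  test_frac: float = 0.15, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/val/test index partition, reproducible from seed."""
    n = len(features)
    if len(targets) != n:
        raise ValueError("features and targets differ in length")
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if abs(train_frac + val_frac + test_frac - 1.0) > 1e-9 or min(
            train_frac, val_frac, test_frac) < 0:
        raise ValueError("invalid split fractions")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(n * train_frac))
    n_val = int(round(n * val_frac))
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def assemble_dataset(beams: list[tuple[list[SpotRecord], LogHeader]]
                     ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Row-aligned feature (6-col) and target (3-col) tables from aggregated spots.

    Spots with zero delivered MU have no defined delivered position and are
    excluded; the count of exclusions is returned.
    """
    frames = [spot_records_to_frame(records, header) for records, header in beams
              if records]
    if not frames:
        raise ValueError("no spot records supplied")
    df = pd.concat(frames, ignore_index=True)
    n_excluded = int(df["zero_mu"].sum())
    df = df[~df["zero_mu"]]
    return (df[FEATURE_COLUMNS].reset_index(drop=True),
            df[TARGET_COLUMNS].reset_index(drop=True),
            n_excluded)


def dataset_from_logs(logs: list[LogFile]) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    return assemble_dataset([(aggregate_pulses_to_spots(log), log.header) for log in logs])


def _forward(Xs: np.ndarray, W1, b1, W2, b2) -> tuple[np.ndarray, np.ndarray]:
    H = np.tanh(Xs @ W1.T + b1)
    return H, H @ W2.T + b2


class SpotErrorNet(RegressorMixin, BaseEstimator):
    """Shallow feedforward delivered-spot regressor (tanh hidden layer, linear out).

    Parameters
    ----------
    hidden_units : width of the single hidden layer (default 5).
    train_frac, val_frac, test_frac : internal split fractions (default 70/15/15).
    max_iter : maximum accepted optimizer steps.
    patience : validation evaluations without improvement before stopping.
    solver : "levenberg_marquardt" (default) or "quasi_newton" (L-BFGS-B).
    random_state : seed for the split and the weight initialization.

    Fitted attributes (trailing underscore) hold the normalization statistics,
    weight matrices, the training-feature ranges (for extrapolation warnings)
    and the held-out :class:`FitMetrics`.
    """

    def __init__(self, hidden_units: int = 5, train_frac: float = 0.70,
                 val_frac: float = 0.15, test_frac: float = 0.15,
                 max_iter: int = 200, patience: int = 20,
                 solver: str = "levenberg_marquardt", random_state: int | None = 0):
        self.hidden_units = hidden_units
        self.train_frac = train_frac
        self.val_frac = val_frac
        self.test_frac = test_frac
        self.max_iter = max_iter
        self.patience = patience
        self.solver = solver
        self.random_state = random_state

    # -- parameter vector packing -------------------------------------------------
    def _shapes(self, n_features: int, n_outputs: int):
        H = self.hidden_units
        return (H, n_features), (H,), (n_outputs, H), (n_outputs,)

    def _unpack(self, theta: np.ndarray, n_features: int, n_outputs: int):
        shapes = self._shapes(n_features, n_outputs)
        parts = []
        k = 0
        for shp in shapes:
            size = int(np.prod(shp))
            parts.append(theta[k:k + size].reshape(shp))
            k += size
        return parts

    @staticmethod
    def _pack(W1, b1, W2, b2) -> np.ndarray:
        return np.concatenate([W1.ravel(), b1.ravel(), W2.ravel(), b2.ravel()])

    def _coerce_X(self, X):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            if hasattr(self, "feature_names_in_"):
                X = X[list(self.feature_names_in_)]
            elif set(FEATURE_COLUMNS) <= set(names):
                X = X[FEATURE_COLUMNS]
            return np.asarray(X, dtype=float), list(X.columns)
        return np.asarray(X, dtype=float), None

    # -- training -----------------------------------------------------------------
    def fit(self, X, y) -> "SpotErrorNet":
        X, feat_names = self._coerce_X(X)
        if isinstance(y, pd.DataFrame):
            y = np.asarray(y, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X and y must be 2-D with matching length")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in training data")
        n, F = X.shape
        O = y.shape[1]
        tr, va, te = split_dataset(X, y, self.train_frac, self.val_frac,
                                   self.test_frac,
                                   seed=0 if self.random_state is None else self.random_state)
        self.input_mean_ = X[tr].mean(axis=0)
        self.input_scale_ = np.where(X[tr].std(axis=0) > 0, X[tr].std(axis=0), 1.0)
        self.output_mean_ = y[tr].mean(axis=0)
        self.output_scale_ = np.where(y[tr].std(axis=0) > 0, y[tr].std(axis=0), 1.0)
        Xs = (X - self.input_mean_) / self.input_scale_
        Ys = (y - self.output_mean_) / self.output_scale_

        rng = np.random.default_rng(self.random_state)
        H = self.hidden_units
        W1 = rng.uniform(-0.7, 0.7, size=(H, F))
        b1 = rng.uniform(-0.7, 0.7, size=H)
        W2 = rng.uniform(-0.5, 0.5, size=(O, H))
        b2 = np.zeros(O)
        theta0 = self._pack(W1, b1, W2, b2)

        if self.solver == "levenberg_marquardt":
            theta, n_iter = self._fit_lm(theta0, Xs[tr], Ys[tr], Xs[va], Ys[va], F, O)
        elif self.solver == "quasi_newton":
            theta, n_iter = self._fit_qn(theta0, Xs[tr], Ys[tr], Xs[va], Ys[va], F, O)
        else:
            raise ValueError(f"unknown solver {self.solver!r}")

        self.W1_, self.b1_, self.W2_, self.b2_ = self._unpack(theta, F, O)
        self.n_iter_ = n_iter
        self.n_features_in_ = F
        if feat_names is not None:
            self.feature_names_in_ = np.asarray(feat_names, dtype=object)
        self.feature_range_ = np.stack([X.min(axis=0), X.max(axis=0)])

        # held-out metrics on the test split only
        _, pred_s = _forward(Xs[te], self.W1_, self.b1_, self.W2_, self.b2_)
        resid_s = pred_s - Ys[te]
        mse = float(np.mean(resid_s ** 2))
        sst_s = float(np.sum((Ys[te] - Ys[te].mean(axis=0)) ** 2))
        r2_s = 1.0 - float(np.sum(resid_s ** 2)) / sst_s if sst_s > 0 else float("nan")
        pred = pred_s * self.output_scale_ + self.output_mean_
        resid = pred - y[te]
        sst = float(np.sum((y[te] - y[te].mean(axis=0)) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else float("nan")
        out_names = TARGET_COLUMNS if O == len(TARGET_COLUMNS) else [f"y{i}" for i in range(O)]
        per_out = {}
        for j, name in enumerate(out_names):
            sst_j = float(np.sum((y[te, j] - y[te, j].mean()) ** 2))
            per_out[name] = (1.0 - float(np.sum(resid[:, j] ** 2)) / sst_j
                             if sst_j > 0 else float("nan"))
        self.metrics_ = FitMetrics(mse, r2_s, r2, per_out, len(tr), len(va), len(te))
        self.split_indices_ = (tr, va, te)
        return self

    def _residual_jacobian(self, theta, Xs, Ys, F, O):
        W1, b1, W2, b2 = self._unpack(theta, F, O)
        Hid, pred = _forward(Xs, W1, b1, W2, b2)
        r = pred - Ys                                   # (n, O)
        n = len(Xs)
        G = 1.0 - Hid ** 2                              # tanh'
        H = self.hidden_units
        J_W1 = np.einsum("oh,nh,nf->nohf", W2, G, Xs).reshape(n, O, H * F)
        J_b1 = np.einsum("oh,nh->noh", W2, G)
        J_W2 = np.zeros((n, O, O * H))
        J_b2 = np.zeros((n, O, O))
        for o in range(O):
            J_W2[:, o, o * H:(o + 1) * H] = Hid
            J_b2[:, o, o] = 1.0
        J = np.concatenate([J_W1, J_b1, J_W2, J_b2], axis=2).reshape(n * O, -1)
        return r.reshape(-1), J

    def _val_loss(self, theta, Xv, Yv, F, O):
        W1, b1, W2, b2 = self._unpack(theta, F, O)
        _, pred = _forward(Xv, W1, b1, W2, b2)
        return float(np.mean((pred - Yv) ** 2))

    def _fit_lm(self, theta, Xt, Yt, Xv, Yv, F, O):
        """Levenberg-Marquardt on the full least-squares objective with
        validation-based early stopping."""
        lam = 1e-2
        r, J = self._residual_jacobian(theta, Xt, Yt, F, O)
        loss = float(r @ r)
        best_theta = theta.copy()
        best_val = self._val_loss(theta, Xv, Yv, F, O) if len(Xv) else np.inf
        stall = 0
        n_iter = 0
        for _ in range(self.max_iter):
            A = J.T @ J
            g = J.T @ r
            if float(np.linalg.norm(g)) < 1e-12:
                break
            accepted = False
            for _retry in range(12):
                M = A + lam * np.diag(np.diag(A)) + 1e-12 * np.eye(len(A))
                try:
                    delta = np.linalg.solve(M, -g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                cand = theta + delta
                r_c, J_c = self._residual_jacobian(cand, Xt, Yt, F, O)
                loss_c = float(r_c @ r_c)
                if np.isfinite(loss_c) and loss_c < loss:
                    theta, r, J, loss = cand, r_c, J_c, loss_c
                    lam = max(lam / 5.0, 1e-12)
                    accepted = True
                    break
                lam *= 4.0
            n_iter += 1
            if not accepted:
                break
            if len(Xv):
                val = self._val_loss(theta, Xv, Yv, F, O)
                if val < best_val - 1e-15:
                    best_val = val
                    best_theta = theta.copy()
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
            else:
                best_theta = theta.copy()
        if not np.isfinite(loss):
            raise RuntimeError("training diverged: non-finite loss")
        return best_theta, n_iter

    def _fit_qn(self, theta0, Xt, Yt, Xv, Yv, F, O):
        """Quasi-Newton (L-BFGS-B) fallback on the same objective."""
        n = len(Xt)

        def obj(theta):
            W1, b1, W2, b2 = self._unpack(theta, F, O)
            Hid, pred = _forward(Xt, W1, b1, W2, b2)
            r = pred - Yt
            loss = float(np.sum(r ** 2)) / n
            G = (1.0 - Hid ** 2)
            dpred = 2.0 * r / n
            gW2 = dpred.T @ Hid
            gb2 = dpred.sum(axis=0)
            dH = (dpred @ W2) * G
            gW1 = dH.T @ Xt
            gb1 = dH.sum(axis=0)
            return loss, self._pack(gW1, gb1, gW2, gb2)

        best = {"theta": theta0.copy(),
                "val": self._val_loss(theta0, Xv, Yv, F, O) if len(Xv) else np.inf,
                "stall": 0, "n": 0}

        def cb(theta):
            best["n"] += 1
            if len(Xv):
                val = self._val_loss(theta, Xv, Yv, F, O)
                if val < best["val"] - 1e-15:
                    best["val"] = val
                    best["theta"] = theta.copy()
                    best["stall"] = 0
                else:
                    best["stall"] += 1
                    if best["stall"] >= self.patience:
                        raise StopIteration
            else:
                best["theta"] = theta.copy()

        try:
            minimize(obj, theta0, jac=True, method="L-BFGS-B",
                     options={"maxiter": self.max_iter * 10}, callback=cb)
        except StopIteration:
            pass
        return best["theta"], best["n"]

    # -- inference ----------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "W1_")
        X, _ = self._coerce_X(X)
        Xs = (X - self.input_mean_) / self.input_scale_
        _, pred_s = _forward(Xs, self.W1_, self.b1_, self.W2_, self.b2_)
        return pred_s * self.output_scale_ + self.output_mean_


def train(features: pd.DataFrame, targets: pd.DataFrame,
          config: TrainConfig | None = None) -> SpotErrorNet:
    """Fit a :class:`SpotErrorNet` from a :class:`TrainConfig`.

    Feature/target DataFrame columns are reordered to the canonical naming,
    so metrics are invariant to input column order.
    """
    config = config or TrainConfig()
    if isinstance(features, pd.DataFrame) and set(FEATURE_COLUMNS) <= set(features.columns):
        features = features[FEATURE_COLUMNS]
    if isinstance(targets, pd.DataFrame) and set(TARGET_COLUMNS) <= set(targets.columns):
        targets = targets[TARGET_COLUMNS]
    est = SpotErrorNet(hidden_units=config.hidden_neurons, train_frac=config.train_frac,
                       val_frac=config.val_frac, test_frac=config.test_frac,
                       max_iter=config.max_iter, patience=config.patience,
                       solver=config.solver, random_state=config.seed)
    return est.fit(features, targets)


def predict_plan(model: SpotErrorNet, plan: TreatmentPlan) -> np.ndarray:
    """Predicted delivered (x, y, MU) per planned spot, in delivery order.

    Warns (but proceeds) when plan features fall outside the training
    feature ranges — the network is then extrapolating.
    """
    check_is_fitted(model, "W1_")
    feats = extract_plan_features(plan)[FEATURE_COLUMNS]
    X = np.asarray(feats, dtype=float)
    lo, hi = model.feature_range_
    if np.any(X < lo) or np.any(X > hi):
        cols = [FEATURE_COLUMNS[j] for j in
                np.flatnonzero(np.any((X < lo) | (X > hi), axis=0))]
        warnings.warn(f"plan features outside training range: {cols}; "
                      "predictions are extrapolations", stacklevel=2)
    return model.predict(feats)


# -- serialization ------------------------------------------------------------------

def model_to_json(model: SpotErrorNet, path: str | Path | None = None) -> str:
    check_is_fitted(model, "W1_")
    doc = {
        "format": "protonspot-error-model-v1",
        "params": model.get_params(),
        "architecture": [int(model.n_features_in_), int(model.hidden_units),
                         int(model.W2_.shape[0])],
        "feature_names": (list(model.feature_names_in_)
                          if hasattr(model, "feature_names_in_") else None),
        "input_mean": model.input_mean_.tolist(),
        "input_scale": model.input_scale_.tolist(),
        "output_mean": model.output_mean_.tolist(),
        "output_scale": model.output_scale_.tolist(),
        "W1": model.W1_.tolist(), "b1": model.b1_.tolist(),
        "W2": model.W2_.tolist(), "b2": model.b2_.tolist(),
        "feature_range": model.feature_range_.tolist(),
        "metrics": asdict(model.metrics_),
        "n_iter": int(model.n_iter_),
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_from_json(source: str | Path) -> SpotErrorNet:
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
        doc = json.loads(Path(source).read_text())
    else:
        doc = json.loads(source)
    if doc.get("format") != "protonspot-error-model-v1":
        raise ValueError("not a serialized spot-error model")
    model = SpotErrorNet(**doc["params"])
    model.W1_ = np.array(doc["W1"])
    model.b1_ = np.array(doc["b1"])
    model.W2_ = np.array(doc["W2"])
    model.b2_ = np.array(doc["b2"])
    model.input_mean_ = np.array(doc["input_mean"])
    model.input_scale_ = np.array(doc["input_scale"])
    model.output_mean_ = np.array(doc["output_mean"])
    model.output_scale_ = np.array(doc["output_scale"])
    model.feature_range_ = np.array(doc["feature_range"])
    model.n_features_in_ = doc["architecture"][0]
    if doc.get("feature_names"):
        model.feature_names_in_ = np.asarray(doc["feature_names"], dtype=object)
    m = doc["metrics"]
    model.metrics_ = FitMetrics(**m)
    model.n_iter_ = doc["n_iter"]
    return model
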