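"""The fuzzy deep learning (FDL) classifier and its SGD trainer.

The network chains three components:

1. **Fuzzification** — every input feature i carries a bank of M adaptive
   Gaussian membership functions (centers C[i, m], spreads S[i, m]); an input
   vector x becomes the membership tensor mu[i, m] = exp(-((x_i - C)/S)^2 / 2).
2. **Rule layer** — R Takagi–Sugeno rules, each selecting one membership
   function per feature. Firing strengths use the product t-norm, computed as
   the exponential of summed log-memberships for numerical stability; the
   strengths are normalized to sum to one (the weighted average below is
   invariant to this common positive rescaling). Each of K aggregation units
   carries affine consequents f_{rk}(x) = P[r, k] . x + b[r, k] and applies
   the standard weighted-average defuzzification
   z_k = sum_r(w_r f_{rk}) / sum_r(w_r).
3. **Deep classification head** — the K aggregated outputs feed dense
   rectified-linear layers and a 6-way softmax producing survival-class
   scores that sum to one.

All parameters — membership centers and spreads, rule consequents, dense
weights — are trained jointly by mini-batch stochastic gradient descent on
the categorical cross-entropy, with early stopping on validation accuracy.
Gradients are derived analytically (and verified against central differences
in the test suite). All randomness flows from explicit integer seeds, so a
fixed seed reproduces training bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .schema import N_CLASSES

SIGMA_TRAIN_FLOOR = 1e-3  # spreads are clamped here after every SGD step
SIGMA_INIT_FLOOR = 0.1


@dataclass(frozen=True)
class FDLConfig:
    """Architecture of the fuzzy front end and dense head."""

    n_rules: int = 16
    n_mfs: int = 2
    n_agg_units: int = 8
    hidden: tuple[int, ...] = (64, 32)
    seed: int = 0


@dataclass(frozen=True)
class TrainConfig:
    """SGD training protocol: learning rate 1e-5 and batch size 32 by default,
    early stopping after 12 epochs without validation-accuracy improvement."""

    learning_rate: float = 1e-5
    batch_size: int = 32
    patience_epochs: int = 12
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if not 1 <= self.patience_epochs <= self.max_epochs:
            raise ValueError("need 1 <= patience_epochs <= max_epochs")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _DenseStack:
    """Plain fully connected rectifier layers + softmax head (shared by the
    FDL head and the dense baseline)."""

    def __init__(self, in_dim: int, hidden: tuple[int, ...], n_classes: int,
                 rng: np.random.Generator):
        dims = [in_dim, *hidden, n_classes]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [x]
        h = x
        for i in range(len(self.W) - 1):
            h = _relu(h @ self.W[i] + self.b[i])
            acts.append(h)
        logits = h @ self.W[-1] + self.b[-1]
        return logits, acts

    def backward(self, dlogits: np.ndarray, acts: list[np.ndarray]
                 ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Returns (dW, db, dx) given d(loss)/d(logits)."""
        dW = [np.zeros_like(w) for w in self.W]
        db = [np.zeros_like(b) for b in self.b]
        g = dlogits
        for i in range(len(self.W) - 1, -1, -1):
            dW[i] = acts[i].T @ g
            db[i] = g.sum(axis=0)
            g = g @ self.W[i].T
            if i > 0:
                g = g * (acts[i] > 0)
        return dW, db, g

    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]


def _flatten(arrays: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([a.ravel() for a in arrays])


def _unflatten(flat: np.ndarray, arrays: list[np.ndarray]) -> None:
    i = 0
    for a in arrays:
        a[...] = flat[i : i + a.size].reshape(a.shape)
        i += a.size
    if i != flat.size:
        raise ValueError(f"parameter vector has {flat.size} entries, expected {i}")


class FDLNetwork:
    """Fuzzification -> rule firing -> defuzzification -> dense head."""

    kind = "fdl"

    def __init__(self, input_dim: int, n_classes: int = N_CLASSES,
                 config: FDLConfig = FDLConfig(), X_init: np.ndarray | None = None):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.input_dim = input_dim
        self.n_classes = n_classes
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, M, R, K = input_dim, config.n_mfs, config.n_rules, config.n_agg_units

        self.C, self.S = self._init_banks(d, M, X_init)
        self.A = self._init_antecedents(rng, d, M, R, X_init)  # (R, d) int, fixed
        self._A_onehot = np.zeros((R, d, M))
        self._A_onehot[np.arange(R)[:, None], np.arange(d)[None, :], self.A] = 1.0
        self.P = rng.normal(0.0, 0.05, size=(R, K, d))  # affine consequent slopes
        self.b_rule = np.zeros((R, K))
        self.head = _DenseStack(K, config.hidden, n_classes, rng)

    # -- initialization ----------------------------------------------------

    @staticmethod
    def _init_banks(d: int, M: int, X_init: np.ndarray | None
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Centers from per-feature quantiles of the training data (evenly
        spread levels), falling back to a [0, 1] grid when degenerate.

        Spreads start at half the adjacent-center gap, floored both at 0.1
        and at sqrt(d)/4. The dimension-dependent floor keeps the product
        t-norm soft at initialization: each rule multiplies d per-feature
        memberships, so with narrow Gaussians the summed log-membership gaps
        between rules grow with d and the normalized firing collapses to a
        hard winner-take-all partition, starving all but one rule of
        gradient. sqrt(d)/4 keeps the spread of summed log-memberships O(1).
        """
        C = np.tile(np.linspace(0.0, 1.0, M), (d, 1))
        if X_init is not None and len(X_init):
            q = (np.arange(M) + 0.5) / M
            C = np.quantile(X_init, q, axis=0).T  # (d, M)
            degenerate = (np.diff(C, axis=1).min(axis=1) <= 1e-12) if M > 1 else np.zeros(d, bool)
            lo = X_init.min(axis=0)
            hi = np.maximum(X_init.max(axis=0), lo + 1.0)
            for i in np.flatnonzero(degenerate):
                C[i] = np.linspace(lo[i], hi[i], M)
        soft_floor = max(SIGMA_INIT_FLOOR, np.sqrt(d) / 4.0)
        if M > 1:
            gaps = np.diff(C, axis=1)
            half = 0.5 * np.concatenate(
                [gaps[:, :1], 0.5 * (gaps[:, :-1] + gaps[:, 1:]), gaps[:, -1:]], axis=1
            )
            S = np.maximum(half, soft_floor)
        else:
            S = np.full((d, 1), max(0.5, soft_floor))
        return C.astype(float), S.astype(float)

    def _init_antecedents(self, rng: np.random.Generator, d: int, M: int, R: int,
                          X_init: np.ndarray | None) -> np.ndarray:
        """Each rule's antecedent is the nearest membership function per
        feature of a prototype training sample (random prototypes when no
        data is given)."""
        if X_init is None or len(X_init) == 0:
            return rng.integers(0, M, size=(R, d))
        n = len(X_init)
        idx = rng.choice(n, size=R, replace=R > n)
        protos = X_init[idx]  # (R, d)
        dist = np.abs(protos[:, :, None] - self.C[None, :, :])  # (R, d, M)
        return dist.argmin(axis=2)

    # -- forward / backward ------------------------------------------------

    def _forward_cached(self, X: np.ndarray) -> dict:
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(f"expected (n, {self.input_dim}) input, got {X.shape}")
        diff = X[:, :, None] - self.C[None, :, :]          # (n, d, M)
        logmu = -0.5 * (diff / self.S[None]) ** 2          # (n, d, M)
        logw = np.einsum("ndm,rdm->nr", logmu, self._A_onehot)  # (n, R)
        shifted = logw - logw.max(axis=1, keepdims=True)
        ew = np.exp(shifted)
        wn = ew / ew.sum(axis=1, keepdims=True)            # normalized firing
        F = np.einsum("nd,rkd->nrk", X, self.P) + self.b_rule[None]  # (n, R, K)
        z = np.einsum("nr,nrk->nk", wn, F)                 # defuzzified units
        logits, acts = self.head.forward(z)
        probs = _softmax(logits)
        return {"X": X, "diff": diff, "wn": wn, "F": F, "z": z,
                "logits": logits, "acts": acts, "probs": probs}

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class-probability matrix (n, n_classes); rows sum to one."""
        return self._forward_cached(np.asarray(X, dtype=float))["probs"]

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray
                       ) -> tuple[float, np.ndarray]:
        """Mean cross-entropy and its gradient as one flat vector."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = len(X)
        cache = self._forward_cached(X)
        probs = cache["probs"]
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(n), y] + eps).mean())

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dW, db, dz = self.head.backward(dlogits, cache["acts"])

        wn, F, diff = cache["wn"], cache["F"], cache["diff"]
        dF = wn[:, :, None] * dz[:, None, :]                    # (n, R, K)
        dP = np.einsum("nrk,nd->rkd", dF, X)
        db_rule = dF.sum(axis=0)
        dwn = np.einsum("nk,nrk->nr", dz, F)
        # wn is a softmax of the summed log-memberships
        dlogw = wn * (dwn - (dwn * wn).sum(axis=1, keepdims=True))
        dlogmu = np.einsum("nr,rdm->ndm", dlogw, self._A_onehot)
        dC = (dlogmu * diff / self.S[None] ** 2).sum(axis=0)
        dS = (dlogmu * diff**2 / self.S[None] ** 3).sum(axis=0)

        grads = _flatten([dC, dS, dP, db_rule, *dW, *db])
        return loss, grads

    # -- parameter registry ------------------------------------------------

    def params(self) -> list[np.ndarray]:
        return [self.C, self.S, self.P, self.b_rule, *self.head.params()]

    def get_flat_params(self) -> np.ndarray:
        return _flatten(self.params())

    def set_flat_params(self, flat: np.ndarray) -> None:
        _unflatten(np.asarray(flat, dtype=float), self.params())

    def post_step(self) -> None:
        np.maximum(self.S, SIGMA_TRAIN_FLOOR, out=self.S)

    # -- prediction --------------------------------------------------------

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax class labels; ties break toward the lowest class index."""
        return self.predict_scores(X).argmax(axis=1)

    # -- checkpointing -----------------------------------------------------

    def to_checkpoint(self) -> dict:
        return {
            "kind": self.kind,
            "input_dim": self.input_dim,
            "n_classes": self.n_classes,
            "config": {
                "n_rules": self.config.n_rules,
                "n_mfs": self.config.n_mfs,
                "n_agg_units": self.config.n_agg_units,
                "hidden": list(self.config.hidden),
                "seed": self.config.seed,
            },
            "antecedents": self.A.tolist(),
            "params": self.get_flat_params().tolist(),
        }

    @classmethod
    def from_checkpoint(cls, d: dict) -> "FDLNetwork":
        cfg = FDLConfig(
            n_rules=d["config"]["n_rules"],
            n_mfs=d["config"]["n_mfs"],
            n_agg_units=d["config"]["n_agg_units"],
            hidden=tuple(d["config"]["hidden"]),
            seed=d["config"]["seed"],
        )
        net = cls(d["input_dim"], d["n_classes"], cfg)
        net.A = np.asarray(d["antecedents"], dtype=int)
        R, dd, M = cfg.n_rules, d["input_dim"], cfg.n_mfs
        net._A_onehot = np.zeros((R, dd, M))
        net._A_onehot[np.arange(R)[:, None], np.arange(dd)[None, :], net.A] = 1.0
        net.set_flat_params(np.asarray(d["params"], dtype=float))
        return net


def build_fdl(input_dim: int, n_classes: int = N_CLASSES,
              config: FDLConfig = FDLConfig(),
              X_init: np.ndarray | None = None) -> FDLNetwork:
    """Construct an FDL network; deterministic given ``config.seed``."""
    return FDLNetwork(input_dim, n_classes, config, X_init=X_init)


# ---------------------------------------------------------------------------
# training

class TrainingDiverged(RuntimeError):
    pass


def train(model, X_train: np.ndarray, y_train: np.ndarray,
          X_val: np.ndarray, y_val: np.ndarray,
          config: TrainConfig = TrainConfig()) -> TrainHistory:
    """Mini-batch SGD with early stopping on validation accuracy.

    An epoch is one pass over the training data in a freshly shuffled order.
    Training halts once ``patience_epochs`` epochs pass without strict
    improvement of validation accuracy (or at ``max_epochs``); the model is
    restored to the parameters of the best validation epoch. The model object
    must expose ``loss_and_grads``, ``get/set_flat_params``, ``post_step``
    and ``predict``.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=int)
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation data must be non-empty")

    rng = np.random.default_rng(config.seed)
    hist = TrainHistory()
    best_acc = -np.inf
    best_params = model.get_flat_params().copy()
    since_best = 0
    n = len(X_train)

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        batch_losses = []
        for bi, start in enumerate(range(0, n, config.batch_size)):
            idx = perm[start : start + config.batch_size]
            loss, grads = model.loss_and_grads(X_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {bi}"
                )
            model.set_flat_params(model.get_flat_params() - config.learning_rate * grads)
            model.post_step()
            batch_losses.append(loss)

        train_acc = float((model.predict(X_train) == y_train).mean())
        val_acc = float((model.predict(X_val) == y_val).mean())
        hist.train_loss.append(float(np.mean(batch_losses)))
        hist.train_accuracy.append(train_acc)
        hist.val_accuracy.append(val_acc)

        if val_acc > best_acc:
            best_acc = val_acc
            best_params = model.get_flat_params().copy()
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        hist.stopped_epoch = epoch
        if since_best >= config.patience_epochs:
            break

    model.set_flat_params(best_params)
    return hist


def save_checkpoint(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_checkpoint()), encoding="utf-8")


def load_checkpoint(path: str | Path):
    from .baselines import DenseBaseline  # cycle-free at call time

    d = json.loads(Path(path).read_text(encoding="utf-8"))
    if d["kind"] == "fdl":
        return FDLNetwork.from_checkpoint(d)
    if d["kind"] == "dl":
        return DenseBaseline.from_checkpoint(d)
    raise ValueError(f"unknown checkpoint kind {d['kind']!r}")
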