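"""The DeepMF network: masked reconstruction + Laplacian-regularized training.

The model is an M-input / N-output network whose hidden layers all have K
nodes.  Feeding the one-hot vector of feature i selects row i of the
first-layer weight matrix U; that K-vector passes through ReLU, through the
(L-1) hidden-to-hidden maps (each followed by ReLU), and finally through
the last-layer weights V to produce the predicted expression row.  U and V
are therefore the feature and sample latent matrices of a (rectified)
matrix factorization, and the full forward pass over all features yields
the refined matrix A_hat that simultaneously denoises observed entries and
imputes missing ones.

Training minimizes

    L_mix = L_global + alpha * L_local + beta * L_reg

where L_global is the mean per-feature squared reconstruction error with
missing cells dropped, L_local is the graph-Laplacian smoothness penalty of
U and V on the (remote-pair-masked) feature / sample similarity graphs, and
L_reg is the squared Frobenius norm of all weights.  Everything runs on
NumPy with analytic gradients and an Adam optimizer; the matrices involved
are small enough that a deep-learning framework would be pure overhead.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .matrix import OmicsMatrix
from .proximity import ProximityGraph, feature_sample_graphs, local_penalty

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Hyperparameters for one DeepMF training run.

    alpha weighs the local (Laplacian) loss, beta the L2 regularization.
    Restart r of ``restarts`` initializes weights from seed ``seed + r``.
    ``validation_fraction`` > 0 holds out that fraction of observed cells
    for architecture selection (0 = train on everything).
    """

    alpha: float = 0.1
    beta: float = 1e-4
    epochs: int = 2000
    learning_rate: float = 0.01
    restarts: int = 10
    seed: int = 0
    validation_fraction: float = 0.0
    optimizer_name: str = "adam"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.epochs < 1 or self.restarts < 1:
            raise ValueError("epochs and restarts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.optimizer_name not in ("adam", "sgd"):
            raise ValueError("optimizer_name must be 'adam' or 'sgd'")


@dataclass
class LossBreakdown:
    """One epoch's loss components; mix = global + alpha*local + beta*reg."""

    global_: float
    local: float
    reg: float
    mix: float


@dataclass
class DeepMFModel:
    """Network weights.  No biases anywhere: A_hat is an explicit function
    of (U, W_hidden, V), and with L=1 the model is a ReLU-rectified bilinear
    factorization ReLU(U) @ V."""

    U: np.ndarray                      # (M, K) first-layer weights
    W_hidden: list[np.ndarray]         # L-1 matrices, each (K, K)
    V: np.ndarray                      # (K, N) last-layer weights

    @property
    def K(self) -> int:
        return self.U.shape[1]

    @property
    def L(self) -> int:
        return len(self.W_hidden) + 1

    @property
    def M(self) -> int:
        return self.U.shape[0]

    @property
    def N(self) -> int:
        return self.V.shape[1]

    def forward_all(self) -> np.ndarray:
        """Predictions for every feature: stack of forward(e_i), shape (M, N)."""
        h = np.maximum(self.U, 0.0)
        for w in self.W_hidden:
            h = np.maximum(h @ w, 0.0)
        return h @ self.V

    def forward(self, feature_index: int) -> np.ndarray:
        """Predicted expression row for one one-hot encoded feature."""
        if not 0 <= feature_index < self.M:
            raise IndexError(
                f"feature_index {feature_index} out of range [0, {self.M})"
            )
        h = np.maximum(self.U[feature_index], 0.0)
        for w in self.W_hidden:
            h = np.maximum(h @ w, 0.0)
        return h @ self.V


@dataclass
class FitResult:
    model: DeepMFModel
    history: list[LossBreakdown]
    refined: OmicsMatrix
    selected_restart: int
    final_mix: float

    def save(self, out_dir: str) -> None:
        """Write U.tsv, V.tsv, A_hat.tsv, loss_history.tsv and manifest.json."""
        from .matrix import write_matrix

        os.makedirs(out_dir, exist_ok=True)
        np.savetxt(os.path.join(out_dir, "U.tsv"), self.model.U, delimiter="\t")
        np.savetxt(os.path.join(out_dir, "V.tsv"), self.model.V, delimiter="\t")
        write_matrix(self.refined, os.path.join(out_dir, "A_hat.tsv"))
        with open(os.path.join(out_dir, "loss_history.tsv"), "w") as fh:
            fh.write("epoch\tglobal\tlocal\treg\tmix\n")
            for e, lb in enumerate(self.history):
                fh.write(f"{e}\t{lb.global_}\t{lb.local}\t{lb.reg}\t{lb.mix}\n")
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(
                {
                    "selected_restart": self.selected_restart,
                    "final_mix": self.final_mix,
                    "K": self.model.K,
                    "L": self.model.L,
                },
                fh, indent=2,
            )


def masked_global_loss(y: np.ndarray, yhat: np.ndarray, mask: np.ndarray) -> float:
    """(1/M) * sum of squared errors over observed cells only.

    Reduces to the plain mean-per-feature squared error when nothing is
    missing; an all-missing matrix contributes 0.
    """
    y = np.atleast_2d(y)
    yhat = np.atleast_2d(yhat)
    mask = np.atleast_2d(mask)
    if y.shape != yhat.shape or y.shape != mask.shape:
        raise ValueError("y, yhat and mask shapes must agree")
    r = np.where(mask, y - yhat, 0.0)
    return float((r * r).sum() / y.shape[0])


def total_loss(
    model: DeepMFModel,
    m: OmicsMatrix,
    graphs: tuple[ProximityGraph, ProximityGraph],
    cfg: TrainingConfig,
) -> LossBreakdown:
    """All loss components of ``model`` on matrix ``m``."""
    gf, gs = graphs
    if gf.size != m.n_features or gs.size != m.n_samples:
        raise ValueError(
            f"graphs of sizes ({gf.size}, {gs.size}) do not match matrix "
            f"{m.n_features}x{m.n_samples}"
        )
    glob = masked_global_loss(m.observed_values(), model.forward_all(), m.mask)
    loc = local_penalty(model.U, gf, "feature") + local_penalty(model.V, gs, "sample")
    reg = float((model.U ** 2).sum() + (model.V ** 2).sum()
                + sum((w ** 2).sum() for w in model.W_hidden))
    mix = glob + cfg.alpha * loc + cfg.beta * reg
    return LossBreakdown(glob, loc, reg, mix)


def _init_model(m_rows: int, n_cols: int, K: int, L: int, rng: np.random.Generator) -> DeepMFModel:
    # U starts nonnegative so no hidden unit is born dead behind the first
    # ReLU; V and the hidden maps use symmetric fan-scaled uniform init.
    u = rng.uniform(0.0, math.sqrt(6.0 / (1 + K)), size=(m_rows, K))
    ws = [
        rng.uniform(-1.0, 1.0, size=(K, K)) * math.sqrt(6.0 / (2 * K))
        for _ in range(L - 1)
    ]
    v = rng.uniform(-1.0, 1.0, size=(K, n_cols)) * math.sqrt(6.0 / (K + n_cols))
    return DeepMFModel(U=u, W_hidden=ws, V=v)


def loss_and_gradients(
    model: DeepMFModel,
    m: OmicsMatrix,
    graphs: tuple[ProximityGraph, ProximityGraph],
    cfg: TrainingConfig,
) -> tuple[LossBreakdown, dict]:
    """L_mix and its analytic gradients w.r.t. U, W_hidden and V.

    Missing cells never enter the residual, so neither the loss nor any
    gradient depends on the values stored behind the mask.
    """
    gf, gs = graphs
    y0 = m.observed_values()
    msk = m.mask
    mm = m.n_features

    # forward pass, keeping pre-activations for the ReLU gates
    zs: list[np.ndarray] = [model.U]
    h = np.maximum(model.U, 0.0)
    hs: list[np.ndarray] = [h]
    for w in model.W_hidden:
        z = h @ w
        h = np.maximum(z, 0.0)
        zs.append(z)
        hs.append(h)
    yhat = h @ model.V

    r = np.where(msk, yhat - y0, 0.0)
    glob = float((r * r).sum() / mm)
    loc = local_penalty(model.U, gf, "feature") + local_penalty(model.V, gs, "sample")
    reg = float((model.U ** 2).sum() + (model.V ** 2).sum()
                + sum((w ** 2).sum() for w in model.W_hidden))
    mix = glob + cfg.alpha * loc + cfg.beta * reg

    dyhat = (2.0 / mm) * r
    dv = hs[-1].T @ dyhat + cfg.alpha * 4.0 * (model.V @ gs.laplacian) \
        + cfg.beta * 2.0 * model.V
    dh = dyhat @ model.V.T
    dws: list[np.ndarray] = [None] * len(model.W_hidden)
    for t in range(len(model.W_hidden) - 1, -1, -1):
        dz = dh * (zs[t + 1] > 0)
        dws[t] = hs[t].T @ dz + cfg.beta * 2.0 * model.W_hidden[t]
        dh = dz @ model.W_hidden[t].T
    du = dh * (zs[0] > 0) + cfg.alpha * 4.0 * (gf.laplacian @ model.U) \
        + cfg.beta * 2.0 * model.U

    return LossBreakdown(glob, loc, reg, mix), {"U": du, "W_hidden": dws, "V": dv}


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _train_once(
    m: OmicsMatrix,
    K: int,
    L: int,
    cfg: TrainingConfig,
    graphs: tuple[ProximityGraph, ProximityGraph],
    restart_seed: int,
) -> tuple[DeepMFModel, list[LossBreakdown]] | None:
    """One full-batch gradient-descent run; None if the loss went non-finite."""
    rng = np.random.default_rng(restart_seed)
    model = _init_model(m.n_features, m.n_samples, K, L, rng)
    params = [model.U, model.V] + model.W_hidden
    if cfg.optimizer_name == "adam":
        opt = _Adam(params, cfg.learning_rate)
    else:
        opt = None
    history: list[LossBreakdown] = []
    for _ in range(cfg.epochs):
        lb, grads = loss_and_gradients(model, m, graphs, cfg)
        if not math.isfinite(lb.mix):
            return None
        history.append(lb)
        glist = [grads["U"], grads["V"]] + grads["W_hidden"]
        if opt is not None:
            opt.step(params, glist)
        else:
            for p, g in zip(params, glist):
                p -= cfg.learning_rate * g
    final, _ = loss_and_gradients(model, m, graphs, cfg)
    if not math.isfinite(final.mix):
        return None
    history.append(final)
    return model, history


def fit(
    m: OmicsMatrix,
    K: int,
    L: int,
    cfg: TrainingConfig | None = None,
    graphs: tuple[ProximityGraph, ProximityGraph] | None = None,
) -> FitResult:
    """Train with multiple random restarts and keep the minimum-L_mix run.

    Similarity graphs are built once from the input matrix (missing-aware)
    unless precomputed ones are supplied.  Restart r draws its weights from
    seed ``cfg.seed + r``; runs whose loss goes non-finite are excluded.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    cfg = cfg or TrainingConfig()
    if graphs is None:
        graphs = feature_sample_graphs(m)

    best: tuple[float, int, DeepMFModel, list[LossBreakdown]] | None = None
    for r in range(cfg.restarts):
        out = _train_once(m, K, L, cfg, graphs, cfg.seed + r)
        if out is None:
            logger.warning("restart %d diverged (non-finite loss); excluded", r)
            continue
        model, history = out
        final = history[-1].mix
        if best is None or final < best[0]:
            best = (final, r, model, history)
    if best is None:
        raise RuntimeError("all restarts diverged; try a smaller learning rate")
    final_mix, sel, model, history = best
    refined = OmicsMatrix(
        model.forward_all(),
        np.ones(m.shape, dtype=bool),
        list(m.feature_ids),
        list(m.sample_ids),
    )
    return FitResult(model, history, refined, sel, final_mix)


def impute(r: FitResult, feature_index: int, sample_index: int) -> float:
    """Model prediction A_hat[i, j] — denoised if observed, imputed if missing."""
    if not 0 <= sample_index < r.model.N:
        raise IndexError(
            f"sample_index {sample_index} out of range [0, {r.model.N})"
        )
    return float(r.model.forward(feature_index)[sample_index])


def _holdout_split(
    m: OmicsMatrix, fraction: float, rng: np.random.Generator, max_retries: int = 20
) -> np.ndarray:
    """Boolean matrix marking held-out observed cells; every row and column
    keeps at least one observed training cell."""
    obs = np.flatnonzero(m.mask.ravel())
    n_hold = int(round(fraction * obs.size))
    if n_hold == 0:
        return np.zeros(m.shape, dtype=bool)
    for _ in range(max_retries):
        chosen = rng.choice(obs, size=n_hold, replace=False)
        hold = np.zeros(m.shape, dtype=bool)
        hold.ravel()[chosen] = True
        train_mask = m.mask & ~hold
        if train_mask.any(axis=1).all() and train_mask.any(axis=0).all():
            return hold
    raise RuntimeError(
        "could not draw a validation holdout leaving every row and column observed"
    )


def select_architecture(
    m: OmicsMatrix,
    C: int,
    L_candidates: list[int] | None = None,
    cfg: TrainingConfig | None = None,
) -> tuple[int, int, FitResult]:
    """Grid-search K in [2, C] x L_candidates by held-out validation L_mix.

    A ``validation_fraction`` of observed cells is masked during training
    and scored by the masked squared error on exactly those cells (plus the
    alpha/beta penalty terms); the (K, L) pair with minimal validation
    L_mix wins and its FitResult is returned.
    """
    if C < 2:
        raise ValueError(f"C must be >= 2, got {C}")
    cfg = cfg or TrainingConfig(validation_fraction=0.1)
    if cfg.validation_fraction == 0:
        cfg = TrainingConfig(**{**asdict(cfg), "validation_fraction": 0.1})
    L_candidates = L_candidates or [1]
    rng = np.random.default_rng(cfg.seed)
    hold = _holdout_split(m, cfg.validation_fraction, rng)
    train = m.copy()
    train.mask = m.mask & ~hold
    train.values = np.where(train.mask, train.values, np.nan)
    graphs = feature_sample_graphs(train)

    y_hold = np.where(hold, m.values, 0.0)
    best: tuple[float, int, int, FitResult] | None = None
    for K in range(2, C + 1):
        for L in L_candidates:
            res = fit(train, K, L, cfg, graphs=graphs)
            glob_val = masked_global_loss(y_hold, res.refined.values, hold)
            score = glob_val + cfg.alpha * res.history[-1].local \
                + cfg.beta * res.history[-1].reg
            logger.info("architecture K=%d L=%d validation L_mix=%.6g", K, L, score)
            if best is None or score < best[0]:
                best = (score, K, L, res)
    assert best is not None
    _, K, L, res = best
    return K, L, res
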