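"""Joint objective and alternating min–max training.

The objective couples a focal classification loss ``L_c`` on labeled
source beats with a domain-discrimination loss ``L_d`` on all beats:

    E(w_f, w_c, w_d) = L_c(w_f, w_c) - lambda * L_d(w_f, w_d)

Training alternates, per mini-batch, between (step A) descending E in
(w_f, w_c) with w_d frozen — which pushes the features to confuse the
discriminator — and (step B) descending L_d in w_d with (w_f, w_c)
frozen — which sharpens the discriminator.  At balance the features
carry class information but little domain information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import ModelParams, build_model

_EPS = 1e-12


@dataclass
class LossTerms:
    """Components of the joint objective for one mini-batch."""

    L_c: float
    L_d: float
    lambda_: float

    @property
    def E(self) -> float:
        return self.L_c - self.lambda_ * self.L_d


@dataclass
class TrainConfig:
    lr: float = 0.001
    batch_size: int = 128          # split evenly source/target when adapting
    lambda_: float = 0.2
    gamma: float = 2.0             # focal-loss focusing exponent
    dropout: float = 0.2
    momentum: float = 0.0
    epochs: int = 100
    patience: int = 20             # early stop on validation macro sensitivity
    val_fraction: float = 0.1
    seed: int = 0
    variant: str = "multi_scale"
    check_routing: bool = False    # assert frozen groups every batch

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 1 or self.lambda_ < 0:
            raise ValueError("invalid training configuration")


@dataclass
class History:
    epoch: list[int] = field(default_factory=list)
    L_c: list[float] = field(default_factory=list)
    L_d: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    val_macro_sen: list[float] = field(default_factory=list)
    disc_acc: list[float] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        return [
            {k: getattr(self, k)[i] for k in
             ("epoch", "L_c", "L_d", "train_acc", "val_acc",
              "val_macro_sen", "disc_acc")}
            for i in range(len(self.epoch))
        ]


def focal_loss(probs: np.ndarray, labels: np.ndarray, gamma: float = 2.0) -> float:
    """Mean focal loss  -(1 - p_true)^gamma * log(p_true).

    ``probs`` rows are class probabilities; ``labels`` are class indices.
    With gamma = 0 this is exactly mean cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = np.clip(probs[np.arange(len(labels)), labels], _EPS, 1.0)
    return float(np.mean(-((1.0 - p) ** gamma) * np.log(p)))


def domain_loss(d_hat: np.ndarray, d: np.ndarray) -> float:
    """Mean binary cross-entropy of predicted domain probabilities."""
    p = np.clip(d_hat, _EPS, 1.0 - _EPS)
    return float(np.mean(-(d * np.log(p) + (1 - d) * np.log(1 - p))))


def joint_objective(terms: LossTerms) -> float:
    """E = L_c - lambda * L_d (classification sum over source rows only)."""
    return terms.E


def _focal_grad_logits(logits: np.ndarray, labels: np.ndarray,
                       gamma: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Focal loss and its gradient w.r.t. logits (mean over the batch)."""
    n = logits.shape[0]
    probs = nn.softmax(logits)
    p_t = np.clip(probs[np.arange(n), labels], _EPS, 1.0)
    loss = float(np.mean(-((1.0 - p_t) ** gamma) * np.log(p_t)))
    # dL/dp_t, then chain through softmax: dz = g * p_t * (onehot - probs)
    g = gamma * (1.0 - p_t) ** (gamma - 1.0) * np.log(p_t) if gamma != 0 else 0.0
    g = g - (1.0 - p_t) ** gamma / p_t
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0
    dz = (g * p_t)[:, None] * (onehot - probs) / n
    return loss, dz, probs


def _bce_grad_logits(logits: np.ndarray,
                     d: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """BCE-with-logits and its gradient w.r.t. logits (mean over batch)."""
    p = nn.sigmoid(logits)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    loss = float(np.mean(-(d * np.log(pc) + (1 - d) * np.log(1 - pc))))
    return loss, (p - d) / len(d), p


def predict(params: ModelParams, X: np.ndarray,
            rr: np.ndarray | None = None) -> np.ndarray:
    """Class probabilities in evaluation mode (dropout off, BN running stats)."""
    X = np.asarray(X, dtype=nn.DTYPE)
    if rr is not None:
        rr = np.asarray(rr, dtype=nn.DTYPE)
    f = params.F.forward(X, train=False)
    logits = params.C.forward(f, rr, train=False)
    return nn.softmax(logits)


def _macro_sensitivity(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    sens = []
    for c in np.unique(y_true):
        mask = y_true == c
        sens.append(float(np.mean(y_pred[mask] == c)))
    return float(np.mean(sens))


def _val_split(n: int, fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = max(1, int(round(n * fraction))) if fraction > 0 and n > 1 else 0
    return idx[n_val:], idx[:n_val]


def train_supervised(X: np.ndarray, rr: np.ndarray, y: np.ndarray,
                     cfg: TrainConfig,
                     params: ModelParams | None = None) -> tuple[ModelParams, History]:
    """Plain focal-loss classifier training (no domain adaptation)."""
    return _train(X, rr, y, None, None, cfg, params, adversarial=False)


def train_adversarial(X_src: np.ndarray, rr_src: np.ndarray, y_src: np.ndarray,
                      X_tgt: np.ndarray | None, rr_tgt: np.ndarray | None,
                      cfg: TrainConfig,
                      params: ModelParams | None = None) -> tuple[ModelParams, History]:
    """Alternating min–max training of (F, C) against D.

    ``X_tgt`` beats are unlabeled; an empty/None target degrades to plain
    supervised training.  With ``lambda_ = 0`` the discriminator has no
    influence on (w_f, w_c) and is left untrained (its updates would be
    dead computation), giving an exact no-adaptation control.  Returns
    the best checkpoint by validation macro sensitivity (held-out source
    split) and the per-epoch history.
    """
    if X_tgt is not None and len(X_tgt) == 0:
        X_tgt = None
    return _train(X_src, rr_src, y_src, X_tgt, rr_tgt, cfg, params,
                  adversarial=X_tgt is not None)


def _train(X: np.ndarray, rr: np.ndarray, y: np.ndarray,
           X_tgt, rr_tgt, cfg: TrainConfig, params: ModelParams | None,
           adversarial: bool) -> tuple[ModelParams, History]:
    if len(X) == 0:
        raise ValueError("source set is empty")
    X = np.asarray(X, dtype=nn.DTYPE)
    rr = np.asarray(rr, dtype=nn.DTYPE)
    y = np.asarray(y, dtype=np.int64)
    if params is None:
        params = build_model(D=X.shape[1], variant=cfg.variant,
                             lambda_=cfg.lambda_, dropout=cfg.dropout,
                             seed=cfg.seed)
    F, C, D = params.F, params.C, params.D

    rng = np.random.default_rng(nn.derive_seed(cfg.seed, "train"))
    tr_idx, val_idx = _val_split(len(X), cfg.val_fraction, rng)
    Xtr, rtr, ytr = X[tr_idx], rr[tr_idx], y[tr_idx]
    Xval, rval, yval = X[val_idx], rr[val_idx], y[val_idx]

    # With a zero adversarial weight the discriminator contributes an
    # exactly-zero gradient to (w_f, w_c), so its own updates are dead
    # computation for the classifier: they are skipped, leaving the
    # (w_f, w_c) trajectory bit-identical to the full procedure at
    # lambda = 0 while making the lambda = 0 control cheap.
    use_disc = adversarial and cfg.lambda_ > 0
    if adversarial:
        X_tgt = np.asarray(X_tgt, dtype=nn.DTYPE)
        n_held = max(1, len(X_tgt) // 10)
        tgt_idx = rng.permutation(len(X_tgt))
        tgt_tr, tgt_held = tgt_idx[n_held:], tgt_idx[:n_held]
        if len(tgt_tr) == 0:
            tgt_tr = tgt_idx
        Xt = X_tgt[tgt_tr]
        Xt_held = X_tgt[tgt_held]
        n_src_b = max(1, cfg.batch_size // 2)
        n_tgt_b = max(1, cfg.batch_size - n_src_b)
    else:
        n_src_b = cfg.batch_size

    opt_fc = nn.SGD(nn.collect_params(F, C), cfg.lr, cfg.momentum)
    opt_d = nn.SGD(nn.collect_params(D), cfg.lr, cfg.momentum)

    hist = History()
    best_state, best_sen, best_epoch = nn.get_state(F, C, D), -1.0, -1
    n_batches = max(1, len(Xtr) // n_src_b)

    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(Xtr))
        if adversarial:
            tperm = rng.permutation(len(Xt))
        ep_lc, ep_ld, ep_correct, ep_count = 0.0, 0.0, 0, 0

        for b in range(n_batches):
            sl = perm[b * n_src_b : (b + 1) * n_src_b]
            xb, rb, yb = Xtr[sl], rtr[sl], ytr[sl]
            if adversarial:
                tl = [tperm[(b * n_tgt_b + j) % len(Xt)] for j in range(n_tgt_b)]
                xt = Xt[tl]
                x_all = np.concatenate([xb, xt])
                d_all = np.concatenate([np.zeros(len(xb)), np.ones(len(xt))])
            else:
                x_all, d_all = xb, None

            if cfg.check_routing:
                h_d = nn.param_hash(D)

            # --- step A: update (w_f, w_c); w_d frozen -------------------
            f_all = F.forward(x_all, train=True)
            logits_c = C.forward(f_all[: len(xb)], rb, train=True)
            lc, dz_c, probs = _focal_grad_logits(logits_c, yb, cfg.gamma)
            g_f = np.zeros_like(f_all)
            g_f[: len(xb)] = C.backward(dz_c)
            if use_disc:
                logits_d = D.forward(f_all, train=True)
                ld, dz_d, _ = _bce_grad_logits(logits_d, d_all)
                # dE/df = dLc/df - lambda * dLd/df
                g_f -= cfg.lambda_ * D.backward(dz_d)
            else:
                ld = 0.0
            F.backward(g_f)
            if not (np.isfinite(lc) and np.isfinite(ld)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} batch {b}: "
                    f"L_c={lc} L_d={ld}"
                )
            opt_fc.step()

            if cfg.check_routing:
                assert nn.param_hash(D) == h_d, "step A modified w_d"

            # --- step B: update w_d; (w_f, w_c) frozen -------------------
            # The discriminator gradients computed in step A are exact for
            # this batch's features (w_d was frozen there), so step B is a
            # plain descent step on L_d using them: the discriminator
            # trains on the features the extractor actually produced, one
            # half-step stale with respect to w_f.
            if use_disc:
                if cfg.check_routing:
                    h_fc = nn.param_hash(F, C)
                opt_d.step()
                if cfg.check_routing:
                    assert nn.param_hash(F, C) == h_fc, "step B modified w_f/w_c"

            ep_lc += lc * len(xb)
            ep_ld += ld * (len(x_all) if adversarial else 1)
            ep_correct += int(np.sum(probs.argmax(axis=1) == yb))
            ep_count += len(xb)

        # --- epoch bookkeeping ------------------------------------------
        if len(Xval):
            val_pred = predict(params, Xval, rval).argmax(axis=1)
            val_acc = float(np.mean(val_pred == yval))
            val_sen = _macro_sensitivity(yval, val_pred)
        else:
            val_acc = val_sen = float("nan")
        if use_disc and len(Xval) and len(Xt_held):
            d_eval_x = np.concatenate([Xval[:256], Xt_held[:256]])
            d_eval_d = np.concatenate([np.zeros(len(Xval[:256])),
                                       np.ones(len(Xt_held[:256]))])
            d_prob = nn.sigmoid(D.forward(F.forward(d_eval_x, train=False),
                                          train=False))
            disc_acc = float(np.mean((d_prob >= 0.5) == d_eval_d))
        else:
            disc_acc = float("nan")

        hist.epoch.append(epoch)
        hist.L_c.append(ep_lc / max(ep_count, 1))
        hist.L_d.append(ep_ld / max(ep_count * 2, 1) if adversarial else 0.0)
        hist.train_acc.append(ep_correct / max(ep_count, 1))
        hist.val_acc.append(val_acc)
        hist.val_macro_sen.append(val_sen)
        hist.disc_acc.append(disc_acc)

        sel = val_sen if len(Xval) else hist.train_acc[-1]
        if sel > best_sen:
            best_sen, best_epoch = sel, epoch
            best_state = nn.get_state(F, C, D)
        elif epoch - best_epoch >= cfg.patience:
            break

    nn.set_state(best_state, F, C, D)
    return params, hist
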