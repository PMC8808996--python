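"""Training and prediction for bootstrap-aggregated transfer models.

Each ensemble member is trained on an independent with-replacement
resample of the cells and of the patients.  Every Adam step draws a
minibatch of cells and a minibatch of patients, pushes both through the
shared hidden block (dropout active), computes the variant's weighted
loss — cell-type cross-entropy, patient cross-entropy or negative Cox
partial likelihood, batch MMD between the two latent sets, and L2 weight
decay — and backpropagates analytically.  Ensemble predictions are the
elementwise mean of member head outputs, which preserves the probability
simplex.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import DegasConfig, load_config, save_config
from .containers import ExpressionMatrix, LabelSet, check_paired
from .losses import class_loss, cox_loss, cox_loss_grad, mmd_loss_and_grad
from .network import DegasNetwork

_FORMAT_VERSION = 1


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


@dataclass
class DegasEnsemble:
    members: list[DegasNetwork]
    config: DegasConfig
    gene_ids: list[str]
    cell_classes: list[str] | None
    patient_head: str
    patient_classes: list[str] | None
    history: list[list[dict]] = field(default_factory=list)

    def _check(self, X: ExpressionMatrix) -> None:
        if X.stage != "unit":
            raise ValueError("prediction input must be unit-stage")
        if list(X.gene_ids) != list(self.gene_ids):
            missing = sorted(set(self.gene_ids) - set(X.gene_ids))
            raise ValueError(f"gene order mismatch; missing {missing[:5]}")

    def predict_patient_head(self, X: ExpressionMatrix) -> np.ndarray:
        """Ensemble-mean patient-head output.  On cells this yields
        disease-attribute impressions; on patients, the fitted predictor.
        Classification variants return a probability matrix, Cox variants
        a hazard-score vector."""
        self._check(X)
        if self.patient_head == "none":
            raise ValueError("this variant has no patient head")
        outs = []
        for net in self.members:
            Z, _ = net.hidden(X.values)
            outs.append(net.patient_probs(Z) if self.patient_head == "class"
                        else net.cox_scores(Z))
        return np.mean(outs, axis=0)

    def predict_cell_head(self, X: ExpressionMatrix) -> np.ndarray:
        """Ensemble-mean cell-type probabilities.  On patients this is the
        cellular-composition impression."""
        self._check(X)
        if self.cell_classes is None:
            raise ValueError("this variant has no cell head")
        outs = []
        for net in self.members:
            Z, _ = net.hidden(X.values)
            outs.append(net.class_probs(Z))
        return np.mean(outs, axis=0)

    # ------------------------------------------------------ save/load --

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        save_config(self.config, d / "config.yaml")
        manifest = {
            "format_version": _FORMAT_VERSION,
            "gene_ids": self.gene_ids,
            "cell_classes": self.cell_classes,
            "patient_head": self.patient_head,
            "patient_classes": self.patient_classes,
            "n_members": len(self.members),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for i, net in enumerate(self.members):
            np.savez(d / f"member_{i}.npz", **net.params)

    @classmethod
    def load(cls, directory: str | Path) -> "DegasEnsemble":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        if manifest["format_version"] > _FORMAT_VERSION:
            raise ValueError("model directory written by a newer format version")
        config = load_config(d / "config.yaml")
        members = []
        for i in range(manifest["n_members"]):
            net = DegasNetwork(
                manifest["gene_ids"], config.hidden_units, config.architecture,
                cell_classes=manifest["cell_classes"],
                patient_head=manifest["patient_head"],
                patient_classes=manifest["patient_classes"],
            )
            with np.load(d / f"member_{i}.npz") as data:
                net.params = {k: data[k].copy() for k in data.files}
            net.dtype = net.params["W0"].dtype  # match training precision
            members.append(net)
        return cls(members, config, manifest["gene_ids"], manifest["cell_classes"],
                   manifest["patient_head"], manifest["patient_classes"])


def _validate_inputs(X_cell, Y_cell, X_pat, Y_pat, config) -> None:
    for X, name in ((X_cell, "cell"), (X_pat, "patient")):
        if X.stage != "unit":
            raise ValueError(f"{name} matrix must be unit-stage (run the scaling pipeline first)")
    if list(X_cell.gene_ids) != list(X_pat.gene_ids):
        raise ValueError("cell and patient matrices must share an identical ordered gene set")
    if config.uses_cell_labels:
        if Y_cell is None or Y_cell.kind != "class_onehot":
            raise ValueError(f"variant {config.model_variant} requires one-hot cell labels")
        check_paired(X_cell, Y_cell)
    if config.patient_head == "class":
        if Y_pat is None or Y_pat.kind != "class_onehot":
            raise ValueError(f"variant {config.model_variant} requires one-hot patient labels")
        check_paired(X_pat, Y_pat)
    elif config.patient_head == "cox":
        if Y_pat is None or Y_pat.kind != "survival":
            raise ValueError(f"variant {config.model_variant} requires survival patient labels")
        check_paired(X_pat, Y_pat)
        if Y_pat.event.sum() == 0:
            raise ValueError("survival labels contain no events")


def _clamped_batch(requested: int, available: int, what: str) -> int:
    if requested > available:
        warnings.warn(
            f"{what} batch size {requested} exceeds resample size {available}; clamping",
            stacklevel=3,
        )
        return available
    return requested


def batch_losses_and_grads(
    net: DegasNetwork,
    Xc: np.ndarray,
    Yc: np.ndarray | None,
    Xp: np.ndarray,
    Y_pat,
    config: DegasConfig,
    dropout_rng: np.random.Generator | None = None,
    mmd_sigma0: float = 1.0,
) -> tuple[dict, dict]:
    """Component losses and parameter gradients for one joint batch.

    ``Y_pat`` is a one-hot array (classification head) or a
    ``(time, event)`` pair (Cox head).  Dropout is applied only when
    ``dropout_rng`` is given.

    The MMD kernel uses fixed bandwidths ``mmd_sigma0 * scales`` rather
    than a per-batch median heuristic: an adaptive bandwidth shrinks as
    the domains align, so the alignment force grows without bound and
    collapses the latent space (verified empirically); with fixed
    bandwidths the force vanishes smoothly as the domains coincide.
    """
    cb = Xc.shape[0]
    dtype = net.dtype
    Xb = np.vstack([Xc, Xp])
    keep = config.dropout_keep if dropout_rng is not None else 1.0
    Z, cache = net.hidden(Xb, dropout_keep=keep, rng=dropout_rng)
    Zc, Zp = Z[:cb], Z[cb:]
    g_latent = np.zeros_like(Z)
    comp: dict[str, float] = {}
    grads: dict[str, np.ndarray] = {}

    if config.uses_cell_labels:
        P = net.class_probs(Zc)
        comp["cell_class"] = class_loss(P, Yc)
        dlog = (config.lambda0 * (P - Yc) / cb).astype(dtype)
        g_latent[:cb] += dlog @ net.params["W_class"].T
        grads["W_class"] = Zc.T @ dlog
        grads["b_class"] = dlog.sum(axis=0)
    if config.patient_head == "class":
        Pp = net.patient_probs(Zp)
        comp["patient_class"] = class_loss(Pp, Y_pat)
        dlogp = (config.lambda1 * (Pp - Y_pat) / Xp.shape[0]).astype(dtype)
        g_latent[cb:] += dlogp @ net.params["W_pat"].T
        grads["W_pat"] = Zp.T @ dlogp
        grads["b_pat"] = dlogp.sum(axis=0)
    elif config.patient_head == "cox":
        tb, eb = Y_pat
        s = net.cox_scores(Zp)
        comp["patient_cox"] = cox_loss(s, tb, eb)
        du = (config.lambda1 * cox_loss_grad(s, tb, eb) * s * (1.0 - s))[:, None].astype(dtype)
        g_latent[cb:] += du @ net.params["W_cox"].T
        grads["W_cox"] = Zp.T @ du
        grads["b_cox"] = du.sum(axis=0)

    if config.lambda2 > 0:
        mmd, gC, gP = mmd_loss_and_grad(Zc, Zp, config.mmd_kernel_scales, mmd_sigma0)
        comp["mmd"] = mmd
        g_latent[:cb] += (config.lambda2 * gC).astype(dtype)
        g_latent[cb:] += (config.lambda2 * gP).astype(dtype)
    comp["l2"] = net.l2_penalty()

    hidden_grads = net.hidden_backward(g_latent, cache)
    grads.update(hidden_grads)
    if config.lambda3 > 0:
        nw = net.n_weights()
        for k in net.weight_names():
            grads[k] = grads.get(k, 0.0) + 2.0 * config.lambda3 * net.params[k] / nw
    return comp, grads


def _train_member(
    X_cell: ExpressionMatrix,
    Y_cell: LabelSet | None,
    X_pat: ExpressionMatrix,
    Y_pat: LabelSet | None,
    config: DegasConfig,
    member_index: int,
    log_every: int,
) -> tuple[DegasNetwork, list[dict]]:
    rng = np.random.default_rng([config.seed, member_index])
    n_cells, n_pats = X_cell.n_samples, X_pat.n_samples

    dtype = np.float32  # training numerics; prediction-time casts match
    boot_c = rng.integers(0, n_cells, size=n_cells)
    boot_p = rng.integers(0, n_pats, size=n_pats)
    Xc = X_cell.values[boot_c].astype(dtype)
    Xp = X_pat.values[boot_p].astype(dtype)
    Yc = Y_cell.onehot[boot_c].astype(dtype) if config.uses_cell_labels else None
    if config.patient_head == "class":
        Yp = Y_pat.onehot[boot_p].astype(dtype)
    elif config.patient_head == "cox":
        t_all, e_all = Y_pat.time[boot_p], Y_pat.event[boot_p]

    net = DegasNetwork(
        X_cell.gene_ids, config.hidden_units, config.architecture,
        cell_classes=(Y_cell.class_names if config.uses_cell_labels else None),
        patient_head=config.patient_head,
        patient_classes=(Y_pat.class_names if config.patient_head == "class" else None),
        rng=rng,
        dtype=dtype,
    )
    opt = _Adam(net.params, config.learning_rate)
    cb = _clamped_batch(config.cell_batch, n_cells, "cell")
    pb = _clamped_batch(config.patient_batch, n_pats, "patient")
    history: list[dict] = []

    for step in range(config.train_steps):
        ci = rng.choice(n_cells, size=cb, replace=False)
        if config.patient_head == "cox":
            for _ in range(50):
                pi = rng.choice(n_pats, size=pb, replace=False)
                if e_all[pi].sum() > 0:
                    break
            else:
                raise RuntimeError("could not draw a patient batch containing an event")
        else:
            pi = rng.choice(n_pats, size=pb, replace=False)

        Yc_b = Yc[ci] if config.uses_cell_labels else None
        if config.patient_head == "class":
            Yp_b = Yp[pi]
        elif config.patient_head == "cox":
            Yp_b = (t_all[pi], e_all[pi])
        else:
            Yp_b = None
        dropout_rng = rng if config.dropout_keep < 1.0 else None
        comp, grads = batch_losses_and_grads(net, Xc[ci], Yc_b, Xp[pi], Yp_b,
                                             config, dropout_rng=dropout_rng)
        opt.step(net.params, grads)
        if log_every and (step % log_every == 0 or step == config.train_steps - 1):
            history.append({"step": step, **comp})
    return net, history


def train(
    X_cell: ExpressionMatrix,
    Y_cell: LabelSet | None,
    X_pat: ExpressionMatrix,
    Y_pat: LabelSet | None,
    config: DegasConfig,
    log_every: int = 100,
) -> DegasEnsemble:
    """Train a bootstrap-aggregated ensemble of ``config.n_bootstrap``
    networks; deterministic given ``config.seed``."""
    _validate_inputs(X_cell, Y_cell, X_pat, Y_pat, config)
    members, histories = [], []
    for m in range(config.n_bootstrap):
        net, hist = _train_member(X_cell, Y_cell, X_pat, Y_pat, config, m, log_every)
        members.append(net)
        histories.append(hist)
    return DegasEnsemble(
        members, config, list(X_cell.gene_ids),
        (list(Y_cell.class_names) if config.uses_cell_labels else None),
        config.patient_head,
        (list(Y_pat.class_names) if config.patient_head == "class" else None),
        histories,
    )


def predict_patient_head(ens: DegasEnsemble, X: ExpressionMatrix) -> np.ndarray:
    return ens.predict_patient_head(X)


def predict_cell_head(ens: DegasEnsemble, X: ExpressionMatrix) -> np.ndarray:
    return ens.predict_cell_head(X)


__all__ = ["DegasEnsemble", "train", "predict_patient_head", "predict_cell_head",
           "batch_losses_and_grads"]
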