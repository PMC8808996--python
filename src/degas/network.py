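"""The multitask network: a shared hidden block with a cell-type head and
a patient head.

The hidden block is either a single sigmoid layer or a three-layer
DenseNet in which layer ``l`` receives the concatenation of the original
input and every earlier layer's activation; all layers have
``hidden_units`` sigmoid units.  Heads are linear maps from the final
hidden activation: a softmax classification head and/or a single
sigmoid "hazard score" output for survival.  Dropout (inverted, hidden
activations only) is applied during training.

All gradients are derived analytically and checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .containers import ExpressionMatrix


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DegasNetwork:
    """One member network. Parameters live in ``self.params`` (dict of
    numpy arrays); layer weights are ``W{l}``/``b{l}``, the class head
    ``W_class``/``b_class``, the Cox head ``W_cox``/``b_cox``."""

    def __init__(
        self,
        gene_ids: list[str],
        hidden_units: int,
        architecture: str = "densenet3",
        cell_classes: list[str] | None = None,
        patient_head: str = "none",  # class | cox | none
        patient_classes: list[str] | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ) -> None:
        if architecture not in ("single_layer", "densenet3"):
            raise ValueError(f"unknown architecture {architecture!r}")
        self.gene_ids = [str(g) for g in gene_ids]
        self.hidden_units = int(hidden_units)
        self.architecture = architecture
        self.n_layers = 1 if architecture == "single_layer" else 3
        self.cell_classes = list(cell_classes) if cell_classes else None
        self.patient_head = patient_head
        self.patient_classes = list(patient_classes) if patient_classes else None
        if patient_head == "class" and not self.patient_classes:
            raise ValueError("patient_head='class' requires patient_classes")
        self.dtype = np.dtype(dtype)  # float32 for training speed, float64 default
        self.params: dict[str, np.ndarray] = {}
        if rng is None:
            rng = np.random.default_rng(0)
        self._init_params(rng)

    # ------------------------------------------------------------ init --

    def _glorot(self, rng, fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(self.dtype)

    def _init_params(self, rng: np.random.Generator) -> None:
        G, H = len(self.gene_ids), self.hidden_units
        for l in range(self.n_layers):
            fan_in = G + l * H
            self.params[f"W{l}"] = self._glorot(rng, fan_in, H)
            self.params[f"b{l}"] = np.zeros(H, dtype=self.dtype)
        if self.cell_classes is not None:
            self.params["W_class"] = self._glorot(rng, H, len(self.cell_classes))
            self.params["b_class"] = np.zeros(len(self.cell_classes), dtype=self.dtype)
        if self.patient_head == "class":
            self.params["W_pat"] = self._glorot(rng, H, len(self.patient_classes))
            self.params["b_pat"] = np.zeros(len(self.patient_classes), dtype=self.dtype)
        elif self.patient_head == "cox":
            self.params["W_cox"] = self._glorot(rng, H, 1)
            self.params["b_cox"] = np.zeros(1, dtype=self.dtype)

    def weight_names(self) -> list[str]:
        return [k for k in self.params if k.startswith("W")]

    # --------------------------------------------------------- forward --

    def _check_genes(self, X: ExpressionMatrix) -> None:
        if X.stage != "unit":
            raise ValueError(f"network input must be unit-stage, got {X.stage!r}")
        if list(X.gene_ids) != self.gene_ids:
            missing = sorted(set(self.gene_ids) - set(X.gene_ids))
            raise ValueError(
                f"gene order mismatch with trained network; "
                f"{len(missing)} training genes missing, e.g. {missing[:5]}"
            )

    def hidden(
        self,
        X: np.ndarray,
        dropout_keep: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Forward pass of the hidden block on a raw array.

        Returns the final (post-dropout) activation and a cache for
        :meth:`hidden_backward`.
        """
        X = np.asarray(X, dtype=self.dtype)
        inputs, acts_raw, mults, acts_drop = [], [], [], []
        for l in range(self.n_layers):
            inp = X if l == 0 else np.hstack([X] + acts_drop)
            a = sigmoid(inp @ self.params[f"W{l}"] + self.params[f"b{l}"])
            if dropout_keep < 1.0:
                if rng is None:
                    raise ValueError("dropout requires an rng")
                mult = (rng.random(a.shape) < dropout_keep).astype(self.dtype) / dropout_keep
            else:
                mult = None
            inputs.append(inp)
            acts_raw.append(a)
            mults.append(mult)
            acts_drop.append(a if mult is None else a * mult)
        cache = {"X": X, "inputs": inputs, "acts_raw": acts_raw,
                 "mults": mults, "acts_drop": acts_drop}
        return acts_drop[-1], cache

    def hidden_backward(self, g_latent: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Backpropagate a gradient w.r.t. the final hidden activation
        through the (dense) hidden block; returns per-parameter grads."""
        G = cache["X"].shape[1]
        H = self.hidden_units
        grads: dict[str, np.ndarray] = {}
        g_drop = [np.zeros_like(a) for a in cache["acts_raw"]]
        g_drop[-1] = g_drop[-1] + g_latent
        for l in range(self.n_layers - 1, -1, -1):
            mult = cache["mults"][l]
            g_raw = g_drop[l] if mult is None else g_drop[l] * mult
            a = cache["acts_raw"][l]
            g_pre = g_raw * a * (1.0 - a)
            grads[f"W{l}"] = cache["inputs"][l].T @ g_pre
            grads[f"b{l}"] = g_pre.sum(axis=0)
            if l > 0:
                # only the activation segments of the concatenated input
                # are needed upstream; skip the (large) raw-X block
                g_acts = g_pre @ self.params[f"W{l}"][G:].T
                for j in range(l):
                    g_drop[j] += g_acts[:, j * H: (j + 1) * H]
        return grads

    def class_probs(self, Z: np.ndarray) -> np.ndarray:
        if self.cell_classes is None:
            raise ValueError("network has no cell classification head")
        return softmax(Z @ self.params["W_class"] + self.params["b_class"])

    def patient_probs(self, Z: np.ndarray) -> np.ndarray:
        if self.patient_head != "class":
            raise ValueError("network has no patient classification head")
        return softmax(Z @ self.params["W_pat"] + self.params["b_pat"])

    def cox_scores(self, Z: np.ndarray) -> np.ndarray:
        if self.patient_head != "cox":
            raise ValueError("network has no Cox head")
        return sigmoid(Z @ self.params["W_cox"] + self.params["b_cox"]).reshape(-1)

    def n_weights(self) -> int:
        return int(sum(self.params[k].size for k in self.weight_names()))

    def l2_penalty(self) -> float:
        """Mean squared layer weight (biases excluded).

        Normalising by parameter count keeps the default penalty weight
        meaningful across gene-set sizes and architectures; an
        unnormalised sum at these layer sizes would dwarf the data losses
        and drive all weights to zero.
        """
        total = sum((self.params[k] ** 2).sum() for k in self.weight_names())
        return float(total / self.n_weights())


# ------------------------------------------------- public operations ----

def forward_hidden(net: DegasNetwork, X: ExpressionMatrix) -> np.ndarray:
    """Latent representation (final hidden activation, no dropout)."""
    net._check_genes(X)
    Z, _ = net.hidden(X.values)
    return Z


def forward_class(net: DegasNetwork, X: ExpressionMatrix, head: str = "cell") -> np.ndarray:
    """Softmax class probabilities from the requested head; rows sum to 1."""
    Z = forward_hidden(net, X)
    return net.class_probs(Z) if head == "cell" else net.patient_probs(Z)


def forward_cox(net: DegasNetwork, X: ExpressionMatrix) -> np.ndarray:
    """Sigmoid hazard scores in (0,1); larger = higher proportional hazard."""
    Z = forward_hidden(net, X)
    return net.cox_scores(Z)


__all__ = ["DegasNetwork", "forward_hidden", "forward_class", "forward_cox",
           "sigmoid", "softmax"]
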