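"""Loss functions for the multitask transfer-learning model.

Four ingredients are combined per model variant:

* cell-type classification loss — mean multiclass cross-entropy;
* patient loss — cross-entropy (classification head) or the negative Cox
  partial log-likelihood (survival head, Breslow tie handling, risk set
  ``{j : t_j >= t_i}``);
* a squared maximum-mean-discrepancy (MMD) penalty between the latent
  representations of cells and patients, with a multi-scale Gaussian
  kernel (biased V-statistic, so identical sets give exactly 0);
* an L2 penalty on layer weights (biases excluded).

The weighted total is ``lambda0*cell + lambda1*patient + lambda2*MMD +
lambda3*L2`` with terms dropped according to the variant (``Blank*`` has
no cell term, ``*Blank`` no patient term).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

EPS = 1e-8


# ---------------------------------------------------------------- Cox ----

def _risk_mask(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be equal-length vectors")
    if np.any(time <= 0):
        raise ValueError("survival times must be strictly positive")
    ev = np.flatnonzero(event == 1)
    if ev.size == 0:
        raise ValueError("no events in batch")
    # mask[e, j] = 1 iff sample j is at risk at event e's time (t_j >= t_e)
    mask = time[None, :] >= time[ev, None]
    return ev, mask


def cox_loss(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Negative Cox partial log-likelihood of per-sample risk scores.

    ``-sum_{i: event} [ s_i - log sum_{t_j >= t_i} exp(s_j) ]``; lower is
    better and the value is invariant to adding a constant to all scores.
    """
    scores = np.asarray(scores, float).reshape(-1)
    ev, mask = _risk_mask(time, event)
    if scores.shape[0] != np.asarray(time).shape[0]:
        raise ValueError("scores length must match time/event length")
    lse = np.array([logsumexp(scores[m]) for m in mask])
    return float(-(scores[ev] - lse).sum())


def cox_loss_grad(scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Gradient of :func:`cox_loss` with respect to the scores."""
    scores = np.asarray(scores, float).reshape(-1)
    ev, mask = _risk_mask(time, event)
    p = np.exp(scores - scores.max())
    denom = mask @ p  # one risk-set sum per event
    grad = -np.asarray(event, float).copy()
    grad += p * (mask.T @ (1.0 / denom))
    return grad


# ----------------------------------------------------- classification ----

def class_loss(P: np.ndarray, Y: np.ndarray) -> float:
    """Mean multiclass cross-entropy of predicted probabilities ``P``
    against one-hot truth ``Y``; probabilities are clamped at 1e-8."""
    P = np.asarray(P, float)
    Y = np.asarray(Y, float)
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: P {P.shape} vs Y {Y.shape}")
    return float(-(Y * np.log(np.clip(P, EPS, None))).sum() / P.shape[0])


# ---------------------------------------------------------------- MMD ----

def _as_float(Z: np.ndarray) -> np.ndarray:
    # float64 throughout: kernel weights scale like 1/sigma^2 and can
    # overflow float32 when the latent sets nearly coincide
    return np.asarray(Z, dtype=np.float64)


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = (A * A).sum(axis=1)[:, None]
    bb = (B * B).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * (A @ B.T), 0.0)


def median_bandwidth(Z_a: np.ndarray, Z_b: np.ndarray) -> float:
    """Median pairwise Euclidean distance of the pooled samples (the
    median heuristic); falls back to 1 when degenerate.

    Floored at 1e-4 so kernel gradients stay finite when the two sets
    nearly coincide (the MMD optimum).
    """
    Z = np.vstack([_as_float(Z_a), _as_float(Z_b)])
    d2 = _sq_dists(Z, Z)
    iu = np.triu_indices(Z.shape[0], k=1)
    med = float(np.sqrt(np.median(d2[iu]))) if iu[0].size else 0.0
    if med == 0.0:
        return 1.0
    return max(med, 1e-4)


def _multiscale_kernel(d2: np.ndarray, scales, sigma0: float) -> np.ndarray:
    K = np.zeros_like(d2)
    for s in scales:
        K += np.exp(-d2 / (2.0 * (s * sigma0) ** 2))
    return K


def mmd_loss(
    Z_cell: np.ndarray,
    Z_pat: np.ndarray,
    scales=(1.0, 2.0, 4.0, 8.0, 16.0),
    sigma0: float | None = None,
) -> float:
    """Biased squared-MMD estimate between two latent sample sets under a
    multi-scale Gaussian kernel.  Zero iff the empirical kernel mean
    embeddings coincide (in particular for identical sets)."""
    Z_cell = np.atleast_2d(_as_float(Z_cell))
    Z_pat = np.atleast_2d(_as_float(Z_pat))
    if Z_cell.shape[0] < 2 or Z_pat.shape[0] < 2:
        raise ValueError("MMD needs at least 2 samples on each side")
    if Z_cell.shape[1] != Z_pat.shape[1]:
        raise ValueError("latent dimensions differ")
    if sigma0 is None:
        sigma0 = median_bandwidth(Z_cell, Z_pat)
    Kcc = _multiscale_kernel(_sq_dists(Z_cell, Z_cell), scales, sigma0)
    Kpp = _multiscale_kernel(_sq_dists(Z_pat, Z_pat), scales, sigma0)
    Kcp = _multiscale_kernel(_sq_dists(Z_cell, Z_pat), scales, sigma0)
    return float(Kcc.mean() + Kpp.mean() - 2.0 * Kcp.mean())


def mmd_loss_grad(
    Z_cell: np.ndarray,
    Z_pat: np.ndarray,
    scales=(1.0, 2.0, 4.0, 8.0, 16.0),
    sigma0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of :func:`mmd_loss` w.r.t. both latent matrices.

    The kernel bandwidth (median heuristic) is treated as a constant.
    """
    C = _as_float(Z_cell)
    P = _as_float(Z_pat)
    nc, npat = C.shape[0], P.shape[0]
    if sigma0 is None:
        sigma0 = median_bandwidth(C, P)
    d2_cc = _sq_dists(C, C)
    d2_pp = _sq_dists(P, P)
    d2_cp = _sq_dists(C, P)
    gC = np.zeros_like(C)
    gP = np.zeros_like(P)
    for s in scales:
        inv2s2 = 1.0 / ((s * sigma0) ** 2)
        Wcc = np.exp(-d2_cc * (0.5 * inv2s2)) * inv2s2
        Wpp = np.exp(-d2_pp * (0.5 * inv2s2)) * inv2s2
        Wcp = np.exp(-d2_cp * (0.5 * inv2s2)) * inv2s2
        # d/dx exp(-|x-y|^2/(2sig^2)) = -W * (x - y)
        gC += (-2.0 / nc**2) * (Wcc.sum(1)[:, None] * C - Wcc @ C)
        gC += (2.0 / (nc * npat)) * (Wcp.sum(1)[:, None] * C - Wcp @ P)
        gP += (-2.0 / npat**2) * (Wpp.sum(1)[:, None] * P - Wpp @ P)
        gP += (2.0 / (nc * npat)) * (Wcp.sum(0)[:, None] * P - Wcp.T @ C)
    return gC, gP


def mmd_loss_and_grad(
    Z_cell: np.ndarray,
    Z_pat: np.ndarray,
    scales,
    sigma0: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fused value + gradients of the squared MMD at a fixed bandwidth.

    Shares the kernel evaluations between the value and the gradients
    (the training hot path); works in the input dtype.  Requires an
    explicit ``sigma0``.
    """
    C, P = np.asarray(Z_cell), np.asarray(Z_pat)
    nc, npat = C.shape[0], P.shape[0]
    d2_cc = _sq_dists(C, C)
    d2_pp = _sq_dists(P, P)
    d2_cp = _sq_dists(C, P)
    value = 0.0
    gC = np.zeros_like(C)
    gP = np.zeros_like(P)
    for s in scales:
        inv2s2 = 1.0 / ((s * sigma0) ** 2)
        Kcc = np.exp(d2_cc * (-0.5 * inv2s2))
        Kpp = np.exp(d2_pp * (-0.5 * inv2s2))
        Kcp = np.exp(d2_cp * (-0.5 * inv2s2))
        value += Kcc.mean() + Kpp.mean() - 2.0 * Kcp.mean()
        Wcc, Wpp, Wcp = Kcc * inv2s2, Kpp * inv2s2, Kcp * inv2s2
        gC += (-2.0 / nc**2) * (Wcc.sum(1)[:, None] * C - Wcc @ C)
        gC += (2.0 / (nc * npat)) * (Wcp.sum(1)[:, None] * C - Wcp @ P)
        gP += (-2.0 / npat**2) * (Wpp.sum(1)[:, None] * P - Wpp @ P)
        gP += (2.0 / (nc * npat)) * (Wcp.sum(0)[:, None] * P - Wcp.T @ C)
    return float(value), gC, gP


# -------------------------------------------------------------- total ----

_REQUIRED = {
    "ClassCox": ("cell_class", "patient_cox"),
    "ClassClass": ("cell_class", "patient_class"),
    "ClassBlank": ("cell_class",),
    "BlankClass": ("patient_class",),
    "BlankCox": ("patient_cox",),
}


def total_loss(variant: str, losses: dict, config) -> float:
    """Weighted sum of component losses for a model variant.

    ``losses`` maps component names (``cell_class``, ``patient_class``,
    ``patient_cox``, ``mmd``, ``l2``) to unweighted values; ``l2`` is the
    network's weight penalty (mean squared layer weight, biases excluded).
    """
    if variant not in _REQUIRED:
        raise ValueError(f"unknown variant {variant!r}")
    missing = [k for k in _REQUIRED[variant] if k not in losses]
    if missing:
        raise ValueError(f"variant {variant} requires loss components {missing}")
    total = config.lambda2 * losses.get("mmd", 0.0) + config.lambda3 * losses.get("l2", 0.0)
    if "cell_class" in _REQUIRED[variant]:
        total += config.lambda0 * losses["cell_class"]
    if "patient_class" in _REQUIRED[variant]:
        total += config.lambda1 * losses["patient_class"]
    if "patient_cox" in _REQUIRED[variant]:
        total += config.lambda1 * losses["patient_cox"]
    return float(total)


__all__ = [
    "cox_loss",
    "cox_loss_grad",
    "class_loss",
    "mmd_loss",
    "mmd_loss_grad",
    "mmd_loss_and_grad",
    "median_bandwidth",
    "total_loss",
    "EPS",
]
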