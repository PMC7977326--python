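"""Two-way orthogonal PLS model layer.

The model decomposes two blocks measured on the same samples as

    X = T Wᵀ + T⊥ P⊥ᵀ + E,      Y = U Cᵀ + U⊥ Q⊥ᵀ + F,

with the inner relation U = T·B_T + H (and symmetrically T = U·B_U).  The
joint scores T, U capture variation shared between the blocks; the orthogonal
(specific) parts T⊥, U⊥ capture systematic variation in one block unrelated
to the other; E, F are residuals.  Estimation first strips the orthogonal
subspaces from each block and then maximises covariance between the filtered
blocks with (optionally penalised) NIPALS.  Penalties apply only to the joint
loadings; the orthogonal estimation is never penalised.

With no penalty this is O2PLS; with an L1 penalty SO2PLS; with a group-wise
penalty GO2PLS; with Kx = Ky = 0 the same code gives PLS / sPLS / gPLS.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .blocks import OmicsBlock, center_scale
from .core import (
    LoadingPair,
    OverPenalizedError,
    PenaltySpec,
    deflate,
    nipals_pair,
    orthogonalize_loading,
)

logger = logging.getLogger(__name__)

__all__ = ["O2Fit", "fit", "estimate_orthogonal", "filter_orthogonal",
           "transform", "predict", "save_fit", "load_fit"]

_SERIAL_VERSION = 1


@dataclass
class O2Fit:
    """A fitted two-block decomposition.

    Arrays follow the standard O2PLS symbols: joint loadings ``W`` (p x K),
    ``C`` (q x K); joint scores ``T``, ``U`` (N x K); orthogonal X-part basis
    ``Worth`` (p x Kx), scores ``Torth`` (N x Kx), loadings ``Porth`` (p x Kx);
    Y-side analogues ``Corth``/``Uorth``/``Qorth``; diagonal inner-relation
    coefficient matrices ``B_T``, ``B_U`` (K x K).  ``x_rotation``/
    ``y_rotation`` map filtered data to scores (``T = X̃ · x_rotation``) and
    are what :func:`transform` applies to new samples.
    """

    W: np.ndarray
    C: np.ndarray
    T: np.ndarray
    U: np.ndarray
    Worth: np.ndarray
    Torth: np.ndarray
    Porth: np.ndarray
    Corth: np.ndarray
    Uorth: np.ndarray
    Qorth: np.ndarray
    B_T: np.ndarray
    B_U: np.ndarray
    x_rotation: np.ndarray
    y_rotation: np.ndarray
    x_means: np.ndarray
    y_means: np.ndarray
    x_scales: np.ndarray | None
    y_scales: np.ndarray | None
    x_feature_ids: list[str]
    y_feature_ids: list[str]
    sample_ids: list[str]
    K: int
    Kx: int
    Ky: int
    pen_x: PenaltySpec | None = None
    pen_y: PenaltySpec | None = None
    variance_summary: dict = field(default_factory=dict)
    convergence: list[dict] = field(default_factory=list)

    @property
    def selected_x(self) -> np.ndarray:
        """Indices of X features with a non-zero loading in any component."""
        return np.flatnonzero(np.any(self.W != 0, axis=1))

    @property
    def selected_y(self) -> np.ndarray:
        return np.flatnonzero(np.any(self.C != 0, axis=1))


def _as_block(X, name: str) -> OmicsBlock:
    if isinstance(X, OmicsBlock):
        return X
    return OmicsBlock(np.asarray(X, dtype=float))


def _sequential_joint(
    X: np.ndarray,
    Y: np.ndarray,
    K: int,
    pen_x: PenaltySpec,
    pen_y: PenaltySpec,
    tol: float,
    max_iter: int,
    allow_rank_exhausted: bool = False,
) -> tuple[np.ndarray, ...]:
    """Extract K joint loading pairs with deflation and orthogonalisation.

    Returns (W, C, T, U, P, Q, diagnostics) where P, Q are the score-regression
    loadings used to build the rotation matrices.  When the cross-covariance
    is numerically exhausted before K components (exactly low-rank data),
    extraction either stops early (``allow_rank_exhausted``) or raises.
    """
    p, q = X.shape[1], Y.shape[1]
    Xk, Yk = X.copy(), Y.copy()
    W = np.zeros((p, K))
    C = np.zeros((q, K))
    T = np.zeros((X.shape[0], K))
    U = np.zeros((Y.shape[0], K))
    P = np.zeros((p, K))
    Q = np.zeros((q, K))
    diags: list[dict] = []

    def _pen_for(pen, k):
        # a sequence gives one spec per component; a single spec is constant
        if isinstance(pen, (list, tuple)):
            return pen[k]
        return pen

    cov_first = None
    n_done = K
    for k in range(K):
        try:
            pair = nipals_pair(
                Xk, Yk, _pen_for(pen_x, k), _pen_for(pen_y, k),
                tol=tol, max_iter=max_iter,
            )
        except OverPenalizedError:
            if allow_rank_exhausted and k > 0:
                n_done = k
                logger.info("cross-covariance exhausted after %d components", k)
                break
            raise
        cov_k = abs(float(pair.t @ pair.u))
        if cov_first is None:
            cov_first = max(cov_k, 1e-300)
        elif cov_k < 1e-10 * cov_first:
            if allow_rank_exhausted:
                n_done = k
                logger.info("cross-covariance exhausted after %d components", k)
                break
            raise ValueError(
                f"cross-covariance is numerically exhausted at component {k + 1}; "
                f"requested K={K} exceeds the joint rank of the data"
            )
        w, c = pair.w, pair.c
        if k > 0:
            w = orthogonalize_loading(w, [W[:, i] for i in range(k)])
            c = orthogonalize_loading(c, [C[:, i] for i in range(k)])
        t = Xk @ w
        u = Yk @ c
        W[:, k], C[:, k], T[:, k], U[:, k] = w, c, t, u
        P[:, k] = Xk.T @ t / (t @ t)
        Q[:, k] = Yk.T @ u / (u @ u)
        Xk = deflate(Xk, t)
        Yk = deflate(Yk, u)
        diags.append(
            {"component": k + 1, "iterations": pair.iterations,
             "converged": bool(pair.converged),
             "lam_w": pair.lam_w, "lam_c": pair.lam_c}
        )
    if n_done < K:
        W, C = W[:, :n_done], C[:, :n_done]
        T, U = T[:, :n_done], U[:, :n_done]
        P, Q = P[:, :n_done], Q[:, :n_done]
    return W, C, T, U, P, Q, diags


def estimate_orthogonal(
    X: np.ndarray, T: np.ndarray, Kx: int, W: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate ``Kx`` orthogonal (Y-unrelated) components of ``X``.

    From the joint residual ``E = X - T Wᵀ`` (or the regression residual when
    ``W`` is not supplied), the orthogonal basis ``Worth`` is taken as the
    first ``Kx`` left singular vectors of ``Eᵀ T`` — the directions of X
    structure entangled with the joint scores that Y cannot explain.  Returns
    ``(Worth, Torth, Porth)`` with ``Torth = X·Worth`` and ``Porth`` the
    regression of X on those scores; all empty when ``Kx = 0``.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    p = X.shape[1]
    if Kx < 0:
        raise ValueError("Kx must be non-negative")
    if Kx == 0:
        n = X.shape[0]
        return np.zeros((p, 0)), np.zeros((n, 0)), np.zeros((p, 0))
    if W is not None:
        E = X - T @ W.T
    else:
        coef, *_ = np.linalg.lstsq(T, X, rcond=None)
        E = X - T @ coef
    G = E.T @ T
    u_svd, s, _ = np.linalg.svd(G, full_matrices=False)
    scale = np.linalg.norm(X) * np.linalg.norm(T)
    rank = int(np.sum(s > max(scale, 1e-300) * 1e-12))
    if Kx > rank:
        raise ValueError(
            f"Kx={Kx} exceeds the rank {rank} of the joint-residual cross product"
        )
    Worth = u_svd[:, :Kx]
    Torth = X @ Worth
    Porth = X.T @ Torth @ np.linalg.inv(Torth.T @ Torth)
    return Worth, Torth, Porth


def filter_orthogonal(X: np.ndarray, Torth: np.ndarray) -> np.ndarray:
    """Project the orthogonal scores out: ``X̃ = (I - T⊥(T⊥ᵀT⊥)⁻¹T⊥ᵀ) X``."""
    X = np.asarray(X, dtype=float)
    Torth = np.asarray(Torth, dtype=float)
    if Torth.size == 0:
        return X.copy()
    G = Torth.T @ Torth
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("orthogonal scores are collinear; cannot filter")
    return X - Torth @ np.linalg.solve(G, Torth.T @ X)


def fit(
    X,
    Y,
    K: int = 1,
    Kx: int = 0,
    Ky: int = 0,
    pen_x: PenaltySpec | None = None,
    pen_y: PenaltySpec | None = None,
    scale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> O2Fit:
    """Fit the two-block decomposition with ``K`` joint and ``Kx``/``Ky``
    orthogonal components.

    Pipeline: center both blocks; estimate ``K + max(Kx, Ky)`` unpenalised
    joint components to expose the orthogonal structure; estimate and filter
    out the orthogonal parts; re-estimate ``K`` (optionally penalised) joint
    components on the filtered blocks with deflation and loading
    orthogonalisation; fit the diagonal inner relation by least squares.

    ``X``/``Y`` may be arrays, DataFrames or :class:`OmicsBlock`s with matched
    sample order.
    """
    pen_x = pen_x or PenaltySpec.none()
    pen_y = pen_y or PenaltySpec.none()
    bx = _as_block(X, "X")
    by = _as_block(Y, "Y")
    if bx.n_samples != by.n_samples:
        raise ValueError(
            f"X has {bx.n_samples} samples but Y has {by.n_samples}"
        )
    if K < 1:
        raise ValueError("K must be at least 1 (no joint part to estimate otherwise)")
    n, p, q = bx.n_samples, bx.n_features, by.n_features
    if K + max(Kx, Ky) > min(n, p, q) - 1:
        raise ValueError(
            f"K + max(Kx, Ky) = {K + max(Kx, Ky)} exceeds min(N, p, q) - 1 = {min(n, p, q) - 1}"
        )
    bx = center_scale(bx, scale=scale)
    by = center_scale(by, scale=scale)
    Xc, Yc = bx.data, by.data

    # initial unpenalised joint fit; extra components expose orthogonal structure
    K_init = K + max(Kx, Ky)
    W0, C0, T0, U0, *_ = _sequential_joint(
        Xc, Yc, K_init, PenaltySpec.none(), PenaltySpec.none(), tol, max_iter,
        allow_rank_exhausted=True,
    )
    Worth, Torth, Porth = estimate_orthogonal(Xc, T0, Kx, W0)
    Corth, Uorth, Qorth = estimate_orthogonal(Yc, U0, Ky, C0)
    Xf = filter_orthogonal(Xc, Torth)
    Yf = filter_orthogonal(Yc, Uorth)

    W, C, T, U, P, Q, diags = _sequential_joint(
        Xf, Yf, K, pen_x, pen_y, tol, max_iter
    )
    # rotations mapping filtered data to scores: T = X̃ · W (PᵀW)⁻¹
    x_rotation = W @ np.linalg.inv(P.T @ W)
    y_rotation = C @ np.linalg.inv(Q.T @ C)

    d_t = np.array([(T[:, k] @ U[:, k]) / (T[:, k] @ T[:, k]) for k in range(K)])
    d_u = np.array([(U[:, k] @ T[:, k]) / (U[:, k] @ U[:, k]) for k in range(K)])
    B_T = np.diag(d_t)
    B_U = np.diag(d_u)

    def _var_summary(M, S, L, Sorth, Lorth):
        total = float(np.sum(M**2))
        joint = float(np.sum((S @ L.T) ** 2))
        orth = float(np.sum((Sorth @ Lorth.T) ** 2)) if Sorth.size else 0.0
        resid = float(np.sum((M - S @ L.T - (Sorth @ Lorth.T if Sorth.size else 0.0)) ** 2))
        if total == 0:
            return {"joint": 0.0, "orthogonal": 0.0, "residual": 0.0}
        return {"joint": joint / total, "orthogonal": orth / total,
                "residual": resid / total}

    variance_summary = {
        "x": _var_summary(Xc, T, W, Torth, Porth),
        "y": _var_summary(Yc, U, C, Uorth, Qorth),
    }

    return O2Fit(
        W=W, C=C, T=T, U=U,
        Worth=Worth, Torth=Torth, Porth=Porth,
        Corth=Corth, Uorth=Uorth, Qorth=Qorth,
        B_T=B_T, B_U=B_U,
        x_rotation=x_rotation, y_rotation=y_rotation,
        x_means=bx.means, y_means=by.means,
        x_scales=bx.scales, y_scales=by.scales,
        x_feature_ids=bx.feature_ids, y_feature_ids=by.feature_ids,
        sample_ids=bx.sample_ids,
        K=K, Kx=Kx, Ky=Ky, pen_x=pen_x, pen_y=pen_y,
        variance_summary=variance_summary, convergence=diags,
    )


def _prepare_new(fitres: O2Fit, new, side: str) -> np.ndarray:
    """Center new data with training constants, checking the feature set."""
    ids = fitres.x_feature_ids if side == "x" else fitres.y_feature_ids
    means = fitres.x_means if side == "x" else fitres.y_means
    scales = fitres.x_scales if side == "x" else fitres.y_scales
    if isinstance(new, OmicsBlock):
        if new.feature_ids != ids:
            missing = sorted(set(ids) - set(new.feature_ids))
            raise ValueError(
                f"feature set of new {side.upper()} does not match training block; "
                f"missing: {missing[:10]}"
            )
        arr = new.data
    else:
        arr = np.asarray(new, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] != len(ids):
            raise ValueError(
                f"new {side.upper()} has {arr.shape[1]} features; training had {len(ids)}"
            )
    out = arr - means
    if scales is not None:
        out = out / scales
    return out


def transform(fitres: O2Fit, new, side: str = "x") -> np.ndarray:
    """Joint scores of new samples.

    The training orthogonal filter (``Worth``/``Porth``, never re-estimated)
    is applied first — new orthogonal scores ``Xnew·Worth`` are removed via
    the orthogonal loadings — then the filtered data is rotated to joint
    scores.
    """
    if side not in ("x", "y"):
        raise ValueError("side must be 'x' or 'y'")
    Z = _prepare_new(fitres, new, side)
    basis = fitres.Worth if side == "x" else fitres.Corth
    load = fitres.Porth if side == "x" else fitres.Qorth
    rot = fitres.x_rotation if side == "x" else fitres.y_rotation
    if basis.size:
        Z = Z - (Z @ basis) @ load.T
    return Z @ rot


def predict(fitres: O2Fit, new, direction: str = "x_to_y") -> np.ndarray:
    """Predict one block from the other through the joint subspace.

    ``x_to_y``: ``Ŷ = Tnew·B_T·Cᵀ`` plus Y's centering constants.  Only the
    joint part is predictable; the target block's orthogonal variation is, by
    model assumption, unrelated to the predictor block.
    """
    if direction == "x_to_y":
        scores = transform(fitres, new, side="x") @ fitres.B_T
        out = scores @ fitres.C.T
        if fitres.y_scales is not None:
            out = out * fitres.y_scales
        return out + fitres.y_means
    if direction == "y_to_x":
        scores = transform(fitres, new, side="y") @ fitres.B_U
        out = scores @ fitres.W.T
        if fitres.x_scales is not None:
            out = out * fitres.x_scales
        return out + fitres.x_means
    raise ValueError("direction must be 'x_to_y' or 'y_to_x'")


# ---------------------------------------------------------------------------
# serialization: one JSON file; floats round-trip exactly via repr


def _pen_to_json(pen) -> dict | list | None:
    if pen is None:
        return None
    if isinstance(pen, (list, tuple)):
        return [_pen_to_json(p) for p in pen]
    d = {"mode": pen.mode, "keep": pen.keep, "lam": pen.lam}
    if pen.groups is not None:
        d["groups"] = {
            "names": pen.groups.names,
            "indices": [ix.tolist() for ix in pen.groups.indices],
        }
    return d


def _pen_from_json(d) -> PenaltySpec | list | None:
    if d is None:
        return None
    if isinstance(d, list):
        return [_pen_from_json(x) for x in d]
    groups = None
    if d.get("groups"):
        from .blocks import GroupStructure

        groups = GroupStructure(
            names=d["groups"]["names"],
            indices=[np.array(ix, dtype=int) for ix in d["groups"]["indices"]],
        )
    return PenaltySpec(mode=d["mode"], keep=d["keep"], lam=d["lam"], groups=groups)


_ARRAY_FIELDS = [
    "W", "C", "T", "U", "Worth", "Torth", "Porth", "Corth", "Uorth", "Qorth",
    "B_T", "B_U", "x_rotation", "y_rotation", "x_means", "y_means",
]


def save_fit(fitres: O2Fit, path) -> None:
    """Write a fitted model to a single JSON file (arrays round-trip exactly)."""
    doc: dict = {
        "format": "go2pls-model",
        "version": _SERIAL_VERSION,
        "K": fitres.K, "Kx": fitres.Kx, "Ky": fitres.Ky,
        "x_feature_ids": fitres.x_feature_ids,
        "y_feature_ids": fitres.y_feature_ids,
        "sample_ids": fitres.sample_ids,
        "pen_x": _pen_to_json(fitres.pen_x),
        "pen_y": _pen_to_json(fitres.pen_y),
        "variance_summary": fitres.variance_summary,
        "convergence": fitres.convergence,
        "arrays": {},
        "x_scales": None if fitres.x_scales is None else fitres.x_scales.tolist(),
        "y_scales": None if fitres.y_scales is None else fitres.y_scales.tolist(),
    }
    for name in _ARRAY_FIELDS:
        arr = getattr(fitres, name)
        doc["arrays"][name] = {"shape": list(arr.shape), "data": arr.ravel().tolist()}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_fit(path) -> O2Fit:
    """Read a model written by :func:`save_fit`."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "go2pls-model":
        raise ValueError(f"{path} is not a go2pls model file")
    arrays = {
        name: np.array(spec["data"], dtype=float).reshape(spec["shape"])
        for name, spec in doc["arrays"].items()
    }
    return O2Fit(
        **arrays,
        x_scales=None if doc["x_scales"] is None else np.array(doc["x_scales"]),
        y_scales=None if doc["y_scales"] is None else np.array(doc["y_scales"]),
        x_feature_ids=doc["x_feature_ids"],
        y_feature_ids=doc["y_feature_ids"],
        sample_ids=doc["sample_ids"],
        K=doc["K"], Kx=doc["Kx"], Ky=doc["Ky"],
        pen_x=_pen_from_json(doc["pen_x"]),
        pen_y=_pen_from_json(doc["pen_y"]),
        variance_summary=doc["variance_summary"],
        convergence=doc["convergence"],
    )
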