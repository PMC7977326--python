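"""Penalized NIPALS engine.

Extracts one pair of joint loading vectors (w, c) at a time by alternating
power iterations that maximise the covariance ``cᵀ Ỹᵀ X̃ w`` under a unit-norm
constraint, optionally with

* an L1 penalty on the loadings, solved by soft-thresholding, or
* a group-wise L2 penalty with size-adjusted thresholds ``sqrt(p_j)·λ``,
  which selects whole feature groups at a time (all-in / all-out).

Sparse selection is the all-singleton special case of the group penalty, so a
single thresholding code path serves both and the two are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .blocks import GroupStructure

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltySpec",
    "LoadingPair",
    "OverPenalizedError",
    "DegenerateComponentError",
    "soft_threshold",
    "group_threshold",
    "lambda_for_top_h",
    "nipals_pair",
    "orthogonalize_loading",
    "deflate",
]


class OverPenalizedError(ValueError):
    """Every group was thresholded to zero.

    ``max_feasible_lam`` is the largest λ at which at least one group would
    still survive.
    """

    def __init__(self, message: str, max_feasible_lam: float):
        super().__init__(message)
        self.max_feasible_lam = max_feasible_lam


class DegenerateComponentError(ValueError):
    """A loading vector lies entirely in the span of the previous ones."""


@dataclass
class PenaltySpec:
    """Per-block sparsity request.

    mode
        ``"none"`` (dense loadings), ``"sparse"`` (individual features) or
        ``"group"`` (whole feature groups).
    keep
        Number of groups (``mode="group"``) or features (``mode="sparse"``)
        to retain; the penalty level λ is derived from it at every iteration.
    lam
        Explicit penalty level; exactly one of ``keep``/``lam`` may be set
        for a penalised mode.
    groups
        Required for ``mode="group"``; ignored otherwise.
    """

    mode: str = "none"
    keep: int | None = None
    lam: float | None = None
    groups: GroupStructure | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "sparse", "group"):
            raise ValueError(f"unknown penalty mode {self.mode!r}")
        if self.mode == "none":
            if self.keep is not None or (self.lam not in (None, 0, 0.0)):
                raise ValueError("mode='none' takes no keep/lam")
        else:
            if (self.keep is None) == (self.lam is None):
                raise ValueError("set exactly one of keep or lam")
            if self.keep is not None and self.keep <= 0:
                raise ValueError("keep must be a positive integer")
            if self.lam is not None and self.lam < 0:
                raise ValueError("lam must be non-negative")
        if self.mode == "group" and self.groups is None:
            raise ValueError("mode='group' requires a GroupStructure")

    @classmethod
    def none(cls) -> "PenaltySpec":
        return cls(mode="none")

    @classmethod
    def sparse(cls, keep: int | None = None, lam: float | None = None) -> "PenaltySpec":
        return cls(mode="sparse", keep=keep, lam=lam)

    @classmethod
    def group(
        cls,
        groups: GroupStructure,
        keep: int | None = None,
        lam: float | None = None,
    ) -> "PenaltySpec":
        return cls(mode="group", keep=keep, lam=lam, groups=groups)

    def effective_groups(self, p: int) -> GroupStructure | None:
        """Group structure the thresholding operates on (singletons for sparse)."""
        if self.mode == "none":
            return None
        if self.mode == "sparse":
            return GroupStructure.singletons(p)
        assert self.groups is not None
        self.groups.validate_for(p)
        return self.groups

    def validate_keep(self, p: int) -> None:
        if self.keep is None:
            return
        n_units = p if self.mode == "sparse" else self.groups.n_groups  # type: ignore[union-attr]
        if self.keep > n_units:
            kind = "features" if self.mode == "sparse" else "groups"
            raise ValueError(f"keep={self.keep} exceeds the {n_units} available {kind}")


@dataclass
class LoadingPair:
    """One extracted pair of joint loadings and scores.

    ``w`` (length p) and ``c`` (length q) are unit-norm; ``t = X̃ w`` and
    ``u = Ỹ c`` are the corresponding scores on the current (deflated) data.
    """

    w: np.ndarray
    c: np.ndarray
    t: np.ndarray
    u: np.ndarray
    iterations: int
    converged: bool
    lam_w: float = 0.0
    lam_c: float = 0.0


def soft_threshold(a: np.ndarray, lam: float) -> np.ndarray:
    """Soft-thresholding operator ``sgn(a)(|a| - lam)_+`` (elementwise)."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


def group_threshold(a: np.ndarray, groups: GroupStructure, lam: float) -> np.ndarray:
    """Group-wise shrinkage with size-adjusted thresholds.

    Each group's sub-vector ``a^(j)`` is scaled by ``(1 - sqrt(p_j)·lam /
    ‖a^(j)‖₂)_+`` — zeroed when its norm does not exceed ``sqrt(p_j)·lam`` —
    and the result is rescaled to unit L2 norm (the Lagrangian constant of the
    unit-norm constraint is absorbed into the renormalisation).  A group
    survives iff ``‖a^(j)‖₂ > sqrt(p_j)·lam``.
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    a = np.asarray(a, dtype=float)
    groups.validate_for(a.size)
    out = np.zeros_like(a)
    max_feasible = 0.0
    any_alive = False
    for ix in groups.indices:
        sub = a[ix]
        nrm = float(np.linalg.norm(sub))
        thresh = np.sqrt(ix.size) * lam
        if nrm > 0:
            max_feasible = max(max_feasible, nrm / np.sqrt(ix.size))
        if nrm > thresh and nrm > 0:
            out[ix] = (1.0 - thresh / nrm) * sub
            any_alive = True
    if not any_alive:
        raise OverPenalizedError(
            f"all {groups.n_groups} groups thresholded to zero at lam={lam:g}; "
            f"largest feasible lam is {max_feasible:g}",
            max_feasible_lam=max_feasible,
        )
    return out / np.linalg.norm(out)


def lambda_for_top_h(group_norms: np.ndarray, h: int) -> float:
    """Penalty level λ at which exactly the top ``h`` groups survive.

    ``group_norms`` are the size-adjusted group norms ``‖a^(j)‖₂ / sqrt(p_j)``.
    Returns the midpoint between the h-th and (h+1)-th largest values (0 when
    ``h`` equals the number of groups).  When those two values tie, λ is
    placed below the tied value so that every tied group survives (possibly
    more than ``h``; logged).
    """
    if h <= 0:
        raise ValueError("h must be a positive integer")
    norms = np.asarray(group_norms, dtype=float)
    if h > norms.size:
        raise ValueError(f"h={h} exceeds the {norms.size} groups")
    if h == norms.size:
        return 0.0
    srt = np.sort(norms)[::-1]
    hi, lo = srt[h - 1], srt[h]
    if hi > lo:
        return float((hi + lo) / 2.0)
    # tie at the boundary: keep every group at the tied value
    below = srt[srt < hi]
    n_tied = int(np.sum(norms == hi))
    logger.info(
        "tie at the selection boundary: keeping all %d groups at norm %g (h=%d)",
        n_tied, hi, h,
    )
    if below.size == 0:
        return 0.0
    return float((hi + below[0]) / 2.0)


def _apply_penalty(
    a: np.ndarray,
    groups: GroupStructure | None,
    lam: float | None,
    keep: int | None,
) -> tuple[np.ndarray, float]:
    """Threshold + renormalise one loading update; returns (vector, λ used)."""
    nrm = np.linalg.norm(a)
    if nrm == 0:
        raise OverPenalizedError("loading update is identically zero", 0.0)
    if groups is None:
        return a / nrm, 0.0
    if keep is not None:
        adj = np.array(
            [np.linalg.norm(a[ix]) / np.sqrt(ix.size) for ix in groups.indices]
        )
        lam = lambda_for_top_h(adj, keep)
    assert lam is not None
    if lam == 0:
        return a / nrm, 0.0
    return group_threshold(a, groups, lam), float(lam)


def _sign_fix(v: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude entry is positive (sign convention)."""
    j = int(np.argmax(np.abs(v)))
    return -v if v[j] < 0 else v


def nipals_pair(
    Xk: np.ndarray,
    Yk: np.ndarray,
    pen_x: PenaltySpec | None = None,
    pen_y: PenaltySpec | None = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
    init: str = "deterministic",
    rng: np.random.Generator | None = None,
) -> LoadingPair:
    """Extract one pair of joint loadings from column-centered ``Xk, Yk``.

    Alternates ``c ∝ threshold(Ykᵀt)``, ``u = Yk c``, ``w ∝ threshold(Xkᵀu)``,
    ``t = Xk w`` until the loading change (after sign alignment) drops below
    ``tol`` or ``max_iter`` is hit (warning, ``converged=False``).  With no
    penalty this is plain NIPALS, whose fixed point is the dominant singular
    pair of ``Ykᵀ Xk``.  When a penalty requests ``keep`` units, λ is
    recomputed from the current update at every iteration so the count is
    exact at convergence.

    The default initialisation is deterministic — the ``Yk`` column with the
    largest variance — so repeated runs are reproducible; ``init="random"``
    draws from ``rng`` instead.
    """
    pen_x = pen_x or PenaltySpec.none()
    pen_y = pen_y or PenaltySpec.none()
    Xk = np.asarray(Xk, dtype=float)
    Yk = np.asarray(Yk, dtype=float)
    if Xk.shape[0] != Yk.shape[0]:
        raise ValueError("Xk and Yk must have the same number of rows")
    p, q = Xk.shape[1], Yk.shape[1]
    pen_x.validate_keep(p)
    pen_y.validate_keep(q)
    gx = pen_x.effective_groups(p)
    gy = pen_y.effective_groups(q)

    if init == "random":
        if rng is None:
            rng = np.random.default_rng()
        t = rng.standard_normal(Xk.shape[0])
    else:
        t = Yk[:, int(np.argmax(Yk.var(axis=0)))].copy()
    if np.linalg.norm(t) == 0:
        t = np.ones(Xk.shape[0])

    w_prev = np.zeros(p)
    c_prev = np.zeros(q)
    lam_w = lam_c = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        c, lam_c = _apply_penalty(Yk.T @ t, gy, pen_y.lam, pen_y.keep)
        u = Yk @ c
        w, lam_w = _apply_penalty(Xk.T @ u, gx, pen_x.lam, pen_x.keep)
        t = Xk @ w
        # sign alignment before measuring the change
        w_cmp = -w if np.dot(w, w_prev) < 0 else w
        c_cmp = -c if np.dot(c, c_prev) < 0 else c
        delta = max(np.linalg.norm(w_cmp - w_prev), np.linalg.norm(c_cmp - c_prev))
        w_prev, c_prev = w, c
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("NIPALS did not converge in %d iterations", max_iter)

    w = _sign_fix(w)
    c = _sign_fix(c)
    return LoadingPair(
        w=w, c=c, t=Xk @ w, u=Yk @ c,
        iterations=it, converged=converged, lam_w=lam_w, lam_c=lam_c,
    )


def orthogonalize_loading(
    wk: np.ndarray,
    previous: list[np.ndarray],
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Orthogonalise ``wk`` against earlier loadings on its support.

    Restricted to the selected-variable index set ``support`` (defaults to the
    non-zeros of ``wk``), the projection of ``wk`` onto the span of the
    previous loadings is subtracted; entries off the support are untouched.
    When no previous loading touches the support the span is the zero subspace
    and ``wk`` is returned unchanged.  The result is renormalised to unit norm.
    """
    wk = np.asarray(wk, dtype=float)
    if support is None:
        support = np.flatnonzero(wk)
    support = np.asarray(support, dtype=int)
    prev = [np.asarray(v, dtype=float) for v in previous]
    for v in prev:
        if v.size != wk.size:
            raise ValueError("previous loadings must have the same length as wk")
    if not prev or support.size == 0:
        nrm = np.linalg.norm(wk)
        return wk / nrm if nrm else wk
    basis = [v[support] for v in prev if np.linalg.norm(v[support]) > 0]
    if not basis:
        return wk / np.linalg.norm(wk)
    M = np.column_stack(basis)
    sub = wk[support]
    coef, *_ = np.linalg.lstsq(M, sub, rcond=None)
    resid = sub - M @ coef
    if np.linalg.norm(resid) <= 1e-12 * max(np.linalg.norm(sub), 1.0):
        raise DegenerateComponentError(
            "loading lies in the span of previous components on its support"
        )
    out = wk.copy()
    out[support] = resid
    return out / np.linalg.norm(out)


def deflate(Xk: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Regression deflation: remove the score direction ``t`` from ``Xk``.

    Returns ``Xk - t (tᵀt)⁻¹ tᵀ Xk``; every column of the result is orthogonal
    to ``t``, so successive scores are mutually orthogonal.
    """
    t = np.asarray(t, dtype=float).ravel()
    tt = float(t @ t)
    if tt == 0:
        raise ValueError("cannot deflate by a zero score vector")
    return Xk - np.outer(t, (t @ Xk) / tt)
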