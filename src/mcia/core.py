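"""The MCIA solver: sequential covariance-maximizing axes across K triplets.

Multiple co-inertia analysis finds, per order h, a synthetic sample-space axis
``v^h`` (the reference structure) and one auxiliary feature-space axis
``u_k^h`` per table, maximizing the weighted sum of squared covariances

    sum_k  w_k * cov^2(X_k Q_k u_k, v),   cov(a, b) = a' D b,

subject to ``v' D v = 1`` and ``u_k' Q_k u_k = 1``.  The optimum ``v`` is the
dominant eigenvector of ``S = sum_k w_k X_k Q_k X_k' D`` and
``u_k = X_k' D v / ||X_k' D v||_Q``.  Subsequent axes are extracted after
deflating each table by the Q-orthogonal projection onto its extracted
auxiliary axis, which enforces the orthogonality constraints between orders.

The shared sample dimension n is small relative to feature counts in omics
data, so ``S`` is formed explicitly and solved with a dense symmetric
eigendecomposition (after the similarity transform ``D^1/2 S D^-1/2``), making
the whole procedure deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

from .errors import AlignmentError, InvalidArgumentError, RankError
from .tables import TripletTable

WeightingScheme = Literal["uniform", "inverse_first_eigenvalue"]


@dataclass(frozen=True)
class MciaConfig:
    """Solver configuration.

    ``n_axes`` of None resolves to ``min(10, n - 1)`` at run time.  The sign
    rule is fixed: per axis, the synthetic score entry of largest magnitude is
    made positive, and all auxiliary axes and scores flip with it.
    """

    n_axes: int | None = None
    weighting_scheme: WeightingScheme = "uniform"
    metric_convention: str = "col_weights"
    sample_weight_convention: str = "uniform"
    eig_tol: float = 1e-10
    sign_rule: str = "largest_magnitude_positive"

    def __post_init__(self) -> None:
        if self.n_axes is not None and self.n_axes < 1:
            raise InvalidArgumentError(f"n_axes must be >= 1, got {self.n_axes}")
        if self.weighting_scheme not in ("uniform", "inverse_first_eigenvalue"):
            raise InvalidArgumentError(f"unknown weighting scheme {self.weighting_scheme!r}")
        if self.eig_tol <= 0:
            raise InvalidArgumentError("eig_tol must be positive")


@dataclass
class MciaResult:
    """Everything MCIA computes, fully labeled.

    ``synthetic_scores`` columns are the D-orthonormal reference axes ``v^h``;
    ``aux_axes[name]`` columns are the Q_k-orthonormal ``u_k^h``;
    ``table_scores[name]`` columns are ``X_k^(h) Q_k u_k^h`` where ``X^(h)``
    is the (h-1)-times deflated matrix, matching the sequential construction.
    ``pseudo_eigenvalues[k, h] = w_k cov^2(score, v^h)`` sums over tables to
    ``eigenvalues[h]``.  A table whose profile rank is exhausted before axis H
    stores zero auxiliary axes and zero scores for the remaining orders (it
    contributes nothing there); orthonormality holds for all non-zero columns.
    ``full_spectrum`` holds every eigenvalue of the first-order operator,
    needed for variance-explained proportions.
    """

    eigenvalues: np.ndarray
    full_spectrum: np.ndarray
    synthetic_scores: np.ndarray
    aux_axes: dict[str, np.ndarray]
    table_scores: dict[str, np.ndarray]
    table_weights: np.ndarray
    pseudo_eigenvalues: np.ndarray
    config: MciaConfig
    table_names: list[str]
    feature_ids: dict[str, list[str]]
    sample_ids: list[str]
    D_diag: np.ndarray

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_tables(self) -> int:
        return len(self.table_names)


def _check_aligned(tables: Sequence[TripletTable]) -> None:
    if not tables:
        raise InvalidArgumentError("at least one triplet table is required")
    names = [t.name for t in tables]
    if len(set(names)) != len(names):
        raise InvalidArgumentError(f"table names must be unique, got {names}")
    ref = tables[0]
    for t in tables[1:]:
        if t.sample_ids != ref.sample_ids:
            raise AlignmentError(
                f"tables {ref.name!r} and {t.name!r} have different sample ids; "
                "run align_samples before building triplets"
            )
        if not np.allclose(t.D_diag, ref.D_diag, rtol=0, atol=1e-12):
            raise AlignmentError(
                f"tables {ref.name!r} and {t.name!r} carry different sample weights D"
            )


def _crossproduct(t: TripletTable) -> np.ndarray:
    """The n x n sample-space operator X Q X' of one table (without D)."""
    return (t.X * t.Q_diag[None, :]) @ t.X.T


def _dominant_eigpair(C: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, float]:
    """Dominant eigenpair of C @ diag(d) via the symmetric fold d^1/2 C d^1/2.

    Returns (v, lam) with v' diag(d) v = 1.
    """
    sq = np.sqrt(d)
    B = (C * sq[None, :]) * sq[:, None]
    B = 0.5 * (B + B.T)
    vals, vecs = scipy.linalg.eigh(B)
    lam = float(vals[-1])
    w = vecs[:, -1]
    v = w / sq
    return v, lam


def compute_table_weights(
    tables: Sequence[TripletTable], scheme: WeightingScheme = "uniform"
) -> np.ndarray:
    """Per-table weights w_k of the MCIA criterion.

    ``uniform`` gives every table weight 1.  ``inverse_first_eigenvalue`` sets
    ``w_k = 1 / lambda1_k`` with ``lambda1_k`` the dominant eigenvalue of the
    single-table operator ``X_k Q_k X_k' D``, equalizing each table's leading
    inertia (standard multiblock practice).
    """
    _check_aligned(tables)
    if scheme == "uniform":
        return np.ones(len(tables))
    if scheme != "inverse_first_eigenvalue":
        raise InvalidArgumentError(f"unknown weighting scheme {scheme!r}")
    weights = np.empty(len(tables))
    for k, t in enumerate(tables):
        _, lam = _dominant_eigpair(_crossproduct(t), t.D_diag)
        if lam <= 0:
            raise RankError(f"table {t.name!r} has zero inertia; cannot weight by 1/lambda1")
        weights[k] = 1.0 / lam
    return weights


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Flip v so its largest-magnitude entry is positive (deterministic plots)."""
    idx = int(np.argmax(np.abs(v)))
    return -v if v[idx] < 0 else v


def solve_first_axis(
    tables: Sequence[TripletTable],
    weights: Sequence[float] | None = None,
    eig_tol: float = 1e-10,
) -> tuple[np.ndarray, list[np.ndarray], float]:
    """One order of MCIA: dominant eigenpair of S = sum_k w_k X_k Q_k X_k' D.

    Returns ``(v, [u_k], lam)`` with ``v' D v = 1`` and each ``u_k``
    Q_k-normalized (a zero vector if the deflated table has no covariance
    left along ``v``).
    """
    _check_aligned(tables)
    weights = np.ones(len(tables)) if weights is None else np.asarray(weights, dtype=float)
    if weights.shape != (len(tables),) or (weights <= 0).any():
        raise InvalidArgumentError("weights must be positive, one per table")
    d = tables[0].D_diag
    C = np.zeros((len(d), len(d)))
    for w, t in zip(weights, tables):
        C += w * _crossproduct(t)
    v, lam = _dominant_eigpair(C, d)
    if lam <= eig_tol:
        raise RankError("no co-inertia variance left: the pooled operator S is (numerically) zero")
    v = _fix_sign(v)
    us = []
    for t in tables:
        a = t.X.T @ (d * v)
        norm = float(np.sqrt(a @ (t.Q_diag * a)))
        us.append(a / norm if norm > eig_tol else np.zeros_like(a))
    return v, us, lam


def deflate(tables: Sequence[TripletTable], us: Sequence[np.ndarray]) -> list[TripletTable]:
    """Remove each table's extracted auxiliary axis by Q-orthogonal projection.

    For a Q_k-normalized ``u_k`` the sample rows of ``X_k`` are projected onto
    the Q-orthogonal complement of ``u_k``:  ``X <- X - (X Q u) u'``.  The
    resulting residual satisfies ``X Q u = 0``, so later axes are
    Q-orthogonal to ``u`` and the extracted score direction is annihilated.
    Zero axes (tables already exhausted along v) leave the table unchanged.
    """
    if len(tables) != len(us):
        raise InvalidArgumentError("one auxiliary axis per table is required")
    out = []
    for t, u in zip(tables, us):
        u = np.asarray(u, dtype=float)
        if u.shape != (t.n_features,):
            raise InvalidArgumentError(
                f"axis length {u.shape} does not match table {t.name!r} ({t.n_features} features)"
            )
        if not u.any():
            out.append(t)
            continue
        scores = t.X @ (t.Q_diag * u)
        out.append(replace(t, X=t.X - np.outer(scores, u)))
    return out


def run_mcia(tables: Sequence[TripletTable], config: MciaConfig | None = None) -> MciaResult:
    """Full sequential MCIA: H rounds of solve_first_axis + deflate.

    Scores for axis h are computed from the (h-1)-times deflated matrices, as
    in the sequential construction; eigenvalues are nonincreasing and the
    per-table pseudo-eigenvalues sum to the global eigenvalue on every axis.
    """
    config = config or MciaConfig()
    _check_aligned(tables)
    n = tables[0].n_samples
    H = config.n_axes if config.n_axes is not None else min(10, n - 1)
    if H > n - 1:
        raise RankError(
            f"n_axes={H} exceeds the rank bound n - 1 = {n - 1} for {n} samples"
        )
    if H < 1:
        raise RankError("need at least 2 samples to extract an axis")
    weights = compute_table_weights(tables, config.weighting_scheme)

    d = tables[0].D_diag
    C = np.zeros((n, n))
    for w, t in zip(weights, tables):
        C += w * _crossproduct(t)
    sq = np.sqrt(d)
    B = (C * sq[None, :]) * sq[:, None]
    spectrum = np.sort(scipy.linalg.eigh(0.5 * (B + B.T), eigvals_only=True))[::-1]
    spectrum = np.clip(spectrum, 0.0, None)

    names = [t.name for t in tables]
    eigenvalues = np.empty(H)
    V = np.empty((n, H))
    aux = {t.name: np.zeros((t.n_features, H)) for t in tables}
    scores = {t.name: np.zeros((n, H)) for t in tables}
    pseudo = np.empty((len(tables), H))

    current = list(tables)
    for h in range(H):
        v, us, lam = solve_first_axis(current, weights, config.eig_tol)
        eigenvalues[h] = lam
        V[:, h] = v
        for k, (t, u) in enumerate(zip(current, us)):
            s = t.X @ (t.Q_diag * u)
            aux[t.name][:, h] = u
            scores[t.name][:, h] = s
            cov = float(s @ (d * v))
            pseudo[k, h] = weights[k] * cov * cov
        current = deflate(current, us)

    return MciaResult(
        eigenvalues=eigenvalues,
        full_spectrum=spectrum,
        synthetic_scores=V,
        aux_axes=aux,
        table_scores=scores,
        table_weights=weights,
        pseudo_eigenvalues=pseudo,
        config=config,
        table_names=names,
        feature_ids={t.name: list(t.feature_ids) for t in tables},
        sample_ids=list(tables[0].sample_ids),
        D_diag=d.copy(),
    )
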