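"""Co-structure statistics: variance explained, pseudo-eigenvalues, RV, divergence.

These quantify how much structure the tables share and which table drives each
axis: variance-explained proportions over the full first-order spectrum,
per-table pseudo-eigenvalue contributions (which sum to the global eigenvalue
on every axis), pairwise RV coefficients between analyzed configurations, and
per-sample divergence from the reference structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MciaResult, _crossproduct, deflate
from .errors import AlignmentError, DataDomainError, InvalidArgumentError
from .tables import TripletTable


@dataclass
class RvMatrix:
    """Symmetric K x K matrix of pairwise RV coefficients with unit diagonal."""

    table_names: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.table_names, columns=self.table_names)


def variance_explained(eigenvalues: Sequence[float]) -> np.ndarray:
    """Proportions lambda_h / sum(lambda) over a FULL eigenvalue spectrum.

    Pass :attr:`MciaResult.full_spectrum` (or any complete spectrum of the
    first-order operator); passing only the extracted top-H eigenvalues would
    overstate the proportions.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0 or (lam < -1e-12).any():
        raise InvalidArgumentError("eigenvalues must be nonnegative and non-empty")
    total = lam.sum()
    if total <= 0:
        raise DataDomainError("all-zero eigenvalue spectrum has no variance to apportion")
    return lam / total


def pseudo_eigenvalues(result: MciaResult, tables: Sequence[TripletTable]) -> pd.DataFrame:
    """Recompute each table's contribution w_k cov^2(X^(h) Q u^h, v^h) per axis.

    Replays the deflation sequence from the original triplets using the stored
    auxiliary axes, so this is an independent check of
    :attr:`MciaResult.pseudo_eigenvalues` (rows: tables, columns: axes).
    """
    if [t.name for t in tables] != result.table_names:
        raise InvalidArgumentError("tables do not match the result (names or order differ)")
    for t in tables:
        if t.n_features != len(result.feature_ids[t.name]):
            raise InvalidArgumentError(f"table {t.name!r} feature count differs from the result")
    d = result.D_diag
    K, H = len(tables), result.n_axes
    out = np.empty((K, H))
    current = list(tables)
    for h in range(H):
        v = result.synthetic_scores[:, h]
        us = [result.aux_axes[t.name][:, h] for t in current]
        for k, (t, u) in enumerate(zip(current, us)):
            s = t.X @ (t.Q_diag * u)
            cov = float(s @ (d * v))
            out[k, h] = result.table_weights[k] * cov * cov
        current = deflate(current, us)
    return pd.DataFrame(
        out, index=result.table_names, columns=[f"axis{h + 1}" for h in range(H)]
    )


def _folded_crossproduct(t: TripletTable) -> np.ndarray:
    """Symmetric fold D^1/2 X Q X' D^1/2 of one table's sample-space operator."""
    sq = np.sqrt(t.D_diag)
    C = _crossproduct(t)
    return (C * sq[None, :]) * sq[:, None]


def rv_coefficient(a: TripletTable, b: TripletTable) -> float:
    """RV coefficient between two analyzed configurations, in [0, 1].

    RV = trace(W_a W_b) / sqrt(trace(W_a^2) trace(W_b^2)) with
    W_t = X_t Q_t X_t' D: total co-inertia over the geometric mean of total
    squared inertias.  1 means identical sample-space structure, 0 none.
    """
    if a.sample_ids != b.sample_ids:
        raise AlignmentError(f"tables {a.name!r} and {b.name!r} are not sample-aligned")
    if not np.allclose(a.D_diag, b.D_diag, rtol=0, atol=1e-12):
        raise AlignmentError(f"tables {a.name!r} and {b.name!r} carry different D weights")
    Ca, Cb = _folded_crossproduct(a), _folded_crossproduct(b)
    na, nb = float(np.sum(Ca * Ca)), float(np.sum(Cb * Cb))
    if na <= 0 or nb <= 0:
        zero = a.name if na <= 0 else b.name
        raise DataDomainError(f"table {zero!r} has zero inertia; RV is undefined")
    return float(np.sum(Ca * Cb)) / float(np.sqrt(na * nb))


def rv_matrix(tables: Sequence[TripletTable]) -> RvMatrix:
    """All pairwise RV coefficients; symmetric with unit diagonal."""
    if len(tables) < 2:
        raise InvalidArgumentError("rv_matrix needs at least two tables")
    K = len(tables)
    values = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            values[i, j] = values[j, i] = rv_coefficient(tables[i], tables[j])
    return RvMatrix(table_names=[t.name for t in tables], values=values)


def sample_divergence(
    result: MciaResult,
    axes: Sequence[int] = (0, 1),
    normalized: bool = True,
) -> pd.DataFrame:
    """Per-sample, per-table distance from the reference structure.

    In the subspace of the chosen axes (0-based), each sample has one point
    per table and a common reference point; the Euclidean segment length
    measures cross-platform discordance for that sample (short = concordant).

    With ``normalized=True`` (default) each table's score column is scaled to
    unit D-norm and the reference is the unit synthetic axis ``v^h``, so
    identical tables give exactly zero divergence.  With ``normalized=False``
    raw table scores are compared against ``v^h * sqrt(lambda_h)`` (the
    reference placed on the score scale), preserving score magnitudes.
    """
    axes = list(axes)
    if not axes:
        raise InvalidArgumentError("at least one axis is required")
    if max(axes) >= result.n_axes or min(axes) < 0:
        raise InvalidArgumentError(
            f"axes {axes} out of range for a result with {result.n_axes} axes"
        )
    d = result.D_diag
    n, K = result.n_samples, result.n_tables
    sq = np.zeros((n, K))
    for k, name in enumerate(result.table_names):
        for h in axes:
            s = result.table_scores[name][:, h]
            if normalized:
                norm = float(np.sqrt(s @ (d * s)))
                point = s / norm if norm > 0 else np.zeros_like(s)
                ref = result.synthetic_scores[:, h]
            else:
                point = s
                ref = result.synthetic_scores[:, h] * np.sqrt(result.eigenvalues[h])
            sq[:, k] += (point - ref) ** 2
    return pd.DataFrame(np.sqrt(sq), index=result.sample_ids, columns=result.table_names)
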