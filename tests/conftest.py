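"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: the pooled operator
is built as a plain (non-symmetric) matrix and handed to a generic
eigendecomposition, covariances are evaluated as explicit dot products, and
traces as elementwise double loops.
"""

from __future__ import annotations

import numpy as np
import pytest

from mcia import RawTable, TripletTable, nsc_triplet


def random_raw(rng: np.random.Generator, n_features: int, n_samples: int,
               name: str = "T") -> RawTable:
    """A random strictly-positive expression-like table."""
    values = rng.lognormal(mean=1.0, sigma=0.4, size=(n_features, n_samples))
    return RawTable(
        name=name,
        feature_ids=[f"{name}_F{j}" for j in range(n_features)],
        sample_ids=[f"S{i}" for i in range(n_samples)],
        values=values,
        missing_mask=np.zeros((n_features, n_samples), dtype=bool),
    )


def random_triplets(rng: np.random.Generator, n_samples: int, feature_counts,
                    metric: str = "col_weights") -> list[TripletTable]:
    """Sample-aligned random NSC triplets, one per feature count."""
    return [
        nsc_triplet(random_raw(rng, q, n_samples, name=f"T{k + 1}"), metric=metric)
        for k, q in enumerate(feature_counts)
    ]


def identity_triplet(X: np.ndarray, name: str = "T1") -> TripletTable:
    """Wrap an arbitrary matrix (samples x features) with identity metrics.

    Used for pure linear-algebra checks (SVD reductions, RV on constructed
    configurations) that do not require the NSC centering identities.
    """
    n, q = X.shape
    return TripletTable(
        name=name,
        feature_ids=[f"F{j}" for j in range(q)],
        sample_ids=[f"S{i}" for i in range(n)],
        X=np.asarray(X, dtype=float),
        row_weights=np.full(n, 1.0 / n),
        col_weights=np.full(q, 1.0 / q),
        Q_diag=np.ones(q),
        D_diag=np.ones(n),
        grand_total=1.0,
    )


def pooled_operator(tables, weights) -> np.ndarray:
    """Oracle: S = sum_k w_k X_k Q_k X_k' D as an explicit plain matrix."""
    d = tables[0].D_diag
    n = tables[0].n_samples
    S = np.zeros((n, n))
    for w, t in zip(weights, tables):
        S += w * (t.X @ np.diag(t.Q_diag) @ t.X.T @ np.diag(d))
    return S


def dominant_eigpair_oracle(S: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, float]:
    """Oracle: dominant eigenpair of a plain (possibly nonsymmetric) matrix,
    D-renormalized, via numpy's general eigensolver."""
    vals, vecs = np.linalg.eig(S)
    idx = int(np.argmax(vals.real))
    lam = float(vals[idx].real)
    v = vecs[:, idx].real
    v = v / np.sqrt(v @ (d * v))
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    return v, lam


def criterion_value(tables, weights, v) -> float:
    """Oracle: sum_k w_k cov^2(X_k Q_k u_k, v) with each u_k set optimally for v."""
    d = tables[0].D_diag
    total = 0.0
    for w, t in zip(weights, tables):
        a = t.X.T @ (d * v)
        norm = np.sqrt(a @ (t.Q_diag * a))
        if norm == 0:
            continue
        u = a / norm
        s = t.X @ (t.Q_diag * u)
        cov = s @ (d * v)
        total += w * cov * cov
    return float(total)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
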