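"""Loading, cleaning and transforming raw omics tables into statistical triplets.

A raw table is a features x samples matrix of nonnegative intensities with an
explicit missing-value mask.  The cleaning operations here mirror the standard
multi-platform expression workflow: collapse duplicate feature identifiers to
the highest-average row, drop features with too many missing values, impute the
remainder with a small positive constant, log-transform, and restrict all
tables to a common sample set.

The end point of the pipeline is :func:`nsc_triplet`, which builds the
non-symmetric correspondence analysis (NSC) statistical triplet ``(X, Q, D)``:
centered row profiles ``x_ij = p_ij / r_i - c_j`` (samples as rows), a diagonal
feature metric ``Q`` and a diagonal sample weight ``D``.  These triplets are
the unit of analysis consumed by :mod:`mcia.core`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataDomainError, InvalidArgumentError, TableFormatError

logger = logging.getLogger(__name__)

MetricConvention = Literal["col_weights", "identity"]
SampleWeightConvention = Literal["uniform", "identity"]


@dataclass
class RawTable:
    """A labeled feature x sample matrix with a missing-value mask.

    ``feature_ids`` may contain duplicates until
    :func:`collapse_duplicate_features` is applied; ``sample_ids`` must be
    unique.  ``values`` entries under the mask are ignored by every operation.
    """

    name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        shape = (len(self.feature_ids), len(self.sample_ids))
        if self.values.shape != shape:
            raise TableFormatError(
                f"table {self.name!r}: values shape {self.values.shape} does not "
                f"match {len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.missing_mask.shape != self.values.shape:
            raise TableFormatError(
                f"table {self.name!r}: missing_mask shape {self.missing_mask.shape} "
                f"does not match values shape {self.values.shape}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise TableFormatError(f"table {self.name!r}: duplicate sample ids {dupes}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str = "table") -> "RawTable":
        """Build from a features x samples DataFrame; NaN cells become missing."""
        values = frame.to_numpy(dtype=float)
        return cls(
            name=name,
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=values,
            missing_mask=np.isnan(values),
        )

    def to_frame(self) -> pd.DataFrame:
        """Features x samples DataFrame with NaN in masked cells."""
        values = self.values.copy()
        values[self.missing_mask] = np.nan
        return pd.DataFrame(values, index=list(self.feature_ids), columns=list(self.sample_ids))


@dataclass
class TripletTable:
    """One table's NSC statistical triplet ``(X, Q, D)``.

    ``X`` holds the centered row profiles with samples as rows (length *n*) and
    features as columns (length *q_k*).  ``Q_diag`` is the diagonal feature
    metric, ``D_diag`` the diagonal sample weight shared by all tables of a
    run.  ``row_weights``/``col_weights`` are the marginal relative totals
    ``r_i`` and ``c_j`` of the raw nonnegative matrix; ``grand_total`` is its
    overall sum ``m_++``.
    """

    name: str
    feature_ids: list[str]
    sample_ids: list[str]
    X: np.ndarray
    row_weights: np.ndarray
    col_weights: np.ndarray
    Q_diag: np.ndarray
    D_diag: np.ndarray
    grand_total: float

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, q = len(self.sample_ids), len(self.feature_ids)
        if self.X.shape != (n, q):
            raise TableFormatError(
                f"triplet {self.name!r}: X shape {self.X.shape} != ({n}, {q})"
            )
        for attr, size in (("row_weights", n), ("col_weights", q), ("Q_diag", q), ("D_diag", n)):
            arr = np.asarray(getattr(self, attr), dtype=float)
            setattr(self, attr, arr)
            if arr.shape != (size,):
                raise TableFormatError(
                    f"triplet {self.name!r}: {attr} has shape {arr.shape}, expected ({size},)"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def check_invariants(self, tol_center: float = 1e-10, tol_weights: float = 1e-12) -> None:
        """Raise AssertionError if the NSC centering/weight identities fail."""
        row_sums = self.X.sum(axis=1)
        assert np.max(np.abs(row_sums)) < tol_center, "rows of X must sum to zero"
        col_means = self.row_weights @ self.X
        assert np.max(np.abs(col_means)) < tol_center, "columns must be r-weighted centered"
        assert abs(self.row_weights.sum() - 1.0) < tol_weights, "row weights must sum to 1"
        assert abs(self.col_weights.sum() - 1.0) < tol_weights, "column weights must sum to 1"
        assert np.all(self.Q_diag > 0), "Q metric must be positive"
        assert np.all(self.D_diag > 0), "D weights must be positive"


def _masked_row_means(raw: RawTable) -> np.ndarray:
    """Mean over non-missing entries per feature; -inf for all-missing rows."""
    counts = (~raw.missing_mask).sum(axis=1)
    sums = np.where(raw.missing_mask, 0.0, raw.values).sum(axis=1)
    means = np.full(raw.n_features, -np.inf)
    ok = counts > 0
    means[ok] = sums[ok] / counts[ok]
    return means


def collapse_duplicate_features(raw: RawTable) -> RawTable:
    """Keep, per duplicated feature id, the row with the highest non-missing mean.

    Output order follows the first occurrence of each id; ties keep the
    first-occurring row.  Tables with unique ids are returned unchanged.
    """
    if len(set(raw.feature_ids)) == raw.n_features:
        return raw
    means = _masked_row_means(raw)
    best: dict[str, int] = {}
    order: list[str] = []
    for idx, fid in enumerate(raw.feature_ids):
        if fid not in best:
            best[fid] = idx
            order.append(fid)
        elif means[idx] > means[best[fid]]:
            best[fid] = idx
    keep = [best[fid] for fid in order]
    return RawTable(
        name=raw.name,
        feature_ids=order,
        sample_ids=list(raw.sample_ids),
        values=raw.values[keep].copy(),
        missing_mask=raw.missing_mask[keep].copy(),
    )


def filter_by_missingness(raw: RawTable, max_missing: int) -> RawTable:
    """Drop features with more than ``max_missing`` missing entries."""
    if max_missing < 0:
        raise InvalidArgumentError(f"max_missing must be >= 0, got {max_missing}")
    counts = raw.missing_mask.sum(axis=1)
    keep = np.flatnonzero(counts <= max_missing)
    if keep.size == raw.n_features:
        return raw
    dropped = raw.n_features - keep.size
    logger.info("table %s: dropped %d features with > %d missing values", raw.name, dropped, max_missing)
    return RawTable(
        name=raw.name,
        feature_ids=[raw.feature_ids[i] for i in keep],
        sample_ids=list(raw.sample_ids),
        values=raw.values[keep].copy(),
        missing_mask=raw.missing_mask[keep].copy(),
    )


def impute_small_positive(raw: RawTable, fill_value: float) -> RawTable:
    """Replace every masked entry with a small positive constant and clear the mask."""
    if not fill_value > 0:
        raise InvalidArgumentError(f"fill_value must be > 0, got {fill_value}")
    if not raw.missing_mask.any():
        return raw
    values = raw.values.copy()
    values[raw.missing_mask] = fill_value
    return RawTable(
        name=raw.name,
        feature_ids=list(raw.feature_ids),
        sample_ids=list(raw.sample_ids),
        values=values,
        missing_mask=np.zeros_like(raw.missing_mask),
    )


def log_transform(raw: RawTable, base: float = 10.0) -> RawTable:
    """Log-transform all non-missing values (base 10 by default).

    Every non-missing value must be strictly positive; the first offending
    feature/sample pair is named in the error.
    """
    if base <= 0 or base == 1:
        raise InvalidArgumentError(f"log base must be positive and != 1, got {base}")
    bad = (~raw.missing_mask) & (raw.values <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataDomainError(
            f"table {raw.name!r}: non-positive value {raw.values[i, j]} at feature "
            f"{raw.feature_ids[i]!r}, sample {raw.sample_ids[j]!r}; impute or shift first"
        )
    values = raw.values.copy()
    ok = ~raw.missing_mask
    values[ok] = np.log(values[ok]) / np.log(base)
    return replace(raw, values=values, missing_mask=raw.missing_mask.copy())


def shift_to_nonnegative(raw: RawTable) -> RawTable:
    """Add the global minimum's magnitude to all values if any are negative.

    Explicit opt-in for log-scale inputs that dip below zero; a no-op on
    already-nonnegative tables.
    """
    ok = ~raw.missing_mask
    if not ok.any():
        return raw
    lowest = raw.values[ok].min()
    if lowest >= 0:
        return raw
    logger.info("table %s: shifting all values by %+g to restore nonnegativity", raw.name, -lowest)
    values = raw.values.copy()
    values[ok] = values[ok] - lowest
    return replace(raw, values=values, missing_mask=raw.missing_mask.copy())


def align_samples(
    tables: Sequence[RawTable], mode: Literal["intersect", "strict"] = "intersect"
) -> list[RawTable]:
    """Restrict all tables to a shared sample set, in the first table's order."""
    if not tables:
        raise InvalidArgumentError("align_samples requires at least one table")
    if mode not in ("intersect", "strict"):
        raise InvalidArgumentError(f"unknown alignment mode {mode!r}")
    sets = [set(t.sample_ids) for t in tables]
    common = set.intersection(*sets)
    if mode == "strict":
        for t, s in zip(tables, sets):
            if s != common or len(s) != len(sets[0]):
                missing = sorted(set.union(*sets) - s)
                extra = sorted(s - set.intersection(*sets))
                raise AlignmentError(
                    f"strict alignment failed: table {t.name!r} lacks {missing} "
                    f"and/or privately holds {extra}"
                )
    if not common:
        raise AlignmentError(
            "sample id intersection is empty across tables "
            + str([t.name for t in tables])
        )
    order = [s for s in tables[0].sample_ids if s in common]
    out = []
    for t in tables:
        cols = [t.sample_ids.index(s) for s in order]
        out.append(
            RawTable(
                name=t.name,
                feature_ids=list(t.feature_ids),
                sample_ids=list(order),
                values=t.values[:, cols].copy(),
                missing_mask=t.missing_mask[:, cols].copy(),
            )
        )
    return out


def nsc_triplet(
    raw: RawTable,
    metric: MetricConvention = "col_weights",
    sample_weights: SampleWeightConvention = "uniform",
) -> TripletTable:
    """Build the non-symmetric correspondence analysis triplet for one table.

    The raw features x samples matrix is transposed once so that mathematical
    rows are samples.  With marginals ``r_i = m_i+/m_++`` and
    ``c_j = m_+j/m_++`` the centered row profile is
    ``x_ij = p_ij / r_i - c_j`` where ``p_ij = m_ij/m_++``.  Rows of ``X``
    then sum to zero exactly, and columns are centered under the row weights.

    Parameters
    ----------
    metric:
        ``"col_weights"`` sets ``Q = diag(c_j)`` (features weighted by their
        relative abundance); ``"identity"`` uses the classical unweighted NSC
        metric.
    sample_weights:
        ``"uniform"`` sets ``D = (1/n) I`` so eigenvalues are comparable
        across sample sizes; ``"identity"`` uses ``D = I`` (same axes and
        proportions, eigenvalues scaled by ``n``).

    Features whose raw total is zero carry no inertia and are dropped with a
    warning; missing or negative entries are a hard error.
    """
    if metric not in ("col_weights", "identity"):
        raise InvalidArgumentError(f"unknown metric convention {metric!r}")
    if sample_weights not in ("uniform", "identity"):
        raise InvalidArgumentError(f"unknown sample weight convention {sample_weights!r}")
    if raw.missing_mask.any():
        raise DataDomainError(
            f"table {raw.name!r} still has {int(raw.missing_mask.sum())} missing "
            "values; filter and impute before building a triplet"
        )
    if (raw.values < 0).any():
        i, j = np.argwhere(raw.values < 0)[0]
        raise DataDomainError(
            f"table {raw.name!r}: negative value {raw.values[i, j]} at feature "
            f"{raw.feature_ids[i]!r}, sample {raw.sample_ids[j]!r}; NSC needs "
            "nonnegative input (consider shift_to_nonnegative)"
        )

    M = raw.values.T  # n samples x q features
    feature_ids = list(raw.feature_ids)
    col_totals = M.sum(axis=0)
    zero = np.flatnonzero(col_totals == 0)
    if zero.size:
        dropped = [feature_ids[j] for j in zero]
        logger.warning(
            "table %s: dropping %d zero-total features: %s",
            raw.name, len(dropped), ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
        keep = np.flatnonzero(col_totals > 0)
        M = M[:, keep]
        feature_ids = [feature_ids[j] for j in keep]
        col_totals = col_totals[keep]
    if M.shape[1] == 0:
        raise DataDomainError(f"table {raw.name!r}: no features left with positive totals")

    row_totals = M.sum(axis=1)
    if (row_totals <= 0).any():
        bad = [raw.sample_ids[i] for i in np.flatnonzero(row_totals <= 0)]
        raise DataDomainError(f"table {raw.name!r}: zero total for sample(s) {bad}")
    grand = float(M.sum())

    r = row_totals / grand
    c = col_totals / grand
    P = M / grand
    X = P / r[:, None] - c[None, :]

    n = len(raw.sample_ids)
    Q_diag = c.copy() if metric == "col_weights" else np.ones(len(feature_ids))
    D_diag = np.full(n, 1.0 / n) if sample_weights == "uniform" else np.ones(n)
    return TripletTable(
        name=raw.name,
        feature_ids=feature_ids,
        sample_ids=list(raw.sample_ids),
        X=X,
        row_weights=r,
        col_weights=c,
        Q_diag=Q_diag,
        D_diag=D_diag,
        grand_total=grand,
    )
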