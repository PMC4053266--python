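"""Feature-space projection, per-axis-end selection, and cross-table consensus.

Features are superimposed onto the same MCIA axes as the samples: a feature's
coordinate on axis h is its covariance with the synthetic axis,
``(X_k' D v^h)_j``, proportional to its auxiliary-axis entry ``u_k^h[j]``.
Selecting the most extreme features at each end of an axis, then requiring the
same feature to appear at the same axis end in several tables, yields robust
cross-platform marker calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MciaResult
from .errors import InvalidArgumentError
from .tables import TripletTable

_END_ORDER = {"positive": 0, "negative": 1}


@dataclass(frozen=True)
class FeatureRecord:
    """One selected feature at one axis end of one table (axis is 1-based)."""

    table_name: str
    feature_id: str
    axis: int
    end: str
    score: float
    rank: int


@dataclass
class FeatureSelection:
    """Ranked per-(table, axis, end) feature lists."""

    records: list[FeatureRecord]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.table_name, r.feature_id, r.axis, r.end, r.score, r.rank) for r in self.records],
            columns=["table_name", "feature_id", "axis", "end", "score", "rank"],
        )


@dataclass(frozen=True)
class ConsensusCall:
    """A feature selected at the same axis end in enough tables."""

    feature_id: str
    axis: int
    end: str
    supporting_tables: tuple[str, ...]

    @property
    def support_count(self) -> int:
        return len(self.supporting_tables)


def feature_scores(
    result: MciaResult,
    tables: Sequence[TripletTable] | None = None,
    scale: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-table feature coordinates on every axis.

    The coordinate of feature j on axis h is ``(X_k^(h)' D v^h)_j``, i.e. the
    feature column's covariance with the synthetic axis under the sequential
    (deflated) construction; it equals ``u_k^h[j]`` times the table's
    covariance with the axis, so rankings agree with the auxiliary axes while
    staying comparable across tables.  ``scale=True`` additionally multiplies
    by sqrt(lambda_h).
    """
    if tables is not None and [t.name for t in tables] != result.table_names:
        raise InvalidArgumentError("tables do not match the result (names or order differ)")
    cov = np.sqrt(result.pseudo_eigenvalues / result.table_weights[:, None])
    out: dict[str, pd.DataFrame] = {}
    cols = [f"axis{h + 1}" for h in range(result.n_axes)]
    for k, name in enumerate(result.table_names):
        coords = result.aux_axes[name] * cov[k][None, :]
        if scale:
            coords = coords * np.sqrt(result.eigenvalues)[None, :]
        out[name] = pd.DataFrame(coords, index=result.feature_ids[name], columns=cols)
    return out


def top_features(
    scores: Mapping[str, pd.DataFrame],
    n_per_end: int,
    axes: Iterable[int] | None = None,
) -> FeatureSelection:
    """The n most positive and n most negative features per table and axis.

    ``axes`` are 1-based axis numbers (default: all available).  Zero scores
    belong to neither end.  Ranks run 1..m per (table, axis, end) in
    nonincreasing |score|; ties break lexicographically on feature id.
    """
    if n_per_end < 0:
        raise InvalidArgumentError(f"n_per_end must be >= 0, got {n_per_end}")
    records: list[FeatureRecord] = []
    for name, frame in scores.items():
        all_axes = range(1, frame.shape[1] + 1)
        for axis in (all_axes if axes is None else axes):
            if not 1 <= axis <= frame.shape[1]:
                raise InvalidArgumentError(
                    f"axis {axis} out of range for table {name!r} with {frame.shape[1]} axes"
                )
            col = frame.iloc[:, axis - 1]
            for end in ("positive", "negative"):
                picked = _tie_broken(col, end)[:n_per_end]
                for rank, (fid, score) in enumerate(picked, start=1):
                    records.append(
                        FeatureRecord(
                            table_name=name, feature_id=str(fid), axis=axis,
                            end=end, score=float(score), rank=rank,
                        )
                    )
    return FeatureSelection(records=records)


def _tie_broken(col: pd.Series, end: str) -> list[tuple[str, float]]:
    """Candidates of one sign ordered by extremity then feature id."""
    if end == "positive":
        items = [(str(i), float(v)) for i, v in col.items() if v > 0]
    else:
        items = [(str(i), float(v)) for i, v in col.items() if v < 0]
    items.sort(key=lambda t: (-abs(t[1]), t[0]))
    return items


def consensus_features(selection: FeatureSelection, min_tables: int = 2) -> list[ConsensusCall]:
    """Features selected at the same axis end in at least ``min_tables`` tables.

    Output is sorted by (axis, end [positive first], descending support,
    feature id).  A feature at opposite ends of the same axis in two tables
    does not co-support a call.
    """
    if min_tables < 2:
        raise InvalidArgumentError(f"min_tables must be >= 2, got {min_tables}")
    groups: dict[tuple[str, int, str], set[str]] = {}
    for r in selection:
        groups.setdefault((r.feature_id, r.axis, r.end), set()).add(r.table_name)
    calls = [
        ConsensusCall(feature_id=fid, axis=axis, end=end, supporting_tables=tuple(sorted(tabs)))
        for (fid, axis, end), tabs in groups.items()
        if len(tabs) >= min_tables
    ]
    calls.sort(key=lambda c: (c.axis, _END_ORDER[c.end], -c.support_count, c.feature_id))
    return calls


def consensus_to_frame(calls: Sequence[ConsensusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.feature_id, c.axis, c.end, ";".join(c.supporting_tables), c.support_count) for c in calls],
        columns=["feature_id", "axis", "end", "supporting_tables", "support_count"],
    )
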