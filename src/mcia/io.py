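"""Delimited-text readers/writers and the run manifest.

Everything on disk is plain TSV (CSV via flag): first column feature or row
ids, header row sample or column ids, empty cells / ``NA`` / ``NaN`` parsed as
missing, floats serialized with 12 significant digits so written results
round-trip within 1e-12.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import asdict, dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import __version__
from .core import MciaResult
from .errors import TableFormatError
from .tables import RawTable

FLOAT_FORMAT = "%.12g"
_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_raw_table(path: str | Path, name: str | None = None, delimiter: str = "\t") -> RawTable:
    """Read a features x samples delimited table; NA/empty cells become missing."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep=delimiter, index_col=0, na_values=_NA_VALUES,
            keep_default_na=False, encoding="utf-8",
        )
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise TableFormatError(f"cannot read table from {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise TableFormatError(f"{path}: no sample columns found (check the delimiter)")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric cell: {exc}") from exc
    return RawTable.from_frame(frame, name=name or path.stem)


def write_raw_table(raw: RawTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write a cleaned table in the same dialect it was read from."""
    raw.to_frame().to_csv(path, sep=delimiter, float_format=FLOAT_FORMAT, na_rep="NA")


def write_matrix(frame: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


@dataclass
class FilterStep:
    """One preprocessing decision on one table, for the manifest."""

    table: str
    stage: str
    n_features_before: int
    n_features_after: int
    n_samples_before: int
    n_samples_after: int
    dropped_features: list[str] = field(default_factory=list)
    detail: str = ""


@dataclass
class RunManifest:
    """Traceable record of one run: config, per-stage shapes, drops, seeds."""

    command: str
    config: dict
    tables: list[str]
    steps: list[FilterStep] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())

    def record(self, step: FilterStep) -> None:
        self.steps.append(step)

    def to_yaml(self) -> str:
        payload = {
            "tool": {"name": "mcia", "version": self.version},
            "timestamp": self.timestamp,
            "command": self.command,
            "config": self.config,
            "tables": self.tables,
            "seeds": self.seeds,
            "steps": [asdict(s) for s in self.steps],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml(), encoding="utf-8")


def write_result(result: MciaResult, outdir: str | Path) -> dict[str, Path]:
    """Serialize the numeric core of an MciaResult as TSV files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    axes = [f"axis{h + 1}" for h in range(result.n_axes)]

    eig = pd.DataFrame({"eigenvalue": result.eigenvalues}, index=axes)
    paths["eigenvalues"] = outdir / "eigenvalues.tsv"
    write_matrix(eig, paths["eigenvalues"], index_label="axis")

    prop = result.full_spectrum / result.full_spectrum.sum()
    ve = pd.DataFrame(
        {"eigenvalue": result.full_spectrum, "proportion": prop},
        index=[f"axis{h + 1}" for h in range(len(result.full_spectrum))],
    )
    paths["variance_explained"] = outdir / "variance_explained.tsv"
    write_matrix(ve, paths["variance_explained"], index_label="axis")

    syn = pd.DataFrame(result.synthetic_scores, index=result.sample_ids, columns=axes)
    paths["synthetic_scores"] = outdir / "synthetic_scores.tsv"
    write_matrix(syn, paths["synthetic_scores"], index_label="sample")

    for name in result.table_names:
        scores = pd.DataFrame(result.table_scores[name], index=result.sample_ids, columns=axes)
        p = outdir / f"table_scores_{name}.tsv"
        write_matrix(scores, p, index_label="sample")
        paths[f"table_scores_{name}"] = p

    pe = pd.DataFrame(result.pseudo_eigenvalues, index=result.table_names, columns=axes)
    paths["pseudo_eigenvalues"] = outdir / "pseudo_eigenvalues.tsv"
    write_matrix(pe, paths["pseudo_eigenvalues"], index_label="table")
    return paths
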