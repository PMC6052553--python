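"""Readers and writers for the plain-text interchange formats.

Counts travel as TSV/CSV with feature IDs in the first column and sample IDs
in the header; labels as a two-column CSV ``sample_id,group``; simulation
truth as TSV; DE results as TSV whose leading ``#`` comment lines echo the
run configuration so any result file can be regenerated from its header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import CountMatrix, GroupAssignment, InputError
from .detest import DEResult
from .simulate import SimDesign, SimOutput, SimTruth

__all__ = [
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "read_truth",
    "write_truth",
    "read_results",
    "write_results",
    "read_feature_list",
    "write_sim_output",
]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path: str | Path) -> CountMatrix:
    """Load and validate a count matrix from TSV (default) or CSV.

    Errors name the offending cell: duplicated IDs, ragged rows, negative
    or non-integer entries are all rejected.
    """
    path = Path(path)
    sep = _sep(path)
    with open(path) as fh:  # pandas mangles duplicate header names, so check raw
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = [c.strip() for c in line.rstrip("\n").split(sep)][1:]
                break
        else:
            raise InputError(f"{path}: empty file")
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise InputError(f"{path}: duplicate sample ID {col!r}")
        seen.add(col)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: malformed table ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path}: duplicate feature ID {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]][0]
        raise InputError(f"{path}: non-numeric entries in sample column {bad!r}")
    if np.isnan(values.astype(np.float64)).any():
        i, j = np.argwhere(np.isnan(values.astype(np.float64)))[0]
        raise InputError(f"{path}: missing value at feature {df.index[i]!r}, sample {df.columns[j]!r}")
    for cond, what in ((values < 0, "negative"), (values != np.floor(values), "non-integer")):
        if cond.any():
            i, j = np.argwhere(cond)[0]
            raise InputError(
                f"{path}: {what} count {values[i, j]!r} at feature {df.index[i]!r},"
                f" sample {df.columns[j]!r}"
            )
    return CountMatrix.from_frame(df)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    counts.to_frame().to_csv(path, sep=_sep(path), index_label="feature_id")


def read_labels(path: str | Path) -> GroupAssignment:
    """Load a two-column ``sample_id,group`` CSV (header required)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two columns (sample_id, group)")
    sample, group = df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)
    if sample.duplicated().any():
        raise InputError(f"{path}: duplicate sample ID {sample[sample.duplicated()].iloc[0]!r}")
    return GroupAssignment(dict(zip(sample, group)))


def write_labels(groups: GroupAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.labels.keys()), "group": list(groups.labels.values())}
    ).to_csv(path, index=False)


def read_truth(path: str | Path) -> SimTruth:
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "category", "fold_change", "is_de"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: truth table needs columns {sorted(required)}")
    return SimTruth(
        list(df["feature_id"].astype(str)),
        df["category"].to_numpy(dtype=object),
        df["fold_change"].to_numpy(dtype=np.float64),
        df["is_de"].astype(bool).to_numpy(),
    )


def write_truth(truth: SimTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_results(result: DEResult, path: str | Path) -> None:
    """Write a DE result TSV with a ``#``-prefixed configuration echo."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in result.metadata.items():
            fh.write(f"# {key}={value}\n")
        result.to_frame().to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a DE result (or any external call table), skipping comments."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_feature_list(path: str | Path) -> list[str]:
    """One feature ID per line; blank lines ignored."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise InputError(f"{path}: empty feature list")
    return ids


def write_sim_output(sim: SimOutput, outdir: str | Path) -> dict[str, Path]:
    """Write counts.tsv, labels.csv, truth.tsv and design.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "labels": outdir / "labels.csv",
        "truth": outdir / "truth.tsv",
        "design": outdir / "design.json",
    }
    write_counts(sim.counts, paths["counts"])
    write_labels(sim.groups, paths["labels"])
    write_truth(sim.truth, paths["truth"])
    with open(paths["design"], "w") as fh:
        json.dump(sim.design.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
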