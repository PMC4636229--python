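"""Readers, writers, bundled example tables and model comparison.

Pattern tables are delimited text (TSV by default, CSV accepted): one column
per item named by its label, a ``count`` column, and an optional ``group``
column; one row per distinct pattern, header required.  Fit results round-trip
through JSON at full precision; posterior scores are written as TSV.

Three small published cross-classifications ship with the package as
fixtures: ``army`` (four dichotomous attitude items, N = 1000), ``italian``
(four dichotomous stereotype items in two randomized target-group conditions,
N = 1007 + 994) and ``alcohol`` (two 4-category reasons-for-abstaining items,
N = 547).
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import PatternTable
from .estimation import FitResult, ModelSpec
from .scoring import PosteriorScore

__all__ = [
    "read_pattern_table",
    "write_pattern_table",
    "write_fit",
    "read_fit",
    "write_scores",
    "compare_models",
    "load_fixture",
    "FIXTURES",
]

FIXTURES = ("army", "italian", "alcohol")


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as e:
        raise ValueError(f"cannot parse {path}: {e}") from e


def read_pattern_table(
    path: str | Path,
    n_categories: Sequence[int] | None = None,
    count_col: str = "count",
    group_col: str = "group",
) -> PatternTable:
    """Read a pattern-frequency table from delimited text.

    Item columns are all columns other than ``count`` and ``group``; category
    counts per item are inferred (2 when all codes are 0/1, otherwise the
    maximum code) unless given explicitly.  Duplicate pattern rows within a
    group are summed with a warning; real-valued counts are accepted so exact
    population tables pass through.
    """
    df = _read_frame(path)
    if count_col not in df.columns:
        raise ValueError(f"{path}: missing required column {count_col!r}")
    item_cols = [c for c in df.columns if c not in (count_col, group_col)]
    if not item_cols:
        raise ValueError(f"{path}: no item columns found")
    if len(df) == 0:
        raise ValueError(f"{path}: empty table")
    counts = pd.to_numeric(df[count_col], errors="coerce")
    if counts.isna().any():
        row = int(counts.index[counts.isna()][0]) + 2  # header is line 1
        raise ValueError(f"{path}: non-numeric count at line {row}")
    if (counts < 0).any():
        row = int(counts.index[counts < 0][0]) + 2
        raise ValueError(f"{path}: negative count at line {row}")
    for c in item_cols:
        codes = pd.to_numeric(df[c], errors="coerce")
        if codes.isna().any() or (codes != codes.round()).any():
            row = int(codes.index[codes.isna() | (codes != codes.round())][0]) + 2
            raise ValueError(f"{path}: non-integer category code in {c!r} at line {row}")

    groups = df[group_col].astype(str).tolist() if group_col in df.columns else None
    raw_patterns = [tuple(int(v) for v in row) for row in df[item_cols].to_numpy()]

    if n_categories is None:
        n_categories = []
        for c in item_cols:
            vals = set(int(v) for v in df[c])
            if vals <= {0, 1}:
                n_categories.append(2)
            else:
                n_categories.append(max(vals))
        n_categories = tuple(n_categories)

    agg: dict[tuple, float] = {}
    dups = False
    for i, pat in enumerate(raw_patterns):
        key = (groups[i] if groups else None, pat)
        if key in agg:
            dups = True
        agg[key] = agg.get(key, 0.0) + float(counts.iloc[i])
    if dups:
        warnings.warn(f"{path}: duplicate pattern rows summed")
    return PatternTable(
        patterns=[k[1] for k in agg],
        counts=np.array(list(agg.values())),
        item_labels=tuple(item_cols),
        n_categories=n_categories,
        groups=[k[0] for k in agg] if groups else None,
    )


def write_pattern_table(
    table: PatternTable, path: str | Path, probs: Sequence[float] | None = None
) -> None:
    """Write a table in the same layout it is read from (optional prob column)."""
    path = Path(path)
    data = {lab: [p[i] for p in table.patterns] for i, lab in enumerate(table.item_labels)}
    data["count"] = table.counts
    if table.groups:
        data["group"] = table.groups
    if probs is not None:
        data["prob"] = list(probs)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def load_fixture(name: str) -> PatternTable:
    """Load one of the bundled example tables: 'army', 'italian', 'alcohol'."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    ref = resources.files("ebeirt.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as p:
        return read_pattern_table(p)


def fixture_path(name: str) -> Path:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    ref = resources.files("ebeirt.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as p:
        return Path(p)


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------


def write_fit(fit: FitResult, path: str | Path) -> None:
    """Serialize a FitResult to JSON at full precision."""
    payload = {
        "spec": fit.spec.to_dict(),
        "estimates": fit.estimates,
        "standard_errors": fit.standard_errors,
        "loglik": fit.loglik,
        "lr_chisq": fit.lr_chisq,
        "df": fit.df,
        "p_value": fit.p_value,
        "bic": fit.bic,
        "converged": fit.converged,
        "n_free": fit.n_free,
        "start_values": fit.start_values,
        "theta": list(map(float, fit.theta)),
        "data_hash": fit.data_hash,
        "n_obs": fit.n_obs,
        "message": fit.message,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit(path: str | Path) -> FitResult:
    """Reconstruct a FitResult written by :func:`write_fit` (bit-equal fields)."""
    d = json.loads(Path(path).read_text())
    return FitResult(
        spec=ModelSpec.from_dict(d["spec"]),
        estimates=d["estimates"],
        standard_errors=d["standard_errors"],
        loglik=d["loglik"],
        lr_chisq=d["lr_chisq"],
        df=d["df"],
        p_value=d["p_value"],
        bic=d["bic"],
        converged=d["converged"],
        n_free=d["n_free"],
        start_values=d["start_values"],
        theta=np.array(d["theta"]),
        data_hash=d["data_hash"],
        n_obs=d["n_obs"],
        message=d.get("message", ""),
    )


def write_scores(
    scores: Sequence[PosteriorScore],
    path: str | Path,
    table: PatternTable | None = None,
) -> None:
    """Write posterior scores as TSV: pattern, count, mean, SD, Pr[pattern]."""
    rows = []
    for i, s in enumerate(scores):
        row = {f"item{j + 1}": v for j, v in enumerate(s.pattern)}
        if table is not None:
            row = dict(zip(table.item_labels, s.pattern))
            row["count"] = float(table.counts[i])
        if s.group is not None:
            row["group"] = s.group
        row["posterior_mean"] = s.mean
        row["posterior_sd"] = float(np.sqrt(s.variance))
        row["pattern_prob"] = s.pattern_prob
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


def compare_models(
    fits: Sequence[FitResult],
    names: Sequence[str] | None = None,
    baseline: int = 0,
) -> pd.DataFrame:
    """Side-by-side fit statistics with differences against a baseline fit.

    All fits must come from the same data (checked by content hash).  The
    returned frame carries L^2, df, p, BIC, the L^2/df differences against the
    baseline, and flags the lowest-BIC model as preferred.
    """
    if not fits:
        raise ValueError("no fits to compare")
    h0 = fits[0].data_hash
    if any(f.data_hash != h0 for f in fits):
        raise ValueError("fits come from different data (hash mismatch)")
    names = list(names) if names else [f"model{i + 1}" for i in range(len(fits))]
    base = fits[baseline]
    rows = []
    for name, f in zip(names, fits):
        rows.append(
            {
                "model": name,
                "lr_chisq": f.lr_chisq,
                "df": f.df,
                "p_value": f.p_value,
                "bic": f.bic,
                "delta_chisq": f.lr_chisq - base.lr_chisq,
                "delta_df": f.df - base.df,
            }
        )
    out = pd.DataFrame(rows)
    out["preferred"] = out["bic"] == out["bic"].min()
    return out
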