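"""Readers and writers for the pipeline's plain-text formats.

All formats are UTF-8 text with '.' decimal separators:

- spot tables: TSV with header ``array_id antibody_id replicate_index
  foreground background``;
- sample metadata: CSV with header ``sample_id,group,center,age,sex,mmse``
  (blank mmse = missing);
- expression / correlation / similarity matrices: TSV, first column the
  row id, remaining columns sample or protein ids;
- gene sets: one identifier per line;
- ground truth and reports: JSON.

write(read(path)) round-trips bit-exactly; malformed files are rejected
with the offending id or line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from signalome.preprocess import SPOT_COLUMNS, validate_spot_table


class ParseError(ValueError):
    pass


_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def read_spot_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        spots = pd.read_csv(
            path, sep="\t", dtype={"array_id": str, "antibody_id": str},
            float_precision="round_trip",
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    try:
        return validate_spot_table(spots)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    spots[SPOT_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ParseError(f"{path}: missing sample_id column")
    dup = meta["sample_id"].duplicated()
    if dup.any():
        raise ParseError(f"{path}: duplicate sample_id {meta.loc[dup, 'sample_id'].iloc[0]!r}")
    if "mmse" in meta.columns:
        meta["mmse"] = pd.to_numeric(meta["mmse"], errors="coerce")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False, float_format="%g")


def read_matrix(path: str | Path, index_name: str = "antibody_id") -> pd.DataFrame:
    """Read a TSV matrix with row ids in the first column."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate {index_name} {dupes[:5]}")
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        raise ParseError(f"{path}: non-numeric column(s) {list(non_numeric)[:5]}")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ParseError(f"{path}: missing or non-numeric cell in row {row!r}")
    df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "antibody_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_gene_set(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and duplicates dropped."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    seen: dict[str, None] = {}
    for ln in lines:
        g = ln.strip()
        if g:
            seen.setdefault(g, None)
    return list(seen)


def write_gene_set(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n", encoding="utf-8")


def read_similarity_matrix(path: str | Path) -> pd.DataFrame:
    S = read_matrix(path, index_name="protein_id")
    if list(S.index) != list(S.columns):
        raise ParseError(f"{path}: similarity matrix rows and columns differ")
    return S


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
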