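"""Tab-separated readers/writers for the pipeline's tables.

All matrices are gene x sample TSVs with a header row and the gene symbol in
the first column; floats are written with a fixed "%.10g" format so reruns
with the same seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from agewire.errors import InputError

FLOAT_FORMAT = "%.10g"

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "read_catalog",
    "read_ortholog_map",
    "read_ct_table",
    "write_table",
]


def read_matrix(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        raise InputError(f"duplicate gene symbols in {path}")
    return frame


def write_matrix(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene")
    return path


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "age", "sex"}
    missing = required - set(meta.columns)
    if missing:
        raise InputError(f"metadata missing columns: {sorted(missing)}")
    if "cohort" not in meta.columns:
        meta["cohort"] = "cohort1"
    if meta["sample_id"].duplicated().any():
        raise InputError("duplicate sample_ids in metadata")
    return meta


def read_catalog(path) -> pd.DataFrame:
    catalog = pd.read_csv(path, sep="\t")
    missing = {"symbol", "class"} - set(catalog.columns)
    if missing:
        raise InputError(f"gene catalog missing columns: {sorted(missing)}")
    if catalog["symbol"].duplicated().any():
        raise InputError("duplicate symbols in gene catalog")
    return catalog


def read_ortholog_map(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    missing = {"human_symbol", "rodent_symbol"} - set(table.columns)
    if missing:
        raise InputError(f"ortholog map missing columns: {sorted(missing)}")
    # keep the map one-to-one: drop human symbols mapped more than once
    table = table.drop_duplicates("human_symbol", keep=False)
    table = table.drop_duplicates("rodent_symbol", keep=False)
    return dict(zip(table["human_symbol"], table["rodent_symbol"]))


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)
    return path
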