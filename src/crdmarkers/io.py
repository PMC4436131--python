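"""TSV/JSON I/O with reproducibility headers.

Every table the pipeline writes carries ``#`` header lines embedding the
resolved config hash and seed, so a rerun with the same config reproduces
files bit-exactly and any output can be traced to its run.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, set):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_gene_list(genes, path, comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for gene in sorted(genes):
            fh.write(f"{gene}\n")
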