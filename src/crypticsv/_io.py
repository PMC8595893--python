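"""Deterministic TSV I/O helpers.

All tables are written with a ``##`` provenance preamble (tool version and the
effective parameters of the stage that produced them) followed by a plain
tab-separated table. Gzipped outputs are written with mtime=0 so reruns with an
identical configuration are byte-identical.
"""

from __future__ import annotations

import csv
import gzip
from pathlib import Path

import pandas as pd

from . import __version__


def meta_lines(stage: str, params: dict | None = None) -> dict:
    meta = {"tool": f"crypticsv {__version__}", "stage": stage}
    if params:
        meta["params"] = ";".join(f"{k}={v}" for k, v in sorted(params.items()))
    return meta


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = str(path)
    preamble = "".join(f"## {k}={v}\n" for k, v in (meta or {}).items())
    body = df.to_csv(sep="\t", index=False, quoting=csv.QUOTE_NONE)
    data = (preamble + body).encode()
    if path.endswith(".gz"):
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                gz.write(data)
    else:
        Path(path).write_bytes(data)


def read_tsv(path, dtype=None) -> pd.DataFrame:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    n_skip = 0
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("##"):
                n_skip += 1
            else:
                break
    return pd.read_csv(
        path,
        sep="\t",
        skiprows=n_skip,
        dtype=dtype,
        quoting=csv.QUOTE_NONE,
        keep_default_na=False,
    )
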