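"""Plain-text I/O helpers: key=value parameter configs, pmf tables,
BED intervals and bedGraph profiles.

Everything here is deliberately simple, line-oriented text so that every
artifact the pipeline writes can be inspected (and versioned) directly.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "write_config",
    "read_config",
    "write_pmf",
    "read_pmf",
    "read_bed",
    "write_bed",
    "write_bedgraph",
]


def _parse_scalar(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def write_config(path: str | os.PathLike, values: Mapping) -> None:
    """Write a flat ``key = value`` config; keys are written sorted so the
    output is byte-stable."""
    with open(path, "w") as fh:
        for key in sorted(values):
            fh.write(f"{key} = {values[key]!r}\n" if isinstance(values[key], str)
                     else f"{key} = {values[key]}\n")


def read_config(path: str | os.PathLike) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            val = val.strip()
            if val.startswith(("'", '"')) and val.endswith(val[0]):
                out[key.strip()] = val[1:-1]
            else:
                out[key.strip()] = _parse_scalar(val)
    return out


def write_pmf(path: str | os.PathLike, pmf: np.ndarray) -> None:
    """Two-column TSV ``count<TAB>probability``."""
    with open(path, "w") as fh:
        fh.write("count\tprobability\n")
        for m, p in enumerate(np.asarray(pmf, float)):
            fh.write(f"{m}\t{p:.12e}\n")


def read_pmf(path: str | os.PathLike) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    pmf = np.zeros(int(df["count"].max()) + 1)
    pmf[df["count"].to_numpy()] = df["probability"].to_numpy()
    return pmf


_BED_COLS = ["chrom", "start", "end", "name"]


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED3/BED4 file (0-based half-open intervals)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = _BED_COLS[: df.shape[1]] + list(df.columns[4:])
    return df


def write_bed(path: str | os.PathLike, df: pd.DataFrame) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(path: str | os.PathLike, chrom: str, starts, ends,
                   values) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")
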