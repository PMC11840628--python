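"""TSV serialisation of both representations.

MAG files are the five integer columns (``Ai``, ``Aj``, ``Info``, ``Core``,
``Type``), one row per bond in bond-number order.  SOLex files carry one row
per core preceded by the global row (``core`` = 0), with a ``molecule_id``
column so a mixture fits in one file; the 44 attribute columns hold plain
integers (the RCn/Arr codes serialise as integers and are re-padded on
reading).  Both formats round-trip bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .attributes import (
    ATTRIBUTES,
    ArrCode,
    N_COUNT_ATTRIBUTES,
    RCnCode,
    SOLexMixture,
    SOLexMolecule,
)
from .mag import MAGEdge, MAGMolecule

__all__ = [
    "read_mag_tsv",
    "write_mag_tsv",
    "read_solex_tsv",
    "write_solex_tsv",
    "ParseError",
]

MAG_COLUMNS = ["Ai", "Aj", "Info", "Core", "Type"]
_ATTR_NAMES = [a.name for a in ATTRIBUTES]


class ParseError(ValueError):
    """Malformed input file (carries the offending line where known)."""


def write_mag_tsv(mag: MAGMolecule, path: str | Path) -> None:
    df = pd.DataFrame(mag.matrix(), columns=MAG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_mag_tsv(path: str | Path) -> MAGMolecule:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != MAG_COLUMNS:
        raise ParseError(
            f"{path}: line 1: expected columns {MAG_COLUMNS}, got {list(df.columns)}"
        )
    for i, row in enumerate(df.itertuples(index=False), start=2):
        for v in row:
            if not isinstance(v, (int, np.integer)):
                raise ParseError(f"{path}: line {i}: non-integer field {v!r}")
    edges = [MAGEdge(*map(int, row)) for row in df.itertuples(index=False)]
    return MAGMolecule(edges)


def write_solex_tsv(
    molecules: SOLexMixture | SOLexMolecule | list[SOLexMolecule],
    path: str | Path,
) -> None:
    if isinstance(molecules, SOLexMolecule):
        molecules = [molecules]
    rows = []
    for mi, mol in enumerate(molecules):
        m = mol.matrix
        for core in range(m.shape[0]):
            rows.append([mi, core, *m[core]])
    df = pd.DataFrame(rows, columns=["molecule_id", "core", *_ATTR_NAMES])
    df.to_csv(path, sep="\t", index=False)


def read_solex_tsv(path: str | Path) -> list[SOLexMolecule]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    expected = ["molecule_id", "core", *_ATTR_NAMES]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: line 1: expected columns {expected[:4]}..., "
                         f"got {list(df.columns)[:4]}...")
    out = []
    for _mid, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("core")
        cores = grp[grp["core"] > 0]
        if cores.empty:
            raise ParseError(f"{path}: molecule {_mid} has no core rows")
        counts = cores[_ATTR_NAMES[:N_COUNT_ATTRIBUTES]].to_numpy(dtype=np.int64)
        rcn = [RCnCode.from_int(int(v)) for v in cores["RCn"]]
        arr = [ArrCode.from_int(int(v)) for v in cores["Arr"]]
        out.append(SOLexMolecule(counts, rcn=rcn, arr=arr))
    return out
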