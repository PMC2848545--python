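"""The tool's tab-delimited input/output dialect.

Input: a header of one-letter factor codes each followed by its association
rank (e.g. ``T1<TAB>B2``), then one line per gene group giving the percent
occupancies in header-column order followed by the group name.  The
association order is the rank sort, irrespective of column order.  Output:
the groups x mechanisms compatibility chart (-1 compatible / 0
incompatible, consumable by Cluster/Treeview-class tools as a plain grid)
and the mechanism-key file mapping each id to its dissociation sequence.
All files are UTF-8, Unix newlines, ASCII "-1".
"""

from __future__ import annotations

import re
from typing import Sequence, TextIO

import pandas as pd

from .mechanisms import FactorOrder

__all__ = [
    "PathComFormatError",
    "read_pathcom_input",
    "write_pathcom_input",
    "write_compatibility_matrix",
    "read_compatibility_matrix",
    "write_mechanism_key",
]

_HEADER_TOKEN = re.compile(r"^(?P<code>\S)(?P<rank>[1-9]\d*)$")


class PathComFormatError(ValueError):
    """Malformed input, reported with a 1-based line number."""

    def __init__(self, message: str, line: int | None = None) -> None:
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _as_text(stream) -> TextIO:
    if isinstance(stream, (str, bytes)):
        raise TypeError("pass an open text stream or use a path-based wrapper")
    return stream


def _parse_header(line: str, lineno: int) -> tuple[FactorOrder, list[str]]:
    tokens = line.rstrip("\n").split("\t")
    pairs: list[tuple[str, int]] = []
    for tok in tokens:
        m = _HEADER_TOKEN.match(tok.strip())
        if not m:
            raise PathComFormatError(
                f"bad header token {tok!r} (expected code+rank, e.g. 'T1')", lineno
            )
        pairs.append((m.group("code"), int(m.group("rank"))))
    codes = [c for c, _ in pairs]
    ranks = sorted(r for _, r in pairs)
    if len(set(codes)) != len(codes):
        raise PathComFormatError(f"duplicate factor codes in header {codes}", lineno)
    if ranks != list(range(1, len(pairs) + 1)):
        raise PathComFormatError(
            f"association ranks {sorted(r for _, r in pairs)} are not 1..n", lineno
        )
    ordered = [c for c, _ in sorted(pairs, key=lambda p: p[1])]
    return FactorOrder(ordered), codes


def _parse_row(
    fields: list[str], n: int, lineno: int, name_first: bool
) -> tuple[list[float], str]:
    if len(fields) != n + 1:
        raise PathComFormatError(
            f"expected {n} occupancies plus a group name ({n + 1} fields), "
            f"got {len(fields)}", lineno,
        )
    raw = fields[1:] if name_first else fields[:-1]
    name = fields[0] if name_first else fields[-1]
    vals = []
    for f in raw:
        try:
            v = float(f)
        except ValueError:
            raise PathComFormatError(f"non-numeric occupancy {f!r}", lineno) from None
        if not (v == v) or v in (float("inf"), float("-inf")):
            raise PathComFormatError(f"non-finite occupancy {f!r}", lineno)
        if v < 0 or v > 100:
            raise PathComFormatError(f"occupancy {v} outside [0, 100]", lineno)
        vals.append(v)
    if not name.strip():
        raise PathComFormatError("empty group name", lineno)
    return vals, name.strip()


def read_pathcom_input(stream) -> tuple[FactorOrder, pd.DataFrame]:
    """Parse the occupancy-table input dialect.

    Returns the association order (sorted by header ranks) and a DataFrame
    indexed by group name with one column per factor code.  The group name
    normally trails the occupancy fields; a leading-name layout is
    auto-detected as a fallback when the trailing-name reading fails.
    """
    stream = _as_text(stream)
    lines = stream.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise PathComFormatError("empty input", 1)
    assoc, header_codes = _parse_header(lines[0], 1)
    n = assoc.n
    if len(lines) == 1:
        raise PathComFormatError("no data rows after header", 2)

    rows_fields = [ln.split("\t") for ln in lines[1:]]

    def parse_all(name_first: bool):
        names, data = [], []
        for off, fields in enumerate(rows_fields, start=2):
            vals, name = _parse_row(fields, n, off, name_first)
            names.append(name)
            data.append(vals)
        return names, data

    try:
        names, data = parse_all(name_first=False)
    except PathComFormatError as trailing_err:
        try:
            names, data = parse_all(name_first=True)
        except PathComFormatError:
            raise trailing_err from None

    table = pd.DataFrame(data, columns=header_codes, index=names)
    table.index.name = "group"
    # Column order follows the header, but all lookups are by code.
    return assoc, table


def write_pathcom_input(
    assoc: FactorOrder, table: pd.DataFrame, stream, decimals: int = 6
) -> None:
    """Write an occupancy table in the input dialect (trailing group name)."""
    stream = _as_text(stream)
    stream.write("\t".join(f"{c}{i}" for i, c in enumerate(assoc.codes, 1)) + "\n")
    for name, row in table.iterrows():
        vals = [_fmt(float(row[c]), decimals) for c in assoc.codes]
        stream.write("\t".join(vals + [str(name)]) + "\n")


def _fmt(v: float, decimals: int) -> str:
    s = f"{v:.{decimals}f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_compatibility_matrix(matrix: pd.DataFrame, stream) -> None:
    """Write the chart: header row of mechanism ids, then name + cells rows."""
    stream = _as_text(stream)
    stream.write("\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
    for name, row in matrix.iterrows():
        cells = [str(int(v)) for v in row]
        stream.write(str(name) + "\t" + "\t".join(cells) + "\n")


def read_compatibility_matrix(stream) -> pd.DataFrame:
    """Read back a chart written by :func:`write_compatibility_matrix`."""
    stream = _as_text(stream)
    df = pd.read_csv(stream, sep="\t", index_col=0)
    df.columns = [int(c) for c in df.columns]
    df.index.name = None
    bad = set(df.to_numpy().ravel()) - {-1, 0}
    if bad:
        raise PathComFormatError(f"matrix cells outside {{-1, 0}}: {sorted(bad)}")
    return df.astype(int)


def write_mechanism_key(key: Sequence[tuple[int, str]], stream) -> None:
    """Write the id -> dissociation-sequence key, ids ascending."""
    stream = _as_text(stream)
    last = 0
    for mid, seq in key:
        if mid <= last:
            raise ValueError("mechanism ids must be strictly ascending")
        last = mid
        stream.write(f"{mid}\t{seq}\n")
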