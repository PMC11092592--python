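"""Generic STAR file reading and writing.

Supports the subset used for STA interchange: named data blocks containing
either a ``loop_`` table (returned as a DataFrame) or bare key-value pairs
(returned as a single-row DataFrame).  Numeric columns are inferred on read.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["read_star", "write_star", "StarError"]


class StarError(ValueError):
    pass


def _coerce(series: pd.Series) -> pd.Series:
    try:
        return pd.to_numeric(series)
    except (ValueError, TypeError):
        return series


def read_star(text: str) -> dict[str, pd.DataFrame]:
    """Parse STAR text into ``{block_name: DataFrame}`` in file order."""
    blocks: dict[str, pd.DataFrame] = {}
    name: str | None = None
    columns: list[str] = []
    rows: list[list[str]] = []
    kv: dict[str, str] = {}
    in_loop = False

    def flush() -> None:
        nonlocal columns, rows, kv, in_loop
        if name is not None:
            if columns:
                df = pd.DataFrame(rows, columns=columns)
                blocks[name] = df.apply(_coerce)
            elif kv:
                df = pd.DataFrame([kv])
                blocks[name] = df.apply(_coerce)
        columns, rows, kv, in_loop = [], [], {}, False

    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("data_"):
            flush()
            name = stripped[5:]
            continue
        if stripped == "loop_":
            in_loop = True
            continue
        if stripped.startswith("_"):
            token = stripped.split()[0][1:]
            if in_loop:
                columns.append(token)
            else:
                parts = stripped.split(None, 1)
                if len(parts) != 2:
                    raise StarError(f"key without value: {stripped!r}")
                kv[token] = parts[1]
            continue
        if name is None:
            raise StarError(f"data outside any block: {stripped!r}")
        values = stripped.split()
        if len(values) != len(columns):
            raise StarError(
                f"block {name!r}: row has {len(values)} fields, "
                f"expected {len(columns)}"
            )
        rows.append(values)
    flush()
    return blocks


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def write_star(blocks: dict[str, pd.DataFrame]) -> str:
    """Serialize ``{block_name: DataFrame}`` as STAR loop tables."""
    out = io.StringIO()
    for name, df in blocks.items():
        out.write(f"data_{name}\n\nloop_\n")
        for i, col in enumerate(df.columns, start=1):
            out.write(f"_{col} #{i}\n")
        for _, row in df.iterrows():
            out.write(" ".join(_fmt(v) for v in row) + "\n")
        out.write("\n")
    return out.getvalue()
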