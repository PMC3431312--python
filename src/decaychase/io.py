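"""Reading and writing the pipeline's long-format TSV tables.

The expression matrix schema (schema version ``decaychase-expression-v1``)
is long with header columns transcript_id, condition, replicate, time_min,
intensity and optional detection_p.  Times stay in minutes exactly as
given; unknown extra columns are preserved verbatim on round trips.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["ParseError", "read_expression_tsv", "write_expression_tsv", "write_tsv"]

SCHEMA_COMMENT = "# decaychase-expression-v1"

REQUIRED = ["transcript_id", "condition", "replicate", "time_min", "intensity"]
KEY = ["transcript_id", "condition", "replicate", "time_min"]


class ParseError(ValueError):
    """Raised for malformed input tables, with a line reference where possible."""


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a long-format expression TSV, checking schema and key uniqueness."""
    path = Path(path)
    with path.open() as fh:
        n_comment = 0
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    dup = df.duplicated(subset=KEY, keep="first")
    if dup.any():
        # +2: one for the header line, one for 1-based numbering
        line_no = int(dup.idxmax()) + n_comment + 2
        key = df.loc[dup.idxmax(), KEY].tolist()
        raise ParseError(
            f"{path}: duplicate (transcript, condition, replicate, time) key {key} "
            f"at line {line_no}"
        )
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an expression matrix with the schema-version header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as plain TSV."""
    df.to_csv(path, sep="\t", index=False)
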