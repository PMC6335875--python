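"""Read-only loader for GEO Series Matrix text files.

Parses the expression table between ``!series_matrix_table_begin`` and
``!series_matrix_table_end`` plus the per-sample annotation lines
(``!Sample_*``).  Study-specific metadata fields (hours awake, sample index,
condition) cannot be derived from the annotations alone and are left for a
user-supplied mapping file.
"""

from __future__ import annotations

import csv
import io as _stdio

import pandas as pd

from .io import ExpressionMatrix

__all__ = ["load_geo_series_matrix"]


def load_geo_series_matrix(path):
    """Return (ExpressionMatrix, sample annotation skeleton DataFrame)."""
    annotations: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = False
    with open(path, newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                saw_begin = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                parts = next(csv.reader([line], delimiter="\t"))
                key = parts[0][len("!Sample_"):]
                vals = parts[1:]
                base = key
                i = 2
                while key in annotations:
                    key = f"{base}.{i}"
                    i += 1
                annotations[key] = vals
    if not saw_begin:
        raise ValueError(f"{path}: missing !series_matrix_table_begin marker")
    if not table_lines:
        raise ValueError(f"{path}: empty series matrix table")
    expr = pd.read_csv(_stdio.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    expr.columns = [c.strip('"') for c in expr.columns]
    expr.index = pd.Index([str(i).strip('"') for i in expr.index], name="feature_id")
    matrix = ExpressionMatrix(values=expr.astype(float), flags=None)
    skeleton = pd.DataFrame(annotations, index=expr.columns)
    skeleton.index.name = "sample_id"
    return matrix, skeleton
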