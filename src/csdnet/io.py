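"""Reading and writing labelled expression matrices.

The on-disk format is delimited text (TSV by default): the first row holds
gene identifiers, the first column holds sample identifiers, and every other
cell is a numeric expression value.  Files with genes as rows are accepted
through ``transpose=True``.  Parsing is strict: an empty, NA or non-numeric
cell aborts with the offending gene and sample named, because imputation of
missing values is deliberately not implemented.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_expression", "write_expression", "validate_expression"]


def validate_expression(expr: pd.DataFrame, name: str = "expression matrix") -> pd.DataFrame:
    """Check the invariants of a samples x genes expression matrix.

    Requires at least 3 samples (rows) and 2 genes (columns), unique labels
    on both axes, and a fully finite numeric body.  Returns the validated
    frame (with a float body) so callers can chain.
    """
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate sample identifiers {dups}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate gene identifiers {dups}")
    if expr.shape[0] < 3:
        raise ValueError(f"{name}: need at least 3 samples, got {expr.shape[0]}")
    if expr.shape[1] < 2:
        raise ValueError(f"{name}: need at least 2 genes, got {expr.shape[1]}")

    try:
        values = expr.to_numpy(dtype=float)
    except (TypeError, ValueError):
        # locate the first offending cell for the error message
        for gene in expr.columns:
            col = pd.to_numeric(expr[gene], errors="coerce")
            bad = col.index[col.isna() & expr[gene].notna()]
            if len(bad):
                raise ValueError(
                    f"{name}: non-numeric value {expr.at[bad[0], gene]!r} for gene "
                    f"{gene!r} in sample {bad[0]!r}; imputation of missing values "
                    "is not implemented"
                ) from None
        raise
    if not np.isfinite(values).all():
        rows, cols = np.nonzero(~np.isfinite(values))
        sample, gene = expr.index[rows[0]], expr.columns[cols[0]]
        raise ValueError(
            f"{name}: missing or non-finite value for gene {gene!r} in sample "
            f"{sample!r}; imputation of missing values is not implemented"
        )
    out = expr.astype(float)
    return out


def read_expression(
    path,
    sep: str = "\t",
    transpose: bool = False,
    name: str | None = None,
) -> pd.DataFrame:
    """Read a labelled expression matrix from delimited text.

    Parameters
    ----------
    path
        File with gene identifiers in the first row, sample identifiers in
        the first column, numeric cells elsewhere.
    sep
        Field delimiter, tab by default (use ``","`` for CSV).
    transpose
        Set when the file stores genes as rows and samples as columns.
    """
    frame = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=object,
                        keep_default_na=False, na_values=[])
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if transpose:
        frame = frame.T
    label = name or str(path)

    # strict numeric parse with cell-accurate diagnostics
    numeric = {}
    for gene in frame.columns:
        col = pd.to_numeric(frame[gene].replace("", np.nan), errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            raw = frame.at[bad[0], gene]
            raise ValueError(
                f"{label}: cannot parse value {raw!r} for gene {gene!r} in sample "
                f"{bad[0]!r}; imputation of missing values is not implemented"
            )
        numeric[gene] = col
    out = pd.DataFrame(numeric, index=frame.index)
    return validate_expression(out, name=label)


def write_expression(expr: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a samples x genes matrix in the package's delimited-text format."""
    expr.to_csv(path, sep=sep, index_label="sample")
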