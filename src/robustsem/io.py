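"""Reading rectangular numeric data from delimited text files."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_data"]


def read_data(path, sep=None, header: bool | str = "infer") -> pd.DataFrame:
    """Read an n x p numeric table from CSV/TSV.

    ``sep=None`` infers the delimiter; ``header`` may be True, False or
    'infer'.  Returns a DataFrame whose columns are the variable names (or
    y1..yp when the file has no header).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    hdr = {True: 0, False: None, "infer": "infer"}[header]
    df = pd.read_csv(path, sep=sep, header=hdr)
    if hdr is None or all(
        isinstance(c, (int, np.integer)) for c in df.columns
    ):
        df.columns = [f"y{i + 1}" for i in range(df.shape[1])]
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ValueError("data file contains non-numeric columns")
    return df
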