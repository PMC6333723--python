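"""Published reference tables shipped with the package.

Three small CSVs hold the per-pair kappa tables (five-point weighted and
binary unweighted) and the binary concordance counts of a five-reader
dual-phase amyloid study. They are inputs for the ``reproduce-paper``
checks and the acceptance computations; nothing in the computation path
depends on them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .agreement import ConcordanceCounts


def _load(name: str) -> pd.DataFrame:
    with resources.files("gmedge.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def pairwise_weighted_kappas() -> pd.DataFrame:
    """Per-pair linearly weighted kappas, five-point score (Table 1 layout)."""
    return _load("table1.csv")


def pairwise_binary_kappas() -> pd.DataFrame:
    """Per-pair unweighted kappas, binary classification (Table 2 layout)."""
    return _load("table2.csv")


def concordance_table() -> pd.DataFrame:
    """Binary concordance counts for both methods (Table 3 layout)."""
    return _load("table3.csv")


def concordance_counts_for(method: str) -> ConcordanceCounts:
    df = concordance_table()
    if method not in df.columns:
        raise KeyError(f"no concordance column {method!r}")
    return ConcordanceCounts(tuple(int(v) for v in df[method]))
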