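"""Loaders for the bundled data files."""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

__all__ = ["load_duplicate_pairs_reference"]


def load_duplicate_pairs_reference() -> pd.DataFrame:
    """Published Ka/Ks/ratio/divergence-time estimates for MYB duplicate gene
    pairs in the Capsicum chinense genome (regression fixture for the ratio
    and clock arithmetic).  Columns: gene_a, gene_b, mode, ka, ks, ratio,
    t_mya; NA rows are pairs the original analysis left uncomputed.
    """
    text = resources.files("mybkit.data").joinpath(
        "duplicate_pairs_reference.tsv"
    ).read_text()
    return pd.read_csv(StringIO(text), sep="\t", comment="#")
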