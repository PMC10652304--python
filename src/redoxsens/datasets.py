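"""Bundled reference datasets."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_oa_joint_top20() -> pd.DataFrame:
    """Top-20 composite-sensitivity ranking of mouse OA joint proteins.

    A published reference ranking of the twenty highest-scoring proteins
    (simultaneously the top 20 and the upper 50th CSS percentile) from a
    senolytic-treated osteoarthritic mouse joint proteome.  Columns:
    gene name, protein name, UniProt accession, Louvain community label,
    net oxidative-PTM sign in the old and young treated conditions
    (-1 loss, 0 no change, +1 gain), and the composite sensitivity score
    rounded to two decimals.
    """
    path = resources.files("redoxsens.data").joinpath("oa_joint_top20.tsv")
    with resources.as_file(path) as fh:
        return pd.read_csv(fh, sep="\t")
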