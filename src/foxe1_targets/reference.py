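"""Curated composite-site reference set.

``rat_composite_hits.tsv`` transcribes the 30 published NF1/CTF-FoxE1
composite instances found in promoter regions of FoxE1-regulated rat genes:
gene symbol, expression status after FoxE1 silencing (up/down), reported
spacer length, strand, and the promoter fragment (display markup removed).
It is the worked-example fixture for the scanner: rescanning each fragment
must recover the reported spacer length and strand.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = "rat_composite_hits.tsv"


def load_reference_hits() -> pd.DataFrame:
    """The curated fragment table: gene, status, spacer_len, strand, sequence."""
    with resources.files("foxe1_targets.data").joinpath(_DATA).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["spacer_len"] = df["spacer_len"].astype(int)
    df["strand"] = df["strand"].astype(int)
    return df
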