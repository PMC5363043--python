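"""Bundled reference metadata: the published multi-tissue compendium summary.

The packaged table lists, for each cohort of the systemic sclerosis
compendium this pipeline was designed around, its tissue of origin, GEO
accession(s), array count and the number of co-expression modules found in
it.  It is metadata only — the expression data themselves are not shipped —
and is used for bookkeeping such as compendium-level totals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def compendium_summary() -> pd.DataFrame:
    """The per-dataset summary table (dataset, tissue, accession, counts)."""
    with resources.files("miccnet.data").joinpath("ssc_compendium_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def compendium_totals() -> dict[str, int]:
    """Total array and module counts across the compendium."""
    df = compendium_summary()
    return {
        "n_datasets": int(len(df)),
        "total_arrays": int(df["n_arrays"].sum()),
        "total_modules": int(df["n_modules"].sum()),
    }
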