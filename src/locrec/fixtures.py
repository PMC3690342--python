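"""Packaged reference data: the 2013 SUBA3 corpus snapshot.

The underlying evidence corpus (per-protein accessions) was never
deposited, but its published summary tables were printed in full:
per-compartment FP/MS reconciliation counts (``table1.tsv``), the
pairwise dual-localization matrix (``table2.tsv``), and the corpus-level
headline counts (``suba3_2013_counts.json``). These transcriptions are
faithful to the print, including its known internal inconsistencies —
see the documented quirks in the methods note (contradicted total, the
plasma-membrane diagonal, two rounding cells). Tests and the acceptance
script recompute the derived quantities from these counts; they never
assert the inconsistent printed cells.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .dualloc import read_lower_tsv

_DATA = resources.files("locrec.data")


def load_table1() -> pd.DataFrame:
    """Per-compartment FP claim counts with MS confirmation status,
    indexed by compartment.

    Columns: ``n_fp``, ``n_confirmed``, ``n_contradicted``,
    ``n_unvalidated`` plus the percentages exactly as printed
    (``printed_pct_agree``, ``printed_pct_disagree``).
    """
    with resources.as_file(_DATA / "table1.tsv") as p:
        df = pd.read_csv(p, sep="\t", index_col="compartment")
    return df


def load_table2() -> pd.DataFrame:
    """The pairwise dual-localization matrix, reconstructed to full
    symmetric form from the lower-triangular print layout."""
    with resources.as_file(_DATA / "table2.tsv") as p:
        return read_lower_tsv(p)


def load_headline_counts() -> dict:
    """Corpus-level headline counts (entries/publications/proteins per
    method, internal-consistency counts, dual-claim partition)."""
    return json.loads((_DATA / "suba3_2013_counts.json").read_text())


def load_curated_dual_examples() -> set[str]:
    """The shipped example curated dual-targeted protein list."""
    text = (_DATA / "curated_dual_examples.txt").read_text()
    return {
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }


def read_curated_dual(path) -> set[str]:
    """Read a user-supplied curated dual-targeted list (one protein id
    per line, ``#`` comments allowed)."""
    with open(path, encoding="utf-8") as fh:
        return {
            line.strip().upper()
            for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        }
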