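"""Sampling design of the 14-species congeneric-pairs survey.

Seven plant genera, each represented by one restricted endemic and one
widespread congener, with three populations sampled per species (42
populations in total) in the Sierra de Cazorla mountains.  Per-population
sample sizes ``n`` are the numbers of flowering individuals fingerprinted.
This table drives design bookkeeping (totals, expected record counts) and
gives the synthetic generator its target dimensions.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["design_table", "total_individuals", "expected_records_per_marker"]

_ROWS = [
    # genus, species, distribution, population, n
    ("Anthyllis", "Anthyllis ramburii", "restricted", "anra1", 25),
    ("Anthyllis", "Anthyllis ramburii", "restricted", "anra2", 25),
    ("Anthyllis", "Anthyllis ramburii", "restricted", "anra3", 25),
    ("Anthyllis", "Anthyllis vulneraria", "widespread", "anvu1", 25),
    ("Anthyllis", "Anthyllis vulneraria", "widespread", "anvu2", 25),
    ("Anthyllis", "Anthyllis vulneraria", "widespread", "anvu3", 25),
    ("Aquilegia", "Aquilegia pyrenaica cazorlensis", "restricted", "aqca1", 25),
    ("Aquilegia", "Aquilegia pyrenaica cazorlensis", "restricted", "aqca2", 25),
    ("Aquilegia", "Aquilegia pyrenaica cazorlensis", "restricted", "aqca3", 25),
    ("Aquilegia", "Aquilegia vulgaris vulgaris", "widespread", "aqvu1", 25),
    ("Aquilegia", "Aquilegia vulgaris vulgaris", "widespread", "aqvu2", 25),
    ("Aquilegia", "Aquilegia vulgaris vulgaris", "widespread", "aqvu3", 25),
    ("Convolvulus", "Convolvulus boissieri", "restricted", "cboi1", 25),
    ("Convolvulus", "Convolvulus boissieri", "restricted", "cboi2", 28),
    ("Convolvulus", "Convolvulus boissieri", "restricted", "cboi3", 25),
    ("Convolvulus", "Convolvulus arvensis", "widespread", "carv1", 25),
    ("Convolvulus", "Convolvulus arvensis", "widespread", "carv2", 25),
    ("Convolvulus", "Convolvulus arvensis", "widespread", "carv3", 25),
    ("Daphne", "Daphne oleoides", "restricted", "dole1", 25),
    ("Daphne", "Daphne oleoides", "restricted", "dole2", 25),
    ("Daphne", "Daphne oleoides", "restricted", "dole3", 25),
    ("Daphne", "Daphne laureola", "widespread", "dlau1", 25),
    ("Daphne", "Daphne laureola", "widespread", "dlau2", 25),
    ("Daphne", "Daphne laureola", "widespread", "dlau3", 25),
    ("Erodium", "Erodium cazorlanum", "restricted", "ecazF", 32),
    ("Erodium", "Erodium cazorlanum", "restricted", "ecazL", 33),
    ("Erodium", "Erodium cazorlanum", "restricted", "ecazT", 40),
    ("Erodium", "Erodium cicutarium", "widespread", "ecicC", 28),
    ("Erodium", "Erodium cicutarium", "widespread", "ecicF", 30),
    ("Erodium", "Erodium cicutarium", "widespread", "ecicT", 23),
    ("Teucrium", "Teucrium rotundifolium", "restricted", "trot1", 25),
    ("Teucrium", "Teucrium rotundifolium", "restricted", "trot2", 25),
    ("Teucrium", "Teucrium rotundifolium", "restricted", "trot3", 25),
    ("Teucrium", "Teucrium similatum", "widespread", "tsim1", 25),
    ("Teucrium", "Teucrium similatum", "widespread", "tsim2", 25),
    ("Teucrium", "Teucrium similatum", "widespread", "tsim3", 25),
    ("Viola", "Viola cazorlensis", "restricted", "vcaz1", 25),
    ("Viola", "Viola cazorlensis", "restricted", "vcaz2", 25),
    ("Viola", "Viola cazorlensis", "restricted", "vcaz3", 25),
    ("Viola", "Viola odorata", "widespread", "vodo1", 24),
    ("Viola", "Viola odorata", "widespread", "vodo2", 25),
    ("Viola", "Viola odorata", "widespread", "vodo3", 25),
]


def design_table() -> pd.DataFrame:
    """One row per sampled population: genus, species, distribution, population, n."""
    return pd.DataFrame(
        _ROWS, columns=["genus", "species", "distribution", "population", "n"]
    )


def total_individuals() -> int:
    """Total sampled individuals across the 42 populations."""
    return int(design_table()["n"].sum())


def expected_records_per_marker() -> int:
    """Population-level records each marker type contributes to the table."""
    return len(design_table())
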