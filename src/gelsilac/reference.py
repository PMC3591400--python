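"""Bundled reference tables of significantly regulated membrane proteins.

Two curated tables of differentially expressed proteins between
ciprofloxacin-resistant and wild-type J774 macrophage membrane fractions
(one per gel fraction, light = resistant line over heavy = wild type),
with the published normalised log2(L/H) ratio, two-sided Z-statistic
p-value and sequence coverage for each protein.  The over-expressed efflux
transporter detected only in the light channel carries the "+" sentinel.
They serve as desk-scale regression fixtures for the significance filter
and the report formatter.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evidence import OneChannel, ProteinQuant, Tier

__all__ = ["load_reference_table"]

_FILES = {
    "F1": "reference_f1_significant.tsv",
    "F2": "reference_f2_significant.tsv",
}


def load_reference_frame(fraction: str) -> pd.DataFrame:
    if fraction not in _FILES:
        raise ValueError(f"unknown fraction {fraction!r}")
    with resources.files("gelsilac.data").joinpath(_FILES[fraction]).open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_reference_table(fraction: str) -> list[ProteinQuant]:
    """Reference rows as :class:`ProteinQuant` records (already normalised;
    all unambiguous tier)."""
    frame = load_reference_frame(fraction)
    quants = []
    for row in frame.itertuples(index=False):
        if row.log2_lh == "+":
            value: float | OneChannel = OneChannel.LIGHT_ONLY
        elif row.log2_lh == "-":
            value = OneChannel.HEAVY_ONLY
        else:
            value = float(row.log2_lh)
        one_channel = isinstance(value, OneChannel)
        quants.append(
            ProteinQuant(
                accession=row.accession,
                fraction=fraction,
                name=row.name,
                n_unique_peptides=3,
                tier=Tier.UNAMBIGUOUS,
                log2_lh=value,
                norm_log2=value,
                p_value=0.0 if one_channel else float(row.p_value),
                coverage=float(row.coverage),
            )
        )
    return quants
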