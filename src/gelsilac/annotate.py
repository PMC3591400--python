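"""Category summaries of identified / regulated proteins.

Instead of querying a live GO/enrichment web service (whose results are
version-dependent and not reproducible), the pipeline takes a user-supplied
annotation map — a TSV of accession, cellular-localization category,
biological-function category, one category per axis per accession — and
summarises protein lists against it as counts and display percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "LOCALIZATION_CATEGORIES",
    "FUNCTION_CATEGORIES",
    "AnnotationMap",
    "CategorySummary",
    "categorize",
]

LOCALIZATION_CATEGORIES = (
    "plasma membrane",
    "ER/Golgi",
    "ribosome",
    "mitochondrion",
    "endosome/lysosome",
    "nucleus",
    "unknown membrane",
    "cytoskeleton",
    "cytosol",
    "extracellular",
)

FUNCTION_CATEGORIES = (
    "transport",
    "protein metabolism",
    "nucleic-acid metabolism",
    "carbohydrate metabolism",
    "lipid metabolism",
    "adhesion/motility/immune",
    "structural",
    "other",
)


@dataclass(frozen=True)
class AnnotationMap:
    """accession -> (localization, function), one category per axis."""

    entries: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for acc, (loc, fun) in self.entries.items():
            if loc not in LOCALIZATION_CATEGORIES:
                raise ValueError(f"{acc}: unknown localization {loc!r}")
            if fun not in FUNCTION_CATEGORIES:
                raise ValueError(f"{acc}: unknown function {fun!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        required = {"accession", "localization", "function"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        return cls(
            {
                r.accession: (r.localization, r.function)
                for r in frame.itertuples(index=False)
            }
        )

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CategorySummary:
    """Per-axis category counts with integer display percentages."""

    localization: pd.DataFrame
    function: pd.DataFrame
    n_total: int
    n_mapped: int

    @property
    def n_unmapped(self) -> int:
        return self.n_total - self.n_mapped

    def to_tsv(self, path: str | Path) -> None:
        loc = self.localization.assign(axis="localization")
        fun = self.function.assign(axis="function")
        pd.concat([loc, fun], ignore_index=True)[
            ["axis", "category", "count", "percent"]
        ].to_csv(path, sep="\t", index=False)


def _axis_table(assignments: list[str], vocabulary: tuple[str, ...]) -> pd.DataFrame:
    counts = {cat: 0 for cat in vocabulary}
    for cat in assignments:
        counts[cat] += 1
    n_mapped = len(assignments)
    rows = [
        {
            "category": cat,
            "count": cnt,
            "percent": int(round(100.0 * cnt / n_mapped)) if n_mapped else 0,
        }
        for cat, cnt in counts.items()
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def categorize(accessions: Iterable[str], amap: AnnotationMap) -> CategorySummary:
    """Count proteins per localization and function category.

    Percentages are over mapped accessions, rounded to integers for display;
    unmapped accessions are reported separately and counts conserve:
    sum(counts) + unmapped = input size.
    """
    accs = list(dict.fromkeys(accessions))  # de-duplicate, keep order
    mapped = [acc for acc in accs if acc in amap]
    locs = [amap.entries[a][0] for a in mapped]
    funs = [amap.entries[a][1] for a in mapped]
    return CategorySummary(
        localization=_axis_table(locs, LOCALIZATION_CATEGORIES),
        function=_axis_table(funs, FUNCTION_CATEGORIES),
        n_total=len(accs),
        n_mapped=len(mapped),
    )
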