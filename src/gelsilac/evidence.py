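"""Core data types for quantified peptide evidence and their tabular I/O.

One :class:`PeptideEvidence` row is a single quantified peptide observation:
a peptide sequence attributed to one or more protein accessions, localised to
a gel band of one fraction, with an identification probability and light
(e.g. drug-resistant line) and heavy (wild-type) channel intensities.
Peptides detected in only one isotope channel — the hallmark of extreme
regulation such as a massively over-expressed efflux transporter — carry a
one-channel sentinel instead of a finite log2 ratio and are printed as "+"
(light only) or "-" (heavy only) in reports.

The on-disk format is plain UTF-8 TSV with "." as decimal separator.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .lane import GelBand, GelLane
from .sequence import DECOY_PREFIX

__all__ = [
    "OneChannel",
    "Tier",
    "PeptideEvidence",
    "ProteinQuant",
    "peptide_log_ratio",
    "read_evidence",
    "write_evidence",
    "write_report",
    "read_report",
    "report_frame",
    "EVIDENCE_COLUMNS",
]


class OneChannel(enum.Enum):
    """Sentinel for peptides/proteins detected in a single isotope channel."""

    LIGHT_ONLY = "+"   # no heavy signal: beyond-scale over-expression
    HEAVY_ONLY = "-"   # no light signal: beyond-scale under-expression

    def __str__(self) -> str:  # report rendering
        return self.value


class Tier(str, enum.Enum):
    """Evidence tier: >=3 unique peptides is unambiguous identification."""

    UNAMBIGUOUS = "unambiguous"
    LOW_EVIDENCE = "low_evidence"


def peptide_log_ratio(light: float, heavy: float) -> float | OneChannel:
    """log2(light/heavy), or a one-channel sentinel when a channel is absent.

    ``light > 0, heavy == 0`` yields ``OneChannel.LIGHT_ONLY`` (rendered "+"),
    the mirrored case yields ``HEAVY_ONLY``; both zero is rejected.
    """
    if light < 0 or heavy < 0:
        raise ValueError("intensities must be non-negative")
    if light == 0 and heavy == 0:
        raise ValueError("at least one channel must have signal")
    if heavy == 0:
        return OneChannel.LIGHT_ONLY
    if light == 0:
        return OneChannel.HEAVY_ONLY
    return math.log2(light / heavy)


@dataclass(frozen=True)
class PeptideEvidence:
    """One quantified peptide-spectrum observation."""

    peptide: str
    charge: int
    accessions: tuple[str, ...]
    band: GelBand
    probability: float
    light_intensity: float
    heavy_intensity: float

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("evidence needs at least one accession")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        if self.light_intensity < 0 or self.heavy_intensity < 0:
            raise ValueError("negative intensity")
        if self.light_intensity == 0 and self.heavy_intensity == 0:
            raise ValueError("both channels empty")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def fraction(self) -> str:
        return self.band.fraction

    @property
    def log2_ratio(self) -> float | OneChannel:
        return peptide_log_ratio(self.light_intensity, self.heavy_intensity)

    @property
    def is_one_channel(self) -> bool:
        return isinstance(self.log2_ratio, OneChannel)

    @property
    def is_decoy(self) -> bool:
        return all(a.startswith(DECOY_PREFIX) for a in self.accessions)


@dataclass
class ProteinQuant:
    """Final per-protein quantification, one report row."""

    accession: str
    fraction: str
    name: str = ""
    n_unique_peptides: int = 0
    tier: Tier = Tier.LOW_EVIDENCE
    per_band_ratios: Mapping[int, float] = field(default_factory=dict)
    log2_lh: float | OneChannel = math.nan
    n_one_channel: int = 0
    norm_log2: float | OneChannel = math.nan
    p_value: float = math.nan
    q_value: float = math.nan
    coverage: float = math.nan
    fractions_seen: tuple[str, ...] = ()

    @property
    def is_one_channel(self) -> bool:
        return isinstance(self.log2_lh, OneChannel)

    @property
    def finite_norm(self) -> float:
        """Normalised ratio as float (NaN for one-channel records)."""
        return math.nan if isinstance(self.norm_log2, OneChannel) else self.norm_log2


# ---------------------------------------------------------------------------
# Evidence TSV I/O

EVIDENCE_COLUMNS = (
    "fraction",
    "band_index",
    "section",
    "peptide",
    "charge",
    "accessions",
    "probability",
    "light_intensity",
    "heavy_intensity",
)


def _fmt_intensity(x: float) -> str:
    if x == 0:
        return ""
    return format(x, ".6g")


def read_evidence(
    path: str | Path, lanes: Mapping[str, GelLane] | None = None
) -> list[PeptideEvidence]:
    """Read a peptide-evidence TSV.

    Expected header: fraction, band_index, section, peptide, charge,
    accessions (semicolon-separated), probability, light_intensity,
    heavy_intensity (empty = channel not detected).  When ``lanes`` maps
    fraction labels to calibrated :class:`GelLane` objects, bands get their MW
    windows; otherwise bands are uncalibrated.  Malformed rows are rejected
    with their line numbers.
    """
    records: list[PeptideEvidence] = []
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(EVIDENCE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(
                f"{path}: missing column(s) {', '.join(sorted(missing))}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                fraction = row["fraction"].strip()
                index = int(row["band_index"])
                if lanes is not None and fraction in lanes:
                    band = lanes[fraction].band(index)
                else:
                    band = GelBand(fraction=fraction, index=index,
                                   section=row["section"].strip())
                light = float(row["light_intensity"] or 0.0)
                heavy = float(row["heavy_intensity"] or 0.0)
                records.append(
                    PeptideEvidence(
                        peptide=row["peptide"].strip(),
                        charge=int(row["charge"]),
                        accessions=tuple(
                            a for a in row["accessions"].split(";") if a
                        ),
                        band=band,
                        probability=float(row["probability"]),
                        light_intensity=light,
                        heavy_intensity=heavy,
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems:
        raise ValueError(
            f"{path}: {len(problems)} malformed row(s):\n" + "\n".join(problems)
        )
    return records


def write_evidence(records: Iterable[PeptideEvidence], path: str | Path) -> None:
    """Write evidence as TSV (inverse of :func:`read_evidence`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EVIDENCE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.band.fraction,
                    r.band.index,
                    r.band.section,
                    r.peptide,
                    r.charge,
                    ";".join(r.accessions),
                    format(r.probability, ".6g"),
                    _fmt_intensity(r.light_intensity),
                    _fmt_intensity(r.heavy_intensity),
                ]
            )


# ---------------------------------------------------------------------------
# Report TSV

REPORT_COLUMNS = (
    "section",
    "accession",
    "name",
    "log2_lh",
    "norm_log2",
    "p_value",
    "q_value",
    "coverage",
    "n_unique_peptides",
    "tier",
    "fractions_seen",
    "other_log2",
    "other_p",
    "other_flag",
)


def _fmt_ratio(x: float | OneChannel) -> str:
    if isinstance(x, OneChannel):
        return str(x)
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return format(x, ".2f")


def _fmt_p(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return format(x, ".3f")


def _sort_key(q: ProteinQuant):
    # one-channel records first, then by |normalised ratio| descending
    mag = math.inf if q.is_one_channel else abs(q.finite_norm)
    return (0 if q.is_one_channel else 1, -mag, q.accession)


def report_frame(
    quants: Sequence[ProteinQuant],
    other: Mapping[str, ProteinQuant] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Report table: over-expressed then lower-expressed, each sorted by
    descending |ratio| with one-channel sentinels first.

    ``other`` maps accessions to the same protein's quantification in the
    other fraction; its ratio/p are carried as cross-reference columns, with
    flag "ns" when not significant there and "ni." when not identified.
    """
    over = [q for q in quants
            if q.log2_lh is OneChannel.LIGHT_ONLY
            or (not q.is_one_channel and q.finite_norm > 0)]
    over_ids = {id(q) for q in over}
    under = [q for q in quants if id(q) not in over_ids]
    rows = []
    for section, block in (("over", over), ("under", under)):
        for q in sorted(block, key=_sort_key):
            if other is None:
                o_log2, o_p, o_flag = "", "", ""
            elif q.accession in other:
                oq = other[q.accession]
                o_log2 = _fmt_ratio(oq.norm_log2)
                o_p = _fmt_p(oq.p_value)
                significant = oq.is_one_channel or (
                    not math.isnan(oq.p_value) and oq.p_value < alpha
                )
                o_flag = "" if significant else "ns"
            else:
                o_log2, o_p, o_flag = "", "", "ni."
            rows.append(
                {
                    "section": section,
                    "accession": q.accession,
                    "name": q.name,
                    "log2_lh": _fmt_ratio(q.log2_lh),
                    "norm_log2": _fmt_ratio(q.norm_log2),
                    "p_value": _fmt_p(q.p_value),
                    "q_value": _fmt_p(q.q_value),
                    "coverage": "" if math.isnan(q.coverage)
                    else format(q.coverage, ".1f"),
                    "n_unique_peptides": q.n_unique_peptides,
                    "tier": q.tier.value,
                    "fractions_seen": ";".join(q.fractions_seen) or q.fraction,
                    "other_log2": o_log2,
                    "other_p": o_p,
                    "other_flag": o_flag,
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(
    quants: Sequence[ProteinQuant],
    path: str | Path,
    other: Mapping[str, ProteinQuant] | None = None,
    alpha: float = 0.05,
    header_comment: str | None = None,
) -> None:
    """Write the per-protein report TSV (empty input gives a header-only file).

    One-channel proteins render their ratio as "+" (or "-") and their p-value
    as "0.000"; p-values are printed with 3 decimals and coverage with 1.
    """
    frame = report_frame(quants, other=other, alpha=alpha)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a report TSV back as a string-typed table (round-trip partner of
    :func:`write_report`)."""
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
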