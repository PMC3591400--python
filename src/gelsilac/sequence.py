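"""Protein and peptide sequence utilities for SILAC GeLC-MS/MS workflows.

This module covers the sequence-level arithmetic the rest of the pipeline
relies on: in-silico tryptic digestion (Keil rule: cleave C-terminal to K/R
unless followed by P), monoisotopic peptide masses with SILAC (13C6 Lys/Arg,
+6.020129 Da per labelled residue) and propionamide (+71.037114 Da per Cys)
modifications, shuffled-decoy database construction, and sequence-coverage
computation for report tables.

Monoisotopic residue masses and the water/proton constants come from
pyteomics; everything built on top of them is implemented here.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mass as _pymass

__all__ = [
    "CANONICAL_RESIDUES",
    "DECOY_PREFIX",
    "LABEL_SHIFT_DA",
    "PROPIONAMIDE_DA",
    "MassConstants",
    "ProteinEntry",
    "Peptide",
    "protein_mass_kda",
    "tryptic_digest",
    "peptide_mass",
    "precursor_mz",
    "shuffle_decoy",
    "coverage_percent",
    "read_fasta",
    "write_fasta",
    "build_decoy_database",
]

#: The 20 canonical amino acids.  I and L are distinct; B/Z/X/U are rejected.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Accession prefix reserved for shuffled decoy entries.
DECOY_PREFIX = "DECOY_"

#: SILAC 13C6 label shift per K or R residue (6 x (13C - 12C)), in Da.
LABEL_SHIFT_DA = 6.020129

#: Propionamide (acrylamide adduct) on cysteine, in Da.
PROPIONAMIDE_DA = 71.037114

WATER_DA = _pymass.calculate_mass(formula="H2O")
PROTON_DA = 1.00727646677

#: Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES: Mapping[str, float] = {
    aa: _pymass.std_aa_mass[aa] for aa in sorted(CANONICAL_RESIDUES)
}


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty amino-acid sequence")
    for ch in sequence:
        if ch not in CANONICAL_RESIDUES:
            raise ValueError(
                f"non-canonical residue {ch!r} in sequence (only the 20 "
                "canonical one-letter codes are accepted)"
            )


@dataclass(frozen=True)
class MassConstants:
    """Bundle of monoisotopic mass constants used throughout the package."""

    label_shift_da: float = LABEL_SHIFT_DA
    propionamide_da: float = PROPIONAMIDE_DA
    proton_da: float = PROTON_DA
    water_da: float = WATER_DA
    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(RESIDUE_MASSES)
    )


DEFAULT_CONSTANTS = MassConstants()


def protein_mass_kda(
    sequence: str, constants: MassConstants = DEFAULT_CONSTANTS
) -> float:
    """Monoisotopic mass of an unmodified protein chain, in kDa."""
    _validate_sequence(sequence)
    da = sum(constants.residue_masses[aa] for aa in sequence) + constants.water_da
    return da / 1000.0


@dataclass(frozen=True)
class ProteinEntry:
    """One database protein (target or shuffled decoy).

    ``mw_kda`` is the monoisotopic mass of the full chain; when omitted it is
    computed from the sequence, and when supplied it must agree with the
    computed value to 1e-6 kDa.
    """

    accession: str
    sequence: str
    description: str = ""
    is_decoy: bool = False
    mw_kda: float | None = None

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        computed = protein_mass_kda(self.sequence)
        if self.mw_kda is None:
            object.__setattr__(self, "mw_kda", computed)
        elif abs(self.mw_kda - computed) > 1e-6:
            raise ValueError(
                f"mw_kda={self.mw_kda!r} disagrees with computed chain mass "
                f"{computed!r} for {self.accession}"
            )
        if self.is_decoy and not self.accession.startswith(DECOY_PREFIX):
            raise ValueError(
                f"decoy entry {self.accession!r} lacks the {DECOY_PREFIX!r} prefix"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Peptide:
    """A (possibly modified) tryptic peptide.

    ``mods`` is a tuple of ``(position, mass_delta_da)`` pairs with 0-based
    residue positions.  ``n_labeled_sites`` counts K plus R residues, i.e. the
    number of SILAC label incorporations in the heavy channel.
    """

    sequence: str
    missed_cleavages: int = 0
    mods: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        for pos, _delta in self.mods:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"modification position {pos} outside peptide")

    @property
    def n_labeled_sites(self) -> int:
        return sum(1 for aa in self.sequence if aa in "KR")

    def with_propionamide(self) -> "Peptide":
        """Return a copy carrying propionamide on every cysteine."""
        mods = tuple(
            (i, PROPIONAMIDE_DA) for i, aa in enumerate(self.sequence) if aa == "C"
        )
        return Peptide(self.sequence, self.missed_cleavages, self.mods + mods)


def _cleavage_boundaries(sequence: str) -> list[int]:
    """Positions after which trypsin cleaves (Keil rule), plus the C terminus."""
    cuts = []
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == n or sequence[i + 1] != "P"):
            cuts.append(i + 1)
    if not cuts or cuts[-1] != n:
        cuts.append(n)
    return cuts


def tryptic_digest(
    protein: ProteinEntry | str,
    max_missed: int = 2,
    min_length: int | None = None,
    max_length: int | None = None,
) -> list[Peptide]:
    """In-silico tryptic digestion with up to ``max_missed`` missed cleavages.

    Cleaves C-terminal to K or R except when the next residue is P.  Returns
    peptides in N-to-C order (by start position, then increasing length); each
    carries its internal missed-cleavage count.  Optional length bounds filter
    the output (both inclusive); by default nothing is filtered.
    """
    sequence = protein.sequence if isinstance(protein, ProteinEntry) else protein
    _validate_sequence(sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0] + _cleavage_boundaries(sequence)
    peptides: list[Peptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 1 + max_missed + 1, len(bounds))):
            frag = sequence[bounds[i] : bounds[j]]
            if min_length is not None and len(frag) < min_length:
                continue
            if max_length is not None and len(frag) > max_length:
                continue
            peptides.append(Peptide(frag, missed_cleavages=j - i - 1))
    return peptides


def peptide_mass(
    peptide: Peptide | str,
    heavy: bool = False,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """Monoisotopic peptide mass in Da.

    Sum of residue masses plus water plus modification deltas; in the heavy
    channel each K/R adds the SILAC label shift.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    m = sum(constants.residue_masses[aa] for aa in peptide.sequence)
    m += constants.water_da
    m += sum(delta for _pos, delta in peptide.mods)
    if heavy:
        m += peptide.n_labeled_sites * constants.label_shift_da
    return m


def precursor_mz(
    mass_da: float, charge: int, constants: MassConstants = DEFAULT_CONSTANTS
) -> float:
    """m/z of a precursor ion: (M + z*proton) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass_da + charge * constants.proton_da) / charge


def shuffle_decoy(
    protein: ProteinEntry, seed: int, preserve_kr: bool = False
) -> ProteinEntry:
    """Shuffled decoy of a target entry (Fisher-Yates permutation).

    Length and amino-acid composition are preserved; the result carries the
    reserved decoy prefix.  ``preserve_kr=True`` keeps every K/R at its
    original position (preserving the tryptic cleavage pattern) and permutes
    only the remaining residues.  Deterministic for a fixed seed.
    """
    if protein.is_decoy:
        raise ValueError(f"{protein.accession} is already a decoy")
    rng = random.Random(seed)
    residues = list(protein.sequence)
    if preserve_kr:
        idx = [i for i, aa in enumerate(residues) if aa not in "KR"]
        sub = [residues[i] for i in idx]
        rng.shuffle(sub)
        for i, aa in zip(idx, sub):
            residues[i] = aa
    else:
        rng.shuffle(residues)
    return ProteinEntry(
        accession=DECOY_PREFIX + protein.accession,
        sequence="".join(residues),
        description=f"shuffled decoy of {protein.accession}",
        is_decoy=True,
    )


def coverage_percent(
    protein: ProteinEntry, peptides: Iterable[Peptide | str]
) -> float:
    """Sequence coverage: percent of residues covered by >= 1 peptide.

    Overlapping peptides count residues once.  Every occurrence of each
    peptide in the protein is marked.  Reported to one decimal, matching the
    usual report convention.
    """
    covered = [False] * len(protein.sequence)
    for pep in peptides:
        seq = pep.sequence if isinstance(pep, Peptide) else pep
        start = protein.sequence.find(seq)
        if start < 0:
            raise ValueError(
                f"peptide {seq!r} does not occur in protein {protein.accession}"
            )
        while start >= 0:
            for k in range(start, start + len(seq)):
                covered[k] = True
            start = protein.sequence.find(seq, start + 1)
    return round(100.0 * sum(covered) / len(covered), 1)


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein FASTA; entries prefixed ``DECOY_`` are flagged as decoys."""
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        entries.append(
            ProteinEntry(
                accession=record.id,
                sequence=seq,
                description=record.description[len(record.id) :].strip(),
                is_decoy=record.id.startswith(DECOY_PREFIX),
            )
        )
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.accession, description=e.description)
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def build_decoy_database(
    targets: Sequence[ProteinEntry], seed: int, preserve_kr: bool = False
) -> list[ProteinEntry]:
    """Concatenated target-decoy database: targets followed by one shuffled
    decoy per target.  Decoy ``i`` is shuffled under ``seed + i`` so the whole
    database is reproducible from one seed."""
    decoys = [
        shuffle_decoy(p, seed=seed + i, preserve_kr=preserve_kr)
        for i, p in enumerate(targets)
    ]
    return list(targets) + decoys
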