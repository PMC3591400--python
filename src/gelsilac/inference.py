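"""Protein inference: peptide filtering, gel-band grouping, tiers, decoy FDR.

Identifications of the same accession recur in multiple, often adjacent gel
bands; they are pooled into one :class:`ProteinGroup` per accession.  An
accession whose peptide set is a strict subset of (or identical to) another
accession's set carries no independent evidence and is merged into that group
(parsimony).  Peptide sequences shared between surviving groups count for
identification of each but are flagged non-unique: they are excluded from the
unique-peptide count that sets the evidence tier and from quantification.

The protein probability of a group is the maximum identification probability
over its retained peptides — a deliberate proxy for an upstream
protein-inference engine's posterior, which is a pipeline input, not
something this package models.  Groups below the probability threshold
(default >= 0.95) are dropped.  Decoy groups estimate the false discovery
rate as #decoys / #targets within an evidence tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .evidence import PeptideEvidence, Tier
from .sequence import DECOY_PREFIX

__all__ = [
    "ProteinGroup",
    "filter_peptides",
    "group_proteins",
    "decoy_fdr",
    "merge_fractions",
]

logger = logging.getLogger(__name__)


@dataclass
class ProteinGroup:
    """Grouped redundant identifications of one accession across gel bands."""

    accession: str
    members: tuple[str, ...]
    evidence: tuple[PeptideEvidence, ...]
    unique_peptide_sequences: frozenset[str]
    bands_seen: tuple[int, ...]
    n_unique_peptides: int
    tier: Tier
    protein_probability: float
    fraction: str

    @property
    def is_decoy(self) -> bool:
        return self.accession.startswith(DECOY_PREFIX)

    @property
    def peptide_sequences(self) -> frozenset[str]:
        return frozenset(e.peptide for e in self.evidence)


def filter_peptides(
    evidence: Iterable[PeptideEvidence], p_min: float = 0.70
) -> list[PeptideEvidence]:
    """Retain peptide evidence with identification probability >= ``p_min``
    (records strictly below the threshold are the ones removed)."""
    if not 0.0 <= p_min <= 1.0:
        raise ValueError("p_min must be in [0, 1]")
    evidence = list(evidence)
    kept = [e for e in evidence if e.probability >= p_min]
    logger.info(
        "peptide filter p>=%.2f: kept %d / %d", p_min, len(kept), len(evidence)
    )
    return kept


def group_proteins(
    evidence: Iterable[PeptideEvidence],
    prob_min: float = 0.95,
    min_unique_for_unambiguous: int = 3,
) -> list[ProteinGroup]:
    """Group filtered evidence into one protein group per accession.

    Pools all bands per accession, merges peptide-set-subsumed accessions
    (parsimony), drops groups whose protein probability (max retained peptide
    probability) is below ``prob_min``, and assigns the evidence tier from the
    count of distinct peptide sequences unique to the group (charge or
    modification variants of one sequence count once).
    """
    evidence = list(evidence)
    peptides_of: dict[str, set[str]] = {}
    rows_of: dict[str, list[PeptideEvidence]] = {}
    for e in evidence:
        for acc in e.accessions:
            peptides_of.setdefault(acc, set()).add(e.peptide)
            rows_of.setdefault(acc, []).append(e)

    # parsimony: largest peptide sets first; subset (or equal) sets merge in
    order = sorted(peptides_of, key=lambda a: (-len(peptides_of[a]), a))
    reps: list[str] = []
    members_of: dict[str, list[str]] = {}
    for acc in order:
        target = next(
            (r for r in reps if peptides_of[acc] <= peptides_of[r]), None
        )
        if target is None:
            reps.append(acc)
            members_of[acc] = [acc]
        else:
            members_of[target].append(acc)

    # peptide sequences claimed by more than one surviving group are degenerate
    claims: dict[str, int] = {}
    for rep in reps:
        for seq in peptides_of[rep]:
            claims[seq] = claims.get(seq, 0) + 1

    groups: list[ProteinGroup] = []
    for rep in reps:
        rows = []
        seen = set()
        for acc in members_of[rep]:
            for e in rows_of[acc]:
                if id(e) not in seen:
                    seen.add(id(e))
                    rows.append(e)
        unique_seqs = frozenset(
            s for s in peptides_of[rep] if claims[s] == 1
        )
        if not unique_seqs:
            logger.info("dropping %s: no peptide unique to the group", rep)
            continue
        prob = max(e.probability for e in rows)
        if prob < prob_min:
            continue
        fractions = {e.fraction for e in rows}
        if len(fractions) != 1:
            raise ValueError(
                f"group {rep} mixes fractions {sorted(fractions)}; group each "
                "fraction's evidence separately"
            )
        n_unique = len(unique_seqs)
        groups.append(
            ProteinGroup(
                accession=rep,
                members=tuple(sorted(members_of[rep])),
                evidence=tuple(rows),
                unique_peptide_sequences=unique_seqs,
                bands_seen=tuple(sorted({e.band.index for e in rows})),
                n_unique_peptides=n_unique,
                tier=(
                    Tier.UNAMBIGUOUS
                    if n_unique >= min_unique_for_unambiguous
                    else Tier.LOW_EVIDENCE
                ),
                protein_probability=prob,
                fraction=fractions.pop(),
            )
        )
    groups.sort(key=lambda g: g.accession)
    return groups


def decoy_fdr(
    groups: Sequence[ProteinGroup], tier: Tier | None = None
) -> float:
    """Target-decoy FDR estimate, in percent: 100 * #decoys / #targets,
    optionally restricted to one evidence tier."""
    if tier is not None:
        groups = [g for g in groups if g.tier == tier]
    n_decoy = sum(1 for g in groups if g.is_decoy)
    n_target = sum(1 for g in groups if not g.is_decoy)
    if n_target == 0:
        raise ValueError("FDR undefined: no target groups in the selection")
    return 100.0 * n_decoy / n_target


def _accessions(items: Iterable) -> list[str]:
    out = []
    for it in items:
        out.append(it.accession if hasattr(it, "accession") else str(it))
    if len(set(out)) != len(out):
        raise ValueError("input list contains duplicate accessions")
    return out


def merge_fractions(groups_f1: Iterable, groups_f2: Iterable) -> pd.DataFrame:
    """Cross-fraction union keyed by accession.

    Accepts protein groups, quantifications, or bare accession strings.
    Returns a table with boolean presence columns and a ``presence`` label
    (``F1-only`` / ``F2-only`` / ``both``); its length obeys
    |A ∪ B| = |A| + |B| − |A ∩ B|.
    """
    a = set(_accessions(groups_f1))
    b = set(_accessions(groups_f2))
    rows = [
        {
            "accession": acc,
            "in_f1": acc in a,
            "in_f2": acc in b,
            "presence": (
                "both" if acc in a and acc in b
                else "F1-only" if acc in a else "F2-only"
            ),
        }
        for acc in sorted(a | b)
    ]
    return pd.DataFrame(rows, columns=["accession", "in_f1", "in_f2", "presence"])
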