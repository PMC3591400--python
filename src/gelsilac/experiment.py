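"""Top-level model/results surface for a GeLC-SILAC experiment.

:class:`SilacExperiment` is built from per-fraction peptide evidence (read
from TSV, simulated, or passed in memory) plus a :class:`PipelineConfig`;
``fit()`` runs the whole analysis — peptide probability filter, gel-band
protein grouping with parsimony, tier assignment and decoy FDR, band-wise
ratio aggregation, median normalisation and Z-statistic significance — and
returns a :class:`SilacResults` carrying the per-protein estimates, the
fitted null distributions, significance calls, cross-fraction union and a
``summary()`` table.

    >>> exp = SilacExperiment.simulate(PipelineConfig(seed=7))
    >>> res = exp.fit()
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .evidence import (
    PeptideEvidence,
    ProteinQuant,
    Tier,
    read_evidence,
    write_report,
)
from .inference import (
    ProteinGroup,
    decoy_fdr,
    filter_peptides,
    group_proteins,
    merge_fractions,
)
from .lane import GelLane
from .quantify import band_ratios, protein_ratio
from .sequence import ProteinEntry, coverage_percent
from .significance import RatioDistribution, apply_significance, significant_set
from .simulate import generate_truth, simulate_evidence

__all__ = ["SilacExperiment", "SilacResults"]


def _lanes_from_config(config: PipelineConfig) -> dict[str, GelLane]:
    return {
        "F1": GelLane.log_linear(
            "F1", config.lane_f1_bands, config.lane_mw_top_kda,
            config.lane_mw_bottom_kda, n_sections=11,
        ),
        "F2": GelLane.log_linear(
            "F2", config.lane_f2_bands, config.lane_mw_top_kda,
            config.lane_mw_bottom_kda, n_sections=10,
        ),
    }


class SilacExperiment:
    """A two-channel gel-fractionated SILAC experiment ready to analyse."""

    def __init__(
        self,
        evidence: Mapping[str, Sequence[PeptideEvidence]],
        config: PipelineConfig | None = None,
        lanes: Mapping[str, GelLane] | None = None,
        proteins: Mapping[str, ProteinEntry] | None = None,
        truths: Mapping[str, object] | None = None,
    ) -> None:
        if not evidence:
            raise ValueError("no evidence supplied")
        self.config = config or PipelineConfig()
        self.evidence = {f: list(rows) for f, rows in evidence.items()}
        self.lanes = dict(lanes) if lanes else _lanes_from_config(self.config)
        self.proteins = dict(proteins) if proteins else {}
        self.truths = dict(truths) if truths else {}

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        evidence_paths: Mapping[str, str | Path],
        config: PipelineConfig | None = None,
        fasta: Mapping[str, ProteinEntry] | None = None,
    ) -> "SilacExperiment":
        config = config or PipelineConfig()
        lanes = _lanes_from_config(config)
        evidence = {
            fraction: read_evidence(path, lanes=lanes)
            for fraction, path in evidence_paths.items()
        }
        return cls(evidence, config=config, lanes=lanes, proteins=fasta)

    @classmethod
    def simulate(cls, config: PipelineConfig | None = None) -> "SilacExperiment":
        """Ground-truthed synthetic two-fraction experiment from the config's
        simulation block (fraction seeds derived from ``config.seed``)."""
        config = config or PipelineConfig()
        lanes = _lanes_from_config(config)
        evidence: dict[str, list[PeptideEvidence]] = {}
        truths = {}
        for k, fraction in enumerate(("F1", "F2")):
            seed = (config.seed + 1000 * k) % 2**31
            truth = generate_truth(
                n_proteins=config.sim_n_proteins,
                frac_regulated=config.sim_frac_regulated,
                effect_size_range_log2=(
                    config.sim_effect_min_log2, config.sim_effect_max_log2,
                ),
                noise_sd=config.sim_noise_sd,
                mixing_offset=config.sim_mixing_offset,
                decoy_fraction=config.sim_decoy_fraction,
                n_one_channel=config.sim_n_one_channel,
                extreme_threshold=config.sim_extreme_threshold,
                peptides_per_protein_mean=config.sim_peptides_per_protein,
                seed=seed,
            )
            evidence[fraction] = simulate_evidence(
                truth,
                lanes[fraction],
                spillover=config.sim_spillover,
                seed=(seed + 1) % 2**31,
            )
            truths[fraction] = truth
        return cls(evidence, config=config, lanes=lanes, truths=truths)

    # -- analysis -----------------------------------------------------------

    def fit(self) -> "SilacResults":
        cfg = self.config
        quants: dict[str, list[ProteinQuant]] = {}
        groups: dict[str, list[ProteinGroup]] = {}
        distributions: dict[str, RatioDistribution] = {}
        fdr: dict[str, dict[str, float | None]] = {}
        counts: dict[str, dict[str, int]] = {}

        for fraction, rows in self.evidence.items():
            filtered = filter_peptides(rows, cfg.peptide_p_min)
            all_groups = group_proteins(
                filtered, cfg.protein_p_min, cfg.min_unique_peptides
            )
            targets = [g for g in all_groups if not g.is_decoy]
            has_decoys = any(g.is_decoy for g in all_groups)
            fdr[fraction] = {
                tier.value: (
                    _safe_fdr(all_groups, tier) if has_decoys else None
                )
                for tier in Tier
            }
            frac_quants = [self._quantify(g) for g in targets]
            distributions[fraction] = apply_significance(
                frac_quants,
                fraction=fraction,
                scale_estimator=cfg.scale_estimator,
                fit_tier=Tier.UNAMBIGUOUS,
            )
            quants[fraction] = frac_quants
            groups[fraction] = all_groups
            counts[fraction] = {
                "evidence_in": len(rows),
                "evidence_filtered": len(filtered),
                "groups": len(all_groups),
                "targets_retained": len(targets),
                "quantified": sum(
                    1
                    for q in frac_quants
                    if q.is_one_channel or not math.isnan(q.log2_lh)
                ),
            }

        merged = None
        if len(quants) >= 2:
            fractions = sorted(quants)
            merged = merge_fractions(quants[fractions[0]], quants[fractions[1]])
            seen = {
                acc: tuple(
                    f
                    for f, flag in zip(fractions, (row.in_f1, row.in_f2))
                    if flag
                )
                for acc, row in zip(merged["accession"],
                                    merged.itertuples(index=False))
            }
            for frac_quants in quants.values():
                for q in frac_quants:
                    q.fractions_seen = seen.get(q.accession, (q.fraction,))
        else:
            for frac_quants in quants.values():
                for q in frac_quants:
                    q.fractions_seen = (q.fraction,)

        return SilacResults(
            experiment=self,
            quants=quants,
            groups=groups,
            distributions=distributions,
            fdr=fdr,
            merged=merged,
            counts=counts,
        )

    def _quantify(self, group: ProteinGroup) -> ProteinQuant:
        cfg = self.config
        bands = band_ratios(group, outlier_mad_limit=cfg.outlier_mad_limit)
        value = protein_ratio(bands, mode=cfg.averaging_mode)
        coverage = math.nan
        if group.accession in self.proteins:
            try:
                coverage = coverage_percent(
                    self.proteins[group.accession],
                    sorted(group.peptide_sequences),
                )
            except ValueError:
                coverage = math.nan
        return ProteinQuant(
            accession=group.accession,
            fraction=group.fraction,
            n_unique_peptides=group.n_unique_peptides,
            tier=group.tier,
            per_band_ratios={
                b.band_index: b.mean_log2 for b in bands if b.has_finite
            },
            log2_lh=value,
            n_one_channel=sum(b.n_one_channel for b in bands),
            coverage=coverage,
        )


def _safe_fdr(groups, tier):
    try:
        return decoy_fdr(groups, tier)
    except ValueError:
        return None


@dataclass
class SilacResults:
    """Fitted experiment: per-protein estimates, null fits, calls, union."""

    experiment: SilacExperiment
    quants: dict[str, list[ProteinQuant]]
    groups: dict[str, list[ProteinGroup]]
    distributions: dict[str, RatioDistribution]
    fdr: dict[str, dict[str, float | None]]
    merged: pd.DataFrame | None
    counts: dict[str, dict[str, int]]

    def significant(
        self, fraction: str, alpha: float | None = None,
        require_tier: Tier | None = Tier.UNAMBIGUOUS,
    ) -> list[ProteinQuant]:
        alpha = self.experiment.config.alpha if alpha is None else alpha
        return significant_set(self.quants[fraction], alpha, require_tier)

    def quant_index(self, fraction: str) -> dict[str, ProteinQuant]:
        return {q.accession: q for q in self.quants[fraction]}

    def ratio_histogram(
        self, fraction: str, bins: int = 25,
        tier: Tier | None = Tier.UNAMBIGUOUS,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Binned counts of normalised log2 ratios (the Gaussian-shaped
        distribution expected for a 1:1 mixture)."""
        values = np.array([
            q.finite_norm
            for q in self.quants[fraction]
            if (tier is None or q.tier == tier) and not q.is_one_channel
        ])
        values = values[np.isfinite(values)]
        return np.histogram(values, bins=bins)

    def plot_ratio_histogram(self, fraction: str, bins: int = 25, ax=None):
        """Histogram of normalised ratios with the fitted Gaussian overlay
        (requires matplotlib)."""
        import matplotlib.pyplot as plt
        from scipy import stats as _st

        if ax is None:
            _fig, ax = plt.subplots()
        counts, edges = self.ratio_histogram(fraction, bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        width = edges[1] - edges[0]
        ax.bar(centers, counts, width=width * 0.9, color="0.6")
        d = self.distributions[fraction]
        x = np.linspace(edges[0], edges[-1], 200)
        ax.plot(x, counts.sum() * width * _st.norm.pdf(x, 0.0, d.sigma), "k-")
        ax.set_xlabel("normalised log2(L/H)")
        ax.set_ylabel("proteins")
        ax.set_title(f"{fraction}: median 0, sigma {d.sigma:.2f}")
        return ax

    def summary(self, alpha: float | None = None) -> str:
        alpha = self.experiment.config.alpha if alpha is None else alpha
        lines = ["GeLC-SILAC experiment summary", "=" * 30]
        for fraction in sorted(self.quants):
            c = self.counts[fraction]
            d = self.distributions[fraction]
            sig = self.significant(fraction, alpha)
            unamb = sum(
                1 for q in self.quants[fraction] if q.tier == Tier.UNAMBIGUOUS
            )
            lines += [
                f"[{fraction}] evidence {c['evidence_in']} -> filtered "
                f"{c['evidence_filtered']} -> protein groups "
                f"{c['targets_retained']} (unambiguous {unamb})",
                f"[{fraction}] ratio distribution: median {d.median:+.3f} "
                f"(removed), sigma {d.sigma:.3f} ({d.estimator})",
                f"[{fraction}] significant at p < {alpha:g}: {len(sig)}",
            ]
            for tier_name, value in self.fdr[fraction].items():
                if value is not None:
                    lines.append(
                        f"[{fraction}] decoy FDR ({tier_name}): {value:.1f}%"
                    )
        if self.merged is not None:
            both = int((self.merged["in_f1"] & self.merged["in_f2"]).sum())
            lines.append(
                f"[union] {len(self.merged)} unique proteins "
                f"({both} present in both fractions)"
            )
        return "\n".join(lines)

    def write_reports(self, outdir: str | Path, alpha: float | None = None
                      ) -> list[Path]:
        """Per-fraction report TSVs (with cross-fraction columns), the
        cross-fraction union table and per-fraction histogram tables."""
        alpha = self.experiment.config.alpha if alpha is None else alpha
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        fractions = sorted(self.quants)
        for fraction in fractions:
            other = None
            if len(fractions) == 2:
                other_frac = fractions[1 - fractions.index(fraction)]
                other = self.quant_index(other_frac)
            d = self.distributions[fraction]
            path = outdir / f"report_{fraction}.tsv"
            write_report(
                self.quants[fraction],
                path,
                other=other,
                alpha=alpha,
                header_comment=(
                    f"fraction {fraction}; ratio orientation "
                    f"{self.experiment.config.ratio_orientation}; median "
                    f"{d.median:+.4f} removed; sigma {d.sigma:.4f} "
                    f"({d.estimator})"
                ),
            )
            written.append(path)
            counts, edges = self.ratio_histogram(fraction)
            hist = pd.DataFrame(
                {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
            )
            hpath = outdir / f"histogram_{fraction}.tsv"
            hist.to_csv(hpath, sep="\t", index=False)
            written.append(hpath)
        if self.merged is not None:
            mpath = outdir / "union.tsv"
            self.merged.to_csv(mpath, sep="\t", index=False)
            written.append(mpath)
        return written
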