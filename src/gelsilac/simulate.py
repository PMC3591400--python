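"""Ground-truthed synthetic GeLC-SILAC experiments.

The generator emulates the statistical structure the downstream analysis
assumes for a two-fraction (F1/F2) gel-based SILAC experiment:

* a proteome in which most proteins are unregulated (true log2 L/H = 0) and a
  small minority is regulated, with effect magnitudes drawn uniformly from a
  configurable range (default |log2| in [0.8, 4.5], the scale seen for
  significantly regulated membrane proteins);
* optionally one or more "efflux-transporter-like" extreme proteins whose true
  ratio exceeds the one-channel threshold, so their heavy channel drops out
  for essentially every peptide and they are reported with the "+" sentinel;
* peptides produced by in-silico tryptic digestion of a random sequence with
  the protein's molecular weight, landing in the MW-matched gel band with
  configurable spill-over into the two adjacent bands;
* multiplicative lognormal ratio noise: peptide log2 ratio = true ratio +
  mixing offset + Normal(0, noise_sd).  The global mixing offset models
  imperfect 1:1 pooling of the light and heavy lysates and is removed later by
  median normalisation;
* two-population identification scores: target peptides score high
  (Beta(20,2) by default); decoy peptides score low (Beta(2,8)) apart from a
  small contaminating fraction of false high-confidence matches drawn from
  the target component — precisely the events a target-decoy FDR counts;
* decoy proteins that produce decoy-only evidence (Poisson "random match"
  peptide counts, ratio noise around 0) and never share accessions with
  targets.

Everything is bit-reproducible from the seeds passed in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evidence import PeptideEvidence
from .lane import GelLane, default_lane
from .sequence import DECOY_PREFIX, tryptic_digest

__all__ = [
    "ProbModel",
    "SimTruth",
    "generate_truth",
    "simulate_evidence",
    "simulate_null_experiment",
    "simulate_proteoform",
]

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
#: mean residue mass in Da used to size random sequences to a target MW
_MEAN_RESIDUE_DA = 111.1


@dataclass(frozen=True)
class ProbModel:
    """Two-population identification-probability model.

    Target peptides draw from ``Beta(*target_beta)``.  Decoy peptides draw
    from ``Beta(*decoy_beta)`` except with probability ``decoy_high_weight``
    they draw from the target component (a false high-confidence match).
    """

    target_beta: tuple[float, float] = (20.0, 2.0)
    decoy_beta: tuple[float, float] = (2.0, 8.0)
    decoy_high_weight: float = 0.05


@dataclass
class SimTruth:
    """Ground truth for one simulated fraction.

    ``proteins`` has one row per database entry with columns: accession,
    mw_kda, true_log2_ratio (NaN for decoys), regulated, one_channel,
    n_peptides_expected, is_decoy.
    """

    proteins: pd.DataFrame
    noise_sd: float
    mixing_offset: float
    decoy_fraction: float
    extreme_threshold: float
    seed: int

    @property
    def targets(self) -> pd.DataFrame:
        return self.proteins[~self.proteins["is_decoy"]]

    @property
    def decoys(self) -> pd.DataFrame:
        return self.proteins[self.proteins["is_decoy"]]

    def to_tsv(self, path) -> None:
        self.proteins.to_csv(path, sep="\t", index=False)


def generate_truth(
    n_proteins: int = 500,
    frac_regulated: float = 0.1,
    effect_size_range_log2: tuple[float, float] = (0.8, 4.5),
    noise_sd: float = 0.3,
    mixing_offset: float = 0.1,
    decoy_fraction: float = 0.5,
    n_one_channel: int = 1,
    extreme_threshold: float = 5.0,
    peptides_per_protein_mean: float = 6.0,
    mw_range_kda: tuple[float, float] = (10.0, 250.0),
    seed: int = 0,
) -> SimTruth:
    """Draw a ground-truth protein table.

    ``frac_regulated`` of the targets get a nonzero true log2 ratio with
    magnitude uniform in ``effect_size_range_log2`` and random sign; the first
    ``n_one_channel`` regulated proteins instead get an extreme positive ratio
    (``extreme_threshold`` + 1) so that their heavy channel will drop out.
    Protein MWs are log-uniform on ``mw_range_kda``.  ``decoy_fraction`` is
    the decoys-per-target ratio of the concatenated database.
    """
    if not 0.0 <= frac_regulated <= 1.0:
        raise ValueError("frac_regulated must be in [0, 1]")
    if not 0.0 <= decoy_fraction:
        raise ValueError("decoy_fraction must be >= 0")
    lo, hi = effect_size_range_log2
    if not 0 < lo <= hi:
        raise ValueError("effect_size_range_log2 must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)

    n_reg = int(round(n_proteins * frac_regulated))
    n_one_channel = min(n_one_channel, n_reg) if n_reg else 0
    ratios = np.zeros(n_proteins)
    regulated = np.zeros(n_proteins, dtype=bool)
    one_channel = np.zeros(n_proteins, dtype=bool)
    reg_idx = rng.choice(n_proteins, size=n_reg, replace=False)
    regulated[reg_idx] = True
    magnitudes = rng.uniform(lo, hi, size=n_reg)
    signs = rng.choice([-1.0, 1.0], size=n_reg)
    ratios[reg_idx] = signs * magnitudes
    extreme = reg_idx[:n_one_channel]
    ratios[extreme] = extreme_threshold + 1.0
    one_channel[extreme] = True

    log_lo, log_hi = math.log(mw_range_kda[0]), math.log(mw_range_kda[1])
    mws = np.exp(rng.uniform(log_lo, log_hi, size=n_proteins))

    n_decoys = int(round(n_proteins * decoy_fraction))
    decoy_mws = np.exp(rng.uniform(log_lo, log_hi, size=n_decoys))

    width = len(str(max(n_proteins + n_decoys, 1)))
    frames = [
        pd.DataFrame(
            {
                "accession": [f"SIM{i:0{width}d}" for i in range(n_proteins)],
                "mw_kda": mws,
                "true_log2_ratio": ratios,
                "regulated": regulated,
                "one_channel": one_channel,
                "n_peptides_expected": peptides_per_protein_mean,
                "is_decoy": False,
            }
        )
    ]
    if n_decoys:
        frames.append(
            pd.DataFrame(
                {
                    "accession": [
                        f"{DECOY_PREFIX}SIM{i:0{width}d}" for i in range(n_decoys)
                    ],
                    "mw_kda": decoy_mws,
                    "true_log2_ratio": np.nan,
                    "regulated": False,
                    "one_channel": False,
                    "n_peptides_expected": peptides_per_protein_mean,
                    "is_decoy": True,
                }
            )
        )
    proteins = pd.concat(frames, ignore_index=True)
    return SimTruth(
        proteins=proteins,
        noise_sd=noise_sd,
        mixing_offset=mixing_offset,
        decoy_fraction=decoy_fraction,
        extreme_threshold=extreme_threshold,
        seed=seed,
    )


def _random_sequence(rng: np.random.Generator, mw_kda: float) -> str:
    length = max(30, int(round(mw_kda * 1000.0 / _MEAN_RESIDUE_DA)))
    return "".join(rng.choice(_ALPHABET, size=length))


def _peptide_pool(
    rng: np.random.Generator, mw_kda: float, min_len: int = 6, max_len: int = 40
) -> list[str]:
    """Distinct tryptic peptides (<=2 missed cleavages, length-bounded) of a
    random protein sequence sized to the requested MW."""
    seq = _random_sequence(rng, mw_kda)
    peptides = tryptic_digest(seq, max_missed=2, min_length=min_len,
                              max_length=max_len)
    return sorted({p.sequence for p in peptides})


def _spill_band(
    rng: np.random.Generator, lane: GelLane, home_index: int, spillover: float
) -> int:
    u = rng.random()
    if u < spillover / 2:
        return max(1, home_index - 1)
    if u < spillover:
        return min(lane.n_bands, home_index + 1)
    return home_index


def simulate_evidence(
    truth: SimTruth,
    lane: GelLane,
    peptides_per_protein_mean: float | None = None,
    prob_params: ProbModel = ProbModel(),
    spillover: float = 0.2,
    decoy_peptides_mean: float = 1.0,
    fixed_peptide_count: bool = False,
    intensity_log_mean: float = math.log(1.0e6),
    intensity_log_sd: float = 0.5,
    seed: int = 0,
) -> list[PeptideEvidence]:
    """Simulate the peptide-evidence table of one fraction.

    Per target protein the peptide count is Poisson (or exactly the rounded
    mean when ``fixed_peptide_count`` — the calibration condition with known
    homogeneous protein-level sd); distinct peptide sequences are sampled from
    the in-silico digest of a random protein of matching MW.  Each peptide
    lands in the MW-matched band (probability ``spillover`` split evenly
    between the two adjacent bands), its log2 ratio is
    truth + mixing_offset + N(0, noise_sd), and its heavy (resp. light)
    channel is dropped when the sampled ratio is >= (resp. <=) the extreme
    threshold.  Decoy proteins emit decoy-only evidence with random-match
    peptide counts and the two-population score model.
    """
    if lane is None or lane.n_bands == 0:
        raise ValueError("a calibrated, non-empty lane is required")
    if not 0.0 <= spillover < 1.0:
        raise ValueError("spillover must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[PeptideEvidence] = []
    thr = truth.extreme_threshold

    for row in truth.proteins.itertuples(index=False):
        if row.is_decoy:
            n = int(rng.poisson(decoy_peptides_mean))
            if n == 0:
                continue
            for _ in range(n):
                length = int(rng.integers(8, 16))
                pep = "".join(rng.choice(_ALPHABET, size=length))
                band = lane.band(int(rng.integers(1, lane.n_bands + 1)))
                ratio = rng.normal(0.0, 1.0)
                heavy = float(np.exp(rng.normal(intensity_log_mean,
                                                intensity_log_sd)))
                light = heavy * 2.0**ratio
                if rng.random() < prob_params.decoy_high_weight:
                    prob = rng.beta(*prob_params.target_beta)
                else:
                    prob = rng.beta(*prob_params.decoy_beta)
                records.append(
                    PeptideEvidence(
                        peptide=pep,
                        charge=int(rng.integers(2, 4)),
                        accessions=(row.accession,),
                        band=band,
                        probability=float(prob),
                        light_intensity=light,
                        heavy_intensity=heavy,
                    )
                )
            continue

        mean = (
            row.n_peptides_expected
            if peptides_per_protein_mean is None
            else peptides_per_protein_mean
        )
        n = int(round(mean)) if fixed_peptide_count else int(rng.poisson(mean))
        if n == 0:
            continue
        pool = _peptide_pool(rng, row.mw_kda)
        # small proteins can digest into fewer length-bounded peptides than
        # requested; top the pool up so the fixed-count contract holds
        attempts = 0
        while len(pool) < n and attempts < 10:
            extra = set(pool) | set(_peptide_pool(rng, row.mw_kda))
            pool = sorted(extra)
            attempts += 1
        if not pool:
            continue
        n = min(n, len(pool))
        chosen = rng.choice(len(pool), size=n, replace=False)
        home = lane.band_for_mw(row.mw_kda).index
        for k in chosen:
            band = lane.band(_spill_band(rng, lane, home, spillover))
            ratio = (
                row.true_log2_ratio
                + truth.mixing_offset
                + (rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0)
            )
            base = float(np.exp(rng.normal(intensity_log_mean, intensity_log_sd)))
            if ratio >= thr:
                light, heavy = base, 0.0
            elif ratio <= -thr:
                light, heavy = 0.0, base
            else:
                heavy = base
                light = heavy * 2.0**ratio
            records.append(
                PeptideEvidence(
                    peptide=pool[k],
                    charge=int(rng.integers(2, 4)),
                    accessions=(row.accession,),
                    band=band,
                    probability=float(rng.beta(*prob_params.target_beta)),
                    light_intensity=light,
                    heavy_intensity=heavy,
                )
            )
    return records


def simulate_null_experiment(
    n_proteins: int = 2000,
    noise_sd: float = 0.3,
    n_peptides: int = 6,
    mixing_offset: float = 0.1,
    fraction: str = "F1",
    seed: int = 0,
) -> tuple[SimTruth, list[PeptideEvidence]]:
    """Null-only calibration experiment with known protein-level sd.

    Every protein is unregulated, gets exactly ``n_peptides`` peptides and no
    band spill-over, so each protein-level ratio is
    N(mixing_offset, noise_sd^2 / n_peptides) — the homogeneous-variance
    condition under which the pooled-sigma Z test is exactly calibrated.
    """
    truth = generate_truth(
        n_proteins=n_proteins,
        frac_regulated=0.0,
        noise_sd=noise_sd,
        mixing_offset=mixing_offset,
        decoy_fraction=0.0,
        n_one_channel=0,
        peptides_per_protein_mean=float(n_peptides),
        seed=seed,
    )
    evidence = simulate_evidence(
        truth,
        default_lane(fraction),
        spillover=0.0,
        fixed_peptide_count=True,
        seed=seed + 1,
    )
    return truth, evidence


def simulate_proteoform(
    accession: str = "SIMCTSB",
    precursor_mw_kda: float = 37.3,
    processed_mw_kda: float = 27.5,
    precursor_ratio: float = 1.5,
    processed_ratio: float = 0.0,
    shared_peptide_fraction: float = 0.7,
    n_peptides_per_form: int = 12,
    n_bands_per_form: tuple[int, int] = (3, 2),
    noise_sd: float = 0.3,
    lane: GelLane | None = None,
    seed: int = 0,
) -> list[PeptideEvidence]:
    """Cathepsin-B-like two-proteoform scenario.

    One accession emits two evidence clusters: the intact precursor in the
    upper gel region (default 37.3 kDa, up-regulated at +1.5 log2) and the
    processed enzyme in the lower region (27.5 kDa, unregulated).  A fraction
    of the peptide sequences is shared between the forms (the processed chain
    is a subsequence of the precursor); the remainder is precursor-specific
    (propeptide-region peptides absent from the lower bands).  With
    ``shared_peptide_fraction=1`` the forms are distinguishable only by band
    position.  Rows are spread round-robin over each form's contiguous bands.
    """
    if not precursor_mw_kda > processed_mw_kda:
        raise ValueError("precursor MW must exceed processed MW")
    if not 0.0 <= shared_peptide_fraction <= 1.0:
        raise ValueError("shared_peptide_fraction must be in [0, 1]")
    lane = lane or default_lane("F1")
    rng = np.random.default_rng(seed)

    up_home = lane.band_for_mw(precursor_mw_kda).index
    lo_home = lane.band_for_mw(processed_mw_kda).index
    b_up, b_lo = n_bands_per_form
    upper = [up_home + d for d in range(b_up)]
    lower = [lo_home + d for d in range(b_lo)]
    upper = [min(max(1, i), lane.n_bands) for i in upper]
    lower = [min(max(1, i), lane.n_bands) for i in lower]
    if max(upper) + 1 >= min(lower):
        raise ValueError(
            "precursor and processed MW windows overlap on this lane; the two "
            "forms would not be band-resolvable"
        )

    pool = _peptide_pool(rng, precursor_mw_kda)
    n_shared = int(round(shared_peptide_fraction * n_peptides_per_form))
    n_specific = n_peptides_per_form - n_shared
    need = n_shared + n_specific
    if len(pool) < need:
        raise ValueError("digest pool too small for requested peptide counts")
    picked = rng.choice(len(pool), size=need, replace=False)
    shared = [pool[i] for i in picked[:n_shared]]
    specific = [pool[i] for i in picked[n_shared:]]

    def emit(sequences, bands, true_ratio):
        seqs = list(sequences)
        rng.shuffle(seqs)
        for j, seq in enumerate(seqs):
            band = lane.band(bands[j % len(bands)])
            ratio = true_ratio + (
                rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            )
            heavy = float(np.exp(rng.normal(math.log(1.0e6), 0.5)))
            light = heavy * 2.0**ratio
            records.append(
                PeptideEvidence(
                    peptide=seq,
                    charge=int(rng.integers(2, 4)),
                    accessions=(accession,),
                    band=band,
                    probability=float(rng.beta(20.0, 2.0)),
                    light_intensity=light,
                    heavy_intensity=heavy,
                )
            )

    records: list[PeptideEvidence] = []
    emit(shared + specific, upper, precursor_ratio)
    # the processed form lacks the precursor-specific peptides: reuse shared
    # sequences (with repetition across bands) up to the per-form count
    lower_seqs = [shared[i % len(shared)] for i in range(n_peptides_per_form)] \
        if shared else []
    emit(lower_seqs, lower, processed_ratio)
    return records
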