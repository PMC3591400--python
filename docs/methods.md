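# Methods

This note documents the statistical model behind `gelsilac`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## The measurement model

A GeLC-SILAC experiment measures, for each quantified peptide *i* of
protein *p* in gel band *b*, a light/heavy intensity ratio.  We work
throughout on the log₂ scale and model

    x_{pib} = beta_p + delta + eps_{pib},     eps ~ N(0, sigma_noise^2)

where `beta_p` is the protein's true log₂(L/H) regulation (0 for the
unregulated majority), `delta` a global mixing offset from imperfect 1:1
pooling of the two lysates, and `eps` multiplicative (lognormal) measurement
noise.  Peptides whose heavy (resp. light) channel falls below detection
carry a one-channel sentinel instead of a ratio; this happens for proteins
whose regulation is beyond the measurable dynamic range (the "+" rows of a
report, e.g. a massively over-expressed efflux transporter).

**Aggregation.** The protein estimate is the unweighted mean of per-band
mean peptide ratios ("mean of band means").  This matches the convention of
averaging a protein's per-band ratios when it appears in multiple adjacent
bands, and makes the estimate robust to one band contributing many
peptides.  A pooled-peptide mean is available (`averaging_mode = pooled`).
Peptides attributable to more than one protein group are excluded from
quantification (and from the unique-peptide count); an optional rejection of
peptide ratios further than 3 MADs from their band median (off by default)
stands in for manual ratio curation.

**Normalisation and test.** Per fraction, the median of finite protein
ratios among unambiguous-tier proteins is subtracted (removing `delta`),
and the null scale sigma is estimated from the same set — either the sample
SD (default) or the Gaussian-consistent MAD (1.4826·MAD), which ignores the
regulated minority.  Each protein then receives a two-sided standard-normal
p-value at z = (ratio − median)/sigma, plus an informational
Benjamini–Hochberg q-value; the primary call is raw p < alpha (0.05).
One-channel proteins are excluded from the median/sigma fit, printed with
p = 0.000 and always called significant.  Restricting the fit to the
unambiguous tier mirrors fitting the ratio histogram to proteins with ≥ 3
peptides; p-values are still assigned to every quantified protein.  With
the SD estimator, sigma deliberately absorbs both measurement noise and any
regulated tail — this makes the test conservative on strongly structured
data (only effects large relative to the empirical spread are called), which
is the intended behaviour of an empirical-null Z test.

**Identification and FDR.** Peptide evidence is filtered at probability
≥ 0.70 (the boundary value is kept).  One group per accession pools all gel
bands; accessions whose peptide set is a subset of another's merge into it
(parsimony).  The group's protein probability is the maximum retained
peptide probability — a proxy, because upstream protein-inference posteriors
are inputs to this pipeline, not something it models; groups below 0.95 are
dropped ("0.95 or higher" resolved as ≥).  Groups are tiered by distinct
unique peptide sequences (charge/modification variants count once):
≥ 3 = unambiguous, 1–2 = low evidence.  FDR per tier is
100·#decoys/#targets against a shuffled-decoy database (Fisher–Yates
whole-sequence permutation; a K/R-position-preserving mode exists behind a
flag since the tryptic cleavage pattern of plain shuffles differs from the
target's).

**Proteoforms.** Band index encodes molecular weight (log-linear lane
calibration between 250 and 10 kDa by default; 65 bands for fraction F1, 72
for F2).  A protein's occupied bands are clustered into contiguous runs;
a gap of more than one empty band separates candidate forms, and forms whose
MW windows overlap within a tolerance are re-merged.  Each form gets:

* an MW estimate (peptide-count-weighted geometric mean of band midpoints),
* a ratio (mean of its band means),
* a **measurement SE** from the pooled within-band peptide variance,
  Var = s²·Σ(1/n_b)/B², with df = Σ(n_b−1) — the appropriate uncertainty
  for parameter recovery,
* a **band-replicate t test** (one-sample t on the B band means, df = B−1)
  as the per-protein significance assessment.

The band-replicate test is what makes the *pooled* quantification of a
genuinely heterogeneous protein (precursor up-regulated, processed form
unchanged) correctly non-significant: pooling inflates the between-band
scatter by the form difference itself, while each resolved form is tested
against its own homogeneous replicates.  The two SEs answer different
questions and deliberately differ.

## The synthetic-data generator

`generate_truth` + `simulate_evidence` emulate one fraction of a
two-fraction experiment under the model above.  Defaults are the study
conditions the package is validated under:

| parameter | default | rationale |
| --- | --- | --- |
| n_proteins | 500 | desk-scale fraction |
| frac_regulated | 0.10 | small regulated minority |
| effect range | \|log₂\| ∈ [0.8, 4.5], random sign | span of significantly regulated membrane proteins |
| n_one_channel | 1 | one transporter-like extreme protein (true log₂ = threshold+1) |
| extreme threshold | 5.0 | sampled ratio ≥ 5 drops the heavy channel (≤ −5 the light) |
| noise_sd | 0.3 log₂ units | peptide-level lognormal noise |
| mixing_offset | 0.1 log₂ units | imperfect 1:1 pooling, removed by normalisation |
| peptides/protein | Poisson(6) | typical unambiguous identification |
| spill-over | 0.2 into the two adjacent bands | proteins appear in adjacent bands |
| protein MW | log-uniform 10–250 kDa | matches log-spaced lane calibration |
| target scores | Beta(20, 2) | high-confidence identifications |
| decoy scores | 0.95·Beta(2, 8) + 0.05·Beta(20, 2) | mostly low, with rare false high-confidence matches |
| decoy peptides | Poisson(1.0), decoys/targets = 0.5 | decoy hits are isolated random matches |

The decoy score contamination (5% from the target component) is what a
target-decoy procedure exists to count: without a false-high tail no decoy
would ever survive the 0.95 protein filter and tiered FDR would be
identically zero.  Under these defaults decoys essentially never reach three
retained unique peptides — across seeds the expected count per run is ≪ 1,
though the event is possible (it is a Poisson tail, not an impossibility).

`simulate_null_experiment` is the calibration configuration: no regulation,
exactly 6 peptides per protein, no spill-over.  Then every protein-level
ratio is N(delta, sigma_noise²/6) — homogeneous variance — and the pooled-σ
Z test is exactly calibrated, so the p < 0.05 call rate on null data is an
honest check of the machinery.  With Poisson peptide counts and spill-over
the per-protein variance is heterogeneous and the single-σ test is mildly
anti-conservative (call rate ≈ 0.06 at Poisson(6)); that is a property of
the single-σ method itself, visible in the generator, and the reason the
calibration configuration fixes the count.

`simulate_proteoform` builds the two-form scenario: an intact precursor
(default 37.3 kDa, +1.5 log₂) occupying three contiguous upper bands and the
processed enzyme (27.5 kDa, 0.0) in two lower bands, 12 peptides per form,
a configurable fraction of peptide sequences shared between forms (the
processed chain is a subsequence of the precursor) and the remainder
precursor-specific.

**What the generator does not emulate:** spectrum-level structure
(m/z peaks, retention time, XIC reconstruction), peptide-level
intensity-dependent noise, correlated peptides within a protein,
protein-level biological variance beyond the regulation effect, shared
(degenerate) peptides between target proteins, and realistic sequence
composition (random uniform residues).  Passing tests therefore validate the
statistical machinery under the stated model, not performance on any
particular real dataset.

## Numerical conventions and edge cases

* Monoisotopic residue masses, water and proton from pyteomics; the SILAC
  label shift 6.020129 Da equals 6·(¹³C−¹²C) to 1e-5 Da; propionamide
  71.037114 Da per cysteine.  Digestion follows the Keil rule (cleave after
  K/R, not before P), ≤ 2 missed cleavages by default; I/L distinct;
  B/Z/X/U rejected.  `tryptic_digest` applies no length filter by default
  (the simulator and CLI use 6–40 residues).
* Median normalisation requires ≥ 3 finite ratios; zero estimated spread is
  an error.  p-values of one-channel records are the sentinel 0.0.
* Outlier rejection uses raw MADs ("> 3 MAD from the band median"); it is
  disabled when MAD = 0 or fewer than 3 values.
* Ties in the all-one-channel direction resolve to light-only.
* Tests aggregate stochastic checks over fixed seeds with binomial bounds
  derived from the nominal coverage (e.g. a ±2·SE interval at df ≈ 9–10 has
  t coverage ≈ 0.92 per form, ≈ 0.86 jointly).
* Problem sizes in the test suite and acceptance script (500–2000 simulated
  proteins, 20 proteoform replicates, 1000+500 target/decoy proteins) are
  chosen so each check has sampling error well below its tolerance while the
  whole suite runs in seconds.

## Known limitations

* The protein probability is a max-peptide proxy, not a proper
  protein-level posterior; externally computed protein probabilities can be
  supplied by pre-filtering the evidence.
* No weighting of peptides by signal intensity when averaging (the
  information is retained in the evidence records).
* Cross-fraction merging is by accession only; it does not reconcile
  conflicting proteoform structure between fractions.
* The lane calibration is a global log-linear fit; real gels deviate at the
  extremes, so MW estimates near the lane ends inherit that bias.
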