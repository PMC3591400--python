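"""Synthetic-data generator: determinism, truth structure, noise laws."""

import math

import numpy as np
import pytest

from gelsilac.evidence import OneChannel
from gelsilac.simulate import (
    generate_truth,
    simulate_evidence,
    simulate_null_experiment,
    simulate_proteoform,
)


class TestGenerateTruth:
    def test_no_regulation_means_all_null(self):
        truth = generate_truth(n_proteins=50, frac_regulated=0.0,
                               n_one_channel=0, seed=3)
        assert (truth.targets["true_log2_ratio"] == 0.0).all()
        assert not truth.targets["regulated"].any()

    def test_seed_reproducibility(self):
        a = generate_truth(n_proteins=40, seed=11)
        b = generate_truth(n_proteins=40, seed=11)
        assert a.proteins.equals(b.proteins)

    def test_regulated_count_is_exact_fraction(self):
        truth = generate_truth(n_proteins=1000, frac_regulated=0.1, seed=5)
        assert truth.targets["regulated"].sum() == 100

    def test_effect_sizes_in_range(self):
        truth = generate_truth(n_proteins=500, frac_regulated=0.2,
                               n_one_channel=0, seed=9)
        effects = truth.targets.loc[truth.targets["regulated"],
                                    "true_log2_ratio"].abs()
        assert ((effects >= 0.8) & (effects <= 4.5)).all()

    def test_one_channel_truth_exceeds_threshold(self):
        truth = generate_truth(n_proteins=100, n_one_channel=1, seed=2)
        extreme = truth.targets[truth.targets["one_channel"]]
        assert len(extreme) == 1
        assert (extreme["true_log2_ratio"].abs()
                >= truth.extreme_threshold).all()

    def test_decoy_fraction_and_prefix(self):
        truth = generate_truth(n_proteins=100, decoy_fraction=0.5, seed=4)
        assert len(truth.decoys) == 50
        assert truth.decoys["accession"].str.startswith("DECOY_").all()
        assert not truth.targets["accession"].str.startswith("DECOY_").any()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_truth(frac_regulated=1.5, seed=0)


class TestSimulateEvidence:
    def test_noise_free_ratios_equal_truth(self, lane_f1):
        truth = generate_truth(n_proteins=30, noise_sd=0.0, mixing_offset=0.0,
                               decoy_fraction=0.0, n_one_channel=0, seed=6)
        evidence = simulate_evidence(truth, lane_f1, seed=7)
        true_of = dict(zip(truth.proteins["accession"],
                           truth.proteins["true_log2_ratio"]))
        for rec in evidence:
            assert rec.log2_ratio == pytest.approx(
                true_of[rec.accessions[0]], abs=1e-9
            )

    def test_zero_spillover_single_band(self, lane_f1):
        truth = generate_truth(n_proteins=40, decoy_fraction=0.0,
                               n_one_channel=0, seed=8)
        evidence = simulate_evidence(truth, lane_f1, spillover=0.0, seed=9)
        bands = {}
        for rec in evidence:
            bands.setdefault(rec.accessions[0], set()).add(rec.band.index)
        assert all(len(b) == 1 for b in bands.values())

    def test_spillover_reaches_adjacent_bands_only(self, lane_f1):
        truth = generate_truth(n_proteins=40, decoy_fraction=0.0,
                               n_one_channel=0,
                               peptides_per_protein_mean=12.0, seed=8)
        evidence = simulate_evidence(truth, lane_f1, spillover=0.5, seed=9)
        spread = {}
        for rec in evidence:
            spread.setdefault(rec.accessions[0], set()).add(rec.band.index)
        assert any(len(b) > 1 for b in spread.values())
        assert all(max(b) - min(b) <= 2 for b in spread.values())

    def test_bit_reproducible(self, lane_f1):
        truth = generate_truth(n_proteins=25, seed=10)
        a = simulate_evidence(truth, lane_f1, seed=11)
        b = simulate_evidence(truth, lane_f1, seed=11)
        assert a == b

    def test_decoy_evidence_disjoint_from_targets(self, lane_f1):
        truth = generate_truth(n_proteins=60, decoy_fraction=1.0, seed=12)
        evidence = simulate_evidence(truth, lane_f1, seed=13)
        target_accs = set(truth.targets["accession"])
        for rec in evidence:
            if rec.is_decoy:
                assert not set(rec.accessions) & target_accs

    def test_extreme_protein_drops_heavy_channel(self, lane_f1):
        truth = generate_truth(n_proteins=50, n_one_channel=1,
                               decoy_fraction=0.0, seed=14)
        extreme_acc = truth.targets.loc[truth.targets["one_channel"],
                                        "accession"].iloc[0]
        evidence = simulate_evidence(truth, lane_f1, seed=15)
        extreme_rows = [r for r in evidence if r.accessions[0] == extreme_acc]
        assert extreme_rows
        assert all(r.log2_ratio is OneChannel.LIGHT_ONLY for r in extreme_rows)

    def test_per_protein_mean_close_to_truth(self, lane_f1):
        """Normal theory: protein mean of ~6 peptide ratios at sd 0.3 falls
        within 3*0.3/sqrt(n) of truth for >= 99% of proteins."""
        truth = generate_truth(n_proteins=500, noise_sd=0.3, mixing_offset=0.0,
                               decoy_fraction=0.0, n_one_channel=0, seed=16)
        evidence = simulate_evidence(truth, lane_f1, seed=17)
        true_of = dict(zip(truth.proteins["accession"],
                           truth.proteins["true_log2_ratio"]))
        per_protein = {}
        for rec in evidence:
            per_protein.setdefault(rec.accessions[0], []).append(
                rec.log2_ratio
            )
        ok = total = 0
        for acc, ratios in per_protein.items():
            finite = [r for r in ratios if not isinstance(r, OneChannel)]
            if not finite:
                continue
            total += 1
            bound = 3 * 0.3 / math.sqrt(len(finite))
            ok += abs(np.mean(finite) - true_of[acc]) <= bound
        assert total > 400
        assert ok / total >= 0.99

    def test_null_evidence_median_converges_to_offset(self, lane_f1):
        truth = generate_truth(n_proteins=5000, frac_regulated=0.0,
                               n_one_channel=0, decoy_fraction=0.0,
                               mixing_offset=0.25, seed=18)
        evidence = simulate_evidence(truth, lane_f1, seed=19)
        ratios = [r.log2_ratio for r in evidence
                  if not isinstance(r.log2_ratio, OneChannel)]
        assert np.median(ratios) == pytest.approx(0.25, abs=0.02)


class TestNullCalibration:
    def test_fixed_peptide_count_and_no_spill(self):
        _truth, evidence = simulate_null_experiment(n_proteins=100, seed=20)
        per_protein = {}
        for rec in evidence:
            per_protein.setdefault(rec.accessions[0], []).append(rec.band.index)
        counts = {len(v) for v in per_protein.values()}
        assert counts == {6}
        assert all(len(set(v)) == 1 for v in per_protein.values())


class TestSimulateProteoform:
    def test_deterministic(self, lane_f1):
        assert simulate_proteoform(seed=1) == simulate_proteoform(seed=1)

    def test_two_disjoint_band_clusters(self, lane_f1):
        evidence = simulate_proteoform(seed=2, lane=lane_f1)
        upper_band = lane_f1.band_for_mw(37.3).index
        lower_band = lane_f1.band_for_mw(27.5).index
        bands = sorted({r.band.index for r in evidence})
        assert bands[0] >= upper_band and bands[-1] <= lower_band + 2
        gaps = [b2 - b1 for b1, b2 in zip(bands, bands[1:])]
        assert max(gaps) > 2  # resolvable: more than one empty band between

    def test_fully_shared_peptides_differ_only_by_band(self, lane_f1):
        evidence = simulate_proteoform(shared_peptide_fraction=1.0, seed=3,
                                       lane=lane_f1)
        upper_cut = lane_f1.band_for_mw(31.0).index  # between the two forms
        upper = {r.peptide for r in evidence if r.band.index <= upper_cut}
        lower = {r.peptide for r in evidence if r.band.index > upper_cut}
        assert upper == lower

    def test_precursor_specific_peptides_absent_below(self, lane_f1):
        evidence = simulate_proteoform(shared_peptide_fraction=0.7, seed=4,
                                       lane=lane_f1)
        upper_cut = lane_f1.band_for_mw(31.0).index
        upper = {r.peptide for r in evidence if r.band.index <= upper_cut}
        lower = {r.peptide for r in evidence if r.band.index > upper_cut}
        assert lower < upper  # strictly fewer sequences below

    def test_overlapping_forms_rejected(self, lane_f1):
        with pytest.raises(ValueError):
            simulate_proteoform(precursor_mw_kda=28.0, processed_mw_kda=27.5,
                                lane=lane_f1, seed=5)
        with pytest.raises(ValueError):
            simulate_proteoform(precursor_mw_kda=20.0, processed_mw_kda=27.5,
                                lane=lane_f1, seed=5)
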