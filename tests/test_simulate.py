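"""Unit and property tests for the synthetic-data generator."""

import numpy as np
import pytest

from cnaphase import simulate
from cnaphase.simulate import (CNASpec, ConfigError, SimulationConfig,
                               SomaticParams, expected_vaf,
                               sample_read_counts_array, simulate_het_sites,
                               simulate_patient)


class TestHetSites:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(seed=7, genome=(("1", 10_000_000),))
        assert simulate_het_sites(cfg) == simulate_het_sites(cfg)

    def test_poisson_site_count_expectation(self):
        """Density 10/Mb on a 100 Mb chromosome: mean count over 200 seeds
        within 3 standard errors of 1000 (Poisson mean = variance)."""
        counts = []
        for seed in range(200):
            cfg = SimulationConfig(seed=seed, het_site_density=10.0,
                                   genome=(("1", 100_000_000),))
            counts.append(len(simulate_het_sites(cfg)))
        se = np.sqrt(1000 / 200)
        assert abs(np.mean(counts) - 1000) < 3 * se

    def test_sites_stay_on_their_chromosome_sorted_unique(self):
        cfg = SimulationConfig(seed=1, het_site_density=5.0,
                               genome=(("1", 20_000_000), ("2", 10_000_000)))
        sites = simulate_het_sites(cfg)
        by_chrom = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append(s.pos)
        assert set(by_chrom) == {"1", "2"}
        for chrom, length in cfg.genome:
            pos = by_chrom[chrom]
            assert pos == sorted(pos)
            assert len(pos) == len(set(pos))
            assert all(1 <= p <= length for p in pos)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(genome=(("1", 0),))


class TestExpectedVaf:
    def test_pure_normal_is_half(self):
        spec = CNASpec("T1", "1", 0, 100, "A", 0)
        assert expected_vaf("A", spec, 0.0) == 0.5
        assert expected_vaf("B", None, 0.0) == 0.5

    def test_pure_tumor_loss_of_alt_homolog_is_zero(self):
        spec = CNASpec("T1", "1", 0, 100, "A", 0)
        assert expected_vaf("A", spec, 1.0) == 0.0
        assert expected_vaf("B", spec, 1.0) == 1.0

    def test_mixture_formula_hand_value(self):
        # purity 0.6, loss of the non-ALT homolog: (0.6+0.4)/(0.6+0.8) = 1/1.4
        spec = CNASpec("T1", "1", 0, 100, "B", 0)
        assert expected_vaf("A", spec, 0.6) == pytest.approx(1 / 1.4, abs=1e-12)

    def test_outside_cna_is_half_at_any_purity(self):
        for purity in (0.0, 0.3, 1.0):
            assert expected_vaf("A", None, purity) == 0.5

    def test_gain_shifts_toward_amplified_homolog(self):
        spec = CNASpec("T1", "1", 0, 100, "A", 2)
        assert expected_vaf("A", spec, 0.8) > 0.5 > expected_vaf("B", spec, 0.8)

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError):
            expected_vaf("A", None, 1.5)


class TestReadCounts:
    def test_af_extremes_are_deterministic(self, rng):
        alt, total = sample_read_counts_array(np.zeros(500), 50, rng)
        assert (alt == 0).all()
        alt, total = sample_read_counts_array(np.ones(500), 50, rng)
        assert (alt == total).all()

    def test_counts_conserved_and_depth_positive(self, rng):
        af = rng.uniform(0, 1, size=2000)
        alt, total = sample_read_counts_array(af, 30, rng)
        assert (total >= 1).all()
        assert ((0 <= alt) & (alt <= total)).all()

    def test_binomial_mean_recovery(self, rng):
        """AF 0.5 at depth 100 over 10,000 draws: mean alt/total within
        3 standard errors of 0.5."""
        alt, total = sample_read_counts_array(np.full(10_000, 0.5), 100, rng)
        ratios = alt / total
        se = ratios.std(ddof=1) / np.sqrt(ratios.size)
        assert abs(ratios.mean() - 0.5) < 3 * se


class TestSimulatePatient:
    def test_multicentric_tumors_share_no_somatic_keys(self, clean_patient):
        _, patient = clean_patient
        truth = patient.truth
        t1 = set().union(*(truth.somatic_by_region[r]
                           for r in truth.region_to_tumor
                           if truth.region_to_tumor[r] == "T1"))
        t2 = set().union(*(truth.somatic_by_region[r]
                           for r in truth.region_to_tumor
                           if truth.region_to_tumor[r] == "T2"))
        assert truth.scenario == "multi-centric"
        assert t1 and t2 and not (t1 & t2)

    def test_metastasis_scenario_shares_exactly_k_keys(self, small_genome):
        cfg = SimulationConfig(
            seed=5, tumors_per_patient=2, regions_per_tumor=1,
            genome=small_genome,
            somatic_params=SomaticParams(trunk_mutations_per_tumor=10,
                                         private_mutations_per_region=3,
                                         trunk_detection_prob=1.0,
                                         cross_tumor_shared=4))
        truth = simulate_patient(cfg, 0).truth
        assert truth.scenario == "metastasis"
        assert len(truth.cross_tumor_mutations) == 4
        shared = (set(truth.trunk_mutations["T1"])
                  & set(truth.trunk_mutations["T2"]))
        assert shared == set(truth.cross_tumor_mutations)

    def test_high_purity_deep_loss_separates_haplotypes(self, small_genome):
        """Purity 1, depth 10,000, one-copy loss of homolog A: observed AF
        is below 0.5 for alt-on-A sites and above for alt-on-B sites."""
        spec = CNASpec("T1", "1", 0, 60_000_000, "A", 0)
        cfg = SimulationConfig(
            seed=9, tumors_per_patient=1, regions_per_tumor=1,
            purity_per_region=1.0, mean_depth=10_000.0, het_site_density=1.0,
            genome=small_genome, cna_specs=(spec,),
            somatic_params=SomaticParams(trunk_mutations_per_tumor=0,
                                         private_mutations_per_region=0))
        patient = simulate_patient(cfg, 0)
        phase = {(s.chrom, s.pos): s.alt_homolog for s in patient.truth.het_sites}
        checked = 0
        for rec in patient.records:
            if (rec.chrom, rec.pos) not in phase or rec.chrom != "1":
                continue
            alt, total = rec.counts["T1R1"]
            af = alt / total
            assert (af < 0.5) == (phase[(rec.chrom, rec.pos)] == "A")
            checked += 1
        assert checked > 20

    def test_same_seed_reproduces_patient_exactly(self, small_genome):
        cfg = SimulationConfig(seed=42, genome=small_genome,
                               het_site_density=1.0)
        a = simulate_patient(cfg, 0)
        b = simulate_patient(cfg, 0)
        assert a.records == b.records
        assert a.truth == b.truth

    def test_overlapping_cnas_rejected(self, small_genome):
        specs = (CNASpec("T1", "1", 0, 10_000_000, "A", 0),
                 CNASpec("T1", "1", 5_000_000, 20_000_000, "B", 2))
        with pytest.raises(ConfigError):
            SimulationConfig(genome=small_genome, cna_specs=specs)

    def test_normal_af_centers_on_half_and_cna_sites_on_expected(self,
                                                                 small_genome):
        spec = CNASpec("T1", "1", 0, 60_000_000, "A", 0)
        cfg = SimulationConfig(
            seed=13, tumors_per_patient=1, regions_per_tumor=1,
            purity_per_region=0.8, mean_depth=200.0, het_site_density=3.0,
            genome=small_genome, cna_specs=(spec,),
            somatic_params=SomaticParams(trunk_mutations_per_tumor=0,
                                         private_mutations_per_region=0))
        patient = simulate_patient(cfg, 0)
        phase = {(s.chrom, s.pos): s.alt_homolog for s in patient.truth.het_sites}
        normal_afs, tumor_afs_a = [], []
        for rec in patient.records:
            h = phase.get((rec.chrom, rec.pos))
            alt, total = rec.counts[patient.normal_sample]
            normal_afs.append(alt / total)
            if rec.chrom == "1" and h == "A":
                alt, total = rec.counts["T1R1"]
                tumor_afs_a.append(alt / total)
        want = simulate.expected_vaf("A", spec, 0.8)
        for values, target in ((normal_afs, 0.5), (tumor_afs_a, want)):
            arr = np.array(values)
            se = arr.std(ddof=1) / np.sqrt(arr.size)
            assert abs(arr.mean() - target) < 4 * se


class TestTruthRoundTrip:
    def test_round_trip_identity(self, clean_patient, tmp_path):
        _, patient = clean_patient
        path = tmp_path / "truth.json"
        simulate.write_truth(patient.truth, str(path))
        assert simulate.read_truth(str(path)) == patient.truth

    def test_empty_truth_round_trips(self, tmp_path):
        truth = simulate.SimulationTruth("P0", "multi-centric", [], [], {}, [],
                                         {}, {})
        path = tmp_path / "empty.json"
        simulate.write_truth(truth, str(path))
        assert simulate.read_truth(str(path)) == truth

    def test_truth_enumerates_all_cnas(self, small_genome, tmp_path):
        specs = (CNASpec("T1", "1", 0, 10_000_000, "A", 0),
                 CNASpec("T2", "2", 0, 10_000_000, "B", 2))
        cfg = SimulationConfig(seed=3, tumors_per_patient=3,
                               genome=small_genome, cna_specs=specs,
                               het_site_density=0.5)
        truth = simulate_patient(cfg, 0).truth
        path = tmp_path / "t.json"
        simulate.write_truth(truth, str(path))
        assert len(simulate.read_truth(str(path)).cna_specs) == 2


class TestVcfRoundTrip:
    def test_vcf_preserves_counts(self, clean_patient, tmp_path):
        from cnaphase import filtering
        cfg, patient = clean_patient
        path = tmp_path / "p.vcf"
        simulate.write_patient_vcf(patient, str(path), genome=cfg.genome)
        obs = filtering.read_vcf_observations(str(path))
        by_key = {(o.sample_id, o.chrom, o.pos, o.ref, o.alt):
                  (o.alt_reads, o.total_reads) for o in obs}
        for rec in patient.records:
            for sample, (alt, total) in rec.counts.items():
                assert by_key[(sample, rec.chrom, rec.pos, rec.ref,
                               rec.alt)] == (alt, total)

    def test_vcf_bytes_deterministic(self, small_genome, tmp_path):
        cfg = SimulationConfig(seed=8, genome=small_genome,
                               het_site_density=0.5)
        paths = []
        for name in ("a.vcf", "b.vcf"):
            patient = simulate_patient(cfg, 0)
            p = tmp_path / name
            simulate.write_patient_vcf(patient, str(p), genome=cfg.genome)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
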