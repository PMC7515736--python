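"""Generator contracts: determinism, planted structure, binding model, DE coupling."""

import numpy as np
import pytest

from seqdap.motifs import encode, score_site
from seqdap.synthetic import (
    SyntheticConfig,
    SyntheticTruth,
    default_carg_pwm,
    default_carg_tffm,
    expected_amplitude,
    generate_de_table,
    generate_genome,
    simulate_experiment,
)
from seqdap.synthetic import _loci  # type: ignore


@pytest.fixture(scope="module")
def tiny_cfg():
    return SyntheticConfig(
        genome_length=80_000, n_single_sites=20, n_pair_sites=15,
        n_decoy_sites=50, seed=7,
    )


@pytest.fixture(scope="module")
def tiny_data(tiny_cfg):
    return generate_genome(tiny_cfg)


class TestTruthMotifs:
    def test_default_pwm_is_palindromic_and_normalized(self):
        pwm = default_carg_pwm()
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(pwm.probs, pwm.probs[::-1, ::-1])

    def test_default_tffm_rows_normalized(self):
        tffm = default_carg_tffm()
        np.testing.assert_allclose(tffm.transitions.sum(axis=2), 1.0, atol=1e-12)


class TestGenerateGenome:
    def test_determinism(self, tiny_cfg, tiny_data):
        genome2, truth2 = generate_genome(tiny_cfg)
        genome, truth = tiny_data
        assert genome == genome2
        assert truth.to_json() == truth2.to_json()

    def test_pair_spacing_by_construction(self):
        cfg = SyntheticConfig(
            genome_length=120_000, n_single_sites=0, n_pair_sites=10,
            n_decoy_sites=0, spacing_weights={46: 1.0}, seed=3,
        )
        _, truth = generate_genome(cfg)
        assert len(truth.pairs) == 10
        assert all(p["start2"] - p["start1"] == 46 for p in truth.pairs)

    def test_zero_sites_leaves_no_record(self):
        cfg = SyntheticConfig(
            genome_length=50_000, n_single_sites=0, n_pair_sites=0,
            n_decoy_sites=0, seed=4,
        )
        _, truth = generate_genome(cfg)
        assert truth.singles == [] and truth.pairs == []

    def test_planted_instances_score_high_under_truth_model(self, tiny_data):
        genome, truth = tiny_data
        pwm = default_carg_pwm()
        scores = [
            score_site(pwm, genome[s["chrom"]][s["start"] : s["start"] + 16])
            for s in truth.singles
        ]
        assert np.mean(np.array(scores) >= 0.7) > 0.8

    def test_recorded_lr_matches_genome_content(self, tiny_data):
        genome, truth = tiny_data
        pwm = default_carg_pwm()
        for s in truth.singles[:10]:
            window = genome[s["chrom"]][s["start"] : s["start"] + 16]
            lo_f = pwm.log_odds_scan(encode(window), "+")[0]
            lo_r = pwm.log_odds_scan(encode(window), "-")[0]
            # recorded LR is for the instance in its sampled orientation
            assert s["lr"] == pytest.approx(
                float(np.exp(lo_f if s["strand"] == "+" else lo_r)), rel=1e-6
            )

    def test_truth_round_trips_through_json(self, tiny_data):
        _, truth = tiny_data
        again = SyntheticTruth.from_json(truth.to_json())
        assert again.to_json() == truth.to_json()

    def test_impossible_placement_raises(self):
        cfg = SyntheticConfig(
            genome_length=8_000, n_single_sites=500, n_pair_sites=0,
            n_decoy_sites=0, seed=5,
        )
        with pytest.raises(RuntimeError, match="collision"):
            generate_genome(cfg)


class TestSimulateExperiment:
    def test_cooperative_pair_beats_dimer_signal(self, tiny_cfg, tiny_data):
        genome, truth = tiny_data
        loci_d = {}
        for chrom, center, signal in _loci(truth, tiny_cfg, "dimer", 16):
            loci_d[(chrom, center)] = signal
        pair_seen = 0
        for p in truth.pairs:
            if p["spacing"] not in (36, 46, 57):
                continue
            c1 = p["start1"] + 7.5
            c2 = p["start2"] + 7.5
            mid = (c1 + c2) / 2
            tet = [
                s for ch, c, s in _loci(truth, tiny_cfg, "tetramer", 16)
                if ch == p["chrom"] and c == mid
            ]
            best = c1 if p["lr1"] >= p["lr2"] else c2
            assert tet[0] > loci_d[(p["chrom"], best)]
            pair_seen += 1
        assert pair_seen > 0

    def test_no_cooperativity_limit_equalizes_complexes(self):
        cfg = SyntheticConfig(
            genome_length=60_000, n_single_sites=15, n_pair_sites=0,
            n_decoy_sites=0, omega_amplitude=1.0, seed=6,
        )
        _, truth = generate_genome(cfg)
        sig_d = sorted(s for _, _, s in _loci(truth, cfg, "dimer", 16))
        sig_t = sorted(s for _, _, s in _loci(truth, cfg, "tetramer", 16))
        assert sig_d == sig_t

    def test_replicates_share_loci_but_jitter_summits(self, tiny_cfg, tiny_data):
        genome, truth = tiny_data
        reps, _ = simulate_experiment(genome, truth, tiny_cfg, "tetramer")
        assert len(reps) == tiny_cfg.n_replicates
        assert len(reps[0]) == len(reps[1])
        summit_diffs = [
            abs(a.summit - b.summit) for a, b in zip(reps[0], reps[1])
        ]
        assert any(d > 0 for d in summit_diffs)
        assert max(summit_diffs) < 8 * tiny_cfg.summit_jitter_sd

    def test_simulation_determinism(self, tiny_cfg, tiny_data):
        genome, truth = tiny_data
        r1, t1 = simulate_experiment(genome, truth, tiny_cfg, "dimer")
        r2, t2 = simulate_experiment(genome, truth, tiny_cfg, "dimer")
        assert r1 == r2
        for a, b in zip(t1, t2):
            for chrom in a.coverage:
                np.testing.assert_array_equal(a.coverage[chrom], b.coverage[chrom])

    def test_unknown_complex_kind_rejected(self, tiny_cfg, tiny_data):
        genome, truth = tiny_data
        with pytest.raises(ValueError, match="complex_kind"):
            simulate_experiment(genome, truth, tiny_cfg, "trimer")

    def test_coverage_nonnegative_and_peaks_on_loci(self, tiny_cfg, tiny_data):
        genome, truth = tiny_data
        reps, tracks = simulate_experiment(genome, truth, tiny_cfg, "tetramer")
        for t in tracks:
            for vec in t.coverage.values():
                assert (vec >= 0).all()
        # every emitted peak window contains a planted site
        site_pos = [(s["chrom"], s["start"] + 7.5) for s in truth.singles]
        site_pos += [
            (p["chrom"], (p["start1"] + p["start2"]) / 2 + 7.5) for p in truth.pairs
        ]
        for peak in reps[0]:
            iv = peak.interval
            assert any(
                c == iv.chrom and iv.start <= pos < iv.end for c, pos in site_pos
            )


class TestAmplitudeMapping:
    def test_monotone_in_signal(self):
        cfg = SyntheticConfig()
        sig = np.logspace(-1, 9, 30)
        amps = [expected_amplitude(s, cfg) for s in sig]
        assert all(b > a for a, b in zip(amps, amps[1:]))


class TestDeTable:
    def test_full_sensitivity_passes_every_regulated_gene(self, tiny_cfg, tiny_data):
        _, truth = tiny_data
        table = generate_de_table(truth, tiny_cfg, sensitivity=1.0)
        by_gene = table.set_index("gene_id")
        for gid in truth.regulated:
            row = by_gene.loc[gid]
            assert abs(row["logFC"]) > 1.0 and row["FDR"] < 0.05

    def test_zero_sensitivity_pass_rate_matches_fp_rate(self):
        cfg = SyntheticConfig(
            genome_length=400_000, n_single_sites=30, n_pair_sites=0,
            n_decoy_sites=0, gene_spacing=2500, de_fp_rate=0.02, seed=8,
        )
        _, truth = generate_genome(cfg)
        table = generate_de_table(truth, cfg, sensitivity=0.0)
        passed = ((table["logFC"].abs() > 1) & (table["FDR"] < 0.05)).sum()
        n = len(table)
        # binomial expectation n * fp_rate, allow 4 sd
        expect = n * cfg.de_fp_rate
        sd = np.sqrt(n * cfg.de_fp_rate * (1 - cfg.de_fp_rate))
        assert abs(passed - expect) <= 4 * sd + 1

    def test_determinism(self, tiny_cfg, tiny_data):
        _, truth = tiny_data
        t1 = generate_de_table(truth, tiny_cfg)
        t2 = generate_de_table(truth, tiny_cfg)
        assert t1.equals(t2)

    def test_regulated_coupled_to_binding(self):
        cfg = SyntheticConfig(seed=9)
        _, truth = generate_genome(cfg)
        from seqdap.targets import bound_genes, regulatory_regions
        from seqdap.genome_io import GenomicInterval

        regions = regulatory_regions(truth.genes)
        sites = [
            GenomicInterval(s["chrom"], s["start"], s["start"] + 16)
            for s in truth.singles
        ]
        sites += [
            GenomicInterval(p["chrom"], p["start1"], p["start2"] + 16)
            for p in truth.pairs
        ]
        with_site = bound_genes(sites, regions)
        without = {g.gene_id for g in truth.genes} - with_site
        rate_bound = len(set(truth.regulated) & with_site) / max(len(with_site), 1)
        rate_unbound = len(set(truth.regulated) & without) / max(len(without), 1)
        assert rate_bound > rate_unbound + 0.2
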