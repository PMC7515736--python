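"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import warnings

import pytest

from seqdap.comparison import build_union_catalogue, cfr_rank_and_deciles
from seqdap.motifs import reverse_complement
from seqdap.pooling import consensus_peaks
from seqdap.synthetic import (
    SyntheticConfig,
    default_carg_pwm,
    default_carg_tffm,
    generate_genome,
    sample_from_pwm,
    sample_from_tffm,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def truth_pwm():
    return default_carg_pwm()


@pytest.fixture(scope="session")
def truth_tffm():
    return default_carg_tffm()


def plant_in_background(truth, n, length, rng, first_order=False):
    """Sequences of ``length`` bp with one motif instance each, random
    position and strand, uniform background."""
    seqs = []
    W = truth.width
    for _ in range(n):
        bg = "".join(rng.choice(list("ACGT"), length))
        pos = int(rng.integers(0, length - W))
        inst = (
            sample_from_tffm(truth, rng) if first_order else sample_from_pwm(truth, rng)
        )
        if rng.random() < 0.5:
            inst = reverse_complement(inst)
        seqs.append(bg[:pos] + inst + bg[pos + W :])
    return seqs


@pytest.fixture(scope="session")
def mixed_fixture():
    """Default-condition synthetic study: genome, truth, dimer and tetramer
    experiments, consensus peaks and the union catalogue."""
    cfg = SyntheticConfig(seed=1)
    genome, truth = generate_genome(cfg)
    reps_t, tracks_t = simulate_experiment(genome, truth, cfg, "tetramer")
    reps_d, tracks_d = simulate_experiment(genome, truth, cfg, "dimer")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cons_t = consensus_peaks(reps_t, tracks_t)
        cons_d = consensus_peaks(reps_d, tracks_d)
        entries = build_union_catalogue(cons_t, cons_d, tracks_t, tracks_d)
        ranked = cfr_rank_and_deciles(entries)
    return {
        "cfg": cfg,
        "genome": genome,
        "truth": truth,
        "replicates": {"tetramer": reps_t, "dimer": reps_d},
        "tracks": {"tetramer": tracks_t, "dimer": tracks_d},
        "consensus": {"tetramer": cons_t, "dimer": cons_d},
        "entries": entries,
        "ranked": ranked,
    }
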