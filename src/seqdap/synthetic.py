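"""Synthetic data with the statistical structure the downstream analysis assumes.

The generator emulates a seq-DAP-seq study on a small GC-heterogeneous
genome: a quasi-palindromic 16-bp CArG-like motif is planted both as single
sites (bound by a dimer) and as site pairs at controlled center-to-center
spacings (bound cooperatively by a tetramer), together with unbound decoy
motif occurrences that give background regions a realistic motif content.
Replicate peak calls with summit jitter, overdispersed coverage tracks, gene
models and differential-expression tables statistically coupled to binding
are all derived from one recorded ground truth, so every downstream stage
has a recovery oracle.

Binding model: the expected signal of a locus is the likelihood ratio (LR)
of its best single site for a dimer, plus LR1·LR2·ω(d) for a site pair at
spacing d when the complex can tetramerize (ω ≥ 1, peaking at the
configured preferred spacings with optional ~10.5-bp helical harmonics).
Signal maps to read-coverage amplitude through a logarithmic response
amp = amp_scale·log1p(signal/K) — LRs of sampled 16-mers span many orders
of magnitude and raw proportionality would be dominated by a handful of
sites.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    CalledPeak,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    write_bedgraph,
    write_fasta,
    write_gene_table,
    write_narrowpeak,
)
from .motifs import PWM, TFFM1, encode, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_carg_pwm",
    "default_carg_tffm",
    "single_dependency_tffm",
    "generate_genome",
    "simulate_experiment",
    "generate_de_table",
    "sample_from_pwm",
    "sample_from_tffm",
]


def default_carg_pwm(pseudo: float = 0.0) -> PWM:
    """Exactly palindromic 16-bp CArG-like truth motif.

    CC-(A/T)6-GG core (positions 4–13, 1-based) with weakly informative
    3-bp flanks; the A/T stretch carries the A-tract/T-tract polarity
    typical of CArG boxes (A-biased 5' half, T-biased 3' half), which keeps
    the instance population unimodal. Generator parameter, not a claim
    about any real motif.
    """
    flank = [0.30, 0.20, 0.20, 0.30]
    c_outer = [0.05, 0.80, 0.10, 0.05]
    c_inner = [0.03, 0.90, 0.02, 0.05]
    a_bias = [0.60, 0.05, 0.05, 0.30]
    t_bias = a_bias[::-1]
    cols = [flank, flank, flank, c_outer, c_inner] + [a_bias] * 3 + [t_bias] * 3
    cols += [c_inner[::-1], c_outer[::-1], flank, flank, flank]
    probs = np.array(cols, dtype=float)
    assert np.allclose(probs, probs[::-1, ::-1])  # palindromic by construction
    return PWM(probs, np.full(4, 0.25), pseudocount=0.01)


def default_carg_tffm() -> TFFM1:
    """First-order CArG-like truth model: A/T-tract positions prefer to
    repeat the previous base (AA/TT runs), a dinucleotide dependency a PWM
    cannot express."""
    pwm = default_carg_pwm()
    W = pwm.width
    transitions = np.repeat(pwm.probs[1:, None, :], 4, axis=1)
    run_a = np.array([0.80, 0.03, 0.03, 0.14])
    run_t = np.array([0.14, 0.03, 0.03, 0.80])
    for pos in range(6, 11):  # A/T stretch, motif positions 7..11 (0-based 6..10)
        transitions[pos - 1, 0] = run_a  # previous base A
        transitions[pos - 1, 3] = run_t  # previous base T
    bg = np.full((4, 4), 0.25)
    return TFFM1(pwm.probs[0].copy(), transitions, bg, pseudocount=0.01)


def single_dependency_tffm(pos: int = 8, strength: float = 0.9) -> TFFM1:
    """First-order truth with one strongly dependent position: at motif
    position ``pos`` (0-based) the base repeats the previous A or T with
    probability ``strength``. Oracle fixture for dependency recovery."""
    pwm = default_carg_pwm()
    transitions = np.repeat(pwm.probs[1:, None, :], 4, axis=1)
    run_a = np.array([strength, 0.02, 0.02, 0.96 - strength])
    transitions[pos - 1, 0] = run_a
    transitions[pos - 1, 3] = run_a[::-1]
    return TFFM1(pwm.probs[0].copy(), transitions, np.full((4, 4), 0.25), 0.01)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic experiment."""

    genome_length: int = 400_000          # total bp across chromosomes
    n_chromosomes: int = 2
    gc_low: float = 0.32                  # per-window GC targets oscillate
    gc_high: float = 0.48                 # between these two values
    gc_window: int = 1000
    n_single_sites: int = 150
    n_pair_sites: int = 100
    n_decoy_sites: int = 1000             # unbound motif occurrences
    spacing_weights: dict[int, float] = field(
        default_factory=lambda: {36: 1 / 3, 46: 1 / 3, 57: 1 / 3}
    )
    s_max: int = 100
    omega_amplitude: float = 8.0          # cooperativity at a preferred spacing
    omega_sd: float = 1.5                 # Gaussian bump width, bp
    omega_harmonics: int = 0              # extra bumps at +10.5 bp steps
    n_replicates: int = 2
    library_size: float = 1_000_000.0
    bg_rate: float = 0.05                 # background reads per bp
    nb_size: float = 20.0                 # NB dispersion (var = mu + mu^2/size)
    amp_scale: float = 5.0                # reads/bp per log-unit of signal
    occupancy_k: float = 50.0             # signal soft scale in amp mapping
    kernel_half: int = 200                # peak shape half-width, bp
    coverage_window: int = 10             # NB drawing granularity, bp
    calling_floor: float = 1.0            # min expected amplitude to call a peak
    summit_jitter_sd: float = 10.0
    edge_margin: int = 1000
    locus_gap: int = 600                  # min separation between bound loci
    gene_length: int = 1500
    gene_spacing: int = 5000
    reg_prob: float = 0.6                 # P(regulated | bound)
    base_reg_prob: float = 0.02           # P(regulated | unbound)
    de_sensitivity: float = 0.9
    de_fp_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_single_sites, self.n_pair_sites, self.n_decoy_sites) < 0:
            raise ValueError("site counts must be >= 0")
        if any(d > self.s_max for d in self.spacing_weights):
            raise ValueError("pair spacings must not exceed s_max")
        if self.omega_amplitude < 1:
            raise ValueError("cooperativity omega must be >= 1")

    def omega(self, d: float) -> float:
        """Cooperativity ω(d) ≥ 1: Gaussian bumps at the preferred spacings."""
        val = 1.0
        for s in self.spacing_weights:
            for h in range(self.omega_harmonics + 1):
                center = s + 10.5 * h
                val += (self.omega_amplitude - 1.0) * float(
                    np.exp(-((d - center) ** 2) / (2 * self.omega_sd**2))
                )
        return val


@dataclass
class SyntheticTruth:
    """Recorded ground truth of one generated dataset."""

    singles: list[dict]        # {chrom, start, strand, lr}
    pairs: list[dict]          # {chrom, start1, strand1, lr1, start2, strand2, lr2, spacing}
    decoys: list[dict]         # {chrom, start, strand}
    genes: list[GeneModel]
    regulated: dict[str, int]  # gene_id -> direction (+1/-1)
    motif_json: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "singles": self.singles,
                "pairs": self.pairs,
                "decoys": self.decoys,
                "genes": [
                    {
                        "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                        "tss": g.tss, "tts": g.tts, "exons": list(map(list, g.exons)),
                    }
                    for g in self.genes
                ],
                "regulated": self.regulated,
                "motif": self.motif_json,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        genes = [
            GeneModel(
                g["gene_id"], g["chrom"], g["strand"], g["tss"], g["tts"],
                tuple(tuple(e) for e in g["exons"]),
            )
            for g in d["genes"]
        ]
        return cls(
            d["singles"], d["pairs"], d["decoys"], genes,
            {k: int(v) for k, v in d["regulated"].items()}, d["motif"], d["seed"],
        )


def sample_from_pwm(pwm: PWM, rng: np.random.Generator) -> str:
    bases = [rng.choice(4, p=col / col.sum()) for col in pwm.probs]
    return "".join("ACGT"[b] for b in bases)


def sample_from_tffm(tffm: TFFM1, rng: np.random.Generator) -> str:
    b = int(rng.choice(4, p=tffm.initial / tffm.initial.sum()))
    out = [b]
    for k in range(tffm.width - 1):
        row = tffm.transitions[k, out[-1]]
        out.append(int(rng.choice(4, p=row / row.sum())))
    return "".join("ACGT"[x] for x in out)


def _lr_of_window(model: PWM | TFFM1, window: str) -> float:
    lo = float(model.log_odds_scan(encode(window), "+")[0])
    return float(np.exp(np.clip(lo, -700, 700)))


def generate_genome(
    config: SyntheticConfig,
    motif: PWM | TFFM1 | None = None,
    max_retries: int = 200,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Draw the background genome and plant single sites, site pairs, decoys,
    and gene models.

    The background follows per-window GC targets oscillating between
    ``gc_low`` and ``gc_high``; motif instances are sampled from the truth
    model and written at recorded positions on random strands, pairs at a
    center-to-center distance drawn from ``spacing_weights``. Colliding or
    overrunning placements are re-drawn; persistent failure raises.
    """
    rng = np.random.default_rng([config.seed, 0])
    motif = motif if motif is not None else default_carg_pwm()
    W = motif.width
    chrom_len = config.genome_length // config.n_chromosomes
    genome_arr: dict[str, np.ndarray] = {}
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        x = np.arange(chrom_len)
        mid = (config.gc_low + config.gc_high) / 2
        amp = (config.gc_high - config.gc_low) / 2
        gc = mid + amp * np.sin(2 * np.pi * x / (20 * config.gc_window))
        # per-base probabilities (A, C, G, T) from the local GC target
        p = np.empty((chrom_len, 4))
        p[:, 1] = p[:, 2] = gc / 2
        p[:, 0] = p[:, 3] = (1 - gc) / 2
        u = rng.random(chrom_len)
        cdf = np.cumsum(p, axis=1)
        genome_arr[name] = (u[:, None] > cdf).sum(axis=1).astype(np.int8)

    chroms = sorted(genome_arr)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def collides(chrom: str, start: int, end: int, gap: int) -> bool:
        for a, b in occupied[chrom]:
            if a - gap < end and start < b + gap:
                return True
        return False

    def place(span: int, gap: int) -> tuple[str, int]:
        for _ in range(max_retries):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            lo = config.edge_margin
            hi = chrom_len - config.edge_margin - span
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            if not collides(chrom, start, start + span, gap):
                occupied[chrom].append((start, start + span))
                return chrom, start
        raise RuntimeError("could not place a site without collision; "
                           "reduce site counts or enlarge the genome")

    def write_instance(chrom: str, start: int) -> tuple[str, float]:
        strand = "+" if rng.random() < 0.5 else "-"
        inst = (
            sample_from_pwm(motif, rng)
            if isinstance(motif, PWM)
            else sample_from_tffm(motif, rng)
        )
        placed = inst if strand == "+" else reverse_complement(inst)
        genome_arr[chrom][start : start + W] = encode(placed)
        return strand, _lr_of_window(motif, inst)

    singles = []
    for _ in range(config.n_single_sites):
        chrom, start = place(W, config.locus_gap)
        strand, lr = write_instance(chrom, start)
        singles.append({"chrom": chrom, "start": start, "strand": strand, "lr": lr})

    spacings = sorted(config.spacing_weights)
    weights = np.array([config.spacing_weights[s] for s in spacings], dtype=float)
    weights /= weights.sum()
    pairs = []
    for _ in range(config.n_pair_sites):
        d = int(spacings[int(rng.choice(len(spacings), p=weights))])
        chrom, start1 = place(W + d, config.locus_gap)
        start2 = start1 + d  # equal widths: center distance == start distance
        strand1, lr1 = write_instance(chrom, start1)
        strand2, lr2 = write_instance(chrom, start2)
        pairs.append(
            {
                "chrom": chrom, "start1": start1, "strand1": strand1, "lr1": lr1,
                "start2": start2, "strand2": strand2, "lr2": lr2, "spacing": d,
            }
        )

    decoys = []
    for _ in range(config.n_decoy_sites):
        chrom, start = place(W, 2)
        strand, _ = write_instance(chrom, start)
        decoys.append({"chrom": chrom, "start": start, "strand": strand})

    genes = _tile_genes(config, chrom_len, chroms)
    regulated = _draw_regulated(config, rng, genes, singles, pairs)
    genome = {
        c: "".join("ACGT"[b] for b in genome_arr[c]) for c in chroms
    }
    truth = SyntheticTruth(
        singles=singles, pairs=pairs, decoys=decoys, genes=genes,
        regulated=regulated, motif_json=motif.to_json(), seed=config.seed,
    )
    return genome, truth


def _tile_genes(config: SyntheticConfig, chrom_len: int, chroms: list[str]) -> list[GeneModel]:
    """Alternating-strand genes tiled at fixed spacing, two exons each."""
    genes = []
    k = 0
    for chrom in chroms:
        pos = config.edge_margin
        while pos + config.gene_length < chrom_len - config.edge_margin:
            strand = "+" if k % 2 == 0 else "-"
            start, end = pos, pos + config.gene_length
            third = config.gene_length // 3
            exons = ((start, start + third), (end - third, end))
            tss, tts = (start, end) if strand == "+" else (end, start)
            genes.append(GeneModel(f"gene{k:04d}", chrom, strand, tss, tts, exons))
            k += 1
            pos += config.gene_spacing
    return genes


def _draw_regulated(
    config: SyntheticConfig,
    rng: np.random.Generator,
    genes: list[GeneModel],
    singles: list[dict],
    pairs: list[dict],
) -> dict[str, int]:
    """Truth regulatory status, coupled to binding: a gene whose regulatory
    region holds a planted site is regulated with ``reg_prob``, others with
    ``base_reg_prob``."""
    from .targets import regulatory_regions

    sites = [(s["chrom"], s["start"]) for s in singles]
    sites += [(p["chrom"], (p["start1"] + p["start2"]) // 2) for p in pairs]
    regions = regulatory_regions(genes)
    regulated: dict[str, int] = {}
    for r in regions:
        has_site = any(
            c == r.interval.chrom and r.interval.start <= pos < r.interval.end
            for c, pos in sites
        )
        prob = config.reg_prob if has_site else config.base_reg_prob
        if rng.random() < prob:
            regulated[r.gene_id] = 1 if rng.random() < 0.5 else -1
    return regulated


# ---------------------------------------------------------------------------
# Experiment simulation


def _loci(truth: SyntheticTruth, config: SyntheticConfig, kind: str, W: int):
    """Per-locus (chrom, summit-position, expected signal)."""
    loci = []
    for s in truth.singles:
        center = s["start"] + (W - 1) / 2
        loci.append((s["chrom"], center, s["lr"]))
    for p in truth.pairs:
        c1 = p["start1"] + (W - 1) / 2
        c2 = p["start2"] + (W - 1) / 2
        best = max(p["lr1"], p["lr2"])
        if kind == "tetramer" and p["spacing"] <= config.s_max:
            signal = best + p["lr1"] * p["lr2"] * config.omega(p["spacing"])
            center = (c1 + c2) / 2
        else:
            signal = best
            center = c1 if p["lr1"] >= p["lr2"] else c2
        loci.append((p["chrom"], center, signal))
    return loci


def expected_amplitude(signal: float, config: SyntheticConfig) -> float:
    """Map binding signal to expected coverage amplitude (reads/bp at summit)."""
    return config.amp_scale * float(np.log1p(signal / config.occupancy_k))


def simulate_experiment(
    genome: dict[str, str],
    truth: SyntheticTruth,
    config: SyntheticConfig,
    complex_kind: str,
) -> tuple[list[list[CalledPeak]], list[CoverageTrack]]:
    """Replicate peak calls and coverage tracks for a dimer or tetramer
    experiment on the given truth.

    Coverage is drawn negative-binomially per ``coverage_window`` around a
    triangular summit-centered kernel; peaks are emitted where the expected
    amplitude exceeds ``calling_floor``, with the summit jittered
    N(0, summit_jitter_sd) per replicate and a −log10 p from the Poisson
    tail of the simulated counts against the background rate.
    """
    if complex_kind not in ("dimer", "tetramer"):
        raise ValueError(f"complex_kind must be 'dimer' or 'tetramer', got {complex_kind!r}")
    W = json.loads(truth.motif_json)
    W = len(W["probs"]) if "probs" in W else len(W["transitions"]) + 1
    kind_tag = 1 if complex_kind == "dimer" else 2
    rng = np.random.default_rng([config.seed, 7, kind_tag])
    loci = _loci(truth, config, complex_kind, W)
    chrom_lens = {c: len(s) for c, s in genome.items()}

    # expected per-bp coverage
    mu = {c: np.full(n, config.bg_rate) for c, n in chrom_lens.items()}
    amps = []
    for chrom, center, signal in loci:
        amp = expected_amplitude(signal, config)
        amps.append(amp)
        lo = int(center) - config.kernel_half
        hi = int(center) + config.kernel_half + 1
        x = np.arange(lo, hi)
        kern = amp * (1 - np.abs(x - center) / config.kernel_half).clip(min=0)
        clo, chi = max(0, lo), min(chrom_lens[chrom], hi)
        mu[chrom][clo:chi] += kern[clo - lo : chi - lo]

    replicate_peaks: list[list[CalledPeak]] = []
    tracks: list[CoverageTrack] = []
    win = config.coverage_window
    for _rep in range(config.n_replicates):
        cov = {}
        for chrom, m in mu.items():
            n = len(m)
            nwin = (n + win - 1) // win
            pad = nwin * win - n
            mw = np.pad(m, (0, pad)).reshape(nwin, win).sum(axis=1)
            # negative binomial: var = mu + mu^2 / size
            size = config.nb_size
            pnb = size / (size + mw)
            counts = rng.negative_binomial(size, np.clip(pnb, 1e-12, 1.0))
            per_bp = np.repeat(counts / win, win)[:n]
            cov[chrom] = per_bp
        tracks.append(CoverageTrack(coverage=cov, library_size=config.library_size))

        peaks = []
        for k, (chrom, center, _signal) in enumerate(loci):
            if amps[k] <= config.calling_floor:
                continue
            summit = int(round(center + rng.normal(0, config.summit_jitter_sd)))
            summit = int(np.clip(summit, 1, chrom_lens[chrom] - 2))
            start = max(0, summit - 200)
            end = min(chrom_lens[chrom], summit + 201)
            obs = float(cov[chrom][max(0, summit - 100) : summit + 100].sum())
            bg_mean = config.bg_rate * 200
            nlp = float(-stats.poisson.logsf(max(obs - 1, 0), bg_mean) / np.log(10))
            nlp = min(nlp, 500.0)
            peaks.append(
                CalledPeak(
                    interval=GenomicInterval(chrom, start, end),
                    summit_offset=summit - start,
                    score=min(1000.0, 10 * nlp),
                    neg_log10_p=nlp,
                    name=f"{complex_kind}_r{_rep}_p{k}",
                    signal=amps[k],
                )
            )
        peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
        replicate_peaks.append(peaks)
    return replicate_peaks, tracks


def generate_de_table(
    truth: SyntheticTruth,
    config: SyntheticConfig,
    sensitivity: float | None = None,
) -> pd.DataFrame:
    """Per-gene (gene_id, logFC, FDR) coupled to the truth regulatory status.

    Truth-regulated genes pass the |logFC| > 1, FDR < 0.05 filter with
    probability ``sensitivity``; all other draws pass with probability
    ``de_fp_rate`` (false positives).
    """
    if sensitivity is None:
        sensitivity = config.de_sensitivity
    rng = np.random.default_rng([config.seed, 11])
    rows = []
    for g in truth.genes:
        direction = truth.regulated.get(g.gene_id, 0)
        if direction != 0 and rng.random() < sensitivity:
            logfc = direction * (1.0 + rng.exponential(1.0))
            fdr = rng.uniform(0.0, 0.05) * 0.999
        elif rng.random() < config.de_fp_rate:
            sign = 1 if rng.random() < 0.5 else -1
            logfc = sign * (1.0 + rng.exponential(1.0))
            fdr = rng.uniform(0.0, 0.05) * 0.999
        else:
            logfc = rng.normal(0, 0.35)
            logfc = float(np.clip(logfc, -0.99, 0.99))
            fdr = rng.uniform(0.05, 1.0)
        rows.append({"gene_id": g.gene_id, "logFC": float(logfc), "FDR": float(fdr)})
    return pd.DataFrame(rows)


def write_fixture(
    outdir: str | Path,
    genome: dict[str, str],
    truth: SyntheticTruth,
    config: SyntheticConfig,
    experiments: dict[str, tuple[list[list[CalledPeak]], list[CoverageTrack]]],
    de_tables: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Write FASTA, per-replicate narrowPeak + bedGraph, gene TSV, DE TSV
    and the truth JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, outdir / "genome.fa")
    write_gene_table(truth.genes, outdir / "genes.tsv")
    (outdir / "truth.json").write_text(truth.to_json())
    (outdir / "config.json").write_text(json.dumps(asdict(config), default=str))
    for name, (replicate_peaks, tracks) in experiments.items():
        for r, (peaks, track) in enumerate(zip(replicate_peaks, tracks)):
            write_narrowpeak(peaks, outdir / f"{name}_rep{r + 1}.narrowPeak")
            write_bedgraph(track, outdir / f"{name}_rep{r + 1}.bedGraph")
    for name, table in (de_tables or {}).items():
        table.to_csv(outdir / f"de_{name}.tsv", sep="\t", index=False)
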