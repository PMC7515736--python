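"""End-to-end orchestration of the analysis stages over a run directory.

Every stage reads its inputs from and writes its outputs under one run
directory; ``run_all`` executes simulate → pool → compare → motif →
evaluate → spacing → targets and records a manifest (config snapshot, seed,
package version, per-file checksums) so that a rerun with the same config
is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparison import build_union_catalogue, cfr_rank_and_deciles, profile_matrices, write_union_bed
from .evaluation import compute_auroc, sample_matched_negatives, write_roc_tsv
from .genome_io import read_bedgraph, read_fasta, read_gene_table, read_narrowpeak
from .motifs import load_model, select_training_peaks, train_pwm, train_tffm
from .pooling import consensus_peaks, read_consensus_bed, write_consensus_bed
from .spacing import (
    PREFERRED_SPACINGS,
    decile_spacing_trend,
    normalized_enrichment,
    pair_spacing_counts,
    preferred_spacing_fraction_by_decile,
)
from .synthetic import (
    SyntheticConfig,
    generate_de_table,
    generate_genome,
    simulate_experiment,
    write_fixture,
)
from .targets import (
    bound_genes,
    de_gene_sets,
    overlap_significance,
    read_de_table,
    regulatory_regions,
    write_gene_set,
)

logger = logging.getLogger(__name__)

EXPERIMENTS = ("tetramer", "dimer")

#: validated parameter ranges; every printed constant is a named default
DEFAULT_PARAMS: dict = {
    "min_replicates": 2,
    "reproducibility_alpha": 1e-4,
    "half_width": 200,
    "overlap_f": 0.8,
    "nonoverlap_max": 0.5,
    "specificity_fold": 2.0,
    "training_n": 600,
    "motif_width": 16,
    "site_threshold": 0.7,
    "s_max": 100,
    "preferred_spacings": sorted(PREFERRED_SPACINGS),
    "gc_bin": 0.05,
    "logfc_min": 1.0,
    "fdr_max": 0.05,
    "upstream": 3000,
    "downstream": 1000,
}

_RANGES = {
    "min_replicates": (1, 100),
    "reproducibility_alpha": (0.0, 1.0),
    "half_width": (1, 10_000),
    "overlap_f": (0.0, 1.0),
    "nonoverlap_max": (0.0, 1.0),
    "specificity_fold": (1.0, 1000.0),
    "training_n": (1, 1_000_000),
    "motif_width": (4, 64),
    "site_threshold": (0.0, 1.0),
    "s_max": (1, 10_000),
    "gc_bin": (0.001, 1.0),
    "logfc_min": (0.0, 100.0),
    "fdr_max": (0.0, 1.0),
    "upstream": (0, 1_000_000),
    "downstream": (0, 1_000_000),
}


def validate_params(params: dict) -> dict:
    """Merge user parameters over the defaults and range-check them all
    before any stage runs."""
    merged = dict(DEFAULT_PARAMS)
    unknown = set(params) - set(merged)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    merged.update(params)
    for key, (lo, hi) in _RANGES.items():
        v = merged[key]
        if not (lo <= v <= hi) or (key in ("overlap_f", "gc_bin") and v <= lo):
            raise ValueError(f"parameter {key}={v} outside valid range ({lo}, {hi}]")
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Run:
    """One run directory with its parameters and seed."""

    def __init__(self, outdir: str | Path, params: dict | None = None, seed: int = 0):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.params = validate_params(params or {})
        self.seed = int(seed)

    # -- simulate -----------------------------------------------------------
    def simulate(self, synth_overrides: dict | None = None) -> None:
        cfg = SyntheticConfig(seed=self.seed, **(synth_overrides or {}))
        genome, truth = generate_genome(cfg)
        experiments = {
            name: simulate_experiment(genome, truth, cfg, name) for name in EXPERIMENTS
        }
        de_tables = {
            "comparison1": generate_de_table(truth, cfg),
            "comparison2": generate_de_table(
                truth, dataclasses.replace(cfg, seed=cfg.seed + 104729)
            ),
        }
        write_fixture(self.outdir, genome, truth, cfg, experiments, de_tables)
        self._manifest_update("simulate")

    # -- pool ---------------------------------------------------------------
    def pool(self) -> None:
        cfg = self._synth_config()
        chrom_sizes = {c: len(s) for c, s in self._genome().items()}
        for name in EXPERIMENTS:
            reps, tracks = self._replicates(name, cfg, chrom_sizes)
            cons = consensus_peaks(
                reps, tracks,
                reproducibility_alpha=self.params["reproducibility_alpha"],
                min_replicates=self.params["min_replicates"],
            )
            write_consensus_bed(cons, self.outdir / f"{name}_consensus.bed")
        self._manifest_update("pool")

    # -- compare ------------------------------------------------------------
    def compare(self) -> None:
        cfg = self._synth_config()
        chrom_sizes = {c: len(s) for c, s in self._genome().items()}
        cons = {n: read_consensus_bed(self.outdir / f"{n}_consensus.bed") for n in EXPERIMENTS}
        tracks = {
            n: self._replicates(n, cfg, chrom_sizes)[1] for n in EXPERIMENTS
        }
        entries = build_union_catalogue(
            cons["tetramer"], cons["dimer"], tracks["tetramer"], tracks["dimer"],
            overlap_f=self.params["overlap_f"],
            nonoverlap_max=self.params["nonoverlap_max"],
        )
        ranked = cfr_rank_and_deciles(entries)
        write_union_bed(entries, self.outdir / "union_catalogue.bed")
        mat_a, mat_b, mean_a, mean_b = profile_matrices(
            ranked, tracks["tetramer"], tracks["dimer"]
        )
        np.savetxt(self.outdir / "heatmap_tetramer.tsv", mat_a, delimiter="\t", fmt="%.6g")
        np.savetxt(self.outdir / "heatmap_dimer.tsv", mat_b, delimiter="\t", fmt="%.6g")
        pd.DataFrame({"tetramer": mean_a, "dimer": mean_b}).to_csv(
            self.outdir / "mean_profiles.tsv", sep="\t", index=False
        )
        self._manifest_update("compare")

    # -- motif --------------------------------------------------------------
    def motif(self) -> None:
        genome = self._genome()
        cons = read_consensus_bed(self.outdir / "tetramer_consensus.bed")
        seqs = select_training_peaks(cons, genome, n=self.params["training_n"])
        # peak windows are summit-centered, so a centered positional prior
        # keeps the site posterior where the signal is
        pwm = train_pwm(
            seqs, W=self.params["motif_width"], seed=self.seed, center_prior_sd=50.0
        )
        tffm = train_tffm(seqs, pwm, seed=self.seed, center_prior_sd=50.0)
        (self.outdir / "pwm.json").write_text(pwm.to_json())
        (self.outdir / "tffm.json").write_text(tffm.to_json())
        (self.outdir / "pwm.meme").write_text(pwm.to_meme("carg_like"))
        self._manifest_update("motif")

    # -- evaluate -----------------------------------------------------------
    def evaluate(self) -> None:
        genome = self._genome()
        genes = read_gene_table(self.outdir / "genes.tsv")
        cons = read_consensus_bed(self.outdir / "tetramer_consensus.bed")
        ranked = sorted(
            cons, key=lambda p: (-p.mean_norm_cov, p.interval.chrom, p.interval.start)
        )
        held_out = ranked[self.params["training_n"]:]
        if len(held_out) < 10:
            logger.warning("few held-out peaks (%d); evaluating on all", len(held_out))
            held_out = ranked
        positives = [p.interval for p in held_out]
        negatives = sample_matched_negatives(
            positives, genome, genes, [p.interval for p in cons],
            gc_bin=self.params["gc_bin"], seed=self.seed,
        )
        pos_seqs = [genome[iv.chrom][iv.start:iv.end] for iv in positives]
        neg_seqs = negatives.sequences(genome)
        metrics = {}
        for name in ("pwm", "tffm"):
            model = load_model(self.outdir / f"{name}.json")
            auroc, roc = compute_auroc(model, pos_seqs, neg_seqs)
            metrics[f"auroc_{name}"] = auroc
            write_roc_tsv(roc, self.outdir / f"roc_{name}.tsv")
        with open(self.outdir / "negatives.bed", "w") as fh:
            for iv, orig, gc in zip(negatives.regions, negatives.origins, negatives.gc):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{orig}\t{gc:.4f}\t.\n")
        (self.outdir / "evaluation.json").write_text(json.dumps(metrics, indent=2))
        self._manifest_update("evaluate")

    # -- spacing ------------------------------------------------------------
    def spacing(self) -> None:
        genome = self._genome()
        model = load_model(self.outdir / "tffm.json")
        cons = read_consensus_bed(self.outdir / "tetramer_consensus.bed")
        pos_seqs = [
            genome[p.interval.chrom][p.interval.start:p.interval.end] for p in cons
        ]
        genes = read_gene_table(self.outdir / "genes.tsv")
        # a denser background set (5x) keeps the per-spacing background
        # frequencies away from zero at desk scale
        positives = [p.interval for p in cons]
        negatives = sample_matched_negatives(
            positives * 5, genome, genes, positives,
            gc_bin=self.params["gc_bin"], seed=self.seed + 1,
        )
        neg_seqs = negatives.sequences(genome)
        thr, s_max = self.params["site_threshold"], self.params["s_max"]
        pos_prof = pair_spacing_counts(pos_seqs, model, thr, s_max)
        neg_prof = pair_spacing_counts(neg_seqs, model, thr, s_max)
        enrich = normalized_enrichment(pos_prof, neg_prof)
        with open(self.outdir / "spacing_profile.tsv", "w") as fh:
            f_pos = pos_prof.frequencies()
            f_neg = neg_prof.frequencies()
            fh.write("n\tC_pos\tC_neg\tf_pos\tf_neg\tN\n")
            for n in range(s_max + 1):
                fh.write(
                    f"{n}\t{int(pos_prof.counts[n])}\t{int(neg_prof.counts[n])}\t"
                    f"{f_pos[n]:.8g}\t{f_neg[n]:.8g}\t{enrich[n]:.8g}\n"
                )
        # decile analysis over the union catalogue
        deciles: dict[int, list[str]] = {}
        with open(self.outdir / "union_catalogue.bed") as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                d = int(f[10])
                if d > 0:
                    deciles.setdefault(d, []).append(
                        genome[f[0]][int(f[1]):int(f[2])]
                    )
        fractions = preferred_spacing_fraction_by_decile(
            deciles, model, thr, frozenset(self.params["preferred_spacings"]), s_max
        )
        rho, p = decile_spacing_trend(fractions)
        out = {"fraction_by_decile": fractions, "spearman_rho": rho, "spearman_p": p}
        (self.outdir / "spacing_deciles.json").write_text(json.dumps(out, indent=2))
        self._manifest_update("spacing")

    # -- targets ------------------------------------------------------------
    def targets(self) -> None:
        genes = read_gene_table(self.outdir / "genes.tsv")
        regions = regulatory_regions(
            genes, upstream=self.params["upstream"], downstream=self.params["downstream"]
        )
        cons = read_consensus_bed(self.outdir / "tetramer_consensus.bed")
        bound = bound_genes([p.interval for p in cons], regions)
        tables = [
            ("regulator", read_de_table(self.outdir / "de_comparison1.tsv")),
            ("regulator", read_de_table(self.outdir / "de_comparison2.tsv")),
        ]
        de = de_gene_sets(
            tables, logfc_min=self.params["logfc_min"], fdr_max=self.params["fdr_max"]
        )
        universe = len(genes)
        both = bound & de.ids()
        k, p, nlp = overlap_significance(bound, de.ids(), universe)
        write_gene_set(bound, self.outdir / "bound_genes.txt")
        write_gene_set(de.ids(), self.outdir / "regulated_genes.txt")
        write_gene_set(both, self.outdir / "bound_and_regulated_genes.txt")
        summary = {
            "n_bound": len(bound),
            "n_regulated": len(de.ids()),
            "n_bound_and_regulated": k,
            "universe": universe,
            "hypergeom_p": p,
            "neg_log10_p": nlp,
        }
        (self.outdir / "targets_summary.json").write_text(json.dumps(summary, indent=2))
        self._manifest_update("targets")

    # -- plumbing -----------------------------------------------------------
    def run_all(self, synth_overrides: dict | None = None) -> None:
        self.simulate(synth_overrides)
        self.pool()
        self.compare()
        self.motif()
        self.evaluate()
        self.spacing()
        self.targets()

    def _genome(self) -> dict[str, str]:
        path = self.outdir / "genome.fa"
        if not path.exists():
            raise FileNotFoundError(
                "genome.fa not found: run the 'simulate' stage first"
            )
        return read_fasta(path)

    def _synth_config(self) -> SyntheticConfig:
        path = self.outdir / "config.json"
        if not path.exists():
            raise FileNotFoundError("config.json not found: run 'simulate' first")
        d = json.loads(path.read_text())
        d["spacing_weights"] = {int(k): v for k, v in d["spacing_weights"].items()}
        return SyntheticConfig(**d)

    def _replicates(self, name: str, cfg: SyntheticConfig, chrom_sizes: dict):
        reps, tracks = [], []
        r = 1
        while (self.outdir / f"{name}_rep{r}.narrowPeak").exists():
            reps.append(read_narrowpeak(self.outdir / f"{name}_rep{r}.narrowPeak"))
            tracks.append(
                read_bedgraph(
                    self.outdir / f"{name}_rep{r}.bedGraph", chrom_sizes, cfg.library_size
                )
            )
            r += 1
        if not reps:
            raise FileNotFoundError(
                f"no replicates found for {name}: run 'simulate' first"
            )
        return reps, tracks

    def _manifest_update(self, stage: str) -> None:
        path = self.outdir / "manifest.json"
        manifest = json.loads(path.read_text()) if path.exists() else {
            "version": __version__,
            "seed": self.seed,
            "params": {k: (v if not isinstance(v, float) else v) for k, v in self.params.items()},
            "stages": {},
        }
        checksums = {
            f.name: _sha256(f)
            for f in sorted(self.outdir.iterdir())
            if f.is_file() and f.name != "manifest.json"
        }
        manifest["stages"][stage] = True
        manifest["checksums"] = checksums
        path.write_text(json.dumps(manifest, indent=2, default=str))
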