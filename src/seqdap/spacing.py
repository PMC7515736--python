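"""CArG-box intersite-spacing statistics.

Within each bound region, every unordered pair of motif hits above a score
threshold contributes one count at its center-to-center distance n
(0 <= n <= S_max). Counts C_n are normalized to frequencies
f_n = C_n / sum_k C_k, and the spacing enrichment of a positive (bound)
region set against a background set is the frequency ratio
N_n = f_pos,n / f_neg,n. Site orientation is deliberately ignored: the
CArG-box models are quasi-palindromic, so strand combinations are collapsed.

Spacing is measured center-to-center (for fixed-width sites this equals the
offset difference); an edge-to-edge convention is available via
``edge_to_edge=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .motifs import PWM, TFFM1, scan_region

logger = logging.getLogger(__name__)

__all__ = [
    "SpacingProfile",
    "pair_spacing_counts",
    "spacing_frequency",
    "normalized_enrichment",
    "preferred_spacing_fraction_by_decile",
    "annotate_probe",
    "PREFERRED_SPACINGS",
]

# enriched tetramer intersite spacings: ~36-37, 46-47 and ~57 bp
PREFERRED_SPACINGS = frozenset({36, 37, 46, 47, 57})


@dataclass
class SpacingProfile:
    """Pair-spacing counts C_n for n = 0..S_max and derived frequencies."""

    counts: np.ndarray
    s_max: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.s_max + 1:
            raise ValueError("counts must have length S_max + 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        return spacing_frequency(self.counts)

    def to_tsv(self, path) -> None:
        f = self.frequencies() if self.total > 0 else np.full(self.s_max + 1, np.nan)
        with open(path, "w") as fh:
            fh.write("n\tC\tf\n")
            for n in range(self.s_max + 1):
                fh.write(f"{n}\t{int(self.counts[n])}\t{f[n]:.8g}\n")


def pair_spacing_counts(
    region_sequences: Iterable[str],
    model: PWM | TFFM1,
    threshold: float = 0.7,
    s_max: int = 100,
    min_spacing: int = 0,
) -> SpacingProfile:
    """Count thresholded site-pair spacings within each region.

    All unordered pairs of hits (any strand combination) with
    center-to-center distance min_spacing <= n <= s_max increment C_n.
    Pairs never span region boundaries. Overlapping sites (n < W) are
    counted by default — raise ``min_spacing`` to exclude them.
    """
    counts = np.zeros(s_max + 1, dtype=np.int64)
    for k, seq in enumerate(region_sequences):
        _, hits = scan_region(model, seq, threshold, region_id=f"r{k}")
        if len(hits) < 2:
            continue
        offsets = np.array(sorted(h.offset for h in hits))
        # center-to-center distance equals offset difference for equal-width sites
        d = np.abs(offsets[:, None] - offsets[None, :])
        iu = np.triu_indices(len(offsets), k=1)
        for n in d[iu]:
            if min_spacing <= n <= s_max:
                counts[n] += 1
    return SpacingProfile(counts=counts, s_max=s_max)


def spacing_frequency(counts: np.ndarray) -> np.ndarray:
    """f_n = C_n / sum_k C_k; an all-zero profile is undefined."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("spacing profile undefined: no site pairs counted")
    return counts / total


def normalized_enrichment(
    pos: SpacingProfile, neg: SpacingProfile
) -> np.ndarray:
    """N_n = f_pos,n / f_neg,n; NaN (flagged undefined, logged) where f_neg,n = 0."""
    if pos.s_max != neg.s_max:
        raise ValueError("profiles must share S_max")
    f_pos = pos.frequencies()
    f_neg = neg.frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.where(f_neg > 0, f_pos / f_neg, np.nan)
    undef = int(((f_neg == 0) & (f_pos > 0)).sum())
    if undef:
        logger.info(
            "normalized enrichment undefined at %d spacings (background empty)", undef
        )
    return n


def preferred_spacing_fraction_by_decile(
    decile_sequences: Mapping[int, Sequence[str]],
    model: PWM | TFFM1,
    threshold: float = 0.7,
    preferred: frozenset[int] | set[int] = PREFERRED_SPACINGS,
    s_max: int = 100,
) -> dict[int, float]:
    """Percentage of regions per CFR decile containing >= 1 preferred-spacing
    site pair.

    ``decile_sequences`` maps decile index (1 = strongest CFR) to the region
    sequences assigned to it. Empty deciles return NaN (logged).
    """
    if not preferred:
        raise ValueError("preferred spacing set must be non-empty")
    out: dict[int, float] = {}
    for d, seqs in sorted(decile_sequences.items()):
        if not seqs:
            logger.info("decile %d empty; percentage undefined", d)
            out[d] = float("nan")
            continue
        n_pos = 0
        for k, seq in enumerate(seqs):
            _, hits = scan_region(model, seq, threshold, region_id=f"d{d}_r{k}")
            offsets = sorted(h.offset for h in hits)
            found = False
            for i in range(len(offsets)):
                for j in range(i + 1, len(offsets)):
                    if abs(offsets[j] - offsets[i]) in preferred:
                        found = True
                        break
                if found:
                    break
            n_pos += found
        out[d] = 100.0 * n_pos / len(seqs)
    return out


def decile_spacing_trend(fractions: Mapping[int, float]) -> tuple[float, float]:
    """Spearman correlation of decile index vs preferred-spacing percentage.

    A negative rho means the percentage falls off from the strongest-CFR
    decile to the weakest, the signature of tetramer-driven pair binding.
    """
    items = [(d, v) for d, v in sorted(fractions.items()) if np.isfinite(v)]
    rho, p = stats.spearmanr([d for d, _ in items], [v for _, v in items])
    return float(rho), float(p)


@dataclass(frozen=True)
class ProbeBox:
    """One annotated box occurrence in a probe sequence."""

    pattern: str
    start: int
    end: int

    @property
    def center(self) -> float:
        return (self.start + self.end - 1) / 2


def annotate_probe(
    sequence: str,
    patterns: Sequence[str] | None = None,
    model: PWM | TFFM1 | None = None,
    threshold: float = 0.7,
) -> tuple[list[ProbeBox], dict[tuple[int, int], float]]:
    """Annotate box positions and pairwise center-to-center distances.

    Either exact nucleotide ``patterns`` (searched on the given strand; every
    occurrence reported, absent patterns yield no annotation) or a motif
    ``model`` with a score threshold. Returns (boxes, {(i, j): distance})
    with boxes indexed in report order.
    """
    boxes: list[ProbeBox] = []
    if patterns is not None:
        for pat in patterns:
            start = sequence.find(pat)
            while start != -1:
                boxes.append(ProbeBox(pat, start, start + len(pat)))
                start = sequence.find(pat, start + 1)
    elif model is not None:
        _, hits = scan_region(model, sequence, threshold, region_id="probe")
        W = model.width
        for h in hits:
            boxes.append(ProbeBox(sequence[h.offset : h.offset + W], h.offset, h.offset + W))
    else:
        raise ValueError("provide either patterns or a model")
    distances = {
        (i, j): abs(boxes[j].center - boxes[i].center)
        for i in range(len(boxes))
        for j in range(i + 1, len(boxes))
    }
    return boxes, distances
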