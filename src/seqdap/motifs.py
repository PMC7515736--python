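"""Binding-site models: 0-order PWM and first-order TFFM.

Both model classes score a W-mer by the likelihood ratio LR between the
motif model and a background model, mapped to a bounded site score
s = LR / (1 + LR) in [0, 1] (0.5 means indistinguishable from background,
1.0 is the ceiling). Training is seeded expectation-maximisation under a
ZOOPS assumption (zero-or-one site per sequence, either strand): the PWM
trainer plays the role MEME fills for 0-order motifs, with optional
reverse-complement symmetrisation for quasi-palindromic motifs such as the
CArG box; the TFFM trainer fits the first-order (dinucleotide-dependent)
emission chain starting from a PWM initialisation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "TFFM1",
    "SiteHit",
    "encode",
    "reverse_complement",
    "select_training_peaks",
    "train_pwm",
    "train_tffm",
    "score_site",
    "scan_region",
]

_ALPHABET = "ACGT"
_LOOKUP = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(_ALPHABET):
    _LOOKUP[ord(_c)] = _i
    _LOOKUP[ord(_c.lower())] = _i

_TINY = 1e-300


def encode(seq: str) -> np.ndarray:
    """Encode to int8: A=0 C=1 G=2 T=3, anything else (N, ...) = -1."""
    return _LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTacgtN", "TGCAtgcaN")
    return seq.translate(comp)[::-1]


@dataclass(frozen=True)
class SiteHit:
    """A thresholded motif match inside one region."""

    region_id: str
    offset: int
    strand: str
    score: float

    def center(self, width: int) -> float:
        """Site center in region coordinates: offset + (W-1)/2."""
        return self.offset + (width - 1) / 2


# ---------------------------------------------------------------------------
# PWM


@dataclass
class PWM:
    """Position weight matrix: independent per-position probabilities.

    ``probs`` has shape (W, 4) over A,C,G,T; ``background`` is the 0-order
    background distribution (strand-symmetric).
    """

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (W, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("all probabilities must be > 0 (apply a pseudocount)")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.background[::-1].copy(),
                   self.pseudocount)

    def log_odds_scan(self, encoded: np.ndarray, strand: str = "+") -> np.ndarray:
        """log-LR at every offset on one strand; -inf where the window has an N."""
        W = self.width
        n = len(encoded) - W + 1
        if n <= 0:
            return np.empty(0)
        probs = self.probs if strand == "+" else self.probs[::-1, ::-1]
        bg = self.background if strand == "+" else self.background[::-1]
        table = np.log(probs) - np.log(bg)[None, :]  # (W, 4)
        out = np.zeros(n)
        bad = np.zeros(n, dtype=bool)
        for j in range(W):
            col = encoded[j : j + n]
            ok = col >= 0
            bad |= ~ok
            out[ok] += table[j, col[ok]]
        out[bad] = -np.inf
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "pwm",
                "probs": self.probs.tolist(),
                "background": self.background.tolist(),
                "pseudocount": self.pseudocount,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PWM":
        d = json.loads(text)
        return cls(np.array(d["probs"]), np.array(d["background"]), d["pseudocount"])

    def to_meme(self, name: str = "motif1") -> str:
        """Minimal MEME motif format for interoperability."""
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "Background letter frequencies",
            " ".join(f"{b} {f:.6f}" for b, f in zip(_ALPHABET, self.background)),
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width}",
        ]
        for row in self.probs:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# TFFM (first-order)


def _stationary(trans: np.ndarray) -> np.ndarray:
    """Stationary distribution of a 4x4 row-stochastic matrix."""
    vals, vecs = np.linalg.eig(trans.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()


@dataclass
class TFFM1:
    """First-order motif model: P(x1) and P(x_i | x_{i-1}) for i = 2..W,
    against a first-order background chain started at its stationary
    distribution."""

    initial: np.ndarray              # (4,)
    transitions: np.ndarray          # (W-1, 4, 4), rows are P(x_i | x_{i-1})
    bg_transitions: np.ndarray       # (4, 4)
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.bg_transitions = np.asarray(self.bg_transitions, dtype=float)
        if not np.allclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transitions.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("every conditional row must sum to 1")
        self.bg_start = _stationary(self.bg_transitions)

    @property
    def width(self) -> int:
        return self.transitions.shape[0] + 1

    @property
    def background(self) -> np.ndarray:
        """Stationary single-nucleotide background (for score parity with PWM)."""
        return self.bg_start

    def log_odds_scan(self, encoded: np.ndarray, strand: str = "+") -> np.ndarray:
        W = self.width
        n = len(encoded) - W + 1
        if n <= 0:
            return np.empty(0)
        log_init = np.log(self.initial)
        log_trans = np.log(self.transitions)
        log_bg_start = np.log(self.bg_start)
        log_bg_trans = np.log(self.bg_trans_sym())
        out = np.zeros(n)
        bad = np.zeros(n, dtype=bool)
        if strand == "+":
            first = encoded[0:n]
            ok = first >= 0
            bad |= ~ok
            out[ok] += log_init[first[ok]] - log_bg_start[first[ok]]
            for k in range(1, W):
                a = encoded[k - 1 : k - 1 + n]
                b = encoded[k : k + n]
                ok = (a >= 0) & (b >= 0)
                bad |= ~ok
                out[ok] += (
                    log_trans[k - 1, a[ok], b[ok]] - log_bg_trans[a[ok], b[ok]]
                )
        else:
            # score of the reverse complement of each window: motif pair term
            # for window bases (y_j, y_{j+1}) is trans[W-2-j][comp(y_{j+1}), comp(y_j)]
            last = encoded[W - 1 : W - 1 + n]
            ok = last >= 0
            bad |= ~ok
            out[ok] += log_init[3 - last[ok]] - log_bg_start[3 - last[ok]]
            for j in range(W - 1):
                a = encoded[j : j + n]
                b = encoded[j + 1 : j + 1 + n]
                ok = (a >= 0) & (b >= 0)
                bad |= ~ok
                out[ok] += (
                    log_trans[W - 2 - j, 3 - b[ok], 3 - a[ok]]
                    - log_bg_trans[3 - b[ok], 3 - a[ok]]
                )
        out[bad] = -np.inf
        return out

    def bg_trans_sym(self) -> np.ndarray:
        return self.bg_transitions

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "tffm1",
                "initial": self.initial.tolist(),
                "transitions": self.transitions.tolist(),
                "bg_transitions": self.bg_transitions.tolist(),
                "pseudocount": self.pseudocount,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TFFM1":
        d = json.loads(text)
        return cls(
            np.array(d["initial"]),
            np.array(d["transitions"]),
            np.array(d["bg_transitions"]),
            d["pseudocount"],
        )


# ---------------------------------------------------------------------------
# Training-set selection


def select_training_peaks(peaks, genome: dict[str, str], n: int = 600) -> list[str]:
    """Sequences of the n best consensus peaks, judged by mean normalized
    coverage (ties broken by coordinate for run-to-run determinism).

    Returns 401-bp sequences clipped at chromosome bounds. Fewer than n
    peaks triggers a warning and all are used.
    """
    if not genome:
        raise ValueError("genome sequence is required to extract training peaks")
    ranked = sorted(
        peaks,
        key=lambda p: (-p.mean_norm_cov, p.interval.chrom, p.interval.start),
    )
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} peaks available for a training set of {n}; using all"
        )
    chosen = ranked[:n]
    seqs = []
    for p in chosen:
        chrom_seq = genome[p.interval.chrom]
        lo = max(0, p.interval.start)
        hi = min(len(chrom_seq), p.interval.end)
        seqs.append(chrom_seq[lo:hi])
    return seqs


# ---------------------------------------------------------------------------
# Background estimation (strand-symmetric)


def _background_mono(encoded_seqs: list[np.ndarray]) -> np.ndarray:
    counts = np.ones(4)
    for e in encoded_seqs:
        valid = e[e >= 0]
        counts += np.bincount(valid, minlength=4)
    counts = (counts + counts[::-1]) / 2  # strand symmetry
    return counts / counts.sum()


def _background_dinuc(encoded_seqs: list[np.ndarray]) -> np.ndarray:
    counts = np.ones((4, 4))
    for e in encoded_seqs:
        a, b = e[:-1], e[1:]
        ok = (a >= 0) & (b >= 0)
        np.add.at(counts, (a[ok], b[ok]), 1.0)
    counts = (counts + counts[::-1, ::-1].T) / 2  # strand symmetry (reversibility)
    return counts / counts.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# ZOOPS-EM PWM training


def _em_pwm(
    E: np.ndarray,
    Ec: np.ndarray,
    bg: np.ndarray,
    probs: np.ndarray,
    gamma_site: float,
    pseudocount: float,
    max_iter: int,
    tol: float,
    position_prior: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Run ZOOPS EM iterations from a given PWM start; returns
    (probs, gamma_site, final log-likelihood). ``position_prior`` is an
    optional per-offset prior (length m, summing to 1); default uniform."""
    W = probs.shape[0]
    n, L = E.shape
    m = L - W + 1
    log_bg = np.log(bg)
    oops = gamma_site >= 1.0  # exactly one site per sequence: no gamma update
    if oops:
        gamma_site = 1.0 - 1e-9
    if position_prior is None:
        pos_p = np.full(m, 1.0 / m)
    else:
        pos_p = np.asarray(position_prior, dtype=float)
        pos_p = pos_p / pos_p.sum()
    prev_ll = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        table = np.log(probs) - log_bg[None, :]
        lo_f = _pwm_matrix_logodds(E, table)
        lo_r = _pwm_matrix_logodds(E, table[::-1, ::-1])
        lr_f = np.exp(np.clip(lo_f, -700, 700))
        lr_r = np.exp(np.clip(lo_r, -700, 700))
        w_f = gamma_site / 2 * pos_p[None, :] * lr_f
        w_r = gamma_site / 2 * pos_p[None, :] * lr_r
        total = (1.0 - gamma_site) + w_f.sum(axis=1) + w_r.sum(axis=1)
        ll = float(np.log(total + _TINY).sum())
        resp_f = w_f / total[:, None]
        resp_r = w_r / total[:, None]
        counts = np.full((W, 4), pseudocount)
        for j in range(W):
            col = Ec[:, j : j + m]
            np.add.at(
                counts[j], col.ravel(),
                np.where(E[:, j : j + m] >= 0, resp_f, 0.0).ravel(),
            )
            # reverse-strand window at offset i contributes the complement of
            # its base at window position W-1-j to motif position j
            colr = Ec[:, W - 1 - j : W - 1 - j + m]
            np.add.at(
                counts[j], (3 - colr).ravel(),
                np.where(E[:, W - 1 - j : W - 1 - j + m] >= 0, resp_r, 0.0).ravel(),
            )
        probs = counts / counts.sum(axis=1, keepdims=True)
        if not oops:
            gamma_site = min(max((resp_f.sum() + resp_r.sum()) / n, 1e-6), 1 - 1e-6)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return probs, gamma_site, ll


def _seed_wmer(encoded_seqs: list[np.ndarray], W: int, bg: np.ndarray) -> str | None:
    """Most background-enriched canonical W-mer occurring at least twice,
    or None when every W-mer is unique."""
    codes: list[np.ndarray] = []
    powers = 4 ** np.arange(W, dtype=np.int64)
    for e in encoded_seqs:
        m = len(e) - W + 1
        if m <= 0:
            continue
        ec = np.where(e >= 0, e, 0).astype(np.int64)
        fwd = np.zeros(m, dtype=np.int64)
        rev = np.zeros(m, dtype=np.int64)
        bad = np.zeros(m, dtype=bool)
        for j in range(W):
            bad |= e[j : j + m] < 0
            fwd += ec[j : j + m] * powers[j]
            rev += (3 - ec[j : j + m]) * powers[W - 1 - j]
        canon = np.minimum(fwd, rev)[~bad]
        codes.append(canon)
    if not codes or sum(len(c) for c in codes) == 0:
        raise ValueError(f"no valid {W}-mer found; try a smaller width")
    allcodes = np.concatenate(codes)
    uniq, counts = np.unique(allcodes, return_counts=True)
    repeated = counts >= 2
    if not repeated.any():
        return None
    uniq, counts = uniq[repeated], counts[repeated]
    # expected log-probability of each unique W-mer under the background
    log_bg = np.log(bg)
    digits = uniq.copy()
    log_exp = np.zeros(len(uniq))
    for _ in range(W):
        log_exp += log_bg[digits % 4]
        digits //= 4
    enrich = np.log(counts) - log_exp
    best_code = int(uniq[np.argmax(enrich)])
    letters = []
    for _ in range(W):
        letters.append(_ALPHABET[best_code % 4])
        best_code //= 4
    return "".join(letters)


def _pad_encode(sequences: Sequence[str]) -> np.ndarray:
    """Stack sequences into an (n, Lmax) int8 matrix, right-padded with -1.

    Padded/N positions render any window touching them invalid (LR 0), so
    they drop out of the EM responsibilities.
    """
    lmax = max(len(s) for s in sequences)
    E = np.full((len(sequences), lmax), -1, dtype=np.int8)
    for i, s in enumerate(sequences):
        E[i, : len(s)] = encode(s)
    return E


def _pwm_matrix_logodds(E: np.ndarray, table: np.ndarray) -> np.ndarray:
    """(n, m) log-odds of every window under a (W,4) log-odds table."""
    W = table.shape[0]
    n, L = E.shape
    m = L - W + 1
    Ec = np.where(E >= 0, E, 0)
    out = np.zeros((n, m))
    bad = np.zeros((n, m), dtype=bool)
    for j in range(W):
        col = E[:, j : j + m]
        bad |= col < 0
        out += table[j, Ec[:, j : j + m]]
    out[bad] = -np.inf
    return out


def _kmer_codes(e: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fwd codes, rc codes, valid mask) for every k-window of one sequence."""
    m = len(e) - k + 1
    if m <= 0:
        z = np.empty(0, dtype=np.int64)
        return z, z, np.empty(0, dtype=bool)
    powers = 4 ** np.arange(k, dtype=np.int64)
    ec = np.where(e >= 0, e, 0).astype(np.int64)
    fwd = np.zeros(m, dtype=np.int64)
    rev = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        ok &= e[j : j + m] >= 0
        fwd += ec[j : j + m] * powers[j]
        rev += (3 - ec[j : j + m]) * powers[k - 1 - j]
    return fwd, rev, ok


def _core_kmer_seed(
    encoded: list[np.ndarray], W: int, bg: np.ndarray, k: int = 8
) -> np.ndarray | None:
    """Initial PWM from aligned occurrences of the most enriched core k-mer.

    The canonical (strand-collapsed) k-mer with the highest
    observed/expected ratio anchors an alignment: every occurrence is
    expanded to a W-window with the k-mer centered (reverse-complemented
    occurrences flipped into the k-mer's orientation) and base frequencies
    are averaged.
    """
    k = min(k, W)
    per_seq = [_kmer_codes(e, k) for e in encoded]
    canon = [np.minimum(f, r)[ok] for f, r, ok in per_seq]
    if not canon or sum(len(c) for c in canon) == 0:
        return None
    uniq, counts = np.unique(np.concatenate(canon), return_counts=True)
    log_bg = np.log(bg)
    digits = uniq.copy()
    log_exp = np.zeros(len(uniq))
    for _ in range(k):
        log_exp += log_bg[digits % 4]
        digits //= 4
    keep = counts >= 3
    if not keep.any():
        keep = counts >= 2
    if not keep.any():
        return None
    enrich = np.where(keep, np.log(counts) - log_exp, -np.inf)
    target = int(uniq[np.argmax(enrich)])
    lead = (W - k) // 2
    counts_mat = np.full((W, 4), 1.0)
    for e, (fwd, rev, ok) in zip(encoded, per_seq):
        for pos in np.flatnonzero(ok & (np.minimum(fwd, rev) == target)):
            start = pos - lead
            win = e[max(0, start) : start + W] if start >= 0 else None
            if win is None or len(win) < W or np.any(win < 0):
                continue
            if fwd[pos] != target:  # occurrence is on the reverse strand
                win = 3 - win[::-1]
            counts_mat[np.arange(W), win] += 1.0
    return counts_mat / counts_mat.sum(axis=1, keepdims=True)


def train_pwm(
    sequences: Sequence[str],
    W: int = 16,
    palindromic: bool = True,
    seed: int = 0,
    pseudocount: float = 0.01,
    max_iter: int = 200,
    tol: float = 1e-4,
    site_prior: float = 0.8,
    n_starts: int = 30,
    center_halfwidth: int | None = 60,
    center_prior_sd: float | None = None,
) -> PWM:
    """Fit a W-bp PWM by seeded multi-start ZOOPS expectation-maximisation.

    Zero-or-one site per sequence, both strands considered. Candidate
    starting points are W-mers drawn deterministically from the data (plus
    the most background-enriched repeated W-mer, when one exists); each
    candidate runs a short EM burst and the best-likelihood start runs to
    convergence (delta logL < ``tol``) or ``max_iter`` iterations. With
    ``palindromic`` the final matrix is averaged with its reverse
    complement, which makes the model exactly strand-symmetric.

    ``site_prior`` is the ZOOPS probability that a sequence carries a site;
    passing 1.0 fixes one site per sequence (OOPS), appropriate when every
    window is known to contain one (e.g. summit-centered peak windows).
    ``center_halfwidth`` biases candidate draws to the middle of each
    sequence: peak windows are summit-centered, and DAP/ChIP peak summits
    sit on the motif, so central W-mers are far likelier to be instances
    (the same central-enrichment assumption MEME-chip makes). Set None to
    sample uniformly. ``center_prior_sd`` additionally puts a Gaussian
    positional prior (sd in bp) on the site location around the window
    center during EM — appropriate for summit-centered windows, where it
    stops weak sites' responsibility drifting onto spurious offsets.
    """
    if not sequences:
        raise ValueError("no training sequences")
    if any(len(s) < W for s in sequences):
        raise ValueError(f"all sequences must be at least W={W} long")
    encoded = [encode(s) for s in sequences]
    bg = _background_mono(encoded)
    E = _pad_encode(sequences)
    Ec = np.where(E >= 0, E, 0)
    pos_prior = None
    if center_prior_sd is not None:
        m_all = E.shape[1] - W + 1
        centers = np.arange(m_all) + (W - 1) / 2
        mid = (E.shape[1] - 1) / 2
        pos_prior = np.exp(-((centers - mid) ** 2) / (2 * center_prior_sd**2))
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    core = _core_kmer_seed(encoded, W, bg)
    if core is not None:
        starts.append(core)
    seeds: list[np.ndarray] = []
    repeated = _seed_wmer(encoded, W, bg)
    if repeated is not None:
        seeds.append(encode(repeated))
    attempts = 0
    while len(seeds) < n_starts and attempts < 50 * n_starts:
        attempts += 1
        i = int(rng.integers(0, len(encoded)))
        m_i = len(encoded[i]) - W + 1
        if m_i <= 0:
            continue
        lo, hi = 0, m_i
        if center_halfwidth is not None:
            mid = (len(encoded[i]) - W) // 2
            lo = max(0, mid - center_halfwidth)
            hi = min(m_i, mid + center_halfwidth + 1)
        off = int(rng.integers(lo, hi))
        win = encoded[i][off : off + W]
        if np.any(win < 0):
            continue
        seeds.append(win.copy())
    if not seeds and not starts:
        raise ValueError(f"no valid {W}-mer seed found; try a smaller width")

    def init_from(wmer: np.ndarray) -> np.ndarray:
        probs = np.full((W, 4), 0.5 / 3)
        probs[np.arange(W), wmer] = 0.5
        return probs

    starts.extend(init_from(wmer) for wmer in seeds)
    best = None
    for init in starts:
        probs, gamma, ll = _em_pwm(
            E, Ec, bg, init, site_prior, pseudocount, 6, tol, pos_prior
        )
        if best is None or ll > best[2]:
            best = (probs, gamma, ll)
    probs, gamma, _ = best
    probs, gamma, _ = _em_pwm(
        E, Ec, bg, probs, gamma, pseudocount, max_iter, tol, pos_prior
    )
    if palindromic:
        # Quasi-palindromic motifs leave the window phase on a likelihood
        # ridge (flanks are weak); resolve it by picking the shift that makes
        # the matrix most self-reverse-complementary, refine briefly, then
        # symmetrize exactly.
        def shifted(p: np.ndarray, s: int) -> np.ndarray:
            out = np.tile(bg, (W, 1)).astype(float)
            if s >= 0:
                out[: W - s] = p[s:]
            else:
                out[-s:] = p[: W + s]
            return out

        best_s = min(
            range(-3, 4),
            key=lambda s: float(
                np.abs(shifted(probs, s) - shifted(probs, s)[::-1, ::-1]).sum()
            ),
        )
        if best_s != 0:
            probs, _, _ = _em_pwm(
                E, Ec, bg, shifted(probs, best_s), gamma, pseudocount, 5, tol,
                pos_prior,
            )
        probs = (probs + probs[::-1, ::-1]) / 2
    return PWM(probs, bg, pseudocount)


# ---------------------------------------------------------------------------
# TFFM training (EM over the hidden site location, first-order emissions)


def train_tffm(
    sequences: Sequence[str],
    pwm_init: PWM,
    seed: int = 0,
    pseudocount: float = 0.01,
    max_iter: int = 100,
    tol: float = 1e-4,
    site_prior: float = 0.8,
    collapse_alpha: float = 0.01,
    center_prior_sd: float | None = None,
) -> TFFM1:
    """Fit a first-order motif model starting from a PWM.

    Emission conditionals are initialised from the PWM columns (identical
    rows, i.e. no dependency); the background is the strand-symmetrised
    dinucleotide chain of the training sequences. EM over the hidden site
    position/strand (ZOOPS) runs to convergence; the per-iteration data
    log-likelihood is non-decreasing.

    After convergence each position's 4x4 conditional is tested for a real
    first-order dependency (G-test of the soft transition counts against
    the position marginal, 9 df); positions that do not reject at
    ``collapse_alpha`` fall back to identical rows (the marginal), so the
    model only spends parameters where the data support them. Pass
    ``collapse_alpha=0`` to keep all conditionals.
    """
    if not sequences:
        raise ValueError("no training sequences")
    W = pwm_init.width
    if any(len(s) < W for s in sequences):
        raise ValueError(f"all sequences must be at least W={W} long")
    encoded = [encode(s) for s in sequences]
    bg_trans = _background_dinuc(encoded)
    initial = pwm_init.probs[0].copy()
    transitions = np.repeat(pwm_init.probs[1:, None, :], 4, axis=1)
    E = _pad_encode(sequences)
    n, L = E.shape
    m = L - W + 1
    Ec = np.where(E >= 0, E, 0)
    if center_prior_sd is not None:
        centers = np.arange(m) + (W - 1) / 2
        pos_p = np.exp(-((centers - (L - 1) / 2) ** 2) / (2 * center_prior_sd**2))
        pos_p /= pos_p.sum()
    else:
        pos_p = np.full(m, 1.0 / m)
    oops = site_prior >= 1.0
    gamma_site = float(min(site_prior, 1.0 - 1e-9))
    prev_ll = -np.inf
    ll_trace: list[float] = []
    model = TFFM1(initial, transitions, bg_trans, pseudocount)
    log_bg_trans = np.log(bg_trans)
    for _ in range(max_iter):
        log_init = np.log(model.initial)
        log_trans = np.log(model.transitions)
        log_bg_start = np.log(model.bg_start)
        # forward-strand log odds
        lo_f = np.zeros((n, m))
        bad = np.zeros((n, m), dtype=bool)
        first = E[:, 0:m]
        bad |= first < 0
        lo_f += log_init[Ec[:, 0:m]] - log_bg_start[Ec[:, 0:m]]
        for k in range(1, W):
            a, b = Ec[:, k - 1 : k - 1 + m], Ec[:, k : k + m]
            bad |= (E[:, k - 1 : k - 1 + m] < 0) | (E[:, k : k + m] < 0)
            lo_f += log_trans[k - 1, a, b] - log_bg_trans[a, b]
        lo_f[bad] = -np.inf
        # reverse-strand log odds (score of the reverse complement window)
        lo_r = np.zeros((n, m))
        bad = np.zeros((n, m), dtype=bool)
        last = E[:, W - 1 : W - 1 + m]
        bad |= last < 0
        lastc = Ec[:, W - 1 : W - 1 + m]
        lo_r += log_init[3 - lastc] - log_bg_start[3 - lastc]
        for j in range(W - 1):
            a, b = Ec[:, j : j + m], Ec[:, j + 1 : j + 1 + m]
            bad |= (E[:, j : j + m] < 0) | (E[:, j + 1 : j + 1 + m] < 0)
            lo_r += log_trans[W - 2 - j, 3 - b, 3 - a] - log_bg_trans[3 - b, 3 - a]
        lo_r[bad] = -np.inf

        lr_f = np.exp(np.clip(lo_f, -700, 700))
        lr_r = np.exp(np.clip(lo_r, -700, 700))
        w_f = gamma_site / 2 * pos_p[None, :] * lr_f
        w_r = gamma_site / 2 * pos_p[None, :] * lr_r
        total = (1.0 - gamma_site) + w_f.sum(axis=1) + w_r.sum(axis=1)
        ll = float(np.log(total + _TINY).sum())
        ll_trace.append(ll)
        resp_f = w_f / total[:, None]
        resp_r = w_r / total[:, None]

        init_counts = np.full(4, pseudocount)
        trans_counts = np.full((W - 1, 4, 4), pseudocount)
        np.add.at(
            init_counts, Ec[:, 0:m].ravel(),
            np.where(E[:, 0:m] >= 0, resp_f, 0.0).ravel(),
        )
        np.add.at(
            init_counts, (3 - Ec[:, W - 1 : W - 1 + m]).ravel(),
            np.where(E[:, W - 1 : W - 1 + m] >= 0, resp_r, 0.0).ravel(),
        )
        for k in range(1, W):
            a, b = Ec[:, k - 1 : k - 1 + m], Ec[:, k : k + m]
            wts = np.where(
                (E[:, k - 1 : k - 1 + m] >= 0) & (E[:, k : k + m] >= 0), resp_f, 0.0
            )
            np.add.at(trans_counts[k - 1], (a.ravel(), b.ravel()), wts.ravel())
            # reverse strand: motif step k maps to window bases (W-1-k, W-k),
            # complemented and swapped
            ar, br = Ec[:, W - 1 - k : W - 1 - k + m], Ec[:, W - k : W - k + m]
            wts = np.where(
                (E[:, W - 1 - k : W - 1 - k + m] >= 0)
                & (E[:, W - k : W - k + m] >= 0),
                resp_r,
                0.0,
            )
            np.add.at(trans_counts[k - 1], ((3 - br).ravel(), (3 - ar).ravel()), wts.ravel())
        initial = init_counts / init_counts.sum()
        transitions = trans_counts / trans_counts.sum(axis=2, keepdims=True)
        if not oops:
            gamma_site = min(max((resp_f.sum() + resp_r.sum()) / n, 1e-6), 1 - 1e-6)
        model = TFFM1(initial, transitions, bg_trans, pseudocount)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    if collapse_alpha > 0:
        # Hard-assign each sequence's MAP site (EM responsibilities are
        # soft and selection-correlated, which overdisperses a count-based
        # test); G-test each position's 4x4 transition table for a real
        # dependency and collapse non-significant positions to the marginal.
        from scipy import stats as _stats

        # Read each window in a coin-flip direction (not the MAP strand):
        # content-dependent strand selection would itself induce spurious
        # dependencies in the counts, while a random reading direction keeps
        # the test calibrated and still detects the (quasi-palindromic)
        # dependencies the motif carries on both strands.
        flip_rng = np.random.default_rng([seed, 0x7FF])
        hard = np.zeros((W - 1, 4, 4))
        for i in range(n):
            post = resp_f[i].sum() + resp_r[i].sum()
            if post < 0.5:
                continue
            jf, jr = int(np.argmax(resp_f[i])), int(np.argmax(resp_r[i]))
            off = jf if resp_f[i, jf] >= resp_r[i, jr] else jr
            win = E[i, off : off + W]
            if np.any(win < 0):
                continue
            forward = flip_rng.random() < 0.5
            for k in range(1, W):
                if forward:
                    a, b = win[k - 1], win[k]
                else:
                    a, b = 3 - win[W - k], 3 - win[W - 1 - k]
                hard[k - 1, a, b] += 1
        transitions = model.transitions.copy()
        for k in range(W - 1):
            tab = hard[k]
            total = tab.sum()
            if total <= 0:
                continue
            expected = tab.sum(axis=1, keepdims=True) @ tab.sum(axis=0, keepdims=True) / total
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(tab > 0, tab * np.log(tab / np.clip(expected, _TINY, None)), 0.0)
            g = 2.0 * float(terms.sum())
            if _stats.chi2.sf(g, df=9) > collapse_alpha:
                soft = np.clip(trans_counts[k] - pseudocount, 0.0, None)
                marginal = soft.sum(axis=0) + 4 * pseudocount
                transitions[k] = np.tile(marginal / marginal.sum(), (4, 1))
        model = TFFM1(initial, transitions, bg_trans, pseudocount)
    model.training_ll_ = ll_trace
    return model


# ---------------------------------------------------------------------------
# Scoring and scanning


def _lr_to_score(log_lr: np.ndarray | float) -> np.ndarray | float:
    """s = LR / (1 + LR) computed stably from log LR; -inf maps to 0."""
    x = np.asarray(log_lr, dtype=float)
    with np.errstate(over="ignore"):
        s = np.where(
            x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x))
        )
    s = np.where(np.isneginf(x), 0.0, s)
    return float(s) if np.isscalar(log_lr) or np.ndim(log_lr) == 0 else s


def score_site(model: PWM | TFFM1, window: str, strand: str | None = None) -> float:
    """Site score s in [0, 1] for a single W-mer.

    Windows containing N score 0 (logged). When ``strand`` is None both
    strands are scored and the max is taken.
    """
    if len(window) != model.width:
        raise ValueError(f"window length {len(window)} != model width {model.width}")
    e = encode(window)
    if np.any(e < 0):
        logger.debug("window %r contains non-ACGT letters; score 0", window)
        return 0.0
    if strand is None:
        lo = max(
            float(model.log_odds_scan(e, "+")[0]),
            float(model.log_odds_scan(e, "-")[0]),
        )
    else:
        lo = float(model.log_odds_scan(e, strand)[0])
    return float(_lr_to_score(lo))


def scan_scores(model: PWM | TFFM1, sequence: str) -> np.ndarray:
    """Per-offset site scores, max over strands (empty if region < W)."""
    e = encode(sequence)
    if len(e) < model.width:
        return np.empty(0)
    lo = np.maximum(model.log_odds_scan(e, "+"), model.log_odds_scan(e, "-"))
    return np.asarray(_lr_to_score(lo))


def scan_region(
    model: PWM | TFFM1,
    sequence: str,
    threshold: float = 0.7,
    region_id: str = "region",
) -> tuple[float, list[SiteHit]]:
    """Best site score in the region plus all hits with s >= threshold.

    Every offset is scored on both strands; at one offset only the
    higher-scoring strand is reported. Regions shorter than W return
    (0.0, []) with a warning.
    """
    e = encode(sequence)
    W = model.width
    if len(e) < W:
        warnings.warn(f"region {region_id!r} shorter than model width {W}")
        return 0.0, []
    lo_f = model.log_odds_scan(e, "+")
    lo_r = model.log_odds_scan(e, "-")
    best_strand = np.where(lo_f >= lo_r, "+", "-")
    lo = np.maximum(lo_f, lo_r)
    scores = np.asarray(_lr_to_score(lo))
    hits = [
        SiteHit(region_id, int(i), str(best_strand[i]), float(scores[i]))
        for i in np.flatnonzero(scores >= threshold)
    ]
    return float(scores.max(initial=0.0)), hits


def load_model(path: str | Path) -> PWM | TFFM1:
    text = Path(path).read_text()
    kind = json.loads(text).get("type")
    if kind == "pwm":
        return PWM.from_json(text)
    if kind == "tffm1":
        return TFFM1.from_json(text)
    raise ValueError(f"unknown model type {kind!r} in {path}")
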