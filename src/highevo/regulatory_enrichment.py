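"""Proximity of induced mutations to TF-associated regulatory sequence.

Deaminase-fusion mutagenesis is expected to concentrate C→T/G→A
mutations near the tagged TF's binding sites.  This module provides:

* log-odds PWM scanning of genomic sequence on both strands;
* chaining of nearby motif hits into motif clusters (the role a
  cluster-buster-style scanner plays in the original workflow);
* distances from variant positions to the nearest feature interval;
* a resampling enrichment test: the focal variants are compared, per
  feature track, against repeated draws of background variants
  (natural-population SNPs), with a Fisher exact test per replicate
  and Benjamini–Hochberg correction across tracks within a replicate;
* export of fixed-width sequence windows centered on the focal SNPs,
  the input an external de novo motif-discovery tool consumes.

Coordinate conventions: variant positions are 1-based, feature
intervals 0-based half-open.  The distance of position ``pos`` to an
interval ``[start, end)`` is 0 when ``start <= pos-1 < end`` and
otherwise the gap in bases to the closest interval base; "within W
bp" means distance <= W.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rate_spectrum import contingency_test
from .variant_io import FeatureTrack

__all__ = [
    "PWM",
    "MotifHit",
    "EnrichmentResult",
    "read_jaspar",
    "pwm_scan",
    "cluster_hits",
    "distance_to_nearest",
    "proximity_enrichment",
    "extract_windows",
    "shared_mutation_policy",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PSEUDOCOUNT = 0.01


@dataclass
class PWM:
    """Position weight matrix over {A, C, G, T}.

    ``matrix`` has shape (width, 4) with rows summing to 1.
    ``score_threshold`` is in log-odds units; when ``None``, scanning
    uses ``threshold_fraction`` of the maximal achievable score.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    score_threshold: float | None = None
    threshold_fraction: float = 0.6

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 4:
            raise ValueError("matrix must be (width >= 4, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """(width, 4) log-odds scores; zero cells get a 0.01 pseudocount."""
        probs = self.matrix.copy()
        if np.any(probs == 0):
            probs = probs + _PSEUDOCOUNT
            probs /= probs.sum(axis=1, keepdims=True)
        return np.log(probs / self.background[None, :])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def effective_threshold(self) -> float:
        if self.score_threshold is not None:
            return self.score_threshold
        return self.threshold_fraction * self.max_score()

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1].copy(), self.background[::-1].copy(),
                   self.score_threshold, self.threshold_fraction)


def read_jaspar(path: str, background: np.ndarray | None = None) -> list[PWM]:
    """Read PWMs from a JASPAR-format text file (counts normalized per
    position)."""
    out = []
    with open(path) as fh:
        for motif in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([[motif.counts[b][i] for b in "ACGT"]
                               for i in range(motif.length)], dtype=float)
            probs = counts / counts.sum(axis=1, keepdims=True)
            name = motif.matrix_id or motif.name
            out.append(PWM(str(name), probs,
                           background if background is not None else np.full(4, 0.25)))
    return out


def write_jaspar(pwms: Sequence[PWM], path: str, counts_scale: int = 100) -> None:
    """Write PWMs as JASPAR text (probabilities scaled to pseudo-counts)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\t{pwm.name}\n")
            counts = np.rint(pwm.matrix * counts_scale).astype(int)
            for bi, base in enumerate("ACGT"):
                row = " ".join(str(int(c)) for c in counts[:, bi])
                fh.write(f"{base}  [ {row} ]\n")


@dataclass
class MotifHit:
    start: int           # 0-based
    strand: str          # '+' or '-'
    score: float
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _scan_one_strand(codes: np.ndarray, logodds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w = logodds.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    scores = logodds[np.arange(w)[None, :], safe].sum(axis=1)
    return scores, valid


def pwm_scan(sequence: str, pwm: PWM) -> list[MotifHit]:
    """Scan both strands; a hit is any window whose log-odds score
    reaches the PWM's effective threshold.  Windows containing N are
    skipped.  Hits are reported with plus-strand coordinates, sorted
    by start (plus strand first on ties)."""
    codes = _encode(sequence)
    threshold = pwm.effective_threshold()
    hits: list[MotifHit] = []
    for strand, lo in (("+", pwm.log_odds()), ("-", pwm.reverse_complement().log_odds())):
        scores, valid = _scan_one_strand(codes, lo)
        for start in np.flatnonzero(valid & (scores >= threshold)):
            hits.append(MotifHit(int(start), strand, float(scores[start]), pwm.width))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def cluster_hits(hits: Sequence[MotifHit], max_gap: int = 35, min_hits: int = 2,
                 chrom: str = "seq", name: str = "motif_clusters") -> FeatureTrack:
    """Chain motif hits into cluster intervals.

    Hits (sorted by start) are chained while the gap between one hit's
    end and the next hit's start is <= ``max_gap``; chains with >=
    ``min_hits`` members become intervals spanning the first hit's
    start to the last hit's end.
    """
    intervals: list[tuple[str, int, int]] = []
    chain: list[MotifHit] = []
    for hit in sorted(hits, key=lambda h: h.start):
        if chain and hit.start - chain[-1].end > max_gap:
            if len(chain) >= min_hits:
                intervals.append((chrom, chain[0].start, max(h.end for h in chain)))
            chain = []
        chain.append(hit)
    if len(chain) >= min_hits:
        intervals.append((chrom, chain[0].start, max(h.end for h in chain)))
    return FeatureTrack(name, intervals)


def distance_to_nearest(
    positions: Sequence[tuple[str, int]],
    track: FeatureTrack,
) -> np.ndarray:
    """Distance (bp) from each 1-based position to the nearest interval.

    0 when the position lies inside an interval; ``inf`` when the
    track has no interval on that chromosome.
    """
    per_chrom = track.by_chrom()
    prepared: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, arr in per_chrom.items():
        order = np.argsort(arr[:, 0])
        starts = arr[order, 0]
        # running max of ends over intervals with start <= any given
        # position: handles nested/overlapping intervals exactly
        end_cummax = np.maximum.accumulate(arr[order, 1])
        prepared[chrom] = (starts, end_cummax)
    out = np.empty(len(positions))
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, _pos) in enumerate(positions):
        by_chrom.setdefault(chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        if chrom not in prepared:
            out[idx] = math.inf
            continue
        starts, end_cummax = prepared[chrom]
        p0 = np.array([positions[i][1] for i in idx], dtype=np.int64) - 1
        j = np.searchsorted(starts, p0, side="right")
        best = np.full(len(idx), math.inf)
        has_right = j < len(starts)
        best[has_right] = starts[np.minimum(j, len(starts) - 1)][has_right] - p0[has_right]
        has_left = j > 0
        reach = end_cummax[np.maximum(j, 1) - 1]  # furthest end among intervals at/left of p0
        inside = has_left & (reach > p0)
        left_gap = p0 - (reach - 1)
        best = np.where(has_left & ~inside, np.minimum(best, left_gap), best)
        best[inside] = 0.0
        out[idx] = best
    return out


@dataclass
class EnrichmentResult:
    """Per-track enrichment of focal variants near features.

    One entry per resampling replicate: the 2x2 table (focal/background
    x within/beyond window), cross-product odds ratio, raw Fisher p and
    BH-adjusted p (adjusted across tracks within the replicate).
    """

    track: str
    window: int
    tables: list[tuple[int, int, int, int]]
    odds_ratios: list[float]
    p_raw: list[float]
    p_adjusted: list[float]
    n_focal: int
    degenerate: bool = False

    @property
    def median_odds_ratio(self) -> float:
        return float(np.median(self.odds_ratios))

    @property
    def median_p_adjusted(self) -> float:
        return float(np.median(self.p_adjusted))


def proximity_enrichment(
    focal: Sequence[tuple[str, int]],
    background_pool: Sequence[tuple[str, int]],
    tracks: Sequence[FeatureTrack],
    window: int = 100,
    n_sample: int = 10_000,
    n_reps: int = 500,
    seed: int | np.random.Generator = 0,
) -> list[EnrichmentResult]:
    """Resampling enrichment of focal variants near each feature track.

    Per replicate, ``n_sample`` background variants are drawn from the
    pool (without replacement when the pool is large enough, otherwise
    with replacement) and a Fisher exact test compares the
    within-``window`` fraction of focal vs. sampled background
    positions.  BH adjustment is applied across tracks within each
    replicate.  Distances are precomputed once, so replicates only
    re-draw indices.
    """
    if len(focal) == 0:
        raise ValueError("focal set is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    replace = len(background_pool) < n_sample

    focal_within = []
    pool_within = []
    for track in tracks:
        focal_within.append(distance_to_nearest(focal, track) <= window)
        pool_within.append(distance_to_nearest(background_pool, track) <= window)

    n_focal = len(focal)
    results = [
        EnrichmentResult(track.name, window, [], [], [], [], n_focal,
                         degenerate=(len(track) == 0))
        for track in tracks
    ]
    for _ in range(n_reps):
        idx = rng.choice(len(background_pool), size=n_sample, replace=replace)
        raw_ps = []
        for ti in range(len(tracks)):
            a = int(focal_within[ti].sum())
            b = n_focal - a
            c = int(pool_within[ti][idx].sum())
            d = n_sample - c
            odds, p = contingency_test(a, b, c, d)
            results[ti].tables.append((a, b, c, d))
            results[ti].odds_ratios.append(odds)
            raw_ps.append(p)
        adj = multipletests(raw_ps, method="fdr_bh")[1] if len(raw_ps) > 1 else raw_ps
        for ti in range(len(tracks)):
            results[ti].p_raw.append(raw_ps[ti])
            results[ti].p_adjusted.append(float(adj[ti]))
    return results


def extract_windows(
    variants: Sequence[tuple[str, int]],
    genome: Mapping[str, str],
    width: int = 200,
) -> dict[str, tuple[str, bool]]:
    """Fixed-width sequence windows centered on each SNP.

    Each window is ``width`` bp with the variant at 1-based position
    ``ceil(width/2)`` within the window; windows truncated at
    chromosome ends are padded with N and flagged.  Returns
    ``{"chrom:pos": (sequence, padded_flag)}`` — the FASTA input for
    external de novo motif discovery.
    """
    center = math.ceil(width / 2)
    out: dict[str, tuple[str, bool]] = {}
    for chrom, pos in variants:
        seq = genome[chrom]
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"position {chrom}:{pos} beyond chromosome end ({len(seq)})")
        start0 = pos - center          # 0-based inclusive
        end0 = start0 + width          # 0-based exclusive
        left_pad = max(0, -start0)
        right_pad = max(0, end0 - len(seq))
        window = "N" * left_pad + seq[max(0, start0):min(len(seq), end0)] + "N" * right_pad
        out[f"{chrom}:{pos}"] = (window, left_pad > 0 or right_pad > 0)
    return out


def shared_mutation_policy(
    set_a: Sequence[tuple[str, int]],
    set_b: Sequence[tuple[str, int]],
) -> tuple[list[tuple[str, int]], list[tuple[str, int]], float]:
    """Keep mutations shared between two TF analyses in both lists.

    Returns ``(list_a, list_b, overlap_fraction)`` where the overlap
    fraction is the number of shared positions over the number of
    distinct positions across both sets.
    """
    a, b = list(dict.fromkeys(set_a)), list(dict.fromkeys(set_b))
    shared = set(a) & set(b)
    union = set(a) | set(b)
    frac = len(shared) / len(union) if union else 0.0
    return a, b, frac
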