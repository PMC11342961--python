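"""Mutation-rate estimation and mutation-spectrum statistics.

The per-base per-generation rate is estimated from isogenized
chromosomes as ``u = Nvar / (nbp * G)``, where ``Nvar`` is the number
of de novo mutations carried by the line, ``nbp`` the number of
callable bases (positions covered by 10-200 reads in the sample) and
``G`` the number of generations of mutagenesis.  Because an isogenized
chromosome harvests a single chromosome copy — half the variation of
the diploid individual it came from — ``nbp`` rather than ``2 nbp``
is used, so ``u`` is on the scale of a diploid genome.

Spectrum statistics classify variants into deaminase-signature SNPs
(C→T / G→A), other SNPs, insertions, deletions and MNPs, and summarize
zygosity and singleton structure.  Enrichment of the deaminase
signature in mutagenized vs. background variants is tested with
Fisher's exact test, reporting the cross-product odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .private_variants import PrivateVariantSet, round_percent
from .variant_io import DepthTrack, Genotype, VariantRecord

__all__ = [
    "MutationRateEstimate",
    "RateAggregate",
    "SpectrumSummary",
    "count_callable",
    "reconcile_replicates",
    "estimate_rate",
    "aggregate_rates",
    "classify_variant",
    "spectrum_summary",
    "spectrum_fraction",
    "contingency_test",
    "occurrence_stats",
]

SPECTRUM_CLASSES = ("CtoT_GtoA", "other_SNP", "insertion", "deletion", "MNP")


@dataclass
class MutationRateEstimate:
    line_id: str
    n_var: int
    n_bp: int
    g: int
    u: float

    def __post_init__(self) -> None:
        if self.n_bp <= 0 or self.g < 1:
            raise ValueError("need n_bp > 0 and g >= 1")
        assert math.isclose(self.u, self.n_var / (self.n_bp * self.g))


@dataclass
class RateAggregate:
    mean: float
    se: float
    sd: float
    n_lines: int


@dataclass
class SpectrumSummary:
    counts: dict[str, int]
    singleton_fraction: float | None
    het_fraction: float | None
    n_variants: int
    n_occurrences: int


def count_callable(
    depth: DepthTrack,
    sample: str,
    chrom: str,
    lo: int = 10,
    hi: int = 200,
) -> int:
    """Number of bases on ``chrom`` covered by ``lo``–``hi`` reads (inclusive)."""
    try:
        lengths, values = depth.runs[sample][chrom]
    except KeyError as exc:
        raise KeyError(f"no depth for sample {sample!r} chromosome {chrom!r}") from exc
    mask = (values >= lo) & (values <= hi)
    return int(lengths[mask].sum())


def reconcile_replicates(counts: Sequence[int]) -> int:
    """Variant count for a line from its replicate counts.

    Replicates of an isogenic line should agree; when they do not, the
    higher count is used (discordance is nearly always a dropout in
    the lower-coverage replicate).
    """
    if len(counts) == 0:
        raise ValueError("need at least one replicate count")
    return max(counts)


def estimate_rate(n_var: int, n_bp: int, g: int, line_id: str = "") -> MutationRateEstimate:
    """u = Nvar / (nbp * G), the diploid per-base per-generation rate."""
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    if g < 1:
        raise ValueError("g must be >= 1")
    return MutationRateEstimate(line_id, n_var, n_bp, g, n_var / (n_bp * g))


def aggregate_rates(estimates: Sequence[MutationRateEstimate]) -> RateAggregate:
    """Arithmetic mean across lines; SE = sample SD / sqrt(n_lines).

    Both SE and SD are exposed: published "±" values do not always say
    which they are.
    """
    if not estimates:
        raise ValueError("no estimates to aggregate")
    us = np.array([e.u for e in estimates])
    sd = float(us.std(ddof=1)) if len(us) > 1 else 0.0
    return RateAggregate(float(us.mean()), sd / math.sqrt(len(us)), sd, len(us))


def classify_variant(record: VariantRecord) -> str:
    """Spectrum class: deaminase SNP, other SNP, insertion, deletion, MNP."""
    ref, alt = record.ref, record.alt
    if len(ref) == 1 and len(alt) == 1:
        if (ref, alt) in (("C", "T"), ("G", "A")):
            return "CtoT_GtoA"
        return "other_SNP"
    if len(ref) < len(alt):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "MNP"


def spectrum_summary(pset: PrivateVariantSet) -> SpectrumSummary:
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    n_occ = n_singleton = n_het_occ = 0
    for var in pset.variants:
        counts[classify_variant(var.record)] += 1
        n_occ += len(var.carriers)
        if var.singleton:
            n_singleton += 1
        n_het_occ += sum(1 for s in var.carriers if var.zygosity[s] is Genotype.HET)
    n = len(pset.variants)
    return SpectrumSummary(
        counts=counts,
        singleton_fraction=(n_singleton / n) if n else None,
        het_fraction=(n_het_occ / n_occ) if n_occ else None,
        n_variants=n,
        n_occurrences=n_occ,
    )


def spectrum_fraction(pset: PrivateVariantSet) -> dict[str, float | None]:
    """Deaminase-signature fraction with both denominators.

    Returns ``of_snps`` (C→T/G→A among SNPs) and ``of_all`` (among all
    variants), plus the rounded percentages.  Empty denominators yield
    ``None`` rather than 0.
    """
    summary = spectrum_summary(pset)
    n_ctga = summary.counts["CtoT_GtoA"]
    n_snp = n_ctga + summary.counts["other_SNP"]
    n_all = summary.n_variants
    of_snps = (n_ctga / n_snp) if n_snp else None
    of_all = (n_ctga / n_all) if n_all else None
    return {
        "n_ctga": n_ctga,
        "n_snp": n_snp,
        "n_all": n_all,
        "of_snps": of_snps,
        "of_all": of_all,
        "pct_of_snps": round_percent(of_snps) if of_snps is not None else None,
        "pct_of_all": round_percent(of_all) if of_all is not None else None,
    }


def contingency_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, p_two_sided)``.  The odds ratio is the
    sample cross-product ``(a*d)/(b*c)`` (not the conditional MLE); a
    zero off-diagonal cell gives ``inf``, a zero diagonal cell 0.  The
    p-value is the exact two-sided hypergeometric probability and is
    computed for every table.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cells must be non-negative integers")
    if b * c == 0:
        odds = math.inf if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return odds, float(p)


def occurrence_stats(pset: PrivateVariantSet) -> tuple[float | None, float | None, int]:
    """(singleton fraction over variants, het fraction over carrier
    occurrences, total occurrences)."""
    summary = spectrum_summary(pset)
    return summary.singleton_fraction, summary.het_fraction, summary.n_occurrences
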