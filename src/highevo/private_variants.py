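"""Identification of candidate de novo mutations as private variants.

A joint multi-sample call contains mostly standing variation shared
across laboratory stocks.  Variants *private* to the mutagenized set
(or, symmetrically, to the non-mutagenized background set) are the
proxy for de novo mutations.  Privateness is assessed strictly: a
variant is not private if any sample outside the designated set carries
the alternative allele, even through a call that would fail every
downstream quality filter.  Missing genotypes never count as carrying.

The full pipeline (:func:`run_private_pipeline`) chains, in order:

1. QUAL >= 10 site prefilter on the joint call;
2. private-variant selection against the full sample set;
3. per-carrier genotype filtering (DP in [10, 200]; het calls
   additionally need AO > 2 and RO > 2) merged with the replicate
   rescue rule (a variant carried by >= 2 members of one replicate
   group is kept regardless of depth or allele depth);
4. cross-set coverage filter (a variant private to one set must have a
   non-missing call in >= 2 samples of the opposite set);
5. introgression detection (samples with a dense run of "private"
   variants carry foreign background, not de novo mutations) followed
   by recomputation of privateness without the flagged samples;
6. mean-depth sample exclusion, reported for downstream counting.

Every stage appends a row to a removal ledger so the fraction of the
joint call eliminated at each step can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .variant_io import Genotype, GenotypeCall, VariantRecord

__all__ = [
    "SampleManifest",
    "ChromSets",
    "PrivateVariant",
    "PrivateVariantSet",
    "StageLedger",
    "PipelineResult",
    "qual_prefilter",
    "select_private",
    "genotype_filter",
    "replicate_rescue",
    "cross_coverage_filter",
    "detect_introgression",
    "depth_exclusion",
    "reversion_audit",
    "run_private_pipeline",
    "round_percent",
    "privateness_removed_percent",
]


def round_percent(fraction: float, digits: int = 1) -> float:
    """Percentage with half-up rounding to ``digits`` decimals."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def privateness_removed_percent(n_total: int, n_private: int) -> float:
    """Percent of the joint call removed by the privateness stage."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round_percent((n_total - n_private) / n_total)


@dataclass
class ChromSets:
    """Sample-set definitions for one chromosome."""

    full: list[str]
    mutagenized: list[str]
    background: list[str]

    def __post_init__(self) -> None:
        if set(self.mutagenized) & set(self.background):
            raise ValueError("mutagenized and background sets overlap")
        for name, sub in (("mutagenized", self.mutagenized), ("background", self.background)):
            if not set(sub) <= set(self.full):
                raise ValueError(f"{name} set is not a subset of the full set")

    def target(self, which: str) -> list[str]:
        return {"mutagenized": self.mutagenized, "background": self.background}[which]

    def opposite(self, which: str) -> list[str]:
        return {"mutagenized": self.background, "background": self.mutagenized}[which]

    def without(self, excluded: Iterable[str]) -> "ChromSets":
        drop = set(excluded)
        return ChromSets(
            [s for s in self.full if s not in drop],
            [s for s in self.mutagenized if s not in drop],
            [s for s in self.background if s not in drop],
        )


@dataclass
class SampleManifest:
    """Sample sets per chromosome, replicate groups, per-sample metadata.

    ``mean_depth`` is in reads; ``generations`` is the integer G used
    for rate estimation; ``tags`` carries chromosome-role labels such
    as ``isogenic-chr3``.
    """

    chromosomes: dict[str, ChromSets]
    replicate_groups: dict[str, list[str]] = field(default_factory=dict)
    mean_depth: dict[str, float] = field(default_factory=dict)
    generations: dict[str, int] = field(default_factory=dict)
    tags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for group, members in self.replicate_groups.items():
            for s in members:
                if s in seen:
                    raise ValueError(f"sample {s} in replicate groups {seen[s]} and {group}")
                seen[s] = group

    def group_of(self, sample: str) -> str | None:
        for group, members in self.replicate_groups.items():
            if sample in members:
                return group
        return None

    def without_samples(self, excluded: Iterable[str]) -> "SampleManifest":
        drop = set(excluded)
        return SampleManifest(
            {c: cs.without(drop) for c, cs in self.chromosomes.items()},
            {g: [s for s in m if s not in drop]
             for g, m in self.replicate_groups.items()
             if any(s not in drop for s in m)},
            {s: d for s, d in self.mean_depth.items() if s not in drop},
            {s: g for s, g in self.generations.items() if s not in drop},
            {s: t for s, t in self.tags.items() if s not in drop},
        )


@dataclass
class PrivateVariant:
    """A variant private to one sample set, with carrier bookkeeping."""

    record: VariantRecord
    carriers: list[str]
    zygosity: dict[str, Genotype]
    passed_filter: dict[str, bool] = field(default_factory=dict)
    rescued: bool = False

    @property
    def singleton(self) -> bool:
        return len(self.carriers) == 1


@dataclass
class PrivateVariantSet:
    target_label: str
    variants: list[PrivateVariant] = field(default_factory=list)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.record.key for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class StageLedger:
    """Counts surviving each pipeline stage, per target set."""

    rows: list[dict] = field(default_factory=list)

    def add(self, stage: str, target: str, count: int, note: str = "") -> None:
        self.rows.append({"stage": stage, "target": target, "count": count, "note": note})

    def count(self, stage: str, target: str) -> int:
        for row in self.rows:
            if row["stage"] == stage and row["target"] == target:
                return row["count"]
        raise KeyError((stage, target))

    def removed_percent_at_privateness(self) -> float:
        """Percent of the QUAL-passing joint call removed by the
        privateness stage (both private sets combined)."""
        total = self.count("input", "all")
        private = self.count("private", "mutagenized") + self.count("private", "background")
        return privateness_removed_percent(total, private)


@dataclass
class PipelineResult:
    mutagenized: PrivateVariantSet
    background: PrivateVariantSet
    ledger: StageLedger
    introgressed_samples: list[str]
    retained_samples: list[str]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def qual_prefilter(records: Sequence[VariantRecord], min_qual: float = 10.0) -> list[VariantRecord]:
    """Drop records with QUAL below ``min_qual`` (QUAL < 10 removed)."""
    return [r for r in records if r.qual >= min_qual]


def select_private(
    records: Sequence[VariantRecord],
    sets: ChromSets,
    target: str,
    chrom: str | None = None,
) -> PrivateVariantSet:
    """Variants carried only by samples of the target set.

    A variant is private to the target set iff at least one target-set
    sample carries the ALT allele and no full-set sample outside the
    target carries it — at any quality.  Samples absent from the full
    set are ignored.
    """
    target_samples = sets.target(target)
    if not target_samples:
        raise ValueError(f"target set {target!r} is empty")
    target_set = set(target_samples)
    others = [s for s in sets.full if s not in target_set]
    out = PrivateVariantSet(target)
    for rec in records:
        if chrom is not None and rec.chrom != chrom:
            continue
        carriers = [s for s in target_samples
                    if s in rec.calls and rec.calls[s].gt.carries_alt()]
        if not carriers:
            continue
        if any(s in rec.calls and rec.calls[s].gt.carries_alt() for s in others):
            continue
        out.variants.append(PrivateVariant(
            record=rec,
            carriers=carriers,
            zygosity={s: rec.calls[s].gt for s in carriers},
        ))
    return out


def genotype_filter(call: GenotypeCall, dp_lo: int = 10, dp_hi: int = 200, min_obs: int = 3) -> bool:
    """Per-sample genotype quality filter.

    Pass iff DP in [dp_lo, dp_hi] and, for heterozygous calls, at
    least ``min_obs`` reads support each allele (AO > 2 and RO > 2 at
    the defaults).  Homozygous calls need only the depth bound.
    """
    if call.gt is Genotype.MISSING:
        raise ValueError("genotype_filter is undefined for missing calls")
    dp = call.dp if call.dp is not None else 0
    if not (dp_lo <= dp <= dp_hi):
        return False
    if call.gt is Genotype.HET:
        ao = call.ao if call.ao is not None else 0
        ro = call.ro if call.ro is not None else 0
        return ao >= min_obs and ro >= min_obs
    return True


def replicate_rescue(carriers: Sequence[str], manifest: SampleManifest) -> bool:
    """True iff >= 2 carriers belong to one replicate group.

    Replicates of an isogenic line share the isogenized chromosome, so
    concordant presence validates a variant regardless of depth or
    allele-observation counts.
    """
    counts: dict[str, int] = {}
    for s in carriers:
        group = manifest.group_of(s)
        if group is not None:
            counts[group] = counts.get(group, 0) + 1
    return any(n >= 2 for n in counts.values())


def _apply_genotype_and_rescue(
    pset: PrivateVariantSet,
    manifest: SampleManifest,
    dp_lo: int = 10,
    dp_hi: int = 200,
    min_obs: int = 3,
) -> PrivateVariantSet:
    """Keep variants with >= 1 passing carrier or a replicate rescue.

    All carriers stay listed; per-carrier pass flags and the rescue
    flag are recorded.
    """
    out = PrivateVariantSet(pset.target_label)
    for var in pset.variants:
        passed = {
            s: genotype_filter(var.record.calls[s], dp_lo, dp_hi, min_obs)
            for s in var.carriers
        }
        rescued = replicate_rescue(var.carriers, manifest)
        if any(passed.values()) or rescued:
            out.variants.append(PrivateVariant(
                record=var.record,
                carriers=list(var.carriers),
                zygosity=dict(var.zygosity),
                passed_filter=passed,
                rescued=rescued,
            ))
    return out


def cross_coverage_filter(
    pset: PrivateVariantSet,
    sets: ChromSets,
    min_nonmissing: int = 2,
) -> PrivateVariantSet:
    """Require coverage of the site in the opposite sample set.

    A variant private to one set is only a fair de novo candidate if
    its site was genotyped (non-missing) in at least ``min_nonmissing``
    samples of the opposite set.
    """
    opposite = sets.opposite(pset.target_label)
    out = PrivateVariantSet(pset.target_label)
    for var in pset.variants:
        n = sum(
            1 for s in opposite
            if s in var.record.calls and var.record.calls[s].gt is not Genotype.MISSING
        )
        if n >= min_nonmissing:
            out.variants.append(var)
    return out


def detect_introgression(
    psets: Sequence[PrivateVariantSet],
    window_kb: float = 100.0,
    min_count: int = 20,
) -> list[str]:
    """Flag samples whose private variants form a dense linkage block.

    A run of >= ``min_count`` private variants within any
    ``window_kb`` window on one chromosome indicates introgressed
    foreign background rather than de novo mutation.  Returns flagged
    sample ids sorted.
    """
    window = int(window_kb * 1000)
    positions: dict[str, dict[str, list[int]]] = {}
    for pset in psets:
        for var in pset.variants:
            for s in var.carriers:
                positions.setdefault(s, {}).setdefault(var.record.chrom, []).append(var.record.pos)
    flagged = []
    for sample, per_chrom in positions.items():
        hit = False
        for pos_list in per_chrom.values():
            pos_list.sort()
            lo = 0
            for hi in range(len(pos_list)):
                while pos_list[hi] - pos_list[lo] > window:
                    lo += 1
                if hi - lo + 1 >= min_count:
                    hit = True
                    break
            if hit:
                break
        if hit:
            flagged.append(sample)
    return sorted(flagged)


def depth_exclusion(
    manifest: SampleManifest,
    chrom: str,
    thresholds: Mapping[str, float] | None = None,
    default_threshold: float = 5.0,
) -> list[str]:
    """Samples retained for counting on ``chrom`` by mean depth.

    Defaults mirror the study design: chr2-like chromosomes require
    mean depth >= 9x, chr3-like >= 5x; unknown chromosomes fall back
    to the global default (5x).
    """
    if thresholds is None:
        thresholds = {"chr2": 9.0, "chr3": 5.0}
    threshold = None
    for key, value in thresholds.items():
        if chrom == key or chrom.startswith(key):
            threshold = value
            break
    if threshold is None:
        threshold = default_threshold
    return [s for s, d in manifest.mean_depth.items() if d >= threshold]


def reversion_audit(
    records: Sequence[VariantRecord],
    sets: ChromSets,
    chrom: str | None = None,
) -> tuple[int, int]:
    """Audit sites fixed for the ALT allele in the background set.

    Returns ``(n_hom_alt_background_sites, n_reverted)``: sites where
    every background sample is hom-alt, and among those, sites where
    any mutagenized sample is het or hom-ref (a reversion toward the
    reference allele).  De novo mutations matching the reference would
    only be visible at such sites.
    """
    n_sites = n_reverted = 0
    for rec in records:
        if chrom is not None and rec.chrom != chrom:
            continue
        bg_calls = [rec.calls[s] for s in sets.background if s in rec.calls]
        if not bg_calls or any(c.gt is not Genotype.HOM_ALT for c in bg_calls):
            continue
        n_sites += 1
        for s in sets.mutagenized:
            call = rec.calls.get(s)
            if call is not None and call.gt in (Genotype.HET, Genotype.HOM_REF):
                n_reverted += 1
                break
    return n_sites, n_reverted


def _private_both_sets(records, sets, chrom, manifest, dp_lo, dp_hi, min_obs, min_nonmissing):
    out = {}
    for target in ("mutagenized", "background"):
        pset = select_private(records, sets, target, chrom)
        filtered = _apply_genotype_and_rescue(pset, manifest, dp_lo, dp_hi, min_obs)
        covered = cross_coverage_filter(filtered, sets, min_nonmissing)
        out[target] = (pset, filtered, covered)
    return out


def run_private_pipeline(
    records: Sequence[VariantRecord],
    manifest: SampleManifest,
    chrom: str,
    min_qual: float = 10.0,
    dp_lo: int = 10,
    dp_hi: int = 200,
    min_obs: int = 3,
    min_nonmissing: int = 2,
    introgression_window_kb: float = 100.0,
    introgression_min_count: int = 20,
    depth_thresholds: Mapping[str, float] | None = None,
) -> PipelineResult:
    """Full private-variant pipeline for one chromosome.

    Applies QUAL prefilter, privateness selection, genotype filtering
    with replicate rescue, cross-set coverage, introgression-based
    sample removal with privateness recomputation, and mean-depth
    sample exclusion.  The ledger records the count surviving every
    stage; privateness recomputation after sample removal may *add*
    variants (a disqualifying carrier disappeared) and such additions
    are recorded separately.
    """
    sets = manifest.chromosomes[chrom]
    ledger = StageLedger()
    n_chrom = sum(1 for r in records if r.chrom == chrom)
    ledger.add("total", "all", n_chrom, "records on chromosome before any filter")

    kept = [r for r in qual_prefilter(records, min_qual) if r.chrom == chrom]
    ledger.add("input", "all", len(kept), f"QUAL >= {min_qual}")

    first = _private_both_sets(kept, sets, chrom, manifest, dp_lo, dp_hi, min_obs, min_nonmissing)
    for target in ("mutagenized", "background"):
        pset, filtered, covered = first[target]
        ledger.add("private", target, len(pset))
        ledger.add("genotype_filter", target, len(filtered))
        ledger.add("cross_coverage", target, len(covered))

    flagged = detect_introgression(
        [first["mutagenized"][2], first["background"][2]],
        introgression_window_kb,
        introgression_min_count,
    )
    final = {t: first[t][2] for t in ("mutagenized", "background")}
    if flagged:
        reduced = manifest.without_samples(flagged)
        sets2 = reduced.chromosomes[chrom]
        second = _private_both_sets(kept, sets2, chrom, reduced, dp_lo, dp_hi, min_obs, min_nonmissing)
        for target in ("mutagenized", "background"):
            before = final[target].keys()
            final[target] = second[target][2]
            added = len(final[target].keys() - before)
            ledger.add("post_introgression", target, len(final[target]),
                       f"removed samples: {','.join(flagged)}; newly private: {added}")
    else:
        for target in ("mutagenized", "background"):
            ledger.add("post_introgression", target, len(final[target]), "no samples flagged")

    retained = depth_exclusion(
        manifest.without_samples(flagged) if flagged else manifest,
        chrom,
        depth_thresholds,
    )
    ledger.add("depth_retained_samples", "all", len(retained))
    return PipelineResult(
        mutagenized=final["mutagenized"],
        background=final["background"],
        ledger=ledger,
        introgressed_samples=flagged,
        retained_samples=sorted(retained),
    )
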