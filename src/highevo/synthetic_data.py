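"""Forward simulator of TF-fused deaminase germline mutagenesis.

Generates the inputs the analysis pipeline consumes — genome FASTA,
feature tracks, per-sample depth, and a joint multi-sample variant
table — with the statistical structure the analysis assumes:

* a random genome with planted TF-motif matches and regulatory
  "peak" intervals around a subset of them;
* laboratory stocks carrying private fixed homozygous differences and
  contiguous pockets of residual heterozygosity shared by every
  individual sampled from the stock;
* mutagenized lineages accumulating de novo mutations over discrete
  generations, Poisson per base per generation, at the base rate
  outside target windows and ``target_rate_multiplier`` times that
  inside windows around planted motif sites; a configurable fraction
  of induced mutations are deaminase-signature C→T / G→A changes;
* isogenization of one chromosome: a single chromosome copy is
  sampled from a lineage (each heterozygous mutation survives with
  probability 1/2 and becomes homozygous), and replicate samples of a
  line share the resolved chromosome;
* sequencing emission with overdispersed depth, binomial allele
  observations with a per-read error rate, depth-dependent missing
  genotypes, and low-QUAL artifact records.

Every sampled quantity flows from one :class:`numpy.random.Generator`,
so a fixed seed reproduces the emitted files byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .private_variants import ChromSets, SampleManifest
from .regulatory_enrichment import PWM
from .variant_io import DepthTrack, FeatureTrack, Genotype, GenotypeCall, VariantRecord

__all__ = [
    "SimGenome",
    "MutagenesisModel",
    "SequencingModel",
    "SimTruth",
    "DeNovoMutation",
    "StandingVariant",
    "CapacityError",
    "default_pwm",
    "build_genome",
    "simulate_background_stocks",
    "simulate_mutagenesis",
    "sample_individual",
    "simulate_isogenization",
    "emit_joint_table",
    "effective_isogenic_rate",
    "calibrate_base_rate",
    "simulate_experiment",
    "SimulationResult",
]

_BASES = np.array(list("ACGT"))
_OTHER = {b: [o for o in "ACGT" if o != b] for b in "ACGT"}


class CapacityError(RuntimeError):
    """Requested feature placement does not fit the genome."""


def default_pwm(name: str = "synthetic_homeodomain") -> PWM:
    """A synthetic homeodomain-style PWM (TAATGG core, width 8).

    Built in code — not a database matrix — so simulations carry no
    external data dependency.
    """
    consensus = "TTAATGGC"
    w = len(consensus)
    matrix = np.full((w, 4), 0.04)
    for i, base in enumerate(consensus):
        matrix[i, "ACGT".index(base)] = 0.88
    matrix /= matrix.sum(axis=1, keepdims=True)
    return PWM(name, matrix)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class SimGenome:
    sequences: dict[str, str]
    motif_sites: FeatureTrack
    peak_sites: FeatureTrack
    pwm: PWM

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASE_BYTES[rng.choice(4, size=length, p=p)]


def _sample_motif(rng: np.random.Generator, pwm: PWM, max_mismatch: int) -> str:
    """Draw a site from the PWM, within ``max_mismatch`` of consensus."""
    consensus = pwm.consensus()
    for _ in range(200):
        site = "".join(rng.choice(_BASES, p=pwm.matrix[i]) for i in range(pwm.width))
        if sum(a != b for a, b in zip(site, consensus)) <= max_mismatch:
            return site
    return consensus


def build_genome(
    seed: int | np.random.Generator,
    chrom_lengths: Mapping[str, int],
    gc: float = 0.42,
    pwm: PWM | None = None,
    n_motif_sites: int = 50,
    n_peaks: int = 10,
    peak_width: int = 500,
    max_mismatch: int = 1,
    max_tries: int = 10_000,
) -> SimGenome:
    """Random genome with planted motif sites and peak intervals.

    Motif sites are placed uniformly at random without overlap; each
    of the ``n_peaks`` peak intervals (width ``peak_width``) is
    centered on one motif site, so every peak contains at least one
    site.  Sequence outside planted sites is i.i.d. with the given GC
    content.  Placement that fails after ``max_tries`` attempts raises
    :class:`CapacityError`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pwm = pwm or default_pwm()
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    if min(chrom_lengths.values()) < 10_000:
        raise ValueError("chromosomes must be >= 10 kb")

    sequences = {c: _random_sequence(rng, chrom_lengths[c], gc) for c in chroms}
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    sites: list[tuple[str, int, int]] = []
    w = pwm.width
    for _ in range(n_motif_sites):
        for attempt in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            start = int(rng.integers(0, chrom_lengths[chrom] - w))
            if all(start + w <= s or start >= e for s, e in placed[chrom]):
                break
        else:
            raise CapacityError(f"could not place {n_motif_sites} motif sites")
        placed[chrom].append((start, start + w))
        site = _sample_motif(rng, pwm, max_mismatch)
        sequences[chrom][start:start + w] = np.frombuffer(site.encode("ascii"), dtype=np.uint8)
        sites.append((chrom, start, start + w))

    sites.sort()
    if n_peaks > len(sites):
        raise CapacityError("n_peaks exceeds the number of motif sites")
    peak_idx = rng.choice(len(sites), size=n_peaks, replace=False)
    peaks = []
    for i in sorted(peak_idx):
        chrom, s, e = sites[i]
        mid = (s + e) // 2
        start = max(0, mid - peak_width // 2)
        end = min(chrom_lengths[chrom], start + peak_width)
        peaks.append((chrom, start, end))

    return SimGenome(
        sequences={c: seq.tobytes().decode("ascii") for c, seq in sequences.items()},
        motif_sites=FeatureTrack("motif_sites", sites),
        peak_sites=FeatureTrack("peaks", peaks),
        pwm=pwm,
    )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass
class MutagenesisModel:
    """Parameters of the deaminase mutagenesis process.

    ``base_rate`` is the diploid per-base per-generation mutation rate
    outside target windows (default: the endogenous Drosophila rate,
    8.4e-9).  Inside windows of ``target_window`` bp around each
    planted motif site the rate is ``target_rate_multiplier`` times
    higher; the default multiplier of 50 gives roughly a ten-fold
    genome-wide elevation at the default window coverage and is a free
    simulator knob, not a measured quantity.  An induced mutation is a
    deaminase event (C→T, or G→A for a target cytosine on the minus
    strand) with probability ``deamination_fraction``; otherwise it is
    a uniform other substitution at a uniform position.  A surviving
    mutation is sampled heterozygous with probability ``het_fraction``.
    """

    base_rate: float = 8.4e-9
    target_rate_multiplier: float = 50.0
    target_window: int = 100
    deamination_fraction: float = 0.85
    generations: int = 10
    het_fraction: float = 0.883

    def __post_init__(self) -> None:
        if not (0 <= self.deamination_fraction <= 1):
            raise ValueError("deamination_fraction must be in [0, 1]")
        if self.target_rate_multiplier < 1:
            raise ValueError("target_rate_multiplier must be >= 1")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (0 <= self.het_fraction <= 1):
            raise ValueError("het_fraction must be in [0, 1]")


@dataclass
class SequencingModel:
    """Short-read sequencing emission model.

    Depth is overdispersed around ``mean_depth`` (negative-binomial
    blocks; variance = m + dispersion * m^2); genotypes at sites with
    depth below ``missing_below`` are emitted missing; each read
    miscalls its allele with probability ``error_rate``.  A fraction
    ``artifact_fraction`` of emitted records are injected low-quality
    artifacts with QUAL < 10.
    """

    mean_depth: float = 19.2
    depth_dispersion: float = 0.2
    error_rate: float = 0.002
    missing_below: int = 5
    artifact_fraction: float = 0.1
    depth_block: int = 1000

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0 <= self.artifact_fraction < 1):
            raise ValueError("artifact_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandingVariant:
    chrom: str
    pos: int            # 1-based
    ref: str
    alt: str
    kind: str           # 'fixed' or 'pocket'

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class DeNovoMutation:
    chrom: str
    pos: int            # 1-based
    ref: str
    alt: str
    zygosity: int       # copies in the diploid individual: 1 (het) or 2 (hom)
    generation: int
    in_target: bool

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class StockVariation:
    stock: str
    fixed: list[StandingVariant] = field(default_factory=list)
    pockets: list[tuple[str, int, int]] = field(default_factory=list)
    pocket_variants: list[StandingVariant] = field(default_factory=list)


@dataclass
class Lineage:
    lineage_id: str
    stock: str
    mutations: list[DeNovoMutation] = field(default_factory=list)


@dataclass
class SampleSpec:
    sample_id: str
    kind: str                      # 'individual' or 'isogenic'
    stock: str
    lineage: str | None = None
    generation: int = 0
    line_id: str | None = None     # replicate group for isogenic samples
    isogenic_chrom: str | None = None
    # non-mutagenized samples default to the background set; auxiliary
    # stocks (balancer-like) can sit in the full set only
    in_background_set: bool = True
    kept_mutations: frozenset = frozenset()      # de novo keys fixed hom on the isogenized chromosome
    kept_pocket: frozenset = frozenset()         # pocket-variant keys fixed hom on the isogenized chromosome

    @property
    def mutagenized(self) -> bool:
        return self.lineage is not None


@dataclass
class SimTruth:
    genome: SimGenome
    model: MutagenesisModel
    stocks: dict[str, StockVariation] = field(default_factory=dict)
    lineages: dict[str, Lineage] = field(default_factory=dict)
    samples: dict[str, SampleSpec] = field(default_factory=dict)

    def index(self) -> dict[tuple, tuple]:
        """variant key -> ('fixed'|'pocket', stock) or ('denovo', lineage)."""
        idx: dict[tuple, tuple] = {}
        for stock in self.stocks.values():
            for v in stock.fixed:
                idx[v.key] = ("fixed", stock.stock)
            for v in stock.pocket_variants:
                idx[v.key] = ("pocket", stock.stock)
        for lin in self.lineages.values():
            for m in lin.mutations:
                idx[m.key] = ("denovo", lin.lineage_id)
        return idx

    def dosage(self, sample: SampleSpec, variant, _index: dict | None = None) -> int:
        """ALT-allele copies this sample truly carries at ``variant``."""
        idx = _index if _index is not None else self.index()
        origin = idx.get(variant.key)
        if origin is None:
            return 0
        kind, owner = origin
        if kind in ("fixed", "pocket"):
            if owner != sample.stock:
                return 0
            if kind == "fixed":
                return 2
            if sample.kind == "isogenic" and variant.chrom == sample.isogenic_chrom:
                return 2 if variant.key in sample.kept_pocket else 0
            return 1
        if sample.lineage != owner or variant.generation > sample.generation:
            return 0
        if sample.kind == "isogenic" and variant.chrom == sample.isogenic_chrom:
            return 2 if variant.key in sample.kept_mutations else 0
        return variant.zygosity

    def all_variants(self) -> list:
        """All distinct truth variants, sorted by position."""
        seen: dict[tuple, object] = {}
        for stock in self.stocks.values():
            for v in stock.fixed + stock.pocket_variants:
                seen.setdefault(v.key, v)
        for lineage in self.lineages.values():
            for m in lineage.mutations:
                seen.setdefault(m.key, m)
        return [seen[k] for k in sorted(seen)]


# ---------------------------------------------------------------------------
# Standing variation
# ---------------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, n: int, length: int, taken: set[int]) -> list[int]:
    """n distinct 0-based positions avoiding ``taken`` (updates it)."""
    out: list[int] = []
    while len(out) < n:
        p = int(rng.integers(0, length))
        if p not in taken:
            taken.add(p)
            out.append(p)
    return out


def _substitute(rng: np.random.Generator, ref: str) -> str:
    return _OTHER[ref][int(rng.integers(0, 3))]


def simulate_background_stocks(
    genome: SimGenome,
    n_stocks: int,
    fixed_diff_rate: float = 1e-4,
    het_pocket_count: int = 5,
    het_pocket_len: int = 50_000,
    seed: int | np.random.Generator = 0,
    pocket_variant_rate: float = 1e-4,
    stock_names: Sequence[str] | None = None,
) -> SimTruth:
    """Standing variation of laboratory stocks.

    Each stock carries private fixed homozygous differences (Poisson,
    ``fixed_diff_rate`` per base) and ``het_pocket_count`` contiguous
    pockets of residual heterozygosity of length ``het_pocket_len``;
    within a pocket, heterozygous variants occur at
    ``pocket_variant_rate`` per base and are shared by every
    individual sampled from the stock.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = SimTruth(genome=genome, model=MutagenesisModel())
    names = list(stock_names) if stock_names else [f"stock{i+1}" for i in range(n_stocks)]
    taken: dict[str, set[int]] = {c: set() for c in genome.sequences}
    for name in names:
        stock = StockVariation(name)
        for chrom, seq in genome.sequences.items():
            length = len(seq)
            n_fixed = int(rng.poisson(fixed_diff_rate * length))
            for p in sorted(_draw_positions(rng, n_fixed, length, taken[chrom])):
                ref = seq[p]
                stock.fixed.append(StandingVariant(chrom, p + 1, ref, _substitute(rng, ref), "fixed"))
        for _ in range(het_pocket_count):
            chrom = list(genome.sequences)[int(rng.integers(0, len(genome.sequences)))]
            seq = genome.sequences[chrom]
            length = len(seq)
            pocket_len = min(het_pocket_len, length)
            start = int(rng.integers(0, length - pocket_len + 1))
            stock.pockets.append((chrom, start, start + pocket_len))
            n_var = int(rng.poisson(pocket_variant_rate * pocket_len))
            for off in sorted(rng.integers(0, pocket_len, size=n_var)):
                p = start + int(off)
                if p in taken[chrom]:
                    continue
                taken[chrom].add(p)
                ref = seq[p]
                stock.pocket_variants.append(
                    StandingVariant(chrom, p + 1, ref, _substitute(rng, ref), "pocket"))
        truth.stocks[name] = stock
    return truth


# ---------------------------------------------------------------------------
# Mutagenesis
# ---------------------------------------------------------------------------

def _merged_target_windows(genome: SimGenome, window: int) -> dict[str, np.ndarray]:
    """Motif sites expanded by ``window`` bp, merged, per chromosome."""
    out: dict[str, np.ndarray] = {}
    for chrom, arr in genome.motif_sites.by_chrom().items():
        length = len(genome.sequences[chrom])
        expanded = np.clip(arr + [-window, window], 0, length)
        merged: list[list[int]] = []
        for s, e in expanded[np.argsort(expanded[:, 0])]:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([int(s), int(e)])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def _target_length(genome: SimGenome, window: int) -> int:
    return sum(int((arr[:, 1] - arr[:, 0]).sum())
               for arr in _merged_target_windows(genome, window).values())


def _sample_pos_in_intervals(rng, intervals: np.ndarray) -> tuple[int, int]:
    """Uniform 0-based position within a merged interval set (one chrom)."""
    lens = intervals[:, 1] - intervals[:, 0]
    cum = np.cumsum(lens)
    r = int(rng.integers(0, cum[-1]))
    i = int(np.searchsorted(cum, r, side="right"))
    offset = r - (cum[i - 1] if i else 0)
    return int(intervals[i, 0] + offset), i


def _in_intervals(p: int, intervals: np.ndarray) -> bool:
    if len(intervals) == 0:
        return False
    j = int(np.searchsorted(intervals[:, 0], p, side="right"))
    return j > 0 and p < intervals[j - 1, 1]


def simulate_mutagenesis(
    genome: SimGenome,
    model: MutagenesisModel,
    n_lineages: int,
    seed: int | np.random.Generator = 0,
    truth: SimTruth | None = None,
    stock: str = "highevo_stock",
    lineage_prefix: str = "lineage",
) -> SimTruth:
    """Accumulate de novo mutations in ``n_lineages`` over generations.

    Per lineage and generation, mutation counts are Poisson with
    per-base rate ``base_rate`` outside target windows and
    ``base_rate * target_rate_multiplier`` inside; a deaminase event
    requires a C or G reference base and yields C→T or G→A.  Lineages
    inherit all earlier mutations (accumulation is monotone).  When
    ``truth`` is given (standing variation already simulated), the
    lineages are appended to it; the lineages' founder stock is
    ``stock``, created empty if absent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if truth is None:
        truth = SimTruth(genome=genome, model=model)
    else:
        truth.model = model
    truth.stocks.setdefault(stock, StockVariation(stock))

    windows = _merged_target_windows(genome, model.target_window)
    chroms = list(genome.sequences)
    per_chrom_target = {c: int((windows[c][:, 1] - windows[c][:, 0]).sum()) if c in windows and len(windows[c]) else 0
                        for c in chroms}
    per_chrom_len = {c: len(genome.sequences[c]) for c in chroms}

    standing_taken = {
        c: {v.pos - 1 for s in truth.stocks.values()
            for v in s.fixed + s.pocket_variants if v.chrom == c}
        for c in chroms
    }

    for li in range(n_lineages):
        lineage = Lineage(f"{lineage_prefix}{li+1}", stock)
        used: dict[str, set[int]] = {c: set(standing_taken[c]) for c in chroms}
        for gen in range(1, model.generations + 1):
            for chrom in chroms:
                t_len = per_chrom_target[chrom]
                o_len = per_chrom_len[chrom] - t_len
                for in_target, lam in (
                    (True, model.base_rate * model.target_rate_multiplier * t_len),
                    (False, model.base_rate * o_len),
                ):
                    if lam <= 0:
                        continue
                    for _ in range(int(rng.poisson(lam))):
                        mut = _draw_mutation(rng, genome, model, chrom,
                                             windows.get(chrom), in_target, used[chrom], gen)
                        if mut is not None:
                            lineage.mutations.append(mut)
        lineage.mutations.sort(key=lambda m: (m.chrom, m.pos))
        truth.lineages[lineage.lineage_id] = lineage
    return truth


def _draw_mutation(rng, genome, model, chrom, windows, in_target, used, gen,
                   max_tries: int = 10_000):
    seq = genome.sequences[chrom]
    length = len(seq)
    deaminase = bool(rng.random() < model.deamination_fraction)
    for _ in range(max_tries):
        if in_target:
            p, _ = _sample_pos_in_intervals(rng, windows)
        else:
            p = int(rng.integers(0, length))
            if windows is not None and len(windows) and _in_intervals(p, windows):
                continue
        if p in used:
            continue
        ref = seq[p]
        if deaminase:
            if ref == "C":
                alt = "T"
            elif ref == "G":
                alt = "A"
            else:
                continue  # deaminase acts on C/G only; redraw position
        else:
            alt = _substitute(rng, ref)
        used.add(p)
        zyg = 1 if rng.random() < model.het_fraction else 2
        return DeNovoMutation(chrom, p + 1, ref, alt, zyg, gen, in_target)
    return None


# ---------------------------------------------------------------------------
# Sampling and isogenization
# ---------------------------------------------------------------------------

def sample_individual(
    truth: SimTruth,
    sample_id: str,
    stock: str,
    lineage: str | None = None,
    generation: int = 0,
    in_background_set: bool = True,
) -> SampleSpec:
    """Register a diploid individual sampled from a stock or lineage.

    ``in_background_set=False`` puts a non-mutagenized sample in the
    full set only (an auxiliary balancer-like stock): it can veto
    privateness but is not part of the background contrast.
    """
    if lineage is not None and lineage not in truth.lineages:
        raise KeyError(f"unknown lineage {lineage!r}")
    if stock not in truth.stocks:
        raise KeyError(f"unknown stock {stock!r}")
    spec = SampleSpec(sample_id, "individual", stock, lineage, generation,
                      in_background_set=in_background_set)
    truth.samples[sample_id] = spec
    return spec


def simulate_isogenization(
    truth: SimTruth,
    lineage: str,
    replicate_count: int = 2,
    seed: int | np.random.Generator = 0,
    chrom: str | None = None,
    line_id: str | None = None,
    generation: int | None = None,
) -> list[SampleSpec]:
    """Isogenize one chromosome of a lineage into a replicated line.

    One chromosome copy is sampled: each heterozygous de novo mutation
    on the isogenized chromosome survives with probability 1/2 and
    becomes homozygous; homozygous mutations always survive.  The
    founder stock's heterozygous pocket variants on that chromosome
    are resolved the same way.  All ``replicate_count`` samples share
    the resolved chromosome identically.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lineage not in truth.lineages:
        raise KeyError(f"unknown lineage {lineage!r}")
    lin = truth.lineages[lineage]
    chrom = chrom or list(truth.genome.sequences)[-1]
    generation = generation if generation is not None else truth.model.generations
    line_id = line_id or f"{lineage}_iso"

    kept = frozenset(
        m.key for m in lin.mutations
        if m.chrom == chrom and m.generation <= generation
        and (m.zygosity == 2 or rng.random() < 0.5)
    )
    stock = truth.stocks[lin.stock]
    kept_pocket = frozenset(
        v.key for v in stock.pocket_variants
        if v.chrom == chrom and rng.random() < 0.5
    )
    out = []
    for r in range(1, replicate_count + 1):
        spec = SampleSpec(
            sample_id=f"{line_id}_r{r}",
            kind="isogenic",
            stock=lin.stock,
            lineage=lineage,
            generation=generation,
            line_id=line_id,
            isogenic_chrom=chrom,
            kept_mutations=kept,
            kept_pocket=kept_pocket,
        )
        truth.samples[spec.sample_id] = spec
        out.append(spec)
    return out


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def _depth_runs(rng, seq_model: SequencingModel, length: int) -> tuple[np.ndarray, np.ndarray]:
    m = seq_model.mean_depth
    if seq_model.depth_dispersion <= 0:
        return np.array([length]), np.array([int(round(m))])
    block = seq_model.depth_block
    n_blocks = math.ceil(length / block)
    r = 1.0 / seq_model.depth_dispersion
    values = rng.negative_binomial(r, r / (r + m), size=n_blocks)
    lengths = np.full(n_blocks, block, dtype=np.int64)
    lengths[-1] = length - block * (n_blocks - 1)
    return lengths, values.astype(np.int64)


def _call_genotype(dp: int, ao: int, missing_below: int) -> Genotype:
    if dp <= 0 or dp < missing_below:
        return Genotype.MISSING
    af = ao / dp
    if af <= 0.15:
        return Genotype.HOM_REF
    if af >= 0.85:
        return Genotype.HOM_ALT
    return Genotype.HET


def emit_joint_table(
    truth: SimTruth,
    seq_model: SequencingModel | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[VariantRecord], DepthTrack, SampleManifest]:
    """Emit the joint variant table, depth tracks and sample manifest.

    Per-sample depth at a site comes from that sample's simulated
    depth track; ALT observations are binomial in the true allele
    dosage with the model's per-read error rate; genotypes are called
    by allele-fraction thresholds and emitted missing below the depth
    cutoff.  True variants get high QUAL; injected artifact records
    (fraction ``artifact_fraction`` of all emitted records) get
    QUAL < 10.  The manifest records sample sets per chromosome,
    replicate groups, per-sample generation counts and mean depths.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq_model = seq_model or SequencingModel()
    samples = list(truth.samples)
    genome = truth.genome

    depth = DepthTrack()
    edges: dict[tuple[str, str], np.ndarray] = {}
    for s in samples:
        for chrom, seq in genome.sequences.items():
            lengths, values = _depth_runs(rng, seq_model, len(seq))
            depth.set_runs(s, chrom, lengths, values)
            edges[(s, chrom)] = np.cumsum(lengths)

    def depth_lookup(s: str, chrom: str, pos: int) -> int:
        run = int(np.searchsorted(edges[(s, chrom)], pos, side="left"))
        return int(depth.runs[s][chrom][1][run])

    variants = truth.all_variants()
    index = truth.index()
    # depth per sample at every truth site, vectorized per chromosome
    dp_at: dict[str, np.ndarray] = {}
    by_chrom_pos: dict[str, np.ndarray] = {}
    order_in_chrom: dict[int, tuple[str, int]] = {}
    for chrom in genome.sequences:
        pos = np.array([v.pos for v in variants if v.chrom == chrom], dtype=np.int64)
        by_chrom_pos[chrom] = pos
    for s in samples:
        parts = []
        for chrom in genome.sequences:
            pos = by_chrom_pos[chrom]
            runs = np.searchsorted(edges[(s, chrom)], pos, side="left")
            parts.append(depth.runs[s][chrom][1][runs])
        dp_at[s] = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    # variants grouped per chromosome in all_variants' sorted order
    vi_per_sample_order = {}
    offset = 0
    for chrom in genome.sequences:
        n = len(by_chrom_pos[chrom])
        for i, v in enumerate([v for v in variants if v.chrom == chrom]):
            vi_per_sample_order[v.key] = offset + i
        offset += n

    err = seq_model.error_rate
    records: list[VariantRecord] = []
    for variant in variants:
        vi = vi_per_sample_order[variant.key]
        dps = np.array([dp_at[s][vi] for s in samples], dtype=np.int64)
        dose = np.array([truth.dosage(truth.samples[s], variant, index) for s in samples])
        p_alt = (dose / 2) * (1 - err) + (1 - dose / 2) * err
        aos = rng.binomial(dps, p_alt)
        calls: dict[str, GenotypeCall] = {}
        for k, s in enumerate(samples):
            dp, ao = int(dps[k]), int(aos[k])
            gt = _call_genotype(dp, ao, seq_model.missing_below)
            calls[s] = GenotypeCall(gt, dp, dp - ao, ao)
        qual = float(np.round(rng.uniform(50.0, 3000.0), 2))
        records.append(VariantRecord(variant.chrom, variant.pos, variant.ref,
                                     variant.alt, qual, calls))

    # low-QUAL artifact records
    n_true = len(records)
    f = seq_model.artifact_fraction
    n_art = int(round(n_true * f / (1 - f))) if f > 0 else 0
    taken = {(r.chrom, r.pos) for r in records}
    chroms = list(genome.sequences)
    for _ in range(n_art):
        for _ in range(1000):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(1, len(genome.sequences[chrom]) + 1))
            if (chrom, pos) not in taken:
                break
        taken.add((chrom, pos))
        ref = genome.sequences[chrom][pos - 1]
        alt = _substitute(rng, ref)
        victim = samples[int(rng.integers(0, len(samples)))]
        calls = {}
        for s in samples:
            dp = depth_lookup(s, chrom, pos)
            if s == victim and dp > 0:
                ao = min(dp, 1 + int(rng.integers(0, 2)))
                calls[s] = GenotypeCall(Genotype.HET, dp, dp - ao, ao)
            else:
                gt = Genotype.MISSING if (dp <= 0 or dp < seq_model.missing_below) else Genotype.HOM_REF
                calls[s] = GenotypeCall(gt, dp, dp, 0)
        qual = float(np.round(rng.uniform(0.0, 9.99), 2))
        records.append(VariantRecord(chrom, pos, ref, alt, qual, calls))
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt))

    mutagenized = [s for s in samples if truth.samples[s].mutagenized]
    background = [s for s in samples
                  if not truth.samples[s].mutagenized and truth.samples[s].in_background_set]
    chrom_sets = {c: ChromSets(list(samples), mutagenized, background) for c in chroms}
    groups: dict[str, list[str]] = {}
    for s in samples:
        line = truth.samples[s].line_id
        if line is not None:
            groups.setdefault(line, []).append(s)
    manifest = SampleManifest(
        chromosomes=chrom_sets,
        replicate_groups=groups,
        mean_depth={s: round(depth.mean_depth(s), 3) for s in samples},
        generations={s: truth.samples[s].generation for s in samples},
        tags={s: ([f"isogenic-{truth.samples[s].isogenic_chrom}"]
                  if truth.samples[s].kind == "isogenic" else [])
              for s in samples},
    )
    return records, depth, manifest


# ---------------------------------------------------------------------------
# Rate calibration and one-call experiment
# ---------------------------------------------------------------------------

def effective_isogenic_rate(model: MutagenesisModel, genome: SimGenome, chrom: str) -> float:
    """Expected value of the estimator u = Nvar/(nbp*G) on an
    isogenized chromosome under this model.

    Combines the genome-wide elevation from target windows with the
    1/2 transmission probability of heterozygous mutations at
    isogenization.
    """
    length = len(genome.sequences[chrom])
    windows = _merged_target_windows(genome, model.target_window).get(chrom)
    t_len = int((windows[:, 1] - windows[:, 0]).sum()) if windows is not None and len(windows) else 0
    coverage = t_len / length
    elevation = 1 + coverage * (model.target_rate_multiplier - 1)
    transmission = model.het_fraction / 2 + (1 - model.het_fraction)
    return model.base_rate * elevation * transmission


def calibrate_base_rate(target_u: float, model: MutagenesisModel,
                        genome: SimGenome, chrom: str) -> MutagenesisModel:
    """Return a model whose expected isogenic-rate estimate is ``target_u``."""
    probe = replace(model, base_rate=1.0)
    unit = effective_isogenic_rate(probe, genome, chrom)
    return replace(model, base_rate=target_u / unit)


@dataclass
class SimulationResult:
    genome: SimGenome
    truth: SimTruth
    records: list[VariantRecord]
    depth: DepthTrack
    manifest: SampleManifest


def simulate_experiment(
    seed: int,
    chrom_lengths: Mapping[str, int] | None = None,
    gc: float = 0.42,
    n_motif_sites: int = 100,
    n_peaks: int = 20,
    model: MutagenesisModel | None = None,
    seq_model: SequencingModel | None = None,
    n_lines: int = 20,
    replicate_count: int = 2,
    n_background_individuals: int = 6,
    n_mutagenized_individuals: int = 0,
    n_background_stocks: int = 2,
    fixed_diff_rate: float = 1e-4,
    het_pocket_count: int = 5,
    het_pocket_len: int = 50_000,
    pocket_variant_rate: float = 1e-4,
    isogenic_chrom: str | None = None,
) -> SimulationResult:
    """One full mutation-accumulation experiment, end to end.

    Builds a genome, simulates background-stock standing variation,
    mutagenized lineages, chr3-style isogenic lines with replicates,
    background individuals, and emits the joint table.  A single seed
    drives everything, so two runs with the same arguments are
    identical.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = dict(chrom_lengths or {"chr3": 2_000_000})
    model = model or MutagenesisModel()
    seq_model = seq_model or SequencingModel()
    genome = build_genome(rng, chrom_lengths, gc=gc,
                          n_motif_sites=n_motif_sites, n_peaks=n_peaks)
    truth = simulate_background_stocks(
        genome, n_background_stocks, fixed_diff_rate, het_pocket_count,
        het_pocket_len, rng, pocket_variant_rate,
        stock_names=["highevo_stock"] + [f"bg_stock{i}" for i in range(1, n_background_stocks)],
    )
    simulate_mutagenesis(genome, model, n_lines + n_mutagenized_individuals,
                         rng, truth, stock="highevo_stock")
    lineage_ids = list(truth.lineages)
    isogenic_chrom = isogenic_chrom or list(chrom_lengths)[-1]
    for i in range(n_lines):
        simulate_isogenization(truth, lineage_ids[i], replicate_count, rng,
                               chrom=isogenic_chrom, line_id=f"line{i+1}")
    for j, lid in enumerate(lineage_ids[n_lines:], 1):
        sample_individual(truth, f"mut_ind{j}", "highevo_stock", lid, model.generations)
    # background-set individuals come from the founder stock of the
    # mutagenized lineages; individuals of other stocks enter the full
    # set only, like the auxiliary balancer stocks in a real design
    stocks = list(truth.stocks)
    for k in range(n_background_individuals):
        stock = stocks[k % len(stocks)]
        sample_individual(truth, f"bg_{stock}_{k+1}", stock, None, 0,
                          in_background_set=(stock == "highevo_stock"))
    records, depth, manifest = emit_joint_table(truth, seq_model, rng)
    return SimulationResult(genome, truth, records, depth, manifest)
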