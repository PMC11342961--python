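"""Readers and writers for the formats the pipeline touches.

Joint multi-sample VCF (freebayes-style FORMAT ``GT:DP:RO:AO``), BED3
feature tracks, FASTA genomes, and per-sample per-base depth tables.
Coordinate conventions are enforced at this boundary: VCF positions are
1-based, BED intervals 0-based half-open.  :func:`pos_to_zero_based` and
:func:`zero_based_to_pos` are the only places where +/-1 arithmetic
happens.

Multi-allelic VCF records are decomposed on read: every ALT allele
becomes its own biallelic :class:`VariantRecord`.  A diploid genotype
containing allele index *k* maps to ``het`` (one copy) or ``hom_alt``
(two copies) for the record of allele *k*; copies of *other* ALT alleles
count as reference for zygosity purposes.  AO is the per-allele
observation count; RO is the record-level reference observation count,
unchanged — matching freebayes FORMAT semantics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genotype",
    "GenotypeCall",
    "VariantRecord",
    "FeatureTrack",
    "DepthTrack",
    "VcfFormatError",
    "BedFormatError",
    "ConsistencyError",
    "pos_to_zero_based",
    "zero_based_to_pos",
    "read_joint_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_depth_table",
    "write_depth_table",
    "read_depth_bedgraph",
    "write_depth_bedgraph",
    "records_equal",
]


class VcfFormatError(ValueError):
    """Malformed VCF input (bad header, or FORMAT lacking GT)."""


class BedFormatError(ValueError):
    """Malformed BED input (bad column count, or start >= end)."""


class ConsistencyError(ValueError):
    """Input is well-formed but internally inconsistent."""


def pos_to_zero_based(pos: int) -> int:
    """1-based VCF position -> 0-based sequence index."""
    return pos - 1


def zero_based_to_pos(idx: int) -> int:
    """0-based sequence index -> 1-based VCF position."""
    return idx + 1


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


@dataclass
class GenotypeCall:
    """One sample's call at one (decomposed) variant record.

    ``dp``/``ro``/``ao`` may be ``None`` when the caller emitted no
    value (always possible for ``missing`` genotypes).
    """

    gt: Genotype
    dp: int | None = None
    ro: int | None = None
    ao: int | None = None

    def __post_init__(self) -> None:
        for name in ("dp", "ro", "ao"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


_BASES = set("ACGT")


@dataclass
class VariantRecord:
    """A biallelic variant with per-sample genotype calls.

    ``pos`` is 1-based; ``ref``/``alt`` are non-empty strings over
    {A,C,G,T} (lengths may differ for indels).  ``calls`` preserves
    the joint call's sample order.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele) - _BASES:
                raise ValueError(f"{name} must be a non-empty ACGT string, got {allele!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self) -> list[str]:
        """Samples whose genotype contains at least one ALT copy."""
        return [s for s, c in self.calls.items() if c.gt.carries_alt()]


def records_equal(a: VariantRecord, b: VariantRecord, qual_tol: float = 1e-3) -> bool:
    """Field-for-field equality; QUAL compared with tolerance because
    VCF text carries it through a 32-bit float."""
    if (a.chrom, a.pos, a.ref, a.alt) != (b.chrom, b.pos, b.ref, b.alt):
        return False
    if abs(a.qual - b.qual) > qual_tol * max(1.0, abs(a.qual)):
        return False
    if list(a.calls) != list(b.calls):
        return False
    for s in a.calls:
        ca, cb = a.calls[s], b.calls[s]
        if (ca.gt, ca.dp, ca.ro, ca.ao) != (cb.gt, cb.dp, cb.ro, cb.ao):
            return False
    return True


@dataclass
class FeatureTrack:
    """Named set of genomic intervals, 0-based half-open (BED)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"bad interval {chrom}:{start}-{end} (need 0 <= start < end)")
        self.intervals.sort()

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Intervals per chromosome as (n, 2) int arrays, sorted by start."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, []).append((start, end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


class DepthTrack:
    """Per-sample per-chromosome read depth, run-length encoded.

    ``runs[sample][chrom]`` is a pair of int arrays ``(lengths, values)``
    covering the chromosome from position 1 without gaps.
    """

    def __init__(self, runs: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] | None = None):
        self.runs: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = runs or {}

    @classmethod
    def from_constant(cls, samples: Iterable[str], chrom_lengths: Mapping[str, int], depth: int) -> "DepthTrack":
        runs = {
            s: {c: (np.array([length], dtype=np.int64), np.array([depth], dtype=np.int64))
                for c, length in chrom_lengths.items()}
            for s in samples
        }
        return cls(runs)

    def set_runs(self, sample: str, chrom: str, lengths: np.ndarray, values: np.ndarray) -> None:
        lengths = np.asarray(lengths, dtype=np.int64)
        values = np.asarray(values, dtype=np.int64)
        if lengths.shape != values.shape:
            raise ValueError("lengths and values must have equal shape")
        if np.any(lengths <= 0) or np.any(values < 0):
            raise ValueError("run lengths must be positive and depths non-negative")
        self.runs.setdefault(sample, {})[chrom] = (lengths, values)

    def samples(self) -> list[str]:
        return list(self.runs)

    def chrom_length(self, sample: str, chrom: str) -> int:
        lengths, _ = self.runs[sample][chrom]
        return int(lengths.sum())

    def depth_at(self, sample: str, chrom: str, pos: int) -> int:
        """Depth at 1-based position ``pos``."""
        lengths, values = self.runs[sample][chrom]
        edges = np.cumsum(lengths)
        idx = int(np.searchsorted(edges, pos, side="left"))
        if idx >= len(values):
            raise KeyError(f"position {pos} beyond {chrom} for {sample}")
        return int(values[idx])

    def to_array(self, sample: str, chrom: str) -> np.ndarray:
        lengths, values = self.runs[sample][chrom]
        return np.repeat(values, lengths)

    def mean_depth(self, sample: str, chrom: str | None = None) -> float:
        chroms = [chrom] if chrom is not None else list(self.runs[sample])
        tot = n = 0
        for c in chroms:
            lengths, values = self.runs[sample][c]
            tot += int(lengths @ values)
            n += int(lengths.sum())
        return tot / n


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_FORMAT_LINES = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">',
    '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">',
]


def _scalar(value) -> int | None:
    if value is None:
        return None
    if isinstance(value, (tuple, list, np.ndarray)):
        value = value[0]
    return None if value is None else int(value)


def read_joint_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a joint multi-sample VCF into decomposed biallelic records.

    Multi-allelic sites yield one record per ALT allele (see module
    docstring for the genotype mapping).  Missing QUAL becomes 0 so the
    record fails any QUAL >= 10 prefilter.  Raises
    :class:`VcfFormatError` if the header is malformed or a record's
    FORMAT lacks GT.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"malformed VCF header in {path}: {exc}") from exc
    out: list[VariantRecord] = []
    with vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            if "GT" not in rec.format:
                raise VcfFormatError(
                    f"FORMAT lacks GT at {rec.chrom}:{rec.pos} in {path}"
                )
            qual = float(rec.qual) if rec.qual is not None else 0.0
            for i, alt in enumerate(rec.alts):
                calls: dict[str, GenotypeCall] = {}
                for s in samples:
                    sd = rec.samples[s]
                    gt_tuple = sd.get("GT", (None,))
                    dp = _scalar(sd.get("DP"))
                    ro = _scalar(sd.get("RO"))
                    ao_raw = sd.get("AO")
                    if isinstance(ao_raw, (tuple, list)):
                        ao = None if ao_raw[i] is None else int(ao_raw[i])
                    else:
                        ao = _scalar(ao_raw)
                    if gt_tuple is None or all(a is None for a in gt_tuple):
                        calls[s] = GenotypeCall(Genotype.MISSING, dp, ro, ao)
                        continue
                    copies = sum(1 for a in gt_tuple if a == i + 1)
                    if copies == 0:
                        gt = Genotype.HOM_REF
                    elif copies == 1:
                        gt = Genotype.HET
                    else:
                        gt = Genotype.HOM_ALT
                    calls[s] = GenotypeCall(gt, dp, ro, ao)
                out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, str(alt), qual, calls))
    return out


_GT_TUPLES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
    Genotype.MISSING: (None, None),
}


def write_vcf(records: Sequence[VariantRecord], samples: Sequence[str], path: str | Path) -> None:
    """Write decomposed biallelic records as a VCF v4.2 text file.

    Every record must carry calls for exactly ``samples`` (same order);
    otherwise a :class:`ConsistencyError` is raised.  Round-trips with
    :func:`read_joint_vcf`.
    """
    header = pysam.VariantHeader()
    for line in _FORMAT_LINES:
        header.add_line(line)
    seen: list[str] = []
    for rec in records:
        if rec.chrom not in seen:
            seen.append(rec.chrom)
    for chrom in seen:
        header.contigs.add(chrom)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in records:
            if set(rec.calls) != set(samples):
                raise ConsistencyError(
                    f"record {rec.chrom}:{rec.pos} has samples {sorted(rec.calls)}, expected {sorted(samples)}"
                )
            out = vf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
                qual=rec.qual,
            )
            for s in samples:
                call = rec.calls[s]
                out.samples[s]["GT"] = _GT_TUPLES[call.gt]
                if call.dp is not None:
                    out.samples[s]["DP"] = call.dp
                if call.ro is not None:
                    out.samples[s]["RO"] = call.ro
                if call.ao is not None:
                    out.samples[s]["AO"] = (call.ao,)
            vf.write(out)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, name: str | None = None) -> FeatureTrack:
    """Read a BED3+ file into a sorted :class:`FeatureTrack`.

    Extra columns beyond the first three are ignored.  ``start >= end``
    raises :class:`BedFormatError` naming the offending line.
    """
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"{path}:{lineno}: need 0 <= start < end, got {start}, {end}"
                )
            intervals.append((chrom, start, end))
    return FeatureTrack(name or Path(path).stem, intervals)


def write_bed(track: FeatureTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}; duplicate names raise."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ConsistencyError(f"duplicate sequence name {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(entries: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Depth tables
# ---------------------------------------------------------------------------

def _runs_from_array(depths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(depths)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(depths)]))
    return (ends - starts).astype(np.int64), depths[starts].astype(np.int64)


def read_depth_table(path: str | Path, sample: str) -> DepthTrack:
    """Read a samtools-depth-style table (chrom, 1-based pos, depth).

    Positions must be contiguous from 1 within each chromosome.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"])
    track = DepthTrack()
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if pos[0] != 1 or np.any(np.diff(pos) != 1):
            raise ConsistencyError(f"depth table {path}: non-contiguous positions on {chrom}")
        lengths, values = _runs_from_array(sub["depth"].to_numpy())
        track.set_runs(sample, str(chrom), lengths, values)
    return track


def write_depth_table(track: DepthTrack, sample: str, path: str | Path) -> None:
    """Write one sample's depth as a per-base 3-column table.

    Only sensible for small genomes; prefer
    :func:`write_depth_bedgraph` at simulation scale.
    """
    with open(path, "w") as fh:
        for chrom, (lengths, values) in track.runs[sample].items():
            pos = 1
            for length, value in zip(lengths, values):
                for p in range(pos, pos + int(length)):
                    fh.write(f"{chrom}\t{p}\t{int(value)}\n")
                pos += int(length)


def write_depth_bedgraph(track: DepthTrack, sample: str, path: str | Path) -> None:
    """Write one sample's depth as bedGraph (chrom, 0-based start, end, depth)."""
    with open(path, "w") as fh:
        for chrom, (lengths, values) in track.runs[sample].items():
            start = 0
            for length, value in zip(lengths, values):
                fh.write(f"{chrom}\t{start}\t{start + int(length)}\t{int(value)}\n")
                start += int(length)


def read_depth_bedgraph(path: str | Path, sample: str) -> DepthTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "depth"])
    track = DepthTrack()
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
            raise ConsistencyError(f"bedGraph {path}: non-contiguous runs on {chrom}")
        track.set_runs(sample, str(chrom), (ends - starts), sub["depth"].to_numpy())
    return track
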