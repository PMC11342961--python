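from __future__ import annotations

import numpy as np
import pytest

from highevo.private_variants import ChromSets, SampleManifest
from highevo.synthetic_data import (MutagenesisModel, SequencingModel,
                                    build_genome, calibrate_base_rate,
                                    emit_joint_table, sample_individual,
                                    simulate_background_stocks,
                                    simulate_isogenization,
                                    simulate_mutagenesis)
from highevo.variant_io import Genotype, GenotypeCall, VariantRecord


def make_call(gt="hom_ref", dp=20, ro=None, ao=None):
    gt = Genotype(gt)
    if gt is Genotype.MISSING:
        return GenotypeCall(gt)
    if ao is None:
        ao = {"hom_ref": 0, "het": dp // 2, "hom_alt": dp}[gt.value]
    if ro is None:
        ro = dp - ao
    return GenotypeCall(gt, dp, ro, ao)


def make_record(chrom="chr3", pos=100, ref="C", alt="T", qual=50.0, calls=None):
    return VariantRecord(chrom, pos, ref, alt, qual, calls or {})


def random_joint_table(rng: np.random.Generator, n_variants=200, n_samples=12,
                       chrom="chr3", span=5_000_000):
    """Randomized joint table + manifest exercising every pipeline rule."""
    samples = [f"s{i}" for i in range(n_samples)]
    # a couple of samples outside the full set, a mut/bg partition, replicate groups
    n_full = max(4, n_samples - int(rng.integers(0, 3)))
    full = samples[:n_full]
    n_mut = int(rng.integers(1, max(2, n_full - 2)))
    mutagenized = full[:n_mut]
    n_bg = int(rng.integers(1, max(2, n_full - n_mut)))
    background = full[n_mut:n_mut + n_bg]
    groups = {}
    gi = 0
    i = 0
    while i + 1 < len(mutagenized):
        if rng.random() < 0.6:
            size = 2 if rng.random() < 0.8 else min(3, len(mutagenized) - i)
            groups[f"g{gi}"] = mutagenized[i:i + size]
            gi += 1
            i += size
        else:
            i += 1
    manifest = SampleManifest(
        chromosomes={chrom: ChromSets(full, mutagenized, background)},
        replicate_groups=groups,
        mean_depth={s: float(rng.uniform(3, 30)) for s in samples},
        generations={s: int(rng.integers(1, 26)) for s in samples},
    )
    gt_choices = np.array(["hom_ref", "het", "hom_alt", "missing"])
    records = []
    positions = set()
    bases = "ACGT"

    def one_record(pos, carrier_bias=None):
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        calls = {}
        for s in samples:
            if carrier_bias is not None:
                gt = "het" if s == carrier_bias else str(rng.choice(
                    ["hom_ref", "missing"], p=[0.8, 0.2]))
            else:
                gt = str(rng.choice(gt_choices, p=[0.55, 0.2, 0.1, 0.15]))
            dp = int(rng.integers(0, 250))
            ao = {"hom_ref": int(rng.integers(0, min(dp, 1) + 1)),
                  "het": int(rng.integers(0, dp + 1)),
                  "hom_alt": dp,
                  "missing": 0}[gt]
            calls[s] = (GenotypeCall(Genotype.MISSING) if gt == "missing"
                        else GenotypeCall(Genotype(gt), dp, dp - ao, ao))
        return VariantRecord(chrom, pos, str(ref), str(alt),
                             float(np.round(rng.uniform(0, 40), 2)), calls)

    for _ in range(n_variants):
        pos = int(rng.integers(1, span))
        while pos in positions:
            pos = int(rng.integers(1, span))
        positions.add(pos)
        records.append(one_record(pos))
    # occasionally plant an introgression-like cluster in one sample
    if rng.random() < 0.4 and mutagenized:
        victim = mutagenized[int(rng.integers(0, len(mutagenized)))]
        anchor = int(rng.integers(1, span - 60_000))
        for k in range(25):
            pos = anchor + int(rng.integers(0, 50_000))
            if pos in positions:
                continue
            positions.add(pos)
            records.append(one_record(pos, carrier_bias=victim))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records, manifest


@pytest.fixture(scope="session")
def small_genome():
    return build_genome(11, {"chrA": 100_000}, n_motif_sites=20, n_peaks=5)


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Small experiment with noise-free sequencing: emitted genotypes
    equal truth genotypes, so pipeline output can be compared with the
    simulated truth exactly."""
    rng = np.random.default_rng(7)
    genome = build_genome(rng, {"chr3": 500_000}, n_motif_sites=30, n_peaks=6)
    model = calibrate_base_rate(2e-6, MutagenesisModel(generations=10), genome, "chr3")
    truth = simulate_background_stocks(genome, 2, seed=rng,
                                       stock_names=["highevo_stock", "bg_stock"])
    simulate_mutagenesis(genome, model, 6, rng, truth, stock="highevo_stock")
    for i, lid in enumerate(list(truth.lineages)):
        simulate_isogenization(truth, lid, 2, rng, chrom="chr3", line_id=f"line{i+1}")
    for k in range(4):
        sample_individual(truth, f"bg{k}", ["highevo_stock", "bg_stock"][k % 2], None, 0)
    seq_model = SequencingModel(mean_depth=30, depth_dispersion=0.0, error_rate=0.0,
                                missing_below=0, artifact_fraction=0.0)
    records, depth, manifest = emit_joint_table(truth, seq_model, rng)
    return {"genome": genome, "truth": truth, "records": records,
            "depth": depth, "manifest": manifest, "model": model}
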