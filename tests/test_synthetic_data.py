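import math

import numpy as np
import pytest
from scipy import stats

from highevo.rate_spectrum import classify_variant
from highevo.synthetic_data import (CapacityError, MutagenesisModel,
                                    SequencingModel, build_genome,
                                    calibrate_base_rate, default_pwm,
                                    effective_isogenic_rate, emit_joint_table,
                                    sample_individual,
                                    simulate_background_stocks,
                                    simulate_isogenization,
                                    simulate_mutagenesis)
from highevo.variant_io import Genotype


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def test_build_genome_places_nonoverlapping_consensus_sites():
    genome = build_genome(1, {"c": 100_000}, n_motif_sites=50, n_peaks=10, max_mismatch=1)
    sites = genome.motif_sites.intervals
    assert len(sites) == 50
    for (c1, s1, e1), (c2, s2, e2) in zip(sites, sites[1:]):
        assert c1 != c2 or e1 <= s2  # sorted, non-overlapping
    consensus = genome.pwm.consensus()
    for chrom, start, end in sites:
        planted = genome.sequences[chrom][start:end]
        assert sum(a != b for a, b in zip(planted, consensus)) <= 1
    # every peak contains at least one motif site
    for chrom, ps, pe in genome.peak_sites.intervals:
        assert any(c == chrom and s >= ps and e <= pe for c, s, e in sites)


def test_build_genome_gc_zero_is_at_only_outside_sites():
    genome = build_genome(2, {"c": 20_000}, gc=0.0, n_motif_sites=3, n_peaks=1)
    seq = np.array(list(genome.sequences["c"]))
    mask = np.ones(len(seq), dtype=bool)
    for _, s, e in genome.motif_sites.intervals:
        mask[s:e] = False
    assert set(seq[mask]) <= {"A", "T"}


def test_build_genome_deterministic():
    g1 = build_genome(5, {"c": 15_000}, n_motif_sites=10, n_peaks=2)
    g2 = build_genome(5, {"c": 15_000}, n_motif_sites=10, n_peaks=2)
    assert g1.sequences == g2.sequences
    assert g1.motif_sites.intervals == g2.motif_sites.intervals


def test_build_genome_capacity_error():
    with pytest.raises(CapacityError):
        build_genome(3, {"c": 10_000}, n_motif_sites=5, n_peaks=6)


# ---------------------------------------------------------------------------
# standing variation
# ---------------------------------------------------------------------------

def test_background_stocks_structure(small_genome):
    truth = simulate_background_stocks(small_genome, 2, fixed_diff_rate=1e-3,
                                       het_pocket_count=2, het_pocket_len=5_000,
                                       seed=4, pocket_variant_rate=2e-3)
    for stock in truth.stocks.values():
        assert len(stock.pockets) == 2
        for chrom, start, end in stock.pockets:
            assert end - start == 5_000
        for v in stock.pocket_variants:
            assert any(c == v.chrom and s < v.pos <= e for c, s, e in stock.pockets)
    # stocks carry disjoint variant sets (positions drawn without collision)
    keys = [set(v.key for v in s.fixed + s.pocket_variants) for s in truth.stocks.values()]
    assert not (keys[0] & keys[1])


def test_background_stocks_zero_rate_no_fixed_diffs(small_genome):
    truth = simulate_background_stocks(small_genome, 1, fixed_diff_rate=0.0,
                                       het_pocket_count=0, seed=0)
    stock = next(iter(truth.stocks.values()))
    assert stock.fixed == [] and stock.pocket_variants == []


# ---------------------------------------------------------------------------
# mutagenesis
# ---------------------------------------------------------------------------

def test_uniform_rate_puts_mutations_in_targets_at_coverage_fraction(small_genome):
    """With multiplier 1 the in-target fraction matches the fraction of
    the genome covered by target windows (binomial test)."""
    model = MutagenesisModel(base_rate=1e-3, target_rate_multiplier=1.0,
                             target_window=100, generations=5,
                             deamination_fraction=0.0)
    truth = simulate_mutagenesis(small_genome, model, 4, seed=6)
    muts = [m for lin in truth.lineages.values() for m in lin.mutations]
    assert len(muts) >= 1000
    n_in = sum(m.in_target for m in muts)
    from highevo.synthetic_data import _target_length
    frac = _target_length(small_genome, 100) / small_genome.total_length()
    p = stats.binomtest(n_in, len(muts), frac).pvalue
    assert p > 1e-4


def test_doubling_generations_doubles_mean_count(small_genome):
    kwargs = dict(base_rate=4e-4, target_rate_multiplier=1.0, deamination_fraction=0.5)
    n = {}
    for g, seed in ((5, 10), (10, 11)):
        truth = simulate_mutagenesis(small_genome, MutagenesisModel(generations=g, **kwargs),
                                     10, seed=seed)
        n[g] = sum(len(l.mutations) for l in truth.lineages.values())
    ratio = n[10] / n[5]
    # Poisson sampling error: each count ~ Poisson(mean >= 1000)
    assert 1.8 < ratio < 2.2


def test_deamination_one_yields_only_signature_mutations(small_genome):
    model = MutagenesisModel(base_rate=1e-4, deamination_fraction=1.0, generations=3)
    truth = simulate_mutagenesis(small_genome, model, 3, seed=12)
    muts = [m for lin in truth.lineages.values() for m in lin.mutations]
    assert muts
    assert all((m.ref, m.alt) in (("C", "T"), ("G", "A")) for m in muts)


def test_mutation_accumulation_is_monotone(small_genome):
    model = MutagenesisModel(base_rate=1e-6, generations=8)
    truth = simulate_mutagenesis(small_genome, model, 2, seed=13)
    for lin in truth.lineages.values():
        gens = [m.generation for m in lin.mutations]
        assert all(1 <= g <= 8 for g in gens)


# ---------------------------------------------------------------------------
# isogenization
# ---------------------------------------------------------------------------

def test_isogenization_replicates_share_truth(small_genome):
    model = MutagenesisModel(base_rate=2e-6, generations=5)
    truth = simulate_mutagenesis(small_genome, model, 1, seed=14)
    reps = simulate_isogenization(truth, "lineage1", replicate_count=2, seed=15)
    assert reps[0].kept_mutations == reps[1].kept_mutations
    assert reps[0].line_id == reps[1].line_id


def test_isogenization_unknown_lineage_raises(small_genome):
    truth = simulate_mutagenesis(small_genome, MutagenesisModel(), 1, seed=0)
    with pytest.raises(KeyError):
        simulate_isogenization(truth, "nope")


def test_het_transmission_probability_is_half(small_genome):
    """A heterozygous de novo mutation survives isogenization with
    probability 1/2 (binomial CI over 500 transmissions)."""
    model = MutagenesisModel(base_rate=5e-5, generations=4, het_fraction=1.0)
    truth = simulate_mutagenesis(small_genome, model, 1, seed=16)
    lin = truth.lineages["lineage1"]
    n_het = len(lin.mutations)
    assert n_het >= 10
    rng = np.random.default_rng(17)
    kept = 0
    total = 0
    for i in range(500):
        reps = simulate_isogenization(truth, "lineage1", 1, rng, line_id=f"t{i}")
        kept += len(reps[0].kept_mutations)
        total += sum(1 for m in lin.mutations if m.chrom == reps[0].isogenic_chrom)
    lo, hi = stats.binomtest(kept, total, 0.5).proportion_ci(0.999)
    assert lo <= 0.5 <= hi


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def test_noise_free_emission_matches_truth(noise_free_experiment):
    exp = noise_free_experiment
    truth, records = exp["truth"], exp["records"]
    index = truth.index()
    expected_gt = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}
    by_key = {}
    for v in truth.all_variants():
        by_key[v.key] = v
    assert len(records) == len(by_key)
    for rec in records:
        v = by_key[rec.key]
        for s, call in rec.calls.items():
            d = truth.dosage(truth.samples[s], v, index)
            assert call.gt is expected_gt[d], (rec.key, s)


def test_low_depth_yields_mostly_missing(small_genome):
    truth = simulate_background_stocks(small_genome, 1, fixed_diff_rate=1e-3, seed=20)
    sample_individual(truth, "s1", next(iter(truth.stocks)), None, 0)
    seq = SequencingModel(mean_depth=5, depth_dispersion=0.3, missing_below=10,
                          artifact_fraction=0.0)
    records, _, _ = emit_joint_table(truth, seq, seed=21)
    gts = [r.calls["s1"].gt for r in records]
    assert sum(1 for g in gts if g is Genotype.MISSING) > len(gts) / 2


def test_artifact_fraction_controls_low_qual_share(small_genome):
    truth = simulate_background_stocks(small_genome, 2, fixed_diff_rate=2e-3, seed=22)
    for i, s in enumerate(truth.stocks):
        sample_individual(truth, f"ind{i}", s, None, 0)
    seq = SequencingModel(artifact_fraction=0.1)
    records, _, _ = emit_joint_table(truth, seq, seed=23)
    n_low = sum(1 for r in records if r.qual < 10)
    frac = n_low / len(records)
    lo, hi = stats.binomtest(n_low, len(records), 0.1).proportion_ci(0.999)
    assert lo <= 0.1 <= hi, frac


def test_emission_deterministic(small_genome):
    truth = simulate_background_stocks(small_genome, 1, seed=24)
    sample_individual(truth, "s1", next(iter(truth.stocks)), None, 0)
    r1, d1, m1 = emit_joint_table(truth, SequencingModel(), seed=25)
    r2, d2, m2 = emit_joint_table(truth, SequencingModel(), seed=25)
    assert [(r.key, r.qual) for r in r1] == [(r.key, r.qual) for r in r2]
    assert m1.mean_depth == m2.mean_depth


# ---------------------------------------------------------------------------
# rate calibration
# ---------------------------------------------------------------------------

def test_calibrate_base_rate_inverts_effective_rate(small_genome):
    model = MutagenesisModel(generations=12)
    cal = calibrate_base_rate(5e-8, model, small_genome, "chrA")
    assert effective_isogenic_rate(cal, small_genome, "chrA") == pytest.approx(5e-8)


def test_spectrum_recovery_at_085(noise_free_experiment):
    """deamination_fraction = 0.85 is recovered in the emitted variant
    classes of true de novo mutations (binomial CI)."""
    exp = noise_free_experiment
    assert exp["model"].deamination_fraction == 0.85
    muts = [m for lin in exp["truth"].lineages.values() for m in lin.mutations]
    n_sig = sum(1 for m in muts if (m.ref, m.alt) in (("C", "T"), ("G", "A")))
    lo, hi = stats.binomtest(n_sig, len(muts), 0.85).proportion_ci(0.999)
    assert lo <= 0.85 <= hi
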