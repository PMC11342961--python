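import numpy as np
import pytest

from highevo.private_variants import (ChromSets, SampleManifest,
                                      cross_coverage_filter, depth_exclusion,
                                      detect_introgression, genotype_filter,
                                      privateness_removed_percent,
                                      qual_prefilter, replicate_rescue,
                                      reversion_audit, run_private_pipeline,
                                      select_private)
from highevo.variant_io import Genotype, GenotypeCall

from conftest import make_call, make_record, random_joint_table
from reference_impl import reference_pipeline


def _manifest(full, mut, bg, groups=None, chrom="chr3", depths=None):
    return SampleManifest(
        chromosomes={chrom: ChromSets(full, mut, bg)},
        replicate_groups=groups or {},
        mean_depth=depths or {s: 20.0 for s in full},
    )


# ---------------------------------------------------------------------------
# qual prefilter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("qual,kept", [(10.0, True), (9.99, False), (0.0, False), (1000.0, True)])
def test_qual_boundary(qual, kept):
    recs = [make_record(qual=qual, calls={"a": make_call()})]
    assert (len(qual_prefilter(recs)) == 1) is kept


def test_qual_prefilter_counts():
    rng = np.random.default_rng(1)
    quals = np.concatenate([rng.uniform(0, 9.99, size=37), rng.uniform(10, 100, size=63)])
    rng.shuffle(quals)
    recs = [make_record(pos=i + 1, qual=float(q), calls={"a": make_call()})
            for i, q in enumerate(quals)]
    assert len(qual_prefilter(recs)) == 63


# ---------------------------------------------------------------------------
# privateness
# ---------------------------------------------------------------------------

def test_private_basic_and_strictness():
    full = ["m1", "m2", "b1", "balancer"]
    sets = ChromSets(full, ["m1", "m2"], ["b1"])
    only_mut = make_record(pos=10, calls={
        "m1": make_call("het"), "m2": make_call(), "b1": make_call(), "balancer": make_call()})
    # a low-quality (filter-failing) het in a non-target sample still voids privateness
    leaked = make_record(pos=20, calls={
        "m1": make_call("het"), "m2": make_call(), "b1": make_call(),
        "balancer": GenotypeCall(Genotype.HET, dp=2, ro=1, ao=1)})
    missing_elsewhere = make_record(pos=30, calls={
        "m1": make_call("hom_alt"), "m2": make_call("missing"),
        "b1": make_call("missing"), "balancer": make_call()})
    pset = select_private([only_mut, leaked, missing_elsewhere], sets, "mutagenized")
    assert {v.record.pos for v in pset.variants} == {10, 30}


def test_private_empty_target_raises():
    sets = ChromSets(["a"], [], ["a"])
    with pytest.raises(ValueError):
        select_private([], sets, "mutagenized")


def test_private_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    records, manifest = random_joint_table(rng, n_variants=200, n_samples=12)
    sets = manifest.chromosomes["chr3"]
    for target in ("mutagenized", "background"):
        got = select_private(records, sets, target).keys()
        tset = set(sets.target(target))
        others = [s for s in sets.full if s not in tset]
        expected = set()
        for r in records:
            carrier = any(s in r.calls and r.calls[s].gt.carries_alt() for s in tset)
            leak = any(s in r.calls and r.calls[s].gt.carries_alt() for s in others)
            if carrier and not leak:
                expected.add(r.key)
        assert got == expected


# ---------------------------------------------------------------------------
# genotype filter & rescue
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("gt,dp,ao,ro,expected", [
    ("het", 20, 3, 3, True),     # minimum passing het
    ("het", 20, 2, 18, False),   # AO > 2 required
    ("het", 20, 18, 2, False),   # RO > 2 required
    ("hom_alt", 9, 9, 0, False),
    ("hom_alt", 10, 10, 0, True),
    ("hom_alt", 200, 200, 0, True),
    ("hom_alt", 201, 201, 0, False),
    ("hom_ref", 15, 0, 15, True),
])
def test_genotype_filter_boundaries(gt, dp, ao, ro, expected):
    assert genotype_filter(GenotypeCall(Genotype(gt), dp, ro, ao)) is expected


def test_genotype_filter_missing_is_undefined():
    with pytest.raises(ValueError):
        genotype_filter(GenotypeCall(Genotype.MISSING))


def test_replicate_rescue_rules():
    manifest = _manifest(["a1", "a2", "b1", "p"], ["a1", "a2", "b1", "p"], [],
                         groups={"L": ["a1", "a2", "p"], "M": ["b1"]})
    assert replicate_rescue(["a1", "a2"], manifest)          # both replicates, any depth
    assert not replicate_rescue(["a1", "b1"], manifest)      # different lines
    assert replicate_rescue(["a1", "p"], manifest)           # parent counts as group member
    assert not replicate_rescue(["a1"], manifest)


# ---------------------------------------------------------------------------
# cross coverage
# ---------------------------------------------------------------------------

def test_cross_coverage_boundary():
    full = ["m1", "b1", "b2", "b3"]
    sets = ChromSets(full, ["m1"], ["b1", "b2", "b3"])

    def rec(n_bg_called):
        calls = {"m1": make_call("het", dp=30, ao=10, ro=20)}
        for i, b in enumerate(["b1", "b2", "b3"]):
            calls[b] = make_call("hom_ref") if i < n_bg_called else make_call("missing")
        return make_record(calls=calls)

    for n, kept in [(0, False), (1, False), (2, True), (3, True)]:
        pset = select_private([rec(n)], sets, "mutagenized")
        out = cross_coverage_filter(pset, sets)
        assert (len(out) == 1) is kept, n


# ---------------------------------------------------------------------------
# introgression
# ---------------------------------------------------------------------------

def _pset_with_positions(sample, positions, chrom="chr2L"):
    from highevo.private_variants import PrivateVariant, PrivateVariantSet
    pset = PrivateVariantSet("mutagenized")
    for p in positions:
        rec = make_record(chrom=chrom, pos=p, calls={sample: make_call("het")})
        pset.variants.append(PrivateVariant(rec, [sample], {sample: Genotype.HET}))
    return pset


def test_introgression_flags_dense_cluster():
    positions = list(range(1_000_000, 1_030_000, 1200))  # 25 variants in 30 kb
    pset = _pset_with_positions("s1", positions)
    assert detect_introgression([pset], window_kb=100, min_count=20) == ["s1"]


def test_introgression_uniform_scatter_not_flagged():
    rng = np.random.default_rng(5)
    positions = sorted(rng.choice(20_000_000, size=30, replace=False) + 1)
    pset = _pset_with_positions("s1", [int(p) for p in positions])
    # brute-force max-in-window check confirms the construction is sparse
    max_in_window = max(sum(1 for q in positions if p <= q <= p + 100_000) for p in positions)
    assert max_in_window < 20
    assert detect_introgression([pset]) == []


def test_introgression_no_variants_no_flags():
    from highevo.private_variants import PrivateVariantSet
    assert detect_introgression([PrivateVariantSet("mutagenized")]) == []


# ---------------------------------------------------------------------------
# depth exclusion & reversion audit
# ---------------------------------------------------------------------------

def test_depth_exclusion_per_chromosome_thresholds():
    manifest = SampleManifest(
        chromosomes={c: ChromSets(["s"], ["s"], []) for c in ("chr2", "chr3")},
        mean_depth={"s": 7.0, "t": 4.9, "u": 9.0},
    )
    manifest.mean_depth.update({"t": 4.9, "u": 9.0})
    assert "s" in depth_exclusion(manifest, "chr3")
    assert "s" not in depth_exclusion(manifest, "chr2")
    assert "t" not in depth_exclusion(manifest, "chr3")
    assert "t" not in depth_exclusion(manifest, "chr2")
    assert "u" in depth_exclusion(manifest, "chr2")
    # unknown chromosome falls back to the 5x default
    assert set(depth_exclusion(manifest, "chrX")) == {"s", "u"}


def test_reversion_audit_counts():
    full = ["m1", "b1", "b2"]
    sets = ChromSets(full, ["m1"], ["b1", "b2"])

    def fixed_site(pos, mut_gt="hom_alt"):
        return make_record(pos=pos, calls={
            "m1": make_call(mut_gt), "b1": make_call("hom_alt"), "b2": make_call("hom_alt")})

    recs = [fixed_site(p) for p in (10, 20, 30, 40, 50)]
    assert reversion_audit(recs, sets) == (5, 0)
    recs[2] = fixed_site(30, mut_gt="het")  # one planted reversion
    assert reversion_audit(recs, sets) == (5, 1)


# ---------------------------------------------------------------------------
# ledger arithmetic
# ---------------------------------------------------------------------------

def test_privateness_removed_percent():
    assert privateness_removed_percent(636_143, 1_083 + 896) == 99.7
    assert privateness_removed_percent(621_906, 26_829 + 728) == 95.6


# ---------------------------------------------------------------------------
# full pipeline vs brute-force oracle, and invariants
# ---------------------------------------------------------------------------

def _compare_with_oracle(records, manifest, chrom="chr3"):
    got = run_private_pipeline(records, manifest, chrom)
    ref = reference_pipeline(records, manifest, chrom)
    for target, pset in (("mutagenized", got.mutagenized), ("background", got.background)):
        got_map = {v.record.key: (tuple(v.carriers), v.rescued, v.zygosity)
                   for v in pset.variants}
        assert got_map == ref["final"][target], target
    assert got.introgressed_samples == ref["flagged"]
    assert got.retained_samples == ref["retained"]
    assert got.ledger.count("input", "all") == ref["counts"]["n_input"]
    assert got.ledger.count("private", "mutagenized") == ref["counts"]["private_mutagenized"]
    assert got.ledger.count("private", "background") == ref["counts"]["private_background"]
    return got


def test_pipeline_matches_oracle_on_randomized_tables():
    rng = np.random.default_rng(2024)
    for _ in range(20):
        records, manifest = random_joint_table(
            rng, n_variants=int(rng.integers(50, 300)),
            n_samples=int(rng.integers(6, 16)))
        got = _compare_with_oracle(records, manifest)
        # antisymmetry: no variant in both private sets
        assert not (got.mutagenized.keys() & got.background.keys())
        # zygosity accounting over carrier occurrences
        for pset in (got.mutagenized, got.background):
            for v in pset.variants:
                zs = [v.zygosity[s] for s in v.carriers]
                n_het = sum(1 for z in zs if z is Genotype.HET)
                n_hom = sum(1 for z in zs if z is Genotype.HOM_ALT)
                assert n_het + n_hom == len(v.carriers)


def test_pipeline_stage_monotonicity():
    rng = np.random.default_rng(77)
    records, manifest = random_joint_table(rng, n_variants=250, n_samples=12)
    got = run_private_pipeline(records, manifest, "chr3")
    for target in ("mutagenized", "background"):
        n_priv = got.ledger.count("private", target)
        n_gt = got.ledger.count("genotype_filter", target)
        n_cov = got.ledger.count("cross_coverage", target)
        assert n_priv >= n_gt >= n_cov


def test_pipeline_recovers_truth_noise_free(noise_free_experiment):
    """With noise-free sequencing, the mutagenized-private set equals the
    set of transmitted de novo mutations in the simulated truth."""
    exp = noise_free_experiment
    got = run_private_pipeline(exp["records"], exp["manifest"], "chr3")
    truth_keys = set()
    for spec in exp["truth"].samples.values():
        if spec.kind == "isogenic":
            truth_keys |= set(spec.kept_mutations)
    assert got.mutagenized.keys() == truth_keys
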