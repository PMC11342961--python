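"""Simulate a small deaminase-mutagenesis experiment.

Builds a 500 kb genome with planted TF-motif sites, mutagenizes 8
lineages for 10 generations at an elevated rate near the motifs,
isogenizes each into a replicated line, and emits the joint variant
table a real experiment's variant caller would produce.
"""

from highevo import MutagenesisModel, simulate_experiment
from highevo.synthetic_data import SequencingModel

sim = simulate_experiment(
    seed=7,
    chrom_lengths={"chr3": 500_000},
    n_motif_sites=50,
    n_peaks=10,
    model=MutagenesisModel(base_rate=5e-7, target_rate_multiplier=50,
                           generations=10),
    seq_model=SequencingModel(mean_depth=19.2),
    n_lines=8,
    n_background_individuals=4,
)

n_denovo = sum(len(l.mutations) for l in sim.truth.lineages.values())
print(f"samples sequenced:        {len(sim.manifest.mean_depth)}")
print(f"joint variant records:    {len(sim.records)}")
print(f"true de novo mutations:   {n_denovo}")
print(f"planted motif sites:      {len(sim.genome.motif_sites)}")
in_target = sum(m.in_target for l in sim.truth.lineages.values() for m in l.mutations)
print(f"de novo inside target windows: {in_target} "
      f"({100 * in_target / n_denovo:.0f}% of mutations in "
      f"{100 * 50 * 208 / 500_000:.0f}% of the genome)")
# Most records are stock standing variation and sequencing artifacts;
# only the de novo mutations are private to the mutagenized samples —
# exactly the haystack the private-variant pipeline is built to search.
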