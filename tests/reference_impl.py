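"""Independent brute-force reference implementations used as oracles.

Everything here is written with plain nested loops, directly from the
filtering rules, and deliberately shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import math

from highevo.variant_io import Genotype

HET = Genotype.HET
HOM_ALT = Genotype.HOM_ALT
MISSING = Genotype.MISSING


def _carries(call) -> bool:
    return call.gt in (HET, HOM_ALT)


def _gt_pass(call, dp_lo=10, dp_hi=200, min_obs=3) -> bool:
    dp = call.dp or 0
    if dp < dp_lo or dp > dp_hi:
        return False
    if call.gt is HET:
        return (call.ao or 0) >= min_obs and (call.ro or 0) >= min_obs
    return True


def _group_of(sample, groups):
    for g, members in groups.items():
        if sample in members:
            return g
    return None


def _private_one_target(records, full, target_samples, opposite_samples, groups,
                        min_nonmissing=2):
    """One target set: privateness -> genotype/rescue -> cross coverage.

    Returns a dict key -> (carriers tuple, rescued flag, zygosity dict).
    """
    out = {}
    tset = set(target_samples)
    others = [s for s in full if s not in tset]
    for rec in records:
        carriers = []
        for s in target_samples:
            if s in rec.calls and _carries(rec.calls[s]):
                carriers.append(s)
        if not carriers:
            continue
        leaked = False
        for s in others:
            if s in rec.calls and _carries(rec.calls[s]):
                leaked = True
        if leaked:
            continue
        # genotype filter or replicate rescue
        any_pass = False
        for s in carriers:
            if _gt_pass(rec.calls[s]):
                any_pass = True
        group_counts = {}
        for s in carriers:
            g = _group_of(s, groups)
            if g is not None:
                group_counts[g] = group_counts.get(g, 0) + 1
        rescued = any(n >= 2 for n in group_counts.values())
        if not any_pass and not rescued:
            continue
        # cross coverage in the opposite set
        n_nonmiss = 0
        for s in opposite_samples:
            if s in rec.calls and rec.calls[s].gt is not MISSING:
                n_nonmiss += 1
        if n_nonmiss < min_nonmissing:
            continue
        zyg = {s: rec.calls[s].gt for s in carriers}
        out[(rec.chrom, rec.pos, rec.ref, rec.alt)] = (tuple(carriers), rescued, zyg)
    return out


def _privateness_counts(records, full, target_samples):
    """Count of variants private to the target set (pre-filter)."""
    n = 0
    tset = set(target_samples)
    others = [s for s in full if s not in tset]
    for rec in records:
        has_carrier = any(s in rec.calls and _carries(rec.calls[s]) for s in target_samples)
        leaked = any(s in rec.calls and _carries(rec.calls[s]) for s in others)
        if has_carrier and not leaked:
            n += 1
    return n


def _introgressed(private_maps, window_bp, min_count):
    """Brute-force sliding-window sweep over each carrier's positions."""
    per_sample = {}
    for pmap in private_maps:
        for (chrom, pos, _r, _a), (carriers, _res, _z) in pmap.items():
            for s in carriers:
                per_sample.setdefault(s, []).append((chrom, pos))
    flagged = []
    for s, items in per_sample.items():
        by_chrom = {}
        for chrom, pos in items:
            by_chrom.setdefault(chrom, []).append(pos)
        hit = False
        for positions in by_chrom.values():
            for anchor in positions:
                n = sum(1 for p in positions if anchor <= p <= anchor + window_bp)
                if n >= min_count:
                    hit = True
        if hit:
            flagged.append(s)
    return sorted(flagged)


def reference_pipeline(records, manifest, chrom,
                       min_qual=10.0, min_nonmissing=2,
                       window_kb=100.0, min_count=20,
                       depth_thresholds=None):
    """Brute-force re-implementation of the full private pipeline.

    Returns a dict with both private maps, privateness counts, the
    flagged samples and the depth-retained samples — the facts the
    package pipeline also reports.
    """
    sets = manifest.chromosomes[chrom]
    groups = manifest.replicate_groups
    recs = [r for r in records if r.chrom == chrom and r.qual >= min_qual]

    def run(full, mut, bg, groups):
        return {
            "mutagenized": _private_one_target(recs, full, mut, bg, groups, min_nonmissing),
            "background": _private_one_target(recs, full, bg, mut, groups, min_nonmissing),
        }

    first = run(sets.full, sets.mutagenized, sets.background, groups)
    counts = {
        "n_input": len(recs),
        "private_mutagenized": _privateness_counts(recs, sets.full, sets.mutagenized),
        "private_background": _privateness_counts(recs, sets.full, sets.background),
    }
    flagged = _introgressed([first["mutagenized"], first["background"]],
                            int(window_kb * 1000), min_count)
    final = first
    if flagged:
        drop = set(flagged)
        full2 = [s for s in sets.full if s not in drop]
        mut2 = [s for s in sets.mutagenized if s not in drop]
        bg2 = [s for s in sets.background if s not in drop]
        groups2 = {g: [s for s in m if s not in drop] for g, m in groups.items()}
        final = run(full2, mut2, bg2, groups2)

    if depth_thresholds is None:
        depth_thresholds = {"chr2": 9.0, "chr3": 5.0}
    threshold = 5.0
    for key, value in depth_thresholds.items():
        if chrom == key or chrom.startswith(key):
            threshold = value
            break
    retained = sorted(s for s, d in manifest.mean_depth.items()
                      if d >= threshold and s not in set(flagged))
    return {"final": final, "counts": counts, "flagged": flagged, "retained": retained}


# ---------------------------------------------------------------------------
# Motif / interval oracles
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_scan(sequence: str, pwm) -> list[tuple[int, str, float]]:
    """Score every window on both strands directly from the matrix."""
    lo = pwm.log_odds()
    threshold = pwm.effective_threshold()
    w = pwm.width
    seq = sequence.upper()
    hits = []
    for start in range(len(seq) - w + 1):
        window = seq[start:start + w]
        if "N" in window:
            continue
        fwd = sum(lo[i, "ACGT".index(window[i])] for i in range(w))
        if fwd >= threshold:
            hits.append((start, "+", fwd))
        rc = "".join(_COMP[b] for b in reversed(window))
        rev = sum(lo[i, "ACGT".index(rc[i])] for i in range(w))
        if rev >= threshold:
            hits.append((start, "-", rev))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def brute_force_clusters(hits, max_gap, min_hits):
    """Chain construction by explicit scanning over sorted hits."""
    ordered = sorted(hits, key=lambda h: h.start)
    clusters = []
    i = 0
    while i < len(ordered):
        chain = [ordered[i]]
        j = i + 1
        while j < len(ordered) and ordered[j].start - chain[-1].end <= max_gap:
            chain.append(ordered[j])
            j += 1
        if len(chain) >= min_hits:
            clusters.append((chain[0].start, max(h.end for h in chain)))
        i = j
    return clusters


def brute_force_distance(chrom, pos, intervals):
    """Minimum distance from a 1-based position to any interval."""
    p0 = pos - 1
    best = math.inf
    for ic, start, end in intervals:
        if ic != chrom:
            continue
        if start <= p0 < end:
            return 0.0
        best = min(best, start - p0 if p0 < start else p0 - (end - 1))
    return best


# ---------------------------------------------------------------------------
# Fisher p by exhaustive hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p: sum of probabilities of all tables with the
    same margins whose probability does not exceed the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
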