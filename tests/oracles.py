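"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive — per-base sets and exhaustive
enumeration — and shares no code with the package.
"""

from itertools import combinations


def brute_force_fractional_counts(fragments, features, min_overlap=30):
    """All-pairs per-base overlap enumeration of the fractional counting rule.

    ``fragments``: list of (n_hits, [hit]) where hit = [(chrom, start, end)].
    ``features``: list of (fid, chrom, start, end).
    """
    counts = {fid: 0.0 for fid, *_ in features}
    for n_hits, hits in fragments:
        for hit in hits:
            base_sets = {}
            for chrom, s, e in hit:
                base_sets.setdefault(chrom, set()).update(range(s, e))
            overlapped = []
            for fid, fchrom, fs, fe in features:
                ov = len(base_sets.get(fchrom, set()) & set(range(fs, fe)))
                if ov >= min_overlap:
                    overlapped.append(fid)
            for fid in overlapped:
                counts[fid] += 1.0 / (n_hits * len(overlapped))
    return counts


def brute_force_pileup(fragments, chrom_sizes):
    """Naive per-base pileup over every hit block of every fragment."""
    depth = {c: [0] * n for c, n in chrom_sizes.items()}
    for _, hits in fragments:
        for hit in hits:
            for chrom, s, e in hit:
                for pos in range(s, e):
                    depth[chrom][pos] += 1
    return depth


def hypergeom_upper_enumerated(k, K, n, N):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    return hypergeom_upper_table(K, n, N)[k]


def hypergeom_upper_table(K, n, N):
    """[P(X >= k) for k in 0..min(n, K)] by enumerating every C(N, n) draw."""
    population = [1] * K + [0] * (N - K)
    tally = [0] * (min(n, K) + 1)
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        tally[sum(population[i] for i in draw)] += 1
    upper = []
    for k in range(len(tally)):
        upper.append(sum(tally[k:]) / total)
    return upper
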