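"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-loop kernel sums,
union-find read grouping, exhaustive run scanning, position-by-position
motif matching and full permutation enumeration for the rank test.
"""

from __future__ import annotations

import math
from itertools import combinations


def kernel_sum(events, position, bandwidth):
    """Plain-loop Gaussian kernel sum at one position."""
    total = 0.0
    for e in events:
        z = (position - e) / bandwidth
        total += math.exp(-0.5 * z * z) / (bandwidth * math.sqrt(2 * math.pi))
    return total


def brute_force_groups(reads, min_group_reads=5):
    """Union-find transitive-overlap grouping; reads are dicts with
    chrom/start/end/strand/conversions."""
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = reads[i], reads[j]
            if (
                a["chrom"] == b["chrom"]
                and a["strand"] == b["strand"]
                and a["start"] < b["end"]
                and b["start"] < a["end"]
            ):
                union(i, j)
    buckets = {}
    for i in range(n):
        buckets.setdefault(find(i), []).append(reads[i])
    return [g for g in buckets.values() if len(g) >= min_group_reads]


def _conv_positions(read):
    if read["strand"] == "+":
        return [read["start"] + o for o in read["conversions"]]
    return [read["end"] - 1 - o for o in read["conversions"]]


def brute_force_call_sites(
    reads,
    sequences=None,
    min_read_len=13,
    min_group_reads=5,
    min_cluster_reads=2,
    min_conversions=2,
    min_site_width=11,
    max_site_width=100,
    bandwidth=3.0,
    min_kde_depth=5,
):
    """Naive site caller: returns a sorted list of site tuples
    (chrom, start, end, read_count, conversion_count, mode, strand)."""
    reads = [r for r in reads if r["end"] - r["start"] >= min_read_len]
    sites = []
    for group in brute_force_groups(reads, min_group_reads):
        chrom = group[0]["chrom"]
        strand = group[0]["strand"]
        seq = sequences.get(chrom) if sequences else None
        gstart = min(r["start"] for r in group)
        gend = max(r["end"] for r in group)
        signal_events = [p for r in group for p in _conv_positions(r)]
        # background: one event per covered sense-T position not converted
        # in every read covering it
        depth = {}
        converted = {}
        eligible = set()
        for r in group:
            conv = set(_conv_positions(r))
            for pos in range(r["start"], r["end"]):
                depth[pos] = depth.get(pos, 0) + 1
                if pos in conv:
                    converted[pos] = converted.get(pos, 0) + 1
                if seq is not None:
                    want = "T" if strand == "+" else "A"
                    if pos >= len(seq) or seq[pos] != want:
                        continue
                eligible.add(pos)
        background_events = [
            p for p in sorted(eligible) if converted.get(p, 0) < depth[p]
        ]
        positions = list(range(gstart, gend))
        signal = [kernel_sum(signal_events, p, bandwidth) for p in positions]
        background = [kernel_sum(background_events, p, bandwidth) for p in positions]
        s_tot, b_tot = sum(signal), sum(background)
        if s_tot > 0:
            signal = [s / s_tot for s in signal]
        if b_tot > 0:
            background = [b / b_tot for b in background]
        ratio = []
        for i, p in enumerate(positions):
            if depth.get(p, 0) < min_kde_depth:
                ratio.append(None)
            elif signal[i] + background[i] > 0:
                ratio.append(signal[i] / (signal[i] + background[i]))
            else:
                ratio.append(0.0)
        above = [
            ratio[i] is not None and signal[i] > background[i]
            for i in range(len(positions))
        ]
        i = 0
        while i < len(positions):
            if not above[i]:
                i += 1
                continue
            j = i
            while j < len(positions) and above[j]:
                j += 1
            run_start, run_end = positions[i], positions[i] + (j - i)
            width = run_end - run_start
            conv_count = sum(1 for p in signal_events if run_start <= p < run_end)
            conv_reads = sum(
                1
                for r in group
                if any(run_start <= p < run_end for p in _conv_positions(r))
            )
            if (
                min_site_width <= width <= max_site_width
                and conv_count >= min_conversions
                and conv_reads >= min_cluster_reads
            ):
                best = None
                for k in range(i, j):
                    if ratio[k] is not None and (best is None or ratio[k] > ratio[best] + 1e-15):
                        best = k
                mode = positions[best]
                read_count = sum(
                    1 for r in group if r["start"] < run_end and r["end"] > run_start
                )
                sites.append((chrom, run_start, run_end, read_count, conv_count, mode, strand))
            i = j
    return sorted(sites)


def brute_force_scan(sequence, pattern, alphabet):
    """Position-by-position degenerate matcher; alphabet maps symbol->bases."""
    hits = []
    k = len(pattern)
    for i in range(len(sequence) - k + 1):
        if all(sequence[i + j] in alphabet[pattern[j]] for j in range(k)):
            hits.append(i)
    return hits


def exhaustive_rank_test(a, b):
    """U statistic and exact two-sided p by full enumeration of labelings."""
    def u_stat(x, y):
        u = 0.0
        for xi in x:
            for yi in y:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    pooled = list(a) + list(b)
    n_a = len(a)
    center = n_a * len(b) / 2.0
    u_obs = u_stat(a, b)
    dev = abs(u_obs - center)
    hits = total = 0
    for combo in combinations(range(len(pooled)), n_a):
        chosen = [pooled[i] for i in combo]
        rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(chosen, rest) - center) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total
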