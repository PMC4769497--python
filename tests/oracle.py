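"""Independent brute-force recomputation of summary statistics.

Works from the generator's ground-truth manifest using flat lists and
plain Python counting — no accumulators, no merging — so it can serve as
an oracle for the map-reduce statistics engine.
"""

from collections import Counter


def phred_scores(qualities: str) -> list[int]:
    return [ord(c) - 33 for c in qualities]


def brute_force_read_type(manifest, read_type: str) -> dict:
    """Summary numbers for one read type, recomputed from flat lists."""
    seqs = [m.sequences[read_type] for m in manifest if read_type in m.sequences]
    quals = [m.qualities[read_type] for m in manifest if read_type in m.qualities]
    if not seqs:
        return {"no_reads": True}
    pooled = Counter("".join(seqs))
    lengths = [len(s) for s in seqs]
    total = sum(lengths)
    acgt = sum(pooled[b] for b in "ACGT")
    per_read_means = [sum(phred_scores(q)) / len(q) for q in quals]
    return {
        "reads": len(seqs),
        "nucleotides": total,
        "mean_length": total / len(seqs),
        "min_length": min(lengths),
        "max_length": max(lengths),
        "base_counts": {b: pooled.get(b, 0) for b in "ACGTN"},
        "base_percent": {b: 100.0 * pooled.get(b, 0) / total for b in "ACGTN"},
        "gc_percent": 100.0 * (pooled["G"] + pooled["C"]) / acgt if acgt else 0.0,
        "mean_quality": sum(per_read_means) / len(per_read_means),
    }


def brute_force_channel_nucleotides(manifest, read_type: str) -> dict:
    out: Counter = Counter()
    for m in manifest:
        if read_type in m.sequences:
            out[m.channel] += len(m.sequences[read_type])
    return dict(out)
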