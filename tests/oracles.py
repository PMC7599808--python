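"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seed-index machinery: plain Hamming
scans over every (stage, reference, offset, tail) combination.
"""


def naive_cascade(read_seq, refs, max_tail=3, trna_max_mismatch=1):
    """Full-enumeration annotation oracle, same tie rules as the cascade."""
    def scan(seq, ref_seq, max_mm):
        hits = []
        for start in range(len(ref_seq) - len(seq) + 1):
            mm = sum(a != b for a, b in
                     zip(seq, ref_seq[start:start + len(seq)]))
            if mm <= max_mm:
                hits.append((mm, start))
        return hits

    stages = [("tRNA", refs.by_class("tRNA"), trna_max_mismatch),
              ("miRNA", refs.by_class("miRNA"), 0),
              ("rRNA", refs.by_class("rRNA"), 1),
              ("mRNA", refs.by_class("mRNA"), 1),
              ("other_sRNA", refs.by_class("other_sRNA"), 1),
              ("genome", refs.by_class("genome_decoy"), 1)]
    for stage, pool, max_mm in stages:
        if stage == "miRNA":
            for t in range(0, max_tail + 1):
                if t and any(c not in "AT"
                             for c in read_seq[len(read_seq) - t:]):
                    continue
                core = read_seq[:len(read_seq) - t]
                if not core:
                    continue
                candidates = []
                for name, seq in pool:
                    for mm, start in scan(core, seq, 0):
                        candidates.append((mm, start, name, t))
                if candidates:
                    mm, start, name, t = min(candidates)
                    return (stage, name, start, start + len(core), mm, t)
            continue
        candidates = []
        for name, seq in pool:
            for mm, start in scan(read_seq, seq, max_mm):
                candidates.append((mm, start, name))
        if candidates:
            mm, start, name = min(candidates)
            return (stage, name, start, start + len(read_seq), mm, 0)
    return ("unmapped", "", 0, 0, 0, 0)


def brute_force_trim(read, adapter, min_overlap=10, max_mismatch_rate=0.1):
    """Adapter-occurrence oracle: all offsets, fewest mismatches, leftmost."""
    best = None
    for start in range(0, len(read) - min_overlap + 1):
        overlap = min(len(adapter), len(read) - start)
        if overlap < min_overlap:
            continue
        mm = sum(a != b for a, b in zip(read[start:start + overlap], adapter))
        if mm <= int(max_mismatch_rate * overlap):
            if best is None or mm < best[1]:
                best = (start, mm)
    return None if best is None else read[:best[0]]


def bh_step_up(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, plain python."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
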