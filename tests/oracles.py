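"""Independent brute-force reference implementations used as test oracles.

Everything here is written position-by-position / mutation-by-mutation in
plain Python, deliberately ignoring the vectorized code paths it checks.
"""

from collections import defaultdict

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
BASES = "ACGT"


def revcomp(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


def pyr_context(seq: str, pos: int):
    """(context 3-mer, flipped) or None, by direct string manipulation."""
    if pos < 1 or pos >= len(seq) - 1:
        return None
    tri = seq[pos - 1 : pos + 2]
    if "N" in tri:
        return None
    if tri[1] in "AG":
        return revcomp(tri), True
    return tri, False


def sbs_label(seq: str, pos: int, alt: str):
    """SBS96 label like A[C>T]G for a forward-strand SNV, or None."""
    ctx = pyr_context(seq, pos)
    if ctx is None:
        return None
    tri, flipped = ctx
    a = COMP[alt] if flipped else alt
    return f"{tri[0]}[{tri[1]}>{a}]{tri[2]}", ("c" if flipped else "w")


def assign_oracle(midpoints, site_ids, bins, h):
    """Per-nucleotide sweep applying site-over-flank, nearest-midpoint,
    smallest-id precedence.  Returns {pos: (is_site, bin, owner)}."""
    claims = defaultdict(list)
    for mid, sid, b in zip(midpoints, site_ids, bins):
        for p in range(mid - 3 * h, mid + 3 * h):
            in_site = mid - h <= p < mid + h
            claims[p].append((0 if in_site else 1, abs(p - mid), sid, b))
    out = {}
    for p, lst in claims.items():
        not_site, _, sid, b = min(lst)
        out[p] = (1 - not_site, b, sid)
    return out


def opportunity_oracle(seq: str, assignment: dict):
    """Per-position enumeration of (bin, is_site, class label) -> count."""
    counts = defaultdict(int)
    skipped = 0
    for p, (is_site, b, _sid) in assignment.items():
        ctx = pyr_context(seq, p)
        if ctx is None:
            skipped += 1
            continue
        tri, _ = ctx
        for alt in BASES:
            if alt != tri[1]:
                counts[b, is_site, f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"] += 1
        counts[b, is_site, "indel"] += 1
    return counts, skipped


def table_oracle(seq: str, assignment: dict, mutations):
    """Per-mutation tally into (bin, is_site, class label) -> n_mut.

    ``mutations`` yields (pos, ref, alt) tuples; indels are records where
    len(ref) != len(alt).
    """
    counts = defaultdict(int)
    unassigned = 0
    for pos, ref, alt in mutations:
        if pos not in assignment:
            unassigned += 1
            continue
        is_site, b, _sid = assignment[pos]
        if len(ref) != len(alt):
            counts[b, is_site, "indel"] += 1
        else:
            lab = sbs_label(seq, pos, alt)
            if lab is None:
                continue
            counts[b, is_site, lab[0]] += 1
    return counts, unassigned


def bh_oracle(pvals):
    """Step-up Benjamini-Hochberg by the direct formula with monotone floor."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    prev = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * n / rank_from_end)
        q[i] = val
        prev = val
    return q
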