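"""Genomic elements: site normalization, flanks, position assignment, opportunities.

A "site" is a genomic element (CTCF binding site, TSS, open-chromatin peak)
redefined as a fixed-width window ``[mid-h, mid+h)`` around its midpoint, with
equal-width upstream ``[mid-3h, mid-h)`` and downstream ``[mid+h, mid+3h)``
flanking control sequences; the two flanks combined are twice as wide as the
site.  Because adjacent elements may overlap, site and flank positions are
pooled genome-wide and deduplicated so that every nucleotide is counted exactly
once, as a site position or a flank position but never both.

Mutational opportunity counting expands every retained position into the three
single-nucleotide substitutions compatible with its trinucleotide context plus
one indel opportunity, stratified by megabase-rate bin and site/flank status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import trinuc
from .genome import Genome


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class SiteSet:
    """Uniform-width elements, each represented by its midpoint.

    ``site_id`` is a stable integer identifier; subsetting preserves the
    original ids so that downsampled analyses remain traceable.  ``names``
    optionally carries the element names from the input BED (e.g. gene symbols
    for TSS sites).
    """

    half_width: int
    site_id: np.ndarray  # int64
    chrom: np.ndarray  # object (str)
    midpoint: np.ndarray  # int64
    names: np.ndarray | None = None
    n_dropped_boundary: int = 0
    n_dropped_unknown_chrom: int = 0
    n_duplicates: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    def __len__(self) -> int:
        return self.n_sites

    def site_intervals(self) -> list[GenomicInterval]:
        h = self.half_width
        return [
            GenomicInterval(c, int(m) - h, int(m) + h)
            for c, m in zip(self.chrom, self.midpoint)
        ]

    def subset(self, indices) -> "SiteSet":
        idx = np.asarray(indices)
        return SiteSet(
            half_width=self.half_width,
            site_id=self.site_id[idx],
            chrom=self.chrom[idx],
            midpoint=self.midpoint[idx],
            names=None if self.names is None else self.names[idx],
        )


def read_bed(path) -> list[tuple[GenomicInterval, str | None]]:
    """Read BED3/BED6; returns (interval, name) pairs.

    Columns beyond the third are ignored except column 4 (name).
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            out.append((GenomicInterval(chrom, start, end), name))
    return out


def normalize_sites(
    raw,
    half_width: int,
    genome_index,
    names=None,
) -> SiteSet:
    """Redefine raw elements as fixed-width windows around their midpoints.

    The midpoint of ``[start, end)`` is ``floor((start+end)/2)``.  Elements on
    chromosomes absent from ``genome_index`` and elements whose full analysis
    window ``[mid-3h, mid+3h)`` exits the chromosome are dropped (counted on
    the returned SiteSet) so that every retained site has exactly equal site
    and flank widths.  Duplicate elements (same chromosome and midpoint) are
    collapsed to the first occurrence.  Output preserves input order.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if hasattr(genome_index, "lengths"):
        genome_index = genome_index.lengths
    ids, chroms, mids, kept_names = [], [], [], []
    n_boundary = n_unknown = n_dup = 0
    seen = set()
    next_id = 0
    for i, iv in enumerate(raw):
        length = genome_index.get(iv.chrom)
        if length is None:
            n_unknown += 1
            continue
        mid = (iv.start + iv.end) // 2
        if mid - 3 * half_width < 0 or mid + 3 * half_width > length:
            n_boundary += 1
            continue
        key = (iv.chrom, mid)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        ids.append(next_id)
        next_id += 1
        chroms.append(iv.chrom)
        mids.append(mid)
        if names is not None:
            kept_names.append(names[i])
    return SiteSet(
        half_width=half_width,
        site_id=np.array(ids, dtype=np.int64),
        chrom=np.array(chroms, dtype=object),
        midpoint=np.array(mids, dtype=np.int64),
        names=np.array(kept_names, dtype=object) if names is not None else None,
        n_dropped_boundary=n_boundary,
        n_dropped_unknown_chrom=n_unknown,
        n_duplicates=n_dup,
    )


def build_flanks(site_set: SiteSet) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Upstream/downstream flank pair per site, each of width 2h."""
    h = site_set.half_width
    return [
        (
            GenomicInterval(c, int(m) - 3 * h, int(m) - h),
            GenomicInterval(c, int(m) + h, int(m) + 3 * h),
        )
        for c, m in zip(site_set.chrom, site_set.midpoint)
    ]


@dataclass
class PositionAssignment:
    """Deduplicated genome positions retained for analysis.

    Per chromosome: sorted position array with parallel is_site / bin / owner
    arrays.  Every retained position appears exactly once; a position covered
    by any site interval is a site position (site-over-flank precedence), and
    multiple claims are resolved to the site with the nearest midpoint, ties
    to the smaller site_id.
    """

    half_width: int
    per_chrom: dict = field(default_factory=dict)
    # chrom -> dict(pos=int64[], is_site=bool[], bin=int32[], owner=int64[])

    @property
    def n_positions(self) -> int:
        return sum(len(d["pos"]) for d in self.per_chrom.values())

    def lookup(self, chrom: str, positions: np.ndarray):
        """Vectorized lookup; returns (assigned mask, is_site, bin, owner)."""
        positions = np.asarray(positions, dtype=np.int64)
        d = self.per_chrom.get(chrom)
        if d is None or len(d["pos"]) == 0:
            z = np.zeros(len(positions), dtype=np.int64)
            return np.zeros(len(positions), dtype=bool), z.astype(bool), z, z
        idx = np.searchsorted(d["pos"], positions)
        idx_c = np.clip(idx, 0, len(d["pos"]) - 1)
        hit = d["pos"][idx_c] == positions
        return hit, d["is_site"][idx_c], d["bin"][idx_c], d["owner"][idx_c]

    def to_tsv(self, path) -> None:
        import pandas as pd

        frames = []
        for chrom, d in self.per_chrom.items():
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": d["pos"],
                        "is_site": d["is_site"].astype(int),
                        "bin": d["bin"],
                        "owner": d["owner"],
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def assign_positions(site_set: SiteSet, bins) -> PositionAssignment:
    """Pool site and flank positions genome-wide and deduplicate.

    ``bins`` maps site_id to its megabase-rate bin label (dict or array
    aligned with ``site_set``).  Flank positions inherit the bin of their
    owning site.  Overlap resolution: site interval beats flank, then nearest
    midpoint, then smaller site_id.
    """
    h = site_set.half_width
    if isinstance(bins, dict):
        bin_arr = np.array([bins[int(s)] for s in site_set.site_id], dtype=np.int32)
    else:
        bin_arr = np.asarray(bins, dtype=np.int32)
        if len(bin_arr) != site_set.n_sites:
            raise ValueError("bins must be aligned with site_set")
    offsets = np.arange(-3 * h, 3 * h, dtype=np.int64)
    in_site_off = (offsets >= -h) & (offsets < h)
    per_chrom: dict = {}
    for chrom in np.unique(site_set.chrom):
        sel = np.where(site_set.chrom == chrom)[0]
        mids = site_set.midpoint[sel]
        sids = site_set.site_id[sel]
        sbins = bin_arr[sel]
        n = len(sel)
        pos = (mids[:, None] + offsets[None, :]).ravel()
        dist = np.abs(np.tile(offsets, n))
        not_site = ~np.tile(in_site_off, n)
        owner = np.repeat(sids, 6 * h)
        obin = np.repeat(sbins, 6 * h)
        # first occurrence per position under (site-first, nearest, smallest id)
        order = np.lexsort((owner, dist, not_site, pos))
        pos_s = pos[order]
        first = np.empty(len(pos_s), dtype=bool)
        first[0] = True
        np.not_equal(pos_s[1:], pos_s[:-1], out=first[1:])
        keep = order[first]
        keep_pos = pos[keep]
        per_chrom[str(chrom)] = {
            "pos": keep_pos,
            "is_site": ~not_site[keep],
            "bin": obin[keep],
            "owner": owner[keep],
        }
    return PositionAssignment(half_width=h, per_chrom=per_chrom)


def extract_context(genome: Genome, chrom: str, pos: int):
    """Pyrimidine-normalized reference trinucleotide at ``pos``.

    Returns ``(3-mer, flipped)`` where ``flipped`` marks reverse-complemented
    (purine-centred) contexts, or None at chromosome edges or when any base in
    the window is N.
    """
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    arr = genome.codes(chrom)
    if pos < 1 or pos >= len(arr) - 1:
        return None
    ctx, flipped = trinuc.context_index(arr[pos - 1], arr[pos], arr[pos + 1])
    ctx = int(ctx)
    if ctx < 0:
        return None
    centre = "CT"[ctx // 16]
    label = trinuc.BASES[(ctx % 16) // 4] + centre + trinuc.BASES[ctx % 4]
    return label, bool(flipped)


@dataclass
class OpportunityCounts:
    """Mutational opportunities per (bin, is_site, class) stratum.

    ``counts`` has shape (n_bins, 2, 97): axis 1 indexes flank (0) / site (1),
    axis 2 the 96 SBS classes plus the indel class.  Every valid position
    contributes one opportunity to each of the three SNV classes sharing its
    context and one to the indel class; positions whose trinucleotide window
    contains N or falls off the chromosome are skipped (counted).
    """

    counts: np.ndarray
    bin_labels: np.ndarray  # label of bin axis i
    n_skipped: int = 0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def context_positions(self) -> np.ndarray:
        """(n_bins, 2) valid position counts recovered from the indel row."""
        return self.counts[:, :, trinuc.INDEL_CLASS]


def count_opportunities(genome: Genome, assignment: PositionAssignment) -> OpportunityCounts:
    """Tally opportunities for every assigned position."""
    all_bins = sorted(
        {int(b) for d in assignment.per_chrom.values() for b in np.unique(d["bin"])}
    )
    if not all_bins:
        raise ValueError("empty assignment")
    bin_index = {b: i for i, b in enumerate(all_bins)}
    nb = len(all_bins)
    counts = np.zeros((nb, 2, trinuc.N_CLASSES), dtype=np.int64)
    n_skipped = 0
    for chrom, d in assignment.per_chrom.items():
        arr = genome.codes(chrom)
        pos = d["pos"]
        inner = (pos >= 1) & (pos < len(arr) - 1)
        n_skipped += int((~inner).sum())
        p = pos[inner]
        ctx, _ = trinuc.context_index(arr[p - 1], arr[p], arr[p + 1])
        valid = ctx >= 0
        n_skipped += int((~valid).sum())
        p_ctx = ctx[valid]
        p_bin = np.array([bin_index[int(b)] for b in np.unique(d["bin"])])[
            np.searchsorted(np.unique(d["bin"]), d["bin"][inner][valid])
        ]
        p_site = d["is_site"][inner][valid].astype(np.int64)
        flat = (p_bin * 2 + p_site) * trinuc.N_CONTEXTS + p_ctx
        ctx_counts = np.bincount(flat, minlength=nb * 2 * trinuc.N_CONTEXTS).reshape(
            nb, 2, trinuc.N_CONTEXTS
        )
        for c in range(trinuc.N_CONTEXTS):
            for k in trinuc.CONTEXT_CLASSES[c]:
                counts[:, :, k] += ctx_counts[:, :, c]
        counts[:, :, trinuc.INDEL_CLASS] += ctx_counts.sum(axis=2)
    return OpportunityCounts(
        counts=counts,
        bin_labels=np.array(all_bins, dtype=np.int64),
        n_skipped=n_skipped,
    )
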