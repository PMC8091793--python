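"""Synthetic cohort generator with controllable localized mutational effects.

The generator emulates the statistical structure the regression consumes, not
the underlying biology: an i.i.d. random genome, fixed-width elements placed
along it, and per-tumour mutations whose placement probability is the product
of a smooth megabase-scale rate multiplier, an injected site-level fold
change, and (for carrier tumours) a cofactor-dependent fold change.  SNV
classes are drawn from a configurable SBS96 weight vector restricted to the
trinucleotide context of the sampled position; indels are placed uniformly.
A trinucleotide-preserving shuffle relocates each mutation to a random
same-context position within a local window, destroying site-level enrichment
while preserving class composition and regional rates — the null used for
calibration benchmarks.

Every sampling step derives its own stream from the spec seed, so genomes,
site sets and cohorts are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import trinuc
from .genome import Genome
from .intervals import SiteSet
from .mutations import MutationSet

MBP = 1_000_000


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    ``mean_rate`` is the expected number of mutations per megabase per tumour;
    it is scaled to the synthetic genome so that per-stratum counts are
    comparable to what a whole-genome cohort yields on a full reference.
    ``site_rate_bias`` skews site placement towards high-rate megabase blocks
    (weight proportional to multiplier**bias); with nonzero bias the min_gap
    constraint is not enforced, so adjacent analysis windows may overlap and
    exercise the pooling/deduplication path, as dense real site catalogues do.
    """

    genome_length: int = 5_000_000
    chrom: str = "chr1"
    base_weights: tuple = (0.25, 0.25, 0.25, 0.25)
    n_sites: int = 10_000
    half_width: int = 25
    min_gap: int | None = None  # default 6*half_width: disjoint analysis windows
    n_tumours: int = 50
    mean_rate: float = 2000.0  # mutations / Mbp / tumour
    heterogeneity_sigma: float = 0.5
    heterogeneity_smooth_mbp: float = 2.0  # correlation scale of the rate field
    heterogeneity_profile: tuple | None = None  # per-Mbp multipliers
    class_weights: tuple | None = None  # 96 SBS weights, default uniform
    indel_fraction: float = 0.07
    site_fold_change: float = 1.0
    carrier_fraction: float = 0.0
    carrier_fold_change: float = 1.0
    site_rate_bias: float = 0.0
    tumour_dispersion: float | None = None  # NB shape for per-tumour totals; None = Poisson
    rate_window: int = 1_000_000  # sites are placed so this window fits the chromosome
    seed: int = 1

    def __post_init__(self):
        w = np.asarray(self.base_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("base weights must be non-negative and normalizable")
        if self.class_weights is not None:
            cw = np.asarray(self.class_weights, dtype=float)
            if len(cw) != 96 or (cw < 0).any() or cw.sum() <= 0:
                raise ValueError("class_weights must be 96 non-negative values")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must be in [0, 1]")

    @property
    def gap(self) -> int:
        return 6 * self.half_width if self.min_gap is None else self.min_gap

    def _child_rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    def profile(self) -> np.ndarray:
        """Realized per-Mbp rate multipliers (from the spec or drawn).

        Drawn profiles are lognormal fields with marginal log-sd
        ``heterogeneity_sigma`` and a Gaussian autocorrelation of scale
        ``heterogeneity_smooth_mbp`` megabases.  The smoothing reflects the
        multi-megabase correlation length of real mutation-rate covariates
        (replication timing, chromatin domains); an uncorrelated per-Mbp
        field would make the one-megabase window count a biased estimate of
        the site-local rate, which is not the regime the rate covariate
        models.
        """
        n_blocks = -(-self.genome_length // MBP)
        if self.heterogeneity_profile is not None:
            prof = np.asarray(self.heterogeneity_profile, dtype=float)
            if len(prof) != n_blocks:
                raise ValueError(f"profile must have {n_blocks} per-Mbp entries")
            return prof
        rng = self._child_rng(2)
        if self.heterogeneity_sigma <= 0:
            return np.ones(n_blocks)
        s = self.heterogeneity_smooth_mbp
        if s <= 0:
            z = rng.normal(size=n_blocks)
        else:
            pad = int(np.ceil(4 * s))
            raw = rng.normal(size=n_blocks + 2 * pad)
            d = np.arange(-pad, pad + 1, dtype=float)
            k = np.exp(-0.5 * (d / s) ** 2)
            k /= k.sum()
            z = np.convolve(raw, k, mode="valid")
            z /= np.sqrt((k**2).sum())  # restore unit marginal variance
        return np.exp(self.heterogeneity_sigma * z)

    def position_multipliers(self) -> np.ndarray:
        """Per-position rate multipliers.

        The per-Mbp profile values sit at megabase-block centres and are
        linearly interpolated between them, giving the smooth megabase-scale
        rate variation the MbpRate covariate is designed for (a hard step
        inside a rate window would make the window count a biased estimate of
        the site-local rate).
        """
        prof = self.profile()
        pos = np.arange(self.genome_length, dtype=np.float64)
        if len(prof) == 1:
            return np.full(self.genome_length, float(prof[0]))
        centres = np.minimum(
            np.arange(len(prof), dtype=np.float64) * MBP + MBP / 2,
            self.genome_length - 1,
        )
        return np.interp(pos, centres, prof)


@dataclass
class TruthRecord:
    """Realized generator state sufficient to recompute expected enrichment."""

    carriers: list
    profile: list
    site_fold_change: float
    carrier_fold_change: float
    indel_fraction: float
    seed: int
    n_tumours: int
    w_site: float  # sum of rate multipliers over site positions
    w_flank: float  # ... over flank positions
    w_total: float  # ... over all SNV-eligible positions
    n_site_pos: int
    n_flank_pos: int

    def expected_snv_site_flank_ratio(self) -> float:
        """Expected aggregate per-bp SNV rate ratio of sites vs flanks."""
        n_car = len(self.carriers)
        n_non = self.n_tumours - n_car
        fc, cfc = self.site_fold_change, self.carrier_fold_change
        out_site = self.w_total - self.w_site
        site_rate = flank_rate = 0.0
        for n_t, mult in ((n_non, fc), (n_car, fc * cfc)):
            if n_t == 0:
                continue
            z = out_site + self.w_site * mult
            site_rate += n_t * self.w_site * mult / z
            flank_rate += n_t * self.w_flank / z
        return (site_rate / self.n_site_pos) / (flank_rate / self.n_flank_pos)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def simulate_genome(spec: SimulationSpec) -> Genome:
    """I.i.d. random genome over ACGT with the spec's base weights."""
    if spec.genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    rng = spec._child_rng(0)
    w = np.asarray(spec.base_weights, dtype=float)
    cdf = np.cumsum(w / w.sum())
    codes = np.searchsorted(cdf, rng.random(spec.genome_length), side="right")
    return Genome({spec.chrom: np.minimum(codes, 3).astype(np.uint8)})


def _sample_unique(rng, limit: int, n: int, weights_cdf=None) -> np.ndarray:
    """n distinct integers below limit, optionally weighted by a cdf array."""
    out: np.ndarray = np.empty(0, dtype=np.int64)
    while len(out) < n:
        need = int((n - len(out)) * 1.3) + 16
        if weights_cdf is None:
            draw = rng.integers(0, limit, size=need)
        else:
            u = rng.random(need) * weights_cdf[-1]
            draw = np.searchsorted(weights_cdf, u, side="right")
        out = np.unique(np.concatenate([out, draw]))
    return rng.permutation(out)[:n]


def simulate_sites(spec: SimulationSpec, genome: Genome) -> SiteSet:
    """Place site midpoints so every analysis window fits the chromosome.

    Without placement bias, midpoints are sampled uniformly at least
    ``min_gap`` apart (the classic reduced-range construction); with bias,
    midpoints are sampled without replacement proportional to the megabase
    multiplier raised to the bias.
    """
    h = spec.half_width
    L = genome.lengths[spec.chrom]
    # keep the full megabase rate window on the chromosome: on genome-scale
    # data the fraction of elements with truncated rate windows is negligible,
    # and a toy genome should emulate that regime rather than fill its lowest
    # rate bin with edge-truncated window counts; when the chromosome is
    # shorter than the rate window every window spans it entirely and no edge
    # bias is possible
    margin = 3 * h if L <= spec.rate_window else max(3 * h, spec.rate_window // 2)
    lo, hi = margin, L - margin  # valid midpoints: [lo, hi] inclusive
    span = hi - lo + 1
    if spec.n_sites == 0:
        return SiteSet(
            half_width=h,
            site_id=np.empty(0, dtype=np.int64),
            chrom=np.empty(0, dtype=object),
            midpoint=np.empty(0, dtype=np.int64),
        )
    rng = spec._child_rng(1)
    if spec.site_rate_bias != 0.0:
        mult = spec.position_multipliers()[lo : hi + 1]
        cdf = np.cumsum(mult ** spec.site_rate_bias)
        mids = lo + np.sort(_sample_unique(rng, span, spec.n_sites, weights_cdf=cdf))
    else:
        g = spec.gap
        reduced = span - (spec.n_sites - 1) * g
        if reduced < spec.n_sites:
            raise ValueError(
                f"cannot place {spec.n_sites} sites with min_gap {g} on {L} bp"
            )
        picks = np.sort(rng.choice(reduced, size=spec.n_sites, replace=False))
        mids = lo + picks + np.arange(spec.n_sites) * g
    return SiteSet(
        half_width=h,
        site_id=np.arange(spec.n_sites, dtype=np.int64),
        chrom=np.full(spec.n_sites, spec.chrom, dtype=object),
        midpoint=mids.astype(np.int64),
    )


_BASE_CHARS = np.array(list("ACGTN"))


def simulate_cohort(spec: SimulationSpec, genome: Genome, sites: SiteSet):
    """Draw a multi-tumour mutation set; returns (MutationSet, TruthRecord)."""
    rng = spec._child_rng(3)
    arr = genome.codes(spec.chrom)
    L = len(arr)
    prof = spec.profile()
    mult = spec.position_multipliers()
    h = spec.half_width
    site_mask = np.zeros(L, dtype=bool)
    flank_mask = np.zeros(L, dtype=bool)
    for m in sites.midpoint:
        site_mask[m - h : m + h] = True
        flank_mask[m - 3 * h : m - h] = True
        flank_mask[m + h : m + 3 * h] = True
    flank_mask &= ~site_mask
    w_base = mult.copy()
    w_base[0] = w_base[-1] = 0.0  # no trinucleotide context at chromosome edges

    # context and class machinery for vectorized class draws
    ctx = np.full(L, -1, dtype=np.int64)
    c_idx, flip = trinuc.context_index(arr[:-2], arr[1:-1], arr[2:])
    ctx[1:-1] = c_idx
    flipped = np.zeros(L, dtype=bool)
    flipped[1:-1] = flip
    cw = (
        np.asarray(spec.class_weights, dtype=float)
        if spec.class_weights is not None
        else np.ones(96)
    )
    ctx_probs = cw[trinuc.CONTEXT_CLASSES]  # (32, 3)
    ctx_cdf = np.cumsum(ctx_probs, axis=1)
    ctx_cdf /= ctx_cdf[:, -1:][:]

    tumours = np.array([f"T{i:04d}" for i in range(spec.n_tumours)])
    carriers_mask = (
        rng.random(spec.n_tumours) < spec.carrier_fraction
        if spec.carrier_fraction > 0
        else np.zeros(spec.n_tumours, dtype=bool)
    )
    mean_total = spec.mean_rate * L / MBP
    if spec.tumour_dispersion is None:
        totals = rng.poisson(mean_total, size=spec.n_tumours)
    else:
        k = spec.tumour_dispersion
        totals = rng.negative_binomial(k, k / (k + mean_total), size=spec.n_tumours)
    n_indels = rng.binomial(totals, spec.indel_fraction)
    n_snvs = totals - n_indels

    # assemble column code arrays first; categoricals keep the frame compact
    pos_parts, ref_parts, alt_parts, tum_parts, cls_parts, strand_parts = (
        [] for _ in range(6)
    )
    # alt categories: 4 bases for SNVs plus the 16 single-base insertions
    alt_categories = list("ACGT") + [a + b for a in "ACGT" for b in "ACGT"]
    for carrier in (False, True):
        group = np.where(carriers_mask == carrier)[0]
        if len(group) == 0:
            continue
        f = spec.site_fold_change * (spec.carrier_fold_change if carrier else 1.0)
        w = w_base.copy()
        if f != 1.0:
            w[site_mask] *= f
        cdf = np.cumsum(w)
        n_grp = int(n_snvs[group].sum())
        u = rng.random(n_grp) * cdf[-1]
        pos = np.searchsorted(cdf, u, side="right")
        p_ctx = ctx[pos]
        pick = (rng.random(n_grp)[:, None] > ctx_cdf[p_ctx]).sum(axis=1)
        cls = trinuc.CONTEXT_CLASSES[p_ctx, pick]
        alt_pyr = trinuc.CLASS_ALT_PYR[cls]
        flipped_pos = flipped[pos]
        alt_code = np.where(flipped_pos, trinuc.COMPLEMENT[alt_pyr], alt_pyr)
        pos_parts.append(pos)
        ref_parts.append(arr[pos].astype(np.int8))
        alt_parts.append(alt_code.astype(np.int8))
        tum_parts.append(np.repeat(group, n_snvs[group]).astype(np.int32))
        cls_parts.append(cls.astype(np.int64))
        strand_parts.append(flipped_pos.astype(np.int8))  # 0=w, 1=c
    n_ind_total = int(n_indels.sum())
    if n_ind_total:
        ipos = rng.integers(0, L, size=n_ind_total)
        ins = rng.integers(0, 4, size=n_ind_total)
        pos_parts.append(ipos)
        ref_parts.append(arr[ipos].astype(np.int8))
        alt_parts.append((4 + arr[ipos] * 4 + ins).astype(np.int8))
        tum_parts.append(np.repeat(np.arange(spec.n_tumours), n_indels).astype(np.int32))
        cls_parts.append(np.full(n_ind_total, trinuc.INDEL_CLASS, dtype=np.int64))
        strand_parts.append(np.full(n_ind_total, 2, dtype=np.int8))  # '.'
    if pos_parts:
        df = pd.DataFrame(
            {
                "chrom": pd.Categorical.from_codes(
                    np.zeros(sum(map(len, pos_parts)), dtype=np.int8), [spec.chrom]
                ),
                "pos": np.concatenate(pos_parts),
                "ref": pd.Categorical.from_codes(
                    np.concatenate(ref_parts), list("ACGT")
                ),
                "alt": pd.Categorical.from_codes(
                    np.concatenate(alt_parts), alt_categories
                ),
                "tumour": pd.Categorical.from_codes(
                    np.concatenate(tum_parts), list(tumours)
                ),
                "class_id": np.concatenate(cls_parts),
                "strand": pd.Categorical.from_codes(
                    np.concatenate(strand_parts), ["w", "c", "."]
                ),
            }
        )
    else:
        df = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "tumour", "class_id", "strand"]
        )
    truth = TruthRecord(
        carriers=list(tumours[carriers_mask]),
        profile=list(map(float, prof)),
        site_fold_change=spec.site_fold_change,
        carrier_fold_change=spec.carrier_fold_change,
        indel_fraction=spec.indel_fraction,
        seed=spec.seed,
        n_tumours=spec.n_tumours,
        w_site=float(w_base[site_mask].sum()),
        w_flank=float(w_base[flank_mask].sum()),
        w_total=float(w_base.sum()),
        n_site_pos=int(site_mask.sum()),
        n_flank_pos=int(flank_mask.sum()),
    )
    return MutationSet(df=df), truth


def shuffle_trinucleotide_preserving(
    ms: MutationSet, genome: Genome, window: int = 1_000_000, seed: int = 1
) -> MutationSet:
    """Relocate each mutation within a local window, preserving context.

    Every SNV moves to a uniformly chosen position with the identical
    pyrimidine-normalized trinucleotide context within +/- window/2 of its
    original position; indels move to any in-window position.  Classes (and
    hence the SBS96 histogram) are preserved exactly; mutations with no
    same-context position in their window stay in place (counted).
    """
    rng = np.random.default_rng(seed)
    half = window // 2
    df = ms.df.copy().reset_index(drop=True)
    new_pos = df["pos"].to_numpy().copy()
    new_ref = df["ref"].to_numpy(dtype=object).copy()
    new_alt = df["alt"].to_numpy(dtype=object).copy()
    new_strand = df["strand"].to_numpy(dtype=object).copy()
    n_stuck = 0
    for chrom, sub in df.groupby("chrom", observed=True):
        arr = genome.codes(chrom)
        ctx = np.full(len(arr), -1, dtype=np.int64)
        c_idx, flip = trinuc.context_index(arr[:-2], arr[1:-1], arr[2:])
        ctx[1:-1] = c_idx
        flipped = np.zeros(len(arr), dtype=bool)
        flipped[1:-1] = flip
        ctx_positions = {c: np.where(ctx == c)[0] for c in range(trinuc.N_CONTEXTS)}
        cid = sub["class_id"].to_numpy()
        pos = sub["pos"].to_numpy()
        idx = sub.index.to_numpy()
        snv = (cid >= 0) & (cid < trinuc.INDEL_CLASS)
        for c in np.unique(trinuc.CLASS_CONTEXT[cid[snv]]):
            cand = ctx_positions[int(c)]
            m = snv & (trinuc.CLASS_CONTEXT[np.clip(cid, 0, 95)] == c)
            p = pos[m]
            lo = np.searchsorted(cand, p - half)
            hi = np.searchsorted(cand, p + half)
            n_avail = hi - lo
            ok = n_avail > 0
            n_stuck += int((~ok).sum())
            choice = cand[lo[ok] + rng.integers(0, n_avail[ok])]
            tgt = idx[m][ok]
            new_pos[tgt] = choice
            alt_pyr = trinuc.CLASS_ALT_PYR[cid[m][ok]]
            alt_code = np.where(flipped[choice], trinuc.COMPLEMENT[alt_pyr], alt_pyr)
            new_ref[tgt] = _BASE_CHARS[arr[choice]]
            new_alt[tgt] = _BASE_CHARS[alt_code]
            new_strand[tgt] = np.where(flipped[choice], "c", "w")
        ind = cid == trinuc.INDEL_CLASS
        if ind.any():
            p = pos[ind]
            lo = np.maximum(p - half, 0)
            hi = np.minimum(p + half, len(arr))
            choice = lo + rng.integers(0, hi - lo)
            tgt = idx[ind]
            new_pos[tgt] = choice
            old_alt = new_alt[tgt]
            new_ref[tgt] = _BASE_CHARS[arr[choice]]
            new_alt[tgt] = np.array(
                [_BASE_CHARS[arr[c]] + a[1:] for c, a in zip(choice, old_alt)],
                dtype=object,
            )
    out = df.assign(pos=new_pos, ref=new_ref, alt=new_alt, strand=new_strand)
    return MutationSet(df=out, counters={**ms.counters, "shuffle_kept_in_place": n_stuck})
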