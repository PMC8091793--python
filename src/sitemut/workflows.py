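"""Cohort-level orchestration: subset sweeps, filters, benchmarks, screens.

These routines reproduce the standard analyses built on the site-enrichment
test: the default battery of mutation subsets with batch FDR, exclusion of
outlier tumours with exceptionally strong single-genome signals, power
analysis by down-sampling sites and genomes, value-binned site-group
comparisons at matched site counts, gene-set TSS analysis, the binary
genetic-feature interaction screen, and percent-genome-altered (PGA)
computation for feature construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from . import trinuc
from .genome import Genome
from .intervals import SiteSet, normalize_sites
from .model import (
    InteractionResult,
    RM2Result,
    bh_fdr,
    rm2_test,
    test_cofactor_interaction,
)
from .mutations import (
    MutationSet,
    SignatureCatalog,
    assign_signatures,
    classify_mutations,
    filter_hypermutators,
    subset_mask,
    subset_mutations,
    subset_tumours,
)
from .tabulate import CohortTabulator, build_cofactor_table

log = logging.getLogger(__name__)

DEFAULT_SUBSETS = ("total",) + trinuc.PYRIMIDINE_SUBS + ("w", "c", "indel")


@dataclass
class CohortConfig:
    """Analysis parameters; defaults follow the CTCF-style site convention
    (use half_width=100 for TSS / open-chromatin-like elements)."""

    half_width: int = 25
    n_bins: int = 10
    min_cohort_size: int = 25
    hypermutator_threshold: int = 90_000
    outlier_fdr: float = 0.001
    alpha: float = 0.05
    seed: int = 1
    n_draws: int = 1000
    include_mbp: bool = True
    filter_outliers: bool = False

    def __post_init__(self):
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        for name in ("n_bins", "min_cohort_size", "hypermutator_threshold",
                     "outlier_fdr", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _ensure_classified(ms: MutationSet, genome: Genome) -> MutationSet:
    if (ms.df["class_id"].to_numpy() == trinuc.CLASS_UNCLASSIFIED).any():
        return classify_mutations(ms, genome)
    return ms


def _subset_seed_rngs(seed: int, names) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def run_cohort_analysis(
    sites,
    mutations: MutationSet,
    genome: Genome,
    subsets=None,
    config: CohortConfig | None = None,
    catalog: SignatureCatalog | None = None,
) -> pd.DataFrame:
    """Default analysis battery: one site-enrichment test per mutation subset.

    Applies the hypermutator filter (and, when ``config.filter_outliers``, the
    single-tumour outlier filter), builds the subset-invariant table pieces
    once, runs the site test for every subset and BH-adjusts p-values across
    the batch.  ``sites`` may be a SiteSet or raw intervals (normalized with
    ``config.half_width``).  With a signature catalog, per-signature subsets
    are appended to the battery.
    """
    config = config or CohortConfig()
    if not isinstance(sites, SiteSet):
        sites = normalize_sites(sites, config.half_width, genome.lengths)
    if sites.n_sites == 0:
        raise ValueError("no sites remain after normalization")
    ms = _ensure_classified(mutations, genome)
    ms, _hyper = filter_hypermutators(ms, config.hypermutator_threshold)
    if config.filter_outliers:
        ms, _outliers = filter_outlier_tumours(sites, ms, genome, config)
    n_tumours = len(ms.tumours)
    if n_tumours < config.min_cohort_size:
        raise ValueError(
            f"cohort has {n_tumours} tumours (< {config.min_cohort_size}); "
            "pool small cohorts into a meta-cohort before analysis"
        )
    if catalog is not None:
        ms = assign_signatures(ms, catalog)
    if subsets is None:
        subsets = list(DEFAULT_SUBSETS)
        if catalog is not None:
            present = sorted(ms.df["signature"].dropna().unique())
            subsets += present
    tab = CohortTabulator(sites, genome, ms, n_bins=config.n_bins)
    rngs = _subset_seed_rngs(config.seed, subsets)
    results: list[RM2Result] = []
    for name in subsets:
        table = tab.table_for_mask(subset_mask(ms, name))
        results.append(
            rm2_test(
                table,
                n_draws=config.n_draws,
                seed=rngs[name],
                include_mbp=config.include_mbp,
                subset=name,
                n_sites=sites.n_sites,
            )
        )
    qs = bh_fdr([r.p_site for r in results])
    for r, q in zip(results, qs):
        r.fdr = float(q)
    return pd.DataFrame([r.to_row() for r in results])


def filter_outlier_tumours(
    sites: SiteSet, mutations: MutationSet, genome: Genome,
    config: CohortConfig | None = None,
):
    """Drop tumours whose single-genome site signal is exceptionally strong.

    Megabase rates and bins are learned from the full cohort; each tumour's
    own mutations are then tested alone, p-values BH-adjusted across tumours,
    and tumours with q below ``config.outlier_fdr`` and a positive site
    coefficient are removed.  Returns (kept MutationSet, outlier roster).
    """
    config = config or CohortConfig()
    ms = _ensure_classified(mutations, genome)
    tab = CohortTabulator(sites, genome, ms, n_bins=config.n_bins)
    tumours = ms.tumours
    tumour_col = ms.df["tumour"].to_numpy()
    ps, coefs = [], []
    for t in tumours:
        res = rm2_test(
            tab.table_for_mask(tumour_col == t),
            n_draws=0,
            include_mbp=config.include_mbp,
            subset=t,
        )
        ps.append(res.p_site)
        coefs.append(res.coef_site)
    qs = bh_fdr(ps)
    outliers = {
        t: {"q": float(q), "coef": float(c)}
        for t, q, c in zip(tumours, qs, coefs)
        if q < config.outlier_fdr and c > 0
    }
    kept = subset_tumours(ms, [t for t in tumours if t not in outliers])
    if outliers:
        log.info("removed %d outlier tumours: %s", len(outliers), sorted(outliers))
    return kept, outliers


def power_analysis(
    sites: SiteSet,
    mutations: MutationSet,
    genome: Genome,
    site_grid,
    genome_grid,
    n_reps: int = 100,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Fraction of significant runs and median p over a down-sampling grid.

    For every (n_sites, n_genomes) cell, ``n_reps`` random subsets of sites
    and tumours are drawn (seeded from ``config.seed``) and the total-mutation
    site test is run on each; the cell records the fraction of runs with
    p below ``config.alpha`` and the median p.
    """
    config = config or CohortConfig()
    ms = _ensure_classified(mutations, genome)
    tumours = np.array(ms.tumours)
    for ns in site_grid:
        if ns > sites.n_sites:
            raise ValueError(f"site grid value {ns} exceeds {sites.n_sites} sites")
    for ng in genome_grid:
        if ng > len(tumours):
            raise ValueError(f"genome grid value {ng} exceeds {len(tumours)} tumours")
    rows = []
    ss = np.random.SeedSequence(config.seed)
    cells = [(ns, ng) for ns in site_grid for ng in genome_grid]
    cell_seeds = ss.spawn(len(cells))
    for (ns, ng), cseed in zip(cells, cell_seeds):
        rng = np.random.default_rng(cseed)
        ps = []
        for _ in range(n_reps):
            s_idx = np.sort(rng.choice(sites.n_sites, size=ns, replace=False))
            t_sel = rng.choice(tumours, size=ng, replace=False)
            sub_sites = sites.subset(s_idx)
            sub_ms = subset_tumours(ms, t_sel)
            tab = CohortTabulator(sub_sites, genome, sub_ms, n_bins=config.n_bins)
            res = rm2_test(
                tab.table(subset_mutations(sub_ms, "total")),
                n_draws=0,
                include_mbp=config.include_mbp,
            )
            ps.append(res.p_site)
        ps = np.array(ps)
        rows.append(
            {
                "n_sites": ns,
                "n_genomes": ng,
                "frac_significant": float((ps < config.alpha).mean()),
                "median_p": float(np.median(ps)),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def group_sites_by_value(sites: SiteSet, values, n_bins: int = 5) -> dict:
    """Equal-frequency site bins by a per-site numeric value (bin 1 = lowest).

    Ranks use stable tie-breaking by input order; bin sizes differ by at most
    one.  Returns {bin label: SiteSet}.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != sites.n_sites:
        raise ValueError("values must align with sites")
    n = sites.n_sites
    if n < n_bins:
        raise ValueError(f"{n} sites cannot fill {n_bins} bins")
    order = np.argsort(values, kind="stable")
    sizes = np.full(n_bins, n // n_bins, dtype=int)
    sizes[: n % n_bins] += 1
    out, start = {}, 0
    for b, size in enumerate(sizes, start=1):
        out[b] = sites.subset(np.sort(order[start : start + size]))
        start += size
    return out


def compare_binned_downsampled(
    binned: dict,
    mutations: MutationSet,
    genome: Genome,
    n_sample: int = 4500,
    n_iter: int = 100,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Compare site bins at matched site counts via repeated down-sampling.

    Within every bin, ``n_iter`` random samples of ``n_sample`` sites are
    tested and the iteration achieving the median p (lower median for even
    ``n_iter``) is reported; reported p-values are then BH-adjusted across
    bins.
    """
    config = config or CohortConfig()
    ms = _ensure_classified(mutations, genome)
    for label, s in binned.items():
        if s.n_sites < n_sample:
            raise ValueError(
                f"bin {label} has {s.n_sites} sites < n_sample {n_sample}; "
                "reduce n_sample"
            )
    rows = []
    ss = np.random.SeedSequence(config.seed)
    bin_seeds = ss.spawn(len(binned))
    for (label, s), bseed in zip(sorted(binned.items()), bin_seeds):
        iter_seeds = bseed.spawn(n_iter)

        def one_iter(i, n_draws):
            rng = np.random.default_rng(iter_seeds[i])
            idx = np.sort(rng.choice(s.n_sites, size=n_sample, replace=False))
            sub = s.subset(idx)
            tab = CohortTabulator(sub, genome, ms, n_bins=config.n_bins)
            return rm2_test(
                tab.table(subset_mutations(ms, "total")),
                n_draws=n_draws,
                seed=np.random.default_rng(iter_seeds[i]),
                include_mbp=config.include_mbp,
                subset=f"bin{label}",
                n_sites=n_sample,
            )

        ps = np.array([one_iter(i, 0).p_site for i in range(n_iter)])
        med_idx = int(np.argsort(ps, kind="stable")[(n_iter - 1) // 2])
        res = one_iter(med_idx, config.n_draws)
        row = res.to_row()
        row["bin"] = label
        row["median_iteration"] = med_idx
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    return out


def read_gmt(path) -> dict:
    """GMT gene sets: {set name: set of gene symbols}."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def geneset_analysis(
    tss_sites: SiteSet,
    gene_sets: dict,
    mutations: MutationSet,
    genome: Genome,
    min_size: int = 100,
    max_size: int = 1000,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Site test restricted to the TSSs of each gene set.

    ``tss_sites.names`` must carry gene symbols.  Set size is the number of
    distinct set genes present in the TSS annotation; sets outside
    [min_size, max_size] (inclusive) are dropped.  Reported p-values are
    BH-adjusted across surviving sets.
    """
    config = config or CohortConfig()
    if tss_sites.names is None:
        raise ValueError("tss_sites must carry gene names")
    ms = _ensure_classified(mutations, genome)
    names = tss_sites.names
    present = set(names)
    rows = []
    rngs = _subset_seed_rngs(config.seed, sorted(gene_sets))
    for set_name in sorted(gene_sets):
        genes = set(gene_sets[set_name]) & present
        if not (min_size <= len(genes) <= max_size):
            continue
        idx = np.where(np.isin(names, list(genes)))[0]
        sub = tss_sites.subset(idx)
        tab = CohortTabulator(sub, genome, ms, n_bins=config.n_bins)
        res = rm2_test(
            tab.table(subset_mutations(ms, "total")),
            n_draws=config.n_draws,
            seed=rngs[set_name],
            include_mbp=config.include_mbp,
            subset=set_name,
            n_sites=sub.n_sites,
        )
        row = res.to_row()
        row["gene_set"] = set_name
        row["n_genes"] = len(genes)
        rows.append(row)
    if not rows:
        log.warning("no gene sets within [%d, %d] genes", min_size, max_size)
        return pd.DataFrame()
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    return out


def filter_features(features: pd.DataFrame, cohort_size: int,
                    min_carriers: int = 15, max_fraction: float = 2 / 3) -> list:
    """Feature columns neither too rare (< min_carriers) nor too frequent
    (> max_fraction of the cohort); both bounds strict, as printed."""
    keep = []
    for col in features.columns:
        carriers = int(features[col].sum())
        if carriers < min_carriers or carriers > max_fraction * cohort_size:
            continue
        keep.append(col)
    return keep


def screen_genetic_features(
    features: pd.DataFrame,
    sites,
    mutations: MutationSet,
    genome: Genome,
    config: CohortConfig | None = None,
):
    """Interaction screen of binary tumour features against site classes.

    ``features`` is a tumours x features 0/1 table; ``sites`` is one SiteSet
    or {class name: SiteSet}.  After frequency filtering, every feature x
    site-class pair gets the cofactor-interaction test; main-effect p-values
    are BH-adjusted over the whole screen and hits require adjusted main
    significance, unadjusted interaction p < 0.05 and positive site and
    interaction coefficients.  Returns (results DataFrame,
    {(site class, feature): InteractionResult}).
    """
    config = config or CohortConfig()
    if isinstance(sites, SiteSet):
        sites = {"sites": sites}
    ms = _ensure_classified(mutations, genome)
    roster = ms.tumours
    feats = features.reindex(roster).fillna(0).astype(int)
    keep = filter_features(feats, len(roster))
    rows, details = [], {}
    keys = [(sc, f) for sc in sorted(sites) for f in keep]
    rngs = _subset_seed_rngs(config.seed, keys)
    for site_class, feat in keys:
        cofactor = dict(zip(roster, feats[feat].to_numpy()))
        table = build_cofactor_table(
            sites[site_class], genome, ms, ms, cofactor, n_bins=config.n_bins
        )
        res = test_cofactor_interaction(
            table,
            seed=rngs[(site_class, feat)],
            n_draws=config.n_draws,
            include_mbp=config.include_mbp,
        )
        details[(site_class, feat)] = res
        rows.append(
            {
                "site_class": site_class,
                "feature": feat,
                "n_carriers": int(feats[feat].sum()),
                "p_site": res.p_site,
                "coef_site": res.coef_site,
                "p_interaction": res.p_interaction,
                "coef_interaction": res.coef_interaction,
                "fc": res.fc,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_site"] = bh_fdr(out["p_site"])
        out["hit"] = [
            details[(r.site_class, r.feature)].is_hit(r.q_site, config.alpha)
            for r in out.itertuples()
        ]
    return out, details


def compute_pga(
    segments: pd.DataFrame,
    wgd: dict,
    autosome_lengths: dict,
) -> pd.DataFrame:
    """Percent genome altered per tumour, median-dichotomised.

    ``segments`` columns: tumour, chrom, start, end, total_cn.  The copy-number
    baseline is 2, or 4 for tumours flagged whole-genome duplicated; only
    autosomes (keys of ``autosome_lengths``) count, segments elsewhere are
    ignored with a counter.  ``pga_high`` is 1 for strictly above-median PGA.
    """
    total_bp = float(sum(autosome_lengths.values()))
    autosomes = set(autosome_lengths)
    n_sex = int((~segments["chrom"].isin(autosomes)).sum())
    if n_sex:
        log.info("ignored %d segments outside the autosomes", n_sex)
    tumours = sorted(set(segments["tumour"]) | set(wgd))
    pga = {}
    auto = segments[segments["chrom"].isin(autosomes)]
    for t in tumours:
        baseline = 4 if wgd.get(t, False) else 2
        sub = auto[(auto["tumour"] == t) & (auto["total_cn"] != baseline)]
        altered = float((sub["end"] - sub["start"]).sum())
        pga[t] = 100.0 * altered / total_bp
    out = pd.DataFrame({"tumour": tumours, "pga": [pga[t] for t in tumours]})
    med = out["pga"].median()
    out["pga_high"] = (out["pga"] > med).astype(int)
    out.attrs["n_sex_segments_ignored"] = n_sex
    return out


def width_sweep(
    raw_intervals,
    mutations: MutationSet,
    genome: Genome,
    half_widths,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Total-mutation site test across a range of half-width values."""
    config = config or CohortConfig()
    rows = []
    for h in half_widths:
        cfg = replace(config, half_width=int(h))
        sites = normalize_sites(raw_intervals, cfg.half_width, genome.lengths)
        res = run_cohort_analysis(sites, mutations, genome, subsets=["total"],
                                  config=cfg)
        res["half_width"] = int(h)
        rows.append(res)
    return pd.concat(rows, ignore_index=True)
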