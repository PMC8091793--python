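"""Regression table construction: megabase rates, rate binning, count strata.

The regression input is one row per (bin, is_site, class [, cofac]) stratum
carrying the observed mutation count (n_mut), the mutational opportunity count
(n_posits) and the megabase-scale rate covariate (mbp_rate).  Megabase rates
are always computed from the *total* cohort mutation set — never from the
analysed subset — so that bins are identical across subset analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import trinuc
from .intervals import (
    OpportunityCounts,
    PositionAssignment,
    SiteSet,
    assign_positions,
    count_opportunities,
)
from .mutations import MutationSet, subset_tumours

TABLE_COLUMNS = ["bin", "is_site", "cofac", "class_id", "n_mut", "n_posits", "mbp_rate"]


@dataclass
class SiteRateTable:
    """Per-site raw mutation count in the one-megabase window, plus bin label."""

    site_id: np.ndarray
    count: np.ndarray
    bin: np.ndarray | None = None  # labels 1..B once binned

    def bin_of(self) -> dict:
        if self.bin is None:
            raise ValueError("sites not yet binned")
        return {int(s): int(b) for s, b in zip(self.site_id, self.bin)}


def site_mbp_rates(
    site_set: SiteSet, all_mutations: MutationSet, window: int = 1_000_000
) -> SiteRateTable:
    """Total cohort mutation count within +/- window/2 of each site midpoint.

    The window is half-open ``[mid - window//2, mid + window//2)`` and is
    truncated at chromosome edges without rescaling.
    """
    half = window // 2
    counts = np.zeros(site_set.n_sites, dtype=np.int64)
    pos_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in all_mutations.df.groupby("chrom", observed=True)
    }
    for chrom in np.unique(site_set.chrom):
        sel = np.where(site_set.chrom == chrom)[0]
        mut_pos = pos_by_chrom.get(str(chrom))
        if mut_pos is None:
            continue
        mids = site_set.midpoint[sel]
        lo = np.searchsorted(mut_pos, mids - half, side="left")
        hi = np.searchsorted(mut_pos, mids + half, side="left")
        counts[sel] = hi - lo
    return SiteRateTable(site_id=site_set.site_id.copy(), count=counts)


def bin_sites_by_rate(rates: SiteRateTable, n_bins: int = 10) -> SiteRateTable:
    """Distribute sites into equal-frequency bins by log1p window count.

    Sites are ranked by log1p(count) with ties broken by stable input order and
    split into ``n_bins`` contiguous rank groups whose sizes differ by at most
    one (larger groups first).  Bin 1 holds the lowest rates.
    """
    n = len(rates.site_id)
    if n < n_bins:
        raise ValueError(
            f"{n} sites cannot fill {n_bins} bins; lower n_bins to at most {n}"
        )
    order = np.argsort(np.log1p(rates.count), kind="stable")
    sizes = np.full(n_bins, n // n_bins, dtype=np.int64)
    sizes[: n % n_bins] += 1
    bins = np.empty(n, dtype=np.int64)
    start = 0
    for b, size in enumerate(sizes, start=1):
        bins[order[start : start + size]] = b
        start += size
    return SiteRateTable(site_id=rates.site_id, count=rates.count, bin=bins)


def _table_skeleton(opportunities: OpportunityCounts, rates: SiteRateTable) -> pd.DataFrame:
    """All nonzero-opportunity rows with covariates, n_mut left to the caller.

    Carries a ``_flat`` helper column with the stratum's flat index
    ``(bin_axis*2 + is_site)*97 + class``.
    """
    if rates.bin is None:
        raise ValueError("rates must be binned first")
    bin_labels = opportunities.bin_labels
    nb = len(bin_labels)
    bin_mean = {
        int(b): float(rates.count[rates.bin == b].mean()) for b in np.unique(rates.bin)
    }
    bins_col = np.repeat(bin_labels, 2 * trinuc.N_CLASSES)
    site_col = np.tile(np.repeat([0, 1], trinuc.N_CLASSES), nb)
    class_col = np.tile(np.arange(trinuc.N_CLASSES), 2 * nb)
    npos = opportunities.counts.reshape(-1)
    table = pd.DataFrame(
        {
            "bin": bins_col,
            "is_site": site_col,
            "cofac": 0,
            "class_id": class_col,
            "n_mut": 0,
            "n_posits": npos,
            "mbp_rate": [bin_mean.get(int(b), 0.0) for b in bins_col],
            "_flat": np.arange(nb * 2 * trinuc.N_CLASSES),
        }
    )
    return table[npos > 0].reset_index(drop=True)


def build_regression_table(
    assignment: PositionAssignment,
    opportunities: OpportunityCounts,
    analysed: MutationSet,
    rates: SiteRateTable,
    cofac: int | None = None,
) -> pd.DataFrame:
    """Tally analysed mutations into the (bin, is_site, class) strata.

    Each analysed mutation landing on an assigned position increments the
    n_mut of its stratum; mutations on unassigned positions or without a class
    are ignored (the counts are attached as DataFrame attrs).  ``mbp_rate`` of
    a row is the mean raw window count over the sites of its bin; site and
    flank rows of a bin share it.  Rows with zero opportunities are dropped.
    ``cofac`` stamps a constant cofactor level onto the rows (tables for the
    two tumour groups are built separately and concatenated).
    """
    bin_labels = opportunities.bin_labels
    nb = len(bin_labels)
    bin_pos = {int(b): i for i, b in enumerate(bin_labels)}
    nmut = np.zeros((nb, 2, trinuc.N_CLASSES), dtype=np.int64)
    n_unassigned = 0
    n_unclassified = 0
    for chrom, sub in analysed.df.groupby("chrom", observed=True):
        cid = sub["class_id"].to_numpy()
        classified = cid >= 0
        n_unclassified += int((~classified).sum())
        pos = sub["pos"].to_numpy()[classified]
        cid = cid[classified]
        hit, is_site, bins, _ = assignment.lookup(str(chrom), pos)
        n_unassigned += int((~hit).sum())
        if not hit.any():
            continue
        b_idx = np.array([bin_pos[int(b)] for b in bins[hit]])
        flat = (b_idx * 2 + is_site[hit].astype(np.int64)) * trinuc.N_CLASSES + cid[hit]
        nmut += np.bincount(flat, minlength=nb * 2 * trinuc.N_CLASSES).reshape(
            nb, 2, trinuc.N_CLASSES
        )
    table = _table_skeleton(opportunities, rates)
    table["n_mut"] = nmut.reshape(-1)[table["_flat"].to_numpy()]
    table = table.drop(columns="_flat")
    if cofac is not None:
        table["cofac"] = int(cofac)
    table.attrs["n_unassigned_mutations"] = n_unassigned
    table.attrs["n_unclassified_mutations"] = n_unclassified
    table.attrs["has_cofac"] = cofac is not None
    return table


class CohortTabulator:
    """Caches the subset-invariant pieces of table construction.

    Rates, bins, position assignment and opportunity counts depend only on the
    site set and the total cohort mutations, so they are computed once and
    reused across mutation-subset analyses.
    """

    def __init__(self, site_set: SiteSet, genome, all_mutations: MutationSet,
                 n_bins: int = 10, window: int = 1_000_000):
        self.site_set = site_set
        self.genome = genome
        self.all_mutations = all_mutations
        self.n_bins = n_bins
        self.rates = bin_sites_by_rate(
            site_mbp_rates(site_set, all_mutations, window=window), n_bins=n_bins
        )
        self.assignment = assign_positions(site_set, self.rates.bin)
        self.opportunities = count_opportunities(genome, self.assignment)
        # per-mutation stratum index over the full cohort, computed once so
        # that subset tables reduce to a masked bincount
        bin_pos = {int(b): i for i, b in enumerate(self.opportunities.bin_labels)}
        df = all_mutations.df
        n = len(df)
        self._flat = np.full(n, -1, dtype=np.int64)
        cid_all = df["class_id"].to_numpy()
        for chrom, sub in df.groupby("chrom", observed=True):
            loc = sub.index.to_numpy()
            cid = cid_all[loc]
            classified = cid >= 0
            pos = sub["pos"].to_numpy()[classified]
            hit, is_site, bins, _ = self.assignment.lookup(str(chrom), pos)
            if not hit.any():
                continue
            b_idx = np.array([bin_pos[int(b)] for b in bins[hit]])
            tgt = loc[classified][hit]
            self._flat[tgt] = (
                b_idx * 2 + is_site[hit].astype(np.int64)
            ) * trinuc.N_CLASSES + cid[hit]
        nb = len(self.opportunities.bin_labels)
        self._skeleton = _table_skeleton(self.opportunities, self.rates)
        self._nb = nb

    def table_for_mask(self, mask: np.ndarray) -> pd.DataFrame:
        """Regression table for the cohort rows selected by a boolean mask."""
        flat = self._flat[mask]
        assigned = flat >= 0
        nmut = np.bincount(
            flat[assigned], minlength=self._nb * 2 * trinuc.N_CLASSES
        )
        table = self._skeleton.copy()
        table["n_mut"] = nmut[table["_flat"].to_numpy()]
        table.attrs["n_unassigned_mutations"] = int((~assigned).sum())
        table.attrs["has_cofac"] = False
        return table.drop(columns="_flat")

    def table(self, analysed: MutationSet) -> pd.DataFrame:
        return build_regression_table(
            self.assignment, self.opportunities, analysed, self.rates
        )


def build_cofactor_table(
    site_set: SiteSet,
    genome,
    all_mutations: MutationSet,
    analysed: MutationSet,
    cofactor,
    n_bins: int = 10,
    window: int = 1_000_000,
    shared_bins: bool = False,
) -> pd.DataFrame:
    """Two-group regression table for a binary tumour-level cofactor.

    ``cofactor`` maps tumour id to 0/1.  By default rates, bins, assignment
    and opportunities are computed separately from each group's total
    mutations; ``shared_bins=True`` is a compatibility switch that bins once
    from the pooled cohort and only splits the mutation counts.
    """
    cofactor = dict(cofactor)
    unknown = set(analysed.df["tumour"].unique()) - set(cofactor)
    if unknown:
        raise ValueError(f"tumours without cofactor label: {sorted(unknown)[:5]} ...")
    levels = set(cofactor.values())
    if not levels <= {0, 1} or len(levels) < 2:
        raise ValueError("cofactor must take both values 0 and 1")
    parts = []
    if shared_bins:
        tab = CohortTabulator(site_set, genome, all_mutations, n_bins, window)
        for level in (0, 1):
            tums = [t for t, v in cofactor.items() if v == level]
            part = build_regression_table(
                tab.assignment, tab.opportunities,
                subset_tumours(analysed, tums), tab.rates, cofac=level,
            )
            parts.append(part)
    else:
        for level in (0, 1):
            tums = [t for t, v in cofactor.items() if v == level]
            group_all = subset_tumours(all_mutations, tums)
            tab = CohortTabulator(site_set, genome, group_all, n_bins, window)
            part = build_regression_table(
                tab.assignment, tab.opportunities,
                subset_tumours(analysed, tums), tab.rates, cofac=level,
            )
            parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    out.attrs["has_cofac"] = True
    out.attrs["n_unassigned_mutations"] = sum(
        p.attrs["n_unassigned_mutations"] for p in parts
    )
    return out


def table_to_tsv(table: pd.DataFrame, path) -> None:
    """Audit dump with human-readable class labels."""
    out = table.copy()
    out["class"] = [trinuc.CLASS_LABELS[k] for k in out["class_id"]]
    out[["bin", "is_site", "cofac", "class", "n_mut", "n_posits", "mbp_rate"]].to_csv(
        path, sep="\t", index=False
    )
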