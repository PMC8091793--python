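"""Somatic mutation ingestion, filtering, classification and subsetting.

Mutation records live in a pandas DataFrame with one row per (tumour, variant)
call.  SNVs carry an SBS96 class id and a strand label: Watson ('w') when the
forward-strand reference base is a pyrimidine (C/T), Crick ('c') otherwise.
Records with ``len(ref) != len(alt)`` are indels, pooled under a single class;
multi-nucleotide variants with ``len(ref) == len(alt) > 1`` are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import trinuc
from .genome import Genome

log = logging.getLogger(__name__)

COLUMNS = ["chrom", "pos", "ref", "alt", "tumour"]

REFALT_SELECTORS = set(trinuc.PYRIMIDINE_SUBS)
STRAND_SELECTORS = {"w", "c"}


@dataclass
class MutationSet:
    """Per-tumour variant records plus ingestion/classification counters."""

    df: pd.DataFrame
    counters: dict = field(default_factory=dict)

    def __post_init__(self):
        if "class_id" not in self.df.columns:
            self.df = self.df.assign(
                class_id=np.int64(trinuc.CLASS_UNCLASSIFIED), strand="."
            )
        self.df = self.df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return self.n

    @property
    def tumours(self) -> list[str]:
        return sorted(self.df["tumour"].unique())

    @property
    def tumour_totals(self) -> pd.Series:
        return self.df["tumour"].value_counts()

    def is_snv(self) -> np.ndarray:
        return (
            (self.df["ref"].str.len() == 1) & (self.df["alt"].str.len() == 1)
        ).to_numpy()

    def replace(self, df: pd.DataFrame, **extra_counters) -> "MutationSet":
        return MutationSet(df=df, counters={**self.counters, **extra_counters})


def _dedup(df: pd.DataFrame, counters: dict) -> pd.DataFrame:
    n0 = len(df)
    df = df.drop_duplicates(subset=["tumour", "chrom", "pos", "ref", "alt"])
    dups = n0 - len(df)
    if dups:
        counters["duplicate_rows_collapsed"] = dups
        log.warning("collapsed %d duplicate identical mutation rows", dups)
    return df


def load_mutations(path, fmt: str | None = None, genome: Genome | None = None,
                   tumour_id: str | None = None) -> MutationSet:
    """Load mutations from VCF or a 5-column TSV (chrom, pos, ref, alt, tumour).

    VCF positions (1-based) are converted to 0-based; multi-allelic records are
    expanded to one record per alternative allele.  When ``genome`` is given,
    reference alleles are checked against it and mismatches counted.  TSV
    headers are auto-detected.
    """
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    counters: dict = {}
    if fmt == "vcf":
        df = _load_vcf(path, tumour_id, counters)
    elif fmt == "tsv":
        df = _load_tsv(path, counters)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    df = _dedup(df, counters)
    if genome is not None:
        ok = np.ones(len(df), dtype=bool)
        mism = 0
        for chrom, sub in df.groupby("chrom", observed=True):
            if chrom not in genome:
                ok[sub.index] = False
                continue
            arr = genome.codes(chrom)
            snv = (sub["ref"].str.len() == 1).to_numpy()
            pos = sub["pos"].to_numpy()
            refs = trinuc.BASE_CODE[
                np.frombuffer("".join(sub["ref"].str[0]).encode(), dtype=np.uint8)
            ]
            inb = pos < len(arr)
            good = inb & (~snv | (arr[np.minimum(pos, len(arr) - 1)] == refs))
            mism += int((~good).sum())
        counters["ref_mismatch"] = mism
    return MutationSet(df=df, counters=counters)


def _load_tsv(path, counters) -> pd.DataFrame:
    rows, bad = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                bad += 1
                log.warning("malformed TSV row at line %d", lineno)
                continue
            chrom, pos, ref, alt, tum = parts[:5]
            if lineno == 1 and not pos.lstrip("-").isdigit():
                continue  # header
            try:
                rows.append((chrom, int(pos), ref.upper(), alt.upper(), tum))
            except ValueError:
                bad += 1
                log.warning("malformed TSV row at line %d", lineno)
    if bad:
        counters["malformed_rows"] = bad
    if not rows and bad:
        raise ValueError(f"no parsable rows in {path}")
    return pd.DataFrame(rows, columns=COLUMNS)


def _load_vcf(path, tumour_id, counters) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt is None or set(alt.upper()) - set("ACGTN"):
                    continue
                if tumour_id is not None:
                    tums = [tumour_id]
                elif samples:
                    tums = [
                        s
                        for s in samples
                        if any(a not in (None, 0) for a in (rec.samples[s].get("GT") or (1,)))
                    ] or samples
                else:
                    tums = ["tumour"]
                for t in tums:
                    rows.append((rec.chrom, rec.pos - 1, rec.ref.upper(), alt.upper(), t))
    if not rows:
        raise ValueError(f"no parsable records in {path}")
    return pd.DataFrame(rows, columns=COLUMNS)


def filter_hypermutators(ms: MutationSet, threshold: int = 90_000):
    """Remove tumours with at least ``threshold`` mutations.

    Returns ``(kept, removed)`` where ``removed`` maps tumour id to its
    mutation total; kept and removed partition the input records.
    """
    totals = ms.tumour_totals
    hyper = totals[totals >= threshold]
    keep = ~ms.df["tumour"].isin(hyper.index)
    kept = ms.replace(ms.df[keep], hypermutators_removed=len(hyper))
    return kept, dict(hyper)


def classify_mutations(ms: MutationSet, genome: Genome) -> MutationSet:
    """Assign SBS96 class and strand to every record (vectorized).

    SNVs whose reference base disagrees with the genome are rejected (dropped
    with a counter); SNVs at chromosome edges or with N in their context are
    flagged excluded; MNVs are excluded with a counter.
    """
    df = ms.df.copy()
    class_id = np.full(len(df), trinuc.CLASS_EXCLUDED, dtype=np.int64)
    strand = np.full(len(df), ".", dtype=object)
    snv = ms.is_snv()
    mnv = (df["ref"].str.len() == df["alt"].str.len()) & ~snv
    indel = ~snv & ~mnv
    class_id[indel.to_numpy()] = trinuc.INDEL_CLASS
    reject = np.zeros(len(df), dtype=bool)
    for chrom, sub in df[snv].groupby("chrom", observed=True):
        if chrom not in genome:
            reject[sub.index] = True
            continue
        arr = genome.codes(chrom)
        pos = sub["pos"].to_numpy()
        refc = trinuc.BASE_CODE[
            np.frombuffer("".join(sub["ref"]).encode(), dtype=np.uint8)
        ]
        altc = trinuc.BASE_CODE[
            np.frombuffer("".join(sub["alt"]).encode(), dtype=np.uint8)
        ]
        inb = (pos >= 0) & (pos < len(arr))
        mism = inb & (arr[np.minimum(pos, len(arr) - 1)] != refc)
        reject[sub.index[~inb | mism]] = True
        ok = inb & ~mism
        p = pos[ok]
        inner = (p >= 1) & (p < len(arr) - 1)
        idx_ok = sub.index.to_numpy()[ok]
        # edge positions stay excluded
        p2 = p[inner]
        ctx, flipped = trinuc.context_index(arr[p2 - 1], arr[p2], arr[p2 + 1])
        valid = ctx >= 0
        alt_pyr = np.where(flipped, trinuc.COMPLEMENT[altc[ok][inner]], altc[ok][inner])
        cls = trinuc.class_from_context(np.maximum(ctx, 0), alt_pyr)
        tgt = idx_ok[inner][valid]
        class_id[tgt] = cls[valid]
        strand[tgt] = np.where(flipped[valid], "c", "w")
    df["class_id"] = class_id
    df["strand"] = strand
    n_rej = int(reject.sum())
    n_mnv = int(mnv.sum())
    out = df[~reject]
    return ms.replace(out, ref_mismatch_rejected=n_rej, mnv_excluded=n_mnv)


def classify_mutation(chrom: str, pos: int, ref: str, alt: str, genome: Genome):
    """Classify a single record; returns (class label, strand) or None if excluded."""
    df = pd.DataFrame([(chrom, pos, ref.upper(), alt.upper(), "t")], columns=COLUMNS)
    res = classify_mutations(MutationSet(df=df), genome)
    if res.n == 0:
        raise ValueError("reference allele mismatch")
    k = int(res.df["class_id"].iloc[0])
    if k < 0:
        return None
    return trinuc.CLASS_LABELS[k], res.df["strand"].iloc[0]


@dataclass
class SignatureCatalog:
    """SBS signature profiles (96 x signatures) and per-tumour exposures."""

    profiles: pd.DataFrame  # index: 96 class labels, columns: signatures
    exposures: pd.DataFrame  # index: tumours, columns: signatures

    def __post_init__(self):
        self.profiles = self.profiles.sort_index(axis=1)
        self.exposures = self.exposures.sort_index(axis=1)
        if list(self.profiles.columns) != list(self.exposures.columns):
            raise ValueError("profiles and exposures name different signatures")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("signature profiles must each sum to 1")
        if (self.exposures.to_numpy() < 0).any():
            raise ValueError("exposures must be non-negative")
        missing = set(trinuc.CLASS_LABELS[:96]) - set(self.profiles.index)
        if missing:
            raise ValueError(f"profiles missing {len(missing)} SBS classes")

    @classmethod
    def from_tsv(cls, profiles_path, exposures_path) -> "SignatureCatalog":
        prof = pd.read_csv(profiles_path, sep="\t", index_col=0)
        expo = pd.read_csv(exposures_path, sep="\t", index_col=0)
        return cls(profiles=prof, exposures=expo)

    @property
    def signatures(self) -> list[str]:
        return list(self.profiles.columns)


def assign_signatures(ms: MutationSet, catalog: SignatureCatalog) -> MutationSet:
    """Label each SNV with its most probable signature in its tumour.

    The score of signature s for a mutation of class k in tumour t is
    ``exposure[t, s] * profile[k, s]``; the argmax wins, ties going to the
    lexicographically smallest signature name.  Indels and excluded records
    are left unassigned, as are mutations of tumours absent from the exposure
    table (counted with a warning).
    """
    df = ms.df.copy()
    sigs = np.array(catalog.signatures)
    prof = catalog.profiles.reindex(list(trinuc.CLASS_LABELS[:96])).to_numpy()
    signature = np.full(len(df), None, dtype=object)
    n_missing = 0
    snv_classified = (df["class_id"].to_numpy() >= 0) & (
        df["class_id"].to_numpy() < trinuc.INDEL_CLASS
    )
    for tum, sub in df[snv_classified].groupby("tumour", observed=True):
        if tum not in catalog.exposures.index:
            n_missing += len(sub)
            continue
        expo = catalog.exposures.loc[tum].to_numpy()
        scores = prof[sub["class_id"].to_numpy()] * expo[None, :]
        signature[sub.index] = sigs[np.argmax(scores, axis=1)]
    if n_missing:
        log.warning("%d mutations from tumours without exposures left unassigned", n_missing)
    df["signature"] = signature
    return ms.replace(df, signature_unassigned_no_exposure=n_missing)


def subset_mask(ms: MutationSet, selector: str) -> np.ndarray:
    """Boolean row mask of the records matching a subset selector.

    Selectors: ``total``; ``snv``; ``indel``; a pyrimidine-normalized ref>alt
    pair (``C>A`` ... ``T>G``); a strand (``w``/``c``); or a signature label
    previously assigned.  Excluded records (class_id < 0) never match.
    """
    df = ms.df
    cid = df["class_id"].to_numpy()
    snv = (cid >= 0) & (cid < trinuc.INDEL_CLASS)
    if selector == "total":
        return cid >= 0
    if selector == "snv":
        return snv
    if selector == "indel":
        return cid == trinuc.INDEL_CLASS
    if selector in REFALT_SELECTORS:
        sub = trinuc.PYRIMIDINE_SUBS.index(selector)
        return snv & (cid // 16 == sub)
    if selector in STRAND_SELECTORS:
        return snv & (df["strand"].to_numpy() == selector)
    if "signature" in df.columns and selector in set(df["signature"].dropna().unique()):
        return snv & (df["signature"].to_numpy() == selector)
    raise ValueError(f"unknown selector {selector!r}")


def subset_mutations(ms: MutationSet, selector: str) -> MutationSet:
    """Select records by mutation family; see :func:`subset_mask`."""
    return MutationSet(
        df=ms.df[subset_mask(ms, selector)], counters=dict(ms.counters)
    )


def subset_tumours(ms: MutationSet, tumours) -> MutationSet:
    """Restrict to records of the given tumours."""
    return MutationSet(
        df=ms.df[ms.df["tumour"].isin(set(tumours))], counters=dict(ms.counters)
    )
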