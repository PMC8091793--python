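"""Method benchmarks: null calibration, recovery, covariate ablation, interaction.

These reproduce, at desk scale, the validation battery the framework is
shipped with: false-positive calibration on simulated null cohorts, recovery
of an injected site-level fold change, the value of the megabase-rate
covariate on confounded site catalogues, and detection of carrier-restricted
localized mutagenesis.  Fixed study conditions live in the ``*_SPEC``
dictionaries; each replicate derives its own seed from the caller's base seed.

Problem sizes are chosen so that a full battery runs on one CPU in minutes:
calibration cohorts use a 5 Mbp genome with 10,000 50-bp sites, 50 tumours
and 2 mutations/kb per tumour, which yields per-stratum counts comparable to
a whole-genome cohort; recovery and interaction runs scale the genome and
cohort up (10 Mbp / 20,000 sites / 100 tumours where stated).
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import kstest

from .model import rm2_test, test_cofactor_interaction
from .mutations import subset_mask
from .simulate import (
    SimulationSpec,
    shuffle_trinucleotide_preserving,
    simulate_cohort,
    simulate_genome,
    simulate_sites,
)
from .tabulate import CohortTabulator, build_cofactor_table
from .workflows import CohortConfig, run_cohort_analysis

#: null cohorts for calibration: the generator defaults (fold change 1,
#: megabase heterogeneity present)
CALIBRATION_SPEC: dict = {}

#: injected-enrichment recovery conditions
RECOVERY_SPEC = dict(
    genome_length=10_000_000, n_sites=20_000, n_tumours=100, site_fold_change=1.3
)

#: rate-covariate ablation conditions: a dense catalogue of 20,000 clustered
#: sites preferring low-rate regions (placement weight multiplier^-2, as
#: regulatory elements prefer early-replicating low-rate chromatin), strong
#: megabase heterogeneity and a modest injected enrichment
ABLATION_SPEC = dict(
    n_sites=20_000, site_fold_change=1.15, heterogeneity_sigma=1.0,
    site_rate_bias=-2.0,
)

#: carrier-restricted enrichment conditions
INTERACTION_SPEC = dict(
    n_tumours=100, carrier_fraction=0.3, carrier_fold_change=1.3,
    site_fold_change=1.0,
)


def _seed(base: int, i: int) -> int:
    return (int(base) * 1009 + i) % (2**31 - 1)


def _make(seed: int, **kw):
    spec = SimulationSpec(seed=seed, **kw)
    g = simulate_genome(spec)
    s = simulate_sites(spec, g)
    ms, truth = simulate_cohort(spec, g, s)
    return spec, g, s, ms, truth


def null_calibration(n_cohorts: int = 200, base_seed: int = 1) -> pd.DataFrame:
    """Default battery on independent null cohorts.

    Returns one row per cohort with the total-subset p-value and whether any
    subset reached q < 0.05 after per-cohort BH adjustment.  Summary keys are
    attached as DataFrame attrs: ``prop_any_significant`` and
    ``ks_p_total_uniform`` (KS test of the total-subset p-values against
    U(0,1)).
    """
    rows = []
    for i in range(n_cohorts):
        seed = _seed(base_seed, i)
        _, g, s, ms, _ = _make(seed, **CALIBRATION_SPEC)
        cfg = CohortConfig(seed=seed, n_draws=0)
        res = run_cohort_analysis(s, ms, g, config=cfg)
        rows.append(
            {
                "seed": seed,
                "p_total": float(res.loc[res["subset"] == "total", "p"].iloc[0]),
                "any_q_significant": bool((res["q"] < 0.05).any()),
                "min_q": float(res["q"].min()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["prop_any_significant"] = float(out["any_q_significant"].mean())
    out.attrs["ks_p_total_uniform"] = float(kstest(out["p_total"], "uniform").pvalue)
    return out


def enrichment_recovery(n_seeds: int = 50, base_seed: int = 1,
                        fc_band=(1.2, 1.4), n_draws: int = 1000) -> pd.DataFrame:
    """Detect an injected site fold change of 1.3 and estimate it.

    A replicate succeeds when the site test is significant (p < 0.05) and the
    estimated fold change falls inside ``fc_band``.
    """
    rows = []
    for i in range(n_seeds):
        seed = _seed(base_seed, 1000 + i)
        _, g, s, ms, truth = _make(seed, **RECOVERY_SPEC)
        tab = CohortTabulator(s, g, ms)
        r = rm2_test(tab.table_for_mask(subset_mask(ms, "total")),
                     n_draws=n_draws, seed=seed)
        rows.append(
            {
                "seed": seed,
                "p": r.p_site,
                "fc": r.fc,
                "expected_ratio": truth.expected_snv_site_flank_ratio(),
                "success": bool(r.p_site < 0.05 and fc_band[0] <= r.fc <= fc_band[1]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["success_rate"] = float(out["success"].mean())
    return out


def mbp_rate_ablation(n_pairs: int = 20, base_seed: int = 1) -> pd.DataFrame:
    """Paired comparison of the model with and without megabase information.

    The ablated model carries no megabase-rate information at all: sites are
    pooled into a single bin, removing both the covariate and the rate
    stratification it rides on.  For each pair the enriched cohort and its
    trinucleotide-preserving shuffle are analysed both ways; the full model
    should beat the ablated one on the true signal, while the ablated model
    should report spuriously small p-values on the shuffled null.
    """
    rows = []
    for i in range(n_pairs):
        seed = _seed(base_seed, 2000 + i)
        _, g, s, ms, _ = _make(seed, **ABLATION_SPEC)
        tab_full = CohortTabulator(s, g, ms)
        tab_abl = CohortTabulator(s, g, ms, n_bins=1)
        p_true_full = rm2_test(tab_full.table_for_mask(subset_mask(ms, "total")),
                               n_draws=0).p_site
        p_true_abl = rm2_test(tab_abl.table_for_mask(subset_mask(ms, "total")),
                              n_draws=0).p_site
        sh = shuffle_trinucleotide_preserving(ms, g, seed=seed)
        sh_full = CohortTabulator(s, g, sh)
        sh_abl = CohortTabulator(s, g, sh, n_bins=1)
        p_null_full = rm2_test(sh_full.table_for_mask(subset_mask(sh, "total")),
                               n_draws=0).p_site
        p_null_abl = rm2_test(sh_abl.table_for_mask(subset_mask(sh, "total")),
                              n_draws=0).p_site
        rows.append(
            {
                "seed": seed,
                "p_true_full": p_true_full,
                "p_true_ablated": p_true_abl,
                "p_null_full": p_null_full,
                "p_null_ablated": p_null_abl,
                "true_win": bool(p_true_full < p_true_abl),
                "null_win": bool(p_null_abl < p_null_full),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["true_win_rate"] = float(out["true_win"].mean())
    out.attrs["null_win_rate"] = float(out["null_win"].mean())
    return out


def interaction_recovery(n_seeds: int = 50, base_seed: int = 1) -> pd.DataFrame:
    """Detect carrier-restricted site enrichment through the interaction term."""
    rows = []
    for i in range(n_seeds):
        seed = _seed(base_seed, 3000 + i)
        _, g, s, ms, truth = _make(seed, **INTERACTION_SPEC)
        carriers = set(truth.carriers)
        cof = {t: int(t in carriers) for t in ms.tumours}
        table = build_cofactor_table(s, g, ms, ms, cof)
        r = test_cofactor_interaction(table, seed=seed, n_draws=0, per_group=False)
        rows.append(
            {
                "seed": seed,
                "n_carriers": len(carriers),
                "p_interaction": r.p_interaction,
                "coef_interaction": r.coef_interaction,
                "success": bool(r.p_interaction < 0.05 and r.coef_interaction > 0),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["success_rate"] = float(out["success"].mean())
    return out
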