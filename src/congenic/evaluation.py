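"""Simulation-based calibration and recovery checks for the pipeline.

These routines run the full analysis on synthetic experiment pairs with known
ground truth and measure how the pipeline behaves under the study conditions:
false-positive calibration under the null, recovery (recall) of true cis
effects as a function of effect size, and operating characteristics of the
probe-level SNP screen.  They back both the test suite and the reproduction
script; every number they return is recomputed from a fresh simulation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .concordance import ReciprocalConcordance, select_concordant
from .diffexpr import average_regions, differential_test
from .expression import COMBINED, GROUP_INP, GROUP_IP, ExpressionMatrix
from .probe_snp import ProbeSNPScreen
from .simulate import SimulationConfig, simulate_congenic_pair, simulate_probe_level

__all__ = [
    "context_results",
    "null_calibration",
    "concordance_recall",
    "probe_screen_calibration",
]


def context_results(matrix: ExpressionMatrix, method: str = "student") -> pd.DataFrame:
    """Two-group tests in every region plus the cross-region average."""
    frames = [
        differential_test(matrix.subset_region(r), method) for r in matrix.regions
    ]
    frames.append(differential_test(average_regions(matrix), method))
    return pd.concat(frames, ignore_index=True)


def null_calibration(
    seed: int,
    n_probe_sets: int = 20_000,
    alphas: Sequence[float] = (0.01, 0.05),
    selection_alpha: float = 0.05,
) -> dict:
    """False-positive calibration on an all-null experiment pair.

    Simulates a pair with no allele effects and no animal random effect (the
    shared per-animal effect is exchangeable within a probe set but correlates
    probe sets, so the binomial reference for panel-wide counts assumes it
    away), then measures per-context raw-p significance rates and the
    dual-significance concordance selection rate.

    Returns a dict with ``sig_rates`` {alpha: {context: fraction p <= alpha}},
    ``context_selection_rates`` {context: fraction of probe sets qualifying
    via that context}, ``selection_rate`` (any context), and ``n``.
    """
    cfg = SimulationConfig(
        n_probe_sets=n_probe_sets,
        frac_cis_regulated=0.0,
        n_trans_regulated=0,
        sigma_animal=0.0,
        frac_snp_probes=0.0,
        seed=seed,
    )
    mat_a, mat_b, _, _ = simulate_congenic_pair(cfg)
    res_a = context_results(mat_a)
    res_b = context_results(mat_b)
    sig_rates = {
        alpha: {
            ctx: float((sub["p"] <= alpha).mean())
            for ctx, sub in res_a.groupby("context")
        }
        for alpha in alphas
    }
    model = ReciprocalConcordance.from_results(res_a, res_b)
    records = select_concordant(model.pairs, alpha=selection_alpha)
    contexts = sorted(model.pairs["context"].unique())
    context_rates = {
        ctx: float(
            records["qualifying_contexts"].map(lambda cs: ctx in cs).mean()
        )
        for ctx in contexts
    }
    return {
        "n": n_probe_sets,
        "sig_rates": sig_rates,
        "context_selection_rates": context_rates,
        "selection_rate": float(records["selected"].mean()),
    }


def concordance_recall(
    delta: float,
    seed: int,
    n_regulated: int = 200,
    alpha: float = 0.05,
    sigma_resid: float = 0.2,
) -> dict:
    """Recall of true cis probe sets by the dual-significance filter.

    Simulates a reciprocal pair (8v8 and 6v6 animals) in which *n_regulated*
    in-interval probe sets carry a fixed-magnitude allele effect |delta|
    (random sign, identical across experiments), runs the per-region and
    combined tests in both, and measures the fraction of the truly regulated
    probe sets selected by :func:`~congenic.concordance.select_concordant`.
    """
    n_in = int(np.ceil(n_regulated / 0.8))
    cfg = SimulationConfig(
        n_probe_sets=n_in + 50,
        n_in_interval=n_in,
        frac_cis_regulated=n_regulated / n_in,
        n_trans_regulated=0,
        delta_fixed=delta,
        sigma_resid=sigma_resid,
        frac_snp_probes=0.0,
        seed=seed,
    )
    mat_a, mat_b, _, truth = simulate_congenic_pair(cfg)
    model = ReciprocalConcordance.from_results(
        context_results(mat_a), context_results(mat_b)
    )
    res = model.fit(alpha=alpha)
    true_cis = set(truth.loc[truth["locus_class"] == "cis", "probe_set_id"])
    selected = set(res.selected_ids)
    return {
        "n": len(true_cis),
        "recall": len(selected & true_cis) / len(true_cis),
        "n_selected": res.n_selected,
    }


def probe_screen_calibration(
    seed: int,
    n_probe_sets: int = 600,
    frac_snp: float = 0.5,
    snp_offset: float = 2.0,
    sigma_resid: float = 0.2,
) -> dict:
    """Sensitivity and false-flag rate of the probe-level SNP screen.

    Half the simulated probe sets (by default) receive one probe with a
    *snp_offset* log2 mismatch loss in iNP-allele carriers.  Sensitivity is
    the fraction of designated probes flagged; the false-flag rate is the
    per-probe flag rate among all probes of the unaffected probe sets.
    """
    cfg = SimulationConfig(
        n_probe_sets=n_probe_sets,
        frac_cis_regulated=0.0,
        n_trans_regulated=0,
        frac_snp_probes=frac_snp,
        snp_offset=snp_offset,
        sigma_resid=sigma_resid,
        seed=seed,
    )
    _, _, _, truth = simulate_congenic_pair(cfg)
    plm = simulate_probe_level(cfg, truth)
    screened = ProbeSNPScreen(plm).fit()
    table = screened.table
    flagged = set(table.loc[table["flagged"].fillna(False).astype(bool), "probe_id"])
    snp_probes = set(truth["snp_probe_id"].dropna())
    snp_sets = set(truth.loc[truth["snp_probe_id"].notna(), "probe_set_id"])
    null_probes = table.loc[~table["probe_set_id"].isin(snp_sets), "probe_id"]
    n_false = sum(p in flagged for p in null_probes)
    return {
        "n_snp_probes": len(snp_probes),
        "n_null_probes": len(null_probes),
        "sensitivity": len(flagged & snp_probes) / len(snp_probes),
        "false_flag_rate": n_false / len(null_probes),
    }
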