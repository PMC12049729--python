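"""Canned simulation experiments used for benchmarking the five scores.

These reproduce, at desk scale, the simulator-based method comparison:
a selection-free baseline cohort is generated on a synthetic coding
set, immune selection of increasing strength is applied, all five
immunoediting statistics are scored against the s = 0 baseline as
reference, and score distributions are compared across s with two-sided
Wilcoxon rank-sum tests under Benjamini–Hochberg correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .benchmark import METHODS, gradient_wilcoxon, selection_gradient_experiment
from .es_ccf import es_ccf_p
from .hbmr import hbmr_permutation_p, hbmr_score, substitution_class_probs
from .immune_dnds import context_weights, immune_dnds_score
from .oe_ratio import estimate_reference_rates, oe_permutation_p
from .regions import SubstitutionSpace
from .simulate import (
    SelectionConfig,
    build_synthetic_coding_set,
    default_spectrum,
    simulate_baseline_cohort,
)

#: default problem sizes for the desk-scale experiments
GRADIENT_N_SAMPLES = 120
GRADIENT_N_MUTATIONS = 400
CALIBRATION_N_SAMPLES = 200
CALIBRATION_N_MUTATIONS = 300
CALIBRATION_N_PERM = 200
CDS_LENGTH = 9999
BINDER_FRACTION = 0.3


def _world(seed: int, cds_length: int = CDS_LENGTH, binder_fraction: float = BINDER_FRACTION):
    regions, annotation = build_synthetic_coding_set(
        cds_length, binder_fraction, seed=seed
    )
    return regions, annotation, SubstitutionSpace(regions)


def simulate_world_and_baseline(
    seed: int,
    n_samples: int = GRADIENT_N_SAMPLES,
    n_mutations: int = GRADIENT_N_MUTATIONS,
    cds_length: int = CDS_LENGTH,
    binder_fraction: float = BINDER_FRACTION,
):
    """Synthetic coding set + annotation + baseline cohort from one seed."""
    regions, annotation, space = _world(seed, cds_length, binder_fraction)
    config = SelectionConfig(
        n_samples=n_samples,
        n_mutations=n_mutations,
        cds_length=cds_length,
        binder_fraction=binder_fraction,
        seed=seed + 1,
    )
    baseline = simulate_baseline_cohort(
        config, default_spectrum(), regions, annotation, space=space
    )
    return regions, annotation, space, baseline


def selection_gradient(
    seed: int,
    s_values=(0.0, 0.25, 0.5, 0.75, 1.0),
    mode: str = "combined",
    n_samples: int = GRADIENT_N_SAMPLES,
    n_mutations: int = GRADIENT_N_MUTATIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score all methods over a selection-strength grid.

    Returns ``(panel, tests)``: the concatenated per-sample score panel
    with an ``s`` column, and the Wilcoxon table comparing every pair
    of s groups per method, BH-adjusted over the whole family.
    """
    regions, annotation, space, baseline = simulate_world_and_baseline(
        seed, n_samples=n_samples, n_mutations=n_mutations
    )
    panel = selection_gradient_experiment(
        baseline, annotation, regions, s_values=s_values, mode=mode, space=space
    )
    rows = []
    from itertools import combinations

    for method in METHODS:
        for s1, s2 in combinations(sorted(s_values), 2):
            rows.append(gradient_wilcoxon(panel, method, s1, s2))
    tests = pd.DataFrame(rows)
    tests["p_adjusted"] = multipletests(tests["p"], method="fdr_bh")[1]
    return panel, tests


def extreme_adjusted_p(tests: pd.DataFrame, s_values=(0.0, 0.25, 0.5, 0.75, 1.0)) -> dict:
    """Adjusted p between the lowest and highest s, per method."""
    lo, hi = min(s_values), max(s_values)
    sel = tests[(tests["s_low"] == lo) & (tests["s_high"] == hi)]
    return dict(zip(sel["method"], sel["p_adjusted"]))


def null_calibration(
    seed: int,
    n_samples: int = CALIBRATION_N_SAMPLES,
    n_mutations: int = CALIBRATION_N_MUTATIONS,
    n_perm: int = CALIBRATION_N_PERM,
) -> dict:
    """Score and permutation-test a selection-free cohort against itself.

    Returns per-method score medians and per-sample permutation
    p-value arrays, for checking that the scores center on 1 (0 for
    ES-CCF) and that the permutation nulls are uniform.
    """
    regions, annotation, space, baseline = simulate_world_and_baseline(
        seed, n_samples=n_samples, n_mutations=n_mutations
    )
    rates = estimate_reference_rates(baseline, space=space)
    pt = substitution_class_probs(space)
    weights = context_weights(baseline)

    out: dict = {"medians": {}, "p_values": {}}
    for method, name in (("refSample", "oe_ref_sample"), ("codon", "oe_codon")):
        res = oe_permutation_p(baseline, rates, method, n_perm=n_perm, seed=seed + 2)
        out["medians"][name] = float(res["score"].median())
        out["p_values"][name] = res["p_value"].to_numpy()

    ss = np.random.SeedSequence(seed + 3)
    child_seeds = ss.generate_state(2 * n_samples)
    hbmr_scores, hbmr_p, dnds_scores, dnds_p, es_scores, es_p = [], [], [], [], [], []
    for i, sample in enumerate(baseline.samples()):
        df = baseline.df[baseline.df["sample"] == sample]
        h = hbmr_score(df, annotation, space, pt)
        hbmr_scores.append(h.hbmr)
        hbmr_p.append(
            hbmr_permutation_p(df, annotation, space, pt, n_perm, int(child_seeds[2 * i]))
            if h.assignable
            else np.nan
        )
        d = immune_dnds_score(
            df, annotation, space, weights, n_perm=n_perm, seed=int(child_seeds[2 * i + 1])
        )
        dnds_scores.append(d.immune_dnds)
        dnds_p.append(d.p_value)
        neo = df["is_neoantigen"].eq(True)
        es, p = es_ccf_p(
            df.loc[neo, "ccf"].to_numpy(),
            df.loc[~neo, "ccf"].to_numpy(),
            n_perm=n_perm,
            seed=int(child_seeds[2 * i + 1]) ^ 0x5A5A5A,
        )
        es_scores.append(es)
        es_p.append(p)
    out["medians"]["hbmr"] = float(np.nanmedian(hbmr_scores))
    out["medians"]["immune_dnds"] = float(np.nanmedian(dnds_scores))
    out["medians"]["es_ccf"] = float(np.nanmedian(es_scores))
    out["p_values"]["hbmr"] = np.asarray(hbmr_p)
    out["p_values"]["immune_dnds"] = np.asarray(dnds_p)
    out["p_values"]["es_ccf"] = np.asarray(es_p)
    return out


def fraction_below(p_values: np.ndarray, alpha: float = 0.05) -> float:
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    return float(np.mean(p < alpha)) if len(p) else np.nan
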