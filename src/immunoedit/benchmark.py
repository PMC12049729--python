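"""Orchestration: score all five methods, classify, compare.

``score_all`` applies the sample-eligibility filters (at least one
nonsynonymous mutation, one synonymous mutation and one neoantigen),
runs the five immunoediting statistics and assigns each sample an
edited / unedited / unassigned status per method.  The comparison
helpers compute Spearman concordance between scores, UpSet-style
intersections of edited sets, paired case/control (PDX-style)
proportions and Wilcoxon/Fisher group statistics with
Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .es_ccf import classify_es_ccf, ccf_enrichment_score, es_ccf_p
from .hbmr import hbmr_permutation_p, hbmr_score, substitution_class_probs
from .immune_dnds import context_weights, immune_dnds_score
from .mutation_io import MutationTable
from .oe_ratio import ReferenceRates, estimate_reference_rates, oe_permutation_p, oe_ratio_sample
from .regions import CodingRegionSet, RegionAnnotation, SubstitutionSpace

METHODS = ["oe_ref_sample", "oe_codon", "hbmr", "immune_dnds", "es_ccf"]


@dataclass
class ScoringConfig:
    n_perm: int = 0
    seed: int = 0
    weights_source: str = "cohort"
    es_with_p: bool = True
    min_nonsynonymous: int = 1
    min_synonymous: int = 1
    min_neoantigens: int = 1


def eligible_samples(cohort: MutationTable, config: ScoringConfig) -> list[str]:
    """Samples passing the eligibility filters for immunoediting scoring."""
    df = cohort.df
    keep = []
    for s, g in df.groupby("sample", sort=False):
        neo = g["is_neoantigen"].eq(True).sum()
        nobs = (g["consequence"] == "nonsynonymous").sum()
        sobs = (g["consequence"] == "synonymous").sum()
        if (
            nobs >= config.min_nonsynonymous
            and sobs >= config.min_synonymous
            and neo >= config.min_neoantigens
        ):
            keep.append(s)
    return keep


def _status(score: float, p: float | None = None, need_p: bool = False) -> str:
    if np.isnan(score) or (need_p and (p is None or np.isnan(p))):
        return "unassigned"
    if need_p:
        return "edited" if (score < 0 and p < 0.05) else "unedited"
    return "edited" if score < 1 else "unedited"


def score_all(
    cohort: MutationTable,
    reference: MutationTable,
    annotation: RegionAnnotation,
    regions: CodingRegionSet,
    config: ScoringConfig | None = None,
    space: SubstitutionSpace | None = None,
    rates: ReferenceRates | None = None,
) -> pd.DataFrame:
    """Five-method score panel, one row per eligible sample.

    Any method failure is isolated to an unassigned status for that
    sample and method; the panel never aborts.  Permutation p-values
    are computed when ``config.n_perm`` > 0.
    """
    config = config or ScoringConfig()
    if space is None:
        space = SubstitutionSpace(regions)
    if rates is None:
        rates = estimate_reference_rates(reference, space=space)
    pt = substitution_class_probs(space)
    weights = (
        context_weights(cohort) if config.weights_source == "cohort" else context_weights(None)
    )
    keep = eligible_samples(cohort, config)
    sub = MutationTable(cohort.df[cohort.df["sample"].isin(keep)].copy(), list(cohort.provenance))

    oe_p: dict[str, pd.DataFrame] = {}
    if config.n_perm > 0 and sub.df["sample"].nunique() >= 2:
        for method in ("refSample", "codon"):
            oe_p[method] = oe_permutation_p(
                sub, rates, method, n_perm=config.n_perm, seed=config.seed
            ).set_index("sample")

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.generate_state(max(len(keep), 1))
    rows = []
    for child, sample in zip(child_seeds, keep):
        df = sub.df[sub.df["sample"] == sample]
        row: dict = {"sample": sample}
        for method, name in (("refSample", "oe_ref_sample"), ("codon", "oe_codon")):
            try:
                r = oe_ratio_sample(df, rates, method)
                row[f"{name}_score"] = r.score
                row[f"{name}_p"] = (
                    float(oe_p[method].loc[sample, "p_value"]) if method in oe_p else np.nan
                )
            except Exception:
                row[f"{name}_score"] = np.nan
                row[f"{name}_p"] = np.nan
            row[f"{name}_status"] = _status(row[f"{name}_score"])
        try:
            h = hbmr_score(df, annotation, space, pt)
            row["hbmr_score"] = h.hbmr
            row["hbmr_p"] = (
                hbmr_permutation_p(df, annotation, space, pt, config.n_perm, int(child))
                if config.n_perm > 0 and h.assignable
                else np.nan
            )
        except Exception:
            row["hbmr_score"], row["hbmr_p"] = np.nan, np.nan
        row["hbmr_status"] = _status(row["hbmr_score"])
        try:
            d = immune_dnds_score(
                df, annotation, space, weights, n_perm=config.n_perm, seed=int(child)
            )
            row["immune_dnds_score"] = d.immune_dnds
            row["immune_dnds_p"] = d.p_value
        except Exception:
            row["immune_dnds_score"], row["immune_dnds_p"] = np.nan, np.nan
        row["immune_dnds_status"] = _status(row["immune_dnds_score"])
        try:
            with_ccf = df[df["ccf"].notna()]
            neo = with_ccf["is_neoantigen"].eq(True)
            ant = with_ccf.loc[neo, "ccf"].to_numpy()
            non = with_ccf.loc[~neo, "ccf"].to_numpy()
            if config.n_perm > 0:
                es, p = es_ccf_p(ant, non, n_perm=config.n_perm, seed=int(child))
            else:
                es, p = ccf_enrichment_score(ant, non).es, np.nan
            row["es_ccf_score"], row["es_ccf_p"] = es, p
        except Exception:
            row["es_ccf_score"], row["es_ccf_p"] = np.nan, np.nan
        row["es_ccf_status"] = classify_es_ccf(
            row["es_ccf_score"], row["es_ccf_p"], with_p=config.es_with_p
        )
        row["es_ccf_status_without_p"] = classify_es_ccf(
            row["es_ccf_score"], row["es_ccf_p"], with_p=False
        )
        rows.append(row)
    return pd.DataFrame(rows)


def concordance_and_overlap(panel: pd.DataFrame, min_pairs: int = 3) -> dict:
    """Spearman concordance matrix plus edited-set intersections.

    Correlations use only samples assignable (non-NaN score) by both
    methods and are missing below ``min_pairs`` shared samples.
    Intersections are UpSet-style exclusive subsets over edited sets;
    their counts sum to the union of edited samples.
    """
    corr = {}
    for m1, m2 in combinations(METHODS, 2):
        x = panel[f"{m1}_score"]
        y = panel[f"{m2}_score"]
        ok = x.notna() & y.notna()
        if ok.sum() >= min_pairs:
            rho, p = stats.spearmanr(x[ok], y[ok])
            corr[(m1, m2)] = {"rho": float(rho), "p": float(p), "n": int(ok.sum())}
        else:
            corr[(m1, m2)] = {"rho": np.nan, "p": np.nan, "n": int(ok.sum())}
    status_counts = {
        m: panel[f"{m}_status"].value_counts().to_dict() for m in METHODS
    }
    edited = {m: set(panel.loc[panel[f"{m}_status"] == "edited", "sample"]) for m in METHODS}
    union = set().union(*edited.values())
    exclusive = {}
    for sample in union:
        key = tuple(sorted(m for m in METHODS if sample in edited[m]))
        exclusive[key] = exclusive.get(key, 0) + 1
    return {
        "correlations": corr,
        "status_counts": status_counts,
        "edited_sets": {m: sorted(v) for m, v in edited.items()},
        "exclusive_intersections": exclusive,
        "union_edited": len(union),
        "union_proportion": len(union) / len(panel) if len(panel) else np.nan,
    }


def paired_comparison(
    case_panel: pd.DataFrame, control_panel: pd.DataFrame, pairing: dict[str, str]
) -> dict:
    """Case/control paired score comparison (PDX vs matched tumour style).

    For each method a pair is flagged "reduced selection in case" iff
    both scores are assigned and the case score is strictly greater
    than the control score (all five scores are oriented so that lower
    means more edited).  Per-method proportions use pairs where that
    method assigned both samples; the union proportion counts pairs
    flagged by at least one method over all pairs.
    """
    cases = case_panel.set_index("sample")
    controls = control_panel.set_index("sample")
    per_method = {}
    union_flagged: set[str] = set()
    for m in METHODS:
        flagged, assessed = [], 0
        for case_id, control_id in pairing.items():
            if case_id not in cases.index or control_id not in controls.index:
                continue
            cs = cases.loc[case_id, f"{m}_score"]
            ct = controls.loc[control_id, f"{m}_score"]
            if np.isnan(cs) or np.isnan(ct):
                continue
            assessed += 1
            if cs > ct:
                flagged.append(case_id)
        per_method[m] = {
            "n_flagged": len(flagged),
            "n_assessed": assessed,
            "proportion": len(flagged) / assessed if assessed else np.nan,
            "flagged": sorted(flagged),
        }
        union_flagged.update(flagged)
    n_pairs = len(pairing)
    return {
        "per_method": per_method,
        "union_flagged": sorted(union_flagged),
        "union_proportion": len(union_flagged) / n_pairs if n_pairs else np.nan,
        "n_pairs": n_pairs,
    }


def group_statistics(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    categorical: bool = False,
) -> pd.DataFrame:
    """Pairwise two-group tests with Benjamini–Hochberg adjustment.

    Continuous data: two-sided Wilcoxon rank-sum (Mann–Whitney U);
    categorical (boolean) data: two-sided Fisher's exact test on the
    2x2 table.  Constant comparisons get p = 1 with a note.  Adjusted
    p-values are BH within the emitted family of pairwise tests.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for g1, g2 in combinations(labels, 2):
        x = values[groups == g1]
        y = values[groups == g2]
        if len(x) == 0 or len(y) == 0:
            raise ValueError("each group must be nonempty")
        note = ""
        if categorical:
            table = [
                [int(np.sum(x.astype(bool))), int(np.sum(~x.astype(bool)))],
                [int(np.sum(y.astype(bool))), int(np.sum(~y.astype(bool)))],
            ]
            stat, p = stats.fisher_exact(table, alternative="two-sided")
        else:
            x = x[~np.isnan(x.astype(float))]
            y = y[~np.isnan(y.astype(float))]
            pooled = np.concatenate([x, y])
            if len(np.unique(pooled)) <= 1:
                stat, p, note = np.nan, 1.0, "constant data"
            else:
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"group1": g1, "group2": g2, "statistic": stat, "p": p, "note": note})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def selection_gradient_experiment(
    baseline: MutationTable,
    annotation: RegionAnnotation,
    regions: CodingRegionSet,
    s_values=(0.0, 0.25, 0.5, 0.75, 1.0),
    mode: str = "combined",
    config: ScoringConfig | None = None,
    space: SubstitutionSpace | None = None,
) -> pd.DataFrame:
    """Score every method across a grid of selection strengths.

    The s = 0 baseline serves as the reference cohort for the OE
    methods at every s.  Returns the concatenated panels with an ``s``
    column.
    """
    from .simulate import apply_immune_selection

    config = config or ScoringConfig()
    if space is None:
        space = SubstitutionSpace(regions)
    rates = estimate_reference_rates(baseline, space=space)
    panels = []
    for s in s_values:
        cohort = apply_immune_selection(baseline, s=s, mode=mode)
        panel = score_all(
            cohort, baseline, annotation, regions, config=config, space=space, rates=rates
        )
        panel.insert(1, "s", s)
        panels.append(panel)
    return pd.concat(panels, ignore_index=True)


def gradient_wilcoxon(panel: pd.DataFrame, method: str, s_low: float, s_high: float) -> dict:
    """Two-sided Wilcoxon between two s groups of one method's scores."""
    col = f"{method}_score"
    x = panel.loc[(panel["s"] == s_low), col].dropna()
    y = panel.loc[(panel["s"] == s_high), col].dropna()
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return {
        "method": method,
        "s_low": s_low,
        "s_high": s_high,
        "median_low": float(x.median()),
        "median_high": float(y.median()),
        "p": float(res.pvalue),
        "n_low": len(x),
        "n_high": len(y),
    }
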