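"""Immune dN/dS: selection inside vs outside the immunopeptidome.

The immunopeptidome (ON region) is the set of CDS positions covered by
at least one strong-binder peptide window (%rank below 0.5 by default);
its complement is the OFF region.  Within each region

    dN/dS = (Nobs / Nsite) / (Sobs / Ssite)

with site counts corrected by the 192 mutation contexts: every possible
substitution at every region position contributes its context weight to
the nonsynonymous or synonymous site total.  The immune dN/dS is the
ON/OFF ratio; values below 1 indicate depletion of nonsynonymous
mutations in the immunopeptidome, i.e. immunoediting.

The permutation p-value is a reimplementation choice: each observed
mutation is reassigned ON/OFF with probability proportional to its
consequence's weighted site total in each region, the statistic is
recomputed, and one-sided fractions are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic import CONTEXT_192_INDEX
from .mutation_io import MutationTable
from .regions import CodingRegionSet, RegionAnnotation, SubstitutionSpace

PEPTIDE_LEN = 9


@dataclass
class DndsResult:
    sample: str
    n_obs_on: int
    s_obs_on: int
    n_obs_off: int
    s_obs_off: int
    n_site_on: float
    s_site_on: float
    n_site_off: float
    s_site_off: float
    dnds_on: float
    dnds_off: float
    immune_dnds: float
    p_value: float = np.nan
    p_high: float = np.nan
    assignable: bool = True
    reason: str = ""


def annotate_immunopeptidome(
    regions: CodingRegionSet,
    strong_binders: pd.DataFrame,
    rank_threshold: float = 0.5,
    annotation: RegionAnnotation | None = None,
) -> RegionAnnotation:
    """Mark ON positions from a per-peptide %rank table.

    ``strong_binders`` is long-form with columns ``transcript``,
    ``start_aa`` and ``rank`` (EL %rank of the 9-mer starting at that
    codon, best over alleles).  A CDS position is ON iff it lies in at
    least one window with rank strictly below the threshold; uncovered
    positions are OFF.  When an existing (binding) annotation is given,
    the ON flags are attached to a copy of it.
    """
    flags = {}
    for region in regions:
        n_aa = len(region) // 3
        on_aa = np.zeros(n_aa, dtype=bool)
        sub = strong_binders[strong_binders["transcript"] == region.transcript_id]
        hits = sub[sub["rank"] < rank_threshold]
        for start in hits["start_aa"].to_numpy(dtype=np.int64):
            on_aa[start : min(start + PEPTIDE_LEN, n_aa)] = True
        flags[region.transcript_id] = np.repeat(on_aa, 3)[: len(region)]
    if annotation is not None:
        return RegionAnnotation(
            affinity=annotation.affinity,
            binding=annotation.binding,
            immunopeptidome=flags,
            threshold_nm=annotation.threshold_nm,
        )
    affinity = {t: np.full(len(regions[t]), np.nan) for t in regions.regions}
    binding = {t: f.copy() for t, f in flags.items()}
    return RegionAnnotation(affinity=affinity, binding=binding, immunopeptidome=flags)


def context_weights(cohort: MutationTable | None = None) -> np.ndarray:
    """192-vector of context weights (cohort mutation spectrum or uniform)."""
    if cohort is None:
        return np.full(192, 1.0 / 192)
    idx = cohort.df["context"].map(CONTEXT_192_INDEX).dropna().astype(int)
    counts = np.bincount(idx, minlength=192).astype(float)
    if counts.sum() == 0:
        raise ValueError("cohort has no context-annotated mutations")
    return counts / counts.sum()


def weighted_site_counts(
    on_rows: np.ndarray, space: SubstitutionSpace, weights: np.ndarray
) -> tuple[float, float]:
    """Context-weighted (Nsite, Ssite) over the rows marked by ``on_rows``.

    Each enumerated substitution in the position set contributes its
    context weight to the nonsynonymous or synonymous total.  Weights
    are renormalized to sum to 1 if they do not.
    """
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("context weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("context weights sum to zero")
    if not np.isclose(total, 1.0):
        weights = weights / total
    w = weights[space.ctx192[on_rows]]
    syn = space.is_syn[on_rows]
    return float(w[~syn].sum()), float(w[syn].sum())


def _ratio(num, den):
    return num / den if den > 0 else np.nan


def immune_dnds_score(
    sample_df: pd.DataFrame,
    annotation: RegionAnnotation,
    space: SubstitutionSpace,
    weights: np.ndarray,
    n_perm: int = 0,
    seed: int = 0,
) -> DndsResult:
    """Immune dN/dS for one sample with optional permutation p.

    Assignable only when each region has at least one synonymous
    mutation and positive weighted site counts; otherwise the failing
    count is named in ``reason``.
    """
    sample = str(sample_df["sample"].iloc[0]) if len(sample_df) else ""
    on_rows = space.position_flags(annotation, "immunopeptidome")
    n_site_on, s_site_on = weighted_site_counts(on_rows, space, weights)
    n_site_off, s_site_off = weighted_site_counts(~on_rows, space, weights)

    coding = sample_df[sample_df["consequence"].isin(["synonymous", "nonsynonymous"])]
    on = annotation.lookup("immunopeptidome", coding["transcript"], coding["cds_pos"])
    syn = np.asarray(coding["consequence"] == "synonymous")
    n_on, s_on = int((on & ~syn).sum()), int((on & syn).sum())
    n_off, s_off = int((~on & ~syn).sum()), int((~on & syn).sum())

    reason = ""
    if s_on < 1:
        reason = "no synonymous mutations in immunopeptidome"
    elif s_off < 1:
        reason = "no synonymous mutations outside immunopeptidome"
    elif min(n_site_on, s_site_on) <= 0:
        reason = "zero weighted sites in immunopeptidome"
    elif min(n_site_off, s_site_off) <= 0:
        reason = "zero weighted sites outside immunopeptidome"
    dnds_on = _ratio(_ratio(n_on, n_site_on), _ratio(s_on, s_site_on))
    dnds_off = _ratio(_ratio(n_off, n_site_off), _ratio(s_off, s_site_off))
    immune = dnds_on / dnds_off if not reason and dnds_off > 0 else np.nan
    result = DndsResult(
        sample=sample,
        n_obs_on=n_on,
        s_obs_on=s_on,
        n_obs_off=n_off,
        s_obs_off=s_off,
        n_site_on=n_site_on,
        s_site_on=s_site_on,
        n_site_off=n_site_off,
        s_site_off=s_site_off,
        dnds_on=dnds_on,
        dnds_off=dnds_off,
        immune_dnds=immune,
        assignable=not reason and not np.isnan(immune),
        reason=reason,
    )
    if n_perm > 0 and result.assignable:
        result.p_value, result.p_high = dnds_permutation_p(result, n_perm, seed)
    return result


def dnds_permutation_p(result: DndsResult, n_perm: int = 1000, seed: int = 0):
    """One-sided permutation fractions for an immune dN/dS result.

    Mutations are reassigned to ON/OFF with consequence-specific
    probabilities given by the weighted site fractions, so the null
    matches context-driven neutral placement.  Returns
    ``(p_low, p_high)``: fractions of permuted statistics <= and >= the
    real one (ties count toward both); ``p_low`` is the one-sided
    p-value in the editing direction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n_tot = result.n_obs_on + result.n_obs_off
    s_tot = result.s_obs_on + result.s_obs_off
    p_n = result.n_site_on / (result.n_site_on + result.n_site_off)
    p_s = result.s_site_on / (result.s_site_on + result.s_site_off)
    n_on = rng.binomial(n_tot, p_n, size=n_perm)
    s_on = rng.binomial(s_tot, p_s, size=n_perm)
    with np.errstate(invalid="ignore", divide="ignore"):
        dnds_on = (n_on / result.n_site_on) / (s_on / result.s_site_on)
        dnds_off = ((n_tot - n_on) / result.n_site_off) / (
            (s_tot - s_on) / result.s_site_off
        )
        stat = dnds_on / dnds_off
    ok = np.isfinite(stat)
    if not ok.any():
        return np.nan, np.nan
    p_low = float(np.sum(stat[ok] <= result.immune_dnds) / ok.sum())
    p_high = float(np.sum(stat[ok] >= result.immune_dnds) / ok.sum())
    return p_low, p_high


def score_dnds_cohort(
    cohort: MutationTable,
    annotation: RegionAnnotation,
    space: SubstitutionSpace,
    weights_source: str = "cohort",
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample immune dN/dS for a cohort.

    ``weights_source`` selects the 192-context weights: the cohort's
    observed mutation spectrum (default), each sample's own spectrum, or
    uniform.
    """
    if weights_source == "cohort":
        shared = context_weights(cohort)
    elif weights_source == "uniform":
        shared = context_weights(None)
    elif weights_source != "sample":
        raise ValueError("weights_source must be cohort, sample or uniform")
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(cohort.df["sample"].nunique())
    for child, s in zip(child_seeds, cohort.samples()):
        df = cohort.df[cohort.df["sample"] == s]
        if weights_source == "sample":
            shared = context_weights(MutationTable(df.copy()))
        rows.append(
            immune_dnds_score(df, annotation, space, shared, n_perm=n_perm, seed=int(child))
        )
    return pd.DataFrame([r.__dict__ for r in rows])
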