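"""HLA-binding mutation ratio (HBMR).

Coding positions are split into HLA-binding and non-binding regions by
an aggregated per-position binding affinity (harmonic mean across
alleles of each allele's lowest affinity over the peptide windows
covering the position; binding iff aggregated affinity < 500 nM).  The
observed HBMR is the ratio of nonsynonymous/synonymous ratios in
binding vs non-binding regions; it is normalized by an expected HBMR
computed from the exhaustive set of possible substitutions weighted by
the 96 substitution-class probabilities P_t:

    HBMR = HBMRobs / HBMRexp,   HBMR < 1 indicating immunoediting.

The permutation null shuffles binding flags over CDS positions while
preserving the number of binding positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mutation_io import MutationTable
from .regions import CodingRegionSet, RegionAnnotation, SubstitutionSpace

PEPTIDE_LEN = 9  # amino acids per peptide window


@dataclass
class HbmrResult:
    sample: str
    n_binding: int
    s_binding: int
    n_nonbinding: int
    s_nonbinding: int
    hbmr_obs: float
    hbmr_exp: float
    hbmr: float
    p_value: float = np.nan
    assignable: bool = True
    reason: str = ""


def aggregate_affinities(
    peptide_affinities: pd.DataFrame, cds_length: int
) -> np.ndarray:
    """Per-CDS-position aggregated affinity from per-allele peptide scores.

    ``peptide_affinities`` is long-form with columns ``start_aa`` (0-based
    index of the peptide's first codon), ``allele`` and ``affinity_nm``.
    For each allele the minimum affinity over the <= 9 peptide windows
    covering a position's codon is taken; positions are then aggregated
    by the harmonic mean across alleles.  Positions covered by no window
    get NaN.
    """
    n_aa = cds_length // 3
    alleles = pd.unique(peptide_affinities["allele"])
    minima = np.full((len(alleles), n_aa), np.inf)
    for ai, allele in enumerate(alleles):
        sub = peptide_affinities[peptide_affinities["allele"] == allele]
        for start, aff in zip(sub["start_aa"].to_numpy(), sub["affinity_nm"].to_numpy()):
            start = int(start)
            stop = min(start + PEPTIDE_LEN, n_aa)
            np.minimum.at(minima[ai], np.arange(start, stop), aff)
    covered = np.isfinite(minima).all(axis=0)
    with np.errstate(divide="ignore"):
        harmonic = len(alleles) / np.sum(1.0 / minima, axis=0)
    per_aa = np.where(covered, harmonic, np.nan)
    return np.repeat(per_aa, 3)[:cds_length]


def annotate_binding_regions(
    regions: CodingRegionSet,
    peptide_affinities: pd.DataFrame,
    threshold_nm: float = 500.0,
) -> RegionAnnotation:
    """Build a :class:`RegionAnnotation` from per-peptide affinities.

    ``peptide_affinities`` needs a ``transcript`` column on top of the
    long-form columns of :func:`aggregate_affinities`.  Binding is
    strict: aggregated affinity exactly at the threshold is non-binding.
    """
    affinity, binding = {}, {}
    for region in regions:
        sub = peptide_affinities[peptide_affinities["transcript"] == region.transcript_id]
        agg = aggregate_affinities(sub, len(region))
        affinity[region.transcript_id] = agg
        with np.errstate(invalid="ignore"):
            binding[region.transcript_id] = np.nan_to_num(agg, nan=np.inf) < threshold_nm
    return RegionAnnotation(affinity=affinity, binding=binding, threshold_nm=threshold_nm)


def substitution_class_probs(
    space: SubstitutionSpace, cohort: MutationTable | None = None
) -> np.ndarray:
    """96-vector of substitution-class probabilities P_t.

    By default P_t is the frequency of each pyrimidine-collapsed class
    among all possible substitutions of the region set (sums to 1).
    Passing a cohort estimates P_t from its observed mutations instead.
    """
    if cohort is None:
        counts = np.bincount(space.ctx96, minlength=96).astype(float)
    else:
        from .genetic import CONTEXT_96_INDEX

        idx = cohort.df["context96"].map(CONTEXT_96_INDEX).dropna().astype(int)
        counts = np.bincount(idx, minlength=96).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no substitutions to estimate class probabilities from")
    return counts / total


def expected_class_counts(space: SubstitutionSpace, binding_rows: np.ndarray):
    """Per-class counts of possible substitutions, split four ways.

    ``binding_rows`` is a boolean per enumerated substitution (the
    binding flag of its position).  Returns ``(Nb, Sb, Nn, Sn)`` each a
    96-vector.
    """
    nonsyn = ~space.is_syn
    out = []
    for region_mask in (binding_rows, ~binding_rows):
        for cons_mask in (nonsyn, space.is_syn):
            out.append(np.bincount(space.ctx96[region_mask & cons_mask], minlength=96))
    return tuple(out)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def hbmr_expected(space: SubstitutionSpace, binding_rows: np.ndarray, pt: np.ndarray) -> float:
    nb, sb, nn, sn = expected_class_counts(space, binding_rows)
    return _ratio(_ratio(nb @ pt, sb @ pt), _ratio(nn @ pt, sn @ pt))


def hbmr_score(
    sample_df: pd.DataFrame,
    annotation: RegionAnnotation,
    space: SubstitutionSpace,
    pt: np.ndarray,
) -> HbmrResult:
    """Normalized HBMR for one sample's mutation slice."""
    sample = str(sample_df["sample"].iloc[0]) if len(sample_df) else ""
    coding = sample_df[sample_df["consequence"].isin(["synonymous", "nonsynonymous"])]
    binding = annotation.lookup("binding", coding["transcript"], coding["cds_pos"])
    syn = np.asarray(coding["consequence"] == "synonymous")
    n_b = int((binding & ~syn).sum())
    s_b = int((binding & syn).sum())
    n_n = int((~binding & ~syn).sum())
    s_n = int((~binding & syn).sum())
    hbmr_obs = _ratio(_ratio(n_b, s_b), _ratio(n_n, s_n))
    binding_rows = space.position_flags(annotation, "binding")
    hbmr_exp = hbmr_expected(space, binding_rows, pt)
    failing = ""
    if s_b < 1:
        failing = "no synonymous mutations in binding regions"
    elif s_n < 1:
        failing = "no synonymous mutations in non-binding regions"
    elif n_n < 1:
        failing = "no nonsynonymous mutations in non-binding regions"
    elif not hbmr_exp > 0:
        failing = "expected HBMR undefined"
    score = hbmr_obs / hbmr_exp if not failing else np.nan
    return HbmrResult(
        sample=sample,
        n_binding=n_b,
        s_binding=s_b,
        n_nonbinding=n_n,
        s_nonbinding=s_n,
        hbmr_obs=hbmr_obs if not failing else np.nan,
        hbmr_exp=hbmr_exp,
        hbmr=score,
        assignable=not failing,
        reason=failing,
    )


def hbmr_permutation_p(
    sample_df: pd.DataFrame,
    annotation: RegionAnnotation,
    space: SubstitutionSpace,
    pt: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for one sample's normalized HBMR.

    Binding flags are shuffled over CDS positions (counts preserved);
    observed and expected HBMR are both recomputed under each permuted
    annotation.  p is the fraction of permuted normalized HBMR strictly
    below the real one; NaN when the real score or every permutation is
    unassignable.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    real = hbmr_score(sample_df, annotation, space, pt)
    if not real.assignable:
        return np.nan
    rng = np.random.default_rng(seed)

    # stack per-position structures once: positions here are the rows of the
    # (transcript-concatenated) flag vectors
    pos_flags = []
    offsets = {}
    off = 0
    for tid in space.transcript_ids:
        flags = annotation.binding[tid]
        offsets[tid] = off
        pos_flags.append(flags)
        off += len(flags)
    flags0 = np.concatenate(pos_flags)
    n_pos = len(flags0)

    # enumerated substitutions: class count matrices per position
    sub_pos = np.empty(space.n, dtype=np.int64)
    for ti, tid in enumerate(space.transcript_ids):
        m = space.transcript_idx == ti
        sub_pos[m] = space.pos[m] + offsets[tid]
    n_mat = np.zeros((n_pos, 96), dtype=np.float32)
    s_mat = np.zeros((n_pos, 96), dtype=np.float32)
    np.add.at(n_mat, (sub_pos[~space.is_syn], space.ctx96[~space.is_syn]), 1.0)
    np.add.at(s_mat, (sub_pos[space.is_syn], space.ctx96[space.is_syn]), 1.0)

    # observed mutations: flattened position index and consequence
    coding = sample_df[sample_df["consequence"].isin(["synonymous", "nonsynonymous"])]
    mut_pos = coding["cds_pos"].to_numpy(dtype=np.int64) + np.array(
        [offsets[t] for t in coding["transcript"]], dtype=np.int64
    )
    mut_syn = np.asarray(coding["consequence"] == "synonymous")

    perm_flags = rng.permuted(
        np.broadcast_to(flags0, (n_perm, n_pos)).copy(), axis=1
    ).astype(np.float32)
    # expected side: class counts in permuted binding set
    nb_t = perm_flags @ n_mat
    sb_t = perm_flags @ s_mat
    nn_t = n_mat.sum(axis=0) - nb_t
    sn_t = s_mat.sum(axis=0) - sb_t
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = ((nb_t @ pt) / (sb_t @ pt)) / ((nn_t @ pt) / (sn_t @ pt))
        # observed side
        fb = perm_flags[:, mut_pos].astype(bool)
        n_b = (fb & ~mut_syn).sum(axis=1)
        s_b = (fb & mut_syn).sum(axis=1)
        n_n = (~fb & ~mut_syn).sum(axis=1)
        s_n = (~fb & mut_syn).sum(axis=1)
        obs = (n_b / s_b) / (n_n / s_n)
        norm = obs / exp
    ok = (s_b >= 1) & (s_n >= 1) & (n_n >= 1) & np.isfinite(norm)
    if not ok.any():
        return np.nan
    return float(np.sum(norm[ok] < real.hbmr) / ok.sum())


def score_hbmr_cohort(
    cohort: MutationTable,
    annotation: RegionAnnotation,
    space: SubstitutionSpace,
    pt: np.ndarray | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample normalized HBMR (optionally with permutation p)."""
    if pt is None:
        pt = substitution_class_probs(space)
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(cohort.df["sample"].nunique())
    for child, s in zip(child_seeds, cohort.samples()):
        df = cohort.df[cohort.df["sample"] == s]
        res = hbmr_score(df, annotation, space, pt)
        if n_perm > 0 and res.assignable:
            res.p_value = hbmr_permutation_p(df, annotation, space, pt, n_perm, int(child))
        rows.append(res)
    return pd.DataFrame([r.__dict__ for r in rows])
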