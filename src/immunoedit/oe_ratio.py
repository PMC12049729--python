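"""Observed/expected neoantigen ratios (reference-sample and codon methods).

Both scores compare the observed rate of neoantigens per nonsynonymous
mutation in a sample against a neutral expectation built from a
reference cohort assumed free of immune selection:

* reference-sample method: per-context rates N̄_s (nonsynonymous per
  synonymous) and B̄_s (neoantigens per nonsynonymous) are estimated
  from the reference; the sample's synonymous mutations then predict
  Npred = Σ_s N̄_s·S_s and Bpred = Σ_s B̄_s·N̄_s·S_s.
* codon method: Npred = Σ_s (1−P̄_s)·C_s, where P̄_s is the probability
  that a substitution with context s is synonymous (enumerated over the
  coding-region set), and Bpred = B̄_coding · |C| ignores context.

score = (Bobs/Nobs) / (Bpred/Npred); values below 1 indicate depletion
of neoantigens, i.e. immunoediting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic import CONTEXT_192_INDEX
from .mutation_io import MutationTable
from .regions import CodingRegionSet, SubstitutionSpace


@dataclass
class ReferenceRates:
    """Per-context neutral rates estimated from a reference cohort.

    ``nbar``/``bbar``/``psyn`` are 192-vectors (NaN where the context's
    denominator is zero: undefined, not zero); ``b_coding`` is the
    scalar expected number of neoantigens per coding mutation.
    """

    nbar: np.ndarray
    bbar: np.ndarray
    psyn: np.ndarray
    b_coding: float
    n_samples: int = 0
    n_mutations: int = 0

    def __post_init__(self):
        for name in ("nbar", "bbar", "psyn"):
            v = getattr(self, name)
            if v.shape != (192,):
                raise ValueError(f"{name} must be a 192-vector")
            if np.nanmin(v, initial=0.0) < 0:
                raise ValueError(f"{name} has negative entries")
        if not (np.isnan(self.b_coding) or 0 <= self.b_coding <= 1):
            raise ValueError("b_coding must lie in [0, 1]")


@dataclass
class OEResult:
    sample: str
    method: str
    n_obs: int
    s_obs: int
    b_obs: int
    n_pred: float
    b_pred: float
    score: float
    p_value: float = np.nan
    assignable: bool = True
    reason: str = ""
    dropped_contexts: int = 0


def _context_indices(context: pd.Series) -> np.ndarray:
    idx = context.map(CONTEXT_192_INDEX)
    out = np.full(len(context), -1, dtype=np.int64)
    ok = idx.notna()
    out[np.asarray(ok)] = idx[ok].astype(np.int64)
    return out


def _counts_by_context(df: pd.DataFrame) -> dict[str, np.ndarray]:
    ctx = _context_indices(df["context"])
    coding = np.asarray(df["consequence"].isin(["synonymous", "nonsynonymous"])) & (ctx >= 0)
    syn = coding & np.asarray(df["consequence"] == "synonymous")
    nonsyn = coding & np.asarray(df["consequence"] == "nonsynonymous")
    neo = nonsyn & np.asarray(df["is_neoantigen"].eq(True))
    return {
        "coding": np.bincount(ctx[coding], minlength=192).astype(float),
        "syn": np.bincount(ctx[syn], minlength=192).astype(float),
        "nonsyn": np.bincount(ctx[nonsyn], minlength=192).astype(float),
        "neo": np.bincount(ctx[neo], minlength=192).astype(float),
    }


def estimate_reference_rates(
    reference: MutationTable,
    regions: CodingRegionSet | None = None,
    space: SubstitutionSpace | None = None,
    pseudocount: float = 0.0,
) -> ReferenceRates:
    """Estimate N̄_s, B̄_s, P̄_s and B̄_coding from a reference cohort.

    N̄_s and B̄_s are per-context count ratios over the cohort; contexts
    with a zero denominator are NaN (flagged undefined).  With
    ``pseudocount`` > 0 every numerator and denominator cell gets that
    additive offset instead.  P̄_s comes from exhaustive substitution
    enumeration over the region set, not from the cohort.
    """
    c = _counts_by_context(reference.df)
    eps = pseudocount
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = np.where(c["syn"] + eps > 0, (c["nonsyn"] + eps) / (c["syn"] + eps), np.nan)
        bbar = np.where(c["nonsyn"] + eps > 0, (c["neo"] + eps) / (c["nonsyn"] + eps), np.nan)
    total_coding = c["coding"].sum()
    b_coding = c["neo"].sum() / total_coding if total_coding > 0 else np.nan
    if space is None:
        if regions is None:
            raise ValueError("either regions or a prebuilt SubstitutionSpace is required")
        space = SubstitutionSpace(regions)
    return ReferenceRates(
        nbar=nbar,
        bbar=bbar,
        psyn=space.synonymous_probability(),
        b_coding=float(b_coding),
        n_samples=reference.df["sample"].nunique(),
        n_mutations=len(reference.df),
    )


def _score_from_context_counts(
    counts: dict[str, np.ndarray], rates: ReferenceRates, method: str
) -> tuple[float, float, float, int]:
    """(n_pred, b_pred, score, dropped_contexts) from per-context counts."""
    n_obs = counts["nonsyn"].sum()
    s_obs = counts["syn"].sum()
    b_obs = counts["neo"].sum()
    if method == "refSample":
        usable = ~np.isnan(rates.nbar) & ~np.isnan(rates.bbar)
        present = counts["syn"] > 0
        dropped = int(np.sum(counts["syn"][present & ~usable]))
        s = counts["syn"] * usable
        n_pred = float(np.nansum(rates.nbar * s))
        b_pred = float(np.nansum(rates.bbar * rates.nbar * s))
    elif method == "codon":
        usable = ~np.isnan(rates.psyn)
        present = counts["coding"] > 0
        dropped = int(np.sum(counts["coding"][present & ~usable]))
        cs = counts["coding"] * usable
        n_pred = float(np.nansum((1.0 - rates.psyn) * cs))
        b_pred = float(rates.b_coding * counts["coding"].sum())
    else:
        raise ValueError(f"unknown OE method {method!r}")
    if n_obs < 1 or s_obs < 1 or n_pred <= 0 or b_pred <= 0:
        return n_pred, b_pred, np.nan, dropped
    score = (b_obs / n_obs) / (b_pred / n_pred)
    return n_pred, b_pred, float(score), dropped


def oe_ratio_sample(
    sample_df: pd.DataFrame, rates: ReferenceRates, method: str = "refSample"
) -> OEResult:
    """Score one sample's mutation slice against reference rates.

    ``method`` is ``"refSample"`` or ``"codon"``.  Unassignable samples
    (no synonymous or nonsynonymous mutations, or vanished denominators)
    come back with ``assignable=False`` and a reason.
    """
    counts = _counts_by_context(sample_df)
    n_obs = int(counts["nonsyn"].sum())
    s_obs = int(counts["syn"].sum())
    b_obs = int(counts["neo"].sum())
    n_pred, b_pred, score, dropped = _score_from_context_counts(counts, rates, method)
    sample = str(sample_df["sample"].iloc[0]) if len(sample_df) else ""
    reason = ""
    if np.isnan(score):
        if n_obs < 1:
            reason = "no nonsynonymous mutations"
        elif s_obs < 1:
            reason = "no synonymous mutations"
        elif n_pred <= 0:
            reason = "Npred is zero (undefined contexts dropped)"
        else:
            reason = "Bpred is zero"
    return OEResult(
        sample=sample,
        method=method,
        n_obs=n_obs,
        s_obs=s_obs,
        b_obs=b_obs,
        n_pred=n_pred,
        b_pred=b_pred,
        score=score,
        assignable=not np.isnan(score),
        reason=reason,
        dropped_contexts=dropped,
    )


def score_oe_cohort(
    cohort: MutationTable, rates: ReferenceRates, method: str = "refSample"
) -> pd.DataFrame:
    """Per-sample OE scores for a whole cohort (one row per sample)."""
    rows = [
        oe_ratio_sample(cohort.df[cohort.df["sample"] == s], rates, method)
        for s in cohort.samples()
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def _per_mutation_weights(df: pd.DataFrame, rates: ReferenceRates, method: str):
    """Per-mutation contributions to (Nobs, Sobs, Bobs, Npred, Bpred)."""
    ctx = _context_indices(df["context"])
    coding = np.asarray(df["consequence"].isin(["synonymous", "nonsynonymous"])) & (ctx >= 0)
    syn = coding & np.asarray(df["consequence"] == "synonymous")
    nonsyn = coding & np.asarray(df["consequence"] == "nonsynonymous")
    neo = nonsyn & np.asarray(df["is_neoantigen"].eq(True))
    safe_ctx = np.where(ctx >= 0, ctx, 0)
    if method == "refSample":
        nbar = np.nan_to_num(rates.nbar[safe_ctx], nan=0.0)
        bbar = np.nan_to_num(rates.bbar[safe_ctx], nan=0.0)
        usable = ~np.isnan(rates.nbar[safe_ctx]) & ~np.isnan(rates.bbar[safe_ctx])
        w_npred = np.where(syn & usable, nbar, 0.0)
        w_bpred = np.where(syn & usable, bbar * nbar, 0.0)
    elif method == "codon":
        psyn = rates.psyn[safe_ctx]
        usable = ~np.isnan(psyn)
        w_npred = np.where(coding & usable, 1.0 - np.nan_to_num(psyn), 0.0)
        w_bpred = np.where(coding, rates.b_coding, 0.0)
    else:
        raise ValueError(f"unknown OE method {method!r}")
    return nonsyn.astype(float), syn.astype(float), neo.astype(float), w_npred, w_bpred


def oe_permutation_p(
    cohort: MutationTable,
    rates: ReferenceRates,
    method: str = "refSample",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort-level permutation p-values for the OE scores.

    Each permutation reassigns all mutation records across samples
    uniformly at random while preserving every sample's mutation count,
    then rescores.  For each sample, p is the fraction of its permuted
    scores strictly below its real score (ties count as not below);
    permutations where the sample is unassignable are skipped and the
    effective denominator reported.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if cohort.df["sample"].nunique() < 2:
        raise ValueError("permutation null needs at least 2 samples")
    rng = np.random.default_rng(seed)
    df = cohort.df
    samples = pd.unique(df["sample"])
    sample_idx = pd.Series(np.arange(len(samples)), index=samples)
    labels = df["sample"].map(sample_idx).to_numpy()
    n_samp = len(samples)
    wN, wS, wB, wNp, wBp = _per_mutation_weights(df, rates, method)

    def scores_for(lab: np.ndarray) -> np.ndarray:
        n_obs = np.bincount(lab, weights=wN, minlength=n_samp)
        s_obs = np.bincount(lab, weights=wS, minlength=n_samp)
        b_obs = np.bincount(lab, weights=wB, minlength=n_samp)
        n_pred = np.bincount(lab, weights=wNp, minlength=n_samp)
        b_pred = np.bincount(lab, weights=wBp, minlength=n_samp)
        ok = (n_obs >= 1) & (s_obs >= 1) & (n_pred > 0) & (b_pred > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sc = (b_obs / n_obs) / (b_pred / n_pred)
        return np.where(ok, sc, np.nan)

    real = scores_for(labels)
    below = np.zeros(n_samp)
    valid = np.zeros(n_samp)
    for _ in range(n_perm):
        perm = scores_for(rng.permutation(labels))
        ok = ~np.isnan(perm) & ~np.isnan(real)
        below[ok] += perm[ok] < real[ok]
        valid += ~np.isnan(perm)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid > 0, below / valid, np.nan)
    p = np.where(np.isnan(real), np.nan, p)
    return pd.DataFrame(
        {"sample": samples, "score": real, "p_value": p, "n_perm_effective": valid.astype(int)}
    )
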