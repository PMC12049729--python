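"""Somatic-mutation simulation under graded immune selection.

The simulator draws coding SNVs from a 192-context spectrum onto a
synthetic coding-region set with per-position aggregated HLA binding
affinities, assigns CCFs from a clonal/subclonal mixture, and then
applies immune selection of strength s in [0, 1]: each neoantigen's CCF
is depressed by its normalized immunogenicity a = (500 − affinity)/499,

    CCF_s = CCF − s·a,

and neoantigens falling below a detectability threshold (CCF_s < 0.2)
are removed.  Three modes dissociate the two effects: ``combined``
(depress and remove), ``remove_only`` (remove, survivors revert to the
original CCF) and ``ccf_only`` (depress, keep everything).  The s = 0
baseline doubles as the selection-free reference cohort for the
OE-ratio methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genetic import BASES, CONTEXT_192_INDEX, CONTEXTS_96, CONTEXTS_192
from .mutation_io import MutationTable
from .regions import CodingRegion, CodingRegionSet, RegionAnnotation, SubstitutionSpace

AFFINITY_BINDER_THRESHOLD = 500.0  # nM
BINDER_RUN_NT = 27  # one 9-mer peptide window of CDS


@dataclass
class ContextSpectrum:
    """Probability of each of the 192 mutation contexts."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (192,):
            raise ValueError("spectrum must be a 192-vector")
        if (self.probs < 0).any():
            raise ValueError("spectrum probabilities must be nonnegative")
        total = self.probs.sum()
        if total <= 0:
            raise ValueError("spectrum sums to zero")
        self.probs = self.probs / total


@dataclass
class SelectionConfig:
    """Simulator parameters.

    Defaults follow the study conditions: 500 samples of 1,000 mutations
    each, detectability threshold 0.2, and a CCF mixture of 60% clonal
    mass (truncated normal near 1) with a Beta-shaped subclonal tail
    (mode ~0.35).
    """

    n_samples: int = 500
    n_mutations: int = 1000
    s: float = 0.0
    mode: str = "combined"
    detect_threshold: float = 0.2
    clonal_mass: float = 0.6
    clonal_sd: float = 0.08
    subclonal_alpha: float = 2.0
    subclonal_beta: float = 2.857
    binder_fraction: float = 0.3
    cds_length: int = 30000
    affinity_min_nm: float = 1.0
    affinity_max_nm: float = 50000.0
    ccf_floor: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.s <= 1:
            raise ValueError("selection strength s must lie in [0, 1]")
        if not 0 < self.detect_threshold < 1:
            raise ValueError("detectability threshold must lie in (0, 1)")
        if self.n_samples < 1 or self.n_mutations < 1:
            raise ValueError("cohort dimensions must be >= 1")
        if self.mode not in ("combined", "remove_only", "ccf_only"):
            raise ValueError(f"unknown selection mode {self.mode!r}")


def normalized_immunogenicity(affinity_nm) -> np.ndarray:
    """a = (500 − affinity)/(500 − 1) for binder affinities, else 0.

    Maps affinity 1 nM to a = 1 and affinity approaching 500 nM to
    a -> 0; positions at or above 500 nM are never neoantigens.
    """
    aff = np.asarray(affinity_nm, dtype=float)
    a = (AFFINITY_BINDER_THRESHOLD - aff) / (AFFINITY_BINDER_THRESHOLD - 1.0)
    return np.clip(np.where(aff < AFFINITY_BINDER_THRESHOLD, a, 0.0), 0.0, 1.0)


def estimate_context_probs(cohort: MutationTable) -> ContextSpectrum:
    """Empirical 192-context spectrum of an annotated cohort."""
    if len(cohort) == 0:
        raise ValueError("cannot estimate a spectrum from an empty cohort")
    idx = cohort.df["context"].map(CONTEXT_192_INDEX).dropna().astype(int)
    if len(idx) == 0:
        raise ValueError("cohort has no context annotations")
    return ContextSpectrum(np.bincount(idx, minlength=192).astype(float))


def default_spectrum() -> ContextSpectrum:
    """A transition-dominated stand-in for a pan-cancer mutation spectrum.

    C>T/G>A transitions dominate (as in most epithelial tumours), with
    flanking bases uniform within each substitution type.
    """
    sub_weight = {
        ("C", "T"): 0.21, ("G", "A"): 0.21,
        ("C", "A"): 0.06, ("G", "T"): 0.06,
        ("C", "G"): 0.03, ("G", "C"): 0.03,
        ("T", "C"): 0.08, ("A", "G"): 0.08,
        ("T", "A"): 0.03, ("A", "T"): 0.03,
        ("T", "G"): 0.04, ("A", "C"): 0.04,
    }
    probs = np.empty(192)
    for i, ctx in enumerate(CONTEXTS_192):
        probs[i] = sub_weight[(ctx[2], ctx[4])] / 16.0
    return ContextSpectrum(probs)


def build_synthetic_coding_set(
    total_length: int = 30000,
    binder_fraction: float = 0.3,
    affinity_min_nm: float = 1.0,
    affinity_max_nm: float = 50000.0,
    seed: int = 0,
    transcript_id: str = "SYN1",
) -> tuple[CodingRegionSet, RegionAnnotation]:
    """Random in-frame CDS with synthetic per-position binding affinities.

    The sequence is drawn codon by codon with internal stop codons
    rejected.  Binder positions are laid down in contiguous 27-nt runs
    (one 9-mer peptide window each) until the requested fraction of
    positions is reached; binder positions get aggregated affinities
    log-uniform on [1, 500) nM, the rest log-uniform on [500, max) nM.
    The immunopeptidome flag of the returned annotation coincides with
    the binding flag: the synthetic strong-binder windows stand in for
    both region definitions.
    """
    if total_length % 3 != 0 or total_length < 9:
        raise ValueError("total_length must be a positive multiple of 3 (>= 9)")
    if not 0 <= binder_fraction < 1:
        raise ValueError("binder fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_codons = total_length // 3
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(BASES), size=3))
        if c not in stops:
            codons.append(c)
    cds = "".join(codons)
    region = CodingRegion(transcript_id, "chrS", "+", ((0, total_length),), cds)
    regions = CodingRegionSet([region])

    target = int(round(binder_fraction * total_length))
    flags = np.zeros(total_length, dtype=bool)
    guard = 0
    while flags.sum() < target:
        start = int(rng.integers(0, max(1, total_length - BINDER_RUN_NT)))
        flags[start : start + BINDER_RUN_NT] = True
        guard += 1
        if guard > 100 * max(1, target):
            raise RuntimeError("could not realize the requested binder fraction")
    affinity = np.empty(total_length)
    n_bind = int(flags.sum())
    affinity[flags] = np.exp(
        rng.uniform(np.log(affinity_min_nm), np.log(AFFINITY_BINDER_THRESHOLD), n_bind)
    )
    affinity[~flags] = np.exp(
        rng.uniform(
            np.log(AFFINITY_BINDER_THRESHOLD), np.log(affinity_max_nm), total_length - n_bind
        )
    )
    annotation = RegionAnnotation(
        affinity={transcript_id: affinity},
        binding={transcript_id: flags},
        immunopeptidome={transcript_id: flags.copy()},
    )
    return regions, annotation


def draw_ccf(rng: np.random.Generator, n: int, config: SelectionConfig) -> np.ndarray:
    """CCFs from the clonal/subclonal mixture, conditioned on detectability.

    Observed baseline mutations must be detectable, so draws below the
    detectability threshold are rejected and redrawn; the support is
    [threshold, 1].
    """
    clonal = rng.random(n) < config.clonal_mass
    ccf = np.empty(n)
    n_clonal = int(clonal.sum())
    # truncated normal around 1 for the clonal peak, support (threshold, 1]
    a = (config.detect_threshold - 1.0) / config.clonal_sd
    ccf[clonal] = stats.truncnorm.rvs(
        a, 0.0, loc=1.0, scale=config.clonal_sd, size=n_clonal, random_state=rng
    )
    sub = rng.beta(config.subclonal_alpha, config.subclonal_beta, n - n_clonal)
    for _ in range(1000):
        low = sub < config.detect_threshold
        if not low.any():
            break
        sub[low] = rng.beta(config.subclonal_alpha, config.subclonal_beta, int(low.sum()))
    ccf[~clonal] = sub
    return np.clip(ccf, config.detect_threshold, 1.0)


def simulate_baseline_cohort(
    config: SelectionConfig,
    spectrum: ContextSpectrum,
    regions: CodingRegionSet,
    annotation: RegionAnnotation,
    space: SubstitutionSpace | None = None,
) -> MutationTable:
    """Selection-free (s = 0) cohort of coding SNVs.

    Each mutation is drawn by sampling a context from the spectrum,
    placing it uniformly on a CDS site matching that trinucleotide,
    translating for the consequence, flagging it as a neoantigen iff the
    position's aggregated affinity is below 500 nM and the change is
    nonsynonymous, and drawing a CCF from the mixture model.  Within a
    sample, duplicate (position, alt) draws are rejected and resampled.
    """
    rng = np.random.default_rng(config.seed)
    if space is None:
        space = SubstitutionSpace(regions)
    present = np.bincount(space.ctx192, minlength=192) > 0
    missing = spectrum.probs[~present].sum()
    if missing > 0:
        usable = spectrum.probs * present
        if usable.sum() == 0:
            raise ValueError("no spectrum context has a matching CDS site")
        probs = usable / usable.sum()
    else:
        probs = spectrum.probs
    # rows of the substitution space grouped by context
    order = np.argsort(space.ctx192, kind="stable")
    sorted_ctx = space.ctx192[order]
    ctx_start = np.searchsorted(sorted_ctx, np.arange(193))

    affinity_rows = np.empty(space.n)
    for ti, tid in enumerate(space.transcript_ids):
        m = space.transcript_idx == ti
        affinity_rows[m] = annotation.affinity[tid][space.pos[m]]

    frames = []
    for i in range(config.n_samples):
        need = config.n_mutations
        chosen: list[np.ndarray] = []
        seen: set[int] = set()
        guard = 0
        while need > 0:
            ctx_draw = rng.choice(192, size=need, p=probs)
            counts = np.bincount(ctx_draw, minlength=192)
            rows = []
            for c in np.nonzero(counts)[0]:
                lo, hi = ctx_start[c], ctx_start[c + 1]
                rows.append(order[lo + rng.integers(0, hi - lo, size=counts[c])])
            rows = np.concatenate(rows)
            fresh = [r for r in rows if r not in seen]
            # duplicates within this batch are also dropped
            fresh = list(dict.fromkeys(fresh))
            seen.update(fresh)
            chosen.append(np.array(fresh, dtype=np.int64))
            need = config.n_mutations - sum(len(c) for c in chosen)
            guard += 1
            if guard > 1000:
                raise RuntimeError("could not place the requested number of mutations")
        rows = np.concatenate(chosen)[: config.n_mutations]
        ccf = draw_ccf(rng, len(rows), config)
        syn = space.is_syn[rows]
        aff_r = affinity_rows[rows]
        neo = (~syn) & (aff_r < AFFINITY_BINDER_THRESHOLD)
        vaf = ccf / 2.0
        depth = 100
        frames.append(
            pd.DataFrame(
                {
                    "sample": f"S{i:04d}",
                    "transcript": np.array(space.transcript_ids)[space.transcript_idx[rows]],
                    "cds_pos": space.pos[rows],
                    "ref": np.array(list(BASES))[space.ref[rows]],
                    "alt": np.array(list(BASES))[space.alt[rows]],
                    "context": np.array(CONTEXTS_192, dtype=object)[space.ctx192[rows]],
                    "context96": np.array(CONTEXTS_96, dtype=object)[space.ctx96[rows]],
                    "consequence": np.where(syn, "synonymous", "nonsynonymous"),
                    "vaf": vaf,
                    "alt_count": np.maximum(np.round(vaf * depth), 1).astype(int),
                    "depth": depth,
                    "filter": "PASS",
                    "ccf": ccf,
                    "is_neoantigen": neo,
                    "affinity": aff_r,
                    "in_binding_region": aff_r < AFFINITY_BINDER_THRESHOLD,
                    "in_immunopeptidome": aff_r < AFFINITY_BINDER_THRESHOLD,
                }
            )
        )
    table = MutationTable(pd.concat(frames, ignore_index=True))
    table.provenance.append(
        {
            "step": "simulate_baseline",
            "n_samples": config.n_samples,
            "n_mutations": config.n_mutations,
            "seed": config.seed,
            "s": 0.0,
            "spectrum_mass_without_sites": float(missing),
        }
    )
    return table


def apply_immune_selection(
    baseline: MutationTable,
    s: float,
    mode: str = "combined",
    threshold: float = 0.2,
    ccf_floor: float = 0.01,
    survivors_keep_shifted: bool = True,
) -> MutationTable:
    """Apply immune selection of strength ``s`` to a baseline cohort.

    Every neoantigen's depressed CCF is CCF_s = CCF − s·a with
    a = (500 − affinity)/499.  ``combined``: neoantigens with
    CCF_s < threshold are removed, survivors keep the depressed CCF
    (or the original one with ``survivors_keep_shifted=False``);
    ``remove_only``: same removal, survivors revert to the original
    CCF; ``ccf_only``: depressed CCFs are kept (floored at
    ``ccf_floor``) and nothing is removed.  Non-neoantigen mutations are
    untouched in every mode.
    """
    if mode not in ("combined", "remove_only", "ccf_only"):
        raise ValueError(f"unknown selection mode {mode!r}")
    if not 0 <= s <= 1:
        raise ValueError("selection strength s must lie in [0, 1]")
    df = baseline.df.copy()
    neo = df["is_neoantigen"].eq(True).to_numpy()
    a = normalized_immunogenicity(df["affinity"].to_numpy())
    ccf = df["ccf"].to_numpy(dtype=float)
    ccf_s = ccf - s * a
    removed = neo & (ccf_s < threshold)
    new_ccf = ccf.copy()
    if mode == "combined":
        if survivors_keep_shifted:
            new_ccf[neo] = np.clip(ccf_s[neo], ccf_floor, 1.0)
        keep = ~removed
    elif mode == "remove_only":
        keep = ~removed
    else:  # ccf_only
        new_ccf[neo] = np.clip(ccf_s[neo], ccf_floor, 1.0)
        keep = np.ones(len(df), dtype=bool)
    df["ccf"] = new_ccf
    df = df[keep]
    out = baseline.with_df(
        df,
        {
            "step": "immune_selection",
            "s": s,
            "mode": mode,
            "threshold": threshold,
            "removed": int(removed.sum() if mode != "ccf_only" else 0),
        },
    )
    return out
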