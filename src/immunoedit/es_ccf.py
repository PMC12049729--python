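"""Enrichment score of cancer cell fraction (ES-CCF).

A Kolmogorov–Smirnov-like statistic comparing the CCF distributions of
antigenic (neoantigen) and non-antigenic mutations within a sample.
The CCF range (0, 1] is divided into L equal intervals (default 100),
traversed from high CCF to low, so that neoantigens concentrated at low
CCF accumulate late and drive the statistic negative.  Interval r gets
the normalized rank R_r = |L/2 − r| + 1; within each mutation class the
interval masses are a_r = m_r R_r / Σ m_r R_r, cumulated into F; the
signed distance D(n) = F_N(n) − F_M(n) yields

    ES-CCF = max(0, max_n D(n)) − |min(0, min_n D(n))|

ES-CCF < 0 indicates a down-shift of neoantigen CCFs (immunoediting);
the classification additionally requires permutation p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_INTERVALS = 100


@dataclass
class CcfEnrichmentState:
    n_intervals: int
    counts_antigenic: np.ndarray
    counts_non_antigenic: np.ndarray
    rank_weights: np.ndarray
    f_antigenic: np.ndarray
    f_non_antigenic: np.ndarray
    distance: np.ndarray
    es: float
    p_value: float = np.nan
    assignable: bool = True
    n_excluded_zero_ccf: int = 0


def _bin_indices(ccf: np.ndarray, L: int, descending: bool = True) -> np.ndarray:
    """Interval rank r (1..L) of each CCF; left-open right-closed bins.

    With the default high-to-low traversal, r=1 is the interval
    (1−1/L, 1] and r=L is (0, 1/L].
    """
    # round before ceil to keep values like 0.28*100 == 28.000000000000004
    # in their closed-right bin
    edges = np.ceil(np.round(ccf * L, 9)).astype(np.int64)
    edges = np.clip(edges, 1, L)
    return (L - edges + 1) if descending else edges


def _interval_masses(counts: np.ndarray, rank_weights: np.ndarray) -> np.ndarray:
    weighted = counts * rank_weights
    total = weighted.sum()
    return weighted / total if total > 0 else weighted


def ccf_enrichment_score(
    antigenic_ccf,
    non_antigenic_ccf,
    n_intervals: int = DEFAULT_INTERVALS,
    descending: bool = True,
) -> CcfEnrichmentState:
    """ES-CCF for one sample from the two CCF lists.

    CCF values of exactly 0 are excluded (counted in the result); an
    empty class after exclusion makes the sample unassignable
    (``es`` = NaN).  ``descending=False`` flips the traversal
    orientation (and the sign convention of the score).
    """
    L = int(n_intervals)
    if L < 2:
        raise ValueError("need at least 2 intervals")
    ant = np.asarray(antigenic_ccf, dtype=float)
    non = np.asarray(non_antigenic_ccf, dtype=float)
    if ((ant < 0) | (ant > 1)).any() or ((non < 0) | (non > 1)).any():
        raise ValueError("CCF values must lie in [0, 1]")
    excluded = int((ant == 0).sum() + (non == 0).sum())
    ant, non = ant[ant > 0], non[non > 0]
    r = np.arange(1, L + 1)
    rank_weights = np.abs(L / 2 - r) + 1
    counts_a = np.bincount(_bin_indices(ant, L, descending) - 1, minlength=L).astype(float)
    counts_n = np.bincount(_bin_indices(non, L, descending) - 1, minlength=L).astype(float)
    assignable = len(ant) >= 1 and len(non) >= 1
    f_a = np.cumsum(_interval_masses(counts_a, rank_weights))
    f_n = np.cumsum(_interval_masses(counts_n, rank_weights))
    d = f_a - f_n
    es = float(max(0.0, d.max()) - abs(min(0.0, d.min()))) if assignable else np.nan
    return CcfEnrichmentState(
        n_intervals=L,
        counts_antigenic=counts_a,
        counts_non_antigenic=counts_n,
        rank_weights=rank_weights,
        f_antigenic=f_a,
        f_non_antigenic=f_n,
        distance=d,
        es=es,
        assignable=assignable,
        n_excluded_zero_ccf=excluded,
    )


def es_ccf_p(
    antigenic_ccf,
    non_antigenic_ccf,
    n_perm: int = 1000,
    seed: int = 0,
    n_intervals: int = DEFAULT_INTERVALS,
    descending: bool = True,
) -> tuple[float, float]:
    """Permutation p for ES-CCF, one-sided toward editing.

    Class labels are shuffled over the pooled CCFs preserving class
    sizes; p is the fraction of permuted ES less than or equal to the
    real ES (ties count).  Returns ``(es, p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    state = ccf_enrichment_score(antigenic_ccf, non_antigenic_ccf, n_intervals, descending)
    if not state.assignable:
        return state.es, np.nan
    ant = np.asarray(antigenic_ccf, dtype=float)
    non = np.asarray(non_antigenic_ccf, dtype=float)
    pool = np.concatenate([ant[ant > 0], non[non > 0]])
    n_ant = int((ant > 0).sum())
    L = int(n_intervals)
    r = np.arange(1, L + 1)
    rank_weights = np.abs(L / 2 - r) + 1
    bins = _bin_indices(pool, L, descending) - 1
    onehot = np.zeros((len(pool), L))
    onehot[np.arange(len(pool)), bins] = 1.0
    labels = np.zeros((n_perm, len(pool)), dtype=bool)
    labels[:, :n_ant] = True
    labels = np.random.default_rng(seed).permuted(labels, axis=1)
    counts_a = labels.astype(float) @ onehot
    counts_n = (~labels).astype(float) @ onehot
    wa = counts_a * rank_weights
    wn = counts_n * rank_weights
    with np.errstate(invalid="ignore", divide="ignore"):
        f_a = np.cumsum(wa / wa.sum(axis=1, keepdims=True), axis=1)
        f_n = np.cumsum(wn / wn.sum(axis=1, keepdims=True), axis=1)
    d = f_a - f_n
    es_perm = np.maximum(d.max(axis=1), 0.0) - np.abs(np.minimum(d.min(axis=1), 0.0))
    ok = np.isfinite(es_perm)
    p = float(np.sum(es_perm[ok] <= state.es) / ok.sum()) if ok.any() else np.nan
    return state.es, p


def classify_es_ccf(es: float, p: float, with_p: bool = True) -> str:
    """edited / unedited / unassigned under the ES-CCF rules.

    The full rule requires ES < 0 and p < 0.05; the ``without_p``
    variant (``with_p=False``) requires only ES < 0.
    """
    if np.isnan(es) or (with_p and np.isnan(p)):
        return "unassigned"
    if es < 0 and (not with_p or p < 0.05):
        return "edited"
    return "unedited"
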