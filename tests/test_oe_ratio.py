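"""OE-ratio estimation, scoring and permutation null."""

import numpy as np
import pandas as pd
import pytest

from immunoedit import MutationTable
from immunoedit.oe_ratio import (
    ReferenceRates,
    estimate_reference_rates,
    oe_permutation_p,
    oe_ratio_sample,
)


def _rates(nbar=None, bbar=None, psyn=None, b_coding=0.2):
    def vec(v):
        out = np.full(192, np.nan)
        if v is not None:
            for idx, val in v.items():
                out[idx] = val
        return out

    return ReferenceRates(vec(nbar), vec(bbar), vec(psyn), b_coding)


def _sample(rows):
    df = pd.DataFrame(rows)
    return MutationTable(df).df


CTX = "A[C>T]G"  # arbitrary fixed context
from immunoedit.genetic import CONTEXT_192_INDEX

CID = CONTEXT_192_INDEX[CTX]


def mut(consequence, neo=False, ctx=CTX, sample="S1"):
    return dict(
        sample=sample, transcript="T", cds_pos=1, ref="C", alt="T",
        context=ctx, consequence=consequence, is_neoantigen=neo,
    )


class TestReferenceRates:
    def test_hand_tally(self, small_space):
        """Context with 4 nonsynonymous, 2 synonymous, 1 neoantigen."""
        rows = (
            [mut("nonsynonymous") for _ in range(3)]
            + [mut("nonsynonymous", neo=True)]
            + [mut("synonymous") for _ in range(2)]
        )
        rates = estimate_reference_rates(MutationTable(pd.DataFrame(rows)), space=small_space)
        assert rates.nbar[CID] == 2.0
        assert rates.bbar[CID] == 0.25
        assert rates.b_coding == pytest.approx(1 / 6)

    def test_all_neoantigen_cohort(self, small_space):
        rows = [mut("nonsynonymous", neo=True) for _ in range(5)] + [mut("synonymous")]
        rates = estimate_reference_rates(MutationTable(pd.DataFrame(rows)), space=small_space)
        assert rates.bbar[CID] == 1.0

    def test_undefined_contexts_flagged_nan(self, small_space):
        rows = [mut("nonsynonymous")]  # no synonymous mutation in this context
        rates = estimate_reference_rates(MutationTable(pd.DataFrame(rows)), space=small_space)
        assert np.isnan(rates.nbar[CID])

    def test_rate_scale_invariance(self, baseline_cohort, synthetic_world):
        """Duplicating every reference record leaves all rates unchanged."""
        _, _, space = synthetic_world
        r1 = estimate_reference_rates(baseline_cohort, space=space)
        doubled = MutationTable(
            pd.concat([baseline_cohort.df, baseline_cohort.df], ignore_index=True)
        )
        r2 = estimate_reference_rates(doubled, space=space)
        np.testing.assert_allclose(r1.nbar, r2.nbar, equal_nan=True)
        np.testing.assert_allclose(r1.bbar, r2.bbar, equal_nan=True)
        assert r1.b_coding == pytest.approx(r2.b_coding)


class TestOEScores:
    def test_ref_sample_worked_example(self):
        """N=2, B=0.25 sole context; Sobs=1, Nobs=2, Bobs=1 -> score 2.0."""
        rates = _rates(nbar={CID: 2.0}, bbar={CID: 0.25})
        df = _sample([mut("synonymous"), mut("nonsynonymous"), mut("nonsynonymous", neo=True)])
        res = oe_ratio_sample(df, rates, "refSample")
        assert res.n_pred == 2.0
        assert res.b_pred == 0.5
        assert res.score == pytest.approx(2.0, abs=1e-12)

    def test_codon_worked_example(self):
        """P=0.3, 10 coding mutations, B_coding=0.2, Bobs=1, Nobs=7 -> 0.5."""
        rates = _rates(psyn={CID: 0.3}, b_coding=0.2)
        rows = [mut("nonsynonymous") for _ in range(6)] + [mut("nonsynonymous", neo=True)]
        rows += [mut("synonymous") for _ in range(3)]
        res = oe_ratio_sample(_sample(rows), rates, "codon")
        assert res.n_pred == pytest.approx(7.0)
        assert res.b_pred == pytest.approx(2.0)
        assert res.score == pytest.approx(0.5, abs=1e-12)

    def test_identity_when_observation_matches_expectation(self):
        """Observed neoantigen rate equal to Bpred/Npred gives score 1."""
        rates = _rates(nbar={CID: 1.0}, bbar={CID: 0.5})
        df = _sample(
            [mut("synonymous"), mut("nonsynonymous"), mut("nonsynonymous", neo=True)]
        )
        # Npred = 1, Bpred = 0.5 -> expected rate 0.5 == observed 1/2
        res = oe_ratio_sample(df, rates, "refSample")
        assert res.score == pytest.approx(1.0, abs=1e-12)

    def test_edited_rule_threshold(self):
        from immunoedit.benchmark import _status

        assert _status(0.8) == "edited"
        assert _status(1.0) == "unedited"
        assert _status(np.nan) == "unassigned"

    def test_undefined_context_dropped_with_reason(self):
        rates = _rates()  # all contexts undefined
        df = _sample([mut("synonymous"), mut("nonsynonymous", neo=True)])
        res = oe_ratio_sample(df, rates, "refSample")
        assert not res.assignable
        assert res.dropped_contexts == 1

    def test_brute_force_oracle_random_instances(self, baseline_cohort, synthetic_world):
        """Vectorised scoring equals a dict-based tally on real cohort slices."""
        _, _, space = synthetic_world
        rates = estimate_reference_rates(baseline_cohort, space=space)
        psyn = {i: rates.psyn[i] for i in range(192)}
        for sample in baseline_cohort.samples()[:5]:
            df = baseline_cohort.df[baseline_cohort.df["sample"] == sample]
            # brute force: loop over records
            from immunoedit.genetic import CONTEXT_192_INDEX as C

            n_pred = b_pred = 0.0
            npred_c = bpred_c = 0.0
            n_obs = s_obs = b_obs = n_coding = 0
            for _, r in df.iterrows():
                if r["consequence"] not in ("synonymous", "nonsynonymous"):
                    continue
                cid = C[r["context"]]
                n_coding += 1
                npred_c += 1.0 - psyn[cid]
                if r["consequence"] == "synonymous":
                    s_obs += 1
                    if not np.isnan(rates.nbar[cid]) and not np.isnan(rates.bbar[cid]):
                        n_pred += rates.nbar[cid]
                        b_pred += rates.bbar[cid] * rates.nbar[cid]
                else:
                    n_obs += 1
                    if r["is_neoantigen"]:
                        b_obs += 1
            expected_ref = (b_obs / n_obs) / (b_pred / n_pred)
            expected_codon = (b_obs / n_obs) / ((rates.b_coding * n_coding) / npred_c)
            got_ref = oe_ratio_sample(df, rates, "refSample")
            got_codon = oe_ratio_sample(df, rates, "codon")
            assert got_ref.score == pytest.approx(expected_ref, abs=1e-12)
            assert got_codon.score == pytest.approx(expected_codon, abs=1e-12)

    def test_self_reference_neutrality(self, baseline_cohort, synthetic_world):
        """Pooled reference scored as one sample against its own rates -> 1.

        Exact over the contexts whose rates are defined; contexts seen
        only as synonymous or only as nonsynonymous have undefined rates
        and are excluded from both observation and prediction.
        """
        from immunoedit.genetic import CONTEXTS_192

        _, _, space = synthetic_world
        rates = estimate_reference_rates(baseline_cohort, space=space)
        defined = {
            CONTEXTS_192[i]
            for i in range(192)
            if not (np.isnan(rates.nbar[i]) or np.isnan(rates.bbar[i]))
        }
        pooled = baseline_cohort.df[baseline_cohort.df["context"].isin(defined)].copy()
        pooled["sample"] = "POOL"
        res = oe_ratio_sample(pooled, rates, "refSample")
        assert res.score == pytest.approx(1.0, abs=1e-12)

    def test_removing_neoantigens_decreases_scores(self, baseline_cohort, synthetic_world):
        _, _, space = synthetic_world
        rates = estimate_reference_rates(baseline_cohort, space=space)
        sample = baseline_cohort.samples()[0]
        df = baseline_cohort.df[baseline_cohort.df["sample"] == sample]
        neo_idx = df.index[df["is_neoantigen"].eq(True)][:5]
        df_removed = df.drop(neo_idx)
        for method in ("refSample", "codon"):
            full = oe_ratio_sample(df, rates, method).score
            less = oe_ratio_sample(df_removed, rates, method).score
            assert less < full


class TestPermutation:
    def _cohort(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(6):
            for j in range(30):
                cons = "synonymous" if rng.random() < 0.3 else "nonsynonymous"
                rows.append(
                    mut(cons, neo=(cons == "nonsynonymous" and rng.random() < 0.3),
                        sample=f"S{i}")
                )
        return MutationTable(pd.DataFrame(rows))

    def test_trivial_fractions(self):
        rates = _rates(nbar={CID: 1.0}, bbar={CID: 0.5}, psyn={CID: 0.3}, b_coding=0.2)
        cohort = self._cohort()
        res = oe_permutation_p(cohort, rates, "refSample", n_perm=1, seed=0)
        # with a single permutation p is 0.0 or 1.0 for every assignable sample
        assert set(res["p_value"].dropna()) <= {0.0, 1.0}
        assert (res["n_perm_effective"] <= 1).all()

    def test_requires_two_samples(self):
        rates = _rates(nbar={CID: 1.0}, bbar={CID: 0.5})
        single = MutationTable(pd.DataFrame([mut("synonymous")]))
        with pytest.raises(ValueError):
            oe_permutation_p(single, rates, "refSample", n_perm=10)

    def test_permutation_preserves_sample_sizes(self):
        """Permuted per-sample scores come from count-preserving shuffles:
        a cohort of identical samples yields p spread over [0,1]."""
        rates = _rates(nbar={CID: 1.0}, bbar={CID: 0.5}, psyn={CID: 0.3}, b_coding=0.2)
        cohort = self._cohort()
        res = oe_permutation_p(cohort, rates, "refSample", n_perm=50, seed=1)
        ok = res["p_value"].dropna()
        assert len(ok) >= 4
        assert (ok >= 0).all() and (ok <= 1).all()
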