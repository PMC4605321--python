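"""Off-target pipeline: annotation, filtering, stability metric, permutation test."""

import numpy as np
import pytest
from scipy import stats

from rloopkmc.specificity import (
    SpecificityRecord,
    annotate_mismatches,
    correlate_with_cleavage,
    filter_offtarget_set,
    record_seed,
    stability_metric,
)
from rloopkmc.synthetic_data import GeneratorSpec, inject_mismatch, make_pair
from rloopkmc.thermo import EnergyModel, GuideTargetPair

from _oracles import permutation_p_exhaustive


def _mm_type_for(pair, p):
    return {"G": "rG.dG", "C": "rC.dC", "A": "rA.dA", "U": "rU.dT"}[pair.guide_base(p)]


class TestAnnotate:
    def test_perfect_complement_is_empty(self):
        ann = annotate_mismatches("ACGU" * 5, "ACGT" * 5)
        assert ann == []

    def test_constructed_ra_da_at_position_14(self):
        spec = GeneratorSpec(seed=8)
        for i in range(40):
            pair = make_pair(spec, i)
            if pair.guide_base(14) == "A":
                break
        mutated = inject_mismatch(pair, 14, "rA.dA")
        ann = annotate_mismatches(mutated.guide, mutated.protospacer)
        assert ann == [(14, "rA.dA", True)]

    def test_adjacent_mismatches_flagged_not_isolated(self):
        spec = GeneratorSpec(seed=8)
        for i in range(60):
            pair = make_pair(spec, i)
            if pair.guide_base(13) == "C" and pair.guide_base(14) == "A":
                break
        else:
            pytest.fail("no suitable random pair found")
        mutated = inject_mismatch(inject_mismatch(pair, 13, "rC.dC"), 14, "rA.dA")
        ann = annotate_mismatches(mutated.guide, mutated.protospacer)
        assert [(p, t) for p, t, _ in ann] == [(13, "rC.dC"), (14, "rA.dA")]
        assert all(not iso for _, _, iso in ann)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="lengths differ"):
            annotate_mismatches("ACGU" * 5, "ACGT" * 4)


class TestFilter:
    @staticmethod
    def _rec(pair, rec_id="r", freq=0.5):
        return SpecificityRecord(record_id=rec_id, pair=pair, cutting_frequency=freq)

    def test_empty_input_empty_output(self):
        kept, reasons = filter_offtarget_set([])
        assert kept == []
        assert sum(reasons.values()) == 0

    def test_known_mixture_keeps_exactly_compliant_records(self):
        spec = GeneratorSpec(seed=14)
        records, compliant_ids = [], []
        i = 0
        made = 0
        while made < 10:
            pair = make_pair(spec, i)
            i += 1
            rid = f"r{made}"
            if made < 3:  # compliant: one canonical PAM-distal mismatch
                p = 10 + made
                rec = self._rec(inject_mismatch(pair, p, _mm_type_for(pair, p)), rid)
                compliant_ids.append(rid)
            elif made < 5:  # PAM-proximal mismatch
                rec = self._rec(inject_mismatch(pair, 4, _mm_type_for(pair, 4)), rid)
            elif made < 7:  # no mismatch at all
                rec = self._rec(pair, rid)
            elif made < 9:  # two mismatches
                rec = self._rec(
                    inject_mismatch(
                        inject_mismatch(pair, 11, _mm_type_for(pair, 11)),
                        15,
                        _mm_type_for(pair, 15),
                    ),
                    rid,
                )
            else:  # non-canonical ("other") mismatch type
                proto = list(pair.protospacer)
                m = 12
                g = pair.guide_base(m)
                # swap the bound base to a non-WC partner different from the guide base
                other = {"A": "C", "C": "A", "G": "U", "U": "G"}[g]
                from rloopkmc.thermo import DNA_COMPLEMENT

                proto[len(proto) - m] = DNA_COMPLEMENT[other.replace("U", "T")]
                rec = self._rec(
                    GuideTargetPair(guide=pair.guide, protospacer="".join(proto)), rid
                )
            records.append(rec)
            made += 1
        kept, reasons = filter_offtarget_set(records)
        assert sorted(r.record_id for r in kept) == sorted(compliant_ids)
        assert reasons["pam_proximal"] == 2
        assert reasons["multiple_or_no_mismatch"] == 4
        assert reasons["type_other"] == 1
        for r in kept:
            assert r.mismatch_position >= 10
            assert r.mismatch_type in {"rG.dG", "rC.dC", "rA.dA", "rU.dT"}


class TestStabilityMetric:
    def test_zero_prefactor_frozen_below_threshold(self, model):
        pair = make_pair(GeneratorSpec(seed=2), 0)
        occ = stability_metric(pair, model, m_star=16, reps=20, m0=10, seed=5, k0=0.0)
        assert occ.mean_frac == 0.0

    def test_delegates_to_threshold_occupancy(self, model):
        from rloopkmc.invasion_kmc import build_rate_table, simulate_residency
        from rloopkmc.observables import threshold_occupancy

        pair = make_pair(GeneratorSpec(seed=2), 1)
        occ = stability_metric(pair, model, reps=100, seed=31, max_t=50.0)
        rates = build_rate_table(pair, model)
        ens = simulate_residency(rates, 10, 50.0, 100, 31)
        ref = threshold_occupancy(ens, 16)
        assert occ.mean_frac == ref.mean_frac
        assert occ.sem == ref.sem

    def test_strong_mismatch_penalty_reduces_stability(self, model):
        """A heavily destabilized stack at position 12 lowers the fraction of
        time the R-loop extends past 16 (matched seeds and replicates)."""
        penal = EnergyModel(
            nn_dna_dna=model.nn_dna_dna,
            nn_rna_dna=model.nn_rna_dna,
            nn_mismatch={k: 3.0 for k in model.nn_mismatch},
        )
        spec = GeneratorSpec(seed=21)
        pair = make_pair(spec, 3)
        mutated = inject_mismatch(pair, 12, _mm_type_for(pair, 12))
        base = stability_metric(pair, penal, reps=1000, seed=77)
        hit = stability_metric(mutated, penal, reps=1000, seed=77)
        assert hit.mean_frac < base.mean_frac

    def test_record_seed_stable_and_distinct(self):
        assert record_seed(5, "a") == record_seed(5, "a")
        assert record_seed(5, "a") != record_seed(5, "b")
        assert record_seed(6, "a") != record_seed(5, "a")
        assert 0 <= record_seed(5, "a") < 2**31


class TestCorrelation:
    def test_identical_vectors_hit_minimum_p(self):
        x = np.arange(12, dtype=float)
        res = correlate_with_cleavage(x, x.copy(), n_perm=500, seed=0, exact=False)
        assert res.r == pytest.approx(1.0)
        assert res.p_perm == pytest.approx(1.0 / 501.0)

    def test_tiny_sample_matches_exhaustive_enumeration(self, rng):
        for _ in range(5):
            x = rng.normal(size=4)
            y = rng.normal(size=4)
            res = correlate_with_cleavage(x, y, n_perm=100_000, seed=1)
            assert res.exact
            assert res.p_perm == pytest.approx(permutation_p_exhaustive(x, y), abs=1e-15)

    def test_affine_rescaling_leaves_p_unchanged(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        a = correlate_with_cleavage(x, y, n_perm=2000, seed=3, exact=False)
        b = correlate_with_cleavage(x, 4.2 * y + 17.0, n_perm=2000, seed=3, exact=False)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.p_perm == b.p_perm

    def test_spearman_flag_uses_ranks(self, rng):
        x = rng.uniform(size=20)
        y = np.exp(7 * x)  # monotone but nonlinear
        res = correlate_with_cleavage(x, y, n_perm=999, seed=2, method="spearman", exact=False)
        assert res.r == pytest.approx(1.0)

    def test_pearson_r_cross_checked_against_scipy(self, rng):
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        res = correlate_with_cleavage(x, y, n_perm=100, seed=0, exact=False)
        assert res.r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_with_cleavage(np.ones(5), np.arange(5.0), n_perm=10)

    def test_length_preconditions(self):
        with pytest.raises(ValueError):
            correlate_with_cleavage(np.arange(2.0), np.arange(2.0), n_perm=10)
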