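import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forestdiv.data_model import StudyCommunity
from forestdiv.metrics import (
    EmptyReferenceError,
    compare_communities,
    compute_all_metrics,
    intactness,
    metric_correlations,
    metrics_to_frame,
    relative_abundance,
    relative_richness,
    sorensen_similarity,
)

from conftest import naive_metrics, random_community_pair


class TestWorkedExample:
    def test_comparison_bookkeeping(self, toy_pair):
        cmp = compare_communities(*toy_pair)
        assert cmp.ratios == {"sp a": 0.5, "sp b": 1.0, "sp c": 0.0}
        assert (cmp.n_ref, cmp.n_man, cmp.n_shared, cmp.n_diff) == (3, 3, 2, 2)
        assert cmp.total_man == 19.0 and cmp.total_ref == 17.0

    def test_four_metric_values(self, toy_pair):
        cmp = compare_communities(*toy_pair)
        assert intactness(cmp) == pytest.approx(0.5)
        assert sorensen_similarity(cmp) == pytest.approx(2 / 3)
        assert relative_richness(cmp) == pytest.approx(0.0)
        assert relative_abundance(cmp) == pytest.approx(math.log(19 / 17))


class TestIdentityAndLimits:
    def _pair(self, man, ref):
        return (
            StudyCommunity("s", "p", "SC", man, 1),
            StudyCommunity("s", "p", "REFERENCE", ref, 1),
        )

    def test_identical_communities(self):
        ref = {"a": 3.0, "b": 0.5}
        cmp = compare_communities(*self._pair(dict(ref), ref))
        assert intactness(cmp) == 1.0
        assert sorensen_similarity(cmp) == 1.0
        assert relative_richness(cmp) == 0.0
        assert relative_abundance(cmp) == 0.0

    def test_disjoint_communities(self):
        cmp = compare_communities(*self._pair({"x": 2.0}, {"a": 1.0, "b": 1.0}))
        assert intactness(cmp) == 0.0
        assert sorensen_similarity(cmp) == 0.0

    def test_empty_reference_is_error(self):
        with pytest.raises(EmptyReferenceError):
            compare_communities(*self._pair({"a": 1.0}, {}))

    def test_reference_zero_abundance_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            compare_communities(*self._pair({"a": 1.0}, {"a": 0.0}))

    def test_zero_richness_managed_excludes_sr_ta(self):
        # a managed community can only be empty if all species were lost;
        # model this as an influx-only community with zero abundance entries
        man = {"x": 0.0}
        cmp = compare_communities(*self._pair(man, {"a": 1.0}))
        assert relative_richness(cmp) is None
        assert relative_abundance(cmp) is None


class TestProperties:
    @given(st.integers(0, 2**32 - 1), st.floats(0.01, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, seed, c):
        man, ref = random_community_pair(np.random.default_rng(seed))
        cmp1 = compare_communities(man, ref)
        man2 = StudyCommunity(
            "s", "p", "SC", {k: v * c for k, v in man.species_mean_abundance.items()}, 1
        )
        ref2 = StudyCommunity(
            "s", "p", "REFERENCE",
            {k: v * c for k, v in ref.species_mean_abundance.items()}, 1,
        )
        cmp2 = compare_communities(man2, ref2)
        assert intactness(cmp1) == pytest.approx(intactness(cmp2), abs=1e-9)
        assert sorensen_similarity(cmp1) == sorensen_similarity(cmp2)
        if cmp1.n_man:
            assert relative_richness(cmp1) == relative_richness(cmp2)
            assert relative_abundance(cmp1) == pytest.approx(
                relative_abundance(cmp2), abs=1e-9
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_sorensen_symmetric_in_the_pair(self, seed):
        man, ref = random_community_pair(np.random.default_rng(seed))
        if not man.species_mean_abundance:
            return
        cmp_f = compare_communities(man, ref)
        swapped_ref = StudyCommunity("s", "p", "REFERENCE", man.species_mean_abundance, 1)
        swapped_man = StudyCommunity("s", "p", "SC", ref.species_mean_abundance, 1)
        cmp_b = compare_communities(swapped_man, swapped_ref)
        assert sorensen_similarity(cmp_f) == pytest.approx(sorensen_similarity(cmp_b))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_removing_managed_only_species_never_changes_intactness(self, seed):
        rng = np.random.default_rng(seed)
        man, ref = random_community_pair(rng)
        novel = [s for s in man.species_mean_abundance if s.startswith("new")]
        if not novel:
            return
        cmp1 = compare_communities(man, ref)
        trimmed = dict(man.species_mean_abundance)
        trimmed.pop(novel[0])
        if not trimmed:
            return
        cmp2 = compare_communities(StudyCommunity("s", "p", "SC", trimmed, 1), ref)
        assert intactness(cmp1) == pytest.approx(intactness(cmp2))
        assert relative_richness(cmp1) != relative_richness(cmp2)
        assert relative_abundance(cmp1) != relative_abundance(cmp2)
        if cmp1.n_shared > 0:  # with no shared species SI is pinned at 0
            assert sorensen_similarity(cmp1) != sorensen_similarity(cmp2)

    def test_batch_equals_naive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            man, ref = random_community_pair(rng)
            cmp = compare_communities(man, ref)
            IN, SI, SR, TA = naive_metrics(
                man.species_mean_abundance, ref.species_mean_abundance
            )
            assert intactness(cmp) == pytest.approx(IN, abs=1e-12)
            assert sorensen_similarity(cmp) == pytest.approx(SI, abs=1e-12)
            got_sr = relative_richness(cmp)
            if SR is None:
                assert got_sr is None
            else:
                assert got_sr == pytest.approx(SR, abs=1e-12)
            got_ta = relative_abundance(cmp)
            if TA is None:
                assert got_ta is None
            else:
                assert got_ta == pytest.approx(TA, abs=1e-12)


class TestBatchAndCorrelations:
    def test_one_record_per_study_system(self, toy_pair):
        man, ref = toy_pair
        man2 = StudyCommunity("s1", "p1", "PC", {"sp a": 1.0}, 1)
        records = compute_all_metrics([man, ref, man2])
        assert {r.system for r in records} == {"AG", "PC"}

    def test_study_without_reference_yields_nothing(self, toy_pair):
        man, _ = toy_pair
        log: list[dict] = []
        assert compute_all_metrics([man], exclusion_log=log) == []
        assert log[0]["reason"] == "no_reference_community"

    def test_correlations_diagonal_and_variance_conservation(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(0, 1, 40)
        import pandas as pd

        df = pd.DataFrame(
            {
                "IN": 1 / (1 + np.exp(-(latent + rng.normal(0, 0.3, 40)))),
                "SI": 1 / (1 + np.exp(-(latent + rng.normal(0, 0.3, 40)))),
                "SR": 0.5 * latent + rng.normal(0, 0.3, 40),
                "TA": 0.4 * latent + rng.normal(0, 0.3, 40),
            }
        )
        rho, pca = metric_correlations(df)
        assert np.allclose(np.diag(rho), 1.0)
        # one shared latent driver -> all pairwise correlations positive
        assert (rho.to_numpy() > 0).all()
        assert pca["explained_variance"].sum() == pytest.approx(4.0, rel=1e-6)

    def test_correlations_require_three_rows(self):
        import pandas as pd

        df = pd.DataFrame({"IN": [0.5], "SI": [0.5], "SR": [0.0], "TA": [0.0]})
        with pytest.raises(ValueError, match=">=3"):
            metric_correlations(df)
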