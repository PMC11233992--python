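import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle_formulas as orc
from ecostatus import IncidenceMatrix, index_table
from ecostatus.indices import (
    REGISTRY,
    brillouin,
    camargo,
    chao2,
    chao_single,
    dominance_suite,
    evenness_suite,
    fisher_alpha,
    hill_numbers,
    hurlbert_pie,
    kothe_deficit,
    mcintosh_m,
    richness_ratios,
    shannon,
    simpson_concentration,
    total_abundance,
)

C4321 = {"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0}


class TestFrozenExamples:
    """Hand-derived values for small assemblages."""

    def test_hill_numbers(self):
        assert hill_numbers({"A": 10}) == (1, 1, 1)
        assert hill_numbers({"A": 10, "B": 10}) == pytest.approx((2, 2, 2))
        n0, n1, n2 = hill_numbers(C4321)
        assert n0 == 4
        assert n1 == pytest.approx(3.5961, abs=5e-5)
        assert n2 == pytest.approx(10 / 3, rel=1e-12)

    def test_shannon(self):
        assert shannon({"A": 7}) == 0
        assert shannon({"A": 10, "B": 10}) == pytest.approx(math.log(2), rel=1e-12)
        assert shannon(C4321) == pytest.approx(1.27985, abs=5e-6)

    def test_simpson(self):
        assert simpson_concentration({"A": 7}) == 1
        assert simpson_concentration({"A": 10, "B": 10}) == pytest.approx(0.5)
        assert simpson_concentration(C4321) == pytest.approx(0.30, rel=1e-12)

    def test_richness_ratios(self):
        r = richness_ratios(C4321)
        assert r["margalef"] == pytest.approx(1.3029, abs=5e-5)
        assert r["gleason"] == pytest.approx(1.7372, abs=5e-5)
        assert r["menhinick"] == pytest.approx(1.2649, abs=5e-5)
        assert r["odum"] == pytest.approx(4.0, rel=1e-12)
        assert richness_ratios({"A": 1, "B": 99})["margalef"] == pytest.approx(
            1 / math.log(100)
        )
        scaled = {k: 10 * v for k, v in C4321.items()}
        assert richness_ratios(scaled)["menhinick"] == pytest.approx(0.4)

    def test_brillouin(self):
        assert brillouin({"A": 5}) == pytest.approx(0.0, abs=1e-12)
        assert brillouin({"A": 2, "B": 2}) == pytest.approx(0.4479, abs=5e-5)
        assert brillouin(C4321) < shannon(C4321)

    def test_mcintosh(self):
        assert mcintosh_m({"A": 9}) == pytest.approx(0.0, abs=1e-12)
        assert mcintosh_m(C4321) == pytest.approx(0.6614, abs=5e-5)
        # evenness limit: large even assemblages approach 1
        m_small = mcintosh_m({f"s{i}": 100.0 for i in range(5)})
        m_big = mcintosh_m({f"s{i}": 100.0 for i in range(50)})
        assert m_small < m_big < 1.0

    def test_camargo(self):
        assert camargo({"A": 10, "B": 10}) == 1.0
        assert camargo({"A": 5}) == 1.0
        assert camargo(C4321) == pytest.approx(0.75, rel=1e-12)

    def test_pie(self):
        assert hurlbert_pie({"A": 9}) == pytest.approx(0.0, abs=1e-12)
        assert hurlbert_pie({"A": 10, "B": 10}) == pytest.approx(0.5263, abs=5e-5)
        assert hurlbert_pie(C4321) == pytest.approx(0.7778, abs=5e-5)

    def test_fisher_alpha(self):
        counts = {f"s{i}": 10.0 for i in range(10)}  # S=10, N=100
        alpha = fisher_alpha(counts)
        assert alpha == pytest.approx(2.77, abs=0.005)
        assert abs(alpha * math.log(1 + 100 / alpha) - 10) < 1e-9
        # strictly increasing in S at fixed N
        a5 = fisher_alpha({f"s{i}": 40.0 for i in range(5)})
        a15 = fisher_alpha({f"s{i}": 200 / 15 for i in range(15)})
        assert a5 < a15

    def test_chao2(self):
        # m=3 units, S_obs=8, q1=3, q2=1 -> 9.0
        presence = np.zeros((3, 8), dtype=bool)
        presence[:, :4] = True  # 4 species in all units
        presence[0, 4] = presence[1, 4] = True  # q2 species
        presence[0, 5] = True
        presence[1, 6] = True
        presence[2, 7] = True  # three uniques
        inc = IncidenceMatrix(units=["u1", "u2", "u3"], species=[f"x{i}" for i in range(8)], presence=presence)
        assert chao2(inc) == pytest.approx(9.0, rel=1e-12)
        # q1 = 0 -> S_obs exactly
        inc0 = IncidenceMatrix(["u1", "u2"], ["a", "b"], np.ones((2, 2), bool))
        assert chao2(inc0) == 2.0

    def test_chao_single(self):
        # f1=2, f2=1 -> S_obs + 2*1/(2*2)
        counts = {"A": 5.0, "B": 2.0, "C": 1.0, "D": 1.0}
        assert chao_single(counts) == pytest.approx(4 + 2 / 4)
        assert chao_single({"A": 5, "B": 5}) == 2.0

    def test_kothe(self):
        assert kothe_deficit({f"s{i}": 1.0 for i in range(30)}, 40) == pytest.approx(25.0)
        assert kothe_deficit({f"s{i}": 1.0 for i in range(7)}, 7) == 0.0
        assert kothe_deficit({"A": 1.0}, 1) == 0.0
        with pytest.raises(ValueError):
            kothe_deficit({"A": 1.0}, 0)

    def test_evenness(self):
        e = evenness_suite({"A": 10, "B": 10})
        assert e["E1"] == pytest.approx(1.0, rel=1e-12)
        e = evenness_suite(C4321)
        assert e["E1"] == pytest.approx(0.9232, abs=5e-5)
        assert e["E2"] == pytest.approx(0.8990, abs=5e-5)
        assert e["E5"] == pytest.approx(0.8988, abs=5e-5)
        single = evenness_suite({"A": 3})
        assert math.isnan(single["E1"]) and math.isnan(single["E3"])
        assert single["E2"] == pytest.approx(1.0)

    def test_redundancy(self):
        assert evenness_suite({"A": 10, "B": 10})["redundancy"] == pytest.approx(
            0.0, abs=1e-12
        )
        # maximally uneven integer partition attains redundancy 1
        assert evenness_suite({"A": 8.0, "B": 1.0, "C": 1.0})["redundancy"] == pytest.approx(1.0)

    def test_dominance(self):
        d = dominance_suite({"A": 9})
        assert d["berger_parker"] == 1.0 and d["mcnaughton"] == 100.0
        d = dominance_suite(C4321)
        assert d["berger_parker"] == pytest.approx(0.4)
        assert d["mcnaughton"] == pytest.approx(70.0)

    def test_total_abundance(self):
        assert total_abundance({}) == 0.0
        assert total_abundance(C4321) == 10.0


def test_all_zero_counts_rejected():
    for fn in (shannon, simpson_concentration, hill_numbers, camargo, dominance_suite):
        with pytest.raises(ValueError):
            fn({"A": 0.0})


def test_oracle_equivalence(random_assemblages):
    """Every index matches its independent literal-formula oracle."""
    pairs = [
        (shannon, orc.o_shannon),
        (simpson_concentration, orc.o_simpson),
        (lambda c: richness_ratios(c)["margalef"], orc.o_margalef),
        (lambda c: richness_ratios(c)["gleason"], orc.o_gleason),
        (lambda c: richness_ratios(c)["menhinick"], orc.o_menhinick),
        (lambda c: richness_ratios(c)["odum"], orc.o_odum),
        (brillouin, orc.o_brillouin),
        (mcintosh_m, orc.o_mcintosh),
        (camargo, orc.o_camargo),
        (hurlbert_pie, orc.o_pie),
        (chao_single, orc.o_chao_single),
        (lambda c: dominance_suite(c)["berger_parker"], orc.o_berger_parker),
        (lambda c: dominance_suite(c)["mcnaughton"], orc.o_mcnaughton),
    ]
    for counts in random_assemblages:
        for impl, oracle in pairs:
            assert impl(counts) == pytest.approx(oracle(counts), rel=1e-10)
        n0, n1, n2 = hill_numbers(counts)
        e0, e1, e2 = orc.o_hill(counts)
        assert (n0, n1, n2) == pytest.approx((e0, e1, e2), rel=1e-10)
        ev, oev = evenness_suite(counts), orc.o_evenness(counts)
        for key in ("E1", "E2", "E3", "E4", "E5", "simpson_evenness"):
            assert ev[key] == pytest.approx(oev[key], rel=1e-10)
        red, ored = ev["redundancy"], orc.o_redundancy(counts)
        if ored is None:
            assert math.isnan(red)
        else:
            assert red == pytest.approx(ored, rel=1e-10)
        if orc.o_richness(counts) >= 2 and orc.o_total(counts) > orc.o_richness(counts):
            assert fisher_alpha(counts) == pytest.approx(
                orc.o_fisher_alpha(counts), rel=1e-6
            )
        assert kothe_deficit(counts, 86) == pytest.approx(
            orc.o_kothe(counts, 86), rel=1e-10
        )


counts_strategy = st.dictionaries(
    st.text(st.characters(min_codepoint=97, max_codepoint=122), min_size=1, max_size=5),
    st.floats(min_value=0.01, max_value=1e4, allow_nan=False),
    min_size=1,
    max_size=30,
)


@settings(deadline=None, derandomize=True)
@given(counts_strategy)
def test_hill_ordering_and_identities(counts):
    n0, n1, n2 = hill_numbers(counts)
    assert n0 >= n1 - 1e-9 and n1 >= n2 - 1e-9 and n2 >= 1 - 1e-9
    assert math.exp(shannon(counts)) == pytest.approx(n1, rel=1e-12)
    assert 1 / simpson_concentration(counts) == pytest.approx(n2, rel=1e-12)


@settings(deadline=None, derandomize=True)
@given(counts_strategy, st.floats(min_value=0.1, max_value=100.0))
def test_scale_invariance_of_proportion_indices(counts, k):
    scaled = {sp: v * k for sp, v in counts.items()}
    assert shannon(scaled) == pytest.approx(shannon(counts), rel=1e-9)
    assert simpson_concentration(scaled) == pytest.approx(
        simpson_concentration(counts), rel=1e-9
    )
    assert camargo(scaled) == pytest.approx(camargo(counts), rel=1e-9)
    d0, d1 = dominance_suite(counts), dominance_suite(scaled)
    assert d1["berger_parker"] == pytest.approx(d0["berger_parker"], rel=1e-9)
    assert d1["mcnaughton"] == pytest.approx(d0["mcnaughton"], rel=1e-9)


@settings(deadline=None, derandomize=True)
@given(counts_strategy, st.randoms(use_true_random=False))
def test_permutation_invariance(counts, rnd):
    items = list(counts.items())
    rnd.shuffle(items)
    permuted = dict(items)
    assert shannon(permuted) == pytest.approx(shannon(counts), rel=1e-12)
    assert simpson_concentration(permuted) == pytest.approx(
        simpson_concentration(counts), rel=1e-12
    )
    assert camargo(permuted) == pytest.approx(camargo(counts), rel=1e-12)


def test_chao2_at_least_observed_richness(default_dataset):
    for s in default_dataset:
        est = chao2(s.incidence)
        s_obs = len(s.incidence.species)
        assert est >= s_obs - 1e-12
        occ = s.incidence.presence.sum(axis=0)
        if (occ == 1).sum() <= 1:
            assert est == pytest.approx(s_obs)


def test_direction_on_designed_pair():
    """Even vs dominant assemblage with equal S and N: diversity/evenness
    indices favor the even one, dominance-type indices the uneven one."""
    S, N = 10, 1000
    even = {f"s{i}": N / S for i in range(S)}
    p = 0.6 * 0.4 ** np.arange(S)
    p /= p.sum()
    dominant = {f"s{i}": float(N * p[i]) for i in range(S)}
    assert shannon(even) > shannon(dominant)
    assert mcintosh_m(even) > mcintosh_m(dominant)
    assert camargo(even) > camargo(dominant)
    assert hurlbert_pie(even) > hurlbert_pie(dominant)
    assert evenness_suite(even)["E1"] > evenness_suite(dominant)["E1"]
    assert simpson_concentration(even) < simpson_concentration(dominant)
    assert dominance_suite(even)["berger_parker"] < dominance_suite(dominant)["berger_parker"]
    assert dominance_suite(even)["mcnaughton"] < dominance_suite(dominant)["mcnaughton"]
    assert evenness_suite(even)["redundancy"] < evenness_suite(dominant)["redundancy"]


class TestIndexTable:
    def test_composition_matches_per_sample_ops(self, default_dataset, default_table):
        frame = default_table.frame
        assert frame.shape == (28, 26)
        s = default_dataset.samples[0]
        assert frame.loc[s.sample_id, "Shannon"] == pytest.approx(
            shannon(s.positive_counts)
        )
        assert frame.loc[s.sample_id, "HillN0"] == s.richness

    def test_single_species_sample_undefined_columns(self):
        from ecostatus import AbundanceSample, SampleSet

        ss = SampleSet(
            samples=[AbundanceSample(sample_id="s1", counts={"A": 50.0})],
            labels={"s1": "good"},
        )
        table = index_table(ss, reference_richness=10)
        row = table.frame.loc["s1"]
        assert math.isnan(row["E1"]) and math.isnan(row["E3"])
        assert row["HillN0"] == 1.0

    def test_full_battery_no_exceptions(self, default_table):
        vals = default_table.frame.to_numpy()
        assert np.all(np.isfinite(vals) | np.isnan(vals))

    def test_unknown_registry_name_listed(self):
        from ecostatus.indices import resolve_registry

        with pytest.raises(KeyError, match="Shannon"):
            resolve_registry(["NotAnIndex"])
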