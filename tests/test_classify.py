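"""Strand-coordination taxonomy: examples, oracle agreement, symmetry.

The independent oracle is a regex classifier over the whole-pattern shape,
written without run-length encoding, so the two routes share no code.
"""

from __future__ import annotations

import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperclust.classify import (
    ClusterType,
    arm_ratio_variance,
    classify_pattern,
    switch_direction_summary,
    switch_geometry,
    terminal_distance_analysis,
    type_distribution,
)

T = ClusterType


def oracle_classify(pattern: str, min_mutations: int = 4) -> ClusterType:
    if re.search("[^CG]", pattern):
        return T.NON_CG
    if len(pattern) < min_mutations:
        return T.BELOW_SIZE_FILTER
    if re.fullmatch("C+", pattern):
        return T.C_COORDINATED
    if re.fullmatch("G+", pattern):
        return T.G_COORDINATED
    if re.fullmatch("C{2,}G{2,}", pattern):
        return T.CG_SINGLE_SWITCH_5PC
    if re.fullmatch("G{2,}C{2,}", pattern):
        return T.CG_SINGLE_SWITCH_5PG
    if re.fullmatch("GC+|C+G", pattern):
        return T.C_COORDINATED_TERMINAL_G
    if re.fullmatch("CG+|G+C", pattern):
        return T.G_COORDINATED_TERMINAL_C
    return T.CG_MULTIPLE_SWITCH


@pytest.mark.parametrize(
    "pattern,expected",
    [
        ("CCCC", T.C_COORDINATED),
        ("GGGGG", T.G_COORDINATED),
        ("CCGG", T.CG_SINGLE_SWITCH_5PC),
        ("GGGCC", T.CG_SINGLE_SWITCH_5PG),
        ("CCCG", T.C_COORDINATED_TERMINAL_G),
        ("GCCC", T.C_COORDINATED_TERMINAL_G),  # terminal at the 5' side
        ("CGGG", T.G_COORDINATED_TERMINAL_C),
        ("GGGC", T.G_COORDINATED_TERMINAL_C),
        ("CGCG", T.CG_MULTIPLE_SWITCH),
        ("CCGCC", T.CG_MULTIPLE_SWITCH),  # internal singleton is not terminal
        ("GCCCG", T.CG_MULTIPLE_SWITCH),
        ("CCC", T.BELOW_SIZE_FILTER),
        ("CCAC", T.NON_CG),
        ("TTTT", T.NON_CG),
    ],
)
def test_taxonomy_examples(pattern, expected):
    assert classify_pattern(pattern) is expected


def test_empty_pattern_rejected():
    with pytest.raises(ValueError):
        classify_pattern("")


def _revcomp(pattern: str) -> str:
    return pattern.translate(str.maketrans("ACGT", "TGCA"))[::-1]


#: Reverse-complementing the genome swaps mutated C <-> G and reverses
#: 5' <-> 3', so C/G labels swap while switch polarity is preserved.
REVCOMP_MAP = {
    T.C_COORDINATED: T.G_COORDINATED,
    T.G_COORDINATED: T.C_COORDINATED,
    T.C_COORDINATED_TERMINAL_G: T.G_COORDINATED_TERMINAL_C,
    T.G_COORDINATED_TERMINAL_C: T.C_COORDINATED_TERMINAL_G,
    T.CG_SINGLE_SWITCH_5PC: T.CG_SINGLE_SWITCH_5PC,
    T.CG_SINGLE_SWITCH_5PG: T.CG_SINGLE_SWITCH_5PG,
    T.CG_MULTIPLE_SWITCH: T.CG_MULTIPLE_SWITCH,
    T.NON_CG: T.NON_CG,
    T.BELOW_SIZE_FILTER: T.BELOW_SIZE_FILTER,
}


@settings(max_examples=500, derandomize=True, deadline=None)
@given(st.text(alphabet="CG", min_size=1, max_size=50))
def test_oracle_agreement_and_revcomp_symmetry(pattern):
    got = classify_pattern(pattern)
    assert got is oracle_classify(pattern)
    assert classify_pattern(_revcomp(pattern)) is REVCOMP_MAP[got]


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=30))
def test_any_acgt_pattern_maps_to_exactly_one_type(pattern):
    assert classify_pattern(pattern) is oracle_classify(pattern)


def test_single_switch_needs_two_plus_two():
    # a lone base next to a run can never be single-switch
    for pattern in ["CGGG", "CCCG", "GCCC", "GGGC", "CGGGGG", "CCCCCG"]:
        assert classify_pattern(pattern) not in {
            T.CG_SINGLE_SWITCH_5PC,
            T.CG_SINGLE_SWITCH_5PG,
        }


class TestDistribution:
    def test_single_switch_fraction_1_of_24(self, make_cluster):
        clusters = [make_cluster("CCCC", cluster_id=f"s1:{i}") for i in range(23)]
        clusters.append(make_cluster("CCGG", cluster_id="s1:24"))
        table = type_distribution(clusters)
        row = table[table["display_class"] == "single_switch"].iloc[0]
        assert row["count"] == 1
        assert row["fraction"] == pytest.approx(1 / 24)
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_excluded_types_not_in_denominator(self, make_cluster):
        clusters = [
            make_cluster("CCCC"),
            make_cluster("CCAC"),  # non-CG
            make_cluster("CCC"),  # below size
        ]
        table = type_distribution(clusters)
        assert table["n_cg_clusters"].iloc[0] == 1
        assert table["n_non_cg"].iloc[0] == 1
        assert table["n_below_size"].iloc[0] == 1
        coord = table[table["display_class"] == "coordinated"].iloc[0]
        assert coord["fraction"] == pytest.approx(1.0)

    def test_identical_strata_give_identical_rows(self, make_cluster):
        clusters = [
            make_cluster("CCCC", sample_id="a"),
            make_cluster("CCGG", sample_id="a"),
            make_cluster("CCCC", sample_id="b"),
            make_cluster("CCGG", sample_id="b"),
        ]
        table = type_distribution(clusters, strata={"a": "A", "b": "B"})
        a = table[table["stratum"] == "A"].drop(columns="stratum").reset_index(drop=True)
        b = table[table["stratum"] == "B"].drop(columns="stratum").reset_index(drop=True)
        assert a.equals(b)

    def test_empty_stratum_not_an_error(self, make_cluster):
        table = type_distribution([])
        assert len(table) == 0


class TestSwitchDirection:
    def test_direct_count(self, make_cluster):
        clusters = [make_cluster(p) for p in ["CCGG", "CCCGG", "GGCC"]]
        s = switch_direction_summary(clusters)
        assert s["frac_5pC_3pG"] == pytest.approx(2 / 3)
        assert s["frac_5pG_3pC"] == pytest.approx(1 / 3)
        assert s["frac_5pC_3pG"] + s["frac_5pG_3pC"] == pytest.approx(1.0)

    def test_all_one_direction(self, make_cluster):
        s = switch_direction_summary([make_cluster("CCGG"), make_cluster("CCCGGG")])
        assert s["frac_5pC_3pG"] == 1.0 and s["frac_5pG_3pC"] == 0.0

    def test_empty_flagged(self, make_cluster):
        s = switch_direction_summary([make_cluster("CCCC")])
        assert math.isnan(s["frac_5pC_3pG"])


class TestTerminalDistances:
    def test_terminal_at_3prime(self, make_cluster):
        cl = make_cluster("CCCG", positions=[100, 200, 300, 5000])
        table, _ = terminal_distance_analysis([cl])
        row = table.iloc[0]
        assert row["dist_terminal_nonmatched"] == 4700
        assert row["dist_terminal_matched"] == 100

    def test_terminal_at_5prime_symmetric(self, make_cluster):
        cl = make_cluster("GCCC", positions=[10, 20, 30, 40])
        table, _ = terminal_distance_analysis([cl])
        row = table.iloc[0]
        assert row["dist_terminal_nonmatched"] == 10
        assert row["dist_terminal_matched"] == 10

    def test_ranksum_direction_on_simulated_mixture(self, make_cluster, rng):
        """Random colocalization puts the nonmatched terminal farther out.

        Coordinated tracts plus an independent nearby mutation have large
        nonmatched distances; genuine switch-like events keep the terminal
        close. A mixture dominated by colocalization must give a rank-sum
        shift toward larger nonmatched distances.
        """
        clusters = []
        for i in range(40):
            base = 10_000 * (i + 1)
            inner = sorted(int(p) for p in base + np.sort(rng.integers(0, 800, size=4)))
            inner = sorted(set(inner))
            while len(inner) < 4:
                inner.append(max(inner) + 37)
            stray = max(inner) + int(rng.integers(3000, 8000))
            clusters.append(
                make_cluster("CCCCG"[: len(inner)] + "G", positions=inner + [stray],
                             cluster_id=f"s1:{i}")
            )
        table, test = terminal_distance_analysis(clusters)
        assert test is not None
        assert table["dist_terminal_nonmatched"].median() > table["dist_terminal_matched"].median()

    def test_non_terminal_cluster_rejected(self, make_cluster):
        with pytest.raises(ValueError, match="terminal"):
            terminal_distance_analysis([make_cluster("CCCC")])


class TestArmGeometry:
    def test_symmetric_arms_log_ratio_zero(self, make_cluster):
        cl = make_cluster("CCGG", positions=[1000, 2000, 3000, 4000])
        geom = switch_geometry(cl)
        assert geom.left_arm_bp == geom.right_arm_bp == 1000
        assert geom.log_ratio == 0.0
        assert geom.switch_point == 2500

    def test_non_single_switch_rejected(self, make_cluster):
        with pytest.raises(ValueError):
            switch_geometry(make_cluster("CCCC"))

    def test_variance_comparison_detects_asymmetry(self, make_cluster):
        def ss(left, right, sid, i):
            # arms spanning `left` and `right` bp, two mutations each
            pos = [1000, 1000 + left, 20_000, 20_000 + right]
            return make_cluster("CCGG", positions=pos, sample_id=sid, cluster_id=f"{sid}:{i}")

        sym = [ss(1000, 1000, "a", i) for i in range(3)]
        asym = [ss(100, 1000, "b", 0), ss(1000, 1000, "b", 1), ss(10_000, 1000, "b", 2)]
        table, comps = arm_ratio_variance(sym + asym, strata={"a": "sym", "b": "asym"})
        assert len(table) == 6
        row = comps.iloc[0]
        var_sym = row["var_a"] if row["stratum_a"] == "sym" else row["var_b"]
        var_asym = row["var_b"] if row["stratum_b"] == "asym" else row["var_a"]
        assert var_asym > var_sym
        assert np.allclose(
            table.loc[table["stratum"] == "sym", "log_ratio"], 0.0
        )
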