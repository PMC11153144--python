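import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phenolic.metrics import (
    GenusExpressionProfile,
    benjamini_hochberg,
    compare_by_saturation,
    correlate_with_bh,
    dominance,
    empirical_threshold,
    talent,
)


def _profile(genus, pathways_by_habitat=None, trophic=None):
    return GenusExpressionProfile(
        genus=genus,
        expressed_pathways={
            h: set(p) for h, p in (pathways_by_habitat or {}).items()
        },
        trophic_expression=dict(trophic or {}),
    )


# ---------------------------------------------------------------------------
# talent

@pytest.mark.parametrize(
    "counts_by_habitat, expected",
    [
        ({"bog": 20}, True),
        ({"palsa": 14, "bog": 14, "fen": 14}, False),
        ({"fen": 15}, True),  # threshold is inclusive ("at least 15")
    ],
)
def test_talent_threshold_applied_per_habitat(counts_by_habitat, expected):
    prof = _profile(
        "g", {h: range(n) for h, n in counts_by_habitat.items()}
    )
    res = talent([prof])["g"]
    assert res.talented is expected
    assert res.talent_count == max(counts_by_habitat.values())


def test_talent_is_or_over_habitats():
    prof = _profile("g", {"palsa": range(3), "bog": range(16)})
    res = talent([prof])["g"]
    assert res.talented_by_habitat == {"bog": True, "palsa": False}
    assert res.talented


# ---------------------------------------------------------------------------
# dominance

def _trophic(genus_share, total=100.0, habitats=("bog",), depths=("surface", "middle", "deep")):
    mine, others = {}, {}
    for h in habitats:
        for d in depths:
            mine[("monomer", h, d)] = genus_share * total
            others[("monomer", h, d)] = (1 - genus_share) * total
    return mine, others


@pytest.mark.parametrize("share, expected", [(0.12, True), (0.09, False), (0.10, True)])
def test_dominance_share_threshold_inclusive(share, expected):
    mine, others = _trophic(share)
    profs = [_profile("g", trophic=mine), _profile("rest", trophic=others)]
    res = dominance(profs)
    assert res["g"].dominant is expected
    assert res["g"].dominance_share == pytest.approx(share)


def test_single_genus_community_has_share_one():
    mine, _ = _trophic(1.0)
    res = dominance([_profile("g", trophic=mine)])
    assert res["g"].dominance_share == pytest.approx(1.0)
    assert res["g"].dominant


def test_share_is_averaged_over_depths_within_habitat():
    # 30% at one depth, 0% at the two others -> mean 10% -> dominant (>=)
    mine = {("monomer", "bog", "surface"): 30.0}
    others = {
        ("monomer", "bog", "surface"): 70.0,
        ("monomer", "bog", "middle"): 100.0,
        ("monomer", "bog", "deep"): 100.0,
    }
    res = dominance([_profile("g", trophic=mine), _profile("rest", trophic=others)])
    assert res["g"].dominance_share == pytest.approx(0.1)
    assert res["g"].dominant


def test_zero_total_stratum_excluded_with_warning():
    mine = {("monomer", "bog", "surface"): 5.0, ("monomer", "bog", "middle"): 0.0}
    others = {("monomer", "bog", "surface"): 5.0, ("monomer", "bog", "middle"): 0.0}
    with pytest.warns(UserWarning, match="zero total"):
        res = dominance([_profile("g", trophic=mine), _profile("rest", trophic=others)])
    assert res["g"].dominance_share == pytest.approx(0.5)  # only the live stratum


def test_flags_match_brute_force_on_random_tables(rng):
    habitats, depths = ("palsa", "bog", "fen"), ("surface", "middle", "deep")
    genera = [f"g{i}" for i in range(6)]
    for _ in range(10):
        profs = []
        raw = {}
        for g in genera:
            tro = {
                ("monomer", h, d): float(rng.integers(0, 50))
                for h in habitats
                for d in depths
            }
            raw[g] = tro
            profs.append(_profile(g, trophic=tro))
        res = dominance(profs, threshold=0.25)
        for g in genera:
            shares = []
            for h in habitats:
                per_depth = []
                for d in depths:
                    tot = sum(raw[x][("monomer", h, d)] for x in genera)
                    if tot > 0:
                        per_depth.append(raw[g][("monomer", h, d)] / tot)
                if per_depth:
                    shares.append(sum(per_depth) / len(per_depth))
            expect = any(s >= 0.25 for s in shares)
            assert res[g].dominant == expect


# ---------------------------------------------------------------------------
# empirical threshold

def test_constructed_distribution_yields_threshold_15():
    """100 genus counts with exactly 5 values >= 15 and 6 >= 14: the smallest
    value whose upper tail is <= 0.05 is 15."""
    values = [14] + [15, 16, 17, 18, 19] + [13] * 10 + [5] * 84
    assert len(values) == 100
    res = empirical_threshold(values, alpha=0.05)
    assert res.threshold == 15
    assert res.tail_fraction == 0.05
    assert res.attainable


def test_alpha_one_returns_minimum():
    res = empirical_threshold([3, 9, 1, 4], alpha=1.0)
    assert res.threshold == 1


def test_degenerate_distribution_flagged_unattainable():
    res = empirical_threshold([0, 0, 0, 0], alpha=0.05)
    assert not res.attainable
    assert res.threshold > 0


# ---------------------------------------------------------------------------
# rank-sum

def exact_ranksum_p(a, b):
    """Full enumeration oracle: two-sided p over all C(n+m, n) label splits."""
    pooled = sorted(a) + sorted(b)
    n = len(a)
    obs = sum(
        1
        for x in a
        for y in b
        if x > y
    ) + 0.5 * sum(1 for x in a for y in b if x == y)
    center = len(a) * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        grp = set(combo)
        u = sum(
            1
            for i in grp
            for j in range(len(pooled))
            if j not in grp and pooled[i] > pooled[j]
        ) + 0.5 * sum(
            1
            for i in grp
            for j in range(len(pooled))
            if j not in grp and pooled[i] == pooled[j]
        )
        total += 1
        if abs(u - center) >= abs(obs - center) - 1e-12:
            count += 1
    return count / total


def test_textbook_separation_p_is_one_tenth():
    res = compare_by_saturation(
        [1, 2, 3, 4, 5, 6], ["saturated"] * 3 + ["unsaturated"] * 3
    )
    assert res.p_value == pytest.approx(0.1)
    assert res.direction == "less"


def test_identical_groups_p_is_one():
    res = compare_by_saturation(
        [5, 7, 7, 5], ["saturated", "saturated", "unsaturated", "unsaturated"]
    )
    assert res.p_value == pytest.approx(1.0)


def test_large_shift_is_highly_significant(rng):
    a = rng.normal(0, 1, 20)
    b = rng.normal(50, 1, 20)
    res = compare_by_saturation(
        np.concatenate([a, b]), ["saturated"] * 20 + ["unsaturated"] * 20
    )
    assert res.p_value < 0.001


def test_empty_group_is_an_error():
    with pytest.raises(ValueError, match="unsaturated"):
        compare_by_saturation([1, 2], ["saturated", "saturated"])


@pytest.mark.parametrize("n, m", [(2, 2), (3, 3), (3, 5), (4, 4), (5, 6), (7, 7)])
def test_exact_path_matches_full_enumeration(n, m, rng):
    """Oracle sweep over small group sizes (tie-free draws)."""
    for _ in range(3):
        vals = rng.permutation(np.arange(1.0, n + m + 1))
        a, b = vals[:n], vals[n:]
        res = compare_by_saturation(
            np.concatenate([a, b]), ["saturated"] * n + ["unsaturated"] * m
        )
        assert res.p_value == pytest.approx(exact_ranksum_p(list(a), list(b)))


# ---------------------------------------------------------------------------
# BH-adjusted correlations

def test_bh_step_up_hand_example():
    """p = {0.01, 0.02, 0.03} over 3 tests: adjusted = {0.03, 0.03, 0.03}
    (0.01*3/1, 0.02*3/2, 0.03*3/3 then monotone from the largest down)."""
    adj = benjamini_hochberg([0.01, 0.02, 0.03])
    assert adj == pytest.approx([0.03, 0.03, 0.03])


def test_bh_monotone_and_capped():
    p = [0.001, 0.5, 0.04, 0.9, 0.012]
    adj = benjamini_hochberg(p)
    order = np.argsort(p)
    assert all(np.diff(adj[order]) >= -1e-12)
    assert adj.max() <= 1.0
    assert all(adj >= np.array(p) - 1e-12)


def _pair_rows(group, label, x, y):
    return pd.DataFrame({"group": group, "label": label, "x": x, "y": y})


def test_perfect_linear_pair_has_r_one():
    table = _pair_rows("g1", "lin", [1, 2, 3, 4], [2, 4, 6, 8])
    out = correlate_with_bh(table)
    assert out.loc[0, "r"] == pytest.approx(1.0)
    assert out.loc[0, "direction"] == "positive"


def test_zero_variance_variable_reported_undefined():
    table = _pair_rows("g1", "flat", [1, 2, 3, 4], [5, 5, 5, 5])
    out = correlate_with_bh(table)
    assert math.isnan(out.loc[0, "r"]) and math.isnan(out.loc[0, "p_adjusted"])


def test_group_split_changes_adjustment(rng):
    """BH within two declared groups differs from pooled adjustment: a
    middling p-value ranks first in its own small group but not overall."""
    x = np.arange(10.0)
    frames = []
    specs = [
        ("grpA", "strong", x, x + rng.normal(0, 0.1, 10)),
        ("grpA", "medium", x, x + rng.normal(0, 3.0, 10)),
        ("grpB", "weak", x, rng.normal(0, 1, 10)),
    ]
    for group, label, xs, ys in specs:
        frames.append(_pair_rows(group, label, xs, ys))
    split = correlate_with_bh(pd.concat(frames, ignore_index=True))
    pooled_input = pd.concat(frames, ignore_index=True).assign(group="all")
    pooled = correlate_with_bh(pooled_input)
    s = split.set_index("label")["p_adjusted"]
    p = pooled.set_index("label")["p_adjusted"]
    assert not np.allclose(s.to_numpy(), p.loc[s.index].to_numpy())


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError, match="3 complete pairs"):
        correlate_with_bh(_pair_rows("g", "short", [1, 2], [2, 1]))
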