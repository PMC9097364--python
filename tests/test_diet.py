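import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avidiet import diet
from avidiet.errors import AmbiguousDietError, ClassificationError


def _profile(**pct):
    base = {c: 0.0 for c in ("Inv", "Ect", "End", "Vunk", "Fish", "Scav",
                             "Fruit", "Nect", "Seed", "PlantO")}
    annotations = {}
    for k in ("fruit_hardness", "granivory_mode", "invert_hardness"):
        if k in pct:
            annotations[k] = pct.pop(k)
    base.update(pct)
    total = sum(base.values())
    if total < 100.0:  # fill with a neutral column for valid closure
        base["PlantO"] += 100.0 - total
    return diet.DietProfile(percentages=base, **annotations)


# ---------------------------------------------------------------------------
# Preprocessing


def test_tetrapods_merged():
    p = diet.preprocess_profile(_profile(Ect=30, End=30, PlantO=40))
    assert p.percentages["Tetr"] == 60
    assert p.percentages["Ect"] == 0 and p.percentages["End"] == 0


def test_unknown_vertebrate_split_evenly():
    p = diet.preprocess_profile(_profile(Vunk=20, Fish=40, Inv=40))
    assert p.percentages["Fish"] == 50
    assert p.percentages["Tetr"] == 10
    assert p.percentages["Vunk"] == 0


def test_no_vunk_is_identity():
    p0 = _profile(Fish=70, Inv=30)
    p = diet.preprocess_profile(p0)
    assert p.percentages["Fish"] == 70
    assert p.percentages["Tetr"] == 0


def test_profile_sum_validated():
    with pytest.raises(ValueError, match="sum"):
        diet.DietProfile(percentages={"Inv": 50.0})


# ---------------------------------------------------------------------------
# Classification


def test_hard_invertivore_standard():
    cat = diet.classify_diet(_profile(Inv=90, invert_hardness="hard"))
    assert cat.name == "InvertivoreH" and cat.specialist_level == "standard"


def test_piscivore_semi():
    p = _profile(Fish=55, Inv=45)
    assert diet.classify_diet(p, include_semi=False) is None
    cat = diet.classify_diet(p, include_semi=True)
    assert cat.name == "Piscivore" and cat.specialist_level == "semi"


def test_generalist_when_everything_small():
    cat = diet.classify_diet(_profile(Inv=30, Fish=30, Seed=30, Fruit=10))
    assert cat.name == "Generalist"


def test_tetrapod_hunter_via_merge():
    cat = diet.classify_diet(_profile(Ect=40, End=45, Inv=15))
    assert cat.name == "TetrapodHunter"


def test_ambiguous_semi_cutoffs_report_both():
    p = _profile(Fish=50, Scav=50)
    with pytest.raises(AmbiguousDietError) as err:
        diet.classify_diet(p, include_semi=True)
    assert set(err.value.categories) == {"Piscivore", "Scavenger"}


def test_granivore_modes():
    assert diet.classify_diet(_profile(Seed=95, granivory_mode="husk")).name == "GranivoreH"
    assert diet.classify_diet(_profile(Seed=95, granivory_mode="swallow")).name == "GranivoreS"
    with pytest.raises(ClassificationError):
        diet.classify_diet(_profile(Seed=95))


def test_semi_refines_standard():
    """Any standard classification is preserved when semi rules are enabled."""
    rows = [
        _profile(Inv=92, invert_hardness="medium"),
        _profile(Fish=75, Inv=25),
        _profile(PlantO=85),
        _profile(Scav=100),
        _profile(Inv=28, Fish=28, Seed=28, Fruit=16),
    ]
    for p in rows:
        std = diet.classify_diet(p, include_semi=False)
        both = diet.classify_diet(p, include_semi=True)
        assert std is not None
        assert both.name == std.name and both.specialist_level == "standard"


# ---------------------------------------------------------------------------
# Mass regression


def test_intercept_only():
    m = diet.SkeletalMeasures(HL=0, bcL=0, dHW=0, UL=0, dUW=0, TL=0)
    est = diet.enan_mass(m, log10_halfwidth=0.1)
    assert est.mean == pytest.approx(10 ** -2.626)
    assert est.lower == pytest.approx(10 ** -2.726)
    assert est.upper == pytest.approx(10 ** -2.526)


def test_ul_coefficient_direction():
    base = diet.SkeletalMeasures(HL=1, bcL=1, dHW=1, UL=1, dUW=1, TL=1)
    longer_ulna = diet.SkeletalMeasures(HL=1, bcL=1, dHW=1, UL=1 + np.log10(2),
                                        dUW=1, TL=1)
    ratio = diet.enan_mass(longer_ulna).mean / diet.enan_mass(base).mean
    assert np.log10(ratio) == pytest.approx(-1.451 * np.log10(2), rel=1e-12)


def test_longhand_arithmetic():
    vals = dict(HL=1.91, bcL=1.13, dHW=0.62, UL=1.95, dUW=0.70, TL=1.74)
    m = diet.SkeletalMeasures(**vals, correction=1.02)
    lp = (-2.626 + 1.528 * vals["HL"] + 0.34 * vals["bcL"] + 0.828 * vals["dHW"]
          - 1.451 * vals["UL"] + 0.811 * vals["dUW"] + 0.378 * vals["TL"])
    est = diet.enan_mass(m, unit_to_g=1000.0)
    assert est.mean == pytest.approx(1.02 * 10 ** lp * 1000.0, rel=1e-12)


def test_mean_lower_ratio_default():
    m = diet.SkeletalMeasures(HL=2, bcL=1, dHW=1, UL=1, dUW=1, TL=1)
    est = diet.enan_mass(m)
    assert est.mean / est.lower == pytest.approx(1.25, rel=1e-9)


def test_aggregate_mass_rules():
    assert diet.aggregate_mass(sex_masses=[100, 140]) == 120
    assert diet.aggregate_mass(population_masses=[100, 200],
                               population_counts=[3, 1]) == 125
    assert diet.aggregate_mass(min_max=(80, 120)) == 100
    with pytest.raises(ValueError):
        diet.aggregate_mass()


# ---------------------------------------------------------------------------
# Youden cut-points


def _brute_force_youden(masses, labels):
    """Exhaustive oracle: evaluate J at every midpoint by direct counting."""
    x = np.log10(np.asarray(masses, dtype=float))
    labs = np.asarray(labels)
    uniq = sorted(set(labs))
    m0 = x[labs == uniq[0]].mean()
    m1 = x[labs == uniq[1]].mean()
    pos_label = uniq[1] if m1 >= m0 else uniq[0]
    xs = np.unique(x)
    best_j, best = -2.0, []
    for t in 0.5 * (xs[:-1] + xs[1:]):
        tp = sum(1 for xi, li in zip(x, labs) if li == pos_label and xi > t)
        fn = sum(1 for xi, li in zip(x, labs) if li == pos_label and xi <= t)
        tn = sum(1 for xi, li in zip(x, labs) if li != pos_label and xi <= t)
        fp = sum(1 for xi, li in zip(x, labs) if li != pos_label and xi > t)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if j > best_j + 1e-12:
            best_j, best = j, [t]
        elif abs(j - best_j) <= 1e-12:
            best.append(t)
    return sorted(10 ** np.array(best)), best_j


def test_perfect_separation():
    res = diet.youden_cutpoints([10, 20, 30, 1000, 2000], ["i", "i", "i", "v", "v"])
    assert res.youden_j == pytest.approx(1.0)
    assert len(res.thresholds_g) == 1
    assert 30 < res.thresholds_g[0] < 1000


def test_identical_distributions_give_zero_j():
    masses = [10, 20, 30, 40, 10, 20, 30, 40]
    labels = ["a"] * 4 + ["b"] * 4
    res = diet.youden_cutpoints(masses, labels)
    assert res.youden_j == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(50))
def test_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 60))
    labels = rng.choice(["a", "b"], size=n)
    if len(set(labels)) < 2:
        labels[0] = "a"
        labels[1] = "b"
    masses = rng.lognormal(mean=np.where(labels == "b", 5.0, 4.0), sigma=1.0)
    res = diet.youden_cutpoints(masses, labels)
    want_t, want_j = _brute_force_youden(masses, labels)
    assert res.youden_j == pytest.approx(want_j, abs=1e-12)
    np.testing.assert_allclose(res.thresholds_g, want_t, rtol=1e-9)


def test_multiple_optima_returned():
    # two separated clumps of the positive class around the negatives
    masses = [10, 100, 1000]
    labels = ["neg", "pos", "pos"]
    res = diet.youden_cutpoints(masses, labels)
    assert res.youden_j == pytest.approx(1.0)
    # interleaved guilds: two thresholds tie at the optimum
    masses = [10, 100, 50, 1000]
    labels = ["neg", "neg", "pos", "pos"]
    res = diet.youden_cutpoints(masses, labels)
    assert res.youden_j == pytest.approx(0.5)
    assert len(res.thresholds_g) == 2
    assert res.thresholds_g[0] < 100 < res.thresholds_g[1]


def test_sensitivity_specificity_sum_identity():
    rng = np.random.default_rng(7)
    labels = np.array(["a"] * 30 + ["b"] * 30)
    masses = rng.lognormal(np.where(labels == "b", 5.5, 4.0), 0.7)
    res = diet.youden_cutpoints(masses, labels)
    t = np.log10(res.thresholds_g[0])
    x = np.log10(masses)
    pos = labels == "b"
    sens = np.sum(pos & (x > t)) / pos.sum()
    spec = np.sum(~pos & (x <= t)) / (~pos).sum()
    assert sens + spec == pytest.approx(1 + res.youden_j)


@given(st.floats(0.5, 3.0), st.integers(0, 1000))
@settings(max_examples=25, deadline=None)
def test_rank_invariance_under_power_transform(power, seed):
    """J and the bracketing order statistics survive monotone transforms."""
    rng = np.random.default_rng(seed)
    labels = np.array(["a"] * 15 + ["b"] * 15)
    masses = rng.lognormal(np.where(labels == "b", 5.0, 3.5), 0.8)
    res1 = diet.youden_cutpoints(masses, labels)
    res2 = diet.youden_cutpoints(masses ** power, labels)
    assert res1.youden_j == pytest.approx(res2.youden_j, abs=1e-12)
    assert len(res1.thresholds_g) == len(res2.thresholds_g)
    srt = np.sort(masses)
    for t1, t2 in zip(res1.thresholds_g, res2.thresholds_g):
        below1 = np.searchsorted(srt, t1)
        below2 = np.searchsorted(np.sort(masses ** power), t2)
        assert below1 == below2


def test_single_class_rejected():
    with pytest.raises(ClassificationError):
        diet.youden_cutpoints([1, 2, 3], ["a", "a", "a"])


# ---------------------------------------------------------------------------
# Mass rules


def test_small_upper_bound_excludes_vertivory_and_folfrug():
    est = diet.MassEstimate(mean=206, lower=166, upper=246)
    exc = diet.mass_rule(est)
    assert exc == (diet.VERTIVORE_CATEGORIES | diet.FOLFRUG_CATEGORIES)


def test_straddling_range_excludes_nothing():
    est = diet.MassEstimate(mean=340, lower=274, upper=406)
    assert diet.mass_rule(est) == set()


def test_large_lower_bound_excludes_small_bodied_diets():
    est = diet.MassEstimate(mean=600, lower=500, upper=700)
    exc = diet.mass_rule(est)
    assert exc == (diet.INVERTIVORE_CATEGORIES | diet.GRANNECT_CATEGORIES)
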