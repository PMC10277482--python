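import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cld4 import (CriteriaConfig, Criterion, FeatureTable, compute_micl,
                  default_criteria, normalize_weights, rate_criterion,
                  select_top)
from cld4.micl import DegenerateCriterionError


def test_rating_extremes_match_campaign_best_and_worst():
    # titres spanning 1.2 to 6.3 g/L: worst rates 0, best rates 1
    titres = pd.Series({"C30": 1.2, "C19": 6.3, "Cmid": 3.75})
    r = rate_criterion(titres, "max_is_best")
    assert r["C30"] == 0.0 and r["C19"] == 1.0
    assert r["Cmid"] == pytest.approx(0.5)  # midway value rates 0.5


def test_reverse_rated_criterion_swaps_best_and_worst():
    lact = pd.Series({"C06": 0.3, "C15": 7.0})
    r = rate_criterion(lact, "min_is_best")
    assert r["C06"] == 1.0 and r["C15"] == 0.0


def test_degenerate_criterion_raises():
    with pytest.raises(DegenerateCriterionError):
        rate_criterion(pd.Series([2.0, 2.0, 2.0]), "max_is_best")


def test_weight_normalisation():
    crits = [Criterion(f"c{i}", f"f{i}", "max_is_best", 1.0)
             for i in range(19)]
    crits.append(Criterion("tsb", "ftsb", "min_is_best", 3.0))
    w = normalize_weights(crits)
    assert w["tsb"] == pytest.approx(3 / 22)
    assert w.sum() == pytest.approx(1.0)
    assert normalize_weights(crits[:1]).iloc[0] == 1.0
    equal = normalize_weights(crits[:4])
    assert np.allclose(equal, 0.25)
    with pytest.raises(ValueError):
        normalize_weights([Criterion("z", "f", "max_is_best", 0.0)])


def _toy_table():
    return FeatureTable(pd.DataFrame(
        {"titre": [1.0, 3.0, 5.0], "lactate": [4.0, 1.0, 2.0]},
        index=["A", "B", "C"]))


def _toy_config(w_titre=1.0, w_lact=2.0):
    return CriteriaConfig([
        Criterion("Titre", "titre", "max_is_best", w_titre),
        Criterion("Lactate", "lactate", "min_is_best", w_lact)])


def _brute_force_micl(values, directions, weights):
    """Independent spreadsheet-style oracle for the weighted-sum index."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    scores = []
    for i in range(values.shape[0]):
        total = 0.0
        for j in range(values.shape[1]):
            col = values[:, j]
            best = col.max() if directions[j] == "max_is_best" else col.min()
            worst = col.min() if directions[j] == "max_is_best" else col.max()
            total += w[j] * (values[i, j] - worst) / (best - worst)
        scores.append(total)
    return np.array(scores)


def test_micl_matches_brute_force_oracle_on_toy_table():
    table, config = _toy_table(), _toy_config()
    result = compute_micl(table, config)
    expected = _brute_force_micl(table.values.to_numpy(),
                                 ["max_is_best", "min_is_best"], [1.0, 2.0])
    assert np.allclose(result.scores[table.clone_ids], expected)


def test_all_best_clone_scores_one_and_all_worst_zero():
    table = FeatureTable(pd.DataFrame(
        {"titre": [5.0, 1.0, 3.0], "lactate": [0.5, 6.0, 3.0]},
        index=["best", "worst", "mid"]))
    result = compute_micl(table, _toy_config())
    assert result.scores["best"] == pytest.approx(1.0)
    assert result.scores["worst"] == pytest.approx(0.0)
    assert result.ranking[0] == "best"


def test_degenerate_criterion_excluded_and_weights_renormalised():
    table = FeatureTable(pd.DataFrame(
        {"titre": [1.0, 2.0], "flat": [3.0, 3.0]}, index=["A", "B"]))
    config = CriteriaConfig([
        Criterion("Titre", "titre", "max_is_best", 1.0),
        Criterion("Flat", "flat", "max_is_best", 5.0)])
    result = compute_micl(table, config)
    assert result.excluded_criteria == ["Flat"]
    assert result.weights.sum() == pytest.approx(1.0)
    assert result.scores["B"] == pytest.approx(1.0)


def test_missing_value_renormalises_and_flags_clone():
    table = FeatureTable(pd.DataFrame(
        {"titre": [1.0, 2.0, 3.0], "lactate": [5.0, np.nan, 1.0]},
        index=["A", "B", "C"]))
    result = compute_micl(table, _toy_config(1.0, 1.0))
    assert result.incomplete_clones == ["B"]
    # B's score uses the titre rating alone
    assert result.scores["B"] == pytest.approx(0.5)
    assert 0.0 <= result.scores.min() and result.scores.max() <= 1.0


def test_all_criteria_degenerate_is_an_error():
    table = FeatureTable(pd.DataFrame({"flat": [1.0, 1.0]}, index=["A", "B"]))
    config = CriteriaConfig([Criterion("Flat", "flat", "max_is_best", 1.0)])
    with pytest.raises(ValueError):
        compute_micl(table, config)


def test_improving_one_value_never_lowers_the_score():
    table, config = _toy_table(), _toy_config()
    base = compute_micl(table, config).scores["A"]
    better = _toy_table()
    better.values.loc["A", "titre"] = 2.0  # toward best, still interior
    assert compute_micl(better, config).scores["A"] >= base


def test_affine_rescaling_leaves_ratings_unchanged():
    table, config = _toy_table(), _toy_config()
    ratings = compute_micl(table, config).ratings
    scaled = _toy_table()
    scaled.values["titre"] = scaled.values["titre"] * 3.7 - 12.0
    assert np.allclose(compute_micl(scaled, config).ratings, ratings)


def test_zero_weight_criterion_is_neutral():
    table = _toy_table()
    base = compute_micl(table, _toy_config()).scores
    extended = CriteriaConfig(_toy_config().criteria + [
        Criterion("Extra", "titre", "min_is_best", 0.0)])
    assert np.allclose(compute_micl(table, extended).scores, base)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_random_tables_keep_scores_and_ratings_bounded(seed):
    rng = np.random.default_rng(seed)
    n, m = rng.integers(2, 12), rng.integers(1, 8)
    values = rng.normal(0, 10, (n, m)) * rng.lognormal(0, 1, m)
    df = pd.DataFrame(values, columns=[f"f{j}" for j in range(m)],
                      index=[f"C{i}" for i in range(n)])
    config = CriteriaConfig([
        Criterion(f"c{j}", f"f{j}",
                  "max_is_best" if rng.random() < 0.5 else "min_is_best",
                  float(rng.uniform(0.1, 5)))
        for j in range(m)])
    result = compute_micl(FeatureTable(df), config)
    assert ((result.ratings >= -1e-12) & (result.ratings <= 1 + 1e-12)).all().all()
    assert (result.scores >= -1e-12).all() and (result.scores <= 1 + 1e-12).all()


def test_ties_break_lexicographically_by_clone_id():
    table = FeatureTable(pd.DataFrame(
        {"titre": [1.0, 1.0, 2.0]}, index=["B", "A", "C"]))
    config = CriteriaConfig([Criterion("T", "titre", "max_is_best", 1.0)])
    assert compute_micl(table, config).ranking == ["C", "A", "B"]


def test_select_top_contract():
    result = compute_micl(_toy_table(), _toy_config())
    assert select_top(result, 3) == result.ranking
    assert select_top(result, 0) == []
    with pytest.raises(ValueError):
        select_top(result, 4)


def test_default_registry_has_20_criteria_with_tsb_weight_3():
    config = default_criteria()
    assert len(config.criteria) == 20
    tsb = [c for c in config.criteria if c.feature == "TSB:end_point"][0]
    assert tsb.raw_weight == 3.0 and tsb.direction == "min_is_best"
    reversed_feats = {c.feature for c in config.criteria
                      if c.direction == "min_is_best"}
    assert {"Lactate:max", "Lactate:avg", "Lactate:end_point",
            "Aggregate:end_point", "Fragment:end_point",
            "TSB:end_point"} == reversed_feats
    assert config.weights().sum() == pytest.approx(1.0)
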