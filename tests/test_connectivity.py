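"""Weighted-KS scoring, WTCS combination, aggregation and candidate selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import reposyn as r
from reposyn import InputError, QuerySignature
from reposyn.simulate import SignatureCompendium


def _series(scores: dict) -> pd.Series:
    return pd.Series(scores, dtype=float)


def _ranked(scores: dict) -> pd.Series:
    s = _series(scores)
    return s.loc[r.rank_profile(s)]


def _es_oracle(ranked_scores, gene_set, w):
    """Straight-line running-sum reference implementation (loop form)."""
    genes = list(ranked_scores.index)
    scores = list(ranked_scores.to_numpy())
    hits = [g in gene_set for g in genes]
    nh = sum(hits)
    nr = sum(abs(s) ** w for s, h in zip(scores, hits) if h) if w else nh
    best, run = 0.0, 0.0
    for s, h in zip(scores, hits):
        if h:
            run += (abs(s) ** w / nr) if w else 1.0 / nh
        else:
            run -= 1.0 / (len(genes) - nh)
        if abs(run) > abs(best):
            best = run
    return best


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def test_rank_profile_descending_with_gene_id_tiebreak():
    assert list(r.rank_profile(_series({"a": 2, "b": 1, "c": 3}))) == ["c", "a", "b"]
    assert list(r.rank_profile(_series({"b": 1, "a": 1}))) == ["a", "b"]


def test_rank_profile_order_invariant_to_input_permutation():
    s = _series({"a": 1.0, "b": 3.0, "c": 2.0, "d": 3.0})
    assert list(r.rank_profile(s)) == list(r.rank_profile(s.sample(frac=1, random_state=0)))


def test_rank_profile_rejects_missing_scores():
    with pytest.raises(InputError):
        r.rank_profile(pd.Series({"a": 1.0, "b": np.nan}))


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def test_top_set_es_plus_one_bottom_set_minus_one():
    ranked = _ranked({f"g{i}": 10 - i for i in range(10)})
    assert r.enrichment_score(ranked, {"g0", "g1"}, w=0) == pytest.approx(1.0)
    assert r.enrichment_score(ranked, {"g8", "g9"}, w=0) == pytest.approx(-1.0)


def test_es_matches_loop_oracle_on_random_profiles():
    rng = np.random.default_rng(1)
    for w in (0.0, 1.0):
        for _ in range(20):
            n = 40
            s = pd.Series(rng.normal(size=n), index=[f"g{i:02d}" for i in range(n)])
            ranked = s.loc[r.rank_profile(s)]
            gene_set = set(rng.choice(s.index, size=8, replace=False))
            assert r.enrichment_score(ranked, gene_set, w) == pytest.approx(
                _es_oracle(ranked, gene_set, w), abs=1e-12)


def test_es_null_distribution_symmetric_about_zero():
    """Classic KS form (w=0): random sets give a signed-max statistic that is
    exactly antisymmetric, so the null mean is 0. (The weighted form w=1 is
    deliberately not symmetric on a null profile: weight concentrates at both
    extremes of the ranking and the long low-weight middle drift dominates
    the signed maximum.)"""
    rng = np.random.default_rng(7)
    n, draws = 1000, 2000
    s = pd.Series(rng.normal(size=n), index=[f"g{i:04d}" for i in range(n)])
    ranked = s.loc[r.rank_profile(s)]
    es = np.array([r.enrichment_score(ranked, set(rng.choice(s.index, 50, replace=False)), w=0)
                   for _ in range(draws)])
    se = es.std(ddof=1) / np.sqrt(draws)
    assert abs(es.mean()) < 4 * se


def test_es_antisymmetric_under_list_reversal_w0():
    rng = np.random.default_rng(2)
    s = pd.Series(rng.normal(size=30), index=[f"g{i:02d}" for i in range(30)])
    ranked = s.loc[r.rank_profile(s)]
    gene_set = set(rng.choice(s.index, 6, replace=False))
    fwd = r.enrichment_score(ranked, gene_set, w=0)
    rev = r.enrichment_score(ranked.iloc[::-1], gene_set, w=0)
    assert fwd == pytest.approx(-rev, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.sampled_from([0.0, 1.0]))
def test_es_always_within_unit_interval(seed, w):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 60))
    s = pd.Series(rng.normal(size=n), index=[f"g{i:02d}" for i in range(n)])
    ranked = s.loc[r.rank_profile(s)]
    k = int(rng.integers(1, n))
    gene_set = set(rng.choice(s.index, size=k, replace=False))
    es = r.enrichment_score(ranked, gene_set, w)
    assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12


def test_es_empty_intersection_flagged_not_zero():
    ranked = _ranked({"a": 1.0, "b": 0.5})
    with pytest.raises(InputError):
        r.enrichment_score(ranked, {"zzz"}, w=0)


# ---------------------------------------------------------------------------
# WTCS
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("eu,ed,expected", [
    (0.8, -0.6, 0.7),     # opposite signs: average of magnitudes with sign
    (0.5, 0.3, 0.0),      # same sign: no connectivity
    (-1.0, 1.0, -1.0),    # perfect reverser
    (-0.5, -0.3, 0.0),
    (0.0, 0.4, 0.0),      # zero is not opposite-signed
])
def test_wtcs_combination_rule(eu, ed, expected):
    assert r.wtcs(eu, ed) == pytest.approx(expected)


def test_wtcs_one_tailed_passthrough():
    assert r.wtcs(-0.4, None) == pytest.approx(-0.4)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _toy_compendium(per_condition_profiles: dict, meta_rows: list) -> SignatureCompendium:
    profiles = pd.DataFrame(per_condition_profiles)
    meta = pd.DataFrame(meta_rows).set_index("condition_id", drop=False)
    return SignatureCompendium(profiles, meta.loc[profiles.columns])


def test_rs_is_mean_of_cell_line_means(small_config):
    comp = r.simulate_compendium(small_config)
    up, down = r.planted_core_genes(small_config)
    res = r.score_and_aggregate(QuerySignature(set(up), set(down)), comp)
    cond = res.conditions
    for pert, row in res.perturbagens.iterrows():
        sub = cond[cond["perturbagen"] == pert]
        expected = sub.groupby("cell_line")["wtcs"].mean().mean()
        assert row["rs"] == pytest.approx(expected, abs=1e-12)
        assert row["n_conditions"] == len(sub)
        assert -1.0 <= row["rs"] <= 1.0


def test_rs_worked_example_mean_of_means():
    # cell line A scores {-0.4, -0.2}, cell line B {-0.5} -> RS = -0.4
    wtcs_by_cell = pd.Series([-0.4, -0.2, -0.5])
    cells = pd.Series(["A", "A", "B"])
    rs = wtcs_by_cell.groupby(cells).mean().mean()
    assert rs == pytest.approx(-0.4)


def test_rs_invariant_to_within_cell_line_duplication(small_config):
    comp = r.simulate_compendium(small_config)
    up, down = r.planted_core_genes(small_config)
    query = QuerySignature(set(up), set(down))
    base = r.score_and_aggregate(query, comp)

    pert = small_config.reverser_ids[0]
    meta = comp.metadata
    cl = meta.loc[meta["perturbagen"] == pert, "cell_line"].iloc[0]
    dup_ids = meta.index[(meta["perturbagen"] == pert) & (meta["cell_line"] == cl)]
    dup_profiles = comp.profiles[dup_ids].copy()
    dup_profiles.columns = [f"{c}_dup" for c in dup_ids]
    dup_meta = meta.loc[dup_ids].copy()
    dup_meta["condition_id"] = dup_profiles.columns
    dup_meta = dup_meta.set_index("condition_id", drop=False)
    bigger = SignatureCompendium(
        pd.concat([comp.profiles, dup_profiles], axis=1),
        pd.concat([meta, dup_meta]))

    dup = r.score_and_aggregate(query, bigger)
    assert dup.perturbagens.loc[pert, "rs"] == pytest.approx(
        base.perturbagens.loc[pert, "rs"], abs=1e-12)
    assert dup.perturbagens.loc[pert, "n_conditions"] == \
        base.perturbagens.loc[pert, "n_conditions"] + len(dup_ids)


def test_query_genes_absent_from_compendium_dropped_with_count(small_config):
    comp = r.simulate_compendium(small_config)
    up, down = r.planted_core_genes(small_config)
    query = QuerySignature(set(up) | {"NOT_A_GENE"}, set(down))
    res = r.score_and_aggregate(query, comp)
    assert res.dropped_query_genes == 1


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------

def _result_from_rows(rows):
    perts = pd.DataFrame(rows).set_index("perturbagen")
    return r.ConnectivityResult(pd.DataFrame(), perts)


def test_selection_boundaries_are_strict():
    res = _result_from_rows([
        {"perturbagen": "exactly10", "rs": -0.9, "n_conditions": 10, "n_cell_lines": 2},
        {"perturbagen": "eleven", "rs": -0.35, "n_conditions": 12, "n_cell_lines": 3},
        {"perturbagen": "exactly_rs", "rs": -0.3, "n_conditions": 12, "n_cell_lines": 3},
        {"perturbagen": "weak", "rs": -0.1, "n_conditions": 12, "n_cell_lines": 3},
    ])
    tbl = r.select_candidates(res)
    assert tbl.loc["exactly10", "reason"] == "too_few_conditions"
    assert not tbl.loc["exactly10", "selected"]
    assert tbl.loc["eleven", "selected"]
    assert not tbl.loc["exactly_rs", "selected"]        # strict inequality
    assert tbl.loc["exactly_rs", "reason"] == "score_above_threshold"
    selected = tbl[tbl["selected"]]
    assert selected["rs"].is_monotonic_increasing


def test_planted_reversers_and_only_them_selected(small_config):
    comp = r.simulate_compendium(small_config)
    up, down = r.planted_core_genes(small_config)
    res = r.score_and_aggregate(QuerySignature(set(up), set(down)), comp)
    tbl = r.select_candidates(res)
    assert set(tbl.index[tbl["selected"]]) == set(small_config.reverser_ids)


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def test_permutation_p_for_maximum_statistic():
    rng = np.random.default_rng(0)
    s = pd.Series(rng.normal(size=200), index=[f"g{i:03d}" for i in range(200)])
    ranked = s.loc[r.rank_profile(s)]
    p = r.permutation_null(ranked, set_size=10, es_obs=1.0, w=0, n_perm=199, seed=1)
    assert p == pytest.approx(1.0 / 200.0)
    p0 = r.permutation_null(ranked, set_size=10, es_obs=0.0, w=0, n_perm=199, seed=1)
    assert p0 == pytest.approx(1.0, abs=0.01)


def test_permutation_p_deterministic_and_consistent_across_depth():
    rng = np.random.default_rng(3)
    s = pd.Series(rng.normal(size=300), index=[f"g{i:03d}" for i in range(300)])
    ranked = s.loc[r.rank_profile(s)]
    es_obs = 0.35
    p1 = r.permutation_null(ranked, 20, es_obs, w=1, n_perm=999, seed=5)
    p1b = r.permutation_null(ranked, 20, es_obs, w=1, n_perm=999, seed=5)
    assert p1 == p1b
    p2 = r.permutation_null(ranked, 20, es_obs, w=1, n_perm=4999, seed=6)
    # binomial agreement between shallow and deep estimates
    se = np.sqrt(p2 * (1 - p2) / 999)
    assert abs(p1 - p2) < 4 * se + 2e-3


def test_permutation_null_validates_inputs():
    s = pd.Series([1.0, 0.5], index=["a", "b"])
    with pytest.raises(InputError):
        r.permutation_null(s, set_size=2, es_obs=0.5, n_perm=200, seed=0)
    with pytest.raises(InputError):
        r.permutation_null(s, set_size=1, es_obs=0.5, n_perm=10, seed=0)
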