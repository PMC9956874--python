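"""Permutation-null engine: enumeration oracle, degeneracies, calibration."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import exomatch as em
from exomatch.io import ProteinRecord


def _pc(seq_by_iso, genes=None):
    recs = [
        ProteinRecord(i, (genes or {}).get(i, i), s) for i, s in seq_by_iso.items()
    ]
    return em.count_isoform_aas(recs)


def _expr(pc, values, columns=("r1",)):
    arr = np.atleast_2d(np.asarray(values, float))
    if arr.shape[0] != pc.n_isoforms:
        arr = arr.T
    return pd.DataFrame(arr, index=pd.Index(pc.isoform_ids, name="isoform_id"), columns=list(columns))


@pytest.fixture(scope="module")
def three_iso():
    pc = _pc({"i1": "MW", "i2": "MMMW", "i3": "AAAG"})
    return pc, _expr(pc, [3.0, 2.0, 1.0])


def test_exhaustive_matches_brute_force_enumeration(three_iso):
    pc, expr = three_iso
    res = em.permute_null(pc, expr, seed=0, exhaustive=True)
    assert res.n_perm == 6

    counts = pc.counts.to_numpy(float)
    profiles = []
    for perm in itertools.permutations([3.0, 2.0, 1.0]):
        weighted = sum(e * c for e, c in zip(perm, counts))
        profiles.append(weighted / weighted.sum())
    profiles = np.asarray(profiles)
    med = np.median(profiles, axis=0)
    expected = np.linalg.norm(profiles - med, axis=1)
    assert np.array_equal(np.sort(res.distances), np.sort(expected))
    assert np.allclose(res.median, med, atol=0)


def test_uniform_expression_gives_degenerate_null(three_iso):
    pc, _ = three_iso
    expr = _expr(pc, [2.0, 2.0, 2.0])
    res = em.permute_null(pc, expr, n_perm=50, seed=1)
    assert np.all(res.distances == 0)


def test_identical_compositions_give_degenerate_null():
    pc = _pc({"i1": "MWMW", "i2": "MW", "i3": "MWMWMW"})
    expr = _expr(pc, [5.0, 1.0, 0.5])
    res = em.permute_null(pc, expr, n_perm=50, seed=2)
    common = em.normalize({"M": 1, "W": 1}).values
    assert np.allclose(res.profiles, common, atol=1e-12)
    assert np.all(res.distances == 0)


def test_permutation_preserves_expression_multiset(three_iso):
    pc, expr = three_iso
    C, e, names = em.permutation._entity_matrix(pc, expr, "isoform", None)
    rng = np.random.default_rng(3)
    perms = rng.permuted(np.tile(e, (200, 1)), axis=1)
    for row in perms:
        assert sorted(row) == sorted(e)


def test_gene_level_moves_isoforms_together():
    pc = _pc(
        {"a1": "MW", "a2": "MMMW", "b1": "AAAG"},
        genes={"a1": "gA", "a2": "gA", "b1": "gB"},
    )
    expr = _expr(pc, [2.0, 1.0, 4.0])
    C, e, names = em.permutation._entity_matrix(pc, expr, "gene", None)
    assert names == ["gA", "gB"]
    assert e == pytest.approx([3.0, 4.0])
    # gene A keeps its internal 2:1 isoform weighting
    expected_gA = (2 / 3) * pc.counts.loc["a1"].to_numpy() + (1 / 3) * pc.counts.loc["a2"].to_numpy()
    assert np.allclose(C[0], expected_gA)


def test_gene_level_null_differs_from_isoform_level(small_fixture):
    fx, pc = small_fixture
    rg = em.permute_null(pc, fx.expression, n_perm=64, seed=4, level="gene")
    ri = em.permute_null(pc, fx.expression, n_perm=64, seed=4, level="isoform")
    assert rg.profiles.shape == ri.profiles.shape == (64, 20)
    assert not np.allclose(rg.distances, ri.distances)


def test_reproducible_for_fixed_seed(small_fixture):
    fx, pc = small_fixture
    a = em.permute_null(pc, fx.expression, n_perm=100, seed=7)
    b = em.permute_null(pc, fx.expression, n_perm=100, seed=7)
    assert np.array_equal(a.distances, b.distances)
    c = em.permute_null(pc, fx.expression, n_perm=100, seed=8)
    assert not np.array_equal(a.distances, c.distances)


def test_percentile_trivial_and_rank_oracle(three_iso):
    pc, expr = three_iso
    res = em.permute_null(pc, expr, seed=5, exhaustive=True)
    at_median = em.normalize(res.median)
    assert em.percentile_of(res, at_median) == 0.0
    far = em.AAProfile.from_mapping({"C": 1.0}, "far")
    assert em.percentile_of(res, far, label="far") == 100.0
    assert res.observed["far"].percentile == 100.0
    # rank oracle: percentile of each permuted profile equals its strict rank
    for k in range(res.n_perm):
        prof = em.normalize(res.profiles[k])
        expect = 100.0 * np.sum(res.distances < res.distances[k]) / res.n_perm
        assert em.percentile_of(res, prof) == pytest.approx(expect)


def test_single_entity_or_zero_perms_rejected():
    pc = _pc({"i1": "MW"})
    expr = _expr(pc, [1.0])
    with pytest.raises(ValueError, match="two entities"):
        em.permute_null(pc, expr, n_perm=5, seed=0)
    pc2 = _pc({"i1": "MW", "i2": "AAAG"})
    with pytest.raises(ValueError, match="n_perm"):
        em.permute_null(pc2, _expr(pc2, [1.0, 2.0]), n_perm=0, seed=0)


def test_per_aa_summary_quantiles_match_order_statistics(small_fixture):
    fx, pc = small_fixture
    res = em.permute_null(pc, fx.expression, n_perm=200, seed=9)
    obs = em.weighted_profile(pc, fx.expression)
    em.percentile_of(res, obs, label="obs")
    df = em.per_aa_null_summary(res).set_index("aa")
    for i, aa in enumerate(em.AMINO_ACIDS):
        col = np.sort(res.profiles[:, i])
        assert df.loc[aa, "median"] == pytest.approx(np.median(col))
        assert df.loc[aa, "q1"] == pytest.approx(np.quantile(col, 0.25))
        assert df.loc[aa, "q3"] == pytest.approx(np.quantile(col, 0.75))
        iqr = df.loc[aa, "q3"] - df.loc[aa, "q1"]
        assert df.loc[aa, "upper_fence"] == pytest.approx(df.loc[aa, "q3"] + 1.5 * iqr)
        assert df.loc[aa, "observed_obs"] == pytest.approx(obs.values[i])


def test_per_aa_summary_degenerate_null_zero_width(three_iso):
    pc, _ = three_iso
    res = em.permute_null(pc, _expr(pc, [1.0, 1.0, 1.0]), n_perm=30, seed=10)
    df = em.per_aa_null_summary(res)
    assert np.allclose(df["q3"] - df["q1"], 0.0)


def test_null_member_lies_within_null_range(small_fixture):
    fx, pc = small_fixture
    res = em.permute_null(pc, fx.expression, n_perm=100, seed=11)
    k = 37
    prof = em.normalize(res.profiles[k])
    df = em.per_aa_null_summary(res)
    for i in range(20):
        assert df["min"][i] - 1e-12 <= prof.values[i] <= df["max"][i] + 1e-12


def test_calibration_percentiles_roughly_uniform(small_fixture):
    """A null-generated 'observed' profile should have a uniform percentile."""
    fx, pc = small_fixture
    pct = em.calibration_percentiles(pc, fx.expression, n_trials=400, n_perm=200, seed=12)
    assert ((0 <= pct) & (pct <= 100)).all()
    ks = stats.kstest(pct / 100.0, "uniform").statistic
    assert ks < 0.08  # coarse: 400 trials, +/- Monte-Carlo error
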