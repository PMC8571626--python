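"""PERMANOVA, ANOVA-on-distances and IndVal.g against independent oracles."""

import itertools
import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from skbio import DistanceMatrix

from microstab import (FeatureTable, bray_curtis, distance_group_test, indval,
                       permanova, to_relative)
from microstab.diversity import write_distance_matrix
from tests.conftest import make_metadata, random_counts_table


def _meta_for(ids, **columns):
    rows = []
    for i, sid in enumerate(ids):
        row = {"sample_id": sid, "niche": "endo", "treatment": "control",
               "timepoint": "T0", "experiment": "e1", "replicate": f"r{i}"}
        for col, values in columns.items():
            row[col] = values[i]
        rows.append(row)
    return make_metadata(rows)


# ------------------------------------------------------------------ PERMANOVA

def test_permanova_ss_decomposition_and_r2():
    rng = np.random.default_rng(11)
    table = random_counts_table(rng, n_features=20, n_samples=12)
    dm = bray_curtis(to_relative(table))
    meta = _meta_for(dm.ids,
                     treatment=["control"] * 6 + ["nutrient"] * 6,
                     timepoint=["T0", "T1", "T2"] * 4)
    res = permanova(dm, meta, terms=["treatment", "timepoint"], n_perm=99, seed=1)
    t = res.table
    assert t.loc["Total", "SS"] == pytest.approx(
        t.drop("Total").loc[:, "SS"].sum(), abs=1e-9)
    assert t["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)
    assert ((t["p"].dropna() > 0) & (t["p"].dropna() <= 1)).all()
    assert (t["p"].dropna() >= 1 / (1 + 99) - 1e-12).all()


def test_permanova_duplicated_groups_zero_between_ss():
    """Group B holding exact copies of group A's samples → SS_between ≈ 0, F ≈ 0."""
    rng = np.random.default_rng(13)
    base = rng.integers(1, 40, size=(15, 3)).astype(float)
    data = np.hstack([base, base])
    table = FeatureTable(pd.DataFrame(
        data, index=[f"f{i}" for i in range(15)],
        columns=[f"s{j}" for j in range(6)]))
    dm = bray_curtis(table)
    meta = _meta_for(dm.ids, treatment=["control"] * 3 + ["nutrient"] * 3)
    res = permanova(dm, meta, terms=["treatment"], n_perm=49, seed=2)
    assert res.table.loc["treatment", "SS"] == pytest.approx(0.0, abs=1e-9)
    assert res.table.loc["treatment", "F"] == pytest.approx(0.0, abs=1e-9)


def test_permanova_confounded_terms_rejected():
    rng = np.random.default_rng(15)
    dm = bray_curtis(random_counts_table(rng, n_features=10, n_samples=6))
    meta = _meta_for(dm.ids,
                     treatment=["control", "control", "control",
                                "nutrient", "nutrient", "nutrient"],
                     experiment=["e1", "e1", "e1", "e2", "e2", "e2"])
    with pytest.raises(ValueError, match="confounded|singular"):
        permanova(dm, meta, terms=["treatment", "experiment"], n_perm=9, seed=0)


def _exhaustive_permanova_p(dm: DistanceMatrix, labels: list[str]) -> float:
    """Brute-force p over all distinct two-group assignments (oracle)."""
    n = len(labels)
    group_a = [i for i, g in enumerate(labels) if g == labels[0]]
    k = len(group_a)

    def pseudo_f(assign_a: tuple[int, ...]) -> float:
        lab = np.array(["B"] * n, dtype=object)
        lab[list(assign_a)] = "A"
        d2 = np.asarray(dm.data) ** 2
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ d2 @ j
        x = np.hstack([np.ones((n, 1)),
                       (lab[:, None] == np.array(["A", "B"])[None, :]).astype(float)])
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        h = (u[:, s > 1e-10]) @ (u[:, s > 1e-10]).T
        ss_model = np.sum(h * g)                       # tr(H G)
        ss_mean = np.sum((np.ones((n, n)) / n) * g)    # intercept-only fit
        ss_term = ss_model - ss_mean
        ss_resid = np.trace(g) - ss_model
        return (ss_term / 1) / (ss_resid / (n - 2))

    f_obs = pseudo_f(tuple(group_a))
    fs = [pseudo_f(assign) for assign in itertools.combinations(range(n), k)]
    return sum(f >= f_obs - 1e-12 for f in fs) / len(fs)


def test_permanova_monte_carlo_matches_exhaustive():
    """On 6 samples / 2 groups, Monte-Carlo p is within 2 s.e. of the
    exhaustive-enumeration p."""
    rng = np.random.default_rng(17)
    table = random_counts_table(rng, n_features=12, n_samples=6)
    dm = bray_curtis(to_relative(table))
    labels = ["control"] * 3 + ["nutrient"] * 3
    meta = _meta_for(dm.ids, treatment=labels)
    p_exact = _exhaustive_permanova_p(dm, labels)
    n_perm = 4999
    res = permanova(dm, meta, terms=["treatment"], n_perm=n_perm, seed=21)
    p_mc = res.table.loc["treatment", "p"]
    se = math.sqrt(p_exact * (1 - p_exact) / n_perm)
    assert abs(p_mc - p_exact) <= 2 * se + 2 / n_perm


def test_permanova_matches_vegan_adonis2(tmp_path):
    """Cross-check df, SS, R2 and F against R vegan::adonis2 (by='terms')."""
    rng = np.random.default_rng(19)
    table = random_counts_table(rng, n_features=25, n_samples=12)
    dm = bray_curtis(to_relative(table))
    treatment = ["control", "nutrient", "temperature"] * 4
    timepoint = ["T0"] * 6 + ["T1"] * 6
    meta = _meta_for(dm.ids, treatment=treatment, timepoint=timepoint)
    res = permanova(dm, meta, terms=["treatment", "timepoint"], n_perm=99, seed=3)

    write_distance_matrix(dm, tmp_path / "dm.tsv")
    pd.DataFrame({"treatment": treatment, "timepoint": timepoint},
                 index=list(dm.ids)).to_csv(tmp_path / "meta.tsv", sep="\t")
    rscript = textwrap.dedent("""
        suppressMessages(library(vegan))
        d <- as.dist(as.matrix(read.table("dm.tsv", sep="\t", header=TRUE,
                                          row.names=1, check.names=FALSE,
                                          comment.char="")))
        m <- read.table("meta.tsv", sep="\t", header=TRUE, row.names=1)
        fit <- adonis2(d ~ treatment + timepoint, data=m, permutations=99,
                       by="terms")
        out <- data.frame(term=rownames(fit), df=fit$Df, SS=fit$SumOfSqs,
                          R2=fit$R2, F=fit$F)
        write.table(out, "vegan_out.tsv", sep="\t", row.names=FALSE, quote=FALSE)
    """)
    (tmp_path / "run.R").write_text(rscript)
    subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True,
                   capture_output=True)
    vg = pd.read_csv(tmp_path / "vegan_out.tsv", sep="\t").set_index("term")
    for term in ("treatment", "timepoint", "Residual", "Total"):
        assert res.table.loc[term, "df"] == vg.loc[term, "df"]
        assert res.table.loc[term, "SS"] == pytest.approx(vg.loc[term, "SS"],
                                                          abs=1e-8)
        assert res.table.loc[term, "R2"] == pytest.approx(vg.loc[term, "R2"],
                                                          abs=1e-8)
    for term in ("treatment", "timepoint"):
        assert res.table.loc[term, "F"] == pytest.approx(vg.loc[term, "F"],
                                                         abs=1e-8)


# --------------------------------------------------- ANOVA on distance values

def test_distance_anova_hand_example():
    """A=(1,2,3), B=(4,5,6): F = 13.5 on df (1, 4); t(B−A) = 3/√(2/3)."""
    res = distance_group_test([1, 2, 3, 4, 5, 6],
                              ["A", "A", "A", "B", "B", "B"])
    assert res.F == pytest.approx(13.5, abs=1e-12)
    assert (res.df_between, res.df_within) == (1, 4)
    t = res.contrasts.iloc[0]
    assert t["t"] == pytest.approx(3 / math.sqrt(2 / 3), abs=1e-12)
    f_scipy, p_scipy = sps.f_oneway([1, 2, 3], [4, 5, 6])
    assert res.F == pytest.approx(f_scipy) and res.p == pytest.approx(p_scipy)


def test_distance_anova_identical_groups():
    res = distance_group_test([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                              ["A", "A", "A", "B", "B", "B"])
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert (res.contrasts["p_adj"] == 1.0).all()


def test_distance_anova_excludes_small_groups():
    with pytest.warns(UserWarning, match="excluded"):
        res = distance_group_test([1, 2, 3, 4, 9],
                                  ["A", "A", "B", "B", "C"])
    assert res.excluded_groups == ["C"]
    assert res.df_within == 2


def test_distance_anova_holm_adjustment_reference():
    """Holm-adjusted p equal statsmodels' reference on 3-group data."""
    rng = np.random.default_rng(23)
    vals = np.concatenate([rng.normal(0, 1, 5), rng.normal(1, 1, 5),
                           rng.normal(3, 1, 5)])
    groups = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
    res = distance_group_test(vals, groups)
    from statsmodels.stats.multitest import multipletests
    expect = multipletests(res.contrasts["p_raw"], method="holm")[1]
    assert np.allclose(res.contrasts["p_adj"], expect)


# -------------------------------------------------------------------- IndVal

def _two_group_table(values: np.ndarray, ids=None) -> FeatureTable:
    n = values.shape[1]
    return FeatureTable(pd.DataFrame(
        values, index=ids or [f"f{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(n)]).astype(float))


def test_indval_perfect_indicator():
    """Present in every sample of group 1 only → A = B = stat = 1."""
    table = _two_group_table(np.array([[5, 3, 4, 0, 0, 0]]))
    res = indval(table, ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0)
    row = res.iloc[0]
    assert row["A"] == pytest.approx(1.0, abs=1e-12)
    assert row["B"] == pytest.approx(1.0, abs=1e-12)
    assert row["stat"] == pytest.approx(1.0, abs=1e-12)
    assert row["group_combination"] == "g1"


def test_indval_equal_groups_stat():
    """Equal mean abundance and full occupancy in both groups → best
    single-group stat = √0.5."""
    table = _two_group_table(np.array([[2, 2, 2, 2, 2, 2]]))
    res = indval(table, ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0)
    assert res.iloc[0]["A"] == pytest.approx(0.5, abs=1e-12)
    assert res.iloc[0]["stat"] == pytest.approx(math.sqrt(0.5), abs=1e-12)


def _oracle_indval_p(values: np.ndarray, labels: list[str]) -> np.ndarray:
    """Exhaustive enumeration oracle, independently coded: best single-group
    IndVal.g over all distinct assignments of the label multiset."""
    n = len(labels)
    k_a = labels.count(labels[0])
    levels = sorted(set(labels))

    def best_stat(assign_a: frozenset) -> np.ndarray:
        stats = []
        for level_members in (assign_a, frozenset(range(n)) - assign_a):
            idx = sorted(level_members)
            other = sorted(set(range(n)) - set(idx))
            mean_in = values[:, idx].mean(axis=1)
            mean_out = values[:, other].mean(axis=1)
            with np.errstate(invalid="ignore"):
                a = mean_in / (mean_in + mean_out)
            a = np.nan_to_num(a)
            b = (values[:, idx] > 0).mean(axis=1)
            stats.append(np.sqrt(a * b))
        return np.maximum(*stats)

    obs_a = frozenset(i for i, g in enumerate(labels) if g == labels[0])
    obs = best_stat(obs_a)
    count = np.zeros(values.shape[0])
    total = 0
    for combo in itertools.combinations(range(n), k_a):
        count += best_stat(frozenset(combo)) >= obs - 1e-12
        total += 1
    return count / total


def test_indval_exhaustive_matches_independent_oracle():
    """8 samples in 2 groups of 4: exhaustive p over all 70 assignments
    equals an independently coded enumeration."""
    rng = np.random.default_rng(29)
    values = rng.integers(0, 12, size=(10, 8)).astype(float)
    values[values.sum(axis=1) == 0, 0] = 1
    labels = ["g1"] * 4 + ["g2"] * 4
    table = _two_group_table(values)
    res = indval(table, labels, n_perm="exhaustive")
    oracle = _oracle_indval_p(values, labels)
    assert res.attrs["n_permutations"] == 70
    assert np.allclose(res["p"].to_numpy(), oracle, atol=1e-12)


def test_indval_monte_carlo_close_to_exhaustive():
    rng = np.random.default_rng(31)
    values = rng.integers(0, 8, size=(5, 8)).astype(float)
    values[values.sum(axis=1) == 0, 0] = 1
    labels = ["g1"] * 4 + ["g2"] * 4
    table = _two_group_table(values)
    p_ex = indval(table, labels, n_perm="exhaustive")["p"].to_numpy()
    p_mc = indval(table, labels, n_perm=1999, seed=5)["p"].to_numpy()
    se = np.sqrt(p_ex * (1 - p_ex) / 1999)
    assert np.all(np.abs(p_mc - p_ex) <= 2 * se + 2 / 1999)


def test_indval_scale_invariance_and_g_correction():
    rng = np.random.default_rng(37)
    values = rng.integers(0, 10, size=(6, 9)).astype(float)
    values[values.sum(axis=1) == 0, 0] = 1
    labels = ["g1"] * 3 + ["g2"] * 6
    table = _two_group_table(values)
    res = indval(table, labels, n_perm=49, seed=1)
    res_scaled = indval(_two_group_table(values * 7.3), labels, n_perm=49, seed=1)
    assert np.allclose(res["stat"], res_scaled["stat"], atol=1e-12)
    # duplicating every sample of one group preserves its mean → A unchanged
    dup = np.hstack([values, values[:, :3]])
    table_dup = FeatureTable(pd.DataFrame(
        dup, index=[f"f{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(12)]))
    res_dup = indval(table_dup, labels + ["g1"] * 3, n_perm=49, seed=1)
    assert np.allclose(res["A"], res_dup["A"], atol=1e-12)


def test_indval_p_never_zero_and_max_order_capped():
    table = _two_group_table(np.array([[9, 9, 9, 0, 0, 0]]))
    with pytest.warns(UserWarning, match="max_order"):
        res = indval(table, ["g1"] * 3 + ["g2"] * 3, max_order=2, n_perm=19, seed=0)
    assert (res["p"] >= 1 / 20).all()
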