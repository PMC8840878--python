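"""Sequential Procrustes ANOVA, allometry, disparity, size-adjusted LDA."""

import numpy as np
import pandas as pd
import pytest

from gearmorph.procrustes import AlignedDataset
from gearmorph.shape_stats import (
    ModelSpec,
    fit_allometry,
    flatten_shapes,
    lda_classify,
    morphological_disparity,
    procrustes_anova,
    size_adjust_shapes,
    unflatten_shapes,
)

from conftest import random_aligned


def test_flatten_roundtrip_and_column_means():
    al = random_aligned(np.random.default_rng(0), n=12, k=5)
    flat = flatten_shapes(al)
    assert flat.shape == (12, 10)
    np.testing.assert_allclose(unflatten_shapes(flat), al.shape_coordinates)
    np.testing.assert_allclose(
        flat.mean(axis=0).reshape(5, 2), al.consensus, atol=1e-12
    )


def test_anova_matches_brute_force_group_oracle():
    """n=6, k=4, one two-level factor: SS and F equal the direct
    between/within cross-product computation."""
    rng = np.random.default_rng(10)
    al = random_aligned(rng, n=6, k=4)
    g = np.array(["a", "a", "a", "b", "b", "b"])
    cov = pd.DataFrame({"id": al.ids, "grp": g})
    tab = procrustes_anova(al, cov, ModelSpec(["grp"], n_perm=99, seed=0)).table

    y = flatten_shapes(al)
    grand = y.mean(axis=0)
    ss_between = sum(
        (g == lev).sum() * ((y[g == lev].mean(axis=0) - grand) ** 2).sum()
        for lev in ("a", "b")
    )
    ss_total = ((y - grand) ** 2).sum()
    ss_within = ss_total - ss_between
    f_oracle = (ss_between / 1) / (ss_within / 4)

    row = tab[tab.term == "grp"].iloc[0]
    assert row.SS == pytest.approx(ss_between, rel=1e-10)
    assert row.F == pytest.approx(f_oracle, rel=1e-10)
    assert row.R2 == pytest.approx(ss_between / ss_total, rel=1e-10)


def test_anova_univariate_matches_sequential_ols_oracle():
    """On a 1-column response the sequential SS equal a classical nested
    OLS decomposition computed by hand."""
    rng = np.random.default_rng(11)
    n = 20
    x = rng.normal(size=n)
    g = rng.choice(["u", "v"], n)
    y1 = 0.5 * x + (g == "u") * 0.3 + rng.normal(size=n)
    coords = np.zeros((n, 2, 2))  # degenerate container: put y1 in one coord
    coords[:, 0, 0] = y1
    al = AlignedDataset(coords, np.exp(x), coords.mean(0), [f"f{i}" for i in range(n)])
    cov = pd.DataFrame({"id": al.ids, "x": x, "g": g})
    tab = procrustes_anova(al, cov, ModelSpec(["x", "g"], n_perm=99, seed=0)).table

    yc = y1 - y1.mean()
    x1 = np.column_stack([np.ones(n), x])
    x2 = np.column_stack([x1, (g == "v").astype(float)])
    rss = lambda X: float(((yc - X @ np.linalg.lstsq(X, yc, rcond=None)[0]) ** 2).sum())
    ss_x = float((yc**2).sum()) - rss(x1)
    ss_g = rss(x1) - rss(x2)
    assert tab[tab.term == "x"].SS.iloc[0] == pytest.approx(ss_x, abs=1e-8)
    assert tab[tab.term == "g"].SS.iloc[0] == pytest.approx(ss_g, abs=1e-8)


def test_anova_decomposition_and_reproducibility(small_cohort):
    """Sequential SS sum to the total; p-values reproduce under the seed
    and are invariant to specimen order."""
    from gearmorph.procrustes import gpa_align

    al = gpa_align(small_cohort.landmarks)
    cov = small_cohort.covariates.frame
    spec = ModelSpec(["centroid_size", "sex"], n_perm=199, seed=5)
    t1 = procrustes_anova(al, cov, spec).table
    t2 = procrustes_anova(al, cov, spec).table
    pd.testing.assert_frame_equal(t1, t2)
    body = t1[~t1.term.isin(["Residuals", "Total"])]
    total = t1[t1.term == "Total"].SS.iloc[0]
    resid = t1[t1.term == "Residuals"].SS.iloc[0]
    assert body.SS.sum() + resid == pytest.approx(total, rel=1e-10)
    assert body.df.sum() + t1[t1.term == "Residuals"].df.iloc[0] == al.n - 1

    # permute fish order: identical table (stable association ids<->rows)
    order = np.random.default_rng(0).permutation(al.n)
    al2 = AlignedDataset(
        al.shape_coordinates[order],
        al.centroid_sizes[order],
        al.consensus,
        [al.ids[i] for i in order],
    )
    t3 = procrustes_anova(al2, cov, spec).table
    np.testing.assert_allclose(
        t1.sort_values("term").SS.to_numpy(), t3.sort_values("term").SS.to_numpy()
    )


def test_anova_rank_deficient_term_named():
    al = random_aligned(np.random.default_rng(12), n=10, k=4)
    cov = pd.DataFrame({"id": al.ids, "a": ["x"] * 5 + ["y"] * 5})
    cov["b"] = cov["a"]  # perfectly aliased
    with pytest.raises(ValueError, match="'b'"):
        procrustes_anova(al, cov, ModelSpec(["a", "b"], n_perm=99, seed=0))


def test_allometry_recovers_constructed_signal():
    """Shape built as consensus + c*log(size)*v with no noise -> R2 ~ 1."""
    rng = np.random.default_rng(13)
    n, k = 30, 6
    sizes = np.exp(rng.normal(2.0, 0.2, n))
    v = rng.normal(size=(k, 2))
    v /= np.sqrt((v**2).sum())
    base = rng.normal(size=(k, 2))
    coords = base + 0.05 * (np.log(sizes)[:, None, None] - 2.0) * v
    coords -= coords.mean(axis=1, keepdims=True)
    # NOTE: not re-normalized to unit size so the linear signal is exact
    al = AlignedDataset(coords, sizes, coords.mean(0), [f"f{i}" for i in range(n)])
    tab = fit_allometry(al, n_perm=99, seed=0).table
    assert tab[tab.term == "log_centroid_size"].R2.iloc[0] >= 0.999


def test_allometry_residuals_orthogonal_to_predictor(small_cohort):
    from gearmorph.procrustes import gpa_align

    al = gpa_align(small_cohort.landmarks)
    resid = size_adjust_shapes(al).to_numpy()
    x = np.log(al.centroid_sizes)
    xc = x - x.mean()
    assert np.abs(xc @ resid).max() <= 1e-8
    assert np.abs(resid.mean(axis=0)).max() <= 1e-10


def test_allometry_constant_size_errors():
    al = random_aligned(np.random.default_rng(14), n=8, k=4)
    al.centroid_sizes = np.full(8, 3.0)
    with pytest.raises(ValueError, match="constant"):
        fit_allometry(al, n_perm=99)


def test_size_adjust_exact_linear_dependence():
    """Shapes exactly linear in size leave ~zero residuals."""
    rng = np.random.default_rng(15)
    n, k = 20, 5
    sizes = np.exp(rng.normal(0, 0.3, n))
    v = rng.normal(size=(k, 2))
    coords = 0.2 * np.log(sizes)[:, None, None] * v + rng.normal(size=(k, 2))
    al = AlignedDataset(coords, sizes, coords.mean(0), [f"f{i}" for i in range(n)])
    resid = size_adjust_shapes(al).to_numpy()
    assert np.abs(resid).max() <= 1e-8


def test_lda_separable_and_chance():
    rng = np.random.default_rng(16)
    n, p = 100, 10
    labels = np.array(["high"] * 50 + ["low"] * 50)
    x = rng.normal(size=(n, p))
    x[labels == "high", 0] += 10.0  # 10 within-class SDs apart
    df = pd.DataFrame(x, index=[f"f{i}" for i in range(n)])
    res = lda_classify(df, pd.Series(labels, index=df.index), seed=0)
    assert res.accuracy >= 0.95
    assert res.confusion.to_numpy().sum() == 30
    assert set(res.train_ids).isdisjoint(res.test_ids)

    # permuted labels: chance-level mean accuracy over seeds
    accs = []
    for seed in range(25):
        perm = rng.permutation(labels)
        accs.append(
            lda_classify(df, pd.Series(perm, index=df.index), seed=seed).accuracy
        )
    assert 0.40 <= np.mean(accs) <= 0.60


def test_lda_errors_on_tiny_class():
    rng = np.random.default_rng(17)
    df = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"f{i}" for i in range(8)])
    labels = pd.Series(["a"] * 7 + ["b"], index=df.index)
    with pytest.raises(ValueError, match="[Tt]oo few"):
        lda_classify(df, labels, seed=0)


def test_disparity_direct_sum_oracle():
    """PV equals mean squared deviation from the group mean on a 5-specimen
    toy; identical shapes give PV = 0."""
    rng = np.random.default_rng(18)
    coords = rng.normal(size=(5, 4, 2))
    same = np.repeat(coords[:1], 4, axis=0)
    all_coords = np.concatenate([coords, same])
    al = AlignedDataset(
        all_coords, np.ones(9), all_coords.mean(0), [f"f{i}" for i in range(9)]
    )
    g = np.array(["var"] * 5 + ["same"] * 4)
    res = morphological_disparity(al, g, n_perm=99, seed=0)

    y = coords.reshape(5, -1)
    pv_oracle = ((y - y.mean(axis=0)) ** 2).sum() / 5  # divisor n, not n-1
    assert res.variances["var"] == pytest.approx(pv_oracle, rel=1e-12)
    assert res.variances["same"] == 0.0
    assert res.differences.loc["var", "same"] == pytest.approx(pv_oracle)


def test_disparity_validation():
    al = random_aligned(np.random.default_rng(19), n=6, k=4)
    with pytest.raises(ValueError, match="fewer than 2"):
        morphological_disparity(al, ["a"] * 5 + ["b"], n_perm=99)
    with pytest.raises(ValueError, match="2 groups"):
        morphological_disparity(al, ["a"] * 6, n_perm=99)
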