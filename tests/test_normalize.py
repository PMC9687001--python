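"""Units, normalization and NB likelihood-ratio test behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import polymodes as pm
from polymodes.normalize import estimate_dispersion, nb_lrt

# ---------------------------------------------------------------------------
# TPM


def test_tpm_forced_by_formula():
    counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
    lengths = pd.Series([1000, 2000], index=["g1", "g2"])
    tpm = pm.compute_tpm(counts, lengths)["s1"]
    assert tpm.tolist() == pytest.approx([2e6 / 3, 1e6 / 3])


def test_tpm_symmetry_and_column_sums():
    rng = np.random.default_rng(0)
    n = 50
    counts = pd.DataFrame(rng.integers(0, 500, size=(n, 4)),
                          index=[f"g{i}" for i in range(n)], columns=list("abcd"))
    lengths = pd.Series(rng.integers(200, 5000, size=n), index=counts.index)
    tpm = pm.compute_tpm(counts, lengths)
    assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)
    equal = pd.DataFrame(7, index=counts.index, columns=["s"])
    t2 = pm.compute_tpm(equal, pd.Series(1000, index=counts.index))
    assert np.allclose(t2["s"], 1e6 / n)


def test_tpm_zero_length_error_names_gene():
    counts = pd.DataFrame({"s": [1, 2]}, index=["g1", "g2"])
    lengths = pd.Series([1000, 0], index=counts.index)
    with pytest.raises(ValueError, match="g2"):
        pm.compute_tpm(counts, lengths)


def test_tpm_all_zero_column_warns():
    counts = pd.DataFrame({"s": [0, 0]}, index=["g1", "g2"])
    with pytest.warns(UserWarning, match="all-zero"):
        tpm = pm.compute_tpm(counts, pd.Series(1000, index=counts.index))
    assert (tpm["s"] == 0).all()


# ---------------------------------------------------------------------------
# TMM


def test_tmm_no_composition_bias_and_depth_invariance():
    rng = np.random.default_rng(1)
    base = rng.integers(1, 400, size=800)
    identical = pd.DataFrame({"a": base, "b": base, "c": base},
                             index=[f"g{i}" for i in range(800)])
    assert np.allclose(pm.tmm_factors(identical), 1.0, atol=1e-9)
    scaled = pd.DataFrame({"a": base, "b": base * 2},
                          index=[f"g{i}" for i in range(800)])
    assert np.allclose(pm.tmm_factors(scaled), 1.0, atol=1e-9)


def _tmm_oracle(obs, ref):
    """Direct re-computation of the doubly trimmed weighted mean of M."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(m)
    lo_m = np.floor(n * 0.3) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * 0.05) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    kk = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2.0 ** (np.sum(m[kk] / w[kk]) / np.sum(1.0 / w[kk]))


def test_tmm_spiked_composition_matches_oracle():
    """10% of genes spiked x8 in one sample: factor equals the direct
    trimmed weighted mean, independently recomputed."""
    rng = np.random.default_rng(2)
    n = 2000
    base = rng.integers(5, 500, size=n)
    spiked = base.copy()
    idx = rng.choice(n, size=n // 10, replace=False)
    spiked[idx] = spiked[idx] * 8
    counts = pd.DataFrame({"ref": base, "obs": spiked},
                          index=[f"g{i}" for i in range(n)])
    factors = pm.tmm_factors(counts, ref_sample="ref")
    raw = _tmm_oracle(spiked, base)
    expected = np.array([1.0, raw])
    expected /= np.exp(np.mean(np.log(expected)))
    assert factors["obs"] == pytest.approx(expected[1], abs=1e-6)
    assert factors["ref"] == pytest.approx(expected[0], abs=1e-6)


def test_tmm_geometric_mean_one():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.integers(0, 300, size=(500, 5)),
                          index=[f"g{i}" for i in range(500)],
                          columns=list("abcde"))
    f = pm.tmm_factors(counts)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-6)


def test_tmm_disjoint_sample_warns():
    counts = pd.DataFrame({"a": [10, 20, 0, 0], "b": [0, 0, 5, 5],
                           "c": [10, 20, 1, 1]}, index=list("wxyz"))
    with pytest.warns(UserWarning, match="no expressed genes"):
        f = pm.tmm_factors(counts, ref_sample="a")
    assert np.isfinite(f).all()


# ---------------------------------------------------------------------------
# dispersion


def test_dispersion_recovery():
    """Common Cox-Reid estimate recovers the simulation truth."""
    rng = np.random.default_rng(11)
    mu = rng.lognormal(np.log(100), 1.0, size=2000)
    pois = pd.DataFrame(rng.poisson(mu[:, None], size=(2000, 6)),
                        index=[f"g{i}" for i in range(2000)],
                        columns=list("abcdef"))
    est = estimate_dispersion(pois, np.ones((6, 1)))
    assert est.common < 0.05
    r = 1 / 0.4
    nb = pd.DataFrame(rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 6)),
                      index=pois.index, columns=pois.columns)
    est2 = estimate_dispersion(nb, np.ones((6, 1)))
    assert 0.3 <= est2.common <= 0.5


def test_dispersion_constant_gene_at_lower_bound():
    counts = pd.DataFrame([[50] * 6], index=["g0"], columns=list("abcdef"))
    est = estimate_dispersion(counts, np.ones((6, 1)))
    assert est.tagwise["g0"] <= est.grid[1]


# ---------------------------------------------------------------------------
# NB LRT


def test_nb_lrt_null_calibration(null_de):
    """Type-I error near nominal and uniform null p-values."""
    p = null_de["p_value"].to_numpy()
    assert 0.03 <= (p < 0.05).mean() <= 0.07
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_nb_lrt_all_zero_gene():
    rng = np.random.default_rng(4)
    y = rng.poisson(50, size=(20, 6))
    y[3] = 0
    counts = pd.DataFrame(y, index=[f"g{i}" for i in range(20)],
                          columns=list("abcdef"))
    de = pm.de_two_group(counts, np.array(["A"] * 3 + ["B"] * 3), "A", "B",
                         dispersion=0.2).set_index("gene_id")
    assert de.loc["g3", "log2FC"] == 0
    assert de.loc["g3", "p_value"] == 1
    assert de.loc["g3", "flag"] == "all_zero"


def test_nb_lrt_power_on_planted_fold_changes():
    """Planted log2FC=3 on 10% of genes is recovered at FDR<0.05 & FC>2."""
    rng = np.random.default_rng(12)
    n = 3000
    r = 1 / 0.2
    fc = np.ones(n)
    planted = rng.choice(n, size=n // 10, replace=False)
    fc[planted] = 8.0
    ya = rng.negative_binomial(r, r / (r + (100 * fc)[:, None]), size=(n, 3))
    yb = rng.negative_binomial(r, r / (r + 100), size=(n, 3))
    counts = pd.DataFrame(np.hstack([ya, yb]),
                          index=[f"g{i}" for i in range(n)], columns=list("abcdef"))
    de = pm.de_two_group(counts, np.array(["A"] * 3 + ["B"] * 3), "A", "B")
    hits = ((de["fdr"] < 0.05) & (de["log2FC"].abs() > 1)).to_numpy()
    assert hits[planted].mean() >= 0.90


def test_nb_lrt_depth_scaling_leaves_log2fc_invariant():
    """Scaling one sample's counts only moves its effective library size."""
    rng = np.random.default_rng(13)
    mu = rng.lognormal(np.log(200), 0.8, size=400)
    r = 1 / 0.2
    y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(400, 6))
    counts = pd.DataFrame(y, index=[f"g{i}" for i in range(400)],
                          columns=list("abcdef"))
    groups = np.array(["A"] * 3 + ["B"] * 3)
    de1 = pm.de_two_group(counts, groups, "A", "B", dispersion=0.2)
    scaled = counts.copy()
    scaled["a"] = scaled["a"] * 4
    de2 = pm.de_two_group(scaled, groups, "A", "B", dispersion=0.2)
    assert np.allclose(de1["log2FC"], de2["log2FC"], atol=5e-2)


def test_nb_lrt_single_gene_matches_statsmodels():
    """Cross-check one NB GLM fit against statsmodels at fixed dispersion."""
    import statsmodels.api as sm

    rng = np.random.default_rng(14)
    y = rng.negative_binomial(5, 5 / (5 + 120), size=8)
    counts = pd.DataFrame([y], index=["g0"],
                          columns=[f"s{i}" for i in range(8)])
    X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
    lib = counts.sum(axis=0).astype(float)
    ours = nb_lrt(counts, X, 1, dispersion=0.2,
                  norm_factors=pd.Series(1.0, index=counts.columns),
                  lib_size=lib)
    ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=0.2),
                 offset=np.log(lib.to_numpy())).fit()
    assert ours["log2FC"].iloc[0] == pytest.approx(ref.params[1] / np.log(2),
                                                   abs=1e-4)


def test_design_rank_checked():
    counts = pd.DataFrame([[1, 2, 3, 4]], index=["g"], columns=list("abcd"))
    X = np.ones((4, 2))
    with pytest.raises(ValueError, match="full rank"):
        nb_lrt(counts, X, 1, dispersion=0.1)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_closed_forms():
    assert pm.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert pm.bh_adjust([0.2]) == pytest.approx([0.2])
    out = pm.bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(out[1]) and not np.isnan(out[[0, 2]]).any()


def _bh_oracle(p):
    """Brute-force step-up: find the largest k with p_(k) <= k q / m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        prev = min(prev, p[order[i]] * m / (i + 1))
        adj[order[i]] = prev
    return adj


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                min_size=1, max_size=60))
def test_bh_matches_stepup_oracle(pvals):
    ours = pm.bh_adjust(pvals)
    assert np.allclose(ours, _bh_oracle(pvals), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(15)
    p = rng.uniform(size=200)
    ours = pm.bh_adjust(p)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, ref, atol=1e-12)
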