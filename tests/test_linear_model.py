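"""Normalization, contrast algebra, OLS equivalence, moderation, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tilemeth import linear_model as lm


def _make_table(values: dict[str, np.ndarray], n_reps: int = 1,
                probe_ids=None) -> pd.DataFrame:
    """Long-format table from per-factor probe value arrays."""
    frames = []
    some = np.atleast_2d(next(iter(values.values())))
    probe_ids = probe_ids or [f"P{i}" for i in range(some.shape[1])]
    for factor, arr in values.items():
        arr = np.atleast_2d(arr)
        genotype = factor.split("_")[0]
        for rep in range(1, arr.shape[0] + 1):
            frames.append(pd.DataFrame({
                "probe_id": probe_ids,
                "sample_id": f"{factor}_r{rep}",
                "factor": factor,
                "replicate": rep,
                "dye": "Cy5" if factor.endswith("IP") else "Cy3",
                "array": f"{genotype}_r{rep}",
                "log2_intensity": arr[rep - 1],
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _two_array_table(a1: np.ndarray, a2: np.ndarray) -> pd.DataFrame:
    n = len(a1)
    return pd.DataFrame({
        "probe_id": [f"P{i}" for i in range(n)] * 2,
        "sample_id": ["s1"] * n + ["s2"] * n,
        "factor": ["B73_IP"] * n + ["Mo17_IP"] * n,
        "replicate": 1,
        "dye": "Cy5",
        "array": ["a1"] * n + ["a2"] * n,
        "log2_intensity": np.concatenate([a1, a2]),
    })


def test_identical_arrays_map_identically_and_preserve_rank():
    rng = np.random.default_rng(0)
    a = rng.normal(10, 1, size=200)
    out = lm.normalize(_two_array_table(a, a.copy()))
    o1 = out[out["array"] == "a1"]["log2_intensity"].to_numpy()
    o2 = out[out["array"] == "a2"]["log2_intensity"].to_numpy()
    assert np.allclose(o1, o2)
    assert np.array_equal(np.argsort(o1), np.argsort(a))


def test_log2_offset_between_arrays_removed():
    rng = np.random.default_rng(1)
    a = rng.normal(10, 1, size=500)
    out = lm.normalize(_two_array_table(a, a + 1.0))
    med = out.groupby("array")["log2_intensity"].median()
    assert abs(med["a1"] - med["a2"]) < 1e-9
    # offset removal is exact: the two arrays become identical
    o1 = out[out["array"] == "a1"]["log2_intensity"].to_numpy()
    o2 = out[out["array"] == "a2"]["log2_intensity"].to_numpy()
    assert np.allclose(o1, o2)


def test_simulated_array_effects_equalize_medians():
    rng = np.random.default_rng(2)
    # odd probe count: the median is an order statistic, so exact equality
    # survives the monotone glog transform
    base = rng.normal(10, 1, size=401)
    tables = []
    for j in range(4):
        off = rng.normal(0, 0.5)
        tables.append(pd.DataFrame({
            "probe_id": [f"P{i}" for i in range(401)],
            "sample_id": f"s{j}",
            "factor": "B73_IP", "replicate": 1, "dye": "Cy5",
            "array": f"a{j}",
            "log2_intensity": base + off + rng.normal(0, 0.2, 401),
        }))
    out = lm.normalize(pd.concat(tables, ignore_index=True))
    med = out.groupby("array")["log2_intensity"].median()
    assert med.max() - med.min() < 1e-9


def test_constant_array_raises_zero_spread():
    a = np.full(50, 10.0)
    b = np.random.default_rng(0).normal(10, 1, 50)
    with pytest.raises(ValueError, match="zero spread"):
        lm.normalize(_two_array_table(a, b))


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def test_noiseless_contrast_values():
    tbl = _make_table({"B73_IP": np.array([2.0]), "B73_input": np.array([0.0]),
                       "Mo17_IP": np.array([0.0]),
                       "Mo17_input": np.array([0.0])})
    est = lm.fit_contrasts(tbl)
    assert est.loc[0, "b73_meth"] == pytest.approx(2.0)
    assert est.loc[0, "cgh"] == pytest.approx(0.0)
    assert est.loc[0, "mo17_meth_corr"] == pytest.approx(0.0)
    assert est.loc[0, "diff_meth"] == pytest.approx(2.0)


def test_pav_input_difference_does_not_leak_into_diff_meth():
    """A 2-unit input drop in Mo17 moves cgh to -2 but leaves diff_meth
    untouched: the input correction removes hybridization-efficiency
    differences from the methylation comparison."""
    tbl = _make_table({"B73_IP": np.array([1.0]), "B73_input": np.array([0.0]),
                       "Mo17_IP": np.array([-1.0]),
                       "Mo17_input": np.array([-2.0])})
    est = lm.fit_contrasts(tbl)
    assert est.loc[0, "cgh"] == pytest.approx(-2.0)
    assert est.loc[0, "b73_meth"] == pytest.approx(1.0)
    assert est.loc[0, "mo17_meth_corr"] == pytest.approx(1.0)
    assert est.loc[0, "diff_meth"] == pytest.approx(0.0)


def test_estimates_match_ols_oracle():
    """Factor means and contrast SEs agree with statsmodels OLS per probe."""
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    n_probes = 20
    vals = {f: rng.normal(0, 1, size=(3, n_probes)) for f in lm.FACTORS}
    tbl = _make_table(vals, n_reps=3)
    est = lm.fit_contrasts(tbl).set_index("probe_id")
    for i in [0, 7, 19]:
        pid = f"P{i}"
        y, X = [], []
        for k, f in enumerate(lm.FACTORS):
            for rep in range(3):
                y.append(vals[f][rep, i])
                X.append([1.0 if j == k else 0.0 for j in range(4)])
        fit = sm.OLS(np.array(y), np.array(X)).fit()
        L = lm.CONTRASTS["diff_meth"]
        want = float(np.asarray(L @ fit.params).squeeze())
        assert est.loc[pid, "diff_meth"] == pytest.approx(want, abs=1e-10)
        want_se = float(np.sqrt(L @ fit.cov_params() @ L))
        assert est.loc[pid, "se_diff_meth"] == pytest.approx(want_se,
                                                             abs=1e-10)


def test_missing_factor_raises_by_name():
    tbl = _make_table({"B73_IP": np.array([1.0]),
                       "B73_input": np.array([0.0]),
                       "Mo17_IP": np.array([0.0])})
    with pytest.raises(ValueError, match="Mo17_input"):
        lm.fit_contrasts(tbl)


def test_contrast_algebra_invariant(estimates):
    lhs = estimates["diff_meth"] + estimates["mo17_meth_corr"]
    assert np.allclose(lhs, estimates["b73_meth"], atol=1e-9)


# ---------------------------------------------------------------------------
# moderation
# ---------------------------------------------------------------------------

def _null_estimates(n_probes: int, seed: int, sigma: float = 1.0,
                    df_scale=None) -> pd.DataFrame:
    """Null data: all factor means equal, Gaussian noise, 3 reps."""
    rng = np.random.default_rng(seed)
    vals = {f: rng.normal(0, sigma, size=(3, n_probes)) for f in lm.FACTORS}
    if df_scale is not None:
        # per-probe heteroscedasticity so the prior df is finite
        scale = df_scale(rng, n_probes)
        for f in vals:
            vals[f] = vals[f] * scale
    return lm.fit_contrasts(_make_table(vals, n_reps=3))


def test_equal_variances_recover_pooled_t_limit():
    """When sample variances do not vary, d0 -> inf and the moderated t is
    an ordinary t computed with a single shared (pooled) variance. The
    shared variance carries the chi-square bias correction of the moment
    estimator: for constant s2 = c on df residual df it equals
    c * exp(-(digamma(df/2) - log(df/2))), the same value limma's prior fit
    returns in this limit."""
    from scipy.special import digamma

    est = _null_estimates(2_000, seed=4)
    # force identical variances: the limit case
    est["s2"] = 1.7
    out = lm.moderate(est)
    assert np.isinf(out["d0"].iloc[0])
    want = est["diff_meth"] / np.sqrt(out["s0_2"] * est["v_diff_meth"])
    assert np.allclose(out["t_diff_meth"], want)
    df = est["df_resid"].iloc[0]
    expected_s0 = 1.7 * np.exp(-(digamma(df / 2.0) - np.log(df / 2.0)))
    assert out["s0_2"].iloc[0] == pytest.approx(expected_s0, rel=1e-9)
    # shrinkage leaves every probe with the same posterior variance
    assert out["s2_post"].std() == pytest.approx(0.0, abs=1e-12)


def test_shrinkage_fixed_point_and_betweenness():
    est = _null_estimates(3_000, seed=5,
                          df_scale=lambda rng, n: rng.gamma(2, 1, n) ** 0.5)
    out = lm.moderate(est)
    d0, s0 = out["d0"].iloc[0], out["s0_2"].iloc[0]
    assert np.isfinite(d0)
    s2, s2p = out["s2"].to_numpy(), out["s2_post"].to_numpy()
    lo = np.minimum(s2, s0) - 1e-12
    hi = np.maximum(s2, s0) + 1e-12
    assert np.all((s2p >= lo) & (s2p <= hi))
    # a probe whose sample variance equals the prior is left unchanged
    df = out["df_resid"].iloc[0]
    assert (d0 * s0 + df * s0) / (d0 + df) == pytest.approx(s0)


def test_null_calibration_10k_probes():
    est = _null_estimates(10_000, seed=6,
                          df_scale=lambda rng, n: rng.gamma(4, 0.25, n) ** 0.5)
    out = lm.moderate(est)
    p = out["p_diff_meth"].to_numpy()
    frac = np.mean(p < 0.01)
    sd = np.sqrt(0.01 * 0.99 / len(p))
    assert abs(frac - 0.01) < 4 * sd
    q = out["q_diff_meth"].to_numpy()
    assert np.mean(q < 0.05) <= 0.06


def test_too_few_probes_raises():
    est = _null_estimates(5, seed=7)
    with pytest.raises(ValueError, match="insufficient probes"):
        lm.moderate(est)


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force step-up: q_i = min over j with p_(j) >= p_(i) of
    min(1, n*p_(j)/j)."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, n * p[i] / rank)
        q[i] = prev
    return np.minimum(q, 1.0)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=200))
def test_bh_matches_brute_force_stepup(pvals):
    from statsmodels.stats.multitest import multipletests
    p = np.array(pvals)
    got = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(got, _bh_oracle(p), atol=1e-12)


def test_qvalues_monotone_in_p(estimates):
    sub = estimates.sort_values("p_diff_meth")
    q = sub["q_diff_meth"].to_numpy()
    assert np.all(np.diff(q) >= -1e-12)


# ---------------------------------------------------------------------------
# independent cross-check against limma (R)
# ---------------------------------------------------------------------------

def test_moderated_t_matches_limma(tmp_path):
    """d0, s0^2 and the moderated t agree with limma's eBayes on the same
    design (4 factor means, contrast = differential methylation)."""
    import subprocess

    rng = np.random.default_rng(8)
    n_probes = 200
    scale = rng.gamma(3, 1.0 / 3.0, n_probes) ** 0.5
    vals = {f: rng.normal(0, 1, size=(3, n_probes)) * scale
            for f in lm.FACTORS}
    tbl = _make_table(vals, n_reps=3)
    out = lm.moderate(lm.fit_contrasts(tbl))

    wide = tbl.pivot_table(index="probe_id", columns="sample_id",
                           values="log2_intensity")
    factors = (tbl.drop_duplicates("sample_id").set_index("sample_id")
               ["factor"].loc[wide.columns])
    wide.to_csv(tmp_path / "y.csv")
    factors.to_csv(tmp_path / "f.csv")
    script = tmp_path / "check.R"
    script.write_text("""
suppressMessages(library(limma))
args <- commandArgs(trailingOnly=TRUE)
y <- read.csv(args[1], row.names=1, check.names=FALSE)
f <- read.csv(args[2], row.names=1)[[1]]
design <- model.matrix(~0 + factor(f, levels=c("B73_IP","Mo17_IP","B73_input","Mo17_input")))
colnames(design) <- c("B73_IP","Mo17_IP","B73_input","Mo17_input")
fit <- lmFit(as.matrix(y), design)
cm <- matrix(c(1,-1,-1,1), ncol=1)
rownames(cm) <- colnames(design)
fit2 <- eBayes(contrasts.fit(fit, cm))
res <- data.frame(probe=rownames(y), t=fit2$t[,1], d0=fit2$df.prior, s0=fit2$s2.prior)
write.csv(res, args[3], row.names=FALSE)
""")
    subprocess.run(["Rscript", str(script), str(tmp_path / "y.csv"),
                    str(tmp_path / "f.csv"), str(tmp_path / "r.csv")],
                   check=True, capture_output=True)
    rres = pd.read_csv(tmp_path / "r.csv").set_index("probe")
    mine = out.set_index("probe_id").loc[rres.index]
    assert mine["d0"].iloc[0] == pytest.approx(rres["d0"].iloc[0], rel=1e-4)
    assert mine["s0_2"].iloc[0] == pytest.approx(rres["s0"].iloc[0], rel=1e-4)
    assert np.allclose(mine["t_diff_meth"], rres["t"], rtol=1e-6, atol=1e-8)
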