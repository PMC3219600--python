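"""Normalization, per-probe contrast fitting, and moderated statistics.

The experiment hybridizes immunoprecipitated (IP, Cy5) and input (Cy3) DNA
from two inbreds to the same tiling array. Per probe we estimate four factor
means (B73_IP, Mo17_IP, B73_input, Mo17_input) by least squares and report
four contrasts:

* ``b73_meth``       = B73_IP - B73_input          (B73 methylation)
* ``cgh``            = Mo17_input - B73_input      (copy number / hybridization
                                                    efficiency)
* ``mo17_meth_corr`` = Mo17_IP - Mo17_input        (Mo17 methylation corrected
                                                    for the CGH difference)
* ``diff_meth``      = b73_meth - mo17_meth_corr   (positive = B73
                                                    hypermethylated)

Because each dye is confounded with the IP/input role in this design, the dye
term is absorbed into the factor means; the CGH contrast (input vs input,
same dye) and diff_meth (IP vs IP after input correction) are the dye-free
quantities — which is exactly why the Mo17 methylation estimate is corrected
by the input-vs-input contrast.

Standard errors are shrunk toward a common prior by empirical Bayes
(moment-matching of log sample variances, as in the moderated-t literature)
and q-values control the FDR by Benjamini-Hochberg within each contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

FACTORS = ("B73_IP", "Mo17_IP", "B73_input", "Mo17_input")

CONTRASTS = {
    # contrast name -> weights over FACTORS
    "b73_meth": np.array([1.0, 0.0, -1.0, 0.0]),
    "cgh": np.array([0.0, 0.0, -1.0, 1.0]),
    "mo17_meth_corr": np.array([0.0, 1.0, 0.0, -1.0]),
    "diff_meth": np.array([1.0, -1.0, -1.0, 1.0]),
}


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(table: pd.DataFrame, method: str = "affine_glog") -> pd.DataFrame:
    """Variance-stabilizing style normalization across arrays.

    Each array's linear-scale intensities are affinely calibrated (median/MAD)
    to a reference pseudo-array, then passed through a generalized-log
    (arcsinh-type) transform. Array medians agree exactly afterwards and rank
    order within an array is preserved.
    """
    if method != "affine_glog":
        raise ValueError(f"unknown normalization method: {method!r}")
    arrays = table["array"].unique()
    if len(arrays) < 2:
        raise ValueError("need at least 2 arrays to normalize")
    out = table.copy()
    linear = np.power(2.0, out["log2_intensity"].to_numpy(dtype=float))
    med = np.empty(len(arrays))
    mad = np.empty(len(arrays))
    groups = {a: (out["array"] == a).to_numpy() for a in arrays}
    for i, a in enumerate(arrays):
        y = linear[groups[a]]
        med[i] = np.median(y)
        mad[i] = np.median(np.abs(y - med[i]))
        if mad[i] == 0:
            # MAD degenerates on strongly discrete signal; fall back to SD
            mad[i] = float(np.std(y))
        if mad[i] == 0:
            raise ValueError(f"zero spread: array {a} is constant")
    ref_med = float(np.median(med))
    ref_mad = float(np.median(mad))
    calibrated = np.empty_like(linear)
    for i, a in enumerate(arrays):
        m = groups[a]
        calibrated[m] = (linear[m] - med[i]) / mad[i] * ref_mad + ref_med
    # glog: ~log2 for large y, linear through 0 for small/negative y. The
    # offset c sets where the transform bends; it should sit at the additive
    # noise floor, far below the signal range, so that well-measured
    # intensities are transformed (close to) logarithmically.
    c = ref_med * 2.0 ** -8
    out["log2_intensity"] = np.log2(
        (calibrated + np.sqrt(calibrated ** 2 + c ** 2)) / 2.0)
    return out


# ---------------------------------------------------------------------------
# per-probe linear model
# ---------------------------------------------------------------------------

def fit_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Least-squares factor means and the four contrasts, per probe.

    Returns one row per probe with contrast estimates, their unscaled
    variances (``v_<contrast>``), the residual variance ``s2`` and residual
    degrees of freedom ``df_resid``. With zero residual df the variance is
    NaN (estimates remain defined).
    """
    present = set(table["factor"].unique())
    missing = [f for f in FACTORS if f not in present]
    if missing:
        raise ValueError(f"missing factor(s): {', '.join(missing)}")

    wide = table.pivot_table(index="probe_id", columns="sample_id",
                             values="log2_intensity")
    if wide.isna().any().any():
        raise ValueError("every probe must be measured in every sample")
    sample_factor = (table.drop_duplicates("sample_id")
                     .set_index("sample_id")["factor"])
    factors = sample_factor.loc[wide.columns].to_numpy()

    X = np.stack([(factors == f).astype(float) for f in FACTORS], axis=1)
    n_samples = X.shape[0]
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = xtx_inv @ X.T                      # 4 x n_samples
    Y = wide.to_numpy(dtype=float)           # n_probes x n_samples
    beta = Y @ hat.T                         # n_probes x 4
    resid = Y - beta @ X.T
    df_resid = n_samples - 4
    if df_resid > 0:
        s2 = (resid ** 2).sum(axis=1) / df_resid
    else:
        s2 = np.full(len(wide), np.nan)

    out = pd.DataFrame({"probe_id": wide.index.to_numpy()})
    for name, L in CONTRASTS.items():
        out[name] = beta @ L
        out[f"v_{name}"] = float(L @ xtx_inv @ L)
    out["s2"] = s2
    out["df_resid"] = df_resid
    for name in CONTRASTS:
        out[f"se_{name}"] = np.sqrt(out["s2"] * out[f"v_{name}"])
    return out


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to the observed sample variances.

    Under the hierarchical model s2 ~ s0^2 * F(df, d0), the log variances
    have mean log(s0^2) + [psi(df/2)-log(df/2)] - [psi(d0/2)-log(d0/2)] and
    variance psi'(df/2) + psi'(d0/2). Returns (d0, s0^2); d0 may be inf when
    the observed spread is no larger than expected under a shared variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 10:
        raise ValueError("insufficient probes to estimate prior")
    z = np.log(s2)
    e_bias = special.digamma(df / 2.0) - np.log(df / 2.0)
    evar = np.var(z, ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s0_bias = special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        s0_2 = float(np.exp(np.mean(z) - e_bias + s0_bias))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(z) - e_bias))
    return d0, s0_2


def moderate(estimates: pd.DataFrame, fdr_q: float = 0.05) -> pd.DataFrame:
    """Add moderated t, p and BH q-values for every contrast.

    The posterior variance is the precision-weighted blend
    s2_post = (d0*s0^2 + df*s2) / (d0 + df); the moderated t uses s2_post on
    d0 + df degrees of freedom. Probes with undefined residual variance are
    excluded from the prior fit and get NaN statistics.
    """
    out = estimates.copy()
    df = float(out["df_resid"].iloc[0])
    s2 = out["s2"].to_numpy(dtype=float)
    usable = np.isfinite(s2) & (s2 >= 0) & (df > 0)
    if usable.sum() < 10:
        raise ValueError("insufficient probes to estimate prior")
    d0, s0_2 = estimate_prior(np.maximum(s2[usable], 1e-300), df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    s2_post[~usable] = np.nan
    out["s2_post"] = s2_post
    out["d0"] = d0
    out["s0_2"] = s0_2
    out["df_total"] = df_total
    for name in CONTRASTS:
        se = np.sqrt(s2_post * out[f"v_{name}"].to_numpy())
        with np.errstate(divide="ignore", invalid="ignore"):
            t = out[name].to_numpy() / se
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        out[f"t_{name}"] = t
        out[f"p_{name}"] = p
        out[f"q_{name}"] = q
        out[f"sig_{name}"] = q < fdr_q
    return out


def fit_and_moderate(table: pd.DataFrame, fdr_q: float = 0.05) -> pd.DataFrame:
    """Convenience: :func:`fit_contrasts` followed by :func:`moderate`."""
    return moderate(fit_contrasts(table), fdr_q=fdr_q)
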