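"""Circular binary segmentation and Gaussian-mixture classification.

This is the engine behind both copy-number (CGH) segment calling and DMR
calling: ordered per-chromosome probe statistics are cut into segments of
homogeneous mean by recursive circular binary segmentation (CBS) with a
permutation test, the segment means are modeled as a K-component univariate
Gaussian mixture with unequal variances fit by EM, and each segment is
labeled by its posterior probability of arising from the extreme components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._rng import substream


@dataclass
class Segment:
    """A maximal run of probes with a shared mean statistic.

    ``start``/``end`` are probe indices within the segmented series
    (half-open); genomic coordinates are attached downstream from the probe
    map. Labels: class1 = lowest-mean mixture component, class3 = highest,
    no_change = middle, unclassified = no component reaches the posterior
    threshold.
    """

    start: int
    end: int
    mean: float
    label: str = "unlabeled"
    posterior: np.ndarray | None = None

    @property
    def n_probes(self) -> int:
        return self.end - self.start


@dataclass
class MixtureModel:
    """Univariate Gaussian mixture with unequal variances, sorted by mean."""

    means: np.ndarray
    variances: np.ndarray
    proportions: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.means)


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------

def _arc_t_max(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Best circular arc (i, j] by two-sample |t|, with tie-breaking.

    Scans all non-wrapping windows of every length k in
    [min_width, n - min_width]; a wrapping arc's complement is a non-wrapping
    window of the complementary length with the same |t|, so the scan covers
    every circular arc. Ties resolve to the smallest left index, then the
    shortest arc. A zero pooled variance with distinct means scores +inf.
    """
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    S2 = np.concatenate([[0.0], np.cumsum(x * x)])
    tot, tot2 = S[-1], S2[-1]
    best = (-np.inf, -1, -1)  # (t2, i, k)
    for k in range(min_width, n - min_width + 1):
        win = S[k:] - S[:-k]
        win2 = S2[k:] - S2[:-k]
        m_in = win / k
        m_out = (tot - win) / (n - k)
        ss_within = tot2 - k * m_in ** 2 - (n - k) * m_out ** 2
        s2p = np.maximum(ss_within, 0.0) / max(n - 2, 1)
        num = (m_in - m_out) ** 2 * (k * (n - k) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = np.where(s2p > 1e-300, num / s2p,
                          np.where(num > 1e-300, np.inf, 0.0))
        kmax = float(np.max(t2))
        if kmax > best[0]:
            i = int(np.argmax(t2))
            best = (kmax, i, k)
        elif kmax == best[0] and best[0] > -np.inf:
            i = int(np.argmax(t2))
            if i < best[1]:
                best = (kmax, i, k)
    t2, i, k = best
    return t2, i, i + k


def _perm_max_t(x: np.ndarray, min_width: int, n_perm: int,
                rng: np.random.Generator, batch: int = 250) -> np.ndarray:
    """Max arc t^2 for permuted copies of x (vectorized over permutations)."""
    n = len(x)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm = rng.permuted(np.tile(x, (b, 1)), axis=1)
        S = np.concatenate([np.zeros((b, 1)), np.cumsum(perm, axis=1)], axis=1)
        S2 = np.concatenate([np.zeros((b, 1)),
                             np.cumsum(perm * perm, axis=1)], axis=1)
        tot = S[:, -1:]
        tot2 = S2[:, -1:]
        best = np.full(b, -np.inf)
        for k in range(min_width, n - min_width + 1):
            win = S[:, k:] - S[:, :-k]
            win2 = S2[:, k:] - S2[:, :-k]
            m_in = win / k
            m_out = (tot - win) / (n - k)
            ss_within = tot2 - k * m_in ** 2 - (n - k) * m_out ** 2
            s2p = np.maximum(ss_within, 0.0) / max(n - 2, 1)
            num = (m_in - m_out) ** 2 * (k * (n - k) / n)
            with np.errstate(divide="ignore", invalid="ignore"):
                t2 = np.where(s2p > 1e-300, num / s2p,
                              np.where(num > 1e-300, np.inf, 0.0))
            best = np.maximum(best, t2.max(axis=1))
        out[done:done + b] = best
        done += b
    return out


def cbs_segment(values: np.ndarray, alpha: float = 0.01, n_perm: int = 1000,
                min_width: int = 2, seed: int = 0) -> list[Segment]:
    """Segment an ordered series by recursive CBS with a permutation test.

    For the current segment the arc maximizing the two-sample |t| between
    inside and outside is found by exact O(n^2) scan; the split is accepted
    iff its permutation p-value (n_perm within-segment shuffles) is <= alpha,
    and the procedure recurses into the parts. Series shorter than
    2*min_width return a single segment.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    rng = substream(seed, "cbs")
    segments: list[Segment] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        seg = x[lo:hi]
        if n < 2 * min_width or np.ptp(seg) == 0.0:
            segments.append(Segment(lo, hi, float(seg.mean())))
            return
        t2, i, j = _arc_t_max(seg, min_width)
        if not np.isfinite(t2) and t2 < 0:
            segments.append(Segment(lo, hi, float(seg.mean())))
            return
        if np.isposinf(t2):
            # zero pooled variance with distinct means: two exactly-constant
            # runs. Under any continuous noise model this has probability
            # zero by chance, so it is a certain change point; the
            # permutation null (plain exchangeability) is misspecified here
            # and would charge the split the combinatorial price of the
            # arrangement instead.
            p = 0.0
        else:
            perm = _perm_max_t(seg, min_width, n_perm, rng)
            p = (1.0 + np.sum(perm >= t2)) / (n_perm + 1.0)
        if p > alpha:
            segments.append(Segment(lo, hi, float(seg.mean())))
            return
        cuts = sorted({lo, lo + i, lo + j, hi})
        for a, b in zip(cuts[:-1], cuts[1:]):
            recurse(a, b)

    recurse(0, len(x))
    segments.sort(key=lambda s: s.start)
    return segments


# ---------------------------------------------------------------------------
# EM for a univariate Gaussian mixture
# ---------------------------------------------------------------------------

def _log_pdf_matrix(x: np.ndarray, means: np.ndarray, variances: np.ndarray,
                    proportions: np.ndarray) -> np.ndarray:
    """n x K matrix of log(pi_k) + log N(x | mu_k, sigma_k^2)."""
    d = x[:, None] - means[None, :]
    return (np.log(proportions)[None, :]
            - 0.5 * np.log(2.0 * np.pi * variances)[None, :]
            - 0.5 * d * d / variances[None, :])


def em_fit(values: np.ndarray, K: int = 3, init: str | tuple = "quantile",
           tol: float = 1e-6, max_iter: int = 500, seed: int = 0) -> MixtureModel:
    """Fit a K-component Gaussian mixture with unequal variances by EM.

    Initialization is deterministic: component means at evenly spaced
    quantiles (10th/50th/90th percentile for K=3), shared initial variance,
    equal proportions. A collapsing component (variance below floor with
    vanishing weight) triggers a jittered restart, up to 5 times.
    The log-likelihood is non-decreasing across iterations.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2 * K:
        raise ValueError(f"need at least {2 * K} points to fit {K} components")
    rng = substream(seed, "em")
    # scale-aware floor: a component is allowed to concentrate on very few
    # points (a lone extreme segment is a real class), but never to a true
    # zero-variance singularity
    var_floor = max(1e-12, 1e-9 * float(np.var(x)))

    if isinstance(init, str):
        if init != "quantile":
            raise ValueError(f"unknown init: {init!r}")
        qs = np.linspace(0.1, 0.9, K) if K > 1 else np.array([0.5])
        base_means = np.quantile(x, qs)
    else:
        base_means = np.asarray(init, dtype=float)
        if len(base_means) != K:
            raise ValueError("init means must have length K")

    last_err = None
    for attempt in range(6):
        means = base_means.copy()
        if attempt > 0:
            means = means + rng.normal(0.0, max(x.std(), 1e-3) * 0.1, size=K)
        variances = np.full(K, max(x.var(), var_floor))
        proportions = np.full(K, 1.0 / K)
        trace: list[float] = []
        converged = False
        failed = False
        it = 0
        for it in range(1, max_iter + 1):
            logp = _log_pdf_matrix(x, means, variances, proportions)
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            resp = np.exp(logp - norm[:, None])
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-8):
                failed = True
                last_err = "component collapsed (empty)"
                break
            means = (resp * x[:, None]).sum(axis=0) / nk
            d = x[:, None] - means[None, :]
            variances = np.maximum((resp * d * d).sum(axis=0) / nk,
                                   var_floor)
            proportions = nk / n
            trace.append(ll)
            if len(trace) > 1:
                denom = max(abs(trace[-2]), 1.0)
                if (trace[-1] - trace[-2]) / denom < tol:
                    converged = True
                    break
        if failed:
            continue
        order = np.argsort(means)
        logp = _log_pdf_matrix(x, means[order], variances[order],
                               proportions[order])
        final_ll = float(logsumexp(logp, axis=1).sum())
        return MixtureModel(means=means[order], variances=variances[order],
                            proportions=proportions[order],
                            log_likelihood=final_ll, n_iterations=it,
                            converged=converged, loglik_trace=trace)
    raise RuntimeError(f"EM failed after 5 restarts: {last_err}")


def posterior(values: np.ndarray, model: MixtureModel,
              effective_n: np.ndarray | None = None) -> np.ndarray:
    """Posterior component probabilities for each value under the mixture.

    With ``effective_n`` (e.g. probes per segment) the component variances
    are divided by it, treating each value as a mean of that many draws.
    """
    x = np.asarray(values, dtype=float)
    variances = model.variances[None, :]
    if effective_n is not None:
        variances = variances / np.asarray(effective_n, dtype=float)[:, None]
    d = x[:, None] - model.means[None, :]
    logp = (np.log(model.proportions)[None, :]
            - 0.5 * np.log(2.0 * np.pi * variances)
            - 0.5 * d * d / variances)
    return np.exp(logp - logsumexp(logp, axis=1)[:, None])


def classify_by_posterior(segments: list[Segment], model: MixtureModel,
                          threshold: float = 0.95,
                          weight_by: str = "segment_mean_only") -> list[Segment]:
    """Label segments by mixture posterior at their mean.

    A segment is labeled class1/class3 iff that extreme component's posterior
    exceeds ``threshold``; the middle component above threshold gives
    no_change; anything else is unclassified. ``weight_by='nprobe_weighted'``
    scales component variances by 1/n_probes (a segment mean of many probes
    is a more precise observation).
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must be in (0.5, 1]")
    if weight_by not in ("segment_mean_only", "nprobe_weighted"):
        raise ValueError(f"unknown weight_by: {weight_by!r}")
    if model.K != 3:
        raise ValueError("classification expects a 3-component model")
    means = np.array([s.mean for s in segments])
    eff = (np.array([s.n_probes for s in segments], dtype=float)
           if weight_by == "nprobe_weighted" else None)
    post = posterior(means, model, effective_n=eff)
    labels = np.array(["class1", "no_change", "class3"])
    out = []
    for seg, pr in zip(segments, post):
        k = int(np.argmax(pr))
        label = labels[k] if pr[k] > threshold else "unclassified"
        out.append(Segment(seg.start, seg.end, seg.mean, label=label,
                           posterior=pr))
    return out
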