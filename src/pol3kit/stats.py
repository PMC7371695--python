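"""Statistical primitives for the count-based pipelines.

Self-contained implementations of the between-sample and per-feature
statistics the analysis modules build on:

* :func:`tmm_factors` — trimmed-mean-of-M-values composition scaling
  factors between sequencing libraries.
* :func:`moderated_t` — two-sample t-tests with empirical-Bayes variance
  shrinkage (posterior variance ``(d0*s0^2 + d*s^2)/(d0 + d)``, p-values on
  ``d0 + d`` degrees of freedom), with the shrinkage prior estimated by
  method-of-moments on the log sample variances when not supplied.
* :func:`bh_adjust` — Benjamini–Hochberg step-up FDR adjustment.
* :func:`ks_two_sample` — two-sample Kolmogorov–Smirnov D with the
  asymptotic two-sided p-value.
* :func:`hypergeom_overlap` — expected overlap of two gene sets drawn from
  a common universe, with hypergeometric enrichment/depletion tails.

scipy supplies distribution functions only; the statistics themselves are
computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as spstats

__all__ = [
    "EbayesPrior",
    "tmm_factors",
    "estimate_ebayes_prior",
    "moderated_t",
    "bh_adjust",
    "ks_two_sample",
    "hypergeom_overlap",
]


@dataclass(frozen=True)
class EbayesPrior:
    """Empirical-Bayes variance prior: scale ``s0_sq`` and df ``d0``.

    ``d0`` may be ``inf`` (complete shrinkage: every feature uses ``s0_sq``);
    internally it is capped at 1e9, numerically indistinguishable from
    infinite for any realistic residual df.
    """

    s0_sq: float
    d0: float

    def __post_init__(self) -> None:
        if not (self.s0_sq > 0):
            raise ValueError(f"prior variance must be > 0, got {self.s0_sq}")
        if self.d0 < 0:
            raise ValueError(f"prior df must be >= 0, got {self.d0}")


D0_CAP = 1e9


def _as_matrix(counts) -> tuple[np.ndarray, list, list]:
    """Coerce a DataFrame or array to (values, feature ids, sample labels)."""
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.index), list(counts.columns)
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2:
        raise ValueError("count matrix must be 2-D (features x samples)")
    return arr, list(range(arr.shape[0])), list(range(arr.shape[1]))


def tmm_factors(
    counts,
    ref_sample=None,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    For sample *s* against the reference *r*, with library sizes ``N``:
    per-feature ``M = log2((y_s/N_s)/(y_r/N_r))`` and
    ``A = 0.5*log2(y_s*y_r/(N_s*N_r))`` are computed over features nonzero in
    both samples; the upper and lower ``logratio_trim`` quantiles of M and
    ``abundance_trim`` quantiles of A are discarded; the factor is
    ``2**(sum(w*M)/sum(w))`` with inverse delta-method variance weights
    computed from the tag fractions ``p = y/N``:
    ``w = 1 / ((1 - p_s)/p_s + (1 - p_r)/p_r)``.  Weighting by composition
    rather than raw counts makes each factor an exact function of the two
    samples' tag fractions, so factors are invariant to sequencing depth.
    Factors are rescaled so their geometric mean is 1.

    ``ref_sample=None`` picks the sample whose upper-quartile CPM is closest
    to the mean upper quartile (deterministic).
    """
    mat, _, samples = _as_matrix(counts)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if np.any(mat < 0):
        raise ValueError("negative counts")
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        bad = [samples[i] for i in np.nonzero(lib <= 0)[0]]
        raise ValueError(f"zero-total column(s): {bad}")

    if ref_sample is None:
        uq = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = samples.index(ref_sample)

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(
            mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], logratio_trim, abundance_trim
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, logratio_trim, abundance_trim) -> float:
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        raise ValueError("no features nonzero in both sample and reference")
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # edgeR-style degenerate case: no composition difference detectable
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    w = 1.0 / ((1.0 - p_obs) / p_obs + (1.0 - p_ref) / p_ref)

    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = spstats.rankdata(m, method="average")
    rank_a = spstats.rankdata(a, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        raise ValueError(
            "trimming removed all features; widen logratio_trim/abundance_trim"
        )
    return float(2 ** (np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])))


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log scale)."""
    if x <= 0:
        return D0_CAP * 2  # over the cap: treated as infinite d0
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_ebayes_prior(sample_vars: np.ndarray, df: float) -> EbayesPrior:
    """Method-of-moments fit of a scaled-F prior to per-feature variances.

    Models ``s^2 ~ s0^2 * F(df, d0)`` and matches the first two moments of
    ``log s^2`` using digamma/trigamma identities; features with zero sample
    variance are excluded from the fit.
    """
    v = np.asarray(sample_vars, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 2:
        raise ValueError(
            "cannot estimate a variance prior from <2 positive sample variances; "
            "supply an EbayesPrior explicitly"
        )
    z = np.log(v)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        if d0 > D0_CAP:
            d0 = D0_CAP
        s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = D0_CAP
        s0_sq = math.exp(e_mean)
    return EbayesPrior(s0_sq=s0_sq, d0=d0)


def moderated_t(
    matrix,
    groups,
    prior: EbayesPrior | None = None,
    alpha: float = 0.01,
    strict: bool = True,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-tests, one per feature.

    Parameters
    ----------
    matrix
        features x samples real-valued scores (DataFrame or array).
    groups
        length-n_samples sequence with exactly two levels; the log2 fold
        change is group2 - group1 in order of first appearance.
    prior
        Variance prior; estimated from the data when ``None`` (requires
        >=2 samples in at least one group... residual df >= 1 overall).
    alpha
        Significance threshold on the BH-adjusted p-value.
    strict
        ``True`` flags ``adj_p < alpha``, ``False`` flags ``adj_p <= alpha``.

    Returns a DataFrame indexed by feature with columns ``log2fc``,
    ``avg_score`` (mean of the two group means — the MvA x-axis), ``t_mod``,
    ``df_total``, ``p``, ``adj_p``, ``significant``.
    """
    mat, features, samples = _as_matrix(matrix)
    if not np.all(np.isfinite(mat)):
        raise ValueError("scores must be finite")
    groups = np.asarray(groups)
    if groups.size != mat.shape[1]:
        raise ValueError(
            f"groups has length {groups.size} but matrix has {mat.shape[1]} samples"
        )
    levels = list(dict.fromkeys(groups.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    idx1 = groups == levels[0]
    idx2 = groups == levels[1]
    n1, n2 = int(idx1.sum()), int(idx2.sum())
    df_resid = n1 + n2 - 2
    if prior is None and (n1 < 2 or n2 < 2):
        raise ValueError(
            "each group needs >=2 samples to estimate the variance prior; "
            "supply `prior` for smaller designs"
        )

    x1, x2 = mat[:, idx1], mat[:, idx2]
    mean1, mean2 = x1.mean(axis=1), x2.mean(axis=1)
    # pooled (equal-variance) per-feature sample variance
    ss = np.zeros(mat.shape[0])
    if n1 > 1:
        ss += x1.var(axis=1, ddof=1) * (n1 - 1)
    if n2 > 1:
        ss += x2.var(axis=1, ddof=1) * (n2 - 1)
    s_sq = ss / df_resid if df_resid > 0 else np.full(mat.shape[0], np.nan)

    if prior is None:
        if np.all(s_sq <= 0):
            raise ValueError(
                "all features have zero pooled variance; the variance prior is degenerate"
            )
        prior = estimate_ebayes_prior(s_sq, df_resid)

    d0 = min(prior.d0, D0_CAP)
    if d0 + df_resid <= 0:
        raise ValueError("total degrees of freedom (d0 + residual df) must be > 0")
    s_post_sq = (d0 * prior.s0_sq + df_resid * s_sq) / (d0 + df_resid)
    se = np.sqrt(s_post_sq * (1.0 / n1 + 1.0 / n2))
    delta = mean2 - mean1
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, delta / se, np.where(delta == 0, 0.0, np.inf * np.sign(delta)))
    df_total = d0 + df_resid
    p = 2.0 * spstats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    adj = bh_adjust(p)
    significant = (adj < alpha) if strict else (adj <= alpha)
    return pd.DataFrame(
        {
            "log2fc": delta,
            "avg_score": (mean1 + mean2) / 2.0,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "adj_p": adj,
            "significant": significant,
        },
        index=pd.Index(features, name="feature_id"),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (asymptotic two-sided p).

    D is the supremum over all pooled data points of the absolute difference
    of the two empirical CDFs (evaluated at every distinct pooled value, so
    ties are handled deterministically); the p-value uses the Kolmogorov
    asymptotic series at ``sqrt(n1*n2/(n1+n2)) * D``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.union1d(x, y)
    fx = np.searchsorted(x, grid, side="right") / x.size
    fy = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.max(np.abs(fx - fy)))
    en = math.sqrt(x.size * y.size / (x.size + y.size))
    p = _kolmogorov_sf(en * d)
    return d, min(max(p, 0.0), 1.0)


def _kolmogorov_sf(t: float) -> float:
    """P(sup|B(F)| > t) for the Kolmogorov distribution: 2*sum (-1)^{k-1} e^{-2k^2 t^2}."""
    if t <= 0:
        return 1.0
    total = 0.0
    for k in range(1, 101):
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * t * t)
        total += term
        if abs(term) < 1e-16:
            break
    return total


def hypergeom_overlap(
    n1: int, n2: int, N: int, k_observed: int | None = None
) -> tuple[float, float, float]:
    """Expected overlap of two size-``n1``/``n2`` sets in a universe of ``N``.

    Returns ``(expected, p_depletion, p_enrichment)`` where
    ``expected = n1*n2/N`` and the tails come from the hypergeometric
    distribution of the overlap count: ``p_depletion = P(K <= k)``,
    ``p_enrichment = P(K >= k)`` (both include the observed point mass).
    When ``k_observed`` is None only the expectation is meaningful and the
    tails are returned as NaN.
    """
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError(f"need 0 <= n1, n2 <= N; got n1={n1}, n2={n2}, N={N}")
    expected = n1 * n2 / N if N > 0 else float("nan")
    if k_observed is None:
        return expected, float("nan"), float("nan")
    if not (0 <= k_observed <= min(n1, n2)):
        raise ValueError(f"k_observed={k_observed} outside [0, min(n1, n2)]")
    if k_observed < n1 + n2 - N:
        raise ValueError(f"k_observed={k_observed} below the forced minimum {n1 + n2 - N}")
    dist = spstats.hypergeom(N, n1, n2)
    p_dep = float(dist.cdf(k_observed))
    p_enr = float(dist.sf(k_observed - 1))
    return expected, min(p_dep, 1.0), min(p_enr, 1.0)
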