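"""Spike-in-normalized pol III ChIP occupancy analysis.

Occupancy at a pol III locus is scored as the log2 ratio of IP to input tag
counts after each library is scaled by its exogenous spike-in total (tags
mapping to the spiked human chromatin), so that genome-wide shifts in pol
III binding between samples are preserved rather than normalized away:

    score_i = log2( ((ip_i + a) / ip_spike_total) /
                    ((input_i + a) / input_spike_total) )

with pseudocount ``a`` (default 0.5) guarding unoccupied loci.

Downstream operations: an occupied/not-occupied cut-off estimated from the
bimodal score distribution (two-component Gaussian mixture, EM with
deterministic median-split initialization, boundary at posterior 0.5),
reference-sample quantile classes, moderated-t differential occupancy with
an MvA table, Venn-style partitions of significant loci across conditions,
cross-experiment stability classes, cumulative isotype/isoacceptor scores
with quartile ranks, and positive score differences for circular-plot
exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pol3kit.catalog import LocusCatalog, group_loci
from pol3kit.stats import EbayesPrior, moderated_t

__all__ = [
    "ChipSample",
    "CutoffModel",
    "spike_normalized_scores",
    "score_sample_set",
    "estimate_occupancy_cutoff",
    "assign_quantile_classes",
    "differential_occupancy",
    "venn_partition",
    "cross_condition_classes",
    "aggregate_group_scores",
    "positive_score_differences",
]


@dataclass
class ChipSample:
    """One ChIP experiment: per-locus IP/input tag counts plus spike totals."""

    sample_id: str
    genotype: str  # e.g. WT / KO
    state: str  # e.g. fasted / refed
    ip_counts: pd.Series  # locus_id -> IP tags
    input_counts: pd.Series  # locus_id -> input tags
    ip_spike_total: float
    input_spike_total: float

    def __post_init__(self) -> None:
        if self.ip_spike_total <= 0 or self.input_spike_total <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: spike totals must be > 0 "
                f"(got IP {self.ip_spike_total}, input {self.input_spike_total})"
            )
        if (self.ip_counts < 0).any() or (self.input_counts < 0).any():
            raise ValueError(f"sample {self.sample_id!r}: negative tag counts")


def spike_normalized_scores(sample: ChipSample, pseudocount: float = 0.5) -> pd.Series:
    """Spike-normalized log2(IP/input) occupancy score per locus."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    missing = sample.ip_counts.index.difference(sample.input_counts.index)
    if len(missing):
        raise ValueError(
            f"sample {sample.sample_id!r}: loci missing from input table: "
            f"{list(missing[:5])}..."
        )
    inp = sample.input_counts.loc[sample.ip_counts.index]
    ip_density = (sample.ip_counts + pseudocount) / sample.ip_spike_total
    input_density = (inp + pseudocount) / sample.input_spike_total
    scores = np.log2(ip_density / input_density)
    scores.name = sample.sample_id
    return scores


def score_sample_set(samples: list[ChipSample], pseudocount: float = 0.5) -> pd.DataFrame:
    """Score a set of samples into a locus x sample matrix (shared universe)."""
    cols = [spike_normalized_scores(s, pseudocount) for s in samples]
    mat = pd.concat(cols, axis=1)
    if mat.isna().any().any():
        raise ValueError("samples do not share a common locus universe")
    return mat


@dataclass
class CutoffModel:
    """Two-component Gaussian mixture fit with the occupied/not cut-off."""

    cutoff: float
    means: tuple[float, float]  # (low mode, high mode)
    sds: tuple[float, float]
    weights: tuple[float, float]
    n_iter: int
    log_likelihood: float
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def is_occupied(self, scores) -> pd.Series | np.ndarray:
        occ = np.asarray(scores, dtype=float) >= self.cutoff
        if isinstance(scores, pd.Series):
            return pd.Series(occ, index=scores.index, name="occupied")
        return occ


def _normal_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))


def estimate_occupancy_cutoff(
    scores,
    max_iter: int = 500,
    tol: float = 1e-10,
    min_sd: float = 1e-3,
) -> CutoffModel:
    """Estimate the occupied/not-occupied score cut-off from a bimodal sample.

    Fits a two-component Gaussian mixture by EM with deterministic
    initialization (components seeded from the halves below/above the
    median, equal weights) and places the cut-off where the posterior
    probability of the high component crosses 0.5 between the two means.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ValueError(f"need >=50 scores to estimate a cut-off, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("scores are constant; no cut-off exists")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.array([max(lo.std(), min_sd), max(hi.std(), min_sd)])
    w = np.array([0.5, 0.5])

    ll_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        dens = np.stack([w[k] * _normal_pdf(x, mu[k], sd[k]) for k in range(2)])
        total = dens.sum(axis=0)
        total = np.maximum(total, 1e-300)
        resp = dens / total
        ll = float(np.sum(np.log(total)))
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mu = (resp @ x) / nk
        sd = np.sqrt(np.maximum((resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk, min_sd**2))
        w = nk / x.size
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_prev = ll
    if not converged:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(last log-likelihood change {ll - ll_prev:.3e}); "
            f"means={mu.tolist()}, sds={sd.tolist()}, weights={w.tolist()}"
        )

    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    if mu[1] - mu[0] < 1e-9:
        raise ValueError("mixture collapsed to one component; distribution not bimodal")
    cutoff = _posterior_boundary(mu, sd, w)
    return CutoffModel(
        cutoff=float(cutoff),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        weights=(float(w[0]), float(w[1])),
        n_iter=it,
        log_likelihood=ll,
        diagnostics={"n": int(x.size)},
    )


def _posterior_boundary(mu, sd, w) -> float:
    """Score where the two weighted component densities are equal, in (mu0, mu1)."""
    from scipy.optimize import brentq

    def log_ratio(t):
        return (
            math.log(w[1] / w[0])
            + math.log(sd[0] / sd[1])
            - 0.5 * ((t - mu[1]) / sd[1]) ** 2
            + 0.5 * ((t - mu[0]) / sd[0]) ** 2
        )

    lo, hi = mu[0], mu[1]
    f_lo, f_hi = log_ratio(lo), log_ratio(hi)
    if f_lo * f_hi < 0:
        return brentq(log_ratio, lo, hi, xtol=1e-12)
    # posterior never crosses 0.5 between the means (very unequal weights);
    # fall back to the midpoint weighted by the sds
    return float((mu[0] * sd[1] + mu[1] * sd[0]) / (sd[0] + sd[1]))


def assign_quantile_classes(reference_scores: pd.Series, q: int = 5) -> pd.Series:
    """Assign each locus a class 1..q by its quantile in the reference sample.

    Class 1 is the lowest-scoring quantile.  Class sizes differ by at most 1
    when scores are distinct; ties at a boundary go to the lower class
    (ranking ties are broken by locus order, deterministically).
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    n = len(reference_scores)
    if q > n:
        raise ValueError(f"q={q} exceeds the number of loci ({n})")
    from scipy.stats import rankdata

    ranks = rankdata(reference_scores.to_numpy(), method="min").astype(int) - 1
    classes = (ranks * q) // n + 1
    return pd.Series(classes, index=reference_scores.index, name="quantile_class")


def differential_occupancy(
    scores: pd.DataFrame,
    groups,
    alpha: float = 0.01,
    cutoff: float | None = None,
    prior: EbayesPrior | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Moderated-t differential occupancy between two sample groups.

    Returns the moderated-t table (``log2fc``, ``avg_score``, ``t_mod``,
    ``p``, ``adj_p``, ``significant``) augmented with a ``below_cutoff``
    column (the MvA "grey" class: score below the occupied cut-off in every
    sample) when ``cutoff`` is given.  ``avg_score``/``log2fc`` are the MvA
    x/y axes.
    """
    res = moderated_t(scores, groups, prior=prior, alpha=alpha, strict=strict)
    if cutoff is not None:
        res["below_cutoff"] = (scores < cutoff).all(axis=1).to_numpy()
    else:
        res["below_cutoff"] = False
    return res


def _significant_ids(res: pd.DataFrame, direction: str) -> set:
    sig = res["significant"]
    if direction == "up":
        sig = sig & (res["log2fc"] > 0)
    elif direction == "down":
        sig = sig & (res["log2fc"] < 0)
    elif direction != "any":
        raise ValueError(f"direction must be 'up', 'down' or 'any', got {direction!r}")
    return set(res.index[sig])


def venn_partition(
    results_a: pd.DataFrame, results_b: pd.DataFrame, direction: str = "up"
) -> tuple[int, int, int]:
    """(A-only, both, B-only) counts of loci significant in the given direction."""
    if set(results_a.index) != set(results_b.index):
        raise ValueError("results A and B cover different locus universes")
    sig_a = _significant_ids(results_a, direction)
    sig_b = _significant_ids(results_b, direction)
    return (len(sig_a - sig_b), len(sig_a & sig_b), len(sig_b - sig_a))


def cross_condition_classes(
    res_x: pd.DataFrame, res_y: pd.DataFrame
) -> pd.Series:
    """Classify each locus by its joint significance pattern in two contrasts.

    ``stable``            not significant in either contrast
    ``reciprocal``        significant in both with opposite fold-change signs
    ``concordant``        significant in both with the same sign
    ``X_preferential``    significant only in X
    ``Y_preferential_up`` / ``Y_preferential_down``
                          significant only in Y, split by the sign of its
                          fold change

    Exhaustive and exclusive: every locus receives exactly one class.
    """
    if set(res_x.index) != set(res_y.index):
        raise ValueError("contrasts cover different locus universes")
    res_y = res_y.loc[res_x.index]
    sx = res_x["significant"].to_numpy()
    sy = res_y["significant"].to_numpy()
    fx = res_x["log2fc"].to_numpy()
    fy = res_y["log2fc"].to_numpy()
    out = np.where(
        ~sx & ~sy,
        "stable",
        np.where(
            sx & sy,
            np.where(np.sign(fx) != np.sign(fy), "reciprocal", "concordant"),
            np.where(
                sx,
                "X_preferential",
                np.where(fy < 0, "Y_preferential_down", "Y_preferential_up"),
            ),
        ),
    )
    return pd.Series(out, index=res_x.index, name="cross_class")


def aggregate_group_scores(
    scores: pd.Series,
    catalog: LocusCatalog,
    level: str = "isotype",
) -> pd.DataFrame:
    """Cumulative occupancy score per tRNA isotype or isoacceptor group.

    The cumulative score is log2 of the sum of linear-scale per-locus
    occupancies (``log2(sum_i 2**score_i)``), so it is additive on linear
    scale and permutation-invariant within groups.  Groups are ranked by
    cumulative score (1 = highest) and assigned quartiles (1 = top quartile).
    Groups with no scored locus are dropped with a warning.
    """
    import warnings

    groups = group_loci(catalog, level)
    rows = []
    for name, ids in groups.items():
        present = [i for i in ids if i in scores.index]
        if not present:
            warnings.warn(f"group {name!r} has no scored loci; omitted", stacklevel=2)
            continue
        vals = scores.loc[present].to_numpy(dtype=float)
        rows.append((name, float(np.log2(np.sum(2.0**vals))), len(present)))
    df = pd.DataFrame(rows, columns=["group", "cumulative_score", "n_loci"]).set_index("group")
    df["rank"] = df["cumulative_score"].rank(ascending=False, method="first").astype(int)
    n = len(df)
    df["quartile"] = ((df["rank"] - 1) * 4) // max(n, 1) + 1
    return df


def positive_score_differences(
    scores_ko: pd.Series,
    scores_wt: pd.Series,
    occupied: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-locus KO - WT score differences, with the positive-only export set.

    Restricted to loci occupied in at least one sample when an ``occupied``
    mask is given.  Returns the full table with columns ``delta`` and
    ``positive``; the plotted/exported subset is ``table[table.positive]``
    (negative differences stay in the full table but are excluded from the
    positive set, mirroring circular-plot conventions).
    """
    if set(scores_ko.index) != set(scores_wt.index):
        raise ValueError("KO and WT scores cover different locus universes")
    scores_wt = scores_wt.loc[scores_ko.index]
    delta = scores_ko - scores_wt
    table = pd.DataFrame({"delta": delta, "positive": delta > 0})
    if occupied is not None:
        table = table.loc[occupied.reindex(table.index, fill_value=False)]
    return table
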