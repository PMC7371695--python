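"""Gene-level RNA-seq differential expression with a dual cut-off.

Counts are filtered to expressed genes (CPM threshold in a minimum number of
samples), scaled with TMM, converted to log2-CPM, and tested per gene with
the empirical-Bayes moderated t.  A gene is *selected* as differentially
expressed only if it clears both the adjusted-p threshold and a minimum
absolute log2 fold change — the dual rule avoids calling tiny but
statistically certain shifts.  A reverse-cumulative-frequency comparison of
per-group expression, with a KS test, checks whether differential genes at
high and low expression behave alike.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pol3kit.stats import EbayesPrior, ks_two_sample, moderated_t, tmm_factors

__all__ = [
    "filter_expressed",
    "log_cpm",
    "de_analysis",
    "reverse_cumulative",
]


def filter_expressed(
    counts: pd.DataFrame, cpm_min: float = 1.0, min_samples: int | None = None
) -> pd.DataFrame:
    """Keep genes with CPM >= ``cpm_min`` in at least ``min_samples`` samples.

    ``min_samples`` defaults to half the samples (rounded down, at least 1).
    """
    if cpm_min < 0:
        raise ValueError("cpm_min must be >= 0")
    if min_samples is None:
        min_samples = max(1, counts.shape[1] // 2)
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    if cpm_min == 0:
        return counts
    lib = counts.sum(axis=0)
    cpm = counts * 1e6 / lib
    keep = (cpm >= cpm_min).sum(axis=1) >= min_samples
    return counts.loc[keep]


def log_cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """TMM-scaled log2 counts-per-million."""
    factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0) * factors
    return np.log2((counts + pseudocount) * 1e6 / eff_lib)


def de_analysis(
    counts: pd.DataFrame,
    groups,
    alpha: float = 0.01,
    lfc_min: float = 0.5,
    cpm_min: float = 1.0,
    min_samples: int | None = None,
    prior: EbayesPrior | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Differential expression with the dual adjusted-p / fold-change rule.

    Pipeline: expression filter -> TMM-scaled log2-CPM ->
    :func:`pol3kit.stats.moderated_t` (BH-adjusted) -> selection by
    ``adj_p < alpha`` AND ``|log2fc| > lfc_min``.

    Returns (per-gene result table, summary dict with ``n_expressed``,
    ``n_selected``, ``n_up``, ``n_down``).  ``direction`` is the sign of the
    fold change of group 2 relative to group 1.
    """
    groups = np.asarray(groups)
    if min_samples is None:
        sizes = pd.Series(groups).value_counts()
        min_samples = int(sizes.min())
    expressed = filter_expressed(counts, cpm_min=cpm_min, min_samples=min_samples)
    if expressed.shape[0] == 0:
        raise ValueError("no genes pass the expression filter")
    scores = log_cpm(expressed)
    res = moderated_t(scores, groups, prior=prior, alpha=alpha, strict=True)
    res = res.rename(columns={"avg_score": "avg_expr"})
    res["selected"] = res["significant"] & (res["log2fc"].abs() > lfc_min)
    res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
    summary = {
        "n_expressed": int(res.shape[0]),
        "n_selected": int(res["selected"].sum()),
        "n_up": int((res["selected"] & (res["direction"] == "up")).sum()),
        "n_down": int((res["selected"] & (res["direction"] == "down")).sum()),
    }
    return res, summary


def reverse_cumulative(
    values_by_group: dict[str, np.ndarray], grid=None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Reverse cumulative frequency curves plus a KS comparison.

    For each group *g*, the curve is ``F̄_g(x) = fraction of values >= x``
    evaluated on a shared grid (all pooled distinct values by default).
    With exactly two groups the first is the reference for the KS test.

    Returns (long-format DataFrame with columns ``x`` and one fraction column
    per group, non-increasing in ``x``; KS dict with ``d`` and ``p`` or empty
    when there are not exactly two groups).
    """
    if not values_by_group:
        raise ValueError("no groups given")
    arrays = {g: np.sort(np.asarray(v, dtype=float)) for g, v in values_by_group.items()}
    for g, v in arrays.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    if grid is None:
        grid = np.unique(np.concatenate(list(arrays.values())))
    else:
        grid = np.asarray(grid, dtype=float)
    out = pd.DataFrame({"x": grid})
    for g, v in arrays.items():
        # fraction >= x: count of values at or above each grid point
        out[g] = (v.size - np.searchsorted(v, grid, side="left")) / v.size
    ks: dict[str, float] = {}
    if len(arrays) == 2:
        (g1, v1), (g2, v2) = arrays.items()
        d, p = ks_two_sample(v1, v2)
        ks = {"d": d, "p": p, "reference": g1}
    return out, ks
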