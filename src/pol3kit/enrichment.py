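"""Gene-set and cross-study list-comparison statistics.

* :func:`gsea_es` — gene-set enrichment running score: walking down a ranked
  gene list, the running sum rises by a (statistic-weighted) increment at
  set members and falls by ``1/(N - |S|)`` at non-members; the enrichment
  score is the signed maximum deviation, with an optional seeded
  gene-label permutation p-value.
* :func:`rrho_map` — threshold-free rank-rank hypergeometric overlap: for a
  grid of rank cut-off pairs (i, j), the -log10 hypergeometric enrichment
  p-value of the overlap between the top-i genes of one list and the top-j
  of the other.  Sensitive to weak but consistent agreement between two
  differential-expression rankings.
* :func:`set_overlap_test` — fixed-threshold set overlap against the
  hypergeometric null (observed vs expected ``|A||B|/N``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pol3kit.stats import hypergeom_overlap

__all__ = ["RankedList", "gsea_es", "rrho_map", "set_overlap_test", "rank_by"]


class RankedList:
    """A gene list ordered by a statistic (descending), ties broken by gene id."""

    def __init__(self, gene_ids, statistic):
        gene_ids = list(gene_ids)
        statistic = np.asarray(statistic, dtype=float)
        if len(gene_ids) != statistic.size:
            raise ValueError("gene_ids and statistic lengths differ")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids in ranked list")
        order = sorted(range(len(gene_ids)), key=lambda i: (-statistic[i], gene_ids[i]))
        self.gene_ids = [gene_ids[i] for i in order]
        self.statistic = statistic[order]

    def __len__(self) -> int:
        return len(self.gene_ids)


def rank_by(table: pd.DataFrame, by: str = "log2fc") -> RankedList:
    """Build a RankedList from a result table.

    ``by="log2fc"`` ranks by fold change; ``by="signed_p"`` ranks by
    sign(log2fc) * -log10(p) (sign-adjusted p-values).
    """
    if by == "log2fc":
        stat = table["log2fc"].to_numpy()
    elif by == "signed_p":
        p = np.clip(table["p"].to_numpy(), 1e-300, 1.0)
        stat = np.sign(table["log2fc"].to_numpy()) * (-np.log10(p))
    else:
        raise ValueError(f"unknown ranking statistic {by!r}")
    return RankedList(list(table.index), stat)


def gsea_es(
    ranked: RankedList,
    gene_set,
    weight_exponent: float = 1.0,
    n_permutations: int = 0,
    seed: int | None = None,
) -> dict:
    """Running enrichment score of ``gene_set`` along the ranked list.

    At a hit (gene in the set) the running sum increases by
    ``|stat|^w / sum over hits of |stat|^w`` (uniform ``1/|S|`` when the hit
    weights sum to zero, e.g. ``w=0`` handled exactly); at a miss it
    decreases by ``1/(N - |S|)``.  ES is the running value of largest
    absolute magnitude (signed).  With ``n_permutations > 0`` a two-sided
    permutation p-value is computed by reassigning set labels uniformly at
    random (seeded).

    Returns ``{"es", "running", "hit_ranks", "p_perm"}``; ``p_perm`` is None
    without permutations.
    """
    gene_set = set(gene_set)
    n = len(ranked)
    is_hit = np.array([g in gene_set for g in ranked.gene_ids])
    n_hits = int(is_hit.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole list; ES is degenerate (no misses)")

    running = _running_profile(ranked.statistic, is_hit, weight_exponent)
    es = float(running[np.argmax(np.abs(running))])

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm_hits = np.zeros(n, dtype=bool)
            perm_hits[rng.choice(n, size=n_hits, replace=False)] = True
            r = _running_profile(ranked.statistic, perm_hits, weight_exponent)
            if abs(r[np.argmax(np.abs(r))]) >= abs(es):
                count += 1
        p_perm = (count + 1) / (n_permutations + 1)

    return {
        "es": es,
        "running": running,
        "hit_ranks": np.nonzero(is_hit)[0] + 1,
        "p_perm": p_perm,
    }


def _running_profile(stat: np.ndarray, is_hit: np.ndarray, w: float) -> np.ndarray:
    n = stat.size
    n_hits = int(is_hit.sum())
    weights = np.abs(stat) ** w if w != 0 else np.ones(n)
    hit_total = weights[is_hit].sum()
    steps = np.where(
        is_hit,
        (weights / hit_total) if hit_total > 0 else (1.0 / n_hits),
        -1.0 / (n - n_hits),
    )
    if hit_total <= 0:
        steps = np.where(is_hit, 1.0 / n_hits, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def rrho_map(
    list_a: RankedList, list_b: RankedList, step: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Rank-rank hypergeometric overlap map between two rankings.

    Both lists must contain exactly the same genes.  For each grid point
    (i, j) — rank thresholds in multiples of ``step`` (default ``ceil(N/100)``)
    — the overlap ``k`` of the top-i of A with the top-j of B is scored by
    the hypergeometric enrichment tail P(K >= k), reported as -log10 p.

    Returns (map as a DataFrame indexed by the A-threshold with B-threshold
    columns, info dict with ``max``, ``max_i``, ``max_j``, ``step``).
    """
    if set(list_a.gene_ids) != set(list_b.gene_ids):
        raise ValueError("the two ranked lists cover different gene universes")
    n = len(list_a)
    if step is None:
        step = -(-n // 100)
    if step < 1:
        raise ValueError("step must be >= 1")
    rank_b = {g: r for r, g in enumerate(list_b.gene_ids, start=1)}
    thresholds = np.arange(step, n + 1, step)
    # cell (bi, bj) counts genes with rank_A in its i-block and rank_B in its j-block
    nt = thresholds.size
    cells = np.zeros((nt, nt))
    for ra, g in enumerate(list_a.gene_ids, start=1):
        bi = min((ra - 1) // step, nt - 1)
        bj = min((rank_b[g] - 1) // step, nt - 1)
        if ra <= thresholds[-1] and rank_b[g] <= thresholds[-1]:
            cells[bi, bj] += 1
    k = cells.cumsum(axis=0).cumsum(axis=1)

    from scipy.stats import hypergeom

    ii = thresholds[:, None] * np.ones(nt, dtype=int)[None, :]
    jj = np.ones(nt, dtype=int)[:, None] * thresholds[None, :]
    p_enr = hypergeom.sf(k - 1, n, ii, jj)
    neglog = -np.log10(np.clip(p_enr, 1e-320, 1.0))
    df = pd.DataFrame(neglog, index=thresholds, columns=thresholds)
    df.index.name = "top_A"
    df.columns.name = "top_B"
    flat = int(np.argmax(neglog))
    mi, mj = np.unravel_index(flat, neglog.shape)
    info = {
        "max": float(neglog[mi, mj]),
        "max_i": int(thresholds[mi]),
        "max_j": int(thresholds[mj]),
        "step": int(step),
    }
    return df, info


def set_overlap_test(set_a, set_b, universe_size: int) -> dict:
    """Observed vs expected overlap of two gene sets in a shared universe.

    Returns ``observed``, ``expected`` (= |A||B|/N), and hypergeometric
    ``p_depletion`` / ``p_enrichment`` (both tails include the observed
    count).
    """
    set_a, set_b = set(set_a), set(set_b)
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise ValueError("set larger than the universe")
    observed = len(set_a & set_b)
    expected, p_dep, p_enr = hypergeom_overlap(
        len(set_a), len(set_b), universe_size, observed
    )
    return {
        "observed": observed,
        "expected": expected,
        "p_depletion": p_dep,
        "p_enrichment": p_enr,
    }
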