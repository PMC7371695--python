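"""Seeded generators emulating the study's three assay designs.

Each generator is a pure function of its parameters and a seed (identical
inputs give bit-identical outputs) and returns both the simulated tables and
a ground-truth record, so downstream tests can check error control and
parameter recovery rather than merely executing.

Emulated designs (the generators' defaults):

* ChIP: ~500 pol III loci with a bimodal occupancy-score distribution
  (occupied fraction 0.6), 2 replicate IP/input pairs per genotype, human
  spike-in chromatin at 2.5% of each library.
* Ribosome profiling: matched footprint (RF) and RNA libraries for 3
  animals per genotype, a 200-transcript Drosophila spike panel at a 1/15
  material ratio, and a global translation scale factor applied to the
  knockout's RF counts only (0.87, i.e. a ~13% reduction).
* RNA-seq: ~12,000 expressed genes, 7 wild-type vs 5 knockout libraries,
  ~7.8% of genes differentially expressed with an 89% downward bias.

Counts are negative-binomial (gamma-Poisson); per-sample random streams are
split from the seed so adding replicates never reshuffles earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pol3kit.chip import ChipSample

__all__ = ["SimTruth", "simulate_chip", "simulate_ribo", "simulate_rnaseq"]


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    seed: int
    params: dict
    per_feature: pd.DataFrame
    per_sample: pd.DataFrame = field(default_factory=pd.DataFrame)


def _nb(rng: np.random.Generator, mean, dispersion: float):
    """Negative-binomial draw via gamma-Poisson; Poisson when dispersion=0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def simulate_chip(
    n_loci: int = 500,
    occupied_fraction: float = 0.6,
    effect_loci_fraction: float = 0.1,
    effect_size: float = 2.0,
    n_reps: int = 2,
    depth: float = 1e6,
    spike_fraction: float = 0.025,
    seed: int = 0,
    score_noise_sd: float = 0.3,
    dispersion: float = 0.01,
    occupied_mean: float = 4.0,
    unoccupied_mean: float = -2.0,
    mode_sd: float = 1.0,
) -> tuple[list[ChipSample], SimTruth]:
    """Simulate spike-in ChIP IP/input count tables for a WT/KO contrast.

    Occupied loci sit around ``occupied_mean`` log2 enrichment, unoccupied
    around ``unoccupied_mean`` (bimodal score distribution).  A fraction
    ``effect_loci_fraction`` of the *occupied* loci gain ``effect_size``
    log2 units of occupancy in the KO genotype.  Each replicate adds
    N(0, ``score_noise_sd``) biological noise on the log2 enrichment;
    ``dispersion`` models only the residual overdispersion of tag counting
    in pooled libraries (biological replicate variation is the explicit
    score-noise term, so the default is near-Poisson).
    Spike totals are ``depth * spike_fraction`` with per-sample depth
    noise; IP locus counts are negative-binomial around the enrichment
    implied by the true scores.

    Returns (samples: 2 genotypes x ``n_reps`` :class:`ChipSample`, truth).
    """
    for name, val in [
        ("occupied_fraction", occupied_fraction),
        ("effect_loci_fraction", effect_loci_fraction),
        ("spike_fraction", spike_fraction),
    ]:
        _check_fraction(name, val)
    if n_reps < 1 or n_loci < 1:
        raise ValueError("n_loci and n_reps must be >= 1")
    if not (0 < spike_fraction < 1):
        raise ValueError("spike_fraction must be in (0, 1)")

    ss = np.random.SeedSequence(seed)
    shared_ss, *sample_ss = ss.spawn(1 + 2 * n_reps * 2)  # 2 genotypes, IP+input streams
    rng = np.random.default_rng(shared_ss)

    locus_ids = [f"locus_{i + 1:04d}" for i in range(n_loci)]
    lam = rng.lognormal(mean=0.0, sigma=0.5, size=n_loci)
    lam /= lam.sum()
    n_occ = int(round(occupied_fraction * n_loci))
    occupied = np.zeros(n_loci, dtype=bool)
    occupied[rng.choice(n_loci, size=n_occ, replace=False)] = True
    true_score = np.where(
        occupied,
        rng.normal(occupied_mean, mode_sd, n_loci),
        rng.normal(unoccupied_mean, mode_sd, n_loci),
    )
    effect = np.zeros(n_loci)
    occ_idx = np.nonzero(occupied)[0]
    n_eff = int(round(effect_loci_fraction * n_occ))
    if n_eff > 0:
        eff_idx = rng.choice(occ_idx, size=n_eff, replace=False)
        effect[eff_idx] = effect_size

    # constant scale so expected IP mouse tags sum to depth*(1-spike) for WT
    z = float(np.sum(lam * 2.0**true_score))
    mouse_budget = depth * (1.0 - spike_fraction)

    samples: list[ChipSample] = []
    sample_rows = []
    stream = iter(sample_ss)
    for genotype in ("WT", "KO"):
        for rep in range(1, n_reps + 1):
            rng_ip = np.random.default_rng(next(stream))
            rng_input = np.random.default_rng(next(stream))
            depth_factor = rng_ip.lognormal(0.0, 0.2)
            rep_noise = rng_ip.normal(0.0, score_noise_sd, n_loci)
            score_s = true_score + rep_noise + (effect if genotype == "KO" else 0.0)
            ip_mean = depth_factor * mouse_budget * lam * 2.0**score_s / z
            ip_counts = _nb(rng_ip, ip_mean, dispersion)
            ip_spike = float(rng_ip.poisson(depth_factor * depth * spike_fraction))
            input_factor = rng_input.lognormal(0.0, 0.2)
            input_counts = _nb(rng_input, input_factor * mouse_budget * lam, dispersion)
            input_spike = float(rng_input.poisson(input_factor * depth * spike_fraction))
            sample_id = f"{genotype}_rep{rep}"
            samples.append(
                ChipSample(
                    sample_id=sample_id,
                    genotype=genotype,
                    state="refed",
                    ip_counts=pd.Series(ip_counts, index=locus_ids, dtype=float),
                    input_counts=pd.Series(input_counts, index=locus_ids, dtype=float),
                    ip_spike_total=max(ip_spike, 1.0),
                    input_spike_total=max(input_spike, 1.0),
                )
            )
            sample_rows.append((sample_id, genotype, rep, depth_factor, input_factor))

    truth = SimTruth(
        seed=seed,
        params={
            "n_loci": n_loci,
            "occupied_fraction": occupied_fraction,
            "effect_loci_fraction": effect_loci_fraction,
            "effect_size": effect_size,
            "n_reps": n_reps,
            "depth": depth,
            "spike_fraction": spike_fraction,
            "score_noise_sd": score_noise_sd,
            "dispersion": dispersion,
        },
        per_feature=pd.DataFrame(
            {
                "true_score": true_score,
                "occupied": occupied,
                "effect": effect,
            },
            index=pd.Index(locus_ids, name="locus_id"),
        ),
        per_sample=pd.DataFrame(
            sample_rows,
            columns=["sample_id", "genotype", "rep", "ip_depth_factor", "input_depth_factor"],
        ).set_index("sample_id"),
    )
    return samples, truth


def simulate_ribo(
    n_genes: int = 5000,
    global_te_factor: float = 0.87,
    de_fraction: float = 0.0,
    te_effect: float = -1.0,
    dispersion: float = 0.1,
    n_reps: int = 3,
    n_spike: int = 200,
    seed: int = 0,
    depth: float = 5e6,
    spike_ratio: float = 1.0 / 15.0,
    two_transcript_fraction: float = 0.2,
    spike_dispersion: float = 0.0,
) -> tuple[dict, SimTruth]:
    """Simulate matched RF/RNA count tables with a Drosophila spike panel.

    RNA counts are negative-binomial around per-gene baselines; RF counts
    scale those baselines by each gene's translation efficiency, by
    ``global_te_factor`` in KO samples (the global translational shift the
    spike anchoring must recover), and by per-gene ``te_effect`` for a
    ``de_fraction`` of genes.  Spike transcripts contribute a fixed
    ``spike_ratio`` of the mouse material and are untouched by the TE
    factors; every library gets its own depth factor.  Because the spike is
    one shared extract aliquoted into every library, its between-sample
    variation is counting noise only (``spike_dispersion`` defaults to
    Poisson), unlike the per-animal mouse ``dispersion``.

    Returns a dict with ``rf_counts``/``rna_counts`` (transcripts x samples
    DataFrames), ``gene_map`` (transcript -> gene Series), ``spike_ids``,
    ``groups`` — plus the :class:`SimTruth`.
    """
    _check_fraction("de_fraction", de_fraction)
    if global_te_factor <= 0:
        raise ValueError("global_te_factor must be > 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if n_spike < 1:
        raise ValueError("n_spike must be >= 1")

    ss = np.random.SeedSequence(seed)
    shared_ss, *sample_ss = ss.spawn(1 + 2 * n_reps * 2)
    rng = np.random.default_rng(shared_ss)

    gene_ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=n_genes)
    te_log2 = rng.normal(0.0, 0.5, n_genes)
    n_de = int(round(de_fraction * n_genes))
    effect = np.zeros(n_genes)
    if n_de:
        effect[rng.choice(n_genes, size=n_de, replace=False)] = te_effect

    # transcripts: a fraction of genes have two isoforms splitting the signal
    two = rng.random(n_genes) < two_transcript_fraction
    tx_rows = []
    for i, g in enumerate(gene_ids):
        if two[i]:
            split = rng.uniform(0.3, 0.7)
            tx_rows.append((f"{g}.t1", g, base[i] * split))
            tx_rows.append((f"{g}.t2", g, base[i] * (1 - split)))
        else:
            tx_rows.append((f"{g}.t1", g, base[i]))
    tx_ids = [r[0] for r in tx_rows]
    tx_gene = pd.Series([r[1] for r in tx_rows], index=tx_ids, name="gene_id")
    tx_base = np.array([r[2] for r in tx_rows])
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    tx_gene_idx = np.array([gene_pos[g] for g in tx_gene])
    tx_te = 2.0 ** te_log2[tx_gene_idx]
    tx_effect = 2.0 ** effect[tx_gene_idx]

    spike_ids = [f"spike_{i + 1:04d}" for i in range(n_spike)]
    spike_base = rng.lognormal(mean=np.log(150.0), sigma=0.5, size=n_spike)
    spike_base *= spike_ratio * tx_base.sum() / spike_base.sum()

    all_ids = tx_ids + spike_ids
    rf = {}
    rna = {}
    groups = []
    stream = iter(sample_ss)
    scale = depth / (tx_base.sum() * (1 + spike_ratio))
    sample_rows = []
    for genotype in ("WT", "KO"):
        for rep in range(1, n_reps + 1):
            rng_rf = np.random.default_rng(next(stream))
            rng_rna = np.random.default_rng(next(stream))
            g = global_te_factor if genotype == "KO" else 1.0
            eff = tx_effect if genotype == "KO" else 1.0
            f_rf = rng_rf.lognormal(0.0, 0.15)
            f_rna = rng_rna.lognormal(0.0, 0.15)
            rf_mouse = _nb(rng_rf, f_rf * scale * tx_base * tx_te * g * eff, dispersion)
            rf_spike = _nb(rng_rf, f_rf * scale * spike_base, spike_dispersion)
            rna_mouse = _nb(rng_rna, f_rna * scale * tx_base, dispersion)
            rna_spike = _nb(rng_rna, f_rna * scale * spike_base, spike_dispersion)
            sample_id = f"{genotype}_rep{rep}"
            rf[sample_id] = np.concatenate([rf_mouse, rf_spike])
            rna[sample_id] = np.concatenate([rna_mouse, rna_spike])
            groups.append(genotype)
            sample_rows.append((sample_id, genotype, rep, f_rf, f_rna))

    data = {
        "rf_counts": pd.DataFrame(rf, index=all_ids, dtype=float),
        "rna_counts": pd.DataFrame(rna, index=all_ids, dtype=float),
        "gene_map": tx_gene,
        "spike_ids": spike_ids,
        "groups": groups,
    }
    truth = SimTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "global_te_factor": global_te_factor,
            "de_fraction": de_fraction,
            "te_effect": te_effect,
            "dispersion": dispersion,
            "n_reps": n_reps,
            "n_spike": n_spike,
            "depth": depth,
            "spike_ratio": spike_ratio,
        },
        per_feature=pd.DataFrame(
            {"baseline": base, "te_log2": te_log2, "te_effect": effect},
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        per_sample=pd.DataFrame(
            sample_rows, columns=["sample_id", "genotype", "rep", "rf_depth", "rna_depth"]
        ).set_index("sample_id"),
    )
    return data, truth


def simulate_rnaseq(
    n_genes: int = 12000,
    de_fraction: float = 937 / 12056,
    down_bias: float = 0.89,
    effect_size: float = 1.0,
    dispersion: float = 0.05,
    n_per_group: int | tuple[int, int] = (7, 5),
    seed: int = 0,
    depth: float = 1e7,
) -> tuple[pd.DataFrame, list, SimTruth]:
    """Simulate a gene-level RNA-seq count matrix for a two-group contrast.

    ``de_fraction`` of genes receive a ``effect_size`` log2 shift in group 2,
    a fraction ``down_bias`` of them downward.  Baselines are log-normal;
    counts negative-binomial; group sizes may be unbalanced (the study
    design is 7 vs 5).

    Returns (counts DataFrame, group labels, truth).
    """
    _check_fraction("de_fraction", de_fraction)
    _check_fraction("down_bias", down_bias)
    if isinstance(n_per_group, int):
        n1 = n2 = n_per_group
    else:
        n1, n2 = n_per_group
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")

    ss = np.random.SeedSequence(seed)
    shared_ss, *sample_ss = ss.spawn(1 + n1 + n2)
    rng = np.random.default_rng(shared_ss)

    gene_ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=np.log(120.0), sigma=1.2, size=n_genes)
    n_de = int(round(de_fraction * n_genes))
    effect = np.zeros(n_genes)
    if n_de:
        idx = rng.choice(n_genes, size=n_de, replace=False)
        down = rng.random(n_de) < down_bias
        effect[idx] = np.where(down, -effect_size, effect_size)

    scale = depth / base.sum()
    cols = {}
    groups = []
    stream = iter(sample_ss)
    for j in range(n1 + n2):
        genotype = "WT" if j < n1 else "KO"
        rng_s = np.random.default_rng(next(stream))
        f = rng_s.lognormal(0.0, 0.1)
        mean = f * scale * base * (2.0**effect if genotype == "KO" else 1.0)
        cols[f"{genotype}_{(j % n1) + 1 if genotype == 'WT' else (j - n1) + 1}"] = _nb(
            rng_s, mean, dispersion
        )
        groups.append(genotype)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"), dtype=float)
    truth = SimTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "de_fraction": de_fraction,
            "down_bias": down_bias,
            "effect_size": effect_size,
            "dispersion": dispersion,
            "n_per_group": (n1, n2),
            "depth": depth,
        },
        per_feature=pd.DataFrame(
            {"baseline": base, "effect": effect},
            index=pd.Index(gene_ids, name="gene_id"),
        ),
    )
    return counts, groups, truth
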