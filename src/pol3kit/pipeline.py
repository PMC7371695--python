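"""Config-driven end-to-end runs with a reproducibility manifest.

A run is described by a single YAML document with one block per stage
(``chip``, ``rnaseq``, ``ribo``, ``enrich``); each block either points at
input files or carries a ``simulate`` block of generator overrides.  All
parameters are range-checked up front (unknown keys are rejected with a
suggestion) so a run never fails halfway through on a typo.

Every run writes a manifest recording the config hash, package version,
SHA-256 checksums of every output, and wall-clock time per stage; a re-run
of an identical config (fixed seeds) reproduces identical checksums.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pol3kit import chip as chipmod
from pol3kit import enrichment as enrichmod
from pol3kit import io as iomod
from pol3kit import ribo as ribomod
from pol3kit import rnaseq as rnamod
from pol3kit import simulate as simmod

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline", "ConfigError"]

logger = logging.getLogger("pol3kit.pipeline")

ALL_STAGES = ("chip", "rnaseq", "ribo", "enrich")


class ConfigError(ValueError):
    """Invalid run configuration."""


#: key -> (default, validator); validators raise ConfigError on bad values
def _positive(name):
    def check(v):
        if not (isinstance(v, (int, float)) and v > 0):
            raise ConfigError(f"{name} must be a positive number, got {v!r}")
        return float(v)

    return check


def _prob(name):
    def check(v):
        if not (isinstance(v, (int, float)) and 0 < v < 1):
            raise ConfigError(f"{name} must be in (0, 1), got {v!r}")
        return float(v)

    return check


def _nonneg(name):
    def check(v):
        if not (isinstance(v, (int, float)) and v >= 0):
            raise ConfigError(f"{name} must be >= 0, got {v!r}")
        return float(v)

    return check


def _int_min(name, lo):
    def check(v):
        if not (isinstance(v, int) and v >= lo):
            raise ConfigError(f"{name} must be an integer >= {lo}, got {v!r}")
        return v

    return check


def _path(name):
    def check(v):
        if v is None:
            return None
        return str(v)

    return check


def _str(name):
    def check(v):
        return None if v is None else str(v)

    return check


def _cutoff(name):
    def check(v):
        if v == "mixture":
            return v
        if isinstance(v, str) and v.startswith("fixed:"):
            try:
                float(v.split(":", 1)[1])
            except ValueError:
                raise ConfigError(f"{name}: bad fixed cutoff {v!r}") from None
            return v
        raise ConfigError(f"{name} must be 'mixture' or 'fixed:<score>', got {v!r}")

    return check


_SCHEMAS = {
    "chip": {
        "simulate": (None, None),
        "sample_sheet": (None, _path("chip.sample_sheet")),
        "catalog": (None, _path("chip.catalog")),
        "alpha": (0.01, _prob("chip.alpha")),
        "pseudocount": (0.5, _nonneg("chip.pseudocount")),
        "quantiles": (5, _int_min("chip.quantiles", 2)),
        "cutoff": ("mixture", _cutoff("chip.cutoff")),
    },
    "rnaseq": {
        "simulate": (None, None),
        "counts": (None, _path("rnaseq.counts")),
        "groups": (None, None),
        "alpha": (0.01, _prob("rnaseq.alpha")),
        "lfc_min": (0.5, _nonneg("rnaseq.lfc_min")),
        "cpm_min": (1.0, _nonneg("rnaseq.cpm_min")),
    },
    "ribo": {
        "simulate": (None, None),
        "rf_counts": (None, _path("ribo.rf_counts")),
        "rna_counts": (None, _path("ribo.rna_counts")),
        "gene_map": (None, _path("ribo.gene_map")),
        "spike_ids": (None, _path("ribo.spike_ids")),
        "groups": (None, None),
        "reference_sample": (None, _str("ribo.reference_sample")),
        "pseudocount": (0.5, _nonneg("ribo.pseudocount")),
    },
    "enrich": {
        "gene_sets": (None, _path("enrich.gene_sets")),
        "rank_by": ("log2fc", _str("enrich.rank_by")),
        "rrho_step": (None, None),
        "gsea_weight": (1.0, _nonneg("enrich.gsea_weight")),
    },
}

_TOP_KEYS = {"output_dir", "seed", *ALL_STAGES}


@dataclass
class RunConfig:
    output_dir: Path
    seed: int = 0
    stages: dict = field(default_factory=dict)

    def canonical(self) -> str:
        doc = {"output_dir": str(self.output_dir), "seed": self.seed, **self.stages}
        return yaml.safe_dump(doc, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "version": self.version, "stages": self.stages},
            indent=2,
            sort_keys=True,
        )


def _suggest(key: str, known) -> str:
    match = difflib.get_close_matches(key, list(known), n=1)
    return f" (did you mean {match[0]!r}?)" if match else ""


def validate_config(path: str | Path) -> RunConfig:
    """Parse and range-check a run config; fill and echo defaults."""
    path = Path(path)
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        k = sorted(unknown)[0]
        raise ConfigError(f"{path}: unknown key {k!r}{_suggest(k, _TOP_KEYS)}")
    if "output_dir" not in doc:
        raise ConfigError(f"{path}: output_dir is required")
    seed = doc.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")

    stages = {}
    for stage in ALL_STAGES:
        if stage not in doc:
            continue
        block = doc[stage] or {}
        if not isinstance(block, dict):
            raise ConfigError(f"{stage}: block must be a mapping")
        schema = _SCHEMAS[stage]
        unknown = set(block) - set(schema)
        if unknown:
            k = sorted(unknown)[0]
            raise ConfigError(f"{stage}: unknown key {k!r}{_suggest(k, schema)}")
        resolved = {}
        for key, (default, check) in schema.items():
            value = block.get(key, default)
            if check is not None and value is not None:
                value = check(value)
            resolved[key] = value
        for key in ("sample_sheet", "counts", "rf_counts", "rna_counts", "gene_map",
                    "spike_ids", "catalog", "gene_sets"):
            if resolved.get(key):
                p = Path(resolved[key])
                if not p.is_absolute():
                    p = path.parent / p
                if not p.exists():
                    raise ConfigError(f"{stage}.{key}: path does not exist: {p}")
                resolved[key] = str(p)
        stages[stage] = resolved
        logger.info("stage %s config: %s", stage, resolved)
    return RunConfig(output_dir=Path(doc["output_dir"]), seed=seed, stages=stages)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages=None) -> RunManifest:
    """Execute the configured stages and write outputs plus a manifest.

    ``stages`` restricts execution to a subset (default: every configured
    stage).  The enrich stage consumes the rnaseq stage's results and
    therefore requires it in the same run or its outputs on disk.
    """
    if stages is None:
        stages = [s for s in ALL_STAGES if s in config.stages]
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    for s in stages:
        if s not in config.stages:
            raise ConfigError(f"stage {s!r} requested but not configured")

    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    from pol3kit import __version__

    manifest = RunManifest(config_hash=config.config_hash, version=__version__)
    context: dict = {}
    runners = {
        "chip": _run_chip,
        "rnaseq": _run_rnaseq,
        "ribo": _run_ribo,
        "enrich": _run_enrich,
    }
    for stage in [s for s in ALL_STAGES if s in stages]:
        t0 = time.perf_counter()
        logger.info("running stage %s", stage)
        outputs = runners[stage](config.stages[stage], config, out_dir, context)
        manifest.stages[stage] = {
            "outputs": {name: _sha256(p) for name, p in outputs.items()},
            "seconds": round(time.perf_counter() - t0, 3),
        }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    logger.info("manifest written to %s", manifest_path)
    return manifest


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def _run_chip(block, config, out_dir: Path, context) -> dict[str, Path]:
    if block["sample_sheet"]:
        samples = iomod.read_chip_samples(block["sample_sheet"])
        truth = None
    elif block["simulate"] is not None:
        params = dict(block["simulate"] or {})
        params.setdefault("seed", config.seed)
        samples, truth = simmod.simulate_chip(**params)
    else:
        raise ConfigError("chip: provide either sample_sheet or simulate")

    scores = chipmod.score_sample_set(samples, pseudocount=block["pseudocount"])
    if block["cutoff"] == "mixture":
        model = chipmod.estimate_occupancy_cutoff(scores.mean(axis=1).to_numpy())
        cutoff = model.cutoff
    else:
        cutoff = float(block["cutoff"].split(":", 1)[1])
    occupied = scores >= cutoff
    classes = chipmod.assign_quantile_classes(scores.iloc[:, 0], q=block["quantiles"])

    table = scores.copy()
    for col in scores.columns:
        table[f"{col}_occupied"] = occupied[col]
    table["quantile_class"] = classes
    occ_path = out_dir / "chip_occupancy.tsv"
    table.rename_axis("locus_id").to_csv(occ_path, sep="\t")

    genotypes = [s.genotype for s in samples]
    diff = chipmod.differential_occupancy(
        scores, genotypes, alpha=block["alpha"], cutoff=cutoff
    )
    diff_path = out_dir / "chip_differential.tsv"
    diff.rename_axis("locus_id").to_csv(diff_path, sep="\t")

    summary = {
        "cutoff": cutoff,
        "n_loci": int(scores.shape[0]),
        "n_occupied_any": int(occupied.any(axis=1).sum()),
        "n_significant": int(diff["significant"].sum()),
        "alpha": block["alpha"],
    }
    sum_path = out_dir / "chip_summary.json"
    _write_json(summary, sum_path)

    outputs = {"occupancy": occ_path, "differential": diff_path, "summary": sum_path}
    if truth is not None:
        truth_path = out_dir / "chip_truth.tsv"
        truth.per_feature.to_csv(truth_path, sep="\t")
        outputs["truth"] = truth_path
    context["chip"] = {"scores": scores, "diff": diff, "cutoff": cutoff}
    return outputs


def _run_rnaseq(block, config, out_dir: Path, context) -> dict[str, Path]:
    truth = None
    if block["counts"]:
        counts = iomod.read_count_matrix(block["counts"])
        groups = block["groups"]
        if not groups:
            raise ConfigError("rnaseq: groups are required with a counts file")
        if len(groups) != counts.shape[1]:
            raise ConfigError(
                f"rnaseq: {len(groups)} group labels for {counts.shape[1]} samples"
            )
    elif block["simulate"] is not None:
        params = dict(block["simulate"] or {})
        params.setdefault("seed", config.seed)
        counts, groups, truth = simmod.simulate_rnaseq(**params)
    else:
        raise ConfigError("rnaseq: provide either counts or simulate")

    res, summary = rnamod.de_analysis(
        counts, groups, alpha=block["alpha"], lfc_min=block["lfc_min"],
        cpm_min=block["cpm_min"],
    )
    de_path = out_dir / "rnaseq_de.tsv"
    res.rename_axis("gene_id").to_csv(de_path, sep="\t")
    sum_path = out_dir / "rnaseq_summary.json"
    _write_json(summary, sum_path)

    groups_arr = np.asarray(groups)
    levels = list(dict.fromkeys(groups_arr.tolist()))
    selected = res.index[res["selected"]]
    revcum_outputs = {}
    if len(selected) > 0:
        expr = rnamod.log_cpm(counts.loc[counts.index.intersection(selected)])
        values = {
            lev: expr.loc[:, groups_arr == lev].mean(axis=1).to_numpy() for lev in levels
        }
        curves, ks = rnamod.reverse_cumulative(values)
        rc_path = out_dir / "rnaseq_revcum.tsv"
        curves.to_csv(rc_path, sep="\t", index=False)
        _write_json(ks, out_dir / "rnaseq_revcum_ks.json")
        revcum_outputs = {
            "revcum": rc_path,
            "revcum_ks": out_dir / "rnaseq_revcum_ks.json",
        }

    outputs = {"de": de_path, "summary": sum_path, **revcum_outputs}
    if truth is not None:
        truth_path = out_dir / "rnaseq_truth.tsv"
        truth.per_feature.to_csv(truth_path, sep="\t")
        outputs["truth"] = truth_path
    context["rnaseq"] = {"res": res, "summary": summary, "truth": truth}
    return outputs


def _run_ribo(block, config, out_dir: Path, context) -> dict[str, Path]:
    truth = None
    if block["rf_counts"]:
        for key in ("rna_counts", "gene_map", "spike_ids"):
            if not block[key]:
                raise ConfigError(f"ribo: {key} is required with rf_counts")
        rf = iomod.read_count_matrix(block["rf_counts"])
        rna = iomod.read_count_matrix(block["rna_counts"])
        gene_map = iomod.read_gene_map(block["gene_map"])
        spike_ids = [
            line.strip()
            for line in Path(block["spike_ids"]).read_text().splitlines()
            if line.strip()
        ]
        groups = block["groups"]
        if not groups:
            raise ConfigError("ribo: groups are required with count files")
    elif block["simulate"] is not None:
        params = dict(block["simulate"] or {})
        params.setdefault("seed", config.seed)
        data, truth = simmod.simulate_ribo(**params)
        rf, rna = data["rf_counts"], data["rna_counts"]
        gene_map, spike_ids, groups = data["gene_map"], data["spike_ids"], data["groups"]
    else:
        raise ConfigError("ribo: provide either rf_counts or simulate")

    ref = block["reference_sample"] or rf.columns[0]
    te, corrections = ribomod.te_pipeline(
        rf, rna, gene_map, spike_ids, reference_sample=ref,
        pseudocount=block["pseudocount"],
    )

    te_path = out_dir / "ribo_te.tsv"
    te.rename_axis("gene_id").to_csv(te_path, sep="\t")
    corr_path = out_dir / "ribo_correction_factors.tsv"
    corrections.to_csv(corr_path, sep="\t")

    shift = ribomod.global_te_shift(te, groups)
    shift_path = out_dir / "ribo_shift.json"
    _write_json(shift, shift_path)

    diff = ribomod.differential_te(te, groups)
    diff_path = out_dir / "ribo_differential.tsv"
    diff.rename_axis("gene_id").to_csv(diff_path, sep="\t")

    outputs = {
        "te": te_path,
        "correction_factors": corr_path,
        "shift": shift_path,
        "differential": diff_path,
    }
    if truth is not None:
        truth_path = out_dir / "ribo_truth.tsv"
        truth.per_feature.to_csv(truth_path, sep="\t")
        outputs["truth"] = truth_path
    context["ribo"] = {"te": te, "shift": shift, "diff": diff}
    return outputs


def _run_enrich(block, config, out_dir: Path, context) -> dict[str, Path]:
    if "rnaseq" not in context:
        raise ConfigError(
            "enrich: requires the rnaseq stage in the same run (it consumes its results)"
        )
    res = context["rnaseq"]["res"]
    ranked = enrichmod.rank_by(res, by=block["rank_by"])

    if block["gene_sets"]:
        gene_sets = iomod.read_gene_sets(block["gene_sets"])
    elif context["rnaseq"]["truth"] is not None:
        truth = context["rnaseq"]["truth"].per_feature
        true_down = set(truth.index[truth["effect"] < 0]) & set(res.index)
        gene_sets = {"true_downregulated": true_down}
    else:
        raise ConfigError("enrich: gene_sets file required when rnaseq input is not simulated")

    summary = {}
    profile_paths = {}
    for name, members in gene_sets.items():
        result = enrichmod.gsea_es(ranked, members, weight_exponent=block["gsea_weight"])
        profile = pd.DataFrame(
            {"rank": np.arange(1, len(ranked) + 1), "running_es": result["running"]}
        )
        p_path = out_dir / f"enrich_es_{name}.tsv"
        profile.to_csv(p_path, sep="\t", index=False)
        profile_paths[f"es_{name}"] = p_path
        overlap = enrichmod.set_overlap_test(
            members, set(res.index[res["selected"]]), universe_size=len(ranked)
        )
        summary[name] = {"es": result["es"], "overlap_with_selected": overlap}

    sum_path = out_dir / "enrich_summary.json"
    _write_json(summary, sum_path)
    return {"summary": sum_path, **profile_paths}
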