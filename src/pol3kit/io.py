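"""TSV schemas shared by the analysis modules, the pipeline, and the CLI.

All interchange formats are plain tab-separated text:

* count matrix — first column feature IDs, header row of sample labels;
* ChIP sample sheet — ``sample_id  genotype  state  ip_spike_total
  input_spike_total  counts_path`` with per-sample count files of
  ``locus_id  ip_count  input_count``;
* transcript-to-gene map — ``transcript_id  gene_id``;
* gene sets — one set per line: ``name<TAB>id1,id2,...``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from pol3kit.chip import ChipSample

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_chip_samples",
    "write_chip_samples",
    "read_gene_map",
    "read_gene_sets",
]


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()][:5].tolist()
        raise ValueError(f"{path}: duplicate feature IDs, e.g. {dups}")
    if (df < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_chip_samples(sample_sheet: str | Path) -> list[ChipSample]:
    """Read ChIP samples from a sample sheet plus per-sample count files.

    ``counts_path`` entries are resolved relative to the sheet's directory.
    """
    sheet_path = Path(sample_sheet)
    sheet = pd.read_csv(sheet_path, sep="\t")
    required = {
        "sample_id", "genotype", "state", "ip_spike_total", "input_spike_total",
        "counts_path",
    }
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"{sheet_path}: sample sheet missing columns {sorted(missing)}")
    samples = []
    for row in sheet.itertuples(index=False):
        counts_path = Path(row.counts_path)
        if not counts_path.is_absolute():
            counts_path = sheet_path.parent / counts_path
        counts = pd.read_csv(counts_path, sep="\t", index_col="locus_id")
        samples.append(
            ChipSample(
                sample_id=str(row.sample_id),
                genotype=str(row.genotype),
                state=str(row.state),
                ip_counts=counts["ip_count"].astype(float),
                input_counts=counts["input_count"].astype(float),
                ip_spike_total=float(row.ip_spike_total),
                input_spike_total=float(row.input_spike_total),
            )
        )
    return samples


def write_chip_samples(samples: list[ChipSample], out_dir: str | Path) -> Path:
    """Write samples as a sheet plus per-sample count files; returns sheet path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        counts_name = f"{s.sample_id}_counts.tsv"
        pd.DataFrame(
            {"ip_count": s.ip_counts, "input_count": s.input_counts}
        ).rename_axis("locus_id").to_csv(out_dir / counts_name, sep="\t")
        rows.append(
            (s.sample_id, s.genotype, s.state, s.ip_spike_total, s.input_spike_total,
             counts_name)
        )
    sheet = pd.DataFrame(
        rows,
        columns=["sample_id", "genotype", "state", "ip_spike_total",
                 "input_spike_total", "counts_path"],
    )
    sheet_path = out_dir / "sample_sheet.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    return sheet_path


def read_gene_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"transcript_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: need columns transcript_id and gene_id")
    return df.set_index("transcript_id")["gene_id"]


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>id1,id2,...'")
            name, ids = parts
            sets[name] = {g for g in ids.split(",") if g}
    return sets
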