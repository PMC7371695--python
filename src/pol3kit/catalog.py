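"""Pol III locus catalog: BED-backed locus models, tRNA naming, grouping.

The catalog is the locus universe every ChIP analysis runs against.  Loci
carry a gene class (tRNA, 5S, 4.5S, SINE, type-3 promoter, other) and, for
tRNA genes, an isotype (amino acid carried; initiator Met is its own
isotype, distinct from elongator Met) and anticodon, so that occupancy
scores can be aggregated by isotype or isoacceptor.

Coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

__all__ = [
    "GENE_CLASSES",
    "ISOTYPES",
    "Pol3Locus",
    "LocusCatalog",
    "CatalogError",
    "parse_trna_name",
    "read_locus_catalog",
    "write_catalog",
    "group_loci",
]

GENE_CLASSES = ("tRNA", "5S", "4.5S", "SINE", "type3", "other")

#: Three-letter amino-acid codes accepted as tRNA isotypes.  Initiator
#: methionine (iMet) is distinct from elongator Met; selenocysteine tRNA
#: (SeC) is included, giving the 22 isotype classes of the mouse tRNA set.
ISOTYPES = frozenset(
    {
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His",
        "Ile", "Leu", "Lys", "Met", "iMet", "Phe", "Pro", "SeC", "Ser",
        "Thr", "Trp", "Tyr", "Val",
    }
)

_ISOTYPE_ALIASES = {"Sec": "SeC", "SeC": "SeC", "Ini": "iMet", "iMet": "iMet"}


class CatalogError(ValueError):
    """Malformed catalog input (BED or annotation)."""


@dataclass(frozen=True)
class Pol3Locus:
    """One annotated pol III locus.

    ``isotype``/``anticodon`` are set exactly when ``gene_class == "tRNA"``.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"
    gene_class: str = "other"
    isotype: str | None = None
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CatalogError(
                f"locus {self.locus_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.gene_class not in GENE_CLASSES:
            raise CatalogError(
                f"locus {self.locus_id!r}: unknown gene class {self.gene_class!r}; "
                f"expected one of {GENE_CLASSES}"
            )
        is_trna = self.gene_class == "tRNA"
        if is_trna and (self.isotype is None or self.anticodon is None):
            raise CatalogError(f"tRNA locus {self.locus_id!r} needs isotype and anticodon")
        if not is_trna and (self.isotype is not None or self.anticodon is not None):
            raise CatalogError(
                f"non-tRNA locus {self.locus_id!r} must not carry isotype/anticodon"
            )


@dataclass
class LocusCatalog:
    """Ordered, ID-indexed collection of :class:`Pol3Locus`."""

    loci: list[Pol3Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {}
        for locus in self.loci:
            if locus.locus_id in self._index:
                raise CatalogError(f"duplicate locus_id {locus.locus_id!r}")
            self._index[locus.locus_id] = locus

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[Pol3Locus]:
        return iter(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._index

    def __getitem__(self, locus_id: str) -> Pol3Locus:
        return self._index[locus_id]

    @property
    def locus_ids(self) -> list[str]:
        return [locus.locus_id for locus in self.loci]

    def trna_loci(self) -> list[Pol3Locus]:
        return [locus for locus in self.loci if locus.gene_class == "tRNA"]


def parse_trna_name(name: str) -> tuple[str, str]:
    """Parse a systematic tRNA gene name into (isotype, anticodon).

    Accepted dialects::

        tRNA-Ile-TAT          (GtRNAdb-style; optional trailing -<n>-<n> copy suffix)
        tRNA-iMet-CAT         (initiator Met, distinct from tRNA-Met-CAT)
        tRNA-SeC-TCA          (selenocysteine; "Sec" accepted as alias)

    Abbreviated locus names (e.g. supplementary-table shorthands like
    ``n-Ti16``) are not systematic and must be resolved through the
    annotation TSV passed to :func:`read_locus_catalog` instead.
    """
    parts = name.split("-")
    if len(parts) >= 3 and parts[0].lower() in {"trna", "tr"}:
        isotype = _ISOTYPE_ALIASES.get(parts[1], parts[1])
        anticodon = parts[2].upper()
        if isotype in ISOTYPES and len(anticodon) == 3 and anticodon.isalpha():
            return isotype, anticodon
    raise CatalogError(
        f"unrecognized tRNA name {name!r}; accepted dialects: "
        "'tRNA-<Isotype>-<Anticodon>' (e.g. tRNA-Ile-TAT, tRNA-iMet-CAT, tRNA-SeC-TCA); "
        "abbreviated names need an annotation TSV"
    )


def _read_annotation(path: Path) -> dict[str, tuple[str, str | None, str | None]]:
    """Annotation TSV: locus_id, gene_class, [isotype], [anticodon]."""
    mapping: dict[str, tuple[str, str | None, str | None]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"locus_id", "name", "id"}:
                continue
            if len(fields) < 2:
                raise CatalogError(f"{path}:{lineno}: need at least locus_id and gene_class")
            locus_id, gene_class = fields[0], fields[1]
            if gene_class not in GENE_CLASSES:
                raise CatalogError(
                    f"{path}:{lineno}: unknown gene class {gene_class!r} "
                    f"(expected one of {GENE_CLASSES})"
                )
            isotype = fields[2] if len(fields) > 2 and fields[2] else None
            anticodon = fields[3] if len(fields) > 3 and fields[3] else None
            if isotype is not None:
                isotype = _ISOTYPE_ALIASES.get(isotype, isotype)
                if isotype not in ISOTYPES:
                    raise CatalogError(f"{path}:{lineno}: unknown isotype {isotype!r}")
            mapping[locus_id] = (gene_class, isotype, anticodon)
    return mapping


def read_locus_catalog(
    bed_path: str | Path, annotation_path: str | Path | None = None
) -> LocusCatalog:
    """Read a locus catalog from a BED file, optionally with an annotation TSV.

    Classification precedence per BED record: annotation TSV entry for the
    record name, then systematic-name parsing (``tRNA-Xxx-NNN`` -> tRNA;
    names containing ``5S``/``Rn5s`` -> 5S, ``4.5S``/``Rn4.5s`` -> 4.5S,
    ``SINE`` -> SINE), else class ``other``.
    """
    bed_path = Path(bed_path)
    annot = _read_annotation(Path(annotation_path)) if annotation_path else {}
    loci: list[Pol3Locus] = []
    with open(bed_path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CatalogError(f"{bed_path}:{lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CatalogError(
                    f"{bed_path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from exc
            if start >= end:
                raise CatalogError(f"{bed_path}:{lineno}: start ({start}) >= end ({end})")
            strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "+"
            gene_class, isotype, anticodon = _classify(name, annot)
            loci.append(
                Pol3Locus(name, chrom, start, end, strand, gene_class, isotype, anticodon)
            )
    if not loci:
        warnings.warn(f"{bed_path}: no records; catalog is empty", stacklevel=2)
    return LocusCatalog(loci)


def _classify(
    name: str, annot: dict[str, tuple[str, str | None, str | None]]
) -> tuple[str, str | None, str | None]:
    if name in annot:
        gene_class, isotype, anticodon = annot[name]
        if gene_class == "tRNA" and (isotype is None or anticodon is None):
            try:
                isotype, anticodon = parse_trna_name(name)
            except CatalogError as exc:
                raise CatalogError(
                    f"annotation marks {name!r} as tRNA without isotype/anticodon "
                    "and the name is not systematic"
                ) from exc
        return gene_class, isotype, anticodon
    try:
        isotype, anticodon = parse_trna_name(name)
        return "tRNA", isotype, anticodon
    except CatalogError:
        pass
    lowered = name.lower()
    if "4.5s" in lowered or "rn4.5s" in lowered:
        return "4.5S", None, None
    if "5s" in lowered:
        return "5S", None, None
    if "sine" in lowered:
        return "SINE", None, None
    return "other", None, None


def write_catalog(catalog: LocusCatalog, path: str | Path) -> None:
    """Write the canonical catalog TSV (round-trips through ``read_catalog_tsv``)."""
    with open(path, "w") as handle:
        handle.write("locus_id\tchrom\tstart\tend\tstrand\tgene_class\tisotype\tanticodon\n")
        for locus in catalog:
            handle.write(
                f"{locus.locus_id}\t{locus.chrom}\t{locus.start}\t{locus.end}\t"
                f"{locus.strand}\t{locus.gene_class}\t{locus.isotype or ''}\t"
                f"{locus.anticodon or ''}\n"
            )


def read_catalog_tsv(path: str | Path) -> LocusCatalog:
    """Read the canonical catalog TSV written by :func:`write_catalog`."""
    loci = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["locus_id", "chrom", "start", "end", "strand", "gene_class",
                    "isotype", "anticodon"]
        if header != expected:
            raise CatalogError(f"{path}: unexpected header {header}")
        for raw in handle:
            f = raw.rstrip("\n").split("\t")
            loci.append(
                Pol3Locus(f[0], f[1], int(f[2]), int(f[3]), f[4], f[5],
                          f[6] or None, f[7] or None)
            )
    return LocusCatalog(loci)


def group_loci(
    catalog: LocusCatalog, level: Literal["isotype", "isoacceptor", "gene_class"]
) -> dict[str, list[str]]:
    """Partition loci into groups at the requested level.

    ``isotype`` and ``isoacceptor`` partition the tRNA loci only (isoacceptor
    keys are ``"<isotype>-<anticodon>"``); ``gene_class`` partitions the whole
    catalog.  Group order follows first appearance in the catalog.
    """
    groups: dict[str, list[str]] = {}
    if level == "gene_class":
        for locus in catalog:
            groups.setdefault(locus.gene_class, []).append(locus.locus_id)
    elif level == "isotype":
        for locus in catalog.trna_loci():
            groups.setdefault(locus.isotype, []).append(locus.locus_id)  # type: ignore[arg-type]
    elif level == "isoacceptor":
        for locus in catalog.trna_loci():
            groups.setdefault(f"{locus.isotype}-{locus.anticodon}", []).append(locus.locus_id)
    else:
        raise ValueError(
            f"unknown grouping level {level!r}; expected isotype, isoacceptor or gene_class"
        )
    return groups


def make_synthetic_catalog(
    n_trna: int = 400,
    n_5s: int = 30,
    n_other: int = 70,
    seed: int = 0,
) -> LocusCatalog:
    """Build a synthetic locus catalog with a realistic class/isotype layout.

    Convenience for simulations and examples: tRNA loci cycle through all 22
    isotypes with 1-3 anticodons each, plus 5S genes and a mix of 4.5S, SINE,
    and type-3 loci.  Deterministic given ``seed``.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    anticodons = {
        iso: [_random_anticodon(rng) for _ in range(int(rng.integers(1, 4)))]
        for iso in sorted(ISOTYPES)
    }
    loci: list[Pol3Locus] = []
    pos = 1000
    isotype_cycle = sorted(ISOTYPES)
    for i in range(n_trna):
        iso = isotype_cycle[i % len(isotype_cycle)]
        anti = anticodons[iso][i % len(anticodons[iso])]
        loci.append(
            Pol3Locus(f"tRNA-{iso}-{anti}-{i + 1}", f"chr{1 + i % 19}", pos, pos + 72,
                      "+" if i % 2 == 0 else "-", "tRNA", iso, anti)
        )
        pos += 5000
    for i in range(n_5s):
        loci.append(Pol3Locus(f"Rn5s-{i + 1}", "chr8", pos, pos + 120, "+", "5S"))
        pos += 2000
    other_classes = ["4.5S", "SINE", "type3", "other"]
    for i in range(n_other):
        cls = other_classes[i % len(other_classes)]
        loci.append(
            Pol3Locus(f"{cls}-locus-{i + 1}", f"chr{1 + i % 19}", pos, pos + 300, "+", cls)
        )
        pos += 3000
    return LocusCatalog(loci)


def _random_anticodon(rng) -> str:
    return "".join(rng.choice(list("ACGT"), size=3))
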