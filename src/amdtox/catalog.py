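"""Curated KO-keyed metal-resistance-gene (MRG) catalog.

The catalog maps KEGG Orthology identifiers to resistance mechanisms
(Export, Import, Biochemical Transformation, Regulation, Intracellular
Accumulation, Extracellular Sequestration), the metals they act on, and
their provenance. Two fixtures ship with the package: the 48 metal-specific
marker KOs covering Al, Cu, Fe, Mn, Zn, Ni and As, and the 16 KOs used as a
proxy for extracellular sequestration via exopolysaccharide (EPS) synthesis,
assembly and transport.

The builder operations reproduce the curation pipeline for a user-supplied
BacMet-style export: keep best above-threshold KO annotations per gene,
aggregate records sharing a KO (union of compounds and symbols), keep
metal-related rows confirmed by an explicit curator flag, and merge with EPS
and literature entries (BacMet provenance wins on duplicate KOs). The manual
"gene description matches KO description" judgment of the original curation
is externalized as the curator-flag column, which keeps the pipeline
deterministic and the curation auditable.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "BacMetRecord",
    "KOAnnotation",
    "MRGEntry",
    "MRGCatalog",
    "MECHANISMS",
    "METAL_VOCABULARY",
    "select_best_hits",
    "aggregate_by_ko",
    "filter_metal_only",
    "merge_catalog",
    "load_table3_fixture",
    "load_table4_fixture",
    "default_catalog",
    "metals_for_ko",
]

logger = logging.getLogger(__name__)

KO_PATTERN = re.compile(r"^K\d{5}$")

MECHANISMS = (
    "Export",
    "Import",
    "Biochemical Transformation",
    "Regulation",
    "Intracellular Accumulation",
    "Extracellular Sequestration",
)

#: Metals and metalloids recognised when down-selecting BacMet compound strings.
METAL_VOCABULARY = (
    "Ag", "Al", "As", "Au", "Bi", "Cd", "Co", "Cr", "Cu", "Fe", "Ga", "Hg",
    "Mn", "Mo", "Ni", "Pb", "Sb", "Se", "Te", "Tl", "W", "Zn",
)

SOURCES = ("BacMet", "KEGG", "literature", "EPS")


@dataclass
class BacMetRecord:
    bacmet_id: str
    gene_symbol: str
    organism: str = ""
    compounds: tuple[str, ...] = ()
    description: str = ""


@dataclass
class KOAnnotation:
    subject_id: str
    ko: str
    score: float
    above_threshold: bool
    evalue: float

    def __post_init__(self) -> None:
        if not KO_PATTERN.match(self.ko):
            raise ValidationError(f"malformed KO identifier {self.ko!r}")


@dataclass
class MRGEntry:
    ko: str
    gene_symbols: tuple[str, ...]
    metals: tuple[str, ...]
    mechanism: str
    specific: bool
    source: str
    pathway: str = ""
    primary_metal: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not KO_PATTERN.match(self.ko):
            raise ValidationError(f"malformed KO identifier {self.ko!r}")
        if self.mechanism not in MECHANISMS:
            raise ValidationError(f"unknown mechanism {self.mechanism!r} for {self.ko}")
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r} for {self.ko}")
        if not self.metals and self.source != "EPS":
            raise ValidationError(f"entry {self.ko} has no metals and is not an EPS proxy")


class MRGCatalog:
    """Ordered collection of unique-KO :class:`MRGEntry` records."""

    def __init__(self, entries: Iterable[MRGEntry]):
        self.entries: list[MRGEntry] = list(entries)
        self._by_ko: dict[str, MRGEntry] = {}
        for entry in self.entries:
            if entry.ko in self._by_ko:
                raise ValidationError(f"duplicate KO {entry.ko} in catalog")
            self._by_ko[entry.ko] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, ko: str) -> bool:
        return ko in self._by_ko

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, ko: str) -> MRGEntry:
        return self._by_ko[ko]

    @property
    def kos(self) -> list[str]:
        return [e.ko for e in self.entries]

    def mechanism_of(self, ko: str) -> str:
        return self._by_ko[ko].mechanism

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ko": [e.ko for e in self.entries],
                "gene_symbols": [",".join(e.gene_symbols) for e in self.entries],
                "primary_metal": [e.primary_metal for e in self.entries],
                "metals": [",".join(e.metals) for e in self.entries],
                "mechanism": [e.mechanism for e in self.entries],
                "specific": [e.specific for e in self.entries],
                "source": [e.source for e in self.entries],
                "pathway": [e.pathway for e in self.entries],
                "description": [e.description for e in self.entries],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MRGCatalog":
        required = {"ko", "gene_symbols", "metals", "mechanism", "specific", "source"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"catalog table lacks columns: {sorted(missing)}")

        def split(cell) -> tuple[str, ...]:
            if pd.isna(cell) or cell == "":
                return ()
            return tuple(str(cell).split(","))

        entries = []
        for row in frame.itertuples():
            entries.append(
                MRGEntry(
                    ko=row.ko,
                    gene_symbols=split(row.gene_symbols),
                    metals=split(row.metals),
                    mechanism=row.mechanism,
                    specific=bool(row.specific) if not isinstance(row.specific, str)
                    else row.specific.strip().lower() == "true",
                    source=row.source,
                    pathway="" if not hasattr(row, "pathway") or pd.isna(row.pathway)
                    else str(row.pathway),
                    primary_metal="" if not hasattr(row, "primary_metal")
                    or pd.isna(row.primary_metal) else str(row.primary_metal),
                    description="" if not hasattr(row, "description")
                    or pd.isna(row.description) else str(row.description),
                )
            )
        return cls(entries)

    @classmethod
    def from_tsv(cls, path) -> "MRGCatalog":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def select_best_hits(
    annotations: Sequence[KOAnnotation], evalue_max: float = 1e-4
) -> list[KOAnnotation]:
    """Best above-threshold annotation per subject, E-value strictly below cut."""
    eligible = [a for a in annotations if a.above_threshold and a.evalue < evalue_max]
    best: dict[str, KOAnnotation] = {}
    for hit in eligible:
        incumbent = best.get(hit.subject_id)
        if (
            incumbent is None
            or (hit.score, -hit.evalue, incumbent.ko) > (incumbent.score, -incumbent.evalue, hit.ko)
        ):
            best[hit.subject_id] = hit
    return [best[s] for s in sorted(best)]


def aggregate_by_ko(
    bacmet: Sequence[BacMetRecord], hits: Sequence[KOAnnotation]
) -> list[tuple[str, tuple[str, ...], tuple[str, ...]]]:
    """One row per KO: (ko, merged compounds, merged gene symbols).

    Several BacMet records can share a function (same KO) under different
    taxonomic entries; their compound lists and symbols are unioned.
    """
    by_id = {rec.bacmet_id: rec for rec in bacmet}
    grouped: dict[str, tuple[set, set]] = {}
    for hit in hits:
        if hit.subject_id not in by_id:
            raise SchemaError(f"annotation references unknown BacMet id {hit.subject_id!r}")
        rec = by_id[hit.subject_id]
        compounds, symbols = grouped.setdefault(hit.ko, (set(), set()))
        compounds.update(rec.compounds)
        symbols.add(rec.gene_symbol)
    return [
        (ko, tuple(sorted(compounds)), tuple(sorted(symbols)))
        for ko, (compounds, symbols) in sorted(grouped.items())
    ]


def filter_metal_only(
    rows: Sequence[tuple[str, tuple[str, ...], tuple[str, ...]]],
    metal_vocabulary: Sequence[str] = METAL_VOCABULARY,
    curator_flags: Mapping[str, bool] | None = None,
) -> list[tuple[str, tuple[str, ...], tuple[str, ...]]]:
    """Keep rows with at least one recognised metal AND a true curator flag."""
    if not metal_vocabulary:
        raise ValueError("metal vocabulary must be non-empty")
    vocab = set(metal_vocabulary)
    flags = dict(curator_flags or {})
    kept = []
    for ko, compounds, symbols in rows:
        if not vocab.intersection(compounds):
            continue
        if not flags.get(ko, False):
            continue
        kept.append((ko, compounds, symbols))
    return kept


def merge_catalog(
    bacmet_derived: Sequence[MRGEntry],
    eps: Sequence[MRGEntry] = (),
    literature: Sequence[MRGEntry] = (),
) -> MRGCatalog:
    """Merge sources into one unique-KO catalog; BacMet provenance wins.

    Duplicate KOs across sources collapse into the higher-precedence entry.
    Entries that disagree on the mechanism for the same KO are a curation
    error and raise :class:`ValidationError` listing the offending KOs.
    """
    precedence = {"BacMet": 0, "KEGG": 1, "literature": 2, "EPS": 3}
    merged: dict[str, MRGEntry] = {}
    conflicts = []
    for entry in list(bacmet_derived) + list(literature) + list(eps):
        incumbent = merged.get(entry.ko)
        if incumbent is None:
            merged[entry.ko] = entry
            continue
        if incumbent.mechanism != entry.mechanism:
            conflicts.append(entry.ko)
            continue
        if precedence[entry.source] < precedence[incumbent.source]:
            merged[entry.ko] = entry
    if conflicts:
        raise ValidationError(
            "conflicting mechanism labels for KOs: " + ", ".join(sorted(set(conflicts)))
        )
    catalog = MRGCatalog(merged.values())
    counts = pd.Series([e.source for e in catalog]).value_counts().to_dict()
    logger.info("merged catalog: %d KOs (%s)", len(catalog), counts)
    return catalog


def _load_fixture(filename: str) -> list[MRGEntry]:
    ref = resources.files("amdtox.data") / filename
    with ref.open() as fh:
        return list(MRGCatalog.from_frame(pd.read_csv(fh, sep="\t")))


def load_table3_fixture() -> list[MRGEntry]:
    """The 48 metal-specific marker KOs (Al, Cu, Fe, Mn, Zn, Ni, As)."""
    entries = _load_fixture("mrg_metal_specific_cm.tsv")
    if len(entries) != 48:
        raise SchemaError(
            f"metal-specific fixture corrupted: expected 48 entries, found {len(entries)}"
        )
    return entries


def load_table4_fixture() -> list[MRGEntry]:
    """The 16 EPS synthesis/assembly/transport KOs (extracellular sequestration)."""
    entries = _load_fixture("mrg_eps_cm.tsv")
    if len(entries) != 16:
        raise SchemaError(
            f"EPS fixture corrupted: expected 16 entries, found {len(entries)}"
        )
    return entries


def default_catalog() -> MRGCatalog:
    """Both packaged fixtures merged (64 unique KOs)."""
    return merge_catalog(load_table3_fixture(), eps=load_table4_fixture())


def metals_for_ko(catalog: MRGCatalog, ko: str) -> list[str]:
    if ko not in catalog:
        raise KeyError(f"KO {ko!r} not in catalog")
    return list(catalog[ko].metals)
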