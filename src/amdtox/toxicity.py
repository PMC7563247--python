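"""Toxic potency factors (TPF) and per-layer toxicity rankings.

Two dimensionless indices compare a metal(loid)'s presence in water against
its USEPA National Ambient Water Quality Criteria chronic ("constant contact")
standard, with no hardness adjustment:

* ``TPF-1 = dissolved concentration / CCCF standard`` — speciation-blind.
* ``TPF-2 = free-cation activity / CCCF standard`` — speciation-aware.
  The free-cation activity is taken as ``concentration x free-ion fraction x
  gamma``; the activity coefficient defaults to 1, which treats the free-ion
  molar fraction itself as the activity. ``gamma`` is an explicit hook for a
  stricter thermodynamic definition.

Elements are ranked per layer by descending TPF. Adjacent elements are joined
with ``~`` (effective tie), ``>>`` (dominance, ratio at least ``big_factor``)
or ``>``. Arsenic is an oxyanion/neutral acid at low pH, not a cation, so it
carries no TPF-2.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .errors import SchemaError

__all__ = [
    "WaterChemistry",
    "RankString",
    "round_sigfig",
    "derive_mn_standard",
    "compute_tpf1",
    "compute_tpf2",
    "tpf_table",
    "rank_elements",
]

logger = logging.getLogger(__name__)

#: Elements that are not cationic in acidic water and therefore have no TPF-2.
NON_CATIONIC = ("As(III)", "As(V)", "As")


@dataclass
class WaterChemistry:
    """Per-layer dissolved concentrations plus the measured layer conditions.

    ``data`` is a long-format table with columns ``layer``, ``element``,
    ``conc_ug_per_L``; ``conditions`` (optional) has one row per layer with at
    least ``layer``, ``pH`` and ``temperature_C``.
    """

    data: pd.DataFrame
    conditions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = {"layer", "element", "conc_ug_per_L"} - set(self.data.columns)
        if missing:
            raise SchemaError(f"water chemistry table lacks columns: {sorted(missing)}")

    @property
    def layers(self) -> list[str]:
        return list(dict.fromkeys(self.data["layer"]))

    def concentration(self, layer: str, element: str) -> float:
        sel = self.data[(self.data["layer"] == layer) & (self.data["element"] == element)]
        if sel.empty:
            raise KeyError(f"no concentration for {element!r} in layer {layer!r}")
        return float(sel["conc_ug_per_L"].iloc[0])


def round_sigfig(x: float, n: int = 2) -> float:
    """Round ``x`` to ``n`` significant figures, halves away from zero."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if x == 0 or not math.isfinite(x):
        return x
    d = Decimal(repr(float(x)))
    quantum = Decimal(1).scaleb(d.adjusted() - n + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def derive_mn_standard(fe_standard: float, reported: bool = False) -> float:
    """Mn chronic standard derived from the Fe standard as Fe/6.

    The USEPA criteria list no Mn value; the ratio of the Fe and Mn drinking
    water standards (6:1) is used instead. With ``reported=True`` the value is
    rounded to the nearest integer for display; computations use the raw
    quotient.
    """
    if fe_standard <= 0:
        raise ValueError("Fe standard must be positive")
    raw = fe_standard / 6.0
    if reported:
        return float(Decimal(repr(raw)).quantize(Decimal(1), rounding=ROUND_HALF_UP))
    return raw


def compute_tpf1(concentration: float, standard: float) -> float:
    """Speciation-blind toxic potency: dissolved concentration over standard."""
    if standard <= 0:
        raise ValueError("standard must be positive")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    return concentration / standard


def compute_tpf2(
    concentration: float,
    free_fraction: float,
    gamma: float = 1.0,
    standard: float = 1.0,
) -> float:
    """Speciation-aware toxic potency: free-cation activity over standard."""
    if not 0.0 <= free_fraction <= 1.0:
        raise ValueError("free_fraction must be in [0, 1]")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if standard <= 0:
        raise ValueError("standard must be positive")
    return concentration * free_fraction * gamma / standard


def tpf_table(
    chem: WaterChemistry | pd.DataFrame,
    standards: Mapping[str, float] | pd.Series,
    fractions: pd.DataFrame | None = None,
    gamma: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One TPF record per (element, layer) with a dissolved concentration.

    ``standards`` maps element to its CCCF standard (ug/L). Elements without a
    standard are skipped with a warning. ``fractions`` is a long table with
    ``layer``, ``element``, ``free_percent``; elements absent from it (or
    non-cationic ones) get no TPF-2. ``gamma`` optionally maps element to an
    activity coefficient (default 1).
    """
    data = chem.data if isinstance(chem, WaterChemistry) else chem
    standards = dict(standards)
    gamma = dict(gamma or {})
    frac_lookup: dict[tuple[str, str], float] = {}
    if fractions is not None:
        for row in fractions.itertuples():
            if pd.notna(row.free_percent):
                frac_lookup[(row.layer, row.element)] = float(row.free_percent) / 100.0

    records = []
    for row in data.itertuples():
        element, layer, conc = row.element, row.layer, float(row.conc_ug_per_L)
        if element not in standards:
            logger.warning("element %s has no CCCF standard; skipped", element)
            continue
        std = float(standards[element])
        g = float(gamma.get(element, 1.0))
        tpf1 = compute_tpf1(conc, std)
        free = frac_lookup.get((layer, element))
        if element in NON_CATIONIC or free is None:
            tpf2 = math.nan
        else:
            tpf2 = compute_tpf2(conc, free, g, std)
        records.append(
            {
                "layer": layer,
                "element": element,
                "concentration": conc,
                "standard": std,
                "free_fraction": math.nan if free is None else free,
                "gamma": g,
                "tpf1_raw": tpf1,
                "tpf1_reported": round_sigfig(tpf1, 2),
                "tpf2_raw": tpf2,
                "tpf2_reported": math.nan if math.isnan(tpf2) else round_sigfig(tpf2, 2),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "layer", "element", "concentration", "standard", "free_fraction",
            "gamma", "tpf1_raw", "tpf1_reported", "tpf2_raw", "tpf2_reported",
        ],
    )


@dataclass
class RankString:
    """An ordered toxicity ranking such as ``Fe(II) >> Zn > Mn ~ Co``."""

    elements: list[str]
    separators: list[str] = field(default_factory=list)

    SEPS = ("~", ">>", ">")

    def __post_init__(self) -> None:
        if len(self.separators) != max(len(self.elements) - 1, 0):
            raise ValueError("need exactly one separator between consecutive elements")
        for sep in self.separators:
            if sep not in self.SEPS:
                raise ValueError(f"unknown separator {sep!r}")

    def render(self) -> str:
        parts = [self.elements[0]] if self.elements else []
        for sep, elem in zip(self.separators, self.elements[1:]):
            parts.extend([sep, elem])
        return " ".join(parts)

    __str__ = render

    @classmethod
    def parse(cls, text: str) -> "RankString":
        tokens = text.split()
        elements, separators = [], []
        for i, tok in enumerate(tokens):
            if i % 2 == 0:
                elements.append(tok)
            else:
                separators.append(tok)
        return cls(elements, separators)


def rank_elements(
    tpfs: Mapping[str, float],
    tie_tol: float = 0.05,
    big_factor: float = 5.0,
) -> RankString:
    """Rank elements by descending TPF; ties broken alphabetically.

    Adjacent values a >= b are joined with ``~`` when their symmetric relative
    difference ``2|a-b|/(a+b)`` is within ``tie_tol``, with ``>>`` when
    ``a/b >= big_factor`` and with ``>`` otherwise.
    """
    if not tpfs:
        raise ValueError("cannot rank an empty map")
    if any(v < 0 for v in tpfs.values()):
        raise ValueError("TPF values must be non-negative")
    ordered = sorted(tpfs.items(), key=lambda kv: (-kv[1], kv[0]))
    elements = [e for e, _ in ordered]
    separators = []
    for (_, a), (_, b) in zip(ordered, ordered[1:]):
        if a == b or (a + b > 0 and 2.0 * abs(a - b) / (a + b) <= tie_tol):
            separators.append("~")
        elif b == 0 or a / b >= big_factor:
            separators.append(">>")
        else:
            separators.append(">")
    return RankString(elements, separators)


def rank_layer(table: pd.DataFrame, layer: str, which: str = "tpf1_raw", **kwargs) -> RankString:
    """Convenience: rank all elements of one layer of a ``tpf_table`` output."""
    sub = table[table["layer"] == layer].dropna(subset=[which])
    return rank_elements(dict(zip(sub["element"], sub[which])), **kwargs)


def write_tpf_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_standards_tsv(path) -> dict[str, float]:
    frame = pd.read_csv(path, sep="\t")
    if not {"element", "cccf_ug_per_L"} <= set(frame.columns):
        raise SchemaError("standards table needs columns element, cccf_ug_per_L")
    return dict(zip(frame["element"], frame["cccf_ug_per_L"].astype(float)))
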