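"""Loaders for the packaged study tables.

These hold the published per-layer water chemistry, the chronic water-quality
standards, the speciation summary (free-cation percentages and predominant
species), the printed toxic potency factors used as ranking inputs, and the
deep-layer MAG metadata. The printed rankings are kept as constants so the
ranking logic can be validated against them.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .toxicity import WaterChemistry, derive_mn_standard

__all__ = [
    "load_water_chemistry",
    "load_standards",
    "load_free_fractions",
    "load_printed_tpf",
    "PRINTED_RANKINGS",
    "LAYERS",
]

LAYERS = ("upper", "chemocline", "deep")

#: Published per-layer toxicity rankings (element order and separators).
PRINTED_RANKINGS = {
    ("upper", "tpf1"): "Al > Cu > Fe(III) ~ Mn ~ Zn ~ Co > Ni > As(V)",
    ("chemocline", "tpf1"): "Al > Fe(II) > Zn > Mn > Co > Ni > Cu > As(V)",
    ("deep", "tpf1"): "Fe(II) >> Zn > Mn > As(III) ~ Co > Al > Ni > Cu",
    ("upper", "tpf2"): "Cu > Al > Mn > Co > Zn > Fe(III) ~ Ni",
    ("chemocline", "tpf2"): "Fe(II) > Al > Mn > Zn > Co > Ni > Cu",
    ("deep", "tpf2"): "Fe(II) >> Mn > Zn > Co > Ni > Al > Cu",
}


def _read(filename: str) -> pd.DataFrame:
    ref = resources.files("amdtox.data") / filename
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_water_chemistry() -> WaterChemistry:
    """Historical mean dissolved concentrations (ug/L) for the three layers."""
    return WaterChemistry(
        data=_read("water_chemistry_cm.tsv"),
        conditions=_read("layer_conditions_cm.tsv"),
    )


def load_standards(derive_mn: bool = True) -> dict[str, float]:
    """Chronic (CCCF) standards in ug/L; Mn derived as Fe/6 when requested.

    The derived Mn value is kept unrounded for computation (the published
    table displays it rounded to 167).
    """
    table = _read("standards_cm.tsv")
    standards = dict(zip(table["element"], table["cccf_ug_per_L"].astype(float)))
    if derive_mn:
        standards["Mn"] = derive_mn_standard(standards["Fe(II)"])
    return standards


def load_free_fractions() -> pd.DataFrame:
    """Speciation summary per layer: free-cation % and predominant species."""
    return _read("free_fractions_cm.tsv")


def load_printed_tpf() -> pd.DataFrame:
    """The published TPF-1/TPF-2 values (inputs for ranking reproduction)."""
    return _read("printed_tpf_cm.tsv")
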