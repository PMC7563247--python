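"""TPM normalization, KO functional profiles and RNA:DNA expression ratios.

Mapped read counts per predicted gene are normalized to transcripts per
million: per sample, ``rate_g = count_g / length_g`` and ``TPM_g = 1e6 *
rate_g / sum(rates)``, so every sample column sums to one million over all
genes. Gene-level TPM is summed per KEGG Orthology group into a functional
profile; the TPM denominator always includes every predicted gene, annotated
or not, so KO profiles sum to less than 1e6 whenever unannotated genes exist.
Expression per KO is the ratio RNA_TPM / DNA_TPM, undefined (missing) where
the DNA TPM is zero — a ratio with a zero denominator carries no information
and is reported as a blank, never as infinity or zero.
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "genes_to_frame",
    "compute_tpm",
    "aggregate_by_ko_tpm",
    "expression_ratio",
    "mrg_subset_profile",
    "annotated_fraction",
    "domain_mechanism_rollup",
    "slope_sign",
]


def genes_to_frame(genes) -> pd.DataFrame:
    """Coerce a gene catalog (DataFrame or GeneRecord sequence) to a DataFrame."""
    if isinstance(genes, pd.DataFrame):
        frame = genes
    else:
        frame = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "length": [g.length for g in genes],
                "ko": [g.ko for g in genes],
                "domain": [g.domain for g in genes],
                "mag_id": [g.mag_id for g in genes],
            }
        )
    if "gene_id" not in frame.columns or "length" not in frame.columns:
        raise SchemaError("gene catalog needs gene_id and length columns")
    return frame


def compute_tpm(counts: pd.DataFrame, genes) -> pd.DataFrame:
    """Length-normalized relative abundance (gene x sample), columns sum to 1e6.

    ``counts`` is gene x sample (index = gene_id), integer or fractional.
    An all-zero sample yields an all-zero column rather than NaN.
    """
    frame = genes_to_frame(genes).set_index("gene_id")
    lengths = frame["length"].reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()][:5].tolist()
        raise SchemaError(f"counted genes missing from catalog: {missing} ...")
    if (lengths <= 0).any():
        raise SchemaError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    rates = counts.div(lengths, axis=0)
    denom = rates.sum(axis=0)
    denom = denom.replace(0.0, np.nan)  # all-zero samples -> 0/NaN -> fill 0
    return (rates.div(denom, axis=1) * 1e6).fillna(0.0)


def aggregate_by_ko_tpm(tpm: pd.DataFrame, genes) -> pd.DataFrame:
    """Sum member-gene TPM per KO (KO x sample functional profile).

    Genes without a KO contribute to no row but were already part of the TPM
    denominator, preserving the whole-community normalization.
    """
    frame = genes_to_frame(genes).set_index("gene_id")
    kos = frame["ko"].reindex(tpm.index)
    mask = kos.notna() & (kos != "")
    grouped = tpm[mask].groupby(kos[mask]).sum()
    grouped.index.name = "ko"
    return grouped.sort_index()


def expression_ratio(rna: pd.DataFrame, dna: pd.DataFrame) -> pd.DataFrame:
    """Elementwise RNA_TPM / DNA_TPM over the union of KOs (absent = 0).

    DNA = 0 gives a missing value (NaN); RNA = 0 with DNA > 0 gives 0.
    """
    kos = dna.index.union(rna.index)
    samples = dna.columns.union(rna.columns)
    d = dna.reindex(index=kos, columns=samples, fill_value=0.0).astype(float)
    r = rna.reindex(index=kos, columns=samples, fill_value=0.0).astype(float)
    out = r / d.where(d > 0)
    return out


def mrg_subset_profile(profile: pd.DataFrame, catalog) -> pd.DataFrame:
    """Rows restricted to catalog KOs, in catalog order."""
    order = [ko for ko in catalog.kos if ko in profile.index]
    return profile.loc[order]


def annotated_fraction(genes, catalog, denominator: str = "annotated") -> float:
    """Share of genes whose KO belongs to the MRG catalog.

    ``denominator="annotated"`` (default) divides by the number of
    KO-annotated genes; ``"all"`` divides by every predicted gene. The wording
    of the source statistic is ambiguous between the two, so both are exposed.
    """
    frame = genes_to_frame(genes)
    if "ko" not in frame.columns:
        raise SchemaError("gene catalog lacks a ko column")
    kos = frame["ko"]
    annotated = kos.notna() & (kos != "")
    if denominator == "annotated":
        n_denom = int(annotated.sum())
        if n_denom == 0:
            raise ValueError("no KO-annotated genes")
    elif denominator == "all":
        n_denom = len(frame)
        if n_denom == 0:
            raise ValueError("empty gene catalog")
    else:
        raise ValueError("denominator must be 'annotated' or 'all'")
    in_catalog = int(kos[annotated].isin(set(catalog.kos)).sum())
    return in_catalog / n_denom


def domain_mechanism_rollup(profile: pd.DataFrame, genes, catalog) -> pd.DataFrame:
    """Sum gene-level TPM of catalog genes into (domain, mechanism) x sample.

    ``profile`` is the gene x sample TPM table. Totals are conserved: the
    rollup sums to the same per-sample total as the KO-level MRG subset.
    """
    frame = genes_to_frame(genes).set_index("gene_id")
    kos = frame["ko"].reindex(profile.index)
    member = kos.isin(set(catalog.kos))
    sub = profile[member]
    domains = frame["domain"].reindex(sub.index)
    if domains.isna().any() or (domains == "").any():
        bad = sub.index[domains.isna() | (domains == "")].tolist()
        raise ValidationError(f"genes lacking a domain label: {bad}")
    mechanisms = kos[member].map(lambda ko: catalog.mechanism_of(ko))
    grouped = sub.groupby([domains, mechanisms]).sum()
    grouped.index.names = ["domain", "mechanism"]
    return grouped.sort_index()


def slope_sign(
    expression_by_layer: Mapping[str, float],
    concentration_by_layer: Mapping[str, float],
    flat_tol: float = 1e-12,
) -> str:
    """Sign of the OLS slope of expression against concentration.

    Only the regression slope is interpreted — no significance is implied.
    Layers with undefined (NaN) expression are dropped; at least two defined
    points are required.
    """
    pairs = [
        (concentration_by_layer[layer], expr)
        for layer, expr in expression_by_layer.items()
        if layer in concentration_by_layer and not math.isnan(expr)
    ]
    if len(pairs) < 2:
        raise ValueError("need at least two layers with defined expression")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        return "flat"
    slope = np.polyfit(x, y, 1)[0]
    if abs(slope) < flat_tol:
        return "flat"
    return "positive" if slope > 0 else "negative"
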