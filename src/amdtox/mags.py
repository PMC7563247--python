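"""MAG selection rules and per-MAG metal-resistance profiles.

Metagenome-assembled genomes (MAGs) pass three gates before profiling:

* MIMAG quality — medium requires completeness >= 50% and contamination
  < 10%; the high tier additionally needs completeness >= 90%, contamination
  < 5% and rRNA/tRNA evidence, without which a genome is capped at medium.
* ANI dereplication — species-level redundancy is removed greedily: MAGs are
  visited in descending score (completeness - 5 x contamination, a documented
  simplification of dRep's scoring) and kept only if their average nucleotide
  identity to every already-kept representative is below 96.5%.
* transcriptional coverage — MAGs with fewer than 500 mapped mRNA reads carry
  too little signal for expression profiling and are excluded (exactly 500
  is kept).

Profiling then computes TPM within each MAG (the denominator is that MAG's
own genes, making rows comparable across genomes of different sizes),
aggregates by KO, restricts to the MRG catalog and forms RNA:DNA ratios.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import SchemaError
from .quantify import aggregate_by_ko_tpm, compute_tpm, expression_ratio, genes_to_frame, mrg_subset_profile

__all__ = [
    "MAGRecord",
    "load_mag_fixture",
    "classify_mimag",
    "filter_by_mrna",
    "dereplicate_by_ani",
    "validate_ani",
    "per_mag_mrg_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class MAGRecord:
    mag_id: str
    taxonomy: str
    rel_abundance: float
    completeness: float
    contamination: float
    mrna_reads: int | None = None


def load_mag_fixture() -> pd.DataFrame:
    """The packaged deep-layer MAG metadata table (13 genomes).

    Mapped-mRNA counts were not published for these genomes, so the fixture
    carries no ``mrna_reads`` column; the mRNA filter is exercised on
    synthetic tables instead.
    """
    ref = resources.files("amdtox.data") / "mags_cm.tsv"
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def classify_mimag(
    completeness: float,
    contamination: float,
    has_rrna_trna_info: bool = False,
) -> str:
    """MIMAG tier: ``high``, ``medium``, ``low`` or ``failed``.

    ``high`` needs completeness >= 90, contamination < 5 AND rRNA/tRNA
    evidence; checkM-style tables lack that evidence, so their best genomes
    classify as medium.
    """
    if not 0 <= completeness <= 100:
        raise ValueError("completeness must be a percentage in [0, 100]")
    if contamination < 0:
        raise ValueError("contamination must be non-negative")
    if contamination >= 10:
        return "failed"
    if completeness >= 90 and contamination < 5 and has_rrna_trna_info:
        return "high"
    if completeness >= 50:
        return "medium"
    return "low"


def filter_by_mrna(mags: pd.DataFrame, min_reads: int = 500) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a MAG table into (kept, excluded) by mapped-mRNA read count.

    "Fewer than ``min_reads``" is excluded, so the boundary value is kept.
    """
    if "mrna_reads" not in mags.columns:
        raise SchemaError("MAG table lacks an mrna_reads column")
    keep = mags["mrna_reads"] >= min_reads
    return mags[keep].copy(), mags[~keep].copy()


def validate_ani(ani: pd.DataFrame, atol: float = 1e-6) -> None:
    mat = ani.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or list(ani.index) != list(ani.columns):
        raise SchemaError("ANI matrix must be square with matching labels")
    if not np.allclose(mat, mat.T, atol=atol):
        raise SchemaError("ANI matrix is not symmetric")
    if not np.allclose(np.diag(mat), 100.0, atol=atol):
        raise SchemaError("ANI matrix diagonal must be 100")


def dereplicate_by_ani(
    mags: pd.DataFrame, ani: pd.DataFrame, threshold: float = 96.5
) -> pd.DataFrame:
    """Greedy species-level dereplication below an ANI threshold.

    Score = completeness - 5 x contamination; ties broken by mag_id so the
    result does not depend on input order.
    """
    validate_ani(ani)
    if set(mags["mag_id"]) != set(ani.index):
        raise SchemaError("MAG table and ANI matrix label sets differ")
    scored = mags.assign(_score=mags["completeness"] - 5.0 * mags["contamination"])
    scored = scored.sort_values(["_score", "mag_id"], ascending=[False, True])
    kept: list[str] = []
    for mag_id in scored["mag_id"]:
        if all(float(ani.loc[mag_id, other]) < threshold for other in kept):
            kept.append(mag_id)
    out = mags[mags["mag_id"].isin(kept)].copy()
    return out.set_index("mag_id").loc[kept].reset_index()


def per_mag_mrg_matrix(
    genes,
    dna_counts: pd.Series | pd.DataFrame,
    rna_counts: pd.Series | pd.DataFrame,
    catalog,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-MAG MRG profiles: (gene TPM, transcript TPM, expression), MAG x KO.

    TPM is normalized within each MAG over that MAG's genes only. Counts are
    a single sample (Series, or a one-column DataFrame). MAGs with zero total
    counts produce all-zero rows with a warning.
    """
    frame = genes_to_frame(genes)
    if frame["mag_id"].isna().any() or (frame["mag_id"] == "").any():
        raise SchemaError("every profiled gene needs a mag_id")

    def as_series(counts, label):
        if isinstance(counts, pd.DataFrame):
            if counts.shape[1] != 1:
                raise SchemaError(f"{label} counts must be a single sample")
            return counts.iloc[:, 0]
        return counts

    dna = as_series(dna_counts, "DNA")
    rna = as_series(rna_counts, "RNA")

    dna_rows, rna_rows, expr_rows = {}, {}, {}
    for mag_id, sub in frame.groupby("mag_id"):
        gene_ids = sub["gene_id"]
        d = dna.reindex(gene_ids).fillna(0.0).to_frame("sample")
        r = rna.reindex(gene_ids).fillna(0.0).to_frame("sample")
        if float(d.to_numpy().sum()) == 0.0:
            logger.warning("MAG %s has zero total DNA counts; all-zero row", mag_id)
        dna_ko = aggregate_by_ko_tpm(compute_tpm(d, sub), sub)
        rna_ko = aggregate_by_ko_tpm(compute_tpm(r, sub), sub)
        dna_mrg = mrg_subset_profile(dna_ko, catalog)
        rna_mrg = mrg_subset_profile(rna_ko, catalog)
        expr = expression_ratio(rna_mrg, dna_mrg)
        dna_rows[mag_id] = dna_mrg["sample"]
        rna_rows[mag_id] = rna_mrg["sample"]
        expr_rows[mag_id] = expr["sample"]

    kos = [ko for ko in catalog.kos]
    gene_tpm = pd.DataFrame(dna_rows).T.reindex(columns=kos).fillna(0.0)
    tx_tpm = pd.DataFrame(rna_rows).T.reindex(columns=kos).fillna(0.0)
    expression = pd.DataFrame(expr_rows).T.reindex(columns=kos)
    for df in (gene_tpm, tx_tpm, expression):
        df.index.name = "mag_id"
        df.columns.name = "ko"
    return gene_tpm, tx_tpm, expression
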