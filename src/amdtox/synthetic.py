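"""Synthetic gene catalogs, count matrices, water chemistry and MAG tables.

Everything downstream of read mapping consumes plain tables (gene catalogs,
count matrices, chemistry, MAG metadata), so the whole analysis chain can be
exercised against data with known ground truth and no external downloads.

The count model is negative-binomial with length-proportional means: each
gene gets a log-normal relative abundance ``a_g``; the expected DNA count is
``depth * a_g * len_g / sum(a * len)`` and the expected RNA count is the same
with an extra per-KO expression multiplier. Aggregated to TPM this makes the
planted RNA:DNA ratio exact in expectation, so recovery error measures only
counting noise. All randomness flows through a counter-based (Philox)
generator keyed by the seed plus a per-operation stream constant, so any one
operation is reproducible on its own and identical configs give identical
output, byte for byte.

Sequences, reads, assemblies and phylogenetic structure are out of scope —
this emulates the *tables* a mapping pipeline produces, not the pipeline.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .toxicity import WaterChemistry

__all__ = [
    "SimConfig",
    "GeneRecord",
    "CountMatrix",
    "CountTables",
    "gen_gene_catalog",
    "gen_count_tables",
    "gen_water_chemistry",
    "gen_mag_table",
]

DOMAINS = ("Bacteria", "Archaea", "Eukaryota")

# per-operation stream constants so each generator draws from its own
# independent counter-based stream
_STREAM_CATALOG = 1
_STREAM_COUNTS = 2
_STREAM_WATER = 3
_STREAM_MAGS = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=(int(seed) << 16) + stream))


@dataclass
class SimConfig:
    """Study-scale defaults for the simulated community.

    The defaults mirror the sequenced system: two replicate samples per
    run, ~10^4-gene catalogs with ~half of genes KO-annotated, ~3% of
    annotated genes matching the MRG catalog, a deep-layer-like domain mix,
    and 1e7 mapped reads per sample. ``dispersion`` is the negative-binomial
    size parameter (larger = closer to Poisson); 10 models the mild technical
    overdispersion of mapped counts. ``expression_effects`` plants true
    RNA:DNA multipliers per KO (default 1 everywhere).
    """

    n_genes: int = 10_000
    n_samples: int = 2
    domain_mix: dict[str, float] = field(
        default_factory=lambda: {"Bacteria": 0.5, "Archaea": 0.3, "Eukaryota": 0.2}
    )
    mrg_fraction: float = 0.03
    annotated_fraction: float = 0.5
    length_log_mean: float = 6.8  # ~900 bp median gene length
    length_log_sd: float = 0.35
    dna_depth: float = 1e7
    rna_depth: float = 1e7
    dispersion: float = 10.0
    abundance_log_sd: float = 0.7
    expression_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be non-negative")
        if abs(sum(self.domain_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("domain_mix proportions must sum to 1")
        if not set(self.domain_mix) <= set(DOMAINS):
            raise ConfigurationError(f"domains must be among {DOMAINS}")
        if not 0.0 <= self.mrg_fraction <= 1.0:
            raise ConfigurationError("mrg_fraction must be in [0, 1]")
        if not 0.0 <= self.annotated_fraction <= 1.0:
            raise ConfigurationError("annotated_fraction must be in [0, 1]")
        if self.dna_depth <= 0 or self.rna_depth <= 0:
            raise ConfigurationError("depths must be positive")
        if not self.dispersion > 0:
            raise ConfigurationError("dispersion must be positive")


@dataclass
class GeneRecord:
    gene_id: str
    length: int
    ko: str | None
    evalue: float | None
    domain: str
    mag_id: str | None = None


@dataclass
class CountMatrix:
    molecule: str  # "DNA" | "RNA"
    counts: pd.DataFrame  # gene x sample, non-negative integers
    sample_ids: list[str]


@dataclass
class CountTables:
    """DNA and RNA count matrices plus the planted per-KO expression truth."""

    dna: CountMatrix
    rna: CountMatrix
    truth: pd.DataFrame  # columns: ko, multiplier, true_expression


def gen_gene_catalog(config: SimConfig, catalog) -> list[GeneRecord]:
    """Simulate a predicted-gene catalog with planted MRG annotations.

    A fraction ``annotated_fraction`` of genes carries a KO; of those, a
    binomial share ``mrg_fraction`` draws its KO uniformly from the MRG
    catalog, the rest draw decoy KOs guaranteed to be outside it.
    """
    config.validate()
    catalog_kos = list(catalog.kos) if catalog is not None else []
    if not catalog_kos and config.mrg_fraction > 0:
        raise ConfigurationError("mrg_fraction > 0 requires a non-empty MRG catalog")
    if config.n_genes == 0:
        return []

    rng = _rng(config.seed, _STREAM_CATALOG)
    n = config.n_genes
    lengths = np.maximum(
        100, np.rint(rng.lognormal(config.length_log_mean, config.length_log_sd, n))
    ).astype(int)
    domains = rng.choice(
        list(config.domain_mix), size=n, p=list(config.domain_mix.values())
    )
    annotated = rng.random(n) < config.annotated_fraction
    is_mrg = annotated & (rng.random(n) < config.mrg_fraction)

    in_catalog = set(catalog_kos)
    decoys = [f"K{i:05d}" for i in range(90_000, 99_999) if f"K{i:05d}" not in in_catalog]

    width = len(str(n))
    records = []
    for i in range(n):
        if not annotated[i]:
            ko, evalue = None, None
        elif is_mrg[i]:
            ko = catalog_kos[rng.integers(len(catalog_kos))]
            evalue = 10.0 ** rng.uniform(-40, -5)
        else:
            ko = decoys[rng.integers(len(decoys))]
            evalue = 10.0 ** rng.uniform(-40, -5)
        records.append(
            GeneRecord(
                gene_id=f"gene_{i + 1:0{width}d}",
                length=int(lengths[i]),
                ko=ko,
                evalue=evalue,
                domain=str(domains[i]),
            )
        )
    return records


def gen_count_tables(genes: Sequence[GeneRecord], config: SimConfig) -> CountTables:
    """Draw DNA and RNA count matrices and record the planted truth.

    The recorded ``true_expression`` is the expected TPM ratio, i.e. the raw
    multiplier rescaled by the community-wide factor ``sum(w) / sum(w * m)``
    that whole-sample normalization introduces (w = abundance x length).
    With all multipliers at 1 that factor is 1.
    """
    config.validate()
    if not genes:
        raise ConfigurationError("gene catalog must be non-empty")
    rng = _rng(config.seed, _STREAM_COUNTS)
    n = len(genes)
    lengths = np.array([g.length for g in genes], dtype=float)
    abundance = rng.lognormal(0.0, config.abundance_log_sd, n)
    mult = np.array(
        [config.expression_effects.get(g.ko, 1.0) if g.ko else 1.0 for g in genes]
    )

    w = abundance * lengths
    mu_dna = config.dna_depth * w / w.sum()
    wm = w * mult
    mu_rna = config.rna_depth * wm / wm.sum()

    def draw(mu: np.ndarray) -> np.ndarray:
        out = np.zeros((n, config.n_samples), dtype=np.int64)
        for j in range(config.n_samples):
            if math.isfinite(config.dispersion):
                p = config.dispersion / (config.dispersion + mu)
                out[:, j] = rng.negative_binomial(config.dispersion, p)
            else:  # Poisson limit
                out[:, j] = rng.poisson(mu)
        return out

    gene_ids = [g.gene_id for g in genes]
    samples = [f"sample_{j + 1}" for j in range(config.n_samples)]
    dna = pd.DataFrame(draw(mu_dna), index=gene_ids, columns=samples)
    rna = pd.DataFrame(draw(mu_rna), index=gene_ids, columns=samples)
    dna.index.name = rna.index.name = "gene_id"

    scale = w.sum() / wm.sum()
    truth_rows = {}
    for g, m in zip(genes, mult):
        if g.ko and g.ko not in truth_rows:
            truth_rows[g.ko] = (float(m), float(m) * scale)
    truth = pd.DataFrame(
        [(ko, m, t) for ko, (m, t) in sorted(truth_rows.items())],
        columns=["ko", "multiplier", "true_expression"],
    )
    return CountTables(
        dna=CountMatrix("DNA", dna, samples),
        rna=CountMatrix("RNA", rna, samples),
        truth=truth,
    )


def gen_water_chemistry(
    n_layers: int,
    ranges: Mapping[str, tuple[float, float]],
    seed: int = 0,
    pH_range: tuple[float, float] = (2.5, 4.5),
    temperature_C: float = 18.0,
) -> WaterChemistry:
    """Log-uniform concentrations per element and layer (Table-1-like schema)."""
    rng = _rng(seed, _STREAM_WATER)
    for element, (lo, hi) in ranges.items():
        if lo <= 0 or hi <= 0:
            raise ConfigurationError(f"bounds for {element} must be positive")
        if lo > hi:
            raise ConfigurationError(f"lower bound above upper bound for {element}")
    layers = [f"layer_{i + 1}" for i in range(n_layers)]
    rows = []
    for layer in layers:
        for element, (lo, hi) in ranges.items():
            conc = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            rows.append({"layer": layer, "element": element, "conc_ug_per_L": conc})
    conditions = pd.DataFrame(
        {
            "layer": layers,
            "pH": rng.uniform(*sorted(pH_range), size=n_layers),
            "temperature_C": temperature_C,
        }
    )
    return WaterChemistry(data=pd.DataFrame(rows), conditions=conditions)


def gen_mag_table(
    n_mags: int,
    seed: int = 0,
    n_low_mrna: int = 0,
    duplicate_pairs: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Simulate MAG metadata, a pairwise ANI matrix and a gene assignment.

    ``n_low_mrna`` MAGs are planted below the 500-mapped-mRNA-read threshold;
    ``duplicate_pairs`` consecutive MAG pairs are planted at 99% ANI (the
    rest of the off-diagonal sits well below the species threshold). If
    ``gene_ids`` is given, each gene is assigned to a MAG uniformly and the
    mapping is returned (empty dict otherwise).
    """
    if n_mags < 1:
        raise ConfigurationError("n_mags must be >= 1")
    if n_low_mrna > n_mags:
        raise ConfigurationError("cannot plant more low-mRNA MAGs than MAGs")
    if duplicate_pairs * 2 > n_mags:
        raise ConfigurationError("too many duplicate pairs for n_mags")
    rng = _rng(seed, _STREAM_MAGS)
    mag_ids = [f"MAG_{i + 1:03d}" for i in range(n_mags)]
    completeness = rng.uniform(50, 100, n_mags).round(1)
    contamination = rng.uniform(0, 10, n_mags).round(1)
    abundance = rng.lognormal(0, 1, n_mags)
    abundance = (abundance / abundance.sum() * 100).round(2)
    mrna = rng.negative_binomial(5, 5 / (5 + 5000.0), n_mags).astype(int) + 500
    low_idx = rng.choice(n_mags, size=n_low_mrna, replace=False)
    mrna[low_idx] = rng.integers(0, 500, size=n_low_mrna)
    mags = pd.DataFrame(
        {
            "mag_id": mag_ids,
            "taxonomy": [f"d__Synthetic;s__sp{i + 1}" for i in range(n_mags)],
            "rel_abundance": abundance,
            "completeness": completeness,
            "contamination": contamination,
            "mrna_reads": mrna,
        }
    )

    ani = rng.uniform(78, 92, size=(n_mags, n_mags))
    ani = (ani + ani.T) / 2.0
    np.fill_diagonal(ani, 100.0)
    for k in range(duplicate_pairs):
        i, j = 2 * k, 2 * k + 1
        ani[i, j] = ani[j, i] = 99.0
    ani_df = pd.DataFrame(ani, index=mag_ids, columns=mag_ids)

    assignment: dict[str, str] = {}
    if gene_ids is not None:
        picks = rng.integers(0, n_mags, size=len(gene_ids))
        assignment = {g: mag_ids[k] for g, k in zip(gene_ids, picks)}
    return mags, ani_df, assignment
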