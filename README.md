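# amdtox

Metal toxicity ranking and metal-resistance-gene (MRG) profiling for acidic,
metal-rich waters — built around a permanently stratified (meromictic) acid
pit lake with an oxic upper layer, a sharp chemocline and a metal-loaded
anoxic deep layer.

The package is aimed at geomicrobiologists and environmental engineers who
want to connect water chemistry to microbial function: which dissolved
metal(loid)s are most toxic in each layer, and how the resident communities
— or individual metagenome-assembled genomes (MAGs) — respond at the gene
and transcript level.

## What it computes

**Toxic potency factors.** For each element with a chronic USEPA water
quality criterion (NAWQC-CCCF, µg/L, no hardness adjustment):

    TPF-1 = dissolved concentration / standard
    TPF-2 = free-cation activity   / standard

TPF-1 ignores speciation; TPF-2 multiplies the concentration by the free-ion
fraction (and an optional activity coefficient γ, default 1). Elements are
ranked per layer with `~` / `>` / `>>` separators. The Mn standard is
derived as Fe/6; arsenic, being non-cationic at low pH, has no TPF-2.

**Equilibrium speciation.** A damped fixed-point solver partitions each
metal between its free ion and sulfate/chloride complexes (plus As
protonation states) at fixed pH, with Davies activity coefficients
recomputed self-consistently with ionic strength. The complexation constants
ship in an editable YAML and come from standard compilations — they are
deliberately not tied to any single study.

**MRG catalog.** A curated KO-keyed catalog of metal-resistance genes: 48
metal-specific markers (Al, Cu, Fe, Mn, Zn, Ni, As) plus 16
exopolysaccharide synthesis/assembly/transport KOs used as a proxy for
extracellular metal sequestration — 64 unique KOs, each with mechanism,
metals, specificity and provenance. A deterministic pipeline rebuilds a
catalog from a user-supplied BacMet-style export (best hits, KO aggregation,
metal-vocabulary filter, curator flags, source merge).

**Quantification.** TPM normalization of gene×sample count matrices
(`TPM_g = 1e6 · (count_g/len_g) / Σ(count/len)`), KO-level functional
profiles, RNA:DNA expression ratios (missing where DNA TPM is zero),
MRG subsets, domain×mechanism rollups, and slope-sign trends of expression
against concentration.

**MAG profiling.** MIMAG quality tiers, greedy ANI dereplication (<96.5%),
a minimum mapped-mRNA filter (500 reads), and per-MAG MRG gene/transcript/
expression matrices with TPM normalized within each MAG.

**Synthetic data.** A seeded, counter-based generator for gene catalogs,
negative-binomial DNA/RNA counts with planted per-KO expression multipliers,
water chemistry and MAG tables — so the entire chain is testable with known
ground truth and no downloads.

## Worked example

```python
from amdtox import fixtures, toxicity

chem      = fixtures.load_water_chemistry()   # per-layer dissolved metals, ug/L
standards = fixtures.load_standards()         # chronic criteria, Mn derived as Fe/6
fractions = fixtures.load_free_fractions()    # free-cation % per layer

table = toxicity.tpf_table(chem, standards, fractions)
deep = table[table.layer == "deep"]
print(deep[["element", "concentration", "tpf1_reported", "tpf2_reported"]]
      .to_string(index=False))
print(toxicity.rank_elements(dict(zip(deep.element, deep.tpf1_raw))))
```

prints

```
element  concentration  tpf1_reported  tpf2_reported
     Al        5090.00       59.00000            3.5
As(III)       17200.00      110.00000            NaN
  As(V)           0.13        0.00087            NaN
     Co        2040.00      110.00000           86.0
     Cu          50.00        5.60000            2.5
 Fe(II)     6310000.00     6300.00000         4800.0
     Mn      116000.00      700.00000          570.0
     Ni         917.00       18.00000            7.8
     Zn      109000.00      910.00000          130.0

Fe(II) >> Zn > Mn >> As(III) > Co > Al > Ni > Cu >> As(V)
```

Reading this: ferrous iron in the deep anoxic layer sits 6300× above its
chronic water-quality criterion — far ahead of every other element (`>>`
marks a ≥5× drop) — and is still 4800× above it counting only the free Fe²⁺
fraction. Arsenic rows have no TPF-2 because As(III) is a neutral acid at
this pH, not a cation. A `NaN`/blank expression or TPF-2 entry always means
"undefined", never zero.

The same chain runs from the shell:

```sh
amdtox tpf --out tpf.tsv                 # packaged chemistry tables
amdtox speciate --chem water.tsv --ph 4.5 --out speciation.tsv
amdtox catalog fixtures --out catalog/
amdtox simulate --outdir sim/ --seed 1
amdtox profile --genes sim/genes.tsv --dna sim/dna_counts.tsv \
               --rna sim/rna_counts.tsv --outdir profiles/
```

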