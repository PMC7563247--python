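# Methods

This note documents the models, defaults and numerical choices behind
`amdtox`. The package quantifies metal toxicity in a stratified acidic pit
lake and profiles microbial metal-resistance genes (MRGs) from
metagenome/metatranscriptome count tables. All empirical statements below are
computed by the test suite or `scripts/acceptance.py`; nothing is quoted from
external runs.

## Toxic potency factors

For each element with a chronic USEPA water-quality criterion (NAWQC-CCCF, in
µg/L, no hardness adjustment), two dimensionless indices are computed per
lake layer:

* **TPF-1** = dissolved concentration / standard. Speciation-blind.
* **TPF-2** = free-cation activity / standard, with the activity taken as
  concentration × free-ion fraction × γ and γ defaulting to 1. With γ = 1
  this reconstructs every published TPF-2 from the published free-ion
  percentages, which indicates the original calculation used the molar
  free-ion share as the "activity"; γ is retained as an explicit hook for a
  stricter thermodynamic definition (note γ ≤ 1 implies TPF-2 ≤ TPF-1).

Manganese has no NAWQC criterion; its standard is derived as the Fe standard
divided by 6 (the ratio of the corresponding drinking-water standards). The
*unrounded* quotient (166.67 µg/L) is used in computations; the displayed
value is 167. This distinction matters: the deep-layer Mn TPF-1 is
116000/166.67 = 696 → 700 at two significant figures, whereas dividing by the
rounded 167 would report 690.

Arsenic is an oxyanion (As(V)) or neutral acid (As(III)) at lake pH, not a
cation, so it carries no TPF-2.

Reported TPFs are rounded to two significant figures, halves away from zero.
The source table rounds inconsistently (two significant figures for large
values, whole numbers for small ones), so golden-value comparisons accept
agreement either within 5% relative or to within half a unit when the
reference is printed as a whole number.

Rankings sort elements by descending TPF with alphabetical tie-breaks.
Separators between adjacent elements: `~` when the symmetric relative
difference is ≤ 0.05, `>>` when the ratio is ≥ 5, else `>`. These thresholds
are configurable heuristics; no single threshold reproduces every published
tie mark, so only the element order (all six published rankings) and the
dominance mark after Fe(II) in the deep layer are treated as reproducible.

## Equilibrium speciation

The speciation solver approximates the geochemical-modelling step that
produced the published free-ion percentages. The model:

* **Components** — total dissolved concentrations (mol/L, converted from
  µg/L via molar masses) for the metals, sulfate and chloride. Redox couples
  (Fe(II)/Fe(III), As(III)/As(V)) are *inputs*, as measured; no redox
  equilibria, mineral saturation or surface complexation are solved.
* **pH fixed** — proton activity is 10^−pH; no proton mass balance or charge
  balance. This matches how measured pH is used in practice.
* **Mass action** — each complex satisfies
  a_complex = K · Π a_component^ν on activities. The shipped default set
  (`data/thermo_default.yaml`) covers metal–sulfate 1:1 and 1:2 and
  metal–chloride 1:1 complexes, bisulfate, and the As(III)/As(V) protonation
  states. The log K values are standard MINTEQ/WATEQ-family constants at
  25 °C and are editable; they are **not** site-specific or drawn from any
  single study.
* **Activity model** — Davies equation, log10 γ = −A z²(√I/(1+√I) − 0.3 I)
  with A fixed at 0.509 (25 °C). Lake temperatures (12.5–18.3 °C) shift A by
  under 2%, which is negligible against the uncertainty in the constants.
  Molarity stands in for molality (dilute approximation). Ionic strength and
  all γ are recomputed from the current species distribution every iteration,
  so the converged solution is self-consistent.
* **Solver** — damped multiplicative fixed-point iteration on the free
  component concentrations: each free concentration is rescaled by
  (total/implied)^0.5 per sweep. This is robust and unconditionally positive
  for the small component sets used here, where a full Newton scheme would
  add complexity without need. Defaults: damping 0.5, tolerance 10⁻¹² on the
  relative mass-balance residual (tighter than the 10⁻⁸ guarantee so
  derived fractions are accurate to ~10⁻¹⁰), max 1000 iterations;
  non-convergence raises an error carrying the worst residual.

Verification: for any single-complex system the solver matches the closed
form quadratic to 10⁻¹⁰ relative; mass balance holds to 10⁻⁸ on the full
three-layer chemistry; γ → 1 as I → 0 and decreases monotonically for
I ≤ 0.3; adding ligand never increases a free fraction.

**Known limitation** — the published free-ion percentages came from a
PHREEQC run whose thermodynamic database is not identified. With the shipped
constants the deep-layer free Fe²⁺ fraction computes near 50%, below the
published 76.4%; at ionic strength ~0.25 mol/L the result is sensitive to
both the FeSO₄ association constant and the activity model. The package
therefore does not promise to reproduce the published speciation
percentages; the published percentages themselves are shipped as a fixture
and used directly for TPF-2. Only a broad plausibility interval is asserted
for the computed fraction.

## MRG catalog

The catalog maps KEGG Orthology identifiers (strictly validated as
`K#####`) to resistance mechanisms — Export, Import, Biochemical
Transformation, Regulation, Intracellular Accumulation, Extracellular
Sequestration — with metals, specificity, provenance and (for EPS markers) a
biosynthesis/assembly pathway. Two fixtures ship with the package: 48
metal-specific marker KOs for Al, Cu, Fe, Mn, Zn, Ni and As, and 16 KOs for
exopolysaccharide synthesis (glycosyltransferases), assembly and transport
(Wzx-Wzy dependent and ABC-transport pathways) used as a proxy for
extracellular metal sequestration. Merged they give 64 unique KOs.

Rebuilding a full catalog from a BacMet export is implemented as a
deterministic pipeline: best above-threshold KO annotation per gene with
E-value < 10⁻⁴ (exclusive); aggregation of records sharing a KO (set union
of compounds and symbols); down-selection to rows whose compounds intersect
a configurable metal/metalloid vocabulary **and** whose curator flag is
true; merge across sources with BacMet provenance winning duplicate KOs and
mechanism conflicts raising an error. The curator flag externalizes the
manual "gene description matches KO description" judgment — no text-matching
heuristic can reproduce expert curation, so the pipeline makes that judgment
an explicit, auditable input. The BacMet database itself is not bundled;
users supply their own export.

## Quantification

TPM per gene and sample: rate_g = count_g / length_g, TPM_g = 10⁶ ·
rate_g / Σ rates. The denominator includes **all** predicted genes,
annotated or not, so KO-level profiles sum to less than 10⁶ whenever
unannotated genes exist. All-zero samples produce all-zero columns, not NaN.
Counts may be integers or non-negative reals (fractional multi-mapping).

KO functional profiles sum member-gene TPM. Expression per KO is
RNA_TPM / DNA_TPM on the outer join of the two KO universes: zero DNA makes
the ratio *missing* (a zero denominator carries no information — it is never
infinity, and dropping it as zero would fabricate repression); zero RNA over
positive DNA is a true 0. Replicates are kept as separate samples and never
silently averaged.

The MRG-annotated share of a gene set is reported with the number of
KO-annotated genes as the default denominator (the alternative, all
predicted genes, is exposed as an option since the statistic is ambiguous in
informal usage). Domain × mechanism rollups sum catalog-member gene TPM and
conserve the MRG-subset total per sample. Expression-versus-concentration
trends report only the sign of the OLS slope (threshold 10⁻¹² for "flat");
no significance is implied.

## MAG selection and profiling

* MIMAG tiers: medium requires completeness ≥ 50% and contamination < 10%;
  contamination ≥ 10% fails; the high tier additionally requires
  completeness ≥ 90%, contamination < 5% **and** rRNA/tRNA evidence, without
  which a genome is capped at medium. Applied to the 13 packaged deep-layer
  genomes this yields medium for all 13.
* ANI dereplication is greedy in descending score
  (completeness − 5 × contamination, a documented simplification of dRep's
  scoring adequate for rule testing; ties broken by MAG id so the result is
  order-independent). A candidate is kept iff its ANI to every kept
  representative is < 96.5%.
* MAGs with fewer than 500 mapped mRNA reads are excluded from expression
  profiling; exactly 500 is kept ("fewer than" dictates strict less-than).
  The published table does not include per-MAG mRNA counts, so this filter
  is validated on synthetic plants only.
* Per-MAG profiles compute TPM **within** each MAG (denominator = that MAG's
  genes only), then aggregate by KO, restrict to the catalog and form
  RNA:DNA ratios. Within-MAG normalization makes rows comparable across
  genomes of different sizes; each MAG row of the gene-TPM matrix sums to
  10⁶ over that MAG's KOs when all its genes are annotated.

## Synthetic data

The generator emulates the *tables* a mapping pipeline produces — gene
catalogs, DNA/RNA count matrices, water chemistry, MAG metadata with an ANI
matrix — never sequences, reads, assemblies or phylogenetic structure.

Count model: gene g gets a log-normal relative abundance a_g (log-sd 0.7, a
moderately heavy-tailed community); the expected DNA count is
depth · a_g·len_g / Σ(a·len) and the expected RNA count carries an extra
per-KO multiplier m. Counts are negative-binomial with size parameter
(dispersion) 10 — mild technical overdispersion of mapped counts, with
`inf` giving the Poisson limit. Because DNA and RNA share a_g, the planted
KO-level TPM ratio is exact in expectation: m_ko · Σ(a·len)/Σ(a·len·m), and
that normalized value is what the ground-truth table records.

Defaults mirror the study conditions: 10,000 genes, 2 replicate samples, a
deep-layer-like domain mix (50% Bacteria, 30% Archaea, 20% Eukaryota), 50%
of genes KO-annotated, 3% of annotated genes drawn from the MRG catalog,
10⁷ expected mapped reads per sample, gene lengths log-normal around
~900 bp. Gene lengths are floored at 100 bp.

All randomness flows through a counter-based (Philox) generator keyed by
(seed, per-operation stream constant): identical configurations give
byte-identical outputs and each operation is independently reproducible.

What passing tests show — and do not show: recovery of planted expression
multipliers (median relative error < 10% at 200 KOs, 10⁴ genes, 10⁷ reads)
demonstrates that the TPM/aggregation/ratio chain is unbiased and correctly
normalized under this noise model. Real metagenomes add mapping ambiguity,
contaminant reads, strain-level coverage variation and compositional
effects that the generator does not emulate; results on real data inherit
those caveats.

## Problem sizes

The shipped tests and the acceptance script run the chemistry/toxicity chain
on the full three-layer table (25 element×layer records), the speciation
solver on systems of up to 12 components and 20 complexes, and simulations
of 10⁴ genes × 1–2 samples at 10⁷ reads — sizes chosen so the complete suite
executes in seconds while every statistical check retains comfortable power.
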