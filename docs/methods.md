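# Methods

This document records the modelling assumptions, parameter choices and
numerical conventions behind `bgcflux`, including everything that is an
implementation choice rather than a community standard.

## 1. Input model and parsing

A cluster is one annotated region GenBank document. The parser consumes
three feature types:

* `region` — `product` qualifiers name the cluster classes; supported
  classes are `NRPS`, `T1PKS` and `transAT-PKS` (anything else is kept as
  `other` and rejected at classification time);
* `CDS` — genes, identified by `locus_tag`, with `gene_kind =
  biosynthetic` marking core genes and `gene_functions` carrying smCOG
  codes (`SMCOG<4 digits>`);
* `aSDomain` — functional domains, matched to their gene by `locus_tag`
  (falling back to coordinate containment), with `specificity` entries of
  the form `consensus: <code>` and `KR activity: active|inactive`.

Coordinates are 0-based half-open internally (Biopython's convention);
GenBank's 1-based inclusive form exists only at the I/O boundary. On
minus-strand genes, translation order is the reverse of genomic order;
domains are always stored in translation order. Unknown domain names are
preserved as `UNKNOWN` and logged (strict mode raises instead).
`aSModule` features, when present, are honored as annotated modules;
everything else is grouped by the assembly step.

## 2. Module assembly

Domains not covered by annotated modules are grouped per gene, split before
every condensation-type domain (C, Cy, KS). Cross-gene **bridging modules**
are merged when a gene ends in a carrier-less KS group and the next gene
opens with a carrier-bearing, KS-less group. A group qualifies as a module
if it contains condensation or release chemistry, or a carrier plus load
chemistry; leftovers are logged as non-modular. Release-only stubs (bare
TE/TD) are folded into the preceding module.

Activity rules, in order:

* **DHD** (trans-AT only): KS ending one gene + DH,ACP opening the next →
  module inactive.
* **oMT in a PKS module** → module inactive (such KS domains are
  non-elongating); oMT in NRPS modules is an ordinary methylation.
* An explicitly `inactive` KS annotation → inactive.
* Minimal active sets: cis-PKS `KS+AT+carrier`; trans-AT `KS+carrier`
  (the AT acts in trans); NRPS `(C|Cy)+(A|CAL)+carrier`.
* **KR cascade**: an absent or inactive KR silences DH and ER (they act on
  the KR product); an unannotated KR defaults to active. ER additionally
  requires DH.
* **Truncation**: the chain is released at the first TE/TD-containing
  module; later modules emit no reactions.

Load-module classification for the first module: GNAT → GNAT load; FkbH →
FkbH load; CAL without KS → CAL load; KS present → no load module (the
module is a full extender); AT+carrier → standard PKS load; A with C/Cy →
fatty-acyl-acylated NRPS load (the paper-style "C in the initiating module"
rule); A alone → standard NRPS load. With no load module the first active
extender's monomer starts the chain without a condensation.

## 3. Reaction calculus

Domain templates are listed in the README. Additional conventions:

* The carrier protein (ACP/PCP) is one shared pool species per cluster
  (`<cluster>_carrier`); loads consume it, condensations and release return
  it, so its net balance is exactly zero.
* Backbone intermediates `<cluster>_chain_n` are lumped pseudo-metabolites;
  elemental balance is asserted only for cofactors and small molecules.
  In-module tailoring produces `_v<k>` variants without advancing `n`.
* Extender selection: PKS codes `mal`, `mmal`, `emal`, `mxmal` map to
  malonyl-, methylmalonyl-, ethylmalonyl-CoA and methoxymalonyl-ACP;
  NRPS codes map to the 20 proteinogenic amino acids plus the rare monomers
  below. Non-specific codes (`X`, `NRP`, `PK`, …) fall back to a generic
  amino acid (NRPS) or malonyl-CoA (PKS); the generic amino acid is fed by
  20 pseudo-reactions `aa → generic_aa`.
* **Methoxymalonyl-ACP gating** *(implementer-defined)*: the `mxmal` route
  (1,3-bisphosphoglycerate → glyceryl-carrier → methoxymalonyl-ACP,
  delivered carrier-bound so no AT load is emitted) requires a cluster gene
  with smCOG 1256; otherwise the module falls back to malonyl-CoA with a
  warning.
* **Rare-monomer subpathways** *(implementer-defined, lumped)*: hpg, bht
  and dhpg from tyrosine; 2-aminobutyrate from threonine; pipecolate from
  lysine; ahba via a lumped aminoshikimate route. The stoichiometries are
  plausible lumped forms, not curated enzymology.
* **smCOG-triggered tailoring** *(implementer-defined)*: after release,
  genes with smCOG 1062/1256/1084 add an NDP-hexose glycosylation, 1109 a
  C5N-unit incorporation (acetyl-CoA + glycine + ATP), and 1002 an
  ATP-dependent ligation, applied in gene genomic order to successive
  `product_t<k>` species.
* Products without TE/TD are released by an implicit hydrolysis with a
  warning.

Validation asserts: every chain intermediate produced and consumed exactly
once, the final product never consumed, no dead ends, zero net carrier.
The cofactor audit checks the identities ATP = #A-loads, SAM = SAH =
#active MTs, NADPH = #KR + #ER (+1 per TD), CO₂ = #KS condensations, with
GNAT/precursor/tailoring contributions tallied separately.

## 4. GEM integration

Reconstructions are inserted as a block of irreversible reactions
(bounds 0–1000 mmol·gDW⁻¹·h⁻¹) prefixed with the cluster id, plus one
demand reaction `DM_<cluster>_product` used as the production objective.
Metabolites resolve against the reference model by exact id
(`<base>_<compartment>`), then a curated synonym table, then creation as a
new cytosolic species. Insertion is a pure function (the input model is
untouched) and non-destructive (wild-type maximum growth unchanged within
1e-9 relative). Id collisions raise instead of overwriting.

## 5. Constraint-based analysis

Parameters (all exposed as function/CLI arguments):

| parameter | default | unit |
|---|---|---|
| glucose uptake limit | 0.8 | mmol·gDW⁻¹·h⁻¹ |
| unconstrained uptakes | ammonium, phosphate, sulphate, oxygen, water, protons | — |
| production growth fraction | 0.9 | — |
| knockout growth fixation | 0.999 | — |
| essentiality floor | 0.5 × wild-type growth | — |
| reporting threshold | 0.1 % production gain | — |
| default flux bound | 1000 | mmol·gDW⁻¹·h⁻¹ |

A reaction knockout sets both bounds to zero. Mutant production is
evaluated with growth *fixed* (lb = ub) at 99.9 % of the mutant optimum and
compared against the wild-type reference computed by the same fixation on
the unperturbed model. Infeasible mutant LPs are treated as essential and
skipped. Only objective values are contracted (flux vectors are
solver-dependent); repeated solves agree to 1e-6 relative. The test suite
checks all objective values against an independent
`scipy.optimize.linprog` (HiGHS) implementation that shares no solver code
with the cobrapy/GLPK path.

## 6. Synthetic fixtures

The generator emits exactly the qualifier vocabulary the parser documents
(one shared dialect table), with deterministic layout (300 bp per domain,
100 bp gaps, fixed record date), so `spec → file → parse` is the identity
on all spec fields and files are byte-identical across runs. The random
grammar produces NRPS / T1PKS / trans-AT / hybrid clusters with all load
variants, KR activity annotations, oMT-inactivated modules, cross-gene
bridging and DHD splits, TE/TD terminators, minus-strand genes and
free-standing trailing domains — together with the *expected* assembly
outcome derived from the grammar itself, which serves as the round-trip
oracle.

It does **not** emulate full antiSMASH records: no sequence realism, no
HTML/knownclusterblast payloads, no PFAM coordinates, no multi-region
files, and domain coordinates are equispaced rather than biological.

## 7. The toy reference model

34 reactions, one cytosolic compartment, small-rational coefficients:
lumped glycolysis (2 ATP + 2 NADH + 2 pyruvate per glucose), pyruvate
dehydrogenase, lumped TCA (1 ATP + 3 NADH per acetyl-CoA), oxidative
phosphorylation at P/O = 2, a reversible transhydrogenase (making NADPH and
NADH interchangeable 1:1), six amino acids, malonyl-/methylmalonyl-CoA,
SAM regeneration, a fatty-acyl pool, an NDP-hexose donor, and a
non-forced ATP dissipation reaction.

The engineered knockout target works by by-product detoxification:
biomass co-produces 1 `byp`, which must be condensed with a glycolytic
side-product `glx` (spilled at 1/4 per glucose; free route `BYPT`, no gene)
or drained at the cost of one acetyl-CoA (`BYPD`, gene `g_byp`). Because
the free capacity is stoichiometrically coupled to glucose flux rather than
a fixed bound, the model stays homogeneous (doubling glucose doubles
growth) and the all-zero flux vector remains feasible on empty media.

Hand derivation with glucose-equivalent accounting (24 ATP per fully
oxidized glucose): growth costs c₀ = 27/8 glucose per biomass unit, excess
`byp` disposal d = 7/24 glucose, and the demo gly-ala-ser tripeptide costs
q = 11/8 glucose per unit. With glucose G = 0.8 and spill ratio σ = 1/4:

* wild-type growth μ* = G(1 + dσ)/(c₀ + d) = **103/440** ≈ 0.23409 h⁻¹
  (at the optimum the free route saturates and `BYPD` carries the excess);
* production at 90 % growth = (G − 0.9 G(1 + dσ) + dσG)/q = **103/1650**
  ≈ 0.06242;
* knocking out `g_byp` caps growth at σG = **1/5**; at 99.9 % fixation the
  mutant's product rate is (G − 0.999 c₀ σG)/q = 0.0914, against a
  wild-type reference of 0.001·G(1 + dσ)/q, giving a relative gain of
  exactly **14978/103** ≈ 145.42.

All three values are asserted in the tests at 1e-9 relative against the LP
solver. Other gene-annotated reactions are either essential (skipped by the
50 % floor) or growth-neutral (gain ≈ 0), so `BYPD` is the unique
candidate.

## 8. Limitations

* Chain intermediates are lumped: no stereochemistry, cyclization pattern
  or elemental formula is tracked for the product.
* One reconstruction per region; multi-product clusters and iterative
  modules are out of scope, as are multi-reaction knockouts,
  over-expression and regulatory effects.
* Rare-monomer and tailoring stoichiometries are documented lumped guesses
  (flagged above), adequate for flux accounting but not for mechanistic
  claims.
* Collinearity is assumed: modules act in genomic/translation order.
* Problem sizes are desk-scale by design (toy model ≤ 40 reactions,
  clusters of 1–8 genes); the code paths are the same ones a genome-scale
  model would exercise, and runtimes in the test suite are seconds.
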