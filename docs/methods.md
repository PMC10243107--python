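# Methods

## Problem and data model

Metaproteomic quantification tables come in three levels — proteins or
peptides with MS1-based intensity/area values, or peptide-spectrum matches
(PSMs) whose per-sample counts serve as a spectral-counting abundance
proxy. All three land in one in-memory container, `QuantTable`: a features
× samples float matrix plus per-feature metadata (canonical sequence,
master protein accessions, Confidence / Quan Info / Marker / Description
text columns). Sample identity comes from the abundance column headers (PD
dialect), the caller (generic dialect), or the mzTab
ms_run → assay → study_variable declarations (PSM rows carry their run's
sample label).

Missing values are NaN everywhere and are never conflated with zero: an
empty cell reads as missing, a written `0` reads as zero, and
zero-replacement is an explicit opt-in step that additionally marks the
table so that downstream feature counting does not treat substituted zeros
as measurements.

## Sequence canonicalization

Annotation joins key on the bare peptide: bracketed flanking residues
(`[K].PEPTIDE.[R]`), bracketed/parenthesized modification annotations and
lowercase modification tags are removed and only A–Z is kept. Vendor
notation for modifications varies, so this is a package convention; it is
applied identically to quantification and annotation inputs so the join
key is consistent by construction. An optional I→L mapping on both sides of
the taxonomy join mirrors the "equate I and L" option of
lowest-common-ancestor peptide annotation tools; it is off by default.

## Pipeline order

Stages always run in this order: read → metadata filters → valid-value
filter → PSM collapse (PSM input) → zero replacement → renormalization →
taxonomy/function joins → aggregation → KEGG name enrichment → export →
sample rename/reorder. The order is semantically load-bearing in one
place: zeros introduced by replacement would count as "valid" if the
valid-value filter ran after it, so the filter always runs first. Metadata
filters and the valid-value filter commute (both are pure row subsets),
which the tests check.

The valid-value percentage converts to a count with ceiling ("at least
X%"). Renormalization scales each sample column so its sum of non-missing
values equals T = mean of per-sample sums; any constant T yields
proportional columns, and the mean keeps outputs on the input scale.
A sample with no positive value is an error, not a silent skip.

PSM collapse counts PSM rows per canonical sequence per sample (0, not
missing, when absent), conserving the total row count exactly; master
accessions are unioned in first-seen order, and per-group text metadata
keeps the first non-empty value seen.

## Annotation semantics

Taxonomy is peptide-keyed with the rank vocabulary lca, superkingdom,
kingdom (accepted when present), phylum, class, order, family, genus,
species. Ranks below a peptide's LCA are missing; each rank column is
treated independently — no lineage fill-down, so a genus-only annotation
contributes to family-level "unassigned" rather than being promoted.

Function is either peptide-keyed or propagated from master proteins: with
several master accessions a feature receives the deduplicated union of
their category sets, since protein grouping gives no principled way to
prefer one master's annotation. eggNOG-mapper conventions are honored: `-`
is empty, COG category cells split into single letters, other categories
split on commas, `ko:` prefixes are stripped (configurable), and KEGG
pathway cells that list both `koNNNNN` and `mapNNNNN` forms keep only the
`ko` form to avoid double counting (a map-only entry is kept; the
deduplication is configurable off). Duplicate annotation rows for one key
keep the first and log a warning.

Unassigned handling is a single switch: `empty` leaves unmatched cells
missing (those features are then excluded from aggregation), `labeled`
writes the literal `unassigned` into every missing cell — including ranks
above a matched peptide's LCA — so aggregated tables partition the whole
input.

KEGG id → name enrichment is offline-first through a two-column tsv
mapping; ids without a name get empty text plus a warning count. An online
mode queries the public KEGG REST list endpoints and caches into the
mapping file; it is off by default and never used by the test suite. The
name column is inserted directly after its key column and is headed
"Pathway name" / "KO name" / "Module name" / "Reaction name".

## Aggregation

All three aggregations share one expand → group → sum core. A feature with
k codes in the grouping category contributes its full abundance to each of
the k groups; this double counting across groups is deliberate (summing a
pathway's abundance should not depend on how many other pathways a protein
participates in) and documented; an even fractional split is available per
call. Missing abundances contribute nothing; a group with no contributor
in a sample gets sum 0, and the companion counts table disambiguates true
zeros (counts count non-missing values, excluding substituted zeros).
Group rows are sorted lexicographically by key so output is deterministic
and invariant to input row order. Taxon-specific-function keys are emitted
as two adjacent columns named by the rank and the category verbatim
(e.g. `family`, `KEGG_Pathway`).

Text exports are tab-separated UTF-8 with `.` decimals and full float
precision (lossless round trip); xlsx is available throughout. Sample
columns can be renamed and reordered afterwards, on in-memory tables or on
previously written files; the reorder must be a permutation of the sample
columns and key columns are untouched.

## Synthetic scenarios

The generator emulates a human gut metaproteome experiment: 30 proteins /
60 peptides / 4 samples / 300 PSM rows by default, lineages drawn from a
fixed pool of eight gut bacterial families plus a human fraction (20%)
carrying a `HumanDB` marker, microbial rows carrying the
`MGDBinhouse` / `MGDBpublic` / `MGDBinhouse;MGDBpublic` markers,
85% High confidence, and an 8% "No Quan Values" quan-info fraction whose
rows are all-missing. Abundances are log-normal (meanlog 10, sdlog 1.5,
the MS1 intensity scale) with 15% missing completely at random; values are
rounded to their serialized precision at generation time so every file
dialect carries exactly the numbers the truth tables were computed from.
Annotation coverage is 90% for both taxonomy (Unipept-style file) and
function (eggNOG-style file), so unassigned handling is always exercised;
30% of annotated proteins carry 2–3 codes per category and 15% of peptides
have two master proteins. Truth tables are computed inside the generator
by direct naive summation over its own records — independent of the
package's aggregation core, which the test suite additionally checks
against a second brute-force reference written in the tests.

One format asymmetry is inherent: mzTab 1.0 PEP rows carry a single
accession, so a peptide with two master proteins cannot be serialized
losslessly to mzTab. The cross-dialect equivalence checks therefore draw
their scenarios with single masters (the population all three dialects
represent identically); multi-master behaviour is covered through the PD
dialect.

What the generator does **not** emulate: realistic taxonomic abundance
distributions, intensity-dependent (non-MCAR) missingness, shared peptides
between unrelated lineages, retention times or spectra. Passing tests
therefore demonstrate the correctness of parsing, joining and aggregation
arithmetic on structurally faithful inputs, not robustness to every
real-data pathology (e.g. malformed vendor exports beyond the errors
tested).

## Numerical and design choices

- Abundance cells accept only `.` decimals; thousands separators are
  rejected with the row index, for determinism across locales.
- Renormalization and aggregation agreement is asserted at 1e-9 relative;
  observed errors are at the float64 epsilon level.
- Determinism: one integer seed drives a scenario end to end; text outputs
  are byte-identical across runs and xlsx determinism is achieved by
  pinning workbook timestamps.
- Problem sizes in the test suite and acceptance script (100 scenarios of
  20 peptides × 3 samples for the oracle sweep; the default 60-peptide
  scenario elsewhere) were chosen so the whole battery runs in seconds
  while every code path — multi-valued expansion, unassigned handling,
  missing data, both unassigned modes — occurs many times per sweep.
- Protein- and peptide-based functional inputs are treated as mutually
  exclusive per run.
- The GUI-free surface is deliberate: functions are the interface, the CLI
  is a thin driver, logging goes to stderr and outputs only to files.

## Known limitations

- mzTab-M 2.0, mzIdentML and vendor binary formats are out of scope.
- No imputation beyond zero replacement; no between-run peak matching.
- KEGG module completeness, GO graph operations and downstream statistics
  are deliberately left to dedicated tools.
- PD "Quan Info" vocabularies are version-dependent; filters are plain
  set-membership tests with no hardcoded vocabulary.
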