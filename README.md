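# metapept

**metapept** parses, filters, annotates and aggregates label-free
quantitative metaproteomic data. It is a headless library plus CLI for the
common chore between a database search and downstream statistics: you have
an identification/quantification table (proteins, peptides or PSMs, from a
Proteome Discoverer export, an mzTab 1.0 file, or any tabular file), a
per-peptide taxonomy table (Unipept-style lowest-common-ancestor export)
and a per-protein functional annotation table (eggNOG-mapper-style export
with COG/GO/EC/CAZy/KEGG columns), and you want one tidy matrix per
biological question — *taxon × sample*, *function × sample*, or
*taxon-specific function × sample* — ready for statistics.

## What it computes

For features *i* (peptides or proteins) with abundances *a*<sub>ij</sub> in
samples *j* and an annotation key *k(i)* (a taxon at a chosen rank, a
functional code in a chosen category, or the pair of both), the aggregated
abundance of group *g* is the plain sum over the features carrying that
annotation:

    A_gj = Σ_{i : k(i) ∋ g}  a_ij        (missing cells contribute nothing)

A feature with *k* codes in a functional category contributes its **full**
abundance to each of the *k* groups (a fractional split is available but
off by default). A companion counts table reports how many features
actually contributed a measured value per group and sample. Supporting
steps: metadata filters (Confidence / Quan Info / Marker keep-sets),
valid-value filters, optional zero replacement, total-sum renormalization
(each sample column is scaled so its sum equals the mean of the per-sample
sums, preserving within-sample ratios), PSM → per-peptide spectral
counting, I/L equating for taxonomy joins, and master-protein propagation
of functional annotations (union over a peptide's master accessions).

## Worked example

No real dataset is needed: the `fixtures` module writes a complete
synthetic gut-metaproteome scenario (PD-style xlsx/txt, mzTab, Unipept-style
csv/tsv, eggNOG-style tsv, an offline KEGG id→name mapping, and the
ground-truth tables it was generated from):

```sh
metapept fixtures --seed 7 --out demo/fx --walkthrough
```

Then run the documented workflow — keep High-confidence microbial peptides,
renormalize, join taxonomy and protein-based function, and quantify
family-specific KEGG pathways:

```sh
metapept run --config demo/run.yaml
```

with `demo/run.yaml`:

```yaml
input:    {path: demo/fx/pd_peptides.xlsx, format: pd, level: peptide}
filters:
  confidence_keep: [High]
  quan_info_keep: [Shared]
  marker_keep: [MGDBinhouse, MGDBpublic, "MGDBinhouse;MGDBpublic"]
  renormalize: true
taxonomy: {path: demo/fx/unipept.csv}
function: {path: demo/fx/eggnog.tsv, basis: protein}
unassigned_mode: labeled
aggregation:
  pairs: ["family:KEGG_Pathway"]
  retrieve_kegg_names: true
  emit_counts: true
kegg:     {mapping_path: demo/fx/kegg_names.tsv}
output:   {dir: demo/out, format: txt}
```

This writes `demo/out/family_KEGG_Pathway.txt`, which begins:

```
family          KEGG_Pathway  Pathway name                                 S1         S2        S3       S4
Bacteroidaceae  ko00020       Citrate cycle (TCA cycle)                    115394.36  56020.57  6967.32  7125.16
Bacteroidaceae  ko00250       Alanine, aspartate and glutamate metabolism  258613.03  351638.15 23112.66 10447.65
```

Each row is one microbial family × KEGG pathway pair; the sample columns
are the summed (renormalized) abundances of every filter-passing peptide
whose taxonomy resolves to that family and whose master protein(s) carry
that pathway. `family_KEGG_Pathway_counts.txt` holds the matching
contributing-peptide counts, and `run_report.json` records per-stage row
counts (here: 80 peptides read → 50 after the marker/confidence filters).
`metapept validate --config demo/run.yaml` checks a config without touching
any input.

## Library use

```python
import metapept as mp

qt = mp.read_pd_export("peptides.xlsx", "peptide")
qt = mp.apply_meta_filters(qt, mp.FilterSpec(confidence_keep={"High"}))
qt = mp.renormalize(qt)
at = mp.join_taxonomy(qt, mp.read_unipept("unipept.csv"), mode="labeled")
at = mp.join_function(at, mp.read_eggnog("eggnog.tsv"), basis="protein",
                      mode="labeled")
table = mp.aggregate_taxon_function(at, "family", "KEGG_Pathway")
mp.write_output(table, "family_pathways.tsv")
```

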