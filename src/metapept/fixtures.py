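"""Synthetic metaproteomic scenario generator with recorded ground truth.

Generates internally consistent Proteome Discoverer-style, mzTab,
Unipept-style and eggNOG-mapper-style files for a fictive gut-microbiome
experiment, together with truth tables computed by direct naive summation
inside the generator.  The full pipeline can therefore be exercised and
checked end to end without any real dataset.

Abundances are drawn log-normal (meanlog 10, sdlog 1.5) to mimic the MS1
intensity scale; missingness is completely at random.  Every quantity is
driven by a single integer seed: the same seed yields byte-identical files
and truth tables.
"""

from __future__ import annotations

import datetime
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import CATEGORIES, RANKS, UNASSIGNED
from .errors import ConfigurationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: microbial family lineages (superkingdom..species), gut-community flavored
LINEAGE_POOL = [
    ("Bacteria", "Bacillati", "Bacillota", "Clostridia", "Eubacteriales",
     "Lachnospiraceae", "Blautia", "Blautia obeum"),
    ("Bacteria", "Bacillati", "Bacillota", "Clostridia", "Eubacteriales",
     "Oscillospiraceae", "Faecalibacterium", "Faecalibacterium prausnitzii"),
    ("Bacteria", "Bacteroidati", "Bacteroidota", "Bacteroidia",
     "Bacteroidales", "Bacteroidaceae", "Bacteroides", "Bacteroides fragilis"),
    ("Bacteria", "Bacteroidati", "Bacteroidota", "Bacteroidia",
     "Bacteroidales", "Prevotellaceae", "Prevotella", "Prevotella copri"),
    ("Bacteria", "Pseudomonadati", "Pseudomonadota", "Gammaproteobacteria",
     "Enterobacterales", "Enterobacteriaceae", "Escherichia",
     "Escherichia coli"),
    ("Bacteria", "Bacillati", "Actinomycetota", "Actinomycetes",
     "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium",
     "Bifidobacterium longum"),
    ("Bacteria", "Bacillati", "Bacillota", "Bacilli", "Lactobacillales",
     "Lactobacillaceae", "Lactobacillus", "Lactobacillus gasseri"),
    ("Bacteria", "Fusobacteriati", "Fusobacteriota", "Fusobacteriia",
     "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium",
     "Fusobacterium nucleatum"),
]

HUMAN_LINEAGE = ("Eukaryota", "Metazoa", "Chordata", "Mammalia", "Primates",
                 "Hominidae", "Homo", "Homo sapiens")

LINEAGE_RANKS = ("superkingdom", "kingdom", "phylum", "class", "order",
                 "family", "genus", "species")

#: per-category functional code pools with human-readable names for the
#: KEGG categories (used to build the offline id->name mapping file)
KEGG_PATHWAYS = {
    "ko00010": "Glycolysis / Gluconeogenesis",
    "ko00020": "Citrate cycle (TCA cycle)",
    "ko00051": "Fructose and mannose metabolism",
    "ko00061": "Fatty acid biosynthesis",
    "ko00250": "Alanine, aspartate and glutamate metabolism",
    "ko00500": "Starch and sucrose metabolism",
    "ko00620": "Pyruvate metabolism",
    "ko00680": "Methane metabolism",
}
KEGG_KOS = {f"K{n:05d}": f"ortholog group K{n:05d}" for n in range(1, 13)}
KEGG_MODULES = {f"M{n:05d}": f"module M{n:05d}" for n in range(1, 7)}
KEGG_REACTIONS = {f"R{n:05d}": f"reaction R{n:05d}" for n in range(1, 9)}

FUNCTION_POOL = {
    "COG_category": list("CEGJKMP"),
    "GOs": [f"GO:{n:07d}" for n in (8150, 3824, 5975, 6096, 6099, 16310)],
    "EC": ["1.1.1.1", "2.7.1.2", "2.7.1.11", "4.1.2.13", "1.2.1.12", "5.3.1.1"],
    "CAZy": ["GH13", "GH2", "GT4", "GH31", "CBM48"],
    "KEGG_ko": sorted(KEGG_KOS),
    "KEGG_Pathway": sorted(KEGG_PATHWAYS),
    "KEGG_Module": sorted(KEGG_MODULES),
    "KEGG_Reaction": sorted(KEGG_REACTIONS),
}

MICROBIAL_MARKERS = ("MGDBinhouse", "MGDBpublic", "MGDBinhouse;MGDBpublic")
HUMAN_MARKER = "HumanDB"


@dataclass
class ScenarioParams:
    """Knobs of the synthetic experiment (defaults are the study conditions)."""

    seed: int = 0
    n_proteins: int = 30
    n_peptides: int = 60
    n_samples: int = 4
    n_psm_rows: int = 300
    missing_rate: float = 0.15
    multi_annotation_rate: float = 0.3
    multi_master_rate: float = 0.15
    human_fraction: float = 0.2
    tax_coverage: float = 0.9      # fraction of peptides in the Unipept file
    func_coverage: float = 0.9     # fraction of proteins in the eggNOG file
    abundance_meanlog: float = 10.0
    abundance_sdlog: float = 1.5

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_peptides", "n_samples", "n_psm_rows"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("missing_rate", "multi_annotation_rate",
                     "multi_master_rate", "human_fraction",
                     "tax_coverage", "func_coverage"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticScenario:
    """A generated experiment plus its ground-truth aggregations.

    ``truth`` maps a descriptive key (e.g. ``"pair_family_KEGG_Pathway"``)
    to a DataFrame with the key columns first and one column per sample,
    computed by the generator's own naive summation.
    """

    params: ScenarioParams
    samples: list
    proteins: list      # dicts: accession, lineage, functions, annotated
    peptides: list      # dicts: sequence, masters, marker, ..., abundances
    psms: list          # (sequence, sample) tuples
    kegg_mapping: dict
    truth: dict = field(default_factory=dict)


# -- generation ----------------------------------------------------------

def _random_peptide(rng: np.random.Generator, taken: set) -> str:
    while True:
        length = int(rng.integers(8, 15))
        seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))
        seq += "KR"[int(rng.integers(0, 2))]  # tryptic-looking terminus
        if seq not in taken:
            taken.add(seq)
            return seq


def _draw_functions(rng: np.random.Generator, multi_rate: float) -> dict:
    functions = {}
    for category, pool in FUNCTION_POOL.items():
        n = 1 + (int(rng.integers(1, 3)) if rng.random() < multi_rate else 0)
        picks = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
        functions[category] = frozenset(pool[i] for i in picks)
    return functions


def generate_scenario(params: ScenarioParams | None = None, **kwargs
                      ) -> SyntheticScenario:
    """Draw a full synthetic experiment and compute its truth tables.

    Peptides map to existing master proteins; lineages come from a fixed
    gut-community pool (plus a human fraction); abundances are log-normal
    with MCAR missingness; PSM rows are random (peptide, sample) draws.
    """
    if params is None:
        params = ScenarioParams(**kwargs)
    elif kwargs:
        raise ConfigurationError("pass either params or keyword overrides")
    rng = np.random.default_rng(params.seed)
    samples = [f"S{i + 1}" for i in range(params.n_samples)]

    proteins = []
    for i in range(params.n_proteins):
        human = rng.random() < params.human_fraction
        lineage_values = HUMAN_LINEAGE if human else \
            LINEAGE_POOL[int(rng.integers(0, len(LINEAGE_POOL)))]
        proteins.append({
            "accession": f"P{i + 1:05d}",
            "human": human,
            "lineage": dict(zip(LINEAGE_RANKS, lineage_values)),
            "functions": _draw_functions(rng, params.multi_annotation_rate),
            "annotated": rng.random() < params.func_coverage,
        })

    taken: set = set()
    peptides = []
    for _ in range(params.n_peptides):
        first = proteins[int(rng.integers(0, params.n_proteins))]
        masters = [first]
        if rng.random() < params.multi_master_rate and params.n_proteins > 1:
            second = proteins[int(rng.integers(0, params.n_proteins))]
            if second["accession"] != first["accession"] \
                    and second["human"] == first["human"]:
                masters.append(second)
        human = first["human"]
        # LCA depth: how far down the lineage Unipept could resolve
        depth = int(rng.integers(2, len(LINEAGE_RANKS) + 1))
        lineage = {r: (first["lineage"][r] if j < depth else None)
                   for j, r in enumerate(LINEAGE_RANKS)}
        lca = [v for v in lineage.values() if v is not None][-1]
        abundances = []
        quan_info = "Shared" if rng.random() < 0.92 else "No Quan Values"
        for _j in range(params.n_samples):
            if quan_info == "No Quan Values" or rng.random() < params.missing_rate:
                abundances.append(None)
            else:
                drawn = float(rng.lognormal(
                    params.abundance_meanlog, params.abundance_sdlog))
                # round to the serialized precision so every dialect carries
                # exactly the value the truth tables were computed from
                abundances.append(float(f"{drawn:.10g}"))
        peptides.append({
            "sequence": _random_peptide(rng, taken),
            "masters": [m["accession"] for m in masters],
            "human": human,
            "marker": HUMAN_MARKER if human else
                MICROBIAL_MARKERS[int(rng.integers(0, 3))],
            "confidence": "High" if rng.random() < 0.85 else "Medium",
            "quan_info": quan_info,
            "lineage": lineage,
            "lca": lca,
            "tax_annotated": rng.random() < params.tax_coverage,
            "abundances": abundances,
        })

    by_sequence = {p["sequence"]: p for p in peptides}
    psms = []
    for _ in range(params.n_psm_rows):
        seq = peptides[int(rng.integers(0, params.n_peptides))]["sequence"]
        psms.append((seq, samples[int(rng.integers(0, params.n_samples))]))

    mapping = {**KEGG_PATHWAYS, **KEGG_KOS, **KEGG_MODULES, **KEGG_REACTIONS}
    scenario = SyntheticScenario(params=params, samples=samples,
                                 proteins=proteins, peptides=peptides,
                                 psms=psms, kegg_mapping=mapping)
    _compute_truth(scenario)
    return scenario


# -- truth (naive summation, independent of the aggregate module) --------

def _peptide_tax_value(peptide: dict, rank: str) -> str | None:
    if not peptide["tax_annotated"]:
        return None
    if rank == "lca":
        return peptide["lca"]
    return peptide["lineage"].get(rank)


def _peptide_func_codes(peptide: dict, category: str,
                        proteins_by_acc: dict) -> frozenset:
    codes: set = set()
    for acc in peptide["masters"]:
        protein = proteins_by_acc[acc]
        if protein["annotated"]:
            codes |= protein["functions"][category]
    return frozenset(codes)


def _naive_table(rows: dict, counts: dict, key_names: list, samples: list,
                 n: int) -> pd.DataFrame:
    ordered = sorted(rows)
    data = []
    for key in ordered:
        record = dict(zip(key_names, key))
        for j, s in enumerate(samples):
            record[s] = rows[key][j]
            record[f"n_{s}"] = counts[key][j]
        data.append(record)
    columns = key_names + [c for s in samples for c in (s, f"n_{s}")]
    return pd.DataFrame(data, columns=columns)


def _truth_aggregate(peptides: list, proteins: list, samples: list,
                     rank: str | None, category: str | None,
                     matrix_key: str = "abundances") -> pd.DataFrame:
    """Brute-force expand -> group -> sum over the generator's records.

    Labeled unassigned mode: peptides missing an annotation fall in the
    ``unassigned`` group.  Sums skip missing cells; counts tally peptides
    with a non-missing value.
    """
    proteins_by_acc = {p["accession"]: p for p in proteins}
    sums: dict = defaultdict(lambda: [0.0] * len(samples))
    counts: dict = defaultdict(lambda: [0] * len(samples))
    for peptide in peptides:
        keys = [()]
        if rank is not None:
            value = _peptide_tax_value(peptide, rank) or UNASSIGNED
            keys = [k + (value,) for k in keys]
        if category is not None:
            codes = sorted(_peptide_func_codes(peptide, category,
                                               proteins_by_acc)) or [UNASSIGNED]
            keys = [k + (c,) for k in keys for c in codes]
        values = peptide[matrix_key]
        for key in keys:
            sums[key]  # a key is a group even if every abundance is missing
            counts[key]
            for j in range(len(samples)):
                if values[j] is not None:
                    sums[key][j] += values[j]
                    counts[key][j] += 1
    key_names = [n for n in (rank, category) if n is not None]
    return _naive_table(sums, counts, key_names, samples, len(samples))


def _compute_truth(sc: SyntheticScenario) -> None:
    """Default-pipeline truth: raw abundances, labeled mode, protein basis."""
    truth = {}
    truth["taxon_family"] = _truth_aggregate(
        sc.peptides, sc.proteins, sc.samples, "family", None)
    truth["taxon_genus"] = _truth_aggregate(
        sc.peptides, sc.proteins, sc.samples, "genus", None)
    truth["function_KEGG_Pathway"] = _truth_aggregate(
        sc.peptides, sc.proteins, sc.samples, None, "KEGG_Pathway")
    truth["function_KEGG_ko"] = _truth_aggregate(
        sc.peptides, sc.proteins, sc.samples, None, "KEGG_ko")
    truth["pair_family_KEGG_Pathway"] = _truth_aggregate(
        sc.peptides, sc.proteins, sc.samples, "family", "KEGG_Pathway")

    # per-peptide PSM counts
    counts: dict = defaultdict(lambda: [0] * len(sc.samples))
    sample_index = {s: j for j, s in enumerate(sc.samples)}
    for seq, sample in sc.psms:
        counts[(seq,)][sample_index[sample]] += 1
    truth["psm_counts"] = _naive_table(
        counts, counts, ["sequence"], sc.samples, len(sc.samples))

    sc.truth = truth


def walkthrough_truth(sc: SyntheticScenario) -> pd.DataFrame:
    """Truth for the documented walkthrough: confidence "High", microbial
    markers only, quan-info "Shared", total-sum renormalization, then the
    family x KEGG pathway aggregation (labeled mode)."""
    kept = [p for p in sc.peptides
            if p["confidence"] == "High"
            and p["marker"] in MICROBIAL_MARKERS
            and p["quan_info"] == "Shared"]
    n = len(sc.samples)
    sums = [0.0] * n
    for p in kept:
        for j in range(n):
            if p["abundances"][j] is not None:
                sums[j] += p["abundances"][j]
    if any(not s > 0 for s in sums):
        raise ConfigurationError("walkthrough scenario: a sample has no "
                                 "surviving abundance; enlarge the scenario")
    target = sum(sums) / n
    renormalized = []
    for p in kept:
        q = dict(p)
        q["abundances"] = [None if v is None else v / sums[j] * target
                           for j, v in enumerate(p["abundances"])]
        renormalized.append(q)
    return _truth_aggregate(renormalized, sc.proteins, sc.samples,
                            "family", "KEGG_Pathway")


def walkthrough_scenario(seed: int = 42) -> SyntheticScenario:
    """A scenario sized for the documented walkthrough (microbial family
    specific pathways), with human and sub-High-confidence rows present so
    the metadata filters have work to do."""
    sc = generate_scenario(ScenarioParams(seed=seed, n_peptides=80,
                                          n_proteins=40))
    sc.truth["walkthrough_pair_family_KEGG_Pathway"] = walkthrough_truth(sc)
    return sc


# -- serialization -------------------------------------------------------

def _format_value(value) -> str:
    return "" if value is None else f"{value:.10g}"


def _write_pd_peptides(sc: SyntheticScenario, directory: Path) -> None:
    header = ["Annotated Sequence", "Confidence", "Quan Info", "Marker",
              "Master Protein Accessions", "Description"] + \
             [f"Abundance: {s}" for s in sc.samples]
    rows = []
    for p in sc.peptides:
        rows.append([f"[K].{p['sequence']}.[A]", p["confidence"],
                     p["quan_info"], p["marker"], ";".join(p["masters"]),
                     "synthetic peptide"] +
                    [_format_value(v) for v in p["abundances"]])
    with open(directory / "pd_peptides.txt", "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    _write_xlsx(directory / "pd_peptides.xlsx", header, [
        [cell if i < 6 else (None if cell == "" else float(cell))
         for i, cell in enumerate(row)] for row in rows
    ])


def _write_xlsx(path: Path, header: list, rows: list) -> None:
    """Deterministic xlsx writer: workbook timestamps are pinned so the same
    scenario always produces byte-identical bytes."""
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = "export"
    epoch = datetime.datetime(2000, 1, 1)
    wb.properties.created = epoch
    wb.properties.modified = epoch
    ws.append(header)
    for row in rows:
        ws.append(row)
    wb.save(str(path))


def _write_pd_psms(sc: SyntheticScenario, directory: Path) -> None:
    with open(directory / "pd_psms.txt", "w", encoding="utf-8") as fh:
        fh.write("Annotated Sequence\tConfidence\tSpectrum File\n")
        for seq, sample in sc.psms:
            fh.write(f"[K].{seq}.[A]\tHigh\t{sample}\n")


def _write_mztab(sc: SyntheticScenario, directory: Path) -> None:
    lines = [
        "MTD\tmzTab-version\t1.0.0",
        "MTD\tmzTab-mode\tSummary",
        "MTD\tmzTab-type\tQuantification",
        "MTD\tdescription\tsynthetic metaproteomic scenario",
    ]
    for j, sample in enumerate(sc.samples, start=1):
        lines.append(f"MTD\tms_run[{j}]-location\tfile://{sample}.mzML")
    for j in range(1, len(sc.samples) + 1):
        lines.append(f"MTD\tassay[{j}]-ms_run_ref\tms_run[{j}]")
    for j, sample in enumerate(sc.samples, start=1):
        lines.append(f"MTD\tstudy_variable[{j}]-description\t{sample}")
        lines.append(f"MTD\tstudy_variable[{j}]-assay_refs\tassay[{j}]")
    lines.append("")

    pep_header = ["PEH", "sequence", "accession", "unique", "database",
                  "database_version", "search_engine",
                  "best_search_engine_score[1]", "modifications",
                  "retention_time", "charge", "mass_to_charge"] + \
                 [f"peptide_abundance_study_variable[{j}]"
                  for j in range(1, len(sc.samples) + 1)]
    lines.append("\t".join(pep_header))
    for p in sc.peptides:
        accession = p["masters"][0] if p["masters"] else "null"
        row = ["PEP", p["sequence"], accession, "1", "null", "null", "null",
               "null", "null", "null", "2", "500.0"] + \
              [("null" if v is None else f"{v:.10g}") for v in p["abundances"]]
        lines.append("\t".join(row))
    lines.append("")

    run_of = {s: j for j, s in enumerate(sc.samples, start=1)}
    psm_header = ["PSH", "PSM_ID", "sequence", "accession", "unique",
                  "database", "database_version", "search_engine",
                  "search_engine_score[1]", "modifications", "retention_time",
                  "charge", "exp_mass_to_charge", "calc_mass_to_charge",
                  "spectra_ref", "pre", "post", "start", "end"]
    lines.append("\t".join(psm_header))
    by_sequence = {p["sequence"]: p for p in sc.peptides}
    for i, (seq, sample) in enumerate(sc.psms, start=1):
        masters = by_sequence[seq]["masters"]
        accession = masters[0] if masters else "null"
        lines.append("\t".join(
            ["PSM", str(i), seq, accession, "1", "null", "null", "null",
             "null", "null", "null", "2", "500.0", "500.0",
             f"ms_run[{run_of[sample]}]:scan={i}", "K", "A", "1",
             str(len(seq))]))
    with open(directory / "quant.mzTab", "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _write_unipept(sc: SyntheticScenario, directory: Path) -> None:
    header = ["peptide", "lca", *LINEAGE_RANKS]
    rows = []
    for p in sc.peptides:
        if not p["tax_annotated"]:
            continue
        rows.append([p["sequence"], p["lca"]] +
                    [p["lineage"][r] or "" for r in LINEAGE_RANKS])
    with open(directory / "unipept.csv", "w", encoding="utf-8") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")
    with open(directory / "unipept.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _write_eggnog(sc: SyntheticScenario, directory: Path) -> None:
    columns = ["query", "seed_ortholog", "evalue", "score", "eggNOG_OGs",
               "max_annot_lvl", "COG_category", "Description",
               "Preferred_name", "GOs", "EC", "KEGG_ko", "KEGG_Pathway",
               "KEGG_Module", "KEGG_Reaction", "KEGG_rclass", "BRITE",
               "KEGG_TC", "CAZy", "BiGG_Reaction", "PFAMs"]
    with open(directory / "eggnog.tsv", "w", encoding="utf-8") as fh:
        fh.write("## synthetic eggNOG-mapper-style annotations\n")
        fh.write("#" + "\t".join(columns) + "\n")
        for protein in sc.proteins:
            if not protein["annotated"]:
                continue
            functions = protein["functions"]

            def cell(category: str) -> str:
                codes = sorted(functions[category])
                if not codes:
                    return "-"
                if category == "COG_category":
                    return "".join(codes)
                if category == "KEGG_ko":
                    return ",".join(f"ko:{c}" for c in codes)
                if category == "KEGG_Pathway":
                    # eggNOG lists both ko and map forms of each pathway
                    return ",".join(codes + [c.replace("ko", "map", 1)
                                             for c in codes])
                return ",".join(codes)

            row = [protein["accession"], "seed", "1e-50", "200", "OG@1",
                   "2|Bacteria", cell("COG_category"), "synthetic protein",
                   "-", cell("GOs"), cell("EC"), cell("KEGG_ko"),
                   cell("KEGG_Pathway"), cell("KEGG_Module"),
                   cell("KEGG_Reaction"), "-", "-", "-", cell("CAZy"),
                   "-", "-"]
            fh.write("\t".join(row) + "\n")
        fh.write("## 1 query scanned\n")


def _write_kegg_mapping(sc: SyntheticScenario, directory: Path) -> None:
    with open(directory / "kegg_names.tsv", "w", encoding="utf-8") as fh:
        for key in sorted(sc.kegg_mapping):
            fh.write(f"{key}\t{sc.kegg_mapping[key]}\n")


def write_scenario(sc: SyntheticScenario, directory) -> dict:
    """Write every input dialect plus the truth tables under ``directory``.

    Returns a name -> path mapping of everything written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_pd_peptides(sc, directory)
    _write_pd_psms(sc, directory)
    _write_mztab(sc, directory)
    _write_unipept(sc, directory)
    _write_eggnog(sc, directory)
    _write_kegg_mapping(sc, directory)
    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    paths = {
        "pd_peptides_txt": directory / "pd_peptides.txt",
        "pd_peptides_xlsx": directory / "pd_peptides.xlsx",
        "pd_psms_txt": directory / "pd_psms.txt",
        "mztab": directory / "quant.mzTab",
        "unipept_csv": directory / "unipept.csv",
        "unipept_tsv": directory / "unipept.tsv",
        "eggnog": directory / "eggnog.tsv",
        "kegg_mapping": directory / "kegg_names.tsv",
    }
    for name, table in sc.truth.items():
        path = truth_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        paths[f"truth_{name}"] = path
    return {k: str(v) for k, v in paths.items()}
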