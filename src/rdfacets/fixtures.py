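"""Seeded synthetic tables with planted, machine-checkable structure.

The main generator emulates a viral-integration-site database of the kind
produced by whole-genome sequencing of paired tumor/normal liver tissue:
one row per detected HBV integration, carrying the sample id, tissue type,
nearest human gene, genomic region class, chromosome and coordinate (a
dependent facet: a coordinate is meaningless without its chromosome), and
the region of the HBV genome the breakpoint maps to.

The generator plants ground truth that the exploratory-search operations
must recover:

* *recurrent* genes — an integration is considered recurrent when it
  affects a gene in at least 4 distinct samples. Background genes are
  drawn at ≤ 2 occurrences so planted recurrence is separable (a fixture
  convention, not a biological claim).
* *shared* genes, integrated in both tumor and normal tissue (in different
  samples), recoverable by a tumor∧normal conjunction query.
* *co-located pairs* — samples carrying a tumor and a normal breakpoint on
  the same chromosome; no other sample/chromosome tumor∧normal overlap is
  allowed to arise by chance.

Row counts are fixed by the plan; the seed randomizes sample assignment,
chromosomes, coordinates and region labels only. Identical seeds yield
byte-identical tables.

A second generator produces small random tables (with optional dependent,
hidden and typed columns) used to exercise conversion and the query engine
against brute-force oracles.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

from .convert import TableSource
from .schema import DatabaseStructure, parse_structure_config

HBV_DATABASE = "hbv_integrations"
HBV_NAMESPACE = "https://rdfacets.io/data/hbv/"

#: Approximate hg19-scale chromosome lengths (Mb), for coordinate ranges.
_CHROM_MB = {
    "chr1": 249, "chr2": 243, "chr3": 198, "chr4": 191, "chr5": 181,
    "chr6": 171, "chr7": 159, "chr8": 146, "chr9": 141, "chr10": 136,
    "chr11": 135, "chr12": 134, "chr13": 115, "chr14": 107, "chr15": 103,
    "chr16": 90, "chr17": 81, "chr18": 78, "chr19": 59, "chr20": 63,
    "chr21": 48, "chr22": 51, "chrX": 155,
}

HBV_STRUCTURE_CONFIG = f"""\
databases:
  - name: {HBV_DATABASE}
    namespace: {HBV_NAMESPACE}
    columns:
      - column: sample_id
        display_name: Sample
        display_order: 0
      - column: tissue
        display_name: Tissue type
        display_order: 1
      - column: gene
        display_name: Human gene
        display_order: 2
        entity_type: gene
      - column: region
        display_name: Genomic region
        display_order: 3
      - column: chromosome
        display_name: Chromosome
        display_order: 4
      - column: coordinate
        display_name: Integration coordinate
        display_order: 5
        datatype: integer
        depends_on: chromosome
        indexed: false
      - column: hbv_region
        display_name: HBV genome region
        display_order: 6
"""


def hbv_structure() -> DatabaseStructure:
    """Parsed structure of the integration fixture database."""
    return parse_structure_config(HBV_STRUCTURE_CONFIG)


@dataclass
class IntegrationFixtureSpec:
    """Plan for one synthetic integration table.

    ``planted_recurrent`` / ``planted_recurrent_normal`` map a gene to
    (integration count, distinct-sample count); the distinct-sample count
    must be at least 4 — the recurrence criterion. Background gene pools are
    tissue-specific so that shared genes are exactly the planted ones.
    """

    n_samples: int = 88
    planted_recurrent: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "GENE_T1": (8, 8), "GENE_T2": (6, 6), "GENE_T3": (5, 5),
        "GENE_T4": (4, 4), "GENE_T5": (4, 4)})
    planted_recurrent_normal: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"GENE_N1": (4, 4)})
    planted_shared: tuple[str, ...] = ("GENE_S1", "GENE_S2", "GENE_S3")
    n_colocated_pairs: int = 2
    background_tumor_singles: int = 32
    background_tumor_doubles: int = 10
    background_normal_singles: int = 14
    background_normal_doubles: int = 1
    region_weights: dict[str, float] = field(default_factory=lambda: {
        "exon": 0.28, "intron": 0.34, "promoter": 0.16, "intergenic": 0.22})
    hbv_region_weights: dict[str, float] = field(default_factory=lambda: {
        "X": 0.24, "core": 0.15, "enhancer": 0.10, "other": 0.51})
    seed: int = 0

    def validate(self) -> None:
        for where, plan in (("tumor", self.planted_recurrent),
                            ("normal", self.planted_recurrent_normal)):
            for gene, (n_int, n_smp) in plan.items():
                if n_smp < 4:
                    raise ValueError(
                        f"planted {where} gene {gene!r}: recurrence requires "
                        f"at least 4 distinct samples, got {n_smp}")
                if n_int < n_smp:
                    raise ValueError(
                        f"planted {where} gene {gene!r}: integration count "
                        f"{n_int} below distinct-sample count {n_smp}")
                if n_smp > self.n_samples:
                    raise ValueError(
                        f"planted {where} gene {gene!r}: needs {n_smp} "
                        f"samples but only {self.n_samples} exist")
        for name, w in (("region_weights", self.region_weights),
                        ("hbv_region_weights", self.hbv_region_weights)):
            if not w or any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
                raise ValueError(f"{name} must be non-negative with positive sum")
        if self.n_colocated_pairs > self.n_samples:
            raise ValueError("more co-located pairs than samples")

    @property
    def tumor_rows(self) -> int:
        return (sum(n for n, _ in self.planted_recurrent.values())
                + len(self.planted_shared) + self.n_colocated_pairs
                + self.background_tumor_singles + 2 * self.background_tumor_doubles)

    @property
    def normal_rows(self) -> int:
        return (sum(n for n, _ in self.planted_recurrent_normal.values())
                + len(self.planted_shared) + self.n_colocated_pairs
                + self.background_normal_singles + 2 * self.background_normal_doubles)

    @property
    def tissue_split(self) -> float:
        """Fraction of integrations located in tumor tissue."""
        return self.tumor_rows / (self.tumor_rows + self.normal_rows)


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    labels = sorted(weights)
    w = np.array([weights[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=w / w.sum())]


def generate_integration_table(spec: IntegrationFixtureSpec | None = None
                               ) -> tuple[TableSource, dict]:
    """Generate the integration table and its ground-truth manifest."""
    spec = spec or IntegrationFixtureSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i:02d}" for i in range(1, spec.n_samples + 1)]
    chroms = sorted(_CHROM_MB)

    # (tissue, gene, sample, planted_chromosome-or-None)
    plan: list[tuple[str, str, str, str | None]] = []

    def plant_recurrent(tissue: str, table: dict[str, tuple[int, int]]):
        for gene in sorted(table):
            n_int, n_smp = table[gene]
            chosen = list(rng.choice(samples, size=n_smp, replace=False))
            extra = list(rng.choice(chosen, size=n_int - n_smp, replace=True))
            for s in chosen + extra:
                plan.append((tissue, gene, s, None))

    plant_recurrent("tumor", spec.planted_recurrent)
    plant_recurrent("normal", spec.planted_recurrent_normal)

    for gene in spec.planted_shared:
        s_t, s_n = rng.choice(samples, size=2, replace=False)
        plan.append(("tumor", gene, s_t, None))
        plan.append(("normal", gene, s_n, None))

    colocated = []
    coloc_samples = rng.choice(samples, size=spec.n_colocated_pairs, replace=False)
    for i, s in enumerate(coloc_samples, start=1):
        chrom = chroms[rng.integers(len(chroms))]
        plan.append(("tumor", f"GENE_CT{i}", s, chrom))
        plan.append(("normal", f"GENE_CN{i}", s, chrom))
        colocated.append({"sample": s, "chromosome": chrom})

    def plant_background(tissue: str, prefix: str, singles: int, doubles: int):
        for i in range(1, doubles + 1):
            gene = f"{prefix}D{i:03d}"
            for s in rng.choice(samples, size=2, replace=True):
                plan.append((tissue, gene, s, None))
        for i in range(1, singles + 1):
            plan.append((tissue, f"{prefix}S{i:03d}",
                         samples[rng.integers(len(samples))], None))

    plant_background("tumor", "GENE_BT", spec.background_tumor_singles,
                     spec.background_tumor_doubles)
    plant_background("normal", "GENE_BN", spec.background_normal_singles,
                     spec.background_normal_doubles)

    # Chromosome assignment: within one sample, tumor and normal rows never
    # share a chromosome unless the pair was planted as co-located.
    used: dict[tuple[str, str], set[str]] = {}
    rows = []
    for tissue, gene, sample, planted_chrom in plan:
        other = "normal" if tissue == "tumor" else "tumor"
        if planted_chrom is not None:
            chrom = planted_chrom
        else:
            forbidden = used.get((sample, other), set())
            chrom = chroms[rng.integers(len(chroms))]
            while chrom in forbidden:
                chrom = chroms[rng.integers(len(chroms))]
        used.setdefault((sample, tissue), set()).add(chrom)
        coordinate = int(rng.integers(1, _CHROM_MB[chrom] * 1_000_000))
        rows.append({
            "sample_id": sample,
            "tissue": tissue,
            "gene": gene,
            "region": _weighted_choice(rng, spec.region_weights),
            "chromosome": chrom,
            "coordinate": str(coordinate),
            "hbv_region": _weighted_choice(rng, spec.hbv_region_weights),
        })

    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    header = ["sample_id", "tissue", "gene", "region", "chromosome",
              "coordinate", "hbv_region"]
    table = TableSource(HBV_DATABASE, header, rows)

    gene_counts: dict[str, dict] = {}
    for r in rows:
        gc = gene_counts.setdefault(r["gene"], {
            "tumor": 0, "normal": 0, "tumor_samples": set(), "normal_samples": set()})
        gc[r["tissue"]] += 1
        gc[f"{r['tissue']}_samples"].add(r["sample_id"])
    for gc in gene_counts.values():
        gc["tumor_samples"] = sorted(gc["tumor_samples"])
        gc["normal_samples"] = sorted(gc["normal_samples"])

    manifest = {
        "seed": spec.seed,
        "n_samples": spec.n_samples,
        "tumor_rows": spec.tumor_rows,
        "normal_rows": spec.normal_rows,
        "total_rows": len(rows),
        "tissue_split": spec.tissue_split,
        "recurrent_tumor_genes": {
            g: {"integrations": n, "samples": s}
            for g, (n, s) in sorted(spec.planted_recurrent.items())},
        "recurrent_normal_genes": {
            g: {"integrations": n, "samples": s}
            for g, (n, s) in sorted(spec.planted_recurrent_normal.items())},
        "shared_genes": sorted(spec.planted_shared),
        "colocated_pairs": sorted(colocated, key=lambda d: d["sample"]),
        "gene_counts": {g: gene_counts[g] for g in sorted(gene_counts)},
    }
    return table, manifest


def table_to_tsv(table: TableSource) -> str:
    """Serialize a table as TSV (deterministic)."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(table.header)
    for row in table.rows:
        writer.writerow([row[h] for h in table.header])
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Random toy tables for oracle testing
# ---------------------------------------------------------------------------

def generate_random_table(seed: int, max_rows: int = 120, max_cols: int = 8,
                          empty_frac: float = 0.1
                          ) -> tuple[TableSource, DatabaseStructure]:
    """A random table plus matching structure, for oracle comparisons.

    Columns draw from small per-column vocabularies (so facet values
    repeat), one column may be integer-typed, one may depend on another,
    and hidden/non-indexed flags are exercised. At most *empty_frac* of
    cells are empty.
    """
    rng = np.random.default_rng(seed)
    n_rows = int(rng.integers(1, max_rows + 1))
    n_cols = int(rng.integers(2, max_cols + 1))
    name = f"rnd{seed}"
    ns = f"https://rdfacets.io/data/{name}/"

    col_lines = []
    headers = [f"col{j}" for j in range(n_cols)]
    int_col = int(rng.integers(n_cols)) if rng.random() < 0.5 else -1
    dep_pair = None
    if n_cols >= 2 and rng.random() < 0.5:
        a, b = rng.choice(n_cols, size=2, replace=False)
        if int(a) != int_col:  # prerequisite of the dependent col is b
            dep_pair = (int(a), int(b))
    hidden_col = int(rng.integers(n_cols)) if rng.random() < 0.4 else -1
    unindexed_col = int(rng.integers(n_cols)) if rng.random() < 0.5 else -1
    for j, h in enumerate(headers):
        lines = [f"      - column: {h}", f"        display_order: {j}"]
        if j == int_col and (dep_pair is None or dep_pair[0] != j):
            lines.append("        datatype: integer")
        if dep_pair is not None and dep_pair[0] == j:
            lines.append(f"        depends_on: {headers[dep_pair[1]]}")
        if j == hidden_col:
            lines.append("        hidden: true")
        if j == unindexed_col:
            lines.append("        indexed: false")
        col_lines.append("\n".join(lines))
    config = (f"databases:\n  - name: {name}\n    namespace: {ns}\n"
              "    columns:\n" + "\n".join(col_lines) + "\n")
    structure = parse_structure_config(config)

    vocabs = []
    for j in range(n_cols):
        size = int(rng.integers(2, 9))
        if j == int_col and (dep_pair is None or dep_pair[0] != j):
            vocabs.append([str(int(v)) for v in rng.integers(1, 500, size=size)])
        else:
            vocabs.append([f"col{j}v{k}" for k in range(size)])

    rows = []
    for _ in range(n_rows):
        row = {}
        for j, h in enumerate(headers):
            if rng.random() < empty_frac:
                row[h] = ""
            else:
                row[h] = vocabs[j][rng.integers(len(vocabs[j]))]
        rows.append(row)
    return TableSource(name, headers, rows), structure
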