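"""Readers and writers for the formats the tool touches.

FASTA parsing goes through Biopython; everything else is plain
tab-separated or key-value text so outputs diff cleanly and contain no
timestamps — two runs on identical inputs produce identical bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assessment import (
    CompletenessClass,
    ConsistencyClass,
    QualityReport,
    ThresholdConfig,
)

logger = logging.getLogger("hogqc")

__all__ = [
    "ProteomeInput",
    "ProteomeInputError",
    "read_proteome",
    "write_fasta",
    "write_report",
    "write_category_fastas",
    "load_config",
]

Record = tuple[str, str]


class ProteomeInputError(ValueError):
    """Malformed proteome or isoform input."""


@dataclass
class ProteomeInput:
    """A parsed query proteome with its gene (isoform) grouping."""

    records: list[Record]
    gene_map: dict[str, str] = field(default_factory=dict)
    fasta_path: str | None = None
    isoform_path: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_map:
            self.gene_map = {pid: pid for pid, _ in self.records}


def _clean_sequence(pid: str, seq: str) -> str:
    seq = seq.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        logger.info("stripping internal stop marks from %s", pid)
        seq = seq.replace("*", "")
    return seq


def read_proteome(fasta_path: str, isoform_path: str | None = None) -> ProteomeInput:
    """Read a protein FASTA plus an optional isoform file.

    The record id is the first whitespace-delimited token of the
    description line.  The isoform file holds one gene per line: the
    comma-separated ids of all its isoforms; proteins absent from it are
    singleton genes.  Stop marks (``*``) are stripped with a log note.
    """
    records: list[Record] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(fasta_path, "fasta"):
        pid = rec.id
        if pid in seen:
            raise ProteomeInputError(f"duplicate protein id {pid!r}")
        seen.add(pid)
        records.append((pid, _clean_sequence(pid, str(rec.seq))))
    if not records:
        raise ProteomeInputError(f"no records in {fasta_path!r}")

    gene_map: dict[str, str] = {}
    if isoform_path is not None:
        with open(isoform_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                ids = [tok.strip() for tok in line.split(",") if tok.strip()]
                if not ids:
                    continue
                gene_id = ids[0]
                for pid in ids:
                    if pid not in seen:
                        raise ProteomeInputError(
                            f"isoform file line {lineno}: id {pid!r} not in FASTA"
                        )
                    if pid in gene_map:
                        raise ProteomeInputError(
                            f"protein {pid!r} listed for two genes"
                        )
                    gene_map[pid] = gene_id
    for pid, _ in records:
        gene_map.setdefault(pid, pid)
    return ProteomeInput(records=records, gene_map=gene_map,
                         fasta_path=fasta_path, isoform_path=isoform_path)


def write_fasta(records: list[Record], path: str, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# -- report output -------------------------------------------------------------

_COMPLETENESS_ORDER = [
    CompletenessClass.SINGLE,
    CompletenessClass.DUPLICATED_EXPECTED,
    CompletenessClass.DUPLICATED_UNEXPECTED,
    CompletenessClass.MISSING,
]
_CONSISTENCY_ORDER = [
    ConsistencyClass.CONSISTENT,
    ConsistencyClass.INCONSISTENT,
    ConsistencyClass.CONTAMINANT,
    ConsistencyClass.AMBIGUOUS_CONTAMINANT,
    ConsistencyClass.UNKNOWN,
]


def _summary_text(report: QualityReport) -> str:
    comp_n = report.completeness_counts()
    comp_p = report.completeness_percentages()
    cons_n = report.consistency_counts()
    cons_p = report.consistency_percentages()
    struct_p = report.structure_percentages()
    lines = [
        "# Proteome quality assessment",
        f"ancestral_lineage\t{report.ancestral_lineage}",
        f"lineage_warning\t{report.lineage_warning}",
        f"conserved_hogs\t{report.conserved_total}",
        f"selected_genes\t{len(report.proteins)}",
        "",
        "## Completeness (conserved ancestral repertoire)",
    ]
    for cls in _COMPLETENESS_ORDER:
        lines.append(f"{cls}\t{comp_n[cls]}\t{comp_p[cls]:.2f}%")
    lines.append("")
    lines.append("## Consistency (selected genes)")
    for cls in _CONSISTENCY_ORDER:
        lines.append(f"{cls}\t{cons_n[cls]}\t{cons_p[cls]:.2f}%")
    lines.append("")
    lines.append("## Gene-model structure")
    lines.append(f"partial\t{struct_p['partial']:.2f}%")
    lines.append(f"fragment\t{struct_p['fragment']:.2f}%")
    lines.append("")
    lines.append("## Detected contaminant clades")
    if report.contaminant_clades:
        for clade in report.contaminant_clades:
            lines.append(f"contaminant\t{clade}")
    else:
        lines.append("contaminant\tnone")
    for note in report.notes:
        lines.append(f"# note: {note}")
    return "\n".join(lines) + "\n"


def write_report(report: QualityReport, out_prefix: str) -> dict[str, str]:
    """Write the summary, per-protein table and isoform selection files.

    Returns the mapping of logical name to written path.  Files:
    ``<prefix>_summary.txt`` (human-readable), ``<prefix>_detail.tsv``
    (one row per selected protein), ``<prefix>_summary.yaml``
    (machine-readable key-value) and ``<prefix>_selected_isoform.txt``.
    """
    paths = {
        "summary": f"{out_prefix}_summary.txt",
        "detail": f"{out_prefix}_detail.tsv",
        "machine": f"{out_prefix}_summary.yaml",
        "isoforms": f"{out_prefix}_selected_isoform.txt",
    }
    with open(paths["summary"], "w") as fh:
        fh.write(_summary_text(report))

    with open(paths["detail"], "w") as fh:
        fh.write("protein_id\tgene_id\tcategory\tpartial\tfragment\t"
                 "placed_hog\troot_hog\n")
        for pa in report.proteins:
            fh.write(
                f"{pa.protein_id}\t{pa.gene_id}\t{pa.category}\t"
                f"{int(pa.partial)}\t{int(pa.fragment)}\t"
                f"{pa.placed_hog or 'NA'}\t{pa.root_hog or 'NA'}\n"
            )

    payload = {
        "ancestral_lineage": report.ancestral_lineage,
        "lineage_warning": report.lineage_warning,
        "conserved_hogs": report.conserved_total,
        "selected_genes": len(report.proteins),
        "completeness_counts": report.completeness_counts(),
        "completeness_percent": report.completeness_percentages(),
        "consistency_counts": report.consistency_counts(),
        "consistency_percent": report.consistency_percentages(),
        "structure_percent": report.structure_percentages(),
        "contaminant_clades": report.contaminant_clades,
        "notes": report.notes,
    }
    with open(paths["machine"], "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)

    with open(paths["isoforms"], "w") as fh:
        for gene_id, protein_id in report.isoform_listing:
            fh.write(f"{gene_id}\t{protein_id}\n")
    return paths


def write_category_fastas(
    report: QualityReport, proteome: ProteomeInput, out_prefix: str
) -> dict[str, str]:
    """One FASTA per problem category, byte-identical to the input.

    Categories: inconsistent, contaminant (including ambiguous) and
    unknown.  Requires the original FASTA records.
    """
    if not proteome.records:
        raise ProteomeInputError("input FASTA required for category output")
    by_id = dict(proteome.records)
    buckets: dict[str, list[Record]] = {
        "inconsistent": [],
        "contaminant": [],
        "unknown": [],
    }
    for pa in report.proteins:
        if pa.category == ConsistencyClass.INCONSISTENT:
            bucket = "inconsistent"
        elif pa.category in (ConsistencyClass.CONTAMINANT,
                             ConsistencyClass.AMBIGUOUS_CONTAMINANT):
            bucket = "contaminant"
        elif pa.category == ConsistencyClass.UNKNOWN:
            bucket = "unknown"
        else:
            continue
        buckets[bucket].append((pa.protein_id, by_id[pa.protein_id]))
    paths = {}
    for bucket, records in buckets.items():
        path = f"{out_prefix}_{bucket}.fa"
        write_fasta(records, path)
        paths[bucket] = path
    return paths


def load_config(path: str | None) -> ThresholdConfig:
    """Build a ThresholdConfig from a YAML key-value file (or defaults)."""
    if path is None:
        return ThresholdConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in ThresholdConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ProteomeInputError(f"unknown config keys: {sorted(unknown)}")
    return ThresholdConfig(**data)
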