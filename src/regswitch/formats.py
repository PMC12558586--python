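"""Readers and writers for the external formats the pipeline touches.

All coordinates are 0-based half-open internally; conversion to and from
1-based conventions (VCF) happens only here. Risk-allele orientation is
always explicit in the input (``RISK=`` INFO key in VCF, a ``risk`` column
in the TSV dialect) and is never inferred from allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
REGION_KINDS = ("promoter", "enhancer")


@dataclass(frozen=True)
class RegulatoryRegion:
    """A typed regulatory interval (promoter or enhancer), 0-based half-open."""

    region_id: str
    chrom: str
    start: int
    end: int
    kind: str
    strand: str = "+"
    target_gene: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region {self.region_id}: start {self.start} >= end {self.end}"
            )
        if self.kind not in REGION_KINDS:
            raise ValueError(f"region kind must be one of {REGION_KINDS}: {self.kind!r}")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class RegulatoryVariant:
    """A bi-allelic SNP with explicit risk (disease-state) orientation.

    ``pos`` is 0-based. ``nonrisk_allele`` is the protective allele whose
    sequence context defines the healthy state; ``risk_allele`` defines the
    disease state.
    """

    rsid: str
    chrom: str
    pos: int
    nonrisk_allele: str
    risk_allele: str
    region_id: str = ""

    def __post_init__(self) -> None:
        for allele in (self.nonrisk_allele, self.risk_allele):
            if allele not in VALID_BASES:
                raise ValueError(
                    f"{self.rsid}: allele {allele!r} is not a single base in ACGT"
                )
        if self.nonrisk_allele == self.risk_allele:
            raise ValueError(f"{self.rsid}: risk and non-risk alleles are identical")


@dataclass
class PatientGenotype:
    """Risk-allele dosage per SNP for one patient."""

    patient_id: str
    disease: str = "none"  # UC, CD or none
    dosages: dict[str, int] = field(default_factory=dict)

    def active_rsids(self, min_dosage: int = 1) -> set[str]:
        """SNPs at which the patient carries at least ``min_dosage`` risk alleles."""
        return {r for r, d in self.dosages.items() if d >= min_dosage}


@dataclass
class DEGTable:
    """Differential-expression results for one tissue: gene, log2fc, adj_p."""

    frame: pd.DataFrame  # columns: gene, log2fc, adj_p
    tissue_label: str = ""

    def __post_init__(self) -> None:
        bad = self.frame[(self.frame.adj_p < 0) | (self.frame.adj_p > 1)]
        if len(bad):
            raise ValueError(
                f"DEG table {self.tissue_label!r}: adj_p outside [0,1] for "
                f"{bad.gene.tolist()[:5]}"
            )


# ---------------------------------------------------------------------------
# regions


def read_regions(path: str | Path, kind: str) -> list[RegulatoryRegion]:
    """Read a BED file of regulatory regions of one kind.

    Column 4, when present, is used as both region id and target gene.
    Coordinates are kept as BED half-open 0-based. Output is sorted by
    (chrom, start) and exact duplicate intervals are dropped.
    """
    if kind not in REGION_KINDS:
        raise ValueError(f"kind must be one of {REGION_KINDS}")
    regions: dict[tuple, RegulatoryRegion] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 else "+"
            key = (chrom, start, end, kind)
            if key in regions:
                continue
            regions[key] = RegulatoryRegion(
                region_id=name, chrom=chrom, start=start, end=end,
                kind=kind, strand=strand,
                target_gene=name if kind == "promoter" else "",
            )
    return sorted(regions.values(), key=lambda r: (r.chrom, r.start, r.end))


def build_promoter(
    tss: int,
    strand: str,
    first_exon_end: int,
    upstream_bp: int = 5000,
    *,
    gene: str = "",
    chrom: str = "",
) -> RegulatoryRegion:
    """Construct a promoter region: ``upstream_bp`` upstream of the TSS through
    the end of the gene's first exon.

    ``first_exon_end`` is the far boundary of the first exon in transcription
    direction: the genomic end (exclusive) for + strand genes, the genomic
    start for − strand genes. A start clipped below 0 is truncated with a
    warning rather than rejected.
    """
    if strand == "+":
        if first_exon_end <= tss:
            raise ValueError("+ strand promoter requires first_exon_end > tss")
        start, end = tss - upstream_bp, first_exon_end
    elif strand == "-":
        if first_exon_end >= tss:
            raise ValueError("- strand promoter requires first_exon_end < tss")
        start, end = first_exon_end, tss + upstream_bp
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if start < 0:
        log.warning("promoter for %s clipped at origin (start %d)", gene or "gene", start)
        start = 0
    return RegulatoryRegion(
        region_id=gene or f"{chrom}:{start}-{end}", chrom=chrom,
        start=start, end=end, kind="promoter", strand=strand, target_gene=gene,
    )


# ---------------------------------------------------------------------------
# variants + genotypes


def read_variants_and_genotypes(
    path: str | Path,
    disease_labels: Mapping[str, str] | None = None,
) -> tuple[list[RegulatoryVariant], list[PatientGenotype]]:
    """Read bi-allelic SNPs plus per-patient risk-allele dosages.

    Two dialects are accepted, keyed on file extension:

    * ``.vcf`` — VCF v4.x; each record must carry an ``RISK=REF`` or
      ``RISK=ALT`` INFO entry naming the risk allele. Multi-allelic records
      are skipped with a warning. Positions are converted 1-based → 0-based.
    * anything else — a TSV with columns ``rsid chrom pos_1based nonrisk
      risk`` followed by one 0/1/2 dosage column per patient.

    Missing genotypes count as dosage 0 (non-carrier) with a warning.
    ``disease_labels`` optionally maps patient id → UC/CD/none.
    """
    disease_labels = dict(disease_labels or {})
    path = Path(path)
    if path.suffix == ".vcf":
        variants, patients = _read_vcf(path)
    else:
        variants, patients = _read_genotype_tsv(path)
    for p in patients:
        p.disease = disease_labels.get(p.patient_id, "none")
    return variants, patients


def _read_vcf(path: Path) -> tuple[list[RegulatoryVariant], list[PatientGenotype]]:
    import pysam

    variants: list[RegulatoryVariant] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        patients = {s: PatientGenotype(patient_id=s) for s in sample_ids}
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                log.warning("skipping multi-allelic record %s", rec.id)
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                log.warning("skipping non-SNP record %s", rec.id)
                continue
            try:
                risk_key = rec.info.get("RISK")
            except (KeyError, ValueError):  # key absent from the VCF header
                risk_key = None
            if isinstance(risk_key, tuple):
                risk_key = risk_key[0]
            if risk_key not in ("REF", "ALT"):
                raise ValueError(f"record {rec.id}: missing RISK=REF|ALT INFO field")
            risk, nonrisk = (ref, alt) if risk_key == "REF" else (alt, ref)
            rsid = rec.id or f"{rec.chrom}:{rec.pos}"
            variants.append(RegulatoryVariant(
                rsid=rsid, chrom=rec.chrom, pos=rec.pos - 1,
                nonrisk_allele=nonrisk, risk_allele=risk,
            ))
            for s in sample_ids:
                gt = rec.samples[s].get("GT", (None,))
                alleles = [a for a in gt if a is not None]
                if len(alleles) < 2:
                    log.warning("missing genotype for %s at %s treated as dosage 0", s, rsid)
                    dosage = 0
                else:
                    risk_code = 0 if risk_key == "REF" else 1
                    dosage = sum(1 for a in alleles if a == risk_code)
                patients[s].dosages[rsid] = dosage
    if n_skipped:
        log.warning("skipped %d non-bi-allelic record(s) in %s", n_skipped, path)
    return variants, [patients[s] for s in sample_ids]


def _read_genotype_tsv(path: Path) -> tuple[list[RegulatoryVariant], list[PatientGenotype]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["rsid", "chrom", "pos_1based", "nonrisk", "risk"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    sample_ids = [c for c in df.columns if c not in fixed]
    variants: list[RegulatoryVariant] = []
    patients = {s: PatientGenotype(patient_id=s) for s in sample_ids}
    for _, row in df.iterrows():
        variant = RegulatoryVariant(
            rsid=row.rsid, chrom=row.chrom, pos=int(row.pos_1based) - 1,
            nonrisk_allele=row.nonrisk, risk_allele=row.risk,
        )
        variants.append(variant)
        for s in sample_ids:
            raw = row[s]
            try:
                dosage = int(raw)
            except (TypeError, ValueError):
                dosage = -1
            if dosage not in (0, 1, 2):
                log.warning(
                    "patient %s at %s: dosage %r treated as 0", s, variant.rsid, raw
                )
                dosage = 0
            patients[s].dosages[variant.rsid] = dosage
    return variants, [patients[s] for s in sample_ids]


def assign_regions(
    variants: Iterable[RegulatoryVariant],
    regions: Iterable[RegulatoryRegion],
) -> list[RegulatoryVariant]:
    """Attach each variant to the first region containing its position.

    Variants falling in no region are dropped with a warning: the workflow
    only considers SNPs inside promoters or enhancers.
    """
    regions = list(regions)
    out = []
    for v in variants:
        hit = next(
            (r for r in regions if r.chrom == v.chrom and v.pos in r), None
        )
        if hit is None:
            log.warning("variant %s falls in no regulatory region; dropped", v.rsid)
            continue
        out.append(RegulatoryVariant(
            rsid=v.rsid, chrom=v.chrom, pos=v.pos,
            nonrisk_allele=v.nonrisk_allele, risk_allele=v.risk_allele,
            region_id=hit.region_id,
        ))
    return out


# ---------------------------------------------------------------------------
# motifs, sequences


def read_jaspar(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read a JASPAR PFM file into (name, 4×w count matrix) pairs, rows A,C,G,T.

    Both the bracketed 2016+ format and 4-line raw count blocks are handled
    by Biopython's JASPAR parser. Order of motifs in the file is preserved.
    """
    out: list[tuple[str, np.ndarray]] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            name = m.name or m.matrix_id
            if np.any(counts < 0):
                raise ValueError(f"motif {name}: negative count")
            widths = {len(m.counts[b]) for b in "ACGT"}
            if len(widths) != 1:
                raise ValueError(f"motif {name}: rows of unequal width")
            out.append((name, counts))
    return out


def read_fasta_windows(path: str | Path) -> dict[str, str]:
    """Read SNP-window sequences keyed by record id (e.g. ``rs1|risk``)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# DEG tables, annotation and term lists


def read_deg_table(
    path: str | Path,
    tissue_label: str = "",
    gene_col: str = "gene",
    log2fc_col: str = "log2fc",
    adjp_col: str = "adj_p",
) -> DEGTable:
    """Read a differential-expression TSV.

    Duplicate gene rows keep the smallest adjusted p (with a warning);
    non-numeric statistics are an error.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in (gene_col, log2fc_col, adjp_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.rename(columns={gene_col: "gene", log2fc_col: "log2fc", adjp_col: "adj_p"})
    for col in ("log2fc", "adj_p"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df.gene.duplicated().any():
        log.warning("%s: duplicate gene rows; keeping smallest adj_p", path)
        df = df.sort_values("adj_p", kind="stable").drop_duplicates("gene")
    df = df[["gene", "log2fc", "adj_p"]].reset_index(drop=True)
    return DEGTable(frame=df, tissue_label=tissue_label)


def read_gene_go_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (gene/TF, GO id) TSV into a mapping gene → term set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "go_id"],
                     dtype=str, comment="!")
    ann: dict[str, set[str]] = {}
    for gene, go_id in zip(df.gene, df.go_id):
        ann.setdefault(gene, set()).add(go_id)
    return ann


def read_term_list(path: str | Path) -> set[str]:
    """Read a plain-text GO id list (one id per line; blank lines ignored)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table deterministically (no index, \\n line endings)."""
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
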