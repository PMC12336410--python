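"""Build composite-exon and intron annotations from a GTF.

Exonic reads report mature-mRNA abundance and intronic reads pre-mRNA
abundance, so the split pipeline needs, per gene, (a) the union of all exon
and UTR intervals across isoforms (the "composite exon") and (b) the gene
span minus that union (the introns).  This module parses GENCODE-dialect
GTFs into :class:`GeneModel` objects, derives both interval sets, and writes
them back out as GTF or SAF for external read counters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .intervals import (
    GenomicInterval,
    merge_intervals,
    subtract_intervals,
    total_width,
)

logger = logging.getLogger(__name__)

# feature types folded into the composite exon
_EXONIC_FEATURES = frozenset({"exon", "UTR", "five_prime_utr", "three_prime_utr"})


class GTFParseError(ValueError):
    """Raised for a malformed GTF line; the message names the line number."""


@dataclass
class GeneModel:
    """All transcript structures of one gene parsed from a GTF."""

    gene_id: str
    strand: str
    gene_span: GenomicInterval
    #: transcript_id -> list of exon/UTR intervals
    transcripts: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def validate(self) -> None:
        for tx_id, ivs in self.transcripts.items():
            for iv in ivs:
                if iv.chrom != self.gene_span.chrom or iv.strand != self.strand:
                    raise ValueError(
                        f"gene {self.gene_id}: interval of {tx_id} on a different "
                        "chromosome or strand than the gene"
                    )
                if iv.start < self.gene_span.start or iv.end > self.gene_span.end:
                    raise ValueError(
                        f"gene {self.gene_id}: exon {iv.start}-{iv.end} of {tx_id} "
                        f"outside gene span "
                        f"{self.gene_span.start}-{self.gene_span.end}"
                    )


@dataclass
class AnnotationSet:
    """Per-gene composite exons and introns, mutually disjoint and spanning."""

    composite_exons: dict[str, list[GenomicInterval]]
    introns: dict[str, list[GenomicInterval]]
    exon_length: dict[str, int]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.composite_exons)


def _parse_attributes(attr_field: str) -> dict[str, str]:
    """Parse the GENCODE attribute dialect: key "value"; pairs."""
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf(gtf_text: str) -> dict[str, GeneModel]:
    """Parse GTF content into a mapping gene_id -> :class:`GeneModel`.

    GTF 1-based closed coordinates are converted to the internal 0-based
    half-open convention.  Genes whose features disagree on chromosome or
    strand (annotation artifacts) are dropped with a warning.
    """
    spans: dict[str, GenomicInterval] = {}
    tx_intervals: dict[str, dict[str, list[GenomicInterval]]] = {}
    tx_gene: dict[str, str] = {}
    bad_genes: set[str] = set()

    lines = gtf_text.splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 9:
            raise GTFParseError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GTFParseError(
                f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
            ) from exc
        if end1 < start1:
            raise GTFParseError(f"line {lineno}: end {end1} < start {start1}")
        if strand not in ("+", "-"):
            raise GTFParseError(f"line {lineno}: bad strand {strand!r}")
        attrs = _parse_attributes(attr)
        gene_id = attrs.get("gene_id")
        if gene_id is None:
            raise GTFParseError(f"line {lineno}: missing gene_id attribute")
        iv = GenomicInterval(chrom, start1 - 1, end1, strand)

        if feature == "gene":
            if gene_id in spans and (
                spans[gene_id].chrom != chrom or spans[gene_id].strand != strand
            ):
                bad_genes.add(gene_id)
            spans[gene_id] = iv
        elif feature in _EXONIC_FEATURES:
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise GTFParseError(f"line {lineno}: missing transcript_id attribute")
            tx_gene[tx_id] = gene_id
            tx_intervals.setdefault(gene_id, {}).setdefault(tx_id, []).append(iv)

    if not spans and not tx_intervals:
        logger.warning("parse_gtf: no gene or exon features found in input")
        return {}

    genes: dict[str, GeneModel] = {}
    for gene_id in sorted(set(spans) | set(tx_intervals)):
        txs = tx_intervals.get(gene_id, {})
        all_ivs = [iv for ivs in txs.values() for iv in ivs]
        chroms = {iv.chrom for iv in all_ivs}
        strands = {iv.strand for iv in all_ivs}
        if gene_id in spans:
            chroms.add(spans[gene_id].chrom)
            strands.add(spans[gene_id].strand)
        if len(chroms) > 1 or len(strands) > 1 or gene_id in bad_genes:
            logger.warning(
                "dropping gene %s: features on multiple chromosomes/strands", gene_id
            )
            continue
        span = spans.get(gene_id)
        if span is None:
            # infer span from features when no gene line is present
            span = GenomicInterval(
                all_ivs[0].chrom,
                min(iv.start for iv in all_ivs),
                max(iv.end for iv in all_ivs),
                all_ivs[0].strand,
            )
        model = GeneModel(gene_id=gene_id, strand=span.strand, gene_span=span,
                          transcripts=txs)
        model.validate()
        genes[gene_id] = model
    return genes


def build_composite_exons(gene: GeneModel) -> list[GenomicInterval]:
    """Union of all exon and UTR intervals across the gene's isoforms."""
    all_ivs = [iv for ivs in gene.transcripts.values() for iv in ivs]
    if not all_ivs:
        logger.warning("gene %s has no transcripts; empty composite exon", gene.gene_id)
        return []
    return merge_intervals(all_ivs)


def build_introns(
    gene: GeneModel,
    composite: list[GenomicInterval],
    mask: list[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Gene span minus the composite exons.

    ``mask`` optionally holds same-strand exon intervals of *other* genes to
    subtract as well (cross-gene contamination control; off by default since
    the base procedure is pure per-gene subtraction).
    """
    blocks = list(composite)
    if mask:
        blocks += [
            iv for iv in mask
            if iv.chrom == gene.gene_span.chrom and iv.strand == gene.strand
        ]
    return subtract_intervals(gene.gene_span, blocks)


def build_annotation(
    genes: dict[str, GeneModel], mask_cross_gene: bool = False
) -> AnnotationSet:
    """Derive the :class:`AnnotationSet` for all genes."""
    composites = {gid: build_composite_exons(g) for gid, g in genes.items()}
    introns: dict[str, list[GenomicInterval]] = {}
    for gid, g in genes.items():
        mask = None
        if mask_cross_gene:
            mask = [
                iv
                for other, ivs in composites.items()
                if other != gid
                for iv in ivs
                if iv.chrom == g.gene_span.chrom and iv.strand == g.strand
            ]
        introns[gid] = build_introns(g, composites[gid], mask=mask)
    lengths = {gid: total_width(ivs) for gid, ivs in composites.items()}
    return AnnotationSet(composite_exons=composites, introns=introns,
                         exon_length=lengths)


def utr3_eligibility(gtf_text: str) -> dict[str, bool]:
    """Per-gene flag: do all isoforms share one 3'UTR start coordinate?

    Motif scanning is restricted to genes whose isoforms agree on the 3'UTR
    start (alternative-splicing confound control).  Uses three_prime_utr
    features; the start is the leftmost coordinate on '+' genes and the
    rightmost on '-' genes.  Genes without annotated 3'UTRs are ineligible.
    """
    starts: dict[str, dict[str, int]] = {}
    strands: dict[str, str] = {}
    for lineno, line in enumerate(gtf_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or fields[2] != "three_prime_utr":
            continue
        attrs = _parse_attributes(fields[8])
        gid, tx = attrs.get("gene_id"), attrs.get("transcript_id")
        if gid is None or tx is None:
            raise GTFParseError(f"line {lineno}: three_prime_utr missing ids")
        start0, end = int(fields[3]) - 1, int(fields[4])
        strand = fields[6]
        strands[gid] = strand
        per_tx = starts.setdefault(gid, {})
        if strand == "+":
            per_tx[tx] = min(per_tx.get(tx, start0), start0)
        else:
            per_tx[tx] = max(per_tx.get(tx, end), end)
    return {
        gid: len(set(per_tx.values())) == 1 for gid, per_tx in starts.items()
    }


def write_annotation(
    intervals_by_gene: dict[str, list[GenomicInterval]],
    dialect: str = "GTF",
    feature: str = "exon",
    source: str = "introdelta",
) -> str:
    """Serialize per-gene intervals as GTF or SAF text (1-based closed).

    Round-trip safe: parsing the GTF output reproduces the interval sets.
    """
    if dialect not in ("GTF", "SAF"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'GTF' or 'SAF'")
    lines: list[str] = []
    if dialect == "SAF":
        lines.append("GeneID\tChr\tStart\tEnd\tStrand")
        for gid in sorted(intervals_by_gene):
            for iv in intervals_by_gene[gid]:
                lines.append(f"{gid}\t{iv.chrom}\t{iv.start + 1}\t{iv.end}\t{iv.strand}")
    else:
        lines.append("##provider: introdelta")
        for gid in sorted(intervals_by_gene):
            for iv in intervals_by_gene[gid]:
                attrs = f'gene_id "{gid}"; transcript_id "{gid}";'
                lines.append(
                    "\t".join(
                        [iv.chrom, source, feature, str(iv.start + 1), str(iv.end),
                         ".", iv.strand, ".", attrs]
                    )
                )
    return "\n".join(lines) + "\n"
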