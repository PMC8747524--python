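"""Genic-context and coding-effect annotation of SNPs.

Classifies each SNP against gene models from a GFF3 as promoter
(default: the 1 kb upstream of the strand-aware gene start), exon,
intron or intergenic, and classifies SNPs inside coding sequence as
synonymous or nonsynonymous by strand- and frame-aware codon
substitution under the standard genetic code.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

logger = logging.getLogger(__name__)


class Context(enum.Enum):
    PROMOTER = "promoter"
    EXON = "exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"


#: precedence used when collapsing multi-gene hits to one context per SNP
_PRECEDENCE = {
    Context.EXON: 0,
    Context.INTRON: 1,
    Context.PROMOTER: 2,
    Context.INTERGENIC: 3,
}


@dataclass(frozen=True)
class SnpContext:
    context: Context
    gene_id: str | None


@dataclass(frozen=True)
class CodingEffect:
    gene_id: str
    codon_index: int  # 0-based codon number within the CDS
    codon_pos: int  # 0-based position within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def effect(self) -> str:
        return "SYNONYMOUS" if self.ref_aa == self.alt_aa else "NONSYNONYMOUS"


@dataclass(frozen=True)
class GeneModel:
    """One gene: span, strand, exon and CDS intervals (1-based inclusive).

    CDS intervals are stored in genomic order; ``cds_ok`` is False when
    the total CDS length is not divisible by 3 (the model is flagged,
    not rejected).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"{self.gene_id}: exon outside gene span")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def cds_ok(self) -> bool:
        return self.cds_length % 3 == 0

    def promoter_interval(
        self, promoter_len: int = 1000, strand_aware: bool = True
    ) -> tuple[int, int]:
        """1-based inclusive promoter window upstream of the gene start.

        Strand-aware by default (upstream of the transcription start);
        with ``strand_aware=False`` the literal lower coordinate is
        used for both strands.
        """
        if strand_aware and self.strand == "-":
            return (self.end + 1, self.end + promoter_len)
        return (max(1, self.start - promoter_len), self.start - 1)


def load_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Parse gene models from a GFF3 file (via an in-memory gffutils db)."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = tuple(
            sorted((f.start, f.end) for f in db.children(gene, featuretype="exon"))
        )
        cds = tuple(
            sorted((f.start, f.end) for f in db.children(gene, featuretype="CDS"))
        )
        if not exons and cds:
            exons = cds
        model = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end, exons=exons, cds=cds,
        )
        if cds and not model.cds_ok:
            logger.warning(
                "%s: CDS length %d not divisible by 3", gene.id, model.cds_length
            )
        models.append(model)
    return models


def classify_context(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    promoter_len: int = 1000,
    strand_aware: bool = True,
    chrom_length: int | None = None,
) -> list[SnpContext]:
    """All gene associations of one SNP.

    Inside an exon of a gene -> EXON; inside the gene but not in an
    exon -> INTRON; within ``promoter_len`` upstream of a gene start
    -> PROMOTER.  A SNP hitting several genes reports every
    association; use :func:`primary_context` to collapse with the
    precedence EXON > INTRON > PROMOTER.
    """
    if pos < 1 or (chrom_length is not None and pos > chrom_length):
        raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
    hits: list[SnpContext] = []
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.start <= pos <= g.end:
            in_exon = any(s <= pos <= e for s, e in g.exons)
            hits.append(
                SnpContext(Context.EXON if in_exon else Context.INTRON, g.gene_id)
            )
        else:
            ps, pe = g.promoter_interval(promoter_len, strand_aware)
            if ps <= pos <= pe:
                hits.append(SnpContext(Context.PROMOTER, g.gene_id))
    if not hits:
        hits.append(SnpContext(Context.INTERGENIC, None))
    return hits


def primary_context(hits: Sequence[SnpContext]) -> SnpContext:
    """Collapse multi-gene hits with precedence EXON > INTRON > PROMOTER."""
    return min(hits, key=lambda h: _PRECEDENCE[h.context])


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """1-based inclusive fetch from a pyfaidx Fasta or a plain mapping."""
    seq = reference[chrom]
    if hasattr(seq, "__getitem__") and not isinstance(seq, str):
        return str(seq[start - 1 : end]).upper()
    return str(seq)[start - 1 : end].upper()


def cds_sequence(gene: GeneModel, reference) -> str:
    """Spliced CDS in translation order (reverse-complemented on minus)."""
    parts = [_fetch(reference, gene.chrom, s, e) for s, e in gene.cds]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _cds_index(gene: GeneModel, pos: int) -> int:
    """0-based index of a genomic position within the spliced CDS."""
    offset = 0
    if gene.strand == "+":
        for s, e in gene.cds:
            if s <= pos <= e:
                return offset + (pos - s)
            offset += e - s + 1
    else:
        for s, e in reversed(gene.cds):
            if s <= pos <= e:
                return offset + (e - pos)
            offset += e - s + 1
    raise ValueError(f"position {gene.chrom}:{pos} is not in the CDS of {gene.gene_id}")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def coding_effect(
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
    gene: GeneModel,
    reference,
) -> CodingEffect:
    """Synonymous/nonsynonymous classification of a coding SNP.

    The affected codon is extracted strand- and frame-aware from the
    spliced CDS, the alt base substituted (complemented on the minus
    strand), and both codons translated with the standard genetic code.
    """
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        raise ValueError("coding_effect handles single-base substitutions only")
    if gene.chrom != chrom:
        raise ValueError(f"SNP on {chrom} but gene {gene.gene_id} on {gene.chrom}")
    if not gene.cds_ok:
        logger.warning(
            "%s: CDS length not divisible by 3; effect computed from complete codons",
            gene.gene_id,
        )
    idx = _cds_index(gene, pos)
    cds = cds_sequence(gene, reference)
    ref_base = ref_allele.upper()
    alt_base = alt_allele.upper()
    if gene.strand == "-":
        ref_base = ref_base.translate(_COMPLEMENT)
        alt_base = alt_base.translate(_COMPLEMENT)
    if cds[idx] != ref_base:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: CDS has {cds[idx]}, "
            f"expected {ref_base}"
        )
    codon_index, codon_pos = divmod(idx, 3)
    cstart = codon_index * 3
    ref_codon = cds[cstart : cstart + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"incomplete terminal codon in {gene.gene_id}")
    alt_codon = ref_codon[:codon_pos] + alt_base + ref_codon[codon_pos + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return CodingEffect(
        gene_id=gene.gene_id, codon_index=codon_index, codon_pos=codon_pos,
        ref_codon=ref_codon, alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa,
    )


def annotate_snps(
    snps: Sequence[tuple[str, int, str, str]],
    genes: Sequence[GeneModel],
    reference=None,
    promoter_len: int = 1000,
    strand_aware: bool = True,
) -> "pd.DataFrame":
    """Tabulate primary context (and coding effect where applicable)."""
    import pandas as pd

    by_id = {g.gene_id: g for g in genes}
    rows = []
    for chrom, pos, ref, alt in snps:
        hits = classify_context(chrom, pos, genes, promoter_len, strand_aware)
        top = primary_context(hits)
        effect = ""
        if (
            reference is not None
            and top.context is Context.EXON
            and len(ref) == 1 == len(alt)
        ):
            gene = by_id[top.gene_id]
            try:
                _cds_index(gene, pos)
                eff = coding_effect(chrom, pos, ref, alt, gene, reference)
                effect = eff.effect
            except ValueError:
                effect = "NONCODING_EXON"
        rows.append(
            (chrom, pos, ref, alt, top.context.value, top.gene_id or ".", effect)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "context", "gene", "effect"]
    )
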