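"""Backcross breeding simulator.

Simulates the pedigrees by which near-isogenic lines (NILs) are bred:
a donor x recurrent F1 is backcrossed to the recurrent parent for
``n`` generations, selecting at each generation a progeny plant that
still carries the donor allele at a target locus, then selfed for
``m`` generations (BCnFm).  The result is a mosaic genome whose
donor-derived intervals are known exactly, plus a multi-sample VCF
with read-sampling noise on allele depths, so that every downstream
analysis stage can be scored against truth.

Coordinates are 1-based inclusive in VCF output, 0-based half-open in
BED output and in the in-memory mosaic intervals.

Recombination follows the Haldane model: crossover counts per
chromosome are Poisson with mean genetic-length/100 (no interference),
positions uniform along the chromosome.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DONOR = "donor"
RECURRENT = "recurrent"

#: default seed; the reference genome assembly accession of the crop
DEFAULT_SEED = 97103

# A haplotype is a list of (start, end, origin) tuples, 0-based
# half-open, tiling [0, chrom_length) with no gap or overlap.
Haplotype = list[tuple[int, int, str]]


class SelectionError(RuntimeError):
    """No donor-carrying progeny found within the retry cap."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names, physical lengths (bp) and genetic lengths (cM)."""

    chromosomes: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length, cm in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{name}: physical length must be > 0")
            if cm <= 0:
                raise ValueError(f"{name}: genetic length must be > 0")

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length, _ in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def genetic_length(self, chrom: str) -> float:
        for name, _, cm in self.chromosomes:
            if name == chrom:
                return cm
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(c[1] for c in self.chromosomes)


def default_layout(cm_per_mb: float = 5.0) -> GenomeLayout:
    """Eleven chromosomes (2n = 2x = 22), 30-38 Mb each.

    Genetic lengths default to 5 cM/Mb, a typical genome-wide average
    for a ~360 Mb cucurbit genome with a ~1800 cM linkage map.
    """
    lengths = [36, 34, 30, 32, 34, 30, 32, 30, 38, 32, 30]  # Mb
    chroms = tuple(
        (f"chr{i + 1}", mb * 1_000_000, mb * cm_per_mb)
        for i, mb in enumerate(lengths)
    )
    return GenomeLayout(chromosomes=chroms)


def test_layout(
    n_chrom: int = 2, length_bp: int = 5_000_000, cm_per_mb: float = 5.0
) -> GenomeLayout:
    """Small layout for simulation studies and tests."""
    return GenomeLayout(
        chromosomes=tuple(
            (f"chr{i + 1}", length_bp, length_bp / 1e6 * cm_per_mb)
            for i in range(n_chrom)
        )
    )


@dataclass(frozen=True)
class ParentalVariantSet:
    """Biallelic sites at which the two parents are opposite homozygotes.

    The donor parent carries the alt allele homozygously, the recurrent
    parent the ref allele.  ``sites`` holds (chrom, pos 1-based, ref,
    alt, vtype) with positions strictly increasing within chromosome.
    """

    sites: tuple[tuple[str, int, str, str, str], ...]

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        for chrom, pos, ref, alt, vtype in self.sites:
            if ref == alt:
                raise ValueError(f"{chrom}:{pos} ref == alt")
            if vtype not in ("SNP", "InDel"):
                raise ValueError(f"{chrom}:{pos} bad vtype {vtype}")
            if chrom in last and pos <= last[chrom]:
                raise ValueError(f"{chrom}:{pos} positions not increasing")
            last[chrom] = pos

    def by_chrom(self) -> dict[str, list[tuple[int, str, str, str]]]:
        out: dict[str, list[tuple[int, str, str, str]]] = {}
        for chrom, pos, ref, alt, vtype in self.sites:
            out.setdefault(chrom, []).append((pos, ref, alt, vtype))
        return out

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class MosaicGenome:
    """Diploid genome as two per-chromosome interval mosaics."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]

    def origins_at(self, chrom: str, pos_1based: int) -> tuple[str, str]:
        """Parental origin of each haplotype at a 1-based position."""
        p = pos_1based - 1
        return tuple(_origin_at(h, p) for h in self.haplotypes[chrom])  # type: ignore[return-value]

    def donor_dose(self, chrom: str, pos_1based: int) -> int:
        return sum(o == DONOR for o in self.origins_at(chrom, pos_1based))

    def donor_segments(self, chrom: str) -> list[tuple[int, int]]:
        """Merged 0-based half-open intervals carrying >= 1 donor haplotype."""
        ivs = [
            (s, e)
            for h in self.haplotypes[chrom]
            for (s, e, o) in h
            if o == DONOR
        ]
        return merge_intervals(ivs)


@dataclass(frozen=True)
class PedigreeSpec:
    """A BCnFm pedigree with foreground selection at one locus.

    ``selected_locus`` is a (chrom, pos 1-based) pair retained donor-
    carrying through every generation, or None for unselected pedigrees.
    With ``fix_selected`` (the default), the final selfing generation
    selects a plant donor-homozygous at the locus — a finished NIL is a
    fixed line, so its last selection step fixes the target region.
    """

    n_backcrosses: int
    n_selfings: int
    selected_locus: tuple[str, int] | None = None
    retry_cap: int = 1000
    fix_selected: bool = True

    def __post_init__(self) -> None:
        if self.n_backcrosses < 0:
            raise ValueError("n_backcrosses must be >= 0")
        if self.n_selfings < 0:
            raise ValueError("n_selfings must be >= 0")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _origin_at(hap: Haplotype, pos0: int) -> str:
    for s, e, o in hap:
        if s <= pos0 < e:
            return o
    raise IndexError(f"position {pos0} outside haplotype [0, {hap[-1][1]})")


def _slice(hap: Haplotype, start: int, end: int) -> Haplotype:
    out: Haplotype = []
    for s, e, o in hap:
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            out.append((lo, hi, o))
    return out


def _compact(hap: Haplotype) -> Haplotype:
    out: Haplotype = []
    for seg in hap:
        if out and out[-1][2] == seg[2] and out[-1][1] == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def _gamete_chrom(
    hap_a: Haplotype,
    hap_b: Haplotype,
    length: int,
    cm: float,
    rng: np.random.Generator,
) -> Haplotype:
    n_xo = rng.poisson(cm / 100.0)
    breaks = sorted(int(x) for x in rng.integers(1, length, size=n_xo))
    breaks = [b for i, b in enumerate(breaks) if i == 0 or b != breaks[i - 1]]
    cur = int(rng.integers(2))
    haps = (hap_a, hap_b)
    points = [0, *breaks, length]
    out: Haplotype = []
    for i in range(len(points) - 1):
        out.extend(_slice(haps[cur], points[i], points[i + 1]))
        cur ^= 1
    return _compact(out)


def simulate_meiosis(
    parent: MosaicGenome, layout: GenomeLayout, rng: np.random.Generator
) -> dict[str, Haplotype]:
    """One gamete: per chromosome, a recombinant of the parent's haplotypes.

    Crossover count ~ Poisson(cM/100), positions uniform (Haldane, no
    interference); the starting haplotype is chosen with probability 1/2.
    """
    gamete = {}
    for chrom, length, cm in layout.chromosomes:
        a, b = parent.haplotypes[chrom]
        gamete[chrom] = _gamete_chrom(a, b, length, cm, rng)
    return gamete


def _uniform_genome(layout: GenomeLayout, origin: str) -> dict[str, Haplotype]:
    return {c: [(0, length, origin)] for c, length, _ in layout.chromosomes}


def f1_genome(layout: GenomeLayout) -> MosaicGenome:
    """Donor x recurrent F1: one haplotype from each parent."""
    donor = _uniform_genome(layout, DONOR)
    rec = _uniform_genome(layout, RECURRENT)
    return MosaicGenome(
        haplotypes={c: (donor[c], rec[c]) for c in layout.names}
    )


def donor_fraction(genome: MosaicGenome, layout: GenomeLayout) -> float:
    """Fraction of the diploid genome derived from the donor parent."""
    donor_bp = sum(
        e - s
        for chrom in layout.names
        for hap in genome.haplotypes[chrom]
        for (s, e, o) in hap
        if o == DONOR
    )
    return donor_bp / (2 * layout.total_length)


def _select_child(
    make_child,
    locus: tuple[str, int] | None,
    retry_cap: int,
    min_dose: int = 1,
) -> MosaicGenome:
    for _ in range(max(1, retry_cap)):
        child = make_child()
        if locus is None or child.donor_dose(*locus) >= min_dose:
            return child
    raise SelectionError(
        f"no progeny with donor dose >= {min_dose} at {locus[0]}:{locus[1]} "
        f"within {retry_cap} tries"
    )


def simulate_pedigree(
    spec: PedigreeSpec,
    layout: GenomeLayout,
    rng: np.random.Generator,
) -> tuple[MosaicGenome, dict[str, list[tuple[int, int]]]]:
    """Advance one plant through a BCnFm pedigree.

    Single-progeny advancement: at every generation one offspring is
    drawn, redrawn (up to ``spec.retry_cap`` times) until it carries
    the donor allele at ``selected_locus``.  Selfing is simulated
    generation by generation, so residual heterozygosity can persist
    as in real NILs.

    Returns the final genome and its truth segments: per chromosome,
    the maximal 0-based half-open intervals carrying >= 1 donor
    haplotype.
    """
    if spec.selected_locus is not None:
        chrom, pos = spec.selected_locus
        if chrom not in layout.names or not 1 <= pos <= layout.length(chrom):
            raise ValueError(f"selected locus {chrom}:{pos} outside layout")

    recurrent_hap = _uniform_genome(layout, RECURRENT)

    def backcross(parent: MosaicGenome) -> MosaicGenome:
        g = simulate_meiosis(parent, layout, rng)
        return MosaicGenome(
            haplotypes={c: (g[c], list(recurrent_hap[c])) for c in layout.names}
        )

    def self_cross(parent: MosaicGenome) -> MosaicGenome:
        g1 = simulate_meiosis(parent, layout, rng)
        g2 = simulate_meiosis(parent, layout, rng)
        return MosaicGenome(
            haplotypes={c: (g1[c], g2[c]) for c in layout.names}
        )

    cur = f1_genome(layout)
    for _ in range(spec.n_backcrosses):
        parent = cur
        cur = _select_child(
            lambda: backcross(parent), spec.selected_locus, spec.retry_cap
        )
    for gen in range(spec.n_selfings):
        parent = cur
        final = gen == spec.n_selfings - 1
        min_dose = 2 if (final and spec.fix_selected) else 1
        cur = _select_child(
            lambda: self_cross(parent), spec.selected_locus, spec.retry_cap,
            min_dose=min_dose,
        )
    truth = {c: cur.donor_segments(c) for c in layout.names}
    return cur, truth


# ---------------------------------------------------------------------------
# synthetic reference sequence, variants and gene models
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def emit_reference(
    layout: GenomeLayout, rng: np.random.Generator, path: str | Path
) -> dict[str, np.ndarray]:
    """Write a synthetic random reference genome as FASTA.

    Returns the per-chromosome sequence arrays (dtype S1) so variant
    generation can draw ref alleles consistent with the file.  Intended
    for small test layouts; memory is ~1 byte/bp.
    """
    seqs: dict[str, np.ndarray] = {}
    with open(path, "w") as fh:
        for chrom, length, _ in layout.chromosomes:
            seq = _BASES[rng.integers(0, 4, size=length)]
            seqs[chrom] = seq
            fh.write(f">{chrom}\n")
            raw = seq.tobytes().decode()
            for line in textwrap.wrap(raw, 70):
                fh.write(line + "\n")
    return seqs


def make_parental_variants(
    layout: GenomeLayout,
    rng: np.random.Generator,
    n_snps: int = 213_920,
    n_indels: int = 11_695,
    reference: dict[str, np.ndarray] | None = None,
) -> ParentalVariantSet:
    """Draw divergent loci between the two parents.

    Default counts emulate a genome-wide parental comparison of two
    watermelon inbreds (~214k SNPs, ~12k small InDels); scale them
    down together with the layout for tests.  Sites are uniform along
    the genome, SNP alt drawn from the three non-ref bases, InDels are
    1-4 bp insertions or deletions.  With ``reference`` given, ref
    alleles match the sequence.
    """
    total = layout.total_length
    sites: list[tuple[str, int, str, str, str]] = []
    n_total = n_snps + n_indels
    # allocate per chromosome proportionally to length
    chroms = layout.chromosomes
    counts = rng.multinomial(
        n_total, [length / total for _, length, _ in chroms]
    )
    base_list = "ACGT"
    for (chrom, length, _), k in zip(chroms, counts):
        if k == 0:
            continue
        # leave 10 bp tail room for deletions
        pos = np.sort(
            rng.choice(np.arange(1, max(2, length - 10)), size=min(k, length - 12), replace=False)
        )
        is_indel = rng.random(len(pos)) < (n_indels / n_total)
        for p, ind in zip(pos, is_indel):
            p = int(p)
            if reference is not None:
                ref_base = reference[chrom][p - 1].decode()
            else:
                ref_base = base_list[int(rng.integers(4))]
            if not ind:
                alt = base_list[int(rng.integers(4))]
                while alt == ref_base:
                    alt = base_list[int(rng.integers(4))]
                sites.append((chrom, p, ref_base, alt, "SNP"))
            else:
                k_ins = int(rng.integers(1, 5))
                extra = "".join(
                    base_list[int(b)] for b in rng.integers(0, 4, size=k_ins)
                )
                if rng.random() < 0.5:  # insertion
                    sites.append((chrom, p, ref_base, ref_base + extra, "InDel"))
                else:  # deletion
                    if reference is not None:
                        tail = (
                            reference[chrom][p : p + k_ins].tobytes().decode()
                        )
                    else:
                        tail = extra
                    sites.append((chrom, p, ref_base + tail, ref_base, "InDel"))
    return ParentalVariantSet(sites=tuple(sites))


def emit_gene_models(
    layout: GenomeLayout,
    rng: np.random.Generator,
    path: str | Path,
    gene_spacing: int = 200_000,
    n_exons: int = 3,
    exon_len: int = 300,
    intron_len: int = 500,
) -> int:
    """Write synthetic gene models as GFF3; returns the gene count.

    Genes are placed every ``gene_spacing`` bp with alternating strand,
    ``n_exons`` exons of ``exon_len`` bp (total CDS divisible by 3 when
    exon_len*n_exons is) separated by introns.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length, _ in layout.chromosomes:
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for chrom, length, _ in layout.chromosomes:
            span = n_exons * exon_len + (n_exons - 1) * intron_len
            start = 10_000
            while start + span < length - 10_000:
                n += 1
                gid = f"gene{n:05d}"
                strand = "+" if n % 2 else "-"
                end = start + span - 1
                fh.write(
                    f"{chrom}\tnilscan\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={gid}\n"
                )
                fh.write(
                    f"{chrom}\tnilscan\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={gid}.1;Parent={gid}\n"
                )
                exon_starts = [
                    start + i * (exon_len + intron_len) for i in range(n_exons)
                ]
                exons = [(s, s + exon_len - 1) for s in exon_starts]
                if strand == "-":
                    order = exons[::-1]
                else:
                    order = exons
                phase = 0
                for i, (s, e) in enumerate(exons):
                    fh.write(
                        f"{chrom}\tnilscan\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                        f"ID={gid}.1.exon{i + 1};Parent={gid}.1\n"
                    )
                for s, e in order:
                    fh.write(
                        f"{chrom}\tnilscan\tCDS\t{s}\t{e}\t.\t{strand}\t{phase}\t"
                        f"ID={gid}.1.cds;Parent={gid}.1\n"
                    )
                    phase = (3 - ((e - s + 1) - phase) % 3) % 3
                start += gene_spacing
    return n


# ---------------------------------------------------------------------------
# VCF / BED emission
# ---------------------------------------------------------------------------

def _vcf_header(samples: Sequence[str], layout: GenomeLayout) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=nilscan-breeding-simulator",
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="SNP or InDel">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for chrom, length, _ in layout.chromosomes:
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def emit_vcf(
    genomes: dict[str, MosaicGenome],
    variants: ParentalVariantSet,
    layout: GenomeLayout,
    rng: np.random.Generator,
    vcf_path: str | Path,
    mean_depth: float = 25.0,
    error_rate: float = 0.0,
    mq: float = 60.0,
    truth_dir: str | Path | None = None,
) -> Path:
    """Write a multi-sample VCF with read-sampling noise.

    Per sample and site, DP ~ Poisson(mean_depth) and the alt depth is
    binomial with success probability g/2 shifted by ``error_rate``
    misreads, where g is the true alt dosage (donor allele = alt).
    GT is the *true* genotype; downstream genotyping works from AD/DP.

    When ``truth_dir`` is given, one BED file of donor truth segments
    is written per sample next to the VCF.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    samples = list(genomes)
    vcf_path = Path(vcf_path)
    lines: list[str] = [_vcf_header(samples, layout)]
    n_sites = len(variants.sites)
    # vectorised depth draws: sites x samples
    dp = rng.poisson(mean_depth, size=(n_sites, len(samples)))
    for i, (chrom, pos, ref, alt, vtype) in enumerate(variants.sites):
        fields = [
            chrom, str(pos), ".", ref, alt, "60", "PASS",
            f"MQ={mq:g};TYPE={vtype}", "GT:AD:DP",
        ]
        for j, sample in enumerate(samples):
            g = genomes[sample].donor_dose(chrom, pos)
            d = int(dp[i, j])
            if d == 0:
                fields.append("./.:0,0:0")
                continue
            p_alt = (g / 2) * (1 - error_rate) + (1 - g / 2) * error_rate
            n_alt = int(rng.binomial(d, p_alt))
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}[g]
            fields.append(f"{gt}:{d - n_alt},{n_alt}:{d}")
        lines.append("\t".join(fields) + "\n")
    try:
        vcf_path.write_text("".join(lines))
    except OSError as exc:
        raise OSError(f"failed writing VCF to {vcf_path}: {exc}") from exc
    if truth_dir is not None:
        truth_dir = Path(truth_dir)
        truth_dir.mkdir(parents=True, exist_ok=True)
        for sample in samples:
            bed = truth_dir / f"{sample}.truth.bed"
            with open(bed, "w") as fh:
                for chrom in layout.names:
                    for s, e in genomes[sample].donor_segments(chrom):
                        fh.write(f"{chrom}\t{s}\t{e}\t{sample}\n")
    return vcf_path


def write_pedigree_log(
    path: str | Path, specs: dict[str, PedigreeSpec], seed: int
) -> None:
    """TSV log of the pedigrees simulated in a run."""
    with open(path, "w") as fh:
        fh.write("sample\tn_backcrosses\tn_selfings\tselected_locus\tseed\n")
        for sample, spec in specs.items():
            locus = (
                f"{spec.selected_locus[0]}:{spec.selected_locus[1]}"
                if spec.selected_locus
                else "."
            )
            fh.write(
                f"{sample}\t{spec.n_backcrosses}\t{spec.n_selfings}\t{locus}\t{seed}\n"
            )
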