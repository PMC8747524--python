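"""End-to-end orchestration of the introgression-mapping stages.

A single :class:`RunConfig` (loadable from YAML) drives
simulate -> matrix -> introgress -> cir -> annotate -> caps -> assoc,
with one seed for all randomness.  Each stage writes its outputs under
the run directory and the run report records every output file with a
SHA-256 checksum, so identical config + seed give identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from nilscan import annotation as ann
from nilscan import association as assoc
from nilscan import breeding, caps, introgression
from nilscan.genotypes import GenotypeMatrix, build_matrix

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PedigreeConfig:
    n_backcrosses: int = 3
    n_selfings: int = 3
    select: str | None = None  # "chrom:pos"

    def locus(self) -> tuple[str, int] | None:
        if self.select is None:
            return None
        chrom, pos = self.select.rsplit(":", 1)
        return chrom, int(pos)


@dataclass
class RunConfig:
    """All stage parameters, sample roles and paths for one run."""

    out_dir: str
    seed: int = breeding.DEFAULT_SEED
    donor: str = "DRD"
    # NIL sample name -> recurrent parent sample name
    nils: dict[str, str] = field(
        default_factory=lambda: {"DRDSBA": "SBA", "DRD45NC": "45NC"}
    )
    pedigrees: dict[str, PedigreeConfig] = field(
        default_factory=lambda: {
            "DRDSBA": PedigreeConfig(3, 3, "chr1:2500000"),
            "DRD45NC": PedigreeConfig(2, 3, "chr1:2500000"),
        }
    )
    # simulation
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    cm_per_mb: float = 5.0
    n_snps: int = 2000
    n_indels: int = 100
    mean_depth: float = 25.0
    error_rate: float = 0.001
    emit_reference: bool = True
    gene_spacing: int = 200_000
    # matrix
    min_depth: int = 3
    min_mq: float = 30.0
    # introgression
    window_size: int = 1_000_000
    min_donor_loci: int = 5
    min_donor_frac: float = 0.8
    max_gap_windows: int = 1
    # annotation
    promoter_len: int = 1000
    # caps
    amplicon_halfwidth: int = 150
    max_caps_snps: int = 50
    # association
    alpha: float = 0.05
    phenotype_table: str | None = None
    marker_table: str | None = None

    def validate(self) -> None:
        roles = {self.donor, *self.nils, *self.nils.values()}
        for nil in self.pedigrees:
            if nil not in self.nils:
                raise ValueError(f"pedigree for {nil!r} but no recurrent assigned")
        for nil in self.nils:
            if nil not in self.pedigrees:
                raise ValueError(f"NIL {nil!r} has no pedigree")
            if not self.nils[nil]:
                raise ValueError(f"NIL {nil!r} has no recurrent parent")
        if len(roles) < 2 + len(self.nils):
            raise ValueError("sample roles must be distinct names")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        peds = {
            k: PedigreeConfig(**v) for k, v in raw.pop("pedigrees", {}).items()
        }
        cfg = cls(**{k: v for k, v in raw.items() if k != "pedigrees"})
        if peds:
            cfg.pedigrees = peds
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the stages in dependency order; return the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
    }
    outputs: dict[str, Path] = {}

    def record(stage: str, **files: Path) -> None:
        report["stages"][stage] = {
            "status": "OK",
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()},
        }
        outputs.update(files)

    rng = np.random.default_rng(config.seed)
    layout = breeding.test_layout(
        config.n_chromosomes, config.chrom_length, config.cm_per_mb
    )

    # --- simulate ---------------------------------------------------------
    try:
        reference = None
        files: dict[str, Path] = {}
        if config.emit_reference:
            ref_path = out / "reference.fa"
            reference = breeding.emit_reference(layout, rng, ref_path)
            gff_path = out / "genes.gff3"
            breeding.emit_gene_models(
                layout, rng, gff_path, gene_spacing=config.gene_spacing
            )
            files["reference"] = ref_path
            files["gff"] = gff_path
        variants = breeding.make_parental_variants(
            layout, rng, config.n_snps, config.n_indels, reference
        )
        genomes: dict[str, breeding.MosaicGenome] = {
            config.donor: breeding.MosaicGenome(
                haplotypes={
                    c: ([(0, layout.length(c), breeding.DONOR)],
                        [(0, layout.length(c), breeding.DONOR)])
                    for c in layout.names
                }
            )
        }
        for rec in dict.fromkeys(config.nils.values()):
            genomes[rec] = breeding.MosaicGenome(
                haplotypes={
                    c: ([(0, layout.length(c), breeding.RECURRENT)],
                        [(0, layout.length(c), breeding.RECURRENT)])
                    for c in layout.names
                }
            )
        specs = {}
        for nil, ped in config.pedigrees.items():
            spec = breeding.PedigreeSpec(
                n_backcrosses=ped.n_backcrosses,
                n_selfings=ped.n_selfings,
                selected_locus=ped.locus(),
            )
            specs[nil] = spec
            genomes[nil], _ = breeding.simulate_pedigree(spec, layout, rng)
        vcf_path = out / "simulated.vcf"
        breeding.emit_vcf(
            genomes, variants, layout, rng, vcf_path,
            mean_depth=config.mean_depth, error_rate=config.error_rate,
            truth_dir=out / "truth",
        )
        log_path = out / "pedigrees.tsv"
        breeding.write_pedigree_log(log_path, specs, config.seed)
        files.update(vcf=vcf_path, pedigree_log=log_path)
        record("simulate", **files)
    except Exception as exc:
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    # --- matrix -----------------------------------------------------------
    try:
        matrix = build_matrix(
            vcf_path, min_depth=config.min_depth, min_mq=config.min_mq
        )
        matrix_path = out / "matrix.tsv"
        matrix.to_tsv(matrix_path)
        record("matrix", matrix=matrix_path)
    except Exception as exc:
        raise PipelineError(f"stage 'matrix' failed: {exc}") from exc

    # --- introgress -------------------------------------------------------
    try:
        loci_by_nil = {}
        segments_by_nil = {}
        seg_files = {}
        for nil, rec in config.nils.items():
            loci, tallies = introgression.find_informative_loci(
                matrix, config.donor, rec
            )
            loci_by_nil[nil] = loci
            segs = introgression.find_segments(
                matrix, loci, nil,
                window_size=config.window_size,
                min_donor_loci=config.min_donor_loci,
                min_donor_frac=config.min_donor_frac,
                max_gap_windows=config.max_gap_windows,
            )
            segments_by_nil[nil] = segs
            bed = out / f"{nil}.segments.bed"
            introgression.segments_to_bed(segs, bed)
            seg_files[f"segments_{nil}"] = bed
        record("introgress", **seg_files)
    except Exception as exc:
        raise PipelineError(f"stage 'introgress' failed: {exc}") from exc

    # --- cir --------------------------------------------------------------
    try:
        # informative loci shared by every donor/recurrent comparison
        keysets = [
            {(l.chrom, l.pos, l.ref, l.alt) for l in loci}
            for loci in loci_by_nil.values()
        ]
        shared = set.intersection(*keysets)
        any_loci = next(iter(loci_by_nil.values()))
        common_loci = [
            l for l in any_loci if (l.chrom, l.pos, l.ref, l.alt) in shared
        ]
        cirs = introgression.intersect_nils(
            segments_by_nil, matrix=matrix, loci=common_loci
        )
        cir_bed = out / "cirs.bed"
        introgression.cirs_to_bed(cirs, cir_bed)
        record("cir", cirs=cir_bed)
    except Exception as exc:
        raise PipelineError(f"stage 'cir' failed: {exc}") from exc

    cir_snps = [
        (s.chrom, s.pos, s.ref, s.alt)
        for cir in cirs
        for s in cir.common_snps
    ]

    # --- annotate ---------------------------------------------------------
    if config.emit_reference:
        try:
            genes = ann.load_gene_models(out / "genes.gff3")
            ref_seqs = {
                c: reference[c].tobytes().decode() for c in layout.names
            }
            table = ann.annotate_snps(
                cir_snps, genes, ref_seqs, promoter_len=config.promoter_len
            )
            ann_path = out / "cir_snp_annotation.tsv"
            table.to_csv(ann_path, sep="\t", index=False)
            record("annotate", annotation=ann_path)
        except Exception as exc:
            raise PipelineError(f"stage 'annotate' failed: {exc}") from exc

        # --- caps ---------------------------------------------------------
        try:
            catalogue = caps.load_enzymes()
            candidates = []
            half = config.amplicon_halfwidth
            for chrom, pos, ref_a, alt_a in cir_snps[: config.max_caps_snps]:
                seq = ref_seqs[chrom]
                start = max(0, pos - 1 - half)
                end = min(len(seq), pos - 1 + len(ref_a) + half)
                flank = seq[start:end]
                candidates.extend(
                    caps.differential_digest(
                        flank, pos - 1 - start, ref_a, alt_a, catalogue,
                        chrom=chrom, pos=pos, amplicon_halfwidth=half,
                    )
                )
            caps_path = out / "caps_candidates.tsv"
            caps.candidates_to_tsv(candidates, caps_path)
            record("caps", candidates=caps_path)
        except Exception as exc:
            raise PipelineError(f"stage 'caps' failed: {exc}") from exc

    # --- assoc ------------------------------------------------------------
    try:
        pheno = assoc.load_phenotypes(config.phenotype_table)
        markers = assoc.load_marker_genotypes(config.marker_table)
        results = assoc.analyze_markers(pheno, markers, alpha=config.alpha)
        assoc_path = out / "association.tsv"
        results.to_csv(assoc_path, sep="\t", index=False)
        record("assoc", association=assoc_path)
    except Exception as exc:
        raise PipelineError(f"stage 'assoc' failed: {exc}") from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
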