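import numpy as np
import pytest

from nilscan import breeding
from nilscan.genotypes import build_matrix


def pure_genome(layout, origin):
    return breeding.MosaicGenome(
        haplotypes={
            c: ([(0, layout.length(c), origin)], [(0, layout.length(c), origin)])
            for c in layout.names
        }
    )


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One simulated trio (donor, recurrent, BC3F6 NIL) with its matrix.

    Error-free reads at depth 30, 1000 divergent loci on 2 x 5 Mb
    chromosomes, selection at chr1:2,500,000.
    """
    rng = np.random.default_rng(20240601)
    layout = breeding.test_layout(2, 5_000_000)
    variants = breeding.make_parental_variants(layout, rng, n_snps=950, n_indels=50)
    spec = breeding.PedigreeSpec(3, 5, ("chr1", 2_500_000))
    nil, truth = breeding.simulate_pedigree(spec, layout, rng)
    genomes = {
        "DRD": pure_genome(layout, breeding.DONOR),
        "SBA": pure_genome(layout, breeding.RECURRENT),
        "NIL": nil,
    }
    out = tmp_path_factory.mktemp("sim")
    vcf = breeding.emit_vcf(
        genomes, variants, layout, rng, out / "sim.vcf",
        mean_depth=30.0, error_rate=0.0, truth_dir=out,
    )
    matrix = build_matrix(vcf)
    return {
        "layout": layout,
        "variants": variants,
        "genomes": genomes,
        "truth": truth,
        "vcf": vcf,
        "matrix": matrix,
        "selected_locus": ("chr1", 2_500_000),
    }
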