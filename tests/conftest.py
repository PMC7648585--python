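"""Shared fixtures: tiny VCFs, genotype matrices, and group trees."""

from __future__ import annotations

import numpy as np
import pytest

from ancestry_scan import ComparisonSpec, GenotypeMatrix, Topology

GROUPS = ["mel_A", "mel_B", "mel_C", "silv_A", "silv_B", "silv_C"]

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=scaf1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""

# 5 SNPs (one multiallelic) + 1 indel among them
VCF_BODY = """\
scaf1\t100\t.\tA\tT\t.\tPASS\t.\tGT:DP:GQ\t0/0:30:99\t0/1:25:80\t1/1:30:99
scaf1\t200\t.\tC\tG\t.\tPASS\t.\tGT:DP:GQ\t0/0:4:99\t0/0:30:19\t0/1:30:99
scaf1\t250\t.\tA\tAT\t.\tPASS\t.\tGT:DP:GQ\t0/0:30:99\t0/1:30:99\t0/0:30:99
scaf1\t300\t.\tG\tA,C\t.\tPASS\t.\tGT:DP:GQ\t0/1:30:99\t1/2:30:99\t2/2:30:99
scaf1\t400\t.\tT\tC\t.\tPASS\t.\tGT:DP:GQ\t./.:0:0\t0/0:30:99\t0/1:30:99
scaf1\t500\t.\tG\tT\t.\tPASS\t.\tGT:DP:GQ\t1/1:30:99\t1/1:30:99\t0/0:5:20
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(VCF_HEADER + VCF_BODY)
    return path


def make_gm(genotypes, positions=None, depth=None, gq=None, taxa=None,
            scaffold="scaf1"):
    """Build a GenotypeMatrix from a (sites, samples, 2) array of allele
    indices (-1 for missing)."""
    genotypes = np.asarray(genotypes, dtype=np.int16)
    n_sites, n_samples, _ = genotypes.shape
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    if positions is None:
        positions = 100 * (1 + np.arange(n_sites))
    if taxa is None:
        taxa = {s: s for s in sample_ids}
    else:
        taxa = dict(zip(sample_ids, taxa))
    return GenotypeMatrix(
        scaffold_id=scaffold,
        positions=np.asarray(positions, dtype=np.int64),
        sample_ids=sample_ids,
        genotypes=genotypes,
        depth=(np.full((n_sites, n_samples), 30, dtype=np.int32)
               if depth is None else np.asarray(depth, dtype=np.int32)),
        gq=(np.full((n_sites, n_samples), 99, dtype=np.int32)
            if gq is None else np.asarray(gq, dtype=np.int32)),
        alleles=[("A", "T", "C", "G")] * n_sites,
        sample_to_taxon=taxa,
    )


def default_comparison(n_per_group: int = 3) -> ComparisonSpec:
    """The comparison matching the simulator's default species tree and tract."""
    return ComparisonSpec(
        name="hybrid_zone",
        groups={g: [f"{g}_{i + 1}" for i in range(n_per_group)] for g in GROUPS},
        species_tree=Topology.from_newick("((mel_B,mel_C),(silv_B,silv_C));"),
        focal_pair=("mel_A", "silv_A"),
    )


@pytest.fixture
def comparison():
    return default_comparison()
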