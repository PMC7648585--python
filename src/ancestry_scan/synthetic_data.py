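"""Synthetic genotype data with implanted introgression tracts.

The generator emulates the statistical structure the scan assumes: a
two-clade species tree over six taxon groups, background incomplete-lineage
-sorting (ILS) noise in which a fraction of genomic blocks follow a random
non-species genealogy, and narrow introgressed tracts inside which the
recipient and donor groups are forced to form a cherry.  Each block's
genealogy drops Poisson-distributed mutations per branch onto block sites
(infinite sites within a block, saturating when mutation events exceed the
block length); diploid genotypes pair two independently simulated
haplotypes per sample.  Missing calls and sub-threshold DP/GQ calls are
injected at configured rates.  Output is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .element_delimitation import CandidateElement, Interval
from .genotype_matrix import MISSING, GenotypeMatrix
from .topology_weighting import (Topology, enumerate_topologies, move_leaf,
                                 shared_ancestry_set)

DEFAULT_GROUPS = {
    "mel_A": 3, "mel_B": 3, "mel_C": 3,
    "silv_A": 3, "silv_B": 3, "silv_C": 3,
}
# two clades of three groups each, mirroring three co-distributed races of
# one species plus three relatives from the sister clade
DEFAULT_SPECIES_NEWICK = "(((mel_A,mel_B),mel_C),((silv_A,silv_B),silv_C));"


@dataclass(frozen=True)
class TractSpec:
    """An implanted introgression tract: blocks [block_start, block_end)
    in which `recipient` is forced to be the cherry partner of `donor`."""

    recipient: str
    donor: str
    block_start: int
    block_end: int


@dataclass
class SimulationConfig:
    """Study conditions for one simulated scaffold.

    Defaults follow the scan's operating regime: 100-SNP blocks (one
    tree-building window per block), 200 blocks, 20% background ILS, a
    single 8-block introgression tract, ~3 expected mutations per branch
    per block, and 2% each of missing and low-quality calls.
    """

    groups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    species_newick: str = DEFAULT_SPECIES_NEWICK
    block_length_snps: int = 100
    n_blocks: int = 200
    ils_rate: float = 0.2
    tract_specs: list[TractSpec] = field(
        default_factory=lambda: [TractSpec("mel_A", "silv_A", 96, 104)])
    branch_scale: float = 3.0
    missing_rate: float = 0.02
    low_dp_rate: float = 0.02
    seed: int = 0
    scaffold_id: str = "scaffold_1"
    site_spacing_bp: int = 10

    @property
    def species_tree(self) -> Topology:
        return Topology.from_newick(self.species_newick)

    def __post_init__(self):
        for r in (self.ils_rate, self.missing_rate, self.low_dp_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        covered: dict[str, list[tuple[int, int]]] = {}
        for t in self.tract_specs:
            if not (0 <= t.block_start < t.block_end <= self.n_blocks):
                raise ValueError("tract block range outside [0, n_blocks)")
            for s, e in covered.setdefault(t.recipient, []):
                if t.block_start < e and s < t.block_end:
                    raise ValueError(
                        f"overlapping tracts for recipient {t.recipient!r}")
            covered[t.recipient].append((t.block_start, t.block_end))


@dataclass
class TruthSet:
    """Simulator ground truth for recovery scoring."""

    tracts: list[Interval]            # genomic coordinates of implanted tracts
    block_bounds: list[Interval]      # genomic span of every block
    block_topology_ids: list[str]     # per-block genealogy canonical id
    block_is_target: list[bool]       # genealogy in the tract's target set


def _sample_names(groups: dict[str, int]) -> list[str]:
    return [f"{g}_{i + 1}" for g in groups for i in range(groups[g])]


def simulate(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Generate a diploid genotype matrix plus its truth set."""
    rng = np.random.default_rng(config.seed)
    group_labels = list(config.groups)
    species = config.species_tree
    if set(species.labels) != set(group_labels):
        raise ValueError("species tree labels must match the group names")
    all_topos = enumerate_topologies(tuple(sorted(group_labels)))
    alt_topos = [t for t in all_topos if t != species]

    samples = _sample_names(config.groups)
    n_samples = len(samples)
    # haplotype layout: two haplotypes per sample, grouped by taxon group
    hap_group: list[str] = []
    for g in group_labels:
        hap_group.extend([g] * (2 * config.groups[g]))
    n_hap = len(hap_group)
    hap_of_group = {g: [h for h, gg in enumerate(hap_group) if gg == g]
                    for g in group_labels}

    # forced tract genealogies and their target sets
    tract_topo: dict[int, Topology] = {}
    target_ids: set[str] = set()
    for t in config.tract_specs:
        forced = move_leaf(species, t.recipient, t.donor)
        others = tuple(sorted(set(group_labels) - {t.recipient, t.donor}))
        sp4 = species.restrict(others)
        target_ids |= {x.canonical_id
                       for x in shared_ancestry_set(sp4, (t.recipient, t.donor))}
        for b in range(t.block_start, t.block_end):
            tract_topo[b] = forced

    L = config.block_length_snps
    n_sites_total = L * config.n_blocks
    positions = 1 + config.site_spacing_bp * np.arange(n_sites_total)
    hap = np.zeros((n_sites_total, n_hap), dtype=np.int16)
    block_ids: list[str] = []
    block_is_target: list[bool] = []
    block_bounds: list[Interval] = []

    for b in range(config.n_blocks):
        if b in tract_topo:
            topo = tract_topo[b]
        elif rng.random() < config.ils_rate:
            topo = alt_topos[rng.integers(len(alt_topos))]
        else:
            topo = species
        block_ids.append(topo.canonical_id)
        block_is_target.append(topo.canonical_id in target_ids)
        lo = b * L
        block_bounds.append(Interval(config.scaffold_id,
                                     int(positions[lo]),
                                     int(positions[lo + L - 1])))

        # branch set: every edge of the group topology (carriers = groups on
        # the side away from the smallest group), plus one pendant branch
        # per haplotype (carrier = that haplotype alone)
        branch_carriers: list[np.ndarray] = []
        for side in topo.branch_sides():
            carriers = np.fromiter(
                (h for g in side for h in hap_of_group[g]), dtype=np.intp)
            branch_carriers.append(carriers)
        for h in range(n_hap):
            branch_carriers.append(np.array([h], dtype=np.intp))

        n_mut = rng.poisson(config.branch_scale, size=len(branch_carriers))
        events = np.repeat(np.arange(len(branch_carriers)), n_mut)
        if events.size > L:  # infinite sites saturates: keep a random subset
            events = rng.choice(events, size=L, replace=False)
        sites = rng.choice(L, size=events.size, replace=False)
        for branch, site in zip(events.tolist(), sites.tolist()):
            hap[lo + site, branch_carriers[branch]] = 1

    # keep segregating sites only (the VCF holds variants)
    seg = hap.any(axis=1)
    hap = hap[seg]
    positions = positions[seg]
    n_sites = hap.shape[0]

    # haplotypes 2i and 2i+1 form diploid sample i (both group-ordered)
    genotypes = np.empty((n_sites, n_samples, 2), dtype=np.int16)
    genotypes[:, :, 0] = hap[:, 0::2]
    genotypes[:, :, 1] = hap[:, 1::2]

    depth = np.full((n_sites, n_samples), 30, dtype=np.int32)
    gq = np.full((n_sites, n_samples), 99, dtype=np.int32)
    low = rng.random((n_sites, n_samples)) < config.low_dp_rate
    low_dp_side = rng.random((n_sites, n_samples)) < 0.5
    depth[low & low_dp_side] = rng.integers(0, 5, size=int((low & low_dp_side).sum()))
    gq[low & ~low_dp_side] = rng.integers(0, 20, size=int((low & ~low_dp_side).sum()))
    miss = rng.random((n_sites, n_samples)) < config.missing_rate
    genotypes[miss] = MISSING
    depth[miss] = 0
    gq[miss] = 0

    gm = GenotypeMatrix(
        scaffold_id=config.scaffold_id,
        positions=positions,
        sample_ids=samples,
        genotypes=genotypes,
        depth=depth,
        gq=gq,
        alleles=[("A", "T")] * n_sites,
        sample_to_taxon={s: s.rsplit("_", 1)[0] for s in samples},
    )
    truth = TruthSet(
        tracts=[Interval(config.scaffold_id,
                         int(1 + config.site_spacing_bp * t.block_start * L),
                         int(config.site_spacing_bp * (t.block_end * L - 1) + 1))
                for t in config.tract_specs],
        block_bounds=block_bounds,
        block_topology_ids=block_ids,
        block_is_target=block_is_target,
    )
    return gm, truth


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal VCF v4.2 with GT/DP/GQ.

    Output is byte-identical for identical input (no timestamps).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={gm.scaffold_id}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for s in range(gm.n_sites):
            ref, *alts = gm.alleles[s]
            fields = [gm.scaffold_id, str(int(gm.positions[s])), ".", ref,
                      ",".join(alts), ".", "PASS", ".", "GT:DP:GQ"]
            for i in range(gm.n_samples):
                a, b = gm.genotypes[s, i]
                gt = "./." if a == MISSING else f"{a}/{b}"
                fields.append(f"{gt}:{gm.depth[s, i]}:{gm.gq[s, i]}")
            fh.write("\t".join(fields) + "\n")


def recovery_report(elements: list[CandidateElement],
                    truth: TruthSet) -> dict[str, float]:
    """Score called elements against implanted tracts.

    recall: fraction of truth tracts overlapped by >= 1 element;
    precision: fraction of elements overlapping >= 1 tract (NaN with a flag
    when no elements were called); boundary_error_bp: mean absolute offset
    of matched element edges from tract edges.
    """
    elem_iv = [Interval(e.scaffold_id, e.start, e.end) for e in elements]
    hit_tracts = [any(t.overlaps(e) for e in elem_iv) for t in truth.tracts]
    recall = (float(np.mean(hit_tracts)) if truth.tracts else float("nan"))
    if elem_iv:
        hits = [any(e.overlaps(t) for t in truth.tracts) for e in elem_iv]
        precision = float(np.mean(hits))
        no_elements = False
    else:
        precision = float("nan")
        no_elements = True
    offsets = []
    for e in elem_iv:
        for t in truth.tracts:
            if e.overlaps(t):
                offsets.extend([abs(e.start - t.start), abs(e.end - t.end)])
    return {
        "recall": recall,
        "precision": precision,
        "boundary_error_bp": float(np.mean(offsets)) if offsets else float("nan"),
        "n_elements": float(len(elements)),
        "no_elements_flag": float(no_elements),
    }
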