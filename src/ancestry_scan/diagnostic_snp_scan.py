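"""Diagnostically fixed SNPs between two phenotype-defined taxon groups.

A site is diagnostically fixed when every observed allele in one group is a
single allele, every observed allele in the other group is a single
different allele (a heterozygote disqualifies its group, since it exposes
both alleles), missingness across the contrast samples stays within a cap,
and every sample of each required taxon carries a call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .genotype_matrix import MISSING, GenotypeMatrix


@dataclass
class GroupContrast:
    """Two phenotype groups of taxa, exclusions, and presence rules."""

    name: str
    group_a: set[str]
    group_b: set[str]
    excluded_taxa: set[str] = field(default_factory=set)
    required_taxa: set[str] = field(default_factory=set)
    max_missing_fraction: float = 0.20

    def __post_init__(self):
        self.group_a, self.group_b = set(self.group_a), set(self.group_b)
        self.excluded_taxa = set(self.excluded_taxa)
        self.required_taxa = set(self.required_taxa)
        if self.group_a & self.group_b:
            raise ValueError("contrast groups must be disjoint")
        if self.excluded_taxa & (self.group_a | self.group_b):
            raise ValueError("excluded taxa must be outside both groups")

    @classmethod
    def from_yaml(cls, path) -> "GroupContrast":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            name=doc["name"],
            group_a=set(doc["group_a"]),
            group_b=set(doc["group_b"]),
            excluded_taxa=set(doc.get("excluded_taxa", [])),
            required_taxa=set(doc.get("required_taxa", [])),
            max_missing_fraction=float(doc.get("max_missing_fraction", 0.20)),
        )


@dataclass(frozen=True)
class DiagnosticSNP:
    scaffold_id: str
    position: int
    allele_a: int
    allele_b: int
    n_observed_a: int
    n_observed_b: int


def _group_samples(gm: GenotypeMatrix, taxa: set[str],
                   excluded: set[str]) -> list[int]:
    return [i for i, s in enumerate(gm.sample_ids)
            if gm.sample_to_taxon[s] in taxa
            and gm.sample_to_taxon[s] not in excluded]


def diagnostic_fixed_snps(gm: GenotypeMatrix,
                          contrast: GroupContrast) -> list[DiagnosticSNP]:
    """All diagnostically fixed SNPs for a contrast, sorted by position.

    Fixation is evaluated on observed calls only; the missingness
    denominator is the samples of the two contrast groups (excluded taxa
    removed).
    """
    idx_a = _group_samples(gm, contrast.group_a, contrast.excluded_taxa)
    idx_b = _group_samples(gm, contrast.group_b, contrast.excluded_taxa)
    if not idx_a or not idx_b:
        raise ValueError("a contrast group is empty after exclusions")
    idx_req = [i for i, s in enumerate(gm.sample_ids)
               if gm.sample_to_taxon[s] in contrast.required_taxa]

    gt = gm.genotypes
    missing = gm.missing_mask
    contrast_idx = idx_a + idx_b
    out = []
    for s in range(gm.n_sites):
        if missing[s, contrast_idx].mean() > contrast.max_missing_fraction:
            continue
        if idx_req and missing[s, idx_req].any():
            continue
        obs_a = gt[s, idx_a][~missing[s, idx_a]]
        obs_b = gt[s, idx_b][~missing[s, idx_b]]
        if obs_a.size == 0 or obs_b.size == 0:
            continue
        ua, ub = np.unique(obs_a), np.unique(obs_b)
        if len(ua) == 1 and len(ub) == 1 and ua[0] != ub[0]:
            out.append(DiagnosticSNP(
                scaffold_id=gm.scaffold_id,
                position=int(gm.positions[s]),
                allele_a=int(ua[0]),
                allele_b=int(ub[0]),
                n_observed_a=obs_a.shape[0],
                n_observed_b=obs_b.shape[0],
            ))
    return sorted(out, key=lambda d: d.position)


@dataclass(frozen=True)
class SNPCluster:
    scaffold_id: str
    start: int
    end: int
    n_snps: int


def cluster_snps(snps: list[DiagnosticSNP],
                 max_gap: float = 5000) -> list[SNPCluster]:
    """Single-linkage clustering of position-sorted SNPs: consecutive SNPs
    at most max_gap bp apart join a cluster."""
    clusters = []
    run: list[DiagnosticSNP] = []
    for snp in snps:
        if run and snp.position - run[-1].position > max_gap:
            clusters.append(run)
            run = []
        run.append(snp)
    if run:
        clusters.append(run)
    return [SNPCluster(c[0].scaffold_id, c[0].position, c[-1].position, len(c))
            for c in clusters]
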