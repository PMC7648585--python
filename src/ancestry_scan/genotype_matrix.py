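"""Genotype matrix I/O, quality masking, and site filtering.

The scan consumes a joint multi-sample VCF.  Genotype calls with read depth
< 5 or genotype quality < 20 are marked missing, sites with minor-allele
count < 2 over observed allele copies are removed, and sites with > 10%
missing calls are removed.  Diploid calls are then resolved to one tip per
individual by seeded pseudo-haploidization for distance/tree building.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pysam

MISSING = -1

_SNP_ALLELE = re.compile(r"^[ACGTacgt]$")


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid genotype calls for one scaffold.

    genotypes holds allele indices, shape (n_sites, n_samples, 2); a missing
    call is (-1, -1).  positions are 1-based and strictly increasing.
    """

    scaffold_id: str
    positions: np.ndarray
    sample_ids: list[str]
    genotypes: np.ndarray
    depth: np.ndarray
    gq: np.ndarray
    alleles: list[tuple[str, ...]]
    sample_to_taxon: dict[str, str]
    n_skipped_records: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing (no duplicates)")
        missing = set(self.sample_ids) - set(self.sample_to_taxon)
        if missing:
            raise ValueError(f"sample_to_taxon missing entries for: {sorted(missing)}")
        half = (self.genotypes == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise ValueError("half-missing diploid calls are not allowed")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """(n_sites, n_samples) bool: call is missing."""
        return self.genotypes[:, :, 0] == MISSING

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            positions=self.positions[idx],
            genotypes=self.genotypes[idx],
            depth=self.depth[idx],
            gq=self.gq[idx],
            alleles=[self.alleles[i] for i in np.flatnonzero(np.asarray(idx))]
            if np.asarray(idx).dtype == bool
            else [self.alleles[i] for i in idx],
        )


@dataclass
class HaplotypeMatrix:
    """One allele per site per tip (one tip per individual), plus the seed
    used to resolve heterozygotes, recorded for reproducibility."""

    scaffold_id: str
    positions: np.ndarray
    tip_ids: list[str]
    alleles: np.ndarray  # (n_sites, n_tips), MISSING = -1
    sample_to_taxon: dict[str, str]
    seed: int

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def read_taxon_map(path) -> dict[str, str]:
    """Two-column TSV (sample_id, taxon) -> dict."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, taxon = line.split("\t")[:2]
            out[sample] = taxon
    return out


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    scaf, span = region.split(":", 1)
    start, end = span.split("-")
    return scaf, int(start), int(end)


def read_vcf(path, region: str | None = None,
             taxon_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Load SNP records from a multi-sample VCF into a GenotypeMatrix.

    Biallelic and multiallelic SNPs are loaded; non-SNP records (indels,
    monomorphic reference records, symbolic alleles) are skipped and
    counted.  Absent DP/GQ values are treated as 0.  `region` uses 1-based
    inclusive coordinates (`scaffold` or `scaffold:start-end`); an absent
    region scaffold yields an empty matrix with a warning.
    """
    want_scaf = want_start = want_end = None
    if region is not None:
        want_scaf, want_start, want_end = _parse_region(region)

    positions, gts, dps, gqs, alleles = [], [], [], [], []
    samples: list[str] = []
    scaffold = want_scaf
    n_skipped = 0
    seen_scaffolds = set()

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            seen_scaffolds.add(rec.chrom)
            if want_scaf is not None:
                if rec.chrom != want_scaf:
                    continue
                if want_start is not None and not (want_start <= rec.pos <= want_end):
                    continue
            alts = rec.alts or ()
            is_snp = (len(alts) >= 1 and _SNP_ALLELE.match(rec.ref or "")
                      and all(_SNP_ALLELE.match(a or "") for a in alts))
            if not is_snp:
                n_skipped += 1
                continue
            if want_scaf is None:
                if scaffold is None:
                    scaffold = rec.chrom
                elif rec.chrom != scaffold:
                    raise ValueError(
                        "VCF spans multiple scaffolds; pass a region to select one")
            gt_row = np.full((len(samples), 2), MISSING, dtype=np.int16)
            dp_row = np.zeros(len(samples), dtype=np.int32)
            gq_row = np.zeros(len(samples), dtype=np.int32)
            for i, name in enumerate(samples):
                call = rec.samples[name]
                gt = call.get("GT")
                if gt is not None and len(gt) == 2 and None not in gt:
                    gt_row[i] = gt
                dp = call.get("DP")
                gq = call.get("GQ")
                dp_row[i] = 0 if dp is None else dp
                gq_row[i] = 0 if gq is None else gq
            positions.append(rec.pos)
            gts.append(gt_row)
            dps.append(dp_row)
            gqs.append(gq_row)
            alleles.append((rec.ref,) + tuple(alts))

    if want_scaf is not None and want_scaf not in seen_scaffolds:
        warnings.warn(f"region scaffold {want_scaf!r} absent from VCF; "
                      "returning an empty matrix")
    if taxon_map is None:
        taxon_map = {s: s for s in samples}
    n = len(positions)
    return GenotypeMatrix(
        scaffold_id=scaffold or (want_scaf or ""),
        positions=np.array(positions, dtype=np.int64),
        sample_ids=samples,
        genotypes=(np.stack(gts) if n else
                   np.empty((0, len(samples), 2), dtype=np.int16)),
        depth=(np.stack(dps) if n else np.empty((0, len(samples)), dtype=np.int32)),
        gq=(np.stack(gqs) if n else np.empty((0, len(samples)), dtype=np.int32)),
        alleles=alleles,
        sample_to_taxon=taxon_map,
        n_skipped_records=n_skipped,
    )


def mask_low_quality(gm: GenotypeMatrix, min_depth: int = 5,
                     min_gq: int = 20) -> GenotypeMatrix:
    """Mark calls with depth < min_depth or GQ < min_gq as missing (idempotent)."""
    if min_depth < 0 or min_gq < 0:
        raise ValueError("thresholds must be >= 0")
    bad = (gm.depth < min_depth) | (gm.gq < min_gq)
    genotypes = gm.genotypes.copy()
    genotypes[bad] = MISSING
    return replace(gm, genotypes=genotypes)


def _minor_allele_counts(gm: GenotypeMatrix) -> np.ndarray:
    """Per site: observed allele copies not belonging to the majority allele."""
    out = np.zeros(gm.n_sites, dtype=np.int64)
    flat = gm.genotypes.reshape(gm.n_sites, -1)
    for s in range(gm.n_sites):
        obs = flat[s][flat[s] != MISSING]
        if obs.size == 0:
            continue
        counts = np.bincount(obs)
        out[s] = obs.size - counts.max()
    return out


def filter_mac(gm: GenotypeMatrix, min_minor_allele_count: int = 2) -> GenotypeMatrix:
    """Remove sites whose minor-allele count over observed copies is below
    the threshold (monomorphic sites and singletons at the default of 2)."""
    if min_minor_allele_count < 0:
        raise ValueError("min_minor_allele_count must be >= 0")
    keep = _minor_allele_counts(gm) >= min_minor_allele_count
    return gm.take_sites(keep)


def filter_missingness(gm: GenotypeMatrix,
                       max_missing_fraction: float = 0.10) -> GenotypeMatrix:
    """Remove sites where the missing-call fraction across all samples
    exceeds (strictly) the threshold."""
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = gm.missing_mask.mean(axis=1) if gm.n_samples else np.zeros(gm.n_sites)
    return gm.take_sites(frac <= max_missing_fraction)


def pseudo_haploidize(gm: GenotypeMatrix, seed: int) -> HaplotypeMatrix:
    """Resolve diploid calls to one allele per individual.

    Homozygous calls copy their allele; heterozygous calls pick one of the
    two alleles uniformly using a generator seeded by (seed, site index,
    sample index), so the result is independent of processing order.
    """
    a, b = gm.genotypes[:, :, 0], gm.genotypes[:, :, 1]
    out = a.copy()
    het_sites, het_samples = np.nonzero((a != b) & (a != MISSING))
    for s, i in zip(het_sites.tolist(), het_samples.tolist()):
        ss = np.random.SeedSequence(seed, spawn_key=(s, i))
        pick = np.random.default_rng(ss).integers(2)
        out[s, i] = gm.genotypes[s, i, pick]
    return HaplotypeMatrix(
        scaffold_id=gm.scaffold_id,
        positions=gm.positions.copy(),
        tip_ids=list(gm.sample_ids),
        alleles=out,
        sample_to_taxon=dict(gm.sample_to_taxon),
        seed=seed,
    )
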