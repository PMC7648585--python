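"""End-to-end orchestration: filtered matrix -> forest -> track -> elements."""

from __future__ import annotations

from dataclasses import dataclass

from .element_delimitation import (CandidateElement, Interval, delimit_elements,
                                   intersect_peaks)
from .genotype_matrix import (GenotypeMatrix, HaplotypeMatrix, filter_mac,
                              filter_missingness, mask_low_quality,
                              pseudo_haploidize)
from .shared_ancestry_scan import (ComparisonSpec, Peak, WeightingTrack,
                                   call_peaks, make_track)
from .topology_weighting import weight_tree
from .window_forest import build_forest, make_windows


def filter_genotypes(gm: GenotypeMatrix, *, min_depth: int = 5, min_gq: int = 20,
                     min_mac: int = 2,
                     max_missing: float = 0.10) -> GenotypeMatrix:
    """Quality mask then site filters, in the pipeline's canonical order."""
    gm = mask_low_quality(gm, min_depth=min_depth, min_gq=min_gq)
    gm = filter_mac(gm, min_minor_allele_count=min_mac)
    return filter_missingness(gm, max_missing_fraction=max_missing)


@dataclass
class ScanResult:
    track: WeightingTrack
    peaks: list[Peak]
    n_windows: int
    n_windows_passed: int


def scan_comparison(hm: HaplotypeMatrix, comparison: ComparisonSpec, *,
                    size: int = 100, step: int = 25,
                    min_snps_per_sample: int = 30,
                    threshold: float = 0.95,
                    min_regions: int = 1,
                    exact_limit: int = 100_000,
                    seed: int = 0) -> ScanResult:
    """Windows -> trees -> weightings -> smoothed track -> peaks."""
    windows = make_windows(hm.positions, hm.scaffold_id, size=size, step=step)
    trees, passed = build_forest(hm, windows, min_snps_per_sample)
    weightings = [
        weight_tree(t, comparison.groups, exact_limit=exact_limit, seed=seed)
        if t is not None else None
        for t in trees
    ]
    track = make_track(comparison, windows, weightings, hm.positions,
                       size=size, step=step)
    return ScanResult(
        track=track,
        peaks=call_peaks(track, threshold=threshold, min_regions=min_regions),
        n_windows=len(windows),
        n_windows_passed=sum(passed),
    )


def run_scan(gm: GenotypeMatrix, comparisons: list[ComparisonSpec], *,
             haploidize_seed: int = 0, threshold: float = 0.95,
             require_all: bool = True,
             prior_intervals: list[Interval] | None = None,
             snps=None, **scan_kwargs) -> tuple[dict[str, ScanResult],
                                                list[CandidateElement]]:
    """Filter, scan every comparison, and delimit candidate elements."""
    filtered = filter_genotypes(gm)
    hm = pseudo_haploidize(filtered, seed=haploidize_seed)
    results = {c.name: scan_comparison(hm, c, threshold=threshold, **scan_kwargs)
               for c in comparisons}
    consistent = intersect_peaks({name: r.peaks for name, r in results.items()},
                                 require_all=require_all)
    elements = delimit_elements(consistent, snps=snps,
                                prior_intervals=prior_intervals,
                                supporting_comparisons=list(results))
    return results, elements
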