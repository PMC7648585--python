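"""Genome track of shared-ancestry signal: target weighting, smoothing, peaks.

For each window the raw signal is the summed weight of the five
shared-ancestry topologies of a comparison.  The smoothed track is, for
each step-sized region of the scaffold, the mean raw value of all (up to
size/step) windows covering that region; peaks are maximal runs of regions
at or above a threshold, reported as 1-based inclusive genomic intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .topology_weighting import Topology, Weighting, shared_ancestry_set
from .window_forest import WindowSpec


@dataclass
class ComparisonSpec:
    """Six taxon groups, the species tree on the four non-focal groups, and
    the focal comimetic pair; target_set is derived and cached."""

    name: str
    groups: dict[str, list[str]]  # group label -> sample/tip ids
    species_tree: Topology        # on the 4 non-focal groups
    focal_pair: tuple[str, str]
    target_set: list[Topology] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if len(self.groups) != 6:
            raise ValueError("a comparison requires exactly six groups")
        expected = set(self.groups) - set(self.focal_pair)
        if set(self.species_tree.labels) != expected:
            raise ValueError("species_tree must cover exactly the four non-focal groups")
        if self.target_set is None:
            self.target_set = shared_ancestry_set(self.species_tree,
                                                  tuple(self.focal_pair))

    @property
    def target_ids(self) -> list[str]:
        return [t.canonical_id for t in self.target_set]

    @classmethod
    def from_yaml(cls, path) -> "ComparisonSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            name=doc["name"],
            groups={g: list(v) for g, v in doc["groups"].items()},
            species_tree=Topology.from_newick(doc["species_tree"]),
            focal_pair=tuple(doc["focal_pair"]),
        )


def target_signal(weighting: Weighting, spec: ComparisonSpec) -> float:
    """Summed weight of the five shared-ancestry topologies, in [0, 1]."""
    return float(sum(weighting.weights[tid] for tid in spec.target_ids))


@dataclass
class Region:
    """One step-sized stretch of the scaffold with its smoothed weighting."""

    snp_index_start: int
    snp_index_end: int
    genomic_start: int
    genomic_end: int
    smoothed: float
    n_covering_windows: int


@dataclass
class WeightingTrack:
    """Raw per-window and smoothed per-region shared-ancestry signal."""

    comparison: str
    scaffold_id: str
    windows: list[WindowSpec]
    raw: np.ndarray          # per window, NaN where no tree was built
    regions: list[Region]

    @property
    def smoothed(self) -> np.ndarray:
        return np.array([r.smoothed for r in self.regions])


def smooth_track(raw, windows: list[WindowSpec], positions,
                 size: int = 100, step: int = 25) -> list[Region]:
    """Mean of all windows overlapping each step-sized region.

    Interior regions are covered by size/step windows; scaffold edges are
    averaged over the available windows only (no padding).  Windows without
    a value (NaN) are excluded from the mean.
    """
    raw = np.asarray(raw, dtype=float)
    positions = np.asarray(positions)
    n_windows = len(windows)
    if n_windows == 0:
        return []
    span = size // step  # windows covering an interior region
    n_regions = n_windows + span - 1
    n_sites = len(positions)
    out = []
    for j in range(n_regions):
        lo = max(0, j - span + 1)
        hi = min(j, n_windows - 1)
        vals = raw[lo:hi + 1]
        vals = vals[~np.isnan(vals)]
        snp_start = j * step
        snp_end = min(snp_start + step, n_sites)
        out.append(Region(
            snp_index_start=snp_start,
            snp_index_end=snp_end,
            genomic_start=int(positions[snp_start]),
            genomic_end=int(positions[snp_end - 1]),
            smoothed=float(vals.mean()) if vals.size else float("nan"),
            n_covering_windows=int(vals.size),
        ))
    return out


def make_track(comparison: ComparisonSpec, windows: list[WindowSpec],
               weightings: list[Weighting | None], positions,
               size: int = 100, step: int = 25) -> WeightingTrack:
    """Assemble raw + smoothed track from per-window weightings (None where
    the window produced no tree)."""
    raw = np.array([target_signal(w, comparison) if w is not None else np.nan
                    for w in weightings])
    scaffold = windows[0].scaffold_id if windows else ""
    return WeightingTrack(
        comparison=comparison.name,
        scaffold_id=scaffold,
        windows=windows,
        raw=raw,
        regions=smooth_track(raw, windows, positions, size=size, step=step),
    )


@dataclass(frozen=True)
class Peak:
    """Maximal run of regions with smoothed signal >= threshold."""

    scaffold_id: str
    start: int   # 1-based inclusive genomic
    end: int
    height: float
    n_regions: int
    comparison: str = ""


def call_peaks(track: WeightingTrack, threshold: float = 1.0,
               min_regions: int = 1) -> list[Peak]:
    """Maximal runs of >= min_regions consecutive regions with smoothed
    value >= threshold, as genomic intervals spanning the first SNP of the
    first region to the last SNP of the last region."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    peaks = []
    run: list[Region] = []
    for region in track.regions + [None]:  # type: ignore[list-item]
        above = region is not None and region.smoothed >= threshold
        if above:
            run.append(region)
            continue
        if len(run) >= min_regions:
            peaks.append(Peak(
                scaffold_id=track.scaffold_id,
                start=run[0].genomic_start,
                end=run[-1].genomic_end,
                height=max(r.smoothed for r in run),
                n_regions=len(run),
                comparison=track.comparison,
            ))
        run = []
    return peaks
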