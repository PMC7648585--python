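"""Candidate regulatory element delimitation.

Peaks that are consistent across comparisons, optionally constrained to
previously published intervals, are combined with diagnostic-SNP clusters
into candidate cis-regulatory elements.  Coordinates are 1-based inclusive
internally; BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .diagnostic_snp_scan import DiagnosticSNP
from .shared_ancestry_scan import Peak


@dataclass(frozen=True)
class Interval:
    scaffold_id: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("interval start must be <= end")

    def overlaps(self, other: "Interval") -> bool:
        return (self.scaffold_id == other.scaffold_id
                and self.start <= other.end and other.start <= self.end)

    def clip(self, other: "Interval") -> "Interval":
        if not self.overlaps(other):
            raise ValueError("cannot clip to a non-overlapping interval")
        return Interval(self.scaffold_id,
                        max(self.start, other.start), min(self.end, other.end))


@dataclass
class CandidateElement:
    name: str
    scaffold_id: str
    start: int
    end: int
    supporting_comparisons: list[str]
    n_diagnostic_snps: int = 0
    prior_interval: Interval | None = None

    @property
    def has_snp_support(self) -> bool:
        return self.n_diagnostic_snps > 0


def _merge(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for iv in sorted(intervals, key=lambda x: (x.scaffold_id, x.start, x.end)):
        if out and out[-1].overlaps(iv):
            out[-1] = Interval(iv.scaffold_id, out[-1].start,
                               max(out[-1].end, iv.end))
        else:
            out.append(iv)
    return out


def _as_interval(peak) -> Interval:
    if isinstance(peak, Interval):
        return peak
    return Interval(peak.scaffold_id, peak.start, peak.end)


def intersect_peaks(peak_sets: dict[str, list[Peak]],
                    require_all: bool = True) -> list[Interval]:
    """Intervals consistent across comparisons.

    require_all: the pointwise intersection of peak coverage over every
    comparison; otherwise the union of stretches covered by >= 2
    comparisons (>= 1 when only one comparison is given).
    """
    if not peak_sets:
        raise ValueError("need at least one comparison")
    per_comp = {name: _merge([_as_interval(p) for p in peaks])
                for name, peaks in peak_sets.items()}
    events: list[tuple[str, int, int]] = []  # (scaffold, pos, delta)
    for ivs in per_comp.values():
        for iv in ivs:
            events.append((iv.scaffold_id, iv.start, +1))
            events.append((iv.scaffold_id, iv.end + 1, -1))
    need = len(per_comp) if require_all else min(2, len(per_comp))
    out: list[Interval] = []
    events.sort()
    depth = 0
    open_start: int | None = None
    current_scaf: str | None = None
    for scaf, pos, delta in events:
        if scaf != current_scaf:
            depth = 0
            open_start = None
            current_scaf = scaf
        prev = depth
        depth += delta
        if prev < need <= depth:
            open_start = pos
        elif prev >= need > depth and open_start is not None:
            out.append(Interval(scaf, open_start, pos - 1))
            open_start = None
    return out


def delimit_elements(intervals: list[Interval],
                     snps: list[DiagnosticSNP] | None = None,
                     prior_intervals: list[Interval] | None = None,
                     supporting_comparisons: list[str] | None = None,
                     name_prefix: str = "element") -> list[CandidateElement]:
    """Turn consistent intervals into candidate elements.

    Each interval is clipped to the prior interval it overlaps when priors
    are given (intervals overlapping no prior are dropped, since the search
    is constrained to previously delimited regions); diagnostic SNPs are
    counted by position containment.  Elements without SNP support are
    retained but flagged (n_diagnostic_snps == 0).
    """
    snps = snps or []
    elements = []
    for iv in intervals:
        prior = None
        clipped = iv
        if prior_intervals:
            for p in prior_intervals:
                if p.scaffold_id != iv.scaffold_id:
                    raise ValueError(
                        f"prior interval on scaffold {p.scaffold_id!r} does not "
                        f"match {iv.scaffold_id!r}")
                if p.overlaps(iv):
                    prior = p
                    clipped = iv.clip(p)
                    break
            if prior is None:
                continue
        n_snps = sum(1 for s in snps
                     if s.scaffold_id == clipped.scaffold_id
                     and clipped.start <= s.position <= clipped.end)
        elements.append(CandidateElement(
            name=f"{name_prefix}{len(elements) + 1}",
            scaffold_id=clipped.scaffold_id,
            start=clipped.start,
            end=clipped.end,
            supporting_comparisons=list(supporting_comparisons or []),
            n_diagnostic_snps=n_snps,
            prior_interval=prior,
        ))
    return elements


def to_bed_line(iv) -> str:
    """1-based inclusive interval -> BED (0-based half-open) line."""
    return f"{iv.scaffold_id}\t{iv.start - 1}\t{iv.end}"
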