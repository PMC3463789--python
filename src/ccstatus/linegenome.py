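"""Line-level genome merge, residual heterozygosity, and classification.

The mosaics of the most recent obligate ancestor pair are jointly reduced
to a *line genome*: intervals fixed for a single founder plus segregating
regions annotated with the set of founders still segregating.  Maximum
residual heterozygosity is the total segregating length divided by the
tracked genome length, and the line is classified by genome-wide
homozygosity: >= 98 % complete, >= 90 % distributable, else in progress
(boundaries inclusive).

Two passes find segregating regions.  Within an ancestor, a heterozygous
mosaic segment becomes a region whose boundaries tighten to the closest
heterozygous genotype calls bounding the run.  Between ancestors, any
interval where the union of founder haplotypes across the pair holds two
or more distinct founders becomes a region, with boundaries snapped to
the nearest informative genotypes flanking the discordance.  Regions in
which consecutive informative markers are consistently inconsistent with
the founder-table prediction in every genotyped ancestor are treated as a
feature of the line's haplotype and reclassified as fixed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import FOUNDERS, chrom_sort_key, genome_length_mb, validate_chrom_lengths
from .reconstruct import DiplotypeMosaic, MarkerPanel, Segment, _FIDX

__all__ = [
    "SegregatingRegion",
    "FixedSegment",
    "LineGenome",
    "LineStatusReport",
    "classify_line",
    "residual_heterozygosity",
    "merge_segregating_regions",
    "within_ancestor_segregating",
    "between_ancestor_segregating",
    "apply_fixed_override",
    "build_line_genome",
    "write_line_genome",
    "read_line_genome",
]

COMPLETE_HOMOZYGOSITY_PERCENT = 98.0
DISTRIBUTABLE_HOMOZYGOSITY_PERCENT = 90.0

_EDGE_TOL = 1e-9  # Mb; guards float jitter when tiling intervals


@dataclass(frozen=True)
class SegregatingRegion:
    """Interval still segregating between >= 2 founders."""

    chrom: str
    start_mb: float
    end_mb: float
    founders: frozenset[str]

    def __post_init__(self) -> None:
        if not self.end_mb > self.start_mb:
            raise ValueError(
                f"segregating region must have end > start "
                f"({self.chrom}:{self.start_mb}-{self.end_mb})"
            )
        if not self.founders <= set(FOUNDERS) or len(self.founders) < 2:
            raise ValueError(f"bad founder set {sorted(self.founders)}")

    @property
    def length_mb(self) -> float:
        return self.end_mb - self.start_mb

    @property
    def founder_code(self) -> str:
        return "".join(sorted(self.founders))


@dataclass(frozen=True)
class FixedSegment:
    """Interval fixed for a single founder."""

    chrom: str
    start_mb: float
    end_mb: float
    founder: str

    @property
    def length_mb(self) -> float:
        return self.end_mb - self.start_mb


@dataclass
class LineGenome:
    """Fixed segments plus segregating regions tiling the tracked genome."""

    line_id: str
    fixed: list[FixedSegment]
    segregating: list[SegregatingRegion]
    chrom_lengths: dict[str, float]

    def fixed_length_mb(self) -> float:
        return sum(s.length_mb for s in self.fixed)

    def segregating_length_mb(self) -> float:
        return sum(r.length_mb for r in self.segregating)


@dataclass
class LineStatusReport:
    """Classification summary for one line."""

    line_id: str
    het_percent: float
    status: str
    ancestor_sire: str
    ancestor_dam: str
    genome_length_mb: float
    n_segregating_regions: int = 0
    segregating_mb: float = 0.0
    n_markers: int = 0

    @property
    def homozygosity_percent(self) -> float:
        return 100.0 - self.het_percent

    def to_dict(self) -> dict:
        return {
            "line_id": self.line_id,
            "het_percent": self.het_percent,
            "homozygosity_percent": self.homozygosity_percent,
            "status": self.status,
            "ancestor_sire": self.ancestor_sire,
            "ancestor_dam": self.ancestor_dam,
            "genome_length_mb": self.genome_length_mb,
            "n_segregating_regions": self.n_segregating_regions,
            "segregating_mb": self.segregating_mb,
            "n_markers": self.n_markers,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# classification and heterozygosity
# ---------------------------------------------------------------------------


def classify_line(het_percent: float) -> str:
    """Classify by homozygosity: >=98 complete, >=90 distributable, else in_progress."""
    if not 0.0 <= het_percent <= 100.0:
        raise ValueError(f"het_percent must be in [0, 100], got {het_percent}")
    homozygosity = 100.0 - het_percent
    if homozygosity >= COMPLETE_HOMOZYGOSITY_PERCENT:
        return "complete"
    if homozygosity >= DISTRIBUTABLE_HOMOZYGOSITY_PERCENT:
        return "distributable"
    return "in_progress"


def merge_segregating_regions(
    regions: Iterable[SegregatingRegion],
) -> list[SegregatingRegion]:
    """Union overlapping/touching regions per chromosome, merging founder sets."""
    by_chrom: dict[str, list[SegregatingRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[SegregatingRegion] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start_mb, r.end_mb))
        cur_start, cur_end, cur_f = rs[0].start_mb, rs[0].end_mb, set(rs[0].founders)
        for r in rs[1:]:
            if r.start_mb <= cur_end + _EDGE_TOL:
                cur_end = max(cur_end, r.end_mb)
                cur_f |= r.founders
            else:
                merged.append(
                    SegregatingRegion(chrom, cur_start, cur_end, frozenset(cur_f))
                )
                cur_start, cur_end, cur_f = r.start_mb, r.end_mb, set(r.founders)
        merged.append(SegregatingRegion(chrom, cur_start, cur_end, frozenset(cur_f)))
    return merged


def residual_heterozygosity(
    regions: Iterable[SegregatingRegion],
    chrom_lengths: Mapping[str, float],
) -> float:
    """Total segregating length over tracked genome length, as a percentage.

    Overlapping regions are unioned first; a region outside its
    chromosome's bounds is fatal.
    """
    chrom_lengths = validate_chrom_lengths(chrom_lengths)
    merged = merge_segregating_regions(regions)
    total = 0.0
    for r in merged:
        if r.chrom not in chrom_lengths:
            raise ValueError(f"region on untracked chromosome {r.chrom}")
        if r.start_mb < -_EDGE_TOL or r.end_mb > chrom_lengths[r.chrom] + _EDGE_TOL:
            raise ValueError(
                f"region {r.chrom}:{r.start_mb}-{r.end_mb} outside chromosome "
                f"bounds [0, {chrom_lengths[r.chrom]}]"
            )
        total += r.length_mb
    return 100.0 * total / genome_length_mb(chrom_lengths)


# ---------------------------------------------------------------------------
# segregating-region discovery
# ---------------------------------------------------------------------------


def within_ancestor_segregating(
    mosaic: DiplotypeMosaic,
    calls: np.ndarray,
    panel: MarkerPanel,
) -> list[SegregatingRegion]:
    """Heterozygous mosaic segments tightened to their bounding het calls.

    Each heterozygous-state segment becomes a region running from the
    first to the last heterozygous genotype call it contains; a
    heterozygous segment with no supporting het call is dropped with a
    warning (reconstruction/genotype disagreement).
    """
    calls = np.asarray(calls, dtype=np.int8)
    regions = []
    for seg in mosaic.segments:
        if seg.homozygous:
            continue
        idx = np.arange(seg.first_idx, seg.last_idx + 1)
        het = idx[calls[idx] == 1]
        if len(het) == 0 or panel.pos_mb[het[-1]] <= panel.pos_mb[het[0]]:
            warnings.warn(
                f"heterozygous segment {seg.chrom}:{seg.start_mb:.3f}-"
                f"{seg.end_mb:.3f} ({'/'.join(seg.state)}) has "
                f"{len(het)} het call(s); dropped",
                stacklevel=2,
            )
            continue
        regions.append(
            SegregatingRegion(
                chrom=seg.chrom,
                start_mb=float(panel.pos_mb[het[0]]),
                end_mb=float(panel.pos_mb[het[-1]]),
                founders=frozenset(seg.state),
            )
        )
    return regions


def _founder_union_track(
    mosaics: Sequence[DiplotypeMosaic], chrom: str
) -> list[tuple[float, float, frozenset[str]]]:
    """Atomic intervals with the union of founder haplotypes across animals."""
    edges: set[float] = set()
    per_animal: list[list[Segment]] = []
    for m in mosaics:
        segs = m.by_chrom(chrom)
        per_animal.append(segs)
        for s in segs:
            edges.add(s.start_mb)
            edges.add(s.end_mb)
    cuts = sorted(edges)
    track = []
    for a, b in zip(cuts, cuts[1:]):
        if b - a <= _EDGE_TOL:
            continue
        mid = (a + b) / 2.0
        union: set[str] = set()
        for segs in per_animal:
            for s in segs:
                if s.start_mb <= mid < s.end_mb:
                    union.update(s.state)
                    break
        track.append((a, b, frozenset(union)))
    return track


def _nearest_informative(
    panel: MarkerPanel, chrom: str, founders: frozenset[str]
) -> np.ndarray:
    """Positions of markers on ``chrom`` informative within ``founders``."""
    sl = panel.chrom_slice(chrom)
    cols = [_FIDX[f] for f in sorted(founders)]
    sub = panel.alleles[sl][:, cols]
    mask = (sub == 0).any(axis=1) & (sub == 1).any(axis=1)
    if not mask.any():  # fall back to panel-wide informativeness
        mask = panel.informative()[sl]
    return panel.pos_mb[sl][mask]


def between_ancestor_segregating(
    mosaics: Sequence[DiplotypeMosaic],
    panel: MarkerPanel,
    chrom_lengths: Mapping[str, float] | None = None,
) -> list[SegregatingRegion]:
    """Intervals where the ancestors' joint haplotypes hold >= 2 founders.

    The joint haplotype multiset is 4 autosomal haplotypes for a pair (3
    on the X when one ancestor is male).  Discordant intervals are merged
    and their boundaries snapped outward to the nearest genotyped-
    informative marker positions flanking the discordance (chromosome
    ends when none exists), so the region always covers the discordance.
    """
    if len(mosaics) < 2:
        raise ValueError("need at least two ancestor mosaics")
    chroms = mosaics[0].chromosomes
    for m in mosaics[1:]:
        if m.chromosomes != chroms:
            raise ValueError("ancestor mosaics are on mismatched panels")
    regions = []
    for chrom in chroms:
        track = _founder_union_track(mosaics, chrom)
        if not track:
            continue
        chrom_end = max(b for _, b, _ in track)
        if chrom_lengths is not None:
            chrom_end = float(chrom_lengths[chrom])
        # merge contiguous discordant atoms
        runs: list[tuple[float, float, set[str]]] = []
        for a, b, union in track:
            if len(union) < 2:
                continue
            if runs and abs(runs[-1][1] - a) <= _EDGE_TOL:
                runs[-1] = (runs[-1][0], b, runs[-1][2] | union)
            else:
                runs.append((a, b, set(union)))
        for a, b, founders in runs:
            pos = _nearest_informative(panel, chrom, frozenset(founders))
            left = pos[pos <= a + _EDGE_TOL]
            right = pos[pos >= b - _EDGE_TOL]
            start = float(left[-1]) if len(left) else 0.0
            end = float(right[0]) if len(right) else chrom_end
            regions.append(
                SegregatingRegion(chrom, start, max(end, start + _EDGE_TOL), frozenset(founders))
            )
    return merge_segregating_regions(regions) if regions else []


def _state_at(mosaic: DiplotypeMosaic, chrom: str, pos: float) -> tuple[str, ...] | None:
    for s in mosaic.by_chrom(chrom):
        if s.start_mb <= pos < s.end_mb:
            return s.state
    return None


def _implied_genotype(state: tuple[str, ...], alleles: np.ndarray) -> int:
    a1 = int(alleles[_FIDX[state[0]]])
    a2 = int(alleles[_FIDX[state[-1]]])
    if a1 < 0 or a2 < 0:
        return -9
    return a1 + a2


def apply_fixed_override(
    regions: Iterable[SegregatingRegion],
    calls_by_animal: Mapping[str, np.ndarray],
    panel: MarkerPanel,
    k: int = 3,
    mosaics: Mapping[str, DiplotypeMosaic] | None = None,
) -> list[SegregatingRegion]:
    """Drop regions that are consistently inconsistent with the founder table.

    A region is reclassified as fixed (removed) when >= ``k`` consecutive
    informative markers inside it carry the same non-missing call in ALL
    genotyped ancestors while that call disagrees with the founder-table
    prediction of every ancestor's assigned haplotype: we take such runs
    to be a feature of the line's haplotype rather than true segregation.
    """
    if k < 2:
        raise ValueError(f"run length k must be >= 2, got {k}")
    calls_by_animal = {a: np.asarray(c, dtype=np.int8) for a, c in calls_by_animal.items()}
    informative = panel.informative()
    retained = []
    for region in regions:
        sl = panel.chrom_slice(region.chrom)
        idx = np.arange(sl.start, sl.stop)
        inside = (
            (panel.pos_mb[idx] >= region.start_mb - _EDGE_TOL)
            & (panel.pos_mb[idx] <= region.end_mb + _EDGE_TOL)
            & informative[idx]
        )
        marker_idx = idx[inside]
        run = 0
        overridden = False
        for i in marker_idx:
            calls_here = [c[i] for c in calls_by_animal.values()]
            same_call = len(set(calls_here)) == 1 and calls_here[0] >= 0
            discordant = same_call
            if same_call:
                pos = float(panel.pos_mb[i])
                for animal, c in calls_by_animal.items():
                    if mosaics is not None and animal in mosaics:
                        state = _state_at(mosaics[animal], region.chrom, pos)
                    else:
                        state = None
                    if state is None:
                        discordant = False
                        break
                    expected = _implied_genotype(state, panel.alleles[i])
                    if expected < 0 or expected == c[i]:
                        discordant = False
                        break
            run = run + 1 if discordant else 0
            if run >= k:
                overridden = True
                break
        if not overridden:
            retained.append(region)
    return retained


# ---------------------------------------------------------------------------
# line genome assembly
# ---------------------------------------------------------------------------


def _subtract(
    start: float, end: float, blocks: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Pieces of [start, end) not covered by sorted, disjoint ``blocks``."""
    out = []
    cur = start
    for a, b in blocks:
        if b <= cur + _EDGE_TOL or a >= end - _EDGE_TOL:
            continue
        if a > cur + _EDGE_TOL:
            out.append((cur, min(a, end)))
        cur = max(cur, b)
    if cur < end - _EDGE_TOL:
        out.append((cur, end))
    return out


def _majority_founder(
    mosaics: Sequence[DiplotypeMosaic], chrom: str, start: float, end: float
) -> str:
    weight: dict[str, float] = {}
    for m in mosaics:
        for s in m.by_chrom(chrom):
            ov = min(s.end_mb, end) - max(s.start_mb, start)
            if ov > 0:
                for f in s.state:
                    weight[f] = weight.get(f, 0.0) + ov
    if not weight:
        raise ValueError(f"no mosaic coverage in {chrom}:{start}-{end}")
    top = max(weight.values())
    return sorted(f for f, w in weight.items() if w == top)[0]


def build_line_genome(
    mosaics: Sequence[DiplotypeMosaic],
    regions: Iterable[SegregatingRegion],
    chrom_lengths: Mapping[str, float],
    override_fixed: Iterable[SegregatingRegion] = (),
    line_id: str = "",
) -> LineGenome:
    """Assemble the tiling line genome from ancestor mosaics and regions.

    Outside segregating regions every ancestor haplotype must agree on a
    single founder; disagreement there indicates an upstream bug and is
    fatal.  Intervals removed by the fixed override are labeled with the
    length-weighted majority founder of the ancestors' haplotypes.
    """
    chrom_lengths = validate_chrom_lengths(chrom_lengths)
    regions = list(regions)
    override_fixed = list(override_fixed)
    segregating = merge_segregating_regions(regions) if regions else []
    overrides = merge_segregating_regions(override_fixed) if override_fixed else []
    fixed: list[FixedSegment] = []
    chroms = mosaics[0].chromosomes if mosaics else sorted(chrom_lengths, key=chrom_sort_key)
    for chrom in chroms:
        clen = chrom_lengths[chrom]
        seg_blocks = sorted(
            (max(0.0, r.start_mb), min(clen, r.end_mb))
            for r in segregating
            if r.chrom == chrom
        )
        ov_blocks = sorted(
            (max(0.0, r.start_mb), min(clen, r.end_mb))
            for r in overrides
            if r.chrom == chrom
        )
        for a, b in ov_blocks:
            for fa, fb in _subtract(a, b, seg_blocks):
                fixed.append(FixedSegment(chrom, fa, fb, _majority_founder(mosaics, chrom, fa, fb)))
        blocked = sorted(seg_blocks + ov_blocks)
        for fa, fb in _subtract(0.0, clen, blocked):
            # split at mosaic boundaries so a single-founder check is exact
            cuts = {fa, fb}
            for m in mosaics:
                for s in m.by_chrom(chrom):
                    for e in (s.start_mb, s.end_mb):
                        if fa < e < fb:
                            cuts.add(e)
            pieces = sorted(cuts)
            for pa, pb in zip(pieces, pieces[1:]):
                if pb - pa <= _EDGE_TOL:
                    continue
                mid = (pa + pb) / 2.0
                union: set[str] = set()
                for m in mosaics:
                    st = _state_at(m, chrom, mid)
                    if st is not None:
                        union.update(st)
                if len(union) != 1:
                    raise ValueError(
                        f"ancestors fixed for different founders outside any "
                        f"segregating region at {chrom}:{pa:.4f}-{pb:.4f} "
                        f"({sorted(union)}); upstream inconsistency"
                    )
                fixed.append(FixedSegment(chrom, pa, pb, union.pop()))
    # merge adjacent fixed segments with the same founder
    fixed.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start_mb))
    merged_fixed: list[FixedSegment] = []
    for s in fixed:
        prev = merged_fixed[-1] if merged_fixed else None
        if (
            prev is not None
            and prev.chrom == s.chrom
            and prev.founder == s.founder
            and abs(prev.end_mb - s.start_mb) <= _EDGE_TOL
        ):
            merged_fixed[-1] = FixedSegment(prev.chrom, prev.start_mb, s.end_mb, prev.founder)
        else:
            merged_fixed.append(s)
    clipped = [
        SegregatingRegion(
            r.chrom,
            max(0.0, r.start_mb),
            min(chrom_lengths[r.chrom], r.end_mb),
            r.founders,
        )
        for r in segregating
    ]
    return LineGenome(
        line_id=line_id,
        fixed=merged_fixed,
        segregating=clipped,
        chrom_lengths=dict(chrom_lengths),
    )


# ---------------------------------------------------------------------------
# line haplotype file I/O
# ---------------------------------------------------------------------------

_LG_COLS = ["chrom", "start_mb", "end_mb", "status", "founders"]


def write_line_genome(lg: LineGenome, path: str | Path) -> None:
    """Write the line haplotype TSV (status fixed|segregating)."""
    rows = [
        {
            "chrom": s.chrom,
            "start_mb": repr(s.start_mb),
            "end_mb": repr(s.end_mb),
            "status": "fixed",
            "founders": s.founder,
        }
        for s in lg.fixed
    ] + [
        {
            "chrom": r.chrom,
            "start_mb": repr(r.start_mb),
            "end_mb": repr(r.end_mb),
            "status": "segregating",
            "founders": r.founder_code,
        }
        for r in lg.segregating
    ]
    rows.sort(key=lambda r: (chrom_sort_key(r["chrom"]), float(r["start_mb"])))
    pd.DataFrame(rows, columns=_LG_COLS).to_csv(path, sep="\t", index=False)


def read_line_genome(
    path: str | Path, chrom_lengths: Mapping[str, float], line_id: str = ""
) -> LineGenome:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "founders": str})
    fixed = []
    segregating = []
    for _, row in df.iterrows():
        if row["status"] == "fixed":
            fixed.append(
                FixedSegment(str(row["chrom"]), float(row["start_mb"]), float(row["end_mb"]), row["founders"])
            )
        else:
            segregating.append(
                SegregatingRegion(
                    str(row["chrom"]),
                    float(row["start_mb"]),
                    float(row["end_mb"]),
                    frozenset(row["founders"]),
                )
            )
    return LineGenome(
        line_id=line_id,
        fixed=fixed,
        segregating=segregating,
        chrom_lengths=validate_chrom_lengths(chrom_lengths),
    )
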