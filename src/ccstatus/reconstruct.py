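"""Founder-haplotype mosaic reconstruction from biallelic SNP calls.

Each genotyped animal's genome is decoded as a mosaic of the eight founder
haplotypes with a hidden Markov model over diplotype states: the 36
unordered founder pairs on autosomes (8 homozygous + 28 heterozygous) and
the 8 haploid founder states on the male X.  Decoding is Viterbi with ties
broken toward the lexicographically smaller state, so reconstruction is
deterministic.  Genotype calls count B alleles (0/1/2) with ``N`` for
missing; emission uses a per-allele error rate and treats missing calls
and markers with unknown founder alleles as uninformative.

Recombination breakpoints are subsequently placed at the midpoint of the
ambiguous interval between the last informative marker supporting one
state and the first informative marker supporting the next
(:func:`estimate_breakpoints`).  Segments are extended to position 0 and
to the configured chromosome length at the ends, so mosaics tile each
chromosome.  Coordinates are Mb floats, 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import CHROM_LENGTHS_M37, FOUNDERS, chrom_sort_key, validate_chrom_lengths

__all__ = [
    "MarkerPanel",
    "GenotypeTable",
    "HmmParams",
    "Segment",
    "DiplotypeMosaic",
    "emission_probability",
    "reconstruct_mosaic",
    "reconstruct_all",
    "estimate_breakpoints",
    "write_mosaic",
    "read_mosaic",
]

_FIDX = {f: i for i, f in enumerate(FOUNDERS)}


# ---------------------------------------------------------------------------
# marker panel and genotype table
# ---------------------------------------------------------------------------


class MarkerPanel:
    """Biallelic SNP panel with founder alleles.

    Markers carry a chromosome (1-19 or X), an Mb position and the allele
    (0 = A-allele, 1 = B-allele, -1 = unknown) of each of the eight
    founders.  Markers are sorted internally by (chromosome, position);
    positions must be strictly increasing within a chromosome.
    """

    def __init__(
        self,
        marker_ids: Sequence[str],
        chroms: Sequence[str],
        pos_mb: Sequence[float],
        founder_alleles: np.ndarray,
    ):
        n = len(marker_ids)
        alleles = np.asarray(founder_alleles, dtype=np.int8)
        if alleles.shape != (n, 8):
            raise ValueError(f"founder_alleles must be (n_markers, 8), got {alleles.shape}")
        chroms = [str(c) for c in chroms]
        pos = np.asarray(pos_mb, dtype=float)
        if np.any(pos < 0):
            raise ValueError("marker positions must be >= 0 Mb")
        order = sorted(range(n), key=lambda i: (chrom_sort_key(chroms[i]), pos[i]))
        self.marker_ids = [str(marker_ids[i]) for i in order]
        self.chroms = np.array([chroms[i] for i in order], dtype=object)
        self.pos_mb = pos[order]
        self.alleles = alleles[order]
        self._chrom_index: dict[str, slice] = {}
        start = 0
        for i in range(1, n + 1):
            if i == n or self.chroms[i] != self.chroms[start]:
                self._chrom_index[str(self.chroms[start])] = slice(start, i)
                start = i
        for chrom, sl in self._chrom_index.items():
            p = self.pos_mb[sl]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"marker positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_index)

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_index[str(chrom)]

    def informative(self) -> np.ndarray:
        """Boolean mask of markers with both alleles among known founders."""
        has0 = (self.alleles == 0).any(axis=1)
        has1 = (self.alleles == 1).any(axis=1)
        return has0 & has1

    # CSV dialect: marker,chrom,pos_mb,A,B,C,D,E,F,G,H with alleles 0/1/N

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerPanel":
        cols = ["marker", "chrom", "pos_mb", *FOUNDERS]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"panel table missing columns {missing}")
        alleles = (
            df[list(FOUNDERS)]
            .astype(str)
            .apply(lambda s: s.str.strip().str.upper())
            .replace({"N": "-1"})
            .astype(np.int8)
            .to_numpy()
        )
        if not np.isin(alleles, [-1, 0, 1]).all():
            raise ValueError("founder alleles must be 0, 1 or N")
        return cls(df["marker"].tolist(), df["chrom"].tolist(), df["pos_mb"].tolist(), alleles)

    @classmethod
    def read_csv(cls, path: str | Path) -> "MarkerPanel":
        return cls.from_frame(pd.read_csv(path, dtype={"chrom": str}))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"marker": self.marker_ids, "chrom": self.chroms, "pos_mb": self.pos_mb}
        )
        for j, f in enumerate(FOUNDERS):
            df[f] = [("N" if a < 0 else str(a)) for a in self.alleles[:, j]]
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class GenotypeTable:
    """Genotype calls (B-allele counts 0/1/2, -1 for N) per animal x marker."""

    def __init__(self, panel: MarkerPanel, calls: Mapping[str, np.ndarray]):
        self.panel = panel
        self.calls: dict[str, np.ndarray] = {}
        for animal, row in calls.items():
            arr = np.asarray(row, dtype=np.int8)
            if arr.shape != (len(panel),):
                raise ValueError(
                    f"genotype row for {animal!r} has length {arr.shape}, "
                    f"panel has {len(panel)} markers"
                )
            if not np.isin(arr, [-1, 0, 1, 2]).all():
                raise ValueError(f"genotype calls for {animal!r} outside {{0,1,2,N}}")
            self.calls[str(animal)] = arr

    @property
    def animals(self) -> list[str]:
        return list(self.calls)

    def __getitem__(self, animal: str) -> np.ndarray:
        return self.calls[animal]

    @classmethod
    def read_csv(cls, path: str | Path, panel: MarkerPanel) -> "GenotypeTable":
        df = pd.read_csv(path, dtype=str)
        if "marker" not in df.columns:
            raise ValueError("genotype table must have a 'marker' column")
        df = df.set_index("marker")
        try:
            df = df.loc[panel.marker_ids]
        except KeyError as exc:
            raise ValueError(f"genotype table does not cover the panel: {exc}") from exc
        calls = {}
        for animal in df.columns:
            col = df[animal].str.strip().str.upper().replace({"N": "-1"}).astype(np.int8)
            calls[animal] = col.to_numpy()
        return cls(panel, calls)

    def write_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"marker": self.panel.marker_ids})
        for animal, row in self.calls.items():
            df[animal] = [("N" if c < 0 else str(c)) for c in row]
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# HMM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HmmParams:
    """Decoding parameters: per-allele error rate and per-Mb switch rate."""

    eps: float = 0.002
    r_per_mb: float = 0.005
    chrom_lengths: Mapping[str, float] = field(
        default_factory=lambda: dict(CHROM_LENGTHS_M37)
    )

    def __post_init__(self) -> None:
        if not 0 < self.eps < 0.5:
            raise ValueError(f"eps must be in (0, 0.5), got {self.eps}")
        if not self.r_per_mb > 0:
            raise ValueError(f"r_per_mb must be positive, got {self.r_per_mb}")
        object.__setattr__(self, "chrom_lengths", validate_chrom_lengths(self.chrom_lengths))


def _call_prob(implied: int, call: int, eps: float) -> float:
    # per-allele error: each of the two reported alleles flips independently
    if implied == 0:
        probs = ((1 - eps) ** 2, 2 * eps * (1 - eps), eps**2)
    elif implied == 1:
        probs = (eps * (1 - eps), (1 - eps) ** 2 + eps**2, eps * (1 - eps))
    else:
        probs = (eps**2, 2 * eps * (1 - eps), (1 - eps) ** 2)
    return probs[call]


def emission_probability(
    call: int,
    state: tuple[str, ...] | str,
    founder_alleles: Sequence[int],
    eps: float,
) -> float:
    """P(observed call | diplotype state) at one marker.

    ``state`` is an unordered founder pair like ``("A", "B")`` (or a
    single letter for the male X, modelled as the homozygous diplotype).
    ``founder_alleles`` is the 8-vector of founder alleles at the marker
    (0/1, -1 for unknown).  Missing calls and unknown founder alleles give
    probability 1 (the marker is uninformative for the state).
    """
    if not 0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    if isinstance(state, str):
        state = (state, state)
    if len(state) == 1:
        state = (state[0], state[0])
    if call < 0:
        return 1.0
    a1 = founder_alleles[_FIDX[state[0]]]
    a2 = founder_alleles[_FIDX[state[1]]]
    if a1 < 0 or a2 < 0:
        return 1.0
    return _call_prob(int(a1) + int(a2), int(call), eps)


def _log_emissions_diploid(
    calls: np.ndarray, alleles: np.ndarray, eps: float
) -> np.ndarray:
    """Log emission matrix (n_markers, 64) over ordered founder pairs."""
    n = len(calls)
    # implied genotype per ordered pair; -1 where either founder allele unknown
    a = alleles.astype(np.int16)
    implied = a[:, :, None] + a[:, None, :]  # (n, 8, 8)
    unknown = (a[:, :, None] < 0) | (a[:, None, :] < 0)
    implied = implied.reshape(n, 64)
    unknown = unknown.reshape(n, 64)
    table = np.empty((3, 3))
    for g in range(3):
        for c in range(3):
            table[g, c] = _call_prob(g, c, eps)
    out = np.zeros((n, 64))
    obs = calls >= 0
    idx = np.where(obs)[0]
    for i in idx:
        row = np.where(unknown[i], 1.0, table[implied[i].clip(0), calls[i]])
        out[i] = np.log(row)
    return out


def _log_emissions_haploid(calls: np.ndarray, alleles: np.ndarray, eps: float) -> np.ndarray:
    """Log emission matrix (n_markers, 8); haploid state f behaves as (f, f)."""
    n = len(calls)
    a = alleles.astype(np.int16)
    table = np.empty((3, 3))
    for g in range(3):
        for c in range(3):
            table[g, c] = _call_prob(g, c, eps)
    out = np.zeros((n, 8))
    for i in np.where(calls >= 0)[0]:
        row = np.where(a[i] < 0, 1.0, table[(2 * a[i]).clip(0), calls[i]])
        out[i] = np.log(row)
    return out


def _haploid_log_trans(d_mb: float, r: float) -> np.ndarray:
    # recombination events Poisson(r*d); on an event the haplotype founder is
    # redrawn uniformly from the eight, so staying keeps mass 1-q + q/8
    q = 1.0 - np.exp(-r * d_mb)
    move = q / 8.0
    stay = 1.0 - q + move
    lt = np.full((8, 8), np.log(max(move, 1e-300)))
    np.fill_diagonal(lt, np.log(stay))
    return lt


_SWITCH_COUNT_64 = (
    (np.arange(64)[:, None] // 8 != np.arange(64)[None, :] // 8).astype(int)
    + (np.arange(64)[:, None] % 8 != np.arange(64)[None, :] % 8).astype(int)
)


def _diploid_log_trans(d_mb: float, r: float) -> np.ndarray:
    """Log transition matrix over the 64 ordered diplotype states.

    Weights decrease with the number of haplotype switches: stay 1, one
    switch q/8, two switches q/64.  The double-switch weight is linear in
    q (not q^2): in inbred material the two haplotypes are often IBD
    copies of the same recombinant, so coincident switches occur at a
    rate proportional to the recombination probability itself.  Rows are
    normalized.
    """
    q = max(1.0 - np.exp(-r * d_mb), 1e-300)
    w = np.array([1.0, q / 8.0, q / 64.0])
    z = w[0] + 14.0 * w[1] + 49.0 * w[2]
    return np.log(w[_SWITCH_COUNT_64] / z)


def _viterbi(log_emit: np.ndarray, dists: np.ndarray, r: float, diploid: bool) -> np.ndarray:
    """MAP state path; ties resolved toward the smallest state index."""
    n, n_states = log_emit.shape
    delta = log_emit[0].copy()
    back = np.zeros((n, n_states), dtype=np.int16)
    for t in range(1, n):
        if diploid:
            lt = _diploid_log_trans(dists[t - 1], r)
        else:
            lt = _haploid_log_trans(dists[t - 1], r)
        cand = delta[:, None] + lt
        best = np.argmax(cand, axis=0)  # first (smallest) index wins ties
        back[t] = best
        delta = cand[best, np.arange(n_states)] + log_emit[t]
    path = np.empty(n, dtype=np.int16)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# mosaics
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """One mosaic segment: half-open [start_mb, end_mb) with a diplotype state.

    ``state`` is a sorted founder tuple of length 2 (autosomes, female X)
    or 1 (male X).  ``first_idx``/``last_idx`` are panel marker indices of
    the first/last marker assigned to the segment.  ``flag`` is empty,
    ``"low_confidence"`` (fewer than 2 informative markers on the
    chromosome) or ``"uniform"`` (no informative call at all).
    """

    chrom: str
    start_mb: float
    end_mb: float
    state: tuple[str, ...]
    support: int
    first_idx: int
    last_idx: int
    flag: str = ""

    @property
    def homozygous(self) -> bool:
        return len(self.state) == 1 or self.state[0] == self.state[1]

    @property
    def length_mb(self) -> float:
        return self.end_mb - self.start_mb


@dataclass
class DiplotypeMosaic:
    """Ordered mosaic segments for one animal, tiling each chromosome."""

    animal: str
    sex: str
    segments: list[Segment]

    def by_chrom(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == str(chrom)]

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.chrom, None)
        return list(seen)


def _ordered_to_state(idx: int, diploid: bool) -> tuple[str, ...]:
    if not diploid:
        return (FOUNDERS[idx],)
    i, j = divmod(idx, 8)
    return tuple(sorted((FOUNDERS[i], FOUNDERS[j])))


def _segment_support(
    state: tuple[str, ...], calls: np.ndarray, alleles: np.ndarray
) -> int:
    f1 = _FIDX[state[0]]
    f2 = _FIDX[state[-1]]
    known = (alleles[:, f1] >= 0) & (alleles[:, f2] >= 0)
    return int(np.sum((calls >= 0) & known))


def reconstruct_mosaic(
    calls: np.ndarray,
    panel: MarkerPanel,
    sex: str,
    params: HmmParams | None = None,
    animal: str = "",
) -> DiplotypeMosaic:
    """Viterbi-decode one animal's genome into founder-diplotype segments.

    Autosomes and the female X are decoded over the 36 unordered diplotype
    states (as 64 ordered states, collapsed); the male X over 8 haploid
    states.  Chromosomes with fewer than two informative markers yield a
    single flagged segment.  Segment boundaries fall at the midpoint
    between adjacent markers of differing state and are extended to 0 and
    to the configured chromosome length at the ends; run
    :func:`estimate_breakpoints` to refine boundaries to informative-
    marker midpoints.
    """
    if params is None:
        params = HmmParams()
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    calls = np.asarray(calls, dtype=np.int8)
    if calls.shape != (len(panel),):
        raise ValueError("genotype row length does not match panel")
    informative = panel.informative()
    segments: list[Segment] = []
    for chrom in panel.chromosomes:
        if chrom not in params.chrom_lengths:
            raise ValueError(f"no configured length for chromosome {chrom}")
        sl = panel.chrom_slice(chrom)
        c_calls = calls[sl]
        c_alleles = panel.alleles[sl]
        c_pos = panel.pos_mb[sl]
        clen = params.chrom_lengths[chrom]
        diploid = not (chrom == "X" and sex == "male")
        n_inf = int(np.sum(informative[sl] & (c_calls >= 0)))
        flag = ""
        if n_inf == 0:
            flag = "uniform"
        elif np.sum(informative[sl]) < 2:
            flag = "low_confidence"
        if diploid:
            log_emit = _log_emissions_diploid(c_calls, c_alleles, params.eps)
        else:
            log_emit = _log_emissions_haploid(c_calls, c_alleles, params.eps)
        path = _viterbi(log_emit, np.diff(c_pos), params.r_per_mb, diploid)
        states = [_ordered_to_state(int(s), diploid) for s in path]
        # collapse runs of equal unordered state
        run_start = 0
        runs: list[tuple[int, int, tuple[str, ...]]] = []
        for i in range(1, len(states) + 1):
            if i == len(states) or states[i] != states[run_start]:
                runs.append((run_start, i - 1, states[run_start]))
                run_start = i
        for k, (a, b, state) in enumerate(runs):
            start = 0.0 if k == 0 else (c_pos[runs[k - 1][1]] + c_pos[a]) / 2.0
            end = clen if k == len(runs) - 1 else (c_pos[b] + c_pos[runs[k + 1][0]]) / 2.0
            segments.append(
                Segment(
                    chrom=chrom,
                    start_mb=float(start),
                    end_mb=float(end),
                    state=state,
                    support=_segment_support(state, c_calls, c_alleles),
                    first_idx=sl.start + a,
                    last_idx=sl.start + b,
                    flag=flag,
                )
            )
    return DiplotypeMosaic(animal=animal, sex=sex, segments=segments)


def _states_distinguishable(
    s1: tuple[str, ...], s2: tuple[str, ...], alleles: np.ndarray
) -> np.ndarray:
    """Markers (rows of ``alleles``) whose implied genotypes differ for s1/s2."""

    def implied(state: tuple[str, ...]) -> np.ndarray:
        a1 = alleles[:, _FIDX[state[0]]].astype(np.int16)
        a2 = alleles[:, _FIDX[state[-1]]].astype(np.int16)
        g = a1 + a2
        g[(a1 < 0) | (a2 < 0)] = -9
        return g

    g1 = implied(s1)
    g2 = implied(s2)
    return (g1 >= 0) & (g2 >= 0) & (g1 != g2)


def estimate_breakpoints(
    mosaic: DiplotypeMosaic, panel: MarkerPanel, calls: np.ndarray | None = None
) -> DiplotypeMosaic:
    """Place each segment boundary at the midpoint of its ambiguous interval.

    For the boundary between states s1 and s2, the ambiguous interval runs
    from the last marker in the left segment that is informative for
    (s1 vs s2) and actually called, to the first such marker in the right
    segment; the breakpoint is their arithmetic mean.  When ``calls`` is
    omitted, marker informativity alone anchors the interval.  Boundaries
    at chromosome ends stay at the chromosome ends.
    """
    if calls is not None:
        calls = np.asarray(calls, dtype=np.int8)
    new_segments = [replace(s) for s in mosaic.segments]
    by_chrom: dict[str, list[Segment]] = {}
    for s in new_segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        for left, right in zip(segs, segs[1:]):
            idx = np.arange(left.first_idx, right.last_idx + 1)
            ok = _states_distinguishable(
                left.state, right.state, panel.alleles[idx]
            )
            if calls is not None:
                ok &= calls[idx] >= 0
            left_mask = idx <= left.last_idx
            l_idx = idx[ok & left_mask]
            r_idx = idx[ok & ~left_mask]
            left_anchor = panel.pos_mb[l_idx[-1]] if len(l_idx) else panel.pos_mb[left.last_idx]
            right_anchor = panel.pos_mb[r_idx[0]] if len(r_idx) else panel.pos_mb[right.first_idx]
            boundary = (float(left_anchor) + float(right_anchor)) / 2.0
            boundary = max(boundary, left.start_mb)
            left.end_mb = boundary
            right.start_mb = boundary
    return DiplotypeMosaic(animal=mosaic.animal, sex=mosaic.sex, segments=new_segments)


def reconstruct_all(
    genotypes: GenotypeTable,
    sex_map: Mapping[str, str],
    params: HmmParams | None = None,
    refine_breakpoints: bool = True,
) -> dict[str, DiplotypeMosaic]:
    """Reconstruct (and by default breakpoint-refine) every animal."""
    out = {}
    for animal in genotypes.animals:
        sex = sex_map.get(animal)
        if sex is None:
            raise ValueError(f"no sex recorded for animal {animal!r}")
        m = reconstruct_mosaic(genotypes[animal], genotypes.panel, sex, params, animal)
        if refine_breakpoints:
            m = estimate_breakpoints(m, genotypes.panel, genotypes[animal])
        out[animal] = m
    return out


# ---------------------------------------------------------------------------
# mosaic I/O (BED-like TSV)
# ---------------------------------------------------------------------------

_MOSAIC_COLS = ["chrom", "start_mb", "end_mb", "founder1", "founder2", "support"]


def write_mosaic(mosaic: DiplotypeMosaic, path: str | Path) -> None:
    rows = []
    for s in mosaic.segments:
        rows.append(
            {
                "chrom": s.chrom,
                "start_mb": repr(s.start_mb),
                "end_mb": repr(s.end_mb),
                "founder1": s.state[0],
                "founder2": s.state[1] if len(s.state) == 2 else "",
                "support": s.support,
            }
        )
    pd.DataFrame(rows, columns=_MOSAIC_COLS).to_csv(path, sep="\t", index=False)


def read_mosaic(path: str | Path, animal: str = "", sex: str = "female") -> DiplotypeMosaic:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "founder1": str, "founder2": str})
    segments = []
    for _, row in df.iterrows():
        f2 = row["founder2"]
        state = (
            (str(row["founder1"]),)
            if (pd.isna(f2) or str(f2) == "")
            else tuple(sorted((str(row["founder1"]), str(f2))))
        )
        segments.append(
            Segment(
                chrom=str(row["chrom"]),
                start_mb=float(row["start_mb"]),
                end_mb=float(row["end_mb"]),
                state=state,
                support=int(row["support"]),
                first_idx=-1,
                last_idx=-1,
            )
        )
    return DiplotypeMosaic(animal=animal, sex=sex, segments=segments)
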