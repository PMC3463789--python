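"""Forward-in-time simulator of the eight-founder funnel breeding design.

Three generations of mixing combine eight inbred founders into a single
outbred sibship (four pairwise crosses, two four-way crosses, one
eight-way cross), followed by brother-sister inbreeding — one mating pair
and a sibship of two per generation, with an optional split into two
parallel arms to exercise obligate-ancestor logic.  Meioses place
crossovers as a Poisson process per Mb with no interference; the X
follows sex-specific transmission (males carry a single maternal X and
pass it intact to daughters).  The Y chromosome and mitochondria are not
simulated.

Every animal's genome is tracked exactly as founder-labeled intervals,
so the simulator doubles as a truth oracle: genotype calls are derived
from the true haplotypes and the founder allele table, with configurable
per-allele error and missingness, and exact heterozygosity can be
computed for any animal subset.  All randomness flows from the config
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import CHROM_LENGTHS_M37, FOUNDERS, validate_chrom_lengths
from .pedigree import Individual, Pedigree
from .reconstruct import DiplotypeMosaic, GenotypeTable, MarkerPanel, Segment

__all__ = [
    "SimConfig",
    "SimAnimal",
    "SimResult",
    "simulate_funnel",
    "simulate_pedigree",
    "make_marker_panel",
    "true_heterozygosity",
    "true_segments",
    "true_diplotype_mosaic",
]

# a haplotype is a list of (end_mb, founder_letter) intervals covering
# [0, chrom_length); starts are implicit
Haplotype = list[tuple[float, str]]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated line."""

    n_sib_generations: int = 10
    founder_order: tuple[str, ...] = FOUNDERS
    recomb_rate_per_mb: float = 0.005
    genotyping_error: float = 0.002
    missing_rate: float = 0.0
    marker_spacing_mb: float = 1.0
    chrom_lengths: Mapping[str, float] = field(
        default_factory=lambda: dict(CHROM_LENGTHS_M37)
    )
    seed: int = 0
    line_id: str = "SIM1"
    n_arms: int = 1
    arm_split_generation: int = 1  # sib generation at which arms diverge

    def __post_init__(self) -> None:
        if self.n_sib_generations < 0:
            raise ValueError("n_sib_generations must be >= 0")
        if sorted(self.founder_order) != sorted(FOUNDERS):
            raise ValueError("founder_order must be a permutation of A..H")
        for name in ("genotyping_error", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not self.marker_spacing_mb > 0:
            raise ValueError("marker_spacing_mb must be positive")
        if not self.recomb_rate_per_mb >= 0:
            raise ValueError("recomb_rate_per_mb must be >= 0")
        if self.n_arms not in (1, 2):
            raise ValueError("n_arms must be 1 or 2")
        object.__setattr__(
            self, "chrom_lengths", validate_chrom_lengths(self.chrom_lengths)
        )


@dataclass
class SimAnimal:
    """True genome of one simulated animal.

    ``haplotypes[chrom]`` holds 2 haplotypes for autosomes and the female
    X, and 1 for the male X.
    """

    id: str
    sex: str
    generation: int
    sire: str | None
    dam: str | None
    haplotypes: dict[str, list[Haplotype]]


@dataclass
class SimResult:
    """Everything a downstream module needs, plus the truth."""

    config: SimConfig
    pedigree: Pedigree
    animals: dict[str, SimAnimal]
    panel: MarkerPanel
    genotypes: GenotypeTable
    extant_ids: list[str]

    @property
    def sex_map(self) -> dict[str, str]:
        return {a.id: a.sex for a in self.animals.values()}


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _recombine(h1: Haplotype, h2: Haplotype, clen: float, rate: float, rng) -> Haplotype:
    n_xo = rng.poisson(rate * clen)
    cuts = np.sort(rng.uniform(0.0, clen, size=n_xo)) if n_xo else np.empty(0)
    which = int(rng.integers(2))
    sources = (h1, h2)
    out: Haplotype = []
    prev = 0.0
    for cut in [*cuts.tolist(), clen]:
        src = sources[which]
        for end, label in src:
            if end <= prev:
                continue
            stop = min(end, cut)
            if not out or out[-1][1] != label:
                out.append((stop, label))
            else:
                out[-1] = (stop, label)
            if end >= cut:
                break
        prev = cut
        which = 1 - which
    # normalize: drop zero-length artifacts, force final end
    clean: Haplotype = []
    for end, label in out:
        if clean and end <= clean[-1][0]:
            continue
        if clean and clean[-1][1] == label:
            clean[-1] = (end, label)
        else:
            clean.append((end, label))
    if clean[-1][0] != clen:
        clean[-1] = (clen, clean[-1][1])
    return clean


def _gametes(parent: SimAnimal, cfg: SimConfig, rng, child_sex: str) -> dict[str, Haplotype]:
    """One gamete per chromosome; X obeys sex-specific transmission."""
    out = {}
    for chrom, clen in cfg.chrom_lengths.items():
        haps = parent.haplotypes[chrom]
        if chrom == "X":
            if parent.sex == "male":
                if child_sex == "male":
                    continue  # son's X comes from the dam
                out[chrom] = [t for t in haps[0]]
                continue
        out[chrom] = _recombine(haps[0], haps[-1], clen, cfg.recomb_rate_per_mb, rng)
    return out


def _mate(
    sire: SimAnimal,
    dam: SimAnimal,
    child_id: str,
    child_sex: str,
    generation: int,
    cfg: SimConfig,
    rng,
) -> SimAnimal:
    pat = _gametes(sire, cfg, rng, child_sex)
    mat = _gametes(dam, cfg, rng, child_sex)
    haplotypes: dict[str, list[Haplotype]] = {}
    for chrom in cfg.chrom_lengths:
        if chrom == "X" and child_sex == "male":
            haplotypes[chrom] = [mat[chrom]]
        else:
            haplotypes[chrom] = [pat[chrom], mat[chrom]]
    return SimAnimal(
        id=child_id,
        sex=child_sex,
        generation=generation,
        sire=sire.id,
        dam=dam.id,
        haplotypes=haplotypes,
    )


# ---------------------------------------------------------------------------
# breeding design
# ---------------------------------------------------------------------------


def _founder_animal(letter: str, idx: int, sex: str, cfg: SimConfig) -> SimAnimal:
    haps = {
        chrom: ([[(clen, letter)]] if chrom == "X" and sex == "male" else [[(clen, letter)], [(clen, letter)]])
        for chrom, clen in cfg.chrom_lengths.items()
    }
    return SimAnimal(
        id=f"{cfg.line_id}-F{idx}{letter}",
        sex=sex,
        generation=0,
        sire=None,
        dam=None,
        haplotypes={c: [list(h) for h in hh] for c, hh in haps.items()},
    )


def _breed(cfg: SimConfig, rng) -> tuple[dict[str, SimAnimal], list[str]]:
    """Run the funnel + sib-mating design; returns animals and extant ids."""
    animals: dict[str, SimAnimal] = {}

    def add(a: SimAnimal) -> SimAnimal:
        animals[a.id] = a
        return a

    order = cfg.founder_order
    founders = []
    for i, letter in enumerate(order):
        sex = "male" if i % 2 == 0 else "female"
        founders.append(add(_founder_animal(letter, i, sex, cfg)))
    # G1: four pairwise crosses; sexes arranged so G2 crosses are possible
    g1 = []
    for j in range(4):
        sex = "male" if j % 2 == 0 else "female"
        g1.append(
            add(_mate(founders[2 * j], founders[2 * j + 1], f"{cfg.line_id}-G1-{j}", sex, 1, cfg, rng))
        )
    # G2: two four-way crosses
    g2_m = add(_mate(g1[0], g1[1], f"{cfg.line_id}-G2-0", "male", 2, cfg, rng))
    g2_f = add(_mate(g1[2], g1[3], f"{cfg.line_id}-G2-1", "female", 2, cfg, rng))
    # G2:F1, the eight-way cross: generation 3, a sibship of two
    sib_m = add(_mate(g2_m, g2_f, f"{cfg.line_id}-G3-0", "male", 3, cfg, rng))
    sib_f = add(_mate(g2_m, g2_f, f"{cfg.line_id}-G3-1", "female", 3, cfg, rng))
    pairs = [(sib_m, sib_f)]
    extant = [sib_m.id, sib_f.id]
    for t in range(1, cfg.n_sib_generations + 1):
        gen = 3 + t
        split = cfg.n_arms == 2 and t == cfg.arm_split_generation and len(pairs) == 1
        new_pairs = []
        extant = []
        for arm, (sire, dam) in enumerate(pairs):
            n_off = 4 if split else 2
            kids = []
            for j in range(n_off):
                sex = "male" if j % 2 == 0 else "female"
                kid = _mate(
                    sire, dam, f"{cfg.line_id}-G{gen}-{arm}{j}", sex, gen, cfg, rng
                )
                kids.append(add(kid))
            for j in range(0, n_off, 2):
                new_pairs.append((kids[j], kids[j + 1]))
            extant.extend(k.id for k in kids)
        pairs = new_pairs
    return animals, extant


def _pedigree_of(animals: Mapping[str, SimAnimal], line_id: str) -> Pedigree:
    individuals = [
        Individual(
            id=a.id,
            sire=a.sire,
            dam=a.dam,
            sex=a.sex,
            generation=a.generation,
            line=line_id,
        )
        for a in animals.values()
    ]
    return Pedigree(individuals, line_id=line_id)


def simulate_pedigree(cfg: SimConfig) -> tuple[Pedigree, list[str]]:
    """Pedigree and extant ids only (no genotypes); deterministic under seed."""
    rng = np.random.default_rng(cfg.seed)
    animals, extant = _breed(cfg, rng)
    return _pedigree_of(animals, cfg.line_id), extant


# ---------------------------------------------------------------------------
# markers and genotypes
# ---------------------------------------------------------------------------


def make_marker_panel(cfg: SimConfig) -> MarkerPanel:
    """Evenly spaced biallelic markers, each splitting the eight founders.

    Founder allele vectors are drawn uniformly over the non-constant
    binary 8-vectors, so every marker is informative.  Deterministic
    under the config seed.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # decoupled from breeding stream
    ids, chroms, pos, alleles = [], [], [], []
    for chrom, clen in cfg.chrom_lengths.items():
        p = np.arange(cfg.marker_spacing_mb / 2.0, clen, cfg.marker_spacing_mb)
        for i, x in enumerate(p):
            vec = rng.integers(0, 2, size=8)
            while vec.min() == vec.max():
                vec = rng.integers(0, 2, size=8)
            ids.append(f"m{chrom}_{i}")
            chroms.append(chrom)
            pos.append(float(x))
            alleles.append(vec)
    return MarkerPanel(ids, chroms, np.array(pos), np.array(alleles, dtype=np.int8))


def _labels_at(hap: Haplotype, positions: np.ndarray) -> np.ndarray:
    ends = np.array([e for e, _ in hap])
    labels = np.array([FOUNDERS.index(l) for _, l in hap])
    return labels[np.searchsorted(ends, positions, side="right").clip(max=len(ends) - 1)]


def _genotypes_for(
    animal: SimAnimal, panel: MarkerPanel, cfg: SimConfig, rng
) -> np.ndarray:
    calls = np.empty(len(panel), dtype=np.int8)
    for chrom in panel.chromosomes:
        sl = panel.chrom_slice(chrom)
        positions = panel.pos_mb[sl]
        haps = animal.haplotypes[chrom]
        allele_sum = np.zeros(len(positions), dtype=np.int16)
        unknown = np.zeros(len(positions), dtype=bool)
        for hap in haps:
            fidx = _labels_at(hap, positions)
            a = panel.alleles[sl][np.arange(len(positions)), fidx].astype(np.int16)
            err = rng.random(len(positions)) < cfg.genotyping_error
            a_obs = np.where(err, 1 - a, a)
            unknown |= a < 0
            allele_sum += a_obs
        if len(haps) == 1:  # male X reported as homozygous
            allele_sum *= 2
        call = allele_sum.astype(np.int8)
        call[unknown] = -1
        miss = rng.random(len(positions)) < cfg.missing_rate
        call[miss] = -1
        calls[sl] = call
    return calls


def simulate_funnel(cfg: SimConfig) -> SimResult:
    """Run the full design: pedigree, true genomes, panel, noisy genotypes."""
    rng = np.random.default_rng(cfg.seed)
    animals, extant = _breed(cfg, rng)
    panel = make_marker_panel(cfg)
    geno_rng = np.random.default_rng(cfg.seed + 2)
    calls = {aid: _genotypes_for(a, panel, cfg, geno_rng) for aid, a in animals.items()}
    return SimResult(
        config=cfg,
        pedigree=_pedigree_of(animals, cfg.line_id),
        animals=animals,
        panel=panel,
        genotypes=GenotypeTable(panel, calls),
        extant_ids=extant,
    )


# ---------------------------------------------------------------------------
# truth oracles
# ---------------------------------------------------------------------------


def true_segments(
    animals: Sequence[SimAnimal], chrom: str
) -> list[tuple[float, float, frozenset[str]]]:
    """Atomic intervals with the joint founder-label set across ``animals``."""
    haps: list[Haplotype] = []
    for a in animals:
        haps.extend(a.haplotypes[chrom])
    edges = sorted({e for h in haps for e, _ in h} | {0.0})
    out = []
    for a_pos, b_pos in zip(edges, edges[1:]):
        mid = (a_pos + b_pos) / 2.0
        labels = frozenset(
            next(label for end, label in h if end > mid) for h in haps
        )
        out.append((a_pos, b_pos, labels))
    return out


def true_heterozygosity(
    animals: Sequence[SimAnimal],
    chrom_lengths: Mapping[str, float],
    chroms: Iterable[str] | None = None,
) -> float:
    """Exact percent of genome where the joint haplotype set holds >= 2 founders.

    For a single animal this is its autosomal heterozygosity (the male X
    contributes nothing, having one haplotype); for an ancestor pair it
    is the maximum heterozygosity bound (4 joint autosomal haplotypes,
    3 on the X when the sire is male).
    """
    chrom_lengths = validate_chrom_lengths(chrom_lengths)
    use = list(chroms) if chroms is not None else list(chrom_lengths)
    het = 0.0
    total = 0.0
    for chrom in use:
        total += chrom_lengths[chrom]
        for a_pos, b_pos, labels in true_segments(animals, chrom):
            if len(labels) >= 2:
                het += b_pos - a_pos
    return 100.0 * het / total


def true_diplotype_mosaic(
    animal: SimAnimal, chrom_lengths: Mapping[str, float]
) -> DiplotypeMosaic:
    """The animal's true genome in mosaic form (marker-free; support 0)."""
    chrom_lengths = validate_chrom_lengths(chrom_lengths)
    segments = []
    for chrom in chrom_lengths:
        haps = animal.haplotypes[chrom]
        prev_state: tuple[str, ...] | None = None
        for a_pos, b_pos, _ in true_segments([animal], chrom):
            state = tuple(
                sorted(next(label for end, label in h if end > (a_pos + b_pos) / 2) for h in haps)
            )
            if prev_state == state and segments:
                last = segments[-1]
                segments[-1] = Segment(
                    last.chrom, last.start_mb, b_pos, last.state, 0, -1, -1
                )
            else:
                segments.append(Segment(chrom, a_pos, b_pos, state, 0, -1, -1))
            prev_state = state
    return DiplotypeMosaic(animal=animal.id, sex=animal.sex, segments=segments)
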