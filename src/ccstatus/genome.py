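"""Reference genome constants and chromosome bookkeeping.

Coordinates throughout the package are megabase floats on the NCBI m37
mouse assembly, 0-based, half-open.  Only the 19 autosomes and the X are
tracked; the Y chromosome and the mitochondrial genome are excluded.
"""

from __future__ import annotations

from collections.abc import Mapping

#: Founder strain letter codes, in canonical order.
FOUNDERS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H")

#: Chromosome labels in canonical sort order (autosomes 1-19, then X).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20)) + ("X",)

#: NCBI m37 chromosome lengths in Mb (autosomes + X).
CHROM_LENGTHS_M37: dict[str, float] = {
    "1": 197.195,
    "2": 181.748,
    "3": 159.599,
    "4": 155.630,
    "5": 152.537,
    "6": 149.517,
    "7": 152.525,
    "8": 131.738,
    "9": 124.076,
    "10": 129.993,
    "11": 121.843,
    "12": 121.257,
    "13": 120.284,
    "14": 125.194,
    "15": 103.494,
    "16": 98.319,
    "17": 95.272,
    "18": 90.772,
    "19": 61.342,
    "X": 166.650,
}


def chrom_sort_key(chrom: str) -> tuple[int, int]:
    """Sort key placing autosomes numerically before the X chromosome."""
    c = str(chrom)
    if c == "X":
        return (1, 0)
    try:
        return (0, int(c))
    except ValueError as exc:
        raise ValueError(f"unknown chromosome label {chrom!r}") from exc


def validate_chrom_lengths(lengths: Mapping[str, float]) -> dict[str, float]:
    """Validate a chromosome-length table and return a normalized copy."""
    out: dict[str, float] = {}
    for chrom, length in lengths.items():
        chrom_sort_key(chrom)
        if not length > 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        out[str(chrom)] = float(length)
    if not out:
        raise ValueError("empty chromosome-length table")
    return dict(sorted(out.items(), key=lambda kv: chrom_sort_key(kv[0])))


def genome_length_mb(lengths: Mapping[str, float]) -> float:
    """Total tracked genome length in Mb."""
    return float(sum(lengths.values()))
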