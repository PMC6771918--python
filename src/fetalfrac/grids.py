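"""Fixed genomic tilings (bin grids) that define feature order.

A :class:`BinGrid` is an ordered list of ``(chrom, start, end)`` windows,
0-based half-open (BED convention), produced by tiling each chromosome at a
fixed resolution; the final bin of a chromosome is truncated at the chromosome
end.  Copy-number profiles and Y read-count vectors are always interpreted
relative to a grid, so the grid doubles as the feature index of every model in
this package.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

from .errors import ConfigurationError

# GRCh38 primary-assembly chromosome lengths (bp).
GRCH38_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468, "chrX": 156_040_895, "chrY": 57_227_415,
}


def strip_chr_prefix(name: str) -> str:
    """Return the chromosome name without a leading ``chr`` prefix."""
    return name[3:] if name.lower().startswith("chr") else name


def normalize_chrom_names(lengths: dict[str, int], style: str) -> dict[str, int]:
    """Re-key a chromosome length table to a consistent naming style.

    Parameters
    ----------
    lengths
        Mapping chromosome name -> length in bp.
    style
        ``"chr"`` forces a ``chr`` prefix, ``"plain"`` strips it.
    """
    if style not in {"chr", "plain"}:
        raise ConfigurationError(f"unknown chromosome naming style {style!r}")
    out: dict[str, int] = {}
    for name, length in lengths.items():
        base = strip_chr_prefix(name)
        key = f"chr{base}" if style == "chr" else base
        if key in out:
            raise ConfigurationError(f"chromosome name collision on {key!r}")
        out[key] = length
    return out


@dataclass(frozen=True)
class BinGrid:
    """Ordered genomic tiling; immutable once built.

    Attributes
    ----------
    bins
        Tuple of ``(chrom, start, end)`` with 0-based half-open coordinates,
        sorted by (chromosome table order, start).
    resolution
        Nominal bin width in bp; only the last bin of a chromosome may be
        shorter.
    assembly_label
        Free-text label of the underlying length table.
    """

    bins: tuple[tuple[str, int, int], ...]
    resolution: int
    assembly_label: str = "custom"
    _index: dict[tuple[str, int], int] = field(
        init=False, repr=False, compare=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {(c, s): i for i, (c, s, _) in enumerate(self.bins)}
        )

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chroms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c, _, _ in self.bins:
            seen.setdefault(c)
        return tuple(seen)

    def index_of(self, chrom: str, start: int) -> int | None:
        """Grid position of the bin starting at (chrom, start), or None."""
        return self._index.get((chrom, start))

    def chrom_mask(self, chroms: set[str]):
        """Boolean mask (numpy array) of bins lying on the given chromosomes.

        Matching ignores a ``chr`` prefix so ``{"X"}`` also selects ``chrX``.
        """
        import numpy as np

        wanted = {strip_chr_prefix(c) for c in chroms}
        return np.array([strip_chr_prefix(c) in wanted for c, _, _ in self.bins])

    def checksum(self) -> str:
        """SHA-256 over the bin coordinates and resolution; identifies the grid."""
        h = hashlib.sha256()
        h.update(str(self.resolution).encode())
        for c, s, e in self.bins:
            h.update(f"{c}:{s}-{e};".encode())
        return h.hexdigest()


def make_bin_grid(
    chrom_lengths: dict[str, int], resolution: int, assembly_label: str = "custom"
) -> BinGrid:
    """Tile chromosomes into fixed-width bins.

    Each chromosome of length ``L`` yields ``ceil(L / resolution)`` bins;
    the last bin is truncated at the chromosome end.
    """
    if not chrom_lengths:
        raise ConfigurationError("empty chromosome length table")
    if resolution <= 0:
        raise ConfigurationError(f"resolution must be positive, got {resolution}")
    bins: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ConfigurationError(f"non-positive length for {chrom!r}: {length}")
        for i in range(math.ceil(length / resolution)):
            start = i * resolution
            bins.append((chrom, start, min(start + resolution, length)))
    return BinGrid(tuple(bins), resolution, assembly_label)


def grch38_grid(resolution: int = 100_000, include_y: bool = True) -> BinGrid:
    """Default GRCh38 autosome + X (+ Y) grid at 100-kb resolution."""
    lengths = dict(GRCH38_LENGTHS)
    if not include_y:
        lengths.pop("chrY")
    return make_bin_grid(lengths, resolution, assembly_label="GRCh38")


def grch38_y_grid(resolution: int = 5_000) -> BinGrid:
    """Default GRCh38 chrY grid at 5-kb resolution (11,446 bins)."""
    return make_bin_grid(
        {"chrY": GRCH38_LENGTHS["chrY"]}, resolution, assembly_label="GRCh38"
    )
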