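"""Binned genome coordinate system for shallow-WGS copy-number analysis.

The pipeline never touches reads or a FASTA: everything downstream operates
on fixed-width genomic bins (default 1 Mb) carrying a GC fraction and a
usability flag. Chromosome lengths are a built-in human-like table so the
package is testable without downloads; coordinates are 0-based half-open
(BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeBins", "build_genome", "CHROMOSOME_LENGTHS_MB", "AUTOSOMES"]

# Human-like chromosome lengths in Mb (rounded to whole Mb; close to GRCh38).
CHROMOSOME_LENGTHS_MB: dict[str, int] = {
    "1": 249, "2": 242, "3": 198, "4": 190, "5": 182, "6": 171,
    "7": 159, "8": 145, "9": 138, "10": 134, "11": 135, "12": 133,
    "13": 114, "14": 107, "15": 102, "16": 90, "17": 83, "18": 80,
    "19": 59, "20": 64, "21": 47, "22": 51, "X": 156, "Y": 57,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

_GC_MEAN = 0.41
_GC_AR_COEF = 0.85        # lag-1 autocorrelation of the GC field; GC must
                          # decorrelate well within a chromosome so that GC
                          # and chromosome identity are not confounded
_GC_STATIONARY_SD = 0.05  # stationary SD of the walk before clipping
_GC_LO, _GC_HI = 0.2, 0.8


@dataclass
class GenomeBins:
    """Per-bin genome annotation: chromosome, interval, GC, usability.

    Bins within a chromosome are contiguous, non-overlapping and sorted;
    chromosomes appear in karyotype order (1..22, X, Y).
    """

    chrom: np.ndarray   # str per bin
    start: np.ndarray   # int64, 0-based inclusive
    end: np.ndarray     # int64, exclusive
    gc: np.ndarray      # float in [0.2, 0.8]
    usable: np.ndarray  # bool
    _slices: dict[str, slice] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.gc = np.asarray(self.gc, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.gc) == len(self.usable) == n):
            raise ValueError("GenomeBins fields must have equal length")
        if np.any(self.end <= self.start):
            raise ValueError("bins must have positive width")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("gc must lie in [0, 1]")
        self._slices = {}
        i = 0
        while i < n:
            c = self.chrom[i]
            j = i
            while j < n and self.chrom[j] == c:
                j += 1
            if c in self._slices:
                raise ValueError(f"chromosome {c} appears in two blocks")
            s = self.start[i:j]
            e = self.end[i:j]
            if j - i > 1 and (np.any(np.diff(s) <= 0) or np.any(s[1:] != e[:-1])):
                raise ValueError(f"bins on chromosome {c} must be sorted and contiguous")
            self._slices[c] = slice(i, j)
            i = j

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[chrom]

    def chrom_mask(self, chrom: str) -> np.ndarray:
        m = np.zeros(self.n_bins, dtype=bool)
        m[self._slices[chrom]] = True
        return m

    @property
    def is_autosome(self) -> np.ndarray:
        return np.isin(self.chrom.astype(str), AUTOSOMES)

    @property
    def is_x(self) -> np.ndarray:
        return self.chrom.astype(str) == "X"

    @property
    def is_y(self) -> np.ndarray:
        return self.chrom.astype(str) == "Y"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom.astype(str), "start": self.start,
             "end": self.end, "gc": self.gc, "usable": self.usable}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeBins":
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(),
            end=df["end"].to_numpy(),
            gc=df["gc"].to_numpy(dtype=float),
            usable=df["usable"].to_numpy(dtype=bool),
        )


def build_genome(
    bin_width: int = 1_000_000,
    scale: float = 1.0,
    seed: int = 0,
) -> GenomeBins:
    """Build a binned human-like genome with a smooth seeded GC field.

    Parameters
    ----------
    bin_width : int
        Bin width in bp; must be >= 10,000.
    scale : float
        Shrinks every chromosome proportionally (0 < scale <= 1); scale=0.05
        gives a ~150-bin genome for fast tests while keeping all 24
        chromosomes present.
    seed : int
        Seeds the GC random walk; identical seeds give identical GC.

    The GC fraction follows a per-chromosome AR(1) walk with mean 0.41 and
    stationary SD 0.05, clipped to [0.2, 0.8] — a smooth heterogeneous field
    sufficient to exercise GC correction, not a real-genome track.
    """
    if bin_width < 10_000:
        raise ValueError("bin_width must be >= 10,000 bp")
    if not (0 < scale <= 1):
        raise ValueError("scale must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    chroms, starts, ends = [], [], []
    for name, mb in CHROMOSOME_LENGTHS_MB.items():
        length = int(round(mb * 1_000_000 * scale))
        n = int(np.ceil(length / bin_width))
        if n < 1:
            raise ValueError(f"chromosome {name} has 0 bins at scale {scale}")
        s = np.arange(n, dtype=np.int64) * bin_width
        e = np.minimum(s + bin_width, length)
        chroms.extend([name] * n)
        starts.append(s)
        ends.append(e)
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    chrom = np.asarray(chroms, dtype=object)

    # AR(1) walk restarted at each chromosome boundary
    n_total = len(chrom)
    innov_sd = _GC_STATIONARY_SD * np.sqrt(1.0 - _GC_AR_COEF**2)
    gc = np.empty(n_total)
    i = 0
    while i < n_total:
        j = i
        while j < n_total and chrom[j] == chrom[i]:
            j += 1
        m = j - i
        eps = rng.normal(0.0, innov_sd, size=m)
        walk = np.empty(m)
        walk[0] = rng.normal(0.0, _GC_STATIONARY_SD)
        for k in range(1, m):
            walk[k] = _GC_AR_COEF * walk[k - 1] + eps[k]
        gc[i:j] = _GC_MEAN + walk
        i = j
    gc = np.clip(gc, _GC_LO, _GC_HI)

    return GenomeBins(
        chrom=chrom, start=start, end=end, gc=gc,
        usable=np.ones(n_total, dtype=bool),
    )
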