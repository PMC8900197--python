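"""Read-count simulator for embryo liquid-biopsy copy-number screening.

Generates per-bin shallow-WGS read counts with the statistical structure the
downstream analysis assumes: ~2 million reads per sample over ~3,000 one-Mb
bins, a smooth multiplicative GC coverage bias, negative-binomial
amplification overdispersion, bin dropout, whole-chromosome and segmental
gains/losses with mosaic fractions, and optional mixing with a 46,XX
(maternal) contaminant. The model is linear in copy number: a chromosome at
three copies produces a 50% increase in expected read counts over the
disomic baseline, a one-copy chromosome a 50% decrease, and a mosaic event
of fraction m shifts the expectation by a factor 1 + m*(cn-2)/2.

Source profiles emulate the sample types of a non-invasive screening study:
spent culture medium (SCM), blastocoel fluid (BF, lower DNA input hence
noisier), and the cell-based references (ICM/WB).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeBins

__all__ = [
    "CnvEvent",
    "SampleKaryotype",
    "SourceProfile",
    "BinCounts",
    "DEFAULT_PROFILES",
    "simulate_sample",
    "simulate_reference_panel",
    "simulate_cohort",
    "technical_success",
    "expected_copy_number",
]

_GC_PIVOT = 0.41  # bias factor is 1 at the genome-average GC


@dataclass(frozen=True)
class CnvEvent:
    """One gain/loss event: bin interval (half-open, chromosome-local bin
    indices), target copy number, and mosaic fraction m (m=1 is full)."""

    chrom: str
    start_bin: int
    end_bin: int
    copy_number: int
    mosaic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.copy_number not in (0, 1, 3, 4):
            raise ValueError("event copy_number must be one of {0, 1, 3, 4}")
        if not (0 < self.mosaic_fraction <= 1):
            raise ValueError("mosaic_fraction must lie in (0, 1]")
        if self.end_bin <= self.start_bin:
            raise ValueError("event interval must be non-empty")


@dataclass(frozen=True)
class SampleKaryotype:
    """Simulation ground truth: constitutional sex plus a list of CNV events.

    An empty event list is a euploid truth.
    """

    sex: str = "XX"
    events: tuple[CnvEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in ("XX", "XY"):
            raise ValueError("sex must be 'XX' or 'XY'")
        object.__setattr__(self, "events", tuple(self.events))
        by_chrom: dict[str, list[CnvEvent]] = {}
        for ev in self.events:
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for evs in by_chrom.values():
            evs.sort(key=lambda e: e.start_bin)
            for a, b in zip(evs, evs[1:]):
                if b.start_bin < a.end_bin:
                    raise ValueError("events overlap")

    @property
    def is_euploid(self) -> bool:
        return len(self.events) == 0

    @property
    def classification(self) -> str:
        return "euploid" if self.is_euploid else "aneuploid"


@dataclass(frozen=True)
class SourceProfile:
    """Noise/technical profile of one DNA source.

    dispersion is the negative-binomial overdispersion alpha with
    var = mu * (1 + alpha * mu); alpha -> 0 recovers Poisson counts.
    gc_bias_strength scales a log-linear GC coverage bias
    exp(strength * (gc - 0.41)). contamination is the read fraction
    originating from a 46,XX contaminant genome.
    """

    total_reads: int = 2_000_000
    dispersion: float = 0.01
    gc_bias_strength: float = 1.0
    dropout_rate: float = 0.0
    contamination: float = 0.0

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError("total_reads must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not (0 <= self.contamination <= 1):
            raise ValueError("contamination must lie in [0, 1]")


#: Default source profiles. SCM: full read yield, moderate WGA
#: overdispersion. BF: ~5-fold lower DNA input emulated as fewer effective
#: reads, higher dispersion and bin dropout. ICM/WB: cell-based references,
#: cleaner amplification.
DEFAULT_PROFILES: dict[str, SourceProfile] = {
    "SCM": SourceProfile(total_reads=2_000_000, dispersion=0.01,
                         gc_bias_strength=1.0, dropout_rate=0.0),
    "BF": SourceProfile(total_reads=1_000_000, dispersion=0.05,
                        gc_bias_strength=1.0, dropout_rate=0.10),
    "ICM": SourceProfile(total_reads=2_000_000, dispersion=0.002,
                         gc_bias_strength=0.5, dropout_rate=0.0),
    "WB": SourceProfile(total_reads=2_000_000, dispersion=0.002,
                        gc_bias_strength=0.5, dropout_rate=0.0),
}


@dataclass
class BinCounts:
    """One sample's non-negative integer read count per genome bin."""

    sample_id: str
    source: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def _base_copy_number(genome: GenomeBins, sex: str) -> np.ndarray:
    cn = np.full(genome.n_bins, 2.0)
    if sex == "XY":
        cn[genome.is_x] = 1.0
        cn[genome.is_y] = 1.0
    else:
        cn[genome.is_y] = 0.0
    return cn


def expected_copy_number(truth: SampleKaryotype, genome: GenomeBins) -> np.ndarray:
    """Per-bin effective copy number: base ploidy with mosaic events
    interpolated as base + m*(cn - base)."""
    cn = _base_copy_number(genome, truth.sex)
    for ev in truth.events:
        if ev.chrom not in genome.chromosomes:
            raise ValueError(f"event chromosome {ev.chrom} not in genome")
        sl = genome.chrom_slice(ev.chrom)
        n_chrom = sl.stop - sl.start
        if not (0 <= ev.start_bin < ev.end_bin <= n_chrom):
            raise ValueError("event interval outside chromosome bins")
        idx = slice(sl.start + ev.start_bin, sl.start + ev.end_bin)
        base = cn[idx]
        cn[idx] = base + ev.mosaic_fraction * (ev.copy_number - base)
    return cn


def _round_to_total(scaled: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding so the integer counts sum exactly to total."""
    floor = np.floor(scaled).astype(np.int64)
    remainder = int(total - floor.sum())
    if remainder > 0:
        frac = scaled - floor
        take = np.argsort(-frac, kind="stable")[:remainder]
        floor[take] += 1
    return floor


def simulate_sample(
    truth: SampleKaryotype,
    profile: SourceProfile,
    genome: GenomeBins,
    seed: int,
    sample_id: str = "sample",
    source: str = "SCM",
) -> BinCounts:
    """Draw one sample's per-bin read counts.

    Expected intensity in bin b is
    [(1-c)*cn_embryo(b)/2 + c*cn_XX(b)/2] * exp(s*(gc_b - 0.41)) * usable_b,
    with c the contamination fraction and s the GC-bias strength; counts are
    negative-binomial draws rescaled to the profile's exact total_reads.
    """
    if not np.any(genome.usable):
        raise ValueError("genome has no usable bins")
    rng = np.random.default_rng(seed)

    cn_embryo = expected_copy_number(truth, genome)
    cn_contam = _base_copy_number(genome, "XX")
    c = profile.contamination
    dosage = (1.0 - c) * cn_embryo / 2.0 + c * cn_contam / 2.0
    bias = np.exp(profile.gc_bias_strength * (genome.gc - _GC_PIVOT))
    intensity = dosage * bias * genome.usable

    if profile.dropout_rate > 0:
        dropped = rng.random(genome.n_bins) < profile.dropout_rate
        intensity = np.where(dropped, 0.0, intensity)

    total_intensity = intensity.sum()
    if total_intensity <= 0:
        raise ValueError("all bins have zero expected intensity")
    mu = profile.total_reads * intensity / total_intensity

    if profile.dispersion <= 1e-12:
        raw = rng.poisson(mu).astype(float)
    else:
        # NB with var = mu*(1 + alpha*mu): shape r = 1/alpha, p = r/(r+mu)
        r = 1.0 / profile.dispersion
        p = r / (r + mu)
        raw = np.where(mu > 0, rng.negative_binomial(r, np.maximum(p, 1e-12)), 0).astype(float)

    raw_total = raw.sum()
    if raw_total <= 0:
        raise ValueError("simulated zero total reads; increase total_reads")
    counts = _round_to_total(raw * (profile.total_reads / raw_total), profile.total_reads)
    return BinCounts(sample_id=sample_id, source=source, counts=counts)


def technical_success(
    counts: BinCounts, genome: GenomeBins, min_nonzero_fraction: float = 0.8
) -> bool:
    """A sample yields reliable data when enough usable bins received reads.

    Mirrors the screening notion of technical success: a sample whose
    nonzero-bin fraction (over usable bins) falls below the threshold is a
    'no result'.
    """
    usable = genome.usable
    if not np.any(usable):
        return False
    frac = np.mean(counts.counts[usable] > 0)
    return bool(frac >= min_nonzero_fraction)


def simulate_reference_panel(
    n_ref: int,
    profile: SourceProfile,
    genome: GenomeBins,
    seed: int,
    source: str = "control",
) -> tuple[list[BinCounts], list[SampleKaryotype]]:
    """Simulate a euploid reference panel (alternating XX / XY truths).

    Returns the panel counts together with their (event-free) truths.
    """
    if n_ref < 3:
        raise ValueError("a reference panel needs at least 3 samples")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31, size=n_ref)
    counts, truths = [], []
    for k in range(n_ref):
        truth = SampleKaryotype(sex="XX" if k % 2 == 0 else "XY")
        counts.append(
            simulate_sample(truth, profile, genome, int(seeds[k]),
                            sample_id=f"ref{k:03d}", source=source)
        )
        truths.append(truth)
    return counts, truths


def simulate_cohort(
    n: int,
    aneuploid_rate: float,
    mosaic_rate: float,
    profiles: dict[str, SourceProfile],
    genome: GenomeBins,
    seed: int,
    mosaic_range: tuple[float, float] = (0.5, 0.95),
    autosomes_only: bool = True,
) -> tuple[list[SampleKaryotype], dict[str, list[BinCounts]]]:
    """Simulate a cohort of embryos, one truth each, one BinCounts per source.

    Each aneuploid truth carries a single random whole-chromosome gain or
    loss (cn 3 or 1); with probability mosaic_rate the event is mosaic with
    m drawn uniformly from mosaic_range. Defaults mirror a screening cohort
    with an aneuploidy rate of 47/148 ~ 31.8%.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if not (0 <= aneuploid_rate <= 1 and 0 <= mosaic_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    candidates = [c for c in genome.chromosomes if autosomes_only and c not in ("X", "Y")] \
        or genome.chromosomes

    truths: list[SampleKaryotype] = []
    for _ in range(n):
        sex = "XX" if rng.random() < 0.5 else "XY"
        events: tuple[CnvEvent, ...] = ()
        if rng.random() < aneuploid_rate:
            chrom = candidates[rng.integers(len(candidates))]
            n_chrom = genome.chrom_slice(chrom).stop - genome.chrom_slice(chrom).start
            cn = 3 if rng.random() < 0.5 else 1
            m = 1.0
            if rng.random() < mosaic_rate:
                m = float(rng.uniform(*mosaic_range))
            events = (CnvEvent(chrom, 0, n_chrom, cn, m),)
        truths.append(SampleKaryotype(sex=sex, events=events))

    counts: dict[str, list[BinCounts]] = {src: [] for src in profiles}
    for src, profile in profiles.items():
        seeds = rng.integers(0, 2**31, size=n)
        for k, truth in enumerate(truths):
            counts[src].append(
                simulate_sample(truth, profile, genome, int(seeds[k]),
                                sample_id=f"emb{k:03d}", source=src)
            )
    return truths, counts
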