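"""Copy-number and ploidy calling from CBS segments.

The copy-ratio scale is linear in cellular fraction: a whole-chromosome
event present in a fraction m of cells shifts the chromosome ratio to
1 + m*(cn-2)/2, so the mosaic fraction is recovered as m = 2*|r - 1| for
single-copy events. Only mosaicism at or above 50% is reported; events with
estimated m below the reporting floor are treated as euploid, matching
clinical practice for non-invasive screening. A band above ``full_cutoff``
separates "full" aneuploidy (printed with integer copy numbers, e.g.
47,XY,+21) from reported mosaics (printed with the fraction, e.g.
46,XX,+16[0.6]).

``AneuploidyCaller`` applies the rules per sample; ``AneuploidyScreen``
chains normalization, segmentation and calling into one scikit-learn style
fit/predict estimator over raw count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .genome import GenomeBins
from .normalize import (
    CopyRatioNormalizer,
    CopyRatioProfile,
    SampleNotAnalyzableError,
)
from .segment import CBSSegmenter, Segment
from .simulate import BinCounts

__all__ = [
    "ChromosomeCall",
    "PloidyCall",
    "mosaic_fraction",
    "call_chromosome",
    "call_sex",
    "classify_sample",
    "AneuploidyCaller",
    "AneuploidyScreen",
]

POSITIVE_CLASS = "aneuploid/mosaic"

_STATES = ("euploid", "gain", "loss", "mosaic_gain", "mosaic_loss", "segmental")


@dataclass
class ChromosomeCall:
    chrom: str
    state: str = "euploid"
    estimated_cn: float = 2.0          # 2*r of the dominant segment
    mosaic_fraction: float | None = None
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")


@dataclass
class PloidyCall:
    sample_id: str
    classification: str  # euploid | aneuploid/mosaic | no_result
    karyotype: str
    sex: str             # XX | XY | indeterminate
    chromosome_calls: list[ChromosomeCall] = field(default_factory=list)

    @property
    def is_positive(self) -> bool:
        return self.classification == POSITIVE_CLASS


def mosaic_fraction(r: float, direction: str) -> float:
    """Invert the linear mixture r = 1 + m*(cn-2)/2 for single-copy events:
    m = clamp(2*|r-1|, 0, 1). Returns 0 when the direction contradicts the
    sign of the shift."""
    if r < 0:
        raise ValueError("ratio must be non-negative")
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    if (direction == "gain" and r < 1) or (direction == "loss" and r > 1):
        return 0.0
    return float(np.clip(2.0 * abs(r - 1.0), 0.0, 1.0))


def call_chromosome(
    segments: list[Segment],
    chrom: str | None = None,
    report_floor: float = 0.5,
    full_cutoff: float = 0.8,
    whole_chrom_fraction: float = 0.8,
    min_segment_bins: int = 10,
) -> ChromosomeCall:
    """Call one chromosome from its segment partition.

    The dominant deviating segment (largest |mean - 1|) drives the call: a
    segment spanning >= whole_chrom_fraction of the chromosome's bins with
    m >= full_cutoff is a full gain/loss; with report_floor <= m <
    full_cutoff a mosaic gain/loss; below report_floor the chromosome is
    reported euploid. A sub-chromosomal deviating segment of at least
    min_segment_bins with m >= report_floor is reported as segmental.
    """
    if not segments:
        raise ValueError("call_chromosome needs at least one segment")
    chrom = chrom if chrom is not None else segments[0].chrom
    total_bins = sum(s.n_bins for s in segments)
    dominant = max(segments, key=lambda s: (abs(s.mean - 1.0), -s.start))
    r = dominant.mean
    direction = "gain" if r > 1 else "loss"
    m = mosaic_fraction(r, direction)
    est_cn = 2.0 * r

    if m < report_floor:
        return ChromosomeCall(chrom=chrom, estimated_cn=est_cn, segments=[dominant])
    span = dominant.n_bins / total_bins
    if span >= whole_chrom_fraction:
        if m >= full_cutoff:
            state = direction
            m_out = 1.0
        else:
            state = f"mosaic_{direction}"
            m_out = m
        return ChromosomeCall(chrom=chrom, state=state, estimated_cn=est_cn,
                              mosaic_fraction=m_out, segments=[dominant])
    if dominant.n_bins >= min_segment_bins:
        return ChromosomeCall(chrom=chrom, state="segmental", estimated_cn=est_cn,
                              mosaic_fraction=m, segments=[dominant])
    return ChromosomeCall(chrom=chrom, estimated_cn=est_cn, segments=[dominant])


def call_sex(
    profile: CopyRatioProfile,
    xx_window: tuple[float, float] = (0.8, 1.2),
    xy_window: tuple[float, float] = (0.35, 0.65),
    y_present_threshold: float = 0.5,
) -> str:
    """Sex from sex-chromosome dosage.

    The X dosage is judged against the XX panel branch (X ~ 1 for XX,
    ~ 0.5 for XY); Y presence is judged against the XY panel branch
    (Y ~ 1 when a Y is present, ~ 0 otherwise) and must agree with the X
    window, else the call is indeterminate.
    """
    x = profile.x_ratio_vs_xx
    y = profile.y_ratio_vs_xy
    if not np.isfinite(x):
        return "indeterminate"
    y_present = np.isfinite(y) and y >= y_present_threshold
    if xx_window[0] <= x <= xx_window[1] and not y_present:
        return "XX"
    if xy_window[0] <= x <= xy_window[1] and (y_present or not np.isfinite(y)):
        return "XY"
    return "indeterminate"


def _format_m(m: float) -> str:
    s = f"{m:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def classify_sample(
    chromosome_calls: list[ChromosomeCall],
    sex: str,
    sample_id: str = "sample",
    technical_failure: bool = False,
) -> PloidyCall:
    """Sample-level two-category classification and ISCN-like karyotype.

    Any non-euploid chromosome makes the sample aneuploid/mosaic; a
    technical failure yields no_result. Full whole-chromosome events change
    the modal count (47,XY,+21; 45,XX,-16); reported mosaics keep 46 and
    append the fraction (46,XX,+16[0.6]); segmental events print as
    dup/del (46,XY,del(7)[0.8]).
    """
    if technical_failure:
        return PloidyCall(sample_id=sample_id, classification="no_result",
                          karyotype="", sex=sex, chromosome_calls=chromosome_calls)
    abnormal = [c for c in chromosome_calls if c.state != "euploid"]
    count = 46
    parts: list[str] = []
    for c in abnormal:
        if c.state in ("gain", "loss"):
            cn_int = int(round(c.estimated_cn))
            if cn_int == 2:
                cn_int = 3 if c.state == "gain" else 1
            count += cn_int - 2
            parts.append(("+" if c.state == "gain" else "-") + c.chrom)
        elif c.state in ("mosaic_gain", "mosaic_loss"):
            sign = "+" if c.state == "mosaic_gain" else "-"
            parts.append(f"{sign}{c.chrom}[{_format_m(c.mosaic_fraction)}]")
        else:  # segmental
            kind = "dup" if c.estimated_cn > 2 else "del"
            parts.append(f"{kind}({c.chrom})[{_format_m(c.mosaic_fraction)}]")
    sex_token = sex if sex in ("XX", "XY") else "??"
    karyotype = ",".join([str(count), sex_token] + parts)
    classification = POSITIVE_CLASS if abnormal else "euploid"
    return PloidyCall(sample_id=sample_id, classification=classification,
                      karyotype=karyotype, sex=sex, chromosome_calls=chromosome_calls)


class AneuploidyCaller(BaseEstimator):
    """Applies the chromosome- and sample-level calling rules to
    (profile, segments) pairs produced by the normalizer and segmenter."""

    def __init__(
        self,
        report_floor: float = 0.5,
        full_cutoff: float = 0.8,
        whole_chrom_fraction: float = 0.8,
        min_segment_bins: int = 10,
        xx_window: tuple[float, float] = (0.8, 1.2),
        xy_window: tuple[float, float] = (0.35, 0.65),
    ) -> None:
        self.report_floor = report_floor
        self.full_cutoff = full_cutoff
        self.whole_chrom_fraction = whole_chrom_fraction
        self.min_segment_bins = min_segment_bins
        self.xx_window = xx_window
        self.xy_window = xy_window

    def fit(self, X=None, y=None) -> "AneuploidyCaller":
        return self

    def call(
        self,
        profile: CopyRatioProfile,
        segments: dict[str, list[Segment]],
        technical_failure: bool = False,
    ) -> PloidyCall:
        calls = []
        for chrom, segs in segments.items():
            if not segs:
                continue
            calls.append(call_chromosome(
                segs, chrom=chrom, report_floor=self.report_floor,
                full_cutoff=self.full_cutoff,
                whole_chrom_fraction=self.whole_chrom_fraction,
                min_segment_bins=self.min_segment_bins,
            ))
        sex = call_sex(profile, xx_window=self.xx_window, xy_window=self.xy_window)
        return classify_sample(calls, sex, sample_id=profile.sample_id,
                               technical_failure=technical_failure)

    def predict(self, pairs: list[tuple[CopyRatioProfile, dict[str, list[Segment]]]]) -> np.ndarray:
        return np.asarray([self.call(p, s).classification for p, s in pairs], dtype=object)


class AneuploidyScreen(BaseEstimator):
    """End-to-end screen: counts -> ratios -> segments -> ploidy call.

    ``fit(X)`` consumes a euploid reference-panel count matrix;
    ``predict(X)`` returns 'euploid' / 'aneuploid/mosaic' / 'no_result'
    labels per sample, and ``screen`` the full :class:`PloidyCall` objects.
    """

    def __init__(
        self,
        genome: GenomeBins | None = None,
        normalizer: CopyRatioNormalizer | None = None,
        segmenter: CBSSegmenter | None = None,
        caller: AneuploidyCaller | None = None,
        random_state: int = 0,
    ) -> None:
        self.genome = genome
        self.normalizer = normalizer
        self.segmenter = segmenter
        self.caller = caller
        self.random_state = random_state

    def fit(self, X, y=None, sexes: list[str] | None = None) -> "AneuploidyScreen":
        if self.genome is None:
            raise ValueError("AneuploidyScreen requires a genome")
        self.normalizer_ = self.normalizer or CopyRatioNormalizer(genome=self.genome)
        self.normalizer_.set_params(genome=self.genome)
        self.normalizer_.fit(X, sexes=sexes)
        self.segmenter_ = self.segmenter or CBSSegmenter(
            genome=self.genome, random_state=self.random_state)
        self.segmenter_.set_params(genome=self.genome)
        self.caller_ = self.caller or AneuploidyCaller()
        return self

    def screen_one(self, counts: BinCounts) -> PloidyCall:
        if not hasattr(self, "normalizer_"):
            raise RuntimeError("AneuploidyScreen is not fitted")
        try:
            profile = self.normalizer_.transform_profile(counts)
        except SampleNotAnalyzableError:
            return PloidyCall(sample_id=counts.sample_id, classification="no_result",
                              karyotype="", sex="indeterminate")
        segments = self.segmenter_.segment(profile)
        return self.caller_.call(profile, segments)

    def screen(self, X) -> list[PloidyCall]:
        rows = self.normalizer_._rows(X)
        return [self.screen_one(bc) for bc in rows]

    def predict(self, X) -> np.ndarray:
        return np.asarray([c.classification for c in self.screen(X)], dtype=object)
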