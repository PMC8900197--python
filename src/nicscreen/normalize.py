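"""Raw bin counts -> copy-ratio profile.

Four steps, matching standard shallow-WGS CNV practice: (1) bin filtering
(usability, GC range, reference-panel support, dropout), (2) GC correction
by dividing out a lowess trend of log2 depth versus GC fitted on autosomal
bins, (3) normalization against a euploid reference panel of per-bin
medians, kept separately for XX and XY panel samples so sex chromosomes
have a meaningful baseline, and (4) anchoring so the median autosomal ratio
is exactly 1. On this scale a chromosome at three copies sits at ratio 1.5
and a one-copy chromosome at 0.5; a mosaic of fraction m at 1 +- m/2.

`CopyRatioNormalizer` packages the steps as a scikit-learn transformer:
``fit`` consumes a matrix of euploid panel counts, ``transform`` maps
sample count matrices to copy-ratio matrices (NaN at masked bins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeBins
from .simulate import BinCounts

__all__ = [
    "SampleNotAnalyzableError",
    "ReferencePanel",
    "CopyRatioProfile",
    "filter_bins",
    "gc_correct",
    "build_panel",
    "reference_normalize",
    "CopyRatioNormalizer",
]

logger = logging.getLogger(__name__)


class SampleNotAnalyzableError(RuntimeError):
    """Raised when too few informative bins remain (technical failure)."""


@dataclass
class ReferencePanel:
    """Per-bin median normalized depth of a euploid panel, by panel sex.

    Autosomal medians pool all panel samples; X medians come from the XX and
    XY subsets respectively and Y medians only from XY samples (Y coverage in
    XX samples is background and carries no baseline). NaN marks bins masked
    by low median or excess panel variability (CV above ``cv_cutoff``).
    """

    median_xx: np.ndarray
    median_xy: np.ndarray
    n_samples: int
    cv_cutoff: float

    @property
    def n_bins(self) -> int:
        return len(self.median_xx)

    def branch(self, sex: str) -> np.ndarray:
        return self.median_xx if sex == "XX" else self.median_xy


@dataclass
class CopyRatioProfile:
    """Normalized per-bin copy ratios (NaN where invalid), anchored so the
    median valid autosomal ratio is 1."""

    sample_id: str
    ratio: np.ndarray
    valid: np.ndarray
    baseline: float                  # autosomal median depth before anchoring
    sex_model: str = "XX"            # panel branch the ratios were computed against
    x_ratio_vs_xx: float = float("nan")  # mean X ratio against the XX branch
    y_ratio_vs_xy: float = float("nan")  # mean Y ratio against the XY branch

    @property
    def n_bins(self) -> int:
        return len(self.ratio)


def filter_bins(
    counts: BinCounts,
    genome: GenomeBins,
    panel: ReferencePanel | None = None,
    gc_range: tuple[float, float] = (0.2, 0.8),
    min_panel_median: float = 0.1,
    mask_zero: bool = True,
    max_masked_autosomal_fraction: float = 0.5,
) -> tuple[BinCounts, np.ndarray]:
    """Mask uninformative bins; error out when the sample is not analyzable.

    A bin is masked when it is flagged unusable in the genome, its GC falls
    outside ``gc_range``, its reference-panel median (better branch) is below
    ``min_panel_median``, or (by default) it received zero reads. If more
    than ``max_masked_autosomal_fraction`` of autosomal bins are masked the
    sample is declared not analyzable — the pipeline's technical-failure
    category.
    """
    if counts.n_bins != genome.n_bins:
        raise ValueError("counts not aligned to genome bins")
    mask = genome.usable.copy()
    mask &= (genome.gc >= gc_range[0]) & (genome.gc <= gc_range[1])
    if panel is not None:
        best = np.fmax(np.nan_to_num(panel.median_xx, nan=0.0),
                       np.nan_to_num(panel.median_xy, nan=0.0))
        auto_or_ok = best >= min_panel_median
        mask &= auto_or_ok
    if mask_zero:
        mask &= counts.counts > 0
    auto = genome.is_autosome
    masked_frac = 1.0 - np.mean(mask[auto])
    logger.info(
        "filter_bins[%s]: %d/%d bins masked (%.1f%% of autosomal)",
        counts.sample_id, int((~mask).sum()), genome.n_bins, 100 * masked_frac,
    )
    if masked_frac > max_masked_autosomal_fraction:
        raise SampleNotAnalyzableError(
            f"sample {counts.sample_id}: {100 * masked_frac:.1f}% of autosomal "
            "bins masked — not analyzable"
        )
    return counts, mask


def gc_correct(
    counts: BinCounts,
    genome: GenomeBins,
    mask: np.ndarray | None = None,
    span: float = 0.3,
    robust_iter: int = 2,
    min_bins: int = 100,
    max_fit_points: int = 2000,
) -> np.ndarray:
    """Divide out a lowess trend of log2 depth versus GC.

    The trend is fitted on valid autosomal bins (robust lowess, fraction
    ``span``, ``robust_iter`` re-weighting iterations; at most
    ``max_fit_points`` evenly-spaced points for speed) and evaluated at every
    valid bin by interpolation over GC. The output preserves the mean
    autosomal depth; masked bins are NaN.
    """
    if mask is None:
        mask = np.ones(genome.n_bins, dtype=bool)
    depth = counts.counts.astype(float)
    if depth[mask].sum() <= 0:
        raise ValueError("all valid counts are zero")
    valid = mask & (depth > 0)
    fit_bins = valid & genome.is_autosome
    n_fit = int(fit_bins.sum())
    if n_fit < min_bins:
        raise SampleNotAnalyzableError(
            f"only {n_fit} valid autosomal bins (< {min_bins}) for GC fit"
        )

    gc_fit = genome.gc[fit_bins]
    y_fit = np.log2(depth[fit_bins])
    if np.ptp(gc_fit) < 1e-9:
        trend_at = np.full(genome.n_bins, 0.0)  # constant GC: nothing to remove
    else:
        order = np.argsort(gc_fit, kind="stable")
        gc_s, y_s = gc_fit[order], y_fit[order]
        if len(gc_s) > max_fit_points:
            sel = np.linspace(0, len(gc_s) - 1, max_fit_points).astype(int)
            gc_s, y_s = gc_s[sel], y_s[sel]
        fitted = lowess(y_s, gc_s, frac=span, it=robust_iter, return_sorted=True)
        xs, ys = fitted[:, 0], fitted[:, 1]
        trend_at = np.interp(genome.gc, xs, ys)
        trend_at = trend_at - np.mean(np.interp(gc_fit, xs, ys))

    corrected = np.where(valid, depth / np.exp2(trend_at), np.nan)
    # preserve mean autosomal depth
    before = depth[fit_bins].mean()
    after = np.nanmean(corrected[fit_bins])
    corrected = corrected * (before / after)
    return corrected


def _infer_panel_sexes(depths: np.ndarray, genome: GenomeBins) -> list[str]:
    """Classify panel samples as XX/XY from relative Y coverage."""
    auto_med = np.nanmedian(depths[:, genome.is_autosome], axis=1)
    y_cols = depths[:, genome.is_y]
    with np.errstate(invalid="ignore"):
        y_rel = np.nanmedian(np.nan_to_num(y_cols, nan=0.0), axis=1) / auto_med
    return ["XY" if r > 0.25 else "XX" for r in y_rel]


def build_panel(
    panel_depths: list[np.ndarray],
    genome: GenomeBins,
    sexes: list[str] | None = None,
    cv_cutoff: float = 0.3,
) -> ReferencePanel:
    """Median-combine GC-corrected euploid depths into a reference panel.

    Each sample is scaled to its autosomal median; per-bin medians are taken
    across all samples on autosomes and within the XX / XY subsets on the
    sex chromosomes. Bins whose across-panel coefficient of variation
    exceeds ``cv_cutoff``, or whose median is not positive, are masked (NaN).
    """
    if len(panel_depths) < 3:
        raise ValueError("a reference panel needs at least 3 samples")
    depths = np.vstack([np.asarray(d, dtype=float) for d in panel_depths])
    if depths.shape[1] != genome.n_bins:
        raise ValueError("panel depths not aligned to genome bins")
    auto = genome.is_autosome
    scale = np.nanmedian(depths[:, auto], axis=1)
    if np.any(~np.isfinite(scale)) or np.any(scale <= 0):
        raise ValueError("panel sample with non-positive autosomal median")
    norm = depths / scale[:, None]
    if sexes is None:
        sexes = _infer_panel_sexes(norm, genome)
    sexes_arr = np.asarray(sexes, dtype=object)

    def _combine(rows: np.ndarray, cols: np.ndarray, out_med: np.ndarray) -> None:
        if not rows.any():
            return
        sub = norm[np.ix_(rows, cols)]
        with np.errstate(invalid="ignore"):
            med = np.nanmedian(sub, axis=0)
            mean = np.nanmean(sub, axis=0)
            sd = np.nanstd(sub, axis=0, ddof=1) if rows.sum() > 1 else np.zeros(sub.shape[1])
            cv = np.where(mean > 0, sd / mean, np.inf)
        med = np.where((med > 0) & (cv <= cv_cutoff), med, np.nan)
        out_med[cols] = med

    all_rows = np.ones(len(sexes_arr), dtype=bool)
    xx_rows = sexes_arr == "XX"
    xy_rows = sexes_arr == "XY"

    median_xx = np.full(genome.n_bins, np.nan)
    median_xy = np.full(genome.n_bins, np.nan)
    _combine(all_rows, auto, median_xx)
    median_xy[auto] = median_xx[auto]
    _combine(xx_rows, genome.is_x, median_xx)
    _combine(xy_rows, genome.is_x, median_xy)
    _combine(xy_rows, genome.is_y, median_xy)
    # Y against an XX panel has no baseline: stays NaN in median_xx

    if not np.any(np.isfinite(median_xx[auto])):
        raise ValueError("reference panel masked every autosomal bin")
    return ReferencePanel(median_xx=median_xx, median_xy=median_xy,
                          n_samples=len(panel_depths), cv_cutoff=cv_cutoff)


def _finite_mean(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    return float(finite.mean()) if len(finite) else float("nan")


def _branch_ratio(depths: np.ndarray, median: np.ndarray, auto: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = depths / median
    anchor = np.nanmedian(r[auto])
    if not np.isfinite(anchor) or anchor <= 0:
        raise SampleNotAnalyzableError("no valid autosomal bins after panel intersection")
    return r / anchor


def reference_normalize(
    depths: np.ndarray,
    panel: ReferencePanel,
    genome: GenomeBins,
    sample_id: str = "sample",
    sex_windows: tuple[tuple[float, float], tuple[float, float]] = ((0.8, 1.2), (0.35, 0.65)),
) -> CopyRatioProfile:
    """Divide GC-corrected depths by the panel medians and anchor the
    autosomal median ratio to exactly 1.

    The sample is normalized against both panel branches; the X dosage
    against the XX branch together with the Y dosage against the XY branch
    selects the better-fitting sex model, which determines the branch used
    for the sex chromosomes of the returned profile.
    """
    if len(depths) != panel.n_bins or panel.n_bins != genome.n_bins:
        raise ValueError("depths, panel and genome must share bins")
    auto = genome.is_autosome
    r_xx = _branch_ratio(depths, panel.median_xx, auto)
    r_xy = _branch_ratio(depths, panel.median_xy, auto)

    x_vs_xx = _finite_mean(r_xx[genome.is_x])
    y_vs_xy = _finite_mean(r_xy[genome.is_y])

    (xx_lo, xx_hi), (xy_lo, xy_hi) = sex_windows
    sex_model = "XX"
    if np.isfinite(x_vs_xx) and xy_lo <= x_vs_xx <= xy_hi:
        sex_model = "XY"

    r = r_xx if sex_model == "XX" else r_xy
    valid = np.isfinite(r)
    if not valid.any():
        raise SampleNotAnalyzableError("no valid bins after normalization")
    baseline = float(np.nanmedian(depths[auto]))
    return CopyRatioProfile(
        sample_id=sample_id, ratio=r, valid=valid, baseline=baseline,
        sex_model=sex_model, x_ratio_vs_xx=x_vs_xx, y_ratio_vs_xy=y_vs_xy,
    )


class CopyRatioNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer: euploid panel counts -> fitted
    reference, sample counts -> per-bin copy ratios.

    Parameters
    ----------
    genome : GenomeBins
        Bin annotation shared by panel and samples.
    gc_span, gc_robust_iter : float, int
        Lowess span and robustness iterations of the GC fit.
    gc_range : (float, float)
        Bins with GC outside this range are masked.
    min_panel_median : float
        Bins whose panel median normalized depth falls below this are masked.
    cv_cutoff : float
        Bins with across-panel coefficient of variation above this are masked.
    min_bins : int
        Minimum valid autosomal bins required for the GC fit.
    max_masked_autosomal_fraction : float
        Beyond this masked fraction a sample raises SampleNotAnalyzableError.

    Attributes
    ----------
    panel_ : ReferencePanel
        Fitted per-bin medians (XX and XY branches).
    n_features_in_ : int
        Number of genome bins.
    """

    def __init__(
        self,
        genome: GenomeBins | None = None,
        gc_span: float = 0.3,
        gc_robust_iter: int = 2,
        gc_range: tuple[float, float] = (0.2, 0.8),
        min_panel_median: float = 0.1,
        cv_cutoff: float = 0.3,
        min_bins: int = 100,
        max_masked_autosomal_fraction: float = 0.5,
        sex_windows: tuple[tuple[float, float], tuple[float, float]] = ((0.8, 1.2), (0.35, 0.65)),
    ) -> None:
        self.genome = genome
        self.gc_span = gc_span
        self.gc_robust_iter = gc_robust_iter
        self.gc_range = gc_range
        self.min_panel_median = min_panel_median
        self.cv_cutoff = cv_cutoff
        self.min_bins = min_bins
        self.max_masked_autosomal_fraction = max_masked_autosomal_fraction
        self.sex_windows = sex_windows

    def _as_bincounts(self, row: np.ndarray, sample_id: str) -> BinCounts:
        return BinCounts(sample_id=sample_id, source="NA", counts=np.asarray(row))

    def _corrected_depth(self, counts: BinCounts, panel: ReferencePanel | None) -> np.ndarray:
        counts, mask = filter_bins(
            counts, self.genome, panel=panel, gc_range=self.gc_range,
            min_panel_median=self.min_panel_median,
            max_masked_autosomal_fraction=self.max_masked_autosomal_fraction,
        )
        return gc_correct(
            counts, self.genome, mask, span=self.gc_span,
            robust_iter=self.gc_robust_iter, min_bins=self.min_bins,
        )

    def fit(self, X, y=None, sexes: list[str] | None = None) -> "CopyRatioNormalizer":
        """Fit the reference panel from a (n_panel_samples, n_bins) euploid
        count matrix (or a list of BinCounts)."""
        if self.genome is None:
            raise ValueError("CopyRatioNormalizer requires a genome")
        rows = self._rows(X)
        depths = [self._corrected_depth(bc, panel=None) for bc in rows]
        self.panel_ = build_panel(depths, self.genome, sexes=sexes, cv_cutoff=self.cv_cutoff)
        self.n_features_in_ = self.genome.n_bins
        return self

    def _rows(self, X) -> list[BinCounts]:
        if isinstance(X, BinCounts):
            return [X]
        if len(X) > 0 and isinstance(X[0], BinCounts):
            return list(X)
        arr = np.asarray(X)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.ndim != 2:
            raise ValueError("X must be a 2D count matrix or list of BinCounts")
        if arr.shape[1] != self.genome.n_bins:
            raise ValueError(
                f"X has {arr.shape[1]} bins, genome has {self.genome.n_bins}"
            )
        return [self._as_bincounts(arr[i], f"s{i:03d}") for i in range(arr.shape[0])]

    def transform_profile(self, counts: BinCounts) -> CopyRatioProfile:
        """Full profile (ratios + sex diagnostics) for one sample."""
        if not hasattr(self, "panel_"):
            raise RuntimeError("CopyRatioNormalizer is not fitted")
        depth = self._corrected_depth(counts, panel=self.panel_)
        return reference_normalize(
            depth, self.panel_, self.genome, sample_id=counts.sample_id,
            sex_windows=self.sex_windows,
        )

    def transform(self, X) -> np.ndarray:
        """Copy-ratio matrix (n_samples, n_bins); NaN at masked bins."""
        rows = self._rows(X)
        return np.vstack([self.transform_profile(bc).ratio for bc in rows])
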