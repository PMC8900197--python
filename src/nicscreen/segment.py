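"""Circular binary segmentation (CBS) of copy-ratio profiles.

From-scratch implementation of the canonical change-point recursion: the
statistic is the pooled two-sample t between an arc (i, j] and its
complement on the circle, maximized over all arcs; significance comes from
a within-chromosome permutation test, and significant arcs split the data
recursively until no segment can be divided further. Wrapping arcs need not
be enumerated because a wrapped arc and its complement give the same |T|;
the search therefore runs over contiguous windows x[i:j].

Segmentation runs on linear-scale ratios so that whole-copy shifts sit at
literal +-50% of baseline. The permutation loop stops early once the
exceedance count already guarantees p >= alpha — the split decision is
identical to the full run, but null chromosomes cost only a few dozen
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeBins
from .normalize import CopyRatioProfile

__all__ = [
    "Segment",
    "max_t_arc",
    "permutation_pvalue",
    "segment_chromosome",
    "merge_segments",
    "segment_genome",
    "CBSSegmenter",
]


@dataclass
class Segment:
    """A constant-mean run of bins.

    start/end are half-open indices in the chromosome's *valid-bin* index
    space; pvalue is the p of the split that created the segment (1 for a
    never-split chromosome).
    """

    chrom: str
    start: int
    end: int
    mean: float
    pvalue: float = 1.0

    @property
    def n_bins(self) -> int:
        return self.end - self.start


def _arc_t_matrix(x: np.ndarray, min_width: int = 1) -> tuple[np.ndarray, int]:
    """|T| for every admissible arc (i, j), vectorized over the (i, j) grid.

    Entry [i, j] is the pooled two-sample t between x[i:j] and its
    complement; inadmissible pairs (empty arc/complement, or pieces shorter
    than min_width) are NaN. Arcs whose pooled within-variance is zero but
    whose means differ get T = +inf (a perfect step).
    """
    n = len(x)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    total = cs[-1]
    sq_total = float(np.dot(x, x))

    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    k = j - i  # arc length
    valid = (k >= 1) & (k <= n - 1)
    left = i
    right = n - j
    if min_width > 1:
        valid &= (k >= min_width)
        valid &= (left == 0) | (left >= min_width)
        valid &= (right == 0) | (right >= min_width)

    with np.errstate(divide="ignore", invalid="ignore"):
        s_arc = cs[j] - cs[i]
        k_f = k.astype(float)
        m1 = s_arc / k_f
        m2 = (total - s_arc) / (n - k_f)
        ss_within = sq_total - k_f * m1**2 - (n - k_f) * m2**2
        s2 = ss_within / max(n - 2, 1)
        denom = np.sqrt(s2 * (1.0 / k_f + 1.0 / (n - k_f)))
        t = np.abs(m1 - m2) / denom
        # perfect two-level split: zero pooled variance, nonzero contrast
        perfect = (ss_within <= 1e-12 * max(sq_total, 1.0)) & (np.abs(m1 - m2) > 0)
        t = np.where(perfect, np.inf, t)
    t = np.where(valid, t, np.nan)
    return t, n


def _max_abs_t(x: np.ndarray, min_width: int = 1) -> tuple[int, int, float]:
    t, n = _arc_t_matrix(x, min_width)
    flat = np.where(np.isnan(t), -1.0, t).ravel()
    tmax = flat.max()
    if not tmax > 0:
        return 0, n, 0.0
    # an arc and its complement describe the same split with the same |T| up
    # to rounding; break such ties to the smallest i, then smallest j
    if np.isinf(tmax):
        tied = flat == np.inf
    else:
        tied = flat >= tmax * (1.0 - 1e-12)
    best = int(np.argmax(tied))  # first True in row-major order
    i, j = divmod(best, n + 1)
    return i, j, float(t[i, j])


def max_t_arc(x: np.ndarray, min_width: int = 1) -> tuple[int, int, float]:
    """Best circular arc: boundaries (i, j) maximizing |T| and the value.

    Ties break to the smallest i, then the smallest j. A zero-variance
    input returns (0, n, 0.0).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("max_t_arc needs at least 4 data points")
    if np.ptp(x) == 0:
        return 0, n, 0.0
    return _max_abs_t(x, min_width)


def _batch_max_t(xb: np.ndarray, min_width: int = 1) -> np.ndarray:
    """Max |T| over admissible arcs for each row of a (B, n) batch.

    For a fixed arc length k the t statistic is monotone in the arc sum, so
    only the extreme windowed sums per length need evaluating — O(n^2) work
    per row but vectorized across the batch.
    """
    B, n = xb.shape
    cs = np.concatenate([np.zeros((B, 1)), np.cumsum(xb, axis=1)], axis=1)
    total = cs[:, -1]
    sq_total = np.einsum("ij,ij->i", xb, xb)
    best = np.zeros(B)
    nd = max(n - 2, 1)
    mw = min_width
    for k in range(max(1, mw), n):
        w = cs[:, k:] - cs[:, :-k]  # windowed sums, start i in [0, n-k]
        if mw > 1:
            # pieces [0,i), [i,i+k), [i+k,n) must each be empty or >= mw wide
            last = n - k
            parts = []
            if last >= mw:  # i = 0 and i = last leave one outer piece of n-k bins
                parts.append(w[:, :1])
                parts.append(w[:, last:last + 1])
            lo, hi = mw, last - mw
            if hi >= lo:
                parts.append(w[:, lo:hi + 1])
            if not parts:
                continue
            w = np.concatenate(parts, axis=1)
        s_hi = w.max(axis=1)
        s_lo = w.min(axis=1)
        for s in (s_hi, s_lo):
            m1 = s / k
            m2 = (total - s) / (n - k)
            ss_within = sq_total - k * m1**2 - (n - k) * m2**2
            contrast = np.abs(m1 - m2)
            with np.errstate(divide="ignore", invalid="ignore"):
                denom = np.sqrt(np.maximum(ss_within, 0.0) / nd * (1.0 / k + 1.0 / (n - k)))
                t = np.where(
                    ss_within <= 1e-12 * np.maximum(sq_total, 1.0),
                    np.where(contrast > 0, np.inf, 0.0),
                    contrast / denom,
                )
            best = np.maximum(best, t)
    return best


_PERM_BATCH = 64


def _perm_exceedances(
    x: np.ndarray,
    t_obs: float,
    n_perm: int,
    rng: np.random.Generator,
    min_width: int,
    stop_count: int | None = None,
) -> tuple[int, int]:
    """Count permutations with max |T| >= t_obs, in deterministic batches.

    If stop_count is given, stop after the batch in which the count reaches
    it (the significance decision is then already settled). Returns
    (count, permutations actually examined).
    """
    count = 0
    done = 0
    while done < n_perm:
        b = min(_PERM_BATCH, n_perm - done)
        xb = rng.permuted(np.broadcast_to(x, (b, len(x))), axis=1)
        t = _batch_max_t(xb, min_width)
        count += int(np.sum(t >= t_obs))
        done += b
        if stop_count is not None and count >= stop_count:
            break
    return count, done


def permutation_pvalue(
    x: np.ndarray,
    t_obs: float,
    n_perm: int = 1000,
    seed: int = 0,
    min_width: int = 1,
) -> float:
    """Permutation p-value of the max-|T| statistic within the chromosome:
    p = (1 + #{perm max |T| >= t_obs}) / (n_perm + 1)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    count, _ = _perm_exceedances(x, t_obs, n_perm, rng, min_width)
    return (1 + count) / (n_perm + 1)


def _is_significant(
    x: np.ndarray,
    t_obs: float,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    min_width: int,
) -> tuple[bool, float]:
    """Permutation test with deterministic early stopping: stop as soon as
    the exceedance count already guarantees p >= alpha. The accept/reject
    decision is identical to the full n_perm run."""
    # smallest count making (1 + count) / (n_perm + 1) >= alpha
    stop_count = int(np.ceil(alpha * (n_perm + 1) - 1))
    count, done = _perm_exceedances(x, t_obs, n_perm, rng, min_width,
                                    stop_count=max(stop_count, 1))
    if done < n_perm or count >= max(stop_count, 1):
        return False, (1 + count) / (done + 1)
    p = (1 + count) / (n_perm + 1)
    return p < alpha, p


def segment_chromosome(
    x: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: int = 0,
    chrom: str = "",
) -> list[Segment]:
    """Recursively split one chromosome's ratio vector at significant arcs.

    Returns an ordered partition; no segment is shorter than min_width
    (except a whole chromosome shorter than that, returned unsplit).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if min_width < 2:
        raise ValueError("min_width must be >= 2")
    x = np.asarray(x, dtype=float)
    n = len(x)
    rng = np.random.default_rng(seed)
    boundaries: list[tuple[int, int, float]] = []

    def recurse(lo: int, hi: int, p_created: float) -> None:
        seg = x[lo:hi]
        m = hi - lo
        if m < max(2 * min_width, 4) or np.ptp(seg) == 0:
            boundaries.append((lo, hi, p_created))
            return
        i, j, t = _max_abs_t(seg, min_width)
        if t <= 0:
            boundaries.append((lo, hi, p_created))
            return
        ok, p = _is_significant(seg, t, alpha, n_perm, rng, min_width)
        if not ok:
            boundaries.append((lo, hi, p_created))
            return
        cuts = [lo]
        if i > 0:
            cuts.append(lo + i)
        if j < m:
            cuts.append(lo + j)
        cuts.append(hi)
        for a, b in zip(cuts, cuts[1:]):
            recurse(a, b, p)

    recurse(0, n, 1.0)
    boundaries.sort()
    return [
        Segment(chrom=chrom, start=a, end=b, mean=float(np.mean(x[a:b])), pvalue=p)
        for a, b, p in boundaries
    ]


def merge_segments(segments: list[Segment], merge_threshold: float = 0.1) -> list[Segment]:
    """Merge adjacent segments whose means differ by less than the threshold
    (in ratio units); the merged mean is the bin-count-weighted mean."""
    if not segments:
        return []
    out = [Segment(**vars(segments[0]))]
    for seg in segments[1:]:
        prev = out[-1]
        if seg.start != prev.end or seg.chrom != prev.chrom:
            raise ValueError("segments must be ordered and contiguous on one chromosome")
        if abs(seg.mean - prev.mean) < merge_threshold:
            n1, n2 = prev.n_bins, seg.n_bins
            out[-1] = Segment(
                chrom=prev.chrom, start=prev.start, end=seg.end,
                mean=(n1 * prev.mean + n2 * seg.mean) / (n1 + n2),
                pvalue=min(prev.pvalue, seg.pvalue),
            )
        else:
            out.append(Segment(**vars(seg)))
    return out


def segment_genome(
    profile: CopyRatioProfile,
    genome: GenomeBins,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    merge_threshold: float = 0.1,
    seed: int = 0,
) -> dict[str, list[Segment]]:
    """Segment every chromosome of a profile (valid bins only).

    Returns chromosome -> ordered segments in that chromosome's valid-bin
    index space. Per-chromosome seeds derive deterministically from `seed`.
    """
    rng = np.random.default_rng(seed)
    result: dict[str, list[Segment]] = {}
    for chrom in genome.chromosomes:
        sub_seed = int(rng.integers(0, 2**31))
        sl = genome.chrom_slice(chrom)
        valid = profile.valid[sl]
        x = profile.ratio[sl][valid]
        if len(x) == 0:
            result[chrom] = []
            continue
        if len(x) < max(min_width, 4):
            segs = [Segment(chrom=chrom, start=0, end=len(x), mean=float(np.mean(x)))]
        else:
            segs = segment_chromosome(
                x, alpha=alpha, n_perm=n_perm, min_width=min_width,
                seed=sub_seed, chrom=chrom,
            )
        result[chrom] = merge_segments(segs, merge_threshold)
    return result


class CBSSegmenter:
    """Thin estimator-style wrapper over :func:`segment_genome`.

    Stateless (``fit`` only records the genome); ``transform`` maps a list
    of profiles to per-bin segment-mean arrays and keeps the full segment
    lists in ``segments_``.
    """

    def __init__(
        self,
        genome: GenomeBins | None = None,
        alpha: float = 0.01,
        n_perm: int = 1000,
        min_width: int = 3,
        merge_threshold: float = 0.1,
        random_state: int = 0,
    ) -> None:
        self.genome = genome
        self.alpha = alpha
        self.n_perm = n_perm
        self.min_width = min_width
        self.merge_threshold = merge_threshold
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "genome": self.genome, "alpha": self.alpha, "n_perm": self.n_perm,
            "min_width": self.min_width, "merge_threshold": self.merge_threshold,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "CBSSegmenter":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "CBSSegmenter":
        return self

    def segment(self, profile: CopyRatioProfile) -> dict[str, list[Segment]]:
        if self.genome is None:
            raise ValueError("CBSSegmenter requires a genome")
        return segment_genome(
            profile, self.genome, alpha=self.alpha, n_perm=self.n_perm,
            min_width=self.min_width, merge_threshold=self.merge_threshold,
            seed=self.random_state,
        )

    def transform(self, profiles: list[CopyRatioProfile]) -> np.ndarray:
        """Per-bin segment means, NaN outside valid bins."""
        self.segments_ = [self.segment(p) for p in profiles]
        out = np.full((len(profiles), self.genome.n_bins), np.nan)
        for row, (profile, segmap) in enumerate(zip(profiles, self.segments_)):
            for chrom, segs in segmap.items():
                sl = self.genome.chrom_slice(chrom)
                idx = np.flatnonzero(profile.valid[sl]) + sl.start
                for s in segs:
                    out[row, idx[s.start:s.end]] = s.mean
        return out
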