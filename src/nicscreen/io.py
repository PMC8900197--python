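"""File formats and configuration.

Dialects (all plain text, fixed column orders):

* bin tables — BED-like TSV ``chrom  start  end  count``, 0-based half-open
  (a ``one_based`` toggle converts 1-based inclusive input on read);
* genome tables — TSV ``chrom start end gc usable``;
* segments — SEG TSV ``sample  chrom  loc.start  loc.end  num.mark
  seg.mean  seg.ratio`` with seg.mean = log2(ratio);
* calls and truth sheets — CSV with a header row;
* reference panels — TSV of per-bin medians with a JSON sidecar;
* pipeline configuration — a single YAML file; unknown keys are an error
  and a SHA-256 hash of the canonical config is stamped into outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .call import PloidyCall
from .genome import GenomeBins
from .normalize import ReferencePanel
from .segment import Segment
from .simulate import BinCounts, SampleKaryotype

__all__ = [
    "read_bin_table", "write_bin_table", "read_genome", "write_genome",
    "read_ratio", "write_ratio", "read_seg", "write_seg",
    "read_calls", "write_calls", "read_truth", "write_truth",
    "read_panel", "write_panel",
    "PipelineConfig", "load_config", "config_hash", "write_cohort",
]

BIN_COLUMNS = ["chrom", "start", "end", "count"]
SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean", "seg.ratio"]
CALL_COLUMNS = ["sample_id", "classification", "karyotype", "sex"]
TRUTH_COLUMNS = ["sample_id", "sex", "karyotype_string", "classification"]


class FileFormatError(ValueError):
    """Malformed input file; the message names the file and row."""


def _fail(path, row, msg) -> None:
    loc = f"{path}" + (f", row {row}" if row is not None else "")
    raise FileFormatError(f"{loc}: {msg}")


def read_bin_table(
    path,
    genome: GenomeBins | None = None,
    sample_id: str | None = None,
    source: str = "NA",
    one_based: bool = False,
) -> BinCounts:
    """Read a BED-like TSV of per-bin counts; validates column count,
    integer non-negative counts and sorted bins."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        _fail(path, None, "empty file")
    if list(df.columns) != BIN_COLUMNS:
        _fail(path, None, f"expected columns {BIN_COLUMNS}, found {list(df.columns)}")
    try:
        start = df["start"].astype(np.int64)
        end = df["end"].astype(np.int64)
    except ValueError:
        _fail(path, None, "start/end must be integers")
    counts = np.empty(len(df), dtype=np.int64)
    for i, v in enumerate(df["count"]):
        try:
            c = int(v)
        except (TypeError, ValueError):
            _fail(path, i + 2, f"non-integer count {v!r}")
        if c < 0:
            _fail(path, i + 2, f"negative count {c}")
        counts[i] = c
    if one_based:
        start = start - 1
    prev_chrom, prev_end = None, None
    for i, (ch, s, e) in enumerate(zip(df["chrom"], start, end)):
        if e <= s:
            _fail(path, i + 2, f"empty interval {s}-{e}")
        if ch == prev_chrom and s < prev_end:
            _fail(path, i + 2, "bins unsorted or overlapping")
        prev_chrom, prev_end = ch, e
    if genome is not None:
        if len(df) != genome.n_bins:
            _fail(path, None, f"{len(df)} bins, genome has {genome.n_bins}")
        if not (np.all(df["chrom"].to_numpy() == genome.chrom.astype(str))
                and np.array_equal(start.to_numpy(), genome.start)):
            _fail(path, None, "bin coordinates do not match the genome")
    return BinCounts(sample_id=sample_id or path.stem, source=source, counts=counts)


def write_bin_table(counts: BinCounts, genome: GenomeBins, path) -> None:
    df = pd.DataFrame({
        "chrom": genome.chrom.astype(str), "start": genome.start,
        "end": genome.end, "count": counts.counts,
    })
    df.to_csv(path, sep="\t", index=False)


def write_ratio(profile, genome: GenomeBins, path) -> None:
    """Write a copy-ratio profile as TSV ``chrom start end ratio`` (NA at
    invalid bins), with the sample metadata in ``# key=value`` header lines."""
    from .normalize import CopyRatioProfile  # local to avoid cycle at import

    assert isinstance(profile, CopyRatioProfile)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id={profile.sample_id}\n")
        fh.write(f"# sex_model={profile.sex_model}\n")
        fh.write(f"# baseline={profile.baseline!r}\n")
        fh.write(f"# x_ratio_vs_xx={profile.x_ratio_vs_xx!r}\n")
        fh.write(f"# y_ratio_vs_xy={profile.y_ratio_vs_xy!r}\n")
        fh.write("chrom\tstart\tend\tratio\n")
        for ch, s, e, r, v in zip(genome.chrom, genome.start, genome.end,
                                  profile.ratio, profile.valid):
            val = f"{float(r)!r}" if v and np.isfinite(r) else "NA"
            fh.write(f"{ch}\t{s}\t{e}\t{val}\n")


def read_ratio(path):
    """Read a copy-ratio TSV written by :func:`write_ratio`."""
    from .normalize import CopyRatioProfile

    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# ") and "=" in line:
            key, _, val = line[2:].strip().partition("=")
            meta[key] = val
            body_start = i + 1
        else:
            break
    import io as _io
    try:
        df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t",
                         dtype={"chrom": str}, na_values=["NA"],
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        _fail(path, None, "empty file")
    if list(df.columns) != ["chrom", "start", "end", "ratio"]:
        _fail(path, None, "expected columns chrom, start, end, ratio")
    ratio = df["ratio"].to_numpy(float)
    valid = np.isfinite(ratio)
    return CopyRatioProfile(
        sample_id=meta.get("sample_id", path.stem),
        ratio=ratio, valid=valid,
        baseline=float(meta.get("baseline", "nan")),
        sex_model=meta.get("sex_model", "XX"),
        x_ratio_vs_xx=float(meta.get("x_ratio_vs_xx", "nan")),
        y_ratio_vs_xy=float(meta.get("y_ratio_vs_xy", "nan")),
    )


def write_genome(genome: GenomeBins, path) -> None:
    genome.to_frame().to_csv(path, sep="\t", index=False)


def read_genome(path) -> GenomeBins:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GenomeBins.from_frame(df)


def write_seg(
    segments: dict[str, list[Segment]],
    genome: GenomeBins,
    valid: np.ndarray,
    path,
    sample_id: str = "sample",
) -> None:
    """Write segments in SEG format with genomic coordinates.

    Segment bin indices live in valid-bin index space; `valid` maps them
    back to genome bins. seg.mean is log2(ratio); the linear ratio is kept
    in seg.ratio.
    """
    rows = []
    for chrom, segs in segments.items():
        sl = genome.chrom_slice(chrom)
        idx = np.flatnonzero(valid[sl]) + sl.start
        for s in segs:
            bins = idx[s.start:s.end]
            if len(bins) == 0:
                continue
            rows.append({
                "sample": sample_id, "chrom": chrom,
                "loc.start": int(genome.start[bins[0]]),
                "loc.end": int(genome.end[bins[-1]]),
                "num.mark": int(s.n_bins),
                "seg.mean": float(np.log2(s.mean)) if s.mean > 0 else float("-inf"),
                "seg.ratio": float(s.mean),
            })
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        _fail(path, None, "empty file")
    if list(df.columns) != SEG_COLUMNS:
        _fail(path, None, f"expected columns {SEG_COLUMNS}, found {list(df.columns)}")
    return df


def write_calls(calls: list[PloidyCall], path) -> None:
    pd.DataFrame(
        [{"sample_id": c.sample_id, "classification": c.classification,
          "karyotype": c.karyotype, "sex": c.sex} for c in calls],
        columns=CALL_COLUMNS,
    ).to_csv(path, index=False)


def read_calls(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        _fail(path, None, "empty file")
    missing = [c for c in ("sample_id", "classification") if c not in df.columns]
    if missing:
        _fail(path, None, f"missing columns {missing}")
    return df


def write_truth(truths: list[SampleKaryotype], sample_ids: list[str], path,
                sexes_only: bool = False) -> None:
    rows = []
    for sid, t in zip(sample_ids, truths):
        karyo = ";".join(
            f"{'+' if e.copy_number > 2 else '-'}{e.chrom}"
            + (f"[{e.mosaic_fraction:g}]" if e.mosaic_fraction < 1 else "")
            for e in t.events
        )
        rows.append({"sample_id": sid, "sex": t.sex,
                     "karyotype_string": f"46,{t.sex}" if t.is_euploid else karyo,
                     "classification": t.classification})
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        _fail(path, None, "empty file")
    if "sample_id" not in df.columns or "classification" not in df.columns:
        _fail(path, None, "truth sheet needs sample_id and classification columns")
    return df


def write_panel(panel: ReferencePanel, genome: GenomeBins, path) -> None:
    path = Path(path)
    pd.DataFrame({
        "chrom": genome.chrom.astype(str), "start": genome.start, "end": genome.end,
        "median_xx": panel.median_xx, "median_xy": panel.median_xy,
    }).to_csv(path, sep="\t", index=False)
    sidecar = {"n_samples": panel.n_samples, "cv_cutoff": panel.cv_cutoff}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_panel(path) -> ReferencePanel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ReferencePanel(
        median_xx=df["median_xx"].to_numpy(float),
        median_xy=df["median_xy"].to_numpy(float),
        n_samples=int(meta["n_samples"]), cv_cutoff=float(meta["cv_cutoff"]),
    )


# ---------------------------------------------------------------- config

_CONFIG_DEFAULTS: dict[str, dict] = {
    "genome": {"bin_width": 1_000_000, "scale": 1.0, "seed": 0},
    "profiles": {},          # source -> SourceProfile fields
    "normalization": {
        "gc_span": 0.3, "gc_robust_iter": 2, "gc_range": [0.2, 0.8],
        "min_panel_median": 0.1, "cv_cutoff": 0.3, "min_bins": 100,
        "max_masked_autosomal_fraction": 0.5,
    },
    "cbs": {"alpha": 0.01, "n_perm": 1000, "min_width": 3, "merge_threshold": 0.1},
    "calling": {
        "report_floor": 0.5, "full_cutoff": 0.8, "whole_chrom_fraction": 0.8,
        "min_segment_bins": 10, "xx_window": [0.8, 1.2], "xy_window": [0.35, 0.65],
    },
    "cohort": {"n": 148, "aneuploid_rate": 47 / 148, "mosaic_rate": 0.2,
               "n_ref": 20, "sources": ["SCM", "ICM"]},
    "io": {"one_based": False},
    "seed": 0,
}


@dataclasses.dataclass
class PipelineConfig:
    genome: dict
    profiles: dict
    normalization: dict
    cbs: dict
    calling: dict
    cohort: dict
    io: dict
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _merge_strict(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in user.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults and path != "profiles":
            raise KeyError(f"unknown config key: {where}")
        if isinstance(defaults.get(key), dict) and isinstance(value, dict):
            out[key] = _merge_strict(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config; unknown keys raise (no silent defaults)."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise FileFormatError(f"{path}: config must be a mapping")
        data = raw
    if overrides:
        data = {**data, **overrides}
    merged = _merge_strict(_CONFIG_DEFAULTS, data)
    return PipelineConfig(**merged)


def config_hash(config: PipelineConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_cohort(
    out_dir,
    genome: GenomeBins,
    truths: list[SampleKaryotype],
    counts_by_source: dict[str, list[BinCounts]],
    config: PipelineConfig | None = None,
) -> None:
    """Write a simulated cohort: per-sample bin TSVs under source
    subdirectories, the truth CSV, the genome table, and a manifest JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_genome(genome, out_dir / "genome.tsv")
    sample_ids = [f"emb{k:03d}" for k in range(len(truths))]
    write_truth(truths, sample_ids, out_dir / "truth.csv")
    manifest = {"n_samples": len(truths), "sources": {}, "genome": "genome.tsv",
                "truth": "truth.csv"}
    if config is not None:
        manifest["config_hash"] = config_hash(config)
    for source, counts in counts_by_source.items():
        sub = out_dir / source
        sub.mkdir(exist_ok=True)
        files = []
        for bc in counts:
            f = f"{bc.sample_id}.tsv"
            write_bin_table(bc, genome, sub / f)
            files.append(f"{source}/{f}")
        manifest["sources"][source] = files
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
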