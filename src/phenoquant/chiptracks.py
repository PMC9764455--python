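"""Control-subtracted, smoothed, replicate-averaged ChIP coverage tracks.

Implements the normalization used for enhancer-mark ChIP-seq browser
tracks: subtract a control (e.g. total-H3) coverage track from the signal
track bin-by-bin, smooth with a centered moving average (500 bp by
default), and average replicates, reporting their pairwise Pearson
correlations. Tracks are uniformly binned, 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenomicTrack",
    "subtract_control",
    "smooth_track",
    "average_replicates",
    "cpm_scale",
    "read_bedgraph",
    "write_bedgraph",
    "read_bigwig",
]


@dataclass
class GenomicTrack:
    """Uniformly binned coverage values on one chromosome.

    Bin ``i`` covers ``[start_bp + i*bin_size_bp, start_bp + (i+1)*bin_size_bp)``.
    Values are signed reals: control subtraction may go negative.
    """

    chrom: str
    bin_size_bp: int
    start_bp: int
    values: np.ndarray

    def __post_init__(self):
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1D")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def same_grid(self, other: "GenomicTrack") -> bool:
        return (self.chrom == other.chrom
                and self.bin_size_bp == other.bin_size_bp
                and self.start_bp == other.start_bp
                and self.n_bins == other.n_bins)


def _require_grid(a: GenomicTrack, b: GenomicTrack) -> None:
    if not a.same_grid(b):
        raise ValueError(
            "tracks are on different grids "
            f"({a.chrom}:{a.start_bp}/{a.bin_size_bp}x{a.n_bins} vs "
            f"{b.chrom}:{b.start_bp}/{b.bin_size_bp}x{b.n_bins}); "
            "no implicit resampling")


def subtract_control(signal: GenomicTrack, control: GenomicTrack) -> GenomicTrack:
    """Per-bin ``signal - control`` (e.g. H3K4me1 minus total H3)."""
    _require_grid(signal, control)
    return GenomicTrack(signal.chrom, signal.bin_size_bp, signal.start_bp,
                        signal.values - control.values)


def smooth_track(track: GenomicTrack, window_bp: int = 500,
                 edge: str = "truncate") -> GenomicTrack:
    """Centered moving average over ``window_bp``.

    The window is converted to ``ceil(window_bp / bin_size_bp)`` bins,
    forced odd so it is centered. Edge bins average over the available
    (truncated) window by default; ``edge="reflect"`` mirrors instead.
    A window smaller than one bin returns the track unchanged with a
    warning.
    """
    if window_bp < track.bin_size_bp:
        warnings.warn("smoothing window smaller than one bin; returning input")
        return GenomicTrack(track.chrom, track.bin_size_bp, track.start_bp,
                            track.values.copy())
    w = int(np.ceil(window_bp / track.bin_size_bp))
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w)
    if edge == "truncate":
        num = np.convolve(track.values, kernel, mode="same")
        den = np.convolve(np.ones_like(track.values), kernel, mode="same")
        out = num / den
    elif edge == "reflect":
        h = w // 2
        padded = np.pad(track.values, h, mode="reflect")
        out = np.convolve(padded, kernel / w, mode="valid")
    else:
        raise ValueError(f"unknown edge policy {edge!r}")
    return GenomicTrack(track.chrom, track.bin_size_bp, track.start_bp, out)


def average_replicates(tracks: list[GenomicTrack]
                       ) -> tuple[GenomicTrack, np.ndarray]:
    """Per-bin mean of replicate tracks plus their pairwise Pearson matrix.

    A zero-variance replicate has undefined correlation; its entries are
    reported as NaN.
    """
    if not tracks:
        raise ValueError("need at least one track")
    for t in tracks[1:]:
        _require_grid(tracks[0], t)
    mat = np.vstack([t.values for t in tracks])
    avg = GenomicTrack(tracks[0].chrom, tracks[0].bin_size_bp,
                       tracks[0].start_bp, mat.mean(axis=0))
    n = len(tracks)
    pearson = np.full((n, n), np.nan)
    sds = mat.std(axis=1)
    for i in range(n):
        for j in range(n):
            if sds[i] > 0 and sds[j] > 0:
                pearson[i, j] = float(np.corrcoef(mat[i], mat[j])[0, 1])
    return avg, pearson


def cpm_scale(track: GenomicTrack) -> GenomicTrack:
    """Optional depth normalization: scale bins to counts-per-million of
    the track total. Off by default in the pipeline."""
    total = track.values.sum()
    if total == 0:
        raise ValueError("cannot CPM-scale an all-zero track")
    return GenomicTrack(track.chrom, track.bin_size_bp, track.start_bp,
                        track.values * 1e6 / total)


# ---------------------------------------------------------------------------
# I/O

def write_bedgraph(track: GenomicTrack, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            s = track.start_bp + i * track.bin_size_bp
            fh.write(f"{track.chrom}\t{s}\t{s + track.bin_size_bp}\t{v:.6g}\n")


def read_bedgraph(path) -> GenomicTrack:
    """Read a single-chromosome, uniformly binned bedGraph."""
    chroms, starts, ends, vals = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            c, s, e, v = line.split()[:4]
            chroms.append(c)
            starts.append(int(s))
            ends.append(int(e))
            vals.append(float(v))
    if not vals:
        raise ValueError(f"no intervals in {path}")
    if len(set(chroms)) != 1:
        raise ValueError("expected a single chromosome per bedGraph")
    widths = {e - s for s, e in zip(starts, ends)}
    if len(widths) != 1:
        raise ValueError("bins are not uniform")
    bin_size = widths.pop()
    for a, b in zip(ends[:-1], starts[1:]):
        if a != b:
            raise ValueError("bins are not contiguous")
    return GenomicTrack(chroms[0], bin_size, starts[0], np.array(vals))


def read_bigwig(path, chrom: str, bin_size_bp: int,
                start_bp: int = 0, end_bp: int | None = None) -> GenomicTrack:
    """Read a bigWig into a uniformly binned track (read-only support)."""
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        if end_bp is None:
            end_bp = bw.chroms()[chrom]
        n = (end_bp - start_bp) // bin_size_bp
        vals = bw.stats(chrom, start_bp, start_bp + n * bin_size_bp,
                        nBins=n, type="mean")
    finally:
        bw.close()
    arr = np.array([v if v is not None else 0.0 for v in vals])
    return GenomicTrack(chrom, bin_size_bp, start_bp, arr)
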