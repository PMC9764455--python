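"""Single-larva lipidomics from MALDI imaging mass spectrometry sections.

A MALDI-MSI run over a population section yields one intensity image per
annotated m/z channel. This module deconvolves such a stack into a
larva × metabolite abundance matrix: larvae are segmented on the total
ion current (TIC) image, per-larva abundances aggregated per channel,
optionally batch-adjusted, and analyzed by PCA and lipid-class
enrichment.

Two deliberately simplified stand-ins are provided and named as such:

- ``batch_adjust`` ("combat_lite") is a per-channel location/scale
  alignment of batches to the pooled moments — not the empirical-Bayes
  ComBat model.
- ``class_enrichment`` ("class_ranksum") summarizes per-channel group
  log2 fold changes by class median and a rank-sum test of members vs
  non-members — not an ontology enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import binary_closing, disk

__all__ = [
    "IonChannel",
    "IonImageStack",
    "LarvaLabelMask",
    "AbundanceMatrix",
    "SegmentationParams",
    "segment_larvae",
    "per_larva_abundance",
    "batch_adjust",
    "pca_profiles",
    "class_enrichment",
    "read_ion_dir",
    "write_ion_dir",
    "read_imzml",
]


@dataclass(frozen=True)
class IonChannel:
    mz: float
    formula: str = ""
    adduct: str = ""
    lipid_class: str = "unassigned"

    @property
    def name(self) -> str:
        return f"mz{self.mz:.4f}"


@dataclass
class IonImageStack:
    """Per-m/z intensity planes over one section grid."""

    planes: np.ndarray              # (n_channels, H, W), non-negative-ish
    channels: list[IonChannel]
    pixel_size_um: float

    def __post_init__(self):
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3:
            raise ValueError("planes must be (n_channels, H, W)")
        if self.planes.shape[0] != len(self.channels):
            raise ValueError("plane count != channel count")
        mzs = [c.mz for c in self.channels]
        if len(set(mzs)) != len(mzs):
            raise ValueError("channel m/z values must be unique")
        if any(m <= 0 for m in mzs):
            raise ValueError("m/z values must be positive")

    @property
    def grid(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def tic(self) -> np.ndarray:
        """Total ion current: per-pixel sum over channels."""
        return self.planes.sum(axis=0)


@dataclass
class LarvaLabelMask:
    labels: np.ndarray              # 2D int, 0 = background, 1..N larvae

    def __post_init__(self):
        self.labels = np.asarray(self.labels)

    @property
    def n_larvae(self) -> int:
        return int(self.labels.max())

    def pixel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass
class AbundanceMatrix:
    """Larvae × metabolite abundances with sample metadata.

    ``values`` is a DataFrame indexed by larva id with one column per
    channel name; ``meta`` carries ``group`` and ``batch`` per larva.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    aggregation: str = "mean"

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("abundance matrix must have no missing cells")
        if self.meta.empty:
            self.meta = pd.DataFrame(index=self.values.index,
                                     columns=["group", "batch"])
            self.meta["group"] = "all"
            self.meta["batch"] = "b0"
        self.meta = self.meta.loc[self.values.index]


@dataclass
class SegmentationParams:
    threshold: float | None = None   # None => Otsu on the TIC image
    closing_radius: int = 0          # 0 keeps adjacent larvae separate
    min_area_px: int = 5
    connectivity: int = 1            # 4-connected components


def segment_larvae(stack: IonImageStack,
                   params: SegmentationParams | None = None) -> LarvaLabelMask:
    """Segment individual larvae on the total-ion-current image.

    The TIC image is thresholded (Otsu unless a fixed threshold is given),
    optionally morphologically closed, and 4-connected components above
    ``min_area_px`` are labeled. Labels are renumbered 1..N in row-major
    centroid order so numbering is stable across runs.
    """
    params = params or SegmentationParams()
    tic = stack.tic()
    if np.ptp(tic) == 0:
        return LarvaLabelMask(np.zeros(stack.grid, dtype=int))
    if params.threshold is not None:
        fg = tic > params.threshold
    else:
        # Otsu on log-compressed TIC: separates background from tissue even
        # when larvae differ widely in brightness (e.g. batch effects)
        shifted = tic - tic.min()
        fg = np.log1p(shifted) > threshold_otsu(np.log1p(shifted))
    if params.closing_radius > 0:
        fg = binary_closing(fg, disk(params.closing_radius))
    structure = ndimage.generate_binary_structure(2, params.connectivity)
    lab, n = ndimage.label(fg, structure=structure)
    out = np.zeros_like(lab)
    comps = []
    for i in range(1, n + 1):
        sel = lab == i
        if sel.sum() < params.min_area_px:
            continue
        cy, cx = ndimage.center_of_mass(sel)
        comps.append((cy, cx, sel))
    comps.sort(key=lambda t: (t[0], t[1]))
    for new_id, (_, _, sel) in enumerate(comps, start=1):
        out[sel] = new_id
    return LarvaLabelMask(out)


def per_larva_abundance(stack: IonImageStack, mask: LarvaLabelMask,
                        aggregation: str = "mean",
                        meta: pd.DataFrame | None = None) -> AbundanceMatrix:
    """Aggregate each channel plane over each larva's pixels.

    ``aggregation`` is ``"mean"`` (default; robust to larva size
    differences) or ``"sum"``.
    """
    n = mask.n_larvae
    if n == 0:
        raise ValueError("label mask contains no larvae")
    if aggregation not in ("mean", "sum"):
        raise ValueError("aggregation must be 'mean' or 'sum'")
    ids = np.arange(1, n + 1)
    agg = ndimage.mean if aggregation == "mean" else ndimage.sum_labels
    data = {}
    for plane, ch in zip(stack.planes, stack.channels):
        data[ch.name] = np.asarray(agg(plane, labels=mask.labels, index=ids),
                                   dtype=float)
    values = pd.DataFrame(data, index=pd.Index(ids, name="larva"))
    if meta is not None:
        meta = meta.loc[values.index]
    return AbundanceMatrix(values=values, meta=meta if meta is not None
                           else pd.DataFrame(), aggregation=aggregation)


def batch_adjust(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Location/scale batch alignment ("combat_lite").

    Per channel, each batch's values are centered and scaled to the pooled
    mean/SD over all samples. Group labels are never used. Batches with
    zero within-batch variance are centered only. A single batch, or any
    batch with fewer than 2 samples, passes through with a warning.

    The transform is exactly idempotent: after one pass all batch means
    equal the pooled mean and all batch SDs equal the pooled SD, so a
    second pass is the identity.
    """
    batches = matrix.meta["batch"]
    sizes = batches.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        if len(sizes) > 1:
            warnings.warn("some batch has < 2 samples; batch_adjust is a passthrough")
        return AbundanceMatrix(matrix.values.copy(), matrix.meta.copy(),
                               matrix.aggregation)
    vals = matrix.values.to_numpy(dtype=float).copy()
    pooled_mean = vals.mean(axis=0)
    pooled_sd = vals.std(axis=0)          # ddof=0: makes the map idempotent
    for b in sizes.index:
        rows = (batches == b).to_numpy()
        bm = vals[rows].mean(axis=0)
        bs = vals[rows].std(axis=0)
        # zero within-batch variance: center only (scale left at 1)
        scale = np.divide(pooled_sd, bs, out=np.ones_like(bs), where=bs > 0)
        vals[rows] = (vals[rows] - bm) * scale + pooled_mean
    out = pd.DataFrame(vals, index=matrix.values.index,
                       columns=matrix.values.columns)
    return AbundanceMatrix(out, matrix.meta.copy(), matrix.aggregation)


def pca_profiles(matrix: AbundanceMatrix, n_components: int = 2
                 ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Column-standardized PCA of the abundance matrix.

    Constant columns are dropped with a warning. The sign of each
    component is fixed so its largest-magnitude loading is positive.
    Returns (scores per larva, loadings per channel, variance fractions).
    """
    from sklearn.decomposition import PCA

    if len(matrix.values) < 2:
        raise ValueError("PCA needs more than one sample")
    vals = matrix.values
    sds = vals.std(axis=0, ddof=0)
    keep = sds[sds > 0].index
    if len(keep) < len(vals.columns):
        warnings.warn(f"dropping {len(vals.columns) - len(keep)} constant column(s)")
    if len(keep) == 0:
        scores = pd.DataFrame(np.zeros((len(vals), 0)), index=vals.index)
        return scores, pd.DataFrame(), np.array([])
    X = (vals[keep] - vals[keep].mean(axis=0)) / sds[keep]
    k = min(n_components, len(keep), len(vals) - 1)
    pca = PCA(n_components=k)
    sc = pca.fit_transform(X.to_numpy())
    load = pca.components_.T
    for j in range(k):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] *= -1
            sc[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(sc, index=vals.index, columns=cols)
    loadings = pd.DataFrame(load, index=keep, columns=cols)
    return scores, loadings, pca.explained_variance_ratio_


def class_enrichment(matrix: AbundanceMatrix, group_a: str, group_b: str,
                     class_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Lipid-class level group contrast ("class_ranksum").

    Per channel, the log2 fold change of group ``group_b`` over
    ``group_a`` (ratio of group means) is computed; per class, members'
    log2FCs are summarized by their median and compared against all
    non-member channels with a two-sided Wilcoxon rank-sum test.

    ``class_map`` maps channel name -> class; by default it is read off
    the matrix columns only if provided. Classes with no members are
    omitted with a warning.
    """
    groups = matrix.meta["group"]
    for g in (group_a, group_b):
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    if class_map is None:
        raise ValueError("class_map is required (channel name -> lipid class)")
    a = matrix.values[(groups == group_a).to_numpy()]
    b = matrix.values[(groups == group_b).to_numpy()]
    eps = np.finfo(float).tiny
    l2fc = np.log2((b.mean(axis=0) + eps) / (a.mean(axis=0) + eps))

    classes = sorted({c for c in class_map.values() if c != "unassigned"})
    rows = []
    for cls in classes:
        members = [ch for ch in matrix.values.columns if class_map.get(ch) == cls]
        if not members:
            warnings.warn(f"class {cls!r} has no member channels; omitted")
            continue
        others = [ch for ch in matrix.values.columns if class_map.get(ch) != cls]
        m = l2fc[members].to_numpy()
        o = l2fc[others].to_numpy()
        if len(others) == 0 or (np.ptp(np.concatenate([m, o])) == 0):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(m, o, alternative="two-sided").pvalue)
        rows.append({"lipid_class": cls, "n_members": len(members),
                     "median_log2fc": float(np.median(m)), "p": p})
    return pd.DataFrame(rows, columns=["lipid_class", "n_members",
                                       "median_log2fc", "p"])


# ---------------------------------------------------------------------------
# I/O

def write_ion_dir(stack: IonImageStack, outdir) -> None:
    """Write per-channel float32 TIFF planes plus channels.tsv."""
    import os
    import tifffile

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for i, (plane, ch) in enumerate(zip(stack.planes, stack.channels)):
        fname = f"plane_{i:03d}.tif"
        tifffile.imwrite(os.path.join(outdir, fname),
                         plane.astype(np.float32))
        rows.append({"file": fname, "mz": ch.mz, "formula": ch.formula,
                     "adduct": ch.adduct, "lipid_class": ch.lipid_class})
    tbl = pd.DataFrame(rows)
    tbl["pixel_size_um"] = stack.pixel_size_um
    tbl.to_csv(os.path.join(outdir, "channels.tsv"), sep="\t", index=False)


def read_ion_dir(path) -> IonImageStack:
    import os
    import tifffile

    tbl = pd.read_csv(os.path.join(path, "channels.tsv"), sep="\t")
    planes, channels = [], []
    for _, row in tbl.iterrows():
        planes.append(tifffile.imread(os.path.join(path, row["file"])).astype(float))
        channels.append(IonChannel(mz=float(row["mz"]),
                                   formula=str(row.get("formula", "") or ""),
                                   adduct=str(row.get("adduct", "") or ""),
                                   lipid_class=str(row.get("lipid_class", "unassigned"))))
    return IonImageStack(planes=np.stack(planes), channels=channels,
                         pixel_size_um=float(tbl["pixel_size_um"].iloc[0]))


def read_imzml(path, channels: list[IonChannel], ppm: float = 5.0,
               pixel_size_um: float | None = None) -> IonImageStack:
    """Bin centroided imzML spectra onto a provided m/z channel list.

    For each pixel and channel, intensities within ±``ppm`` of the channel
    m/z are summed. Upstream annotation (which species each m/z is) is
    assumed done, as per the deposited-data workflow.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    xs = [c[0] for c in parser.coordinates]
    ys = [c[1] for c in parser.coordinates]
    w = max(xs)
    h = max(ys)
    planes = np.zeros((len(channels), h, w))
    targets = np.array([c.mz for c in channels])
    tol = targets * ppm * 1e-6
    for idx, (x, y, *_z) in enumerate(parser.coordinates):
        mzs, intensities = parser.getspectrum(idx)
        mzs = np.asarray(mzs)
        intensities = np.asarray(intensities)
        for ci, (t, dt) in enumerate(zip(targets, tol)):
            sel = np.abs(mzs - t) <= dt
            if sel.any():
                planes[ci, y - 1, x - 1] = intensities[sel].sum()
    if pixel_size_um is None:
        pixel_size_um = float(
            parser.imzmldict.get("pixel size x", 0) or 100.0)
    return IonImageStack(planes=planes, channels=list(channels),
                         pixel_size_um=pixel_size_um)
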