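"""Seeded phantom generators with machine-readable ground truth.

Every input type the pipeline consumes can be generated here with known
ground truth, so each downstream stage is testable without deposited
data:

- confocal phantoms: punctate transcription sites over a textured nuclear
  background, with an optional radially decaying co-enrichment of a second
  channel around each site (isotropic in physical µm space, resampled to
  anisotropic voxels, as in real confocal stacks where z-spacing exceeds
  xy);
- MALDI population sections: larva-shaped elliptical blobs whose pixel
  intensities encode per-larva, per-metabolite abundances drawn from
  group-specific lipid-class distributions, with optional batch offsets;
- larval trajectories: correlated random walks with injected
  pause-and-reorient (head-cast) events, plus still larvae;
- paired signal/control genomic coverage tracks;
- cuticle fields of punctate trichomes.

All randomness derives from one root seed through named substreams, so
adding one generator call never shifts the draws of another, and every
generator is a pure function of its config.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .behavior import Trajectory
from .chiptracks import GenomicTrack
from .maldi import IonChannel, IonImageStack
from .microenv import VolumeStack
from .morpho import Image2D

__all__ = [
    "substream",
    "ConfocalPhantomConfig",
    "ConfocalTruth",
    "gen_confocal_phantom",
    "IonPhantomConfig",
    "IonTruth",
    "default_lipid_panel",
    "gen_ion_phantom",
    "TrajectoryConfig",
    "TrajectoryTruth",
    "gen_trajectories",
    "TrackSpec",
    "TrackTruth",
    "gen_track_pair",
    "CuticleTruth",
    "gen_cuticle_phantom",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent named RNG substream derived from one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ===========================================================================
# Confocal phantom

@dataclass
class RegionSites:
    """Sites to place with xy centers inside a named 2D region mask."""

    mask: np.ndarray
    n_sites: int


@dataclass
class ConfocalPhantomConfig:
    shape_voxels: tuple[int, int, int] = (32, 192, 192)
    voxel_size_um: tuple[float, float, float] = (0.25, 0.08, 0.08)
    n_sites: int = 100
    site_peak_snr: float = 5.0
    site_amplitude_sigma: float = 0.0    # log-normal sigma of per-site amplitude
    enriched_fraction: float = 1.0       # fraction of sites carrying enrichment
    enrichment_amplitude: float = 1.0    # fold change of channel 2 at site center
    enrichment_sigma_um: float = 0.5
    background_mean: float = 100.0
    background_sd: float = 10.0
    psf_sigma_um: float = 0.15
    noise_model: str = "gaussian"        # none | gaussian | poisson
    min_separation_um: float | None = None   # default 3 * psf_sigma_um
    region_masks: dict[str, RegionSites] | None = None
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.shape_voxels):
            raise ValueError("shape_voxels must be positive")
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.site_peak_snr <= 0:
            raise ValueError("site_peak_snr must be > 0")
        if self.enrichment_amplitude < 1:
            raise ValueError("enrichment_amplitude must be >= 1")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @property
    def separation_um(self) -> float:
        return (self.min_separation_um if self.min_separation_um is not None
                else 3.0 * self.psf_sigma_um)


@dataclass
class ConfocalTruth:
    sites: pd.DataFrame          # z, y, x, z_um, y_um, x_um, peak_amplitude, enriched, region


def _place_points_3d(rng, shape, vsz, n, min_sep_um, margin_um,
                     xy_mask=None, existing=None) -> np.ndarray:
    """Rejection-sample voxel coordinates at a physical minimum separation."""
    shape = np.asarray(shape)
    vsz = np.asarray(vsz)
    margin = np.ceil(margin_um / vsz).astype(int)
    lo = margin
    hi = shape - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small for the requested margin")
    placed = [] if existing is None else [np.asarray(p) for p in existing]
    out = []
    min_sep2 = min_sep_um ** 2
    max_tries = 2000 * max(n, 1)
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} sites at separation {min_sep_um} µm; "
                "volume too crowded")
        c = np.array([rng.integers(lo[i], hi[i]) for i in range(3)])
        if xy_mask is not None and not xy_mask[c[1], c[2]]:
            continue
        p = c * vsz
        ok = True
        for q in placed:
            if (((q * vsz) - p) ** 2).sum() < min_sep2:
                ok = False
                break
        if ok:
            placed.append(c)
            out.append(c)
    return np.array(out, dtype=int).reshape(n, 3)


def gen_confocal_phantom(config: ConfocalPhantomConfig
                         ) -> tuple[VolumeStack, ConfocalTruth]:
    """Generate a two-channel confocal phantom.

    The ``"rna"`` channel holds ``n_sites`` PSF-blurred puncta whose
    post-blur peak is ``site_peak_snr * background_sd`` above background
    (times an optional per-site log-normal factor); the ``"mark"`` channel
    is ``background * (1 + (A - 1) * exp(-r^2 / 2 sigma^2))`` around each
    enriched site (physical distance r), then blurred and noised. Site
    placement respects a physical minimum separation (3 PSF sigma by
    default) so ground-truth matching is unambiguous.
    """
    cfg = config
    vsz = np.asarray(cfg.voxel_size_um)
    shape = tuple(cfg.shape_voxels)
    place_rng = substream(cfg.seed, "confocal.place")
    amp_rng = substream(cfg.seed, "confocal.amplitude")
    noise_rng = substream(cfg.seed, "confocal.noise")

    margin = max(cfg.separation_um, 3 * cfg.enrichment_sigma_um
                 if cfg.enrichment_amplitude > 1 else cfg.separation_um)
    coords_list = []
    regions = []
    if cfg.region_masks:
        existing: list[np.ndarray] = []
        for name, rs in cfg.region_masks.items():
            c = _place_points_3d(place_rng, shape, vsz, rs.n_sites,
                                 cfg.separation_um, margin,
                                 xy_mask=np.asarray(rs.mask) > 0,
                                 existing=existing)
            existing.extend(list(c))
            coords_list.append(c)
            regions.extend([name] * rs.n_sites)
        if cfg.n_sites:
            c = _place_points_3d(place_rng, shape, vsz, cfg.n_sites,
                                 cfg.separation_um, margin, existing=existing)
            coords_list.append(c)
            regions.extend([""] * cfg.n_sites)
    else:
        coords_list.append(_place_points_3d(place_rng, shape, vsz,
                                            cfg.n_sites, cfg.separation_um,
                                            margin))
        regions.extend([""] * cfg.n_sites)
    coords = (np.vstack(coords_list) if coords_list else
              np.empty((0, 3), dtype=int))
    n_total = len(coords)

    sigma_vox = cfg.psf_sigma_um / vsz
    # post-blur peak of a unit delta under a (discrete) Gaussian PSF
    g0 = float(np.prod(1.0 / (np.sqrt(2 * np.pi) * sigma_vox)))

    amps = cfg.site_peak_snr * cfg.background_sd * np.exp(
        amp_rng.normal(0.0, cfg.site_amplitude_sigma, size=n_total)
        if cfg.site_amplitude_sigma > 0 else np.zeros(n_total))
    enriched = np.zeros(n_total, dtype=bool)
    if cfg.enrichment_amplitude > 1 and n_total:
        k = int(round(cfg.enriched_fraction * n_total))
        enriched[:k] = True

    rna = np.full(shape, float(cfg.background_mean))
    deltas = np.zeros(shape)
    for (z, y, x), a in zip(coords, amps):
        deltas[z, y, x] += a / g0
    rna += ndimage.gaussian_filter(deltas, sigma=sigma_vox, mode="nearest")

    enrich_field = np.ones(shape)
    if cfg.enrichment_amplitude > 1:
        half = np.ceil(4 * cfg.enrichment_sigma_um / vsz).astype(int)
        for (z, y, x), flag in zip(coords, enriched):
            if not flag:
                continue
            lo = np.maximum([z, y, x] - half, 0)
            hi = np.minimum([z, y, x] + half + 1, shape)
            ax = [(np.arange(lo[i], hi[i]) - [z, y, x][i]) * vsz[i]
                  for i in range(3)]
            r2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                  + ax[2][None, None, :] ** 2)
            enrich_field[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
                (cfg.enrichment_amplitude - 1)
                * np.exp(-r2 / (2 * cfg.enrichment_sigma_um ** 2)))
    mark = ndimage.gaussian_filter(cfg.background_mean * enrich_field,
                                   sigma=sigma_vox, mode="nearest")

    if cfg.noise_model == "gaussian":
        rna = rna + noise_rng.normal(0, cfg.background_sd, shape)
        mark = mark + noise_rng.normal(0, cfg.background_sd, shape)
    elif cfg.noise_model == "poisson":
        rna = noise_rng.poisson(np.maximum(rna, 0)).astype(float)
        mark = noise_rng.poisson(np.maximum(mark, 0)).astype(float)

    stack = VolumeStack(channels={"rna": rna, "mark": mark},
                        voxel_size_um=tuple(vsz))
    sites = pd.DataFrame({
        "z": coords[:, 0], "y": coords[:, 1], "x": coords[:, 2],
        "z_um": coords[:, 0] * vsz[0], "y_um": coords[:, 1] * vsz[1],
        "x_um": coords[:, 2] * vsz[2],
        "peak_amplitude": amps, "enriched": enriched, "region": regions,
    }) if n_total else pd.DataFrame(columns=["z", "y", "x", "z_um", "y_um",
                                             "x_um", "peak_amplitude",
                                             "enriched", "region"])
    return stack, ConfocalTruth(sites=sites)


# ===========================================================================
# MALDI ion phantom

def default_lipid_panel(n_tg: int = 8, n_gpl: int = 8, n_other: int = 4
                        ) -> list[IonChannel]:
    """A synthetic pre-annotated lipid panel: triglycerides around
    m/z 800-900, glycerophospholipids around 700-800, plus unassigned."""
    channels = []
    for i in range(n_tg):
        channels.append(IonChannel(mz=815.65 + 2.1 * i, formula=f"TG{i}",
                                   adduct="+K", lipid_class="triglyceride"))
    for i in range(n_gpl):
        channels.append(IonChannel(mz=744.55 + 2.3 * i, formula=f"PC{i}",
                                   adduct="+H",
                                   lipid_class="glycerophospholipid"))
    for i in range(n_other):
        channels.append(IonChannel(mz=600.40 + 3.7 * i, formula=f"X{i}",
                                   lipid_class="unassigned"))
    return channels


@dataclass
class BatchSpec:
    assignment: Sequence[str]                 # batch label per larva
    additive: dict[str, float] = field(default_factory=dict)
    multiplicative: dict[str, float] = field(default_factory=dict)


@dataclass
class IonPhantomConfig:
    grid_shape: tuple[int, int] = (160, 160)
    pixel_size_um: float = 100.0
    n_larvae: int = 10
    larva_axes_px: tuple[float, float] = (12.0, 5.0)
    axis_jitter: float = 0.2                  # +-20% per-larva axis jitter
    min_gap_px: int = 2
    channels: list[IonChannel] = field(default_factory=default_lipid_panel)
    groups: Sequence[str] | None = None       # per larva; default half A half B
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    abundance_lognormal_params: tuple[float, float] = (4.0, 0.5)  # per-channel level
    individual_sigma: float = 0.2             # per-larva log-normal spread
    noise_sd: float = 0.0
    batches: BatchSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_larvae < 0:
            raise ValueError("n_larvae must be >= 0")
        mzs = [c.mz for c in self.channels]
        if len(set(mzs)) != len(mzs) or any(m <= 0 for m in mzs):
            raise ValueError("channel m/z values must be unique and positive")
        for g, effects in self.group_effects.items():
            if any(f <= 0 for f in effects.values()):
                raise ValueError("fold changes must be > 0")

    def group_labels(self) -> list[str]:
        if self.groups is not None:
            if len(self.groups) != self.n_larvae:
                raise ValueError("groups must have one label per larva")
            return list(self.groups)
        half = self.n_larvae // 2
        return ["A"] * half + ["B"] * (self.n_larvae - half)


@dataclass
class IonTruth:
    labels: np.ndarray           # ground-truth larva label mask
    abundance: pd.DataFrame      # larva x channel, pre-noise, pre-batch
    meta: pd.DataFrame           # group, batch per larva


def gen_ion_phantom(config: IonPhantomConfig
                    ) -> tuple[IonImageStack, IonTruth]:
    """Generate a population-section ion-image stack.

    Each larva is an axis-aligned ellipse of pixels (axes jittered
    ±``axis_jitter``); inside larva i, channel c's plane equals
    ``abundance[i, c]`` (after any batch offset), background is 0, and
    Gaussian noise of ``noise_sd`` is added everywhere. Larvae never
    overlap and keep a ``min_gap_px`` gap (the assay separates larvae in
    the mold); impossible packings raise after bounded retries.
    """
    cfg = config
    H, W = cfg.grid_shape
    place_rng = substream(cfg.seed, "ion.place")
    ab_rng = substream(cfg.seed, "ion.abundance")
    noise_rng = substream(cfg.seed, "ion.noise")

    labels = np.zeros((H, W), dtype=int)
    occupied = np.zeros((H, W), dtype=bool)
    yy, xx = np.mgrid[0:H, 0:W]
    max_tries = 500 * max(cfg.n_larvae, 1)
    tries = 0
    placed = 0
    while placed < cfg.n_larvae:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {cfg.n_larvae} larvae without overlap")
        a = cfg.larva_axes_px[0] * (1 + cfg.axis_jitter
                                    * place_rng.uniform(-1, 1))
        b = cfg.larva_axes_px[1] * (1 + cfg.axis_jitter
                                    * place_rng.uniform(-1, 1))
        cy = place_rng.uniform(b + 1, H - b - 1)
        cx = place_rng.uniform(a + 1, W - a - 1)
        ell = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        grown = ndimage.binary_dilation(ell, iterations=cfg.min_gap_px)
        if (grown & occupied).any() or not ell.any():
            continue
        placed += 1
        labels[ell] = placed
        occupied |= grown

    # renumber ground-truth labels in row-major centroid order, matching
    # the segmenter's convention so matrices align by construction
    if placed:
        order = sorted(range(1, placed + 1),
                       key=lambda i: ndimage.center_of_mass(labels == i))
        relabeled = np.zeros_like(labels)
        for new_id, old_id in enumerate(order, start=1):
            relabeled[labels == old_id] = new_id
        labels = relabeled

    groups = cfg.group_labels()
    if cfg.batches is not None:
        if len(cfg.batches.assignment) != cfg.n_larvae:
            raise ValueError("batch assignment must have one label per larva")
        batch_of = list(cfg.batches.assignment)
    else:
        batch_of = ["b0"] * cfg.n_larvae

    mu, sig = cfg.abundance_lognormal_params
    level = np.exp(ab_rng.normal(mu, sig, size=len(cfg.channels)))
    abundance = np.empty((cfg.n_larvae, len(cfg.channels)))
    for i in range(cfg.n_larvae):
        indiv = np.exp(ab_rng.normal(0.0, cfg.individual_sigma,
                                     size=len(cfg.channels)))
        fold = np.array([
            cfg.group_effects.get(groups[i], {}).get(c.lipid_class, 1.0)
            for c in cfg.channels])
        abundance[i] = level * indiv * fold

    planes = np.zeros((len(cfg.channels), H, W))
    for c in range(len(cfg.channels)):
        plane = planes[c]
        for i in range(cfg.n_larvae):
            v = abundance[i, c]
            if cfg.batches is not None:
                v = (v * cfg.batches.multiplicative.get(batch_of[i], 1.0)
                     + cfg.batches.additive.get(batch_of[i], 0.0))
            plane[labels == i + 1] = v
    if cfg.noise_sd > 0:
        planes += noise_rng.normal(0, cfg.noise_sd, planes.shape)

    names = [c.name for c in cfg.channels]
    idx = pd.Index(np.arange(1, cfg.n_larvae + 1), name="larva")
    truth = IonTruth(
        labels=labels,
        abundance=pd.DataFrame(abundance, index=idx, columns=names),
        meta=pd.DataFrame({"group": groups, "batch": batch_of}, index=idx))
    stack = IonImageStack(planes=planes, channels=list(cfg.channels),
                          pixel_size_um=cfg.pixel_size_um)
    return stack, truth


# ===========================================================================
# Trajectories

@dataclass
class TrajectoryConfig:
    duration_s: float = 120.0
    rate_hz: float = 30.0
    mean_speed_mm_s: float = 0.25
    speed_sd: float = 0.05            # per-step speed spread
    turn_sd_deg: float = 10.0         # per-step heading noise
    head_cast_rate_per_min: float = 1.5
    head_cast_angle_deg: float = 90.0
    head_cast_pause_s: float = 1.0
    still_fraction: float = 0.0
    still_jitter_mm: float = 0.005
    n_larvae: int = 26
    seed: int = 0

    def __post_init__(self):
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rate_hz and duration_s must be > 0")
        if not 0 <= self.still_fraction <= 1:
            raise ValueError("still_fraction must be in [0, 1]")


@dataclass
class TrajectoryTruth:
    larvae: pd.DataFrame                     # larva_id, mover, true speed, n_events
    events: dict[str, np.ndarray]            # injected head-cast times per larva


def _sample_event_starts(rng, n_steps, rate_hz, rate_per_min, pause_steps
                         ) -> np.ndarray:
    """Poisson event count, times placed with a refractory gap so events
    never overlap (a larva cannot cast twice at once)."""
    duration_s = n_steps / rate_hz
    n_ev = rng.poisson(rate_per_min * duration_s / 60.0)
    gap = pause_steps + int(round(1.0 * rate_hz))
    starts: list[int] = []
    for _ in range(200):
        if len(starts) >= n_ev:
            break
        lo = int(0.5 * rate_hz)
        hi = n_steps - pause_steps - int(0.5 * rate_hz)
        if hi <= lo:
            break
        s = int(rng.integers(lo, hi))
        if all(abs(s - t) >= gap for t in starts):
            starts.append(s)
    return np.array(sorted(starts), dtype=int)


def gen_trajectories(config: TrajectoryConfig
                     ) -> tuple[pd.DataFrame, TrajectoryTruth]:
    """Generate larval trajectories as a tidy table.

    Movers follow a correlated random walk (per-step heading noise
    ``turn_sd_deg``, per-step speed ~ N(mean, sd) clipped at 0) with
    injected head casts: a pause of ``head_cast_pause_s`` followed by a
    heading jump of ±``head_cast_angle_deg``, times recorded. Still larvae
    jitter around a fixed point with zero mean displacement.

    Returns ``(table, truth)`` with table columns larva_id, t_s, x_mm,
    y_mm.
    """
    cfg = config
    n_steps = int(round(cfg.duration_s * cfg.rate_hz))
    pause_steps = int(round(cfg.head_cast_pause_s * cfg.rate_hz))
    t = np.arange(n_steps + 1) / cfg.rate_hz

    frames = []
    truth_rows = []
    events: dict[str, np.ndarray] = {}
    for li in range(cfg.n_larvae):
        lid = f"larva{li:03d}"
        rng = substream(cfg.seed, f"traj.{li}")
        mover = rng.uniform() >= cfg.still_fraction
        if mover:
            ev = _sample_event_starts(rng, n_steps, cfg.rate_hz,
                                      cfg.head_cast_rate_per_min, pause_steps)
            heading0 = rng.uniform(0, 2 * np.pi)
            x0, y0 = rng.uniform(0, 10, size=2)
            turn = (np.deg2rad(rng.normal(0, cfg.turn_sd_deg, n_steps))
                    if cfg.turn_sd_deg > 0 else np.zeros(n_steps))
            speeds = np.maximum(
                0.0, cfg.mean_speed_mm_s
                + (rng.normal(0, cfg.speed_sd, n_steps)
                   if cfg.speed_sd > 0 else 0.0))
            jump_signs = np.where(rng.uniform(size=len(ev)) < 0.5, 1.0, -1.0)
            # freeze the walk during pauses, jump the heading afterwards
            moving = np.ones(n_steps, dtype=bool)
            for s in ev:
                moving[s:s + pause_steps] = False
            turn = turn * moving
            for s, sgn in zip(ev, jump_signs):
                jend = s + pause_steps
                if jend < n_steps:
                    turn[jend] += sgn * np.deg2rad(cfg.head_cast_angle_deg)
            heading = heading0 + np.cumsum(turn)
            step = speeds * moving / cfg.rate_hz
            x = np.concatenate([[x0], x0 + np.cumsum(step * np.cos(heading))])
            y = np.concatenate([[y0], y0 + np.cumsum(step * np.sin(heading))])
            events[lid] = ev / cfg.rate_hz
        else:
            x0, y0 = rng.uniform(0, 10, size=2)
            x = x0 + rng.normal(0, cfg.still_jitter_mm, n_steps + 1)
            y = y0 + rng.normal(0, cfg.still_jitter_mm, n_steps + 1)
            events[lid] = np.array([])
        frames.append(pd.DataFrame({"larva_id": lid, "t_s": t,
                                    "x_mm": x, "y_mm": y}))
        path = float(np.hypot(np.diff(x), np.diff(y)).sum())
        truth_rows.append({"larva_id": lid, "mover": mover,
                           "true_speed_mm_s": path / cfg.duration_s,
                           "n_events": len(events[lid])})
    table = pd.concat(frames, ignore_index=True)
    truth = TrajectoryTruth(larvae=pd.DataFrame(truth_rows), events=events)
    return table, truth


# ===========================================================================
# Genomic track pairs

@dataclass
class TrackSpec:
    baseline: float = 1.0
    peaks: tuple = ()            # (center_bin, sigma_bins, height)
    impulses: tuple = ()         # (bin, value)
    noise_sd: float = 0.0


@dataclass
class TrackTruth:
    signal: np.ndarray           # pre-noise values
    control: np.ndarray


def _render_spec(spec: TrackSpec, n_bins: int) -> np.ndarray:
    vals = np.full(n_bins, float(spec.baseline))
    i = np.arange(n_bins)
    for center, sigma, height in spec.peaks:
        vals += height * np.exp(-0.5 * ((i - center) / sigma) ** 2)
    for b, v in spec.impulses:
        vals[int(b)] += v
    return vals


def gen_track_pair(n_bins: int, bin_size_bp: int = 100,
                   signal_spec: TrackSpec | None = None,
                   control_spec: TrackSpec | None = None,
                   seed: int = 0, chrom: str = "chr2L"
                   ) -> tuple[GenomicTrack, GenomicTrack, TrackTruth]:
    """Paired signal/control coverage tracks on one chromosome with
    uniform bins; pre-noise values are retained as ground truth."""
    if n_bins <= 0:
        raise ValueError("n_bins must be > 0")
    signal_spec = signal_spec or TrackSpec()
    control_spec = control_spec or TrackSpec()
    s_true = _render_spec(signal_spec, n_bins)
    c_true = _render_spec(control_spec, n_bins)
    s = s_true.copy()
    c = c_true.copy()
    if signal_spec.noise_sd > 0:
        s = s + substream(seed, "track.signal").normal(
            0, signal_spec.noise_sd, n_bins)
    if control_spec.noise_sd > 0:
        c = c + substream(seed, "track.control").normal(
            0, control_spec.noise_sd, n_bins)
    return (GenomicTrack(chrom, bin_size_bp, 0, s),
            GenomicTrack(chrom, bin_size_bp, 0, c),
            TrackTruth(signal=s_true, control=c_true))


# ===========================================================================
# Cuticle phantom

@dataclass
class CuticleTruth:
    coordinates: np.ndarray      # (n, 2) row, col


def gen_cuticle_phantom(n_trichomes: int = 25,
                        shape: tuple[int, int] = (128, 128),
                        roi_mask: np.ndarray | None = None,
                        spacing_px: float = 6.0,
                        amplitude: float = 100.0,
                        background_mean: float = 10.0,
                        background_sd: float = 2.0,
                        psf_sigma_px: float = 1.2,
                        seed: int = 0) -> tuple[Image2D, CuticleTruth]:
    """Punctate trichome field over a noisy background.

    Puncta are placed at a minimum spacing within the ROI (full frame by
    default); each is a Gaussian of the given post-blur peak amplitude.
    Infeasible packings raise after bounded retries.
    """
    rng = substream(seed, "cuticle")
    H, W = shape
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask) > 0
    margin = int(np.ceil(3 * psf_sigma_px))
    pts: list[tuple[int, int]] = []
    tries = 0
    max_tries = 2000 * max(n_trichomes, 1)
    while len(pts) < n_trichomes:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_trichomes} trichomes at spacing "
                f"{spacing_px}px")
        r = int(rng.integers(margin, H - margin))
        c = int(rng.integers(margin, W - margin))
        if roi_mask is not None and not roi_mask[r, c]:
            continue
        if all((r - p[0]) ** 2 + (c - p[1]) ** 2 >= spacing_px ** 2
               for p in pts):
            pts.append((r, c))
    coords = np.array(pts, dtype=int).reshape(len(pts), 2)

    img = np.zeros((H, W))
    g0 = 1.0 / (2 * np.pi * psf_sigma_px ** 2)
    for r, c in coords:
        img[r, c] += amplitude / g0
    img = ndimage.gaussian_filter(img, psf_sigma_px, mode="nearest")
    img += background_mean
    if background_sd > 0:
        img += rng.normal(0, background_sd, (H, W))
    return Image2D(img), CuticleTruth(coordinates=coords)
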