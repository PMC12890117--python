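"""Seeded synthetic data with known ground truth for the paper-chip assay.

Everything the downstream pipeline consumes can be generated here with the
true answer attached: capillary-flow videos with a planted front trajectory,
fluorescence micrographs with planted agglutinated clusters and free
particles, and replicate calibration tables drawn around a known standard
curve.  The dose-response world follows the Heidelberger-Kendall precipitin
picture: the extent of particle immunoagglutination is bell-shaped in
log-concentration (antibody excess → equivalence → antigen excess), and the
flow-velocity response is semi-log linear below the equivalence point, then
plateaus and declines.

Default ground-truth parameters are the plasma-assay standard curve
(velocity = 0.540·log10 c + 0.040 px/frame, equivalence near 19 ng/mL); a
PBS preset (slope 0.136, intercept 0.575) is provided.  All randomness is
driven by a single seed via numpy's SeedSequence spawning, so identical
(spec, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidInputError
from .flow import ChannelGeometry, FrameStack

__all__ = [
    "AssayGroundTruth",
    "FlowVideoSpec",
    "ParticleImageSpec",
    "ParticleImageTruth",
    "agglutination_extent",
    "true_velocity",
    "generate_flow_video",
    "generate_particle_image",
    "generate_calibration_table",
    "bell_cluster_counts",
    "write_frame_stack",
]

#: margin (px) of dry paper rendered around the channel in synthetic frames
FRAME_MARGIN = 10
#: dry-paper intensity in synthetic flow frames (0-255)
DRY_INTENSITY = 220


@dataclass(frozen=True)
class AssayGroundTruth:
    """True parameters of a synthetic assay world.

    slope_m
        Velocity gain per decade of concentration (px/frame per log10 ng/mL)
        in the antibody-excess zone.  Default 0.540 (diluted-plasma assay).
    intercept_b
        Velocity at 1 ng/mL (px/frame).  Default 0.040.
    c_eq
        Equivalence concentration (ng/mL): the bell peak where agglutination
        is maximal and the velocity response plateaus.  Default 19.
    bell_width_s
        Width of the agglutination bell in log10-concentration decades.
    noise_sd_v
        Replicate velocity noise sd (px/frame); homoscedastic.
    decline_factor
        Fraction of slope_m at which velocity declines past c_eq.
    """

    slope_m: float = 0.540
    intercept_b: float = 0.040
    c_eq: float = 19.0
    bell_width_s: float = 1.0
    noise_sd_v: float = 0.02
    decline_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope_m <= 0:
            raise InvalidInputError("slope_m must be positive (antibody-excess zone)")
        if self.c_eq <= 0:
            raise InvalidInputError("c_eq must be positive")
        if self.bell_width_s <= 0:
            raise InvalidInputError("bell_width_s must be positive")
        if self.noise_sd_v < 0:
            raise InvalidInputError("noise_sd_v must be ≥ 0")

    @classmethod
    def pbs(cls, **overrides) -> "AssayGroundTruth":
        """The buffer-only (PBS) assay world: shallower slope, higher intercept,
        no saturation within the tested range (equivalence pushed far right)."""
        defaults = dict(slope_m=0.136, intercept_b=0.575, c_eq=100.0)
        defaults.update(overrides)
        return cls(**defaults)


def agglutination_extent(c: float, gt: AssayGroundTruth) -> float:
    """Relative extent of particle immunoagglutination at concentration ``c``.

    Modeled as a Gaussian in log10-concentration centred on the equivalence
    point: ``exp(-(log10 c - log10 c_eq)^2 / (2 s^2))``, peaking at 1 at
    c = c_eq and approaching 0 in both the far antibody-excess and far
    antigen-excess limits; exactly 0 at c = 0 (no antigen, no specific
    agglutination).
    """
    if c < 0:
        raise InvalidInputError(f"concentration must be ≥ 0, got {c}")
    if c == 0:
        return 0.0
    z = (math.log10(c) - math.log10(gt.c_eq)) / gt.bell_width_s
    return math.exp(-0.5 * z * z)


def true_velocity(c: float, gt: AssayGroundTruth) -> float:
    """Noise-free capillary flow velocity (px/frame) at concentration ``c``.

    Semi-log linear ``b + m·log10(c)`` up to the equivalence point, then a
    plateau-and-decline: past c_eq the velocity falls at ``decline_factor``
    times the rise slope per decade.  Continuous at c_eq.
    """
    if c <= 0:
        raise InvalidInputError(f"concentration must be > 0, got {c}")
    lc = math.log10(c)
    leq = math.log10(gt.c_eq)
    if lc <= leq:
        return gt.intercept_b + gt.slope_m * lc
    peak = gt.intercept_b + gt.slope_m * leq
    return peak - gt.slope_m * (lc - leq) * gt.decline_factor


@dataclass(frozen=True)
class FlowVideoSpec:
    """Geometry and acquisition parameters of a synthetic flow video."""

    n_frames: int = 60
    fps: float = 30.0
    channel_length_px: int = 200
    channel_width_px: int = 40
    idle_frames: int = 0
    corrupt_frames: tuple[int, ...] = ()
    jitter_sd_px: float = 0.0
    wet_dry_contrast: float = 80.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidInputError("fps must be positive")
        if not (0 <= self.idle_frames < self.n_frames):
            raise InvalidInputError("need 0 ≤ idle_frames < n_frames")
        if any(not (0 <= f < self.n_frames) for f in self.corrupt_frames):
            raise InvalidInputError("corrupt_frames must lie in [0, n_frames)")
        if self.wet_dry_contrast <= 0:
            raise InvalidInputError("wet_dry_contrast must be positive")
        if self.jitter_sd_px < 0:
            raise InvalidInputError("jitter_sd_px must be ≥ 0")

    @property
    def frame_shape(self) -> tuple[int, int]:
        h = self.channel_width_px + 2 * FRAME_MARGIN
        w = FRAME_MARGIN + self.channel_length_px + FRAME_MARGIN
        return (h, w)

    def geometry(self) -> ChannelGeometry:
        """The ChannelGeometry matching the rendered frames."""
        return ChannelGeometry(
            roi=(FRAME_MARGIN, FRAME_MARGIN, self.channel_length_px, self.channel_width_px),
            entry_line=FRAME_MARGIN,
            channel_length_px=self.channel_length_px,
        )


def generate_flow_video(
    spec: FlowVideoSpec,
    v: float,
    seed: int = 0,
) -> tuple[FrameStack, np.ndarray]:
    """Render a synthetic capillary-flow video at constant velocity ``v``.

    From ``idle_frames`` onward the wet front advances at ``v`` px/frame from
    the entry line, with optional Gaussian positional jitter; wet pixels are
    darker than dry paper by ``wet_dry_contrast``.  Frames listed in
    ``corrupt_frames`` have their wet/dry boundary destroyed (rendered
    all-dry or all-wet at random), emulating acquisition glitches where the
    detected distance collapses to zero or the full channel length mid-flow.

    Returns the frame stack and the planted per-frame front positions
    (integer px, as rendered — i.e. before corruption).
    """
    if v < 0:
        raise InvalidInputError("velocity must be ≥ 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    L = spec.channel_length_px
    h, w = spec.frame_shape
    entry = FRAME_MARGIN

    jitter = (
        rng.normal(0.0, spec.jitter_sd_px, size=spec.n_frames)
        if spec.jitter_sd_px > 0
        else np.zeros(spec.n_frames)
    )
    corrupt_all_wet = {
        f: bool(rng.integers(0, 2)) for f in sorted(set(spec.corrupt_frames))
    }

    truth = np.zeros(spec.n_frames, dtype=np.float64)
    frames = np.full((spec.n_frames, h, w), DRY_INTENSITY, dtype=np.uint8)
    wet_value = int(round(max(0.0, DRY_INTENSITY - spec.wet_dry_contrast)))
    ch_rows = slice(FRAME_MARGIN, FRAME_MARGIN + spec.channel_width_px)
    for f in range(spec.n_frames):
        base = 0.0 if f < spec.idle_frames else v * (f - spec.idle_frames)
        pos = int(round(np.clip(base + jitter[f], 0.0, float(L))))
        truth[f] = pos
        if f in corrupt_all_wet:
            front = L if corrupt_all_wet[f] else 0
        else:
            front = pos
        if front > 0:
            # loading zone plus the wetted run of the main channel
            frames[f, ch_rows, : entry + front] = wet_value
    stack = FrameStack(
        frames=frames,
        fps=spec.fps,
        metadata={
            "seed": seed,
            "corrupt_frames": sorted(corrupt_all_wet),
            "idle_frames": spec.idle_frames,
            "velocity_px_per_frame": v,
        },
    )
    return stack, truth


@dataclass(frozen=True)
class ParticleImageSpec:
    """Parameters of a synthetic fluorescence micrograph.

    Agglutinated clusters have lognormal pixel areas at or above the counting
    size threshold; free (non-agglutinated) particles are small blobs below
    it.  Particles live on the green channel, as in the physical assay where
    a green bandpass filter isolates the particles' fluorescence.
    """

    height_px: int = 256
    width_px: int = 256
    n_clusters: int = 6
    cluster_area_log_mean: float = 4.8  # median area ≈ 120 px
    cluster_area_log_sd: float = 0.4
    n_singles: int = 40
    single_area_range: tuple[int, int] = (3, 20)
    background_mean: float = 30.0
    background_sd: float = 10.0
    particle_intensity_range: tuple[int, int] = (150, 255)
    min_cluster_area: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.particle_intensity_range
        if not (0 <= lo <= hi <= 255):
            raise InvalidInputError("particle_intensity_range must be within [0, 255]")
        lo, hi = self.single_area_range
        if not (1 <= lo <= hi):
            raise InvalidInputError("single_area_range must be positive")
        if hi >= self.min_cluster_area:
            raise InvalidInputError(
                "single areas must stay below the cluster size threshold"
            )
        if self.background_sd < 0 or self.background_mean < 0:
            raise InvalidInputError("background parameters must be ≥ 0")


@dataclass
class ParticleImageTruth:
    """Ground truth accompanying one synthetic micrograph."""

    cluster_mask: np.ndarray
    single_mask: np.ndarray
    cluster_pixels: int
    single_pixels: int


_NEIGHBORS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _grow_blob(
    rng: np.random.Generator,
    area: int,
    shape: tuple[int, int],
    blocked: np.ndarray,
    max_attempts: int = 1000,
) -> list[tuple[int, int]] | None:
    """Grow a random connected blob of exactly ``area`` pixels avoiding
    ``blocked`` pixels; returns None if placement fails."""
    h, w = shape
    for _ in range(max_attempts):
        r0 = int(rng.integers(0, h))
        c0 = int(rng.integers(0, w))
        if blocked[r0, c0]:
            continue
        pixels = {(r0, c0)}
        frontier = [(r0, c0)]
        stuck = False
        while len(pixels) < area:
            candidates = []
            for r, c in frontier:
                for dr, dc in _NEIGHBORS4:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and not blocked[rr, cc] and (rr, cc) not in pixels:
                        candidates.append((rr, cc))
            if not candidates:
                stuck = True
                break
            pick = candidates[int(rng.integers(0, len(candidates)))]
            pixels.add(pick)
            frontier.append(pick)
        if not stuck:
            return sorted(pixels)
    return None


def _block_around(blocked: np.ndarray, pixels: list[tuple[int, int]]) -> None:
    """Mark pixels and their 8-neighbourhood as blocked (1-px separation keeps
    planted objects disjoint under 8-connectivity labeling)."""
    h, w = blocked.shape
    for r, c in pixels:
        blocked[max(0, r - 1) : min(h, r + 2), max(0, c - 1) : min(w, c + 2)] = True


def generate_particle_image(
    spec: ParticleImageSpec,
) -> tuple[np.ndarray, ParticleImageTruth]:
    """Render one synthetic fluorescence micrograph with planted objects.

    The green channel carries the particles (intensities drawn from
    ``particle_intensity_range``, all above the counting intensity threshold)
    over Gaussian background noise clipped to [0, 255]; red and blue carry
    background noise only.  Planted objects are mutually disjoint with ≥1 px
    separation, so connected-component labeling recovers them exactly.

    Returns the RGB uint8 image and the ground truth (cluster/single masks
    and their separate pixel totals).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    shape = (spec.height_px, spec.width_px)
    blocked = np.zeros(shape, dtype=bool)
    cluster_mask = np.zeros(shape, dtype=bool)
    single_mask = np.zeros(shape, dtype=bool)

    cluster_areas = [
        max(
            spec.min_cluster_area,
            int(round(rng.lognormal(spec.cluster_area_log_mean, spec.cluster_area_log_sd))),
        )
        for _ in range(spec.n_clusters)
    ]
    single_areas = [
        int(rng.integers(spec.single_area_range[0], spec.single_area_range[1] + 1))
        for _ in range(spec.n_singles)
    ]

    for kind, mask, areas in (
        ("cluster", cluster_mask, cluster_areas),
        ("single", single_mask, single_areas),
    ):
        for area in areas:
            pixels = _grow_blob(rng, area, shape, blocked)
            if pixels is None:
                raise GenerationError(
                    f"could not place a {kind} of {area} px after 1000 attempts; "
                    "image too small or too crowded"
                )
            for r, c in pixels:
                mask[r, c] = True
            _block_around(blocked, pixels)

    def _background() -> np.ndarray:
        if spec.background_sd == 0 and spec.background_mean == 0:
            return np.zeros(shape, dtype=np.uint8)
        noise = rng.normal(spec.background_mean, spec.background_sd, size=shape)
        return np.clip(noise, 0, 255).round().astype(np.uint8)

    green = _background()
    particle_mask = cluster_mask | single_mask
    n_particle_px = int(particle_mask.sum())
    lo, hi = spec.particle_intensity_range
    green[particle_mask] = rng.integers(lo, hi + 1, size=n_particle_px, dtype=np.int64)
    image = np.stack([_background(), green, _background()], axis=-1)

    truth = ParticleImageTruth(
        cluster_mask=cluster_mask,
        single_mask=single_mask,
        cluster_pixels=int(cluster_mask.sum()),
        single_pixels=int(single_mask.sum()),
    )
    return image, truth


def bell_cluster_counts(
    concs: "list[float] | np.ndarray",
    gt: AssayGroundTruth,
    max_clusters: int = 12,
) -> list[int]:
    """Planted cluster counts along a concentration series, following the
    precipitin bell: ``round(max_clusters · extent(c))``."""
    return [int(round(max_clusters * agglutination_extent(c, gt))) for c in concs]


def generate_calibration_table(
    concs: "list[float] | np.ndarray",
    gt: AssayGroundTruth,
    n_rep: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate velocity measurements around the true dose-response curve.

    Returns a tidy table with columns ``conc_ng_ml``, ``replicate``,
    ``velocity_px_per_frame`` where each velocity is
    ``true_velocity(c) + Normal(0, noise_sd_v)``.
    """
    if n_rep < 1:
        raise InvalidInputError("n_rep must be ≥ 1")
    concs = [float(c) for c in concs]
    if any(c <= 0 for c in concs):
        raise InvalidInputError("calibration concentrations must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for c in concs:
        mu = true_velocity(c, gt)
        noise = rng.normal(0.0, gt.noise_sd_v, size=n_rep) if gt.noise_sd_v > 0 else np.zeros(n_rep)
        for rep in range(n_rep):
            rows.append((c, rep, mu + noise[rep]))
    return pd.DataFrame(
        rows, columns=["conc_ng_ml", "replicate", "velocity_px_per_frame"]
    )


def write_frame_stack(
    directory: "str | Path",
    stack: FrameStack,
    ground_truth: np.ndarray | None = None,
    spec: FlowVideoSpec | None = None,
) -> Path:
    """Write a frame stack as zero-padded PNGs plus a JSON sidecar.

    The sidecar records fps, geometry and (when given) the planted front
    trace, so a written fixture is fully self-describing.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for f in range(len(stack)):
        iio.imwrite(directory / f"frame_{f:04d}.png", stack.frames[f])
    sidecar: dict = {"fps": stack.fps, "n_frames": len(stack), **stack.metadata}
    if spec is not None:
        sidecar["spec"] = asdict(spec)
        sidecar["geometry"] = {
            "roi": list(spec.geometry().roi),
            "entry_line": spec.geometry().entry_line,
            "channel_length_px": spec.channel_length_px,
        }
    if ground_truth is not None:
        sidecar["true_front_px"] = [float(x) for x in ground_truth]
    path = directory / "video.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path
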