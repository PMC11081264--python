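"""Ground-truthed synthetic two-channel neurite transport movies and images.

The generator emulates the statistical structure of dual-colour time-lapse
imaging of vesicular transport along a straight 1-D neurite: vesicles carry
one or both fluorophores, move anterogradely/retrogradely/bidirectionally or
sit still, switch between runs and pauses with memoryless (exponential)
waiting times, and are rendered as PSF-blurred boxes of their physical
length onto a multi-row line scan with optional Poisson photon noise and
Gaussian read noise. Every movie ships with a per-vesicle, per-frame ground
truth table, so each downstream measurement can be validated against the
quantity it claims to estimate.

Presets encode published experimental conditions: co-labelling probabilities
for wild-type and syd-2 mutant SNB-1/RAB-3 co-transport, and dendrite
signal-extent cohorts matching reported per-genotype mean +/- SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.ndimage import gaussian_filter1d

from .core import ConfigurationError, Movie, PixelGeometry
from .quantify import NeuriteProfile

__all__ = [
    "VesicleSpec",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_movie",
    "simulate_static_image",
    "simulate_dendrite_cohort",
    "make_preset_config",
    "MOVIE_PRESETS",
    "DENDRITE_PRESETS",
    "DIRECTION_CLASSES",
]

DIRECTION_CLASSES = ("anterograde", "retrograde", "bidirectional", "stationary")

# Direction-call tie tolerance in micrometres (2 px at the default scale);
# shared with tracing.classify_direction.
DEFAULT_TIE_TOL_UM = 2 * 0.126


@dataclass(frozen=True)
class VesicleSpec:
    """Ground-truth parameters of one simulated vesicle."""

    id: int
    channels: tuple[str, ...]  # subset of ("A", "B"); both => co-labelled
    x0: float  # initial position, um from cell-body edge
    direction_class: str
    speed: float  # um/s while running
    pause_rate: float  # events/s while running
    pause_duration_mean: float  # s
    reversal_rate: float  # events/s, bidirectional only
    length: float  # physical extent along the neurite, um
    brightness: float  # expected integrated photons per frame

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigurationError("vesicle must carry at least one channel")
        if self.speed < 0 or self.length < 0:
            raise ConfigurationError("speed and length must be non-negative")
        if self.direction_class == "stationary" and self.speed != 0:
            raise ConfigurationError("stationary vesicles must have speed 0")
        if self.direction_class not in DIRECTION_CLASSES:
            raise ConfigurationError(f"unknown direction class {self.direction_class!r}")


@dataclass
class SimulationConfig:
    """Full specification of a synthetic dual-channel acquisition.

    ``p_colabel`` is the probability that a channel-A vesicle also carries
    channel B (so the fraction of A vesicles co-migrating with B converges
    to it); ``p_b_only`` is the fraction of vesicles carrying B alone.
    """

    geometry: PixelGeometry = field(default_factory=PixelGeometry)
    n_vesicles: int = 80
    p_colabel: float = 0.35
    p_b_only: float = 0.25
    direction_mix: dict = field(
        default_factory=lambda: {
            "anterograde": 0.45,
            "retrograde": 0.25,
            "bidirectional": 0.15,
            "stationary": 0.15,
        }
    )
    speed_loc: float = 1.0  # um/s
    speed_scale: float = 0.25
    speed_min: float = 0.15
    length_loc: float = 1.2  # um
    length_scale: float = 0.35
    length_min: float = 0.3
    pause_rate: float = 0.2  # per s (saltatory transport: ~5 um mean run at 1 um/s)
    pause_duration_mean: float = 2.0  # s
    reversal_rate: float = 0.05  # per s (bidirectional)
    brightness: float = 2000.0  # photons per frame, integrated over the vesicle
    psf_sigma: float = 0.2  # um
    background_level: float = 20.0  # photons per pixel per frame
    photon_noise: bool = True
    read_noise_sd: float = 3.0
    origin_px: int = 6
    cell_body_brightness: float = 300.0  # added per pixel over [0, origin_px)
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.geometry, PixelGeometry):
            raise ConfigurationError("geometry must be a PixelGeometry")
        if not 0.0 <= self.p_colabel <= 1.0:
            raise ConfigurationError("p_colabel must lie in [0, 1]")
        if not 0.0 <= self.p_b_only <= 1.0:
            raise ConfigurationError("p_b_only must lie in [0, 1]")
        if self.n_vesicles < 0:
            raise ConfigurationError("n_vesicles must be non-negative")
        total = sum(self.direction_mix.get(k, 0.0) for k in DIRECTION_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("direction_mix probabilities must sum to 1")
        if any(v < 0 for v in self.direction_mix.values()):
            raise ConfigurationError("direction_mix probabilities must be non-negative")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ConfigurationError("noise levels must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        return d


@dataclass
class SimulationTruth:
    """Per-vesicle specs and per-frame positions emitted alongside a movie.

    ``vesicles`` has one row per vesicle (channels, direction class and
    truth direction call by the net-displacement rule, kinematics, length);
    ``positions`` is long-format (vesicle_id, frame, t_s, x_um).
    """

    vesicles: pd.DataFrame
    positions: pd.DataFrame
    config: SimulationConfig
    seed: int

    def trace_table(self, channel: str) -> pd.DataFrame:
        """Truth positions of the vesicles carrying ``channel`` as an
        ingestible trace table (trace_id, channel, t_s, x_um)."""
        col = "channel_a" if channel == "A" else "channel_b"
        ids = self.vesicles.loc[self.vesicles[col], "id"]
        sub = self.positions[self.positions["vesicle_id"].isin(ids)]
        return pd.DataFrame(
            {
                "trace_id": sub["vesicle_id"].to_numpy(),
                "channel": channel,
                "t_s": sub["t_s"].to_numpy(),
                "x_um": sub["x_um"].to_numpy(),
            }
        )


# ---------------------------------------------------------------------------
# presets

MOVIE_PRESETS: dict[str, dict] = {
    # Wild-type SNB-1/RAB-3 dual-colour imaging: ~35% of moving SNB-1
    # vesicles co-transport RAB-3 (simultaneous acquisition, 3 fps).
    "WT_SNB1_RAB3": {"p_colabel": 0.35},
    # syd-2 mutant: co-transport incidence drops to ~15%.
    "syd2_SNB1_RAB3": {"p_colabel": 0.15},
}

# Dendrite signal-extent cohorts: (mean %, SD %) of dendrite length showing
# signal, per genotype.
DENDRITE_PRESETS: dict[str, tuple[float, float]] = {
    "wt_dendrite": (39.0, 27.0),
    "lrk1_dendrite": (92.0, 2.0),
    "apb3_dendrite": (69.0, 28.0),
    "syd2_dendrite": (25.0, 25.0),
}


def make_preset_config(preset: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Build a SimulationConfig from a named movie preset."""
    if preset not in MOVIE_PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; choose from {sorted(MOVIE_PRESETS)}"
        )
    kwargs = dict(MOVIE_PRESETS[preset])
    kwargs.update(overrides)
    kwargs.setdefault("seed", seed)
    cfg = SimulationConfig(**kwargs)
    cfg.seed = seed
    return cfg


# ---------------------------------------------------------------------------
# movie simulation


def _sample_specs(cfg: SimulationConfig, rng: np.random.Generator) -> list[VesicleSpec]:
    g = cfg.geometry
    neurite_len = (g.n_px - cfg.origin_px) * g.pixel_size
    classes = [k for k in DIRECTION_CLASSES]
    probs = np.array([cfg.direction_mix.get(k, 0.0) for k in classes])
    specs = []
    for i in range(cfg.n_vesicles):
        # channel assignment: B-only with prob p_b_only, otherwise the
        # vesicle carries A and is co-labelled with prob p_colabel
        if rng.random() < cfg.p_b_only:
            channels: tuple[str, ...] = ("B",)
        elif rng.random() < cfg.p_colabel:
            channels = ("A", "B")
        else:
            channels = ("A",)
        dcls = classes[rng.choice(len(classes), p=probs)]
        if dcls == "stationary":
            speed = 0.0
        else:
            speed = max(cfg.speed_min, rng.normal(cfg.speed_loc, cfg.speed_scale))
        length = max(cfg.length_min, rng.normal(cfg.length_loc, cfg.length_scale))
        if dcls == "anterograde":
            x0 = rng.uniform(0.0, 0.7 * neurite_len)
        elif dcls == "retrograde":
            x0 = rng.uniform(0.3 * neurite_len, neurite_len)
        elif dcls == "bidirectional":
            x0 = rng.uniform(0.1 * neurite_len, 0.9 * neurite_len)
        else:
            x0 = rng.uniform(0.0, neurite_len)
        specs.append(
            VesicleSpec(
                id=i,
                channels=channels,
                x0=x0,
                direction_class=dcls,
                speed=speed,
                pause_rate=cfg.pause_rate,
                pause_duration_mean=cfg.pause_duration_mean,
                reversal_rate=cfg.reversal_rate if dcls == "bidirectional" else 0.0,
                length=length,
                brightness=cfg.brightness,
            )
        )
    return specs


def _advect(specs: list[VesicleSpec], cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Markov run/pause/reverse advection; returns (n_vesicles, n_frames) um."""
    g = cfg.geometry
    n = len(specs)
    nf = g.n_frames
    dt = g.frame_interval
    neurite_len = (g.n_px - cfg.origin_px) * g.pixel_size
    lo, hi = -0.5, neurite_len + 0.5

    pos = np.array([s.x0 for s in specs], dtype=float)
    speed = np.array([s.speed for s in specs])
    sign = np.ones(n)
    for i, s in enumerate(specs):
        if s.direction_class == "retrograde":
            sign[i] = -1.0
        elif s.direction_class == "bidirectional":
            sign[i] = rng.choice([-1.0, 1.0])
    pause_rate = np.array([s.pause_rate for s in specs])
    rev_rate = np.array([s.reversal_rate for s in specs])
    pause_mean = np.array([s.pause_duration_mean for s in specs])
    moving_cls = np.array([s.direction_class != "stationary" for s in specs])

    paused_until = np.full(n, -1.0)  # simulation time when pause ends
    out = np.empty((n, nf))
    out[:, 0] = pos
    p_pause = 1.0 - np.exp(-pause_rate * dt)
    p_rev = 1.0 - np.exp(-rev_rate * dt)
    for f in range(1, nf):
        t = f * dt
        running = moving_cls & (paused_until < t)
        pos[running] += sign[running] * speed[running] * dt
        np.clip(pos, lo, hi, out=pos)
        # transitions evaluated after the step
        start_pause = running & (rng.random(n) < p_pause)
        if start_pause.any():
            paused_until[start_pause] = t + rng.exponential(pause_mean[start_pause])
        reverse = running & ~start_pause & (rng.random(n) < p_rev)
        sign[reverse] *= -1.0
        out[:, f] = pos
    return out


def _render_channel(
    specs: list[VesicleSpec],
    positions: np.ndarray,
    cfg: SimulationConfig,
    channel: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render all vesicles carrying ``channel`` into a (t, y, x) stack."""
    g = cfg.geometry
    nf, ny, nx = g.n_frames, g.line_width_px, g.n_px
    px = g.pixel_size
    profile = np.zeros((nf, nx))
    sigma = max(cfg.psf_sigma, 1e-6)
    col_um = (np.arange(nx) - cfg.origin_px) * px  # pixel centres, um

    for spec, xs in zip(specs, positions):
        if channel not in spec.channels:
            continue
        half = spec.length / 2.0
        w_um = half + 4.0 * sigma
        w_px = int(math.ceil(w_um / px)) + 1
        c_px = np.rint(xs / px + cfg.origin_px).astype(int)
        cols = c_px[:, None] + np.arange(-w_px, w_px + 1)[None, :]
        valid = (cols >= 0) & (cols < nx)
        cc = np.clip(cols, 0, nx - 1)
        d = col_um[cc] - xs[:, None]  # offset of pixel centre from vesicle centre
        # box of physical length convolved with a Gaussian PSF, integrated
        # per pixel (pixel-centre sampling x pixel size)
        box = 0.5 * (
            sstats.norm.cdf((d + half) / sigma) - sstats.norm.cdf((d - half) / sigma)
        ) * 2.0
        dens = spec.brightness / max(spec.length, 2 * sigma)
        contrib = dens * box * px * valid
        np.add.at(profile, (np.arange(nf)[:, None], cc), contrib)

    # transverse PSF: distribute the line profile over the imaged rows
    rows = np.arange(ny) - (ny - 1) / 2.0
    tw = np.exp(-0.5 * (rows * px / sigma) ** 2)
    tw /= tw.sum()
    stack = profile[:, None, :] * tw[None, :, None]
    stack += cfg.background_level
    if cfg.cell_body_brightness > 0 and cfg.origin_px > 0:
        stack[:, :, : cfg.origin_px] += cfg.cell_body_brightness
    if cfg.photon_noise:
        stack = rng.poisson(stack).astype(float)
    if cfg.read_noise_sd > 0:
        stack += rng.normal(0.0, cfg.read_noise_sd, size=stack.shape)
    return np.clip(stack, 0.0, None)


def _truth_direction(net: float, tie_tol: float = DEFAULT_TIE_TOL_UM) -> str:
    if abs(net) < tie_tol:
        return "excluded"
    return "anterograde" if net > 0 else "retrograde"


def simulate_movie(
    config: SimulationConfig, specs: list[VesicleSpec] | None = None
) -> tuple[Movie, Movie, SimulationTruth]:
    """Generate a co-registered dual-channel movie plus ground truth.

    Co-labelled vesicles occupy identical positions in both channels.
    Deterministic given ``config.seed``: dynamics and per-channel noise
    streams are split from the master seed by fixed offsets.

    Pass ``specs`` for controlled experiments with explicitly chosen
    vesicles (initial positions, kinetics, labels); otherwise vesicles are
    sampled from the config's distributions.
    """
    config.validate()
    g = config.geometry
    rng_dyn = np.random.default_rng([config.seed, 0])
    rng_a = np.random.default_rng([config.seed, 1])
    rng_b = np.random.default_rng([config.seed, 2])

    if specs is None:
        specs = _sample_specs(config, rng_dyn)
    positions = (
        _advect(specs, config, rng_dyn) if specs else np.zeros((0, g.n_frames))
    )

    stack_a = _render_channel(specs, positions, config, "A", rng_a)
    stack_b = _render_channel(specs, positions, config, "B", rng_b)
    movie_a = Movie(stack_a, g, channel="A", origin=config.origin_px)
    movie_b = Movie(stack_b, g, channel="B", origin=config.origin_px)

    t_s = np.arange(g.n_frames) * g.frame_interval
    ves_rows = []
    pos_frames = []
    for spec, xs in zip(specs, positions):
        net = xs[-1] - xs[0]
        ves_rows.append(
            {
                "id": spec.id,
                "channel_a": "A" in spec.channels,
                "channel_b": "B" in spec.channels,
                "colabeled": len(spec.channels) == 2,
                "direction_class": spec.direction_class,
                "speed_um_s": spec.speed,
                "length_um": spec.length,
                "x0_um": spec.x0,
                "net_displacement_um": net,
                "direction_truth": (
                    "stationary"
                    if spec.direction_class == "stationary"
                    else _truth_direction(net)
                ),
                "seed": config.seed,
            }
        )
        pos_frames.append(
            pd.DataFrame(
                {
                    "vesicle_id": spec.id,
                    "frame": np.arange(g.n_frames),
                    "t_s": t_s,
                    "x_um": xs,
                }
            )
        )
    vesicles = pd.DataFrame(
        ves_rows,
        columns=[
            "id", "channel_a", "channel_b", "colabeled", "direction_class",
            "speed_um_s", "length_um", "x0_um", "net_displacement_um",
            "direction_truth", "seed",
        ],
    )
    positions_df = (
        pd.concat(pos_frames, ignore_index=True)
        if pos_frames
        else pd.DataFrame(columns=["vesicle_id", "frame", "t_s", "x_um"])
    )
    truth = SimulationTruth(vesicles=vesicles, positions=positions_df, config=config, seed=config.seed)
    return movie_a, movie_b, truth


# ---------------------------------------------------------------------------
# static images


def simulate_static_image(kind: str, params: dict | None = None, seed: int = 0):
    """Generate a single static fixture with known truth.

    Parameters
    ----------
    kind : {"cell_body_puncta", "neurite_profile", "dendrite_extent"}
        * ``cell_body_puncta`` -> (image 2-D array, mask, truth): uniform
          disk puncta of known punctum/cytosol intensity ratio on a
          cytosolic disk.
        * ``neurite_profile`` -> (NeuriteProfile, truth): puncta along a
          neurite with a known furthest signal position (um).
        * ``dendrite_extent`` -> (NeuriteProfile, truth): plateau signal
          covering a known fraction of the dendrite length.
    params : dict
        Truth values and rendering options; see defaults in code.
    seed : int
        Seeds the noise (and any placement randomness).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "cell_body_puncta":
        return _sim_cell_body_puncta(params, rng)
    if kind == "neurite_profile":
        return _sim_neurite_profile(params, rng)
    if kind == "dendrite_extent":
        return _sim_dendrite_extent(params, rng)
    raise ConfigurationError(f"unknown static image kind {kind!r}")


class GenerationError(RuntimeError):
    """Requested configuration cannot be placed (e.g. puncta packing)."""


def _sim_cell_body_puncta(params: dict, rng: np.random.Generator):
    shape = params.get("shape", (64, 64))
    n_puncta = params.get("n_puncta", 5)
    ratio = params.get("ratio", 3.0)
    cytosol = params.get("cytosol_level", 50.0)
    bg = params.get("background_level", 5.0)
    r_punct = params.get("punctum_radius_px", 2)
    min_sep = params.get("min_separation_px", 3 * (2 * r_punct + 1))
    noise = params.get("noise", False)
    read_sd = params.get("read_noise_sd", 2.0)

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_cell = params.get("cell_radius_px", min(h, w) // 2 - 2)
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_cell**2

    img = np.full(shape, bg, dtype=float)
    img[mask] = cytosol

    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < n_puncta:
        tries += 1
        if tries > 5000:
            raise GenerationError(
                f"cannot place {n_puncta} puncta with min separation {min_sep}px "
                f"inside a cell of radius {r_cell}px"
            )
        py = int(rng.integers(int(cy - 0.6 * r_cell), int(cy + 0.6 * r_cell) + 1))
        px_ = int(rng.integers(int(cx - 0.6 * r_cell), int(cx + 0.6 * r_cell) + 1))
        if any((py - y0) ** 2 + (px_ - x0) ** 2 < min_sep**2 for y0, x0 in centers):
            continue
        centers.append((py, px_))
    for py, px_ in centers:
        disk = (yy - py) ** 2 + (xx - px_) ** 2 <= r_punct**2
        img[disk] = ratio * cytosol
    if noise:
        img = rng.poisson(img).astype(float) + rng.normal(0, read_sd, img.shape)
        img = np.clip(img, 0, None)
    truth = {
        "n_puncta": len(centers),
        "centers": centers,
        "ratio": ratio,
        "cytosol_level": cytosol,
        "punctum_radius_px": r_punct,
    }
    return img, mask, truth


def _sim_neurite_profile(params: dict, rng: np.random.Generator):
    length_um = params.get("length_um", 120.0)
    px = params.get("pixel_size", 0.126)
    furthest_um = params.get("furthest_um", 30.0)
    n_puncta = params.get("n_puncta", 6)
    amplitude = params.get("amplitude", 120.0)
    bg = params.get("background_level", 10.0)
    sigma_um = params.get("punctum_sigma_um", 0.4)
    noise_sd = params.get("noise_sd", 3.0) if params.get("noise", True) else 0.0

    dist = np.arange(0.0, length_um, px)
    intensity = np.full(dist.shape, bg)
    if furthest_um > length_um:
        raise ConfigurationError("furthest_um exceeds the neurite length")
    pos = [furthest_um]
    if n_puncta > 1:
        pos.extend(rng.uniform(0.0, furthest_um, size=n_puncta - 1).tolist())
    for p in pos:
        intensity += amplitude * np.exp(-0.5 * ((dist - p) / sigma_um) ** 2)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0, noise_sd, dist.shape)
        intensity = np.clip(intensity, 0, None)
    profile = NeuriteProfile(
        distance_um=dist,
        intensity=intensity,
        background=(bg, max(noise_sd, 1e-9)),
    )
    truth = {"furthest_um": furthest_um, "punctum_positions_um": sorted(pos)}
    return profile, truth


def _sim_dendrite_extent(params: dict, rng: np.random.Generator):
    dendrite_um = params.get("dendrite_length_um", 40.0)
    tail_um = params.get("tail_um", 5.0)
    px = params.get("pixel_size", 0.126)
    fraction = params["extent_fraction"]
    signal = params.get("signal_level", 100.0)
    bg = params.get("background_level", 10.0)
    edge_sigma_px = params.get("edge_sigma_px", 1.0)
    noise_sd = params.get("noise_sd", 3.0) if params.get("noise", True) else 0.0

    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("extent_fraction must lie in [0, 1]")
    dist = np.arange(0.0, dendrite_um + tail_um, px)
    extent_um = fraction * dendrite_um
    intensity = np.where(dist <= extent_um, signal, bg).astype(float)
    if edge_sigma_px > 0 and 0.0 < fraction < 1.0:
        intensity = gaussian_filter1d(intensity, edge_sigma_px)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0, noise_sd, dist.shape)
        intensity = np.clip(intensity, 0, None)
    profile = NeuriteProfile(
        distance_um=dist,
        intensity=intensity,
        dendrite_span=(0.0, dendrite_um),
        background=(bg, max(noise_sd, 1e-9)),
    )
    truth = {"extent_fraction": fraction, "extent_um": extent_um, "extent_percent": 100 * fraction}
    return profile, truth


def simulate_dendrite_cohort(
    preset: str | tuple[float, float], n_animals: int = 20, seed: int = 0, **params
):
    """Generate a cohort of dendrite profiles matching reported statistics.

    The per-genotype extent values in the literature are cohort sample
    statistics (mean and SD over the imaged animals), so the cohort's truth
    extents are moment-matched stratified normal quantiles whose sample
    mean and SD equal the preset values exactly (before clipping to
    [1, 99.5]%), rather than an iid draw whose small-sample mean would
    wander. The seed permutes quantile assignment and drives pixel noise.

    Returns (profiles, truth DataFrame with one row per animal).
    """
    if isinstance(preset, str):
        if preset not in DENDRITE_PRESETS:
            raise ConfigurationError(
                f"unknown dendrite preset {preset!r}; choose from {sorted(DENDRITE_PRESETS)}"
            )
        mean_pct, sd_pct = DENDRITE_PRESETS[preset]
        label = preset
    else:
        mean_pct, sd_pct = preset
        label = "custom"
    if n_animals < 2:
        raise ConfigurationError("cohort needs at least 2 animals")

    rng = np.random.default_rng(seed)
    z = sstats.norm.ppf((np.arange(n_animals) + 0.5) / n_animals)
    z = (z - z.mean()) / z.std(ddof=1)  # exact sample moments
    extents = np.clip(mean_pct + sd_pct * z, 1.0, 99.5)
    rng.shuffle(extents)

    profiles, rows = [], []
    for i, pct in enumerate(extents):
        p = dict(params)
        p["extent_fraction"] = pct / 100.0
        profile, truth = simulate_static_image(
            "dendrite_extent", p, seed=int(rng.integers(0, 2**31 - 1))
        )
        profiles.append(profile)
        rows.append(
            {
                "animal": i,
                "preset": label,
                "truth_extent_percent": pct,
                "truth_extent_um": truth["extent_um"],
            }
        )
    return profiles, pd.DataFrame(rows)
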