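"""Synthetic single-cell populations, lineages and rendered cell images.

The generator emulates the statistical structure of fission-yeast C-CDK
biosensor experiments so that every downstream analysis stage can be tested
with ground truth in hand:

* steady-state populations with a configurable C-CDK level model — either
  concentration scaling with cell size, or size-independent induction
  sampled throughout the induction time course;
* a CDK-activity dose-response in which the effective half-activation level
  K_eff depends on cell length (size coupling), genotype (wild-type vs the
  tyrosine-phosphorylation-dead AF mutant, with or without PP2A) and
  DNA-per-volume (ploidy), evaluated either as a graded Hill curve or as
  bistable two-state switching with the same curve as switching probability;
* time-lapse lineages with linear length growth, size-proportional C-CDK
  accumulation, a size- and level-dependent division hazard, mitotic
  degradation of C-CDK, and a small probability of degradation without
  division;
* rendered multi-channel cell images (two brightfield exposures with
  independent texture, a translocation-biosensor channel and a uniform
  C-CDK level channel) for testing the quantification pipeline end to end.

All randomness flows from ``config.seed`` (or an explicit generator);
identical config + seed gives bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ConfigurationError, SizingError
from .lineage import (
    DEGRADATION,
    DEGRADATION_WITHOUT_DIVISION,
    DIVISION,
    LineageEvent,
    LineageTrace,
)
from .quantify import CellImage

__all__ = [
    "SizeDist",
    "LevelParams",
    "ResponseParams",
    "PloidyInhibition",
    "HazardParams",
    "ImagingParams",
    "SimConfig",
    "GENOTYPE_KEYS",
    "default_response_params",
    "effective_threshold",
    "graded_activity",
    "simulate_population",
    "simulate_lineages",
    "render_cell_image",
]

#: Reference cell length at which size coupling leaves K_eff unchanged.
REF_LENGTH_UM = 10.0

GENOTYPE_KEYS = ("WT", "WT_ppa2d", "AF", "AF_ppa2d")


@dataclass(frozen=True)
class SizeDist:
    """Distribution of cell length (µm): truncated normal, or uniform over
    [min, max] for designs that need equal occupancy of every size bin."""

    mean_length_um: float = 10.5
    sd_um: float = 2.0
    min_um: float = 7.0
    max_um: float = 16.0
    dist: str = "normal"


@dataclass(frozen=True)
class LevelParams:
    """C-CDK level model.

    ``size_scaled``: level = intercept + slope * length + noise, the
    steady-state scaling of C-CDK concentration with cell size.

    ``induction``: level = rate * (t - lag) + noise with the sampling time t
    drawn uniformly over the induction window, emulating sequential sampling
    of a tetracycline induction where expression is independent of size.
    """

    mode: str = "size_scaled"
    slope_au_per_um: float = 50.0
    intercept_au: float = 0.0
    rate_au_per_s: float = 0.25
    lag_s: float = 1000.0
    sample_window_s: float = 4000.0
    noise_sd_au: float = 25.0


@dataclass(frozen=True)
class ResponseParams:
    """Activity response of one genotype.

    ``k0_au`` is the half-activation C-CDK level at the reference length;
    size coupling lowers the effective threshold exponentially with length
    (∂log K / ∂length = -size_coupling_per_um).  In graded mode the activity
    is the Hill curve itself; in bistable mode the curve gives the
    probability of the 'on' state and activity is drawn from the on/off
    state distributions.
    """

    k0_au: float
    slope_h: float
    top: float = 10.0
    bottom: float = 0.5
    size_coupling_per_um: float = 0.0
    bistable: bool = False
    switch_noise_sd: float = 0.75
    activity_noise_sd: float = 0.3


def default_response_params() -> dict[str, ResponseParams]:
    """Per-genotype defaults.

    Wild type switches bistably at a high, strongly size-coupled threshold;
    deleting PP2A shifts the threshold down without reshaping the response;
    the AF mutant responds gradedly with a shallower slope, and AF PP2AΔ is
    the most permissive, nearly size-flat background.
    """
    return {
        "WT": ResponseParams(600.0, 6.0, 10.0, 0.5, 0.25, True, 0.75),
        "WT_ppa2d": ResponseParams(450.0, 6.0, 10.0, 0.5, 0.25, True, 0.75),
        "AF": ResponseParams(350.0, 2.5, 8.0, 0.5, 0.10, False, activity_noise_sd=1.25),
        "AF_ppa2d": ResponseParams(250.0, 1.8, 8.0, 0.5, 0.05, False, activity_noise_sd=1.25),
    }


@dataclass(frozen=True)
class PloidyInhibition:
    """Additive threshold term gamma * DNA-units / volume (AU).

    Implements titratable DNA-dependent inhibition: at large volume the
    extra threshold vanishes, so haploid/diploid responses converge.
    """

    gamma_au_fl: float = 25000.0
    dna_units: dict[int, float] = field(default_factory=lambda: {1: 1.0, 2: 2.0})


@dataclass(frozen=True)
class HazardParams:
    """Division hazard: rate = baseline * logistic(size) * logistic(level)."""

    baseline_per_min: float = 0.25
    size_half_um: float = 9.5
    level_half_au: float = 450.0
    size_sharpness_per_um: float = 2.0
    level_sharpness_per_au: float = 0.02


@dataclass(frozen=True)
class ImagingParams:
    pixel_size_um: float = 0.15
    psf_sigma_px: float = 1.0
    background_au: float = 10.0
    noise_sd_au: float = 1.5
    bf_texture_sd: float = 30.0
    bf_base: float = 100.0
    #: dark cell-wall rim shared by both brightfield exposures
    bf_wall_depth: float = 40.0
    bf_wall_sigma_px: float = 1.0
    cytoplasm_au: float = 100.0
    #: nucleus radius as a fraction of the cell radius
    nucleus_radius_frac: float = 0.5
    margin_px: int = 12


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_cells: int = 1000
    genotypes: tuple[str, ...] = ("WT",)
    ploidies: tuple[int, ...] = (1,)
    size_dist: SizeDist = field(default_factory=SizeDist)
    radius_um: dict[int, float] = field(default_factory=lambda: {1: 1.75, 2: 2.3})
    level: LevelParams = field(default_factory=LevelParams)
    response: dict[str, ResponseParams] = field(default_factory=default_response_params)
    ploidy_inhibition: PloidyInhibition = field(default_factory=PloidyInhibition)
    hazard: HazardParams = field(default_factory=HazardParams)
    frame_interval_min: float = 3.0
    #: probability that a triggered degradation event is not followed by
    #: division, calibrated to the observed 5% in the AF background
    skip_division_prob: float = 0.05
    growth_rate_um_per_min: float = 0.03
    level_accum_au_per_um_min: float = 1.0
    level_floor_au: float = 20.0
    lineage_level_noise_sd: float = 10.0
    imaging: ImagingParams = field(default_factory=ImagingParams)
    #: fractions of gating artefacts injected into simulated populations
    unfocused_frac: float = 0.0
    doublet_frac: float = 0.0

    def validate(self) -> None:
        sd = self.size_dist
        positives = {
            "size sd": sd.sd_um,
            "size min": sd.min_um,
            "size mean": sd.mean_length_um,
            "frame interval": self.frame_interval_min,
            "growth rate": self.growth_rate_um_per_min,
            "pixel size": self.imaging.pixel_size_um,
        }
        for name, v in positives.items():
            if not np.isfinite(v) or v <= 0:
                raise ConfigurationError(f"{name} must be finite and positive, got {v}")
        if not sd.min_um < sd.max_um:
            raise ConfigurationError("size min must be below size max")
        for name, p in {"skip_division_prob": self.skip_division_prob,
                        "unfocused_frac": self.unfocused_frac,
                        "doublet_frac": self.doublet_frac}.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        for g in self.genotypes:
            if g not in self.response:
                raise ConfigurationError(f"no response parameters for genotype {g!r}")
            rp = self.response[g]
            for v in (rp.k0_au, rp.slope_h, rp.top, rp.bottom,
                      rp.size_coupling_per_um, rp.switch_noise_sd):
                if not np.isfinite(v):
                    raise ConfigurationError(f"non-finite response parameter for {g!r}")
            if rp.k0_au <= 0 or rp.slope_h <= 0:
                raise ConfigurationError(f"k0 and slope_h must be positive for {g!r}")
        for p in self.ploidies:
            if p not in self.radius_um or p not in self.ploidy_inhibition.dna_units:
                raise ConfigurationError(f"missing radius or DNA units for ploidy {p}")


def _rng(config: SimConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def split_genotype(key: str) -> tuple[str, bool]:
    """Genotype key -> (WT/AF, PP2A present)."""
    base = key.split("_")[0]
    return base, not key.endswith("_ppa2d")


def effective_threshold(
    params: ResponseParams,
    length_um: np.ndarray | float,
    dna_per_volume: np.ndarray | float = 0.0,
    gamma_au_fl: float = 0.0,
) -> np.ndarray:
    """K_eff = K0 * exp(-coupling * (length - ref)) + gamma * DNA/volume."""
    length_um = np.asarray(length_um, dtype=float)
    return params.k0_au * np.exp(
        -params.size_coupling_per_um * (length_um - REF_LENGTH_UM)
    ) + gamma_au_fl * np.asarray(dna_per_volume, dtype=float)


def graded_activity(
    params: ResponseParams, level_au: np.ndarray | float, k_eff: np.ndarray | float
) -> np.ndarray:
    """Hill response: bottom + (top-bottom) / (1 + (K_eff/level)^h)."""
    level = np.maximum(np.asarray(level_au, dtype=float), 1e-12)
    frac = 1.0 / (1.0 + (np.asarray(k_eff, dtype=float) / level) ** params.slope_h)
    return params.bottom + (params.top - params.bottom) * frac


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Rejection-sampled truncated normal (deterministic under a fixed rng)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def _draw_lengths(rng: np.random.Generator, sd: SizeDist, n: int) -> np.ndarray:
    if sd.dist == "uniform":
        return rng.uniform(sd.min_um, sd.max_um, size=n)
    if sd.dist != "normal":
        raise ConfigurationError(f"unknown size distribution {sd.dist!r}")
    return _truncated_normal(rng, sd.mean_length_um, sd.sd_um, sd.min_um, sd.max_um, n)


def _draw_levels(
    config: SimConfig, rng: np.random.Generator, lengths: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (level_au, time_s) per cell under the configured level model."""
    lp = config.level
    n = len(lengths)
    if lp.mode == "size_scaled":
        level = lp.intercept_au + lp.slope_au_per_um * lengths
        times = np.zeros(n)
    elif lp.mode == "induction":
        times = lp.lag_s + rng.uniform(0.0, lp.sample_window_s, size=n)
        level = lp.rate_au_per_s * (times - lp.lag_s)
    else:
        raise ConfigurationError(f"unknown level mode {lp.mode!r}")
    level = level + rng.normal(0.0, lp.noise_sd_au, size=n)
    return np.maximum(level, 1.0), times


def simulate_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a steady-state population of single-cell records.

    Returns ``(records, truth)``; ``config.n_cells`` cells are drawn for
    every (genotype, ploidy) combination.  ``truth`` carries one row per
    record (matched on ``cell_id``) with the generating quantities: K_eff,
    the true activity, the on/off state and any injected gating artefacts.
    """
    config.validate()
    rng = _rng(config, rng)
    px2 = config.imaging.pixel_size_um**2
    rec_rows, truth_rows = [], []
    idx = 0
    for genotype in config.genotypes:
        rp = config.response[genotype]
        for ploidy in config.ploidies:
            n = config.n_cells
            radius = config.radius_um[ploidy]
            sd = config.size_dist
            lengths = _draw_lengths(rng, sd, n)
            volumes = np.pi * radius**2 * lengths
            dna_per_vol = config.ploidy_inhibition.dna_units[ploidy] / volumes
            level, times = _draw_levels(config, rng, lengths)
            k_eff = effective_threshold(
                rp, lengths, dna_per_vol, config.ploidy_inhibition.gamma_au_fl
            )
            if rp.bistable:
                p_on = 1.0 / (1.0 + (k_eff / level) ** rp.slope_h)
                on = rng.uniform(size=n) < p_on
                activity = rng.normal(
                    np.where(on, rp.top, rp.bottom), rp.switch_noise_sd
                )
            else:
                on = np.zeros(n, dtype=bool)
                activity = graded_activity(rp, level, k_eff) + rng.normal(
                    0.0, rp.activity_noise_sd, size=n
                )
            activity = np.maximum(activity, 0.01)

            focus = rng.normal(75.0, 3.0, size=n)
            unfocused = rng.uniform(size=n) < config.unfocused_frac
            focus[unfocused] = rng.normal(55.0, 4.0, size=int(unfocused.sum()))
            doublet = rng.uniform(size=n) < config.doublet_frac

            base, pp2a = split_genotype(genotype)
            area = (2.0 * radius * (lengths - 2.0 * radius) + np.pi * radius**2) / px2
            rec_len = np.where(doublet, 2.0 * lengths, lengths)
            rec_area = np.where(doublet, 2.0 * area, area)
            ids = [f"cell{idx + i:06d}" for i in range(n)]
            idx += n
            rec_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": ids,
                        "sample_id": f"{genotype}_p{ploidy}",
                        "time_s": times,
                        "genotype": base,
                        "pp2a": pp2a,
                        "ploidy": ploidy,
                        "length_um": rec_len,
                        "radius_um": radius,
                        "area_px2": rec_area,
                        "volume_fl": np.pi * radius**2 * rec_len,
                        "cdk_level_au": level,
                        "activity_nc": activity,
                        "focus_grad_rms": focus,
                        "gated": False,
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": ids,
                        "genotype_key": genotype,
                        "ploidy": ploidy,
                        "true_length_um": lengths,
                        "true_radius_um": radius,
                        "true_volume_fl": volumes,
                        "true_level_au": level,
                        "true_activity": activity,
                        "true_nc": activity,
                        "k_eff_au": k_eff,
                        "true_on": on,
                        "is_doublet": doublet,
                        "is_unfocused": unfocused,
                    }
                )
            )
    records = pd.concat(rec_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return records, truth


def simulate_lineages(
    config: SimConfig,
    n_lineages: int,
    duration_min: float,
    genotype: str = "AF",
    ploidy: int = 1,
    rng: np.random.Generator | None = None,
) -> list[LineageTrace]:
    """Simulate time-lapse traces with growth, degradation and division.

    Per frame: length grows linearly; C-CDK level accumulates in proportion
    to length (plus noise); the division hazard per minute is
    ``baseline * logistic(length) * logistic(level)`` and converts to a
    per-frame event probability ``1 - exp(-rate * dt)``.  At a triggered
    event the level drops to the degradation floor, and with probability
    ``1 - skip_division_prob`` the length halves (division); otherwise the
    cell keeps its size (degradation without division).  Ground-truth events
    are recorded on each trace.
    """
    config.validate()
    rng = _rng(config, rng)
    dt = config.frame_interval_min
    n_frames = int(round(duration_min / dt)) + 1
    if n_frames < 2:
        raise ConfigurationError("duration must cover at least 2 frames")
    rp = config.response[genotype]
    hz = config.hazard
    radius = config.radius_um[ploidy]
    sd = config.size_dist

    L = np.empty((n_lineages, n_frames))
    level = np.empty((n_lineages, n_frames))
    L[:, 0] = _draw_lengths(rng, sd, n_lineages)
    level[:, 0] = rng.uniform(config.level_floor_au, 300.0, size=n_lineages)
    events: list[list[LineageEvent]] = [[] for _ in range(n_lineages)]

    for t in range(1, n_frames):
        rate = (
            hz.baseline_per_min
            / (1.0 + np.exp(-hz.size_sharpness_per_um * (L[:, t - 1] - hz.size_half_um)))
            / (1.0 + np.exp(-hz.level_sharpness_per_au * (level[:, t - 1] - hz.level_half_au)))
        )
        fire = rng.uniform(size=n_lineages) < 1.0 - np.exp(-rate * dt)
        skip = rng.uniform(size=n_lineages) < config.skip_division_prob
        grow = L[:, t - 1] + config.growth_rate_um_per_min * dt
        accum = (
            level[:, t - 1]
            + config.level_accum_au_per_um_min * L[:, t - 1] * dt
            + rng.normal(0.0, config.lineage_level_noise_sd, size=n_lineages)
        )
        divide = fire & ~skip
        L[:, t] = np.where(divide, L[:, t - 1] / 2.0, grow)
        level[:, t] = np.where(fire, config.level_floor_au, np.maximum(accum, 1.0))
        for i in np.nonzero(fire)[0]:
            events[i].append(LineageEvent(t, DEGRADATION))
            events[i].append(
                LineageEvent(t, DIVISION if divide[i] else DEGRADATION_WITHOUT_DIVISION)
            )

    volumes = np.pi * radius**2 * L
    dna_per_vol = config.ploidy_inhibition.dna_units[ploidy] / volumes
    k_eff = effective_threshold(rp, L, dna_per_vol, config.ploidy_inhibition.gamma_au_fl)
    activity = graded_activity(rp, level, k_eff)

    times = np.arange(n_frames) * dt
    traces = []
    for i in range(n_lineages):
        frames = pd.DataFrame(
            {
                "time_min": times,
                "size": L[i],
                "level": level[i],
                "activity": activity[i],
            }
        )
        traces.append(
            LineageTrace(
                cell_id=f"lin{i:05d}",
                frames=frames,
                frame_interval_min=dt,
                events=events[i],
            )
        )
    return traces


def render_cell_image(
    truth_row,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    cell_id: str | None = None,
) -> CellImage:
    """Render one cell as a multi-channel image from its ground truth.

    The cell is a horizontal rod (rectangle with semicircular caps) of the
    true length and radius; the nucleus is a disc at the cell mid-point.
    The biosensor channel has cytoplasmic intensity c and nuclear intensity
    c * (true N/C); the level channel is uniform at the true level inside
    the mask.  The two brightfield renderings share the cell outline but
    carry independent texture noise, so the pixelwise standard deviation
    across the pair is elevated inside the cell.  All channels are blurred
    with the PSF sigma, then given additive background and read noise.
    """
    rng = _rng(config, rng)
    im = config.imaging
    px = im.pixel_size_um
    length_px = float(truth_row["true_length_um"]) / px
    radius_px = float(truth_row["true_radius_um"]) / px
    nc = float(truth_row["true_nc"])
    level = float(truth_row["true_level_au"])

    margin = im.margin_px
    if margin < 3:
        raise SizingError("margin must leave at least 3 px around the cell")
    W = int(np.ceil(length_px)) + 2 * margin
    H = int(np.ceil(2 * radius_px)) + 2 * margin
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    half_core = length_px / 2.0 - radius_px
    if half_core < 0:
        raise SizingError("cell length below its diameter")
    dx = np.maximum(np.abs(xx - cx) - half_core, 0.0)
    dist = np.hypot(dx, yy - cy)
    mask = dist <= radius_px
    nucleus = np.hypot(xx - cx, yy - cy) <= im.nucleus_radius_frac * radius_px

    bios = im.cytoplasm_au * mask.astype(float)
    bios[nucleus & mask] = im.cytoplasm_au * nc
    level_ch = level * mask.astype(float)
    # dark cell-wall rim: deterministic, shared by both exposures (it is the
    # shared outline), so it cancels in the pair difference; the independent
    # texture inside the cell is what elevates the pair stdev
    wall = im.bf_wall_depth * np.exp(
        -((dist - radius_px) ** 2) / (2.0 * im.bf_wall_sigma_px**2)
    )
    bf1 = im.bf_base - wall + rng.normal(0.0, im.bf_texture_sd, size=(H, W)) * mask
    bf2 = im.bf_base - wall + rng.normal(0.0, im.bf_texture_sd, size=(H, W)) * mask

    def _finish(ch: np.ndarray, background: float) -> np.ndarray:
        if im.psf_sigma_px > 0:
            ch = ndi.gaussian_filter(ch, im.psf_sigma_px)
        out = ch + background
        if im.noise_sd_au > 0:
            out = out + rng.normal(0.0, im.noise_sd_au, size=ch.shape)
        return out

    return CellImage(
        bf1=_finish(bf1, 0.0),
        bf2=_finish(bf2, 0.0),
        channels={
            "biosensor": _finish(bios, im.background_au),
            "level": _finish(level_ch, im.background_au),
        },
        pixel_size_um=px,
        cell_id=cell_id if cell_id is not None else str(truth_row.get("cell_id", "")),
    )
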