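"""Digital bowel-wall phantom with known ground truth.

Emulates the quantitative part of a stricture MR-enterography exam: an
annular bowel wall around a gas-filled lumen, imaged with a 16-echo
T2*-weighted acquisition and an 18-b-value diffusion acquisition, with
Rician magnitude noise, optional per-frame translational motion and a rim
of short-T2* gas-transition voxels along the lumen.  Every voxel's true
tissue parameters are returned alongside the simulated series so each
downstream stage can be tested against ground truth.

Geometry is a single axial annulus replicated along z (a thin slab),
matching the study convention of single-slice bowel-wall regions of
interest.  The phantom does not model k-space, coils, or susceptibility
fields: the gas artifact is a T2*-value perturbation of rim voxels, not a
field simulation, and motion is an integer-voxel in-plane translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ivim import DiffusionSeries
from .t2star import EchoSeries

__all__ = [
    "ECHO_TIMES_MS",
    "B_SCHEME",
    "expand_b_scheme",
    "TissueParams",
    "PhantomSpec",
    "GroundTruth",
    "INFLAMMATORY_PARAMS",
    "NONINFLAMMATORY_PARAMS",
    "t2star_signal",
    "ivim_signal",
    "add_rician_noise",
    "make_phantom",
    "estimate_noise_sigma",
]

#: The 16 echo times (ms) of the multi-echo spoiled gradient-echo protocol.
ECHO_TIMES_MS = np.array([
    2.0, 5.1, 8.3, 11.4, 14.6, 17.7, 20.8, 24.0,
    27.1, 30.3, 33.4, 36.5, 39.7, 42.8, 46.0, 49.1,
])

#: The 18 diffusion weightings (s/mm^2) with their number of averages; the
#: generator emits every average as a separate frame (60 frames in total).
B_SCHEME: tuple[tuple[float, int], ...] = (
    (0, 9), (1, 3), (2, 3), (5, 3), (10, 3), (20, 3), (30, 3), (40, 3),
    (50, 3), (75, 3), (100, 3), (150, 3), (200, 3), (300, 3), (400, 3),
    (500, 3), (600, 3), (700, 3),
)


def expand_b_scheme(
    scheme: tuple[tuple[float, int], ...] = B_SCHEME,
) -> np.ndarray:
    """Expand a (b, n_averages) scheme into one b-value per frame."""
    return np.array([b for b, reps in scheme for _ in range(reps)], float)


class InvalidParameterError(ValueError):
    """A tissue-parameter value outside its physical domain."""


@dataclass(frozen=True)
class TissueParams:
    """True tissue parameters of one phantom compartment.

    t2star : ms; s0 : a.u.; d, d_star : mm^2/s; f : dimensionless.
    """

    t2star: float
    s0: float
    d: float
    d_star: float
    f: float

    def __post_init__(self) -> None:
        if not self.t2star > 0:
            raise InvalidParameterError(f"t2star must be > 0, got {self.t2star}")
        if not self.s0 > 0:
            raise InvalidParameterError(f"s0 must be > 0, got {self.s0}")
        if not 0 <= self.d < self.d_star:
            raise InvalidParameterError(
                f"need 0 <= d < d_star, got d={self.d}, d_star={self.d_star}"
            )
        if not 0 <= self.f <= 1:
            raise InvalidParameterError(f"f must be in [0, 1], got {self.f}")


#: Reference tissue values at the reported bowel-wall group medians.
INFLAMMATORY_PARAMS = TissueParams(t2star=25.4, s0=100.0,
                                   d=0.0012, d_star=0.06, f=0.15)
NONINFLAMMATORY_PARAMS = TissueParams(t2star=18.6, s0=100.0,
                                      d=0.0014, d_star=0.06, f=0.18)

PHENOTYPES = ("inflammatory", "mixed", "chronic")


@dataclass
class PhantomSpec:
    """Recipe for one simulated stricture acquisition.

    sections is a list of ``(section_id, phenotype, TissueParams)``; with
    more than one section the annulus is partitioned into equal angular
    wedges, one per section.  ``snr`` is the wall-tissue S0 divided by the
    Gaussian channel sigma at the shortest TE / b=0 (``inf`` = noiseless).
    ``motion_shifts`` are per-frame integer in-plane translations (cycled
    over frames).  ``gas_rim_fraction`` of the wall voxels bordering the
    lumen get their T2* replaced by ``gas_t2star`` (ms), emulating the
    gas-tissue transition artifact.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 3)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.3)
    lumen_radius: float = 6.0
    wall_thickness: float = 6.0
    sections: tuple = (
        (1, "inflammatory", INFLAMMATORY_PARAMS),
        (2, "chronic", NONINFLAMMATORY_PARAMS),
    )
    background_params: TissueParams | None = None
    snr: float = np.inf
    motion_shifts: np.ndarray | None = None
    gas_rim_fraction: float = 0.0
    gas_t2star: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gas_rim_fraction <= 1:
            raise ValueError("gas_rim_fraction must be in [0, 1]")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if not self.sections:
            raise ValueError("need at least one section")
        for sid, phen, params in self.sections:
            if phen not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {phen!r} in section {sid}")
            if not isinstance(params, TissueParams):
                raise TypeError("section params must be TissueParams")
        nx, ny, _ = self.grid_shape
        dx, dy, _ = self.voxel_spacing
        r_out = self.lumen_radius + self.wall_thickness
        if r_out >= min(nx * dx, ny * dy) / 2:
            raise ValueError(
                f"outer wall radius {r_out} mm exceeds the grid half-extent"
            )


@dataclass
class GroundTruth:
    """True parameter maps and masks underlying a simulated acquisition."""

    maps: dict[str, np.ndarray]
    wall_mask: np.ndarray
    artifact_mask: np.ndarray
    section_id_map: np.ndarray          # int, -1 outside the wall
    sections: pd.DataFrame = field(repr=False)


def t2star_signal(params: TissueParams, echo_times) -> np.ndarray:
    """Noiseless monoexponential echo train ``S0 * exp(-TE/T2*)``."""
    te = np.atleast_1d(np.asarray(echo_times, dtype=float))
    if np.any(te < 0):
        raise ValueError("echo times must be non-negative")
    if te.size > 1 and np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    return params.s0 * np.exp(-te / params.t2star)


def ivim_signal(params: TissueParams, b_values) -> np.ndarray:
    """Noiseless biexponential IVIM decay.

    ``S(b) = S0 * [f exp(-b D*) + (1-f) exp(-b D)]`` with D* as the full
    pseudo-decay rate.
    """
    b = np.atleast_1d(np.asarray(b_values, dtype=float))
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return params.s0 * (
        params.f * np.exp(-b * params.d_star)
        + (1.0 - params.f) * np.exp(-b * params.d)
    )


def add_rician_noise(signal: np.ndarray, sigma: float, seed=0) -> np.ndarray:
    """Apply Rician magnitude noise: ``|S + n1 + i*n2|`` with iid N(0, sigma).

    ``seed`` may be an integer or a ``numpy.random.Generator``; sigma = 0
    returns the input unchanged (as a float copy).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(signal + n1, n2)


def _annulus_geometry(spec: PhantomSpec):
    """In-plane lumen/wall masks and per-voxel wedge (section) ids."""
    nx, ny, nz = spec.grid_shape
    dx, dy, _ = spec.voxel_spacing
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    y = (np.arange(ny) - (ny - 1) / 2) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    r = np.hypot(xx, yy)
    lumen2d = r < spec.lumen_radius
    wall2d = (r >= spec.lumen_radius) & \
        (r < spec.lumen_radius + spec.wall_thickness)
    theta = np.arctan2(yy, xx)  # [-pi, pi)
    edges = np.linspace(-np.pi, np.pi, len(spec.sections) + 1)
    wedge = np.clip(np.digitize(theta, edges) - 1, 0, len(spec.sections) - 1)
    rep = lambda m: np.repeat(m[:, :, None], nz, axis=2)
    return rep(lumen2d), rep(wall2d), rep(wedge)


def _gas_rim(wall: np.ndarray, lumen: np.ndarray, fraction: float,
             rng: np.random.Generator) -> np.ndarray:
    """Pick ``fraction`` of the wall voxels 4-adjacent to the lumen."""
    rim = np.zeros_like(wall)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        rim |= np.roll(lumen, shift, axis=axis)
    rim &= wall
    idx = np.flatnonzero(rim)
    n_pick = int(round(fraction * idx.size))
    picked = rng.choice(idx, size=n_pick, replace=False) if n_pick else []
    mask = np.zeros(wall.size, dtype=bool)
    mask[np.sort(np.asarray(picked, dtype=int))] = True
    return mask.reshape(wall.shape)


def _apply_motion(volume: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    out = volume.copy()
    for i in range(volume.shape[3]):
        sx, sy = shifts[i % len(shifts)]
        out[..., i] = np.roll(out[..., i], (int(sx), int(sy)), axis=(0, 1))
    return out


def make_phantom(
    spec: PhantomSpec,
) -> tuple[EchoSeries, DiffusionSeries, GroundTruth]:
    """Simulate one stricture acquisition from a phantom recipe.

    Returns the multi-echo series (16 echoes), the diffusion series (60
    frames, every average a separate frame) and the ground truth.  With
    ``snr = inf`` and no motion the voxel signals equal the analytic decay
    models exactly; identical spec + seed gives bit-identical output.
    """
    lumen, wall, wedge = _annulus_geometry(spec)
    ss = np.random.SeedSequence(spec.seed)
    rng_gas, rng_echo, rng_dwi = (np.random.default_rng(s)
                                  for s in ss.spawn(3))
    artifact = _gas_rim(wall, lumen, spec.gas_rim_fraction, rng_gas)

    section_id_map = np.full(spec.grid_shape, -1, dtype=int)
    section_id_map[wall] = 0
    field_names = ("t2star", "s0", "d", "d_star", "f")
    true_maps = {name: np.full(spec.grid_shape, np.nan) for name in field_names}
    sig_maps = {name: np.zeros(spec.grid_shape) for name in field_names}
    rows = []
    for i, (sid, phen, params) in enumerate(spec.sections):
        sel = wall & (wedge == i)
        section_id_map[sel] = sid
        for name in field_names:
            true_maps[name][sel] = getattr(params, name)
            sig_maps[name][sel] = getattr(params, name)
        rows.append({"section_id": sid, "phenotype": phen,
                     **{name: getattr(params, name) for name in field_names}})
    # Gas-tissue transition rim: a short-T2* perturbation of the true map.
    true_maps["t2star"][artifact] = spec.gas_t2star
    sig_maps["t2star"][artifact] = spec.gas_t2star
    if spec.background_params is not None:
        bg = ~wall & ~lumen
        for name in field_names:
            sig_maps[name][bg] = getattr(spec.background_params, name)

    tissue = sig_maps["s0"] > 0
    t2 = np.where(tissue, sig_maps["t2star"], 1.0)
    echo_vol = np.where(
        tissue[..., None],
        sig_maps["s0"][..., None] * np.exp(-ECHO_TIMES_MS / t2[..., None]),
        0.0,
    )
    b = expand_b_scheme()
    d = sig_maps["d"][..., None]
    d_star = np.where(tissue, sig_maps["d_star"], 1.0)[..., None]
    f = sig_maps["f"][..., None]
    dwi_vol = np.where(
        tissue[..., None],
        sig_maps["s0"][..., None]
        * (f * np.exp(-b * d_star) + (1.0 - f) * np.exp(-b * d)),
        0.0,
    )

    if spec.motion_shifts is not None:
        shifts = np.atleast_2d(np.asarray(spec.motion_shifts, dtype=int))
        echo_vol = _apply_motion(echo_vol, shifts)
        dwi_vol = _apply_motion(dwi_vol, shifts)

    if np.isfinite(spec.snr):
        sigma = float(np.mean([p.s0 for _, _, p in spec.sections])) / spec.snr
        echo_vol = add_rician_noise(echo_vol, sigma, rng_echo)
        dwi_vol = add_rician_noise(dwi_vol, sigma, rng_dwi)

    truth = GroundTruth(
        maps=true_maps,
        wall_mask=wall,
        artifact_mask=artifact,
        section_id_map=section_id_map,
        sections=pd.DataFrame(rows),
    )
    echo = EchoSeries(echo_vol, ECHO_TIMES_MS.copy(), spec.voxel_spacing)
    dwi = DiffusionSeries(dwi_vol, b, spec.voxel_spacing)
    return echo, dwi, truth


def estimate_noise_sigma(volume: np.ndarray, air_mask: np.ndarray) -> float:
    """Estimate the Gaussian channel sigma from signal-free (air) voxels.

    Over air the magnitude is Rayleigh distributed with ``E[M^2] = 2 sigma^2``,
    so the second-moment estimator ``sqrt(mean(M^2) / 2)`` is used, pooling
    all frames of a 4D volume.
    """
    air_mask = np.asarray(air_mask, dtype=bool)
    samples = np.asarray(volume, dtype=float)[air_mask]
    if samples.size == 0:
        raise ValueError("air mask selects no voxels")
    return float(np.sqrt(np.mean(samples ** 2) / 2.0))
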