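"""Segmented biexponential IVIM fitting.

Intravoxel incoherent motion (IVIM) separates the diffusion-weighted signal
decay into a slow tissue-diffusion compartment and a fast pseudodiffusion
compartment attributed to capillary perfusion:

    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ]

with the tissue diffusion coefficient D and the pseudodiffusion coefficient
D* in mm^2/s and the perfusion fraction f dimensionless.  D* is the full
decay rate of the pseudodiffusion term (not an increment on top of D).

The segmented fit estimates the parameters in three deterministic steps:

1. a log-linear monoexponential fit over the high-b frames
   (``b >= cutoff``), where the pseudodiffusion term has fully decayed,
   gives D and the extrapolated intercept A;
2. ``f = clamp(1 - A / mean S(b=0), 0, 1)``;
3. with D and f held fixed, a bounded 1-D least-squares search over all
   frames gives D*; ``S0`` is the mean b=0 signal.

When the pseudodiffusion decay is slow (D* near 0.02 mm^2/s) its tail has
not fully vanished at the cutoff and contaminates step 1, biasing D and f
by a few percent.  The fit therefore runs one refinement pass by default:
the estimated pseudodiffusion signal is subtracted and steps 1-3 repeat on
the corrected signal.  This keeps the deterministic segmented structure
(D* is still a 1-D problem, never a joint refit) while removing the
contamination to well below the estimator's noise floor.

Voxels with a negligible perfusion fraction have an undefined
pseudodiffusion coefficient; :func:`filter_perfusion_voxels` drops them
before any D* statistics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .t2star import ParameterMap

logger = logging.getLogger(__name__)

#: Default b-value (s/mm^2) above which the pseudodiffusion term is treated
#: as fully decayed.  At a typical bowel-wall D* of 0.06 mm^2/s the pseudo
#: term has decayed by exp(-12) at b = 200.
DEFAULT_CUTOFF: float = 200.0

#: Fit bounds, bracketing the plausible bowel-wall range with wide margins.
D_BOUNDS: tuple[float, float] = (1e-5, 5e-3)        # mm^2/s
D_STAR_BOUNDS: tuple[float, float] = (5e-3, 0.5)    # mm^2/s

#: Default perfusion-fraction threshold below which D* is considered
#: undefined (strictly smaller values are excluded; f == f_min is kept).
DEFAULT_F_MIN: float = 0.001


@dataclass
class DiffusionSeries:
    """A 4D magnitude stack with one diffusion weighting per frame.

    ``b_values`` may contain repeats: the acquisition scheme lists several
    averages per b-value and each average arrives as its own frame.
    """

    volume: np.ndarray
    b_values: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.volume.ndim != 4:
            raise ValueError(f"volume must be 4D, got {self.volume.ndim}D")
        if self.b_values.ndim != 1 or len(self.b_values) != self.volume.shape[3]:
            raise ValueError(
                f"{len(self.b_values)} b-values for "
                f"{self.volume.shape[3]} frames"
            )
        if np.any(self.b_values < 0):
            raise ValueError("b-values must be non-negative")
        if not np.any(self.b_values == 0):
            raise ValueError("series must contain at least one b=0 frame")
        if np.any(self.volume < 0):
            raise ValueError("magnitude volume must be non-negative")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volume.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.volume.shape[3]


def average_repeats(series: DiffusionSeries) -> DiffusionSeries:
    """Collapse repeated b-values to their arithmetic frame mean.

    The returned series has one frame per distinct b-value, in order of
    first appearance.  How the scanner combined its repeats is not knowable
    from magnitude exports, so this is an explicit, optional preprocessing
    step rather than a default.
    """
    _, first_idx = np.unique(series.b_values, return_index=True)
    order = np.sort(first_idx)
    unique_b = series.b_values[order]
    frames = [
        series.volume[..., series.b_values == b].mean(axis=3) for b in unique_b
    ]
    return DiffusionSeries(
        volume=np.stack(frames, axis=3),
        b_values=unique_b,
        voxel_spacing=series.voxel_spacing,
    )


def _loglinear(b: np.ndarray, log_s: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of log-signal against b."""
    bm, lm = b.mean(), log_s.mean()
    db = b - bm
    slope = float(db @ (log_s - lm)) / float(db @ db)
    return slope, float(lm - slope * bm)


def fit_ivim_segmented_voxel(
    signal: np.ndarray,
    b_values: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    d_bounds: tuple[float, float] = D_BOUNDS,
    d_star_bounds: tuple[float, float] = D_STAR_BOUNDS,
    n_refine: int = 1,
) -> tuple[float, float, float, float, bool]:
    """Segmented IVIM fit for one voxel.

    ``n_refine`` pseudodiffusion-subtraction passes follow the initial
    segmented fit (0 = the plain two-stage algorithm).  Returns
    ``(d, f, d_star, s0, fit_ok)``; NaNs with ``fit_ok=False`` when the
    voxel's signal cannot support the fit (non-positive high-b signal or
    non-positive b=0 mean).
    """
    signal = np.asarray(signal, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if signal.shape != b_values.shape:
        raise ValueError(
            f"signal length {signal.size} != b-value count {b_values.size}"
        )
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    high = b_values >= cutoff
    if len(np.unique(b_values[high])) < 2:
        raise ValueError(
            f"need at least 2 distinct b-values >= cutoff ({cutoff}); "
            f"got {np.unique(b_values[high])}"
        )
    b0 = b_values == 0
    if not b0.any():
        raise ValueError("no b=0 frame")

    nan_out = (np.nan, np.nan, np.nan, np.nan, False)
    s0 = float(signal[b0].mean())
    if s0 <= 0:
        return nan_out

    result = None
    pseudo = np.zeros_like(signal)
    for _ in range(1 + max(0, n_refine)):
        corrected = signal - pseudo
        # Step 1: log-linear monoexponential fit over the high-b frames.
        pos = high & (corrected > 0)
        if len(np.unique(b_values[pos])) < 2:
            break
        slope, intercept = _loglinear(b_values[pos],
                                      np.log(corrected[pos]))
        d = float(np.clip(-slope, *d_bounds))
        a = float(np.exp(intercept))

        # Step 2: perfusion fraction from the intercept ratio.
        f = float(np.clip(1.0 - a / s0, 0.0, 1.0))

        # Step 3: bounded 1-D fit of D* over all frames with D, f fixed.
        tissue = (1.0 - f) * np.exp(-b_values * d)

        def sse(d_star: float) -> float:
            r = signal - s0 * (f * np.exp(-b_values * d_star) + tissue)
            return float(r @ r)

        res = minimize_scalar(
            sse, bounds=d_star_bounds, method="bounded",
            options={"xatol": 1e-10, "maxiter": 500},
        )
        if not res.success or not np.isfinite(res.x):
            break
        result = (d, f, float(res.x), s0, True)
        pseudo = s0 * f * np.exp(-b_values * result[2])
    return result if result is not None else nan_out


def fit_ivim_map(
    series: DiffusionSeries,
    mask: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    collapse_repeats: bool = False,
) -> tuple[dict[str, ParameterMap], int]:
    """Voxel-wise segmented IVIM fit over a mask.

    Returns a dict of ParameterMaps keyed ``d``, ``f``, ``d_star``, ``s0``
    plus the count of masked voxels whose fit failed (NaN in all maps).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ValueError(
            f"mask shape {mask.shape} != series grid {series.grid_shape}"
        )
    if not mask.any():
        raise ValueError("mask is empty")
    if collapse_repeats:
        series = average_repeats(series)

    out = {name: np.full(series.grid_shape, np.nan)
           for name in ("d", "f", "d_star", "s0")}
    signals = series.volume[mask]
    flat = {name: np.full(signals.shape[0], np.nan) for name in out}
    n_failed = 0
    for i in range(signals.shape[0]):
        d, f, d_star, s0, ok = fit_ivim_segmented_voxel(
            signals[i], series.b_values, cutoff
        )
        if ok:
            flat["d"][i], flat["f"][i] = d, f
            flat["d_star"][i], flat["s0"][i] = d_star, s0
        else:
            n_failed += 1
    for name in out:
        out[name][mask] = flat[name]
    if n_failed:
        logger.info("IVIM fit failed in %d of %d masked voxels",
                    n_failed, signals.shape[0])
    units = {"d": "mm^2/s", "f": "dimensionless",
             "d_star": "mm^2/s", "s0": "a.u."}
    spacing = series.voxel_spacing
    maps = {name: ParameterMap(name, out[name], units[name], spacing)
            for name in out}
    return maps, n_failed


def filter_perfusion_voxels(
    f_map: ParameterMap,
    d_star_map: ParameterMap,
    f_min: float = DEFAULT_F_MIN,
) -> tuple[np.ndarray, int]:
    """Drop D* values from voxels whose perfusion fraction is negligible.

    The pseudodiffusion coefficient is undefined where the perfusion
    compartment carries (essentially) no signal.  Voxels with ``f < f_min``
    are excluded (strict inequality: ``f == f_min`` is kept); the returned
    array holds the surviving finite D* values and the count is the number
    of voxels removed by the threshold.
    """
    if f_map.volume.shape != d_star_map.volume.shape:
        raise ValueError(
            f"f map shape {f_map.volume.shape} != "
            f"D* map shape {d_star_map.volume.shape}"
        )
    f = f_map.volume
    d_star = d_star_map.volume
    valid = np.isfinite(f) & np.isfinite(d_star)
    keep = valid & (f >= f_min)
    excluded = int(np.count_nonzero(valid & (f < f_min)))
    values = d_star[keep]
    if values.size == 0:
        logger.warning(
            "no voxels survive the perfusion-fraction filter (f_min=%g); "
            "D* summary will be undefined", f_min,
        )
    return values, excluded


def mask_low_perfusion(
    f_map: ParameterMap,
    d_star_map: ParameterMap,
    f_min: float = DEFAULT_F_MIN,
) -> ParameterMap:
    """Return a copy of the D* map with low-perfusion voxels set to NaN."""
    if f_map.volume.shape != d_star_map.volume.shape:
        raise ValueError("f map and D* map are on different grids")
    vol = d_star_map.volume.copy()
    vol[np.isfinite(f_map.volume) & (f_map.volume < f_min)] = np.nan
    return ParameterMap("d_star", vol, d_star_map.units,
                        d_star_map.voxel_spacing)
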