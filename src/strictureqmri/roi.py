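"""Per-section ROI aggregation under the study's exclusion rules.

A stricture section is analysed on a bowel-wall mask from which artifact
zones (gas-tissue transitions, metal) are subtracted.  Parameter values are
summarised per section by their median and interquartile range — the median
being robust to the outliers that partial voluming, noise and residual
motion leave in voxel-wise maps.  Sections whose effective mask (wall minus
artifact) is empty, or whose map holds no finite value, are excluded with a
recorded reason rather than raising, mirroring the exclusion-then-aggregate
bookkeeping of a clinical reading session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .t2star import ParameterMap

logger = logging.getLogger(__name__)

#: Histopathological grouping rule: predominantly inflammatory and mixed
#: sections are pooled as "inflammatory"; predominantly chronic sections
#: form the "noninflammatory" group.
PHENOTYPE_GROUPS = {
    "inflammatory": "inflammatory",
    "mixed": "inflammatory",
    "chronic": "noninflammatory",
}


@dataclass
class ROISet:
    """Bowel-wall mask plus artifact mask on one grid."""

    wall_mask: np.ndarray
    artifact_mask: np.ndarray | None = None
    shifts: np.ndarray | None = None    # optional per-frame adjustments

    def __post_init__(self) -> None:
        self.wall_mask = np.asarray(self.wall_mask, dtype=bool)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros_like(self.wall_mask)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != self.wall_mask.shape:
            raise ValueError(
                f"artifact mask shape {self.artifact_mask.shape} != "
                f"wall mask shape {self.wall_mask.shape}"
            )


def effective_mask(roi: ROISet) -> tuple[np.ndarray, int]:
    """Wall minus artifact, plus the number of wall voxels subtracted."""
    eff = roi.wall_mask & ~roi.artifact_mask
    removed = int(np.count_nonzero(roi.wall_mask & roi.artifact_mask))
    return eff, removed


def aggregate_section(
    pmap: ParameterMap,
    roi: ROISet,
    section_id,
    **metadata,
) -> dict:
    """Summarise one parameter map over one section's effective ROI.

    Returns a record dict with the median, 25th/75th percentiles (linear
    interpolation between order statistics), voxel count and volume in mm^3.
    NaN voxels (failed fits, filtered D*) are dropped before aggregation;
    a section with an empty effective mask or no finite value is returned
    flagged ``excluded`` with a reason instead of raising.
    """
    if roi.wall_mask.shape != pmap.volume.shape:
        raise ValueError(
            f"ROI grid {roi.wall_mask.shape} != map grid {pmap.volume.shape}"
        )
    rec = {
        "section_id": section_id,
        "parameter": pmap.name,
        **metadata,
        "median": np.nan,
        "p25": np.nan,
        "p75": np.nan,
        "n_voxels": 0,
        "volume_mm3": 0.0,
        "excluded": False,
        "exclusion_reason": "",
    }
    eff, removed = effective_mask(roi)
    rec["n_artifact_removed"] = removed
    if not eff.any():
        rec["excluded"] = True
        rec["exclusion_reason"] = "artifact-obscured"
        logger.warning("section %s excluded: artifact obscures the ROI",
                       section_id)
        return rec
    values = pmap.volume[eff]
    finite = values[np.isfinite(values)]
    n_dropped = values.size - finite.size
    if n_dropped:
        logger.info("section %s/%s: dropped %d NaN voxels before aggregation",
                    section_id, pmap.name, n_dropped)
    if finite.size == 0:
        rec["excluded"] = True
        rec["exclusion_reason"] = "no-valid-voxels"
        logger.warning("section %s excluded: no finite %s values",
                       section_id, pmap.name)
        return rec
    rec["median"] = float(np.median(finite))
    rec["p25"], rec["p75"] = (
        float(v) for v in np.percentile(finite, [25, 75], method="linear")
    )
    rec["n_voxels"] = int(finite.size)
    rec["volume_mm3"] = float(finite.size * pmap.voxel_volume_mm3)
    return rec


def group_sections(
    records: pd.DataFrame,
    phenotype_col: str = "phenotype",
) -> pd.DataFrame:
    """Attach the inflammatory/noninflammatory group label to each record."""
    records = records.copy()
    unknown = ~records[phenotype_col].isin(PHENOTYPE_GROUPS)
    if unknown.any():
        idx = records.index[unknown][0]
        raise ValueError(
            f"row {idx}: unknown phenotype "
            f"{records.loc[idx, phenotype_col]!r} "
            f"(expected one of {sorted(PHENOTYPE_GROUPS)})"
        )
    records["group"] = records[phenotype_col].map(PHENOTYPE_GROUPS)
    return records


def align_series(volume: np.ndarray, reference: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and undo per-frame integer in-plane translations.

    For each frame of a 4D series the integer (dx, dy) shift maximising the
    circular cross-correlation with the reference frame is estimated via
    FFT; the inverse shift is applied so all frames align with the
    reference.  Returns the aligned series and the estimated motion shifts,
    one (dx, dy) row per frame.  A degenerate (constant) frame gets a zero
    shift with a warning.

    This is a deliberately simple translational stand-in for deformable
    registration: the phantom's motion model is integer translation, and
    the alignment only needs to restore mask validity.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("expected a 4D series")
    nx, ny = volume.shape[:2]
    ref = volume[..., reference]
    f_ref = np.fft.fft2(ref, axes=(0, 1))
    aligned = volume.copy()
    shifts = np.zeros((volume.shape[3], 2), dtype=int)
    for i in range(volume.shape[3]):
        frame = volume[..., i]
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            logger.warning("frame %d is constant; assuming zero shift", i)
            continue
        f_frame = np.fft.fft2(frame, axes=(0, 1))
        corr = np.fft.ifft2(f_frame * np.conj(f_ref), axes=(0, 1)).real
        corr2d = corr.sum(axis=2)
        dx, dy = np.unravel_index(np.argmax(corr2d), corr2d.shape)
        if dx > nx // 2:
            dx -= nx
        if dy > ny // 2:
            dy -= ny
        shifts[i] = (dx, dy)
        aligned[..., i] = np.roll(frame, (-dx, -dy), axis=(0, 1))
    return aligned, shifts


def tabulate_exclusions(records: pd.DataFrame) -> dict:
    """Summarise the in/analysed/excluded accounting of a record table."""
    excluded = records[records["excluded"]]
    return {
        "records_in": int(len(records)),
        "records_analyzed": int(len(records) - len(excluded)),
        "records_excluded": int(len(excluded)),
        "reasons": excluded.groupby("exclusion_reason").size().to_dict(),
    }
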