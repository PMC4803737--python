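"""Grasp classification from glove goniometers (+ optional index-finger force).

Eight canonical functional hand grips are recognized from the three glove
goniometer angles (thumb, index, middle), optionally augmented with the
index-finger force sensor reading.  Each grip is summarized by a *pose
template* — per-dimension mean and SD over repeated acquisitions — and a
measurement x is assigned to grip i when it falls inside the axis-aligned
ellipsoid centered on the template mean with semi-axes k·SD (k = 3 by
default):

    d_i(x) = Σ_j ((x_j − μ_ij) / (k·σ_ij))²  ≤ 1   (boundary inclusive).

If x lies inside several ellipsoids the smallest normalized distance d_i wins;
outside all of them no grip is recognized.  Two grips (pulp pinch and key
pinch) share nearly identical angle signatures and are only separable once the
force dimension is included (R³ → R⁴).

The index/palm force channels are separately discretized into three
interaction levels: zero (< 1 N), low (1–10 N inclusive), high (> 10 N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PoseTemplate",
    "SD_FLOOR_ANGLE_DEG",
    "SD_FLOOR_FORCE_N",
    "fit_pose_templates",
    "classify_pose",
    "classify_poses",
    "classify_pose_with_force",
    "force_level",
    "force_levels",
    "read_templates",
    "write_templates",
]

#: SD floors guard against zero-volume ellipsoids from degenerate training
SD_FLOOR_ANGLE_DEG = 0.5
SD_FLOOR_FORCE_N = 0.1


@dataclass(frozen=True)
class PoseTemplate:
    """Per-grip classification ellipsoid: mean and SD per dimension.

    Dimensions 0–2 are goniometer angles in degrees; an optional dimension 3
    is the index-finger force in N.
    """

    pose_id: int
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "sd", np.asarray(self.sd, float))
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-d vectors of equal length")
        if self.mean.shape[0] not in (3, 4):
            raise ValueError("templates have 3 (angles) or 4 (+force) dimensions")
        if np.any(self.sd <= 0):
            raise ValueError("template SDs must be > 0 (apply the SD floor)")

    @property
    def dims(self) -> int:
        return self.mean.shape[0]


def _sd_floor(dims: int) -> np.ndarray:
    floor = np.full(dims, SD_FLOOR_ANGLE_DEG)
    if dims == 4:
        floor[3] = SD_FLOOR_FORCE_N
    return floor


def fit_pose_templates(samples: dict[int, np.ndarray]) -> list[PoseTemplate]:
    """Fit templates from labelled measurement vectors.

    ``samples`` maps pose_id → array (n_i, d) with n_i ≥ 2 and a common d of
    3 or 4.  Means and population SDs are computed per dimension; SDs are
    floored at 0.5° (angles) / 0.1 N (force).
    """
    if not samples:
        raise ValueError("no labelled samples")
    dims = None
    templates = []
    for pose_id in sorted(samples):
        x = np.asarray(samples[pose_id], float)
        if x.ndim != 2:
            raise ValueError(f"pose {pose_id}: samples must be a 2-d array")
        if x.shape[0] < 2:
            raise ValueError(f"pose {pose_id}: need at least two samples")
        if dims is None:
            dims = x.shape[1]
            if dims not in (3, 4):
                raise ValueError("samples must have 3 or 4 dimensions")
        elif x.shape[1] != dims:
            raise ValueError("mixed sample dimensionalities")
        sd = np.maximum(x.std(axis=0, ddof=0), _sd_floor(dims))
        templates.append(PoseTemplate(pose_id=pose_id, mean=x.mean(axis=0), sd=sd))
    return templates


def _check_templates(templates) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    if not templates:
        raise ValueError("no templates")
    dims = templates[0].dims
    if any(tp.dims != dims for tp in templates):
        raise ValueError("all templates in one classifier must share dims")
    means = np.stack([tp.mean for tp in templates])
    sds = np.stack([tp.sd for tp in templates])
    ids = np.array([tp.pose_id for tp in templates])
    return means, sds, ids, dims


def classify_poses(x: np.ndarray, templates, k: float = 3.0) -> np.ndarray:
    """Vectorized ellipsoid classification.

    ``x`` has shape (n, d); returns an int array of pose ids, 0 where the
    measurement lies outside every ellipsoid.
    """
    means, sds, ids, dims = _check_templates(templates)
    x = np.asarray(x, float)
    if x.ndim != 2 or x.shape[1] != dims:
        raise ValueError(f"measurements must have shape (n, {dims})")
    z = (x[:, None, :] - means[None, :, :]) / (k * sds[None, :, :])
    d2 = np.sum(z**2, axis=2)  # (n, n_templates)
    best = np.argmin(d2, axis=1)
    inside = d2[np.arange(len(x)), best] <= 1.0
    return np.where(inside, ids[best], 0)


def classify_pose(x, templates, k: float = 3.0) -> int | None:
    """Classify a single measurement vector; None when no grip is recognized."""
    result = classify_poses(np.asarray(x, float)[None, :], templates, k=k)[0]
    return None if result == 0 else int(result)


def classify_pose_with_force(angles, f_index: float, templates, k: float = 3.0):
    """Classify (angles, index force) against 4-dimensional templates."""
    _, _, _, dims = _check_templates(templates)
    if dims != 4:
        raise ValueError("force-augmented classification needs 4-dim templates")
    angles = np.asarray(angles, float)
    if angles.shape != (3,):
        raise ValueError("expected three goniometer angles")
    return classify_pose(np.append(angles, f_index), templates, k=k)


def force_level(f: float) -> str:
    """Three-level interaction force: zero (<1 N), low (1–10 N), high (>10 N)."""
    if f < 0:
        raise ValueError("negative force")
    if f < 1.0:
        return "zero"
    if f <= 10.0:
        return "low"
    return "high"


def force_levels(f) -> np.ndarray:
    """Vectorized three-level discretization."""
    f = np.asarray(f, float)
    if np.any(f < 0):
        raise ValueError("negative force")
    out = np.where(f < 1.0, "zero", np.where(f <= 10.0, "low", "high"))
    return out


_ANGLE_COLS = ["thumb_deg", "index_deg", "middle_deg"]
_FORCE_COL = "f_index_N"


def write_templates(templates, path) -> None:
    """Write templates as CSV: pose_id, mean_<dim>..., sd_<dim>..."""
    _, _, _, dims = _check_templates(templates)
    cols = _ANGLE_COLS + ([_FORCE_COL] if dims == 4 else [])
    rows = []
    for tp in sorted(templates, key=lambda tp: tp.pose_id):
        row = {"pose_id": tp.pose_id}
        row.update({f"mean_{c}": m for c, m in zip(cols, tp.mean)})
        row.update({f"sd_{c}": s for c, s in zip(cols, tp.sd)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_templates(path) -> list[PoseTemplate]:
    df = pd.read_csv(path)
    dims = 4 if f"mean_{_FORCE_COL}" in df.columns else 3
    cols = _ANGLE_COLS + ([_FORCE_COL] if dims == 4 else [])
    templates = []
    for _, row in df.iterrows():
        templates.append(
            PoseTemplate(
                pose_id=int(row["pose_id"]),
                mean=np.array([row[f"mean_{c}"] for c in cols]),
                sd=np.array([row[f"sd_{c}"] for c in cols]),
            )
        )
    return templates
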