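"""Feature assembly for the two regression stages.

Stage 1 sees the normalized FMG channels plus their first differences (the
derivative captures the direction of amplitude change, which a static
sample-wise map cannot see).  Stage 2 additionally sees the stage-1
predicted 6-DoF loads, their first differences, and a spherical-coordinate
transform of each (x, y, z) prediction triple — radius, polar angle from
+Z, azimuth — exposing load magnitude and direction explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError


@dataclass(frozen=True)
class FeatureRecipe:
    """Which feature blocks to assemble, per stage."""

    stage: int = 1
    include_raw: bool = True
    include_derivative: bool = True
    include_stage1_pred: bool = False
    include_pred_derivative: bool = False
    include_spherical: bool = False

    @classmethod
    def stage1(cls) -> "FeatureRecipe":
        return cls(stage=1)

    @classmethod
    def stage2(cls) -> "FeatureRecipe":
        return cls(
            stage=2,
            include_stage1_pred=True,
            include_pred_derivative=True,
            include_spherical=True,
        )


def derivative(x: np.ndarray, trial_id: np.ndarray | None = None) -> np.ndarray:
    """First difference per column, leading row 0; per trial if ids given."""
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[0] < 2:
        raise DataError("derivative requires at least 2 samples")
    out = np.empty_like(x)
    if trial_id is None:
        out[0] = 0.0
        out[1:] = np.diff(x, axis=0)
    else:
        trial_id = np.asarray(trial_id)
        for t in np.unique(trial_id):
            m = trial_id == t
            seg = x[m]
            d = np.zeros_like(seg)
            if seg.shape[0] > 1:
                d[1:] = np.diff(seg, axis=0)
            out[m] = d
    return out[:, 0] if squeeze else out


def spherical_transform(triples: np.ndarray) -> np.ndarray:
    """Map each (x, y, z) column triple to (r, theta, phi) in radians.

    ISO physics convention: r = sqrt(x^2+y^2+z^2), theta = arccos(z/r)
    (0 at the +Z pole, and defined as 0 when r = 0), phi = atan2(y, x).
    """
    x = np.asarray(triples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("spherical transform requires finite input")
    if x.ndim != 2 or x.shape[1] % 3 != 0:
        raise DataError(f"column count must be a multiple of 3, got {x.shape}")
    out = np.empty_like(x)
    for k in range(x.shape[1] // 3):
        xx, yy, zz = x[:, 3 * k], x[:, 3 * k + 1], x[:, 3 * k + 2]
        r = np.sqrt(xx**2 + yy**2 + zz**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.where(r > 0, np.arccos(np.clip(zz / np.where(r > 0, r, 1.0), -1, 1)), 0.0)
        phi = np.arctan2(yy, xx)
        out[:, 3 * k] = r
        out[:, 3 * k + 1] = theta
        out[:, 3 * k + 2] = phi
    return out


def inverse_spherical(spherical: np.ndarray) -> np.ndarray:
    """Inverse of :func:`spherical_transform` (for round-trip checks)."""
    s = np.asarray(spherical, dtype=float)
    out = np.empty_like(s)
    for k in range(s.shape[1] // 3):
        r, theta, phi = s[:, 3 * k], s[:, 3 * k + 1], s[:, 3 * k + 2]
        out[:, 3 * k] = r * np.sin(theta) * np.cos(phi)
        out[:, 3 * k + 1] = r * np.sin(theta) * np.sin(phi)
        out[:, 3 * k + 2] = r * np.cos(theta)
    return out


def feature_names(recipe: FeatureRecipe, channel_names: tuple, output_names: tuple) -> list[str]:
    """Stable column manifest for an assembled feature matrix."""
    names: list[str] = []
    if recipe.include_raw:
        names += list(channel_names)
    if recipe.include_derivative:
        names += [f"d_{c}" for c in channel_names]
    if recipe.include_stage1_pred:
        names += [f"pred_{o}" for o in output_names]
    if recipe.include_pred_derivative:
        names += [f"d_pred_{o}" for o in output_names]
    if recipe.include_spherical:
        sph = ("r", "theta", "phi")
        for k in range(len(output_names) // 3):
            names += [f"sph{k + 1}_{s}" for s in sph]
    return names


def assemble_features(
    recipe: FeatureRecipe,
    fmg: np.ndarray,
    stage1_pred: np.ndarray | None = None,
    trial_id: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate feature blocks in the fixed order
    raw | d(raw) | pred | d(pred) | spherical(pred)."""
    fmg = np.asarray(fmg, dtype=float)
    blocks: list[np.ndarray] = []
    if recipe.include_raw:
        blocks.append(fmg)
    if recipe.include_derivative:
        blocks.append(derivative(fmg, trial_id))
    if recipe.include_stage1_pred or recipe.include_pred_derivative or recipe.include_spherical:
        if stage1_pred is None:
            raise DataError("stage-2 recipe requires stage-1 predictions")
        pred = np.asarray(stage1_pred, dtype=float)
        if pred.shape[0] != fmg.shape[0]:
            raise DataError(
                f"row mismatch: fmg has {fmg.shape[0]} rows, predictions {pred.shape[0]}"
            )
        if recipe.include_stage1_pred:
            blocks.append(pred)
        if recipe.include_pred_derivative:
            blocks.append(derivative(pred, trial_id))
        if recipe.include_spherical:
            blocks.append(spherical_transform(pred))
    return np.hstack(blocks)
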