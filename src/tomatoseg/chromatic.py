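"""First-layer classification: per-pixel integrated colour parameter.

Ripe tomato pixels are strongly red-dominant, so a single linear chromatic
discriminant

    icp(R, G, B) = alpha * R - beta * B - gamma * G

separates candidate fruit pixels from foliage and soil: the first-layer mask
keeps exactly the pixels whose integrated colour parameter strictly exceeds a
scalar separation parameter.  The subtraction of the G and (down-weighted) B
channels makes the discriminant robust to broad illumination changes that
would defeat a plain red-channel threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import as_rgb_image

#: Operating point established on 600 calibration pixels (3 groups of 200).
DEFAULT_ALPHA = 1.00
DEFAULT_BETA = 0.25
DEFAULT_GAMMA = 1.00
DEFAULT_SEPARATION = 10.0


@dataclass(frozen=True)
class ChromaticParams:
    """Coefficients and threshold of the chromatic discriminant."""

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA
    separation_parameter: float = DEFAULT_SEPARATION

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("alpha, beta, gamma must be non-negative")


def integrated_colour_parameter(
    pixel: np.ndarray | tuple, params: ChromaticParams = ChromaticParams()
) -> np.ndarray | float:
    """Evaluate alpha*R - beta*B - gamma*G in real arithmetic.

    Accepts a single (R, G, B) triple or any array whose last axis is the
    colour channel; the computation is never clamped to 8-bit range because
    the parameter is legitimately negative on green and achromatic pixels.
    """
    arr = np.asarray(pixel, dtype=np.float64)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    out = params.alpha * r - params.beta * b - params.gamma * g
    return float(out) if out.ndim == 0 else out


def first_layer_mask(
    img: np.ndarray, params: ChromaticParams = ChromaticParams()
) -> np.ndarray:
    """Chromatic-difference mask: 255 where icp strictly exceeds the threshold.

    Ties at exactly the separation parameter are background (strict ">").
    """
    rgb = as_rgb_image(img)
    icp = integrated_colour_parameter(rgb, params)
    return np.where(icp > params.separation_parameter, 255, 0).astype(np.uint8)


@dataclass
class CalibrationReport:
    """Suggested separation parameter and the trade-off it implies."""

    suggested_threshold: float
    tomato_miss_fraction: float
    non_target_leakage: float
    group_summaries: pd.DataFrame


def load_pixel_groups(path) -> dict[str, np.ndarray]:
    """Read calibration pixel samples from CSV (columns group,R,G,B).

    Groups follow the M/N/K convention for tomato, green-vegetation and other
    background sample sets; every listed group letter is returned.
    """
    df = pd.read_csv(path)
    required = {"group", "R", "G", "B"}
    if not required.issubset(df.columns):
        raise ValueError(f"pixel-group CSV needs columns {sorted(required)}")
    groups: dict[str, np.ndarray] = {}
    for name, sub in df.groupby("group"):
        groups[str(name)] = sub[["R", "G", "B"]].to_numpy(dtype=np.float64)
    return groups


def identify_tomato_group(groups: dict[str, np.ndarray]) -> str:
    """Return the key of the group with the largest mean R - G excess.

    The tomato sample set is the one whose red component dominates green;
    identifying it by that property avoids relying on a fixed letter
    convention for the group names.
    """
    if not groups:
        raise ValueError("no pixel groups given")
    return max(groups, key=lambda k: float(np.mean(groups[k][:, 0] - groups[k][:, 1])))


def calibrate_separation_parameter(
    groups: dict[str, np.ndarray],
    params: ChromaticParams = ChromaticParams(),
    tolerance: float = 0.0,
    margin: float = 0.0,
) -> CalibrationReport:
    """Suggest a separation parameter from labelled pixel samples.

    Evaluates the integrated colour parameter on every sample, then returns
    the largest threshold that still keeps at least ``1 - tolerance`` of the
    tomato-group values strictly above it — concretely, the ``tolerance``
    quantile (by order statistic) of the tomato values minus ``margin``.
    The fraction of non-tomato samples exceeding that threshold is reported
    as leakage.  Deterministic; never overrides the configured default.
    """
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValueError("every pixel group must be non-empty")
    if not 0.0 <= tolerance <= 1.0:
        raise ValueError("tolerance must lie in [0, 1]")
    tomato_key = identify_tomato_group(groups)
    values = {k: integrated_colour_parameter(v, params) for k, v in groups.items()}
    tomato = np.sort(np.atleast_1d(values[tomato_key]))
    n_miss = int(np.floor(tolerance * tomato.size))
    threshold = float(tomato[n_miss]) - margin
    others = np.concatenate(
        [np.atleast_1d(values[k]) for k in groups if k != tomato_key]
    ) if len(groups) > 1 else np.empty(0)
    leakage = float(np.mean(others > threshold)) if others.size else 0.0
    miss = float(np.mean(tomato <= threshold))
    rows = []
    for k in sorted(groups):
        v = np.atleast_1d(values[k])
        rows.append(
            {
                "group": k,
                "n": v.size,
                "icp_mean": float(v.mean()),
                "icp_min": float(v.min()),
                "icp_max": float(v.max()),
                "is_tomato": k == tomato_key,
            }
        )
    return CalibrationReport(
        suggested_threshold=threshold,
        tomato_miss_fraction=miss,
        non_target_leakage=leakage,
        group_summaries=pd.DataFrame(rows),
    )
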