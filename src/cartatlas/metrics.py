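"""Reduce a simulation history to the five mechanical response trajectories.

For each stance frame, the contact region is the set of elements with at
least one node in contact; over that region we report the peak and the
area-weighted average (weights: element articular-face areas) of maximum
principal stress, maximum principal strain, minimum principal strain,
fibril strain and pore pressure. "Peak" means the extremum in the
physically adverse direction: the maximum for tensile stress/strain,
fibril strain and pore pressure, the minimum (most negative) for the
compressive principal strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fem import FieldHistory, _voigt_to_tensor, face_areas

__all__ = ["StanceTrajectories", "principal_values", "summarize",
           "PARAMETERS"]

PARAMETERS = ("max_principal_stress", "max_principal_strain",
              "min_principal_strain", "fibril_strain", "pore_pressure")

# Sign of the adverse extremum per parameter (+1: max, -1: min).
_PEAK_SIGN = {"max_principal_stress": 1, "max_principal_strain": 1,
              "min_principal_strain": -1, "fibril_strain": 1,
              "pore_pressure": 1}


@dataclass(frozen=True)
class StanceTrajectories:
    """Peak and contact-averaged series of the five parameters vs stance."""

    stance_pct: np.ndarray
    peak: dict        # parameter -> (T,) array
    mean: dict        # parameter -> (T,) array

    def to_frame(self) -> pd.DataFrame:
        data = {"stance_pct": self.stance_pct}
        for par in PARAMETERS:
            data[f"{par}_peak"] = self.peak[par]
            data[f"{par}_mean"] = self.mean[par]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path) -> "StanceTrajectories":
        df = pd.read_csv(path)
        return cls(df["stance_pct"].to_numpy(),
                   {p: df[f"{p}_peak"].to_numpy() for p in PARAMETERS},
                   {p: df[f"{p}_mean"].to_numpy() for p in PARAMETERS})


def principal_values(tensor: np.ndarray, tol: float = 1e-8):
    """Eigenvalues of a symmetric 3x3 tensor, sorted descending."""
    t = np.asarray(tensor, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise ValueError("tensor must be 3x3")
    scale = max(np.abs(t).max(), 1.0)
    if not np.allclose(t, np.swapaxes(t, -1, -2), atol=tol * scale):
        raise ValueError("tensor is not symmetric within tolerance")
    w = np.linalg.eigvalsh(0.5 * (t + np.swapaxes(t, -1, -2)))
    return w[..., ::-1]


def _contact_elements(history: FieldHistory, frame: int) -> np.ndarray:
    flags = history.contact_flags[frame]
    return np.nonzero(flags[history.elements].any(axis=1))[0]


def _element_face_areas(history: FieldHistory) -> np.ndarray:
    # articular (z+) face of each element, VTK local nodes 4..7
    return face_areas(history.nodes, history.elements[:, 4:8])


def summarize(history: FieldHistory) -> StanceTrajectories:
    """Peak and contact-area-averaged trajectories from a FieldHistory.

    Element values are Gauss-point means; the peak is the Gauss-point
    extremum over the contact region. Frames with an empty contact
    region get NaN (recorded as missing, warned once, never fabricated).
    """
    T = len(history.times)
    areas = _element_face_areas(history)
    peak = {p: np.full(T, np.nan) for p in PARAMETERS}
    mean = {p: np.full(T, np.nan) for p in PARAMETERS}
    empty_frames = 0

    for frame in range(T):
        els = _contact_elements(history, frame)
        if len(els) == 0:
            empty_frames += 1
            continue
        w = areas[els]
        stress_t = _voigt_to_tensor(history.stress[frame, els])   # (E,8,3,3)
        strain_t = _voigt_to_tensor(history.strain[frame, els])
        sig_p = np.linalg.eigvalsh(stress_t)
        eps_p = np.linalg.eigvalsh(strain_t)
        p_nodes = history.p[frame][history.elements[els]]          # (E,8)
        gp = {
            "max_principal_stress": sig_p[..., 2],
            "max_principal_strain": eps_p[..., 2],
            "min_principal_strain": eps_p[..., 0],
            "fibril_strain": history.fibril_strain[frame, els],
            "pore_pressure": p_nodes,
        }
        for par, vals in gp.items():
            elem_val = vals.mean(axis=1)
            mean[par][frame] = float((w * elem_val).sum() / w.sum())
            if _PEAK_SIGN[par] > 0:
                peak[par][frame] = float(vals.max())
            else:
                peak[par][frame] = float(vals.min())

    if empty_frames:
        warnings.warn(f"{empty_frames} frame(s) had an empty contact region; "
                      "values recorded as missing", stacklevel=2)
    stance = (history.stance_pct if history.stance_pct is not None
              else np.asarray(history.times))
    return StanceTrajectories(np.asarray(stance, dtype=float), peak, mean)


def plot_trajectories(traj_list, parameter: str, kind: str = "peak", ax=None):
    """Mean +/- SD band across subjects for one parameter (plot helper)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    series = np.stack([getattr(t, kind)[parameter] for t in traj_list])
    grid = traj_list[0].stance_pct
    m, s = np.nanmean(series, axis=0), np.nanstd(series, axis=0)
    ax.plot(grid, m, lw=2)
    ax.fill_between(grid, m - s, m + s, alpha=0.3)
    ax.set_xlabel("stance [%]")
    ax.set_ylabel(f"{parameter} ({kind})")
    return ax
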