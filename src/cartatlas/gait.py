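"""Simplified gait loading for the medial compartment.

A generic stance-phase waveform (axial tibiofemoral force in body-weight
units plus knee flexion angle) is scaled by the subject's body weight,
split 50/50 between compartments, and reduced by the fraction of load the
meniscus carries. The waveform itself is an input: the packaged CSV is a
representative instrumented-knee gait profile and users may substitute
their own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

G_M_PER_S2 = 9.81

__all__ = ["GaitWaveform", "LoadingProfile", "build_loading",
           "resample_waveform", "default_gait_waveform"]


@dataclass(frozen=True)
class GaitWaveform:
    stance_pct: np.ndarray     # strictly increasing, spans [0, 100]
    axial_force_bw: np.ndarray  # total tibiofemoral axial force / body weight
    flexion_deg: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.stance_pct, dtype=float)
        f = np.asarray(self.axial_force_bw, dtype=float)
        a = np.asarray(self.flexion_deg, dtype=float)
        if not (len(s) == len(f) == len(a)) or len(s) < 2:
            raise ValueError("waveform arrays must share a length >= 2")
        if np.any(np.diff(s) <= 0) or s[0] != 0.0 or s[-1] != 100.0:
            raise ValueError("stance_pct must strictly increase from 0 to 100")
        if np.any(f < 0):
            raise ValueError("axial_force_bw must be >= 0")
        object.__setattr__(self, "stance_pct", s)
        object.__setattr__(self, "axial_force_bw", f)
        object.__setattr__(self, "flexion_deg", a)

    @classmethod
    def from_csv(cls, path) -> "GaitWaveform":
        df = pd.read_csv(path)
        return cls(df["stance_pct"].to_numpy(),
                   df["axial_force_bw"].to_numpy(),
                   df["flexion_deg"].to_numpy())


@dataclass(frozen=True)
class LoadingProfile:
    stance_pct: np.ndarray
    medial_force_n: np.ndarray
    flexion_deg: np.ndarray
    body_mass_kg: float
    meniscus_fraction: float

    def to_json(self, path) -> None:
        payload = {
            "stance_pct": self.stance_pct.tolist(),
            "medial_force_n": self.medial_force_n.tolist(),
            "flexion_deg": self.flexion_deg.tolist(),
            "body_mass_kg": self.body_mass_kg,
            "meniscus_fraction": self.meniscus_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LoadingProfile":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.asarray(d["stance_pct"]), np.asarray(d["medial_force_n"]),
                   np.asarray(d["flexion_deg"]), d["body_mass_kg"],
                   d["meniscus_fraction"])


def build_loading(waveform: GaitWaveform, body_mass_kg: float,
                  meniscus_fraction: float, medial_share: float = 0.5,
                  g: float = G_M_PER_S2) -> LoadingProfile:
    """Medial-compartment force profile in newtons.

    ``medial_force_n(t) = axial_force_bw(t) * m * g * medial_share *
    (1 - meniscus_fraction)``: half of the body-weight-scaled joint force
    goes through the medial compartment and the meniscus-borne share is
    subtracted because the meniscus is not meshed. Flexion passes through.
    """
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be > 0")
    if not (0.0 <= meniscus_fraction < 1.0):
        raise ValueError("meniscus_fraction must be in [0, 1)")
    if not (0.0 < medial_share <= 1.0):
        raise ValueError("medial_share must be in (0, 1]")
    force = (waveform.axial_force_bw * body_mass_kg * g
             * medial_share * (1.0 - meniscus_fraction))
    return LoadingProfile(waveform.stance_pct.copy(), force,
                          waveform.flexion_deg.copy(),
                          float(body_mass_kg), float(meniscus_fraction))


def resample_waveform(waveform: GaitWaveform, n_points: int) -> GaitWaveform:
    """Linearly interpolate onto a uniform 0..100% grid of ``n_points``."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(0.0, 100.0, n_points)
    return GaitWaveform(
        grid,
        np.interp(grid, waveform.stance_pct, waveform.axial_force_bw),
        np.interp(grid, waveform.stance_pct, waveform.flexion_deg),
    )


def default_gait_waveform() -> GaitWaveform:
    """The packaged representative stance-phase waveform."""
    with resources.files("cartatlas.data").joinpath("gait_waveform.csv").open() as fh:
        return GaitWaveform.from_csv(fh)
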