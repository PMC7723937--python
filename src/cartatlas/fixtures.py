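"""Synthetic data generators for every pipeline input.

Generates, deterministically from a seed: a template atlas library with
parametric condyle-on-plateau geometries, subject dimension tables,
rater measurement tables with known variance components, and paired
stance trajectories with controllable effects. Dimension distributions
default to values typical of adult knees (ML about 80 +/- 4 mm, AP
medial about 53 +/- 4 mm, AP lateral about 62 +/- 4.6 mm, JSW medial
about 3.9 +/- 1 mm, JSW lateral about 5.4 +/- 0.9 mm); these are
realistic sampling ranges, not recovery targets.

Atlas geometry: the medial tibial cartilage is a flat hexahedral slab
(half the joint space width thick) whose footprint is AP medial long and
``MEDIAL_FOOTPRINT_FRACTION * ML`` wide; the femoral cartilage layer sits
above it with a spherical articular surface that touches the tibial
surface at the footprint center. The sphere radius is the effective
relative-curvature radius of the compartment contact -- much larger than
the condyle radius itself because the concave plateau and the meniscus
make the contact conforming -- and doubles as the rigid counter-surface
for the desk-scale solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import (MEDIAL_FOOTPRINT_FRACTION, AtlasLibrary, TemplateAtlas,
                    validate_atlas)
from .dimensions import AnatomicalDimensions
from .spm import PairedTrajectories

__all__ = ["FixtureSpec", "gen_atlas_library", "gen_subject_dimensions",
           "gen_rater_table", "gen_paired_trajectories"]

_DIM_DEFAULTS = {
    # mean, sd, lower clip (mm)
    "ml": (80.0, 4.0, 60.0),
    "ap_medial": (53.0, 4.3, 38.0),
    "ap_lateral": (62.0, 4.6, 45.0),
    "jsw_medial": (3.9, 1.0, 2.0),
    "jsw_lateral": (5.4, 0.9, 2.5),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Controls for all synthetic generators; fixed seed => identical bytes."""

    seed: int = 0
    n_atlases: int = 21
    dim_stats: dict = field(default_factory=lambda: dict(_DIM_DEFAULTS))
    meniscus_range: tuple = (0.3, 0.5)
    contact_radius_range: tuple = (130.0, 180.0)
    body_mass_mean_sd: tuple = (80.0, 12.0)
    sigma2_subject: float = 9.0
    sigma2_error: float = 1.0
    mesh_nx: int = 6
    mesh_ny: int = 6
    mesh_nz: int = 3       # element layers per cartilage slab
    effect_profile: np.ndarray | None = None


def _sample_dims(rng, stats) -> AnatomicalDimensions:
    vals = {}
    for name, (mean, sd, lo) in stats.items():
        vals[name] = float(np.clip(rng.normal(mean, sd), lo, None))
    return AnatomicalDimensions(**vals)


def _box_grid(nx, ny, nz, lx, ly):
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    pts = np.array([[x, y] for y in ys for x in xs])

    def nid(i, j, k):
        return k * (nx + 1) * (ny + 1) + j * (nx + 1) + i

    elems = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                elems.append([nid(i, j, k), nid(i + 1, j, k),
                              nid(i + 1, j + 1, k), nid(i, j + 1, k),
                              nid(i, j, k + 1), nid(i + 1, j, k + 1),
                              nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    return pts, np.array(elems, dtype=int)


def _build_atlas(atlas_id, dims, meniscus_fraction, radius, spec) -> TemplateAtlas:
    nx, ny, nz = spec.mesh_nx, spec.mesh_ny, spec.mesh_nz
    lx = dims.ap_medial
    ly = MEDIAL_FOOTPRINT_FRACTION * dims.ml
    # The deformable (tibial-side) slab takes two thirds of the joint
    # space width; the thinner femoral cap above completes JSW. In the
    # desk-scale simulation the femoral layer is replaced by the rigid
    # counter-surface plus the penalty foundation, so most of the
    # compartment's cartilage compliance lives in the meshed slab.
    jt = (2.0 / 3.0) * dims.jsw_medial   # tibial slab thickness
    jf = (1.0 / 3.0) * dims.jsw_medial   # femoral layer thickness
    pts2d, elems_layer = _box_grid(nx, ny, nz, lx, ly)
    npl = len(pts2d)               # nodes per z-plane
    center = np.array([lx / 2.0, ly / 2.0])

    # tibial slab: flat planes z in [0, jt]
    z_tib = np.linspace(0.0, jt, nz + 1)
    tib_nodes = np.concatenate(
        [np.column_stack([pts2d, np.full(npl, z)]) for z in z_tib])

    # femoral layer: spherical lower surface touching the tibial top at center
    r2 = ((pts2d - center) ** 2).sum(axis=1)
    r2 = np.minimum(r2, (0.85 * radius) ** 2)   # keep the cap well-defined
    sag = radius - np.sqrt(radius ** 2 - r2)
    z_base = jt + sag
    fem_nodes = np.concatenate(
        [np.column_stack([pts2d, z_base + frac * jf])
         for frac in np.linspace(0.0, 1.0, nz + 1)])

    nodes = np.vstack([tib_nodes, fem_nodes])
    n_tib = len(tib_nodes)
    elems = np.vstack([elems_layer, elems_layer + n_tib])
    m = len(elems)

    tib_ids = np.arange(n_tib)
    fem_ids = np.arange(n_tib, len(nodes))
    node_sets = {
        "tibial_cartilage": tib_ids,
        "femoral_cartilage": fem_ids,
        "tibial_bottom": np.arange(npl),
        "contact_surface": np.arange(nz * npl, (nz + 1) * npl),
    }
    split = np.tile([1.0, 0.0, 0.0], (m, 1))
    counter = {"type": "sphere", "radius": float(radius),
               "center": [float(center[0]), float(center[1]),
                          float(jt + radius)]}
    a = TemplateAtlas(atlas_id=atlas_id, nodes=nodes, elements=elems,
                      node_sets=node_sets, dims=dims,
                      meniscus_fraction=float(meniscus_fraction),
                      split_line_field=split, counter_surface=counter)
    validate_atlas(a)
    return a


def gen_atlas_library(spec: FixtureSpec) -> AtlasLibrary:
    """Deterministic synthetic atlas library (default 21 templates)."""
    if spec.n_atlases < 1:
        raise ValueError("n_atlases must be >= 1")
    rng = np.random.default_rng(spec.seed)
    atlases = []
    for i in range(spec.n_atlases):
        dims = _sample_dims(rng, spec.dim_stats)
        mf = rng.uniform(*spec.meniscus_range)
        radius = rng.uniform(*spec.contact_radius_range)
        atlases.append(_build_atlas(f"atlas_{i:02d}", dims, mf, radius, spec))
    return AtlasLibrary(atlases)


def gen_subject_dimensions(spec: FixtureSpec, n_subjects: int = 9) -> pd.DataFrame:
    """Subject dimension table: one knee + body mass per row."""
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    m_mean, m_sd = spec.body_mass_mean_sd
    for i in range(n_subjects):
        d = _sample_dims(rng, spec.dim_stats)
        rows.append({"subject_id": f"subj_{i:02d}",
                     **{k: getattr(d, k) for k in
                        ("ml", "ap_medial", "ap_lateral",
                         "jsw_medial", "jsw_lateral")},
                     "body_mass_kg": float(np.clip(
                         rng.normal(m_mean, m_sd), 45.0, None))})
    return pd.DataFrame(rows)


def gen_rater_table(spec: FixtureSpec, n_subjects: int, n_raters: int,
                    n_trials: int, mean: float = 80.0) -> pd.DataFrame:
    """Long-form rater measurement table with known variance components.

    value = mean + subject effect (Normal, sigma2_subject) + iid error
    (Normal, sigma2_error). The expected single-measurement absolute
    agreement ICC is sigma2_subject / (sigma2_subject + sigma2_error).
    """
    if n_subjects < 2 or n_raters < 1 or n_trials < 2:
        raise ValueError("need n_subjects >= 2, n_raters >= 1, n_trials >= 2")
    rng = np.random.default_rng(spec.seed + 2)
    subj = rng.normal(0.0, np.sqrt(spec.sigma2_subject), n_subjects)
    rows = []
    for r in range(n_raters):
        err = rng.normal(0.0, np.sqrt(spec.sigma2_error),
                         (n_subjects, n_trials))
        for s in range(n_subjects):
            for t in range(n_trials):
                rows.append({"subject_id": f"subj_{s:02d}", "rater": r + 1,
                             "trial": t + 1,
                             "value_mm": mean + subj[s] + err[s, t]})
    return pd.DataFrame(rows)


def gen_paired_trajectories(spec: FixtureSpec, n_subjects: int,
                            n_points: int = 101, noise_sd: float = 1.0,
                            smooth_sigma: float = 0.0) -> PairedTrajectories:
    """Paired stance trajectories: cond_b = cond_a + effect_profile + noise.

    Each subject gets a smooth random baseline curve shared by both
    conditions plus independent per-condition noise (optionally smoothed
    with a Gaussian kernel of ``smooth_sigma`` grid points; the same
    kernel in both conditions keeps the null exchangeable). A zero
    ``effect_profile`` therefore yields an exact sign-flip null.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(spec.seed + 3)
    grid = np.linspace(0.0, 100.0, n_points)
    effect = spec.effect_profile
    effect = np.zeros(n_points) if effect is None else np.asarray(effect, float)
    if len(effect) != n_points:
        raise ValueError("effect_profile length must equal n_points")

    phase = rng.uniform(0, 2 * np.pi, (n_subjects, 3))
    amp = rng.normal(1.0, 0.3, (n_subjects, 3))
    base = sum(amp[:, [j]] * np.sin((j + 1) * 2 * np.pi * grid / 100.0
                                    + phase[:, [j]]) for j in range(3))

    def noise():
        e = rng.normal(0.0, noise_sd, (n_subjects, n_points))
        if smooth_sigma > 0:
            from scipy.ndimage import gaussian_filter1d
            e = gaussian_filter1d(e, smooth_sigma, axis=1, mode="nearest")
        return e

    cond_a = base + noise()
    cond_b = base + effect + noise()
    return PairedTrajectories(cond_a=cond_a, cond_b=cond_b, stance_pct=grid)
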