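"""Template atlases: selection by normalized-dimension RMSE and per-axis scaling.

An atlas is a previously meshed medial-compartment cartilage model (nodes,
hexahedral elements, named node sets) together with the five anatomical
dimensions of the knee it was built from and the fraction of compartment
load carried by the meniscus. A subject's model is obtained by picking the
atlas with the minimum root-mean-square error in ML-normalized dimensions
and scaling its nodal coordinates axis by axis: anterior-posterior = x,
medial-lateral = y, joint-space-width (thickness) = z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dimensions import AnatomicalDimensions, NormalizedDimensions, normalize_dimensions
from . import vtkio

__all__ = [
    "TemplateAtlas",
    "AtlasLibrary",
    "match_template",
    "scale_template",
    "measure_dimensions",
    "hex_jacobians",
    "save_library",
    "load_library",
]

# Fraction of the full ML length covered by the medial-compartment mesh
# footprint in the y direction. Used symmetrically by the synthetic atlas
# generator and by measure_dimensions, so generated dimensions round-trip.
MEDIAL_FOOTPRINT_FRACTION = 0.45

REQUIRED_SETS = ("femoral_cartilage", "tibial_cartilage", "tibial_bottom",
                 "contact_surface")


@dataclass
class TemplateAtlas:
    """One template FE mesh plus the metadata needed to select and scale it.

    ``counter_surface`` describes the rigid femoral surface used by the
    desk-scale solver: ``{"type": "sphere", "radius": R, "center": [x,y,z]}``
    (after anisotropic scaling the sphere becomes an ellipsoid with
    ``radii`` instead of ``radius``).
    """

    atlas_id: str
    nodes: np.ndarray              # (n, 3) mm
    elements: np.ndarray           # (m, 8) 0-based, VTK hex ordering
    node_sets: dict[str, np.ndarray]
    dims: AnatomicalDimensions
    meniscus_fraction: float
    split_line_field: np.ndarray   # (m, 3) unit vectors
    counter_surface: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        if self.elements.min() < 0 or self.elements.max() >= len(self.nodes):
            raise ValueError("element connectivity indices out of range")
        if not (0.0 <= self.meniscus_fraction < 1.0):
            raise ValueError("meniscus_fraction must be in [0, 1)")
        self.split_line_field = np.asarray(self.split_line_field, dtype=float)

    def tibial_elements(self) -> np.ndarray:
        """Indices of elements whose nodes all lie in the tibial cartilage set."""
        tib = np.zeros(len(self.nodes), dtype=bool)
        tib[self.node_sets["tibial_cartilage"]] = True
        return np.nonzero(tib[self.elements].all(axis=1))[0]


@dataclass
class AtlasLibrary:
    atlases: list[TemplateAtlas]

    def __post_init__(self) -> None:
        if not self.atlases:
            raise ValueError("atlas library must be non-empty")
        ids = [a.atlas_id for a in self.atlases]
        if len(set(ids)) != len(ids):
            raise ValueError("atlas_ids must be unique")

    def __len__(self) -> int:
        return len(self.atlases)

    def get(self, atlas_id: str) -> TemplateAtlas:
        for a in self.atlases:
            if a.atlas_id == atlas_id:
                return a
        raise KeyError(atlas_id)

    def mean_meniscus_fraction(self) -> float:
        return float(np.mean([a.meniscus_fraction for a in self.atlases]))


def match_template(subject: NormalizedDimensions,
                   library: AtlasLibrary) -> list[tuple[str, float]]:
    """Rank atlases by RMSE of normalized dimensions, best first.

    The RMSE runs over all five normalized fields; the ML term is
    identically zero (both sides normalize to 1), so this equals a
    four-field RMSE. Ties keep library order (stable sort).
    """
    s = subject.as_array()
    out = []
    for a in library.atlases:
        t = normalize_dimensions(a.dims).as_array()
        rmse = float(np.sqrt(np.mean((s - t) ** 2)))
        out.append((a.atlas_id, rmse))
    out.sort(key=lambda pair: pair[1])  # stable: ties keep library order
    return out


def default_scale_origin(atlas: TemplateAtlas) -> np.ndarray:
    """Centroid of the tibial contact-surface node set (the scaling origin)."""
    return atlas.nodes[atlas.node_sets["contact_surface"]].mean(axis=0)


def scale_factors(atlas_dims: AnatomicalDimensions,
                  subject: AnatomicalDimensions,
                  use_lateral: bool = False) -> np.ndarray:
    """Per-axis scale factors (sx, sy, sz) mapping atlas to subject.

    The medial compartment is the meshed one, so AP medial governs x and
    JSW medial governs z by default; ``use_lateral`` switches to the
    lateral pair (configuration switch, not the default behavior).
    """
    if use_lateral:
        sx = subject.ap_lateral / atlas_dims.ap_lateral
        sz = subject.jsw_lateral / atlas_dims.jsw_lateral
    else:
        sx = subject.ap_medial / atlas_dims.ap_medial
        sz = subject.jsw_medial / atlas_dims.jsw_medial
    sy = subject.ml / atlas_dims.ml
    s = np.array([sx, sy, sz])
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError(f"non-positive or non-finite scale factors {s}")
    return s


def scale_template(atlas: TemplateAtlas, subject: AnatomicalDimensions,
                   origin: np.ndarray | None = None,
                   use_lateral: bool = False) -> TemplateAtlas:
    """Anisotropically scale an atlas mesh to a subject's dimensions.

    Nodes map as ``origin + diag(sx, sy, sz) @ (node - origin)``;
    connectivity, node sets and meniscus fraction are untouched; the
    split-line field is re-normalized to unit length; the rigid
    counter-surface sphere becomes an ellipsoid.
    """
    if origin is None:
        origin = default_scale_origin(atlas)
    origin = np.asarray(origin, dtype=float)
    s = scale_factors(atlas.dims, subject, use_lateral=use_lateral)
    nodes = origin + (atlas.nodes - origin) * s

    split = atlas.split_line_field * s
    norms = np.linalg.norm(split, axis=1, keepdims=True)
    split = np.divide(split, norms, out=np.zeros_like(split), where=norms > 0)

    cs = dict(atlas.counter_surface)
    if cs.get("type") == "sphere":
        c = origin + (np.asarray(cs["center"], dtype=float) - origin) * s
        cs = {"type": "ellipsoid", "center": c.tolist(),
              "radii": (float(cs["radius"]) * s).tolist()}
    elif cs.get("type") == "ellipsoid":
        c = origin + (np.asarray(cs["center"], dtype=float) - origin) * s
        cs = {"type": "ellipsoid", "center": c.tolist(),
              "radii": (np.asarray(cs["radii"], dtype=float) * s).tolist()}

    return replace(atlas, nodes=nodes, dims=subject, split_line_field=split,
                   counter_surface=cs)


# Gauss / corner natural coordinates for the Jacobian check (VTK ordering).
_XI_CORNERS = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)


def _dshape(xi: np.ndarray) -> np.ndarray:
    """Derivatives of the 8 trilinear shape functions at natural coords xi."""
    g = np.empty((8, 3))
    for i, (a, b, c) in enumerate(_XI_CORNERS):
        g[i] = 0.125 * np.array([
            a * (1 + b * xi[1]) * (1 + c * xi[2]),
            (1 + a * xi[0]) * b * (1 + c * xi[2]),
            (1 + a * xi[0]) * (1 + b * xi[1]) * c])
    return g


def hex_jacobians(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Jacobian determinant of each element at each of its 8 corners, (m, 8)."""
    X = nodes[elements]  # (m, 8, 3)
    det = np.empty((len(elements), 8))
    for j, xi in enumerate(_XI_CORNERS):
        G = _dshape(xi)                    # (8, 3)
        J = np.einsum("ia,eib->eab", G, X)  # (m, 3, 3)
        det[:, j] = np.linalg.det(J)
    return det


def validate_atlas(atlas: TemplateAtlas) -> None:
    """Raise if the atlas violates its structural invariants."""
    for name in REQUIRED_SETS:
        if name not in atlas.node_sets or len(atlas.node_sets[name]) == 0:
            raise ValueError(f"missing or empty node set {name!r}")
    det = hex_jacobians(atlas.nodes, atlas.elements)
    if det.min() <= 0:
        raise ValueError("non-positive hexahedron Jacobian")


def measure_dimensions(atlas: TemplateAtlas) -> dict[str, float]:
    """Measure ML, AP medial and JSW medial back from a mesh.

    AP medial is the x extent of the mesh, ML is the y extent divided by
    the medial footprint fraction, and JSW medial is the femoral-surface
    height above the tibial bone interface on the central column (where
    the two cartilage layers meet). Lateral dimensions are not measurable
    from a medial-only mesh and live in the metadata alone.
    """
    xyz = atlas.nodes
    ap = float(xyz[:, 0].max() - xyz[:, 0].min())
    ml = float((xyz[:, 1].max() - xyz[:, 1].min()) / MEDIAL_FOOTPRINT_FRACTION)
    center = xyz[:, :2].mean(axis=0)
    fem = atlas.node_sets["femoral_cartilage"]
    r2 = ((xyz[fem, :2] - center) ** 2).sum(axis=1)
    near = fem[r2 <= np.partition(r2, 3)[3] + 1e-12]  # ~4 nearest columns
    jsw = float(xyz[near, 2].max() - xyz[:, 2].min())
    return {"ml": ml, "ap_medial": ap, "jsw_medial": jsw}


# ---------------------------------------------------------------- library I/O

def save_library(library: AtlasLibrary, root) -> None:
    """Write one directory per atlas (mesh.vtk + atlas.json) plus library.json."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for a in library.atlases:
        d = root / a.atlas_id
        d.mkdir(exist_ok=True)
        vtkio.write_vtk(d / "mesh.vtk", a.nodes, a.elements,
                        {"split_line": a.split_line_field})
        meta = {
            "atlas_id": a.atlas_id,
            "dims": {k: getattr(a.dims, k) for k in
                     ("ml", "ap_medial", "ap_lateral", "jsw_medial", "jsw_lateral")},
            "meniscus_fraction": a.meniscus_fraction,
            "counter_surface": a.counter_surface,
            "node_sets": {k: np.asarray(v).tolist() for k, v in a.node_sets.items()},
        }
        (d / "atlas.json").write_text(json.dumps(meta, indent=1))
    index = {"atlases": [a.atlas_id for a in library.atlases]}
    (root / "library.json").write_text(json.dumps(index, indent=1))


def load_library(root) -> AtlasLibrary:
    root = Path(root)
    index = json.loads((root / "library.json").read_text())
    atlases = []
    for aid in index["atlases"]:
        d = root / aid
        meta = json.loads((d / "atlas.json").read_text())
        nodes, elements, cvec = vtkio.read_vtk(d / "mesh.vtk")
        atlases.append(TemplateAtlas(
            atlas_id=meta["atlas_id"],
            nodes=nodes,
            elements=elements,
            node_sets={k: np.asarray(v, dtype=int)
                       for k, v in meta["node_sets"].items()},
            dims=AnatomicalDimensions(**meta["dims"]),
            meniscus_fraction=meta["meniscus_fraction"],
            split_line_field=cvec["split_line"],
            counter_surface=meta.get("counter_surface", {}),
        ))
    return AtlasLibrary(atlases)
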