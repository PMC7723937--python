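"""Minimal legacy-ASCII VTK unstructured-grid I/O for hexahedral meshes.

Supports exactly what the atlas meshes need: POINTS, CELLS of type 12
(linear hexahedron) and optional per-cell vector data. Coordinates are
written with 17 significant digits so a write/read round trip is exact.
"""

from __future__ import annotations

import numpy as np

VTK_HEX = 12


def write_vtk(path, nodes: np.ndarray, elements: np.ndarray,
              cell_vectors: dict[str, np.ndarray] | None = None) -> None:
    nodes = np.asarray(nodes, dtype=float)
    elements = np.asarray(elements, dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncartatlas mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for p in nodes:
            fh.write("%.17g %.17g %.17g\n" % tuple(p))
        fh.write(f"CELLS {len(elements)} {len(elements) * 9}\n")
        for e in elements:
            fh.write("8 " + " ".join(str(i) for i in e) + "\n")
        fh.write(f"CELL_TYPES {len(elements)}\n")
        fh.write("\n".join(["12"] * len(elements)) + "\n")
        if cell_vectors:
            fh.write(f"CELL_DATA {len(elements)}\n")
            for name, vec in cell_vectors.items():
                vec = np.asarray(vec, dtype=float)
                fh.write(f"VECTORS {name} double\n")
                for v in vec:
                    fh.write("%.17g %.17g %.17g\n" % tuple(v))


def read_vtk(path):
    """Read a legacy ASCII unstructured grid written by :func:`write_vtk`.

    Returns ``(nodes, elements, cell_vectors)``.
    """
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))
    pos = 0

    def expect(word):
        nonlocal pos
        while tokens[pos].upper() != word:
            pos += 1
        pos += 1

    expect("POINTS")
    npts = int(tokens[pos]); pos += 2  # skip dtype
    nodes = np.array(tokens[pos:pos + 3 * npts], dtype=float).reshape(npts, 3)
    pos += 3 * npts
    expect("CELLS")
    ncell = int(tokens[pos]); pos += 2  # skip size
    elements = np.empty((ncell, 8), dtype=int)
    for i in range(ncell):
        n = int(tokens[pos]); pos += 1
        if n != 8:
            raise ValueError("only hexahedral cells are supported")
        elements[i] = [int(t) for t in tokens[pos:pos + 8]]
        pos += 8
    expect("CELL_TYPES")
    pos += 1 + ncell
    cell_vectors: dict[str, np.ndarray] = {}
    while pos < len(tokens):
        if tokens[pos].upper() == "VECTORS":
            name = tokens[pos + 1]
            pos += 3
            vec = np.array(tokens[pos:pos + 3 * ncell], dtype=float)
            cell_vectors[name] = vec.reshape(ncell, 3)
            pos += 3 * ncell
        else:
            pos += 1
    return nodes, elements, cell_vectors
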