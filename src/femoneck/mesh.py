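"""Tetrahedral mesh container and plain-text mesh I/O.

The organ-level geometry is a 4-node (optionally 10-node) tetrahedral volume
mesh with a triangulated boundary surface and named surface node sets
(femoral head, condyles, trochanters, neck, patella groove).  Node
coordinates are millimetres throughout.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = ["TetMesh", "tet_volumes", "extract_surface", "write_vtu", "write_msh", "read_msh"]


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of 4-node tetrahedra (positive for right-handed order)."""
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def extract_surface(tets: np.ndarray) -> np.ndarray:
    """Boundary triangles of a tet mesh, outward oriented.

    Faces appearing in exactly one tetrahedron form the boundary.  The local
    face ordering of a positive-volume tet makes each returned triangle wind
    outward.
    """
    # local faces with outward normals for a positively oriented tet
    faces = np.concatenate([
        tets[:, [0, 2, 1]],
        tets[:, [0, 1, 3]],
        tets[:, [1, 2, 3]],
        tets[:, [0, 3, 2]],
    ])
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


@dataclass
class TetMesh:
    """Tetrahedral volume mesh with named surface node sets.

    Attributes
    ----------
    nodes : (n, 3) float array, mm
    tets : (m, 4) or (m, 10) int array
        10-node meshes keep corner nodes in columns 0..3 and edge midside
        nodes in the Gmsh/ANSYS order 01,12,20,03,13,23.
    surface : (s, 3) int array
        Outward-oriented boundary triangles (corner node ids).
    node_sets : dict of name -> int array (surface node ids)
    frame : dict
        Anatomical frame metadata: unit vectors ``anterior``, ``medial``,
        ``superior`` in mesh coordinates.
    ground_truth : dict
        Construction parameters (present for synthetic meshes only).
    """

    nodes: np.ndarray
    tets: np.ndarray
    surface: np.ndarray
    node_sets: dict = field(default_factory=dict)
    frame: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def order(self) -> int:
        return 1 if self.tets.shape[1] == 4 else 2

    @property
    def surface_nodes(self) -> np.ndarray:
        return np.unique(self.surface)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets[:, :4])

    def validate(self) -> None:
        """Check the mesh invariants; raise ``ValueError`` on violation."""
        vols = self.volumes()
        if not np.all(vols > 0):
            bad = int(np.argmin(vols))
            raise ValueError(f"non-positive tet volume at element {bad}: {vols[bad]:g}")
        surf = set(self.surface_nodes.tolist())
        for name, ids in self.node_sets.items():
            if len(ids) == 0:
                raise ValueError(f"named node set {name!r} is empty")
            if not set(np.asarray(ids).tolist()) <= surf:
                raise ValueError(f"named node set {name!r} contains non-surface nodes")
        # closed surface: every edge shared by exactly two boundary triangles
        edges = np.concatenate([self.surface[:, [0, 1]], self.surface[:, [1, 2]],
                                self.surface[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError("surface is not closed / not manifold")

    def to_quadratic(self) -> "TetMesh":
        """Promote a 4-node mesh to 10-node by inserting edge midside nodes."""
        if self.order == 2:
            return self
        edge_local = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
        edges = np.concatenate([self.tets[:, list(e)] for e in edge_local])
        key = np.sort(edges, axis=1)
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        mid = 0.5 * (self.nodes[uniq[:, 0]] + self.nodes[uniq[:, 1]])
        mid_ids = self.n_nodes + inv.reshape(6, -1).T
        tets10 = np.hstack([self.tets, mid_ids]).astype(np.int64)
        return TetMesh(np.vstack([self.nodes, mid]), tets10, self.surface,
                       dict(self.node_sets), dict(self.frame), dict(self.ground_truth))

    # ---- I/O -------------------------------------------------------------

    def surface_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.nodes, faces=self.surface, process=False)

    def write_stl(self, path: str) -> None:
        self.surface_trimesh().export(path)

    def write(self, path: str) -> None:
        """Write VTU (``.vtu``) or Gmsh MSH 4.1 ASCII (``.msh``) by extension."""
        if str(path).endswith(".vtu"):
            write_vtu(path, self.nodes, self.tets)
        elif str(path).endswith(".msh"):
            write_msh(path, self.nodes, self.tets)
        else:
            raise ValueError(f"unsupported mesh extension: {path}")

    def write_meta(self, path: str) -> None:
        meta = {
            "frame": {k: np.asarray(v).tolist() for k, v in self.frame.items()},
            "ground_truth": _jsonable(self.ground_truth),
            "node_sets": {k: np.asarray(v).tolist() for k, v in self.node_sets.items()},
        }
        with open(path, "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def read_msh(cls, path: str, meta_path: str | None = None) -> "TetMesh":
        nodes, tets = read_msh(path)
        mesh = cls(nodes, tets, extract_surface(tets[:, :4]))
        if meta_path:
            with open(meta_path) as fh:
                meta = json.load(fh)
            mesh.frame = {k: np.asarray(v) for k, v in meta.get("frame", {}).items()}
            mesh.ground_truth = meta.get("ground_truth", {})
            mesh.node_sets = {k: np.asarray(v, dtype=np.int64)
                              for k, v in meta.get("node_sets", {}).items()}
        return mesh


def _jsonable(d):
    out = {}
    for k, v in d.items():
        v = np.asarray(v)
        out[k] = v.tolist() if v.ndim else float(v) if v.dtype.kind == "f" else v.item()
    return out


# VTK cell type ids
_VTK_TET4, _VTK_TET10 = 10, 24


def write_vtu(path: str, nodes: np.ndarray, cells: np.ndarray,
              point_data: dict | None = None, cell_data: dict | None = None) -> None:
    """Minimal ASCII VTU (VTK XML unstructured grid) writer for tet meshes."""
    npts, ncell = len(nodes), len(cells)
    k = cells.shape[1]
    ctype = _VTK_TET4 if k == 4 else _VTK_TET10
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        fh.write(f'<UnstructuredGrid><Piece NumberOfPoints="{npts}" NumberOfCells="{ncell}">\n')
        fh.write('<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        np.savetxt(fh, nodes, fmt="%.9g")
        fh.write('</DataArray></Points>\n<Cells>\n')
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        np.savetxt(fh, cells, fmt="%d")
        fh.write('</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        np.savetxt(fh, np.arange(1, ncell + 1) * k, fmt="%d")
        fh.write('</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
        np.savetxt(fh, np.full(ncell, ctype), fmt="%d")
        fh.write('</DataArray>\n</Cells>\n')
        for tag, data in (("PointData", point_data), ("CellData", cell_data)):
            if data:
                fh.write(f"<{tag}>\n")
                for name, arr in data.items():
                    arr = np.atleast_2d(np.asarray(arr, float))
                    if arr.shape[0] == 1:
                        arr = arr.T
                    fh.write(f'<DataArray type="Float64" Name="{name}" '
                             f'NumberOfComponents="{arr.shape[1]}" format="ascii">\n')
                    np.savetxt(fh, arr, fmt="%.9g")
                    fh.write('</DataArray>\n')
                fh.write(f"</{tag}>\n")
        fh.write('</Piece></UnstructuredGrid></VTKFile>\n')


def write_msh(path: str, nodes: np.ndarray, tets: np.ndarray) -> None:
    """Gmsh MSH v4.1 ASCII writer (single 3-D entity, tet4 or tet10)."""
    etype = 4 if tets.shape[1] == 4 else 11
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        fh.write("$Entities\n0 0 0 1\n1 0 0 0 0 0 0 0 0\n$EndEntities\n")
        fh.write(f"$Nodes\n1 {len(nodes)} 1 {len(nodes)}\n")
        fh.write(f"3 1 0 {len(nodes)}\n")
        for i in range(len(nodes)):
            fh.write(f"{i + 1}\n")
        for p in nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n1 {len(tets)} 1 {len(tets)}\n")
        fh.write(f"3 1 {etype} {len(tets)}\n")
        for i, conn in enumerate(tets + 1):
            fh.write(str(i + 1) + " " + " ".join(map(str, conn)) + "\n")
        fh.write("$EndElements\n")


def read_msh(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a Gmsh MSH v4.1 ASCII file written by :func:`write_msh`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = lines.index("$Nodes")
    _, total, _, _ = map(int, lines[i + 1].split())
    j = i + 2
    coords = np.empty((total, 3))
    ids = np.empty(total, dtype=np.int64)
    filled = 0
    while filled < total:
        _, _, _, nblk = map(int, lines[j].split())
        j += 1
        for k in range(nblk):
            ids[filled + k] = int(lines[j + k])
        j += nblk
        for k in range(nblk):
            coords[filled + k] = [float(x) for x in lines[j + k].split()]
        j += nblk
        filled += nblk
    order = np.argsort(ids)
    coords = coords[order]
    remap = {int(ids[o]): n for n, o in enumerate(order)}
    i = lines.index("$Elements")
    _, total, _, _ = map(int, lines[i + 1].split())
    j = i + 2
    conn = []
    read = 0
    while read < total:
        _, _, etype, nblk = map(int, lines[j].split())
        j += 1
        for k in range(nblk):
            parts = [int(x) for x in lines[j + k].split()]
            conn.append([remap[p] for p in parts[1:]])
        j += nblk
        read += nblk
    return coords, np.asarray(conn, dtype=np.int64)
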