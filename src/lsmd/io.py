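"""PLY and STL readers/writers (ASCII and binary little-endian), mm units.

Only triangle meshes are supported.  STL stores three vertex records per
facet; on load, records with bit-identical coordinates are merged so shared
vertices become a single index (STL writers emit identical floats for shared
corners, so exact hashing suffices — no tolerance merging).

Registered meshes may carry a per-vertex displacement written as three extra
PLY properties ``ux uy uz``.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .mesh import MeshFormatError, TriangleMesh

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def load_mesh(path, fmt: str | None = None):
    """Read a PLY or STL file into a :class:`TriangleMesh`.

    Returns ``(mesh, extra)`` unpacking is not needed by callers: the return
    value is the mesh; any extra per-vertex PLY properties are attached as
    ``mesh.vertex_data`` (dict of name -> array), notably the displacement
    triple ``ux, uy, uz``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such mesh file: {path}")
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    if fmt == "ply":
        return _load_ply(path)
    if fmt == "stl":
        return _load_stl(path)
    raise MeshFormatError(f"unsupported mesh format {fmt!r}")


def save_mesh(mesh: TriangleMesh, path, fmt: str | None = None, *,
              binary: bool = False, displacement: np.ndarray | None = None) -> None:
    """Write PLY (optionally with a per-vertex ``ux uy uz`` triple) or STL."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    if fmt == "ply":
        _save_ply(mesh, path, binary=binary, displacement=displacement)
    elif fmt == "stl":
        if displacement is not None:
            raise MeshFormatError("STL cannot carry per-vertex displacement")
        _save_stl(mesh, path, binary=binary)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")


# ---------------------------------------------------------------------------
# PLY

def _load_ply(path: Path) -> TriangleMesh:
    raw = path.read_bytes()
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise MeshFormatError(f"{path} is not a PLY file")
    end = raw.index(b"\n", end) + 1
    header = raw[:end].decode("ascii", errors="replace").splitlines()
    body = raw[end:]

    fmt = None
    elements: list[tuple[str, int, list]] = []  # (name, count, [props])
    for line in header[1:]:
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if tok[1] == "list":
                elements[-1][2].append(("list", _PLY_DTYPES[tok[2]],
                                        _PLY_DTYPES[tok[3]], tok[4]))
            else:
                elements[-1][2].append(("scalar", _PLY_DTYPES[tok[1]], tok[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshFormatError(f"unsupported PLY format {fmt!r}")

    vertices = faces = None
    vertex_data: dict[str, np.ndarray] = {}
    if fmt == "ascii":
        tokens = body.split()
        pos = 0
        for name, count, props in elements:
            if any(p[0] == "list" for p in props):
                rows = []
                for _ in range(count):
                    n = int(tokens[pos]); pos += 1
                    rows.append([int(t) for t in tokens[pos:pos + n]])
                    pos += n
                if name == "face":
                    faces = _triangulate(rows)
            else:
                width = len(props)
                block = np.array(tokens[pos:pos + count * width],
                                 dtype=np.float64).reshape(count, width)
                pos += count * width
                if name == "vertex":
                    vertices, vertex_data = _split_vertex_block(block, props)
    else:
        offset = 0
        for name, count, props in elements:
            if any(p[0] == "list" for p in props):
                rows = []
                cdt, idt = np.dtype("<" + props[0][1]), np.dtype("<" + props[0][2])
                for _ in range(count):
                    n = int(np.frombuffer(body, cdt, 1, offset)[0])
                    offset += cdt.itemsize
                    rows.append(np.frombuffer(body, idt, n, offset).tolist())
                    offset += idt.itemsize * n
                if name == "face":
                    faces = _triangulate(rows)
            else:
                dt = np.dtype([(p[2], "<" + p[1]) for p in props])
                block = np.frombuffer(body, dt, count, offset)
                offset += dt.itemsize * count
                if name == "vertex":
                    cols = np.column_stack([block[p[2]].astype(np.float64)
                                            for p in props])
                    vertices, vertex_data = _split_vertex_block(cols, props)
    if vertices is None or faces is None:
        raise MeshFormatError(f"{path}: PLY missing vertex or face element")
    mesh = TriangleMesh(vertices, faces)
    mesh.vertex_data = vertex_data
    return mesh


def _split_vertex_block(block, props):
    names = [p[2] for p in props]
    for ax in "xyz":
        if ax not in names:
            raise MeshFormatError("PLY vertex element lacks x/y/z")
    vertices = block[:, [names.index(a) for a in "xyz"]]
    extra = {n: block[:, i] for i, n in enumerate(names) if n not in "xyz"}
    return vertices, extra


def _triangulate(rows) -> np.ndarray:
    for r in rows:
        if len(r) != 3:
            raise MeshFormatError("non-triangular PLY face encountered")
    return np.asarray(rows, dtype=np.int64)


def _save_ply(mesh, path, *, binary, displacement):
    v = mesh.vertices
    cols = [v]
    extra_names = []
    if displacement is not None:
        displacement = np.asarray(displacement, dtype=np.float64)
        if displacement.shape != v.shape:
            raise MeshFormatError("displacement shape must match vertices")
        cols.append(displacement)
        extra_names = ["ux", "uy", "uz"]
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {len(v)}"]
    header += [f"property double {n}" for n in ("x", "y", "z")]
    header += [f"property double {n}" for n in extra_names]
    header += [f"element face {mesh.n_faces}",
               "property list uchar int vertex_indices", "end_header"]
    data = np.hstack(cols)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(data.astype("<f8").tobytes())
            face_dt = np.dtype([("n", "u1"), ("idx", "<i4", 3)])
            frec = np.empty(mesh.n_faces, face_dt)
            frec["n"] = 3
            frec["idx"] = mesh.faces
            fh.write(frec.tobytes())
        else:
            for row in data:
                fh.write((" ".join(repr(float(x)) for x in row) + "\n").encode())
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode())


# ---------------------------------------------------------------------------
# STL

def _load_stl(path: Path) -> TriangleMesh:
    raw = path.read_bytes()
    if raw[:5].lower() == b"solid" and b"facet" in raw[:200]:
        tri = _parse_stl_ascii(raw)
    else:
        if len(raw) < 84:
            raise MeshFormatError(f"{path}: truncated binary STL")
        (n,) = struct.unpack("<I", raw[80:84])
        rec = np.dtype([("normal", "<f4", 3), ("v", "<f4", (3, 3)),
                        ("attr", "<u2")])
        body = np.frombuffer(raw, rec, n, 84)
        tri = body["v"].astype(np.float64)
    return _merge_stl_triangles(tri)


def _parse_stl_ascii(raw: bytes) -> np.ndarray:
    verts = []
    for line in raw.decode("ascii", errors="replace").splitlines():
        tok = line.split()
        if tok[:1] == ["vertex"]:
            verts.append([float(t) for t in tok[1:4]])
    if len(verts) % 3:
        raise MeshFormatError("ASCII STL vertex count not a multiple of 3")
    return np.asarray(verts, dtype=np.float64).reshape(-1, 3, 3)


def _merge_stl_triangles(tri: np.ndarray) -> TriangleMesh:
    flat = tri.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    mesh = TriangleMesh(uniq, faces)
    mesh.vertex_data = {}
    return mesh


def _save_stl(mesh, path, *, binary):
    v = mesh.vertices
    tri = v[mesh.faces]  # (M, 3, 3)
    normals = mesh.face_normals()
    if binary:
        rec = np.dtype([("normal", "<f4", 3), ("v", "<f4", (3, 3)),
                        ("attr", "<u2")])
        body = np.zeros(mesh.n_faces, rec)
        body["normal"] = normals
        body["v"] = tri
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", mesh.n_faces))
            fh.write(body.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid lsmd\n")
            for fn, t in zip(normals, tri):
                fh.write(f"  facet normal {fn[0]:.9e} {fn[1]:.9e} {fn[2]:.9e}\n")
                fh.write("    outer loop\n")
                for p in t:
                    fh.write(f"      vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid lsmd\n")
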