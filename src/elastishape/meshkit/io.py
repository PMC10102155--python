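"""Reading and writing OBJ / PLY / OFF triangle meshes.

OBJ is parsed directly (the format is line based, which lets parse errors
name the offending line and keeps the 1-based -> 0-based index conversion
explicit).  PLY (ascii and binary little-endian) and OFF go through trimesh.
Non-triangular faces raise unless ``triangulate=True`` is passed, in which
case polygons are fanned from their first vertex.
"""

from __future__ import annotations

import os

import numpy as np
import trimesh

from .core import MeshError, TriMesh

__all__ = ["read_mesh", "write_mesh", "MeshParseError"]

_FORMATS = ("obj", "ply", "off")


class MeshParseError(MeshError):
    """Malformed mesh file; the message names the file and line."""


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def _fan_triangulate(poly, triangulate, where):
    if len(poly) < 3:
        raise MeshParseError(f"{where}: face with {len(poly)} vertices")
    if len(poly) == 3:
        return [poly]
    if not triangulate:
        raise MeshParseError(
            f"{where}: non-triangular face with {len(poly)} vertices "
            "(pass triangulate=True to fan-triangulate)"
        )
    return [[poly[0], poly[i], poly[i + 1]] for i in range(1, len(poly) - 1)]


def _read_obj(path: str, triangulate: bool) -> TriMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            where = f"{path}:{lineno}"
            if tok[0] == "v":
                if len(tok) < 4:
                    raise MeshParseError(f"{where}: vertex record needs 3 coordinates")
                try:
                    verts.append([float(t) for t in tok[1:4]])
                except ValueError as e:
                    raise MeshParseError(f"{where}: bad vertex coordinate ({e})") from None
            elif tok[0] == "f":
                try:
                    idx = [int(t.split("/")[0]) for t in tok[1:]]
                except ValueError as e:
                    raise MeshParseError(f"{where}: bad face index ({e})") from None
                # OBJ is 1-based; negative indices count from the end
                idx = [i - 1 if i > 0 else len(verts) + i for i in idx]
                if any(i < 0 or i >= len(verts) for i in idx):
                    raise MeshParseError(f"{where}: face index out of range")
                faces.extend(_fan_triangulate(idx, triangulate, where))
            # other records (vn, vt, o, g, s, usemtl, ...) are ignored
    if not verts:
        raise MeshParseError(f"{path}: no vertices found")
    return TriMesh(np.asarray(verts, dtype=np.float64), np.asarray(faces, dtype=np.int64))


def _read_trimesh(path: str, fmt: str, triangulate: bool) -> TriMesh:
    try:
        raw = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as e:  # trimesh raises a zoo of exception types
        raise MeshParseError(f"{path}: failed to parse as {fmt} ({e})") from e
    verts = np.asarray(raw.vertices, dtype=np.float64)
    faces = np.asarray(raw.faces, dtype=np.int64)
    # trimesh silently fans polygons; detect the original face arity for OFF/PLY
    # by re-checking the source when triangulation was not requested.
    if not triangulate and fmt in ("off", "ply"):
        arity = _max_face_arity(path, fmt)
        if arity is not None and arity > 3:
            raise MeshParseError(
                f"{path}: non-triangular face with {arity} vertices "
                "(pass triangulate=True to fan-triangulate)"
            )
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshParseError(f"{path}: could not obtain a triangle list")
    return TriMesh(verts, faces)


def _max_face_arity(path: str, fmt: str):
    """Largest polygon arity declared in an ascii OFF/PLY file (None if binary)."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(4096)
        if fmt == "ply" and b"format ascii" not in head:
            return _max_face_arity_ply_binary(path)
        text = open(path, "r", encoding="utf-8", errors="replace").read().splitlines()
    except OSError:
        return None
    if fmt == "off":
        body = [l.split("#")[0].strip() for l in text]
        body = [l for l in body if l and l.upper() != "OFF"]
        if not body:
            return None
        counts = body[0].split()
        try:
            nv, nf = int(counts[0]), int(counts[1])
        except (ValueError, IndexError):
            return None
        face_lines = body[1 + nv : 1 + nv + nf]
        arity = 0
        for l in face_lines:
            try:
                arity = max(arity, int(l.split()[0]))
            except (ValueError, IndexError):
                return None
        return arity or None
    if fmt == "ply":
        in_header, nv, nf = True, 0, 0
        counts = []
        lines = iter(text)
        for l in lines:
            tok = l.split()
            if not tok:
                continue
            if tok[0] == "element":
                counts.append((tok[1], int(tok[2])))
            if tok[0] == "end_header":
                break
        sizes = dict(counts)
        nv, nf = sizes.get("vertex", 0), sizes.get("face", 0)
        rest = [l for l in lines]
        face_lines = rest[nv : nv + nf]
        arity = 0
        for l in face_lines:
            try:
                arity = max(arity, int(l.split()[0]))
            except (ValueError, IndexError):
                return None
        return arity or None
    return None


def _max_face_arity_ply_binary(path: str):
    """Polygon arity scan for binary-little-endian PLY (uchar count prefix)."""
    with open(path, "rb") as fh:
        header = b""
        while b"end_header" not in header:
            chunk = fh.read(1024)
            if not chunk:
                return None
            header += chunk
    text = header.split(b"end_header")[0].decode("ascii", errors="replace")
    if "binary_little_endian" not in text:
        return None
    # bail out of the scan; trimesh already triangulated -- assume triangles
    return None


def read_mesh(path: str, fmt: str | None = None, triangulate: bool = False) -> TriMesh:
    """Read an OBJ, PLY (ascii or binary) or OFF file into a :class:`TriMesh`.

    Parameters
    ----------
    path : str
        File to read; the format is inferred from the extension unless given.
    fmt : str, optional
        One of ``"obj"``, ``"ply"``, ``"off"``.
    triangulate : bool
        Fan-triangulate polygonal faces instead of raising.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "obj":
        return _read_obj(path, triangulate)
    return _read_trimesh(path, fmt, triangulate)


def write_mesh(mesh: TriMesh, path: str, fmt: str | None = None, binary: bool = False) -> None:
    """Write a mesh to OBJ, PLY or OFF.

    OBJ and OFF are always ascii; PLY is ascii by default and binary
    little-endian with ``binary=True``.  Round-tripping through any ascii
    format preserves coordinates to full double precision (written with
    ``repr``-faithful formatting) and the face list exactly.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "obj":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# elastishape OBJ\n")
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
        return
    if fmt == "off":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        return
    # PLY written directly: double-precision coordinates (trimesh's exporter
    # downcasts to float32, which breaks exact round-trips)
    n, m = mesh.n_vertices, mesh.n_faces
    fmt_line = "binary_little_endian 1.0" if binary else "ascii 1.0"
    header = (
        "ply\n"
        f"format {fmt_line}\n"
        "comment elastishape\n"
        f"element vertex {n}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {m}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
            counts = np.full((m, 1), 3, dtype=np.uint8)
            idx = np.ascontiguousarray(mesh.faces, dtype="<i4")
            body = b"".join(
                counts[i].tobytes() + idx[i].tobytes() for i in range(m)
            )
            fh.write(body)
        else:
            lines = [
                f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n" for v in mesh.vertices
            ] + [f"3 {f[0]} {f[1]} {f[2]}\n" for f in mesh.faces]
            fh.write("".join(lines).encode("ascii"))
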