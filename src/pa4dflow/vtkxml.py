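"""Minimal ASCII VTK XML readers/writers for unstructured grids and polydata.

Covers the subset of the format this package exchanges with visualisation
tools: .vtu files holding tetrahedra (cell type 10) plus optional boundary
triangles (cell type 5) with point/cell data arrays, and .vtp files holding
polylines with point data.  Data are always written in ascii format,
little-endian declaration, Float64/Int64 arrays.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from typing import Optional

import numpy as np

VTK_TET = 10
VTK_TRIANGLE = 5

_TYPE_MAP = {
    "Float64": float, "Float32": float,
    "Int64": np.int64, "Int32": np.int64, "UInt8": np.int64,
}


def _fmt_array(a: np.ndarray) -> str:
    a = np.asarray(a)
    if np.issubdtype(a.dtype, np.floating):
        return " ".join(repr(float(v)) for v in a.ravel())
    return " ".join(str(int(v)) for v in a.ravel())


def _data_array(name: Optional[str], a: np.ndarray, ncomp: int = 1) -> ET.Element:
    a = np.asarray(a)
    vtype = "Float64" if np.issubdtype(a.dtype, np.floating) else "Int64"
    el = ET.Element("DataArray", type=vtype, format="ascii")
    if name:
        el.set("Name", name)
    if ncomp != 1:
        el.set("NumberOfComponents", str(ncomp))
    el.text = _fmt_array(a)
    return el


def _parse_data_array(el: ET.Element) -> np.ndarray:
    dtype = _TYPE_MAP.get(el.get("type", "Float64"), float)
    text = el.text or ""
    vals = np.array(text.split(), dtype=float).astype(dtype)
    ncomp = int(el.get("NumberOfComponents", "1"))
    if ncomp > 1:
        vals = vals.reshape(-1, ncomp)
    return vals


def write_vtu(path, points: np.ndarray, tets: np.ndarray,
              triangles: Optional[np.ndarray] = None,
              point_data: Optional[dict[str, np.ndarray]] = None,
              cell_data: Optional[dict[str, np.ndarray]] = None) -> None:
    """Write a tet (+ optional boundary-triangle) mesh as ascii .vtu.

    ``cell_data`` arrays must cover tets first, then triangles.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tets = np.asarray(tets, dtype=np.int64).reshape(-1, 4)
    tris = (np.asarray(triangles, dtype=np.int64).reshape(-1, 3)
            if triangles is not None else np.zeros((0, 3), np.int64))
    n_cells = len(tets) + len(tris)
    conn = np.concatenate([tets.ravel(), tris.ravel()])
    offsets = np.concatenate([
        4 * (np.arange(len(tets)) + 1),
        4 * len(tets) + 3 * (np.arange(len(tris)) + 1),
    ])
    types = np.concatenate([
        np.full(len(tets), VTK_TET), np.full(len(tris), VTK_TRIANGLE),
    ])

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(len(points)),
                          NumberOfCells=str(n_cells))
    pts_el = ET.SubElement(piece, "Points")
    pts_el.append(_data_array(None, points, 3))
    cells_el = ET.SubElement(piece, "Cells")
    cells_el.append(_data_array("connectivity", conn))
    cells_el.append(_data_array("offsets", offsets))
    cells_el.append(_data_array("types", types))
    if point_data:
        pd_el = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = arr.shape[1] if arr.ndim == 2 else 1
            pd_el.append(_data_array(name, arr, ncomp))
    if cell_data:
        cd_el = ET.SubElement(piece, "CellData")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            ncomp = arr.shape[1] if arr.ndim == 2 else 1
            cd_el.append(_data_array(name, arr, ncomp))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_vtu(path) -> dict:
    """Read an ascii .vtu written by :func:`write_vtu` (or equivalent).

    Returns dict with ``points``, ``tets``, ``triangles``, ``point_data``,
    ``cell_data`` (cell arrays split into ``(tet_part, tri_part)``).
    """
    piece = ET.parse(path).getroot().find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK unstructured grid file")
    points = _parse_data_array(piece.find("./Points/DataArray")).reshape(-1, 3)
    arrays = {el.get("Name"): el for el in piece.findall("./Cells/DataArray")}
    conn = _parse_data_array(arrays["connectivity"]).astype(np.int64).ravel()
    offsets = _parse_data_array(arrays["offsets"]).astype(np.int64).ravel()
    types = _parse_data_array(arrays["types"]).astype(np.int64).ravel()
    starts = np.concatenate([[0], offsets[:-1]])
    tets, tris = [], []
    for s, e, t in zip(starts, offsets, types):
        if t == VTK_TET:
            tets.append(conn[s:e])
        elif t == VTK_TRIANGLE:
            tris.append(conn[s:e])
        else:
            raise ValueError(f"unsupported VTK cell type {t}")
    tets = np.array(tets, np.int64).reshape(-1, 4)
    tris = np.array(tris, np.int64).reshape(-1, 3)

    def _collect(tag):
        out = {}
        sec = piece.find(tag)
        if sec is not None:
            for el in sec.findall("DataArray"):
                out[el.get("Name")] = _parse_data_array(el)
        return out

    cell_data = {}
    for name, arr in _collect("CellData").items():
        cell_data[name] = (arr[: len(tets)], arr[len(tets):])
    return {
        "points": points, "tets": tets, "triangles": tris,
        "point_data": _collect("PointData"), "cell_data": cell_data,
    }


def write_vtp(path, points: np.ndarray, lines: list[np.ndarray],
              point_data: Optional[dict[str, np.ndarray]] = None,
              polys: Optional[np.ndarray] = None) -> None:
    """Write polylines (and/or triangle polys) as ascii .vtp."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    root = ET.Element("VTKFile", type="PolyData", version="0.1",
                      byte_order="LittleEndian")
    pdata = ET.SubElement(root, "PolyData")
    polys_arr = (np.asarray(polys, np.int64).reshape(-1, 3)
                 if polys is not None else np.zeros((0, 3), np.int64))
    piece = ET.SubElement(pdata, "Piece", NumberOfPoints=str(len(points)),
                          NumberOfLines=str(len(lines)),
                          NumberOfPolys=str(len(polys_arr)))
    pts_el = ET.SubElement(piece, "Points")
    pts_el.append(_data_array(None, points, 3))
    if lines:
        lines_el = ET.SubElement(piece, "Lines")
        conn = np.concatenate([np.asarray(l, np.int64).ravel() for l in lines])
        offsets = np.cumsum([len(l) for l in lines])
        lines_el.append(_data_array("connectivity", conn))
        lines_el.append(_data_array("offsets", offsets))
    if len(polys_arr):
        polys_el = ET.SubElement(piece, "Polys")
        polys_el.append(_data_array("connectivity", polys_arr.ravel()))
        polys_el.append(_data_array("offsets", 3 * (np.arange(len(polys_arr)) + 1)))
    if point_data:
        pd_el = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = arr.shape[1] if arr.ndim == 2 else 1
            pd_el.append(_data_array(name, arr, ncomp))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def read_vtp(path) -> dict:
    """Read an ascii .vtp; returns points, list of line index arrays, point data."""
    piece = ET.parse(path).getroot().find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK polydata file")
    points = _parse_data_array(piece.find("./Points/DataArray")).reshape(-1, 3)
    lines: list[np.ndarray] = []
    lines_el = piece.find("Lines")
    if lines_el is not None:
        arrays = {el.get("Name"): el for el in lines_el.findall("DataArray")}
        conn = _parse_data_array(arrays["connectivity"]).astype(np.int64).ravel()
        offsets = _parse_data_array(arrays["offsets"]).astype(np.int64).ravel()
        start = 0
        for off in offsets:
            lines.append(conn[start:off])
            start = off
    point_data = {}
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for el in pd_el.findall("DataArray"):
            point_data[el.get("Name")] = _parse_data_array(el)
    return {"points": points, "lines": lines, "point_data": point_data}
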