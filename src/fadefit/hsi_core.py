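"""Hyperspectral cube data model and ENVI I/O.

A :class:`HyperCube` is a rows x cols x bands intensity array with a shared
wavelength axis, a modality tag (``reflectance`` or ``fluorescence``), a
boolean validity mask and free-form provenance metadata.  Cubes are stored on
disk as ENVI header/binary pairs (the de facto standard for hyperspectral
imagery); the mask travels as a one-band companion image on the same spatial
grid, since the ENVI format has no standard mask slot.

Spatial convention is (row, col), 0-based, row-major.  Spectral cropping uses
a closed interval [lo, hi] in nanometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SpectralAxis",
    "HyperCube",
    "PixelBlock",
    "StitchLayout",
    "Placement",
    "read_cube",
    "write_cube",
    "crop_spectral",
    "stitch",
    "extract",
    "to_pixel_block",
    "block_to_canvas",
]

MODALITIES = ("reflectance", "fluorescence", "pseudoabsorbance")


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing band-centre wavelengths in nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectral axis needs at least 2 bands")
        if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )

    def index_nearest(self, wavelength_nm: float) -> int:
        """Index of the band whose centre is closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class HyperCube:
    """3-D spectral image: data[row, col, band] with wavelength axis and mask.

    Masked-out pixels (mask False) are excluded from every downstream
    statistic; full-canvas renderings carry NaN at those positions.
    """

    data: np.ndarray
    axis: SpectralAxis
    modality: str
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"band count {self.data.shape[2]} != axis length {len(self.axis)}"
            )
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape must equal spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "HyperCube":
        return HyperCube(
            self.data.copy(), self.axis, self.modality, self.mask.copy(), dict(self.meta)
        )


@dataclass
class PixelBlock:
    """Pixels-as-rows matrix view of one or more cubes.

    ``spatial_index`` holds one (cube_id, row, col) triple per matrix row so
    results can be re-inserted into cube geometry; ``variable_labels`` holds
    one (block, wavelength_nm) pair per column, block in {"F", "R"}.
    """

    matrix: np.ndarray
    spatial_index: np.ndarray  # (n, 3) int
    variable_labels: list[tuple[str, float]]
    flags: dict = field(default_factory=dict)  # row index -> reason

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.spatial_index = np.asarray(self.spatial_index, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.spatial_index.shape != (self.matrix.shape[0], 3):
            raise ValueError("spatial_index must be (n_rows, 3)")
        if len(self.variable_labels) != self.matrix.shape[1]:
            raise ValueError("one variable label per column required")
        for blk in ("F", "R"):
            wl = [w for b, w in self.variable_labels if b == blk]
            if wl and np.any(np.diff(wl) <= 0):
                raise ValueError(f"{blk}-block wavelengths must be strictly increasing")

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]

    def with_matrix(self, matrix: np.ndarray, flags: dict | None = None) -> "PixelBlock":
        """Same geometry, new values (used by row/column transforms)."""
        merged = dict(self.flags)
        if flags:
            merged.update(flags)
        return PixelBlock(matrix, self.spatial_index, list(self.variable_labels), merged)


@dataclass(frozen=True)
class Placement:
    cube_id: int
    row_offset: int
    col_offset: int
    n_rows: int
    n_cols: int


@dataclass
class StitchLayout:
    """Non-overlapping placements of source cubes on a common canvas."""

    placements: list[Placement]

    @property
    def canvas_shape(self) -> tuple[int, int]:
        rows = max(p.row_offset + p.n_rows for p in self.placements)
        cols = max(p.col_offset + p.n_cols for p in self.placements)
        return rows, cols

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "cube_id": p.cube_id,
                    "row_offset": p.row_offset,
                    "col_offset": p.col_offset,
                    "n_rows": p.n_rows,
                    "n_cols": p.n_cols,
                }
                for p in self.placements
            ]
        )

    @classmethod
    def from_json(cls, text: str) -> "StitchLayout":
        return cls([Placement(**d) for d in json.loads(text)])

    @classmethod
    def row_layout(cls, shapes: Sequence[tuple[int, int]]) -> "StitchLayout":
        """Default layout: cubes side by side in one row, top-aligned."""
        placements = []
        col = 0
        for i, (r, c) in enumerate(shapes):
            placements.append(Placement(i, 0, col, r, c))
            col += c
        return cls(placements)


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

def _sibling(base: Path, ext: str) -> Path:
    """Append an extension without clobbering dots already in the name."""
    return base.parent / (base.name + ext)


_DTYPE_TO_ENVI = {np.dtype("float32"): 4, np.dtype("float64"): 5, np.dtype("uint8"): 1}
_ENVI_TO_DTYPE = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64}


def _write_envi_array(arr: np.ndarray, base: Path, extra: dict | None = None) -> None:
    if arr.ndim == 2:
        arr = arr[:, :, None]
    rows, cols, bands = arr.shape
    dtype = arr.dtype
    code = _DTYPE_TO_ENVI[np.dtype(dtype)]
    # BSQ on disk: band, line, sample
    arr.transpose(2, 0, 1).tofile(_sibling(base, ".dat"))
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        "interleave = bsq",
        "byte order = 0",
    ]
    for key, val in (extra or {}).items():
        lines.append(f"{key} = {val}")
    _sibling(base, ".hdr").write_text("\n".join(lines) + "\n")


def _parse_envi_header(path: Path) -> dict:
    text = path.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"{path} is not an ENVI header")
    header: dict[str, str] = {}
    body = text.split("\n", 1)[1] if "\n" in text else ""
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i]
        i += 1
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and "}" not in val:
            parts = [val]
            while i < len(lines) and "}" not in lines[i]:
                parts.append(lines[i])
                i += 1
            if i < len(lines):
                parts.append(lines[i])
                i += 1
            val = " ".join(parts)
        header[key] = val
    return header


def _read_envi_array(base: Path) -> tuple[np.ndarray, dict]:
    hdr_path = _sibling(base, ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    header = _parse_envi_header(hdr_path)
    rows = int(header["lines"])
    cols = int(header["samples"])
    bands = int(header["bands"])
    dtype = _ENVI_TO_DTYPE[int(header["data type"])]
    interleave = header.get("interleave", "bsq").lower()
    offset = int(header.get("header offset", 0))
    raw = np.fromfile(_sibling(base, ".dat"), dtype=dtype, offset=offset)
    expected = rows * cols * bands
    if raw.size != expected:
        raise ValueError(
            f"binary size {raw.size} does not match header {rows}x{cols}x{bands}"
        )
    if interleave == "bsq":
        arr = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        arr = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    return np.ascontiguousarray(arr), header


def _parse_envi_list(val: str) -> np.ndarray:
    val = val.strip()
    if not (val.startswith("{") and val.endswith("}")):
        raise ValueError("malformed ENVI list value")
    return np.array([float(x) for x in val[1:-1].replace("\n", " ").split(",") if x.strip()])


def write_cube(cube: HyperCube, path: str | Path) -> None:
    """Write a cube as an ENVI header/binary pair plus mask companion image.

    ``path`` is the base path; ``.hdr``/``.dat`` extensions are appended, and
    the mask goes to ``<base>.mask.hdr``/``.dat``.
    """
    if cube.data.shape[0] == 0 or cube.data.shape[1] == 0:
        raise ValueError("cannot write an empty cube (0 pixels)")
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    wl = ", ".join(f"{w:.6f}" for w in cube.axis.wavelengths)
    extra = {
        "wavelength units": "Nanometers",
        "wavelength": "{" + wl + "}",
        "modality": cube.modality,
        "description": "{" + json.dumps(cube.meta).replace("}", "\\u007d") + "}",
    }
    _write_envi_array(cube.data.astype(np.float64), base, extra)
    _write_envi_array(
        cube.mask.astype(np.uint8), Path(str(base) + ".mask"), {"description": "{validity mask}"}
    )


def read_cube(path: str | Path, modality: str | None = None) -> HyperCube:
    """Read an ENVI header/binary pair written by :func:`write_cube`.

    Also accepts third-party ENVI pairs (any of BIL/BIP/BSQ) as long as the
    header carries a ``wavelength`` list in nm; the mask companion is optional
    and defaults to all-true.
    """
    base = Path(path)
    arr, header = _read_envi_array(base)
    if "wavelength" not in header:
        raise ValueError("no spectral axis: header lacks a wavelength list")
    axis = SpectralAxis(_parse_envi_list(header["wavelength"]))
    mod = modality or header.get("modality", "reflectance")
    meta: dict = {}
    desc = header.get("description", "")
    if desc.startswith("{") and desc.endswith("}"):
        try:
            meta = json.loads(desc[1:-1].replace("\\u007d", "}"))
        except (json.JSONDecodeError, TypeError):
            meta = {"description": desc[1:-1].strip()}
    mask = None
    mask_base = Path(str(base) + ".mask")
    if _sibling(mask_base, ".hdr").exists():
        mask_arr, _ = _read_envi_array(mask_base)
        mask = mask_arr[:, :, 0].astype(bool)
    return HyperCube(arr, axis, mod, mask, meta if isinstance(meta, dict) else {})


# ---------------------------------------------------------------------------
# Spectral cropping, stitching, pixel-table conversion
# ---------------------------------------------------------------------------

def crop_spectral(cube: HyperCube, lo: float, hi: float) -> HyperCube:
    """Keep exactly the bands with lo <= wavelength <= hi (closed interval)."""
    if lo >= hi:
        raise ValueError("crop interval requires lo < hi")
    wl = cube.axis.wavelengths
    keep = (wl >= lo) & (wl <= hi)
    if not keep.any():
        raise ValueError(f"no bands in range [{lo}, {hi}]")
    return HyperCube(
        cube.data[:, :, keep],
        SpectralAxis(wl[keep]),
        cube.modality,
        cube.mask.copy(),
        dict(cube.meta),
    )


def stitch(
    cubes: Sequence[HyperCube], layout: StitchLayout | None = None
) -> tuple[HyperCube, StitchLayout]:
    """Place cubes on a common canvas; uncovered canvas pixels are masked out.

    Cubes may differ in spatial size but must share axis and modality.  The
    default layout places them side by side in one row.  The returned layout
    allows lossless extraction of each source region via :func:`extract`.
    """
    if not cubes:
        raise ValueError("nothing to stitch")
    axis = cubes[0].axis
    modality = cubes[0].modality
    for c in cubes[1:]:
        if c.axis != axis:
            raise ValueError("all cubes must share the same spectral axis")
        if c.modality != modality:
            raise ValueError("all cubes must share the same modality")
    if layout is None:
        layout = StitchLayout.row_layout([c.data.shape[:2] for c in cubes])
    if len(layout.placements) != len(cubes):
        raise ValueError("layout must have one placement per cube")
    rows, cols = layout.canvas_shape
    covered = np.zeros((rows, cols), dtype=bool)
    canvas = np.zeros((rows, cols, len(axis)))
    mask = np.zeros((rows, cols), dtype=bool)
    for p in layout.placements:
        c = cubes[p.cube_id]
        if c.data.shape[:2] != (p.n_rows, p.n_cols):
            raise ValueError(f"placement shape mismatch for cube {p.cube_id}")
        sl = (slice(p.row_offset, p.row_offset + p.n_rows),
              slice(p.col_offset, p.col_offset + p.n_cols))
        if covered[sl].any():
            raise ValueError("overlapping placements")
        covered[sl] = True
        canvas[sl] = c.data
        mask[sl] = c.mask
    meta = {"stitched_from": [dict(c.meta) for c in cubes]}
    return HyperCube(canvas, axis, modality, mask, meta), layout


def extract(canvas: HyperCube, layout: StitchLayout, cube_id: int) -> HyperCube:
    """Cut one source region back out of a stitched canvas."""
    (p,) = [p for p in layout.placements if p.cube_id == cube_id]
    sl = (slice(p.row_offset, p.row_offset + p.n_rows),
          slice(p.col_offset, p.col_offset + p.n_cols))
    meta = dict(canvas.meta)
    src = meta.pop("stitched_from", None)
    if src is not None and cube_id < len(src):
        meta = dict(src[cube_id])
    return HyperCube(canvas.data[sl].copy(), canvas.axis, canvas.modality,
                     canvas.mask[sl].copy(), meta)


def to_pixel_block(cube: HyperCube, cube_id: int = 0, block: str | None = None) -> PixelBlock:
    """Flatten unmasked pixels to rows (row-major order).

    ``block`` labels the columns "F" or "R"; default by modality
    (fluorescence -> F, anything reflectance-derived -> R).
    """
    if cube.n_valid == 0:
        raise ValueError("all pixels masked; nothing to tabulate")
    if block is None:
        block = "F" if cube.modality == "fluorescence" else "R"
    rr, cc = np.nonzero(cube.mask)
    matrix = cube.data[rr, cc, :]
    index = np.column_stack([np.full_like(rr, cube_id), rr, cc])
    labels = [(block, float(w)) for w in cube.axis.wavelengths]
    return PixelBlock(matrix, index, labels)


def block_to_canvas(
    block: PixelBlock, shape: tuple[int, int], columns: slice | None = None
) -> np.ndarray:
    """Re-insert block rows into canvas geometry; missing pixels become NaN."""
    cols = columns if columns is not None else slice(None)
    values = block.matrix[:, cols]
    out = np.full((shape[0], shape[1], values.shape[1]), np.nan)
    out[block.spatial_index[:, 1], block.spatial_index[:, 2], :] = values
    return out
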