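"""Circular-buffer extraction and landscape composition/configuration metrics.

Around each sampling site a set of circular buffers (100-4000 m in the
default design) is cut from a categorical land-use raster with seven
classes.  Within each buffer eleven driver variables are computed: the
seven class area proportions, three landscape-level configuration
metrics following FRAGSTATS conventions — Largest Patch Index (LPI, %),
Contagion (CONTAG, %), Shannon's Diversity Index (SHDI) — and the human
activity intensity of land surface (HAILS, %), a construction-land
equivalent computed from per-class conversion coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import PipelineConfig, SiteRecord, ValidationError

_EIGHT = np.ones((3, 3), dtype=int)  # patch connectivity structure


@dataclass
class LandUseGrid:
    """Categorical raster with integer class codes on a metric grid.

    ``codes[0, 0]`` is the top-left (north-west) cell, as in the ESRI
    ASCII format; ``xll``/``yll`` give the lower-left corner of the
    lower-left cell in projected metres.
    """

    codes: np.ndarray
    cellsize: float
    xll: float = 0.0
    yll: float = 0.0
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValidationError("land-use grid must be 2-D")
        if self.cellsize <= 0:
            raise ValidationError("cell size must be positive")
        if not np.issubdtype(self.codes.dtype, np.integer):
            self.codes = self.codes.astype(np.int64)

    @property
    def nrows(self) -> int:
        return self.codes.shape[0]

    @property
    def ncols(self) -> int:
        return self.codes.shape[1]

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, same shape as codes."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xll + (cols + 0.5) * self.cellsize
        y = self.yll + (self.nrows - 1 - rows + 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def contains(self, x: float, y: float) -> bool:
        return (
            self.xll <= x <= self.xll + self.ncols * self.cellsize
            and self.yll <= y <= self.yll + self.nrows * self.cellsize
        )

    # -- ESRI ASCII I/O ----------------------------------------------------

    @classmethod
    def from_ascii(cls, path) -> "LandUseGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValidationError(f"ESRI ASCII header missing {key}")
        body = np.loadtxt(lines[i:], dtype=float)
        body = np.atleast_2d(body)
        if body.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValidationError(
                f"grid body shape {body.shape} does not match header "
                f"({int(header['nrows'])}, {int(header['ncols'])})"
            )
        return cls(
            codes=body.astype(np.int64),
            cellsize=header["cellsize"],
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            nodata=int(header.get("nodata_value", -9999)),
        )

    def to_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll:g}\n")
            fh.write(f"yllcorner {self.yll:g}\n")
            fh.write(f"cellsize {self.cellsize:g}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            np.savetxt(fh, self.codes, fmt="%d")


# ---------------------------------------------------------------------------
# buffers and composition
# ---------------------------------------------------------------------------


def _site_xy(site) -> tuple[float, float]:
    if isinstance(site, SiteRecord):
        return site.x, site.y
    return float(site[0]), float(site[1])


def extract_buffer(grid: LandUseGrid, site, radius: float) -> np.ndarray:
    """Boolean mask of cells whose centre lies within ``radius`` of the site.

    The site is given as a ``SiteRecord`` (using its projected x/y) or an
    (x, y) tuple in the grid's coordinate system.
    """
    if radius < grid.cellsize:
        raise ValidationError(
            f"radius {radius} m smaller than cell size {grid.cellsize} m"
        )
    x0, y0 = _site_xy(site)
    if not np.isfinite([x0, y0]).all():
        raise ValidationError("site lacks projected coordinates")
    if not grid.contains(x0, y0):
        raise ValidationError(f"site ({x0}, {y0}) outside grid extent")
    xs, ys = grid.cell_centres()
    mask = (xs - x0) ** 2 + (ys - y0) ** 2 <= radius**2
    # warn when the circle pokes out of the raster
    if (
        x0 - radius < grid.xll
        or x0 + radius > grid.xll + grid.ncols * grid.cellsize
        or y0 - radius < grid.yll
        or y0 + radius > grid.yll + grid.nrows * grid.cellsize
    ):
        warnings.warn("buffer extends beyond grid edge; using the interior part")
    return mask


def landuse_proportions(
    grid: LandUseGrid, mask: np.ndarray, classes: Sequence[int] | None = None
) -> dict[int, float]:
    """Per-class cell proportions within the masked, non-NODATA area."""
    cells = grid.codes[mask]
    cells = cells[cells != grid.nodata]
    if cells.size == 0:
        raise ValidationError("buffer contains no valid (non-NODATA) cells")
    if classes is None:
        classes = sorted(np.unique(cells).tolist())
    total = cells.size
    return {int(c): float(np.count_nonzero(cells == c)) / total for c in classes}


def patch_label(grid: LandUseGrid, mask: np.ndarray) -> np.ndarray:
    """Patch id map: 8-connected components of equal class code within mask.

    Returns an integer array (0 outside the mask / NODATA; patch ids
    start at 1 and are unique across classes).
    """
    valid = mask & (grid.codes != grid.nodata)
    out = np.zeros(grid.codes.shape, dtype=np.int64)
    next_id = 0
    for code in np.unique(grid.codes[valid]):
        lab, n = ndimage.label(valid & (grid.codes == code), structure=_EIGHT)
        out[lab > 0] = lab[lab > 0] + next_id
        next_id += n
    return out


def metric_lpi(patches: np.ndarray, mask: np.ndarray) -> float:
    """Largest Patch Index: largest patch area as % of the masked area."""
    ids = patches[mask & (patches > 0)]
    if ids.size == 0:
        raise ValidationError("no patches in mask")
    counts = np.bincount(ids)
    return 100.0 * counts.max() / ids.size


def metric_shdi(proportions: Mapping[int, float] | Sequence[float]) -> float:
    """Shannon's Diversity Index over class area proportions."""
    p = np.asarray(
        list(proportions.values()) if isinstance(proportions, Mapping) else proportions,
        dtype=float,
    )
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError("proportions must sum to 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _adjacencies(grid: LandUseGrid, mask: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Double-counted 4-neighbour adjacency matrix g_ik within mask."""
    valid = mask & (grid.codes != grid.nodata)
    codes_present = sorted(np.unique(grid.codes[valid]).tolist())
    idx = {c: i for i, c in enumerate(codes_present)}
    m = len(codes_present)
    g = np.zeros((m, m), dtype=float)
    c = grid.codes
    # horizontal neighbours
    pair_ok = valid[:, :-1] & valid[:, 1:]
    a = c[:, :-1][pair_ok]
    b = c[:, 1:][pair_ok]
    # vertical neighbours
    pair_ok_v = valid[:-1, :] & valid[1:, :]
    av = c[:-1, :][pair_ok_v]
    bv = c[1:, :][pair_ok_v]
    aa = np.concatenate([a, av])
    bb = np.concatenate([b, bv])
    ia = np.vectorize(idx.get, otypes=[int])(aa) if aa.size else np.array([], int)
    ib = np.vectorize(idx.get, otypes=[int])(bb) if bb.size else np.array([], int)
    np.add.at(g, (ia, ib), 1.0)
    np.add.at(g, (ib, ia), 1.0)  # double count: each adjacency seen from both cells
    return g, codes_present


def metric_contag(grid: LandUseGrid, mask: np.ndarray) -> float:
    """Contagion index (%) from class proportions and cell adjacencies.

    CONTAG = [1 + sum_i sum_k P*_ik ln P*_ik / (2 ln m)] * 100 with
    P*_ik = P_i * g_ik / sum_k' g_ik'; a single-class mask is defined as
    100 (maximal contagion).
    """
    props = landuse_proportions(grid, mask)
    present = [c for c, p in props.items() if p > 0]
    if len(present) < 2:
        return 100.0
    g, codes_present = _adjacencies(grid, mask)
    if g.sum() == 0:
        raise ValidationError("no cell adjacencies inside mask")
    p = np.array([props[c] for c in codes_present])
    row_sums = g.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pstar = p[:, None] * np.where(row_sums > 0, g / np.where(row_sums == 0, 1, row_sums), 0.0)
    terms = pstar[pstar > 0]
    m = len(codes_present)
    return float((1.0 + (terms * np.log(terms)).sum() / (2.0 * np.log(m))) * 100.0)


def hails(
    proportions: Mapping[int, float],
    ci: Mapping[str, float],
    class_names: Mapping[int, str] | None = None,
) -> float:
    """Human activity intensity of land surface, in percent.

    The construction-land-equivalent area is ``S_CLE = sum_i SL_i * CI_i``
    over class area shares ``SL_i``; HAILS = 100 * S_CLE / S, i.e. the
    CI-weighted sum of class proportions scaled to percent.
    """
    from .core_io import DEFAULT_CLASS_NAMES

    names = class_names or DEFAULT_CLASS_NAMES
    total = 0.0
    for code, p in proportions.items():
        if p == 0:
            continue
        name = names.get(int(code))
        if name is None or name not in ci:
            raise ValidationError(f"HAILS coefficient missing for class code {code}")
        total += p * ci[name]
    return 100.0 * total


DRIVER_METRIC_COLUMNS = ["LPI", "CONTAG", "SHDI", "HAILS"]


def driver_table(
    grid: LandUseGrid,
    sites: Sequence[SiteRecord],
    radius: float,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Eleven driver variables per site at one buffer radius.

    Columns: ``prop_<class>`` for each of the seven land-use classes,
    then LPI, CONTAG, SHDI and HAILS; the radius is recorded in
    ``DataFrame.attrs['radius_m']``.
    """
    config = config or PipelineConfig()
    codes = sorted(config.class_names)
    rows = []
    for site in sites:
        mask = extract_buffer(grid, site, radius)
        props = landuse_proportions(grid, mask, classes=codes)
        patches = patch_label(grid, mask)
        row = {f"prop_{config.class_names[c]}": props[c] for c in codes}
        row["LPI"] = metric_lpi(patches, mask & (grid.codes != grid.nodata))
        row["CONTAG"] = metric_contag(grid, mask)
        row["SHDI"] = metric_shdi([props[c] for c in codes])
        row["HAILS"] = hails(props, config.hails_ci, config.class_names)
        rows.append(row)
    df = pd.DataFrame(rows, index=[s.site_id for s in sites])
    df.index.name = "site_id"
    df.attrs["radius_m"] = float(radius)
    return df
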