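"""Core data model, ST readers/writers, and spatial neighbor graphs.

The central container is :class:`SpatialDataset`: spots with coordinates,
a spot x gene expression matrix, an optional spot x feature image-feature
matrix, and optional ground-truth labels.  Readers cover the Visium-like
on-disk layout (MatrixMarket MTX + barcodes/features TSV + positions CSV)
and plain CSV/TSV tables.  ``spatial_neighbors`` builds the per-spot
neighbor sets used by the spatial-aware smoothers and by the diagnostics.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy.spatial.distance import cdist

from .utils import check_finite

log = logging.getLogger("stweave")


@dataclass
class SpatialDataset:
    """Spots with coordinates, expression, optional image features/labels.

    coords use (x, y) order; for pixel coordinates x is the column and y
    the row, origin at the top-left.  All row counts must equal the number
    of spots and numeric matrices must be finite.
    """

    spot_ids: list[str]
    coords: np.ndarray
    expression: np.ndarray
    image_features: np.ndarray | None = None
    labels: np.ndarray | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.spot_ids)
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids must be unique")
        self.coords = check_finite("coords", self.coords)
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords must be {n}x2, got {self.coords.shape}")
        self.expression = check_finite("expression", self.expression)
        if self.expression.shape[0] != n:
            raise ValueError("expression row count != number of spots")
        if self.image_features is not None:
            self.image_features = check_finite("image_features", self.image_features)
            if self.image_features.shape[0] != n:
                raise ValueError("image_features row count != number of spots")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != n:
                raise ValueError("labels length != number of spots")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


@dataclass
class NeighborGraph:
    """Per-spot neighbor index lists with nonnegative weights.

    ``weights`` store the Euclidean distance to each neighbor (the
    smoothers and diagnostics consume d_ij from here).  ``method`` is
    either ``knn`` or ``grid``.
    """

    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    method: str

    def __post_init__(self):
        if self.method not in ("knn", "grid"):
            raise ValueError(f"unknown neighbor method {self.method!r}")
        n = len(self.neighbors)
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            nb = np.asarray(nb, dtype=int)
            w = np.asarray(w, dtype=float)
            if np.any(nb == i):
                raise ValueError(f"self-loop at spot {i}")
            if nb.size and (nb.min() < 0 or nb.max() >= n):
                raise ValueError(f"neighbor index out of range at spot {i}")
            if np.any(w < 0):
                raise ValueError(f"negative weight at spot {i}")
            self.neighbors[i] = nb
            self.weights[i] = w

    @property
    def n_spots(self) -> int:
        return len(self.neighbors)


@dataclass
class EmbeddingSet:
    """A spot x latent-dimension matrix tagged with its provenance.

    The default working space downstream is the top-20-PC embedding of a
    modality; ``provenance`` records the strategy string that produced it.
    """

    matrix: np.ndarray
    provenance: str

    def __post_init__(self):
        self.matrix = check_finite("embedding matrix", self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("embedding must be a 2-D matrix with q >= 1")
        if not self.provenance:
            raise ValueError("provenance must be non-empty")

    @property
    def q(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# readers


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_file(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"required file {stem}[.gz] not found in {dir_path}")


def _read_positions(path: Path) -> pd.DataFrame:
    """Read a 10x tissue-positions CSV in either dialect.

    Headerless 6-column (tissue_positions_list.csv) or headered
    (tissue_positions.csv): barcode, in_tissue, array_row, array_col,
    pxl_row_in_fullres, pxl_col_in_fullres.
    """
    with _open_maybe_gz(path) as fh:
        first = fh.readline()
    has_header = "barcode" in first.lower()
    cols = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 6:
        raise ValueError(f"positions file {path} has {df.shape[1]} columns, expected 6")
    df = df.iloc[:, :6]
    df.columns = cols
    return df


def read_visium_like(dir_path, orientation: str = "auto") -> SpatialDataset:
    """Read a Visium-like directory into a :class:`SpatialDataset`.

    Expects ``matrix.mtx(.gz)``, ``barcodes.tsv(.gz)``, ``features.tsv(.gz)``
    and a positions CSV (``tissue_positions*.csv(.gz)`` or
    ``positions.csv``).  ``orientation`` controls the MTX layout:
    ``spots`` (spots x genes), ``genes`` (genes x spots, transposed on
    read) or ``auto`` (matched against the barcode count).  Spots present
    in the matrix but absent from positions are dropped with a logged
    count; a >50% barcode mismatch is fatal.
    """
    dir_path = Path(dir_path)
    mtx_path = _find_file(dir_path, "matrix.mtx")
    bc_path = _find_file(dir_path, "barcodes.tsv")
    ft_path = _find_file(dir_path, "features.tsv")
    pos_path = None
    for stem in ("tissue_positions.csv", "tissue_positions_list.csv", "positions.csv"):
        try:
            pos_path = _find_file(dir_path, stem)
            break
        except FileNotFoundError:
            continue
    if pos_path is None:
        raise FileNotFoundError(f"no positions CSV found in {dir_path}")

    with _open_maybe_gz(mtx_path) as fh:
        mat = spio.mmread(fh)
    mat = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].astype(str).tolist()
    features = pd.read_csv(ft_path, sep="\t", header=None)[0].astype(str).tolist()

    if orientation == "auto":
        if mat.shape[0] == len(barcodes) and mat.shape[1] == len(features):
            pass
        elif mat.shape[0] == len(features) and mat.shape[1] == len(barcodes):
            mat = mat.T
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither "
                f"{len(barcodes)} barcodes x {len(features)} features nor its transpose"
            )
    elif orientation == "genes":
        mat = mat.T
    elif orientation != "spots":
        raise ValueError(f"orientation must be auto/spots/genes, got {orientation!r}")
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(f"matrix shape {mat.shape} inconsistent with barcodes/features")

    pos = _read_positions(pos_path).set_index("barcode")
    present = [b for b in barcodes if b in pos.index]
    n_missing = len(barcodes) - len(present)
    if n_missing > 0.5 * len(barcodes):
        raise ValueError(
            f"{n_missing}/{len(barcodes)} barcodes missing from positions file"
        )
    if n_missing:
        log.info("dropped %d spots absent from positions file", n_missing)
    keep = [i for i, b in enumerate(barcodes) if b in pos.index]
    mat = mat[keep]
    sub = pos.loc[present]
    coords = np.column_stack([sub["pxl_col"].to_numpy(float), sub["pxl_row"].to_numpy(float)])
    return SpatialDataset(
        spot_ids=present,
        coords=coords,
        expression=mat,
        meta={"source": str(dir_path), "feature_names": json.dumps(features)},
    )


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_tables(expr_path, coords_path, imgfeat_path=None) -> SpatialDataset:
    """Read plain spot x gene / spot x feature tables (CSV or TSV).

    First column = spot id.  Matrices are aligned on the intersection of
    spot ids, row order taken from the coords file.
    """
    expr = _read_table(expr_path)
    coords = _read_table(coords_path)
    ids = [str(i) for i in coords.index if i in expr.index]
    imgfeat = None
    if imgfeat_path is not None:
        imf = _read_table(imgfeat_path)
        ids = [i for i in ids if i in imf.index]
        if ids:
            imgfeat = imf.loc[ids].to_numpy(float)
    if not ids:
        raise ValueError("no spot ids shared between expression and coords tables")
    return SpatialDataset(
        spot_ids=ids,
        coords=coords.loc[ids].iloc[:, :2].to_numpy(float),
        expression=expr.loc[ids].to_numpy(float),
        image_features=imgfeat,
        meta={"feature_names": json.dumps(list(expr.columns))},
    )


# ---------------------------------------------------------------------------
# neighbors


def spatial_neighbors(coords: np.ndarray, method: str = "knn", k: int = 6) -> NeighborGraph:
    """Build a spatial neighbor graph over spot coordinates.

    ``knn``: k nearest spots by Euclidean distance, ties broken by lower
    spot index (deterministic).  k defaults to 6 — a hex-packed Visium
    array has 6 immediate neighbors.  ``grid``: 4-connectivity on an
    integer lattice (unit offsets), for simulated grids.  Weights are the
    Euclidean distances.
    """
    coords = check_finite("coords", coords)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots")
    if method == "knn":
        if k >= n:
            raise ValueError(f"k={k} must be smaller than n={n}")
        D = cdist(coords, coords)
        neighbors, weights = [], []
        for i in range(n):
            order = np.lexsort((np.arange(n), D[i]))  # ties -> lower index
            order = order[order != i][:k]
            neighbors.append(order)
            weights.append(D[i, order])
        return NeighborGraph(neighbors=neighbors, weights=weights, method="knn")
    if method == "grid":
        key = np.rint(coords).astype(int)
        lookup = {}
        for i, (x, y) in enumerate(map(tuple, key)):
            lookup.setdefault((x, y), []).append(i)
        neighbors, weights = [], []
        for i, (x, y) in enumerate(map(tuple, key)):
            nb = [j for j in lookup.get((x, y), []) if j != i]  # co-located spots
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb.extend(lookup.get((x + dx, y + dy), []))
            nb = np.array(sorted(nb), dtype=int)
            neighbors.append(nb)
            weights.append(np.linalg.norm(coords[nb] - coords[i], axis=1))
        return NeighborGraph(neighbors=neighbors, weights=weights, method="grid")
    raise ValueError(f"unknown neighbor method {method!r}")


# ---------------------------------------------------------------------------
# writers


def write_outputs(out_dir, dataset: SpatialDataset | None = None,
                  embedding: EmbeddingSet | None = None,
                  labels: np.ndarray | None = None,
                  spot_ids: list[str] | None = None,
                  report=None, force: bool = False) -> list[Path]:
    """Write analysis outputs (CSV/JSON) with a spot_id column.

    Refuses to overwrite existing files unless ``force``.  Returns the
    list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _target(name: str) -> Path:
        p = out_dir / name
        if p.exists() and not force:
            raise FileExistsError(f"{p} exists; pass force=True to overwrite")
        written.append(p)
        return p

    if dataset is not None:
        ids = dataset.spot_ids
        pd.DataFrame(dataset.coords, index=ids, columns=["x", "y"]).rename_axis(
            "spot_id").to_csv(_target("coords.csv"))
        pd.DataFrame(dataset.expression, index=ids).rename_axis("spot_id").to_csv(
            _target("expression.csv"))
        if dataset.image_features is not None:
            pd.DataFrame(dataset.image_features, index=ids).rename_axis(
                "spot_id").to_csv(_target("image_features.csv"))
        if spot_ids is None:
            spot_ids = ids
    if embedding is not None:
        if spot_ids is None:
            spot_ids = [str(i) for i in range(embedding.matrix.shape[0])]
        df = pd.DataFrame(embedding.matrix, index=spot_ids,
                          columns=[f"dim{j}" for j in range(embedding.q)])
        df.rename_axis("spot_id").to_csv(_target("embedding.csv"))
    if labels is not None:
        labels = np.asarray(labels)
        if labels.size == 0:
            raise ValueError("refusing to write an empty label vector")
        if spot_ids is None:
            spot_ids = [str(i) for i in range(labels.shape[0])]
        pd.DataFrame({"label": labels}, index=spot_ids).rename_axis(
            "spot_id").to_csv(_target("labels.csv"))
    if report is not None:
        payload = report.to_dict() if hasattr(report, "to_dict") else report
        _target("report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return written
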