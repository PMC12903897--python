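"""Readers and writers for spatial-transcriptomics inputs and pipeline outputs.

Supports the 10x Visium Matrix-Market bundle (``matrix.mtx[.gz]`` +
``features.tsv[.gz]`` + ``barcodes.tsv[.gz]`` + ``spatial/tissue_positions``)
and plain dense CSV/TSV matrices.  All tabular outputs are plain text so a
run's artifacts round-trip losslessly.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import (
    AlignmentError,
    ClusteringScores,
    CountMatrix,
    DomainAssignment,
    FactorModel,
    FormatError,
    SpotCoordinates,
)

_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _find(base: Path, names: list[str]) -> Path:
    for name in names:
        p = base / name
        if p.exists():
            return p
    raise FormatError(f"none of {names} found under {base}")


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_positions(bundle: Path) -> pd.DataFrame:
    """Read either Visium positions dialect into a canonical frame."""
    spatial = bundle / "spatial"
    candidates = [
        spatial / "tissue_positions.csv",
        spatial / "tissue_positions_list.csv",
        bundle / "tissue_positions.csv",
        bundle / "tissue_positions_list.csv",
    ]
    path = next((p for p in candidates if p.exists()), None)
    if path is None:
        raise FormatError(
            f"no tissue_positions(.csv|_list.csv) found under {bundle} or {spatial}"
        )
    if path.name == "tissue_positions_list.csv":
        pos = pd.read_csv(path, header=None, names=_POSITION_COLUMNS)
    else:
        pos = pd.read_csv(path)
        pos = pos.rename(columns={pos.columns[0]: "barcode"})
        missing = [c for c in _POSITION_COLUMNS if c not in pos.columns]
        if missing:
            raise FormatError(f"{path} lacks expected columns {missing}")
    pos["barcode"] = pos["barcode"].astype(str)
    return pos


def read_visium(
    bundle_path: str | Path,
    *,
    use_pixel_coords: bool = False,
    drop_empty_spots: bool = False,
) -> tuple[CountMatrix, SpotCoordinates]:
    """Read a Visium-style Matrix-Market bundle.

    Only in-tissue spots (tissue flag 1) are retained.  Counts and
    coordinates are joined on barcode strings, so file row order is
    irrelevant.  Coordinates default to the integer array grid
    (array_row, array_col); ``use_pixel_coords`` switches to full-resolution
    pixel positions.

    Parameters
    ----------
    bundle_path
        Directory holding ``matrix.mtx[.gz]``, ``features.tsv[.gz]``,
        ``barcodes.tsv[.gz]`` and a ``spatial/tissue_positions*.csv``.
    drop_empty_spots
        Spots whose total count is zero break per-spot sum-to-one
        normalization downstream; by default they raise, with this flag they
        are silently dropped.
    """
    bundle = Path(bundle_path)
    if not bundle.is_dir():
        raise FormatError(f"{bundle} is not a directory")
    mtx_path = _find(bundle, ["matrix.mtx", "matrix.mtx.gz"])
    feat_path = _find(bundle, ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"])
    bc_path = _find(bundle, ["barcodes.tsv", "barcodes.tsv.gz"])

    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    with _open_maybe_gz(feat_path) as fh:
        features = pd.read_csv(fh, sep="\t", header=None)
    with _open_maybe_gz(bc_path) as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None)[0].astype(str).tolist()
    gene_ids = features[0].astype(str).tolist()
    if counts.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"matrix {counts.shape} does not match {len(gene_ids)} features × "
            f"{len(barcodes)} barcodes"
        )

    pos = _read_positions(bundle)
    pos = pos[pos["in_tissue"] == 1]
    pos_index = {b: i for i, b in enumerate(pos["barcode"])}
    keep = [j for j, b in enumerate(barcodes) if b in pos_index]
    unmatched_counts = len(barcodes) - len(keep)
    if not keep:
        raise AlignmentError(
            f"no barcode overlap: {unmatched_counts} count barcodes unmatched, "
            f"{len(pos_index)} in-tissue position barcodes unmatched"
        )

    counts = counts[:, keep]
    kept_barcodes = [barcodes[j] for j in keep]
    cols = (
        ["pxl_row_in_fullres", "pxl_col_in_fullres"]
        if use_pixel_coords
        else ["array_row", "array_col"]
    )
    coord_rows = pos.iloc[[pos_index[b] for b in kept_barcodes]][cols].to_numpy(float)

    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        if drop_empty_spots:
            nonzero = totals > 0
            counts = counts[:, nonzero]
            kept_barcodes = [b for b, nz in zip(kept_barcodes, nonzero) if nz]
            coord_rows = coord_rows[nonzero]
        else:
            bad = int((totals == 0).sum())
            raise ValueError(
                f"{bad} spot(s) have zero total counts; per-spot normalization is "
                "undefined — pass drop_empty_spots=True to discard them"
            )

    return (
        CountMatrix(counts, gene_ids, kept_barcodes),
        SpotCoordinates(coord_rows, kept_barcodes),
    )


def write_visium_bundle(
    out_dir: str | Path,
    counts: CountMatrix,
    coords: SpotCoordinates,
    in_tissue: np.ndarray | None = None,
) -> Path:
    """Write a minimal Visium-style bundle consumable by :func:`read_visium`.

    Used by the synthetic generator and test fixtures.  ``in_tissue`` marks
    spots to flag out-of-tissue (default: all in tissue).
    """
    out = Path(out_dir)
    (out / "spatial").mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(counts.values))
    with open(out / "features.tsv", "w") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(out / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(counts.spot_ids) + "\n")
    flags = np.ones(counts.n_spots, dtype=int) if in_tissue is None else np.asarray(in_tissue, int)
    pos = pd.DataFrame(
        {
            "barcode": counts.spot_ids,
            "in_tissue": flags,
            "array_row": coords.coords[:, 0].astype(int),
            "array_col": coords.coords[:, 1].astype(int),
            "pxl_row_in_fullres": coords.coords[:, 0] * 100.0,
            "pxl_col_in_fullres": coords.coords[:, 1] * 100.0,
        }
    )
    pos.to_csv(out / "spatial" / "tissue_positions.csv", index=False)
    return out


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_csv_matrix(
    counts_path: str | Path,
    coords_path: str | Path,
    *,
    drop_empty_spots: bool = False,
) -> tuple[CountMatrix, SpotCoordinates]:
    """Read a dense genes × spots CSV/TSV plus a spot-coordinate table.

    The counts file has a header row of spot ids and gene ids in the first
    column; the coordinates file has columns (spot id, x, y).  Delimiter is
    inferred from the extension.
    """
    counts_path, coords_path = Path(counts_path), Path(coords_path)
    for p in (counts_path, coords_path):
        if not p.exists():
            raise FormatError(f"missing file: {p}")
    sep = _sep_for(counts_path)
    with open(counts_path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate spot ids in {counts_path} header")
    df = pd.read_csv(counts_path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate gene ids in {counts_path}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().to_numpy().any() and not df[col].isna().all():
            row = df.index[int(np.argmax(converted.isna().to_numpy()))]
            raise FormatError(
                f"non-numeric value in {counts_path} at gene '{row}', spot '{col}'"
            )
        df[col] = converted
    gene_ids = [str(g) for g in df.index]
    spot_ids = [str(c) for c in df.columns]
    counts = CountMatrix(sp.csr_matrix(df.to_numpy(float)), gene_ids, spot_ids)

    cf = pd.read_csv(coords_path, sep=_sep_for(coords_path))
    cf = cf.rename(columns={cf.columns[0]: "spot_id"})
    cf["spot_id"] = cf["spot_id"].astype(str)
    coord_index = {b: i for i, b in enumerate(cf["spot_id"])}
    missing = [b for b in spot_ids if b not in coord_index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} spot(s) in counts have no coordinates, e.g. {missing[:5]}"
        )
    xy = cf.iloc[[coord_index[b] for b in spot_ids], 1:3].to_numpy(float)
    coords = SpotCoordinates(xy, spot_ids)

    totals = np.asarray(counts.values.sum(axis=0)).ravel()
    if (totals == 0).any():
        if drop_empty_spots:
            nz = totals > 0
            counts = CountMatrix(
                counts.values[:, nz],
                gene_ids,
                [b for b, k in zip(spot_ids, nz) if k],
            )
            coords = SpotCoordinates(xy[nz], counts.spot_ids)
        else:
            raise ValueError(
                f"{int((totals == 0).sum())} spot(s) have zero total counts; "
                "pass drop_empty_spots=True to discard them"
            )
    return counts, coords


def write_results(
    out_dir: str | Path,
    assignment: DomainAssignment,
    model: FactorModel,
    spot_ids: list[str],
    scores: ClusteringScores | None = None,
    run_params: dict | None = None,
    markers: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write all pipeline outputs to ``out_dir``; returns the file map.

    Emits labels CSV, embedding CSV (factors × spots), objective-trace CSV,
    run-metadata JSON, and — when truth labels were scored — a metrics JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    labels = pd.DataFrame({"spot_id": spot_ids, "domain": assignment.labels})
    files["labels"] = out / "labels.csv"
    labels.to_csv(files["labels"], index=False)

    emb = pd.DataFrame(
        model.h,
        index=[f"factor_{i}" for i in range(model.h.shape[0])],
        columns=spot_ids,
    )
    files["embedding"] = out / "embedding.csv"
    emb.to_csv(files["embedding"])

    trace = pd.DataFrame(
        {
            "iteration": np.arange(1, len(model.objective_trace) + 1),
            "objective": model.objective_trace,
            "err_h": model.err_trace,
        }
    )
    files["objective_trace"] = out / "objective_trace.csv"
    trace.to_csv(files["objective_trace"], index=False)

    meta = dict(run_params or {})
    meta.update(model.metadata())
    meta["n_domains"] = int(assignment.k)
    meta["clustering_seed"] = assignment.seed
    files["metadata"] = out / "run_metadata.json"
    files["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True))

    if scores is not None:
        files["metrics"] = out / "metrics.json"
        files["metrics"].write_text(json.dumps(scores.as_dict(), indent=2))

    if markers is not None:
        files["markers"] = out / "markers.csv"
        markers.to_csv(files["markers"], index=False)
    return files
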