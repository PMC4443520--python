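"""Readers and writers for the interchange formats used by the pipeline.

TPS landmark files (the tpsDig/tpsUtil family format), FASTA alignments
(via Biopython), ESRI ASCII grids, and tab-delimited tables. Delimited
output is UTF-8, tab-separated, '.' decimal, with missing values as NA.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .morphometrics import LandmarkConfiguration
from .niche import EnvGrid, OccurrenceSet
from .popgen import PopulationPartition, SequenceAlignment

__all__ = [
    "read_tps",
    "write_tps",
    "read_fasta",
    "write_fasta",
    "read_partition",
    "write_partition",
    "read_esri_ascii",
    "write_esri_ascii",
    "read_grid_stack",
    "write_grid_stack",
    "read_occurrences",
    "write_occurrences",
    "write_table",
]


# ---------------------------------------------------------------------------
# TPS landmark files


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations.

    Handles ``LM=`` blocks of coordinate lines with optional ``ID=``,
    ``IMAGE=`` and ``SCALE=`` keys; coordinates are multiplied by the
    scale factor when present. Record order is preserved.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    configs: list[LandmarkConfiguration] = []
    i = 0
    n_rec = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise InputError(f"{path.name}: expected LM= at line {i + 1}, got {line!r}")
        n_rec += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise InputError(f"{path.name}: bad LM count in record {n_rec}") from exc
        coords = []
        i += 1
        while i < len(lines) and len(coords) < k:
            if not lines[i]:
                i += 1
                continue
            parts = lines[i].split()
            if len(parts) != 2:
                raise InputError(
                    f"{path.name}: record {n_rec} declares LM={k} but has only "
                    f"{len(coords)} coordinate lines"
                )
            coords.append([float(parts[0]), float(parts[1])])
            i += 1
        if len(coords) != k:
            raise InputError(
                f"{path.name}: record {n_rec} declares LM={k} but has only "
                f"{len(coords)} coordinate lines"
            )
        spec_id = ""
        scale = None
        while i < len(lines) and lines[i] and not lines[i].upper().startswith("LM="):
            key, _, val = lines[i].partition("=")
            key = key.strip().upper()
            if key == "ID":
                spec_id = val.strip()
            elif key == "IMAGE" and not spec_id:
                spec_id = val.strip()
            elif key == "SCALE":
                scale = float(val)
            i += 1
        arr = np.asarray(coords, float)
        if scale is not None:
            arr = arr * scale
        configs.append(LandmarkConfiguration(coords=arr, specimen_id=spec_id))
    if not configs:
        warnings.warn(f"{path.name}: no TPS records found", stacklevel=2)
    return configs


def write_tps(path: str | Path, configs: list[LandmarkConfiguration]) -> None:
    with open(path, "w") as fh:
        for i, cfg in enumerate(configs):
            pts = cfg.all_points
            fh.write(f"LM={len(pts)}\n")
            for x, y in pts:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={cfg.specimen_id or i}\n")


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path, locus: str = "") -> SequenceAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no sequences in {path}")
    return SequenceAlignment(
        ids=[r.id for r in records], seqs=[str(r.seq) for r in records], locus=locus
    )


def write_fasta(path: str | Path, aln: SequenceAlignment) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_partition(path: str | Path) -> PopulationPartition:
    """Delimited ``id<TAB>group`` (or comma) mapping file."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise InputError("partition file needs id and group columns")
    return PopulationPartition(
        mapping=dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    )


def write_partition(path: str | Path, part: PopulationPartition) -> None:
    with open(path, "w") as fh:
        for k, v in part.mapping.items():
            fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# ESRI ASCII rasters


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read one ESRI ASCII grid; returns (array with NaN at nodata, header)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise InputError(f"{path.name}: missing header field {key}")
    arr = np.asarray([v for row in rows for v in row], float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if arr.size != nrows * ncols:
        raise InputError(
            f"{path.name}: expected {nrows * ncols} cells, found {arr.size}"
        )
    arr = arr.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, header


def write_esri_ascii(
    path: str | Path,
    array: np.ndarray,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
    nodata: float = -9999.0,
) -> None:
    arr = np.where(np.isnan(array), nodata, array)
    nrows, ncols = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner:.10g}\n")
        fh.write(f"yllcorner {yllcorner:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in arr:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def write_grid_stack(directory: str | Path, grid: EnvGrid) -> None:
    """One ``<layer>.asc`` file per layer; masked cells written as nodata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, layer in grid.layers.items():
        arr = np.where(grid.mask, layer, np.nan)
        write_esri_ascii(
            directory / f"{name}.asc", arr,
            xllcorner=grid.xll, yllcorner=grid.yll,
            cellsize=grid.cellsize, nodata=grid.nodata,
        )


def read_grid_stack(paths: list[str | Path]) -> EnvGrid:
    """Stack several ESRI ASCII files into one EnvGrid (shared mask)."""
    layers = {}
    headers = []
    for p in paths:
        arr, header = read_esri_ascii(p)
        layers[Path(p).stem] = arr
        headers.append(header)
    first = headers[0]
    for h in headers[1:]:
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if h[key] != first[key]:
                raise InputError("grid layers have mismatched headers")
    mask = np.ones(next(iter(layers.values())).shape, dtype=bool)
    for arr in layers.values():
        mask &= ~np.isnan(arr)
    layers = {k: np.where(mask, v, 0.0) for k, v in layers.items()}
    return EnvGrid(
        layers=layers, mask=mask,
        xll=first["xllcorner"], yll=first["yllcorner"], cellsize=first["cellsize"],
        nodata=first.get("nodata_value", -9999.0),
    )


# ---------------------------------------------------------------------------
# occurrences and tables


def read_occurrences(path: str | Path) -> list[OccurrenceSet]:
    """``lon,lat,label`` delimited text -> one OccurrenceSet per label."""
    df = pd.read_csv(path, sep=None, engine="python",
                     names=["lon", "lat", "label"], header=None, comment="#")
    out = []
    for label, sub in df.groupby("label", sort=True):
        out.append(OccurrenceSet(lon=sub["lon"].to_numpy(),
                                 lat=sub["lat"].to_numpy(), label=str(label)))
    return out


def write_occurrences(path: str | Path, sets: list[OccurrenceSet]) -> None:
    with open(path, "w") as fh:
        for occ in sets:
            for lon, lat in zip(occ.lon, occ.lat):
                fh.write(f"{lon:.10g},{lat:.10g},{occ.label}\n")


def write_table(path: str | Path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index=index)
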