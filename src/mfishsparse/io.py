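"""Readers and writers for cell image sets, label images and dictionaries.

A cell lives in a directory with a ``manifest.yaml`` naming the five
fluorochrome channel images (documented order F, G, A, R, Y: Spectrum Gold,
Green, Aqua, Red and Spectrum Red), the DAPI image, and optionally the
ground-truth label image and a mask.  Channel order is always taken from the
manifest, never inferred from filenames.  Label images are 8-bit rasters
using the 0 (background) / 1..24 (class) / 255 (overlap) convention.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .solvers import Dictionary
from .synthetic import SimulatedCell

__all__ = [
    "CellDataset",
    "FLUOR_NAMES",
    "read_cell",
    "write_cell",
    "read_label_image",
    "write_label_image",
    "save_dictionary",
    "load_dictionary",
    "validate_label_image",
]

FLUOR_NAMES = ("F", "G", "A", "R", "Y")
VALID_LABELS = frozenset(range(0, 25)) | {255}


@dataclass
class CellDataset:
    """Paths making up one cell's image set."""

    cell_id: str
    channel_paths: list[Path]
    dapi_path: Path
    truth_path: Path | None = None
    mask_path: Path | None = None

    @classmethod
    def from_manifest(cls, path: str | Path) -> "CellDataset":
        path = Path(path)
        if path.is_dir():
            path = path / "manifest.yaml"
        if not path.exists():
            raise FileNotFoundError(f"no manifest at {path}")
        spec = yaml.safe_load(path.read_text())
        base = path.parent
        channels = [base / p for p in spec["channels"]]
        if len(channels) != 5:
            raise ValueError(
                f"manifest lists {len(channels)} fluor channels; an M-FISH set has exactly 5"
            )
        return cls(
            cell_id=str(spec.get("cell_id", base.name)),
            channel_paths=channels,
            dapi_path=base / spec["dapi"],
            truth_path=(base / spec["truth"]) if spec.get("truth") else None,
            mask_path=(base / spec["mask"]) if spec.get("mask") else None,
        )


def validate_label_image(labels: np.ndarray, name: str = "label image") -> np.ndarray:
    """Check the 0 / 1..24 / 255 convention; report offending coordinates."""
    labels = np.asarray(labels)
    bad = ~np.isin(labels, list(VALID_LABELS))
    if bad.any():
        coords = np.argwhere(bad)[:5]
        values = labels[bad][:5]
        raise ValueError(
            f"{name} contains invalid labels {values.tolist()} at pixel "
            f"coordinates {coords.tolist()} (valid: 0, 1..24, 255)"
        )
    return labels.astype(np.uint8)


def read_label_image(path: str | Path) -> np.ndarray:
    return validate_label_image(iio.imread(path), name=str(path))


def write_label_image(labels: np.ndarray, path: str | Path) -> None:
    validate_label_image(labels)
    iio.imwrite(Path(path), np.asarray(labels, dtype=np.uint8))


def read_cell(dataset: CellDataset | str | Path):
    """Load a cell's aligned multichannel stack.

    Returns ``(stack, dapi, truth, mask)`` where ``stack`` is ``H x W x 5``
    float, ``truth``/``mask`` are ``None`` when absent.  Integer images are
    promoted to float.
    """
    if not isinstance(dataset, CellDataset):
        dataset = CellDataset.from_manifest(dataset)
    planes = [np.asarray(tifffile.imread(p), dtype=float) for p in dataset.channel_paths]
    dapi = np.asarray(tifffile.imread(dataset.dapi_path), dtype=float)
    shapes = {p.name: planes[i].shape for i, p in enumerate(dataset.channel_paths)}
    shapes[dataset.dapi_path.name] = dapi.shape
    ref = planes[0].shape
    offenders = {k: v for k, v in shapes.items() if v != ref}
    if offenders:
        raise ValueError(f"channel shape mismatch (expected {ref}): {offenders}")
    for i, plane in enumerate(planes):
        if plane.ndim != 2:
            raise ValueError(f"channel {dataset.channel_paths[i].name} is not grayscale 2-D")
    stack = np.stack(planes, axis=-1)
    truth = read_label_image(dataset.truth_path) if dataset.truth_path else None
    if truth is not None and truth.shape != ref:
        raise ValueError(f"truth image shape {truth.shape} does not match channels {ref}")
    mask = None
    if dataset.mask_path:
        mask = np.asarray(iio.imread(dataset.mask_path)) > 0
        if mask.shape != ref:
            raise ValueError(f"mask shape {mask.shape} does not match channels {ref}")
    return stack, dapi, truth, mask


def write_cell(cell: SimulatedCell, outdir: str | Path, cell_id: str | None = None) -> Path:
    """Write a simulated cell in the manifest layout the readers consume.

    Channels and DAPI go to float32 TIFF, the ground truth to an 8-bit PNG;
    the manifest echoes the full simulation config (including the seed) so
    every artifact can be regenerated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cell_id = cell_id or outdir.name
    channel_files = []
    for i, name in enumerate(FLUOR_NAMES[: cell.channels.shape[2]]):
        fname = f"channel_{i}_{name}.tif"
        tifffile.imwrite(outdir / fname, cell.channels[:, :, i].astype(np.float32))
        channel_files.append(fname)
    tifffile.imwrite(outdir / "dapi.tif", cell.dapi.astype(np.float32))
    write_label_image(cell.truth, outdir / "truth.png")
    cfg = asdict(cell.config)
    if cfg.get("crosstalk") is not None:
        cfg["crosstalk"] = np.asarray(cfg["crosstalk"]).tolist()
    manifest = {
        "cell_id": cell_id,
        "channels": channel_files,
        "channel_order": list(FLUOR_NAMES[: cell.channels.shape[2]]),
        "dapi": "dapi.tif",
        "truth": "truth.png",
        "mask": None,
        "config": cfg,
        "code_table": {int(c): code.tolist() for c, code in cell.code_table.codes.items()},
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir / "manifest.yaml"


def save_dictionary(dictionary: Dictionary, prefix: str | Path) -> tuple[Path, Path]:
    """Persist a dictionary as ``<prefix>_matrix.npy`` + ``<prefix>_columns.csv``.

    The matrix is stored in its normalized frame; the CSV carries each
    column's class label and original norm.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    matrix_path = prefix.with_name(prefix.name + "_matrix.npy")
    cols_path = prefix.with_name(prefix.name + "_columns.csv")
    np.save(matrix_path, dictionary.matrix)
    pd.DataFrame(
        {"column": np.arange(dictionary.N),
         "class": dictionary.class_of_column,
         "scale": dictionary.scales}
    ).to_csv(cols_path, index=False)
    return matrix_path, cols_path


def load_dictionary(prefix: str | Path) -> Dictionary:
    prefix = Path(prefix)
    matrix = np.load(prefix.with_name(prefix.name + "_matrix.npy"))
    table = pd.read_csv(prefix.with_name(prefix.name + "_columns.csv"))
    d = Dictionary(matrix, table["class"].to_numpy(), normalize=False)
    d.scales = table["scale"].to_numpy(dtype=float)
    return d
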