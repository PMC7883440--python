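"""File formats: TIFF stacks with JSON sidecars, ROI inputs, tables, configs.

Conventions: coordinates are 0-based ``(row, col) = (y, x)``, pixel-centred.
A count stack is stored as a multi-page TIFF in plane-major page order
(``page = plane * n_species + species``) with a JSON sidecar naming the
species order and pixel size.  ROI masks come either as a 16-bit label TIFF
(0 = background) or an ImageJ ROI archive (.zip of .roi), each with a CSV
mapping label/name to category and sample labels; label images are the mask
authority and archives are rasterised on load.
"""

from __future__ import annotations

import json
import struct
import warnings
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import polygon as draw_polygon

from .calibration import SessionCalibration, session_cf
from .ion_imaging import AccumulatedCounts, IonImageStack
from .roi_quant import Roi


# ---------------------------------------------------------------------------
# Ion-image stacks
# ---------------------------------------------------------------------------


def write_stack(stack: IonImageStack, tiff_path, sidecar_path=None) -> None:
    """Write a stack as multi-page TIFF plus JSON sidecar."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    n_planes, n_species, h, w = stack.counts.shape
    pages = stack.counts.reshape(n_planes * n_species, h, w).astype(np.uint32)
    tifffile.imwrite(tiff_path, pages)
    sidecar = {
        "species_order": stack.species_order,
        "pixel_size_um": stack.pixel_size_um,
        "n_planes": n_planes,
        "metadata": stack.metadata,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_stack(tiff_path, sidecar_path=None) -> IonImageStack:
    """Read a stack written by :func:`write_stack`.

    Raises distinct errors for a missing sidecar, non-integer pixel data
    (naming the offending page) and a species/page-count mismatch.
    """
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing stack sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    species = sidecar["species_order"]

    with tifffile.TiffFile(tiff_path) as tf:
        pages = []
        for i, page in enumerate(tf.pages):
            arr = page.asarray()
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(
                    f"stack page {i} has non-integer pixel data ({arr.dtype})"
                )
            pages.append(arr)
    n_pages = len(pages)
    if n_pages % len(species) != 0:
        raise ValueError(
            f"page count {n_pages} is not divisible by "
            f"{len(species)} species in the sidecar"
        )
    n_planes = n_pages // len(species)
    if sidecar.get("n_planes") not in (None, n_planes):
        raise ValueError(
            f"sidecar declares {sidecar['n_planes']} planes but the TIFF "
            f"implies {n_planes}"
        )
    counts = np.stack(pages).reshape(n_planes, len(species), *pages[0].shape)
    return IonImageStack(
        counts=counts.astype(np.int64),
        species_order=list(species),
        pixel_size_um=float(sidecar["pixel_size_um"]),
        metadata=sidecar.get("metadata", {}),
    )


def write_accumulated(acc: AccumulatedCounts, tiff_path, sidecar_path=None) -> None:
    """Write accumulated counts as multi-page TIFF (one page per species)."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    tifffile.imwrite(tiff_path, acc.counts.astype(np.uint32))
    sidecar = {
        "species_order": acc.species_order,
        "pixel_size_um": acc.pixel_size_um,
        "shifts_applied": [list(s) for s in acc.shifts_applied],
        "metadata": acc.metadata,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_accumulated(tiff_path, sidecar_path=None) -> AccumulatedCounts:
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    sidecar = json.loads(Path(sidecar_path).read_text())
    counts = tifffile.imread(tiff_path).astype(np.int64)
    shifts = [tuple(s) for s in sidecar["shifts_applied"]]
    # recompute the all-plane coverage mask from the recorded shifts
    from .ion_imaging import translate

    valid = np.ones(counts.shape[1:], dtype=bool)
    ones = np.ones(counts.shape[1:], dtype=np.int64)
    for dx, dy in shifts:
        valid &= translate(ones, -dx, -dy).astype(bool)
    return AccumulatedCounts(
        counts=counts,
        species_order=list(sidecar["species_order"]),
        shifts_applied=shifts,
        valid_mask=valid,
        pixel_size_um=float(sidecar["pixel_size_um"]),
        metadata=sidecar.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# Ground-truth scene rasters
# ---------------------------------------------------------------------------


def write_scene(scene, out_dir) -> None:
    """Write a scene's label map (16-bit), f maps (32-bit float) and ROI table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "truth_labels.tif", scene.label_map.astype(np.uint16))
    tifffile.imwrite(out / "truth_fC.tif", scene.f_c_map.astype(np.float32))
    tifffile.imwrite(out / "truth_fN.tif", scene.f_n_map.astype(np.float32))
    pd.DataFrame(
        {
            "label": list(scene.category_of_cell),
            "category": list(scene.category_of_cell.values()),
        }
    ).to_csv(out / "roi_mapping.csv", index=False)


# ---------------------------------------------------------------------------
# ROI inputs: label image or ImageJ archive, plus mapping CSV
# ---------------------------------------------------------------------------

_ROI_MAPPING_COLUMNS = ("label", "category")


def _mapping_row(mapping: pd.DataFrame, key) -> dict:
    row = mapping[mapping["label"].astype(str) == str(key)]
    if row.empty:
        return {}
    return row.iloc[0].to_dict()


def read_rois_label_image(label_tiff, mapping_csv) -> list[Roi]:
    """ROIs from a label TIFF (0 = background) and a label→category CSV.

    The mapping CSV needs ``label`` and ``category`` columns; optional
    ``sample_id``, ``timepoint_h`` and ``treatment`` columns are carried
    through.  Every nonzero label must be mapped; unmapped labels raise an
    error listing them.
    """
    labels = tifffile.imread(label_tiff)
    mapping = pd.read_csv(mapping_csv)
    for col in _ROI_MAPPING_COLUMNS:
        if col not in mapping.columns:
            raise ValueError(f"ROI mapping is missing the {col!r} column")
    present = sorted(int(v) for v in np.unique(labels) if v != 0)
    if not present:
        warnings.warn("label image contains no ROIs", stacklevel=2)
        return []
    mapped = {str(v) for v in mapping["label"]}
    unmapped = [v for v in present if str(v) not in mapped]
    if unmapped:
        raise ValueError(f"unmapped ROI labels: {unmapped}")
    rois = []
    for v in present:
        row = _mapping_row(mapping, v)
        ys, xs = np.nonzero(labels == v)
        rois.append(
            Roi(
                id=v,
                category=str(row["category"]),
                pixels=(ys, xs),
                sample_id=str(row.get("sample_id", "") or ""),
                timepoint_h=float(row.get("timepoint_h", float("nan"))),
                treatment=str(row.get("treatment", "") or ""),
            )
        )
    return rois


# Minimal ImageJ .roi codec (header layout per the ImageJ source); supports
# the shapes used for manually drawn cell outlines: rectangle, oval,
# polygon, freehand and traced outlines.
_IJ_TYPES = {0: "polygon", 1: "rect", 2: "oval", 7: "freehand", 8: "traced"}


def decode_imagej_roi(data: bytes) -> dict:
    """Decode one ImageJ .roi blob to a shape dict."""
    if data[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI (missing 'Iout' magic)")
    roi_type = data[6]
    if roi_type not in _IJ_TYPES:
        raise ValueError(f"unsupported ImageJ ROI type {roi_type}")
    top, left, bottom, right, n = struct.unpack(">hhhhh", data[8:18])
    shape = {"kind": _IJ_TYPES[roi_type], "top": top, "left": left,
             "bottom": bottom, "right": right}
    if shape["kind"] in ("polygon", "freehand", "traced"):
        xs = struct.unpack(f">{n}h", data[64 : 64 + 2 * n])
        ys = struct.unpack(f">{n}h", data[64 + 2 * n : 64 + 4 * n])
        shape["xs"] = [left + v for v in xs]
        shape["ys"] = [top + v for v in ys]
    return shape


def encode_imagej_roi(shape: dict) -> bytes:
    """Encode a shape dict as an ImageJ .roi blob (round-trip counterpart)."""
    kinds = {v: k for k, v in _IJ_TYPES.items()}
    roi_type = kinds[shape["kind"]]
    if shape["kind"] in ("polygon", "freehand", "traced"):
        xs, ys = shape["xs"], shape["ys"]
        top, left = min(ys), min(xs)
        bottom, right = max(ys) + 1, max(xs) + 1
        n = len(xs)
    else:
        top, left = shape["top"], shape["left"]
        bottom, right = shape["bottom"], shape["right"]
        n = 0
    head = bytearray(64)
    head[:4] = b"Iout"
    struct.pack_into(">h", head, 4, 228)  # version
    head[6] = roi_type
    struct.pack_into(">hhhhh", head, 8, top, left, bottom, right, n)
    body = b""
    if n:
        body = struct.pack(
            f">{n}h", *(x - left for x in shape["xs"])
        ) + struct.pack(f">{n}h", *(y - top for y in shape["ys"]))
    return bytes(head) + body


def _shape_to_pixels(shape: dict, image_shape) -> tuple[np.ndarray, np.ndarray]:
    h, w = image_shape
    if shape["kind"] == "rect":
        yy, xx = np.mgrid[shape["top"] : shape["bottom"], shape["left"] : shape["right"]]
        ys, xs = yy.ravel(), xx.ravel()
    elif shape["kind"] == "oval":
        cy = (shape["top"] + shape["bottom"] - 1) / 2
        cx = (shape["left"] + shape["right"] - 1) / 2
        ry = max((shape["bottom"] - shape["top"]) / 2, 0.5)
        rx = max((shape["right"] - shape["left"]) / 2, 0.5)
        yy, xx = np.mgrid[0:h, 0:w]
        m = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1
        ys, xs = np.nonzero(m)
    else:
        ys, xs = draw_polygon(shape["ys"], shape["xs"], (h, w))
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    return ys[keep], xs[keep]


def read_rois_archive(zip_path, mapping_csv, image_shape) -> list[Roi]:
    """ROIs from an ImageJ .zip archive of .roi files plus a mapping CSV.

    The mapping's ``label`` column holds the ROI entry name (without the
    ``.roi`` extension).  ROIs are rasterised onto ``image_shape``.
    """
    mapping = pd.read_csv(mapping_csv)
    rois = []
    unmapped = []
    with zipfile.ZipFile(zip_path) as zf:
        names = [n for n in zf.namelist() if n.endswith(".roi")]
        for i, name in enumerate(sorted(names), start=1):
            key = name[: -len(".roi")]
            row = _mapping_row(mapping, key)
            if not row:
                unmapped.append(key)
                continue
            shape = decode_imagej_roi(zf.read(name))
            ys, xs = _shape_to_pixels(shape, image_shape)
            rois.append(
                Roi(
                    id=i,
                    category=str(row["category"]),
                    pixels=(ys, xs),
                    sample_id=str(row.get("sample_id", "") or ""),
                    timepoint_h=float(row.get("timepoint_h", float("nan"))),
                    treatment=str(row.get("treatment", "") or ""),
                )
            )
    if unmapped:
        raise ValueError(f"unmapped ROI names: {unmapped}")
    return rois


def read_rois(mask_path, mapping_csv, image_shape=None) -> list[Roi]:
    """Dispatch on the mask file type (.zip archive vs label TIFF)."""
    mask_path = Path(mask_path)
    if mask_path.suffix.lower() == ".zip":
        if image_shape is None:
            raise ValueError("image_shape is required for ROI archives")
        return read_rois_archive(mask_path, mapping_csv, image_shape)
    return read_rois_label_image(mask_path, mapping_csv)


# ---------------------------------------------------------------------------
# Calibration tables
# ---------------------------------------------------------------------------


def read_calibrations(csv_path) -> dict[tuple[str, str], SessionCalibration]:
    """Read standard-scan measurements into per-session calibrations.

    CSV columns: ``session_id, isotope, r_irms_standard, measured_ratio``
    (one row per standard scan).  Returns ``{(session_id, isotope): cal}``.
    """
    df = pd.read_csv(csv_path)
    out = {}
    for (sid, iso), g in df.groupby(["session_id", "isotope"]):
        refs = g["r_irms_standard"].unique()
        if len(refs) != 1:
            raise ValueError(
                f"conflicting reference ratios for session {sid}/{iso}"
            )
        out[(str(sid), str(iso))] = session_cf(
            float(refs[0]),
            g["measured_ratio"].tolist(),
            isotope=str(iso),
            session_id=str(sid),
        )
    return out


def calibration_to_yaml(cal: SessionCalibration, path) -> None:
    Path(path).write_text(yaml.safe_dump(vars(cal)))


def calibration_from_yaml(path) -> SessionCalibration:
    return SessionCalibration(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Run configuration and manifest
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load a YAML run configuration as a plain mapping."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a YAML mapping")
    return cfg


def write_manifest(out_dir, command: str, inputs: dict, parameters: dict) -> Path:
    """Record inputs, parameters, seeds and versions for reproducibility."""
    import nanosip

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": parameters,
        "versions": {"nanosip": nanosip.__version__, "numpy": np.__version__},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
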