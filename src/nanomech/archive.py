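"""Readers/writers for the documented force-curve archive format.

An archive is a directory containing one ``metadata.json`` document (tip,
calibration, grid geometry, labels, units) plus one two-column text file per
curve (``curve_0000.tsv`` ...: piezo position in meters, deflection in the
declared unit).  A single-file HDF5 container mirroring the same schema is
written/read when the path ends in ``.h5`` / ``.hdf5``.

The format is deliberately plain: proprietary instrument formats (Bruker
Nanoscope, JPK, Asylum) are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np

from .curves import (
    CantileverCalibration,
    DeflectionUnit,
    Direction,
    ForceVolume,
    RawForceCurve,
    TipGeometry,
    validate_curve,
)

__all__ = ["read_archive", "write_archive", "ArchiveError"]

_FORMAT_VERSION = 1


class ArchiveError(ValueError):
    """Raised for malformed or unreadable archives."""


def _tip_to_dict(tip: TipGeometry) -> dict:
    d = asdict(tip)
    d["kind"] = tip.kind.value
    return {k: v for k, v in d.items() if v is not None}


def _tip_from_dict(d: dict) -> TipGeometry:
    try:
        return TipGeometry(**d)
    except (TypeError, ValueError) as exc:
        raise ArchiveError(f"bad tip metadata: {exc}") from exc


def _calib_to_dict(c: CantileverCalibration) -> dict:
    return {k: v for k, v in asdict(c).items() if v is not None}


def _curve_meta(curve: RawForceCurve, filename: str) -> dict:
    return {
        "file": filename,
        "n_samples": int(curve.n_samples),
        "deflection_unit": curve.deflection_unit.value,
        "direction": curve.direction.value,
        "labels": curve.labels,
    }


def _write_curve_file(path: Path, curve: RawForceCurve) -> None:
    data = np.column_stack([curve.z_m, curve.deflection])
    header = f"z_m\tdeflection_{curve.deflection_unit.value}"
    np.savetxt(path, data, fmt="%.17e", delimiter="\t", header=header)


def _read_curve_file(path: Path, expected_n: int) -> tuple[np.ndarray, np.ndarray]:
    try:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    except OSError as exc:
        raise ArchiveError(f"missing curve file {path.name}") from exc
    except ValueError as exc:
        raise ArchiveError(f"unparseable curve file {path.name}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 2:
        raise ArchiveError(f"curve file {path.name} is not two-column")
    if data.shape[0] != expected_n:
        raise ArchiveError(
            f"curve file {path.name} truncated: expected {expected_n} samples, "
            f"found {data.shape[0]}"
        )
    return data[:, 0], data[:, 1]


def write_archive(
    obj: Union[ForceVolume, list[RawForceCurve], RawForceCurve],
    path: Union[str, Path],
) -> Path:
    """Write curves or a force volume to an archive directory or HDF5 file.

    Returns the path written.  Raises :class:`ArchiveError` for empty input.
    """
    path = Path(path)
    if isinstance(obj, RawForceCurve):
        obj = [obj]
    if isinstance(obj, list) and len(obj) == 0:
        raise ArchiveError("nothing to write: empty curve list")

    if path.suffix.lower() in (".h5", ".hdf5"):
        return _write_hdf5(obj, path)

    path.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, ForceVolume):
        curves = obj.curves()
        grid_meta = {"rows": obj.rows, "cols": obj.cols}
        volume_meta = {
            "pixel_pitch_m": obj.pixel_pitch_m,
            "scan_area_m2": obj.scan_area_m2,
            "labels": obj.labels,
        }
    else:
        curves = obj
        grid_meta = None
        volume_meta = None

    first = curves[0]
    curve_entries = []
    for i, curve in enumerate(curves):
        if curve.tip != first.tip or curve.calibration != first.calibration:
            raise ArchiveError(
                "all curves in one archive must share tip and calibration"
            )
        fname = f"curve_{i:04d}.tsv"
        _write_curve_file(path / fname, curve)
        curve_entries.append(_curve_meta(curve, fname))

    meta = {
        "format_version": _FORMAT_VERSION,
        "tip": _tip_to_dict(first.tip),
        "calibration": _calib_to_dict(first.calibration),
        "n_curves": len(curves),
        "grid": grid_meta,
        "volume": volume_meta,
        "curves": curve_entries,
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def read_archive(
    path: Union[str, Path]
) -> Union[ForceVolume, list[RawForceCurve]]:
    """Read an archive written by :func:`write_archive`.

    Returns a :class:`ForceVolume` when the metadata declares a grid,
    otherwise a list of :class:`RawForceCurve`.  Every returned curve is
    validated; violations raise :class:`ArchiveError` naming the curve.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_hdf5(path)

    meta_path = path / "metadata.json"
    if not meta_path.is_file():
        raise ArchiveError(f"no metadata.json in {path}")
    meta = json.loads(meta_path.read_text())
    for key in ("tip", "calibration", "n_curves", "curves"):
        if key not in meta:
            raise ArchiveError(f"metadata.json missing required key '{key}'")

    tip = _tip_from_dict(meta["tip"])
    calibration = CantileverCalibration(**meta["calibration"])
    entries = meta["curves"]
    if len(entries) != meta["n_curves"]:
        raise ArchiveError(
            f"metadata declares {meta['n_curves']} curves but lists "
            f"{len(entries)} entries"
        )

    curves: list[RawForceCurve] = []
    for entry in entries:
        z, d = _read_curve_file(path / entry["file"], entry["n_samples"])
        curve = RawForceCurve(
            z_m=z,
            deflection=d,
            deflection_unit=DeflectionUnit(entry["deflection_unit"]),
            direction=Direction(entry["direction"]),
            tip=tip,
            calibration=calibration,
            labels=entry.get("labels", {}),
        )
        violations = validate_curve(curve)
        if violations:
            raise ArchiveError(
                f"invalid curve {entry['file']}: " + "; ".join(violations)
            )
        curves.append(curve)

    grid = meta.get("grid")
    if grid is None:
        return curves
    rows, cols = grid["rows"], grid["cols"]
    if rows * cols != len(curves):
        raise ArchiveError(
            f"grid {rows}x{cols} does not match curve count {len(curves)}"
        )
    vol_meta = meta.get("volume") or {}
    return ForceVolume(
        grid=[curves[r * cols : (r + 1) * cols] for r in range(rows)],
        pixel_pitch_m=vol_meta.get("pixel_pitch_m", 1.0),
        scan_area_m2=vol_meta.get("scan_area_m2"),
        labels=vol_meta.get("labels", {}),
    )


# -- HDF5 mirror ------------------------------------------------------------

def _write_hdf5(obj, path: Path) -> Path:
    import h5py

    if isinstance(obj, ForceVolume):
        curves = obj.curves()
    else:
        curves = obj
    first = curves[0]
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["tip"] = json.dumps(_tip_to_dict(first.tip))
        f.attrs["calibration"] = json.dumps(_calib_to_dict(first.calibration))
        if isinstance(obj, ForceVolume):
            f.attrs["grid"] = json.dumps({"rows": obj.rows, "cols": obj.cols})
            f.attrs["volume"] = json.dumps(
                {
                    "pixel_pitch_m": obj.pixel_pitch_m,
                    "scan_area_m2": obj.scan_area_m2,
                    "labels": obj.labels,
                }
            )
        for i, curve in enumerate(curves):
            g = f.create_group(f"curve_{i:04d}")
            g.create_dataset("z_m", data=curve.z_m)
            g.create_dataset("deflection", data=curve.deflection)
            g.attrs["deflection_unit"] = curve.deflection_unit.value
            g.attrs["direction"] = curve.direction.value
            g.attrs["labels"] = json.dumps(curve.labels)
    return path


def _read_hdf5(path: Path):
    import h5py

    if not path.is_file():
        raise ArchiveError(f"no such archive file: {path}")
    with h5py.File(path, "r") as f:
        tip = _tip_from_dict(json.loads(f.attrs["tip"]))
        calibration = CantileverCalibration(**json.loads(f.attrs["calibration"]))
        names = sorted(k for k in f.keys() if k.startswith("curve_"))
        curves = []
        for name in names:
            g = f[name]
            curve = RawForceCurve(
                z_m=g["z_m"][:],
                deflection=g["deflection"][:],
                deflection_unit=DeflectionUnit(g.attrs["deflection_unit"]),
                direction=Direction(g.attrs["direction"]),
                tip=tip,
                calibration=calibration,
                labels=json.loads(g.attrs["labels"]),
            )
            violations = validate_curve(curve)
            if violations:
                raise ArchiveError(
                    f"invalid curve {name}: " + "; ".join(violations)
                )
            curves.append(curve)
        grid_attr = f.attrs.get("grid")
        if grid_attr is None:
            return curves
        grid = json.loads(grid_attr)
        vol_meta = json.loads(f.attrs.get("volume", "{}"))
    rows, cols = grid["rows"], grid["cols"]
    if rows * cols != len(curves):
        raise ArchiveError(
            f"grid {rows}x{cols} does not match curve count {len(curves)}"
        )
    return ForceVolume(
        grid=[curves[r * cols : (r + 1) * cols] for r in range(rows)],
        pixel_pitch_m=vol_meta.get("pixel_pitch_m", 1.0),
        scan_area_m2=vol_meta.get("scan_area_m2"),
        labels=vol_meta.get("labels", {}),
    )
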