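"""HDF5 map-cube persistence, map export and run configuration.

Cube layout::

    /maps/counts        rows x cols x channels, integer
    /maps/energy_axis   keV per channel
    /meta/instrument    JSON-serialized InstrumentConfig (attribute)
    /meta/sample        JSON-serialized SampleModel (attribute)
    /meta/dwell_s, /meta/step_nm
    /truth/<element>    optional wt-fraction ground truth
    /truth/labels       optional compartment labels

Pixel convention: row-major, (row 0, col 0) at top-left.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .forward import InstrumentConfig, MapCube, SampleModel
from .phantom import GroundTruthMaps, LabelMap, TissueProfile


class CubeFormatError(ValueError):
    pass


def _to_json(obj) -> str:
    return json.dumps(dataclasses.asdict(obj))


def write_cube(cube: MapCube, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        maps = f.create_group("maps")
        maps.create_dataset("counts", data=cube.counts, compression="gzip")
        maps.create_dataset("energy_axis", data=cube.instrument.energy_axis_kev)
        meta = f.create_group("meta")
        meta.attrs["instrument"] = _to_json(cube.instrument)
        meta.attrs["sample"] = _to_json(cube.sample)
        meta.attrs["dwell_s"] = cube.dwell_s
        meta.attrs["step_nm"] = cube.step_nm
        meta.attrs["pixel_convention"] = "row-major, origin top-left"
        if cube.truth is not None:
            tr = f.create_group("truth")
            for el, arr in cube.truth.conc.items():
                tr.create_dataset(el, data=arr)
            tr.create_dataset("labels", data=cube.truth.label_map.labels)
            tr.attrs["pixel_size_nm"] = cube.truth.label_map.pixel_size_nm
            tr.attrs["cbar"] = json.dumps(cube.truth.profile.cbar)


def read_cube(path) -> MapCube:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "maps" not in f or "counts" not in f["maps"]:
            raise CubeFormatError(f"{path}: missing dataset /maps/counts")
        if "meta" not in f:
            raise CubeFormatError(f"{path}: missing group /meta")
        counts = f["maps/counts"][...]
        meta = f["meta"].attrs
        inst_d = json.loads(meta["instrument"])
        inst_d["spot_nm"] = tuple(inst_d["spot_nm"])
        instrument = InstrumentConfig(**inst_d)
        sample = SampleModel(**json.loads(meta["sample"]))
        truth = None
        if "truth" in f:
            tr = f["truth"]
            conc = {el: tr[el][...] for el in tr if el != "labels"}
            lm = LabelMap(tr["labels"][...], float(tr.attrs["pixel_size_nm"]))
            profile = TissueProfile(weights=TissueProfile.default_weights(),
                                    cbar=json.loads(tr.attrs["cbar"]))
            truth = GroundTruthMaps(conc, lm, profile)
        return MapCube(counts, float(meta["dwell_s"]), float(meta["step_nm"]),
                       instrument, sample, truth=truth)


def export_maps(maps: dict, fmt: str, out_dir) -> list:
    """Write one file per element map; returns the written paths."""
    if not maps:
        raise ValueError("no maps to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for el, arr in maps.items():
        arr = np.asarray(arr)
        if fmt.upper() == "CSV":
            p = out_dir / f"{el}.csv"
            np.savetxt(p, arr, delimiter=",")
        elif fmt.upper() in ("TIFF", "TIF"):
            import tifffile
            p = out_dir / f"{el}.tif"
            tifffile.imwrite(p, arr.astype(np.float32))
        else:
            raise ValueError(f"unknown export format {fmt!r}")
        paths.append(p)
    return paths


_CONFIG_KEYS = {
    "seed", "shape", "pixel_size_nm", "profile", "pt_contrast", "cv",
    "dwell_s", "instrument", "sample", "reference_live_time_s",
    "fit", "k", "scaling", "out_dir",
}


def load_config(path) -> dict:
    """YAML run configuration; unknown top-level keys are rejected."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg
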