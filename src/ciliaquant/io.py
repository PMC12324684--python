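"""Readers and writers for the pipeline's on-disk formats.

Tables are UTF-8 TSV/CSV with a mandatory header row, "." decimal
separator and no thousands separators. Lengths are always µm and times
minutes in files (hours appear only inside rate units); intensities are
arbitrary fluorescence units. Images are multi-page grayscale TIFFs (one
page per channel); ground truth and provenance travel as JSON sidecars.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ciliaquant.interactome import ContaminantRegistry, PsmTable
from ciliaquant.imaging import ImageStack
from ciliaquant.kinetics import LengthTrace, traces_from_frame, traces_to_frame


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc


def read_psm_table(psm_path: str | Path, meta_path: str | Path) -> PsmTable:
    """PSM TSV (protein_id + one column per run) and run-metadata TSV."""
    counts = _read_table(psm_path, "\t")
    if "protein_id" not in counts.columns:
        raise ValueError(f"{psm_path}: missing 'protein_id' column")
    counts = counts.set_index("protein_id")
    meta = _read_table(meta_path, "\t")
    if "run_id" not in meta.columns:
        raise ValueError(f"{meta_path}: missing 'run_id' column")
    return PsmTable(counts, meta.set_index("run_id"))


def write_psm_table(psm: PsmTable, psm_path: str | Path, meta_path: str | Path) -> None:
    psm.counts.rename_axis("protein_id").to_csv(psm_path, sep="\t")
    psm.meta.rename_axis("run_id").to_csv(meta_path, sep="\t")


def read_registry(path: str | Path) -> ContaminantRegistry:
    frame = _read_table(path, "\t")
    return ContaminantRegistry.from_frame(frame)


def write_registry(registry: ContaminantRegistry, path: str | Path) -> None:
    registry.to_frame().to_csv(path, sep="\t", index=False)


def read_traces(path: str | Path) -> list[LengthTrace]:
    """Long-format trace CSV: cilium_id, condition, replicate, time_min, length_um."""
    return traces_from_frame(_read_table(path, ","))


def write_traces(traces: list[LengthTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def write_image(stack: ImageStack, path: str | Path) -> None:
    """Multi-page grayscale TIFF, one page per channel, names in metadata."""
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, data, metadata={
        "channel_names": names, "pixel_size_um": stack.pixel_size_um})


def read_image(path: str | Path,
               channel_names: list[str] | None = None,
               pixel_size_um: float | None = None) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    names = channel_names or meta.get("channel_names") or [
        f"channel_{i}" for i in range(data.shape[0])]
    px = pixel_size_um or meta.get("pixel_size_um")
    if px is None:
        raise ValueError(f"{path}: pixel size not in metadata; pass pixel_size_um")
    return ImageStack(channels={n: data[i].astype(float) for i, n in enumerate(names)},
                      pixel_size_um=float(px))


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(out_path: str | Path, config: dict,
                     input_paths: list[str | Path] | None = None) -> None:
    """JSON sidecar recording the thresholds, seed and input checksums."""
    from ciliaquant import __version__

    record = {
        "version": __version__,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "inputs": {str(p): file_checksum(p) for p in (input_paths or [])},
    }
    write_json(record, out_path)
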