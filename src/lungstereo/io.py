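"""Persistence: labelled sections as TIFF + JSON sidecar, phantoms as
compressed voxel archives with a ground-truth JSON."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .phantom import GroundTruth, Label, Phantom3D, SectionImage


def save_section(path: str | Path, section: SectionImage) -> None:
    """Multi-page TIFF (labels page 0, alveolus identities page 1) plus a
    ``.json`` sidecar with the section metadata and label map."""
    path = Path(path)
    pages = [section.labels.astype(np.int32)]
    has_ids = section.alveolus_id is not None
    if has_ids:
        pages.append(section.alveolus_id.astype(np.int32))
    tifffile.imwrite(path, np.stack(pages))
    sidecar = {
        "z_um": section.z_um,
        "thickness_um": section.thickness_um,
        "pixel_um": section.pixel_um,
        "label_map": {lab.name: int(lab) for lab in Label},
        "alveolus_id_page": 1 if has_ids else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_section(path: str | Path) -> SectionImage:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if pages.ndim == 2:
        pages = pages[None]
    labels = pages[0].astype(np.uint8)
    id_page = meta.get("alveolus_id_page")
    ids = pages[id_page].astype(np.int32) if id_page is not None else None
    return SectionImage(
        labels=labels,
        alveolus_id=ids,
        z_um=float(meta["z_um"]),
        thickness_um=float(meta["thickness_um"]),
        pixel_um=float(meta["pixel_um"]),
    )


def save_phantom(path: str | Path, phantom: Phantom3D) -> None:
    """Compressed voxel archive (.npz) plus ``<stem>.groundtruth.json``."""
    path = Path(path)
    np.savez_compressed(
        path,
        labels=phantom.labels,
        alveolus_id=phantom.alveolus_id,
        voxel_um=phantom.voxel_um,
        seed=-1 if phantom.seed is None else phantom.seed,
        meta=json.dumps(phantom.meta),
    )
    if phantom.ground_truth is not None:
        gt_path = path.parent / (path.stem + ".groundtruth.json")
        gt_path.write_text(json.dumps(dataclasses.asdict(phantom.ground_truth), indent=2))


def load_phantom(path: str | Path) -> Phantom3D:
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        seed = int(npz["seed"])
        phantom = Phantom3D(
            labels=npz["labels"],
            alveolus_id=npz["alveolus_id"],
            voxel_um=float(npz["voxel_um"]),
            seed=None if seed < 0 else seed,
            meta=json.loads(str(npz["meta"])),
        )
    gt_path = path.parent / (path.stem + ".groundtruth.json")
    if gt_path.exists():
        phantom.ground_truth = GroundTruth(**json.loads(gt_path.read_text()))
    return phantom
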