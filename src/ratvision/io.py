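"""On-disk artifacts: reference patterns, reports, manifests.

Numeric payloads round-trip losslessly through ``.npz`` archives; CSV is
used for human-readable tables (accuracy matrices, CSF curves) and PNG only
for presentation renderings of stimuli and maps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, is_dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .readout import AccuracyMatrix
from .saliency import SaliencyMap, overlay_rgb


@dataclass
class ReferencePattern:
    kind: str  # 'accuracy_matrix' | 'saliency_map'
    payload: object
    source: str = ""


def load_reference(path, kind: str, source: str = "") -> ReferencePattern:
    """Load and validate a deposited reference pattern.

    ``accuracy_matrix``: CSV with one condition column per axis and an
    ``accuracy`` column in [0, 1].  ``saliency_map``: .npz with array ``S``
    and optional boolean ``sig_salient`` / ``sig_antisalient``.
    """
    path = Path(path)
    if kind == "accuracy_matrix":
        df = pd.read_csv(path)
        if "accuracy" not in df.columns:
            raise ValueError("accuracy_matrix CSV needs an 'accuracy' column")
        axes = [c for c in df.columns if c != "accuracy"]
        if not axes:
            raise ValueError("accuracy_matrix CSV needs condition columns")
        cells = df.set_index(axes)["accuracy"]
        payload = AccuracyMatrix(cells, meta={"source": source or str(path)})
    elif kind == "saliency_map":
        arrs = np.load(path)
        if "S" not in arrs:
            raise ValueError("saliency_map archive needs array 'S'")
        S = arrs["S"]
        sal = arrs["sig_salient"].astype(bool) if "sig_salient" in arrs else np.zeros(S.shape, bool)
        anti = arrs["sig_antisalient"].astype(bool) if "sig_antisalient" in arrs else np.zeros(S.shape, bool)
        payload = SaliencyMap(S, sal, anti, p_threshold=float(arrs.get("p_threshold", np.nan)),
                              n_permutations=int(arrs["n_permutations"]) if "n_permutations" in arrs else 0)
    else:
        raise ValueError(f"unknown reference kind {kind!r}")
    return ReferencePattern(kind=kind, payload=payload, source=source or str(path))


def save_stimulus_png(image: np.ndarray, path) -> None:
    """8-bit grayscale PNG (presentation only)."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)


def save_stimulus_set(stimuli, directory) -> "pd.DataFrame":
    """Write a stimulus set as 8-bit PNGs plus a manifest CSV.

    ``stimuli`` is an iterable of (object_id, ViewParams, image); the
    manifest records (object_id, size_deg, azimuth_deg, inplane_deg,
    hshift_deg, style, file).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (object_id, view, image) in enumerate(stimuli):
        fn = f"{object_id}_{i:05d}.png"
        save_stimulus_png(image, directory / fn)
        rows.append(
            {
                "object_id": object_id,
                "size_deg": view.size_deg,
                "azimuth_deg": view.azimuth_deg,
                "inplane_deg": view.inplane_deg,
                "hshift_deg": view.hshift_deg,
                "style": view.style,
                "file": fn,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def load_stimulus_set(directory):
    """Load a stimulus set written by :func:`save_stimulus_set`."""
    from .stimuli import ViewParams

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        with Image.open(directory / row["file"]) as im:
            img = np.asarray(im, dtype=np.float64) / 255.0
        view = ViewParams(
            size_deg=row["size_deg"], azimuth_deg=row["azimuth_deg"],
            inplane_deg=row["inplane_deg"], hshift_deg=row["hshift_deg"],
            style=row["style"],
        )
        out.append((row["object_id"], view, img))
    return out


def save_saliency_png(smap: SaliencyMap, path) -> None:
    rgb = (overlay_rgb(smap) * 255).round().astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(provenance: dict) -> str:
    return hashlib.sha256(
        json.dumps(provenance, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_artifact(name: str, obj, directory: Path) -> list[tuple[str, str]]:
    """Write one artifact; returns (filename, type) entries."""
    written = []
    if isinstance(obj, AccuracyMatrix):
        fn = f"{name}.csv"
        obj.to_csv(directory / fn)
        written.append((fn, "accuracy_matrix"))
    elif isinstance(obj, SaliencyMap):
        fn = f"{name}.npz"
        np.savez_compressed(
            directory / fn, S=obj.S, sig_salient=obj.sig_salient,
            sig_antisalient=obj.sig_antisalient,
            p_threshold=obj.p_threshold, n_permutations=obj.n_permutations,
        )
        written.append((fn, "saliency_map"))
        png = f"{name}.png"
        save_saliency_png(obj, directory / png)
        written.append((png, "saliency_png"))
    elif isinstance(obj, np.ndarray):
        fn = f"{name}.npz"
        np.savez_compressed(directory / fn, data=obj)
        written.append((fn, "array"))
    elif isinstance(obj, pd.DataFrame) or isinstance(obj, pd.Series):
        fn = f"{name}.csv"
        obj.to_csv(directory / fn)
        written.append((fn, "table"))
    elif is_dataclass(obj) and not isinstance(obj, type):
        fn = f"{name}.json"
        with open(directory / fn, "w") as fh:
            json.dump(asdict(obj), fh, indent=1, default=str)
        written.append((fn, "json"))
    elif isinstance(obj, (dict, list, float, int, str, bool)) or obj is None:
        fn = f"{name}.json"
        with open(directory / fn, "w") as fh:
            json.dump(obj, fh, indent=1, default=str)
        written.append((fn, "json"))
    else:
        raise TypeError(f"cannot serialize artifact {name!r} of type {type(obj)}")
    return written


def save_report(report, directory) -> dict:
    """Write every report artifact plus a manifest with SHA-256 hashes.

    On any failure, partially written files are removed before re-raising.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    written_paths = []
    try:
        for name, obj in report.artifacts.items():
            if isinstance(obj, dict) and all(
                isinstance(v, SaliencyMap) or v is None for v in obj.values()
            ) and obj and not all(v is None for v in obj.values()):
                for key, smap in obj.items():
                    if smap is None:
                        continue
                    sub = f"{name}_{'_'.join(map(str, key)) if isinstance(key, tuple) else key}"
                    for fn, typ in _write_artifact(sub, smap, directory):
                        written_paths.append(directory / fn)
                        entries.append({"file": fn, "type": typ})
            elif isinstance(obj, list) and obj and isinstance(obj[0], dict) and "accuracy" in obj[0]:
                rows = []
                for row in obj:
                    acc: AccuracyMatrix = row["accuracy"]
                    sub = f"{name}_layer{row['layer']}_run{row.get('run', 0)}_scale{row['scale']}"
                    for fn, typ in _write_artifact(sub, acc, directory):
                        written_paths.append(directory / fn)
                        entries.append({"file": fn, "type": typ})
                    rows.append({k: v for k, v in row.items() if k != "accuracy"})
                for fn, typ in _write_artifact(f"{name}_summary", rows, directory):
                    written_paths.append(directory / fn)
                    entries.append({"file": fn, "type": typ})
            else:
                for fn, typ in _write_artifact(name, obj, directory):
                    written_paths.append(directory / fn)
                    entries.append({"file": fn, "type": typ})
        for e in entries:
            e["sha256"] = _sha256(directory / e["file"])
        manifest = {
            "kind": report.kind,
            "config_hash": _config_hash(report.provenance),
            "provenance": report.provenance,
            "files": entries,
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return manifest
    except Exception:
        for p in written_paths:
            if Path(p).exists():
                Path(p).unlink()
        raise
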