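"""On-disk formats: recordings, matrices, and result manifests.

Recordings are stored as a plain numeric CSV (channels in rows, samples in
columns) plus a JSON sidecar carrying the sampling rate, labels, MNI
coordinates and provenance; square matrices as TSV with a label header row
and a JSON sidecar. ``write_results`` lays out a stage's artifacts
deterministically and writes a manifest with SHA-256 content hashes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a Recording to ``path`` (CSV) with a ``.json`` sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter=",")
    sidecar = {
        "rate": rec.rate,
        "labels": rec.labels,
        "coords": rec.coords.tolist(),
        "meta": rec.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path,
                   sidecar: str | Path | None = None) -> Recording:
    """Read a Recording written by :func:`write_recording`."""
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    try:
        meta = json.loads(Path(sidecar).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar}: {exc}") from exc
    for key in ("rate", "labels", "coords"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required {key!r}")
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if data.shape[0] != len(meta["labels"]):
        raise ValueError(
            f"matrix has {data.shape[0]} rows but sidecar lists "
            f"{len(meta['labels'])} labels"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite values")
    return Recording(data=data, rate=float(meta["rate"]),
                     labels=meta["labels"],
                     coords=np.asarray(meta["coords"], dtype=float),
                     meta=meta.get("meta", {}))


def write_matrix(mat: np.ndarray, labels: list[str], path: str | Path,
                 sidecar: dict | None = None) -> Path:
    """Write a labelled square matrix as TSV (+ optional JSON sidecar)."""
    path = Path(path)
    frame = pd.DataFrame(np.asarray(mat), index=labels, columns=labels)
    frame.to_csv(path, sep="\t")
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.to_numpy(dtype=float), list(frame.index.astype(str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(results: dict[str, object], outdir: str | Path,
                  force: bool = False) -> dict:
    """Serialise a results mapping into ``outdir`` and return the manifest.

    Each key becomes one file: ndarray values -> ``<key>.tsv``, everything
    JSON-serialisable -> ``<key>.json``. Refuses to write into a non-empty
    directory unless ``force`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"{outdir} is not empty; pass force=True (--force) to overwrite"
        )
    artifacts = {}
    for key, value in results.items():
        if isinstance(value, np.ndarray):
            target = outdir / f"{key}.tsv"
            np.savetxt(target, value, delimiter="\t")
        else:
            target = outdir / f"{key}.json"
            target.write_text(json.dumps(value, indent=1, default=_coerce))
        artifacts[target.name] = _sha256(target)
    manifest = {"artifacts": artifacts}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _coerce(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"cannot serialise {type(obj)}")
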