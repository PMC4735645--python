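"""Bundled channel/region montages with MNI-mm coordinates.

Two static tables are packaged:

``"1020-19"``
    The 19 scalp electrodes of the international 10-20 placement
    (Fp1 ... O2), with approximate standard MNI positions. Order follows
    the conventional anterior-to-posterior listing.

``"ba-84"``
    84 cortical regions (42 Brodmann areas x 2 hemispheres, interleaved
    L/R in ascending area number). The coordinates are a SYNTHETIC
    stand-in: anatomically plausible centroids mirrored across the
    midline, packaged as a fixture for geometry-dependent analyses, not
    derived from any particular anatomical atlas release.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_FILES = {
    "1020-19": "electrodes_1020_19.tsv",
    "ba-84": "ba84_centroids_synthetic.tsv",
}


def bundled_montage(name: str) -> tuple[list[str], np.ndarray]:
    """Return ``(labels, coords)`` for a packaged montage.

    Parameters
    ----------
    name : {"1020-19", "ba-84"}

    Returns
    -------
    labels : list of str
    coords : ndarray, shape (n, 3), MNI millimetres
    """
    if name not in _FILES:
        raise KeyError(
            f"unknown montage {name!r}; available: {sorted(_FILES)}"
        )
    ref = resources.files("phasegraph.data").joinpath(_FILES[name])
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    labels = table["label"].tolist()
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    return labels, coords
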