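"""Readers/writers: provenance-stamped CSV tables and PNG rasters.

Every table written by the pipeline carries a one-line comment header
recording the package version, configuration hash and seed, so any output
file can be traced back to the exact run that produced it.  Readers skip
comment lines, making write -> read lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

PROVENANCE_PREFIX = "# phenoshoot"


def write_table(df: pd.DataFrame, path, config_hash: str = "", seed=None) -> Path:
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"{PROVENANCE_PREFIX} v{__version__} config={config_hash or 'none'} seed={seed if seed is not None else 'none'}\n"
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_png(path, array: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(array)).save(path, format="PNG")
    return path


def read_png(path) -> np.ndarray:
    return np.asarray(Image.open(path))


def write_mask_png(path, mask: np.ndarray) -> Path:
    """Binary mask as a 1-bit PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(mask, dtype=bool)).convert("1").save(path, format="PNG")
    return path


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("1"), dtype=bool)
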