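"""File I/O: float32 TIFF images/sinograms, CSV spectra and histories."""

from __future__ import annotations

import numpy as np
import tifffile

__all__ = ["write_image", "read_image", "write_history", "read_history"]


def write_image(path, array: np.ndarray) -> None:
    """Write an image or sinogram as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(array, dtype=np.float32))


def read_image(path) -> np.ndarray:
    """Read a float TIFF back as float64."""
    return tifffile.imread(str(path)).astype(np.float64)


def write_history(path, history) -> None:
    """Write a relative-change history as CSV (iteration, rel_change)."""
    arr = np.column_stack([np.arange(1, len(history) + 1), np.asarray(history)])
    np.savetxt(path, arr, delimiter=",", header="iteration,rel_change", comments="")


def read_history(path) -> np.ndarray:
    return np.atleast_2d(np.genfromtxt(path, delimiter=",", skip_header=1))[:, 1]
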