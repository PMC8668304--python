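"""Postprocessing of tumor probability maps.

Two steps: a global probability threshold turns the tumor-class map into a
binary mask, then connected components smaller than a minimum area are
deleted.  Small-region removal only ever clears tumor pixels; background is
untouched, so the output mask is always a subset of the input and the
operation is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .errors import FormatError, TumorsegError

_CONNECTIVITY = {4: 1, 8: 2}


@dataclass
class PostprocessConfig:
    threshold_tau: float = 0.5
    min_region_px: int = 100
    connectivity: int = 8

    def __post_init__(self):
        if not 0.0 <= self.threshold_tau <= 1.0:
            raise TumorsegError(f"threshold_tau must be in [0, 1], got {self.threshold_tau}")
        if self.min_region_px < 0:
            raise TumorsegError("min_region_px must be >= 0")
        if self.connectivity not in _CONNECTIVITY:
            raise TumorsegError(f"connectivity must be 4 or 8, got {self.connectivity}")


def global_threshold(prob_map: np.ndarray, tau: float) -> np.ndarray:
    """Binarize a probability map: pixel = 1 iff probability >= tau."""
    if not 0.0 <= tau <= 1.0:
        raise TumorsegError(f"tau must be in [0, 1], got {tau}")
    arr = np.asarray(prob_map, dtype=np.float64)
    return (arr >= tau).astype(np.uint8)


def remove_small_regions(
    mask: np.ndarray, min_region_px: int, connectivity: int = 8
) -> np.ndarray:
    """Delete connected 1-components with area < ``min_region_px``."""
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise FormatError("remove_small_regions expects a binary {0,1} mask")
    if connectivity not in _CONNECTIVITY:
        raise FormatError(f"connectivity must be 4 or 8, got {connectivity}")
    if min_region_px <= 1:
        return arr.astype(np.uint8)
    labels = morphology.label(arr.astype(bool), connectivity=_CONNECTIVITY[connectivity])
    areas = np.bincount(labels.ravel())
    keep = areas >= min_region_px
    keep[0] = False
    return keep[labels].astype(np.uint8)


def postprocess_probability_map(
    prob_map: np.ndarray, config: PostprocessConfig | None = None
) -> np.ndarray:
    """Threshold then clean a tumor probability map."""
    cfg = config if config is not None else PostprocessConfig()
    mask = global_threshold(prob_map, cfg.threshold_tau)
    return remove_small_regions(mask, cfg.min_region_px, cfg.connectivity)
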