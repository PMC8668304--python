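import numpy as np
import pytest

from tumorseg.phantom import NoiseSpec, PhantomSpec, TumorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_tumor_spec():
    """240x240 phantom with a centered radius-20 tumor and no noise."""
    return PhantomSpec(
        tumor=TumorSpec(present=True, center=(119.5, 119.5), radius_px=20.0),
        noise=NoiseSpec(sigma=0.0),
        seed=7,
    )


@pytest.fixture
def small_base_spec():
    """64x64 base spec used for fast dataset-level tests."""
    return PhantomSpec(
        height=64,
        width=64,
        tumor=TumorSpec(radius_px=9.0),
        noise=NoiseSpec(sigma=0.02),
    )


# ---------------------------------------------------------------- oracles


def median_oracle(image: np.ndarray) -> np.ndarray:
    """Literal sort-and-middle median over replicated-border 3x3 windows."""
    padded = np.pad(image, 1, mode="edge")
    out = np.empty_like(image, dtype=np.float64)
    h, w = image.shape
    for i in range(h):
        for j in range(w):
            window = sorted(padded[i : i + 3, j : j + 3].ravel())
            out[i, j] = window[4]
    return out


def correlate_oracle(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Per-pixel correlation with edge replication, expanded by hand."""
    padded = np.pad(image, 1, mode="edge")
    h, w = image.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(3):
                for b in range(3):
                    acc += kernel[a, b] * padded[i + a, j + b]
            out[i, j] = acc
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Brute-force BFS connected components of the 1-pixels."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp = set()
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps
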