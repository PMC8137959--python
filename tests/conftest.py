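import math

import numpy as np
import pytest

from nucmorph.synthetic import ShapeSpec, gen_mask


@pytest.fixture(scope="session")
def disk_mask_r50():
    """Rasterized disk, radius 50 px, centered on a 201x201 grid."""
    return gen_mask(ShapeSpec(kind="disk", a=50, b=50, grid=(201, 201)))


@pytest.fixture(scope="session")
def rect_mask_40x20():
    """Filled axis-aligned rectangle: 40 foreground columns x 20 rows."""
    m = np.zeros((30, 50), dtype=np.uint8)
    m[5:25, 5:45] = 1
    return m


def random_blob_mask(seed: int, grid=(101, 101)):
    """A reproducible irregular blob mask for oracle suites.

    Retries (deterministically) the rare draws whose rasterization
    pinches apart.
    """
    from nucmorph.synthetic import SyntheticError

    rng = np.random.default_rng(seed)
    for _ in range(20):
        a = rng.uniform(15, 35)
        ratio = rng.uniform(0.4, 1.0)
        try:
            return gen_mask(
                ShapeSpec(
                    kind="blob",
                    a=a,
                    b=a * ratio,
                    grid=grid,
                    theta=float(rng.uniform(-180, 180)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    irregularity=float(rng.uniform(0.05, 0.35)),
                    n_vertices=int(rng.integers(12, 32)),
                )
            )
        except SyntheticError:
            continue
    raise RuntimeError(f"no valid blob for seed {seed}")


def brute_force_width(points: np.ndarray, angle_deg: float) -> float:
    """Projected extent of a point set along a given direction."""
    th = math.radians(angle_deg)
    proj = points[:, 0] * math.cos(th) + points[:, 1] * math.sin(th)
    return float(proj.max() - proj.min())
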