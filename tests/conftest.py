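import numpy as np
import pytest

from csfcount import PipelineConfig
from csfcount.image import ImageFrame, quantize


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


def make_disk_frame(
    seed: int,
    n: int = 128,
    n_circles: tuple[int, int] = (1, 3),
    noise_sd: float = 150.0,
    pixel_size: float = 0.476,
) -> tuple[ImageFrame, list[tuple[float, float, float]]]:
    """Small frame with non-overlapping dark soft-edged disks.

    Returns the frame and the planted (cx_px, cy_px, r_px) truth list.
    """
    import math

    rng = np.random.default_rng(seed)
    canvas = np.full((n, n), 36000.0)
    k = int(rng.integers(n_circles[0], n_circles[1] + 1))
    placed: list[tuple[float, float, float]] = []
    yy, xx = np.mgrid[0:n, 0:n]
    for _ in range(k):
        r = rng.uniform(4.5, 7.0) / pixel_size
        for _try in range(200):
            cx = rng.uniform(r + 8, n - r - 8)
            cy = rng.uniform(r + 8, n - r - 8)
            if all(math.hypot(cx - a, cy - b) > r + rr + 6 for a, b, rr in placed):
                break
        placed.append((cx, cy, r))
        rho = np.hypot(xx - cx, yy - cy)
        canvas -= 16000.0 / (1.0 + np.exp(np.clip((rho - r) / 0.9, -40, 40)))
    if noise_sd > 0:
        canvas += rng.normal(0, noise_sd, canvas.shape)
    frame = ImageFrame(quantize(canvas, 16), 16, pixel_size, "bright_field")
    return frame, placed
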