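"""Shared test helpers: random geometry and simple spectrum builders."""

import numpy as np

from mdfret import Spectrum


def rectangular_spectrum(lo, hi, value, step=0.1) -> Spectrum:
    w = np.arange(lo, hi + step / 2, step)
    return Spectrum(w, np.full_like(w, float(value)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_unit(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    v = rng.normal(size=(n or 1, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return v if n else v[0]
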