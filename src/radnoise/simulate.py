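"""Seeded generators for repeated radiograph pairs.

Every generator is a pure function of its arguments and an integer seed.  The
two members of a pair draw from distinct RNG substreams derived from the seed
(``SeedSequence(seed, spawn_key=(member,))``) so they are statistically
independent yet jointly reproducible.  Signal scales linearly with mAs through
the reference station (exposure reciprocity); per-pixel variance in a uniform
region is ``gain * mean + electronic_sd**2`` before any correlation term.
"""

from __future__ import annotations

import numpy as np

from .radiograph import InvalidArgumentError, NoiseModel, Radiograph
from .scene import ChestSceneSpec, render_chest_scene

#: Default flat-panel pixel pitch in mm.
DEFAULT_PITCH = 0.15


def substream(seed: int, *key: int) -> np.random.Generator:
    """RNG for a fixed substream of ``seed`` (reproducible independence)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)))


def derive_seed(seed: int, *key: int) -> int:
    """A derived integer seed < 2**31, stable in ``(seed, key)``."""
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)).generate_state(1)[0] % (2**31))


def generate_uniform_pair(
    shape: tuple[int, int],
    mean_at_ref: float,
    mas: float,
    ref_mas: float,
    noise: NoiseModel,
    pitch: float = DEFAULT_PITCH,
    seed: int = 0,
    kvp: float = 85.0,
    label: str = "solid_water",
) -> tuple[Radiograph, Radiograph]:
    """Two independent realizations of a uniform (solid-water) radiograph.

    Expected signal is ``mean_at_ref * mas / ref_mas`` everywhere.  The same
    seed reproduces both members bit-identically.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows < 1 or cols < 1:
        raise InvalidArgumentError("shape must be positive")
    if not mas > 0 or not ref_mas > 0:
        raise InvalidArgumentError("mas and ref_mas must be > 0")
    if not pitch > 0:
        raise InvalidArgumentError("pitch must be > 0")
    scene = np.full((rows, cols), mean_at_ref * mas / ref_mas, dtype=np.float64)
    members = tuple(
        Radiograph(noise.realize(scene, substream(seed, m)), pitch, mas, kvp, label)
        for m in (0, 1)
    )
    return members  # type: ignore[return-value]


def generate_chest_pair(
    spec: ChestSceneSpec,
    mas: float,
    ref_mas: float,
    noise: NoiseModel,
    pitch: float = DEFAULT_PITCH,
    seed: int = 0,
    kvp: float = 85.0,
    label: str = "chest",
) -> tuple[Radiograph, Radiograph]:
    """Two independent noisy realizations of the synthetic chest scene.

    The deterministic scene is available separately via
    :func:`radnoise.scene.render_chest_scene` for oracle checks.
    """
    if not pitch > 0:
        raise InvalidArgumentError("pitch must be > 0")
    scene = render_chest_scene(spec, mas, ref_mas)
    members = tuple(
        Radiograph(noise.realize(scene, substream(seed, m)), pitch, mas, kvp, label)
        for m in (0, 1)
    )
    return members  # type: ignore[return-value]
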