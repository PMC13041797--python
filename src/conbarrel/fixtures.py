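"""Seeded synthetic fixtures: noisy replicas of ideal barrels.

Used to exercise the inverse parameter fit and the symmetry metric under
controlled coordinate noise; identical seeds give bitwise-identical
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import BackboneModel, generate_backbone
from .topology import INNER_S3, get_preset

__all__ = ["FixtureConfig", "make_fixture"]


@dataclass(frozen=True)
class FixtureConfig:
    preset: str = "soluble_hexamer_small"
    barrel: str = INNER_S3          # which barrel of the preset to perturb
    sigma: float = 0.05             # nm, per-coordinate Gaussian noise
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.replicates < 1:
            raise ValueError(
                f"replicates must be >= 1, got {self.replicates}")


def make_fixture(config: FixtureConfig) -> list[BackboneModel]:
    """Noisy replicas of the chosen preset barrel, deterministic per seed."""
    spec = get_preset(config.preset).barrel(config.barrel).spec
    ideal = generate_backbone(spec)
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.replicates):
        noise = (rng.normal(0.0, config.sigma, ideal.coords.shape)
                 if config.sigma > 0 else 0.0)
        out.append(replace(
            ideal,
            coords=ideal.coords + noise,
            provenance=f"fixture:{config.preset}:{config.seed}:{i}",
        ))
    return out
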