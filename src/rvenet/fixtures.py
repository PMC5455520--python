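"""Deterministic scaled-down fixtures for tests and quick exploration.

``tiny`` (5³ mesh, ~20 fibers) solves end-to-end in well under a second;
``small`` (20³ mesh, baseline 698-fiber density) is the scaled-down RVE
used for integration-level runs.
"""

from __future__ import annotations

from .config import GeometryConfig, RunConfig
from .network import BASELINE_FIBER_COUNT, FiberNetwork, calibrate_network

_SIZES = {
    "tiny": {"divisions": 5, "fibers": 20, "seed": 11},
    "small": {"divisions": 20, "fibers": BASELINE_FIBER_COUNT, "seed": 11},
}


def make_fixture(size: str = "tiny") -> tuple[RunConfig, FiberNetwork]:
    """Pre-generated configuration + calibrated network for a fixture size."""
    if size not in _SIZES:
        raise ValueError(f"unknown fixture size {size!r}; choose from {sorted(_SIZES)}")
    preset = _SIZES[size]
    config = RunConfig(
        geometry=GeometryConfig(edge_length=10.0, mesh_divisions=preset["divisions"]),
        seed=preset["seed"],
    )
    config.fiber.concentration = preset["fibers"] / BASELINE_FIBER_COUNT * 1.5
    network = calibrate_network(
        config.rve_geometry(), preset["fibers"], preset["seed"], diameter=config.fiber.diameter
    )
    network.concentration = config.fiber.concentration
    return config, network
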