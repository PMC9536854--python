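"""Somatotopic dorsal-column maps: position ranking, zone wiring, sampling.

Dorsal-column fibers preserve a somatotopic order: fibers from the center
of a receptive field sit most medial and most dorsal at the stimulated
level, with surround fibers displaced laterally and ventrally.  Fiber
positions on a grid are ranked by Z = X^0.15 + Y^0.45, where X and Y are
the mediolateral and dorsoventral coordinates normalized to ranks in
[0, 1] (0 = most medial / most dorsal).  The 20 lowest-Z positions form
tier 1, the next 20 tier 2, the next 20 tier 3.  A sampled map draws 15
positions per tier without replacement, assigns each fiber a diameter from
a truncated normal (µ = 4.4 µm, σ = 1.0 µm, truncated to [2.2, 8] µm),
and wires tiers to network zones according to the targeting condition:

- ``center``:   tier 1 → zone 1, tier 2 → zone 2, tier 3 → zone 3
- ``surround``: tier 1 → zone 2, tier 2 → zone 1, tier 3 → zone 3
- ``mix``:      tier 1 split 8 → zone 1 / 7 → zone 2; tier 2 fills the
  complements (7 → zone 1 / 8 → zone 2); tier 3 → zone 3
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FiberPosition",
    "DCMap",
    "default_grid",
    "rank_positions",
    "sample_map",
    "draw_diameters",
    "map_to_network_inputs",
]

DIAMETER_MEAN_UM = 4.4
DIAMETER_SD_UM = 1.0
DIAMETER_RANGE_UM = (2.2, 8.0)
# Underlying-normal parameters chosen so that, AFTER truncation to the
# simulated range, the sampled diameters have exactly mean 4.4 µm and SD
# 1.0 µm (plain truncation of N(4.4, 1) would bias the mean to ≈4.438 and
# shrink the SD to ≈0.958); solved by moment matching.
_DIAMETER_LOC = 4.344722755737022
_DIAMETER_SCALE = 1.0622403329208705
FIBERS_PER_TIER = 15
TIER_SIZE = 20
N_ZONES = 3
TARGETINGS = ("center", "mix", "surround")


@dataclass(frozen=True)
class FiberPosition:
    """A candidate fiber position on the dorsal-column grid.

    ``x``/``y`` are physical coordinates in mm (x mediolateral from the
    midline, y dorsoventral depth below the cord surface); ``x_rank`` and
    ``y_rank`` are the normalized ranks in [0, 1] used by the Z ordering.
    """

    x: float
    y: float
    x_rank: float
    y_rank: float
    index: int

    @property
    def z_score(self) -> float:
        return self.x_rank**0.15 + self.y_rank**0.45


@dataclass
class DCMap:
    """45 sampled fibers with positions, diameters and zone assignments."""

    fibers: list  # dicts: {position: FiberPosition, diameter_um, zone}
    targeting: str
    seed: int

    def zone_fibers(self, zone: int) -> list:
        return [f for f in self.fibers if f["zone"] == zone]

    def to_json(self) -> str:
        return json.dumps(
            {
                "targeting": self.targeting,
                "seed": self.seed,
                "fibers": [
                    {
                        "x": f["position"].x,
                        "y": f["position"].y,
                        "position_index": f["position"].index,
                        "diameter_um": f["diameter_um"],
                        "zone": f["zone"],
                    }
                    for f in self.fibers
                ],
            },
            indent=1,
        )


def default_grid(
    n_ml: int = 10,
    n_dv: int = 6,
    ml_extent_mm: tuple[float, float] = (0.05, 0.9),
    dv_extent_mm: tuple[float, float] = (0.06, 0.45),
) -> list[FiberPosition]:
    """The default dorsal-column fiber lattice (10 mediolateral × 6 depth).

    Spans one half of the dorsal columns from just lateral of the midline
    to the lateral edge, and from just below the dorsal surface to the
    ventral border of the columns.
    """
    xs = np.linspace(*ml_extent_mm, n_ml)
    ys = np.linspace(*dv_extent_mm, n_dv)
    # normalized ranks: 0 = most medial / most dorsal
    xr = np.linspace(0.0, 1.0, n_ml)
    yr = np.linspace(0.0, 1.0, n_dv)
    grid = []
    idx = 0
    for j, (y, yrank) in enumerate(zip(ys, yr)):
        for i, (x, xrank) in enumerate(zip(xs, xr)):
            grid.append(FiberPosition(x=float(x), y=float(y), x_rank=float(xrank), y_rank=float(yrank), index=idx))
            idx += 1
    return grid


def rank_positions(grid: list[FiberPosition]) -> list[list[FiberPosition]]:
    """Sort positions by Z = X^0.15 + Y^0.45 and cut into three tiers of 20.

    Ties are broken by (x_rank, y_rank) ascending.  Requires ≥60 unique
    positions; positions beyond the first 60 are unused.
    """
    if len(grid) < 3 * TIER_SIZE:
        raise ValueError(f"grid must contain at least {3 * TIER_SIZE} positions")
    seen = {(p.x_rank, p.y_rank) for p in grid}
    if len(seen) != len(grid):
        raise ValueError("duplicate positions in grid")
    ordered = sorted(grid, key=lambda p: (p.z_score, p.x_rank, p.y_rank))
    return [ordered[i * TIER_SIZE : (i + 1) * TIER_SIZE] for i in range(3)]


def _trunc_params(mean: float, sd: float) -> tuple[float, float]:
    if mean == DIAMETER_MEAN_UM and sd == DIAMETER_SD_UM:
        return _DIAMETER_LOC, _DIAMETER_SCALE
    return mean, sd  # custom means/SDs: plain truncation


def draw_diameters(n: int, rng: np.random.Generator,
                   mean: float = DIAMETER_MEAN_UM, sd: float = DIAMETER_SD_UM) -> np.ndarray:
    """Fiber diameters: truncated normal on [2.2, 8] µm with mean 4.4, SD 1.0."""
    lo, hi = DIAMETER_RANGE_UM
    loc, scale = _trunc_params(mean, sd)
    a = (lo - loc) / scale
    b = (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


_ZONE_WIRING = {
    # targeting -> list of (tier index, zone, count)
    "center": [(0, 1, 15), (1, 2, 15), (2, 3, 15)],
    "surround": [(0, 2, 15), (1, 1, 15), (2, 3, 15)],
    "mix": [(0, 1, 8), (0, 2, 7), (1, 1, 7), (1, 2, 8), (2, 3, 15)],
}


def sample_map(
    tiers: list[list[FiberPosition]],
    targeting: str,
    seed: int,
    diameter_mean: float = DIAMETER_MEAN_UM,
    diameter_sd: float = DIAMETER_SD_UM,
) -> DCMap:
    """Draw one randomized dorsal-column map (15 fibers per tier)."""
    if targeting not in _ZONE_WIRING:
        raise ValueError(f"unknown targeting {targeting!r}; expected one of {TARGETINGS}")
    if len(tiers) != 3 or any(len(t) != TIER_SIZE for t in tiers):
        raise ValueError("expected three tiers of 20 positions")
    rng = np.random.default_rng(seed)
    fibers = []
    for tier_idx in range(3):
        rules = [r for r in _ZONE_WIRING[targeting] if r[0] == tier_idx]
        n_needed = sum(r[2] for r in rules)
        chosen = rng.choice(TIER_SIZE, size=n_needed, replace=False)
        positions = [tiers[tier_idx][c] for c in chosen]
        diams = draw_diameters(n_needed, rng, mean=diameter_mean, sd=diameter_sd)
        k = 0
        for _, zone, count in rules:
            for _ in range(count):
                fibers.append({"position": positions[k], "diameter_um": float(diams[k]), "zone": zone})
                k += 1
    return DCMap(fibers=fibers, targeting=targeting, seed=seed)


def map_to_network_inputs(dc_map: DCMap, library, freq: float, pw: float, amplitude: float) -> dict[int, list]:
    """Resolve each fiber's library response into per-zone spike-train bundles.

    Returns ``{zone: [spike_times_ms, ...]}`` with 15 Aβ channels per zone;
    silent (subthreshold) fibers yield empty trains.  Library lookups use
    the nearest simulated diameter.
    """
    if not library.entries:
        raise ValueError("empty response library")
    bundles: dict[int, list] = {z: [] for z in (1, 2, 3)}
    for f in dc_map.fibers:
        spikes = library.spikes(f["position"].index, f["diameter_um"], freq, pw, amplitude)
        bundles[f["zone"]].append(np.asarray(spikes, dtype=float))
    return bundles
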