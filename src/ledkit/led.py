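"""The lineage-specific expression divergence (LED) statistic.

Given expression profiles of a 1:1:1 ortholog triple in species X, Y and Z,
the pairwise Euclidean distances E_XY, E_XZ, E_YZ define an unrooted
three-taxon tree, and the branch length leading to each species is recovered
by the classical three-point formula

    LED_X = (E_XY + E_XZ - E_YZ) / 2

(and cyclically for Y and Z).  A gene whose expression shifted along one
lineage shows one disproportionately long branch.  Because species differ in
generation time and in divergence time from the internal node, raw LED values
can also be scaled by the total number of generations elapsed along each
branch (generations per year × years since the internal node).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .profiles import TRIPLE_AXES

__all__ = [
    "euclidean_distance",
    "compute_led",
    "BranchScale",
    "scale_per_generation",
    "led_table",
]

#: magnitude below which a negative branch length is treated as a
#: floating-point artifact and clamped to zero
NEGATIVE_TOL = 1e-12


def euclidean_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance between two expression profiles.

    Raises ``ValueError`` on length mismatch.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(
            f"profile length mismatch: {p.shape} vs {q.shape}"
        )
    return float(np.sqrt(np.sum((p - q) ** 2)))


def compute_led(e_xy, e_xz, e_yz, *, atol: float = NEGATIVE_TOL):
    """Branch lengths of the unrooted three-taxon tree from pairwise distances.

    Accepts scalars or equal-length arrays.  Distances produced from actual
    vectors satisfy the triangle inequality, so all three branch lengths are
    non-negative; negatives with magnitude ≤ ``atol`` are clamped to zero and
    larger negatives (a non-metric input) raise ``ValueError``.

    Returns ``(led_x, led_y, led_z)`` with the same shape as the inputs.
    """
    e_xy = np.asarray(e_xy, dtype=float)
    e_xz = np.asarray(e_xz, dtype=float)
    e_yz = np.asarray(e_yz, dtype=float)
    if (e_xy < 0).any() or (e_xz < 0).any() or (e_yz < 0).any():
        raise ValueError("pairwise distances must be non-negative")
    led_x = 0.5 * (e_xy + e_xz - e_yz)
    led_y = 0.5 * (e_xy + e_yz - e_xz)
    led_z = 0.5 * (e_xz + e_yz - e_xy)
    stacked = np.stack([led_x, led_y, led_z])
    if (stacked < -atol).any():
        worst = float(stacked.min())
        raise ValueError(
            "triangle inequality violated: branch length "
            f"{worst:g} below -{atol:g}; input distances are not metric"
        )
    stacked = np.clip(stacked, 0.0, None)
    if stacked.ndim == 1:  # scalar inputs
        return float(stacked[0]), float(stacked[1]), float(stacked[2])
    return stacked[0], stacked[1], stacked[2]


@dataclass(frozen=True)
class BranchScale:
    """Generation scaling for one species' branch.

    ``days_to_anthesis`` is the days-to-flowering proxy for generation
    length; ``divergence_my`` the age (million years) of the internal node
    of the three-taxon tree along this branch.
    """

    species: str
    days_to_anthesis: float
    divergence_my: float

    def __post_init__(self) -> None:
        if self.days_to_anthesis <= 0 or self.divergence_my <= 0:
            raise ValueError(
                f"{self.species}: days_to_anthesis and divergence_my "
                "must be strictly positive"
            )

    @property
    def generations_per_year(self) -> float:
        return 365.0 / self.days_to_anthesis

    @property
    def total_generations(self) -> float:
        """Generations elapsed along the branch: 365/days × My × 10^6."""
        return self.generations_per_year * self.divergence_my * 1e6


def scale_per_generation(
    led: pd.DataFrame, scales: Mapping[str, BranchScale]
) -> pd.DataFrame:
    """Divide each lineage's LED column by that branch's total generations.

    ``led`` must contain columns ``led_x``, ``led_y``, ``led_z``; ``scales``
    maps each axis (``"x"``/``"y"``/``"z"``) to its :class:`BranchScale`.
    Returns a copy with added ``led_<axis>_per_generation`` columns; row
    order is preserved.
    """
    missing = [a for a in TRIPLE_AXES if a not in scales]
    if missing:
        raise ValueError(f"missing BranchScale for axis/axes {missing}")
    out = led.copy()
    for axis in TRIPLE_AXES:
        out[f"led_{axis}_per_generation"] = (
            out[f"led_{axis}"] / scales[axis].total_generations
        )
    return out


def led_table(
    triples: pd.DataFrame, profiles: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Pairwise distances and LED for every aligned ortholog triple.

    Parameters
    ----------
    triples:
        Aligned triples (columns ``gene_x``, ``gene_y``, ``gene_z``), e.g.
        the output of :func:`ledkit.profiles.align_triples`.
    profiles:
        Per-axis profile DataFrames (genes × tissues, rows summing to one).

    Returns
    -------
    DataFrame with one row per triple: ``triple_id``, the three gene ids,
    ``e_xy``/``e_xz``/``e_yz`` and ``led_x``/``led_y``/``led_z``.
    """
    mats = {}
    for axis in TRIPLE_AXES:
        mats[axis] = profiles[axis].loc[triples[f"gene_{axis}"]].to_numpy(
            dtype=float
        )
    e_xy = np.sqrt(((mats["x"] - mats["y"]) ** 2).sum(axis=1))
    e_xz = np.sqrt(((mats["x"] - mats["z"]) ** 2).sum(axis=1))
    e_yz = np.sqrt(((mats["y"] - mats["z"]) ** 2).sum(axis=1))
    led_x, led_y, led_z = compute_led(e_xy, e_xz, e_yz)
    out = pd.DataFrame(
        {
            "triple_id": [f"t{i:06d}" for i in range(len(triples))],
            "gene_x": triples["gene_x"].to_numpy(),
            "gene_y": triples["gene_y"].to_numpy(),
            "gene_z": triples["gene_z"].to_numpy(),
            "e_xy": e_xy,
            "e_xz": e_xz,
            "e_yz": e_yz,
            "led_x": led_x,
            "led_y": led_y,
            "led_z": led_z,
        }
    )
    return out
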