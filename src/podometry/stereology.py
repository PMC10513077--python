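"""Model-based stereology: 2D profile readouts to 3D quantities.

Per-glomerulus section measurements (tuft profile area, podocyte nuclear
profile density and area fraction) are extrapolated to tuft volume,
podocyte numerical density and total podocyte number under standard
geometric assumptions:

* tuft volume by the Weibel–Gómez estimator ``V = (β/k)·A^{3/2}`` with the
  sphere shape coefficient β = 1.38 and size-distribution coefficient
  k = 1;
* nuclei modeled as spheres, so the mean random-section profile area is
  ``ā = (2/3)πR²`` and the mean caliper diameter is ``D = 2√(3ā/(2π))``;
* numerical density from profile density by ``N_V = N_A / D``;
* volume density by the Delesse principle, ``V_V = A_A``;
* total number ``N = N_V · V``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StereologyParams",
    "StereologyRecord",
    "tuft_volume",
    "caliper_diameter",
    "density_and_count",
    "stereology_table",
]


@dataclass(frozen=True)
class StereologyParams:
    beta: float = 1.38   # sphere shape coefficient
    k: float = 1.0       # size-distribution coefficient
    nucleus_shape: str = "sphere"

    def __post_init__(self) -> None:
        if self.beta < 1 or self.k < 1:
            raise ValueError("beta and k must be >= 1")
        if self.nucleus_shape != "sphere":
            raise NotImplementedError("only spherical nuclei are supported")


@dataclass(frozen=True)
class StereologyRecord:
    glomerulus_id: int
    tuft_volume_um3: float
    mean_caliper_diameter_um: float
    numerical_density_per_um3: float
    volume_density: float
    total_podocytes: float


def tuft_volume(tuft_area_um2: float, params: StereologyParams = StereologyParams()) -> float:
    """Weibel–Gómez volume from a single profile area: V = (β/k)·A^{3/2}."""
    if tuft_area_um2 < 0:
        raise ValueError("area must be nonnegative")
    return (params.beta / params.k) * tuft_area_um2**1.5


def caliper_diameter(mean_nuclear_profile_area_um2: float,
                     params: StereologyParams = StereologyParams()) -> float:
    """Mean caliper diameter of spherical nuclei from mean section area.

    Inverts ā = (2/3)πR²: R = √(3ā/(2π)), D = 2R.
    """
    a = mean_nuclear_profile_area_um2
    if not a > 0:
        raise ValueError("mean nuclear profile area must be positive")
    return 2.0 * math.sqrt(3.0 * a / (2.0 * math.pi))


def density_and_count(
    profile_density_per_um2: float,
    caliper_diameter_um: float,
    tuft_volume_um3: float,
    nuclear_area_fraction: float,
    glomerulus_id: int = 0,
) -> StereologyRecord:
    """N_V = N_A / D, V_V = A_A (Delesse), N = N_V · V."""
    if caliper_diameter_um <= 0:
        raise ValueError("caliper diameter must be positive")
    if tuft_volume_um3 < 0:
        raise ValueError("volume must be nonnegative")
    if not (0.0 <= nuclear_area_fraction <= 1.0):
        raise ValueError("area fraction must be in [0, 1]")
    n_v = profile_density_per_um2 / caliper_diameter_um
    return StereologyRecord(
        glomerulus_id=glomerulus_id,
        tuft_volume_um3=tuft_volume_um3,
        mean_caliper_diameter_um=caliper_diameter_um,
        numerical_density_per_um3=n_v,
        volume_density=nuclear_area_fraction,
        total_podocytes=n_v * tuft_volume_um3,
    )


def stereology_table(morphometry: pd.DataFrame,
                     params: StereologyParams = StereologyParams()) -> pd.DataFrame:
    """Apply the 3D extrapolation to a per-glomerulus morphometry table.

    Expects the columns written by the morphometry stage
    (``glomerulus_id``, ``tuft_area_um2``, ``podocyte_count``,
    ``mean_nuclear_area_um2``, ``nuclear_tuft_ratio``).  Glomeruli without
    nuclei (undefined mean nuclear area) are skipped.
    """
    records = []
    for row in morphometry.itertuples(index=False):
        a_bar = row.mean_nuclear_area_um2
        if not (isinstance(a_bar, (int, float)) and a_bar > 0) or math.isnan(a_bar):
            continue
        v = tuft_volume(row.tuft_area_um2, params)
        d = caliper_diameter(a_bar, params)
        n_a = row.podocyte_count / row.tuft_area_um2 if row.tuft_area_um2 > 0 else 0.0
        rec = density_and_count(
            n_a, d, v, min(1.0, float(row.nuclear_tuft_ratio)),
            glomerulus_id=int(row.glomerulus_id),
        )
        records.append(rec.__dict__)
    return pd.DataFrame.from_records(
        records,
        columns=["glomerulus_id", "tuft_volume_um3", "mean_caliper_diameter_um",
                 "numerical_density_per_um3", "volume_density", "total_podocytes"],
    )
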