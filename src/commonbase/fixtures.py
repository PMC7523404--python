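"""Embedded benchmark datasets and a seedable synthetic-data generator.

The eight hypothetical datasets bundled here are small worked examples, one
per analysis configuration, used throughout the documentation and the test
suite:

1. hormone concentration (pg/mL) vs dCq(w), tight fit (case A)
2. same design, noisier response (case A)
3. dataset 1 reanalyzed with the maximum x as baseline (no new raw data)
4. dCq(w) vs huddling time in minutes (case B; dataset 1 with axes swapped)
5. dCq(w) of gene A vs dCq(w) of gene B (case C)
6. bacterial density (cells/nL) vs dCq(w), logarithmic in x (case D)
7. dCq(w) vs larval length at pupation in mm, exponential in y (case E)
8. three diet groups across a temperature gradient (ANCOVA)

Only the *input* columns are embedded.  Derived quantities (fitted slopes,
predicted ratios, confidence bands) are deliberately excluded so that tests
must recompute them rather than echo stored answers.

:func:`generate` draws synthetic datasets of the same shapes with known
parameters from ``numpy.random.default_rng`` (the PCG64 generator), so every
dataset is reproducible from its spec alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["example_table", "SyntheticSpec", "generate", "TABLE_IDS"]

TABLE_IDS = (1, 2, 3, 4, 5, 6, 7, 8)

# -- embedded input columns -------------------------------------------------

_HORMONE_X = (8.7, 8.9, 9.4, 9.5, 9.8, 10.1, 10.2, 10.4, 10.6, 10.9)

_DCQ_1 = (0.633, 0.568, 0.534, 0.474, 0.487, 0.428, 0.387, 0.398, 0.360, 0.296)

_DCQ_2 = (0.683, 0.568, 0.598, 0.424, 0.537, 0.428, 0.337, 0.491, 0.360, 0.334)

_DCQ_B_5 = (0.882, 0.845, 0.833, 0.829, 0.811, 0.806, 0.798, 0.766, 0.771, 0.755)

_CELLS_6 = (385.61, 260.29, 176.41, 115.56, 74.72, 49.29, 33.37, 23.12)

_DCQ_6 = (0.345, 0.368, 0.381, 0.405, 0.433, 0.445, 0.468, 0.488)

_DCQ_7 = (0.345, 0.368, 0.381, 0.405, 0.433, 0.445, 0.468, 0.488)

_LENGTH_7 = (8.23, 12.96, 16.49, 24.44, 44.89, 54.76, 75.45, 110.39)

_TEMPS_8 = (22, 24, 26, 28, 30, 32, 34, 36)

_DCQ_8 = {
    "control": (0.511, 0.540, 0.615, 0.694, 0.798, 0.801, 0.895, 0.985),
    "treatment1": (0.238, 0.241, 0.394, 0.401, 0.452, 0.511, 0.631, 0.673),
    "treatment2": (0.236, 0.261, 0.388, 0.424, 0.462, 0.513, 0.586, 0.695),
}


def example_table(table_id: int) -> pd.DataFrame:
    """Return the input columns of embedded dataset 1–8 as a DataFrame.

    Dataset 3 is dataset 1's raw data (it differs only in baseline choice),
    and dataset 4 is dataset 1 with the axes swapped; both are returned in
    their analysis orientation.  Column names state variable and unit.
    """
    if table_id in (1, 3):
        return pd.DataFrame(
            {"hormone_pg_ml": _HORMONE_X, "delta_cq_w": _DCQ_1}
        )
    if table_id == 2:
        return pd.DataFrame(
            {"hormone_pg_ml": _HORMONE_X, "delta_cq_w": _DCQ_2}
        )
    if table_id == 4:
        return pd.DataFrame(
            {"delta_cq_w": _DCQ_1, "huddling_min": _HORMONE_X}
        )
    if table_id == 5:
        return pd.DataFrame({"delta_cq_a": _DCQ_1, "delta_cq_b": _DCQ_B_5})
    if table_id == 6:
        return pd.DataFrame({"cells_per_nl": _CELLS_6, "delta_cq_w": _DCQ_6})
    if table_id == 7:
        return pd.DataFrame({"delta_cq_w": _DCQ_7, "length_mm": _LENGTH_7})
    if table_id == 8:
        rows = [
            (group, temp, dcq)
            for group, dcqs in _DCQ_8.items()
            for temp, dcq in zip(_TEMPS_8, dcqs)
        ]
        return pd.DataFrame(rows, columns=["group", "temperature_c", "delta_cq"])
    raise ValidationError(
        f"unknown table id {table_id!r}; valid ids are {TABLE_IDS}"
    )


# -- synthetic generation ---------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for one synthetic dataset.

    Defaults emulate the hormone study of dataset 1: ten samples over a
    hormone range of 8.7–10.9 pg/mL, slope -0.139 dCq(w) per pg/mL,
    intercept 1.83, and Gaussian noise with SD 0.021 (the residual scatter
    implied by that dataset's slope precision).  ``mode`` selects the
    functional shape; for ``"ancova"`` the ``group_offsets`` map names each
    group's intercept shift added to ``intercept``.
    """

    mode: str = "A"
    slope: float = -0.139
    intercept: float = 1.83
    noise_sd: float = 0.021
    n: int = 10
    x_range: Tuple[float, float] = (8.7, 10.9)
    group_offsets: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("A", "B", "C", "D", "E", "ancova"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n < 3:
            raise ValidationError("n must be >= 3 per group")
        if not self.x_range[0] < self.x_range[1]:
            raise ValidationError("x_range must be increasing")
        if self.mode == "ancova" and not self.group_offsets:
            raise ValidationError("mode 'ancova' requires group_offsets")
        if self.mode == "D" and self.x_range[0] <= 0:
            raise ValidationError("mode 'D' needs a positive x_range")


_MODE_COLUMNS = {
    "A": ("x", "delta_cq_w"),
    "B": ("delta_cq_w", "y"),
    "C": ("delta_cq_a", "delta_cq_b"),
    "D": ("x", "delta_cq_w"),
    "E": ("delta_cq_w", "y"),
}


def generate(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw one dataset from a spec; same spec, same data.

    The linear relationship y = m*x + b + eps is generated on the scale on
    which that mode is linear: mode D builds the response from log10(x) over
    a geometric grid, mode E exponentiates a linear log10(y).  For
    ``"ancova"``, every group shares the covariate grid and slope and gets
    its own intercept.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.x_range
    m, b = spec.slope, spec.intercept

    if spec.mode == "ancova":
        frames = []
        for group, offset in spec.group_offsets.items():
            x = np.linspace(lo, hi, spec.n)
            y = m * x + (b + offset) + rng.normal(0.0, spec.noise_sd, spec.n)
            frames.append(
                pd.DataFrame({"group": group, "x": x, "delta_cq": y})
            )
        return pd.concat(frames, ignore_index=True)

    if spec.mode == "D":
        x = np.geomspace(lo, hi, spec.n)
        predictor = np.log10(x)
    else:
        x = np.linspace(lo, hi, spec.n)
        predictor = x

    y = m * predictor + b + rng.normal(0.0, spec.noise_sd, spec.n)
    if spec.mode == "E":
        y = 10.0**y

    xcol, ycol = _MODE_COLUMNS[spec.mode]
    return pd.DataFrame({xcol: x, ycol: y})
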