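"""Delimited-text readers and writers plus run configuration.

Input is comma-separated with a header row; output is tab-separated with
'#'-prefixed metadata lines, rounded at a configurable precision only at
write time (all in-memory values keep full float precision).  The dialect is
chosen so results paste cleanly into spreadsheet software.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, TextIO, Tuple, Union

import numpy as np
import pandas as pd

from .ancova import Contrast, AncovaFit, GroupedData
from .exceptions import ValidationError
from .expression_models import ExpressionCurve, ResponseCurve
from .linreg import LinearFit
from .quantification import (
    MAX_PLAUSIBLE_EFFICIENCY,
    WellRecord,
)

__all__ = [
    "RunConfig",
    "load_config",
    "read_well_table",
    "read_xy_table",
    "read_grouped_table",
    "write_fit_report",
    "write_curve",
    "write_contrasts",
]

PathLike = Union[str, Path]

WELL_COLUMNS = ("sample_id", "gene", "role", "cq", "efficiency")


@dataclass
class RunConfig:
    """Knobs shared by the command-line pipeline.

    Precedence when assembling one: command-line flags > config file >
    these defaults.
    """

    conf_level: float = 0.95
    alpha: float = 0.05
    baseline_policy: str = "mean"
    mode: str = "A"
    grid_size: int = 0  # 0: observed x values only, no extra even grid
    allow_extrapolation: bool = False
    null_as_unity: bool = False
    adjustment: str = "none"
    output_precision: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.conf_level < 1.0:
            raise ValidationError("conf_level must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.grid_size not in (0,) and self.grid_size < 2:
            raise ValidationError("grid_size must be 0 (off) or >= 2")
        if self.output_precision < 0:
            raise ValidationError("output_precision must be >= 0")


_BOOL_FIELDS = {"allow_extrapolation", "null_as_unity"}
_INT_FIELDS = {"grid_size", "output_precision", "seed"}
_FLOAT_FIELDS = {"conf_level", "alpha"}


def load_config(path: PathLike) -> dict:
    """Parse a flat ``key = value`` config file into a RunConfig kwargs dict.

    Blank lines and '#' comments are ignored.  Unknown keys are an error so
    typos do not silently fall back to defaults.
    """
    known = {f.name for f in dataclasses.fields(RunConfig)}
    out: dict = {}
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(
                f"{path}:{lineno}: expected 'key = value', got {raw!r}"
            )
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in known:
            raise ValidationError(f"{path}:{lineno}: unknown option {key!r}")
        if key in _BOOL_FIELDS:
            if value.lower() not in ("true", "false", "1", "0", "yes", "no"):
                raise ValidationError(
                    f"{path}:{lineno}: {key} must be true/false"
                )
            out[key] = value.lower() in ("true", "1", "yes")
        elif key in _INT_FIELDS:
            out[key] = int(value)
        elif key in _FLOAT_FIELDS:
            out[key] = float(value)
        else:
            out[key] = value
    return out


# -- readers ----------------------------------------------------------------


def _read_csv(path: PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no records (empty file)") from None
    return df


def read_well_table(path: PathLike) -> List[WellRecord]:
    """Read long-format well data: sample_id,gene,role,cq,efficiency.

    Every row is validated; errors name the offending data row (1-based,
    header excluded).  Efficiencies above the plausibility bound are
    rejected here — a value like 85 is almost certainly percentage-style
    and must be converted as E = 1 + pct/100 before import.
    """
    df = _read_csv(path)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ValidationError(f"{path}: no records")

    records: List[WellRecord] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 1
        try:
            cq = float(row["cq"])
            eff = float(row["efficiency"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: row {rowno}: unparseable number in cq/efficiency"
            ) from None
        if math.isnan(cq) or math.isnan(eff):
            raise ValidationError(f"{path}: row {rowno}: blank cq/efficiency")
        if eff > MAX_PLAUSIBLE_EFFICIENCY:
            raise ValidationError(
                f"{path}: row {rowno}: efficiency {eff} exceeds"
                f" {MAX_PLAUSIBLE_EFFICIENCY}; if this is a percentage,"
                " convert it as E = 1 + pct/100"
            )
        try:
            records.append(
                WellRecord(
                    sample_id=str(row["sample_id"]),
                    gene=str(row["gene"]),
                    role=str(row["role"]).strip().lower(),
                    cq=cq,
                    efficiency=eff,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {rowno}: {exc}") from None
    return records


def read_xy_table(
    path: PathLike,
) -> Tuple[np.ndarray, np.ndarray, Tuple[str, str]]:
    """Read a two-column numeric table; returns (x, y, (x_name, y_name)).

    The first column is the independent variable.  Blank or non-numeric
    cells are rejected with the row named; fewer than three complete rows is
    an error (no regression is possible).
    """
    df = _read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(
            f"{path}: need two columns after the header, got {df.shape[1]}"
        )
    df = df.iloc[:, :2]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: row {int(bad[0]) + 1}: blank or non-numeric"
                f" value in column {col!r}"
            )
        df[col] = coerced
    if len(df) < 3:
        raise ValidationError(
            f"{path}: need at least 3 complete rows, got {len(df)}"
        )
    x_name, y_name = (str(c) for c in df.columns)
    return (
        df.iloc[:, 0].to_numpy(dtype=float),
        df.iloc[:, 1].to_numpy(dtype=float),
        (x_name, y_name),
    )


def read_grouped_table(
    path: PathLike,
    group_col: str = "group",
) -> GroupedData:
    """Read an ANCOVA table: group, covariate, delta_cq columns."""
    df = _read_csv(path)
    if df.shape[1] < 3:
        raise ValidationError(
            f"{path}: need columns group, x, delta_cq; got {list(df.columns)}"
        )
    if group_col not in df.columns:
        group_col = str(df.columns[0])
    numeric = [c for c in df.columns if c != group_col][:2]
    return GroupedData.from_dataframe(
        df, group_col=group_col, x_col=numeric[0], y_col=numeric[1]
    )


# -- writers ----------------------------------------------------------------


def _open_out(out: "PathLike | TextIO"):
    if hasattr(out, "write"):
        return out, False
    return open(out, "w", encoding="utf-8"), True


def _fmt(value: float, precision: int) -> str:
    return f"{value:.{precision}f}"


def write_fit_report(
    fit: LinearFit, out: "PathLike | TextIO", precision: int = 3
) -> None:
    """One-row TSV with every LinearFit field (full precision on request)."""
    handle, close = _open_out(out)
    try:
        fields = [f.name for f in dataclasses.fields(fit)]
        handle.write("\t".join(fields) + "\n")
        cells = []
        for name in fields:
            value = getattr(fit, name)
            if isinstance(value, float):
                cells.append(_fmt(value, precision))
            else:
                cells.append(str(value))
        handle.write("\t".join(cells) + "\n")
    finally:
        if close:
            handle.close()


def write_curve(
    curve: "ExpressionCurve | ResponseCurve",
    fit: LinearFit,
    out: "PathLike | TextIO",
    precision: int = 3,
) -> None:
    """Curve TSV with a '#' metadata header recording the provenance."""
    handle, close = _open_out(out)
    is_expression = isinstance(curve, ExpressionCurve)
    try:
        handle.write(f"# mode\t{curve.mode}\n")
        handle.write(f"# m\t{fit.m!r}\n")
        handle.write(f"# ci_slope\t{fit.ci_low!r}\t{fit.ci_high!r}\n")
        handle.write(f"# conf_level\t{fit.conf_level!r}\n")
        handle.write(f"# x0\t{curve.baseline.x0!r}\n")
        handle.write(f"# baseline_policy\t{curve.baseline.policy.value}\n")
        handle.write(f"# null_slope\t{curve.null_slope}\n")
        if not is_expression:
            handle.write(f"# y0_hat\t{curve.y0_hat!r}\n")
        if is_expression:
            handle.write("input\tr_hat\tci_low\tci_high\n")
            rows = zip(curve.inputs, curve.r_hat, curve.ci_low, curve.ci_high)
        else:
            handle.write("ratio\ty_hat\tci_low\tci_high\n")
            rows = zip(curve.ratios, curve.y_hat, curve.ci_low, curve.ci_high)
        for cells in rows:
            handle.write(
                "\t".join(_fmt(float(c), precision) for c in cells) + "\n"
            )
    finally:
        if close:
            handle.close()


def write_contrasts(
    contrasts: Sequence[Contrast],
    fit: AncovaFit,
    out: "PathLike | TextIO",
    precision: int = 3,
) -> None:
    """ANCOVA report: '#' header with the fit, then one row per contrast."""
    handle, close = _open_out(out)
    try:
        handle.write(f"# m_common\t{fit.m_common!r}\n")
        for name, b in fit.intercepts.items():
            handle.write(f"# intercept\t{name}\t{b!r}\n")
        h = fit.homogeneity
        handle.write(
            f"# homogeneity\tF={h.f_stat!r}\tdf=({h.df_num},{h.df_den})"
            f"\tp={h.p_value!r}\n"
        )
        if fit.forced:
            handle.write("# warning\tcommon slope forced despite heterogeneity\n")
        handle.write(
            "group_i\tgroup_j\tdiff\tci_low\tci_high\tp"
            "\tr_hat\tr_ci_low\tr_ci_high\n"
        )
        for c in contrasts:
            handle.write(
                "\t".join(
                    [
                        c.group_i,
                        c.group_j,
                        _fmt(c.diff, precision),
                        _fmt(c.ci[0], precision),
                        _fmt(c.ci[1], precision),
                        _fmt(c.p_value, precision),
                        _fmt(c.r_hat, precision),
                        _fmt(c.r_ci[0], precision),
                        _fmt(c.r_ci[1], precision),
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()
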