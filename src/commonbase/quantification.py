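"""Efficiency-weighted Cq arithmetic.

The common base method puts every qPCR assay on one base-10 log scale by
weighting each quantification cycle with the log of its own amplification
efficiency:

    Cq(w) = log10(E) * Cq

A perfectly doubling assay (E = 2) contributes log10(2) * Cq; a hypothetical
base-10 assay (E = 10) contributes Cq unchanged.  Because all values then
share one scale, normalization against reference genes is a plain arithmetic
mean subtraction, and a difference of two normalized values (a ddCq(w)) maps
to a relative expression ratio as R = 10**(-ddCq(w)).

The log base is fixed at 10 throughout the package.  Mixing bases silently
corrupts every downstream ratio, so no base option is exposed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .exceptions import EfficiencyWarning, ValidationError

__all__ = [
    "WellRecord",
    "WeightedCq",
    "DeltaCqSample",
    "ExpressionRatio",
    "validate_efficiency",
    "weighted_cq",
    "delta_cq",
    "ddcq_to_ratio",
    "ratio_to_ddcq",
]

#: Efficiencies at or below this are rejected: E = 1 means no amplification,
#: E < 1 decay, and values up to 1.2 are almost always percentage-style
#: efficiencies that must be converted as E = 1 + pct/100 first.
MIN_EFFICIENCY = 1.2

#: Above this the record is accepted but flagged: E = 2 is perfect doubling,
#: so anything beyond 2.2 is biologically implausible for a real assay.
MAX_PLAUSIBLE_EFFICIENCY = 2.2

_PERCENT_HINT = (
    "efficiency must be the per-cycle amplification factor (perfect doubling"
    " = 2.0), not a percentage; convert percentage efficiency as"
    " E = 1 + pct/100"
)


def validate_efficiency(efficiency: float, context: str = "") -> None:
    """Reject impossible efficiencies; warn on implausibly high ones.

    Raises :class:`ValidationError` for E <= 1.2 (no amplification, decay, or
    percentage-style input) and emits :class:`EfficiencyWarning` for E > 2.2.
    """
    where = f" ({context})" if context else ""
    if not math.isfinite(efficiency):
        raise ValidationError(f"efficiency must be finite{where}")
    if efficiency <= MIN_EFFICIENCY:
        raise ValidationError(
            f"efficiency {efficiency!r} is not a valid amplification factor"
            f"{where}: {_PERCENT_HINT}"
        )
    if efficiency > MAX_PLAUSIBLE_EFFICIENCY:
        warnings.warn(
            f"efficiency {efficiency!r} exceeds {MAX_PLAUSIBLE_EFFICIENCY}"
            f"{where}; accepted, but check that it is not a percentage"
            " or a typo",
            EfficiencyWarning,
            stacklevel=3,
        )


@dataclass(frozen=True)
class WellRecord:
    """One qPCR measurement: a (sample, gene) pair with Cq and efficiency.

    ``role`` is either ``"target"`` (gene of interest) or ``"reference"``
    (assumed stably expressed; used for normalization).
    """

    sample_id: str
    gene: str
    role: str
    cq: float
    efficiency: float

    def __post_init__(self) -> None:
        if self.role not in ("target", "reference"):
            raise ValidationError(
                f"role must be 'target' or 'reference', got {self.role!r}"
                f" (sample {self.sample_id!r}, gene {self.gene!r})"
            )
        if not math.isfinite(self.cq) or self.cq <= 0:
            raise ValidationError(
                f"cq must be a positive cycle count, got {self.cq!r}"
                f" (sample {self.sample_id!r}, gene {self.gene!r})"
            )
        validate_efficiency(
            self.efficiency,
            context=f"sample {self.sample_id!r}, gene {self.gene!r}",
        )


@dataclass(frozen=True)
class WeightedCq:
    """log10(E) * Cq for one measurement, on the common base-10 scale."""

    value: float
    sample_id: str
    gene: str


@dataclass(frozen=True)
class DeltaCqSample:
    """A per-sample reference-normalized weighted Cq, dCq(w).

    Higher values mean *lower* expression of the gene of interest.
    ``covariates`` optionally carries named per-sample quantities (hormone
    concentration, temperature, ...) for downstream regression or ANCOVA.
    """

    sample_id: str
    value: float
    n_refs: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_refs < 1:
            raise ValidationError("n_refs must be >= 1")
        if not math.isfinite(self.value):
            raise ValidationError(
                f"delta Cq(w) must be finite (sample {self.sample_id!r})"
            )


@dataclass(frozen=True)
class ExpressionRatio:
    """A relative expression ratio R = 10**(-ddCq(w)); always positive."""

    value: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value > 0):
            raise ValidationError(
                f"expression ratio must be a positive finite number, got"
                f" {self.value!r}"
            )

    def __float__(self) -> float:
        return float(self.value)


def weighted_cq(record: WellRecord) -> WeightedCq:
    """Efficiency-weight one measurement: value = log10(E) * Cq."""
    # WellRecord validated on construction; revalidate cheaply in case the
    # caller built one through dataclasses.replace or similar back doors.
    validate_efficiency(
        record.efficiency,
        context=f"sample {record.sample_id!r}, gene {record.gene!r}",
    )
    return WeightedCq(
        value=math.log10(record.efficiency) * record.cq,
        sample_id=record.sample_id,
        gene=record.gene,
    )


def delta_cq(goi: WeightedCq, refs: Iterable[WeightedCq]) -> DeltaCqSample:
    """Normalize a gene of interest against one or more reference genes.

    dCq(w) = Cq(w)_GOI - mean(Cq(w)_REF_i).  The arithmetic mean is correct
    here (never the geometric mean): the values are already on a log scale.
    All inputs must come from the same sample.
    """
    refs = list(refs)
    if not refs:
        raise ValidationError(
            f"at least one reference gene is required to normalize"
            f" sample {goi.sample_id!r}"
        )
    for ref in refs:
        if ref.sample_id != goi.sample_id:
            raise ValidationError(
                f"reference {ref.gene!r} belongs to sample"
                f" {ref.sample_id!r}, not {goi.sample_id!r};"
                " normalization must stay within one sample"
            )
    ref_mean = sum(r.value for r in refs) / len(refs)
    return DeltaCqSample(
        sample_id=goi.sample_id,
        value=goi.value - ref_mean,
        n_refs=len(refs),
    )


def ddcq_to_ratio(ddcq: float) -> ExpressionRatio:
    """Convert a ddCq(w) to a relative expression ratio, R = 10**(-ddcq)."""
    ddcq = float(ddcq)
    if not math.isfinite(ddcq):
        raise ValidationError(f"ddCq(w) must be finite, got {ddcq!r}")
    return ExpressionRatio(10.0 ** (-ddcq))


def ratio_to_ddcq(r: "ExpressionRatio | float") -> float:
    """Invert :func:`ddcq_to_ratio`: ddCq(w) = -log10(R)."""
    value = float(r)
    if not (math.isfinite(value) and value > 0):
        raise ValidationError(
            f"expression ratio must be positive, got {value!r}"
        )
    return -math.log10(value)
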