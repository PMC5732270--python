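"""The mismatch decomposition: normalized condition responses and the
iMM / iRS / iPE indices.

For each neuron/tone point the baseline-corrected spike counts to the tone
as deviant (DEV), standard (STD) and control (CTR) are divided by the
Euclidean norm N = sqrt(DEV² + STD² + CTR²), putting every response in
[0, 1].  Differences between normalized responses define:

* iMM = DEV_n − STD_n  — neuronal mismatch,
* iRS = CTR_n − STD_n  — repetition suppression,
* iPE = DEV_n − CTR_n  — prediction error,

with the exact identity iMM = iRS + iPE.  A positive iPE means the deviant
response exceeds the adaptation-matched control, i.e. genuine deviance
detection rather than stimulus-specific adaptation alone.  The legacy SSA
index (DEV − STD)/(DEV + STD) is provided for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .response import ResponseMeasure

__all__ = [
    "ConditionTriplet",
    "IndexSet",
    "normalize_triplet",
    "compute_indices",
    "ssa_index",
    "decompose",
    "pair_with_control",
]


@dataclass
class ConditionTriplet:
    """Raw (DEV, STD, CTR) responses of one neuron/tone point."""

    dev: float
    std: float
    ctr: float
    control_type: str = "cascade"  # or "many_standards"
    neuron_id: str | int | None = None
    tone_index: int | None = None
    direction: str | None = None  # "ascending" | "descending"
    station: str | None = None

    def __post_init__(self) -> None:
        if min(self.dev, self.std, self.ctr) < 0:
            raise ValueError("condition responses must be non-negative")


@dataclass
class IndexSet:
    """Normalized responses and derived indices for one point.

    ``defined`` is False for the degenerate all-zero triplet, whose
    normalization is undefined; such points are excluded from population
    summaries (they can never pass the significance inclusion rule).
    """

    dev_n: float
    std_n: float
    ctr_n: float
    imm: float
    irs: float
    ipe: float
    ssa: float
    defined: bool = True


def normalize_triplet(
    triplet: ConditionTriplet | tuple[float, float, float],
) -> tuple[float, float, float]:
    """Divide (DEV, STD, CTR) by its Euclidean norm; unit vector out."""
    dev, std, ctr = _unpack(triplet)
    n = math.sqrt(dev * dev + std * std + ctr * ctr)
    if n == 0.0:
        raise ZeroDivisionError("all-zero triplet has no defined normalization")
    return dev / n, std / n, ctr / n


def compute_indices(dev_n: float, std_n: float, ctr_n: float) -> IndexSet:
    """Index differences from already-normalized responses.

    iMM = iRS + iPE holds exactly because the three indices are pairwise
    differences of the same three numbers.
    """
    imm = dev_n - std_n
    irs = ctr_n - std_n
    ipe = dev_n - ctr_n
    return IndexSet(
        dev_n=dev_n,
        std_n=std_n,
        ctr_n=ctr_n,
        imm=imm,
        irs=irs,
        ipe=ipe,
        ssa=ssa_index(dev_n, std_n),
    )


def ssa_index(dev: float, std: float) -> float:
    """Legacy adaptation index (DEV − STD)/(DEV + STD); NaN when both are
    zero."""
    if dev < 0 or std < 0:
        raise ValueError("responses must be non-negative")
    total = dev + std
    if total == 0.0:
        return float("nan")
    return (dev - std) / total


def decompose(
    triplet: ConditionTriplet | tuple[float, float, float],
) -> IndexSet:
    """Normalization plus indices in one call; degenerate triplets yield an
    IndexSet of NaNs flagged ``defined=False``."""
    dev, std, ctr = _unpack(triplet)
    try:
        dev_n, std_n, ctr_n = normalize_triplet((dev, std, ctr))
    except ZeroDivisionError:
        nan = float("nan")
        return IndexSet(nan, nan, nan, nan, nan, nan, nan, defined=False)
    out = compute_indices(dev_n, std_n, ctr_n)
    out.ssa = ssa_index(dev, std)
    return out


def pair_with_control(
    dev: ResponseMeasure | float,
    cascade_asc: ResponseMeasure | float | None,
    cascade_desc: ResponseMeasure | float | None,
    many_standards: ResponseMeasure | float | None,
    std: ResponseMeasure | float,
    direction: str,
    **meta,
) -> list[ConditionTriplet]:
    """Build the (DEV, STD, CTR) triplets for one deviant tone.

    Ascending deviants take the ascending cascade as control and descending
    deviants the descending cascade, so the tone immediately preceding the
    target is the same in the oddball and cascade sequences.  The
    many-standards control applies to both directions.  One triplet per
    available control type is returned.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    cascade = cascade_asc if direction == "ascending" else cascade_desc
    if cascade is None:
        raise ValueError(f"missing {direction} cascade control")
    out = [
        ConditionTriplet(
            dev=_val(dev), std=_val(std), ctr=_val(cascade),
            control_type="cascade", direction=direction, **meta,
        )
    ]
    if many_standards is not None:
        out.append(
            ConditionTriplet(
                dev=_val(dev), std=_val(std), ctr=_val(many_standards),
                control_type="many_standards", direction=direction, **meta,
            )
        )
    return out


def _val(x: ResponseMeasure | float) -> float:
    return float(x.bcsc) if isinstance(x, ResponseMeasure) else float(x)


def _unpack(
    triplet: ConditionTriplet | tuple[float, float, float],
) -> tuple[float, float, float]:
    if isinstance(triplet, ConditionTriplet):
        return float(triplet.dev), float(triplet.std), float(triplet.ctr)
    dev, std, ctr = triplet
    if min(dev, std, ctr) < 0:
        raise ValueError("condition responses must be non-negative")
    return float(dev), float(std), float(ctr)
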