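"""ChIP-qPCR and expression arithmetic.

Percent input, fold-over-reference (e.g. a histone-mark ChIP over total
H3) with first-order error propagation, re-ChIP enrichment relative to the
first ChIP's input, ΔΔCq relative expression against a housekeeping-gene
panel, and the paired two-tailed t-test.

All quantities assume an amplification efficiency of 2.0 per cycle (one
Cq cycle = one doubling); the efficiency is configurable per measure. All
standard errors are first-order delta-method values propagated from the
replicate Cq spread (SEM by default, SD selectable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import t as t_dist

ROLES = ("IP", "input", "IgG", "first_chip_input")


@dataclass
class QpcrMeasure:
    """Replicate Cq values for one target in one well group."""

    target: str
    cq: tuple[float, ...]
    role: str = "IP"
    input_fraction: float = 1.0
    antibody: str = ""
    efficiency: float = 2.0
    spread: str = "sem"  # sem | sd — which replicate spread to propagate

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if len(self.cq) < 1 or any(c <= 0 for c in self.cq):
            raise ValueError("need >= 1 positive Cq replicate")
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")
        if self.efficiency <= 1:
            raise ValueError("efficiency must exceed 1 per cycle")

    @property
    def mean_cq(self) -> float:
        return float(np.mean(self.cq))

    @property
    def se_cq(self) -> float:
        if len(self.cq) == 1:
            return 0.0
        sd = float(np.std(self.cq, ddof=1))
        return sd if self.spread == "sd" else sd / math.sqrt(len(self.cq))


@dataclass(frozen=True)
class RatioWithError:
    value: float
    se: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


def percent_input(ip: QpcrMeasure, input_: QpcrMeasure) -> RatioWithError:
    """ChIP enrichment as the percentage of input chromatin recovered.

    The input Cq is first corrected for its dilution: an input that is a
    fraction f of the IP chromatin would have amplified log_E(1/f) cycles
    earlier at full strength. Then

        %input = 100 * E^(adjusted input Cq - IP Cq).

    The SE follows by the delta method from the replicate Cq SEs:
    SE% = %input * ln(E) * sqrt(SE_IP^2 + SE_input^2).
    """
    if input_.role not in ("input", "first_chip_input"):
        raise ValueError(f"denominator must have an input role, got {input_.role!r}")
    e = ip.efficiency
    adjusted_input_cq = input_.mean_cq - math.log(1.0 / input_.input_fraction, e)
    value = 100.0 * e ** (adjusted_input_cq - ip.mean_cq)
    se = value * math.log(e) * math.sqrt(ip.se_cq**2 + input_.se_cq**2)
    return RatioWithError(value, se)


def rechip_enrichment(second_chip: QpcrMeasure, first_input: QpcrMeasure) -> RatioWithError:
    """Sequential-ChIP enrichment relative to the *first* ChIP's input."""
    if first_input.role != "first_chip_input":
        raise ValueError("re-ChIP denominator must have role 'first_chip_input'")
    return percent_input(second_chip, first_input)


def fold_over_reference(a: RatioWithError, b: RatioWithError) -> RatioWithError:
    """Ratio of two measured quantities with propagated relative errors,
    e.g. percent-input of a histone mark over percent-input of total H3."""
    if b.value == 0:
        raise ValueError("reference value is zero")
    r = a.value / b.value
    se = abs(r) * math.sqrt((a.se / a.value) ** 2 + (b.se / b.value) ** 2)
    return RatioWithError(r, se)


def ddcq_expression(
    target_cq: dict[str, float],
    housekeeping_cq: dict[str, dict[str, float]],
    condition: str = "kd",
    control: str = "ctrl",
    efficiency: float = 2.0,
) -> float:
    """ΔΔCq fold change of ``condition`` relative to ``control``.

    ``target_cq`` maps condition -> mean target Cq; ``housekeeping_cq``
    maps housekeeping gene -> {condition -> mean Cq}. ΔCq per condition is
    the target Cq minus the arithmetic mean of the housekeeping Cqs (the
    geometric mean of the housekeeping quantities in linear space);
    fold = E^(ΔCq_control − ΔCq_condition).
    """
    for cond in (condition, control):
        if cond not in target_cq:
            raise ValueError(f"target Cq missing condition {cond!r}")
        missing = [g for g, d in housekeeping_cq.items() if cond not in d]
        if missing:
            raise ValueError(
                f"housekeeping set mismatch: genes {missing} lack condition {cond!r}"
            )
    if not housekeeping_cq:
        raise ValueError("need at least one housekeeping gene")
    dcq = {
        cond: target_cq[cond]
        - float(np.mean([d[cond] for d in housekeeping_cq.values()]))
        for cond in (condition, control)
    }
    return float(efficiency ** (dcq[control] - dcq[condition]))


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired two-tailed Student's t-test on matched values.

    Returns (t, df, p). Computed from the textbook formula on the paired
    differences: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1, p two-sided
    from the t distribution.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("differences have zero variance; t is undefined")
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return t, df, p
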