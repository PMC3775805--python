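"""Flat-harmonic cross-link restraints and satisfaction rules.

A DSS/BS3 cross-link constrains the distance between the linked CB atoms.
The score is flat (zero penalty) across the whole range a relaxed linker can
bridge and rises quadratically beyond it:

    penalty(d) = 0                                   if |d - x0| <= tol
               = ((|d - x0| - tol) / sigma)^2        otherwise

With the DSS defaults x0 = 15.0 A, tol = 15.0 A, sigma = 1.0 A the penalty
kicks in only past 30.0 A.  Satisfaction rules are explicit objects because
two thresholds coexist in practice: 30.0 A on the Euclidean distance when
scoring, 34.0 A on the SAS distance when filtering models or enumerating
virtual cross-links.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .sasd import CrossLink

__all__ = [
    "RestraintParams",
    "Metric",
    "SatisfactionRule",
    "flat_harmonic",
    "is_satisfied",
    "write_rosetta_constraints",
    "EUCLIDEAN_SCORING_RULE",
    "SASD_FILTER_RULE",
]

DEFAULT_ATOM_NAME = "CB"


@dataclass(frozen=True)
class RestraintParams:
    """Flat-harmonic parameters (Angstrom). Defaults are the DSS values."""

    x0: float = 15.0
    tolerance: float = 15.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


class Metric(str, Enum):
    EUCLIDEAN = "euclidean"
    SASD = "sasd"


@dataclass(frozen=True)
class SatisfactionRule:
    metric: Metric = Metric.SASD
    threshold: float = 34.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


#: 30.0 A Euclidean threshold used when scoring models with restraints.
EUCLIDEAN_SCORING_RULE = SatisfactionRule(Metric.EUCLIDEAN, 30.0)
#: 34.0 A SAS threshold used for filtering and virtual cross-links.
SASD_FILTER_RULE = SatisfactionRule(Metric.SASD, 34.0)


def flat_harmonic(d: float, params: RestraintParams = RestraintParams()) -> float:
    """Flat-harmonic penalty for an observed distance ``d`` (Angstrom)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    excess = abs(d - params.x0) - params.tolerance
    if excess <= 0:
        return 0.0
    return (excess / params.sigma) ** 2


def is_satisfied(xl: CrossLink, rule: SatisfactionRule = SASD_FILTER_RULE) -> bool:
    """Whether a cross-link is satisfied under the given rule.

    Pairwise links compare the rule's distance (which must have been
    computed); a negative SAS distance (no solvent path) is never satisfied.
    Mono-links are satisfied iff their site is solvent-accessible.
    """
    if xl.is_mono:
        if xl.accessible is None:
            raise ValueError(f"mono-link {xl.spec1}: accessibility not computed")
        return xl.accessible
    d = xl.euclidean if rule.metric is Metric.EUCLIDEAN else xl.sasd
    if d is None:
        raise ValueError(f"cross-link {xl.spec1}-{xl.spec2}: {rule.metric.value} not computed")
    return 0.0 <= d <= rule.threshold


def write_rosetta_constraints(
    xls: Iterable[CrossLink],
    params: RestraintParams = RestraintParams(),
    atom_name: str = DEFAULT_ATOM_NAME,
) -> str:
    """Emit ROSETTA AtomPair FLAT_HARMONIC constraint lines.

    One line per pairwise cross-link, in the field order ROSETTA expects
    (note: x0, then standard deviation, then tolerance):

        AtomPair CB 1A CB 8A FLAT_HARMONIC 15.0 1.0 15.0

    The atom name from the spec is used when present, else ``atom_name``.
    Mono-links cannot be expressed as AtomPair constraints and raise.
    """
    lines = []
    for xl in xls:
        if xl.is_mono:
            raise ValueError(f"mono-link {xl.spec1} cannot be written as an AtomPair")
        a1 = xl.spec1.atom_name or atom_name
        a2 = xl.spec2.atom_name or atom_name
        lines.append(
            f"AtomPair {a1} {xl.spec1.res_seq}{xl.spec1.chain_id} "
            f"{a2} {xl.spec2.res_seq}{xl.spec2.chain_id} "
            f"FLAT_HARMONIC {params.x0} {params.sigma} {params.tolerance}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
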