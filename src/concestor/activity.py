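"""Reporter-activity and binding-titration statistics.

Reporter activities are replicate fluorescence intensities per construct,
normalized to a reference construct as percent-of-reference: the reference
mean is set to 100% and every test construct is reported as
``100 * mean(test) / mean(ref) ± SEM``, where the SEM uses the test
construct's n-1 sample standard deviation and the reference's uncertainty is
not propagated (matching the per-construct "±" reporting convention).

Binding titrations are summarized by a detection threshold: the smallest
protein amount at which a shift is detected.  The relative affinity of a
variant site versus a reference site is the percent ratio of these
thresholds, reported as-is at the granularity of the titration steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


class TitrationError(ValueError):
    """Raised for non-monotone detection series or an undetectable variant."""


@dataclass(frozen=True)
class ActivityMeasurements:
    """Replicate reporter intensities for one construct (arbitrary units)."""

    construct_id: str
    intensities: tuple[float, ...]
    segment: str = "A6"
    sex: str = "female"

    def __post_init__(self) -> None:
        if len(self.intensities) < 1:
            raise ValueError(f"{self.construct_id}: need at least one replicate")
        if any(x <= 0 for x in self.intensities):
            raise ValueError(f"{self.construct_id}: intensities must be positive")

    @property
    def n(self) -> int:
        return len(self.intensities)

    @property
    def mean(self) -> float:
        return sum(self.intensities) / self.n

    @property
    def sem(self) -> float:
        """Standard error of the mean (n-1 sd); NaN for a single replicate."""
        if self.n < 2:
            return math.nan
        m = self.mean
        var = sum((x - m) ** 2 for x in self.intensities) / (self.n - 1)
        return math.sqrt(var) / math.sqrt(self.n)


@dataclass(frozen=True)
class NormalizedActivity:
    """Percent-of-reference activity with its SEM on the percent scale."""

    construct_id: str
    percent: float
    sem_percent: float
    n: int

    def __str__(self) -> str:  # the field's reporting convention
        return f"{self.percent:.0f}±{self.sem_percent:.0f}% (n={self.n})"


@dataclass(frozen=True)
class TitrationSeries:
    """Per-lane detection outcomes over increasing protein amounts (ng).

    Detection must be monotone: once a shift is detected it stays detected at
    every higher amount (violations are a data error, not noise to smooth).
    """

    probe_id: str
    amounts_ng: tuple[float, ...]
    detected: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.amounts_ng) != len(self.detected):
            raise TitrationError(f"{self.probe_id}: amounts and detections differ in length")
        if len(self.amounts_ng) == 0:
            raise TitrationError(f"{self.probe_id}: empty titration series")
        if any(b >= a for a, b in zip(self.amounts_ng[1:], self.amounts_ng)):
            raise TitrationError(f"{self.probe_id}: amounts must be strictly increasing")
        seen = False
        for d in self.detected:
            if seen and not d:
                raise TitrationError(
                    f"{self.probe_id}: detection must be monotone non-decreasing"
                )
            seen = seen or d

    @property
    def threshold_ng(self) -> float | None:
        """Smallest amount with a detected shift, or None if never detected."""
        for amount, d in zip(self.amounts_ng, self.detected):
            if d:
                return amount
        return None


def normalize_activity(
    test: ActivityMeasurements, ref: ActivityMeasurements
) -> NormalizedActivity:
    """Percent-of-reference normalization.

    ``percent = 100 * mean(test) / mean(ref)``;
    ``sem_percent = 100 * sem(test) / mean(ref)``.  Reference uncertainty is
    ignored.  Segment and sex labels must agree — activities measured in
    different segments or sexes are not comparable.
    """
    if (test.segment, test.sex) != (ref.segment, ref.sex):
        raise ValueError(
            f"label mismatch: {test.segment}/{test.sex} vs {ref.segment}/{ref.sex}"
        )
    ref_mean = ref.mean
    if ref_mean == 0:
        raise ValueError("reference mean is zero")
    return NormalizedActivity(
        construct_id=test.construct_id,
        percent=100.0 * test.mean / ref_mean,
        sem_percent=100.0 * test.sem / ref_mean,
        n=test.n,
    )


def fold_range(percents: Sequence[float]) -> float:
    """Ratio of the largest to the smallest mean activity (>= 1)."""
    if not percents:
        raise ValueError("need at least one mean")
    if any(p <= 0 for p in percents):
        raise ValueError("means must be positive")
    return max(percents) / min(percents)


def additivity(
    singles: Sequence[float], combined_observed: float
) -> dict[str, float]:
    """Additive expectation for combined mutations on the percent scale.

    With the reference at 100%, each single mutation contributes its
    deviation from 100, so ``expected = 100 + sum(single_i - 100)`` and
    ``deviation = observed - expected`` (negative means sub-additive).
    """
    if not singles:
        raise ValueError("need at least one single-mutation mean")
    expected = 100.0 + sum(s - 100.0 for s in singles)
    return {"expected": expected, "deviation": combined_observed - expected}


def relative_affinity(reference: TitrationSeries, variant: TitrationSeries) -> float:
    """Percent affinity of the variant site relative to the reference site.

    ``100 * threshold(reference) / threshold(variant)`` where the threshold
    is the minimal protein amount producing a detected shift.  The estimate's
    granularity is that of the titration steps; no interpolation.
    """
    ref_thr = reference.threshold_ng
    var_thr = variant.threshold_ng
    if ref_thr is None:
        raise TitrationError(f"{reference.probe_id}: reference series has no detected lane")
    if var_thr is None:
        raise TitrationError(f"{variant.probe_id}: variant never detected (affinity below range)")
    return 100.0 * ref_thr / var_thr
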