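"""Brown-planthopper severity grading from five-clump field counts.

Each 1 m observation plot is surveyed at five points (four corners plus the
centre); the plot-level pest pressure is the arithmetic mean count in
individuals per clump.  Following the national survey rules for rice
planthoppers, the mean maps to three levels: mild (< 5 individuals per
clump), moderate (5–10, both boundaries inclusive) and severe (> 10).

Because planthopper density drifts quickly, a single-date count is a noisy
label.  The dual-date label averages the two survey dates' plot means and
grades that average — the labelling used by the dual-temporal
difference-feature scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SEVERITY_LEVELS", "plot_mean", "grade", "dual_label", "PlotSurvey"]

#: Ordered severity levels, mild -> severe.
SEVERITY_LEVELS = ("mild", "moderate", "severe")

#: numeric rank of each level (1-based, used by the synthetic stress model)
SEVERITY_RANK = {lab: i + 1 for i, lab in enumerate(SEVERITY_LEVELS)}


def plot_mean(clump_counts) -> float:
    """Arithmetic mean of per-clump counts (individuals per clump)."""
    counts = np.asarray(clump_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one clump count")
    if np.any(counts < 0):
        raise ValueError("clump counts cannot be negative")
    return float(counts.mean())


def grade(mean_count: float) -> str:
    """Severity level for a plot-mean count.

    mild iff < 5; moderate iff in [5, 10]; severe iff > 10.  The printed
    interval bounds put 5 and 10 in the moderate class.
    """
    if mean_count < 0:
        raise ValueError("mean count cannot be negative")
    if mean_count < 5:
        return "mild"
    if mean_count <= 10:
        return "moderate"
    return "severe"


@dataclass
class PlotSurvey:
    """One observation plot's counts at both survey dates.

    ``counts_t1`` / ``counts_t2`` may be the five raw clump counts or an
    already-averaged plot mean (field tables often record the mean).
    """

    plot_id: int
    counts_t1: object = None
    counts_t2: object = None
    mean_t1: float = field(default=None)
    mean_t2: float = field(default=None)

    def __post_init__(self) -> None:
        if self.mean_t1 is None and self.counts_t1 is not None:
            self.mean_t1 = plot_mean(np.atleast_1d(self.counts_t1))
        if self.mean_t2 is None and self.counts_t2 is not None:
            self.mean_t2 = plot_mean(np.atleast_1d(self.counts_t2))

    @property
    def dual_mean(self) -> float:
        if self.mean_t1 is None or self.mean_t2 is None:
            raise ValueError("both survey dates are required for the dual-date mean")
        return (self.mean_t1 + self.mean_t2) / 2.0

    def severity(self, date: str | None = None) -> str:
        """Severity label: dual-date by default, or for one date ('T1'/'T2')."""
        if date is None:
            return grade(self.dual_mean)
        mean = {"T1": self.mean_t1, "T2": self.mean_t2}.get(date)
        if mean is None:
            raise ValueError(f"no counts recorded for date {date!r}")
        return grade(mean)


def dual_label(survey: PlotSurvey) -> str:
    """Severity graded on the average of the two dates' plot means.

    Symmetric in the two dates; raises if either date is missing.
    """
    return grade(survey.dual_mean)
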