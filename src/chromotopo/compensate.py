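"""Dosage-compensation ratios from dual-luciferase reporter tables.

A firefly luciferase reporter carrying a roX element is transcriptionally
up-regulated (~2-fold) when the MSL complex assembles on it; a co-transfected
Renilla luciferase normalises for transfection efficiency.  Compensation is
the ratio of relative activity (firefly/Renilla) between cells transfected
with the roX-bearing plasmid and cells transfected with a plasmid lacking
the roX site, averaged over independent experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LuciferaseSample",
    "CompensationResult",
    "relative_activity",
    "compensation_ratio",
    "compare_treatments",
]


@dataclass(frozen=True)
class LuciferaseSample:
    """One dual-luciferase measurement."""

    sample_id: str
    plasmid: str  # "roX" or "no_roX"
    firefly: float
    renilla: float
    treatment_label: str = ""

    def __post_init__(self):
        if self.plasmid not in ("roX", "no_roX"):
            raise ValueError(f"plasmid must be 'roX' or 'no_roX', got {self.plasmid!r}")
        if self.firefly <= 0 or self.renilla <= 0:
            raise ValueError(f"sample {self.sample_id}: activities must be positive")


@dataclass(frozen=True)
class CompensationResult:
    """Fold compensation over replicate experiments.

    ``fold`` is the mean of per-replicate ratios (experiments were averaged
    at the replicate level); ``fold_of_means`` divides the arm means
    instead, reported alongside for comparison.
    """

    fold: float
    sd: float
    n: int
    fold_of_means: float
    treatment_label: str = ""

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n) if self.n > 1 else float("nan")


def relative_activity(sample: LuciferaseSample) -> float:
    """Firefly activity normalised to the Renilla internal control."""
    return sample.firefly / sample.renilla


def compensation_ratio(
    rox_samples: Sequence[LuciferaseSample],
    no_rox_samples: Sequence[LuciferaseSample],
    treatment_label: str = "",
) -> CompensationResult:
    """Fold enhancement of the roX-bearing reporter over the roX-less one.

    Replicates are paired by order (experiment i of each arm); each pair
    contributes one ratio of relative activities, and the fold is the mean
    of those ratios.  With unequal arm sizes the ratio of arm means is the
    primary estimate and no replicate sd is defined.
    """
    if len(rox_samples) == 0 or len(no_rox_samples) == 0:
        raise ValueError("both arms need at least one sample")
    ra = np.array([relative_activity(s) for s in rox_samples])
    rb = np.array([relative_activity(s) for s in no_rox_samples])
    fold_of_means = float(ra.mean() / rb.mean())
    if ra.size == rb.size:
        ratios = ra / rb
        fold = float(ratios.mean())
        sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
        n = int(ratios.size)
    else:
        fold, sd, n = fold_of_means, float("nan"), int(min(ra.size, rb.size))
    return CompensationResult(
        fold=fold, sd=sd, n=n, fold_of_means=fold_of_means,
        treatment_label=treatment_label,
    )


def compare_treatments(
    a: CompensationResult, b: CompensationResult
) -> tuple[float, float]:
    """Welch t-test on fold compensation between two treatments.

    Returns ``(t_statistic, p_value)``; used e.g. to ask whether an ISWI
    knockdown changes the compensation of the reporter.
    """
    if a.n < 2 or b.n < 2 or not np.isfinite(a.sd) or not np.isfinite(b.sd):
        raise ValueError("need >= 2 paired replicates per treatment for a test")
    t, p = stats.ttest_ind_from_stats(
        a.fold, a.sd, a.n, b.fold, b.sd, b.n, equal_var=False
    )
    return float(t), float(p)
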