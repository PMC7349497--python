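"""Error statistics of the dietary-intake validation trials.

The packaged fixture holds the 13 validation trials comparing, per
meal, the control measurement (weighing scale) against three assessment
methods: an automated 24-hour dietary recall interview
(``recall_24hr``), the MyFitnessPal tracking app (``myfitnesspal``),
and the 3D-scanner pipeline this package implements (``scanner``).
Cells where a method was not administered are ``NF`` (not found): the
no-information participant group never used MyFitnessPal.

Summary statistics per method, over the trials where the method has
data:

* total absolute error (g) — sum of |estimate - actual|;
* absolute error percent — total absolute error divided by the total
  actual grams of those trials, times 100;
* standard deviation (g) — population SD (divide by n) of the
  per-trial absolute errors.

The recall-method summary printed in the original study record (389 g,
51%, SD 34 g) is not reproducible from its own per-trial column by any
single rule (the column's absolute errors sum to 504 g); it is kept
here as metadata only and is never recomputed or asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "Trial",
    "MethodStats",
    "PRINTED_RECALL_SUMMARY",
    "load_reference_trials",
    "method_stats",
]

METHODS = ("recall_24hr", "myfitnesspal", "scanner")

#: Recall-method summary as originally printed; metadata only (see module
#: docstring), never recomputed.
PRINTED_RECALL_SUMMARY = {
    "total_abs_error_g": 389.0,
    "abs_error_pct": 51.0,
    "sd_g": 34.0,
}


@dataclass(frozen=True)
class Trial:
    """One meal: control grams and per-method estimated grams."""

    trial: int
    actual_g: float
    estimates: dict  # method -> grams, or None where not administered

    def error(self, method: str) -> float | None:
        est = self.estimates.get(method)
        return None if est is None else est - self.actual_g


@dataclass(frozen=True)
class MethodStats:
    total_abs_error_g: float
    abs_error_pct: float
    sd_g: float


def load_reference_trials() -> list[Trial]:
    """The 13 packaged validation trials, verbatim."""
    with resources.files("mealscan.data").joinpath("intake_trials.csv").open() as fh:
        df = pd.read_csv(fh, na_values=["NF"])
    trials = []
    for row in df.itertuples(index=False):
        est = {}
        for method in METHODS:
            val = getattr(row, f"{method}_g")
            est[method] = None if pd.isna(val) else float(val)
        trials.append(Trial(trial=int(row.trial), actual_g=float(row.actual_g), estimates=est))
    return trials


def method_stats(trials, method: str) -> MethodStats:
    """Summary error statistics for one method.

    Only trials where the method reported a value contribute, both to
    the error total and to the actual-gram denominator of the percent.

    Raises
    ------
    ValueError
        If the method reported in no trial.
    """
    errors = []
    actual = []
    for t in trials:
        e = t.error(method)
        if e is not None:
            errors.append(abs(e))
            actual.append(t.actual_g)
    if not errors:
        raise ValueError(f"method {method!r} has no data in any trial")
    errors = np.asarray(errors, dtype=float)
    total = float(errors.sum())
    pct = 100.0 * total / float(np.sum(actual))
    sd = float(np.sqrt(np.mean((errors - errors.mean()) ** 2)))  # population SD
    return MethodStats(total_abs_error_g=total, abs_error_pct=pct, sd_g=sd)
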