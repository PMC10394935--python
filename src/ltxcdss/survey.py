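"""Survey psychometrics: Lawshe content-validity ratio with item retention,
Cronbach's alpha, and PSSUQ subscale scoring.

The content validity ratio for one item is CVR = (n_e - N/2) / (N/2), where
n_e experts of N rated the item essential; it runs from -1 (none) through 0
(exactly half) to +1 (unanimous).  The minimum CVR an item must reach
depends on panel size; the conventional critical-value table ships as
editable CSV config rather than hard-coded numbers.

Item retention supports a secondary mean-score rule with *two* thresholds —
keep at or above ``mean_keep``, drop below ``mean_drop`` — because retention
protocols sometimes leave a gap between the two; items whose mean falls in
[mean_drop, mean_keep) are flagged borderline instead of being silently
classified.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

__all__ = [
    "SurveyMatrix",
    "CvrItem",
    "cvr",
    "lawshe_critical_value",
    "retain_items",
    "RetentionResult",
    "cronbach_alpha",
    "PSSUQ_V3_SUBSCALES",
    "pssuq_scores",
    "pooled_stats",
    "PssuqResult",
]


@dataclass
class SurveyMatrix:
    """A respondents x items score grid with declared scale bounds."""

    scores: pd.DataFrame  # rows = respondents, columns = items
    scale_min: float = 1.0
    scale_max: float = 7.0

    def __post_init__(self):
        if not isinstance(self.scores, pd.DataFrame):
            self.scores = pd.DataFrame(self.scores)
        values = self.scores.to_numpy(dtype=float)
        in_range = np.isnan(values) | ((values >= self.scale_min) & (values <= self.scale_max))
        if not in_range.all():
            bad = np.argwhere(~in_range)[0]
            raise ValueError(
                f"score out of [{self.scale_min}, {self.scale_max}] at "
                f"respondent {self.scores.index[bad[0]]!r}, item {self.scores.columns[bad[1]]!r}"
            )

    @property
    def n_respondents(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]


def cvr(n_e: int, n_experts: int) -> float:
    """Lawshe content validity ratio (n_e - N/2) / (N/2)."""
    if n_experts < 1:
        raise ValueError(f"need at least one expert, got {n_experts}")
    if not 0 <= n_e <= n_experts:
        raise ValueError(f"essential count must be in [0, {n_experts}], got {n_e}")
    half = n_experts / 2.0
    return (n_e - half) / half


def lawshe_critical_value(n_experts: int, table_path=None) -> float:
    """Minimum CVR for retention at the given panel size.

    Reads the bundled critical-value table (or a caller-supplied CSV with
    columns ``n_experts, critical_cvr``); for a panel size between tabulated
    rows the next-smaller tabulated size is used.
    """
    if table_path is None:
        text = resources.files("ltxcdss").joinpath("data/lawshe_critical_values.csv").read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(table_path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    table = sorted((int(r["n_experts"]), float(r["critical_cvr"])) for r in rows)
    if n_experts < table[0][0]:
        raise ValueError(f"no critical value tabulated for panels smaller than {table[0][0]}")
    value = table[0][1]
    for n, crit in table:
        if n <= n_experts:
            value = crit
    return value


@dataclass
class CvrItem:
    label: str
    n_essential: int
    n_experts: int
    cvr: float = field(init=False)
    retained: bool | None = None

    def __post_init__(self):
        self.cvr = cvr(self.n_essential, self.n_experts)


@dataclass
class RetentionResult:
    retained: list[CvrItem]
    discarded: list[CvrItem]
    borderline: list[CvrItem]

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def retain_items(
    items: Sequence[CvrItem],
    critical_value: float,
    mean_scores: Mapping[str, float] | None = None,
    mean_keep: float = 3.6,
    mean_drop: float = 3.5,
) -> RetentionResult:
    """Partition items into retained / discarded / borderline.

    An item is retained iff its CVR reaches ``critical_value`` and (when mean
    scores are supplied) its mean reaches ``mean_keep``.  Items passing the
    CVR bar whose mean lies in [``mean_drop``, ``mean_keep``) fall in the gap
    between the keep and drop rules and are flagged borderline.
    """
    if mean_drop > mean_keep:
        raise ValueError("mean_drop threshold cannot exceed mean_keep")
    retained, discarded, borderline = [], [], []
    for item in items:
        if item.cvr < critical_value:
            item.retained = False
            discarded.append(item)
            continue
        if mean_scores is None:
            item.retained = True
            retained.append(item)
            continue
        mean = mean_scores[item.label]
        if mean >= mean_keep:
            item.retained = True
            retained.append(item)
        elif mean < mean_drop:
            item.retained = False
            discarded.append(item)
        else:
            item.retained = None
            borderline.append(item)
    return RetentionResult(retained, discarded, borderline)


def cronbach_alpha(matrix: SurveyMatrix | pd.DataFrame) -> float:
    """Internal-consistency reliability over a respondents x items grid.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    with sample (ddof=1) variances.  Rows with any missing cell are dropped
    listwise before computation.
    """
    scores = matrix.scores if isinstance(matrix, SurveyMatrix) else pd.DataFrame(matrix)
    scores = scores.dropna(axis=0, how="any")
    n, k = scores.shape
    if k < 2:
        raise ValueError(f"need at least 2 items, got {k}")
    if n < 2:
        raise ValueError(f"need at least 2 complete respondents, got {n}")
    values = scores.to_numpy(dtype=float)
    item_vars = values.var(axis=0, ddof=1)
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateInputError("total-score variance is zero; alpha is undefined")
    return (k / (k - 1)) * (1.0 - item_vars.sum() / total_var)


# PSSUQ Version 3 (16 items): 1-6 system usefulness, 7-12 information
# quality, 13-15 interface quality, overall = all 16.  Fully overridable.
PSSUQ_V3_SUBSCALES: dict[str, tuple[int, ...]] = {
    "system_usefulness": tuple(range(1, 7)),
    "information_quality": tuple(range(7, 13)),
    "interface_quality": tuple(range(13, 16)),
    "overall": tuple(range(1, 17)),
}


@dataclass
class PssuqResult:
    respondent_scores: pd.DataFrame  # rows respondents, columns subscales
    pooled: pd.DataFrame  # rows subscales, columns mean/median/sd/n


def pooled_stats(scores: Sequence[float]) -> dict[str, float | None]:
    """Pooled mean, median and sample SD of per-respondent scores.

    SD is undefined (reported as None) for a single respondent.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("no scores supplied")
    return {
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else None,
        "n": int(arr.size),
    }


def pssuq_scores(
    matrix: SurveyMatrix | pd.DataFrame,
    item_map: Mapping[str, Sequence] | None = None,
) -> PssuqResult:
    """Score a PSSUQ response matrix into subscale and overall results.

    ``item_map`` maps subscale name to the item labels (matrix columns) it
    comprises; defaults to the 16-item Version-3 layout with integer item
    labels.  A respondent's subscale score is the mean of their items in the
    subscale; pooled statistics are then taken across respondents.
    Every matrix column must belong to at least one subscale.
    """
    scores = matrix.scores if isinstance(matrix, SurveyMatrix) else pd.DataFrame(matrix)
    item_map = dict(item_map) if item_map is not None else {
        k: v for k, v in PSSUQ_V3_SUBSCALES.items()
    }
    mapped = {label for items in item_map.values() for label in items}
    unmapped = [c for c in scores.columns if c not in mapped]
    if unmapped:
        raise ValueError(f"items not mapped to any subscale: {unmapped}")
    per_resp = {}
    for subscale, items in item_map.items():
        missing = [i for i in items if i not in scores.columns]
        if missing:
            raise ValueError(f"subscale {subscale!r} references absent items: {missing}")
        per_resp[subscale] = scores[list(items)].mean(axis=1)
    respondent_scores = pd.DataFrame(per_resp)
    pooled = pd.DataFrame(
        {sub: pooled_stats(col) for sub, col in respondent_scores.items()}
    ).T[["mean", "median", "sd", "n"]]
    return PssuqResult(respondent_scores=respondent_scores, pooled=pooled)
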