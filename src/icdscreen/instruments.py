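"""Scoring and diagnostic algorithms for the IDQ and IAQ screening scales.

The International Depression Questionnaire (IDQ, 9 items) and International
Anxiety Questionnaire (IAQ, 8 items) are self-report screens aligned with the
ICD-11 descriptions of Depressive Episode and Generalized Anxiety Disorder.
Each item is rated 0 ("Never") to 4 ("Every day"); an item is *endorsed* when
rated 3 ("Most days") or 4 ("Every day").  Caseness is algorithmic, not
cut-off based:

* IDQ: at least one of the two affective-cluster items (1, 2) endorsed,
  at least 5 of the 9 items endorsed in total, and the functional-impairment
  question answered "Yes".
* IAQ: at least one of the two essential-feature items (1, 2) endorsed,
  at least 4 of the 8 items endorsed, and impairment answered "Yes".

Severity scores are plain item sums (0-36 for the IDQ, 0-32 for the IAQ).
The PHQ-9 and GAD-7 comparators use the conventional >= 10 sum cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilres
from typing import Optional, Sequence

import numpy as np
import yaml
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "InstrumentSpec",
    "ResponseVector",
    "DiagnosticResult",
    "PrevalenceResult",
    "load_instrument",
    "endorsement_vector",
    "sum_score",
    "diagnose",
    "diagnose_depressive_episode",
    "diagnose_gad",
    "comparator_case",
    "prevalence_with_ci",
    "reference_resource",
]


def reference_resource() -> dict:
    """Load the bundled instrument resource (item texts, anchors, published
    2PL parameters and observed response distributions)."""
    with _ilres.files("icdscreen.resources").joinpath("instruments.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class InstrumentSpec:
    """Static definition of one instrument: items and diagnostic rule.

    ``core_items`` are 1-based indices (matching the published item tables)
    of the affective-cluster / essential-feature items, at least one of which
    must be endorsed for caseness.
    """

    name: str
    item_texts: tuple[str, ...]
    core_items: frozenset[int]
    min_endorsed: int
    endorsement_threshold: int = 3

    def __post_init__(self) -> None:
        if not self.core_items <= set(range(1, self.n_items + 1)):
            raise ValueError("core_items must be 1-based indices within the item range")
        if self.min_endorsed > self.n_items:
            raise ValueError("min_endorsed cannot exceed the number of items")

    @property
    def n_items(self) -> int:
        return len(self.item_texts)

    @property
    def score_max(self) -> int:
        return 4 * self.n_items


def load_instrument(name: str) -> InstrumentSpec:
    """Return the bundled spec for ``"idq"`` or ``"iaq"``."""
    res = reference_resource()
    key = name.lower()
    if key not in ("idq", "iaq"):
        raise KeyError(f"unknown instrument {name!r}; expected 'idq' or 'iaq'")
    block = res[key]
    return InstrumentSpec(
        name=block["name"],
        item_texts=tuple(block["items"]),
        core_items=frozenset(block["core_items"]),
        min_endorsed=int(block["min_endorsed"]),
        endorsement_threshold=int(res["endorsement_threshold"]),
    )


@dataclass(frozen=True)
class ResponseVector:
    """One respondent's ordinal answers (0-4) plus the yes/no impairment item.

    ``impairment`` is True/False, or None when the impairment question was
    not answered (caseness is then undetermined for otherwise-positive
    symptom profiles).
    """

    values: tuple[int, ...]
    impairment: Optional[bool] = None

    def __post_init__(self) -> None:
        for i, v in enumerate(self.values, start=1):
            if not (isinstance(v, (int, np.integer)) and 0 <= int(v) <= 4):
                raise ValueError(
                    f"invalid response {v!r} at item {i}: responses must be integers in 0-4"
                )


@dataclass(frozen=True)
class DiagnosticResult:
    """Outcome of applying a diagnostic algorithm to one respondent.

    ``case`` is None when the symptom criteria are met but the impairment
    answer is missing (undetermined), per the complete-information policy.
    """

    endorsed_mask: tuple[bool, ...]
    n_endorsed: int
    core_met: bool
    impairment_met: Optional[bool]
    case: Optional[bool]
    sum_score: int

    @property
    def undetermined(self) -> bool:
        return self.case is None


@dataclass(frozen=True)
class PrevalenceResult:
    n_cases: int
    n_total: int
    proportion: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95


def _check_length(responses: ResponseVector, spec: InstrumentSpec) -> None:
    if len(responses.values) != spec.n_items:
        raise ValueError(
            f"{spec.name} expects {spec.n_items} item responses, got {len(responses.values)}"
        )


def endorsement_vector(responses: ResponseVector, spec: InstrumentSpec) -> np.ndarray:
    """Boolean endorsement per item: rated at or above the 'Most days' anchor."""
    _check_length(responses, spec)
    return np.asarray(responses.values) >= spec.endorsement_threshold


def sum_score(responses: ResponseVector) -> int:
    """Severity sum score across all items (0 to 4 x n_items)."""
    return int(np.sum(responses.values))


def diagnose(responses: ResponseVector, spec: InstrumentSpec) -> DiagnosticResult:
    """Apply the ICD-11-derived diagnostic algorithm for ``spec``.

    Caseness requires (i) at least one core item endorsed, (ii) at least
    ``spec.min_endorsed`` items endorsed overall, and (iii) impairment
    answered "Yes".  A missing impairment answer leaves a symptom-positive
    respondent undetermined (``case=None``) rather than counting them as a
    non-case.
    """
    endorsed = endorsement_vector(responses, spec)
    n_endorsed = int(endorsed.sum())
    core_met = bool(any(endorsed[i - 1] for i in spec.core_items))
    symptoms_met = core_met and n_endorsed >= spec.min_endorsed
    if responses.impairment is None:
        case = False if not symptoms_met else None
    else:
        case = symptoms_met and bool(responses.impairment)
    return DiagnosticResult(
        endorsed_mask=tuple(bool(e) for e in endorsed),
        n_endorsed=n_endorsed,
        core_met=core_met,
        impairment_met=responses.impairment,
        case=case,
        sum_score=sum_score(responses),
    )


def diagnose_depressive_episode(
    responses: ResponseVector, spec: InstrumentSpec | None = None
) -> DiagnosticResult:
    """IDQ rule: core item endorsed, >=5 of 9 endorsed, impairment yes."""
    spec = spec or load_instrument("idq")
    if spec.n_items != 9:
        raise ValueError("depressive-episode algorithm requires a 9-item instrument")
    return diagnose(responses, spec)


def diagnose_gad(
    responses: ResponseVector, spec: InstrumentSpec | None = None
) -> DiagnosticResult:
    """IAQ rule: essential feature endorsed, >=4 of 8 endorsed, impairment yes."""
    spec = spec or load_instrument("iaq")
    if spec.n_items != 8:
        raise ValueError("generalized-anxiety algorithm requires an 8-item instrument")
    return diagnose(responses, spec)


def comparator_case(responses: Sequence[int], cutoff: int = 10) -> tuple[int, bool]:
    """Sum-score caseness for the PHQ-9 / GAD-7 comparators (items rated 0-3)."""
    arr = list(responses)
    for i, v in enumerate(arr, start=1):
        if not (isinstance(v, (int, np.integer)) and 0 <= int(v) <= 3):
            raise ValueError(
                f"invalid response {v!r} at item {i}: comparator items must be integers in 0-3"
            )
    score = int(sum(arr))
    return score, score >= cutoff


def prevalence_with_ci(
    n_cases: int, n_total: int, conf_level: float = 0.95
) -> PrevalenceResult:
    """Point prevalence with a Wilson score interval.

    The Wilson interval inverts the score test for a binomial proportion and
    behaves well for the small proportions typical of diagnostic prevalence.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_cases <= n_total:
        raise ValueError("n_cases must be between 0 and n_total")
    lo, hi = proportion_confint(n_cases, n_total, alpha=1 - conf_level, method="wilson")
    phat = n_cases / n_total
    # exact boundary values at phat = 0 or 1; guard numerical dust elsewhere
    lo = 0.0 if n_cases == 0 else min(float(lo), phat)
    hi = 1.0 if n_cases == n_total else max(float(hi), phat)
    return PrevalenceResult(
        n_cases=int(n_cases),
        n_total=int(n_total),
        proportion=n_cases / n_total,
        ci_low=float(lo),
        ci_high=float(hi),
        conf_level=conf_level,
    )
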