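"""Scoring of pipeline output against synthetic ground truth.

A term is *flagged* when its mean p-value across imputations is at or
below 0.05 (the bold marker of the report tables).  A true main effect
counts as recovered when it appears in any flagged term, individually
or inside an interaction; a true interaction counts when a flagged
interaction matches its pair.  Derived k-day-average columns stand in
for their source variable (``x03_4DaysAv`` recovers ``x03``): the
window average is the same physical quantity, and the generator makes
the two nearly collinear by design, so the screen may legitimately
retain either.  False positives are flagged non-intercept terms that
match no true term under that mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

from milasso import stepwise as sw
from milasso.features import TEMPORAL_SUFFIXES
from milasso.pooling import PooledModel
from milasso.synthetic_data import SimulationDesign


def base_variable(name: str) -> str:
    """Source variable of a (possibly derived) column name."""
    for suffix in TEMPORAL_SUFFIXES.values():
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


@dataclass
class RecoveryScore:
    mains_recovered: int
    n_true_mains: int
    interactions_recovered: int
    n_true_interactions: int
    false_positives: int
    flagged_terms: list[str]
    blocking_in_model: int


def score_recovery(model: PooledModel, design: SimulationDesign) -> RecoveryScore:
    true_mains = set(design.true_mains)
    true_inters = {tuple(sorted(p)) for p in design.true_interactions}

    flagged = [t.term for t in model.terms if t.primary and t.term != "(Intercept)"]
    got_mains: set[str] = set()
    got_inters: set[tuple[str, str]] = set()
    fp = 0
    for term in flagged:
        parts = tuple(sorted(base_variable(v) for v in sw.parse_term(term)))
        if len(parts) == 1:
            if parts[0] in true_mains:
                got_mains.add(parts[0])
            else:
                fp += 1
        else:
            if parts in true_inters:
                got_inters.add(parts)  # type: ignore[arg-type]
                got_mains.update(p for p in parts if p in true_mains)
            else:
                fp += 1

    all_terms = [t.term for t in model.terms if t.term != "(Intercept)"]
    blocking = sum(
        1 for t in all_terms
        for v in sw.parse_term(t)
        if v.startswith("Origin")
    )
    return RecoveryScore(
        mains_recovered=len(got_mains),
        n_true_mains=len(true_mains),
        interactions_recovered=len(got_inters),
        n_true_interactions=len(true_inters),
        false_positives=fp,
        flagged_terms=flagged,
        blocking_in_model=blocking,
    )
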