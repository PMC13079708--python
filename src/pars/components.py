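"""Per-visit pharmacological risk components.

Five engineered components feed the aggregate score:

* ``ddi_score``    — severity-weighted DDI burden, 3*N_major + 2*N_moderate + 1*N_minor
                     over all unordered pairs of the visit's unique drugs;
* ``has_polypharmacy`` — 1 iff the visit records >= 5 unique drugs;
* ``azcert_max``   — the highest per-drug QT-risk score at the visit, with
                     known=3, possible=2, conditional=1, unlisted=0;
* ``acb_score``    — the summed anticholinergic cognitive burden (unlisted
                     drugs contribute 0);
* ``sero_any``     — 1 iff at least one serotonergic agent is present.

``azcert_sum`` (the summed QT score) and ``sero_count`` are computed and
reported for description but are not part of the composite; ``azcert_max``
is the primary QT signal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import pandas as pd

from .cohort import Cohort, Visit
from .knowledge_base import KnowledgeBase

#: the five composite inputs, in canonical order
PARS_COMPONENTS = ("ddi_score", "has_polypharmacy", "azcert_max", "acb_score", "sero_any")

POLYPHARMACY_CUTOFF = 5

_SEVERITY_WEIGHT = {"major": 3, "moderate": 2, "minor": 1}
_QT_SCORE = {"known": 3, "possible": 2, "conditional": 1}


@dataclass(frozen=True)
class DdiCounts:
    """Pair counts by interaction severity; sums to C(n_drugs, 2)."""

    n_major: int
    n_moderate: int
    n_minor: int
    n_none: int

    @property
    def total_pairs(self) -> int:
        return self.n_major + self.n_moderate + self.n_minor + self.n_none


@dataclass(frozen=True)
class ComponentScores:
    visit_id: str
    ddi_score: int
    has_polypharmacy: int
    azcert_max: int
    azcert_sum: int
    acb_score: int
    sero_count: int
    sero_any: int
    n_drugs: int
    n_major: int
    n_moderate: int
    n_minor: int
    n_none: int


def count_ddi_pairs(visit: Visit, kb: KnowledgeBase) -> DdiCounts:
    """Classify every unordered pair of the visit's unique drugs.

    A single-drug visit has no pairs, hence all-zero counts; pairs absent
    from the DDI table count as "no interaction found".
    """
    counts = {"major": 0, "moderate": 0, "minor": 0, "none": 0}
    for a, b in combinations(sorted(visit.drugs), 2):
        counts[kb.pair_severity(a, b)] += 1
    return DdiCounts(counts["major"], counts["moderate"], counts["minor"], counts["none"])


def ddi_score(counts: DdiCounts) -> int:
    """Severity-weighted interaction burden: 3*major + 2*moderate + 1*minor."""
    return 3 * counts.n_major + 2 * counts.n_moderate + 1 * counts.n_minor


def polypharmacy_flag(visit: Visit) -> int:
    """1 iff the visit's unique drug set has >= 5 members."""
    return int(visit.n_drugs >= POLYPHARMACY_CUTOFF)


def azcert_drug_score(kb: KnowledgeBase, drug: str) -> int:
    """QT-risk score of one drug: known=3, possible=2, conditional=1, else 0."""
    cat = kb.qt_category(drug)
    return _QT_SCORE.get(cat, 0)


def azcert_visit_scores(visit: Visit, kb: KnowledgeBase) -> tuple[int, int]:
    """(max, sum) of per-drug QT-risk scores over the visit's unique drugs."""
    scores = [azcert_drug_score(kb, d) for d in visit.drugs]
    return max(scores), sum(scores)


def acb_visit_score(visit: Visit, kb: KnowledgeBase) -> int:
    """Summed anticholinergic burden; unlisted drugs contribute 0."""
    return sum(kb.acb_score(d) for d in visit.drugs)


def sero_scores(visit: Visit, kb: KnowledgeBase) -> tuple[int, int]:
    """(count, any-flag) of serotonergic agents at the visit."""
    count = sum(kb.is_serotonergic(d) for d in visit.drugs)
    return count, int(count >= 1)


def compute_components(visit: Visit, kb: KnowledgeBase) -> ComponentScores:
    """Assemble all per-visit risk components; deterministic in (visit, kb)."""
    counts = count_ddi_pairs(visit, kb)
    az_max, az_sum = azcert_visit_scores(visit, kb)
    s_count, s_any = sero_scores(visit, kb)
    return ComponentScores(
        visit_id=visit.visit_id,
        ddi_score=ddi_score(counts),
        has_polypharmacy=polypharmacy_flag(visit),
        azcert_max=az_max,
        azcert_sum=az_sum,
        acb_score=acb_visit_score(visit, kb),
        sero_count=s_count,
        sero_any=s_any,
        n_drugs=visit.n_drugs,
        n_major=counts.n_major,
        n_moderate=counts.n_moderate,
        n_minor=counts.n_minor,
        n_none=counts.n_none,
    )


def components_frame(cohort: Cohort, kb: KnowledgeBase) -> pd.DataFrame:
    """Component table for a whole cohort, indexed by visit_id."""
    rows = [asdict(compute_components(v, kb)) for v in cohort]
    return pd.DataFrame(rows).set_index("visit_id")
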