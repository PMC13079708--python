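"""Cohort-level companion analyses.

Component redundancy (variance inflation factors and quartile-based
discordance between polypharmacy and DDI burden), ranked patient risk
profiles, and top-visit reports.  Outputs are de-identified: ranks and age
decades only, never raw identifiers or exact ages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .components import PARS_COMPONENTS


class AnalyticsError(ValueError):
    pass


def component_vifs(components: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per component, VIF = 1/(1 - R^2), from an
    OLS regression of each component on the other four (intercept included),
    plus the pairwise correlation matrix.

    A perfectly collinear component is flagged with infinite VIF.
    """
    cols = list(PARS_COMPONENTS)
    missing = [c for c in cols if c not in components.columns]
    if missing:
        raise AnalyticsError(f"missing component columns: {missing}")
    sub = components[cols].astype(float)
    if len(sub) < 6:
        raise AnalyticsError("need at least 6 visits for VIF estimation")
    rows = {}
    for c in cols:
        X = sm.add_constant(sub.drop(columns=c))
        r2 = sm.OLS(sub[c], X).fit().rsquared
        rows[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vif = pd.Series(rows, name="vif")
    corr = sub.corr()
    return pd.DataFrame({"vif": vif}), corr


def discordance_counts(components: pd.DataFrame) -> dict:
    """Quartile-based discordance between drug count and DDI burden.

    Quartiles of ``ddi_score`` are computed over all visits; reported are
    visits with < 5 drugs yet ddi_score >= Q75, and polypharmacy visits with
    ddi_score <= Q25 (comparisons inclusive, exactly as defined).
    """
    if len(components) == 0:
        raise AnalyticsError("empty component table")
    ddi = components["ddi_score"].astype(float)
    q25, q75 = ddi.quantile(0.25), ddi.quantile(0.75)
    poly = components["has_polypharmacy"].astype(int) == 1
    high_ddi = ddi >= q75
    low_ddi = ddi <= q25
    return {
        "q25": float(q25),
        "q75": float(q75),
        "n_highDDI_nonpoly": int((high_ddi & ~poly).sum()),
        "n_poly_lowDDI": int((low_ddi & poly).sum()),
        "n_visits": int(len(components)),
    }


def age_decade(age: float) -> str:
    """Decade band of an age in years, e.g. 62 -> \"60-69\" (lower edge inclusive)."""
    if age < 0:
        raise AnalyticsError(f"negative age {age}")
    lo = int(age // 10) * 10
    return f"{lo}–{lo + 9}"


PROFILE_RANK_KEYS = ("n_high_risk", "parsr_max", "parsr_mean")


def patient_profiles(
    cohort: Cohort,
    pars_frame: pd.DataFrame,
    rank_by: str = "n_high_risk",
    top_k: int | None = 10,
) -> pd.DataFrame:
    """Per-patient risk aggregates, ranked descending by the chosen key.

    ``pars_frame`` is the scored-visit table (columns ``pars``,
    ``pars_rescaled``, ``high_risk``, indexed by visit_id).  Ties break on
    ``parsr_mean`` and then on stable patient order; output rows are
    de-identified (rank + age decade).
    """
    if rank_by not in PROFILE_RANK_KEYS:
        raise AnalyticsError(f"rank_by must be one of {PROFILE_RANK_KEYS}")
    rows = []
    for pid in cohort.patient_ids:
        visits = cohort.patient_visits(pid)
        vids = [v.visit_id for v in visits]
        sub = pars_frame.loc[vids]
        first = min(visits, key=lambda v: (v.date, v.visit_id))
        rows.append(
            {
                "patient_id": pid,
                "n_visits": len(vids),
                "parsr_max": float(sub["pars_rescaled"].max()),
                "parsr_mean": float(sub["pars_rescaled"].mean()),
                "pars_max": float(sub["pars"].max()),
                "pars_mean": float(sub["pars"].mean()),
                "n_high_risk": int(sub["high_risk"].sum()),
                "sex": first.sex,
                "age_decade": age_decade(first.age),
            }
        )
    prof = pd.DataFrame(rows)
    prof = prof.sort_values(
        [rank_by, "parsr_mean", "patient_id"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    prof.insert(0, "rank", np.arange(1, len(prof) + 1))
    prof = prof.drop(columns="patient_id")
    if top_k is not None:
        prof = prof.head(top_k)
    return prof


def top_visits(
    cohort: Cohort,
    pars_frame: pd.DataFrame,
    k: int = 10,
    dedup_regimens: bool = False,
) -> pd.DataFrame:
    """Top-k visits ranked by the rescaled score, de-identified.

    With ``dedup_regimens`` only the highest-scoring visit per unique drug
    set is retained, giving one representative record per regimen.
    """
    rows = []
    for v in cohort:
        rows.append(
            {
                "visit_id": v.visit_id,
                "sex": v.sex,
                "age_decade": age_decade(v.age),
                "regimen": ";".join(sorted(v.drugs)),
                "pars_rescaled": float(pars_frame.loc[v.visit_id, "pars_rescaled"]),
            }
        )
    tab = pd.DataFrame(rows).sort_values(
        ["pars_rescaled", "visit_id"], ascending=[False, True], kind="stable"
    )
    if dedup_regimens:
        tab = tab.drop_duplicates(subset="regimen", keep="first")
    tab = tab.head(k).reset_index(drop=True)
    tab.insert(0, "rank", np.arange(1, len(tab) + 1))
    return tab.drop(columns="visit_id")
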