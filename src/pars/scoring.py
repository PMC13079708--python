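"""PARS aggregation: z-standardization, composite, 0-10 rescale, high-risk label.

The PsychoPharm Aggregated Risk Score (PARS) for visit *i* is the unweighted
mean of the z-scores of the five risk components,

    z_i^X = (X_i - mu_X) / sigma_X,      PARS_i = mean_X z_i^X,

with mu_X and sigma_X fitted on a declared *reference set* (the full cohort
for description, the training split during modelling, so that no held-out
information leaks into the parameters).  For clinical display PARS is
min-max rescaled to 0-10 against the reference minimum/maximum, and a binary
High-risk label marks visits at or above the reference 75th percentile
(expected prevalence ~25%, up to ties).

Conventions recorded in the fitted parameters: sample (n-1) standard
deviation; linear-interpolation percentiles; a component that is constant on
the reference set is flagged degenerate and contributes z = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import PARS_COMPONENTS

#: rescaled-score band edges: [0,3) low, [3,6) moderate, [6,10] high
BAND_EDGES = (3.0, 6.0)
LABEL_PERCENTILE = 75.0


class ScoringError(ValueError):
    pass


@dataclass
class StandardizationParams:
    """Per-component mean/SD fitted on the reference set (ddof=1)."""

    mean: pd.Series
    sd: pd.Series
    degenerate: pd.Series  # boolean: sigma == 0
    n_reference: int


@dataclass
class RescaleParams:
    pars_min: float
    pars_max: float
    n_reference: int

    @property
    def is_degenerate(self) -> bool:
        return self.pars_max == self.pars_min


@dataclass
class LabelParams:
    tau75: float
    n_reference: int


def fit_standardization(components: pd.DataFrame) -> StandardizationParams:
    """Fit per-component mean and sample SD on a reference component table."""
    if len(components) == 0:
        raise ScoringError("empty reference set")
    missing = [c for c in PARS_COMPONENTS if c not in components.columns]
    if missing:
        raise ScoringError(f"missing component columns: {missing}")
    sub = components[list(PARS_COMPONENTS)].astype(float)
    mean = sub.mean()
    sd = sub.std(ddof=1) if len(sub) > 1 else pd.Series(0.0, index=sub.columns)
    sd = sd.fillna(0.0)
    degenerate = sd == 0.0
    if degenerate.any():
        warnings.warn(
            f"constant component(s) on the reference set: "
            f"{list(degenerate[degenerate].index)}; their z-scores are set to 0",
            stacklevel=2,
        )
    return StandardizationParams(mean=mean, sd=sd, degenerate=degenerate, n_reference=len(sub))


def pars_composite(
    components: pd.DataFrame, params: StandardizationParams
) -> tuple[pd.DataFrame, pd.Series]:
    """z-scores and their equal-weight mean (the PARS composite) per visit.

    Degenerate components contribute z = 0.
    """
    sub = components[list(PARS_COMPONENTS)].astype(float)
    sd = params.sd.where(~params.degenerate, 1.0)
    z = (sub - params.mean) / sd
    z.loc[:, params.degenerate[params.degenerate].index] = 0.0
    z.columns = [f"z_{c}" for c in PARS_COMPONENTS]
    pars = z.mean(axis=1)
    pars.name = "pars"
    return z, pars


def fit_rescale(reference_pars) -> RescaleParams:
    """Record the reference min/max for 0-10 min-max display scaling."""
    vals = np.asarray(reference_pars, dtype=float)
    if vals.size == 0:
        raise ScoringError("empty reference set")
    return RescaleParams(float(vals.min()), float(vals.max()), int(vals.size))


def rescale(pars, params: RescaleParams, clip: bool = True):
    """Map PARS onto the 0-10 display scale: reference min -> 0, max -> 10.

    Values outside the reference range extrapolate linearly; with
    ``clip=True`` (the display convention) they are clipped into [0, 10].
    """
    if params.is_degenerate:
        raise ScoringError("degenerate rescale parameters (reference min == max)")
    out = 10.0 * (np.asarray(pars, dtype=float) - params.pars_min) / (
        params.pars_max - params.pars_min
    )
    if clip:
        out = np.clip(out, 0.0, 10.0)
    if np.isscalar(pars):
        return float(out)
    return out


def fit_label_threshold(reference_pars) -> LabelParams:
    """tau75: linear-interpolation 75th percentile of the reference PARS."""
    vals = np.asarray(reference_pars, dtype=float)
    if vals.size == 0:
        raise ScoringError("empty reference set")
    return LabelParams(float(np.quantile(vals, LABEL_PERCENTILE / 100.0)), int(vals.size))


def label_high_risk(pars, params: LabelParams):
    """High-risk label: 1 iff PARS >= tau75 (inclusive at the threshold)."""
    out = (np.asarray(pars, dtype=float) >= params.tau75).astype(int)
    if np.isscalar(pars):
        return int(out)
    return out


def band(pars_rescaled: float) -> str:
    """Risk band of a 0-10 display score: [0,3) low, [3,6) moderate, [6,10] high."""
    x = float(pars_rescaled)
    if not (0.0 <= x <= 10.0):
        raise ScoringError(f"rescaled score {x} outside [0, 10]")
    if x < BAND_EDGES[0]:
        return "low"
    if x < BAND_EDGES[1]:
        return "moderate"
    return "high"


@dataclass
class ParsParams:
    """All reference-set parameters of a fitted PARS model."""

    standardization: StandardizationParams
    rescale: RescaleParams
    label: LabelParams
    reference_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean": self.standardization.mean.to_dict(),
            "sd": self.standardization.sd.to_dict(),
            "degenerate": self.standardization.degenerate.astype(bool).to_dict(),
            "pars_min": self.rescale.pars_min,
            "pars_max": self.rescale.pars_max,
            "tau75": self.label.tau75,
            "n_reference": self.standardization.n_reference,
            "sd_convention": "sample (ddof=1)",
            "percentile_method": "linear interpolation",
        }


class ParsScoreModel:
    """Aggregate risk-score model over a per-visit component table.

    Parameters
    ----------
    components : DataFrame
        Indexed by visit_id with (at least) the five component columns.

    Examples
    --------
    >>> model = ParsScoreModel(components)
    >>> res = model.fit()                      # full-cohort reference
    >>> res = model.fit(reference=train_ids)   # train-only reference
    >>> res.frame[["pars", "pars_rescaled", "band", "high_risk"]]
    """

    def __init__(self, components: pd.DataFrame):
        missing = [c for c in PARS_COMPONENTS if c not in components.columns]
        if missing:
            raise ScoringError(f"missing component columns: {missing}")
        self.components = components

    @classmethod
    def from_cohort(cls, cohort, kb) -> "ParsScoreModel":
        from .components import components_frame

        return cls(components_frame(cohort, kb))

    def fit(self, reference=None) -> "ParsResults":
        """Fit all reference-set parameters and score every visit.

        ``reference`` is an explicit collection of visit_ids (e.g. the
        training split); ``None`` uses the full table, the descriptive
        convention.  Held-out visits never influence the parameters.
        """
        if reference is None:
            ref = self.components
            ref_ids = list(self.components.index)
        else:
            ref_ids = list(reference)
            missing = set(ref_ids) - set(self.components.index)
            if missing:
                raise ScoringError(f"reference visit_ids not in table: {sorted(missing)[:5]}")
            ref = self.components.loc[ref_ids]
        std = fit_standardization(ref)
        _, ref_pars = pars_composite(ref, std)
        params = ParsParams(
            standardization=std,
            rescale=fit_rescale(ref_pars),
            label=fit_label_threshold(ref_pars),
            reference_ids=ref_ids,
        )
        return ParsResults(self, params)


class ParsResults:
    """Scored visits plus the fitted reference-set parameters."""

    def __init__(self, model: ParsScoreModel, params: ParsParams):
        self.model = model
        self.params = params
        z, pars = pars_composite(model.components, params.standardization)
        frame = z.copy()
        frame["pars"] = pars
        frame["pars_rescaled_raw"] = rescale(pars, params.rescale, clip=False)
        frame["pars_rescaled"] = rescale(pars, params.rescale, clip=True)
        frame["band"] = [band(x) for x in frame["pars_rescaled"]]
        frame["high_risk"] = label_high_risk(pars.to_numpy(), params.label)
        self.frame = frame

    @property
    def pars(self) -> pd.Series:
        return self.frame["pars"]

    @property
    def high_risk(self) -> pd.Series:
        return self.frame["high_risk"]

    def reference_frame(self) -> pd.DataFrame:
        return self.frame.loc[self.params.reference_ids]

    def summary(self) -> pd.DataFrame:
        """Descriptive table (mean/SD/median/IQR/min-max) of components and scores."""
        cols = {}
        comp = self.model.components
        for name in list(PARS_COMPONENTS) + ["azcert_sum", "sero_count"]:
            if name in comp.columns:
                cols[name] = comp[name].astype(float)
        cols["pars"] = self.frame["pars"]
        cols["pars_rescaled"] = self.frame["pars_rescaled"]
        tab = pd.DataFrame(
            {
                "mean": {k: v.mean() for k, v in cols.items()},
                "sd": {k: v.std(ddof=1) for k, v in cols.items()},
                "median": {k: v.median() for k, v in cols.items()},
                "q25": {k: v.quantile(0.25) for k, v in cols.items()},
                "q75": {k: v.quantile(0.75) for k, v in cols.items()},
                "min": {k: v.min() for k, v in cols.items()},
                "max": {k: v.max() for k, v in cols.items()},
            }
        )
        tab.loc["high_risk_prevalence_pct"] = [
            100.0 * self.frame["high_risk"].mean()
        ] + [np.nan] * 6
        return tab

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="visit_id")
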