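"""Synthetic knowledge bases and longitudinal prescription cohorts.

The study's clinical dataset is private, so this module generates cohorts
with the same statistical skeleton: ~680 adult psychiatric outpatients,
1-13 visits each (median ~2.5), 68.5% female, age ~N(60.1, 18.3) truncated
at 18, regimens of >= 2 drugs with CNS-heavy co-occurrence and roughly half
of visits meeting the polypharmacy criterion.  Drugs are synthetic names
organized in CNS classes (antipsychotic, antidepressant, sedative,
anticholinergic adjunct) and somatic classes (cardiovascular, metabolic,
respiratory); CNS drugs preferentially carry QT/ACB/serotonergic annotations
and dense interaction pairs, so DDI burden co-varies with drug count as in
real prescribing data.

Each generated cohort comes with a *planted truth*: a per-drug log-odds
contribution to a latent high-risk propensity that shapes prescribing (CNS
drugs positive, somatic drugs negative, plus a mild age effect).  Labels for
recovery experiments come from the scoring pipeline's own percentile rule —
the planted propensity only decides who gets which drugs — so end-to-end
recovery tests exercise the pipeline exactly as it is used on real data.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.stats import truncnorm

from .cohort import Cohort, Visit, apply_inclusion_filters
from .knowledge_base import KnowledgeBase, write_knowledge_base

CNS_CLASSES = ("antipsychotic", "antidepressant", "sedative", "anticholinergic_adjunct")
SOMATIC_CLASSES = ("cardiovascular", "metabolic", "respiratory")


@dataclass
class SynthConfig:
    """Generator parameters; defaults emulate the target outpatient cohort."""

    n_patients: int = 680
    female_fraction: float = 0.685
    age_mean: float = 60.1
    age_sd: float = 18.3
    age_min: float = 18.0
    #: geometric visit-count parameter; 1 - sqrt(1/2) puts the sample median near 2.5
    visit_geometric_p: float = 0.2928932
    visit_max: int = 13
    #: drugs per class
    class_sizes: dict = field(default_factory=lambda: {
        "antipsychotic": 14, "antidepressant": 14, "sedative": 10,
        "anticholinergic_adjunct": 8,
        "cardiovascular": 14, "metabolic": 12, "respiratory": 8,
    })
    #: per-class probability of appearing on the QT list (then known/possible/conditional)
    qt_fraction: dict = field(default_factory=lambda: {
        "antipsychotic": 0.7, "antidepressant": 0.45, "sedative": 0.15,
        "anticholinergic_adjunct": 0.1,
        "cardiovascular": 0.2, "metabolic": 0.05, "respiratory": 0.05,
    })
    #: per-class probability of an ACB listing (score drawn from 1-3)
    acb_fraction: dict = field(default_factory=lambda: {
        "antipsychotic": 0.55, "antidepressant": 0.45, "sedative": 0.5,
        "anticholinergic_adjunct": 0.95,
        "cardiovascular": 0.05, "metabolic": 0.05, "respiratory": 0.1,
    })
    #: per-class probability of serotonergic listing
    sero_fraction: dict = field(default_factory=lambda: {
        "antipsychotic": 0.3, "antidepressant": 0.9, "sedative": 0.15,
        "anticholinergic_adjunct": 0.05,
        "cardiovascular": 0.0, "metabolic": 0.0, "respiratory": 0.05,
    })
    #: DDI pair densities: within-CNS, CNS-somatic, within-somatic
    ddi_density_cns: float = 0.35
    ddi_density_cross: float = 0.08
    ddi_density_somatic: float = 0.05
    #: regimen size = regimen_min + Binomial(regimen_spread, p_lo + (p_hi - p_lo) * u)
    regimen_min: int = 2
    regimen_spread: int = 8
    regimen_p_lo: float = 0.12
    regimen_p_hi: float = 0.52
    #: probability a follow-up visit keeps the previous regimen unchanged
    persistence: float = 0.8
    #: latent CNS-severity mixing: Beta(a, b); "strong" presets are bimodal
    severity_beta_a: float = 2.0
    severity_beta_b: float = 2.0
    #: CNS share of the regimen = cns_share_lo + (hi - lo) * propensity
    cns_share_lo: float = 0.2
    cns_share_hi: float = 0.8
    #: somatic-drug slots per regimen; None couples somatic count to size
    somatic_slots: int | None = None
    #: mild age tilt of the latent propensity (per year from age 60)
    age_effect: float = 0.002
    #: planted per-drug log-odds scale; 0 disables the planted signal (null config)
    effect_scale: float = 1.0
    seed: int = 0

    def vocabulary(self) -> dict:
        """class -> list of synthetic drug names (deterministic)."""
        return {
            cls: [f"{cls}_{i:02d}" for i in range(1, n + 1)]
            for cls, n in self.class_sizes.items()
        }

    @classmethod
    def strong_signal(cls, **kw) -> "SynthConfig":
        """Preset for parameter-recovery experiments.

        A bimodal patient mix with sharply separated CNS vs somatic
        prescribing; a *constant* regimen size, so drug composition rather
        than drug count carries the whole signal and somatic presence
        strictly displaces CNS drugs; high regimen persistence; and fully
        clean somatic drugs (no annotations, no interaction pairs), whose
        association with the high-risk label is therefore purely
        substitutive — the planted-negative mechanism."""
        zero_somatic = {c: 0.0 for c in SOMATIC_CLASSES}
        return cls(
            severity_beta_a=0.6, severity_beta_b=0.6,
            cns_share_lo=0.08, cns_share_hi=0.92,
            regimen_min=7, regimen_spread=0,
            persistence=0.95,
            ddi_density_cross=0.0, ddi_density_somatic=0.0,
            qt_fraction={**cls().qt_fraction, **zero_somatic},
            acb_fraction={**cls().acb_fraction, **zero_somatic},
            sero_fraction={**cls().sero_fraction, **zero_somatic},
            **kw,
        )

    @classmethod
    def null(cls, **kw) -> "SynthConfig":
        """No planted effects; recovery labels are pure noise."""
        return cls(effect_scale=0.0, **kw)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PlantedTruth:
    """Per-drug planted log-odds effects and the class structure behind them."""

    drug_effects: dict  # drug -> float
    drug_classes: dict  # drug -> class name
    config: SynthConfig

    def effect_sign(self, drug: str) -> int:
        e = self.drug_effects[drug]
        return 0 if e == 0 else (1 if e > 0 else -1)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"drug_effects": self.drug_effects, "drug_classes": self.drug_classes,
                 "config": asdict(self.config)},
                fh, indent=1,
            )


def generate_knowledge_base(config: SynthConfig, seed: int | None = None) -> KnowledgeBase:
    """Synthetic reference tables with class-structured annotation densities."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    vocab = config.vocabulary()
    kb = KnowledgeBase(provenance={"source": "synthetic", "seed": str(seed)})

    for cls, drugs in vocab.items():
        for d in drugs:
            if rng.random() < config.qt_fraction[cls]:
                kb.azcert[d] = rng.choice(["known", "possible", "conditional"])
            if rng.random() < config.acb_fraction[cls]:
                kb.acb[d] = int(rng.choice([1, 2, 3], p=[0.4, 0.3, 0.3]))
            if rng.random() < config.sero_fraction[cls]:
                kb.sero.add(d)

    cns = [d for c in CNS_CLASSES for d in vocab.get(c, [])]
    somatic = [d for c in SOMATIC_CLASSES for d in vocab.get(c, [])]
    all_drugs = cns + somatic
    cns_set = set(cns)
    for i, a in enumerate(all_drugs):
        for b in all_drugs[i + 1:]:
            n_cns = (a in cns_set) + (b in cns_set)
            dens = {2: config.ddi_density_cns, 1: config.ddi_density_cross,
                    0: config.ddi_density_somatic}[n_cns]
            if rng.random() < dens:
                kb.ddi[frozenset((a, b))] = rng.choice(
                    ["major", "moderate", "minor"], p=[0.3, 0.45, 0.25]
                )
    return kb


def planted_truth(config: SynthConfig, kb: KnowledgeBase) -> PlantedTruth:
    """Planted log-odds per drug, scaled by ``effect_scale``.

    A drug's recoverable association with the high-risk label combines two
    mechanisms: cluster membership (CNS drugs flow to high-propensity
    patients — positive) and within-regimen substitution (a drug displaces
    alternatives, so what matters is its risk load *relative* to the average
    CNS drug it replaces).  Risk load sums the drug's annotations (ACB
    score, QT category weight, serotonergic membership) and its
    severity-weighted interaction degree.  For CNS drugs with above-average
    load both mechanisms push the same way, so they are planted positive
    (magnitude proportional to the relative load); for below-average CNS
    drugs the mechanisms oppose and the effect is set to 0 (ambiguous,
    excluded from sign scoring).  Somatic drugs with no risk signal at all
    are planted negative (pure substitution); annotated somatic drugs pull
    both ways and get 0.
    """
    qt_w = {"known": 3, "possible": 2, "conditional": 1}
    sev_w = {"major": 3, "moderate": 2, "minor": 1}
    pair_weight = {}
    for pair, sev in kb.ddi.items():
        for d in pair:
            pair_weight[d] = pair_weight.get(d, 0) + sev_w[sev]

    def risk_load(d):
        return (
            kb.acb.get(d, 0)
            + qt_w.get(kb.azcert.get(d), 0)
            + (2 if d in kb.sero else 0)
            + pair_weight.get(d, 0) / 8.0
        )

    vocab = config.vocabulary()
    cns_drugs = [d for c in CNS_CLASSES for d in vocab.get(c, [])]
    mean_cns = float(np.mean([risk_load(d) for d in cns_drugs])) if cns_drugs else 0.0

    effects, classes = {}, {}
    for cls, drugs in vocab.items():
        for d in drugs:
            if cls in CNS_CLASSES:
                rel = risk_load(d) - mean_cns
                eff = 0.25 * rel if rel > 0 else 0.0
            elif risk_load(d) == 0:
                eff = -1.0
            else:
                eff = 0.0
            effects[d] = config.effect_scale * eff
            classes[d] = cls
    return PlantedTruth(effects, classes, config)


def _truncated_geometric(rng, p: float, kmax: int) -> int:
    u = rng.random()
    k = 1 + int(np.floor(np.log1p(-u) / np.log1p(-p)))
    return int(min(k, kmax))


def _sample_regimen(
    rng, size: int, cns_share: float, cns: list, somatic: list,
    somatic_slots: int | None = None,
) -> set:
    """Draw a regimen of ``size`` drugs with a CNS/somatic mix set by
    ``cns_share``.  By default the somatic count scales with regimen size
    (comedication grows with polypharmacy, the realistic coupling); with
    ``somatic_slots`` it is drawn from a fixed number of slots instead, so
    somatic presence is independent of regimen size given the share."""
    if somatic_slots is None:
        slots = size
    else:
        # interpolate: CNS-heavy regimens use the fixed slot count (somatic
        # presence independent of size), somatic-heavy regimens open up to
        # the full size so they stay somatic-dominated
        slots = int(round(somatic_slots * cns_share + size * (1.0 - cns_share)))
    n_som = int(rng.binomial(max(slots, 0), 1.0 - cns_share))
    n_som = min(n_som, size, len(somatic))
    n_cns = min(size - n_som, len(cns))
    picks = set(rng.choice(cns, size=n_cns, replace=False)) if n_cns else set()
    if n_som:
        picks |= set(rng.choice(somatic, size=n_som, replace=False))
    return picks


def generate_cohort(
    config: SynthConfig, seed: int | None = None, kb: KnowledgeBase | None = None
) -> tuple[Cohort, PlantedTruth]:
    """Longitudinal synthetic cohort plus its planted ground truth.

    Per patient: sex, a truncated-normal age, a latent CNS-severity
    propensity, and a base regimen drawn by class; per visit: the base
    regimen with small random edits (regimens persist across most visits, as
    in real follow-up data).  Every generated visit satisfies the inclusion
    filters (>= 2 drugs, adult).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if kb is None:
        kb = generate_knowledge_base(config, seed=seed + 1 if seed is not None else None)
    truth = planted_truth(config, kb)

    vocab = config.vocabulary()
    cns = [d for c in CNS_CLASSES for d in vocab.get(c, [])]
    somatic = [d for c in SOMATIC_CLASSES for d in vocab.get(c, [])]
    a = (config.age_min - config.age_mean) / config.age_sd
    start = _dt.date(2023, 1, 1)

    visits = []
    vid = 0
    for i in range(config.n_patients):
        pid = f"p{i:04d}"
        sex = "F" if rng.random() < config.female_fraction else "M"
        age = float(truncnorm.rvs(a, np.inf, loc=config.age_mean, scale=config.age_sd,
                                  random_state=rng))
        u = float(rng.beta(config.severity_beta_a, config.severity_beta_b))
        propensity = float(np.clip(u + config.age_effect * (age - 60.0), 0.0, 1.0))
        cns_share = config.cns_share_lo + (config.cns_share_hi - config.cns_share_lo) * propensity
        size = config.regimen_min + int(rng.binomial(
            config.regimen_spread,
            config.regimen_p_lo + (config.regimen_p_hi - config.regimen_p_lo) * propensity,
        ))
        regimen = _sample_regimen(rng, size, cns_share, cns, somatic)
        n_visits = _truncated_geometric(rng, config.visit_geometric_p, config.visit_max)
        day = int(rng.integers(0, 28))
        for j in range(n_visits):
            if j > 0 and rng.random() > config.persistence:
                pool = cns if rng.random() < cns_share else somatic
                candidates = [d for d in pool if d not in regimen]
                action = rng.random()
                if action < 0.5 and candidates:
                    regimen = regimen | {rng.choice(candidates)}
                elif len(regimen) > 2:
                    regimen = regimen - {rng.choice(sorted(regimen))}
            date = start + _dt.timedelta(days=day + 30 * j + int(rng.integers(0, 10)))
            visits.append(Visit(
                visit_id=f"v{vid:05d}", patient_id=pid, date=date, sex=sex,
                age=round(age + j / 12.0, 1), drugs=frozenset(regimen),
            ))
            vid += 1
    cohort = Cohort(visits)
    filtered, log = apply_inclusion_filters(cohort)
    assert len(log) == 0, "generator must emit filter-passing visits"
    return filtered, truth


def tie_free_component_sample(
    config: SynthConfig, seed: int, n_visits: int = 2000, max_tries: int = 50
):
    """Component table of exactly ``n_visits`` whose composite score has no
    tie at the 75th-percentile order-statistic boundary.

    The percentile-label prevalence argument (label ~25% of visits) assumes
    a tie-free score distribution; component scores are integers, so ties
    can occur.  This helper advances deterministic sub-seeds until the
    sampled cohort satisfies the tie-free precondition at the quantile
    boundary, then returns its component table.
    """
    from .components import components_frame
    from .scoring import ParsScoreModel

    for k in range(max_tries):
        s = seed + 1009 * k
        kb = generate_knowledge_base(config, seed=s + 1)
        cohort, _ = generate_cohort(config, seed=s, kb=kb)
        comp = components_frame(cohort, kb)
        if len(comp) < n_visits:
            continue
        comp = comp.iloc[:n_visits]
        pars = ParsScoreModel(comp).fit().pars.to_numpy()
        srt = np.sort(pars)
        pos = 0.75 * (n_visits - 1)
        idx = int(np.floor(pos))
        if pos > idx and srt[idx] < srt[idx + 1]:
            return comp
    raise RuntimeError("no tie-free sample found; enlarge max_tries or vocabulary")


def write_simulation(config: SynthConfig, seed: int, out_dir) -> dict:
    """Materialize one simulation: cohort.csv, the four KB files, truth.json."""
    from pathlib import Path

    from .cohort import write_cohort_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kb = generate_knowledge_base(config, seed=seed + 1)
    cohort, truth = generate_cohort(config, seed=seed, kb=kb)
    paths = write_knowledge_base(kb, out)
    write_cohort_csv(cohort, out / "cohort.csv")
    truth.to_json(out / "truth.json")
    return {"cohort": out / "cohort.csv", "truth": out / "truth.json", **paths}


def recovery_experiment(config: SynthConfig, seed: int, bootstrap_B: int = 0) -> dict:
    """End-to-end pipeline check on a cohort with known planted structure.

    Pipeline: components -> composite score with a train-only reference ->
    high-risk labels -> drug-only logistic fit on the training patients ->
    held-out evaluation.  Reports held-out AUC, Brier, and — for drugs with
    cohort support >= 20 — the fraction whose fitted coefficient sign matches
    the planted sign.

    Null configs (``effect_scale == 0``) replace the percentile label with
    i.i.d. Bernoulli(0.25) noise (a percentile label would still be a
    deterministic function of the drug set) and report the pooled
    out-of-fold AUC from patient-grouped 5-fold cross-validation, which
    should sit at chance.

    If a generated label vector is single-class on train or test, the cohort
    is regenerated with the next seed (logged in the report).
    """
    from .components import components_frame
    from .scoring import ParsScoreModel
    from .screening import RiskScreeningModel, coefficient_table

    attempts = 0
    while True:
        kb = generate_knowledge_base(config, seed=seed + 1)
        cohort, truth = generate_cohort(config, seed=seed, kb=kb)
        comp = components_frame(cohort, kb)
        rng = np.random.default_rng(seed + 2)

        if config.effect_scale == 0.0:
            import pandas as pd

            labels = pd.Series(
                rng.binomial(1, 0.25, size=len(comp)), index=comp.index, name="high_risk"
            )
            if labels.nunique() < 2:
                seed += 1
                attempts += 1
                continue
            sm = RiskScreeningModel(cohort, labels, drugs_only=True)
            cv = sm.cross_validate(k=5)
            pooled = cv.pooled_metrics()
            return {
                "null": True, "auc": pooled["auc"], "brier": pooled["brier"],
                "prevalence": float(labels.mean()), "n_visits": len(comp),
                "regenerations": attempts,
            }

        # labels from the pipeline's own percentile rule, train-only reference
        sm_split_labels = ParsScoreModel(comp).fit().high_risk  # for stratification only
        screen0 = RiskScreeningModel(cohort, sm_split_labels, drugs_only=True)
        split = screen0.patient_split(scheme="highrisk", seed=seed)
        train_ids = split.train_visit_ids(cohort)
        res_pars = ParsScoreModel(comp).fit(reference=train_ids)
        labels = res_pars.high_risk
        y_tr = labels.loc[train_ids]
        y_te = labels.loc[split.test_visit_ids(cohort)]
        if y_tr.nunique() < 2 or y_te.nunique() < 2:
            seed += 1
            attempts += 1
            continue

        screen = RiskScreeningModel(cohort, labels, drugs_only=True)
        res = screen.fit(split)
        m = res.metrics()
        coefs = coefficient_table(res.fitted, cohort, min_support=20)
        agree = [
            int(np.sign(row.coefficient) == truth.effect_sign(row.drug))
            for row in coefs.itertuples()
            if truth.effect_sign(row.drug) != 0
        ]
        out = {
            "null": False,
            "auc": m["auc"],
            "brier": m["brier"],
            "accuracy": m["accuracy"],
            "f1_1": m["f1_1"],
            "prevalence": float(labels.mean()),
            "sign_agreement": float(np.mean(agree)) if agree else float("nan"),
            "n_eval_drugs": len(agree),
            "n_visits": len(comp),
            "regenerations": attempts,
        }
        if bootstrap_B:
            out["auc_ci"] = res.auc_ci(B=bootstrap_B, seed=seed + 3)
        return out
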