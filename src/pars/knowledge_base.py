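"""Drug-risk knowledge base: pairwise DDI severities and the three risk lists.

Every component score depends on four reference tables, supplied as versioned
file snapshots (no network access):

* a pairwise drug-drug interaction (DDI) table graded major/moderate/minor —
  pairs absent from the table mean "no interaction found";
* the QT-prolongation (torsades de pointes) risk list with categories
  known/possible/conditional;
* the Anticholinergic Cognitive Burden (ACB) list with per-drug scores 1-3;
* a serotonergic-agent list.

Drug identity is a canonical name: case-folded, trimmed, internal whitespace
collapsed.  Matching is exact on canonical names; drugs absent from a list
contribute 0 to every downstream score (closed-world rule).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

DDI_SEVERITIES = ("major", "moderate", "minor")
QT_CATEGORIES = ("known", "possible", "conditional")
ACB_SCORES = (1, 2, 3)

_WS = re.compile(r"\s+")


class KnowledgeBaseError(ValueError):
    """Malformed reference table or invalid query."""


def normalize_drug_name(raw: str) -> str:
    """Canonicalize a drug name: casefold, trim, collapse internal whitespace.

    Idempotent.  Raises :class:`KnowledgeBaseError` on empty / whitespace-only
    input.
    """
    if raw is None:
        raise KnowledgeBaseError("drug name is missing")
    name = _WS.sub(" ", str(raw).strip()).casefold()
    if not name:
        raise KnowledgeBaseError(f"invalid drug name: {raw!r}")
    return name


@dataclass
class KnowledgeBase:
    """Queryable container for the four drug-risk reference tables.

    Attributes
    ----------
    ddi : dict
        ``frozenset({a, b}) -> severity`` with severity in
        ``{"major", "moderate", "minor"}``.  Lookup is symmetric by
        construction; self-pairs are never stored.
    azcert : dict
        canonical drug name -> QT category (``known``/``possible``/``conditional``).
    acb : dict
        canonical drug name -> anticholinergic burden score (1, 2 or 3).
    sero : set
        canonical names of serotonergic agents.
    provenance : dict
        free-text source/version labels, carried through unmodified.
    """

    ddi: dict[frozenset, str] = field(default_factory=dict)
    azcert: dict[str, str] = field(default_factory=dict)
    acb: dict[str, int] = field(default_factory=dict)
    sero: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def pair_severity(self, a: str, b: str) -> str:
        """Severity of the interaction between two distinct drugs.

        Returns one of ``major``/``moderate``/``minor``/``none``; the result
        is symmetric in the pair, and pairs absent from the table are
        ``none``.
        """
        a, b = normalize_drug_name(a), normalize_drug_name(b)
        if a == b:
            raise KnowledgeBaseError(f"self-pair query: {a!r}")
        return self.ddi.get(frozenset((a, b)), "none")

    def qt_category(self, drug: str) -> str | None:
        return self.azcert.get(normalize_drug_name(drug))

    def acb_score(self, drug: str) -> int:
        return self.acb.get(normalize_drug_name(drug), 0)

    def is_serotonergic(self, drug: str) -> bool:
        return normalize_drug_name(drug) in self.sero


def _read_csv(path, **kw) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, **kw)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def load_knowledge_base(
    ddi_path, azcert_path, acb_path, sero_path, provenance: dict | None = None
) -> KnowledgeBase:
    """Load and validate the four reference tables.

    File dialects (UTF-8, header row required):

    * ``ddi.csv`` — columns ``drug_a,drug_b,severity``
    * ``azcert.csv`` — columns ``drug,category``
    * ``acb.csv`` — columns ``drug,score`` (1|2|3)
    * ``sero.csv`` — single column ``drug``

    Names are canonicalized; identical duplicate rows are collapsed.
    A pair stored twice with *different* severities is a hard error (a
    silently corrupted table would bias every downstream score), as is any
    severity/category/score token outside its allowed domain.
    """
    kb = KnowledgeBase(provenance=dict(provenance or {}))

    ddi = _read_csv(ddi_path)
    for col in ("drug_a", "drug_b", "severity"):
        if col not in ddi.columns:
            raise KnowledgeBaseError(f"{ddi_path}: missing column {col!r}")
    for idx, row in ddi.iterrows():
        a = normalize_drug_name(row["drug_a"])
        b = normalize_drug_name(row["drug_b"])
        sev = str(row["severity"]).strip().casefold()
        if sev not in DDI_SEVERITIES:
            raise KnowledgeBaseError(f"{ddi_path} row {idx}: unknown severity {sev!r}")
        if a == b:
            raise KnowledgeBaseError(f"{ddi_path} row {idx}: self-pair {a!r}")
        key = frozenset((a, b))
        if key in kb.ddi and kb.ddi[key] != sev:
            raise KnowledgeBaseError(
                f"{ddi_path} row {idx}: conflicting severities for pair "
                f"({a!r}, {b!r}): {kb.ddi[key]!r} vs {sev!r}"
            )
        kb.ddi[key] = sev

    az = _read_csv(azcert_path)
    for col in ("drug", "category"):
        if col not in az.columns:
            raise KnowledgeBaseError(f"{azcert_path}: missing column {col!r}")
    for idx, row in az.iterrows():
        d = normalize_drug_name(row["drug"])
        cat = str(row["category"]).strip().casefold()
        if cat not in QT_CATEGORIES:
            raise KnowledgeBaseError(f"{azcert_path} row {idx}: unknown category {cat!r}")
        if d in kb.azcert and kb.azcert[d] != cat:
            raise KnowledgeBaseError(f"{azcert_path} row {idx}: conflicting category for {d!r}")
        kb.azcert[d] = cat

    acb = _read_csv(acb_path)
    for col in ("drug", "score"):
        if col not in acb.columns:
            raise KnowledgeBaseError(f"{acb_path}: missing column {col!r}")
    for idx, row in acb.iterrows():
        d = normalize_drug_name(row["drug"])
        try:
            score = int(str(row["score"]).strip())
        except ValueError:
            raise KnowledgeBaseError(f"{acb_path} row {idx}: unparseable score {row['score']!r}")
        if score not in ACB_SCORES:
            raise KnowledgeBaseError(f"{acb_path} row {idx}: score {score} outside {{1,2,3}}")
        if d in kb.acb and kb.acb[d] != score:
            raise KnowledgeBaseError(f"{acb_path} row {idx}: conflicting score for {d!r}")
        kb.acb[d] = score

    sero = _read_csv(sero_path)
    if "drug" not in sero.columns:
        raise KnowledgeBaseError(f"{sero_path}: missing column 'drug'")
    kb.sero = {normalize_drug_name(d) for d in sero["drug"]}

    return kb


def write_knowledge_base(kb: KnowledgeBase, out_dir) -> dict[str, Path]:
    """Write a knowledge base back to its four-file dialect.

    Rows are sorted so that the same knowledge base always serializes to
    byte-identical files; reloading the written files reproduces the maps
    exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name}.csv" for name in ("ddi", "azcert", "acb", "sero")}

    rows = sorted((tuple(sorted(pair)), sev) for pair, sev in kb.ddi.items())
    pd.DataFrame(
        [(a, b, sev) for (a, b), sev in rows], columns=["drug_a", "drug_b", "severity"]
    ).to_csv(paths["ddi"], index=False)
    pd.DataFrame(
        sorted(kb.azcert.items()), columns=["drug", "category"]
    ).to_csv(paths["azcert"], index=False)
    pd.DataFrame(sorted(kb.acb.items()), columns=["drug", "score"]).to_csv(
        paths["acb"], index=False
    )
    pd.DataFrame({"drug": sorted(kb.sero)}).to_csv(paths["sero"], index=False)
    return paths


def load_knowledge_base_dir(kb_dir, provenance: dict | None = None) -> KnowledgeBase:
    """Load a knowledge base from a directory holding the four standard files."""
    kb_dir = Path(kb_dir)
    return load_knowledge_base(
        kb_dir / "ddi.csv",
        kb_dir / "azcert.csv",
        kb_dir / "acb.csv",
        kb_dir / "sero.csv",
        provenance=provenance,
    )
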