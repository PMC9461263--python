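"""Phecode construction from encounter-level ICD codes.

A *phecode occurrence* is one distinct encounter carrying at least one ICD
code mapped to that phecode — multiple qualifying ICD rows on the same
encounter count once. Two encounter scopes are supported: ``all`` (any
encounter type) and ``visit`` (appointment/office/hospital/procedure only,
excluding message-like channels). Cases need ``count >= min_occurrences``,
controls have count 0, and anyone in between is excluded from both groups
(or optionally kept as a control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import VISIT_TYPES

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"


@dataclass
class PhecodeCounts:
    """Long-format per-(person, phecode) occurrence counts plus bookkeeping."""

    counts: pd.DataFrame  # person_id, phecode, count
    scope: str
    persons: list  # full person universe (so zero counts are recoverable)
    unknown_icd: dict = field(default_factory=dict)  # unmapped code -> row tally


def count_occurrences(
    encounters: pd.DataFrame,
    ontology: pd.DataFrame,
    persons: list,
    scope: str = "all",
) -> PhecodeCounts:
    """Count distinct qualifying encounters per (person, phecode).

    ``persons`` fixes the cohort universe: people with no encounters are
    controls for every phecode. Unknown ICD codes are ignored and tallied.
    """
    if scope not in ("all", "visit"):
        raise ValueError("scope must be 'all' or 'visit'")
    enc = encounters.copy()
    if scope == "visit":
        enc = enc[enc["encounter_type"].isin(VISIT_TYPES)]
    mapping = ontology.set_index(["icd_code", "icd_version"])["phecode"]
    keys = pd.MultiIndex.from_frame(enc[["icd_code", "icd_version"]])
    mapped = mapping.reindex(keys)
    unknown_mask = mapped.isna().to_numpy()
    unknown: dict[str, int] = {}
    if unknown_mask.any():
        for code in enc.loc[unknown_mask, "icd_code"]:
            unknown[code] = unknown.get(code, 0) + 1
    enc = enc[~unknown_mask].assign(phecode=mapped[~unknown_mask].to_numpy())
    counts = (
        enc.drop_duplicates(["person_id", "phecode", "encounter_id"])
        .groupby(["person_id", "phecode"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return PhecodeCounts(counts=counts, scope=scope, persons=list(persons), unknown_icd=unknown)


def define_cases(
    counts: PhecodeCounts,
    min_occurrences: int = 1,
    intermediate_as_control: bool = False,
) -> pd.DataFrame:
    """Case/control/excluded status per (person, phecode), wide on people.

    Returns a long DataFrame (person_id, phecode, count, status). With
    ``min_occurrences=1`` the case/control split is exhaustive. People with
    0 < count < min_occurrences are excluded unless
    ``intermediate_as_control`` reassigns them to controls.
    """
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    phecodes = sorted(counts.counts["phecode"].unique())
    full = pd.MultiIndex.from_product(
        [counts.persons, phecodes], names=["person_id", "phecode"]
    ).to_frame(index=False)
    long = full.merge(counts.counts, on=["person_id", "phecode"], how="left")
    long["count"] = long["count"].fillna(0).astype(int)
    status = np.where(
        long["count"] >= min_occurrences,
        CASE,
        np.where(long["count"] == 0, CONTROL, EXCLUDED),
    )
    if intermediate_as_control:
        status = np.where(status == EXCLUDED, CONTROL, status)
    long["status"] = status
    return long


def case_matrix(statuses: pd.DataFrame) -> pd.DataFrame:
    """Pivot statuses to a person x phecode frame of 1/0/NaN (case/control/excluded)."""
    val = statuses["status"].map({CASE: 1.0, CONTROL: 0.0, EXCLUDED: np.nan})
    return statuses.assign(_y=val).pivot(
        index="person_id", columns="phecode", values="_y"
    )


def retention_curve(
    encounters: pd.DataFrame,
    ontology: pd.DataFrame,
    persons: list,
    min_grid: list[int] = (1, 2, 3, 4, 5),
    scopes: list[str] = ("all", "visit"),
) -> pd.DataFrame:
    """Proportion of retained cases vs the 1-occurrence definition.

    For each (scope, min_occurrences, phecode): cases(min)/cases(1). The
    proportion is missing (NaN) when cases(1) = 0. Monotone non-increasing
    in ``min_occurrences`` by construction (nested case sets).
    """
    rows = []
    for scope in scopes:
        counts = count_occurrences(encounters, ontology, persons, scope=scope)
        per_phecode = counts.counts.groupby("phecode")["count"]
        base = per_phecode.apply(lambda c: (c >= 1).sum())
        for m in min_grid:
            cases_m = per_phecode.apply(lambda c, m=m: (c >= m).sum())
            for ph in base.index:
                denom = base[ph]
                rows.append(
                    {
                        "scope": scope,
                        "min_occurrences": m,
                        "phecode": ph,
                        "n_cases": int(cases_m[ph]),
                        "proportion_retained": (cases_m[ph] / denom) if denom > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def filter_testable(
    statuses: pd.DataFrame,
    groups: pd.Series,
    min_cases: int = 50,
) -> dict[str, list[str]]:
    """Phecodes testable per group: case count strictly > ``min_cases``.

    ``groups`` maps person_id -> group label (e.g. GIA); people without a
    group are ignored.
    """
    df = statuses.merge(
        groups.rename("group"), left_on="person_id", right_index=True, how="inner"
    )
    case_counts = (
        df[df["status"] == CASE].groupby(["group", "phecode"]).size().rename("n")
    )
    out: dict[str, list[str]] = {g: [] for g in groups.unique()}
    for (grp, ph), n in case_counts.items():
        if n > min_cases:
            out.setdefault(grp, []).append(ph)
    return {g: sorted(v) for g, v in out.items()}
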