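"""From raw slider responses to mean fingerprints, plus study-level statistics.

The rating pipeline mirrors a standard psychophysical workflow:

1. **Z-score per participant and attribute** across materials, removing
   individual differences in slider use (bias and gain).
2. **Exclude discordant raters**: for each attribute, a participant whose
   ratings correlate negatively (or not at all) with the across-participant
   mean ratings is dropped for that attribute.
3. **Average** the surviving Z-scores per (material, attribute) cell, giving a
   mean fingerprint per material on the ``zscore`` scale.

The module also implements the statistics used to derive and validate the
attribute set itself: attribute importance from free-naming responses
(``importance = ap * (max(ao) - ao)`` where ``ap`` is the naming probability
and ``ao`` the mean naming rank), Fleiss's kappa for inter-rater agreement of
categorical cluster assignments, and unanimity counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import N_ATTRIBUTES, Fingerprint, FingerprintSet

__all__ = [
    "RATING_COLUMNS",
    "Exclusion",
    "AggregationReport",
    "zscore_participant",
    "exclude_discordant",
    "aggregate_ratings",
    "attribute_importance",
    "fleiss_kappa",
    "unanimity_counts",
    "rating_study_total",
    "boundary_study_trials",
]

RATING_COLUMNS = ["participant_id", "material_id", "attribute_id", "response"]
SLIDER_RANGE = (0.0, 100.0)


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    if table.duplicated(["participant_id", "material_id", "attribute_id"]).any():
        dup = table[table.duplicated(["participant_id", "material_id", "attribute_id"])].iloc[0]
        raise ValueError(
            "duplicate (participant, material, attribute) triple: "
            f"({dup['participant_id']}, {dup['material_id']}, {dup['attribute_id']})")
    if not np.isfinite(table["response"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite responses in ratings table")
    return table


@dataclass(frozen=True)
class Exclusion:
    participant_id: str
    attribute_id: int
    reason: str


@dataclass
class AggregationReport:
    """Aggregated mean fingerprints plus the audit trail of excluded raters."""

    fingerprints: FingerprintSet | None
    excluded: list[Exclusion] = field(default_factory=list)
    n_ratings_used: int = 0
    flagged_constant: list[tuple[str, int]] = field(default_factory=list)


def zscore_participant(table: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Z-score responses within each (participant, attribute) stratum across materials.

    Uses the sample (n-1) standard deviation. Strata with zero variance are set
    to 0 and returned as flagged pairs so the exclusion step can drop them.
    """
    table = _check_table(table).copy()
    flagged: list[tuple[str, int]] = []
    out = np.empty(len(table), dtype=float)
    grouped = table.groupby(["participant_id", "attribute_id"], sort=False)
    for (pid, aid), idx in grouped.indices.items():
        resp = table["response"].to_numpy(dtype=float)[idx]
        sd = resp.std(ddof=1) if resp.size > 1 else 0.0
        if sd == 0.0:
            out[idx] = 0.0
            flagged.append((pid, int(aid)))
        else:
            out[idx] = (resp - resp.mean()) / sd
    table["response"] = out
    return table, flagged


def _pearson_or_nan(a: np.ndarray, b: np.ndarray) -> float:
    ac, bc = a - a.mean(), b - b.mean()
    denom = math.sqrt(float(ac @ ac) * float(bc @ bc))
    if denom == 0.0:
        return float("nan")
    return float(ac @ bc) / denom


def exclude_discordant(
    table: pd.DataFrame,
    flagged_constant: list[tuple[str, int]] | None = None,
) -> AggregationReport:
    """Flag participants whose ratings oppose the group consensus.

    For each attribute, the provisional mean rating per material is computed
    over *all* participants (including the one under test). A participant with
    a negative or undefined correlation against that mean is excluded for that
    attribute. An attribute rated by a single participant is never excluded.
    """
    table = _check_table(table)
    excluded: list[Exclusion] = []
    flagged = set(flagged_constant or [])
    for aid, sub in table.groupby("attribute_id", sort=True):
        pivot = sub.pivot(index="material_id", columns="participant_id", values="response")
        provisional = pivot.mean(axis=1)
        for pid in pivot.columns:
            if (pid, int(aid)) in flagged:
                excluded.append(Exclusion(pid, int(aid), "zero variance"))
                continue
            if pivot.shape[1] == 1:
                continue  # correlation with own mean is 1 by construction
            col = pivot[pid]
            mask = col.notna()
            r = _pearson_or_nan(col[mask].to_numpy(), provisional[mask].to_numpy())
            if math.isnan(r):
                excluded.append(Exclusion(pid, int(aid), "undefined correlation"))
            elif r < 0.0:
                excluded.append(Exclusion(pid, int(aid), f"negative correlation ({r:.3f})"))
    return AggregationReport(fingerprints=None, excluded=excluded)


def aggregate_ratings(table: pd.DataFrame) -> AggregationReport:
    """Full pipeline: Z-score, exclude discordant raters, average across participants.

    Returns mean fingerprints on the ``zscore`` scale together with the
    exclusion report and the number of ratings that survived.
    """
    zscored, flagged = zscore_participant(table)
    report = exclude_discordant(zscored, flagged)
    drop = {(e.participant_id, e.attribute_id) for e in report.excluded}
    key = list(zip(zscored["participant_id"], zscored["attribute_id"].astype(int)))
    keep = np.fromiter(((k not in drop) for k in key), dtype=bool, count=len(zscored))
    surviving = zscored[keep]

    cell = surviving.groupby(["material_id", "attribute_id"])["response"]
    means = cell.mean().unstack("attribute_id")
    expected = list(range(1, N_ATTRIBUTES + 1))
    missing_cols = [a for a in expected if a not in means.columns]
    empty = [(m, a) for a in expected if a in means.columns
             for m in means.index[means[a].isna()]]
    if missing_cols or empty:
        raise ValueError(
            "cells with zero surviving ratings: "
            f"attributes {missing_cols} entirely empty; cells {empty[:10]}")
    means = means[expected]

    fps = FingerprintSet(
        Fingerprint(str(mid), means.loc[mid].to_numpy(dtype=float), scale="zscore")
        for mid in means.index)
    report.fingerprints = fps
    report.n_ratings_used = int(len(surviving))
    report.flagged_constant = flagged
    return report


# ---------------------------------------------------------------------------
# free-naming statistics
# ---------------------------------------------------------------------------

def attribute_importance(
    naming: pd.DataFrame,
    clusters: dict[str, int],
) -> pd.DataFrame:
    """Combined attribute importance from free-naming responses.

    ``naming`` is long-form with columns ``participant_id, trial, term, rank``;
    ``clusters`` maps each retained term to an attribute id. For each attribute:

    * ``ap`` — fraction of (participant, trial) responses mentioning it,
    * ``ao`` — mean rank over its mentions (lower = named earlier),
    * ``importance`` — ``ap * (max(ao) - ao)``, the max taken over attributes,

    so an attribute is important when it is named often *and* early. Attributes
    never mentioned get ``ap = 0``, undefined ``ao`` (NaN) and importance 0.
    """
    required = ["participant_id", "trial", "term", "rank"]
    missing = [c for c in required if c not in naming.columns]
    if missing:
        raise ValueError(f"naming table missing columns: {missing}")
    unmapped = sorted(set(naming["term"]) - set(clusters))
    if unmapped:
        raise ValueError(f"terms without a cluster assignment: {unmapped[:10]}")

    df = naming.copy()
    df["attribute_id"] = df["term"].map(clusters).astype(int)
    n_responses = df.groupby(["participant_id", "trial"]).ngroups

    rows = []
    for aid in range(1, N_ATTRIBUTES + 1):
        sub = df[df["attribute_id"] == aid]
        mentions = sub.groupby(["participant_id", "trial"]).ngroups
        ap = mentions / n_responses if n_responses else 0.0
        ao = float(sub["rank"].mean()) if len(sub) else float("nan")
        rows.append({"attribute_id": aid, "ap": ap, "ao": ao})
    out = pd.DataFrame(rows).set_index("attribute_id")
    max_ao = out["ao"].max(skipna=True)
    out["importance"] = (out["ap"] * (max_ao - out["ao"])).fillna(0.0)
    return out


# ---------------------------------------------------------------------------
# inter-rater agreement
# ---------------------------------------------------------------------------

def _assignment_counts(assignments: pd.DataFrame) -> np.ndarray:
    required = ["response_id", "rater_id", "attribute_id"]
    missing = [c for c in required if c not in assignments.columns]
    if missing:
        raise ValueError(f"assignments table missing columns: {missing}")
    if assignments.duplicated(["response_id", "rater_id"]).any():
        raise ValueError("a rater assigned the same response more than once")
    counts = (
        assignments.groupby(["response_id", "attribute_id"]).size()
        .unstack("attribute_id", fill_value=0)
        .reindex(columns=range(1, N_ATTRIBUTES + 1), fill_value=0)
    )
    per_response = counts.sum(axis=1).to_numpy()
    if len(set(per_response)) != 1:
        raise ValueError("every response must be rated by the same number of raters")
    if per_response[0] < 2:
        raise ValueError("Fleiss kappa needs at least 2 raters per response")
    return counts.to_numpy(dtype=float)


def fleiss_kappa(assignments: pd.DataFrame) -> float:
    """Fleiss's kappa for multiple raters assigning responses to the 16 attributes.

    Chance-corrected agreement: 1 for perfect agreement, 0 at chance level.
    Requires a balanced design (every response rated by the same r >= 2 raters).
    """
    counts = _assignment_counts(assignments)
    n_items, r = counts.shape[0], counts.sum(axis=1)[0]
    p_j = counts.sum(axis=0) / (n_items * r)
    p_i = ((counts * counts).sum(axis=1) - r) / (r * (r - 1))
    p_bar = p_i.mean()
    p_e = float((p_j * p_j).sum())
    if p_e == 1.0:
        return 1.0  # all raters always pick the same single category
    return float((p_bar - p_e) / (1.0 - p_e))


def unanimity_counts(assignments: pd.DataFrame) -> dict[str, int]:
    """Counts of responses whose modal attribute reaches each agreement level."""
    counts = _assignment_counts(assignments)
    r = int(counts.sum(axis=1)[0])
    modal = counts.max(axis=1)
    return {
        "unanimous": int((modal == r).sum()),
        "at_least_3": int((modal >= 3).sum()),
        "at_least_2": int((modal >= 2).sum()),
    }


# ---------------------------------------------------------------------------
# study-design arithmetic
# ---------------------------------------------------------------------------

def rating_study_total(
    n_attributes: int = N_ATTRIBUTES,
    n_materials: int = 347,
    participants_per_attribute: int = 20,
) -> int:
    """Total ratings collected in a full rating study design."""
    return n_attributes * n_materials * participants_per_attribute


def boundary_study_trials(
    n_arrangements: int = 3,
    n_attributes: int = N_ATTRIBUTES,
    n_anchors: int = 2,
) -> int:
    """Responses per participant in the boundary-anchor identification study."""
    return n_arrangements * n_attributes * n_anchors
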