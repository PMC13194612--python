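"""Binary multi-criteria druggability scoring and confidence tiers.

Each candidate protein is scored against a configurable set of criteria;
meeting a criterion scores 1 (times its weight, default 1), failing scores 0.
The default preset carries the eight equal-weight criteria used for
target triage: MW < 90 kDa, GRAVY < 0, instability index < 40, aliphatic
index > 70, solubility > 0.45, no transmembrane helices, no Sec/SPI signal
peptide, and favourable surface/disorder/secondary-structure features.
Totals map to confidence tiers (very_high/high/moderate/low); a total >= 8
under the default preset marks a high-confidence druggable target.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .physchem import PropertyProfile

_COMPARATORS = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
    "=": operator.eq,
    "==": operator.eq,
}

TIERS = ("very_high", "high", "moderate", "low")


@dataclass(frozen=True)
class Criterion:
    """One scored rule: compare a source value against a threshold."""

    name: str
    source: str  # key into the merged property/annotation mapping
    comparator: str  # one of < <= > >= = boolean
    threshold: float | bool | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS and self.comparator != "boolean":
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.weight <= 0:
            raise ValueError("criterion weight must be > 0")

    def evaluate(self, value) -> int:
        if self.comparator == "boolean":
            return int(bool(value))
        return int(_COMPARATORS[self.comparator](value, self.threshold))


def default_criteria(signal_peptide_scored_when: str = "absent") -> list[Criterion]:
    """The eight-criterion equal-weight preset.

    ``signal_peptide_scored_when`` sets the direction of the signal-peptide
    criterion: "absent" (default; consistent with selecting cytoplasmic
    proteins, a Sec/SPI probability < 0.5 scores 1) or "present".
    """
    sp_cmp = "<" if signal_peptide_scored_when == "absent" else ">="
    return [
        Criterion("mw_below_90kda", "mw", "<", 90_000.0),
        Criterion("gravy_negative", "gravy", "<", 0.0),
        Criterion("instability_below_40", "instability_index", "<", 40.0),
        Criterion("aliphatic_above_70", "aliphatic_index", ">", 70.0),
        Criterion("soluble_above_0.45", "solubility_score", ">", 0.45),
        Criterion("no_tm_helices", "tm_helix_count", "=", 0),
        Criterion("signal_peptide", "signal_peptide_prob", sp_cmp, 0.5),
        Criterion("netsurf_favourable", "netsurf_favourable", "boolean"),
    ]


def netsurf_favourable(
    surface_accessible: Sequence[bool],
    disordered: Sequence[bool],
    ss_fraction: float,
    min_accessible_fraction: float = 0.30,
    max_disordered_run: int = 20,
    min_ss_fraction: float = 0.30,
) -> int:
    """Structural-favourability flag from per-residue predictions.

    Scores 1 iff the solvent-accessible fraction is >= 30%, the longest
    consecutive disordered run is shorter than 20 residues (strict), and the
    helix+sheet fraction meets a configurable minimum (default 0.30).
    """
    if len(surface_accessible) != len(disordered):
        raise ValueError("per-residue lists must have equal length")
    if not surface_accessible:
        raise ValueError("empty per-residue lists")
    accessible_frac = sum(bool(x) for x in surface_accessible) / len(surface_accessible)
    longest = run = 0
    for flag in disordered:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    ok = (
        accessible_frac >= min_accessible_fraction
        and longest < max_disordered_run
        and ss_fraction >= min_ss_fraction
    )
    return int(ok)


@dataclass
class ScoreCard:
    """Per-protein scoring result: raw values, 0/1 per criterion, total, tier."""

    protein_id: str
    criterion_scores: dict[str, int]
    raw_values: dict[str, float]
    total_score: float
    tier: str | None = None

    def __post_init__(self) -> None:
        expected = sum(self.criterion_scores.values())
        # criterion_scores store weighted contributions; totals must agree
        if abs(self.total_score - expected) > 1e-9:
            raise ValueError("total_score must equal the sum of criterion scores")


def evaluate_criteria(
    protein_id: str,
    profile: PropertyProfile | Mapping[str, float] | None,
    annotations: Mapping[str, object] | None = None,
    criteria: Sequence[Criterion] | None = None,
) -> ScoreCard:
    """Score one protein against a criteria list (tier left unset).

    ``profile`` supplies computed physicochemical values, ``annotations``
    supplies external-prediction columns; the two are merged, annotations
    winning on key collisions.  When the per-residue NetSurfP-style columns
    (``surface_accessible``, ``disordered``, ``secondary_structure_fraction``)
    are present, the derived ``netsurf_favourable`` value is added
    automatically.  A criterion whose source value is missing raises a
    ``KeyError`` naming the criterion.
    """
    criteria = list(criteria) if criteria is not None else default_criteria()
    values: dict[str, object] = {}
    if profile is not None:
        if isinstance(profile, PropertyProfile):
            values.update(vars(profile))
        else:
            values.update(profile)
    if annotations:
        values.update(annotations)
    if "netsurf_favourable" not in values and {
        "surface_accessible",
        "disordered",
        "secondary_structure_fraction",
    } <= set(values):
        values["netsurf_favourable"] = netsurf_favourable(
            values["surface_accessible"],
            values["disordered"],
            float(values["secondary_structure_fraction"]),
        )

    scores: dict[str, int] = {}
    raw: dict[str, float] = {}
    for crit in criteria:
        if crit.source not in values:
            raise KeyError(
                f"criterion {crit.name!r}: source value {crit.source!r} missing "
                f"for protein {protein_id!r}"
            )
        value = values[crit.source]
        scores[crit.name] = crit.evaluate(value) * crit.weight
        try:
            raw[crit.name] = float(value)  # per-residue lists are not stored raw
        except (TypeError, ValueError):
            pass
    total = sum(scores.values())
    return ScoreCard(protein_id, scores, raw, total)


DEFAULT_CUTPOINTS = (8, 7, 5)  # very_high >= 8, high >= 7, moderate >= 5, else low


def assign_tier(total_score: float, cutpoints: Sequence[float] = DEFAULT_CUTPOINTS) -> str:
    """Map a total score to a confidence tier by descending cutpoints.

    ``cutpoints`` are the inclusive lower bounds of (very_high, high,
    moderate); anything below the last is low.  Must be strictly decreasing.
    """
    if len(cutpoints) != 3:
        raise ValueError("cutpoints must be (very_high, high, moderate) bounds")
    if not (cutpoints[0] > cutpoints[1] > cutpoints[2]):
        raise ValueError("cutpoints must be strictly decreasing")
    for bound, tier in zip(cutpoints, TIERS):
        if total_score >= bound:
            return tier
    return "low"


def score_proteins(
    profiles: Mapping[str, PropertyProfile | Mapping[str, float]],
    annotations: pd.DataFrame | None = None,
    criteria: Sequence[Criterion] | None = None,
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS,
) -> list[ScoreCard]:
    """Score and tier a set of proteins; annotations indexed by protein id."""
    cards = []
    for pid, profile in profiles.items():
        ann = annotations.loc[pid].to_dict() if annotations is not None else None
        card = evaluate_criteria(pid, profile, ann, criteria)
        card.tier = assign_tier(card.total_score, cutpoints)
        cards.append(card)
    return cards


def summarize_tiers(scorecards: Sequence[ScoreCard]) -> pd.DataFrame:
    """Tier counts and percentages (2 decimals) over the scored set."""
    if not scorecards:
        raise ValueError("no scorecards to summarize")
    counts = {tier: 0 for tier in TIERS}
    for card in scorecards:
        if card.tier is None:
            raise ValueError(f"scorecard {card.protein_id!r} has no tier")
        counts[card.tier] += 1
    total = len(scorecards)
    return pd.DataFrame(
        {
            "tier": list(TIERS),
            "count": [counts[t] for t in TIERS],
            "percentage": [round(100.0 * counts[t] / total, 2) for t in TIERS],
        }
    )


def summarize_kegg(
    annotations: pd.DataFrame, candidate_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-KEGG-category counts and percentages over the annotated subset.

    Proteins without a category value are excluded from the denominator;
    the literal category "unclassified" counts as its own category.
    """
    if len(candidate_ids) == 0:
        return pd.DataFrame(columns=["kegg_category", "count", "percentage"])
    sub = annotations.loc[list(candidate_ids)]
    cats = sub["kegg_category"].dropna()
    if cats.empty:
        return pd.DataFrame(columns=["kegg_category", "count", "percentage"])
    counts = cats.value_counts()
    out = pd.DataFrame(
        {
            "kegg_category": counts.index,
            "count": counts.values,
            "percentage": (100.0 * counts.values / len(cats)).round(2),
        }
    )
    return out.reset_index(drop=True)
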