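"""Subtractive-genomics filter cascade.

Reduces a bacterial proteome to essential, cytoplasmic, human-non-homologous
drug-target candidates in four chained stages:

1. redundancy removal — greedy longest-first clustering at a sequence
   identity threshold (CD-HIT-style representative selection, but with exact
   global alignments instead of the word heuristic),
2. essentiality — keep proteins whose predicted essentiality score meets a
   threshold (default 0.24),
3. localization consensus — keep proteins called cytoplasmic, with
   per-tool confidence rules, by a configurable number of predictors,
4. human non-homology — drop proteins with a significant BLASTP hit against
   the human proteome (E-value AND identity AND coverage conditions).

External predictors (essentiality, localization, BLAST) are consumed as
annotation columns; this module never runs them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationTable:
    """External predictor outputs, one row per protein.

    ``table`` is indexed by protein id; expected columns (a subset may be
    present depending on the stages run): ``essentiality_score``,
    ``psortb_call``, ``psortb_score``, ``cello2go_call``,
    ``cello2go_reliability``, ``deeplocpro_call``, ``deeplocpro_prob``,
    ``tm_helix_count``, ``signal_peptide_prob``, ``solubility_score``,
    ``surface_accessible`` (list of bool), ``disordered`` (list of bool),
    ``secondary_structure_fraction``, ``kegg_category``.

    ``hits`` is a long-format table of human best hits with columns
    ``protein_id``, ``evalue``, ``identity_pct``, ``coverage_pct``.
    """

    table: pd.DataFrame
    hits: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["protein_id", "evalue", "identity_pct", "coverage_pct"]
        )
    )

    def __post_init__(self) -> None:
        required = {"evalue", "identity_pct", "coverage_pct"}
        if not required.issubset(self.hits.columns):
            raise ValueError(f"hits table must have columns {sorted(required)}")

    def validate_against(self, proteins: Sequence[ProteinRecord]) -> None:
        """Check ids and per-residue list lengths against a proteome."""
        by_id = {p.id: p for p in proteins}
        unknown = set(self.table.index) - set(by_id)
        if unknown:
            raise ValueError(f"annotation rows for unknown proteins: {sorted(unknown)[:5]}")
        for col in ("surface_accessible", "disordered"):
            if col in self.table.columns:
                for pid, val in self.table[col].items():
                    if isinstance(val, (list, tuple)) and len(val) != len(by_id[pid]):
                        raise ValueError(
                            f"{col} length {len(val)} != sequence length "
                            f"{len(by_id[pid])} for {pid!r}"
                        )

    def hits_for(self, protein_id: str) -> pd.DataFrame:
        return self.hits[self.hits["protein_id"] == protein_id]


@dataclass(frozen=True)
class FilterTrace:
    """Audit record of one cascade stage."""

    stage: str
    input_ids: tuple[str, ...]
    retained_ids: tuple[str, ...]
    reasons: dict[str, str]  # removed id -> reason code

    def __post_init__(self) -> None:
        if not set(self.retained_ids) <= set(self.input_ids):
            raise ValueError("retained ids must be a subset of input ids")
        removed = set(self.input_ids) - set(self.retained_ids)
        if removed - set(self.reasons):
            raise ValueError("every removed id needs a reason code")

    @property
    def n_in(self) -> int:
        return len(self.input_ids)

    @property
    def n_out(self) -> int:
        return len(self.retained_ids)


# ---------------------------------------------------------------------------
# Stage 1: redundancy removal


def _make_aligner() -> Align.PairwiseAligner:
    # Needleman–Wunsch with match=1, mismatch=0, linear gap penalty -1;
    # identity defined as matches / alignment length (gaps included).
    aligner = Align.PairwiseAligner(mode="global")
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: exact matches over alignment length."""
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def cluster_redundant(
    proteins: Sequence[ProteinRecord], identity_threshold: float = 0.70
) -> tuple[list[list[ProteinRecord]], list[ProteinRecord]]:
    """Greedy longest-first clustering at an identity threshold.

    Sequences are visited longest first (ties broken by id for determinism);
    each joins the first existing cluster whose *representative* (founder) it
    matches at >= threshold identity, else founds a new cluster.  Returns
    (clusters, representatives); the union of clusters is the input.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    aligner = _make_aligner()
    ordered = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    clusters: list[list[ProteinRecord]] = []
    for prot in ordered:
        for cluster in clusters:
            rep = cluster[0]
            if pairwise_identity(prot.sequence, rep.sequence, aligner) >= identity_threshold:
                cluster.append(prot)
                break
        else:
            clusters.append([prot])
    representatives = [c[0] for c in clusters]
    return clusters, representatives


# ---------------------------------------------------------------------------
# Stages 2-4: annotation-driven filters


def filter_essential(
    table: AnnotationTable,
    ids: Iterable[str],
    threshold: float = 0.24,
    missing: str = "error",
) -> FilterTrace:
    """Retain proteins with essentiality_score >= threshold (boundary kept).

    ``missing`` controls proteins without a score: "error" (default) or
    "fail" (treated as non-essential).
    """
    ids = tuple(ids)
    scores = table.table.get("essentiality_score")
    if scores is None:
        raise ValueError("annotation table lacks 'essentiality_score'")
    retained, reasons = [], {}
    for pid in ids:
        score = scores.get(pid)
        if score is None or (isinstance(score, float) and math.isnan(score)):
            if missing == "error":
                raise ValueError(f"missing essentiality score for {pid!r}")
            reasons[pid] = "no_essentiality_score"
        elif score >= threshold:
            retained.append(pid)
        else:
            reasons[pid] = f"essentiality_below_{threshold}"
    return FilterTrace("essential", ids, tuple(retained), reasons)


_LOCALIZATION_TOOLS = ("psortb", "cello2go", "deeplocpro")


def _tool_votes(row: pd.Series) -> dict[str, bool | None]:
    """Per-tool cytoplasmic vote; None if the tool did not report.

    A tool votes cytoplasmic only when its call is 'cytoplasmic' AND its
    confidence rule is met: PSORTb score >= 7.5, DeepLocPro probability
    >= 0.5; CELLO2GO counts whenever cytoplasmic is its top-reliability call.
    """
    votes: dict[str, bool | None] = {}
    call = row.get("psortb_call")
    if isinstance(call, str):
        votes["psortb"] = call == "cytoplasmic" and float(row.get("psortb_score", 0.0)) >= 7.5
    else:
        votes["psortb"] = None
    call = row.get("cello2go_call")
    votes["cello2go"] = (call == "cytoplasmic") if isinstance(call, str) else None
    call = row.get("deeplocpro_call")
    if isinstance(call, str):
        votes["deeplocpro"] = call == "cytoplasmic" and float(row.get("deeplocpro_prob", 0.0)) >= 0.5
    else:
        votes["deeplocpro"] = None
    return votes


def localization_consensus(
    table: AnnotationTable, ids: Iterable[str], min_votes: int | None = None
) -> FilterTrace:
    """Retain proteins called cytoplasmic by enough predictors.

    Default rule: a majority of the tools that reported for the protein.
    Proteins with no reporting tool are removed with reason ``no_tool_report``.
    """
    ids = tuple(ids)
    retained, reasons = [], {}
    for pid in ids:
        row = table.table.loc[pid]
        votes = _tool_votes(row)
        reporting = [v for v in votes.values() if v is not None]
        if not reporting:
            reasons[pid] = "no_tool_report"
            continue
        needed = min_votes if min_votes is not None else len(reporting) // 2 + 1
        if sum(reporting) >= needed:
            retained.append(pid)
        else:
            reasons[pid] = "not_cytoplasmic_consensus"
    return FilterTrace("localization", ids, tuple(retained), reasons)


def filter_human_nonhomologous(
    table: AnnotationTable,
    ids: Iterable[str],
    evalue_cut: float = 1e-3,
    identity_cut: float = 30.0,
    coverage_cut: float = 30.0,
    combine: str = "and",
) -> FilterTrace:
    """Retain proteins with no significant human hit.

    A hit is significant iff ``evalue <= evalue_cut`` AND
    ``identity > identity_cut`` AND ``coverage > coverage_cut`` (the
    combination is configurable: ``combine="any"`` makes a hit significant
    when any one condition holds).  Proteins with no hits at all are retained.
    """
    ids = tuple(ids)
    hits = table.hits
    for col in ("evalue", "identity_pct", "coverage_pct"):
        vals = pd.to_numeric(hits[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"malformed hit rows: non-numeric {col}")
    retained, reasons = [], {}
    for pid in ids:
        sub = hits[hits["protein_id"] == pid]
        conds = pd.DataFrame(
            {
                "e": sub["evalue"] <= evalue_cut,
                "i": sub["identity_pct"] > identity_cut,
                "c": sub["coverage_pct"] > coverage_cut,
            }
        )
        significant = conds.all(axis=1) if combine == "and" else conds.any(axis=1)
        if significant.any():
            reasons[pid] = "significant_human_hit"
        else:
            retained.append(pid)
    return FilterTrace("human_homology", ids, tuple(retained), reasons)


# ---------------------------------------------------------------------------
# Cascade


@dataclass(frozen=True)
class CascadeConfig:
    identity_threshold: float = 0.70
    essentiality_threshold: float = 0.24
    min_localization_votes: int | None = None  # None = majority of reporting
    evalue_cut: float = 1e-3
    identity_cut: float = 30.0
    coverage_cut: float = 30.0
    hit_combine: str = "and"
    missing_essentiality: str = "error"


@dataclass
class CascadeResult:
    traces: list[FilterTrace]
    candidate_ids: tuple[str, ...]
    clusters: list[list[ProteinRecord]]

    @property
    def stage_counts(self) -> dict[str, int]:
        counts = {}
        for tr in self.traces:
            counts[tr.stage] = tr.n_out
        return counts


def run_cascade(
    proteins: Sequence[ProteinRecord],
    table: AnnotationTable,
    config: CascadeConfig | None = None,
) -> CascadeResult:
    """Run the full cascade: redundancy -> essential -> localization ->
    human non-homology.  Stage n consumes stage n-1's retained set."""
    config = config or CascadeConfig()
    if not proteins:
        return CascadeResult([], (), [])
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in proteome")
    table.validate_against(proteins)

    clusters, reps = cluster_redundant(proteins, config.identity_threshold)
    rep_ids = tuple(p.id for p in reps)
    reasons = {
        m.id: f"redundant_with_{c[0].id}" for c in clusters for m in c[1:]
    }
    traces = [FilterTrace("redundancy", tuple(ids), rep_ids, reasons)]

    tr = filter_essential(
        table, rep_ids, config.essentiality_threshold, config.missing_essentiality
    )
    traces.append(tr)
    tr = localization_consensus(table, tr.retained_ids, config.min_localization_votes)
    traces.append(tr)
    tr = filter_human_nonhomologous(
        table,
        tr.retained_ids,
        config.evalue_cut,
        config.identity_cut,
        config.coverage_cut,
        config.hit_combine,
    )
    traces.append(tr)
    return CascadeResult(traces, tr.retained_ids, clusters)
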