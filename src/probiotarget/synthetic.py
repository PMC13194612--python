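"""Synthetic input generators with known ground truth.

Every input the pipeline consumes can be generated here with controlled
parameters, so each analysis stage is testable by parameter recovery:

* proteomes with declared redundancy groups (substitution-only mutants of a
  founder sequence, so pairwise identity is countable without alignment),
* annotation tables with tunable per-filter pass rates,
* OD600 microplates drawn from a four-parameter log-logistic dose–response
  with truncated Gaussian noise,
* Ct tables with specified true ΔΔCt effects and replicate noise,
* trajectories as independent Gaussian fluctuations about a reference
  structure with a per-residue amplitude profile (plus optional rigid drift).

One global integer seed drives a splittable per-generator stream: generator
k uses ``numpy.random.SeedSequence(seed, spawn_key=(k,))``, so adding a new
generator never perturbs the output of existing ones, and identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import ll4
from .filtering import ProteinRecord
from .physchem import CANONICAL
from .trajectory import Trajectory

# fixed spawn keys; append new generators at the end, never renumber
_STREAMS = {"proteome": 0, "annotations": 1, "plate": 2, "ct": 3, "trajectory": 4}

QPCR_TARGET_GENES = ("nadH", "pyrH", "atpD", "def", "glmS", "murE")
REFERENCE_GENE = "16S"


@dataclass
class SyntheticSpec:
    """Ground-truth parameters for all generators.

    ``dose_response_params`` is (lower, upper, slope, ic50 µg/mL, noise_sd);
    lower/upper are OD600 asymptotes at infinite/zero dose.  ``ddct_effects``
    maps (gene, condition) to the true ΔΔCt; ``ct_noise_sd`` is the
    replicate Ct noise in cycles.  ``traj_amplitudes`` is the per-residue
    fluctuation SD profile in nm (per coordinate).
    """

    seed: int = 0
    n_proteins: int = 20
    length_range: tuple[int, int] = (120, 400)
    redundancy_groups: list[tuple[int, float]] = field(default_factory=list)
    filter_pass_rates: dict[str, float] = field(
        default_factory=lambda: {
            "essential": 0.18,
            "cytoplasmic": 0.85,
            "nonhomologous": 0.40,
        }
    )
    dose_response_params: tuple[float, float, float, float, float] = (
        0.0,
        0.893,
        1.0,
        91.28,
        0.02,
    )
    ddct_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    ct_noise_sd: float = 0.15
    n_frames: int = 5001
    dt_ns: float = 0.01
    traj_amplitudes: np.ndarray | None = None
    traj_drift_nm_per_ns: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid length_range")
        for size, ident in self.redundancy_groups:
            if size < 1 or not 0.0 <= ident <= 1.0:
                raise ValueError("redundancy group identities must lie in [0, 1]")
        for name, p in self.filter_pass_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pass rate {name} outside [0, 1]")
        if self.dose_response_params[4] < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.traj_amplitudes is not None and np.any(np.asarray(self.traj_amplitudes) < 0):
            raise ValueError("fluctuation amplitudes must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


# ---------------------------------------------------------------------------
# Proteome


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL), size=length))


def _mutate(rng: np.random.Generator, sequence: str, n_substitutions: int) -> str:
    """Substitute exactly n distinct positions with a different residue."""
    seq = list(sequence)
    positions = rng.choice(len(seq), size=n_substitutions, replace=False)
    for pos in positions:
        alternatives = [c for c in CANONICAL if c != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(seq)


def generate_proteome(spec: SyntheticSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Proteome with declared redundancy groups plus singleton background.

    Each group (size, identity) gets a founder and size-1 mutants carrying
    exactly floor((1 - identity) * L) substitutions, so any member's
    identity to the founder is >= the target by construction.  Remaining
    proteins up to ``n_proteins`` are independent random singletons.  The
    truth table records group membership and mutation counts.
    """
    rng = spec.rng("proteome")
    lo, hi = spec.length_range
    records: list[ProteinRecord] = []
    truth_rows = []
    counter = 0
    for g, (size, identity) in enumerate(spec.redundancy_groups):
        length = int(rng.integers(lo, hi + 1))
        founder = _random_sequence(rng, length)
        n_mut = int(np.floor((1.0 - identity) * length + 1e-9))
        for member in range(size):
            counter += 1
            pid = f"P{counter:04d}"
            seq = founder if member == 0 else _mutate(rng, founder, n_mut)
            records.append(ProteinRecord(pid, seq))
            truth_rows.append(
                {
                    "protein_id": pid,
                    "group": f"G{g}",
                    "is_founder": member == 0,
                    "length": length,
                    "n_substitutions": 0 if member == 0 else n_mut,
                    "identity_to_founder": 1.0 if member == 0 else (length - n_mut) / length,
                }
            )
    while counter < spec.n_proteins:
        counter += 1
        pid = f"P{counter:04d}"
        length = int(rng.integers(lo, hi + 1))
        records.append(ProteinRecord(pid, _random_sequence(rng, length)))
        truth_rows.append(
            {
                "protein_id": pid,
                "group": pid,
                "is_founder": True,
                "length": length,
                "n_substitutions": 0,
                "identity_to_founder": 1.0,
            }
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Annotations


def generate_annotations(
    spec: SyntheticSpec, records: Sequence[ProteinRecord]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Annotation + hits tables with per-filter intended outcomes.

    Pass/fail per filter is drawn from ``filter_pass_rates``; scores are then
    placed on the passing or failing side of each published threshold.
    Returns (annotation table indexed by id, long-format hits table, truth
    table of intended outcomes).
    """
    rng = spec.rng("annotations")
    rates = spec.filter_pass_rates
    kegg_pool = [
        "genetic information processing",
        "amino acid metabolism",
        "nucleotide metabolism",
        "glycan biosynthesis and metabolism",
        "energy metabolism",
        "carbohydrate metabolism",
        "unclassified",
    ]
    rows, hit_rows, truth_rows = [], [], []
    for rec in records:
        length = len(rec.sequence)
        essential = rng.random() < rates["essential"]
        cytoplasmic = rng.random() < rates["cytoplasmic"]
        nonhomologous = rng.random() < rates["nonhomologous"]
        ess_score = rng.uniform(0.24, 1.0) if essential else rng.uniform(0.0, 0.239)
        if cytoplasmic:
            loc = {
                "psortb_call": "cytoplasmic",
                "psortb_score": float(rng.uniform(7.5, 10.0)),
                "cello2go_call": "cytoplasmic",
                "cello2go_reliability": float(rng.uniform(0.7, 1.0)),
                "deeplocpro_call": "cytoplasmic",
                "deeplocpro_prob": float(rng.uniform(0.5, 1.0)),
            }
        else:
            loc = {
                "psortb_call": "membrane",
                "psortb_score": float(rng.uniform(7.5, 10.0)),
                "cello2go_call": "membrane",
                "cello2go_reliability": float(rng.uniform(0.7, 1.0)),
                "deeplocpro_call": "membrane",
                "deeplocpro_prob": float(rng.uniform(0.5, 1.0)),
            }
        if not nonhomologous:
            hit_rows.append(
                {
                    "protein_id": rec.id,
                    "evalue": float(10.0 ** rng.uniform(-50, -5)),
                    "identity_pct": float(rng.uniform(35, 90)),
                    "coverage_pct": float(rng.uniform(40, 100)),
                }
            )
        elif rng.random() < 0.5:  # weak, non-significant hit
            hit_rows.append(
                {
                    "protein_id": rec.id,
                    "evalue": float(10.0 ** rng.uniform(-10, 0)),
                    "identity_pct": float(rng.uniform(5, 28)),
                    "coverage_pct": float(rng.uniform(5, 28)),
                }
            )
        accessible = rng.random(length) < 0.45
        disordered = rng.random(length) < 0.05
        rows.append(
            {
                "protein_id": rec.id,
                "essentiality_score": float(ess_score),
                **loc,
                "tm_helix_count": 0 if cytoplasmic else int(rng.integers(1, 6)),
                "signal_peptide_prob": float(rng.uniform(0.0, 0.4)),
                "solubility_score": float(rng.uniform(0.3, 0.9)),
                "surface_accessible": accessible.tolist(),
                "disordered": disordered.tolist(),
                "secondary_structure_fraction": float(rng.uniform(0.25, 0.8)),
                "kegg_category": kegg_pool[int(rng.integers(len(kegg_pool)))],
            }
        )
        truth_rows.append(
            {
                "protein_id": rec.id,
                "essential": essential,
                "cytoplasmic": cytoplasmic,
                "nonhomologous": nonhomologous,
            }
        )
    ann = pd.DataFrame(rows).set_index("protein_id")
    hits = pd.DataFrame(hit_rows, columns=["protein_id", "evalue", "identity_pct", "coverage_pct"])
    return ann, hits, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Dose-response plate


def generate_plate(
    spec: SyntheticSpec,
    concentrations: Sequence[float],
    n_replicates: int = 3,
    drug: str = "pantoprazole",
) -> pd.DataFrame:
    """OD600 plate from the spec's LL4 curve plus truncated Gaussian noise.

    Treated wells cover each positive concentration x replicate; drug-free
    growth-control wells (concentration 0) are always included.  OD noise is
    truncated at zero (instrument floor).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    concentrations = [float(c) for c in concentrations]
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be >= 0")
    lower, upper, slope, ic50, noise_sd = spec.dose_response_params
    rng = spec.rng("plate")
    rows = []
    all_concs = sorted(set(concentrations) | {0.0})
    for conc in all_concs:
        role = "growth_control" if conc == 0.0 else "treated"
        mean_od = float(ll4(conc, slope, lower, upper, ic50))
        for rep in range(1, n_replicates + 1):
            od = mean_od + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "drug": drug,
                    "concentration_ug_ml": conc,
                    "replicate": rep,
                    "od600": max(0.0, od),
                    "role": role,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR Ct table


def default_ddct_effects(
    conditions: Sequence[str] = ("50", "100"),
) -> dict[tuple[str, str], float]:
    """True ΔΔCt effects emulating strong, dose-dependent transcriptional
    repression of the six assayed genes (larger ΔΔCt = stronger repression)."""
    base = {
        "atpD": (1.55, 4.24),
        "nadH": (2.26, 3.28),
        "murE": (2.19, 3.66),
        "def": (1.61, 4.52),
        "glmS": (1.80, 6.21),
        "pyrH": (2.51, 2.66),
    }
    return {
        (gene, cond): vals[i]
        for gene, vals in base.items()
        for i, cond in enumerate(conditions)
    }


def generate_ct_table(
    spec: SyntheticSpec,
    n_replicates: int = 3,
    control_condition: str = "control",
) -> pd.DataFrame:
    """Ct table whose expected ΔΔCt equals the spec's true effects.

    The reference gene's Ct is condition-independent in expectation; each
    target gene has a gene-specific baseline Ct, shifted by the true ΔΔCt in
    treated conditions.  Replicate noise is Gaussian with ``ct_noise_sd``.
    """
    if n_replicates < 1:
        raise ValueError("each gene/condition needs >= 1 replicate")
    effects = spec.ddct_effects or default_ddct_effects()
    genes = sorted({g for g, _ in effects})
    conditions = [control_condition] + sorted({c for _, c in effects})
    missing_ref = REFERENCE_GENE in genes
    if missing_ref:
        raise ValueError("reference gene cannot carry a ΔΔCt effect")
    rng = spec.rng("ct")
    base_ct = {gene: 20.0 + 2.0 * i for i, gene in enumerate(genes)}
    ref_ct = 12.0
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
            rows.append(
                {"gene": REFERENCE_GENE, "condition": cond, "replicate": rep,
                 "ct": ref_ct + noise}
            )
            for gene in genes:
                shift = 0.0 if cond == control_condition else effects[(gene, cond)]
                noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd > 0 else 0.0
                rows.append(
                    {"gene": gene, "condition": cond, "replicate": rep,
                     "ct": base_ct[gene] + shift + noise}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectory


def make_reference_structure(
    n_residues: int, spacing_nm: float = 0.38, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic Cα-only reference chain (coords nm, masses Da, residue idx).

    A gently curved helix-like curve with ~0.38 nm between consecutive Cα
    atoms; masses are the Cα carbon-12 convention (12 Da) — geometry only,
    no physics is implied.
    """
    t = np.arange(n_residues, dtype=float)
    coords = np.stack(
        [0.23 * np.cos(t * 1.75), 0.23 * np.sin(t * 1.75), 0.15 * t], axis=1
    )
    rng = np.random.default_rng(seed)
    coords += rng.normal(0.0, 0.01, coords.shape)
    masses = np.full(n_residues, 12.0)
    residue_index = np.arange(1, n_residues + 1)
    return coords, masses, residue_index


def default_amplitude_profile(n_residues: int) -> np.ndarray:
    """Per-residue fluctuation SD profile (nm per coordinate): a rigid core
    around 0.03 nm with progressively floppier loop peaks, all distinct so
    the RMSF rank order is identifiable."""
    base = np.linspace(0.025, 0.045, n_residues)
    profile = base.copy()
    for centre, amp in ((int(n_residues * 0.25), 0.09), (int(n_residues * 0.7), 0.14)):
        width = max(2, n_residues // 20)
        idx = np.arange(n_residues)
        profile += amp * np.exp(-0.5 * ((idx - centre) / width) ** 2)
    return profile


def graded_amplitude_profile(
    n_residues: int, start_nm: float = 0.03, step: float = 1.08
) -> np.ndarray:
    """Strictly geometric per-residue amplitude profile (nm per coordinate).

    Designed for rank-order recovery checks: consecutive amplitudes differ
    by ``step`` (default 8%), well above the ~1/sqrt(2 N_frames) relative
    Monte-Carlo error of an RMSF estimate, so the true ordering is
    identifiable from a few thousand frames.
    """
    return start_nm * step ** np.arange(n_residues)


def generate_trajectory(
    spec: SyntheticSpec,
    reference: np.ndarray,
    masses: np.ndarray,
    residue_index: np.ndarray,
) -> Trajectory:
    """Harmonic-fluctuation trajectory about a reference structure.

    Frame t = reference + iid Gaussian displacement with per-residue SD from
    the amplitude profile (per coordinate), plus optional rigid-body drift
    along x at ``traj_drift_nm_per_ns``.  The expected per-atom RMSF is
    amplitude x sqrt(3) (three independent coordinates).
    """
    reference = np.asarray(reference, dtype=float)
    residue_index = np.asarray(residue_index, dtype=int)
    n_atoms = reference.shape[0]
    n_res = len(np.unique(residue_index))
    amplitudes = (
        np.asarray(spec.traj_amplitudes, dtype=float)
        if spec.traj_amplitudes is not None
        else default_amplitude_profile(n_res)
    )
    if len(amplitudes) != n_res:
        raise ValueError(
            f"amplitude profile length {len(amplitudes)} != residue count {n_res}"
        )
    res_order = {r: i for i, r in enumerate(np.unique(residue_index))}
    atom_sd = np.array([amplitudes[res_order[r]] for r in residue_index])
    rng = spec.rng("trajectory")
    times = np.arange(spec.n_frames) * spec.dt_ns
    noise = rng.normal(0.0, 1.0, (spec.n_frames, n_atoms, 3)) * atom_sd[None, :, None]
    coords = reference[None, :, :] + noise
    if spec.traj_drift_nm_per_ns:
        coords[:, :, 0] += (spec.traj_drift_nm_per_ns * times)[:, None]
    return Trajectory(times, coords, masses, residue_index)
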