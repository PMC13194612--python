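"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA for proteomes (via Biopython), TSV for annotation/hits/edge/plate/Ct
tables, and multi-frame XYZ for trajectories (first line atom count, comment
line carrying ``t= <ns>``, then ``element x y z`` per atom, coordinates in
nm) with a sidecar TSV mapping atom index -> residue index and mass.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .filtering import AnnotationTable, ProteinRecord
from .trajectory import Trajectory

_BOOL_LIST_COLUMNS = ("surface_accessible", "disordered")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def _encode_bool_list(values) -> str:
    return "".join("1" if v else "0" for v in values)


def _decode_bool_list(text: str) -> list[bool]:
    return [c == "1" for c in str(text)]


def write_annotations(table: AnnotationTable, path: str | Path, hits_path: str | Path) -> None:
    df = table.table.copy()
    for col in _BOOL_LIST_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(_encode_bool_list)
    df.to_csv(path, sep="\t", index_label="protein_id")
    table.hits.to_csv(hits_path, sep="\t", index=False)


def read_annotations(path: str | Path, hits_path: str | Path | None = None) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    for col in _BOOL_LIST_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(_decode_bool_list)
    if hits_path is not None:
        hits = pd.read_csv(hits_path, sep="\t")
    else:
        hits = pd.DataFrame(columns=["protein_id", "evalue", "identity_pct", "coverage_pct"])
    return AnnotationTable(df, hits)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    expected = {"node_a", "node_b", "score"}
    if not expected.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(expected)}")
    return df


def read_plate(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df["gene"] = df["gene"].astype(str)
    df["condition"] = df["condition"].astype(str)
    return df


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t= {traj.times[t]:.6f}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[t, a]
                fh.write(f"{traj.elements[a]} {x:.6f} {y:.6f} {z:.6f}\n")


def write_topology(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "atom_index": np.arange(1, traj.n_atoms + 1),
            "residue_index": traj.residue_index,
            "mass": traj.masses,
        }
    ).to_csv(path, sep="\t", index=False)


def read_xyz(path: str | Path, topology_path: str | Path) -> Trajectory:
    top = pd.read_csv(topology_path, sep="\t")
    masses = top["mass"].to_numpy(float)
    residue_index = top["residue_index"].to_numpy(int)
    times, frames, elements = [], [], []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n_atoms = int(lines[i].strip())
        comment = lines[i + 1]
        time = 0.0
        for token in comment.replace("=", "= ").split():
            try:
                time = float(token)
                break
            except ValueError:
                continue
        frame, elems = [], []
        for j in range(n_atoms):
            parts = lines[i + 2 + j].split()
            elems.append(parts[0])
            frame.append([float(parts[1]), float(parts[2]), float(parts[3])])
        times.append(time)
        frames.append(frame)
        elements = elems
        i += 2 + n_atoms
    coords = np.asarray(frames, dtype=float)
    if coords.shape[1] != len(masses):
        raise ValueError("topology atom count does not match trajectory")
    return Trajectory(np.asarray(times), coords, masses, residue_index, elements)
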