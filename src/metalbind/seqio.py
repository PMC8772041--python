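"""Readers and writers for sequences, binding annotations, structure tracks
and encoded feature matrices.

External files use 1-based residue numbering (PDB/BioLip convention);
everything in memory is 0-based.  Sequences come as plain FASTA; binding
annotations and per-residue structure predictions as tab-separated tables;
feature matrices as tab-separated text with a header naming every column.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .discretize import ALPHABET, AA20

logger = logging.getLogger(__name__)

#: Minimum chain length retained when assembling a dataset.
MIN_CHAIN_LENGTH = 50

VALID_LIGANDS = frozenset({"CA", "MG"})

_NONSTANDARD = re.compile(f"[^{AA20}X]")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass(frozen=True, eq=False)
class ProteinChain:
    """A protein chain with per-residue binding labels and predicted structure.

    All tracks are parallel to ``sequence``: ``binding_mask`` is boolean,
    ``ss`` holds one of H/E/C per residue, ``rsa`` lies in [0, 1] and the
    dihedrals in [-180, 180] degrees.
    """

    chain_id: str
    sequence: str
    binding_mask: np.ndarray
    ss: np.ndarray
    rsa: np.ndarray
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        n = len(self.sequence)
        for name in ("binding_mask", "ss", "rsa", "phi", "psi"):
            track = getattr(self, name)
            if len(track) != n:
                raise ValueError(
                    f"chain {self.chain_id!r}: track {name} has length "
                    f"{len(track)}, sequence has {n}"
                )
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(f"chain {self.chain_id!r}: illegal residues {sorted(bad)}")
        if not set(np.asarray(self.ss)).issubset({"H", "E", "C"}):
            raise ValueError(f"chain {self.chain_id!r}: secondary structure outside H/E/C")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_binding(self) -> int:
        return int(np.count_nonzero(self.binding_mask))


@dataclass(frozen=True)
class BindingRecord:
    chain_id: str
    ligand: str
    positions: tuple[int, ...]  # 1-based, strictly increasing


@dataclass
class AnnotationTable:
    """BioLip-style binding annotations: one row per (chain, ligand)."""

    records: list[BindingRecord] = field(default_factory=list)

    def positions_for(self, chain_id: str, ligand: str | None = None) -> set[int]:
        """Union of 1-based binding positions for a chain (optionally one ligand)."""
        out: set[int] = set()
        for rec in self.records:
            if rec.chain_id == chain_id and (ligand is None or rec.ligand == ligand):
                out.update(rec.positions)
        return out

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.chain_id, None)
        return list(seen)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (chain_id, sequence) pairs.

    Sequences are uppercased; any character outside the 20 standard one-letter
    codes is replaced by the unknown token 'X' with a logged warning.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        cleaned = _NONSTANDARD.sub("X", seq)
        n_sub = sum(a != b for a, b in zip(seq, cleaned))
        if n_sub:
            logger.warning(
                "%s: %d non-standard residue(s) in %r replaced by 'X'",
                path, n_sub, rec.id,
            )
        records.append((rec.id, cleaned))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for chain_id, seq in records:
            fh.write(f">{chain_id}\n{seq}\n")


def read_binding_annotations(path) -> AnnotationTable:
    """Read a 3-column TSV (chain_id, ligand, comma-separated 1-based positions)."""
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            chain_id, ligand, pos_field = parts
            ligand = ligand.strip().upper()
            if ligand not in VALID_LIGANDS:
                raise FormatError(
                    f"{path}:{lineno}: ligand {ligand!r} not in {sorted(VALID_LIGANDS)}"
                )
            positions: list[int] = []
            if pos_field.strip():
                for tok in pos_field.split(","):
                    try:
                        positions.append(int(tok))
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: non-integer position {tok!r}"
                        ) from None
            if any(p <= 0 for p in positions):
                raise FormatError(f"{path}:{lineno}: positions must be 1-based positive")
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise FormatError(f"{path}:{lineno}: positions must be strictly increasing")
            table.records.append(BindingRecord(chain_id, ligand, tuple(positions)))
    return table


def write_binding_annotations(path, table: AnnotationTable) -> None:
    with open(path, "w") as fh:
        for rec in table.records:
            fh.write(f"{rec.chain_id}\t{rec.ligand}\t{','.join(map(str, rec.positions))}\n")


_STRUCT_COLS = ["chain_id", "pos", "ss", "rsa", "phi", "psi"]


def read_structure_annotations(path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Read per-residue predicted-structure tracks.

    Input rows: chain_id, 1-based residue index, ss in {H,E,C}, rsa in [0,1],
    phi and psi in [-180,180].  Returns ``{chain_id: (ss, rsa, phi, psi)}``
    with contiguous 0-based arrays; a gap in residue indices is an error.
    """
    try:
        df = pd.read_csv(path, sep="\t", names=_STRUCT_COLS, header=None,
                         dtype={"chain_id": str, "ss": str},
                         keep_default_na=False, float_precision="round_trip")
        df["pos"] = df["pos"].astype(int)
        for col in ("rsa", "phi", "psi"):
            df[col] = df[col].astype(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: malformed structure table: {exc}") from None
    out = {}
    for chain_id, grp in df.groupby("chain_id", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        if pos[0] != 1 or not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise FormatError(f"{path}: chain {chain_id!r}: residue indices not contiguous from 1")
        if not set(grp["ss"]).issubset({"H", "E", "C"}):
            raise FormatError(f"{path}: chain {chain_id!r}: ss label outside H/E/C")
        rsa = grp["rsa"].to_numpy()
        if ((rsa < 0) | (rsa > 1)).any():
            raise FormatError(f"{path}: chain {chain_id!r}: rsa outside [0, 1]")
        phi = grp["phi"].to_numpy()
        psi = grp["psi"].to_numpy()
        for name, ang in (("phi", phi), ("psi", psi)):
            if ((ang < -180) | (ang > 180)).any():
                raise FormatError(f"{path}: chain {chain_id!r}: {name} outside [-180, 180]")
        out[str(chain_id)] = (grp["ss"].to_numpy(), rsa, phi, psi)
    return out


def write_structure_annotations(path, chains: Iterable[ProteinChain]) -> None:
    with open(path, "w") as fh:
        for ch in chains:
            for i in range(len(ch)):
                fh.write(
                    f"{ch.chain_id}\t{i + 1}\t{ch.ss[i]}\t{float(ch.rsa[i])!r}"
                    f"\t{float(ch.phi[i])!r}\t{float(ch.psi[i])!r}\n"
                )


def join_chains(
    sequences: Sequence[tuple[str, str]],
    annotations: AnnotationTable,
    structure: dict[str, tuple],
    ligand: str | None = None,
    min_length: int = MIN_CHAIN_LENGTH,
) -> list[ProteinChain]:
    """Assemble ProteinChain objects from the three input tables.

    1-based binding positions become a 0-based boolean mask.  Chains shorter
    than ``min_length`` residues are dropped (count logged).  A binding
    position beyond the chain length, or a structure track of the wrong
    length, is an error naming the chain.
    """
    chains = []
    n_dropped = 0
    for chain_id, seq in sequences:
        if chain_id not in structure:
            raise FormatError(f"chain {chain_id!r}: no structure annotations")
        ss, rsa, phi, psi = structure[chain_id]
        if len(ss) != len(seq):
            raise FormatError(
                f"chain {chain_id!r}: structure length {len(ss)} != sequence length {len(seq)}"
            )
        if len(seq) < min_length:
            n_dropped += 1
            continue
        mask = np.zeros(len(seq), dtype=bool)
        for pos in annotations.positions_for(chain_id, ligand):
            if pos > len(seq):
                raise FormatError(
                    f"chain {chain_id!r}: binding position {pos} beyond length {len(seq)}"
                )
            mask[pos - 1] = True
        chains.append(ProteinChain(chain_id, seq, mask,
                                   np.asarray(ss), np.asarray(rsa, dtype=float),
                                   np.asarray(phi, dtype=float), np.asarray(psi, dtype=float)))
    if n_dropped:
        logger.info("dropped %d chain(s) shorter than %d residues", n_dropped, min_length)
    return chains


def write_feature_matrix(path, vectors, labels, names: Sequence[str] | None = None) -> None:
    """Write encoded fragments as TSV: a ``label`` column then named feature columns.

    Floats are written with Python repr (shortest round-trip decimal), so
    read_feature_matrix returns bit-identical values.
    """
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    dims = {v.shape for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"ragged feature vectors: dimensions {sorted(d[0] for d in dims)}")
    d = vectors[0].shape[0] if vectors else (len(names) if names else 0)
    if names is None:
        names = [f"f{i}" for i in range(d)]
    if len(names) != d and vectors:
        raise ValueError(f"{len(names)} column names for {d}-dim vectors")
    with open(path, "w") as fh:
        fh.write("\t".join(["label", *names]) + "\n")
        for vec, lab in zip(vectors, labels):
            fh.write("\t".join([str(int(lab)), *(repr(float(x)) for x in vec)]) + "\n")


def read_feature_matrix(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a feature matrix written by :func:`write_feature_matrix`.

    Returns ``(X, y, feature_names)``.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "label":
            raise FormatError(f"{path}: missing 'label' header column")
        names = header[1:]
        rows, labels = [], []
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} columns")
            labels.append(int(parts[0]))
            rows.append([float(x) for x in parts[1:]])
    X = np.array(rows, dtype=float) if rows else np.empty((0, len(names)))
    y = np.array(labels, dtype=int)
    if not math.prod(X.shape) and rows:
        raise FormatError(f"{path}: empty matrix body")
    return X, y, names
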