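"""Readers and writers for the external formats the tool touches.

Formats supported:

* multi-record FASTA (sequences in, via Biopython),
* PSI-BLAST ASCII PSSM files (the ``-out_ascii_pssm`` dialect; only the
  first, log-odds score block is used),
* per-residue label tables and prediction tables (TSV),
* minimal PDB output for reconstructed fragments (C-alpha traces or full
  N/CA/C backbones, via biotite).

Angles that are undefined at chain termini are stored in files with the
sentinel value ``360.0`` (outside the valid (-180, 180] range) and carried
in memory as ``NaN``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

#: Column order of PSI-BLAST ASCII PSSM files (the header order of the
#: log-odds block).  All profiles in a run use this order.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Mapping of non-standard residue letters onto a standard letter used for
#: table lookups (physicochemical properties, max-ASA).  The original letter
#: is preserved in all outputs; only lookups are redirected.  B (Asx) -> D,
#: Z (Glx) -> E, X/U/O (unknown, selenocysteine, pyrrolysine) -> A.
NONSTANDARD_MAP = {"B": "D", "Z": "E", "X": "A", "U": "A", "O": "A"}

#: File sentinel for undefined (terminal) angles.
ANGLE_SENTINEL = 360.0

_SS_ALPHABET = ("C", "H", "E")


def canonical_residue(letter: str) -> str:
    """Map a residue letter to the standard letter used for table lookups."""
    letter = letter.upper()
    if letter in STANDARD_AA:
        return letter
    try:
        return NONSTANDARD_MAP[letter]
    except KeyError:
        raise ValueError(f"unrecognised residue letter {letter!r}") from None


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue structure labels.

    Label arrays, when present, have length ``len(sequence)``.  Angles are
    degrees in (-180, 180] with NaN marking undefined positions: ``phi`` of
    residue 1 and ``psi`` of residue L are undefined; ``theta`` is defined
    for residues 2..L-1 and ``tau`` for residues 2..L-2 (1-based).  ``asa``
    is in A^2, ``rasa`` in [0, 1].  ``ca_coords`` optionally carries the
    native C-alpha trace (L x 3, Angstrom) used for fragment evaluation.
    """

    id: str
    sequence: str
    ss: np.ndarray | None = None
    phi: np.ndarray | None = None
    psi: np.ndarray | None = None
    theta: np.ndarray | None = None
    tau: np.ndarray | None = None
    asa: np.ndarray | None = None
    rasa: np.ndarray | None = None
    ca_coords: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for letter in self.sequence:
            canonical_residue(letter)  # raises on junk
        L = len(self.sequence)
        for name in ("ss", "phi", "psi", "theta", "tau", "asa", "rasa"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr)
            if arr.shape != (L,):
                raise ValueError(
                    f"{self.id}: label {name!r} has length {arr.shape}, "
                    f"expected ({L},)"
                )
            setattr(self, name, arr)
        if self.rasa is not None:
            ok = np.isnan(self.rasa) | ((self.rasa >= 0) & (self.rasa <= 1))
            if not ok.all():
                raise ValueError(f"{self.id}: rASA outside [0, 1]")
        if self.ss is not None and not set(self.ss) <= set(_SS_ALPHABET):
            raise ValueError(f"{self.id}: SS labels outside {{C,H,E}}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_labels(self) -> bool:
        return all(
            getattr(self, n) is not None
            for n in ("ss", "phi", "psi", "theta", "tau", "rasa")
        )


@dataclass
class PSSMProfile:
    """An L x 20 PSI-BLAST log-odds matrix aligned to a sequence.

    Columns follow :data:`PSSM_ALPHABET` (the PSI-BLAST header order).
    """

    id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"{self.id}: PSSM must be L x 20, got {self.scores.shape}"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased.  An empty file or duplicate record ids raise
    ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(path: str | Path, sequence: str | None = None,
              id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file (first score block only).

    If ``sequence`` is given, the residue letters in the PSSM rows are
    cross-checked against it and a mismatch raises ``ValueError`` citing the
    (1-based) position.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and all(t in PSSM_ALPHABET for t in tokens[:20]):
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: no PSSM column header found")

    rows: list[list[float]] = []
    letters: list[str] = []
    for lineno, line in enumerate(lines[header_idx + 1:], header_idx + 2):
        tokens = line.split()
        if not tokens:
            break  # blank line ends the matrix block
        if not tokens[0].isdigit():
            break  # trailing statistics (K, Lambda) section
        if len(tokens) < 22:
            raise ValueError(
                f"{path}:{lineno}: truncated PSSM row "
                f"({len(tokens)} fields, expected >= 22)"
            )
        idx = int(tokens[0])
        if idx != len(rows) + 1:
            raise ValueError(
                f"{path}:{lineno}: row index {idx} out of order "
                f"(expected {len(rows) + 1})"
            )
        letters.append(tokens[1])
        rows.append([float(t) for t in tokens[2:22]])

    if not rows:
        raise ValueError(f"{path}: PSSM contains no residue rows")
    if sequence is not None:
        if len(sequence) != len(rows):
            raise ValueError(
                f"{path}: PSSM has {len(rows)} rows but sequence has "
                f"{len(sequence)} residues"
            )
        for pos, (a, b) in enumerate(zip(letters, sequence.upper()), 1):
            if a != b:
                raise ValueError(
                    f"{path}: PSSM residue {a!r} disagrees with sequence "
                    f"{b!r} at position {pos}"
                )
    return PSSMProfile(id=id or path.stem, scores=np.array(rows))


def write_pssm(profile: PSSMProfile, sequence: str, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (log-odds block only)."""
    if len(sequence) != len(profile):
        raise ValueError(
            f"{profile.id}: sequence length {len(sequence)} != "
            f"PSSM rows {len(profile)}"
        )
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("          " + "".join(f"{a:>4}" for a in PSSM_ALPHABET) + "\n")
        for i, (letter, row) in enumerate(zip(sequence, profile.scores), 1):
            cells = "".join(f"{v:4.0f}" for v in row)
            fh.write(f"{i:5d} {letter:1s}   {cells}\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# Label tables

_LABEL_COLUMNS = ("index", "AA", "SS3", "phi", "psi", "theta", "tau", "ASA",
                  "rASA")


def _angle_to_file(v: float) -> float:
    return ANGLE_SENTINEL if (v is None or math.isnan(v)) else v


def _angle_from_file(v: float) -> float:
    return math.nan if v == ANGLE_SENTINEL else v


def write_label_table(record: ProteinRecord, path: str | Path) -> None:
    """Write per-residue ground-truth labels as TSV (sentinel 360 for
    undefined angles)."""
    if not record.has_labels:
        raise ValueError(f"{record.id}: record has incomplete labels")
    with open(path, "w") as fh:
        fh.write("\t".join(_LABEL_COLUMNS) + "\n")
        for i in range(len(record)):
            asa = record.asa[i] if record.asa is not None else math.nan
            fh.write(
                f"{i + 1}\t{record.sequence[i]}\t{record.ss[i]}\t"
                f"{_angle_to_file(record.phi[i]):.3f}\t"
                f"{_angle_to_file(record.psi[i]):.3f}\t"
                f"{_angle_to_file(record.theta[i]):.3f}\t"
                f"{_angle_to_file(record.tau[i]):.3f}\t"
                f"{asa:.3f}\t{record.rasa[i]:.4f}\n"
            )


def read_label_table(path: str | Path, record: ProteinRecord) -> ProteinRecord:
    """Attach labels from a TSV label table to ``record`` (returns a new
    record)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != list(_LABEL_COLUMNS):
        raise ValueError(f"{path}: missing or malformed label header")
    n = len(lines) - 1
    if n != len(record):
        raise ValueError(
            f"{path}: {n} label rows but sequence {record.id} has "
            f"{len(record)} residues"
        )
    ss = np.empty(n, dtype="<U1")
    phi, psi, theta, tau, asa, rasa = (np.empty(n) for _ in range(6))
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(_LABEL_COLUMNS):
            raise ValueError(
                f"{path}:{lineno}: expected {len(_LABEL_COLUMNS)} columns, "
                f"got {len(parts)}"
            )
        i = int(parts[0]) - 1
        ss[i] = parts[2]
        phi[i] = _angle_from_file(float(parts[3]))
        psi[i] = _angle_from_file(float(parts[4]))
        theta[i] = _angle_from_file(float(parts[5]))
        tau[i] = _angle_from_file(float(parts[6]))
        asa[i] = float(parts[7])
        rasa[i] = float(parts[8])
    return ProteinRecord(
        id=record.id, sequence=record.sequence, ss=ss, phi=phi, psi=psi,
        theta=theta, tau=tau, asa=asa, rasa=rasa,
        ca_coords=record.ca_coords,
    )


# ---------------------------------------------------------------------------
# Prediction tables

_PRED_COLUMNS = ("index", "AA", "SS3", "P(C)", "P(H)", "P(E)", "rASA",
                 "phi", "psi", "theta", "tau")


def write_prediction_table(bundle, sequence: str, path: str | Path) -> None:
    """Write a per-residue prediction table (TSV).

    Columns: 1-based index, amino acid, predicted SS3 label, the three SS
    probabilities (order C, H, E; rows sum to 1), relative ASA and the four
    decoded angles in degrees (sentinel 360 where undefined).
    """
    L = len(sequence)
    if bundle.ss_probs.shape[0] != L:
        raise ValueError(
            f"bundle length {bundle.ss_probs.shape[0]} != sequence length {L}"
        )
    with open(path, "w") as fh:
        fh.write("\t".join(_PRED_COLUMNS) + "\n")
        for i in range(L):
            pc, ph, pe = bundle.ss_probs[i]
            fh.write(
                f"{i + 1}\t{sequence[i]}\t{bundle.ss_label[i]}\t"
                f"{pc:.4f}\t{ph:.4f}\t{pe:.4f}\t{bundle.rasa[i]:.4f}\t"
                f"{_angle_to_file(bundle.phi[i]):.2f}\t"
                f"{_angle_to_file(bundle.psi[i]):.2f}\t"
                f"{_angle_to_file(bundle.theta[i]):.2f}\t"
                f"{_angle_to_file(bundle.tau[i]):.2f}\n"
            )


def read_prediction_table(path: str | Path) -> dict:
    """Read a prediction table back into plain arrays.

    Returns a dict with keys ``sequence, ss_label, ss_probs, rasa, phi, psi,
    theta, tau``.  A row with the wrong column count raises ``ValueError``
    with the line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != list(_PRED_COLUMNS):
        raise ValueError(f"{path}: missing or malformed prediction header")
    seq: list[str] = []
    ss: list[str] = []
    probs: list[list[float]] = []
    rasa: list[float] = []
    angles: dict[str, list[float]] = {k: [] for k in ("phi", "psi", "theta",
                                                      "tau")}
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(_PRED_COLUMNS):
            raise ValueError(
                f"{path}:{lineno}: expected {len(_PRED_COLUMNS)} columns, "
                f"got {len(parts)}"
            )
        seq.append(parts[1])
        ss.append(parts[2])
        probs.append([float(parts[3]), float(parts[4]), float(parts[5])])
        rasa.append(float(parts[6]))
        for k, p in zip(("phi", "psi", "theta", "tau"), parts[7:11]):
            angles[k].append(_angle_from_file(float(p)))
    return {
        "sequence": "".join(seq),
        "ss_label": np.array(ss),
        "ss_probs": np.array(probs),
        "rasa": np.array(rasa),
        **{k: np.array(v) for k, v in angles.items()},
    }


# ---------------------------------------------------------------------------
# PDB fragments


def write_fragment_pdb(coords: np.ndarray, path: str | Path,
                       sequence: str | None = None,
                       atom_names: Sequence[str] | None = None) -> None:
    """Write a coordinate set as a minimal PDB file (ATOM records, chain A).

    ``coords`` is N x 3.  By default every atom is a C-alpha of its own
    residue; pass ``atom_names`` (cycled over residues, e.g. ("N", "CA",
    "C")) for full backbones.  NaN coordinates raise ``ValueError``.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coords must be N x 3, got {coords.shape}")
    if np.isnan(coords).any():
        raise ValueError("coords contain NaN")
    n = coords.shape[0]
    names = list(atom_names) if atom_names else ["CA"]
    per_res = len(names)
    if n % per_res:
        raise ValueError(f"{n} atoms do not divide into {per_res} per residue")
    n_res = n // per_res

    three = {a: b for a, b in zip(
        "ACDEFGHIKLMNPQRSTVWY",
        ["ALA", "CYS", "ASP", "GLU", "PHE", "GLY", "HIS", "ILE", "LYS",
         "LEU", "MET", "ASN", "PRO", "GLN", "ARG", "SER", "THR", "VAL",
         "TRP", "TYR"])}
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.repeat(np.arange(1, n_res + 1), per_res)
    atoms.atom_name = np.tile(np.array(names), n_res)
    if sequence is not None and len(sequence) == n_res:
        atoms.res_name = np.repeat(
            np.array([three.get(canonical_residue(a), "ALA")
                      for a in sequence]), per_res)
    else:
        atoms.res_name = np.full(n, "ALA")
    atoms.element = np.array([nm[0] for nm in atoms.atom_name])
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def load_corpus(fasta_path: str | Path, pssm_dir: str | Path,
                labels_dir: str | Path | None = None,
                ) -> list[tuple[ProteinRecord, PSSMProfile]]:
    """Load a corpus from disk: a multi-record FASTA, a directory of
    ``<id>.pssm`` profiles and (optionally) a directory of ``<id>.tsv``
    label tables."""
    pssm_dir = Path(pssm_dir)
    records = read_fasta(fasta_path)
    corpus = []
    for rec in records:
        prof = read_pssm(pssm_dir / f"{rec.id}.pssm", sequence=rec.sequence,
                         id=rec.id)
        if labels_dir is not None:
            rec = read_label_table(Path(labels_dir) / f"{rec.id}.tsv", rec)
        corpus.append((rec, prof))
    return corpus


def read_fragment_pdb(path: str | Path) -> np.ndarray:
    """Read coordinates back from a fragment PDB (all ATOM records)."""
    from biotite.structure.io.pdb import PDBFile

    return PDBFile.read(str(path)).get_structure(model=1).coord
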