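"""Synthetic protein corpora with geometrically self-consistent labels.

The generator emulates everything the training pipeline needs, with no
external data: per-protein secondary-structure segments, sequences whose
residue composition is coupled to the local structure class, torsion
angles drawn around textbook Ramachandran centers per class, backbones
built from those torsions (so the C-alpha angles theta/tau and the trace
coordinates are mutually consistent by construction), a burial-proxy
solvent accessibility, and mock PSSM profiles that carry a residue
one-hot signal plus a structure-class leak.

It stands in for a curated experimental corpus; it makes no claim of
evolutionary or loop-geometry realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import geometry as geom
from .io_formats import (PSSM_ALPHABET, ProteinRecord, PSSMProfile,
                         write_fasta, write_label_table, write_pssm)
from .pipeline import asa_from_rasa

#: Residues favoured by each structure class (classic propensity lists:
#: helix formers, beta-branched/aromatic sheet formers, turn/coil formers).
CLASS_PREFERRED = {
    "H": "AELMQKRH",
    "E": "VIYCWFT",
    "C": "GPSDN",
}

#: Canonical (phi, psi) centers per class, degrees: ideal alpha-helix,
#: antiparallel beta-strand, and a broad polyproline-ish coil basin.
ANGLE_MEANS = {"H": (-57.0, -47.0), "E": (-120.0, 130.0),
               "C": (-80.0, 120.0)}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic corpus.

    ``coupling`` in [0, 1] sets how strongly residue identity follows the
    structure class (1 = always drawn from the class-preferred set);
    ``pssm_noise`` is the s.d. of the integer-rounded Gaussian noise on
    the mock log-odds scores, against a one-hot signal of ``pssm_scale``
    and a class leak of ``leak_scale``.
    """

    n_proteins: int = 200
    length_range: tuple[int, int] = (30, 70)
    segment_length: dict = field(default_factory=lambda: {
        "H": (4, 14), "E": (3, 8), "C": (2, 7)})
    angle_sigma: dict = field(default_factory=lambda: {
        "H": (8.0, 8.0), "E": (15.0, 15.0), "C": (40.0, 60.0)})
    coupling: float = 0.6
    pssm_scale: float = 7.0
    leak_scale: float = 2.0
    pssm_noise: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if any(s < 0 for pair in self.angle_sigma.values() for s in pair):
            raise ValueError("angle sigmas must be non-negative")
        if self.length_range[0] < 17:
            raise ValueError(
                "minimum protein length must cover one 17-residue window")
        if self.pssm_noise < 0:
            raise ValueError("pssm_noise must be non-negative")


def _wrap(deg: np.ndarray) -> np.ndarray:
    """Wrap degrees into (-180, 180]."""
    out = (np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(out == -180.0, 180.0, out)


def _sample_ss(L: int, cfg: SyntheticConfig, rng: np.random.Generator,
               ) -> np.ndarray:
    """Alternate coil and structured (H or E) segments until L residues."""
    classes: list[str] = []
    structured_next = bool(rng.integers(2))
    while len(classes) < L:
        cls = rng.choice(["H", "E"]) if structured_next else "C"
        lo, hi = cfg.segment_length[cls]
        classes.extend(cls * int(rng.integers(lo, hi + 1)))
        structured_next = not structured_next
    return np.array(classes[:L])


def _sample_sequence(ss: np.ndarray, cfg: SyntheticConfig,
                     rng: np.random.Generator) -> str:
    letters = []
    for cls in ss:
        if rng.random() < cfg.coupling:
            letters.append(rng.choice(list(CLASS_PREFERRED[cls])))
        else:
            letters.append(rng.choice(list(PSSM_ALPHABET)))
    return "".join(letters)


def _sample_angles(ss: np.ndarray, cfg: SyntheticConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    L = len(ss)
    phi = np.empty(L)
    psi = np.empty(L)
    for cls in ("H", "E", "C"):
        sel = ss == cls
        mp, ms = ANGLE_MEANS[cls]
        sp, ssig = cfg.angle_sigma[cls]
        phi[sel] = rng.normal(mp, sp, sel.sum())
        psi[sel] = rng.normal(ms, ssig, sel.sum())
    return _wrap(phi), _wrap(psi)


def _class_leak(cls: str, cfg: SyntheticConfig) -> np.ndarray:
    """A 20-vector over the PSSM alphabet marking the class-preferred
    residues (centered so the leak has zero mean)."""
    pref = np.array([a in CLASS_PREFERRED[cls] for a in PSSM_ALPHABET],
                    dtype=float)
    return cfg.leak_scale * (pref - pref.mean())


def _mock_pssm(sequence: str, ss: np.ndarray, cfg: SyntheticConfig,
               rng: np.random.Generator) -> np.ndarray:
    L = len(sequence)
    scores = np.zeros((L, 20))
    col = {a: k for k, a in enumerate(PSSM_ALPHABET)}
    for i, (aa, cls) in enumerate(zip(sequence, ss)):
        scores[i, col[aa]] += cfg.pssm_scale
        scores[i] += _class_leak(cls, cfg)
    if cfg.pssm_noise > 0:
        scores += rng.normal(0.0, cfg.pssm_noise, scores.shape)
    return np.clip(np.rint(scores), -13, 13)


def generate_protein(pid: str, L: int, cfg: SyntheticConfig,
                     rng: np.random.Generator,
                     ) -> tuple[ProteinRecord, PSSMProfile]:
    ss = _sample_ss(L, cfg, rng)
    sequence = _sample_sequence(ss, cfg, rng)
    phi, psi = _sample_angles(ss, cfg, rng)

    backbone = geom.build_backbone_from_torsions(phi, psi)
    ca = geom.ca_from_backbone(backbone)
    theta_c, tau_c = geom.compute_theta_tau(ca)
    theta = np.full(L, np.nan)
    tau = np.full(L, np.nan)
    theta[1:L - 1] = theta_c
    tau[1:L - 2] = tau_c
    phi = phi.copy()
    psi = psi.copy()
    phi[0] = np.nan
    psi[-1] = np.nan

    # burial proxy: residues far from the C-alpha centroid are "exposed"
    d = np.linalg.norm(ca - ca.mean(axis=0), axis=1)
    span = d.max() - d.min()
    rasa = (d - d.min()) / span if span > 0 else np.full(L, 0.5)
    asa = asa_from_rasa(rasa, sequence)

    record = ProteinRecord(id=pid, sequence=sequence, ss=ss, phi=phi,
                           psi=psi, theta=theta, tau=tau, asa=asa,
                           rasa=rasa, ca_coords=ca)
    profile = PSSMProfile(id=pid, scores=_mock_pssm(sequence, ss, cfg, rng))
    return record, profile


def generate_corpus(config: SyntheticConfig | None = None,
                    ) -> list[tuple[ProteinRecord, PSSMProfile]]:
    """Generate the full corpus deterministically from ``config.seed``."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    corpus = []
    for k in range(cfg.n_proteins):
        L = int(rng.integers(lo, hi + 1))
        corpus.append(generate_protein(f"synth{k:04d}", L, cfg, rng))
    return corpus


def corrupt_labels(corpus, rate: float, seed: int = 0,
                   angle_sigma: float = 30.0):
    """Stress-test helper: resample SS labels (uniformly over C/H/E) and
    jitter defined angles by wrapped Gaussian noise at the given rate.

    Geometry-derived coordinates are left untouched, so corrupted labels
    are deliberately *inconsistent* with the stored trace.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for rec, prof in corpus:
        L = len(rec)
        ss = rec.ss.copy()
        hit = rng.random(L) < rate
        ss[hit] = rng.choice(["C", "H", "E"], hit.sum())
        angles = {}
        for name in ("phi", "psi", "theta", "tau"):
            a = getattr(rec, name).copy()
            hit = (rng.random(L) < rate) & ~np.isnan(a)
            a[hit] = _wrap(a[hit] + rng.normal(0, angle_sigma, hit.sum()))
            angles[name] = a
        out.append((replace_labels(rec, ss=ss, **angles), prof))
    return out


def replace_labels(rec: ProteinRecord, **kwargs) -> ProteinRecord:
    fields = dict(id=rec.id, sequence=rec.sequence, ss=rec.ss, phi=rec.phi,
                  psi=rec.psi, theta=rec.theta, tau=rec.tau, asa=rec.asa,
                  rasa=rec.rasa, ca_coords=rec.ca_coords)
    fields.update(kwargs)
    return ProteinRecord(**fields)


def write_corpus(corpus, out_dir: str | Path) -> None:
    """Write a corpus in the package's file dialects: one FASTA, one
    PSI-BLAST-style PSSM per protein (``pssm/<id>.pssm``) and one label
    table per protein (``labels/<id>.tsv``)."""
    out = Path(out_dir)
    (out / "pssm").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    write_fasta([rec for rec, _ in corpus], out / "proteins.fasta")
    for rec, prof in corpus:
        write_pssm(prof, rec.sequence, out / "pssm" / f"{rec.id}.pssm")
        write_label_table(rec, out / "labels" / f"{rec.id}.tsv")
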