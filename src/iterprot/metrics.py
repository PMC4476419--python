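"""Evaluation statistics: Q3, periodicity-aware angle MAE, Pearson
correlation for solvent accessibility, two-state angle accuracy, the
3x3 secondary-structure confusion matrix, and a per-amino-acid accuracy
table.

Unless noted otherwise, statistics are pooled over residues across the
whole corpus (residue-weighted), not averaged per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SS_CLASSES = ("C", "H", "E")

#: Two-state boundaries: state 1 is phi in [0, 150) degrees and psi in
#: [-100, 60) degrees; state 0 is the rest of the circle.  Intervals are
#: closed on the left, open on the right.
TWO_STATE_BOUNDS = {"phi": (0.0, 150.0), "psi": (-100.0, 60.0)}


def _check_ss(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    bad = set(labels) - set(SS_CLASSES)
    if bad:
        raise ValueError(f"secondary-structure labels outside {{C,H,E}}: "
                         f"{sorted(bad)}")
    return labels


def q3(true_ss: np.ndarray, pred_ss: np.ndarray) -> float:
    """Fraction of residues whose 3-state label is predicted correctly."""
    true_ss = _check_ss(true_ss)
    pred_ss = _check_ss(pred_ss)
    if true_ss.shape != pred_ss.shape:
        raise ValueError("label arrays differ in length")
    if true_ss.size == 0:
        raise ValueError("empty label arrays")
    return float(np.mean(true_ss == pred_ss))


def periodic_mae(true_deg: np.ndarray, pred_deg: np.ndarray,
                 mask: np.ndarray | None = None) -> float:
    """Mean absolute angular error honouring 360-degree wrap-around.

    Each difference d contributes min(|d|, 360 - |d|).  ``mask`` selects
    the positions included (defined angles); an all-false mask raises.
    NaNs in either array are excluded automatically.
    """
    t = np.asarray(true_deg, dtype=float)
    p = np.asarray(pred_deg, dtype=float)
    if t.shape != p.shape:
        raise ValueError("angle arrays differ in length")
    valid = ~(np.isnan(t) | np.isnan(p))
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if not valid.any():
        raise ValueError("no defined angle pairs to average")
    d = np.abs((t[valid] - p[valid]) % 360.0)
    return float(np.mean(np.minimum(d, 360.0 - d)))


def two_state_bin(angles_deg: np.ndarray, which: str) -> np.ndarray:
    """Map angles to the two-state bins (1 inside [lo, hi), 0 otherwise)."""
    if which not in TWO_STATE_BOUNDS:
        raise ValueError(f"which must be 'phi' or 'psi', got {which!r}")
    lo, hi = TWO_STATE_BOUNDS[which]
    a = np.asarray(angles_deg, dtype=float)
    return ((a >= lo) & (a < hi)).astype(int)


def two_state_angle_accuracy(true_deg: np.ndarray, pred_deg: np.ndarray,
                             which: str,
                             mask: np.ndarray | None = None) -> float:
    """Fraction of residues whose predicted angle falls in the same
    two-state bin as the true angle."""
    t = np.asarray(true_deg, dtype=float)
    p = np.asarray(pred_deg, dtype=float)
    valid = ~(np.isnan(t) | np.isnan(p))
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if not valid.any():
        raise ValueError("no defined angle pairs")
    return float(np.mean(two_state_bin(t[valid], which)
                         == two_state_bin(p[valid], which)))


def misclassification_matrix(true_ss: np.ndarray, pred_ss: np.ndarray,
                             ) -> pd.DataFrame:
    """3x3 count matrix: rows are true classes (C, H, E), columns predicted."""
    true_ss = _check_ss(true_ss)
    pred_ss = _check_ss(pred_ss)
    if true_ss.shape != pred_ss.shape:
        raise ValueError("label arrays differ in length")
    counts = np.zeros((3, 3), dtype=int)
    ix = {c: k for k, c in enumerate(SS_CLASSES)}
    for t, p in zip(true_ss, pred_ss):
        counts[ix[t], ix[p]] += 1
    return pd.DataFrame(counts, index=list(SS_CLASSES),
                        columns=list(SS_CLASSES))


def per_class_accuracy(confusion: pd.DataFrame) -> dict[str, float]:
    """Diagonal / row-sum per true class (NaN for an absent class)."""
    out = {}
    for c in SS_CLASSES:
        row = confusion.loc[c].sum()
        out[c] = float(confusion.loc[c, c] / row) if row else float("nan")
    return out


def pairwise_confusion_rates(confusion: pd.DataFrame) -> dict[str, float]:
    """Symmetric misclassification rates between class pairs (H<->E,
    H<->C, E<->C), each normalized by the total residues of the pair."""
    rates = {}
    for a, b in (("H", "E"), ("H", "C"), ("E", "C")):
        mixed = confusion.loc[a, b] + confusion.loc[b, a]
        total = confusion.loc[a].sum() + confusion.loc[b].sum()
        rates[f"{a}<->{b}"] = float(mixed / total) if total else float("nan")
    return rates


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient; constant input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length arrays with n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def per_aa_accuracy_table(sequences: list[str], true_ss: list[np.ndarray],
                          pred_ss: list[np.ndarray]) -> pd.DataFrame:
    """Per-amino-acid secondary-structure accuracy.

    One row per amino-acid letter (sorted), with columns ``abundance``
    (residue count), ``frequency`` (% of all residues) and ``accuracy``
    (% correct), plus a trailing ``Overall`` row.
    """
    aa_all, ok_all = [], []
    for seq, t, p in zip(sequences, true_ss, pred_ss):
        aa_all.extend(seq)
        ok_all.extend(np.asarray(t) == np.asarray(p))
    df = pd.DataFrame({"AA": aa_all, "ok": ok_all})
    total = len(df)
    g = df.groupby("AA")["ok"]
    table = pd.DataFrame({
        "abundance": g.size(),
        "frequency": 100.0 * g.size() / total,
        "accuracy": 100.0 * g.mean(),
    }).sort_index()
    table.loc["Overall"] = [total, 100.0, 100.0 * df["ok"].mean()]
    table["abundance"] = table["abundance"].astype(int)
    return table


@dataclass
class EvaluationReport:
    """All corpus-level statistics for one prediction round."""

    q3: float
    mae: dict[str, float]                 # per-angle periodic MAE, degrees
    asa_cc: float                         # raw ASA (A^2) correlation
    rasa_cc: float
    rasa_mae: float
    two_state_phi: float
    two_state_psi: float
    confusion: pd.DataFrame
    per_class: dict[str, float]
    per_aa: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "q3": self.q3,
            "mae_phi": self.mae["phi"],
            "mae_psi": self.mae["psi"],
            "mae_theta": self.mae["theta"],
            "mae_tau": self.mae["tau"],
            "asa_cc": self.asa_cc,
            "rasa_cc": self.rasa_cc,
            "rasa_mae": self.rasa_mae,
            "two_state_phi": self.two_state_phi,
            "two_state_psi": self.two_state_psi,
            "per_class_accuracy": self.per_class,
            "confusion": self.confusion.values.tolist(),
        }


def evaluate_corpus(records, bundles, max_asa_lookup=None) -> EvaluationReport:
    """Score a list of prediction bundles against labelled records.

    ``records`` carry the ground truth (see ``ProteinRecord``); ``bundles``
    are the matching predictions.  Raw-ASA correlation uses each record's
    stored ASA and the bundle's rASA scaled back to A^2 via
    ``max_asa_lookup`` (defaults to the pipeline's max-ASA table).
    """
    if max_asa_lookup is None:
        from .pipeline import asa_from_rasa
        max_asa_lookup = asa_from_rasa

    true_ss = np.concatenate([r.ss for r in records])
    pred_ss = np.concatenate([b.ss_label for b in bundles])
    mae = {}
    two_state = {}
    for name in ("phi", "psi", "theta", "tau"):
        t = np.concatenate([getattr(r, name) for r in records])
        p = np.concatenate([getattr(b, name) for b in bundles])
        mae[name] = periodic_mae(t, p)
        if name in ("phi", "psi"):
            two_state[name] = two_state_angle_accuracy(t, p, name)
    true_rasa = np.concatenate([r.rasa for r in records])
    pred_rasa = np.concatenate([b.rasa for b in bundles])
    true_asa = np.concatenate([r.asa for r in records])
    pred_asa = np.concatenate([
        max_asa_lookup(b.rasa, r.sequence)
        for r, b in zip(records, bundles)])
    confusion = misclassification_matrix(true_ss, pred_ss)
    return EvaluationReport(
        q3=q3(true_ss, pred_ss),
        mae=mae,
        asa_cc=pearson_cc(true_asa, pred_asa),
        rasa_cc=pearson_cc(true_rasa, pred_rasa),
        rasa_mae=float(np.mean(np.abs(true_rasa - pred_rasa))),
        two_state_phi=two_state["phi"],
        two_state_psi=two_state["psi"],
        confusion=confusion,
        per_class=per_class_accuracy(confusion),
        per_aa=per_aa_accuracy_table(
            [r.sequence for r in records],
            [r.ss for r in records],
            [b.ss_label for b in bundles]),
    )
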