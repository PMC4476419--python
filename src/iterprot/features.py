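"""Per-residue input features: evolutionary profile + physicochemical
properties, windowed over 17 residues, optionally augmented with the
previous iteration's predictions.

Each residue's input vector concatenates the feature rows of a 17-residue
window (8 on each side).  At chain termini the terminal residue's entire
feature row is repeated to fill the window.  Iteration 1 uses 27 features
per window position (20 PSSM log-odds + 7 physicochemical properties),
giving 17 x 27 = 459 inputs; later iterations append the previous round's
3 secondary-structure probabilities, 1 relative ASA and 8 angle sin/cos
channels for 17 x 39 = 663 inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import PSSMProfile, canonical_residue

#: Window half-width; the full window is ``2 * WINDOW_HALF + 1 = 17``.
WINDOW_HALF = 8

#: Seven physicochemical properties per amino acid, in the order: steric
#: parameter (graph shape index), hydrophobicity, volume, polarizability,
#: isoelectric point, helix probability, sheet probability.  Values from
#: Meiler et al., J Mol Model 7:360-369 (2001).
PP_TABLE: dict[str, tuple[float, ...]] = {
    "A": (1.28, 0.31, 1.00, 0.05, 6.11, 0.42, 0.23),
    "C": (1.77, 1.54, 2.43, 0.13, 6.35, 0.17, 0.41),
    "D": (1.60, -0.77, 2.78, 0.11, 2.95, 0.25, 0.20),
    "E": (1.56, -0.64, 3.78, 0.15, 3.09, 0.42, 0.21),
    "F": (2.94, 1.79, 5.89, 0.29, 5.67, 0.30, 0.38),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07, 0.13, 0.15),
    "H": (2.99, 0.13, 4.66, 0.23, 7.69, 0.27, 0.30),
    "I": (4.19, 1.80, 4.00, 0.19, 6.04, 0.30, 0.45),
    "K": (1.89, -0.99, 4.77, 0.22, 9.99, 0.32, 0.27),
    "L": (2.59, 1.70, 4.00, 0.19, 6.04, 0.39, 0.31),
    "M": (2.35, 1.23, 4.43, 0.22, 5.71, 0.38, 0.32),
    "N": (1.60, -0.60, 2.95, 0.13, 6.52, 0.21, 0.22),
    "P": (2.67, 0.72, 2.72, 0.00, 6.80, 0.13, 0.34),
    "Q": (1.56, -0.22, 3.95, 0.18, 5.65, 0.36, 0.25),
    "R": (2.34, -1.01, 6.13, 0.29, 10.74, 0.36, 0.25),
    "S": (1.31, -0.04, 1.60, 0.06, 5.70, 0.20, 0.28),
    "T": (3.03, 0.26, 2.60, 0.11, 5.60, 0.21, 0.36),
    "V": (3.67, 1.22, 3.00, 0.14, 6.02, 0.27, 0.49),
    "W": (3.21, 2.25, 8.08, 0.41, 5.94, 0.32, 0.42),
    "Y": (2.94, 0.96, 6.47, 0.30, 5.66, 0.25, 0.41),
}

#: Per-window-position feature counts.
N_PSSM = 20
N_PP = 7
N_BASE = N_PSSM + N_PP          # iteration 1
N_FEEDBACK = 3 + 1 + 8          # SS probs + rASA + angle channels
DIM_ITER1 = 17 * N_BASE         # 459
DIM_LATER = 17 * (N_BASE + N_FEEDBACK)  # 663

#: Prediction groups that can be fed back into later iterations, with their
#: per-residue widths.
FEEDBACK_WIDTHS = {"ss": 3, "asa": 1, "angles": 8}


@dataclass
class FeatureMatrix:
    """Windowed per-residue input vectors for one protein and iteration."""

    X: np.ndarray          # L x D
    iteration: int

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")

    @property
    def dim(self) -> int:
        return self.X.shape[1]


def pp_features(sequence: str) -> np.ndarray:
    """L x 7 physicochemical property matrix for a sequence.

    Non-standard letters use the documented canonical mapping.
    """
    return np.array([PP_TABLE[canonical_residue(a)] for a in sequence])


def normalize_features(raw: np.ndarray,
                       params: tuple[np.ndarray, np.ndarray] | None = None,
                       ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Min-max scale each feature column to [0, 1].

    With ``params=None`` the column minima/maxima are fit on ``raw`` (the
    training set) and returned for reuse; otherwise the given ``(mins,
    maxs)`` are applied and values outside the training range are clipped to
    [0, 1].  A zero-range column maps to the constant 0.5.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("non-finite values in feature matrix")
    if params is None:
        mins = raw.min(axis=0)
        maxs = raw.max(axis=0)
    else:
        mins, maxs = params
        if mins.shape[0] != raw.shape[1]:
            raise ValueError(
                f"normalization params have {mins.shape[0]} columns, "
                f"matrix has {raw.shape[1]}"
            )
    span = maxs - mins
    out = np.empty_like(raw)
    flat = span == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, ~flat] = (raw[:, ~flat] - mins[~flat]) / span[~flat]
    out[:, flat] = 0.5
    np.clip(out, 0.0, 1.0, out=out)
    return out, (mins, maxs)


def window_features(per_residue: np.ndarray, i: int,
                    w: int = WINDOW_HALF) -> np.ndarray:
    """Flat feature vector for residue ``i`` (0-based): the concatenated
    rows of the window ``i-w .. i+w``, with the terminal residue's entire
    row repeated beyond the chain ends."""
    L = per_residue.shape[0]
    if not 0 <= i < L:
        raise IndexError(f"residue index {i} out of range for length {L}")
    idx = np.clip(np.arange(i - w, i + w + 1), 0, L - 1)
    return per_residue[idx].ravel()


def window_all(per_residue: np.ndarray, w: int = WINDOW_HALF) -> np.ndarray:
    """Windowed vectors for every residue at once (L x (2w+1)*d)."""
    L, d = per_residue.shape
    idx = np.clip(np.arange(L)[:, None] + np.arange(-w, w + 1)[None, :],
                  0, L - 1)
    return per_residue[idx].reshape(L, (2 * w + 1) * d)


def assemble_iteration_features(
    pssm: PSSMProfile,
    pp: np.ndarray,
    prev_predictions=None,
    iteration: int | None = None,
    feedback_groups: tuple[str, ...] = ("ss", "asa", "angles"),
) -> FeatureMatrix:
    """Build the raw (un-normalized) windowed feature matrix for one
    iteration.

    ``prev_predictions`` must be ``None`` for iteration 1 and a complete
    prediction bundle for later iterations; the bundle's angle channels are
    the sin/cos encodings, never raw degrees, and masked (terminal) channels
    carry 0.  ``iteration`` may be given explicitly to enforce the contract
    (a bundle supplied for iteration 1 is an error, never silently ignored).
    """
    if iteration is None:
        iteration = 1 if prev_predictions is None else 2
    if iteration == 1 and prev_predictions is not None:
        raise ValueError("iteration 1 takes no previous predictions")
    if iteration >= 2 and prev_predictions is None:
        raise ValueError(f"iteration {iteration} requires a prediction bundle")
    L = len(pssm)
    if pp.shape != (L, N_PP):
        raise ValueError(f"PP matrix shape {pp.shape}, expected ({L}, {N_PP})")
    base = np.hstack([pssm.scores, pp])
    if prev_predictions is None:
        return FeatureMatrix(X=window_all(base), iteration=1)

    blocks = [base]
    for group in feedback_groups:
        if group == "ss":
            arr = getattr(prev_predictions, "ss_probs", None)
        elif group == "asa":
            arr = getattr(prev_predictions, "rasa", None)
            arr = arr if arr is None else arr.reshape(-1, 1)
        elif group == "angles":
            arr = getattr(prev_predictions, "angle_channels", None)
            if arr is not None:
                mask = getattr(prev_predictions, "angle_mask", None)
                if mask is not None:
                    arr = np.where(mask, arr, 0.0)
        else:
            raise ValueError(f"unknown feedback group {group!r}")
        if arr is None:
            raise ValueError(
                f"previous-iteration bundle is missing the {group!r} "
                f"prediction group"
            )
        if arr.shape[0] != L:
            raise ValueError(
                f"feedback group {group!r} has {arr.shape[0]} rows, "
                f"expected {L}"
            )
        blocks.append(arr)
    per_residue = np.hstack(blocks)
    return FeatureMatrix(X=window_all(per_residue), iteration=iteration)


def expected_dim(iteration: int,
                 feedback_groups: tuple[str, ...] = ("ss", "asa", "angles"),
                 ) -> int:
    """Exact input dimension for an iteration under a feedback configuration."""
    if iteration <= 1:
        return DIM_ITER1
    extra = sum(FEEDBACK_WIDTHS[g] for g in feedback_groups)
    return 17 * (N_BASE + extra)
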