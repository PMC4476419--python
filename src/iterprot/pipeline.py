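"""The parallel multi-step iterative predictor.

Each iteration trains three independent networks — secondary structure
(3 outputs, classes C/H/E), relative solvent accessibility (1 output) and
backbone angles (8 outputs: the sin/cos channels of theta, tau, phi, psi)
— on windowed profile + physicochemical features.  From iteration 2
onward every predictor additionally receives the previous iteration's
predictions of *all three* tasks as input features, so each structural
property is refined in the light of the others.  Three iterations are the
default; the feedback can be restricted (e.g. secondary structure only)
for ablation experiments.

Angles are regressed as sine/cosine pairs to remove the 360-degree
periodicity and decoded with the two-argument arctangent,
alpha = atan2(sin alpha, cos alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np

from . import features as feat
from . import network as net
from .io_formats import PSSMProfile, ProteinRecord, canonical_residue

#: Fixed channel order of the angle head.
ANGLE_CHANNEL_ORDER = ("sin_theta", "cos_theta", "sin_tau", "cos_tau",
                       "sin_phi", "cos_phi", "sin_psi", "cos_psi")

#: Angle name per channel pair, in channel order.
_ANGLE_NAMES = ("theta", "tau", "phi", "psi")

#: Sigmoid-range affine target window for the [-1, 1] sin/cos channels:
#: channel v maps to TARGET_LO + (TARGET_HI - TARGET_LO) * (v + 1) / 2.
TARGET_LO = 0.1
TARGET_HI = 0.9

SS_ORDER = ("C", "H", "E")

#: Theoretical maximum solvent accessible surface area per residue type,
#: in A^2 (Tien et al., PLoS ONE 8:e80635, 2013).  Used to normalize ASA
#: to relative ASA in [0, 1].
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


# ---------------------------------------------------------------------------
# Angle codec


def angle_definedness(L: int) -> np.ndarray:
    """L x 8 boolean mask of structurally defined angle channels.

    1-based conventions: phi undefined for residue 1, psi for residue L,
    theta defined for residues 2..L-1, tau for residues 2..L-2.
    """
    theta = np.zeros(L, bool)
    theta[1:L - 1] = True
    tau = np.zeros(L, bool)
    tau[1:L - 2] = True
    phi = np.zeros(L, bool)
    phi[1:] = True
    psi = np.zeros(L, bool)
    psi[:L - 1] = True
    per_angle = {"theta": theta, "tau": tau, "phi": phi, "psi": psi}
    return np.stack([per_angle[n] for n in _ANGLE_NAMES
                     for _ in range(2)], axis=1)


def encode_angles(phi: np.ndarray, psi: np.ndarray, theta: np.ndarray,
                  tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Encode degree arrays as the L x 8 sin/cos channel matrix + mask.

    Channel order is (sin theta, cos theta, sin tau, cos tau, sin phi,
    cos phi, sin psi, cos psi).  NaN (undefined) positions carry 0 in both
    channels and False in the mask.
    """
    arrays = {"theta": theta, "tau": tau, "phi": phi, "psi": psi}
    L = len(phi)
    channels = np.zeros((L, 8))
    mask = np.zeros((L, 8), bool)
    for k, name in enumerate(_ANGLE_NAMES):
        a = np.asarray(arrays[name], dtype=float)
        ok = ~np.isnan(a)
        rad = np.radians(np.where(ok, a, 0.0))
        channels[:, 2 * k] = np.where(ok, np.sin(rad), 0.0)
        channels[:, 2 * k + 1] = np.where(ok, np.cos(rad), 0.0)
        mask[:, 2 * k] = ok
        mask[:, 2 * k + 1] = ok
    return channels, mask


def decode_angle(s, c):
    """Quadrant-correct decode of (sin, cos) to degrees in (-180, 180].

    Scale-invariant (any positive common factor on s and c is irrelevant).
    (0, 0) decodes to NaN — the masked/undefined marker.
    """
    s = np.asarray(s, dtype=float)
    c = np.asarray(c, dtype=float)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(s, c))
    ang = np.where((s == 0) & (c == 0), np.nan, ang)
    ang = np.where(ang <= -180.0, 180.0, ang)
    return float(ang) if ang.ndim == 0 else ang


def decode_channels(channels: np.ndarray, mask: np.ndarray | None = None,
                    ) -> dict[str, np.ndarray]:
    """Decode an L x 8 channel matrix to degree arrays (NaN where masked)."""
    out = {}
    for k, name in enumerate(_ANGLE_NAMES):
        a = decode_angle(channels[:, 2 * k], channels[:, 2 * k + 1])
        if mask is not None:
            a = np.where(mask[:, 2 * k], a, np.nan)
        out[name] = a
    return out


# ---------------------------------------------------------------------------
# ASA normalization


def rasa_from_asa(asa, residues: str) -> np.ndarray:
    """Relative ASA = ASA / max-ASA(residue type), clipped to [0, 1].

    ``residues`` is a sequence string matched elementwise (a single letter
    broadcasts).  Non-standard letters use the canonical lookup mapping.
    """
    asa = np.atleast_1d(np.asarray(asa, dtype=float))
    if (asa < 0).any():
        raise ValueError("ASA must be non-negative")
    if len(residues) == 1:
        residues = residues * asa.shape[0]
    mx = np.array([MAX_ASA[canonical_residue(a)] for a in residues])
    return np.clip(asa / mx, 0.0, 1.0)


def asa_from_rasa(rasa, residues: str) -> np.ndarray:
    """Inverse of :func:`rasa_from_asa` (within the clipping range)."""
    rasa = np.atleast_1d(np.asarray(rasa, dtype=float))
    if len(residues) == 1:
        residues = residues * rasa.shape[0]
    mx = np.array([MAX_ASA[canonical_residue(a)] for a in residues])
    return np.clip(rasa, 0.0, 1.0) * mx


# ---------------------------------------------------------------------------
# Bundles and model containers


@dataclass
class PredictionBundle:
    """Per-residue predictions of one iteration for one protein."""

    ss_probs: np.ndarray        # L x 3, order C, H, E; rows sum to 1
    ss_label: np.ndarray        # argmax letters
    rasa: np.ndarray            # in [0, 1]
    angle_channels: np.ndarray  # L x 8 sin/cos, in [-1, 1]
    angle_mask: np.ndarray      # L x 8 bool (structural definedness)
    phi: np.ndarray             # decoded degrees, NaN where masked
    psi: np.ndarray
    theta: np.ndarray
    tau: np.ndarray
    iteration: int = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the whole iterative scheme."""

    n_iterations: int = 3
    network: net.NetworkConfig = field(default_factory=net.NetworkConfig)
    feedback_groups: tuple[str, ...] = ("ss", "asa", "angles")
    seed: int = 0
    oof_folds: int = 0   # >1: out-of-fold feedback features during training

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        unknown = set(self.feedback_groups) - set(feat.FEEDBACK_WIDTHS)
        if unknown:
            raise ValueError(f"unknown feedback groups {sorted(unknown)}")


@dataclass
class IterativeModel:
    """The trained model: one (ss, asa, angles) network triple per
    iteration plus that iteration's feature-normalization parameters."""

    iterations: list[dict[str, net.TrainedNetwork]]
    norm_params: list[tuple[np.ndarray, np.ndarray]]
    config: PipelineConfig

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


def derived_seed(seed: int, *key: int) -> int:
    """Deterministic per-component seed fan-out from one run seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Feature/target assembly helpers


def _base_rows(record: ProteinRecord, profile: PSSMProfile) -> np.ndarray:
    return np.hstack([profile.scores, feat.pp_features(record.sequence)])


def _raw_features(records, profiles, bundles, iteration, groups):
    """Stacked raw windowed features for the whole corpus."""
    mats = []
    for j, (rec, prof) in enumerate(zip(records, profiles)):
        prev = None if iteration == 1 else bundles[j]
        fm = feat.assemble_iteration_features(
            prof, feat.pp_features(rec.sequence), prev,
            iteration=iteration, feedback_groups=groups)
        expected = feat.expected_dim(iteration, groups)
        if fm.dim != expected:
            raise AssertionError(
                f"iteration {iteration}: feature dim {fm.dim} != {expected}")
        mats.append(fm.X)
    return np.vstack(mats)


def _targets(records):
    """Stacked supervised targets: SS one-hot, rASA, scaled angle channels
    (+ mask)."""
    ss_rows, rasa_rows, ang_rows, mask_rows = [], [], [], []
    for rec in records:
        onehot = np.zeros((len(rec), 3))
        for k, cls in enumerate(SS_ORDER):
            onehot[:, k] = rec.ss == cls
        ss_rows.append(onehot)
        rasa_rows.append(rec.rasa.reshape(-1, 1))
        channels, mask = encode_angles(rec.phi, rec.psi, rec.theta, rec.tau)
        ang_rows.append(TARGET_LO + (TARGET_HI - TARGET_LO)
                        * (channels + 1.0) / 2.0)
        mask_rows.append(mask)
    return (np.vstack(ss_rows), np.vstack(rasa_rows),
            np.vstack(ang_rows), np.vstack(mask_rows))


def _heads_to_bundles(nets, Xn, records, iteration):
    """Run the three heads on normalized features and split into
    per-protein bundles."""
    ss_out = net.predict(nets["ss"], Xn)
    rasa_out = net.predict(nets["asa"], Xn)
    ang_out = net.predict(nets["angles"], Xn)
    channels_all = np.clip(
        (ang_out - TARGET_LO) / (TARGET_HI - TARGET_LO) * 2.0 - 1.0,
        -1.0, 1.0)
    bundles = []
    start = 0
    for rec in records:
        L = len(rec)
        sl = slice(start, start + L)
        start += L
        probs = ss_out[sl]
        probs = probs / probs.sum(axis=1, keepdims=True)
        label = np.array([SS_ORDER[k] for k in np.argmax(probs, axis=1)])
        mask = angle_definedness(L)
        channels = np.where(mask, channels_all[sl], 0.0)
        angles = decode_channels(channels, mask)
        bundles.append(PredictionBundle(
            ss_probs=probs, ss_label=label,
            rasa=np.clip(rasa_out[sl, 0], 0.0, 1.0),
            angle_channels=channels, angle_mask=mask,
            iteration=iteration, **angles))
    return bundles


def _train_heads(Xn, targets, config: PipelineConfig, iteration: int,
                 ) -> dict[str, net.TrainedNetwork]:
    ss_t, rasa_t, ang_t, ang_mask = targets
    heads = {}
    for h, (name, Y, mask) in enumerate(
            (("ss", ss_t, None), ("asa", rasa_t, None),
             ("angles", ang_t, ang_mask))):
        cfg = replace(config.network,
                      seed=derived_seed(config.seed, iteration, h))
        heads[name] = net.train_network(Xn, Y, cfg, mask=mask)
    return heads


# ---------------------------------------------------------------------------
# Training and prediction


def _check_training_inputs(records, profiles):
    if not records:
        raise ValueError("no training proteins given")
    if len(records) != len(profiles):
        raise ValueError("records and profiles differ in count")
    for rec, prof in zip(records, profiles):
        if len(prof) != len(rec):
            raise ValueError(
                f"{rec.id}: profile has {len(prof)} rows for "
                f"{len(rec)} residues")
        for group in ("ss", "phi", "psi", "theta", "tau", "rasa"):
            if getattr(rec, group) is None:
                raise ValueError(
                    f"{rec.id}: missing required label group {group!r}")


def train_iterative(records: list[ProteinRecord],
                    profiles: list[PSSMProfile],
                    config: PipelineConfig | None = None,
                    base_model: IterativeModel | None = None,
                    ) -> IterativeModel:
    """Train the full iterative model.

    Iteration 1 trains the three predictors on profile + physicochemical
    features alone; each later iteration k first predicts the training
    corpus with the iteration-(k-1) networks and appends those predictions
    to the inputs.  With ``config.oof_folds > 1`` the feedback features are
    instead produced out-of-fold by fold-held-out copies of the previous
    iteration's networks (guards against feedback overfitting).

    ``base_model`` optionally donates its iteration-1 networks (and
    normalization), so feedback ablations can share the same first round.
    """
    config = config or PipelineConfig()
    _check_training_inputs(records, profiles)

    iterations: list[dict[str, net.TrainedNetwork]] = []
    norm_params: list[tuple[np.ndarray, np.ndarray]] = []
    targets = _targets(records)
    bundles = None

    for it in range(1, config.n_iterations + 1):
        raw = _raw_features(records, profiles, bundles, it,
                            config.feedback_groups)
        if it == 1 and base_model is not None:
            heads = base_model.iterations[0]
            params = base_model.norm_params[0]
            Xn, _ = feat.normalize_features(raw, params)
        else:
            Xn, params = feat.normalize_features(raw)
            heads = _train_heads(Xn, targets, config, it)
        iterations.append(heads)
        norm_params.append(params)

        if it == config.n_iterations:
            break
        if config.oof_folds > 1:
            bundles = _oof_bundles(records, profiles, targets, config, it,
                                   bundles)
        else:
            bundles = _heads_to_bundles(heads, Xn, records, it)
    return IterativeModel(iterations=iterations, norm_params=norm_params,
                          config=config)


def _oof_bundles(records, profiles, targets, config, iteration,
                 prev_bundles):
    """Out-of-fold feedback: each protein's feedback features come from
    networks trained without its fold."""
    k = config.oof_folds
    fold_of = np.arange(len(records)) % k
    bundles: list = [None] * len(records)
    for f in range(k):
        tr = [i for i in range(len(records)) if fold_of[i] != f]
        te = [i for i in range(len(records)) if fold_of[i] == f]
        if not te:
            continue
        raw_tr = _raw_features([records[i] for i in tr],
                               [profiles[i] for i in tr],
                               None if prev_bundles is None
                               else [prev_bundles[i] for i in tr],
                               iteration, config.feedback_groups)
        Xn_tr, params = feat.normalize_features(raw_tr)
        t = _targets([records[i] for i in tr])
        fold_cfg = replace(config, seed=derived_seed(config.seed, 900 + f))
        heads = _train_heads(Xn_tr, t, fold_cfg, iteration)
        raw_te = _raw_features([records[i] for i in te],
                               [profiles[i] for i in te],
                               None if prev_bundles is None
                               else [prev_bundles[i] for i in te],
                               iteration, config.feedback_groups)
        Xn_te, _ = feat.normalize_features(raw_te, params)
        for i, b in zip(te, _heads_to_bundles(
                heads, Xn_te, [records[i] for i in te], iteration)):
            bundles[i] = b
    return bundles


def predict_iterative(model: IterativeModel, record: ProteinRecord,
                      profile: PSSMProfile) -> list[PredictionBundle]:
    """Predict one protein, returning the bundle of every iteration (the
    last entry is the final prediction)."""
    if len(profile) != len(record):
        raise ValueError(
            f"{record.id}: profile has {len(profile)} rows for "
            f"{len(record)} residues")
    bundles: list[PredictionBundle] = []
    prev = None
    for it, (heads, params) in enumerate(
            zip(model.iterations, model.norm_params), 1):
        fm = feat.assemble_iteration_features(
            profile, feat.pp_features(record.sequence), prev,
            iteration=it, feedback_groups=model.config.feedback_groups)
        expected = feat.expected_dim(it, model.config.feedback_groups)
        if fm.dim != expected or heads["ss"].input_dim != expected:
            raise ValueError(
                f"iteration {it}: feature dim {fm.dim} does not match "
                f"checkpoint input dim {heads['ss'].input_dim}")
        Xn, _ = feat.normalize_features(fm.X, params)
        prev = _heads_to_bundles(heads, Xn, [record], it)[0]
        bundles.append(prev)
    return bundles


def predict_corpus(model: IterativeModel, records, profiles,
                   iteration: int | None = None):
    """Final-iteration (or given-iteration) bundles for a list of proteins."""
    it = model.n_iterations if iteration is None else iteration
    return [predict_iterative(model, r, p)[it - 1]
            for r, p in zip(records, profiles)]


# ---------------------------------------------------------------------------
# Persistence

_CHECKPOINT_VERSION = 1


def save_model(model: IterativeModel, path: str | Path) -> None:
    """Serialize the model (weights, configs, normalization) to one file."""
    payload = {
        "version": _CHECKPOINT_VERSION,
        "pipeline_config": model.config,
        "target_scaling": (TARGET_LO, TARGET_HI),
        "norm_params": model.norm_params,
        "iterations": [
            {name: {"weights": n.weights, "config": n.config,
                    "input_dim": n.input_dim, "output_dim": n.output_dim}
             for name, n in heads.items()}
            for heads in model.iterations],
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> IterativeModel:
    payload = joblib.load(path)
    if payload.get("version") != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version in {path}")
    iterations = [
        {name: net.TrainedNetwork(weights=d["weights"], config=d["config"],
                                  input_dim=d["input_dim"],
                                  output_dim=d["output_dim"])
         for name, d in heads.items()}
        for heads in payload["iterations"]]
    return IterativeModel(iterations=iterations,
                          norm_params=payload["norm_params"],
                          config=payload["pipeline_config"])
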