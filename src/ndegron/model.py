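"""Gradient-boosted sequence-to-stability model over one-hot P1-P5 features.

A motif is encoded as a 100-column binary vector (5 positions x 20 residues,
position-major blocks with residues in canonical alphabetical order within
each block); together with its PSI label this forms the n x 101 training
matrix.  An XGBoost regression-tree ensemble maps the encoding to predicted
PSI (pPSI), reported clamped to the attainable [1, 4] range.  Per-feature
attributions use the ensemble's exact additive tree-path decomposition
(TreeSHAP), whose baseline-plus-contributions sum reproduces the raw
prediction to numerical precision.

Default hyperparameters: 986 trees of depth 11, learning rate 0.085,
subsample 0.904, colsample_bytree 0.810, squared-error objective, with a
minimum read-count filter of 20 and an 80/20 train/validation split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import mean_squared_error, r2_score

from .genetics import AA_ALPHABET, validate_motif
from .psi import MotifDatabase

PSI_MIN, PSI_MAX = 1.0, 4.0

#: Frozen feature-column order: position-major, residue-alphabetical.
FEATURE_COLUMNS = tuple(f"P{p}_{aa}" for p in range(1, 6) for aa in AA_ALPHABET)
N_FEATURES = len(FEATURE_COLUMNS)  # 100

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass
class ModelConfig:
    """Training configuration; hyperparameter defaults are the tuned values."""

    min_reads: int = 20
    split_fraction: float = 0.8
    split_seed: int = 0
    n_estimators: int = 986
    max_depth: int = 11
    learning_rate: float = 0.085
    subsample: float = 0.904
    colsample_bytree: float = 0.810
    objective: str = "reg:squarederror"
    tree_method: str = "hist"
    training_seed: int = 0
    n_jobs: int = 0  # 0 -> xgboost default (all available cores)


@dataclass
class EncodedDataset:
    """One-hot features (n x 100, rows sum to 5) with PSI labels."""

    features: np.ndarray
    labels: np.ndarray
    motifs: list[str]

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass
class TrainReport:
    n_train: int
    n_val: int
    rmse_val: float
    r2_val: float
    config: dict = field(default_factory=dict)

    def __str__(self) -> str:
        return (
            f"trained on {self.n_train} motifs, validated on {self.n_val}: "
            f"RMSE {self.rmse_val:.3f}, R^2 {self.r2_val:.3f}"
        )


@dataclass
class Attribution:
    """Additive per-feature attribution for one motif: ``baseline +
    sum(contributions)`` equals the raw (unclamped) prediction."""

    motif: str
    baseline: float
    contributions: np.ndarray  # length 100, FEATURE_COLUMNS order
    prediction: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.contributions, index=list(FEATURE_COLUMNS), name=self.motif)


@dataclass
class StabilityModel:
    """A trained ensemble plus the metadata needed to use it safely."""

    booster: xgb.Booster
    config: ModelConfig
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS
    report: TrainReport | None = None


def encode(motifs, labels=None) -> EncodedDataset:
    """One-hot encode motifs (and optional PSI labels) into an
    :class:`EncodedDataset`.  Rejects nonstandard residues."""
    motifs = list(motifs)
    features = np.zeros((len(motifs), N_FEATURES), dtype=np.uint8)
    for row, motif in enumerate(motifs):
        validate_motif(motif)
        for p, aa in enumerate(motif):
            features[row, 20 * p + _AA_INDEX[aa]] = 1
    if labels is None:
        labels = np.full(len(motifs), np.nan)
    return EncodedDataset(
        features=features, labels=np.asarray(labels, dtype=float), motifs=motifs
    )


def decode(features: np.ndarray) -> list[str]:
    """Inverse of :func:`encode` for valid one-hot rows."""
    features = np.asarray(features)
    out = []
    for row in features:
        residues = []
        for p in range(5):
            block = row[20 * p : 20 * (p + 1)]
            (active,) = np.nonzero(block)
            if active.size != 1:
                raise ValueError("row is not a valid one-hot motif encoding")
            residues.append(AA_ALPHABET[active[0]])
        out.append("".join(residues))
    return out


def prepare_training(
    db: MotifDatabase, config: ModelConfig | None = None
) -> tuple[EncodedDataset, EncodedDataset]:
    """Filter by minimum read count, encode, and split into disjoint,
    exhaustive train/validation sets by a seeded shuffle."""
    config = config or ModelConfig()
    records = db.records.loc[db.records["total"] >= config.min_reads]
    if len(records) == 0:
        raise ValueError(
            f"no motifs pass the min_reads={config.min_reads} filter"
        )
    data = encode(records["motif"], records["psi"].to_numpy())
    rng = np.random.default_rng(config.split_seed)
    order = rng.permutation(len(data))
    n_train = int(round(config.split_fraction * len(data)))
    train_idx, val_idx = order[:n_train], order[n_train:]

    def take(idx) -> EncodedDataset:
        return EncodedDataset(
            features=data.features[idx],
            labels=data.labels[idx],
            motifs=[data.motifs[i] for i in idx],
        )

    return take(train_idx), take(val_idx)


def train(
    train_data: EncodedDataset,
    val_data: EncodedDataset,
    config: ModelConfig | None = None,
) -> StabilityModel:
    """Fit the gradient-boosted ensemble and evaluate on the validation
    split.  With (near-)constant validation labels R^2 is undefined and
    reported as NaN with a warning."""
    config = config or ModelConfig()
    regressor = xgb.XGBRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        subsample=config.subsample,
        colsample_bytree=config.colsample_bytree,
        objective=config.objective,
        tree_method=config.tree_method,
        random_state=config.training_seed,
        **({"n_jobs": config.n_jobs} if config.n_jobs else {}),
    )
    regressor.fit(train_data.features, train_data.labels)
    booster = regressor.get_booster()
    pred_val = booster.inplace_predict(val_data.features)
    rmse = float(np.sqrt(mean_squared_error(val_data.labels, pred_val)))
    if np.std(val_data.labels) == 0:
        warnings.warn("validation labels are constant; R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = float(r2_score(val_data.labels, pred_val))
    report = TrainReport(
        n_train=len(train_data), n_val=len(val_data), rmse_val=rmse, r2_val=r2,
        config=asdict(config),
    )
    return StabilityModel(booster=booster, config=config, report=report)


def predict(model: StabilityModel, motifs) -> pd.Series:
    """Predicted PSI per motif, clamped to [1, 4]."""
    data = encode(motifs)
    raw = model.booster.inplace_predict(data.features)
    return pd.Series(
        np.clip(raw.astype(float), PSI_MIN, PSI_MAX), index=data.motifs, name="ppsi"
    )


def predict_raw(model: StabilityModel, motifs) -> np.ndarray:
    """Unclamped ensemble output (the quantity attributions sum to)."""
    return model.booster.inplace_predict(encode(motifs).features).astype(float)


def sample_motifs(
    rng: np.random.Generator, n: int, weighting: str = "uniform"
) -> list[str]:
    """Random 5-residue motifs, uniform over amino acids by default or with
    ``weighting='nnk'`` proportional to NNK codon multiplicities."""
    alphabet = np.array(list(AA_ALPHABET))
    if weighting == "uniform":
        p = None
    elif weighting == "nnk":
        from .genetics import AA_TO_NNK_CODONS

        mult = np.array([len(AA_TO_NNK_CODONS[aa]) for aa in AA_ALPHABET], dtype=float)
        p = mult / mult.sum()
    else:
        raise ValueError("weighting must be 'uniform' or 'nnk'")
    draws = rng.choice(alphabet, size=(n, 5), p=p)
    return ["".join(row) for row in draws]


def enumerate_constrained(constraint: dict[int, str]) -> list[str]:
    """Every motif satisfying ``constraint`` (position -> required residue),
    in lexicographic order.  The unconstrained space is 20^5; callers should
    constrain or sample instead of enumerating it blindly."""
    pools = [
        [constraint[p]] if p in constraint else list(AA_ALPHABET)
        for p in range(1, 6)
    ]
    out: list[str] = []

    def rec(prefix: str, depth: int) -> None:
        if depth == 5:
            out.append(prefix)
            return
        for aa in pools[depth]:
            rec(prefix + aa, depth + 1)

    rec("", 0)
    return out


def select_candidates(
    model: StabilityModel,
    constraint,
    direction: str,
    threshold: float,
    k: int,
    candidates=None,
    rng: np.random.Generator | None = None,
    n_sample: int = 100_000,
) -> pd.Series:
    """Top ``k`` motifs from a constrained space, ranked by predicted PSI.

    ``constraint`` is either a dict (position -> residue, enumerated
    exhaustively) or a callable predicate applied to sampled/supplied
    candidates.  ``direction`` is ``'stable'`` (descending pPSI, keep
    pPSI > threshold) or ``'unstable'`` (ascending, keep pPSI < threshold).
    Ties break lexicographically; if fewer than ``k`` motifs pass, all
    passing motifs are returned with a warning.
    """
    if direction not in ("stable", "unstable"):
        raise ValueError("direction must be 'stable' or 'unstable'")
    if candidates is None:
        if isinstance(constraint, dict):
            candidates = enumerate_constrained(constraint)
        else:
            rng = rng or np.random.default_rng(0)
            candidates = [m for m in sample_motifs(rng, n_sample) if constraint(m)]
    elif isinstance(constraint, dict):
        candidates = [
            m for m in candidates
            if all(m[p - 1] == aa for p, aa in constraint.items())
        ]
    else:
        candidates = [m for m in candidates if constraint(m)]
    candidates = sorted(set(candidates))
    ppsi = predict(model, candidates)
    if direction == "stable":
        passing = ppsi[ppsi > threshold].sort_values(
            ascending=False, kind="mergesort"
        )
    else:
        passing = ppsi[ppsi < threshold].sort_values(kind="mergesort")
    if len(passing) < k:
        warnings.warn(
            f"only {len(passing)} motifs pass the threshold (requested {k})",
            stacklevel=2,
        )
    return passing.head(k)


def attribute(model: StabilityModel, motif: str) -> Attribution:
    """Exact additive tree-path attribution (TreeSHAP) for one motif."""
    data = encode([motif])
    dmat = xgb.DMatrix(data.features)
    contribs = model.booster.predict(dmat, pred_contribs=True)[0]
    baseline = float(contribs[-1])
    contributions = contribs[:-1].astype(float)
    return Attribution(
        motif=motif,
        baseline=baseline,
        contributions=contributions,
        prediction=baseline + float(contributions.sum()),
    )


def mean_attributions(model: StabilityModel, motifs) -> pd.DataFrame:
    """Mean attribution of each feature over the motifs that carry it.

    Returns a DataFrame indexed by feature column with ``mean_contribution``
    and ``n_active`` (motifs carrying the feature).
    """
    data = encode(motifs)
    dmat = xgb.DMatrix(data.features)
    contribs = model.booster.predict(dmat, pred_contribs=True)
    active = data.features.astype(bool)
    n_active = active.sum(axis=0)
    sums = np.where(active, contribs[:, :-1], 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(n_active > 0, sums / np.maximum(n_active, 1), np.nan)
    return pd.DataFrame(
        {"mean_contribution": means, "n_active": n_active},
        index=list(FEATURE_COLUMNS),
    )


# ---------------------------------------------------------------------------
# persistence


def save_model(model: StabilityModel, path: str | Path) -> None:
    """Serialise the ensemble (UBJSON) plus a JSON sidecar with the config,
    the frozen feature-column order, and the training report."""
    path = Path(path)
    model.booster.save_model(str(path))
    sidecar = {
        "feature_columns": list(model.feature_columns),
        "config": asdict(model.config),
        "report": asdict(model.report) if model.report else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> StabilityModel:
    path = Path(path)
    booster = xgb.Booster()
    booster.load_model(str(path))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if tuple(sidecar["feature_columns"]) != FEATURE_COLUMNS:
        raise ValueError("model artifact was trained with a different column order")
    config = ModelConfig(**sidecar["config"])
    report = TrainReport(**sidecar["report"]) if sidecar.get("report") else None
    return StabilityModel(booster=booster, config=config, report=report)
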