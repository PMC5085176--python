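"""Random-forest classification of encoded peptide windows.

The forest itself is delegated to scikit-learn behind a thin seam; the
bespoke parts — coupling-model encoding, class balancing, cross-validation
— stay library-agnostic.  A window's score is the forest's positive-class
vote fraction; the call is positive when the score reaches the decision
threshold.

The self-consistency principle is enforced throughout: a K-centered query
may only be scored by a predictor trained on K-centered samples, and
likewise for P, R and T.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from carbonsite.coupling import CouplingModel, encode_many, fit_coupling_model
from carbonsite.errors import SelfConsistencyError
from carbonsite.seq_io import PredictionRecord, ProteinRecord
from carbonsite.windows import PeptideWindow, SampleSet, WindowConfig, extract_windows

BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters.

    500 trees with sqrt-of-features splits is the customary default for
    random forests on low-dimensional tabular features; the decision
    threshold 0.5 calls a site when at least half the trees vote positive.
    """

    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError(
                f"decision_threshold must be in (0, 1), "
                f"got {self.decision_threshold}"
            )


@dataclass
class TrainedPredictor:
    """A coupling model plus a fitted forest for one center type."""

    coupling_model: CouplingModel
    forest: RandomForestClassifier
    rf_config: RFConfig
    center_type: str
    metadata: dict = field(default_factory=dict)


def train(train_set: SampleSet, config: RFConfig | None = None,
          alpha: float = 0.0,
          fallback_policy: str = "marginal") -> TrainedPredictor:
    """Fit the coupling model and the forest on a training sample set.

    Class balance is the caller's responsibility (the cross-validation
    driver expands positives before calling in here); both classes must be
    present.  Deterministic for a fixed seed.
    """
    config = config or RFConfig()
    if not train_set.positives or not train_set.negatives:
        raise ValueError(
            "training requires both positive and negative samples "
            f"(got {train_set.n_positive} positive, "
            f"{train_set.n_negative} negative)"
        )
    model = fit_coupling_model(train_set, alpha=alpha,
                               fallback_policy=fallback_policy)
    windows = list(train_set.positives) + list(train_set.negatives)
    X = encode_many(windows, model)
    y = np.array([1] * train_set.n_positive + [0] * train_set.n_negative)
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    metadata = {
        "n_positive": train_set.n_positive,
        "n_negative": train_set.n_negative,
        "n_synthetic": sum(w.synthetic for w in train_set.positives),
        "seed": config.seed,
        "trained_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return TrainedPredictor(coupling_model=model, forest=forest,
                            rf_config=config,
                            center_type=train_set.center_type,
                            metadata=metadata)


def score_windows(predictor: TrainedPredictor,
                  windows: Sequence[PeptideWindow]
                  ) -> list[tuple[PeptideWindow, float]]:
    """Score windows with the matching predictor; order preserved."""
    for w in windows:
        if w.center_type != predictor.center_type:
            raise SelfConsistencyError(
                f"self-consistency violated: a {w.center_type}-centered "
                f"window ({w.protein_id}:{w.center_position}) cannot be "
                f"scored by the {predictor.center_type}-trained predictor"
            )
    if not windows:
        return []
    X = encode_many(windows, predictor.coupling_model)
    positive_col = list(predictor.forest.classes_).index(1)
    scores = predictor.forest.predict_proba(X)[:, positive_col]
    return list(zip(windows, scores.tolist()))


def predict_protein(predictors: Mapping[str, TrainedPredictor],
                    protein: ProteinRecord,
                    config: WindowConfig | None = None,
                    residue_types: Sequence[str] | None = None
                    ) -> list[PredictionRecord]:
    """Scan a protein and score every candidate residue of the requested
    types, each with its own residue-specific predictor."""
    requested = list(residue_types) if residue_types else sorted(predictors)
    records: list[PredictionRecord] = []
    for center in requested:
        predictor = predictors.get(center)
        if predictor is None:
            raise SelfConsistencyError(
                f"no trained predictor available for center residue "
                f"{center!r}"
            )
        xi = predictor.coupling_model.xi
        wc = WindowConfig(
            xi=xi,
            center_type=center,
            identity_threshold=(config.identity_threshold if config else 0.30),
            filter_enabled=False,
        )
        windows = extract_windows(protein, wc)
        threshold = predictor.rf_config.decision_threshold
        for window, score in score_windows(predictor, windows):
            call = (PredictionRecord.POSITIVE_CALL if score >= threshold
                    else PredictionRecord.NEGATIVE_CALL)
            records.append(
                PredictionRecord(
                    protein_id=protein.id,
                    position=window.center_position,
                    residue=center,
                    score=score,
                    call=call,
                )
            )
    records.sort(key=lambda r: (r.protein_id, r.position))
    return records


def save_bundle(predictor: TrainedPredictor, directory: str | Path) -> None:
    """Persist a predictor as a directory bundle.

    Layout: coupling_model.json (portable, diffable), forest.joblib (the
    fitted scikit-learn forest) and metadata.json (format version, config,
    training metadata).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    predictor.coupling_model.to_json(directory / "coupling_model.json")
    joblib.dump(predictor.forest, directory / "forest.joblib")
    meta = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "center_type": predictor.center_type,
        "rf_config": asdict(predictor.rf_config),
        "metadata": predictor.metadata,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_bundle(directory: str | Path) -> TrainedPredictor:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    if meta.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model-bundle format version "
            f"{meta.get('format_version')!r} (expected {BUNDLE_FORMAT_VERSION})"
        )
    coupling = CouplingModel.from_json(directory / "coupling_model.json")
    forest = joblib.load(directory / "forest.joblib")
    return TrainedPredictor(
        coupling_model=coupling,
        forest=forest,
        rf_config=RFConfig(**meta["rf_config"]),
        center_type=meta["center_type"],
        metadata=meta.get("metadata", {}),
    )
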