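"""Random-forest baselines on fingerprint matrices and masking attributions.

Model naming follows the convention ``RF_Morgan`` for the ligand-only model
and ``RF_PLEC_n`` for a protein-ligand contact fingerprint model with
distance cutoff ``n`` Å.  Attribution uses atom masking: the importance of
atom *i* is ``s_i = score(m) - score(m \\ i)``, the drop in the forest's
active-class probability when the atom is replaced by a typeless dummy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score

from synthscreen.fingerprints import (
    FeaturizerConfig,
    mask_atom,
    morgan_fingerprint,
    plec_fingerprint,
)
from synthscreen.synth_generator import SyntheticComplex

logger = logging.getLogger(__name__)

#: default forest hyperparameters (not externally prescribed; exposed here)
DEFAULT_RF_PARAMS = {
    "n_estimators": 500,
    "max_features": "sqrt",
    "max_depth": None,
    "n_jobs": 1,
}


@dataclass
class TrainedModel:
    classifier: RandomForestClassifier
    tag: str  # "morgan" | "plec"
    featurizer: FeaturizerConfig
    seed: int

    @property
    def name(self) -> str:
        if self.tag == "morgan":
            return "RF_Morgan"
        return f"RF_PLEC_{self.featurizer.plec_cutoff:g}"

    def predict_score(self, X) -> np.ndarray:
        """Active-class probability in [0, 1] for each row."""
        proba = self.classifier.predict_proba(X)
        active_col = list(self.classifier.classes_).index(1)
        return proba[:, active_col]


def _featurize(cmplx: SyntheticComplex, tag: str, config: FeaturizerConfig):
    if tag == "morgan":
        return morgan_fingerprint(cmplx.ligand, config)
    if tag == "plec":
        return plec_fingerprint(cmplx, config)
    raise ValueError(f"unknown featurizer tag {tag!r}")


def _stack(fps, n_bits: int) -> sparse.csr_matrix:
    indptr = np.zeros(len(fps) + 1, dtype=np.int64)
    cols = []
    for i, fp in enumerate(fps):
        cols.append(fp.indices)
        indptr[i + 1] = indptr[i] + len(fp.indices)
    data = np.ones(int(indptr[-1]), dtype=np.float32)
    col_idx = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64)
    return sparse.csr_matrix((data, col_idx, indptr), shape=(len(fps), n_bits))


def build_dataset(
    complexes: list[SyntheticComplex], tag: str, config: FeaturizerConfig
) -> tuple[sparse.csr_matrix, np.ndarray, list[str]]:
    """Featurize complexes into a sparse matrix, 0/1 labels and an id list.

    Complexes that fail featurization are skipped with a warning; row order
    otherwise matches input order.
    """
    if not complexes:
        raise ValueError("empty complex list")
    rules = {c.rule for c in complexes}
    if len(rules) > 1:
        raise ValueError(f"complexes mix rules: {sorted(rules)}")
    fps, labels, ids = [], [], []
    for cmplx in complexes:
        try:
            fps.append(_featurize(cmplx, tag, config))
        except Exception:
            logger.warning("featurization failed for complex %s; skipped", cmplx.id)
            continue
        labels.append(1 if cmplx.is_active else 0)
        ids.append(cmplx.id)
    if not fps:
        raise ValueError("no complexes could be featurized")
    n_bits = fps[0].n_bits
    return _stack(fps, n_bits), np.array(labels, dtype=int), ids


def train_random_forest(
    X,
    y,
    tag: str,
    featurizer: FeaturizerConfig,
    seed: int = 0,
    hyper: dict | None = None,
) -> TrainedModel:
    """Fit a seeded random forest; identical inputs give identical models."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    params = dict(DEFAULT_RF_PARAMS)
    if hyper:
        params.update(hyper)
    clf = RandomForestClassifier(random_state=int(seed), **params)
    clf.fit(X, y)
    return TrainedModel(classifier=clf, tag=tag, featurizer=featurizer, seed=int(seed))


def evaluate_classifier(
    model: TrainedModel, X_test, y_test, seed: int = 0
) -> dict[str, float]:
    """Accuracy, AU-PRC, the majority-label baseline and balanced variants.

    Accuracy thresholds the forest's active-class probability at 0.5.
    ``random_accuracy`` is what labelling everything with the most common
    class would score.  Balanced variants are computed on a seeded
    label-balanced resample of the test set (majority class down-sampled).
    """
    y_test = np.asarray(y_test)
    if len(np.unique(y_test)) < 2:
        raise ValueError("AU-PRC undefined: test labels contain a single class")
    scores = model.predict_score(X_test)
    pred = (scores >= 0.5).astype(int)
    frac_active = y_test.mean()
    out = {
        "accuracy": float((pred == y_test).mean()),
        "au_prc": float(average_precision_score(y_test, scores)),
        "random_accuracy": float(max(frac_active, 1 - frac_active)),
    }
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y_test == 1)
    neg = np.flatnonzero(y_test == 0)
    k = min(len(pos), len(neg))
    idx = np.concatenate(
        [
            rng.choice(pos, size=k, replace=False),
            rng.choice(neg, size=k, replace=False),
        ]
    )
    out["balanced_accuracy"] = float((pred[idx] == y_test[idx]).mean())
    out["balanced_au_prc"] = float(average_precision_score(y_test[idx], scores[idx]))
    return out


def save_model(model: TrainedModel, prefix) -> None:
    """Persist a trained model (joblib) with a JSON metadata sidecar."""
    import json
    from dataclasses import asdict

    import joblib

    joblib.dump(model.classifier, f"{prefix}.joblib")
    meta = {
        "name": model.name,
        "tag": model.tag,
        "seed": model.seed,
        "featurizer": asdict(model.featurizer),
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(prefix) -> TrainedModel:
    """Invert :func:`save_model`."""
    import json

    import joblib

    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    return TrainedModel(
        classifier=joblib.load(f"{prefix}.joblib"),
        tag=meta["tag"],
        featurizer=FeaturizerConfig(**meta["featurizer"]),
        seed=meta["seed"],
    )


@dataclass
class AttributionScores:
    """Per-heavy-atom masking scores ``s_i`` plus the unmasked model score."""

    scores: np.ndarray
    base_score: float
    complex_id: str = ""

    def __len__(self) -> int:
        return len(self.scores)


def masking_attributions(
    model: TrainedModel, featurizer: FeaturizerConfig, cmplx: SyntheticComplex
) -> AttributionScores:
    """Per-atom attributions ``s_i = score(m) - score(m \\ i)``.

    Higher ``s_i`` means the model's active-class confidence relies more on
    atom *i*.  All masked variants are featurized and scored in one batch.
    """
    n_atoms = cmplx.ligand.mol.GetNumAtoms()
    fps = [_featurize(cmplx, model.tag, featurizer)]
    for i in range(n_atoms):
        fps.append(_featurize(mask_atom(cmplx, i), model.tag, featurizer))
    X = _stack(fps, fps[0].n_bits)
    scores = model.predict_score(X)
    base = float(scores[0])
    return AttributionScores(
        scores=base - scores[1:], base_score=base, complex_id=cmplx.id
    )
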