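"""Hierarchical cell-type classification.

A cascade of five classifiers sorts each cell at increasingly fine
distinctions: (1) neuron / non-neuron / error, (2) non-neuronal subclass,
(3) excitatory / inhibitory, (4) excitatory subclass, (5) inhibitory
subclass.  Models 1-4 consume nucleus + soma features; model 5 additionally
consumes the 120-D postsynaptic-shape histogram.  Objects predicted as
errors are excluded from all further routing.  Each level's classifier is
chosen by a randomized search over several model families with stratified
k-fold cross-validation, selected by accuracy and then F1.

After inhibitory routing, cells that separate as excitatory-like in the
PSS-augmented feature space (spiny proximal dendrites) are re-routed through
the excitatory subclass model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score, precision_recall_fscore_support
from sklearn.model_selection import ParameterSampler, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_COLUMNS

# ---------------------------------------------------------------------------
# taxonomy

ERROR_LABEL = "error"
NON_NEURONAL_SUBCLASSES = ("astrocyte", "microglia", "oligodendrocyte", "OPC",
                           "pericyte")
EXCITATORY_SUBCLASSES = ("23P", "4P", "5P-IT", "5P-ET", "5P-NP", "6P-IT", "6P-CT")
INHIBITORY_SUBCLASSES = ("BC", "BPC", "MC", "NGC")


@dataclass(frozen=True)
class Taxonomy:
    """Routing graph of the cascade: every leaf has exactly one root path."""

    non_neuronal: tuple = NON_NEURONAL_SUBCLASSES
    excitatory: tuple = EXCITATORY_SUBCLASSES
    inhibitory: tuple = INHIBITORY_SUBCLASSES

    @property
    def leaves(self) -> tuple:
        return self.non_neuronal + self.excitatory + self.inhibitory + (ERROR_LABEL,)

    def level1(self, leaf: str) -> str:
        if leaf == ERROR_LABEL:
            return ERROR_LABEL
        if leaf in self.non_neuronal:
            return "non-neuron"
        if leaf in self.excitatory or leaf in self.inhibitory:
            return "neuron"
        raise KeyError(f"label {leaf!r} outside the taxonomy")

    def neuron_class(self, leaf: str) -> str:
        if leaf in self.excitatory:
            return "excitatory"
        if leaf in self.inhibitory:
            return "inhibitory"
        raise KeyError(f"label {leaf!r} is not neuronal")

    def path(self, leaf: str) -> str:
        l1 = self.level1(leaf)
        if l1 == ERROR_LABEL:
            return ERROR_LABEL
        if l1 == "non-neuron":
            return f"non-neuron/{leaf}"
        return f"neuron/{self.neuron_class(leaf)}/{leaf}"


# ---------------------------------------------------------------------------
# per-level model search

#: model families of the randomized search, in tie-break (simplicity) order
FAMILY_SEARCH_SPACES = {
    "svm_linear": (lambda seed: SVC(kernel="linear", random_state=seed),
                   {"C": loguniform(1e-2, 1e2)}),
    "decision_tree": (lambda seed: DecisionTreeClassifier(random_state=seed),
                      {"max_depth": randint(2, 16),
                       "min_samples_split": randint(2, 10)}),
    "nearest_neighbors": (lambda seed: KNeighborsClassifier(),
                          {"n_neighbors": randint(1, 20)}),
    "svm_rbf": (lambda seed: SVC(kernel="rbf", random_state=seed),
                {"C": loguniform(1e-1, 1e3), "gamma": loguniform(1e-3, 1e1)}),
    "random_forest": (lambda seed: RandomForestClassifier(random_state=seed),
                      {"n_estimators": randint(50, 300),
                       "max_depth": randint(3, 16)}),
    "mlp": (lambda seed: MLPClassifier(random_state=seed, max_iter=500),
            {"hidden_layer_sizes": [(32,), (64,), (64, 32)],
             "alpha": loguniform(1e-5, 1e-1)}),
}


@dataclass
class TrainedLevel:
    """One fitted cascade level with its cross-validation report."""

    model: object
    family: str
    params: dict
    feature_columns: list
    classes: list
    cv_accuracy: float
    cv_f1: float
    cv_reports: pd.DataFrame = None

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict(features[self.feature_columns].to_numpy())


def train_level(features: pd.DataFrame, labels,
                candidate_families=None,
                n_draws: int = 50,
                cv_folds: int = 10,
                seed: int = 0) -> TrainedLevel:
    """Randomized model search with stratified k-fold CV for one level.

    For each candidate family ``n_draws`` hyperparameter draws are scored by
    stratified cross-validated accuracy; the best configuration is selected
    by accuracy, then macro F1, then family simplicity (fixed order).  Folds
    are reduced with a warning when the rarest class has fewer members than
    requested folds.
    """
    labels = pd.Series(labels)
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a level")
    folds = int(min(cv_folds, counts.min()))
    if folds < cv_folds:
        warnings.warn(f"reducing CV folds from {cv_folds} to {folds}: "
                      "rarest class is too small")
    folds = max(folds, 2)
    if candidate_families is None:
        candidate_families = list(FAMILY_SEARCH_SPACES)

    rows = []
    best = None
    for fi, family in enumerate(candidate_families):
        factory, space = FAMILY_SEARCH_SPACES[family]
        sampler = ParameterSampler(space, n_iter=n_draws, random_state=seed + fi)
        for params in sampler:
            est = factory(seed).set_params(**params)
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            acc = cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean()
            f1 = cross_val_score(est, X, y, cv=cv, scoring="f1_macro").mean()
            rows.append({"family": family, "params": params,
                         "cv_accuracy": acc, "cv_f1": f1})
            key = (acc, f1, -fi)
            if best is None or key > best[0]:
                best = (key, family, params)
    report = pd.DataFrame(rows)
    _, family, params = best
    factory, _ = FAMILY_SEARCH_SPACES[family]
    model = factory(seed).set_params(**params).fit(X, y)
    sel = report[(report["family"] == family)]
    sel = sel[sel["params"].apply(lambda p: p == params)].iloc[0]
    return TrainedLevel(model=model, family=family, params=dict(params),
                        feature_columns=list(features.columns),
                        classes=list(classes),
                        cv_accuracy=float(sel["cv_accuracy"]),
                        cv_f1=float(sel["cv_f1"]), cv_reports=report)


# ---------------------------------------------------------------------------
# the cascade


@dataclass
class HierarchicalModel:
    """Five fitted classifiers plus the routing taxonomy."""

    object_model: TrainedLevel                # 1: neuron / non-neuron / error
    non_neuronal_model: TrainedLevel          # 2
    neuron_class_model: TrainedLevel          # 3: excitatory / inhibitory
    excitatory_model: TrainedLevel            # 4
    inhibitory_model: TrainedLevel | None     # 5 (nucleus+soma+PSS)
    taxonomy: Taxonomy = field(default_factory=Taxonomy)
    reroute_model: object | None = None       # exc-vs-inh in PSS-augmented space
    reroute_columns: list = field(default_factory=list)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "HierarchicalModel":
        return joblib.load(path)


def train_cascade(features: pd.DataFrame, leaf_labels: pd.Series,
                  pss_columns: list | None = None,
                  feature_columns: list | None = None,
                  candidate_families=("svm_linear", "svm_rbf"),
                  n_draws: int = 5, cv_folds: int = 5,
                  seed: int = 0,
                  taxonomy: Taxonomy | None = None) -> HierarchicalModel:
    """Train all cascade levels from a labelled, standardized feature table.

    ``leaf_labels`` holds taxonomy leaves (including "error" examples).
    PSS columns, if present, are used by the inhibitory model and by the
    excitatory re-routing classifier.
    """
    taxonomy = taxonomy or Taxonomy()
    labels = leaf_labels.reindex(features.index)
    if labels.isna().any():
        raise ValueError("labels missing for some feature rows")
    bad = set(labels.unique()) - set(taxonomy.leaves)
    if bad:
        raise KeyError(f"labels outside the taxonomy: {sorted(bad)}")

    if feature_columns is None:
        feature_columns = [c for c in FEATURE_COLUMNS if c in features.columns]
    if pss_columns is None:
        pss_columns = [c for c in features.columns if c.startswith("pss_")]
    base = features[feature_columns]

    level1 = labels.map(taxonomy.level1)
    kw = dict(candidate_families=candidate_families, n_draws=n_draws,
              cv_folds=cv_folds, seed=seed)
    object_model = train_level(base, level1, **kw)

    nn_mask = level1 == "non-neuron"
    non_neuronal_model = train_level(base[nn_mask], labels[nn_mask], **kw)

    neuron_mask = level1 == "neuron"
    neuron_class = labels[neuron_mask].map(taxonomy.neuron_class)
    neuron_class_model = train_level(base[neuron_mask], neuron_class, **kw)

    exc_mask = neuron_mask & labels.isin(taxonomy.excitatory)
    excitatory_model = train_level(base[exc_mask], labels[exc_mask], **kw)

    inhibitory_model = None
    reroute_model = None
    reroute_columns: list = []
    inh_mask = neuron_mask & labels.isin(taxonomy.inhibitory)
    if pss_columns and inh_mask.any():
        pss_ok = features[pss_columns].notna().all(axis=1)
        cols = feature_columns + pss_columns
        inh_train = inh_mask & pss_ok
        if inh_train.any():
            inhibitory_model = train_level(features.loc[inh_train, cols],
                                           labels[inh_train], **kw)
        # re-routing rule: excitatory vs inhibitory in PSS-augmented space
        both = neuron_mask & pss_ok
        if both.any() and labels[both].isin(taxonomy.excitatory).any():
            y = labels[both].map(taxonomy.neuron_class)
            reroute_model = LogisticRegression(max_iter=1000).fit(
                features.loc[both, cols].to_numpy(), y.to_numpy())
            reroute_columns = cols

    return HierarchicalModel(
        object_model=object_model,
        non_neuronal_model=non_neuronal_model,
        neuron_class_model=neuron_class_model,
        excitatory_model=excitatory_model,
        inhibitory_model=inhibitory_model,
        taxonomy=taxonomy,
        reroute_model=reroute_model,
        reroute_columns=reroute_columns,
    )


def predict_cascade(model: HierarchicalModel, features: pd.DataFrame,
                    reroute: bool = True) -> pd.DataFrame:
    """Route cells through the cascade.

    Returns a frame indexed by cell id with ``leaf_label``, ``path`` and a
    ``pending_pss`` flag for inhibitory-routed cells lacking PSS features.
    Error-labelled cells are not routed further.
    """
    missing = [c for c in model.object_model.feature_columns
               if c not in features.columns]
    if missing:
        raise ValueError(f"missing required feature columns: {missing}")

    idx = features.index
    leaf = pd.Series("", index=idx, dtype=object)
    path = pd.Series("", index=idx, dtype=object)
    pending = pd.Series(False, index=idx)

    l1 = pd.Series(model.object_model.predict(features), index=idx)
    err = l1 == ERROR_LABEL
    leaf[err] = ERROR_LABEL
    path[err] = ERROR_LABEL

    nn = l1 == "non-neuron"
    if nn.any():
        sub = pd.Series(model.non_neuronal_model.predict(features[nn]),
                        index=idx[nn])
        leaf[nn] = sub
        path[nn] = "non-neuron/" + sub

    neuron = l1 == "neuron"
    if neuron.any():
        ncls = pd.Series(model.neuron_class_model.predict(features[neuron]),
                         index=idx[neuron])
        exc = ncls[ncls == "excitatory"].index
        inh = ncls[ncls == "inhibitory"].index

        if reroute and model.reroute_model is not None and len(inh):
            inh, moved = _apply_reroute(model, features, inh)
            exc = exc.union(moved)

        if len(exc):
            sub = pd.Series(model.excitatory_model.predict(features.loc[exc]),
                            index=exc)
            leaf[exc] = sub
            path[exc] = "neuron/excitatory/" + sub
        if len(inh):
            if model.inhibitory_model is None:
                leaf[inh] = "inhibitory"
                path[inh] = "neuron/inhibitory"
                pending[inh] = True
            else:
                cols = model.inhibitory_model.feature_columns
                have = [c for c in cols if c in features.columns]
                ok = (features.loc[inh, have].notna().all(axis=1)
                      if len(have) == len(cols)
                      else pd.Series(False, index=inh))
                good = inh[ok]
                bad = inh[~ok]
                if len(good):
                    sub = pd.Series(model.inhibitory_model.predict(
                        features.loc[good]), index=good)
                    leaf[good] = sub
                    path[good] = "neuron/inhibitory/" + sub
                if len(bad):
                    leaf[bad] = "inhibitory"
                    path[bad] = "neuron/inhibitory"
                    pending[bad] = True

    return pd.DataFrame({"leaf_label": leaf, "path": path,
                         "pending_pss": pending})


def _apply_reroute(model: HierarchicalModel, features: pd.DataFrame,
                   inhibitory_ids) -> tuple[pd.Index, pd.Index]:
    """Split predicted-inhibitory cells into (kept, re-routed-to-excitatory)."""
    cols = model.reroute_columns
    have = [c for c in cols if c in features.columns]
    if len(have) != len(cols):
        return inhibitory_ids, pd.Index([])
    block = features.loc[inhibitory_ids, cols]
    ok = block.notna().all(axis=1)
    candidates = inhibitory_ids[ok]
    if not len(candidates):
        return inhibitory_ids, pd.Index([])
    pred = model.reroute_model.predict(features.loc[candidates, cols].to_numpy())
    moved = candidates[pred == "excitatory"]
    kept = inhibitory_ids.difference(moved)
    return kept, moved


def reroute_misplaced_excitatory(features: pd.DataFrame,
                                 model: HierarchicalModel) -> pd.DataFrame:
    """Re-route PSS-bearing predicted-inhibitory cells that separate as
    excitatory-like; returns a log of reassignments with new subclasses."""
    if len(features) == 0:
        return pd.DataFrame(columns=["new_label"])
    if model.reroute_model is None:
        return pd.DataFrame(columns=["new_label"])
    _, moved = _apply_reroute(model, features, features.index)
    if not len(moved):
        return pd.DataFrame(columns=["new_label"])
    sub = model.excitatory_model.predict(features.loc[moved])
    return pd.DataFrame({"new_label": sub}, index=moved)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(predictions: pd.Series, reference: pd.Series,
             class_weights: dict | None = None,
             taxonomy: Taxonomy | None = None) -> dict:
    """Weighted accuracy, per-class precision/recall/F1 and confusion matrix.

    Weighted accuracy is the class-frequency-weighted mean of per-class
    recall, with weights taken from the reference labels (the sampling rate
    of each class) unless supplied.
    """
    taxonomy = taxonomy or Taxonomy()
    predictions = pd.Series(predictions)
    reference = pd.Series(reference).reindex(predictions.index)
    if reference.isna().any():
        raise ValueError("reference labels missing for some predictions")
    valid = set(taxonomy.leaves) | {"inhibitory"}
    bad = (set(predictions.unique()) | set(reference.unique())) - valid
    if bad:
        raise KeyError(f"labels outside the taxonomy: {sorted(bad)}")

    classes = sorted(set(reference.unique()))
    prec, rec, f1, support = precision_recall_fscore_support(
        reference, predictions, labels=classes, zero_division=0)
    if class_weights is None:
        weights = support / support.sum()
    else:
        weights = np.array([class_weights.get(c, 0.0) for c in classes])
        weights = weights / weights.sum()
    cm = confusion_matrix(reference, predictions, labels=classes)
    return {
        "weighted_accuracy": float((weights * rec).sum()),
        "per_class": pd.DataFrame({"precision": prec, "recall": rec,
                                   "f1": f1, "support": support}, index=classes),
        "confusion": pd.DataFrame(cm, index=classes, columns=classes),
    }
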