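"""Pool-based active learning with least-confidence uncertainty sampling.

Protocol: 20% of the samples (floor) form the initial labeled set, 30%
(floor) the query pool, and the remainder a held-out test set.  Each
iteration queries the pool sample whose top-class posterior probability is
smallest — the instance the current model is least confident about — moves
it (with its true label, an oracle annotator) into the labeled set, and
refits the model from scratch.  Querying stops when the pool is exhausted
or an iteration budget is hit; test accuracy is recorded after every refit.

Margin and entropy sampling are available behind the ``query_strategy``
switch but least-confidence is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import confusion_matrix
from .models import (
    HierarchicalKnnModel,
    NetHyper,
    TwoLayerNetModel,
    fit_hierarchical,
    fit_nn,
)
from .panel import GROUPS, PanelDefinition, default_panel
from .synthetic import STREAM_MODEL, STREAM_SPLIT, substream

logger = logging.getLogger(__name__)

MODEL_SPECS = ("hierarchical_knn", "two_layer_nn")
QUERY_STRATEGIES = ("least_confidence", "margin", "entropy")

LABELED_FRAC = 0.20
POOL_FRAC = 0.30


@dataclass
class ALConfig:
    model_spec: str = "hierarchical_knn"
    k: int = 5
    net: NetHyper = field(default_factory=NetHyper)
    budget: int | None = None          # None: run until the pool is empty
    query_strategy: str = "least_confidence"

    def validate(self) -> None:
        if self.model_spec not in MODEL_SPECS:
            raise ValueError(f"model_spec must be one of {MODEL_SPECS}")
        if self.query_strategy not in QUERY_STRATEGIES:
            raise ValueError(f"query_strategy must be one of {QUERY_STRATEGIES}")
        if self.budget is not None and self.budget < 0:
            raise ValueError("budget must be >= 0")


@dataclass
class QueryRecord:
    iteration: int
    sample_id: str
    confidence: float  # minimized quantity at selection time


@dataclass
class ALState:
    """Labeled / pool / test partition plus the running model and history."""

    labeled_ids: list[str]
    pool_ids: list[str]
    test_ids: list[str]
    seed: int
    redraws: int = 0
    model: object | None = None
    query_history: list[QueryRecord] = field(default_factory=list)

    def check_partition(self, n_total: int) -> None:
        ids = self.labeled_ids + self.pool_ids + self.test_ids
        if len(ids) != n_total or len(set(ids)) != n_total:
            raise ValueError("labeled/pool/test do not partition the dataset")


def split_dataset(
    table: pd.DataFrame, seed: int
) -> ALState:
    """Draw the initial 20/30/50 labeled/pool/test partition.

    The labeled draw is repeated (new draws from the split sub-stream) until
    it contains at least one healthy and one non-healthy sample, so the
    hierarchical stage 1 is trainable; the redraw count is logged and kept
    on the state.
    """
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    present = set(table["group"])
    missing = [g for g in GROUPS if g not in present]
    if missing:
        raise ValueError(f"classes absent from dataset: {missing}")

    n_labeled = int(np.floor(LABELED_FRAC * n))
    n_pool = int(np.floor(POOL_FRAC * n))
    rng = substream(seed, STREAM_SPLIT)
    ids = table["sample_id"].to_numpy()
    groups = table.set_index("sample_id")["group"]

    redraws = 0
    while True:
        perm = rng.permutation(n)
        labeled = list(ids[perm[:n_labeled]])
        lab_groups = set(groups.loc[labeled])
        if "healthy" in lab_groups and lab_groups - {"healthy"}:
            break
        redraws += 1
    if redraws:
        logger.info("initial labeled set redrawn %d time(s)", redraws)
    pool = list(ids[perm[n_labeled : n_labeled + n_pool]])
    test = list(ids[perm[n_labeled + n_pool :]])
    state = ALState(labeled_ids=labeled, pool_ids=pool, test_ids=test,
                    seed=seed, redraws=redraws)
    state.check_partition(n)
    return state


def _posteriors(model, X: np.ndarray) -> np.ndarray:
    return model.predict_table(X)


def _query_scores(probs: np.ndarray, strategy: str) -> np.ndarray:
    """Per-sample score; the query selects the minimum."""
    if strategy == "least_confidence":
        return probs.max(axis=1)
    if strategy == "margin":
        part = np.sort(probs, axis=1)
        return part[:, -1] - part[:, -2]
    if strategy == "entropy":
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(probs > 0, probs * np.log(probs), 0.0).sum(axis=1)
        return -h  # max entropy = min score
    raise ValueError(strategy)


def select_query(
    model, pool: pd.DataFrame, panel: PanelDefinition | None = None,
    strategy: str = "least_confidence",
) -> tuple[str, float]:
    """Pool sample with the smallest top-class posterior probability.

    Ties resolve to the smallest index (row order of ``pool``).  Returns
    (sample_id, confidence at selection time).
    """
    if len(pool) == 0:
        raise ValueError("empty query pool")
    panel = panel if panel is not None else default_panel()
    X = pool[panel.columns].to_numpy(float)
    probs = _posteriors(model, X)
    scores = _query_scores(probs, strategy)
    i = int(np.argmin(scores))  # first minimum -> smallest index
    return str(pool["sample_id"].iloc[i]), float(probs[i].max())


def _fit(config: ALConfig, labeled: pd.DataFrame, panel: PanelDefinition,
         seed: int, iteration: int):
    if config.model_spec == "hierarchical_knn":
        return fit_hierarchical(labeled, k=config.k, panel=panel)
    rng = substream(seed, STREAM_MODEL, iteration)
    return fit_nn(labeled, hyper=config.net, rng=rng, panel=panel)


def _test_accuracy(model, test: pd.DataFrame, panel: PanelDefinition) -> float:
    X = test[panel.columns].to_numpy(float)
    probs = _posteriors(model, X)
    pred = [GROUPS[i] for i in probs.argmax(axis=1)]
    return float(np.mean(pred == test["group"].to_numpy()))


@dataclass
class ALResult:
    state: ALState
    confusion: np.ndarray               # 3x3 counts on the test set
    learning_curve: pd.DataFrame        # iteration, n_labeled, test_accuracy

    @property
    def final_accuracy(self) -> float:
        return float(self.learning_curve["test_accuracy"].iloc[-1])


def run_al(
    table: pd.DataFrame,
    config: ALConfig | None = None,
    seed: int = 0,
    panel: PanelDefinition | None = None,
) -> ALResult:
    """Full active-learning run: split, iterative querying, final evaluation.

    Fully reproducible from (table, config, seed).  The test partition is
    never touched by training or querying; the learning curve holds one row
    for the initial model plus one per query iteration.
    """
    config = config if config is not None else ALConfig()
    config.validate()
    panel = panel if panel is not None else default_panel()
    state = split_dataset(table, seed)
    indexed = table.set_index("sample_id", drop=False)

    labeled = indexed.loc[state.labeled_ids]
    test = indexed.loc[state.test_ids]
    model = _fit(config, labeled, panel, seed, iteration=0)
    curve = [(0, len(labeled), _test_accuracy(model, test, panel))]

    n_queries = len(state.pool_ids)
    if config.budget is not None:
        n_queries = min(n_queries, config.budget)
    for it in range(1, n_queries + 1):
        pool = indexed.loc[state.pool_ids]
        sample_id, conf = select_query(
            model, pool, panel=panel, strategy=config.query_strategy
        )
        state.query_history.append(QueryRecord(it, sample_id, conf))
        state.pool_ids.remove(sample_id)
        state.labeled_ids.append(sample_id)
        labeled = indexed.loc[state.labeled_ids]
        model = _fit(config, labeled, panel, seed, iteration=it)
        curve.append((it, len(labeled), _test_accuracy(model, test, panel)))

    state.model = model
    X_test = test[panel.columns].to_numpy(float)
    pred = [GROUPS[i] for i in _posteriors(model, X_test).argmax(axis=1)]
    cm = confusion_matrix(test["group"].to_numpy(), pred)
    lc = pd.DataFrame(curve, columns=["iteration", "n_labeled", "test_accuracy"])
    return ALResult(state=state, confusion=cm, learning_curve=lc)
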