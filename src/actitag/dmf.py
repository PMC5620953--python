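"""The Dichotomous Mapped Forest (DMF).

A fixed 8-node hierarchy of classifiers routes each window from the root to
one of the 10 activity-tag leaves.  Every node discriminates between 2 or 3
disjoint tag groups and is trained independently on the samples whose tag
belongs to one of its groups: SFFS picks the node's descriptor subset, a
supervised subspace mapping (maximally collapsing metric or discriminative
autoencoder) is fitted on the selected, z-scored descriptors, and a random
forest is trained on the mapped data.  At inference, a sample descends the
tree by the argmax group at each node; the per-node group confidences along
the path are fused into a single confidence, either as a plain product or
weighted by the level weights

    phi_k = 2 (l - k + 1) / (l^2 + l),    sum_k phi_k = 1,

which let misclassifications near the root (where many leaves are still in
play) dominate the fused confidence.

The default tree (l = 5 levels):

    N1 (level 1): {walk + 6 transitions} vs {sit, stand, lie}
    N2 (level 2): sit / stand / lie (ternary)
    N3 (level 2): walk vs {6 transitions}
    N4 (level 3): {lying-involved transitions} vs {sit2stand, stand2sit}
    N5 (level 4): sit2stand vs stand2sit
    N6 (level 4): {lie2sit, lie2stand} vs {sit2lie, stand2lie}
    N7 (level 5): lie2sit vs lie2stand
    N8 (level 5): sit2lie vs stand2lie

Root-to-leaf paths visit 2-5 nodes.  Only 8 classifiers cover the 10-class
problem, against 45 for a one-vs-one decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import mapping as mp
from .features import FeatureSubset, sffs_select
from .tags import ActivityTag, TAG_ORDER, as_tag

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityTag",
    "DMFConfig",
    "DichotomyNode",
    "Dichotomy",
    "Prediction",
    "build_dichotomy",
    "level_weight",
    "one_vs_one_count",
    "train_dmf",
    "predict_dmf",
    "fuse_confidence_unweighted",
    "fuse_confidence_weighted",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

@dataclass
class DichotomyNode:
    """One classifier node: 2-3 disjoint tag groups at a tree level."""

    id: str
    level: int
    groups: list[frozenset[ActivityTag]]
    #: child node id per group; None = the group is a leaf (single tag)
    children: list["str | None"]

    def __post_init__(self) -> None:
        if not 2 <= len(self.groups) <= 3:
            raise ValueError(f"node {self.id}: needs 2 or 3 groups")
        seen: set[ActivityTag] = set()
        for g in self.groups:
            if seen & g:
                raise ValueError(f"node {self.id}: groups not disjoint")
            seen |= g

    @property
    def tags(self) -> frozenset[ActivityTag]:
        return frozenset().union(*self.groups)

    def group_of(self, tag: ActivityTag) -> int:
        for u, g in enumerate(self.groups):
            if tag in g:
                return u
        raise KeyError(f"tag {tag} not handled by node {self.id}")


@dataclass
class Dichotomy:
    """The fixed classifier tree: 8 nodes, 10 leaves, l levels."""

    nodes: dict[str, DichotomyNode]
    root: str = "N1"

    @property
    def levels(self) -> int:
        return max(n.level for n in self.nodes.values())

    @property
    def level_weights(self) -> np.ndarray:
        l = self.levels
        return np.array([level_weight(l, k) for k in range(1, l + 1)])

    def path(self, tag: "ActivityTag | str") -> list[str]:
        """Node ids on the root-to-leaf path of ``tag``."""
        tag = as_tag(tag)
        out, nid = [], self.root
        while nid is not None:
            node = self.nodes[nid]
            out.append(nid)
            nid = node.children[node.group_of(tag)]
        return out

    @property
    def leaves(self) -> list[ActivityTag]:
        out = []
        for node in self.nodes.values():
            for g, child in zip(node.groups, node.children):
                if child is None:
                    out.extend(g)
        return out


def build_dichotomy() -> Dichotomy:
    """The default 8-node tree described in the module docstring."""
    T = ActivityTag
    f = frozenset
    nodes = [
        DichotomyNode(
            "N1", 1,
            [f({T.WALK, T.SIT2STAND, T.STAND2SIT, T.LIE2SIT, T.SIT2LIE, T.LIE2STAND, T.STAND2LIE}),
             f({T.SIT, T.STAND, T.LIE})],
            ["N3", "N2"],
        ),
        DichotomyNode("N2", 2, [f({T.SIT}), f({T.STAND}), f({T.LIE})], [None, None, None]),
        DichotomyNode(
            "N3", 2,
            [f({T.WALK}),
             f({T.SIT2STAND, T.STAND2SIT, T.LIE2SIT, T.SIT2LIE, T.LIE2STAND, T.STAND2LIE})],
            [None, "N4"],
        ),
        DichotomyNode(
            "N4", 3,
            [f({T.LIE2SIT, T.SIT2LIE, T.LIE2STAND, T.STAND2LIE}),
             f({T.SIT2STAND, T.STAND2SIT})],
            ["N6", "N5"],
        ),
        DichotomyNode("N5", 4, [f({T.SIT2STAND}), f({T.STAND2SIT})], [None, None]),
        DichotomyNode(
            "N6", 4,
            [f({T.LIE2SIT, T.LIE2STAND}), f({T.SIT2LIE, T.STAND2LIE})],
            ["N7", "N8"],
        ),
        DichotomyNode("N7", 5, [f({T.LIE2SIT}), f({T.LIE2STAND})], [None, None]),
        DichotomyNode("N8", 5, [f({T.SIT2LIE}), f({T.STAND2LIE})], [None, None]),
    ]
    return Dichotomy(nodes={n.id: n for n in nodes})


def level_weight(l: int, k: int) -> float:
    """phi_k = 2 (l - k + 1) / (l^2 + l); strictly decreasing in k, sums to 1."""
    if not 1 <= k <= l:
        raise ValueError(f"level k={k} out of range 1..{l}")
    return 2.0 * (l - k + 1) / (l**2 + l)


def one_vs_one_count(n_classes: int = 10) -> int:
    """Number of binary classifiers a one-vs-one decomposition needs."""
    return n_classes * (n_classes - 1) // 2


# ---------------------------------------------------------------------------
# Confidence fusion
# ---------------------------------------------------------------------------

def fuse_confidence_unweighted(path_confidences: Sequence[float]) -> float:
    """Plain product of the on-path node confidences."""
    conf = np.asarray(path_confidences, dtype=float)
    if conf.size == 0:
        raise ValueError("empty confidence path")
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError("confidences must lie in [0, 1]")
    return float(np.prod(conf))


def fuse_confidence_weighted(
    path_confidences: Sequence[float], levels: Sequence[int], l: int
) -> float:
    """Product of phi_k * p_k over the on-path levels (no renormalization).

    Levels without an on-path node contribute nothing (the indicator in the
    fusion rule skips them).  Because phi_k < 1 whenever l >= 2, weighted
    fusion shrinks absolute confidences relative to the plain product.
    """
    conf = np.asarray(path_confidences, dtype=float)
    if conf.size == 0:
        raise ValueError("empty confidence path")
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError("confidences must lie in [0, 1]")
    if len(levels) != conf.size:
        raise ValueError("levels and confidences must align")
    out = 1.0
    for p, k in zip(conf, levels):
        out *= level_weight(l, int(k)) * p
    return float(out)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class DMFConfig:
    """Hyperparameters of the whole forest; defaults are the package defaults."""

    mapping_kind: str = "metric"  # "metric" (MCM) or "deep" (DAUT)
    n_trees: int = 100
    max_depth: int = 12
    bagging_fraction: float = 0.8
    sffs_max_features: int = 5
    sffs_cv_folds: int = 3
    #: univariate-F prefilter pool size fed to SFFS (None = all descriptors)
    sffs_prefilter: "int | None" = 30
    #: mapped dimension per node; None = min(10, n_selected - 1)
    mapped_dim: "int | None" = None
    mcm_max_iter: int = 60
    mcm_tol: float = 1e-5
    #: cap on rows used for the O(n^2) MCM objective (seeded subsample)
    mcm_max_samples: int = 250
    daut_lambda: "float | str" = 1.0
    daut_max_iter: int = 100
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.mapping_kind not in ("metric", "deep"):
            raise ValueError("mapping_kind must be 'metric' or 'deep'")


@dataclass
class _FittedNode:
    node: DichotomyNode
    selected: list[int]
    mu: np.ndarray
    sd: np.ndarray
    mapping: "mp.MetricMapping | mp.AutoencoderMapping"
    forest: RandomForestClassifier
    sffs: FeatureSubset = field(repr=False, default=None)


@dataclass
class DMFModel:
    """A trained dichotomous mapped forest."""

    dichotomy: Dichotomy
    config: DMFConfig
    fitted: dict[str, _FittedNode]
    n_features: int
    feature_names: "list[str] | None" = None
    #: provenance of the rows used for SFFS + mapping (e.g. subject groups)
    mapping_provenance: "list | None" = None
    version: int = MODEL_FORMAT_VERSION


@dataclass
class Prediction:
    """One window's routed prediction."""

    tag: ActivityTag
    confidence: float  # weighted fusion (phi_k * p_k product)
    confidence_unweighted: float
    path_nodes: list[str]
    path_levels: list[int]
    path_confidences: list[float]


def _prepare_node_data(
    node: DichotomyNode, X: np.ndarray, y_tags: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    member = np.array([t in node.tags for t in y_tags])
    Xn = X[member]
    yn = np.array([node.group_of(t) for t in y_tags[member]], dtype=int)
    return Xn, yn


def train_dmf(
    X: np.ndarray,
    y: Sequence["ActivityTag | str"],
    mapping_kind: "str | None" = None,
    config: DMFConfig | None = None,
    rng_seed: int = 0,
    feature_names: "list[str] | None" = None,
    selection_data: "tuple[np.ndarray, Sequence] | None" = None,
    mapping_provenance: "list | None" = None,
) -> DMFModel:
    """Train the full dichotomy.

    For each node: restrict to the samples whose tag belongs to the node's
    groups, relabel by group index, select descriptors with SFFS, fit the
    subspace mapping on the z-scored selection, and train a random forest
    on the mapped data.  ``selection_data`` optionally provides a separate
    (X, y) used only for SFFS and the mapping fit (training setting C);
    the forests always train on ``(X, y)``.

    Deterministic: all per-node randomness is spawned from ``rng_seed``.
    """
    config = config or DMFConfig()
    if mapping_kind is not None:
        config = replace(config, mapping_kind=mapping_kind)
    X = np.asarray(X, dtype=float)
    y_tags = np.array([as_tag(t) for t in y], dtype=object)
    present = set(y_tags)
    dich = build_dichotomy()
    missing = [t for t in TAG_ORDER if t not in present]
    if missing:
        t = missing[0]
        node = next(n for n in dich.nodes.values() if t in n.tags)
        raise ValueError(
            f"training data is missing tag {t.value!r} required by node {node.id}"
        )
    if selection_data is not None:
        X_sel_src = np.asarray(selection_data[0], dtype=float)
        y_sel_src = np.array([as_tag(t) for t in selection_data[1]], dtype=object)
    else:
        X_sel_src, y_sel_src = X, y_tags

    ss = np.random.SeedSequence(rng_seed)
    node_ids = sorted(dich.nodes)  # fixed order -> order-independent results
    child_seeds = {nid: s for nid, s in zip(node_ids, ss.spawn(len(node_ids)))}
    fitted: dict[str, _FittedNode] = {}
    for nid in node_ids:
        node = dich.nodes[nid]
        seeds = child_seeds[nid].generate_state(4) % (2**31 - 1)
        Xs, ys = _prepare_node_data(node, X_sel_src, y_sel_src)
        Xn, yn = _prepare_node_data(node, X, y_tags)
        for u, g in enumerate(node.groups):
            if not (ys == u).any() or not (yn == u).any():
                miss = "/".join(t.value for t in sorted(g, key=lambda t: t.value))
                raise ValueError(f"node {nid}: no training samples for group {{{miss}}}")

        candidates = None
        if config.sffs_prefilter is not None and X.shape[1] > config.sffs_prefilter:
            candidates = _prefilter_univariate(Xs, ys, config.sffs_prefilter)
        subset = sffs_select(
            Xs, ys,
            max_features=min(config.sffs_max_features, X.shape[1]),
            cv_folds=config.sffs_cv_folds,
            rng_seed=int(seeds[0]),
            candidates=candidates,
        )
        sel = subset.indices
        Xs_sel = Xs[:, sel]
        mu = Xs_sel.mean(axis=0)
        sd = Xs_sel.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        if not config.standardize:
            mu, sd = np.zeros_like(mu), np.ones_like(sd)
        Zs = (Xs_sel - mu) / sd
        d = config.mapped_dim or max(1, min(10, len(sel) - 1))
        d = min(d, len(sel))
        if config.mapping_kind == "metric":
            Zf, yf = Zs, ys
            if len(Zs) > config.mcm_max_samples:
                idx = np.random.default_rng(int(seeds[1])).choice(
                    len(Zs), config.mcm_max_samples, replace=False
                )
                Zf, yf = Zs[idx], ys[idx]
            mapping = mp.fit_mcm(
                Zf, yf, d=d, max_iter=config.mcm_max_iter,
                tol=config.mcm_tol, rng_seed=int(seeds[2]),
            )
        else:
            Y1h = np.eye(len(node.groups))[ys]
            mapping = mp.fit_daut(
                Zs, Y1h, d=d, lam=config.daut_lambda,
                max_iter=config.daut_max_iter, rng_seed=int(seeds[2]),
            )
        Zn = (Xn[:, sel] - mu) / sd
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            max_samples=config.bagging_fraction,
            class_weight="balanced_subsample",
            random_state=int(seeds[3]),
            n_jobs=1,
        )
        forest.fit(mp.transform(Zn, mapping), yn)
        fitted[nid] = _FittedNode(
            node=node, selected=list(sel), mu=mu, sd=sd,
            mapping=mapping, forest=forest, sffs=subset,
        )
        logger.debug("node %s: %d samples, features %s", nid, len(Xn), sel)
    return DMFModel(
        dichotomy=dich, config=config, fitted=fitted,
        n_features=X.shape[1], feature_names=feature_names,
        mapping_provenance=mapping_provenance,
    )


def _prefilter_univariate(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Top-k descriptor columns by one-way ANOVA F statistic."""
    from sklearn.feature_selection import f_classif

    F, _ = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0)
    return sorted(np.argsort(F)[::-1][:k].tolist())


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_dmf(Z: np.ndarray, model: DMFModel) -> list[Prediction]:
    """Route each sample through the dichotomy and fuse path confidences."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[None, :]
    if Z.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features}, got {Z.shape[1]}"
        )
    l = model.dichotomy.levels
    n = Z.shape[0]
    # route sample index sets node by node so each forest predicts in batch
    paths: list[list[tuple[str, int, float]]] = [[] for _ in range(n)]
    leaf_tag: list[ActivityTag | None] = [None] * n
    frontier = {model.dichotomy.root: np.arange(n)}
    while frontier:
        nxt: dict[str, list[np.ndarray]] = {}
        for nid, idx in frontier.items():
            fn = model.fitted[nid]
            Xn = (Z[idx][:, fn.selected] - fn.mu) / fn.sd
            proba = fn.forest.predict_proba(mp.transform(Xn, fn.mapping))
            classes = fn.forest.classes_
            best = np.argmax(proba, axis=1)
            for row, (i, b) in enumerate(zip(idx, best)):
                u = int(classes[b])
                conf = float(proba[row, b])
                paths[i].append((nid, fn.node.level, conf))
                child = fn.node.children[u]
                if child is None:
                    (leaf,) = fn.node.groups[u]
                    leaf_tag[i] = leaf
                else:
                    nxt.setdefault(child, []).append(i)
        frontier = {nid: np.array(ix) for nid, ix in nxt.items()}
    out = []
    for i in range(n):
        nodes_, levels_, confs_ = zip(*paths[i])
        out.append(
            Prediction(
                tag=leaf_tag[i],
                confidence=fuse_confidence_weighted(confs_, levels_, l),
                confidence_unweighted=fuse_confidence_unweighted(confs_),
                path_nodes=list(nodes_),
                path_levels=list(levels_),
                path_confidences=list(confs_),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: DMFModel, path) -> None:
    """Serialize the trained model bundle (versioned joblib archive)."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> DMFModel:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format {blob.get('format_version')!r}, "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    return blob["model"]
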