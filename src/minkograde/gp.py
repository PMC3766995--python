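"""Genetic-programming symbolic binary classifier over curve features.

The classifier evolves strongly-typed expression trees whose root is
Boolean-valued: comparison nodes (<, <=, >, >=) map real subexpressions
to Booleans, logical nodes (AND, OR, NOT, XOR) combine Booleans, and
arithmetic nodes (+, -, *, protected / returning 1 on a zero divisor)
combine reals.  Leaves are feature references or numeric constants
drawn uniformly from the per-feature training range.  A sample is
classified as the positive class (grade IV) when the root evaluates to
True.

Evolution is generational with tournament selection, subtree crossover
between type-compatible points, elitism, and — with the configured
mutation probability — one of four mutators chosen uniformly:

* replace branch: substitute a random subtree by a fresh random one;
* change node type: swap a node's operator for an arity- and
  type-compatible one (or redraw a leaf);
* full tree shaker: re-randomize every numeric constant;
* one point shaker: re-randomize a single numeric constant.

Offspring violating the depth or length (node-count) limits are
discarded and the first parent retained, so every individual in every
generation satisfies the limits.  Fitness is raw training accuracy;
evolution stops early once a tree classifies the training set
perfectly.  All randomness flows from a single seed, making runs
bit-reproducible.

The statsmodels-style surface is :class:`GPClassifier` (model built
from data) whose ``fit`` returns :class:`GPResults`; cross-validation
and the parameter grid search return :class:`CVResult` objects with
``summary()`` tables.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "GPConfig",
    "GPModel",
    "GPClassifier",
    "GPResults",
    "CVResult",
    "DEFAULT_PARAM_GRID",
    "evaluate_tree",
    "gp_train",
    "cross_validate",
    "grid_search",
]

# operator table: name -> (return type, child types)
_OPS: dict[str, tuple[str, tuple[str, ...]]] = {
    "and": ("bool", ("bool", "bool")),
    "or": ("bool", ("bool", "bool")),
    "xor": ("bool", ("bool", "bool")),
    "not": ("bool", ("bool",)),
    "lt": ("bool", ("real", "real")),
    "le": ("bool", ("real", "real")),
    "gt": ("bool", ("real", "real")),
    "ge": ("bool", ("real", "real")),
    "add": ("real", ("real", "real")),
    "sub": ("real", ("real", "real")),
    "mul": ("real", ("real", "real")),
    "div": ("real", ("real", "real")),
}
_BOOL_BRANCH = ("and", "or", "xor", "not", "lt", "le", "gt", "ge")
_CMP = ("lt", "le", "gt", "ge")
_LOGIC2 = ("and", "or", "xor")
_ARITH = ("add", "sub", "mul", "div")
_SYMBOL = {
    "and": "AND", "or": "OR", "xor": "XOR", "not": "NOT",
    "lt": "<", "le": "<=", "gt": ">", "ge": ">=",
    "add": "+", "sub": "-", "mul": "*", "div": "/",
}


class Node:
    """One expression-tree node (operator, feature leaf or constant)."""

    __slots__ = ("op", "children", "feature", "value")

    def __init__(self, op, children=None, feature=None, value=None):
        self.op = op
        self.children = children or []
        self.feature = feature
        self.value = value
        if op in _OPS:
            arity = len(_OPS[op][1])
            if len(self.children) != arity:
                raise ValueError(f"{op} expects {arity} children")
            for child, want in zip(self.children, _OPS[op][1]):
                if child.ret_type != want:
                    raise ValueError(
                        f"{op} child of type {child.ret_type}, wants {want}"
                    )
        elif op == "feat":
            if feature is None:
                raise ValueError("feature leaf needs a feature index")
        elif op == "const":
            if value is None or not np.isfinite(value):
                raise ValueError("constant leaf needs a finite value")
        else:
            raise ValueError(f"unknown op {op!r}")

    @property
    def ret_type(self) -> str:
        return _OPS[self.op][0] if self.op in _OPS else "real"

    def clone(self) -> "Node":
        return Node(
            self.op,
            [c.clone() for c in self.children],
            self.feature,
            self.value,
        )

    def length(self) -> int:
        return 1 + sum(c.length() for c in self.children)

    def depth(self) -> int:
        return 1 + max((c.depth() for c in self.children), default=0)

    def to_str(self, names: Sequence[str] = FEATURE_NAMES) -> str:
        if self.op == "feat":
            return names[self.feature]
        if self.op == "const":
            return f"{self.value:.4g}"
        if self.op == "not":
            return f"NOT({self.children[0].to_str(names)})"
        a, b = (c.to_str(names) for c in self.children)
        return f"({a} {_SYMBOL[self.op]} {b})"

    def __str__(self) -> str:
        return self.to_str()

    def to_dict(self, names: Sequence[str] = FEATURE_NAMES) -> dict:
        d: dict = {"op": self.op}
        if self.op == "feat":
            d["feature"] = names[self.feature]
        elif self.op == "const":
            d["value"] = self.value
        else:
            d["children"] = [c.to_dict(names) for c in self.children]
        return d

    @staticmethod
    def from_dict(d: dict, names: Sequence[str] = FEATURE_NAMES) -> "Node":
        op = d["op"]
        if op == "feat":
            return Node("feat", feature=list(names).index(d["feature"]))
        if op == "const":
            return Node("const", value=float(d["value"]))
        return Node(
            op, [Node.from_dict(c, names) for c in d["children"]]
        )


def _eval(node: Node, X: np.ndarray):
    """Vectorized evaluation over a (n_samples, n_features) matrix."""
    op = node.op
    if op == "feat":
        return X[:, node.feature]
    if op == "const":
        return np.full(X.shape[0], node.value)
    with np.errstate(all="ignore"):
        if op in _ARITH:
            a = _eval(node.children[0], X)
            b = _eval(node.children[1], X)
            if op == "add":
                return a + b
            if op == "sub":
                return a - b
            if op == "mul":
                return a * b
            return np.where(b == 0, 1.0, a / np.where(b == 0, 1.0, b))
        if op in _CMP:
            a = _eval(node.children[0], X)
            b = _eval(node.children[1], X)
            if op == "lt":
                return a < b
            if op == "le":
                return a <= b
            if op == "gt":
                return a > b
            return a >= b
        a = _eval(node.children[0], X)
        if op == "not":
            return ~a
        b = _eval(node.children[1], X)
        if op == "and":
            return a & b
        if op == "or":
            return a | b
        return a ^ b


@dataclass
class GPConfig:
    """Run parameters of the evolutionary search.

    The value sets exercised by the reference parameter grid are
    generations {70, 100}, mutation probability {10, 15} percent,
    population 70, tree depth {8, 10} and tree length {25, 50, 80};
    tournament size, crossover probability and elitism default to
    common GP practice.
    """

    max_generations: int = 100
    mutation_probability_percent: float = 15.0
    population_size: int = 70
    max_tree_depth: int = 8
    max_tree_length: int = 50
    tournament_size: int = 2
    crossover_probability: float = 0.9
    elitism_count: int = 1
    n_folds: int = 10
    n_runs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < self.tournament_size:
            raise ValueError("population_size must be >= tournament_size")
        if not (0 <= self.mutation_probability_percent <= 100):
            raise ValueError("mutation probability must be a percentage")


DEFAULT_PARAM_GRID: dict[str, tuple] = {
    "max_generations": (70, 100),
    "mutation_probability_percent": (10, 15),
    "max_tree_depth": (8, 10),
    "max_tree_length": (25, 50, 80),
}


@dataclass
class GPModel:
    """A fitted symbolic classifier: one Boolean expression tree."""

    tree: Node
    feature_names: tuple[str, ...] = FEATURE_NAMES
    classes: tuple[str, str] = ("gradeII", "gradeIV")
    training_accuracy: float | None = None

    @property
    def depth(self) -> int:
        return self.tree.depth()

    @property
    def length(self) -> int:
        return self.tree.length()

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean predictions (True = positive class) for a matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.asarray(_eval(self.tree, X), dtype=bool)

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        pred = self.predict(X)
        return np.where(pred, self.classes[1], self.classes[0])

    def to_json(self) -> str:
        return json.dumps(
            {
                "tree": self.tree.to_dict(self.feature_names),
                "feature_names": list(self.feature_names),
                "classes": list(self.classes),
                "training_accuracy": self.training_accuracy,
            },
            sort_keys=True,
        )

    @staticmethod
    def from_json(text: str) -> "GPModel":
        d = json.loads(text)
        names = tuple(d.get("feature_names", FEATURE_NAMES))
        return GPModel(
            tree=Node.from_dict(d["tree"], names),
            feature_names=names,
            classes=tuple(d["classes"]),
            training_accuracy=d.get("training_accuracy"),
        )

    def __str__(self) -> str:
        return self.tree.to_str(self.feature_names)


def evaluate_tree(model: GPModel, fv: FeatureVector | np.ndarray) -> str:
    """Deterministically classify one feature vector (class label)."""
    x = fv.as_array() if isinstance(fv, FeatureVector) else np.asarray(fv)
    return str(model.predict_labels(x.reshape(1, -1))[0])


# ---------------------------------------------------------------------------
# random tree construction
# ---------------------------------------------------------------------------

def _random_const(rng, ranges: np.ndarray) -> Node:
    j = rng.integers(ranges.shape[0])
    lo, hi = ranges[j]
    return Node("const", value=float(rng.uniform(lo, hi)))


def _random_real(rng, ranges, depth: int) -> Node:
    if depth <= 1 or rng.random() < 0.4:
        if rng.random() < 0.7:
            return Node("feat", feature=int(rng.integers(ranges.shape[0])))
        return _random_const(rng, ranges)
    op = _ARITH[rng.integers(len(_ARITH))]
    return Node(
        op, [_random_real(rng, ranges, depth - 1) for _ in range(2)]
    )


def _random_bool(rng, ranges, depth: int) -> Node:
    # a Boolean subtree needs >= 2 levels (comparison over real leaves)
    if depth <= 2 or rng.random() < 0.5:
        op = _CMP[rng.integers(len(_CMP))]
        return Node(
            op,
            [
                _random_real(rng, ranges, max(depth - 1, 1))
                for _ in range(2)
            ],
        )
    op = _BOOL_BRANCH[rng.integers(len(_BOOL_BRANCH))]
    ret, args = _OPS[op]
    kids = [
        _random_bool(rng, ranges, depth - 1)
        if t == "bool"
        else _random_real(rng, ranges, depth - 1)
        for t in args
    ]
    return Node(op, kids)


def _random_tree(rng, ranges, ret_type: str, max_depth: int,
                 max_length: int) -> Node:
    for _ in range(50):
        depth = int(rng.integers(2, max(max_depth, 3)))
        tree = (
            _random_bool(rng, ranges, depth)
            if ret_type == "bool"
            else _random_real(rng, ranges, depth)
        )
        if tree.length() <= max_length and tree.depth() <= max_depth:
            return tree
    # minimal fallbacks always satisfy any admissible limit
    if ret_type == "bool":
        return Node(
            "gt",
            [
                Node("feat", feature=int(rng.integers(ranges.shape[0]))),
                _random_const(rng, ranges),
            ],
        )
    return Node("feat", feature=int(rng.integers(ranges.shape[0])))


def _collect(node: Node, out: list, depth: int = 1) -> None:
    out.append((node, depth))
    for c in node.children:
        _collect(c, out, depth + 1)


def _replace_node(root: Node, target: Node, repl: Node) -> Node:
    if root is target:
        return repl
    root.children = [
        _replace_node(c, target, repl) for c in root.children
    ]
    return root


# ---------------------------------------------------------------------------
# variation operators
# ---------------------------------------------------------------------------

def _crossover(rng, p1: Node, p2: Node) -> Node:
    child = p1.clone()
    nodes1: list = []
    _collect(child, nodes1)
    nodes2: list = []
    _collect(p2, nodes2)
    node, _ = nodes1[rng.integers(len(nodes1))]
    want = node.ret_type
    donors = [n for n, _ in nodes2 if n.ret_type == want]
    if not donors:
        return child
    donor = donors[rng.integers(len(donors))].clone()
    return _replace_node(child, node, donor)


def _mut_replace_branch(rng, ranges, tree: Node, cfg: GPConfig) -> Node:
    nodes: list = []
    _collect(tree, nodes)
    node, depth = nodes[rng.integers(len(nodes))]
    budget = max(cfg.max_tree_depth - depth + 1, 2)
    repl = _random_tree(
        rng, ranges, node.ret_type, budget, cfg.max_tree_length
    )
    return _replace_node(tree, node, repl)


def _mut_change_node_type(rng, ranges, tree: Node, cfg: GPConfig) -> Node:
    nodes: list = []
    _collect(tree, nodes)
    mutable = [
        n
        for n, _ in nodes
        if n.op in _CMP
        or n.op in _LOGIC2
        or n.op in _ARITH
        or n.op in ("feat", "const")
    ]
    if not mutable:
        return tree
    node = mutable[rng.integers(len(mutable))]
    if node.op in _CMP:
        node.op = _CMP[rng.integers(len(_CMP))]
    elif node.op in _LOGIC2:
        node.op = _LOGIC2[rng.integers(len(_LOGIC2))]
    elif node.op in _ARITH:
        node.op = _ARITH[rng.integers(len(_ARITH))]
    elif node.op == "feat":
        node.feature = int(rng.integers(ranges.shape[0]))
    else:
        new = _random_const(rng, ranges)
        node.value = new.value
    return tree


def _mut_full_shaker(rng, ranges, tree: Node, cfg: GPConfig) -> Node:
    nodes: list = []
    _collect(tree, nodes)
    for n, _ in nodes:
        if n.op == "const":
            n.value = _random_const(rng, ranges).value
    return tree


def _mut_one_point_shaker(rng, ranges, tree: Node, cfg: GPConfig) -> Node:
    nodes: list = []
    _collect(tree, nodes)
    consts = [n for n, _ in nodes if n.op == "const"]
    if consts:
        node = consts[rng.integers(len(consts))]
        node.value = _random_const(rng, ranges).value
    return tree


_MUTATORS = (
    _mut_replace_branch,
    _mut_change_node_type,
    _mut_full_shaker,
    _mut_one_point_shaker,
)


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def _as_xy(
    X, y, feature_names=None
) -> tuple[np.ndarray, np.ndarray, tuple[str, str], tuple[str, ...]]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype == bool:
        classes = ("gradeII", "gradeIV")
        ybin = y
    else:
        uniq = sorted(str(u) for u in np.unique(y))
        if len(uniq) != 2:
            raise ValueError(
                f"need exactly 2 classes, got {len(uniq)}: {uniq}"
            )
        classes = (uniq[0], uniq[1])
        ybin = np.asarray([str(v) for v in y]) == classes[1]
    names = tuple(feature_names) if feature_names else tuple(
        FEATURE_NAMES[: X.shape[1]]
    )
    return X, ybin, classes, names


def gp_train(
    X,
    y,
    cfg: GPConfig,
    rng: np.random.Generator | None = None,
    feature_names: Sequence[str] | None = None,
) -> GPModel:
    """Evolve a symbolic classifier on a training set.

    ``y`` may be a Boolean array (True = positive class) or an array of
    two label strings (the lexicographically larger is positive, so
    grade IV is the positive class).  Requires at least two samples per
    class.
    """
    X, ybin, classes, names = _as_xy(X, y, feature_names)
    if ybin.all() or (~ybin).all() or min(
        np.count_nonzero(ybin), np.count_nonzero(~ybin)
    ) < 2:
        raise ValueError("training set needs >= 2 samples of each class")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    lo = X.min(axis=0)
    hi = X.max(axis=0)
    same = hi == lo
    ranges = np.column_stack([lo - same, hi + same])

    def fitness(tree: Node) -> float:
        pred = np.asarray(_eval(tree, X), dtype=bool)
        return float(np.mean(pred == ybin))

    pop = [
        _random_tree(rng, ranges, "bool", cfg.max_tree_depth,
                     cfg.max_tree_length)
        for _ in range(cfg.population_size)
    ]
    fits = [fitness(t) for t in pop]

    def tournament() -> Node:
        idx = rng.integers(len(pop), size=cfg.tournament_size)
        best = max(idx, key=lambda i: fits[i])
        return pop[best]

    p_mut = cfg.mutation_probability_percent / 100.0
    for _ in range(cfg.max_generations):
        if max(fits) >= 1.0:
            break
        order = np.argsort(fits)[::-1]
        new_pop = [pop[i].clone() for i in order[: cfg.elitism_count]]
        while len(new_pop) < cfg.population_size:
            p1 = tournament()
            if rng.random() < cfg.crossover_probability:
                child = _crossover(rng, p1, tournament())
            else:
                child = p1.clone()
            if rng.random() < p_mut:
                mut = _MUTATORS[rng.integers(len(_MUTATORS))]
                child = mut(rng, ranges, child, cfg)
            if (
                child.depth() <= cfg.max_tree_depth
                and child.length() <= cfg.max_tree_length
            ):
                new_pop.append(child)
            else:
                new_pop.append(p1.clone())
        pop = new_pop
        fits = [fitness(t) for t in pop]

    best = int(np.argmax(fits))
    return GPModel(
        tree=pop[best],
        feature_names=names,
        classes=classes,
        training_accuracy=fits[best],
    )


@dataclass
class CVResult:
    """Repeated stratified cross-validation outcome."""

    fold_accuracies: np.ndarray  # (n_runs, n_folds)
    run_means: np.ndarray
    best_run: int
    best_run_accuracy: float
    best_models: list  # per run: fold model with highest test accuracy
    fold_models: list  # per run: list of per-fold models
    n_runs: int
    n_folds: int
    seeds: list[int]
    config: GPConfig | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(self.run_means.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.run_means.std(ddof=1)) if self.n_runs > 1 else 0.0

    def summary(self) -> str:
        lines = [
            "GP cross-validation",
            f"  runs x folds        : {self.n_runs} x {self.n_folds}",
            f"  mean accuracy       : {self.mean_accuracy:.4f}"
            f" +/- {self.std_accuracy:.4f}",
            f"  best run            : #{self.best_run}"
            f"  accuracy {self.best_run_accuracy:.4f}",
        ]
        if self.best_models:
            lines.append(
                f"  best run model      : {self.best_models[self.best_run]}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies.tolist(),
            "run_means": self.run_means.tolist(),
            "best_run": int(self.best_run),
            "best_run_accuracy": float(self.best_run_accuracy),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "n_runs": self.n_runs,
            "n_folds": self.n_folds,
            "seeds": [int(s) for s in self.seeds],
            "best_models": [str(m) for m in self.best_models],
        }


def _stratified_folds(ybin: np.ndarray, n_folds: int, seed: int):
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(ybin, dtype=float), ybin))


def cross_validate(
    X,
    y,
    cfg: GPConfig,
    folds: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    feature_names: Sequence[str] | None = None,
) -> CVResult:
    """Stratified n-fold CV repeated n_runs times with derived seeds.

    Each run re-shuffles the stratified folds (unless explicit
    ``folds`` are supplied) and reports the mean test accuracy over
    folds; the overall report carries the best run and the mean +/-
    std across runs.  Model selection inside a fold uses only that
    fold's training portion.
    """
    X, ybin, classes, names = _as_xy(X, y, feature_names)
    counts = np.bincount(ybin.astype(int), minlength=2)
    loo = cfg.n_folds == len(ybin)  # leave-one-out: singleton test folds
    if folds is None and not loo and counts.min() < cfg.n_folds:
        raise ValueError(
            f"each class needs >= n_folds={cfg.n_folds} samples, "
            f"got {counts.tolist()}"
        )
    ss = np.random.SeedSequence(cfg.seed)
    run_seeds = [int(s) for s in ss.generate_state(cfg.n_runs) % (2**31)]

    n_folds = len(folds) if folds is not None else cfg.n_folds
    fold_acc = np.zeros((cfg.n_runs, n_folds))
    best_models: list[GPModel] = []
    fold_models: list[list[GPModel]] = []
    for r, run_seed in enumerate(run_seeds):
        if folds is not None:
            run_folds = folds
        elif loo:
            idx = np.arange(len(ybin))
            run_folds = [
                (np.delete(idx, i), np.array([i])) for i in idx
            ]
        else:
            run_folds = _stratified_folds(ybin, n_folds, run_seed)
        rng = np.random.default_rng(run_seed)
        best_fold_acc, best_fold_model = -1.0, None
        run_models: list[GPModel] = []
        for k, (train, test) in enumerate(run_folds):
            model = gp_train(
                X[train], ybin[train], cfg, rng=rng, feature_names=names
            )
            model.classes = classes
            acc = float(
                np.mean(model.predict(X[test]) == ybin[test])
            )
            fold_acc[r, k] = acc
            run_models.append(model)
            if acc > best_fold_acc:
                best_fold_acc, best_fold_model = acc, model
        best_models.append(best_fold_model)
        fold_models.append(run_models)

    run_means = fold_acc.mean(axis=1)
    best_run = int(np.argmax(run_means))
    return CVResult(
        fold_accuracies=fold_acc,
        run_means=run_means,
        best_run=best_run,
        best_run_accuracy=float(run_means[best_run]),
        best_models=best_models,
        fold_models=fold_models,
        n_runs=cfg.n_runs,
        n_folds=n_folds,
        seeds=run_seeds,
        config=cfg,
    )


def grid_search(
    X,
    y,
    cfg: GPConfig,
    grid: dict[str, tuple] | None = None,
) -> list[tuple[GPConfig, CVResult]]:
    """Cross-validate every configuration of the parameter grid.

    The default grid is the reference 2x2x2x3 = 24-configuration
    Cartesian product.  Results are ranked by best-run accuracy,
    non-increasing; every configuration's result is retained.
    """
    if grid is None:
        grid = DEFAULT_PARAM_GRID
    if not grid:
        raise ValueError("grid must be non-empty")
    keys = sorted(grid)
    results = []
    for i, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        sub = replace(cfg, **dict(zip(keys, combo)), seed=cfg.seed + i)
        results.append((sub, cross_validate(X, y, sub)))
    results.sort(key=lambda item: item[1].best_run_accuracy, reverse=True)
    return results


# ---------------------------------------------------------------------------
# model/results surface
# ---------------------------------------------------------------------------

class GPClassifier:
    """Symbolic-classification model over a labeled feature table.

    Parameters
    ----------
    X
        (n_samples, n_features) matrix of curve descriptors.
    y
        Class labels (two classes; the lexicographically larger label,
        e.g. ``gradeIV``, is the positive class) or a Boolean array.
    feature_names
        Column names; defaults to the canonical 15 descriptor names.
    config
        :class:`GPConfig`; defaults are the package defaults.
    """

    def __init__(self, X, y, feature_names=None, config: GPConfig | None = None):
        self.config = config or GPConfig()
        self.X, self.ybin, self.classes, self.feature_names = _as_xy(
            X, y, feature_names
        )

    @classmethod
    def from_dataframe(cls, df, label_col: str = "label",
                       feature_cols=None, config=None) -> "GPClassifier":
        cols = list(feature_cols) if feature_cols else [
            c for c in FEATURE_NAMES if c in df.columns
        ]
        return cls(
            df[cols].to_numpy(float),
            df[label_col].to_numpy(),
            feature_names=cols,
            config=config,
        )

    @classmethod
    def from_feature_vectors(cls, fvs: Sequence[FeatureVector],
                             config=None) -> "GPClassifier":
        X = np.stack([fv.as_array() for fv in fvs])
        y = np.asarray([fv.label for fv in fvs])
        return cls(X, y, config=config)

    def fit(self, seed: int | None = None) -> "GPResults":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        model = gp_train(
            self.X, self.ybin, cfg, feature_names=self.feature_names
        )
        model.classes = self.classes
        return GPResults(model=model, config=cfg, classifier=self)

    def cross_validate(self, **overrides) -> CVResult:
        cfg = replace(self.config, **overrides) if overrides else self.config
        return cross_validate(
            self.X, self.ybin, cfg, feature_names=self.feature_names
        )

    def grid_search(self, grid=None) -> list[tuple[GPConfig, CVResult]]:
        return grid_search(self.X, self.ybin, self.config, grid=grid)


@dataclass
class GPResults:
    """Fit results: the best-of-run expression tree and diagnostics."""

    model: GPModel
    config: GPConfig
    classifier: GPClassifier | None = None

    def predict(self, X) -> np.ndarray:
        return self.model.predict_labels(np.asarray(X, dtype=float))

    def summary(self) -> str:
        m = self.model
        lines = [
            "GP symbolic classifier",
            f"  classes (neg/pos)   : {m.classes[0]} / {m.classes[1]}",
            f"  training accuracy   : {m.training_accuracy:.4f}",
            f"  tree depth / length : {m.depth} / {m.length}",
            f"  model               : {m}",
            f"  config              : generations={self.config.max_generations}"
            f" pop={self.config.population_size}"
            f" mut={self.config.mutation_probability_percent}%"
            f" depth<={self.config.max_tree_depth}"
            f" length<={self.config.max_tree_length}"
            f" seed={self.config.seed}",
        ]
        return "\n".join(lines)
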