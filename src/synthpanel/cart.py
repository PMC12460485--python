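"""Classification and regression trees with leaf-donor sampling.

This is the base model of every synthesis condition: a greedy binary
recursive partition fitted on observed data, whose leaves retain the
*observed* response values ("donors").  Synthesis routes a new record to
its leaf and draws one donor uniformly, so every synthetic value is an
observed value (no smoothing) — the classic sequential tree-based
statistical-disclosure-control mechanism.

Conventions (deliberately deterministic):

* impurity is the within-node sum of squared deviations for a continuous
  response and ``n * Gini`` for a categorical one;
* numeric splits are found by an exhaustive scan over midpoints between
  consecutive distinct values;
* categorical predictors are ordered per node by mean response (event rate
  for a binary response) and scanned as if ordered — the classic CART
  optimality shortcut, exact for binary/continuous responses;
* a split is accepted only if both children hold at least ``min_leaf``
  records, the node holds at least ``min_split``, and the impurity decrease
  is at least ``complexity`` times the root impurity (rpart's ``cp``
  semantics);
* ties are broken toward the lowest predictor index, then the smallest
  threshold / shortest left level-prefix;
* at prediction time an unseen category routes to the split side that held
  the majority of training records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TreeHyperparams", "FittedTree", "fit_tree", "assign_leaf", "synthesize_variable"]


@dataclass(frozen=True)
class TreeHyperparams:
    """Stopping rules; defaults follow the conventional CART-synthesis
    package defaults (min_leaf 5, near-zero complexity, no depth cap)."""

    min_leaf: int = 5
    min_split: int = 10
    complexity: float = 1e-8
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.min_split < 2 * self.min_leaf:
            raise ValueError("min_split must be >= 2 * min_leaf")
        if self.complexity < 0:
            raise ValueError("complexity must be >= 0")


@dataclass
class _Node:
    # Leaf: donor_values set, children None.  Internal: split info set.
    leaf_id: int = -1
    donor_values: np.ndarray | None = None
    predictor: str | None = None
    predictor_index: int = -1
    is_categorical: bool = False
    threshold: float = np.nan
    left_levels: frozenset = field(default_factory=frozenset)
    right_levels: frozenset = field(default_factory=frozenset)
    majority_left: bool = True
    decrease: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class FittedTree:
    """A fitted recursive partition with donor multisets per leaf."""

    root: _Node
    predictors: list[str]
    categorical: frozenset
    response_kind: str
    hyperparams: TreeHyperparams
    n_leaves: int

    def apply(self, X: pd.DataFrame) -> np.ndarray:
        """Vectorised leaf assignment; returns an int leaf id per row."""
        for name in self.predictors:
            if name not in X.columns:
                raise KeyError(f"predictor {name!r} missing at prediction time")
            if X[name].isna().any():
                raise ValueError(f"predictor {name!r} has missing values at prediction time")
        out = np.empty(len(X), dtype=np.int64)
        cols = {name: X[name].to_numpy() for name in self.predictors}
        idx = np.arange(len(X))
        stack = [(self.root, idx)]
        while stack:
            node, rows = stack.pop()
            if rows.size == 0:
                continue
            if node.is_leaf:
                out[rows] = node.leaf_id
                continue
            vals = cols[node.predictor][rows]
            if node.is_categorical:
                in_left = np.isin(vals, list(node.left_levels))
                in_right = np.isin(vals, list(node.right_levels))
                unseen = ~(in_left | in_right)
                if unseen.any():
                    if node.majority_left:
                        in_left = in_left | unseen
                    else:
                        in_right = in_right | unseen
                go_left = in_left
            else:
                go_left = vals.astype(float) <= node.threshold
            stack.append((node.left, rows[go_left]))
            stack.append((node.right, rows[~go_left]))
        return out

    def leaves(self) -> dict[int, np.ndarray]:
        """Map leaf id -> donor value array."""
        found: dict[int, np.ndarray] = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                found[node.leaf_id] = node.donor_values
            else:
                stack.extend([node.left, node.right])
        return found

    def internal_nodes(self) -> list[_Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend([node.left, node.right])
        return out

    def to_dict(self) -> dict:
        """Serialisable description (for the release sheet)."""

        def rec(node: _Node) -> dict:
            if node.is_leaf:
                return {"leaf": node.leaf_id, "n_donors": int(len(node.donor_values))}
            split = {
                "predictor": node.predictor,
                "decrease": float(node.decrease),
            }
            if node.is_categorical:
                split["left_levels"] = sorted(map(str, node.left_levels))
            else:
                split["threshold"] = float(node.threshold)
            split["left"] = rec(node.left)
            split["right"] = rec(node.right)
            return split

        return {
            "response_kind": self.response_kind,
            "predictors": list(self.predictors),
            "n_leaves": self.n_leaves,
            "tree": rec(self.root),
        }


def _impurity_continuous(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2)) if y.size else 0.0


def _impurity_categorical(onehot: np.ndarray) -> float:
    # n * Gini = n - sum_k n_k^2 / n
    n = onehot.shape[0]
    if n == 0:
        return 0.0
    counts = onehot.sum(axis=0)
    return float(n - np.dot(counts, counts) / n)


def _best_split_ordered(
    sort_vals: np.ndarray,
    y_sorted: np.ndarray,
    onehot_sorted: np.ndarray | None,
    min_leaf: int,
) -> tuple[float, int] | None:
    """Best boundary on an already value-sorted column.

    Returns (impurity_decrease_children_total, boundary_index) where the
    left child is rows [0:boundary) — or None if no admissible boundary.
    The scan visits boundaries in ascending order and keeps the first
    maximiser, so ties resolve to the smallest threshold.
    """
    n = sort_vals.shape[0]
    if n < 2 * min_leaf:
        return None
    # admissible boundaries: between distinct values, both children >= min_leaf
    cut = np.arange(min_leaf, n - min_leaf + 1)
    distinct = sort_vals[cut - 1] != sort_vals[cut]
    cut = cut[distinct]
    if cut.size == 0:
        return None
    if onehot_sorted is None:
        s1 = np.cumsum(y_sorted)
        s2 = np.cumsum(y_sorted**2)
        n_left = cut.astype(float)
        sl1, sl2 = s1[cut - 1], s2[cut - 1]
        sse_left = sl2 - sl1**2 / n_left
        n_right = n - n_left
        sr1, sr2 = s1[-1] - sl1, s2[-1] - sl2
        sse_right = sr2 - sr1**2 / n_right
        child = sse_left + sse_right
    else:
        csum = np.cumsum(onehot_sorted, axis=0)
        n_left = cut.astype(float)
        left_counts = csum[cut - 1]
        right_counts = csum[-1] - left_counts
        n_right = n - n_left
        gini_left = n_left - np.einsum("ij,ij->i", left_counts, left_counts) / n_left
        gini_right = n_right - np.einsum("ij,ij->i", right_counts, right_counts) / n_right
        child = gini_left + gini_right
    best = int(np.argmin(child))  # first minimum -> smallest threshold on ties
    return float(child[best]), int(cut[best])


def fit_tree(
    predictors: pd.DataFrame,
    response,
    kind: str,
    hp: TreeHyperparams | None = None,
    categorical: list[str] | None = None,
) -> FittedTree:
    """Fit a CART on complete rows of ``predictors`` against ``response``.

    ``kind`` is ``"continuous"`` or ``"categorical"``.  Columns listed in
    ``categorical`` (plus object/categorical dtypes) are treated as nominal.
    A constant response yields a root-only tree — not an error.
    """
    hp = hp or TreeHyperparams()
    if kind not in ("continuous", "categorical"):
        raise ValueError("kind must be 'continuous' or 'categorical'")
    names = list(predictors.columns)
    if not names:
        raise ValueError("at least one predictor is required")
    y = np.asarray(response)
    n = y.shape[0]
    if n == 0:
        raise ValueError("empty training data")
    if len(predictors) != n:
        raise ValueError("predictors and response have different lengths")
    if predictors.isna().any().any() or pd.isna(pd.Series(y)).any():
        raise ValueError("missing values among training rows")

    cat_names = set(categorical or [])
    for name in names:
        dt = predictors[name].dtype
        if dt == object or isinstance(dt, pd.CategoricalDtype):
            cat_names.add(name)
    cols = {name: predictors[name].to_numpy() for name in names}

    if kind == "continuous":
        y_num = y.astype(float)
        onehot = None
        # score used only to order categorical levels
        level_score = y_num
    else:
        classes, y_codes = np.unique(y, return_inverse=True)
        onehot = np.eye(len(classes))[y_codes]
        y_num = y_codes.astype(float)
        # binary: event rate of the last class; multiclass falls back to the
        # mean class code, adequate for the binary responses used here.
        level_score = onehot[:, -1] if len(classes) == 2 else y_num

    def node_impurity(rows: np.ndarray) -> float:
        if onehot is None:
            return _impurity_continuous(y_num[rows])
        return _impurity_categorical(onehot[rows])

    root_impurity = node_impurity(np.arange(n))
    min_decrease = hp.complexity * root_impurity
    leaf_counter = [0]

    def make_leaf(rows: np.ndarray) -> _Node:
        node = _Node(leaf_id=leaf_counter[0], donor_values=y[rows].copy())
        leaf_counter[0] += 1
        return node

    def grow(rows: np.ndarray, depth: int) -> _Node:
        node_imp = node_impurity(rows)
        if (
            rows.size < hp.min_split
            or node_imp <= 0
            or (hp.max_depth is not None and depth >= hp.max_depth)
        ):
            return make_leaf(rows)

        best = None  # (decrease, j, payload); strict > keeps lowest j on ties
        for j, name in enumerate(names):
            vals = cols[name][rows]
            if name in cat_names:
                levels, codes = np.unique(vals, return_inverse=True)
                if levels.shape[0] < 2:
                    continue
                means = np.zeros(levels.shape[0])
                np.add.at(means, codes, level_score[rows])
                counts = np.bincount(codes, minlength=levels.shape[0]).astype(float)
                means /= counts
                # order levels by mean response; ties by level position
                order = np.argsort(means, kind="stable")
                rank = np.empty_like(order)
                rank[order] = np.arange(order.shape[0])
                ordered = rank[codes].astype(float)
                srt = np.argsort(ordered, kind="stable")
                res = _best_split_ordered(
                    ordered[srt],
                    y_num[rows][srt],
                    onehot[rows][srt] if onehot is not None else None,
                    hp.min_leaf,
                )
                if res is None:
                    continue
                child_imp, boundary = res
                decrease = node_imp - child_imp
                if best is None or decrease > best[0] + 1e-12:
                    n_left_rank = int(ordered[srt][boundary - 1]) + 1
                    left_lv = frozenset(levels[order[:n_left_rank]].tolist())
                    right_lv = frozenset(levels[order[n_left_rank:]].tolist())
                    n_left = int(np.sum(ordered < n_left_rank))
                    best = (decrease, j, ("cat", left_lv, right_lv, n_left, rows.size - n_left))
            else:
                fvals = vals.astype(float)
                srt = np.argsort(fvals, kind="stable")
                res = _best_split_ordered(
                    fvals[srt],
                    y_num[rows][srt],
                    onehot[rows][srt] if onehot is not None else None,
                    hp.min_leaf,
                )
                if res is None:
                    continue
                child_imp, boundary = res
                decrease = node_imp - child_imp
                if best is None or decrease > best[0] + 1e-12:
                    thr = 0.5 * (fvals[srt][boundary - 1] + fvals[srt][boundary])
                    best = (decrease, j, ("num", thr))

        if best is None or best[0] < max(min_decrease, 1e-12):
            return make_leaf(rows)

        decrease, j, payload = best
        name = names[j]
        vals = cols[name][rows]
        if payload[0] == "cat":
            _, left_lv, right_lv, n_left, n_right = payload
            go_left = np.isin(vals, list(left_lv))
            node = _Node(
                predictor=name,
                predictor_index=j,
                is_categorical=True,
                left_levels=left_lv,
                majority_left=n_left >= n_right,
                decrease=decrease,
            )
            node.right_levels = right_lv
        else:
            thr = payload[1]
            go_left = vals.astype(float) <= thr
            node = _Node(
                predictor=name,
                predictor_index=j,
                is_categorical=False,
                threshold=thr,
                decrease=decrease,
            )
        node.left = grow(rows[go_left], depth + 1)
        node.right = grow(rows[~go_left], depth + 1)
        return node

    root = grow(np.arange(n), 0)
    return FittedTree(
        root=root,
        predictors=names,
        categorical=frozenset(cat_names),
        response_kind=kind,
        hyperparams=hp,
        n_leaves=leaf_counter[0],
    )


def assign_leaf(tree: FittedTree, row: pd.DataFrame | pd.Series | dict) -> int:
    """Deterministic leaf id for one predictor record."""
    if isinstance(row, dict):
        row = pd.DataFrame([row])
    elif isinstance(row, pd.Series):
        row = row.to_frame().T
    return int(tree.apply(row)[0])


def synthesize_variable(
    tree: FittedTree,
    new_predictors: pd.DataFrame,
    rng: np.random.Generator,
    proper: bool = False,
) -> np.ndarray:
    """Draw one donor value per row from each row's assigned leaf.

    ``proper=True`` bootstraps each leaf's donor multiset before drawing
    (proper synthesis); the default draws directly from fitted leaves
    (improper synthesis, the conventional package default).
    """
    leaf_ids = tree.apply(new_predictors)
    donors = tree.leaves()
    if proper:
        donors = {
            k: v[rng.integers(0, len(v), size=len(v))] for k, v in sorted(donors.items())
        }
    out = np.empty(len(new_predictors), dtype=np.asarray(next(iter(donors.values()))).dtype)
    for leaf_id in np.unique(leaf_ids):
        pool = donors[int(leaf_id)]
        if pool is None or len(pool) == 0:
            raise RuntimeError(f"leaf {leaf_id} has no donors")  # impossible by invariant
        mask = leaf_ids == leaf_id
        out[mask] = pool[rng.integers(0, len(pool), size=int(mask.sum()))]
    return out
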