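"""Parsimony-based phylogenetic signal of a discrete tropism character.

The trait is the per-line tropism frequency binned into three unordered
states (low/no, moderate, high).  Goodness of fit of the character to a
phylogeny is its *tree length*: the minimum number of unordered state changes
needed to map the character onto the tree (Fitch parsimony; Hartigan's
generalization at polytomies).  Significance is assessed by a randomization
test: the observed length is compared against lengths of characters obtained
by uniformly permuting the observed tip states across the tips, and
``p = #{null <= observed} / n_random`` — the probability of a fit as good or
better arising by chance.  A character that fits no better than random
permutations yields p near (or exactly) 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .synthetic_data import TraitSimSpec, simulate_character

__all__ = [
    "bin_frequency",
    "fitch_length",
    "ParsimonyRandomization",
    "PhyloSignalResult",
    "randomization_test",
    "trace_report",
    "load_tree",
]

#: Frequency bins (percent) for the three-state tropism character:
#: [0, 10) -> low, [10, 60) -> moderate, [60, 100] -> high.
STATE_LOW = "low"
STATE_MODERATE = "moderate"
STATE_HIGH = "high"
_BIN_EDGES = (10.0, 60.0)


def bin_frequency(frequency: float) -> str:
    """Map a tropism frequency in percent onto the three-state character."""
    if not 0.0 <= frequency <= 100.0:
        raise ValueError(f"frequency must be in [0, 100], got {frequency}")
    if frequency < _BIN_EDGES[0]:
        return STATE_LOW
    if frequency < _BIN_EDGES[1]:
        return STATE_MODERATE
    return STATE_HIGH


def load_tree(path_or_string, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted leaf-labeled tree (newick by default)."""
    import os

    kwargs = {"preserve_underscores": True} if schema == "newick" else {}
    if isinstance(path_or_string, (str, os.PathLike)) and os.path.exists(path_or_string):
        tree = dendropy.Tree.get(path=str(path_or_string), schema=schema, **kwargs)
    else:
        tree = dendropy.Tree.get(data=str(path_or_string), schema=schema, **kwargs)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 leaves")
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels must be unique")
    return tree


def fitch_length(tree: dendropy.Tree, states: dict[str, str]) -> int:
    """Minimum number of unordered state changes of ``states`` on ``tree``.

    A single postorder pass; at a node whose children carry state sets
    S_1..S_c, each state is scored by how many child sets contain it, the node
    keeps the majority states, and ``c - max_count`` changes are added
    (Hartigan's rule, which reduces to Fitch intersection/union on binary
    nodes and is exact on polytomies).
    """
    steps = 0
    node_sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else None
            if label not in states:
                raise KeyError(f"no state for leaf {label!r}")
            node_sets[id(node)] = frozenset([states[label]])
            continue
        children = node.child_nodes()
        counts: dict[str, int] = {}
        for child in children:
            for s in node_sets[id(child)]:
                counts[s] = counts.get(s, 0) + 1
        m = max(counts.values())
        steps += len(children) - m
        node_sets[id(node)] = frozenset(s for s, c in counts.items() if c == m)
    return steps


@dataclass
class PhyloSignalResult:
    """Result of a parsimony randomization test.

    Attributes
    ----------
    observed_length
        Tree length (steps) of the observed character.
    null_lengths
        Tree lengths of the ``n_random`` simulated characters.
    p_value
        Fraction of null lengths less than or equal to the observed length
        (ties count as a fit "as good").
    """

    observed_length: int
    null_lengths: np.ndarray
    p_value: float
    n_random: int
    seed: int | None
    null_model: str = "permutation"

    def null_histogram(self) -> pd.DataFrame:
        """Counts of null characters per tree length."""
        lengths, counts = np.unique(self.null_lengths, return_counts=True)
        return pd.DataFrame({"length": lengths.astype(int), "count": counts.astype(int)})

    def summary(self) -> str:
        hist = self.null_histogram()
        lines = [
            "Parsimony randomization test",
            "============================",
            f"observed tree length : {self.observed_length} steps",
            f"null model           : {self.null_model} ({self.n_random} characters"
            + (f", seed {self.seed})" if self.seed is not None else ")"),
            f"null length range    : {int(hist['length'].min())}-{int(hist['length'].max())}",
            f"P(fit as good or better by chance) = {self.p_value:.4g}",
        ]
        return "\n".join(lines)

    def plot_null(self, ax=None):
        """Histogram of null tree lengths with the observed length marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = self.null_histogram()
        ax.bar(hist["length"], hist["count"], width=0.8, color="0.6", label="null")
        ax.axvline(self.observed_length, color="crimson", label="observed")
        ax.set_xlabel("tree length (steps)")
        ax.set_ylabel("random characters")
        ax.legend()
        return ax


class ParsimonyRandomization:
    """Model object: a tree plus an observed discrete character.

    ``fit`` runs the randomization test and returns a
    :class:`PhyloSignalResult`.

    Parameters
    ----------
    tree
        Rooted leaf-labeled tree (branch lengths ignored).
    states
        Mapping of every leaf label to its character state.
    null_model
        ``"permutation"`` (default): uniform relabelings of the observed
        multiset, so every null character has exactly the observed state
        counts.  ``"multinomial"``: i.i.d. tip states drawn with the observed
        state proportions.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        states: dict[str, str],
        null_model: str = "permutation",
    ):
        if null_model not in ("permutation", "multinomial"):
            raise ValueError(f"unknown null model {null_model!r}")
        self.tree = tree
        self.leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        missing = [lbl for lbl in self.leaf_labels if lbl not in states]
        if missing:
            raise KeyError(f"no state for leaves: {missing}")
        self.states = {lbl: states[lbl] for lbl in self.leaf_labels}
        self.null_model = null_model

    @classmethod
    def from_frequencies(
        cls,
        tree: dendropy.Tree,
        frequencies: dict[str, float],
        null_model: str = "permutation",
    ) -> "ParsimonyRandomization":
        """Build the model from per-line tropism frequencies in percent."""
        return cls(
            tree,
            {label: bin_frequency(f) for label, f in frequencies.items()},
            null_model=null_model,
        )

    @property
    def observed_length(self) -> int:
        return fitch_length(self.tree, self.states)

    def fit(self, n_random: int = 1000, seed: int | None = None) -> PhyloSignalResult:
        if n_random < 1:
            raise ValueError("n_random must be >= 1")
        rng = np.random.default_rng(seed)
        observed = self.observed_length
        values = list(self.states.values())
        n = len(values)
        null_lengths = np.empty(n_random, dtype=int)
        if self.null_model == "permutation":
            multiset: dict[str, int] = {}
            for s in values:
                multiset[s] = multiset.get(s, 0) + 1
            spec = TraitSimSpec(model="permutation", state_multiset=multiset)
            for i in range(n_random):
                null_lengths[i] = fitch_length(
                    self.tree, simulate_character(self.tree, spec, rng=rng)
                )
        else:  # multinomial
            alphabet = sorted(set(values))
            probs = np.array([values.count(s) for s in alphabet], float)
            probs /= probs.sum()
            for i in range(n_random):
                draw = rng.choice(alphabet, size=n, p=probs)
                null_lengths[i] = fitch_length(
                    self.tree, dict(zip(self.leaf_labels, draw))
                )
        p = float(np.count_nonzero(null_lengths <= observed)) / n_random
        return PhyloSignalResult(
            observed_length=observed,
            null_lengths=null_lengths,
            p_value=p,
            n_random=n_random,
            seed=seed,
            null_model=self.null_model,
        )


def randomization_test(
    tree: dendropy.Tree,
    states: dict[str, str],
    n_random: int = 1000,
    seed: int | None = None,
    null_model: str = "permutation",
) -> PhyloSignalResult:
    """Convenience wrapper: build the model and fit in one call."""
    return ParsimonyRandomization(tree, states, null_model=null_model).fit(
        n_random=n_random, seed=seed
    )


def trace_report(
    tree: dendropy.Tree, states: dict[str, str], result: PhyloSignalResult
) -> dict:
    """Tabular report: observed length, null histogram, p, per-clade summary.

    The per-clade summary lists, for every internal node, the state counts of
    the leaves below it.
    """
    alphabet = sorted(set(states.values()))
    clade_rows = []
    clade_idx = 0
    leaf_cache: dict[int, list[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leaf_cache[id(node)] = [node.taxon.label]
            continue
        leaves = [l for c in node.child_nodes() for l in leaf_cache[id(c)]]
        leaf_cache[id(node)] = leaves
        row = {"clade": clade_idx, "n_leaves": len(leaves)}
        for s in alphabet:
            row[f"n_{s}"] = sum(1 for l in leaves if states[l] == s)
        clade_rows.append(row)
        clade_idx += 1
    return {
        "observed_length": result.observed_length,
        "p_value": result.p_value,
        "n_random": result.n_random,
        "null_model": result.null_model,
        "null_histogram": result.null_histogram(),
        "clade_summary": pd.DataFrame(clade_rows),
    }
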