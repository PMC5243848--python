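"""Pairwise identity/divergence matrices, group divergence summaries, and a
neighbor-joining tree for clade visualization.

Divergence is uncorrected p-distance x 100 by default (the scale on which
the conventional 16S and MLSA species thresholds are defined); a
Jukes-Cantor-corrected mode is available behind a flag.  Comparable columns
are counted with pairwise deletion (both residues non-gap, non-N) unless
complete deletion is requested.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from skbio.tree import TreeNode

from .seqio import Msa

_BASES = frozenset("ACGT")


@dataclass
class DistanceMatrix:
    """Symmetric percent identity or divergence matrix over labeled strains."""

    labels: list[str]
    values: np.ndarray
    mode: str = "divergence"  # or "identity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if self.mode not in ("identity", "divergence"):
            raise ValueError("mode must be 'identity' or 'divergence'")

    def to_divergence(self) -> "DistanceMatrix":
        if self.mode == "divergence":
            return self
        return DistanceMatrix(list(self.labels), 100.0 - self.values,
                              mode="divergence")

    def to_identity(self) -> "DistanceMatrix":
        if self.mode == "identity":
            return self
        return DistanceMatrix(list(self.labels), 100.0 - self.values,
                              mode="identity")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", lineterminator="\n")

    def to_phylip(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def identity_matrix(
    msa: Msa, mode: str = "identity", jc_correct: bool = False,
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """Percent identity (or divergence) between all pairs of an alignment.

    Identity = 100 x matches / compared, with *compared* counting columns
    where both residues are in {A,C,G,T} (pairwise deletion) or, with
    ``deletion="complete"``, columns unambiguous in every sequence.
    ``jc_correct`` applies the Jukes-Cantor correction to the divergence.
    """
    if len(msa) < 2:
        raise ValueError("identity matrix needs at least 2 sequences")
    arr = msa.to_array()
    valid = np.isin(arr, list(_BASES))
    if deletion == "complete":
        keep = valid.all(axis=0)
        arr = arr[:, keep]
        valid = valid[:, keep]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = len(msa)
    ident = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        compared = int(both.sum())
        if compared == 0:
            raise ValueError(
                f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
            )
        p = float((arr[i][both] != arr[j][both]).sum()) / compared
        if jc_correct:
            if p >= 0.75:
                raise ValueError(
                    f"p-distance {p:.3f} between {msa.ids[i]!r} and "
                    f"{msa.ids[j]!r} exceeds the Jukes-Cantor domain"
                )
            p = -0.75 * math.log1p(-4.0 * p / 3.0)
        ident[i, j] = ident[j, i] = 100.0 * (1.0 - p)
    dm = DistanceMatrix(list(msa.ids), ident, mode="identity")
    return dm if mode == "identity" else dm.to_divergence()


@dataclass
class GroupDivergence:
    """Within- and between-group divergence summaries (mean +/- SD, percent).

    SD uses the population divisor (n) over the fixed set of strain pairs.
    Within-group values are undefined (NaN) for singleton groups.
    """

    within: pd.DataFrame   # index: group; columns: mean, sd, n_pairs
    between: pd.DataFrame  # index: (group_a, group_b); columns: mean, sd, n_pairs

    def between_value(self, a: str, b: str) -> float:
        key = tuple(sorted((a, b)))
        return float(self.between.loc[key, "mean"])


def group_divergence(matrix: DistanceMatrix, grouping: dict[str, str]) -> GroupDivergence:
    """Summarize a divergence matrix by a strain -> group mapping.

    Within-group statistics run over unordered distinct pairs inside each
    group; between-group statistics over all cross pairs of each group pair.
    """
    dm = matrix.to_divergence()
    missing = [l for l in dm.labels if l not in grouping]
    if missing:
        raise ValueError(f"ungrouped labels: {missing}")
    groups: dict[str, list[int]] = {}
    for i, label in enumerate(dm.labels):
        groups.setdefault(grouping[label], []).append(i)
    if not groups:
        raise ValueError("no groups")

    within_rows = {}
    for g, idx in sorted(groups.items()):
        if len(idx) < 2:
            within_rows[g] = {"mean": np.nan, "sd": np.nan, "n_pairs": 0}
            continue
        vals = [dm.values[i, j] for i, j in itertools.combinations(idx, 2)]
        within_rows[g] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals)),  # population SD
            "n_pairs": len(vals),
        }
    between_rows = {}
    for ga, gb in itertools.combinations(sorted(groups), 2):
        vals = [dm.values[i, j] for i in groups[ga] for j in groups[gb]]
        between_rows[(ga, gb)] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals)),
            "n_pairs": len(vals),
        }
    within = pd.DataFrame.from_dict(within_rows, orient="index")
    between = pd.DataFrame.from_dict(between_rows, orient="index")
    if not between.empty:
        between.index = pd.MultiIndex.from_tuples(between.index)
    return GroupDivergence(within=within, between=between)


def nj_tree(matrix: DistanceMatrix) -> str:
    """Saitou-Nei neighbor-joining tree as a Newick string.

    Input must be a divergence-mode matrix with at least 3 labels.  Labels
    are presented to the join in sorted order so tie-breaking is
    deterministic; negative branch lengths are clamped to zero with the
    excess moved to the sibling edge.
    """
    if matrix.mode != "divergence":
        raise ValueError("nj_tree requires a divergence-mode matrix")
    if len(matrix.labels) < 3:
        raise ValueError("nj_tree needs at least 3 labels")
    order = sorted(range(len(matrix.labels)), key=lambda i: matrix.labels[i])
    labels = [matrix.labels[i] for i in order]
    values = matrix.values[np.ix_(order, order)]
    dm = skbio.DistanceMatrix(values, ids=labels)
    tree = skbio.tree.nj(dm, neg_as_zero=True)
    return str(tree).strip()


def is_monophyletic(newick: str, labels) -> bool:
    """True iff some edge bipartition of the tree separates exactly ``labels``."""
    tree = TreeNode.read([newick])
    tips = {t.name for t in tree.tips()}
    query = set(labels)
    unknown = query - tips
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if query == tips:
        return True
    for node in tree.traverse(include_self=False):
        clade = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if clade == query or tips - clade == query:
            return True
    return False
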