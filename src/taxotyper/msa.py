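"""Column-level alignment operations: masking, site classification,
composition, and pairwise global alignment.

``N`` is treated as missing data (like a gap) throughout: the manual
"elimination of ambiguous characters" step of typical 16S curation is
replaced by this deterministic rule.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .seqio import Msa, SequenceRecord

_BASES = ("A", "C", "G", "T")


@dataclass
class ColumnMask:
    """Original 1-based column indices retained after masking."""

    kept: list[int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.kept, self.kept[1:])):
            raise ValueError("mask indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.kept)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("kept_index\toriginal_index\n")
            for i, orig in enumerate(self.kept, start=1):
                fh.write(f"{i}\t{orig}\n")


@dataclass
class SiteClassification:
    """Counts of conserved / variable / parsimony-informative / singleton
    columns.  Assessed over non-gap, non-N residues only."""

    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.__dict__, fh, indent=2)
            fh.write("\n")

    def __add__(self, other: "SiteClassification") -> "SiteClassification":
        return SiteClassification(
            self.conserved + other.conserved,
            self.variable + other.variable,
            self.parsimony_informative + other.parsimony_informative,
            self.singleton + other.singleton,
        )


def mask_gappy_columns(
    msa: Msa, max_gap_fraction: float = 0.5
) -> tuple[Msa, ColumnMask]:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_fraction``.

    ``N`` counts as a gap for the purposes of this rule.  A column at exactly
    the threshold is kept (the rule is ``> max_gap_fraction``).
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    arr = msa.to_array()
    gap_frac = ((arr == "-") | (arr == "N")).mean(axis=0)
    kept = [int(i) + 1 for i in np.nonzero(gap_frac <= max_gap_fraction)[0]]
    if not kept:
        raise ValueError("masking removed every column")
    return msa.select_columns(kept), ColumnMask(kept)


def classify_sites(msa: Msa) -> SiteClassification:
    """Classify alignment columns by their nucleotide state pattern.

    Per column, over non-gap non-N residues: one state -> conserved;
    two or more states -> variable.  A variable column with at least two
    states each carried by at least two sequences is parsimony-informative;
    other variable columns are singleton-containing.  Columns with fewer
    than two informative residues are not assessed.
    """
    if len(msa) < 2:
        raise ValueError("site classification needs at least 2 sequences")
    conserved = variable = informative = singleton = 0
    arr = msa.to_array()
    for col in arr.T:
        counts = Counter(c for c in col if c in _BASES)
        if sum(counts.values()) < 2:
            continue
        if len(counts) == 1:
            conserved += 1
        else:
            variable += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative += 1
            else:
                singleton += 1
    return SiteClassification(conserved, variable, informative, singleton)


def gc_content(records) -> float:
    """Mean per-record G+C percentage over A/C/G/T residues.

    Gaps and N are excluded from the denominator.  Records with no A/C/G/T
    residues are excluded from the mean (with a warning).
    """
    import warnings

    if isinstance(records, (Msa,)):
        records = records.records
    if isinstance(records, SequenceRecord):
        records = [records]
    records = list(records)
    if not records:
        raise ValueError("gc_content needs at least one record")
    vals = []
    for r in records:
        counts = Counter(r.residues)
        total = sum(counts[b] for b in _BASES)
        if total == 0:
            warnings.warn(f"record {r.id!r} has no unambiguous residues; excluded")
            continue
        vals.append(100.0 * (counts["G"] + counts["C"]) / total)
    if not vals:
        raise ValueError("no record with unambiguous residues")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Pairwise global alignment (Gotoh affine-gap DP).
#
# Tie-breaking during traceback is fixed: prefer a substitution step over a
# gap, and among gaps prefer the gap in the second sequence.  This makes the
# aligned output a pure function of the inputs and scoring parameters.

_NEG = float("-inf")


def pairwise_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment of two ungapped sequences.

    Affine gap scoring: a gap of length L scores
    ``gap_open + (L - 1) * gap_extend``.  Returns the two aligned strings
    (equal length, '-' for gaps) and the optimal score.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else str(a)
    sb = b.residues if isinstance(b, SequenceRecord) else str(b)
    if not sa or not sb:
        raise ValueError("pairwise_align requires non-empty sequences")
    if "-" in sa or "-" in sb:
        raise ValueError("pairwise_align requires ungapped inputs")
    n, m = len(sa), len(sb)

    # M: both consumed; X: gap in b (a consumed); Y: gap in a (b consumed).
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if sa[i - 1] == sb[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)

    score = max(M[n, m], X[n, m], Y[n, m])
    # Traceback, preferring M, then X (gap in second sequence), then Y.
    i, j = n, m
    if M[i, j] == score:
        state = "M"
    elif X[i, j] == score:
        state = "X"
    else:
        state = "Y"
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = match if sa[i - 1] == sb[j - 1] else mismatch
            prev = M[i, j] - s
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i, j = i - 1, j - 1
            if M[i, j] == prev:
                state = "M"
            elif X[i, j] == prev:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            cur = X[i, j]
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + gap_open == cur:
                state = "M"
            elif X[i, j] + gap_extend == cur:
                state = "X"
            else:
                state = "Y"
        else:
            cur = Y[i, j]
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + gap_open == cur:
                state = "M"
            elif Y[i, j] + gap_extend == cur:
                state = "Y"
            else:
                state = "X"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)
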