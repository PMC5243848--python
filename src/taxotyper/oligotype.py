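"""Entropy-based oligotyping of marker-gene alignments.

An oligotype (OT) is the string of residues a sequence carries at a fixed,
ordered set of high-entropy alignment columns.  The workflow is: compute a
per-column Shannon entropy profile of a masked alignment, select the k
highest-entropy columns as the typing scheme (k = 12 by default, the
convention for 16S rRNA subtyping of the *Acidithiobacillus* complex),
extract each record's OT string, and classify strings against a catalog of
known oligotypes.

A transcribed catalog of the 18 named *Acidithiobacillus* species-complex
oligotypes ships with the package (:func:`load_default_catalog`).
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .seqio import Msa, SequenceRecord

_BASES = ("A", "C", "G", "T")

#: High-entropy positions of the canonical 12-position 16S scheme, in
#: E. coli 16S rRNA reference numbering, spanning variable regions V2-V6.
ECOLI_REFERENCE_POSITIONS = (46, 47, 62, 257, 263, 264, 266, 417, 418, 588, 725, 765)

DEFAULT_K = 12


@dataclass
class EntropyProfile:
    """Per-column Shannon entropy (bits) of a masked alignment.

    ``values[i]`` is the entropy of 1-based column ``i + 1``.
    ``reference_positions``, when given, maps each column to a coordinate on
    a reference gene (e.g. E. coli 16S numbering).
    """

    values: np.ndarray
    reference_positions: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 2.0 + 1e-12):
            raise ValueError("entropy values must lie in [0, 2] bits")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class OligotypeScheme:
    """Ordered 1-based alignment columns that define the oligotype."""

    positions: list[int]
    reference_positions: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("scheme needs at least one position")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("scheme positions must be strictly increasing")
        if self.reference_positions is not None and len(
            self.reference_positions
        ) != len(self.positions):
            raise ValueError("reference_positions length mismatch")

    @property
    def k(self) -> int:
        return len(self.positions)


@dataclass
class OligotypeCatalog:
    """Map from OT id to (string, taxon, subclade, flags)."""

    entries: pd.DataFrame  # columns: ot_id, string, taxon, subclade, ...

    def __post_init__(self) -> None:
        strings = self.entries["string"]
        if strings.duplicated().any():
            raise ValueError("catalog OT strings must be unique")
        if strings.str.len().nunique() != 1:
            raise ValueError("catalog OT strings must share one length")
        self._by_string = {
            row.string: row for row in self.entries.itertuples(index=False)
        }

    @property
    def k(self) -> int:
        return int(self.entries["string"].str.len().iloc[0])

    def lookup(self, ot_string: str):
        """Catalog row for an exact OT string match, or None."""
        return self._by_string.get(ot_string)

    @classmethod
    def from_csv(cls, path) -> "OligotypeCatalog":
        df = pd.read_csv(path, dtype={"ot_id": str, "string": str})
        required = {"ot_id", "string", "taxon", "subclade"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"catalog lacks columns: {sorted(missing)}")
        return cls(df)


def load_default_catalog() -> OligotypeCatalog:
    """The packaged 18-entry *Acidithiobacillus* species-complex catalog."""
    ref = resources.files("taxotyper.data").joinpath("ot_catalog.csv")
    with resources.as_file(ref) as path:
        return OligotypeCatalog.from_csv(path)


@dataclass
class OligotypeCall:
    """One record's oligotype string and its catalog classification."""

    record_id: str
    ot_string: str
    ot_id: str | None = None
    taxon: str | None = None
    subclade: str | None = None
    n_missing: int = 0
    sample: str | None = None


def entropy_profile(msa: Msa) -> EntropyProfile:
    """Shannon entropy (bits) of each alignment column.

    Entropy is computed over {A,C,G,T} frequencies among non-gap, non-N
    residues; gaps and N are excluded and the frequencies renormalized.
    Columns with fewer than two informative residues get entropy 0.
    """
    if len(msa) < 2:
        raise ValueError("entropy profile needs at least 2 sequences")
    arr = msa.to_array()
    counts = np.stack([(arr == b).sum(axis=0) for b in _BASES])  # (4, ncols)
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    h = np.where(totals >= 2, np.nansum(terms, axis=0), 0.0)
    return EntropyProfile(values=h)


def select_positions(profile: EntropyProfile, k: int = DEFAULT_K) -> OligotypeScheme:
    """The k highest-entropy columns, ties broken toward the lower index.

    Returned in ascending column order (1-based).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(profile)
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} available columns")
    order = sorted(range(n), key=lambda i: (-profile.values[i], i))
    chosen = sorted(order[:k])
    refs = None
    if profile.reference_positions is not None:
        refs = [profile.reference_positions[i] for i in chosen]
    return OligotypeScheme(positions=[i + 1 for i in chosen],
                           reference_positions=refs)


def assign_oligotype(
    record: SequenceRecord, scheme: OligotypeScheme, sample: str | None = None
) -> OligotypeCall:
    """Extract a record's oligotype string at the scheme positions.

    Gaps are preserved as ``-`` and ``N`` as ``N``; both count toward
    ``n_missing``.
    """
    if scheme.positions[-1] > len(record):
        raise ValueError(
            f"scheme position {scheme.positions[-1]} beyond record length "
            f"{len(record)}: scheme/alignment mismatch"
        )
    s = "".join(record.residues[p - 1] for p in scheme.positions)
    n_missing = sum(1 for c in s if c in "-N")
    return OligotypeCall(record_id=record.id, ot_string=s,
                         n_missing=n_missing, sample=sample)


def assign_oligotypes(
    msa: Msa, scheme: OligotypeScheme, samples: dict[str, str] | None = None
) -> list[OligotypeCall]:
    """Oligotype every record of an alignment."""
    samples = samples or {}
    return [assign_oligotype(r, scheme, samples.get(r.id)) for r in msa]


NOVEL = "novel OT"
UNCLASSIFIABLE = "unclassifiable"


def classify_against_catalog(
    call: OligotypeCall, catalog: OligotypeCatalog, max_missing: int = 0
) -> OligotypeCall:
    """Classify a call by exact string match against the catalog.

    Returns the call with ot_id/taxon/subclade filled in; strings with more
    than ``max_missing`` gap/N positions are ``unclassifiable``, unmatched
    strings are ``novel OT``.
    """
    if len(call.ot_string) != catalog.k:
        raise ValueError(
            f"call string length {len(call.ot_string)} != catalog k {catalog.k}"
        )
    if call.n_missing > max_missing:
        call.taxon = UNCLASSIFIABLE
        return call
    row = catalog.lookup(call.ot_string)
    if row is None:
        call.taxon = NOVEL
        return call
    call.ot_id = row.ot_id
    call.taxon = row.taxon
    call.subclade = row.subclade
    return call


def classify_calls(calls, catalog: OligotypeCatalog, max_missing: int = 0):
    return [classify_against_catalog(c, catalog, max_missing) for c in calls]


def ot_frequency_table(calls, min_major: int = 3) -> pd.DataFrame:
    """OT string counts partitioned into major and minor oligotypes.

    An OT is *major* when its count is at least ``min_major`` (default 3;
    chosen so that three-member oligotypes count as major).  Sorted by
    descending count, then string.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no oligotype calls")
    counts = Counter(c.ot_string for c in calls)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["ot_string", "count"])
    df["status"] = np.where(df["count"] >= min_major, "major", "minor")
    return df


def ot_relative_abundance(calls) -> pd.DataFrame:
    """Sample-by-OT relative-abundance matrix (rows sum to 1).

    Each call must carry a sample label; samples without calls are dropped
    with a warning.
    """
    grouped: dict[str, Counter] = defaultdict(Counter)
    for c in calls:
        if c.sample is None:
            warnings.warn(f"call {c.record_id!r} has no sample label; dropped")
            continue
        grouped[c.sample][c.ot_string] += 1
    if not grouped:
        raise ValueError("no calls with sample labels")
    samples = sorted(grouped)
    ots = sorted({ot for counts in grouped.values() for ot in counts})
    mat = np.zeros((len(samples), len(ots)))
    for i, s in enumerate(samples):
        total = sum(grouped[s].values())
        for j, ot in enumerate(ots):
            mat[i, j] = grouped[s][ot] / total
    return pd.DataFrame(mat, index=samples, columns=ots)


def calls_to_frame(calls) -> pd.DataFrame:
    """Tabular view of calls (id, ot_string, ot_id, taxon, subclade, n_missing)."""
    return pd.DataFrame(
        [
            {
                "id": c.record_id,
                "ot_string": c.ot_string,
                "ot_id": c.ot_id,
                "taxon": c.taxon,
                "subclade": c.subclade,
                "n_missing": c.n_missing,
            }
            for c in calls
        ]
    )
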