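"""Multilocus sequence analysis: allele calling, sequence-type assignment,
and marker concatenation.

Follows MLST conventions: within one locus every distinct sequence receives
an allele number (dense from 1, in first-seen order); the vector of allele
numbers across the scheme's loci defines a strain's sequence type (ST).
Allele equality is exact string equality after uppercasing — length
variants are distinct alleles.  Incomplete profiles never receive an ST.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .seqio import Msa, SequenceRecord

#: The 8-locus housekeeping-gene scheme used for the *Acidithiobacillus*
#: species complex, in concatenation order.
DEFAULT_LOCI = ("ilvE", "trx", "rpsE", "ruvB", "rplU", "ihfB", "hslV", "fdx")

#: Normalization of locus-name spelling variants seen in the literature.
LOCUS_ALIASES = {
    "trx?": "trx",
    "hsiv": "hslV",
    "hsIV": "hslV",
    "ihfb": "ihfB",
    "ilve": "ilvE",
}


def normalize_locus(name: str) -> str:
    return LOCUS_ALIASES.get(name, LOCUS_ALIASES.get(name.lower(), name))


@dataclass
class MlsaScheme:
    """Ordered locus list; the order fixes concatenation and profile layout."""

    loci: tuple[str, ...] = DEFAULT_LOCI

    def __post_init__(self) -> None:
        self.loci = tuple(normalize_locus(l) for l in self.loci)
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")


class AlleleDb:
    """Per-locus registry of allele number -> ungapped sequence."""

    def __init__(self, loci) -> None:
        self._alleles: dict[str, dict[str, int]] = {l: {} for l in loci}

    def n_alleles(self, locus: str) -> int:
        return len(self._alleles[locus])

    def get_or_assign(self, locus: str, sequence: str) -> int:
        """Allele number for a sequence, creating the next number if new."""
        seqs = self._alleles[locus]
        key = sequence.upper()
        if key not in seqs:
            seqs[key] = len(seqs) + 1
        return seqs[key]

    def lookup(self, locus: str, sequence: str) -> int | None:
        return self._alleles[locus].get(sequence.upper())

    def sequences(self, locus: str) -> dict[int, str]:
        return {num: seq for seq, num in self._alleles[locus].items()}

    def write_fasta_per_locus(self, outdir) -> None:
        from pathlib import Path

        from .seqio import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for locus, seqs in self._alleles.items():
            records = [
                SequenceRecord(id=f"{locus}_{num}", residues=seq)
                for seq, num in sorted(seqs.items(), key=lambda kv: kv[1])
            ]
            if records:
                write_fasta(records, outdir / f"{locus}.fasta")


@dataclass
class MlsaProfile:
    """One strain's allele numbers in scheme order, plus its ST if complete."""

    strain: str
    alleles: dict[str, int | None] = field(default_factory=dict)
    st: int | None = None

    def is_complete(self, scheme: MlsaScheme) -> bool:
        return all(self.alleles.get(l) is not None for l in scheme.loci)

    def vector(self, scheme: MlsaScheme) -> tuple:
        return tuple(self.alleles.get(l) for l in scheme.loci)


def call_alleles(
    locus_sequences: dict[str, dict[str, str]],
    scheme: MlsaScheme,
    db: AlleleDb | None = None,
) -> tuple[list[MlsaProfile], AlleleDb]:
    """Assign allele numbers for every strain at every scheme locus.

    ``locus_sequences`` maps locus -> {strain -> ungapped sequence}.
    Matching is exact (case-insensitive); unseen sequences are appended to
    the database with the next dense number.  Strains missing any locus get
    an incomplete profile (allele None at that locus) and no ST.
    """
    db = db or AlleleDb(scheme.loci)
    strains: list[str] = []
    for locus in scheme.loci:
        for strain in locus_sequences.get(locus, {}):
            if strain not in strains:
                strains.append(strain)
    profiles = []
    for strain in strains:
        prof = MlsaProfile(strain=strain)
        for locus in scheme.loci:
            seq = locus_sequences.get(locus, {}).get(strain)
            if seq is None:
                warnings.warn(f"strain {strain!r} missing locus {locus!r}; "
                              "profile incomplete")
                prof.alleles[locus] = None
                continue
            if "-" in seq:
                raise ValueError(
                    f"strain {strain!r} locus {locus!r}: allele sequences "
                    "must be ungapped"
                )
            prof.alleles[locus] = db.get_or_assign(locus, seq)
        profiles.append(prof)
    return profiles, db


def assign_sts(profiles, scheme: MlsaScheme) -> list[MlsaProfile]:
    """Number distinct complete allele profiles as STs, in first-seen order."""
    st_map: dict[tuple, int] = {}
    for prof in profiles:
        if not prof.is_complete(scheme):
            prof.st = None
            continue
        vec = prof.vector(scheme)
        if vec not in st_map:
            st_map[vec] = len(st_map) + 1
        prof.st = st_map[vec]
    return list(profiles)


def profiles_to_frame(profiles, scheme: MlsaScheme) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"strain": p.strain}
        row.update({l: p.alleles.get(l) for l in scheme.loci})
        row["ST"] = p.st
        rows.append(row)
    return pd.DataFrame(rows)


def concatenate(
    locus_alignments: dict[str, Msa], scheme: MlsaScheme
) -> tuple[Msa, pd.DataFrame]:
    """Column-wise concatenation of per-locus alignments in scheme order.

    Every locus alignment must contain each retained strain; strains absent
    from any locus are excluded with a warning.  Returns the concatenate and
    a provenance table (concat_column, locus, local_column), 1-based.
    """
    loci = [l for l in scheme.loci if l in locus_alignments]
    if not loci:
        raise ValueError("no scheme locus present in the input")
    strain_sets = [set(locus_alignments[l].ids) for l in loci]
    common = set.intersection(*strain_sets)
    dropped = set.union(*strain_sets) - common
    if dropped:
        warnings.warn(f"strains absent from some locus, excluded: {sorted(dropped)}")
    if not common:
        raise ValueError("no strain present in every locus alignment")
    order = [s for s in locus_alignments[loci[0]].ids if s in common]

    pieces = {s: [] for s in order}
    provenance = []
    offset = 0
    for locus in loci:
        aln = locus_alignments[locus]
        by_id = {r.id: r for r in aln}
        for s in order:
            pieces[s].append(by_id[s].residues)
        for local in range(1, aln.ncols + 1):
            provenance.append(
                {"concat_column": offset + local, "locus": locus,
                 "local_column": local}
            )
        offset += aln.ncols
    records = [
        SequenceRecord(id=s, residues="".join(pieces[s])) for s in order
    ]
    return Msa(records), pd.DataFrame(provenance)
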