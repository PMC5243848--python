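"""Per-locus selection statistics: Tajima's D and Nei-Gojobori dN/dS.

Tajima's D follows the 1989 formulation with complete deletion by default
(columns containing any gap or N removed alignment-wide).  dN/dS uses the
unweighted Nei-Gojobori (1986) method with the Jukes-Cantor correction:
potential synonymous sites counted per codon position, observed differences
averaged over all substitution pathways that avoid stop codons, and the
ratio taken as mean dN over mean dS across pairs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .seqio import Msa

_BASES = ("A", "C", "G", "T")

#: Sentinel for statistics that are undefined on the given input
#: (e.g. Tajima's D with no segregating sites, dN/dS with dS = 0).
UNDEFINED = float("nan")


@dataclass
class SelectionStats:
    """Selection summary for one locus (or one group within a locus)."""

    locus: str
    n: int
    S: int | None = None
    pi: float | None = None
    tajimas_d: float = UNDEFINED
    dn: float = UNDEFINED
    ds: float = UNDEFINED
    dn_ds: float = UNDEFINED


# ---------------------------------------------------------------------------
# Tajima's D

def _complete_deletion(msa: Msa) -> np.ndarray:
    arr = msa.to_array()
    keep = np.isin(arr, _BASES).all(axis=0)
    return arr[:, keep]


def segregating_sites_and_pi(msa: Msa, deletion: str = "complete"):
    """Number of segregating sites S and mean pairwise differences pi.

    pi is the average count of differing sites over all unordered sequence
    pairs (a count, not a per-site rate).
    """
    arr = msa.to_array()
    if deletion == "complete":
        arr = _complete_deletion(msa)
        n = arr.shape[0]
        S = int(sum(len(set(col)) > 1 for col in arr.T))
        diffs = [
            int((arr[i] != arr[j]).sum())
            for i, j in itertools.combinations(range(n), 2)
        ]
        pi = float(np.mean(diffs)) if diffs else 0.0
        return S, pi
    raise ValueError("only complete deletion is supported here")


def tajimas_d(msa: Msa, locus: str = "") -> SelectionStats:
    """Tajima's D for an alignment (complete deletion of gap/N columns).

    Undefined (NaN) when there are no segregating sites.
    """
    n = len(msa)
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    S, pi = segregating_sites_and_pi(msa)
    stats = SelectionStats(locus=locus, n=n, S=S, pi=pi)
    if S == 0:
        return stats
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    stats.tajimas_d = (pi - S / a1) / math.sqrt(var)
    return stats


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) dN/dS

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[11]  # bacterial; same
# codon->amino-acid map as the standard code.


@lru_cache(maxsize=1)
def _codon_map() -> dict[str, str]:
    table = dict(_STANDARD_TABLE.forward_table)
    for stop in _STANDARD_TABLE.stop_codons:
        table[stop] = "*"
    return table


@lru_cache(maxsize=None)
def potential_synonymous_sites(codon: str) -> float:
    """Fraction-weighted count of synonymous sites in one codon.

    For each codon position, the fraction of the 3 possible single-nucleotide
    changes that are synonymous; changes creating stop codons count as
    nonsynonymous.  Sum over the 3 positions.
    """
    table = _codon_map()
    aa = table[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} in frame")
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if table[mut] == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Observed (Sd, Nd) between two codons, averaged over substitution
    pathways; pathways passing through a stop codon are dropped and the
    remainder renormalized."""
    table = _codon_map()
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if table[nxt] == "*":
                ok = False
                break
            if table[nxt] == table[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        # All pathways blocked by stops; count every change as nonsynonymous.
        return 0.0, float(len(diff_pos))
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return UNDEFINED
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _pair_dn_ds(s1: str, s2: str) -> tuple[float, float]:
    """(dN, dS) for one aligned coding pair; codons containing gaps or N in
    either sequence are excluded."""
    S_pot = N_pot = 0.0
    Sd = Nd = 0.0
    ncod = 0
    for k in range(0, len(s1), 3):
        c1, c2 = s1[k:k + 3], s2[k:k + 3]
        if len(c1) < 3:
            break
        if any(ch not in _BASES for ch in c1 + c2):
            continue
        S_pot += (potential_synonymous_sites(c1)
                  + potential_synonymous_sites(c2)) / 2.0
        ncod += 1
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    if ncod == 0:
        return UNDEFINED, UNDEFINED
    N_pot = 3.0 * ncod - S_pot
    pS = Sd / S_pot if S_pot > 0 else 0.0
    pN = Nd / N_pot if N_pot > 0 else 0.0
    return _jc_correct(pN), _jc_correct(pS)


def nei_gojobori(msa: Msa, locus: str = "") -> SelectionStats:
    """Unweighted NG86 dN/dS over all sequence pairs of a coding alignment.

    The alignment length must be a multiple of 3 and in frame (no internal
    stops).  dN/dS = mean dN / mean dS over pairs; undefined (NaN) when
    mean dS is 0 or any pair's proportion exceeds the Jukes-Cantor domain.
    """
    if len(msa) < 2:
        raise ValueError("dN/dS needs at least 2 sequences")
    if msa.ncols % 3 != 0:
        raise ValueError("coding alignment length must be a multiple of 3")
    table = _codon_map()
    for r in msa:
        for k in range(0, msa.ncols - 3, 3):  # internal stops only
            codon = r.residues[k:k + 3]
            if all(c in _BASES for c in codon) and table[codon] == "*":
                raise ValueError(f"record {r.id!r}: internal stop at codon "
                                 f"{k // 3 + 1}")
    dns, dss = [], []
    for i, j in itertools.combinations(range(len(msa)), 2):
        dn, ds = _pair_dn_ds(msa[i].residues, msa[j].residues)
        dns.append(dn)
        dss.append(ds)
    stats = SelectionStats(locus=locus, n=len(msa))
    if any(math.isnan(v) for v in dns + dss):
        warnings.warn("a pairwise proportion exceeded the Jukes-Cantor "
                      "domain; dN/dS undefined")
        return stats
    stats.dn = float(np.mean(dns))
    stats.ds = float(np.mean(dss))
    stats.dn_ds = stats.dn / stats.ds if stats.ds > 0 else UNDEFINED
    return stats


def branch_group_dnds(
    locus_alignments: dict[str, Msa], grouping: dict[str, str]
) -> dict[str, dict[str, SelectionStats]]:
    """NG86 restricted to within-group pairs, per group per locus.

    Groups with fewer than 2 strains at a locus are skipped with a warning.
    Undefined ratios are preserved as NaN.
    """
    out: dict[str, dict[str, SelectionStats]] = {}
    groups = sorted(set(grouping.values()))
    for locus, msa in locus_alignments.items():
        out[locus] = {}
        for g in groups:
            members = [r for r in msa if grouping.get(r.id) == g]
            if len(members) < 2:
                warnings.warn(f"group {g!r} has <2 strains at locus {locus!r}; "
                              "skipped")
                continue
            out[locus][g] = nei_gojobori(Msa(members), locus=locus)
    return out
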