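"""Synthetic species-complex generator.

Produces ground-truthed inputs for every other module: a 16S-like marker
alignment for a configurable number of clades, codon-structured
housekeeping loci with controlled selection pressure (omega), duplicate
rRNA copies per genome, and a metadata table with a configurable fraction
of deliberately mislabeled records.

Sequence evolution is Jukes-Cantor (equal rates and frequencies, apart from
the target G+C at the root; no indels — alignments are generated gap-free).
Branch lengths are chosen so that the *expected* pairwise p-distance
between two clade ancestors equals ``inter_clade_divergence`` and between
two strains of one clade equals ``within_clade_divergence``, via
p = (3/4)(1 - exp(-4d/3)) for a path of d expected substitutions per site.
Coding loci evolve codon-wise: synonymous changes are always accepted,
nonsynonymous changes with probability omega, and changes creating stop
codons are rejected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import Msa, SequenceRecord
from .selection import _codon_map

_BASES = ("A", "C", "G", "T")
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

#: Codon counts per default locus, sized like a typical 8-locus
#: housekeeping scheme (fragment lengths of a few hundred bp each).
DEFAULT_MLSA_LOCI = (
    ("ilvE", 296), ("trx", 98), ("rpsE", 161), ("ruvB", 282),
    ("rplU", 96), ("ihfB", 75), ("hslV", 144), ("fdx", 93),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic species complex."""

    seed: int
    n_clades: int = 4
    strains_per_clade: int = 10
    gene_length_16s: int = 1054
    inter_clade_divergence: float = 0.10
    within_clade_divergence: float = 0.005
    rrna_copies: int = 2
    copy_divergence: float = 0.0
    mlsa_loci: tuple = DEFAULT_MLSA_LOCI
    omega: float = 0.1
    mislabel_rate: float = 0.2
    gc_target: float = 0.55
    clade_names: tuple | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("inter_clade_divergence", "within_clade_divergence",
                     "copy_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.75:
                raise ValueError(f"{name} = {v} outside [0, 0.75)")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if not 0.0 <= self.mislabel_rate <= 1.0:
            raise ValueError("mislabel_rate must lie in [0, 1]")
        if min(self.n_clades, self.strains_per_clade, self.rrna_copies) < 1:
            raise ValueError("counts must be >= 1")
        if self.clade_names is not None and len(self.clade_names) != self.n_clades:
            raise ValueError("clade_names length must equal n_clades")

    @property
    def clades(self) -> list[str]:
        if self.clade_names is not None:
            return list(self.clade_names)
        return [f"clade_{i + 1}" for i in range(self.n_clades)]


@dataclass
class GroundTruth:
    """Per-record truth emitted alongside the synthetic data."""

    records: dict = field(default_factory=dict)  # id -> {...}
    tree: str = ""
    per_locus_omega: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(
                {"records": self.records, "tree": self.tree,
                 "per_locus_omega": self.per_locus_omega},
                fh, indent=2,
            )
            fh.write("\n")


def _branch_for_pairwise_p(p: float) -> float:
    """Per-branch expected substitutions/site so that two tips joined at a
    common ancestor show expected p-distance ``p``."""
    if p == 0.0:
        return 0.0
    d = -0.75 * math.log1p(-4.0 * p / 3.0)  # path length for p
    return d / 2.0


def _p_change(t: float) -> float:
    """JC probability that a site differs after branch length t."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def _random_root(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    return rng.choice(4, size=length, p=probs)


def _evolve(rng: np.random.Generator, seq: np.ndarray, t: float) -> np.ndarray:
    """JC evolution of an integer-coded sequence along branch length t."""
    out = seq.copy()
    if t == 0.0:
        return out
    hit = rng.random(len(seq)) < _p_change(t)
    if hit.any():
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shifts) % 4
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[i] for i in seq)


def _evolve_coding(
    rng: np.random.Generator, seq: np.ndarray, t: float, omega: float,
    table: dict,
) -> np.ndarray:
    """Codon-aware evolution: propose JC changes site by site; reject stops;
    accept nonsynonymous proposals with probability omega."""
    out = seq.copy()
    if t == 0.0:
        return out
    p = _p_change(t)
    for i in range(len(out)):
        if rng.random() >= p:
            continue
        new_base = (out[i] + rng.integers(1, 4)) % 4
        cstart = (i // 3) * 3
        codon = out[cstart:cstart + 3].copy()
        old = _decode(codon)
        codon[i - cstart] = new_base
        new = _decode(codon)
        if table[new] == "*":
            continue  # stop codons rejected outright
        if table[new] != table[old] and rng.random() >= omega:
            continue  # nonsynonymous proposal rejected
        out[i] = new_base
    return out


def _random_coding_root(
    rng: np.random.Generator, n_codons: int, gc: float, table: dict
) -> np.ndarray:
    out = np.empty(n_codons * 3, dtype=np.int64)
    for c in range(n_codons):
        while True:
            codon = _random_root(rng, 3, gc)
            if table[_decode(codon)] != "*":
                out[c * 3:c * 3 + 3] = codon
                break
    return out


def simulate_complex(cfg: SimulationConfig):
    """Generate a synthetic species complex.

    Returns ``(msa_16s, locus_alignments, metadata, truth)`` where
    ``metadata`` is a list of per-record dict rows (id, declared_taxon,
    source, latitude, longitude) and ``truth`` a :class:`GroundTruth`.
    Everything is reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    table = _codon_map()
    clades = cfg.clades

    t_inter = _branch_for_pairwise_p(cfg.inter_clade_divergence)
    t_within = _branch_for_pairwise_p(cfg.within_clade_divergence)
    t_copy = _branch_for_pairwise_p(cfg.copy_divergence)

    root16 = _random_root(rng, cfg.gene_length_16s, cfg.gc_target)
    coding_roots = {
        name: _random_coding_root(rng, ncod, cfg.gc_target, table)
        for name, ncod in cfg.mlsa_loci
    }

    records_16s: list[SequenceRecord] = []
    locus_records: dict[str, list[SequenceRecord]] = {
        name: [] for name, _ in cfg.mlsa_loci
    }
    metadata: list[dict] = []
    truth = GroundTruth(
        per_locus_omega={name: cfg.omega for name, _ in cfg.mlsa_loci}
    )
    newick_clades = []

    for ci, clade in enumerate(clades):
        anc16 = _evolve(rng, root16, t_inter)
        anc_coding = {
            name: _evolve_coding(rng, coding_roots[name], t_inter,
                                 cfg.omega, table)
            for name, _ in cfg.mlsa_loci
        }
        strain_labels = []
        for si in range(cfg.strains_per_clade):
            strain = f"c{ci + 1}s{si + 1}"
            strain_labels.append(f"{strain}:{t_within:.6f}")
            genome16 = _evolve(rng, anc16, t_within)

            mislabeled = bool(rng.random() < cfg.mislabel_rate)
            if mislabeled and cfg.n_clades > 1:
                others = [c for c in clades if c != clade]
                declared = others[int(rng.integers(len(others)))]
            else:
                declared = clade
                mislabeled = False
            lat = float(np.round(rng.uniform(-70, 70), 3))
            lon = float(np.round(rng.uniform(-180, 180), 3))

            for copy in range(cfg.rrna_copies):
                rid = strain if cfg.rrna_copies == 1 else f"{strain}r{copy + 1}"
                seq16 = _evolve(rng, genome16, t_copy)
                records_16s.append(
                    SequenceRecord(id=rid, residues=_decode(seq16),
                                   declared_taxon=declared)
                )
                metadata.append(
                    {"id": rid, "declared_taxon": declared,
                     "source": "synthetic", "latitude": lat, "longitude": lon}
                )
                truth.records[rid] = {
                    "clade": clade, "strain": strain,
                    "mislabeled": mislabeled, "true_ot": None,
                }
            for name, _ in cfg.mlsa_loci:
                locus_records[name].append(
                    SequenceRecord(
                        id=strain,
                        residues=_decode(
                            _evolve_coding(rng, anc_coding[name], t_within,
                                           cfg.omega, table)
                        ),
                        declared_taxon=declared,
                    )
                )
        newick_clades.append(
            "(" + ",".join(strain_labels) + f"){clade}:{t_inter:.6f}"
        )

    truth.tree = "(" + ",".join(newick_clades) + ");"
    msa16 = Msa(records_16s)
    locus_alignments = {name: Msa(recs) for name, recs in locus_records.items()}
    return msa16, locus_alignments, metadata, truth


def plant_oligotype_signal(
    msa: Msa,
    positions: list[int],
    clade_strings: dict[str, str],
    clade_of: dict[str, str],
    truth: GroundTruth | None = None,
) -> Msa:
    """Overwrite the residues at ``positions`` (1-based) with each clade's
    oligotype string, guaranteeing OT separability between clades.

    ``clade_of`` maps record id to clade; ``truth`` (if given) records the
    planted string per record.
    """
    k = len(positions)
    for clade, s in clade_strings.items():
        if len(s) != k:
            raise ValueError(
                f"string for clade {clade!r} has length {len(s)}, expected {k}"
            )
    if positions and positions[-1] > msa.ncols:
        raise ValueError("scheme position beyond alignment width")
    out = []
    for r in msa:
        clade = clade_of[r.id]
        s = clade_strings[clade]
        residues = list(r.residues)
        for pos, ch in zip(positions, s):
            residues[pos - 1] = ch
        out.append(
            SequenceRecord(id=r.id, residues="".join(residues),
                           description=r.description,
                           declared_taxon=r.declared_taxon,
                           metadata=dict(r.metadata))
        )
        if truth is not None and r.id in truth.records:
            truth.records[r.id]["true_ot"] = s
    return Msa(out)


def write_metadata_tsv(metadata: list[dict], path) -> None:
    """Emit the metadata rows as the standard tab-separated table."""
    import pandas as pd

    pd.DataFrame(metadata).to_csv(path, sep="\t", index=False,
                                  lineterminator="\n")
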