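"""Threshold-driven species/genus delineation and taxonomy auditing.

Two tiers of evidence are combined: 16S rRNA identity (conventional 97%
and conservative 98.7% species cutoffs; 1.3% divergence; 94% genus cutoff)
and MLSA concatenate divergence (3% species threshold, standing in for the
70% DNA-DNA hybridization standard).  Comparisons at the species MLSA
boundary are strict: a pair at exactly 3.0% divergence is *not* distinct.

The audit compares each record's declared taxon with the taxon implied by
its oligotype, partitioning records into correct / mis-assigned /
unassigned / novel.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import pandas as pd

from .divergence import DistanceMatrix, group_divergence
from .oligotype import NOVEL, UNCLASSIFIABLE, OligotypeCall, OligotypeCatalog


@dataclass
class ThresholdConfig:
    """Identity/divergence thresholds (percent) used for delineation."""

    species_16s_identity_conservative: float = 98.7
    species_16s_identity_classic: float = 97.0
    species_16s_divergence: float = 1.3
    species_mlsa_divergence: float = 3.0
    genus_16s_identity: float = 94.0
    genus_16s_divergence_hint: float = 5.0
    #: candidate_genus is flagged when MLSA divergence exceeds this multiple
    #: of the species threshold (plus the 16S genus identity cutoff).
    genus_mlsa_multiple: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "species_16s_identity_conservative", "species_16s_identity_classic",
            "species_16s_divergence", "species_mlsa_divergence",
            "genus_16s_identity", "genus_16s_divergence_hint",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} = {v} outside (0, 100)")
        if self.species_16s_identity_conservative < self.species_16s_identity_classic:
            raise ValueError("conservative identity cutoff must be >= classic")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


DISTINCT = "distinct_species"
NOT_DISTINCT = "not_distinct"
CANDIDATE_SPECIES = "candidate_species"
CANDIDATE_GENUS = "candidate_genus"
CONFLICTING = "conflicting"

CORRECT = "correct"
MIS_ASSIGNED = "mis-assigned"
UNASSIGNED = "unassigned"
NOVEL_AUDIT = "novel"


@dataclass
class DelineationReport:
    """Pairwise threshold verdicts plus the per-record assignment audit."""

    verdicts: pd.DataFrame = field(default_factory=pd.DataFrame)
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)
    audit_rates: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "verdicts": self.verdicts.to_dict(orient="records"),
            "audit": self.audit.to_dict(orient="records"),
            "audit_rates": self.audit_rates,
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")

    def to_markdown(self, path) -> None:
        lines = ["# Delineation report", "", "## Thresholds", ""]
        for k, v in self.thresholds.items():
            lines.append(f"- {k}: {v}")
        if not self.verdicts.empty:
            lines += ["", "## Pairwise verdicts", "",
                      self.verdicts.to_markdown(index=False)]
        if not self.audit.empty:
            lines += ["", "## Assignment audit", "",
                      self.audit.to_markdown(index=False)]
        if self.audit_rates:
            lines += ["", "## Audit rates", ""]
            for k, v in self.audit_rates.items():
                lines.append(f"- {k}: {v}")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")


def pairwise_verdicts(
    dm16s: DistanceMatrix | None,
    dm_mlsa: DistanceMatrix | None,
    grouping: dict[str, str],
    cfg: ThresholdConfig | None = None,
) -> DelineationReport:
    """Species/genus verdict for every pair of named taxa.

    Verdict logic, on mean between-group values:

    * MLSA available: divergence strictly above the species MLSA threshold
      -> ``distinct_species``, otherwise ``not_distinct``.
    * Only 16S: identity below ``100 - species_16s_divergence``
      -> ``distinct_species`` at the 16S tier, else ``not_distinct``.
    * Both tiers disagreeing -> ``conflicting``.
    * ``candidate_genus`` flag when 16S identity falls below the genus
      cutoff or MLSA divergence exceeds ``genus_mlsa_multiple`` times the
      species threshold.
    """
    cfg = cfg or ThresholdConfig()
    if dm16s is None and dm_mlsa is None:
        raise ValueError("at least one distance matrix is required")
    taxa = sorted(set(grouping.values()))
    for t in taxa:
        if not any(g == t for g in grouping.values()):
            raise ValueError(f"taxon {t!r} has no strains")

    gd16 = (
        group_divergence(dm16s.to_divergence(), grouping)
        if dm16s is not None else None
    )
    gdml = (
        group_divergence(dm_mlsa.to_divergence(), grouping)
        if dm_mlsa is not None else None
    )

    rows = []
    for a, b in itertools.combinations(taxa, 2):
        row: dict = {"taxon_a": a, "taxon_b": b}
        ident16 = mlsa_div = None
        if gd16 is not None:
            ident16 = 100.0 - gd16.between_value(a, b)
            row["identity_16s"] = round(ident16, 4)
        if gdml is not None:
            mlsa_div = gdml.between_value(a, b)
            row["divergence_mlsa"] = round(mlsa_div, 4)

        v16 = vml = None
        if ident16 is not None:
            v16 = (DISTINCT if ident16 < 100.0 - cfg.species_16s_divergence
                   else NOT_DISTINCT)
        if mlsa_div is not None:
            vml = (DISTINCT if mlsa_div > cfg.species_mlsa_divergence
                   else NOT_DISTINCT)

        if vml is not None and v16 is not None and vml != v16:
            verdict = CONFLICTING
        else:
            verdict = vml if vml is not None else v16

        genus_flag = False
        if ident16 is not None and ident16 < cfg.genus_16s_identity:
            genus_flag = True
        if (mlsa_div is not None and
                mlsa_div > cfg.genus_mlsa_multiple * cfg.species_mlsa_divergence):
            genus_flag = True
        if genus_flag and verdict == DISTINCT:
            verdict = CANDIDATE_GENUS
        row["verdict"] = verdict
        row["candidate_genus_flag"] = genus_flag
        rows.append(row)
    return DelineationReport(
        verdicts=pd.DataFrame(rows), thresholds=cfg.to_dict()
    )


def audit_assignments(
    calls: list[OligotypeCall],
    declared: dict[str, str | None],
    kinds: dict[str, str] | None = None,
) -> DelineationReport:
    """Compare declared taxa with oligotype-derived taxa, record by record.

    ``calls`` must already be classified against a catalog.  ``declared``
    maps record id to its declared taxon (None/empty = unassigned).
    ``kinds`` optionally maps record id to e.g. "isolate" or "clone";
    mis-assignment rates are then reported per kind as well as overall.

    Categories partition the records: *novel* (OT not in the catalog,
    or unclassifiable), then *unassigned* (no declared taxon; the
    OT-derived taxon is attached as a proposal), then *correct* /
    *mis-assigned* by comparison of the two taxa.
    """
    kinds = kinds or {}
    rows = []
    for call in calls:
        dec = declared.get(call.record_id)
        dec = dec.strip() if isinstance(dec, str) else dec
        ot_taxon = call.taxon
        if ot_taxon in (None, NOVEL, UNCLASSIFIABLE):
            category = NOVEL_AUDIT
            proposal = None
        elif not dec:
            category = UNASSIGNED
            proposal = ot_taxon
        elif dec == ot_taxon:
            category = CORRECT
            proposal = None
        else:
            category = MIS_ASSIGNED
            proposal = ot_taxon
        rows.append(
            {
                "id": call.record_id,
                "declared_taxon": dec or None,
                "ot_id": call.ot_id,
                "ot_taxon": None if ot_taxon in (NOVEL, UNCLASSIFIABLE) else ot_taxon,
                "category": category,
                "proposal": proposal,
                "kind": kinds.get(call.record_id),
            }
        )
    audit = pd.DataFrame(rows)
    rates = _audit_rates(audit)
    return DelineationReport(audit=audit, audit_rates=rates)


def _audit_rates(audit: pd.DataFrame) -> dict:
    def rates_for(df: pd.DataFrame) -> dict:
        n = len(df)
        counts = df["category"].value_counts().to_dict()
        assigned = counts.get(CORRECT, 0) + counts.get(MIS_ASSIGNED, 0)
        out = {"n": n, "counts": counts}
        out["misassignment_rate_pct"] = (
            round(100.0 * counts.get(MIS_ASSIGNED, 0) / assigned, 2)
            if assigned else None
        )
        return out

    result = {"overall": rates_for(audit)}
    if audit["kind"].notna().any():
        for kind, df in audit.groupby("kind"):
            result[str(kind)] = rates_for(df)
    return result


def cross_tab(
    calls: list[OligotypeCall],
    declared: dict[str, str | None],
    catalog: OligotypeCatalog,
    min_major: int = 3,
) -> pd.DataFrame:
    """OT-by-declared-taxon contingency table with totals and a Rest row.

    Rows are catalog OT ids (plus "Rest" pooling OTs whose total count is
    below ``min_major`` and all non-catalog strings); columns are declared
    taxa plus "unassigned" and a "Total" column.
    """
    from collections import Counter

    counts: Counter = Counter()
    string_totals: Counter = Counter()
    for call in calls:
        dec = declared.get(call.record_id)
        dec = dec.strip() if isinstance(dec, str) else dec
        col = dec if dec else "unassigned"
        key = call.ot_id if call.ot_id is not None else "Rest"
        counts[(key, col)] += 1
        string_totals[key] += 1

    # Pool sub-threshold catalog OTs into Rest as well.
    pooled: Counter = Counter()
    for (key, col), c in counts.items():
        if key != "Rest" and string_totals[key] < min_major:
            pooled[("Rest", col)] += c
        else:
            pooled[(key, col)] += c

    if not pooled:
        raise ValueError("no calls to tabulate")
    rows = sorted({k for k, _ in pooled}, key=_ot_sort_key)
    cols = sorted({c for _, c in pooled})
    table = pd.DataFrame(0, index=rows, columns=cols)
    for (key, col), c in pooled.items():
        table.loc[key, col] = c
    table["Total"] = table.sum(axis=1)
    return table


def _ot_sort_key(key: str):
    if key == "Rest":
        return (1, 0)
    try:
        return (0, int(key.removeprefix("OT")))
    except ValueError:
        return (0, 10**9)
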