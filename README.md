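# taxotyper

Three-tier molecular typing for bacterial species complexes, built around
the *Acidithiobacillus* species complex — a group of acidophilic,
sulfur-oxidizing bacteria whose seven named species and numerous cryptic
phylotypes are notoriously hard to tell apart from 16S rRNA data alone.

`taxotyper` is for microbial systematists and ecologists who need to
resolve closely related lineages below the resolution of a 16S gene tree,
audit the (frequently wrong) taxon labels attached to public sequence
records, and quantify divergence between candidate species. It implements
three complementary tiers:

1. **Oligotyping** — per-column Shannon entropy of a masked 16S alignment,
   H(c) = −Σ_b p_b log₂ p_b over b ∈ {A,C,G,T}; the k = 12 highest-entropy
   columns form the typing scheme, and the string of residues a sequence
   carries at those columns is its oligotype (OT). OT strings are matched
   exactly against a packaged catalog of the 18 named species-complex
   oligotypes (e.g. OT1 `AGCCCGTCGTCG` → *A. caldus*, OT24 `AATGTCCTTATA`
   → *A. thiooxidans*).
2. **Identity / divergence** — pairwise percent identity with pairwise
   deletion (divergence = 100 − identity, i.e. the uncorrected p-distance
   × 100), group-level within/between summaries (mean ± population SD),
   and threshold verdicts: distinct species at > 1.3 % 16S divergence
   (conservative 98.7 % identity cutoff) or > 3 % MLSA-concatenate
   divergence; < 94 % 16S identity flags a candidate genus.
3. **MLSA** — MLST-style allele and sequence-type (ST) calling over an
   8-locus housekeeping scheme (*ilvE, trx, rpsE, ruvB, rplU, ihfB, hslV,
   fdx*), marker concatenation, Tajima's D
   (D = (π − S/a₁)/√(e₁S + e₂S(S−1))) and Nei–Gojobori (1986) dN/dS with
   Jukes–Cantor correction.

A ground-truthed synthetic species-complex generator (`taxotyper.simulate`)
provides Jukes–Cantor-evolved 16S alignments, codon-structured coding loci
with controlled selection pressure ω, duplicate rRNA copies per genome, and
deliberately mislabeled metadata — so every stage of the pipeline can be
exercised and validated without downloading data.

## Worked example

```python
import taxotyper as tt

# simulate a 3-clade complex with 20% mislabeled records
cfg = tt.SimulationConfig(seed=1, n_clades=3, strains_per_clade=6,
                          gene_length_16s=1054, rrna_copies=1,
                          mislabel_rate=0.2)
msa16, loci, meta, truth = tt.simulate_complex(cfg)

# tier 1: oligotype scheme from the entropy profile
scheme = tt.select_positions(tt.entropy_profile(msa16), k=12)
calls = tt.assign_oligotypes(msa16, scheme)
print(len({c.ot_string for c in calls}), "distinct OTs at positions",
      scheme.positions)

# tier 2: divergence between the true clades
dm = tt.identity_matrix(msa16, mode="divergence")
grouping = {r.id: truth.records[r.id]["clade"] for r in msa16}
gd = tt.group_divergence(dm, grouping)
print(gd.between.round(2))

# tier 3: sequence types and selection statistics on one locus
scheme8 = tt.MlsaScheme(tuple(loci))
profiles, _ = tt.call_alleles(
    {l: {r.id: r.ungapped for r in a} for l, a in loci.items()}, scheme8)
tt.assign_sts(profiles, scheme8)
print("STs:", len({p.st for p in profiles}))
print("ilvE dN/dS:", round(tt.nei_gojobori(loci["ilvE"]).dn_ds, 3))
```

Output:

```
11 distinct OTs at positions [1, 2, 10, 26, 46, 140, 208, 211, 473, 669, 960, 989]
                 mean    sd  n_pairs
clade_1 clade_2  7.75  0.15       36
        clade_3  9.17  0.27       36
clade_2 clade_3  8.70  0.25       36
STs: 18
ilvE dN/dS: 0.129
```

The 18 strains resolve into 18 STs (every simulated genome is distinct at
this divergence), the between-clade divergence sits near the simulated 10 %
target (a single realization; pairs of clade ancestors scatter around it),
and the housekeeping locus shows the strong purifying selection
(dN/dS near ω = 0.1) it was generated under.

A `taxotyper` command-line interface exposes the same pipeline as
subcommands (`simulate`, `mask`, `entropy`, `oligotype`, `classify`,
`distmat`, `njtree`, `mlsa-type`, `selection`, `delineate`, `report`); run
`taxotyper --help`.

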