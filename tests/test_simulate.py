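import numpy as np
import pytest

from taxotyper.divergence import group_divergence, identity_matrix
from taxotyper.oligotype import entropy_profile
from taxotyper.seqio import write_fasta
from taxotyper.simulate import (GroundTruth, SimulationConfig,
                                plant_oligotype_signal, simulate_complex,
                                write_metadata_tsv)


def small_cfg(**kw):
    base = dict(seed=11, n_clades=3, strains_per_clade=4,
                gene_length_16s=300, rrna_copies=1,
                mlsa_loci=(("locA", 60),), inter_clade_divergence=0.10,
                within_clade_divergence=0.01, mislabel_rate=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"omega": 1.5}, {"inter_clade_divergence": 0.8},
        {"mislabel_rate": -0.1}, {"n_clades": 0},
    ])
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)


class TestSimulateComplex:
    def test_zero_within_divergence_identical_strains(self):
        cfg = small_cfg(within_clade_divergence=0.0)
        msa, loci, meta, truth = simulate_complex(cfg)
        by_clade = {}
        for r in msa:
            by_clade.setdefault(truth.records[r.id]["clade"], set()).add(r.residues)
        assert all(len(s) == 1 for s in by_clade.values())

    def test_same_seed_byte_identical(self, tmp_path):
        for run in ("a", "b"):
            cfg = small_cfg()
            msa, loci, meta, truth = simulate_complex(cfg)
            write_fasta(msa, tmp_path / f"16s_{run}.fasta")
            write_metadata_tsv(meta, tmp_path / f"meta_{run}.tsv")
            truth.to_json(tmp_path / f"truth_{run}.json")
        for stem in ("16s", "meta", "truth"):
            ext = {"16s": "fasta", "meta": "tsv", "truth": "json"}[stem]
            assert ((tmp_path / f"{stem}_a.{ext}").read_bytes()
                    == (tmp_path / f"{stem}_b.{ext}").read_bytes())

    def test_interclade_divergence_within_monte_carlo_tolerance(self):
        """Realized mean inter-clade p-distance vs the 0.10 target over
        replicates, judged against 3 binomial standard errors."""
        target, length, reps = 0.10, 1054, 20
        vals = []
        for seed in range(reps):
            cfg = SimulationConfig(seed=seed, n_clades=2, strains_per_clade=1,
                                   gene_length_16s=length, rrna_copies=1,
                                   mlsa_loci=(), within_clade_divergence=0.0,
                                   inter_clade_divergence=target,
                                   mislabel_rate=0.0)
            msa, _, _, _ = simulate_complex(cfg)
            dm = identity_matrix(msa, mode="divergence")
            vals.append(dm.values[0, 1] / 100.0)
        se = np.sqrt(target * (1 - target) / length) / np.sqrt(reps)
        assert abs(np.mean(vals) - target) < 3 * se

    def test_gc_content_near_target(self):
        cfg = small_cfg(gene_length_16s=2000, gc_target=0.55)
        msa, *_ = simulate_complex(cfg)
        # measure on the root-proximal consensus: any sequence is close
        from taxotyper.msa import gc_content

        assert abs(gc_content(msa) - 55.0) < 2.0 * 100 / 100  # within 2 points

    def test_rrna_copies_emitted_per_strain(self):
        cfg = small_cfg(rrna_copies=2)
        msa, _, meta, truth = simulate_complex(cfg)
        assert len(msa) == 3 * 4 * 2
        strains = {truth.records[r.id]["strain"] for r in msa}
        assert len(strains) == 12

    def test_zero_copy_divergence_copies_identical(self):
        cfg = small_cfg(rrna_copies=2, copy_divergence=0.0)
        msa, _, _, truth = simulate_complex(cfg)
        by_strain = {}
        for r in msa:
            by_strain.setdefault(truth.records[r.id]["strain"], set()).add(r.residues)
        assert all(len(s) == 1 for s in by_strain.values())

    def test_mislabeled_records_carry_wrong_clade(self):
        cfg = small_cfg(mislabel_rate=1.0)
        msa, _, _, truth = simulate_complex(cfg)
        for r in msa:
            info = truth.records[r.id]
            assert info["mislabeled"]
            assert r.declared_taxon != info["clade"]

    def test_coding_loci_in_frame_and_stop_free(self):
        from taxotyper.selection import _codon_map

        table = _codon_map()
        cfg = small_cfg(omega=1.0, inter_clade_divergence=0.3)
        _, loci, _, _ = simulate_complex(cfg)
        for msa in loci.values():
            assert msa.ncols % 3 == 0
            for r in msa:
                codons = [r.residues[k:k + 3] for k in range(0, msa.ncols, 3)]
                assert all(table[c] != "*" for c in codons)


class TestPlantOligotypeSignal:
    def test_planted_strings_recovered_exactly(self):
        cfg = small_cfg(within_clade_divergence=0.0)
        msa, _, _, truth = simulate_complex(cfg)
        positions = [10, 50, 90, 130, 170, 210, 240, 250, 260, 270, 280, 290]
        strings = {"clade_1": "A" * 12, "clade_2": "C" * 12, "clade_3": "G" * 12}
        clade_of = {rid: info["clade"] for rid, info in truth.records.items()}
        planted = plant_oligotype_signal(msa, positions, strings, clade_of, truth)
        for r in planted:
            s = "".join(r.residues[p - 1] for p in positions)
            assert s == strings[clade_of[r.id]]
            assert truth.records[r.id]["true_ot"] == s

    def test_identical_strings_make_clades_indistinguishable(self):
        cfg = small_cfg(within_clade_divergence=0.0, n_clades=2)
        msa, _, _, truth = simulate_complex(cfg)
        positions = list(range(1, 13))
        strings = {"clade_1": "ACGTACGTACGT", "clade_2": "ACGTACGTACGT"}
        clade_of = {rid: info["clade"] for rid, info in truth.records.items()}
        planted = plant_oligotype_signal(msa, positions, strings, clade_of)
        ots = {"".join(r.residues[p - 1] for p in positions) for r in planted}
        assert len(ots) == 1

    def test_scheme_entropy_dominates_when_within_divergence_zero(self):
        cfg = small_cfg(within_clade_divergence=0.0)
        msa, _, _, truth = simulate_complex(cfg)
        positions = [5, 25, 45, 65, 85, 105, 125, 145, 165, 185, 205, 225]
        strings = {"clade_1": "AAAAAAAAAAAA", "clade_2": "CCCCCCCCCCCC",
                   "clade_3": "GGGGGGGGGGGG"}
        clade_of = {rid: info["clade"] for rid, info in truth.records.items()}
        planted = plant_oligotype_signal(msa, positions, strings, clade_of)
        h = entropy_profile(planted).values
        scheme_h = [h[p - 1] for p in positions]
        other_h = [h[i] for i in range(len(h)) if (i + 1) not in positions]
        assert min(scheme_h) >= max(other_h) - 1e-9

    def test_length_mismatch_errors(self):
        cfg = small_cfg()
        msa, _, _, truth = simulate_complex(cfg)
        clade_of = {rid: info["clade"] for rid, info in truth.records.items()}
        with pytest.raises(ValueError):
            plant_oligotype_signal(msa, [1, 2, 3], {"clade_1": "AC",
                                                    "clade_2": "ACG",
                                                    "clade_3": "ACG"},
                                   clade_of)


class TestParameterRecovery:
    def test_group_divergence_recovers_interclade_target(self, small_complex):
        cfg, (msa, loci, meta, truth) = small_complex
        grouping = {r.id: truth.records[r.id]["clade"] for r in msa}
        dm = identity_matrix(msa, mode="divergence")
        gd = group_divergence(dm, grouping)
        between = gd.between["mean"].mean() / 100.0
        # 3 SE of a binomial proportion at the simulated length
        se = np.sqrt(0.10 * 0.90 / cfg.gene_length_16s)
        assert abs(between - cfg.inter_clade_divergence) < 4 * se

    def test_audit_recovers_mislabel_rate(self, small_complex):
        cfg, (msa, loci, meta, truth) = small_complex
        flagged = sum(info["mislabeled"] for info in truth.records.values())
        declared_wrong = sum(
            1 for r in msa
            if r.declared_taxon != truth.records[r.id]["clade"]
        )
        assert flagged == declared_wrong  # metadata consistent with truth
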