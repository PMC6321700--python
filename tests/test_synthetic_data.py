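"""Ground-truth generator: determinism, construction invariants,
status logic, divergence process, fragmentation and expression."""

import numpy as np
import pandas as pd
import pytest

from avirescue import expression as ex
from avirescue import seqio_qc as sq
from avirescue import synthetic_data as sd
from avirescue.composition import gc_content
from avirescue.seqio_qc import _CODON_TABLE


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_lost": 1.5},
            {"omega": 0.0},
            {"divergence": -0.1},
            {"n_tissues": 1},
            {"tsi_targets": [2.0]},
        ],
    )
    def test_rejects_invalid(self, kwargs):
        base = {"n_genes": 1}
        with pytest.raises(ValueError):
            sd.SimulationConfig(**{**base, **kwargs})

    def test_rejects_too_short_cds(self):
        with pytest.raises(ValueError, match="10 codons"):
            sd.LengthDist(min_codons=5, max_codons=10, mean_codons=7)

    def test_species_names_default(self):
        assert sd.SimulationConfig(n_species=2).species_names == ("chicken", "duck")


class TestReferenceGeneset:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = sd.SimulationConfig(n_genes=10, seed=1)
        for sub in ("a", "b"):
            (tmp_path / sub).mkdir()
            sd.write_outputs(sd.simulate_all(cfg), tmp_path / sub)
        a = (tmp_path / "a" / "reference_cds.fa").read_bytes()
        b = (tmp_path / "b" / "reference_cds.fa").read_bytes()
        assert a == b

    def test_cds_construction_invariants(self, small_sim):
        for rec in small_sim.reference.cds:
            cds = str(rec.seq)
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            pep = sq.translate(cds)  # raises on internal stop
            assert pep.endswith("*")

    def test_proteins_are_translations(self, small_sim):
        peps = {r.id: str(r.seq) for r in small_sim.reference.proteins}
        for rec in small_sim.reference.cds:
            assert peps[rec.id] == sq.translate(str(rec.seq))[:-1]

    def test_realized_gc_near_target(self, small_sim):
        g = small_sim.reference.genes
        realized = [gc_content(str(r.seq)) for r in small_sim.reference.cds]
        assert np.allclose(realized, g["true_gc"])
        assert (np.abs(g["true_gc"] - g["target_gc"]) <= 5.0).all()
        assert np.corrcoef(g["true_gc"], g["target_gc"])[0, 1] >= 0.95

    def test_bimodal_mixture_recovered_by_fit(self):
        from sklearn.mixture import GaussianMixture

        cfg = sd.SimulationConfig(
            n_genes=100,
            gc_mixture=sd.GCMixture(means=(48.0, 65.0), sds=(2.5, 2.5), weights=(0.4, 0.6)),
            seed=5,
        )
        ref = sd.simulate_reference_geneset(cfg)
        gm = GaussianMixture(n_components=2, random_state=0, n_init=5)
        gm.fit(ref.genes["true_gc"].to_numpy().reshape(-1, 1))
        fitted = sorted(gm.means_.ravel())
        assert fitted[0] == pytest.approx(48.0, abs=2.0)
        assert fitted[1] == pytest.approx(65.0, abs=2.0)

    def test_unsatisfiable_gc_target_names_gene(self):
        with pytest.raises(sd.SimulationError, match="gene_0001"):
            sd._sample_cds(60, 100.0, np.random.default_rng(0), "gene_0001")


class TestEvolveOrthologs:
    def test_zero_divergence_identity(self):
        cfg = sd.SimulationConfig(n_genes=5, n_species=2, divergence=0.0, p_lost=0.0, seed=2)
        ref = sd.simulate_reference_geneset(cfg)
        orth = sd.evolve_species_orthologs(ref, cfg)
        ref_seqs = {r.id: str(r.seq) for r in ref.cds}
        for sp, recs in orth.species_cds.items():
            for rec in recs:
                assert str(rec.seq) == ref_seqs[rec.id]

    def test_omega_zero_only_synonymous_changes(self, rng):
        cds = "ATG" + "AAACCCGGGTTCACCGATCATTGC" * 6 + "TAA"
        diverged, n_syn, n_nonsyn = sd._evolve_cds(cds, 0.0, 0.3, rng)
        assert n_nonsyn == 0
        assert sq.translate(diverged) == sq.translate(cds)
        assert diverged != cds  # some synonymous changes happened

    def test_acceptance_counts_reflect_omega(self):
        # at omega<1 nonsynonymous acceptances are down-weighted relative
        # to the ~1:2.8 syn:nonsyn proposal mix
        cfg = sd.SimulationConfig(n_genes=40, n_species=1, omega=0.5, divergence=0.3,
                                  p_lost=0.0, seed=3)
        orth = sd.evolve_species_orthologs(sd.simulate_reference_geneset(cfg), cfg)
        t = orth.truth
        ratio = t["n_nonsyn_accepted"].sum() / t["n_syn_accepted"].sum()
        # expected approx omega * N_sites/S_sites ~ 0.5 * 3.5 in [1.2, 2.3]
        assert 1.0 < ratio < 2.6

    def test_status_proportions_converge(self):
        cfg = sd.SimulationConfig(
            n_genes=500, n_species=1, p_lost=0.1, p_hidden=0.3, divergence=0.0, seed=4
        )
        orth = sd.evolve_species_orthologs(sd.simulate_reference_geneset(cfg), cfg)
        t = orth.truth
        n = len(t)
        f_lost = (t["status"] == "lost").mean()
        se_lost = np.sqrt(0.1 * 0.9 / n)
        assert abs(f_lost - 0.1) <= 3 * se_lost
        p_hidden_marginal = 0.9 * 0.3
        f_hidden = (t["status"] == "hidden").mean()
        se_hidden = np.sqrt(p_hidden_marginal * (1 - p_hidden_marginal) / n)
        assert abs(f_hidden - p_hidden_marginal) <= 3 * se_hidden

    def test_lost_genes_emit_nothing(self, small_sim):
        truth = small_sim.truth
        for sp, recs in small_sim.transcripts.transcripts.items():
            produced = {r.id for r in small_sim.orthologs.species_cds[sp]}
            lost = set(truth.loc[(truth.species == sp) & (truth.status == "lost"), "gene"])
            assert produced & lost == set()
            tr_genes = set(
                small_sim.transcripts.transcript_truth.query("species == @sp")["gene"]
            )
            assert tr_genes & lost == set()

    def test_hidden_excluded_from_annotation(self, small_sim):
        truth = small_sim.truth
        for sp, ann in small_sim.annotations.items():
            t_sp = truth[truth.species == sp]
            assert set(ann) == set(t_sp.loc[t_sp.status == "annotated", "gene"])


class TestFragmentTranscripts:
    def _run(self, frag, seed=6, n=12):
        cfg = sd.SimulationConfig(
            n_genes=n, n_species=1, p_lost=0.0, divergence=0.0,
            fragmentation=frag, seed=seed,
        )
        ref = sd.simulate_reference_geneset(cfg)
        orth = sd.evolve_species_orthologs(ref, cfg)
        return ref, orth, sd.fragment_transcripts(orth, cfg), cfg

    def test_identity_settings_reproduce_cds(self):
        frag = sd.FragmentationConfig(
            full_length_prob=1.0, utr_prob=0.0, revcomp_prob=0.0, duplicate_prob=0.0
        )
        ref, orth, ts, cfg = self._run(frag)
        sp = cfg.species_names[0]
        cds = {r.id: str(r.seq) for r in orth.species_cds[sp]}
        tt = ts.transcript_truth
        for rec, (_, row) in zip(ts.transcripts[sp], tt.iterrows()):
            assert str(rec.seq) == cds[row["gene"]]
            assert row["coverage"] == 1.0

    def test_duplicates_collapse_back(self):
        frag = sd.FragmentationConfig(
            full_length_prob=1.0, utr_prob=0.0, revcomp_prob=0.0,
            duplicate_prob=0.5, max_duplicate_trim=0.0,
        )
        ref, orth, ts, cfg = self._run(frag, n=20)
        sp = cfg.species_names[0]
        recs = ts.transcripts[sp]
        assert len(recs) > 20  # duplicates present
        reps, _ = sq.collapse_redundancy(recs)
        assert len(reps) == 20

    def test_revcomp_strand_invariant_peptides(self):
        outs = []
        for rc in (0.0, 1.0):
            frag = sd.FragmentationConfig(
                full_length_prob=1.0, utr_prob=0.0, revcomp_prob=rc, duplicate_prob=0.0
            )
            ref, orth, ts, cfg = self._run(frag, seed=8)
            peps = set()
            for rec in ts.transcripts[cfg.species_names[0]]:
                orf = sq.find_longest_orf(str(rec.seq), min_length_aa=10, require_start=False)
                peps.add(orf.peptide)
            outs.append(peps)
        assert outs[0] == outs[1]

    def test_coverage_recorded_in_truth(self):
        frag = sd.FragmentationConfig(full_length_prob=0.0, min_coverage=0.4,
                                      utr_prob=0.0, revcomp_prob=0.0, duplicate_prob=0.0)
        ref, orth, ts, cfg = self._run(frag, n=30)
        t = orth.truth
        assert t["transcript_coverage"].between(0.3, 1.0).all()
        assert (t["transcript_coverage"] < 1.0).any()


class TestSimulateExpression:
    def test_profile_boundary_cases_exact(self):
        assert ex.tsi(sd.tsi_profile(0.0, 8), warn_few_tissues=False).tsi == 0.0
        assert ex.tsi(sd.tsi_profile(1.0, 8), warn_few_tissues=False).tsi == 1.0

    def test_single_tissue_for_target_one(self):
        cfg = sd.SimulationConfig(n_genes=5, tsi_targets=[1.0] * 5, seed=9)
        counts = sd.simulate_expression(
            [f"g{i}" for i in range(5)], [1.0] * 5, cfg
        )
        assert ((counts > 0).sum(axis=1) == 1).all()

    def test_tissue_totals_near_library_size(self):
        cfg = sd.SimulationConfig(n_genes=200, seed=10)
        counts = sd.simulate_expression(
            [f"g{i}" for i in range(200)], np.random.default_rng(0).uniform(0, 1, 200), cfg
        )
        totals = counts.sum(axis=0)
        assert ((totals - 1e6).abs() / 1e6 <= 0.10).all()

    def test_determinism(self):
        cfg = sd.SimulationConfig(n_genes=20, seed=12)
        genes = [f"g{i}" for i in range(20)]
        targets = [0.5] * 20
        a = sd.simulate_expression(genes, targets, cfg)
        b = sd.simulate_expression(genes, targets, cfg)
        assert a.equals(b)


class TestSimulateReads:
    def test_filter_removes_exactly_flagged(self, rng):
        cfg = sd.ReadSimConfig(n_reads=1000, frac_short=0.1, frac_low_quality=0.1)
        transcripts = [type("T", (), {"seq": "ACGT" * 100})() for _ in range(3)]
        reads, truth = sd.simulate_reads(transcripts, cfg, rng)
        kept, log = sq.filter_reads(reads)
        kept_ids = {r.id for r in kept}
        flagged = set(truth.loc[truth.flagged_short | truth.flagged_low_quality, "read_id"])
        assert kept_ids == set(truth["read_id"]) - flagged

    def test_clean_reads_all_pass(self, rng):
        cfg = sd.ReadSimConfig(n_reads=100, frac_short=0.0, frac_low_quality=0.0)
        transcripts = [type("T", (), {"seq": "ACGT" * 100})()]
        reads, _ = sd.simulate_reads(transcripts, cfg, rng)
        kept, _ = sq.filter_reads(reads)
        assert len(kept) == 100

    def test_deterministic_fastq(self, tmp_path):
        cfg = sd.SimulationConfig(n_genes=5, n_species=1, seed=13,
                                  reads=sd.ReadSimConfig(n_reads=50))
        for sub in ("a", "b"):
            (tmp_path / sub).mkdir()
            sd.write_outputs(sd.simulate_all(cfg), tmp_path / sub)
        fq = "chicken_reads.fq"
        assert (tmp_path / "a" / fq).read_bytes() == (tmp_path / "b" / fq).read_bytes()
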