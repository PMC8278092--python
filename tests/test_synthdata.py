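"""Synthetic cohort generator: determinism, planted structure, null behaviour."""
import numpy as np
import pandas as pd
import pytest

from cernet.diffexpr import de_test_counts
from cernet.synthdata import (CohortConfig, embed_site, generate_cohort,
                              read_fixture, write_fixture)
from cernet.targets import ScanParams, scan_targets

from helpers import reverse_complement_rna


def _mini(**kw):
    base = dict(n_mrna=10, n_lncrna=6, n_mirna=6, n_stable_mirna=1,
                n_per_group=10, n_circuits=1, seed=0)
    base.update(kw)
    return CohortConfig(**base)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a = generate_cohort(_mini(seed=7))
        b = generate_cohort(_mini(seed=7))
        pd.testing.assert_frame_equal(a.rna.values, b.rna.values)
        pd.testing.assert_frame_equal(a.mirna.values, b.mirna.values)
        assert a.sequences == b.sequences
        pd.testing.assert_frame_equal(a.whitelist, b.whitelist)
        assert a.truth.de_features == b.truth.de_features
        assert a.truth.circuits == b.truth.circuits
        assert a.truth.planted_sites == b.truth.planted_sites

    def test_fixture_files_bit_identical(self, small_cohort, tmp_path):
        p1 = write_fixture(small_cohort, tmp_path / "one")
        p2 = write_fixture(small_cohort, tmp_path / "two")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_fixture_roundtrip(self, small_cohort, tmp_path):
        write_fixture(small_cohort, tmp_path)
        back = read_fixture(tmp_path)
        pd.testing.assert_frame_equal(back.rna.values, small_cohort.rna.values)
        pd.testing.assert_frame_equal(back.mirna.values,
                                      small_cohort.mirna.values)
        assert back.sequences == small_cohort.sequences
        assert back.truth.de_features == small_cohort.truth.de_features
        assert back.truth.circuits == small_cohort.truth.circuits
        assert back.truth.planted_sites == small_cohort.truth.planted_sites
        assert back.config == small_cohort.config
        assert [g.set_id for g in back.gene_sets] == \
               [g.set_id for g in small_cohort.gene_sets]

    def test_tsv_format_contract(self, small_cohort, tmp_path):
        paths = write_fixture(small_cohort, tmp_path)
        header, first = paths["rna_counts"].read_text().splitlines()[:2]
        cols = header.split("\t")
        assert cols[0] == "feature_id"
        assert cols[1:] == list(small_cohort.rna.values.columns)
        assert first.split("\t")[0] == small_cohort.rna.values.index[0]

    def test_fasta_parseable_one_record_per_transcript(self, small_cohort,
                                                       tmp_path):
        from Bio import SeqIO
        paths = write_fixture(small_cohort, tmp_path)
        recs = list(SeqIO.parse(str(paths["lncrna_fasta"]), "fasta"))
        assert len(recs) == len(small_cohort.sequences["lncrna"])
        for rec in recs:
            assert str(rec.seq) == small_cohort.sequences["lncrna"][rec.id]


class TestConfigValidation:
    def test_too_many_circuits_rejected(self):
        with pytest.raises(ValueError, match="n_circuits"):
            CohortConfig(n_mrna=5, n_lncrna=5, n_mirna=5, n_stable_mirna=1,
                         n_circuits=5)

    @pytest.mark.parametrize("field,value", [
        ("n_mrna", 0), ("de_fraction", 1.5), ("sponge_strength", -0.1),
        ("site_mode", "other"), ("mirna_len", 30), ("n_per_group", -1),
    ])
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(ValueError):
            CohortConfig(**{field: value})


class TestEmbedSite:
    def test_poly_a_start_zero(self):
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        seq = embed_site("A" * 100, mir, 0)
        assert len(seq) == 100
        assert seq[:22] == reverse_complement_rna(mir).replace("U", "T")
        assert seq[22:] == "A" * 78

    def test_roundtrip_with_scanner(self):
        rng = np.random.default_rng(1)
        mir = "".join(rng.choice(list("ACGU"), 22))
        background = "".join(rng.choice(list("ACGT"), 200))
        seq = embed_site(background, mir, 50)
        hits = scan_targets(mir, seq)
        assert any(h.start == 51 and h.end == 72 for h in hits)

    def test_out_of_bounds_names_transcript(self):
        with pytest.raises(ValueError, match="LNC0001"):
            embed_site("ACGT" * 5, "U" * 22, 10, name="LNC0001")


class TestPlantedStructure:
    def test_every_circuit_mirna_has_sites_on_both_arms(self, small_cohort):
        sites = {(m, t) for (m, t, _, _) in small_cohort.truth.planted_sites}
        for lnc, mir, mrna in small_cohort.truth.circuits:
            assert (mir, lnc) in sites and (mir, mrna) in sites

    def test_circuits_reference_existing_features(self, small_cohort):
        rna = set(small_cohort.rna.values.index)
        mirs = set(small_cohort.mirna.values.index)
        for lnc, mir, mrna in small_cohort.truth.circuits:
            assert lnc in rna and mrna in rna and mir in mirs

    def test_whitelist_covers_planted_pairs_plus_decoys(self, small_cohort):
        wl = {(r.mirna_id, r.target_id)
              for r in small_cohort.whitelist.itertuples()}
        planted = {(m, t) for (m, t, _, _) in small_cohort.truth.planted_sites}
        assert planted <= wl
        assert len(wl) == len(planted) + small_cohort.config.n_decoys

    def test_circuit_correlation_signs_hold(self):
        """One planted circuit, sponge 0.8, n=50 per group: the three
        correlation signs hold in >= 95% of 100 seeded replicates."""
        ok = 0
        for seed in range(1, 101):
            c = generate_cohort(_mini(n_per_group=50, sponge_strength=0.8,
                                      seed=seed))
            lnc, mir, mrna = c.truth.circuits[0]
            x = np.log2(pd.concat([c.rna.values, c.mirna.values]) + 1.0)
            r_lg = np.corrcoef(x.loc[lnc], x.loc[mrna])[0, 1]
            r_ml = np.corrcoef(x.loc[mir], x.loc[lnc])[0, 1]
            r_mg = np.corrcoef(x.loc[mir], x.loc[mrna])[0, 1]
            ok += (r_lg > 0) and (r_ml < 0) and (r_mg < 0)
        assert ok >= 95

    def test_no_circuits_no_coupling_mean_correlation_zero(self):
        """Without circuits and sponge coupling, random lncRNA-mRNA pairs are
        uncorrelated in expectation (Monte-Carlo over 200 replicate cohorts)."""
        rs = []
        for seed in range(200):
            c = generate_cohort(_mini(n_circuits=0, sponge_strength=0.0,
                                      block_sd=0.0, seed=seed))
            rng = np.random.default_rng(seed)
            lnc = rng.choice(c.rna.subset_biotype("lncRNA").index)
            mrna = rng.choice(c.rna.subset_biotype("mRNA").index)
            x = np.log2(c.rna.values + 1.0)
            rs.append(np.corrcoef(x.loc[lnc], x.loc[mrna])[0, 1])
        rs = np.array(rs)
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean()) < 2 * se + 1e-12

    def test_null_cerna_pair_pass_rate_nominal(self):
        """On a pure null cohort the fraction of random lncRNA-mRNA pairs with
        r > 0 and p < .05 sits at the nominal .025 within binomial error."""
        from cernet.cerna import correlation_with_p
        passed = total = 0
        for seed in range(3):
            c = generate_cohort(CohortConfig(
                n_mrna=300, n_lncrna=300, n_mirna=5, n_stable_mirna=1,
                n_per_group=20, n_circuits=0, sponge_strength=0.0,
                de_fraction=0.0, block_sd=0.0, seed=seed))
            x = np.log2(c.rna.values.to_numpy() + 1.0)
            for i in range(300):  # disjoint pairs: mRNA i vs lncRNA i
                r, p = correlation_with_p(x[i], x[300 + i])
                passed += (r > 0) and (p < 0.05)
                total += 1
        rate = passed / total
        band = 3.5 * np.sqrt(0.025 * 0.975 / total)
        assert abs(rate - 0.025) < band

    def test_planted_de_recovered_by_diffexpr(self):
        """Planted DE (|lfc| around 3) at n=20 per group is recovered with
        sensitivity >= 0.8 and FDR <= 0.1, averaged over 20 seeds."""
        sens, fdr = [], []
        for seed in range(20):
            c = generate_cohort(CohortConfig(
                n_mrna=100, n_lncrna=30, n_mirna=10, n_stable_mirna=2,
                n_per_group=20, n_circuits=2, lfc_mean=3.0, seed=seed))
            res = de_test_counts(c.rna.values, c.rna.groups)
            truth = {f for f, _ in c.truth.de_features
                     if f in c.rna.values.index}
            called = set(res.loc[res["is_de"], "feature_id"])
            sens.append(len(called & truth) / len(truth))
            fdr.append(len(called - truth) / len(called) if called else 0.0)
        assert np.mean(sens) >= 0.8
        assert np.mean(fdr) <= 0.1


class TestStableTier:
    def test_stable_mirnas_never_de_or_circuit(self, small_cohort):
        cfg = small_cohort.config
        stable = set(small_cohort.mirna.values.index[-cfg.n_stable_mirna:])
        de = {f for f, _ in small_cohort.truth.de_features}
        assert not stable & de
        assert not stable & {m for _, m, _ in small_cohort.truth.circuits}
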