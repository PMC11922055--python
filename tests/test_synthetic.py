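"""Generator-level checks: determinism, conservation, and calibration of
every discrete sampling step against closed-form binomial/multinomial
intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stallkit as sk
from stallkit.synthetic import (
    SENSE_CODONS,
    AcetylationProfile,
    CohortModel,
    DwellModel,
    InvalidConfigError,
    default_abundance,
    default_misinc_signature,
)


def binom_interval(n, p, conf=0.99):
    lo, hi = stats.binom.interval(conf, n, p)
    return lo, hi


# ---------------------------------------------------------------------------
# tRNA reference
# ---------------------------------------------------------------------------

class TestTRNAReference:
    def test_default_complement_26_substrates_9_anticodons(self, ref):
        subs = ref.substrates()
        assert len(subs) == 26
        assert len({g.anticodon for g in subs}) == 9
        assert {g.amino_acid for g in subs} == {"Leu", "Ser"}

    def test_ccg_consensus_at_c12(self, ref):
        for g in ref.substrates():
            assert g.sequence[g.c12_index] == "C"
            assert g.sequence[g.c12_index - 1 : g.c12_index + 2] == "CCG"

    def test_decoys_have_no_c12_annotation(self, ref_with_decoys):
        decoys = [g for g in ref_with_decoys.genes if not g.is_substrate]
        assert len(decoys) == 10
        assert all(g.c12_index is None for g in decoys)

    def test_depleted_isodecoders_exist(self, ref):
        for gid in sk.synthetic.KO_DEPLETION:
            assert gid in ref

    def test_single_decoy_reference(self):
        r = sk.make_trna_reference(substrate_copies={}, n_decoys=1, seed=0)
        assert len(r) == 1
        assert r.genes[0].c12_index is None

    def test_empty_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            sk.make_trna_reference(substrate_copies={}, n_decoys=0)

    def test_fasta_byte_identical_for_fixed_seed(self):
        a = sk.make_trna_reference(seed=7, n_decoys=3)
        b = sk.make_trna_reference(seed=7, n_decoys=3)
        assert a.fasta_bytes() == b.fasta_bytes()

    def test_fasta_roundtrip(self, ref, tmp_path):
        p = tmp_path / "ref.fasta"
        ref.to_fasta(str(p))
        back = sk.TRNAReference.from_fasta(str(p))
        assert back.gene_ids == ref.gene_ids
        g = back["Leu-UAA-2"]
        assert g.c12_index == ref["Leu-UAA-2"].c12_index
        assert g.is_substrate
        assert g.sequence == ref["Leu-UAA-2"].sequence


# ---------------------------------------------------------------------------
# Reduction chemistry
# ---------------------------------------------------------------------------

class TestAc4cReads:
    def test_forced_misincorporation_branch(self, ref):
        gid = ref.substrates()[0].gene_id
        prof = AcetylationProfile(
            stoichiometry={gid: 1.0}, p_mis={gid: 1.0}, p_stop={gid: 0.0}, epsilon=0.0)
        one_gene = sk.TRNAReference([ref[gid]])
        reads = sk.simulate_ac4cseq_reads(one_gene, prof, "reduced", 100, seed=0)
        c12 = ref[gid].c12_index
        assert len(reads) == 100
        assert all(r.sequence[c12] == "T" for r in reads)

    def test_forced_stop_branch(self, ref):
        g = ref.substrates()[0]
        prof = AcetylationProfile(
            stoichiometry={g.gene_id: 1.0}, p_mis={g.gene_id: 0.0},
            p_stop={g.gene_id: 1.0}, epsilon=0.0)
        reads = sk.simulate_ac4cseq_reads(sk.TRNAReference([g]), prof, "reduced", 50, seed=0)
        expected = g.sequence[g.c12_index + 1 :]
        assert all(r.sequence == expected for r in reads)

    def test_mock_background_within_binomial_interval(self, ref):
        g = ref.substrates()[0]
        prof = AcetylationProfile(
            stoichiometry={g.gene_id: 1.0}, p_mis={g.gene_id: 1.0},
            p_stop={g.gene_id: 0.0}, epsilon=0.005)
        reads = sk.simulate_ac4cseq_reads(sk.TRNAReference([g]), prof, "mock", 10000, seed=2)
        # under mock, a T at C12 arises only from background error (p = eps/3)
        n_t = sum(r.sequence[g.c12_index] == "T" for r in reads)
        lo, hi = binom_interval(10000, 0.005 / 3)
        assert lo <= n_t <= hi

    def test_branch_probabilities_enumerated(self, ref):
        # s=0.5, p_mis=0.8, p_stop=0.1: among non-truncated reads the T
        # fraction is (s*p_mis)/(1 - s*p_stop) = 0.4/0.95
        g = ref.substrates()[0]
        prof = AcetylationProfile(
            stoichiometry={g.gene_id: 0.5}, p_mis={g.gene_id: 0.8},
            p_stop={g.gene_id: 0.1}, epsilon=0.0)
        reads = sk.simulate_ac4cseq_reads(sk.TRNAReference([g]), prof, "reduced",
                                          50000, seed=3)
        full = [r for r in reads if len(r.sequence) == len(g.sequence)]
        frac = sum(r.sequence[g.c12_index] == "T" for r in full) / len(full)
        expect = 0.4 / 0.95
        sd = np.sqrt(expect * (1 - expect) / len(full))
        assert abs(frac - expect) < 4 * sd

    def test_invalid_treatment(self, ref):
        prof = AcetylationProfile.default(ref)
        with pytest.raises(ValueError):
            sk.simulate_ac4cseq_reads(ref, prof, "heated", 10, seed=0)

    def test_read_count_conservation(self, ref):
        prof = AcetylationProfile.default(ref)
        reads = sk.simulate_ac4cseq_reads(ref, prof, "reduced", 50, seed=0)
        assert len(reads) == 50 * len(ref)


# ---------------------------------------------------------------------------
# tRNA-seq reads
# ---------------------------------------------------------------------------

class TestTrnaseqReads:
    def test_uniform_two_genes_binomial(self, ref):
        two = sk.TRNAReference(ref.genes[:2])
        reads = sk.simulate_trnaseq_reads(two, {g.gene_id: 1.0 for g in two.genes},
                                          depth=10000, seed=4, background_error=0.0)
        n_a = sum(r.read_id.startswith(two.genes[0].gene_id + "|") for r in reads)
        lo, hi = binom_interval(10000, 0.5)
        assert lo <= n_a <= hi
        assert len(reads) == 10000

    def test_zero_abundance_gene_emits_nothing(self, ref):
        two = sk.TRNAReference(ref.genes[:2])
        a, b = (g.gene_id for g in two.genes)
        reads = sk.simulate_trnaseq_reads(two, {a: 1.0, b: 0.0}, depth=500, seed=0)
        assert all(r.read_id.startswith(a + "|") for r in reads)

    def test_all_zero_abundance_rejected(self, ref):
        with pytest.raises(InvalidConfigError):
            sk.simulate_trnaseq_reads(ref, {g: 0.0 for g in ref.gene_ids}, depth=10)

    def test_default_ko_share_is_one_quarter_before_renormalization(self, ref):
        wt = default_abundance(ref, "WT")
        ko = default_abundance(ref, "KO")
        assert ko["Leu-UAA-2"] / wt["Leu-UAA-2"] == 0.25
        assert ko["Ser-AGA-3"] / wt["Ser-AGA-3"] == pytest.approx(1 / 1.5)

    def test_misinc_signature_applied(self, ref):
        g = ref.substrates()[0]
        one = sk.TRNAReference([g])
        sig = {g.gene_id: {g.c12_index: 1.0}}
        reads = sk.simulate_trnaseq_reads(one, {g.gene_id: 1.0}, sig, depth=200,
                                          seed=1, background_error=0.0)
        assert all(r.sequence[g.c12_index] != "C" for r in reads)


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

class TestTranscriptome:
    def test_cds_invariants(self, txome):
        for g in txome.genes:
            assert len(g.cds_sequence) % 3 == 0
            assert g.cds_sequence.startswith("ATG")
            codons = g.codons
            assert codons[-1] in {"TAA", "TAG", "TGA"}
            assert all(c not in {"TAA", "TAG", "TGA"} for c in codons[:-1])

    def test_embedded_run(self):
        t = sk.make_transcriptome(n_genes=3, seed=0,
                                  embedded_runs={"gene0002": (1, ["TTA"] * 3)})
        codons = t["gene0002"].codons
        assert codons[1:4] == ["TTA", "TTA", "TTA"]

    def test_determinism(self):
        a = sk.make_transcriptome(n_genes=100, seed=9)
        b = sk.make_transcriptome(n_genes=100, seed=9)
        assert [g.cds_sequence for g in a.genes] == [g.cds_sequence for g in b.genes]

    def test_stop_codon_weight_rejected(self):
        with pytest.raises(InvalidConfigError):
            sk.make_transcriptome(n_genes=1, codon_weights={"TAA": 1.0})

    def test_uniform_codon_frequencies_multinomial(self):
        t = sk.make_transcriptome(n_genes=60, seed=3)
        counts = {c: 0 for c in SENSE_CODONS}
        for g in t.genes:
            for c in g.codons[1:-1]:  # body codons are the iid draws
                counts[c] += 1
        n = sum(counts.values())
        # familywise 99% via Bonferroni over the 61 codons
        lo, hi = stats.binom.interval(1 - 0.01 / 61, n, 1 / 61)
        for c, k in counts.items():
            assert lo <= k <= hi, c


# ---------------------------------------------------------------------------
# Footprints and expression
# ---------------------------------------------------------------------------

class TestFootprints:
    def test_count_conservation_and_schema(self, txome):
        fp = sk.simulate_footprints(txome, None, DwellModel.flat(), "mono", "WT",
                                    5000, seed=0)
        assert len(fp) == 5000
        assert set(fp["library"]) == {"mono"}
        lengths = fp["length"]
        assert lengths.between(25, 39).all()

    def test_disome_lengths_in_range(self, txome):
        fp = sk.simulate_footprints(txome, None, DwellModel.flat(), "di", "KO",
                                    2000, seed=0)
        assert fp["length"].between(40, 80).all()

    def test_invalid_library(self, txome):
        with pytest.raises(ValueError):
            sk.simulate_footprints(txome, None, DwellModel.flat(), "trisome", "WT", 10)

    def test_single_elevated_codon_ratio(self, txome):
        # w(TTG)=3 -> occupancy ratio vs flat ~ 3 (normalized scale)
        w = {c: 1.0 for c in SENSE_CODONS}
        w["TTG"] = 3.0
        fp = sk.simulate_footprints(txome, None, DwellModel(weights=w), "mono",
                                    "KO", 300000, seed=2)
        occ = sk.codon_occupancy(fp, txome)
        ttg = occ.set_index("codon").loc["TTG", "occupancy"]
        expect = 3.0 * 61 / 63  # injected weight after mean-1 normalization
        assert ttg == pytest.approx(expect, rel=0.05)

    def test_expression_tables_te_multiplier(self, txome):
        rna, rpf = sk.simulate_expression_tables(txome, {"gene0001": 0.5}, seed=1,
                                                 n_replicates=2)
        def density(tbl, cond, gid):
            sub = tbl[(tbl.condition == cond) & (tbl.gene_id == gid)]
            return sub["count"].sum()
        # RNA expectation condition-independent; RPF halved in KO
        g = "gene0001"
        dte = np.log2(density(rpf, "KO", g) / density(rna, "KO", g)) - \
            np.log2(density(rpf, "WT", g) / density(rna, "WT", g))
        assert dte == pytest.approx(-1.0, abs=0.35)

    def test_expression_rejects_nonpositive_multiplier(self, txome):
        with pytest.raises(InvalidConfigError):
            sk.simulate_expression_tables(txome, {"gene0001": 0.0})


# ---------------------------------------------------------------------------
# qPCR, cohort, Sanger
# ---------------------------------------------------------------------------

class TestQpcr:
    def test_noise_free_fraction_one(self):
        ct = sk.simulate_qpcr_ct({"Leu": 1.0}, ct_noise_sd=0.0, seed=0)
        assert sk.charged_fraction(ct, "Leu", "yPhe") == pytest.approx(1.0)

    def test_noise_free_inversion_exact(self):
        ct = sk.simulate_qpcr_ct({"Leu": 0.25}, ct_noise_sd=0.0, seed=0)
        assert sk.charged_fraction(ct, "Leu", "yPhe") == pytest.approx(0.25)

    def test_zero_fraction_rejected(self):
        with pytest.raises(InvalidConfigError):
            sk.simulate_qpcr_ct({"Leu": 0.0})

    def test_monte_carlo_recovery_calibration(self):
        hits = 0
        for seed in range(200):
            ct = sk.simulate_qpcr_ct({"Leu": 0.5}, ct_noise_sd=0.1, seed=seed,
                                     n_replicates=3)
            if abs(sk.charged_fraction(ct, "Leu", "yPhe") - 0.5) <= 0.1:
                hits += 1
        assert hits >= 190


class TestCohort:
    def test_mendelian_limit(self):
        tbl = sk.simulate_cohort(10**6, CohortModel.mendelian(), seed=1)
        n_ko = tbl[tbl.thumpd1 == "-/-"]["count"].sum()
        lo, hi = binom_interval(10**6, 0.25)
        assert lo <= n_ko <= hi
        # per-locus 1:2:1 marginals
        for locus in ("thumpd1", "gcn2"):
            het = tbl.groupby(locus)["count"].sum()["+/-"]
            lo2, hi2 = binom_interval(10**6, 0.5)
            assert lo2 <= het <= hi2

    def test_counts_sum_to_n(self):
        tbl = sk.simulate_cohort(262, CohortModel.default(), seed=2)
        assert tbl["count"].sum() == 262

    def test_zero_viability_blocks_genotype(self):
        v = {(t, g): 1.0 for t in ("+/+", "+/-", "-/-") for g in ("+/+", "+/-", "-/-")}
        for g in ("+/+", "+/-", "-/-"):
            v[("-/-", g)] = 0.0
        tbl = sk.simulate_cohort(5000, CohortModel(viability=v), seed=3)
        assert tbl[tbl.thumpd1 == "-/-"]["count"].sum() == 0

    def test_all_zero_viability_rejected(self):
        with pytest.raises(InvalidConfigError):
            CohortModel(viability={(t, g): 0.0 for t in ("+/+", "+/-", "-/-")
                                   for g in ("+/+", "+/-", "-/-")})

    def test_default_conditional_expectations(self):
        p = CohortModel.default().probabilities()
        func = p.loc[:, ["+/+", "+/-"]]
        ko = p.xs("-/-", level="gcn2")
        assert func.loc["-/-"].sum() / func.sum() == pytest.approx(0.13)
        assert ko["-/-"] / ko.sum() == pytest.approx(0.22)


class TestSanger:
    def test_equal_peaks_at_half_rate(self):
        treated, _ = sk.simulate_sanger_trace(0.5, 0.0, seed=0, noise_sd=0.0)
        h = treated.set_index("base")["height"]
        assert h["T"] == pytest.approx(h["C"])

    def test_background_only_nets_zero(self):
        treated, control = sk.simulate_sanger_trace(0.0, 0.02, seed=1, noise_sd=0.0)
        assert sk.sanger_percent_misinc(treated, control, 12) == pytest.approx(0.0)

    def test_generator_inversion_with_noise(self):
        vals = []
        for seed in range(100):
            treated, control = sk.simulate_sanger_trace(0.3, 0.01, seed=seed)
            vals.append(sk.sanger_percent_misinc(treated, control, 12))
        assert np.mean(vals) == pytest.approx(30.0, abs=2.0)
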