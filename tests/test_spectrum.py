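"""96-context spectra, KL divergence, clustering and signature ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exocapkit.genome import GenomeAssembly, reverse_complement
from exocapkit.simulate import make_signature_catalog, make_signature_mixture
from exocapkit.spectrum import (
    CONTEXT_LABELS,
    MutationSpectrum,
    SignatureCatalog,
    build_spectrum,
    cluster_samples,
    context_index,
    distance_matrix,
    kl_divergence,
    pyrimidine_context,
    rank_signatures,
    read_spectrum_tsv,
    write_spectrum_tsv,
)
from exocapkit.variants import VariantRecord


def snv(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, alt, 100, 50)


class TestBuildSpectrum:
    def test_single_snv_single_cell(self):
        genome = GenomeAssembly("g", {"c": "GACAG"})
        spec = build_spectrum([snv("c", 3, "C", "T")], genome)
        assert spec.total == 1
        assert spec.counts[context_index("C>T", "A", "A")] == 1

    def test_purine_reference_collapsed_to_pyrimidine_strand(self):
        # G>A with 5'T and 3'C: revcomp -> C>T with 5'G and 3'A
        genome = GenomeAssembly("g", {"c": "ATGCA"})
        spec = build_spectrum([snv("c", 3, "G", "A")], genome)
        assert spec.counts[context_index("C>T", "G", "A")] == 1

    def test_chromosome_edge_skipped(self):
        genome = GenomeAssembly("g", {"c": "CATG"})
        spec = build_spectrum([snv("c", 1, "C", "A")], genome)
        assert spec.total == 0 and spec.skipped_ambiguous_context == 1

    def test_n_context_skipped(self):
        genome = GenomeAssembly("g", {"c": "ANCTG"})
        spec = build_spectrum([snv("c", 3, "C", "G")], genome)
        assert spec.total == 0 and spec.skipped_ambiguous_context == 1

    def test_non_snv_counted_not_tabulated(self):
        genome = GenomeAssembly("g", {"c": "GACAG"})
        indel = VariantRecord("c", 2, "AC", "A", 100, 50)
        spec = build_spectrum([indel], genome)
        assert spec.total == 0 and spec.skipped_non_snv == 1

    def test_collapsed6_matches_row_sums(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=96)
        spec = MutationSpectrum("s", counts)
        col = spec.collapsed6
        assert pytest.approx(sum(col.values())) == 1.0
        assert col["C>T"] == pytest.approx(counts[32:48].sum() / counts.sum())

    def test_strand_collapse_involution(self):
        """Reporting every SNV on the opposite strand leaves the spectrum unchanged."""
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        genome = GenomeAssembly("g", {"c": seq})
        fwd = []
        for pos in range(10, 400, 7):
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fwd.append(snv("c", pos, ref, str(alt)))
        spec_fwd = build_spectrum(fwd, genome)

        rc_seq = reverse_complement(seq)
        genome_rc = GenomeAssembly("g", {"c": rc_seq})
        flipped = [
            snv("c", len(seq) - r.pos + 1, reverse_complement(r.ref), reverse_complement(r.alt))
            for r in fwd
        ]
        spec_rc = build_spectrum(flipped, genome_rc)
        assert np.array_equal(spec_fwd.counts, spec_rc.counts)

    def test_multinomial_recovery(self):
        cat = make_signature_catalog(3, np.random.default_rng(1))
        snvs, genome, _ = make_signature_mixture(
            {"Sig02": 1.0}, 10_000, cat, np.random.default_rng(2)
        )
        spec = build_spectrum(snvs, genome)
        assert spec.total == 10_000
        kl = kl_divergence(spec.frequencies, cat.signatures["Sig02"])
        assert kl < 0.05


class TestKl:
    def test_identity(self):
        p = np.full(96, 1 / 96)
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_cell_closed_form(self):
        val = kl_divergence(
            np.array([0.5, 0.5]), np.array([0.9, 0.1]),
            pseudocount=0.0, symmetrized=False,
        )
        expected = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert val == pytest.approx(expected)
        assert val == pytest.approx(0.5108, abs=5e-4)

    def test_symmetrized_is_mean_of_directions(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(96))
        q = rng.dirichlet(np.ones(96))
        f = kl_divergence(p, q, symmetrized=False)
        b = kl_divergence(q, p, symmetrized=False)
        assert kl_divergence(p, q) == pytest.approx(0.5 * (f + b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.ones(96) / 96, np.ones(6) / 6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_nonnegative_and_zero_iff_equal(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.full(96, 0.5))
        q = rng.dirichlet(np.full(96, 0.5))
        d = kl_divergence(p, q)
        assert d >= 0.0
        if not np.allclose(p, q):
            assert d > 0.0
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)


class TestClustering:
    def _spec(self, name, counts):
        return MutationSpectrum(name, np.asarray(counts, dtype=np.int64))

    def test_identical_pair_merges_first_at_zero(self):
        a = np.zeros(96, dtype=int); a[0] = 100
        b = np.zeros(96, dtype=int); b[50] = 100
        dendro, dm = cluster_samples(
            [self._spec("x1", a), self._spec("x2", a), self._spec("far", b)]
        )
        assert dendro.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert dm.loc["x1", "x2"] == pytest.approx(0.0, abs=1e-12)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        specs = [self._spec(f"s{i}", rng.integers(0, 40, 96)) for i in range(5)]
        d1, _ = cluster_samples(specs)
        d2, _ = cluster_samples(list(reversed(specs)))
        assert np.allclose(d1.linkage_matrix[:, 2], d2.linkage_matrix[:, 2])
        assert d1.labels == d2.labels

    def test_planted_two_groups_recovered(self):
        cat = make_signature_catalog(4, np.random.default_rng(8))
        specs = []
        for i, name in enumerate(["Sig01", "Sig01", "Sig01", "Sig03", "Sig03"]):
            snvs, genome, _ = make_signature_mixture(
                {name: 1.0}, 2_000, cat, np.random.default_rng(30 + i)
            )
            specs.append(build_spectrum(snvs, genome, f"s{i}_{name[-1]}"))
        dendro, _ = cluster_samples(specs)
        cut = dendro.cut(2)
        g1 = {s for s, c in cut.items() if c == cut["s0_1"]}
        assert g1 == {"s0_1", "s1_1", "s2_1"}

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples([self._spec("only", np.ones(96, dtype=int))])

    def test_newick_contains_all_labels(self):
        rng = np.random.default_rng(6)
        specs = [self._spec(f"n{i}", rng.integers(1, 30, 96)) for i in range(4)]
        dendro, _ = cluster_samples(specs)
        nwk = dendro.to_newick()
        assert nwk.endswith(";")
        for s in specs:
            assert s.sample_id in nwk


class TestRanking:
    def test_spectrum_equal_to_signature_ranks_first_with_cosine_one(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 100, 96)
        spec = MutationSpectrum("s", counts)
        freq = spec.frequencies
        cat = make_signature_catalog(4, rng)
        cat.signatures["SigSelf"] = freq
        ranking = rank_signatures(spec, SignatureCatalog(dict(cat.signatures)))
        assert ranking[0][0] == "SigSelf"
        assert ranking[0][1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_one_hot_scores_zero(self):
        a = np.zeros(96); a[0] = 1.0
        b = np.zeros(96, dtype=int); b[1] = 50
        cat = SignatureCatalog({"hot": a})
        ranking = rank_signatures(MutationSpectrum("s", b), cat)
        assert ranking[0][1] == pytest.approx(0.0)

    def test_mixture_components_occupy_top_ranks(self):
        cat = make_signature_catalog(6, np.random.default_rng(10))
        snvs, genome, _ = make_signature_mixture(
            {"Sig02": 0.7, "Sig05": 0.3}, 10_000, cat, np.random.default_rng(11)
        )
        spec = build_spectrum(snvs, genome)
        top2 = {name for name, _ in rank_signatures(spec, cat)[:2]}
        assert top2 == {"Sig02", "Sig05"}

    def test_kl_metric_ranks_equal_first(self):
        cat = make_signature_catalog(3, np.random.default_rng(12))
        sig = cat.signatures["Sig01"]
        counts = np.round(sig * 1_000_000).astype(np.int64)
        spec = MutationSpectrum("s", counts)
        ranking = rank_signatures(spec, cat, metric="kl")
        assert ranking[0][0] == "Sig01"

    def test_zero_spectrum_rejected(self):
        cat = make_signature_catalog(2, np.random.default_rng(13))
        with pytest.raises(ValueError):
            rank_signatures(MutationSpectrum("s"), cat)


class TestIO:
    def test_spectrum_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        specs = [
            MutationSpectrum(f"s{i}", rng.integers(0, 9, 96)) for i in range(3)
        ]
        p = tmp_path / "spec.tsv"
        write_spectrum_tsv(specs, p)
        back = read_spectrum_tsv(p)
        for a, b in zip(specs, back):
            assert a.sample_id == b.sample_id
            assert np.array_equal(a.counts, b.counts)

    def test_signature_catalog_tsv_round_trip(self, tmp_path):
        cat = make_signature_catalog(3, np.random.default_rng(15))
        p = tmp_path / "sigs.tsv"
        cat.write_tsv(p)
        back = SignatureCatalog.read_tsv(p)
        for name in cat.signatures:
            assert np.allclose(cat.signatures[name], back.signatures[name])

    def test_pyrimidine_context_helper(self):
        assert pyrimidine_context("C", "T", "A", "G") == ("C>T", "A", "G")
        assert pyrimidine_context("G", "A", "T", "C") == ("C>T", "G", "A")
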