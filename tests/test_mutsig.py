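"""SBS96 catalog construction, NMF extraction, decomposition, exposures."""

import numpy as np
import pandas as pd
import pytest

from stratomics import synthetic
from stratomics.core_io import SBS96_CLASSES, VariantRecord
from stratomics.mutsig import (
    SignatureModel,
    build_catalog,
    compare_exposures,
    decompose_to_reference,
    extract_signatures,
    sbs96_class,
)


def snv(sample, ref, alt, context, gene="G1", pos=100):
    return VariantRecord(
        sample_id=sample, gene=gene, classification="missense",
        chromosome="1", position=pos, ref_allele=ref, alt_allele=alt,
        trinucleotide_context=context,
    )


class TestSbsClasses:
    def test_pyrimidine_reference_direct(self):
        assert sbs96_class("C", "T", "ACA") == "A[C>T]A"

    def test_purine_reference_reverse_complemented(self):
        # G>A in context TGC: revcomp(TGC)=GCA, G>A complements to C>T
        assert sbs96_class("G", "A", "TGC") == "G[C>T]A"

    def test_context_ref_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sbs96_class("C", "T", "AAA")


class TestCatalog:
    def test_row_sums_conserve_snv_count(self):
        variants = [
            snv("S1", "C", "T", "ACA"),
            snv("S1", "G", "A", "TGC"),
            snv("S2", "T", "G", "ATC"),
        ]
        catalog, skipped = build_catalog(variants)
        assert catalog.loc["S1"].sum() == 2
        assert catalog.loc["S2"].sum() == 1
        assert catalog.values.sum() == 3
        assert all(v == 0 for v in skipped.values())
        assert list(catalog.columns) == list(SBS96_CLASSES)

    def test_non_snv_skipped_with_count(self):
        indel = VariantRecord(
            sample_id="S1", gene="G1", classification="frameshift_del",
            chromosome="1", position=5, ref_allele="AT", alt_allele="A",
        )
        catalog, skipped = build_catalog([indel, snv("S1", "C", "T", "ACA")])
        assert skipped["non_snv"] == 1
        assert catalog.values.sum() == 1

    def test_context_mismatch_raises_with_position(self):
        with pytest.raises(ValueError, match="1:101"):
            build_catalog([snv("S1", "C", "T", "AAA")])

    def test_fasta_lookup_path(self, tmp_path):
        # generator emits a small FASTA plus a context-free demo MAF
        rng = np.random.default_rng(5)
        from stratomics.synthetic import _write_fasta_demo
        from stratomics import core_io
        fasta_path = tmp_path / "ref.fa"
        maf_path = tmp_path / "demo.maf"
        _write_fasta_demo(rng, fasta_path, maf_path)
        from pyfaidx import Fasta

        records = core_io.read_maf(maf_path)
        catalog, skipped = build_catalog(records, fasta=Fasta(str(fasta_path)))
        assert catalog.values.sum() == len(records)
        assert skipped["no_context"] == 0


def simulate_catalog(spectra, n_samples, n_mutations, rng, weights=None):
    rows = []
    k = spectra.shape[1]
    for _ in range(n_samples):
        w = weights if weights is not None else rng.dirichlet(np.ones(k))
        counts = np.zeros(96, dtype=int)
        assign = rng.choice(k, p=w, size=n_mutations)
        for j in range(k):
            counts += rng.multinomial(int((assign == j).sum()), spectra[:, j])
        rows.append(counts)
    return pd.DataFrame(
        rows, columns=list(SBS96_CLASSES), index=[f"S{i:03d}" for i in range(n_samples)]
    )


class TestExtraction:
    def test_single_spectrum_selects_k1_and_recovers(self):
        rng = np.random.default_rng(0)
        spectrum = synthetic.generate_spectra(1, 1.0, rng)
        catalog = simulate_catalog(spectrum, 100, 80, rng, weights=np.array([1.0]))
        model = extract_signatures(catalog, k_min=1, k_max=3, n_replicates=8, seed=1)
        assert model.k == 1
        got = model.signatures.values[:, 0]
        truth = spectrum[:, 0]
        cos = got @ truth / (np.linalg.norm(got) * np.linalg.norm(truth))
        assert cos >= 0.99

    def test_determinism_with_same_seed(self):
        rng = np.random.default_rng(1)
        spectra = synthetic.generate_spectra(2, 0.6, rng)
        catalog = simulate_catalog(spectra, 40, 60, rng)
        m1 = extract_signatures(catalog, k_min=1, k_max=2, n_replicates=4, seed=9)
        m2 = extract_signatures(catalog, k_min=1, k_max=2, n_replicates=4, seed=9)
        pd.testing.assert_frame_equal(m1.diagnostics, m2.diagnostics)
        pd.testing.assert_frame_equal(m1.signatures, m2.signatures)
        pd.testing.assert_frame_equal(m1.exposures, m2.exposures)

    def test_model_invariants(self):
        rng = np.random.default_rng(2)
        spectra = synthetic.generate_spectra(2, 0.6, rng)
        catalog = simulate_catalog(spectra, 30, 60, rng)
        model = extract_signatures(catalog, k_min=2, k_max=2, n_replicates=4, seed=3)
        assert np.allclose(model.signatures.sum(axis=0), 1.0, atol=1e-9)
        assert (model.exposures.values >= 0).all()
        recon = model.reconstruction()
        cos = [
            catalog.values[i] @ recon.values[:, i]
            / (np.linalg.norm(catalog.values[i]) * np.linalg.norm(recon.values[:, i]))
            for i in range(len(catalog))
        ]
        assert np.mean(cos) >= 0.9

    def test_all_zero_catalog_rejected(self):
        catalog = pd.DataFrame(0, index=["S1", "S2"], columns=list(SBS96_CLASSES))
        with pytest.raises(ValueError):
            extract_signatures(catalog, n_replicates=2)

    def test_replicate_floor(self):
        catalog = pd.DataFrame(1, index=["S1", "S2"], columns=list(SBS96_CLASSES))
        with pytest.raises(ValueError):
            extract_signatures(catalog, n_replicates=1)


class TestDecomposition:
    def _model_from(self, W):
        names = [f"SIG{i}" for i in range(W.shape[1])]
        return SignatureModel(
            k=W.shape[1],
            signatures=pd.DataFrame(W, index=list(SBS96_CLASSES), columns=names),
            exposures=pd.DataFrame(np.ones((W.shape[1], 2)), index=names, columns=["S1", "S2"]),
            diagnostics=pd.DataFrame(),
            seed=0,
            n_replicates=2,
        )

    def test_exact_reference_copy_is_100_percent(self):
        rng = np.random.default_rng(3)
        ref = pd.DataFrame(
            synthetic.generate_spectra(3, 0.6, rng), index=list(SBS96_CLASSES),
            columns=["R1", "R2", "R3"],
        )
        model = self._model_from(ref.values[:, [1]])
        (d,) = decompose_to_reference(model, ref)
        assert d.assigned_reference == "R2"
        assert d.contributions["R2"] == pytest.approx(100.0, abs=1e-6)
        assert d.best_single_cosine == pytest.approx(1.0)

    def test_exact_mixture_split(self):
        rng = np.random.default_rng(4)
        ref = pd.DataFrame(
            synthetic.generate_spectra(3, 0.6, rng), index=list(SBS96_CLASSES),
            columns=["R1", "R2", "R3"],
        )
        mix = 0.7 * ref.values[:, 0] + 0.3 * ref.values[:, 1]
        model = self._model_from(mix[:, None])
        (d,) = decompose_to_reference(model, ref)
        assert d.contributions["R1"] == pytest.approx(70.0, abs=1e-6)
        assert d.contributions["R2"] == pytest.approx(30.0, abs=1e-6)
        assert d.contributions.sum() == pytest.approx(100.0, abs=1e-6)

    def test_noisy_mixture_assignment(self):
        rng = np.random.default_rng(5)
        ref = pd.DataFrame(
            synthetic.generate_spectra(3, 0.6, rng), index=list(SBS96_CLASSES),
            columns=["R1", "R2", "R3"],
        )
        hits = 0
        trials = 0
        while trials < 200:
            weights = rng.dirichlet([6, 2, 2])
            order = np.sort(weights)[::-1]
            if order[0] - order[1] < 0.1:
                continue  # no clearly dominant component to recover
            trials += 1
            dominant = int(np.argmax(weights))
            mix = ref.values @ weights
            noisy = rng.dirichlet(mix / mix.sum() * 100.0)
            model = self._model_from(noisy[:, None])
            (d,) = decompose_to_reference(model, ref)
            if d.assigned_reference == f"R{dominant + 1}":
                hits += 1
        assert hits / trials >= 0.95


class TestExposureComparison:
    def _model_with_exposures(self, expo, samples):
        k = expo.shape[0]
        names = [f"SIG{i}" for i in range(k)]
        rng = np.random.default_rng(0)
        W = synthetic.generate_spectra(k, 0.8, rng)
        return SignatureModel(
            k=k,
            signatures=pd.DataFrame(W, index=list(SBS96_CLASSES), columns=names),
            exposures=pd.DataFrame(expo, index=names, columns=samples),
            diagnostics=pd.DataFrame(),
            seed=0,
            n_replicates=2,
        )

    def test_planted_shift_detected_with_power(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(200):
            x = rng.gamma(2.0, 5.0, size=50)
            y = rng.gamma(2.0, 15.0, size=50)  # 3x shift
            samples = [f"A{i}" for i in range(50)] + [f"B{i}" for i in range(50)]
            model = self._model_with_exposures(np.r_[x, y][None, :], samples)
            labels = pd.Series(["A"] * 50 + ["B"] * 50, index=samples)
            res = compare_exposures(model, labels)
            if res["p_value"].iloc[0] < 0.01:
                hits += 1
        assert hits / 200 >= 0.95

    def test_null_pvalues_center_near_half(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            x = rng.gamma(2.0, 5.0, size=40)
            y = rng.gamma(2.0, 5.0, size=40)
            samples = [f"A{i}" for i in range(40)] + [f"B{i}" for i in range(40)]
            model = self._model_with_exposures(np.r_[x, y][None, :], samples)
            labels = pd.Series(["A"] * 40 + ["B"] * 40, index=samples)
            ps.append(compare_exposures(model, labels)["p_value"].iloc[0])
        assert 0.35 <= float(np.median(ps)) <= 0.65

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(8)
        expo = rng.gamma(2.0, 5.0, size=(2, 30))
        samples = [f"S{i}" for i in range(30)]
        model = self._model_with_exposures(expo, samples)
        labels = pd.Series(["A"] * 15 + ["B"] * 15, index=samples)
        swapped = labels.map({"A": "B", "B": "A"})
        r1 = compare_exposures(model, labels)
        r2 = compare_exposures(model, swapped)
        assert np.allclose(r1["p_value"].values, r2["p_value"].values)

    def test_proportion_mode(self):
        rng = np.random.default_rng(9)
        expo = rng.gamma(2.0, 5.0, size=(2, 20))
        samples = [f"S{i}" for i in range(20)]
        model = self._model_with_exposures(expo, samples)
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=samples)
        res = compare_exposures(model, labels, mode="proportions")
        assert set(res.index) == {"SIG0", "SIG1"}
        with pytest.raises(ValueError):
            compare_exposures(model, labels, mode="nope")
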