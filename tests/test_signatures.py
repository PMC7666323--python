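from collections import Counter
from itertools import product

import numpy as np
import pandas as pd
import pytest

from gcprofiler.contexts import BASES, CONTEXT_LABELS, context_label, revcomp
from gcprofiler.io import MutationRecord
from gcprofiler.signatures import (
    SignatureModel,
    build_spectrum,
    classify_context,
    cosine_similarity,
    match_catalog,
    nmf,
    pick_rank_elbow,
    scan_ranks,
)


def _snv(sample, ref, alt, ctx, gene="G1", pos=100):
    return MutationRecord(sample, gene, "missense", "chrS", pos, ref, alt, ctx)


class TestContextClassification:
    def test_pyrimidine_read_off(self):
        assert classify_context(_snv("S1", "C", "A", "ACA")) == "A[C>A]A"

    def test_purine_reverse_complement(self):
        assert classify_context(_snv("S1", "G", "T", "TGT")) == "A[C>A]A"

    def test_indel_unclassifiable(self):
        rec = MutationRecord("S1", "G1", "frameshift_indel", "chrS", 5, "A", "-", None)
        assert classify_context(rec) is None

    def test_context_middle_mismatch_warns_not_raises(self):
        assert classify_context(_snv("S1", "C", "A", "AAA")) is None

    def test_all_96_labels_unique_and_covered(self):
        assert len(set(CONTEXT_LABELS)) == 96
        seen = {
            context_label(ref, alt, five + ref + three)
            for ref in ("C", "T")
            for alt in BASES
            if alt != ref
            for five in BASES
            for three in BASES
        }
        assert seen == set(CONTEXT_LABELS)

    def test_strand_invariance_exhaustive_192_configurations(self):
        """Reverse-complementing any SNV configuration leaves the label fixed."""
        n = 0
        for ref, alt, five, three in product(BASES, BASES, BASES, BASES):
            if ref == alt:
                continue
            ctx = five + ref + three
            label = context_label(ref, alt, ctx)
            flipped = context_label(revcomp(ref), revcomp(alt), revcomp(ctx))
            assert label == flipped and label in CONTEXT_LABELS
            n += 1
        assert n == 192


class TestBuildSpectrum:
    def test_single_category_pileup(self):
        recs = [_snv("S1", "C", "A", "ACA", pos=i) for i in range(1, 6)]
        spec = build_spectrum(recs, {"S1"})
        assert spec.counts.loc["cohort", "A[C>A]A"] == 5
        assert spec.counts.loc["cohort"].sum() == 5

    def test_empty_cohort_all_zero(self):
        spec = build_spectrum([], {"S1", "S2"}, granularity="per_sample")
        assert spec.counts.shape == (2, 96)
        assert (spec.counts.to_numpy() == 0).all()

    def test_hundred_snv_fixture_matches_independent_tally(self, rng):
        recs, tally = [], Counter()
        for i in range(100):
            ref = ("C", "T", "G", "A")[int(rng.integers(4))]
            alts = [b for b in BASES if b != ref]
            alt = alts[int(rng.integers(3))]
            five, three = BASES[int(rng.integers(4))], BASES[int(rng.integers(4))]
            recs.append(_snv("S1", ref, alt, five + ref + three, pos=i + 1))
            tally[context_label(ref, alt, five + ref + three)] += 1
        spec = build_spectrum(recs, {"S1"})
        for label, n in tally.items():
            assert spec.counts.loc["cohort", label] == n
        assert spec.counts.loc["cohort"].sum() == 100

    def test_row_sum_conservation_with_unclassifiable(self):
        recs = [
            _snv("S1", "C", "A", "ACA"),
            MutationRecord("S1", "G1", "frameshift_indel", "chrS", 2, "A", "-", None),
        ]
        spec = build_spectrum(recs, {"S1"})
        assert spec.counts.loc["cohort"].sum() == 1
        assert spec.unclassified["cohort"] == 1


class TestNmf:
    def test_error_trace_monotone_nonincreasing(self, rng, catalog):
        v = rng.poisson(5.0, size=(12, 96)).astype(float)
        _, _, _, trace = nmf(v, 3, n_starts=2, seed=5)
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_factors_nonnegative_and_columns_normalized(self, rng):
        v = rng.poisson(5.0, size=(10, 96)).astype(float)
        res = SignatureModel(
            pd.DataFrame(v, columns=list(CONTEXT_LABELS)), 3
        ).fit(n_starts=2, seed=5)
        assert (res.signatures.to_numpy() >= 0).all()
        assert (res.exposures.to_numpy() >= 0).all()
        assert np.allclose(res.signatures.sum(axis=0), 1.0, atol=1e-9)

    def test_same_seed_bit_identical(self, rng):
        v = rng.poisson(4.0, size=(8, 96)).astype(float)
        w1, h1, e1, _ = nmf(v, 2, n_starts=3, seed=11)
        w2, h2, e2, _ = nmf(v, 2, n_starts=3, seed=11)
        assert np.array_equal(w1, w2) and np.array_equal(h1, h2) and e1 == e2

    def test_rank_one_outer_product_recovered(self, catalog):
        profile = catalog["Signature 1"].to_numpy()
        v = np.outer([100.0, 250.0, 400.0], profile)
        res = SignatureModel(pd.DataFrame(v, columns=list(CONTEXT_LABELS)), 1).fit(
            n_starts=3, seed=0
        )
        assert cosine_similarity(res.signatures["S1"], profile) >= 0.999

    def test_rank_bounds_are_hard_errors(self, rng):
        v = rng.poisson(4.0, size=(3, 96)).astype(float)
        with pytest.raises(ValueError):
            nmf(v, 4)
        with pytest.raises(ValueError):
            nmf(v, 0)
        with pytest.raises(ValueError):
            nmf(np.zeros((3, 96)), 1)

    def test_reconstruction_competitive_with_sklearn(self, rng):
        """Independent cross-check against sklearn's multiplicative-update NMF."""
        sklearn_nmf = pytest.importorskip("sklearn.decomposition").NMF
        v = rng.poisson(6.0, size=(15, 96)).astype(float)
        _, _, err, _ = nmf(v, 3, n_starts=5, seed=3)
        ref = sklearn_nmf(
            n_components=3, solver="mu", init="random", random_state=0,
            max_iter=2000, tol=1e-6,
        )
        w = ref.fit_transform(v)
        ref_err = float(np.linalg.norm(v - w @ ref.components_))
        assert err <= ref_err * 1.02


class TestCatalogMatch:
    def test_identity_column_matches_at_cosine_one(self, catalog):
        sigs = catalog[["Signature 1"]].rename(columns={"Signature 1": "S1"})
        out = match_catalog(sigs, catalog)
        assert out.loc[0, "catalog_name"] == "Signature 1"
        assert out.loc[0, "cosine"] == pytest.approx(1.0)

    def test_orthogonal_vector_unassigned(self, catalog):
        v = np.zeros(96)
        # indicator on the catalog's globally least-loaded category
        v[int(catalog.sum(axis=1).to_numpy().argmin())] = 1.0
        sigs = pd.DataFrame({"S1": v}, index=list(CONTEXT_LABELS))
        out = match_catalog(sigs, catalog, threshold=0.75)
        assert out.loc[0, "catalog_name"] == "unassigned"

    def test_noise_perturbed_column_still_matches_source(self, catalog):
        col = catalog["Signature 5"].to_numpy()
        noisy = col + 0.05 * np.full(96, 1 / 96)
        noisy = noisy / noisy.sum()
        sigs = pd.DataFrame({"S1": noisy}, index=list(CONTEXT_LABELS))
        out = match_catalog(sigs, catalog)
        assert out.loc[0, "catalog_name"] == "Signature 5"
        assert out.loc[0, "cosine"] > 0.95

    def test_planted_three_signature_mixture_recovered(self, catalog, rng):
        names = ["Signature 1", "Signature 6", "Signature 17"]
        profiles = catalog[names].to_numpy().T
        exposures = rng.dirichlet([1.0, 1.0, 1.0], size=50)
        v = np.vstack(
            [rng.multinomial(600, exposures[i] @ profiles) for i in range(50)]
        )
        res = SignatureModel(pd.DataFrame(v, columns=list(CONTEXT_LABELS)), 3).fit(
            n_starts=10, seed=17
        )
        out = res.match(catalog)
        assert sorted(out["catalog_name"]) == sorted(names)
        assert (out["cosine"] >= 0.9).all()


class TestRankSelection:
    def test_elbow_found_at_planted_rank(self, catalog):
        """Planted-rank spectra put the error-curve elbow at the true k."""
        names = ["Signature 1", "Signature 6", "Signature 17"]
        profiles = catalog[names].to_numpy().T
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            expo = rng.dirichlet([1.0] * 3, size=40)
            v = np.vstack([rng.multinomial(500, expo[i] @ profiles) for i in range(40)])
            scan = scan_ranks(
                pd.DataFrame(v, columns=list(CONTEXT_LABELS)),
                ks=range(1, 7), n_starts=2, seed=seed, max_iter=500,
            )
            if pick_rank_elbow(scan) == 3:
                hits += 1
        assert hits >= 0.8 * n_seeds
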