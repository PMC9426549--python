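"""SCG-based taxonomic profiling: assignment, medians, normalization."""

import numpy as np
import pandas as pd
import pytest

from soilmep import synthgen
from soilmep.scgprofile import (
    TaxonProfile,
    assign_nearest_reference,
    lineage_at_rank,
    normalize_profile,
    profile_metagenome,
    scg_taxon_profile,
)
from soilmep.seqcluster import AMINO_ACIDS
from soilmep.synthgen import SCG_FAMILIES, _mutate, _random_protein


def make_catalog(taxa, lineages, families=SCG_FAMILIES):
    rows = []
    for t in taxa:
        for fam in families:
            rows.append({"orf_id": f"{t}_{fam}", "family": fam,
                         "cluster_id": f"{t}_{fam}", "lineage": lineages[t]})
    return pd.DataFrame(rows).set_index("orf_id")


LINEAGE_A = "Bacteria;P1;C1;O1;F1;G1;S_a"
LINEAGE_B = "Bacteria;P2;C2;O2;F2;G2;S_b"


class TestNearestReference:
    def test_identical_sequence_assigned_at_zero_distance(self, rng):
        seq = _random_protein(rng, 250)
        refs = pd.DataFrame(
            {"sequence": [seq, _random_protein(rng, 250)],
             "lineage": [LINEAGE_A, LINEAGE_B]},
            index=["refA", "refB"],
        )
        out = assign_nearest_reference(pd.Series({"c1": seq}), refs)
        assert out.loc["c1", "ref_id"] == "refA"
        assert out.loc["c1", "distance"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_tie_goes_to_lexicographically_first(self, rng):
        seq = _random_protein(rng, 200)
        refs = pd.DataFrame(
            {"sequence": [seq, seq], "lineage": [LINEAGE_A, LINEAGE_B]},
            index=["refB", "refA"],
        )
        out = assign_nearest_reference(pd.Series({"c1": seq}), refs)
        assert out.loc["c1", "ref_id"] == "refA"

    def test_mutated_representatives_recover_source(self, rng):
        # 5% substitutions: at least 95% of queries return to their source
        refs = {}
        for i in range(6):
            refs[f"ref{i}"] = _random_protein(rng, 250)
        ref_df = pd.DataFrame(
            {"sequence": list(refs.values()),
             "lineage": [f"Bacteria;P{i};C;O;F;G;S" for i in range(6)]},
            index=list(refs.keys()),
        )
        correct = 0
        trials = 120
        for trial in range(trials):
            src = f"ref{trial % 6}"
            query = _mutate(refs[src], 0.05, rng)
            out = assign_nearest_reference(pd.Series({"q": query}), ref_df)
            correct += out.loc["q", "ref_id"] == src
        assert correct / trials >= 0.95

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            assign_nearest_reference(
                pd.Series({"c": "MKVL"}),
                pd.DataFrame(columns=["sequence", "lineage"]),
            )


class TestProfile:
    def test_uniform_coverage_median_is_constant(self):
        catalog = make_catalog(["A"], {"A": LINEAGE_A})
        coverage = pd.DataFrame(10.0, index=catalog.index, columns=["s1", "s2"])
        profile = scg_taxon_profile(coverage, catalog, rank="species")
        assert (profile.abundance.to_numpy() == 10.0).all()

    def test_median_robust_to_repeat_like_outlier(self):
        # one family at 1000 (a repeat-inflated gene) must not move the
        # estimate off 10 -- the reason medians are used at all
        catalog = make_catalog(["A"], {"A": LINEAGE_A})
        coverage = pd.DataFrame(10.0, index=catalog.index, columns=["s1"])
        coverage.loc["A_SCG-1", "s1"] = 1000.0
        profile = scg_taxon_profile(coverage, catalog, rank="species")
        assert profile.abundance.iloc[0, 0] == 10.0

    def test_matches_brute_force_recomputation(self, rng):
        taxa = ["A", "B", "C"]
        lineages = {"A": LINEAGE_A, "B": LINEAGE_B,
                    "C": "Bacteria;P1;C1;O1;F3;G3;S_c"}
        catalog = make_catalog(taxa, lineages)
        coverage = pd.DataFrame(
            rng.poisson(8.0, size=(len(catalog), 4)).astype(float),
            index=catalog.index, columns=[f"s{j}" for j in range(4)],
        )
        profile = scg_taxon_profile(coverage, catalog, rank="species")
        # brute force: materialize every (taxon, family, sample) sum
        for taxon in profile.abundance.index:
            for s in coverage.columns:
                vals = []
                for fam in SCG_FAMILIES:
                    total = sum(
                        coverage.loc[orf, s]
                        for orf in catalog.index
                        if catalog.loc[orf, "family"] == fam
                        and catalog.loc[orf, "lineage"] == taxon
                    )
                    if total > 0:
                        vals.append(total)
                expected = float(np.median(vals)) if vals else 0.0
                assert profile.abundance.loc[taxon, s] == pytest.approx(expected)

    def test_rank_aggregation_regroups_before_median(self, rng):
        # A and C share phylum P1: at rank phylum their per-family coverage
        # is summed first, then the median taken
        taxa = ["A", "C"]
        lineages = {"A": LINEAGE_A, "C": "Bacteria;P1;C1;O1;F3;G3;S_c"}
        catalog = make_catalog(taxa, lineages)
        coverage = pd.DataFrame(
            rng.poisson(6.0, size=(len(catalog), 2)).astype(float),
            index=catalog.index, columns=["s1", "s2"],
        )
        profile = scg_taxon_profile(coverage, catalog, rank="phylum")
        assert list(profile.abundance.index) == ["Bacteria;P1"]
        fam_sums = coverage.groupby(catalog["family"]).sum()
        for s in ["s1", "s2"]:
            vals = fam_sums[s][fam_sums[s] > 0]
            assert profile.abundance.loc["Bacteria;P1", s] == pytest.approx(
                float(np.median(vals))
            )

    def test_unknown_rank_rejected(self):
        catalog = make_catalog(["A"], {"A": LINEAGE_A})
        coverage = pd.DataFrame(1.0, index=catalog.index, columns=["s1"])
        with pytest.raises(ValueError):
            scg_taxon_profile(coverage, catalog, rank="kingdom")


class TestNormalization:
    def test_single_taxon_relative_abundance_one(self):
        catalog = make_catalog(["A"], {"A": LINEAGE_A})
        coverage = pd.DataFrame(7.0, index=catalog.index, columns=["s1"])
        profile = profile_metagenome(coverage, catalog, rank="species")
        assert profile.abundance.iloc[0, 0] == pytest.approx(1.0)

    def test_two_equal_taxa_split_evenly(self):
        catalog = make_catalog(["A", "B"], {"A": LINEAGE_A, "B": LINEAGE_B})
        coverage = pd.DataFrame(10.0, index=catalog.index, columns=["s1"])
        profile = profile_metagenome(coverage, catalog, rank="species")
        assert profile.normalizers["s1"] == pytest.approx(20.0)
        assert np.allclose(profile.abundance["s1"], 0.5)

    def test_scale_invariance(self, rng):
        catalog = make_catalog(["A", "B"], {"A": LINEAGE_A, "B": LINEAGE_B})
        coverage = pd.DataFrame(
            rng.poisson(9.0, size=(len(catalog), 3)).astype(float) + 1.0,
            index=catalog.index, columns=["s1", "s2", "s3"],
        )
        base = profile_metagenome(coverage, catalog)
        doubled = profile_metagenome(coverage * 2, catalog)
        pd.testing.assert_frame_equal(base.abundance, doubled.abundance)

    def test_zero_coverage_sample_flagged_and_excluded(self):
        catalog = make_catalog(["A"], {"A": LINEAGE_A})
        coverage = pd.DataFrame({"s1": 5.0, "s2": 0.0}, index=catalog.index)
        profile = profile_metagenome(coverage, catalog)
        assert profile.excluded_samples == ["s2"]
        assert list(profile.abundance.columns) == ["s1"]


class TestGenomeSizeInvariance:
    def test_non_scg_orfs_do_not_move_the_profile(self, rng):
        scen = synthgen.simulate_community(4, 2, 80.0, seed=6)
        mg_small = synthgen.simulate_metagenome(scen, orfs_per_megabase=1.0,
                                                seed=6)
        catalog = mg_small.orfs[mg_small.orfs["family"].isin(SCG_FAMILIES)]
        lineage = catalog["taxon"].map(
            lambda t: ";".join(scen.lineages.loc[t])
        )
        cat = pd.DataFrame({"family": catalog["family"], "lineage": lineage})
        # identical SCG coverage, wildly different non-SCG ORF counts:
        # the non-SCG rows never enter the computation
        profile = profile_metagenome(mg_small.coverage, cat)
        extra = pd.DataFrame(
            rng.poisson(50.0, size=(500, len(scen.samples))).astype(float),
            index=[f"junk{i}" for i in range(500)], columns=scen.samples,
        )
        padded = pd.concat([mg_small.coverage, extra])
        profile_padded = profile_metagenome(padded, cat)
        pd.testing.assert_frame_equal(profile.abundance, profile_padded.abundance)

    def test_equal_abundance_unequal_genomes_estimated_equal(self):
        # two taxa at identical cell abundance, 5x genome-size difference:
        # mean estimated relative abundances agree within 5%
        est = {"A": [], "B": []}
        for seed in range(30):
            scen = synthgen.simulate_community(
                2, 3, 100.0, seed=seed, abundance_sigma=0.0, sample_sigma=0.0,
                genome_size_range=(1_000_000, 1_000_000),
            )
            scen.genome_size.iloc[1] = 5_000_000
            mg = synthgen.simulate_metagenome(scen, orfs_per_megabase=3.0,
                                              seed=seed)
            catalog = mg.orfs[mg.orfs["family"].isin(SCG_FAMILIES)]
            cat = pd.DataFrame(
                {"family": catalog["family"],
                 "lineage": catalog["taxon"].map(
                     lambda t: ";".join(scen.lineages.loc[t]))},
            )
            profile = profile_metagenome(mg.coverage, cat)
            for taxon, key in zip(profile.abundance.index, ["A", "B"]):
                est[key].extend(profile.abundance.loc[taxon].tolist())
        mean_a, mean_b = np.mean(est["A"]), np.mean(est["B"])
        assert abs(mean_a - mean_b) / ((mean_a + mean_b) / 2) < 0.05

    def test_true_abundance_recovered_at_depth(self):
        # 10-taxon scenarios: per-sample Pearson r >= 0.95 between the
        # SCG estimate and the generative truth
        scen = synthgen.simulate_community(10, 3, 100.0, seed=21)
        mg = synthgen.simulate_metagenome(scen, orfs_per_megabase=2.0, seed=21)
        catalog = mg.orfs[mg.orfs["family"].isin(SCG_FAMILIES)]
        cat = pd.DataFrame(
            {"family": catalog["family"],
             "lineage": catalog["taxon"].map(
                 lambda t: ";".join(scen.lineages.loc[t]))},
        )
        profile = profile_metagenome(mg.coverage, cat)
        lineage_of = {";".join(scen.lineages.loc[t]): t for t in scen.taxa}
        truth = scen.abundance.rename(index={";".join(scen.lineages.loc[t]): t
                                             for t in scen.taxa})
        for s in scen.samples:
            est = profile.abundance[s]
            true = scen.abundance[s].loc[[lineage_of[l] for l in est.index]]
            r = np.corrcoef(est.to_numpy(), true.to_numpy())[0, 1]
            assert r >= 0.95


def test_lineage_truncation():
    assert lineage_at_rank(LINEAGE_A, "phylum") == "Bacteria;P1"
    assert lineage_at_rank(LINEAGE_A, "species") == LINEAGE_A
    with pytest.raises(ValueError):
        lineage_at_rank(LINEAGE_A, "strain")
    with pytest.raises(ValueError):
        lineage_at_rank("Bacteria;P1", "phylum")
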