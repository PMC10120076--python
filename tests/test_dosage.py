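"""Dosage-expression operations: exon-union lengths vs a per-base oracle,
the length-normalization formula, ortholog aggregation conservation, size
factors, fold changes, dosage bins, FPKM/TPM and the detection filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shhscreen import (
    CountSimConfig,
    DosageExperiment,
    GeneModel,
    aggregate_orthologs,
    assign_bins,
    detection_filter,
    dosage_bins,
    exon_union_length,
    fold_changes,
    fpkm,
    length_normalize,
    simulate_counts,
    size_factors,
    tpm,
)
from shhscreen.errors import DosageError


def union_length_oracle(exons):
    """Per-base incidence: mark every covered base in a set."""
    covered = set()
    for s, e in exons:
        covered.update(range(s, e))
    return len(covered)


class TestExonUnionLength:
    def test_single_exon(self):
        assert exon_union_length([(0, 100)]) == 100

    def test_overlapping_pair(self):
        assert exon_union_length([(0, 100), (50, 150)]) == 150
        assert union_length_oracle([(0, 100), (50, 150)]) == 150

    def test_disjoint_additivity(self):
        assert exon_union_length([(0, 10), (20, 30)]) == 20

    def test_duplicates_counted_once(self):
        assert exon_union_length([(0, 50), (0, 50), (10, 40)]) == 50

    def test_malformed_interval_names_gene(self):
        with pytest.raises(DosageError, match="badgene"):
            exon_union_length([(10, 10)], gene_id="badgene")

    def test_random_models_match_per_base_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 8))
            exons = []
            for _ in range(k):
                s = int(rng.integers(0, 9000))
                exons.append((s, s + int(rng.integers(1, 1000))))
            assert exon_union_length(exons) == union_length_oracle(exons)

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 200)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_union_bounds(self, exons):
        length = exon_union_length(exons)
        assert 0 < length <= sum(e - s for s, e in exons)
        assert length == union_length_oracle(exons)


class TestLengthNormalize:
    def test_counts_equal_length_gives_fifty(self):
        assert length_normalize(1200, 1200) == 50.0
        assert length_normalize(7, 7) == 50.0

    def test_zero_counts(self):
        assert length_normalize(0, 1000) == 0.0

    def test_direct_formula(self):
        assert length_normalize(100, 1000) == pytest.approx(5.0)

    def test_linear_in_counts_inverse_in_length(self, rng):
        rc, gl = 37.0, 890
        base = length_normalize(rc, gl)
        assert length_normalize(3 * rc, gl) == pytest.approx(3 * base)
        assert length_normalize(rc, 2 * gl) == pytest.approx(base / 2)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(DosageError):
            length_normalize(10, 0)


class TestSizeFactors:
    def test_identical_samples_equal_factors(self):
        counts = pd.DataFrame({"s1": [2, 4, 8], "s2": [2, 4, 8]}, index=list("abc"))
        sf = size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_scale_equivariance(self):
        a = pd.DataFrame({"s1": [2, 4, 8], "s2": [4, 8, 16]}, index=list("abc"))
        sf = size_factors(a)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_hand_example_matches_brute_force(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [20, 10, 5]}, index=list("abc"))
        sf = size_factors(counts)
        # brute-force median-of-ratios
        import math
        for j, s in enumerate(["s1", "s2"]):
            ratios = []
            for g in range(3):
                row = counts.iloc[g]
                geo = math.exp(sum(math.log(x) for x in row) / 2)
                ratios.append(row.iloc[j] / geo)
            assert sf[s] == pytest.approx(sorted(ratios)[1])

    def test_no_common_nonzero_gene_errors(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]}, index=list("ab"))
        with pytest.raises(DosageError):
            size_factors(counts)


class TestAggregateOrthologs:
    def setup_case(self):
        counts = pd.DataFrame(
            {"t1": [100, 25], "e1": [100, 0]},
            index=["mGene", "HSA-mGene"],
        )
        lengths = pd.Series({"mGene": 500, "HSA-mGene": 250})
        species = pd.Series({"mGene": "mouse", "HSA-mGene": "human"})
        omap = pd.DataFrame({"human_id": ["HSA-mGene"], "mouse_id": ["mGene"]})
        return counts, lengths, omap, species

    def test_merged_equals_sum_of_length_normalized_inputs(self):
        counts, lengths, omap, species = self.setup_case()
        agg = aggregate_orthologs(counts, lengths, omap, species)
        # mouse len-norm: 50*100/500 = 10; human trisomic: 50*25/250 = 5
        assert agg.merged.loc["mGene", "t1"] == pytest.approx(15.0)
        assert agg.merged.loc["mGene", "e1"] == pytest.approx(10.0)
        assert agg.merged.loc["mGene", "t1"] / agg.merged.loc["mGene", "e1"] == pytest.approx(1.5)
        assert agg.human_fraction.loc["mGene", "t1"] == pytest.approx(5 / 15)

    def test_zero_human_row_is_identity(self):
        counts, lengths, omap, species = self.setup_case()
        counts.loc["HSA-mGene"] = 0
        agg = aggregate_orthologs(counts, lengths, omap, species)
        assert agg.merged.loc["mGene", "t1"] == pytest.approx(10.0)
        assert (agg.human_fraction == 0).all().all()

    def test_unmapped_human_gene_reported_and_excluded(self):
        counts, lengths, omap, species = self.setup_case()
        counts.loc["HSA-orphan"] = [5, 0]
        lengths["HSA-orphan"] = 100
        species["HSA-orphan"] = "human"
        agg = aggregate_orthologs(counts, lengths, omap, species)
        assert agg.unmapped_human == ["HSA-orphan"]
        assert "HSA-orphan" not in agg.merged.index

    def test_missing_length_errors(self):
        counts, lengths, omap, species = self.setup_case()
        with pytest.raises(DosageError, match="no length"):
            aggregate_orthologs(counts, lengths.drop("HSA-mGene"), omap, species)

    def test_conservation_on_random_matrices(self, rng):
        n_mouse, n_samples = 12, 4
        mids = [f"m{i}" for i in range(n_mouse)]
        hids = [f"h{i}" for i in range(n_mouse)]
        counts = pd.DataFrame(
            rng.integers(0, 500, (2 * n_mouse, n_samples)).astype(float),
            index=mids + hids,
            columns=[f"s{j}" for j in range(n_samples)],
        )
        lengths = pd.Series(rng.integers(100, 5000, 2 * n_mouse), index=mids + hids)
        species = pd.Series(["mouse"] * n_mouse + ["human"] * n_mouse, index=mids + hids)
        omap = pd.DataFrame({"human_id": hids, "mouse_id": mids})
        agg = aggregate_orthologs(counts, lengths, omap, species)
        expected = (50 * counts.div(lengths, axis=0)).loc[mids].to_numpy() + (
            50 * counts.div(lengths, axis=0)
        ).loc[hids].to_numpy()
        assert np.array_equal(agg.merged.loc[mids].to_numpy(), expected)


class TestFoldChanges:
    def make_norm(self, t_vals, e_vals, genes=("g1",)):
        data = {}
        for i, v in enumerate(t_vals):
            data[f"t{i}"] = v
        for i, v in enumerate(e_vals):
            data[f"e{i}"] = v
        df = pd.DataFrame(data, index=list(genes))
        genotype = pd.Series(
            ["trisomic"] * len(t_vals) + ["euploid"] * len(e_vals), index=df.columns
        )
        return df, genotype

    def test_identical_means_give_one(self):
        df, gt = self.make_norm([[10.0], [10.0]], [[10.0], [10.0]])
        out = fold_changes(df, gt, detected=pd.Series(True, index=df.index))
        assert out.loc["g1", "fold_change"] == pytest.approx(1.0)

    def test_direct_ratio(self):
        df, gt = self.make_norm([[15.0], [15.0]], [[10.0], [10.0]])
        out = fold_changes(df, gt, detected=pd.Series(True, index=df.index))
        assert out.loc["g1", "fold_change"] == pytest.approx(1.5)

    def test_zero_euploid_uses_pseudocount_never_divides_by_zero(self):
        df, gt = self.make_norm([[4.0], [4.0]], [[0.0], [0.0]])
        out = fold_changes(df, gt, detected=pd.Series(True, index=df.index), pseudocount=0.5)
        assert out.loc["g1", "fold_change"] == pytest.approx(4.5 / 0.5)

    def test_undetected_gene_binned_undetected(self):
        df, gt = self.make_norm([[0.0], [0.0]], [[0.0], [0.0]])
        out = fold_changes(df, gt)
        assert np.isnan(out.loc["g1", "fold_change"])
        assert out.loc["g1", "dosage_bin"] == "undetected"

    def test_parameter_recovery_on_simulated_counts(self):
        """With 4 vs 4 samples, 500 genes and dispersion 0.05 the fitted
        mean trisomic fold change recovers the 3:2 dosage ratio within
        +/-0.05 and null genes stay within +/-0.05 of 1.0."""
        sim = simulate_counts(
            CountSimConfig(n_genes=500, n_trisomic_genes=100, dispersion=0.05, seed=0)
        )
        res = DosageExperiment.from_simulation(sim).fit()
        assert res.mean_trisomic_fold_change == pytest.approx(1.5, abs=0.05)
        null_fc = res.summaries.loc[~res.summaries["trisomic"], "fold_change"].dropna()
        assert null_fc.mean() == pytest.approx(1.0, abs=0.05)

    def test_sample_rescaling_absorbed_by_size_factors(self):
        sim = simulate_counts(
            CountSimConfig(n_genes=120, n_trisomic_genes=30, dispersion=0.05, seed=4)
        )
        res0 = DosageExperiment.from_simulation(sim).fit()
        scaled = sim.counts.copy()
        scaled[scaled.columns[0]] *= 5
        import dataclasses
        sim2 = dataclasses.replace(sim, counts=scaled)
        res1 = DosageExperiment.from_simulation(sim2).fit()
        pd.testing.assert_series_equal(
            res0.summaries["fold_change"], res1.summaries["fold_change"], rtol=1e-9
        )


class TestBins:
    def test_three_way_split(self):
        fc = pd.Series([1.0, 1.5, 2.0])
        counts = dosage_bins(fc)
        assert counts["below"] == 1 and counts["central"] == 1 and counts["above"] == 1

    def test_empty_input_all_zero(self):
        counts = dosage_bins(pd.Series([], dtype=float))
        assert (counts == 0).all()

    @pytest.mark.parametrize("value,expected", [(1.3, "central"), (1.7, "central"), (1.7000001, "above"), (1.2999999, "below")])
    def test_boundaries_closed_central_bin(self, value, expected):
        bins = assign_bins(pd.Series([value]))
        assert bins.iloc[0] == expected

    def test_invalid_bounds(self):
        with pytest.raises(DosageError):
            assign_bins(pd.Series([1.0]), lo=1.7, hi=1.3)


class TestFpkmTpm:
    def test_fpkm_direct_formula(self):
        assert fpkm(10, 1000, 10**6) == pytest.approx(10.0)

    def test_tpm_sums_to_one_million(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 50))
            rc = rng.integers(0, 1000, n).astype(float)
            if rc.sum() == 0:
                rc[0] = 1
            gl = rng.integers(100, 5000, n)
            assert tpm(rc, gl).sum() == pytest.approx(1e6)

    def test_single_gene_tpm(self):
        assert tpm([123.0], [700]) == pytest.approx([1e6])

    def test_zero_totals_rejected(self):
        with pytest.raises(DosageError):
            fpkm(10, 1000, 0)
        with pytest.raises(DosageError):
            tpm([0.0, 0.0], [100, 100])


class TestDetectionFilter:
    def make_evidence(self, detected, fpkms, tpms):
        return pd.DataFrame(
            {
                "detected_in_rnaseq": [detected],
                "fpkm_values": [fpkms],
                "tpm_values": [tpms],
            },
            index=["g"],
        )

    def test_all_three_fail_excluded(self):
        ev = self.make_evidence(False, [0.2, 0.3], [0.1])
        assert detection_filter(ev) == ["g"]

    def test_single_fpkm_rescues(self):
        ev = self.make_evidence(False, [0.2, 3.0], [0.1])
        assert detection_filter(ev) == []

    def test_detected_in_rnaseq_rescues_despite_low_external_evidence(self):
        ev = self.make_evidence(True, [0.2], [0.1])
        assert detection_filter(ev) == []

    def test_missing_column_errors(self):
        ev = self.make_evidence(False, [0.2], [0.1]).drop(columns=["tpm_values"])
        with pytest.raises(DosageError, match="tpm_values"):
            detection_filter(ev)


def test_plot_density_returns_axes():
    import matplotlib

    matplotlib.use("Agg")
    sim = simulate_counts(CountSimConfig(n_genes=80, n_trisomic_genes=20, seed=1))
    ax = DosageExperiment.from_simulation(sim).fit().plot_density()
    assert ax.get_xlabel() == "fold change"


class TestDosageExperimentTranschromosomic:
    def test_merged_recovery(self):
        sim = simulate_counts(
            CountSimConfig(
                n_genes=500, n_trisomic_genes=100, transchromosomic=True, seed=3,
                model_name="TcSim",
            )
        )
        res = DosageExperiment.from_simulation(sim).fit()
        assert res.mean_trisomic_fold_change == pytest.approx(1.5, abs=0.08)
        assert res.aggregation is not None
        # human fraction of merged trisomic signal ~ 1/3 in trisomic samples
        tri_samples = sim.samples.loc[sim.samples["genotype"] == "trisomic", "sample"]
        tri_genes = sim.truth.loc[sim.truth["copies"] == 3, "gene_id"]
        frac = res.aggregation.human_fraction.loc[tri_genes, tri_samples].to_numpy()
        assert np.nanmean(frac) == pytest.approx(1 / 3, abs=0.03)
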