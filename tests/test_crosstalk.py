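import numpy as np
import pandas as pd
import pytest

from spatialtme import coloc, crosstalk, spatial_io, synthgen

from conftest import de_calibration_inputs, make_cells, make_matrix


def lr_layout(receiver_x=30.0, n=30, receptor_high=20, receptor_low=2):
    """Senders at x=0; high-receptor receivers at receiver_x; low-receptor
    receivers at 70 um. Rows spaced 300 um apart so pairs are independent."""
    rows = []
    for i in range(n):
        y = i * 300.0
        rows.append((f"s{i}", 0.0, y, "F1", "C", "P", "T", "Capillary"))
        rows.append((f"hi{i}", receiver_x, y, "F1", "C", "P", "T", "mCAF"))
        rows.append((f"lo{i}", 70.0, y, "F1", "C", "P", "T", "mCAF"))
    cells = pd.DataFrame(
        rows, columns=["cell_id", "x_um", "y_um", "fov_id", "core_id",
                       "patient_id", "region", "cell_type"],
    )
    lig = np.where(cells["cell_type"] == "Capillary", 20, 0)
    rec = np.where(cells["cell_id"].str.startswith("hi"), receptor_high,
                   np.where(cells["cell_id"].str.startswith("lo"),
                            receptor_low, 0))
    filler = np.ones(len(cells), dtype=int)
    matrix = make_matrix(cells, np.vstack([lig, rec, filler]),
                         genes=["DLL4", "NOTCH3", "FILL"])
    return cells, spatial_io.normalize(matrix)


class TestProximityFlags:
    def test_radius_threshold_geometry(self):
        cells = make_cells([0.0, 79.0, 200.0, 281.0], ["mCAF", "Capillary",
                                                       "mCAF", "Capillary"])
        flags = crosstalk.proximity_flags(cells, "mCAF", "Capillary",
                                          mode="radius", threshold=80.0)
        assert flags.proximal.tolist() == [True, False]

    def test_no_target_in_fov_all_distal(self):
        cells = make_cells([0.0, 1.0, 2.0], ["mCAF"] * 3)
        flags = crosstalk.proximity_flags(cells, "mCAF", "Capillary",
                                          mode="radius", threshold=80.0)
        assert not flags.proximal.any()

    def test_missing_reference_error(self):
        cells = make_cells([0.0, 1.0], ["A", "B"])
        with pytest.raises(ValueError, match="reference"):
            crosstalk.proximity_flags(cells, "Z", "A")

    def test_knn_mode_matches_radius_on_sparse_layout(self):
        """When every in-k neighbor also lies inside the radius (and vice
        versa), both predicates agree."""
        rng = np.random.default_rng(8)
        n = 80
        cells = make_cells(rng.uniform(0, 2000, n),
                           rng.choice(["mCAF", "Capillary"], n),
                           ys=rng.uniform(0, 2000, n))
        g = coloc.build_knn(cells, k=n - 1)
        radius = crosstalk.proximity_flags(cells, "mCAF", "Capillary",
                                           mode="radius", threshold=5000.0)
        knn = crosstalk.proximity_flags(cells, "mCAF", "Capillary",
                                        mode="knn", threshold=n - 1, graph=g)
        assert np.array_equal(radius.proximal, knn.proximal)

    def test_radius_predicate_symmetric(self):
        rng = np.random.default_rng(4)
        n = 100
        cells = make_cells(rng.uniform(0, 400, n),
                           rng.choice(["A", "B"], n), ys=rng.uniform(0, 400, n))
        ab = crosstalk.proximity_flags(cells, "A", "B", "radius", 50.0)
        ba = crosstalk.proximity_flags(cells, "B", "A", "radius", 50.0)
        # any proximal A implies at least one proximal B and conversely
        assert ab.proximal.any() == ba.proximal.any()

    def test_truth_flags_reproduced_in_radius_mode(self, default_cohort):
        cfg = default_cohort.config
        flags = crosstalk.proximity_flags(
            default_cohort.cells, cfg.coupling.receiver, cfg.coupling.sender,
            mode="radius", threshold=cfg.coupling.radius_um,
        )
        truth = default_cohort.truth["proximal"].to_numpy()[flags.cell_rows]
        assert np.array_equal(flags.proximal, truth)


class TestProximityDE:
    def test_identical_groups_no_discoveries(self):
        rng = np.random.default_rng(0)
        cells = make_cells(np.arange(40, dtype=float), ["mCAF"] * 40)
        counts = rng.poisson(5, size=(30, 20))
        matrix = spatial_io.normalize(
            make_matrix(cells, np.hstack([counts, counts]) + 1)
        )
        flags = crosstalk.ProximityFlags(
            ref_type="mCAF", target_type="Capillary", mode="radius",
            threshold=80.0, cell_rows=np.arange(40),
            proximal=np.array([True] * 20 + [False] * 20),
        )
        de = crosstalk.proximity_de(matrix, flags)
        assert (de["p"] == 1.0).all()
        assert (de["q"] >= 0.05).all()

    def test_one_group_empty_error(self):
        cells = make_cells(np.arange(4, dtype=float), ["mCAF"] * 4)
        matrix = spatial_io.normalize(make_matrix(cells, np.ones((3, 4), int)))
        flags = crosstalk.ProximityFlags("mCAF", "Capillary", "radius", 80.0,
                                         np.arange(4), np.ones(4, bool))
        with pytest.raises(ValueError, match="empty"):
            crosstalk.proximity_de(matrix, flags)

    def test_planted_program_detected(self):
        cells, matrix, planted, proximal = de_calibration_inputs(
            n_recv=1000, seed=5
        )
        matrix = spatial_io.normalize(matrix)
        flags = crosstalk.proximity_flags(cells, "mCAF", "Capillary",
                                          mode="radius", threshold=30.0)
        de = crosstalk.proximity_de(matrix, flags)
        hits = set(de.loc[de["q"] < 0.05, "gene"])
        assert len(hits & set(planted)) / len(planted) >= 0.8

    def test_q_at_least_p_and_gene_order_invariance(self):
        cells, matrix, planted, _ = de_calibration_inputs(n_recv=200, seed=6)
        matrix = spatial_io.normalize(matrix)
        flags = crosstalk.proximity_flags(cells, "mCAF", "Capillary",
                                          mode="radius", threshold=30.0)
        subset = ["PRG000", "G0005", "PRG001", "G0001"]
        de = crosstalk.proximity_de(matrix, flags, gene_subset=subset)
        assert (de["q"] >= de["p"] - 1e-12).all()
        de2 = crosstalk.proximity_de(matrix, flags, gene_subset=subset[::-1])
        merged = de.merge(de2, on="gene", suffixes=("_a", "_b"))
        assert np.allclose(merged["p_a"], merged["p_b"])


class TestProximalFraction:
    def test_all_proximal_fraction_one(self):
        cells = make_cells([0.0, 10.0, 1000.0, 1010.0],
                           ["mCAF", "Capillary", "mCAF", "Capillary"],
                           region=["T", "T", "N", "N"])
        flags = crosstalk.proximity_flags(cells, "mCAF", "Capillary",
                                          "radius", 80.0)
        table = crosstalk.proximal_fraction(cells, flags)
        got = table.set_index("region")["fraction"]
        assert got["T"] == 1.0 and got["N"] == 1.0

    def test_region_coupling_ordering_recovered(self, default_cohort):
        """mCAFs near capillaries are commoner in T/B than N (planted via the
        region-restricted capillary-CAF niche). Measured at the coupling
        radius; at long range the predicate saturates in every region."""
        flags = crosstalk.proximity_flags(default_cohort.cells, "mCAF",
                                          "Capillary", "radius", 30.0)
        table = crosstalk.proximal_fraction(default_cohort.cells, flags)
        frac = table.set_index("region")["fraction"]
        assert frac["T"] > frac["N"] and frac["B"] > frac["N"]

    def test_empty_region_is_null(self):
        cells = make_cells([0.0, 10.0], ["mCAF", "Capillary"], region="T")
        flags = crosstalk.proximity_flags(cells, "mCAF", "Capillary",
                                          "radius", 80.0)
        table = crosstalk.proximal_fraction(cells, flags)
        assert np.isnan(table.set_index("region").loc["N", "fraction"])


class TestLRScore:
    def test_zero_ligand_zero_score(self):
        cells, matrix = lr_layout()
        zero = matrix.counts.toarray()
        zero[0] = 0
        m = spatial_io.normalize(make_matrix(cells, zero,
                                             genes=["DLL4", "NOTCH3", "FILL"]))
        res = crosstalk.lr_score(m, cells, "DLL4", "NOTCH3",
                                 "Capillary", "mCAF", range_um=80.0)
        assert res.pooled_score == 0.0

    def test_half_saturation_at_kh(self):
        cells, matrix = lr_layout()
        res = crosstalk.lr_score(matrix, cells, "DLL4", "NOTCH3",
                                 "Capillary", "mCAF", range_um=80.0)
        # Kh set exactly to L*R makes the Hill form give 1/2
        lr_product = res.pooled_L * res.pooled_R
        res2 = crosstalk.lr_score(matrix, cells, "DLL4", "NOTCH3",
                                  "Capillary", "mCAF", range_um=80.0,
                                  kh=lr_product)
        assert res2.pooled_score == pytest.approx(0.5)

    def test_score_bounded(self):
        cells, matrix = lr_layout()
        res = crosstalk.lr_score(matrix, cells, "DLL4", "NOTCH3",
                                 "Capillary", "mCAF", range_um=80.0)
        assert 0.0 <= res.pooled_score < 1.0

    def test_range_gating_strictly_lowers_out_of_range_score(self):
        """With the high-receptor receivers in range the score strictly
        exceeds the score after they are moved out of range."""
        near, m_near = lr_layout(receiver_x=30.0)
        far, m_far = lr_layout(receiver_x=500.0)
        s_near = crosstalk.lr_score(m_near, near, "DLL4", "NOTCH3",
                                    "Capillary", "mCAF", range_um=80.0)
        s_far = crosstalk.lr_score(m_far, far, "DLL4", "NOTCH3",
                                   "Capillary", "mCAF", range_um=80.0)
        assert s_near.pooled_score > s_far.pooled_score

    def test_monotone_in_ligand_counts(self):
        cells, _ = lr_layout()
        base = None
        scores = []
        for lig_level in (1, 5, 20):
            lig = np.where(cells["cell_type"] == "Capillary", lig_level, 0)
            rec = np.where(cells["cell_type"] == "mCAF", 5, 0)
            m = spatial_io.normalize(
                make_matrix(cells, np.vstack([lig, rec,
                                              np.ones(len(cells), int)]),
                            genes=["DLL4", "NOTCH3", "FILL"])
            )
            scores.append(
                crosstalk.lr_score(m, cells, "DLL4", "NOTCH3", "Capillary",
                                   "mCAF", range_um=80.0).pooled_score
            )
        assert scores == sorted(scores)

    def test_unknown_gene_error(self):
        cells, matrix = lr_layout()
        with pytest.raises(KeyError):
            crosstalk.lr_score(matrix, cells, "NOPE", "NOTCH3",
                               "Capillary", "mCAF")


class TestLRPermutation:
    def test_p_bounded_below_and_planted_coupling_small_p(self):
        cells, matrix = lr_layout(n=20)
        obs, p = crosstalk.lr_permutation(matrix, cells, "DLL4", "NOTCH3",
                                          "Capillary", "mCAF", range_um=80.0,
                                          n_perm=99, seed=0)
        assert p >= 1 / 100
        assert p <= 0.05

    def test_degenerate_labels_error(self):
        cells = make_cells(np.arange(6, dtype=float), ["mCAF"] * 6)
        matrix = spatial_io.normalize(make_matrix(cells, np.ones((2, 6), int),
                                                  genes=["DLL4", "NOTCH3"]))
        with pytest.raises(ValueError, match="degenerate"):
            crosstalk.lr_permutation(matrix, cells, "DLL4", "NOTCH3",
                                     "mCAF", "mCAF", n_perm=99)


class TestPseudobulk:
    def test_single_cell_fov_equals_that_cell(self):
        cells = make_cells([0.0, 100.0], ["mCAF", "mCAF"], fov=["F1", "F2"])
        matrix = spatial_io.normalize(make_matrix(cells, [[4, 8], [2, 6]]))
        table = crosstalk.fov_pseudobulk(matrix, cells, "mCAF", min_cells=1)
        dense = matrix.normalized.toarray()
        assert np.allclose(table.loc["F1"], dense[:, 0])
        assert np.allclose(table.loc["F2"], dense[:, 1])

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(1)
        cells = make_cells(rng.uniform(0, 100, 12), ["mCAF"] * 12)
        counts = rng.poisson(6, size=(4, 12)) + 1
        m = spatial_io.normalize(make_matrix(cells, counts))
        t1 = crosstalk.fov_pseudobulk(m, cells, "mCAF", min_cells=1)
        perm = rng.permutation(12)
        cells2 = cells.iloc[perm].reset_index(drop=True)
        m2 = spatial_io.normalize(make_matrix(cells2, counts[:, perm]))
        t2 = crosstalk.fov_pseudobulk(m2, cells2, "mCAF", min_cells=1)
        assert np.allclose(t1, t2)

    def test_min_cell_filter_gives_nan(self):
        cells = make_cells([0.0, 1.0, 2.0], ["mCAF", "mCAF", "mCAF"],
                           fov=["F1", "F1", "F2"])
        m = spatial_io.normalize(make_matrix(cells, [[1, 2, 3]]))
        table = crosstalk.fov_pseudobulk(m, cells, "mCAF", min_cells=2)
        assert np.isnan(table.loc["F2"]).all()
        assert np.isfinite(table.loc["F1"]).all()


class TestFOVCorrelation:
    def test_linear_relation_r_one(self):
        x = np.arange(10, dtype=float)
        res = crosstalk.fov_correlation(x, 2 * x)
        assert res.r == pytest.approx(1.0)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        assert crosstalk.fov_correlation(x, x).r == pytest.approx(1.0)

    def test_zero_variance_null_with_note(self):
        res = crosstalk.fov_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(res.r) and "variance" in res.note

    def test_pairwise_nan_deletion(self):
        x = np.array([1.0, 2, np.nan, 4, 5])
        y = np.array([2.0, 4, 6, 8, 10])
        res = crosstalk.fov_correlation(x, y)
        assert res.n == 4 and res.r == pytest.approx(1.0)

    def test_independent_vectors_rarely_exceed_0p4(self):
        rng = np.random.default_rng(0)
        exceed = 0
        for _ in range(100):
            r = crosstalk.fov_correlation(rng.normal(size=60),
                                          rng.normal(size=60)).r
            exceed += abs(r) >= 0.4
        assert exceed <= 5


class TestSignatureScore:
    def test_single_gene_set_is_zscore(self):
        table = pd.DataFrame({"g1": [1.0, 2.0, 3.0], "g2": [9.0, 9.0, 9.0]})
        score, missing = crosstalk.signature_score(table, ["g1"])
        z = (table["g1"] - table["g1"].mean()) / table["g1"].std(ddof=0)
        assert np.allclose(score, z)

    def test_duplicated_gene_same_as_single(self):
        table = pd.DataFrame({"g1": [1.0, 2.0, 3.0]})
        a, _ = crosstalk.signature_score(table, ["g1"])
        b, _ = crosstalk.signature_score(table, ["g1", "g1"])
        assert np.allclose(a, b)

    def test_missing_members_reported_and_all_missing_error(self):
        table = pd.DataFrame({"g1": [1.0, 2.0, 3.0]})
        _, missing = crosstalk.signature_score(table, ["g1", "gX"])
        assert missing == ["gX"]
        with pytest.raises(ValueError, match="member"):
            crosstalk.signature_score(table, ["gX"])

    def test_planted_covarying_signatures_correlate_positively(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(size=50)
        table = pd.DataFrame(
            {f"a{i}": latent + rng.normal(0, 0.5, 50) for i in range(4)}
            | {f"b{i}": latent + rng.normal(0, 0.5, 50) for i in range(4)}
        )
        sa, _ = crosstalk.signature_score(table, [f"a{i}" for i in range(4)])
        sb, _ = crosstalk.signature_score(table, [f"b{i}" for i in range(4)])
        assert crosstalk.fov_correlation(sa, sb).r > 0.5


class TestCorrelatedGenes:
    def test_exact_copy_included_with_r_one(self):
        rng = np.random.default_rng(0)
        anchor = rng.normal(size=30)
        table = pd.DataFrame({"NOTCH3": anchor, "copy": anchor,
                              "noise": rng.normal(size=30)})
        res = crosstalk.correlated_genes(table, "NOTCH3")
        assert res.iloc[0]["gene"] == "copy"
        assert res.iloc[0]["r"] == pytest.approx(1.0)

    def test_constant_gene_excluded_and_constant_anchor_error(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"NOTCH3": rng.normal(size=20),
                              "const": np.ones(20)})
        res = crosstalk.correlated_genes(table, "NOTCH3")
        assert "const" not in set(res["gene"])
        table2 = pd.DataFrame({"NOTCH3": np.ones(20),
                               "g": rng.normal(size=20)})
        with pytest.raises(ValueError, match="constant"):
            crosstalk.correlated_genes(table2, "NOTCH3")

    def test_planted_correlates_recovered(self):
        rng = np.random.default_rng(2)
        n = 200
        anchor = rng.normal(size=n)
        data = {"NOTCH3": anchor}
        for i in range(20):  # true r ~ 0.6
            data[f"hit{i}"] = 0.6 * anchor + 0.8 * rng.normal(size=n)
        for i in range(100):
            data[f"null{i}"] = rng.normal(size=n)
        res = crosstalk.correlated_genes(pd.DataFrame(data), "NOTCH3",
                                         r_min=0.4, p_max=0.05)
        hits = set(res["gene"])
        assert len({f"hit{i}" for i in range(20)} & hits) >= 18
        assert len({g for g in hits if g.startswith("null")}) <= 5
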