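import numpy as np
import pandas as pd
import pytest

from spatialcci.celltype_pairs import all_pair_distances, classify_pairs
from spatialcci.consensus import accuracy_vs_reference
from spatialcci.des import PredictionTable
from spatialcci.simulate import (
    SimulationConfig,
    consistency_filter,
    make_fixture,
    plant_interactions,
    select_celltypes_and_map,
    simulate_dataset,
    write_bundle,
)

SMALL_FIXTURE = dict(
    n_lr=40, n_complex=3, spots_per_band=16, band_rows=8,
    cells_per_type=90, n_noise_genes=5,
)
SMALL_CFG = dict(n_lr_per_pair=6, n_perm=100)


@pytest.fixture(scope="module")
def template():
    return make_fixture(seed=3, **SMALL_FIXTURE)


@pytest.fixture(scope="module")
def cfg():
    return SimulationConfig(seed=3, **SMALL_CFG)


@pytest.fixture(scope="module")
def final_dataset(template, cfg):
    """One fully simulated dataset shared by the slower checks."""
    rng = np.random.default_rng(cfg.seed)
    ds = select_celltypes_and_map(template, cfg, rng)
    ds = plant_interactions(ds, template.db, cfg, rng)
    pre_plant_counts = ds.sc_counts.copy()
    ds = consistency_filter(ds, template.db, cfg)
    return ds, pre_plant_counts


class TestMakeFixture:
    def test_yields_near_and_far_pairs(self, template):
        pairs = classify_pairs(
            all_pair_distances(template.spot_labels, template.st.coords), seed=0
        )
        classes = {p.pair_class for p in pairs}
        assert "near" in classes and "far" in classes

    def test_deterministic_given_seed(self):
        a = make_fixture(seed=5, **SMALL_FIXTURE)
        b = make_fixture(seed=5, **SMALL_FIXTURE)
        pd.testing.assert_frame_equal(a.sc_counts, b.sc_counts)
        np.testing.assert_array_equal(
            np.asarray(a.st.values), np.asarray(b.st.values)
        )

    def test_marker_genes_elevated_in_own_type(self, template):
        ann = template.cell_annotation
        counts = template.sc_counts
        own = counts.loc["MK0_0", ann.index[ann == "type0"]].mean()
        other = counts.loc["MK0_0", ann.index[ann != "type0"]].mean()
        assert own > 10 * other + 1

    def test_too_few_types_rejected(self):
        with pytest.raises(ValueError, match="4 cell types"):
            make_fixture(n_types=3)


class TestSelectAndMap:
    def test_cells_per_spot_within_range(self, template, cfg):
        ds = select_celltypes_and_map(template, cfg, np.random.default_rng(0))
        per_spot = ds.cell_to_spot.value_counts()
        lo, hi = cfg.cells_per_spot_range
        assert per_spot.min() >= lo and per_spot.max() <= hi
        assert lo <= per_spot.mean() <= hi

    def test_spot_expression_is_sum_of_its_cells(self, template, cfg):
        ds = select_celltypes_and_map(template, cfg, np.random.default_rng(1))
        st_vals = np.asarray(ds.st.values)
        for spot in ds.st.spot_ids[:5]:
            cells = ds.cell_to_spot.index[ds.cell_to_spot == spot]
            expected = ds.sc_counts[cells].sum(axis=1).to_numpy()
            j = ds.st.spot_ids.index(spot)
            np.testing.assert_array_equal(st_vals[:, j], expected)

    def test_cells_match_spot_type(self, template, cfg):
        ds = select_celltypes_and_map(template, cfg, np.random.default_rng(2))
        spot_type = dict(zip(ds.spot_labels.spot_ids, ds.spot_labels.labels))
        for cell, spot in ds.cell_to_spot.items():
            assert ds.cell_annotation[cell] == spot_type[spot]

    def test_selected_types_span_near_and_far(self, template, cfg):
        ds = select_celltypes_and_map(template, cfg, np.random.default_rng(3))
        classes = {p.pair_class for p in ds.pair_classes}
        assert "near" in classes and "far" in classes


@pytest.fixture(scope="module")
def planted(template, cfg):
    rng = np.random.default_rng(cfg.seed)
    ds = select_celltypes_and_map(template, cfg, rng)
    before = ds.sc_counts.copy()
    ds = plant_interactions(ds, template.db, cfg, rng)
    return ds, before


class TestPlantInteractions:
    def test_requested_count_per_pair(self, planted, cfg):
        ds, _ = planted
        per_pair = ds.truth.groupby(
            ds.truth.apply(
                lambda r: tuple(sorted((r.source_celltype, r.target_celltype))),
                axis=1,
            )
        ).size()
        assert (per_pair == cfg.n_lr_per_pair).all()

    def test_planted_ligand_mean_strictly_increases(self, planted):
        ds, before = planted
        row = ds.truth.iloc[0]
        sender_cells = ds.cell_annotation.index[
            ds.cell_annotation == row.source_celltype
        ]
        gene = row.ligand.split("+")[0]
        assert (
            ds.sc_counts.loc[gene, sender_cells].mean()
            > before.loc[gene, sender_cells].mean()
        )

    def test_non_planted_genes_untouched(self, planted):
        ds, before = planted
        planted_genes = {
            g
            for lr in ds.truth.itertuples(index=False)
            for g in (str(lr.ligand).split("+") + str(lr.receptor).split("+"))
        }
        untouched = [g for g in ds.sc_counts.index if g not in planted_genes]
        pd.testing.assert_frame_equal(
            ds.sc_counts.loc[untouched], before.loc[untouched]
        )

    def test_st_updated_to_match_cells(self, planted):
        ds, _ = planted
        st_vals = np.asarray(ds.st.values)
        totals = np.zeros_like(st_vals)
        spot_pos = {s: j for j, s in enumerate(ds.st.spot_ids)}
        for cell, spot in ds.cell_to_spot.items():
            totals[:, spot_pos[spot]] += ds.sc_counts[cell].to_numpy()
        np.testing.assert_array_equal(st_vals, totals)


class TestConsistencyFilter:
    def test_kept_plants_match_pair_class(self, final_dataset):
        ds, _ = final_dataset
        kept = ds.truth[ds.truth.kept]
        assert len(kept) > 0
        assert (
            (kept.pair_class == "near") & (kept.range_class == "short")
            | (kept.pair_class == "far") & (kept.range_class == "long")
        ).all()

    def test_discarded_plants_restored(self, final_dataset):
        ds, pre_plant = final_dataset
        dropped = ds.truth[~ds.truth.kept]
        assert len(dropped) > 0
        row = dropped.iloc[0]
        gene = str(row.ligand).split("+")[0]
        cells = ds.cell_annotation.index[ds.cell_annotation == row.source_celltype]
        # the restored values differ from the planted (overexpressed) state
        # and spot sums are consistent with the final cell matrix
        st_vals = np.asarray(ds.st.values)
        spot_pos = {s: j for j, s in enumerate(ds.st.spot_ids)}
        gi = ds.st.gene_ids.index(gene)
        for spot in set(ds.cell_to_spot[cells]):
            cells_here = ds.cell_to_spot.index[ds.cell_to_spot == spot]
            assert st_vals[gi, spot_pos[spot]] == ds.sc_counts.loc[
                gene, cells_here
            ].sum()

    def test_oracle_predictor_gets_perfect_f1(self, final_dataset):
        ds, _ = final_dataset
        kept = ds.truth[ds.truth.kept]
        reference = kept[
            ["source_celltype", "target_celltype", "ligand", "receptor"]
        ]
        oracle = PredictionTable(tool_name="oracle", records=reference.copy())
        metrics = accuracy_vs_reference(oracle, reference)
        assert metrics.f1 == pytest.approx(1.0)
        assert metrics.micro_f1 == pytest.approx(1.0)


class TestEndToEnd:
    def test_simulate_dataset_deterministic(self, template):
        cfg = SimulationConfig(seed=11, n_lr_per_pair=3, n_perm=50)
        ds1, _ = simulate_dataset(cfg, template=template)
        ds2, _ = simulate_dataset(cfg, template=template)
        pd.testing.assert_frame_equal(ds1.truth, ds2.truth)
        pd.testing.assert_frame_equal(ds1.sc_counts, ds2.sc_counts)

    def test_write_bundle_round_trips(self, final_dataset, tmp_path):
        ds, _ = final_dataset
        write_bundle(ds, tmp_path)
        for name in (
            "sc_counts.tsv", "cell_annotation.tsv", "st_counts.tsv",
            "st_coords.tsv", "truth.tsv",
        ):
            assert (tmp_path / name).exists()
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert len(truth) == len(ds.truth)
        st = pd.read_csv(tmp_path / "st_counts.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(st.to_numpy(), np.asarray(ds.st.values))
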