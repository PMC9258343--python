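"""Temperature sampling, dataset assembly, scaffolds, splits, outliers."""

import numpy as np
import pytest
from scipy import stats

from qtst.dataset_builder import (
    QDatasetRow,
    ReactionRecord,
    build_q_dataset,
    count_structures,
    drop_outliers,
    murcko_scaffold,
    reference_murcko_scaffold,
    sample_temperatures,
    scaffold_split,
)
from qtst.errors import ValidationError
from qtst.molecular_data import Structure
from qtst.synthetic_fixtures import FixtureSpec, make_reaction_set


class TestSampleTemperatures:
    def test_range_bounds(self):
        temps = sample_temperatures(1000, 50.0, 2000.0, seed=0)
        assert temps.min() > 50.0 and temps.max() < 2000.0

    def test_inverse_t_uniform_mean(self):
        temps = sample_temperatures(100_000, 50.0, 2000.0, seed=1)
        inv = 1.0 / temps
        expected = (1 / 50.0 + 1 / 2000.0) / 2.0
        se = (1 / 50.0 - 1 / 2000.0) / np.sqrt(12.0) / np.sqrt(len(inv))
        assert abs(inv.mean() - expected) < 3 * se

    def test_inverse_t_ks_uniform(self):
        inv = 1.0 / sample_temperatures(100_000, 50.0, 2000.0, seed=2)
        lo, hi = 1 / 2000.0, 1 / 50.0
        p = stats.kstest(inv, stats.uniform(loc=lo, scale=hi - lo).cdf).pvalue
        assert p > 0.01

    def test_determinism(self):
        a = sample_temperatures(10, 50.0, 2000.0, seed=3)
        b = sample_temperatures(10, 50.0, 2000.0, seed=3)
        c = sample_temperatures(10, 50.0, 2000.0, seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_invalid_range(self):
        with pytest.raises(ValidationError):
            sample_temperatures(5, 2000.0, 50.0, seed=0)


def _stub_reaction(i: int) -> ReactionRecord:
    def stub(role, suffix):
        return Structure(atoms=("O",), coords=[[0, 0, 0]], frequencies=(), role=role, id=f"r{i}_{suffix}")

    return ReactionRecord(
        reaction_id=f"r{i}",
        reactant=stub("reactant", "r"),
        ts=stub("transition_state", "ts").with_(frequencies=(-500.0,)),
        product=stub("product", "p"),
        ea=0.05,
    )


class TestBuildQDataset:
    def test_row_count(self, small_reactions):
        rows = build_q_dataset(small_reactions[:2], n_temps=5, seed=0)
        assert len(rows) == 2 * 3 * 5

    def test_empty_input(self):
        assert build_q_dataset([], n_temps=5, seed=0) == []

    def test_reference_dataset_arithmetic(self):
        reactions = [_stub_reaction(i) for i in range(11_961)]
        assert count_structures(reactions) == 35_883

    def test_rows_carry_finite_log_q_and_roles(self, small_reactions):
        rows = build_q_dataset(small_reactions[:3], seed=0)
        assert all(np.isfinite(r.log_q) for r in rows)
        assert {r.role for r in rows} == {"reactant", "transition_state", "product"}

    def test_invalid_structures_skipped_not_fatal(self, small_reactions):
        bad_ts = small_reactions[0].ts.with_(frequencies=(100.0, 200.0))  # no imaginary mode
        bad = ReactionRecord(
            reaction_id="bad",
            reactant=small_reactions[0].reactant.with_(id="b_r"),
            ts=bad_ts.with_(id="b_ts"),
            product=small_reactions[0].product.with_(id="b_p"),
            ea=0.01,
            temperatures=small_reactions[0].temperatures,
        )
        rows = build_q_dataset([bad] + list(small_reactions[:1]), seed=0)
        assert {r.reaction_id for r in rows} == {small_reactions[0].reaction_id}


class TestMurckoScaffold:
    def test_benzene_is_its_own_scaffold(self):
        assert murcko_scaffold("c1ccccc1") == "c1ccccc1"

    def test_toluene_prunes_to_benzene(self):
        assert murcko_scaffold("Cc1ccccc1") == murcko_scaffold("c1ccccc1")

    def test_acyclic_molecule_empty_scaffold(self):
        assert murcko_scaffold("CCCC") == ""

    @pytest.mark.parametrize(
        "smiles",
        ["Cc1ccccc1", "C1CCCCC1", "CC1CCC(O)CC1", "c1ccc2ccccc2c1", "OCCc1ccncc1"],
    )
    def test_agrees_with_rdkit_reference(self, smiles):
        ours = murcko_scaffold(smiles)
        theirs = reference_murcko_scaffold(smiles)
        assert ours == theirs

    def test_geometry_input_ring_detected(self, small_reactions):
        key = murcko_scaffold(small_reactions[0].reactant)
        assert isinstance(key, str)

    def test_unparsable_smiles(self):
        with pytest.raises(ValidationError):
            murcko_scaffold("not_a_smiles((")


class TestScaffoldSplit:
    def test_partition_disjoint_and_complete(self, small_reactions, small_split):
        all_ids = {r.reaction_id for r in small_reactions}
        fold_ids = set(small_split.folds)
        assert small_split.test_ids | fold_ids == all_ids
        assert not (small_split.test_ids & fold_ids)

    def test_no_scaffold_crosses_boundaries(self, small_split):
        placement = {}
        for rid in small_split.test_ids:
            placement.setdefault(small_split.scaffold_key[rid], set()).add("test")
        for rid, fold in small_split.folds.items():
            placement.setdefault(small_split.scaffold_key[rid], set()).add(f"fold{fold}")
        assert all(len(units) == 1 for units in placement.values())

    def test_same_scaffold_same_unit(self, small_reactions, small_split):
        by_key = {}
        for r in small_reactions:
            key = small_split.scaffold_key[r.reaction_id]
            unit = "test" if r.reaction_id in small_split.test_ids else small_split.folds[r.reaction_id]
            by_key.setdefault(key, set()).add(unit)
        assert all(len(v) == 1 for v in by_key.values())

    def test_test_fraction_within_greedy_bound(self, small_reactions, small_split):
        n = len(small_reactions)
        sizes = {}
        for rid, key in small_split.scaffold_key.items():
            sizes[key] = sizes.get(key, 0) + 1
        largest = max(sizes.values())
        assert 0.10 * n <= len(small_split.test_ids) <= 0.10 * n + largest - 1 + 1e-9

    def test_too_few_groups_rejected(self, small_reactions):
        clones = []
        for i, r in enumerate(small_reactions[:6]):
            clones.append(
                ReactionRecord(
                    reaction_id=f"c{i}",
                    reactant=small_reactions[0].reactant.with_(id=f"c{i}_r"),
                    ts=small_reactions[0].ts.with_(id=f"c{i}_ts"),
                    product=small_reactions[0].product.with_(id=f"c{i}_p"),
                    ea=0.02,
                    temperatures=small_reactions[0].temperatures,
                )
            )
        with pytest.raises(ValidationError, match="scaffold groups"):
            scaffold_split(clones, n_folds=5)


class TestDropOutliers:
    def _rows(self, values):
        return [
            QDatasetRow(structure_id=f"s{i}", reaction_id=f"r{i}", role="reactant",
                        inverse_temperature=0.01, log_q=v)
            for i, v in enumerate(values)
        ]

    def test_full_envelope_is_identity(self):
        rows = self._rows([1.0, 2.0, 3.0])
        kept, report = drop_outliers(rows, 0.0, 1.0)
        assert kept == rows
        assert report.n_removed == 0

    def test_extreme_point_removed(self, rng):
        rows = self._rows(list(rng.normal(0, 1, 2000)) + [1e6])
        kept, report = drop_outliers(rows, 0.0005, 0.999)
        assert report.n_removed >= 1
        assert all(r.log_q < 1e6 for r in kept)

    def test_bookkeeping(self, rng):
        rows = self._rows(rng.normal(0, 1, 500))
        kept, report = drop_outliers(rows, 0.01, 0.99)
        assert report.n_removed == len(rows) - len(kept)


def test_reaction_record_role_validation(small_reactions):
    r = small_reactions[0]
    with pytest.raises(ValidationError, match="role"):
        ReactionRecord(
            reaction_id="x", reactant=r.ts, ts=r.reactant, product=r.product, ea=0.01
        )


def test_fixture_scaffold_diversity():
    reactions = make_reaction_set(FixtureSpec(n_reactions=40, n_temps=2, seed=3))
    keys = {murcko_scaffold(r.reactant) for r in reactions}
    assert len(keys) >= 7  # enough groups for 5 folds + hold-out
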