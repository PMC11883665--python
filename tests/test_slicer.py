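"""Slicing: planted-partition recovery, merging, ranges, export."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from slicefit.confidence import trim_by_confidence
from slicefit.slicer import (ParameterError, export_slices,
                             merge_to_max_splits, slice_by_coordinates,
                             slice_by_pae, slice_multi, slice_range)
from slicefit.structures import PAEMatrix, ca_coordinates
from slicefit.synthetic import PlantedModelSpec, make_planted_model

from conftest import build_model

MANUAL = ("kmeans", "birch", "agglomerative")


def _ari(assignment, labels):
    keys = list(assignment.labels)
    return adjusted_rand_score([labels[k] for k in keys],
                               [assignment.labels[k] for k in keys])


class TestCoordinateClustering:
    @pytest.mark.parametrize("method", MANUAL)
    def test_two_planted_domains_recovered(self, method, planted_two_domain):
        model, labels, _ = planted_two_domain
        trimmed, _ = trim_by_confidence(model)  # drop the linker
        assignment = slice_by_coordinates(trimmed, method, 2, seed=0)
        assert assignment.k == 2
        assert _ari(assignment, labels) == 1.0

    @pytest.mark.parametrize("method", MANUAL)
    def test_three_planted_domains_recovered(self, method,
                                             planted_three_domain):
        model, labels, _ = planted_three_domain
        trimmed, _ = trim_by_confidence(model)
        assignment = slice_by_coordinates(trimmed, method, 3, seed=0)
        assert _ari(assignment, labels) == 1.0

    def test_single_cluster_is_identity_partition(self, toy_model):
        assignment = slice_by_coordinates(toy_model, "kmeans", 1, seed=0)
        assert assignment.k == 1
        assert set(assignment.labels.values()) == {1}

    def test_deterministic_under_seed(self, planted_two_domain):
        model, _, _ = planted_two_domain
        a = slice_by_coordinates(model, "kmeans", 2, seed=7)
        b = slice_by_coordinates(model, "kmeans", 2, seed=7)
        assert a.labels == b.labels

    def test_partition_invariant(self, planted_two_domain):
        model, _, _ = planted_two_domain
        table = ca_coordinates(model)
        for method in MANUAL:
            assignment = slice_by_coordinates(model, method, 3, seed=0)
            assert sorted(assignment.labels) == sorted(table.keys)
            assignment.validate()

    def test_slice_one_is_largest(self, planted_two_domain):
        model, _, _ = planted_two_domain
        assignment = slice_by_coordinates(model, "birch", 3, seed=0)
        sizes = [len(assignment.members(i))
                 for i in range(1, assignment.k + 1)]
        assert sizes == sorted(sizes, reverse=True)

    def test_bad_n_clusters(self, toy_model):
        with pytest.raises(ParameterError):
            slice_by_coordinates(toy_model, "kmeans", 0)
        with pytest.raises(ParameterError):
            slice_by_coordinates(toy_model, "kmeans", 99)

    def test_auto_density_separates_far_domains(self, planted_two_domain):
        model, labels, _ = planted_two_domain
        trimmed, _ = trim_by_confidence(model)
        assignment = slice_by_coordinates(trimmed, "auto_density", seed=0)
        assert assignment.k == 2
        assert _ari(assignment, labels) == 1.0


class TestPAEClustering:
    def test_block_pae_recovers_blocks(self, planted_two_domain):
        model, labels, pae = planted_two_domain
        assignment = slice_by_pae(pae, model)
        assert assignment.k == 2
        # linker rows sit between the cutoffs and may join either block;
        # the planted blocks themselves must be recovered exactly
        core_keys = [k for k, r in zip(model.residue_keys(),
                                       (r for _, r in model.iter_residues()))
                     if r.confidence >= 70]
        truth = [labels[k] for k in core_keys]
        pred = [assignment.labels[k] for k in core_keys]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_uniform_pae_gives_single_slice(self, toy_model):
        model = build_model([80.0] * 30)
        pae = PAEMatrix(np.full((30, 30), 1.0), model.residue_keys())
        assignment = slice_by_pae(pae, model)
        assert assignment.k == 1

    def test_permutation_equivariance(self, planted_two_domain):
        """Permuting residue order then mapping labels back leaves the
        partition unchanged."""
        model, _, pae = planted_two_domain
        base = slice_by_pae(pae, model)
        rng = np.random.default_rng(0)
        perm = rng.permutation(pae.n)
        keys = model.residue_keys()
        perm_keys = [keys[i] for i in perm]
        perm_pae = PAEMatrix(pae.values[np.ix_(perm, perm)], perm_keys)
        perm_model = model.select(perm_keys)
        # select() preserves file order, so rebuild the matrix against the
        # model's own ordering before clustering
        aligned = perm_pae.subset(perm_model.residue_keys())
        again = slice_by_pae(aligned, perm_model)
        groups_a = {}
        groups_b = {}
        for k in keys:
            groups_a.setdefault(base.labels[k], set()).add(k)
            groups_b.setdefault(again.labels[k], set()).add(k)
        assert sorted(map(sorted, groups_a.values())) == \
            sorted(map(sorted, groups_b.values()))

    def test_mismatched_sizes_raise(self, toy_model):
        pae = PAEMatrix(np.zeros((5, 5)), build_model([1.0] * 5).residue_keys())
        with pytest.raises(Exception):
            slice_by_pae(pae, toy_model)


class TestMergeToMaxSplits:
    def test_collinear_centroids_merge_as_brute_force(self):
        """5 slices at x = 0,1,2,50,51 A merge into {0,1,2} and {50,51}."""
        xs = [0.0, 1.0, 2.0, 50.0, 51.0]
        confs = [80.0] * 5
        model = build_model(confs, spacing=1.0)
        # place the five CA atoms at the stated positions
        for res, x in zip(model.chains[0].residues, xs):
            for atom in res.atoms:
                atom.xyz = np.array([x, 0.0, atom.xyz[2] - 0.0])
        table = ca_coordinates(model)
        keys = model.residue_keys()
        assignment = slice_by_coordinates(model, "kmeans", 5, seed=0)
        merged = merge_to_max_splits(assignment, table, 2)
        assert merged.k == 2
        by_x = {x: merged.labels[k]
                for k, x in zip(keys, [r.ca.xyz[0]
                                       for _, r in model.iter_residues()])}
        assert by_x[0.0] == by_x[1.0] == by_x[2.0]
        assert by_x[50.0] == by_x[51.0]
        assert by_x[0.0] != by_x[50.0]

    def test_identity_when_k_below_max(self, planted_two_domain):
        model, _, _ = planted_two_domain
        assignment = slice_by_coordinates(model, "kmeans", 2, seed=0)
        table = ca_coordinates(model)
        assert merge_to_max_splits(assignment, table, 4) is assignment

    def test_max_one_unions_everything(self, planted_two_domain):
        model, _, _ = planted_two_domain
        assignment = slice_by_coordinates(model, "kmeans", 3, seed=0)
        merged = merge_to_max_splits(assignment, ca_coordinates(model), 1)
        assert merged.k == 1
        assert set(merged.labels) == set(assignment.labels)

    def test_never_increases_k(self, planted_three_domain):
        model, _, _ = planted_three_domain
        assignment = slice_by_coordinates(model, "kmeans", 5, seed=0)
        table = ca_coordinates(model)
        for m in (4, 3, 2, 1):
            assert merge_to_max_splits(assignment, table, m).k == m


class TestRangesAndMulti:
    def test_range_three_to_five(self, planted_three_domain):
        model, _, _ = planted_three_domain
        out = slice_range(model, "kmeans", 3, 5, seed=0)
        assert [a.k for a in out] == [3, 4, 5]
        for a in out:
            a.validate()

    def test_degenerate_range(self, planted_two_domain):
        model, _, _ = planted_two_domain
        out = slice_range(model, "birch", 2, 2, seed=0)
        assert len(out) == 1 and out[0].k == 2

    def test_invalid_range(self, toy_model):
        with pytest.raises(ParameterError):
            slice_range(toy_model, "kmeans", 3, 2)
        with pytest.raises(ParameterError):
            slice_range(toy_model, "kmeans", 0, 2)

    def test_multi_two_models_two_each(self, planted_two_domain):
        model, _, _ = planted_two_domain
        other, _, _ = make_planted_model(PlantedModelSpec(seed=5))
        other = other.select(other.residue_keys(), model_id="other")
        out = slice_multi([model, other], [2, 2], "birch", seed=0)
        assert [a.k for a in out] == [2, 2]
        assert out[0].model_id != out[1].model_id

    def test_multi_length_mismatch(self, planted_two_domain):
        model, _, _ = planted_two_domain
        with pytest.raises(ParameterError):
            slice_multi([model], [2, 2])


class TestExport:
    def test_files_key_and_partition(self, planted_two_domain, tmp_path):
        model, _, _ = planted_two_domain
        assignment = slice_by_coordinates(model, "kmeans", 4, seed=0)
        slices = export_slices(model, assignment, tmp_path)
        assert len(slices) == 4
        files = sorted(p.name for p in tmp_path.glob("*_slice*.pdb"))
        assert len(files) == 4
        key = (tmp_path / f"{model.model_id}_colour_key.tsv").read_text()
        assert key.count("\n") == 5  # header + 4 rows
        union = sorted(k for s in slices for k in s.residue_keys)
        assert union == sorted(assignment.labels)

    def test_fragmented_slice_flagged(self, tmp_path):
        model = build_model([80.0] * 60)
        from slicefit.slicer import SliceAssignment
        labels = {}
        for i, key in enumerate(model.residue_keys()):
            labels[key] = 1 if (i < 20 or i >= 40) else 2
        assignment = SliceAssignment(model.model_id, labels, 2, "manual", {})
        export_slices(model, assignment, tmp_path)
        rows = (tmp_path / f"{model.model_id}_colour_key.tsv").read_text().splitlines()
        frag = [r for r in rows[1:] if r.endswith("yes")]
        assert len(frag) == 1 and "\t2\t" in frag[0]
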