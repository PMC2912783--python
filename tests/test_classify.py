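"""The core assignment math: weighted distance, membership probability,
relative distance, node-level and hierarchical classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subtypepredict import (
    DegenerateModelError,
    ExpressionMatrix,
    ParameterError,
    classify_hierarchical,
    classify_node,
    make_unknown,
    membership_probabilities,
    relative_distance,
    weighted_distance,
)
from subtypepredict.reference import ReferenceModel

# ---------------------------------------------------------------------------
# Straight-line oracles: plain-python re-statements of each formula,
# independent of the vectorized implementations they check.
# ---------------------------------------------------------------------------


def oracle_weighted_distance(u, v, w):
    total = 0.0
    for ui, vi, wi in zip(u, v, w):
        total += wi * (ui - vi) ** 2
    return math.sqrt(total)


def oracle_probabilities(distances):
    inv = {c: 1.0 / d for c, d in distances.items()}
    z = sum(inv.values())
    return {c: inv[c] / z for c in distances}


def oracle_relative_distance(d, sigma):
    return d / sigma


class TestWeightedDistance:
    def test_identity_and_pythagoras(self):
        assert weighted_distance([1, 2], [1, 2], [0.3, 0.7]) == 0.0
        assert weighted_distance([0, 0], [3, 4], [1, 1]) == pytest.approx(5.0)

    def test_half_weights_hand_value(self):
        # sqrt(0.5*9 + 0.5*16) = sqrt(12.5)
        assert weighted_distance([0, 0], [3, 4], [0.5, 0.5]) == pytest.approx(
            3.535534, abs=1e-6
        )

    def test_errors(self):
        with pytest.raises(ParameterError):
            weighted_distance([0, 0], [1], [1, 1])
        with pytest.raises(ParameterError):
            weighted_distance([0, 0], [1, 1], [1, -1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=8),
        st.data(),
    )
    def test_symmetry_and_triangle_inequality(self, u, data):
        n = len(u)
        v = data.draw(st.lists(st.floats(-100, 100), min_size=n, max_size=n))
        t = data.draw(st.lists(st.floats(-100, 100), min_size=n, max_size=n))
        w = data.draw(st.lists(st.floats(0, 10), min_size=n, max_size=n))
        duv = weighted_distance(u, v, w)
        assert duv == pytest.approx(weighted_distance(v, u, w), rel=1e-12)
        assert duv <= weighted_distance(u, t, w) + weighted_distance(t, v, w) + 1e-9


class TestMembershipProbabilities:
    def test_symmetric_distances_split_evenly(self):
        assert membership_probabilities({"A": 1.0, "B": 1.0}) == {"A": 0.5, "B": 0.5}

    def test_one_to_three_ratio(self):
        p = membership_probabilities({"A": 1.0, "B": 3.0})
        assert p["A"] == pytest.approx(0.75)
        assert p["B"] == pytest.approx(0.25)

    def test_zero_distance_limit(self):
        assert membership_probabilities({"A": 0.0, "B": 2.0}) == {"A": 1.0, "B": 0.0}

    def test_several_zero_distances_ill_posed(self):
        with pytest.raises(DegenerateModelError):
            membership_probabilities({"A": 0.0, "B": 0.0, "C": 1.0})

    def test_needs_two_children(self):
        with pytest.raises(ParameterError):
            membership_probabilities({"A": 1.0})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1e6), min_size=2, max_size=6))
    def test_normalization_and_order_reversal(self, ds):
        distances = {f"c{i}": d for i, d in enumerate(ds)}
        p = membership_probabilities(distances)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)
        order_d = sorted(distances, key=distances.get)
        order_p = sorted(p, key=p.get, reverse=True)
        # smaller distance -> larger probability (ties aside)
        if len(set(ds)) == len(ds):
            assert order_d == order_p

    def test_monotonicity_in_own_distance(self):
        p_near = membership_probabilities({"A": 0.5, "B": 2.0})["A"]
        p_far = membership_probabilities({"A": 1.0, "B": 2.0})["A"]
        assert p_near > p_far


class TestRelativeDistance:
    @pytest.mark.parametrize(
        "d, sigma, expected", [(0.0, 0.8, 0.0), (0.8, 0.8, 1.0), (2.4, 0.8, 3.0)]
    )
    def test_definition(self, d, sigma, expected):
        assert relative_distance(d, sigma) == pytest.approx(expected)

    def test_zero_sigma_guidance(self):
        with pytest.raises(DegenerateModelError, match="degenerate subtype|coincide"):
            relative_distance(1.0, 0.0)


# ---------------------------------------------------------------------------
# Node-level assignment
# ---------------------------------------------------------------------------


def two_child_model(rng, n=20, g=30, shift=4.0):
    a = rng.normal(size=(g, n))
    b = shift + rng.normal(size=(g, n))
    genes = [f"g{i}" for i in range(g)]
    samples = [f"a{j}" for j in range(n)] + [f"b{j}" for j in range(n)]
    matrix = ExpressionMatrix(genes, samples, np.hstack([a, b]))
    child = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return ReferenceModel("node", genes, matrix, ["A", "B"], child)


def oracle_classify_node(model, unknown, sigma_ddof=0):
    """Independent end-to-end recomputation: covariance eigendecomposition of
    the merged matrix, explicit projection, loop-based statistics."""
    X = np.vstack([model.ref_matrix.values.T, unknown])  # samples x genes
    center = X.mean(axis=0)
    Xc = X - center
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    k = min(X.shape[1], X.shape[0] - 1)
    scores = Xc @ eigvec[:, :k]
    w = eigval[:k] / eigval.sum()
    ref_ids = model.ref_matrix.sample_ids
    out_d, out_s = {}, {}
    for child in model.child_labels:
        rows = [i for i, s in enumerate(ref_ids) if model.sample_child[s] == child]
        c = scores[rows].mean(axis=0)
        out_d[child] = oracle_weighted_distance(scores[-1], c, w)
        ds = [oracle_weighted_distance(scores[i], c, w) for i in rows]
        mean_d = sum(ds) / len(ds)
        var = sum((x - mean_d) ** 2 for x in ds) / (len(ds) - sigma_ddof)
        out_s[child] = math.sqrt(var)
    probs = oracle_probabilities(out_d)
    rel = {c: oracle_relative_distance(out_d[c], out_s[c]) for c in out_d}
    assigned = min(out_d, key=out_d.get)
    return out_d, probs, rel, assigned


class TestClassifyNode:
    def test_centroid_probe_assigned_with_majority_probability(self):
        rng = np.random.default_rng(0)
        model = two_child_model(rng)
        probe = pd.Series(
            model.ref_matrix.values[:, :20].mean(axis=1), index=model.classifier_genes
        )
        res = classify_node(model, probe)
        assert res.assigned_child == "A"
        assert res.probabilities["A"] > 0.5

    def test_label_swap_equivariance(self):
        rng = np.random.default_rng(1)
        model = two_child_model(rng)
        swapped = ReferenceModel(
            model.node_id,
            model.classifier_genes,
            model.ref_matrix,
            ["B", "A"],
            {s: ("B" if c == "A" else "A") for s, c in model.sample_child.items()},
        )
        probe = pd.Series(
            model.ref_matrix.values[:, 25], index=model.classifier_genes
        ) * 0.99
        res = classify_node(model, probe)
        res_swapped = classify_node(swapped, probe)
        flip = {"A": "B", "B": "A"}
        assert res_swapped.assigned_child == flip[res.assigned_child]
        assert res_swapped.probabilities["B"] == pytest.approx(res.probabilities["A"])

    def test_matches_straight_line_oracle_end_to_end(self):
        rng = np.random.default_rng(2)
        model = two_child_model(rng)
        unknown_vec = 4.0 + rng.normal(size=30)  # drawn from child B
        unknown = pd.Series(unknown_vec, index=model.classifier_genes)
        res = classify_node(model, unknown)
        d, p, r, assigned = oracle_classify_node(model, unknown_vec)
        assert res.assigned_child == assigned == "B"
        for child in ("A", "B"):
            assert res.distances[child] == pytest.approx(d[child], rel=1e-8)
            assert res.probabilities[child] == pytest.approx(p[child], rel=1e-8)
            assert res.relative_distances[child] == pytest.approx(r[child], rel=1e-8)

    def test_assignment_consistency_invariant(self):
        rng = np.random.default_rng(3)
        model = two_child_model(rng)
        unknown = pd.Series(rng.normal(size=30), index=model.classifier_genes)
        res = classify_node(model, unknown)
        assert res.assigned_child == max(res.probabilities, key=res.probabilities.get)
        assert res.assigned_child == min(res.distances, key=res.distances.get)
        assert sum(res.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_project_mode_reference_geometry_fixed(self):
        rng = np.random.default_rng(4)
        model = two_child_model(rng)
        u1 = pd.Series(rng.normal(size=30), index=model.classifier_genes)
        u2 = pd.Series(4 + rng.normal(size=30), index=model.classifier_genes)
        r1 = classify_node(model, u1, mode="project")
        r2 = classify_node(model, u2, mode="project")
        # frozen basis: reference PC coordinates identical across predictions
        assert r1.pc3_reference == r2.pc3_reference

    def test_scale_equivariance_of_p_and_r(self):
        rng = np.random.default_rng(5)
        model = two_child_model(rng)
        unknown = pd.Series(rng.normal(size=30), index=model.classifier_genes)
        res = classify_node(model, unknown)
        scaled_matrix = ExpressionMatrix(
            model.classifier_genes,
            model.ref_matrix.sample_ids,
            model.ref_matrix.values * 7.0,
        )
        scaled = ReferenceModel(
            model.node_id, model.classifier_genes, scaled_matrix,
            model.child_labels, model.sample_child,
        )
        res_scaled = classify_node(scaled, unknown * 7.0)
        for child in ("A", "B"):
            assert res_scaled.distances[child] == pytest.approx(
                7.0 * res.distances[child], rel=1e-8
            )
            assert res_scaled.probabilities[child] == pytest.approx(
                res.probabilities[child], rel=1e-8
            )
            assert res_scaled.relative_distances[child] == pytest.approx(
                res.relative_distances[child], rel=1e-8
            )


class TestClassifyHierarchical:
    def test_planted_probe_descends_to_its_leaf(self, default_spec, models):
        from subtypepredict import leaf_mean_profile

        probe = leaf_mean_profile(default_spec, "OA")
        res = classify_hierarchical(models, default_spec.hierarchy, probe)
        assert [r.node_id for r in res.node_results] == ["root", "O"]
        assert res.path == ["O", "OA"]
        assert res.final_subtype == "OA"

    def test_final_leaf_nests_under_assigned_children(self, default_spec, models):
        h = default_spec.hierarchy
        for i, leaf in enumerate(h.leaves() * 4):  # 24 probes
            u = make_unknown(default_spec, leaf, seed=900 + i)
            res = classify_hierarchical(models, h, u)
            path = [label for _, label in h.leaf_path(res.final_subtype)]
            assert res.path == path

    def test_far_probe_flagged_as_outlier(self, default_spec, models):
        u = make_unknown(default_spec, "GA1", displacement=10.0, seed=77)
        res = classify_hierarchical(models, default_spec.hierarchy, u)
        assert res.outlier_flag
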