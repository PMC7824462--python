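import itertools

import numpy as np
import pytest

from lamap.geometry import solve_position
from lamap.intensity import IntensityModel
from lamap.priors import default_priors
from lamap.reference import ReferenceAxes, ReferenceAxis
from lamap.targets import (
    CandidateObject3D,
    InsufficientCandidatesError,
    assignment_logprior,
    candidate_objects,
    intensity_loglik,
    localize_targets,
    relative_distance_feature,
    score_assignment,
    similarity_values,
)
from lamap.volume import CTVolume, LANDMARK_LABELS

PRIOR = default_priors()
MODEL = IntensityModel(mu_b=80, sigma_b=20, mu_f=400, sigma_f=50)


class TestRelativeDistanceFeature:
    def test_point_at_reference(self):
        assert relative_distance_feature((0, 0), (0, 0), (81.6, 0)) == (0, 81.6, 81.6)

    def test_perpendicular_bisector_symmetry(self):
        d_a, d_d, _ = relative_distance_feature((40.8, 33.0), (0, 0), (81.6, 0))
        assert d_a == pytest.approx(d_d)

    def test_three_four_five_triangle(self):
        assert relative_distance_feature((3, 0), (0, 0), (3, 4)) == (3.0, 4.0, 5.0)


def _exact_point(label, ref_a=(0.0, 0.0), ref_d=(81.6, 0.0)):
    mu_a, _ = PRIOR.distance_params(label, "AA")
    mu_d, _ = PRIOR.distance_params(label, "DA")
    return solve_position(ref_a, ref_d, mu_a, mu_d, PRIOR.side_signs[label])


class TestSimilarityValues:
    def test_zero_at_exact_mean_geometry_on_correct_side(self):
        p = _exact_point("LSPV")
        f = similarity_values(p[0], p[1], (0, 0), (81.6, 0), PRIOR, "LSPV")
        assert f == pytest.approx(0.0, abs=1e-18)

    def test_mirror_point_is_masked(self):
        p = _exact_point("LSPV")
        f = similarity_values(p[0], -p[1], (0, 0), (81.6, 0), PRIOR, "LSPV")
        assert f == -np.inf

    @pytest.mark.parametrize("label", LANDMARK_LABELS)
    def test_invariant_under_random_similarity_transforms(self, label):
        """f_k depends only on the distance ratios: 100 random rigid+scale
        transforms of (references, query point) leave it unchanged."""
        rng = np.random.default_rng(2024)
        ref_a = np.array([10.0, 20.0])
        ref_d = ref_a + 81.6 * np.array([np.cos(np.radians(66.9)), np.sin(np.radians(66.9))])
        queries = ref_a + rng.uniform(-60, 60, size=(5, 2))
        for _ in range(100):
            ang = rng.uniform(0, 2 * np.pi)
            scale = rng.uniform(0.3, 3.0)
            shift = rng.uniform(-200, 200, size=2)
            rot = scale * np.array(
                [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
            )
            ta, td = rot @ ref_a + shift, rot @ ref_d + shift
            for q in queries:
                f0 = similarity_values(q[0], q[1], ref_a, ref_d, PRIOR, label)
                f1 = similarity_values(*(rot @ q + shift), ta, td, PRIOR, label)
                if np.isinf(f0):
                    assert np.isinf(f1)
                else:
                    assert f1 == pytest.approx(f0, rel=1e-9, abs=1e-12)


def _vertical_axes(ref_a, ref_d, z_range=(0.0, 19.0)):
    up = np.array([0.0, 0.0, 1.0])
    return ReferenceAxes(
        aa=ReferenceAxis(np.array([*ref_a, 0.0]), up),
        da=ReferenceAxis(np.array([*ref_d, 0.0]), up),
        detections=(),
        delta_mm=float(np.hypot(ref_d[0] - ref_a[0], ref_d[1] - ref_a[1])),
        theta_deg=0.0,
        z_range_mm=z_range,
    )


def _blob_scene(centers_radius=((None, 4.0),)):
    """A (20,140,140) volume with contrast spheres at given (x, y, z) centers."""
    nz, ny, nx = 20, 140, 140
    x, y, z = np.arange(nx), np.arange(ny), np.arange(nz)
    fg = np.zeros((nz, ny, nx), dtype=bool)
    for center, radius in centers_radius:
        cx, cy, cz = center
        fg |= (
            (x[None, None, :] - cx) ** 2
            + (y[None, :, None] - cy) ** 2
            + (z[:, None, None] - cz) ** 2
        ) <= radius**2
    vol = CTVolume(np.where(fg, 400.0, 80.0), spacing=(1.0, 1.0, 1.0))
    mask = fg
    return vol, mask


class TestCandidateObjects:
    AXES = _vertical_axes((20.0, 20.0), (20.0 + 81.6, 20.0))

    def test_single_blob_centroid_and_support(self):
        p = _exact_point("LSPV", (20, 20), (20 + 81.6, 20))
        vol, mask = _blob_scene([((p[0], p[1], 10.0), 4.0)])
        cands = candidate_objects(vol, mask, self.AXES, PRIOR)
        assert len(cands) == 1
        assert cands[0].centroid_mm == pytest.approx((p[0], p[1], 10.0), abs=0.5)
        assert "LSPV" in cands[0].supporting_labels
        assert cands[0].mean_intensity == pytest.approx(400.0)

    def test_alpha_above_global_maximum_gives_no_candidates(self):
        p = _exact_point("LSPV", (20, 20), (20 + 81.6, 20))
        vol, mask = _blob_scene([((p[0], p[1], 10.0), 4.0)])
        assert candidate_objects(vol, mask, self.AXES, PRIOR, alpha=1.0) == []

    def test_separated_blobs_become_distinct_candidates(self):
        p1 = _exact_point("LSPV", (20, 20), (20 + 81.6, 20))
        p2 = _exact_point("RSPV", (20, 20), (20 + 81.6, 20))
        vol, mask = _blob_scene([((p1[0], p1[1], 10.0), 4.0), ((p2[0], p2[1], 10.0), 4.0)])
        cands = candidate_objects(vol, mask, self.AXES, PRIOR)
        assert len(cands) == 2


class TestScores:
    def test_intensity_loglik_at_foreground_mean_is_zero(self):
        c = _candidate(0, (0, 0, 0), intensity=MODEL.mu_f)
        assert intensity_loglik(c, MODEL) == 0.0

    @pytest.mark.parametrize("sign", [1, -1])
    def test_intensity_loglik_one_sigma(self, sign):
        c = _candidate(0, (0, 0, 0), intensity=MODEL.mu_f + sign * MODEL.sigma_f)
        assert intensity_loglik(c, MODEL) == pytest.approx(-1.0)

    def test_intensity_loglik_direct_arithmetic(self):
        c = _candidate(0, (0, 0, 0), intensity=300.0)
        assert intensity_loglik(c, MODEL) == pytest.approx(-4.0)

    def test_assignment_logprior_zero_at_mean_graph(self):
        assignment = {
            k: _candidate(i, (*PRIOR.mean_position(k), 0.0))
            for i, k in enumerate(LANDMARK_LABELS)
        }
        assert assignment_logprior(assignment, PRIOR) == pytest.approx(0.0, abs=1e-18)

    def test_assignment_logprior_one_pair_displaced_by_sigma(self):
        positions = {k: np.array([*PRIOR.mean_position(k), 0.0]) for k in LANDMARK_LABELS}
        # move LAA along the LSPV-LAA axis by exactly that pair's sigma; the
        # other pairs move too, so compare against the hand-rolled double loop
        mu, sigma = PRIOR.pairwise_params("LSPV", "LAA")
        direction = positions["LAA"] - positions["LSPV"]
        positions["LAA"] = positions["LSPV"] + direction / np.linalg.norm(direction) * (
            mu + sigma
        )
        assignment = {
            k: _candidate(i, tuple(positions[k])) for i, k in enumerate(LANDMARK_LABELS)
        }
        expected = 0.0
        for a, b in itertools.combinations(LANDMARK_LABELS, 2):
            m, s = PRIOR.pairwise_params(a, b)
            d = np.linalg.norm(positions[a] - positions[b])
            expected += -((m - d) ** 2) / s**2
        assert assignment_logprior(assignment, PRIOR) == pytest.approx(expected)
        lspv_laa = -((mu - (mu + sigma)) ** 2) / sigma**2
        assert lspv_laa == pytest.approx(-1.0)


def _candidate(index, centroid, intensity=400.0, peak=0.0, labels=LANDMARK_LABELS):
    return CandidateObject3D(
        index=index,
        voxel_count=50,
        centroid_mm=tuple(float(c) for c in centroid),
        mean_intensity=float(intensity),
        peak_similarity=float(peak),
        supporting_labels=frozenset(labels),
    )


def _enumeration_oracle(candidates, prior, model):
    """Independent exhaustive argmax over injective, support-respecting
    assignments, scored with the public per-term functions."""
    best = None
    for perm in itertools.permutations(candidates, 5):
        mapping = dict(zip(LANDMARK_LABELS, perm))
        if any(k not in c.supporting_labels for k, c in mapping.items()):
            continue
        score = sum(
            intensity_loglik(c, model) for c in mapping.values()
        ) + assignment_logprior(mapping, prior)
        tup = tuple(mapping[k].index for k in LANDMARK_LABELS)
        if best is None or score > best[0] or (score == best[0] and tup < best[1]):
            best = (score, tup, mapping)
    return best


def _candidate_pool(n_decoys=3, jitter_seed=0):
    rng = np.random.default_rng(jitter_seed)
    cands = [
        _candidate(i, (*(PRIOR.mean_position(k) + rng.normal(0, 1, 2)), 40.0))
        for i, k in enumerate(LANDMARK_LABELS)
    ]
    for d in range(n_decoys):
        cands.append(
            _candidate(
                5 + d,
                (20.0 + 15 * d, 110.0, 40.0),
                intensity=rng.uniform(250, 400),
                peak=-2.0,
            )
        )
    return cands


class TestLocalizeTargets:
    def test_true_geometry_beats_decoys_with_near_zero_score(self):
        cands = _candidate_pool(jitter_seed=99)
        results, assignment = localize_targets(cands, PRIOR, MODEL)
        assert [r.label for r in results] == list(LANDMARK_LABELS)
        chosen = {assignment.mapping[k].index for k in LANDMARK_LABELS}
        assert chosen == {0, 1, 2, 3, 4}
        assert assignment.total == pytest.approx(0.0, abs=1.0)

    @pytest.mark.parametrize("n_decoys", [1, 2, 3])
    def test_equals_exhaustive_enumeration_up_to_8_candidates(self, n_decoys):
        cands = _candidate_pool(n_decoys=n_decoys, jitter_seed=n_decoys)
        results, assignment = localize_targets(cands, PRIOR, MODEL)
        score, tup, _ = _enumeration_oracle(cands, PRIOR, MODEL)
        assert assignment.total == pytest.approx(score)
        assert tuple(assignment.mapping[k].index for k in LANDMARK_LABELS) == tup

    def test_four_candidates_insufficient(self):
        with pytest.raises(InsufficientCandidatesError):
            localize_targets(_candidate_pool(n_decoys=0)[:4], PRIOR, MODEL)

    def test_missing_label_support_reported(self):
        cands = [
            _candidate(i, (*PRIOR.mean_position(k), 0.0), labels=[k])
            for i, k in enumerate(LANDMARK_LABELS[:4])
        ] + [_candidate(4, (30.0, 30.0, 0.0), labels=["LSPV"])]
        with pytest.raises(InsufficientCandidatesError, match="LAA"):
            localize_targets(cands, PRIOR, MODEL)

    def test_exact_score_ties_break_lexicographically(self):
        cands = _candidate_pool(n_decoys=0, jitter_seed=0)
        twin = _candidate(5, cands[4].centroid_mm, cands[4].mean_intensity)
        _, assignment = localize_targets(cands + [twin], PRIOR, MODEL)
        # candidate 4 and its twin 5 are interchangeable; the smaller index wins
        assert assignment.mapping["LAA"].index == 4

    def test_score_decomposition_readds_to_total(self):
        cands = _candidate_pool()
        results, assignment = localize_targets(cands, PRIOR, MODEL)
        recomputed = score_assignment(assignment.mapping, PRIOR, MODEL)
        assert assignment.total == pytest.approx(
            assignment.intensity_term + assignment.geometry_term
        )
        assert recomputed.total == pytest.approx(assignment.total)
        assert all(r.score == pytest.approx(assignment.total) for r in results)
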