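"""PCA morphospace: spectrum recovery, invariants, PC-axis reconstruction."""

import dataclasses

import numpy as np
import pytest

from larvamorph import (
    EffectivePcRule,
    effective_pcs,
    fit_morphospace,
    generate_outline,
    reconstruct_along_pc,
)
from larvamorph.efa import efa_decompose, efa_normalize, feature_vector
from larvamorph.morphospace import coefficient_matrix
from larvamorph.pipeline import analyze_cohort
from larvamorph.synthetic import MORPHOTYPE_DEFAULTS, LabrumType


def normalized_cohort_matrix(specs, n_per=20, noise=0.02, n_points=128):
    rows, labels = [], []
    for si, spec in enumerate(specs):
        s = dataclasses.replace(spec, noise_sd=noise)
        for i in range(n_per):
            c, _ = generate_outline(s, np.random.default_rng([si, i]), n_points)
            norm, _ = efa_normalize(efa_decompose(c, 12))
            rows.append(feature_vector(norm))
            labels.append(si)
    return np.vstack(rows), np.array(labels)


class TestFit:
    def test_identical_rows_give_zero_spectrum(self):
        X = np.tile(np.arange(8.0), (5, 1))
        m = fit_morphospace(X)
        assert np.all(m.eigenvalues < 1e-24)
        assert m.n_effective == 0

    def test_known_gaussian_spectrum_recovered(self):
        """diag(4, 1) covariance embedded in 10 dims: top two sample
        eigenvalues land within 15% of the population values."""
        rng = np.random.default_rng(42)
        X = np.zeros((500, 10))
        X[:, 0] = rng.normal(0, 2.0, 500)
        X[:, 1] = rng.normal(0, 1.0, 500)
        Q, _ = np.linalg.qr(rng.normal(size=(10, 10)))  # random rotation
        m = fit_morphospace(X @ Q.T)
        assert m.eigenvalues[0] == pytest.approx(4.0, rel=0.15)
        assert m.eigenvalues[1] == pytest.approx(1.0, rel=0.15)
        assert np.all(m.eigenvalues[2:] < 0.15)

    def test_trace_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 12)) * rng.uniform(0.1, 3.0, 12)
        m = fit_morphospace(X)
        total_var = np.var(X, axis=0, ddof=1).sum()
        assert m.eigenvalues.sum() == pytest.approx(total_var, rel=1e-9)

    def test_scores_centered_uncorrelated_variance_matches(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 9))
        m = fit_morphospace(X)
        assert np.abs(m.scores.mean(axis=0)).max() < 1e-9
        cov = np.cov(m.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-6 * m.eigenvalues[0]
        assert np.allclose(np.diag(cov), m.eigenvalues, atol=1e-6)

    def test_eigenvectors_orthonormal_variance_sums_to_one(self):
        rng = np.random.default_rng(2)
        m = fit_morphospace(rng.normal(size=(30, 7)))
        G = m.eigenvectors.T @ m.eigenvectors
        assert np.abs(G - np.eye(G.shape[0])).max() < 1e-9
        assert m.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(m.variance_explained) <= 1e-12)

    def test_projection_round_trip(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6))
        m = fit_morphospace(X)
        back = m.back_project(m.project(X))
        assert np.abs(back - X).max() < 1e-9

    def test_matches_sklearn_pca(self):
        """Independent cross-check against scikit-learn's PCA."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 8)) * rng.uniform(0.2, 2.0, 8)
        m = fit_morphospace(X)
        sk = PCA().fit(X)
        assert np.allclose(m.eigenvalues, sk.explained_variance_, atol=1e-9)
        # eigenvectors agree up to sign
        dots = np.abs(np.sum(m.eigenvectors.T * sk.components_, axis=1))
        assert np.allclose(dots, 1.0, atol=1e-9)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_morphospace(np.zeros((2, 5)))

    def test_unequal_row_lengths_rejected(self):
        from larvamorph.efa import EFACoefficients

        a = EFACoefficients(np.vstack([[1, 0, 0, 0.5]] * 3), normalized=True)
        b = EFACoefficients(np.vstack([[1, 0, 0, 0.5]] * 4), normalized=True)
        with pytest.raises(ValueError):
            coefficient_matrix([a, b])


class TestEffectivePcs:
    @pytest.mark.parametrize(
        "eigenvalues, rule, expected",
        [
            ((4, 1, 1, 1, 1), EffectivePcRule.gt_mean(), 1),
            ((2, 2, 0, 0), EffectivePcRule.gt_mean(), 2),
            # the published head+stylet variance proportions: six PCs
            # at 52.5/24.8/7.5/3.9/3.0/2.5% all clear the 2% floor
            (
                (0.525, 0.248, 0.075, 0.039, 0.030, 0.025, 0.010,
                 0.008, 0.006, 0.004, 0.030 / 10),
                EffectivePcRule.proportion_ge(0.02),
                6,
            ),
        ],
    )
    def test_rules(self, eigenvalues, rule, expected):
        ev = np.sort(np.asarray(eigenvalues, float))[::-1]
        assert effective_pcs(ev, rule) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            effective_pcs(np.array([]))


@pytest.fixture(scope="module")
def model():
    X, _ = normalized_cohort_matrix(
        [MORPHOTYPE_DEFAULTS[LabrumType.triangular],
         MORPHOTYPE_DEFAULTS[LabrumType.trident]],
        n_per=15,
    )
    return fit_morphospace(X)


class TestReconstructAlongPc:

    def test_zero_sd_gives_mean_shape(self, model):
        for pc in (1, 2):
            rec = reconstruct_along_pc(model, pc, 0.0)
            from larvamorph.efa import feature_vector_to_coeffs

            mean_rec = feature_vector_to_coeffs(model.mean)
            from larvamorph.efa import efa_reconstruct

            expected = efa_reconstruct(mean_rec, 256)
            assert np.allclose(rec.points, expected.points, atol=1e-12)

    def test_plus_minus_extremes_symmetric_about_mean(self, model):
        lo = reconstruct_along_pc(model, 1, -2.0)
        hi = reconstruct_along_pc(model, 1, 2.0)
        mid = reconstruct_along_pc(model, 1, 0.0)
        assert np.abs((lo.points + hi.points) / 2 - mid.points).max() < 1e-9

    def test_pc_out_of_range(self, model):
        with pytest.raises(ValueError):
            reconstruct_along_pc(model, 0, 1.0)
        with pytest.raises(ValueError):
            reconstruct_along_pc(model, model.n_components + 1, 1.0)

    def test_labrum_only_variation_localised_in_pc1_extremes(self):
        """A cohort varying only in labrum length concentrates its PC1
        shape change in a small angular region of the outline; most of
        the contour is unchanged beyond the global size renormalization."""
        base = MORPHOTYPE_DEFAULTS[LabrumType.triangular]
        rows = []
        for i, ll in enumerate(np.linspace(0.35, 0.9, 24)):
            s = dataclasses.replace(base, labrum_length_rel=float(ll))
            c, _ = generate_outline(s, np.random.default_rng(i), 128)
            norm, _ = efa_normalize(efa_decompose(c, 12))
            rows.append(feature_vector(norm))
        m = fit_morphospace(np.vstack(rows))

        def radial_on_grid(contour, grid):
            pts = contour.points - contour.points.mean(axis=0)
            phi = np.arctan2(pts[:, 1], pts[:, 0])
            order = np.argsort(phi)
            phi, r = phi[order], np.hypot(pts[order, 0], pts[order, 1])
            phi = np.concatenate([phi - 2 * np.pi, phi, phi + 2 * np.pi])
            return np.interp(grid, phi, np.tile(r, 3))

        grid = np.linspace(-np.pi, np.pi, 720, endpoint=False)
        lo = radial_on_grid(reconstruct_along_pc(m, 1, -2.0, n_points=720), grid)
        hi = radial_on_grid(reconstruct_along_pc(m, 1, 2.0, n_points=720), grid)
        q = hi / lo  # radial ratio; its median is the global scale change
        dev = np.abs(q - np.median(q))
        assert (dev > 0.25 * dev.max()).mean() < 0.15
        assert np.percentile(dev, 75) < 0.1 * dev.max()


class TestClusterRecovery:
    def test_kmeans_purity_on_morphotype_cohort(self):
        """Four morphotype clusters, 30 specimens each: k-means on the
        effective PCs separates them with purity >= 0.9."""
        from scipy.cluster.vq import kmeans2

        specs = [
            MORPHOTYPE_DEFAULTS[LabrumType.triangular],
            MORPHOTYPE_DEFAULTS[LabrumType.trident],
            MORPHOTYPE_DEFAULTS[LabrumType.broad],
            MORPHOTYPE_DEFAULTS[LabrumType.pentadent],
        ]
        X, labels = normalized_cohort_matrix(specs, n_per=30)
        m = fit_morphospace(X)
        k = max(m.n_effective, 2)
        _, assign = kmeans2(m.scores[:, :k], 4, seed=1, minit="++")
        purity = (
            sum(
                max(np.sum((assign == j) & (labels == t)) for t in range(4))
                for j in range(4)
            )
            / len(labels)
        )
        assert purity >= 0.9
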