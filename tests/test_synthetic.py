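import numpy as np
import pytest
from scipy import stats

from radcorr.synthetic import (
    CohortSpec,
    ModalityParams,
    StreakParams,
    clean_volume,
    generate_cohort,
    inject_fiducial_streaks,
    write_cohort,
)
from radcorr.volume import load_mask, load_volume


def small_spec(**kw):
    defaults = dict(
        n_patients=3,
        grid_shape=(24, 24, 24),
        roi_radii_log_median_mm=(7.0, 6.0, 6.5),
        seed=11,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


IDENTITY_MODALITIES = {
    "A": ModalityParams(),
    "B": ModalityParams(),
    "C": ModalityParams(),
}


class TestGenerateCohort:
    def test_shared_weight_one_gives_identical_volumes(self):
        spec = small_spec(shared_weight=1.0, modality_params=dict(IDENTITY_MODALITIES), n_fiducials=0)
        for pat in generate_cohort(spec):
            a, b, c = (pat.volumes[m].values for m in ("A", "B", "C"))
            assert np.array_equal(a, b) and np.array_equal(b, c)

    def test_determinism(self):
        spec = small_spec()
        c1, c2 = generate_cohort(spec), generate_cohort(spec)
        for p1, p2 in zip(c1, c2):
            assert np.array_equal(p1.mask.inside, p2.mask.inside)
            assert p1.fiducials.centers == p2.fiducials.centers
            for m in p1.volumes:
                assert np.array_equal(p1.volumes[m].values, p2.volumes[m].values)

    def test_patient_count_and_geometry(self):
        spec = small_spec(n_patients=5)
        pats = generate_cohort(spec)
        assert len(pats) == 5
        for pat in pats:
            assert pat.mask.n_voxels >= 1
            for ctr in pat.fiducials.centers:
                assert pat.mask.inside[ctr]
            shapes = {v.shape for v in pat.volumes.values()} | {pat.mask.shape}
            assert len(shapes) == 1

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            small_spec(grid_shape=(0, 24, 24))
        with pytest.raises(ValueError):
            small_spec(spacing_mm=(1.0, -1.0, 1.0))
        with pytest.raises(ValueError):
            small_spec(shared_weight=1.5)
        with pytest.raises(ValueError):
            small_spec(volume_coupling=-0.1)

    def test_shared_weight_zero_roi_means_inside_null_band(self):
        # With no shared texture the across-patient Spearman correlation of
        # ROI-mean intensity between two modalities must behave like a null
        # correlation at n=47: inside the two-sided 95% band in >=93% of 200
        # replicate cohorts.  The band itself comes from simulating
        # independent data at n=47.
        rng = np.random.default_rng(5)
        null = np.array(
            [
                stats.spearmanr(rng.standard_normal(47), rng.standard_normal(47)).statistic
                for _ in range(4000)
            ]
        )
        band = np.quantile(np.abs(null), 0.95)
        mods = {"A": ModalityParams(noise_sd=0.05), "B": ModalityParams(noise_sd=0.05)}
        inside = 0
        n_rep = 200
        for rep in range(n_rep):
            spec = CohortSpec(
                n_patients=47,
                grid_shape=(12, 12, 12),
                roi_radii_log_median_mm=(4.0, 3.5, 3.8),
                shared_weight=0.0,
                modality_params=dict(mods),
                n_fiducials=0,
                seed=1000 + rep,
            )
            means = {"A": [], "B": []}
            for pat in generate_cohort(spec):
                for m in means:
                    means[m].append(pat.volumes[m].values[pat.mask.inside].mean())
            rho = stats.spearmanr(means["A"], means["B"]).statistic
            inside += abs(rho) <= band
        assert inside / n_rep >= 0.93

    def test_monotone_transforms_preserve_roi_ranks(self):
        mods = {
            "ident": ModalityParams(transform="identity", gain=3.0, offset=10.0),
            "neg": ModalityParams(transform="negate", gain=2.0),
            "gam": ModalityParams(transform="gamma", gamma=1.7),
        }
        spec = small_spec(shared_weight=1.0, modality_params=mods, n_fiducials=0)
        pat = generate_cohort(spec)[0]
        ref = pat.volumes["ident"].values[pat.mask.inside]
        for m, expected_sign in (("neg", -1.0), ("gam", 1.0)):
            other = pat.volumes[m].values[pat.mask.inside]
            rho = stats.spearmanr(ref, other).statistic
            assert rho == pytest.approx(expected_sign, abs=1e-12)

    def test_roi_volume_converges_to_analytic_ellipsoid(self):
        radii = (7.0, 6.0, 6.5)
        analytic = 4.0 / 3.0 * np.pi * np.prod(radii)
        errors = []
        for spacing, grid in ((2.0, 12), (1.0, 24), (0.5, 48)):
            spec = CohortSpec(
                n_patients=1,
                grid_shape=(grid, grid, grid),
                spacing_mm=(spacing,) * 3,
                roi_radii_log_median_mm=radii,
                roi_radii_log_sigma=1e-9,
                n_fiducials=0,
                modality_params={"A": ModalityParams()},
                seed=3,
            )
            pat = generate_cohort(spec)[0]
            errors.append(abs(pat.truth["roi_volume_mm3"] - analytic))
        assert errors[2] < errors[0]
        assert errors[2] / analytic < 0.02

    def test_volume_coupling_zero_leaves_texture_unconfounded(self):
        # With the coupling off, the across-patient correlation between ROI
        # volume and measured intensity variance is null-like: the mean |rho|
        # over 200 cohorts stays below the single-cohort null 95% bound.
        rhos = []
        for rep in range(200):
            spec = CohortSpec(
                n_patients=20,
                grid_shape=(12, 12, 12),
                roi_radii_log_median_mm=(4.0, 3.5, 3.8),
                volume_coupling=0.0,
                modality_params={"A": ModalityParams(gain=10.0)},
                n_fiducials=0,
                seed=7000 + rep,
            )
            vols, variances = [], []
            for pat in generate_cohort(spec):
                vols.append(pat.truth["roi_volume_mm3"])
                variances.append(pat.volumes["A"].values[pat.mask.inside].var())
            rhos.append(abs(stats.spearmanr(vols, variances).statistic))
        null_bound_n20 = 0.447  # 95% quantile of |rho| under independence, n=20
        assert np.mean(rhos) < null_bound_n20


class TestStreaks:
    def _phantom(self, **kw):
        spec = small_spec(n_patients=1, n_fiducials=2, **kw)
        return generate_cohort(spec)[0], spec

    def test_no_fiducials_leaves_volume_unchanged(self):
        pat, spec = self._phantom()
        vol = pat.volumes["T2w"]
        from radcorr.fiducials import FiducialAnnotation

        out, truth = inject_fiducial_streaks(
            vol, pat.mask, FiducialAnnotation([], []), spec.streak_params
        )
        assert np.array_equal(out.values, vol.values)
        assert truth.voxels.shape == (0, 3)

    def test_zero_amplitude_is_identity(self):
        pat, _ = self._phantom()
        vol = pat.volumes["T2w"]
        out, truth = inject_fiducial_streaks(
            vol, pat.mask, pat.fiducials, StreakParams(amplitude=0.0)
        )
        assert np.array_equal(out.values, vol.values)
        assert truth.voxels.size == 0

    def test_streaks_confined_to_artifact_slices(self):
        pat, _ = self._phantom()
        truth = pat.truth["streaks"]["CT"]
        assert truth.voxels.shape[0] > 0
        allowed = pat.fiducials.all_artifact_slices
        assert set(truth.voxels[:, 2].tolist()) <= allowed

    def test_ground_truth_detectability_count(self):
        # Directly count how many altered voxels moved outside the artifact-
        # free 3-sigma band -- with a 6-sigma amplitude nearly all of them do.
        pat, _ = self._phantom()
        truth = pat.truth["streaks"]["CT"]
        clean = clean_volume(pat, "CT")
        vals_clean = clean.values[pat.mask.inside]
        mu, sigma = vals_clean.mean(), vals_clean.std()
        streaked = pat.volumes["CT"].values
        vox = truth.voxels
        outside = np.abs(streaked[vox[:, 0], vox[:, 1], vox[:, 2]] - mu) > 3 * sigma
        assert outside.mean() > 0.9

    def test_clean_volume_reconstruction(self):
        pat, spec = self._phantom()
        clean = clean_volume(pat, "CBCT")
        truth = pat.truth["streaks"]["CBCT"]
        diff = pat.volumes["CBCT"].values - clean.values
        vox = truth.voxels
        assert diff[vox[:, 0], vox[:, 1], vox[:, 2]] == pytest.approx(truth.deltas)
        diff[vox[:, 0], vox[:, 1], vox[:, 2]] = 0.0
        assert np.max(np.abs(diff)) == 0.0


def test_write_cohort_roundtrip(tmp_path):
    spec = small_spec(n_patients=2)
    pats = generate_cohort(spec)
    manifest = write_cohort(pats, tmp_path)
    assert len(manifest) == 2 * 3
    row = manifest.iloc[0]
    vol = load_volume(row["volume"], row["modality"])
    mask = load_mask(row["mask"])
    orig = pats[0].volumes[row["modality"]]
    assert vol.shape == orig.shape
    assert vol.values == pytest.approx(orig.values, rel=1e-6)  # float32 on disk
    assert np.array_equal(mask.inside, pats[0].mask.inside)
    assert (tmp_path / "manifest.csv").exists()
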