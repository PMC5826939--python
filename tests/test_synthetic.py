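"""Synthetic-data generators: reference spectra, phantoms, electropherograms."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepatoquant.synthetic import (
    CLASS_AMPLITUDES,
    LABEL_CODES,
    DropletLaw,
    Electropherogram,
    ElectropherogramSpec,
    HyperspectralStack,
    IsoformSpec,
    ReferenceSpectrum,
    SpectralAxis,
    TissuePhantomSpec,
    apply_phosphatase,
    generate_cohort,
    generate_electropherogram,
    generate_phantom,
    make_reference_spectra,
)


class TestSpectralAxis:
    def test_default_axis_covers_ch_stretch(self, axis):
        vals = axis.values
        assert vals[0] == 2800.0 and len(vals) == 40
        assert np.all(np.diff(vals) == 5.0)

    @pytest.mark.parametrize("kwargs", [{"step": 0}, {"step": -1}, {"n_channels": 1}])
    def test_invalid_axis_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpectralAxis(**{"start_wavenumber": 2800.0, "step": 5.0, "n_channels": 40, **kwargs})


class TestReferenceSpectra:
    @pytest.mark.parametrize(
        "which,center", [(0, 2850.0), (1, 2930.0), (2, 2960.0)],
        ids=["lipid", "protein", "dna"],
    )
    def test_argmax_at_cluster_center(self, axis, references, which, center):
        spec = references[which].evaluate(axis)
        assert axis.values[spec.argmax()] == center

    def test_spectra_nonnegative_and_peak_normalized(self, axis, references):
        for ref in references:
            y = ref.evaluate(axis)
            assert np.all(y >= 0) and y.max() == pytest.approx(1.0)

    def test_narrow_sigma_limit_is_delta_like(self, axis):
        ref = ReferenceSpectrum("lipid", (2850.0,), (1e-3,), (1.0,))
        y = ref.evaluate(axis)
        center_idx = int(np.argmax(np.abs(axis.values - 2850.0) < 1e-9))
        assert y[center_idx] == pytest.approx(1.0)
        assert np.all(y[np.arange(len(y)) != center_idx] < 1e-10)

    def test_axis_not_covering_center_errors(self):
        short = SpectralAxis(2900.0, 5.0, 10)
        with pytest.raises(ValueError, match="2850"):
            make_reference_spectra(short)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            ReferenceSpectrum("lipid", (2850.0,), (10.0,), (0.0,))
        with pytest.raises(ValueError):
            ReferenceSpectrum("lipid", (2600.0,), (10.0,), (1.0,))


class TestPhantom:
    def test_deterministic_given_seed(self):
        spec = TissuePhantomSpec(height_px=64, width_px=64, mode="normal", seed=7)
        s1, g1 = generate_phantom(spec)
        s2, g2 = generate_phantom(spec)
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(g1.label_image, g2.label_image)
        assert g1.true_lipid_fraction == g2.true_lipid_fraction

    def test_noiseless_fraction_hits_target_band(self, noiseless_phantom):
        _, gt = noiseless_phantom
        assert 0.25 <= gt.true_lipid_fraction <= 0.31

    def test_true_fraction_matches_brute_force_recount(self, noiseless_phantom):
        stack, gt = noiseless_phantom
        lipid_mask = gt.label_image == LABEL_CODES["lipid"]
        lipid_signal = stack.data[lipid_mask].sum()
        total = stack.data.sum()
        assert abs(lipid_signal / total - gt.true_lipid_fraction) < 1e-12

    def test_lipid_pixels_proportional_to_reference(self, axis, references, noiseless_phantom):
        stack, gt = noiseless_phantom
        lipid_ref = references[0].evaluate(axis)
        spectra = stack.data[gt.label_image == LABEL_CODES["lipid"]]
        # per-pixel ratio to the reference must be a constant across channels
        ratios = spectra / lipid_ref[None, :]
        assert np.allclose(ratios, ratios[:, :1], rtol=1e-10)

    def test_every_pixel_is_nonnegative_combination_of_references(
        self, axis, references, noiseless_phantom
    ):
        stack, _ = noiseless_phantom
        basis = np.stack([r.evaluate(axis) for r in references])  # (3, C)
        flat = stack.data.reshape(-1, stack.data.shape[-1])
        coef, res, *_ = np.linalg.lstsq(basis.T, flat.T, rcond=None)
        assert np.all(coef > -1e-9)
        recon = basis.T @ coef
        assert np.allclose(recon.T, flat, atol=1e-9)

    def test_unreachable_target_errors(self):
        # a droplet law whose minimum droplet overshoots a tiny target on a
        # tiny field can never settle inside the +/-0.03 band
        law = DropletLaw(median_um=30.0, sigma_log=1e-6, max_um=50.0)
        spec = TissuePhantomSpec(
            height_px=40, width_px=40, mode="nash", target_lipid_fraction=0.05,
            droplet_law=law, noise_sigma=0.0, seed=0,
        )
        with pytest.raises(RuntimeError):
            generate_phantom(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TissuePhantomSpec(target_lipid_fraction=1.5)
        with pytest.raises(ValueError):
            TissuePhantomSpec(pixel_size=0.0)
        with pytest.raises(ValueError):
            TissuePhantomSpec(droplet_law=DropletLaw(3.0, 1.0, 80.0))

    def test_stack_tiff_roundtrip(self, tmp_path, noiseless_phantom):
        stack, _ = noiseless_phantom
        path = tmp_path / "frame.tif"
        stack.save(path)
        loaded = HyperspectralStack.load(path)
        assert loaded.axis == stack.axis
        assert loaded.pixel_size == stack.pixel_size
        np.testing.assert_allclose(loaded.data, stack.data.astype(np.float32), rtol=1e-6)


class TestElectropherogram:
    def test_single_unmodified_isoform_is_one_gaussian(self):
        spec = ElectropherogramSpec(
            unmodified_pI=6.4, baseline_level=0.0, noise_sigma=0.0, seed=0
        )
        trace, truth = generate_electropherogram(spec)
        assert truth == {"unmodified": 1.0}
        assert trace.pI[np.argmax(trace.intensity)] == pytest.approx(6.4, abs=0.01)
        # symmetric Gaussian: intensity at center +/- delta matches
        i = np.argmax(trace.intensity)
        np.testing.assert_allclose(trace.intensity[i - 20], trace.intensity[i + 20], rtol=1e-6)

    def test_equal_concentrations_give_equal_areas(self):
        spec = ElectropherogramSpec(
            unmodified_pI=6.4,
            isoforms=(
                IsoformSpec("unmodified", 0.0, 0.5, 0.05),
                IsoformSpec("phospho", -0.5, 0.5, 0.05),
            ),
            baseline_level=0.0,
            noise_sigma=0.0,
            n_points=3001,
        )
        trace, _ = generate_electropherogram(spec)
        mid = 6.4 - 0.25
        left = np.trapezoid(trace.intensity[trace.pI < mid], trace.pI[trace.pI < mid])
        right = np.trapezoid(trace.intensity[trace.pI >= mid], trace.pI[trace.pI >= mid])
        assert abs(left - right) < 1e-6

    def test_glycosyl_peak_lies_above_unmodified_pI(self):
        spec = ElectropherogramSpec(
            unmodified_pI=6.0,
            isoforms=(
                IsoformSpec("unmodified", 0.0, 0.6),
                IsoformSpec("glycosyl", 0.4, 0.4),
            ),
            baseline_level=0.0,
            noise_sigma=0.0,
        )
        trace, _ = generate_electropherogram(spec)
        gly_region = trace.pI > 6.2
        assert trace.intensity[gly_region].max() > 0.1
        peak_pi = trace.pI[gly_region][np.argmax(trace.intensity[gly_region])]
        assert peak_pi > 6.0

    def test_shift_conventions_enforced(self):
        with pytest.raises(ValueError):  # phospho must shift down
            ElectropherogramSpec(
                isoforms=(IsoformSpec("unmodified", 0.0, 0.5), IsoformSpec("phospho", 0.1, 0.5))
            )
        with pytest.raises(ValueError):  # acetyl below phospho
            ElectropherogramSpec(
                isoforms=(
                    IsoformSpec("phospho", -0.4, 0.5),
                    IsoformSpec("acetyl", -0.1, 0.5),
                )
            )
        with pytest.raises(ValueError):  # glycosyl must shift up
            ElectropherogramSpec(
                isoforms=(IsoformSpec("unmodified", 0.0, 0.5), IsoformSpec("glycosyl", -0.2, 0.5))
            )
        with pytest.raises(ValueError):  # concentrations must sum to 1
            ElectropherogramSpec(isoforms=(IsoformSpec("unmodified", 0.0, 0.7),))

    def test_isoform_center_outside_axis_errors(self):
        with pytest.raises(ValueError, match="outside pI axis"):
            ElectropherogramSpec(
                unmodified_pI=5.1,
                isoforms=(
                    IsoformSpec("unmodified", 0.0, 0.5),
                    IsoformSpec("acetyl", -0.5, 0.5),
                ),
            )

    def test_csv_roundtrip(self, tmp_path, three_isoform_spec):
        trace, _ = generate_electropherogram(three_isoform_spec)
        path = tmp_path / "trace.csv"
        trace.save_csv(path)
        loaded = Electropherogram.load_csv(path)
        np.testing.assert_allclose(loaded.pI, trace.pI, rtol=1e-8)
        np.testing.assert_allclose(loaded.intensity, trace.intensity, rtol=1e-6)


class TestPhosphatase:
    def test_complete_dephosphorylation(self):
        spec = ElectropherogramSpec(
            isoforms=(IsoformSpec("unmodified", 0.0, 0.6), IsoformSpec("phospho", -0.2, 0.4))
        )
        out = apply_phosphatase(spec)
        assert out.ground_truth() == {"unmodified": 1.0}

    def test_acetyl_isoforms_untouched(self):
        spec = ElectropherogramSpec(
            isoforms=(IsoformSpec("unmodified", 0.0, 0.5), IsoformSpec("acetyl", -0.5, 0.5))
        )
        out = apply_phosphatase(spec)
        assert out.ground_truth() == spec.ground_truth()

    def test_mass_transfer_arithmetic(self):
        spec = ElectropherogramSpec(
            isoforms=(
                IsoformSpec("unmodified", 0.0, 0.2),
                IsoformSpec("phospho", -0.15, 0.3),
                IsoformSpec("acetyl", -0.5, 0.5),
            )
        )
        truth = apply_phosphatase(spec).ground_truth()
        assert truth["unmodified"] == pytest.approx(0.5)
        assert truth.get("phospho", 0.0) == 0.0
        assert truth["acetyl"] == pytest.approx(0.5)

    def test_partial_efficiency(self):
        spec = ElectropherogramSpec(
            isoforms=(IsoformSpec("unmodified", 0.0, 0.6), IsoformSpec("phospho", -0.2, 0.4))
        )
        truth = apply_phosphatase(spec, efficiency=0.5).ground_truth()
        assert truth["phospho"] == pytest.approx(0.2)
        assert truth["unmodified"] == pytest.approx(0.8)

    @settings(deadline=None, max_examples=30)
    @given(
        u=st.floats(0.01, 1.0),
        p=st.floats(0.01, 1.0),
        a=st.floats(0.0, 1.0),
        eff=st.floats(0.0, 1.0),
    )
    def test_concentration_conserved_exactly(self, u, p, a, eff):
        total = u + p + a
        isoforms = [
            IsoformSpec("unmodified", 0.0, u / total),
            IsoformSpec("phospho", -0.2, p / total),
        ]
        if a > 0:
            isoforms.append(IsoformSpec("acetyl", -0.6, a / total))
        # renormalize exactly to 1 to satisfy the spec invariant
        s = sum(i.relative_concentration for i in isoforms)
        isoforms = [
            dataclasses.replace(i, relative_concentration=i.relative_concentration / s)
            for i in isoforms
        ]
        spec = ElectropherogramSpec(isoforms=tuple(isoforms))
        out = apply_phosphatase(spec, efficiency=eff)
        assert sum(out.ground_truth().values()) == pytest.approx(1.0, abs=1e-12)


class TestCohort:
    def test_minimal_cohort_manifest(self, tmp_path):
        manifest = generate_cohort(
            1, 1, 0, tmp_path / "c", frames_per_sample=1, frame_shape=(48, 48),
            proteins=["AKT"], replicates=2,
        )
        assert len(manifest["samples"]) == 2
        seeds = [s["seed"] for s in manifest["samples"]]
        assert len(set(seeds)) == 2
        modes = {s["sample_id"]: s["mode"] for s in manifest["samples"]}
        assert modes["nash_01"] == "nash" and modes["normal_01"] == "normal"
        for s in manifest["samples"]:
            for fr in s["frames"]:
                assert (tmp_path / "c" / fr["file"]).exists()
            for rep in s["cief"]["AKT"]["replicates"]:
                assert (tmp_path / "c" / rep["file"]).exists()

    def test_rerun_is_byte_identical(self, tmp_path):
        kwargs = dict(frames_per_sample=1, frame_shape=(48, 48), proteins=["AKT"], replicates=2)
        generate_cohort(1, 1, 5, tmp_path / "a", **kwargs)
        generate_cohort(1, 1, 5, tmp_path / "b", **kwargs)
        a = (tmp_path / "a" / "manifest.json").read_bytes()
        b = (tmp_path / "b" / "manifest.json").read_bytes()
        assert a == b

    def test_counts_below_one_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_cohort(0, 1, 0, tmp_path / "x")
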