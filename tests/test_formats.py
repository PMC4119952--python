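import numpy as np
import pytest

import dxt.formats as fmts
from dxt.fixtures import FixtureSpec, write_hdf5_stack, write_smv_sweep
from dxt.formats import (
    DuplicateFormatError,
    Format,
    FormatHDF5Stack,
    FormatRegistry,
    FormatSMV,
    FormatSMVADSC,
    FormatSMVADSCReversedPhi,
    FormatSMVADSCTwoTheta,
    MalformedContainerError,
    MalformedHeaderError,
    MissingMetadataError,
    OrphanFormatError,
    UnknownFormatError,
    default_registry,
    hdf5_stack_models,
    smv_build_models,
    smv_read_header,
)
from dxt.geometry import rotation_about_axis


def small_spec(**overrides) -> FixtureSpec:
    kwargs = dict(image_size=(64, 64), beam_centre=(3.2, 3.2), n_images=1,
                  poisson_noise=False, seed=3)
    kwargs.update(overrides)
    return FixtureSpec(**kwargs)


@pytest.fixture
def adsc_file(tmp_path):
    return write_smv_sweep(small_spec(), tmp_path / "adsc")[0]


@pytest.fixture
def reversed_phi_file(tmp_path):
    return write_smv_sweep(small_spec(serial_number="915"), tmp_path / "rev")[0]


@pytest.fixture
def two_theta_file(tmp_path):
    return write_smv_sweep(
        small_spec(serial_number="926", two_theta=30.0), tmp_path / "tth"
    )[0]


class TestSmvHeader:
    def test_key_value_parsing(self):
        data = b"{\nHEADER_BYTES=128;\nDISTANCE=150.0;\nlower_case=x;\n}\n"
        data += b" " * (128 - len(data))
        header = smv_read_header(data)
        assert header["DISTANCE"] == "150.0"
        assert header["HEADER_BYTES"] == "128"
        assert header["LOWER_CASE"] == "x"  # keys are upper-cased

    def test_trailing_padding_ignored(self):
        body = b"{\nHEADER_BYTES=512;\nDISTANCE=1.0;\n}\n"
        data = body + b" " * (512 - len(body)) + b"GARBAGE=1;\n"
        header = smv_read_header(data)
        assert "GARBAGE" not in header

    def test_missing_brace_rejected(self):
        with pytest.raises(MalformedHeaderError):
            smv_read_header(b"HEADER_BYTES=512;\n" + b" " * 512)

    def test_missing_header_bytes_rejected(self):
        with pytest.raises(MalformedHeaderError):
            smv_read_header(b"{\nDISTANCE=1.0;\n}\n" + b" " * 512)

    def test_truncated_file_rejected(self):
        with pytest.raises(MalformedHeaderError):
            smv_read_header(b"{\nHEADER_BYTES=512;\n}\n")


class TestSmvModels:
    HEADER = {
        "SIZE1": "2048", "SIZE2": "2048", "PIXEL_SIZE": "0.1024",
        "DISTANCE": "150", "WAVELENGTH": "0.9795",
        "BEAM_CENTER_X": "94", "BEAM_CENTER_Y": "94",
        "OSC_START": "0.0", "OSC_RANGE": "0.5",
    }

    def test_beam_centre_round_trip(self):
        beam, detector, goniometer, scan = smv_build_models(self.HEADER)
        panel = detector[0]
        assert panel.origin == pytest.approx((-94, 94, 150))
        hit = detector.beam_centre(beam)
        assert hit.panel_id == 0
        assert hit.xy == pytest.approx((94, 94), abs=1e-9)
        assert goniometer.rotation_axis == pytest.approx((1, 0, 0))
        assert beam.wavelength == 0.9795

    def test_zero_osc_range_is_still(self):
        header = dict(self.HEADER, OSC_RANGE="0")
        _, _, _, scan = smv_build_models(header)
        assert scan.is_still

    def test_missing_key_named_in_error(self):
        header = {k: v for k, v in self.HEADER.items() if k != "WAVELENGTH"}
        with pytest.raises(MissingMetadataError, match="WAVELENGTH"):
            smv_build_models(header)


class TestRegistry:
    def test_builtin_tree_shape(self):
        reg = default_registry()
        assert reg.children(Format) == [FormatSMV, FormatHDF5Stack]
        assert reg.children(FormatSMV) == [FormatSMVADSC]
        assert set(reg.children(FormatSMVADSC)) == {
            FormatSMVADSCReversedPhi, FormatSMVADSCTwoTheta,
        }

    def test_duplicate_registration_rejected(self):
        reg = default_registry()
        with pytest.raises(DuplicateFormatError):
            reg.register(FormatSMV)

    def test_orphan_parent_rejected(self):
        reg = FormatRegistry()

        class Orphan(Format):
            format_name = "Orphan"
            parent_format = FormatSMV  # not registered in this registry

        with pytest.raises(OrphanFormatError):
            reg.register(Orphan)

    def test_registration_chain_depth(self):
        reg = FormatRegistry()
        reg.register(FormatSMV)
        reg.register(FormatSMVADSC)
        reg.register(FormatSMVADSCReversedPhi)
        assert reg.children(FormatSMVADSC) == [FormatSMVADSCReversedPhi]


class TestResolution:
    def test_plain_adsc(self, adsc_file):
        assert fmts.global_registry.find_format_class(adsc_file) is FormatSMVADSC

    def test_reversed_phi_serial_gates_deepest_class(self, reversed_phi_file):
        found = fmts.global_registry.find_format_class(reversed_phi_file)
        assert found is FormatSMVADSCReversedPhi

    def test_two_theta_serial(self, two_theta_file):
        found = fmts.global_registry.find_format_class(two_theta_file)
        assert found is FormatSMVADSCTwoTheta

    def test_empty_file_unknown(self, tmp_path):
        empty = tmp_path / "empty.img"
        empty.write_bytes(b"")
        with pytest.raises(UnknownFormatError):
            fmts.global_registry.find_format_class(empty)

    def test_garbage_file_unknown(self, tmp_path):
        junk = tmp_path / "junk.bin"
        junk.write_bytes(b"\x00\x01\x02 not an image")
        with pytest.raises(UnknownFormatError):
            default_registry().find_format_class(junk)

    def test_ancestor_chain_understands(self, reversed_phi_file):
        cls = fmts.global_registry.find_format_class(reversed_phi_file)
        while cls is not None:
            assert cls.understands(reversed_phi_file)
            cls = cls.parent_format

    def test_registering_unrelated_format_changes_nothing(self, adsc_file, reversed_phi_file):
        """Registry monotonicity: an extra class that does not understand
        these files leaves lookup results unchanged."""
        reg = default_registry()
        before = (reg.find_format_class(adsc_file), reg.find_format_class(reversed_phi_file))

        class FormatNope(Format):
            format_name = "Nope"
            parent_format = Format

            @classmethod
            def understands(cls, path):
                return False

        reg.register(FormatNope)
        after = (reg.find_format_class(adsc_file), reg.find_format_class(reversed_phi_file))
        assert before == after


class TestReversedPhi:
    def test_axis_negated_only(self, reversed_phi_file):
        child = FormatSMVADSCReversedPhi(reversed_phi_file)
        parent = FormatSMVADSC(reversed_phi_file)
        assert child.get_goniometer().rotation_axis == pytest.approx((-1, 0, 0))
        # override minimality: everything else equals the parent's models
        assert child.get_beam() == parent.get_beam()
        assert child.get_detector() == parent.get_detector()
        assert child.get_scan() == parent.get_scan()

    def test_double_reversal_restores_axis(self, reversed_phi_file):
        g = FormatSMVADSCReversedPhi(reversed_phi_file).get_goniometer()
        assert g.reversed().rotation_axis == pytest.approx((1, 0, 0))


class TestTwoTheta:
    def test_zero_angle_detector_equals_parent(self, tmp_path):
        path = write_smv_sweep(
            small_spec(serial_number="926", two_theta=0.0), tmp_path / "t0"
        )[0]
        child = FormatSMVADSCTwoTheta(path)
        parent = FormatSMVADSC(path)
        assert child.get_detector() == parent.get_detector()
        assert child.get_beam() == parent.get_beam()
        assert child.get_goniometer() == parent.get_goniometer()

    def test_ninety_degrees_swings_origin_to_y(self, tmp_path):
        path = write_smv_sweep(
            small_spec(serial_number="926", two_theta=90.0, beam_centre=(0.0, 0.0),
                       distance=150.0),
            tmp_path / "t90",
        )[0]
        det = FormatSMVADSCTwoTheta(path).get_detector()
        assert det[0].origin == pytest.approx((0, 150, 0), abs=1e-9)

    def test_rotation_preserves_origin_norm(self, two_theta_file):
        child = FormatSMVADSCTwoTheta(two_theta_file).get_detector()
        parent = FormatSMVADSC(two_theta_file).get_detector()
        assert np.linalg.norm(child[0].origin) == pytest.approx(
            np.linalg.norm(parent[0].origin)
        )
        R = rotation_about_axis((1, 0, 0), -30.0)
        assert child[0].fast_axis == pytest.approx(R @ parent[0].fast_axis)
        assert child[0].slow_axis == pytest.approx(R @ parent[0].slow_axis)

    def test_missing_two_theta_key_rejected(self, tmp_path):
        path = write_smv_sweep(small_spec(serial_number="926"), tmp_path / "sn")[0]
        fmt = FormatSMVADSCTwoTheta(path)
        with pytest.raises(MissingMetadataError, match="TWOTHETA"):
            fmt.get_detector()


class TestHDF5:
    def test_image_count_and_models_match_smv(self, tmp_path):
        spec = small_spec(n_images=5, osc_width=0.5)
        smv = write_smv_sweep(spec, tmp_path / "smv")
        h5 = write_hdf5_stack(spec, tmp_path / "stack.h5")
        (beam, det, gonio, scan), n = hdf5_stack_models(h5)
        assert n == 5
        smv_fmt = FormatSMVADSC(smv[0])
        assert beam == smv_fmt.get_beam()
        assert det == smv_fmt.get_detector()
        assert gonio == smv_fmt.get_goniometer()
        assert scan.image_range == (1, 5)
        assert scan.osc_width == 0.5

    def test_resolves_to_stack_format(self, tmp_path):
        h5 = write_hdf5_stack(small_spec(), tmp_path / "stack.h5")
        assert fmts.global_registry.find_format_class(h5) is FormatHDF5Stack
        assert FormatHDF5Stack.multi_image

    def test_missing_geometry_group_rejected(self, tmp_path):
        import h5py

        h5 = write_hdf5_stack(small_spec(), tmp_path / "broken.h5")
        with h5py.File(h5, "a") as f:
            del f["geometry"]
        with pytest.raises(MalformedContainerError):
            hdf5_stack_models(h5)

    def test_smv_file_not_understood(self, adsc_file):
        assert not FormatHDF5Stack.understands(adsc_file)


class TestPluginDir:
    PLUGIN = """
from dxt.formats import FormatSMVADSC

class FormatSMVADSCLocal(FormatSMVADSC):
    format_name = "SMVADSCLocal"
    parent_format = FormatSMVADSC
    gated = ("555",)

    @classmethod
    def understands(cls, path):
        if not FormatSMVADSC.understands(path):
            return False
        return cls.read_header(path).get("DETECTOR_SN") in cls.gated
"""

    def test_plugin_loaded_and_resolves(self, tmp_path):
        plugin_dir = tmp_path / "plugins"
        plugin_dir.mkdir()
        (plugin_dir / "local_format.py").write_text(self.PLUGIN)
        (plugin_dir / "broken.py").write_text("raise RuntimeError('bad plugin')\n")
        reg = default_registry()
        loaded = reg.load_plugin_dir(plugin_dir)
        assert [cls.format_name for cls in loaded] == ["SMVADSCLocal"]
        path = write_smv_sweep(small_spec(serial_number="555"), tmp_path / "loc")[0]
        assert reg.find_format_class(path).format_name == "SMVADSCLocal"

    def test_missing_plugin_dir_is_not_fatal(self, tmp_path):
        reg = default_registry()
        assert reg.load_plugin_dir(tmp_path / "nope") == []
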