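"""Architecture construction: layer censuses, shape contracts, determinism."""

import numpy as np
import pytest

from nglseg.models import (MODEL_NAMES, ArchitectureSpec, SegmentationModel,
                           build_model, describe_architecture)

SMALL = dict(width_scale=0.0625)  # cheap networks for shape/determinism tests


class TestArchitectureAudit:
    def test_segnet_canonical_census(self):
        spec, _ = build_model("segnet", 3, seed=0)
        d = describe_architecture(spec)
        assert d["conv"] == 26 and d["mp"] == 5 and d["up"] == 5
        assert d["skip"] == 0 and d["pooling_depth"] == 5

    @pytest.mark.parametrize("name,depth,skips", [
        ("segnet", 5, 0), ("unet", 4, 4), ("3l_sn", 3, 0),
        ("3l_usn", 3, 3), ("2l_usn", 2, 2), ("2l_conv_usn", 2, 2),
    ])
    def test_pooling_depth_and_skip_census(self, name, depth, skips):
        spec, _ = build_model(name, 3, seed=0, **SMALL)
        d = describe_architecture(spec)
        assert d["pooling_depth"] == depth
        assert d["mp"] == d["up"] == depth
        assert d["skip"] == skips
        assert len(spec.skip_pairs) == skips
        assert d["out"] == 1
        # every convolution is followed by batch normalization
        assert d["bn"] == d["conv"]

    def test_skip_links_exactly_for_unet_variants(self):
        for name in MODEL_NAMES:
            spec, _ = build_model(name, 3, seed=0, **SMALL)
            expected = name in ("unet", "3l_usn", "2l_usn", "2l_conv_usn")
            assert bool(spec.skip_pairs) is expected

    def test_2l_conv_usn_adds_one_bottleneck_conv(self):
        d_plain = describe_architecture(build_model("2l_usn", 3, **SMALL)[0])
        d_conv = describe_architecture(build_model("2l_conv_usn", 3, **SMALL)[0])
        assert d_conv["conv"] == d_plain["conv"] + 1
        assert d_conv["mp"] == d_plain["mp"] and d_conv["skip"] == d_plain["skip"]

    def test_capacity_ordering_segnet_exceeds_shallow(self):
        _, segnet = build_model("segnet", 3, seed=0)
        _, shallow = build_model("3l_sn", 3, seed=0)
        assert segnet.n_parameters > shallow.n_parameters

    def test_describe_is_deterministic(self):
        a = describe_architecture(build_model("3l_usn", 3, seed=1)[0])
        b = describe_architecture(build_model("3l_usn", 3, seed=2)[0])
        assert a == b

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            build_model("4l_usn", 3)
        with pytest.raises(ValueError):
            build_model("segnet", input_channels=2)


class TestNetworkContracts:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    @pytest.mark.parametrize("size", [(64, 64), (128, 128)])
    def test_output_shape_matches_input(self, name, size):
        _, net = build_model(name, 3, seed=0, **SMALL)
        x = np.random.default_rng(0).random((1, *size, 3), dtype=np.float32)
        out = net.forward(x)
        assert out.shape == (1, *size)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_zero_input_scores_strictly_inside_unit_interval(self, name):
        _, net = build_model(name, 3, seed=0, **SMALL)
        out = net.forward(np.zeros((1, 64, 64, 3), dtype=np.float32))
        assert np.all(np.isfinite(out))
        assert np.all(out > 0) and np.all(out < 1)

    def test_same_seed_same_first_forward(self):
        x = np.random.default_rng(5).random((2, 32, 32, 3), dtype=np.float32)
        _, a = build_model("3l_usn", 3, seed=7, **SMALL)
        _, b = build_model("3l_usn", 3, seed=7, **SMALL)
        _, c = build_model("3l_usn", 3, seed=8, **SMALL)
        assert np.array_equal(a.forward(x), b.forward(x))
        assert not np.array_equal(a.forward(x), c.forward(x))

    def test_indivisible_spatial_dims_rejected(self):
        _, net = build_model("3l_usn", 3, seed=0, **SMALL)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 60, 64, 3), dtype=np.float32))

    def test_checkpoint_roundtrip(self, tmp_path):
        _, net = build_model("2l_usn", 3, seed=3, **SMALL)
        x = np.random.default_rng(1).random((1, 32, 32, 3), dtype=np.float32)
        before = net.forward(x)
        path = str(tmp_path / "model.npz")
        net.save(path)
        from nglseg.models import SegmentationNetwork
        loaded = SegmentationNetwork.load(path)
        assert np.array_equal(loaded.forward(x), before)
        assert loaded.spec.layer_sequence == net.spec.layer_sequence

    def test_spec_json_roundtrip(self):
        spec, _ = build_model("unet", 3, seed=0, **SMALL)
        again = ArchitectureSpec.from_json(spec.to_json())
        assert again == spec


class TestEstimator:
    def test_sklearn_param_interface(self):
        model = SegmentationModel(arch="2l_usn", beta=0.9)
        params = model.get_params()
        assert params["arch"] == "2l_usn" and params["beta"] == 0.9
        model.set_params(epochs=3)
        assert model.epochs == 3

    def test_fit_predict_shapes_and_range(self, rng):
        X = rng.random((6, 32, 32, 3), dtype=np.float32)
        y = (rng.random((6, 32, 32)) < 0.1).astype(np.uint8)
        model = SegmentationModel(arch="2l_usn", epochs=2, width_scale=0.0625,
                                  val_fraction=0.0, random_state=0)
        model.fit(X, y)
        proba = model.predict_proba(X)
        assert proba.shape == (6, 32, 32)
        assert np.all((proba > 0) & (proba < 1))
        assert set(np.unique(model.predict(X))) <= {0, 1}
        assert model.n_parameters_ == model.network_.n_parameters
        assert len(model.history_) == 2

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            SegmentationModel().predict_proba(np.zeros((1, 32, 32, 3)))
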