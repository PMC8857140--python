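"""Fixture shapes, configuration parsing, output writing, CLI plumbing."""

import json
import os

import numpy as np
import pytest

from biofilmosc.config import ConfigError, read_config
from biofilmosc.io import write_outputs
from biofilmosc.model2d import GeometryError, Grid2D
from biofilmosc.shapes import (disc, generate_fixture, polygon_from_csv,
                               three_biofilm_layout, wall_half_disc)


@pytest.fixture
def grid():
    return Grid2D(h=0.01)


class TestShapes:
    def test_disc_area_matches_analytic(self, grid):
        sh = disc(grid, radius=0.2)
        area = sh.mask.sum() * grid.h**2
        assert area == pytest.approx(np.pi * 0.2**2, rel=0.02)

    def test_wall_half_disc_touches_exactly_one_wall(self, grid):
        sh = wall_half_disc(grid, radius=0.3)
        assert sh.mask[0, :].any()          # bottom wall
        assert not sh.mask[-1, :].any()
        assert not sh.mask[:, 0].any() and not sh.mask[:, -1].any()

    def test_three_biofilm_layout_structure(self, grid):
        from scipy import ndimage
        shapes = three_biofilm_layout(grid)
        assert len(shapes) == 3
        combined = np.zeros(grid.shape, dtype=bool)
        for s in shapes:
            combined |= s.mask
        lab, n = ndimage.label(combined)
        assert n == 3
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=np.arange(1, 4))
        # the bottom component is the largest
        bottom_label = lab[lab[0 + 1, :] > 0]  # labels present near y=0
        bottom = np.unique(lab[1, :][lab[1, :] > 0])
        assert len(bottom) == 1
        assert sizes[bottom[0] - 1] == sizes.max()

    def test_generator_dispatch_and_unknown_name(self, grid):
        sh = generate_fixture("disc", grid, radius=0.1)
        assert sh.mask.any()
        with pytest.raises(GeometryError):
            generate_fixture("pentagon", grid)

    def test_oversized_shape_is_rejected(self, grid):
        with pytest.raises(GeometryError):
            disc(grid, radius=2.0)   # would cover the inlet column

    def test_polygon_rasterization(self, grid, tmp_path):
        path = tmp_path / "poly.csv"
        # a 0.4 x 0.4 square centered in the cell
        verts = [(1.3, 1.3), (1.7, 1.3), (1.7, 1.7), (1.3, 1.7)]
        path.write_text("\n".join(f"{x},{y}" for x, y in verts))
        sh = polygon_from_csv(str(path), grid)
        assert sh.mask.sum() * grid.h**2 == pytest.approx(0.16, rel=0.05)


class TestConfig:
    def test_empty_file_gives_full_defaults(self, tmp_path, p):
        f = tmp_path / "c.yaml"
        f.write_text("")
        cfg, params = read_config(str(f))
        assert cfg.mode == "simulate1d"
        assert params == p

    def test_u0_override_reaches_parameters(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text("params:\n  u0: 10\n")
        _, params = read_config(str(f))
        assert params.u0 == 10.0

    def test_wrong_case_parameter_names_nearest_key(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text("params:\n  delta_g: 10\n")
        with pytest.raises(ConfigError, match="delta_G"):
            read_config(str(f))

    def test_unknown_section_key_is_rejected(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text("run:\n  t_endh: 5\n")
        with pytest.raises(ConfigError, match="t_end"):
            read_config(str(f))

    def test_unknown_mode_is_rejected(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text("run:\n  mode: simulate4d\n")
        with pytest.raises(ConfigError):
            read_config(str(f))

    def test_seed_parsing(self, tmp_path):
        f = tmp_path / "c.yaml"
        f.write_text("seed: 42\n")
        cfg, _ = read_config(str(f))
        assert cfg.seed == 42


class TestWriteOutputs:
    def test_trace_and_metadata_roundtrip(self, tmp_path, p):
        from biofilmosc import run_1d
        tr = run_1d(0.1, p, 0.2)
        paths = write_outputs(tr, [], {"mode": "simulate1d"},
                              str(tmp_path / "out"), p, seed=7)
        assert os.path.exists(paths["trace"])
        meta = json.load(open(paths["config"]))
        assert meta["seed"] == 7
        assert meta["params_paper_units"]["D_K"] == pytest.approx(0.497)

    def test_rerun_is_bit_identical(self, tmp_path, p):
        import hashlib
        from biofilmosc import run_1d
        sums = []
        for d in ("a", "b"):
            tr = run_1d(0.1, p, 0.5, seed=3)
            paths = write_outputs(tr, [], {}, str(tmp_path / d), p, seed=3)
            sums.append(hashlib.sha256(
                open(paths["trace"], "rb").read()).hexdigest())
        assert sums[0] == sums[1]

    def test_empty_trace_writes_header_only(self, tmp_path, p):
        from biofilmosc.model1d import OscillationTrace
        empty = OscillationTrace(*[np.array([])] * 9)
        paths = write_outputs(empty, [], {}, str(tmp_path / "e"))
        lines = open(paths["trace"]).read().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("time_h")

    def test_snapshot_hdf5_contents(self, tmp_path, p):
        import h5py
        from biofilmosc import run_1d
        tr, snaps = run_1d(0.1, p, 0.2, snapshot_every_h=0.1)
        paths = write_outputs(tr, snaps, {}, str(tmp_path / "s"))
        with h5py.File(paths["snapshots"]) as f:
            assert "t_0" in f and "x" in f["t_0"]
            assert f["t_0"].attrs["time_h"] == 0.0


class TestCli:
    def test_simulate1d_writes_outputs(self, tmp_path):
        from click.testing import CliRunner
        from biofilmosc.cli import main
        r = CliRunner().invoke(main, [
            "simulate1d", "--width-um", "100", "--t-end", "0.2",
            "--seed", "1", "--out", str(tmp_path / "o")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "o" / "trace.csv").exists()

    def test_param_override_and_bad_value(self, tmp_path):
        from click.testing import CliRunner
        from biofilmosc.cli import main
        r = CliRunner().invoke(main, [
            "simulate1d", "--param", "G0=oops", "--t-end", "0.1",
            "--out", str(tmp_path / "o")])
        assert r.exit_code == 2

    def test_unknown_subcommand_exits_2(self):
        from click.testing import CliRunner
        from biofilmosc.cli import main
        r = CliRunner().invoke(main, ["simulate9d"])
        assert r.exit_code == 2

    def test_sensitivity_single_target(self, tmp_path):
        from click.testing import CliRunner
        from biofilmosc.cli import main
        r = CliRunner().invoke(main, [
            "sensitivity", "--target", "V_th", "--out",
            str(tmp_path / "s")])
        assert r.exit_code == 0, r.output
        out = (tmp_path / "s" / "sensitivity.csv").read_text()
        assert "V_th" in out
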