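"""Synthetic generator: membrane surface, PIP2 sorting, protein walks, GRO."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

from curvsense import (GeneratorConfig, boltzmann_radial_occupancy,
                       generate_membrane_frame, generate_membrane_frames,
                       generate_protein_trace, radial_energy, read_gro,
                       surface_height, write_gro)
from curvsense.config import ProteinSpec
from curvsense.errors import InvalidConfigError
from curvsense.frames import BeadFrame
from curvsense.geometry import circle_rect_area
from curvsense.synthetic import _rng, local_curvature

from conftest import DEFAULT_PARAMS


class TestSurfaceHeight:
    def test_flat_limit_d_zero(self):
        # d = 0 collapses the sigmoid to the constant inner plateau
        h = surface_height(np.array([0.0, 3.0, 12.0, 25.0]),
                           (15.0, 0.527, 11.0, 0.0, 8.5))
        assert np.allclose(h, 11.0, atol=1e-12)

    def test_asymptotic_plateau_matches_symbolic_limit(self):
        # oracle: sympy limit of the model expression as r -> oo
        import sympy as sp

        r, a, b, c, d, x0 = sp.symbols("r a b c d x0", positive=True)
        expr = a + (c - a) / (1 + sp.exp(b * (r - x0))) ** d
        lim = sp.limit(expr.subs({a: 15, b: 0.527, c: 11, d: 1, x0: 8.5}),
                       r, sp.oo)
        assert float(lim) == pytest.approx(15.0)
        assert surface_height(1e6, DEFAULT_PARAMS) == pytest.approx(float(lim),
                                                                    abs=1e-9)

    def test_height_at_x0_is_plateau_midpoint(self):
        # closed form at r = x0 for the symmetric (d = 1) shape
        a, _, c, _, x0 = DEFAULT_PARAMS
        assert surface_height(x0, DEFAULT_PARAMS) == pytest.approx(
            0.5 * (a + c), abs=1e-12)

    def test_monotone_between_asymptotes(self):
        r = np.linspace(0.0, 30.0, 400)
        h = surface_height(r, DEFAULT_PARAMS)
        assert np.all(np.diff(h) > 0)

    def test_nonfinite_params_rejected(self):
        with pytest.raises(InvalidConfigError):
            surface_height(1.0, (np.nan, 1, 1, 1, 1))
        with pytest.raises(InvalidConfigError):
            surface_height(-1.0, DEFAULT_PARAMS)


class TestMembraneFrame:
    def test_headgroups_sit_on_surface(self, gen_config, membrane_frames):
        fr = membrane_frames[0]
        sel = (fr.species == "PC_head") & (fr.leaflet == "top")
        pos = fr.positions[sel]
        r = np.hypot(pos[:, 0] - 16, pos[:, 1] - 20)
        resid = pos[:, 2] - surface_height(r, gen_config.profile_params)
        assert abs(np.mean(resid)) < 0.05
        assert np.std(resid) == pytest.approx(gen_config.noise_sigma, rel=0.15)

    def test_pip2_top_leaflet_only(self, membrane_frames):
        for fr in membrane_frames:
            pip2 = fr.species == "PIP2_head"
            assert pip2.sum() > 0
            assert np.all(fr.leaflet[pip2] == "top")

    def test_pip2_count_binomial(self):
        # 4000 lipid sites at 2.5% -> 100 +/- 3 binomial SDs
        cfg = GeneratorConfig(n_pc=3900, pip2_fraction=0.025, seed=5)
        assert cfg.n_lipids == 4000
        counts = [int(np.sum(generate_membrane_frame(cfg, rng=_rng(5, 0, t)).species
                             == "PIP2_head")) for t in range(4)]
        sd = np.sqrt(4000 * 0.025 * 0.975)
        for c in counts:
            assert abs(c - 100) <= 3 * sd

    def test_pip2_uniform_without_sorting(self):
        # weight 0: chi-square over 20 equal-area annuli must not reject
        cfg = GeneratorConfig(n_pc=4875, pip2_fraction=0.025,
                              pip2_curvature_weight=0.0, seed=7, n_frames=1)
        assert cfg.n_lipids == 5000
        pos = np.vstack([generate_membrane_frame(cfg, rng=_rng(7, 0, t)
                                                 ).select("PIP2_head")
                         for t in range(8)])
        r = np.hypot(pos[:, 0] - 16, pos[:, 1] - 20)
        # equal clipped-area radial edges over the whole box
        rect = (0.0, 32.0, 0.0, 40.0)
        total = 32.0 * 40.0
        edges = [0.0]
        for k in range(1, 20):
            target = total * k / 20
            lo, hi = 0.0, 26.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if circle_rect_area((16, 20), mid, rect) < target:
                    lo = mid
                else:
                    hi = mid
            edges.append(0.5 * (lo + hi))
        edges.append(26.0)
        counts, _ = np.histogram(r, edges)
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01

    def test_pip2_enriched_at_concave(self, gen_config, membrane_frames):
        # concave band lies at smaller r, so sorted PIP2 sits closer in
        fr = membrane_frames[0]
        r_pip2 = np.hypot(*(fr.select("PIP2_head")[:, :2] - (16, 20)).T)
        pc = fr.positions[(fr.species == "PC_head") & (fr.leaflet == "top")]
        r_pc = np.hypot(pc[:, 0] - 16, pc[:, 1] - 20)
        assert np.mean(r_pip2) < np.mean(r_pc)

    def test_pip2_sorting_monotonic_in_weight(self):
        # common random numbers: concave-region PIP2 fraction never decreases
        fractions = []
        for w in (0.0, 4.0, 8.0, 12.0, 16.0):
            cfg = GeneratorConfig(pip2_curvature_weight=w, seed=3)
            fr = generate_membrane_frame(cfg, rng=_rng(3, 0, 0))
            pos = fr.select("PIP2_head")
            r = np.hypot(pos[:, 0] - 16, pos[:, 1] - 20)
            k = local_curvature(r, cfg)
            fractions.append(np.mean(k > 0.01))   # concave-region fraction
        assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] > fractions[0]

    def test_zero_lipids_with_pip2_rejected(self):
        with pytest.raises(InvalidConfigError):
            GeneratorConfig(n_pc=0, pip2_fraction=0.025).validate()

    def test_determinism_bitwise(self, gen_config):
        a = generate_membrane_frames(gen_config)
        b = generate_membrane_frames(gen_config)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.positions, fb.positions)
            assert np.array_equal(fa.species, fb.species)


class TestProteinTrace:
    def test_uniform_occupancy_when_weights_zero(self, pc_only_config):
        # free diffusion: occupancy matches the area-proportional (uniform)
        # Boltzmann occupancy; assert TV distance plus the bulk RDF property
        # on bins with enough statistics for a sound 5-sigma check
        cfg = dataclasses.replace(
            pc_only_config, protein=ProteinSpec(w_hydro=0.0, w_pip2=0.0))
        energy = radial_energy(cfg)
        assert np.allclose(energy.U, 0.0)
        rs = []
        for rep in range(8):
            tr = generate_protein_trace(cfg, energy, replica_id=rep,
                                        n_steps=10_000)
            rs.append(np.hypot(tr.frames[:, 1] - 16, tr.frames[:, 2] - 20))
        r = np.concatenate(rs)
        edges = np.linspace(0, 25, 101)
        counts, _ = np.histogram(r, edges)
        occ = boltzmann_radial_occupancy(energy, cfg, edges)
        emp = counts / counts.sum()
        tv = 0.5 * np.abs(emp - occ).sum()
        assert tv < 0.1
        expected = counts.sum() * occ
        good = expected >= 1500
        rdf = counts[good] / expected[good]
        assert np.all(np.abs(rdf - 1) < 0.15)

    def test_convex_seeker_peaks_in_convex_band(self, pc_only_config):
        cfg = dataclasses.replace(pc_only_config,
                                  protein=ProteinSpec.preset("full"))
        energy = radial_energy(cfg)
        tr = generate_protein_trace(cfg, energy, n_steps=20_000)
        r = np.hypot(tr.frames[:, 1] - 16, tr.frames[:, 2] - 20)
        # oracle: direct Boltzmann occupancy argmax on the same grid
        edges = np.linspace(0, 25, 101)
        occ = boltzmann_radial_occupancy(energy, cfg, edges)
        counts, _ = np.histogram(r, edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        assert abs(mids[np.argmax(counts)] - mids[np.argmax(occ)]) < 1.0
        k = local_curvature(mids[np.argmax(counts)], cfg)
        assert k < -0.01    # convex by the package sign convention

    def test_pip2_seeker_peaks_in_concave_band(self, gen_config,
                                               membrane_frames):
        cfg = dataclasses.replace(
            gen_config, protein=ProteinSpec(w_hydro=0.0, w_pip2=6.0))
        energy = radial_energy(cfg, frames=membrane_frames)
        tr = generate_protein_trace(cfg, energy, n_steps=20_000)
        r = np.hypot(tr.frames[:, 1] - 16, tr.frames[:, 2] - 20)
        edges = np.linspace(0, 25, 101)
        counts, _ = np.histogram(r, edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        peak_r = mids[np.argmax(counts)]
        assert local_curvature(peak_r, cfg) > 0.01   # concave
        occ = boltzmann_radial_occupancy(energy, cfg, edges)
        assert abs(peak_r - mids[np.argmax(occ)]) < 1.5

    def test_negative_weights_rejected(self, gen_config):
        cfg = dataclasses.replace(gen_config,
                                  protein=ProteinSpec(w_hydro=-1.0))
        with pytest.raises(InvalidConfigError):
            radial_energy(cfg)

    def test_trace_determinism(self, pc_only_config):
        energy = radial_energy(pc_only_config)
        a = generate_protein_trace(pc_only_config, energy, n_steps=500)
        b = generate_protein_trace(pc_only_config, energy, n_steps=500)
        assert np.array_equal(a.frames, b.frames)

    def test_occupancy_equivalence_total_variation(self, pc_only_config):
        # Metropolis chain vs direct Boltzmann summation on the radial grid
        cfg = dataclasses.replace(pc_only_config,
                                  protein=ProteinSpec.preset("split"))
        energy = radial_energy(cfg)
        tr = generate_protein_trace(cfg, energy, n_steps=100_000,
                                    burn_in=5000)
        r = np.hypot(tr.frames[:, 1] - 16, tr.frames[:, 2] - 20)
        edges = np.linspace(0, 25, 101)
        counts, _ = np.histogram(r, edges)
        occ = boltzmann_radial_occupancy(energy, cfg, edges)
        tv = 0.5 * np.abs(counts / counts.sum() - occ).sum()
        assert tv < 0.1


class TestGroRoundTrip:
    def test_single_bead(self, tmp_path):
        fr = BeadFrame(positions=[[1.0, 2.0, 3.0]], species=["PC_head"],
                       leaflet=["top"], residue_index=[-1],
                       box=(32.0, 40.0, 33.0))
        path = write_gro(fr, tmp_path / "one.gro")
        text = path.read_text().splitlines()
        assert text[1].strip() == "1"
        assert len(text) == 4
        back = read_gro(path)
        assert back.box == pytest.approx((32.0, 40.0, 33.0))

    def test_round_trip_positions_to_gro_precision(self, gen_config,
                                                   membrane_frames, tmp_path):
        fr = membrane_frames[0]
        sub = BeadFrame(fr.positions[:1000], fr.species[:1000],
                        fr.leaflet[:1000], fr.residue_index[:1000], fr.box)
        back = read_gro(write_gro(sub, tmp_path / "f.gro"))
        # 0.0005 nm is the GRO 3-decimal rounding bound; the reader stores
        # float32 internally which adds ~coordinate * 2^-23 on top
        float32_eps = np.abs(sub.positions).max() * 2.0 ** -22
        assert np.abs(back.positions - sub.positions).max() \
            <= 0.0005 + float32_eps
        assert np.array_equal(back.species, sub.species)
        assert np.array_equal(back.leaflet, sub.leaflet)

    def test_independent_reader_sees_distinct_resnames(self, gen_config,
                                                       membrane_frames,
                                                       tmp_path):
        # MDAnalysis acts as the independent GRO parser for the hand writer
        import MDAnalysis as mda

        from curvsense import plant_protein_beads

        fr = plant_protein_beads(gen_config, membrane_frames[0])
        path = write_gro(fr, tmp_path / "p.gro",
                         sequence=gen_config.protein.sequence)
        u = mda.Universe(str(path))
        names = set(u.atoms.resnames)
        assert {"DOPC", "POP2"} <= names
        assert {"LEU", "ILE", "VAL", "TYR", "MET"} <= names
        assert len(u.atoms) == len(fr)
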