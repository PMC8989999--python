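"""Generator contracts: determinism, degenerate cases, convergence to spec."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acidhet import synthesize as syn
from acidhet.phylo import jc_distance, p_distance
from acidhet.synthesize import _rod_mask


def const_channel(name, loc, **kw):
    return syn.ChannelSpec(name, on_fraction=1.0, family="normal",
                           loc=loc, scale=0.0, **kw)


class TestSimulatePopulation:
    def test_degenerate_noiseless_case(self):
        spec = syn.PopulationSpec(channels=[const_channel("gfp", 100.0)],
                                  cells_per_field=20, seed=1)
        df = syn.simulate_population(spec)
        assert np.all(df["gfp_raw"] == 100.0)
        assert np.all(df["gfp_true"] == 100.0)

    def test_background_only(self):
        channels = [syn.ChannelSpec("gfp", on_fraction=0.0, off_level=0.0)]
        spec = syn.PopulationSpec(channels=channels, background_mean=5.0,
                                  background_sd=0.0, cells_per_field=20, seed=1)
        df = syn.simulate_population(spec)
        assert np.all(df["gfp_raw"] == 5.0)

    def test_bleed_through_arithmetic(self):
        # measured GFP = 50 + 0.456 * 200 = 141.2
        channels = [const_channel("gfp", 50.0), const_channel("cfp", 200.0)]
        bleed = np.array([[0.0, 0.456], [0.0, 0.0]])
        spec = syn.PopulationSpec(channels=channels, bleed=bleed,
                                  cells_per_field=10, seed=0)
        df = syn.simulate_population(spec)
        assert np.allclose(df["gfp_raw"], 141.2)
        assert np.allclose(df["cfp_raw"], 200.0)

    def test_determinism(self, three_channel_spec):
        a = syn.simulate_population(three_channel_spec)
        b = syn.simulate_population(three_channel_spec)
        pd.testing.assert_frame_equal(a, b)

    def test_on_fraction_converges(self):
        spec = syn.PopulationSpec(
            channels=[syn.ChannelSpec("gfp", on_fraction=0.83, loc=200.0,
                                      scale=20.0)],
            cells_per_field=4000, seed=3)
        df = syn.simulate_population(spec)
        frac = df["gfp_on"].mean()
        lo, hi = stats.binom.interval(0.999, 4000, 0.83)
        assert lo / 4000 <= frac <= hi / 4000

    def test_latent_correlation_recovered(self):
        corr = np.array([[1.0, 0.45], [0.45, 1.0]])
        channels = [syn.ChannelSpec("a", loc=100, scale=10),
                    syn.ChannelSpec("b", loc=100, scale=10)]
        spec = syn.PopulationSpec(channels=channels, correlation=corr,
                                  cells_per_field=1000, seed=5)
        df = syn.simulate_population(spec)
        r = np.corrcoef(df["a_true"], df["b_true"])[0, 1]
        assert abs(r - 0.45) < 0.08  # ~3x sampling sd at n=1000

    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="semi-definite"):
            syn.PopulationSpec(channels=[syn.ChannelSpec("a"),
                                         syn.ChannelSpec("b")],
                               correlation=bad)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            syn.ChannelSpec("a", scale=-1.0)
        with pytest.raises(ValueError):
            syn.PopulationSpec(channels=[syn.ChannelSpec("a")],
                               background_sd=-1.0)


class TestSimulateImages:
    def test_planted_rod_count(self):
        spec = syn.ImageSpec(n_cells=5, noise_model="none", psf_sigma=0.0,
                             seed=2)
        image, truth = syn.simulate_images(spec)
        binary = image > (spec.background_intensity + spec.cell_intensity) / 2
        from scipy import ndimage
        _, n = ndimage.label(binary)
        assert n == 5
        assert len(truth) == 5

    def test_rod_bounding_box(self):
        # 3 um x 0.8 um rod at 0.1 um/px -> 30 x 8 px (+/- 1 px cap rounding)
        mask = _rod_mask((100, 100), cx=50.0, cy=50.0, length_px=30.0,
                         width_px=8.0, theta=0.0)
        rows = np.any(mask, axis=1).sum()
        cols = np.any(mask, axis=0).sum()
        assert abs(cols - 30) <= 1
        assert abs(rows - 8) <= 1

    def test_byte_identical_rerun(self):
        spec = syn.ImageSpec(n_cells=8, noise_model="poisson", seed=11)
        img1, t1 = syn.simulate_images(spec)
        img2, t2 = syn.simulate_images(spec)
        assert img1.tobytes() == img2.tobytes()
        pd.testing.assert_frame_equal(t1, t2)

    def test_overcrowded_request_errors(self):
        spec = syn.ImageSpec(image_size=(64, 64), n_cells=100,
                             max_placement_tries=10, seed=0)
        with pytest.raises(RuntimeError, match="without overlap"):
            syn.simulate_images(spec)


class TestPresenceTable:
    @pytest.mark.parametrize("prob,expected", [(1.0, 100.0), (0.0, 0.0)])
    def test_deterministic_probabilities(self, prob, expected):
        spec = syn.CooccurSpec(n_species=50, regulator_probs={"CadA": prob},
                               seed=0)
        table = syn.simulate_presence_table(spec)
        assert 100.0 * table["CadA"].mean() == expected

    def test_empirical_fraction_within_binomial_ci(self):
        spec = syn.CooccurSpec(n_species=1000,
                               regulator_probs={"CadA": 0.943}, seed=4)
        table = syn.simulate_presence_table(spec)
        lo, hi = stats.binom.interval(0.99, 1000, 0.943)
        assert lo <= table["CadA"].sum() <= hi

    def test_anchor_always_present(self):
        table = syn.simulate_presence_table(syn.CooccurSpec(n_species=10))
        assert (table["CadB"] == 1).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            syn.CooccurSpec(regulator_probs={"CadA": 1.5})


class TestEvolveAlignment:
    NEWICK4 = "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);"

    def test_zero_branch_lengths_identical(self):
        spec = syn.TreeSimSpec(tree="((A:0,B:0):0,(C:0,D:0):0);",
                               seq_length=100, seed=1)
        seqs = syn.evolve_alignment(spec)
        assert len(set(seqs.values())) == 1

    def test_saturation_p_distance(self):
        # at d = 10 the chain is at stationarity: mismatch prob (a-1)/a = 0.75
        spec = syn.TreeSimSpec(tree="(A:5,B:5,C:5);", seq_length=10000,
                               alphabet=syn.NUCLEOTIDE_ALPHABET, seed=2)
        seqs = syn.evolve_alignment(spec)
        assert abs(p_distance(seqs["A"], seqs["B"]) - 0.75) < 0.02

    def test_deterministic_output(self):
        spec = syn.TreeSimSpec(tree=self.NEWICK4, seq_length=200, seed=9)
        assert syn.evolve_alignment(spec) == syn.evolve_alignment(spec)

    def test_jc_corrected_distance_recovers_path_length(self):
        # two leaves separated by path length 0.3; JC inverts the model,
        # so the corrected distance is consistent at large L
        spec = syn.TreeSimSpec(tree="(A:0.15,B:0.15,C:0.15);",
                               seq_length=10000, seed=6)
        seqs = syn.evolve_alignment(spec)
        p = p_distance(seqs["A"], seqs["B"])
        d = jc_distance(p, 4)
        # delta-method SE of the JC estimate
        se = np.sqrt(p * (1 - p) / 10000) / (1 - 4 / 3 * p)
        assert abs(d - 0.3) < 3 * se

    def test_protein_alphabet(self):
        spec = syn.TreeSimSpec(tree=self.NEWICK4, seq_length=300,
                               alphabet=syn.PROTEIN_ALPHABET, seed=3)
        seqs = syn.evolve_alignment(spec)
        assert all(len(s) == 300 for s in seqs.values())
        assert set("".join(seqs.values())) <= set(syn.PROTEIN_ALPHABET)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError, match="3 leaves"):
            syn.evolve_alignment(syn.TreeSimSpec(tree="(A:1,B:1);",
                                                 seq_length=10))
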