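"""The fermentation generator: environment, succession, reads, gene content,
dye phenotype, and the planted ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import indigoferm as ig
from indigoferm.synthetic_data import (BatchSpec, CausalFunctionModel,
                                       EnvDynamicsParams, FermentationDesign,
                                       assign_genome_content, emit_dye_series,
                                       sample_reads, simulate_community,
                                       simulate_environment)

_LOGISTIC = lambda z: 1.0 / (1.0 + np.exp(-z))


def _design(**kw):
    base = dict(batches=(BatchSpec("B1", 25.0, 10.0),),
                sampling_days=(1, 2, 3, 4, 5), read_depth_range=(1000, 2000))
    base.update(kw)
    return FermentationDesign(**base)


def _taxon(tid="T1", **kw):
    base = dict(oxygen_class="facultative", ph_optimum=10.0, ph_width=0.8,
                orp_midpoint=-200.0, orp_direction="prefers_low",
                substrate_affinity={"labile": 0.5, "dead_cells": 0.5, "bran": 0.5},
                baseline_fitness=0.0, indigo_reducer=False)
    base.update(kw)
    return ig.TaxonSpec(taxon_id=tid, **base)


# --- environment -----------------------------------------------------------

def test_ph_stays_within_maintenance_band():
    envs = simulate_environment(_design(sampling_days=tuple(range(1, 210))), seed=3)
    ph = envs[0].records["ph"]
    assert ph.min() >= 9.67 - 0.3 and ph.max() <= 11.2 + 0.3
    # the vat never dwells below the floor: the reset happens the same day
    assert (ph >= 9.67).all()


def test_caoh2_resets_toward_ceiling():
    envs = simulate_environment(_design(sampling_days=tuple(range(1, 60))),
                                EnvDynamicsParams(ph_noise_sd=0.0), seed=0)
    rec = envs[0].records
    resets = rec.index[rec["caoh2_added"]]
    assert len(resets) > 0
    assert np.allclose(rec.loc[resets, "ph"], 11.2)


def test_bran_pulse_then_strict_decay():
    envs = simulate_environment(
        _design(bran_days=(5,), sampling_days=tuple(range(1, 21))), seed=1)
    bran = envs[0].records["bran"]
    assert bran.loc[5] == pytest.approx(1.0)  # no pre-pulse residue
    assert (np.diff(bran.loc[6:20]) < 0).all()
    assert (bran.loc[:4] == 0).all()


def test_zero_dynamics_ph_constant():
    params = EnvDynamicsParams(acid_rate=0.0, ph_noise_sd=0.0)
    envs = simulate_environment(_design(), params, seed=0)
    assert np.allclose(envs[0].records["ph"], 10.0)
    assert not envs[0].records["caoh2_added"].any()


def test_orp_declines_to_negative_plateau():
    envs = simulate_environment(_design(sampling_days=tuple(range(1, 30))),
                                EnvDynamicsParams(orp_noise_sd=0.0), seed=0)
    orp = envs[0].records["orp"]
    assert orp.iloc[0] > 0
    assert (np.diff(orp) <= 0).all()
    assert orp.iloc[-1] == pytest.approx(-550.0, abs=1.0)


def test_non_finite_params_rejected_by_name():
    with pytest.raises(ValueError, match="acid_rate"):
        EnvDynamicsParams(acid_rate=float("nan"))


# --- community succession --------------------------------------------------

def test_identical_taxa_stay_identical():
    taxa = [_taxon("T1"), _taxon("T2")]
    env = simulate_environment(_design(), EnvDynamicsParams(), seed=0)[0]
    traj = simulate_community(
        taxa, env, seed=0,
        params=EnvDynamicsParams(growth_noise_sd=0.0))
    assert np.allclose(traj.loc["T1"], traj.loc["T2"])
    assert np.allclose(traj.loc["T1"], 0.5)


def test_single_taxon_pinned_at_one():
    env = simulate_environment(_design(), seed=0)[0]
    traj = simulate_community([_taxon()], env, seed=0)
    assert np.allclose(traj.to_numpy(), 1.0)


def test_rows_sum_to_one():
    taxa = ig.default_taxa(15, seed=2)
    env = simulate_environment(_design(), seed=2)[0]
    traj = simulate_community(taxa, env, seed=2)
    assert np.allclose(traj.sum(axis=0), 1.0, atol=1e-9)


def test_all_zero_init_rejected():
    env = simulate_environment(_design(), seed=0)[0]
    with pytest.raises(ValueError):
        simulate_community([_taxon("T1"), _taxon("T2")], env, seed=0,
                           init_abundance=[0.0, 0.0])


def test_anaerobe_overtakes_aerobe_as_orp_falls():
    """Aerobe (prefers high ORP) vs obligate anaerobe (prefers low), all else
    equal: once ORP crosses their shared midpoint the anaerobe's share never
    decreases.  Verified against a step-by-step hand evaluation of the
    multiplicative update."""
    shared = dict(ph_optimum=10.0, ph_width=0.8, orp_midpoint=-200.0,
                  substrate_affinity={"labile": 0.3, "dead_cells": 0.3, "bran": 0.3},
                  baseline_fitness=0.0)
    aerobe = ig.TaxonSpec("aer", oxygen_class="aerobe",
                          orp_direction="prefers_high", **shared)
    anaerobe = ig.TaxonSpec("ana", oxygen_class="obligate_anaerobe",
                            orp_direction="prefers_low", **shared)
    # density_penalty kept gentle: the point is the ORP mechanism, and a steep
    # self-crowding slope adds discrete-time overshoot oscillations on top
    params = EnvDynamicsParams(growth_noise_sd=0.0, orp_noise_sd=0.0,
                               ph_noise_sd=0.0, density_penalty=1.0)
    env = simulate_environment(_design(sampling_days=tuple(range(1, 15))),
                               params, seed=0)[0]
    traj = simulate_community([aerobe, anaerobe], env, seed=0, params=params)
    days = env.records.index.to_numpy()
    crossover = days[env.records["orp"].to_numpy() < -200.0][0]
    ana = traj.loc["ana", crossover:]
    assert (np.diff(ana) >= -1e-12).all()

    # hand evaluation of the update rule, day by day
    x = np.array([0.5, 0.5])
    hand = []
    for day in days:
        rec = env.records.loc[day]
        pools = np.array([rec["labile"], rec["dead_cells"], rec["bran"]])
        shared_term = (params.ph_kernel_scale
                       * np.exp(-0.5 * ((rec["ph"] - 10.0) / 0.8) ** 2)
                       + params.substrate_scale * 0.3 * pools.sum())
        f_aer = shared_term + params.orp_kernel_scale * _LOGISTIC(
            (rec["orp"] + 200.0) / params.orp_kernel_width) - params.density_penalty * x[0]
        f_ana = shared_term + params.orp_kernel_scale * _LOGISTIC(
            -(rec["orp"] + 200.0) / params.orp_kernel_width) - params.density_penalty * x[1]
        x = x * np.exp([f_aer, f_ana])
        x = x / x.sum()
        hand.append(x.copy())
    hand = np.array(hand).T
    assert np.allclose(traj.to_numpy(), hand, atol=1e-12)


# --- read sampling ---------------------------------------------------------

def test_counts_sum_to_depths_exactly():
    traj = pd.DataFrame({1: [0.5, 0.5], 2: [0.9, 0.1]}, index=["TA", "TB"])
    counts = sample_reads(traj, [8825, 4000], seed=1)
    assert counts.sum(axis=0).tolist() == [8825, 4000]


def test_degenerate_proportions():
    traj = pd.DataFrame({1: [1.0, 0.0, 0.0]}, index=["TA", "TB", "TC"])
    counts = sample_reads(traj, [500], seed=0)
    assert counts[1].tolist() == [500, 0, 0]


def test_multinomial_mean_matches_binomial_oracle():
    reps = 10_000
    traj = pd.DataFrame(np.tile([[0.7], [0.3]], (1, reps)),
                        index=["TA", "TB"], columns=range(reps))
    counts = sample_reads(traj, [100] * reps, seed=9)
    se = np.sqrt(100 * 0.7 * 0.3 / reps)
    assert abs(counts.loc["TA"].mean() - 70.0) < 3 * se


def test_negative_proportion_rejected():
    traj = pd.DataFrame({1: [1.2, -0.2]}, index=["TA", "TB"])
    with pytest.raises(ValueError):
        sample_reads(traj, [100], seed=0)


# --- genome content --------------------------------------------------------

def test_causal_columns_enriched_in_reducers():
    taxa = ig.default_taxa(20, seed=4)
    n_red = sum(t.indigo_reducer for t in taxa)
    assert n_red >= 2
    causal = ig.CausalFunctionModel(causal_kos=frozenset(
        {"K00296", "K00297", "K00298", "K00299", "K00300"}))
    genome = assign_genome_content(taxa, 300, causal, seed=4)
    red = [t.taxon_id for t in taxa if t.indigo_reducer]
    non = [t.taxon_id for t in taxa if not t.indigo_reducer]
    for ko in sorted(causal.causal_kos):
        assert genome.copies.loc[red, ko].mean() > genome.copies.loc[non, ko].mean()
    assert (genome.copies.to_numpy() >= 0).all()
    assert genome.copies.shape == (20, 300)


def test_empty_causal_set_allowed():
    taxa = [_taxon("T1"), _taxon("T2")]
    genome = assign_genome_content(
        taxa, 10, ig.CausalFunctionModel(causal_kos=frozenset()), seed=0)
    assert (genome.copies.to_numpy() >= 0).all()


def test_causal_without_reducers_rejected():
    taxa = [_taxon("T1"), _taxon("T2")]
    causal = ig.CausalFunctionModel(causal_kos=frozenset({"K00001"}))
    with pytest.raises(ValueError):
        assign_genome_content(taxa, 10, causal, seed=0)


# --- dye series ------------------------------------------------------------

def test_zero_signal_closed_form():
    taxon = _taxon("T1")
    traj = pd.DataFrame({d: [1.0] for d in range(1, 6)}, index=["T1"])
    genome = ig.GenomeContent(copies=pd.DataFrame({"K00001": [0.0]}, index=["T1"]))
    model = CausalFunctionModel(causal_kos=frozenset({"K00001"}), noise_sd=0.0)
    dye = emit_dye_series(traj, genome, model, seed=0)
    expect = model.baseline + (model.saturation - model.baseline) * 0.5
    assert np.allclose(dye["intensity"], expect)


def test_lab_norm_reproduces_intensity():
    ds = ig.simulate_dataset(design=FermentationDesign(
        batches=(BatchSpec("B1", 25.0, 10.0),), sampling_days=(1, 2, 3),
        read_depth_range=(1000, 2000)), taxa=ig.default_taxa(10, seed=0),
        n_kos=50, seed=0)
    norms = np.sqrt(ds.dye_series["L"] ** 2 + ds.dye_series["a"] ** 2
                    + ds.dye_series["b"] ** 2)
    assert np.allclose(norms, ds.dye_series["intensity"], atol=1e-6)
    assert (ds.dye_series["b"] <= 0).all()  # blue direction


def test_noise_free_intensity_monotone_in_signal():
    traj = pd.DataFrame({d: [d / 10.0, 1 - d / 10.0] for d in range(1, 8)},
                        index=["red", "other"])
    genome = ig.GenomeContent(copies=pd.DataFrame(
        {"K00001": [6.0, 0.0]}, index=["red", "other"]))
    model = CausalFunctionModel(causal_kos=frozenset({"K00001"}), noise_sd=0.0)
    dye = emit_dye_series(traj, genome, model, seed=0)
    assert (np.diff(dye["intensity"]) > 0).all()


# --- whole datasets --------------------------------------------------------

def test_dataset_determinism(small_design):
    a = ig.simulate_dataset(design=small_design, taxa=ig.default_taxa(12, seed=3),
                            n_kos=60, seed=3)
    b = ig.simulate_dataset(design=small_design, taxa=ig.default_taxa(12, seed=3),
                            n_kos=60, seed=3)
    pd.testing.assert_frame_equal(a.feature_table.counts, b.feature_table.counts)
    pd.testing.assert_frame_equal(a.dye_series, b.dye_series)
    pd.testing.assert_frame_equal(a.genome_content.copies, b.genome_content.copies)


def test_adding_a_batch_preserves_existing_ones():
    """Per-batch RNG substreams: batch B1's data are unchanged when another
    batch joins the design."""
    d1 = FermentationDesign(batches=(BatchSpec("B1", 25.0, 10.0),),
                            sampling_days=(1, 2, 3), read_depth_range=(1000, 2000))
    d2 = FermentationDesign(batches=(BatchSpec("B1", 25.0, 10.0),
                                     BatchSpec("B9", 60.0, 10.7)),
                            sampling_days=(1, 2, 3), read_depth_range=(1000, 2000))
    taxa = ig.default_taxa(8, seed=1)
    a = ig.simulate_dataset(design=d1, taxa=taxa, n_kos=30, seed=1)
    b = ig.simulate_dataset(design=d2, taxa=taxa, n_kos=30, seed=1)
    cols = a.feature_table.counts.columns
    pd.testing.assert_frame_equal(a.feature_table.counts,
                                  b.feature_table.counts[cols])


def test_dataset_cross_references(small_dataset):
    ds = small_dataset
    for sample in ds.feature_table.samples:
        assert sample in ds.dye_series.index
    assert ds.truth["causal_kos"] <= set(ds.genome_content.kos)
    # causal KOs are annotated as NAD(P)-dependent EC 1.* oxidoreductases
    for ko in ds.truth["causal_kos"]:
        ann = ds.annotations.loc[ko]
        assert ann["nadp_dependent"] and ann["ec_numbers"].startswith("1.")


def test_column_sums_equal_sampled_depths(small_dataset):
    counts = small_dataset.feature_table.counts
    depths = counts.sum(axis=0)
    lo, hi = 10_000, 20_000
    assert ((depths >= lo) & (depths <= hi)).all()
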