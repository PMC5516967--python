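"""Population engine: initiation, elongation, Moran division, reproducibility."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from protomotif.compartments import BiasConfig
from protomotif.observables import motif_frequency
from protomotif.sequence import EMPTY_CODE, MotifSpec, encode_bits
from protomotif.simulate import (
    ExperimentConfig,
    PopulationState,
    derive_trial_seeds,
    division_phase,
    elongation_phase,
    initiate,
    run_experiment,
    run_trial,
)


def single_config(pattern="100", bias=0.9, favored=0, **kw):
    base = dict(N=10, M=8, L=7, r=0.2, rounds=50, burn_in=10, sample_end=50,
                trials=2, seed=7)
    base.update(kw)
    if "rounds" in kw and "sample_end" not in kw:
        base["sample_end"] = base["rounds"]
        base["burn_in"] = min(base["burn_in"], base["rounds"] - 1)
    return ExperimentConfig(bias=BiasConfig.single(MotifSpec(pattern, favored, bias)), **base)


def test_initiate_builds_empty_population():
    cfg = single_config(N=2, M=4)
    state = initiate(cfg)
    assert state.N == 2 and state.M == 4
    assert (state.codes == EMPTY_CODE).all() and (state.prov == 0).all()
    assert state.round == 0
    assert motif_frequency(state, "100") == 0.0


def test_same_seed_gives_identical_initial_rng_state():
    cfg = single_config()
    s1, s2 = initiate(cfg, seed=3), initiate(cfg, seed=3)
    for name in ("elongation", "monomer", "division"):
        assert s1.rng[name].random() == s2.rng[name].random()


def test_run_trial_is_bitwise_deterministic():
    cfg = single_config(rounds=40)
    a = run_trial(cfg, 123)
    b = run_trial(cfg, 123)
    assert np.array_equal(a.motif_freq, b.motif_freq)
    assert np.array_equal(a.comp_freq, b.comp_freq)
    assert np.array_equal(a.event_rounds, b.event_rounds)
    assert np.array_equal(a.event_comp_ids, b.event_comp_ids)
    for x, y in zip(a.prov_counts, b.prov_counts):
        assert np.array_equal(x, y)


def test_deterministic_limit_every_open_strand_gains_a_zero():
    """With r = 1 and b = 1 in a motif-governed compartment, every strand
    below the cap is extended by a 0 monomer."""
    cfg = single_config(pattern="1000", bias=1.0, r=1.0, N=1, M=4)
    state = initiate(cfg)
    for j, bits in enumerate(["1000", "01", "", "1111111"]):
        state.codes[0, j] = encode_bits(bits)
    elongation_phase(state, cfg)
    assert state.codes[0, 0] == encode_bits("10000")
    assert state.codes[0, 1] == encode_bits("010")
    assert state.codes[0, 2] == encode_bits("0")
    assert state.codes[0, 3] == encode_bits("1111111")  # at the cap: untouched


def test_strands_at_cap_never_elongate():
    cfg = single_config(r=1.0, N=2, M=3)
    state = initiate(cfg)
    state.codes[:] = encode_bits("0101010")
    before = state.codes.copy()
    elongation_phase(state, cfg)
    assert np.array_equal(state.codes, before)


def test_elongation_is_append_only():
    cfg = single_config(N=6, M=6, r=0.5)
    state = initiate(cfg)
    for _ in range(30):
        before = state.codes.copy()
        elongation_phase(state, cfg)
        grown = state.codes != before
        assert np.isin(state.codes[grown], np.concatenate(
            [before[grown] * 2, before[grown] * 2 + 1])).all()
        assert (state.codes[~grown] == before[~grown]).all()


def test_division_conserves_surviving_strands():
    """After a division the population is exactly N compartments of M slots
    and every non-empty strand already existed before (no mutation, no
    creation); at most one compartment's contents disappear."""
    cfg = single_config(N=5, M=6, r=0.5)
    state = initiate(cfg)
    for _ in range(40):
        elongation_phase(state, cfg)
        before = Counter(state.codes[state.codes != EMPTY_CODE].tolist())
        rows_before = {
            int(cid): Counter(row[row != EMPTY_CODE].tolist())
            for cid, row in zip(state.comp_ids, state.codes)
        }
        division_phase(state, cfg)
        assert state.codes.shape == (5, 6)
        after = Counter(state.codes[state.codes != EMPTY_CODE].tolist())
        assert not after - before  # nothing appeared
        lost = before - after
        # what vanished is (a daughter's share of) one pre-division
        # compartment: the eliminated entity
        assert not lost or any(not (lost - row) for row in rows_before.values())


def test_forced_division_with_single_compartment():
    """With N = 1 the only compartment always divides and one of its two
    daughters survives; strands never multiply."""
    cfg = single_config(N=1, M=6, r=0.5)
    state = initiate(cfg)
    for _ in range(30):
        elongation_phase(state, cfg)
        before = Counter(state.codes[state.codes != EMPTY_CODE].tolist())
        division_phase(state, cfg)
        after = Counter(state.codes[state.codes != EMPTY_CODE].tolist())
        assert state.codes.shape == (1, 6)
        assert not after - before


def test_elimination_probability_matches_moran_rule():
    """Monte-Carlo over division phases: a round eliminates a non-dividing
    compartment with probability (N-1)/(N+1), i.e. each of the N-1
    non-dividers dies with probability 1/(N+1)."""
    cfg = single_config(N=10, M=2, r=0.2)
    state = initiate(cfg)
    reps = 120_000
    eliminated = 0
    for _ in range(reps):
        ids_before = set(state.comp_ids.tolist())
        division_phase(state, cfg)
        removed = ids_before - set(state.comp_ids.tolist())
        # the parent id is always retired; a second removed id is an
        # eliminated non-dividing compartment
        eliminated += len(removed) - 1
    p_hat = eliminated / reps
    p = (cfg.N - 1) / (cfg.N + 1)
    se = np.sqrt(p * (1 - p) / reps)
    assert abs(p_hat - p) < 4 * se


def test_population_invariants_over_a_trial():
    cfg = single_config(N=8, M=5, rounds=60, r=0.4)
    state = initiate(cfg)
    for t in range(cfg.rounds):
        elongation_phase(state, cfg)
        division_phase(state, cfg)
        assert state.codes.shape == (8, 5)
        assert state.lengths().max() <= cfg.L
        assert (state.lengths() >= 0).all()
        assert len(set(state.comp_ids.tolist())) == 8
        # provenance length always equals strand length
        assert (state.prov < 3 ** state.lengths()).all()


def test_complement_coupling_yields_bit_flipped_trajectories():
    """Running the complemented motif with the bit-flip-coupled monomer
    stream reproduces the original trajectory exactly under strand
    complementation (frequencies, events, provenance all identical)."""
    cfg = single_config(pattern="100", favored=0, bias=0.8, N=12, M=10, rounds=80)
    cfg_flip = single_config(pattern="011", favored=1, bias=0.8, N=12, M=10, rounds=80)
    a = run_trial(cfg, 99)
    b = run_trial(cfg_flip, 99, _flip_monomer_u=True)
    assert np.array_equal(a.motif_freq, b.motif_freq)
    assert np.array_equal(a.comp_freq, b.comp_freq)
    assert np.array_equal(a.event_rounds, b.event_rounds)
    assert np.array_equal(a.event_comp_ids, b.event_comp_ids)
    assert np.array_equal(a.prov_counts[0], b.prov_counts[0])


def test_neutral_dynamics_make_strand_contents_uniform():
    """Under neutral bias the bits of a strand of fixed length are uniform
    over all bit-strings of that length (chi-square on length-3 strands
    pooled over three independent trials)."""
    counts = np.zeros(8)
    for seed in (1, 2, 3):
        cfg = ExperimentConfig(bias=BiasConfig.neutral(), N=30, M=30, L=7, r=0.1,
                               rounds=400, burn_in=100, sample_end=400,
                               trials=1, seed=seed, track_patterns=("000",))
        state = initiate(cfg, seed=seed)
        for _ in range(cfg.rounds):
            elongation_phase(state, cfg)
            division_phase(state, cfg)
        lens = state.lengths()
        codes3 = state.codes[lens == 3] - 8  # strip sentinel: bits in 0..7
        counts += np.bincount(codes3, minlength=8)
    assert counts.sum() > 100
    _, pvalue = stats.chisquare(counts)
    assert pvalue > 0.001


def test_trial_seed_derivation_is_deterministic_and_31_bit():
    seeds = derive_trial_seeds(42, 20)
    assert seeds == derive_trial_seeds(42, 20)
    assert len(set(seeds)) == 20
    assert all(0 <= s < 2**31 for s in seeds)


def test_run_experiment_matches_individual_trials():
    cfg = single_config(rounds=30, trials=3)
    records = run_experiment(cfg)
    seeds = derive_trial_seeds(cfg.seed, 3)
    solo = run_trial(cfg, seeds[1])
    assert np.array_equal(records[1].motif_freq, solo.motif_freq)


def test_invalid_configs_rejected_before_simulation():
    with pytest.raises(ValueError):
        single_config(r=0.0)
    with pytest.raises(ValueError):
        single_config(r=1.5)
    with pytest.raises(ValueError):
        single_config(burn_in=50, sample_end=40)
    with pytest.raises(ValueError):
        single_config(pattern="10000000", L=7)
    with pytest.raises(ValueError):
        single_config(N=0)
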