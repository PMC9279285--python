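"""Generator: planted structure, determinism, noise semantics, round-trip."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cofrac.io import MatrixParseError, read_matrices, read_matrix, write_matrices
from cofrac.synth import (
    SimulationConfig,
    fraction_columns,
    generate_ground_truth,
    simulate_elution,
)


def test_ground_truth_is_deterministic(small_config):
    a = generate_ground_truth(small_config)
    b = generate_ground_truth(small_config)
    assert a == b


def test_simulation_is_deterministic(small_config):
    t = generate_ground_truth(small_config)
    m1, d1 = simulate_elution(t, small_config)
    m2, d2 = simulate_elution(t, small_config)
    pd.testing.assert_frame_equal(d1, d2)
    for ch in m1:
        pd.testing.assert_frame_equal(m1[ch], m2[ch])


def test_no_condition_specific_complexes_when_fraction_zero():
    cfg = SimulationConfig(
        n_proteins=90, n_complexes=8, n_fractions=32,
        condition_specific_fraction=0.0, seed=2,
    )
    truth = generate_ground_truth(cfg)
    assert truth.condition_specific_ids() == []
    for pres in truth.presence.values():
        assert all(pres.values())


def test_mean_complex_size_matches_uniform_3_12():
    # uniform{3..12}: mean 7.5, var 8.25 -> sd of the 50-draw mean ~ 0.406
    cfg = SimulationConfig(n_proteins=500, n_complexes=50, seed=5)
    truth = generate_ground_truth(cfg)
    sizes = [len(m) for m in truth.complexes.values()]
    # overlap promotion can only add members; bound stays generous
    assert abs(np.mean(sizes) - 7.5) < 3 * 0.406 + 1.0


def test_complex_invariants(small_truth, small_config):
    for members in small_truth.complexes.values():
        assert len(members) >= 3
    for mult in small_truth.multiplier.values():
        assert all(v > 0 for v in mult.values())
    n_multi = sum(
        1 for p in small_truth.proteins if len(small_truth.membership(p)) > 1
    )
    assert n_multi > 0  # default overlap fraction plants multi-complex proteins


def test_rejects_oversubscribed_disjoint_design():
    with pytest.raises(ValueError):
        generate_ground_truth(
            SimulationConfig(
                n_proteins=50, n_complexes=10, max_complex_size=12,
                multi_complex_fraction=0.0, seed=0,
            )
        )


def test_zero_noise_replicates_identical():
    cfg = SimulationConfig(
        n_proteins=60, n_complexes=5, n_fractions=48,
        replicate_noise_cv=0.0, missing_rate=0.0, seed=3,
    )
    truth = generate_ground_truth(cfg)
    matrices, design = simulate_elution(truth, cfg)
    for cond in cfg.conditions:
        chans = list(design.loc[design["condition"] == cond, "channel"])
        pd.testing.assert_frame_equal(matrices[chans[0]], matrices[chans[1]])


def test_absent_complex_members_have_zero_rows():
    cfg = SimulationConfig(
        n_proteins=90, n_complexes=8, n_fractions=48,
        condition_specific_fraction=0.5, missing_rate=0.0, seed=7,
    )
    truth = generate_ground_truth(cfg)
    matrices, design = simulate_elution(truth, cfg)
    specific = truth.condition_specific_ids()
    assert specific, "design should plant condition-specific complexes"
    checked = 0
    for cid in specific:
        for cond, present in truth.presence[cid].items():
            if present:
                continue
            chans = design.loc[design["condition"] == cond, "channel"]
            for p in truth.complexes[cid]:
                others = [
                    c for c in truth.membership(p)
                    if c != cid and truth.presence[c][cond]
                ]
                if others:
                    continue  # carried by another present complex
                for ch in chans:
                    assert (matrices[ch].loc[p] == 0).all()
                    checked += 1
    assert checked > 0


def test_intensities_nonnegative(small_data):
    matrices, _ = small_data
    for df in matrices.values():
        assert (df.to_numpy() >= 0).all()


def test_intra_complex_pairs_correlate_above_random(small_truth, small_data):
    """Planted signal: co-complex profiles beat random monomer pairs."""
    matrices, design = small_data
    df = matrices["ch1"]
    rng = np.random.default_rng(0)

    def pearson(a, b):
        x, y = df.loc[a].to_numpy(), df.loc[b].to_numpy()
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    cond = design.loc[design["channel"] == "ch1", "condition"].iloc[0]
    intra = [tuple(sorted(p)) for p in small_truth.intra_complex_pairs(cond)]
    idx = rng.choice(len(intra), size=min(100, len(intra)), replace=False)
    intra_r = np.mean([pearson(*intra[i]) for i in idx])
    monomers = list(small_truth.monomers)
    rand_r = np.mean(
        [
            pearson(*rng.choice(monomers, size=2, replace=False))
            for _ in range(100)
        ]
    )
    assert intra_r > rand_r


# -- persistence ---------------------------------------------------------


def test_round_trip_preserves_values(small_data, tmp_path):
    matrices, design = small_data
    write_matrices(matrices, design, tmp_path / "mats")
    back, design2 = read_matrices(tmp_path / "mats")
    pd.testing.assert_frame_equal(design.astype(str), design2)
    for ch, df in matrices.items():
        assert np.allclose(df.to_numpy(), back[ch].to_numpy(), atol=1e-9)
        assert list(df.index) == list(back[ch].index)


def test_full_fraction_count_round_trip(tmp_path):
    """A 192-fraction matrix reads back with the full column count."""
    cols = fraction_columns(192)
    df = pd.DataFrame(
        np.arange(2 * 192, dtype=float).reshape(2, 192),
        index=["Pa", "Pb"], columns=cols,
    )
    design = pd.DataFrame(
        [{"channel": "ch1", "condition": "cond1", "replicate": "R1"}]
    )
    write_matrices({"ch1": df}, design, tmp_path / "m")
    back, _ = read_matrices(tmp_path / "m")
    assert back["ch1"].shape == (2, 192)


@pytest.mark.parametrize(
    "lines, fragment",
    [
        (
            ["protein_id\tfrac_0001\tfrac_0002", "Pa\t1\t2", "Pa\t3\t4"],
            "duplicate protein id",
        ),
        (["protein_id\tfrac_0001\tfrac_0002", "Pa\t1"], "expected 3 fields"),
        (["wrong\tfrac_0001", "Pa\t1"], "protein_id"),
        (["protein_id\tfrac_0001", "Pa\tnot_a_number"], "not_a_number"),
    ],
)
def test_malformed_matrix_files_raise_named_errors(tmp_path, lines, fragment):
    f = tmp_path / "bad.tsv"
    f.write_text("\n".join(lines) + "\n")
    with pytest.raises(MatrixParseError, match=fragment):
        read_matrix(f)


def test_config_validation_rejects_bad_values():
    for kwargs in [
        {"n_fractions": 1},
        {"missing_rate": 1.0},
        {"peak_width_sd": -1},
        {"min_complex_size": 2},
    ]:
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
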