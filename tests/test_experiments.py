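"""Latin-hypercube sampling, the global scan and its summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from plasdyn import (
    ModelParams,
    ModelVariant,
    ParameterRange,
    beta_equivalence,
    default_ranges,
    lhs_sample,
    main_effects,
    run_experiment_I,
    run_experiment_II,
)
from plasdyn.experiments import ScanResult


# ---------------------------------------------------------------------------
# sampling design
# ---------------------------------------------------------------------------

def test_parameter_range_validation():
    with pytest.raises(ValueError, match="chi"):
        ParameterRange("chi", 0.0, 1e-3, scale="log10")
    with pytest.raises(ValueError, match="psi"):
        ParameterRange("psi", 2.0, 0.0)
    with pytest.raises(ValueError, match="scale"):
        ParameterRange("psi", 0.0, 2.0, scale="cubic")


def test_default_ranges_match_scan_design():
    r = default_ranges()
    assert set(r) == {"psi", "alpha", "beta", "omega", "upsilon", "tau", "gamma", "chi"}
    assert (r["psi"].low, r["psi"].high, r["psi"].scale) == (0.0, 2.0, "uniform")
    assert (r["upsilon"].low, r["upsilon"].high, r["upsilon"].scale) == (1e-4, 1.0, "log10")
    assert (r["chi"].low, r["chi"].high, r["chi"].scale) == (1e-9, 1e-3, "log10")
    assert (r["tau"].low, r["tau"].high, r["tau"].scale) == (1.0, 20.0, "half_power")


def test_lhs_sample_ranges_and_transforms():
    df = lhs_sample(100, seed=0)
    assert len(df) == 100
    assert (df["k"] == 1.0).all()
    # half-power transform puts segregational loss on [0.5^20, 0.5]
    assert df["tau"].between(0.5 ** 20, 0.5).all()
    # log-sampled mutation rate: exponents approximately uniform on [-9, -3]
    assert df["chi"].between(1e-9, 1e-3).all()
    exps = (np.log10(df["chi"]) + 9) / 6
    assert kstest(exps, "uniform").statistic < 0.15
    assert df["upsilon"].between(1e-4, 1.0).all()
    for name in ("alpha", "beta", "omega", "gamma"):
        assert df[name].between(0, 1).all()
    assert df["psi"].between(0, 2).all()


def test_lhs_sample_deterministic_and_stratified():
    a = lhs_sample(50, seed=7)
    b = lhs_sample(50, seed=7)
    pd.testing.assert_frame_equal(a, b)
    c = lhs_sample(50, seed=8)
    assert not a.equals(c)
    # latin-hypercube stratification: one draw per equal-probability stratum
    u = (np.log10(a["chi"]) + 9) / 6
    assert len(np.unique(np.floor(u * 50))) == 50


# ---------------------------------------------------------------------------
# experiment I (reference dynamics)
# ---------------------------------------------------------------------------

def test_experiment_I_structure_and_outcomes():
    result = run_experiment_I(t_end=4000.0, n_out=401)
    assert len(result.trajectories) == 12
    summary = result.summary()
    # without antibiotics, every variant loses the plasmid by 4,000 h
    none = summary[summary["upsilon"] == 0.0]
    assert not none["above_threshold"].any()
    # under plasmid mutation at strong killing, non-adapted bearers vanish
    traj = result.trajectories[(ModelVariant.PLASMID, 0.1)]
    assert traj.plasmid_fraction[-1] > 1e-3
    assert traj.P[-1] < 1e-6 < traj.A[-1]


# ---------------------------------------------------------------------------
# experiment II (global scan) — structure on a miniature scan
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def mini_scan():
    return run_experiment_II(40, seed=9)


def test_scan_row_structure(mini_scan):
    df = mini_scan.data
    assert len(df) == 40 * 6
    counts = df.groupby("set_id").size()
    assert (counts == 6).all()
    # the antibiotic-free twin has upsilon 0 and otherwise identical parameters
    for sid, grp in df.groupby("set_id"):
        none = grp[grp["regime"] == "none"]
        present = grp[grp["regime"] == "antibiotic"]
        assert (none["upsilon"] == 0.0).all()
        assert (present["upsilon"] == present["upsilon_sampled"]).all()
        for col in ("psi", "alpha", "beta", "omega", "tau", "gamma"):
            assert none[col].nunique() == 1 and none[col].iloc[0] == present[col].iloc[0]
    # the no-mutation arm forces chi to zero but keeps the sampled value on record
    nomut = df[df["variant"] == "no_mutation"]
    assert (nomut["chi"] == 0.0).all()
    assert (nomut["chi_sampled"] > 0).all()


def test_scan_determinism(mini_scan):
    again = run_experiment_II(40, seed=9)
    pd.testing.assert_frame_equal(mini_scan.data, again.data)


def test_scan_serialization_roundtrip(mini_scan, tmp_path):
    mini_scan.write(tmp_path)
    df = pd.read_csv(tmp_path / "scan.csv")
    assert len(df) == len(mini_scan.data)
    import json

    with open(tmp_path / "manifest.json") as fh:
        manifest = json.load(fh)
    assert manifest["n"] == 40 and manifest["seed"] == 9
    assert manifest["n_failed"] == 0


def test_antibiotics_only_help_the_plasmid(scan_small):
    # persistence without antibiotics implies persistence with them (same set)
    df = scan_small.data[scan_small.data["converged"]]
    wide = df.pivot_table(index=["set_id", "variant"], columns="regime",
                          values="persistent", aggfunc="first")
    both = wide.dropna()
    implied = ~both["none"].astype(bool) | both["antibiotic"].astype(bool)
    assert implied.mean() >= 0.99


# ---------------------------------------------------------------------------
# main effects and the amelioration-equivalence read-out
# ---------------------------------------------------------------------------

def test_main_effects_contract(scan_small):
    curve = main_effects(scan_small, "beta", n_bins=10)
    t = curve.table
    assert set(t["variant"]) == {"no_mutation", "chromosomal", "plasmid"}
    assert t["persistence_pct"].between(0, 100).all()
    assert (t["n"] >= 10).all()
    # per-variant bin counts add up to the converged antibiotic-regime runs
    conv = scan_small.data[(scan_small.data["regime"] == "antibiotic")
                           & scan_small.data["converged"]]
    for v, grp in t.groupby("variant"):
        assert grp["n"].sum() == (conv["variant"] == v).sum()
    with pytest.raises(KeyError):
        main_effects(scan_small, "resistance")
    with pytest.raises(ValueError):
        main_effects(scan_small, "beta", regime="sometimes")


def test_main_effect_directions(scan_small):
    # antibiotic action helps persistence; plasmid cost hurts it
    ups = main_effects(scan_small, "upsilon", n_bins=8)
    for v in ModelVariant:
        x, y = ups.curve(v)
        assert y[-1] > y[0]
    alpha = main_effects(scan_small, "alpha", n_bins=8)
    x, y = alpha.curve(ModelVariant.NO_MUTATION)
    assert y[-1] < y[0]


def _synthetic_scan(curve_fn_chrom, curve_fn_plasmid, n_per_bin=40, n_bins=10):
    """Scan stub whose per-bin persistence follows the given response curves."""
    rows = []
    sid = 0
    rng = default_ranges()
    for b in range(n_bins):
        beta_mid = (b + 0.5) / n_bins
        for j in range(n_per_bin):
            beta = beta_mid
            for variant, fn in [("chromosomal", curve_fn_chrom), ("plasmid", curve_fn_plasmid),
                                ("no_mutation", lambda x: 0.0)]:
                persistent = (j / n_per_bin) < fn(beta)
                rows.append({
                    "set_id": sid, "variant": variant, "regime": "antibiotic",
                    "k": 1.0, "psi": 1.0, "alpha": 0.2, "beta": beta, "omega": 0.1,
                    "upsilon": 0.1, "upsilon_sampled": 0.1, "tau": 1e-3, "gamma": 0.02,
                    "chi": 1e-6, "chi_sampled": 1e-6, "F": 0.1, "P": 0.4, "A": 0.4,
                    "plasmid_fraction": 0.8 if persistent else 1e-8,
                    "t_converged": 100.0, "converged": True,
                    "persistent": persistent, "failed": False,
                })
            sid += 1
    return ScanResult(data=pd.DataFrame(rows), n=sid, seed=0, ranges=rng)


def test_beta_equivalence_against_constructed_curves():
    # chromosomal rises linearly 0 -> 50%; plasmid rises twice as fast.
    # chromosomal at beta = 0.75 gives 37.5%, attained by plasmid at 0.375.
    scan = _synthetic_scan(lambda b: 0.5 * b, lambda b: min(1.0, b))
    est = beta_equivalence(scan, beta_ref=0.75, n_bins=10)
    assert est == pytest.approx(0.375, abs=0.05)


def test_beta_equivalence_degenerate_reference_level():
    # reference level zero: first plasmid bin already attains it
    scan = _synthetic_scan(lambda b: 0.0, lambda b: min(1.0, b))
    assert beta_equivalence(scan, beta_ref=0.75, n_bins=10) == pytest.approx(0.05, abs=1e-9)


def test_beta_equivalence_unattainable_level():
    scan = _synthetic_scan(lambda b: 0.9, lambda b: 0.1)
    with pytest.raises(ValueError, match="attained range"):
        beta_equivalence(scan, beta_ref=0.75, n_bins=10)


def test_scan_rejects_tiny_input():
    with pytest.raises(ValueError):
        run_experiment_II(0, seed=1)
    with pytest.raises(ValueError):
        lhs_sample(0)
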