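"""The two simulation experiments: reference dynamics and the global scan.

Experiment I runs the default parameter set for each model variant across
four levels of antibiotic action over a fixed 4,000 h horizon and reports
the resulting trajectories.

Experiment II is a global persistence scan: a Latin-hypercube sample of
the eight free parameters, each set integrated to steady state under all
three model variants, both with the sampled antibiotic killing rate and
with antibiotics switched off (no re-sampling), for a paired comparison.
Per-parameter "main effect" curves — the percentage of persistent runs in
bins along one parameter's sampled scale — summarise which conditions
favour plasmid persistence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .model import ModelParams, ModelVariant, PopulationState
from .dynamics import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    PERSISTENCE_THRESHOLD,
    STEADY_TOL,
    T_CAP,
    IntegrationError,
    Trajectory,
    default_initial_state,
    run_to_steady,
    simulate,
)

__all__ = [
    "ParameterRange",
    "default_ranges",
    "lhs_sample",
    "ScanResult",
    "MainEffectCurve",
    "ExperimentIResult",
    "run_experiment_I",
    "run_experiment_II",
    "main_effects",
    "beta_equivalence",
]

_SCALES = ("uniform", "log10", "half_power")


@dataclass(frozen=True)
class ParameterRange:
    """Sampling descriptor for one parameter.

    ``scale`` controls the map from the unit interval to parameter values:
    ``uniform`` is affine on [low, high]; ``log10`` is affine on the
    exponents (low > 0 required); ``half_power`` draws an exponent ``x``
    uniformly on [low, high] and returns ``0.5**x`` — the natural scale
    for segregational loss, where ``x`` plays the role of a plasmid copy
    number.
    """

    name: str
    low: float
    high: float
    scale: str = "uniform"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"{self.name}: unknown scale {self.scale!r}; expected one of {_SCALES}")
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high, got [{self.low}, {self.high}]")
        if self.scale == "log10" and self.low <= 0:
            raise ValueError(f"{self.name}: log10 sampling requires low > 0, got {self.low}")

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Map unit-interval draws to parameter values."""
        u = np.asarray(u, dtype=float)
        if self.scale == "uniform":
            return self.low + u * (self.high - self.low)
        if self.scale == "log10":
            lo, hi = math.log10(self.low), math.log10(self.high)
            return 10.0 ** (lo + u * (hi - lo))
        x = self.low + u * (self.high - self.low)
        return 0.5 ** x

    def to_sampling_scale(self, values: np.ndarray) -> np.ndarray:
        """Project parameter values back onto the scale they were drawn on."""
        values = np.asarray(values, dtype=float)
        if self.scale == "uniform":
            return values
        if self.scale == "log10":
            return np.log10(values)
        return np.log(values) / np.log(0.5)  # exponent x of 0.5**x

    def sampling_bounds(self) -> tuple[float, float]:
        """Bounds on the sampled (transformed) scale, low < high."""
        if self.scale == "log10":
            return math.log10(self.low), math.log10(self.high)
        return self.low, self.high

    def to_dict(self) -> dict:
        return {"name": self.name, "low": self.low, "high": self.high, "scale": self.scale}


def default_ranges() -> dict[str, ParameterRange]:
    """Sampling ranges of the global scan (carrying capacity fixed at 1)."""
    ranges = [
        ParameterRange("psi", 0.0, 2.0),
        ParameterRange("alpha", 0.0, 1.0),
        ParameterRange("beta", 0.0, 1.0),
        ParameterRange("omega", 0.0, 1.0),
        ParameterRange("upsilon", 1e-4, 1.0, scale="log10"),
        ParameterRange("tau", 1.0, 20.0, scale="half_power"),
        ParameterRange("gamma", 0.0, 1.0),
        ParameterRange("chi", 1e-9, 1e-3, scale="log10"),
    ]
    return {r.name: r for r in ranges}


def lhs_sample(
    n: int,
    ranges: dict[str, ParameterRange] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Latin-hypercube design of ``n`` parameter sets.

    Returns a tidy frame, one row per set (indexed by ``set_id``), with
    one column per sampled parameter plus the fixed capacity ``k = 1``.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ranges is None:
        ranges = default_ranges()
    names = list(ranges)
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    data = {name: ranges[name].from_unit(unit[:, j]) for j, name in enumerate(names)}
    df = pd.DataFrame(data)
    df.insert(0, "k", 1.0)
    df.index.name = "set_id"
    return df


@dataclass(frozen=True)
class ExperimentIResult:
    """Trajectories of the reference-parameter runs."""

    trajectories: dict[tuple[ModelVariant, float], Trajectory]
    t_end: float

    def summary(self, threshold: float = PERSISTENCE_THRESHOLD) -> pd.DataFrame:
        rows = []
        for (variant, upsilon), traj in self.trajectories.items():
            fin = traj.final_state()
            rows.append({
                "variant": variant.value,
                "upsilon": upsilon,
                "F": fin.F, "P": fin.P, "A": fin.A,
                "plasmid_fraction": fin.plasmid_fraction,
                "above_threshold": fin.plasmid_fraction > threshold,
            })
        return pd.DataFrame(rows)


def run_experiment_I(
    antibiotic_levels: tuple[float, ...] = (0.0, 1e-3, 1e-2, 1e-1),
    t_end: float = 4000.0,
    n_out: int = 2001,
    base_params: ModelParams | None = None,
) -> ExperimentIResult:
    """Reference dynamics: every variant at each level of antibiotic action."""
    if base_params is None:
        base_params = ModelParams()
    trajectories: dict[tuple[ModelVariant, float], Trajectory] = {}
    for variant in ModelVariant:
        for upsilon in antibiotic_levels:
            p = base_params.with_(variant=variant, upsilon=float(upsilon))
            trajectories[(variant, float(upsilon))] = simulate(p, t_end=t_end, n_out=n_out)
    return ExperimentIResult(trajectories=trajectories, t_end=t_end)


@dataclass(frozen=True)
class ScanResult:
    """Tidy results of the global scan.

    One row per (parameter set x variant x antibiotic regime).  The
    ``upsilon`` column holds the killing rate actually applied in that
    run (0 in the antibiotic-free regime); ``upsilon_sampled`` and
    ``chi_sampled`` keep the drawn values for pairing and binning.
    """

    data: pd.DataFrame
    n: int
    seed: int
    ranges: dict[str, ParameterRange]
    settings: dict = field(default_factory=dict)

    def persistence_percentages(self) -> pd.DataFrame:
        """Percentage of converged runs classified persistent, per variant x regime."""
        conv = self.data[self.data["converged"]]
        out = (
            conv.groupby(["variant", "regime"], sort=True)["persistent"]
            .agg(persistence_pct=lambda s: 100.0 * s.mean(), n="size")
            .reset_index()
        )
        return out

    def manifest(self) -> dict:
        from . import __version__

        return {
            "version": __version__,
            "n": self.n,
            "seed": self.seed,
            "ranges": [r.to_dict() for r in self.ranges.values()],
            "settings": self.settings,
            "n_rows": int(len(self.data)),
            "n_converged": int(self.data["converged"].sum()),
            "n_failed": int(self.data["failed"].sum()),
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(outdir / "scan.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


_REGIMES = ("antibiotic", "none")


def run_experiment_II(
    n: int,
    seed: int = 0,
    ranges: dict[str, ParameterRange] | None = None,
    tol: float = STEADY_TOL,
    t_cap: float = T_CAP,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    max_failure_fraction: float = 0.05,
    progress: bool = False,
) -> ScanResult:
    """Global persistence scan over a Latin-hypercube parameter sample.

    Each of the ``n`` sets is run to steady state under all three model
    variants (the no-mutation arm forces ``chi = 0``), both with the
    sampled antibiotic action and with ``upsilon = 0`` under otherwise
    identical parameters.  Individual solver failures are recorded and
    flagged; more than ``max_failure_fraction`` of failing runs aborts.
    """
    if ranges is None:
        ranges = default_ranges()
    design = lhs_sample(n, ranges=ranges, seed=seed)
    rows: list[dict] = []
    n_failed = 0
    n_total = n * len(ModelVariant) * len(_REGIMES)
    for set_id, row in design.iterrows():
        for variant in ModelVariant:
            chi_eff = 0.0 if variant is ModelVariant.NO_MUTATION else float(row["chi"])
            for regime in _REGIMES:
                ups_eff = float(row["upsilon"]) if regime == "antibiotic" else 0.0
                params = ModelParams(
                    k=float(row["k"]), psi=float(row["psi"]), alpha=float(row["alpha"]),
                    beta=float(row["beta"]), omega=float(row["omega"]), upsilon=ups_eff,
                    tau=float(row["tau"]), gamma=float(row["gamma"]), chi=chi_eff,
                    variant=variant,
                )
                rec = {
                    "set_id": set_id, "variant": variant.value, "regime": regime,
                    "k": params.k, "psi": params.psi, "alpha": params.alpha,
                    "beta": params.beta, "omega": params.omega, "upsilon": ups_eff,
                    "upsilon_sampled": float(row["upsilon"]), "tau": params.tau,
                    "gamma": params.gamma, "chi": chi_eff, "chi_sampled": float(row["chi"]),
                }
                try:
                    res = run_to_steady(params, tol=tol, t_cap=t_cap, rtol=rtol, atol=atol)
                    rec.update(
                        F=res.terminal.F, P=res.terminal.P, A=res.terminal.A,
                        plasmid_fraction=res.plasmid_fraction,
                        t_converged=res.t_converged, converged=res.converged,
                        persistent=res.persistent, failed=False,
                    )
                except IntegrationError:
                    n_failed += 1
                    rec.update(
                        F=np.nan, P=np.nan, A=np.nan, plasmid_fraction=np.nan,
                        t_converged=np.nan, converged=False, persistent=False, failed=True,
                    )
                rows.append(rec)
        if progress and (set_id + 1) % 200 == 0:
            print(f"  scanned {set_id + 1}/{n} parameter sets", flush=True)
    if n_failed > max_failure_fraction * n_total:
        raise RuntimeError(
            f"{n_failed}/{n_total} runs failed to integrate "
            f"(> {100 * max_failure_fraction:.0f}%); check the sampling ranges"
        )
    data = pd.DataFrame(rows)
    settings = {"tol": tol, "t_cap": t_cap, "rtol": rtol, "atol": atol}
    return ScanResult(data=data, n=n, seed=seed, ranges=dict(ranges), settings=settings)


@dataclass(frozen=True)
class MainEffectCurve:
    """Binned persistence percentages along one parameter.

    Bins live on the parameter's sampling scale (log10 for log-sampled
    parameters, the exponent ``x`` for segregational loss).  ``table``
    has one row per bin x variant with the persistence percentage and the
    number of converged runs behind it.
    """

    parameter: str
    scale: str
    edges: np.ndarray
    table: pd.DataFrame

    def curve(self, variant: ModelVariant | str) -> tuple[np.ndarray, np.ndarray]:
        """(bin midpoints on the sampling scale, persistence percentages)."""
        v = variant.value if isinstance(variant, ModelVariant) else variant
        sub = self.table[self.table["variant"] == v].sort_values("bin_mid")
        return sub["bin_mid"].to_numpy(), sub["persistence_pct"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def main_effects(
    scan: ScanResult,
    parameter: str,
    n_bins: int = 20,
    regime: str = "antibiotic",
    min_bin_count: int = 10,
) -> MainEffectCurve:
    """Main-effect curve of one parameter: persistence percentage per bin.

    Only converged runs enter the percentages.  Bins holding fewer than
    ``min_bin_count`` runs for some variant are merged with their
    neighbour so every reported bin is adequately supported.
    """
    if parameter not in scan.ranges:
        raise KeyError(
            f"unknown parameter {parameter!r}; scanned parameters: {list(scan.ranges)}"
        )
    if regime not in _REGIMES:
        raise ValueError(f"regime must be one of {_REGIMES}, got {regime!r}")
    rng = scan.ranges[parameter]
    data = scan.data
    data = data[(data["regime"] == regime) & data["converged"]].copy()
    if len(data) < n_bins * min_bin_count:
        raise ValueError(
            f"scan holds only {len(data)} converged runs in regime {regime!r}; "
            f"need at least {n_bins * min_bin_count} for {n_bins} bins"
        )
    column = {"upsilon": "upsilon_sampled", "chi": "chi_sampled"}.get(parameter, parameter)
    x = rng.to_sampling_scale(data[column].to_numpy())
    lo, hi = rng.sampling_bounds()
    if lo > hi:  # half_power maps a rising exponent to a falling value
        lo, hi = hi, lo
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    variants = list(data["variant"].unique())
    variant_idx = {v: idx[(data["variant"] == v).to_numpy()] for v in variants}

    # merge under-populated bins with a neighbour until every bin is supported
    groups: list[list[int]] = [[b] for b in range(n_bins)]

    def _count(group: list[int]) -> int:
        return min(int(np.isin(variant_idx[v], group).sum()) for v in variants)

    while len(groups) > 1:
        counts = [_count(g) for g in groups]
        if min(counts) >= min_bin_count:
            break
        i = int(np.argmin(counts))
        j = i - 1 if i > 0 else i + 1
        groups[j] = sorted(groups[j] + groups[i])
        del groups[i]

    label_of = {b: gi for gi, g in enumerate(groups) for b in g}
    data["bin"] = [label_of[b] for b in idx]
    bounds = [(edges[g[0]], edges[g[-1] + 1]) for g in groups]
    rows = []
    for (v, gi), grp in data.groupby(["variant", "bin"], sort=True):
        low, high = bounds[int(gi)]
        rows.append({
            "parameter": parameter,
            "variant": v,
            "bin": int(gi),
            "bin_low": float(low),
            "bin_high": float(high),
            "bin_mid": float(0.5 * (low + high)),
            "persistence_pct": 100.0 * grp["persistent"].mean(),
            "n": int(len(grp)),
        })
    table = pd.DataFrame(rows).sort_values(["variant", "bin"]).reset_index(drop=True)
    return MainEffectCurve(parameter=parameter, scale=rng.scale, edges=edges, table=table)


def beta_equivalence(
    scan: ScanResult,
    beta_ref: float = 0.75,
    n_bins: int = 20,
) -> float:
    """Amelioration strength at which plasmid mutation matches chromosomal.

    Reads the main-effect curves of the amelioration strength ``beta``
    (antibiotic-present regime) for both mutation variants, takes the
    chromosomal persistence percentage at ``beta = beta_ref``, and returns
    the smallest ``beta`` at which the linearly interpolated
    plasmid-mutation curve attains that percentage.
    """
    curve = main_effects(scan, "beta", n_bins=n_bins, regime="antibiotic")
    x_c, y_c = curve.curve(ModelVariant.CHROMOSOMAL)
    x_p, y_p = curve.curve(ModelVariant.PLASMID)
    level = float(np.interp(beta_ref, x_c, y_c))
    if y_p[0] >= level:
        return float(x_p[0])
    for i in range(len(x_p) - 1):
        if y_p[i] < level <= y_p[i + 1]:
            frac = (level - y_p[i]) / (y_p[i + 1] - y_p[i])
            return float(x_p[i] + frac * (x_p[i + 1] - x_p[i]))
    raise ValueError(
        f"plasmid-mutation curve never attains the chromosomal level "
        f"{level:.2f}% (attained range {y_p.min():.2f}%..{y_p.max():.2f}%)"
    )
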