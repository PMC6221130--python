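"""Monte-Carlo experiment harness: replicated scenarios, bias/coverage/power.

Each replicate simulates a fresh trio dataset, estimates instrument weights in
half A, scores half B and runs the requested estimators.  Replicates are
seeded from a per-replicate ``SeedSequence`` spawn of the master seed, so any
single replicate is reproducible in isolation and results are invariant to
how replicates are distributed over workers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from .scores import build_scores, estimate_weights
from .sim_population import (AssortmentSpec, ScenarioConfig, advance_generations,
                             build_trio_dataset)

__all__ = [
    "ReplicateRecord",
    "ScenarioSummary",
    "run_replicate",
    "run_scenario",
    "summarize",
    "preset_scenarios",
    "PRESET_NAMES",
]

_METHODS: dict[str, Callable] = {
    "tsls1": est.mr_tsls1,
    "tsls2": est.mr_tsls2,
    "tsls3": est.mr_tsls3,
}

_SUMMARY_METHODS = ("ivw", "egger", "weighted_median", "mbe")


@dataclass
class ReplicateRecord:
    """Estimates and diagnostics from one simulated dataset."""

    scenario_id: str
    replicate: int
    results: dict[str, est.EstimateResult]
    spouse_cor: dict[str, float] = field(default_factory=dict)
    error: Optional[str] = None


@dataclass
class ScenarioSummary:
    """Monte-Carlo operating characteristics of each method in one scenario."""

    scenario_id: str
    true_beta: float
    n_reps: int
    n_failed: int
    per_method: dict[str, dict[str, float]]
    spouse_cor: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, d in self.per_method.items():
            rows.append({"scenario_id": self.scenario_id, "method": m,
                         "true_beta": self.true_beta, "n_reps": self.n_reps,
                         **d})
        return pd.DataFrame(rows)


def run_replicate(cfg: ScenarioConfig, methods: Sequence[str], rep: int,
                  master_seed: int, scenario_id: str = "scenario",
                  robust: bool = False, n_boot: int = 200) -> ReplicateRecord:
    """One fully seeded replicate: simulate, split-half score, estimate."""
    seq = np.random.SeedSequence(master_seed, spawn_key=(rep,))
    s_sim, s_build, s_mr = seq.spawn(3)
    sim = advance_generations(cfg, s_sim)
    trios = build_trio_dataset(sim, np.random.default_rng(s_build))
    weights = estimate_weights(trios)
    scores = build_scores(trios, weights)

    results: dict[str, est.EstimateResult] = {}
    stats_cache = None
    for m in methods:
        if m in _METHODS:
            results[m] = _METHODS[m](scores, trios, robust=robust)
        elif m in _SUMMARY_METHODS:
            if stats_cache is None:
                stats_cache = est.snp_summary_stats(trios)
            results[m] = est.summary_mr(stats_cache, m, n_boot=n_boot,
                                        seed=np.random.default_rng(s_mr))
        else:
            raise ValueError(f"unknown method {m!r}")

    par = sim.parents.phenotypes
    c = sim.couples
    spouse_cor = {
        "cor_xm_xf": float(np.corrcoef(par["X"][c[:, 0]], par["X"][c[:, 1]])[0, 1]),
        "cor_xm_yf": float(np.corrcoef(par["X"][c[:, 0]], par["Y"][c[:, 1]])[0, 1]),
        "cor_ym_xf": float(np.corrcoef(par["Y"][c[:, 0]], par["X"][c[:, 1]])[0, 1]),
        "cor_ym_yf": float(np.corrcoef(par["Y"][c[:, 0]], par["Y"][c[:, 1]])[0, 1]),
    }
    return ReplicateRecord(scenario_id=scenario_id, replicate=rep,
                           results=results, spouse_cor=spouse_cor)


def run_scenario(cfg: ScenarioConfig, n_reps: int = 500,
                 methods: Sequence[str] = ("tsls1", "tsls2", "tsls3"),
                 seed: Optional[int] = None, scenario_id: str = "scenario",
                 robust: bool = False, n_jobs: int = 1,
                 progress: Optional[Callable[[int], None]] = None
                 ) -> list[ReplicateRecord]:
    """Run ``n_reps`` independent replicates of one scenario.

    Deterministic given (seed, replicate index); a failing replicate is
    recorded with its error message rather than aborting the run.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    master = cfg.seed if seed is None else seed

    def one(rep: int) -> ReplicateRecord:
        try:
            return run_replicate(cfg, methods, rep, master, scenario_id, robust)
        except Exception as e:  # noqa: BLE001 - recorded, not fatal
            return ReplicateRecord(scenario_id=scenario_id, replicate=rep,
                                   results={}, error=f"{type(e).__name__}: {e}")

    if n_jobs != 1:
        from joblib import Parallel, delayed
        records = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in range(n_reps))
    else:
        records = []
        for r in range(n_reps):
            records.append(one(r))
            if progress is not None:
                progress(r)
    return list(records)


def summarize(records: Sequence[ReplicateRecord], true_beta: float) -> ScenarioSummary:
    """Aggregate replicate records into bias, SE, false rejection and power.

    * bias = mean estimate - true_beta (exact arithmetic);
    * empirical SE = SD of estimates; mean model SE also reported;
    * false rejection = share of 95% CIs excluding the true value;
    * power = share of 95% CIs excluding 0;
    * assortment-test rejection = share of joint-Wald p-values below 0.05.
    """
    ok = [r for r in records if r.error is None and r.results]
    if not ok:
        raise ValueError("no successful replicates to summarize")
    n_failed = len(records) - len(ok)
    methods = list(ok[0].results)
    per_method: dict[str, dict[str, float]] = {}
    for m in methods:
        ests = np.array([r.results[m].estimate for r in ok])
        ses = np.array([r.results[m].se for r in ok])
        reject_true = np.array([r.results[m].ci_excludes(true_beta) for r in ok])
        reject_zero = np.array([r.results[m].ci_excludes(0.0) for r in ok])
        a_ps = [r.results[m].assort_p for r in ok]
        d = {
            "mean_estimate": float(ests.mean()),
            "bias": float(ests.mean() - true_beta),
            "empirical_se": float(ests.std(ddof=1)) if len(ests) > 1 else float("nan"),
            "mean_model_se": float(ses.mean()),
            "false_rejection": float(reject_true.mean()),
            "power": float(reject_zero.mean()),
            "mc_se_bias": float(ests.std(ddof=1) / math.sqrt(len(ests)))
            if len(ests) > 1 else float("nan"),
        }
        if all(p is not None for p in a_ps):
            d["assort_rejection"] = float(np.mean([p < 0.05 for p in a_ps]))
        per_method[m] = d
    spouse = {}
    if ok[0].spouse_cor:
        for k in ok[0].spouse_cor:
            spouse[k] = float(np.mean([r.spouse_cor[k] for r in ok]))
    return ScenarioSummary(scenario_id=ok[0].scenario_id, true_beta=true_beta,
                           n_reps=len(ok), n_failed=n_failed,
                           per_method=per_method, spouse_cor=spouse)


# ---------------------------------------------------------------------------
# Presets reproducing the published simulation designs
# ---------------------------------------------------------------------------

PRESET_NAMES = ("table1", "table2", "figure2", "figure3",
                "single_trait_suite", "cross_trait_correlated_suite")

_CROSS_XY = AssortmentSpec(pattern="cross_trait", trait_a="X", trait_b="Y")


def _cfg(**kw) -> ScenarioConfig:
    base = dict(n_trios=40_000, n_snps_x=50, n_snps_y=50, h2_x=0.5, h2_y=0.5,
                beta_xy=0.0, n_instrument_snps=50)
    base.update(kw)
    return ScenarioConfig(**base)


def _aux_defs(kind: str) -> tuple:
    """Auxiliary traits genetically correlated with X and/or Y.

    ``horizontal``: traits load directly on the scaled genetic scores of all
    variants in the respective set; ``vertical``: traits load on the
    phenotypes X / Y themselves.  Loadings of sqrt(0.5) with unit-variance
    residual noise give the auxiliary traits ~unit variance and a genetic
    correlation of ~sqrt(0.5) with the corresponding phenotype.
    """
    a = math.sqrt(0.5)
    b = math.sqrt(0.5)
    if kind == "horizontal":
        # genetic_x = delta_X * Z_X has variance h2_x (0.5 in these suites);
        # unit loading gives the auxiliary trait a 50% genetic variance share
        ax = (("genetic_x", 1.0), ("noise", b))
        ay = (("genetic_y", 1.0), ("noise", b))
        both = (("genetic_x", a), ("genetic_y", a), ("noise", b))
    elif kind == "vertical":
        ax = (("X", a), ("noise", b))
        ay = (("Y", a), ("noise", b))
        both = (("X", a), ("Y", a), ("noise", b))
    else:
        raise ValueError(kind)
    return (("AX", ax), ("AY", ay), ("AB", both))


def preset_scenarios(name: str) -> list[tuple[str, ScenarioConfig]]:
    """Named scenario grids mirroring the published simulation designs.

    Returns (scenario_id, config) pairs.  ``table1``: cross-trait assortment
    grid P x h2_Y x instrument-SNP count x |GY| under no causal effect;
    ``table2``: no assortment, true effect 0.05, h2 grid; ``figure2``: P x h2
    grid at one generation; ``figure3``: generations 1..9; the two suites
    cover assortment on auxiliary traits genetically correlated with X and/or
    Y via horizontal or vertical pleiotropy.
    """
    out: list[tuple[str, ScenarioConfig]] = []
    if name == "table1":
        for p in (0.2, 0.6, 1.0):
            for h2y in (0.1, 0.5):
                for n_inst in (10, 50):
                    for n_gy in (10, 50):
                        sid = f"table1_P{p}_h2y{h2y}_gi{n_inst}_gy{n_gy}"
                        out.append((sid, _cfg(h2_y=h2y, n_snps_y=n_gy,
                                              n_instrument_snps=n_inst,
                                              p_assort=p, assortment=_CROSS_XY)))
    elif name == "table2":
        for h2x in (0.1, 0.5):
            for h2y in (0.1, 0.5):
                sid = f"table2_h2x{h2x}_h2y{h2y}"
                out.append((sid, _cfg(h2_x=h2x, h2_y=h2y, beta_xy=0.05)))
    elif name == "figure2":
        for p in (0.2, 0.4, 0.6, 0.8, 1.0):
            for h2x in (0.1, 0.5):
                for h2y in (0.1, 0.5):
                    sid = f"figure2_P{p}_h2x{h2x}_h2y{h2y}"
                    out.append((sid, _cfg(h2_x=h2x, h2_y=h2y, p_assort=p,
                                          assortment=_CROSS_XY)))
    elif name == "figure3":
        for g in range(1, 10):
            out.append((f"figure3_gen{g}",
                        _cfg(p_assort=0.7, assortment=_CROSS_XY, n_generations=g)))
    elif name == "single_trait_suite":
        # single-trait assortment on: X (no bias), Y (no bias), and a trait
        # genetically correlated with both X and Y via horizontal or vertical
        # pleiotropy (bias)
        out.append(("single_X", _cfg(p_assort=0.6, assortment=AssortmentSpec(
            pattern="single_trait", trait_a="X"))))
        out.append(("single_Y", _cfg(p_assort=0.6, assortment=AssortmentSpec(
            pattern="single_trait", trait_a="Y"))))
        for kind in ("horizontal", "vertical"):
            out.append((f"single_both_{kind}", _cfg(
                p_assort=0.6, phenotype_defs=_aux_defs(kind),
                assortment=AssortmentSpec(pattern="single_trait", trait_a="AB"))))
    elif name == "cross_trait_correlated_suite":
        for kind in ("horizontal", "vertical"):
            out.append((f"cross_aux_{kind}", _cfg(
                p_assort=0.6, phenotype_defs=_aux_defs(kind),
                assortment=AssortmentSpec(pattern="cross_trait",
                                          trait_a="AX", trait_b="AY"))))
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return out
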