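"""Desk-scale versions of the three simulation studies.

Study 1 (lexical retrieval): activation starts on the target of a
two-hop neighborhood network and the target's final activation is a
proxy for retrieval efficiency.  Study 2 (false memory, DRM-style): the
same networks, but the budget is split equally over the target's
neighbors and the non-studied target's final activation proxies the
false-alarm rate.  Study 3 (semantic priming): activation starts on a
related or unrelated prime in a semantic network and the target's final
activation proxies the priming advantage.

Each study is expressed as a factorial run manifest (one row per
network/initialization/parameter cell) executed deterministically, with
standardized-OLS summaries, matched low-minus-high clustering
difference scores, and a related-vs-unrelated priming contrast as the
readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .engine import SimParams, simulate, state_at
from .metrics import (
    SemanticTestbed,
    TwoHopNetwork,
    local_clustering,
    make_semantic_testbed,
    make_two_hop_testbed,
)

__all__ = [
    "init_target",
    "init_neighbors",
    "init_prime",
    "build_manifest",
    "execute_manifest",
    "standardized_ols",
    "OlsSummary",
    "difference_scores",
    "priming_contrast",
    "make_matched_pair_suite",
    "run_clustering_study",
    "run_priming_study",
    "DEFAULT_RETENTION_GRID",
    "PRIMING_RETENTION_GRID",
]

DEFAULT_RETENTION_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 10))
PRIMING_RETENTION_GRID: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
ACTIVATION_BUDGET = 100.0
DEFAULT_TIME_STEPS = 10


# -- initialization schemes ------------------------------------------------

def init_target(testbed: TwoHopNetwork, budget: float = ACTIVATION_BUDGET):
    """All of the budget on the target node (lexical-retrieval scheme)."""
    if budget <= 0:
        raise ValueError("budget must be > 0")
    return [(testbed.target, float(budget))]


def init_neighbors(testbed: TwoHopNetwork, budget: float = ACTIVATION_BUDGET):
    """budget / deg(target) on each one-hop neighbor, none on the target.

    Mirrors the false-memory study phase: the target's associates are
    presented, the target itself is not.  The total equals the budget
    exactly for every target degree.
    """
    if budget <= 0:
        raise ValueError("budget must be > 0")
    deg = testbed.network.degree(testbed.target)
    if deg == 0:
        raise ValueError(f"target {testbed.target!r} has degree 0")
    per = float(budget) / deg
    return [(nbr, per) for nbr in sorted(testbed.one_hop)]


def init_prime(testbed: SemanticTestbed, prime: str, budget: float = ACTIVATION_BUDGET):
    """All of the budget on the prime (semantic-priming scheme)."""
    testbed.network.require_node(prime)
    if budget <= 0:
        raise ValueError("budget must be > 0")
    return [(prime, float(budget))]


# -- manifests -------------------------------------------------------------

def build_manifest(
    units: list[dict],
    retention_grid,
    scheme: str,
    time_steps: int = DEFAULT_TIME_STEPS,
    decay: float = 0.0,
    suppress: float = 0.0,
) -> pd.DataFrame:
    """Full factorial of run units x retention values, one row per run.

    Each unit dict identifies a network and readout (and, for the
    priming scheme, the prime and prime type); the grid is crossed in
    deterministic order.
    """
    if not units:
        raise ValueError("units must be non-empty")
    retention_grid = list(retention_grid)
    if not retention_grid:
        raise ValueError("retention_grid must be non-empty")
    rows = []
    for unit in units:
        for r in retention_grid:
            row = dict(unit)
            row.update(
                scheme=scheme,
                retention=float(r),
                decay=float(decay),
                suppress=float(suppress),
                time_steps=int(time_steps),
            )
            rows.append(row)
    manifest = pd.DataFrame(rows)
    if manifest.duplicated().any():
        raise ValueError("manifest rows are not unique")
    return manifest


def execute_manifest(
    manifest: pd.DataFrame,
    networks: dict[str, TwoHopNetwork | SemanticTestbed],
) -> pd.DataFrame:
    """Run every manifest row and record the readout node's final activation.

    The readout is the target's activation at the final time step; the
    returned table carries the manifest columns plus ``final_activation``
    (and the structural covariates already present in the manifest).
    Execution is deterministic: all randomness lives in network
    generation.
    """
    out = []
    for _, row in manifest.iterrows():
        testbed = networks[row["network_id"]]
        params = SimParams(
            retention=row["retention"],
            decay=row["decay"],
            suppress=row["suppress"],
            time_steps=int(row["time_steps"]),
        )
        scheme = row["scheme"]
        if scheme == "target":
            init = init_target(testbed)
            readout = testbed.target
        elif scheme == "neighbors":
            init = init_neighbors(testbed)
            readout = testbed.target
        elif scheme == "prime":
            init = init_prime(testbed, row["prime"])
            readout = row["target"]
        else:
            raise ValueError(f"unknown initialization scheme: {scheme!r}")
        try:
            history = simulate(testbed.network, init, params)
        except Exception as exc:  # attach row identity to failures
            raise RuntimeError(
                f"simulation failed for manifest row {row.to_dict()}"
            ) from exc
        final = state_at(history, params.time_steps)
        rec = row.to_dict()
        rec["final_activation"] = final.activation[readout]
        out.append(rec)
    return pd.DataFrame(out)


# -- statistical summaries -------------------------------------------------

@dataclass
class OlsSummary:
    """Coefficient table plus fit statistics of a standardized OLS."""

    coefficients: pd.DataFrame  # beta, se, t, p per predictor
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int


def standardized_ols(
    results: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    standardize_outcome: bool = True,
) -> OlsSummary:
    """OLS with z-scored predictors (and, by default, z-scored outcome).

    Reports standardized betas with SE, two-sided t tests, adjusted R²
    and the model F.  Set ``standardize_outcome=False`` to keep the
    outcome on its raw scale (betas then carry the outcome's units per
    predictor SD).
    """
    if len(results) <= len(predictors) + 1:
        raise ValueError("not enough rows to fit the model")
    y = results[outcome].astype(float)
    if y.std(ddof=0) == 0:
        raise ValueError(f"outcome {outcome!r} has zero variance")
    if standardize_outcome:
        y = (y - y.mean()) / y.std(ddof=1)
    x = results[predictors].astype(float)
    sds = x.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds[sds == 0].index)
        raise ValueError(f"predictors with zero variance (rank deficient): {bad}")
    x = (x - x.mean()) / sds
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    coef = pd.DataFrame(
        {
            "beta": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).drop(index="const")
    return OlsSummary(
        coefficients=coef,
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
    )


def difference_scores(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Low-C minus high-C differences of z-scored final activations.

    Expects matched pairs: for every (degree, retention) cell exactly one
    ``c_level == "low"`` and one ``c_level == "high"`` row.  Final
    activations are z-scored across the whole table first; the
    per-degree summary averages the per-retention differences.
    Returns (per-cell table, per-degree summary with mean/sd/se).
    """
    req = {"degree", "retention", "c_level", "final_activation"}
    missing = req - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns: {sorted(missing)}")
    z = results.copy()
    z["z_final"] = (
        z["final_activation"] - z["final_activation"].mean()
    ) / z["final_activation"].std(ddof=1)
    wide = z.pivot_table(
        index=["degree", "retention"], columns="c_level", values="z_final"
    )
    if not {"low", "high"} <= set(wide.columns):
        raise ValueError(
            "unmatched low/high pairs: results lack one of the c_level sides "
            f"(found {list(wide.columns)})"
        )
    orphans = wide[wide.isna().any(axis=1)]
    if not orphans.empty:
        raise ValueError(
            f"unmatched low/high pairs at cells: {list(orphans.index)}"
        )
    cells = wide.reset_index()
    cells["difference"] = cells["low"] - cells["high"]
    per_degree = (
        cells.groupby("degree")["difference"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    per_degree["se"] = per_degree["sd"] / np.sqrt(per_degree["n"])
    return cells[["degree", "retention", "low", "high", "difference"]], per_degree


def priming_contrast(
    results: pd.DataFrame, n_boot: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Related-vs-unrelated mean target activation per retention value.

    Requires paired related/unrelated rows for every (target, retention)
    cell.  The paired difference gets a percentile bootstrap interval
    over targets (resampling seeded for reproducibility).
    """
    req = {"target", "retention", "prime_type", "final_activation"}
    missing = req - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns: {sorted(missing)}")
    wide = results.pivot_table(
        index=["target", "retention"], columns="prime_type", values="final_activation"
    )
    if wide.isna().any().any() or not {"related", "unrelated"} <= set(wide.columns):
        bad = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"unpaired related/unrelated runs: {bad}")
    rng = np.random.default_rng(int(seed))
    rows = []
    for r, block in wide.groupby(level="retention"):
        diff = (block["related"] - block["unrelated"]).to_numpy()
        n = len(diff)
        boots = rng.integers(0, n, size=(n_boot, n))
        boot_means = diff[boots].mean(axis=1)
        rows.append(
            {
                "retention": float(r),
                "mean_related": float(block["related"].mean()),
                "mean_unrelated": float(block["unrelated"].mean()),
                "mean_difference": float(diff.mean()),
                "ci_low": float(np.quantile(boot_means, 0.025)),
                "ci_high": float(np.quantile(boot_means, 0.975)),
                "n_pairs": n,
            }
        )
    return pd.DataFrame(rows)


# -- study drivers ---------------------------------------------------------

def make_matched_pair_suite(
    degrees=range(3, 15),
    c_low: float = 0.1,
    c_high: float = 0.7,
    outer_per_neighbor: int = 2,
    seed: int = 0,
) -> dict[str, TwoHopNetwork]:
    """Matched low/high clustering two-hop networks, one pair per degree.

    Per-network seeds are fanned out deterministically from the master
    seed (SeedSequence splitting), so the suite is a pure function of
    its arguments.
    """
    degrees = list(degrees)
    seeds = np.random.SeedSequence(int(seed)).generate_state(2 * len(degrees)) % (2**31)
    suite: dict[str, TwoHopNetwork] = {}
    for i, k in enumerate(degrees):
        suite[f"k{k}_low"] = make_two_hop_testbed(
            k, c_low, outer_per_neighbor, int(seeds[2 * i])
        )
        suite[f"k{k}_high"] = make_two_hop_testbed(
            k, c_high, outer_per_neighbor, int(seeds[2 * i + 1])
        )
    return suite


def run_clustering_study(
    scheme: str,
    degrees=range(3, 15),
    retention_grid=DEFAULT_RETENTION_GRID,
    c_low: float = 0.1,
    c_high: float = 0.7,
    outer_per_neighbor: int = 2,
    time_steps: int = DEFAULT_TIME_STEPS,
    seed: int = 0,
) -> dict:
    """Run the lexical-retrieval ("target") or false-memory ("neighbors") study.

    Builds matched low/high-C two-hop testbeds over the degree grid,
    executes the full factorial against the retention grid with decay
    and suppression at 0, and returns the result table, the standardized
    OLS on retention + degree + clustering, and the matched difference
    scores.
    """
    suite = make_matched_pair_suite(degrees, c_low, c_high, outer_per_neighbor, seed)
    units = []
    for net_id, tb in suite.items():
        units.append(
            {
                "network_id": net_id,
                "target": tb.target,
                "degree": tb.network.degree(tb.target),
                "clustering": local_clustering(tb.network, tb.target),
                "c_level": "low" if net_id.endswith("low") else "high",
            }
        )
    manifest = build_manifest(units, retention_grid, scheme, time_steps)
    results = execute_manifest(manifest, suite)
    ols = standardized_ols(
        results, "final_activation", ["retention", "degree", "clustering"]
    )
    cells, per_degree = difference_scores(results)
    return {
        "networks": suite,
        "manifest": manifest,
        "results": results,
        "ols": ols,
        "difference_cells": cells,
        "difference_by_degree": per_degree,
    }


def run_priming_study(
    n_words: int = 500,
    n_pairs: int = 50,
    retention_grid=PRIMING_RETENTION_GRID,
    time_steps: int = DEFAULT_TIME_STEPS,
    attachment: int = 2,
    seed: int = 0,
) -> dict:
    """Run the semantic-priming study on a generated association network.

    Each target is probed twice per retention value — once from its
    related prime, once from its unrelated prime, 100 activation units
    on the prime either way — and the target's activation after
    ``time_steps`` steps is compared across prime types.
    """
    testbed = make_semantic_testbed(n_words, n_pairs, attachment, seed)
    units = []
    for target, related, unrelated in testbed.triples:
        for prime_type, prime in (("related", related), ("unrelated", unrelated)):
            units.append(
                {
                    "network_id": "semantic",
                    "target": target,
                    "prime": prime,
                    "prime_type": prime_type,
                }
            )
    manifest = build_manifest(units, retention_grid, "prime", time_steps)
    results = execute_manifest(manifest, {"semantic": testbed})
    contrast = priming_contrast(results, seed=seed)
    return {
        "testbed": testbed,
        "manifest": manifest,
        "results": results,
        "contrast": contrast,
    }
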