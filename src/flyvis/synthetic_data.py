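"""Synthetic trees, regimes and trait data with the structure the models assume.

The generator emulates the study conditions: an ultrametric pure-birth tree
rescaled to root depth 1, a binary host-finding regime (either painted onto
one clade or evolved as a two-state Markov process), a Brownian-motion
body-size predictor, and a response trait following a regime-dependent
Ornstein-Uhlenbeck process simulated by exact node-to-node transitions

    child ~ Normal(parent*exp(-a*t) + theta*(1-exp(-a*t)),
                   v_y*(1 - exp(-2*a*t)))

per branch (each branch carries a single regime).  Optionally the response
tracks an optimum that is itself a linear function of the moving predictor,
integrated by Euler-Maruyama; this is the oracle path for the
random-predictor model.  Traits are simulated on log scale, exponentiated
into micrometre-like values, and perturbed with specimen-level lognormal
noise before being summarised into species means, SEs and sample sizes --
the shape of the packaged study tables.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io_fixtures import NON_SAT, SAT, RegimeAssignment, SpeciesTraitTable
from .regimes import RegimePainting
from .trees import UltrametricTree

LN2 = math.log(2.0)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Study-scale defaults for the trait simulator.

    The response is generated on natural-log scale (think ln eye area in
    ln um^2) and exponentiated for the emitted table; the predictor mimics
    ln head width around ln 2000 um.  Half-life and variances are in units
    of the tree depth (= 1).  Specimen noise is lognormal with a 5%
    coefficient of variation, the middle of the 2-8% relative SEs seen in
    the study tables, with 7 specimens per species (the study's median).
    """

    n_tips: int = 18
    seed: int | None = None
    t_half_true: float = 0.1
    v_y_true: float = 0.05
    optima: dict[str, float] = field(
        default_factory=lambda: {SAT: 13.4, NON_SAT: 12.9}
    )
    bm_root: float = 7.6
    bm_sigma2: float = 0.1
    bm_slope: float | None = None  # if set, theta(x) = bm_intercept + bm_slope*x
    bm_intercept: float = 0.0
    dt: float = 1e-3
    specimen_cv: float = 0.05
    n_specimens: int = 7
    response_name: str = "E_area"
    predictor_name: str = "H_width"

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.v_y_true < 0 or self.bm_sigma2 < 0:
            raise ValueError("variances must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


# ----------------------------------------------------------------------- tree
def simulate_tree(n_tips: int, seed=None) -> UltrametricTree:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips, depth rescaled to 1."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31))
    pyrng = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=pyrng,
    )
    # snap terminal branches onto the maximum root-to-tip depth (the
    # simulator is ultrametric only up to float accumulation error), then
    # extend all tips to the next would-be speciation time: the simulator
    # stops exactly at the n-th birth, which would leave a zero-length
    # cherry, and the extension keeps the process a valid Yule sample
    depths = {leaf: leaf.distance_from_root() for leaf in dtree.leaf_node_iter()}
    maxd = max(depths.values())
    extra = pyrng.expovariate(float(n_tips))
    for leaf, d in depths.items():
        leaf.edge.length += maxd - d + extra
    for i, leaf in enumerate(sorted(dtree.leaf_node_iter(), key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"t{i + 1:03d}"
    return UltrametricTree.from_dendropy(dtree, rescale=True)


# -------------------------------------------------------------------- regimes
def _painting_from_node_states(tree: UltrametricTree, node_state: dict[int, str]) -> RegimePainting:
    branch = {n: s for n, s in node_state.items() if n != 0}
    n_changes = sum(
        1 for n in branch if node_state[n] != node_state[int(tree.parent[n])]
    )
    return RegimePainting(
        branch_regime=branch,
        root_regime=node_state[0],
        n_changes=n_changes,
        node_state=dict(sorted(node_state.items())),
    )


def simulate_regimes(
    tree: UltrametricTree,
    mode: str = "clade_paint",
    seed=None,
    *,
    rate: float = 1.0,
    target_clade_size: int | None = None,
    root_state: str = NON_SAT,
):
    """Binary regime data for a tree, with the generating painting as truth.

    ``clade_paint`` assigns SAT to the clade whose tip count is closest to
    ``target_clade_size`` (default: half the tips), emulating a single
    origin of the derived behaviour.  ``markov`` evolves a symmetric
    two-state process at ``rate`` flips per unit branch length from
    ``root_state``.  Returns (RegimeAssignment, RegimePainting, info).
    """
    rng = _rng(seed)
    states = {SAT, NON_SAT}
    other = {SAT: NON_SAT, NON_SAT: SAT}
    if root_state not in states:
        raise ValueError(f"unknown root state {root_state!r}")

    if mode == "clade_paint":
        target = target_clade_size if target_clade_size is not None else tree.n_tips // 2
        if target > tree.n_tips:
            raise ValueError(
                f"requested clade of {target} tips exceeds the {tree.n_tips}-tip tree"
            )
        candidates = [
            (len(tree.clade_tips(n)), n)
            for n in range(1, tree.n_nodes)
            if tree.children[n]  # internal, non-root
        ]
        if not candidates:
            raise ValueError("tree has no internal non-root clade to paint")
        size, node = min(candidates, key=lambda c: (abs(c[0] - target), c[1]))
        derived = other[root_state]
        node_state = {0: root_state}
        in_clade = set()

        def mark(i):
            in_clade.add(i)
            for c in tree.children[i]:
                mark(c)

        mark(node)
        for n in range(1, tree.n_nodes):
            node_state[n] = derived if n in in_clade else root_state
        info = {"clade_node": node, "clade_size": size, "n_events": 1}
    elif mode == "markov":
        node_state = {0: root_state}
        n_events = 0
        for n in range(1, tree.n_nodes):
            state = node_state[int(tree.parent[n])]
            t = 0.0
            length = float(tree.edge_length[n])
            while rate > 0:
                t += rng.exponential(1.0 / rate)
                if t >= length:
                    break
                state = other[state]
                n_events += 1
            node_state[n] = state
        info = {"n_events": n_events}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    painting = _painting_from_node_states(tree, node_state)
    assignment = RegimeAssignment(
        regime={
            tree.labels[i]: node_state[int(i)] for i in tree.tip_indices
        }
    )
    return assignment, painting, info


# --------------------------------------------------------------------- traits
def simulate_tip_values(
    tree: UltrametricTree,
    painting: RegimePainting,
    config: SimulationConfig,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact node-to-node simulation of (predictor x, response y) at the tips.

    x is Brownian motion from ``bm_root``.  y starts at the root regime's
    optimum and relaxes toward the regime optimum of each branch; if
    ``bm_slope`` is set, the optimum instead tracks theta(x) = bm_intercept
    + bm_slope * x and the pair is integrated by Euler-Maruyama with step
    ``dt``.  Values are on the (log) process scale, ordered as
    ``tree.tip_labels``.
    """
    rng = _rng(seed)
    alpha = math.inf if config.t_half_true == 0 else LN2 / config.t_half_true
    v_y = config.v_y_true
    sigma2 = 2.0 * alpha * v_y if np.isfinite(alpha) else math.inf

    theta_of = lambda node: config.optima[painting.regime_of(node)]
    x_val = {0: config.bm_root}
    y_val = {0: theta_of(0) if config.bm_slope is None
             else config.bm_intercept + config.bm_slope * config.bm_root}

    for n in range(1, tree.n_nodes):
        par = int(tree.parent[n])
        t = float(tree.edge_length[n])
        theta = theta_of(n)
        if config.bm_slope is None:
            x_val[n] = x_val[par] + rng.normal(0.0, math.sqrt(config.bm_sigma2 * t))
            if np.isinf(alpha):
                y_val[n] = theta + rng.normal(0.0, math.sqrt(v_y))
            else:
                e = math.exp(-alpha * t)
                mean = y_val[par] * e + theta * (1.0 - e)
                var = v_y * (-math.expm1(-2.0 * alpha * t))
                y_val[n] = mean + rng.normal(0.0, math.sqrt(var))
        else:
            steps = max(1, int(math.ceil(t / config.dt)))
            h = t / steps
            x, y = x_val[par], y_val[par]
            for _ in range(steps):
                x_new = x + rng.normal(0.0, math.sqrt(config.bm_sigma2 * h))
                target = config.bm_intercept + config.bm_slope * x
                y = y - alpha * (y - target) * h + rng.normal(
                    0.0, math.sqrt(sigma2 * h)
                )
                x = x_new
            x_val[n], y_val[n] = x, y

    tips = tree.tip_indices
    x = np.array([x_val[int(i)] for i in tips])
    y = np.array([y_val[int(i)] for i in tips])
    return x, y


def simulate_ou_traits(
    tree: UltrametricTree,
    painting: RegimePainting,
    config: SimulationConfig,
    seed=None,
) -> tuple[SpeciesTraitTable, dict]:
    """Simulate a species trait table (+ ground truth) under the OU model.

    Tip-level process values are exponentiated to micrometre-like scales,
    replicated into ``n_specimens`` lognormal specimen measurements with
    coefficient of variation ``specimen_cv``, and summarised per species
    into mean, SE (sd/sqrt(n); missing for n = 1) and n.
    """
    rng = _rng(seed)
    x, y = simulate_tip_values(tree, painting, config, seed=rng)
    labels = tree.tip_labels
    sigma_ln = math.sqrt(math.log1p(config.specimen_cv**2))

    rows = {}
    for i, label in enumerate(labels):
        row = {}
        for name, log_value in ((config.predictor_name, x[i]), (config.response_name, y[i])):
            value = math.exp(log_value)
            if config.n_specimens == 1 or config.specimen_cv == 0:
                draws = np.full(config.n_specimens, value)
            else:
                draws = value * np.exp(
                    rng.normal(-0.5 * sigma_ln**2, sigma_ln, config.n_specimens)
                )
            row[f"{name}_mean"] = float(draws.mean())
            row[f"{name}_se"] = (
                float(draws.std(ddof=1) / math.sqrt(len(draws)))
                if len(draws) > 1
                else np.nan
            )
            row[f"{name}_n"] = config.n_specimens
        rows[label] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species_id"
    table = SpeciesTraitTable(df.loc[labels])

    truth = {
        "t_half": config.t_half_true,
        "v_y": config.v_y_true,
        "optima": dict(config.optima),
        "bm_root": config.bm_root,
        "bm_sigma2": config.bm_sigma2,
        "bm_slope": config.bm_slope,
        "bm_intercept": config.bm_intercept,
        "tip_log_predictor": {l: float(v) for l, v in zip(labels, x)},
        "tip_log_response": {l: float(v) for l, v in zip(labels, y)},
    }
    return table, truth
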