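"""Seeded generators for trees and trait data.

The generator emulates the structure of a genus-level primate comparative
dataset: an ultrametric pure-birth (Yule) tree of extant taxa scaled to a
calibrated crown age, fossil tips grafted at interior nodes with their
last-occurrence ages, log10 body mass evolving by Brownian motion from a
small-bodied root, and log10 brain mass generated from body mass through a
linear log-log allometry plus a Brownian residual that may carry a
directional trend (brain drifts, body does not).

All generators take explicit integer seeds and use no global random state;
identical seeds give byte-identical output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .tree import Phylogeny, TraitTable


@dataclass
class SimConfig:
    """Study-condition defaults: 37 extant + 23 fossil taxa on a 77-Myr
    crown, allometric slope 0.684 with intercept -0.82 on the grams scale,
    Brownian body mass (alpha 0.02 /Myr from a ~300 g root) and a residual
    rate (0.0015 /Myr) tuned to an extant brain~body R^2 near 0.86."""

    n_extant: int = 37
    n_fossils: int = 23
    height: float = 77.0            # Myr, crown age
    birth_rate: float = 0.1         # /Myr (topology only; tree is rescaled)
    alpha_body: float = 0.02        # log10^2 / Myr
    alpha_resid: float = 0.0015     # log10^2 / Myr
    beta_brain: float = 0.0         # directional trend in residual, /Myr
    slope: float = 0.684
    intercept: float = -0.82        # log10 g scale
    root_log_body: float = 2.5      # log10 g
    seed: int = 0

    def validate(self):
        if self.n_extant < 2:
            raise ValueError("need at least 2 extant taxa")
        for name in ("height", "birth_rate", "alpha_body", "alpha_resid"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self):
        return asdict(self)


@dataclass
class SimTruth:
    """True node states and generating parameters for a simulated dataset."""

    log_body: np.ndarray            # per node, postorder
    residual: np.ndarray
    log_brain: np.ndarray
    config: SimConfig

    def to_dict(self):
        return {"log_body": self.log_body.tolist(),
                "residual": self.residual.tolist(),
                "log_brain": self.log_brain.tolist(),
                "config": self.config.to_dict()}


def simulate_tree(config=None, **overrides):
    """Seeded pure-birth tree, rescaled to the requested height, with
    optional fossil tips grafted at uniformly chosen interior nodes."""
    config = _resolve(config, overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_extant

    # Yule process: split times and random lineage choice
    records = [["t1", 0.0, []], ["t2", 0.0, []]]  # active lineage records
    birth_time = {id(records[0]): 0.0, id(records[1]): 0.0}
    root = [None, 0.0, records[:]]
    t = 0.0
    k = 2
    while k < n:
        t += rng.exponential(1.0 / (config.birth_rate * k))
        i = rng.integers(k)
        parent_rec = records[i]
        c1 = [parent_rec[0], 0.0, []]
        c2 = [f"t{k + 1}", 0.0, []]
        parent_rec[0] = None
        parent_rec[2] = [c1, c2]
        parent_rec[1] = t - birth_time.pop(id(parent_rec))
        # length will be finalised when children close; store birth times
        birth_time[id(c1)] = t
        birth_time[id(c2)] = t
        records[i] = c1
        records.append(c2)
        k += 1
    t_end = t + rng.exponential(1.0 / (config.birth_rate * n))
    for rec in records:
        rec[1] = t_end - birth_time.pop(id(rec))
    # rescale to requested height
    scale = config.height / t_end if t_end > 0 else 1.0

    def rescale(rec):
        rec[1] *= scale
        for c in rec[2]:
            rescale(c)

    rescale(root)
    root[1] = 0.0
    tree = Phylogeny._from_nested(root)

    for f in range(config.n_fossils):
        interior = [i for i in tree.internal_nodes if i != tree.root]
        candidates = interior if interior else list(tree.internal_nodes)
        node = int(candidates[rng.integers(len(candidates))])
        age = float(tree.node_ages[node])
        last_occ = float(rng.uniform(0.0, age)) if age > 0 else 0.0
        tree = tree.graft_fossil(node, f"fossil{f + 1}", last_occ)
    return tree


def simulate_traits(tree, config=None, **overrides):
    """Brownian body mass and (optionally trending) residual on a tree.

    Body mass evolves as BM(alpha_body) from ``root_log_body`` with no
    trend; the allometric residual evolves as BM(alpha_resid) from 0 with
    drift ``beta_brain`` per Myr; log brain mass is
    ``intercept + slope * log_body + residual`` at every node.

    Returns ``(TraitTable, SimTruth)``; tip values in the truth record are
    exactly the values emitted in the table.
    """
    config = _resolve(config, overrides)
    rng = np.random.default_rng(config.seed + 1)  # distinct from topology
    n = tree.n_nodes
    body = np.empty(n)
    resid = np.empty(n)
    body[tree.root] = config.root_log_body
    resid[tree.root] = 0.0
    for i in range(n - 2, -1, -1):  # preorder: parents before children
        p = tree.parent[i]
        l = tree.lengths[i]
        body[i] = body[p] + rng.normal(0.0, np.sqrt(config.alpha_body * l))
        resid[i] = (resid[p] + config.beta_brain * l
                    + rng.normal(0.0, np.sqrt(config.alpha_resid * l)))
    brain = config.intercept + config.slope * body + resid
    tips = tree.tips
    ages = tree.node_ages
    table = TraitTable.from_masses(
        [tree.labels[i] for i in tips],
        10.0 ** brain[tips], 10.0 ** body[tips],
        [abs(ages[i]) < 1e-9 for i in tips])
    return table, SimTruth(log_body=body, residual=resid, log_brain=brain,
                           config=config)


def simulate_dataset(config=None, **overrides):
    """Convenience: tree + traits + truth from one config/seed."""
    config = _resolve(config, overrides)
    tree = simulate_tree(config)
    traits, truth = simulate_traits(tree, config)
    return tree, traits, truth


_FIXTURE_SEED = 20100127


def primate_fixture():
    """Deterministic primate-like dataset: 37 extant genera and 23 fossil
    tips on a 77-Myr crown, with a positive brain trend (0.005 /Myr).

    Returns ``(Phylogeny, TraitTable)``; the same objects are produced on
    every call and platform.
    """
    cfg = SimConfig(beta_brain=0.005, seed=_FIXTURE_SEED)
    tree, traits, _ = simulate_dataset(cfg)
    return tree, traits


def _resolve(config, overrides):
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**config.to_dict(), **overrides})
    return config
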