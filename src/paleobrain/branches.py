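"""Per-branch evolutionary change statistics.

Node values are log10 masses (observed at tips, reconstructed at internal
nodes).  The difference of consecutive log values along a branch is a
proportional change; differences of back-transformed raw masses give the
absolute change; dividing by branch length gives rates per Myr.  A census
of decreasing branches supports the dwarfism scenario analysis: for every
branch on which brain mass decreases, the ratio of the log brain change to
the log body change records how brain mass scaled with body mass during
that reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class QuartileSummary:
    mean: float
    upper_quartile: float           # 75th percentile of delta_log
    upper_branches: pd.DataFrame    # branches above threshold, ranked


@dataclass
class DecreaseCensus:
    trait: str
    n_branches: int
    n_decreasing: int
    fraction_branches: float
    fraction_time: float
    ratios: list = field(default_factory=list)   # brain/body log-change ratios
    ratio_mean: float = np.nan
    ratio_min: float = np.nan
    ratio_max: float = np.nan


def branch_changes(tree, node_values, trait="trait"):
    """Change statistics for every branch of the tree.

    ``node_values`` maps every node id (or is an array over all nodes, in
    postorder) to a log10 value.  Returns a DataFrame with one row per
    branch (child node id as index): parent, child, length_myr, delta_log,
    delta_abs, prop_change (10**delta_log - 1), rate_log, rate_abs and the
    decrease flag.  Rates on zero-length branches are NaN and flagged.
    """
    n = tree.n_nodes
    if isinstance(node_values, dict):
        missing = set(range(n)) - set(node_values)
        if missing:
            raise ValueError(f"missing node values for nodes {sorted(missing)}")
        v = np.array([node_values[i] for i in range(n)], float)
    else:
        v = np.asarray(node_values, float)
        if v.size != n:
            raise ValueError("need a value for every node")
    if not np.isfinite(v).all():
        raise ValueError("non-finite node values")
    rows = []
    for child in range(n - 1):
        parent = int(tree.parent[child])
        l = float(tree.lengths[child])
        dlog = v[child] - v[parent]
        dabs = 10.0 ** v[child] - 10.0 ** v[parent]
        rows.append({
            "parent": parent, "child": child,
            "child_label": tree.labels[child],
            "trait": trait, "length_myr": l,
            "delta_log": dlog, "delta_abs": dabs,
            "prop_change": 10.0 ** dlog - 1.0,
            "rate_log": dlog / l if l > 0 else np.nan,
            "rate_abs": dabs / l if l > 0 else np.nan,
            "zero_length": l == 0.0,
            "decrease": dlog < 0,
        })
    return pd.DataFrame(rows).set_index("child", drop=False)


def quartile_summary(changes):
    """Mean and upper-quartile threshold of per-branch log changes.

    The 75th percentile uses linear interpolation between closest ranks;
    branches strictly above the threshold are listed in descending order.
    """
    d = changes["delta_log"].to_numpy(float)
    if d.size < 4:
        raise ValueError("need at least 4 branches for quartiles")
    q75 = float(np.percentile(d, 75))
    upper = changes[changes["delta_log"] > q75].sort_values(
        "delta_log", ascending=False)
    return QuartileSummary(mean=float(d.mean()), upper_quartile=q75,
                           upper_branches=upper)


def decrease_ratio(delta_log_brain, delta_log_body):
    """Ratio of log brain change to log body change along one branch.

    Unit-invariant: converting both masses (say g to mg) before taking logs
    shifts ancestor and descendant equally and leaves the ratio unchanged.
    """
    if delta_log_body == 0:
        raise ValueError("zero body-mass change: ratio undefined")
    return delta_log_brain / delta_log_body


def decrease_census(brain_changes, body_changes=None, trait="brain"):
    """Census of decreasing branches (and brain/body scaling ratios).

    ``brain_changes`` (and optionally ``body_changes``, aligned on the same
    branches) come from :func:`branch_changes`.  The time fraction is the
    summed length of decreasing branches over the total tree length.  When
    body changes are supplied, the per-branch ratio
    ``delta_log_brain / delta_log_body`` is recorded for each decreasing
    brain branch (branches with zero body change are skipped).
    """
    ch = brain_changes
    dec = ch[ch["decrease"]]
    total_time = float(ch["length_myr"].sum())
    ratios = []
    if body_changes is not None:
        if not ch.index.equals(body_changes.index):
            raise ValueError("brain and body change tables are not aligned")
        for idx in dec.index:
            db = float(body_changes.loc[idx, "delta_log"])
            if db != 0:
                ratios.append(decrease_ratio(float(dec.loc[idx, "delta_log"]),
                                             db))
    n = len(ch)
    nd = len(dec)
    return DecreaseCensus(
        trait=trait, n_branches=n, n_decreasing=nd,
        fraction_branches=nd / n if n else 0.0,
        fraction_time=(float(dec["length_myr"].sum()) / total_time
                       if total_time > 0 else 0.0),
        ratios=ratios,
        ratio_mean=float(np.mean(ratios)) if ratios else np.nan,
        ratio_min=float(np.min(ratios)) if ratios else np.nan,
        ratio_max=float(np.max(ratios)) if ratios else np.nan)


def write_branch_changes(changes, path):
    cols = ["parent", "child", "length_myr", "trait", "delta_log",
            "delta_abs", "prop_change", "rate_log", "rate_abs", "decrease"]
    changes[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
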