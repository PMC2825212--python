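"""End-to-end analysis pipeline.

Runs, in order: the PGLS allometry fit (with branch-scaling LR tests),
tip residual computation, ancestral reconstruction by the requested
methods with and without fossil tips, congruence tables between methods
and between the two tree variants, the directional-trend Bayes-factor
table, the branch-change census, and (optionally) the dwarfism scenario
grid.  Every table is written as TSV next to a JSON manifest recording the
resolved configuration, seeds and MCMC acceptance rates; identical
configurations and seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, branches, reconstruct, scenarios as scen
from .model import PGLS, BrownianMotion, lr_test
from .reconstruct import McmcSettings
from .tree import (TraitTable, read_newick_file, read_trait_table,
                   matched_internal_nodes)

log = logging.getLogger("paleobrain")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class RunConfig:
    tree_path: str = None
    traits_path: str = None
    out_dir: str = "paleobrain_out"
    methods: tuple = ("parsimony", "ml", "mcmc")
    directional: bool = True          # run the trend test
    estimate_kappa: bool = True       # test scaling params in the PGLS
    estimate_lambda: bool = True
    estimate_delta: bool = True
    no_fossils: bool = False          # drop extinct tips before analysis
    mcmc_iterations: int = 50_000
    mcmc_burn_in: int = 10_000
    mcmc_thin: int = 10
    prior_low: float = -100.0
    prior_high: float = 100.0
    seed: int = 0
    scenario_grid: bool = False
    descendant_brain_g: float = 380.0
    descendant_body_kg: tuple = (16.0, 24.0, 32.0)

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        d["descendant_body_kg"] = list(self.descendant_body_kg)
        return d

    def mcmc_settings(self, seed_offset=0):
        return McmcSettings(iterations=self.mcmc_iterations,
                            burn_in=self.mcmc_burn_in, thin=self.mcmc_thin,
                            prior_low=self.prior_low,
                            prior_high=self.prior_high,
                            seed=self.seed + seed_offset)


def _tsv(df, path):
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_full_analysis(config, tree=None, traits=None):
    """Execute the full pipeline; returns a dict of result tables.

    ``tree``/``traits`` may be passed directly (e.g. from the simulators);
    otherwise they are read from the paths in ``config``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "warnings": [],
                "acceptance_rates": {}}
    results = {}

    def stage(name):
        manifest["_stage"] = name
        log.info("stage: %s", name)

    try:
        stage("load")
        if tree is None:
            tree = read_newick_file(config.tree_path)
        if traits is None:
            traits = read_trait_table(config.traits_path)
        traits.validate_against(tree)
        full_tree = tree
        if config.no_fossils:
            fossils = [t for t in traits.fossil_taxa if t in tree.tip_labels]
            if fossils:
                tree = tree.drop_tips(fossils)
                traits = traits.subset(
                    [t for t in traits.taxa if t not in fossils])
        taxa = [t for t in traits.taxa if t in set(tree.tip_labels)]
        traits = traits.subset(taxa)

        stage("pgls")
        d = traits.data
        est = PGLS(tree=tree, estimate_kappa=config.estimate_kappa,
                   estimate_lambda=config.estimate_lambda,
                   estimate_delta=config.estimate_delta)
        est.fit(d["log10_body"].to_numpy(), d["log10_brain"].to_numpy(),
                taxa=taxa)
        fit = est.fit_
        scale_tests = {}
        for pname in ("kappa", "lambda_", "delta"):
            if est.scaling_[pname] != 1.0:
                constrained = PGLS(tree=tree).fit(
                    d["log10_body"].to_numpy(), d["log10_brain"].to_numpy(),
                    taxa=taxa)
                t = lr_test(est.log_likelihood_, constrained.log_likelihood_)
                scale_tests[pname] = {"estimate": est.scaling_[pname],
                                      "LR": t.statistic, "p": t.p_value}
        reg = pd.DataFrame([{
            "intercept": fit.intercept, "slope": fit.slope,
            "t": fit.t_statistic, "df": fit.df, "r_squared": fit.r_squared,
            "kappa": fit.kappa, "lambda": fit.lambda_, "delta": fit.delta,
            "log_likelihood": fit.log_likelihood,
        }]).set_index(pd.Index(["pgls"], name="model"))
        _tsv(reg, out / "regression.tsv")
        results["regression"] = reg
        line = allometry.AllometryLine.from_fit(fit)

        stage("residuals")
        resid = allometry.tip_residuals(traits, line)
        _tsv(resid.to_frame(), out / "tip_residuals.tsv")
        results["tip_residuals"] = resid

        stage("asr")
        values = {
            "brain": dict(zip(taxa, d["log10_brain"])),
            "body": dict(zip(taxa, d["log10_body"])),
            "relative": dict(resid),
        }
        node_tables = []
        estimates = {}
        for ti, (trait, vals) in enumerate(values.items()):
            for mi, method in enumerate(config.methods):
                settings = config.mcmc_settings(seed_offset=10 * ti + mi)
                rec = reconstruct.AncestralStates(
                    tree=tree, method=method, settings=settings)
                rec.fit(vals)
                if method == "mcmc":
                    manifest["acceptance_rates"][f"{trait}/{method}"] = \
                        rec.run_.acceptance_rate
                tab = rec.estimates_.copy()
                tab.insert(0, "trait", trait)
                tab.insert(1, "method", method)
                tab.insert(2, "clade", [
                    ",".join(sorted(tree.clade_tips(i))[:2]) for i in tab.index])
                node_tables.append(tab)
                estimates[(trait, method)] = rec.estimates_["estimate"]
        node_df = pd.concat(node_tables)
        _tsv(node_df, out / "node_estimates.tsv")
        results["node_estimates"] = node_df

        stage("congruence")
        rows = []
        for trait in values:
            ms = [m for m in config.methods]
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    a = estimates[(trait, ms[i])]
                    b = estimates[(trait, ms[j])]
                    c = reconstruct.congruence(a.to_numpy(), b.to_numpy(),
                                               labels=(ms[i], ms[j]))
                    rows.append({"trait": trait, "comparison":
                                 f"{ms[i]} vs {ms[j]}", "r_s": c.r_s,
                                 "p": c.p_value})
        if not config.no_fossils and traits.fossil_taxa:
            ext = [t for t in traits.extant_taxa]
            tree_nf = tree.drop_tips(traits.fossil_taxa)
            pairs = matched_internal_nodes(tree, tree_nf)
            for trait in ("brain", "body"):
                col = "log10_brain" if trait == "brain" else "log10_body"
                vals_nf = dict(zip(ext, traits.subset(ext).data[col]))
                est_nf = reconstruct.asr_ml(tree_nf, vals_nf)
                est_f = estimates[(trait, "ml")] if ("ml" in config.methods) \
                    else None
                if est_f is None:
                    continue
                a = [est_f.loc[na] for na, nb in pairs
                     if na in est_f.index and nb in est_nf.index]
                b = [est_nf.loc[nb, "estimate"] for na, nb in pairs
                     if na in est_f.index and nb in est_nf.index]
                if len(a) >= 3:
                    c = reconstruct.congruence(a, b)
                    rows.append({"trait": trait,
                                 "comparison": "with vs without fossils (ml)",
                                 "r_s": c.r_s, "p": c.p_value})
        cong = pd.DataFrame(rows, columns=["trait", "comparison", "r_s", "p"])
        _tsv(cong.set_index("trait"), out / "congruence.tsv")
        results["congruence"] = cong

        if config.directional:
            stage("trend-test")
            rows = []
            trend_data = {"body": values["body"], "brain": values["brain"],
                          "relative": values["relative"]}
            if tree.is_ultrametric():
                manifest["warnings"].append(
                    "tree is ultrametric: trend test skipped "
                    "(needs path-length variation)")
            else:
                for ti, (trait, vals) in enumerate(trend_data.items()):
                    comp, run_d, run_c = reconstruct.trend_test(
                        tree, vals,
                        settings=config.mcmc_settings(seed_offset=100 + ti))
                    manifest["acceptance_rates"][f"trend/{trait}"] = {
                        "directional": run_d.acceptance_rate,
                        "constant": run_c.acceptance_rate}
                    rows.append({
                        "trait": trait,
                        "log_hm_constant": comp.log_hm_b,
                        "log_hm_directional": comp.log_hm_a,
                        "bayes_factor": comp.bayes_factor,
                        "verdict": comp.verdict})
            trend = pd.DataFrame(rows)
            if len(trend):
                _tsv(trend.set_index("trait"), out / "trend_test.tsv")
            results["trend_test"] = trend

        stage("branch-changes")
        ref_method = "ml" if "ml" in config.methods else config.methods[0]
        n = tree.n_nodes
        change_tables = {}
        for trait, col in (("brain", "log10_brain"), ("body", "log10_body")):
            node_vals = np.empty(n)
            for t in taxa:
                node_vals[tree.tip(t)] = traits.data.loc[t, col]
            estv = estimates[(trait, ref_method)]
            for nid, v in estv.items():
                node_vals[nid] = v
            change_tables[trait] = branches.branch_changes(
                tree, node_vals, trait=trait)
        rel_vals = np.empty(n)
        for t in taxa:
            rel_vals[tree.tip(t)] = resid[t]
        for nid, v in estimates[("relative", ref_method)].items():
            rel_vals[nid] = v
        change_tables["relative"] = branches.branch_changes(
            tree, rel_vals, trait="relative")
        all_changes = pd.concat(change_tables.values())
        branches.write_branch_changes(all_changes, out / "branch_changes.tsv")
        results["branch_changes"] = all_changes

        census = {t: branches.decrease_census(
            change_tables[t],
            change_tables["body"] if t == "brain" else None, trait=t)
            for t in change_tables}
        cen = pd.DataFrame([{
            "trait": c.trait, "n_branches": c.n_branches,
            "n_decreasing": c.n_decreasing,
            "fraction_branches": c.fraction_branches,
            "fraction_time": c.fraction_time,
            "ratio_mean": c.ratio_mean, "ratio_min": c.ratio_min,
            "ratio_max": c.ratio_max,
        } for c in census.values()]).set_index("trait")
        _tsv(cen, out / "decrease_census.tsv")
        results["decrease_census"] = cen

        if config.scenario_grid:
            stage("scenarios")
            brain_census = census["brain"]
            env = (scen.envelope_from_census(brain_census)
                   if brain_census.ratios else scen.PRIMATE_DECREASE_ENVELOPE)
            root_est = estimates[("brain", ref_method)].iloc[-1]
            root_body = estimates[("body", ref_method)].iloc[-1]
            ancestors = [("reconstructed_root", 10.0 ** root_est,
                          10.0 ** root_body)]
            grid = scen.scenario_grid(
                ancestors, config.descendant_brain_g,
                config.descendant_body_kg, line, env)
            scen.write_scenarios(grid, out / "scenarios.tsv")
            results["scenarios"] = grid

        manifest["tables"] = sorted(p.name for p in out.glob("*.tsv"))
        manifest.pop("_stage", None)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(out / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage "
                           f"{_current_stage(manifest)}: {e}") from e
    return results


def _current_stage(manifest):
    return manifest.get("_stage", "unknown")
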