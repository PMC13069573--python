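"""End-to-end orchestration of the full analysis on one dataset.

``run_all`` wires the stages together: simulate (or load) inputs →
NEV → phenotype scores → group contrasts → within-pair decomposition →
top-divergence selection with semantic similarity → enrichment →
TF contingency → age asymmetry → synteny-orientation validation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import dupstats, io, ontology as onto, phenotypes, variability
from .simulate import SimulationDesign, simulate_all

__all__ = ["run_all", "analyze"]


def analyze(panel: io.ExpressionPanel, atlas: io.ConditionAtlas,
            pairs: io.ParalogTable, meta: pd.DataFrame,
            dag: onto.OntologyDAG, top_fraction: float = 0.05,
            ecotype: str | None = "Col-0",
            tissue: str | None = "seedling") -> dict:
    """Run every analysis stage on already-loaded inputs."""
    results: dict = {}

    nev_table, trends = variability.nev_pipeline(panel)
    nev = nev_table["nev_median"]
    results["nev"] = nev_table
    results["trends"] = trends

    resp = phenotypes.responsiveness(atlas, ecotype=ecotype, tissue=tissue)
    taus = phenotypes.tau_table(atlas)
    results["phenotypes"] = resp.join(taus)
    r, p = phenotypes.correlate(nev, resp["responsiveness"], method="pearson")
    rho, rho_p = phenotypes.correlate(nev, resp["responsiveness"],
                                      method="spearman")
    results["nev_responsiveness"] = {"pearson_r": r, "pearson_p": p,
                                     "spearman_rho": rho, "spearman_p": rho_p}

    groups = meta["status"]
    results["group_comparisons"] = dupstats.compare_groups(
        nev, groups,
        [("ssd", "singleton"), ("wgd", "singleton"), ("ssd", "wgd")])
    results["group_medians"] = {
        label: float(nev[groups == label].median())
        for label in ("singleton", "ssd", "wgd")}

    pair_table, low, high = dupstats.pair_min_max(nev, pairs)
    results["pair_min_max"] = pair_table
    singleton_nev = nev[groups == "singleton"].dropna().to_numpy()
    pooled = pd.Series(np.concatenate([low, singleton_nev, high]))
    pooled_groups = pd.Series(["pair_min"] * len(low)
                              + ["singleton"] * len(singleton_nev)
                              + ["pair_max"] * len(high))
    results["min_max_comparison"] = dupstats.compare_groups(
        pooled, pooled_groups,
        [("pair_max", "singleton"), ("singleton", "pair_min"),
         ("pair_max", "pair_min")])

    scored = dupstats.pair_scores(nev, pairs)
    top = dupstats.select_top_divergent(scored, fraction=top_fraction)
    results["top_divergent"] = top
    ssd_top = top[top["mode"] != "wgd"]
    wgd_top = top[top["mode"] == "wgd"]
    if len(ssd_top) >= 2 and len(wgd_top) >= 2:
        ssd_sim = onto.pairwise_similarity(ssd_top, dag)
        wgd_sim = onto.pairwise_similarity(wgd_top, dag)
        results["similarity"] = {"ssd": ssd_sim, "wgd": wgd_sim}
        results["similarity_comparison"] = onto.compare_divergent_similarity(
            ssd_sim, wgd_sim)
        background = set(meta.index)
        for side, col in (("high", "score_max"), ("low", "score_min")):
            which = ssd_top[["gene_a", "gene_b", "score_a", "score_b"]].copy()
            pick_a = (which["score_a"] >= which["score_b"]) == (side == "high")
            study = set(np.where(pick_a, which["gene_a"], which["gene_b"]))
            results[f"enrichment_ssd_{side}"] = onto.enrich(
                study, background, dag)

    results["tf_contingency"] = dupstats.tf_contingency(pairs, meta)

    clades = meta["clade"]
    div = dupstats.pair_divergence(nev, pairs, clades)
    ssd_modes = io.MODES - {"wgd"}
    results["age_asymmetry"] = {
        "ssd": dupstats.age_asymmetry(div, modes=ssd_modes),
        "wgd": dupstats.age_asymmetry(div, modes={"wgd"}),
    }
    try:
        results["synteny_validation"] = dupstats.validate_synteny_orientation(
            pairs.subset({"transposed"}), clades)
    except ValueError:
        results["synteny_validation"] = None
    return results


def run_all(design: SimulationDesign | None = None, seed: int | None = None,
            out_dir: str | Path | None = None) -> dict:
    """Simulate one study under ``design`` and run the whole analysis.

    Returns the simulated data plus every result table/summary; when
    ``out_dir`` is given, writes the main tables as TSV along with a
    run log.
    """
    if design is None:
        design = SimulationDesign()
    if seed is not None:
        design = SimulationDesign(**{**design.to_dict(), "seed": seed})
    data = simulate_all(design)
    dag = onto.OntologyDAG(
        data["ontology"][0].itertuples(index=False, name=None),
        data["ontology"][1])
    results = analyze(data["panel"], data["atlas"], data["pairs"],
                      data["meta"], dag)
    results.update(data)
    results["design"] = design

    if out_dir is not None:
        out_dir = Path(out_dir)
        truth_out = data["truth"].copy()
        truth_out["terms"] = truth_out["terms"].map(
            lambda s: "|".join(sorted(s)))
        io.write_results({
            "nev": results["nev"].rename_axis("gene").reset_index(),
            "phenotypes": results["phenotypes"].rename_axis("gene").reset_index(),
            "top_divergent": results["top_divergent"],
            "truth": truth_out.rename_axis("gene").reset_index(),
            "group_comparisons": pd.DataFrame(
                [c.to_dict() for c in results["group_comparisons"]]),
        }, out_dir)
        io.write_run_log(out_dir, "run-all", design.to_dict())
    return results
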