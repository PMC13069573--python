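"""Synthetic pipeline inputs with planted, recorded ground truth.

The generator emulates the structure of a per-seedling expression
study: a gene × individual × timepoint count panel with mean-dependent
overdispersion, duplication groups (singletons, SSD pairs, WGD pairs)
with planted variability shifts, a condition/tissue atlas whose
treatment responses are coupled to the planted variability, gene ages
(phylostratigraphic clade numbers) with a planted derived-copy
elevation for SSD pairs, transcription-factor flags, and a toy rooted
ontology with gene annotations.

Count model: negative binomial with per-gene mean m drawn log-
uniformly and variance = trend(m) × planted multiplier × m², where the
baseline CV² trend is 1/m + φ0 — the decreasing mean–variance coupling
the NEV normalization exists to remove.  A gene with planted
multiplier μ therefore has expected NEV log2(μ) by construction, which
makes parameter-recovery targets analytic.

Everything is deterministic given the design seed (numpy PCG64); each
stage derives an independent stream from (seed, stage index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ConditionAtlas, ExpressionPanel, ParalogTable

__all__ = ["SimulationDesign", "simulate_panel", "simulate_atlas",
           "simulate_meta", "simulate_all"]


@dataclass
class SimulationDesign:
    """Design of one synthetic study; defaults give the standard run.

    Variability multipliers act on the variance above the mean–CV²
    trend, so a group with multiplier μ has expected group-median NEV
    log2(μ).  ``ssd_derived_inflation`` multiplies on top of
    ``ssd_multiplier`` for the derived copy of each SSD pair, planting
    the derived/ancestral asymmetry.  ``gene_multiplier_sd`` adds
    symmetric per-gene log2-normal spread around the group multiplier
    (real NEV distributions are broad and continuous).
    """

    n_singletons: int = 800
    n_ssd_pairs: int = 400
    n_wgd_pairs: int = 400
    n_individuals: int = 14
    n_timepoints: int = 6
    # baseline dispersion curve: CV2_trend(m) = 1/m + phi0
    phi0: float = 0.05
    mean_range: tuple[float, float] = (5.0, 5000.0)
    singleton_multiplier: float = 1.0
    ssd_multiplier: float = 2.0
    wgd_multiplier: float = 2.0
    ssd_derived_inflation: float = 2.0
    gene_multiplier_sd: float = 0.5  # log2 units
    # gene ages: ancestral clade uniform 1..10, derived +U{1..5} capped at 15
    clade_tie_fraction: float = 0.05
    # transcription factors (pair-level flags; mixed pairs kept rare)
    tf_fraction: dict = field(default_factory=lambda: {
        "singleton": 0.10, "ssd": 0.05, "wgd": 0.20})
    mixed_tf_fraction: float = 0.02
    # duplication sub-modes for SSD pairs
    transposed_fraction: float = 0.3
    orientation_consistency: float = 0.9
    # atlas design
    n_tissues: int = 11
    n_treatments: int = 10
    responsiveness_base: float = 0.5
    responsiveness_coupling: float = 0.5
    responsiveness_noise_sd: float = 0.2
    # ontology design
    n_terms: int = 40
    ontology_depth: int = 4
    annotations_per_gene: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_singletons", "n_ssd_pairs", "n_wgd_pairs",
                     "n_individuals", "n_timepoints", "n_tissues",
                     "n_treatments", "n_terms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("singleton_multiplier", "ssd_multiplier",
                     "wgd_multiplier", "ssd_derived_inflation", "phi0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.clade_tie_fraction <= 1):
            raise ValueError("clade_tie_fraction must be in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.n_singletons + 2 * (self.n_ssd_pairs + self.n_wgd_pairs)

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_clades(rng: np.random.Generator, n_pairs: int,
                 tie_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """(ancestral, derived) clades; derived strictly younger except ties."""
    anc = rng.integers(1, 11, size=n_pairs)
    der = np.minimum(anc + rng.integers(1, 6, size=n_pairs), 15)
    # the cap can only tie when anc == 15, unreachable for anc <= 10
    tie = rng.random(n_pairs) < tie_fraction
    der = np.where(tie, anc, der)
    return anc, der


def simulate_panel(design: SimulationDesign
                   ) -> tuple[ExpressionPanel, pd.DataFrame]:
    """Draw the expression panel and the per-gene truth table.

    Truth columns: group, pair_id, role (ancestral/derived/NaN),
    base_mean, multiplier (realized, incl. per-gene spread), clade,
    is_tf, resp_scale, specificity, seed.
    """
    rng = design.rng(0)
    groups = (["singleton"] * design.n_singletons
              + ["ssd"] * (2 * design.n_ssd_pairs)
              + ["wgd"] * (2 * design.n_wgd_pairs))
    n = len(groups)
    genes = [f"g{i:05d}" for i in range(n)]

    pair_ids: list = [None] * design.n_singletons
    roles: list = [None] * design.n_singletons
    for i in range(design.n_ssd_pairs):
        pair_ids += [f"ssd{i:04d}"] * 2
        roles += ["ancestral", "derived"]
    for i in range(design.n_wgd_pairs):
        pair_ids += [f"wgd{i:04d}"] * 2
        roles += [None, None]

    group_mult = np.array([
        {"singleton": design.singleton_multiplier,
         "ssd": design.ssd_multiplier,
         "wgd": design.wgd_multiplier}[g] for g in groups])
    derived_ssd = np.array([g == "ssd" and r == "derived"
                            for g, r in zip(groups, roles)])
    mult = group_mult * np.where(derived_ssd, design.ssd_derived_inflation, 1.0)
    mult = mult * 2.0 ** rng.normal(0.0, design.gene_multiplier_sd, size=n)

    lo, hi = design.mean_range
    mean = 2.0 ** rng.uniform(math.log2(lo), math.log2(hi), size=n)

    # clades
    clade = np.full(n, np.nan)
    clade[: design.n_singletons] = rng.integers(1, 16, size=design.n_singletons)
    if design.n_ssd_pairs:
        anc, der = _draw_clades(rng, design.n_ssd_pairs,
                                design.clade_tie_fraction)
        s0 = design.n_singletons
        clade[s0: s0 + 2 * design.n_ssd_pairs: 2] = anc
        clade[s0 + 1: s0 + 2 * design.n_ssd_pairs: 2] = der
    if design.n_wgd_pairs:
        w0 = design.n_singletons + 2 * design.n_ssd_pairs
        clade[w0:] = rng.integers(1, 16, size=2 * design.n_wgd_pairs)

    # transcription-factor flags, assigned per pair (mixed pairs rare)
    is_tf = np.zeros(n, dtype=bool)
    is_tf[: design.n_singletons] = (
        rng.random(design.n_singletons) < design.tf_fraction["singleton"])
    for cls, n_pairs, offset in (
            ("ssd", design.n_ssd_pairs, design.n_singletons),
            ("wgd", design.n_wgd_pairs,
             design.n_singletons + 2 * design.n_ssd_pairs)):
        pair_tf = rng.random(n_pairs) < design.tf_fraction[cls]
        mixed = rng.random(n_pairs) < design.mixed_tf_fraction
        for i in range(n_pairs):
            a, b = offset + 2 * i, offset + 2 * i + 1
            if mixed[i]:
                is_tf[a], is_tf[b] = True, False
            else:
                is_tf[a] = is_tf[b] = pair_tf[i]

    # responsiveness scale, monotonically coupled to planted variability
    resp_scale = (design.responsiveness_base
                  + design.responsiveness_coupling * np.log2(mult)
                  + rng.normal(0.0, design.responsiveness_noise_sd, size=n))
    resp_scale = np.maximum(resp_scale, 0.0)
    specificity = rng.uniform(0.0, 1.0, size=n)

    # counts: NB(mean m, var = trend(m) * mult * m^2); var > m guaranteed
    trend_cv2 = 1.0 / mean + design.phi0
    var = trend_cv2 * mult * mean**2
    var = np.maximum(var, mean * (1 + 1e-9))
    nb_p = mean / var
    nb_n = mean**2 / (var - mean)
    shape = (n, design.n_individuals, design.n_timepoints)
    values = rng.negative_binomial(nb_n[:, None, None], nb_p[:, None, None],
                                   size=shape).astype(float)

    panel = ExpressionPanel(
        genes=genes,
        individuals=[f"ind{i:02d}" for i in range(design.n_individuals)],
        timepoints=[f"t{i}" for i in range(design.n_timepoints)],
        values=values,
    )
    truth = pd.DataFrame({
        "group": groups, "pair_id": pair_ids, "role": roles,
        "base_mean": mean, "multiplier": mult, "clade": clade,
        "is_tf": is_tf, "resp_scale": resp_scale,
        "specificity": specificity, "seed": design.seed,
    }, index=pd.Index(genes, name="gene"))
    return panel, truth


def simulate_atlas(design: SimulationDesign,
                   truth: pd.DataFrame) -> ConditionAtlas:
    """Condition/tissue atlas coupled to the planted truth.

    Treatment expression = baseline × 2^effect with effect ~
    N(0, resp_scale); a gene with resp_scale 0 equals its baseline in
    every treatment.  Tissue columns interpolate between uniform
    (specificity 0) and single-tissue (specificity 1) expression.
    """
    rng = design.rng(1)
    genes = truth.index
    n = len(genes)
    mean = truth["base_mean"].to_numpy()

    # the control carries a treatment label so the tissue panel is
    # exactly the dedicated tissue columns
    sample_rows = [("ctrl", "seedling", "control", np.nan, "Col-0")]
    values = {"ctrl": mean}
    for j in range(design.n_treatments):
        sid = f"trt{j:02d}"
        effect = rng.normal(0.0, 1.0, size=n) * truth["resp_scale"].to_numpy()
        values[sid] = mean * 2.0**effect
        sample_rows.append((sid, "seedling", f"treatment{j:02d}", "ctrl", "Col-0"))
    max_tissue = rng.integers(0, design.n_tissues, size=n)
    spec = truth["specificity"].to_numpy()
    for j in range(design.n_tissues):
        sid = f"tissue{j:02d}"
        off = 1.0 + (mean - 1.0) * (1.0 - spec)  # floor .. mean
        values[sid] = np.where(max_tissue == j, mean, off)
        sample_rows.append((sid, f"tissue{j:02d}", np.nan, np.nan, "Col-0"))

    samples = pd.DataFrame(
        sample_rows, columns=["sample", "tissue", "treatment",
                              "baseline", "ecotype"]).set_index("sample")
    return ConditionAtlas(pd.DataFrame(values, index=genes), samples)


def _random_tree(rng: np.random.Generator, n_terms: int,
                 depth: int) -> tuple[list[tuple[str, str]], list[str]]:
    """Random rooted tree (child, parent) edges and its leaves."""
    names = [f"T{i:03d}" for i in range(n_terms)]
    node_depth = {names[0]: 0}
    edges = []
    for i in range(1, n_terms):
        candidates = [t for t, d in node_depth.items() if d < depth]
        parent = candidates[rng.integers(0, len(candidates))]
        edges.append((names[i], parent))
        node_depth[names[i]] = node_depth[parent] + 1
    children = {p for _, p in edges}
    leaves = [t for t in names if t not in children]
    return edges, leaves


def simulate_meta(design: SimulationDesign, truth: pd.DataFrame
                  ) -> tuple[pd.DataFrame, ParalogTable,
                             tuple[pd.DataFrame, dict], pd.DataFrame]:
    """Gene metadata, paralog table, ontology file pair, updated truth.

    SSD copies of a pair draw annotation terms from two disjoint
    root-level subtrees (planting functional divergence); WGD copies
    share one term set.  Transposed pairs carry parent/daughter
    orientation labels consistent with the clades for a configurable
    majority of pairs.  Returns the truth with an added ``terms``
    column.
    """
    rng = design.rng(2)
    truth = truth.copy()
    genes = list(truth.index)

    # --- paralog table -----------------------------------------------------
    rows = []
    ssd_modes = ["tandem", "proximal", "dispersed"]
    for pid in pd.unique(truth["pair_id"].dropna()):
        members = truth.index[truth["pair_id"] == pid]
        a, b = members[0], members[1]
        if truth.loc[a, "group"] == "wgd":
            mode, orientation = "wgd", "unknown"
        else:
            if rng.random() < design.transposed_fraction:
                mode = "transposed"
                # a is ancestral (parent) by construction in simulate_panel
                consistent = rng.random() < design.orientation_consistency
                orientation = "A_is_parent" if consistent else "B_is_parent"
            else:
                mode = ssd_modes[rng.integers(0, len(ssd_modes))]
                orientation = "unknown"
        ks = float(rng.gamma(2.0, 0.5)) if mode != "wgd" else float(rng.gamma(4.0, 0.5))
        rows.append((a, b, mode, orientation, ks))
    pairs = ParalogTable(pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "mode", "orientation", "ks"]))

    # --- ontology ----------------------------------------------------------
    edges, leaves = _random_tree(rng, design.n_terms, design.ontology_depth)
    root = "T000"
    root_children = sorted(c for c, p in edges if p == root)
    subtree_leaves: dict[str, list] = {}
    parent_of = dict(edges)
    for leaf in leaves:
        t = leaf
        while parent_of.get(t) not in (None, root):
            t = parent_of[t]
        subtree_leaves.setdefault(t, []).append(leaf)
    branches = [subtree_leaves[c] for c in root_children if c in subtree_leaves]
    if len(branches) < 2:  # guarantee two disjoint leaf pools
        half = max(1, len(leaves) // 2)
        branches = [leaves[:half], leaves[half:]]

    def sample_terms(pool) -> frozenset:
        k = min(design.annotations_per_gene, len(pool))
        return frozenset(rng.choice(pool, size=k, replace=False))

    annotations: dict[str, frozenset] = {}
    for gene in genes:
        if truth.loc[gene, "group"] != "ssd":
            annotations[gene] = sample_terms(leaves)
    for pid in pd.unique(truth["pair_id"].dropna()):
        members = truth.index[truth["pair_id"] == pid]
        if truth.loc[members[0], "group"] != "ssd":
            # WGD copies share one conserved term set
            shared = sample_terms(leaves)
            annotations[members[0]] = annotations[members[1]] = shared
        else:
            i, j = rng.choice(len(branches), size=2, replace=False)
            annotations[members[0]] = sample_terms(branches[i])
            annotations[members[1]] = sample_terms(branches[j])
    truth["terms"] = truth.index.map(lambda g: annotations.get(g, frozenset()))

    # --- gene metadata -----------------------------------------------------
    meta = pd.DataFrame({
        "status": truth["group"],
        "clade": truth["clade"],
        "is_tf": truth["is_tf"],
        "go_terms": truth["terms"],
        "mean_expression": truth["base_mean"],
    }, index=truth.index)
    edges_df = pd.DataFrame(edges, columns=["child", "parent"])
    return meta, pairs, (edges_df, annotations), truth


def simulate_all(design: SimulationDesign) -> dict:
    """Run all three generators; keys: panel, truth, atlas, meta, pairs,
    ontology (edges DataFrame, annotations dict)."""
    panel, truth = simulate_panel(design)
    atlas = simulate_atlas(design, truth)
    meta, pairs, ontology, truth = simulate_meta(design, truth)
    return {"panel": panel, "truth": truth, "atlas": atlas,
            "meta": meta, "pairs": pairs, "ontology": ontology}
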